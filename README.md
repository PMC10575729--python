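# m6amseq

Single-base identification of cap-adjacent **m6Am**
(N6,2′-O-dimethyladenosine) from a four-library IP-sequencing design, with
ribosome-profiling integration.

m6Am sits on the first transcribed nucleotide, adjacent to the m7G cap.
The anti-m6A antibody used in MeRIP-style experiments pulls down both
internal m6A and cap m6Am; the two are separated by an in-vitro FTO
demethylation contrast, since FTO erases m6Am far more efficiently than
internal m6A. `m6amseq` implements the complete computational side of
such an experiment for analysts working in transcript coordinates:

* **simulate** — a truth-annotated transcriptome and four libraries
  (input, m7G-IP, FTO− m6A-IP, FTO+ m6A-IP) with configurable IP
  enrichment, FTO selectivity, stoichiometry, fragment model and seed;
* **tracks** — per-transcript depth and read-start vectors, cpm
  normalization, bedGraph import/export;
* **callpeaks** — sliding-window IP/input enrichment, FTO-depletion
  filtering and cap-proximity filtering (BED output);
* **callsites** — per-adenosine scoring inside peaks with
  `m1 = start/depth` in the FTO− arm (cap signature) and
  `m2 = (d− − d+)/d−` on cpm depths (FTO sensitivity), combined as
  `score = m1·m2`;
* **motif** — position frequency matrix and IUPAC consensus over 30-nt
  site-centered contexts;
* **te** — translation efficiency `TE = fp_cpm/rna_cpm` (pseudocounted)
  and translation ratios with symmetric log2 ±1 classification;
* **integrate** — shared modified genes across samples, overlap with
  TE-changed genes, Venn partitions and reports.

See `docs/methods.md` for the underlying model, parameter defaults and
limitations.

## Worked example

Run the pipeline at its default scale (two simulated replicates, 200
transcripts — 50 with a cap m6Am and 50 with an internal m6A —
2×10⁵ fragments per library) and inspect the results:

```bash
m6amseq run-all --seed 3 --outdir demo_run
```

```text
$ head -3 demo_run/sites.tsv | cut -f1-3,5-7
transcript_id  gene_id   position  m1   m2                  score
tx0001         gene0001  0         1.0  0.6269430051813472  0.6269430051813472
tx0003         gene0003  0         1.0  0.689873417721519   0.689873417721519
$ head -1 demo_run/motif.pfm
#consensus  NNNNNNNNNNNNNNAVKVWMKMGCRSVYKK  n_sites  50
$ cat demo_run/report/summary.txt
m6Am / translation integration summary

  modified genes in rep1: 50
  modified genes in rep2: 49
  shared modified genes: 49
  translationally changed genes: 35
  venn (modified-only / TE-only / both): 24 / 10 / 25
  overlap: 25 of 49 shared modified genes (51.0%)
```

Reading this output: every called site is an adenosine at transcript
position 0 with `m1 = 1` — all IP fragments covering it start on it, the
cap signature — and `m2 ≈ 0.6–0.7`, meaning FTO treatment removed most of
its IP coverage; the product is the m6Am score. In the consensus line
column 15 is the site A; with default settings all sites sit at position
0, so the 5′ flank is N-padded and the downstream columns are random
sequence (run with `sim.cap_window ≥ 1` to expose the "CA" dinucleotide
context). The summary counts genes modified in both replicates (49 of the
50 planted) and their overlap with translationally upregulated genes from
the paired Ribo-Seq simulation, in which half of the modified genes were
given a planted TE increase.

The same stages run standalone on intermediate files
(`m6amseq simulate|tracks|callpeaks|callsites|motif|te|integrate`), each
accepting `--config config.yaml` with every threshold exposed; a Python
API mirrors the CLI (`import m6amseq`).

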