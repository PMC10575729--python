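# Methods

`m6amseq` identifies cap-adjacent N6,2′-O-dimethyladenosine (m6Am) at
single-base resolution from a four-library immunoprecipitation (IP)
sequencing design, and relates the modified genes to ribosome-profiling
translation changes. This note describes the model behind each stage, the
tunable parameters, the synthetic-data generator used for validation, and
the design choices that were genuinely open.

## The assay model

Four libraries are sequenced from the same fragmented RNA:

| library | selection | what it measures |
|---|---|---|
| `INPUT` | none | fragment background |
| `M7G_IP` | anti-m7G | cap-carrying (5′-terminal) fragments |
| `M6A_IP_FTO_MINUS` | anti-m6A, untreated | m6A **and** m6Am fragments |
| `M6A_IP_FTO_PLUS` | anti-m6A after in-vitro FTO | what survives demethylation |

The anti-m6A antibody cannot distinguish internal m6A from cap m6Am; the
discriminating axis is in-vitro FTO treatment, which under the assay's
conditions erases m6Am with high efficiency while leaving internal m6A
largely intact. A cap m6Am therefore appears as an IP-enriched,
FTO-sensitive, cap-proximal signal; an internal m6A is IP-enriched but
FTO-resistant.

All coordinates are transcript-space, 0-based, half-open; position 0 is
the first transcribed nucleotide. Reads are transcript-sense, so a
fragment's "start" is its 5′-most position.

## Per-nucleotide statistics

For each position inside a candidate peak:

* `m1 = (FTO− start reads) / (FTO− depth)` — the fraction of untreated-IP
  fragments covering the position that *begin* on it. No fragment of a
  capped molecule can extend 5′ of the cap, so at a true cap-adjacent
  site every covering fragment starts there and m1 → 1, while interior
  positions sit at the fragmentation background (≈ 1/fragment-length).
  m1 uses raw counts: the ratio is scale-free.
* `m2 = (FTO− depth − FTO+ depth) / (FTO− depth)` — relative coverage
  loss after FTO treatment, computed on cpm-normalized depths because it
  compares two libraries; clamped to [0, 1] (sampling noise can push the
  treated arm above the untreated one), 0 when the denominator is 0.
* `score = m1 × m2` by default. The product is the minimal combination
  that is high only when a position is simultaneously a dominant start
  (cap signature) and demethylation-sensitive; `min` and `mean` are
  selectable via `sites.combiner`. This combination rule is a package
  choice — the two components are standard, their combination into a
  single ranking is not canonically fixed.

A site call requires base A (T/U alphabet agnostic), FTO− IP depth ≥
`min_site_depth` (default 10 fragments) and `score ≥ min_score` (default
0.1). Several sites per peak are allowed. The reported context is the
30-nt site-centered sense sequence (14 nt of 5′ flank, the site, 15 nt of
3′ flank), N-padded at transcript edges.

## Peak calling and filtering

1. **Enrichment scan** — windows of `window` nt (default 25) every `step`
   nt (default 5, plus a tail window): kept when
   `(mean FTO− IP cpm + pc) / (mean input cpm + pc) ≥ min_fold` (defaults
   pc = 0.5 cpm, fold 2) **and** mean raw IP depth ≥ `min_ip_depth`
   (default 5). Kept windows are merged (overlapping or book-ended), and
   summit (max FTO− IP cpm depth; ties break to the smallest coordinate)
   and enrichment are recomputed on the merged interval.
2. **FTO sensitivity** — `fto_depletion = 1 − mean(FTO+ cpm)/mean(FTO− cpm)`
   within the peak, clamped to [0, 1]; retained when ≥ `min_depletion`
   (default 0.3).
3. **Cap proximity** — summit ≤ `max_tss_distance` (default 100 nt) and,
   when an m7G-IP library exists, m7G-IP/input cpm fold ≥ `m7g_min_fold`
   (default 2) within the peak; without an m7G library the distance test
   alone applies (logged).

The thresholds are conventional MeRIP-style values; the assay literature
gives qualitative criteria only, so every one is exposed in the config.
All fold statistics use cpm with a symmetric pseudocount so library-size
differences cannot masquerade as enrichment. The enrichment scan alone
has an appreciable false-positive rate at these defaults (tens of windows
per 200-transcript null run); it is the conjunction with the FTO and cap
filters that drives the null peak count to ~0, which is how the filter
chain is meant to be used and how it is validated.

## Translation efficiency

`TE = (footprint CDS cpm + pc) / (mRNA cpm + pc)` per gene and condition
(pc default 0.5 cpm); `TR = TE_condition / TE_control`. A gene is
TE-downregulated when `log2(TR) ≤ −1` (halving) and upregulated
symmetrically at `≥ +1`, boundaries inclusive; the threshold is a
parameter (`te.log2_threshold`). Genes absent from either table are
dropped (logged), as are genes with zero control TE. TE and TR are
invariant under library-wide rescaling of any count table.

Gene-level counts are the input; footprint-to-CDS assignment (P-site
offsetting, periodicity QC) is upstream of this package.

## Integration

Gene identity is the join key: a gene counts once per sample however many
sites it carries. `shared_modified_genes` intersects per-sample gene
sets; `overlap_with_te` reports the overlap of the shared set with a
TE-changed set as a percentage with one decimal (NaN sentinel when the
shared set is empty). Site-level replicate intersection with ±2 nt
tolerance is available (`shared_sites`) but off by default.

## The synthetic-data generator

The generator emulates the statistical structure the assay depends on,
not sequencing chemistry:

* **Transcripts** — lengths uniform on [500, 1500] nt, random sequence,
  5′UTR/CDS/3′UTR boundaries drawn within realistic ranges. A configured
  fraction (default 0.25) carries one cap m6Am; an independently drawn
  fraction (default 0.25) carries one internal m6A embedded in a GGACT
  (DRACH-like) context inside the CDS. Cap sites are at position 0 by
  default; with `cap_window > 0` they fall at positions 1..window with an
  encoded C immediately 5′ (TSS heterogeneity), which is what makes the
  "CA" motif observable in the consensus.
* **Fragments** — lengths from a truncated normal (mean 30, sd 5,
  min 20 nt). A molecule of available length L fragments into ~L/len
  pieces exactly one of which is 5′-terminal, so a sampled fragment is
  the terminal one (start = cap position) with probability len/L and
  starts uniformly in the interior otherwise. This terminal share is the
  physical origin of the cap start-pileup that m1 measures; a naive
  uniform-start model underrepresents terminal fragments by a factor of
  ~len and erases the signal.
* **IP selection** — rejection sampling: acceptance weight
  `ip_enrichment` (default 5) for fragments overlapping a methylated
  position (molecule-level methylation is Bernoulli(stoichiometry),
  default 0.8), weight 1 otherwise. The m7G arm weights 5′-terminal
  fragments instead. In the FTO+ arm each m6Am (m6A) mark is erased with
  probability `fto_efficiency_m6am` = 0.9 (`fto_efficiency_m6a` = 0.05)
  *before* IP selection. Defaults for stoichiometry, enrichment and
  efficiencies are calibration choices in the range reported for such
  assays, not measured values.
* **Determinism** — all randomness flows from per-library
  `numpy.random.Generator` streams keyed on the seed; fixed seed ⇒
  bit-identical outputs everywhere, including the full pipeline.

Features of real data deliberately not modeled: genome coordinates and
splicing, sequencing errors and quality scores, duplicate fragments,
antibody off-target binding, non-uniform fragmentation, multi-isoform
genes, batch effects. Passing validation therefore demonstrates that the
statistics recover the planted structure under the assay's own
assumptions, not robustness to those nuisances.

### Synthetic TE counts

`simulate_te_counts` draws per-gene RNA abundance (log-normal, σ = 0.7)
shared between conditions and a baseline TE (σ = 0.3); condition
footprint expectations are multiplied by `2^log2_tr` and all four tables
are Poisson at the target depth. Because cpm normalization measures
ratios against the library total, a net shift in composition offsets
every gene's apparent log2 TR by `log2(Σe / Σe·2^t)`; the generator
rescales the abundance of down-shifted genes so this shift is exactly
zero in expectation. When effects are all in one direction no balance is
possible and the shift remains — exactly the composition bias cpm suffers
on real data, which is why the pipeline's own TE simulation keeps a
background of down-shifted genes.

## Validation problem sizes

The standard validation conditions are 200 transcripts, 50 cap m6Am
(stoichiometry 0.8) and 50 internal m6A, 5× IP enrichment, FTO
efficiencies 0.9/0.05 and 2×10⁵ fragments per library, repeated over 20
seeds; the null control uses the same scale with no modifications and
enrichment 1. Translation-ratio recovery uses 15 genes (3 per log2 TR
class in {−2, −1, 0, +1, +2}) at 10⁶ expected counts per table: with
~6–7×10⁴ counts per gene the per-gene sampling error in log2 TR is
≈0.02–0.04, comfortably inside the ±0.1 recovery claim, whereas spreading
the same depth over many more genes makes the worst-case Poisson error
alone exceed that precision. Classification accuracy is scored away from
the ±1 boundaries, where sampling noise legitimately flips labels.

## Numerical choices and degenerate inputs

* Zero denominators in m1/m2 yield 0, never an error; `start > depth` is
  a data-consistency error.
* `fto_depletion` and m2 are clamped at 0 when the treated arm exceeds
  the untreated one.
* Window merging is idempotent; summit ties break to the smallest
  coordinate; outputs are sorted by (transcript, position) so all
  artifacts are byte-stable.
* Transcripts shorter than one window are skipped by the scan; empty
  inputs produce empty outputs with exit code 0 throughout.
* PFM columns consisting only of N (possible when every site sits at the
  transcript edge) are reported as uniform 0.25 with consensus letter N.

## Known limitations

* Stoichiometry is not estimated, only used in simulation; the score is a
  detection statistic, not a quantitative methylation level.
* No significance model for peaks or sites (no Poisson/NB test, no FDR);
  the null false-positive rate is controlled empirically by the filter
  conjunction and characterised by simulation.
* The m1 statistic presumes cap-adjacent sites; m6Am at internal
  positions of multi-TSS genes would need an isoform-aware model.
* cpm is the only implemented normalization; strongly skewed libraries
  would warrant a robust scale factor.
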