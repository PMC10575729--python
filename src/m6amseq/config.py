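"""Run configuration: every pipeline tunable in one validated structure.

The YAML layout mirrors the stages::

    seed: 0
    n_replicates: 2
    sim: {n_transcripts: 200, depth_per_library: 200000, ...}
    peaks: {window: 25, step: 5, min_fold: 2.0, ...}
    sites: {min_score: 0.1, min_site_depth: 10, combiner: product}
    te: {pseudocount: 0.5, log2_threshold: 1.0}
    te_sim: {effect_log2: 1.5, frac_modified_affected: 0.5, ...}

Unknown keys anywhere are rejected with an error naming the key; every
run writes the fully resolved configuration next to its outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .simulate import SimParams

__all__ = ["PeakParams", "SiteParams", "TEParams", "TESimParams", "RunConfig"]


def _check_keys(d: dict, known: set[str], where: str) -> None:
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {where} config keys: {sorted(unknown)}")


@dataclass
class PeakParams:
    window: int = 25
    step: int = 5
    min_fold: float = 2.0
    min_ip_depth: float = 5.0
    pseudocount: float = 0.5
    min_depletion: float = 0.3
    max_tss_distance: int = 100
    m7g_min_fold: float = 2.0


@dataclass
class SiteParams:
    min_score: float = 0.1
    min_site_depth: int = 10
    combiner: str = "product"


@dataclass
class TEParams:
    pseudocount: float = 0.5
    log2_threshold: float = 1.0


@dataclass
class TESimParams:
    """Synthetic Ribo-Seq/RNA-Seq counts paired with the simulated
    transcriptome: a fraction of m6Am-modified genes receive a planted
    TE increase in the 'condition' sample, plus background changers."""

    depth: int = 1_000_000
    effect_log2: float = 1.5
    frac_modified_affected: float = 0.5
    n_background_up: int = 10
    n_background_down: int = 10


_BLOCKS = {
    "sim": SimParams,
    "peaks": PeakParams,
    "sites": SiteParams,
    "te": TEParams,
    "te_sim": TESimParams,
}


@dataclass
class RunConfig:
    seed: int = 0
    n_replicates: int = 2
    sim: SimParams = field(default_factory=SimParams)
    peaks: PeakParams = field(default_factory=PeakParams)
    sites: SiteParams = field(default_factory=SiteParams)
    te: TEParams = field(default_factory=TEParams)
    te_sim: TESimParams = field(default_factory=TESimParams)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        _check_keys(d, {"seed", "n_replicates", *_BLOCKS}, "top-level")
        kwargs: dict = {}
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        if "n_replicates" in d:
            kwargs["n_replicates"] = int(d["n_replicates"])
        for name, klass in _BLOCKS.items():
            block = d.get(name, {})
            if not isinstance(block, dict):
                raise ValueError(f"config block {name!r} must be a mapping")
            _check_keys(block, set(klass.__dataclass_fields__), name)
            kwargs[name] = klass(**block)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        # the simulator's own seed is slaved to the run seed
        self.sim.seed = self.seed
        self.sim.validate()
        if self.sites.combiner not in ("product", "min", "mean"):
            raise ValueError(f"unknown score combiner {self.sites.combiner!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
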