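"""Analysis configuration with the study's default numeric constants."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass
class AnalysisConfig:
    """Every tunable constant of the pipeline, with the study defaults.

    Distances and windows are in base pairs unless noted.
    """

    # tTRE calling
    peak_window: int = 300          # local-maximum scan window (centred)
    pair_min_gap: int = 50          # min minus->plus TSS separation
    pair_max_gap: int = 250         # max minus->plus TSS separation
    dedup_window: int = 150         # single-strand peak deduplication window
    min_peak_height: float = 5.0    # merged-track height floor for peaks
    quant_flank: int = 100          # counting flank around the tTRE span

    # variability
    variability_fdr: float = 0.2
    pi0_lambda: float = 0.5
    pseudocount_rpm: float = 1.0
    max_sample_pairs: int = 2000    # between-individual pair subsample cap

    # co-expression
    max_pair_distance: int = 5_000_000
    pairs_per_bin: int = 1000
    auc_range: tuple[int, int] = (0, 200_000)
    auc_percentile: float = 5.0     # upper tail percentile for decay curves
    background_n: int = 2_000_000   # null correlation draws
    genotype_r_max: float = 0.05
    genotype_fdr: float = 0.1
    maf_min: float = 0.05
    mrna_rpkm_min: float = 1.0
    mrna_tss_match: int = 250
    mrna_max_distance: int = 1_000_000

    # strand orientation
    adjacent_min: int = 250
    adjacent_max: int = 10_000
    loess_k: int = 200
    orientation_test_bin: tuple[int, int] = (500, 1500)

    # Hi-C
    hic_resolution: int = 5000
    hic_adjacent_resolution: int = 1000
    hic_max_distance: int = 500_000

    # TF dependency permutation null
    n_permutations: int = 1000
    permutation_site_grid: tuple[int, ...] = (
        5000, 10000, 20000, 40000, 70000
    )
    intersection_threshold: int = 2  # ">= 2 sites" vs "<= 1 site" grouping

    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "peak_window", "pair_min_gap", "pair_max_gap", "dedup_window",
            "quant_flank", "max_pair_distance", "pairs_per_bin",
            "adjacent_min", "adjacent_max", "hic_resolution",
            "hic_max_distance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.auc_percentile < 100:
            raise ValueError("auc_percentile must be in (0, 100)")
        if not 0 < self.pi0_lambda < 1:
            raise ValueError("pi0_lambda must be in (0, 1)")

    def replace(self, **kwargs: Any) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("auc_range", "orientation_test_bin", "permutation_site_grid"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_yaml(self, path: str) -> None:
        doc = dataclasses.asdict(self)
        for key in ("auc_range", "orientation_test_bin", "permutation_site_grid"):
            doc[key] = list(doc[key])
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
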