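"""Shared domain types for the tTRE co-expression pipeline.

Coordinates are 0-based, half-open throughout; a TSS is a single 0-based
base position. Strands are "+" / "-"; "." marks unstranded intervals.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class StrandedTrack:
    """Sparse per-chromosome, per-strand map of base position -> 5' read count.

    Counts are stored as parallel sorted ``positions`` / ``counts`` numpy
    arrays per (chrom, strand), the natural container for single-base
    capped-RNA 5' signal.
    """

    def __init__(self, library_id: str, chrom_sizes: dict[str, int]):
        self.library_id = library_id
        self.chrom_sizes = dict(chrom_sizes)
        # (chrom, strand) -> (positions int64 sorted unique, counts float64)
        self._data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}

    def set_counts(
        self, chrom: str, strand: str, positions: np.ndarray, counts: np.ndarray
    ) -> None:
        if chrom not in self.chrom_sizes:
            raise KeyError(f"chromosome {chrom!r} not in chrom_sizes")
        if strand not in STRANDS:
            raise ValueError(f"bad strand {strand!r}")
        positions = np.asarray(positions, dtype=np.int64)
        counts = np.asarray(counts, dtype=np.float64)
        if positions.size:
            order = np.argsort(positions, kind="stable")
            positions, counts = positions[order], counts[order]
            # collapse duplicate positions
            uniq, inverse = np.unique(positions, return_inverse=True)
            if uniq.size != positions.size:
                summed = np.zeros(uniq.size)
                np.add.at(summed, inverse, counts)
                positions, counts = uniq, summed
            if positions[0] < 0 or positions[-1] >= self.chrom_sizes[chrom]:
                raise ValueError(
                    f"position outside chromosome {chrom} "
                    f"(length {self.chrom_sizes[chrom]})"
                )
            if np.any(counts < 0):
                raise ValueError("negative counts")
            keep = counts > 0
            positions, counts = positions[keep], counts[keep]
        self._data[(chrom, strand)] = (positions, counts)

    def add_counts(
        self, chrom: str, strand: str, positions: np.ndarray, counts: np.ndarray
    ) -> None:
        old_p, old_c = self.counts(chrom, strand)
        self.set_counts(
            chrom,
            strand,
            np.concatenate([old_p, np.asarray(positions, dtype=np.int64)]),
            np.concatenate([old_c, np.asarray(counts, dtype=np.float64)]),
        )

    def counts(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted (positions, counts) arrays; empty arrays if nothing stored."""
        return self._data.get(
            (chrom, strand),
            (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.float64)),
        )

    @property
    def total(self) -> float:
        return float(sum(c.sum() for _, c in self._data.values()))

    def keys(self) -> Iterable[tuple[str, str]]:
        return self._data.keys()


@dataclass
class TTRE:
    """One transcribed TRE: a divergent minus/plus TSS pair.

    The minus-strand TSS lies 50-250 bp upstream of the plus-strand TSS so
    the two nascent transcripts point away from each other.
    """

    id: str
    chrom: str
    minus_tss: int
    plus_tss: int
    class_label: str = "unknown"
    variable: bool = False

    def __post_init__(self) -> None:
        if self.plus_tss <= self.minus_tss:
            raise ValueError(
                f"tTRE {self.id}: plus TSS must be downstream of minus TSS"
            )

    @property
    def gap(self) -> int:
        return self.plus_tss - self.minus_tss

    @property
    def span(self) -> GenomicInterval:
        # half-open span covering both TSS bases
        return GenomicInterval(self.chrom, self.minus_tss, self.plus_tss + 1)

    @property
    def center(self) -> float:
        return (self.minus_tss + self.plus_tss) / 2.0


@dataclass
class SampleDesign:
    """Cohort design: library -> individual map with replicate groups."""

    libraries: list[str]
    individual_of: dict[str, str]

    def __post_init__(self) -> None:
        missing = [lib for lib in self.libraries if lib not in self.individual_of]
        if missing:
            raise ValueError(f"libraries without individual: {missing}")

    @property
    def individuals(self) -> list[str]:
        seen: dict[str, None] = {}
        for lib in self.libraries:
            seen.setdefault(self.individual_of[lib], None)
        return list(seen)

    @property
    def replicate_groups(self) -> list[list[str]]:
        groups: dict[str, list[str]] = {}
        for lib in self.libraries:
            groups.setdefault(self.individual_of[lib], []).append(lib)
        return [g for g in groups.values() if len(g) >= 2]

    def library_indices_of_individual(self, individual: str) -> list[int]:
        return [
            i
            for i, lib in enumerate(self.libraries)
            if self.individual_of[lib] == individual
        ]


@dataclass
class ExpressionMatrix:
    """tTRE x library RPM matrices (total and per-strand) with the design.

    Normalisation is reads-per-million of the *library total* read count,
    not the in-tTRE total, so column sums equal 1e6 times the fraction of
    the library's reads falling in tTREs.
    """

    ttre_ids: list[str]
    library_ids: list[str]
    values_total: np.ndarray
    values_plus: np.ndarray
    values_minus: np.ndarray
    design: SampleDesign

    def __post_init__(self) -> None:
        shape = (len(self.ttre_ids), len(self.library_ids))
        for name in ("values_total", "values_plus", "values_minus"):
            v = getattr(self, name)
            if v.shape != shape:
                raise ValueError(f"{name} has shape {v.shape}, expected {shape}")
            if np.any(v < 0):
                raise ValueError(f"{name} contains negative values")

    def row(self, ttre_id: str) -> np.ndarray:
        return self.values_total[self.ttre_ids.index(ttre_id)]

    def subset(self, ttre_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.ttre_ids.index(t) for t in ttre_ids]
        return ExpressionMatrix(
            ttre_ids=list(ttre_ids),
            library_ids=list(self.library_ids),
            values_total=self.values_total[idx],
            values_plus=self.values_plus[idx],
            values_minus=self.values_minus[idx],
            design=self.design,
        )

    def collapse_to_individuals(self) -> tuple[list[str], np.ndarray]:
        """Average replicate libraries; returns (individuals, tTRE x individual)."""
        inds = self.design.individuals
        out = np.empty((len(self.ttre_ids), len(inds)))
        for j, ind in enumerate(inds):
            cols = self.design.library_indices_of_individual(ind)
            out[:, j] = self.values_total[:, cols].mean(axis=1)
        return inds, out


@dataclass
class TFSiteSet:
    """Named set of (unstranded) TF binding-site intervals, kept sorted."""

    tf_name: str
    sites: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sites = sorted(self.sites, key=lambda s: (s.chrom, s.start, s.end))

    def __len__(self) -> int:
        return len(self.sites)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """chrom -> (n, 2) array of [start, end), sorted by start."""
        out: dict[str, list[tuple[int, int]]] = {}
        for s in self.sites:
            out.setdefault(s.chrom, []).append((s.start, s.end))
        return {
            c: np.asarray(v, dtype=np.int64).reshape(-1, 2)
            for c, v in out.items()
        }

    def lengths(self) -> np.ndarray:
        return np.asarray([len(s) for s in self.sites], dtype=np.int64)


class ContactMatrix:
    """Symmetric sparse chromatin contact matrix over a binned genome.

    Bins partition each chromosome at the declared resolution; bin indices
    are global, chromosome blocks concatenated in ``chrom_sizes`` order.
    """

    def __init__(self, chrom_sizes: dict[str, int], resolution: int):
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        self.chrom_sizes = dict(chrom_sizes)
        self.resolution = int(resolution)
        self._values: dict[tuple[int, int], float] = {}
        self.bin_offsets: dict[str, int] = {}
        off = 0
        for chrom, size in self.chrom_sizes.items():
            self.bin_offsets[chrom] = off
            off += -(-size // resolution)
        self.n_bins = off

    def bin_of(self, chrom: str, position: int) -> int:
        return self.bin_offsets[chrom] + position // self.resolution

    def chrom_bin_range(self, chrom: str) -> tuple[int, int]:
        start = self.bin_offsets[chrom]
        return start, start + (-(-self.chrom_sizes[chrom] // self.resolution))

    def set(self, i: int, j: int, value: float) -> None:
        if value < 0:
            raise ValueError("contact values must be non-negative")
        self._values[(i, j)] = value
        self._values[(j, i)] = value

    def get(self, i: int, j: int) -> float:
        return self._values.get((i, j), 0.0)

    def items(self) -> Iterable[tuple[tuple[int, int], float]]:
        return self._values.items()

    def __len__(self) -> int:
        return len(self._values)
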