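"""Readers and writers for the pipeline's plain-text formats.

Formats: 4-column bedGraph (strand-specific 5' signal), BED3+ (TF peaks,
tTRE spans), tab-delimited tTRE/expression tables, 3-column contact
triplets, and the sample-design TSV. All coordinates 0-based half-open.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    ContactMatrix,
    ExpressionMatrix,
    GenomicInterval,
    SampleDesign,
    StrandedTrack,
    TFSiteSet,
    TTRE,
)


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def _bedgraph_arrays(path: str, chrom_sizes: dict[str, int], take_abs: bool):
    """Parse a bedGraph into per-chrom position/count arrays (expanded to base)."""
    per_chrom: dict[str, tuple[list, list]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if start < 0 or end <= start:
                raise ParseError(f"{path}:{lineno}: bad interval {start}-{end}")
            if chrom not in chrom_sizes:
                raise ParseError(
                    f"{path}:{lineno}: chromosome {chrom!r} not in chrom_sizes"
                )
            if take_abs:
                value = abs(value)
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative value {value}")
            if value == 0:
                continue
            pos_list, cnt_list = per_chrom.setdefault(chrom, ([], []))
            # expand multi-base intervals to per-base counts
            pos_list.append(np.arange(start, end, dtype=np.int64))
            cnt_list.append(np.full(end - start, value))
    out = {}
    for chrom, (pos_list, cnt_list) in per_chrom.items():
        out[chrom] = (np.concatenate(pos_list), np.concatenate(cnt_list))
    return out


def read_signal_track(
    plus_path: str,
    minus_path: str,
    chrom_sizes: dict[str, int],
    library_id: str = "",
) -> StrandedTrack:
    """Read one library's plus/minus bedGraph pair into a StrandedTrack.

    Minus-strand values may be stored negative (a common dialect); their
    absolute value is taken.
    """
    track = StrandedTrack(library_id or plus_path, chrom_sizes)
    for path, strand, take_abs in (
        (plus_path, "+", False),
        (minus_path, "-", True),
    ):
        for chrom, (pos, cnt) in _bedgraph_arrays(
            path, chrom_sizes, take_abs
        ).items():
            track.add_counts(chrom, strand, pos, cnt)
    return track


def write_signal_track(track: StrandedTrack, plus_path: str, minus_path: str) -> None:
    """Write per-base bedGraph files (minus strand written with positive values)."""
    handles = {"+": open(plus_path, "w"), "-": open(minus_path, "w")}
    try:
        for (chrom, strand) in sorted(track.keys()):
            pos, cnt = track.counts(chrom, strand)
            fh = handles[strand]
            for p, c in zip(pos, cnt):
                v = int(c) if float(c).is_integer() else c
                fh.write(f"{chrom}\t{p}\t{p + 1}\t{v}\n")
    finally:
        for fh in handles.values():
            fh.close()


def read_peak_bed(path: str, tf_name: str) -> TFSiteSet:
    """Read a BED3+ peak file (0-based half-open); duplicates retained."""
    sites = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if start < 0:
                raise ParseError(f"{path}:{lineno}: negative start")
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            sites.append(GenomicInterval(fields[0], start, end))
    return TFSiteSet(tf_name=tf_name, sites=sites)


def write_peak_bed(siteset: TFSiteSet, path: str) -> None:
    with open(path, "w") as fh:
        for s in siteset.sites:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{siteset.tf_name}\n")


_TTRE_FIXED_COLS = [
    "chrom", "start", "end", "id", "class_label", "variable",
    "minus_tss", "plus_tss",
]


def write_ttre_table(
    ttres: list[TTRE], matrix: ExpressionMatrix | None, path: str
) -> None:
    """Write the tab-delimited tTRE table, one RPM column per library.

    Round-trips losslessly with :func:`read_ttre_table`. Per-strand RPM
    values are written as additional ``<lib>:+`` / ``<lib>:-`` columns when
    a matrix is supplied.
    """
    ids = [t.id for t in ttres]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate tTRE ids: {dup}")
    rows = {
        "chrom": [t.chrom for t in ttres],
        "start": [t.span.start for t in ttres],
        "end": [t.span.end for t in ttres],
        "id": ids,
        "class_label": [t.class_label for t in ttres],
        "variable": [int(t.variable) for t in ttres],
        "minus_tss": [t.minus_tss for t in ttres],
        "plus_tss": [t.plus_tss for t in ttres],
    }
    if matrix is not None:
        if matrix.ttre_ids != ids:
            order = [matrix.ttre_ids.index(i) for i in ids]
        else:
            order = list(range(len(ids)))
        for j, lib in enumerate(matrix.library_ids):
            rows[lib] = matrix.values_total[order, j]
            rows[f"{lib}:+"] = matrix.values_plus[order, j]
            rows[f"{lib}:-"] = matrix.values_minus[order, j]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ttre_table(
    path: str, design: SampleDesign | None = None
) -> tuple[list[TTRE], ExpressionMatrix | None]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    ttres = [
        TTRE(
            id=str(r.id),
            chrom=r.chrom,
            minus_tss=int(r.minus_tss),
            plus_tss=int(r.plus_tss),
            class_label=str(r.class_label),
            variable=bool(r.variable),
        )
        for r in df.itertuples()
    ]
    extra = [c for c in df.columns if c not in _TTRE_FIXED_COLS]
    libs = [c for c in extra if not (c.endswith(":+") or c.endswith(":-"))]
    if not libs:
        return ttres, None
    if design is None:
        design = SampleDesign(
            libraries=libs, individual_of={lib: lib for lib in libs}
        )
    matrix = ExpressionMatrix(
        ttre_ids=[t.id for t in ttres],
        library_ids=libs,
        values_total=df[libs].to_numpy(dtype=float),
        values_plus=df[[f"{lib}:+" for lib in libs]].to_numpy(dtype=float),
        values_minus=df[[f"{lib}:-" for lib in libs]].to_numpy(dtype=float),
        design=design,
    )
    return ttres, matrix


def write_ttre_bed(ttres: list[TTRE], path: str) -> None:
    with open(path, "w") as fh:
        for t in ttres:
            fh.write(
                f"{t.chrom}\t{t.span.start}\t{t.span.end}\t{t.id}\t"
                f"{int(t.variable)}\t.\n"
            )


def read_contact_matrix(
    path: str, chrom_sizes: dict[str, int], resolution: int
) -> ContactMatrix:
    """Read a 3-column (bin_i, bin_j, value) triplet text file.

    The matrix is symmetrised on read; entries absent from the file are 0.
    Duplicate (i, j) entries are ambiguous and rejected.
    """
    matrix = ContactMatrix(chrom_sizes, resolution)
    seen: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            try:
                i, j = int(fields[0]), int(fields[1])
                value = float(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative contact value")
            if i >= matrix.n_bins or j >= matrix.n_bins or i < 0 or j < 0:
                raise ParseError(
                    f"{path}:{lineno}: bin index outside the declared "
                    f"partition ({matrix.n_bins} bins at {resolution} bp)"
                )
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ParseError(f"{path}:{lineno}: duplicate entry for {key}")
            seen.add(key)
            matrix.set(i, j, value)
    return matrix


def write_contact_matrix(matrix: ContactMatrix, path: str) -> None:
    with open(path, "w") as fh:
        for (i, j), v in sorted(matrix.items()):
            if i <= j:
                fh.write(f"{i}\t{j}\t{v:.10g}\n")


def read_design(path: str) -> SampleDesign:
    """Read a 2-column TSV: library_id <tab> individual_id (with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    libs = df.iloc[:, 0].tolist()
    inds = df.iloc[:, 1].tolist()
    return SampleDesign(libraries=libs, individual_of=dict(zip(libs, inds)))


def write_design(design: SampleDesign, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("library\tindividual\n")
        for lib in design.libraries:
            fh.write(f"{lib}\t{design.individual_of[lib]}\n")


def read_chrom_sizes(path: str) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                out[chrom] = int(size)
    return out


def write_chrom_sizes(chrom_sizes: dict[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
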