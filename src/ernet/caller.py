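"""Divergent-pair tTRE calling from merged strand-specific 5' tracks.

The caller scans each strand of the merged track for local maxima in a
centred window, deduplicates nearby peaks, and pairs plus-strand peaks
with a minus-strand peak 50-250 bp upstream — the divergent bidirectional
signature of transcribed regulatory elements. All steps are deterministic;
ties are broken toward the leftmost coordinate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig
from .types import ExpressionMatrix, SampleDesign, StrandedTrack, TTRE


@dataclass(frozen=True)
class StrandPeak:
    chrom: str
    position: int
    strand: str
    height: float

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("peak height must be positive")


def merge_tracks(tracks: list[StrandedTrack]) -> StrandedTrack:
    """Sum per-position, per-strand counts across libraries."""
    if not tracks:
        raise ValueError("no tracks to merge")
    sizes = tracks[0].chrom_sizes
    for t in tracks[1:]:
        if t.chrom_sizes != sizes:
            raise ValueError(
                f"chromosome set mismatch between {tracks[0].library_id!r} "
                f"and {t.library_id!r}"
            )
    merged = StrandedTrack("merged", sizes)
    keys = sorted({k for t in tracks for k in t.keys()})
    for chrom, strand in keys:
        pos = np.concatenate([t.counts(chrom, strand)[0] for t in tracks])
        cnt = np.concatenate([t.counts(chrom, strand)[1] for t in tracks])
        merged.set_counts(chrom, strand, pos, cnt)
    return merged


def find_local_maxima(
    track: StrandedTrack, window: int = 300, min_height: float = 0.0
) -> list[StrandPeak]:
    """Strand-specific local maxima within a centred window.

    A nonzero position p is a peak iff no position q in the open window
    (p - window/2, p + window/2) has a higher count, nor an equal count at
    q < p (leftmost tie wins).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    half = window // 2
    peaks: list[StrandPeak] = []
    for chrom, strand in sorted(track.keys()):
        pos, cnt = track.counts(chrom, strand)
        n = pos.size
        lo = np.searchsorted(pos, pos - half + 1, side="left")
        hi = np.searchsorted(pos, pos + half, side="left")  # exclusive
        for i in range(n):
            c = cnt[i]
            if c < min_height:
                continue
            window_cnt = cnt[lo[i] : hi[i]]
            if np.any(window_cnt > c):
                continue
            # equal count strictly to the left loses the tie
            left_cnt = cnt[lo[i] : i]
            if left_cnt.size and np.any(left_cnt == c):
                continue
            peaks.append(StrandPeak(chrom, int(pos[i]), strand, float(c)))
    return peaks


def deduplicate_peaks(peaks: list[StrandPeak], window: int = 150) -> list[StrandPeak]:
    """Greedy left-to-right dedup: of peaks closer than ``window``, keep the
    highest (leftmost on ties)."""
    out: list[StrandPeak] = []
    for peak in sorted(peaks, key=lambda p: p.position):
        if out and peak.position - out[-1].position < window:
            if peak.height > out[-1].height:
                out[-1] = peak
        else:
            out.append(peak)
    return out


def pair_divergent(
    plus_peaks: list[StrandPeak],
    minus_peaks: list[StrandPeak],
    min_gap: int = 50,
    max_gap: int = 250,
    spacing: int = 150,
) -> list[TTRE]:
    """Pair plus peaks with a minus peak 50-250 bp upstream into tTREs.

    Plus peaks are processed by descending height; each claims its highest
    qualifying unclaimed minus partner (leftmost on ties). Unpaired peaks
    are discarded. Emitted tTREs with any TSS within ``spacing`` bp of a
    higher-total tTRE's TSS are dropped as ambiguous.
    """
    by_chrom_minus: dict[str, list[StrandPeak]] = {}
    for p in sorted(minus_peaks, key=lambda p: p.position):
        by_chrom_minus.setdefault(p.chrom, []).append(p)
    minus_pos = {
        c: np.asarray([p.position for p in ps])
        for c, ps in by_chrom_minus.items()
    }
    claimed: dict[str, set[int]] = {c: set() for c in by_chrom_minus}

    candidates: list[tuple[StrandPeak, StrandPeak]] = []
    order = sorted(
        plus_peaks, key=lambda p: (-p.height, p.chrom, p.position)
    )
    for plus in order:
        if plus.chrom not in minus_pos:
            continue
        pos = minus_pos[plus.chrom]
        lo = int(np.searchsorted(pos, plus.position - max_gap, side="left"))
        hi = int(np.searchsorted(pos, plus.position - min_gap, side="right"))
        best = None
        for k in range(lo, hi):
            if k in claimed[plus.chrom]:
                continue
            cand = by_chrom_minus[plus.chrom][k]
            if best is None or cand.height > best[1].height:
                best = (k, cand)
        if best is not None:
            claimed[plus.chrom].add(best[0])
            candidates.append((best[1], plus))

    ttres = [
        TTRE(
            id="",
            chrom=plus.chrom,
            minus_tss=minus.position,
            plus_tss=plus.position,
        )
        for minus, plus in candidates
    ]
    totals = [m.height + p.height for m, p in candidates]

    # ambiguous-start screen: drop the lower-total of any two tTREs whose
    # TSSs come within `spacing` bp
    keep_order = sorted(
        range(len(ttres)),
        key=lambda i: (-totals[i], ttres[i].chrom, ttres[i].minus_tss),
    )
    kept: list[int] = []
    kept_tss: dict[str, list[int]] = {}
    for i in keep_order:
        t = ttres[i]
        existing = kept_tss.get(t.chrom, [])
        if any(
            abs(t.minus_tss - q) < spacing or abs(t.plus_tss - q) < spacing
            for q in existing
        ):
            continue
        kept.append(i)
        kept_tss.setdefault(t.chrom, []).extend([t.minus_tss, t.plus_tss])

    final = sorted(
        (ttres[i] for i in kept), key=lambda t: (t.chrom, t.minus_tss)
    )
    for k, t in enumerate(final):
        t.id = f"tTRE_{k:05d}"
    return final


def quantify_ttres(
    ttres: list[TTRE],
    tracks: list[StrandedTrack],
    flank: int = 100,
    design: SampleDesign | None = None,
) -> ExpressionMatrix:
    """Per-library per-strand RPM over [minus_tss - flank, plus_tss + flank].

    Values are normalised to reads-per-million of each library's total
    read count (both strands, genome-wide).
    """
    n, m = len(ttres), len(tracks)
    plus = np.zeros((n, m))
    minus = np.zeros((n, m))
    starts = np.asarray([t.minus_tss - flank for t in ttres])
    ends = np.asarray([t.plus_tss + flank for t in ttres])  # inclusive
    chroms = [t.chrom for t in ttres]
    by_chrom: dict[str, np.ndarray] = {}
    for i, c in enumerate(chroms):
        by_chrom.setdefault(c, [])
        by_chrom[c].append(i)
    by_chrom = {c: np.asarray(v) for c, v in by_chrom.items()}

    for j, track in enumerate(tracks):
        total = track.total
        if total <= 0:
            raise ValueError(f"library {track.library_id!r} has zero total reads")
        for chrom, idx in by_chrom.items():
            for strand, target in (("+", plus), ("-", minus)):
                pos, cnt = track.counts(chrom, strand)
                if pos.size == 0:
                    continue
                csum = np.concatenate([[0.0], np.cumsum(cnt)])
                lo = np.searchsorted(pos, starts[idx], side="left")
                hi = np.searchsorted(pos, ends[idx], side="right")
                target[idx, j] = csum[hi] - csum[lo]
        scale = 1e6 / total
        plus[:, j] *= scale
        minus[:, j] *= scale

    libs = [t.library_id for t in tracks]
    if design is None:
        design = SampleDesign(libraries=libs, individual_of={x: x for x in libs})
    return ExpressionMatrix(
        ttre_ids=[t.id for t in ttres],
        library_ids=libs,
        values_total=plus + minus,
        values_plus=plus,
        values_minus=minus,
        design=design,
    )


def call_ttres(
    tracks: list[StrandedTrack], config: AnalysisConfig | None = None
) -> tuple[list[TTRE], ExpressionMatrix]:
    """Full calling pipeline: merge, scan, dedup, pair, quantify."""
    cfg = config or AnalysisConfig()
    merged = merge_tracks(tracks)
    peaks = find_local_maxima(
        merged, window=cfg.peak_window, min_height=cfg.min_peak_height
    )
    plus = deduplicate_peaks(
        [p for p in peaks if p.strand == "+"], window=cfg.dedup_window
    )
    minus = deduplicate_peaks(
        [p for p in peaks if p.strand == "-"], window=cfg.dedup_window
    )
    ttres = pair_divergent(
        plus, minus,
        min_gap=cfg.pair_min_gap, max_gap=cfg.pair_max_gap,
        spacing=cfg.dedup_window,
    )
    matrix = quantify_ttres(ttres, tracks, flank=cfg.quant_flank)
    return ttres, matrix
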