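"""Strand-resolved co-expression of adjacent tTRE pairs.

For each tTRE and its nearest downstream neighbour, the per-strand signal
rows give three correlation categories: sense (same strand on both
elements), convergent (upstream plus with downstream minus — polymerases
pointing at each other), and divergent (upstream minus with downstream
plus). LOESS curves summarise the distance trend, and a t-test in a short
distance window compares convergent vs divergent correlation. The same
machinery compares adjacent with interleaved pairs (one tTRE in between).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from .coexpression import standardize_rows
from .types import ExpressionMatrix, TTRE


def adjacent_pairs(
    ttres: list[TTRE],
    min_d: int = 250,
    max_d: int = 10_000,
) -> pd.DataFrame:
    """Nearest (adjacent) and second-nearest (interleaved) downstream pairs.

    Distance is between the facing TSSs: upstream plus_tss to downstream
    minus_tss. Pairs outside [min_d, max_d] are dropped. Columns: ttre_a,
    ttre_b, chrom, distance, interleaved.
    """
    rows = []
    by_chrom: dict[str, list[TTRE]] = {}
    for t in ttres:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom, group in sorted(by_chrom.items()):
        group = sorted(group, key=lambda t: t.center)
        for i, a in enumerate(group):
            for offset, interleaved in ((1, False), (2, True)):
                if i + offset >= len(group):
                    continue
                b = group[i + offset]
                dist = b.minus_tss - a.plus_tss
                if min_d <= dist <= max_d:
                    rows.append(
                        {
                            "ttre_a": a.id,
                            "ttre_b": b.id,
                            "chrom": chrom,
                            "distance": dist,
                            "interleaved": interleaved,
                        }
                    )
    return pd.DataFrame(
        rows, columns=["ttre_a", "ttre_b", "chrom", "distance", "interleaved"]
    )


def orientation_correlations(
    pairs: pd.DataFrame, matrix: ExpressionMatrix
) -> pd.DataFrame:
    """Add r_sense, r_convergent, r_divergent columns.

    r_convergent = r(A plus, B minus); r_divergent = r(A minus, B plus);
    r_sense = mean of r(A+, B+) and r(A-, B-). Zero-variance strand rows
    leave the affected category as NaN.
    """
    Zp, up = standardize_rows(matrix.values_plus)
    Zm, um = standardize_rows(matrix.values_minus)
    row = {t: i for i, t in enumerate(matrix.ttre_ids)}

    def corr(Z1, u1, i, Z2, u2, j):
        if not (u1[i] and u2[j]):
            return np.nan
        return float(np.dot(Z1[i], Z2[j]))

    out = pairs.copy()
    sense, conv, div = [], [], []
    for rec in pairs.itertuples():
        i, j = row[rec.ttre_a], row[rec.ttre_b]
        pp = corr(Zp, up, i, Zp, up, j)
        mm = corr(Zm, um, i, Zm, um, j)
        sense.append(np.nanmean([pp, mm]) if not (
            np.isnan(pp) and np.isnan(mm)
        ) else np.nan)
        conv.append(corr(Zp, up, i, Zm, um, j))
        div.append(corr(Zm, um, i, Zp, up, j))
    out["r_sense"] = sense
    out["r_convergent"] = conv
    out["r_divergent"] = div
    return out


def loess_curve(
    distances: np.ndarray, values: np.ndarray, k: int = 200
) -> np.ndarray:
    """Local linear regression over each point's k nearest neighbours on
    the distance axis, evaluated at each observed distance.

    The window is the contiguous block of k nearest points in sorted
    distance order and the fit within it is ordinary least squares, so
    k = n reduces exactly to a single global linear regression. k is
    reduced to n (with a warning) when fewer points are available.
    """
    d = np.asarray(distances, dtype=float)
    v = np.asarray(values, dtype=float)
    ok = ~(np.isnan(d) | np.isnan(v))
    n = int(ok.sum())
    if n < 10:
        raise ValueError(f"need >= 10 points, got {n}")
    if k > n:
        import warnings

        warnings.warn(f"k={k} reduced to n={n}")
        k = n
    order = np.argsort(d[ok], kind="stable")
    ds = d[ok][order]
    vs = v[ok][order]

    # k-NN window of each point is contiguous in sorted order; slide its
    # left edge forward while the right neighbour is closer
    starts = np.empty(n, dtype=np.int64)
    left = 0
    for i in range(n):
        left = max(left, i - k + 1)
        left = min(left, n - k)
        while left + k < n and left < i and (
            ds[left + k] - ds[i] < ds[i] - ds[left]
        ):
            left += 1
        starts[i] = left

    c1 = np.concatenate([[0.0], np.cumsum(np.ones(n))])
    cx = np.concatenate([[0.0], np.cumsum(ds)])
    cy = np.concatenate([[0.0], np.cumsum(vs)])
    cxx = np.concatenate([[0.0], np.cumsum(ds * ds)])
    cxy = np.concatenate([[0.0], np.cumsum(ds * vs)])
    lo, hi = starts, starts + k
    sn = c1[hi] - c1[lo]
    sx = cx[hi] - cx[lo]
    sy = cy[hi] - cy[lo]
    sxx = cxx[hi] - cxx[lo]
    sxy = cxy[hi] - cxy[lo]
    denom = sn * sxx - sx * sx
    slope = np.where(denom > 0, (sn * sxy - sx * sy) / np.where(denom > 0, denom, 1.0), 0.0)
    intercept = (sy - slope * sx) / sn
    fitted_sorted = intercept + slope * ds

    fitted = np.full(d.size, np.nan)
    idx = np.flatnonzero(ok)[order]
    fitted[idx] = fitted_sorted
    return fitted


@dataclass
class OrientationTest:
    bin_lo: float
    bin_hi: float
    n_pairs: int
    mean_convergent: float
    mean_divergent: float
    t_welch: float
    p_welch: float
    t_paired: float
    p_paired: float


def orientation_test(
    pairs: pd.DataFrame,
    bin_range: tuple[int, int] = (500, 1500),
    min_pairs: int = 10,
) -> OrientationTest:
    """Convergent vs divergent correlation within a distance window.

    Welch two-sample t-test (one-sided would overstate; two-sided
    reported) plus the paired variant, since both categories come from
    the same pairs.
    """
    lo, hi = bin_range
    sub = pairs[(pairs["distance"] >= lo) & (pairs["distance"] <= hi)]
    sub = sub.dropna(subset=["r_convergent", "r_divergent"])
    if len(sub) < min_pairs:
        raise ValueError(
            f"only {len(sub)} pairs in [{lo}, {hi}] (need {min_pairs})"
        )
    conv = sub["r_convergent"].to_numpy()
    div = sub["r_divergent"].to_numpy()
    if np.allclose(conv, div):
        t_w, p_w, t_p, p_p = 0.0, 1.0, 0.0, 1.0
    else:
        welch = stats.ttest_ind(conv, div, equal_var=False)
        paired = stats.ttest_rel(conv, div)
        t_w, p_w = float(welch.statistic), float(welch.pvalue)
        t_p, p_p = float(paired.statistic), float(paired.pvalue)
    return OrientationTest(
        bin_lo=float(lo),
        bin_hi=float(hi),
        n_pairs=len(sub),
        mean_convergent=float(conv.mean()),
        mean_divergent=float(div.mean()),
        t_welch=t_w,
        p_welch=p_w,
        t_paired=t_p,
        p_paired=p_p,
    )


def adjacent_vs_interleaved_test(
    pairs: pd.DataFrame,
    value_column: str = "r_convergent",
    bin_range: tuple[int, int] = (500, 1500),
    min_pairs: int = 10,
) -> dict:
    """Welch t-test of adjacent vs interleaved correlation in the window."""
    lo, hi = bin_range
    sub = pairs[(pairs["distance"] >= lo) & (pairs["distance"] <= hi)]
    sub = sub.dropna(subset=[value_column])
    adj = sub.loc[~sub["interleaved"], value_column].to_numpy()
    inter = sub.loc[sub["interleaved"], value_column].to_numpy()
    if len(adj) < min_pairs or len(inter) < min_pairs:
        raise ValueError(
            f"underpopulated bin: {len(adj)} adjacent, {len(inter)} interleaved"
        )
    res = stats.ttest_ind(adj, inter, equal_var=False)
    return {
        "n_adjacent": int(len(adj)),
        "n_interleaved": int(len(inter)),
        "mean_adjacent": float(adj.mean()),
        "mean_interleaved": float(inter.mean()),
        "t": float(res.statistic),
        "p": float(res.pvalue),
    }
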