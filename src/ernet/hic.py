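"""Chromatin-contact integration for tTRE pairs.

Extracts the contact frequency between the bins holding each pair's tTRE
midpoints, subtracts a distance-matched background estimated from bins
free of tTREs (on the linear scale, before any log transform), builds
contact decay curves with the co-expression binning machinery, and reuses
the ΔAUC statistic on contacts for cross-modality comparison.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import coexpression
from .tf_dependency import delta_auc
from .types import ContactMatrix, TTRE

# arbitrary-unit overlay scale: 1 AU = 0.1 correlation = 4.5e-3 contact
AU_PER_CORRELATION = 1.0 / 0.1
AU_PER_CONTACT = 1.0 / 4.5e-3


def extract_pair_contacts(
    pairs: pd.DataFrame,
    matrix: ContactMatrix,
    ttres: list[TTRE],
    max_distance: int = 500_000,
) -> pd.DataFrame:
    """Contact frequency between the bins of each pair's tTRE midpoints.

    Pairs whose midpoints fall in the same bin are flagged (``same_bin``)
    and excluded from between-bin analyses; pairs beyond ``max_distance``
    are skipped (``n_skipped`` attr). Missing matrix entries read as 0.
    """
    center = {t.id: (t.chrom, int(t.center)) for t in ttres}
    rows = []
    n_skipped = 0
    for rec in pairs.itertuples():
        if rec.distance > max_distance:
            n_skipped += 1
            continue
        chrom_a, pos_a = center[rec.ttre_a]
        chrom_b, pos_b = center[rec.ttre_b]
        bin_a = matrix.bin_of(chrom_a, pos_a)
        bin_b = matrix.bin_of(chrom_b, pos_b)
        rows.append(
            {
                "ttre_a": rec.ttre_a,
                "ttre_b": rec.ttre_b,
                "chrom": rec.chrom,
                "distance": rec.distance,
                "r": getattr(rec, "r", np.nan),
                "bin_a": bin_a,
                "bin_b": bin_b,
                "raw_contact": matrix.get(bin_a, bin_b),
                "same_bin": bin_a == bin_b,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "ttre_a", "ttre_b", "chrom", "distance", "r",
            "bin_a", "bin_b", "raw_contact", "same_bin",
        ],
    )
    out.attrs["n_skipped"] = n_skipped
    return out


def contact_background(
    matrix: ContactMatrix,
    exclude: list[TTRE],
    max_distance: int = 500_000,
    draws_per_bin: int = 1000,
    seed: int = 0,
) -> dict[int, float]:
    """Mean contact between random non-TRE bin pairs per bin-distance.

    Returns {bin_distance (in bins, >= 1): mean contact}; distances with
    no qualifying bins are interpolated from neighbours.
    """
    rng = np.random.default_rng(seed)
    res = matrix.resolution
    ttre_bins: dict[str, set[int]] = {c: set() for c in matrix.chrom_sizes}
    for t in exclude:
        lo = t.span.start // res
        hi = (t.span.end - 1) // res
        for b in range(lo, hi + 1):
            ttre_bins[t.chrom].add(matrix.bin_offsets[t.chrom] + b)

    clean: dict[str, np.ndarray] = {}
    for chrom in matrix.chrom_sizes:
        lo, hi = matrix.chrom_bin_range(chrom)
        bins = np.asarray(
            [b for b in range(lo, hi) if b not in ttre_bins[chrom]]
        )
        if bins.size:
            clean[chrom] = bins
    if not clean:
        raise ValueError("every bin overlaps a tTRE; no background available")

    max_bins = max(1, max_distance // res)
    bg: dict[int, float] = {}
    missing = []
    chrom_list = list(clean)
    weights = np.asarray([clean[c].size for c in chrom_list], dtype=float)
    weights /= weights.sum()
    for d in range(1, max_bins + 1):
        vals = []
        attempts = 0
        while len(vals) < draws_per_bin and attempts < 20 * draws_per_bin:
            attempts += 1
            chrom = chrom_list[rng.choice(len(chrom_list), p=weights)]
            bins = clean[chrom]
            i = int(bins[rng.integers(0, bins.size)])
            j = i + d
            lo, hi = matrix.chrom_bin_range(chrom)
            if j >= hi or j in ttre_bins[chrom]:
                continue
            vals.append(matrix.get(i, j))
        if vals:
            bg[d] = float(np.mean(vals))
        else:
            missing.append(d)
    for d in missing:  # interpolate from nearest populated neighbours
        known = sorted(bg)
        if not known:
            raise ValueError("no background at any distance")
        lo_n = max((k for k in known if k < d), default=None)
        hi_n = min((k for k in known if k > d), default=None)
        if lo_n is None:
            bg[d] = bg[hi_n]
        elif hi_n is None:
            bg[d] = bg[lo_n]
        else:
            w = (d - lo_n) / (hi_n - lo_n)
            bg[d] = (1 - w) * bg[lo_n] + w * bg[hi_n]
    return bg


def subtract_background(
    contacts: pd.DataFrame, bg: dict[int, float]
) -> pd.DataFrame:
    """Linear-scale background subtraction, then log10 where positive.

    Negative adjusted contacts stay in linear analyses but are flagged
    (``log_valid`` False) and excluded from log-scale analyses.
    """
    out = contacts.copy()
    dist_bins = np.abs(
        out["bin_b"].to_numpy() - out["bin_a"].to_numpy()
    ).astype(int)
    bg_vals = np.asarray([bg.get(d, 0.0) if d > 0 else 0.0 for d in dist_bins])
    adjusted = out["raw_contact"].to_numpy(dtype=float) - bg_vals
    out["bg_at_distance"] = bg_vals
    out["adjusted"] = adjusted
    out["log_valid"] = adjusted > 0
    out["log_adjusted"] = np.where(
        adjusted > 0, np.log10(np.maximum(adjusted, 1e-300)), np.nan
    )
    return out


def contact_decay_curve(
    contacts: pd.DataFrame,
    percentile_spec: str = "median",
    pairs_per_bin: int = 1000,
    value_column: str = "adjusted",
    in_au: bool = False,
) -> coexpression.DecayCurve:
    """Distance-binned percentile curve of (adjusted) contacts.

    Same-bin pairs are excluded. ``in_au`` rescales contacts to the
    overlay's arbitrary units (1 AU per 4.5e-3 contact difference).
    """
    sub = contacts[~contacts["same_bin"]].copy()
    if value_column == "log_adjusted":
        sub = sub[sub["log_valid"]]
    if not len(sub):
        raise ValueError("no usable pairs")
    if in_au:
        sub = sub.copy()
        sub[value_column] = sub[value_column] * AU_PER_CONTACT
    bins = coexpression.bin_by_distance(
        sub, mode="equal_count", pairs_per_bin=pairs_per_bin
    )
    return coexpression.decay_curve(
        sub, bins, percentile_spec=percentile_spec, value_column=value_column
    )


def hic_delta_auc(
    contacts: pd.DataFrame,
    labels: np.ndarray,
    auc_range: tuple[int, int] = (0, 200_000),
    percentile_spec: str = "median",
    pairs_per_bin: int = 1000,
    min_bins: int = 5,
    value_column: str = "adjusted",
) -> tuple[float, float, float]:
    """ΔAUC on contact values, same machinery and sign as co-expression."""
    mask = (~contacts["same_bin"]).to_numpy()
    if value_column == "log_adjusted":
        mask &= contacts["log_valid"].to_numpy()
    return delta_auc(
        contacts["distance"].to_numpy(dtype=float)[mask],
        contacts[value_column].to_numpy(dtype=float)[mask],
        np.asarray(labels, dtype=bool)[mask],
        auc_range=auc_range,
        percentile_spec=percentile_spec,
        pairs_per_bin=pairs_per_bin,
        min_bins=min_bins,
    )


def compare_modalities(
    tf_results_procap: pd.DataFrame,
    tf_results_hic: pd.DataFrame,
    outlier_z: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join the two TF panels and correlate ΔAUC across modalities.

    Returns (per-TF table with outlier flags, per-mode summary with
    Pearson/Spearman correlations). Outliers are TFs whose residual from
    a robust (Theil-Sen) cross-modality regression exceeds ``outlier_z``
    MAD-standardised units.
    """
    a = tf_results_procap[["tf_name", "mode", "delta_auc", "z"]].rename(
        columns={"delta_auc": "delta_procap", "z": "z_procap"}
    )
    b = tf_results_hic[["tf_name", "mode", "delta_auc", "z"]].rename(
        columns={"delta_auc": "delta_hic", "z": "z_hic"}
    )
    joined = a.merge(b, on=["tf_name", "mode"], how="inner")
    dropped = sorted(
        set(a["tf_name"]).symmetric_difference(set(b["tf_name"]))
    )
    if dropped:
        import warnings

        warnings.warn(f"TFs absent from one modality dropped: {dropped}")
    joined["outlier"] = False
    summaries = []
    for mode, sub in joined.groupby("mode"):
        x = sub["delta_procap"].to_numpy()
        y = sub["delta_hic"].to_numpy()
        if len(sub) >= 3 and x.std() > 0 and y.std() > 0:
            pear = float(stats.pearsonr(x, y).statistic)
            spear = float(stats.spearmanr(x, y).statistic)
            # robust fit so a single discordant TF cannot mask itself
            slope = stats.theilslopes(y, x).slope
            intercept = float(np.median(y - slope * x))
            resid = y - (slope * x + intercept)
            scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
            if scale > 0:
                joined.loc[sub.index, "outlier"] = (
                    np.abs(resid / scale) > outlier_z
                )
        else:
            pear = spear = np.nan
        summaries.append(
            {"mode": mode, "n_tfs": len(sub), "pearson": pear, "spearman": spear}
        )
    return joined, pd.DataFrame(summaries)
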