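"""Distance-dependent pairwise co-expression of variably expressed tTREs.

Pearson correlations between all intrachromosomal tTRE pairs within a
distance cap, distance-binned percentile decay curves, an empirical
Gaussian null fitted to interchromosomal (or >1 Mb) correlations,
BH-corrected significance, genotype-independence filtering, and
tTRE-to-mRNA correlation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, StrandedTrack, TTRE

PERCENTILE_SPECS = ("upper5", "median", "p95_low")


def standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows centred and scaled so that r(a, b) = Z[a] . Z[b].

    Returns (Z, usable) where usable flags rows with nonzero variance.
    """
    X = np.asarray(values, dtype=float)
    centred = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((centred**2).sum(axis=1))
    usable = norms > 0
    Z = np.zeros_like(centred)
    Z[usable] = centred[usable] / norms[usable, None]
    return Z, usable


def pearson_rows(x: np.ndarray, y: np.ndarray) -> float:
    """Plain Pearson correlation of two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValueError("zero-variance input")
    return float((xc * yc).sum() / denom)


def pairwise_correlation(
    matrix: ExpressionMatrix,
    ttres: list[TTRE],
    max_distance: int = 5_000_000,
) -> pd.DataFrame:
    """All intrachromosomal tTRE pairs with centre distance <= cap.

    The matrix should already be restricted to variably expressed tTREs.
    Pairs are emitted with member a upstream of b; zero-variance rows are
    excluded from pairing. Columns: ttre_a, ttre_b, idx_a, idx_b, chrom,
    distance, r.
    """
    id_to_row = {t: i for i, t in enumerate(matrix.ttre_ids)}
    Z, usable = standardize_rows(matrix.values_total)

    recs_a, recs_b = [], []
    chroms_out, dists = [], []
    by_chrom: dict[str, list[TTRE]] = {}
    for t in ttres:
        i = id_to_row.get(t.id)
        if i is None or not usable[i]:
            continue
        by_chrom.setdefault(t.chrom, []).append(t)

    for chrom, group in sorted(by_chrom.items()):
        group = sorted(group, key=lambda t: t.center)
        centers = np.asarray([t.center for t in group])
        rows = np.asarray([id_to_row[t.id] for t in group])
        hi = np.searchsorted(centers, centers + max_distance, side="right")
        for i in range(len(group)):
            j = np.arange(i + 1, hi[i])
            if j.size == 0:
                continue
            recs_a.append(np.full(j.size, rows[i]))
            recs_b.append(rows[j])
            chroms_out.append(np.full(j.size, chrom, dtype=object))
            dists.append(centers[j] - centers[i])

    if not recs_a:
        return pd.DataFrame(
            columns=["ttre_a", "ttre_b", "idx_a", "idx_b", "chrom", "distance", "r"]
        )
    ia = np.concatenate(recs_a)
    ib = np.concatenate(recs_b)
    r = np.einsum("ij,ij->i", Z[ia], Z[ib])
    ids = np.asarray(matrix.ttre_ids, dtype=object)
    return pd.DataFrame(
        {
            "ttre_a": ids[ia],
            "ttre_b": ids[ib],
            "idx_a": ia,
            "idx_b": ib,
            "chrom": np.concatenate(chroms_out),
            "distance": np.concatenate(dists),
            "r": np.clip(r, -1.0, 1.0),
        }
    )


FIXED_EDGES_KB = [0, 1, 2, 4, 8, 16, 32, 64, 128, 256, 512, 1024]


def bin_by_distance(
    pairs: pd.DataFrame,
    mode: str = "equal_count",
    pairs_per_bin: int = 1000,
    min_final_fraction: float = 0.2,
) -> list[np.ndarray]:
    """Partition pair rows into distance bins.

    ``fixed_edges``: doubling edges 0-1, 1-2, 2-4, ... 512-1024 kb.
    ``equal_count``: consecutive blocks of ``pairs_per_bin`` pairs sorted
    by distance; a final partial block under 20% of the bin size is
    dropped. Returns positional index arrays into ``pairs``.
    """
    d = pairs["distance"].to_numpy(dtype=float)
    order = np.argsort(d, kind="stable")
    if mode == "fixed_edges":
        edges = np.asarray(FIXED_EDGES_KB, dtype=float) * 1000.0
        out = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            mask = (d >= lo) & (d < hi)
            if mask.any():
                out.append(np.flatnonzero(mask))
        return out
    if mode != "equal_count":
        raise ValueError(f"unknown binning mode {mode!r}")
    if d.size < pairs_per_bin:
        return [order] if d.size else []
    bins = [
        order[k : k + pairs_per_bin] for k in range(0, d.size, pairs_per_bin)
    ]
    if len(bins) > 1 and bins[-1].size < min_final_fraction * pairs_per_bin:
        bins = bins[:-1]
    return bins


def upper_tail_stat(values: np.ndarray, percentile: float) -> float:
    """The k-th highest value, k = ceil(percentile/100 * n).

    For the upper 5th percentile of 1000 values this is the 50th highest,
    i.e. the value with exactly ceil(0.05 n) - 1 members strictly above it
    for distinct values.
    """
    v = np.asarray(values, dtype=float)
    k = int(np.ceil(percentile / 100.0 * v.size))
    k = min(max(k, 1), v.size)
    return float(np.partition(v, v.size - k)[v.size - k])


def bin_stat(values: np.ndarray, spec: str) -> float:
    if spec == "upper5":
        return upper_tail_stat(values, 5.0)
    if spec == "median":
        return upper_tail_stat(values, 50.0)
    if spec == "p95_low":
        v = np.asarray(values, dtype=float)
        k = int(np.ceil(0.05 * v.size))
        k = min(max(k, 1), v.size)
        return float(np.partition(v, k - 1)[k - 1])
    raise ValueError(f"unknown percentile spec {spec!r}")


@dataclass
class DecayCurve:
    """Step function of a per-distance-bin order statistic."""

    bin_lo: np.ndarray      # lower distance bound per bin
    bin_hi: np.ndarray      # upper distance bound per bin
    stat: np.ndarray        # percentile value per bin
    n_per_bin: np.ndarray
    percentile_spec: str

    @property
    def auc(self) -> float:
        """Area under the step curve at unit bin-index width."""
        return float(self.stat.sum())

    def __len__(self) -> int:
        return self.stat.size


def decay_curve(
    pairs: pd.DataFrame,
    bins: list[np.ndarray],
    percentile_spec: str = "upper5",
    value_column: str = "r",
) -> DecayCurve:
    if not bins:
        raise ValueError("no bins")
    d = pairs["distance"].to_numpy(dtype=float)
    v = pairs[value_column].to_numpy(dtype=float)
    lo, hi, st, ns = [], [], [], []
    for idx in bins:
        lo.append(d[idx].min())
        hi.append(d[idx].max())
        st.append(bin_stat(v[idx], percentile_spec))
        ns.append(idx.size)
    return DecayCurve(
        bin_lo=np.asarray(lo),
        bin_hi=np.asarray(hi),
        stat=np.asarray(st),
        n_per_bin=np.asarray(ns),
        percentile_spec=percentile_spec,
    )


@dataclass
class CorrelationNull:
    """Gaussian null for Pearson r: mean fixed at 0, fitted sd."""

    sd: float
    source: str
    qq_statistic: float
    n_draws: int

    def p_two_sided(self, r: np.ndarray) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(np.asarray(r)) / self.sd)


def background_null(
    matrix: ExpressionMatrix,
    ttres: list[TTRE],
    n_draws: int = 2_000_000,
    source: str = "interchromosomal",
    min_distance: int = 1_000_000,
    seed: int = 0,
) -> CorrelationNull:
    """Fit the spurious-correlation null from random qualifying pairs.

    ``interchromosomal``: random tTRE pairs on different chromosomes;
    ``beyond-1Mb``: same chromosome, centre distance > ``min_distance``.
    Draws are with replacement.
    """
    rng = np.random.default_rng(seed)
    id_to_row = {t: i for i, t in enumerate(matrix.ttre_ids)}
    Z, usable = standardize_rows(matrix.values_total)
    items = [
        (id_to_row[t.id], t.chrom, t.center)
        for t in ttres
        if t.id in id_to_row and usable[id_to_row[t.id]]
    ]
    rows = np.asarray([x[0] for x in items])
    chroms = np.asarray([x[1] for x in items], dtype=object)
    centers = np.asarray([x[2] for x in items])
    if rows.size < 2:
        raise ValueError("not enough usable tTREs")
    if source == "interchromosomal" and np.unique(chroms).size < 2:
        raise ValueError("interchromosomal null needs >= 2 chromosomes")

    draws = np.empty(n_draws)
    filled = 0
    while filled < n_draws:
        need = n_draws - filled
        a = rng.integers(0, rows.size, size=2 * need + 16)
        b = rng.integers(0, rows.size, size=2 * need + 16)
        if source == "interchromosomal":
            ok = chroms[a] != chroms[b]
        elif source == "beyond-1Mb":
            ok = (chroms[a] == chroms[b]) & (
                np.abs(centers[a] - centers[b]) > min_distance
            )
        else:
            raise ValueError(f"unknown null source {source!r}")
        a, b = a[ok][:need], b[ok][:need]
        if a.size == 0:
            raise ValueError(f"no qualifying pairs for source {source!r}")
        draws[filled : filled + a.size] = np.einsum(
            "ij,ij->i", Z[rows[a]], Z[rows[b]]
        )
        filled += a.size

    sd = float(draws.std())
    if sd <= 0:
        raise ValueError("degenerate null (sd = 0)")
    sorted_draws = np.sort(draws)
    theo = stats.norm.ppf(
        (np.arange(1, n_draws + 1) - 0.5) / n_draws, scale=sd
    )
    qq = float(np.max(np.abs(sorted_draws - theo)))
    return CorrelationNull(sd=sd, source=source, qq_statistic=qq, n_draws=n_draws)


def correlation_fdr(
    pairs: pd.DataFrame,
    null: CorrelationNull,
    bins: list[np.ndarray] | None = None,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Two-sided empirical-null p per pair, BH q, per-bin significant fraction."""
    out = pairs.copy()
    p = null.p_two_sided(out["r"].to_numpy())
    out["r_p"] = p
    out["q"] = stats.false_discovery_control(p, method="bh") if p.size else p
    frac = None
    if bins is not None:
        sig = out["q"].to_numpy() < fdr
        frac = np.asarray([sig[idx].mean() for idx in bins])
    return out, frac


# ---------------------------------------------------------------- genotype


def snp_maf(genotypes: np.ndarray) -> np.ndarray:
    """Minor allele frequency per SNP row of a 0/1/2 matrix."""
    f = np.asarray(genotypes, dtype=float).mean(axis=1) / 2.0
    return np.minimum(f, 1.0 - f)


def genotype_independence(
    pairs: pd.DataFrame,
    ttres: list[TTRE],
    genotypes: np.ndarray,
    snp_chroms: np.ndarray,
    snp_positions: np.ndarray,
    maf_min: float = 0.05,
    r_max: float = 0.05,
    fdr: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove tTRE pairs whose local genotypes are correlated in the cohort.

    For each tTRE, SNPs falling in its span with MAF > ``maf_min`` are its
    local genotype; tTREs with no such SNP are genotype-independent by
    definition. A pair with local SNPs on both sides is scored by the
    maximum absolute cross-correlation (and its minimum Pearson p over SNP
    pairs); pairs significant at BH FDR < ``fdr`` are removed from the
    main set, and the strict set additionally requires max |r| < r_max.

    Returns (annotated pairs with ``genotype_r``, ``genotype_q``,
    ``retained``, ``strict`` columns, report frame).
    """
    G = np.asarray(genotypes, dtype=float)
    n_ind = G.shape[1]
    maf = snp_maf(G)
    informative = (maf > maf_min) & (G.std(axis=1) > 0)

    snp_chroms = np.asarray(snp_chroms, dtype=object)
    snp_positions = np.asarray(snp_positions, dtype=np.int64)

    local: dict[str, np.ndarray] = {}
    for t in ttres:
        mask = (
            informative
            & (snp_chroms == t.chrom)
            & (snp_positions >= t.span.start)
            & (snp_positions < t.span.end)
        )
        idx = np.flatnonzero(mask)
        if idx.size:
            local[t.id] = idx

    Zg, _ = standardize_rows(G)
    out = pairs.copy()
    n = len(out)
    geno_r = np.full(n, np.nan)
    geno_p = np.full(n, np.nan)
    a_ids = out["ttre_a"].to_numpy()
    b_ids = out["ttre_b"].to_numpy()
    for k in range(n):
        sa = local.get(a_ids[k])
        sb = local.get(b_ids[k])
        if sa is None or sb is None:
            continue
        cross = Zg[sa] @ Zg[sb].T
        r_abs = np.abs(cross)
        geno_r[k] = float(r_abs.max())
        # two-sided Pearson p via the t transform, min over SNP pairs
        r_clip = min(geno_r[k], 1.0 - 1e-12)
        t_stat = r_clip * np.sqrt((n_ind - 2) / (1.0 - r_clip**2))
        geno_p[k] = float(2.0 * stats.t.sf(t_stat, df=n_ind - 2))

    tested = ~np.isnan(geno_p)
    qvals = np.full(n, np.nan)
    if tested.any():
        qvals[tested] = stats.false_discovery_control(geno_p[tested], method="bh")
    removed = tested & (qvals < fdr)
    out["genotype_r"] = geno_r
    out["genotype_q"] = qvals
    out["retained"] = ~removed
    out["strict"] = ~tested | (geno_r < r_max)
    report = pd.DataFrame(
        {
            "n_pairs": [n],
            "n_tested": [int(tested.sum())],
            "n_removed": [int(removed.sum())],
            "n_strict": [int(out["strict"].sum())],
        }
    )
    return out, report


# ------------------------------------------------------------------- mRNA


def mrna_tss_select(
    annotations: pd.DataFrame,
    promoter_ttres: list[TTRE],
    procap: StrandedTrack,
    match: int = 250,
    signal_window: int = 20,
) -> pd.DataFrame:
    """One representative TSS per gene.

    ``annotations`` columns: gene, chrom, strand, tss (one row per
    annotated TSS). Candidates are TSSs within ``match`` bp of a promoter
    tTRE span; among candidates the one with the highest strand-matched
    5' signal in tss +/- ``signal_window`` wins (leftmost on ties). Genes
    with no candidate are dropped.
    """
    prom_by_chrom: dict[str, list[TTRE]] = {}
    for t in promoter_ttres:
        prom_by_chrom.setdefault(t.chrom, []).append(t)
    spans = {
        c: np.asarray([[t.span.start, t.span.end] for t in ts])
        for c, ts in prom_by_chrom.items()
    }

    records = []
    for gene, sub in annotations.groupby("gene", sort=True):
        best = None  # (-signal, tss) minimised
        for row in sub.itertuples():
            sp = spans.get(row.chrom)
            if sp is None:
                continue
            dist = np.maximum(sp[:, 0] - row.tss, row.tss - (sp[:, 1] - 1))
            if not np.any(dist <= match):
                continue
            pos, cnt = procap.counts(row.chrom, row.strand)
            lo = np.searchsorted(pos, row.tss - signal_window, side="left")
            hi = np.searchsorted(pos, row.tss + signal_window, side="right")
            signal = float(cnt[lo:hi].sum())
            key = (-signal, row.tss)
            if best is None or key < best[0]:
                best = (key, row)
        if best is not None:
            row = best[1]
            records.append(
                {
                    "gene": gene,
                    "chrom": row.chrom,
                    "strand": row.strand,
                    "tss": int(row.tss),
                }
            )
    return pd.DataFrame(records, columns=["gene", "chrom", "strand", "tss"])


def ttre_mrna_correlation(
    matrix: ExpressionMatrix,
    mrna: pd.DataFrame,
    tss_map: pd.DataFrame,
    ttres: list[TTRE],
    rpkm_min: float = 1.0,
    max_distance: int = 1_000_000,
) -> pd.DataFrame:
    """Correlate tTRE nascent signal with mRNA expression per individual.

    ``mrna``: gene x individual expression frame (index = gene, columns
    match the design's individuals). Replicate tTRE libraries are
    collapsed by mean. Signed distance is negative when the tTRE lies
    upstream of the TSS in the gene's orientation.
    """
    individuals, collapsed = matrix.collapse_to_individuals()
    missing = [i for i in individuals if i not in mrna.columns]
    if missing:
        raise ValueError(f"mRNA matrix lacks individuals: {missing}")
    expr = mrna[individuals]
    keep = expr.mean(axis=1) >= rpkm_min
    expr = expr.loc[keep]

    Zt, usable_t = standardize_rows(collapsed)
    Zg, usable_g = standardize_rows(expr.to_numpy(dtype=float))
    gene_row = {g: i for i, g in enumerate(expr.index)}
    ttre_row = {t: i for i, t in enumerate(matrix.ttre_ids)}

    records = []
    tss_by_chrom: dict[str, list] = {}
    for row in tss_map.itertuples():
        if row.gene in gene_row and row.strand in ("+", "-"):
            tss_by_chrom.setdefault(row.chrom, []).append(row)
    for t in ttres:
        i = ttre_row.get(t.id)
        if i is None or not usable_t[i]:
            continue
        for row in tss_by_chrom.get(t.chrom, []):
            g = gene_row[row.gene]
            if not usable_g[g]:
                continue
            delta = t.center - row.tss
            if abs(delta) > max_distance:
                continue
            signed = delta if row.strand == "+" else -delta
            records.append(
                {
                    "ttre": t.id,
                    "gene": row.gene,
                    "signed_distance": signed,
                    "distance": abs(delta),
                    "r": float(np.dot(Zt[i], Zg[g])),
                }
            )
    return pd.DataFrame(
        records, columns=["ttre", "gene", "signed_distance", "distance", "r"]
    )
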