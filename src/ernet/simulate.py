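"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator plants a tTRE landscape (divergent TSS pairs 50-250 bp
apart, >= 150 bp spacing), latent log-activities with distance-decaying
correlation rho(d) = rho0 * exp(-d / lambda_d), a variably expressed
subset, TF site sets whose intersection/occupancy damps or boosts the
planted correlation, distance-decaying contact matrices with a
co-expression-linked boost, biallelic genotypes with optional planted
SNP -> tTRE effects, and strand-level convergent cooperativity — each
with recorded ground truth so every downstream stage has a
parameter-recovery test.

All generators are deterministic given (parameters, seed).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

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

TF_ROLES = ("insulator", "activator", "bivalent", "null", "discordant")


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic cohort."""

    ttres: list[TTRE]
    chrom_sizes: dict[str, int]
    variable_ids: set[str] = field(default_factory=set)
    rho0: float = 0.6
    lambda_d: float = 100_000.0
    tf_roles: dict[str, str] = field(default_factory=dict)
    tf_sites: dict[str, TFSiteSet] = field(default_factory=dict)
    # pair-keyed correlation modifiers, keys are sorted (id_a, id_b)
    damp: dict[tuple[str, str], float] = field(default_factory=dict)
    boost: dict[tuple[str, str], float] = field(default_factory=dict)
    contact_damp: dict[tuple[str, str], float] = field(default_factory=dict)
    contact_boost: dict[tuple[str, str], float] = field(default_factory=dict)
    # genotypes
    genotypes: np.ndarray | None = None          # n_snps x n_individuals
    snp_chroms: np.ndarray | None = None
    snp_positions: np.ndarray | None = None
    genotype_effects: list[tuple[str, int, float]] = field(default_factory=list)
    genotype_links: list[tuple[str, str]] = field(default_factory=list)
    # strand-level convergent cooperativity
    convergent_sigma: float = 0.0
    convergent_pairs: list[tuple[str, str]] = field(default_factory=list)

    def rho(self, d: np.ndarray | float) -> np.ndarray | float:
        """Planted correlation at genomic distance d (same chromosome)."""
        return self.rho0 * np.exp(-np.asarray(d, dtype=float) / self.lambda_d)

    def planted_rho_pair(self, a: TTRE, b: TTRE, contact: bool = False) -> float:
        """Planted correlation for a specific pair, modifiers applied."""
        if a.chrom != b.chrom:
            return 0.0
        rho = float(self.rho(abs(a.center - b.center)))
        key = tuple(sorted((a.id, b.id)))
        damp = self.contact_damp if contact else self.damp
        boost = self.contact_boost if contact else self.boost
        if key in damp:
            rho *= damp[key]
        if key in boost:
            rho = 1.0 - (1.0 - rho) * (1.0 - boost[key])
        return rho


def make_design(
    n_individuals: int = 67, n_replicated: int = 8
) -> SampleDesign:
    """Cohort of ``n_individuals``, the first ``n_replicated`` of which
    contribute a replicate library pair (default: 75 libraries)."""
    libraries, individual_of = [], {}
    for i in range(n_individuals):
        ind = f"ind{i:03d}"
        lib = f"lib{i:03d}a"
        libraries.append(lib)
        individual_of[lib] = ind
        if i < n_replicated:
            rep = f"lib{i:03d}b"
            libraries.append(rep)
            individual_of[rep] = ind
    return SampleDesign(libraries=libraries, individual_of=individual_of)


def simulate_ttre_landscape(
    n_ttres: int,
    chrom_sizes: dict[str, int],
    clustering: float = 0.3,
    seed: int = 0,
    min_gap: int = 50,
    max_gap: int = 250,
    min_spacing: int = 150,
    cluster_spacing: tuple[int, int] = (250, 10_000),
) -> list[TTRE]:
    """Place divergent TSS pairs along the genome.

    Each tTRE's plus TSS lies ``min_gap``..``max_gap`` bp downstream of
    its minus TSS; facing TSSs of consecutive elements are >=
    ``min_spacing`` bp apart, with a ``clustering`` fraction given tight
    spacing drawn from ``cluster_spacing`` to populate the short-range
    analyses.
    """
    if not 0 <= clustering <= 1:
        raise ValueError("clustering must be in [0, 1]")
    total = sum(chrom_sizes.values())
    if total < n_ttres * (min_spacing + max_gap + 100):
        raise ValueError(
            f"cannot pack {n_ttres} elements into {total} bp at "
            f">= {min_spacing} bp spacing"
        )
    rng = np.random.default_rng(seed)
    # allocate counts proportional to chromosome length
    chroms = list(chrom_sizes)
    sizes = np.asarray([chrom_sizes[c] for c in chroms], dtype=float)
    alloc = np.floor(n_ttres * sizes / sizes.sum()).astype(int)
    for k in range(n_ttres - alloc.sum()):
        alloc[k % len(chroms)] += 1

    ttres: list[TTRE] = []
    for chrom, n_c in zip(chroms, alloc):
        size = chrom_sizes[chrom]
        cursor = int(rng.integers(100, 1000))
        placed = 0
        while placed < n_c:
            gap = int(rng.integers(min_gap, max_gap + 1))
            minus, plus = cursor, cursor + gap
            if plus + 100 >= size:
                raise ValueError(
                    f"infeasible packing on {chrom}: placed {placed} of {n_c}"
                )
            ttres.append(
                TTRE(
                    id=f"sim_{len(ttres):05d}",
                    chrom=chrom,
                    minus_tss=minus,
                    plus_tss=plus,
                )
            )
            placed += 1
            remaining = n_c - placed
            if remaining == 0:
                break
            if rng.random() < clustering:
                spacing = int(rng.integers(*cluster_spacing))
            else:
                budget = size - plus - remaining * (min_spacing + max_gap + 100)
                expected = max(budget / max(remaining, 1), float(min_spacing))
                spacing = int(rng.uniform(0.5, 1.5) * expected)
            cursor = plus + max(spacing, min_spacing)
            # never spend the room the remaining elements still need
            max_cursor = size - remaining * (min_spacing + max_gap + 101)
            cursor = min(cursor, max_cursor)
            if cursor < plus + min_spacing:
                raise ValueError(
                    f"infeasible packing on {chrom}: placed {placed} of {n_c}"
                )
    return ttres


def enumerate_pairs(ttres: list[TTRE], max_distance: int) -> pd.DataFrame:
    """All intrachromosomal tTRE pairs with centre distance <= cap."""
    rows_a, rows_b, chroms, dists = [], [], [], []
    by_chrom: dict[str, list[TTRE]] = {}
    for t in ttres:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom, group in sorted(by_chrom.items()):
        group = sorted(group, key=lambda t: t.center)
        centers = np.asarray([t.center for t in group])
        ids = np.asarray([t.id for t in group], dtype=object)
        hi = np.searchsorted(centers, centers + max_distance, side="right")
        for i in range(len(group)):
            j = np.arange(i + 1, hi[i])
            if j.size:
                rows_a.append(np.full(j.size, ids[i], dtype=object))
                rows_b.append(ids[j])
                chroms.append(np.full(j.size, chrom, dtype=object))
                dists.append(centers[j] - centers[i])
    if not rows_a:
        return pd.DataFrame(columns=["ttre_a", "ttre_b", "chrom", "distance"])
    return pd.DataFrame(
        {
            "ttre_a": np.concatenate(rows_a),
            "ttre_b": np.concatenate(rows_b),
            "chrom": np.concatenate(chroms),
            "distance": np.concatenate(dists),
        }
    )


def _random_length_pool(
    rng: np.random.Generator, mean: float = 300.0, n: int = 1000
) -> np.ndarray:
    """Plausible ChIP-peak-like site lengths (lognormal, >= 50 bp)."""
    return np.maximum(
        rng.lognormal(np.log(mean), 0.35, size=n).astype(np.int64), 50
    )


def simulate_tf_sites(
    truth: SyntheticTruth,
    tf_name: str,
    tf_role: str,
    n_sites: int,
    seed: int = 0,
    insulation: float = 0.15,
    activation: float = 0.25,
    targeted_fraction: float = 0.0,
    effect_range: int = 200_000,
    intersection_threshold: int = 2,
) -> TFSiteSet:
    """Generate one TF's site set and register its planted effect.

    Sites and effect are generated jointly: sites are placed (uniformly
    by default) and the planted correlation is then modified according
    to the *realised* intersection/occupancy annotation, so the
    association the analysis should recover is exact by construction.
    Uniform placement keeps the site set exchangeable with the shuffled
    sets of the permutation null; a ``targeted_fraction`` of sites can
    optionally be steered toward pair gaps (insulator) or tTRE spans
    (activator) to concentrate the effect, at the cost of that
    exchangeability.

    insulator: pairs with >= ``intersection_threshold`` sites between
    them have rho multiplied by ``insulation``. activator: pairs with an
    occupied member have rho moved toward 1 by ``activation``. bivalent:
    both. null: uniform sites, no effect. discordant: activator for
    expression but contact-damped for the same pairs.
    """
    from .tf_dependency import PairAnnotator, labels_for_mode

    if tf_role not in TF_ROLES:
        raise ValueError(f"unknown TF role {tf_role!r}")
    rng = np.random.default_rng(seed)
    lengths = _random_length_pool(rng)
    ttre_by_id = {t.id: t for t in truth.ttres}
    pairs = enumerate_pairs(truth.ttres, effect_range)

    sites: list[GenomicInterval] = []
    n_targeted = (
        0 if tf_role == "null" else int(targeted_fraction * n_sites)
    )
    targets_gap = tf_role in ("insulator", "bivalent")
    targets_span = tf_role in ("activator", "bivalent", "discordant")

    if n_targeted and targets_gap:
        n_gap_sites = n_targeted if not targets_span else n_targeted // 2
        wide = pairs[pairs["distance"] >= 5000]
        if len(wide):
            chosen = wide.sample(
                n=min(max(n_gap_sites // 2, 1), len(wide)),
                random_state=int(rng.integers(2**31)),
            )
            for rec in chosen.itertuples():
                a = ttre_by_id[rec.ttre_a]
                b = ttre_by_id[rec.ttre_b]
                g0, g1 = a.span.end, b.minus_tss
                for _ in range(2):  # two sites => crosses the threshold
                    if len(sites) >= n_targeted:
                        break
                    ln = int(min(lengths[rng.integers(lengths.size)], max(g1 - g0 - 1, 1)))
                    if g1 - g0 <= ln:
                        continue
                    s = int(rng.integers(g0, g1 - ln))
                    sites.append(GenomicInterval(a.chrom, s, s + ln))
    if targets_span:
        n_span_sites = n_targeted - len(sites)
        candidates = truth.ttres
        for _ in range(n_span_sites):
            t = candidates[int(rng.integers(len(candidates)))]
            ln = int(lengths[rng.integers(lengths.size)])
            s = max(t.span.start - ln // 4, 0)
            sites.append(
                GenomicInterval(
                    t.chrom, s, min(s + ln, truth.chrom_sizes[t.chrom])
                )
            )

    # the rest placed uniformly across the genome
    chroms = list(truth.chrom_sizes)
    sizes = np.asarray([truth.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    while len(sites) < n_sites:
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        ln = int(lengths[rng.integers(lengths.size)])
        size = truth.chrom_sizes[chrom]
        s = int(rng.integers(0, max(size - ln, 1)))
        sites.append(GenomicInterval(chrom, s, min(s + ln, size)))

    siteset = TFSiteSet(tf_name=tf_name, sites=sites[:n_sites])
    truth.tf_roles[tf_name] = tf_role
    truth.tf_sites[tf_name] = siteset

    if tf_role == "null" or not len(pairs):
        return siteset

    annotator = PairAnnotator(pairs, truth.ttres)
    n_int, occ = annotator.annotate(siteset.by_chrom())
    a_ids = pairs["ttre_a"].to_numpy()
    b_ids = pairs["ttre_b"].to_numpy()
    if targets_gap:
        lab = labels_for_mode(n_int, occ, "intersection", intersection_threshold)
        for k in np.flatnonzero(lab):
            key = tuple(sorted((a_ids[k], b_ids[k])))
            truth.damp[key] = min(truth.damp.get(key, 1.0), insulation)
            truth.contact_damp[key] = min(
                truth.contact_damp.get(key, 1.0), insulation
            )
    if targets_span:
        lab = labels_for_mode(n_int, occ, "occupancy", intersection_threshold)
        for k in np.flatnonzero(lab):
            key = tuple(sorted((a_ids[k], b_ids[k])))
            truth.boost[key] = max(truth.boost.get(key, 0.0), activation)
            if tf_role == "discordant":
                truth.contact_damp[key] = min(
                    truth.contact_damp.get(key, 1.0), insulation
                )
            else:
                truth.contact_boost[key] = max(
                    truth.contact_boost.get(key, 0.0), activation
                )
    return siteset


def simulate_genotypes(
    truth: SyntheticTruth,
    individuals: list[str],
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    linked_fraction: float = 0.0,
    beta: float = 0.35,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hardy-Weinberg biallelic genotypes (0/1/2) over the cohort.

    A ``linked_fraction`` of variable tTREs is organised into linked
    pairs: each member receives an in-span SNP, the two SNPs share one
    genotype vector (perfect linkage), and both tTREs get an additive
    effect ``beta`` per standardised allele count on their latent
    activity — the genetically associated pairs the independence filter
    must catch.

    Returns (genotypes, snp_chroms, snp_positions); also stored on truth.
    """
    if n_snps <= 0:
        raise ValueError("n_snps must be positive")
    rng = np.random.default_rng(seed)
    n_ind = len(individuals)
    mafs = rng.uniform(*maf_range, size=n_snps)
    G = rng.binomial(2, mafs[:, None], size=(n_snps, n_ind)).astype(np.int8)
    chroms_list = list(truth.chrom_sizes)
    sizes = np.asarray([truth.chrom_sizes[c] for c in chroms_list], dtype=float)
    which = rng.choice(len(chroms_list), size=n_snps, p=sizes / sizes.sum())
    chroms = np.asarray([chroms_list[i] for i in which], dtype=object)
    positions = np.asarray(
        [int(rng.integers(0, truth.chrom_sizes[c])) for c in chroms],
        dtype=np.int64,
    )

    if linked_fraction > 0:
        variable = [t for t in truth.ttres if t.id in truth.variable_ids]
        by_chrom: dict[str, list[TTRE]] = {}
        for t in variable:
            by_chrom.setdefault(t.chrom, []).append(t)
        candidates = []
        for group in by_chrom.values():
            group = sorted(group, key=lambda t: t.center)
            for a, b in zip(group[:-1], group[1:]):
                if abs(b.center - a.center) <= 5_000_000:
                    candidates.append((a, b))
        n_links = int(round(linked_fraction * len(variable) / 2))
        rng.shuffle(candidates)
        extra_g, extra_c, extra_p = [], [], []
        for a, b in candidates[:n_links]:
            maf = rng.uniform(0.2, 0.5)
            g = rng.binomial(2, maf, size=n_ind).astype(np.int8)
            if g.std() == 0:
                continue
            snp_idx = n_snps + len(extra_g)
            extra_g.append(g)
            extra_c.append(a.chrom)
            extra_p.append(int(rng.integers(a.span.start, a.span.end)))
            truth.genotype_effects.append((a.id, snp_idx, beta))
            snp_idx = n_snps + len(extra_g)
            extra_g.append(g.copy())
            extra_c.append(b.chrom)
            extra_p.append(int(rng.integers(b.span.start, b.span.end)))
            truth.genotype_effects.append((b.id, snp_idx, beta))
            truth.genotype_links.append((a.id, b.id))
        if extra_g:
            G = np.vstack([G, np.asarray(extra_g)])
            chroms = np.concatenate([chroms, np.asarray(extra_c, dtype=object)])
            positions = np.concatenate(
                [positions, np.asarray(extra_p, dtype=np.int64)]
            )

    truth.genotypes = G
    truth.snp_chroms = chroms
    truth.snp_positions = positions
    return G, chroms, positions


def _build_correlation_block(
    truth: SyntheticTruth, group: list[TTRE]
) -> np.ndarray:
    centers = np.asarray([t.center for t in group])
    d = np.abs(centers[:, None] - centers[None, :])
    C = truth.rho(d)
    np.fill_diagonal(C, 1.0)
    if truth.damp or truth.boost:
        ids = [t.id for t in group]
        index = {i: k for k, i in enumerate(ids)}
        for key, factor in truth.damp.items():
            a, b = key
            if a in index and b in index:
                i, j = index[a], index[b]
                C[i, j] *= factor
                C[j, i] = C[i, j]
        for key, amount in truth.boost.items():
            a, b = key
            if a in index and b in index:
                i, j = index[a], index[b]
                C[i, j] = 1.0 - (1.0 - C[i, j]) * (1.0 - amount)
                C[j, i] = C[i, j]
    return C


def _mvn_factor(C: np.ndarray) -> np.ndarray:
    """Square-root factor of C, eigenvalue-clipped to PSD if needed."""
    w, V = np.linalg.eigh(C)
    if w.min() < -1e-8:
        warnings.warn(
            f"correlation block not PSD (min eig {w.min():.3g}); clipped"
        )
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def simulate_expression(
    truth: SyntheticTruth,
    design: SampleDesign,
    tech_cv: float = 0.05,
    bio_cv: float = 0.31,
    seed: int = 0,
    mean_reads: float = 500.0,
    mu_sigma: float = 0.5,
    strand_frac_range: tuple[float, float] = (0.35, 0.65),
    in_ttre_fraction: float = 0.5,
) -> ExpressionMatrix:
    """Sample the cohort expression matrix from the planted model.

    Per-individual latent log-activities are multivariate normal with the
    planted correlation between same-chromosome tTREs (0 across
    chromosomes); only ``truth.variable_ids`` receive biological
    variance. Replicate libraries share their individual's latent value
    and differ by technical noise of magnitude ``tech_cv`` plus Poisson
    counting noise; per-strand matrices split the total by a per-tTRE
    strand ratio drawn once. Counts are RPM-normalised by library total.
    """
    if tech_cv <= 0 or bio_cv < 0:
        raise ValueError("tech_cv must be > 0 and bio_cv >= 0")
    rng = np.random.default_rng(seed)
    ttres = truth.ttres
    m = len(ttres)
    individuals = design.individuals
    n_ind = len(individuals)
    sigma_bio = np.sqrt(np.log1p(bio_cv**2))
    sigma_tech = np.sqrt(np.log1p(tech_cv**2))

    # latent standard-normal field with planted correlation, per chromosome
    Z = np.zeros((m, n_ind))
    row_of = {t.id: i for i, t in enumerate(ttres)}
    by_chrom: dict[str, list[TTRE]] = {}
    for t in ttres:
        by_chrom.setdefault(t.chrom, []).append(t)
    for group in by_chrom.values():
        group = sorted(group, key=lambda t: t.center)
        C = _build_correlation_block(truth, group)
        F = _mvn_factor(C)
        block = F @ rng.standard_normal((len(group), n_ind))
        for k, t in enumerate(group):
            Z[row_of[t.id]] = block[k]

    mu = np.log(mean_reads) + mu_sigma * rng.standard_normal(m)
    bio_scale = np.asarray(
        [sigma_bio if t.id in truth.variable_ids else 0.0 for t in ttres]
    )
    L = mu[:, None] + bio_scale[:, None] * Z  # m x n_ind

    if truth.genotype_effects and truth.genotypes is not None:
        for ttre_id, snp_idx, beta in truth.genotype_effects:
            g = truth.genotypes[snp_idx].astype(float)
            if g.std() > 0:
                L[row_of[ttre_id]] += beta * (g - g.mean()) / g.std()

    frac_plus = rng.uniform(*strand_frac_range, size=m)

    # strand-level convergent cooperativity: shared per-individual factor
    # on the facing strands (A plus, B minus) of planted pairs
    conv_plus = np.zeros((m, n_ind))
    conv_minus = np.zeros((m, n_ind))
    if truth.convergent_sigma > 0 and truth.convergent_pairs:
        for a_id, b_id in truth.convergent_pairs:
            w = truth.convergent_sigma * rng.standard_normal(n_ind)
            conv_plus[row_of[a_id]] += w
            conv_minus[row_of[b_id]] += w

    ind_index = {ind: k for k, ind in enumerate(individuals)}
    n_lib = len(design.libraries)
    lib_ind = np.asarray(
        [ind_index[design.individual_of[lib]] for lib in design.libraries]
    )
    lam_plus = np.exp(
        L[:, lib_ind]
        + conv_plus[:, lib_ind]
        + sigma_tech * rng.standard_normal((m, n_lib))
    ) * frac_plus[:, None]
    lam_minus = np.exp(
        L[:, lib_ind]
        + conv_minus[:, lib_ind]
        + sigma_tech * rng.standard_normal((m, n_lib))
    ) * (1.0 - frac_plus)[:, None]
    counts_plus = rng.poisson(lam_plus).astype(float)
    counts_minus = rng.poisson(lam_minus).astype(float)

    # RPM by the library's sequencing depth, of which tTREs capture a
    # fixed fraction; a depth tied to the realised in-tTRE sum would make
    # rows compositionally anti-correlated
    depth = m * mean_reads / in_ttre_fraction
    scale = 1e6 / depth
    return ExpressionMatrix(
        ttre_ids=[t.id for t in ttres],
        library_ids=list(design.libraries),
        values_total=(counts_plus + counts_minus) * scale,
        values_plus=counts_plus * scale,
        values_minus=counts_minus * scale,
        design=design,
    )


def plant_convergent_effect(
    truth: SyntheticTruth,
    sigma: float,
    window: tuple[int, int] = (250, 1500),
) -> list[tuple[str, str]]:
    """Mark adjacent pairs with facing-TSS distance in ``window`` as
    convergently cooperative; takes effect in simulate_expression."""
    pairs = []
    by_chrom: dict[str, list[TTRE]] = {}
    for t in truth.ttres:
        by_chrom.setdefault(t.chrom, []).append(t)
    for group in by_chrom.values():
        group = sorted(group, key=lambda t: t.center)
        for a, b in zip(group[:-1], group[1:]):
            dist = b.minus_tss - a.plus_tss
            if window[0] <= dist <= window[1]:
                pairs.append((a.id, b.id))
    truth.convergent_sigma = sigma
    truth.convergent_pairs = pairs
    return pairs


def render_signal_tracks(
    truth: SyntheticTruth,
    matrix: ExpressionMatrix,
    reads_per_library: int,
    seed: int = 0,
    background_fraction: float = 0.0,
    jitter_p: float = 0.5,
    jitter_cap: int = 20,
) -> list[StrandedTrack]:
    """Invert quantification: place 5'-end reads at the planted TSSs.

    Per library, reads are multinomially distributed over (tTRE, strand)
    cells proportional to the expression matrix, placed at the TSS plus a
    geometric jitter (p = ``jitter_p``, magnitude capped at
    ``jitter_cap``), with a ``background_fraction`` of reads scattered
    uniformly on random strands.
    """
    rng = np.random.default_rng(seed)
    ttres = truth.ttres
    m = len(ttres)
    plus_tss = np.asarray([t.plus_tss for t in ttres])
    minus_tss = np.asarray([t.minus_tss for t in ttres])
    chrom_of = np.asarray([t.chrom for t in ttres], dtype=object)
    chrom_list = list(truth.chrom_sizes)
    sizes = np.asarray([truth.chrom_sizes[c] for c in chrom_list], dtype=float)

    tracks = []
    for j, lib in enumerate(matrix.library_ids):
        track = StrandedTrack(lib, truth.chrom_sizes)
        weights = np.concatenate(
            [matrix.values_plus[:, j], matrix.values_minus[:, j]]
        )
        if weights.sum() <= 0:
            weights = np.ones(2 * m)
        n_signal = int(round(reads_per_library * (1.0 - background_fraction)))
        cell_counts = rng.multinomial(n_signal, weights / weights.sum())
        per_chrom: dict[tuple[str, str], list[np.ndarray]] = {}
        for cell in np.flatnonzero(cell_counts):
            t_idx = cell % m
            strand = "+" if cell < m else "-"
            tss = plus_tss[t_idx] if strand == "+" else minus_tss[t_idx]
            c = cell_counts[cell]
            mag = np.minimum(rng.geometric(jitter_p, size=c) - 1, jitter_cap)
            sign = rng.integers(0, 2, size=c) * 2 - 1
            pos = np.clip(
                tss + mag * sign, 0,
                truth.chrom_sizes[chrom_of[t_idx]] - 1,
            )
            per_chrom.setdefault((chrom_of[t_idx], strand), []).append(pos)
        n_bg = reads_per_library - n_signal
        if n_bg > 0:
            which = rng.choice(len(chrom_list), size=n_bg, p=sizes / sizes.sum())
            strands = rng.integers(0, 2, size=n_bg)
            for ci, chrom in enumerate(chrom_list):
                for si, strand in enumerate("+-"):
                    mask = (which == ci) & (strands == si)
                    if mask.any():
                        pos = rng.integers(
                            0, truth.chrom_sizes[chrom], size=int(mask.sum())
                        )
                        per_chrom.setdefault((chrom, strand), []).append(pos)
        for (chrom, strand), pos_list in per_chrom.items():
            pos = np.concatenate(pos_list)
            track.set_counts(chrom, strand, pos, np.ones(pos.size))
        tracks.append(track)
    return tracks


def simulate_contacts(
    truth: SyntheticTruth,
    resolution: int = 5000,
    c0: float = 100.0,
    seed: int = 0,
    alpha: float = 1.0,
    d0: float = 10_000.0,
    gamma: float = 3.0,
    max_distance: int = 500_000,
) -> ContactMatrix:
    """Distance-decaying contact matrix with a co-expression-linked boost.

    Expected contact between bins at distance d is
    c0 * (1 + d/d0)^-alpha, multiplied by (1 + gamma * rho_pair) for bin
    pairs holding a planted tTRE pair (contact-side modifiers applied);
    values are Poisson-sampled and symmetric.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    rng = np.random.default_rng(seed)
    matrix = ContactMatrix(truth.chrom_sizes, resolution)

    boost: dict[tuple[int, int], float] = {}
    ttre_by_id = {t.id: t for t in truth.ttres}
    pairs = enumerate_pairs(truth.ttres, max_distance)
    for rec in pairs.itertuples():
        a, b = ttre_by_id[rec.ttre_a], ttre_by_id[rec.ttre_b]
        rho = truth.planted_rho_pair(a, b, contact=True)
        bi = matrix.bin_of(a.chrom, int(a.center))
        bj = matrix.bin_of(b.chrom, int(b.center))
        key = (min(bi, bj), max(bi, bj))
        factor = 1.0 + gamma * max(rho, 0.0)
        boost[key] = max(boost.get(key, 1.0), factor)

    max_off = max(1, max_distance // resolution)
    for chrom in truth.chrom_sizes:
        lo, hi = matrix.chrom_bin_range(chrom)
        n_b = hi - lo
        for off in range(0, max_off + 1):
            if off >= n_b:
                break
            base = c0 * (1.0 + off * resolution / d0) ** (-alpha)
            i_arr = np.arange(lo, hi - off)
            expected = np.full(i_arr.size, base)
            for k, i in enumerate(i_arr):
                b = boost.get((i, i + off))
                if b is not None:
                    expected[k] *= b
            values = rng.poisson(expected)
            for i, v in zip(i_arr, values):
                if v > 0:
                    matrix.set(int(i), int(i + off), float(v))
    return matrix
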