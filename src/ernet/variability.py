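"""Variably expressed tTRE selection.

Between-replicate deviations measure technical noise; between-individual
deviations add biological variance. A one-sided Wilcoxon rank-sum test per
tTRE (H1: individual > replicate deviations) yields p-values, Storey's
uniform-tail estimator gives the true-null proportion pi0, and Storey
q-values select the variable set at the FDR threshold.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class VariabilityResult:
    ttre_id: str
    p_value: float
    q_value: float
    variable: bool


def pairwise_deviations(
    row: np.ndarray,
    design,
    pseudocount: float = 1.0,
    max_sample_pairs: int = 2000,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Absolute log2 pairwise differences within replicate groups and
    between individuals.

    Replicate deviations use all within-group library pairs. Individual
    deviations use one library per individual (the first in design order)
    over all between-individual pairs, subsampled to at most
    ``max_sample_pairs`` with a fixed-seed generator. Using a single
    library rather than the replicate-group mean keeps the two deviation
    samples exchangeable when there is no biological variance, so the
    rank-sum p-values are uniform under the null.
    """
    row = np.asarray(row, dtype=float)
    log_row = np.log2(row + pseudocount)

    rep_devs: list[float] = []
    lib_index = {lib: i for i, lib in enumerate(design.libraries)}
    for group in design.replicate_groups:
        idx = [lib_index[lib] for lib in group]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                rep_devs.append(abs(log_row[idx[a]] - log_row[idx[b]]))
    if not rep_devs:
        raise ValueError("design has no replicate pairs; test undefined")

    individuals = design.individuals
    if len(individuals) < 3:
        raise ValueError("need >= 3 individuals")
    rep_of = np.asarray(
        [design.library_indices_of_individual(ind)[0] for ind in individuals]
    )
    log_reps = log_row[rep_of]
    ii, jj = np.triu_indices(len(individuals), k=1)
    smp = np.abs(log_reps[ii] - log_reps[jj])
    if smp.size > max_sample_pairs:
        gen = rng or np.random.default_rng(0)
        smp = smp[gen.choice(smp.size, size=max_sample_pairs, replace=False)]
    return np.asarray(rep_devs), smp


def variability_test(rep_devs: np.ndarray, smp_devs: np.ndarray) -> float:
    """One-sided Wilcoxon rank-sum p for H1: sample > replicate deviations.

    Exact when both groups have <= 25 values and no ties; normal
    approximation with tie correction otherwise. Completely tied data
    returns p = 1 (no evidence).
    """
    rep = np.asarray(rep_devs, dtype=float)
    smp = np.asarray(smp_devs, dtype=float)
    if rep.size == 0 or smp.size == 0:
        raise ValueError("both deviation lists must be non-empty")
    pooled = np.concatenate([rep, smp])
    if np.all(pooled == pooled[0]):
        return 1.0
    small = rep.size <= 25 and smp.size <= 25
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (small and no_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(smp, rep, alternative="greater", method=method).pvalue
    )


def variability_tests_matrix(
    values: np.ndarray,
    design,
    pseudocount: float = 1.0,
    max_sample_pairs: int = 2000,
) -> np.ndarray:
    """Vectorised per-tTRE rank-sum p-values for a full RPM matrix.

    Uses the normal approximation (tie-corrected) along axis -1; the
    scalar :func:`variability_test` is the reference for small cases.
    """
    values = np.asarray(values, dtype=float)
    m = values.shape[0]
    log_vals = np.log2(values + pseudocount)

    lib_index = {lib: i for i, lib in enumerate(design.libraries)}
    rep_pairs = []
    for group in design.replicate_groups:
        idx = [lib_index[lib] for lib in group]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                rep_pairs.append((idx[a], idx[b]))
    if not rep_pairs:
        raise ValueError("design has no replicate pairs; test undefined")
    ra = np.asarray([p[0] for p in rep_pairs])
    rb = np.asarray([p[1] for p in rep_pairs])
    rep = np.abs(log_vals[:, ra] - log_vals[:, rb])  # m x n_rep_pairs

    individuals = design.individuals
    rep_of = [design.library_indices_of_individual(ind)[0] for ind in individuals]
    log_means = log_vals[:, rep_of]
    ii, jj = np.triu_indices(len(individuals), k=1)
    if ii.size > max_sample_pairs:
        gen = np.random.default_rng(0)
        keep = gen.choice(ii.size, size=max_sample_pairs, replace=False)
        ii, jj = ii[keep], jj[keep]
    smp = np.abs(log_means[:, ii] - log_means[:, jj])  # m x n_smp_pairs

    res = stats.mannwhitneyu(
        smp, rep, alternative="greater", method="asymptotic", axis=-1
    )
    p = np.asarray(res.pvalue, dtype=float).reshape(m)
    # completely tied rows carry no evidence
    tied = np.all(
        np.concatenate([rep, smp], axis=1)
        == np.concatenate([rep, smp], axis=1)[:, :1],
        axis=1,
    )
    p[tied] = 1.0
    return p


def estimate_pi0(p_values: np.ndarray, lam: float = 0.5) -> tuple[float, float]:
    """Storey's pi0 from the uniform tail: #{p > lam} / ((1 - lam) m).

    Returns (pi0, upper bound on the variable fraction in percent).
    """
    if not 0 < lam < 1:
        raise ValueError("lambda must be in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    pi0 = float(np.count_nonzero(p > lam) / ((1.0 - lam) * p.size))
    pi0 = min(pi0, 1.0)
    return pi0, 100.0 * (1.0 - pi0)


def storey_q_values(p_values: np.ndarray, pi0: float) -> np.ndarray:
    """Storey q-values: q(p) = min_{t >= p} pi0 * m * t / #{p_i <= t}."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def select_variable(
    ttre_ids: list[str],
    p_values: np.ndarray,
    pi0: float,
    fdr: float = 0.2,
) -> list[VariabilityResult]:
    q = storey_q_values(p_values, pi0)
    return [
        VariabilityResult(
            ttre_id=t, p_value=float(p), q_value=float(qv), variable=bool(qv < fdr)
        )
        for t, p, qv in zip(ttre_ids, p_values, q)
    ]


def run_variability(
    matrix,
    fdr: float = 0.2,
    lam: float = 0.5,
    pseudocount: float = 1.0,
    max_sample_pairs: int = 2000,
) -> tuple[list[VariabilityResult], float]:
    """Full variability stage on an ExpressionMatrix; returns (results, pi0)."""
    p = variability_tests_matrix(
        matrix.values_total,
        matrix.design,
        pseudocount=pseudocount,
        max_sample_pairs=max_sample_pairs,
    )
    pi0, _ = estimate_pi0(p, lam)
    return select_variable(matrix.ttre_ids, p, pi0, fdr=fdr), pi0
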