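"""Shared fixtures: small synthetic cohorts and brute-force oracles."""
from __future__ import annotations

import numpy as np
import pytest

from ernet import coexpression, simulate
from ernet.types import SampleDesign


@pytest.fixture(scope="session")
def corr_cohort():
    """Correlated cohort: 1200 tTREs over 4 chromosomes, all variable.

    Used by decay-recovery, null-fit, and pair-machinery tests.
    """
    sizes = {f"chr{i + 1}": 5_000_000 for i in range(4)}
    ttres = simulate.simulate_ttre_landscape(1200, sizes, clustering=0.3, seed=101)
    truth = simulate.SyntheticTruth(ttres=ttres, chrom_sizes=sizes)
    truth.variable_ids = {t.id for t in ttres}
    design = simulate.make_design()
    matrix = simulate.simulate_expression(truth, design, seed=102)
    return {
        "sizes": sizes,
        "ttres": ttres,
        "truth": truth,
        "design": design,
        "matrix": matrix,
    }


@pytest.fixture(scope="session")
def pair_table(corr_cohort):
    return coexpression.pairwise_correlation(
        corr_cohort["matrix"], corr_cohort["ttres"], 5_000_000
    )


@pytest.fixture
def tiny_design() -> SampleDesign:
    """4 individuals, the first two replicated (6 libraries)."""
    return simulate.make_design(n_individuals=4, n_replicated=2)


# ------------------------------------------------------------------ oracles


def brute_local_maxima(positions, counts, window):
    """O(n^2) reference for the strand-specific local-maximum rule."""
    half = window // 2
    peaks = []
    for i, (p, c) in enumerate(zip(positions, counts)):
        is_peak = True
        for q, cq in zip(positions, counts):
            if q == p or not (p - half < q < p + half):
                continue
            if cq > c or (cq == c and q < p):
                is_peak = False
                break
        if is_peak:
            peaks.append(p)
    return sorted(peaks)


def brute_pair_annotation(span_a, span_b, sites):
    """Reference intersection/occupancy for one pair.

    A site intersects when it overlaps the open gap between the spans and
    overlaps neither span; it occupies when it overlaps either span.
    Spans and sites are half-open (start, end) tuples on one chromosome.
    """

    def overlaps(x, y):
        return x[0] < y[1] and y[0] < x[1]

    gap = (span_a[1], max(span_b[0], span_a[1]))
    n_int = 0
    occupied = False
    for s in sites:
        occ = overlaps(s, span_a) or overlaps(s, span_b)
        if occ:
            occupied = True
        if gap[0] < gap[1] and overlaps(s, gap) and not occ:
            n_int += 1
    return n_int, occupied


def naive_pearson(x, y):
    """Two-pass textbook Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


def brute_delta_auc(distances, values, labels, lo, hi, pairs_per_bin, spec):
    """Independent re-implementation of the grouped decay-curve AUCs."""

    def tail(vals, pct):
        k = int(np.ceil(pct / 100.0 * len(vals)))
        k = min(max(k, 1), len(vals))
        return sorted(vals, reverse=True)[k - 1]

    def curve(ds, vs):
        pairs = sorted(zip(ds, vs))
        out = []
        for start in range(0, len(pairs) - pairs_per_bin + 1, pairs_per_bin):
            chunk = [v for _, v in pairs[start : start + pairs_per_bin]]
            if spec == "upper5":
                out.append(tail(chunk, 5.0))
            elif spec == "median":
                out.append(tail(chunk, 50.0))
            else:
                raise ValueError(spec)
        return out

    keep = [(d, v, l) for d, v, l in zip(distances, values, labels) if lo <= d <= hi]
    low = [(d, v) for d, v, l in keep if not l]
    high = [(d, v) for d, v, l in keep if l]
    c_low = curve([d for d, _ in low], [v for _, v in low])
    c_high = curve([d for d, _ in high], [v for _, v in high])
    k = min(len(c_low), len(c_high))
    return sum(c_low[:k]) - sum(c_high[:k])
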