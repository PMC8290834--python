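"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by a method unrelated to the package's
implementation path: dense-LP solves via scipy.optimize.linprog, exhaustive
subset/segment enumeration, and full-grid searches. They are deliberately
slow and only run on tiny instances.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog

from minigem.biomass import ConfusionCounts, mcc
from minigem.reduction import GenomeLayout, functional_loss


def dense_lp_fba(S: np.ndarray, lb: np.ndarray, ub: np.ndarray, objective: int):
    """Max c.v subject to S v = 0, lb <= v <= ub, by scipy HiGHS."""
    n = S.shape[1]
    c = np.zeros(n)
    c[objective] = -1.0  # linprog minimizes
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=list(zip(lb, ub)), method="highs")
    if not res.success:
        return None
    return -res.fun


def dense_lp_min_total_flux(
    S: np.ndarray, lb: np.ndarray, ub: np.ndarray, objective: int, optimum: float
):
    """Min sum|v| with the objective flux fixed at its optimum.

    Split v = p - q with p, q >= 0 and minimize sum(p + q); the optimum is
    the minimal total absolute flux over all optimal solutions.
    """
    n = S.shape[1]
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(S.shape[0])
    fix = np.zeros(2 * n)
    fix[objective] = 1.0
    fix[n + objective] = -1.0
    A_eq = np.vstack([A_eq, fix])
    b_eq = np.append(b_eq, optimum)
    bounds = []
    for j in range(n):
        bounds.append((0.0, max(ub[j], 0.0)))
    for j in range(n):
        bounds.append((0.0, max(-lb[j], 0.0)))
    c = np.ones(2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if not res.success:
        return None
    return res.fun


def enumerate_minimal_media(model, min_growth: float) -> set[frozenset]:
    """All minimum-cardinality exchange subsets reaching ``min_growth``."""
    exchanges = [r.id for r in model.reactions if r.id.startswith("EX_")]
    saved = {r: model.reactions.get_by_id(r).lower_bound for r in exchanges}
    best_size = None
    winners: set[frozenset] = set()
    try:
        for size in range(len(exchanges) + 1):
            for subset in itertools.combinations(exchanges, size):
                for rid in exchanges:
                    model.reactions.get_by_id(rid).lower_bound = (
                        saved[rid] if rid in subset else 0.0
                    )
                growth = model.slim_optimize(error_value=0.0)
                if growth >= min_growth - 1e-9:
                    winners.add(frozenset(subset))
            if winners:
                best_size = size
                break
    finally:
        for rid, lbv in saved.items():
            model.reactions.get_by_id(rid).lower_bound = lbv
    return winners


def brute_force_longest_deletion(
    layout: GenomeLayout,
    knockout_growth,
    min_growth_fraction: float,
    baseline: float,
    forbidden: set[str],
) -> int:
    """Length of the longest feasible segment over all breakpoint pairs."""
    points = {1, layout.genome_length}
    for g in layout.genes:
        points.update((max(g.start - 1, 1), g.start, g.end, min(g.end + 1, layout.genome_length)))
    for p in layout.promoters:
        points.update((max(p.position - 1, 1), p.position, min(p.position + 1, layout.genome_length)))
    pts = sorted(points)
    model_genes = {g.id for g in layout.genes if g.model_gene}
    floor = min_growth_fraction * baseline - 1e-9
    best = 0
    for i, s in enumerate(pts):
        for e in pts[i:]:
            silenced = functional_loss(layout, s, e)
            if silenced & forbidden:
                continue
            if knockout_growth(frozenset(silenced & model_genes)) < floor:
                continue
            best = max(best, e - s + 1)
    return best


def brute_force_thresholds(rna: np.ndarray, prot: np.ndarray):
    """Full double-loop threshold search; returns (prot_thr, rna_thr, score)."""
    best = None
    for p in np.unique(prot):
        p_call = prot >= p
        for r in np.unique(rna):
            r_call = rna >= r
            tp = int(np.sum(p_call & r_call))
            fp = int(np.sum(p_call & ~r_call))
            fn = int(np.sum(~p_call & r_call))
            tn = int(np.sum(~p_call & ~r_call))
            score = tp * mcc(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            if best is None or score > best[2] + 1e-12:
                best = (float(p), float(r), float(score))
    return best


def half_life_by_bisection(fit, lo: float = 0.0, hi: float = 1e3) -> float:
    """Time at which the fitted curve doubles, found by bisection."""
    target = 2.0 * fit.predict(0.0)
    f = lambda t: fit.predict(t) - target
    assert f(lo) < 0 < f(hi)
    while hi - lo > 1e-12:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
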