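"""Free-ratio branch model: an independent omega on every branch.

Used to ask whether selective constraint differs across lineages; the
all-branches-equal constraint recovers M0, so a likelihood-ratio test
with (number of branches - 1) degrees of freedom operationalizes
"is any branch's omega different".
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .codon_core import (CodonAlignment, CodonModelParams, FitResult,
                         OMEGA_CAP, _Spectral, _check_taxa, _site_logliks,
                         build_rate_matrix, f3x4_frequencies, fit_M0)
from .site_models import LRTResult
from .trees import PhyloTree

__all__ = ["fit_free_ratio", "constrain_equal_and_compare"]


def _branch_site_lnl(tip_idx, tree, kappa, branch_omega, pi):
    """Log-likelihood with a per-branch omega vector (indexed like edges)."""
    base = CodonModelParams(kappa, 1.0, pi)
    cache: dict[float, _Spectral] = {}
    Ps: list[np.ndarray | None] = [None] * tree.n_nodes
    for k, e in enumerate(tree.edges):
        om = float(branch_omega[k])
        if om not in cache:
            Q = build_rate_matrix(base, omega=max(om, 1e-8))
            cache[om] = _Spectral(Q, pi)
        Ps[e] = cache[om].p_matrix(tree.lengths[e])
    return _site_logliks(tip_idx, tree, Ps, pi)


def fit_free_ratio(alignment: CodonAlignment, tree: PhyloTree,
                   optimize_branch_lengths: bool = True,
                   pi: np.ndarray | None = None, n_starts: int = 2,
                   seed: int = 0, tol: float = 1e-8) -> FitResult:
    """ML fit with one omega per branch, shared kappa, pi fixed at F3x4.

    The returned FitResult carries ``branch_omegas``: a map from the
    child-node label of each branch to its omega estimate.  Branches
    whose omega reaches the cap (no synonymous change on the branch) are
    reported at the cap and listed in ``message``.
    """
    tip_idx = _check_taxa(alignment, tree)
    if pi is None:
        pi = f3x4_frequencies(alignment)
    from .codon_core import compress_patterns
    patterns, _, pat_w = compress_patterns(tip_idx)
    edges = tree.edges
    ne = len(edges)
    n_ev = 0

    def unpack(theta):
        kappa = float(np.exp(theta[0]))
        branch_omega = np.exp(theta[1:1 + ne])
        if optimize_branch_lengths:
            lengths = np.zeros(tree.n_nodes)
            lengths[edges] = np.exp(theta[1 + ne:])
            t = tree.with_lengths(lengths)
        else:
            t = tree
        return kappa, branch_omega, t

    def nll(theta):
        nonlocal n_ev
        n_ev += 1
        kappa, bw, t = unpack(theta)
        return -float(_branch_site_lnl(patterns, t, kappa, bw, pi) @ pat_w)

    base = [np.log(2.0)] + [np.log(0.4)] * ne
    bounds = [(np.log(0.01), np.log(100.0))] + \
             [(np.log(1e-4), np.log(OMEGA_CAP))] * ne
    if optimize_branch_lengths:
        base += list(np.log(np.clip(tree.lengths[edges], 1e-4, None)))
        bounds += [(np.log(1e-7), np.log(50.0))] * ne

    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(1, n_starts)):
        x0 = np.array(base) + (0.0 if s == 0 else rng.normal(0, 0.3, len(base)))
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": tol, "maxiter": 1000})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    kappa, bw, t_hat = unpack(best.x)
    capped = [tree.branch_label(e) for e, om in zip(edges, bw)
              if om >= OMEGA_CAP * 0.999]
    omegas = {tree.branch_label(e): float(min(om, OMEGA_CAP))
              for e, om in zip(edges, bw)}
    params = CodonModelParams(kappa, None, pi)
    msg = f"omega at cap on branches: {', '.join(capped)}" if capped else ""
    return FitResult("free-ratio", -float(best.fun), params, t_hat,
                     bool(best.success), n_ev, branch_omegas=omegas,
                     message=msg)


def constrain_equal_and_compare(alignment: CodonAlignment, tree: PhyloTree,
                                free: FitResult,
                                m0: FitResult | None = None) -> LRTResult:
    """LRT of the free-ratio model against the single-ratio constraint.

    Degrees of freedom = number of branches - 1.  The M0 fit is
    recomputed unless supplied.
    """
    if free.branch_omegas is None:
        raise ValueError("expected a free-ratio fit")
    if m0 is None:
        m0 = fit_M0(alignment, tree)
    df = len(free.branch_omegas) - 1
    stat = max(0.0, 2.0 * (free.lnL - m0.lnL))
    return LRTResult(stat, df, float(chi2.sf(stat, df)))
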