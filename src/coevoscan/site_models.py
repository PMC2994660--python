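"""Site-mixture codon models and the positive-selection test.

M7 draws each site's omega from a Beta(p, q) on (0, 1), discretized into
K equal-probability categories; M8 adds an extra class at omega_s >= 1
holding proportion 1 - p0 of sites.  Because M7 is the p0 -> 1 boundary
of M8, twice the log-likelihood difference is compared to a chi-square
with two degrees of freedom, and per-codon posterior probabilities of
omega > 1 are computed by Bayes Empirical Bayes: the site posteriors are
averaged over a uniform grid prior on the mixture parameters, weighting
each grid cell by its data likelihood, so that parameter uncertainty is
carried into the per-site calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betainc, betaincinv, logsumexp
from scipy.stats import chi2

from .codon_core import (CodonAlignment, CodonModelParams, FitResult,
                         OMEGA_CAP, _check_taxa, f3x4_frequencies,
                         site_logliks_by_omega)
from .trees import PhyloTree

__all__ = [
    "SiteMixture",
    "LRTResult",
    "discretize_beta",
    "fit_M7",
    "fit_M8",
    "lrt_m7_m8",
    "beb_site_posteriors",
]

_SHAPE_LO, _SHAPE_HI = 0.005, 99.0


@dataclass
class SiteMixture:
    """Mixture over site omega: K discretized beta categories carrying
    probability p0 (p0 = 1 for M7) plus, for M8, a point mass 1 - p0 at
    omega_s >= 1."""

    model_id: str
    p0: float
    p: float
    q: float
    omega_s: float | None
    K: int

    def category_omegas(self) -> np.ndarray:
        cats = discretize_beta(self.p, self.q, self.K)
        if self.model_id == "M8":
            return np.append(cats, self.omega_s)
        return cats

    def category_weights(self) -> np.ndarray:
        w = np.full(self.K, self.p0 / self.K)
        if self.model_id == "M8":
            return np.append(w, 1.0 - self.p0)
        return w


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


def discretize_beta(p: float, q: float, K: int) -> np.ndarray:
    """Means of the K equal-probability slices of Beta(p, q).

    Category k spans the (k/K, (k+1)/K) quantile slice; its value is the
    conditional mean of the beta over that slice, so category values lie
    in (0, 1) and average to p / (p + q).
    """
    if p <= 0 or q <= 0:
        raise ValueError("beta shapes must be positive")
    edges = betaincinv(p, q, np.linspace(0.0, 1.0, K + 1))
    mass_above = betainc(p + 1.0, q, edges)
    means = K * (p / (p + q)) * np.diff(mass_above)
    return np.clip(means, 1e-7, 1.0 - 1e-7)


def _mixture_site_lnl(tip_idx, tree, kappa, omegas, weights, pi):
    logl = site_logliks_by_omega(tip_idx, tree, kappa, omegas, pi,
                                 weights=weights)
    return logsumexp(logl + np.log(np.clip(weights, 1e-300, None))[:, None],
                     axis=0)


def _fit_mixture(alignment, tree, model_id, K, optimize_branch_lengths,
                 pi, n_starts, seed, tol, start=None):
    tip_idx = _check_taxa(alignment, tree)
    if pi is None:
        pi = f3x4_frequencies(alignment)
    from .codon_core import compress_patterns
    patterns, _, pat_w = compress_patterns(tip_idx)
    log_pat_w = np.log(pat_w)
    edges = tree.edges
    n_free = (5 if model_id == "M8" else 3)
    n_ev = 0

    def unpack(theta):
        p = float(np.exp(theta[0]))
        q = float(np.exp(theta[1]))
        kappa = float(np.exp(theta[2]))
        if model_id == "M8":
            p0 = float(1.0 / (1.0 + np.exp(-theta[3])))
            omega_s = float(1.0 + np.exp(theta[4]))
            mix = SiteMixture("M8", p0, p, q, omega_s, K)
        else:
            mix = SiteMixture("M7", 1.0, p, q, None, K)
        if optimize_branch_lengths:
            lengths = np.zeros(tree.n_nodes)
            lengths[edges] = np.exp(theta[n_free:])
            t = tree.with_lengths(lengths)
        else:
            t = tree
        return kappa, mix, t

    def nll(theta):
        nonlocal n_ev
        n_ev += 1
        kappa, mix, t = unpack(theta)
        ll = _mixture_site_lnl(patterns, t, kappa, mix.category_omegas(),
                               mix.category_weights(), pi)
        return -float(ll @ pat_w)

    start = dict(start or {})
    clip = lambda v, lo, hi: float(np.clip(v, lo, hi))
    base = [np.log(clip(start.get("p", 0.5), _SHAPE_LO, _SHAPE_HI)),
            np.log(clip(start.get("q", 1.5), _SHAPE_LO, _SHAPE_HI)),
            np.log(clip(start.get("kappa", 2.0), 0.01, 100.0))]
    bounds = [(np.log(_SHAPE_LO), np.log(_SHAPE_HI))] * 2 + \
             [(np.log(0.01), np.log(100.0))]
    if model_id == "M8":
        p0_start = clip(start.get("p0", 0.85), 0.01, 0.999)
        ws_start = clip(start.get("omega_s", 2.5), 1.0 + 1e-4, OMEGA_CAP)
        base += [np.log(p0_start / (1.0 - p0_start)), np.log(ws_start - 1.0)]
        bounds += [(-12.0, 12.0), (np.log(1e-4), np.log(OMEGA_CAP))]
    if optimize_branch_lengths:
        start_lengths = start.get("lengths", tree.lengths[edges])
        base += list(np.log(np.clip(start_lengths, 1e-4, None)))
        bounds += [(np.log(1e-7), np.log(50.0))] * len(edges)

    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(1, n_starts)):
        x0 = np.array(base) + (0.0 if s == 0 else rng.normal(0, 0.4, len(base)))
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": tol, "maxiter": 1000})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    kappa, mix, t_hat = unpack(best.x)
    msg = ""
    if model_id == "M8" and mix.p0 > 0.9999:
        msg = "boundary fit: p0 -> 1 (no selected-class support)"
    params = CodonModelParams(kappa, None, pi)
    return FitResult(model_id, -float(best.fun), params, t_hat,
                     bool(best.success), n_ev, mixture=mix, message=msg)


def fit_M7(alignment: CodonAlignment, tree: PhyloTree, K: int = 10,
           optimize_branch_lengths: bool = True,
           pi: np.ndarray | None = None, n_starts: int = 3,
           seed: int = 0, tol: float = 1e-8,
           start: dict | None = None) -> FitResult:
    """ML fit of the beta site model: omega ~ discretized Beta(p, q).

    ``start`` may carry initial values (p, q, kappa, lengths) — e.g. the
    kappa and branch lengths of a prior M0 fit.
    """
    return _fit_mixture(alignment, tree, "M7", K, optimize_branch_lengths,
                        pi, n_starts, seed, tol, start)


def fit_M8(alignment: CodonAlignment, tree: PhyloTree, K: int = 10,
           optimize_branch_lengths: bool = True,
           pi: np.ndarray | None = None, n_starts: int = 3,
           seed: int = 0, tol: float = 1e-8,
           start: dict | None = None) -> FitResult:
    """ML fit of beta & omega_s: proportion p0 of sites follows the
    discretized beta, the rest sit at a single omega_s >= 1.

    ``start`` as in fit_M7, plus p0 and omega_s; chaining from a fitted
    M7 (see ``site_test``) markedly shortens the optimization.
    """
    return _fit_mixture(alignment, tree, "M8", K, optimize_branch_lengths,
                        pi, n_starts, seed, tol, start)


def site_test(alignment: CodonAlignment, tree: PhyloTree, K: int = 10,
              optimize_branch_lengths: bool = True,
              n_starts: int = 2, seed: int = 0
              ) -> tuple[FitResult, FitResult, LRTResult]:
    """Chained M7 -> M8 fits and their likelihood-ratio test.

    M8 starts from the M7 optimum (same beta shapes, kappa and branch
    lengths, selected class initially small), which both speeds up and
    stabilizes the harder 5-parameter fit.
    """
    fit7 = fit_M7(alignment, tree, K, optimize_branch_lengths,
                  n_starts=n_starts, seed=seed)
    start = {"p": fit7.mixture.p, "q": fit7.mixture.q,
             "kappa": fit7.params.kappa,
             "lengths": fit7.tree.lengths[fit7.tree.edges]}
    fit8 = fit_M8(alignment, tree, K, optimize_branch_lengths,
                  n_starts=n_starts, seed=seed, start=start)
    return fit7, fit8, lrt_m7_m8(fit7, fit8)


def lrt_m7_m8(fit7: FitResult, fit8: FitResult) -> LRTResult:
    """Likelihood-ratio test of M8 against M7: 2(lnL8 - lnL7), clipped at
    zero, against chi-square with 2 degrees of freedom."""
    if fit7.model != "M7" or fit8.model != "M8":
        raise ValueError("expected an M7 fit and an M8 fit")
    if fit7.params.pi.shape != fit8.params.pi.shape or \
            not np.allclose(fit7.params.pi, fit8.params.pi):
        raise ValueError("fits appear to come from different data")
    stat = max(0.0, 2.0 * (fit8.lnL - fit7.lnL))
    return LRTResult(stat, 2, float(chi2.sf(stat, 2)))


def beb_site_posteriors(alignment: CodonAlignment, tree: PhyloTree,
                        fit8: FitResult, grid_points: int = 10,
                        threshold: float = 0.75,
                        reference_taxon: str | None = None) -> pd.DataFrame:
    """Bayes Empirical Bayes per-codon posterior probability of omega > 1.

    A uniform grid prior is placed on (p0, p, q, omega_s): ``grid_points``
    midpoints per dimension spanning p0 in [0, 1], p and q in (0, 2],
    omega_s in [1, 11].  For every (p, q) grid value the beta part is
    discretized into the mixture's K equal-probability categories and
    site likelihoods are evaluated at the category means (branch lengths,
    kappa and the mixture rate scale held at the M8 optimum); each grid
    cell is weighted by its whole-alignment likelihood, and
    P(omega > 1 | site) is the cell-weighted average of the
    selected-class responsibility.

    Returns a table with one row per codon column: alignment codon index,
    amino-acid position in the reference sequence (NaN at reference
    gaps), P(omega > 1), posterior mean omega, and the >= threshold flag.
    """
    if fit8.model != "M8" or fit8.mixture is None:
        raise ValueError("beb_site_posteriors requires an M8 fit")
    if not fit8.converged:
        raise ValueError("M8 fit did not converge; refusing BEB")
    G = grid_points
    tip_idx = _check_taxa(alignment, fit8.tree)
    pi = fit8.params.pi
    kappa = fit8.params.kappa
    K = fit8.mixture.K
    S = alignment.n_sites

    ws_grid = 1.0 + 10.0 * (2.0 * np.arange(1, G + 1) - 1.0) / (2.0 * G)
    p0_grid = (2.0 * np.arange(1, G + 1) - 1.0) / (2.0 * G)
    shape_grid = 2.0 * (2.0 * np.arange(1, G + 1) - 1.0) / (2.0 * G)

    # rate scale and branch lengths held at the M8 optimum
    from .codon_core import mixture_rate_scale
    scale = mixture_rate_scale(kappa, fit8.mixture.category_omegas(),
                               fit8.mixture.category_weights(), pi)
    logL_sel = site_logliks_by_omega(tip_idx, fit8.tree, kappa, ws_grid,
                                     pi, rate_scale=scale)      # (G, S)

    loglik_cells, psel_cells, pmean_cells = [], [], []
    p0s = np.repeat(p0_grid, G)
    wsi = np.tile(np.arange(G), G)
    W = np.zeros((G * G, K + G))
    W[np.arange(G * G), K + wsi] = 1.0 - p0s
    for p in shape_grid:
        for q in shape_grid:
            cats = discretize_beta(p, q, K)
            logL_beta = site_logliks_by_omega(
                tip_idx, fit8.tree, kappa, cats, pi, rate_scale=scale)
            logL = np.vstack([logL_beta, logL_sel])
            shift = logL.max(axis=0)
            Lrel = np.exp(logL - shift)                 # (K + G, S)
            W[:, :K] = p0s[:, None] / K
            F = W @ Lrel                                # (G*G, S)
            loglik_cells.append(np.log(F).sum(axis=1) + shift.sum())
            psel_cells.append((W[:, K:] @ Lrel[K:]) / F)
            omega_support = np.concatenate([cats, ws_grid])
            pmean_cells.append(((W * omega_support[None, :]) @ Lrel) / F)
    loglik = np.concatenate(loglik_cells)
    cell_w = np.exp(loglik - logsumexp(loglik))
    p_gt1 = np.zeros(S)
    mean_omega = np.zeros(S)
    off = 0
    for psel, pmean in zip(psel_cells, pmean_cells):
        w = cell_w[off:off + psel.shape[0]]
        p_gt1 += w @ psel
        mean_omega += w @ pmean
        off += psel.shape[0]

    if reference_taxon is None:
        reference_taxon = alignment.taxa[0]
    r = alignment.taxa.index(reference_taxon)
    ref_codon = alignment.codon_idx[r] >= 0
    ref_pos = np.where(ref_codon, np.cumsum(ref_codon), 0).astype(float)
    ref_pos[~ref_codon] = np.nan

    return pd.DataFrame({
        "site": np.arange(S),
        "ref_position": ref_pos,
        "p_gt1": np.clip(p_gt1, 0.0, 1.0),
        "mean_omega": mean_omega,
        "flagged": p_gt1 >= threshold,
    })
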