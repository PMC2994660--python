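"""Simulators that give every pipeline stage inputs with known truth.

Two generators are provided:

* codon alignments evolved along a tree under the same GY94 machinery
  that the fitters use (single omega, beta-mixture site classes with or
  without a selected class, or branch-specific omega), with a per-site
  truth table; and
* IP/input ChIP coverage tracks over a toy hybrid genome with planted
  fold-enrichment regions.

Every generator takes an explicit seed and is deterministic given the
spec; there is no hidden global randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_core import (CODONS, N_STATES, _Spectral, _unscaled_rate_matrix,
                         mixture_rate_scale, CodonAlignment)
from .trees import PhyloTree

__all__ = [
    "SimSpecCodon",
    "SimSpecChip",
    "simulate_codon_alignment",
    "simulate_chip_experiment",
    "simulate_null_gene_set",
]


@dataclass
class SimSpecCodon:
    """Specification of a codon-alignment simulation.

    model is one of "M0" (params: kappa, omega), "M7" (kappa, p, q, K),
    "M8" (kappa, p0, p, q, omega_s, K) or "branch" (kappa, omega plus
    branch_omegas keyed by child-node label).  Site omega is drawn once
    per site from the model's mixture (for M7/M8, from the K
    equal-probability discretized beta classes) and does not switch
    along the tree.  pi is "uniform" or an explicit 61-vector.
    """

    tree: PhyloTree
    model: str
    params: dict
    n_codons: int
    seed: int
    pi: object = "uniform"

    def frequencies(self) -> np.ndarray:
        if isinstance(self.pi, str):
            if self.pi != "uniform":
                raise ValueError(f"unknown pi spec {self.pi!r}")
            return np.full(N_STATES, 1.0 / N_STATES)
        pi = np.asarray(self.pi, float)
        return pi / pi.sum()


@dataclass
class SimSpecChip:
    """Specification of a ChIP coverage simulation over a toy hybrid genome.

    Input coverage at every base is noise(mu); IP coverage is
    noise(mu * s * f(b)) where f(b) is the planted fold inside enriched
    regions and 1 elsewhere.  Defaults mirror a deeply sequenced input
    (~30x) with an IP at roughly a third of that depth, and negative
    binomial noise (dispersion 0.1) since real ChIP coverage is
    overdispersed; "poisson" is available for oracle checks.
    """

    contig_lengths: dict
    mu: float = 30.0
    s: float = 0.35
    regions: list = field(default_factory=list)  # (contig, start, end, fold, label)
    noise: str = "nb"
    dispersion: float = 0.1
    fragment_length: int = 200
    seed: int = 0


def _draw_site_omegas(spec: SimSpecCodon, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site omega values and a boolean selected-class flag."""
    from .site_models import discretize_beta
    S = spec.n_codons
    p = spec.params
    if spec.model == "M0":
        return np.full(S, float(p["omega"])), np.zeros(S, bool)
    if spec.model == "M7":
        cats = discretize_beta(p["p"], p["q"], int(p.get("K", 10)))
        return rng.choice(cats, size=S), np.zeros(S, bool)
    if spec.model == "M8":
        cats = discretize_beta(p["p"], p["q"], int(p.get("K", 10)))
        sel = rng.random(S) >= p["p0"]
        w = rng.choice(cats, size=S)
        w[sel] = float(p["omega_s"])
        return w, sel
    if spec.model == "branch":
        return np.full(S, float(p.get("omega", 1.0))), np.zeros(S, bool)
    raise ValueError(f"unknown model {spec.model!r}")


def _sample_children(P: np.ndarray, parent_states: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    u = rng.random(parent_states.size)
    return (u[:, None] > cum[parent_states]).sum(axis=1)


def simulate_codon_alignment(spec: SimSpecCodon
                             ) -> tuple[CodonAlignment, pd.DataFrame]:
    """Evolve codon sequences down the tree under the specified model.

    The root codon of each site is drawn from pi; along each branch the
    state evolves by the transition probabilities of the scaled rate
    matrix for that site's omega (or the branch's omega under the
    "branch" model).  Returns the tip alignment and a truth table with
    each site's generating omega and selected-class flag.
    """
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree
    pi = spec.frequencies()
    kappa = float(spec.params.get("kappa", 2.0))
    site_omega, selected = _draw_site_omegas(spec, rng)
    S = spec.n_codons

    branch_omegas = None
    if spec.model == "branch":
        branch_omegas = dict(spec.params["branch_omegas"])

    # Site mixtures share one rate scale (the mixture-average rate), so
    # selected classes evolve faster, mirroring the fitted models; M0 and
    # the branch model scale each generator to unit rate on its own.
    rate_scale = None
    if spec.model in ("M7", "M8"):
        from .site_models import discretize_beta
        p = spec.params
        K = int(p.get("K", 10))
        cats = discretize_beta(p["p"], p["q"], K)
        if spec.model == "M7":
            omegas, weights = cats, np.full(K, 1.0 / K)
        else:
            omegas = np.append(cats, float(p["omega_s"]))
            weights = np.append(np.full(K, p["p0"] / K), 1.0 - p["p0"])
        rate_scale = mixture_rate_scale(kappa, omegas, weights, pi)

    spectral_cache: dict[float, _Spectral] = {}

    def spectral(om: float) -> _Spectral:
        if om not in spectral_cache:
            Q, own = _unscaled_rate_matrix(kappa, max(float(om), 1e-8), pi)
            Q = Q / (own if rate_scale is None else rate_scale)
            spectral_cache[om] = _Spectral(Q, pi)
        return spectral_cache[om]

    states = np.empty((tree.n_nodes, S), dtype=np.int64)
    states[tree.root] = rng.choice(N_STATES, size=S, p=pi)
    preorder = [tree.root]
    i = 0
    while i < len(preorder):
        preorder.extend(tree.children(preorder[i]))
        i += 1
    for node in preorder[1:]:
        t = float(tree.lengths[node])
        if branch_omegas is not None:
            om = float(branch_omegas[tree.branch_label(node)])
            P = spectral(om).p_matrix(t)
            states[node] = _sample_children(P, states[tree.parent[node]], rng)
        else:
            states[node] = states[tree.parent[node]]
            for om in np.unique(site_omega):
                mask = site_omega == om
                P = spectral(float(om)).p_matrix(t)
                states[node, mask] = _sample_children(
                    P, states[tree.parent[node]][mask], rng)

    codon_arr = np.array(CODONS)
    seqs = {tree.taxa[t]: "".join(codon_arr[states[t]])
            for t in range(tree.n_tips)}
    truth = pd.DataFrame({
        "site": np.arange(S),
        "omega": site_omega,
        "selected": selected,
    })
    return CodonAlignment.from_sequences(seqs), truth


def simulate_chip_experiment(spec: SimSpecChip):
    """Simulate IP and input coverage tracks with planted enrichment.

    Returns (ip, input, truth): dicts of contig -> CoverageTrack and a
    truth table of planted region folds.
    """
    from .chip_enrichment import CoverageTrack
    rng = np.random.default_rng(spec.seed)

    def draw(mean: np.ndarray) -> np.ndarray:
        if spec.noise == "poisson":
            return rng.poisson(mean)
        if spec.noise == "nb":
            n = 1.0 / spec.dispersion
            pgeom = n / (n + mean)
            return rng.negative_binomial(n, pgeom)
        raise ValueError(f"unknown noise family {spec.noise!r}")

    ip, inp, rows = {}, {}, []
    for contig, L in spec.contig_lengths.items():
        fold = np.ones(L)
        for (rc, start, end, f, label) in spec.regions:
            if rc != contig:
                continue
            if not (0 <= start < end <= L):
                raise ValueError(f"region {label!r} out of bounds on {contig}")
            if f < 0:
                raise ValueError("fold must be non-negative")
            fold[start:end] = f
            rows.append({"contig": contig, "start": start, "end": end,
                         "fold": f, "label": label})
        inp[contig] = CoverageTrack(contig, draw(np.full(L, spec.mu)))
        ip[contig] = CoverageTrack(contig, draw(spec.mu * spec.s * fold))
    return ip, inp, pd.DataFrame(rows, columns=["contig", "start", "end",
                                                "fold", "label"])


def simulate_null_gene_set(n_genes: int, gene_length: int,
                           omega_background: float, tree: PhyloTree,
                           seed: int, kappa: float = 2.0
                           ) -> list[CodonAlignment]:
    """Homogeneous-omega gene alignments (gene_length codons each) for
    building an empirical window null."""
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_genes)
    genes = []
    for s in child_seeds:
        spec = SimSpecCodon(tree, "M0",
                            {"kappa": kappa, "omega": omega_background},
                            n_codons=gene_length, seed=int(s))
        genes.append(simulate_codon_alignment(spec)[0])
    return genes
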