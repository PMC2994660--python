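"""Codon alignments, the GY94-type rate matrix, pruning likelihood, and
single-ratio (M0) maximum-likelihood fitting.

The substitution model is the Goldman–Yang codon model over the 61 sense
codons of the universal genetic code: the instantaneous rate from codon i
to codon j is zero if the codons differ at more than one position and
otherwise proportional to the target codon frequency pi_j, multiplied by
kappa for transitions and by omega for nonsynonymous changes.  The matrix
is scaled so that one unit of branch length equals one expected
substitution per codon at stationarity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from scipy.optimize import minimize

from .trees import PhyloTree

__all__ = [
    "CODONS",
    "CODON_INDEX",
    "CODON_AA",
    "STOP_CODONS",
    "CodonAlignment",
    "CodonModelParams",
    "FitResult",
    "backtranslate",
    "f3x4_frequencies",
    "build_rate_matrix",
    "transition_probabilities",
    "log_likelihood",
    "fit_M0",
    "OMEGA_CAP",
]

# --------------------------------------------------------------------------
# Universal genetic code: 61 sense codons in lexicographic (ACGT) order.
# --------------------------------------------------------------------------
_TABLE = unambiguous_dna_by_id[1]
_NUC = "ACGT"
STOP_CODONS = frozenset(_TABLE.stop_codons)
CODONS: list[str] = [
    "".join(c) for c in itertools.product(_NUC, repeat=3)
    if "".join(c) not in STOP_CODONS
]
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}
CODON_AA: list[str] = [_TABLE.forward_table[c] for c in CODONS]
N_STATES = len(CODONS)  # 61

OMEGA_CAP = 99.0  # sentinel cap for omega at (near-)zero synonymous divergence


def _pair_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean 61x61 masks: single-nucleotide difference, transition,
    nonsynonymous (all restricted to single-difference pairs)."""
    arr = np.array([[_NUC.index(ch) for ch in c] for c in CODONS])
    diffs = (arr[:, None, :] != arr[None, :, :])
    ndiff = diffs.sum(axis=2)
    single = ndiff == 1
    pos = diffs.argmax(axis=2)
    ii = np.take_along_axis(arr[:, None, :].repeat(N_STATES, 1), pos[..., None], 2)[..., 0]
    jj = np.take_along_axis(arr[None, :, :].repeat(N_STATES, 0), pos[..., None], 2)[..., 0]
    transition = single & (((ii == 0) & (jj == 2)) | ((ii == 2) & (jj == 0))
                           | ((ii == 1) & (jj == 3)) | ((ii == 3) & (jj == 1)))
    aa = np.array(CODON_AA)
    nonsyn = single & (aa[:, None] != aa[None, :])
    return single, transition, nonsyn

_SINGLE, _TRANSITION, _NONSYN = _pair_masks()


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------
class StopCodonError(ValueError):
    """An in-frame stop codon was found in a coding sequence."""


@dataclass
class CodonAlignment:
    """In-frame aligned coding sequences over the 61 sense codons.

    ``codon_idx`` is (n_taxa, n_sites) with the sense-codon index, or -1
    for gap / ambiguous codons (treated as missing data downstream).
    Raw sequences are kept for round-tripping and slicing.
    """

    taxa: list[str]
    sequences: list[str]
    codon_idx: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len({len(s) for s in self.sequences}) > 1:
            raise ValueError("aligned sequences must all have equal length")
        if self.sequences and len(self.sequences[0]) % 3 != 0:
            raise ValueError("alignment length must be divisible by 3")
        if self.codon_idx is None:
            self.codon_idx = self._index(self.sequences)

    @staticmethod
    def _index(seqs: list[str], mask_stops: bool = False) -> np.ndarray:
        n_sites = len(seqs[0]) // 3 if seqs else 0
        idx = np.full((len(seqs), n_sites), -1, dtype=np.int16)
        for t, s in enumerate(seqs):
            su = s.upper()
            for k in range(n_sites):
                codon = su[3 * k:3 * k + 3]
                if codon in CODON_INDEX:
                    idx[t, k] = CODON_INDEX[codon]
                elif codon in STOP_CODONS:
                    if not mask_stops:
                        raise StopCodonError(
                            f"in-frame stop codon {codon} in taxon "
                            f"{t} at codon position {k}")
                # anything else (gaps, Ns) stays -1 = missing
        return idx

    @classmethod
    def from_sequences(cls, seqs: dict[str, str], mask_stops: bool = False
                       ) -> "CodonAlignment":
        taxa = list(seqs)
        sequences = [seqs[t] for t in taxa]
        aln = cls.__new__(cls)
        aln.taxa = taxa
        aln.sequences = sequences
        if len({len(s) for s in sequences}) > 1:
            raise ValueError("aligned sequences must all have equal length")
        if sequences and len(sequences[0]) % 3 != 0:
            raise ValueError("alignment length must be divisible by 3")
        aln.codon_idx = cls._index(sequences, mask_stops=mask_stops)
        return aln

    @classmethod
    def from_fasta(cls, path, mask_stops: bool = False) -> "CodonAlignment":
        from Bio import SeqIO
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
        return cls.from_sequences(seqs, mask_stops=mask_stops)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t, s in zip(self.taxa, self.sequences):
                fh.write(f">{t}\n{s}\n")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codon_idx.shape[1]

    @property
    def nucleotide_length(self) -> int:
        return 3 * self.n_sites

    def slice_codons(self, start: int, end: int) -> "CodonAlignment":
        """Codon-column slice [start, end) as a new alignment."""
        seqs = [s[3 * start:3 * end] for s in self.sequences]
        aln = CodonAlignment.__new__(CodonAlignment)
        aln.taxa = list(self.taxa)
        aln.sequences = seqs
        aln.codon_idx = self.codon_idx[:, start:end].copy()
        return aln

    def concat(self, other: "CodonAlignment") -> "CodonAlignment":
        if self.taxa != other.taxa:
            raise ValueError("taxon sets differ")
        return CodonAlignment(
            list(self.taxa),
            [a + b for a, b in zip(self.sequences, other.sequences)])

    def gap_columns(self) -> np.ndarray:
        """Boolean per codon column: any taxon missing (gap/ambiguous)."""
        return (self.codon_idx < 0).any(axis=0)


@dataclass
class CodonModelParams:
    """kappa > 0, omega >= 0 (scalar for M0), codon frequencies pi (61,)."""

    kappa: float
    omega: float | None
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.omega is not None and self.omega < 0:
            raise ValueError("omega must be non-negative")
        if self.pi.shape != (N_STATES,) or np.any(self.pi < 0):
            raise ValueError("pi must be a non-negative 61-vector")
        s = self.pi.sum()
        if not np.isclose(s, 1.0, atol=1e-6):
            raise ValueError("pi must sum to 1")
        self.pi = self.pi / s


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood codon-model fit."""

    model: str
    lnL: float
    params: CodonModelParams
    tree: PhyloTree
    converged: bool
    n_evaluations: int
    mixture: object | None = None          # SiteMixture for M7/M8
    branch_omegas: dict | None = None      # per-branch map for free-ratio
    message: str = ""


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------
def backtranslate(protein_alignment: dict[str, str],
                  cds_by_taxon: dict[str, str]) -> CodonAlignment:
    """Thread unaligned coding DNA onto an amino-acid alignment.

    Each aligned residue becomes its source codon; gap residues become
    triple-gap codon columns.  Every CDS must translate exactly to its
    ungapped protein row under the universal code (a terminal stop codon
    on the CDS is tolerated and dropped).
    """
    out: dict[str, str] = {}
    for taxon, prot in protein_alignment.items():
        if taxon not in cds_by_taxon:
            raise KeyError(f"no CDS for taxon {taxon!r}")
        cds = cds_by_taxon[taxon].upper().replace("U", "T")
        residues = prot.replace(".", "-")
        ungapped = residues.replace("-", "")
        if len(cds) == 3 * (len(ungapped) + 1) and cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        if len(cds) != 3 * len(ungapped):
            raise ValueError(
                f"taxon {taxon!r}: CDS length {len(cds)} != 3 x ungapped "
                f"protein length {len(ungapped)}")
        translated = str(Seq(cds).translate())
        for k, (aa_obs, aa_exp) in enumerate(zip(translated, ungapped)):
            if aa_obs != aa_exp and aa_exp != "X":
                raise ValueError(
                    f"taxon {taxon!r}: translation mismatch at residue "
                    f"{k + 1} ({aa_obs} != {aa_exp})")
        row, j = [], 0
        for aa in residues:
            if aa == "-":
                row.append("---")
            else:
                row.append(cds[3 * j:3 * j + 3])
                j += 1
        out[taxon] = "".join(row)
    return CodonAlignment.from_sequences(out)


def f3x4_frequencies(alignment: CodonAlignment, pseudocount: float = 0.5
                     ) -> np.ndarray:
    """Equilibrium codon frequencies from position-specific nucleotide
    composition (the F3x4 scheme): pi_ijk proportional to f1(i) f2(j) f3(k)
    over sense codons, renormalized after removing stop-codon mass.

    If any nucleotide is absent at a codon position, ``pseudocount`` is
    added to all four counts at that position so every sense codon keeps
    positive mass.
    """
    if alignment.n_sites == 0:
        raise ValueError("empty alignment")
    counts = np.zeros((3, 4))
    for s in alignment.sequences:
        su = s.upper()
        for pos in range(3):
            sub = su[pos::3]
            for b, nuc in enumerate(_NUC):
                counts[pos, b] += sub.count(nuc)
    for pos in range(3):
        if np.any(counts[pos] == 0):
            counts[pos] += pseudocount
    f = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array([f[0, _NUC.index(c[0])] * f[1, _NUC.index(c[1])]
                   * f[2, _NUC.index(c[2])] for c in CODONS])
    return pi / pi.sum()


def _unscaled_rate_matrix(kappa: float, omega: float, pi: np.ndarray
                          ) -> tuple[np.ndarray, float]:
    """Unnormalized GY94 generator and its mean rate -sum(pi_i Q_ii)."""
    rate = np.where(_TRANSITION, kappa, 1.0) * _SINGLE
    rate = rate * np.where(_NONSYN, omega, 1.0)
    Q = rate * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q, float(-np.dot(pi, np.diag(Q)))


def build_rate_matrix(params: CodonModelParams, omega: float | None = None
                      ) -> np.ndarray:
    """GY94 instantaneous rate matrix Q (61x61), rows summing to zero and
    scaled to one expected substitution per codon per unit branch length."""
    om = params.omega if omega is None else omega
    if om is None:
        raise ValueError("omega required")
    Q, scale = _unscaled_rate_matrix(params.kappa, om, params.pi)
    if scale <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return Q / scale


class _Spectral:
    """Eigendecomposition of a reversible Q for cheap P(t) at many t.

    Q reversible w.r.t. pi means D Q D^-1 is symmetric for
    D = diag(sqrt(pi)); P(t) = D^-1 U exp(L t) U' D.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(np.clip(pi, 1e-300, None))
        B = (Q * d[:, None]) / d[None, :]
        B = 0.5 * (B + B.T)
        self.evals, U = np.linalg.eigh(B)
        self.left = U / d[:, None]      # D^-1 U   (rows scaled)
        self.right = (U * d[:, None]).T  # U' D

    def p_matrix(self, t: float) -> np.ndarray:
        P = (self.left * np.exp(self.evals * t)) @ self.right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def transition_probabilities(Q: np.ndarray, t: float,
                             pi: np.ndarray | None = None) -> np.ndarray:
    """P(t) = exp(Qt); row-stochastic, identity at t = 0."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if pi is not None:
        return _Spectral(Q, pi).p_matrix(t)
    from scipy.linalg import expm
    P = expm(Q * t)
    np.clip(P, 0.0, None, out=P)
    return P / P.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# Pruning likelihood
# --------------------------------------------------------------------------
def _check_taxa(alignment: CodonAlignment, tree: PhyloTree) -> np.ndarray:
    if set(alignment.taxa) != set(tree.taxa):
        raise ValueError("tree tips do not match alignment taxa")
    order = [alignment.taxa.index(t) for t in tree.taxa]
    return alignment.codon_idx[order]


def _site_logliks(tip_idx: np.ndarray, tree: PhyloTree,
                  P_by_node: list[np.ndarray], pi: np.ndarray) -> np.ndarray:
    """Per-site log-likelihood by Felsenstein pruning with per-node scaling.

    ``P_by_node[i]`` is the transition matrix on the branch above node i.
    Missing tip states (index -1) contribute a partial vector of ones.
    """
    n_sites = tip_idx.shape[1]
    partial: list[np.ndarray | None] = [None] * tree.n_nodes
    logscale = np.zeros(n_sites)
    for v in tree.postorder:
        M = np.ones((N_STATES, n_sites))
        for c in tree.children(v):
            if c < tree.n_tips:
                idx = tip_idx[c]
                contrib = P_by_node[c][:, np.clip(idx, 0, None)]
                if (idx < 0).any():
                    contrib = contrib.copy()
                    contrib[:, idx < 0] = 1.0
            else:
                contrib = P_by_node[c] @ partial[c]
                partial[c] = None
            M *= contrib
        m = M.max(axis=0)
        m[m <= 0] = 1.0
        M /= m
        logscale += np.log(m)
        partial[v] = M
    site_lik = pi @ partial[tree.root]
    return np.log(np.clip(site_lik, 1e-300, None)) + logscale


def mixture_rate_scale(kappa: float, omegas: np.ndarray,
                       weights: np.ndarray, pi: np.ndarray) -> float:
    """Weighted-average substitution rate over omega classes.

    Site-mixture models share one set of branch lengths; dividing every
    class generator by this average makes a unit branch length equal one
    expected substitution per codon averaged over site classes, while
    high-omega classes evolve correspondingly faster than low-omega ones.
    """
    rates = np.array([_unscaled_rate_matrix(kappa, max(float(om), 1e-8),
                                            pi)[1] for om in omegas])
    return float(np.dot(np.asarray(weights, float), rates))


def site_logliks_by_omega(alignment_or_idx, tree: PhyloTree, kappa: float,
                          omegas: np.ndarray, pi: np.ndarray,
                          weights: np.ndarray | None = None,
                          rate_scale: float | None = None) -> np.ndarray:
    """(K, n_sites) matrix of per-site log-likelihoods, one row per omega.

    Shared workhorse for the site-mixture models and BEB: tip data and the
    tree are fixed while omega varies across rate classes, so the pruning
    pass is batched over classes.

    Rate scaling: with ``weights`` the class generators share the
    mixture-average scale (the codeml convention for site models); with
    an explicit ``rate_scale`` that fixed scale is used (BEB holds it at
    the M8 optimum); with neither, each class is scaled to unit rate on
    its own (the single-class / M0 case).
    """
    if isinstance(alignment_or_idx, CodonAlignment):
        raise TypeError("pass pre-ordered tip indices")
    tip_idx = alignment_or_idx
    omegas = np.asarray(omegas, float)
    K = len(omegas)
    if weights is not None and rate_scale is None:
        rate_scale = mixture_rate_scale(kappa, omegas, weights, pi)
    # per-node stacks of transition matrices: P[node][k] = P_k(t_node)
    P = np.empty((tree.n_nodes, K, N_STATES, N_STATES))
    for k, om in enumerate(omegas):
        Q, own_rate = _unscaled_rate_matrix(kappa, max(float(om), 1e-8), pi)
        Q = Q / (own_rate if rate_scale is None else rate_scale)
        spec = _Spectral(Q, pi)
        E = np.exp(spec.evals[None, :] * tree.lengths[:, None])
        Pk = (spec.left[None, :, :] * E[:, None, :]) @ spec.right
        np.clip(Pk, 0.0, None, out=Pk)
        Pk /= Pk.sum(axis=2, keepdims=True)
        P[:, k] = Pk
    return _site_logliks_multi(tip_idx, tree, P, pi)


def _site_logliks_multi(tip_idx: np.ndarray, tree: PhyloTree,
                        P: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Pruning over an (n_nodes, K, 61, 61) stack of transition matrices."""
    K = P.shape[1]
    n_sites = tip_idx.shape[1]
    logscale = np.zeros((K, n_sites))
    partial: list[np.ndarray | None] = [None] * tree.n_nodes
    for v in tree.postorder:
        M = None
        for c in tree.children(v):
            if c < tree.n_tips:
                idx = tip_idx[c]
                contrib = np.take(P[c], np.clip(idx, 0, None), axis=2)
                if (idx < 0).any():
                    contrib[:, :, idx < 0] = 1.0
            else:
                contrib = P[c] @ partial[c]
                partial[c] = None
            M = contrib if M is None else M * contrib
        m = M.max(axis=1)
        m[m <= 0] = 1.0
        M /= m[:, None, :]
        logscale += np.log(m)
        partial[v] = M
    site_lik = np.einsum("j,kjs->ks", pi, partial[tree.root])
    return np.log(np.clip(site_lik, 1e-300, None)) + logscale


def log_likelihood(alignment: CodonAlignment, tree: PhyloTree,
                   params: CodonModelParams) -> float:
    """Total log-likelihood of the alignment on the tree under a single-
    omega GY94 model, summed over independent codon sites."""
    if alignment.n_sites == 0:
        raise ValueError("empty alignment")
    tip_idx = _check_taxa(alignment, tree)
    ll = site_logliks_by_omega(tip_idx, tree, params.kappa,
                               np.array([params.omega]), params.pi)
    return float(ll.sum())


# --------------------------------------------------------------------------
# M0 fitting
# --------------------------------------------------------------------------
_LOG_KAPPA_BOUNDS = (np.log(0.01), np.log(100.0))
_LOG_OMEGA_BOUNDS = (np.log(1e-4), np.log(OMEGA_CAP))
_LOG_BLEN_BOUNDS = (np.log(1e-7), np.log(50.0))


def compress_patterns(tip_idx: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique site patterns, inverse map, and multiplicities.

    Identical codon columns have identical likelihoods, so fits evaluate
    each pattern once and weight by its count.
    """
    uniq, inv, counts = np.unique(tip_idx, axis=1, return_inverse=True,
                                  return_counts=True)
    return uniq, inv, counts.astype(float)


def _no_variation(tip_idx: np.ndarray) -> bool:
    obs = np.where(tip_idx >= 0, tip_idx, -1)
    for col in obs.T:
        vals = col[col >= 0]
        if vals.size and (vals != vals[0]).any():
            return False
    return True


def fit_M0(alignment: CodonAlignment, tree: PhyloTree,
           optimize_branch_lengths: bool = True,
           pi: np.ndarray | None = None, n_starts: int = 3,
           seed: int = 0, tol: float = 1e-8) -> FitResult:
    """Maximum-likelihood fit of the one-ratio model: a single omega and
    kappa shared by all sites and branches, pi fixed at F3x4.

    Branch lengths are co-estimated unless ``optimize_branch_lengths`` is
    False, in which case the input tree's lengths are held fixed.
    Optimization is box-constrained quasi-Newton on log-transformed
    parameters with ``n_starts`` jittered restarts.
    """
    if alignment.n_taxa < 2:
        raise ValueError("need at least two taxa")
    tip_idx = _check_taxa(alignment, tree)
    if pi is None:
        pi = f3x4_frequencies(alignment)
    if _no_variation(tip_idx):
        params = CodonModelParams(2.0, np.nan, pi)
        lnl = float(site_logliks_by_omega(
            tip_idx, tree.with_lengths(np.zeros(tree.n_nodes)),
            2.0, np.array([1.0]), pi).sum())
        return FitResult("M0", lnl, params, tree.with_lengths(
            np.zeros(tree.n_nodes)), True, 0,
            message="zero divergence: omega undefined")

    edges = tree.edges
    patterns, _, pat_w = compress_patterns(tip_idx)
    n_ev = 0

    def unpack(theta):
        kappa, omega = np.exp(theta[0]), np.exp(theta[1])
        if optimize_branch_lengths:
            lengths = np.zeros(tree.n_nodes)
            lengths[edges] = np.exp(theta[2:])
            t = tree.with_lengths(lengths)
        else:
            t = tree
        return kappa, omega, t

    def nll(theta):
        nonlocal n_ev
        n_ev += 1
        kappa, omega, t = unpack(theta)
        ll = site_logliks_by_omega(patterns, t, kappa,
                                   np.array([omega]), pi)
        return -float(ll[0] @ pat_w)

    rng = np.random.default_rng(seed)
    base = [np.log(2.0), np.log(0.4)]
    if optimize_branch_lengths:
        base += list(np.log(np.clip(tree.lengths[edges], 1e-4, None)))
    bounds = [_LOG_KAPPA_BOUNDS, _LOG_OMEGA_BOUNDS] + \
        [_LOG_BLEN_BOUNDS] * (len(base) - 2)
    best = None
    for s in range(max(1, n_starts)):
        x0 = np.array(base) + (0.0 if s == 0 else rng.normal(0, 0.3, len(base)))
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": tol, "maxiter": 500})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    kappa, omega, t_hat = unpack(best.x)
    capped = omega >= OMEGA_CAP * 0.999
    params = CodonModelParams(kappa, min(omega, OMEGA_CAP), pi)
    return FitResult(
        "M0", -float(best.fun), params, t_hat, bool(best.success), n_ev,
        message="omega at cap (zero synonymous divergence?)" if capped else "")
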