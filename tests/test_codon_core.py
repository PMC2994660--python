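"""Codon alignment handling, the GY94 generator, and pruning likelihood."""

import numpy as np
import pytest

from coevoscan import (CodonAlignment, CodonModelParams, PhyloTree,
                       SimSpecCodon, backtranslate, build_rate_matrix,
                       f3x4_frequencies, fit_M0, log_likelihood,
                       simulate_codon_alignment, transition_probabilities)
from coevoscan.codon_core import (CODON_INDEX, CODONS, StopCodonError,
                                  _check_taxa, site_logliks_by_omega)

from conftest import random_pi


# ---------------------------------------------------------------- alignment
class TestCodonAlignment:
    def test_rejects_unequal_lengths(self):
        with pytest.raises(ValueError, match="equal length"):
            CodonAlignment.from_sequences({"a": "ATGATG", "b": "ATG"})

    def test_rejects_frame_violation(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            CodonAlignment.from_sequences({"a": "ATGA", "b": "ATGA"})

    def test_stop_codon_raises_unless_masked(self):
        seqs = {"a": "ATGTAA", "b": "ATGCAA"}
        with pytest.raises(StopCodonError):
            CodonAlignment.from_sequences(seqs)
        aln = CodonAlignment.from_sequences(seqs, mask_stops=True)
        assert aln.codon_idx[0, 1] == -1          # masked, treated missing

    def test_gap_and_ambiguous_are_missing(self):
        aln = CodonAlignment.from_sequences({"a": "ATG---GCN", "b": "ATGCCTGCT"})
        assert list(aln.codon_idx[0]) == [CODON_INDEX["ATG"], -1, -1]
        assert aln.gap_columns().tolist() == [False, True, True]

    def test_slice_and_concat_roundtrip(self):
        aln = CodonAlignment.from_sequences({"a": "ATGGCTCAT", "b": "ATGGCACAC"})
        left, right = aln.slice_codons(0, 2), aln.slice_codons(2, 3)
        back = left.concat(right)
        assert back.sequences == aln.sequences


# ------------------------------------------------------------ backtranslate
class TestBacktranslate:
    def test_gap_becomes_triple_gap(self):
        aln = backtranslate({"t": "M-A"}, {"t": "ATGGCT"})
        assert aln.sequences[0] == "ATG---GCT"

    def test_ungapped_is_identity(self):
        cds = "ATGGCTCATACT"
        aln = backtranslate({"t": "MAHT"}, {"t": cds})
        assert aln.sequences[0] == cds

    def test_three_taxon_hand_checked(self):
        prot = {"a": "MA-T", "b": "M-HT", "c": "MAHT"}
        cds = {"a": "ATGGCTACT", "b": "ATGCATACA", "c": "ATGGCACACACG"}
        aln = backtranslate(prot, cds)
        expect = {"a": "ATGGCT---ACT", "b": "ATG---CATACA",
                  "c": "ATGGCACACACG"}
        assert dict(zip(aln.taxa, aln.sequences)) == expect

    def test_terminal_stop_dropped(self):
        aln = backtranslate({"t": "MA"}, {"t": "ATGGCTTAA"})
        assert aln.sequences[0] == "ATGGCT"

    def test_translation_mismatch_reports_position(self):
        with pytest.raises(ValueError, match="residue 2"):
            backtranslate({"t": "MK"}, {"t": "ATGGCT"})

    def test_length_mismatch_reported(self):
        with pytest.raises(ValueError, match="CDS length"):
            backtranslate({"t": "MAH"}, {"t": "ATGGCT"})


# ----------------------------------------------------------------- F3x4 pi
class TestF3x4:
    def test_uniform_composition_gives_uniform_pi(self):
        # every nucleotide once per position across 4 taxa
        seqs = {f"t{i}": "".join(n * 3 for n in "ACGT")[3 * i:3 * i + 3] * 4
                for i in range(4)}
        seqs = {"t0": "AAACCCGGGTTT", "t1": "CCCGGGTTTAAA",
                "t2": "GGGTTTAAACCC", "t3": "TTTAAACCCGGG"}
        pi = f3x4_frequencies(CodonAlignment.from_sequences(seqs))
        assert np.allclose(pi, 1.0 / 61)

    def test_single_codon_matches_product_rule(self):
        # "AAA" x 4: position counts A=4 others 0 -> pseudocount 0.5 each
        aln = CodonAlignment.from_sequences({"t": "AAAAAAAAAAAA"})
        f = np.array([4.5, 0.5, 0.5, 0.5]) / 6.0
        nuc = "ACGT"
        expect = np.array([f[nuc.index(c[0])] * f[nuc.index(c[1])]
                           * f[nuc.index(c[2])] for c in CODONS])
        expect /= expect.sum()
        assert np.allclose(f3x4_frequencies(aln), expect)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_normalized_for_random_alignments(self, sensu_tree, seed):
        spec = SimSpecCodon(sensu_tree, "M0", {"kappa": 2.0, "omega": 0.5},
                            n_codons=40, seed=seed)
        aln, _ = simulate_codon_alignment(spec)
        pi = f3x4_frequencies(aln)
        assert pi.shape == (61,) and np.all(pi > 0)
        assert np.isclose(pi.sum(), 1.0)


# ------------------------------------------------------------- rate matrix
class TestRateMatrix:
    @pytest.mark.parametrize("seed", range(5))
    def test_generator_scaling_and_reversibility(self, seed):
        rng = np.random.default_rng(seed)
        pi = random_pi(rng)
        params = CodonModelParams(float(rng.uniform(0.5, 5)),
                                  float(rng.uniform(0.01, 3)), pi)
        Q = build_rate_matrix(params)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12
        assert np.isclose(-np.dot(pi, np.diag(Q)), 1.0)
        flux = pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-12

    def test_neutral_symmetric_rates_all_equal(self):
        pi = np.full(61, 1.0 / 61)
        Q = build_rate_matrix(CodonModelParams(1.0, 1.0, pi))
        off = Q[~np.eye(61, dtype=bool)]
        rates = off[off > 0]
        assert np.allclose(rates, rates[0])

    def test_named_rate_ratios(self):
        pi = np.full(61, 1.0 / 61)
        Q = build_rate_matrix(CodonModelParams(2.0, 0.5, pi))
        i = CODON_INDEX
        syn_tv = Q[i["CGT"], i["CGA"]]       # Arg->Arg, T->A transversion
        nonsyn_tv = Q[i["TTT"], i["TTA"]]    # Phe->Leu, T->A transversion
        syn_ts = Q[i["TTT"], i["TTC"]]       # Phe->Phe, T->C transition
        assert np.isclose(nonsyn_tv / syn_tv, 0.5)
        assert np.isclose(syn_ts / syn_tv, 2.0)

    def test_double_changes_forbidden(self):
        pi = np.full(61, 1.0 / 61)
        Q = build_rate_matrix(CodonModelParams(2.0, 0.5, pi))
        i = CODON_INDEX
        assert Q[i["AAA"], i["ACC"]] == 0.0
        assert Q[i["AAA"], i["CCC"]] == 0.0


class TestTransitionProbabilities:
    def test_identity_at_zero(self):
        pi = np.full(61, 1.0 / 61)
        Q = build_rate_matrix(CodonModelParams(2.0, 0.5, pi))
        assert np.allclose(transition_probabilities(Q, 0.0), np.eye(61))

    def test_rows_stochastic(self):
        rng = np.random.default_rng(3)
        pi = random_pi(rng)
        Q = build_rate_matrix(CodonModelParams(3.0, 0.2, pi))
        P = transition_probabilities(Q, 0.7, pi=pi)
        assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-10
        assert P.min() >= 0

    def test_long_branch_reaches_stationarity(self):
        rng = np.random.default_rng(4)
        pi = random_pi(rng)
        Q = build_rate_matrix(CodonModelParams(2.0, 1.5, pi))
        P = transition_probabilities(Q, 50.0, pi=pi)
        assert np.abs(P - pi[None, :]).max() < 1e-6

    def test_negative_time_rejected(self):
        pi = np.full(61, 1.0 / 61)
        Q = build_rate_matrix(CodonModelParams(2.0, 0.5, pi))
        with pytest.raises(ValueError):
            transition_probabilities(Q, -0.1)


# --------------------------------------------------------------- likelihood
def _two_taxon_oracle(aln, tree, params):
    """Direct sum over the 61 root states for a 2-tip tree."""
    Q = build_rate_matrix(params)
    tips = {t: i for i, t in enumerate(tree.taxa)}
    Ps = {c: transition_probabilities(Q, tree.lengths[c], pi=params.pi)
          for c in range(2)}
    idx = _check_taxa(aln, tree)
    total = 0.0
    for s in range(aln.n_sites):
        site = 0.0
        for root in range(61):
            term = params.pi[root]
            for tip in range(2):
                obs = idx[tip, s]
                term *= Ps[tip][root, obs] if obs >= 0 else 1.0
            site += term
        total += np.log(site)
    return total


class TestLogLikelihood:
    def test_two_taxon_matches_direct_sum(self):
        rng = np.random.default_rng(5)
        pi = random_pi(rng)
        params = CodonModelParams(2.3, 0.6, pi)
        tree = PhyloTree.from_newick("(a:0.2,b:0.5);")
        aln = CodonAlignment.from_sequences(
            {"a": "ATGGCTCAT---", "b": "ATGGGACACAAA"})
        assert np.isclose(log_likelihood(aln, tree, params),
                          _two_taxon_oracle(aln, tree, params), atol=1e-9)

    def test_concatenation_doubles_lnl(self, sensu_tree):
        spec = SimSpecCodon(sensu_tree, "M0", {"kappa": 2.0, "omega": 0.5},
                            n_codons=30, seed=8)
        aln, _ = simulate_codon_alignment(spec)
        pi = f3x4_frequencies(aln)
        params = CodonModelParams(2.0, 0.5, pi)
        single = log_likelihood(aln, sensu_tree, params)
        double = log_likelihood(aln.concat(aln), sensu_tree, params)
        assert np.isclose(double, 2 * single, rtol=1e-12)

    def test_invariant_to_taxon_order(self, sensu_tree):
        spec = SimSpecCodon(sensu_tree, "M0", {"kappa": 2.0, "omega": 0.5},
                            n_codons=25, seed=9)
        aln, _ = simulate_codon_alignment(spec)
        pi = f3x4_frequencies(aln)
        params = CodonModelParams(2.0, 0.5, pi)
        shuffled = CodonAlignment.from_sequences(
            {t: s for t, s in sorted(zip(aln.taxa, aln.sequences),
                                     reverse=True)})
        assert np.isclose(log_likelihood(aln, sensu_tree, params),
                          log_likelihood(shuffled, sensu_tree, params))

    def test_invariant_to_rerooting(self):
        """Reversibility: the likelihood does not depend on where the
        computational root sits along the unrooted tree."""
        aln = CodonAlignment.from_sequences(
            {"a": "ATGGCT", "b": "ATGGGA", "c": "CTGGCT", "d": "ATGTCT"})
        pi = f3x4_frequencies(aln)
        params = CodonModelParams(2.0, 0.4, pi)
        t1 = PhyloTree.from_newick("((a:0.1,b:0.2):0.3,c:0.4,d:0.5);")
        t2 = PhyloTree.from_newick("((c:0.4,d:0.5):0.3,a:0.1,b:0.2);")
        assert np.isclose(log_likelihood(aln, t1, params),
                          log_likelihood(aln, t2, params), atol=1e-9)

    def test_label_mismatch_rejected(self, sensu_tree):
        aln = CodonAlignment.from_sequences({"x": "ATG", "y": "ATG"})
        pi = np.full(61, 1.0 / 61)
        with pytest.raises(ValueError, match="tips"):
            log_likelihood(aln, sensu_tree, CodonModelParams(2.0, 0.5, pi))


# -------------------------------------------------------------------- fit
class TestFitM0:
    def test_recovers_generating_omega(self, sensu_tree, m0_alignment):
        aln, _ = m0_alignment
        fit = fit_M0(aln, sensu_tree, optimize_branch_lengths=False,
                     n_starts=1)
        assert abs(fit.params.omega - 0.44) < 0.08
        assert fit.converged

    def test_omega_zero_data(self, sensu_tree):
        from Bio.Seq import Seq
        spec = SimSpecCodon(sensu_tree, "M0", {"kappa": 2.0, "omega": 0.0},
                            n_codons=400, seed=21)
        aln, _ = simulate_codon_alignment(spec)
        # purifying limit: all sequences code the same protein
        prots = {str(Seq(s).translate()) for s in aln.sequences}
        assert len(prots) == 1
        fit = fit_M0(aln, sensu_tree, optimize_branch_lengths=False,
                     n_starts=1)
        assert fit.params.omega < 0.02

    def test_zero_divergence_sentinel(self, sensu_tree):
        seq = "ATGGCTCATACT"
        aln = CodonAlignment.from_sequences(
            {t: seq for t in sensu_tree.taxa})
        fit = fit_M0(aln, sensu_tree)
        assert np.isnan(fit.params.omega)
        assert "zero divergence" in fit.message

    def test_refit_from_optimum_is_stable(self, sensu_tree, m0_alignment):
        aln, _ = m0_alignment
        fit = fit_M0(aln, sensu_tree, optimize_branch_lengths=True,
                     n_starts=1)
        # evaluating the reported optimum reproduces the reported lnL
        ll = log_likelihood(aln, fit.tree, fit.params)
        assert np.isclose(ll, fit.lnL, atol=1e-6)

    def test_requires_two_taxa(self, sensu_tree):
        aln = CodonAlignment.from_sequences({"a": "ATG"})
        with pytest.raises(ValueError):
            fit_M0(aln, sensu_tree)
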