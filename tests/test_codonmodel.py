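"""Rate matrix, transition probabilities, likelihood, fitting, LRT, NG86, FDR."""

import numpy as np
import pytest
from scipy.linalg import expm

from cardevol.codonmodel import (
    CodonFrequencies,
    CodonModel,
    ModelSpec,
    PhyloTree,
    branch_rates,
    build_rate_matrix,
    fdr_qvalues,
    fit_model,
    log_likelihood,
    lrt,
    nested_start,
    ng86_rates,
    transition_probabilities,
)
from cardevol.genetics import CODON_INDEX, N_CODONS, SENSE_CODONS
from cardevol.simulate import simulate_site_class_alignment

from conftest import taylor_expm

BL = {"At": 0.3, "Ci": 0.07, "Cr": 0.07}


def _sim(n_codons, omega, kappa=2.0, pi=None, seed=0, bl=BL):
    pi = pi if pi is not None else np.full(61, 1 / 61)
    om = omega if isinstance(omega, dict) else {b: omega for b in BL}
    mat, _ = simulate_site_class_alignment(n_codons, bl, [(1.0, om)], kappa, pi, seed)
    return mat


class TestRateMatrix:
    def test_generator_and_stationarity(self, uniform_pi):
        Q = build_rate_matrix(2.0, 0.5, uniform_pi)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert np.allclose(uniform_pi @ Q, 0.0, atol=1e-12)
        assert np.isclose(-(uniform_pi * np.diag(Q)).sum(), 1.0)

    def test_reversibility(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(61))
        Q = build_rate_matrix(3.0, 0.4, pi)
        flux = pi[:, None] * Q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_symmetric_rates_at_kappa_omega_one(self, uniform_pi):
        Q = build_rate_matrix(1.0, 1.0, uniform_pi)
        off = Q[Q > 0]
        assert np.allclose(off, off[0])

    def test_kappa_omega_ratio_of_entries(self, uniform_pi):
        # synonymous transition TTT->TTC vs non-synonymous transversion TTT->TTA
        Q = build_rate_matrix(2.0, 0.5, uniform_pi)
        i, j_syn, j_non = CODON_INDEX["TTT"], CODON_INDEX["TTC"], CODON_INDEX["TTA"]
        assert np.isclose(Q[i, j_syn] / Q[i, j_non], 2.0 / 0.5)

    def test_rejects_bad_parameters(self, uniform_pi):
        with pytest.raises(ValueError):
            build_rate_matrix(-1.0, 0.5, uniform_pi)
        with pytest.raises(ValueError):
            build_rate_matrix(2.0, -0.1, uniform_pi)


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self, uniform_pi):
        Q = build_rate_matrix(2.0, 0.3, uniform_pi)
        assert np.allclose(transition_probabilities(Q, 0.0, uniform_pi), np.eye(61))

    def test_rows_are_distributions(self):
        rng = np.random.default_rng(1)
        pi = rng.dirichlet(np.ones(61) * 5)
        Q = build_rate_matrix(2.0, 0.3, pi)
        for t in (0.01, 0.5, 3.0):
            P = transition_probabilities(Q, t, pi)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert P.min() >= 0

    def test_matches_series_expansion_oracle(self, uniform_pi):
        Q = build_rate_matrix(2.0, 0.3, uniform_pi)
        P = transition_probabilities(Q, 0.05, uniform_pi)
        assert np.max(np.abs(P - taylor_expm(Q, 0.05))) < 1e-8


class TestLogLikelihood:
    def test_single_codon_zero_time_closed_form(self, uniform_freqs):
        c = CODON_INDEX["ATG"]
        mat = np.array([[c], [c], [c]])
        tree = PhyloTree(0.0, 0.0, 0.0)
        ll = log_likelihood(mat, tree, "M0", {"kappa": 2.0, "omega": 0.3})
        model = CodonModel(mat, "M0")
        expected = float(np.log(model.freqs.pi[c]))
        assert np.isclose(ll, expected, atol=1e-10)

    def test_m0_equals_free_ratio_with_equal_omegas(self):
        mat = _sim(80, 0.2, seed=3)
        params = {"kappa": 2.0, "t_At": 0.3, "t_Ci": 0.07, "t_Cr": 0.07}
        tree = PhyloTree(0.3, 0.07, 0.07)
        ll0 = log_likelihood(mat, tree, "M0", {**params, "omega": 0.2})
        llf = log_likelihood(
            mat, tree, "FR", {**params, "omega_At": 0.2, "omega_Ci": 0.2, "omega_Cr": 0.2}
        )
        assert np.isclose(ll0, llf, atol=1e-9)

    def test_pruning_matches_explicit_state_summation(self, uniform_pi):
        mat = _sim(50, 0.2, seed=1)
        model = CodonModel(mat, "M0", freqs=CodonFrequencies.uniform())
        x = {"kappa": 2.0, "omega": 0.2, "t_At": 0.3, "t_Ci": 0.07, "t_Cr": 0.07}
        Q = build_rate_matrix(2.0, 0.2, uniform_pi)
        Ps = [expm(Q * t) for t in (0.3, 0.07, 0.07)]
        brute = 0.0
        for col in mat.T:
            s = sum(
                uniform_pi[y] * Ps[0][y, col[0]] * Ps[1][y, col[1]] * Ps[2][y, col[2]]
                for y in range(N_CODONS)
            )
            brute += np.log(s)
        assert abs(model.loglike(x) - brute) < 1e-8

    def test_invariant_under_column_permutation(self):
        mat = _sim(60, 0.3, seed=5)
        perm = np.random.default_rng(0).permutation(60)
        model_a = CodonModel(mat, "M0", freqs=CodonFrequencies.uniform())
        model_b = CodonModel(mat[:, perm], "M0", freqs=CodonFrequencies.uniform())
        x = {"kappa": 2.0, "omega": 0.3, "t_At": 0.3, "t_Ci": 0.07, "t_Cr": 0.07}
        assert model_a.loglike(x) == pytest.approx(model_b.loglike(x), abs=1e-9)


class TestFitting:
    def test_identical_sequences_give_zero_branch_lengths(self):
        row = np.arange(40) % 61
        mat = np.vstack([row, row, row])
        res = fit_model(mat, "M0", restarts=0)
        assert all(res.params[f"t_{b}"] < 1e-4 for b in ("At", "Ci", "Cr"))

    def test_refit_is_deterministic(self):
        mat = _sim(120, 0.25, seed=7)
        r1 = fit_model(mat, "M0", restarts=2, seed=42)
        r2 = fit_model(mat, "M0", restarts=2, seed=42)
        assert abs(r1.llf - r2.llf) < 1e-8
        assert np.allclose(r1.params_vector, r2.params_vector)

    def test_summary_mentions_estimates(self):
        mat = _sim(60, 0.25, seed=8)
        res = fit_model(mat, "M0", restarts=0)
        text = res.summary()
        assert "log-likelihood" in text and "omega" in text

    def test_branch_rates_conventions(self):
        mat = _sim(300, {"At": 0.2, "Ci": 0.2, "Cr": 0.2}, seed=9)
        res = fit_model(mat, "FR", restarts=0)
        br = res.branch_rates()
        for b in ("At", "Ci", "Cr"):
            d = br.branches[b]
            if d["dS"] > 0:
                # under the mutational-opportunity convention dN/dS == model omega
                assert d["omega"] == pytest.approx(res.params[f"omega_{b}"], rel=1e-6)
        assert br.N + br.S == pytest.approx(3 * 300)

    def test_branch_rates_zero_length_branch(self):
        mat = _sim(60, 0.2, seed=10)
        model = CodonModel(mat, "FR")
        res = model.fit(restarts=0)
        res.params_vector[model.param_names.index("t_Ci")] = 0.0
        br = res.branch_rates()
        assert br.branches["Ci"]["dN"] == 0 and br.branches["Ci"]["dS"] == 0
        assert np.isnan(br.branches["Ci"]["omega"])


class TestLRT:
    def test_equal_likelihoods_give_p_one(self):
        mat = _sim(60, 0.2, seed=11)
        null = fit_model(mat, "M0", restarts=0)
        alt = fit_model(mat, "FR", start=nested_start("FR", null), restarts=0)
        r = lrt(null, alt)
        assert r.statistic >= 0 and 0 <= r.pvalue <= 1
        # statistic zero -> P exactly 1
        alt2 = alt
        alt2.llf = null.llf
        assert lrt(null, alt2).pvalue == pytest.approx(1.0)

    @pytest.mark.parametrize("stat,df,p", [(3.841, 1, 0.05), (5.991, 2, 0.05)])
    def test_chi_square_quantiles(self, stat, df, p):
        from scipy.stats import chi2

        assert chi2.sf(stat, df) == pytest.approx(p, abs=5e-4)

    def test_nesting_violation_raises(self):
        mat = _sim(60, 0.2, seed=12)
        null = fit_model(mat, "M0", restarts=0)
        alt = fit_model(mat, "FR", start=nested_start("FR", null), restarts=0)
        null.llf = alt.llf + 1.0  # corrupt to simulate optimization failure
        with pytest.raises(RuntimeError):
            lrt(null, alt)


class TestNG86:
    def test_identical_sequences(self):
        r = ng86_rates("AAATTTGGG", "AAATTTGGG")
        assert r.pn == r.ps == r.dn == r.ds == 0

    def test_hand_example_ten_codons(self):
        a = "AAA" * 9 + "TTT"
        b = "AAA" * 9 + "TTC"
        r = ng86_rates(a, b)
        assert r.S == pytest.approx(10 / 3)
        assert r.sd == pytest.approx(1.0)
        assert r.ps == pytest.approx(0.3)
        assert r.ds == pytest.approx(-0.75 * np.log(0.6), abs=1e-6)
        assert r.dn == 0

    def test_single_nonsynonymous_change(self):
        r = ng86_rates("AAA", "AGA")  # Lys -> Arg
        assert r.nd == 1 and r.sd == 0

    def test_saturation_flagged(self):
        # wildly divergent single codon pair: pS can exceed the JC domain
        r = ng86_rates("TTA" * 2, "CTG" * 2)
        assert isinstance(r.saturated, bool)

    def test_multi_path_codon_averages(self):
        # AAA -> AGG differs at two positions; pathways averaged
        r = ng86_rates("AAA", "AGG")
        assert r.nd + r.sd == pytest.approx(2.0)


class TestFDR:
    def test_bh_worked_example(self):
        q = fdr_qvalues([0.01, 0.02, 0.9])
        assert np.allclose(q, [0.03, 0.03, 0.9])

    def test_all_ones(self):
        assert np.allclose(fdr_qvalues([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        assert fdr_qvalues([0.37])[0] == pytest.approx(0.37)

    def test_monotone_in_p_ordering(self, rng):
        p = rng.random(50)
        q = fdr_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_storey_no_larger_than_bh(self, rng):
        p = np.concatenate([rng.random(80), rng.random(20) * 1e-3])
        assert np.all(fdr_qvalues(p, "storey") <= fdr_qvalues(p, "bh") + 1e-12)
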