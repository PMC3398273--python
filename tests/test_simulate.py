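"""Synthetic-data generator: forward simulation, expression model, datasets."""

import numpy as np
import pytest
from scipy.stats import chisquare, norm, spearmanr

from cardevol.codonmodel import build_rate_matrix
from cardevol.genetics import N_CODONS, STOP_CODONS, codons_to_indices
from cardevol.simulate import (
    SimulationConfig,
    default_sample_layout,
    deterministic_expression,
    simulate_codon_alignment,
    simulate_dataset,
    simulate_expression_profile,
    simulate_site_class_alignment,
    skewed_codon_frequencies,
)

from conftest import taylor_expm

BL = {"At": 0.3, "Ci": 0.07, "Cr": 0.07}


class TestCodonAlignmentSimulation:
    def test_zero_branch_lengths_identical_sequences(self, uniform_pi):
        seqs = simulate_codon_alignment(50, {b: 0.0 for b in BL}, 0.2, 2.0, uniform_pi, seed=0)
        assert seqs[0] == seqs[1] == seqs[2]

    def test_no_internal_stop_codons(self, uniform_pi):
        seqs = simulate_codon_alignment(500, BL, 0.5, 2.0, uniform_pi, seed=1)
        for s in seqs:
            for k in range(0, len(s), 3):
                assert s[k : k + 3] not in STOP_CODONS

    def test_rejects_invalid_inputs(self, uniform_pi):
        with pytest.raises(ValueError):
            simulate_codon_alignment(50, BL, 0.2, 2.0, uniform_pi * 2, seed=0)
        with pytest.raises(ValueError):
            simulate_codon_alignment(50, {"At": -0.1, "Ci": 0.1, "Cr": 0.1}, 0.2, 2.0, uniform_pi)
        with pytest.raises(ValueError):
            simulate_codon_alignment(50, BL, -0.2, 2.0, uniform_pi)

    def test_pairwise_difference_matches_analytic_oracle(self, uniform_pi):
        """Fraction of differing codon columns between two tips matches
        1 - sum_i pi_i P_ii(t_sum) from a series-expansion oracle."""
        t = {"At": 0.3, "Ci": 0.07, "Cr": 0.07}
        seqs = simulate_codon_alignment(10000, t, 0.2, 2.0, uniform_pi, seed=2)
        a, b = codons_to_indices(seqs[1]), codons_to_indices(seqs[2])
        observed = float(np.mean(a != b))
        Q = build_rate_matrix(2.0, 0.2, uniform_pi)
        P = taylor_expm(Q, t["Ci"] + t["Cr"], order=20)
        expected = 1.0 - float(uniform_pi @ np.diag(P))
        se = np.sqrt(expected * (1 - expected) / 10000)
        assert abs(observed - expected) < 3 * se

    def test_omega_zero_forbids_amino_acid_changes(self, uniform_pi):
        from cardevol.genetics import translate

        t = {"At": 0.0, "Ci": 0.5, "Cr": 0.0}
        mat, _ = simulate_site_class_alignment(
            400, t, [(1.0, {"At": 0.2, "Ci": 0.0, "Cr": 0.2})], 2.0, uniform_pi, 3
        )
        assert translate(mat[1]) == translate(mat[0])

    def test_codon_frequencies_converge_to_pi(self):
        rng = np.random.default_rng(4)
        pi = skewed_codon_frequencies(0.3, rng)
        mat, _ = simulate_site_class_alignment(
            100000, {b: 0.0 for b in BL}, [(1.0, {b: 0.2 for b in BL})], 2.0, pi, rng
        )
        counts = np.bincount(mat[0], minlength=N_CODONS)
        stat, p = chisquare(counts, pi * counts.sum())
        assert p > 0.01


class TestExpressionSimulation:
    def test_zero_noise_is_deterministic(self):
        layout = default_sample_layout()
        import pandas as pd

        latents = pd.DataFrame(
            {
                "gene_id": ["g1", "g2"],
                "level": [8.0, 10.0],
                "specificity": [0.0, 0.5],
                "preferred_organ": ["leaf", "root"],
                **{f"persist_{s}": [1, 2] for s in ("UV-B", "drought", "salt", "cold", "osmotic")},
            }
        )
        m1 = simulate_expression_profile(latents, layout, 0.0, seed=1)
        m2 = deterministic_expression(latents, layout)
        assert np.allclose(m1.to_numpy(), m2.to_numpy())

    def test_negative_noise_rejected(self):
        layout = default_sample_layout()
        import pandas as pd

        latents = pd.DataFrame(
            {
                "gene_id": ["g1"],
                "level": [8.0],
                "specificity": [0.1],
                "preferred_organ": ["leaf"],
                **{f"persist_{s}": [0] for s in ("UV-B", "drought", "salt", "cold", "osmotic")},
            }
        )
        with pytest.raises(ValueError):
            simulate_expression_profile(latents, layout, -0.1)

    def test_organ_specific_gene_has_high_tau(self):
        from cardevol import expression as em

        layout = default_sample_layout()
        import pandas as pd

        latents = pd.DataFrame(
            {
                "gene_id": ["g1"],
                "level": [12.0],
                "specificity": [0.999],
                "preferred_organ": ["root"],
                **{f"persist_{s}": [0] for s in ("UV-B", "drought", "salt", "cold", "osmotic")},
            }
        )
        clean = deterministic_expression(latents, layout)
        prof = em.breadth_profiles(clean, layout)
        assert prof.loc["g1", "tau"] > 0.99
        assert prof.loc["g1", "spatial_breadth"] == 1

    def test_planted_copula_coupling_recovered(self):
        """With class effects off, the rank correlation between latent
        expression and planted omega approaches the Gaussian-copula value
        (6/pi) asin(rho/2)."""
        cfg = SimulationConfig(
            n_genes=2000,
            class_effects={k: {"Ci": 1.0, "Cr": 1.0} for k in ("CRG", "CGO", "PGO", "SGO")},
            seed=5,
        )
        ds = simulate_dataset(cfg)
        gt = ds.ground_truth
        rho_obs = spearmanr(gt["level"], gt["omega_Cr"]).statistic
        rho_expected = 6.0 / np.pi * np.arcsin(cfg.expr_omega_rho / 2.0)
        se = 1.0 / np.sqrt(cfg.n_genes)
        assert rho_obs < 0
        assert abs(rho_obs - rho_expected) < 3 * se


class TestDataset:
    def test_no_decoys_when_rate_zero(self):
        ds = simulate_dataset(SimulationConfig(n_genes=12, paralog_rate=0.0, seed=6))
        for sp in ("At", "Ci", "Cr"):
            assert len(ds.sequences[sp]) == 12
        assert ds.decoy_ids == []

    def test_decoys_only_in_ingroup(self):
        ds = simulate_dataset(SimulationConfig(n_genes=40, paralog_rate=0.5, seed=7))
        assert len(ds.decoy_ids) > 0
        assert all(not d.startswith("At_") for d in ds.decoy_ids)
        assert len(ds.sequences["At"]) == 40

    def test_artifacts_mutually_keyed(self):
        ds = simulate_dataset(SimulationConfig(n_genes=15, seed=8))
        base = set(ds.ground_truth.index)
        assert {g[3:] for g in ds.sequences["At"]} == base
        assert set(ds.class_table["gene_id"]) == base
        assert set(ds.expression.index) == base
        assert set(ds.transit_table["gene_id"]) <= base

    def test_ng86_ds_matches_configured_scale(self, uniform_pi):
        """Mean pairwise NG86 dS between the ingroup tips is within 20% of
        the value implied by twice the ingroup branch length."""
        from cardevol.codonmodel import ng86_rates
        from cardevol.codonmodel import _unscaled_q

        cfg = SimulationConfig()
        ds_vals = []
        for seed in range(4):
            seqs = simulate_codon_alignment(
                2000, cfg.branch_lengths, cfg.omega_mean, cfg.kappa, uniform_pi, seed=seed
            )
            ds_vals.append(ng86_rates(seqs[1], seqs[2]).ds)
        # oracle: expected synonymous substitutions per codon from the
        # generator's rate decomposition, divided by the Nei-Gojobori
        # (unweighted) synonymous site count per codon
        from cardevol.codonmodel import _SYN_SITES
        from cardevol.genetics import PAIR_I, PAIR_J, PAIR_SYN, PAIR_TS

        _, rate = _unscaled_q(cfg.kappa, cfg.omega_mean, uniform_pi)
        syn_flux = float(
            (uniform_pi[PAIR_I] * uniform_pi[PAIR_J] * np.where(PAIR_TS, cfg.kappa, 1.0))[
                PAIR_SYN
            ].sum()
        )
        rho_s = syn_flux / rate
        t_sum = cfg.branch_lengths["Ci"] + cfg.branch_lengths["Cr"]
        s_ng = float(uniform_pi @ _SYN_SITES)
        expected = t_sum * rho_s / s_ng
        assert np.mean(ds_vals) == pytest.approx(expected, rel=0.20)

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(n_genes=10, seed=9)
        d1 = simulate_dataset(cfg).write(tmp_path / "a")
        d2 = simulate_dataset(SimulationConfig(n_genes=10, seed=9)).write(tmp_path / "b")
        assert d1 == d2

    def test_different_seed_differs(self, tmp_path):
        d1 = simulate_dataset(SimulationConfig(n_genes=10, seed=1)).write(tmp_path / "a")
        d2 = simulate_dataset(SimulationConfig(n_genes=10, seed=2)).write(tmp_path / "b")
        assert d1 != d2

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=0)
        with pytest.raises(ValueError):
            SimulationConfig(paralog_rate=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(noise_sd=-1.0)
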