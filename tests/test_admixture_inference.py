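"""Gibbs admixture sampler, LnP(K), Evanno ΔK, alignment, membership bins."""

import numpy as np
import pytest

from musadiv import admixture_inference as adm
from musadiv.structure_encoding import build_matrices
from musadiv.synthetic_data import (
    SimConfig,
    generate_dosage_population,
    generate_population,
)

CHAIN = dict(burnin=800, iters=800)


@pytest.fixture(scope="module")
def disjoint_pools_matrix():
    """Two populations with disjoint allele pools: trivially separable."""
    table, labels = generate_dosage_population(
        {"AA": (2, 0, 20), "BB": (0, 2, 20)}, L=12, seed=41
    )
    ploidies = {a: 2 for a in table.accessions}
    m_one, _ = build_matrices(table, ploidies)
    truth = np.array([[1.0, 0.0] if labels[a] == "AA" else [0.0, 1.0]
                      for a in m_one.accessions])
    return m_one, truth


class TestGibbsSampler:
    def test_k1_membership_is_exactly_one(self, disjoint_pools_matrix):
        m, _ = disjoint_pools_matrix
        res = adm.gibbs_admixture(m, 1, 200, 200, seed=5)
        assert (res.q_hat == 1.0).all()
        assert res.lnpk == pytest.approx(adm.lnpk_estimate(res.lnl_trace[200:]))

    def test_same_seed_bitwise_identical(self, disjoint_pools_matrix):
        m, _ = disjoint_pools_matrix
        r1 = adm.gibbs_admixture(m, 3, 300, 300, seed=99)
        r2 = adm.gibbs_admixture(m, 3, 300, 300, seed=99)
        assert np.array_equal(r1.q_hat, r2.q_hat)
        assert np.array_equal(r1.lnl_trace, r2.lnl_trace)

    def test_disjoint_pools_fully_resolved(self, disjoint_pools_matrix):
        m, truth = disjoint_pools_matrix
        res = adm.gibbs_admixture(m, 2, **CHAIN, seed=13)
        aligned = adm.align_labels([truth, res.q_hat])[1]
        assert res.q_hat.max(axis=1).min() >= 0.95
        assert np.abs(aligned - truth).mean() < 0.05

    def test_two_seeds_agree_after_alignment_on_strong_structure(self, disjoint_pools_matrix):
        m, _ = disjoint_pools_matrix
        r1 = adm.gibbs_admixture(m, 2, **CHAIN, seed=101)
        r2 = adm.gibbs_admixture(m, 2, **CHAIN, seed=202)
        q2 = adm.align_labels([r1.q_hat, r2.q_hat])[1]
        assert np.abs(r1.q_hat - q2).mean() < 0.05

    def test_rows_are_simplex_and_missing_slots_tolerated(self):
        cfg = SimConfig(seed=55, n_accessions=20, missing_rate=0.2)
        table, _, truth = generate_population(cfg)
        m_one, _ = build_matrices(
            table, {a: int(p) for a, p in zip(table.accessions, truth.ploidy)}
        )
        res = adm.gibbs_admixture(m_one, 3, 300, 300, seed=1)
        assert np.allclose(res.q_hat.sum(axis=1), 1.0, atol=1e-9)
        assert res.f.shape == (3,)
        assert ((res.f > 0) & (res.f < 1)).all()
        assert 0 < res.alpha < 10

    def test_invalid_k_rejected(self, disjoint_pools_matrix):
        m, _ = disjoint_pools_matrix
        with pytest.raises(ValueError):
            adm.gibbs_admixture(m, 0, 10, 10, seed=1)


class TestLnpkEstimate:
    def test_constant_and_two_point_samples(self):
        assert adm.lnpk_estimate([3.0, 3.0, 3.0]) == pytest.approx(3.0)
        assert adm.lnpk_estimate([0.0, 2.0]) == pytest.approx(0.0)  # mean 1 - var 2 / 2

    def test_gaussian_samples_approach_mu_minus_half_variance(self):
        rng = np.random.default_rng(8)
        mu, sigma = -1000.0, 3.0
        x = rng.normal(mu, sigma, size=100_000)
        se = sigma / np.sqrt(len(x)) + sigma**2 * np.sqrt(2 / (len(x) - 1)) / 2
        assert adm.lnpk_estimate(x) == pytest.approx(mu - sigma**2 / 2, abs=3 * se)

    def test_order_invariant(self):
        x = [1.0, 5.0, -2.0, 3.5]
        assert adm.lnpk_estimate(x) == pytest.approx(adm.lnpk_estimate(x[::-1]))

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            adm.lnpk_estimate([1.0])


class TestEvanno:
    def test_worked_example(self):
        h = np.sqrt(2) / 2  # replicate pairs mean +- h have sample sd exactly 1
        lnp = {2: [-100 - h, -100 + h], 3: [-90 - h, -90 + h], 4: [-88 - h, -88 + h]}
        table = adm.evanno_delta_k(lnp)
        assert table.loc[3, "delta_k"] == pytest.approx(8.0, rel=1e-9)
        assert np.isnan(table.loc[2, "delta_k"])
        assert np.isnan(table.loc[4, "delta_k"])

    def test_linear_lnp_gives_zero_delta_everywhere(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            a, b = rng.uniform(-5, 5), rng.uniform(-300, -100)
            lnp = {k: [a * k + b + eps for eps in (-0.5, 0.5)] for k in range(2, 8)}
            table = adm.evanno_delta_k(lnp)
            interior = table["delta_k"].dropna()
            assert np.allclose(interior, 0.0, atol=1e-9)

    def test_zero_sd_reports_undefined(self):
        lnp = {2: [-100.0, -100.0], 3: [-90.0, -90.0], 4: [-88.0, -88.0]}
        assert np.isnan(adm.evanno_delta_k(lnp).loc[3, "delta_k"])

    def test_run_order_invariance(self):
        lnp = {2: [-100.0, -99.0], 3: [-91.0, -89.0], 4: [-88.0, -87.0]}
        flipped = {k: v[::-1] for k, v in lnp.items()}
        assert adm.evanno_delta_k(lnp).equals(adm.evanno_delta_k(flipped))

    def test_requires_consecutive_grid_and_replicates(self):
        with pytest.raises(ValueError):
            adm.evanno_delta_k({2: [-1.0, -2.0], 4: [-1.0, -2.0], 5: [-1.0, -2.0]})
        with pytest.raises(ValueError):
            adm.evanno_delta_k({2: [-1.0], 3: [-1.0], 4: [-1.0]})


class TestSelectK:
    def test_argmax_and_tie_rule(self):
        t = adm.evanno_delta_k(
            {2: [-100.0, -99.0], 3: [-90.0, -89.0], 4: [-88.0, -87.0], 5: [-87.5, -86.5]}
        )
        assert adm.select_k(t) == 3
        import pandas as pd

        tied = pd.DataFrame({"delta_k": [np.nan, 4.0, 4.0, np.nan]}, index=[2, 3, 4, 5])
        assert adm.select_k(tied) == 3

    def test_all_undefined_rejected(self):
        import pandas as pd

        t = pd.DataFrame({"delta_k": [np.nan, np.nan]}, index=[2, 3])
        with pytest.raises(ValueError):
            adm.select_k(t)


class TestAlignLabels:
    def test_identity_and_k1_noop(self):
        rng = np.random.default_rng(7)
        q = rng.dirichlet(np.ones(3), size=10)
        assert np.allclose(adm.align_labels([q, q])[1], q)
        q1 = np.ones((5, 1))
        assert np.allclose(adm.align_labels([q1, q1])[1], q1)

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_permutation_exactly_inverted(self, k):
        rng = np.random.default_rng(k)
        q = rng.dirichlet(np.ones(k) * 0.3, size=30)
        perm = rng.permutation(k)
        aligned = adm.align_labels([q, q[:, perm]])[1]
        assert np.allclose(aligned, q)


class TestClassifyMembership:
    def test_bin_boundaries_and_admixture_flag(self):
        q = np.array(
            [
                [0.95, 0.03, 0.02],  # bin 4, not admixed
                [0.90, 0.05, 0.05],  # bin 3, still admixed (strict boundary)
                [0.70, 0.20, 0.10],  # bin 2
                [0.50, 0.30, 0.20],  # bin 1
            ]
        )
        out = adm.classify_membership(q)
        assert out["bin"].tolist() == [4, 3, 2, 1]
        assert out["admixed"].tolist() == [False, True, True, True]

    def test_uniform_row_is_lowest_bin(self):
        out = adm.classify_membership(np.full((1, 4), 0.25))
        assert out.loc[0, "bin"] == 1 and bool(out.loc[0, "admixed"])

    def test_non_simplex_rows_rejected(self):
        with pytest.raises(ValueError):
            adm.classify_membership(np.array([[0.5, 0.4]]))
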