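"""Dimensionality diagnostics and DIF screening."""

import numpy as np
import pytest

from pfcrosslink.checks import (
    bifactor_ecv_omega,
    dif_screen,
    dimensionality_report,
    one_factor_fit,
    polychoric_matrix,
)
from pfcrosslink.grm import ItemParameters, ResponseMatrix, category_probabilities
from pfcrosslink.scoring import EAPScorer
from pfcrosslink.simulate import SyntheticConfig, make_item_banks, simulate_sample


def _discretize(latent, thresholds=(-0.6, 0.6)):
    return np.digitize(latent, thresholds) + 1


def _one_factor_ordinal(rng, n, p, loadings=None):
    lam = loadings if loadings is not None else rng.uniform(0.5, 0.85, p)
    f = rng.normal(size=(n, 1))
    latent = f @ lam[None, :] + rng.normal(size=(n, p)) * np.sqrt(1 - lam**2)
    return np.column_stack([_discretize(latent[:, j]) for j in range(p)])


class TestPolychoric:
    def test_duplicated_column_gives_unit_correlation(self):
        x = np.random.default_rng(1).integers(1, 4, 500)
        R = polychoric_matrix(np.column_stack([x, x]))
        assert R[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(2)
        x = _discretize(rng.normal(size=5000), (-0.5, 0.7))
        y = _discretize(rng.normal(size=5000), (-1.0, 0.3))
        R = polychoric_matrix(np.column_stack([x, y]))
        assert abs(R[0, 1]) < 0.05

    def test_recovers_generating_correlation(self):
        rng = np.random.default_rng(3)
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=5000)
        x = _discretize(z[:, 0], (-0.5, 0.7))
        y = _discretize(z[:, 1], (-1.0, 0.3))
        R = polychoric_matrix(np.column_stack([x, y]))
        assert R[0, 1] == pytest.approx(0.6, abs=0.04)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(4)
        V = _one_factor_ordinal(rng, 400, 5)
        R = polychoric_matrix(V)
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)

    def test_constant_margin_falls_back_with_warning(self):
        x = np.full(100, 2)
        y = np.random.default_rng(5).integers(1, 4, 100)
        with pytest.warns(UserWarning, match="Spearman"):
            R = polychoric_matrix(np.column_stack([x, y]))
        assert np.isfinite(R[0, 1])

    def test_single_item_rejected(self):
        with pytest.raises(ValueError, match="2 items"):
            polychoric_matrix(np.ones((10, 1), dtype=int))


class TestOneFactorFit:
    def test_model_implied_matrix_fits_perfectly(self):
        lam = np.array([0.8, 0.7, 0.6, 0.75, 0.65])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        fit = one_factor_fit(R, 600)
        assert fit["srmr"] == pytest.approx(0.0, abs=1e-6)
        assert fit["cfi"] == pytest.approx(1.0)
        assert fit["rmsea"] == pytest.approx(0.0, abs=1e-6)

    def test_one_factor_data_passes_benchmarks(self):
        rng = np.random.default_rng(6)
        V = _one_factor_ordinal(rng, 600, 30)
        R = polychoric_matrix(V)
        fit = one_factor_fit(R, 600)
        assert fit["cfi"] > 0.95
        assert fit["srmr"] < 0.08

    def test_two_orthogonal_factors_fail_cfi(self):
        rng = np.random.default_rng(7)
        p = 30
        lam = np.zeros((p, 2))
        lam[:15, 0] = 0.8
        lam[15:, 1] = 0.8
        f = rng.normal(size=(600, 2))
        latent = f @ lam.T + rng.normal(size=(600, p)) * np.sqrt(1 - 0.64)
        V = np.column_stack([_discretize(latent[:, j]) for j in range(p)])
        fit = one_factor_fit(polychoric_matrix(V), 600)
        assert fit["cfi"] < 0.95

    def test_indices_invariant_to_item_order(self):
        rng = np.random.default_rng(8)
        V = _one_factor_ordinal(rng, 400, 12)
        R = polychoric_matrix(V)
        perm = rng.permutation(12)
        f1 = one_factor_fit(R, 400)
        f2 = one_factor_fit(R[np.ix_(perm, perm)], 400)
        for key in ("cfi", "tli", "rmsea", "srmr"):
            assert f1[key] == pytest.approx(f2[key], abs=1e-6)


class TestBifactor:
    def test_pure_one_factor_data_has_high_ecv(self):
        # strong general factor (loadings 0.7-0.9, typical of physical
        # function items) and no group structure
        rng = np.random.default_rng(9)
        V = _one_factor_ordinal(rng, 2000, 24, loadings=rng.uniform(0.7, 0.9, 24))
        ecv, omega_h, _ = bifactor_ecv_omega(polychoric_matrix(V), 2000, 4)
        assert ecv > 0.9
        assert 0 <= omega_h <= 1

    def test_orthogonal_group_factors_have_low_ecv(self):
        rng = np.random.default_rng(10)
        p, m = 24, 3
        lam = np.zeros((p, m))
        for f in range(m):
            lam[f * 8 : (f + 1) * 8, f] = 0.8
        fac = rng.normal(size=(1500, m))
        latent = fac @ lam.T + rng.normal(size=(1500, p)) * np.sqrt(1 - 0.64)
        V = np.column_stack([_discretize(latent[:, j]) for j in range(p)])
        ecv, omega_h, _ = bifactor_ecv_omega(polychoric_matrix(V), 1500, m)
        assert ecv < 0.2
        assert 0 <= omega_h <= 1

    def test_indices_always_in_unit_interval(self):
        rng = np.random.default_rng(11)
        V = _one_factor_ordinal(rng, 300, 15)
        ecv, omega_h, loadings = bifactor_ecv_omega(polychoric_matrix(V), 300, 2)
        assert 0 <= ecv <= 1 and 0 <= omega_h <= 1
        assert loadings.shape[0] == 15

    def test_excessive_factor_count_rejected(self):
        R = np.eye(9)
        with pytest.raises(ValueError, match="group factors"):
            bifactor_ecv_omega(R, 100, 4)


@pytest.fixture(scope="module")
def dif_data():
    cfg = SyntheticConfig(
        n_per_subsample=(1000,), subsample_names=("s",), theta_means=(0.0,), theta_sds=(1.0,), seed=11
    )
    rng = np.random.default_rng(11)
    banks = make_item_banks(cfg, rng)
    data = simulate_sample(banks, cfg, seed=111)
    trait = EAPScorer(bank=banks[0] + banks[1]).fit().transform(data.responses)["theta"].to_numpy()
    group = rng.integers(0, 2, size=1000)
    return banks, data, trait, group


class TestDIFScreen:
    def test_single_level_group_rejected(self, dif_data):
        _, data, trait, _ = dif_data
        with pytest.raises(ValueError, match="2 levels"):
            dif_screen(data.responses, np.zeros(1000, int), trait)

    def test_null_simulation_flags_nothing(self, dif_data):
        # coin-flip grouping with no planted DIF: at most 1 of 30 items may
        # exceed the 0.03 change criterion by chance
        _, data, trait, group = dif_data
        report = dif_screen(data.responses, group, trait)
        assert report.table["flagged"].sum() <= 1
        assert (report.table["delta_r2"] >= -1e-10).all()
        assert report.table[["r2_m1", "r2_m2", "r2_m3"]].ge(0).all().all()
        assert report.table[["r2_m1", "r2_m2", "r2_m3"]].lt(1).all().all()

    def test_nested_logliks_ordered(self, dif_data):
        _, data, trait, group = dif_data
        t = report = dif_screen(data.responses.subset_items("linked"), group, trait).table
        assert (t["loglik_m1"] <= t["loglik_m2"] + 1e-8).all()
        assert (t["loglik_m2"] <= t["loglik_m3"] + 1e-8).all()

    def test_planted_uniform_dif_is_flagged(self, dif_data):
        (anchor, linked), data, _, group = dif_data
        item = linked[0]
        shifted = ItemParameters(item.item_id, item.discrimination, tuple(np.array(item.thresholds) + 1.0))
        values = data.responses.values.copy()
        j = data.responses.item_ids.index(item.item_id)
        g1 = np.flatnonzero(group == 1)
        P = category_probabilities(shifted, data.theta_true[g1])
        u = np.random.default_rng(5).random(g1.size)
        values[g1, j] = 1 + (u[:, None] > np.cumsum(P, axis=1)[:, :-1]).sum(axis=1)
        rm = ResponseMatrix(
            person_ids=data.responses.person_ids,
            item_ids=list(data.responses.item_ids),
            values=values,
            missing=data.responses.missing,
            instrument=data.responses.instrument,
        )
        trait = EAPScorer(bank=anchor + linked).fit().transform(rm)["theta"].to_numpy()
        report = dif_screen(rm, group, trait)
        row = report.table.set_index("item_id").loc[item.item_id]
        assert row["delta_r2"] > 0.03
        assert bool(row["flagged"])


class TestDimensionalityReport:
    def test_study_scale_pooled_items_look_unidimensional(self, study_dataset):
        report = dimensionality_report(study_dataset.responses, n_group_factors=4)
        assert report.benchmark_flags["cfi"]
        assert report.benchmark_flags["srmr"]
        assert report.bifactor["ecv"] > 0.6
        payload = report.to_json_dict()
        assert {e["statistic"] for e in payload["indices"]} == {"cfi", "tli", "rmsea", "srmr", "ecv", "omega_h"}
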