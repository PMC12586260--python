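"""Synthetic data generator, contamination processes, exclusion screen."""

import numpy as np
import pytest

from pfcrosslink.grm import category_probabilities
from pfcrosslink.scoring import observed_benchmark, theta_to_t
from pfcrosslink.simulate import (
    SyntheticConfig,
    contaminate,
    make_item_banks,
    screen_exclusions,
    simulate_sample,
)


class TestConfig:
    def test_defaults_mirror_study_conditions(self):
        cfg = SyntheticConfig()
        assert cfg.n_per_subsample == (185, 172, 262)
        assert cfg.n_anchor_items == 20 and cfg.anchor_categories == 5
        assert cfg.n_linked_items == 10 and cfg.linked_categories == 3

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(reversed_fraction=1.2)
        with pytest.raises(ValueError):
            SyntheticConfig(reversed_fraction=0.6, missing_fraction=0.5)


class TestMakeItemBanks:
    def test_bank_shapes(self, study_banks):
        anchor, linked = study_banks
        assert len(anchor) == 20 and all(it.n_categories == 5 for it in anchor)
        assert len(linked) == 10 and all(it.n_categories == 3 for it in linked)

    def test_thresholds_strictly_increasing(self, study_banks):
        for bank in study_banks:
            for item in bank:
                assert np.all(np.diff(item.thresholds) > 0)

    def test_same_seed_identical_banks(self):
        cfg = SyntheticConfig(seed=5)
        b1 = make_item_banks(cfg, np.random.default_rng(5))
        b2 = make_item_banks(cfg, np.random.default_rng(5))
        for bank1, bank2 in zip(b1, b2):
            for i1, i2 in zip(bank1, bank2):
                assert i1 == i2


class TestSimulateSample:
    def test_cardiology_benchmark_mean_matches_target(self, study_banks):
        cfg = SyntheticConfig(
            n_per_subsample=(185,), subsample_names=("cardiology",), theta_means=(-0.65,), theta_sds=(0.78,), seed=2
        )
        data = simulate_sample(study_banks, cfg, seed=2)
        bench = observed_benchmark(data.responses, study_banks[0])
        assert bench["t_score"].mean() == pytest.approx(43.5, abs=2.0)

    def test_same_seed_identical_dataset(self, study_banks):
        cfg = SyntheticConfig(seed=3)
        d1 = simulate_sample(study_banks, cfg, seed=3)
        d2 = simulate_sample(study_banks, cfg, seed=3)
        assert np.array_equal(d1.responses.values, d2.responses.values)
        assert np.array_equal(d1.theta_true, d2.theta_true)

    def test_category_frequencies_match_model_probabilities(self, study_banks):
        # LLN check: responses at fixed theta=0 follow the closed-form GRM
        # category probabilities
        anchor, linked = study_banks
        cfg = SyntheticConfig(
            n_per_subsample=(50000,), subsample_names=("s",), theta_means=(0.0,), theta_sds=(1e-12,), seed=4
        )
        data = simulate_sample((anchor[:2], linked[:2]), cfg, seed=4)
        for j, item in enumerate(anchor[:2]):
            v = data.responses.values[:, j]
            freq = np.bincount(v, minlength=item.n_categories + 1)[1:] / v.size
            expected = category_probabilities(item, np.array([0.0]))[0]
            assert np.max(np.abs(freq - expected)) < 0.01

    def test_generator_faithfulness(self, study_dataset, study_banks):
        bench = observed_benchmark(study_dataset.responses, study_banks[0])
        r = np.corrcoef(study_dataset.theta_true, bench["theta"])[0, 1]
        assert r > 0.9

    def test_subsample_ordering_over_seeds(self, study_banks):
        # rheumatology lowest; cardiology and psychosomatic comparable
        cfg = SyntheticConfig()
        for seed in range(10):
            data = simulate_sample(study_banks, cfg, seed=seed)
            means = {
                s: theta_to_t(data.theta_true[data.subsample == s].mean())
                for s in cfg.subsample_names
            }
            assert means["rheumatology"] < means["cardiology"]
            assert means["rheumatology"] < means["psychosomatic"]


class TestContaminate:
    def test_zero_fractions_leave_dataset_unchanged(self, study_dataset):
        rng = np.random.default_rng(0)
        out = contaminate(study_dataset, 0.0, 0.0, rng)
        assert np.array_equal(out.responses.values, study_dataset.responses.values)
        assert not out.reversed_flag.any() and not out.missing_flag.any()

    def test_reversed_person_has_flipped_categories(self, study_dataset):
        rng = np.random.default_rng(1)
        out = contaminate(study_dataset, 0.05, 0.0, rng)
        linked_cols = out.responses.item_index("linked")
        K = out.responses.n_categories[linked_cols]
        p = np.flatnonzero(out.reversed_flag)[0]
        assert np.array_equal(out.responses.values[p, linked_cols], K + 1 - study_dataset.responses.values[p, linked_cols])
        anchor_cols = out.responses.item_index("anchor")
        assert np.array_equal(out.responses.values[p, anchor_cols], study_dataset.responses.values[p, anchor_cols])

    def test_default_fractions_give_study_counts(self, study_banks):
        cfg = SyntheticConfig(n_per_subsample=(667,), subsample_names=("s",), theta_means=(-0.75,), theta_sds=(0.87,))
        data = simulate_sample(study_banks, cfg, seed=6)
        out = contaminate(data, cfg.reversed_fraction, cfg.missing_fraction, np.random.default_rng(6))
        assert out.reversed_flag.sum() == 43
        assert out.missing_flag.sum() == 5

    def test_excessive_fractions_rejected(self, study_dataset):
        with pytest.raises(ValueError):
            contaminate(study_dataset, 0.7, 0.4, np.random.default_rng(0))


class TestScreenExclusions:
    def test_clean_dataset_nothing_excluded(self, study_dataset, study_banks):
        anchor, linked = study_banks
        analytic, log = screen_exclusions(study_dataset, anchor, linked)
        assert analytic.responses.n_persons == study_dataset.responses.n_persons
        assert not log["excluded"].any()

    def test_wholly_missing_instrument_always_excluded(self, study_dataset, study_banks):
        anchor, linked = study_banks
        rng = np.random.default_rng(7)
        out = contaminate(study_dataset, 0.0, 0.02, rng)
        analytic, log = screen_exclusions(out, anchor, linked)
        dropped = set(out.responses.person_ids[out.missing_flag])
        assert dropped <= set(log.loc[log["excluded"], "person_id"])
        assert dropped.isdisjoint(set(analytic.responses.person_ids))

    def test_planted_reversed_responders_detected(self):
        # default banks drawn per seed, initial-sample size 667; aggregate
        # over 10 seeds: sensitivity >= 0.9, false positives <= 1%
        hits = total_rev = false_pos = total_clean = 0
        for seed in range(10):
            base = SyntheticConfig(seed=seed)
            cfg = SyntheticConfig(seed=seed, n_per_subsample=base.n_initial_per_subsample)
            anchor, linked = make_item_banks(cfg, np.random.default_rng(seed))
            data = simulate_sample((anchor, linked), cfg, seed=seed + 1000)
            data = contaminate(data, 0.06, 0.0, np.random.default_rng(seed))
            _, log = screen_exclusions(data, anchor, linked)
            flagged = log["reason"].to_numpy() == "reversed_coding"
            hits += (flagged & data.reversed_flag).sum()
            total_rev += data.reversed_flag.sum()
            false_pos += (flagged & ~data.reversed_flag).sum()
            total_clean += (~data.reversed_flag).sum()
        assert hits / total_rev >= 0.9
        assert false_pos / total_clean <= 0.01
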