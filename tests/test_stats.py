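"""Cohort statistics: densities, indices, litter normalization, tests,
multiple-comparison correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from opclamp.stats import (
    caspase_litter_normalization,
    compare_groups,
    compare_multiple,
    count_metrics,
    holm_bonferroni_variant,
    labelling_index,
)
from opclamp.synth import simulate_caspase_cohort, simulate_histology_counts


def _count_table(rows):
    return pd.DataFrame(
        rows,
        columns=["litter_id", "animal_id", "genotype", "field_id", "area_mm2", "marker", "count"],
    )


class TestCountMetrics:
    def test_density_arithmetic(self):
        tab = _count_table(
            [
                (0, "a1", "control", 0, 0.2, "CC1", 100),
                (0, "a1", "control", 1, 0.3, "CC1", 200),
            ]
        )
        out = count_metrics(tab)
        assert out["density_per_mm2"].iloc[0] == pytest.approx(600.0)

    def test_density_additive_over_fields(self):
        """Pooled-field density equals count-weighted pooling of per-field
        densities (not the naive mean of densities)."""
        rng = np.random.default_rng(0)
        rows = [
            (0, "a1", "control", f, float(rng.uniform(0.2, 0.4)), "CC1", int(rng.integers(50, 300)))
            for f in range(4)
        ]
        tab = _count_table(rows)
        out = count_metrics(tab)
        total = sum(r[6] for r in rows) / sum(r[4] for r in rows)
        assert out["density_per_mm2"].iloc[0] == pytest.approx(total)

    def test_labelling_index_arithmetic(self):
        tab = _count_table(
            [
                (0, "a1", "control", 0, 0.3, "Pdgfra", 200),
                (0, "a1", "control", 0, 0.3, "EdU+Pdgfra", 40),
            ]
        )
        out = labelling_index(tab)
        assert out["labelling_index_pct"].iloc[0] == pytest.approx(20.0)

    def test_zero_reference_reported_not_dropped(self):
        tab = _count_table(
            [
                (0, "a1", "control", 0, 0.3, "Pdgfra", 0),
                (0, "a1", "control", 0, 0.3, "EdU+Pdgfra", 0),
            ]
        )
        out = labelling_index(tab)
        assert not out["defined"].iloc[0]
        assert np.isnan(out["labelling_index_pct"].iloc[0])

    def test_planted_index_recovered(self):
        tab, gt = simulate_histology_counts("control", seed=4, edu_index=0.25)
        out = labelling_index(tab)
        # binomial CI at ~1000 reference cells per animal, 28 animals
        assert out["labelling_index_pct"].mean() == pytest.approx(25.0, abs=1.0)

    def test_invalid_tables_rejected(self):
        tab = _count_table([(0, "a1", "control", 0, -0.1, "CC1", 10)])
        with pytest.raises(ValueError, match="positive"):
            count_metrics(tab)
        tab2 = _count_table(
            [(0, "a1", "control", 0, 0.3, "CC1", 10), (1, "a1", "dko", 0, 0.3, "CC1", 10)]
        )
        with pytest.raises(ValueError, match="exactly one litter"):
            count_metrics(tab2)


class TestCaspaseNormalization:
    def test_worked_single_litter(self):
        tab = pd.DataFrame(
            {
                "litter_id": [0, 0, 0],
                "animal_id": ["c1", "c2", "m1"],
                "genotype": ["control", "control", "dko"],
                "fraction": [0.20, 0.24, 0.262],
            }
        )
        ctrl_mean, folds, excluded = caspase_litter_normalization(tab)
        assert ctrl_mean == pytest.approx(0.22)
        assert folds["fold"].iloc[0] == pytest.approx(0.262 / 0.22)
        assert excluded == []

    def test_identical_animals_give_unity(self):
        tab = pd.DataFrame(
            {
                "litter_id": [0, 0, 1, 1],
                "animal_id": list("abcd"),
                "genotype": ["control", "dko", "control", "dko"],
                "fraction": [0.2, 0.2, 0.2, 0.2],
            }
        )
        _, folds, _ = caspase_litter_normalization(tab)
        assert folds["fold"].iloc[0] == pytest.approx(1.0)

    def test_litters_without_controls_excluded(self):
        tab = pd.DataFrame(
            {
                "litter_id": [0, 0, 1],
                "animal_id": list("abc"),
                "genotype": ["control", "dko", "dko"],
                "fraction": [0.2, 0.25, 0.9],
            }
        )
        _, folds, excluded = caspase_litter_normalization(tab)
        assert excluded == [1]
        assert folds["fold"].iloc[0] == pytest.approx(1.25)

    def test_planted_factor_recovered_across_seeds(self):
        folds = []
        for seed in range(8):
            tab, gt = simulate_caspase_cohort("dko", seed=seed)
            _, f, _ = caspase_litter_normalization(tab)
            folds.append(f["fold"].iloc[0])
        assert np.mean(folds) == pytest.approx(1.194, abs=0.05 * 1.194)


class TestCompareGroups:
    def test_identical_samples_zero_effect_nonsignificant(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = compare_groups(a, a)
        assert res.effect_pct == pytest.approx(0.0)
        assert res.p_value > 0.9

    def test_power_for_27pct_difference_at_n14(self):
        """A 27% mean difference at the generator's dispersion is detected
        with power >= 0.8 over 200 simulations (n = 14 per group)."""
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(200):
            a = rng.normal(1000.0, 95.0, 14)
            b = rng.normal(730.0, 95.0 * 0.73, 14)
            if compare_groups(a, b).p_value < 0.05:
                hits += 1
        assert hits / 200 >= 0.8

    def test_type_i_error_calibrated(self):
        """Null simulations keep the rejection rate near alpha = 0.05."""
        rng = np.random.default_rng(6)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(0.0, 1.0, 12)
            b = rng.normal(0.0, 1.0, 12)
            if compare_groups(a, b).p_value < 0.05:
                rejections += 1
        assert 0.035 <= rejections / n_rep <= 0.065

    def test_nonnormal_routes_to_mann_whitney(self):
        rng = np.random.default_rng(2)
        a = rng.lognormal(0.0, 2.0, 30)
        b = rng.lognormal(0.0, 2.0, 30)
        assert compare_groups(a, b).test == "Mann-Whitney U"

    def test_multiple_groups_routing(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(0, 1, 15) for _ in range(3)]
        omnibus, pairs = compare_multiple(groups)
        assert "ANOVA" in omnibus.test
        assert len(pairs) == 3
        skewed = [rng.lognormal(0, 2.0, 15) for _ in range(3)]
        omnibus2, pairs2 = compare_multiple(skewed)
        assert "Dunn" in omnibus2.test
        assert (pairs2["p_adj"] <= 1.0).all()

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])


class TestHolmVariant:
    def test_single_p_unchanged(self):
        assert holm_bonferroni_variant([0.03]) == pytest.approx([0.03])

    def test_two_p_worked_example(self):
        assert holm_bonferroni_variant([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_matches_independent_step_down_oracle(self):
        """1000 random p-vectors agree with statsmodels' Holm step-down."""
        rng = np.random.default_rng(9)
        for _ in range(1000):
            p = rng.uniform(0.0, 1.0, rng.integers(1, 12))
            ours = holm_bonferroni_variant(p)
            _, oracle, _, _ = multipletests(p, method="holm")
            assert np.allclose(ours, oracle, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni_variant([0.1, 1.2])

    def test_literal_rule_can_invert_order(self):
        # the bare multiplication rule is not monotone; the default is
        p = [0.10, 0.11, 0.45]
        literal = holm_bonferroni_variant(p, enforce_monotone=False)
        assert literal[0] > literal[1]
        mono = holm_bonferroni_variant(p)
        srt = np.sort(mono)
        assert np.all(np.diff(srt) >= 0)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=15))
    @settings(max_examples=200, deadline=None)
    def test_corrected_at_least_raw_and_capped(self, pvals):
        out = holm_bonferroni_variant(pvals)
        assert np.all(out >= np.asarray(pvals) - 1e-15)
        assert np.all(out <= 1.0)
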