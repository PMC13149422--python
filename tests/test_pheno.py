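"""Efficiency indices, contrast groups, correlations, ANOVA and pruning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from peff import pheno
from oracles import pdistance_dedup_oracle

positive = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


class TestFormulas:
    def test_shoot_p_content_is_the_product(self):
        assert pheno.shoot_p_content(2.0, 3.0) == 6.0
        assert pheno.shoot_p_content(0.0, 5.0) == 0.0
        with pytest.raises(ValueError):
            pheno.shoot_p_content(-1.0, 2.0)

    def test_pue_ratio_and_zero_denominator(self):
        assert pheno.pue(1.0, 2.0) == 0.5
        with pytest.raises(ValueError):
            pheno.pue(1.0, 0.0)

    @settings(max_examples=100, derandomize=True)
    @given(positive, positive)
    def test_pue_round_trip_identity(self, s, c):
        assert pheno.pue(s, pheno.shoot_p_content(s, c)) * c == pytest.approx(1.0)

    def test_sti_reference_point_and_zero(self):
        assert pheno.sti(3.0, 3.0, 3.0) == pytest.approx(1.0)
        assert pheno.sti(3.0, 0.0, 3.0) == 0.0
        with pytest.raises(ValueError):
            pheno.sti(1.0, 1.0, 0.0)

    @settings(max_examples=100, derandomize=True)
    @given(positive, positive, positive, st.floats(min_value=0.1, max_value=10))
    def test_sti_invariant_under_common_rescaling(self, yp, ys, myp, scale):
        a = pheno.sti(yp, ys, myp)
        b = pheno.sti(yp * scale, ys * scale, myp * scale)
        assert b == pytest.approx(a, rel=1e-9)

    def test_sti_monotone_in_stress_performance(self):
        assert pheno.sti(2.0, 3.0, 2.5) > pheno.sti(2.0, 2.0, 2.5)


class TestPercentChange:
    def test_reported_biomass_reductions(self):
        assert pheno.percent_change(4.82, 3.68) == pytest.approx(-23.65, abs=0.01)
        assert round(abs(pheno.percent_change(4.82, 3.68))) == 24
        assert round(abs(pheno.percent_change(1.43, 1.10))) == 23

    def test_reported_pue_increase(self):
        hp = (0.30 + 0.28) / 2
        lp = (0.40 + 0.40) / 2
        assert round(pheno.percent_change(hp, lp)) == 38

    def test_identity_cases(self):
        assert pheno.percent_change(3.0, 3.0) == 0.0
        with pytest.raises(ValueError):
            pheno.percent_change(0.0, 1.0)

    @settings(max_examples=50, derandomize=True)
    @given(positive, positive)
    def test_antisymmetry_identity(self, a, b):
        lhs = pheno.percent_change(a, b)
        rhs = -pheno.percent_change(b, a) * b / a
        assert lhs == pytest.approx(rhs, rel=1e-9)


def _long_table(rows):
    return pd.DataFrame(rows, columns=["accession", "treatment", "replicate",
                                       "trait", "value"])


class TestDeltaGroups:
    def test_delta_is_hp_minus_lp_mean(self):
        rows = []
        for rep in (1, 2):
            rows += [("a1", "HP", rep, "RDM", 1.5), ("a1", "LP", rep, "RDM", 1.0)]
            rows += [("a2", "HP", rep, "RDM", 1.0), ("a2", "LP", rep, "RDM", 1.3)]
        out = pheno.delta_rdm_groups(_long_table(rows), n_extreme=1, n_pick=1)
        by_acc = out.set_index("accession")
        assert by_acc.loc["a1", "delta_rdm"] == pytest.approx(0.5)
        # negative ΔRDM (more roots under LP) is allowed and ranks low
        assert by_acc.loc["a2", "delta_rdm"] == pytest.approx(-0.3)
        assert by_acc.loc["a1", "group"] == pheno.HIGH_GROUP
        assert by_acc.loc["a2", "group"] == pheno.LOW_GROUP

    def test_ranking_matches_sort_oracle(self):
        rng = np.random.default_rng(40)
        rows = []
        deltas = {}
        for i in range(40):
            acc = f"a{i:02d}"
            hp, lp = rng.uniform(0.5, 3.0, size=2)
            deltas[acc] = hp - lp
            for rep in (1, 2, 3):
                rows += [(acc, "HP", rep, "RDM", hp), (acc, "LP", rep, "RDM", lp)]
        out = pheno.delta_rdm_groups(_long_table(rows), n_extreme=10, n_pick=5)
        ranked = sorted(deltas, key=deltas.get, reverse=True)
        assert list(out["accession"]) == ranked
        assert set(out.loc[out["group"] == pheno.HIGH_GROUP, "accession"]) == set(ranked[:5])
        assert set(out.loc[out["group"] == pheno.LOW_GROUP, "accession"]) == set(ranked[-5:])

    def test_accession_missing_a_treatment_is_excluded(self):
        rows = [("a1", "HP", 1, "RDM", 1.0), ("a1", "LP", 1, "RDM", 0.8),
                ("a2", "HP", 1, "RDM", 1.0)]
        out = pheno.delta_rdm_groups(_long_table(rows), n_extreme=1, n_pick=1)
        assert "a2" not in set(out["accession"])


class TestSpearman:
    def test_monotone_series(self):
        x = np.arange(10.0)
        assert pheno.spearman(x, x ** 3)[0] == pytest.approx(1.0)
        assert pheno.spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_tied_fixture_matches_midrank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 2.0, 4.0, 4.0, 6.0])
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert pheno.spearman(x, y)[0] == pytest.approx(expected, abs=1e-12)

    def test_tie_free_data_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(41)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        expected = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert pheno.spearman(x, y)[0] == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pheno.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _anova_table(shift=0.0, noise=1.0, seed=0, reps=5):
    rng = np.random.default_rng(seed)
    rows = []
    for gi, group in enumerate(("High dRDM", "Low dRDM")):
        for ai in range(3):
            acc = f"{group[:1]}{ai}"
            for treatment in ("HP", "LP"):
                for rep in range(1, reps + 1):
                    value = (
                        5.0
                        + (shift if treatment == "LP" else 0.0)
                        + 0.3 * gi
                        + rng.normal(0, noise)
                    )
                    rows.append((acc, treatment, rep, "trait", value, group))
    return pd.DataFrame(rows, columns=["accession", "treatment", "replicate",
                                       "trait", "value", "group"])


class TestAnova:
    def test_large_treatment_shift_is_detected(self):
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            table = _anova_table(shift=-3.0, noise=1.0, seed=seed)
            p = pheno.anova_two_way(table, "trait")
            hits += p["treatment"] < 0.001
        assert hits >= 0.95 * n_seeds

    def test_null_interaction_pvalues_are_uniform(self):
        ps = []
        for seed in range(200):
            table = _anova_table(shift=0.0, noise=1.0, seed=10_000 + seed)
            ps.append(pheno.anova_two_way(table, "trait")["interaction"])
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_zero_noise_additive_data_has_zero_interaction_ss(self):
        table = _anova_table(shift=-1.0, noise=0.0, seed=1, reps=2)
        _, tab = pheno.anova_two_way(table, "trait", return_table=True)
        assert tab.loc["interaction", "sum_sq"] == pytest.approx(0.0, abs=1e-16)

    def test_single_level_factor_skipped_with_warning(self):
        table = _anova_table(seed=3)
        table = table[table["treatment"] == "HP"]
        with pytest.warns(UserWarning, match="one level"):
            p = pheno.anova_two_way(table, "trait")
        assert "treatment" not in p.index


class TestPDistanceDedup:
    def test_less_missing_twin_is_kept(self):
        data = pd.DataFrame(
            [[0, 1, 0, 1, 0], [0, 1, 0, 1, np.nan], [1, 0, 1, 0, 1]],
            index=["dup_full", "dup_missing", "other"], dtype=float,
        )
        kept = pheno.pdistance_dedup(data, similarity_threshold=0.99, rounds=3)
        assert kept == ["dup_full", "other"]

    def test_distinct_rows_all_retained(self):
        rng = np.random.default_rng(44)
        data = pd.DataFrame(rng.integers(0, 2, size=(6, 40)).astype(float),
                            index=[f"a{i}" for i in range(6)])
        kept = pheno.pdistance_dedup(data, similarity_threshold=0.9997)
        assert kept == list(data.index)

    def test_random_fixture_matches_quadratic_oracle(self):
        rng = np.random.default_rng(45)
        base = rng.integers(0, 2, size=(8, 60)).astype(float)
        rows = [base[i % 8].copy() for i in range(20)]
        for i, row in enumerate(rows):
            flip = rng.random(60) < 0.02
            row[flip] = 1 - row[flip]
            row[rng.random(60) < 0.05] = np.nan
        data = pd.DataFrame(rows, index=[f"acc{i:02d}" for i in range(20)])
        threshold = 0.97
        mine = pheno.pdistance_dedup(data, threshold, rounds=3)
        oracle = pdistance_dedup_oracle(data, threshold, rounds=3)
        assert mine == oracle

    def test_no_retained_pair_is_redundant(self):
        rng = np.random.default_rng(46)
        base = rng.integers(0, 2, size=(5, 50)).astype(float)
        rows = [base[i % 5].copy() for i in range(15)]
        data = pd.DataFrame(rows, index=[f"acc{i:02d}" for i in range(15)])
        threshold = 0.95
        kept = pheno.pdistance_dedup(data, threshold, rounds=3)
        sub = data.loc[kept].to_numpy()
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                both = ~(np.isnan(sub[i]) | np.isnan(sub[j]))
                if both.sum():
                    assert 1 - np.mean(sub[i, both] != sub[j, both]) < threshold


class TestIndicesTable:
    def test_pue_times_content_returns_sdm(self):
        rows = []
        rng = np.random.default_rng(47)
        for i in range(5):
            acc = f"a{i}"
            for treatment in ("HP", "LP"):
                sdm = rng.uniform(2, 6)
                conc = rng.uniform(2, 5)
                rdm = rng.uniform(0.5, 2)
                for rep in (1, 2):
                    rows += [
                        (acc, treatment, rep, "SDM", sdm),
                        (acc, treatment, rep, "RDM", rdm),
                        (acc, treatment, rep, "shoot_P_conc", conc),
                    ]
        table = _long_table(rows)
        idx = pheno.efficiency_indices(table)
        sdm_hp = pheno.treatment_means(table, "SDM")["HP"].to_numpy()
        np.testing.assert_allclose(
            idx["PUE_HP"] * idx["shoot_P_content_HP"], sdm_hp, atol=1e-9
        )
        assert (idx["STI_sdm"] >= 0).all()
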