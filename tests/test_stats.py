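"""Repeated-measures ANOVA, Bonferroni pairs and the accuracy association."""

import numpy as np
import pandas as pd
import pytest

import pillchroma as pc
from pillchroma.recognize import TopKResult
from pillchroma.stats import simulate_table


def _records(values_by_cond, labels=range(1, 20)):
    out = []
    for cond, values in values_by_cond.items():
        for label, v in zip(labels, values):
            out.append(pc.DeltaERecord(label, cond, float(v), 1))
    return out


@pytest.fixture(scope="module")
def full_table():
    """One seeded ΔE table over the full 19 × 2 × 2 × 3 design."""
    return simulate_table(19, noise_sd=1.0, subject_sd=1.0,
                          ev_effect_sd=1.5, rng=np.random.default_rng(42))


class TestSummarize:
    def test_constant_sample(self):
        recs = _records({"B_O_EV0": [7.0] * 19})
        s = pc.summarize_delta_e(recs)
        assert s.loc[0, "mean_delta_e"] == pytest.approx(7.0)
        assert s.loc[0, "sd_delta_e"] == pytest.approx(0.0)

    def test_two_point_formula(self):
        recs = _records({"B_O_EV0": [10.0, 20.0]}, labels=[1, 2])
        s = pc.summarize_delta_e(recs)
        assert s.loc[0, "mean_delta_e"] == pytest.approx(15.0)
        assert s.loc[0, "sd_delta_e"] == pytest.approx(np.sqrt(50.0))

    def test_single_record_sd_convention(self):
        s = pc.summarize_delta_e(_records({"B_O_EV0": [3.0]}, labels=[1]))
        assert s.loc[0, "sd_delta_e"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pc.summarize_delta_e([])

    def test_grand_mean_consistency(self, full_table):
        from pillchroma.catalog import _condition_name
        recs = [pc.DeltaERecord(
                    int(r["medication"]),
                    _condition_name(r["background"], r["flash"], r["ev"]),
                    float(abs(r["delta_e"])), 1)
                for _, r in full_table.iterrows()]
        s = pc.summarize_delta_e(recs)
        assert s["mean_delta_e"].mean() == pytest.approx(
            np.mean([r.delta_e for r in recs]))


class TestThreeWayRmAnova:
    def test_matches_pingouin_univariate_f(self, full_table):
        pg = pytest.importorskip("pingouin")
        ours = {r.effect: r for r in pc.three_way_rm_anova(full_table)}
        # main effect: collapse the other two factors, one-way RM-ANOVA
        coll = full_table.groupby(["medication", "ev"],
                                  as_index=False)["delta_e"].mean()
        ref = pg.rm_anova(data=coll, dv="delta_e", within="ev",
                          subject="medication")
        assert ours["ev"].F == pytest.approx(float(ref["F"][0]), rel=1e-9)
        assert ours["ev"].p_value == pytest.approx(float(ref["p_unc"][0]),
                                                   abs=1e-12)
        # two-way: collapse ev, compare all three effects
        coll2 = full_table.groupby(["medication", "background", "flash"],
                                   as_index=False)["delta_e"].mean()
        ref2 = pg.rm_anova(data=coll2, dv="delta_e",
                           within=["background", "flash"], subject="medication")
        by_src = dict(zip(ref2["Source"], ref2["F"]))
        assert ours["background"].F == pytest.approx(by_src["background"], rel=1e-9)
        assert ours["flash"].F == pytest.approx(by_src["flash"], rel=1e-9)
        assert ours["background:flash"].F == pytest.approx(
            by_src["background * flash"], rel=1e-9)

    def test_reports_seven_effects_with_valid_df(self, full_table):
        results = pc.three_way_rm_anova(full_table)
        assert {r.effect for r in results} == {
            "background", "flash", "ev", "background:flash", "background:ev",
            "flash:ev", "background:flash:ev"}
        for r in results:
            assert r.F >= 0 and 0 <= r.p_value <= 1
            assert r.df2 == 18 * r.df1  # (n−1)·df_effect for 19 subjects

    def test_constant_response_gives_null_f(self):
        table = simulate_table(10, noise_sd=0.0, subject_sd=1.0,
                               rng=np.random.default_rng(0))
        results = pc.three_way_rm_anova(table)
        for r in results:
            assert r.F == pytest.approx(0.0, abs=1e-6)
            assert r.p_value == pytest.approx(1.0)

    def test_incomplete_crossing_raises_naming_cell(self, full_table):
        broken = full_table.drop(index=full_table.index[5])
        with pytest.raises(pc.DesignError, match="missing cell"):
            pc.three_way_rm_anova(broken)

    def test_duplicated_cell_raises(self, full_table):
        dup = pd.concat([full_table, full_table.iloc[[0]]], ignore_index=True)
        with pytest.raises(pc.DesignError):
            pc.three_way_rm_anova(dup)

    def test_gg_correction_shrinks_df_and_weakens_significance(self, full_table):
        plain = {r.effect: r for r in pc.three_way_rm_anova(full_table)}
        gg = {r.effect: r
              for r in pc.three_way_rm_anova(full_table, gg_correction=True)}
        for effect in plain:
            assert gg[effect].df1 <= plain[effect].df1 + 1e-12
            assert gg[effect].df2 <= plain[effect].df2 + 1e-12
            # for clearly significant effects the correction is
            # conservative: p can only grow
            if plain[effect].p_value < 0.01:
                assert gg[effect].p_value >= plain[effect].p_value - 1e-12

    def test_monte_carlo_type_i_smoke(self):
        rates = pc.rejection_rates(120, seed=10)
        for effect, rate in rates.items():
            assert 0.0 <= rate <= 0.13, (effect, rate)

    def test_injected_ev_effect_detected(self):
        rates = pc.rejection_rates(30, ev_effect_sd=2.0, seed=11)
        assert rates["ev"] >= 0.9


class TestStratifiedAnova:
    def test_four_strata_and_twelve_pairs(self, full_table):
        anovas, pairs = pc.ev_stratified_anova(full_table)
        assert len(anovas) == 4
        assert len(pairs) == 12
        strata = {p.stratum for p in pairs}
        assert strata == {("black", "on"), ("black", "off"),
                          ("white", "on"), ("white", "off")}

    def test_bonferroni_factor_three(self, full_table):
        _, pairs = pc.ev_stratified_anova(full_table)
        for p in pairs:
            assert p.adjusted_p == pytest.approx(min(1.0, 3 * p.raw_p))
            assert p.adjusted_p >= p.raw_p - 1e-15

    def test_null_stratum_not_significant(self):
        table = simulate_table(19, noise_sd=1.0, subject_sd=1.0,
                               ev_effect_sd=0.0, rng=np.random.default_rng(5))
        anovas, pairs = pc.ev_stratified_anova(table)
        # no injected effect: most strata/pairs should be quiet
        assert sum(a.p_value < 0.05 for a in anovas) <= 1
        assert sum(p.adjusted_p < 0.05 for p in pairs) <= 2

    def test_ordered_effect_extreme_pair_strongest(self):
        rng = np.random.default_rng(12)
        ps = {(-2.0, 0.0): [], (0.0, 2.0): [], (-2.0, 2.0): []}
        for _ in range(20):
            table = simulate_table(19, noise_sd=1.0, subject_sd=1.0,
                                   ev_effect_sd=1.0, rng=rng)
            _, pairs = pc.ev_stratified_anova(table)
            for p in pairs:
                ps[p.pair].append(p.adjusted_p)
        assert np.mean(ps[(-2.0, 2.0)]) <= np.mean(ps[(-2.0, 0.0)])
        assert np.mean(ps[(-2.0, 2.0)]) <= np.mean(ps[(0.0, 2.0)])

    def test_missing_ev_level_raises(self, full_table):
        broken = full_table[full_table["ev"] > -1.0]
        with pytest.raises(pc.DesignError):
            pc.ev_stratified_anova(broken)


def _acc(cond, k, value):
    return TopKResult(condition_name=cond, k=k, accuracy=value, n_eval=19)


class TestAccuracyVsDeltaE:
    def _summary(self, des):
        return pd.DataFrame({"condition": list(des), "n": 19,
                             "mean_delta_e": list(des.values()),
                             "sd_delta_e": 1.0})

    def test_perfect_inverse_monotone(self):
        des = {f"c{i}": float(i) for i in range(12)}
        accs = [_acc(f"c{i}", 1, 1.0 - i / 20) for i in range(12)]
        report = pc.accuracy_vs_delta_e(accs, self._summary(des))
        assert report["spearman"][1] == pytest.approx(-1.0)
        assert report["violations"][1] == []

    def test_constant_accuracy_degenerate(self):
        des = {f"c{i}": float(i) for i in range(5)}
        accs = [_acc(f"c{i}", 1, 0.5) for i in range(5)]
        report = pc.accuracy_vs_delta_e(accs, self._summary(des))
        assert report["spearman"][1] == 0.0
        assert report["degenerate"][1]

    def test_violating_pair_flagged(self):
        des = {"a": 1.0, "b": 2.0, "c": 3.0}
        accs = [_acc("a", 1, 0.9), _acc("b", 1, 0.2), _acc("c", 1, 0.5)]
        report = pc.accuracy_vs_delta_e(accs, self._summary(des))
        assert ("b", "c") in report["violations"][1]

    def test_key_mismatch_rejected(self):
        des = {"a": 1.0, "b": 2.0}
        accs = [_acc("a", 1, 0.9)]
        with pytest.raises(ValueError):
            pc.accuracy_vs_delta_e(accs, self._summary(des))
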