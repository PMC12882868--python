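"""Relative expression, ANOVA/Tukey preferential calls and luciferase folds."""

import numpy as np
import pandas as pd
import pytest

import mybfunnel as mf
from mybfunnel.synthetic import TARGET_TISSUE


def make_ct(rows):
    return pd.DataFrame(rows, columns=["gene", "tissue", "replicate", "ct"])


def ct_fixture(target_ct_by_tissue, ref_ct=20.0):
    rows = []
    for tissue, cts in target_ct_by_tissue.items():
        for rep, ct in enumerate(cts, start=1):
            rows.append(("CUL", tissue, rep, ref_ct))
            rows.append(("EF1A", tissue, rep, ref_ct))
            rows.append(("geneA", tissue, rep, ct))
    return make_ct(rows)


class TestRelativeExpression:
    def test_equal_target_and_reference_gives_unity(self):
        ct = ct_fixture({"root": [20.0, 20.0]})
        re_t = mf.relative_expression(ct)
        assert (re_t["rel_expr"] == 1.0).all()

    def test_one_cycle_earlier_doubles_expression(self):
        ct = ct_fixture({"root": [19.0, 19.0]})
        re_t = mf.relative_expression(ct)
        assert (re_t["rel_expr"] == 2.0).all()

    def test_global_ct_shift_cancels(self):
        base = ct_fixture({"root": [18.5, 21.0], "leaf": [23.0, 19.5]})
        shifted = base.copy()
        shifted["ct"] = shifted["ct"] + 3.7
        re1 = mf.relative_expression(base)["rel_expr"].to_numpy()
        re2 = mf.relative_expression(shifted)["rel_expr"].to_numpy()
        assert re1 == pytest.approx(re2, rel=1e-12)

    def test_planted_fold_recovered(self):
        """The generator's 8-fold top-internode excess is recovered to within
        20% at six replicates."""
        val = mf.gen_validation_fixtures(["cand1", "cand2"], effect_fold=8.0, n_reps=6, seed=5)
        re_t = mf.relative_expression(val.ct)
        for gene, sub in re_t.groupby("gene"):
            top = sub.loc[sub["tissue"] == TARGET_TISSUE, "rel_expr"].mean()
            rest = sub.loc[sub["tissue"] != TARGET_TISSUE, "rel_expr"].mean()
            assert top / rest == pytest.approx(8.0, rel=0.2)

    def test_missing_reference_rejected(self):
        ct = ct_fixture({"root": [20.0, 20.0]})
        ct = ct[~((ct["gene"] == "CUL") & (ct["replicate"] == 2))]
        with pytest.raises(ValueError, match="lacks reference"):
            mf.relative_expression(ct)


class TestPreferentialCall:
    def test_identical_tissues_give_f_zero_and_false(self):
        re_t = pd.DataFrame(
            [
                ("g", t, r, 1.0)
                for t in ("root", "leaf", "bottom", "top")
                for r in (1, 2, 3)
            ],
            columns=["gene", "tissue", "replicate", "rel_expr"],
        )
        (call,) = mf.preferential_call(re_t, target_tissue="top")
        assert call.f_statistic == 0.0 and call.verdict is False

    def test_strong_target_separation_called_positive(self, rng):
        rows = []
        for t in ("root", "leaf", "bottom", "top"):
            mean = 10.0 if t == "top" else 1.0
            for r in range(4):
                rows.append(("g", t, r, mean + rng.normal(0, 0.1)))
        re_t = pd.DataFrame(rows, columns=["gene", "tissue", "replicate", "rel_expr"])
        (call,) = mf.preferential_call(re_t, target_tissue="top")
        assert call.verdict is True
        target_pairs = call.tukey[
            (call.tukey["tissue_a"] == "top") | (call.tukey["tissue_b"] == "top")
        ]
        assert (target_pairs["p_adj"] < 0.05).all()

    def test_agrees_with_statsmodels_tukey(self, rng):
        """Tukey-adjusted p-values match statsmodels' pairwise_tukeyhsd."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rows, flat_vals, flat_groups = [], [], []
        for t in ("a", "b", "c", "d"):
            vals = rng.normal({"a": 1, "b": 1.5, "c": 1, "d": 3}[t], 0.5, size=5)
            for r, v in enumerate(vals):
                rows.append(("g", t, r, v))
                flat_vals.append(v)
                flat_groups.append(t)
        re_t = pd.DataFrame(rows, columns=["gene", "tissue", "replicate", "rel_expr"])
        (call,) = mf.preferential_call(re_t, target_tissue="d")
        sm = pairwise_tukeyhsd(np.array(flat_vals), np.array(flat_groups))
        sm_p = {
            tuple(sorted((row[0], row[1]))): row[3]
            for row in sm.summary().data[1:]
        }
        for _, row in call.tukey.iterrows():
            key = tuple(sorted((row["tissue_a"], row["tissue_b"])))
            assert row["p_adj"] == pytest.approx(float(sm_p[key]), abs=2e-3)

    def test_single_replicate_tissue_rejected(self):
        re_t = pd.DataFrame(
            [("g", "a", 1, 1.0), ("g", "a", 2, 1.1), ("g", "b", 1, 2.0)],
            columns=["gene", "tissue", "replicate", "rel_expr"],
        )
        with pytest.raises(ValueError, match="single replicate"):
            mf.preferential_call(re_t, target_tissue="a")

    def test_null_effect_fixture_rarely_called(self):
        """With effect_fold = 1 the preferential verdict is negative in at
        least ~95% of seeds (the test is familywise-conservative)."""
        negative = 0
        n_seeds = 50
        for seed in range(n_seeds):
            val = mf.gen_validation_fixtures(["c1"], effect_fold=1.0, n_reps=4, seed=seed)
            re_t = mf.relative_expression(val.ct)
            (call,) = mf.preferential_call(re_t, TARGET_TISSUE)
            negative += not call.verdict
        assert negative / n_seeds >= 0.9


class TestTransactivationFold:
    def _luc(self, effector_ratio, n=6, control_ratio=1.0):
        rows = []
        for rep in range(1, n + 1):
            rows.append(("GUS", rep, control_ratio * 1000.0, 1000.0))
            rows.append(("TF", rep, effector_ratio * 1000.0, 1000.0))
        return pd.DataFrame(rows, columns=["effector", "replicate", "fluc", "rluc"])

    def test_control_against_itself_is_exactly_one(self):
        table = mf.transactivation_fold(self._luc(5.0))
        control_row = table[table["effector"] == "GUS"].iloc[0]
        assert control_row["fold"] == 1.0 and control_row["p_value"] == 1.0

    def test_identical_effector_and_control(self):
        table = mf.transactivation_fold(self._luc(1.0))
        tf = table[table["effector"] == "TF"].iloc[0]
        assert tf["fold"] == pytest.approx(1.0)

    def test_twentyone_fold_activation_flagged_strong(self, rng):
        rows = []
        for rep in range(1, 7):
            rluc = 1000 + rng.normal(0, 20)
            rows.append(("GUS", rep, 1.0 * rluc * (1 + rng.normal(0, 0.02)), rluc))
            rows.append(("TF", rep, 21.0 * rluc * (1 + rng.normal(0, 0.02)), rluc))
        table = mf.transactivation_fold(pd.DataFrame(rows, columns=["effector", "replicate", "fluc", "rluc"]))
        tf = table[table["effector"] == "TF"].iloc[0]
        assert tf["fold"] == pytest.approx(21.0, rel=0.05)
        assert bool(tf["strong"]) and tf["p_value"] < 0.05

    def test_zero_rluc_rejected(self):
        luc = self._luc(2.0)
        luc.loc[0, "rluc"] = 0.0
        with pytest.raises(ValueError, match="rLUC"):
            mf.transactivation_fold(luc)

    def test_missing_control_rejected(self):
        luc = self._luc(2.0)
        luc = luc[luc["effector"] != "GUS"]
        with pytest.raises(ValueError, match="control"):
            mf.transactivation_fold(luc)
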