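"""Unit-variance scaling, hierarchical clustering and candidate selection."""

import numpy as np
import pandas as pd
import pytest

import mybfunnel as mf


def planted_matrix(rng, n_a=20, n_b=20, n_samples=30, r_within=0.9, r_bg=0.3):
    """Two planted correlation blocks built from shared latent factors."""
    g = rng.standard_normal(n_samples)
    fa, fb = rng.standard_normal((2, n_samples))
    rows, names = [], []
    a, b, c = np.sqrt(r_bg), np.sqrt(r_within - r_bg), np.sqrt(1 - r_within)
    for i in range(n_a):
        rows.append(a * g + b * fa + c * rng.standard_normal(n_samples))
        names.append(f"A{i:02d}")
    for i in range(n_b):
        rows.append(a * g + b * fb + c * rng.standard_normal(n_samples))
        names.append(f"B{i:02d}")
    return pd.DataFrame(2.0 ** np.array(rows), index=names,
                        columns=[f"s{j}" for j in range(n_samples)])


class TestUnitVarianceScale:
    def test_two_value_row_forced_by_convention(self):
        m = pd.DataFrame([[0.0, 2.0]], index=["g"], columns=["a", "b"])
        scaled = mf.unit_variance_scale(m).data
        assert scaled.loc["g"].tolist() == pytest.approx([-0.7071, 0.7071], abs=1e-4)

    def test_constant_row_dropped_and_reported(self, caplog):
        m = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with caplog.at_level("WARNING"):
            out = mf.unit_variance_scale(m)
        assert out.dropped == ["flat"]
        assert list(out.data.index) == ["ok"]
        assert "flat" in caplog.text

    def test_all_constant_rows_is_an_error(self):
        m = pd.DataFrame([[1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match="constant"):
            mf.unit_variance_scale(m)

    def test_rows_have_zero_mean_unit_sd(self, rng):
        m = pd.DataFrame(rng.uniform(0, 100, size=(40, 17)))
        scaled = mf.unit_variance_scale(m).data.to_numpy()
        assert np.abs(scaled.mean(axis=1)).max() < 1e-12
        assert np.abs(scaled.std(axis=1, ddof=1) - 1).max() < 1e-12


class TestClusterRows:
    def test_planted_blocks_recovered_exactly(self):
        """At r_within 0.9 vs 0.3 background, the k=2 cut matches the planted
        partition (Rand index 1) for 20 seeds."""
        for seed in range(20):
            m = planted_matrix(np.random.default_rng(seed))
            scaled = mf.unit_variance_scale(m).data
            asg = mf.cluster_rows(scaled, k=2)
            a_labels = {asg.labels[g] for g in m.index if g.startswith("A")}
            b_labels = {asg.labels[g] for g in m.index if g.startswith("B")}
            assert len(a_labels) == 1 and len(b_labels) == 1 and a_labels != b_labels

    def test_k_equal_to_row_count_gives_singletons(self, rng):
        m = pd.DataFrame(rng.uniform(1, 9, (5, 8)), index=list("abcde"))
        asg = mf.cluster_rows(mf.unit_variance_scale(m).data, k=5)
        assert sorted(asg.labels.values()) == [1, 2, 3, 4, 5]

    def test_identical_rows_always_cocluster(self, rng):
        base = rng.uniform(1, 9, 10)
        m = pd.DataFrame(
            [base, base, rng.uniform(1, 9, 10), rng.uniform(1, 9, 10)],
            index=["dup1", "dup2", "x", "y"],
        )
        asg = mf.cluster_rows(mf.unit_variance_scale(m).data, k=2)
        assert asg.labels["dup1"] == asg.labels["dup2"]

    def test_affine_row_transforms_do_not_change_clusters(self, rng):
        """Correlation distance on scaled rows is invariant under per-row
        affine maps of the raw matrix."""
        m = planted_matrix(np.random.default_rng(5), n_a=10, n_b=10)
        scales = rng.uniform(0.5, 4, size=len(m))
        offsets = rng.uniform(0, 10, size=len(m))
        m2 = m.mul(scales, axis=0).add(offsets, axis=0)
        a1 = mf.cluster_rows(mf.unit_variance_scale(m).data, k=2)
        a2 = mf.cluster_rows(mf.unit_variance_scale(m2).data, k=2)
        assert a1.labels == a2.labels

    def test_k_larger_than_rows_rejected(self, rng):
        m = pd.DataFrame(rng.uniform(1, 9, (3, 5)))
        with pytest.raises(ValueError, match="exceeds row count"):
            mf.cluster_rows(m, k=4)


class TestSelectCoclusterCandidates:
    def _assignment(self, mapping):
        return mf.ClusterAssignment(labels=mapping, merges=[], k=len(set(mapping.values())))

    def test_toolbox_cluster_members_returned_without_toolbox(self):
        asg = self._assignment(
            {"t1": 1, "t2": 1, "f1": 1, "f2": 1, "f3": 2, "x": 1}
        )
        cands, diag = mf.select_cocluster_candidates(asg, ["t1", "t2"], ["f1", "f2", "f3"])
        assert cands == {"f1", "f2"}
        assert diag["selected_cluster"] == 1 and diag["toolbox_in_selected"] == 2

    def test_split_toolbox_majority_cluster_selected_with_warning(self, caplog):
        asg = self._assignment({**{f"t{i}": 1 for i in range(13)}, "t13": 2, "f1": 2})
        with caplog.at_level("WARNING"):
            cands, diag = mf.select_cocluster_candidates(
                asg, [f"t{i}" for i in range(14)], ["f1"]
            )
        assert diag["selected_cluster"] == 1 and cands == set()
        assert "split" in caplog.text

    def test_absent_toolbox_is_an_error(self):
        asg = self._assignment({"f1": 1, "f2": 2})
        with pytest.raises(ValueError, match="toolbox"):
            mf.select_cocluster_candidates(asg, ["t1"], ["f1"])

    def test_invariant_under_cluster_relabeling(self):
        base = {"t1": 1, "t2": 1, "f1": 1, "f2": 2, "x": 2}
        relabeled = {g: {1: 2, 2: 1}[c] for g, c in base.items()}
        c1, _ = mf.select_cocluster_candidates(self._assignment(base), ["t1", "t2"], ["f1", "f2"])
        c2, _ = mf.select_cocluster_candidates(self._assignment(relabeled), ["t1", "t2"], ["f1", "f2"])
        assert c1 == c2


class TestInternodeStage:
    def _matrix(self, profiles):
        return pd.DataFrame(
            profiles, columns=list(mf.expr_cluster.INTERNODE_ZONES), dtype=float
        )

    def test_peak_zone_selects_tz_and_mz_peaks(self):
        import mybfunnel.expr_cluster as ec

        m = pd.DataFrame(
            [[1, 2, 10, 8], [9, 8, 2, 1], [1, 1, 2, 9]],
            index=["tz_peak", "early", "mz_peak"],
            columns=list(ec.INTERNODE_ZONES),
            dtype=float,
        )
        out = mf.internode_stage(m, toolbox_ids=[], mode="peak_zone")
        assert out == {"tz_peak", "mz_peak"}

    def test_wrong_zone_columns_rejected(self):
        m = pd.DataFrame([[1, 2, 3]], columns=["a", "b", "c"], dtype=float)
        with pytest.raises(ValueError, match="zone columns"):
            mf.internode_stage(m, toolbox_ids=[], mode="peak_zone")

    def test_both_modes_recover_planted_regulators(self, study):
        truth = study.expression.truth
        family = set(study.genome.truth.ids_with_role("r2r3_family"))
        expected = set(study.regulators)
        for mode in ("cocluster_with_terminal", "peak_zone"):
            out = mf.internode_stage(
                study.expression.internode, study.toolbox, mode=mode, family_ids=family
            )
            assert out == expected, mode

    def test_genes_absent_from_matrix_drop_out(self, study):
        family = set(study.genome.truth.ids_with_role("r2r3_family")) | {"GHOST"}
        out = mf.internode_stage(
            study.expression.internode, study.toolbox,
            mode="peak_zone", family_ids=family,
        )
        assert "GHOST" not in out
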