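"""Fragment modules, variability curves, switching and epigenome clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromdyn.dynamics import (
    cluster_epigenomes,
    cluster_fragments,
    fragment_state_matrix,
    module_contrast_test,
    pair_switch_matrix,
    poisson_signal_score,
    switching_probability,
    variability_curve,
)
from chromdyn.genome import GenomeAssembly, tile_genome
from chromdyn.intervals import flatten, total_length

from conftest import iv, make_segmentation


@pytest.fixture(scope="module")
def frag_assembly():
    return GenomeAssembly("g", (("chrA", 8000),))


class TestFragmentStateMatrix:
    def test_all_quiescent_column(self, frag_assembly):
        seg = make_segmentation(frag_assembly, [])
        frags = tile_genome(frag_assembly, tile=2000, allowlist=None)
        mat, _ = fragment_state_matrix({"t": seg}, frags)
        col = mat[0]
        assert col["Qui"] == 1.0 and col.drop("Qui").sum() == 0.0

    def test_two_tissue_average(self, frag_assembly):
        seg_a = make_segmentation(frag_assembly, [("chrA", 0, 8000, "TssA")], tissue="a")
        seg_b = make_segmentation(frag_assembly, [], tissue="b")
        frags = tile_genome(frag_assembly, tile=2000, allowlist=None)
        mat, per = fragment_state_matrix({"a": seg_a, "b": seg_b}, frags)
        assert mat.loc["TssA", 0] == pytest.approx(0.5)
        assert mat.loc["Qui", 0] == pytest.approx(0.5)
        assert per["a"].loc["TssA", 0] == 1.0

    def test_columns_are_probability_vectors(self, small_config):
        from chromdyn.simulate import simulate_segmentations

        segs, _, _ = simulate_segmentations(small_config)
        asm = next(iter(segs.values())).assembly
        frags = tile_genome(asm, tile=200_000, allowlist=None)
        mat, _ = fragment_state_matrix(segs, frags)
        assert np.allclose(mat.sum(axis=0), 1.0, atol=1e-12)

    def test_fragment_outside_assembly(self, frag_assembly):
        seg = make_segmentation(frag_assembly, [])
        bad = pd.DataFrame({"chrom": ["chrA"], "start": [0], "end": [9000], "index": [0]})
        with pytest.raises(ValueError):
            fragment_state_matrix({"t": seg}, bad)


class TestClusterFragments:
    def test_planted_separation(self):
        rng = np.random.default_rng(0)
        a = np.tile([[0.9], [0.1]], (1, 20)) + rng.normal(0, 0.01, (2, 20))
        b = np.tile([[0.1], [0.9]], (1, 20)) + rng.normal(0, 0.01, (2, 20))
        mat = pd.DataFrame(np.hstack([a, b]), index=["s1", "s2"])
        mat.columns = range(40)
        res = cluster_fragments(mat, k=2, seed=1)
        left = set(res.fragment_module[:20])
        right = set(res.fragment_module[20:])
        assert len(left) == 1 and len(right) == 1 and left != right

    def test_singleton_clusters_and_determinism(self):
        mat = pd.DataFrame(np.eye(4), columns=range(4))
        res = cluster_fragments(mat, k=4, seed=3)
        assert res.fragment_module.nunique() == 4
        res2 = cluster_fragments(mat, k=4, seed=3)
        assert res.fragment_module.equals(res2.fragment_module)

    def test_invalid_k(self):
        mat = pd.DataFrame(np.eye(3), columns=range(3))
        with pytest.raises(ValueError):
            cluster_fragments(mat, k=0)
        with pytest.raises(ValueError):
            cluster_fragments(mat.iloc[:, :0], k=1)


class TestModuleContrast:
    def _assignment(self, labels):
        from chromdyn.dynamics import ModuleAssignment

        s = pd.Series(labels, index=range(len(labels)))
        return ModuleAssignment(s, pd.Series(dtype=int), s.value_counts())

    def test_identical_distributions(self):
        assign = self._assignment(["M3"] * 10 + ["M1"] * 10)
        vals = pd.Series(list(range(10)) + list(range(10)), index=range(20), dtype=float)
        out = module_contrast_test(assign, vals)
        assert out.iloc[0]["t"] == pytest.approx(0.0, abs=1e-12)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 60)
        b = rng.normal(2.0, 2, 80)
        assign = self._assignment(["M3"] * 60 + ["M2"] * 80)
        vals = pd.Series(np.concatenate([a, b]), index=range(140))
        out = module_contrast_test(assign, vals)
        t_ref, p_ref = stats.ttest_ind(b, a, equal_var=False)
        row = out[out["module"] == "M2"].iloc[0]
        assert row["t"] == pytest.approx(t_ref)
        assert row["p"] == pytest.approx(p_ref)
        assert row["p"] < 0.001  # shifted module separates

    def test_small_module_gets_nan(self):
        assign = self._assignment(["M3"] * 5 + ["M1"])
        vals = pd.Series(np.arange(6, dtype=float), index=range(6))
        out = module_contrast_test(assign, vals)
        assert np.isnan(out.iloc[0]["t"])

    def test_degenerate_zero_variance_equal_means(self):
        assign = self._assignment(["M3"] * 4 + ["M1"] * 4)
        vals = pd.Series([2.0] * 8, index=range(8))
        out = module_contrast_test(assign, vals)
        assert out.iloc[0]["t"] == 0.0 and out.iloc[0]["p"] == 1.0

    def test_empty_reference_raises(self):
        assign = self._assignment(["M1"] * 4)
        with pytest.raises(ValueError):
            module_contrast_test(assign, pd.Series(np.arange(4.0), index=range(4)))


class TestVariabilityCurve:
    def test_fully_constitutive(self, toy_assembly):
        rows = [("chrA", 1000, 2000, "EnhA")]
        segs = {f"t{i}": make_segmentation(toy_assembly, rows, tissue=f"t{i}") for i in range(14)}
        curve = variability_curve("EnhA", segs)
        assert np.allclose(curve.values, 1.0)

    def test_fully_specific_additivity(self, toy_assembly):
        segs = {
            f"t{i:02d}": make_segmentation(
                toy_assembly, [("chrA", i * 400, i * 400 + 400, "EnhA")], tissue=f"t{i:02d}"
            )
            for i in range(14)
        }
        curve = variability_curve("EnhA", segs)
        assert np.allclose(curve.values, (np.arange(14) + 1) / 14)

    def test_monotone_and_ends_at_one(self, toy_assembly):
        rng = np.random.default_rng(2)
        segs = {}
        for i in range(6):
            s = int(rng.integers(0, 30)) * 200
            l = int(rng.integers(1, 10)) * 200
            segs[f"t{i}"] = make_segmentation(
                toy_assembly, [("chrA", s, min(s + l, 10_000), "EnhA")], tissue=f"t{i}"
            )
        curve = variability_curve("EnhA", segs)
        assert (np.diff(curve.values) >= -1e-12).all()
        assert curve.values[-1] == pytest.approx(1.0)
        assert curve.values[0] == pytest.approx(max(curve.gl.values()) / curve.tgl)

    def test_matches_per_base_union_oracle(self, toy_assembly):
        rows = {
            "a": [("chrA", 0, 600, "EnhA"), ("chrA", 1000, 1200, "EnhA")],
            "b": [("chrA", 400, 1000, "EnhA")],
            "c": [("chrA", 200, 400, "EnhA"), ("chrB", 0, 200, "EnhA")],
        }
        segs = {t: make_segmentation(toy_assembly, r, tissue=t) for t, r in rows.items()}
        curve = variability_curve("EnhA", segs)
        # brute-force: per-base union in accumulation order
        masks = {}
        for t, r in rows.items():
            m = {"chrA": np.zeros(10_000, bool), "chrB": np.zeros(6_000, bool)}
            for chrom, s, e, _ in r:
                m[chrom][s:e] = True
            masks[t] = m
        acc = {"chrA": np.zeros(10_000, bool), "chrB": np.zeros(6_000, bool)}
        tgl = sum(np.logical_or.reduce([masks[t][c] for t in rows]).sum() for c in acc)
        expect = []
        for t in curve.tissues:
            for c in acc:
                acc[c] |= masks[t][c]
            expect.append(sum(acc[c].sum() for c in acc) / tgl)
        assert np.allclose(curve.values, expect)

    def test_absent_state_empty_curve(self, toy_assembly):
        segs = {"t": make_segmentation(toy_assembly, [])}
        curve = variability_curve("EnhA", segs)
        assert curve.tissues == () and curve.tgl == 0


class TestSwitching:
    def test_half_overlap(self, toy_assembly):
        a = make_segmentation(toy_assembly, [("chrA", 200, 2200, "EnhA")], tissue="a")
        b = make_segmentation(toy_assembly, [("chrA", 1200, 3200, "EnhA")], tissue="b")
        p_ab, p_ba, pair = switching_probability("EnhA", a, b)
        assert (p_ab, p_ba, pair) == (0.5, 0.5, 0.5)

    def test_identical_and_disjoint(self, toy_assembly):
        a = make_segmentation(toy_assembly, [("chrA", 0, 1000, "EnhA")], tissue="a")
        b = make_segmentation(toy_assembly, [("chrA", 2000, 3000, "EnhA")], tissue="b")
        assert switching_probability("EnhA", a, a) == (1.0, 1.0, 1.0)
        assert switching_probability("EnhA", a, b) == (0.0, 0.0, 0.0)

    def test_absent_state_is_nan(self, toy_assembly):
        a = make_segmentation(toy_assembly, [("chrA", 0, 1000, "EnhA")], tissue="a")
        b = make_segmentation(toy_assembly, [], tissue="b")
        p_ab, p_ba, _ = switching_probability("EnhA", a, b)
        assert p_ab == 0.0 and np.isnan(p_ba)

    def test_pair_matrix_symmetric_and_group_structure(self, small_config):
        from chromdyn.simulate import simulate_segmentations

        segs, _, _ = simulate_segmentations(small_config)
        mat = pair_switch_matrix("EnhA", segs)
        assert np.allclose(mat, mat.T, equal_nan=True)
        within_gut = np.mean(
            [mat.loc[a, b] for a in ("jejunum", "ileum") for b in ("cecum", "colon")]
        )
        cross = np.mean(
            [mat.loc[a, b] for a in ("jejunum", "ileum") for b in ("liver", "muscle")]
        )
        assert within_gut > cross


class TestPoissonScore:
    def test_zero_count_scores_zero(self):
        assert poisson_signal_score(0, 1.0) == 0.0

    def test_reference_value(self):
        # P(X>=5 | lambda=1) = 0.0036598..., score ~ 2.4366
        assert poisson_signal_score(5, 1.0) == pytest.approx(
            -np.log10(1 - stats.poisson.cdf(4, 1.0)), rel=1e-9
        )
        assert poisson_signal_score(5, 1.0) == pytest.approx(2.4366, abs=2e-4)

    def test_monotone_in_count(self):
        scores = poisson_signal_score(np.arange(20), 3.0)
        assert (np.diff(scores) >= 0).all()

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            poisson_signal_score(1, 0.0)


class TestEpigenomeClustering:
    def test_replicates_are_siblings(self):
        rng = np.random.default_rng(4)
        base = {t: rng.normal(0, 1, 40) * 10 for t in ("liver", "lung", "muscle")}
        rows = {}
        for t, v in base.items():
            rows[f"{t}_rep1"] = v + rng.normal(0, 0.1, 40)
            rows[f"{t}_rep2"] = v + rng.normal(0, 0.1, 40)
        X = pd.DataFrame(rows).T
        link = cluster_epigenomes(X)
        samples = link.attrs["samples"]
        first_merges = link.iloc[:3][["node_a", "node_b"]].to_numpy().astype(int)
        for a, b in first_merges:
            assert samples[a].split("_")[0] == samples[b].split("_")[0]

    def test_two_samples_single_merge(self):
        X = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        link = cluster_epigenomes(X)
        assert len(link) == 1
        assert link.iloc[0]["height"] == pytest.approx(5.0)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(5, 7)), index=list("edcba"))
        l1 = cluster_epigenomes(X)
        l2 = cluster_epigenomes(X.iloc[::-1])
        pd.testing.assert_frame_equal(l1, l2)

    def test_constant_matrix_warns(self):
        X = pd.DataFrame(np.ones((3, 4)), index=list("abc"))
        with pytest.warns(UserWarning):
            cluster_epigenomes(X)
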