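"""TSE detection, RRAT presence matrices, TSR module assignment and
promoter-shift profiling."""

import math

import numpy as np
import pandas as pd
import pytest

from chromdyn.genome import GeneTable, GenomeAssembly
from chromdyn.specificity import (
    DEFAULT_TISSUES,
    ExpressionMatrix,
    RratTable,
    assign_tsr_modules,
    build_rrat,
    detect_tse_genes,
    module_universe,
    tse_promoter_shift,
)

from conftest import make_segmentation


def _expr(n_genes=1000, tissues=DEFAULT_TISSUES, seed=0):
    rng = np.random.default_rng(seed)
    tpm = pd.DataFrame(
        rng.lognormal(2, 1, size=(n_genes, len(tissues))),
        index=[f"g{i:04d}" for i in range(n_genes)],
        columns=list(tissues),
    )
    return ExpressionMatrix(tpm)


class TestDetectTse:
    def test_top_fraction_size_is_ceil(self):
        expr = _expr(n_genes=1000)
        res = detect_tse_genes(expr, "liver")
        assert len(res.tse_genes) == math.ceil(0.05 * 1000) == 50
        res7 = detect_tse_genes(_expr(n_genes=141), "liver")
        assert len(res7.tse_genes) == math.ceil(0.05 * 141) == 8

    def test_strong_singleton_gene_selected(self):
        expr = _expr(n_genes=1000, seed=1)
        expr.tpm.loc["g0000"] = 10.0
        expr.tpm.loc["g0000", "liver"] = 1000.0  # 100-fold in liver only
        res = detect_tse_genes(expr, "liver")
        assert "g0000" in res.tse_genes

    def test_subgroup_exclusion(self):
        # making same-sub-group tissues extreme must not change jejunum t
        expr = _expr(n_genes=300, seed=2)
        t_before = detect_tse_genes(expr, "jejunum", scale="none").t_values
        expr2 = ExpressionMatrix(expr.tpm.copy(), groups=expr.groups)
        expr2.tpm["ileum"] = 1e6
        expr2.tpm["duodenum"] = 0.0
        t_after = detect_tse_genes(expr2, "jejunum", scale="none").t_values
        pd.testing.assert_series_equal(t_before, t_after)

    def test_tse_tvalues_dominate_rest(self):
        expr = _expr(n_genes=400, seed=3)
        res = detect_tse_genes(expr, "muscle")
        worst_selected = res.t_values[list(res.tse_genes)].min()
        rest = res.t_values.drop(list(res.tse_genes))
        assert worst_selected >= rest[np.isfinite(rest)].max()

    def test_gene_order_invariance(self):
        expr = _expr(n_genes=200, seed=4)
        res1 = detect_tse_genes(expr, "lung")
        shuffled = ExpressionMatrix(expr.tpm.sample(frac=1, random_state=0), groups=expr.groups)
        res2 = detect_tse_genes(shuffled, "lung")
        assert set(res1.tse_genes) == set(res2.tse_genes)

    def test_needs_enough_outside_tissues(self):
        tpm = pd.DataFrame(np.ones((10, 3)), columns=["cortex", "cerebellum", "hypothalamus"])
        with pytest.raises(ValueError):
            detect_tse_genes(ExpressionMatrix(tpm), "cortex")

    def test_planted_recovery_at_five_sigma(self, small_config):
        from chromdyn.simulate import PlantedTruth, simulate_expression

        truth = PlantedTruth(elements=pd.DataFrame())
        expr = simulate_expression(small_config, truth)
        recovered = 0
        planted_total = 0
        for t, planted in truth.tse_genes.items():
            res = detect_tse_genes(expr, t)
            recovered += len(set(planted) & set(res.tse_genes))
            planted_total += len(planted)
        assert recovered / planted_total >= 0.9


class TestRrat:
    def test_single_tissue_column_of_ones(self, toy_assembly):
        segs = {"liver": make_segmentation(toy_assembly, [("chrA", 0, 400, "EnhA")], tissue="liver"),
                "lung": make_segmentation(toy_assembly, [], tissue="lung")}
        rrat = build_rrat(segs, "EnhA")
        assert rrat.presence["liver"].tolist() == [1]
        assert rrat.presence["lung"].tolist() == [0]

    def test_identical_tissues_all_ones(self, toy_assembly):
        rows = [("chrA", 0, 400, "EnhA"), ("chrA", 1000, 1200, "EnhA")]
        segs = {t: make_segmentation(toy_assembly, rows, tissue=t) for t in ("a", "b")}
        rrat = build_rrat(segs, "EnhA")
        assert rrat.presence.to_numpy().tolist() == [[1, 1], [1, 1]]

    def test_chained_overlap_presence_matches_oracle(self, toy_assembly):
        segs = {
            "a": make_segmentation(toy_assembly, [("chrA", 0, 400, "EnhA")], tissue="a"),
            "b": make_segmentation(toy_assembly, [("chrA", 200, 600, "EnhA")], tissue="b"),
            "c": make_segmentation(toy_assembly, [("chrA", 1000, 1200, "EnhA")], tissue="c"),
        }
        rrat = build_rrat(segs, "EnhA")
        assert len(rrat.regions) == 2
        first = rrat.presence.iloc[0]  # [0,600): a and b, not c
        assert first.tolist() == [1, 1, 0]
        assert rrat.presence.iloc[1].tolist() == [0, 0, 1]

    def test_absent_state_raises(self, toy_assembly):
        segs = {"a": make_segmentation(toy_assembly, [], tissue="a")}
        with pytest.raises(ValueError):
            build_rrat(segs, "EnhA")


class TestTsrModules:
    def _rrat(self, presence_rows, tissues=DEFAULT_TISSUES):
        n = len(presence_rows)
        regions = pd.DataFrame(
            {"chrom": "chrA", "start": np.arange(n) * 1000, "end": np.arange(n) * 1000 + 400}
        )
        presence = pd.DataFrame(presence_rows, columns=list(tissues))
        return RratTable("EnhA", regions, presence)

    def test_universe_has_17_categories(self):
        assert len(module_universe()) == 17

    def test_assignment_precedence(self):
        tissues = list(DEFAULT_TISSUES)
        all_ones = [1] * 14
        gut = [1 if t in ("duodenum", "jejunum", "ileum", "cecum", "colon") else 0 for t in tissues]
        brain = [1 if t in ("cortex", "cerebellum", "hypothalamus") else 0 for t in tissues]
        only_liver = [1 if t == "liver" else 0 for t in tissues]
        mixed = [1 if t in ("jejunum", "liver") else 0 for t in tissues]
        rrat = self._rrat([all_ones, gut, brain, only_liver, mixed])
        mods = assign_tsr_modules(rrat)
        assert mods.tolist() == [
            "all_common", "gut_common", "brain_common", "liver_specific", "unassigned"
        ]

    def test_labels_within_universe(self):
        rng = np.random.default_rng(0)
        rows = (rng.random((50, 14)) < 0.4).astype(int)
        rows[rows.sum(axis=1) == 0, 0] = 1
        mods = assign_tsr_modules(self._rrat(list(rows)))
        assert set(mods) <= set(module_universe()) | {"unassigned"}

    def test_tissue_order_invariance(self):
        tissues = list(DEFAULT_TISSUES)
        rng = np.random.default_rng(1)
        rows = (rng.random((30, 14)) < 0.3).astype(int)
        rows[rows.sum(axis=1) == 0, 3] = 1
        rrat = self._rrat(list(rows))
        mods1 = assign_tsr_modules(rrat)
        shuffled = RratTable("EnhA", rrat.regions, rrat.presence[tissues[::-1]])
        mods2 = assign_tsr_modules(shuffled)
        assert mods1.tolist() == mods2.tolist()

    def test_planted_modules_recovered_exactly(self, small_config):
        from chromdyn.simulate import simulate_segmentations

        segs, truth, _ = simulate_segmentations(small_config)
        rrat = build_rrat(segs, small_config.element_state)
        mods = assign_tsr_modules(rrat)
        planted = truth.elements[truth.elements["state"] == small_config.element_state]
        lookup = {(c, s): cat for c, s, cat in
                  zip(planted["chrom"], planted["start"], planted["category"])}
        checked = 0
        for i, (_, reg) in enumerate(rrat.regions.iterrows()):
            key = (reg["chrom"], reg["start"])
            if key in lookup:
                assert mods.iloc[i] == lookup[key]
                checked += 1
        assert checked == len(planted)


class TestPromoterShift:
    def test_planted_construction_and_compositional_oracle(self, toy_assembly):
        from chromdyn.enrichment import fold_enrichment
        from chromdyn.genome import FeatureSet
        from chromdyn.specificity import TseResult

        genes = GeneTable(pd.DataFrame(
            [("g1", "chrA", "+", 3000, 3800, "pc"), ("g2", "chrB", "+", 2000, 2800, "pc")],
            columns=["gene_id", "chrom", "strand", "tss", "tes", "biotype"],
        ))
        focal = make_segmentation(
            toy_assembly, [("chrA", 2800, 3200, "TssA"), ("chrB", 1800, 2200, "TssA")], tissue="f"
        )
        other = make_segmentation(toy_assembly, [("chrA", 7000, 7400, "TssA")], tissue="o")
        tse = TseResult("f", pd.Series(dtype=float), ("g1", "g2"))
        out = tse_promoter_shift(tse, {"f": focal, "o": other}, genes, toy_assembly, window=2000)
        assert out.loc["TssA", "shift"] > 0
        assert out.loc["Qui", "shift"] < 0
        windows = genes.tss_windows(2000, toy_assembly, ids=("g1", "g2"))
        feat = FeatureSet("w", windows)
        fe_f = fold_enrichment(focal.state_intervals("TssA"), feat, toy_assembly).fold_enrichment
        fe_o = fold_enrichment(other.state_intervals("TssA"), feat, toy_assembly).fold_enrichment
        assert out.loc["TssA", "shift"] == pytest.approx(fe_f - fe_o)

    def test_identical_segmentations_zero_shift(self, toy_assembly):
        from chromdyn.specificity import TseResult

        genes = GeneTable(pd.DataFrame(
            [("g1", "chrA", "+", 3000, 3800, "pc")],
            columns=["gene_id", "chrom", "strand", "tss", "tes", "biotype"],
        ))
        rows = [("chrA", 2000, 2400, "TssA")]
        segs = {t: make_segmentation(toy_assembly, rows, tissue=t) for t in ("a", "b", "c")}
        tse = TseResult("a", pd.Series(dtype=float), ("g1",))
        out = tse_promoter_shift(tse, segs, genes, toy_assembly)
        assert np.allclose(out["shift"].fillna(0.0), 0.0)

    def test_missing_gene_raises(self, toy_assembly):
        from chromdyn.specificity import TseResult

        genes = GeneTable(pd.DataFrame(
            [("g1", "chrA", "+", 3000, 3800, "pc")],
            columns=["gene_id", "chrom", "strand", "tss", "tes", "biotype"],
        ))
        segs = {"a": make_segmentation(toy_assembly, [], tissue="a"),
                "b": make_segmentation(toy_assembly, [], tissue="b")}
        tse = TseResult("a", pd.Series(dtype=float), ("gX",))
        with pytest.raises(ValueError):
            tse_promoter_shift(tse, segs, genes, toy_assembly)
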