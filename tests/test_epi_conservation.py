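"""Conservation strata, orthology lifting and epi-conservation rates."""

import numpy as np
import pandas as pd
import pytest

from chromdyn.conservation import (
    OrthologyMap,
    conservation_curve,
    epi_conservation_rate,
    expression_conservation_sets,
    lift_regions,
    quantile_sets,
    segment_scores,
)
from chromdyn.genome import GenomeAssembly

from conftest import iv, make_segmentation


def _identity_map(length=10_000, chrom="chrA", tgt="chrA", identity=1.0, pair=1000):
    n = length // pair
    return OrthologyMap(pd.DataFrame({
        "src_chrom": chrom, "src_start": np.arange(n) * pair,
        "src_end": (np.arange(n) + 1) * pair,
        "tgt_chrom": tgt, "tgt_start": np.arange(n) * pair,
        "tgt_end": (np.arange(n) + 1) * pair,
        "identity": identity,
    }))


class TestSegmentScores:
    def test_constant_track(self, toy_assembly):
        track = pd.DataFrame({"chrom": ["chrA"], "start": [0], "end": [10_000], "score": [1.0]})
        out = segment_scores(track, toy_assembly)
        assert (out["score"] == 1.0).all()
        assert len(out) == 50  # chrB uncovered -> dropped
        assert out.attrs["n_uncovered"] == 30

    def test_split_segment_average(self, toy_assembly):
        track = pd.DataFrame({"chrom": ["chrA", "chrA"], "start": [0, 100],
                              "end": [100, 200], "score": [0.0, 2.0]})
        out = segment_scores(track, toy_assembly)
        assert out.iloc[0]["score"] == pytest.approx(1.0)

    def test_matches_per_base_oracle(self, toy_assembly):
        rng = np.random.default_rng(0)
        rows = []
        pos = 0
        while pos < 3000:
            w = int(rng.integers(30, 300))
            rows.append(("chrA", pos, min(pos + w, 3000), float(rng.normal())))
            pos += w
        track = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
        out = segment_scores(track, toy_assembly)
        base = np.full(10_000, np.nan)
        for _, r in track.iterrows():
            base[r["start"]:r["end"]] = r["score"]
        for _, r in out[out["chrom"] == "chrA"].iterrows():
            seg = base[r["start"]:r["end"]]
            assert r["score"] == pytest.approx(np.nanmean(seg))

    def test_empty_track_raises(self, toy_assembly):
        with pytest.raises(ValueError):
            segment_scores(pd.DataFrame(columns=["chrom", "start", "end", "score"]), toy_assembly)


class TestQuantileSets:
    def _segments(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"chrom": "chrA", "start": np.arange(n) * 200,
                             "end": (np.arange(n) + 1) * 200, "score": rng.normal(size=n)})

    def test_exact_division(self):
        out = quantile_sets(self._segments(1000))
        assert out["set"].value_counts().eq(20).all()

    def test_remainder_spread_over_lowest_sets(self):
        out = quantile_sets(self._segments(1003))
        counts = out["set"].value_counts().sort_index()
        assert counts.iloc[:3].tolist() == [21, 21, 21]
        assert counts.iloc[3:].eq(20).all()

    def test_set_index_monotone_in_score(self):
        segs = self._segments(500, seed=1)
        out = quantile_sets(segs)
        grouped = out.groupby("set")["score"].agg(["min", "max"])
        assert (grouped["max"].to_numpy()[:-1] <= grouped["min"].to_numpy()[1:] + 1e-12).all()

    def test_validation(self):
        with pytest.raises(ValueError):
            quantile_sets(self._segments(10), n_sets=50)
        with pytest.raises(ValueError):
            quantile_sets(self._segments(100), n_sets=1)


class TestLiftRegions:
    def test_identity_map_round_trip(self):
        omap = _identity_map()
        regions = iv(("chrA", 150, 950), ("chrA", 2000, 2600))
        mapped, unmapped = lift_regions(omap, regions)
        assert unmapped.empty
        assert mapped[["chrom", "start", "end"]].to_numpy().tolist() == [
            ["chrA", 150, 950], ["chrA", 2000, 2600]
        ]

    def test_identity_threshold(self):
        omap = _identity_map(identity=0.5)
        mapped, unmapped = lift_regions(omap, iv(("chrA", 100, 300)))
        assert mapped.empty
        assert unmapped[["start", "end"]].to_numpy().tolist() == [[100, 300]]

    def test_split_pieces_conserve_length(self):
        pairs = pd.DataFrame({
            "src_chrom": ["chrA", "chrA"], "src_start": [0, 1000], "src_end": [1000, 2000],
            "tgt_chrom": ["chrB", "chrB"], "tgt_start": [5000, 9000], "tgt_end": [6000, 10_000],
            "identity": [0.9, 0.8],
        })
        omap = OrthologyMap(pairs)
        mapped, unmapped = lift_regions(omap, iv(("chrA", 600, 1400)))
        assert len(mapped) == 2
        total_mapped = int((mapped["end"] - mapped["start"]).sum())
        total_unmapped = int((unmapped["end"] - unmapped["start"]).sum()) if not unmapped.empty else 0
        assert total_mapped + total_unmapped == 800
        assert mapped.iloc[0][["start", "end"]].tolist() == [5600, 6000]
        assert mapped.iloc[1][["start", "end"]].tolist() == [9000, 9400]

    def test_gap_between_pairs_reported_unmapped(self):
        pairs = pd.DataFrame({
            "src_chrom": ["chrA"], "src_start": [500], "src_end": [700],
            "tgt_chrom": ["chrB"], "tgt_start": [0], "tgt_end": [200], "identity": [0.9],
        })
        mapped, unmapped = lift_regions(OrthologyMap(pairs), iv(("chrA", 0, 1000)))
        spans = sorted(map(tuple, unmapped[["start", "end"]].to_numpy()))
        assert spans == [(0, 500), (700, 1000)]
        assert mapped[["start", "end"]].to_numpy().tolist() == [[0, 200]]

    def test_unknown_chromosome_raises(self):
        with pytest.raises(ValueError):
            lift_regions(_identity_map(), iv(("chrZ", 0, 100)))

    def test_map_validation(self):
        bad = pd.DataFrame({
            "src_chrom": ["chrA", "chrA"], "src_start": [0, 500], "src_end": [1000, 1500],
            "tgt_chrom": ["chrB", "chrB"], "tgt_start": [0, 500], "tgt_end": [1000, 1500],
            "identity": [0.9, 0.9],
        })
        with pytest.raises(ValueError):
            OrthologyMap(bad)  # overlapping source intervals


class TestEpiConservationRate:
    def test_identical_segmentations_rate_one(self, toy_assembly):
        seg = make_segmentation(toy_assembly, [("chrA", 1000, 1600, "EnhA")])
        regions = seg.state_intervals("EnhA")
        rates = epi_conservation_rate(regions, seg, "EnhA")
        assert np.allclose(rates, 1.0)

    def test_state_absent_in_target_rate_zero(self, toy_assembly):
        src = make_segmentation(toy_assembly, [("chrA", 1000, 1600, "EnhA")])
        tgt = make_segmentation(toy_assembly, [])
        rates = epi_conservation_rate(src.state_intervals("EnhA"), tgt, "EnhA")
        assert np.allclose(rates, 0.0)

    def test_partial_overlap_matches_fraction(self, toy_assembly):
        tgt = make_segmentation(toy_assembly, [("chrA", 1200, 1400, "EnhA"),
                                               ("chrA", 1600, 1800, "EnhA")])
        region = iv(("chrA", 1000, 1800))
        rates = epi_conservation_rate(region, tgt, "EnhA")
        assert rates.iloc[0] == pytest.approx((200 + 200) / 800)


class TestConservationCurve:
    def test_single_set_populated(self):
        sets = pd.DataFrame({"chrom": "chrA", "start": np.arange(10) * 200,
                             "end": (np.arange(10) + 1) * 200,
                             "score": np.arange(10.0), "set": [0] * 5 + [1] * 5})
        regions = iv(("chrA", 0, 200))
        curve = conservation_curve(regions, pd.Series([0.7]), sets, n_sets=2)
        assert curve[0] == pytest.approx(0.7)
        assert np.isnan(curve[1])

    def test_midpoint_assignment(self):
        sets = pd.DataFrame({"chrom": "chrA", "start": np.arange(10) * 200,
                             "end": (np.arange(10) + 1) * 200,
                             "score": np.arange(10.0), "set": [0] * 5 + [1] * 5})
        region = iv(("chrA", 800, 1400))  # midpoint 1100 -> segment 1000 -> set 1
        curve = conservation_curve(region, pd.Series([0.5]), sets, n_sets=2)
        assert np.isnan(curve[0]) and curve[1] == pytest.approx(0.5)

    def test_planted_u_shape_recovered(self):
        from scipy import stats

        from chromdyn.conservation import pooled_conservation_curve
        from chromdyn.simulate import SimulationConfig, simulate_orthology_pair

        cfg = SimulationConfig(seed=11)
        src, tgt, omap, track, truth = simulate_orthology_pair(cfg)
        sets = quantile_sets(segment_scores(track, src.assembly))
        curve = pooled_conservation_curve(src, tgt, omap, sets)
        rho = stats.spearmanr(curve.to_numpy(), truth.flip_profile).statistic
        assert abs(rho) >= 0.9
        # both arms of the U sit above its minimum
        assert curve.iloc[0] > curve.iloc[25] and curve.iloc[49] > curve.iloc[25]

    def test_constant_flip_rate_flat_curve(self):
        from chromdyn.conservation import pooled_conservation_curve
        from chromdyn.simulate import SimulationConfig, simulate_orthology_pair

        cfg = SimulationConfig(seed=12, flip_profile=tuple([0.4] * 50))
        src, tgt, omap, track, _ = simulate_orthology_pair(cfg)
        sets = quantile_sets(segment_scores(track, src.assembly))
        curve = pooled_conservation_curve(src, tgt, omap, sets)
        assert curve.std() < 0.06  # Monte-Carlo band around a flat line


class TestExpressionConservationSets:
    def _expr(self, n=700, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"g{i:04d}" for i in range(n)]
        a = pd.DataFrame(rng.lognormal(2, 1, (n, 3)), index=idx)
        b = pd.DataFrame(rng.lognormal(2, 1, (n, 3)), index=idx)
        return a, b

    def test_equal_split_700_genes(self):
        a, b = self._expr(700)
        out = expression_conservation_sets(a, b)
        assert out["set"].value_counts().eq(14).all()

    def test_identical_expression_lands_in_last_set(self):
        a, b = self._expr(200, seed=1)
        a.loc["g0000"] = [5.0, 5.0, 5.0]
        b.loc["g0000"] = [5.0, 5.0, 5.0]
        out = expression_conservation_sets(a, b)
        assert out.set_index("gene").loc["g0000", "p"] == 1.0
        assert out.set_index("gene").loc["g0000", "set"] == 49

    def test_divergent_gene_lands_in_first_set(self):
        a, b = self._expr(200, seed=2)
        a.loc["g0001"] = [100.0, 100.1, 99.9]
        b.loc["g0001"] = [1.0, 1.05, 0.95]
        out = expression_conservation_sets(a, b)
        assert out.set_index("gene").loc["g0001", "set"] == 0

    def test_replicate_requirement(self):
        a, b = self._expr(100)
        with pytest.raises(ValueError):
            expression_conservation_sets(a.iloc[:, :1], b)
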