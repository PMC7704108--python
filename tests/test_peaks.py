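"""Peak-module scoring: motif scan, CpG accounting, grouping, linking, tracks."""

import numpy as np
import pandas as pd
import pytest

import memoryscan as ms
from memoryscan.peaks import (
    GROUP_REST,
    GROUP_TOP_Q,
    STATE_INTERMEDIATE,
    STATE_METHYLATED,
    STATE_NO_DATA,
    STATE_UNMETHYLATED,
    KappaBHit,
    ModuleScore,
    PeakMethylation,
    reverse_complement,
)

CONSENSUS = ms.KAPPA_B_CONSENSUS
PWM = ms.pwm_from_consensus(CONSENSUS)


def brute_force_scan(seq, pwm):
    """Oracle: score every start position on both strands with naive loops."""
    lod = np.log2(np.maximum(pwm, 1e-9) / 0.25)
    k = pwm.shape[0]
    best = None
    for pos in range(len(seq) - k + 1):
        for strand in "+-":
            window = seq[pos : pos + k]
            if strand == "-":
                window = reverse_complement(window)
            s = sum(lod[j, "ACGT".index(b)] for j, b in enumerate(window))
            if best is None or s > best[0] + 1e-12:
                best = (s, pos, strand)
    return best


def meth_frame(records):
    """(chrom, pos, count_meth, count_unmeth) records -> internal table."""
    rows = []
    for chrom, pos, m, u in records:
        level = m / (m + u) if m + u else float("nan")
        rows.append((chrom, pos, level, m, u))
    return pd.DataFrame(rows, columns=["chrom", "pos", "level", "count_meth", "count_unmeth"])


def make_score(peak_id, chrom, start, motif_offset, cpgs=(), strand="+",
               m_t0=None, m_t12=None, n_used=0, level_t0=None, level_t12=None):
    peak = ms.GenomicInterval(chrom, start, start + 600, name=peak_id)
    hit = KappaBHit(offset=motif_offset, length=10, score=10.0, strand=strand)
    return ModuleScore(
        peak=peak, hit=hit, cpg_positions=tuple(cpgs),
        level_t0=level_t0, level_t12=level_t12, m_t0=m_t0, m_t12=m_t12,
        n_used=n_used,
    )


class TestMotifScan:
    def test_exact_consensus_found_with_max_score(self):
        seq = "A" * 20 + CONSENSUS + "A" * 20
        hit = ms.scan_kb_motif(seq, PWM)
        assert (hit.offset, hit.strand) == (20, "+")
        max_score = np.log2(np.max(PWM, axis=1) / 0.25).sum()
        assert hit.score == pytest.approx(max_score)

    def test_reverse_complement_same_score_opposite_strand(self):
        fwd = "A" * 15 + CONSENSUS + "A" * 15
        rev = reverse_complement(fwd)
        hf, hr = ms.scan_kb_motif(fwd, PWM), ms.scan_kb_motif(rev, PWM)
        assert hf.score == pytest.approx(hr.score)
        assert {hf.strand, hr.strand} == {"+", "-"}

    def test_matches_brute_force_on_degenerate_toy(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 60))
        # plant two degenerate near-consensus sites
        seq = seq[:10] + "GGGACTTTCA" + seq[20:40] + "GGGTCTTTCC" + seq[50:]
        hit = ms.scan_kb_motif(seq, PWM)
        score, pos, strand = brute_force_scan(seq, PWM)
        assert (hit.offset, hit.strand) == (pos, strand)
        assert hit.score == pytest.approx(score)

    def test_too_short_sequence_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            ms.scan_kb_motif("ACGT", PWM)

    def test_tie_broken_leftmost_then_plus(self):
        seq = CONSENSUS + "TTTT" + CONSENSUS
        hit = ms.scan_kb_motif(seq, PWM)
        assert (hit.offset, hit.strand) == (0, "+")


class TestCpgsInFlank:
    GENOME = "A" * 50 + "CG" + "A" * 8 + CONSENSUS + "A" * 8 + "CG" + "A" * 50

    def test_no_cg_window_empty(self):
        peak = ms.GenomicInterval("c", 0, 40)
        hit = KappaBHit(offset=10, length=10, score=1.0, strand="+")
        assert ms.cpgs_in_flank("A" * 120, peak, hit, flank=10) == []

    def test_hand_enumeration(self):
        # CpG cytosines sit at genomic positions 50 and 78; motif center at 65
        peak = ms.GenomicInterval("c", 40, 100)
        hit = KappaBHit(offset=20, length=10, score=1.0, strand="+")  # motif at 60
        got = ms.cpgs_in_flank(self.GENOME, peak, hit, flank=250)
        assert got == [50, 78]

    def test_boundary_distance_inclusive(self):
        # distances from center 65: |50-65| = 15, |78-65| = 13
        for flank, expect in [(15, [50, 78]), (14, [78]), (13, [78]), (12, [])]:
            peak = ms.GenomicInterval("c", 40, 100)
            hit = KappaBHit(offset=20, length=10, score=1.0, strand="+")
            got = ms.cpgs_in_flank(self.GENOME, peak, hit, flank=flank)
            assert got == expect, (flank, got)


class TestPeakMethylation:
    TABLE = meth_frame(
        [("c", 10, 10, 0), ("c", 20, 10, 0), ("c", 30, 0, 10), ("c", 40, 0, 10)]
    )

    def test_hand_arithmetic(self):
        res = ms.peak_methylation(self.TABLE, [10, 20, 30, 40], "c", min_cov=5)
        assert res.mean_level == pytest.approx(0.5)
        assert res.total == pytest.approx(2.0)
        assert res.n_used == 4

    def test_low_coverage_excluded(self):
        table = meth_frame([("c", 10, 2, 2), ("c", 20, 10, 0)])
        res = ms.peak_methylation(table, [10, 20], "c", min_cov=5)
        assert res.n_used == 1 and res.mean_level == 1.0

    def test_all_unmethylated(self):
        table = meth_frame([("c", 10, 0, 10), ("c", 20, 0, 10)])
        res = ms.peak_methylation(table, [10, 20], "c")
        assert (res.mean_level, res.total) == (0.0, 0.0)

    def test_no_usable_cpgs_returns_sentinel(self):
        res = ms.peak_methylation(self.TABLE, [99], "c")
        assert not res.has_data and res.mean_level is None

    def test_empty_positions_error(self):
        with pytest.raises(ValueError):
            ms.peak_methylation(self.TABLE, [], "c")


class TestClassifyInitialState:
    @pytest.mark.parametrize(
        "level,state",
        [(0.50, STATE_METHYLATED), (0.19, STATE_UNMETHYLATED),
         (0.1999, STATE_UNMETHYLATED), (0.20, STATE_INTERMEDIATE),
         (0.35, STATE_INTERMEDIATE), (1.0, STATE_METHYLATED),
         (0.0, STATE_UNMETHYLATED)],
    )
    def test_boundaries(self, level, state):
        assert ms.classify_initial_state(level) == state

    def test_no_data_propagates(self):
        assert ms.classify_initial_state(PeakMethylation(None, None, 0)) == STATE_NO_DATA


class TestDemethylationGrouping:
    def test_topq_hand_quartile(self):
        scores = [
            make_score(f"p{i}", "c", i * 1000, 0, m_t0=float(d), m_t12=0.0, n_used=1)
            for i, d in enumerate(range(1, 9))
        ]
        groups = ms.demethylation_grouping(scores, mode="topQ")
        # Q3 of 1..8 under linear interpolation is 6.25; strict > keeps {7, 8}
        assert groups["q3"] == pytest.approx(6.25)
        assert sorted(s.delta_m for s in groups[GROUP_TOP_Q]) == [7.0, 8.0]
        assert len(groups[GROUP_REST]) == 6

    def test_all_equal_deltas_topq_empty_with_warning(self):
        scores = [
            make_score(f"p{i}", "c", i * 1000, 0, m_t0=2.0, m_t12=1.0, n_used=1)
            for i in range(4)
        ]
        with pytest.warns(UserWarning, match="identical"):
            groups = ms.demethylation_grouping(scores, mode="topQ")
        assert groups[GROUP_TOP_Q] == []

    def test_quintiles_equal_count_in_sorted_order(self):
        deltas = [3.0, 1.0, 9.0, 7.0, 5.0, 2.0, 8.0, 4.0, 10.0, 6.0]
        scores = [
            make_score(f"p{i}", "c", i * 1000, 0, m_t0=d, m_t12=0.0, n_used=1)
            for i, d in enumerate(deltas)
        ]
        groups = ms.demethylation_grouping(scores, mode="quintile")
        assert [len(b) for b in groups["bins"]] == [2, 2, 2, 2, 2]
        for k, b in enumerate(groups["bins"]):
            assert sorted(s.delta_m for s in b) == [2 * k + 1.0, 2 * k + 2.0]

    def test_too_few_peaks_for_bins_errors(self):
        scores = [make_score("p0", "c", 0, 0, m_t0=1.0, m_t12=0.0, n_used=1)]
        with pytest.raises(ValueError, match="quantile bins"):
            ms.demethylation_grouping(scores, mode="quintile")


class TestLinkPeaksToGenes:
    TSS = pd.DataFrame(
        {"chrom": ["c"] * 4, "pos": [100, 5000, 90_000, 300_000],
         "strand": ["+", "-", "+", "+"], "gene_id": ["gA", "gB", "gC", "gD"]}
    )

    def test_tss_at_motif_center_distance_zero(self):
        s = make_score("p", "c", 0, 95)  # center = 95 + 5 = 100
        (link,) = ms.link_peaks_to_genes([s], self.TSS)
        assert (link.gene_id, link.distance, link.within_10kb) == ("gA", 0, True)

    def test_cap_is_inclusive_just_beyond_dropped(self):
        tss = pd.DataFrame({"chrom": ["c"], "pos": [100_101], "gene_id": ["g"]})
        s = make_score("p", "c", 0, 95)  # center 100 -> distance 100,001
        assert ms.link_peaks_to_genes([s], tss, max_dist=100_000) == []
        tss2 = pd.DataFrame({"chrom": ["c"], "pos": [100_100], "gene_id": ["g"]})
        assert len(ms.link_peaks_to_genes([s], tss2, max_dist=100_000)) == 1

    def test_tie_broken_by_smaller_gene_id(self):
        tss = pd.DataFrame(
            {"chrom": ["c", "c"], "pos": [90, 110], "gene_id": ["zz", "aa"]}
        )
        s = make_score("p", "c", 0, 95)  # center 100, both at distance 10
        (link,) = ms.link_peaks_to_genes([s], tss, max_dist=1000)
        assert link.gene_id == "aa"

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            scores = [
                make_score(f"p{i}", "c", int(rng.integers(0, 500_000)), 100)
                for i in range(3)
            ]
            tss = pd.DataFrame(
                {
                    "chrom": ["c"] * 4,
                    "pos": rng.integers(0, 500_000, 4),
                    "gene_id": [f"g{j}" for j in range(4)],
                }
            )
            links = {l.peak_id: l.gene_id for l in ms.link_peaks_to_genes(scores, tss)}
            for s in scores:
                center = s.hit.center_in(s.peak)
                dists = [(abs(int(p) - center), g) for p, g in zip(tss["pos"], tss["gene_id"])]
                best = min(dists)
                expect = sorted(g for d, g in dists if d == best[0])[0] if best[0] <= 100_000 else None
                assert links.get(s.peak.name) == expect

    def test_empty_tss_errors(self):
        with pytest.raises(ValueError, match="empty"):
            ms.link_peaks_to_genes([], pd.DataFrame(columns=["chrom", "pos", "gene_id"]))


class TestIntervalOps:
    def iv(self, s, e, chrom="c"):
        return ms.GenomicInterval(chrom, s, e)

    def test_disjoint_sets_no_responsive_elements(self):
        assert ms.define_responsive_elements([self.iv(0, 10)], [self.iv(20, 30)]) == []

    def test_bookended_intervals_do_not_overlap(self):
        assert ms.define_responsive_elements([self.iv(0, 10)], [self.iv(10, 20)]) == []

    def test_induced_requires_absence_at_baseline(self):
        p12 = [self.iv(0, 10), self.iv(100, 120)]
        p0 = [self.iv(5, 8)]
        assert ms.induced_peaks(p12, p0) == [self.iv(100, 120)]

    def test_responsive_elements_brute_force_toy(self):
        p65 = [self.iv(0, 10), self.iv(20, 30), self.iv(40, 60), self.iv(70, 80), self.iv(90, 95)]
        ac = [self.iv(8, 22), self.iv(59, 70)]
        got = ms.define_responsive_elements(p65, ac)
        expect = [p for p in p65 if any(p.start < a.end and a.start < p.end for a in ac)]
        assert got == expect == [self.iv(0, 10), self.iv(20, 30), self.iv(40, 60)]

    def test_identical_peaks_merge_to_one(self):
        merged = ms.merge_consensus_peaks([self.iv(0, 100)], [self.iv(0, 100)])
        assert merged == [self.iv(0, 100)]

    def test_overlapping_merge(self):
        merged = ms.merge_consensus_peaks([self.iv(0, 100)], [self.iv(50, 150)])
        assert merged == [self.iv(0, 150)]

    def test_bookended_merge(self):
        merged = ms.merge_intervals([self.iv(0, 10), self.iv(10, 20)])
        assert merged == [self.iv(0, 20)]

    def test_blacklist_removal_hand_evaluated(self):
        first = [self.iv(0, 100), self.iv(300, 400)]
        second = [self.iv(80, 150), self.iv(600, 700)]
        merged = ms.merge_consensus_peaks(first, second, blacklist=[self.iv(120, 130)])
        assert merged == [self.iv(300, 400), self.iv(600, 700)]


class TestScorePeakConsistency:
    def test_m_identity_and_bounds_on_simulated_data(self, toy_genome, meth_tables):
        t0, t12 = meth_tables
        scores = [
            ms.score_peak(toy_genome.sequence, p.interval, PWM, t0, t12)
            for p in toy_genome.peaks
        ]
        usable = [s for s in scores if s.has_data]
        assert usable
        for s in usable:
            assert s.m_t0 - s.delta_m == pytest.approx(s.m_t12)
            assert 0.0 <= s.m_t0 <= s.n_cpg_flank + 1e-9
            assert 0.0 <= s.m_t12 <= s.n_cpg_flank + 1e-9
            assert s.delta_m <= s.m_t0 + 1e-9

    def test_topq_recovers_separated_high_demethylation_peaks(self):
        low = [
            make_score(f"lo{i}", "c", i * 1000, 0, m_t0=5.0, m_t12=4.5, n_used=5)
            for i in range(6)
        ]
        high = [
            make_score(f"hi{i}", "c", 50_000 + i * 1000, 0, m_t0=5.0, m_t12=1.0, n_used=5)
            for i in range(2)
        ]
        groups = ms.demethylation_grouping(low + high, mode="topQ")
        top_ids = {s.peak.name for s in groups[GROUP_TOP_Q]}
        assert top_ids == {"hi0", "hi1"}
        mean_top = np.mean([s.delta_m for s in groups[GROUP_TOP_Q]])
        mean_rest = np.mean([s.delta_m for s in groups[GROUP_REST]])
        assert mean_top > mean_rest


class TestDemethylationProfile:
    def _scores_and_tables(self, seed=7):
        cfg = ms.SimulationConfig(seed=seed)
        genome = ms.simulate_toy_genome(cfg)
        t0, t12 = ms.simulate_methylation_dynamics(genome, cfg)
        scores = [
            ms.score_peak(genome.sequence, p.interval, PWM, t0, t12)
            for p in genome.peaks
        ]
        return scores, t0, t12

    def test_identical_tables_give_zero_difference_curve(self):
        scores, t0, _ = self._scores_and_tables()
        _, curves = ms.demethylation_profile(scores, t0, t0, window=400)
        assert np.allclose(curves["diff_smooth"], 0.0, atol=1e-12)

    def test_difference_curve_peaks_at_origin_and_decays(self):
        scores, t0, t12 = self._scores_and_tables()
        _, curves = ms.demethylation_profile(scores, t0, t12, window=400, grid_step=25)
        diff = curves["diff_smooth"].to_numpy()
        dist = curves["distance"].to_numpy()
        center_val = diff[np.abs(dist).argmin()]
        assert center_val == diff.max() or center_val >= 0.9 * diff.max()
        assert diff[np.abs(dist) <= 50].mean() > diff[np.abs(dist) >= 300].mean()

    def test_too_few_points_errors(self):
        scores, t0, t12 = self._scores_and_tables()
        with pytest.raises(ValueError, match="lowess"):
            ms.demethylation_profile(scores[:1], t0, t12, window=5)


class TestSignalTracks:
    def _track(self, chrom, values, bin_size=10):
        return pd.DataFrame(
            {
                "chrom": chrom,
                "start": np.arange(len(values)) * bin_size,
                "end": np.arange(len(values)) * bin_size + bin_size,
                "value": values,
            }
        )

    def test_identical_samples_unit_scale(self):
        track = self._track("c", [1.0, 2.0, 3.0, 2.0])
        anchors = [ms.GenomicInterval("c", 0, 40)]
        out = ms.normalize_signal({"a": track, "b": track.copy()}, anchors, 40)
        pd.testing.assert_frame_equal(out["a"], out["b"])

    def test_double_depth_sample_rescaled_to_equality(self):
        a = self._track("c", [1.0, 2.0, 3.0, 2.0])
        b = a.copy()
        b["value"] *= 2
        anchors = [ms.GenomicInterval("c", 0, 40)]
        out = ms.normalize_signal({"a": a, "b": b}, anchors, 40)
        assert np.allclose(out["a"]["value"], out["b"]["value"])

    def test_idempotent_fixed_point(self):
        a = self._track("c", [1.0, 2.0, 3.0, 2.0])
        b = self._track("c", [5.0, 1.0, 2.0, 8.0])
        anchors = [ms.GenomicInterval("c", 0, 40)]
        once = ms.normalize_signal({"a": a, "b": b}, anchors, 40)
        twice = ms.normalize_signal(once, anchors, 40)
        for k in once:
            assert np.allclose(once[k]["value"], twice[k]["value"])

    def test_zero_anchor_signal_errors(self):
        a = self._track("c", [0.0, 0.0, 1.0, 1.0])
        anchors = [ms.GenomicInterval("c", 0, 20)]
        with pytest.raises(ValueError, match="zero signal"):
            ms.normalize_signal({"a": a}, anchors, 40)

    def test_constant_track_flat_profile(self):
        track = self._track("c", [2.0] * 400, bin_size=10)
        s = make_score("p", "c", 1500, 195)  # center 1700
        prof = ms.aggregate_profile(track, [s], 4000, half_window=500, bin_size=25)
        assert np.allclose(prof["signal"], 2.0)

    def test_delta_signal_maximal_at_central_bin(self):
        values = np.zeros(400)
        values[170] = 10.0  # bases 1700-1710
        track = self._track("c", values, bin_size=10)
        s = make_score("p", "c", 1500, 195)  # center 1700
        prof = ms.aggregate_profile(track, [s], 4000, half_window=500, bin_size=25)
        assert prof.loc[prof["signal"].idxmax(), "offset"] in (-13, 12, -12, 13)

    def test_three_peak_brute_force_average(self):
        rng = np.random.default_rng(4)
        values = rng.random(800)
        track = self._track("c", values, bin_size=10)
        arr = np.repeat(values, 10)
        scores = [make_score(f"p{i}", "c", c - 300, 295) for i, c in enumerate([2000, 4000, 6000])]
        prof = ms.aggregate_profile(track, scores, 8000, half_window=500, bin_size=50)
        expect = np.mean(
            [arr[c - 500 : c + 500].reshape(20, 50).mean(axis=1) for c in [2000, 4000, 6000]],
            axis=0,
        )
        assert np.allclose(prof["signal"], expect)

    def test_uneven_bins_error(self):
        track = self._track("c", [1.0] * 10)
        with pytest.raises(ValueError, match="divide"):
            ms.aggregate_profile(track, [], 100, half_window=500, bin_size=33)


class TestErnaRpkm:
    def test_unit_arithmetic(self):
        counts = pd.DataFrame({"s1": [0, 100]}, index=["pA", "pB"])
        rpkm = ms.erna_rpkm(counts, {"pA": 1000, "pB": 1000}, {"s1": 1_000_000})
        assert rpkm.loc["pA", "s1"] == 0.0
        assert rpkm.loc["pB", "s1"] == pytest.approx(100.0)

    def test_doubling_library_halves_rpkm(self):
        counts = pd.DataFrame({"s1": [50], "s2": [50]}, index=["p"])
        rpkm = ms.erna_rpkm(counts, {"p": 500}, {"s1": 1e6, "s2": 2e6})
        assert rpkm.loc["p", "s1"] == pytest.approx(2 * rpkm.loc["p", "s2"])

    def test_zero_library_errors(self):
        counts = pd.DataFrame({"s1": [1]}, index=["p"])
        with pytest.raises(ValueError, match="library"):
            ms.erna_rpkm(counts, {"p": 100}, {"s1": 0})


class TestOccupancyChange:
    def test_equal_signals_unchanged(self):
        out = ms.occupancy_change({"p": 5.0}, {"p": 5.0})
        assert out["class"].tolist() == ["unchanged"]

    def test_exact_threshold_inclusive(self):
        out = ms.occupancy_change({"p": 2.0}, {"p": 3.0})  # exactly 1.5-fold
        assert out["class"].tolist() == ["higher_in_second"]

    def test_six_peak_hand_evaluation(self):
        first = {"a": 1.0, "b": 1.0, "c": 1.0, "d": 4.0, "e": 3.0, "f": 2.0}
        second = {"a": 2.0, "b": 1.4, "c": 1.0, "d": 1.0, "e": 2.1, "f": 3.1}
        out = ms.occupancy_change(first, second).set_index("peak_id")["class"]
        assert out["a"] == "higher_in_second"
        assert out["b"] == "unchanged"
        assert out["c"] == "unchanged"
        assert out["d"] == "lower_in_second"
        assert out["e"] == "unchanged"
        assert out["f"] == "higher_in_second"
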