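"""Site classification, chromosome metrics, thresholds and the window scan."""

import itertools
from math import isnan

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from updscreen.genotype_store import MISSING, trio_from_frame
from updscreen.upd_core import (
    CALL_AMBIGUOUS,
    CALL_HET_EXCESS,
    CALL_INSUFFICIENT,
    CALL_NONE,
    CALL_UPHD,
    CALL_UPID,
    ChromosomeStats,
    ClassifyThresholds,
    chromosome_stats,
    classify_chromosome,
    classify_site,
    disomy_direction,
    merge_windows,
    resolve_region,
    scan_partial,
)
from updscreen import trio_sim as ts

from conftest import make_trio, oracle_scan, oracle_site, random_trio_frame


class TestClassifySite:
    @pytest.mark.parametrize("gm,gf,gp", list(itertools.product([0, 1, 2], repeat=3)))
    def test_matches_transmission_oracle_on_all_triples(self, gm, gf, gp):
        got = classify_site(gm, gf, gp)
        informative, merror, match = oracle_site(gm, gf, gp)
        assert got.informative == informative
        assert got.mendelian_error == merror
        assert got.proband_match == match

    @pytest.mark.parametrize("triple", [
        (MISSING, 0, 2), (0, MISSING, 2), (0, 2, MISSING), (MISSING, MISSING, MISSING),
    ])
    def test_missing_genotypes_never_flag_errors(self, triple):
        got = classify_site(*triple)
        assert not got.mendelian_error
        if triple[0] == MISSING or triple[1] == MISSING:
            assert not got.informative
        if triple[2] == MISSING:
            assert got.proband_match == "not_applicable"

    def test_spec_entries(self):
        assert classify_site(0, 2, 1).proband_match == "biparental_het"
        assert not classify_site(0, 2, 1).mendelian_error
        got = classify_site(0, 2, 0)
        assert got.informative and got.mendelian_error and got.proband_match == "mother"
        got = classify_site(0, 0, 1)  # no parent carries the alternate allele
        assert got.mendelian_error and not got.informative


def _stats(chrom="7", n_nonmissing=2000, n_het=1000, n_informative=1000,
           n_ab=1000, n_mm=0, n_mf=0, n_err=0):
    return ChromosomeStats(chrom, n_nonmissing, n_het, n_informative,
                           n_ab, n_mm, n_mf, n_err)


class TestChromosomeStatsAndDirection:
    def test_fully_biparental_counting(self):
        s = _stats(n_informative=10, n_ab=10)
        assert s.pct_ab == 100.0
        assert s.skew == 0.0

    def test_mixed_counting(self):
        s = _stats(n_informative=10, n_ab=1, n_mm=9)
        assert s.pct_match_mother == 90.0
        assert s.pct_ab == 10.0

    def test_simulated_isodisomy_is_pure_maternal(self):
        trio, _, _ = make_trio({"1": ts.Event("upid_maternal")}, seed=10, n_sites=1500)
        s = chromosome_stats(trio, "1")
        assert s.pct_match_mother == 100.0
        assert s.pct_het == 0.0
        assert s.n_ab + s.n_match_mother + s.n_match_father == s.n_informative

    def test_zero_informative_gives_undefined_not_zero(self):
        trio = trio_from_frame(pd.DataFrame({
            "chrom": ["1"], "pos": [10], "ref": "A", "alt": "G", "af": [0.5],
            "gt_mother": [1], "gt_father": [1], "gt_proband": [1],
            "dp_mother": [30], "dp_father": [30], "dp_proband": [30],
            "gq_mother": [99], "gq_father": [99], "gq_proband": [99]}), "female")
        s = chromosome_stats(trio, "1")
        assert s.n_informative == 0
        assert isnan(s.pct_ab) and isnan(s.skew)
        with pytest.raises(ValueError, match="no informative sites"):
            disomy_direction(s)

    def test_direction_argmax_and_ties(self):
        parent, pct = disomy_direction(_stats(n_informative=10000, n_ab=1, n_mf=9999))
        assert parent == "father" and pct == pytest.approx(99.99)
        parent, _ = disomy_direction(_stats(n_informative=10, n_ab=2, n_mm=7, n_mf=1))
        assert parent == "mother"
        parent, pct = disomy_direction(_stats(n_informative=10, n_ab=10))
        assert parent == "undetermined" and pct == 0.0


class TestClassifyChromosome:
    def test_reported_isodisomy_profile(self):
        s = _stats(n_nonmissing=10000, n_het=10, n_informative=10000, n_ab=3, n_mm=9997)
        call = classify_chromosome(s)
        assert call.call == CALL_UPID and call.parent == "mother"
        assert s.skew == pytest.approx(99.97)

    def test_typical_biparental_is_none(self):
        s = _stats(n_nonmissing=2000, n_het=960, n_informative=1000,
                   n_ab=990, n_mm=5, n_mf=5)
        assert classify_chromosome(s).call == CALL_NONE

    def test_heterodisomy_profile(self):
        s = _stats(n_nonmissing=2000, n_het=700, n_informative=1000, n_ab=50, n_mf=950)
        call = classify_chromosome(s)
        assert call.call == CALL_UPHD and call.parent == "father"

    def test_threshold_boundaries_are_strict(self):
        # skew exactly 90 is not "> 90"
        s = _stats(n_nonmissing=2000, n_het=100, n_informative=1000, n_ab=100, n_mm=900)
        assert classify_chromosome(s).call == CALL_NONE
        # het exactly 10 is not "< 10": ambiguous zone
        s = _stats(n_nonmissing=2000, n_het=200, n_informative=1000, n_ab=50, n_mm=950)
        assert s.pct_het == 10.0
        assert classify_chromosome(s).call == CALL_AMBIGUOUS
        # het exactly 30 is not "> 30": still ambiguous
        s = _stats(n_nonmissing=2000, n_het=600, n_informative=1000, n_ab=50, n_mm=950)
        assert s.pct_het == 30.0
        assert classify_chromosome(s).call == CALL_AMBIGUOUS
        # just past the bounds
        s = _stats(n_nonmissing=2000, n_het=199, n_informative=1000, n_ab=50, n_mm=950)
        assert classify_chromosome(s).call == CALL_UPID
        s = _stats(n_nonmissing=2000, n_het=601, n_informative=1000, n_ab=50, n_mm=950)
        assert classify_chromosome(s).call == CALL_UPHD

    def test_floors_give_insufficient_data(self):
        s = _stats(n_nonmissing=999, n_het=0, n_informative=500, n_ab=0, n_mm=500)
        assert classify_chromosome(s).call == CALL_INSUFFICIENT
        s = _stats(n_nonmissing=2000, n_het=0, n_informative=199, n_ab=0, n_mm=199)
        assert classify_chromosome(s).call == CALL_INSUFFICIENT

    def test_male_x_is_never_called(self):
        s = _stats(chrom="X", n_nonmissing=5000, n_het=0, n_informative=2000,
                   n_ab=0, n_mm=2000)
        assert classify_chromosome(s, proband_sex="male").call == CALL_INSUFFICIENT
        assert classify_chromosome(s, proband_sex="female").call == CALL_UPID

    def test_het_excess_is_advisory_flag(self):
        s = _stats(n_nonmissing=2000, n_het=1500, n_informative=1000, n_ab=1000)
        call = classify_chromosome(s)
        assert call.call == CALL_HET_EXCESS and call.parent == "not_applicable"

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ClassifyThresholds(upid_het_max=40, uphd_het_min=30)
        with pytest.raises(ValueError):
            ClassifyThresholds(skew_min=50)


class TestScanPartial:
    def test_clean_biparental_chromosome_yields_nothing(self):
        trio, _, _ = make_trio(seed=30, n_sites=2000, chroms=("1",))
        assert scan_partial(trio, "1") == []

    def test_planted_segment_is_recovered(self):
        ev = ts.Event("partial_upid", parent="father", start=3_000_000, end=9_000_000)
        trio, _, _ = make_trio({"1": ev}, seed=31, n_sites=2000, chroms=("1",))
        windows = scan_partial(trio, "1")
        assert windows
        assert any(w.start < 9_000_000 and w.end > 3_000_000 for w in windows)
        merged = merge_windows(windows)
        # merged candidate overlaps the truth interval substantially
        inter = sum(max(0, min(e, 9_000_000) - max(s, 3_000_000)) for s, e in merged)
        union = sum(e - s for s, e in merged) + 6_000_000 - inter
        assert inter / union >= 0.5

    def test_min_errors_retention_threshold(self):
        ev = ts.Event("partial_upid", parent="father", start=3_000_000, end=9_000_000)
        trio, _, _ = make_trio({"1": ev}, seed=31, n_sites=2000, chroms=("1",))
        max_err = max(w.n_errors for w in scan_partial(trio, "1"))
        assert scan_partial(trio, "1", min_errors=max_err + 1) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(200, 2000))
        frame = random_trio_frame(rng, n)
        trio = trio_from_frame(frame, "female")
        min_err = int(rng.integers(1, 30))
        het_max = float(rng.uniform(5, 60))
        got = [(w.start, w.end, w.n_errors)
               for w in scan_partial(trio, "1", 5_000_000, min_err, het_max)]
        assert got == oracle_scan(frame, 5_000_000, min_err, het_max)

    def test_monotonicity_in_min_errors_and_het(self):
        rng = np.random.default_rng(77)
        trio = trio_from_frame(random_trio_frame(rng, 1500), "female")
        loose = {(w.start, w.end) for w in scan_partial(trio, "1", min_errors=5, het_max_pct=40)}
        stricter_err = {(w.start, w.end)
                        for w in scan_partial(trio, "1", min_errors=10, het_max_pct=40)}
        stricter_het = {(w.start, w.end)
                        for w in scan_partial(trio, "1", min_errors=5, het_max_pct=20)}
        assert stricter_err <= loose
        assert stricter_het <= loose


class TestMergeWindows:
    def test_overlap_union(self):
        assert merge_windows([(100, 5_000_100), (2_000_000, 7_000_000)]) == [(100, 7_000_000)]

    def test_disjoint_unchanged(self):
        assert merge_windows([(0, 10), (20, 30)]) == [(0, 10), (20, 30)]

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 60), st.integers(1, 40)), max_size=25))
    def test_union_preserved_and_idempotent(self, raw):
        ivs = [(s, s + l) for s, l in raw]
        merged = merge_windows(ivs)
        # oracle: union of covered integer points
        points = set()
        for s, e in ivs:
            points.update(range(s, e))
        covered = set()
        for s, e in merged:
            assert s < e
            covered.update(range(s, e))
        assert covered == points
        # disjoint, sorted, minimal; and idempotent
        for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
            assert e1 < s2
        assert merge_windows(merged) == merged


class TestResolveRegion:
    def _trio_with_depth(self, depth_in, n=200, start=1_000_000, end=6_000_000):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(np.arange(start, end), n, replace=False))
        return trio_from_frame(pd.DataFrame({
            "chrom": "4", "pos": pos, "ref": "A", "alt": "G", "af": 0.5,
            "gt_mother": 0, "gt_father": 2, "gt_proband": 0,
            "dp_mother": 30, "dp_father": 30, "dp_proband": depth_in,
            "gq_mother": 99, "gq_father": 99, "gq_proband": 99}), "female")

    def test_half_coverage_resolves_deletion(self):
        trio = self._trio_with_depth(15)
        r = resolve_region(trio, "4", (1_000_000, 6_000_000), genome_mean_depth=30.0)
        assert r.coverage_ratio == pytest.approx(0.5)
        assert r.resolution == "deletion"
        assert r.parent == "mother"  # proband matches the homref mother

    def test_full_coverage_resolves_partial_upd(self):
        trio = self._trio_with_depth(30)
        r = resolve_region(trio, "4", (1_000_000, 6_000_000), genome_mean_depth=30.0)
        assert r.coverage_ratio == pytest.approx(1.0)
        assert r.resolution == "partial_upd"

    def test_ratio_boundary_is_strict(self):
        r = resolve_region(self._trio_with_depth(27), "4",
                           (1_000_000, 6_000_000), genome_mean_depth=30.0)
        assert r.coverage_ratio == pytest.approx(0.9)
        assert r.resolution == "deletion"
        r = resolve_region(self._trio_with_depth(28), "4",
                           (1_000_000, 6_000_000), genome_mean_depth=30.0)
        assert r.resolution == "partial_upd"

    def test_region_without_depth_is_an_error(self):
        trio = self._trio_with_depth(30)
        with pytest.raises(ValueError, match="no proband depth"):
            resolve_region(trio, "4", (7_000_000, 8_000_000), genome_mean_depth=30.0)
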