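import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from intervaltree import IntervalTree

from editcall.lineage_wgs import (
    LINES,
    LineCall,
    LineageConfig,
    LineageError,
    VariantSite,
    apply_site_filters,
    assign_lineage,
    assign_lineages,
    coverage_windows,
    loh_runs,
    mutation_rate_per_passage,
    read_mask_bed,
)


def _site(depths, afs, gts=None, chrom="chr1", pos=100):
    if gts is None:
        gts = tuple("0/1" if af > 0 else "0/0" for af in afs)
    lines = {
        name: LineCall(depth=d, genotype=g, alt_af=af)
        for name, d, g, af in zip(LINES, depths, gts, afs)
    }
    return VariantSite(chrom=chrom, pos=pos, ref="A", alt="G", lines=lines)


class TestSiteFilters:
    def test_depth_below_corridor_removed(self):
        site = _site((29, 35, 40), (0.0, 0.5, 0.5))
        assert apply_site_filters([site], {}, LineageConfig()) == []

    def test_corridor_bounds_inclusive_and_spread_passing(self):
        site = _site((30, 50, 40), (0.0, 0.45, 0.50))
        kept = apply_site_filters([site], {}, LineageConfig())
        assert len(kept) == 1
        assert kept[0].filter_status == "pass"

    def test_low_af_spread_removed(self):
        site = _site((35, 40, 45), (0.40, 0.45, 0.50))
        assert apply_site_filters([site], {}, LineageConfig()) == []

    def test_masked_position_removed(self):
        site = _site((35, 40, 45), (0.0, 0.5, 0.5), pos=100)
        tree = IntervalTree()
        tree.addi(90, 110)
        assert apply_site_filters([site], {"chr1": tree}, LineageConfig()) == []

    @given(
        depths=st.tuples(*[st.integers(10, 70)] * 3),
        afs=st.tuples(*[st.floats(0, 1, allow_nan=False)] * 3),
        narrow=st.tuples(st.integers(30, 40), st.integers(40, 50)),
        spread=st.floats(0.1, 0.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_widening_filters_never_loses_sites(self, depths, afs, narrow, spread):
        site = _site(depths, afs)
        strict = LineageConfig(cov_min=narrow[0], cov_max=narrow[1], af_spread_min=spread)
        loose = LineageConfig(
            cov_min=narrow[0] - 5, cov_max=narrow[1] + 5, af_spread_min=spread / 2
        )
        kept_strict = apply_site_filters([site], {}, strict)
        kept_loose = apply_site_filters([site], {}, loose)
        assert len(kept_loose) >= len(kept_strict)


class TestAssignLineage:
    def test_wt_era_pattern(self):
        site = _site((40, 40, 40), (0.0, 0.5, 0.5), gts=("0/0", "0/1", "0/1"))
        assert assign_lineage(site) == "wt_era"

    def test_kr_era_pattern(self):
        site = _site((40, 40, 40), (0.0, 0.0, 0.5), gts=("0/0", "0/0", "0/1"))
        assert assign_lineage(site) == "kr_era"

    def test_ancestral_pattern(self):
        site = _site((40, 40, 40), (0.5, 0.5, 0.5), gts=("0/1", "0/1", "0/1"))
        assert assign_lineage(site) == "ancestral"

    def test_other_patterns_unassigned(self):
        # alt lost in the last clone: not a forward-lineage pattern
        site = _site((40, 40, 40), (0.5, 0.5, 0.0), gts=("0/1", "0/1", "0/0"))
        assert assign_lineage(site) == "unassigned"

    def test_labels_partition_filtered_sites(self):
        sites = [
            _site((40, 40, 40), (0.0, 0.5, 0.5), gts=("0/0", "0/1", "0/1"), pos=p)
            for p in range(0, 500, 100)
        ]
        annotated, counts = assign_lineages(sites)
        assert sum(counts.values()) == len(annotated) == len(sites)


class TestCoverageWindows:
    def test_uniform_depth_unmasked(self):
        records = [("chr1", 0, 1_000_000, 30.0)]
        table = coverage_windows(records, {}, window_bp=1_000_000)
        assert table.loc[0, "mean_depth"] == pytest.approx(30.0)

    def test_fully_masked_window_missing(self):
        tree = IntervalTree()
        tree.addi(0, 1_000_000)
        records = [("chr1", 0, 1_000_000, 30.0)]
        table = coverage_windows(records, {"chr1": tree}, window_bp=1_000_000)
        assert math.isnan(table.loc[0, "mean_depth"])

    def test_half_masked_window_uses_unmasked_denominator(self):
        tree = IntervalTree()
        tree.addi(0, 500_000)
        records = [("chr1", 500_000, 1_000_000, 20.0)]
        table = coverage_windows(records, {"chr1": tree}, window_bp=1_000_000)
        assert table.loc[0, "mean_depth"] == pytest.approx(20.0)

    def test_multiple_windows_split_correctly(self):
        records = [("chr1", 0, 1_500_000, 10.0), ("chr1", 1_500_000, 2_000_000, 30.0)]
        table = coverage_windows(records, {}, window_bp=1_000_000)
        assert table.loc[0, "mean_depth"] == pytest.approx(10.0)
        assert table.loc[1, "mean_depth"] == pytest.approx(20.0)


class TestMutationRate:
    def test_zero_novel_variants(self):
        assert mutation_rate_per_passage(0, 10, 62.1e6, 3.2e9) == 0.0

    def test_wt_era_rate(self):
        rate = mutation_rate_per_passage(19, 48, 62.1e6, 3.2e9)
        assert rate == pytest.approx(20.4, abs=0.05)

    def test_kr_era_rate(self):
        rate = mutation_rate_per_passage(3, 24, 62.1e6, 3.2e9)
        assert rate == pytest.approx(6.4, abs=0.05)

    def test_invalid_inputs(self):
        with pytest.raises(LineageError):
            mutation_rate_per_passage(1, 0, 62.1e6, 3.2e9)
        with pytest.raises(LineageError):
            mutation_rate_per_passage(1, 10, 0, 3.2e9)


class TestMaskBed:
    def test_round_trip_and_errors(self, tmp_path):
        bed = tmp_path / "mask.bed"
        bed.write_text("chr1\t100\t200\nchr2\t0\t50\n")
        masks = read_mask_bed(bed)
        assert masks["chr1"].overlaps(150)
        assert not masks["chr1"].overlaps(250)
        bad = tmp_path / "bad.bed"
        bad.write_text("chr1\t100\n")
        with pytest.raises(LineageError, match="bad.bed:1"):
            read_mask_bed(bad)


class TestLohRuns:
    def test_detects_run_of_converted_heterozygosity(self):
        def loh_site(pos):
            return _site((40, 40, 40), (0.5, 1.0, 1.0), gts=("0/1", "1/1", "1/1"), pos=pos)

        def het_site(pos):
            return _site((40, 40, 40), (0.5, 0.5, 0.5), gts=("0/1", "0/1", "0/1"), pos=pos)

        sites = [loh_site(p) for p in range(0, 50, 10)] + [het_site(60), loh_site(70)]
        runs = loh_runs(sites, min_run=3)
        assert len(runs) == 1
        assert runs[0]["n_sites"] == 5


class TestPlantedRecovery:
    def test_exact_recovery_of_planted_lineage_counts(self):
        from editcall.synthetic_data import simulate_lineage_sites

        sites, masks, truth = simulate_lineage_sites(
            n_ancestral=10, n_wt_era=5, n_kr_era=3, n_noise=50, seed=17
        )
        kept = apply_site_filters(sites, masks, LineageConfig())
        _, counts = assign_lineages(kept)
        assert counts == {"ancestral": 10, "wt_era": 5, "kr_era": 3, "unassigned": 0}
        assert len(kept) == 18

    def test_recovery_through_vcf_and_bed_boundary(self, tmp_path):
        from editcall.io import write_bed
        from editcall.lineage_wgs import read_sites_vcf
        from editcall.synthetic_data import simulate_lineage_sites, write_lineage_vcf

        sites, masks, _ = simulate_lineage_sites(
            n_ancestral=4, n_wt_era=5, n_kr_era=3, n_noise=12, seed=23
        )
        vcf = tmp_path / "sites.vcf"
        bed = tmp_path / "mask.bed"
        write_lineage_vcf(sites, str(vcf))
        write_bed(
            [("chr1", iv.begin, iv.end) for iv in sorted(masks.get("chr1", IntervalTree()))],
            bed,
        )
        reloaded = read_sites_vcf(vcf)
        assert len(reloaded) == len(sites)
        kept = apply_site_filters(reloaded, read_mask_bed(bed), LineageConfig())
        _, counts = assign_lineages(kept)
        assert counts["wt_era"] == 5
        assert counts["kr_era"] == 3
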