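"""Mendelian-error classification, homozygosity windows, isodisomy calling
and runs-of-homozygosity scanning."""
import itertools

import numpy as np
import pytest

from epitrio.upd_roh import (
    ROHConfig,
    UPDConfig,
    call_isodisomy,
    check_mendelian,
    find_roh,
    homozygosity_windows,
    _roh_informative,
)

from helpers import GT_CLASSES, make_trio, mendelian_oracle


class TestCheckMendelian:
    def test_duplicated_paternal_allele(self):
        """child 1/1, father 0/1, mother 0/0: impossible biparentally,
        explicable by the father's alt twice."""
        chk = check_mendelian(make_trio("hom_alt", "het", "hom_ref"))
        assert chk.status == "inconsistent"
        assert chk.parent_support == "paternal_only"

    def test_ordinary_inheritance_is_consistent(self):
        chk = check_mendelian(make_trio("het", "het", "hom_ref"))
        assert chk.status == "consistent"

    def test_missing_genotype_is_uninformative(self):
        assert check_mendelian(make_trio("het", "missing", "hom_ref")).status == "uninformative"

    def test_monomorphic_trio_is_uninformative(self):
        assert check_mendelian(make_trio("hom_ref", "hom_ref", "hom_ref")).status == "uninformative"

    def test_all_27_configurations_match_transmission_oracle(self):
        """Exhaustive enumeration of one-allele-per-parent transmissions."""
        for c, f, m in itertools.product(GT_CLASSES, repeat=3):
            chk = check_mendelian(make_trio(c, f, m))
            status, support = mendelian_oracle(c, f, m)
            assert chk.status == status, (c, f, m)
            if status != "uninformative":
                assert chk.parent_support == support, (c, f, m)

    def test_hemizygous_male_x_cases(self):
        """A son's X comes from his mother: father's genotype cannot rescue."""
        # child hemi alt, mother hom-ref, father alt: inconsistent, paternal-only support
        rec = make_trio("hom_alt", "hom_alt", "hom_ref", chrom="chrX", hemizygous=True)
        chk = check_mendelian(rec)
        assert chk.status == "inconsistent"
        assert chk.parent_support == "paternal_only"
        # child hemi alt, mother het: consistent
        rec = make_trio("hom_alt", "hom_ref", "het", chrom="chrX", hemizygous=True)
        assert check_mendelian(rec).status == "consistent"


class TestHomozygosityWindows:
    def test_all_hom_window(self):
        recs = [make_trio("hom_alt", "het", "het", pos=1000 + i * 100) for i in range(40)]
        windows = homozygosity_windows(recs, window_bp=500_000)
        assert windows == [(1000, 1.0)]

    def test_empty_window_gets_missing_marker_not_zero(self):
        """A coverage gap (centromere) must be None, not 0.0."""
        recs = [make_trio("het", "het", "hom_ref", pos=p) for p in (1_000, 1_200_000)]
        windows = homozygosity_windows(recs, window_bp=500_000)
        assert len(windows) == 3
        assert windows[0][1] == 0.0
        assert windows[1][1] is None
        assert windows[2][1] == 0.0

    def test_hom_ref_child_calls_are_uninformative(self):
        recs = [make_trio("hom_ref", "het", "het", pos=1000 + i) for i in range(10)]
        assert homozygosity_windows(recs)[0][1] is None

    def test_random_track_matches_per_window_recount_oracle(self):
        rng = np.random.default_rng(6)
        gts = ["hom_ref", "het", "hom_alt"]
        recs = [
            make_trio(gts[int(rng.integers(0, 3))], "het", "het", pos=int(p))
            for p in np.sort(rng.choice(2_000_000, 500, replace=False) + 1)
        ]
        window = 100_000
        windows = homozygosity_windows(recs, window_bp=window)
        origin = recs[0].site.pos
        for start, frac in windows:
            in_win = [r for r in recs if start <= r.site.pos < start + window]
            hom = sum(r.child.gt_class == "hom_alt" for r in in_win)
            informative = sum(r.child.gt_class in ("het", "hom_alt") for r in in_win)
            if informative == 0:
                assert frac is None
            else:
                assert frac == pytest.approx(hom / informative)
        assert windows[0][0] == origin

    def test_order_invariance_after_sorting(self):
        rng = np.random.default_rng(8)
        recs = [
            make_trio("het" if rng.random() < 0.5 else "hom_alt", "het", "het", pos=int(p))
            for p in rng.choice(1_000_000, 200, replace=False) + 1
        ]
        shuffled = list(recs)
        rng.shuffle(shuffled)
        assert homozygosity_windows(recs) == homozygosity_windows(shuffled)


class TestCallIsodisomy:
    def test_planted_paternal_isodisomy_with_error(self, sim_upd_err):
        by_chrom = {}
        for r in sim_upd_err.records:
            by_chrom.setdefault(r.site.chrom, []).append(r)
        report = call_isodisomy("chr9", by_chrom["chr9"])
        assert report.verdict == "paternal_isodisomy"
        assert report.paternal_support_fraction >= 0.95
        assert report.median_window_hom >= 0.98
        assert report.n_inconsistent >= 50

    def test_biparental_chromosomes_yield_none(self, sim_upd_err):
        by_chrom = {}
        for r in sim_upd_err.records:
            by_chrom.setdefault(r.site.chrom, []).append(r)
        for chrom, recs in by_chrom.items():
            if chrom in ("chr9", "chrX"):
                continue
            assert call_isodisomy(chrom, recs).verdict == "none", chrom

    def test_too_few_sites_is_insufficient_data(self):
        recs = [make_trio("hom_alt", "het", "hom_ref", pos=1000 + i) for i in range(10)]
        report = call_isodisomy("chr5", recs)
        assert report.verdict == "none"
        assert report.note == "insufficient data"

    def test_maternal_case_is_symmetric(self):
        from epitrio.synthetic_data import SimulationConfig, simulate_trio

        sim = simulate_trio(
            SimulationConfig(
                seed=303,
                chrom_lengths={"chr7": 3_000_000},
                upd_chrom="chr7",
                upd_parent="mother",
            )
        )
        report = call_isodisomy("chr7", sim.records)
        assert report.verdict == "maternal_isodisomy"
        assert report.maternal_support_fraction >= 0.95


class TestFindROH:
    def test_fully_heterozygous_chromosome_empty(self):
        recs = [make_trio("het", "het", "hom_ref", pos=1 + i * 1000) for i in range(3000)]
        assert find_roh(recs) == []

    def test_whole_chromosome_homozygosity_single_segment(self, sim_upd_err):
        """Degenerate ROH = isodisomy: segments cover the variant span."""
        recs = [make_trio("hom_alt", "het", "hom_ref", pos=1 + i * 2_000) for i in range(2500)]
        segs = find_roh(recs)
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (1, 1 + 2499 * 2_000)
        # same on the simulated isodisomy chromosome, up to error-induced splits
        chr9 = [r for r in sim_upd_err.records if r.site.chrom == "chr9"]
        segs = find_roh(chr9)
        informative = sorted(r.site.pos for r in chr9 if _roh_informative(r) is not None)
        covered = sum(len(s) for s in segs)
        assert covered >= 0.8 * (informative[-1] - informative[0])

    def test_planted_2mb_segment_recovered_within_one_gap(self, sim_roh):
        """Boundary error smaller than the local inter-variant spacing."""
        truth = sim_roh.truth.roh[0]
        segs = find_roh(sim_roh.records, ROHConfig(het_tolerance=0))
        assert len(segs) == 1
        seg = segs[0]
        pos = [r.site.pos for r in sim_roh.records if _roh_informative(r) is not None]
        inside = [p for p in pos if truth["start"] <= p < truth["end"]]
        import bisect

        # local spacing = gap between the informative calls flanking each truth boundary
        i = bisect.bisect_left(pos, inside[0])
        left_gap = pos[i] - pos[i - 1] if i > 0 else pos[0]
        j = bisect.bisect_right(pos, inside[-1]) - 1
        right_gap = pos[j + 1] - pos[j] if j + 1 < len(pos) else 10**9
        assert abs(seg.start - inside[0]) < max(left_gap, 1)
        assert abs(seg.end - inside[-1]) < max(right_gap, 1)

    def test_segments_nonoverlapping_and_flanked_by_hets(self, sim_err):
        by_chrom = {}
        for r in sim_err.records:
            by_chrom.setdefault(r.site.chrom, []).append(r)
        cfg = ROHConfig(min_length_bp=200_000, het_tolerance=2)
        for chrom, recs in by_chrom.items():
            calls = [
                (r.site.pos, r.child.gt_class == "het")
                for r in sorted(recs, key=lambda x: x.site.pos)
                if _roh_informative(r) is not None
            ]
            pos = [p for p, _ in calls]
            segs = find_roh(recs, cfg)
            prev_end = -1
            for seg in segs:
                assert seg.start > prev_end  # non-overlapping, ordered
                prev_end = seg.end
                assert seg.n_het_tolerated <= cfg.het_tolerance
                assert seg.end - seg.start >= cfg.min_length_bp
                # boundaries trimmed to homozygous calls
                import bisect

                i = bisect.bisect_left(pos, seg.start)
                assert pos[i] == seg.start and not calls[i][1]
                j = bisect.bisect_left(pos, seg.end)
                assert pos[j] == seg.end and not calls[j][1]

    def test_het_tolerance_bridges_isolated_hets(self):
        gts = ["hom_alt"] * 2000
        gts[800] = "het"
        gts[1200] = "het"
        recs = [make_trio(g, "het", "het", pos=1 + i * 1000) for i, g in enumerate(gts)]
        segs = find_roh(recs, ROHConfig(min_length_bp=1_000_000, het_tolerance=2))
        assert len(segs) == 1
        assert segs[0].n_het_tolerated == 2
        segs0 = find_roh(recs, ROHConfig(min_length_bp=300_000, het_tolerance=0))
        assert len(segs0) == 3


class TestUPDConfigThresholds:
    def test_support_threshold_blocks_mixed_errors(self):
        """Inconsistencies split between parents must not produce a verdict."""
        recs = []
        # chromosome-wide hom-alt child; alternate which parent could explain
        for i in range(400):
            if i % 2:
                recs.append(make_trio("hom_alt", "het", "hom_ref", pos=1 + i * 5_000))
            else:
                recs.append(make_trio("hom_alt", "hom_ref", "het", pos=1 + i * 5_000))
        report = call_isodisomy("chr3", recs, UPDConfig(min_informative_sites=100))
        assert report.median_window_hom == 1.0
        assert report.verdict == "none"  # support split ~50/50
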