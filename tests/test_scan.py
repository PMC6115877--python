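"""Window construction, the three filter stages, and scan determinism."""

import numpy as np
import pytest

import introscan as I
from introscan.scan import (
    IntrogressedRegion,
    ScaffoldBackground,
    SignificanceCriteria,
    WindowStats,
    clade_summary,
    scaffold_background,
    stage1_d_filter,
    stage2_fd_filter,
    stage3_dxy_filter,
    windows_to_dataframe,
    write_regions_bed,
    write_window_tsv,
)
from introscan.simulate import polarized_tables, read_bed
from introscan.stats import DResult, DxyResult, FdResult, PatternWeights


def table(scaffold="sc1", length=12_000, positions=(), freqs=None):
    positions = np.asarray(positions, dtype=np.int64)
    if freqs is None:
        freqs = np.tile([0.0, 1.0, 1.0, 0.0], (len(positions), 1))
    return I.PolarizedSiteTable(scaffold, length, positions, freqs)


class TestMakeWindows:
    def test_tumbling_with_partial_terminal(self):
        w = I.make_windows(table(), I.WindowSpec(5_000))
        assert [(x.start, x.end) for x in w] == [(0, 5000), (5000, 10000), (10000, 12000)]
        assert [x.partial for x in w] == [False, False, True]

    def test_empty_scaffold_still_windows(self):
        w = I.make_windows(table(), I.WindowSpec(5_000))
        assert all(x.n_sites == 0 for x in w)

    def test_sliding_overlap(self):
        w = I.make_windows(table(length=10_000), I.WindowSpec(5_000, 2_500))
        assert [(x.start, x.end) for x in w] == [
            (0, 5000), (2500, 7500), (5000, 10000), (7500, 10000)
        ]

    def test_site_assignment_uses_zero_based_coordinate(self):
        # pos 5000 has 0-based coordinate 4999 -> first window only
        t = table(positions=[5000, 5001])
        w = I.make_windows(t, I.WindowSpec(5_000))
        assert [x.n_sites for x in w] == [1, 1, 0]

    def test_coverage_count_under_sliding(self):
        t = table(length=20_000, positions=list(range(5001, 15000, 37)))
        w = I.make_windows(t, I.WindowSpec(5_000, 2_500))
        counts = np.zeros(t.n_sites, dtype=int)
        for x in w:
            lo, hi = x.site_slice
            counts[lo:hi] += 1
        # interior sites fall in size/step = 2 windows
        assert np.all(counts == 2)

    def test_window_spec_validation(self):
        with pytest.raises(ValueError):
            I.WindowSpec(5_000, 6_000)
        with pytest.raises(ValueError):
            I.WindowSpec(5_000, 0)


def fake_window(d=None, p=None, gap=0.0, fd=None, dxy_val=None, scaffold="sc1",
                start=0, end=5_000, partial=False):
    abba = gap if (d or 0) >= 0 else 0.0
    baba = 0.0 if (d or 0) >= 0 else gap
    weights = PatternWeights(abba=abba, baba=baba, n_informative=int(gap))
    return WindowStats(
        scaffold=scaffold, start=start, end=end,
        n_sites=int(gap), weights=weights,
        d_result=DResult(d=d, weights=weights, se=0.1 if p is not None else None,
                         z=None, p=p),
        fd_result=FdResult(s_num=1.0 if fd is not None else -1.0,
                           s_den=1.0, fd=fd),
        dxy_result=DxyResult(dxy=dxy_val, n_sites=end - start),
        partial=partial,
    )


class TestStage1:
    crit = SignificanceCriteria()

    def test_zero_d_rejected(self):
        assert stage1_d_filter([fake_window(d=0.0, p=1e-9, gap=50)], self.crit) == []

    def test_all_criteria_met_retained(self):
        w = fake_window(d=0.9, p=1e-5, gap=50)
        assert stage1_d_filter([w], self.crit) == [w]
        assert w.passed("d_significance")

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(d=0.9, p=1e-5, gap=5),     # gap too small
            dict(d=0.5, p=1e-5, gap=50),    # |D| below floor
            dict(d=0.9, p=0.01, gap=50),    # p above threshold
            dict(d=None, p=None, gap=0),    # undefined D never passes
        ],
    )
    def test_single_criterion_failures(self, kwargs):
        assert stage1_d_filter([fake_window(**kwargs)], self.crit) == []

    def test_negative_d_passes_on_magnitude(self):
        w = fake_window(d=-0.9, p=1e-5, gap=50)
        assert stage1_d_filter([w], self.crit) == [w]


class TestStage2:
    crit = SignificanceCriteria()

    def test_percentile_on_arithmetic_sequence(self):
        wins = [fake_window(fd=0.01 * k) for k in range(1, 101)]
        cutoff = np.percentile([0.01 * k for k in range(1, 101)], 90)
        kept = stage2_fd_filter(wins, wins, self.crit)
        assert {w.fd_result.fd for w in kept} == {
            0.01 * k for k in range(1, 101) if 0.01 * k >= cutoff
        }
        assert len(kept) == 10  # linear-interpolation cutoff 0.901 -> k = 91..100

    def test_ties_all_kept(self):
        wins = [fake_window(fd=0.5) for _ in range(10)]
        assert len(stage2_fd_filter(wins, wins, self.crit)) == 10

    def test_undefined_fd_excluded(self):
        wins = [fake_window(fd=0.9), fake_window(fd=None)]
        kept = stage2_fd_filter(wins, wins, self.crit)
        assert len(kept) == 1 and kept[0].fd_result.fd == 0.9

    def test_no_defined_fd_is_an_error(self):
        wins = [fake_window(fd=None)]
        with pytest.raises(RuntimeError, match="f_d"):
            stage2_fd_filter(wins, wins, self.crit)


class TestStage3:
    crit = SignificanceCriteria()
    bg = {"sc1": ScaffoldBackground("sc1", mean_dxy=0.05, se=0.005, n_windows=50)}

    def complete(self, w):
        w.stage_flags["d_significance"] = True
        w.stage_flags["fd_top_percentile"] = True
        return w

    def test_window_at_mean_rejected(self):
        w = self.complete(fake_window(d=0.9, p=1e-5, gap=50, fd=1.0, dxy_val=0.05))
        assert stage3_dxy_filter([w], self.bg, self.crit) == []
        assert w.dxy_p == pytest.approx(0.5)

    def test_extreme_reduction_retained(self):
        w = self.complete(fake_window(d=0.9, p=1e-5, gap=50, fd=1.0, dxy_val=0.0))
        (region,) = stage3_dxy_filter([w], self.bg, self.crit)
        assert isinstance(region, IntrogressedRegion)
        assert w.dxy_z == pytest.approx(-10.0)

    def test_unusable_background_drops_with_flag(self):
        w = self.complete(fake_window(d=0.9, p=1e-5, gap=50, fd=1.0, dxy_val=0.0))
        bad = {"sc1": ScaffoldBackground("sc1", 0.05, 0.0, 1)}
        assert stage3_dxy_filter([w], bad, self.crit) == []
        assert w.stage_flags["dxy_background_unusable"]

    def test_region_requires_all_stages(self):
        w = fake_window(d=0.9, p=1e-5, gap=50)
        with pytest.raises(ValueError):
            IntrogressedRegion(window=w)


class TestBackground:
    def test_partial_windows_excluded(self):
        wins = [fake_window(dxy_val=0.04), fake_window(dxy_val=0.06),
                fake_window(dxy_val=0.5, partial=True)]
        bg = scaffold_background(wins, "sc1")
        assert bg.mean_dxy == pytest.approx(0.05)
        assert bg.n_windows == 2

    def test_single_window_unusable(self):
        bg = scaffold_background([fake_window(dxy_val=0.04)], "sc1")
        assert not bg.usable


class TestEndToEnd:
    def test_cascade_is_monotone(self, default_scan):
        all_iv = {w.interval for w in default_scan.windows}
        s1 = {w.interval for w in default_scan.stage1}
        s2 = {w.interval for w in default_scan.stage2}
        s3 = {r.interval for r in default_scan.regions}
        assert s3 <= s2 <= s1 <= all_iv

    def test_attrition_counts_non_increasing(self, default_scan):
        a = default_scan.attrition
        vals = [a["windows_tested"], a["stage1_d_significant"],
                a["stage2_fd_retained"], a["stage3_dxy_regions"]]
        assert vals == sorted(vals, reverse=True)

    def test_outputs_byte_identical_across_runs(self, default_tables, tmp_path):
        paths = []
        for run in ("a", "b"):
            res = I.run_scan(default_tables, I.WindowSpec(5_000))
            tsv, bed = tmp_path / f"w_{run}.tsv", tmp_path / f"r_{run}.bed"
            write_window_tsv(res.windows, tsv)
            write_regions_bed(res.regions, bed)
            paths.append((tsv.read_bytes(), bed.read_bytes()))
        assert paths[0] == paths[1]

    def test_regions_bed_round_trips(self, default_scan, tmp_path):
        bed = tmp_path / "regions.bed"
        write_regions_bed(default_scan.regions, bed)
        back = read_bed(bed)
        assert [(r[0], r[1], r[2]) for r in back] == [
            r.interval for r in default_scan.regions
        ]

    def test_window_tsv_schema(self, default_scan):
        df = windows_to_dataframe(default_scan.windows)
        assert list(df.columns) == [
            "scaffold", "start", "end", "n_sites", "abba", "baba", "D",
            "se", "z", "p", "fd", "dxy", "stage_flags",
        ]
        assert len(df) == len(default_scan.windows)


class TestCladeSummary:
    def wins(self, n_sig, n_total):
        out = []
        for i in range(n_total):
            w = fake_window(d=0.9, p=1e-5, gap=50, start=i * 500_000,
                            end=(i + 1) * 500_000)
            w.stage_flags["d_significance"] = i < n_sig
            out.append(w)
        return out

    def test_zero_significant(self):
        df = clade_summary({"q1": self.wins(0, 100)})
        assert df.loc[0, "fraction"] == 0.0

    def test_two_quartets_two_rows(self):
        df = clade_summary({"q1": self.wins(3, 10), "q2": self.wins(1, 10)})
        assert len(df) == 2
        assert df.set_index("quartet").loc["q1", "n_windows_significant"] == 3

    def test_null_simulation_fraction_small(self):
        """500-kb adjacent windows on null genomes show close-to-nominal
        D-significance incidence."""
        from introscan.simulate import null_config

        wins = []
        for seed in range(1, 11):
            res = I.simulate(null_config(seed=seed))
            scan = I.run_scan(polarized_tables(res), I.WindowSpec(500_000))
            wins.extend(scan.windows)
        df = clade_summary({"null": wins})
        assert df.loc[0, "n_windows_tested"] == 20
        assert df.loc[0, "fraction"] <= 0.05
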