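"""Breakpoint regression, Gaussian width, origin localisation, reports."""

import dataclasses

import numpy as np
import pytest

from mfaterm import (
    BreakpointRegression,
    FitError,
    GenomeMap,
    Locus,
    Origin,
    Replicon,
    ReplicationParameters,
    S95_FACTOR,
    SyntheticSpec,
    expected_profile,
    fit_breakpoint,
    fit_gaussian_width,
    localize_origin,
    normalize_profiles,
    sample_counts,
    segment_report,
    segments_between,
    slope_asymmetry,
    terminal_fit,
    termination_synchrony,
    trim_outlier_bins,
)
from mfaterm.fit import _ols_line

from conftest import make_segment_dataset


def exhaustive_grid_oracle(x, y, min_side=5, exclude=5):
    """Naive per-candidate polyfit scan; independent of the prefix-sum path."""
    best = (np.inf, None)
    n = len(x)
    lo = max(exclude, min_side - 1)
    for k in range(lo, n - lo):
        ls, li, sl = _naive_line(x[: k + 1], y[: k + 1])
        rs, ri, sr = _naive_line(x[k:], y[k:])
        if sl + sr < best[0]:
            best = (sl + sr, x[k])
    return best


def _naive_line(x, y):
    slope, intercept = np.polyfit(x, y, 1)
    r = y - (slope * x + intercept)
    return slope, intercept, float(r @ r)


class TestBreakpointRegression:
    def test_noiseless_exact_recovery(self):
        x = np.arange(500.0, 1_000_000.0, 1000.0)
        bp = x[300]  # break exactly at a candidate
        y = np.where(x <= bp, 2.0 - 1e-6 * x, 2.0 - 2e-6 * bp + 1e-6 * x)
        est = BreakpointRegression().fit(x[:, None], y)
        assert est.breakpoint_ == bp
        assert est.left_slope_ == pytest.approx(-1e-6, abs=1e-15)
        assert est.right_slope_ == pytest.approx(1e-6, abs=1e-15)
        assert est.sse_ < 1e-18

    def test_matches_exhaustive_oracle_on_noise(self):
        rng = np.random.default_rng(11)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = np.arange(500.0, 200_000.0, 1000.0)
            y = -np.abs(x - 77_500.0) * 2e-6 + rng.normal(0, 0.05, len(x))
            est = BreakpointRegression(exclude_edge=5).fit(x[:, None], y)
            sse_oracle, bp_oracle = exhaustive_grid_oracle(x, y)
            assert est.breakpoint_ == bp_oracle
            assert est.sse_ == pytest.approx(sse_oracle, rel=1e-9)

    def test_too_few_points_rejected(self):
        x = np.arange(8.0)
        with pytest.raises(FitError, match="too few"):
            BreakpointRegression().fit(x[:, None], x)

    def test_sklearn_params_roundtrip(self):
        est = BreakpointRegression(min_side_points=7)
        assert est.get_params()["min_side_points"] == 7
        est.set_params(exclude_edge=3)
        assert est.exclude_edge == 3


class TestFitBreakpoint:
    def test_noiseless_piecewise_recovered_to_half_bin(self, noiseless_v_profile):
        exp, segs = noiseless_v_profile
        for seg in segs:
            f = fit_breakpoint(exp, seg)
            true_arc = seg.arc_length / 2.0
            assert abs(f.fcp_arc - true_arc) <= exp.bin_size / 2
            assert abs(f.left_slope) == pytest.approx(1 / (30_000 * 40), abs=1e-9)
            assert abs(f.right_slope) == pytest.approx(1 / (30_000 * 40), abs=1e-9)
            assert f.left_slope < 0 < f.right_slope
            assert f.fcp_mp_pct == pytest.approx(0.0, abs=0.1)

    def test_symmetric_v_fcp_equals_midpoint(self, noiseless_v_profile):
        exp, segs = noiseless_v_profile
        f = fit_breakpoint(exp, segs[0])
        assert abs(f.fcp_mp_bp) <= exp.bin_size / 2

    def test_reflection_symmetry(self, two_origin_genome):
        genome, origins, params = two_origin_genome
        _, prof = make_segment_dataset(genome, origins, params,
                                       mean_depth=200.0, seed=5)
        seg = segments_between(origins, genome.replicon("c"))[0]
        f = fit_breakpoint(prof, seg)
        mirrored = dataclasses.replace(prof)
        # mirror the profile about the segment midpoint (bins 0..999)
        m = np.arange(prof.n_bins)
        sel = m < 1000
        for arr in (mirrored.mf, mirrored.log2mf):
            arr[sel] = arr[sel][::-1]
        mirrored.mask[sel] = mirrored.mask[sel][::-1]
        g = fit_breakpoint(mirrored, seg)
        assert abs((seg.arc_length - f.fcp_arc) - g.fcp_arc) <= prof.bin_size

    def test_short_arc_rejected(self, noiseless_v_profile):
        exp, segs = noiseless_v_profile
        rep = segs[0].replicon
        tiny = dataclasses.replace(segs[0], arc_length=5000)
        with pytest.raises(FitError, match="10 bins"):
            fit_breakpoint(exp, tiny)


class TestGaussianWidth:
    def test_sigma_zero_truth_collapses_to_lower_bound(self, two_origin_genome):
        genome, origins, params = two_origin_genome
        exp, _ = make_segment_dataset(genome, origins, params, sigma=0.0)
        seg = segments_between(origins, genome.replicon("c"))[0]
        f = fit_gaussian_width(exp, seg, fit_breakpoint(exp, seg))
        assert f.sigma <= exp.bin_size / 2
        assert f.s95 <= exp.bin_size

    @pytest.mark.parametrize("true_sigma", [50_000.0, 20_000.0])
    def test_noiseless_in_class_recovery_within_1pct(self, two_origin_genome,
                                                     true_sigma):
        genome, origins, params = two_origin_genome
        exp, _ = make_segment_dataset(genome, origins, params, sigma=true_sigma)
        seg = segments_between(origins, genome.replicon("c"))[0]
        f = fit_gaussian_width(exp, seg, fit_breakpoint(exp, seg))
        assert f.sigma == pytest.approx(true_sigma, rel=0.01)
        assert f.sigma_converged

    def test_s95_sigma_ratio_is_constant(self, two_origin_genome):
        genome, origins, params = two_origin_genome
        exp, _ = make_segment_dataset(genome, origins, params, sigma=30_000.0)
        seg = segments_between(origins, genome.replicon("c"))[0]
        f = fit_gaussian_width(exp, seg, fit_breakpoint(exp, seg))
        assert f.s95 / f.sigma == pytest.approx(3.919928, abs=1e-9)

    def test_golden_section_matches_grid_oracle(self, two_origin_genome):
        genome, origins, params = two_origin_genome
        exp, prof = make_segment_dataset(genome, origins, params,
                                         sigma=50_000.0, mean_depth=2000.0,
                                         seed=3)
        seg = segments_between(origins, genome.replicon("c"))[0]
        f0 = fit_breakpoint(prof, seg)
        f = fit_gaussian_width(prof, seg, f0, max_line_refits=0)
        # oracle: dense grid over the same bounds with the same lines
        from mfaterm.fit import _segment_points
        from mfaterm.model import gaussian_corrected_mf
        s, y, mf = _segment_points(prof, seg)
        grid = np.linspace(prof.bin_size / 10, seg.arc_length / 4, 4000)
        sses = [
            float(np.sum((mf - gaussian_corrected_mf(
                s, fcp=f0.fcp_arc, sigma=g,
                left_slope=f0.left_slope, left_intercept=f0.left_intercept,
                right_slope=f0.right_slope, right_intercept=f0.right_intercept,
            )) ** 2))
            for g in grid
        ]
        assert f.sse_linear <= min(sses) * (1 + 1e-6) + 1e-15


class TestLocalizeOrigin:
    def _wt_profile(self, origin_pos, seed=0, mean_depth=None):
        genome = GenomeMap({"c": Replicon("c", 2_961_149)}, {})
        params = ReplicationParameters(tau=40.0, v=30_000.0)
        origins = [Origin("c", origin_pos, name="ori")]
        exp, prof = make_segment_dataset(genome, origins, params,
                                         mean_depth=mean_depth, seed=seed)
        return (prof if prof is not None else exp), genome.replicon("c")

    def test_noiseless_apex_within_half_bin(self):
        prof, rep = self._wt_profile(1_200_000)
        for window in (200_000, 400_000):
            apex = localize_origin(prof, rep, window)
            assert abs(apex - 1_200_000) <= prof.bin_size / 2

    def test_wraparound_origin_at_zero(self):
        prof, rep = self._wt_profile(0)
        apex = localize_origin(prof, rep, 300_000)
        err = min(apex, rep.length - apex)
        assert err <= prof.bin_size

    def test_flat_profile_has_no_peak(self):
        genome = GenomeMap({"c": Replicon("c", 1_000_000)}, {})
        rep = genome.replicon("c")
        from mfaterm import MarkerFrequencyProfile
        n = 1000
        prof = MarkerFrequencyProfile(
            replicon=rep, bin_size=1000, mf=np.ones(n),
            log2mf=np.zeros(n), mask=np.zeros(n, dtype=bool),
        )
        with pytest.raises(FitError, match="no peak"):
            localize_origin(prof, rep, 200_000)

    def test_window_below_20_bins_rejected(self):
        prof, rep = self._wt_profile(500_000)
        with pytest.raises(FitError, match="20 bins"):
            localize_origin(prof, rep, 19_000)


class TestSlopeAsymmetry:
    def _fits(self, perturb):
        import mfaterm as m
        perts = [m.rrn_head_on_perturbation(0.3)] if perturb else []
        ds = m.make_ectopic_fixture("left", 2, perturbations=perts)
        covs = [trim_outlier_bins(c) for c in ds.coverages.values()]
        prof = normalize_profiles(covs, "chr1")[0]
        segs = segments_between(ds.origins, ds.genome.replicon("chr1"))
        return [fit_breakpoint(prof, s) for s in segs]

    def test_symmetric_arms_not_flagged(self):
        f1, f2 = self._fits(False)
        rep = slope_asymmetry(f2, f1, origin="oriL3")
        assert rep.ratio == pytest.approx(1.0, abs=0.1)
        assert not rep.flagged

    def test_head_on_perturbed_arm_flagged(self):
        f1, f2 = self._fits(True)
        rep = slope_asymmetry(f2, f1, origin="oriL3")
        assert rep.flagged
        assert rep.ratio < 1 / 1.25 or rep.ratio > 1.25

    def test_threshold_boundary_is_strict(self):
        f1, f2 = self._fits(False)
        ratio = slope_asymmetry(f2, f1, origin="oriL3").ratio
        at_boundary = max(ratio, 1.0 / ratio)
        rep = slope_asymmetry(f2, f1, origin="oriL3", threshold=at_boundary)
        assert not rep.flagged  # ratio exactly at the threshold: no flag

    def test_disjoint_fits_rejected(self):
        f1, f2 = self._fits(False)
        other = dataclasses.replace(
            f1, segment=dataclasses.replace(
                f1.segment,
                left_origin=Origin("chrX", 5), right_origin=Origin("chrX", 10),
            )
        )
        with pytest.raises(FitError, match="share"):
            slope_asymmetry(f1, other)


class TestSynchronyAndReport:
    def test_masked_fcp_bin_uses_nearest_unmasked_neighbor(self,
                                                           two_origin_genome):
        genome, origins, params = two_origin_genome
        _, prof = make_segment_dataset(genome, origins, params,
                                       mean_depth=500.0, seed=1)
        seg = segments_between(origins, genome.replicon("c"))[0]
        f = fit_breakpoint(prof, seg)
        idx = int(f.fcp // prof.bin_size)
        prof.mask[idx] = True
        res = termination_synchrony([prof], [f], f, tolerance_log2=0.05)
        assert res[0].classification == "synchronous"  # fit against itself

    def test_fcp_mp_percent_arithmetic(self):
        rep = Replicon("chr1", 2_961_149)
        o = Origin("chr1", 0, name="oriC1")
        seg = segments_between([o], rep)[0]
        arc = 2_960_000  # use printed example numbers
        f = dataclasses.replace(
            fitless_segmentfit(seg), fcp=1_483_000.0, fcp_arc=1_483_000.0,
            mp=1_480_000.0, fcp_mp_bp=3_000.0,
            fcp_mp_pct=100.0 * 3_000 / arc,
        )
        assert f.fcp_mp_pct == pytest.approx(0.101, abs=0.001)

    def test_segment_report_columns_and_distances(self):
        genome = GenomeMap(
            {"chr1": Replicon("chr1", 2_961_149)},
            {"dif1": Locus("chr1", 1_438_000)},
        )
        rep = genome.replicon("chr1")
        seg = segments_between([Origin("chr1", 0, name="oriC1")], rep)[0]
        f = dataclasses.replace(fitless_segmentfit(seg), fcp=1_483_000.0)
        table = segment_report([f], genome)
        row = table.iloc[0]
        assert row["fcp"] == 1_483_001  # 1-based in reports
        assert row["dist_to_dif1"] == 45_000
        assert {"replicon", "segment", "fcp", "mp", "fcp_mp_bp",
                "fcp_mp_pct", "s95"} <= set(table.columns)

    def test_terminal_fit_picks_lowest_marker_frequency(self, two_origin_genome):
        genome, origins, params = two_origin_genome
        # make the second origin fire late: its segment terminus is deepest
        origins = [origins[0], dataclasses.replace(origins[1], firing_offset=8.0)]
        exp, _ = make_segment_dataset(genome, origins, params)
        segs = segments_between(origins, genome.replicon("c"))
        fits = [fit_breakpoint(exp, s) for s in segs]
        term = terminal_fit(fits, exp)
        ages = [exp.log2mf[int(f.fcp // exp.bin_size)] for f in fits]
        assert exp.log2mf[int(term.fcp // exp.bin_size)] == min(ages)


def fitless_segmentfit(seg):
    """A SegmentFit shell for report-level arithmetic tests."""
    from mfaterm.fit import SegmentFit
    return SegmentFit(
        segment=seg, fcp=0.0, fcp_arc=0.0, left_slope=-1e-6,
        left_intercept=0.0, right_slope=1e-6, right_intercept=0.0,
        sse=0.0, mp=float(seg.arc_length / 2), fcp_mp_bp=0.0, fcp_mp_pct=0.0,
        n_bins_used=100, sigma=1000.0, s95=S95_FACTOR * 1000.0,
    )
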