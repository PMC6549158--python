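"""Fork-convergence inference from marker-frequency profiles.

The breakpoint of the two-sided log-linear coverage profile between two
origins is the fork convergence point (fcp): the position minimising the
total squared error between log2 marker frequencies and two independent
ordinary-least-squares lines, one per arm.  A second stage fits the width
``sigma`` of a Gaussian spread of convergence positions by minimising the
linear-scale error against the Gaussian-corrected mixture model; the span
within which 95% of cells' forks converge is ``S95 = 2 * 1.959964 * sigma``.

The estimators follow the scikit-learn protocol (``fit``/``predict``,
``get_params``, fitted attributes with a trailing underscore) so they
compose with sklearn pipelines; the module-level functions are thin wrappers
producing :class:`SegmentFit` records from profiles and segments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, column_or_1d

from .coverage import MarkerFrequencyProfile
from .genome import GenomeMap, Replicon, circular_distance
from .model import Segment, gaussian_corrected_mf

__all__ = [
    "FitError",
    "Z95",
    "S95_FACTOR",
    "BreakpointRegression",
    "ForkConvergenceRegression",
    "SegmentFit",
    "SlopeAsymmetry",
    "SynchronyResult",
    "fit_breakpoint",
    "fit_gaussian_width",
    "fit_segment",
    "localize_origin",
    "slope_asymmetry",
    "termination_synchrony",
    "terminal_fit",
    "segment_report",
]

Z95 = 1.959964  #: two-sided 95% standard-normal quantile
S95_FACTOR = 2.0 * Z95  #: S95 / sigma


class FitError(ValueError):
    """Fitting preconditions violated or degenerate data."""


# ---------------------------------------------------------------------------
# exhaustive two-line scan


def _two_line_sse_scan(x: np.ndarray, y: np.ndarray, cand: np.ndarray) -> np.ndarray:
    """Total OLS SSE of a two-line fit split at each candidate index.

    For split index ``k`` the left line is fit on points ``0..k`` and the
    right line on ``k..n-1`` (the split point belongs to both sides).
    Prefix sums of centred moments make the full scan O(n).
    """
    x0 = x - x.mean()
    y0 = y - y.mean()
    zeros = np.zeros(1)
    cx = np.concatenate([zeros, np.cumsum(x0)])
    cy = np.concatenate([zeros, np.cumsum(y0)])
    cxx = np.concatenate([zeros, np.cumsum(x0 * x0)])
    cyy = np.concatenate([zeros, np.cumsum(y0 * y0)])
    cxy = np.concatenate([zeros, np.cumsum(x0 * y0)])
    n = len(x)

    def _sse(sx, sy, sxx, syy, sxy, m):
        sxx_c = sxx - sx * sx / m
        sxy_c = sxy - sx * sy / m
        syy_c = syy - sy * sy / m
        with np.errstate(divide="ignore", invalid="ignore"):
            out = syy_c - np.where(sxx_c > 0, sxy_c * sxy_c / np.where(sxx_c > 0, sxx_c, 1.0), 0.0)
        return np.maximum(out, 0.0)

    k = cand
    m_left = (k + 1).astype(float)
    sse_left = _sse(cx[k + 1], cy[k + 1], cxx[k + 1], cyy[k + 1], cxy[k + 1], m_left)
    m_right = (n - k).astype(float)
    sse_right = _sse(
        cx[n] - cx[k], cy[n] - cy[k], cxx[n] - cxx[k],
        cyy[n] - cyy[k], cxy[n] - cxy[k], m_right,
    )
    return sse_left + sse_right


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and SSE of a simple OLS line (centred, stable)."""
    xm = x.mean()
    slope, intercept0 = np.polyfit(x - xm, y, 1)
    intercept = intercept0 - slope * xm
    resid = y - (slope * x + intercept)
    return float(slope), float(intercept), float(resid @ resid)


# ---------------------------------------------------------------------------
# estimators


class BreakpointRegression(RegressorMixin, BaseEstimator):
    """Piecewise two-line OLS regression with an exhaustively searched break.

    Candidates are the observed x positions (optionally restricted); for each
    candidate two independent OLS lines are fit (the candidate point belongs
    to both sides) and the candidate minimising the total SSE is kept, ties
    broken toward the smallest x.

    Parameters
    ----------
    min_side_points:
        Minimum number of points required on each side of a candidate.
    exclude_edge:
        Number of extreme points (per side) excluded from the candidate set,
        e.g. origin-proximal bins.
    candidates:
        Optional explicit array of allowed breakpoint x positions; only
        observed positions among them are used.

    Attributes
    ----------
    breakpoint_ : float
    left_slope_, left_intercept_, right_slope_, right_intercept_ : float
    sse_ : float
        Total squared residual (log space of whatever y was given).
    """

    def __init__(self, min_side_points: int = 5, exclude_edge: int = 0,
                 candidates=None):
        self.min_side_points = min_side_points
        self.exclude_edge = exclude_edge
        self.candidates = candidates

    def _validate(self, X, y):
        X = check_array(X, ensure_2d=True, dtype=float)
        if X.shape[1] != 1:
            raise ValueError("BreakpointRegression expects a single feature")
        y = column_or_1d(y, warn=False).astype(float)
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        return X[:, 0], y

    def _candidate_indices(self, x: np.ndarray) -> np.ndarray:
        n = len(x)
        lo = max(int(self.exclude_edge), self.min_side_points - 1)
        hi = n - 1 - max(int(self.exclude_edge), self.min_side_points - 1)
        idx = np.arange(lo, hi + 1) if hi >= lo else np.array([], dtype=int)
        if self.candidates is not None and idx.size:
            allowed = np.asarray(self.candidates, dtype=float)
            idx = idx[np.isin(x[idx], allowed)]
        return idx

    def fit(self, X, y):
        x, y = self._validate(X, y)
        order = np.argsort(x, kind="stable")
        x, y = x[order], y[order]
        cand = self._candidate_indices(x)
        if cand.size == 0:
            raise FitError(
                f"too few points for a breakpoint fit (n={len(x)}, "
                f"min_side_points={self.min_side_points}, "
                f"exclude_edge={self.exclude_edge})"
            )
        sse = _two_line_sse_scan(x, y, cand)
        k = int(cand[int(np.argmin(sse))])  # argmin returns first = smallest x
        ls, li, sse_l = _ols_line(x[: k + 1], y[: k + 1])
        rs, ri, sse_r = _ols_line(x[k:], y[k:])
        self.n_features_in_ = 1
        self.breakpoint_ = float(x[k])
        self.break_index_ = k
        self.left_slope_, self.left_intercept_ = ls, li
        self.right_slope_, self.right_intercept_ = rs, ri
        self.sse_ = sse_l + sse_r
        self.n_points_ = len(x)
        return self

    def predict(self, X):
        check_is_fitted(self, "breakpoint_")
        X = check_array(X, ensure_2d=True, dtype=float)
        x = X[:, 0]
        left = self.left_intercept_ + self.left_slope_ * x
        right = self.right_intercept_ + self.right_slope_ * x
        return np.where(x <= self.breakpoint_, left, right)


class ForkConvergenceRegression(BreakpointRegression):
    """Breakpoint regression plus a Gaussian convergence-width stage.

    After locating the breakpoint in log2 space, the width ``sigma`` of the
    Gaussian spread of fork-convergence positions is fit by bounded 1-D
    minimisation of the *linear-scale* SSE against the Gaussian-corrected
    mixture of the two arms (the mixture of exponentials is not log-linear).

    Additional parameters
    ---------------------
    fit_sigma : bool
        Run the width stage (default True).
    sigma_bounds : (lo, hi) or None
        Search bounds in x units; None picks ``(spacing/10, span/4)`` from
        the data spacing/span.
    refit_breakpoint : bool
        If True, locally re-optimise the breakpoint jointly with sigma on the
        linear scale (off by default).

    Additional attributes
    ---------------------
    sigma_ : float
    s95_ : float
    sse_linear_ : float
    sigma_converged_ : bool
        False when the bounded minimisation did not converge and a boundary
        value was reported.
    """

    def __init__(self, min_side_points: int = 5, exclude_edge: int = 0,
                 candidates=None, fit_sigma: bool = True, sigma_bounds=None,
                 refit_breakpoint: bool = False):
        super().__init__(min_side_points=min_side_points,
                         exclude_edge=exclude_edge, candidates=candidates)
        self.fit_sigma = fit_sigma
        self.sigma_bounds = sigma_bounds
        self.refit_breakpoint = refit_breakpoint

    # -- sigma machinery ----------------------------------------------------

    def _mixture(self, x, bp, sigma, lines):
        ls, li, rs, ri = lines
        return gaussian_corrected_mf(
            x, fcp=bp, sigma=sigma, left_slope=ls, left_intercept=li,
            right_slope=rs, right_intercept=ri,
        )

    def _sigma_objective(self, x, mf, bp, lines):
        def obj(sigma):
            resid = mf - self._mixture(x, bp, sigma, lines)
            return float(resid @ resid)
        return obj

    def _fit_sigma(self, x, mf, bp, lines, bounds, n_coarse: int = 32):
        """Global 1-D minimisation: the linear-scale SSE in sigma can have a
        boundary minimum (sigma -> 0) in addition to an interior one, so a
        log-spaced coarse scan brackets the best region before Brent
        refinement."""
        lo, hi = bounds
        if not 0 <= lo < hi:
            raise FitError(f"invalid sigma bounds ({lo}, {hi})")
        obj = self._sigma_objective(x, mf, bp, lines)
        grid = np.geomspace(max(lo, 1e-12), hi, n_coarse)
        grid[0], grid[-1] = lo, hi
        vals = [obj(g) for g in grid]
        k = int(np.argmin(vals))
        blo = grid[max(k - 1, 0)]
        bhi = grid[min(k + 1, len(grid) - 1)]
        if blo >= bhi:  # degenerate bracket at a boundary
            return float(grid[k]), float(vals[k]), True
        res = minimize_scalar(
            obj, bounds=(blo, bhi), method="bounded",
            options={"xatol": max(1e-3, 1e-8 * (hi - lo))},
        )
        if res.fun <= vals[k]:
            return float(res.x), float(res.fun), bool(res.success)
        return float(grid[k]), float(vals[k]), bool(res.success)

    def fit(self, X, y):
        super().fit(X, y)
        if not self.fit_sigma:
            return self
        x_raw = check_array(X, ensure_2d=True, dtype=float)[:, 0]
        order = np.argsort(x_raw, kind="stable")
        x = x_raw[order]
        y_sorted = column_or_1d(y).astype(float)[order]
        mf = np.exp2(y_sorted)
        if self.sigma_bounds is not None:
            bounds = self.sigma_bounds
        else:
            spacing = float(np.median(np.diff(np.unique(x)))) if len(x) > 1 else 1.0
            bounds = (spacing / 10.0, (x[-1] - x[0]) / 4.0)
        lines = (self.left_slope_, self.left_intercept_,
                 self.right_slope_, self.right_intercept_)
        sigma, sse_lin, ok = self._fit_sigma(x, mf, self.breakpoint_, lines, bounds)
        if self.refit_breakpoint:
            sigma, sse_lin, ok = self._joint_refit(x, y_sorted, mf, bounds,
                                                   sigma, sse_lin, ok)
        self.sigma_ = sigma
        self.s95_ = S95_FACTOR * sigma
        self.sse_linear_ = sse_lin
        self.sigma_converged_ = ok
        return self

    def _joint_refit(self, x, y, mf, bounds, sigma0, sse0, ok0):
        """Local alternation: rescan breakpoints near the current one on the
        linear scale, refitting lines and sigma per candidate."""
        spacing = float(np.median(np.diff(np.unique(x)))) if len(x) > 1 else 1.0
        half_window = max(2.0 * sigma0, 10.0 * spacing)
        cand = self._candidate_indices(x)
        cand = cand[np.abs(x[cand] - self.breakpoint_) <= half_window]
        best = (sse0, self.breakpoint_, sigma0, ok0, None)
        for k in cand:
            k = int(k)
            ls, li, _ = _ols_line(x[: k + 1], y[: k + 1])
            rs, ri, _ = _ols_line(x[k:], y[k:])
            lines = (ls, li, rs, ri)
            sig, sse, ok = self._fit_sigma(x, mf, x[k], lines, bounds)
            if sse < best[0]:
                best = (sse, float(x[k]), sig, ok, (k, lines))
        sse, bp, sigma, ok, extra = best
        if extra is not None:
            k, (ls, li, rs, ri) = extra
            self.breakpoint_ = bp
            self.break_index_ = k
            self.left_slope_, self.left_intercept_ = ls, li
            self.right_slope_, self.right_intercept_ = rs, ri
            yl = y[: k + 1] - (ls * x[: k + 1] + li)
            yr = y[k:] - (rs * x[k:] + ri)
            self.sse_ = float(yl @ yl + yr @ yr)
        return sigma, sse, ok

    def predict(self, X, scale: str = "log2"):
        check_is_fitted(self, "breakpoint_")
        X = check_array(X, ensure_2d=True, dtype=float)
        x = X[:, 0]
        sigma = getattr(self, "sigma_", None)
        lines = (self.left_slope_, self.left_intercept_,
                 self.right_slope_, self.right_intercept_)
        mf = self._mixture(x, self.breakpoint_, sigma if sigma else 0.0, lines)
        if scale == "linear":
            return mf
        return np.log2(mf)


# ---------------------------------------------------------------------------
# segment-level wrappers


@dataclass
class SegmentFit:
    """Fitted fork-convergence parameters for one inter-origin segment.

    Positions are genomic (0-based); slopes/intercepts are in log2 units per
    bp of clockwise arc coordinate (0 at the left origin).  ``fcp_mp_bp`` is
    the signed clockwise offset of the fcp from the segment midpoint,
    ``fcp_mp_pct`` its magnitude as a percentage of the arc length.
    """

    segment: Segment
    fcp: float
    fcp_arc: float
    left_slope: float
    left_intercept: float
    right_slope: float
    right_intercept: float
    sse: float
    mp: float
    fcp_mp_bp: float
    fcp_mp_pct: float
    n_bins_used: int
    sigma: float | None = None
    s95: float | None = None
    sse_linear: float | None = None
    sigma_converged: bool | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["segment"] = self.segment.label
        d["replicon"] = self.segment.replicon.name
        return d


def _segment_points(profile: MarkerFrequencyProfile, segment: Segment):
    """Unmasked (arc coordinate, log2mf, mf) triples strictly inside the arc."""
    s = segment.arc_coordinate(profile.bin_centers)
    keep = profile.unmasked & (s > 0) & (s < segment.arc_length)
    keep &= np.isfinite(profile.log2mf)
    order = np.argsort(s[keep], kind="stable")
    return s[keep][order], profile.log2mf[keep][order], profile.mf[keep][order]


def fit_breakpoint(
    profile: MarkerFrequencyProfile,
    segment: Segment,
    *,
    min_side_points: int = 5,
    exclude_origin_bins: int = 5,
) -> SegmentFit:
    """Locate the fcp of a segment by exhaustive two-line OLS in log2 space.

    Candidates are the unmasked bin centres strictly inside the arc,
    excluding ``exclude_origin_bins`` bins adjacent to each origin
    (origin-proximal initiation transients); ties break toward the smallest
    clockwise arc coordinate.  ``sigma``/``s95`` are left unset.
    """
    if segment.arc_length < 10 * profile.bin_size:
        raise FitError(
            f"segment {segment.label}: arc shorter than 10 bins "
            f"({segment.arc_length} bp at bin size {profile.bin_size})"
        )
    s, y, _ = _segment_points(profile, segment)
    est = BreakpointRegression(
        min_side_points=min_side_points, exclude_edge=exclude_origin_bins
    )
    est.fit(s[:, None], y)
    arc = float(segment.arc_length)
    fcp_arc = est.breakpoint_
    mp_arc = arc / 2.0
    return SegmentFit(
        segment=segment,
        fcp=float(segment.genomic_position(fcp_arc)),
        fcp_arc=fcp_arc,
        left_slope=est.left_slope_,
        left_intercept=est.left_intercept_,
        right_slope=est.right_slope_,
        right_intercept=est.right_intercept_,
        sse=est.sse_,
        mp=float(segment.genomic_position(mp_arc)),
        fcp_mp_bp=fcp_arc - mp_arc,
        fcp_mp_pct=100.0 * abs(fcp_arc - mp_arc) / arc,
        n_bins_used=est.n_points_,
    )


def fit_gaussian_width(
    profile: MarkerFrequencyProfile,
    segment: Segment,
    fit: SegmentFit,
    *,
    sigma_bounds: tuple[float, float] | None = None,
    refit_breakpoint: bool = False,
    min_side_points: int = 5,
    exclude_origin_bins: int = 5,
    line_exclusion_sigmas: float = 3.0,
    max_line_refits: int = 10,
) -> SegmentFit:
    """Fit the Gaussian convergence width around an existing breakpoint fit.

    Bounded 1-D minimisation of the linear-scale SSE over
    ``sigma in [bin_size/10, arc_length/4]`` (by default); ``S95 = 2*1.959964*sigma``.

    The mixture's L/R lines are the *arm* regressions; a line fitted through
    the Gaussian-smoothed shoulder is biased, which in turn biases sigma low.
    The width fit therefore alternates: fit sigma, re-estimate each arm line
    on the bins farther than ``line_exclusion_sigmas * sigma`` from the fcp,
    and repeat until sigma is stable (1% or a bin-width/100).  Set
    ``max_line_refits=0`` to keep the breakpoint-stage lines unchanged.

    If the minimiser does not converge the boundary value is reported with
    ``sigma_converged = False``.  With ``refit_breakpoint=True`` the fcp is
    locally re-optimised jointly with sigma.
    """
    s, y, mf = _segment_points(profile, segment)
    arc = float(segment.arc_length)
    near = np.abs(s - fit.fcp_arc) <= 4.0 * (arc / 20.0)
    if near.sum() < 10:
        raise FitError(
            f"segment {segment.label}: only {int(near.sum())} unmasked bins "
            "near the fcp; need >= 10 for the width fit"
        )
    bounds = sigma_bounds or (profile.bin_size / 10.0, arc / 4.0)
    est = ForkConvergenceRegression(
        min_side_points=min_side_points, exclude_edge=exclude_origin_bins,
        fit_sigma=True, sigma_bounds=bounds, refit_breakpoint=refit_breakpoint,
    )
    # seed the estimator with the existing breakpoint stage, then run only
    # the width stage (and optional joint refit) on the same points
    est.breakpoint_ = fit.fcp_arc
    est.break_index_ = int(np.searchsorted(s, fit.fcp_arc))
    est.left_slope_, est.left_intercept_ = fit.left_slope, fit.left_intercept
    est.right_slope_, est.right_intercept_ = fit.right_slope, fit.right_intercept
    est.sse_ = fit.sse
    est.n_points_ = len(s)
    est.n_features_in_ = 1
    lines = (fit.left_slope, fit.left_intercept, fit.right_slope, fit.right_intercept)
    sigma, sse_lin, ok = est._fit_sigma(s, mf, fit.fcp_arc, lines, bounds)
    for _ in range(max_line_refits):
        new_lines = _arm_lines_excluding(
            s, y, fit.fcp_arc, line_exclusion_sigmas * sigma,
            min_side_points, lines,
        )
        if new_lines is None:
            break
        new_sigma, sse_lin, ok = est._fit_sigma(
            s, mf, fit.fcp_arc, new_lines, bounds
        )
        lines = new_lines
        est.left_slope_, est.left_intercept_ = lines[0], lines[1]
        est.right_slope_, est.right_intercept_ = lines[2], lines[3]
        if abs(new_sigma - sigma) <= max(0.01 * sigma, profile.bin_size / 100.0):
            sigma = new_sigma
            break
        sigma = new_sigma
    if refit_breakpoint:
        sigma, sse_lin, ok = est._joint_refit(s, y, mf, bounds, sigma, sse_lin, ok)
    out = dataclasses.replace(
        fit,
        sigma=sigma,
        s95=S95_FACTOR * sigma,
        sse_linear=sse_lin,
        sigma_converged=ok,
        left_slope=est.left_slope_, left_intercept=est.left_intercept_,
        right_slope=est.right_slope_, right_intercept=est.right_intercept_,
    )
    if refit_breakpoint and est.breakpoint_ != fit.fcp_arc:
        fcp_arc = est.breakpoint_
        out = dataclasses.replace(
            out,
            fcp=float(segment.genomic_position(fcp_arc)),
            fcp_arc=fcp_arc,
            left_slope=est.left_slope_, left_intercept=est.left_intercept_,
            right_slope=est.right_slope_, right_intercept=est.right_intercept_,
            sse=est.sse_,
            fcp_mp_bp=fcp_arc - segment.arc_length / 2.0,
            fcp_mp_pct=100.0 * abs(fcp_arc - segment.arc_length / 2.0)
            / segment.arc_length,
        )
    return out


def _arm_lines_excluding(s, y, fcp_arc, half_width, min_side_points, fallback):
    """OLS lines per arm using only bins outside ``half_width`` of the fcp;
    None when either arm would drop below ``min_side_points`` points."""
    left = (s <= fcp_arc) & (s < fcp_arc - half_width)
    right = (s >= fcp_arc) & (s > fcp_arc + half_width)
    if left.sum() < min_side_points or right.sum() < min_side_points:
        return None
    ls, li, _ = _ols_line(s[left], y[left])
    rs, ri, _ = _ols_line(s[right], y[right])
    return (ls, li, rs, ri)


def fit_segment(profile, segment, **kwargs) -> SegmentFit:
    """Breakpoint fit followed by the Gaussian width fit."""
    width_keys = {"sigma_bounds", "refit_breakpoint"}
    bp_kwargs = {k: v for k, v in kwargs.items() if k not in width_keys}
    w_kwargs = {k: v for k, v in kwargs.items() if k in width_keys}
    fit = fit_breakpoint(profile, segment, **bp_kwargs)
    return fit_gaussian_width(profile, segment, fit, **bp_kwargs | w_kwargs)


def localize_origin(
    profile: MarkerFrequencyProfile,
    replicon: Replicon,
    window: int,
    *,
    min_side_points: int = 5,
    min_peak_slope: float = 1e-9,
) -> float:
    """Locate a replication origin as the apex of the marker-frequency peak.

    The same two-line machinery is applied to an inverted V within ``window``
    bp centred on the maximum unmasked bin; circular wrap is honoured.  The
    reported apex is the intersection of the fitted ascending and descending
    lines, which is robust to bin-scale jitter of the split candidate (on
    noise-free data it coincides with the best split to within half a bin).
    Run with at least two window sizes and compare the results.
    """
    if window < 20 * profile.bin_size:
        raise FitError(
            f"window must span >= 20 bins ({20 * profile.bin_size} bp), "
            f"got {window}"
        )
    centers = profile.bin_centers
    keep = profile.unmasked & np.isfinite(profile.log2mf)
    if not keep.any():
        raise FitError("profile fully masked")
    c = centers[keep][int(np.argmax(profile.log2mf[keep]))]
    if replicon.circular:
        d = (centers - c + replicon.length / 2.0) % replicon.length \
            - replicon.length / 2.0
    else:
        d = centers - c
    sel = keep & (np.abs(d) <= window / 2.0)
    x, y = d[sel], profile.log2mf[sel]
    order = np.argsort(x, kind="stable")
    est = BreakpointRegression(min_side_points=min_side_points)
    est.fit(x[order][:, None], y[order])
    if est.left_slope_ < min_peak_slope or -est.right_slope_ < min_peak_slope:
        raise FitError("no peak: slope magnitudes below tolerance")
    xi = (est.right_intercept_ - est.left_intercept_) / (
        est.left_slope_ - est.right_slope_
    )
    lo, hi = x[order][0], x[order][-1]
    if not lo <= xi <= hi:
        raise FitError("no peak: fitted apex outside the window")
    apex = c + xi
    return float(apex % replicon.length) if replicon.circular else float(apex)


@dataclass(frozen=True)
class SlopeAsymmetry:
    """|slope| ratio of the two arms leaving a shared origin."""

    origin: str
    ratio: float
    flagged: bool
    threshold: float


def slope_asymmetry(
    fit: SegmentFit, neighbor: SegmentFit, threshold: float = 1.25,
    origin: str | int | None = None,
) -> SlopeAsymmetry:
    """Compare the log2 slope magnitudes of the two arms across an origin.

    ``fit`` and ``neighbor`` must share one origin; the report is flagged
    when the ratio falls strictly outside ``[1/threshold, threshold]``.
    With two origins on a circle both segments share both endpoints, so
    ``origin`` (a position or origin name) selects which one to compare
    across; it may be omitted when the shared origin is unique.
    """
    fit_ids = {
        (fit.segment.left_origin.replicon, fit.segment.left_origin.position),
        (fit.segment.right_origin.replicon, fit.segment.right_origin.position),
    }
    nb_ids = {
        (neighbor.segment.left_origin.replicon, neighbor.segment.left_origin.position),
        (neighbor.segment.right_origin.replicon, neighbor.segment.right_origin.position),
    }
    shared = fit_ids & nb_ids
    if not shared:
        raise FitError("fits do not share an origin")
    if origin is not None:
        def matches(oid):
            for f in (fit, neighbor):
                for o in (f.segment.left_origin, f.segment.right_origin):
                    if (o.replicon, o.position) == oid and (
                        o.name == origin or o.position == origin
                    ):
                        return True
            return False
        shared = {oid for oid in shared if matches(oid)}
        if not shared:
            raise FitError(f"origin {origin!r} is not shared by the two fits")
    elif len(shared) > 1:
        raise FitError(
            "the fits share more than one origin; pass origin= to choose"
        )
    origin_id = sorted(shared)[0]

    def arm_slope(f: SegmentFit):
        lo = (f.segment.left_origin.replicon, f.segment.left_origin.position)
        if lo == origin_id:
            return f.left_slope, f.segment.left_origin.label
        return f.right_slope, f.segment.right_origin.label

    s1, label = arm_slope(fit)
    s2, _ = arm_slope(neighbor)
    if s1 == 0 or s2 == 0:
        raise FitError("zero slope on one arm")
    ratio = abs(s1) / abs(s2)
    flagged = ratio > threshold or ratio < 1.0 / threshold
    return SlopeAsymmetry(origin=label, ratio=ratio, flagged=flagged,
                          threshold=threshold)


@dataclass(frozen=True)
class SynchronyResult:
    """Relative termination timing of chr2 vs one chr1 fcp."""

    chr1_segment: str
    delta_log2: float
    classification: str  # "chr2 ahead" | "chr2 behind" | "synchronous"


def _log2_at(profile: MarkerFrequencyProfile, position: float,
             max_shift: int = 5) -> float:
    """log2 MF at the bin containing ``position``; if masked, the nearest
    unmasked bin within ``max_shift`` bins (circular)."""
    n = profile.n_bins
    idx = int(position // profile.bin_size) % n
    good = profile.unmasked & np.isfinite(profile.log2mf)
    for shift in range(max_shift + 1):
        for j in ((idx + shift) % n, (idx - shift) % n):
            if good[j]:
                return float(profile.log2mf[j])
    raise FitError(
        f"{profile.replicon.name}: no unmasked bin within {max_shift} bins "
        f"of position {position:.0f}"
    )


def termination_synchrony(
    profiles,
    chr1_fits,
    chr2_fit: SegmentFit,
    tolerance_log2: float = 0.05,
) -> list[SynchronyResult]:
    """Classify chr2 termination timing relative to each chr1 fcp.

    ``delta = log2mf(fcp2) - log2mf(fcp1)``: "chr2 ahead" when delta exceeds
    the tolerance (chr2 terminus more abundant, so replicated earlier),
    "chr2 behind" when below minus the tolerance, otherwise "synchronous".
    """
    by_name = {p.replicon.name: p for p in profiles}
    chr2_name = chr2_fit.segment.replicon.name
    if chr2_name not in by_name:
        raise FitError(f"no profile for replicon {chr2_name!r}")
    mf2 = _log2_at(by_name[chr2_name], chr2_fit.fcp)
    results = []
    for f in chr1_fits:
        name = f.segment.replicon.name
        if name not in by_name:
            raise FitError(f"no profile for replicon {name!r}")
        delta = mf2 - _log2_at(by_name[name], f.fcp)
        if delta > tolerance_log2:
            cls = "chr2 ahead"
        elif delta < -tolerance_log2:
            cls = "chr2 behind"
        else:
            cls = "synchronous"
        results.append(SynchronyResult(f.segment.label, float(delta), cls))
    return results


def terminal_fit(fits, profile: MarkerFrequencyProfile) -> SegmentFit:
    """The fit whose fcp is replicated last (lowest log2 MF at the fcp)."""
    if not fits:
        raise FitError("no fits")
    return min(fits, key=lambda f: _log2_at(profile, f.fcp))


def segment_report(fits, genome: GenomeMap) -> pd.DataFrame:
    """One row per segment: fcp (1-based), mp, fcp-mp, S95, slopes and
    shortest distances from the fcp to every named locus on the replicon."""
    if not fits:
        raise FitError("no fits to report")
    locus_names = sorted(genome.loci)
    rows = []
    for f in fits:
        rep = f.segment.replicon
        row = {
            "replicon": rep.name,
            "segment": f.segment.label,
            "fcp": int(round(f.fcp)) + 1,  # 1-based for human-readable output
            "mp": int(round(f.mp)) + 1,
            "fcp_mp_bp": round(f.fcp_mp_bp, 1),
            "fcp_mp_pct": round(f.fcp_mp_pct, 3),
            "left_slope": f.left_slope,
            "right_slope": f.right_slope,
            "sigma": f.sigma,
            "s95": f.s95,
            "sse": f.sse,
        }
        for name in locus_names:
            locus = genome.loci[name]
            if locus.replicon == rep.name:
                row[f"dist_to_{name}"] = circular_distance(
                    rep, int(round(f.fcp)) % rep.length, locus.position,
                    "shortest",
                )
            else:
                row[f"dist_to_{name}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
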