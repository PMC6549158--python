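"""Forward replication model for exponentially growing bacterial populations.

Under steady-state exponential growth (Cooper–Helmstetter), the relative
abundance of a locus in a sequencing library is ``MF(x) ∝ 2^(-age(x)/tau)``,
where ``age(x)`` is the time after the reference initiation event at which
the locus is replicated and ``tau`` the doubling time.  With uniform fork
speed ``v`` the log2 marker frequency is piecewise linear in position with
slope magnitude ``1/(v*tau)`` per bp, descending from each origin to the
fork convergence point (fcp) of its segment.

Cell-to-cell variability of the convergence position is modelled as a
Gaussian of width ``sigma`` centred on the fcp; the population profile is
then a pointwise mixture of the two arms' exponentials, weighted by the
probability that the convergence point lies beyond the position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .genome import GenomeConfigError, GenomeMap, Replicon
from .coverage import MarkerFrequencyProfile

__all__ = [
    "ModelError",
    "Origin",
    "ReplicationParameters",
    "Segment",
    "circular_distance",
    "replication_age",
    "segments_between",
    "theoretical_fcps",
    "theoretical_log2_profile",
    "gaussian_corrected_mf",
    "crts_coupled_offset",
]

from .genome import circular_distance  # re-export next to the model ops


class ModelError(ValueError):
    """Invalid replication-model inputs."""


@dataclass(frozen=True)
class Origin:
    """A replication origin with an optional firing delay.

    ``firing_offset`` is the time (minutes, >= 0) after the reference
    initiation event at which this origin fires; 0 means synchronous
    initiation.
    """

    replicon: str
    position: int
    firing_offset: float = 0.0
    name: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.firing_offset) or self.firing_offset < 0:
            raise ModelError(
                f"origin {self.name or self.position}: firing_offset must be "
                f"finite and >= 0, got {self.firing_offset}"
            )

    @property
    def label(self) -> str:
        return self.name if self.name is not None else f"{self.replicon}:{self.position}"


@dataclass(frozen=True)
class ReplicationParameters:
    """Doubling time tau (minutes) and fork speed v (bp/minute)."""

    tau: float
    v: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ModelError(f"tau must be > 0, got {self.tau}")
        if self.v <= 0:
            raise ModelError(f"v must be > 0, got {self.v}")

    @property
    def log2_slope_per_bp(self) -> float:
        """Magnitude of the log2 marker-frequency slope, 1/(v*tau)."""
        return 1.0 / (self.v * self.tau)


@dataclass(frozen=True)
class Segment:
    """The clockwise arc between two adjacent origins on one replicon."""

    replicon: Replicon
    left_origin: Origin
    right_origin: Origin
    arc_length: int

    @property
    def label(self) -> str:
        return f"{self.left_origin.label}->{self.right_origin.label}"

    def arc_coordinate(self, position) -> np.ndarray:
        """Clockwise offset of genomic position(s) from the left origin."""
        pos = np.asarray(position, dtype=float)
        if self.replicon.circular:
            return (pos - self.left_origin.position) % self.replicon.length
        return pos - self.left_origin.position

    def genomic_position(self, s) -> np.ndarray:
        """Inverse of :meth:`arc_coordinate`."""
        s = np.asarray(s, dtype=float)
        if self.replicon.circular:
            return (self.left_origin.position + s) % self.replicon.length
        return self.left_origin.position + s


def _origins_on(origins, replicon: Replicon) -> list[Origin]:
    ori = [o for o in origins if o.replicon == replicon.name]
    if not ori:
        raise ModelError(f"no origins on replicon {replicon.name!r}")
    for o in ori:
        if not 0 <= o.position < replicon.length:
            raise ModelError(
                f"origin {o.label} position {o.position} outside replicon"
            )
    return ori


def replication_age(x, origins, params: ReplicationParameters, replicon: Replicon):
    """Time (minutes) at which position ``x`` is replicated.

    The age is the minimum over all origins and both fork directions of
    ``firing_offset + arc(origin -> x)/v``; for equal fork speeds this min
    encodes fork meeting exactly.  Vectorised over ``x``.
    """
    ori = _origins_on(origins, replicon)
    xs = np.asarray(x, dtype=float)
    length = replicon.length
    ages = np.full(xs.shape, np.inf)
    for o in ori:
        if replicon.circular:
            cw = (xs - o.position) % length
            ccw = (o.position - xs) % length
        else:
            cw = np.where(xs >= o.position, xs - o.position, np.inf)
            ccw = np.where(xs <= o.position, o.position - xs, np.inf)
        d = np.minimum(cw, ccw)
        ages = np.minimum(ages, o.firing_offset + d / params.v)
    return ages if np.ndim(x) else float(ages)


def segments_between(origins, replicon: Replicon) -> list[Segment]:
    """The n clockwise inter-origin segments of a circular replicon.

    A single origin yields one segment spanning the whole circle (left and
    right origin coincide).
    """
    ori = sorted(_origins_on(origins, replicon), key=lambda o: o.position)
    if len({o.position for o in ori}) != len(ori):
        raise ModelError(f"duplicate origin positions on {replicon.name!r}")
    if not replicon.circular and len(ori) < 2:
        raise ModelError("a linear replicon needs explicit flanking origins")
    segments = []
    n = len(ori)
    for i in range(n):
        left = ori[i]
        right = ori[(i + 1) % n]
        if replicon.circular:
            arc = (right.position - left.position) % replicon.length
            if arc == 0:  # single origin: whole circle
                arc = replicon.length
        else:
            if i == n - 1:
                continue
            arc = right.position - left.position
        segments.append(Segment(replicon, left, right, int(arc)))
    return segments


def theoretical_fcps(
    origins, params: ReplicationParameters, replicon: Replicon
) -> list[tuple[Segment, float]]:
    """Per segment, the position where the arriving-fork identity switches.

    For equal speeds and zero offsets this is the segment midpoint; firing
    offsets shift it by ``v*delta_offset/2`` toward the later origin.  The
    fcp arc coordinate solves ``o_left + s/v = o_right + (arc - s)/v`` and is
    clamped to the segment.
    """
    out = []
    for seg in segments_between(origins, replicon):
        arc = seg.arc_length
        s = (arc + params.v * (seg.right_origin.firing_offset
                               - seg.left_origin.firing_offset)) / 2.0
        s = min(max(s, 0.0), float(arc))
        out.append((seg, float(seg.genomic_position(s))))
    return out


def theoretical_log2_profile(
    genome: GenomeMap,
    origins,
    params: ReplicationParameters,
    bin_size: int,
    reference: str | None = None,
) -> list[MarkerFrequencyProfile]:
    """Noise-free log2 marker-frequency profiles for every replicon.

    ``log2mf(x) = C - age(x)/tau`` with ``C`` chosen so the minimum on the
    normalisation-reference replicon is 0.  Every replicon in the genome must
    carry at least one origin (couple chr2-style origins beforehand with
    :func:`crts_coupled_offset`).
    """
    reps = list(genome.replicons.values())
    if reference is None:
        reference = reps[0].name
    if reference not in genome.replicons:
        raise ModelError(f"unknown reference replicon {reference!r}")
    ages = {}
    centers = {}
    for rep in reps:
        n = math.ceil(rep.length / bin_size)
        starts = np.arange(n) * float(bin_size)
        ends = np.minimum(starts + bin_size, rep.length)
        centers[rep.name] = (starts + ends) / 2.0
        ages[rep.name] = replication_age(centers[rep.name], origins, params, rep)
    c = ages[reference].max() / params.tau
    profiles = []
    for rep in reps:
        log2mf = c - ages[rep.name] / params.tau
        profiles.append(
            MarkerFrequencyProfile(
                replicon=rep,
                bin_size=bin_size,
                mf=np.exp2(log2mf),
                log2mf=log2mf,
                mask=np.zeros(len(log2mf), dtype=bool),
                normalization_reference=reference,
            )
        )
    return profiles


def gaussian_corrected_mf(
    s,
    *,
    fcp: float,
    sigma: float,
    left_slope: float,
    left_intercept: float,
    right_slope: float,
    right_intercept: float,
):
    """Linear-scale marker frequency under Gaussian fork-convergence spread.

    ``MF(s) = Phi((fcp - s)/sigma) * 2^L(s) + (1 - Phi((fcp - s)/sigma)) * 2^R(s)``

    with ``L``/``R`` the left/right log2 regression lines and ``s`` the arc
    coordinate (clockwise from the left origin).  The mixing weight is the
    probability that the cell's convergence point lies beyond ``s``; at
    ``sigma = 0`` this reduces exactly to the piecewise two-line model.
    """
    if sigma < 0:
        raise ModelError(f"sigma must be >= 0, got {sigma}")
    ss = np.asarray(s, dtype=float)
    left = np.exp2(left_intercept + left_slope * ss)
    right = np.exp2(right_intercept + right_slope * ss)
    if sigma == 0:
        w = np.where(ss < fcp, 1.0, np.where(ss > fcp, 0.0, 0.5))
    else:
        w = ndtr((fcp - ss) / sigma)
    out = w * left + (1.0 - w) * right
    return out if np.ndim(s) else float(out)


def crts_coupled_offset(
    genome: GenomeMap,
    chr1_origins,
    params: ReplicationParameters,
    extra_delay: float,
    crts_locus: str = "crtS",
    oric2_locus: str = "oriC2",
) -> Origin:
    """Origin for chr2 whose firing is licensed by replication of crtS.

    chr2 initiates only once the chr1 locus *crtS* has been replicated; the
    returned origin fires at ``replication_age(crtS) + extra_delay``.  As a
    consequence the expected marker frequency at oriC2 equals
    ``MF(crtS) * 2^(-extra_delay/tau)``.
    """
    try:
        crts_rep, crts_pos = genome.locus_position(crts_locus)
        oric2_rep, oric2_pos = genome.locus_position(oric2_locus)
    except GenomeConfigError as exc:
        raise ModelError(str(exc)) from None
    age = replication_age(crts_pos, chr1_origins, params, crts_rep)
    return Origin(
        replicon=oric2_rep.name,
        position=oric2_pos,
        firing_offset=age + extra_delay,
        name=oric2_locus,
    )
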