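"""Population-level replication simulator.

Generates marker-frequency datasets with exactly the statistical structure
the inference assumes: exponentially growing cells, log2 marker frequency
decreasing linearly from each origin toward the fork convergence point,
Gaussian cell-to-cell spread of the convergence position, Poisson read
sampling per bin, optional local depression at head-on rRNA operons, and
chr2 initiation coupled to replication of the chr1 *crtS* locus.  The
default fixtures mirror a two-chromosome *V. cholerae*-like genome with
approximate, clearly-labelled stand-in coordinates (exact coordinates can be
supplied via configuration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .coverage import BinnedCoverage, MarkerFrequencyProfile
from .genome import GenomeMap, Locus, Replicon
from .model import (
    ModelError,
    Origin,
    ReplicationParameters,
    crts_coupled_offset,
    replication_age,
    segments_between,
    theoretical_fcps,
)

__all__ = [
    "RrnPerturbation",
    "SyntheticSpec",
    "SimulatedDataset",
    "expected_profile",
    "sample_counts",
    "co_termination_delay",
    "default_genome",
    "make_wt_like_fixture",
    "make_ectopic_fixture",
]

# --- synthetic stand-in geometry (approximate; real coordinates are inputs) --
CHR1_LENGTH = 2_961_149
CHR2_LENGTH = 1_072_315
ORIC1_POS = 0
ORIL3_OFFSET = 650_000   # ectopic oriC1 copy, left replichore
ORIR4_OFFSET = 1_190_000  # ectopic oriC1 copy, right replichore
CRTS_OFFSET = 695_000    # crtS, left replichore (45 kb beyond oriL3)
DIF1_POS = 1_436_000     # ~45 kb counterclockwise of the chr1 antipode
ORIC2_POS = 0
DIF2_POS = 506_000       # ~30 kb from the chr2 antipode
RRN_LEFT_POS = 2_340_000  # rRNA operon on the left replichore, transcribed
                          # counterclockwise (codirectional with WT forks)

DEFAULT_TAU = 40.0       # doubling time, minutes (minimal-medium-like)
DEFAULT_V = 30_000.0     # fork speed, bp/minute
DEFAULT_BIN = 1_000
DEFAULT_DEPTH = 2_000.0  # read starts per bin at the profile minimum;
                         # ~217x depth equivalent for 75 bp reads and 1 kb bins


@dataclass(frozen=True)
class RrnPerturbation:
    """Local copy-number depression for forks colliding head-on with
    transcription.

    Bins replicated by a fork travelling against ``transcription_direction``,
    within ``extent`` bp downstream of the locus along the fork's travel
    direction, have their expected MF multiplied by ``1 - magnitude * ramp``
    where the ramp decays linearly from 1 at the locus to 0 at ``extent``.
    """

    replicon: str
    position: int
    transcription_direction: str  # "clockwise" | "counterclockwise"
    magnitude: float
    extent: int

    def __post_init__(self) -> None:
        if not 0 <= self.magnitude < 1:
            raise ModelError(f"magnitude must be in [0, 1), got {self.magnitude}")
        if self.extent <= 0:
            raise ModelError(f"extent must be > 0, got {self.extent}")
        if self.transcription_direction not in ("clockwise", "counterclockwise"):
            raise ModelError(
                f"bad transcription_direction {self.transcription_direction!r}"
            )


@dataclass
class SyntheticSpec:
    """Full forward-simulation recipe.

    ``sigma`` maps replicon name to the Gaussian fcp spread (bp), either one
    value for all segments or one value per clockwise segment.
    """

    genome: GenomeMap
    origins: list
    params: ReplicationParameters
    bin_size: int = DEFAULT_BIN
    mean_depth: float = DEFAULT_DEPTH
    sigma: dict = field(default_factory=dict)
    perturbations: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ModelError(f"mean_depth must be > 0, got {self.mean_depth}")
        for v in self.sigma.values():
            vals = np.atleast_1d(np.asarray(v, dtype=float))
            if np.any(vals < 0):
                raise ModelError("sigma values must be >= 0")

    def sigmas_for(self, replicon: str, n_segments: int) -> np.ndarray:
        v = self.sigma.get(replicon, 0.0)
        vals = np.atleast_1d(np.asarray(v, dtype=float))
        if vals.size == 1:
            return np.full(n_segments, float(vals[0]))
        if vals.size != n_segments:
            raise ModelError(
                f"{replicon}: {vals.size} sigma values for {n_segments} segments"
            )
        return vals


def _fork_direction(x: np.ndarray, origins, params, replicon: Replicon):
    """Travel direction (+1 clockwise, -1 counterclockwise) of the fork that
    replicates each position under the piecewise (sigma=0) model."""
    length = replicon.length
    best_age = np.full(x.shape, np.inf)
    direction = np.zeros(x.shape)
    for o in origins:
        if o.replicon != replicon.name:
            continue
        cw = (x - o.position) % length
        ccw = (o.position - x) % length
        for d, dist in ((1.0, cw), (-1.0, ccw)):
            age = o.firing_offset + dist / params.v
            better = age < best_age
            best_age = np.where(better, age, best_age)
            direction = np.where(better, d, direction)
    return direction


def expected_profile(spec: SyntheticSpec) -> list[MarkerFrequencyProfile]:
    """Expected linear-scale marker frequency per bin, unnormalised.

    Per segment the two arms' Cooper–Helmstetter exponentials are mixed by
    the Gaussian convergence-spread weight; head-on perturbations multiply
    the expectation locally.  With all sigmas 0 and no perturbations this is
    exactly ``2^(-age/tau)``.
    """
    params = spec.params
    profiles = []
    for rep in spec.genome.replicons.values():
        n = math.ceil(rep.length / spec.bin_size)
        starts = np.arange(n) * float(spec.bin_size)
        ends = np.minimum(starts + spec.bin_size, rep.length)
        centers = (starts + ends) / 2.0
        mf = np.empty(n)
        segs = segments_between(spec.origins, rep)
        sigmas = spec.sigmas_for(rep.name, len(segs))
        fcps = dict(
            (seg.label, pos)
            for seg, pos in theoretical_fcps(spec.origins, params, rep)
        )
        assigned = np.zeros(n, dtype=bool)
        for seg, sig in zip(segs, sigmas):
            s = seg.arc_coordinate(centers)
            in_seg = (s >= 0) & (s < seg.arc_length) & ~assigned
            assigned |= in_seg
            ss = s[in_seg]
            o_l = seg.left_origin.firing_offset
            o_r = seg.right_origin.firing_offset
            left_log2 = -(o_l + ss / params.v) / params.tau
            right_log2 = -(o_r + (seg.arc_length - ss) / params.v) / params.tau
            fcp_arc = float(seg.arc_coordinate(fcps[seg.label]))
            if sig == 0:
                w = np.where(ss < fcp_arc, 1.0,
                             np.where(ss > fcp_arc, 0.0, 0.5))
            else:
                w = ndtr((fcp_arc - ss) / sig)
            mf[in_seg] = w * np.exp2(left_log2) + (1 - w) * np.exp2(right_log2)
        for pert in spec.perturbations:
            if pert.replicon != rep.name:
                if pert.replicon not in spec.genome.replicons:
                    raise ModelError(
                        f"perturbation replicon {pert.replicon!r} not in genome"
                    )
                continue
            if not 0 <= pert.position < rep.length:
                raise ModelError(
                    f"perturbation position {pert.position} off replicon "
                    f"{rep.name!r}"
                )
            fork_dir = _fork_direction(centers, spec.origins, params, rep)
            head_on = np.where(
                fork_dir > 0,
                pert.transcription_direction == "counterclockwise",
                pert.transcription_direction == "clockwise",
            )
            # distance from the locus downstream along the fork direction
            downstream = np.where(
                fork_dir > 0,
                (centers - pert.position) % rep.length,
                (pert.position - centers) % rep.length,
            )
            hit = head_on & (downstream <= pert.extent)
            ramp = np.where(hit, 1.0 - downstream / pert.extent, 0.0)
            mf *= 1.0 - pert.magnitude * ramp
        with np.errstate(divide="ignore"):
            log2mf = np.log2(mf)
        profiles.append(
            MarkerFrequencyProfile(
                replicon=rep, bin_size=spec.bin_size, mf=mf, log2mf=log2mf,
                mask=np.zeros(n, dtype=bool), normalization_reference=None,
            )
        )
    return profiles


def sample_counts(
    expected: MarkerFrequencyProfile,
    mean_depth: float,
    seed: int,
    *,
    scale_min: float | None = None,
) -> BinnedCoverage:
    """Poisson read counts per bin, ``counts ~ Poisson(mean_depth * MF/minMF)``.

    ``scale_min`` overrides the per-profile minimum, e.g. the global minimum
    across several replicons so their copy-number ratio is preserved.
    Reproducible under ``seed``.
    """
    good = expected.unmasked & np.isfinite(expected.mf)
    if not np.all(expected.mf[good] > 0):
        raise ModelError("expected MF must be > 0 on unmasked bins")
    m = float(np.min(expected.mf[good])) if scale_min is None else float(scale_min)
    rng = np.random.default_rng(seed)
    lam = np.where(good, mean_depth * expected.mf / m, 0.0)
    counts = rng.poisson(lam).astype(float)
    counts[~good] = 0.0
    return BinnedCoverage(expected.replicon, expected.bin_size, counts,
                          mask=~good)


def co_termination_delay(
    genome: GenomeMap,
    chr1_origins,
    params: ReplicationParameters,
    chr2: str = "chr2",
    crts_locus: str = "crtS",
) -> float:
    """The crtS->oriC2 licensing delay (minutes) that makes chr1 and chr2
    terminate simultaneously under the wild-type single-origin program."""
    crts_rep, crts_pos = genome.locus_position(crts_locus)
    chr1_term = max(
        age
        for seg, fcp in theoretical_fcps(
            chr1_origins, params, crts_rep
        )
        for age in [replication_age(fcp, chr1_origins, params, crts_rep)]
    )
    chr2_rep = genome.replicon(chr2)
    chr2_c = (chr2_rep.length / 2.0) / params.v
    crts_age = replication_age(crts_pos, chr1_origins, params, crts_rep)
    delay = chr1_term - chr2_c - crts_age
    return max(0.0, float(delay))


def default_genome(
    chr1_length: int = CHR1_LENGTH,
    chr2_length: int = CHR2_LENGTH,
) -> GenomeMap:
    """Two-chromosome genome with approximate stand-in landmark loci."""
    chr1 = Replicon("chr1", chr1_length, circular=True)
    chr2 = Replicon("chr2", chr2_length, circular=True)
    loci = {
        "oriC1": Locus("chr1", ORIC1_POS),
        "dif1": Locus("chr1", DIF1_POS),
        "crtS": Locus("chr1", (ORIC1_POS - CRTS_OFFSET) % chr1_length),
        "oriL3": Locus("chr1", (ORIC1_POS - ORIL3_OFFSET) % chr1_length),
        "oriR4": Locus("chr1", (ORIC1_POS + ORIR4_OFFSET) % chr1_length),
        "rrn_left": Locus("chr1", RRN_LEFT_POS),
        "oriC2": Locus("chr2", ORIC2_POS),
        "dif2": Locus("chr2", DIF2_POS),
    }
    return GenomeMap(replicons={"chr1": chr1, "chr2": chr2}, loci=loci)


@dataclass
class SimulatedDataset:
    """A ready-to-analyse simulated experiment with its ground truth."""

    genome: GenomeMap
    origins: list
    params: ReplicationParameters
    spec: SyntheticSpec
    expected: list
    coverages: dict
    true_fcps: dict  # replicon -> list of (Segment, fcp position)
    extra_delay: float


def _build_fixture(
    chr1_origin_loci: list[str],
    seed: int,
    *,
    tau: float,
    v: float,
    bin_size: int,
    mean_depth: float,
    sigma: dict,
    extra_delay: float | None,
    perturbations: list,
    genome: GenomeMap | None,
) -> SimulatedDataset:
    genome = genome or default_genome()
    params = ReplicationParameters(tau=tau, v=v)
    chr1_origins = [
        Origin("chr1", genome.loci[name].position, 0.0, name=name)
        for name in chr1_origin_loci
    ]
    if extra_delay is None:
        # the licensing delay is an intrinsic cell property: tune it for
        # co-termination under the wild-type program, whatever the strain
        wt = [Origin("chr1", genome.loci["oriC1"].position, 0.0, name="oriC1")]
        extra_delay = co_termination_delay(genome, wt, params)
    oric2 = crts_coupled_offset(genome, chr1_origins, params, extra_delay)
    origins = chr1_origins + [oric2]
    spec = SyntheticSpec(
        genome=genome, origins=origins, params=params, bin_size=bin_size,
        mean_depth=mean_depth, sigma=sigma, perturbations=list(perturbations),
        seed=seed,
    )
    expected = expected_profile(spec)
    global_min = min(float(np.nanmin(p.mf)) for p in expected)
    seeds = np.random.SeedSequence(seed).generate_state(len(expected)) % (2**31)
    coverages = {
        p.replicon.name: sample_counts(
            p, mean_depth, int(s), scale_min=global_min
        )
        for p, s in zip(expected, seeds)
    }
    true_fcps = {
        rep.name: theoretical_fcps(origins, params, rep)
        for rep in genome.replicons.values()
    }
    return SimulatedDataset(
        genome=genome, origins=origins, params=params, spec=spec,
        expected=expected, coverages=coverages, true_fcps=true_fcps,
        extra_delay=float(extra_delay),
    )


def make_wt_like_fixture(
    seed: int,
    *,
    tau: float = DEFAULT_TAU,
    v: float = DEFAULT_V,
    bin_size: int = DEFAULT_BIN,
    mean_depth: float = DEFAULT_DEPTH,
    sigma: dict | None = None,
    extra_delay: float | None = None,
    perturbations: list = (),
    genome: GenomeMap | None = None,
) -> SimulatedDataset:
    """Wild-type-like two-chromosome dataset: one origin per chromosome,
    crtS-coupled chr2 initiation tuned for co-termination, narrow
    convergence zones."""
    if sigma is None:
        sigma = {"chr1": 1_000.0, "chr2": 1_000.0}
    return _build_fixture(
        ["oriC1"], seed, tau=tau, v=v, bin_size=bin_size,
        mean_depth=mean_depth, sigma=sigma, extra_delay=extra_delay,
        perturbations=list(perturbations), genome=genome,
    )


def make_ectopic_fixture(
    arm: str,
    seed: int,
    *,
    tau: float = DEFAULT_TAU,
    v: float = DEFAULT_V,
    bin_size: int = DEFAULT_BIN,
    mean_depth: float = DEFAULT_DEPTH,
    sigma: dict | None = None,
    extra_delay: float | None = None,
    perturbations: list = (),
    genome: GenomeMap | None = None,
) -> SimulatedDataset:
    """Two-origin chr1 dataset with the ectopic oriC1 copy on the left
    (near crtS, 45 kb away) or right replichore (near the terminus side)."""
    if arm not in ("left", "right"):
        raise ModelError(f"arm must be 'left' or 'right', got {arm!r}")
    if sigma is None:
        sigma = {"chr1": 20_000.0, "chr2": 1_000.0}
    ectopic = "oriL3" if arm == "left" else "oriR4"
    return _build_fixture(
        ["oriC1", ectopic], seed, tau=tau, v=v, bin_size=bin_size,
        mean_depth=mean_depth, sigma=sigma, extra_delay=extra_delay,
        perturbations=list(perturbations), genome=genome,
    )


def rrn_head_on_perturbation(
    magnitude: float = 0.3, extent: int = 50_000,
    position: int = RRN_LEFT_POS,
) -> RrnPerturbation:
    """Default head-on rRNA perturbation for the left-ectopic geometry: the
    operon is transcribed counterclockwise (codirectional with wild-type
    forks), so the clockwise fork emerging from oriL3 collides head-on."""
    return RrnPerturbation(
        replicon="chr1", position=position,
        transcription_direction="counterclockwise",
        magnitude=magnitude, extent=extent,
    )
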