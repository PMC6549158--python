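"""Binned coverage I/O, outlier trimming and marker-frequency normalisation.

Marker frequency analysis (MFA) works on read counts binned along each
replicon.  Counts are the number of read *start* positions per bin, which
keeps them Poisson-like under uniform sampling of an exponentially growing
population.  Bins can be masked (outliers, zero coverage); masked bins never
enter totals, minima or any downstream fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeMap, Replicon

__all__ = [
    "CoverageError",
    "BinnedCoverage",
    "MarkerFrequencyProfile",
    "read_bedgraph",
    "write_bedgraph",
    "depth_from_alignments",
    "trim_outlier_bins",
    "normalize_profiles",
]


class CoverageError(ValueError):
    """Malformed coverage input or empty profile."""


def _n_bins(length: int, bin_size: int) -> int:
    return math.ceil(length / bin_size)


@dataclass
class BinnedCoverage:
    """Read-start counts per fixed-width bin on one replicon.

    ``mask`` marks excluded bins (True = excluded).  The last bin may be
    shorter than ``bin_size`` when the replicon length is not a multiple.
    """

    replicon: Replicon
    bin_size: int
    counts: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        expected = _n_bins(self.replicon.length, self.bin_size)
        if self.counts.ndim != 1 or len(self.counts) != expected:
            raise CoverageError(
                f"{self.replicon.name}: expected {expected} bins of size "
                f"{self.bin_size}, got {len(self.counts)}"
            )
        if np.any(self.counts < 0):
            raise CoverageError(f"{self.replicon.name}: negative counts")
        if self.mask is None:
            self.mask = np.zeros(len(self.counts), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise CoverageError("mask/counts shape mismatch")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins, dtype=float) * self.bin_size

    @property
    def bin_ends(self) -> np.ndarray:
        return np.minimum(self.bin_starts + self.bin_size, self.replicon.length)

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_starts + self.bin_ends) / 2.0

    @property
    def unmasked(self) -> np.ndarray:
        return ~self.mask


@dataclass
class MarkerFrequencyProfile:
    """Normalised marker frequencies (linear and log2) per unmasked bin.

    ``mf`` and ``log2mf`` are full-length arrays with NaN at masked bins.
    After :func:`normalize_profiles`, the minimum unmasked ``log2mf`` on the
    ``normalization_reference`` replicon is 0.
    """

    replicon: Replicon
    bin_size: int
    mf: np.ndarray
    log2mf: np.ndarray
    mask: np.ndarray
    normalization_reference: str | None = None

    def __post_init__(self) -> None:
        self.mf = np.asarray(self.mf, dtype=float)
        self.log2mf = np.asarray(self.log2mf, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_bins(self) -> int:
        return len(self.mf)

    @property
    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins, dtype=float) * self.bin_size

    @property
    def bin_ends(self) -> np.ndarray:
        return np.minimum(self.bin_starts + self.bin_size, self.replicon.length)

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_starts + self.bin_ends) / 2.0

    @property
    def unmasked(self) -> np.ndarray:
        return ~self.mask

    def as_coverage(self) -> BinnedCoverage:
        """Linear MF values repackaged as (float) coverage, e.g. for
        re-normalisation."""
        counts = np.where(self.mask, 0.0, self.mf)
        return BinnedCoverage(self.replicon, self.bin_size, counts, self.mask.copy())


def read_bedgraph(
    path, genome: GenomeMap | None = None, replicon: Replicon | None = None
) -> BinnedCoverage:
    """Read a single-replicon bedGraph (chrom, start, end, value) into bins.

    Intervals must be uniform width (the final interval may be truncated at
    the replicon end); values must be non-negative.  Bins absent from the
    file get count 0.  All mask flags start False.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
        skiprows=lambda i: False,
    )
    df = df[~df["chrom"].str.startswith(("track", "browser"))]
    if df.empty:
        raise CoverageError(f"{path}: no records")
    chroms = df["chrom"].unique()
    if len(chroms) > 1:
        raise CoverageError(
            f"{path}: expected a single replicon, found {sorted(chroms)}"
        )
    chrom = chroms[0]
    if replicon is None:
        if genome is not None:
            if chrom not in genome.replicons:
                raise CoverageError(f"{path}: unknown replicon {chrom!r}")
            replicon = genome.replicons[chrom]
    elif chrom != replicon.name:
        raise CoverageError(
            f"{path}: chromosome {chrom!r} does not match replicon "
            f"{replicon.name!r}"
        )

    start = df["start"].to_numpy(dtype=np.int64)
    end = df["end"].to_numpy(dtype=np.int64)
    value = df["value"].to_numpy(dtype=float)
    if np.any(value < 0):
        raise CoverageError(f"{path}: negative values")
    widths = end - start
    if np.any(widths <= 0):
        raise CoverageError(f"{path}: empty or inverted intervals")
    bin_size = int(widths.max())
    if replicon is None:
        replicon = Replicon(chrom, int(end.max()), circular=True)
    # every interval must be a full bin, except a final partial bin at the
    # replicon end
    full = widths == bin_size
    partial_ok = (end == replicon.length) & (widths < bin_size)
    if not np.all(full | partial_ok):
        raise CoverageError(f"{path}: non-uniform interval widths")
    if np.any(start % bin_size != 0):
        raise CoverageError(f"{path}: intervals not aligned to bin grid")
    if end.max() > replicon.length:
        raise CoverageError(
            f"{path}: interval end {end.max()} beyond replicon length "
            f"{replicon.length}"
        )
    idx = start // bin_size
    if len(np.unique(idx)) != len(idx):
        raise CoverageError(f"{path}: overlapping intervals")
    counts = np.zeros(_n_bins(replicon.length, bin_size), dtype=float)
    counts[idx] = value
    return BinnedCoverage(replicon, bin_size, counts)


def write_bedgraph(
    path, replicon: Replicon, bin_size: int, values: Sequence[float],
    mask: np.ndarray | None = None, float_format: str = "%.10g",
) -> None:
    """Write per-bin values as bedGraph; masked bins are omitted."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    starts = np.arange(n, dtype=np.int64) * bin_size
    ends = np.minimum(starts + bin_size, replicon.length)
    keep = np.ones(n, dtype=bool) if mask is None else ~np.asarray(mask, bool)
    with open(path, "w") as fh:
        for s, e, v in zip(starts[keep], ends[keep], values[keep]):
            fh.write(f"{replicon.name}\t{s}\t{e}\t{float_format % v}\n")


def depth_from_alignments(
    path, genome: GenomeMap, bin_size: int, replicon: str | None = None
):
    """Count read start positions per bin from a coordinate-sorted, indexed
    alignment file.

    Unmapped, secondary and supplementary records are ignored.  Returns one
    :class:`BinnedCoverage` when ``replicon`` is given, otherwise a dict
    keyed by replicon name for every genome replicon present in the file.
    """
    import pysam

    with pysam.AlignmentFile(str(path)) as af:
        try:
            af.check_index()
        except (ValueError, AttributeError) as exc:
            raise CoverageError(f"{path}: missing index ({exc})") from None
        names = set(af.references)
        wanted = [replicon] if replicon is not None else [
            r for r in genome.replicons if r in names
        ]
        if replicon is not None and replicon not in names:
            raise CoverageError(
                f"{path}: replicon {replicon!r} not among alignment references"
            )
        if not wanted:
            raise CoverageError(
                f"{path}: no alignment reference matches a genome replicon"
            )
        out: dict[str, BinnedCoverage] = {}
        for name in wanted:
            if name not in genome.replicons:
                raise CoverageError(f"unknown replicon {name!r}")
            rep = genome.replicons[name]
            ref_len = af.get_reference_length(name)
            if ref_len != rep.length:
                raise CoverageError(
                    f"{path}: reference {name!r} length {ref_len} != genome "
                    f"length {rep.length}"
                )
            counts = np.zeros(_n_bins(rep.length, bin_size), dtype=float)
            for read in af.fetch(name):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                counts[read.reference_start // bin_size] += 1
            out[name] = BinnedCoverage(rep, bin_size, counts)
    return out[replicon] if replicon is not None else out


def trim_outlier_bins(cov: BinnedCoverage, iqr_factor: float = 3.0) -> BinnedCoverage:
    """Mask zero-count bins and Tukey-fence outliers.

    Quartiles are computed over the currently unmasked bins of the replicon;
    bins with count 0 or outside ``[Q1 - f*IQR, Q3 + f*IQR]`` are masked.
    Counts are unchanged.  With zero IQR (all counts equal) only zero-count
    bins are masked.
    """
    if iqr_factor <= 0:
        raise CoverageError(f"iqr_factor must be > 0, got {iqr_factor}")
    unmasked = cov.unmasked
    if unmasked.sum() < 20:
        raise CoverageError(
            f"{cov.replicon.name}: need >= 20 unmasked bins to trim, have "
            f"{int(unmasked.sum())}"
        )
    vals = cov.counts[unmasked]
    q1, q3 = np.percentile(vals, [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - iqr_factor * iqr, q3 + iqr_factor * iqr
    new_mask = cov.mask | (cov.counts == 0) | (cov.counts < lo) | (cov.counts > hi)
    if new_mask.all():
        raise CoverageError(f"{cov.replicon.name}: profile empty after trimming")
    return BinnedCoverage(cov.replicon, cov.bin_size, cov.counts.copy(), new_mask)


def normalize_profiles(
    covs: Iterable[BinnedCoverage], reference: str
) -> list[MarkerFrequencyProfile]:
    """Turn binned counts into marker-frequency profiles on one common scale.

    Counts are divided by the grand total of unmasked counts across all
    replicons, then every value is divided by the minimum unmasked value on
    the reference replicon, so that the minimum log2 marker frequency on the
    reference is exactly 0.  Cross-replicon copy-number ratios (e.g.
    chr2/chr1) are preserved.
    """
    covs = list(covs)
    by_name = {c.replicon.name: c for c in covs}
    if reference not in by_name:
        raise CoverageError(f"reference replicon {reference!r} absent from input")
    ref = by_name[reference]
    if not ref.unmasked.any():
        raise CoverageError(f"reference replicon {reference!r} is fully masked")
    total = sum(float(c.counts[c.unmasked].sum()) for c in covs)
    if total <= 0:
        raise CoverageError("no reads in unmasked bins")
    ref_min = float(ref.counts[ref.unmasked].min()) / total
    if ref_min <= 0:
        raise CoverageError(
            f"reference replicon {reference!r} has zero-count unmasked bins; "
            "trim before normalising"
        )
    profiles = []
    for cov in covs:
        mf = np.where(cov.mask, np.nan, cov.counts / total / ref_min)
        with np.errstate(divide="ignore"):
            log2mf = np.where(cov.mask, np.nan, np.log2(mf))
        profiles.append(
            MarkerFrequencyProfile(
                replicon=cov.replicon,
                bin_size=cov.bin_size,
                mf=mf,
                log2mf=log2mf,
                mask=cov.mask.copy(),
                normalization_reference=reference,
            )
        )
    return profiles
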