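"""Replicon geometry and genome configuration.

A genome is a set of (usually circular) replicons plus named landmark loci
(origins, *dif* sites, *crtS*, rRNA operons, ...).  All coordinates are
0-based, half-open internally; human-readable reports convert to 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "GenomeConfigError",
    "Replicon",
    "Locus",
    "GenomeMap",
    "parse_genome_config",
    "circular_distance",
]


class GenomeConfigError(ValueError):
    """Invalid genome configuration or coordinate arithmetic request."""


@dataclass(frozen=True)
class Replicon:
    """One replicon (chromosome) of the genome."""

    name: str
    length: int
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.name:
            raise GenomeConfigError("replicon name must be non-empty")
        if int(self.length) <= 0:
            raise GenomeConfigError(
                f"replicon {self.name!r}: length must be > 0, got {self.length}"
            )
        object.__setattr__(self, "length", int(self.length))


@dataclass(frozen=True)
class Locus:
    """A named position on a replicon (0-based)."""

    replicon: str
    position: int


@dataclass
class GenomeMap:
    """Replicons plus named landmark loci.

    Invariants: replicon names unique; every locus refers to a known replicon
    and lies in ``[0, replicon.length)``.
    """

    replicons: dict[str, Replicon]
    loci: dict[str, Locus] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, locus in self.loci.items():
            self._check_locus(name, locus)

    def _check_locus(self, name: str, locus: Locus) -> None:
        if locus.replicon not in self.replicons:
            raise GenomeConfigError(
                f"locus {name!r} refers to unknown replicon {locus.replicon!r}"
            )
        length = self.replicons[locus.replicon].length
        if not 0 <= locus.position < length:
            raise GenomeConfigError(
                f"locus {name!r} position {locus.position} outside "
                f"[0, {length}) on replicon {locus.replicon!r}"
            )

    def replicon(self, name: str) -> Replicon:
        try:
            return self.replicons[name]
        except KeyError:
            raise GenomeConfigError(f"unknown replicon {name!r}") from None

    def locus(self, name: str) -> Locus:
        try:
            return self.loci[name]
        except KeyError:
            raise GenomeConfigError(f"unknown locus {name!r}") from None

    def locus_position(self, name: str) -> tuple[Replicon, int]:
        loc = self.locus(name)
        return self.replicons[loc.replicon], loc.position

    def add_locus(self, name: str, replicon: str, position: int) -> None:
        if name in self.loci:
            raise GenomeConfigError(f"duplicate locus name {name!r}")
        locus = Locus(replicon, int(position))
        self._check_locus(name, locus)
        self.loci[name] = locus

    def loci_on(self, replicon: str) -> dict[str, int]:
        """Locus name -> position for loci on one replicon."""
        return {
            n: l.position for n, l in self.loci.items() if l.replicon == replicon
        }


def _resolve_locus_entry(
    name: str,
    entry: Mapping,
    replicons: dict[str, Replicon],
    resolved: dict[str, Locus],
) -> Locus:
    """Resolve one locus entry; supports absolute and relative placement.

    Absolute: ``{replicon: chr1, position: 123}``.
    Relative: ``{replicon: chr1, from: oriC1, offset_bp: 650000,
    replichore: left}`` — ``left`` counts counterclockwise (decreasing
    coordinate) from the anchor, ``right`` clockwise.
    """
    rep_name = entry.get("replicon")
    if rep_name is None:
        raise GenomeConfigError(f"locus {name!r}: missing 'replicon'")
    if rep_name not in replicons:
        raise GenomeConfigError(
            f"locus {name!r} refers to unknown replicon {rep_name!r}"
        )
    length = replicons[rep_name].length
    if "position" in entry:
        position = int(entry["position"])
    elif "from" in entry:
        anchor_name = entry["from"]
        if anchor_name not in resolved:
            raise GenomeConfigError(
                f"locus {name!r}: anchor {anchor_name!r} not defined before it"
            )
        anchor = resolved[anchor_name]
        if anchor.replicon != rep_name:
            raise GenomeConfigError(
                f"locus {name!r}: anchor {anchor_name!r} is on another replicon"
            )
        offset = int(entry["offset_bp"])
        side = entry.get("replichore", "right")
        if side not in ("left", "right"):
            raise GenomeConfigError(
                f"locus {name!r}: replichore must be 'left' or 'right'"
            )
        delta = -offset if side == "left" else offset
        if replicons[rep_name].circular:
            position = (anchor.position + delta) % length
        else:
            position = anchor.position + delta
    else:
        raise GenomeConfigError(
            f"locus {name!r}: need 'position' or 'from'/'offset_bp'"
        )
    return Locus(rep_name, position)


def parse_genome_config(source) -> GenomeMap:
    """Parse a genome configuration into a validated :class:`GenomeMap`.

    ``source`` may be a mapping, a YAML string, or a path to a YAML file with
    the layout::

        replicons:
          - {name: chr1, length: 2961149, circular: true}
        loci:
          oriC1: {replicon: chr1, position: 0}
          oriL3: {replicon: chr1, from: oriC1, offset_bp: 650000, replichore: left}
    """
    if isinstance(source, Mapping):
        data = source
    else:
        text = (
            Path(source).read_text()
            if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists())
            else str(source)
        )
        data = yaml.safe_load(text)
    if not isinstance(data, Mapping) or "replicons" not in data:
        raise GenomeConfigError("genome config must declare 'replicons'")

    replicons: dict[str, Replicon] = {}
    for entry in data["replicons"]:
        rep = Replicon(
            name=entry["name"],
            length=int(entry["length"]),
            circular=bool(entry.get("circular", True)),
        )
        if rep.name in replicons:
            raise GenomeConfigError(f"duplicate replicon name {rep.name!r}")
        replicons[rep.name] = rep

    loci: dict[str, Locus] = {}
    for name, entry in (data.get("loci") or {}).items():
        if name in loci:
            raise GenomeConfigError(f"duplicate locus name {name!r}")
        loci[name] = _resolve_locus_entry(name, entry, replicons, loci)
    return GenomeMap(replicons=replicons, loci=loci)


def circular_distance(
    replicon: Replicon, a: int, b: int, direction: str = "shortest"
) -> int:
    """Arc length from ``a`` to ``b`` along a replicon.

    ``direction`` is ``clockwise`` (increasing coordinate), ``counterclockwise``
    or ``shortest``.  On a linear replicon a direction whose arc would cross
    the end is an error.
    """
    length = replicon.length
    for name, pos in (("a", a), ("b", b)):
        if not 0 <= pos < length:
            raise GenomeConfigError(
                f"position {name}={pos} outside [0, {length}) on {replicon.name!r}"
            )
    if replicon.circular:
        cw = (b - a) % length
        ccw = (a - b) % length
    else:
        cw = b - a if b >= a else None
        ccw = a - b if a >= b else None
    if direction == "clockwise":
        if cw is None:
            raise GenomeConfigError(
                f"clockwise arc {a}->{b} crosses the end of linear replicon "
                f"{replicon.name!r}"
            )
        return cw
    if direction == "counterclockwise":
        if ccw is None:
            raise GenomeConfigError(
                f"counterclockwise arc {a}->{b} crosses the end of linear "
                f"replicon {replicon.name!r}"
            )
        return ccw
    if direction == "shortest":
        arcs = [d for d in (cw, ccw) if d is not None]
        return min(arcs)
    raise GenomeConfigError(f"unknown direction {direction!r}")
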