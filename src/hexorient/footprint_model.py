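"""Deterministic particle-footprint model for ExoIII stall prediction.

A fully wrapped nucleosome protects ``[-nuc_half, +nuc_half]`` around its
dyad (default 72 bp per side, taken as an empirical stall parameter).  A
hexasome is unwrapped on the dimer-distal side by ``distal_unwrap`` bp
(default 40, so the distal stall sits at 72 - 40 = +32 for a dimer-left
hexasome); a tetrasome loses that much on both sides.  ExoIII digests each
strand 3'->5', so the stall it reports on a strand is the footprint edge
first met from that strand's 3' end, and the surviving 5'-labeled fragment
runs from the label to the stall.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .sequence_designer import NpsConstruct

__all__ = [
    "ParticleKind",
    "FootprintParams",
    "ParticleFootprint",
    "StrandStall",
    "footprint",
    "stall_positions",
    "mixed_population_ladder",
]


class ParticleKind(str, enum.Enum):
    NUCLEOSOME = "nucleosome"
    HEXASOME = "hexasome"
    TETRASOME = "tetrasome"


@dataclass(frozen=True)
class FootprintParams:
    nuc_half: int = 72
    distal_unwrap: int = 40

    def __post_init__(self) -> None:
        if not 0 < self.distal_unwrap < self.nuc_half:
            raise ValueError("need 0 < distal_unwrap < nuc_half")


@dataclass(frozen=True)
class ParticleFootprint:
    kind: ParticleKind
    dimer_side: str  # "left", "right" or "none"
    interval: tuple[int, int]  # protected, dyad-relative, inclusive

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0] + 1


@dataclass(frozen=True)
class StrandStall:
    strand: str  # "top" (5' label on the left) or "bottom" (5' label on the right)
    stall: int  # dyad-relative coordinate where ExoIII halts
    fragment_length: int  # labeled 5' end to the stall, in nt


def footprint(
    kind: ParticleKind | str,
    dimer_side: str = "none",
    params: FootprintParams = FootprintParams(),
) -> ParticleFootprint:
    """Protected interval for a particle.

    Nucleosome: [-nuc_half, +nuc_half].  Hexasome: the dimer-distal side is
    shortened by ``distal_unwrap`` (dimer on the left protects
    [-nuc_half, +nuc_half - distal_unwrap]; dimer right is the mirror image).
    Tetrasome (an extrapolation of the model, not a measured footprint): both
    sides shortened by ``distal_unwrap``.
    """
    kind = ParticleKind(kind)
    h, u = params.nuc_half, params.distal_unwrap
    if kind is ParticleKind.NUCLEOSOME:
        interval = (-h, h)
        dimer_side = "none"
    elif kind is ParticleKind.TETRASOME:
        interval = (-(h - u), h - u)
        dimer_side = "none"
    else:
        if dimer_side == "left":
            interval = (-h, h - u)
        elif dimer_side == "right":
            interval = (-(h - u), h)
        else:
            raise ValueError("hexasome requires dimer_side 'left' or 'right'")
    return ParticleFootprint(kind, dimer_side, interval)


def stall_positions(
    fp: ParticleFootprint, construct: NpsConstruct
) -> tuple[StrandStall, StrandStall]:
    """Per-strand ExoIII stall and protected 5'-labeled fragment length.

    The top strand (labeled at the left 5' end) is digested from the right,
    stalling at the footprint's right edge; the bottom strand mirrors it.
    The construct's linkers must cover the footprint.
    """
    left, right = fp.interval
    n = len(construct.seq)
    d = construct.dyad_index
    if d + left < 0 or d + right >= n:
        raise ValueError("footprint extends outside the construct")
    top = StrandStall("top", right, d + right + 1)
    bottom = StrandStall("bottom", left, (n - d - 1) + (-left) + 1)
    return top, bottom


def mixed_population_ladder(
    fractions: dict[str, float],
    params: FootprintParams = FootprintParams(),
) -> dict[int, float]:
    """Expected stall-position weights for a mixture of particle species.

    ``fractions`` maps ``"nucleosome"``, ``"hexasome_left"``,
    ``"hexasome_right"`` or ``"tetrasome"`` to population fractions summing
    to 1.  Each species contributes its weight at both footprint edges; a
    50/50 left/right hexasome mixture therefore yields the symmetric stall
    set {-72, -32, +32, +72} with equal weights.
    """
    vals = np.array(list(fractions.values()), dtype=float)
    if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    ladder: dict[int, float] = {}
    for species, frac in fractions.items():
        if species.startswith("hexasome"):
            side = species.split("_", 1)[1]
            fp = footprint(ParticleKind.HEXASOME, side, params)
        else:
            fp = footprint(ParticleKind(species), params=params)
        for edge in fp.interval:
            ladder[edge] = ladder.get(edge, 0.0) + frac
    return dict(sorted(ladder.items()))
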