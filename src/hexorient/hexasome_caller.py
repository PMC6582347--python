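"""Orientation calling: nucleosome vs. upstream/downstream-biased hexasome.

A particle is classified from its H2B (heterodimer reporter) and H4 (tetramer
control) tag totals on the gene-upstream and gene-downstream sides of the
dyad.  A side is *asymmetric* towards the larger total when that total is at
least ``fold_asym`` (default 2) times the other, and *symmetric* when the two
totals are within ``fold_sym`` (default 1.3) of each other; intermediate
ratios are indeterminate.  An H2B-asymmetric, H4-symmetric particle is an
oriented hexasome; symmetric in both is a nucleosome; an H4-asymmetric
particle is excluded (it likely reflects a mispositioned particle rather than
dimer loss) unless the H4 filter is relaxed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ParticleRecord

__all__ = [
    "Side",
    "Label",
    "CallerConfig",
    "OrientationCall",
    "side_symmetry",
    "classify_particle",
    "call_all",
]


class Side(str, enum.Enum):
    ASYMMETRIC_UP = "asymmetric_up"
    ASYMMETRIC_DOWN = "asymmetric_down"
    SYMMETRIC = "symmetric"
    INDETERMINATE = "indeterminate"


class Label(str, enum.Enum):
    HEX_UP = "HEX_UP"
    HEX_DOWN = "HEX_DOWN"
    NUCLEOSOME = "NUCLEOSOME"
    AMBIGUOUS = "AMBIGUOUS"
    EXCLUDED_H4 = "EXCLUDED_H4"


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds for the fold-change classification rules.

    fold_asym
        Minimum fold difference for a side to be called asymmetric (>= is
        asymmetric; boundary included).
    fold_sym
        Maximum fold difference for a side to be called symmetric (<= is
        symmetric; boundary included).
    require_h4_symmetry
        If True (strict mode), particles with non-symmetric H4 are excluded;
        if False (relaxed mode) the H4 condition is skipped entirely.
    window_half
        Half-width in bp of the dyad window the tag totals were summed over;
        carried for provenance, not used by the rules.
    use_h2a
        Optional second heterodimer reporter: if True, the H2A side call must
        agree with H2B for a hexasome call, otherwise the particle is
        ambiguous.
    """

    fold_asym: float = 2.0
    fold_sym: float = 1.3
    require_h4_symmetry: bool = True
    window_half: int = 74
    use_h2a: bool = False

    def __post_init__(self) -> None:
        if not self.fold_asym > self.fold_sym >= 1.0:
            raise ValueError(
                f"need fold_asym > fold_sym >= 1, got {self.fold_asym}, {self.fold_sym}"
            )


@dataclass(frozen=True)
class OrientationCall:
    label: Label
    h2b_ratio: float  # upstream / downstream; inf if down == 0 < up, nan if 0/0
    h4_ratio: float


def _ratio(up: float, down: float) -> float:
    if down == 0.0:
        return float("nan") if up == 0.0 else float("inf")
    return up / down


def side_symmetry(up: float, down: float, cfg: CallerConfig = CallerConfig()) -> Side:
    """Classify one histone's up/down tag totals.

    ``(0, 0)`` is indeterminate; a single zero with a nonzero partner is
    asymmetric (the ratio is treated as +inf).
    """
    if up < 0 or down < 0:
        raise ValueError(f"tag totals must be non-negative, got ({up}, {down})")
    if up == 0.0 and down == 0.0:
        return Side.INDETERMINATE
    if up >= cfg.fold_asym * down:
        return Side.ASYMMETRIC_UP
    if down >= cfg.fold_asym * up:
        return Side.ASYMMETRIC_DOWN
    if max(up, down) <= cfg.fold_sym * min(up, down):
        return Side.SYMMETRIC
    return Side.INDETERMINATE


def classify_particle(
    p: ParticleRecord, cfg: CallerConfig = CallerConfig()
) -> OrientationCall:
    """Apply the fold-change rules to one particle."""
    h2b_up, h2b_down = p.tag("H2B", "upstream"), p.tag("H2B", "downstream")
    h4_up, h4_down = p.tag("H4", "upstream"), p.tag("H4", "downstream")
    h2b = side_symmetry(h2b_up, h2b_down, cfg)
    h4 = side_symmetry(h4_up, h4_down, cfg)
    call = _label(h2b, h4, cfg)
    if cfg.use_h2a and call in (Label.HEX_UP, Label.HEX_DOWN):
        h2a = side_symmetry(p.tag("H2A", "upstream"), p.tag("H2A", "downstream"), cfg)
        expected = Side.ASYMMETRIC_UP if call is Label.HEX_UP else Side.ASYMMETRIC_DOWN
        if h2a is not expected:
            call = Label.AMBIGUOUS
    return OrientationCall(call, _ratio(h2b_up, h2b_down), _ratio(h4_up, h4_down))


def _label(h2b: Side, h4: Side, cfg: CallerConfig) -> Label:
    if cfg.require_h4_symmetry and h4 is not Side.SYMMETRIC:
        return Label.EXCLUDED_H4
    if h2b is Side.ASYMMETRIC_UP:
        return Label.HEX_UP
    if h2b is Side.ASYMMETRIC_DOWN:
        return Label.HEX_DOWN
    if h2b is Side.SYMMETRIC:
        if not cfg.require_h4_symmetry or h4 is Side.SYMMETRIC:
            return Label.NUCLEOSOME
    return Label.AMBIGUOUS


def call_all(
    particles: list[ParticleRecord], cfg: CallerConfig = CallerConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every particle.

    Returns ``(calls, summary)``: one row per particle with its label and the
    H2B/H4 up:down ratios, and a (gene_index x label) count table whose total
    equals the number of particles.
    """
    if not particles:
        raise ValueError("empty particle list")
    rows = []
    for p in particles:
        call = classify_particle(p, cfg)
        rows.append(
            {
                "gene_id": p.gene_id,
                "chrom": p.chrom,
                "strand": p.strand,
                "gene_index": p.gene_index,
                "dyad": p.dyad,
                "label": call.label.value,
                "h2b_ratio": call.h2b_ratio,
                "h4_ratio": call.h4_ratio,
            }
        )
    calls = pd.DataFrame(rows)
    summary = (
        calls.pivot_table(index="gene_index", columns="label", values="gene_id",
                          aggfunc="count", fill_value=0)
        .reindex(columns=[lab.value for lab in Label], fill_value=0)
    )
    summary.columns.name = "label"
    return calls, summary
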