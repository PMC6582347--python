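"""Widom-601 chimera construction and orientation-biasing sequence design.

A nucleosome positioning sequence (NPS) construct carries a dyad index;
regions are addressed in dyad-relative inclusive coordinates (index =
dyad_index + relative position).  Chimeras are built by *interchanging* two
equal-length regions, each replaced by the reverse complement of the other —
the operation used to swap the strong and weak H2A-H2B binding segments of
the 601 NPS (e.g. -45..-30 with 30..45, or -45..-23 with 23..45).

Orientation-biasing candidates are drawn per position from a supplied
23-position nucleotide frequency profile, substituted into the chosen region,
scored against a motif set, ranked by best exact hit p-value, and retained
below a significance cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .motif_analysis import (
    _SCORE_TOL,
    ScoringMatrix,
    _encode,
    null_distribution,
    score_offsets,
)
from .position_stats import revcomp

__all__ = [
    "NpsConstruct",
    "DesignConfig",
    "DesignResult",
    "interchange_regions",
    "replace_region_with",
    "extract_region",
    "sample_region_sequence",
    "design_oriented",
]

Region = tuple[int, int]  # dyad-relative, inclusive on both ends


@dataclass(frozen=True)
class NpsConstruct:
    """A positioning-sequence construct with an annotated dyad."""

    name: str
    seq: str
    dyad_index: int  # 0-based index of the dyad base within seq
    regions: tuple[tuple[str, int, int], ...] = ()  # (label, start, end), dyad-relative

    def __post_init__(self) -> None:
        if not 0 <= self.dyad_index < len(self.seq):
            raise ValueError("dyad index outside the sequence")
        for label, start, end in self.regions:
            self._check_region((start, end), label)

    def _check_region(self, region: Region, label: str = "") -> tuple[int, int]:
        start, end = region
        if start > end:
            raise ValueError(f"region {label or region}: start > end")
        a = self.dyad_index + start
        b = self.dyad_index + end
        if a < 0 or b >= len(self.seq):
            raise ValueError(f"region {label or region} outside the sequence")
        return a, b


def extract_region(nps: NpsConstruct, region: Region) -> str:
    a, b = nps._check_region(region)
    return nps.seq[a:b + 1]


def interchange_regions(
    nps: NpsConstruct, region_a: Region, region_b: Region, name: str | None = None
) -> NpsConstruct:
    """Swap two regions, each becoming the reverse complement of the other.

    An involution: applying the same interchange twice restores the input.
    Regions must be equal length and non-overlapping.
    """
    a0, a1 = nps._check_region(region_a)
    b0, b1 = nps._check_region(region_b)
    if (a1 - a0) != (b1 - b0):
        raise ValueError("regions must have equal length")
    if max(a0, b0) <= min(a1, b1):
        raise ValueError("regions must not overlap")
    old_a = nps.seq[a0:a1 + 1]
    old_b = nps.seq[b0:b1 + 1]
    chars = list(nps.seq)
    chars[a0:a1 + 1] = revcomp(old_b)
    chars[b0:b1 + 1] = revcomp(old_a)
    return replace(nps, name=name or f"{nps.name}-interchange", seq="".join(chars))


def replace_region_with(
    nps: NpsConstruct, region: Region, replacement: str, name: str | None = None
) -> NpsConstruct:
    """Substitute ``replacement`` at dyad-relative ``region``; rest unchanged."""
    a, b = nps._check_region(region)
    if len(replacement) != b - a + 1:
        raise ValueError(
            f"replacement length {len(replacement)} != region length {b - a + 1}"
        )
    chars = list(nps.seq)
    chars[a:b + 1] = replacement.upper()
    return replace(nps, name=name or f"{nps.name}-replaced", seq="".join(chars))


@dataclass(frozen=True)
class DesignConfig:
    """Candidate generation and retention settings for biasing-sequence design."""

    n_candidates: int = 10000
    region: Region = (-45, -23)
    p_cutoff: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_candidates < 0:
            raise ValueError("n_candidates must be non-negative")
        if not 0 < self.p_cutoff <= 1:
            raise ValueError("p_cutoff must be in (0, 1]")


@dataclass
class DesignResult:
    candidates: pd.DataFrame  # sequence, best_p, best_motif, retained; ranked
    retained: list[NpsConstruct]


def sample_region_sequence(freqs: np.ndarray, rng: np.random.Generator) -> str:
    """Draw one sequence with independent per-position base frequencies.

    ``freqs`` has one row per position with probabilities over A, C, G, T.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 2 or freqs.shape[1] != 4:
        raise ValueError("freqs must be (n_positions, 4)")
    if np.any(freqs < 0) or np.any(np.abs(freqs.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("each row of freqs must be a probability vector")
    cum = freqs.cumsum(axis=1)
    u = rng.random(len(freqs))
    idx = (u[:, None] >= cum).sum(axis=1)
    return "".join("ACGT"[i] for i in idx)


def _best_pvalues(seqs: list[str], motifs: list[ScoringMatrix]) -> tuple[np.ndarray, list[str]]:
    """Best (smallest) exact hit p-value per sequence over motifs and strands."""
    best_p = np.ones(len(seqs))
    best_m = [""] * len(seqs)
    for sm in motifs:
        values, probs = null_distribution(sm)
        tail = np.cumsum(probs[::-1])[::-1]
        for si, seq in enumerate(seqs):
            for s in (seq, revcomp(seq)):
                scores = score_offsets(_encode(s), sm)
                scores = scores[np.isfinite(scores)]
                if len(scores) == 0:
                    continue
                idx = np.searchsorted(values, scores.max() - _SCORE_TOL, side="left")
                p = float(tail[idx]) if idx < len(values) else 0.0
                if p < best_p[si]:
                    best_p[si] = p
                    best_m[si] = sm.name
    return best_p, best_m


def design_oriented(
    nps: NpsConstruct,
    freqs: np.ndarray,
    motifs: list[ScoringMatrix],
    cfg: DesignConfig = DesignConfig(),
) -> DesignResult:
    """Generate, score and filter orientation-biasing region replacements.

    ``cfg.n_candidates`` replacement sequences are drawn from ``freqs``,
    substituted at ``cfg.region``, and the replaced region is scored against
    every motif on both strands; candidates are ranked by best hit p-value
    (ties broken lexicographically by sequence, so ranking is independent of
    generation order) and retained when p < ``cfg.p_cutoff``.
    """
    if not motifs:
        raise ValueError("motif list must be non-empty")
    a, b = nps._check_region(cfg.region)
    region_len = b - a + 1
    freqs = np.asarray(freqs, dtype=float)
    if len(freqs) != region_len:
        raise ValueError(
            f"freqs length {len(freqs)} != region length {region_len}"
        )
    rng = np.random.default_rng(cfg.seed)
    seqs = [sample_region_sequence(freqs, rng) for _ in range(cfg.n_candidates)]
    if not seqs:
        return DesignResult(
            pd.DataFrame(columns=["sequence", "best_p", "best_motif", "retained"]),
            [],
        )
    best_p, best_m = _best_pvalues(seqs, motifs)
    df = pd.DataFrame({"sequence": seqs, "best_p": best_p, "best_motif": best_m})
    df = df.sort_values(["best_p", "sequence"], kind="mergesort").reset_index(drop=True)
    df["retained"] = df["best_p"] < cfg.p_cutoff
    retained = [
        replace_region_with(nps, cfg.region, row.sequence,
                            name=f"{nps.name}-design{rank + 1}")
        for rank, row in enumerate(df[df["retained"]].itertuples())
    ]
    if not retained:
        warnings.warn(
            f"no candidate reached p < {cfg.p_cutoff}; retained set is empty",
            stacklevel=2,
        )
    return DesignResult(df, retained)
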