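"""PWM scanning with exact null p-values and half-window asymmetry tests.

A position frequency matrix is converted to a log2-odds scoring matrix
against a background distribution.  The null distribution of the score of a
random background word is computed exactly: for widths up to
``_EXACT_WIDTH`` by dictionary convolution over the distinct attainable
score sums, and for wider matrices by dynamic programming over a discretized
score lattice.  Hit p-values are exact tail probabilities under that null.

Motif occurrences in dyad-centred windows are split into upstream/downstream
halves and compared with an exact two-sided binomial test; a significantly
asymmetric motif is a *weak* H2A-H2B binding motif when it is enriched on the
dimer-absent half of the oriented hexasomes, and a *strong* binding motif
when enriched on the dimer-present half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import Pfm
from .position_stats import revcomp

__all__ = [
    "ScoringMatrix",
    "MotifHit",
    "HalfCounts",
    "AsymmetryResult",
    "make_scoring_matrix",
    "null_distribution",
    "pvalue_threshold",
    "scan_window",
    "count_halves",
    "binomial_asymmetry",
    "classify_motif",
]

_EXACT_WIDTH = 10  # exact dict DP up to 4**10 words; binned DP beyond

# score-sum keys are merged on a 1e-9 grid position by position, so two
# representations of the same word score can drift by ~width * 5e-10; all
# score comparisons therefore use a slack far above that drift but far below
# the spacing of distinct score levels
_SCORE_TOL = 1e-6

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class ScoringMatrix:
    """Log2-odds scores per (position, base) against a background."""

    name: str
    scores: np.ndarray  # (width, 4)
    background: np.ndarray  # (4,)
    pseudocount: float
    _null: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def width(self) -> int:
        return int(self.scores.shape[0])


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    start: int  # 0-based offset within the window
    strand: str  # "+" or "-"
    width: int
    score: float
    pvalue: float


@dataclass(frozen=True)
class HalfCounts:
    n_up: int
    n_down: int
    n_center: int = 0  # hits whose midpoint falls exactly on the dyad

    def __iter__(self):
        return iter((self.n_up, self.n_down))


@dataclass(frozen=True)
class AsymmetryResult:
    motif: str
    n_up: int
    n_down: int
    pvalue: float


def make_scoring_matrix(
    pfm: Pfm,
    background: np.ndarray | None = None,
    pseudocount: float = 0.001,
) -> ScoringMatrix:
    """Build log2 odds: score(i, b) = log2((p + pc*bg_b) / ((1 + pc)*bg_b)).

    The background-proportional pseudocount keeps all scores finite.  The
    default background is uniform; a 0-order background estimated from the
    scanned windows may be supplied instead.
    """
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or np.any(background <= 0):
        raise ValueError("background must be 4 positive probabilities")
    if abs(background.sum() - 1.0) > 1e-9:
        raise ValueError("background must sum to 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    num = pfm.probs + pseudocount * background
    den = (1.0 + pseudocount) * background
    scores = np.log2(num / den)
    return ScoringMatrix(pfm.name, scores, background, pseudocount)


def null_distribution(
    sm: ScoringMatrix, precision_bins: int = 10000
) -> tuple[np.ndarray, np.ndarray]:
    """Exact null (score values ascending, probabilities) for a random word.

    Cached on the matrix.  Widths <= 10 use the exact dictionary DP (score
    sums merged at 1e-9 resolution); wider matrices use a lattice DP with
    ``precision_bins`` bins over the attainable score range.
    """
    if sm._null is not None:
        return sm._null
    if sm.width <= _EXACT_WIDTH:
        dist: dict[float, float] = {0.0: 1.0}
        for i in range(sm.width):
            nxt: dict[float, float] = {}
            for s, p in dist.items():
                for b in range(4):
                    key = round(s + sm.scores[i, b], 9)
                    nxt[key] = nxt.get(key, 0.0) + p * sm.background[b]
            dist = nxt
        values = np.array(sorted(dist))
        probs = np.array([dist[v] for v in values])
    else:
        lo = sm.scores.min(axis=1).sum()
        hi = sm.scores.max(axis=1).sum()
        scale = (precision_bins - 1) / max(hi - lo, 1e-12)
        ints = np.rint((sm.scores - sm.scores.min(axis=1, keepdims=True)) * scale)
        ints = ints.astype(np.int64)
        pmf = np.zeros(1)
        pmf[0] = 1.0
        for i in range(sm.width):
            width_i = int(ints[i].max()) + 1
            col = np.zeros(width_i)
            for b in range(4):
                col[ints[i, b]] += sm.background[b]
            pmf = np.convolve(pmf, col)
        values = lo + np.arange(len(pmf)) / scale
        probs = pmf
        keep = probs > 0
        values, probs = values[keep], probs[keep]
    sm._null = (values, probs)
    return sm._null


def _tail_prob(sm: ScoringMatrix, score: float, precision_bins: int = 10000) -> float:
    values, probs = null_distribution(sm, precision_bins)
    tail = np.cumsum(probs[::-1])[::-1]
    idx = np.searchsorted(values, score - _SCORE_TOL, side="left")
    if idx >= len(values):
        return 0.0
    return float(tail[idx])


def pvalue_threshold(
    sm: ScoringMatrix, alpha: float, precision_bins: int = 10000
) -> float:
    """Smallest score whose exact null tail probability is <= alpha.

    If alpha is below the minimum attainable tail probability (the
    probability of the single best word), the maximum score is returned with
    a warning: no word can then reach significance.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    values, probs = null_distribution(sm, precision_bins)
    tail = np.cumsum(probs[::-1])[::-1]
    ok = tail <= alpha + 1e-15
    if not ok.any():
        warnings.warn(
            f"alpha={alpha} below the minimum attainable tail probability "
            f"{tail[-1]:.3g}; returning the maximum score",
            stacklevel=2,
        )
        return float(values[-1])
    return float(values[np.argmax(ok)])


def _encode(seq: str) -> np.ndarray:
    """A=0 C=1 G=2 T=3, anything else (N) = -1."""
    out = np.full(len(seq), -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype="S1") == b.encode()] = i
    return out


def score_offsets(codes: np.ndarray, sm: ScoringMatrix) -> np.ndarray:
    """Scores at every start offset; NaN where the word overlaps a non-ACGT base."""
    L, w = len(codes), sm.width
    if L < w:
        return np.empty(0)
    n_off = L - w + 1
    offs = np.arange(n_off)[:, None] + np.arange(w)[None, :]
    words = codes[offs]
    valid = (words >= 0).all(axis=1)
    scores = np.full(n_off, np.nan)
    if valid.any():
        sub = words[valid]
        scores[valid] = sm.scores[np.arange(w)[None, :], sub].sum(axis=1)
    return scores


def scan_window(
    window: str,
    sm: ScoringMatrix,
    alpha: float = 1e-4,
    scan_reverse: bool = False,
    seq_id: str = "",
    precision_bins: int = 10000,
) -> list[MotifHit]:
    """All motif occurrences with exact null p-value <= alpha.

    Offsets whose word overlaps an N are skipped.  With ``scan_reverse`` the
    reverse complement strand is scanned as well; reverse-strand hits are
    reported at their start offset in the forward window's coordinates.
    """
    window = window.upper()
    threshold = pvalue_threshold(sm, alpha, precision_bins)
    hits: list[MotifHit] = []
    codes = _encode(window)
    strands = [("+", codes)]
    if scan_reverse:
        strands.append(("-", _encode(revcomp(window))))
    L, w = len(window), sm.width
    for strand, c in strands:
        scores = score_offsets(c, sm)
        for off in np.nonzero(np.nan_to_num(scores, nan=-np.inf) >= threshold - _SCORE_TOL)[0]:
            start = int(off) if strand == "+" else L - w - int(off)
            hits.append(
                MotifHit(
                    seq_id=seq_id,
                    start=start,
                    strand=strand,
                    width=w,
                    score=float(scores[off]),
                    pvalue=_tail_prob(sm, float(scores[off]), precision_bins),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def count_halves(hits: list[MotifHit], window_length: int) -> HalfCounts:
    """Split hits into upstream/downstream halves of a dyad-centred window.

    A hit is upstream when its midpoint (start + width/2) is strictly left of
    the dyad index and downstream when strictly right; midpoints exactly on
    the dyad are dropped from both halves but counted in ``n_center``.
    """
    if window_length % 2 != 1:
        raise ValueError("window length must be odd (dyad at the centre)")
    center = window_length // 2
    n_up = n_down = n_center = 0
    for h in hits:
        mid = h.start + h.width / 2.0
        if mid < center:
            n_up += 1
        elif mid > center:
            n_down += 1
        else:
            n_center += 1
    return HalfCounts(n_up, n_down, n_center)


def binomial_asymmetry(n_up: int, n_down: int) -> float:
    """Exact two-sided binomial p-value for up/down counts under null 0.5."""
    if n_up < 0 or n_down < 0:
        raise ValueError("counts must be non-negative")
    n = n_up + n_down
    if n == 0:
        raise ValueError("binomial asymmetry test undefined for (0, 0)")
    return float(stats.binomtest(n_up, n, 0.5, alternative="two-sided").pvalue)


def classify_motif(
    asym: AsymmetryResult,
    orientation_class: str,
    alpha: float = 0.05,
    n_motifs: int = 1,
) -> str:
    """Weak vs. strong H2A-H2B binding from the side of enrichment.

    ``orientation_class`` names the hexasome set the windows came from
    (``"HEX_UP"``: dimer on the upstream half; ``"HEX_DOWN"``: downstream).
    Enrichment on the dimer-absent half means the motif disfavours dimer
    binding (weak); on the dimer-present half, favours it (strong).  The
    binomial p is Bonferroni-corrected over ``n_motifs`` before the
    significance gate.
    """
    if orientation_class == "HEX_UP":
        present_up = True
    elif orientation_class == "HEX_DOWN":
        present_up = False
    else:
        raise ValueError(f"unknown orientation class {orientation_class!r}")
    p_adj = min(1.0, asym.pvalue * n_motifs)
    if p_adj >= alpha or asym.n_up == asym.n_down:
        return "unclassified"
    enriched_up = asym.n_up > asym.n_down
    return "strong_binding" if enriched_up == present_up else "weak_binding"
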