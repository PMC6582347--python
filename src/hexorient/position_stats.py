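"""Positional sequence composition around oriented hexasome dyads.

Windows are extracted in gene orientation (reverse complemented for
Crick-strand genes), so position -W is always gene-upstream of the dyad at 0.
Per-position nucleotide or dinucleotide distributions of two particle classes
are divided to form frequency-ratio profiles; blocks of ratio values are then
tested against the null value 1 with one-sample t-tests and a Bonferroni
correction, and label-by-category association is tested with Pearson
chi-squared statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomeSeq, ParticleRecord

__all__ = [
    "MONO_ALPHABET",
    "DI_ALPHABET",
    "PositionalDistribution",
    "RatioProfile",
    "extract_window",
    "positional_distribution",
    "ratio_profile",
    "grouped_ratio_test",
    "contingency_chisq",
    "orientation_position_test",
    "adjacent_orientation_test",
    "revcomp",
]

MONO_ALPHABET = tuple("ACGT")
DI_ALPHABET = tuple("".join(p) for p in itertools.product("ACGT", repeat=2))

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_window(
    genome: GenomeSeq, p: ParticleRecord, half_width: int = 74
) -> str:
    """Dyad-centred window of length ``2*half_width + 1`` in gene orientation.

    Watson genes return the genomic substring ``[dyad - W, dyad + W]``; Crick
    genes return its reverse complement, so index 0 of the result is always
    the gene-upstream edge.  Raises :class:`IndexError` if the window leaves
    the chromosome.
    """
    seq = genome.fetch(p.chrom, p.dyad - half_width, p.dyad + half_width)
    return revcomp(seq) if p.strand == "-" else seq


@dataclass
class PositionalDistribution:
    """Per dyad-relative position, probabilities over an alphabet."""

    alphabet: tuple[str, ...]
    positions: np.ndarray  # signed dyad-relative positions
    probs: pd.DataFrame  # index positions, columns alphabet
    n_sequences: int
    n_dropped: int = 0  # windows containing N, excluded

    def __post_init__(self) -> None:
        sums = self.probs.to_numpy().sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("per-position probabilities must sum to 1")


@dataclass
class RatioProfile:
    """Up/down frequency ratios per (position, symbol).

    ``ratios`` holds up_prob / down_prob; 0/0 is NaN (flagged undefined) and
    x/0 with x > 0 is +inf (flagged infinite); both are excluded from tests.
    """

    ratios: pd.DataFrame
    undefined: pd.DataFrame = field(repr=False, default=None)
    infinite: pd.DataFrame = field(repr=False, default=None)


def positional_distribution(
    windows: list[str], alphabet: str = "mono", half_width: int | None = None
) -> PositionalDistribution:
    """Count symbol frequencies at every dyad-relative position.

    ``alphabet`` is ``"mono"`` or ``"di"``; a dinucleotide at position *i* is
    formed from the bases at (i, i+1), so the dinucleotide grid is
    ``[-W, W-1]``.  Windows containing N are dropped (and counted in
    ``n_dropped``); all windows must share one odd length.
    """
    if not windows:
        raise ValueError("empty window list")
    length = len(windows[0])
    if any(len(w) != length for w in windows):
        raise ValueError("all windows must have equal length")
    if length % 2 != 1:
        raise ValueError("window length must be odd (dyad at the centre)")
    kept = [w.upper() for w in windows if "N" not in w.upper()]
    n_dropped = len(windows) - len(kept)
    if not kept:
        raise ValueError("no windows left after dropping those containing N")
    w_half = length // 2 if half_width is None else half_width

    arr = np.frombuffer("".join(kept).encode(), dtype="S1").reshape(len(kept), length)
    codes = np.zeros(arr.shape, dtype=np.int8)
    for i, base in enumerate(b"ACGT"):
        codes[arr == bytes([base])] = i

    if alphabet == "mono":
        symbols = MONO_ALPHABET
        positions = np.arange(-w_half, w_half + 1)
        counts = np.stack([(codes == i).sum(axis=0) for i in range(4)], axis=1)
    elif alphabet == "di":
        symbols = DI_ALPHABET
        positions = np.arange(-w_half, w_half)
        di = codes[:, :-1] * 4 + codes[:, 1:]
        counts = np.stack([(di == i).sum(axis=0) for i in range(16)], axis=1)
    else:
        raise ValueError(f"alphabet must be 'mono' or 'di', got {alphabet!r}")

    probs = counts / counts.sum(axis=1, keepdims=True)
    df = pd.DataFrame(probs, index=positions, columns=list(symbols))
    df.index.name = "position"
    return PositionalDistribution(symbols, positions, df, len(kept), n_dropped)


def ratio_profile(
    up_dist: PositionalDistribution, down_dist: PositionalDistribution
) -> RatioProfile:
    """Element-wise ratio of two positional distributions (up / down)."""
    if up_dist.alphabet != down_dist.alphabet or not np.array_equal(
        up_dist.positions, down_dist.positions
    ):
        raise ValueError("distributions must share alphabet and positions")
    num = up_dist.probs.to_numpy()
    den = down_dist.probs.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
    undefined = (num == 0) & (den == 0)
    infinite = (num > 0) & (den == 0)
    r[undefined] = np.nan
    r[infinite] = np.inf
    ratios = pd.DataFrame(r, index=up_dist.probs.index, columns=up_dist.probs.columns)
    return RatioProfile(
        ratios,
        pd.DataFrame(undefined, index=ratios.index, columns=ratios.columns),
        pd.DataFrame(infinite, index=ratios.index, columns=ratios.columns),
    )


def grouped_ratio_test(
    profile: RatioProfile, group_size: int = 10, n_groups: int = 14
) -> pd.DataFrame:
    """One-sample t-tests of ratio blocks against the null value 1.

    Positions -G..-1 and +1..+G (dyad excluded, G = group_size * n_groups / 2)
    are tiled into ``n_groups`` contiguous blocks of ``group_size``; per block
    and symbol a two-sided one-sample t-test against 1.0 is computed, and
    Bonferroni-corrected with factor ``n_groups * n_symbols``.  Zero-variance
    blocks get p = 1 when the common value is exactly 1, else p = 0, with a
    ``degenerate`` flag.  Non-finite ratios are excluded from their block.
    """
    if (group_size * n_groups) % 2 != 0:
        raise ValueError("group_size * n_groups must be even to split about the dyad")
    half = group_size * n_groups // 2
    pos = profile.ratios.index.to_numpy()
    needed = np.concatenate([np.arange(-half, 0), np.arange(1, half + 1)])
    if not np.isin(needed, pos).all():
        raise ValueError(f"profile must cover positions +-1..+-{half} (dyad excluded)")
    symbols = list(profile.ratios.columns)
    blocks = [needed[i * group_size:(i + 1) * group_size] for i in range(n_groups)]
    n_tests = n_groups * len(symbols)
    rows = []
    for gid, block in enumerate(blocks):
        for sym in symbols:
            vals = profile.ratios.loc[block, sym].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            degenerate = False
            if len(vals) < 2 or np.ptp(vals) == 0.0:
                degenerate = True
                t = np.nan
                p = 1.0 if len(vals) and np.allclose(vals.mean(), 1.0) else 0.0
            else:
                t, p = stats.ttest_1samp(vals, 1.0)
            rows.append(
                {
                    "group_id": gid,
                    "pos_start": int(block[0]),
                    "pos_end": int(block[-1]),
                    "symbol": sym,
                    "n_used": len(vals),
                    "mean_ratio": float(np.mean(vals)) if len(vals) else np.nan,
                    "t": float(t),
                    "p": float(p),
                    "p_bonferroni": min(1.0, float(p) * n_tests),
                    "degenerate": degenerate,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_factor"] = n_tests
    return out


def contingency_chisq(counts: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence (no continuity correction)."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    if np.any(row_sums == 0):
        raise ValueError(f"zero marginal row(s) {np.where(row_sums == 0)[0].tolist()}")
    if np.any(col_sums == 0):
        raise ValueError(f"zero marginal column(s) {np.where(col_sums == 0)[0].tolist()}")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


_ORIENT_LABELS = ("HEX_UP", "HEX_DOWN", "NUCLEOSOME")


def orientation_position_test(summary: pd.DataFrame) -> pd.Series:
    """Is each gene index's orientation mix different from the pooled mix?

    ``summary`` is the (gene_index x label) count table from ``call_all``;
    only the HEX_UP / HEX_DOWN / NUCLEOSOME columns are used.  For each gene
    index a chi-squared goodness-of-fit test compares that index's label
    counts against the proportions pooled over all indices.
    """
    table = summary.reindex(columns=list(_ORIENT_LABELS)).fillna(0).astype(float)
    if table.to_numpy().sum() == 0:
        raise ValueError("all orientation counts are zero")
    pooled = table.sum(axis=0)
    pooled_prop = pooled / pooled.sum()
    pvals = {}
    for idx, row in table.iterrows():
        present = row > 0
        if np.any(present & (pooled_prop == 0)):
            raise ValueError(f"label present at index {idx} has zero pooled proportion")
        expected = pooled_prop * row.sum()
        keep = expected > 0
        stat, p = stats.chisquare(row[keep], expected[keep])
        pvals[idx] = float(p)
    return pd.Series(pvals, name="p")


def adjacent_orientation_test(
    calls: pd.DataFrame, labels: tuple[str, ...] = _ORIENT_LABELS
) -> pd.DataFrame:
    """Association of orientation between adjacent particles of one gene.

    For the (+1, +2) and (+2, +3) index pairs, genes with a retained label at
    both indices contribute one cell to an orientation-by-orientation
    contingency table, which is tested with :func:`contingency_chisq`.  Run
    it on calls produced under the strict (H4-filtered) and relaxed
    configurations to reproduce both analysis modes.
    """
    sub = calls[calls["label"].isin(labels)]
    wide = sub.pivot_table(index="gene_id", columns="gene_index", values="label",
                           aggfunc="first")
    rows = []
    for a, b in ((1, 2), (2, 3)):
        if a not in wide.columns or b not in wide.columns:
            raise ValueError(f"no genes with calls at both indices ({a}, {b})")
        pair = wide[[a, b]].dropna()
        if len(pair) < 2:
            raise ValueError(f"fewer than 2 genes with calls at both indices ({a}, {b})")
        table = pd.crosstab(pair[a], pair[b])
        if min(table.shape) < 2:
            raise ValueError(f"fewer than 2 orientation categories observed for ({a}, {b})")
        chi2, dof, p = contingency_chisq(table.to_numpy())
        rows.append({"pair": f"+{a}/+{b}", "n_genes": len(pair), "chi2": chi2,
                     "dof": dof, "p": p})
    return pd.DataFrame(rows)
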