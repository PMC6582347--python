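"""Synthetic inputs with the statistical structure the analyses assume.

Every generator is a pure function of its spec and a seed, so reruns are
byte-identical.  The generators emulate the study's real inputs:

* ``gen_cohort`` — a synthetic chromosome of non-overlapping genes, each with
  +1/+2/+3 particles at fixed spacing, per-histone tag totals with Poisson
  noise and a planted H2B asymmetry (factor ``f``) on the dimer-present side
  of hexasomes, H4 symmetric throughout; Crick genes have their genome-strand
  tag columns flipped so the reader's gene-orientation conversion is
  exercised.
* ``gen_sequence_bias`` — dyad-centred windows with a planted C/G enrichment
  on the dimer-present half (A/T on the absent half) and optionally a motif
  consensus inserted into one half.
* ``gen_titration`` — a noisy non-cooperative binding isotherm.
* ``gen_traces`` — continuous-time two-state telegraph traces (unbound->bound
  at k_on * conc, bound->unbound at k_off) sampled at 5 Hz with Gaussian
  observation noise and exponential photobleaching, with true paths emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biophys_fits import FretTrace, TitrationCurve
from .io_formats import GenomeSeq, ParticleRecord, HISTONES
from .position_stats import revcomp

__all__ = [
    "CohortSpec",
    "Cohort",
    "SeqBiasSpec",
    "TraceSpec",
    "gen_cohort",
    "gen_sequence_bias",
    "gen_titration",
    "gen_traces",
]

_CLASSES = ("HEX_UP", "HEX_DOWN", "NUCLEOSOME")


# ---------------------------------------------------------------------------
# ChIP-exo-style cohort

@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for the synthetic tag-count cohort.

    ``depth`` is the Poisson mean of one histone half-window tag total;
    ``asymmetry_factor`` f > 1 multiplies the dimer-present-side H2B mean.
    ``class_probs`` maps gene_index -> (P(HEX_UP), P(HEX_DOWN),
    P(NUCLEOSOME)); the default is orientation-independent thirds.
    ``nb_dispersion`` switches tag noise to negative binomial with that
    shape parameter (overdispersion robustness checks); None keeps Poisson.
    """

    n_genes: int = 300
    crick_fraction: float = 0.5
    class_probs: dict[int, tuple[float, float, float]] = field(
        default_factory=lambda: {i: (1 / 3, 1 / 3, 1 / 3) for i in (1, 2, 3)}
    )
    depth: float = 500.0
    asymmetry_factor: float = 3.0
    seed: int = 0
    particle_spacing: int = 165
    gene_margin: int = 300
    nb_dispersion: float | None = None

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.asymmetry_factor <= 1:
            raise ValueError("asymmetry factor must exceed 1")
        for idx, probs in self.class_probs.items():
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError(f"class probabilities for index {idx} must sum to 1")
        if not 0 <= self.crick_fraction <= 1:
            raise ValueError("crick_fraction must be in [0, 1]")


@dataclass
class Cohort:
    genome: GenomeSeq
    particles: list[ParticleRecord]  # gene-oriented tags
    table: pd.DataFrame  # genomic-orientation TSV image, as written to disk
    truth: pd.DataFrame  # gene_id, gene_index, label


def _draw_counts(rng: np.random.Generator, mean: float, spec: CohortSpec) -> float:
    if spec.nb_dispersion is None:
        return float(rng.poisson(mean))
    r = spec.nb_dispersion
    p = r / (r + mean)
    return float(rng.negative_binomial(r, p))


def gen_cohort(spec: CohortSpec) -> Cohort:
    """Generate a genome, particle table and truth labels for the caller."""
    rng = np.random.default_rng(spec.seed)
    span = 2 * spec.particle_spacing + 2 * spec.gene_margin
    chrom_len = spec.n_genes * span
    chrom_seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, chrom_len)])
    genome = GenomeSeq({"chrS": chrom_seq})

    particles: list[ParticleRecord] = []
    truth_rows = []
    for g in range(spec.n_genes):
        gene_id = f"gene{g:05d}"
        strand = "-" if rng.random() < spec.crick_fraction else "+"
        start = g * span + spec.gene_margin
        for gi in (1, 2, 3):
            # +1 nearest the gene start in transcription direction
            offset = (gi - 1) * spec.particle_spacing
            dyad = start + offset if strand == "+" else start + 2 * spec.particle_spacing - offset
            label = _CLASSES[rng.choice(3, p=spec.class_probs[gi])]
            tags: dict[tuple[str, str], float] = {}
            for hist in HISTONES:
                up_mean = down_mean = spec.depth
                if hist in ("H2A", "H2B"):
                    if label == "HEX_UP":
                        up_mean = spec.depth * spec.asymmetry_factor
                    elif label == "HEX_DOWN":
                        down_mean = spec.depth * spec.asymmetry_factor
                tags[(hist, "upstream")] = _draw_counts(rng, up_mean, spec)
                tags[(hist, "downstream")] = _draw_counts(rng, down_mean, spec)
            particles.append(
                ParticleRecord(gene_id=gene_id, chrom="chrS", strand=strand,
                               gene_index=gi, dyad=int(dyad), tags=tags)
            )
            truth_rows.append({"gene_id": gene_id, "gene_index": gi, "label": label})

    from .io_formats import particles_to_frame

    table = particles_to_frame(particles, orientation="genomic")
    truth = pd.DataFrame(truth_rows)
    return Cohort(genome, particles, table, truth)


# ---------------------------------------------------------------------------
# Positional sequence bias

@dataclass(frozen=True)
class SeqBiasSpec:
    """Planted composition bias and optional motif for oriented windows.

    ``delta`` is the total probability shifted towards C/G on the
    dimer-present half (split evenly between C and G, taken evenly from A and
    T); the dimer-absent half receives the mirror-image A/T enrichment.
    ``motif_consensus`` (if set) is inserted with probability
    ``motif_insert_prob`` at a uniform offset within ``motif_half``
    ("up"/"down") of each window.
    """

    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    delta: float = 0.08
    half_width: int = 74
    motif_consensus: str | None = None
    motif_insert_prob: float = 0.0
    motif_half: str = "up"
    seed: int = 0

    def __post_init__(self) -> None:
        bg = np.asarray(self.background)
        if abs(bg.sum() - 1.0) > 1e-9 or np.any(bg < 0):
            raise ValueError("background must be a probability vector")
        shifted = np.array([bg[0] - self.delta / 2, bg[1] + self.delta / 2,
                            bg[2] + self.delta / 2, bg[3] - self.delta / 2])
        if np.any(shifted < 0) or np.any(shifted > 1):
            raise ValueError("delta pushes a base probability outside [0, 1]")
        if self.motif_half not in ("up", "down"):
            raise ValueError("motif_half must be 'up' or 'down'")


def _half_probs(bg: np.ndarray, delta: float, enrich: str) -> np.ndarray:
    """Base probabilities for one half: 'CG' or 'AT' enriched by delta."""
    out = bg.copy()
    if enrich == "CG":
        out += np.array([-delta / 2, delta / 2, delta / 2, -delta / 2])
    else:
        out += np.array([delta / 2, -delta / 2, -delta / 2, delta / 2])
    return out


def gen_sequence_bias(
    spec: SeqBiasSpec, orientations: list[str]
) -> tuple[list[str], pd.DataFrame]:
    """Windows whose composition is consistent with the given orientations.

    For a HEX_UP window the dimer sits on the upstream half (positions < 0),
    which is C/G-enriched; the downstream half is A/T-enriched.  HEX_DOWN is
    the mirror image; NUCLEOSOME windows are unbiased background.  Returns
    the windows plus truth metadata (orientation, motif offset or -1).
    """
    rng = np.random.default_rng(spec.seed)
    bg = np.asarray(spec.background, dtype=float)
    w = spec.half_width
    length = 2 * w + 1
    bases = np.array(list("ACGT"))
    windows: list[str] = []
    meta = []
    for orient in orientations:
        if orient == "HEX_UP":
            up_p, down_p = _half_probs(bg, spec.delta, "CG"), _half_probs(bg, spec.delta, "AT")
        elif orient == "HEX_DOWN":
            up_p, down_p = _half_probs(bg, spec.delta, "AT"), _half_probs(bg, spec.delta, "CG")
        elif orient == "NUCLEOSOME":
            up_p = down_p = bg
        else:
            raise ValueError(f"unknown orientation {orient!r}")
        probs = np.vstack([np.tile(up_p, (w, 1)), bg, np.tile(down_p, (w, 1))])
        cum = probs.cumsum(axis=1)
        draws = (rng.random(length)[:, None] >= cum).sum(axis=1)
        win = bases[draws]
        motif_at = -1
        if spec.motif_consensus and rng.random() < spec.motif_insert_prob:
            m = spec.motif_consensus.upper()
            if len(m) > w:
                raise ValueError("motif longer than a half-window")
            if spec.motif_half == "up":
                motif_at = int(rng.integers(0, w - len(m) + 1))
            else:
                motif_at = int(rng.integers(w + 1, length - len(m) + 1))
            win[motif_at:motif_at + len(m)] = list(m)
        windows.append("".join(win))
        meta.append({"orientation": orient, "motif_offset": motif_at})
    return windows, pd.DataFrame(meta)


# ---------------------------------------------------------------------------
# Titrations

def gen_titration(
    E0: float,
    EF: float,
    S_half: float,
    concs: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    signal_kind: str = "fret",
) -> TitrationCurve:
    """Isotherm values at the given concentrations plus i.i.d. Gaussian noise."""
    if S_half <= 0:
        raise ValueError("S_half must be positive")
    concs = np.asarray(concs, dtype=float)
    rng = np.random.default_rng(seed)
    signal = EF + (E0 - EF) / (1.0 + concs / S_half)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=len(concs))
    return TitrationCurve(concs, signal, signal_kind)


# ---------------------------------------------------------------------------
# smFRET traces

@dataclass(frozen=True)
class TraceSpec:
    """Two-state telegraph acquisition conditions (5 Hz for 400 s default).

    The unbound (TF-free, wrapped) state is high-FRET; the bound state is
    low-FRET.  Switching is unbound->bound at ``k_on * concentration`` and
    bound->unbound at ``k_off``; traces are truncated at an exponential
    photobleach time.
    """

    k_on: float = 0.0052  # s^-1 nM^-1
    k_off: float = 0.37  # s^-1
    concentration: float = 100.0  # nM
    dt: float = 0.2
    duration: float = 400.0
    unbound_mean: float = 0.7
    bound_mean: float = 0.2
    unbound_sd: float = 0.1
    bound_sd: float = 0.1
    photobleach_rate: float = 0.001  # s^-1; 0 disables bleaching
    n_traces: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("rates must be positive")
        if self.dt <= 0 or self.duration <= self.dt:
            raise ValueError("need dt > 0 and duration > dt")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")


@dataclass
class SimulatedTraces:
    traces: list[FretTrace]
    true_paths: list[np.ndarray]  # 1 = unbound/high, 0 = bound/low, per kept frame
    true_dwells_high: np.ndarray  # complete (uncensored) unbound dwells, seconds
    true_dwells_low: np.ndarray


def _telegraph_frames(
    rng: np.random.Generator, k_u2b: float, k_b2u: float, n_frames: int, dt: float
) -> tuple[np.ndarray, list[float], list[float]]:
    """Continuous-time two-state path sampled at frame instants.

    Returns the frame states (1 = unbound) and the complete interior dwell
    times of each state within the observation window.
    """
    total = n_frames * dt
    if k_u2b == 0.0:
        return np.ones(n_frames, dtype=np.int8), [], []
    pi_unbound = k_b2u / (k_u2b + k_b2u)
    state = 1 if rng.random() < pi_unbound else 0
    t = 0.0
    switch_times = []
    states_seq = [state]
    while True:
        rate = k_u2b if state == 1 else k_b2u
        t += rng.exponential(1.0 / rate)
        if t >= total:
            break
        switch_times.append(t)
        state = 1 - state
        states_seq.append(state)
    frame_t = np.arange(n_frames) * dt
    frames = np.empty(n_frames, dtype=np.int8)
    idx = np.searchsorted(switch_times, frame_t, side="right")
    first = states_seq[0]
    frames = np.where(idx % 2 == 0, first, 1 - first).astype(np.int8)
    # interior dwells: bounded by two switches
    high_dwells, low_dwells = [], []
    for i in range(len(switch_times) - 1):
        dwell = switch_times[i + 1] - switch_times[i]
        s = states_seq[i + 1]
        (high_dwells if s == 1 else low_dwells).append(dwell)
    return frames, high_dwells, low_dwells


def gen_traces(spec: TraceSpec) -> SimulatedTraces:
    """Simulate smFRET traces with their true state paths and dwell times."""
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration / spec.dt))
    k_u2b = spec.k_on * spec.concentration
    traces: list[FretTrace] = []
    paths: list[np.ndarray] = []
    all_high: list[float] = []
    all_low: list[float] = []
    for _ in range(spec.n_traces):
        frames, hd, ld = _telegraph_frames(rng, k_u2b, spec.k_off, n_frames, spec.dt)
        if spec.photobleach_rate > 0:
            t_bleach = rng.exponential(1.0 / spec.photobleach_rate)
            keep = max(2, min(n_frames, int(t_bleach / spec.dt)))
        else:
            keep = n_frames
        frames = frames[:keep]
        noise = rng.normal(0.0, 1.0, keep)
        values = np.where(
            frames == 1,
            spec.unbound_mean + spec.unbound_sd * noise,
            spec.bound_mean + spec.bound_sd * noise,
        )
        times = np.arange(keep) * spec.dt
        traces.append(FretTrace(times, values))
        paths.append(frames)
        all_high.extend(hd)
        all_low.extend(ld)
    return SimulatedTraces(
        traces, paths, np.asarray(all_high), np.asarray(all_low)
    )
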