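"""Ensemble fluorescence formulas and single-molecule kinetics extraction.

Ensemble side: the (ratio)_A FRET efficiency from acceptor emission under
donor vs. direct acceptor excitation, the normalized PIFE signal, and the
non-cooperative binding isotherm

    E([TF]) = E_F + (E_0 - E_F) / (1 + [TF] / S_1/2)

whose S_1/2 is the TF concentration at half the total signal change.

Single-molecule side: each FRET trace is segmented with a two-state Gaussian
hidden Markov model (EM-fitted per trace, most-probable-path decoded — the
same class of model vbFRET fits, restricted to the two states this analysis
assumes), dwell times are tabulated with the censored boundary dwells
excluded, each state's dwell set is fit by least squares to the cumulative
exponential N(t) = N_tot (1 - exp(-k t)), and the per-concentration rates
give k_on (slope of the unbound-state exit rate vs. concentration) and k_off
(horizontal-line fit to the bound-state exit rates).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM
from scipy import optimize

# the EM monitor logs sub-1e-5 likelihood oscillations as non-convergence;
# those are numerical noise at our tolerance and not actionable per trace
logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

__all__ = [
    "SpectraMeasurement",
    "TitrationCurve",
    "IsothermFit",
    "FretTrace",
    "Segmentation",
    "DwellSet",
    "ExponentialFit",
    "KineticRates",
    "fret_ratioA",
    "pife_signal",
    "fit_isotherm",
    "segment_two_state",
    "tabulate_dwells",
    "fit_exponential_cdf",
    "rates_vs_concentration",
]


# ---------------------------------------------------------------------------
# Ensemble formulas

@dataclass(frozen=True)
class SpectraMeasurement:
    """Integrated emissions and extinction coefficients for (ratio)_A FRET.

    ``F_A_510`` is the acceptor emission under donor excitation (donor bleed
    already subtracted), ``F_A_610`` under direct acceptor excitation;
    ``eps_*`` are molar extinction coefficients at the excitation
    wavelengths; ``d_plus`` is the donor labeling efficiency.
    """

    F_A_510: float
    F_A_610: float
    eps_A_610: float
    eps_A_510: float
    eps_D_510: float
    d_plus: float = 1.0

    def __post_init__(self) -> None:
        if min(self.eps_A_610, self.eps_A_510, self.eps_D_510) <= 0:
            raise ValueError("extinction coefficients must be positive")
        if not 0 < self.d_plus <= 1:
            raise ValueError("d_plus must be in (0, 1]")


def fret_ratioA(m: SpectraMeasurement, n_acceptors: int = 2) -> float:
    """FRET efficiency by the (ratio)_A method.

    E = n_acceptors * (eps_A_610 * F_A_510 / F_A_610 - eps_A_510)
        / (eps_D_510 * d_plus)

    The default prefactor of 2 reflects two acceptor molecules per donor.
    """
    if m.F_A_610 <= 0:
        raise ValueError("F_A_610 must be positive")
    return (
        n_acceptors
        * (m.eps_A_610 * m.F_A_510 / m.F_A_610 - m.eps_A_510)
        / (m.eps_D_510 * m.d_plus)
    )


def pife_signal(F_A: float, F_D: float, baseline_ratio: float, invert: bool = False) -> float:
    """Normalized PIFE signal (F_A / F_D over the zero-concentration ratio).

    The ratio is computed as printed (acceptor over donor); ``invert``
    computes F_D / F_A instead for users who prefer the donor-enhancement
    convention, since the donor (Cy3) is the PIFE-responsive dye.
    """
    if F_D <= 0:
        raise ValueError("F_D must be positive")
    if baseline_ratio == 0:
        raise ValueError("baseline ratio must be nonzero")
    ratio = F_D / F_A if invert else F_A / F_D
    return ratio / baseline_ratio


# ---------------------------------------------------------------------------
# Binding isotherm

@dataclass
class TitrationCurve:
    """Concentration series (nM, ascending, may include 0) and signals."""

    concentrations: np.ndarray
    signals: np.ndarray
    signal_kind: str = "fret"  # or "pife"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.concentrations.shape != self.signals.shape:
            raise ValueError("concentrations and signals must have equal length")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")


@dataclass
class IsothermFit:
    """Non-cooperative isotherm parameters with standard errors."""

    E0: float
    EF: float
    S_half: float
    E0_se: float
    EF_se: float
    S_half_se: float
    residual_norm: float
    S_half_in_range: bool

    def predict(self, conc: np.ndarray) -> np.ndarray:
        return _isotherm(np.asarray(conc, dtype=float), self.E0, self.EF, self.S_half)

    def summary(self) -> str:
        flag = "" if self.S_half_in_range else "  [outside measured range]"
        return (
            "Non-cooperative binding isotherm fit\n"
            f"  E0     = {self.E0:.4g} +/- {self.E0_se:.2g}\n"
            f"  EF     = {self.EF:.4g} +/- {self.EF_se:.2g}\n"
            f"  S_1/2  = {self.S_half:.4g} +/- {self.S_half_se:.2g} nM{flag}\n"
            f"  ||residual|| = {self.residual_norm:.3g}"
        )


def _isotherm(c: np.ndarray, E0: float, EF: float, S: float) -> np.ndarray:
    return EF + (E0 - EF) / (1.0 + c / S)


def fit_isotherm(curve: TitrationCurve) -> IsothermFit:
    """Least-squares fit of the non-cooperative isotherm to a titration.

    Initialized at E0 = signal at the lowest concentration, EF = signal at
    the highest, and S_1/2 = the concentration nearest the half-signal point.
    Standard errors come from the fit covariance.  A fitted S_1/2 outside the
    measured concentration range is flagged, not an error.
    """
    c, y = curve.concentrations, curve.signals
    if len(c) < 4:
        raise ValueError("need at least 4 titration points")
    e0, ef = y[0], y[-1]
    half = (e0 + ef) / 2.0
    s0 = c[np.argmin(np.abs(y - half))]
    if s0 <= 0:
        s0 = c[c > 0].min() if np.any(c > 0) else 1.0
    try:
        popt, pcov = optimize.curve_fit(
            _isotherm, c, y, p0=[e0, ef, s0],
            bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"isotherm fit did not converge (init E0={e0}, EF={ef}, S={s0}): {err}"
        ) from err
    ses = np.sqrt(np.diag(pcov))
    resid = y - _isotherm(c, *popt)
    in_range = bool(c.min() <= popt[2] <= c.max())
    if not in_range:
        warnings.warn(
            f"fitted S_1/2 = {popt[2]:.3g} nM outside the measured range "
            f"[{c.min():.3g}, {c.max():.3g}] nM",
            stacklevel=2,
        )
    return IsothermFit(
        E0=float(popt[0]), EF=float(popt[1]), S_half=float(popt[2]),
        E0_se=float(ses[0]), EF_se=float(ses[1]), S_half_se=float(ses[2]),
        residual_norm=float(np.linalg.norm(resid)), S_half_in_range=in_range,
    )


# ---------------------------------------------------------------------------
# Single-molecule traces

@dataclass
class FretTrace:
    """A uniformly sampled FRET time series (default 5 Hz, i.e. dt = 0.2 s)."""

    times: np.ndarray
    values: np.ndarray
    photobleach_index: int | None = None  # first frame after the bleach, if any

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if len(self.times) >= 2:
            dts = np.diff(self.times)
            if np.any(dts <= 0) or np.ptp(dts) > 1e-6 * dts[0]:
                raise ValueError("times must be uniformly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FRET values must be finite")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def truncated(self) -> "FretTrace":
        """The trace up to (excluding) the photobleach frame."""
        if self.photobleach_index is None:
            return self
        i = self.photobleach_index
        return FretTrace(self.times[:i], self.values[:i])


@dataclass
class Segmentation:
    """Idealized two-state path: 1 = high-FRET state, 0 = low-FRET state."""

    states: np.ndarray  # int8 per frame
    means: tuple[float, float]  # (low, high)
    sds: tuple[float, float]
    transmat: np.ndarray
    single_state: bool = False
    log_likelihood: float = 0.0


def segment_two_state(
    trace: FretTrace,
    min_frames: int = 20,
    min_separation: float = 0.1,
    n_iter: int = 200,
) -> Segmentation:
    """Fit a two-state Gaussian HMM to one trace and decode it.

    The model (state means, variances and transition probabilities) is fit by
    expectation-maximization from a deterministic quartile initialization and
    decoded by the most probable path.  Traces whose fitted state means are
    closer than ``min_separation`` (or that never leave one decoded state)
    are flagged single-state and should be excluded from dwell tabulation.
    """
    tr = trace.truncated()
    y = tr.values
    if len(y) < min_frames:
        raise ValueError(f"trace has {len(y)} frames after truncation; need {min_frames}")
    if np.ptp(y) < 1e-12:
        return Segmentation(
            np.zeros(len(y), dtype=np.int8), (float(y[0]), float(y[0])),
            (0.0, 0.0), np.eye(2), single_state=True,
        )
    X = y[:, None]
    model = GaussianHMM(
        n_components=2, covariance_type="diag", init_params="", params="stmc",
        n_iter=n_iter, tol=1e-4, min_covar=1e-6,
    )
    model.startprob_ = np.array([0.5, 0.5])
    model.transmat_ = np.array([[0.95, 0.05], [0.05, 0.95]])
    model.means_ = np.array([[np.quantile(y, 0.25)], [np.quantile(y, 0.75)]])
    var0 = max(np.var(y) / 4.0, 1e-6)
    model.covars_ = np.array([[var0], [var0]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X)
        ll, path = model.decode(X, algorithm="viterbi")
    means = model.means_.ravel()
    sds = np.sqrt(model.covars_.ravel())
    order = np.argsort(means)  # 0 -> low, 1 -> high
    states = np.where(path == order[1], 1, 0).astype(np.int8)
    transmat = model.transmat_[np.ix_(order, order)]
    sep = abs(means[order[1]] - means[order[0]])
    single = bool(sep < min_separation or len(np.unique(states)) < 2)
    return Segmentation(
        states=states,
        means=(float(means[order[0]]), float(means[order[1]])),
        sds=(float(sds[order[0]]), float(sds[order[1]])),
        transmat=transmat,
        single_state=single,
        log_likelihood=float(ll),
    )


@dataclass
class DwellSet:
    """State dwell durations (seconds) with boundary-censoring flags.

    The first and last dwell of every trace are censored (their true length
    is unobserved) and excluded from ``usable_*`` by default.
    """

    high_dwells: np.ndarray
    low_dwells: np.ndarray
    high_censored: np.ndarray  # bool, aligned with high_dwells
    low_censored: np.ndarray

    @property
    def usable_high(self) -> np.ndarray:
        return self.high_dwells[~self.high_censored]

    @property
    def usable_low(self) -> np.ndarray:
        return self.low_dwells[~self.low_censored]

    @staticmethod
    def merge(sets: list["DwellSet"]) -> "DwellSet":
        return DwellSet(
            np.concatenate([s.high_dwells for s in sets]) if sets else np.empty(0),
            np.concatenate([s.low_dwells for s in sets]) if sets else np.empty(0),
            np.concatenate([s.high_censored for s in sets]) if sets else np.empty(0, bool),
            np.concatenate([s.low_censored for s in sets]) if sets else np.empty(0, bool),
        )


def tabulate_dwells(path: np.ndarray, dt: float) -> DwellSet:
    """Run-length encode an idealized path into per-state dwell times."""
    path = np.asarray(path)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if len(path) == 0:
        empty = np.empty(0)
        return DwellSet(empty, empty, np.empty(0, bool), np.empty(0, bool))
    change = np.nonzero(np.diff(path) != 0)[0]
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [len(path) - 1]])
    lengths = (ends - starts + 1) * dt
    run_states = path[starts]
    censored = np.zeros(len(starts), dtype=bool)
    censored[0] = True
    censored[-1] = True
    high = run_states == 1
    return DwellSet(
        high_dwells=lengths[high],
        low_dwells=lengths[~high],
        high_censored=censored[high],
        low_censored=censored[~high],
    )


def extract_dwells(traces: list[FretTrace], min_frames: int = 20) -> DwellSet:
    """Segment a batch of traces and pool their dwell sets.

    Traces shorter than ``min_frames`` after photobleach truncation and
    traces flagged single-state are skipped, mirroring the screening applied
    to experimental traces before dwell tabulation.
    """
    sets: list[DwellSet] = []
    for trace in traces:
        if len(trace.truncated().values) < min_frames:
            continue
        seg = segment_two_state(trace, min_frames=min_frames)
        if seg.single_state:
            continue
        sets.append(tabulate_dwells(seg.states, trace.dt))
    return DwellSet.merge(sets)


@dataclass
class ExponentialFit:
    """Rate from a cumulative-exponential dwell fit, with an MLE cross-check."""

    k: float
    k_se: float
    k_ml: float  # 1 / mean dwell
    n_dwells: int
    n_total_fit: float  # fitted plateau N_tot
    max_cdf_deviation: float  # sup |fit - empirical| / n, a misfit diagnostic
    non_exponential: bool

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.k - 1.96 * self.k_se, self.k + 1.96 * self.k_se)

    def summary(self) -> str:
        flag = "  [non-exponential]" if self.non_exponential else ""
        return (
            f"k = {self.k:.4g} +/- {self.k_se:.2g} s^-1 "
            f"(MLE 1/mean = {self.k_ml:.4g}, n = {self.n_dwells}){flag}"
        )


def fit_exponential_cdf(
    dwells: np.ndarray, min_dwells: int = 50, misfit_threshold: float = 0.1
) -> ExponentialFit:
    """Least-squares fit of N(t) = N_tot (1 - exp(-k t)) to the dwell counts.

    The empirical cumulative count is evaluated at every observed dwell (no
    histogram binning).  The maximum-likelihood estimate 1/mean is reported
    as a cross-check, and a sup-deviation misfit diagnostic above
    ``misfit_threshold`` flags a non-exponential dwell distribution.
    """
    dwells = np.asarray(dwells, dtype=float)
    if len(dwells) < min_dwells:
        raise ValueError(f"need at least {min_dwells} usable dwells, got {len(dwells)}")
    if np.any(dwells <= 0):
        raise ValueError("dwell times must be positive")
    t = np.sort(dwells)
    n = len(t)
    counts = np.searchsorted(t, t, side="right").astype(float)
    k0 = 1.0 / t.mean()

    def model(tt, n_tot, k):
        return n_tot * (1.0 - np.exp(-k * tt))

    popt, pcov = optimize.curve_fit(
        model, t, counts, p0=[float(n), k0], maxfev=10000,
        bounds=([1.0, 1e-12], [np.inf, np.inf]),
    )
    n_tot, k = popt
    k_se = float(np.sqrt(pcov[1, 1]))
    dev = float(np.max(np.abs(model(t, *popt) - counts)) / n)
    # for exponential data the curve-fit rate and 1/mean agree; a large
    # relative discrepancy (e.g. near-identical dwells, where the cumulative
    # count is a step the saturated fit matches pointwise) marks misfit
    rate_discrepancy = abs(k - k0) / k0
    return ExponentialFit(
        k=float(k), k_se=k_se, k_ml=float(k0), n_dwells=n,
        n_total_fit=float(n_tot), max_cdf_deviation=dev,
        non_exponential=bool(dev > misfit_threshold or rate_discrepancy > 0.5),
    )


@dataclass
class KineticRates:
    """k_on from the concentration dependence of the unbound-state exit rate,
    k_off from the horizontal-line fit to the bound-state exit rates."""

    k_on: float  # s^-1 nM^-1
    k_on_se: float
    intercept: float  # s^-1; reported so a through-origin alternative can be judged
    intercept_se: float
    k_off: float  # s^-1
    k_off_se: float
    concentrations: np.ndarray
    unbound_rates: np.ndarray
    bound_rates: np.ndarray

    def summary(self) -> str:
        return (
            "Kinetic rates vs. concentration\n"
            f"  k_on  = {self.k_on:.4g} +/- {self.k_on_se:.2g} s^-1 nM^-1 "
            f"(intercept {self.intercept:.3g} +/- {self.intercept_se:.2g} s^-1)\n"
            f"  k_off = {self.k_off:.4g} +/- {self.k_off_se:.2g} s^-1"
        )


def rates_vs_concentration(
    unbound_rates: np.ndarray,
    bound_rates: np.ndarray,
    concs: np.ndarray,
) -> KineticRates:
    """Combine per-concentration state exit rates into k_on and k_off.

    The unbound-state (high-FRET, TF-free) exit rates are fit with an
    unweighted least-squares line in concentration whose slope is k_on; the
    bound-state exit rates are fit with a horizontal line (their mean), which
    is k_off.
    """
    concs = np.asarray(concs, dtype=float)
    unbound_rates = np.asarray(unbound_rates, dtype=float)
    bound_rates = np.asarray(bound_rates, dtype=float)
    if len(concs) < 3:
        raise ValueError("need at least 3 concentrations")
    if len(unbound_rates) != len(concs) or len(bound_rates) != len(concs):
        raise ValueError("rates and concentrations must align")
    n = len(concs)
    x_bar = concs.mean()
    sxx = float(np.sum((concs - x_bar) ** 2))
    if sxx == 0:
        raise ValueError("concentrations must not all be equal")
    slope = float(np.sum((concs - x_bar) * (unbound_rates - unbound_rates.mean())) / sxx)
    intercept = float(unbound_rates.mean() - slope * x_bar)
    resid = unbound_rates - (intercept + slope * concs)
    s2 = float(np.sum(resid**2) / (n - 2))
    slope_se = float(np.sqrt(s2 / sxx))
    intercept_se = float(np.sqrt(s2 * (1.0 / n + x_bar**2 / sxx)))
    k_off = float(bound_rates.mean())
    k_off_se = float(bound_rates.std(ddof=1) / np.sqrt(len(bound_rates)))
    return KineticRates(
        k_on=float(slope), k_on_se=float(slope_se),
        intercept=float(intercept), intercept_se=float(intercept_se),
        k_off=k_off, k_off_se=k_off_se,
        concentrations=concs, unbound_rates=unbound_rates, bound_rates=bound_rates,
    )
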