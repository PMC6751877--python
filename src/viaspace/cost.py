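"""Cost functions and the viability predicate.

A candidate parameter vector is *viable* when its cost E(theta) clears a
predefined threshold, i.e. the simulated circuit shows the desired
behavior.  Three cost families are implemented:

``harmonic_mse``
    Sum of squared differences between the first n Fourier harmonics of the
    observed readout and of an ideal sine of given amplitude and period.
    Phase-invariant by construction.  Viability: the root-mean deviation per
    harmonic must not exceed a tolerance in nM.
``peak_prominence``
    A loose oscillation detector on the magnitude spectrum: rewards one
    prominent, narrow spectral peak regardless of exact period.  Viability
    additionally pins the leading-harmonic magnitude inside an amplitude
    window.
``time_mse``
    Time-domain mean squared deviation from target steady levels, used for
    bistable behavior (high species -> 400 nM, low species -> 0 nM) under
    two swapped-initial-condition scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .models import ModelSpec, ParameterPoint, ParameterSpace, Trajectory, simulate

__all__ = [
    "HarmonicSpectrum",
    "CostSpec",
    "CostValue",
    "spectrum",
    "harmonics_of",
    "ideal_harmonics",
    "harmonic_mse",
    "peak_sequence_cost",
    "peak_prominence_cost",
    "time_mse",
    "measure_oscillation",
    "Evaluator",
    "scenario",
    "SCENARIO_IDS",
]


@dataclass(frozen=True)
class HarmonicSpectrum:
    """One-sided magnitude spectrum of a uniformly sampled signal.

    Magnitudes are normalized so a pure sine of amplitude A (sampled over an
    integer number of its periods) reports a leading magnitude of A nM.  The
    zero-frequency (mean) component is removed before the transform.
    """

    freqs: np.ndarray  # h^-1
    mags: np.ndarray  # nM
    fundamental_index: int  # bin nearest 1/ideal_period

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        object.__setattr__(self, "mags", np.asarray(self.mags, dtype=float))
        if self.mags.shape != self.freqs.shape:
            raise ValueError("freqs/mags length mismatch")
        if not 0 <= self.fundamental_index < self.freqs.size:
            raise ValueError("fundamental_index out of range")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass(frozen=True)
class CostValue:
    """Cost of one candidate with its viability verdict and diagnostics."""

    value: float
    viable: bool
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CostSpec:
    """Declarative description of one cost function + viability rule.

    Exactly one of ``E0`` / ``per_harmonic_tol`` is set for the MSE-style
    kinds; ``amplitude_window`` only applies to ``peak_prominence``.
    """

    kind: str  # harmonic_mse | peak_prominence | time_mse
    ideal_amplitude: float | None = None  # nM
    ideal_period: float | None = None  # h
    n_harmonics: int = 10
    E0: float | None = None
    per_harmonic_tol: float | None = None  # nM
    amplitude_window: tuple[float, float] | None = None  # nM
    readout: tuple[str, ...] = ("X",)
    target_levels: tuple[float, float] = (400.0, 0.0)  # high, low (nM)
    discard_fraction: float = 0.0  # transient fraction dropped (time_mse)

    def __post_init__(self) -> None:
        if self.kind not in ("harmonic_mse", "peak_prominence", "time_mse"):
            raise ValueError(f"unknown cost kind {self.kind!r}")
        if self.kind in ("harmonic_mse", "time_mse"):
            if (self.E0 is None) == (self.per_harmonic_tol is None):
                raise ValueError("set exactly one of E0 / per_harmonic_tol")
        if self.amplitude_window is not None and self.kind != "peak_prominence":
            raise ValueError("amplitude_window only valid for peak_prominence")


def spectrum(
    traj: Trajectory,
    species: str,
    ideal_period: float,
    discard_fraction: float = 0.0,
) -> HarmonicSpectrum:
    """Magnitude spectrum of one readout species.

    Requires a uniform grid spanning at least two ideal periods.  The
    spectrum carries all bins; harmonic extraction (``harmonics_of``) picks
    the bins nearest integer multiples of 1/ideal_period.
    """
    y = traj.column(species)
    t = traj.t
    if discard_fraction > 0.0:
        keep = t >= t[0] + discard_fraction * (t[-1] - t[0])
        y = y[keep]
        t = t[keep]
    duration = t[-1] - t[0]
    if duration < 2.0 * ideal_period:
        raise ValueError("insufficient duration: need >= 2 ideal periods")
    n = y.size
    mags = 2.0 * np.abs(np.fft.rfft(y - y.mean())) / n
    freqs = np.fft.rfftfreq(n, traj.dt)
    k0 = int(np.argmin(np.abs(freqs - 1.0 / ideal_period)))
    return HarmonicSpectrum(freqs=freqs, mags=mags, fundamental_index=k0)


def harmonics_of(spec: HarmonicSpectrum, ideal_period: float, n_harmonics: int) -> np.ndarray:
    """Magnitudes at the bins nearest multiples of 1/ideal_period (DC excluded)."""
    out = np.empty(n_harmonics)
    for i in range(1, n_harmonics + 1):
        k = int(np.argmin(np.abs(spec.freqs - i / ideal_period)))
        out[i - 1] = spec.mags[max(k, 1)]
    return out


def ideal_harmonics(
    amplitude: float, period: float, grid: Trajectory | np.ndarray
) -> HarmonicSpectrum:
    """Spectrum of the ideal sine A*sin(2*pi*t/T) sampled on the observed grid.

    Sampling the ideal on the same grid lets the discretization/leakage bias
    cancel in the harmonic MSE.
    """
    if amplitude <= 0 or period <= 0:
        raise ValueError("amplitude and period must be positive")
    t = grid.t if isinstance(grid, Trajectory) else np.asarray(grid, dtype=float)
    y = amplitude * np.sin(2.0 * np.pi * t / period)
    traj = Trajectory(t=t, y=y[:, None], species=("ideal",))
    return spectrum(traj, "ideal", period)


def harmonic_mse(
    obs: HarmonicSpectrum,
    ideal: HarmonicSpectrum,
    ideal_period: float,
    n_harmonics: int,
    per_harmonic_tol: float,
) -> CostValue:
    """Harmonic-domain MSE cost: E = sum_i (h_obs_i - h_ideal_i)^2.

    Viable iff sqrt(E/n) <= per_harmonic_tol: the tolerance bounds the rms
    average deviation per harmonic.  (A mean-absolute reading would let a
    flat signal pass whenever the ideal amplitude is below n_harmonics*tol,
    hollowing out the criterion for low-amplitude ideals.)
    """
    ho = harmonics_of(obs, ideal_period, n_harmonics)
    hi = harmonics_of(ideal, ideal_period, n_harmonics)
    dev = ho - hi
    value = float(np.sum(dev**2))
    mad = float(np.mean(np.abs(dev)))
    viable = math.sqrt(value / n_harmonics) <= per_harmonic_tol
    lead = float(obs.mags[1:].max()) if obs.mags.size > 1 else 0.0
    return CostValue(value=value, viable=viable,
                     diagnostics={"leading_mag": lead, "mad": mad})


def peak_sequence_cost(gammas: np.ndarray, sigmas: np.ndarray) -> float:
    """E = -(1/P) sum sigma_i - sum_{i>=2} (gamma_i - gamma_{i-1}).

    The second sum telescopes to gamma_P - gamma_1, so the value equals
    -mean(sigma) - (gamma_P - gamma_1) for any peak sequence.
    """
    gammas = np.asarray(gammas, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    if gammas.size == 0:
        return 0.0
    if gammas.shape != sigmas.shape:
        raise ValueError("gamma/sigma length mismatch")
    return float(-sigmas.mean() - np.sum(np.diff(gammas)))


def peak_prominence_cost(
    obs: HarmonicSpectrum,
    E0: float,
    amplitude_window: tuple[float, float] | None = None,
    max_harmonic_bins: int = 50,
    prominence_frac: float = 0.01,
) -> CostValue:
    """Loose oscillation cost on the magnitude spectrum.

    Local maxima with prominence >= ``prominence_frac`` of the spectral
    maximum are detected on the first ``max_harmonic_bins`` harmonic bins
    past DC.  Peak magnitudes enter the cost sorted ascending, so the
    telescoped difference term equals -(gamma_max - gamma_min): a spectrum
    dominated by one prominent peak scores strongly negative.  sigma_i is
    the standard deviation of the 3-bin window centered on peak i.

    Viable iff value < E0 and the leading-harmonic magnitude (the spectral
    maximum past DC) lies inside ``amplitude_window``.  A spectrum with no
    detected peaks scores 0 and is non-viable.
    """
    mags = obs.mags[1 : max_harmonic_bins + 1]
    if mags.size < 3:
        raise ValueError("spectrum too short for peak detection")
    top = float(mags.max())
    if top <= 0:
        return CostValue(value=0.0, viable=False, diagnostics={"n_peaks": 0})
    idx, _ = find_peaks(mags, prominence=prominence_frac * top)
    if idx.size == 0:
        return CostValue(value=0.0, viable=False, diagnostics={"n_peaks": 0})
    sigmas = np.empty(idx.size)
    padded = np.pad(mags, 1, mode="constant")
    for j, k in enumerate(idx):
        sigmas[j] = np.std(padded[k : k + 3])  # 3-bin window centered on peak
    order = np.argsort(mags[idx], kind="stable")
    gammas = mags[idx][order]
    value = peak_sequence_cost(gammas, sigmas[order])
    lead = float(obs.mags[1:].max())
    viable = value < E0
    if amplitude_window is not None:
        lo, hi = amplitude_window
        viable = viable and (lo <= lead <= hi)
    return CostValue(
        value=value,
        viable=viable,
        diagnostics={"n_peaks": int(idx.size), "leading_mag": lead,
                     "mean_sigma": float(sigmas.mean())},
    )


def time_mse(
    traj: Trajectory,
    targets: dict[str, float],
    tol: float,
    discard_fraction: float = 0.5,
) -> CostValue:
    """Time-domain MSE against constant target levels for chosen species.

    The initial ``discard_fraction`` of the window is dropped so the
    relaxation from the initial condition does not dominate the score.
    The cost value is the mean squared deviation; viable iff the rms
    deviation is <= tol (nM).
    """
    t = traj.t
    keep = t >= t[0] + discard_fraction * (t[-1] - t[0])
    devs = [traj.column(s)[keep] - level for s, level in targets.items()]
    dev = np.concatenate(devs)
    value = float(np.mean(dev**2))
    mad = float(np.mean(np.abs(dev)))
    return CostValue(value=value, viable=math.sqrt(value) <= tol,
                     diagnostics={"rms": math.sqrt(value), "mad": mad})


def measure_oscillation(traj: Trajectory, species: str) -> dict[str, float]:
    """Spectral period/amplitude readout of a (near-)periodic trajectory.

    Period and amplitude are taken from the leading harmonic of the
    mean-removed rectangular-window FFT over the full simulated window: the
    amplitude is the size of the leading harmonic, the period the inverse of
    its frequency.  Peak-based diagnostics (mean inter-peak interval, half
    peak-to-trough excursion) are reported alongside.
    """
    y = traj.column(species)
    n = y.size
    mags = 2.0 * np.abs(np.fft.rfft(y - y.mean())) / n
    freqs = np.fft.rfftfreq(n, traj.dt)
    k = int(np.argmax(mags[1:])) + 1
    out = {
        "period": float(1.0 / freqs[k]),
        "amplitude": float(mags[k]),
    }
    span = y.max() - y.min()
    if span > 0:
        pk, _ = find_peaks(y, prominence=0.05 * span)
        tr, _ = find_peaks(-y, prominence=0.05 * span)
        if pk.size > 1:
            out["period_interpeak"] = float(np.mean(np.diff(traj.t[pk])))
        if pk.size and tr.size:
            out["amplitude_ptp_half"] = float((y[pk].mean() - y[tr].mean()) / 2.0)
    return out


# ---------------------------------------------------------------------------
# Candidate evaluation: model + cost -> viability predicate
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """Simulation protocol for one viability evaluation.

    ``y0_list`` holds one initial state per sub-scenario (bistability uses
    two swapped initial conditions; oscillation costs use one).
    """

    y0_list: tuple[tuple[float, ...], ...]
    duration: float
    dt_out: float = 0.05
    # per-sub-scenario target levels for time_mse, keyed by species
    targets: tuple[dict[str, float], ...] | None = None


class Evaluator:
    """Callable viability predicate: theta -> CostValue.

    Wraps a model, a cost specification and a simulation scenario.  Solver
    failures (non-finite states, integrator errors) mark the candidate
    non-viable with an infinite cost instead of raising.
    """

    def __init__(
        self,
        model: ModelSpec,
        cost: CostSpec,
        scenario: Scenario,
        space: ParameterSpace | None = None,
        tag: str = "",
    ) -> None:
        from .models import parameter_space

        self.model = model
        self.cost = cost
        self.scenario = scenario
        self.space = space or parameter_space(model)
        self.tag = tag or cost.kind
        self.n_sim_calls = 0

    def __call__(self, theta: ParameterPoint | np.ndarray) -> CostValue:
        if not isinstance(theta, ParameterPoint):
            theta = ParameterPoint(np.asarray(theta, dtype=float))
        try:
            return self._evaluate(theta)
        except (RuntimeError, ValueError, FloatingPointError):
            return CostValue(value=float("inf"), viable=False,
                             diagnostics={"failed": 1.0})

    def _evaluate(self, theta: ParameterPoint) -> CostValue:
        c = self.cost
        if c.kind == "time_mse":
            values, viable = [], True
            for y0, targets in zip(self.scenario.y0_list, self.scenario.targets):
                traj = self._simulate(theta, y0)
                cv = time_mse(traj, targets, c.per_harmonic_tol,
                              discard_fraction=c.discard_fraction or 0.5)
                values.append(cv.value)
                viable = viable and cv.viable
            return CostValue(value=float(np.mean(values)), viable=viable,
                             diagnostics={"rms": math.sqrt(float(np.mean(values)))})
        traj = self._simulate(theta, self.scenario.y0_list[0])
        sp = spectrum(traj, c.readout[0], c.ideal_period,
                      discard_fraction=c.discard_fraction)
        if c.kind == "harmonic_mse":
            ideal = ideal_harmonics(c.ideal_amplitude, c.ideal_period, traj)
            return harmonic_mse(sp, ideal, c.ideal_period, c.n_harmonics,
                                c.per_harmonic_tol)
        return peak_prominence_cost(sp, c.E0, c.amplitude_window)

    def _simulate(self, theta: ParameterPoint, y0) -> Trajectory:
        self.n_sim_calls += 1
        return simulate(self.model, theta, np.asarray(y0, dtype=float),
                        self.scenario.duration, self.scenario.dt_out,
                        space=self.space)


# Canonical study scenarios ---------------------------------------------------

SCENARIO_IDS = (
    "repressilator_s1",
    "repressilator_s2",
    "acdc_oscillatory",
    "acdc_bistable",
    "dflipflop",
)

_REP_Y0 = (0.0, 0.0, 0.0, 150.0, 0.0, 0.0)
_ACDC_Y0_A = (0.0, 0.0, 0.0, 37.0, 280.0, 280.0)  # X low / Y high
_ACDC_Y0_B = (0.0, 0.0, 0.0, 280.0, 37.0, 280.0)  # mirrored


def scenario(
    scenario_id: str,
    model: ModelSpec,
    duration: float | None = None,
    dt_out: float = 0.05,
) -> Evaluator:
    """Build the canonical viability evaluator for one study scenario.

    Default evaluation horizons: 48 h for the repressilator and AC-DC
    circuit (the window of every benchmark simulation), four clock periods
    (96 h) for the flip-flop.
    """
    if scenario_id == "repressilator_s1":
        cost = CostSpec(kind="harmonic_mse", ideal_amplitude=300.0,
                        ideal_period=12.0, n_harmonics=10,
                        per_harmonic_tol=10.0, readout=("X",))
        scen = Scenario(y0_list=(_REP_Y0,), duration=duration or 48.0,
                        dt_out=dt_out)
        return Evaluator(model, cost, scen, tag="oscillatory")
    if scenario_id == "repressilator_s2":
        cost = CostSpec(kind="peak_prominence", E0=-200.0,
                        amplitude_window=(200.0, 400.0), ideal_period=12.0,
                        readout=("X",))
        scen = Scenario(y0_list=(_REP_Y0,), duration=duration or 48.0,
                        dt_out=dt_out)
        return Evaluator(model, cost, scen, tag="oscillatory")
    if scenario_id == "acdc_oscillatory":
        cost = CostSpec(kind="harmonic_mse", ideal_amplitude=200.0,
                        ideal_period=12.0, n_harmonics=10,
                        per_harmonic_tol=15.0, readout=("X",))
        scen = Scenario(y0_list=(_ACDC_Y0_A,), duration=duration or 48.0,
                        dt_out=dt_out)
        return Evaluator(model, cost, scen, tag="oscillatory")
    if scenario_id == "acdc_bistable":
        cost = CostSpec(kind="time_mse", per_harmonic_tol=4.0,
                        readout=("X", "Y"), discard_fraction=0.5)
        scen = Scenario(
            y0_list=(_ACDC_Y0_A, _ACDC_Y0_B),
            duration=duration or 48.0,
            dt_out=dt_out,
            targets=({"X": 0.0, "Y": 400.0}, {"X": 400.0, "Y": 0.0}),
        )
        return Evaluator(model, cost, scen, tag="bistable")
    if scenario_id == "dflipflop":
        cost = CostSpec(kind="harmonic_mse", ideal_amplitude=50.0,
                        ideal_period=2.0 * model.clk_period, n_harmonics=10,
                        per_harmonic_tol=10.0, readout=("q",))
        scen = Scenario(y0_list=((0.0, 0.0, 0.0, 0.0),),
                        duration=duration or 4.0 * model.clk_period,
                        dt_out=dt_out)
        return Evaluator(model, cost, scen, tag="oscillatory")
    raise ValueError(f"unknown scenario {scenario_id!r}")
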