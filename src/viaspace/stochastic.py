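"""Stochastic validation with the Gillespie direct method.

Deterministic rate laws are projected directly onto stochastic propensities
(a quasi-steady-state reading of the Hill and Michaelis-Menten terms): each
production term of an ODE becomes one reaction firing at the term's rate
evaluated at the current integer copy numbers, and each degradation term a
first-order (or Michaelian) decay reaction.  With the reaction volume fixed
at V_R * N_A = 1 nM^-1, one molecule corresponds to 1 nM, so deterministic
and stochastic trajectories share axes.

The flip-flop clock enters as a piecewise-constant, time-varying propensity
input: waiting times are drawn with the usual exponential clock but jumps
are never allowed to step across a clock edge (the propensities are redrawn
at the edge instead), which is exact for piecewise-constant rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .models import (
    ModelSpec,
    ParameterPoint,
    ParameterSpace,
    Trajectory,
    parameter_space,
)

__all__ = [
    "ReactionNetwork",
    "EnsembleSummary",
    "project_qssa",
    "ssa_run",
    "summarize_ensemble",
]


@dataclass
class ReactionNetwork:
    """Integer-copy-number reaction system.

    ``propensities(state, t)`` returns the rate vector (h^-1) for the
    current state; ``stoich`` has one row per reaction.
    """

    species: tuple[str, ...]
    stoich: np.ndarray  # (R, S) integer state changes
    propensities: object  # callable (state, t) -> (R,) rates
    # times at which propensities change discontinuously within one period
    clock_period: float | None = None
    clock_edges: tuple[float, ...] = ()

    @property
    def n_reactions(self) -> int:
        return self.stoich.shape[0]


@dataclass
class EnsembleSummary:
    n_runs: int
    mean_amplitude: float | None = None  # nM
    mean_period: float | None = None  # h
    stable_state_distance: float | None = None  # nM
    per_run_amplitude: list = field(default_factory=list)
    per_run_period: list = field(default_factory=list)
    per_run_distance: list = field(default_factory=list)
    runs_without_peaks: int = 0


def project_qssa(
    model: ModelSpec,
    theta: ParameterPoint,
    space: ParameterSpace | None = None,
) -> ReactionNetwork:
    """Project a deterministic model at fixed parameters to reactions.

    One production and one degradation reaction per ODE term; for the
    repressilator and AC-DC circuit that is 12 reactions (6 production,
    6 degradation), for the flip-flop 8 production and 4 degradation.
    """
    space = space or parameter_space(model)
    p = theta.as_dict(space)
    S = len(model.species)

    if model.id in ("repressilator", "acdc"):
        stoich = np.zeros((12, S), dtype=int)
        for i in range(6):
            stoich[i, i] = 1  # production of species i
            stoich[6 + i, i] = -1  # degradation of species i

        if model.id == "repressilator":
            alpha, alpha0, n = p["alpha"], p["alpha0"], p["n"]
            kd, beta = p["Kd"], p["beta"]
            dm, dp = p["delta_m"], p["delta_p"]

            def props(x, t):
                mx, my, mz, X, Y, Z = x
                h = lambda v: (v / kd) ** n if v > 0 else 0.0
                return np.array([
                    alpha / (1.0 + h(Z)) + alpha0,
                    alpha / (1.0 + h(X)) + alpha0,
                    alpha / (1.0 + h(Y)) + alpha0,
                    beta * mx, beta * my, beta * mz,
                    dm * mx, dm * my, dm * mz,
                    dp * X, dp * Y, dp * Z,
                ])
        else:
            alpha, n, beta = p["alpha"], p["n"], p["beta"]
            dm, dp = p["delta_m"], p["delta_p"]
            kda, kdb, kdc, kdd = p["Kd_a"], p["Kd_b"], p["Kd_c"], p["Kd_d"]

            def props(x, t):
                mx, my, mz, X, Y, Z = x
                h = lambda v, kd: (v / kd) ** n if v > 0 else 0.0
                return np.array([
                    alpha / (1.0 + h(Z, kda) + h(Y, kdb)),
                    alpha / (1.0 + h(X, kdc)),
                    alpha / (1.0 + h(Y, kdd)),
                    beta * mx, beta * my, beta * mz,
                    dm * mx, dm * my, dm * mz,
                    dp * X, dp * Y, dp * Z,
                ])

        return ReactionNetwork(species=model.species, stoich=stoich,
                               propensities=props)

    # flip-flop: two production terms and one degradation per species
    a1, a2, a3, a4 = p["alpha1"], p["alpha2"], p["alpha3"], p["alpha4"]
    d1, d2 = p["delta1"], p["delta2"]
    kd, n = p["Kd"], p["n"]
    om1 = float(model.omega1)
    linear = model.omega2 == 1
    if not linear:
        km, eprot = p["K_M"], p["E_prot"]
    ddil = p.get("delta_dil", 0.6)
    period, amp, duty = model.clk_period, model.clk_amplitude, model.clk_duty
    counter = model.counter_mode

    stoich = np.zeros((12, 4), dtype=int)
    for i in range(4):
        stoich[2 * i, i] = 1
        stoich[2 * i + 1, i] = 1
        stoich[8 + i, i] = -1

    def props(x, t):
        a, ac, q, qc = x
        clk = amp if (t % period) / period < duty else 0.0
        d = qc if counter else 0.0
        h = lambda v: (v / kd) ** n if v > 0 else 0.0
        hd, hclk, ha, hac, hq, hqc = h(d), h(clk), h(a), h(ac), h(q), h(qc)
        den_m = 1.0 + hd + hclk + om1 * hd * hclk
        P = a + ac + q + qc
        if linear:
            f1, f2 = d1, d2
        else:
            f1 = d1 * eprot / (km + P) + ddil
            f2 = d2 * eprot / (km + P) + ddil
        return np.array([
            a1 * hd / den_m, a2 / (1.0 + hac),
            a1 / den_m, a2 / (1.0 + ha),
            a3 * ha * hclk / (1.0 + ha + hclk + ha * hclk), a4 / (1.0 + hqc),
            a3 * hac * hclk / (1.0 + hac + hclk + hac * hclk), a4 / (1.0 + hq),
            a * f1, ac * f1, q * f2, qc * f2,
        ])

    half = period * duty
    return ReactionNetwork(species=model.species, stoich=stoich,
                           propensities=props, clock_period=period,
                           clock_edges=(0.0, half))


def _next_clock_edge(t: float, net: ReactionNetwork) -> float:
    period = net.clock_period
    base = math.floor(t / period) * period
    for k in range(3):
        for e in net.clock_edges:
            edge = base + k * period + e
            if edge > t + 1e-12:
                return edge
    return t + period


def ssa_run(
    net: ReactionNetwork,
    y0: np.ndarray,
    duration: float,
    rng: np.random.Generator,
    dt_out: float = 0.05,
    max_events: int = 5_000_000,
    return_events: bool = False,
):
    """One Gillespie direct-method realization, sampled to a uniform grid.

    Exponential waiting times from the total propensity; categorical choice
    of the firing reaction.  A zero total propensity freezes the state; for
    clock-driven networks the simulation still advances to the next clock
    edge, where propensities may revive.  With ``return_events`` the raw
    reaction-firing times are returned alongside the trajectory.
    """
    y0 = np.asarray(y0)
    if np.any(y0 < 0) or not np.issubdtype(y0.dtype, np.integer):
        y0 = np.round(np.asarray(y0, dtype=float)).astype(np.int64)
        if np.any(y0 < 0):
            raise ValueError("initial copy numbers must be non-negative")
    t_grid = np.arange(0.0, duration + 0.5 * dt_out, dt_out)
    out = np.empty((t_grid.size, y0.size), dtype=float)
    state = y0.astype(np.int64)
    t = 0.0
    gi = 0
    events: list[float] = []
    clocked = net.clock_period is not None
    for _ in range(max_events):
        rates = net.propensities(state.astype(float), t)
        total = float(rates.sum())
        if total <= 0.0:
            t_next = _next_clock_edge(t, net) if clocked else duration
        else:
            t_next = t + rng.exponential(1.0 / total)
            if clocked:
                edge = _next_clock_edge(t, net)
                if t_next > edge:  # redraw beyond the edge: rates change there
                    t_next = edge
                    total = 0.0
        while gi < t_grid.size and t_grid[gi] < min(t_next, duration) + 1e-12:
            out[gi] = state
            gi += 1
        if t_next >= duration:
            break
        t = t_next
        if total > 0.0:
            r = rng.random() * total
            j = int(np.searchsorted(np.cumsum(rates), r))
            state = state + net.stoich[j]
            if return_events:
                events.append(t)
    while gi < t_grid.size:
        out[gi] = state
        gi += 1
    traj = Trajectory(t=t_grid, y=out, species=net.species)
    if return_events:
        return traj, np.asarray(events)
    return traj


def summarize_ensemble(
    runs: list[Trajectory],
    mode: str,
    species: str | tuple[str, str] = "X",
    smooth_window: float = 1.0,
) -> EnsembleSummary:
    """Amplitude/period (oscillatory) or state-distance (bistable) statistics.

    Oscillatory runs are lightly smoothed with a moving average before peak
    detection (stochastic traces are jagged); amplitude is half the mean
    peak-to-trough excursion, the period the mean inter-peak interval.
    Runs with fewer than two detected peaks are excluded from the period
    average and counted.  Bistable mode reports |mean(high) - mean(low)|
    over the final third of each run for the two designated species.
    """
    if not runs:
        raise ValueError("need at least one run")
    summary = EnsembleSummary(n_runs=len(runs))
    if mode == "bistable":
        s_hi, s_lo = species if isinstance(species, tuple) else (species, species)
        for tr in runs:
            cut = tr.t >= tr.t[0] + 2.0 * (tr.t[-1] - tr.t[0]) / 3.0
            d = abs(float(tr.column(s_hi)[cut].mean())
                    - float(tr.column(s_lo)[cut].mean()))
            summary.per_run_distance.append(d)
        summary.stable_state_distance = float(np.mean(summary.per_run_distance))
        return summary
    if mode != "oscillatory":
        raise ValueError("mode must be 'oscillatory' or 'bistable'")
    sp = species if isinstance(species, str) else species[0]
    for tr in runs:
        y = tr.column(sp)
        w = max(1, int(round(smooth_window / tr.dt)))
        if w > 1:
            y = np.convolve(y, np.ones(w) / w, mode="same")
        span = y.max() - y.min()
        if span <= 0:
            summary.runs_without_peaks += 1
            continue
        pk, _ = find_peaks(y, prominence=0.2 * span)
        trough, _ = find_peaks(-y, prominence=0.2 * span)
        if pk.size and trough.size:
            amp = (y[pk].mean() - y[trough].mean()) / 2.0
            summary.per_run_amplitude.append(float(amp))
        if pk.size > 1:
            summary.per_run_period.append(float(np.mean(np.diff(tr.t[pk]))))
        else:
            summary.runs_without_peaks += 1
    if summary.per_run_amplitude:
        summary.mean_amplitude = float(np.mean(summary.per_run_amplitude))
    if summary.per_run_period:
        summary.mean_period = float(np.mean(summary.per_run_period))
    return summary
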