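"""Deterministic ODE models of three synthetic gene regulatory circuits.

Three circuits are bundled:

``repressilator``
    Three repressors in a negative-feedback ring (mRNA + protein per gene,
    six state variables).  Sustains limit-cycle oscillations for suitable
    kinetic parameters.
``acdc``
    A toggle switch fused with a repressilator ring.  Depending on the
    kinetic parameters the same topology oscillates ("AC") or latches into
    one of two stable states ("DC").
``dflipflop``
    An edge-triggered master-slave D flip-flop built from two coupled
    bistable switches, driven by an exogenous clock signal CLK and a data
    input d.  With the input wired to the inverted output (d = q_c) it acts
    as a 1-bit counter and oscillates at half the clock frequency.

Concentrations are in nM, time in hours, rates in h^-1.  Parameter bounds
define the feasible hyper-box explored by the search machinery; they reflect
rough physiological ranges for prokaryotic/eukaryotic kinetic rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import odeint

__all__ = [
    "ParameterSpace",
    "ParameterPoint",
    "ModelSpec",
    "Trajectory",
    "get_model",
    "parameter_space",
    "rhs",
    "simulate",
    "clk_signal",
    "check_bounds",
    "MODEL_IDS",
]

MODEL_IDS = ("repressilator", "acdc", "dflipflop")

# Feasible ranges per biochemical parameter class (units: h^-1 or nM).
_BOUNDS = {
    "transcription": (1e-2, 50.0),
    "translation": (1e-2, 50.0),
    "protein_production": (1e-1, 50.0),
    "protein_degradation": (1e-3, 50.0),
    "mrna_degradation": (1e-1, 100.0),
    "dissociation": (1e-2, 250.0),
    "michaelis": (1e-2, 250.0),
    "protease": (10.0, 1000.0),
    "hill": (1.0, 5.0),
}

DILUTION_RATE = 0.6  # h^-1, fixed
REACTION_VOLUME = 1.0  # V_R * N_A in nM^-1, fixed: 1 molecule == 1 nM


@dataclass(frozen=True)
class ParameterSpace:
    """Axis-aligned hyper-box of feasible kinetic parameter values.

    The free parameters span the Cartesian product of per-parameter ranges;
    ``fixed`` holds constants excluded from search and volume bookkeeping
    (dilution rate, reaction volume).
    """

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != upper.shape or lower.shape != (len(self.names),):
            raise ValueError("bounds must match parameter names")
        if not np.all(lower < upper):
            raise ValueError("lower bounds must be strictly below upper bounds")

    @property
    def dim(self) -> int:
        return len(self.names)

    def contains(self, values: np.ndarray) -> np.ndarray:
        """Elementwise feasibility of one point (p,) or many (m, p)."""
        v = np.atleast_2d(np.asarray(values, dtype=float))
        ok = np.all((v >= self.lower) & (v <= self.upper), axis=1)
        return ok if np.asarray(values).ndim > 1 else bool(ok[0])

    def clip(self, values: np.ndarray) -> np.ndarray:
        return np.clip(values, self.lower, self.upper)

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, self.dim))

    def volume(self) -> float:
        """Volume of the full feasible box over the free parameters."""
        return float(np.prod(self.upper - self.lower))

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class ParameterPoint:
    """One candidate parameter vector, ordered as ``ParameterSpace.names``."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def as_dict(self, space: ParameterSpace) -> dict[str, float]:
        d = {n: float(v) for n, v in zip(space.names, self.values)}
        d.update(space.fixed)
        return d


@dataclass(frozen=True)
class ModelSpec:
    """Identity and wiring of one of the bundled circuit models."""

    id: str
    omega1: int = 1  # flip-flop only: 0 competitive, 1 independent TF binding
    omega2: int = 1  # flip-flop only: 0 Michaelian, 1 linear degradation
    clk_period: float = 24.0  # h, flip-flop clock
    clk_amplitude: float = 100.0  # nM
    clk_duty: float = 0.5
    counter_mode: bool = True  # wire d = q_c (1-bit counter)

    def __post_init__(self) -> None:
        if self.id not in MODEL_IDS:
            raise ValueError(f"unknown model id {self.id!r}")
        if self.id != "dflipflop" and (self.omega1, self.omega2) != (1, 1):
            raise ValueError("omega flags are only meaningful for the flip-flop")

    @property
    def species(self) -> tuple[str, ...]:
        if self.id == "dflipflop":
            return ("a", "a_c", "q", "q_c")
        return ("mX", "mY", "mZ", "X", "Y", "Z")


@dataclass(frozen=True)
class Trajectory:
    """Deterministic (or sampled stochastic) time course on a uniform grid."""

    t: np.ndarray
    y: np.ndarray
    species: tuple[str, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        if y.shape != (t.size, len(self.species)):
            raise ValueError("trajectory shape mismatch")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def column(self, name: str) -> np.ndarray:
        return self.y[:, self.species.index(name)]


def get_model(model_id: str, omega1: int = 1, omega2: int = 1, **kwargs) -> ModelSpec:
    if model_id == "dflipflop":
        return ModelSpec(id=model_id, omega1=int(omega1), omega2=int(omega2), **kwargs)
    return ModelSpec(id=model_id, **kwargs)


def parameter_space(model: ModelSpec) -> ParameterSpace:
    """Feasible parameter box for a model variant.

    Flip-flop variants with linear degradation drop the Michaelis constant
    and protease concentration from the free parameters, so the search
    dimension matches the functional form actually simulated.
    """
    b = _BOUNDS
    if model.id == "repressilator":
        spec = [
            ("alpha", b["transcription"]),
            ("alpha0", b["transcription"]),
            ("n", b["hill"]),
            ("beta", b["translation"]),
            ("delta_m", b["mrna_degradation"]),
            ("delta_p", b["protein_degradation"]),
            ("Kd", b["dissociation"]),
        ]
        fixed = {}
    elif model.id == "acdc":
        spec = [
            ("alpha", b["transcription"]),
            ("n", b["hill"]),
            ("beta", b["translation"]),
            ("delta_m", b["mrna_degradation"]),
            ("delta_p", b["protein_degradation"]),
            ("Kd_a", b["dissociation"]),
            ("Kd_b", b["dissociation"]),
            ("Kd_c", b["dissociation"]),
            ("Kd_d", b["dissociation"]),
        ]
        fixed = {}
    else:
        spec = [
            ("alpha1", b["protein_production"]),
            ("alpha2", b["protein_production"]),
            ("alpha3", b["protein_production"]),
            ("alpha4", b["protein_production"]),
            ("delta1", b["protein_degradation"]),
            ("delta2", b["protein_degradation"]),
            ("Kd", b["dissociation"]),
            ("n", b["hill"]),
        ]
        if model.omega2 == 0:  # Michaelian degradation uses the protease pool
            spec += [("K_M", b["michaelis"]), ("E_prot", b["protease"])]
        fixed = {"delta_dil": DILUTION_RATE}
    names = tuple(n for n, _ in spec)
    lower = np.array([lo for _, (lo, hi) in spec])
    upper = np.array([hi for _, (lo, hi) in spec])
    return ParameterSpace(names=names, lower=lower, upper=upper, fixed=fixed)


def clk_signal(t, period: float, amplitude: float, duty: float = 0.5):
    """Square clock waveform: high for the first ``duty`` fraction of each cycle."""
    if period <= 0:
        raise ValueError("period must be positive")
    if not 0 < duty < 1:
        raise ValueError("duty must be in (0, 1)")
    phase = np.mod(np.asarray(t, dtype=float), period) / period
    return np.where(phase < duty, amplitude, 0.0)


def check_bounds(theta: ParameterPoint, space: ParameterSpace) -> bool:
    """True iff the point lies within the feasible box (bounds inclusive)."""
    if theta.values.shape != (space.dim,):
        raise ValueError("parameter dimension mismatch")
    return bool(space.contains(theta.values))


def _hill(x: float, kd: float, n: float) -> float:
    # x >= 0 after clipping; guard the 0^n corner for numerical safety
    if x <= 0.0:
        return 0.0
    return (x / kd) ** n


def _rhs_closure(model: ModelSpec, theta: ParameterPoint, space: ParameterSpace):
    """Build a fast f(y, t) -> dy/dt closure with parameters unpacked once."""
    p = theta.as_dict(space)
    if model.id == "repressilator":
        alpha, alpha0 = p["alpha"], p["alpha0"]
        n, beta = p["n"], p["beta"]
        dm, dp, kd = p["delta_m"], p["delta_p"], p["Kd"]
        if kd <= 0:
            raise ValueError("Kd must be positive")

        def f(y, t):
            mx, my, mz, X, Y, Z = y
            return (
                -dm * mx + alpha / (1.0 + _hill(Z, kd, n)) + alpha0,
                -dm * my + alpha / (1.0 + _hill(X, kd, n)) + alpha0,
                -dm * mz + alpha / (1.0 + _hill(Y, kd, n)) + alpha0,
                beta * mx - dp * X,
                beta * my - dp * Y,
                beta * mz - dp * Z,
            )

        return f

    if model.id == "acdc":
        alpha, n, beta = p["alpha"], p["n"], p["beta"]
        dm, dp = p["delta_m"], p["delta_p"]
        kda, kdb, kdc, kdd = p["Kd_a"], p["Kd_b"], p["Kd_c"], p["Kd_d"]
        if min(kda, kdb, kdc, kdd) <= 0:
            raise ValueError("dissociation constants must be positive")

        def f(y, t):
            mx, my, mz, X, Y, Z = y
            return (
                -dm * mx + alpha / (1.0 + _hill(Z, kda, n) + _hill(Y, kdb, n)),
                -dm * my + alpha / (1.0 + _hill(X, kdc, n)),
                -dm * mz + alpha / (1.0 + _hill(Y, kdd, n)),
                beta * mx - dp * X,
                beta * my - dp * Y,
                beta * mz - dp * Z,
            )

        return f

    # master-slave D flip-flop
    a1, a2, a3, a4 = p["alpha1"], p["alpha2"], p["alpha3"], p["alpha4"]
    d1, d2 = p["delta1"], p["delta2"]
    kd, n = p["Kd"], p["n"]
    if kd <= 0:
        raise ValueError("Kd must be positive")
    om1 = float(model.omega1)
    linear = model.omega2 == 1
    if not linear:
        km, eprot = p["K_M"], p["E_prot"]
        if km <= 0:
            raise ValueError("K_M must be positive")
    ddil = p.get("delta_dil", DILUTION_RATE)
    period, amp, duty = model.clk_period, model.clk_amplitude, model.clk_duty
    counter = model.counter_mode

    def f(y, t, clk_override=None):
        a, ac, q, qc = y
        if clk_override is None:
            clk = amp if (t % period) / period < duty else 0.0
        else:
            clk = clk_override
        d = qc if counter else 0.0
        hd = _hill(d, kd, n)
        hclk = _hill(clk, kd, n)
        ha = _hill(a, kd, n)
        hac = _hill(ac, kd, n)
        hq = _hill(q, kd, n)
        hqc = _hill(qc, kd, n)
        den_master = 1.0 + hd + hclk + om1 * hd * hclk
        P = a + ac + q + qc
        if linear:
            fdeg1, fdeg2 = d1, d2
        else:
            fdeg1 = d1 * eprot / (km + P) + ddil
            fdeg2 = d2 * eprot / (km + P) + ddil
        da = a1 * hd / den_master + a2 / (1.0 + hac) - a * fdeg1
        dac = a1 / den_master + a2 / (1.0 + ha) - ac * fdeg1
        dq = a3 * ha * hclk / (1.0 + ha + hclk + ha * hclk) + a4 / (1.0 + hqc) - q * fdeg2
        dqc = a3 * hac * hclk / (1.0 + hac + hclk + hac * hclk) + a4 / (1.0 + hq) - qc * fdeg2
        return (da, dac, dq, dqc)

    return f


def rhs(
    model: ModelSpec,
    state: np.ndarray,
    t: float,
    theta: ParameterPoint,
    space: ParameterSpace | None = None,
) -> np.ndarray:
    """Right-hand side of the model ODEs at one state/time."""
    space = space or parameter_space(model)
    state = np.asarray(state, dtype=float)
    if state.shape != (len(model.species),):
        raise ValueError("state dimension mismatch")
    f = _rhs_closure(model, theta, space)
    return np.asarray(f(state, t), dtype=float)


def simulate(
    model: ModelSpec,
    theta: ParameterPoint,
    y0: np.ndarray,
    duration: float,
    dt_out: float = 0.05,
    space: ParameterSpace | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> Trajectory:
    """Integrate the model with an adaptive stiff-capable scheme (LSODA).

    The flip-flop clock is a piecewise-constant square wave; the trajectory
    is integrated segment by segment between clock transitions, with CLK held
    constant inside each segment, so the solver never steps across a
    discontinuous right-hand side.  Output states are clipped at zero to
    suppress tiny negative solver excursions.

    Raises ``RuntimeError`` on integrator failure / non-finite states; the
    search layers catch this and mark the candidate non-viable.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    y0 = np.asarray(y0, dtype=float)
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")
    space = space or parameter_space(model)
    f = _rhs_closure(model, theta, space)
    t = np.arange(0.0, duration + 0.5 * dt_out, dt_out)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        if model.id == "dflipflop":
            y = _integrate_piecewise(model, f, y0, t, rtol, atol)
        else:
            y, info = odeint(
                f, y0, t, rtol=rtol, atol=atol, full_output=True, mxstep=10000
            )
            if info["message"] != "Integration successful.":
                raise RuntimeError(f"integration failed: {info['message']}")
    if not np.all(np.isfinite(y)):
        raise RuntimeError("integration produced non-finite state")
    return Trajectory(t=t, y=np.clip(y, 0.0, None), species=model.species)


def _integrate_piecewise(model, f, y0, t, rtol, atol):
    """Segment-wise integration of the clock-driven flip-flop."""
    half = model.clk_period * model.clk_duty
    edges = [0.0]
    k = 0.0
    while k < t[-1]:
        for e in (k, k + half):
            if 0.0 < e < t[-1]:
                edges.append(e)
        k += model.clk_period
    edges.append(t[-1])
    edges = sorted(set(edges))
    y = np.empty((t.size, y0.size))
    state = np.asarray(y0, dtype=float)
    for lo, hi in zip(edges[:-1], edges[1:]):
        clk = float(clk_signal(lo + 1e-9, model.clk_period, model.clk_amplitude,
                               model.clk_duty))
        mask = (t >= lo - 1e-12) & (t <= hi + 1e-12)
        seg_t = np.unique(np.concatenate(([lo], t[mask], [hi])))
        seg_y, info = odeint(
            lambda yy, tt: f(yy, tt, clk), state, seg_t,
            rtol=rtol, atol=atol, full_output=True, mxstep=10000,
        )
        if info["message"] != "Integration successful.":
            raise RuntimeError(f"integration failed: {info['message']}")
        # write back rows that correspond to requested output times
        idx = np.searchsorted(seg_t, t[mask])
        y[mask] = seg_y[idx]
        state = seg_y[-1]
    return y
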