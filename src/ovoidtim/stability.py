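"""Two-state equilibrium unfolding: simulation and linear-extrapolation fits.

The chemical-denaturation model is the standard two-state transition with
linear folded/unfolded baselines (Santoro-Bolen form): at denaturant
concentration ``x`` the observed signal is

    y(x) = [ (a_f + b_f x) + (a_u + b_u x) K(x) ] / [ 1 + K(x) ],
    K(x) = exp( -(dG - m x) / RT ),

where ``dG`` is the folding free energy at zero denaturant (kcal/mol,
positive = stable), ``m`` the denaturant dependence (kcal/mol/M) and
``Cm = dG/m`` the transition midpoint (M).  Fits are nonlinear least
squares over (dG, m, a_f, b_f, a_u, b_u) with standard errors from the
covariance of the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DenaturationCurve",
    "TwoStateFit",
    "MeltReport",
    "simulate_curve",
    "fit_two_state",
    "thermal_melt_summary",
]

GAS_CONSTANT_KCAL = 1.9872041e-3  # kcal / (mol K)
DEFAULT_TEMPERATURE = 298.15  # K ("room temperature")


@dataclass
class DenaturationCurve:
    """Denaturant concentration series (M) and CD signal (arbitrary units)."""

    denaturant: np.ndarray
    signal: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        self.denaturant = np.asarray(self.denaturant, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.denaturant.shape != self.signal.shape:
            raise ValueError("denaturant and signal must have equal length")
        if np.any(self.denaturant < 0):
            raise ValueError("denaturant concentrations must be non-negative")
        if np.any(np.diff(self.denaturant) < 0):
            raise ValueError("denaturant series must be sorted")

    def to_table(self) -> str:
        lines = ["denaturant_M\tsignal"]
        lines += [f"{x:.6g}\t{y:.6g}" for x, y in zip(self.denaturant, self.signal)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_table(cls, text: str, temperature: float = DEFAULT_TEMPERATURE):
        rows = [ln.split() for ln in text.strip().splitlines()[1:]]
        x = np.array([float(r[0]) for r in rows])
        y = np.array([float(r[1]) for r in rows])
        return cls(x, y, temperature)


@dataclass
class TwoStateFit:
    dG: float  # kcal/mol, folding free energy at 0 M
    m_value: float  # kcal/mol/M
    Cm: float  # M
    a_f: float
    b_f: float
    a_u: float
    b_u: float
    errors: dict[str, float] = field(default_factory=dict)
    RT: float = GAS_CONSTANT_KCAL * DEFAULT_TEMPERATURE


def two_state_signal(x, dG, m_value, a_f, b_f, a_u, b_u, RT):
    """Signal of the two-state model with linear baselines."""
    arg = np.clip(-(dG - m_value * np.asarray(x, dtype=float)) / RT, -500, 500)
    K = np.exp(arg)
    return ((a_f + b_f * x) + (a_u + b_u * x) * K) / (1.0 + K)


def simulate_curve(
    dG: float,
    m_value: float,
    baselines: Sequence[float] = (1.0, -0.01, 0.05, -0.005),
    x: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    temperature: float = DEFAULT_TEMPERATURE,
) -> DenaturationCurve:
    """Simulate a denaturation curve with Gaussian noise.

    ``baselines`` is (a_f, b_f, a_u, b_u): intercept/slope of the folded
    (pre-transition) and unfolded (post-transition) baselines.
    """
    if m_value <= 0:
        raise ValueError("m_value must be positive")
    x = np.linspace(0.0, 7.5, 30) if x is None else np.asarray(x, dtype=float)
    RT = GAS_CONSTANT_KCAL * temperature
    a_f, b_f, a_u, b_u = baselines
    y = two_state_signal(x, dG, m_value, a_f, b_f, a_u, b_u, RT)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(x))
    return DenaturationCurve(denaturant=x, signal=y, temperature=temperature)


def _initial_guess(x: np.ndarray, y: np.ndarray, RT: float):
    n_edge = max(3, len(x) // 10)
    pf = np.polyfit(x[:n_edge], y[:n_edge], 1)
    pu = np.polyfit(x[-n_edge:], y[-n_edge:], 1)
    mid_level = 0.5 * (np.polyval(pf, x).mean() + np.polyval(pu, x).mean())
    cm0 = float(x[np.argmin(np.abs(y - mid_level))])
    cm0 = min(max(cm0, x[1]), x[-2]) if len(x) > 3 else cm0
    span = max(0.5, 0.25 * (x[-1] - x[0]))
    m0 = 4.0 * RT / span
    return [m0 * cm0, m0, pf[1], pf[0], pu[1], pu[0]]


def fit_two_state(curve: DenaturationCurve) -> TwoStateFit:
    """Fit the two-state linear-extrapolation model to a curve.

    Requires at least 8 points spanning both baselines and the
    transition; warns when the fitted midpoint falls outside the sampled
    range and raises on non-convergence.
    """
    x, y = curve.denaturant, curve.signal
    if len(x) < 8:
        raise ValueError("need at least 8 points to fit both baselines")
    RT = GAS_CONSTANT_KCAL * curve.temperature

    def f(x, dG, m_value, a_f, b_f, a_u, b_u):
        return two_state_signal(x, dG, m_value, a_f, b_f, a_u, b_u, RT)

    p0 = _initial_guess(x, y, RT)
    try:
        popt, pcov = curve_fit(f, x, y, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(
            f"two-state fit did not converge (initial guess {p0}): {err}"
        ) from err
    dG, m_value, a_f, b_f, a_u, b_u = popt
    if m_value < 0:  # sign-degenerate optimum; flip to the cooperative branch
        dG, m_value = -dG, -m_value
        a_f, b_f, a_u, b_u = a_u, b_u, a_f, b_f
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    cm = dG / m_value
    if not (x[0] <= cm <= x[-1]):
        warnings.warn(f"transition midpoint {cm:.2f} M outside sampled range")
    names = ("dG", "m_value", "a_f", "b_f", "a_u", "b_u")
    return TwoStateFit(
        dG=float(dG),
        m_value=float(m_value),
        Cm=float(cm),
        a_f=float(a_f),
        b_f=float(b_f),
        a_u=float(a_u),
        b_u=float(b_u),
        errors={n: float(e) for n, e in zip(names, perr)},
        RT=RT,
    )


@dataclass
class MeltReport:
    fractional_change: float
    transition_detected: bool
    apparent_midpoint: float | None
    reversible: bool | None
    message: str


def thermal_melt_summary(
    temperature: Sequence[float],
    signal: Sequence[float],
    cooled_signal: float | None = None,
    reversibility_tolerance: float = 0.1,
) -> MeltReport:
    """Summarize a thermal melt monitored by CD.

    Reports the fractional signal change from start to the final
    temperature; fits an apparent midpoint only when a sigmoidal
    transition is detected (relative change above 20% of the signal
    scale), otherwise reports "no complete transition" — the behaviour
    of hyperstable designs that remain folded at 95 °C.
    """
    T = np.asarray(temperature, dtype=float)
    y = np.asarray(signal, dtype=float)
    if np.any(np.diff(T) <= 0):
        raise ValueError("temperature grid must be strictly increasing")
    scale = float(np.max(np.abs(y))) or 1.0
    change = float(y[-1] - y[0])
    frac = change / scale
    detected = abs(frac) > 0.2
    midpoint = None
    if detected:
        def logistic(t, lo, hi, tm, k):
            return lo + (hi - lo) / (1.0 + np.exp(-(t - tm) / k))

        p0 = [y[0], y[-1], float(T[np.argmin(np.abs(y - 0.5 * (y[0] + y[-1])))]), 3.0]
        try:
            popt, _ = curve_fit(logistic, T, y, p0=p0, maxfev=10000)
            midpoint = float(popt[2])
        except RuntimeError:
            detected = False
    reversible = None
    if cooled_signal is not None:
        reversible = bool(abs(cooled_signal - y[0]) <= reversibility_tolerance * scale)
    return MeltReport(
        fractional_change=frac,
        transition_detected=detected,
        apparent_midpoint=midpoint,
        reversible=reversible,
        message=(
            f"apparent midpoint {midpoint:.1f}" if detected and midpoint is not None
            else "no complete transition"
        ),
    )
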