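"""Continuous-variation (Job) analysis and fast-exchange NMR titration.

The Job method varies the guest mole fraction x at fixed total
concentration and locates the maximum of a response proportional to the
complex concentration: a p:q (guest:host) complex peaks at x = p/(p+q),
so a 1:1 complex peaks at 0.5.  The NMR titration exploits fast exchange:
the observed chemical-shift displacement of a guest proton is the
population-weighted average Δδ = Δδ_max · [complex]/C_guest, from which a
shared Ka and per-proton limiting shifts Δδ_max are fitted globally.
Shift displacements are stored signed (δ_free − δ_complex); shielding on
inclusion gives negative values which are never rectified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit

from .binding import BindingSystem, solve_equilibrium
from .core import TernaryComposition

__all__ = [
    "JobSeries",
    "TitrationSeries",
    "job_curve",
    "estimate_stoichiometry",
    "delta_obs_1to1",
    "fit_titration",
    "TitrationFit",
]

# species diffusivities are irrelevant to pure speciation; any positive
# placeholder works for BindingSystem here
_D_PLACEHOLDER = dict(D_guest=1.0, D_host=0.5, D_complex=0.4)


@dataclass
class JobSeries:
    """A continuous-variation series at fixed total concentration."""

    C_total: float
    x: np.ndarray
    y: np.ndarray
    wavelength: float | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y differ in length")
        if np.any((self.x < 0) | (self.x > 1)):
            raise ValueError("mole fractions must lie in [0, 1]")
        if np.any(np.diff(self.x) < 0):
            raise ValueError("mole fractions must be sorted")


@dataclass
class TitrationSeries:
    """Host/guest molar ratios vs per-proton shift displacements (ppm)."""

    ratio: np.ndarray
    ddelta: dict[str, np.ndarray]
    C_guest: float

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=float)
        if np.any(self.ratio < 0) or np.any(np.diff(self.ratio) <= 0):
            raise ValueError("ratios must be nonnegative and increasing")
        if not self.ddelta:
            raise ValueError("need at least one proton column")
        self.ddelta = {k: np.asarray(v, dtype=float) for k, v in self.ddelta.items()}
        for k, v in self.ddelta.items():
            if v.shape != self.ratio.shape:
                raise ValueError(f"proton {k}: length mismatch")


def _complex_conc(Ka: float, guest: float, host: float,
                  p: int, q: int) -> float:
    """Equilibrium complex concentration of a GpHq complex."""
    if p == 1 and q == 1:
        system = BindingSystem(Ka=Ka, **_D_PLACEHOLDER)
        return solve_equilibrium(system, TernaryComposition(guest, host)).C_complex
    zmax = min(guest / p, host / q)
    if Ka == 0 or zmax <= 0:
        return 0.0

    def f(z):
        return Ka * (guest - p * z) ** p * (host - q * z) ** q - z

    return brentq(f, 0.0, zmax, xtol=1e-18, rtol=1e-14)


def job_curve(Ka: float, C_total: float, n: int,
              stoich: tuple[int, int] = (1, 1)) -> JobSeries:
    """Noiseless Job curve: complex concentration vs guest mole fraction.

    ``stoich`` is (p, q) for a GpHq guest:host complex; p=q=1 uses the
    closed-form 1:1 speciation, other small integer stoichiometries are
    solved numerically.
    """
    if Ka < 0 or C_total <= 0:
        raise ValueError("Ka must be nonnegative, C_total positive")
    if n < 3:
        raise ValueError("need at least three grid points")
    p, q = stoich
    if p < 1 or q < 1 or p > 4 or q > 4:
        raise NotImplementedError(f"unsupported stoichiometry {stoich}")
    x = np.linspace(0.0, 1.0, n)
    y = np.array([_complex_conc(Ka, xi * C_total, (1 - xi) * C_total, p, q)
                  for xi in x])
    return JobSeries(C_total=C_total, x=x, y=y)


def estimate_stoichiometry(series: JobSeries) -> dict:
    """Locate the Job maximum and infer the guest:host ratio.

    The discrete maximum is refined by quadratic interpolation through the
    three bracketing points; the inferred ratio is x_max/(1−x_max) (1.0
    for a 1:1 complex, 0.5 for 1:2).  A maximum on the boundary means no
    complexation signal.
    """
    x, y = series.x, series.y
    if x.size < 5:
        raise ValueError("need at least five points")
    i = int(np.argmax(y))
    if i == 0 or i == x.size - 1:
        raise ValueError("no interior maximum: response is monotone (no complexation)")
    x3, y3 = x[i - 1:i + 2], y[i - 1:i + 2]
    a, b, _ = np.polyfit(x3, y3, 2)
    x_max = float(-b / (2 * a)) if a < 0 else float(x[i])
    half_width = float(0.5 * (x3[-1] - x3[0]))
    return {
        "x_max": x_max,
        "x_max_uncertainty": half_width,
        "ratio": x_max / (1.0 - x_max),
    }


def delta_obs_1to1(Ka: float, ddelta_max: float, C_guest: float,
                   C_host: float) -> float:
    """Fast-exchange observed shift displacement, ppm.

    Δδ = Δδ_max · [GH]/C_guest — the bound population times the limiting
    displacement.  Saturates to Δδ_max as host is added in excess.
    """
    if C_guest <= 0:
        raise ValueError("guest concentration must be positive")
    if Ka < 0 or C_host < 0:
        raise ValueError("Ka and host concentration must be nonnegative")
    system = BindingSystem(Ka=Ka, **_D_PLACEHOLDER)
    eq = solve_equilibrium(system, TernaryComposition(C_guest, C_host))
    return ddelta_max * eq.C_complex / C_guest


@dataclass
class TitrationFit:
    """Global titration fit: shared Ka, per-proton Δδ_max."""

    Ka: float
    Ka_sd: float
    ddelta_max: dict[str, float]
    rss: float
    converged: bool
    identifiable: bool


def fit_titration(series: TitrationSeries) -> TitrationFit:
    """Global nonlinear least squares over all proton columns.

    One Ka is shared; each proton gets its own limiting displacement.
    All-zero data leave Ka unidentifiable (flagged, no exception).
    """
    if series.ratio.size < 4:
        raise ValueError("need at least four titration points")
    protons = list(series.ddelta)
    y = np.concatenate([series.ddelta[p] for p in protons])
    if np.allclose(y, 0.0):
        return TitrationFit(Ka=np.nan, Ka_sd=np.nan,
                            ddelta_max={p: 0.0 for p in protons},
                            rss=0.0, converged=True, identifiable=False)
    hosts = series.ratio * series.C_guest

    def model(_x, logKa, *dmax):
        Ka = np.exp(logKa)
        frac = np.array([_bound_fraction(Ka, series.C_guest, h) for h in hosts])
        return np.concatenate([d * frac for d in dmax])

    scale = [series.ddelta[p][np.argmax(np.abs(series.ddelta[p]))] / 0.5
             for p in protons]
    p0 = [np.log(50.0), *scale]
    try:
        popt, pcov = curve_fit(model, np.zeros_like(y), y, p0=p0, maxfev=20000)
        converged = True
    except RuntimeError:
        popt, pcov = np.array(p0), np.full((len(p0), len(p0)), np.nan)
        converged = False
    Ka = float(np.exp(popt[0]))
    Ka_sd = float(Ka * np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else np.nan
    resid = model(None, *popt) - y
    return TitrationFit(
        Ka=Ka, Ka_sd=Ka_sd,
        ddelta_max={p: float(d) for p, d in zip(protons, popt[1:])},
        rss=float(resid @ resid), converged=converged, identifiable=True,
    )


def _bound_fraction(Ka: float, C_guest: float, C_host: float) -> float:
    system = BindingSystem(Ka=Ka, **_D_PLACEHOLDER)
    eq = solve_equilibrium(system, TernaryComposition(C_guest, C_host))
    return eq.C_complex / C_guest
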