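"""1:1 host–guest complexation and its signature in mutual diffusion.

A guest G (salicylate) and a macrocyclic host H (β-cyclodextrin) in fast
equilibrium G + H ⇌ GH with association constant Ka couple the two solute
fluxes: a host gradient drags bound guest along (or, for an inclusion
complex slower than the free guest, drives a counter-current guest flow,
D12 < 0).  With composition-independent species diffusivities D_G, D_H,
D_GH and complex fraction x = [GH], the mutual-diffusion matrix is

    D11 = D_G + (D_GH − D_G)·∂x/∂C1       D12 = (D_GH − D_G)·∂x/∂C2
    D21 = (D_GH − D_H)·∂x/∂C1             D22 = D_H + (D_GH − D_H)·∂x/∂C2

where C1, C2 are total guest and host concentrations.  The module solves
the equilibrium, differentiates it analytically, predicts D_ik, sizes
species via Stokes–Einstein, combines free-species diffusivities into a
complex diffusivity by the inverse-cube-sum (volume-additivity) rule,
estimates Ka from measured D_ik tables, and summarizes co-/counter-
transport ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
from scipy.optimize import minimize_scalar

from .core import CONSTANTS, DiffusionMatrix, TernaryComposition

__all__ = [
    "BindingSystem",
    "EquilibriumState",
    "solve_equilibrium",
    "equilibrium_jacobian",
    "predict_dik_1to1",
    "stokes_einstein_radius",
    "combine_complex_diffusivity",
    "fit_association_constant",
    "KaFit",
    "transport_ratio_summary",
]


@dataclass(frozen=True)
class BindingSystem:
    """Ka (dm³ mol⁻¹) plus species diffusivities (10⁻⁹ m² s⁻¹)."""

    Ka: float
    D_guest: float
    D_host: float
    D_complex: float

    def __post_init__(self) -> None:
        if self.Ka < 0:
            raise ValueError("Ka must be nonnegative")
        if min(self.D_guest, self.D_host, self.D_complex) <= 0:
            raise ValueError("diffusivities must be positive")
        if self.D_complex > min(self.D_guest, self.D_host):
            warn("complex diffusivity exceeds a free-species diffusivity; "
                 "unusual for an association complex", stacklevel=2)


@dataclass(frozen=True)
class EquilibriumState:
    """Free and complexed concentrations (mol dm⁻³) at one composition."""

    C_guest_free: float
    C_host_free: float
    C_complex: float


def solve_equilibrium(system: BindingSystem,
                      comp: TernaryComposition) -> EquilibriumState:
    """Speciation of the 1:1 equilibrium by the stable quadratic root.

    The complex concentration x is the smaller root of
    Ka·x² − (Ka·(C1+C2)+1)·x + Ka·C1·C2 = 0, evaluated in the
    cancellation-free form x = 2c/(−b + √(b²−4ac)).
    """
    Ka, C1, C2 = system.Ka, comp.C1, comp.C2
    if Ka == 0 or C1 == 0 or C2 == 0:
        x = 0.0
    else:
        b = -(Ka * (C1 + C2) + 1.0)
        c = Ka * C1 * C2
        disc = b * b - 4.0 * Ka * c
        x = 2.0 * c / (-b + np.sqrt(disc))
    return EquilibriumState(C_guest_free=C1 - x, C_host_free=C2 - x, C_complex=x)


def equilibrium_jacobian(system: BindingSystem,
                         comp: TernaryComposition) -> tuple[float, float]:
    """(∂x/∂C1, ∂x/∂C2) by implicit differentiation of mass action.

    Both sensitivities lie in [0, 1): adding total guest can convert at
    most all of it into complex.
    """
    Ka = system.Ka
    eq = solve_equilibrium(system, comp)
    g, h = eq.C_guest_free, eq.C_host_free
    denom = 1.0 + Ka * g + Ka * h
    return Ka * h / denom, Ka * g / denom


def predict_dik_1to1(system: BindingSystem,
                     comp: TernaryComposition) -> DiffusionMatrix:
    """Mutual-diffusion matrix implied by 1:1 complexation at ``comp``."""
    dx1, dx2 = equilibrium_jacobian(system, comp)
    dG = system.D_complex - system.D_guest
    dH = system.D_complex - system.D_host
    return DiffusionMatrix(
        D11=system.D_guest + dG * dx1,
        D12=dG * dx2,
        D21=dH * dx1,
        D22=system.D_host + dH * dx2,
    )


def stokes_einstein_radius(D: float, T: float = CONSTANTS.T_default,
                           eta: float = 0.89e-3) -> float:
    """Hydrodynamic radius r_h = kB·T/(6π·η·D), SI units (D in m² s⁻¹)."""
    if min(D, T, eta) <= 0:
        raise ValueError("D, T and eta must be positive")
    return CONSTANTS.kB * T / (6.0 * np.pi * eta * D)


def combine_complex_diffusivity(D_guest: float, D_host: float) -> float:
    """Complex diffusivity from volume additivity: (D_G⁻³ + D_H⁻³)^(−1/3).

    Follows from Stokes–Einstein with r_h ∝ V^(1/3) and additive molecular
    volumes; always below the smaller input.
    """
    if D_guest <= 0 or D_host <= 0:
        raise ValueError("diffusivities must be positive")
    return (D_guest**-3 + D_host**-3) ** (-1.0 / 3.0)


@dataclass
class KaFit:
    """Association-constant estimate with curvature-based uncertainty."""

    Ka: float
    Ka_sd: float
    rss: float
    residuals: list[dict]
    subset: tuple[str, ...]
    at_boundary: bool = False


_COEFFS = ("D11", "D12", "D21", "D22")


def fit_association_constant(
    data: list[tuple[TernaryComposition, DiffusionMatrix]],
    D_guest: float, D_host: float, D_complex: float,
    subset: tuple[str, ...] = ("D12",),
    weights: np.ndarray | None = None,
    Ka_max: float = 1e5,
) -> KaFit:
    """Estimate Ka by least squares on relative D_ik residuals.

    The objective is the weighted sum of squared relative residuals of the
    selected coefficient subset (default D12, the binding-sensitive cross
    coefficient) between the 1:1 model prediction and the measured table.
    Uncertainty comes from the curvature of the residual function at the
    minimum.  Rows with both concentrations zero-product contribute no Ka
    information; if all rows are like that the fit is unidentifiable.
    """
    if len(data) < 2:
        raise ValueError("need at least two composition rows")
    bad = [c for c in subset if c not in _COEFFS]
    if bad:
        raise ValueError(f"unknown coefficients in subset: {bad}")
    if all(comp.C1 * comp.C2 == 0 for comp, _ in data):
        raise ValueError("unidentifiable: every row has C1*C2 = 0")
    w = np.ones(len(data)) if weights is None else np.asarray(weights, float)

    def objective(Ka: float) -> float:
        system = BindingSystem(Ka=Ka, D_guest=D_guest, D_host=D_host,
                               D_complex=D_complex)
        ssr = 0.0
        for wi, (comp, obs) in zip(w, data):
            pred = predict_dik_1to1(system, comp)
            for coef in subset:
                o = getattr(obs, coef)
                if o == 0:
                    continue
                ssr += wi * ((getattr(pred, coef) - o) / o) ** 2
        return ssr

    res = minimize_scalar(objective, bounds=(0.0, Ka_max), method="bounded",
                          options={"xatol": 1e-6})
    Ka_hat = float(res.x)
    rss = float(res.fun)
    at_boundary = Ka_hat < 1e-4 or Ka_hat > Ka_max * (1 - 1e-6)

    # curvature of the SSR profile -> large-sample standard error
    h = max(1e-3, 1e-4 * max(Ka_hat, 1.0))
    lo = max(Ka_hat - h, 0.0)
    f0, fp, fm = objective(Ka_hat), objective(Ka_hat + h), objective(lo)
    curv = (fp - 2 * f0 + fm) / (h * h) if lo == Ka_hat - h else \
        2 * (fp - f0) / (h * h)
    n_res = len(data) * len(subset)
    s2 = rss / max(n_res - 1, 1)
    Ka_sd = float(np.sqrt(2 * s2 / curv)) if curv > 0 else np.inf

    system = BindingSystem(Ka=Ka_hat, D_guest=D_guest, D_host=D_host,
                           D_complex=D_complex)
    rows = []
    for comp, obs in data:
        pred = predict_dik_1to1(system, comp)
        rows.append({
            "C1": comp.C1, "C2": comp.C2, "X1": comp.X1,
            **{f"{c}_obs": getattr(obs, c) for c in _COEFFS},
            **{f"{c}_pred": getattr(pred, c) for c in _COEFFS},
            **{f"{c}_rel_resid": (getattr(pred, c) - getattr(obs, c))
               / getattr(obs, c) if getattr(obs, c) != 0 else np.nan
               for c in _COEFFS},
        })
    return KaFit(Ka=Ka_hat, Ka_sd=Ka_sd, rss=rss, residuals=rows,
                 subset=tuple(subset), at_boundary=at_boundary)


def transport_ratio_summary(
    data: list[tuple[TernaryComposition, DiffusionMatrix]],
) -> dict:
    """Maximum coupled-transport ratios over a composition table.

    ``D12/D22`` is the moles of component 1 co-transported (or, negative,
    counter-transported) per mole of diffusing component 2; ``D21/D11``
    the converse.  Returns the maxima of the absolute ratios with the sign
    of the cross coefficient and the composition where each occurs.
    """
    if not data:
        raise ValueError("empty diffusion table")
    r12 = np.array([m.D12 / m.D22 for _, m in data])
    r21 = np.array([m.D21 / m.D11 for _, m in data])
    i12 = int(np.argmax(np.abs(r12)))
    i21 = int(np.argmax(np.abs(r21)))
    return {
        "max_abs_D12_over_D22": float(abs(r12[i12])),
        "sign_D12_at_max": int(np.sign(data[i12][1].D12)),
        "X1_at_max_D12_over_D22": float(data[i12][0].X1),
        "max_abs_D21_over_D11": float(abs(r21[i21])),
        "sign_D21_at_max": int(np.sign(data[i21][1].D21)),
        "X1_at_max_D21_over_D11": float(data[i21][0].X1),
    }
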