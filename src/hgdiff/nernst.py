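"""Limiting-law (Nernst–Hartley) coupled diffusion of mixed electrolytes.

Ions in a dilute mixed electrolyte do not diffuse independently: a
diffusion potential builds so that no net electric current flows, slowing
the fast ions and dragging the slow ones.  For ionic tracer diffusivities
D_i⁰ the constrained ionic flux is

    J_i = −D_i⁰ [∇c_i − (z_i c_i / S) Σ_k z_k D_k⁰ ∇c_k],
    S   = Σ_j z_j² c_j D_j⁰,

which satisfies Σ_i z_i J_i = 0 for any gradient.  Mapping ionic to solute
fluxes through the salt stoichiometries (each solute tracked by its
distinguishing anion, the common cation partitioned by electroneutrality)
yields the 2×2 mutual-diffusion matrix of the ternary solution — the
limiting-law prediction drawn as solid curves against the measured
coefficients.  The model depends only on concentration ratios, so it has
no absolute-concentration scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    CONSTANTS,
    DiffusionMatrix,
    Electrolyte,
    IonSpecies,
    TernaryComposition,
    composition_grid,
)

__all__ = [
    "IonicSystem",
    "limiting_ionic_diffusivity",
    "ionic_flux_response",
    "nernst_ternary_matrix",
    "nernst_curves",
    "binary_nernst_hartley",
]


def limiting_ionic_diffusivity(ion: IonSpecies, T: float = CONSTANTS.T_default) -> float:
    """Tracer diffusivity at infinite dilution, D⁰ = R·T·λ⁰/(z²·F²), in m² s⁻¹."""
    if ion.lambda0 is None:
        raise ValueError(f"{ion.name}: limiting conductivity not set")
    if T <= 0:
        raise ValueError("temperature must be positive")
    return CONSTANTS.R * T * ion.lambda0 / (ion.z**2 * CONSTANTS.F**2)


def binary_nernst_hartley(ion_plus: IonSpecies, ion_minus: IonSpecies,
                          T: float = CONSTANTS.T_default) -> float:
    """Closed-form binary electrolyte diffusivity (z₊+|z₋|)D₊D₋/(z₊D₊+|z₋|D₋)."""
    dp = _d0(ion_plus, T)
    dm = _d0(ion_minus, T)
    zp, zm = ion_plus.z, abs(ion_minus.z)
    return (zp + zm) * dp * dm / (zp * dp + zm * dm)


def _d0(ion: IonSpecies, T: float) -> float:
    """Prefer the stored tracer diffusivity; fall back to the conductivity route."""
    if ion.D0 is not None:
        return ion.D0
    return limiting_ionic_diffusivity(ion, T)


@dataclass(frozen=True)
class IonicSystem:
    """Two electrolytes sharing a pool of ions, e.g. NaSal + Na4EtRA in water.

    ``tracer_ion(k)`` gives the ion unique to solute k, which carries that
    solute's flux in the common-ion bookkeeping.
    """

    solute1: Electrolyte
    solute2: Electrolyte
    T: float = CONSTANTS.T_default

    def __post_init__(self) -> None:
        if self.solute1.neutral or self.solute2.neutral:
            raise ValueError("the Nernst model applies to charged electrolytes only")

    @property
    def ions(self) -> list[IonSpecies]:
        seen: dict[IonSpecies, None] = {}
        for solute in (self.solute1, self.solute2):
            for ion in solute.stoichiometry:
                seen.setdefault(ion)
        return list(seen)

    def stoichiometric_matrix(self) -> np.ndarray:
        """nu[i, k] = count of ion i in one formula unit of solute k."""
        ions = self.ions
        nu = np.zeros((len(ions), 2))
        for k, solute in enumerate((self.solute1, self.solute2)):
            for ion, count in solute.stoichiometry.items():
                nu[ions.index(ion), k] = count
        return nu

    def tracer_ion(self, k: int) -> int:
        """Index (into ``self.ions``) of the ion unique to solute k (0 or 1)."""
        nu = self.stoichiometric_matrix()
        other = 1 - k
        unique = np.nonzero((nu[:, k] > 0) & (nu[:, other] == 0))[0]
        if unique.size == 0:
            raise ValueError(f"solute {k + 1} has no distinguishing ion")
        return int(unique[0])


def ionic_flux_response(system: IonicSystem,
                        composition: TernaryComposition) -> np.ndarray:
    """Ionic flux per unit solute gradient under the zero-current constraint.

    Returns J of shape (n_ions, 2): column k is the flux of each ion in
    response to a unit concentration gradient of solute k (the ionic
    gradients then being the stoichiometric column nu[:, k]).  Satisfies
    Σ_i z_i·J_i = 0 in each column.
    """
    C = np.array([composition.C1, composition.C2], dtype=float)
    if C.sum() <= 0:
        raise ValueError("degenerate system: both solute concentrations are zero")

    ions = system.ions
    nu = system.stoichiometric_matrix()          # (n_ions, 2)
    z = np.array([ion.z for ion in ions], dtype=float)
    d0 = np.array([_d0(ion, system.T) for ion in ions])
    c_ion = nu @ C                               # ionic concentrations

    if abs(float(z @ c_ion)) > 1e-9 * float(np.abs(z * c_ion).sum() + 1e-300):
        raise ValueError("ionic system is not electroneutral")

    S = float(z**2 * c_ion @ d0)
    field = np.outer(z * c_ion / S, (z * d0) @ nu)   # (n_ions, 2)
    return -d0[:, None] * (nu - field)


def nernst_ternary_matrix(system: IonicSystem,
                          composition: TernaryComposition) -> DiffusionMatrix:
    """Limiting-law mutual-diffusion matrix at one solute composition.

    Returns coefficients in interface units (10⁻⁹ m² s⁻¹).  Endpoint
    compositions (one solute absent) are handled by the same expression,
    which reduces there to the exact tracer/binary limits.
    """
    nu = system.stoichiometric_matrix()
    J = ionic_flux_response(system, composition)
    i1 = system.tracer_ion(0)
    i2 = system.tracer_ion(1)
    n1 = nu[i1, 0]
    n2 = nu[i2, 1]
    # Solute flux = flux of its distinguishing ion / its stoichiometric count;
    # D_mk = -dJ_m/d(grad C_k).  Convert m^2/s -> 1e-9 m^2/s.
    D = np.array([
        [-J[i1, 0] / n1, -J[i1, 1] / n1],
        [-J[i2, 0] / n2, -J[i2, 1] / n2],
    ]) * 1e9
    return DiffusionMatrix(D11=D[0, 0], D12=D[0, 1], D21=D[1, 0], D22=D[1, 1])


def nernst_curves(system: IonicSystem, total: float, n: int):
    """Matrix at each point of an even X1 grid with C1+C2 = ``total``.

    Returns a list of ``(TernaryComposition, DiffusionMatrix)`` pairs.
    """
    return [(comp, nernst_ternary_matrix(system, comp))
            for comp in composition_grid(total, n)]
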