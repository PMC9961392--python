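"""Domain types, physical constants and packaged reference data.

The chemical system under study is the drug sodium salicylate (NaSal,
component 1) diffusing together with one of two macrocyclic hosts
(component 2): the tetraanionic resorcin[4]arene salt Na4EtRA, or neutral
β-cyclodextrin (β-CD), in water at 298.15 K.  Everything downstream —
the Nernst electrolyte predictor, the Taylor peak model and the 1:1
binding model — consumes the types defined here.

Concentrations are held in mol dm⁻³ at the interface and mutual diffusion
coefficients in 10⁻⁹ m² s⁻¹; SI units are used internally wherever a
formula requires them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CONSTANTS",
    "PhysicalConstants",
    "IonSpecies",
    "Electrolyte",
    "TernaryComposition",
    "DiffusionMatrix",
    "load_fixture",
    "fixture_manifest",
    "composition_grid",
    "DIK_COLUMNS",
]

#: CSV column order for mutual-diffusion tables (the package's one dialect).
DIK_COLUMNS = [
    "C1", "C2", "X1",
    "D11", "sd11", "D12", "sd12", "D21", "sd21", "D22", "sd22",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA physical constants (SI units)."""

    R: float = 8.31446261815324        # gas constant, J mol^-1 K^-1
    F: float = 96485.33212331          # Faraday constant, C mol^-1
    kB: float = 1.380649e-23           # Boltzmann constant, J K^-1
    NA: float = 6.02214076e23          # Avogadro number, mol^-1
    T_default: float = 298.15          # default temperature, K

    def __post_init__(self) -> None:
        if min(self.R, self.F, self.kB, self.NA) <= 0:
            raise ValueError("physical constants must be positive")
        if abs(self.R - self.kB * self.NA) / self.R > 1e-6:
            raise ValueError("R must equal kB*NA")


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class IonSpecies:
    """A charged (or flagged-neutral) solution species.

    Parameters
    ----------
    name
        Label, e.g. ``"Na+"``.
    z
        Signed integer charge; must be nonzero for a true ion.
    lambda0
        Limiting molar ionic conductivity, S m² mol⁻¹ (optional).
    D0
        Limiting tracer diffusivity, m² s⁻¹ (optional).

    At least one of ``lambda0`` / ``D0`` must be set.
    """

    name: str
    z: int
    lambda0: float | None = None
    D0: float | None = None

    def __post_init__(self) -> None:
        if self.z == 0:
            raise ValueError(f"{self.name}: ion charge must be nonzero")
        if self.lambda0 is None and self.D0 is None:
            raise ValueError(f"{self.name}: need lambda0 or D0")
        if self.lambda0 is not None and self.lambda0 <= 0:
            raise ValueError(f"{self.name}: lambda0 must be positive")
        if self.D0 is not None and self.D0 <= 0:
            raise ValueError(f"{self.name}: D0 must be positive")


@dataclass(frozen=True)
class Electrolyte:
    """A stoichiometric salt: mapping of ions to positive integer counts.

    Electroneutrality (sum of count*charge = 0) is enforced at
    construction.  A neutral solute such as β-CD is represented by
    ``neutral=True`` with a single carrier "ion" whose charge is ignored.
    """

    name: str
    stoichiometry: dict[IonSpecies, int]
    neutral: bool = False

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValueError(f"{self.name}: empty stoichiometry")
        if any(nu <= 0 for nu in self.stoichiometry.values()):
            raise ValueError(f"{self.name}: stoichiometric counts must be positive")
        if self.neutral:
            return
        if len(self.stoichiometry) < 2:
            raise ValueError(f"{self.name}: a charged electrolyte needs >=2 ions")
        net = sum(nu * ion.z for ion, nu in self.stoichiometry.items())
        if net != 0:
            raise ValueError(f"{self.name}: not electroneutral (net charge {net})")


@dataclass(frozen=True)
class TernaryComposition:
    """Concentrations of the two solutes, mol dm⁻³, with derived fraction X1."""

    C1: float
    C2: float

    def __post_init__(self) -> None:
        if self.C1 < 0 or self.C2 < 0:
            raise ValueError("concentrations must be nonnegative")

    @property
    def total(self) -> float:
        return self.C1 + self.C2

    @property
    def X1(self) -> float:
        """Solute fraction of component 1, C1/(C1+C2); NaN for the empty system."""
        tot = self.total
        return self.C1 / tot if tot > 0 else float("nan")


@dataclass
class DiffusionMatrix:
    """2×2 ternary mutual-diffusion coefficients, interface units 10⁻⁹ m² s⁻¹.

    Main coefficients ``D11``/``D22`` drive each solute down its own
    gradient; cross coefficients ``D12``/``D21`` encode coupled flows
    (positive = co-current, negative = counter-current) through the Fick
    flux law J_i = −D_ii∇C_i − D_ik∇C_k.
    """

    D11: float
    D12: float
    D21: float
    D22: float
    sd11: float | None = None
    sd12: float | None = None
    sd21: float | None = None
    sd22: float | None = None

    def __post_init__(self) -> None:
        if self.D11 <= 0 or self.D22 <= 0:
            raise ValueError("main diffusion coefficients must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.D11, self.D12], [self.D21, self.D22]], dtype=float)

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues sorted descending; raises if complex or nonpositive."""
        lam = np.linalg.eigvals(self.as_array())
        if np.iscomplexobj(lam) and np.abs(lam.imag).max() > 1e-12 * np.abs(lam.real).max():
            raise ValueError("diffusion matrix has complex eigenvalues")
        lam = np.sort(lam.real)[::-1]
        if lam[-1] <= 0:
            raise ValueError("diffusion matrix has nonpositive eigenvalues")
        return lam

    @property
    def is_physical(self) -> bool:
        try:
            self.eigenvalues()
        except ValueError:
            return False
        return True


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------

_FIXTURE_FILES = {
    ("table1", "corrected"): "table1_corrected.csv",
    ("table1", "as_printed"): "table1_as_printed.csv",
    ("table2", "corrected"): "table2_corrected.csv",
    ("table2", "as_printed"): "table2_as_printed.csv",
    ("table3", "corrected"): "table3.csv",
    ("table3", "as_printed"): "table3.csv",
    ("conductivities", "corrected"): "conductivities.csv",
    ("conductivities", "as_printed"): "conductivities.csv",
}


def _data_path(fname: str) -> Path:
    return Path(str(resources.files("hgdiff").joinpath("data", fname)))


def load_fixture(table_id: str, variant: str = "corrected") -> pd.DataFrame:
    """Load a packaged reference table.

    Parameters
    ----------
    table_id
        One of ``table1`` (NaSal + Na4EtRA mutual-diffusion matrix vs
        composition), ``table2`` (NaSal + β-CD), ``table3`` (limiting
        diffusivities of free species and complex) or ``conductivities``
        (limiting ionic conductivities).
    variant
        ``"corrected"`` (default) applies the documented typo corrections
        recorded in the manifest; ``"as_printed"`` is verbatim.
    """
    if variant not in ("corrected", "as_printed"):
        raise KeyError(f"unknown variant {variant!r}")
    try:
        fname = _FIXTURE_FILES[(table_id, variant)]
    except KeyError:
        raise KeyError(f"unknown fixture table {table_id!r}") from None
    df = pd.read_csv(_data_path(fname), float_precision="round_trip")
    if table_id in ("table1", "table2"):
        _validate_dik_table(df, table_id, variant)
    return df


def fixture_manifest() -> dict:
    """JSON manifest of the corrections applied to the corrected variants."""
    with open(_data_path("corrections.json")) as fh:
        return json.load(fh)


def _validate_dik_table(df: pd.DataFrame, table_id: str, variant: str) -> None:
    missing = [c for c in DIK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{table_id}: missing columns {missing}")
    if len(df) != 5:
        raise ValueError(f"{table_id}: expected 5 rows, got {len(df)}")
    if variant == "corrected":
        tot = df["C1"] + df["C2"]
        x1 = np.where(tot > 0, df["C1"] / tot, np.nan)
        if np.nanmax(np.abs(x1 - df["X1"])) > 1e-3:
            raise ValueError(f"{table_id}: X1 inconsistent with C1, C2")


def dik_rows(df: pd.DataFrame) -> list[tuple[TernaryComposition, DiffusionMatrix]]:
    """Convert a mutual-diffusion table into typed (composition, matrix) rows."""
    out = []
    for _, r in df.iterrows():
        comp = TernaryComposition(float(r["C1"]), float(r["C2"]))
        mat = DiffusionMatrix(
            D11=float(r["D11"]), D12=float(r["D12"]),
            D21=float(r["D21"]), D22=float(r["D22"]),
            sd11=float(r["sd11"]), sd12=float(r["sd12"]),
            sd21=float(r["sd21"]), sd22=float(r["sd22"]),
        )
        out.append((comp, mat))
    return out


def composition_grid(total: float, n: int) -> list[TernaryComposition]:
    """``n`` compositions with C1+C2 = ``total`` and X1 evenly spaced on [0, 1]."""
    if total <= 0:
        raise ValueError("total concentration must be positive")
    if n < 2:
        raise ValueError("need at least two grid points")
    x1 = np.linspace(0.0, 1.0, n)
    return [TernaryComposition(float(x * total), float((1 - x) * total)) for x in x1]


# ---------------------------------------------------------------------------
# The paper system's species and solutes
# ---------------------------------------------------------------------------

def default_ions() -> dict[str, IonSpecies]:
    """Ions of the NaSal + Na4EtRA system with their limiting conductivities."""
    cond = load_fixture("conductivities")
    ions = {}
    for _, r in cond.iterrows():
        ions[r["ion"]] = IonSpecies(
            name=str(r["ion"]), z=int(r["z"]),
            lambda0=float(r["lambda0"]), D0=float(r["D0_printed"]) * 1e-9,
        )
    return ions


def default_solutes() -> tuple[Electrolyte, Electrolyte]:
    """NaSal (1 Na⁺ + 1 Sal⁻) and Na4EtRA (4 Na⁺ + 1 EtRA⁴⁻)."""
    ions = default_ions()
    nasal = Electrolyte("NaSal", {ions["Na+"]: 1, ions["Sal-"]: 1})
    na4etra = Electrolyte("Na4EtRA", {ions["Na+"]: 4, ions["EtRA4-"]: 1})
    return nasal, na4etra
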