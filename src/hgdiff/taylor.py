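"""Taylor dispersion peaks for binary and ternary diffusion.

A small pulse injected into laminar flow through a long capillary spreads
into a near-Gaussian peak whose width encodes the mutual diffusion
coefficients.  For a ternary solution the detector trace is a sum of two
exponential modes, one per eigenvalue of the 2×2 diffusion matrix:

    V(t) = V0 + V1·t + Vmax·√(tR/t) · [ W1·exp(−12·D1·(t−tR)²/(r²·t))
                                  + (1−W1)·exp(−12·D2·(t−tR)²/(r²·t)) ]

with baseline V0 + V1·t, retention time tR, tube radius r, and normalized
pre-exponential weights W1, 1−W1 (weights may lie outside [0, 1] when
cross-diffusion is strong).  The module provides the forward model, the
eigenmode map from a diffusion matrix and injection to (D1, D2, W1),
nonlinear least-squares peak fitting, and the inverse problem: recovering
the four D_ik from two or more peaks with independent injections.

Retention time is always a free fit parameter; the geometric L/u value
only seeds the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .core import DiffusionMatrix

__all__ = [
    "TaylorInstrument",
    "InjectionProfile",
    "DispersionPeak",
    "PeakFitResult",
    "taylor_signal",
    "modes_from_matrix",
    "fit_peak",
    "invert_dik",
    "refine_dik",
    "default_instrument",
]


@dataclass(frozen=True)
class TaylorInstrument:
    """Capillary geometry, flow and detector response.

    Defaults follow a dispersion tube of length 30.480 m and internal
    radius 0.3220 mm run at 0.17 mL min⁻¹ with 5 s sampling.
    """

    L: float = 30.480                 # tube length, m
    r: float = 0.3220e-3              # internal radius, m
    Q: float = 0.17e-6 / 60.0         # volumetric flow rate, m^3 s^-1
    dt: float = 5.0                   # sampling interval, s
    R1: float = 1.0                   # detector response per unit C1, V dm^3 mol^-1
    R2: float = 1.0

    def __post_init__(self) -> None:
        if min(self.L, self.r, self.Q, self.dt) <= 0:
            raise ValueError("instrument geometry/flow fields must be positive")

    @property
    def u(self) -> float:
        """Mean flow speed, m s⁻¹."""
        return self.Q / (np.pi * self.r**2)

    @property
    def tR(self) -> float:
        """Geometric retention time L/u, s."""
        return self.L / self.u

    def taylor_valid(self, D_min: float) -> bool:
        """Long-time validity check tR ≥ 50·r²/D for the slowest diffusivity."""
        return self.tR >= 50.0 * self.r**2 / D_min


def default_instrument() -> TaylorInstrument:
    return TaylorInstrument()


@dataclass(frozen=True)
class InjectionProfile:
    """Injected concentration perturbations (mol dm⁻³) and volume (m³)."""

    dC1: float
    dC2: float
    V_inj: float = 0.063e-6

    def __post_init__(self) -> None:
        if self.dC1 == 0 and self.dC2 == 0:
            raise ValueError("injection perturbation must be nonzero")


@dataclass
class DispersionPeak:
    """One detector trace: times (s), signal (V), and its provenance."""

    t: np.ndarray
    V: np.ndarray
    instrument: TaylorInstrument
    injection: InjectionProfile | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.t.shape != self.V.shape:
            raise ValueError("time and signal arrays differ in length")
        if self.t.size < 50:
            raise ValueError("need at least 50 samples spanning the peak")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class PeakFitResult:
    """Fitted peak parameters; D1 ≥ D2 by convention, W2 = 1 − W1 implicit."""

    V0: float
    V1: float
    Vmax: float
    tR: float
    D1: float
    D2: float
    W1: float
    rss: float = np.nan
    converged: bool = True
    w1_identifiable: bool = True

    def __post_init__(self) -> None:
        if self.D2 > self.D1:
            raise ValueError("mode ordering requires D1 >= D2")
        if self.D2 <= 0:
            raise ValueError("mode diffusivities must be positive")


def taylor_signal(fit: PeakFitResult, instrument: TaylorInstrument,
                  t: np.ndarray) -> np.ndarray:
    """Evaluate the two-mode dispersion model at times ``t`` (s, positive)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    return _signal(t, instrument.r, fit.V0, fit.V1, fit.Vmax,
                   fit.tR, fit.D1, fit.D2, fit.W1)


def _signal(t, r, V0, V1, Vmax, tR, D1, D2, W1):
    arg = -12.0 * (t - tR) ** 2 / (r**2 * t)
    # clip to the exp range so absurd optimizer trials cannot overflow
    peak = (W1 * np.exp(np.clip(arg * D1, -700.0, 700.0))
            + (1.0 - W1) * np.exp(np.clip(arg * D2, -700.0, 700.0)))
    return V0 + V1 * t + Vmax * np.sqrt(tR / t) * peak


def modes_from_matrix(D: DiffusionMatrix, injection: InjectionProfile,
                      sensitivities: tuple[float, float] = (1.0, 1.0),
                      ) -> tuple[float, float, float]:
    """Eigenmode diffusivities and weight for one injection.

    The injected perturbation (dC1, dC2) is decomposed on the eigenbasis of
    the diffusion matrix; each eigenvector contributes a mode with its
    eigenvalue as decay coefficient and an amplitude weighted by the
    detector sensitivities.  Returns ``(D1, D2, W1)`` with D1 ≥ D2, in the
    units of ``D`` (10⁻⁹ m² s⁻¹).
    """
    A = D.as_array()
    lam, P = np.linalg.eig(A)
    if np.iscomplexobj(lam) and np.abs(lam.imag).max() > 1e-12 * np.abs(lam.real).max():
        raise ValueError("diffusion matrix has complex eigenvalues")
    lam, P = lam.real, P.real
    order = np.argsort(lam)[::-1]
    lam, P = lam[order], P[:, order]
    if lam[-1] <= 0:
        raise ValueError("diffusion matrix has nonpositive eigenvalues")

    dC = np.array([injection.dC1, injection.dC2], dtype=float)
    coeff = np.linalg.solve(P, dC)
    R = np.asarray(sensitivities, dtype=float)
    amp = coeff * (R @ P)                 # A_m = coeff_m * (R1 P1m + R2 P2m)
    total = amp.sum()
    if abs(total) < 1e-300:
        raise ValueError("degenerate injection: total mode amplitude is zero")
    W1 = float(amp[0] / total)
    return float(lam[0]), float(lam[1]), W1


# ---------------------------------------------------------------------------
# Peak fitting
# ---------------------------------------------------------------------------

def _moment_init(peak: DispersionPeak):
    """Linear baseline, height, apex time and a width-based D guess."""
    t, V = peak.t, peak.V
    n_edge = max(3, t.size // 20)
    edge = np.r_[np.arange(n_edge), np.arange(t.size - n_edge, t.size)]
    slope, intercept = np.polyfit(t[edge], V[edge], 1)
    resid = V - (intercept + slope * t)
    sign = 1.0 if np.abs(resid.max()) >= np.abs(resid.min()) else -1.0
    resid = resid * sign
    i_apex = int(np.argmax(resid))
    height = resid[i_apex]
    floor = 5 * np.std(resid[edge]) + 1e-9 * max(np.abs(V).max(), 1e-30)
    if height <= floor:
        raise ValueError("unfittable peak: no apex detectably above baseline")
    tR0 = t[i_apex]
    w = np.clip(resid, 0, None)
    var = float(np.sum(w * (t - tR0) ** 2) / np.sum(w))
    r2 = peak.instrument.r**2
    D0 = r2 * tR0 / (24.0 * max(var, 1e-12))   # sigma^2 = r^2 tR / (24 D)
    return intercept, slope, sign * height, tR0, D0


def fit_peak(peak: DispersionPeak, mode_count: int = 2,
             max_restarts: int = 4) -> PeakFitResult:
    """Nonlinear least-squares fit of the dispersion model to one trace.

    ``mode_count=1`` fits the binary (single-exponential) form; ``2`` fits
    the full ternary model.  Initialization comes from peak moments.  On
    non-convergence after bounded restarts the best attempt is returned
    with ``converged=False`` rather than raising.
    """
    if mode_count not in (1, 2):
        raise ValueError("mode_count must be 1 or 2")
    V0_0, V1_0, Vmax_0, tR0, D0 = _moment_init(peak)
    r = peak.instrument.r
    t, V = peak.t, peak.V

    # noise-floor estimate from the trace edges; a fit whose rss reaches it
    # (within a safety factor) needs no further starts
    n_edge = max(3, t.size // 20)
    diffs = np.r_[np.diff(V[:n_edge]), np.diff(V[-n_edge:])]
    sigma_est = float(np.std(diffs)) / np.sqrt(2)
    rss_floor = t.size * max(sigma_est, 1e-9 * np.ptp(V)) ** 2 * 3.0

    if mode_count == 1:
        def model(t, V0, V1, Vmax, tR, D):
            return _signal(t, r, V0, V1, Vmax, tR, D, D, 1.0)
        starts = [[V0_0, V1_0, Vmax_0, tR0, D0]]
    else:
        def model(t, V0, V1, Vmax, tR, D1, D2, W1):
            return _signal(t, r, V0, V1, Vmax, tR, D1, D2, W1)
        # the apparent (single-mode) D seeds mode pairs of varying split and
        # weight; weights outside [0,1] occur for strong cross-diffusion
        starts = [[V0_0, V1_0, Vmax_0, tR0, f1 * D0, f2 * D0, w]
                  for (f1, f2) in ((1.3, 0.7), (2.0, 0.5), (1.05, 0.35))
                  for w in (0.5, 0.9, 1.2, 0.1, -0.2)]
    rng = np.random.default_rng(0)
    for _ in range(max_restarts):
        starts.append([V0_0, V1_0, Vmax_0 * rng.normal(1, 0.1),
                       tR0 * rng.normal(1, 0.05),
                       *(D0 * rng.lognormal(0, 0.5, size=mode_count)),
                       *([rng.uniform(-0.5, 1.5)] if mode_count == 2 else [])])

    best, best_rss = None, np.inf
    converged = False
    for trial in starts:
        try:
            popt, _ = curve_fit(model, t, V, p0=trial, maxfev=20000)
        except RuntimeError:
            continue
        if popt[4] <= 0 or (mode_count == 2 and popt[5] <= 0):
            continue
        rss = float(np.sum((model(t, *popt) - V) ** 2))
        if rss < best_rss:
            best, best_rss = popt, rss
            converged = True
        if best_rss <= rss_floor:
            break
    if best is None:
        # every start failed: report the initialization, flagged
        best = np.array(starts[0])
        best_rss = float(np.sum((model(t, *best) - V) ** 2))
        converged = False

    if mode_count == 1:
        V0, V1, Vmax, tR, D = best
        return PeakFitResult(V0=V0, V1=V1, Vmax=Vmax, tR=tR, D1=D, D2=D,
                             W1=1.0, rss=best_rss, converged=converged,
                             w1_identifiable=False)
    V0, V1, Vmax, tR, D1, D2, W1 = best
    if D1 < D2:
        D1, D2, W1 = D2, D1, 1.0 - W1
    # two degeneracies leave W1 meaningless: coincident modes, or one mode
    # carrying essentially no amplitude (its D is then unconstrained)
    identifiable = abs(D1 - D2) > 1e-3 * D1
    if identifiable and abs(W1) < 1e-4:
        D1 = D2 = D2          # only mode 2 is visible
        identifiable = False
    elif identifiable and abs(1.0 - W1) < 1e-4:
        D1 = D2 = D1          # only mode 1 is visible
        identifiable = False
    if not identifiable:
        W1 = np.nan
    return PeakFitResult(V0=V0, V1=V1, Vmax=Vmax, tR=tR, D1=D1, D2=D2,
                         W1=W1, rss=best_rss, converged=converged,
                         w1_identifiable=identifiable)


# ---------------------------------------------------------------------------
# Inverse problem: D_ik from >=2 independent injections
# ---------------------------------------------------------------------------

def invert_dik(fits: list[PeakFitResult], injections: list[InjectionProfile],
               sensitivities: tuple[float, float] = (1.0, 1.0),
               eig_rtol: float = 0.05) -> DiffusionMatrix:
    """Recover the 2×2 diffusion matrix from fitted peaks.

    Needs at least two peaks with linearly independent injections.  The
    shared eigenvalues (averaged across fits, required consistent within
    ``eig_rtol``) and the per-injection weights W1 overdetermine the four
    D_ik, which are found by inverting the ``modes_from_matrix`` forward
    map with ``scipy.optimize.least_squares``.
    """
    if len(fits) < 2 or len(fits) != len(injections):
        raise ValueError("need >=2 fits, one injection each")
    M = np.array([[inj.dC1, inj.dC2] for inj in injections], dtype=float)
    if np.linalg.matrix_rank(M, tol=1e-10 * np.abs(M).max()) < 2:
        raise ValueError("ill-posed: injection vectors are collinear")

    # fitted eigenvalues arrive in SI (m^2/s, as fit_peak reports); the
    # matrix is returned in interface units, 1e-9 m^2/s
    d1s = np.array([f.D1 for f in fits]) * 1e9
    d2s = np.array([f.D2 for f in fits]) * 1e9
    w1_raw = np.array([f.W1 for f in fits])
    collapsed = ~np.isfinite(w1_raw)

    if collapsed.all():
        # every peak is effectively single-mode: each injection vector is
        # then (near) an eigenvector with that peak's eigenvalue, so
        # D @ inj_f = d_f * inj_f determines the matrix directly
        V = M[:2].T
        D = V @ np.diag(d1s[:2]) @ np.linalg.inv(V)
        return DiffusionMatrix(D11=D[0, 0], D12=D[0, 1],
                               D21=D[1, 0], D22=D[1, 1])

    # pool eigenvalues weighted by each mode's visibility |W| in each fit:
    # a mode carrying little amplitude in a peak constrains its eigenvalue
    # poorly there, so that fit should not dominate (or veto) the estimate
    v1 = np.where(collapsed, 0.0, np.clip(np.abs(w1_raw), 0.0, 2.0))
    v2 = np.where(collapsed, 0.0, np.clip(np.abs(1.0 - w1_raw), 0.0, 2.0))
    if v1.sum() == 0 or v2.sum() == 0:
        raise ValueError("one dispersion mode is invisible in every fit")
    lam1 = float((v1 * d1s).sum() / v1.sum())
    lam2 = float((v2 * d2s).sum() / v2.sum())
    for f_idx in range(len(fits)):
        if v1[f_idx] > 0.2 and abs(d1s[f_idx] - lam1) > eig_rtol * lam1:
            raise ValueError("inconsistent eigenvalues across fits")
        if v2[f_idx] > 0.2 and abs(d2s[f_idx] - lam2) > eig_rtol * max(lam2, 1e-12):
            raise ValueError("inconsistent eigenvalues across fits")

    # a collapsed (single-visible-mode) fit still pins its weight: the
    # visible D identifies which mode carried all the amplitude
    w1s = w1_raw.copy()
    for f_idx in np.nonzero(collapsed)[0]:
        w1s[f_idx] = 1.0 if abs(d1s[f_idx] - lam1) <= abs(d1s[f_idx] - lam2) \
            else 0.0

    def residuals(p):
        mat = DiffusionMatrix(D11=p[0], D12=p[1], D21=p[2], D22=p[3]) \
            if p[0] > 0 and p[3] > 0 else None
        if mat is None or not mat.is_physical:
            return np.full(2 + len(fits), 1e3)
        try:
            modes = [modes_from_matrix(mat, inj, sensitivities)
                     for inj in injections]
        except ValueError:
            return np.full(2 + len(fits), 1e3)
        d1, d2 = modes[0][0], modes[0][1]
        res = [(d1 - lam1) / lam1, (d2 - lam2) / max(lam2, 1e-12)]
        res += [m[2] - w for m, w in zip(modes, w1s)]
        return np.array(res)

    starts = [
        np.array([lam1, 0.0, 0.0, lam2]),
        np.array([lam2, 0.0, 0.0, lam1]),
        np.array([0.5 * (lam1 + lam2), 0.1 * (lam1 - lam2),
                  0.1 * (lam1 - lam2), 0.5 * (lam1 + lam2)]),
    ]
    best, best_cost = None, np.inf
    for x0 in starts:
        sol = least_squares(residuals, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if sol.cost < best_cost:
            best, best_cost = sol, sol.cost
        if best_cost < 1e-20:
            break
    if best is None or best_cost > 1e-2:
        raise ValueError("data-inconsistency: no matrix reproduces the fitted modes")
    p = best.x
    return DiffusionMatrix(D11=p[0], D12=p[1], D21=p[2], D22=p[3])


def refine_dik(peaks: list[DispersionPeak], injections: list[InjectionProfile],
               sensitivities: tuple[float, float] = (1.0, 1.0),
               fits: list[PeakFitResult] | None = None,
               initial: DiffusionMatrix | None = None) -> DiffusionMatrix:
    """Joint refinement: fit all raw traces simultaneously with one matrix.

    The two-stage route (per-peak fits, then eigenvalue/weight inversion)
    discards the coupling between peaks; refitting every trace with the
    four D_ik shared — plus per-peak baseline, amplitude and retention
    time — recovers the cross coefficients to the information limit of the
    data.  Per-peak fits supply the starting point (``invert_dik`` where
    it succeeds, pooled eigenvalues otherwise).
    """
    if len(peaks) < 2 or len(peaks) != len(injections):
        raise ValueError("need >=2 peaks, one injection each")
    if fits is None:
        fits = [fit_peak(p) for p in peaks]
    if initial is None:
        try:
            initial = invert_dik(fits, injections, sensitivities)
        except ValueError:
            lam = sorted([f.D1 for f in fits], reverse=True)
            initial = DiffusionMatrix(D11=lam[0] * 1e9, D12=0.0, D21=0.0,
                                      D22=max(lam[-1] * 1e9, 0.05))

    n_pk = len(peaks)
    x0 = np.empty(4 + 4 * n_pk)
    x0[:4] = initial.as_array().ravel()
    for i, f in enumerate(fits):
        x0[4 + 4 * i: 8 + 4 * i] = (f.V0, f.V1, f.Vmax, f.tR)
    scale_t = np.mean([f.tR for f in fits])

    def residuals(x):
        try:
            mat = DiffusionMatrix(D11=x[0], D12=x[1], D21=x[2], D22=x[3])
            mat.eigenvalues()
        except ValueError:
            return np.concatenate([np.full(p.t.size, 1e3) for p in peaks])
        out = []
        for i, (p, inj) in enumerate(zip(peaks, injections)):
            d1, d2, w1 = modes_from_matrix(mat, inj, sensitivities)
            V0, V1, Vmax, tR = x[4 + 4 * i: 8 + 4 * i]
            model = _signal(p.t, p.instrument.r, V0, V1, Vmax, abs(tR),
                            d1 * 1e-9, d2 * 1e-9, w1)
            out.append(model - p.V)
        return np.concatenate(out)

    x_scale = np.r_[np.full(4, 0.5),
                    np.tile([1e-4, 1e-7, np.mean([abs(f.Vmax) for f in fits]),
                             scale_t], n_pk)]
    sol = least_squares(residuals, x0, x_scale=x_scale,
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400)
    return DiffusionMatrix(D11=sol.x[0], D12=sol.x[1],
                           D21=sol.x[2], D22=sol.x[3])
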