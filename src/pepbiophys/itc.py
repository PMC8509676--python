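"""Single-site (1:1) isothermal titration calorimetry: forward model and fit.

The forward model follows the standard overflow-cell (perfusion) accounting
for injection-based microcalorimeters.  Each injection of volume dv into a
cell of working volume V0 displaces an equal volume of the cell contents;
with the symmetric (v/2V0) convention the total concentrations after a
cumulative injected volume v are

    [M]_i = M0 · (1 − v/2V0) / (1 + v/2V0)        (titrand, cell)
    [X]_i = X_syr · (v/V0) / (1 + v/2V0)          (titrant, syringe)

The complex concentration is the smaller root of the 1:1 mass-balance
quadratic with stoichiometry n, the cumulative heat is Q_i = ΔH·V0·[MX]_i,
and the measured per-injection heat includes the displaced-volume
correction

    ΔQ_i = Q_i − Q_{i−1} + (dv_i/V0)·(Q_i + Q_{i−1})/2 + q_dil.

The shape of the isotherm is governed by the Wiseman parameter
c = n·M0/Kd; the fit flags c outside [1, 1000], where Kd is poorly
determined.

Units: concentrations µM, volumes µL, ΔH kcal/mol, heats µcal.  q_dil, a
constant per-injection dilution-heat offset, is in µcal (the unit of the
heats it offsets).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .constants import T_ITC_K

__all__ = [
    "ITCExperiment",
    "ITCFit",
    "post_injection_concentrations",
    "bound_concentration",
    "injection_heats",
    "normalized_heats",
    "molar_ratio",
    "fit_itc",
]

MIN_INJECTIONS = 8
C_VALUE_RANGE = (1.0, 1000.0)


@dataclass
class ITCExperiment:
    """Injection schedule and starting concentrations of an ITC titration."""

    cell_volume: float  # µL, V0
    titrand_conc0: float  # µM, protein in the cell (M0)
    titrant_conc_syringe: float  # µM, peptide in the syringe
    injection_volumes: np.ndarray  # µL per injection
    temperature: float = T_ITC_K  # K

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if self.cell_volume <= 0:
            raise ValueError("cell volume must be positive")
        if self.titrand_conc0 <= 0 or self.titrant_conc_syringe <= 0:
            raise ValueError("concentrations must be positive")
        if self.injection_volumes.ndim != 1 or self.injection_volumes.size == 0:
            raise ValueError("injection_volumes must be a non-empty 1-D array")
        if np.any(self.injection_volumes <= 0):
            raise ValueError("all injection volumes must be positive")
        if float(self.injection_volumes.sum()) >= self.cell_volume:
            raise ValueError("total injected volume must stay below the cell volume")

    @property
    def n_injections(self) -> int:
        return self.injection_volumes.size


@dataclass
class ITCFit:
    """Single-site fit results: Kd, ΔH, stoichiometry n and heat offset."""

    kd: float  # µM
    dh: float  # kcal mol^-1
    n: float  # sites per titrand
    q_dil: float  # µcal per injection
    c_value: float = math.nan  # n·M0/Kd
    identifiable: bool = True
    uncertainties: dict = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.n <= 0:
            raise ValueError("stoichiometry must be positive")


def _cumulative_concentrations(exp: ITCExperiment):
    v = np.cumsum(exp.injection_volumes)
    r = v / (2.0 * exp.cell_volume)
    titrand = exp.titrand_conc0 * (1.0 - r) / (1.0 + r)
    titrant = exp.titrant_conc_syringe * (v / exp.cell_volume) / (1.0 + r)
    return titrand, titrant


def post_injection_concentrations(exp: ITCExperiment, i: int) -> tuple[float, float]:
    """Total titrand and titrant concentrations (µM) in the cell after
    injection ``i`` (1-based)."""
    if not 1 <= i <= exp.n_injections:
        raise IndexError(f"injection index {i} out of range 1..{exp.n_injections}")
    titrand, titrant = _cumulative_concentrations(exp)
    return float(titrand[i - 1]), float(titrant[i - 1])


def bound_concentration(titrand, titrant, kd: float, n: float = 1.0):
    """Complex concentration (µM): smaller root of the 1:1 mass-balance
    quadratic [MX]² − [MX](n·M + X + Kd) + n·M·X = 0."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    if n <= 0:
        raise ValueError("stoichiometry must be positive")
    m = np.asarray(titrand, dtype=float)
    x = np.asarray(titrant, dtype=float)
    if np.any(m < 0) or np.any(x < 0):
        raise ValueError("concentrations must be non-negative")
    b = n * m + x + kd
    disc = np.maximum(b**2 - 4.0 * n * m * x, 0.0)
    mx = 0.5 * (b - np.sqrt(disc))
    mx = np.clip(mx, 0.0, np.minimum(n * m, x))
    return float(mx) if mx.ndim == 0 else mx


def injection_heats(
    exp: ITCExperiment,
    kd: float,
    dh: float,
    n: float = 1.0,
    q_dil: float = 0.0,
) -> np.ndarray:
    """Per-injection heats (µcal) of the single-site model."""
    titrand, titrant = _cumulative_concentrations(exp)
    mx = bound_concentration(titrand, titrant, kd, n)
    # Q in µcal: kcal/mol · µM · µL · 1e-3
    q = dh * exp.cell_volume * np.atleast_1d(mx) * 1e-3
    q_prev = np.concatenate([[0.0], q[:-1]])
    dv = exp.injection_volumes
    dq = q - q_prev + (dv / exp.cell_volume) * (q + q_prev) / 2.0 + q_dil
    return dq


def normalized_heats(exp: ITCExperiment, heats_ucal) -> np.ndarray:
    """Heats normalised by moles of titrant injected, kcal/mol."""
    heats = np.asarray(heats_ucal, dtype=float)
    moles_x_umol = exp.titrant_conc_syringe * exp.injection_volumes * 1e-6
    return heats * 1e-9 / (moles_x_umol * 1e-6)


def molar_ratio(exp: ITCExperiment) -> np.ndarray:
    """Titrant/titrand molar ratio in the cell after each injection."""
    titrand, titrant = _cumulative_concentrations(exp)
    return titrant / titrand


def fit_itc(
    exp: ITCExperiment,
    heats,
    fix_n: bool = False,
    discard_first: bool = False,
) -> ITCFit:
    """Nonlinear least-squares fit of {Kd, ΔH, n, q_dil} to injection heats.

    ``fix_n`` pins the stoichiometry at 1 (the usual single-site
    assumption); ``discard_first`` drops the first injection, whose heat
    is commonly corrupted by diffusion across the syringe tip.  The fit
    is flagged non-identifiable when the Wiseman parameter
    c = n·M0/Kd falls outside [1, 1000].
    """
    heats = np.asarray(heats, dtype=float)
    if heats.shape != (exp.n_injections,):
        raise ValueError("heats must have one entry per injection")
    if exp.n_injections < MIN_INJECTIONS:
        raise ValueError(f"need at least {MIN_INJECTIONS} injections")
    if not np.all(np.isfinite(heats)):
        raise ValueError("heats must be finite")

    mask = np.ones(exp.n_injections, dtype=bool)
    if discard_first:
        mask[0] = False

    def residual(params):
        model = injection_heats(
            exp, params["kd"].value, params["dh"].value, params["n"].value,
            params["q_dil"].value,
        )
        return model[mask] - heats[mask]

    norm = normalized_heats(exp, heats)
    dh_init = float(norm[1] - norm[-1]) if exp.n_injections > 2 else float(norm[0])
    if dh_init == 0.0:
        dh_init = float(norm[0]) or 1.0
    q_dil_init = float(np.mean(heats[-2:]))

    best = None
    for kd_start in (0.1, 1.0, 10.0, 100.0):
        params = lmfit.Parameters()
        params.add("kd", value=kd_start, min=1e-6, max=1e6)
        params.add("dh", value=dh_init)
        params.add("n", value=1.0, min=1e-3, max=10.0, vary=not fix_n)
        params.add("q_dil", value=q_dil_init)
        try:
            res = lmfit.minimize(residual, params, method="leastsq", xtol=1e-13, ftol=1e-13)
        except Exception:
            continue
        ssr = float(np.sum(res.residual**2))
        if best is None or ssr < best[0]:
            best = (ssr, res)
    if best is None:
        raise RuntimeError("single-site ITC fit failed to run from any start")

    res = best[1]
    p = res.params
    unc = {
        name: (p[name].stderr if p[name].stderr is not None else math.nan)
        for name in ("kd", "dh", "n", "q_dil")
    }
    c = p["n"].value * exp.titrand_conc0 / p["kd"].value
    identifiable = C_VALUE_RANGE[0] <= c <= C_VALUE_RANGE[1] and bool(res.success)
    return ITCFit(
        kd=p["kd"].value,
        dh=p["dh"].value,
        n=p["n"].value,
        q_dil=p["q_dil"].value,
        c_value=float(c),
        identifiable=identifiable,
        uncertainties=unc,
        converged=bool(res.success),
    )
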