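"""Far-UV CD helicity estimates and two-state TFE titration thermodynamics.

Two routes to helical content are implemented.  The first is the classical
single-wavelength estimate: the ellipticity at 222 nm divided by the value
expected for a fully formed helix (−39,500 deg cm² dmol⁻¹).  The second
treats a titration with the helix-stabilising cosolvent trifluoroethanol
(TFE) as a two-state disordered ↔ helical equilibrium with a transition
free energy linear in cosolvent concentration,

    ΔG(x) = ΔG_water − m·x,

where x is %v/v TFE, m > 0 is the cosolvent m-value
(cal mol⁻¹ (%v/v)⁻¹) and ΔG_water > 0 means the helix is unfavourable in
water.  The observed ellipticity is the population-weighted average of two
linear baselines (disordered and helical), which yields the familiar
sigmoidal titration curve with midpoint [TFE]₁/₂ = ΔG_water/m.  Fitting
that curve gives the equilibrium constant in water and hence the residual
helical population without any assumption about how the 222-nm signal maps
onto structure content.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.special import expit

from .constants import R_CAL, T_CD_K, THETA_HELIX_222

__all__ = [
    "TFETitrationCurve",
    "HelixCoilFit",
    "helicity_from_theta222",
    "raw_to_ellipticity",
    "two_state_theta",
    "fit_tfe_titration",
    "helical_population",
]

MIN_FIT_POINTS = 8


@dataclass
class TFETitrationCurve:
    """Ellipticity at 222 nm versus TFE concentration for one peptide."""

    tfe: np.ndarray  # % v/v
    theta222: np.ndarray  # deg cm^2 dmol^-1
    peptide: str = ""
    temperature: float = T_CD_K  # K

    def __post_init__(self) -> None:
        self.tfe = np.asarray(self.tfe, dtype=float)
        self.theta222 = np.asarray(self.theta222, dtype=float)
        if self.tfe.shape != self.theta222.shape or self.tfe.ndim != 1:
            raise ValueError("tfe and theta222 must be 1-D arrays of equal length")
        if self.tfe.size < 2:
            raise ValueError("a titration needs at least two points")
        if np.any(self.tfe < 0) or np.any(self.tfe > 100):
            raise ValueError("TFE concentrations must lie in [0, 100] %v/v")
        if np.any(np.diff(self.tfe) <= 0):
            raise ValueError("TFE concentrations must be strictly increasing")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")

    def __len__(self) -> int:
        return self.tfe.size


@dataclass
class HelixCoilFit:
    """Two-state helix-coil parameters fitted to a TFE titration.

    ``dg_water`` is always the product m·[TFE]₁/₂/1000 (kcal/mol) and
    ``helix_fraction_water`` the population K/(1+K) it implies at
    ``temperature``; neither is an independent fit parameter.
    """

    m: float  # cal mol^-1 (%v/v)^-1
    tfe_half: float  # % v/v
    theta_D0: float  # disordered-baseline intercept, deg cm^2 dmol^-1
    slope_D: float  # disordered-baseline slope per %v/v
    theta_H0: float  # helical-baseline intercept
    slope_H: float  # helical-baseline slope per %v/v
    dg_water: float = 0.0  # kcal mol^-1, derived
    helix_fraction_water: float = 0.0  # derived
    temperature: float = T_CD_K
    uncertainties: dict = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self) -> None:
        self.dg_water = self.m * self.tfe_half / 1000.0
        self.helix_fraction_water = helical_population(self.dg_water, self.temperature)


def helicity_from_theta222(theta222):
    """Percent helix from the 222-nm ellipticity.

    Linear estimate 100·θ222/(−39,500).  Positive ellipticities would give
    negative helicity; these are clamped to 0 with a warning.
    """
    h = 100.0 * np.asarray(theta222, dtype=float) / THETA_HELIX_222
    if np.any(h < 0):
        warnings.warn(
            "positive ellipticity at 222 nm gives negative helicity; clamped to 0",
            stacklevel=2,
        )
        h = np.where(h < 0, 0.0, h)
    return float(h) if h.ndim == 0 else h


def raw_to_ellipticity(
    theta_mdeg: float,
    conc: float,
    pathlength: float,
    n_residues: int = 1,
    convention: str = "molar",
) -> float:
    """Convert raw ellipticity (mdeg) to molar or mean-residue ellipticity.

    [Θ] = θ_mdeg / (10·C·l) with C in M and l in cm; the mean-residue
    convention divides additionally by the number of residues.
    """
    if conc <= 0:
        raise ValueError("concentration must be positive")
    if pathlength <= 0:
        raise ValueError("pathlength must be positive")
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if convention not in ("molar", "mean_residue"):
        raise ValueError("convention must be 'molar' or 'mean_residue'")
    theta = theta_mdeg / (10.0 * conc * pathlength)
    if convention == "mean_residue":
        theta /= n_residues
    return theta


def _theta_two_state(x, theta_D0, slope_D, theta_H0, slope_H, m, tfe_half, rt):
    # helical fraction f = K/(1+K) with K = exp(-m (tfe_half - x)/RT),
    # evaluated through the logistic for overflow safety
    f = expit(m * (np.asarray(x, dtype=float) - tfe_half) / rt)
    return (theta_D0 + slope_D * x) * (1.0 - f) + (theta_H0 + slope_H * x) * f


def two_state_theta(tfe, fit: HelixCoilFit, temperature: float | None = None):
    """Model ellipticity at a TFE concentration under a two-state fit."""
    T = fit.temperature if temperature is None else temperature
    if T <= 0:
        raise ValueError("temperature must be positive (K)")
    return _theta_two_state(
        tfe,
        fit.theta_D0,
        fit.slope_D,
        fit.theta_H0,
        fit.slope_H,
        fit.m,
        fit.tfe_half,
        R_CAL * T,
    )


def helical_population(dg_water: float, temperature: float = T_CD_K) -> float:
    """Equilibrium helical fraction K/(1+K), K = exp(−1000·ΔG_water/RT)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    return float(expit(-1000.0 * dg_water / (R_CAL * temperature)))


def _initial_guesses(x, y, rt):
    """Heuristic starting values: baselines from the edge triples, the
    midpoint from the mid-signal crossing, m from the central slope."""
    dfit = np.polyfit(x[:3], y[:3], 1)
    hfit = np.polyfit(x[-3:], y[-3:], 1)
    slope_D, theta_D0 = dfit[0], dfit[1]
    slope_H, theta_H0 = hfit[0], hfit[1]

    mid = 0.5 * (np.polyval(dfit, x) + np.polyval(hfit, x))
    resid = y - mid
    sign_change = np.nonzero(np.diff(np.sign(resid)))[0]
    if sign_change.size:
        i = sign_change[0]
        # linear interpolation of the crossing
        t = resid[i] / (resid[i] - resid[i + 1])
        tfe_half = x[i] + t * (x[i + 1] - x[i])
    else:
        tfe_half = x[np.argmin(np.abs(resid))]
    tfe_half = float(np.clip(tfe_half, x[1], x[-2]))

    # slope of the sigmoid at its midpoint is (theta_H - theta_D)·m/(4RT)
    # on top of the mean baseline slope
    j = int(np.argmin(np.abs(x - tfe_half)))
    lo, hi = max(j - 2, 0), min(j + 3, x.size)
    central_slope = np.polyfit(x[lo:hi], y[lo:hi], 1)[0]
    dtheta = np.polyval(hfit, tfe_half) - np.polyval(dfit, tfe_half)
    excess = central_slope - 0.5 * (slope_D + slope_H)
    m0 = 4.0 * rt * excess / dtheta if dtheta != 0 else 150.0
    m0 = float(np.clip(m0, 5.0, 2000.0))
    return theta_D0, slope_D, theta_H0, slope_H, m0, tfe_half


def fit_tfe_titration(
    curve: TFETitrationCurve,
    fix_baseline_slopes: bool = False,
) -> HelixCoilFit:
    """Least-squares fit of the two-state TFE titration model.

    Six parameters (two linear baselines, m, [TFE]₁/₂) are fitted with a
    damped least-squares (Levenberg–Marquardt) minimiser and a small
    multi-start on the m initial guess; the start with the lowest residual
    sum of squares wins.  ΔG_water and the water-population are derived
    from the fitted m and [TFE]₁/₂.

    Raises
    ------
    ValueError
        If the curve has fewer than 8 points or carries no detectable
        transition (signal range not above 3× the MAD of residuals around
        a straight line).
    """
    x, y = curve.tfe, curve.theta222
    if x.size < MIN_FIT_POINTS:
        raise ValueError(f"need at least {MIN_FIT_POINTS} titration points, got {x.size}")
    lin_resid = y - np.polyval(np.polyfit(x, y, 1), x)
    mad = np.median(np.abs(lin_resid - np.median(lin_resid)))
    signal_range = float(np.ptp(y))
    if signal_range <= 3.0 * mad or signal_range == 0.0:
        raise ValueError("no detectable two-state transition in the titration")

    rt = R_CAL * curve.temperature
    th_d0, s_d, th_h0, s_h, m0, half0 = _initial_guesses(x, y, rt)

    def residual(params):
        return (
            _theta_two_state(
                x,
                params["theta_D0"].value,
                params["slope_D"].value,
                params["theta_H0"].value,
                params["slope_H"].value,
                params["m"].value,
                params["tfe_half"].value,
                rt,
            )
            - y
        )

    best = None
    for m_start in (0.5 * m0, m0, 2.0 * m0):
        params = lmfit.Parameters()
        params.add("theta_D0", value=th_d0)
        params.add("slope_D", value=s_d, vary=not fix_baseline_slopes)
        params.add("theta_H0", value=th_h0)
        params.add("slope_H", value=s_h, vary=not fix_baseline_slopes)
        params.add("m", value=m_start, min=1e-3)
        params.add("tfe_half", value=half0, min=1e-3, max=100.0)
        if fix_baseline_slopes:
            params["slope_D"].value = 0.0
            params["slope_H"].value = 0.0
        try:
            res = lmfit.minimize(
                residual, params, method="leastsq", xtol=1e-13, ftol=1e-13
            )
        except Exception:
            continue
        ssr = float(np.sum(res.residual**2))
        if best is None or ssr < best[0]:
            best = (ssr, res)
    if best is None:
        raise RuntimeError("two-state fit failed to run from any start")
    result = best[1]

    p = result.params
    unc = {
        name: (p[name].stderr if p[name].stderr is not None else math.nan)
        for name in ("m", "tfe_half", "theta_D0", "slope_D", "theta_H0", "slope_H")
    }
    # ΔG = m·t½/1000: propagate with the fit covariance when available
    m_v, t_v = p["m"].value, p["tfe_half"].value
    var = math.nan
    if result.covar is not None and result.errorbars:
        names = [par for par in p if p[par].vary]
        try:
            im, it = names.index("m"), names.index("tfe_half")
            cov = result.covar
            var = (
                t_v**2 * cov[im, im]
                + m_v**2 * cov[it, it]
                + 2.0 * m_v * t_v * cov[im, it]
            ) / 1e6
        except ValueError:
            pass
    unc["dg_water"] = math.sqrt(var) if var == var and var >= 0 else math.nan

    converged = bool(result.success) and result.errorbars
    return HelixCoilFit(
        m=m_v,
        tfe_half=t_v,
        theta_D0=p["theta_D0"].value,
        slope_D=p["slope_D"].value,
        theta_H0=p["theta_H0"].value,
        slope_H=p["slope_H"].value,
        temperature=curve.temperature,
        uncertainties=unc,
        converged=converged,
    )
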