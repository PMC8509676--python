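"""Pulsed-gradient spin-echo (PGSE/DOSY) diffusion decays and hydrodynamics.

With a bipolar-gradient stimulated-echo sequence the peak intensity decays
with gradient strength g as

    I/I0 = exp(−D·γ²δ²·g²·(Δ − δ/3 − τ/2)),

where D is the translational self-diffusion coefficient (cm² s⁻¹), γ the
proton gyromagnetic ratio, δ the gradient duration, Δ the diffusion delay
and τ the recovery delay between the bipolar gradient pair.  The factor
b = γ²δ²(Δ − δ/3 − τ/2), multiplying D·g², is exposed separately.

The hydrodynamic radius follows from the Stokes–Einstein relation by
ratio against an internal reference of known radius measured in the same
sample (dioxane, Rh = 2.12 Å), which cancels temperature, viscosity and
the gradient-coil calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import lmfit
import numpy as np

from .constants import DIOXANE_RH_A, GAMMA_H
from .peptide import rh_scaling_law

__all__ = [
    "DiffusionDecay",
    "DiffusionFit",
    "b_factor",
    "decay_model",
    "fit_decay",
    "rh_from_reference",
    "is_monomer_consistent",
]

MIN_POINTS = 6


@dataclass
class DiffusionDecay:
    """Normalised intensity versus gradient strength plus pulse timings."""

    g: np.ndarray  # T cm^-1
    rel_intensity: np.ndarray  # I/I0
    delta: float = 2.25e-3  # s, gradient duration
    big_delta: float = 0.2  # s, diffusion delay
    tau: float = 1.0e-4  # s, bipolar recovery delay
    gamma: float = GAMMA_H  # rad s^-1 T^-1

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.rel_intensity = np.asarray(self.rel_intensity, dtype=float)
        if self.g.shape != self.rel_intensity.shape or self.g.ndim != 1:
            raise ValueError("g and rel_intensity must be 1-D arrays of equal length")
        if self.g.size < MIN_POINTS:
            raise ValueError(f"need at least {MIN_POINTS} gradient points")
        if np.any(self.g < 0):
            raise ValueError("gradient strengths must be non-negative")
        if np.any(self.rel_intensity <= 0) or np.any(self.rel_intensity > 1.05):
            raise ValueError("relative intensities must lie in (0, 1.05]")
        if not self.delta < self.big_delta:
            raise ValueError("gradient duration must be shorter than the diffusion delay")
        if self.effective_time <= 0:
            raise ValueError("unphysical timing: Δ − δ/3 − τ/2 must be positive")

    @property
    def effective_time(self) -> float:
        return self.big_delta - self.delta / 3.0 - self.tau / 2.0

    def __len__(self) -> int:
        return self.g.size


@dataclass
class DiffusionFit:
    """Fitted diffusion coefficient and optional derived radius."""

    d: float  # cm^2 s^-1
    uncertainty: float = math.nan
    rh_A: float | None = None

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("diffusion coefficient must be positive")


def b_factor(decay: DiffusionDecay) -> float:
    """γ²δ²(Δ − δ/3 − τ/2): the decay exponent is D·b·g²  (s cm⁻²·(T cm⁻¹)⁻²)."""
    return decay.gamma**2 * decay.delta**2 * decay.effective_time


def decay_model(g, d: float, decay: DiffusionDecay):
    """Model I/I0 at gradient strength g for diffusion coefficient d."""
    if d <= 0:
        raise ValueError("diffusion coefficient must be positive")
    g = np.asarray(g, dtype=float)
    out = np.exp(-d * b_factor(decay) * g**2)
    return float(out) if out.ndim == 0 else out


def fit_decay(decay: DiffusionDecay) -> DiffusionFit:
    """Least-squares D on the exponential decay.

    A log-linear regression of ln(I/I0) on g² provides the starting value
    (and serves as an independent cross-check); the reported D comes from
    the fit on the untransformed intensities, which avoids the noise
    re-weighting of the log transform.
    """
    g2 = decay.g**2
    y = decay.rel_intensity
    slope = float(np.polyfit(g2, np.log(y), 1)[0])
    b = b_factor(decay)
    if slope >= 0:
        raise ValueError("intensities do not decay with gradient strength")
    d_init = -slope / b

    def residual(params):
        return np.exp(-params["d"].value * b * g2) - y

    params = lmfit.Parameters()
    params.add("d", value=d_init, min=1e-12)
    res = lmfit.minimize(residual, params, method="leastsq", xtol=1e-14, ftol=1e-14)
    d = res.params["d"].value
    se = res.params["d"].stderr
    return DiffusionFit(d=d, uncertainty=se if se is not None else math.nan)


def rh_from_reference(
    d_solute: float,
    d_reference: float,
    rh_reference: float = DIOXANE_RH_A,
) -> float:
    """Hydrodynamic radius (Å) by Stokes–Einstein ratio against an internal
    reference measured at the same temperature and viscosity."""
    if d_solute <= 0 or d_reference <= 0:
        raise ValueError("diffusion coefficients must be positive")
    return rh_reference * d_reference / d_solute


def is_monomer_consistent(rh_measured_A: float, mw_da: float, tol_A: float = 2.0) -> bool:
    """Whether a measured Rh matches the disordered-monomer scaling law
    for the given mass within ``tol_A`` Å (an oligomer would exceed it)."""
    return abs(rh_measured_A - rh_scaling_law(mw_da)) <= tol_A
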