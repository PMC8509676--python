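"""Fluorescence binding titrations with explicit ligand depletion.

At the micromolar protein concentrations used in tryptophan-fluorescence
titrations the free and total titrant concentrations differ appreciably,
so the hyperbolic isotherm is replaced by the exact 1:1 mass-balance
(quadratic, "ligand depletion") solution:

    F = F0 + (ΔFmax / (2·[M]T)) · [ S − sqrt(S² − 4·[P]T·[M]T) ],
    S = [P]T + [M]T + Kd,

where [M]T is the fixed total protein (titrand) concentration, [P]T the
total peptide (titrant) concentration, F0 the signal without titrant and
ΔFmax the signal change at full complexation.  The model reduces to the
hyperbola F0 + ΔFmax·[P]/(Kd + [P]) when [M]T ≪ Kd.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

__all__ = [
    "FluorescenceTitration",
    "BindingFit",
    "binding_model",
    "inner_filter_correct",
    "fit_titration",
]

MIN_FIT_POINTS = 6
#: Box bounds on Kd during fitting, µM; a fit pinned at a bound is
#: reported as not measurable.
KD_BOUNDS_UM = (1e-3, 1e4)
#: A Kd whose relative standard error exceeds this is not measurable.
MAX_REL_SE = 1.0


@dataclass
class FluorescenceTitration:
    """Titrant concentration versus (blank-subtracted) intensity."""

    protein_conc: float  # µM, fixed titrand
    peptide_conc: np.ndarray  # µM, titrant
    intensity: np.ndarray  # a.u.
    wavelength: float | None = None  # nm, metadata only
    corrected: bool = False  # inner-filter correction applied

    def __post_init__(self) -> None:
        self.peptide_conc = np.asarray(self.peptide_conc, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.protein_conc <= 0:
            raise ValueError("protein concentration must be positive")
        if self.peptide_conc.shape != self.intensity.shape or self.peptide_conc.ndim != 1:
            raise ValueError("peptide_conc and intensity must be 1-D arrays of equal length")
        if np.any(self.peptide_conc < 0):
            raise ValueError("peptide concentrations must be non-negative")
        if np.any(np.diff(self.peptide_conc) < 0):
            raise ValueError("peptide concentrations must be non-decreasing")

    def __len__(self) -> int:
        return self.peptide_conc.size


@dataclass
class BindingFit:
    """Ligand-depletion isotherm parameters.

    ``kd`` is ``None`` when the titration does not determine it
    (``measurable`` False) — mirroring the practice of reporting such
    titrations as "(-)" rather than quoting a meaningless number.
    """

    kd: float | None  # µM
    f0: float  # a.u.
    dfmax: float  # a.u.
    uncertainties: dict = field(default_factory=dict)
    converged: bool = True
    measurable: bool = True

    def __post_init__(self) -> None:
        if self.measurable and (self.kd is None or self.kd <= 0):
            raise ValueError("a measurable fit requires kd > 0")


def binding_model(peptide_conc, protein_conc, kd, f0, dfmax):
    """Exact 1:1 binding signal with ligand depletion (see module docs)."""
    if protein_conc <= 0:
        raise ValueError("protein concentration must be positive")
    if kd <= 0:
        raise ValueError("kd must be positive")
    p = np.asarray(peptide_conc, dtype=float)
    if np.any(p < 0):
        raise ValueError("concentrations must be non-negative")
    s = p + protein_conc + kd
    disc = np.maximum(s**2 - 4.0 * p * protein_conc, 0.0)
    f = f0 + dfmax / (2.0 * protein_conc) * (s - np.sqrt(disc))
    return float(f) if f.ndim == 0 else f


def inner_filter_correct(intensity, a_ex, a_em):
    """Multiplicative inner-filter correction F·10^((A_ex + A_em)/2)."""
    a_ex = np.asarray(a_ex, dtype=float)
    a_em = np.asarray(a_em, dtype=float)
    if np.any(a_ex < 0) or np.any(a_em < 0):
        raise ValueError("absorbances must be non-negative")
    out = np.asarray(intensity, dtype=float) * 10.0 ** ((a_ex + a_em) / 2.0)
    return float(out) if out.ndim == 0 else out


def _flagged(f0: float, dfmax: float, converged: bool) -> BindingFit:
    return BindingFit(
        kd=None, f0=f0, dfmax=dfmax, converged=converged, measurable=False,
        uncertainties={},
    )


def fit_titration(t: FluorescenceTitration) -> BindingFit:
    """Fit {Kd, F0, ΔFmax} to a titration by damped least squares.

    Multi-start on Kd (0.1, 1, 10 µM; lowest residual wins, ties toward
    the smaller Kd).  The Kd is declared not measurable — ``measurable``
    False, ``kd`` None — when the signal carries no information (flat
    titration), when the fit pins Kd at its box bounds, or when the
    relative standard error of Kd exceeds 100%.
    """
    if len(t) < MIN_FIT_POINTS:
        raise ValueError(f"need at least {MIN_FIT_POINTS} titration points, got {len(t)}")
    x, y = t.peptide_conc, t.intensity
    mad = np.median(np.abs(y - np.median(y)))
    rng = float(np.ptp(y))
    if rng <= 3.0 * mad or rng == 0.0:
        # no signal beyond noise: nothing to fit
        return _flagged(f0=float(np.median(y)), dfmax=0.0, converged=False)

    def residual(params):
        return (
            binding_model(
                x, t.protein_conc, params["kd"].value, params["f0"].value,
                params["dfmax"].value,
            )
            - y
        )

    f0_init = float(y[0])
    dfmax_init = float(y[-1] - y[0])
    best = None
    for kd_start in (0.1, 1.0, 10.0):
        params = lmfit.Parameters()
        params.add("kd", value=kd_start, min=KD_BOUNDS_UM[0], max=KD_BOUNDS_UM[1])
        params.add("f0", value=f0_init)
        params.add("dfmax", value=dfmax_init)
        try:
            res = lmfit.minimize(residual, params, method="leastsq", xtol=1e-13, ftol=1e-13)
        except Exception:
            continue
        ssr = float(np.sum(res.residual**2))
        # strict < keeps the earlier (smaller) kd start on ties
        if best is None or ssr < best[0] - 1e-30 * max(1.0, best[0]):
            best = (ssr, res)
    if best is None:
        return _flagged(f0=f0_init, dfmax=dfmax_init, converged=False)

    res = best[1]
    p = res.params
    kd = p["kd"].value
    se = p["kd"].stderr
    unc = {
        name: (p[name].stderr if p[name].stderr is not None else math.nan)
        for name in ("kd", "f0", "dfmax")
    }
    at_bounds = kd <= KD_BOUNDS_UM[0] * 1.01 or kd >= KD_BOUNDS_UM[1] * 0.99
    bad_se = se is None or not np.isfinite(se) or se / kd > MAX_REL_SE
    if at_bounds or bad_se:
        return BindingFit(
            kd=None, f0=p["f0"].value, dfmax=p["dfmax"].value,
            uncertainties=unc, converged=bool(res.success), measurable=False,
        )
    return BindingFit(
        kd=kd, f0=p["f0"].value, dfmax=p["dfmax"].value,
        uncertainties=unc, converged=bool(res.success), measurable=True,
    )
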