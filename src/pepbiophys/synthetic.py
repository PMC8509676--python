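"""Seeded synthetic datasets with the statistical structure of each assay.

Every generator evaluates the corresponding deterministic forward model on
an experimental design and adds Gaussian noise from a seeded stream, so
each fitter in the package can be validated by parameter recovery without
any measured spectra.  Defaults mirror the designs used in the study this
package models: 17-point TFE titrations over 0–40 %v/v, 16-point
fluorescence titrations of 0–30 µM peptide into 3 µM protein, 19 × 2 µL
ITC injections of a 200 µM syringe into a 20 µM cell at 25 °C, and DOSY
decays with δ = 2.25 ms, Δ = 200 ms, τ = 100 µs over 16 linear gradient
steps spanning 2–95% of the maximum gradient.

Generators are pure functions of (truth, design, seed): the same inputs
always produce the identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cd import HelixCoilFit, TFETitrationCurve, two_state_theta
from .constants import T_CD_K, T_ITC_K
from .dosy import DiffusionDecay, decay_model
from .fluorescence import FluorescenceTitration, binding_model
from .itc import ITCExperiment, injection_heats

__all__ = [
    "NoiseSpec",
    "gen_tfe_curve",
    "gen_fluor_titration",
    "gen_itc",
    "gen_dosy",
    "default_itc_experiment",
    "default_dosy_geometry",
]

#: Default maximum gradient strength, T cm^-1 (a 53.5 G/cm z-gradient probe).
DEFAULT_G_MAX = 5.35e-3


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise description for a synthetic dataset.

    ``sigma`` is either an absolute standard deviation in signal units or,
    when ``relative`` is true (default), a fraction of the noiseless
    signal range of the generated dataset — so a 1% noise level means the
    same thing regardless of the design.
    """

    sigma: float = 0.0
    seed: int = 0
    relative: bool = True
    kind: str = "gaussian"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.kind != "gaussian":
            raise ValueError("only gaussian noise is supported")

    def apply(self, clean: np.ndarray) -> np.ndarray:
        if self.sigma == 0:
            return np.array(clean, dtype=float)
        scale = self.sigma * float(np.ptp(clean)) if self.relative else self.sigma
        rng = np.random.default_rng(self.seed)
        return clean + rng.normal(0.0, scale, size=np.shape(clean))


def gen_tfe_curve(
    truth: HelixCoilFit,
    grid=None,
    temperature: float = T_CD_K,
    noise: NoiseSpec = NoiseSpec(),
    peptide: str = "synthetic",
) -> TFETitrationCurve:
    """TFE titration from two-state ground-truth parameters."""
    if grid is None:
        grid = np.linspace(0.0, 40.0, 17)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0) or np.any(grid > 100):
        raise ValueError("TFE grid must lie within [0, 100] %v/v")
    clean = two_state_theta(grid, truth, temperature)
    return TFETitrationCurve(
        tfe=grid, theta222=noise.apply(clean), peptide=peptide, temperature=temperature
    )


def gen_fluor_titration(
    kd: float,
    f0: float,
    dfmax: float,
    protein_conc: float = 3.0,
    peptide_grid=None,
    noise: NoiseSpec = NoiseSpec(),
) -> FluorescenceTitration:
    """Fluorescence titration from ligand-depletion ground truth."""
    if peptide_grid is None:
        peptide_grid = np.linspace(0.0, 30.0, 16)
    peptide_grid = np.asarray(peptide_grid, dtype=float)
    clean = binding_model(peptide_grid, protein_conc, kd, f0, dfmax)
    return FluorescenceTitration(
        protein_conc=protein_conc,
        peptide_conc=peptide_grid,
        intensity=noise.apply(clean),
    )


def default_itc_experiment(
    cell_conc: float = 20.0,
    syringe_conc: float = 200.0,
    n_injections: int = 19,
    injection_volume: float = 2.0,
    cell_volume: float = 200.0,
    temperature: float = T_ITC_K,
) -> ITCExperiment:
    """The study's standard ITC design: 19 × 2 µL into a 200 µL cell."""
    return ITCExperiment(
        cell_volume=cell_volume,
        titrand_conc0=cell_conc,
        titrant_conc_syringe=syringe_conc,
        injection_volumes=np.full(n_injections, injection_volume),
        temperature=temperature,
    )


def gen_itc(
    kd: float,
    dh: float,
    exp: ITCExperiment | None = None,
    n: float = 1.0,
    q_dil: float = 0.0,
    noise: NoiseSpec = NoiseSpec(),
) -> np.ndarray:
    """Per-injection heats (µcal) from single-site ground truth."""
    if exp is None:
        exp = default_itc_experiment()
    clean = injection_heats(exp, kd, dh, n, q_dil)
    return noise.apply(clean)


def default_dosy_geometry(g_max: float = DEFAULT_G_MAX) -> DiffusionDecay:
    """Placeholder decay carrying the study's pulse timings (δ = 2.25 ms,
    Δ = 200 ms, τ = 100 µs) on the standard 16-step gradient grid."""
    g = np.linspace(0.02, 0.95, 16) * g_max
    return DiffusionDecay(g=g, rel_intensity=np.ones_like(g))


def gen_dosy(
    d: float,
    geometry: DiffusionDecay | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> DiffusionDecay:
    """PGSE decay for diffusion coefficient ``d`` (cm² s⁻¹) on the gradient
    grid and timings of ``geometry`` (study defaults when omitted)."""
    if geometry is None:
        geometry = default_dosy_geometry()
    clean = decay_model(geometry.g, d, geometry)
    noisy = np.clip(noise.apply(clean), 1e-9, 1.05)
    return DiffusionDecay(
        g=geometry.g,
        rel_intensity=noisy,
        delta=geometry.delta,
        big_delta=geometry.big_delta,
        tau=geometry.tau,
        gamma=geometry.gamma,
    )
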