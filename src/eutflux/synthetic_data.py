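"""Seeded generators emulating the study's NMR/MS measurements.

Three generators cover the pipeline's inputs:

* :func:`generate_physiology_timeseries` — batch-culture concentration time
  courses from the closed-form exponential-growth model;
* :func:`generate_labeling_timeseries` — tracer-experiment trajectories
  (12C3-glycerol + fully 13C2-labeled ethanolamine) from the dynamic
  isotopic model, with ethanol and acetate split by label state;
* :func:`generate_raw_cid` — "as-measured" isotopologue distributions, i.e.
  the natural-abundance forward convolution of a true CID plus noise.

The noise model is multiplicative Gaussian (default CV 2%, emulating NMR
quantification error) with an additive floor (default 0.02 mM) so that
near-zero concentrations still carry realistic uncertainty; the applied
standard deviation is recorded in the ``sd`` column, and negative noisy
values are clipped to zero (logged).  Identical seeds reproduce identical
tables.  Default sampling mirrors the emulated experiments: hourly samples,
three biological replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import isotopic_mfa
from .isotope_correction import (
    IsotopologueDistribution,
    forward_convolve,
)
from .physiology import PhysioParams, od_to_dryweight, predict_concentrations

__all__ = [
    "SamplingDesign",
    "TRACER_DESIGN",
    "od_to_dryweight",
    "generate_physiology_timeseries",
    "generate_labeling_timeseries",
    "generate_raw_cid",
]
from .timeseries import make_timeseries, validate_timeseries

logger = logging.getLogger(__name__)

#: Quantities reported as a labeled/unlabeled pair in tracer experiments.
SPLIT_QUANTITIES = ("ethanol", "acetate")


@dataclass
class SamplingDesign:
    """When and how the culture is sampled, and how noisy the readout is."""

    t_start: float = 0.0
    t_end: float = 11.0
    n_points: int = 12
    n_replicates: int = 3
    noise_cv: float = 0.02
    noise_floor: float = 0.02
    rng_seed: int = 0

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.n_points < 2:
            raise ValueError("need at least 2 sampling points")
        if self.noise_cv < 0 or self.noise_floor < 0:
            raise ValueError("noise parameters must be >= 0")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(self.t_start, self.t_end, self.n_points)


#: Design matching the emulated tracer experiment: hourly-equivalent
#: sampling restricted to the exponential phase (substrates are exhausted
#: shortly after 8 h at the reference parameters), three replicates.
TRACER_DESIGN = SamplingDesign(t_start=0.0, t_end=7.0, n_points=12)


def _apply_noise(
    values: np.ndarray, design: SamplingDesign, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    sd = np.maximum(design.noise_cv * np.abs(values), design.noise_floor)
    if design.noise_cv == 0 and design.noise_floor == 0:
        return values.copy(), np.full_like(values, 1e-12)
    noisy = values + rng.normal(0.0, 1.0, size=values.shape) * sd
    n_clip = int(np.sum(noisy < 0))
    if n_clip:
        logger.info("clipped %d negative noisy concentrations to 0", n_clip)
        noisy = np.clip(noisy, 0.0, None)
    return noisy, sd


def generate_physiology_timeseries(
    params: PhysioParams, design: SamplingDesign
) -> pd.DataFrame:
    """Noisy replicated culture time courses from the closed-form model.

    All quantities are emitted with label_state ``total``.  With
    ``noise_cv = noise_floor = 0`` the table equals the noiseless model
    output exactly (sd set to a token 1e-12 so the table stays fittable).
    """
    rng = np.random.default_rng(design.rng_seed)
    clean = predict_concentrations(params, design.times)
    rows = []
    for rep in range(1, design.n_replicates + 1):
        for q, grp in clean.groupby("quantity", sort=False):
            noisy, sd = _apply_noise(grp["value"].to_numpy(), design, rng)
            for t, v, s in zip(grp["time_h"], noisy, sd):
                rows.append((rep, float(t), q, "total", float(v), float(s)))
    out = make_timeseries(rows)
    validate_timeseries(out)
    return out


def generate_labeling_timeseries(
    fluxes: isotopic_mfa.FluxParameterSet,
    design: SamplingDesign = TRACER_DESIGN,
    *,
    network: isotopic_mfa.IsotopicNetwork | None = None,
    include_acetaldehyde: bool = False,
) -> pd.DataFrame:
    """Tracer-experiment tables from the dynamic isotopic model.

    Simulates the reference ODE route, then applies the noise model per
    replicate.  Ethanol and acetate are emitted split by label state
    (``unlabeled`` / ``U-13C``); biomass, glycerol, ethanolamine and
    ammonium as ``total``.  Acetaldehyde (a trace metabolite) is excluded
    unless requested.  The flux set must satisfy the steady-state relations
    (a violation raises with the violated balances listed).
    """
    network = network or isotopic_mfa.build_eut_network()
    isotopic_mfa.validate_flux_set(fluxes)
    sim = isotopic_mfa.simulate(network, fluxes, design.times)
    rng = np.random.default_rng(design.rng_seed)

    emit: list[tuple[str, str, str]] = [
        ("biomass", "total", "biomass"),
        ("glycerol", "total", "glycerol"),
        ("ethanolamine", "total", "ethanolamine"),
        ("ammonium", "total", "ammonium"),
        ("ethanol", "unlabeled", "ethanol_unlabeled"),
        ("ethanol", "U-13C", "ethanol_labeled"),
        ("acetate", "unlabeled", "acetate_unlabeled"),
        ("acetate", "U-13C", "acetate_labeled"),
    ]
    if include_acetaldehyde:
        emit += [
            ("acetaldehyde", "unlabeled", "acetaldehyde_unlabeled"),
            ("acetaldehyde", "U-13C", "acetaldehyde_labeled"),
        ]
    rows = []
    for rep in range(1, design.n_replicates + 1):
        for quantity, label_state, col in emit:
            noisy, sd = _apply_noise(sim[col].to_numpy(), design, rng)
            for t, v, s in zip(sim["time_h"], noisy, sd):
                rows.append((rep, float(t), quantity, label_state, float(v), float(s)))
    out = make_timeseries(rows)
    validate_timeseries(out)
    return out


def generate_raw_cid(
    true_cid: IsotopologueDistribution | np.ndarray,
    formula: str | dict[str, int],
    *,
    abundances: dict[str, tuple[float, ...]] | None = None,
    tracer_purity: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> IsotopologueDistribution:
    """Forward natural-abundance convolution of a true CID, plus noise.

    This is the measurement process that the correction step inverts: the
    returned vector is what a low-resolution mass analyzer would report for
    a fragment with the given elemental formula.  The convolution is
    renormalized after truncation at Mn; optional additive Gaussian noise
    (absolute SD ``noise_sd``) is clipped at zero and renormalized to sum 1.
    """
    vec = (
        true_cid.fractions
        if isinstance(true_cid, IsotopologueDistribution)
        else np.asarray(true_cid, dtype=float)
    )
    if abs(vec.sum() - 1.0) > 1e-9:
        raise ValueError("true CID must sum to 1")
    measured = forward_convolve(
        vec, formula, tracer_purity=tracer_purity, abundances=abundances
    )
    measured = measured / measured.sum()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        measured = np.clip(measured + rng.normal(0, noise_sd, measured.shape), 0, None)
        if measured.sum() <= 0:
            raise ValueError("noise wiped out the measured distribution")
        measured = measured / measured.sum()
    return IsotopologueDistribution(measured)
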