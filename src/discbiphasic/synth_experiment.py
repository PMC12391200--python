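"""Synthetic confined-compression cohort generator.

Produces complete, statistically realistic datasets — specimen geometry,
regional ground-truth material parameters, relaxation/creep traces with
instrument quantization, and buoyancy weights — so that every pipeline
stage is testable without any external data.

Regional parameter distributions are truncated normals (lower truncation
at 10% of the mean).  A latent standard-normal "composition" factor is
shared, with opposite loadings, between porosity on one side and
stiffness/swelling pressure on the other, so that the pooled cohort
reproduces a moderate negative porosity-stiffness correlation; the
loading is set by ``latent_coupling`` (the magnitude of the Gaussian
copula correlation between porosity and aggregate modulus).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from .biphasic_core import (
    BiphasicMaterial,
    LoadProtocol,
    SpecimenGeometry,
    creep_strain_ramp,
    relaxation_stress,
)
from .composition import DENSITY_RATIO_PBS, BuoyancyWeights
from .errors import DomainError

__all__ = ["RegionPrior", "RegionalPriors", "SyntheticSpecimen",
           "sample_specimen", "simulate_dma", "simulate_weights",
           "generate_cohort", "truncated_mean", "DEFAULT_PRIORS",
           "DEFAULT_N_PER_REGION"]

DISPLACEMENT_QUANTUM = 1e-6   # m  (1 um)
FORCE_QUANTUM = 1e-3          # N  (1 mN)
TISSUE_DENSITY = 1050.0       # kg m^-3
WATER_DENSITY = 1000.0        # kg m^-3
MAX_CREEP_EQ_STRAIN = 0.15    # linear-theory guard


@dataclass(frozen=True)
class RegionPrior:
    """Per-region true-parameter distribution (reporting units)."""

    H_A_MPa: float
    H_A_sd_MPa: float
    k_1e16: float
    k_sd_1e16: float
    swelling_kPa: float
    swelling_sd_kPa: float
    porosity: float
    porosity_sd: float
    thickness_mm: float
    thickness_sd_mm: float
    fcd_mM: float

    def __post_init__(self) -> None:
        for name in ("H_A_MPa", "k_1e16", "swelling_kPa", "porosity",
                     "thickness_mm"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} mean must be positive")
        if not (0.0 < self.porosity < 1.0):
            raise DomainError("porosity mean must lie in (0, 1)")


@dataclass(frozen=True)
class RegionalPriors:
    """Cohort-level priors: one :class:`RegionPrior` per region plus the
    latent composition coupling and donor structure."""

    NP: RegionPrior
    AF: RegionPrior
    CEP: RegionPrior
    # couplings calibrated once against the pooled-correlation targets
    # (see scripts/calibrate_coupling.py)
    latent_coupling: float = 0.15
    swelling_coupling: float = 0.60
    permeability_coupling: float = 0.20
    n_donors: int = 3
    donor_shift_frac: float = 0.05  # donor shift as fraction of regional SD

    def __post_init__(self) -> None:
        for name in ("latent_coupling", "swelling_coupling",
                     "permeability_coupling"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise DomainError(f"{name} must lie in [0, 1]")

    def region(self, name: str) -> RegionPrior:
        try:
            return getattr(self, name)
        except AttributeError:
            raise DomainError(f"unknown region {name!r}") from None


# Regional means/SDs for aggregate modulus and permeability come from the
# confined-compression rows of the measured-property table; swelling
# pressure SDs are recovered from the reported regional 95% CIs
# (SD = halfwidth * sqrt(n) / t_{0.975, n-1} with n = 10/16/10);
# porosity means are the complements of the FE solid fractions; thickness
# means/SDs are the reported preparation averages.
DEFAULT_PRIORS = RegionalPriors(
    NP=RegionPrior(0.44, 0.44, 2.96, 2.51, 97.86, 81.3, 0.873, 0.05,
                   1.17, 0.35, 182.2),
    AF=RegionPrior(0.57, 0.48, 2.75, 2.29, 161.37, 89.1, 0.817, 0.05,
                   1.17, 0.35, 135.5),
    CEP=RegionPrior(1.19, 0.98, 1.93, 1.74, 193.57, 82.8, 0.693, 0.05,
                    0.92, 0.21, 286.7),
)

DEFAULT_N_PER_REGION = {"AF": 16, "NP": 10, "CEP": 10}
_DISC_LEVELS = ("C2-C3", "C3-C4", "C4-C5", "C5-C6", "C6-C7", "C7-T1")


@dataclass(frozen=True)
class SyntheticSpecimen:
    """Ground-truth record for one synthetic specimen (SI units)."""

    specimen_id: str
    region: str
    donor_id: str
    disc_level: str
    geometry: SpecimenGeometry
    true_material: BiphasicMaterial
    true_swelling_pressure: float  # Pa
    true_porosity: float
    resample_count: int = 0


def _trunc(mean: float, sd: float, lo: float, hi: float = math.inf):
    """Frozen truncated normal on [lo, hi]."""
    if sd <= 0:
        sd = 1e-12 * max(abs(mean), 1.0)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm(a, b, loc=mean, scale=sd)


def truncated_mean(mean: float, sd: float, lo_frac: float = 0.1) -> float:
    """Mean of the truncated sampling distribution actually used for a
    positive parameter (truth for recovery tests)."""
    return float(_trunc(mean, sd, lo_frac * mean).mean())


def _ppf(dist, score: float) -> float:
    return float(dist.ppf(norm.cdf(score)))


def sample_specimen(
    region: str,
    priors: RegionalPriors,
    rng: np.random.Generator | int,
    donor_shift: float = 0.0,
) -> "SyntheticSpecimen":
    """Draw one specimen's ground truth for ``region``.

    ``donor_shift`` is a standard-normal donor effect applied to the
    regional means at ``donor_shift_frac`` of the regional SD.  Draws
    whose protocol-implied creep equilibrium strain (0.2 x swelling
    pressure / H_A) would exceed 15% are resampled (guard against
    linear-theory violation); the count is recorded.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    p = priors.region(region)
    lam = math.sqrt(priors.latent_coupling)
    lam_s = math.sqrt(priors.swelling_coupling)
    lam_k = math.sqrt(priors.permeability_coupling)
    shift = priors.donor_shift_frac * donor_shift

    H_dist = _trunc(p.H_A_MPa + shift * p.H_A_sd_MPa, p.H_A_sd_MPa,
                    0.1 * p.H_A_MPa)
    k_dist = _trunc(p.k_1e16, p.k_sd_1e16, 0.1 * p.k_1e16)
    s_dist = _trunc(p.swelling_kPa + shift * p.swelling_sd_kPa,
                    p.swelling_sd_kPa, 0.1 * p.swelling_kPa)
    phi_dist = _trunc(p.porosity, p.porosity_sd, 0.30, 0.99)
    th_dist = _trunc(p.thickness_mm, p.thickness_sd_mm, 0.1 * p.thickness_mm)

    resamples = 0
    while True:
        z_c = rng.standard_normal()      # latent composition factor
        eps = rng.standard_normal(4)
        phi = _ppf(phi_dist, lam * z_c + math.sqrt(1 - lam**2) * eps[0])
        H_A = _ppf(H_dist, -lam * z_c + math.sqrt(1 - lam**2) * eps[1])
        sw = _ppf(s_dist, -lam_s * z_c + math.sqrt(1 - lam_s**2) * eps[2])
        k = _ppf(k_dist, lam_k * z_c + math.sqrt(1 - lam_k**2) * eps[3])
        thick = float(th_dist.rvs(random_state=rng))
        if 0.2 * (sw * 1e3) / (H_A * 1e6) <= MAX_CREEP_EQ_STRAIN:
            break
        resamples += 1
        if resamples > 100:
            raise DomainError(
                f"could not draw a linear-theory-compatible {region} specimen")

    mat = BiphasicMaterial(H_A=H_A * 1e6, k=k * 1e-16, nu=0.2,
                           phi_w0=phi, c_F0=p.fcd_mM)
    return SyntheticSpecimen(
        specimen_id="",
        region=region,
        donor_id="",
        disc_level="",
        geometry=SpecimenGeometry(thickness=thick * 1e-3, diameter=5e-3),
        true_material=mat,
        true_swelling_pressure=sw * 1e3,
        true_porosity=phi,
        resample_count=resamples,
    )


def simulate_dma(
    spec: SyntheticSpecimen,
    protocol: LoadProtocol = LoadProtocol(),
    rng: np.random.Generator | int = 0,
    quantize: bool = True,
    extra_rms: float = 0.0,
    sample_dt_relax: float = 5.0,
    sample_dt_creep: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the relaxation + creep protocol for one specimen.

    Returns (relaxation, creep) DataFrames in instrument conventions
    (``time_s, displacement_um, force_mN``).  The relaxation force is
    the biphasic ramp-and-hold transient superposed on the osmotic
    baseline so that the equilibrium load equals
    ``true_swelling_pressure * area`` exactly by construction; the creep
    displacement follows the ramped biphasic creep solution under a load
    of ``creep_load_fraction`` of the equilibrium load.  When
    ``quantize`` is on, displacement is rounded to 1 um and force to
    1 mN; ``extra_rms`` adds white displacement noise (m) before
    quantization.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    mat = spec.true_material
    h = spec.geometry.thickness
    area = spec.geometry.area
    eq_load = spec.true_swelling_pressure * area

    # relaxation phase: displacement held at the offset strain.  The
    # hold is extended beyond the nominal duration for slow specimens so
    # the recorded tail is genuinely equilibrated (residual transient
    # below ~0.1 force quantum), mirroring experimental practice of
    # waiting for equilibrium.
    tau_mode = h * h / (math.pi**2 * mat.diffusivity)  # slowest mode
    transient0 = mat.H_A * protocol.offset_strain * area
    t_decay = tau_mode * math.log(
        max(transient0 / (0.1 * FORCE_QUANTUM), 2.0))
    t_rel_end = max(protocol.relax_duration, t_decay)
    dt_rel = max(sample_dt_relax, t_rel_end / 1440.0)
    t_rel = np.arange(0.0, t_rel_end + 1e-9, dt_rel)
    sig_rel = relaxation_stress(mat, h, protocol.offset_strain,
                                protocol.offset_ramp_duration, t_rel)
    force_rel = np.maximum(
        eq_load + (sig_rel - mat.H_A * protocol.offset_strain) * area, 0.0)
    disp_rel = np.minimum(t_rel / protocol.offset_ramp_duration, 1.0) \
        * protocol.offset_strain * h

    # creep phase: ramped load, displacement relative to relaxed state
    load = protocol.creep_load_fraction * eq_load
    sigma0 = load / area
    t_cr = np.arange(0.0, protocol.creep_duration + 1e-9, sample_dt_creep)
    disp_cr = creep_strain_ramp(mat, h, sigma0, protocol.ramp_duration, t_cr) * h
    force_cr = np.minimum(t_cr / protocol.ramp_duration, 1.0) * load

    if extra_rms > 0:
        disp_rel = disp_rel + rng.normal(0.0, extra_rms, disp_rel.shape)
        disp_cr = disp_cr + rng.normal(0.0, extra_rms, disp_cr.shape)
    if quantize:
        disp_rel = np.round(disp_rel / DISPLACEMENT_QUANTUM) * DISPLACEMENT_QUANTUM
        disp_cr = np.round(disp_cr / DISPLACEMENT_QUANTUM) * DISPLACEMENT_QUANTUM
        force_rel = np.round(force_rel / FORCE_QUANTUM) * FORCE_QUANTUM
        force_cr = np.round(force_cr / FORCE_QUANTUM) * FORCE_QUANTUM

    relax_df = pd.DataFrame({
        "time_s": t_rel,
        "displacement_um": disp_rel * 1e6,
        "force_mN": force_rel * 1e3,
    })
    creep_df = pd.DataFrame({
        "time_s": t_cr,
        "displacement_um": disp_cr * 1e6,
        "force_mN": force_cr * 1e3,
    })
    return relax_df, creep_df


def simulate_weights(
    spec: SyntheticSpecimen,
    rng: np.random.Generator | int = 0,
    balance_noise_mg: float = 0.0,
) -> BuoyancyWeights:
    """Buoyancy weights (mg) that invert to the specimen's true porosity.

    W_wet follows from geometry and a nominal tissue density; W_dry and
    W_PBS are back-solved so the porosity formula returns the true value
    exactly before any balance noise is added.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    vol = spec.geometry.area * spec.geometry.thickness      # m^3
    w_wet = vol * TISSUE_DENSITY * 1e6                      # g -> mg: kg*1e6
    phi = spec.true_porosity
    # water mass fraction of the wet weight
    water_mass = vol * phi * WATER_DENSITY * 1e6
    w_dry = w_wet - water_mass
    # invert phi = (wet - dry)/(wet - pbs) * ratio for W_PBS
    w_pbs = w_wet - (w_wet - w_dry) * DENSITY_RATIO_PBS / phi
    if balance_noise_mg > 0:
        w_wet += rng.normal(0.0, balance_noise_mg)
        w_pbs += rng.normal(0.0, balance_noise_mg)
        w_dry += rng.normal(0.0, balance_noise_mg)
    return BuoyancyWeights(W_wet=w_wet, W_PBS=w_pbs, W_dry=w_dry)


def generate_cohort(
    out_dir: Path,
    n_per_region: dict | None = None,
    priors: RegionalPriors = DEFAULT_PRIORS,
    master_seed: int = 0,
    protocol: LoadProtocol = LoadProtocol(),
    quantize: bool = True,
    extra_rms: float = 0.0,
) -> pd.DataFrame:
    """Write a full synthetic dataset directory and return ground truth.

    Layout::

        out_dir/
          specimens/<id>.json       sidecar metadata
          traces/<id>_relaxation.csv, <id>_creep.csv
          weights.csv
          ground_truth.csv

    Fully reproducible from ``master_seed``.
    """
    n_per_region = dict(DEFAULT_N_PER_REGION if n_per_region is None
                        else n_per_region)
    for region, n in n_per_region.items():
        if region not in ("NP", "AF", "CEP"):
            raise DomainError(f"unknown region {region!r}")
        if n < 1:
            raise DomainError("need n >= 1 per region")

    out_dir = Path(out_dir)
    (out_dir / "specimens").mkdir(parents=True, exist_ok=True)
    (out_dir / "traces").mkdir(parents=True, exist_ok=True)

    donor_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(0,)))
    donor_effects = donor_rng.standard_normal(priors.n_donors)

    rows = []
    weight_rows = []
    idx = 0
    for region in ("AF", "NP", "CEP"):
        if region not in n_per_region:
            continue
        for j in range(n_per_region[region]):
            # per-specimen child stream addressable by (seed, index)
            ss = np.random.SeedSequence(entropy=master_seed,
                                        spawn_key=(idx + 1,))
            rng = np.random.default_rng(ss)
            donor_i = idx % priors.n_donors
            spec = sample_specimen(region, priors, rng,
                                   donor_shift=donor_effects[donor_i])
            sid = f"{region}{j + 1:02d}"
            spec = replace(
                spec, specimen_id=sid, donor_id=f"D{donor_i + 1}",
                disc_level=_DISC_LEVELS[idx % len(_DISC_LEVELS)])
            relax_df, creep_df = simulate_dma(
                spec, protocol, rng, quantize=quantize, extra_rms=extra_rms)
            weights = simulate_weights(spec, rng)

            meta = {
                "specimen_id": sid,
                "region": region,
                "donor_id": spec.donor_id,
                "disc_level": spec.disc_level,
                "thickness_mm": spec.geometry.thickness * 1e3,
                "diameter_mm": spec.geometry.diameter * 1e3,
            }
            (out_dir / "specimens" / f"{sid}.json").write_text(
                json.dumps(meta, indent=1))
            relax_df.to_csv(out_dir / "traces" / f"{sid}_relaxation.csv",
                            index=False, float_format="%.6f")
            creep_df.to_csv(out_dir / "traces" / f"{sid}_creep.csv",
                            index=False, float_format="%.6f")
            weight_rows.append({
                "specimen_id": sid,
                "W_wet_mg": weights.W_wet,
                "W_PBS_mg": weights.W_PBS,
                "W_dry_mg": weights.W_dry,
            })
            rows.append({
                "specimen_id": sid,
                "region": region,
                "donor_id": spec.donor_id,
                "disc_level": spec.disc_level,
                "thickness_mm": spec.geometry.thickness * 1e3,
                "H_A_MPa": spec.true_material.H_A / 1e6,
                "k_1e-16_m4_Ns": spec.true_material.k * 1e16,
                "swelling_pressure_kPa": spec.true_swelling_pressure / 1e3,
                "porosity": spec.true_porosity,
                "resample_count": spec.resample_count,
            })
            idx += 1

    pd.DataFrame(weight_rows).to_csv(out_dir / "weights.csv", index=False,
                                     float_format="%.6f")
    truth = pd.DataFrame(rows)
    truth.to_csv(out_dir / "ground_truth.csv", index=False,
                 float_format="%.10g")
    return truth
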