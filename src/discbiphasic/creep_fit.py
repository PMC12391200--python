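"""Per-specimen parameter estimation from confined-compression traces.

The relaxation-phase equilibrium load divided by the specimen area gives
the swelling pressure; the creep-phase displacement trace is fit by
nonlinear least squares against the ramped biphasic creep solution to
estimate the aggregate modulus ``H_A`` and hydraulic permeability ``k``.

Optimization runs in (log H_A, log k) space with a trust-region
least-squares method, which guarantees positivity without constraints
and copes with the orders-of-magnitude scale of ``k``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .biphasic_core import (
    BiphasicMaterial,
    LoadProtocol,
    SeriesControl,
    SpecimenGeometry,
    creep_strain_ramp,
    creep_strain_step,
    gel_time,
    permeability_to_report_units,
)
from .errors import DataQualityError, DomainError

__all__ = ["CreepTrace", "FitResult", "swelling_pressure", "creep_load",
           "initialize_fit", "fit_biphasic_creep", "read_specimen_dir"]

REGIONS = ("NP", "AF", "CEP")


@dataclass
class CreepTrace:
    """Creep-phase record for one specimen (SI units).

    ``displacement`` is measured relative to the post-relaxation
    equilibrium position; ``applied_load`` may be a scalar target or a
    per-sample vector (N).
    """

    time: np.ndarray
    displacement: np.ndarray
    applied_load: np.ndarray | float
    specimen: SpecimenGeometry
    region: str
    donor_id: str = ""
    disc_level: str = ""
    specimen_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.displacement.shape:
            raise DomainError("time and displacement must be 1-D and equal length")
        if self.time[0] != 0.0 or not np.all(np.diff(self.time) > 0):
            raise DomainError("time must increase strictly from 0")
        if not np.all(np.isfinite(self.displacement)):
            raise DomainError("displacement must be finite")
        if np.any(np.abs(self.displacement) >= self.specimen.thickness):
            raise DomainError("displacement exceeds specimen thickness")
        if self.region not in REGIONS:
            raise DomainError(f"region must be one of {REGIONS}")

    @property
    def load_target(self) -> float:
        """Scalar creep load (N): plateau mean if a vector was recorded."""
        if np.ndim(self.applied_load) == 0:
            return float(self.applied_load)
        load = np.asarray(self.applied_load, dtype=float)
        t_plateau = self.time >= 0.5 * self.time[-1]
        return float(load[t_plateau].mean())


@dataclass
class FitResult:
    """Estimated biphasic parameters and fit diagnostics for one specimen."""

    H_A_hat: float                 # Pa
    k_hat: float                   # m^4 N^-1 s^-1
    swelling_pressure: float       # Pa
    r_squared: float
    rmse: float                    # m
    n_iter: int
    converged: bool
    duration_warning: bool = False
    ci_halfwidth_H_A: Optional[float] = None   # Pa
    ci_halfwidth_k: Optional[float] = None     # m^4 N^-1 s^-1
    specimen_id: str = ""
    region: str = ""
    donor_id: str = ""
    disc_level: str = ""

    def __post_init__(self) -> None:
        if self.H_A_hat <= 0 or self.k_hat <= 0:
            raise DomainError("fitted parameters must be positive")
        if not (-1e-9 <= self.r_squared <= 1.0 + 1e-9):
            raise DomainError("r_squared must lie in [0, 1]")
        self.r_squared = min(max(self.r_squared, 0.0), 1.0)

    def to_record(self) -> dict:
        """Flat record mixing SI and reporting units for serialization."""
        return {
            "specimen_id": self.specimen_id,
            "region": self.region,
            "donor_id": self.donor_id,
            "disc_level": self.disc_level,
            "H_A_MPa": self.H_A_hat / 1e6,
            "k_1e-16_m4_Ns": permeability_to_report_units(self.k_hat),
            "swelling_pressure_kPa": self.swelling_pressure / 1e3,
            "H_A_Pa": self.H_A_hat,
            "k_SI": self.k_hat,
            "r_squared": self.r_squared,
            "rmse_um": self.rmse * 1e6,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "duration_warning": self.duration_warning,
        }


def swelling_pressure(equilibrium_load: float, area: float) -> float:
    """Equilibrium load (N) over specimen area (m^2), Pa."""
    if area <= 0:
        raise DomainError("area must be positive")
    if equilibrium_load < 0:
        raise DomainError("equilibrium_load must be non-negative")
    return equilibrium_load / area


def creep_load(equilibrium_load: float, fraction: float) -> float:
    """Creep load as a fraction of the relaxation equilibrium load (N)."""
    if not (0.0 < fraction < 1.0):
        raise DomainError("fraction must lie in (0, 1)")
    if equilibrium_load < 0:
        raise DomainError("equilibrium_load must be non-negative")
    return equilibrium_load * fraction


_UNIT_CREEP_CTL = SeriesControl(tol=1e-12, n_max=400)


def _half_rise_T(level: float) -> float:
    """Dimensionless time at which the unit step creep response reaches
    ``level`` of its equilibrium value (level in (0, 1))."""
    def f(T):
        mat = BiphasicMaterial(H_A=1.0, k=1.0)
        return creep_strain_step(mat, 1.0, 1.0, T, _UNIT_CREEP_CTL) - level
    return brentq(f, 1e-6, 50.0, xtol=1e-12)


def initialize_fit(trace: CreepTrace, protocol: LoadProtocol) -> tuple[float, float]:
    """Moment-style starting values (H_A0, k0) for the least squares fit.

    H_A0 treats 105% of the final observed strain as the equilibrium
    strain; k0 follows from inverting the step solution at the time the
    trace first reaches half the final displacement.
    """
    h = trace.specimen.thickness
    eps = trace.displacement / h
    eps_end = float(np.mean(eps[trace.time >= 0.95 * trace.time[-1]]))
    if eps_end <= 0:
        raise DataQualityError("final creep strain is non-positive")
    sigma0 = trace.load_target / trace.specimen.area
    if sigma0 <= 0:
        raise DataQualityError("creep load target is non-positive")
    H_A0 = sigma0 / (1.05 * eps_end)

    half = 0.5 * eps_end
    above = np.nonzero(eps >= half)[0]
    if len(above) == 0 or above[0] == 0:
        raise DataQualityError("trace never crosses half its final strain")
    i = above[0]
    t_half = float(np.interp(half, eps[i - 1:i + 1], trace.time[i - 1:i + 1]))
    t_half = max(t_half, trace.time[1])
    # fraction of equilibrium reached at t_half under the H_A0 proxy
    level = min(max(half * H_A0 / sigma0, 0.05), 0.95)
    T_half = _half_rise_T(level)
    k0 = T_half * h * h / (H_A0 * t_half)
    return H_A0, k0


def _check_trace_quality(trace: CreepTrace) -> None:
    d = trace.displacement
    n = len(d)
    if n < 30:
        raise DataQualityError(f"trace has only {n} samples (need >= 30)")
    # robust trend check on the raw (possibly quantized) trace
    slope = np.polyfit(trace.time, d, 1)[0]
    if slope <= 0 or d[-5:].mean() <= d[:5].mean():
        raise DataQualityError("creep trace has a non-positive trend")
    smooth = pd.Series(d).rolling(max(5, n // 50), min_periods=1).mean().to_numpy()
    backslide = np.max(np.maximum.accumulate(smooth) - smooth)
    if backslide > 0.25 * (smooth.max() - smooth.min() + 1e-30):
        raise DataQualityError("creep trace is strongly non-monotone")


def fit_biphasic_creep(
    trace: CreepTrace,
    protocol: LoadProtocol = LoadProtocol(),
    ctl: SeriesControl = SeriesControl(),
) -> FitResult:
    """Least-squares fit of (H_A, k) to a creep displacement trace.

    The model is the ramped biphasic creep solution times the specimen
    thickness; the applied stress is the recorded creep load over the
    specimen area (not re-estimated).  Non-convergence is reported in
    the ``converged`` flag rather than raised; implausible traces raise
    :class:`DataQualityError`.
    """
    _check_trace_quality(trace)
    h = trace.specimen.thickness
    sigma0 = trace.load_target / trace.specimen.area
    H_A0, k0 = initialize_fit(trace, protocol)

    t = trace.time
    d_obs = trace.displacement

    def residuals(logp: np.ndarray) -> np.ndarray:
        H_A, k = math.exp(logp[0]), math.exp(logp[1])
        mat = BiphasicMaterial(H_A=H_A, k=k, nu=0.2)
        model = creep_strain_ramp(mat, h, sigma0, protocol.ramp_duration, t, ctl) * h
        return model - d_obs

    x0 = np.array([math.log(H_A0), math.log(k0)])
    sol = least_squares(residuals, x0, method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=500)
    H_A_hat, k_hat = math.exp(sol.x[0]), math.exp(sol.x[1])

    resid = sol.fun
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((d_obs - d_obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    rmse = math.sqrt(ss_res / len(d_obs))

    # delta-method CIs from the Jacobian in log space
    ci_H = ci_k = None
    dof = len(d_obs) - 2
    if dof > 0:
        try:
            JTJ = sol.jac.T @ sol.jac
            cov_log = np.linalg.inv(JTJ) * (ss_res / dof)
            se_log = np.sqrt(np.maximum(np.diag(cov_log), 0.0))
            ci_H = 1.96 * se_log[0] * H_A_hat
            ci_k = 1.96 * se_log[1] * k_hat
        except np.linalg.LinAlgError:
            pass

    mat_hat = BiphasicMaterial(H_A=H_A_hat, k=k_hat)
    tau_hat = gel_time(mat_hat, h)
    duration_warning = bool(t[-1] < 0.2 * tau_hat)
    if duration_warning:
        warnings.warn(
            f"creep trace spans only {t[-1] / tau_hat:.2f} of the estimated "
            "consolidation time; permeability is weakly identified",
            stacklevel=2)

    return FitResult(
        H_A_hat=H_A_hat,
        k_hat=k_hat,
        swelling_pressure=float("nan"),
        r_squared=max(r2, 0.0),
        rmse=rmse,
        n_iter=int(sol.nfev),
        converged=bool(sol.status > 0),
        duration_warning=duration_warning,
        ci_halfwidth_H_A=ci_H,
        ci_halfwidth_k=ci_k,
        specimen_id=trace.specimen_id,
        region=trace.region,
        donor_id=trace.donor_id,
        disc_level=trace.disc_level,
    )


# ---------------------------------------------------------------------------
# file I/O: CSV traces (instrument units um / mN) + JSON sidecars
# ---------------------------------------------------------------------------

def _read_trace_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"time_s", "displacement_um", "force_mN"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"{path}: missing columns {sorted(missing)}")
    return df


def load_specimen(data_dir: Path, specimen_id: str,
                  protocol: LoadProtocol = LoadProtocol()
                  ) -> tuple[CreepTrace, float]:
    """Read one specimen's sidecar + trace CSVs.

    Returns the creep trace and the relaxation equilibrium load (N),
    taken as the mean recorded force over the final 5% of the
    relaxation phase.
    """
    data_dir = Path(data_dir)
    meta_path = data_dir / "specimens" / f"{specimen_id}.json"
    meta = json.loads(meta_path.read_text())
    geom = SpecimenGeometry(
        thickness=meta["thickness_mm"] * 1e-3,
        diameter=meta["diameter_mm"] * 1e-3,
    )
    relax = _read_trace_csv(data_dir / "traces" / f"{specimen_id}_relaxation.csv")
    creep = _read_trace_csv(data_dir / "traces" / f"{specimen_id}_creep.csv")

    t_rel = relax["time_s"].to_numpy()
    tail = t_rel >= 0.95 * t_rel[-1]
    eq_load = float(relax.loc[tail, "force_mN"].mean()) * 1e-3  # N

    trace = CreepTrace(
        time=creep["time_s"].to_numpy(),
        displacement=creep["displacement_um"].to_numpy() * 1e-6,
        applied_load=creep["force_mN"].to_numpy() * 1e-3,
        specimen=geom,
        region=meta["region"],
        donor_id=str(meta.get("donor_id", "")),
        disc_level=str(meta.get("disc_level", "")),
        specimen_id=specimen_id,
    )
    return trace, eq_load


def read_specimen_dir(data_dir: Path) -> list[str]:
    """Specimen ids present in a dataset directory, sorted."""
    spec_dir = Path(data_dir) / "specimens"
    if not spec_dir.is_dir():
        raise DomainError(f"no specimens/ directory under {data_dir}")
    return sorted(p.stem for p in spec_dir.glob("*.json"))


def fit_specimen(data_dir: Path, specimen_id: str,
                 protocol: LoadProtocol = LoadProtocol()) -> FitResult:
    """Full per-specimen estimation: swelling pressure + creep fit."""
    trace, eq_load = load_specimen(data_dir, specimen_id, protocol)
    result = fit_biphasic_creep(trace, protocol)
    result.swelling_pressure = swelling_pressure(eq_load, trace.specimen.area)
    return result
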