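"""Single-site ITC: forward model, fitting, and thermodynamic bookkeeping.

An isothermal titration calorimetry experiment injects a ligand solution
stepwise into a cell containing the macromolecule and records the heat of
each injection. For a single set of N identical, independent sites the
cumulative heat after injection i is

    Q_i = N * Theta_i * M_t(i) * V0 * dH,

where Theta_i is the fractional saturation from the one-site binding
quadratic and M_t, X_t are the effective cell concentrations of
macromolecule and titrant after correcting for the volume displaced by the
injections (the perfusion-cell convention used by the instrument software):

    M_t(i) = M0 * (1 - v_i/(2 V0)) / (1 + v_i/(2 V0))
    X_t(i) = X_s * (v_i/V0)      / (1 + v_i/(2 V0))

with v_i the cumulative injected volume. The observable per-injection heat
also carries the heat of the liquid pushed out of the active volume:

    q_i = Q_i - Q_{i-1} + (dV_i/V0) * (Q_i + Q_{i-1}) / 2.

Fitting minimises the squared residual of q_i over (N, K_D, dH); K_D is
optimised in log space and the fit is multi-started over log-spaced K_D
guesses. Free energy and entropy follow from dG = R T ln K_D and
-T dS = dG - dH; "enthalpic efficiency" is 100*dH/dG.
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "R_KCAL",
    "T_REF",
    "ScheduleError",
    "DegenerateDataError",
    "FitConvergenceError",
    "LowCWarning",
    "InjectionSchedule",
    "TitrationSeries",
    "BindingFit",
    "ReplicateSummary",
    "DeltaCpResult",
    "default_schedule",
    "simulate_isotherm",
    "subtract_dilution",
    "fit_single_site",
    "derive_thermodynamics",
    "summarize_replicates",
    "estimate_delta_cp",
    "write_titration_csv",
    "read_titration_csv",
    "fit_to_json",
]

#: gas constant, kcal mol^-1 K^-1
R_KCAL = 1.9872e-3
#: reference temperature for "298 K" experiments
T_REF = 298.15

KCAL_TO_UCAL = 1e9


class ScheduleError(ValueError):
    """Invalid injection schedule (volumes, concentrations, overfill)."""


class DegenerateDataError(ValueError):
    """Input series carries no usable binding signal."""


class FitConvergenceError(RuntimeError):
    """No optimisation start converged; carries the best residual seen."""

    def __init__(self, message: str, best_cost: float | None = None):
        super().__init__(message)
        self.best_cost = best_cost


class LowCWarning(UserWarning):
    """c = N*M/K_D < 1: the isotherm is too shallow to determine N reliably."""


# ---------------------------------------------------------------------------
# schedules and series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InjectionSchedule:
    """Injection program of one titration.

    Parameters
    ----------
    cell_volume : float
        Active cell volume V0 in litres.
    cell_conc : float
        Initial macromolecule concentration in the cell, molar.
    syringe_conc : float
        Titrant concentration in the syringe, molar.
    injection_volumes : tuple of float
        Per-injection volumes in litres.
    temperature : float
        Experiment temperature, K.
    interval_s : float
        Spacing between injections, seconds (metadata only).
    """

    cell_volume: float
    cell_conc: float
    syringe_conc: float
    injection_volumes: tuple[float, ...]
    temperature: float = T_REF
    interval_s: float = 180.0

    def __post_init__(self):
        vols = tuple(float(v) for v in self.injection_volumes)
        object.__setattr__(self, "injection_volumes", vols)
        if self.cell_volume <= 0:
            raise ScheduleError("cell volume must be positive")
        if self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ScheduleError("concentrations must be positive")
        if self.temperature <= 0:
            raise ScheduleError("temperature must be positive")
        if len(vols) == 0 or any(v <= 0 for v in vols):
            raise ScheduleError("injection volumes must be positive")
        if sum(vols) > self.cell_volume:
            raise ScheduleError(
                f"cumulative injected volume {sum(vols):.3e} L exceeds the "
                f"cell volume {self.cell_volume:.3e} L"
            )

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    @property
    def cumulative_volumes(self) -> np.ndarray:
        return np.cumsum(self.injection_volumes)


def default_schedule(
    n_injections: int = 28,
    injection_volume: float = 10e-6,
    cell_volume: float = 1.4e-3,
    cell_conc: float = 50e-6,
    syringe_conc: float = 500e-6,
    temperature: float = T_REF,
) -> InjectionSchedule:
    """Typical perfusion-calorimeter program: 28 x 10 uL into 1.4 mL,
    50 uM macromolecule, 500 uM titrant, 298.15 K."""
    return InjectionSchedule(
        cell_volume=cell_volume,
        cell_conc=cell_conc,
        syringe_conc=syringe_conc,
        injection_volumes=(injection_volume,) * n_injections,
        temperature=temperature,
    )


@dataclass
class TitrationSeries:
    """One titration: an injection schedule and the measured heats (ucal)."""

    schedule: InjectionSchedule
    heats: np.ndarray
    label: str = ""
    is_blank: bool = False

    def __post_init__(self):
        self.heats = np.asarray(self.heats, dtype=float)
        if self.heats.shape != (self.schedule.n_injections,):
            raise ValueError(
                f"got {self.heats.size} heats for "
                f"{self.schedule.n_injections} injections"
            )
        if not np.all(np.isfinite(self.heats)):
            raise ValueError("heats must be finite")

    def total_heat(self) -> float:
        """Sum of per-injection heats, ucal."""
        return float(np.sum(self.heats))


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def effective_concentrations(
    schedule: InjectionSchedule,
) -> tuple[np.ndarray, np.ndarray]:
    """Displacement-corrected total concentrations after each injection.

    Returns (M_t, X_t) arrays, molar, one entry per injection.
    """
    v = schedule.cumulative_volumes
    v0 = schedule.cell_volume
    dilution = 1.0 + v / (2.0 * v0)
    m_t = schedule.cell_conc * (1.0 - v / (2.0 * v0)) / dilution
    x_t = schedule.syringe_conc * (v / v0) / dilution
    return m_t, x_t


def _saturation(n_sites: float, kd: float, m_t: np.ndarray,
                x_t: np.ndarray) -> np.ndarray:
    """Fractional saturation Theta of the N identical sites."""
    nm = n_sites * m_t
    b = 1.0 + x_t / nm + kd / nm
    disc = b * b - 4.0 * x_t / nm
    if np.any(disc < 0):
        raise FloatingPointError("negative discriminant in binding quadratic")
    return 0.5 * (b - np.sqrt(disc))


def cumulative_heats(n_sites: float, kd: float, dh: float,
                     schedule: InjectionSchedule) -> np.ndarray:
    """Cumulative heat Q_i (ucal) after each injection."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    m_t, x_t = effective_concentrations(schedule)
    theta = _saturation(n_sites, kd, m_t, x_t)
    return n_sites * theta * m_t * schedule.cell_volume * dh * KCAL_TO_UCAL


def simulate_isotherm(n_sites: float, kd: float, dh: float,
                      schedule: InjectionSchedule,
                      label: str = "") -> TitrationSeries:
    """Noise-free per-injection heats of a one-site titration.

    Parameters are the stoichiometry N, dissociation constant K_D (molar)
    and molar enthalpy dH (kcal/mol). Heats are returned in ucal with the
    displaced-volume correction applied to each injection.
    """
    q = cumulative_heats(n_sites, kd, dh, schedule)
    q_prev = np.concatenate(([0.0], q[:-1]))
    dv = np.asarray(schedule.injection_volumes)
    heats = q - q_prev + (dv / schedule.cell_volume) * (q + q_prev) / 2.0
    return TitrationSeries(schedule=schedule, heats=heats, label=label)


def subtract_dilution(series: TitrationSeries,
                      blank: TitrationSeries | None = None) -> TitrationSeries:
    """Remove titrant dilution heat.

    With a blank titration the subtraction is injection-by-injection; the
    schedules must have the same number of injections. Without a blank the
    mean of the final three injections (post-saturation plateau) is used as
    a constant dilution estimate.
    """
    if blank is not None:
        if blank.schedule.n_injections != series.schedule.n_injections:
            raise ValueError(
                "blank and sample titrations have different injection counts"
            )
        corrected = series.heats - blank.heats
    else:
        corrected = series.heats - np.mean(series.heats[-3:])
    return replace(series, heats=corrected)


# ---------------------------------------------------------------------------
# derived thermodynamics
# ---------------------------------------------------------------------------

def derive_thermodynamics(kd: float, dh: float,
                          temperature: float = T_REF
                          ) -> tuple[float, float, float]:
    """(dG, -TdS, efficiency %) from K_D (molar) and dH (kcal/mol).

    dG = R T ln K_D; -T dS = dG - dH; efficiency = 100*dH/dG. Raises
    ValueError when dG = 0 (K_D = 1 M), where the efficiency is undefined.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    dg = R_KCAL * temperature * math.log(kd)
    if dg == 0.0:
        raise ValueError("dG = 0 (K_D = 1 M): enthalpic efficiency undefined")
    tds_neg = dg - dh
    efficiency = 100.0 * dh / dg
    return dg, tds_neg, efficiency


@dataclass
class BindingFit:
    """Fitted one-site parameters and derived thermodynamic quantities."""

    n_sites: float
    kd: float                 # molar
    dh: float                 # kcal/mol
    temperature: float
    dg: float = field(init=False)
    tds_neg: float = field(init=False)
    efficiency: float = field(init=False)   # percent
    n_fixed: bool = False
    fit_rmse: float = float("nan")          # ucal
    c_value: float = float("nan")
    label: str = ""

    def __post_init__(self):
        self.dg, self.tds_neg, self.efficiency = derive_thermodynamics(
            self.kd, self.dh, self.temperature
        )

    @property
    def kd_uM(self) -> float:
        return self.kd * 1e6


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_LOG10_KD_BOUNDS = (-12.0, -1.0)


def _model_heats(n_sites: float, log10_kd: float, dh: float,
                 schedule: InjectionSchedule) -> np.ndarray:
    return simulate_isotherm(n_sites, 10.0 ** log10_kd, dh, schedule).heats


def fit_single_site(series: TitrationSeries,
                    temperature: float | None = None,
                    fix_n: bool = False,
                    n_starts: int = 5) -> BindingFit:
    """Fit (N, K_D, dH) — or (K_D, dH) with N fixed to 1 — to a titration.

    Least squares on the per-injection heats with K_D optimised in log10
    space; `n_starts` log-spaced K_D starting guesses are tried and the best
    converged solution kept. Emits :class:`LowCWarning` when the fitted
    c-value N*M0/K_D falls below 1 and N was not fixed.
    """
    schedule = series.schedule
    if temperature is None:
        temperature = schedule.temperature
    if schedule.n_injections < 6:
        raise DegenerateDataError("need at least 6 injections to fit")
    obs = series.heats
    if np.allclose(obs, 0.0):
        raise DegenerateDataError("all heats are zero: nothing to fit")

    # enthalpy guess from the early, mostly-quantitative injections
    m0 = schedule.cell_conc
    dv0 = schedule.injection_volumes[0]
    mol_per_inj = schedule.syringe_conc * dv0
    dh0 = float(np.clip(obs[0] / (mol_per_inj * KCAL_TO_UCAL), -50, 50))
    if dh0 == 0.0:
        dh0 = -1.0

    kd_starts = np.logspace(-8, -4, n_starts)
    best = None
    best_cost = None
    for kd0 in kd_starts:
        if fix_n:
            x0 = [math.log10(kd0), dh0]

            def resid(x):
                return _model_heats(1.0, x[0], x[1], schedule) - obs

            bounds = ([_LOG10_KD_BOUNDS[0], -100.0],
                      [_LOG10_KD_BOUNDS[1], 100.0])
        else:
            x0 = [1.0, math.log10(kd0), dh0]

            def resid(x):
                return _model_heats(x[0], x[1], x[2], schedule) - obs

            bounds = ([0.05, _LOG10_KD_BOUNDS[0], -100.0],
                      [20.0, _LOG10_KD_BOUNDS[1], 100.0])
        try:
            sol = optimize.least_squares(resid, x0, bounds=bounds,
                                         xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except (FloatingPointError, ValueError):
            continue
        if best_cost is None or sol.cost < best_cost:
            best, best_cost = sol, sol.cost

    if best is None:
        raise FitConvergenceError("no optimisation start converged",
                                  best_cost=best_cost)

    if fix_n:
        n_fit, log_kd, dh_fit = 1.0, best.x[0], best.x[1]
    else:
        n_fit, log_kd, dh_fit = best.x
    kd_fit = 10.0 ** log_kd
    rmse = float(np.sqrt(np.mean(best.fun ** 2)))
    c_value = n_fit * m0 / kd_fit
    if c_value < 1.0 and not fix_n:
        warnings.warn(
            f"c = {c_value:.2f} < 1: stoichiometry is poorly determined; "
            "consider fix_n=True",
            LowCWarning,
            stacklevel=2,
        )
    return BindingFit(n_sites=float(n_fit), kd=float(kd_fit),
                      dh=float(dh_fit), temperature=temperature,
                      n_fixed=fix_n, fit_rmse=rmse, c_value=float(c_value),
                      label=series.label)


# ---------------------------------------------------------------------------
# replicates and dCp
# ---------------------------------------------------------------------------

@dataclass
class ReplicateSummary:
    """Mean and sample SD of fitted parameters over replicate titrations."""

    n_replicates: int
    mean: dict[str, float]
    sd: dict[str, float]


_REPLICATE_PARAMS = ("n_sites", "kd", "dh", "dg", "tds_neg", "efficiency")


def summarize_replicates(fits: list[BindingFit]) -> ReplicateSummary:
    """Per-parameter mean +/- sample SD over replicate fits (>=1)."""
    if not fits:
        raise ValueError("no fits to summarize")
    mean, sd = {}, {}
    for p in _REPLICATE_PARAMS:
        vals = np.array([getattr(f, p) for f in fits], dtype=float)
        mean[p] = float(np.mean(vals))
        sd[p] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return ReplicateSummary(n_replicates=len(fits), mean=mean, sd=sd)


@dataclass
class DeltaCpResult:
    """Heat-capacity change of binding from the dH(T) slope."""

    slope_cal: float        # dCp, cal mol^-1 K^-1
    intercept_kcal: float   # dH extrapolated to T = 0, kcal/mol
    r: float                # Pearson r of the regression
    temperatures: tuple[float, ...]
    dh_values: tuple[float, ...]


def estimate_delta_cp(
    dh_by_temperature: list[tuple[float, float]]
) -> DeltaCpResult:
    """Ordinary least-squares slope of dH (kcal/mol) versus T (K).

    The slope is the binding heat-capacity change dCp, returned in
    cal mol^-1 K^-1; a more negative dCp indicates a larger buried
    interface. Requires at least two distinct temperatures.
    """
    temps = np.array([t for t, _ in dh_by_temperature], dtype=float)
    dhs = np.array([d for _, d in dh_by_temperature], dtype=float)
    if len(np.unique(temps)) < 2:
        raise ValueError("need dH at >=2 distinct temperatures")
    fit = stats.linregress(temps, dhs)
    return DeltaCpResult(
        slope_cal=float(fit.slope) * 1000.0,
        intercept_kcal=float(fit.intercept),
        r=float(fit.rvalue),
        temperatures=tuple(temps),
        dh_values=tuple(dhs),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_titration_csv(series: TitrationSeries, path) -> None:
    """Write a titration to CSV (schema: injection,volume_L,heat_ucal).

    Schedule metadata travel as '#'-prefixed header lines so the file
    round-trips through :func:`read_titration_csv`.
    """
    s = series.schedule
    meta = {
        "cell_volume_L": s.cell_volume,
        "cell_conc_M": s.cell_conc,
        "syringe_conc_M": s.syringe_conc,
        "temperature_K": s.temperature,
        "interval_s": s.interval_s,
        "label": series.label,
        "is_blank": int(series.is_blank),
    }
    buf = io.StringIO()
    for k, v in meta.items():
        buf.write(f"# {k}={v}\n")
    pd.DataFrame({
        "injection": np.arange(1, s.n_injections + 1),
        "volume_L": s.injection_volumes,
        "heat_ucal": series.heats,
    }).to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_titration_csv(path) -> TitrationSeries:
    """Read a titration written by :func:`write_titration_csv`."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").rstrip("\n").partition("=")
            meta[key] = val
    df = pd.read_csv(path, comment="#")
    for col in ("injection", "volume_L", "heat_ucal"):
        if col not in df.columns:
            raise ValueError(f"titration CSV missing column {col!r}")
    schedule = InjectionSchedule(
        cell_volume=float(meta["cell_volume_L"]),
        cell_conc=float(meta["cell_conc_M"]),
        syringe_conc=float(meta["syringe_conc_M"]),
        injection_volumes=tuple(df["volume_L"].to_numpy(dtype=float)),
        temperature=float(meta.get("temperature_K", T_REF)),
        interval_s=float(meta.get("interval_s", 180.0)),
    )
    return TitrationSeries(
        schedule=schedule,
        heats=df["heat_ucal"].to_numpy(dtype=float),
        label=meta.get("label", ""),
        is_blank=bool(int(meta.get("is_blank", "0"))),
    )


def fit_to_json(fit: BindingFit, ndigits_energy: int = 1) -> str:
    """Serialise a fit with both full-precision and table-rounded views."""
    full = {
        "n_sites": fit.n_sites, "kd_M": fit.kd, "dh_kcal_mol": fit.dh,
        "dg_kcal_mol": fit.dg, "tds_neg_kcal_mol": fit.tds_neg,
        "efficiency_pct": fit.efficiency, "temperature_K": fit.temperature,
        "fit_rmse_ucal": fit.fit_rmse, "c_value": fit.c_value,
        "n_fixed": fit.n_fixed, "label": fit.label,
    }
    rounded = {
        "n_sites": round(fit.n_sites, 1),
        "kd_uM": float(f"{fit.kd_uM:.2g}"),
        "dh_kcal_mol": round(fit.dh, ndigits_energy),
        "dg_kcal_mol": round(fit.dg, ndigits_energy),
        "tds_neg_kcal_mol": round(fit.tds_neg, ndigits_energy),
        "efficiency_pct": round(fit.efficiency),
    }
    return json.dumps({"full": full, "rounded": rounded}, indent=2)
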