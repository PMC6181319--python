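"""Two-state DSC: excess heat capacity model, fitting, and T_m shifts.

A differential scanning calorimeter records the excess molar heat capacity
of a protein solution as it is heated through unfolding. For a reversible
two-state transition N <-> U with van't Hoff enthalpy dH_vH and midpoint
T_m, the unfolding equilibrium constant is

    K(T) = exp[-(dH_vH/R) * (1/T - 1/T_m)]

and the excess heat capacity is the temperature derivative of the unfolded
fraction times dH_vH:

    Cp_ex(T) = (dH_vH^2 / (R T^2)) * K / (1 + K)^2,

which peaks at T = T_m with height dH_vH^2/(4 R T_m^2) and integrates to
dH_vH. Ligand binding stabilises the folded state and shifts T_m upward;
delta_tm reports that shift against an apo reference.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .itc import R_KCAL

__all__ = [
    "DscScan",
    "DscFit",
    "UnstableFitError",
    "two_state_cp",
    "fit_two_state",
    "delta_tm",
    "write_dsc_csv",
    "read_dsc_csv",
]


class UnstableFitError(RuntimeError):
    """The scan does not bracket a transition the two-state model can fit."""


@dataclass
class DscScan:
    """One thermogram: ascending temperature grid (K) and Cp (kcal/mol/K)."""

    temperatures: np.ndarray
    cp: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.temperatures.shape != self.cp.shape:
            raise ValueError("temperature and Cp grids differ in length")
        if self.temperatures.ndim != 1 or self.temperatures.size < 2:
            raise ValueError("need a 1-D grid of >=2 temperatures")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperature grid must be strictly increasing")


@dataclass
class DscFit:
    """Fitted two-state parameters."""

    tm: float                     # K
    dh_vh: float                  # kcal/mol
    baseline: tuple[float, float]  # intercept, slope of linear baseline
    fit_rmse: float
    label: str = ""


def two_state_cp(temperature, tm: float, dh_vh: float):
    """Excess heat capacity (kcal/mol/K) of a two-state transition.

    Vectorised over `temperature`. Maximum at T = T_m with value
    dH_vH^2/(4 R T_m^2).
    """
    if tm <= 0 or dh_vh <= 0:
        raise ValueError("tm and dh_vh must be positive")
    t = np.asarray(temperature, dtype=float)
    # K/(1+K)^2 written via the logistic form for overflow safety
    lnk = -(dh_vh / R_KCAL) * (1.0 / t - 1.0 / tm)
    sech_half = 1.0 / np.cosh(lnk / 2.0)       # K/(1+K)^2 = sech^2(lnK/2)/4
    out = (dh_vh ** 2 / (R_KCAL * t ** 2)) * (sech_half ** 2) / 4.0
    return out if out.shape else float(out)


def fit_two_state(scan: DscScan, edge_margin: int = 3) -> DscFit:
    """Least-squares fit of (T_m, dH_vH) plus a shared linear baseline.

    The transition peak must lie in the grid interior; fits are
    multi-started at the empirical peak temperature and +/- 5 K around it.
    Raises :class:`UnstableFitError` when the apparent peak sits at the grid
    edge or the scan has no transition-shaped signal.
    """
    t, cp = scan.temperatures, scan.cp
    # empirical peak after removing a straight line through the endpoints
    straight = np.interp(t, [t[0], t[-1]], [cp[0], cp[-1]])
    excess = cp - straight
    i_peak = int(np.argmax(excess))
    if i_peak < edge_margin or i_peak >= len(t) - edge_margin:
        raise UnstableFitError(
            "transition peak at the edge of the scan; extend the grid"
        )
    peak_height = excess[i_peak]
    noise_scale = np.std(np.diff(excess)) / np.sqrt(2.0) + 1e-12
    if peak_height < 5.0 * noise_scale:
        raise UnstableFitError("no transition detected above noise")

    tm0 = t[i_peak]
    dh0 = max(np.sqrt(max(peak_height, 1e-6) * 4.0 * R_KCAL * tm0 ** 2), 10.0)

    def resid(x):
        tm, dh_vh, b0, b1 = x
        return two_state_cp(t, tm, dh_vh) + b0 + b1 * (t - t[0]) - cp

    best, best_cost = None, np.inf
    for tm_start in (tm0, tm0 - 5.0, tm0 + 5.0):
        sol = optimize.least_squares(
            resid,
            [tm_start, dh0, cp[0], 0.0],
            bounds=([t[0], 1.0, -np.inf, -np.inf],
                    [t[-1], 5000.0, np.inf, np.inf]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if sol.cost < best_cost:
            best, best_cost = sol, sol.cost

    tm, dh_vh, b0, b1 = best.x
    return DscFit(
        tm=float(tm),
        dh_vh=float(dh_vh),
        baseline=(float(b0), float(b1)),
        fit_rmse=float(np.sqrt(np.mean(best.fun ** 2))),
        label=scan.label,
    )


def delta_tm(fit_apo: DscFit, fit_complex: DscFit) -> float:
    """Ligand-induced melting-temperature shift, T_m(complex) - T_m(apo)."""
    return fit_complex.tm - fit_apo.tm


def write_dsc_csv(scan: DscScan, path) -> None:
    """Write a thermogram to CSV (schema: temperature_K,cp_kcal_mol_K)."""
    buf = io.StringIO()
    buf.write(f"# label={scan.label}\n")
    pd.DataFrame({
        "temperature_K": scan.temperatures,
        "cp_kcal_mol_K": scan.cp,
    }).to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_dsc_csv(path) -> DscScan:
    """Read a thermogram written by :func:`write_dsc_csv`."""
    label = ""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "label=" in line:
                label = line.split("label=", 1)[1].strip()
    df = pd.read_csv(path, comment="#")
    for col in ("temperature_K", "cp_kcal_mol_K"):
        if col not in df.columns:
            raise ValueError(f"DSC CSV missing column {col!r}")
    return DscScan(
        temperatures=df["temperature_K"].to_numpy(dtype=float),
        cp=df["cp_kcal_mol_K"].to_numpy(dtype=float),
        label=label,
    )
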