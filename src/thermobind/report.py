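"""Study tables, consistency audits, and thermodynamics-structure correlation.

Binding tables in the calorimetry literature round energies to one decimal
(half away from zero), report K_D in uM, and quote the enthalpic
efficiency 100*dH/dG as an integer percentage. `audit_row` re-derives the
internal identities of such a row — dG = dH + (-TdS) and dG = RT ln K_D —
at the one-decimal tolerance and flags rows that fail, which catches
transcription errors (the packaged reference table contains exactly one,
in its tightest-binding methylated compound). `build_report` merges
thermodynamic results with per-compound interface metrics and reports the
Pearson correlations of dG against interface score, buried surface area,
and shape complementarity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .itc import R_KCAL, T_REF, BindingFit, ReplicateSummary
from .reference import ReferenceRow
from .synth import CompoundMetrics, GroundTruth

__all__ = [
    "StudyTable",
    "CorrelationEntry",
    "CorrelationReport",
    "round_half_away",
    "pearson_r",
    "audit_row",
    "build_report",
]

#: one-decimal tolerance on kcal/mol identities
ENERGY_TOL = 0.15
#: tolerance on the integer efficiency column, percent points
EFFICIENCY_TOL = 1.0


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (table convention, not banker's)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def pearson_r(x, y) -> float:
    """Sample Pearson correlation of two equal-length sequences (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def audit_row(row: ReferenceRow, temperature: float = T_REF) -> list[str]:
    """Check a table row's internal thermodynamic identities.

    Returns human-readable findings; an empty list means the row is
    self-consistent at printed precision (+/-0.15 kcal/mol on energies,
    +/-1 point on the integer efficiency).
    """
    findings = []
    additivity = row.dh + row.tds_neg
    if abs(additivity - row.dg) > ENERGY_TOL:
        findings.append(
            f"{row.compound}: dH + (-TdS) = {additivity:+.1f} differs from "
            f"printed dG = {row.dg:+.1f} kcal/mol"
        )
    dg_from_kd = R_KCAL * temperature * math.log(row.kd_molar)
    if abs(dg_from_kd - row.dg) > ENERGY_TOL:
        findings.append(
            f"{row.compound}: RT ln K_D = {dg_from_kd:+.2f} differs from "
            f"printed dG = {row.dg:+.1f} kcal/mol"
        )
    if row.efficiency_pct is not None:
        eff = 100.0 * row.dh / row.dg
        if abs(round_half_away(eff) - row.efficiency_pct) > EFFICIENCY_TOL:
            findings.append(
                f"{row.compound}: 100*dH/dG = {eff:.1f}% differs from "
                f"printed {row.efficiency_pct}%"
            )
    return findings


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class CorrelationEntry:
    pair: str
    r: float      # reported to 2 decimals
    n: int


@dataclass
class CorrelationReport:
    entries: list[CorrelationEntry]

    def as_dict(self) -> dict[str, float]:
        return {e.pair: e.r for e in self.entries}


@dataclass
class StudyTable:
    """Rounded per-compound table plus the full-precision frame."""

    table: pd.DataFrame        # rounded, publication-style
    full: pd.DataFrame         # unrounded


def _thermo_dict(obj) -> dict[str, float]:
    """Normalise a thermodynamics carrier to a plain parameter dict."""
    if isinstance(obj, BindingFit):
        return {"n_sites": obj.n_sites, "kd_uM": obj.kd_uM, "dh": obj.dh,
                "tds_neg": obj.tds_neg, "dg": obj.dg,
                "efficiency": obj.efficiency}
    if isinstance(obj, ReplicateSummary):
        m = obj.mean
        return {"n_sites": m["n_sites"], "kd_uM": m["kd"] * 1e6,
                "dh": m["dh"], "tds_neg": m["tds_neg"], "dg": m["dg"],
                "efficiency": m["efficiency"]}
    if isinstance(obj, ReferenceRow):
        return {"n_sites": obj.n_sites, "kd_uM": obj.kd_uM, "dh": obj.dh,
                "tds_neg": obj.tds_neg, "dg": obj.dg,
                "efficiency": (float(obj.efficiency_pct)
                               if obj.efficiency_pct is not None
                               else 100.0 * obj.dh / obj.dg)}
    if isinstance(obj, GroundTruth):
        from .itc import derive_thermodynamics
        dg, tds_neg, eff = derive_thermodynamics(obj.kd, obj.dh)
        return {"n_sites": obj.n_sites, "kd_uM": obj.kd * 1e6, "dh": obj.dh,
                "tds_neg": tds_neg, "dg": dg, "efficiency": eff}
    raise TypeError(f"cannot extract thermodynamics from {type(obj)!r}")


_CORRELATION_PAIRS = (
    ("dG_vs_interface_score", "score_topk"),
    ("dG_vs_BSA", "bsa"),
    ("dG_vs_Sc", "sc"),
)


def build_report(
    thermo: dict[str, object],
    metrics: dict[str, CompoundMetrics] | None = None,
) -> tuple[StudyTable, CorrelationReport]:
    """Merge thermodynamic and structural results per compound.

    `thermo` maps compound id to a BindingFit, ReplicateSummary,
    ReferenceRow or GroundTruth; `metrics` (optional) maps compound id to
    its interface metrics. The rounded table follows the publication
    conventions (energies to one decimal half-away-from-zero, integer
    efficiency). Pearson correlations of dG against the interface score,
    BSA, and Sc are computed over compounds carrying both kinds of data;
    with fewer than three such compounds the correlations are skipped with
    a warning.
    """
    rows_full, rows_rounded = [], []
    for compound, carrier in thermo.items():
        d = _thermo_dict(carrier)
        met = metrics.get(compound) if metrics else None
        full = {"compound": compound, **d}
        if met is not None:
            full.update(bsa=met.bsa, sc=met.sc, score_topk=met.score_topk)
        rows_full.append(full)
        rows_rounded.append({
            "compound": compound,
            "N": round_half_away(d["n_sites"], 1),
            "K_D_uM": float(f"{d['kd_uM']:.2g}"),
            "dH_kcal_mol": round_half_away(d["dh"], 1),
            "-TdS_kcal_mol": round_half_away(d["tds_neg"], 1),
            "dG_kcal_mol": round_half_away(d["dg"], 1),
            "dH/dG_pct": int(round_half_away(d["efficiency"])),
        })
    table = StudyTable(
        table=pd.DataFrame(rows_rounded).set_index("compound"),
        full=pd.DataFrame(rows_full).set_index("compound"),
    )

    entries: list[CorrelationEntry] = []
    if metrics:
        shared = [c for c in thermo if c in metrics]
        if len(shared) < 3:
            warnings.warn(
                "fewer than 3 compounds with both thermodynamic and "
                "structural data: correlations skipped",
                stacklevel=2,
            )
        else:
            dg = [_thermo_dict(thermo[c])["dg"] for c in shared]
            for pair_name, attr in _CORRELATION_PAIRS:
                vals = [getattr(metrics[c], attr) for c in shared]
                r = pearson_r(dg, vals)
                entries.append(CorrelationEntry(
                    pair=pair_name, r=round(r, 2), n=len(shared)))
    return table, CorrelationReport(entries=entries)
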