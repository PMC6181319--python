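"""Published thermodynamic parameters for HSA-catechin binding.

The packaged table holds the reported single-site ITC parameters (mean +/- SD
over at least three titrations at 298 K) for eight catechins, ethyl gallate,
and four O-methylated EGCg derivatives binding to human serum albumin.
Gallated catechins (EGCg, ECg, GCg, Cg) carry the galloyl ester on the C ring;
the "-O-Me" entries are EGCg with a single methoxy substitution either on the
B ring (3'/4') or on the galloyl group (3''/4'').

Units follow calorimetric convention: K_D in uM as printed, energies in
kcal/mol, efficiency = 100*dH/dG in percent (only reported for the first
table's compounds). The table is shipped verbatim, including its known
internal inconsistency in the EGCg-3''-O-Me row (dH + (-TdS) != dG), which
the report module's audit is expected to flag rather than repair.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ReferenceRow", "REFERENCE_TABLE", "reference_row", "GALLATED"]


@dataclass(frozen=True)
class ReferenceRow:
    """One compound's published binding parameters (mean and SD)."""

    compound: str
    n_sites: float
    n_sd: float | None          # None where N was fixed to 1
    kd_uM: float
    kd_sd_uM: float
    dh: float                   # kcal/mol
    dh_sd: float
    tds_neg: float              # -T*dS, kcal/mol
    tds_sd: float
    dg: float                   # kcal/mol
    dg_sd: float
    efficiency_pct: int | None  # 100*dH/dG rounded to integer, where reported
    n_fixed: bool = False

    @property
    def kd_molar(self) -> float:
        return self.kd_uM * 1e-6


REFERENCE_TABLE: tuple[ReferenceRow, ...] = (
    # catechins and ethyl gallate
    ReferenceRow("EGCg", 1.1, 0.1, 2.2, 0.3, -4.7, 0.6, -3.0, 0.6, -7.7, 0.1, 61),
    ReferenceRow("ECg", 1.0, 0.1, 1.1, 0.1, -5.1, 0.5, -3.1, 0.5, -8.1, 0.1, 63),
    ReferenceRow("GCg", 1.2, 0.2, 8.8, 3.4, -3.0, 0.1, -3.9, 0.3, -6.9, 0.2, 43),
    ReferenceRow("Cg", 1.0, 0.1, 3.5, 0.5, -2.8, 0.6, -4.6, 0.7, -7.4, 0.1, 38),
    ReferenceRow("EGC", 1.0, 0.2, 20.0, 16.0, -0.6, 0.4, -5.8, 0.7, -6.3, 0.4, 10),
    ReferenceRow("EC", 1.0, None, 49.0, 18.0, -0.8, 0.2, -5.1, 0.4, -5.8, 0.2, 13,
                 n_fixed=True),
    ReferenceRow("GC", 1.0, None, 52.0, 16.0, -1.1, 0.5, -4.7, 0.7, -5.8, 0.2, 19,
                 n_fixed=True),
    ReferenceRow("C", 1.0, 0.2, 5.0, 8.6, -0.3, 0.1, -6.8, 0.7, -7.1, 0.6, 4),
    ReferenceRow("EtGa", 1.0, None, 46.0, 23.0, -1.4, 0.1, -4.5, 0.4, -5.9, 0.3, 24,
                 n_fixed=True),
    # methylated EGCg derivatives (no efficiency column reported)
    ReferenceRow("EGCg-3'-O-Me", 0.9, 0.1, 1.6, 0.2, -9.3, 0.4, 1.4, 0.3,
                 -7.9, 0.1, None),
    ReferenceRow("EGCg-4'-O-Me", 0.9, 0.1, 1.7, 0.1, -7.0, 0.1, -0.8, 0.1,
                 -7.9, 0.1, None),
    ReferenceRow("EGCg-3''-O-Me", 1.0, 0.1, 0.14, 0.02, -7.9, 0.9, 1.4, 0.9,
                 -9.4, 0.1, None),
    ReferenceRow("EGCg-4''-O-Me", 1.0, 0.1, 1.0, 0.1, -9.8, 0.1, 1.6, 0.1,
                 -8.2, 0.1, None),
)

#: compounds bearing the galloyl ester
GALLATED = frozenset(
    {"EGCg", "ECg", "GCg", "Cg",
     "EGCg-3'-O-Me", "EGCg-4'-O-Me", "EGCg-3''-O-Me", "EGCg-4''-O-Me"}
)

_BY_NAME = {row.compound: row for row in REFERENCE_TABLE}


def reference_row(compound: str) -> ReferenceRow:
    """Look up a compound's published row by name.

    Raises
    ------
    KeyError
        If the compound is not in the packaged table.
    """
    try:
        return _BY_NAME[compound]
    except KeyError:
        raise KeyError(
            f"unknown compound {compound!r}; known: {sorted(_BY_NAME)}"
        ) from None
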