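"""Competitive-displacement ITC: two-ligand equilibrium and inhibition rate.

A site marker A (warfarin for site I of albumin) is titrated into receptor
that is either free or pre-loaded with a test ligand B. If A and B share
the site, pre-loading suppresses the heat of the A titration; the assay
statistic compares the total integrated heats of the two arms:

    inhibition (%) = 100 - 100 * dQ(complex arm) / dQ(free arm).

The forward model solves the exact two-ligand competitive mass-action
equilibrium at every injection (monotone bisection on the free receptor
concentration) and converts changes in bound amounts to heat. The heat of
the displaced ligand B is physically present and included by default; it
can be switched off to mimic an analysis that attributes all heat to A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .itc import (
    KCAL_TO_UCAL,
    InjectionSchedule,
    TitrationSeries,
    effective_concentrations,
)

__all__ = [
    "CompetitionSetup",
    "DisplacementResult",
    "competitive_equilibrium",
    "total_heat",
    "inhibition_rate",
    "simulate_displacement",
]


@dataclass(frozen=True)
class CompetitionSetup:
    """One displacement experiment.

    Titrant A (the site marker) is injected into a cell containing the
    receptor pre-mixed with competitor B. Concentrations are molar,
    enthalpies kcal/mol.
    """

    receptor_total: float
    ligand_b_total: float
    kd_a: float
    kd_b: float
    dh_a: float
    dh_b: float
    schedule: InjectionSchedule
    include_displaced_heat: bool = True

    def __post_init__(self):
        if self.receptor_total < 0 or self.ligand_b_total < 0:
            raise ValueError("totals must be non-negative")
        if self.kd_a <= 0 or self.kd_b <= 0:
            raise ValueError("dissociation constants must be positive")


@dataclass
class DisplacementResult:
    """Total heats of both assay arms and the derived inhibition rate."""

    dq_complex: float       # ucal, arm with competitor pre-loaded
    dq_free: float          # ucal, receptor-only arm
    inhibition_pct: float


def competitive_equilibrium(
    receptor_total: float,
    a_total: float,
    b_total: float,
    kd_a: float,
    kd_b: float,
    rtol: float = 1e-12,
) -> tuple[float, float, float]:
    """Exact equilibrium of two ligands competing for one site.

    Solves M_f * (1 + [A]_f/K_A + [B]_f/K_B) = M_t by bisection on the free
    receptor concentration M_f, with [A]_f = A_t/(1 + M_f/K_A) and likewise
    for B (both exact consequences of their mass balances). The bracketing
    function is strictly increasing in M_f, so bisection always converges.

    Returns (free_receptor, bound_a, bound_b), all molar. Mass conservation
    holds to the solver tolerance.
    """
    if receptor_total < 0 or a_total < 0 or b_total < 0:
        raise ValueError("totals must be non-negative")
    if kd_a <= 0 or kd_b <= 0:
        raise ValueError("dissociation constants must be positive")
    if receptor_total == 0:
        return 0.0, 0.0, 0.0

    def occupancy_excess(m_f: float) -> float:
        a_f = a_total / (1.0 + m_f / kd_a)
        b_f = b_total / (1.0 + m_f / kd_b)
        return m_f * (1.0 + a_f / kd_a + b_f / kd_b) - receptor_total

    lo, hi = 0.0, receptor_total
    # occupancy_excess(0) = -M_t < 0, occupancy_excess(M_t) >= 0: bracketed.
    # Iterate to floating-point convergence: a loose interval on M_f gets
    # amplified into the bound concentrations when one K_D is very small.
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mid == lo or mid == hi:
            break
        if occupancy_excess(mid) < 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= rtol * max(lo, 1e-300):
            break
    m_f = 0.5 * (lo + hi)
    a_f = a_total / (1.0 + m_f / kd_a)
    b_f = b_total / (1.0 + m_f / kd_b)
    bound_a = m_f * a_f / kd_a
    bound_b = m_f * b_f / kd_b
    return m_f, bound_a, bound_b


def total_heat(series: TitrationSeries) -> float:
    """Total integrated heat dQ of a titration, ucal."""
    return series.total_heat()


def inhibition_rate(dq_complex: float, dq_free: float) -> float:
    """Binding-inhibition rate (%) from the two assay arms' total heats."""
    if dq_free == 0:
        raise ValueError("dQ of the receptor-only arm is zero: rate undefined")
    return 100.0 - 100.0 * dq_complex / dq_free


def _displacement_heats(setup: CompetitionSetup) -> np.ndarray:
    """Per-injection heats (ucal) of titrating A into receptor + B."""
    schedule = setup.schedule
    v0 = schedule.cell_volume
    m_t, a_t = effective_concentrations(schedule)
    # competitor B sits in the cell from the start and dilutes like the
    # receptor does
    b_scale = m_t / schedule.cell_conc
    b_t = setup.ligand_b_total * b_scale
    r_t = setup.receptor_total * b_scale

    # state before the first injection
    _, bound_a_prev, bound_b_prev = competitive_equilibrium(
        setup.receptor_total, 0.0, setup.ligand_b_total,
        setup.kd_a, setup.kd_b,
    )
    q_prev = 0.0
    dv = np.asarray(schedule.injection_volumes)
    heats = np.empty(schedule.n_injections)
    q_cum_a = 0.0
    q_cum_b = 0.0
    for i in range(schedule.n_injections):
        _, bound_a, bound_b = competitive_equilibrium(
            r_t[i], a_t[i], b_t[i], setup.kd_a, setup.kd_b
        )
        q_cum_a += setup.dh_a * (bound_a - bound_a_prev) * v0 * KCAL_TO_UCAL
        q_cum_b += setup.dh_b * (bound_b - bound_b_prev) * v0 * KCAL_TO_UCAL
        q = q_cum_a + (q_cum_b if setup.include_displaced_heat else 0.0)
        heats[i] = q - q_prev + (dv[i] / v0) * (q + q_prev) / 2.0
        q_prev = q
        bound_a_prev, bound_b_prev = bound_a, bound_b
    return heats


def simulate_displacement(
    setup: CompetitionSetup,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[TitrationSeries, DisplacementResult]:
    """Simulate both arms of the displacement assay.

    Returns the competitor-arm titration series and a
    :class:`DisplacementResult` whose free arm re-runs the identical
    schedule with no competitor. Optional Gaussian noise (ucal, seeded) is
    added to the competitor-arm heats only after the noiseless totals are
    taken, mirroring how the assay statistic uses integrated heats.
    """
    heats_complex = _displacement_heats(setup)
    free_setup = CompetitionSetup(
        receptor_total=setup.receptor_total,
        ligand_b_total=0.0,
        kd_a=setup.kd_a,
        kd_b=setup.kd_b,
        dh_a=setup.dh_a,
        dh_b=setup.dh_b,
        schedule=setup.schedule,
        include_displaced_heat=setup.include_displaced_heat,
    )
    heats_free = _displacement_heats(free_setup)

    dq_complex = float(np.sum(heats_complex))
    dq_free = float(np.sum(heats_free))
    result = DisplacementResult(
        dq_complex=dq_complex,
        dq_free=dq_free,
        inhibition_pct=inhibition_rate(dq_complex, dq_free),
    )
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        heats_complex = heats_complex + rng.normal(0.0, noise_sd,
                                                   heats_complex.size)
    series = TitrationSeries(
        schedule=setup.schedule, heats=heats_complex, label="displacement"
    )
    return series, result
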