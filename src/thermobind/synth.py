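"""Synthetic study generator: every input the pipeline consumes.

The generators emulate a small-molecule binding study on a serum-albumin-
like receptor: perfusion-calorimeter titrations (50 uM cell, 500 uM
syringe, 28 x 10 uL injections at 298.15 K) with additive Gaussian heat
noise, blank (ligand-into-buffer) dilution titrations, capillary-DSC scans
over 303-363 K, and toy protein-ligand complexes with exactly known
interface geometry. The default ground-truth set is the packaged
13-compound reference table, so parameter-recovery tests run against the
study's own printed conditions.

The toy complex is built from spheres: a large central ligand sphere
cradled by a concave shell of receptor "pocket" atoms whose solvent-
expanded spheres are pairwise disjoint. Disjointness means no point is
buried by two receptor atoms at once, so the ground-truth buried surface
area is the exact sum of pairwise spherical-cap areas — an analytic oracle
for the Shrake-Rupley implementation. Optional hydrogen-bond probe atoms
are tucked inside the ligand's expanded envelope where they cannot perturb
any surface, so planted bond counts stay exact too.

All randomness flows from explicit integer seeds; no global state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import reference
from .dsc import DscScan, two_state_cp
from .itc import (
    InjectionSchedule,
    TitrationSeries,
    default_schedule,
    derive_thermodynamics,
    simulate_isotherm,
)
from .structure import Structure

__all__ = [
    "GroundTruth",
    "NoiseModel",
    "ToyComplexTruth",
    "CompoundMetrics",
    "StudyBundle",
    "make_default_truth",
    "synth_titration",
    "synth_blank",
    "synth_dsc",
    "synth_toy_complex",
    "synth_interface_metrics",
    "synth_study",
]


@dataclass(frozen=True)
class GroundTruth:
    """True binding parameters of one synthetic compound."""

    compound_id: str
    n_sites: float
    kd: float          # molar
    dh: float          # kcal/mol
    dcp: float = -150.0   # cal mol^-1 K^-1
    tm_shift: float = 0.0  # K, DSC melting shift vs apo

    def __post_init__(self):
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Additive i.i.d. Gaussian heat noise per injection."""

    heat_sd: float = 0.2   # ucal, typical perfusion-ITC baseline noise
    seed: int | None = None

    def __post_init__(self):
        if self.heat_sd < 0:
            raise ValueError("heat_sd must be non-negative")


#: measured binding heat-capacity changes where available (cal/mol/K)
_KNOWN_DCP = {"EGCg": -148.0, "EGCg-3''-O-Me": -195.0}


def _default_tm_shift(kd: float) -> float:
    """Synthetic affinity-correlated melting shift: 0 K at K_D = 100 uM,
    ~1.5 K per decade of affinity gain."""
    return max(0.0, 1.5 * math.log10(100e-6 / kd))


def make_default_truth() -> list[GroundTruth]:
    """The 13-compound study truth set from the packaged reference table.

    K_D is converted to molar; heat-capacity changes use the two measured
    values where reported and a generic -150 cal/mol/K otherwise; melting
    shifts are synthetic, increasing with affinity.
    """
    out = []
    for row in reference.REFERENCE_TABLE:
        kd = row.kd_molar
        out.append(GroundTruth(
            compound_id=row.compound,
            n_sites=row.n_sites,
            kd=kd,
            dh=row.dh,
            dcp=_KNOWN_DCP.get(row.compound, -150.0),
            tm_shift=_default_tm_shift(kd),
        ))
    return out


def synth_titration(truth: GroundTruth, schedule: InjectionSchedule,
                    noise: NoiseModel = NoiseModel()) -> TitrationSeries:
    """Noisy one-site titration: forward model plus Gaussian heat noise.

    The same seed reproduces the same series bit-for-bit.
    """
    series = simulate_isotherm(truth.n_sites, truth.kd, truth.dh, schedule,
                               label=truth.compound_id)
    if noise.heat_sd > 0:
        rng = np.random.default_rng(noise.seed)
        series.heats = series.heats + rng.normal(
            0.0, noise.heat_sd, series.heats.size)
    return series


def synth_blank(schedule: InjectionSchedule,
                dilution_heat_per_injection: float = 0.0,
                noise: NoiseModel = NoiseModel()) -> TitrationSeries:
    """Blank (titrant-into-buffer) run: constant dilution heat plus noise."""
    heats = np.full(schedule.n_injections, float(dilution_heat_per_injection))
    if noise.heat_sd > 0:
        rng = np.random.default_rng(noise.seed)
        heats = heats + rng.normal(0.0, noise.heat_sd, heats.size)
    return TitrationSeries(schedule=schedule, heats=heats, label="blank",
                           is_blank=True)


def synth_dsc(tm: float, dh_vh: float,
              baseline: tuple[float, ...] = (),
              grid: tuple[float, float, float] = (303.0, 363.0, 0.1),
              noise_sd: float = 0.0, seed: int | None = None,
              label: str = "") -> DscScan:
    """Synthetic thermogram: two-state excess Cp + polynomial baseline + noise.

    `baseline` holds ascending polynomial coefficients in (T - T_start);
    `grid` is (start K, stop K, step K). A transition midpoint outside the
    grid is allowed but flagged with a warning because the subsequent fit
    will be unstable.
    """
    t0, t1, dt = grid
    t = np.arange(t0, t1 + dt / 2, dt)
    if not (t[0] < tm < t[-1]):
        warnings.warn(
            f"T_m = {tm} K lies outside the scan grid [{t[0]}, {t[-1]}]; "
            "the fit will be unstable",
            stacklevel=2,
        )
    cp = two_state_cp(t, tm, dh_vh)
    if baseline:
        cp = cp + np.polynomial.polynomial.polyval(t - t[0], baseline)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cp = cp + rng.normal(0.0, noise_sd, cp.size)
    return DscScan(temperatures=t, cp=cp, label=label)


# ---------------------------------------------------------------------------
# toy complexes
# ---------------------------------------------------------------------------

@dataclass
class ToyComplexTruth:
    """Exact ground truth recorded at generation time."""

    site_center: np.ndarray
    true_ligand_coords: np.ndarray
    contact_pairs: list[tuple[int, int]]   # (receptor idx, ligand idx)
    bsa_analytic: float | None             # A^2; None for the dense pocket
    n_hbond_pairs: int
    hbond_pairs: list[tuple[int, int]]     # (receptor donor, ligand acceptor)


_LIG_R = 3.5      # central ligand sphere radius, A
_POCKET_R = 1.7   # pocket atom radius, A
_SAT_R = 1.0      # satellite radius (buried; shapes the RMSD only)
_PROBE_R = 0.8    # hydrogen-bond probe radius (buried)
_HB_DIST = 2.9    # planted donor-acceptor distance, A


def _cap_pair_bsa(r1: float, r2: float, d: float) -> float:
    """Buried area (both caps) of two overlapping spheres of radii r1, r2."""
    if d >= r1 + r2:
        return 0.0
    x1 = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    x2 = (d * d + r2 * r2 - r1 * r1) / (2.0 * d)
    return 2.0 * math.pi * (r1 * (r1 - x1) + r2 * (r2 - x2))


def synth_toy_complex(
    pocket_depth: float = 0.0,
    n_pocket_atoms: int = 5,
    ligand_shape: str = "cluster",
    seed: int | None = None,
    n_hbond_pairs: int = 0,
    surface_overlap: float | None = None,
    probe: float = 1.4,
    pocket_style: str = "sparse",
) -> tuple[Structure, Structure, ToyComplexTruth]:
    """Build a concave receptor pocket mated with a compact ligand.

    Parameters
    ----------
    pocket_depth : float
        Extra displacement of the pocket shell toward the ligand (A); 0
        places every pocket atom at the contact distance set by
        `surface_overlap`.
    n_pocket_atoms : int
        2..5 pocket atoms (one at the pocket bottom plus a ring); five is
        the most that keeps the solvent-expanded spheres pairwise disjoint,
        which the analytic BSA oracle requires. Ignored for the dense
        pocket style.
    ligand_shape : str
        "sphere" (single central atom) or "cluster" (central atom plus
        three buried satellites that make rotations visible to RMSD).
    n_hbond_pairs : int
        Planted donor-acceptor pairs at 2.9 A; probe atoms sit inside the
        ligand's expanded envelope so surface areas are untouched. Sparse
        style only.
    surface_overlap : float
        Overlap of the solvent-expanded surfaces (A). The sparse default
        2.8 (= two probe radii) corresponds to van-der-Waals contact,
        which is also the Lennard-Jones optimum used by the pose-recovery
        study. For the dense style the default is -0.25: a 0.25 A gap
        between the concave shell envelope and the ligand surface, the
        regime where dot surfaces measure shape complementarity cleanly.
    pocket_style : str
        "sparse": few beads with pairwise-disjoint expanded spheres — the
        exact analytic-BSA oracle. "dense": ~100 overlapping beads on a
        hemispheric shell whose inner envelope is a concave sphere mating
        the ligand's curvature — a genuinely complementary surface for Sc
        (no analytic BSA; `truth.bsa_analytic` is None).

    Returns (receptor, ligand, truth). The construction is verified at
    generation time (disjoint receptor spheres, no hard clashes in the
    ground-truth pose) and regenerated with a derived seed on the rare
    jitter draw that violates it.
    """
    if pocket_style == "dense":
        if n_hbond_pairs:
            raise ValueError("hydrogen-bond probes need the sparse pocket")
        return _dense_toy_complex(
            ligand_shape, seed,
            -0.25 if surface_overlap is None else surface_overlap, probe)
    if pocket_style != "sparse":
        raise ValueError("pocket_style must be 'sparse' or 'dense'")
    if surface_overlap is None:
        surface_overlap = 2.8
    if not 2 <= n_pocket_atoms <= 5:
        raise ValueError("n_pocket_atoms must be in 2..5")
    if n_hbond_pairs > n_pocket_atoms:
        raise ValueError("cannot plant more hydrogen bonds than pocket atoms")
    rl_exp = _LIG_R + probe
    rr_exp = _POCKET_R + probe
    d_contact = rl_exp + rr_exp - surface_overlap - pocket_depth
    if d_contact <= abs(rl_exp - rr_exp):
        raise ValueError("pocket depth/overlap would swallow the pocket atoms")
    if n_hbond_pairs and d_contact > _HB_DIST + _LIG_R - _PROBE_R:
        raise ValueError(
            "hydrogen-bond probes would breach the ligand surface at this "
            "contact distance; use the default surface_overlap"
        )

    rng = np.random.default_rng(seed)
    for _ in range(16):
        phase = rng.uniform(0.0, 2.0 * math.pi)
        # pocket directions: bottom + ring at 76 deg polar angle
        dirs = [np.array([0.0, 0.0, -1.0])]
        n_ring = n_pocket_atoms - 1
        for k in range(n_ring):
            az = phase + 2.0 * math.pi * k / max(n_ring, 1)
            pol = math.radians(76.0)
            dirs.append(np.array([
                math.sin(pol) * math.cos(az),
                math.sin(pol) * math.sin(az),
                -math.cos(pol),
            ]))
        pocket_centers = np.array(dirs) * d_contact

        # receptor expanded spheres must be pairwise disjoint
        ok = True
        for i in range(len(pocket_centers)):
            for j in range(i + 1, len(pocket_centers)):
                if np.linalg.norm(pocket_centers[i] - pocket_centers[j]) \
                        <= 2.0 * rr_exp:
                    ok = False
        if ok:
            break
    else:
        raise RuntimeError("could not place pairwise-disjoint pocket atoms")

    # --- receptor ---
    rec_coords = list(pocket_centers)
    rec_radii = [_POCKET_R] * n_pocket_atoms
    rec_elements = ["N" if i < n_hbond_pairs else "C"
                    for i in range(n_pocket_atoms)]
    rec_donor = np.array([i < n_hbond_pairs for i in range(n_pocket_atoms)])
    rec_charges = np.zeros(n_pocket_atoms)
    rec_charges[0] = -0.25

    receptor = Structure(
        coords=np.array(rec_coords), radii=np.array(rec_radii),
        elements=rec_elements, charges=rec_charges,
        is_donor=rec_donor, is_acceptor=np.zeros(n_pocket_atoms, dtype=bool),
        resnames=["REC"] * n_pocket_atoms, chains=["A"] * n_pocket_atoms,
        label="toy-receptor",
    )

    # --- ligand ---
    (lig_coords, lig_radii, lig_elements,
     lig_charges, lig_acceptor) = _ligand_cluster(rng, ligand_shape)

    hbond_pairs = []
    for k in range(n_hbond_pairs):
        direction = -pocket_centers[k] / np.linalg.norm(pocket_centers[k])
        pos = pocket_centers[k] + _HB_DIST * direction
        hbond_pairs.append((k, len(lig_coords)))
        lig_coords.append(pos)
        lig_radii.append(_PROBE_R)
        lig_elements.append("O")
        lig_charges.append(0.0)
        lig_acceptor.append(True)

    n_lig = len(lig_coords)
    ligand = Structure(
        coords=np.array(lig_coords), radii=np.array(lig_radii),
        elements=lig_elements, charges=np.array(lig_charges),
        is_donor=np.zeros(n_lig, dtype=bool),
        is_acceptor=np.array(lig_acceptor),
        resnames=["LIG"] * n_lig, chains=["B"] * n_lig,
        label="toy-ligand",
    )

    # hard-clash audit of the ground-truth pose (vdW interpenetration)
    for i in range(receptor.n_atoms):
        for j in range(ligand.n_atoms):
            d = np.linalg.norm(receptor.coords[i] - ligand.coords[j])
            limit = 0.55 * (receptor.radii[i] + ligand.radii[j])
            if j == 0 and d < limit:
                raise RuntimeError("ground-truth pose clashes; bad geometry")

    bsa = sum(_cap_pair_bsa(rl_exp, rr_exp, float(np.linalg.norm(c)))
              for c in pocket_centers)
    truth = ToyComplexTruth(
        site_center=np.zeros(3),
        true_ligand_coords=ligand.coords.copy(),
        contact_pairs=[(i, 0) for i in range(n_pocket_atoms)],
        bsa_analytic=bsa,
        n_hbond_pairs=n_hbond_pairs,
        hbond_pairs=hbond_pairs,
    )
    return receptor, ligand, truth


def _ligand_cluster(rng, ligand_shape):
    """Central ligand sphere plus (optionally) three buried satellites."""
    lig_coords = [np.zeros(3)]
    lig_radii = [_LIG_R]
    lig_elements = ["C"]
    lig_charges = [0.25]
    lig_acceptor = [False]
    if ligand_shape == "cluster":
        for _ in range(3):
            v = rng.normal(size=3)
            v[2] = abs(v[2]) + 0.5          # keep satellites in the top half
            v /= np.linalg.norm(v)
            lig_coords.append(0.8 * v)
            lig_radii.append(_SAT_R)
            lig_elements.append("C")
            lig_charges.append(0.0)
            lig_acceptor.append(False)
    elif ligand_shape != "sphere":
        raise ValueError("ligand_shape must be 'sphere' or 'cluster'")
    return lig_coords, lig_radii, lig_elements, lig_charges, lig_acceptor


_DENSE_BEAD_SPACING = 2.0   # A between shell bead centres


def _dense_toy_complex(ligand_shape, seed, surface_overlap, probe):
    """Concave cradle of ~100 overlapping beads mating the ligand sphere.

    Bead centres sit on a hemisphere of radius D = (r_lig + probe) +
    (r_bead + probe) - surface_overlap; because the beads overlap heavily,
    the surviving inner dot surface approximates a concave sphere of
    radius D - (r_bead + probe) whose curvature matches the ligand — a
    genuinely complementary interface. No analytic BSA is available here
    (triple overlaps everywhere), so truth.bsa_analytic is None.
    """
    from .structure import fibonacci_sphere

    rng = np.random.default_rng(seed)
    rl_exp = _LIG_R + probe
    rr_exp = _POCKET_R + probe
    d_shell = rl_exp + rr_exp - surface_overlap
    n = int(4.0 * math.pi * d_shell ** 2 / _DENSE_BEAD_SPACING ** 2)
    dirs = fibonacci_sphere(n)
    dirs = dirs[dirs[:, 2] < 0.0]           # lower hemisphere = the cradle
    n_rec = len(dirs)
    receptor = Structure(
        coords=dirs * d_shell, radii=np.full(n_rec, _POCKET_R),
        elements=["C"] * n_rec, charges=np.zeros(n_rec),
        resnames=["REC"] * n_rec, chains=["A"] * n_rec,
        label="toy-receptor-dense",
    )
    (lig_coords, lig_radii, lig_elements,
     lig_charges, lig_acceptor) = _ligand_cluster(rng, ligand_shape)
    n_lig = len(lig_coords)
    ligand = Structure(
        coords=np.array(lig_coords), radii=np.array(lig_radii),
        elements=lig_elements, charges=np.array(lig_charges),
        is_acceptor=np.array(lig_acceptor),
        resnames=["LIG"] * n_lig, chains=["B"] * n_lig,
        label="toy-ligand",
    )
    truth = ToyComplexTruth(
        site_center=np.zeros(3),
        true_ligand_coords=ligand.coords.copy(),
        contact_pairs=[(i, 0) for i in range(n_rec)],
        bsa_analytic=None,
        n_hbond_pairs=0,
        hbond_pairs=[],
    )
    return receptor, ligand, truth


# ---------------------------------------------------------------------------
# study-level assembly
# ---------------------------------------------------------------------------

@dataclass
class CompoundMetrics:
    """Structure-derived metrics of one compound's modelled complex."""

    bsa: float          # A^2
    sc: float
    score_topk: float   # mean interface score of the 10 best poses


def synth_interface_metrics(
    truths: list[GroundTruth],
    seed: int | None = None,
    bsa_slope: float = -55.0, bsa_intercept: float = 0.0,
    sc_slope: float = -0.05, sc_intercept: float = 0.3,
    score_slope: float = 2.0, score_intercept: float = 0.0,
    noise_frac: float = 0.0,
    temperature: float = 298.15,
) -> dict[str, CompoundMetrics]:
    """Interface metrics linearly tied to each compound's true dG.

    Emulates the empirical pattern that stronger binders bury more surface,
    pack better, and score lower: each metric is slope*dG + intercept plus
    optional fractional Gaussian noise. The injected linearity makes the
    downstream correlation machinery testable with a known answer.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for t in truths:
        dg, _, _ = derive_thermodynamics(t.kd, t.dh, temperature)
        vals = {}
        for name, slope, intercept in (
            ("bsa", bsa_slope, bsa_intercept),
            ("sc", sc_slope, sc_intercept),
            ("score_topk", score_slope, score_intercept),
        ):
            v = slope * dg + intercept
            if noise_frac > 0:
                v += rng.normal(0.0, abs(v) * noise_frac)
            vals[name] = v
        out[t.compound_id] = CompoundMetrics(**vals)
    return out


@dataclass
class StudyBundle:
    """A full synthetic binding study with its generating truth."""

    truths: list[GroundTruth]
    schedule: InjectionSchedule
    titrations: dict[str, list[TitrationSeries]]   # raw, dilution included
    blanks: dict[str, list[TitrationSeries]]
    dsc_apo: DscScan
    dsc_scans: dict[str, DscScan]
    metrics: dict[str, CompoundMetrics]
    apo_tm: float
    dh_vh: float
    seed: int | None = None
    dilution_heat: float = -0.4
    heat_sd: float = 0.2


def synth_study(
    seed: int = 0,
    n_replicates: int = 3,
    heat_sd: float = 0.2,
    dilution_heat: float = -0.4,
    apo_tm: float = 340.0,
    dh_vh: float = 150.0,
    dsc_noise_sd: float = 0.05,
    schedule: InjectionSchedule | None = None,
    truths: list[GroundTruth] | None = None,
) -> StudyBundle:
    """Generate the complete 13-compound synthetic study.

    Per compound: `n_replicates` noisy titrations with a constant dilution
    offset folded in, matched blank runs, and a noisy DSC scan shifted by
    the compound's true tm_shift; plus one apo scan and dG-linked interface
    metrics. Sub-seeds are derived deterministically from `seed`.
    """
    if schedule is None:
        schedule = default_schedule()
    if truths is None:
        truths = make_default_truth()
    root = np.random.default_rng(seed)
    sub = lambda: int(root.integers(0, 2 ** 31 - 1))  # noqa: E731

    titrations: dict[str, list[TitrationSeries]] = {}
    blanks: dict[str, list[TitrationSeries]] = {}
    dsc_scans: dict[str, DscScan] = {}
    for t in truths:
        series_list, blank_list = [], []
        for _ in range(n_replicates):
            s = synth_titration(t, schedule, NoiseModel(heat_sd, sub()))
            s.heats = s.heats + dilution_heat
            series_list.append(s)
            blank_list.append(
                synth_blank(schedule, dilution_heat, NoiseModel(heat_sd, sub()))
            )
        titrations[t.compound_id] = series_list
        blanks[t.compound_id] = blank_list
        dsc_scans[t.compound_id] = synth_dsc(
            apo_tm + t.tm_shift, dh_vh, noise_sd=dsc_noise_sd, seed=sub(),
            label=t.compound_id,
        )
    dsc_apo = synth_dsc(apo_tm, dh_vh, noise_sd=dsc_noise_sd, seed=sub(),
                        label="apo")
    metrics = synth_interface_metrics(truths, seed=sub())
    return StudyBundle(
        truths=truths, schedule=schedule, titrations=titrations,
        blanks=blanks, dsc_apo=dsc_apo, dsc_scans=dsc_scans, metrics=metrics,
        apo_tm=apo_tm, dh_vh=dh_vh, seed=seed,
        dilution_heat=dilution_heat, heat_sd=heat_sd,
    )
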