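"""Interface metrics for protein-ligand complexes.

This module provides the structural quantities used to rationalise binding
thermodynamics:

* solvent-accessible surface area (SASA) by the Shrake-Rupley point-sampling
  construction (quasi-uniform Fibonacci points on probe-expanded spheres);
* buried surface area, BSA = ASA(A) + ASA(B) - ASA(AB);
* shape complementarity Sc in the Lawrence-Colman sense (median of
  normal-alignment scores weighted by a Gaussian of the surface gap),
  evaluated on probe-expanded dot surfaces;
* geometric hydrogen-bond detection (donor-acceptor distance, and the
  D-H...A angle when explicit hydrogens are present);
* a deliberately simple decomposed interface score: screened Coulomb
  electrostatics with a distance-dependent dielectric, a 12-6 Lennard-Jones
  potential split into attractive and capped repulsive parts, and a fixed
  reward per hydrogen bond;
* a rigid-body pose sampler that scores and ranks random ligand placements
  around a binding-site center, with top-k score averaging.

Coordinates are in Angstroms in the PDB right-handed frame. Atomic radii
default to a Bondi-type van der Waals table keyed by element.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import gemmi
import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

__all__ = [
    "VDW_RADII",
    "DEFAULT_RADIUS",
    "Structure",
    "InterfaceMetrics",
    "HBond",
    "Pose",
    "PoseSet",
    "read_pdb",
    "write_pdb",
    "merge",
    "fibonacci_sphere",
    "compute_asa",
    "total_asa",
    "buried_surface_area",
    "dot_surface",
    "sc_from_dots",
    "shape_complementarity",
    "detect_hbonds",
    "interface_score",
    "sample_poses",
    "top_k_mean",
    "rmsd",
]

#: Bondi-type van der Waals radii, Angstrom
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}
DEFAULT_RADIUS = 1.70
DEFAULT_PROBE = 1.4


# ---------------------------------------------------------------------------
# structure container and PDB I/O
# ---------------------------------------------------------------------------

@dataclass
class Structure:
    """A rigid group of atoms with the attributes the metrics need."""

    coords: np.ndarray                 # (n, 3) Angstrom
    radii: np.ndarray                  # (n,) vdW radii
    elements: list[str]
    charges: np.ndarray | None = None  # (n,) partial charges, e
    is_donor: np.ndarray | None = None
    is_acceptor: np.ndarray | None = None
    names: list[str] | None = None
    resnames: list[str] | None = None
    chains: list[str] | None = None
    label: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.radii.shape != (n,):
            raise ValueError("radii length must match coordinates")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")
        if self.charges is None:
            self.charges = np.zeros(n)
        else:
            self.charges = np.asarray(self.charges, dtype=float)
        if self.is_donor is None:
            self.is_donor = np.zeros(n, dtype=bool)
        else:
            self.is_donor = np.asarray(self.is_donor, dtype=bool)
        if self.is_acceptor is None:
            self.is_acceptor = np.zeros(n, dtype=bool)
        else:
            self.is_acceptor = np.asarray(self.is_acceptor, dtype=bool)
        if self.names is None:
            self.names = [e + str(i + 1) for i, e in enumerate(self.elements)]
        if self.resnames is None:
            self.resnames = ["LIG"] * n
        if self.chains is None:
            self.chains = ["A"] * n

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    about: np.ndarray | None = None) -> "Structure":
        """Rigidly transformed copy: rotate about `about` (default the
        centroid), then translate."""
        coords = self.coords.copy()
        if rotation is not None:
            pivot = self.centroid() if about is None else np.asarray(about)
            coords = (coords - pivot) @ np.asarray(rotation).T + pivot
        if translation is not None:
            coords = coords + np.asarray(translation)
        return replace(self, coords=coords)


def merge(a: Structure, b: Structure) -> Structure:
    """Concatenate two structures into one rigid complex."""
    return Structure(
        coords=np.vstack([a.coords, b.coords]),
        radii=np.concatenate([a.radii, b.radii]),
        elements=list(a.elements) + list(b.elements),
        charges=np.concatenate([a.charges, b.charges]),
        is_donor=np.concatenate([a.is_donor, b.is_donor]),
        is_acceptor=np.concatenate([a.is_acceptor, b.is_acceptor]),
        names=list(a.names) + list(b.names),
        resnames=list(a.resnames) + list(b.resnames),
        chains=list(a.chains) + list(b.chains),
        label=f"{a.label}+{b.label}",
    )


def read_pdb(path, charge_table: dict[tuple[str, str], float] | None = None
             ) -> Structure:
    """Read ATOM/HETATM records into a :class:`Structure`.

    Radii come from the packaged element table (unknown elements get
    1.7 A with a warning); charges default to zero unless `charge_table`
    maps (resname, atom name) to a partial charge. N and O atoms are
    flagged as hydrogen-bond donors and acceptors.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    coords, radii, elements = [], [], []
    charges, names, resnames, chains = [], [], [], []
    for model in st:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    el = atom.element.name.upper()
                    if not el:
                        el = atom.name.strip()[:1].upper()
                    if el not in VDW_RADII:
                        warnings.warn(
                            f"unknown element {el!r} for atom "
                            f"{atom.name}: using radius {DEFAULT_RADIUS} A",
                            stacklevel=2,
                        )
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    radii.append(VDW_RADII.get(el, DEFAULT_RADIUS))
                    elements.append(el)
                    q = 0.0
                    if charge_table is not None:
                        q = charge_table.get((residue.name, atom.name), 0.0)
                    charges.append(q)
                    names.append(atom.name)
                    resnames.append(residue.name)
                    chains.append(chain.name)
        break  # first model only
    if not coords:
        raise ValueError(f"no ATOM/HETATM records parsed from {path}")
    els = np.array(elements)
    polar = np.isin(els, ("N", "O"))
    return Structure(
        coords=np.array(coords), radii=np.array(radii), elements=elements,
        charges=np.array(charges), is_donor=polar.copy(),
        is_acceptor=polar.copy(), names=names, resnames=resnames,
        chains=chains, label=str(path),
    )


def write_pdb(structure: Structure, path) -> None:
    """Write a structure to standard PDB (HETATM for LIG residues,
    element column populated)."""
    st = gemmi.Structure()
    st.name = structure.label or "toy"
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    for i in range(structure.n_atoms):
        cname = structure.chains[i]
        if cname not in chain_map:
            chain_map[cname] = gemmi.Chain(cname)
        chain = chain_map[cname]
        resname = structure.resnames[i]
        if (len(chain) == 0 or chain[-1].name != resname):
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(len(chain) + 1, " ")
            res.het_flag = "H" if resname in ("LIG", "UNL") else "A"
            chain.add_residue(res)
        atom = gemmi.Atom()
        atom.name = structure.names[i][:4]
        atom.element = gemmi.Element(structure.elements[i].capitalize())
        x, y, z = structure.coords[i]
        atom.pos = gemmi.Position(x, y, z)
        chain[-1].add_atom(atom)
    for chain in chain_map.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley)
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def compute_asa(structure: Structure, probe: float = DEFAULT_PROBE,
                n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area, A^2.

    Shrake-Rupley: test points on each atom's probe-expanded sphere are
    exposed iff they fall outside every neighbour's expanded sphere;
    ASA_i = (exposed fraction) * 4 pi (r_i + probe)^2.
    """
    unit = fibonacci_sphere(n_points)
    expanded = structure.radii + probe
    coords = structure.coords
    tree = cKDTree(coords)
    max_r = expanded.max()
    asa = np.empty(structure.n_atoms)
    for i in range(structure.n_atoms):
        pts = coords[i] + expanded[i] * unit
        neighbours = tree.query_ball_point(coords[i], expanded[i] + max_r)
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbours:
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > expanded[j] ** 2
        asa[i] = exposed.mean() * 4.0 * math.pi * expanded[i] ** 2
    return asa


def total_asa(structure: Structure, probe: float = DEFAULT_PROBE,
              n_points: int = 960) -> float:
    return float(np.sum(compute_asa(structure, probe, n_points)))


def buried_surface_area(receptor: Structure, ligand: Structure,
                        probe: float = DEFAULT_PROBE,
                        n_points: int = 960) -> float:
    """BSA = ASA(receptor) + ASA(ligand) - ASA(complex), A^2.

    Symmetric in its arguments and non-negative (occlusion can only
    remove accessible area).
    """
    asa_r = total_asa(receptor, probe, n_points)
    asa_l = total_asa(ligand, probe, n_points)
    asa_c = total_asa(merge(receptor, ligand), probe, n_points)
    return asa_r + asa_l - asa_c


# ---------------------------------------------------------------------------
# shape complementarity
# ---------------------------------------------------------------------------

def dot_surface(structure: Structure, probe: float = DEFAULT_PROBE,
                density: float = 15.0) -> tuple[np.ndarray, np.ndarray]:
    """Dot representation of the probe-expanded surface.

    Returns (dots, outward normals); dots on one atom's expanded sphere are
    kept only if they lie outside every other atom's expanded sphere, so
    the result approximates the molecule's solvent-accessible surface at
    about `density` dots per A^2.
    """
    expanded = structure.radii + probe
    coords = structure.coords
    tree = cKDTree(coords)
    max_r = expanded.max()
    dots, normals = [], []
    for i in range(structure.n_atoms):
        n_pts = max(8, int(round(density * 4.0 * math.pi * expanded[i] ** 2)))
        unit = fibonacci_sphere(n_pts)
        pts = coords[i] + expanded[i] * unit
        keep = np.ones(n_pts, dtype=bool)
        for j in tree.query_ball_point(coords[i], expanded[i] + max_r):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            keep &= d2 > expanded[j] ** 2
        dots.append(pts[keep])
        normals.append(unit[keep])
    return np.vstack(dots), np.vstack(normals)


def _sc_one_way(dots_a, normals_a, dots_b, normals_b, w, band):
    if len(dots_a) == 0 or len(dots_b) == 0:
        raise ValueError("no interface dots: empty surface")
    tree_b = cKDTree(dots_b)
    dist, idx = tree_b.query(dots_a)
    shell = dist <= dist.min() + band
    m = float(np.median(dist[shell]))
    interface = dist <= m + band
    if not np.any(interface):
        raise ValueError("no interface dots: surfaces do not meet")
    align = np.sum(normals_a[interface] * (-normals_b[idx[interface]]),
                   axis=1)
    s = align * np.exp(-w * dist[interface] ** 2)
    return float(np.median(s))


def sc_from_dots(dots_a: np.ndarray, normals_a: np.ndarray,
                 dots_b: np.ndarray, normals_b: np.ndarray,
                 w: float = 0.5, band: float = 1.5) -> float:
    """Shape complementarity of two dotted surfaces with outward normals.

    For a dot x on A with nearest partner dot x' on B,
    S(x) = (n_x . -n_x') * exp(-w |x - x'|^2); interface dots are those
    whose nearest-partner distance lies within `band` of the median
    distance of the closest contact shell. Sc is the mean of the two
    one-way medians and lies in (-1, 1]; well-packed interfaces score
    around 0.7.
    """
    s_ab = _sc_one_way(dots_a, normals_a, dots_b, normals_b, w, band)
    s_ba = _sc_one_way(dots_b, normals_b, dots_a, normals_a, w, band)
    return 0.5 * (s_ab + s_ba)


def shape_complementarity(receptor: Structure, ligand: Structure,
                          w: float = 0.5, band: float = 1.5,
                          dot_density: float = 15.0,
                          probe: float = DEFAULT_PROBE) -> float:
    """Sc of a two-body complex from expanded-sphere dot surfaces."""
    dots_r, normals_r = dot_surface(receptor, probe, dot_density)
    dots_l, normals_l = dot_surface(ligand, probe, dot_density)
    if len(dots_r) == 0 or len(dots_l) == 0:
        raise ValueError("empty dot surface")
    return sc_from_dots(dots_r, normals_r, dots_l, normals_l, w, band)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBond:
    """One intermolecular hydrogen bond (donor side named)."""

    donor_mol: str       # "receptor" or "ligand"
    donor_index: int
    acceptor_index: int
    distance: float


def _hbonds_one_way(donor_struct, acceptor_struct, donor_mol,
                    d_max, angle_min) -> list[HBond]:
    out = []
    don_idx = np.flatnonzero(donor_struct.is_donor)
    acc_idx = np.flatnonzero(acceptor_struct.is_acceptor)
    if len(don_idx) == 0 or len(acc_idx) == 0:
        return out
    # explicit hydrogens bonded to each donor, if any
    h_idx = np.flatnonzero(np.array(donor_struct.elements) == "H")
    for di in don_idx:
        d_pos = donor_struct.coords[di]
        hydrogens = [h for h in h_idx
                     if np.linalg.norm(donor_struct.coords[h] - d_pos) < 1.3]
        for ai in acc_idx:
            a_pos = acceptor_struct.coords[ai]
            dist = float(np.linalg.norm(a_pos - d_pos))
            if dist > d_max or dist < 0.5:
                continue
            if hydrogens:
                ok = False
                for h in hydrogens:
                    h_pos = donor_struct.coords[h]
                    v1 = d_pos - h_pos
                    v2 = a_pos - h_pos
                    cosang = np.dot(v1, v2) / (
                        np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
                    angle = math.degrees(math.acos(np.clip(cosang, -1, 1)))
                    if angle >= angle_min:
                        ok = True
                        break
                if not ok:
                    continue
            out.append(HBond(donor_mol, int(di), int(ai), dist))
    return out


def detect_hbonds(receptor: Structure, ligand: Structure,
                  d_max: float = 3.5, angle_min: float = 120.0
                  ) -> list[HBond]:
    """Geometric intermolecular hydrogen bonds.

    A donor-acceptor pair counts when the heavy-atom distance is at most
    `d_max`; when the donor carries an explicit hydrogen, the D-H...A angle
    must additionally reach `angle_min` degrees.
    """
    bonds = _hbonds_one_way(receptor, ligand, "receptor", d_max, angle_min)
    bonds += _hbonds_one_way(ligand, receptor, "ligand", d_max, angle_min)
    return bonds


# ---------------------------------------------------------------------------
# interface score
# ---------------------------------------------------------------------------

@dataclass
class InterfaceMetrics:
    """Decomposed interface score plus surface metrics of one complex."""

    terms: dict[str, float]
    score_total: float
    n_hbonds: int
    bsa: float | None = None
    sc: float | None = None


COULOMB_K = 332.0          # kcal A mol^-1 e^-2
LJ_EPS = 0.1               # kcal/mol well depth per atom pair
LJ_REP_CAP = 10.0          # kcal/mol cap per clashing pair
HBOND_BONUS = -0.5         # kcal/mol per geometric hydrogen bond
SCORE_CUTOFF = 8.0         # A pairwise cutoff


def interface_score(receptor: Structure, ligand: Structure,
                    cutoff: float = SCORE_CUTOFF,
                    include_surface_metrics: bool = True,
                    probe: float = DEFAULT_PROBE,
                    n_points: int = 960,
                    dot_density: float = 15.0) -> InterfaceMetrics:
    """Simple physics score of a two-body interface.

    Terms over intermolecular atom pairs within `cutoff`:

    * ``elec``: screened Coulomb 332 q_i q_j / (4 r^2) — a distance-
      dependent dielectric eps = 4r;
    * ``lj_attractive`` / ``lj_repulsive``: 12-6 Lennard-Jones with
      r_min = r_i + r_j and well depth 0.1 kcal/mol, split at r_min, the
      repulsive branch capped at +10 per pair;
    * ``hbond``: -0.5 per geometric hydrogen bond.

    ``score_total`` is the sum of the terms (more negative = better).
    BSA and Sc are filled in unless `include_surface_metrics` is False
    (pose scoring skips them for speed).
    """
    tree_r = cKDTree(receptor.coords)
    tree_l = cKDTree(ligand.coords)
    pairs = tree_r.query_ball_tree(tree_l, cutoff)
    elec = lj_atr = lj_rep = 0.0
    for i, js in enumerate(pairs):
        if not js:
            continue
        js = np.asarray(js)
        d = np.linalg.norm(ligand.coords[js] - receptor.coords[i], axis=1)
        d = np.maximum(d, 0.1)
        elec += float(np.sum(
            COULOMB_K * receptor.charges[i] * ligand.charges[js] /
            (4.0 * d ** 2)))
        rmin = receptor.radii[i] + ligand.radii[js]
        x6 = (rmin / d) ** 6
        e_lj = LJ_EPS * (x6 ** 2 - 2.0 * x6)
        attr = d >= rmin
        lj_atr += float(np.sum(e_lj[attr]))
        lj_rep += float(np.sum(np.minimum(e_lj[~attr], LJ_REP_CAP)))

    hbonds = detect_hbonds(receptor, ligand)
    terms = {
        "elec": elec,
        "lj_attractive": lj_atr,
        "lj_repulsive": lj_rep,
        "hbond": HBOND_BONUS * len(hbonds),
    }
    metrics = InterfaceMetrics(
        terms=terms,
        score_total=float(sum(terms.values())),
        n_hbonds=len(hbonds),
    )
    if include_surface_metrics:
        metrics.bsa = buried_surface_area(receptor, ligand, probe, n_points)
        try:
            metrics.sc = shape_complementarity(
                receptor, ligand, dot_density=dot_density, probe=probe)
        except ValueError:
            metrics.sc = None
    return metrics


# ---------------------------------------------------------------------------
# pose sampling
# ---------------------------------------------------------------------------

@dataclass
class Pose:
    """One rigid placement of the ligand and its score."""

    rotation: np.ndarray       # (3, 3)
    translation: np.ndarray    # (3,) offset of the centroid from site_center
    metrics: InterfaceMetrics
    ligand: Structure


@dataclass
class PoseSet:
    """Clash-free scored poses, sorted ascending by score_total."""

    poses: list[Pose]
    seed: int | None
    n_requested: int

    def __len__(self) -> int:
        return len(self.poses)

    @property
    def best(self) -> Pose:
        return self.poses[0]


def sample_poses(receptor: Structure, ligand: Structure,
                 site_center, n_poses: int = 2000,
                 max_translation: float = 5.0,
                 seed: int | None = None,
                 clash_factor: float = 0.7) -> PoseSet:
    """Random rigid-body ligand placements around a site, scored and ranked.

    Each pose applies a uniform random rotation about the ligand centroid
    and moves the centroid to `site_center` plus a uniform-in-ball
    translation of radius `max_translation`. Poses where any intermolecular
    pair comes closer than `clash_factor` times the sum of vdW radii are
    discarded as hard clashes. Survivors are scored with
    :func:`interface_score` (energy terms only) and sorted best-first.
    """
    rng = np.random.default_rng(seed)
    site_center = np.asarray(site_center, dtype=float)
    centered = ligand.coords - ligand.centroid()
    tree_r = cKDTree(receptor.coords)
    max_rl = ligand.radii.max()
    poses: list[Pose] = []
    for _ in range(n_poses):
        rot = Rotation.random(rng=rng).as_matrix()
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = max_translation * rng.uniform() ** (1.0 / 3.0)
        offset = radius * direction
        coords = centered @ rot.T + site_center + offset
        # hard-clash test
        clash = False
        for k in range(len(coords)):
            near = tree_r.query_ball_point(
                coords[k], clash_factor * (ligand.radii[k] + max_rl) + 1e-9)
            for j in near:
                dmin = clash_factor * (ligand.radii[k] + receptor.radii[j])
                if np.linalg.norm(coords[k] - receptor.coords[j]) < dmin:
                    clash = True
                    break
            if clash:
                break
        if clash:
            continue
        posed = replace(ligand, coords=coords)
        metrics = interface_score(receptor, posed,
                                  include_surface_metrics=False)
        poses.append(Pose(rotation=rot, translation=offset,
                          metrics=metrics, ligand=posed))
    if not poses:
        raise RuntimeError(
            "no poses survived the clash filter; try a larger "
            "max_translation or a shallower site"
        )
    poses.sort(key=lambda p: p.metrics.score_total)
    return PoseSet(poses=poses, seed=seed, n_requested=n_poses)


def top_k_mean(pose_set: PoseSet, k: int = 10) -> float:
    """Mean score of the k best poses (ranking already ascending)."""
    if len(pose_set) < k:
        raise ValueError(f"need at least {k} poses, have {len(pose_set)}")
    return float(np.mean([p.metrics.score_total
                          for p in pose_set.poses[:k]]))


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Root-mean-square deviation of matched coordinates (no alignment)."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate arrays differ in shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
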