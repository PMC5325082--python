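"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators emulate the raw data the analyses consume, so that each
stage is testable without external downloads:

* :func:`gen_dose_response` — per-oocyte Hill-shaped peak responses with
  multiplicative log-normal noise (currents are positive and their spread
  grows with amplitude).
* :func:`gen_toy_pentamer` — an idealized C5 ring of pseudo-subunits with
  binding-pocket residues planted at exactly known distances and angles
  from a ligand reference point.  No structural realism is attempted; the
  toy's only contract is that the planted geometry is exact, so geometric
  detectors can be checked analytically.
* :func:`gen_pose_ensemble` — docked-pose ensembles with a planted fraction
  of correctly oriented conformations (cationic N placed 4-5 Å along an
  aromatic ring normal) and the remainder placed beyond cation-pi range
  (N at least 7 Å from every ring centroid), with separate energy
  distributions for the two populations.

All generators are pure functions of (config, seed); the planted truth is
returned alongside each dataset and is meant for test suites, never for the
analysis path itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pose_analysis import (AROMATIC_RING_ATOMS, GeomConfig, LigandPose,
                            PoseEnsemble, ring_centroid_normal)
from .structures import (Atom, Chain, InterfaceSpec, Residue, StructureModel,
                         enumerate_interfaces)

__all__ = [
    "DRSimConfig",
    "PoseSimConfig",
    "PlantedResidue",
    "ToyPocketSpec",
    "DEFAULT_ARRANGEMENT",
    "default_concentration_grid",
    "gen_dose_response",
    "gen_toy_pentamer",
    "gen_pose_ensemble",
]

#: The arrangement class of an (a9)2(a10)3 pentamer that realizes all four
#: interface types a9(+)a9(-), a9(+)a10(-), a10(+)a10(-), a10(+)a9(-).
DEFAULT_ARRANGEMENT = ("a9", "a9", "a10", "a10", "a10")


def default_concentration_grid() -> np.ndarray:
    """Ten log-equidistant agonist concentrations, 1 µM to 3 mM (molar)."""
    return np.geomspace(1e-6, 3e-3, 10)


# ---------------------------------------------------------------------------
# Dose-response simulation
# ---------------------------------------------------------------------------

@dataclass
class DRSimConfig:
    """Simulated oocyte concentration-response recordings.

    Defaults mirror a wild-type-like receptor: EC50 18 µM, nH 1.2, six
    oocytes, 10% multiplicative noise, concentrations spanning 1 µM-3 mM.
    """

    ec50: float = 18e-6           # molar
    nh: float = 1.2
    imax: float = 1.0
    sigma: float = 0.1            # sd of log-normal multiplicative noise
    n_oocytes: int = 6
    concentrations: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.concentrations is None:
            self.concentrations = default_concentration_grid()
        self.concentrations = np.asarray(self.concentrations, float)
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentration grid must be strictly increasing")


def gen_dose_response(config: DRSimConfig,
                      seed: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Simulate per-oocyte Hill responses with multiplicative noise.

    response(A) = Imax * A^nH / (A^nH + EC50^nH) * exp(eps),
    eps ~ Normal(0, sigma^2), independent per measurement.  Returns the
    dataset (columns oocyte_id, concentration, current) and the ground
    truth (the generating parameters).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    conc = config.concentrations
    ratio = (conc / config.ec50) ** config.nh
    curve = config.imax * ratio / (1.0 + ratio)
    rows = []
    for i in range(config.n_oocytes):
        eps = rng.normal(0.0, config.sigma, size=len(conc)) if config.sigma > 0 else 0.0
        resp = curve * np.exp(eps)
        for a, r in zip(conc, np.atleast_1d(resp) if np.ndim(resp) else curve):
            rows.append({"oocyte_id": f"oocyte{i + 1:02d}",
                         "concentration": a, "current": r})
    truth = {"ec50": config.ec50, "nh": config.nh, "imax": config.imax,
             "sigma": config.sigma, "n_oocytes": config.n_oocytes}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Toy pentamer with planted pocket geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedResidue:
    """One residue planted at exactly known geometry.

    ``kind``:
      * ``aromatic`` — ring centroid at ``distance`` Å from the ligand
        cationic N, with ``angle_deg`` between the ring normal and the
        centroid-to-N vector (0° = N on the ring axis).
      * ``charged`` — charged-group representative point (Arg CZ, Lys NZ,
        Asp/Glu carboxylate-O midpoint) at ``distance`` Å from the N.
      * ``hbond`` — polar partner atom (Tyr OH, Asp OD1, Ser OG ...) at
        ``distance`` Å from the ligand's O1 acceptor atom.
    """

    torpedo_number: int
    name: str                 # 3-letter residue code
    face: str                 # 'principal' or 'complementary'
    kind: str                 # 'aromatic' | 'charged' | 'hbond'
    distance: float           # Å
    angle_deg: float = 0.0    # aromatics only

    def __post_init__(self) -> None:
        if self.kind not in ("aromatic", "charged", "hbond"):
            raise ValueError(f"unknown plant kind {self.kind!r}")
        if self.face not in ("principal", "complementary"):
            raise ValueError(f"face must be principal/complementary, got {self.face!r}")
        if not (math.isfinite(self.distance) and self.distance > 0):
            raise ValueError("plant distance must be positive and finite")


@dataclass
class ToyPocketSpec:
    """Roster of residues to plant in the toy pocket at interface 0."""

    planted: list[PlantedResidue] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(p.face, p.torpedo_number) for p in self.planted]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (face, torpedo_number) in plant roster")

    @classmethod
    def default(cls) -> "ToyPocketSpec":
        """The canonical agonist-pocket roster of a rat-like a10(+)a9(-)-style
        interface with an a10-like complementary charge set.

        Aromatics W55/Y93/W149/Y190 sit 4.2-4.8 Å from the cationic N on
        their ring axes; Y197 is a hydrogen-bond partner 3.1 Å from the
        ligand ester oxygen; the charged roster reproduces, within the
        default 10 Å radius, the radial ordering D119 < R57 < R79 < D169 <
        D199, with R117 at 8.7 Å and E59 beyond 10 Å.
        """
        return cls([
            PlantedResidue(55, "TRP", "complementary", "aromatic", 4.2),
            PlantedResidue(93, "TYR", "principal", "aromatic", 4.6),
            PlantedResidue(149, "TRP", "principal", "aromatic", 4.4),
            PlantedResidue(190, "TYR", "principal", "aromatic", 4.8),
            PlantedResidue(197, "TYR", "principal", "hbond", 3.1),
            PlantedResidue(119, "ASP", "complementary", "charged", 5.0),
            PlantedResidue(57, "ARG", "complementary", "charged", 6.0),
            PlantedResidue(79, "ARG", "complementary", "charged", 7.0),
            PlantedResidue(169, "ASP", "complementary", "charged", 8.0),
            PlantedResidue(117, "ARG", "complementary", "charged", 8.7),
            PlantedResidue(199, "ASP", "principal", "charged", 9.5),
            PlantedResidue(59, "GLU", "complementary", "charged", 10.5),
        ])


#: Compact acetylcholine-like ligand template (offsets from the cationic N,
#: Å).  O1 is the carbonyl-like acceptor used for hydrogen-bond plants.
_LIGAND_TEMPLATE = (
    ("N", "N", (0.0, 0.0, 0.0)),
    ("C1", "C", (1.47, 0.0, 0.0)),
    ("C2", "C", (0.65, -1.25, 0.45)),
    ("O2", "O", (2.25, 1.05, 0.30)),
    ("O1", "O", (2.95, 1.95, -0.55)),
)

_RING_RADIUS_A = 1.39  # aromatic C-C ring radius, Å


def _golden_directions(n: int) -> np.ndarray:
    """n well-separated unit vectors (golden-section spiral), deterministic."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def _perp(u: np.ndarray) -> np.ndarray:
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    w = np.cross(u, a)
    return w / np.linalg.norm(w)


def _hexagon(center: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> list[np.ndarray]:
    return [center + _RING_RADIUS_A * (math.cos(math.radians(60 * k)) * p1
                                       + math.sin(math.radians(60 * k)) * p2)
            for k in range(6)]


def _aromatic_atoms(name: str, n_ref: np.ndarray, plant: PlantedResidue,
                    u: np.ndarray) -> list[Atom]:
    """Ring with centroid at n_ref + d*u and prescribed axial angle."""
    center = n_ref + plant.distance * u
    w = _perp(u)
    ang = math.radians(plant.angle_deg)
    normal = math.cos(ang) * (-u) + math.sin(ang) * w   # -u points back at N
    normal /= np.linalg.norm(normal)
    p1 = np.cross(normal, u)
    if np.linalg.norm(p1) < 1e-8:       # angle 0: normal parallel to u
        p1 = w
    p1 /= np.linalg.norm(p1)
    p2 = np.cross(normal, p1)
    ring_names = AROMATIC_RING_ATOMS[name]
    coords = _hexagon(center, p1, p2)[:len(ring_names)]
    atoms = [Atom(nm, nm[0], c) for nm, c in zip(ring_names, coords)]
    atoms.append(Atom("CA", "C", center + 3.5 * u))
    return atoms


def _charged_atoms(name: str, n_ref: np.ndarray, plant: PlantedResidue,
                   u: np.ndarray) -> list[Atom]:
    """Side chain whose representative point is exactly n_ref + d*u."""
    point = n_ref + plant.distance * u
    w = _perp(u)
    atoms = [Atom("CA", "C", point + 3.0 * u)]
    if name == "ARG":
        atoms += [Atom("CZ", "C", point),
                  Atom("NE", "N", point + 1.33 * (0.5 * u + 0.87 * w)),
                  Atom("NH1", "N", point + 1.33 * (0.5 * u - 0.87 * w)),
                  Atom("NH2", "N", point - 1.33 * w)]
    elif name == "LYS":
        atoms += [Atom("NZ", "N", point), Atom("CE", "C", point + 1.5 * u)]
    elif name in ("ASP", "GLU"):
        o1, o2 = ("OD1", "OD2") if name == "ASP" else ("OE1", "OE2")
        atoms += [Atom(o1, "O", point + 1.1 * w),
                  Atom(o2, "O", point - 1.1 * w),
                  Atom("CG" if name == "ASP" else "CD", "C", point + 0.8 * u)]
    else:
        raise ValueError(f"cannot plant {name!r} as a charged group")
    return atoms


def _hbond_atoms(name: str, o1_ref: np.ndarray, plant: PlantedResidue,
                 u: np.ndarray) -> list[Atom]:
    """Polar partner atom exactly at o1_ref + d*u; fillers point away."""
    q = o1_ref + plant.distance * u
    w = _perp(u)
    if name == "TYR":
        # full phenol ring behind the OH so aromatic detectors see a complete
        # residue; the ring plane contains u, keeping its axial angle ~90°.
        cz = q + 1.37 * u
        center = cz + _RING_RADIUS_A * u
        atoms = [Atom("OH", "O", q)]
        names = AROMATIC_RING_ATOMS["TYR"]       # CG CD1 CD2 CE1 CE2 CZ
        hexa = _hexagon(center, -u, w)
        order = {"CZ": 0, "CE1": 1, "CD1": 2, "CG": 3, "CD2": 4, "CE2": 5}
        atoms += [Atom(nm, "C", hexa[order[nm]]) for nm in names]
        atoms.append(Atom("CA", "C", center + 3.5 * u))
        return atoms
    if name == "ASP":
        return [Atom("OD1", "O", q), Atom("OD2", "O", q + 2.2 * w),
                Atom("CG", "C", q + 1.1 * w + 0.8 * u), Atom("CA", "C", q + 3.0 * u)]
    if name == "SER":
        return [Atom("OG", "O", q), Atom("CB", "C", q + 1.4 * u),
                Atom("CA", "C", q + 2.8 * u)]
    raise ValueError(f"cannot plant {name!r} as an hbond partner")


def gen_toy_pentamer(spec: ToyPocketSpec | None = None,
                     arrangement: Sequence[str] = DEFAULT_ARRANGEMENT,
                     ring_radius: float = 30.0,
                     include_ligand: bool = True
                     ) -> tuple[StructureModel, InterfaceSpec, dict]:
    """Build a C5-symmetric toy pentamer with an exactly planted pocket.

    Chains A-E sit on a ring of ``ring_radius`` Å; the pocket lies at the
    interface between chain A (principal face) and chain B (complementary
    face), with the ligand reference nitrogen at the mid-angle of the two
    chains.  Planted residues are realized with correct side-chain atom
    names so the geometry operators run unmodified; author numbering equals
    Torpedo numbering in the toy.

    Returns ``(model, pocket_interface, ground_truth)``; the truth dict
    records the ligand N position and each plant's exact geometry.
    """
    spec = spec or ToyPocketSpec.default()
    if len(arrangement) != 5:
        raise ValueError("arrangement must have 5 subunit labels")

    # ligand reference frame at the A/B interface mid-angle
    mid = math.radians(36.0)
    n_ref = np.array([ring_radius * math.cos(mid), ring_radius * math.sin(mid), 0.0])
    lig_atoms = [Atom(nm, el, n_ref + np.array(off)) for nm, el, off in _LIGAND_TEMPLATE]
    o1_ref = next(a.coords for a in lig_atoms if a.name == "O1")

    chain_ids = ["A", "B", "C", "D", "E"]
    face_chain = {"principal": "A", "complementary": "B"}
    plants = sorted(spec.planted, key=lambda p: (p.face, p.torpedo_number))
    dirs = _assign_directions(plants, n_ref, o1_ref,
                              [a.coords for a in lig_atoms])

    residues_by_chain: dict[str, list[Residue]] = {cid: [] for cid in chain_ids}
    truth: dict = {"ligand_n": tuple(n_ref), "plants": {}}
    for plant, u in zip(plants, dirs):
        if plant.kind == "aromatic":
            atoms = _aromatic_atoms(plant.name, n_ref, plant, u)
        elif plant.kind == "charged":
            atoms = _charged_atoms(plant.name, n_ref, plant, u)
        else:
            atoms = _hbond_atoms(plant.name, o1_ref, plant, u)
        cid = face_chain[plant.face]
        residues_by_chain[cid].append(
            Residue(cid, plant.torpedo_number, plant.name, atoms,
                    torpedo_number=plant.torpedo_number))
        truth["plants"][plant.torpedo_number] = {
            "name": plant.name, "face": plant.face, "kind": plant.kind,
            "distance": plant.distance, "angle_deg": plant.angle_deg,
        }

    # inert backbone markers so every chain is non-empty and ring-shaped
    for i, cid in enumerate(chain_ids):
        for j, dtheta in enumerate((-10.0, 0.0, 10.0)):
            theta = math.radians(72.0 * i + dtheta)
            ca = np.array([ring_radius * math.cos(theta),
                           ring_radius * math.sin(theta), 8.0])
            residues_by_chain[cid].append(
                Residue(cid, 300 + j, "GLY", [Atom("CA", "C", ca)],
                        torpedo_number=300 + j))

    chains = []
    for cid, label in zip(chain_ids, arrangement):
        res = sorted(residues_by_chain[cid], key=lambda r: r.author_number)
        chains.append(Chain(cid, label.replace("α", "a"), res))
    if include_ligand:
        lig = Residue("L", 1, "ACH", lig_atoms, is_ligand=True)
        chains.append(Chain("L", "other", [lig]))

    _check_clashes(chains)
    model = StructureModel(chains, source="toy-pentamer")
    interface = enumerate_interfaces(
        StructureModel(chains[:5], source="toy"), list(arrangement))[0]
    return model, interface, truth


#: clearance radius per plant kind: ring radius / side-chain reach + 0.8 A
_PLANT_MARGIN = {"aromatic": 2.3, "charged": 2.2, "hbond": 2.2}


def _assign_directions(plants, n_ref: np.ndarray, o1_ref: np.ndarray,
                       ligand_coords: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Deterministically pick one unit direction per plant from a golden-
    spiral pool, keeping each planted group clear of the ligand body and of
    previously placed groups."""
    pool = _golden_directions(64)
    lig = np.stack(ligand_coords)
    used: set[int] = set()
    placed: list[tuple[np.ndarray, float]] = []
    out = []
    for plant in plants:
        origin = o1_ref if plant.kind == "hbond" else n_ref
        margin = _PLANT_MARGIN[plant.kind]
        chosen = None
        for idx, u in enumerate(pool):
            if idx in used:
                continue
            point = origin + plant.distance * u
            if float(np.min(np.linalg.norm(lig - point, axis=1))) < margin:
                continue
            if any(float(np.linalg.norm(point - p)) < margin + m
                   for p, m in placed):
                continue
            chosen = (idx, u, point)
            break
        if chosen is None:
            raise ValueError(
                f"clashing plant positions: cannot place "
                f"{plant.name}{plant.torpedo_number} at {plant.distance} Å "
                "clear of the ligand and other planted residues")
        used.add(chosen[0])
        placed.append((chosen[2], margin))
        out.append(chosen[1])
    return out


def _check_clashes(chains: Sequence[Chain], min_dist: float = 0.8) -> None:
    coords, owners = [], []
    for c in chains:
        for r in c.residues:
            for a in r.atoms:
                coords.append(a.coords)
                owners.append((c.chain_id, r.author_number))
    arr = np.asarray(coords)
    d = np.linalg.norm(arr[:, None, :] - arr[None, :, :], axis=2)
    n = len(arr)
    for i in range(n):
        for j in range(i + 1, n):
            if owners[i] != owners[j] and d[i, j] < min_dist:
                raise ValueError(
                    f"clashing plant positions: residues {owners[i]} and "
                    f"{owners[j]} have atoms {d[i, j]:.2f} Å apart")


# ---------------------------------------------------------------------------
# Pose-ensemble simulation
# ---------------------------------------------------------------------------

@dataclass
class PoseSimConfig:
    """Planted docking-pose ensembles.

    ``favorable_fraction`` of the ``n_poses`` conformations are placed so
    the cation-pi criterion holds (N 4-5 Å along a pocket-aromatic ring
    normal); the rest violate it (N at least 7 Å from every ring centroid).
    Docking-score defaults put the favorable population near -5.5 kcal/mol
    and the unfavorable one near -3.5 kcal/mol.
    """

    n_poses: int = 200
    favorable_fraction: float = 0.3
    favorable_energy_mean: float = -5.5
    unfavorable_energy_mean: float = -3.5
    energy_sd: float = 0.4
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.favorable_fraction <= 1.0:
            raise ValueError("favorable_fraction must lie in [0, 1]")
        if self.n_poses <= 0:
            raise ValueError("n_poses must be positive")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def gen_pose_ensemble(config: PoseSimConfig, pocket: StructureModel,
                      interface: InterfaceSpec,
                      geom: GeomConfig | None = None,
                      seed: int | None = None
                      ) -> tuple[PoseEnsemble, list[bool]]:
    """Simulate an ensemble with a planted favorable fraction.

    Exactly floor(n_poses * favorable_fraction) poses satisfy the cation-pi
    criterion against the pocket's planted aromatics; the remainder are
    guaranteed to fail it under default geometry.  Returns the ensemble and
    the planted per-pose labels (aligned with pose order).
    """
    geom = geom or GeomConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    rings = []       # (centroid, unit normal pointing toward the pocket)
    all_centroids = []
    lig_ref = None
    for cid in (interface.principal_chain, interface.complementary_chain):
        for res in pocket.chain(cid).residues:
            ring_names = AROMATIC_RING_ATOMS.get(res.name)
            if ring_names is None or res.name == "HIS":
                continue
            atoms = [res.atom(nm) for nm in ring_names]
            if any(a is None for a in atoms):
                continue
            centroid, normal = ring_centroid_normal(
                np.stack([a.coords for a in atoms]))
            all_centroids.append(centroid)
            if res.torpedo_number in geom.aromatic_set:
                rings.append((centroid, normal))
    if not rings:
        raise ValueError("pocket model contains none of the planted aromatics")
    for c in pocket.chains:
        for r in c.residues:
            if r.is_ligand:
                lig_ref = r.atom(geom.cationic_atom).coords
    if lig_ref is None:
        lig_ref = np.mean([c for c in all_centroids], axis=0)
    # orient each ring normal toward the pocket centre
    rings = [(c, n if float(np.dot(n, lig_ref - c)) >= 0 else -n) for c, n in rings]
    all_centroids = np.stack(all_centroids)

    n_fav = int(math.floor(config.n_poses * config.favorable_fraction))
    labels = [True] * n_fav + [False] * (config.n_poses - n_fav)
    rng.shuffle(labels)

    template = [(nm, el, np.array(off)) for nm, el, off in _LIGAND_TEMPLATE]
    poses = []
    for i, fav in enumerate(labels):
        if fav:
            centroid, normal = rings[rng.integers(len(rings))]
            n_pos = centroid + rng.uniform(4.0, 5.0) * normal
        else:
            while True:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                n_pos = lig_ref + rng.uniform(9.0, 14.0) * direction
                dmin = float(np.min(np.linalg.norm(all_centroids - n_pos, axis=1)))
                if dmin > 7.0:
                    break
        rot = _random_rotation(rng)
        atoms = [Atom(nm, el, n_pos + rot @ off) for nm, el, off in template]
        mean = (config.favorable_energy_mean if fav
                else config.unfavorable_energy_mean)
        energy = float(rng.normal(mean, config.energy_sd))
        poses.append(LigandPose(f"pose{i + 1:03d}", atoms, energy, interface))
    return PoseEnsemble(interface, poses, n_runs=config.n_poses), labels
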