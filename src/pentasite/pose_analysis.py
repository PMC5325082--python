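"""Docked-pose orientation analysis for agonist-site interfaces.

An acetylcholine pose is "favorable" when its quaternary-ammonium nitrogen
makes a cation-pi contact with the conserved binding-pocket aromatics
(Torpedo alpha1 positions W55, Y93, W149, Y190).  This module detects those
contacts geometrically, records hydrogen-bond evidence (e.g. to D119 and
Y197), classifies poses, clusters them by RMSD in the common receptor
frame, and summarizes each interface by best binding energy (BBE) and the
frequency of favorable conformations.
"""

from __future__ import annotations

import io
import math
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .structures import (Atom, InterfaceSpec, Residue, StructureModel, _read_text)

__all__ = [
    "GeomConfig",
    "LigandPose",
    "PoseEnsemble",
    "CationPiContact",
    "HBondContact",
    "InteractionReport",
    "InterfaceSummary",
    "PoseCluster",
    "AROMATIC_RING_ATOMS",
    "ring_centroid_normal",
    "detect_cation_pi",
    "detect_hbonds",
    "classify_pose",
    "cluster_poses",
    "pose_rmsd",
    "summarize_interface",
    "average_summaries",
    "read_pose_file",
    "write_pose_table",
    "report_table",
]

#: Ring systems used for cation-pi detection.  For tryptophan the 6-membered
#: benzene ring of the indole is used, the common convention in contact
#: analysis; histidine is optional (off by default).
AROMATIC_RING_ATOMS = {
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

#: Protein heavy atoms treated as hydrogen-bond donors/acceptors.
POLAR_SIDECHAIN_ATOMS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
    "ASN": ("OD1", "ND2"), "GLN": ("OE1", "NE2"),
    "HIS": ("ND1", "NE2"), "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"), "TRP": ("NE1",), "CYS": ("SG",),
}


@dataclass
class GeomConfig:
    """Geometric thresholds for contact detection and pose classification.

    The cation-pi cutoffs (6.0 Å centroid distance, 60° axial angle) and the
    hydrogen-bond cutoffs (3.5 Å heavy-atom distance, 120° D-H...A angle)
    follow common practice in contact analysis; all are configurable.
    ``aromatic_set`` lists the Torpedo-numbered aromatics whose cation-pi
    contacts count towards the favorable verdict, and ``k_contacts`` how
    many are required.
    """

    d_max: float = 6.0              # Å, cationic N to ring centroid
    theta_max: float = 60.0         # degrees, ring normal vs centroid->N
    include_his: bool = False
    hbond_d_max: float = 3.5        # Å, donor-acceptor heavy-atom distance
    hbond_angle_min: float = 120.0  # degrees, D-H...A when hydrogens present
    cationic_atom: str = "N"
    ligand_polar_atoms: tuple[str, ...] = ("O1", "O2")
    aromatic_set: tuple[int, ...] = (55, 93, 149, 190)
    k_contacts: int = 1


@dataclass
class LigandPose:
    """One docked ligand conformation with its docking score (kcal/mol)."""

    pose_id: str
    atoms: list[Atom]
    binding_energy: float
    interface: InterfaceSpec | None = None
    #: optional per-pose receptor side-chain coordinates (flexible residues),
    #: keyed by (chain_id, author_number, atom_name)
    flexible_atoms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.binding_energy):
            raise ValueError(f"pose {self.pose_id}: non-finite binding energy")

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"pose {self.pose_id}: no atom named {name!r}")

    def heavy_coords(self) -> np.ndarray:
        return np.stack([a.coords for a in self.atoms if a.element.upper() != "H"])

    def coords(self) -> np.ndarray:
        return np.stack([a.coords for a in self.atoms])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LigandPose":
        atoms = [Atom(a.name, a.element, np.asarray(rotation) @ a.coords + translation)
                 for a in self.atoms]
        return replace(self, atoms=atoms)


@dataclass
class PoseEnsemble:
    """All poses docked at one interface (n_runs docking attempts)."""

    interface: InterfaceSpec | None
    poses: list[LigandPose]
    n_runs: int

    def __post_init__(self) -> None:
        if self.n_runs <= 0:
            raise ValueError("n_runs must be positive")
        if len(self.poses) > self.n_runs:
            raise ValueError("more poses than docking runs")


@dataclass(frozen=True)
class CationPiContact:
    torpedo_number: int | None
    residue_name: str
    chain_id: str
    distance: float      # Å, cationic N to ring centroid
    axial_angle: float   # degrees


@dataclass(frozen=True)
class HBondContact:
    torpedo_number: int | None
    residue_name: str
    chain_id: str
    protein_atom: str
    ligand_atom: str
    distance: float      # Å


@dataclass
class InteractionReport:
    pose_id: str
    cation_pi_contacts: list[CationPiContact]
    hbonds: list[HBondContact]
    favorable: bool


@dataclass
class InterfaceSummary:
    interface_class: str
    bbe: float                  # kcal/mol, minimum binding energy
    favorable_frequency: float  # percent of poses favorable
    cluster_count: int
    n_poses: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.favorable_frequency <= 100.0:
            raise ValueError("favorable_frequency must be a percentage")


@dataclass
class PoseCluster:
    seed_id: str
    seed_energy: float
    member_ids: list[str]


def ring_centroid_normal(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a (near-)planar ring via SVD plane fit."""
    coords = np.asarray(coords, float)
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    normal = vt[-1]
    return centroid, normal / np.linalg.norm(normal)


def _interface_residues(model: StructureModel, interface: InterfaceSpec) -> list[Residue]:
    out = []
    for cid in (interface.principal_chain, interface.complementary_chain):
        out.extend(r for r in model.chain(cid).residues if not r.is_ligand)
    return out


def _pose_cationic_n(pose: LigandPose, geom: GeomConfig) -> np.ndarray:
    return pose.atom(geom.cationic_atom).coords


def _residue_atom_coords(residue: Residue, name: str, pose: LigandPose | None):
    """Atom coordinates, preferring per-pose flexible side-chain positions."""
    if pose is not None and pose.flexible_atoms:
        key = (residue.chain_id, residue.author_number, name)
        if key in pose.flexible_atoms:
            return np.asarray(pose.flexible_atoms[key], float)
    a = residue.atom(name)
    return None if a is None else a.coords


def detect_cation_pi(pose: LigandPose, model: StructureModel,
                     interface: InterfaceSpec,
                     geom: GeomConfig | None = None) -> list[CationPiContact]:
    """Cation-pi contacts between the pose's cationic N and pocket aromatics.

    A contact is reported when the N-to-ring-centroid distance is at most
    ``geom.d_max`` and the angle between the ring normal and the
    centroid->N vector is at most ``geom.theta_max`` (the axial angle is
    folded to [0, 90°] since the ring normal's sign is arbitrary).
    """
    geom = geom or GeomConfig()
    n_coords = _pose_cationic_n(pose, geom)
    contacts = []
    for res in _interface_residues(model, interface):
        ring = AROMATIC_RING_ATOMS.get(res.name)
        if ring is None or (res.name == "HIS" and not geom.include_his):
            continue
        ring_coords = [_residue_atom_coords(res, a, pose) for a in ring]
        if any(c is None for c in ring_coords):
            warnings.warn(f"{res.name}{res.author_number}/{res.chain_id}: "
                          "missing ring atoms, residue skipped")
            continue
        centroid, normal = ring_centroid_normal(np.stack(ring_coords))
        vec = n_coords - centroid
        dist = float(np.linalg.norm(vec))
        if dist == 0.0 or dist > geom.d_max:
            continue
        unit = vec / dist
        # atan2 form: well-conditioned near 0 deg, unlike acos; |dot| folds
        # the angle to [0, 90] since the ring normal's sign is arbitrary
        angle = math.degrees(math.atan2(
            float(np.linalg.norm(np.cross(normal, unit))),
            abs(float(np.dot(normal, unit)))))
        if angle <= geom.theta_max:
            contacts.append(CationPiContact(res.torpedo_number, res.name,
                                            res.chain_id, dist, angle))
    contacts.sort(key=lambda c: c.distance)
    return contacts


def detect_hbonds(pose: LigandPose, model: StructureModel,
                  interface: InterfaceSpec,
                  geom: GeomConfig | None = None) -> list[HBondContact]:
    """Hydrogen bonds between ligand polar atoms and protein polar side chains.

    A contact requires a donor-acceptor heavy-atom distance at most
    ``geom.hbond_d_max``; when the donor carries explicit hydrogens the
    D-H...A angle must additionally reach ``geom.hbond_angle_min``.  Without
    hydrogens (the usual docking situation) the distance criterion alone is
    applied.
    """
    geom = geom or GeomConfig()
    lig_atoms = [a for a in pose.atoms if a.name in geom.ligand_polar_atoms]
    contacts = []
    for res in _interface_residues(model, interface):
        polar = POLAR_SIDECHAIN_ATOMS.get(res.name, ())
        for pname in polar:
            pcoords = _residue_atom_coords(res, pname, pose)
            if pcoords is None:
                continue
            for la in lig_atoms:
                dist = float(np.linalg.norm(la.coords - pcoords))
                if dist > geom.hbond_d_max or dist == 0.0:
                    continue
                if not _hydrogen_geometry_ok(res, pname, la.coords, geom):
                    continue
                contacts.append(HBondContact(res.torpedo_number, res.name,
                                             res.chain_id, pname, la.name, dist))
    contacts.sort(key=lambda c: c.distance)
    return contacts


def _hydrogen_geometry_ok(res: Residue, donor_name: str,
                          acceptor: np.ndarray, geom: GeomConfig) -> bool:
    """D-H...A angle check; passes in heavy-atom-only mode (no hydrogens)."""
    donor = res.atom(donor_name)
    if donor is None:
        return True
    hydrogens = [a for a in res.atoms if a.element.upper() == "H"
                 and np.linalg.norm(a.coords - donor.coords) < 1.3]
    if not hydrogens:
        return True
    for h in hydrogens:
        v1 = donor.coords - h.coords
        v2 = acceptor - h.coords
        cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
        if angle >= geom.hbond_angle_min:
            return True
    return False


def classify_pose(pose: LigandPose, model: StructureModel,
                  interface: InterfaceSpec,
                  geom: GeomConfig | None = None) -> InteractionReport:
    """Classify one pose as favorable/unfavorable.

    Favorable means at least ``geom.k_contacts`` cation-pi contacts with the
    conserved aromatic set (default {55, 93, 149, 190}, any one sufficing).
    Hydrogen-bond evidence is recorded but does not enter the verdict.
    """
    geom = geom or GeomConfig()
    cpi = detect_cation_pi(pose, model, interface, geom)
    hb = detect_hbonds(pose, model, interface, geom)
    n_key = sum(1 for c in cpi if c.torpedo_number in geom.aromatic_set)
    return InteractionReport(pose.pose_id, cpi, hb, favorable=n_key >= geom.k_contacts)


def pose_rmsd(a: LigandPose, b: LigandPose) -> float:
    """RMSD between two poses in the common receptor frame (no refitting)."""
    ca, cb = a.coords(), b.coords()
    if ca.shape != cb.shape:
        raise ValueError(
            f"poses {a.pose_id} and {b.pose_id} have different atom counts "
            f"({len(ca)} vs {len(cb)})")
    return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=1))))


def cluster_poses(ensemble: PoseEnsemble, rmsd_cutoff: float = 2.0) -> list[PoseCluster]:
    """Greedy energy-ordered clustering at an RMSD cutoff (default 2.0 Å).

    The lowest-energy unassigned pose seeds a cluster; every unassigned pose
    within the cutoff of that seed joins it; repeat.  Deterministic given
    energies, with ties broken by pose_id lexical order.  Seeds come out in
    non-increasing favourability (non-decreasing energy).
    """
    poses = ensemble.poses
    counts = {len(p.atoms) for p in poses}
    if len(counts) > 1:
        raise ValueError(f"inconsistent atom counts across poses: {sorted(counts)}")
    order = sorted(poses, key=lambda p: (p.binding_energy, p.pose_id))
    unassigned = list(order)
    clusters = []
    while unassigned:
        seed = unassigned.pop(0)
        members = [seed]
        rest = []
        for p in unassigned:
            if pose_rmsd(seed, p) <= rmsd_cutoff:
                members.append(p)
            else:
                rest.append(p)
        unassigned = rest
        clusters.append(PoseCluster(seed.pose_id, seed.binding_energy,
                                    [m.pose_id for m in members]))
    return clusters


def summarize_interface(ensemble: PoseEnsemble,
                        reports: Sequence[InteractionReport],
                        rmsd_cutoff: float = 2.0) -> InterfaceSummary:
    """Per-interface summary: BBE, favorable-pose frequency, cluster count.

    BBE is the minimum binding energy over all poses; the frequency is the
    percentage of classified poses that are favorable (denominator = all
    parsed poses).
    """
    if not ensemble.poses:
        raise ValueError("cannot summarize an empty ensemble")
    if len(reports) != len(ensemble.poses):
        raise ValueError("one InteractionReport per pose required")
    bbe = min(p.binding_energy for p in ensemble.poses)
    freq = 100.0 * sum(r.favorable for r in reports) / len(reports)
    n_clusters = len(cluster_poses(ensemble, rmsd_cutoff))
    label = ensemble.interface.class_label if ensemble.interface else "unknown"
    return InterfaceSummary(label, bbe, freq, n_clusters, len(ensemble.poses))


def average_summaries(summaries: Sequence[InterfaceSummary]) -> dict:
    """Mean and SEM of BBE and favorable frequency across replicate runs."""
    if not summaries:
        raise ValueError("no summaries to average")
    bbe = np.array([s.bbe for s in summaries], float)
    freq = np.array([s.favorable_frequency for s in summaries], float)
    n = len(summaries)
    sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return {
        "interface_class": summaries[0].interface_class,
        "n_replicates": n,
        "bbe_mean": float(bbe.mean()), "bbe_sem": sem(bbe),
        "favorable_frequency_mean": float(freq.mean()),
        "favorable_frequency_sem": sem(freq),
    }


# ---------------------------------------------------------------------------
# Pose file I/O: multi-model PDB, AutoDock DLG excerpts, delimited tables
# ---------------------------------------------------------------------------

_DLG_ENERGY_RE = re.compile(r"Estimated Free Energy of Binding\s*=\s*([-+0-9.eE]+)")
_REMARK_ENERGY_RE = re.compile(r"REMARK.*?(?:ENERGY|Energy|energy)\D*?([-+]?\d+\.?\d*(?:[eE][-+]?\d+)?)")


def read_pose_file(source: str, dialect: str | None = None,
                   interface: InterfaceSpec | None = None,
                   n_runs: int | None = None) -> PoseEnsemble:
    """Read a pose ensemble from PDB (multi-MODEL), AutoDock DLG, or a table.

    Dialect is auto-detected unless forced: ``"dlg"`` for AutoDock log
    excerpts (``DOCKED:`` records), ``"pdb"`` for multi-model PDB with a
    REMARK energy per model, ``"table"`` for a delimited file with columns
    (pose, energy, atom, x, y, z).  Poses keep file order; a pose without an
    energy is an error.
    """
    text = _read_text(source)
    if dialect is None:
        if "DOCKED:" in text:
            dialect = "dlg"
        elif re.search(r"^(MODEL|ATOM|HETATM|REMARK)", text, re.M):
            dialect = "pdb"
        elif "," in text or "\t" in text:
            dialect = "table"
        else:
            raise ValueError("cannot detect pose-file dialect (pdb/dlg/table)")
    if dialect == "dlg":
        poses = _read_dlg(text)
    elif dialect == "pdb":
        poses = _read_multimodel_pdb(text)
    elif dialect == "table":
        poses = _read_pose_table(text)
    else:
        raise ValueError(f"unknown pose-file dialect {dialect!r}")
    if not poses:
        raise ValueError("no poses found in input")
    for p in poses:
        p.interface = interface
    return PoseEnsemble(interface, poses, n_runs=n_runs or len(poses))


def _read_multimodel_pdb(text: str) -> list[LigandPose]:
    poses = []
    current_atoms: list[Atom] = []
    energy: float | None = None
    idx = 0

    def flush():
        nonlocal current_atoms, energy, idx
        if current_atoms:
            idx += 1
            if energy is None:
                raise ValueError(f"pose {idx}: no REMARK energy record")
            poses.append(LigandPose(f"pose{idx:03d}", current_atoms, energy))
        current_atoms, energy = [], None

    from .structures import _parse_atom_line
    for lineno, line in enumerate(text.splitlines(), 1):
        rec = line[:6].strip()
        if rec == "MODEL":
            flush()
        elif rec == "ENDMDL":
            flush()
        elif rec == "REMARK":
            m = _REMARK_ENERGY_RE.search(line)
            if m:
                energy = float(m.group(1))
        elif rec in ("ATOM", "HETATM"):
            *_, atom, _h = _parse_atom_line(line, lineno)
            current_atoms.append(atom)
    flush()
    return poses


def _read_dlg(text: str) -> list[LigandPose]:
    poses = []
    in_block = False
    atoms: list[Atom] = []
    energy: float | None = None
    idx = 0
    from .structures import _parse_atom_line
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.startswith("DOCKED:"):
            if in_block and atoms:
                idx += 1
                if energy is None:
                    raise ValueError(f"DOCKED block {idx}: missing "
                                     "'Estimated Free Energy of Binding'")
                poses.append(LigandPose(f"pose{idx:03d}", atoms, energy))
                atoms, energy, in_block = [], None, False
            continue
        in_block = True
        payload = line[len("DOCKED:"):].lstrip()
        if payload.startswith("USER"):
            m = _DLG_ENERGY_RE.search(payload)
            if m:
                energy = float(m.group(1))
        elif payload.startswith(("ATOM", "HETATM")):
            *_, atom, _h = _parse_atom_line(payload, lineno)
            atoms.append(atom)
        elif payload.startswith("ENDMDL"):
            idx += 1
            if energy is None:
                raise ValueError(f"DOCKED block {idx}: missing "
                                 "'Estimated Free Energy of Binding'")
            poses.append(LigandPose(f"pose{idx:03d}", atoms, energy))
            atoms, energy, in_block = [], None, False
    if atoms:
        idx += 1
        if energy is None:
            raise ValueError(f"DOCKED block {idx}: missing "
                             "'Estimated Free Energy of Binding'")
        poses.append(LigandPose(f"pose{idx:03d}", atoms, energy))
    return poses


def _read_pose_table(text: str) -> list[LigandPose]:
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"pose", "energy", "atom", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"pose table needs columns {sorted(required)}, "
                         f"got {list(df.columns)}")
    poses = []
    for pose_id, grp in df.groupby("pose", sort=False):
        energies = grp["energy"].unique()
        if len(energies) != 1 or pd.isna(energies[0]):
            raise ValueError(f"pose {pose_id}: missing or ambiguous energy")
        atoms = [Atom(str(r.atom), _element_of(str(r.atom)),
                      np.array([r.x, r.y, r.z], float))
                 for r in grp.itertuples()]
        poses.append(LigandPose(str(pose_id), atoms, float(energies[0])))
    return poses


def _element_of(atom_name: str) -> str:
    return "".join(ch for ch in atom_name if ch.isalpha())[:1] or "X"


def write_pose_table(ensemble: PoseEnsemble) -> str:
    """Serialize an ensemble to the (pose, energy, atom, x, y, z) CSV dialect."""
    rows = []
    for p in ensemble.poses:
        for a in p.atoms:
            rows.append({"pose": p.pose_id, "energy": p.binding_energy,
                         "atom": a.name, "x": a.coords[0], "y": a.coords[1],
                         "z": a.coords[2]})
    return pd.DataFrame(rows).to_csv(index=False)


def report_table(reports: Iterable[InteractionReport]) -> pd.DataFrame:
    """Per-pose report as a flat DataFrame (one row per pose)."""
    rows = []
    for r in reports:
        rows.append({
            "pose_id": r.pose_id,
            "favorable": r.favorable,
            "n_cation_pi": len(r.cation_pi_contacts),
            "cation_pi_residues": ";".join(
                f"{c.residue_name}{c.torpedo_number}" for c in r.cation_pi_contacts),
            "n_hbonds": len(r.hbonds),
            "hbond_residues": ";".join(
                f"{c.residue_name}{c.torpedo_number}" for c in r.hbonds),
        })
    return pd.DataFrame(rows)
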