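"""Binding-pocket charge environment profiling.

Three views of the electrostatic surroundings of the agonist site: (i) the
residues lining the pocket (any heavy atom within a radius of any ligand
heavy atom, 5 Å by default), (ii) the radial distribution of charged
side-chain groups around the ligand's cationic nitrogen (10 Å by default),
and (iii) the acidic/basic balance of a sequence region (R+K minus D+E, the
whole-domain bookkeeping used to compare subunits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pose_analysis import LigandPose
from .structures import InterfaceSpec, Residue, StructureModel

__all__ = [
    "ChargedGroup",
    "ChargeProfile",
    "ChargeBalance",
    "CHARGED_RESIDUES",
    "pocket_residues",
    "radial_charge_profile",
    "sequence_charge_balance",
    "profile_table",
]

#: Charge sign per residue type.  Histidine is deliberately excluded: the
#: whole-domain balance counts only R/K vs D/E.
CHARGED_RESIDUES = {"ASP": "-", "GLU": "-", "ARG": "+", "LYS": "+"}

#: Representative point per charged side chain: guanidinium carbon for Arg,
#: terminal amine nitrogen for Lys, carboxylate-oxygen midpoint for Asp/Glu.
#: Chosen for stability to hydrogen absence.
_REPRESENTATIVE = {
    "ARG": ("CZ",),
    "LYS": ("NZ",),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


@dataclass(frozen=True)
class ChargedGroup:
    torpedo_number: int | None
    residue_name: str
    charge_sign: str               # '+' or '-'
    face: str                      # 'principal' or 'complementary'
    point: tuple[float, float, float]

    def __post_init__(self) -> None:
        expected = CHARGED_RESIDUES.get(self.residue_name)
        if expected is not None and expected != self.charge_sign:
            raise ValueError(
                f"{self.residue_name}: charge sign must be {expected!r}")


@dataclass
class ChargeProfile:
    """Charged groups around the ligand cationic N, sorted by distance."""

    reference_point: tuple[float, float, float]
    entries: list[tuple[ChargedGroup, float]]
    radius: float

    def __post_init__(self) -> None:
        dists = [d for _, d in self.entries]
        if any(d > self.radius + 1e-9 for d in dists):
            raise ValueError("profile entry beyond radius")
        if any(b < a for a, b in zip(dists, dists[1:])):
            raise ValueError("profile entries must be sorted ascending")


@dataclass(frozen=True)
class ChargeBalance:
    acidic_count: int   # D + E
    basic_count: int    # R + K
    skipped: int = 0    # non-standard letters ignored

    @property
    def balance(self) -> int:
        return self.basic_count - self.acidic_count

    def __add__(self, other: "ChargeBalance") -> "ChargeBalance":
        return ChargeBalance(self.acidic_count + other.acidic_count,
                             self.basic_count + other.basic_count,
                             self.skipped + other.skipped)


def _face_of(residue: Residue, interface: InterfaceSpec) -> str | None:
    """Face assignment follows the interface's chain roles, not geometry."""
    if residue.chain_id == interface.principal_chain:
        return "principal"
    if residue.chain_id == interface.complementary_chain:
        return "complementary"
    return None


def _interface_residues(model: StructureModel, interface: InterfaceSpec):
    for cid in (interface.principal_chain, interface.complementary_chain):
        for r in model.chain(cid).residues:
            if not r.is_ligand:
                yield r


def pocket_residues(model: StructureModel, interface: InterfaceSpec,
                    ligand: LigandPose | Sequence, radius: float = 5.0
                    ) -> list[tuple[Residue, str, float]]:
    """Residues lining the pocket: heavy-atom min distance within ``radius``.

    Returns ``(residue, face, min_distance)`` tuples sorted by distance.
    A residue qualifies when any of its heavy atoms lies within ``radius``
    of any ligand heavy atom.
    """
    lig_coords = _ligand_heavy_coords(ligand)
    if lig_coords.size == 0:
        raise ValueError("no ligand heavy atoms supplied")
    out = []
    for res in _interface_residues(model, interface):
        coords = res.heavy_coords()
        if coords.size == 0:
            continue
        d = np.linalg.norm(coords[:, None, :] - lig_coords[None, :, :], axis=2)
        dmin = float(d.min())
        if dmin <= radius:
            out.append((res, _face_of(res, interface), dmin))
    out.sort(key=lambda t: t[2])
    return out


def _ligand_heavy_coords(ligand) -> np.ndarray:
    if isinstance(ligand, LigandPose):
        return ligand.heavy_coords()
    if isinstance(ligand, Residue):
        return ligand.heavy_coords()
    arr = np.asarray([getattr(a, "coords", a) for a in ligand], float)
    return arr.reshape(-1, 3)


def representative_point(residue: Residue) -> np.ndarray | None:
    """Charged-group representative point, or None if atoms are missing."""
    names = _REPRESENTATIVE.get(residue.name)
    if names is None:
        return None
    atoms = [residue.atom(n) for n in names]
    if any(a is None for a in atoms):
        return None
    return np.mean([a.coords for a in atoms], axis=0)


def radial_charge_profile(model: StructureModel, interface: InterfaceSpec,
                          cationic_n: np.ndarray | Sequence[float],
                          radius: float = 10.0) -> ChargeProfile:
    """Distance distribution of charged groups from the ligand cationic N.

    All Arg/Lys/Asp/Glu of the interface's two chains whose representative
    point lies within ``radius`` of the cationic nitrogen are listed with
    their sign, face annotation and distance, sorted ascending.  Residues
    with missing side-chain atoms are skipped with a warning.
    """
    ref = np.asarray(cationic_n, float).reshape(3)
    entries = []
    for res in _interface_residues(model, interface):
        sign = CHARGED_RESIDUES.get(res.name)
        if sign is None:
            continue
        point = representative_point(res)
        if point is None:
            warnings.warn(f"{res.name}{res.author_number}/{res.chain_id}: "
                          "missing side-chain atoms, group skipped")
            continue
        dist = float(np.linalg.norm(point - ref))
        if dist <= radius:
            group = ChargedGroup(res.torpedo_number, res.name, sign,
                                 _face_of(res, interface), tuple(point))
            entries.append((group, dist))
    entries.sort(key=lambda e: e[1])
    return ChargeProfile(tuple(ref), entries, radius)


def sequence_charge_balance(sequence: str,
                            region: tuple[int, int] | None = None,
                            on_nonstandard: str = "warn") -> ChargeBalance:
    """Acidic (D+E) and basic (R+K) residue counts over a sequence region.

    ``region`` is a 1-based inclusive (start, end) window; default is the
    whole sequence.  Non-standard letters are skipped with a warning by
    default (``on_nonstandard="error"`` raises instead).
    """
    seq = sequence.upper()
    if region is not None:
        start, end = region
        if not (1 <= start <= end <= len(seq)):
            raise ValueError(f"region {region} out of bounds for length {len(seq)}")
        seq = seq[start - 1:end]
    standard = set("ACDEFGHIKLMNPQRSTVWY")
    bad = [c for c in seq if c not in standard]
    if bad:
        if on_nonstandard == "error":
            raise ValueError(f"non-standard residue letters: {sorted(set(bad))}")
        warnings.warn(f"skipping non-standard residue letters: {sorted(set(bad))}")
    acidic = seq.count("D") + seq.count("E")
    basic = seq.count("R") + seq.count("K")
    return ChargeBalance(acidic, basic, skipped=len(bad))


def profile_table(profile: ChargeProfile) -> pd.DataFrame:
    """Radial charge profile as a DataFrame sorted by distance."""
    return pd.DataFrame(
        [{"torpedo_number": g.torpedo_number, "residue": g.residue_name,
          "charge_sign": g.charge_sign, "face": g.face,
          "distance_A": d} for g, d in profile.entries])
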