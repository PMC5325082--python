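"""Receptor structure models, residue-numbering maps, and interface enumeration.

Pentameric ligand-gated ion channels carry their agonist sites at the
interface between adjacent subunits: a principal (+) face contributed by one
subunit (loops A-C) and a complementary (-) face from its neighbour (loops
D-F).  This module reads PDB-format models, keeps a per-chain map from the
author residue numbering to the mature Torpedo alpha1 convention (the
field's standard for naming conserved positions such as W55, Y190 or R117),
and enumerates the five interfaces of an arbitrary circular subunit
arrangement such as (alpha9)2(alpha10)3.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import AlignIO
from Bio.SeqUtils import seq1

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "InterfaceSpec",
    "NumberingMap",
    "PDBParseError",
    "NumberingMismatchError",
    "STANDARD_RESIDUES",
    "load_structure",
    "load_structures",
    "write_structure",
    "build_numbering_map",
    "enumerate_interfaces",
    "interface_table",
]

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Canonical subunit labels used in interface class names.
SUBUNIT_LABELS = ("a9", "a10", "other")


class PDBParseError(ValueError):
    """Raised when a PDB record cannot be parsed; names the offending line."""


class NumberingMismatchError(ValueError):
    """Raised when an alignment's target sequence disagrees with a chain."""


def normalize_subunit_label(label: str) -> str:
    lab = label.replace("α", "a").replace("alpha", "a").strip().lower()
    if lab in ("a9", "a10"):
        return lab
    return "other"


@dataclass
class Atom:
    """A single atom: PDB atom name, element symbol and coordinates in Å."""

    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: empty element symbol")


@dataclass
class Residue:
    """One residue of a chain.

    ``author_number`` is the residue number as printed in the source file;
    ``torpedo_number`` is the mapped mature Torpedo alpha1 position (set by
    :func:`build_numbering_map` or by a synthetic generator), used for all
    analysis-level residue identities.
    """

    chain_id: str
    author_number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    torpedo_number: int | None = None
    is_ligand: bool = False

    def __post_init__(self) -> None:
        if self.torpedo_number is not None and self.torpedo_number <= 0:
            raise ValueError("torpedo_number must be positive when set")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element.upper() != "H"]

    def heavy_coords(self) -> np.ndarray:
        atoms = self.heavy_atoms()
        if not atoms:
            return np.empty((0, 3))
        return np.stack([a.coords for a in atoms])

    @property
    def one_letter(self) -> str:
        return seq1(self.name.capitalize(), undef_code="X")


@dataclass
class Chain:
    chain_id: str
    subunit_label: str = "other"
    residues: list[Residue] = field(default_factory=list)

    def residue_by_author(self, number: int) -> Residue | None:
        for r in self.residues:
            if r.author_number == number:
                return r
        return None

    def residue_by_torpedo(self, number: int) -> Residue | None:
        for r in self.residues:
            if r.torpedo_number == number:
                return r
        return None

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues if not r.is_ligand)


@dataclass
class StructureModel:
    """An ordered collection of chains (plus any ligand residues)."""

    chains: list[Chain] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate chain_id in StructureModel")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in model")

    def residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c.residues

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with ``x -> R x + t`` applied to every atom."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        chains = []
        for c in self.chains:
            residues = []
            for r in c.residues:
                atoms = [Atom(a.name, a.element, rotation @ a.coords + translation)
                         for a in r.atoms]
                residues.append(Residue(r.chain_id, r.author_number, r.name, atoms,
                                        r.torpedo_number, r.is_ligand))
            chains.append(Chain(c.chain_id, c.subunit_label, residues))
        return StructureModel(chains, source=self.source)


# ---------------------------------------------------------------------------
# PDB I/O.  Fixed-column ATOM/HETATM records; one StructureModel per MODEL.
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> tuple[str, str, int, str, Atom, bool]:
    try:
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain_id = line[21].strip() or "A"
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed coordinate record: {line.rstrip()!r}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = "".join(ch for ch in name if ch.isalpha())[:1] or "X"
    hetero = line.startswith("HETATM")
    return chain_id, resname, resseq, name, Atom(name, element, np.array([x, y, z])), hetero


def load_structures(pdb_source: str) -> list[StructureModel]:
    """Parse PDB text (or a path to it) into one StructureModel per MODEL.

    Files without MODEL records yield a single model.  Non-standard residue
    names (ligands, waters) are kept and flagged ``is_ligand``.
    """
    text = _read_text(pdb_source)
    if not text.strip():
        raise PDBParseError("empty PDB input")

    models: list[StructureModel] = []
    chains: dict[str, Chain] = {}
    chain_order: list[str] = []
    current: dict[tuple[str, int, str], Residue] = {}

    def flush() -> None:
        nonlocal chains, chain_order, current
        if chains:
            models.append(StructureModel([chains[cid] for cid in chain_order],
                                         source="pdb"))
        chains, chain_order, current = {}, [], {}

    any_record = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            flush()
        elif rec == "ENDMDL":
            flush()
        elif rec in ("ATOM", "HETATM"):
            any_record = True
            chain_id, resname, resseq, _, atom, hetero = _parse_atom_line(line, lineno)
            key = (chain_id, resseq, resname)
            if key not in current:
                res = Residue(chain_id, resseq, resname,
                              is_ligand=hetero or resname not in STANDARD_RESIDUES)
                current[key] = res
                if chain_id not in chains:
                    chains[chain_id] = Chain(chain_id)
                    chain_order.append(chain_id)
                chains[chain_id].residues.append(res)
            current[key].atoms.append(atom)
    flush()

    if not any_record:
        raise PDBParseError("no ATOM/HETATM records in PDB input")
    return models


def load_structure(pdb_source: str) -> StructureModel:
    """Parse single-model PDB text; raises if the file holds several MODELs."""
    models = load_structures(pdb_source)
    if len(models) != 1:
        raise PDBParseError(
            f"expected a single model, found {len(models)}; use load_structures()")
    return models[0]


def write_structure(model: StructureModel) -> str:
    """Serialize a StructureModel back to PDB text (coordinates to 3 dp)."""
    out = io.StringIO()
    serial = 0
    for chain in model.chains:
        for res in chain.residues:
            record = "HETATM" if res.is_ligand else "ATOM  "
            for atom in res.atoms:
                serial += 1
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                out.write(
                    f"{record}{serial:5d} {name:<4.4s} {res.name:<3.3s} {chain.chain_id:1.1s}"
                    f"{res.author_number:4d}    "
                    f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
                    f"{1.0:6.2f}{0.0:6.2f}          {atom.element:>2.2s}\n")
        out.write("TER\n")
    out.write("END\n")
    return out.getvalue()


def _read_text(source: str) -> str:
    """Accept raw text or a filesystem path."""
    s = str(source)
    if "\n" not in s and len(s) < 4096:
        try:
            from pathlib import Path
            p = Path(s)
            if p.is_file():
                return p.read_text()
        except OSError:
            pass
    return s


# ---------------------------------------------------------------------------
# Numbering maps (author numbering -> mature Torpedo alpha1 numbering)
# ---------------------------------------------------------------------------

class NumberingMap:
    """Strictly increasing map author_number -> torpedo_number for one chain.

    Built from a pairwise alignment of the chain's sequence against the
    mature Torpedo alpha1 reference; aligned non-gap columns each contribute
    one entry, gaps contribute none.
    """

    def __init__(self, chain_id: str, entries: dict[int, int]):
        self.chain_id = chain_id
        self._fwd = dict(sorted(entries.items()))
        keys = list(self._fwd)
        vals = list(self._fwd.values())
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("numbering map must be strictly increasing")
        if any(v <= 0 for v in vals):
            raise ValueError("torpedo numbers must be positive")
        self._inv = {v: k for k, v in self._fwd.items()}
        assert len(self._inv) == len(keys)

    def __len__(self) -> int:
        return len(self._fwd)

    def to_torpedo(self, author_number: int) -> int | None:
        return self._fwd.get(author_number)

    def to_author(self, torpedo_number: int) -> int | None:
        return self._inv.get(torpedo_number)

    def items(self):
        return self._fwd.items()


def _parse_alignment(alignment, fmt: str | None = None):
    if hasattr(alignment, "__len__") and not isinstance(alignment, str):
        return alignment
    text = _read_text(alignment)
    for f in ([fmt] if fmt else ["fasta", "clustal"]):
        try:
            return AlignIO.read(io.StringIO(text), f)
        except ValueError:
            continue
    raise ValueError("could not parse alignment as FASTA or Clustal")


def build_numbering_map(alignment, model: StructureModel, chain_id: str,
                        reference: int | str = 1, fmt: str | None = None,
                        apply: bool = True) -> NumberingMap:
    """Build the author->Torpedo numbering map for one chain.

    Parameters
    ----------
    alignment
        A two-record pairwise alignment (FASTA/Clustal text, path, or a
        Biopython alignment object): the chain's own sequence and the mature
        Torpedo alpha1 reference.
    reference
        Which record is the Torpedo reference: an index (default 1, i.e. the
        second record) or a record id.
    apply
        When true, write the mapped torpedo_number onto the chain residues.
    """
    aln = _parse_alignment(alignment, fmt)
    if len(aln) != 2:
        raise ValueError(f"pairwise alignment required, got {len(aln)} records")
    if isinstance(reference, str):
        ids = [rec.id for rec in aln]
        if reference not in ids:
            raise ValueError(f"reference id {reference!r} not in alignment {ids}")
        ref_idx = ids.index(reference)
    else:
        ref_idx = int(reference)
    target = str(aln[1 - ref_idx].seq).upper()
    ref = str(aln[ref_idx].seq).upper()

    chain = model.chain(chain_id)
    chain_res = [r for r in chain.residues if not r.is_ligand]
    chain_seq = "".join(r.one_letter for r in chain_res)
    target_ungapped = target.replace("-", "")
    if chain_seq != target_ungapped:
        n = min(len(chain_seq), len(target_ungapped))
        pos = next((i for i in range(n) if chain_seq[i] != target_ungapped[i]), n)
        got = chain_seq[pos] if pos < len(chain_seq) else "<end>"
        want = target_ungapped[pos] if pos < len(target_ungapped) else "<end>"
        raise NumberingMismatchError(
            f"chain {chain_id}: alignment target disagrees with chain sequence at "
            f"target position {pos + 1}: chain has {got!r}, alignment has {want!r}")

    entries: dict[int, int] = {}
    ti = ri = 0
    for tcol, rcol in zip(target, ref):
        t_here = tcol != "-"
        r_here = rcol != "-"
        if r_here:
            ri += 1
        if t_here:
            residue = chain_res[ti]
            ti += 1
            if r_here:
                entries[residue.author_number] = ri
    nmap = NumberingMap(chain_id, entries)
    if apply:
        for r in chain_res:
            r.torpedo_number = nmap.to_torpedo(r.author_number)
    return nmap


# ---------------------------------------------------------------------------
# Interface enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InterfaceSpec:
    """One subunit-subunit agonist-site interface of a pentamer.

    ``principal_chain`` contributes the (+) face (loops A-C) and
    ``complementary_chain`` the (-) face (loops D-F); ``class_label`` is the
    interface type, e.g. ``a10(+)a9(-)``.
    """

    principal_chain: str
    complementary_chain: str
    class_label: str

    def __post_init__(self) -> None:
        if self.principal_chain == self.complementary_chain:
            raise ValueError("principal and complementary chains must differ")


def interface_class(principal_label: str, complementary_label: str) -> str:
    return (f"{normalize_subunit_label(principal_label)}(+)"
            f"{normalize_subunit_label(complementary_label)}(-)")


def parse_interface_class(text: str) -> str:
    """Normalize a user-supplied interface class such as ``a10+a9-``."""
    t = text.replace("α", "a").lower().replace("(", "").replace(")", "")
    if t.count("+") == 1 and t.endswith("-"):
        p, c = t[:-1].split("+")
        return interface_class(p, c)
    raise ValueError(f"cannot parse interface class {text!r} (expected e.g. 'a10+a9-')")


def enumerate_interfaces(model: StructureModel, arrangement: Sequence[str],
                         orientation: str = "forward") -> list[InterfaceSpec]:
    """Enumerate the 5 interfaces of a circular pentamer arrangement.

    ``arrangement`` lists the subunit labels of the model's chains in ring
    order (chain i carries label arrangement[i]).  Under the default
    ``forward`` orientation the principal face of subunit i pairs with the
    complementary face of subunit i+1 (ring-wrapped); ``reverse`` pairs it
    with subunit i-1.  Every chain appears exactly once as principal and
    once as complementary.
    """
    if len(arrangement) != 5:
        raise ValueError(f"pentamer arrangement must have 5 labels, got {len(arrangement)}")
    if len(model.chains) != 5:
        raise ValueError(f"model must have 5 chains, got {len(model.chains)}")
    if orientation not in ("forward", "reverse"):
        raise ValueError("orientation must be 'forward' or 'reverse'")
    labels = [normalize_subunit_label(a) for a in arrangement]
    for chain, lab in zip(model.chains, labels):
        if chain.subunit_label == "other":
            chain.subunit_label = lab
        elif chain.subunit_label != lab:
            raise ValueError(
                f"chain {chain.chain_id} is labelled {chain.subunit_label}, "
                f"arrangement says {lab}")
    step = 1 if orientation == "forward" else -1
    interfaces = []
    for i in range(5):
        j = (i + step) % 5
        interfaces.append(InterfaceSpec(
            principal_chain=model.chains[i].chain_id,
            complementary_chain=model.chains[j].chain_id,
            class_label=interface_class(labels[i], labels[j])))
    return interfaces


def interface_table(interfaces: Iterable[InterfaceSpec]):
    """Interfaces as a pandas DataFrame (chain pair, class label)."""
    import pandas as pd

    return pd.DataFrame(
        [{"principal_chain": i.principal_chain,
          "complementary_chain": i.complementary_chain,
          "class_label": i.class_label} for i in interfaces])
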