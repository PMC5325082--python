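import numpy as np
import pytest

import pentasite as ps


@pytest.fixture(scope="session")
def toy_bundle():
    """Default toy pentamer: (model, pocket interface, ground truth)."""
    return ps.gen_toy_pentamer()


@pytest.fixture()
def toy_ligand_pose(toy_bundle):
    """The planted ligand as a LigandPose (energy 0) in the pocket frame."""
    model, iface, _ = toy_bundle
    lig = next(r for c in model.chains for r in c.residues if r.is_ligand)
    return ps.LigandPose("lig", list(lig.atoms), 0.0, iface)


def random_rigid_transform(rng):
    """A uniformly random rotation matrix and a translation in [-50, 50]^3."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.uniform(-50, 50, size=3)


def bare_pentamer():
    """Five one-residue chains with no subunit labels, for arrangement tests."""
    chains = []
    for i, cid in enumerate("ABCDE"):
        atom = ps.Atom("CA", "C", np.array([float(i), 0.0, 0.0]))
        chains.append(ps.Chain(cid, "other", [ps.Residue(cid, 1, "GLY", [atom])]))
    return ps.StructureModel(chains, source="bare")
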