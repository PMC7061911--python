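"""Shared fixtures: hand-written PDB snippets and synthetic builders."""

import numpy as np
import pytest

from vhhkit import structure_io, synthetic


def atom_line(serial, name, resname, chain, resseq, x, y, z,
              occ=1.0, altloc=" ", icode=" ", element=None):
    """Format one fixed-width ATOM record."""
    element = element or name[0]
    return (f"ATOM  {serial:5d} {name:^4s}{altloc}{resname:>3s} {chain}"
            f"{resseq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}"
            f"{0.0:6.2f}          {element:>2s}")


def make_pdb(residues, chain="A"):
    """PDB text from [(resseq, resname, {atom: (x, y, z)}), ...]."""
    lines, serial = [], 1
    for resseq, resname, atoms in residues:
        for name, xyz in atoms.items():
            lines.append(atom_line(serial, name, resname, chain, resseq, *xyz))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def tripeptide_pdb():
    """Minimal hand-written 3-residue backbone."""
    res = []
    for i in range(3):
        x = 3.8 * i
        res.append((i + 1, "ALA", {
            "N": (x, 0.0, 0.0), "CA": (x + 1.2, 0.8, 0.0),
            "C": (x + 2.5, 0.2, 0.3)}))
    return make_pdb(res)


@pytest.fixture
def strand_chain():
    """20-residue ideal central-strand backbone."""
    return synthetic.build_backbone_from_pb_string("d" * 20)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_rigid_transform(rng):
    """A random proper rotation matrix and translation vector."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(
        int(rng.integers(2 ** 31)))).as_matrix()
    t = rng.normal(0, 20, 3)
    return R, t


def apply_rigid(chain, R, t):
    """Return a copy of a BackboneChain under x -> R x + t."""
    new = []
    for r in chain.residues:
        fields = {}
        for name in ("n", "ca", "c", "o", "cb", "sg"):
            v = getattr(r, name)
            fields[name] = None if v is None else R @ v + t
        new.append(structure_io.Residue(
            number=r.number, icode=r.icode, name=r.name, **fields))
    return structure_io.BackboneChain(chain_id=chain.chain_id, residues=new)


def mirror(chain):
    """Reflect a chain through the x=0 plane (negate x)."""
    M = np.diag([-1.0, 1.0, 1.0])
    new = []
    for r in chain.residues:
        fields = {}
        for name in ("n", "ca", "c", "o", "cb", "sg"):
            v = getattr(r, name)
            fields[name] = None if v is None else M @ v
        new.append(structure_io.Residue(
            number=r.number, icode=r.icode, name=r.name, **fields))
    return structure_io.BackboneChain(chain_id=chain.chain_id, residues=new)
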