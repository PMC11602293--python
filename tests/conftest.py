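import numpy as np
import pytest

from mscscreen import Structure, load_apry_sites


def pdb_atom_line(serial, name, resname, chain, resseq, x, y, z, element="C"):
    return (f"ATOM  {serial:>5d} {name:<4s}{'':1s}{resname:>3s} {chain}"
            f"{resseq:>4d}{'':1s}   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2s}")


def write_pdb(path, atoms, model_blocks=None):
    """atoms: list of (serial, name, resname, chain, resseq, xyz)."""
    lines = []
    if model_blocks is None:
        model_blocks = [atoms]
    for k, block in enumerate(model_blocks, start=1):
        if len(model_blocks) > 1:
            lines.append(f"MODEL     {k:>4d}")
        for serial, name, resname, chain, resseq, (x, y, z) in block:
            lines.append(pdb_atom_line(serial, name, resname, chain, resseq, x, y, z))
        if len(model_blocks) > 1:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def triad_pdb(tmp_path):
    """Hand-written 3-residue PDB mirroring the catalytic-triad numbering."""
    atoms = [
        (1, "CA", "ASP", "A", 32, (1.0, 2.0, 3.0)),
        (2, "CA", "HIS", "A", 64, (4.0, 5.0, 6.0)),
        (3, "CA", "SER", "A", 221, (7.0, 8.0, 9.0)),
    ]
    return write_pdb(tmp_path / "triad.pdb", atoms)


@pytest.fixture(scope="session")
def apry_table():
    return load_apry_sites()


@pytest.fixture(scope="session")
def anchor_structure():
    """Single apolar receptor atom at the origin (for bound-ligand pulls)."""
    return Structure(
        residue_ids=[1], residue_names=["LEU"], atom_names=["CA"],
        atom_residue_ids=np.array([1]), coordinates=np.array([[0.0, 0.0, 0.0]]),
    )
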