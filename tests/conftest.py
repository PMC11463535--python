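"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import struct

import gemmi
import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem, rdDistGeom

from mcligand.benchmark import (build_true_model, ramp_bfactors, simulate_map,
                                single_conformer_input)
from mcligand.ligand import LigandModel, assign_bond_orders

TOY_SMILES = "c1ccccc1CCCCCO"      # 12 heavy atoms


def embed_smiles(smiles: str, seed: int = 7) -> tuple[Chem.Mol, np.ndarray]:
    mol = Chem.MolFromSmiles(smiles)
    params = rdDistGeom.ETKDGv3()
    params.randomSeed = seed
    assert rdDistGeom.EmbedMolecule(mol, params) == 0
    AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
    return mol, np.array(mol.GetConformer().GetPositions())


def make_ligand(smiles: str = TOY_SMILES, seed: int = 7,
                chain: str = "A", resnum: int = 401,
                b_factor: float = 15.0) -> LigandModel:
    mol, coords = embed_smiles(smiles, seed)
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    counts: dict[str, int] = {}
    names = []
    for el in elements:
        counts[el] = counts.get(el, 0) + 1
        names.append(f"{el}{counts[el]}")
    return LigandModel(
        atom_names=names, elements=elements, coords=coords,
        b_factors=np.full(len(names), b_factor),
        occupancies=np.ones(len(names)), altlocs=[""] * len(names),
        chain=chain, resnum=resnum, resname="LIG")


def ligand_to_structure(ligand: LigandModel,
                        cell: gemmi.UnitCell | None = None) -> gemmi.Structure:
    st = gemmi.Structure()
    if cell is not None:
        st.cell = cell
    st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    ch = gemmi.Chain(ligand.chain)
    res = gemmi.Residue()
    res.name = ligand.resname
    res.seqid = gemmi.SeqId(ligand.resnum, " ")
    res.het_flag = "H"
    for j, name in enumerate(ligand.atom_names):
        atom = gemmi.Atom()
        atom.name = name
        atom.element = gemmi.Element(ligand.elements[j])
        atom.pos = gemmi.Position(*map(float, ligand.coords[j]))
        atom.occ = float(ligand.occupancies[j])
        atom.b_iso = float(ligand.b_factors[j])
        if ligand.altlocs[j]:
            atom.altloc = ligand.altlocs[j]
        res.add_atom(atom)
    ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_ccp4_raw(path, values, cell_abc, axis_order=(1, 2, 3)):
    """Minimal CCP4 writer used as an independent fixture generator.

    `values` is indexed [x, y, z]; `axis_order` = (MAPC, MAPR, MAPS) with
    1=x, 2=y, 3=z, so permuted-axis twins of the same field can be written.
    """
    values = np.asarray(values, dtype=np.float32)
    mapc, mapr, maps_ = axis_order
    data = np.ascontiguousarray(values.transpose(maps_ - 1, mapr - 1, mapc - 1))
    ns, nr, nc = data.shape
    header = bytearray(1024)
    ints = {1: nc, 2: nr, 3: ns, 4: 2, 5: 0, 6: 0, 7: 0,
            8: values.shape[0], 9: values.shape[1], 10: values.shape[2],
            17: mapc, 18: mapr, 19: maps_, 23: 1, 24: 0}
    for w, v in ints.items():
        struct.pack_into("<i", header, (w - 1) * 4, v)
    for w, v in zip(range(11, 17), (*cell_abc, 90.0, 90.0, 90.0)):
        struct.pack_into("<f", header, (w - 1) * 4, float(v))
    for w, v in zip(range(20, 23), (float(values.min()), float(values.max()),
                                    float(values.mean()))):
        struct.pack_into("<f", header, (w - 1) * 4, v)
    header[52 * 4:52 * 4 + 4] = b"MAP "
    struct.pack_into("<i", header, 53 * 4, 0x00004144)    # little-endian stamp
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


@pytest.fixture(scope="session")
def toy_ligand() -> LigandModel:
    return make_ligand()


@pytest.fixture(scope="session")
def toy_bonded(toy_ligand):
    return assign_bond_orders(toy_ligand, TOY_SMILES)


@pytest.fixture(scope="session")
def toy_pdb(tmp_path_factory, toy_ligand):
    path = tmp_path_factory.mktemp("struct") / "toy.pdb"
    st = ligand_to_structure(toy_ligand, gemmi.UnitCell(40, 40, 40, 90, 90, 90))
    st.write_pdb(str(path))
    return path


@pytest.fixture(scope="session")
def toy_cif(tmp_path_factory, toy_ligand):
    path = tmp_path_factory.mktemp("struct") / "toy.cif"
    st = ligand_to_structure(toy_ligand, gemmi.UnitCell(40, 40, 40, 90, 90, 90))
    st.make_mmcif_document().write_file(str(path))
    return path


@pytest.fixture(scope="session")
def torsional_case():
    """Noise-free 0.50/0.50 torsional-shift benchmark case at 1.0 Å."""
    model, bonded, cell = build_true_model("torsional_shift", (0.5, 0.5))
    model = ramp_bfactors(model, 1.0)
    grid = simulate_map(model, cell, 1.0, seed=1, noise_scale=0.0, ramp=False)
    ligand_in = single_conformer_input(model)
    bonded_in = assign_bond_orders(ligand_in, bonded.template_smiles)
    return {"true_model": model, "cell": cell, "grid": grid,
            "bonded_input": bonded_in}
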