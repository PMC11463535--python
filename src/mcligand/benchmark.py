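"""Synthetic ground-truth suite: two-conformer ligands and simulated maps.

Four disorder archetypes are generated programmatically — a localized ring
flip, a non-localized rigid displacement of a linear ligand, a localized
torsional shift, and a macrocycle with branch rotation. For each archetype a
"true" two-conformer model is built at occupancy splits 0.50/0.50 through
0.10/0.90, and density maps are simulated across 0.8–2.5 Å (0.1 Å steps)
with resolution-ramped B-factors and resolution-proportional Gaussian noise:
360 map/model pairs in all. Feeding only the A conformer back into the
fitting pipeline probes how low an alternate-conformer occupancy can be
detected at each resolution.

Maps are simulated by direct structure-factor summation to the resolution
limit (occupancy-weighted, with a flat bulk-solvent term) followed by
Fourier synthesis, in an orthorhombic P1 box with ≥5 Å of padding.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import gemmi
import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdDistGeom

from ._geometry import rotation_matrix
from .density import (DensityGrid, form_factor_curve, half_sphere_hkl,
                      synthesize_from_coefficients)
from .errors import MCLigandError
from .ligand import BondedLigand, LigandModel, assign_bond_orders
from .multiconformer import MulticonformerModel, embed_model

ARCHETYPES = ("ring_flip", "displacement", "torsional_shift", "macrocycle")
OCC_SPLITS = ((0.50, 0.50), (0.40, 0.60), (0.30, 0.70), (0.20, 0.80), (0.10, 0.90))
RESOLUTIONS = tuple(round(0.8 + 0.1 * k, 1) for k in range(18))

ARCHETYPE_SMILES = {
    "ring_flip": "C1CCCCC1CCCO",              # cyclohexane + hydroxypropyl tail
    "displacement": "CCCCCCCCCO",             # long linear ligand
    "torsional_shift": "c1ccccc1CCCCO",       # phenyl + rotatable chain
    "macrocycle": "CCCCC1CCCCCCCCCCCCC1",     # 14-ring + butyl branch
}

B0_DEFAULT = 10.0       # Å², B-factor at the 0.8 Å end of the ramp
B_RAMP_K = 10.0         # Å² per Å of resolution
NOISE_SCALE = 0.1       # noise s.d. = NOISE_SCALE · σ_map · (resolution / 1 Å)
K_SOL = 0.4
B_SOL = 45.0
BOX_PADDING = 6.0       # Å on each side
_GEOMETRY_SEED = 1234   # fixed: archetype base geometries are reproducible


@dataclass(frozen=True)
class BenchmarkCase:
    archetype: str
    occ_split: tuple[float, float]
    resolution: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise MCLigandError(f"unknown archetype {self.archetype!r}")
        if abs(sum(self.occ_split) - 1.0) > 1e-12:
            raise MCLigandError("occupancy split must sum to exactly 1")
        if round(self.resolution, 1) not in RESOLUTIONS:
            raise MCLigandError(f"resolution {self.resolution} not in the "
                                "0.8–2.5 Å benchmark grid")


def enumerate_benchmark(seed: int = 0) -> list[BenchmarkCase]:
    """The full Cartesian product: 4 archetypes × 5 splits × 18 resolutions."""
    return [BenchmarkCase(a, s, r, seed=seed)
            for a, s, r in itertools.product(ARCHETYPES, OCC_SPLITS, RESOLUTIONS)]


def _embed_archetype(archetype: str) -> BondedLigand:
    smiles = ARCHETYPE_SMILES[archetype]
    mol = Chem.MolFromSmiles(smiles)
    params = rdDistGeom.ETKDGv3()
    params.randomSeed = _GEOMETRY_SEED
    if rdDistGeom.EmbedMolecule(mol, params) != 0:
        raise MCLigandError(f"embedding failed for archetype {archetype}")
    AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
    coords = np.array(mol.GetConformer().GetPositions())
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    counts: dict[str, int] = {}
    names = []
    for el in elements:
        counts[el] = counts.get(el, 0) + 1
        names.append(f"{el}{counts[el]}")
    ligand = LigandModel(
        atom_names=names, elements=elements, coords=coords,
        b_factors=np.full(len(names), B0_DEFAULT),
        occupancies=np.ones(len(names)), altlocs=[""] * len(names),
        chain="A", resnum=401, resname="LIG")
    return assign_bond_orders(ligand, smiles)


def _distal_atoms(bonded: BondedLigand, i: int, j: int) -> set[int]:
    """Atoms on j's side of the (i, j) bond."""
    adj = bonded.adjacency()
    seen = {i, j}
    stack = [j]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    seen.discard(i)
    return seen


def _rotate_about_bond(coords: np.ndarray, bonded: BondedLigand,
                       i: int, j: int, angle_deg: float) -> np.ndarray:
    """Rotate the atoms distal to bond (i → j) about the bond axis."""
    out = coords.copy()
    axis = coords[j] - coords[i]
    R = rotation_matrix(axis, angle_deg)
    moving = sorted(_distal_atoms(bonded, i, j))
    out[moving] = (coords[moving] - coords[j]) @ R.T + coords[j]
    return out


def _relax_with_fixed(bonded: BondedLigand, coords: np.ndarray,
                      fixed: list[int], max_its: int = 500) -> np.ndarray:
    """MMFF94-relax a manually built conformer with some atoms pinned,
    settling it into a genuine local minimum (emulating the regularization a
    hand-built alternate conformer receives before map simulation)."""
    mol = Chem.Mol(bonded.mol)
    conf = mol.GetConformer()
    for i, (x, y, z) in enumerate(coords):
        conf.SetAtomPosition(i, (float(x), float(y), float(z)))
    try:
        props = AllChem.MMFFGetMoleculeProperties(mol)
        ff = AllChem.MMFFGetMoleculeForceField(mol, props)
        for i in fixed:
            ff.AddFixedPoint(int(i))
        ff.Minimize(maxIts=max_its)
    except Exception:
        return coords
    return np.array(mol.GetConformer().GetPositions())


def _alternate_conformer(bonded: BondedLigand, archetype: str) -> np.ndarray:
    """Deterministic B-conformer transform for each disorder archetype.

    All transforms except the rigid displacement are relaxed into the
    nearest force-field minimum with the untouched atoms pinned; a transform
    that collapses back onto conformer A (< 0.2 Å) falls through to the
    opposite rotation sense.
    """
    from .ligand import detect_topology
    from ._geometry import coordinate_rmsd

    coords = bonded.ligand.coords
    mol = bonded.mol
    if archetype == "displacement":
        return coords + np.array([1.0, 0.0, 0.0])
    if archetype == "ring_flip":
        ring = list(mol.GetRingInfo().AtomRings()[0])
        ring_xyz = coords[ring]
        center = ring_xyz.mean(axis=0)
        # mirror the pucker: reflect ring atoms through the mean ring plane
        centered = ring_xyz - center
        _, _, vt = np.linalg.svd(centered)
        normal = vt[2]
        out = coords.copy()
        out[ring] = ring_xyz - 2.0 * np.outer(centered @ normal, normal)
        tail = [i for i in range(bonded.ligand.n_heavy) if i not in ring]
        return _relax_with_fixed(bonded, out, tail)
    features = detect_topology(bonded)
    branch = sorted(set().union(*features.side_chains))
    core = sorted(set(range(bonded.ligand.n_heavy)) - set(branch))
    root = next(a for a in core
                for nb in bonded.adjacency()[a] if nb in branch)
    nxt = next(nb for nb in bonded.adjacency()[root] if nb in branch)
    angle = 120.0 if archetype == "torsional_shift" else 90.0
    for sense in (-1.0, 1.0):
        rotated = _rotate_about_bond(coords, bonded, root, nxt, sense * angle)
        relaxed = _relax_with_fixed(bonded, rotated, core)
        if coordinate_rmsd(relaxed, coords) > 0.2:
            return relaxed
    raise MCLigandError(
        f"could not construct a distinct B conformer for {archetype}")


def _boxed(coords_sets: np.ndarray) -> tuple[np.ndarray, gemmi.UnitCell]:
    """Translate conformers into an orthorhombic P1 box with padding."""
    allxyz = coords_sets.reshape(-1, 3)
    lo = allxyz.min(axis=0)
    hi = allxyz.max(axis=0)
    dims = hi - lo + 2.0 * BOX_PADDING
    dims = np.ceil(dims * 2.0) / 2.0        # round up to 0.5 Å
    shift = BOX_PADDING - lo
    cell = gemmi.UnitCell(float(dims[0]), float(dims[1]), float(dims[2]),
                          90.0, 90.0, 90.0)
    return coords_sets + shift[None, None, :], cell


def build_true_model(archetype: str,
                     occ_split: tuple[float, float]) -> tuple[MulticonformerModel,
                                                              BondedLigand,
                                                              gemmi.UnitCell]:
    """Two-conformer ground-truth model for one archetype and split.

    Conformer A is the archetype's base geometry; conformer B its
    deterministic disorder transform. Returns the model, the bonded topology
    (with conformer-A coordinates), and the P1 box cell.
    """
    if abs(sum(occ_split) - 1.0) > 1e-12:
        raise MCLigandError("occupancy split must sum to 1")
    bonded = _embed_archetype(archetype)
    conf_a = bonded.ligand.coords
    conf_b = _alternate_conformer(bonded, archetype)
    boxed, cell = _boxed(np.stack([conf_a, conf_b]))

    ligand = bonded.ligand.with_coords(boxed[0])
    bonded_boxed = assign_bond_orders(ligand, bonded.template_smiles)
    model = MulticonformerModel(ligand=ligand, conformers=boxed,
                                occupancies=np.array(occ_split),
                                altlocs=["A", "B"])
    return model, bonded_boxed, cell


def ramp_bfactors(model: MulticonformerModel, resolution: float,
                  b0: float = B0_DEFAULT, k: float = B_RAMP_K) -> MulticonformerModel:
    """Uniform ligand B-factor ramp, B(d) = B₀ + k·(d − 0.8 Å).

    Emulates the growth of positional uncertainty as resolution degrades;
    strictly increasing in d.
    """
    b = b0 + k * (float(resolution) - 0.8)
    ligand = model.ligand.with_coords(model.ligand.coords)
    ligand.b_factors = np.full(ligand.n_heavy, b)
    return MulticonformerModel(ligand=ligand, conformers=model.conformers.copy(),
                               occupancies=model.occupancies.copy(),
                               altlocs=list(model.altlocs))


def structure_factors(model: MulticonformerModel, cell: gemmi.UnitCell,
                      resolution: float, hkl: np.ndarray | None = None,
                      bulk_solvent: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy-weighted direct structure-factor summation to `resolution`.

    F(h) = Σ_conf ω_conf Σ_atoms f_el(s)·exp(−B s²/4)·exp(2πi h·x_frac),
    plus a flat bulk-solvent term k_sol·exp(−b_sol s²/4)·F_mask when enabled.
    """
    if hkl is None:
        hkl = half_sphere_hkl(cell, resolution)
    abc = np.array([cell.a, cell.b, cell.c])
    s2 = np.sum((hkl / abc[None, :]) ** 2, axis=1)
    stol2 = s2 / 4.0

    F = np.zeros(len(hkl), dtype=complex)
    elements = model.ligand.elements
    bs = model.ligand.b_factors
    form_factor = {el: form_factor_curve(el, stol2) for el in set(elements)}
    for k_conf in range(model.n_conformers):
        frac = model.conformers[k_conf] / abc[None, :]
        phase = np.exp(2j * np.pi * (hkl @ frac.T))       # (R, N)
        for j, el in enumerate(elements):
            F += (model.occupancies[k_conf] * form_factor[el]
                  * np.exp(-bs[j] * s2 / 4.0) * phase[:, j])
    if bulk_solvent:
        F += _bulk_solvent_sf(model, cell, hkl, s2)
    return hkl, F


def _bulk_solvent_sf(model: MulticonformerModel, cell: gemmi.UnitCell,
                     hkl: np.ndarray, s2: np.ndarray,
                     solvent_radius: float = 2.0) -> np.ndarray:
    """Flat bulk-solvent contribution: FFT of the binary solvent mask scaled
    by k_sol·exp(−b_sol·s²/4)."""
    n = 32
    mg = gemmi.Int8Grid(n, n, n)
    mg.set_unit_cell(cell)
    mg.spacegroup = gemmi.SpaceGroup("P1")
    for xyz in model.conformers.reshape(-1, 3):
        mg.set_points_around(gemmi.Position(*map(float, xyz)),
                             radius=solvent_radius, value=1)
    solvent = 1.0 - np.asarray(mg.array, dtype=float)
    vol = cell.volume
    f_full = np.conj(np.fft.fftn(solvent)) * (vol / n**3)
    idx = np.mod(hkl, n)
    f_mask = f_full[idx[:, 0], idx[:, 1], idx[:, 2]]
    return K_SOL * np.exp(-B_SOL * s2 / 4.0) * f_mask


def simulate_map(model: MulticonformerModel, cell: gemmi.UnitCell,
                 resolution: float, seed: int = 0,
                 noise_scale: float = NOISE_SCALE,
                 bulk_solvent: bool = False,
                 ramp: bool = True) -> DensityGrid:
    """Simulated density for a benchmark model at one resolution.

    B-factors are ramped with resolution (unless `ramp=False`), structure
    factors summed to the resolution limit, the map Fourier synthesized, and
    Gaussian noise of s.d. noise_scale·σ_map·(resolution/1 Å) added
    (seeded; `noise_scale=0` gives the noise-free map). The flat bulk-solvent
    term is available but off by default: under the zero-F000 convention its
    binary-mask form leaves a ligand-shaped depression that systematically
    deflates fitted occupancies (see docs/methods.md).
    """
    if ramp:
        model = ramp_bfactors(model, resolution)
    hkl, F = structure_factors(model, cell, resolution, bulk_solvent=bulk_solvent)
    grid = synthesize_from_coefficients(hkl, F, cell, resolution)
    if noise_scale > 0:
        rng = np.random.default_rng(int(seed) % 2**31)
        sigma = float(grid.values.std())
        noise = rng.normal(0.0, noise_scale * sigma * (resolution / 1.0),
                           size=grid.values.shape)
        grid = DensityGrid(values=grid.values + noise, unit_cell=cell,
                           resolution=resolution, space_group="P 1")
    return grid


def single_conformer_input(true_model: MulticonformerModel) -> LigandModel:
    """The fitting input for a benchmark case: conformer A alone at occupancy
    1.0, embedded in a minimal parent structure (the P1 box)."""
    ligand = true_model.ligand.with_coords(true_model.conformers[0])
    ligand.occupancies = np.ones(ligand.n_heavy)
    single = MulticonformerModel(ligand=ligand,
                                 conformers=true_model.conformers[:1],
                                 occupancies=np.array([1.0]), altlocs=[""])
    parent = _minimal_parent(single)
    ligand.parent = parent
    return ligand


def _minimal_parent(model: MulticonformerModel,
                    cell: gemmi.UnitCell | None = None) -> gemmi.Structure:
    st = gemmi.Structure()
    if cell is not None:
        st.cell = cell
    st.spacegroup_hm = "P 1"
    gm = gemmi.Model("1")
    chain = gemmi.Chain(model.ligand.chain)
    res = gemmi.Residue()
    res.name = model.ligand.resname
    res.seqid = gemmi.SeqId(model.ligand.resnum, " ")
    res.het_flag = "H"
    for j, name in enumerate(model.ligand.atom_names):
        atom = gemmi.Atom()
        atom.name = name
        atom.element = gemmi.Element(model.ligand.elements[j])
        x, y, z = model.conformers[0, j]
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        atom.occ = float(model.occupancies[0])
        atom.b_iso = float(model.ligand.b_factors[j])
        res.add_atom(atom)
    chain.add_residue(res)
    gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_case(case: BenchmarkCase, directory: str) -> dict:
    """Materialize one case as (two-altloc PDB, CCP4 map, manifest record)."""
    import os

    model, _, cell = build_true_model(case.archetype, case.occ_split)
    model = ramp_bfactors(model, case.resolution)
    model.ligand.parent = _minimal_parent(model, cell)
    grid = simulate_map(model, cell, case.resolution, seed=case.seed, ramp=False)

    tag = (f"{case.archetype}_{case.occ_split[0]:.2f}"
           f"_{case.resolution:.1f}A")
    pdb_path = os.path.join(directory, f"{tag}.pdb")
    map_path = os.path.join(directory, f"{tag}.ccp4")
    structure = embed_model(model)
    structure.cell = cell
    structure.write_pdb(pdb_path)
    grid.write_ccp4(map_path)
    return {"archetype": case.archetype, "occ_a": case.occ_split[0],
            "occ_b": case.occ_split[1], "resolution": case.resolution,
            "seed": case.seed, "pdb": pdb_path, "map": map_path}
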