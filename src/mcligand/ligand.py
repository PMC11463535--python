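"""Ligand extraction, chemistry assignment, and topology analysis.

A ligand enters the pipeline as a single-conformer residue inside a deposited
structure. This module pulls that residue out (keeping a handle to the
untouched remainder), assigns bond orders from a SMILES template, and derives
the graph features (terminal atoms, side chains, macrocycle flag) that decide
which sampling strategies apply.

Hydrogens are ignored throughout: at the resolutions where multiconformer
ligand modeling is meaningful, the density constrains heavy atoms only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, rdDetermineBonds

from .errors import BondAssignmentError, LigandInputError, SelectorError

RDLogger.DisableLog("rdApp.*")

_BLANK_ALTLOC = "\x00"


def _is_blank_altloc(altloc: str) -> bool:
    return altloc in ("", " ", _BLANK_ALTLOC)


@dataclass
class LigandModel:
    """Heavy atoms of one ligand residue plus parent-structure context.

    Coordinates are Cartesian angstroms in the as-deposited frame.
    """

    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray          # (N, 3) Å
    b_factors: np.ndarray       # (N,) Å²
    occupancies: np.ndarray     # (N,) in [0, 1]
    altlocs: list[str]
    chain: str
    resnum: int
    resname: str = "LIG"
    parent: gemmi.Structure | None = None   # unmodified full structure

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.b_factors = np.asarray(self.b_factors, dtype=float)
        self.occupancies = np.asarray(self.occupancies, dtype=float)
        n = len(self.atom_names)
        if not (self.coords.shape[0] == n == len(self.elements)
                == self.b_factors.size == self.occupancies.size == len(self.altlocs)):
            raise LigandInputError("inconsistent per-atom array lengths")
        if not np.all(np.isfinite(self.coords)):
            raise LigandInputError("non-finite coordinates")
        if np.any(self.occupancies < 0) or np.any(self.occupancies > 1):
            raise LigandInputError("occupancies outside [0, 1]")
        seen = set()
        for name in self.atom_names:
            if name in seen:
                raise LigandInputError(f"duplicate atom name {name!r}")
            seen.add(name)

    @property
    def n_heavy(self) -> int:
        return len(self.atom_names)

    @property
    def residue_id(self) -> tuple[str, int]:
        return (self.chain, self.resnum)

    def with_coords(self, coords: np.ndarray) -> "LigandModel":
        return LigandModel(
            atom_names=list(self.atom_names), elements=list(self.elements),
            coords=np.array(coords, dtype=float), b_factors=self.b_factors.copy(),
            occupancies=self.occupancies.copy(), altlocs=list(self.altlocs),
            chain=self.chain, resnum=self.resnum, resname=self.resname,
            parent=self.parent)


@dataclass
class BondedLigand:
    """LigandModel plus the covalent graph with template bond orders."""

    ligand: LigandModel
    bonds: list[tuple[int, int, float]]     # (i, j, order); order in {1, 1.5, 2, 3}
    template_smiles: str
    mol: Chem.Mol = field(repr=False, default=None)   # RDKit mol with the input conformer

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {i: set() for i in range(self.ligand.n_heavy)}
        for i, j, _ in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj


@dataclass
class TopologyFeatures:
    """Graph features that select sampling strategies."""

    terminal_atoms: frozenset[int]
    side_chains: tuple[frozenset[int], ...]   # acyclic branches of ≥4 atoms
    long_chains: tuple[frozenset[int], ...]   # branches of >30 atoms
    core_atoms: frozenset[int]
    is_macrocycle: bool
    n_heavy: int


@dataclass
class GeometryReport:
    passed: bool
    reason: str = ""


def _parse_selector(selector: str | tuple[str, int]) -> tuple[str, int]:
    if isinstance(selector, tuple):
        return selector[0], int(selector[1])
    parts = [p.strip() for p in str(selector).split(",")]
    if len(parts) != 2:
        raise SelectorError(f"selector {selector!r} must be 'chain,resnum'")
    try:
        return parts[0], int(parts[1])
    except ValueError as exc:
        raise SelectorError(f"bad residue number in selector {selector!r}") from exc


def load_ligand(structure_path: str, selector: str | tuple[str, int]) -> LigandModel:
    """Extract the selected residue from a PDB or PDBx/mmCIF file.

    If the residue already carries altlocs, only altloc 'A' is kept and its
    occupancy reset to 1.0 (with a warning): the fit starts from a single
    input conformer.
    """
    chain_id, resnum = _parse_selector(selector)
    try:
        structure = gemmi.read_structure(str(structure_path))
    except (RuntimeError, ValueError) as exc:
        raise LigandInputError(f"cannot parse structure {structure_path}: {exc}") from exc
    structure.setup_entities()

    matches = []
    for model in structure:
        for chain in model:
            if chain.name != chain_id:
                continue
            for res in chain:
                if res.seqid.num == resnum:
                    matches.append(res)
        break  # first model only
    if not matches:
        raise SelectorError(f"no residue {chain_id},{resnum} in {structure_path}")
    if len(matches) > 1:
        raise SelectorError(f"selector {chain_id},{resnum} matches {len(matches)} residues")
    res = matches[0]

    has_altlocs = any(not _is_blank_altloc(a.altloc) for a in res)
    names, elements, xyz, bs, occs, alts = [], [], [], [], [], []
    for atom in res:
        if atom.element.is_hydrogen:
            continue
        altloc = "" if _is_blank_altloc(atom.altloc) else atom.altloc
        if has_altlocs and altloc not in ("", "A"):
            continue
        names.append(atom.name)
        elements.append(atom.element.name)
        xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        bs.append(atom.b_iso)
        occs.append(1.0 if has_altlocs else atom.occ)
        alts.append("")
    if has_altlocs:
        warnings.warn(
            f"residue {chain_id},{resnum} has alternate locations; keeping "
            "altloc A with occupancy reset to 1.0", stacklevel=2)
    if not names:
        raise LigandInputError(f"residue {chain_id},{resnum} has no heavy atoms")

    return LigandModel(
        atom_names=names, elements=elements, coords=np.array(xyz),
        b_factors=np.array(bs), occupancies=np.array(occs), altlocs=alts,
        chain=chain_id, resnum=resnum, resname=res.name, parent=structure)


def _mol_from_coords(ligand: LigandModel) -> Chem.Mol:
    """Bare RDKit mol: atoms + one conformer, connectivity perceived from distances."""
    rw = Chem.RWMol()
    for el in ligand.elements:
        atom = Chem.Atom(el)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    conf = Chem.Conformer(ligand.n_heavy)
    for i, (x, y, z) in enumerate(ligand.coords):
        conf.SetAtomPosition(i, (float(x), float(y), float(z)))
    rw.AddConformer(conf)
    mol = rw.GetMol()
    rdDetermineBonds.DetermineConnectivity(mol)
    return mol


def assign_bond_orders(ligand: LigandModel, smiles: str) -> BondedLigand:
    """Assign bond orders from a SMILES template.

    The template's heavy-atom graph must be isomorphic to the connectivity
    perceived from the ligand coordinates; a failure signals either an
    atom-count mismatch or altered connectivity (e.g. a distorted bond).
    """
    template = Chem.MolFromSmiles(smiles)
    if template is None:
        raise BondAssignmentError(f"cannot parse SMILES {smiles!r}")
    template = Chem.RemoveHs(template)
    if template.GetNumAtoms() != ligand.n_heavy:
        raise BondAssignmentError(
            f"template has {template.GetNumAtoms()} heavy atoms, "
            f"ligand has {ligand.n_heavy}")
    raw = _mol_from_coords(ligand)
    try:
        assigned = AllChem.AssignBondOrdersFromTemplate(template, raw)
    except ValueError as exc:
        raise BondAssignmentError(
            "template connectivity cannot be mapped onto ligand coordinates "
            f"({exc})") from exc
    # rebuild from the sanitized template (correct implicit-H counts, needed
    # downstream by embedding and force-field steps), renumbered into the
    # ligand's atom order via the template↔ligand graph isomorphism
    match = assigned.GetSubstructMatch(template)
    if len(match) != ligand.n_heavy or len(set(match)) != ligand.n_heavy:
        raise BondAssignmentError(
            "no graph isomorphism between template and ligand connectivity")
    order = [0] * ligand.n_heavy
    for t_idx, l_idx in enumerate(match):
        order[l_idx] = t_idx
    mol = Chem.RenumberAtoms(template, order)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - sanitize rarely fails here
        raise BondAssignmentError(f"sanitization failed: {exc}") from exc
    conf = Chem.Conformer(ligand.n_heavy)
    for i, (x, y, z) in enumerate(ligand.coords):
        conf.SetAtomPosition(i, (float(x), float(y), float(z)))
    mol.RemoveAllConformers()
    mol.AddConformer(conf)

    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
             for b in mol.GetBonds()]
    _require_connected(ligand.n_heavy, bonds)
    return BondedLigand(ligand=ligand, bonds=bonds, template_smiles=smiles, mol=mol)


def _require_connected(n: int, bonds: list[tuple[int, int, float]]) -> None:
    if n == 0:
        raise LigandInputError("empty ligand")
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for i, j, _ in bonds:
        adj[i].add(j)
        adj[j].add(i)
    seen = {0}
    stack = [0]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    if len(seen) != n:
        raise LigandInputError(
            "ligand bond graph is disconnected (salts/multi-component ligands "
            "are not supported)")


def _ring_systems(mol: Chem.Mol) -> list[set[int]]:
    """Fused ring systems as atom-index sets."""
    rings = [set(r) for r in mol.GetRingInfo().AtomRings()]
    systems: list[set[int]] = []
    for ring in rings:
        merged = ring
        keep = []
        for sys_ in systems:
            if sys_ & merged:
                merged = merged | sys_
            else:
                keep.append(sys_)
        keep.append(merged)
        systems = keep
    return systems


def _longest_path(adj: dict[int, set[int]], nodes: set[int]) -> list[int]:
    """Diameter path of a tree (double BFS)."""
    def bfs(start: int) -> tuple[int, dict[int, int]]:
        prev = {start: -1}
        order = [start]
        for node in order:
            for nb in adj[node]:
                if nb in nodes and nb not in prev:
                    prev[nb] = node
                    order.append(nb)
        return order[-1], prev

    far, _ = bfs(next(iter(sorted(nodes))))
    end, prev = bfs(far)
    path = [end]
    while prev[path[-1]] != -1:
        path.append(prev[path[-1]])
    return path


def detect_topology(bonded: BondedLigand) -> TopologyFeatures:
    """Derive the features that drive sampling-strategy selection.

    The "core" is the largest fused ring system if the ligand has any ring,
    otherwise the longest heavy-atom path. Side chains are acyclic branches of
    at least 4 atoms hanging off the core; branches longer than 30 atoms are
    additionally flagged as long chains. A macrocycle is any ring of 12 or
    more atoms.
    """
    n = bonded.ligand.n_heavy
    adj = bonded.adjacency()
    _require_connected(n, bonded.bonds)

    terminal = frozenset(i for i in range(n) if len(adj[i]) == 1)
    ring_atoms: set[int] = set()
    systems = _ring_systems(bonded.mol)
    for sys_ in systems:
        ring_atoms |= sys_

    if systems:
        core = set(max(systems, key=lambda s: (len(s), -min(s))))
    else:
        core = set(_longest_path(adj, set(range(n))))

    # branches: connected components of the graph minus the core
    remaining = set(range(n)) - core
    branches: list[set[int]] = []
    unvisited = set(remaining)
    while unvisited:
        start = unvisited.pop()
        comp = {start}
        stack = [start]
        while stack:
            for nb in adj[stack.pop()]:
                if nb in remaining and nb not in comp:
                    comp.add(nb)
                    stack.append(nb)
        unvisited -= comp
        branches.append(comp)

    side_chains = tuple(
        frozenset(b) for b in sorted(branches, key=min)
        if len(b) >= 4 and not (b & ring_atoms))
    long_chains = tuple(b for b in side_chains if len(b) > 30)

    ring_sizes = [len(r) for r in bonded.mol.GetRingInfo().AtomRings()]
    is_macrocycle = any(size >= 12 for size in ring_sizes)

    return TopologyFeatures(
        terminal_atoms=terminal, side_chains=side_chains,
        long_chains=long_chains, core_atoms=frozenset(core),
        is_macrocycle=is_macrocycle, n_heavy=n)


def validate_geometry(ligand: LigandModel, smiles: str) -> GeometryReport:
    """Check that the ligand's chemical connectivity survives its coordinates.

    Passing means the SMILES template can still be mapped onto the
    connectivity perceived from the (possibly refined) coordinates — a fast
    sanity check that refinement or sampling did not break or fuse bonds.
    Failures are reported, never raised.
    """
    try:
        assign_bond_orders(ligand, smiles)
    except (BondAssignmentError, LigandInputError) as exc:
        return GeometryReport(passed=False, reason=str(exc))
    return GeometryReport(passed=True)
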