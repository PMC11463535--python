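"""The multiconformer ligand model: 1–3 conformers with occupancies and
altloc labels, embeddable back into the parent structure."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import gemmi
import numpy as np

from .errors import MCLigandError
from .ligand import LigandModel

CULL_OCCUPANCY = 0.1
_ALTLOC_LABELS = "ABC"


@dataclass
class MulticonformerModel:
    """Final model: alternative ligand conformers sharing one topology.

    Occupancies sum to ≤ 1 (the ensemble total is allowed to stay below full
    occupancy); altlocs are 'A', 'B', 'C' in descending occupancy, or blank
    for a single-conformer model.
    """

    ligand: LigandModel
    conformers: np.ndarray        # (K, N, 3) Å
    occupancies: np.ndarray       # (K,)
    altlocs: list[str]

    def __post_init__(self) -> None:
        self.conformers = np.asarray(self.conformers, dtype=float)
        if self.conformers.ndim == 2:
            self.conformers = self.conformers[None]
        self.occupancies = np.asarray(self.occupancies, dtype=float)
        if len(self.altlocs) != self.conformers.shape[0] != self.occupancies.size:
            raise MCLigandError("conformers, occupancies and altlocs must align")
        if self.occupancies.sum() > 1.0 + 1e-6:
            raise MCLigandError("occupancies sum above 1")

    @property
    def n_conformers(self) -> int:
        return self.conformers.shape[0]

    def scaled(self, factor: float) -> "MulticonformerModel":
        return MulticonformerModel(
            ligand=self.ligand, conformers=self.conformers.copy(),
            occupancies=self.occupancies * factor, altlocs=list(self.altlocs))


def select_final_model(weights: np.ndarray, pool_coords: np.ndarray,
                       ligand: LigandModel,
                       cull_threshold: float = CULL_OCCUPANCY,
                       redistribute: bool = False) -> MulticonformerModel:
    """Cull sub-threshold occupancies and label the survivors.

    Conformers with ω ≥ `cull_threshold` (default 0.1) are kept and labeled
    A, B, C in descending occupancy (ties broken by conformer index, lower
    index first). If every weight falls below the threshold the single best
    conformer is returned at its fitted weight, with a warning. Occupancies
    are reported to 2 decimals. With `redistribute`, culled occupancy is
    proportionally rescaled onto the survivors (off by default).
    """
    weights = np.asarray(weights, dtype=float)
    pool_coords = np.asarray(pool_coords, dtype=float)
    keep = np.flatnonzero(weights >= cull_threshold)
    if keep.size == 0:
        best = int(np.argmax(weights))
        warnings.warn("all conformer occupancies below the cull threshold; "
                      "keeping the single best conformer", stacklevel=2)
        keep = np.array([best])
    order = sorted(keep, key=lambda i: (-weights[i], i))[:len(_ALTLOC_LABELS)]
    occs = weights[order].astype(float)
    if redistribute and occs.sum() > 0:
        occs = occs * (weights.sum() / occs.sum())
    occs = np.floor(occs * 100.0 + 0.5) / 100.0
    while occs.sum() > 1.0 + 1e-9:
        occs[int(np.argmax(occs))] -= 0.01
    if len(order) == 1:
        altlocs = [""]
    else:
        altlocs = [_ALTLOC_LABELS[k] for k in range(len(order))]
    return MulticonformerModel(ligand=ligand, conformers=pool_coords[order],
                               occupancies=occs, altlocs=altlocs)


def scale_event_occupancies(model: MulticonformerModel,
                            bdc: float) -> MulticonformerModel:
    """Scale occupancies by (1 − BDC) for models fit into PanDDA event maps.

    BDC is the background density correction fraction; the event map shows
    the bound state at enhanced contrast, so real-space occupancies must be
    deflated by (1 − BDC) before refinement against the original data.
    """
    if not 0.0 <= bdc < 1.0:
        raise MCLigandError(f"BDC must lie in [0, 1), got {bdc}")
    scaled = model.scaled(1.0 - bdc)
    return scaled


def embed_model(model: MulticonformerModel) -> gemmi.Structure:
    """Replace the ligand residue in the parent structure with the
    multiconformer version; everything else is left untouched."""
    ligand = model.ligand
    if ligand.parent is None:
        raise MCLigandError("ligand has no parent structure to embed into")
    structure = ligand.parent.clone()
    target = None
    for chain in structure[0]:
        if chain.name != ligand.chain:
            continue
        for res in chain:
            if res.seqid.num == ligand.resnum and res.name == ligand.resname:
                target = res
                break
    if target is None:
        raise MCLigandError("parent structure no longer contains the ligand residue")

    template_atoms = {}
    for atom in target:
        if atom.name not in template_atoms:
            template_atoms[atom.name] = atom.clone()
    while len(target) > 0:
        del target[0]

    for k in range(model.n_conformers):
        for j, name in enumerate(ligand.atom_names):
            atom = template_atoms.get(name, gemmi.Atom())
            atom = atom.clone()
            atom.name = name
            atom.element = gemmi.Element(ligand.elements[j])
            x, y, z = model.conformers[k, j]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            atom.occ = float(model.occupancies[k])
            atom.b_iso = float(ligand.b_factors[j])
            atom.altloc = model.altlocs[k] if model.altlocs[k] else "\x00"
            target.add_atom(atom)
    return structure


def write_model(model: MulticonformerModel, path: str) -> None:
    """Write the embedded structure as PDB (or mmCIF for .cif paths).

    Non-ligand atoms are carried through in their original order and values;
    two writes of the same model are byte-identical.
    """
    structure = embed_model(model)
    path = str(path)
    if path.endswith((".cif", ".mmcif")):
        structure.make_mmcif_document().write_file(path)
    else:
        structure.write_pdb(path)
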