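"""Biased conformer-pool generation.

Six search strategies bias a stochastic distance-geometry search toward poses
compatible with the binding site: an unconstrained search, a fixed-terminal
search (terminal-atom pair distances pinned), a blob search (conformers
confined to the input ligand's bounding sphere), a branching search (core
atoms fixed, side chains move), a long-chain search (long side chains fixed,
core moves), and an optional 180-degree flip search. The pool is allocated a
total budget (5,000 conformers for ligands under 25 heavy atoms, 7,000
otherwise), split evenly across the applicable strategies, then pruned of
redundant members at 0.2 Å RMSD.

Embedding is delegated to a pluggable engine; the default engine wraps
RDKit's ETKDG implementation. Fixed atoms are honored by rigid alignment onto
the input over the fixed set followed by an exact coordinate snap; distance
pins and bounding spheres are enforced by post-hoc rejection with
oversampling.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
from rdkit import Chem, DistanceGeometry
from rdkit.Chem import AllChem, rdDistGeom
from rdkit.Geometry import Point3D

from ._geometry import align, coordinate_rmsd, rotate_about_centroid, rotation_matrix
from .errors import SamplingError
from .ligand import BondedLigand, LigandModel, TopologyFeatures

DEFAULT_BUDGET_SMALL = 5000
DEFAULT_BUDGET_LARGE = 7000
LARGE_LIGAND_THRESHOLD = 25      # heavy atoms
PRUNE_THRESHOLD = 0.2            # Å
PIN_TOLERANCE = 0.1              # Å
FIXED_ATOM_TOLERANCE = 0.01      # Å
SPHERE_SLACK = 0.1               # Å
BOND_LENGTH_TOLERANCE = 0.15     # relative

STRATEGIES = ("unconstrained", "fixed_terminal", "blob", "branching", "long_chain")


@dataclass(frozen=True)
class ConstraintSet:
    """Geometric constraints a strategy imposes on generated conformers."""

    fixed_atoms: frozenset[int] = frozenset()
    pair_distance_pins: tuple[tuple[int, int, float], ...] = ()
    bounding_sphere: tuple[tuple[float, float, float], float] | None = None

    def __post_init__(self) -> None:
        if self.bounding_sphere is not None and self.bounding_sphere[1] <= 0:
            raise ValueError("bounding sphere radius must be positive")
        for i, j, d in self.pair_distance_pins:
            if d <= 0:
                raise ValueError(f"non-positive pinned distance for pair ({i},{j})")

    @property
    def empty(self) -> bool:
        return (not self.fixed_atoms and not self.pair_distance_pins
                and self.bounding_sphere is None)


@dataclass
class SamplingPlan:
    total_budget: int
    strategies: list[tuple[str, int, ConstraintSet | None]]
    seed: int

    def __post_init__(self) -> None:
        if sum(c for _, c, _ in self.strategies) != self.total_budget:
            raise ValueError("strategy counts must sum to the total budget")
        if any(c <= 0 for _, c, _ in self.strategies):
            raise ValueError("every strategy count must be positive")


@dataclass
class ConformerSet:
    """Alternative coordinate sets sharing one topology and atom order."""

    topology: BondedLigand | None
    coords: np.ndarray                  # (M, N, 3) Å
    sources: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.shape[0] != len(self.sources):
            raise ValueError("one source label per member required")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @staticmethod
    def concatenate(sets: list["ConformerSet"]) -> "ConformerSet":
        sets = [s for s in sets if len(s) > 0]
        if not sets:
            raise SamplingError("no conformers to concatenate")
        topo = next((s.topology for s in sets if s.topology is not None), None)
        return ConformerSet(
            topology=topo,
            coords=np.concatenate([s.coords for s in sets], axis=0),
            sources=[src for s in sets for src in s.sources])

    def subset(self, indices) -> "ConformerSet":
        indices = np.asarray(indices, dtype=int)
        return ConformerSet(topology=self.topology, coords=self.coords[indices],
                            sources=[self.sources[i] for i in indices])


def applicable_strategies(features: TopologyFeatures) -> list[str]:
    out = ["unconstrained", "fixed_terminal", "blob"]
    if features.side_chains:
        out.append("branching")
    if features.long_chains:
        out.append("long_chain")
    return out


def allocate_budget(features: TopologyFeatures, user_count: int | None = None,
                    ligand: LigandModel | None = None, seed: int = 0) -> SamplingPlan:
    """Split the conformer budget evenly across applicable strategies.

    The default budget is 5,000 conformers for ligands with fewer than 25
    heavy atoms and 7,000 otherwise; `user_count` overrides it. A remainder
    after even division is distributed one conformer at a time to the leading
    strategies (unconstrained first).
    """
    if user_count is not None and user_count <= 0:
        raise ValueError("user conformer count must be positive")
    if user_count is not None:
        total = int(user_count)
    elif features.n_heavy < LARGE_LIGAND_THRESHOLD:
        total = DEFAULT_BUDGET_SMALL
    else:
        total = DEFAULT_BUDGET_LARGE

    names = applicable_strategies(features)
    base, rem = divmod(total, len(names))
    entries: list[tuple[str, int, ConstraintSet | None]] = []
    for k, name in enumerate(names):
        count = base + (1 if k < rem else 0)
        cs = build_constraints(name, ligand, features) if ligand is not None else None
        entries.append((name, count, cs))
    return SamplingPlan(total_budget=total, strategies=entries, seed=seed)


def build_constraints(strategy: str, ligand: LigandModel,
                      features: TopologyFeatures) -> ConstraintSet:
    """Materialize a strategy's constraints from the input geometry."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if strategy not in applicable_strategies(features):
        raise SamplingError(f"strategy {strategy!r} not applicable to this ligand")
    coords = ligand.coords
    if strategy == "unconstrained":
        return ConstraintSet()
    if strategy == "fixed_terminal":
        term = sorted(features.terminal_atoms)
        pins = tuple(
            (i, j, float(np.linalg.norm(coords[i] - coords[j])))
            for a, i in enumerate(term) for j in term[a + 1:])
        return ConstraintSet(pair_distance_pins=pins)
    if strategy == "blob":
        center = coords.mean(axis=0)
        radius = float(np.max(np.linalg.norm(coords - center, axis=1)))
        return ConstraintSet(bounding_sphere=(tuple(center), radius))
    if strategy == "branching":
        side = set().union(*features.side_chains)
        fixed = frozenset(set(range(ligand.n_heavy)) - side)
        return ConstraintSet(fixed_atoms=fixed)
    # long_chain
    fixed = frozenset(set().union(*features.long_chains))
    return ConstraintSet(fixed_atoms=fixed)


class EmbeddingEngine(Protocol):
    """Contract for the stochastic conformer embedder.

    Implementations generate up to `count` coordinate sets for the bonded
    ligand, in an arbitrary frame, honoring distance pins approximately (the
    caller re-checks and rejects) and leaving placement to the caller.
    """

    def generate(self, bonded: BondedLigand, constraints: ConstraintSet,
                 count: int, seed: int) -> np.ndarray: ...


class RDKitETKDGEngine:
    """Distance-geometry embedding via RDKit's experimental-torsion
    knowledge method (ETKDG), followed by MMFF94 minimization to relieve
    clashes and settle torsions into force-field minima. Torsion potentials
    and the force field internals are the engine's own business; this
    wrapper only sets constraints, seeds, and the cleanup step.
    """

    def __init__(self, minimize: bool = True, minimize_iters: int = 200) -> None:
        self.minimize = minimize
        self.minimize_iters = minimize_iters

    def generate(self, bonded: BondedLigand, constraints: ConstraintSet,
                 count: int, seed: int) -> np.ndarray:
        mol = Chem.Mol(bonded.mol)
        mol.RemoveAllConformers()
        seed = int(seed) % (2**31 - 1) or 1
        if len(constraints.fixed_atoms) >= bonded.ligand.n_heavy:
            # fully pinned: the constraint determines the conformer
            return np.repeat(bonded.ligand.coords[None], count, axis=0)
        if constraints.fixed_atoms:
            conf0 = bonded.mol.GetConformer()
            coord_map = {int(i): Point3D(*map(float, bonded.ligand.coords[i]))
                         for i in sorted(constraints.fixed_atoms)}
            cids = rdDistGeom.EmbedMultipleConfs(
                mol, numConfs=count, randomSeed=seed, coordMap=coord_map,
                useRandomCoords=True, numThreads=1)
        elif constraints.pair_distance_pins:
            bm = rdDistGeom.GetMoleculeBoundsMatrix(mol)
            for i, j, d in constraints.pair_distance_pins:
                lo, hi = min(i, j), max(i, j)
                bm[lo][hi] = d + 0.01   # upper bound
                bm[hi][lo] = max(d - 0.01, 0.1)   # lower bound
            DistanceGeometry.DoTriangleSmoothing(bm)
            params = rdDistGeom.ETKDGv3()
            params.randomSeed = seed
            params.useRandomCoords = True
            params.numThreads = 1
            params.SetBoundsMat(bm)
            cids = rdDistGeom.EmbedMultipleConfs(mol, count, params)
        else:
            params = rdDistGeom.ETKDGv3()
            params.randomSeed = seed
            params.numThreads = 1
            cids = rdDistGeom.EmbedMultipleConfs(mol, count, params)
        if self.minimize and len(cids):
            try:
                AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=self.minimize_iters,
                                                  numThreads=1)
            except Exception:   # MMFF setup failure: keep raw embeddings
                pass
        out = np.empty((len(cids), mol.GetNumAtoms(), 3))
        for k, cid in enumerate(cids):
            out[k] = mol.GetConformer(cid).GetPositions()
        return out


def _place_in_site(raw: np.ndarray, ligand: LigandModel,
                   constraints: ConstraintSet) -> np.ndarray:
    """Move engine-frame conformers into the binding-site frame.

    With fixed atoms: align on the fixed set, then snap fixed atoms exactly.
    Otherwise: least-squares align on all heavy atoms.
    """
    placed = np.empty_like(raw)
    target = ligand.coords
    if constraints.fixed_atoms:
        sel = np.array(sorted(constraints.fixed_atoms))
        for k, conf in enumerate(raw):
            moved = align(conf, conf[sel], target[sel])
            moved[sel] = target[sel]
            placed[k] = moved
    else:
        for k, conf in enumerate(raw):
            placed[k] = align(conf, conf, target)
    return placed


def verify_constraints(coords: np.ndarray, bonded: BondedLigand,
                       constraints: ConstraintSet) -> np.ndarray:
    """Independent constraint check; returns a boolean keep-mask.

    Deliberately a distinct code path from the generator: plain distance
    arithmetic against the stated tolerances (fixed atoms 0.01 Å, pins 0.1 Å,
    sphere radius + 0.1 Å, bond lengths within 15% of the input model's).
    """
    coords = np.asarray(coords, dtype=float)
    n_members = coords.shape[0]
    ok = np.ones(n_members, dtype=bool)
    ref = bonded.ligand.coords
    if constraints.fixed_atoms:
        sel = sorted(constraints.fixed_atoms)
        dev = np.linalg.norm(coords[:, sel] - ref[None, sel], axis=2)
        ok &= dev.max(axis=1) <= FIXED_ATOM_TOLERANCE + 1e-12
    for i, j, d in constraints.pair_distance_pins:
        dist = np.linalg.norm(coords[:, i] - coords[:, j], axis=1)
        ok &= np.abs(dist - d) <= PIN_TOLERANCE
    if constraints.bounding_sphere is not None:
        center, radius = constraints.bounding_sphere
        r = np.linalg.norm(coords - np.asarray(center)[None, None, :], axis=2)
        ok &= r.max(axis=1) <= radius + SPHERE_SLACK
    bond_idx = np.array([(i, j) for i, j, _ in bonded.bonds])
    ref_len = np.linalg.norm(ref[bond_idx[:, 0]] - ref[bond_idx[:, 1]], axis=1)
    lengths = np.linalg.norm(coords[:, bond_idx[:, 0]] - coords[:, bond_idx[:, 1]], axis=2)
    ok &= np.all(np.abs(lengths - ref_len) <= BOND_LENGTH_TOLERANCE * ref_len, axis=1)
    return ok


def generate_conformers(bonded: BondedLigand, constraints: ConstraintSet,
                        count: int, seed: int,
                        engine: EmbeddingEngine | None = None,
                        source: str = "unconstrained",
                        oversample: int = 3,
                        workers: int = 1) -> ConformerSet:
    """Generate up to `count` conformers satisfying the constraint set.

    Rejection-filtered constraints (sphere, pins) are oversampled up to
    `oversample`× and truncated back to the budget. Results are deterministic
    for a fixed seed and independent of `workers` (generation is chunked with
    per-chunk derived seeds).
    """
    if count <= 0:
        raise ValueError("conformer count must be positive")
    engine = engine if engine is not None else RDKitETKDGEngine()
    needs_rejection = (constraints.pair_distance_pins
                       or constraints.bounding_sphere is not None)
    ask = count * oversample if needs_rejection else count

    chunk_size = max(50, -(-ask // 8))
    chunks = []
    start = 0
    while start < ask:
        chunks.append(min(chunk_size, ask - start))
        start += chunk_size
    chunk_seeds = [(int(seed) + 104729 * (k + 1)) % (2**31 - 1) for k in range(len(chunks))]

    def run_chunk(args):
        n, s = args
        try:
            return engine.generate(bonded, constraints, n, s)
        except Exception:   # engine failure: skip this chunk, not fatal
            return np.empty((0, bonded.ligand.n_heavy, 3))

    if workers > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            raw_parts = list(pool.map(run_chunk, zip(chunks, chunk_seeds)))
    else:
        raw_parts = [run_chunk(a) for a in zip(chunks, chunk_seeds)]
    raw = np.concatenate([p for p in raw_parts if len(p)], axis=0) \
        if any(len(p) for p in raw_parts) else np.empty((0, bonded.ligand.n_heavy, 3))
    if raw.shape[0] == 0:
        raise SamplingError(f"embedding engine produced no conformers ({source})")

    placed = _place_in_site(raw, bonded.ligand, constraints)
    keep = verify_constraints(placed, bonded, constraints)
    placed = placed[keep][:count]
    if placed.shape[0] == 0:
        raise SamplingError(
            f"no conformer satisfied the {source!r} constraints after rejection")
    return ConformerSet(topology=bonded, coords=placed,
                        sources=[source] * placed.shape[0])


def flip_sampling(bonded: BondedLigand) -> ConformerSet:
    """180-degree flips about the principal (x, y, z) axes through the
    centroid, each followed by ±10° refinements in 2° increments about its
    flip axis. Rigid-body only: internal geometry is preserved exactly.
    """
    base = bonded.ligand.coords
    center = base.mean(axis=0)
    members, sources = [], []
    for axis in ("x", "y", "z"):
        flip = rotate_about_centroid(base, rotation_matrix(axis, 180.0), center)
        members.append(flip)
        sources.append(f"flip_{axis}")
    for axis in ("x", "y", "z"):
        flip = rotate_about_centroid(base, rotation_matrix(axis, 180.0), center)
        for delta in (-10, -8, -6, -4, -2, 2, 4, 6, 8, 10):
            refined = rotate_about_centroid(flip, rotation_matrix(axis, float(delta)), center)
            members.append(refined)
            sources.append(f"flip_{axis}{delta:+d}")
    return ConformerSet(topology=bonded, coords=np.stack(members), sources=sources)


def pairwise_rmsd_matrix(coords: np.ndarray) -> np.ndarray:
    """All-pair coordinate RMSDs (no superposition), via the Gram identity."""
    m, n_atoms, _ = coords.shape
    flat = coords.reshape(m, -1)
    sq = np.sum(flat * flat, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (flat @ flat.T)
    np.maximum(d2, 0.0, out=d2)
    return np.sqrt(d2 / n_atoms)


def prune_redundant(conformers: ConformerSet, threshold: float = PRUNE_THRESHOLD,
                    seed: int = 0, keep_first: bool = False) -> ConformerSet:
    """Remove one member of every redundant pair (RMSD < threshold).

    Pairs are visited in member-index order; within a pair the member to
    remove is chosen uniformly at random under the seed (or, with
    `keep_first`, always the later member — used after perturbation so a
    perturbed copy never displaces its parent). Idempotent: a pruned set
    survives a second prune unchanged.
    """
    m = len(conformers)
    if m <= 1:
        return conformers
    rmsd = pairwise_rmsd_matrix(conformers.coords)
    alive = np.ones(m, dtype=bool)
    rng = np.random.default_rng(int(seed) % 2**31)
    for i in range(m):
        if not alive[i]:
            continue
        for j in range(i + 1, m):
            if alive[i] and alive[j] and rmsd[i, j] < threshold:
                if keep_first:
                    victim = j
                else:
                    victim = i if rng.random() < 0.5 else j
                alive[victim] = False
                if victim == i:
                    break
    return conformers.subset(np.flatnonzero(alive))


PERTURB_ROTATIONS = (-15.0, -10.0, -5.0, 5.0, 10.0, 15.0)
PERTURB_TRANSLATION = 0.3   # Å


def perturb(conformers: ConformerSet) -> ConformerSet:
    """Rigid-body perturbations of each member: the member itself, rotations
    of ±5/±10/±15° about each principal axis through its centroid, and ±0.3 Å
    translations along each axis (25 members per input member).
    """
    members, sources = [], []
    for k in range(len(conformers)):
        base = conformers.coords[k]
        src = conformers.sources[k]
        members.append(base)
        sources.append(src)
        for axis in ("x", "y", "z"):
            for angle in PERTURB_ROTATIONS:
                members.append(rotate_about_centroid(base, rotation_matrix(axis, angle)))
                sources.append(src)
        for axis_idx in range(3):
            for sign in (1.0, -1.0):
                shift = np.zeros(3)
                shift[axis_idx] = sign * PERTURB_TRANSLATION
                members.append(base + shift)
                sources.append(src)
    return ConformerSet(topology=conformers.topology, coords=np.stack(members),
                        sources=sources)
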