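"""Model-vs-map and model-vs-model validation metrics.

RSCC (real-space correlation coefficient) is the Pearson correlation between
observed and calculated density over the shared footprint mask. EDIA scores
the density support of a single atom by averaging capped, normalized density
z-scores over a sphere around it, with distance weighting and grid-point
ownership; EDIAm aggregates atom scores with a negative-exponent power mean
so poorly supported atoms dominate. RMSD compares conformers atom-by-atom in
a common frame (no superposition). A torsion-strain calculator is exposed as
a pluggable interface only — strain computation is external.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Protocol

import gemmi
import numpy as np

from ._geometry import coordinate_rmsd
from .density import DensityGrid
from .errors import MetricError
from .multiconformer import MulticonformerModel

ZETA = 1.2
EDIA_RESOLUTION_LIMIT = 2.0     # Å; the spherical-atom assumption fails beyond
EDIAM_EXPONENT = -2.0
EDIAM_SHIFT = 0.1


def rscc(obs: np.ndarray, calc: np.ndarray) -> float:
    """Pearson correlation of observed vs calculated density over one mask."""
    obs = np.asarray(obs, dtype=float).ravel()
    calc = np.asarray(calc, dtype=float).ravel()
    if obs.size != calc.size:
        raise MetricError("observed and calculated vectors differ in length")
    if obs.size < 2:
        raise MetricError("need at least two masked voxels")
    do = obs - obs.mean()
    dc = calc - calc.mean()
    vo, vc = do @ do, dc @ dc
    if vo <= 0.0 or vc <= 0.0:
        raise MetricError("undefined correlation: zero variance")
    return float((do @ dc) / np.sqrt(vo * vc))


def rmsd(conf_a: np.ndarray, conf_b: np.ndarray) -> float:
    """Coordinate-frame RMSD over heavy atoms (identical ordering, no fit)."""
    a = np.asarray(conf_a, dtype=float)
    b = np.asarray(conf_b, dtype=float)
    if a.shape != b.shape:
        raise MetricError(f"atom count mismatch: {a.shape} vs {b.shape}")
    return coordinate_rmsd(a, b)


def closest_conformer_rmsd(model: MulticonformerModel,
                           reference: np.ndarray) -> float:
    """Minimum RMSD from any model conformer to a reference conformer."""
    if model.n_conformers == 0:
        raise MetricError("empty multiconformer model")
    return min(rmsd(model.conformers[k], reference)
               for k in range(model.n_conformers))


@dataclass
class EDIAContext:
    """Map statistics and geometry context for EDIA scoring.

    μ is the map mean and σ its root mean square; z-scores are capped at
    ζ = 1.2. `atoms` (positions + elements of the scored model) provide the
    competition for grid-point ownership.
    """

    mu: float
    sigma: float
    resolution: float
    atom_positions: np.ndarray          # (N, 3)
    atom_elements: list[str]
    zeta: float = ZETA

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise MetricError("map RMS must be positive")
        self.atom_positions = np.asarray(self.atom_positions,
                                         dtype=float).reshape(-1, 3)

    @classmethod
    def from_grid(cls, grid: DensityGrid, atom_positions: np.ndarray,
                  atom_elements: list[str],
                  resolution: float | None = None) -> "EDIAContext":
        res = resolution if resolution is not None else grid.resolution
        if res is None:
            raise MetricError("EDIA requires a map resolution")
        values = grid.values
        return cls(mu=float(values.mean()),
                   sigma=float(np.sqrt(np.mean(values**2))),
                   resolution=float(res), atom_positions=atom_positions,
                   atom_elements=list(atom_elements))

    def radius(self, element: str) -> float:
        """Expected-density radius of the element at this resolution.

        Derived from the package's own atom-shape model: the radius where
        the element's calculated density falls to 10% of its central value,
        at the B-factor typical for the resolution (10 Å² + 10·(d − 0.8 Å)).
        """
        return _density_radius(element, round(float(self.resolution), 3))


@lru_cache(maxsize=None)
def _density_radius(element: str, resolution: float,
                    fraction: float = 0.1) -> float:
    from .density import atom_density

    b_typical = 10.0 + 10.0 * max(resolution - 0.8, 0.0)
    r = np.linspace(0.0, 5.0, 1001)
    rho = atom_density(element, r, b_typical, resolution)
    below = np.flatnonzero(rho <= fraction * rho[0])
    return float(r[below[0]]) if below.size else 5.0


def z_score(rho: np.ndarray, ctx: EDIAContext) -> np.ndarray:
    """Capped normalized density: 0 below the mean, (ρ−μ)/σ in between,
    ζ above the cap."""
    z = (np.asarray(rho, dtype=float) - ctx.mu) / ctx.sigma
    return np.clip(z, 0.0, ctx.zeta)


def _distance_weight(t: np.ndarray) -> np.ndarray:
    """Distance weighting on the scaled distance t = d / r_a.

    Positive inside the atom's expected-density radius (1 − t²), a shallow
    negative lobe between r_a and 1.3·r_a penalizing excess density, zero
    beyond. Analytic form follows the intent of the published EDIA
    weighting; the exact published polynomials are not reproduced (see
    docs/methods.md).
    """
    t = np.asarray(t, dtype=float)
    w = np.zeros_like(t)
    inner = t <= 1.0
    w[inner] = 1.0 - t[inner] ** 2
    outer = (t > 1.0) & (t <= 1.3)
    w[outer] = -0.2 * (1.0 - ((t[outer] - 1.15) / 0.15) ** 2)
    return w


def _sphere_voxels(grid: DensityGrid, center: np.ndarray,
                   radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Voxel indices and densities within `radius` of `center` (periodic)."""
    mg = gemmi.Int8Grid(*grid.shape)
    mg.set_unit_cell(grid.unit_cell)
    mg.spacegroup = gemmi.SpaceGroup("P1")
    mg.set_points_around(gemmi.Position(*map(float, center)),
                         radius=float(radius), value=1)
    idx = np.argwhere(np.asarray(mg.array) > 0)
    rho = grid.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    return idx, rho


def _min_image_dist(grid: DensityGrid, points: np.ndarray,
                    center: np.ndarray) -> np.ndarray:
    orth = grid.orth_matrix()
    frac = np.linalg.solve(orth, (points - center[None, :]).T).T
    frac -= np.round(frac)
    return np.linalg.norm(frac @ orth.T, axis=1)


def edia_atom(atom_index: int, grid: DensityGrid, ctx: EDIAContext) -> float:
    """EDIA score of one atom: the w-weighted, ownership-allocated average of
    capped density z-scores over the sphere around the atom."""
    if ctx.resolution > EDIA_RESOLUTION_LIMIT:
        raise MetricError(
            f"EDIA is invalid at resolutions worse than {EDIA_RESOLUTION_LIMIT} Å "
            f"(map is {ctx.resolution:.2f} Å): the spherical-atom assumption fails")
    center = ctx.atom_positions[atom_index]
    r_a = ctx.radius(ctx.atom_elements[atom_index])
    idx, rho = _sphere_voxels(grid, center, 1.3 * r_a)
    xyz = grid.voxel_positions(idx)
    t = _min_image_dist(grid, xyz, center) / r_a
    w = _distance_weight(t)
    if not np.any(w > 0):
        raise MetricError("no positively weighted grid point around atom")

    # ownership: points inside some atom's core radius are shared equally
    # among those atoms; points in no core belong to their nearest atom
    radii = np.array([ctx.radius(el) for el in ctx.atom_elements])
    t_all = np.stack([
        _min_image_dist(grid, xyz, ctx.atom_positions[j]) / radii[j]
        for j in range(len(ctx.atom_elements))], axis=1)      # (P, N)
    inside = t_all <= 1.0
    n_inside = inside.sum(axis=1)
    o = np.zeros(len(idx))
    has_core = n_inside > 0
    o[has_core & inside[:, atom_index]] = 1.0 / n_inside[has_core & inside[:, atom_index]]
    nearest = np.argmin(t_all, axis=1)
    o[~has_core & (nearest == atom_index)] = 1.0

    z = z_score(rho, ctx)
    score = float(np.sum(w * o * z) / np.sum(w[w > 0]))
    # excess density beyond the atom can only lower support toward zero;
    # the score lives on [0, ζ]
    return min(max(score, 0.0), ctx.zeta)


def ediam(model: MulticonformerModel, grid: DensityGrid,
          ctx: EDIAContext | None = None,
          exponent: float = EDIAM_EXPONENT) -> float:
    """Ligand-level EDIA: power mean of per-atom scores.

    The default exponent of −2 (with a +0.1 shift guarding the pole) weights
    weakly supported atoms most heavily, so one unsupported atom drags the
    molecule score down.
    """
    if ctx is None:
        positions = model.conformers.reshape(-1, 3)
        elements = list(model.ligand.elements) * model.n_conformers
        ctx = EDIAContext.from_grid(grid, positions, elements)
    scores = np.array([edia_atom(j, grid, ctx)
                       for j in range(ctx.atom_positions.shape[0])])
    return float(power_mean(scores, exponent))


def power_mean(scores: np.ndarray, exponent: float,
               shift: float = EDIAM_SHIFT) -> float:
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise MetricError("no atom scores to aggregate")
    if exponent == 0.0:
        return float(np.exp(np.mean(np.log(scores + shift))) - shift)
    return float(np.mean((scores + shift) ** exponent) ** (1.0 / exponent) - shift)


class StrainCalculator(Protocol):
    """Pluggable torsion-strain interface (conformer → kcal/mol).

    No implementation is bundled: strain libraries are external services.
    """

    def __call__(self, model: MulticonformerModel) -> float: ...


@dataclass
class MetricReport:
    """Per-ligand validation summary. Fields are absent (None) rather than
    fabricated when their inputs are missing."""

    rscc: float | None = None
    ediam: float | None = None
    per_atom_edia: dict[str, float] = field(default_factory=dict)
    rmsd_to_reference: float | None = None
    strain_kcal_mol: float | None = None
    extras: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {}
        for key in ("rscc", "ediam", "rmsd_to_reference", "strain_kcal_mol"):
            value = getattr(self, key)
            if value is not None:
                out[key] = value
        if self.per_atom_edia:
            out["per_atom_edia"] = dict(self.per_atom_edia)
        out.update(self.extras)
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_tsv(self) -> str:
        items = [(k, v) for k, v in self.to_dict().items()
                 if not isinstance(v, dict)]
        header = "\t".join(k for k, _ in items)
        row = "\t".join(f"{v:.6g}" for _, v in items)
        return f"{header}\n{row}\n"
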