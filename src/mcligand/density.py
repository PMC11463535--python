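"""Density grids, Fourier synthesis, footprint masks, and calculated density.

Observed density arrives either as a gridded CCP4/MRC map or as map
coefficients in an MTZ file (amplitude + phase columns) that are Fourier
synthesized onto a grid. Calculated density for candidate conformers is
"transcribed" onto the same grid: each atom contributes an isotropic sum of
Gaussians derived from its element's scattering factors, broadened by its
B-factor plus a resolution-dependent blur. Fitting and scoring both operate
on the voxels of a footprint mask — the union of voxels within a cutoff
radius of any atom of the conformer ensemble.

All grids are exposed in one canonical convention: a full-cell array indexed
[u, v, w] along the crystallographic a, b, c axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import gemmi
import numpy as np

from .errors import MapError
from .sampling import ConformerSet

#: extra real-space blur applied on top of atomic B-factors so that a B=0
#: atom's image has FWHM ≈ the map resolution d: B_res = (π d)² / ln 2.
RESOLUTION_BLUR_K = float(np.pi**2 / np.log(2.0))


def mask_radius(resolution: float) -> float:
    """Footprint radius around each atom: 0.5 Å + resolution / 3."""
    return 0.5 + float(resolution) / 3.0


@dataclass
class DensityGrid:
    """A 3-D scalar field on a full unit-cell grid."""

    values: np.ndarray                  # (nu, nv, nw)
    unit_cell: gemmi.UnitCell
    resolution: float | None = None
    space_group: str = "P 1"
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise MapError("density grid must be 3-D")
        if not np.all(np.isfinite(self.values)):
            raise MapError("density grid contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        a, b, c = self.unit_cell.a, self.unit_cell.b, self.unit_cell.c
        nu, nv, nw = self.shape
        return (a / nu, b / nv, c / nw)

    def orth_matrix(self) -> np.ndarray:
        return np.array(self.unit_cell.orth.mat.tolist())

    def voxel_positions(self, indices: np.ndarray) -> np.ndarray:
        """Cartesian centers (K, 3) of the given (K, 3) voxel indices."""
        frac = np.asarray(indices, dtype=float) / np.array(self.shape, dtype=float)
        return frac @ self.orth_matrix().T

    def to_gemmi(self) -> gemmi.FloatGrid:
        g = gemmi.FloatGrid(*self.shape)
        g.set_unit_cell(self.unit_cell)
        g.spacegroup = gemmi.SpaceGroup(self.space_group)
        np.asarray(g.array)[...] = self.values
        return g

    def write_ccp4(self, path: str) -> None:
        m = gemmi.Ccp4Map()
        grid = self.to_gemmi()
        float_grid = gemmi.FloatGrid(np.asarray(grid.array, dtype=np.float32),
                                     self.unit_cell, grid.spacegroup)
        m.grid = float_grid
        m.update_ccp4_header()
        m.write_ccp4_map(str(path))


@dataclass
class FootprintMask:
    """Voxels within the footprint radius of any ensemble atom."""

    voxel_indices: np.ndarray            # (K, 3) int
    radius_rule: str
    n_source_atoms: int = 0

    def __post_init__(self) -> None:
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=int).reshape(-1, 3)
        if self.voxel_indices.shape[0] == 0:
            raise MapError("empty footprint mask: ligand outside the grid?")

    def __len__(self) -> int:
        return self.voxel_indices.shape[0]


@dataclass
class DensityMatrix:
    """Per-conformer calculated density at the masked voxels (unit occupancy)."""

    values: np.ndarray                   # (n_conformers, |mask|)
    mask: FootprintMask = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("density matrix must be 2-D")


def read_map(path: str, resolution: float | None = None) -> DensityGrid:
    """Read a CCP4/MRC map, canonicalized to the full-cell [u, v, w] layout."""
    try:
        m = gemmi.read_ccp4_map(str(path))
        m.setup(float("nan"))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapError(f"cannot read CCP4/MRC map {path}: {exc}") from exc
    values = np.array(m.grid.array, dtype=float)
    if np.any(~np.isfinite(values)):
        raise MapError(f"map {path} does not cover the full unit cell")
    sg = m.grid.spacegroup.hm if m.grid.spacegroup else "P 1"
    return DensityGrid(values=values, unit_cell=m.grid.unit_cell,
                       resolution=resolution, space_group=sg)


def fourier_synthesize(mtz_path: str, columns: str = "FWT,PHWT",
                       sample_rate: float = 3.0) -> DensityGrid:
    """Fourier synthesis of map coefficients onto a real grid.

    `columns` names the amplitude and phase columns ("FWT,PHWT",
    "2FOFCWT,PH2FOFCWT", ...). The grid is sampled at ≤ resolution /
    `sample_rate` per axis and Friedel-completed.
    """
    try:
        mtz = gemmi.read_mtz_file(str(mtz_path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapError(f"cannot read MTZ {mtz_path}: {exc}") from exc
    try:
        amp, phase = (c.strip() for c in columns.split(","))
    except ValueError as exc:
        raise MapError(f"bad column spec {columns!r}; expected 'AMP,PHASE'") from exc
    labels = [c.label for c in mtz.columns]
    for name in (amp, phase):
        if name not in labels:
            raise MapError(f"column {name!r} not in MTZ (has {labels})")
    mtz.update_reso()
    grid = mtz.transform_f_phi_to_map(amp, phase, sample_rate=float(sample_rate))
    return DensityGrid(values=np.array(grid.array, dtype=float),
                       unit_cell=grid.unit_cell,
                       resolution=float(mtz.resolution_high()),
                       space_group=grid.spacegroup.hm if grid.spacegroup else "P 1")


def synthesize_from_coefficients(hkl: np.ndarray, f: np.ndarray,
                                 cell: gemmi.UnitCell, resolution: float,
                                 sample_rate: float = 3.0) -> DensityGrid:
    """Synthesize a P1 map from an explicit half-set of structure factors.

    `hkl` is (R, 3) int, `f` complex amplitudes; Friedel mates are implied.
    """
    mtz = gemmi.Mtz(with_base=True)
    mtz.spacegroup = gemmi.SpaceGroup("P1")
    mtz.set_cell_for_all(cell)
    mtz.add_dataset("synth")
    mtz.add_column("FWT", "F")
    mtz.add_column("PHWT", "P")
    amp = np.abs(f)
    phi = np.rad2deg(np.angle(f))
    data = np.column_stack([hkl.astype(np.float32),
                            amp.astype(np.float32), phi.astype(np.float32)])
    mtz.set_data(data.astype(np.float32))
    mtz.update_reso()
    grid = mtz.transform_f_phi_to_map("FWT", "PHWT", sample_rate=float(sample_rate))
    return DensityGrid(values=np.array(grid.array, dtype=float), unit_cell=cell,
                       resolution=float(resolution), space_group="P 1")


def build_mask(grid: DensityGrid, conformers: ConformerSet,
               radius: float | None = None) -> FootprintMask:
    """Union footprint of every conformer's atoms, with periodic wrapping.

    The same mask must be reused when comparing models against each other on
    the same map (input vs multiconformer output).
    """
    if len(conformers) == 0:
        raise MapError("cannot build a mask from an empty conformer set")
    if radius is None:
        if grid.resolution is None:
            raise MapError("mask radius requires a grid resolution")
        radius = mask_radius(grid.resolution)
    mg = gemmi.Int8Grid(*grid.shape)
    mg.set_unit_cell(grid.unit_cell)
    mg.spacegroup = gemmi.SpaceGroup("P1")
    coords = conformers.coords.reshape(-1, 3)
    for x, y, z in coords:
        mg.set_points_around(gemmi.Position(float(x), float(y), float(z)),
                             radius=float(radius), value=1)
    indices = np.argwhere(np.asarray(mg.array) > 0)
    if indices.shape[0] == 0:
        raise MapError("footprint mask is empty: ligand outside the grid")
    return FootprintMask(voxel_indices=indices,
                         radius_rule=f"0.5 Å + resolution/3 = {radius:.3f} Å",
                         n_source_atoms=coords.shape[0])


def extract_masked(grid: DensityGrid, mask: FootprintMask) -> np.ndarray:
    """Observed density vector over the mask's voxels."""
    idx = mask.voxel_indices
    return grid.values[idx[:, 0], idx[:, 1], idx[:, 2]]


@lru_cache(maxsize=None)
def _it92_coefficients(element: str) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian (a_k, b_k) expansion of the element's scattering factor.

    The constant term of the 4-Gaussian parameterization is carried as a
    fifth Gaussian with b = 0, so it still acquires the B-factor blur.
    """
    el = gemmi.Element(element)
    if el.atomic_number == 0:
        raise MapError(f"unknown element {element!r}")
    coefs = el.it92.get_coefs()          # a1..a4, b1..b4, c
    a = np.array(list(coefs[0:4]) + [coefs[8]])
    b = np.array(list(coefs[4:8]) + [0.0])
    return a, b


def atom_density(element: str, r: np.ndarray, b_iso: float,
                 resolution: float) -> np.ndarray:
    """Isotropic real-space density of one atom at distances `r` (Å).

    Each scattering-factor Gaussian of width b_k becomes a real-space
    Gaussian of width b_k + B, with B = b_iso + RESOLUTION_BLUR_K · d².
    """
    a, b = _it92_coefficients(element)
    b_total = b + float(b_iso) + RESOLUTION_BLUR_K * float(resolution) ** 2
    r2 = np.asarray(r, dtype=float) ** 2
    out = np.zeros_like(r2)
    for ak, bk in zip(a, b_total):
        out += ak * (4.0 * np.pi / bk) ** 1.5 * np.exp(-4.0 * np.pi**2 * r2 / bk)
    return out


def half_sphere_hkl(cell: gemmi.UnitCell, resolution: float) -> np.ndarray:
    """Friedel-unique Miller indices to the resolution limit (orthogonal cell)."""
    hmax = int(np.floor(cell.a / resolution))
    kmax = int(np.floor(cell.b / resolution))
    lmax = int(np.floor(cell.c / resolution))
    h, k, l = np.meshgrid(np.arange(-hmax, hmax + 1),
                          np.arange(-kmax, kmax + 1),
                          np.arange(-lmax, lmax + 1), indexing="ij")
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    s2 = ((hkl[:, 0] / cell.a) ** 2 + (hkl[:, 1] / cell.b) ** 2
          + (hkl[:, 2] / cell.c) ** 2)
    keep = (s2 <= 1.0 / resolution**2) & (s2 > 0)
    hkl = hkl[keep]
    unique = ((hkl[:, 0] > 0)
              | ((hkl[:, 0] == 0) & (hkl[:, 1] > 0))
              | ((hkl[:, 0] == 0) & (hkl[:, 1] == 0) & (hkl[:, 2] > 0)))
    return hkl[unique]


def form_factor_curve(element: str, stol2: np.ndarray) -> np.ndarray:
    """Element scattering factor f₀ at the given (sinθ/λ)² values."""
    a, b = _it92_coefficients(element)
    # b == 0 entry is the constant term
    return np.exp(-stol2[:, None] * b[None, :]) @ a


def _is_orthogonal(cell: gemmi.UnitCell) -> bool:
    return (abs(cell.alpha - 90) < 1e-6 and abs(cell.beta - 90) < 1e-6
            and abs(cell.gamma - 90) < 1e-6)


def _min_image_distances(voxel_xyz: np.ndarray, atom_xyz: np.ndarray,
                         grid: DensityGrid) -> np.ndarray:
    """(K, N) minimum-image distances between voxel centers and atoms."""
    orth = grid.orth_matrix()
    frac = np.linalg.solve(orth, np.concatenate([voxel_xyz, atom_xyz]).T).T
    fv, fa = frac[:len(voxel_xyz)], frac[len(voxel_xyz):]
    d = fv[:, None, :] - fa[None, :, :]
    d -= np.round(d)
    cart = d @ orth.T
    return np.linalg.norm(cart, axis=2)


def transcribe_density(conformers: ConformerSet, mask: FootprintMask,
                       grid: DensityGrid,
                       b_factors: np.ndarray | None = None,
                       method: str = "auto") -> DensityMatrix:
    """Calculated density rows (one per conformer) at the masked voxels.

    Two transcription models are available:

    ``reciprocal``
        Direct structure-factor summation per conformer, truncated at the
        map's resolution limit and Fourier synthesized on the observed grid.
        Reproduces the band-limited character of crystallographic maps and
        keeps fitted occupancies on an absolute scale; orthogonal cells only.
    ``gaussian``
        Real-space sum of element-scattering Gaussians per atom, broadened
        by B plus a resolution blur (`atom_density`). Always nonnegative;
        works for any cell.

    ``auto`` picks ``reciprocal`` for orthogonal cells, else ``gaussian``.
    B-factors default to the input ligand's per-atom values (sampling never
    reassigns them). Deterministic in all modes.
    """
    if grid.resolution is None:
        raise MapError("density transcription requires a grid resolution")
    if conformers.topology is None:
        raise MapError("conformer set lacks topology (elements/B-factors)")
    if method == "auto":
        method = "reciprocal" if _is_orthogonal(grid.unit_cell) else "gaussian"
    ligand = conformers.topology.ligand
    elements = ligand.elements
    bs = np.asarray(b_factors if b_factors is not None else ligand.b_factors,
                    dtype=float)
    if method == "reciprocal":
        return _transcribe_reciprocal(conformers, mask, grid, elements, bs)
    if method != "gaussian":
        raise MapError(f"unknown transcription method {method!r}")
    voxel_xyz = grid.voxel_positions(mask.voxel_indices)
    rows = np.zeros((len(conformers), len(mask)))
    for m in range(len(conformers)):
        dists = _min_image_distances(voxel_xyz, conformers.coords[m], grid)
        for j, el in enumerate(elements):
            rows[m] += atom_density(el, dists[:, j], bs[j], grid.resolution)
    return DensityMatrix(values=rows, mask=mask)


def _transcribe_reciprocal(conformers: ConformerSet, mask: FootprintMask,
                           grid: DensityGrid, elements: list[str],
                           bs: np.ndarray) -> DensityMatrix:
    cell = grid.unit_cell
    if not _is_orthogonal(cell):
        raise MapError("reciprocal transcription requires an orthogonal cell")
    resolution = float(grid.resolution)
    hkl = half_sphere_hkl(cell, resolution)
    abc = np.array([cell.a, cell.b, cell.c])
    s2 = np.sum((hkl / abc[None, :]) ** 2, axis=1)
    stol2 = s2 / 4.0
    atom_factor = np.empty((len(hkl), len(elements)))
    for j, el in enumerate(elements):
        atom_factor[:, j] = form_factor_curve(el, stol2) * np.exp(-bs[j] * s2 / 4.0)

    nu, nv, nw = grid.shape
    idx = mask.voxel_indices
    rows = np.empty((len(conformers), len(mask)))
    for m in range(len(conformers)):
        frac = conformers.coords[m] / abc[None, :]
        phase = np.exp(2j * np.pi * (hkl @ frac.T))          # (R, N)
        F = np.einsum("rj,rj->r", atom_factor, phase.real) \
            + 1j * np.einsum("rj,rj->r", atom_factor, phase.imag)
        g = _resynthesize_exact(hkl, F, cell, resolution, grid.shape)
        rows[m] = g.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    return DensityMatrix(values=rows, mask=mask)


def _resynthesize_exact(hkl: np.ndarray, f: np.ndarray, cell: gemmi.UnitCell,
                        resolution: float,
                        shape: tuple[int, int, int]) -> DensityGrid:
    mtz = gemmi.Mtz(with_base=True)
    mtz.spacegroup = gemmi.SpaceGroup("P1")
    mtz.set_cell_for_all(cell)
    mtz.add_dataset("synth")
    mtz.add_column("FWT", "F")
    mtz.add_column("PHWT", "P")
    data = np.column_stack([hkl.astype(np.float32),
                            np.abs(f).astype(np.float32),
                            np.rad2deg(np.angle(f)).astype(np.float32)])
    mtz.set_data(data.astype(np.float32))
    mtz.update_reso()
    g = mtz.transform_f_phi_to_map("FWT", "PHWT", exact_size=list(shape))
    return DensityGrid(values=np.array(g.array, dtype=float), unit_cell=cell,
                       resolution=resolution, space_group="P 1")
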