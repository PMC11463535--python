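"""Model/Results interface for multiconformer ligand fitting.

`MultiConformerLigandModel` bundles the data of one fitting problem — the
ligand (with its parent structure), the observed density, and the chemistry
template — and `fit()` runs the sampling/QP/MIQP pipeline, returning a
`FitResults` carrying the selected conformers, their occupancies, the
validation metrics and per-stage diagnostics, with a `summary()` table in
the style of statistical modeling packages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import DensityGrid, read_map
from .errors import MapError
from .ligand import BondedLigand, LigandModel, assign_bond_orders, load_ligand
from .metrics import MetricReport
from .multiconformer import MulticonformerModel, write_model
from .pipeline import FitDiagnostics, RunConfig, fit_density, load_density
from .solver import CARDINALITY_XRAY, T_MIN_DEFAULT


class MultiConformerLigandModel:
    """A ligand-vs-density fitting problem.

    Parameters
    ----------
    bonded:
        Ligand with template bond orders (the single input conformer).
    density:
        Observed density grid; must carry a resolution.
    cardinality:
        Maximum number of output conformers (3 for X-ray, 2 for cryo-EM).
    t_min:
        Minimum occupancy a selected conformer may carry in the MIQP.
    """

    def __init__(self, bonded: BondedLigand, density: DensityGrid, *,
                 cardinality: int = CARDINALITY_XRAY,
                 t_min: float = T_MIN_DEFAULT) -> None:
        if density.resolution is None:
            raise MapError("density grid must carry a resolution")
        self.bonded = bonded
        self.density = density
        self.cardinality = cardinality
        self.t_min = t_min

    @classmethod
    def from_files(cls, structure_path: str, map_path: str, selector: str,
                   smiles: str, *, map_kind: str = "xray_map",
                   column_labels: str = "2FOFCWT,PH2FOFCWT",
                   resolution: float | None = None,
                   cardinality: int | None = None) -> "MultiConformerLigandModel":
        """Build the problem from a structure file and a map/MTZ file."""
        config = RunConfig(structure_path=str(structure_path),
                           map_path=str(map_path), selector=selector,
                           smiles=smiles, map_kind=map_kind,
                           column_labels=column_labels, resolution=resolution,
                           cardinality=cardinality)
        ligand = load_ligand(config.structure_path, config.selector)
        bonded = assign_bond_orders(ligand, smiles)
        grid = load_density(config)
        return cls(bonded, grid, cardinality=config.effective_cardinality)

    def fit(self, *, seed: int = 0, n_conformers: int | None = None,
            workers: int = 1, flip: bool = False, engine=None) -> "FitResults":
        """Run sampling, occupancy QP/MIQP selection, and scoring."""
        model, report, diag = fit_density(
            self.bonded, self.density, cardinality=self.cardinality,
            t_min=self.t_min, n_conformers=n_conformers, seed=seed,
            workers=workers, flip=flip, engine=engine)
        return FitResults(problem=self, model=model, report=report,
                          diagnostics=diag, seed=seed)


@dataclass
class FitResults:
    """Outcome of one fit: the multiconformer model plus diagnostics."""

    problem: MultiConformerLigandModel
    model: MulticonformerModel
    report: MetricReport
    diagnostics: FitDiagnostics
    seed: int

    @property
    def occupancies(self) -> np.ndarray:
        return self.model.occupancies

    @property
    def conformers(self) -> np.ndarray:
        return self.model.conformers

    @property
    def altlocs(self) -> list[str]:
        return self.model.altlocs

    def write(self, path: str) -> None:
        write_model(self.model, path)

    def summary(self) -> str:
        lig = self.model.ligand
        lines = [
            "Multiconformer ligand fit",
            "=" * 58,
            f"ligand            {lig.resname} {lig.chain} {lig.resnum}"
            f"  ({lig.n_heavy} heavy atoms)",
            f"map resolution    {self.problem.density.resolution:.2f} Å",
            f"cardinality       {self.problem.cardinality}"
            f"   t_min {self.problem.t_min:.2f}   seed {self.seed}",
            "-" * 58,
            f"{'altloc':<8}{'occupancy':>10}",
        ]
        for k in range(self.model.n_conformers):
            label = self.model.altlocs[k] or "-"
            lines.append(f"{label:<8}{self.model.occupancies[k]:>10.2f}")
        lines.append("-" * 58)
        if self.report.rscc is not None:
            lines.append(f"RSCC              {self.report.rscc:.4f}")
        if self.report.ediam is not None:
            lines.append(f"EDIAm             {self.report.ediam:.4f}")
        for stage, count in self.diagnostics.stage_counts.items():
            lines.append(f"{stage:<18}{count:>8d}")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed vs calculated masked density (needs matplotlib)."""
        import matplotlib.pyplot as plt

        from .density import build_mask, extract_masked, transcribe_density
        from .sampling import ConformerSet

        ensemble = ConformerSet(topology=self.problem.bonded,
                                coords=self.model.conformers,
                                sources=["final"] * self.model.n_conformers)
        mask = build_mask(self.problem.density, ensemble)
        obs = extract_masked(self.problem.density, mask)
        calc = self.model.occupancies @ transcribe_density(
            ensemble, mask, self.problem.density).values
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(obs, calc, s=4, alpha=0.5)
        ax.set_xlabel("observed density")
        ax.set_ylabel("calculated density")
        ax.set_title("masked density agreement")
        return ax
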