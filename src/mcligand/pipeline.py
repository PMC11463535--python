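"""End-to-end orchestration: sample → QP → perturb → QP → MIQP → cull → write.

The stages follow the multiconformer fitting recipe: generate a biased
conformer pool, prune redundancy, fit occupancies to the observed density by
convex QP, enrich the surviving conformers with rigid-body perturbations,
refit, select the parsimonious final set by MIQP (cardinality 3 for X-ray, 2
for cryo-EM; minimum occupancy 0.20), cull conformers below 0.1 occupancy,
and embed the result back into the parent structure.

`fit_density` is the in-memory engine; `run` wraps it for file inputs
(CCP4/MRC maps, MTZ coefficients, PDB/mmCIF structures) and is what the CLI
calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .density import (DensityGrid, DensityMatrix, build_mask, extract_masked,
                      fourier_synthesize, read_map, transcribe_density)
from .errors import MapError, SamplingError
from .ligand import (BondedLigand, LigandModel, assign_bond_orders,
                     detect_topology, load_ligand)
from .metrics import EDIA_RESOLUTION_LIMIT, MetricReport, ediam, rscc
from .multiconformer import (MulticonformerModel, scale_event_occupancies,
                             select_final_model, write_model)
from .sampling import (ConformerSet, EmbeddingEngine, allocate_budget,
                       flip_sampling, generate_conformers, perturb,
                       prune_redundant)
from .solver import (CARDINALITY_CRYOEM, CARDINALITY_XRAY, MIQPProblem,
                     QPProblem, QP_ZERO_WEIGHT, T_MIN_DEFAULT, solve_miqp,
                     solve_qp)

logger = logging.getLogger("mcligand")

MAP_KINDS = ("xray_coefficients", "xray_map", "event_map", "cryoem_map")
MAX_PERTURB_PARENTS = 80       # QP typically leaves 1–80 conformers
MAX_MIQP_POOL = 200            # exhaustive-enumeration limit
MIN_DELIVERY_FRACTION = 0.5    # abort if the engine under-delivers


@dataclass
class RunConfig:
    """Everything one fitting run needs."""

    structure_path: str
    map_path: str
    selector: str
    smiles: str
    map_kind: str = "xray_map"
    column_labels: str = "2FOFCWT,PH2FOFCWT"
    resolution: float | None = None
    n_conformers: int | None = None
    seed: int = 0
    workers: int = 1
    flip_enabled: bool = False
    bdc: float | None = None
    cardinality: int | None = None
    output_path: str | None = None

    def __post_init__(self) -> None:
        if self.map_kind not in MAP_KINDS:
            raise MapError(f"unknown map kind {self.map_kind!r}")
        if self.map_kind in ("event_map", "cryoem_map") and self.resolution is None:
            raise MapError(f"{self.map_kind} requires an explicit resolution")
        if self.bdc is not None and not 0.0 <= self.bdc < 1.0:
            raise MapError("BDC must lie in [0, 1)")

    @property
    def effective_cardinality(self) -> int:
        if self.cardinality is not None:
            return self.cardinality
        return CARDINALITY_CRYOEM if self.map_kind == "cryoem_map" else CARDINALITY_XRAY


@dataclass
class FitDiagnostics:
    """Per-stage counts and objectives, for run-to-run comparability."""

    stage_counts: dict[str, int] = field(default_factory=dict)
    qp1_objective: float | None = None
    qp2_objective: float | None = None
    miqp_objective: float | None = None

    def record(self, stage: str, count: int) -> None:
        self.stage_counts[stage] = int(count)
        logger.info("stage %-18s %6d conformers", stage, count)


def build_pool(bonded: BondedLigand, n_conformers: int | None, seed: int,
               workers: int = 1, flip: bool = False,
               engine: EmbeddingEngine | None = None,
               diagnostics: FitDiagnostics | None = None) -> ConformerSet:
    """Generate, merge, and prune the biased conformer pool."""
    diag = diagnostics if diagnostics is not None else FitDiagnostics()
    features = detect_topology(bonded)
    plan = allocate_budget(features, n_conformers, ligand=bonded.ligand, seed=seed)
    sets = []
    for k, (name, count, constraints) in enumerate(plan.strategies):
        strategy_seed = (seed + 7919 * (k + 1)) % (2**31 - 1)
        try:
            cs = generate_conformers(bonded, constraints, count, strategy_seed,
                                     engine=engine, source=name, workers=workers)
            sets.append(cs)
        except SamplingError as exc:
            logger.warning("strategy %s produced nothing: %s", name, exc)
    if not sets:
        raise SamplingError("sampling: no strategy produced conformers")
    pool = ConformerSet.concatenate(sets)
    if flip:
        pool = ConformerSet.concatenate([pool, flip_sampling(bonded)])
    diag.record("generated", len(pool))
    if len(pool) < MIN_DELIVERY_FRACTION * plan.total_budget:
        raise SamplingError(
            f"sampling under-delivered: {len(pool)} of {plan.total_budget} "
            "requested conformers")
    pool = prune_redundant(pool, seed=seed)
    diag.record("pruned", len(pool))
    return pool


def fit_density(bonded: BondedLigand, grid: DensityGrid, *,
                cardinality: int = CARDINALITY_XRAY,
                t_min: float = T_MIN_DEFAULT,
                n_conformers: int | None = None,
                seed: int = 0, workers: int = 1, flip: bool = False,
                engine: EmbeddingEngine | None = None,
                include_input_conformer: bool = True,
                ) -> tuple[MulticonformerModel, MetricReport, FitDiagnostics]:
    """Fit a multiconformer ligand model to a density grid (in memory)."""
    if grid.resolution is None:
        raise MapError("fitting requires a map resolution")
    diag = FitDiagnostics()
    ligand = bonded.ligand

    pool = build_pool(bonded, n_conformers, seed, workers=workers, flip=flip,
                      engine=engine, diagnostics=diag)
    if include_input_conformer:
        input_set = ConformerSet(topology=bonded, coords=ligand.coords[None],
                                 sources=["input"])
        pool = ConformerSet.concatenate([input_set, pool])

    mask = build_mask(grid, pool)
    b = extract_masked(grid, mask)
    A = transcribe_density(pool, mask, grid)
    qp1 = solve_qp(QPProblem(A=A.values, b=b))
    diag.qp1_objective = qp1.objective
    support = qp1.support
    diag.record("qp1_support", len(support))

    # perturb the strongest QP survivors, re-prune, refit
    order = support[np.argsort(-qp1.weights[support])][:MAX_PERTURB_PARENTS]
    survivors = pool.subset(np.sort(order))
    # deterministic re-prune that never lets a perturbed copy displace its
    # parent, so exact fits survive to the second QP
    enriched = prune_redundant(perturb(survivors), seed=seed + 1, keep_first=True)
    diag.record("perturbed", len(enriched))

    A2 = transcribe_density(enriched, mask, grid)
    qp2 = solve_qp(QPProblem(A=A2.values, b=b))
    diag.qp2_objective = qp2.objective
    support2 = qp2.support
    diag.record("qp2_support", len(support2))
    if len(support2) == 0:
        support2 = np.array([int(np.argmax(qp2.weights))])
    order2 = support2[np.argsort(-qp2.weights[support2])][:MAX_MIQP_POOL]
    final_pool = enriched.subset(np.sort(order2))

    A3 = transcribe_density(final_pool, mask, grid)
    miqp = solve_miqp(MIQPProblem(A=A3.values, b=b,
                                  cardinality=cardinality, t_min=t_min))
    diag.miqp_objective = miqp.objective
    diag.record("miqp_support", len(miqp.support))

    model = select_final_model(miqp.weights, final_pool.coords, ligand)
    diag.record("final", model.n_conformers)

    report = _score_model(model, bonded, grid)
    return model, report, diag


def _score_model(model: MulticonformerModel, bonded: BondedLigand,
                 grid: DensityGrid) -> MetricReport:
    """RSCC (and EDIAm where valid) of the final ensemble against the map,
    over a mask built around the full output ensemble."""
    ensemble = ConformerSet(topology=bonded, coords=model.conformers,
                            sources=["final"] * model.n_conformers)
    mask = build_mask(grid, ensemble)
    obs = extract_masked(grid, mask)
    calc_rows = transcribe_density(ensemble, mask, grid).values
    calc = model.occupancies @ calc_rows
    report = MetricReport()
    try:
        report.rscc = rscc(obs, calc)
    except Exception as exc:     # degenerate masks only
        logger.warning("RSCC unavailable: %s", exc)
    if grid.resolution is not None and grid.resolution <= EDIA_RESOLUTION_LIMIT:
        try:
            report.ediam = ediam(model, grid)
        except Exception as exc:
            logger.warning("EDIAm unavailable: %s", exc)
    return report


def load_density(config: RunConfig) -> DensityGrid:
    if config.map_kind == "xray_coefficients":
        grid = fourier_synthesize(config.map_path, config.column_labels)
        if config.resolution is not None:
            grid.resolution = config.resolution
        return grid
    return read_map(config.map_path, resolution=config.resolution)


def run(config: RunConfig) -> tuple[MulticonformerModel, MetricReport]:
    """File-based end-to-end run; deterministic for a fixed config + seed."""
    ligand = load_ligand(config.structure_path, config.selector)
    bonded = assign_bond_orders(ligand, config.smiles)
    grid = load_density(config)
    if grid.resolution is None:
        raise MapError("map resolution unknown; pass an explicit resolution")
    model, report, _diag = fit_density(
        bonded, grid, cardinality=config.effective_cardinality,
        n_conformers=config.n_conformers, seed=config.seed,
        workers=config.workers, flip=config.flip_enabled)
    if config.map_kind == "event_map" and config.bdc is not None:
        model = scale_event_occupancies(model, config.bdc)
    if config.output_path:
        write_model(model, config.output_path)
    return model, report
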