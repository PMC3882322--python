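"""End-to-end study pipeline: simulate → section → count/measure → analyze.

``simulate_animal`` runs one animal through the full virtual workflow:
tissue generation, optional disease effect, systematic sectioning, frame
placement, optical-dissector counting, nucleator volume measurement of every
counted cell, and scaling of ΣQ⁻ to a whole-striatum estimate N̂.

``run_study`` drives whole cohorts, writes the per-cell and per-animal
tables, compares genotypes at each age, and appends the kinetics and
sample-size calculations to a machine-readable JSON summary.  All outputs
are deterministic functions of the study seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortSpec, apply_disease_effect, generate_tissue
from .config import StudyConfig
from .errors import ConfigurationError
from .estimators import (
    SamplingDesign,
    count_dissector,
    equatorial_profile,
    estimate_total,
    measure_nucleator,
)
from .kinetics import dying_per_section, dying_pool, loss_rate, sample_size
from .microscopy import (
    FrameGrid,
    SamplingGeometry,
    place_frames,
    plan_sections,
    take_sections,
)
from .population import (
    BinSpec,
    GroupComparison,
    PopulationEstimate,
    bin_population,
    compare_groups,
)

__all__ = [
    "AnimalMeasurement",
    "StudyResult",
    "simulate_animal",
    "simulate_cohort",
    "measurements_to_tables",
    "analyze_tables",
    "run_study",
    "SUMMARY_SCHEMA_VERSION",
]

logger = logging.getLogger("stereosim")

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class AnimalMeasurement:
    """Per-animal output of virtual microscopy: ΣQ⁻, nucleator volumes, N̂."""

    animal_id: str
    genotype: str
    age_weeks: float
    sum_Q: int
    nucleator_volumes: np.ndarray  # v̂ per counted cell, µm³
    N_hat: float
    true_count: int

    @property
    def n_measured(self) -> int:
        return int(self.nucleator_volumes.size)


def simulate_animal(
    spec: CohortSpec,
    animal_index: int,
    geometry: SamplingGeometry = SamplingGeometry(),
    animal_id: str | None = None,
    measure_volumes: bool = True,
    n_rays: int = 5,
) -> AnimalMeasurement:
    """Run one animal through the full virtual stereology workflow.

    Randomness is split into per-animal streams derived from
    ``(spec.seed, animal_index)`` so cohorts are order-independent: stream 0
    drives tissue generation (inside :func:`generate_tissue`), 1 the disease
    effect, 2 the section random start, 3 the grid offset, 4 nucleator rays.
    """
    design = SamplingDesign.from_geometry(**asdict(geometry))
    tissue = generate_tissue(spec, animal_index)
    if spec.disease_effect is not None:
        rng_disease = np.random.default_rng([spec.seed, animal_index, 1])
        tissue = apply_disease_effect(tissue, spec.disease_effect, rng_disease)

    rng_sections = np.random.default_rng([spec.seed, animal_index, 2])
    rng_grid = np.random.default_rng([spec.seed, animal_index, 3])
    rng_rays = np.random.default_rng([spec.seed, animal_index, 4])

    plan = plan_sections(tissue.extent, geometry.section_thickness, geometry.period, rng_sections)
    grid = FrameGrid.random(geometry.frame_side, geometry.grid_step, rng_grid)

    sum_Q = 0
    counted_volumes: list[np.ndarray] = []
    for section in take_sections(tissue, plan):
        frames = place_frames(section, grid)
        result = count_dissector(section, frames, design)
        sum_Q += result.sum_Q
        counted_volumes.append(result.counted_volumes)
    true_volumes = (
        np.concatenate(counted_volumes) if counted_volumes else np.empty(0)
    )

    if measure_volumes:
        # the cell's section-plane profile is the equatorial disc of a sphere
        # of its true volume; the nucleator then measures it with random rays
        v_hat = np.array(
            [
                measure_nucleator(equatorial_profile(v), n_rays=n_rays, rng=rng_rays).volume_estimate
                for v in true_volumes
            ]
        )
    else:
        v_hat = true_volumes.copy()

    return AnimalMeasurement(
        animal_id=animal_id or f"{spec.genotype}-{spec.age_weeks:g}w-{animal_index:02d}",
        genotype=spec.genotype,
        age_weeks=spec.age_weeks,
        sum_Q=sum_Q,
        nucleator_volumes=v_hat,
        N_hat=estimate_total(sum_Q, design),
        true_count=tissue.true_count,
    )


def simulate_cohort(
    spec: CohortSpec,
    geometry: SamplingGeometry = SamplingGeometry(),
    measure_volumes: bool = True,
) -> list[AnimalMeasurement]:
    """Simulate every animal of a cohort."""
    return [
        simulate_animal(spec, i, geometry, measure_volumes=measure_volumes)
        for i in range(spec.n_animals)
    ]


def measurements_to_tables(
    measurements: Sequence[AnimalMeasurement],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the per-animal and per-cell tables from raw measurements."""
    animal_rows = []
    cell_rows = []
    for m in measurements:
        animal_rows.append(
            {
                "animal_id": m.animal_id,
                "genotype": m.genotype,
                "age_weeks": m.age_weeks,
                "sum_Q": m.sum_Q,
                "n_measured": m.n_measured,
                "N_hat": m.N_hat,
            }
        )
        for j, v in enumerate(m.nucleator_volumes):
            cell_rows.append(
                {
                    "animal_id": m.animal_id,
                    "genotype": m.genotype,
                    "age_weeks": m.age_weeks,
                    "cell_id": j,
                    "volume_um3": float(v),
                }
            )
    animals = pd.DataFrame(animal_rows)
    cells = pd.DataFrame(
        cell_rows, columns=["animal_id", "genotype", "age_weeks", "cell_id", "volume_um3"]
    )
    return animals, cells


def _population_estimates(
    animals: pd.DataFrame, cells: pd.DataFrame, bins: BinSpec
) -> dict[str, PopulationEstimate]:
    estimates = {}
    volumes_by_animal = dict(tuple(cells.groupby("animal_id")["volume_um3"]))
    for row in animals.itertuples():
        vols = volumes_by_animal.get(row.animal_id, pd.Series(dtype=float)).to_numpy()
        estimates[row.animal_id] = bin_population(
            vols, float(row.N_hat), bins, animal_id=str(row.animal_id)
        )
    return estimates


def analyze_tables(
    animals: pd.DataFrame,
    cells: pd.DataFrame,
    bins: BinSpec = BinSpec(),
    reference_genotype: str = "wild-type",
    bh_correction: bool = False,
) -> dict[float, GroupComparison]:
    """Group comparison (totals and per size bin) for every age with two genotypes.

    Accepts the CSV dialects the pipeline writes, so externally produced
    measurement tables can be analyzed identically.
    """
    required = {"animal_id", "genotype", "age_weeks", "N_hat"}
    missing = required - set(animals.columns)
    if missing:
        raise ConfigurationError(f"per-animal table missing columns: {sorted(missing)}")
    estimates = _population_estimates(animals, cells, bins)
    comparisons: dict[float, GroupComparison] = {}
    for age, sub in animals.groupby("age_weeks"):
        genotypes = set(sub["genotype"])
        others = genotypes - {reference_genotype}
        if reference_genotype not in genotypes or len(others) != 1:
            continue
        other = others.pop()
        ref_ids = sub.loc[sub["genotype"] == reference_genotype, "animal_id"]
        cmp_ids = sub.loc[sub["genotype"] == other, "animal_id"]
        comparisons[float(age)] = compare_groups(
            [estimates[a] for a in ref_ids],
            [estimates[a] for a in cmp_ids],
            bh_correction=bh_correction,
        )
    return comparisons


@dataclass
class StudyResult:
    """All study-level outputs of :func:`run_study`."""

    animals: pd.DataFrame
    cells: pd.DataFrame
    comparisons: dict[float, GroupComparison]
    summary: dict
    output_files: list[Path] = field(default_factory=list)


def _cohort_seed(master_seed: int, cohort_index: int) -> int:
    ss = np.random.SeedSequence([master_seed, cohort_index])
    return int(ss.generate_state(1)[0] % (2**31))


def run_study(config: StudyConfig, out_dir: str | Path) -> StudyResult:
    """Run the full study described by ``config`` and write all outputs.

    Writes ``animals.csv``, ``cells.csv``, ``group_stats.csv``,
    ``summary.json`` and ``run.log`` under ``out_dir``.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise ConfigurationError(f"cannot create output directory {out}: {err}") from err

    geometry = SamplingGeometry(
        section_thickness=config.sampling.section_thickness_um,
        period=config.sampling.period,
        frame_side=config.sampling.frame_side_um,
        grid_step=config.sampling.grid_step_um,
        dissector_height=config.sampling.dissector_height_um,
        guard_zone=config.sampling.guard_zone_um,
    )
    bins = config.bins.to_spec()

    measurements: list[AnimalMeasurement] = []
    for i, cohort_cfg in enumerate(config.cohorts):
        spec = cohort_cfg.to_spec(config.extent_um, _cohort_seed(config.seed, i))
        logger.info(
            "simulating cohort %s %gw (n=%d)", spec.genotype, spec.age_weeks, spec.n_animals
        )
        measurements.extend(simulate_cohort(spec, geometry))

    animals, cells = measurements_to_tables(measurements)
    comparisons = analyze_tables(
        animals, cells, bins, reference_genotype=config.reference_genotype
    )

    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "config": config.echo(),
        "comparisons": {},
    }
    stats_frames = []
    for age, comp in sorted(comparisons.items()):
        summary["comparisons"][f"{age:g}w"] = {
            "n_ref": comp.n_ref,
            "n_cmp": comp.n_cmp,
            "mean_ref": comp.mean_ref,
            "mean_cmp": comp.mean_cmp,
            "sem_ref": comp.sem_ref,
            "sem_cmp": comp.sem_cmp,
            "percent_decline": comp.percent_decline,
            "t": comp.t_statistic,
            "p": comp.p_value,
        }
        frame = comp.to_frame()
        frame.insert(0, "age_weeks", age)
        stats_frames.append(frame)

    # kinetics + power use the oldest compared age (the late-disease time point)
    if comparisons:
        age = max(comparisons)
        comp = comparisons[age]
        params = config.kinetics.to_params()
        deficit = comp.mean_ref - comp.mean_cmp
        if deficit > 0:
            rate = loss_rate(comp.mean_ref, comp.mean_cmp, params)
            pool = dying_pool(rate, params)
            summary["kinetics"] = {
                "age_weeks": age,
                "deficit_neurons": deficit,
                "loss_rate_per_day": rate,
                "dying_pool_neurons": pool,
                "dying_per_section": dying_per_section(pool, params),
            }
            summary["sample_sizes"] = {
                f"rescue_{rf:g}": sample_size(deficit, comp.mean_cmp, config.power.to_spec(rf))
                for rf in config.power.rescue_fractions
            }
        else:
            logger.info("no deficit at %gw; kinetics/power skipped", age)

    files = []
    animals_path = out / "animals.csv"
    animals.to_csv(animals_path, index=False, float_format="%.6g")
    cells_path = out / "cells.csv"
    cells.to_csv(cells_path, index=False, float_format="%.3f")
    files += [animals_path, cells_path]
    if stats_frames:
        stats_path = out / "group_stats.csv"
        pd.concat(stats_frames, ignore_index=True).to_csv(
            stats_path, index=False, float_format="%.6g"
        )
        files.append(stats_path)
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    files.append(summary_path)
    log_path = out / "run.log"
    log_path.write_text(
        "stereosim study run\n"
        f"seed: {config.seed}\n"
        f"resolved config: {json.dumps(config.echo(), sort_keys=True)}\n"
    )
    files.append(log_path)

    return StudyResult(
        animals=animals,
        cells=cells,
        comparisons=comparisons,
        summary=summary,
        output_files=files,
    )
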