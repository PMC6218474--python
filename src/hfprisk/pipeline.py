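"""End-to-end run orchestration: simulate through realm analyses.

``run_pipeline`` executes the stages in order against one synthetic world,
writes every intermediate product into the run directory and finishes with
a manifest recording, per stage, the output files and their SHA-256
checksums plus the seed and package version. Reruns with the same
configuration produce byte-identical directories.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .biogeography import (
    assign_realm,
    filter_biome_realms,
    peak_change_threshold,
    per_realm_analysis,
)
from .hfp_builder import hfp_change
from .io import write_ascii_grid, write_json_report, write_ranges_geojson
from .range_overlap import extent_table
from .risk_model import ModelSettings, threshold_selection
from .risk_transitions import filter_species, label_catalogue, tabulate_transitions
from .sweep_stats import effect_profile, group_sweep
from .synthetic_data import SimConfig, simulate

__all__ = ["RunConfig", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one full pipeline run."""

    out_dir: Path
    sim: SimConfig = field(default_factory=SimConfig)
    t_grid: tuple[int, ...] = tuple(range(0, 8))
    clamp: bool = True
    model: ModelSettings = field(default_factory=ModelSettings)

    def __post_init__(self) -> None:
        if len(self.t_grid) < 2:
            raise ValueError("t_grid needs at least two thresholds")
        if any(not (0 <= t <= 49) for t in self.t_grid):
            raise ValueError("t_grid values must lie in [0, 49]")

    @classmethod
    def from_dict(cls, data: dict, out_dir: str | Path) -> "RunConfig":
        sim = SimConfig(**data.get("sim", {}))
        model = ModelSettings(**data.get("model", {}))
        t_grid = tuple(data.get("t_grid", range(0, 8)))
        return cls(
            out_dir=Path(out_dir),
            sim=sim,
            t_grid=t_grid,
            clamp=bool(data.get("clamp", True)),
            model=model,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory (with manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def record(stage: str, outputs: list[Path]) -> None:
        manifest.append(
            {
                "stage": stage,
                "outputs": {p.name: _sha256(p) for p in outputs},
            }
        )

    stage = "simulate"
    try:
        bundle = simulate(config.sim)
        grid = config.sim.grid
        write_ranges_geojson(out / "ranges.geojson", bundle.ranges)
        _write_csv(bundle.covariates, out / "covariates.csv")
        cats = pd.DataFrame(
            {
                "species_id": [c.species_id for c in bundle.catalogue],
                "category_1996": [c.cat_start for c in bundle.catalogue],
                "category_2010": [c.cat_end for c in bundle.catalogue],
            }
        )
        _write_csv(cats, out / "categories.csv")
        _write_csv(bundle.truth.table, out / "truth.csv")
        write_ascii_grid(out / "realms.asc", bundle.realm_raster, grid)
        write_ascii_grid(out / "biomes.asc", bundle.biome_raster, grid)
        (out / "realm_legend.json").write_text(
            json.dumps({str(k): v for k, v in bundle.realm_legend.items()}),
            encoding="utf-8",
        )
        record(
            stage,
            [
                out / n
                for n in (
                    "ranges.geojson",
                    "covariates.csv",
                    "categories.csv",
                    "truth.csv",
                    "realms.asc",
                    "biomes.asc",
                    "realm_legend.json",
                )
            ],
        )

        stage = "build_hfp"
        write_ascii_grid(out / "hfp1993.asc", bundle.hfp93.values, grid, nodata=-1)
        write_ascii_grid(out / "hfp2009.asc", bundle.hfp09.values, grid, nodata=-1)
        record(stage, [out / "hfp1993.asc", out / "hfp2009.asc"])

        stage = "hfp_change"
        change = hfp_change(bundle.hfp93, bundle.hfp09, clamp_decreases=config.clamp)
        mat = pd.DataFrame(
            change.matrix, index=range(51), columns=[str(c) for c in range(51)]
        )
        mat.index.name = "initial"
        mat.to_csv(out / "hfp_transition_matrix.csv")
        record(stage, [out / "hfp_transition_matrix.csv"])

        stage = "classify"
        retained, exclusions = filter_species(bundle.catalogue)
        labels = label_catalogue(retained)
        label_frame = pd.DataFrame(
            {
                "species_id": [lab.species_id for lab in labels],
                "risk_class": [lab.risk_class for lab in labels],
                "uplist_class": [lab.uplist_class for lab in labels],
            }
        )
        _write_csv(label_frame, out / "labels.csv")
        _write_csv(exclusions, out / "exclusions.csv")
        matrix, shares = tabulate_transitions(labels, retained)
        matrix.to_csv(out / "category_transition_matrix.csv")
        write_json_report(out / "transition_summary.json", shares)
        record(
            stage,
            [
                out / n
                for n in (
                    "labels.csv",
                    "exclusions.csv",
                    "category_transition_matrix.csv",
                    "transition_summary.json",
                )
            ],
        )

        stage = "overlap"
        analysed = set(label_frame["species_id"])
        masks = [m for m in bundle.masks if m.species_id in analysed]
        overlaps = extent_table(
            masks, bundle.hfp93, bundle.hfp09, clamp=config.clamp
        )
        _write_csv(overlaps, out / "overlaps.csv")
        record(stage, [out / "overlaps.csv"])

        stage = "sweep"
        sweep = group_sweep(overlaps, label_frame)
        _write_csv(sweep.table, out / "sweep.csv")
        t_ext, t_delta = effect_profile(sweep)
        write_json_report(
            out / "effect_peaks.json",
            {"t_peak_extent": t_ext, "t_peak_delta": t_delta},
        )
        record(stage, [out / "sweep.csv", out / "effect_peaks.json"])

        stage = "model"
        best_t, curve, reports = threshold_selection(
            overlaps,
            bundle.covariates,
            label_frame,
            config.t_grid,
            config.model,
        )
        _write_csv(curve, out / "model_performance.csv")
        write_json_report(out / "model_report.json", reports[best_t].to_dict())
        record(stage, [out / "model_performance.csv", out / "model_report.json"])

        stage = "realms"
        assignments = [
            assign_realm(
                m, bundle.realm_raster, bundle.biome_raster, bundle.realm_legend
            )
            for m in masks
        ]
        assign_frame = pd.DataFrame(
            {
                "species_id": [a.species_id for a in assignments],
                "realm": [a.realm or "" for a in assignments],
                "biome_realm": [a.biome_realm or "" for a in assignments],
                "realm_fraction": [a.realm_fraction for a in assignments],
            }
        )
        _write_csv(assign_frame, out / "realm_assignments.csv")
        outputs = [out / "realm_assignments.csv"]

        realm_rows = []
        for realm in sorted({a.realm for a in assignments if a.realm}):
            result = per_realm_analysis(
                realm,
                assignments,
                overlaps,
                label_frame,
                bundle.covariates,
                config.t_grid,
                config.model,
            )
            if result is None:
                continue
            r_sweep, r_best_t, r_curve, _ = result
            _write_csv(r_sweep.table, out / f"realm_{realm}_sweep.csv")
            _write_csv(r_curve, out / f"realm_{realm}_performance.csv")
            outputs += [out / f"realm_{realm}_sweep.csv", out / f"realm_{realm}_performance.csv"]
            realm_rows.append({"realm": realm, "best_t": r_best_t})
        _write_csv(pd.DataFrame(realm_rows, columns=["realm", "best_t"]), out / "realm_best_thresholds.csv")
        outputs.append(out / "realm_best_thresholds.csv")

        units = filter_biome_realms(assignments, label_frame)
        unit_rows = []
        for unit, species in sorted(units.items()):
            sub = overlaps[overlaps["species_id"].isin(species)]
            try:
                u_sweep = group_sweep(sub, label_frame)
            except ValueError:
                continue
            unit_rows.append(
                {
                    "biome_realm": unit,
                    "n_species": len(species),
                    "peak_change_t": peak_change_threshold(u_sweep),
                }
            )
        _write_csv(
            pd.DataFrame(
                unit_rows, columns=["biome_realm", "n_species", "peak_change_t"]
            ),
            out / "biome_realm_thresholds.csv",
        )
        outputs.append(out / "biome_realm_thresholds.csv")
        record(stage, outputs)
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise StageError(stage, exc) from exc

    payload = {
        "version": __version__,
        "seed": config.sim.seed,
        "clamp": config.clamp,
        "t_grid": list(config.t_grid),
        "stages": manifest,
    }
    (out / "manifest.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return out
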