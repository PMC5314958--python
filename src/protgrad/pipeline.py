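"""End-to-end pipeline: simulate -> filter -> histograms -> evenness ->
regression -> importance -> correlation, from one config, with reproducible
seeds and a machine-readable manifest.

The globe is treated as one extra stratum (the union of all regions, computed
directly, not as a sum of regional histograms), so a run over R regions and V
variables produces (R + 1) x V histograms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, ProtgradError
from .evenness import AREA_PROT, FRAC_PROT, compare_representativeness, evenness
from .histograms import (
    DEFAULT_TRUNCATION,
    GLOBAL,
    MIN_CLASSES,
    Histogram,
    VariableSpec,
    build_histogram,
    canonical_specs,
    default_class_width,
    ensure_min_classes,
    filter_cells,
    histograms_to_frame,
)
from .importance import RFConfig, kendall_matrix, permutation_importance
from .regression import fit_all, select_model
from .variables import REPRESENTATIVE, VARIABLE_ORDER
from .world import WorldConfig, generate_world, read_cells, write_cells

logger = logging.getLogger(__name__)

STAGES = ("summarize", "evenness", "regress", "importance", "correlate")


@dataclass
class RunConfig:
    """One pipeline run: input world or cell table, stages, seed, output dir."""

    world: WorldConfig | None = None
    cells_path: str | None = None
    regions: list[str] | str = "ALL"
    variables: list[VariableSpec] | None = None      # None -> canonical 15
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    output_dir: str = "protgrad_out"
    min_classes: int = MIN_CLASSES
    truncation: tuple[float, float] = DEFAULT_TRUNCATION
    rf: RFConfig | None = None
    importance_regions: list[str] | str = "GLOBAL"   # forests are costly; opt into regions

    def validate(self) -> None:
        if (self.world is None) == (self.cells_path is None):
            raise ConfigError("provide exactly one of world config or cells_path")
        if not self.stages:
            raise ConfigError("stages must be nonempty")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stage(s) {unknown}; choose from {STAGES}")


@dataclass
class RunBundle:
    config: RunConfig
    cells: pd.DataFrame
    filtered: pd.DataFrame
    histograms: list[Histogram] = field(default_factory=list)
    evenness: pd.DataFrame | None = None
    fits: pd.DataFrame | None = None
    importance: pd.DataFrame | None = None
    importance_meta: dict = field(default_factory=dict)
    kendall: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def _resolve_regions(config: RunConfig, cells: pd.DataFrame) -> list[str]:
    if isinstance(config.regions, str):
        if config.regions != "ALL":
            raise ConfigError("regions must be 'ALL' or a list of labels")
        return sorted(cells["region"].unique())
    missing = [r for r in config.regions if r not in set(cells["region"])]
    if missing:
        raise ConfigError(f"unknown region label(s) {missing}")
    return list(config.regions)


def _resolve_variables(config: RunConfig, cells: pd.DataFrame) -> list[VariableSpec]:
    specs = config.variables if config.variables is not None else canonical_specs()
    missing = [s.name for s in specs if s.name not in cells.columns]
    if missing:
        raise ConfigError(f"requested variable(s) {missing} not in the cell table")
    return specs


def run_pipeline(config: RunConfig) -> RunBundle:
    """Execute the requested stages in order; idempotent for a fixed seed."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.world is not None:
        logger.info("simulate: generating world (seed=%d)", config.world.seed)
        cells = generate_world(config.world)
        write_cells(cells, out / "cells.csv")
    else:
        cells = read_cells(config.cells_path)

    filtered = filter_cells(cells)
    regions = _resolve_regions(config, filtered)
    specs = _resolve_variables(config, filtered)
    strata = regions + [GLOBAL]
    bundle = RunBundle(config=config, cells=cells, filtered=filtered)

    if "summarize" in config.stages:
        for spec in specs:
            width = spec.class_width or default_class_width(
                filtered, spec.name, truncation=config.truncation
            )
            for region in strata:
                try:
                    h = build_histogram(
                        filtered, spec, region=region, width=width,
                        truncation=config.truncation,
                    )
                    h = ensure_min_classes(h, filtered, spec, min_classes=config.min_classes)
                except ProtgradError as exc:
                    raise ProtgradError(
                        f"summarize failed for variable {spec.name!r}, region {region!r}: {exc}"
                    ) from exc
                bundle.histograms.append(h)
        logger.info("summarize: built %d histograms (%d strata x %d variables)",
                    len(bundle.histograms), len(strata), len(specs))
        histograms_to_frame(bundle.histograms).to_csv(out / "histograms.csv", index=False)

    if "evenness" in config.stages:
        rows = []
        for h in bundle.histograms:
            try:
                cmp = compare_representativeness(h)
            except ProtgradError as exc:
                raise ProtgradError(
                    f"evenness failed for variable {h.variable!r}, region {h.region!r}: {exc}"
                ) from exc
            for measure, hp in ((FRAC_PROT, None), (AREA_PROT, None)):
                vec = [c.frac_prot if measure == FRAC_PROT else c.area_prot
                       for c in h.nonempty]
                res = evenness(vec, measure=measure)
                rows.append({
                    "variable": h.variable, "region": h.region, "measure": measure,
                    "n_classes": res.n, "H": res.h, "H_prime": res.h_prime,
                })
            rows[-2]["ratio_fraction_over_quota"] = cmp.ratio
        bundle.evenness = pd.DataFrame(rows)
        bundle.evenness.to_csv(out / "evenness.csv", index=False)

    if "regress" in config.stages:
        rows = []
        model_vars = [s for s in specs if s.group != REPRESENTATIVE]
        for spec in model_vars:
            for region in strata:
                h = next(x for x in bundle.histograms
                         if x.variable == spec.name and x.region == region)
                classes = h.nonempty
                x = np.array([c.midpoint for c in classes])
                y = np.array([c.frac_prot for c in classes])
                try:
                    fits = fit_all(x, y, seed=config.seed)
                    best = select_model(fits)
                except ProtgradError as exc:
                    raise ProtgradError(
                        f"regress failed for variable {spec.name!r}, region {region!r}: {exc}"
                    ) from exc
                failed = [f.family for f in fits if not f.ok]
                if failed:
                    logger.info("regress %s/%s: families failed: %s",
                                spec.name, region, failed)
                for f in fits:
                    if not f.ok:
                        continue
                    row = {
                        "variable": spec.name, "region": region, "family": f.family,
                        "selected": f.family == best.family,
                        "aic": f.aic, "pseudo_r2": f.pseudo_r2,
                        "breakpoint": f.coefficients.get("breakpoint"),
                    }
                    for cname, cval in f.coefficients.items():
                        if cname != "breakpoint":
                            row[f"coef_{cname}"] = cval
                    rows.append(row)
        bundle.fits = pd.DataFrame(rows)
        bundle.fits.to_csv(out / "fits.csv", index=False)

    if "importance" in config.stages:
        rf = config.rf or RFConfig(seed=config.seed)
        imp_regions = bundle_importance_regions(config, regions)
        frames = []
        for region in imp_regions:
            sub = filtered if region == GLOBAL else filtered[filtered["region"] == region]
            try:
                table = permutation_importance(sub, config=rf)
            except ProtgradError as exc:
                raise ProtgradError(f"importance failed for region {region!r}: {exc}") from exc
            frame = table.to_frame()
            frame.insert(0, "region", region)
            frames.append(frame)
            bundle.importance_meta[region] = {
                "chosen_mtry": table.chosen_mtry, "oob_mse": table.oob_mse,
                "ntree": rf.ntree, "nodesize": rf.nodesize, "seed": rf.seed,
                "group_averages": table.group_averages,
            }
        bundle.importance = pd.concat(frames, ignore_index=True)
        bundle.importance.to_csv(out / "importance.csv", index=False)
        (out / "importance_meta.json").write_text(
            json.dumps(bundle.importance_meta, indent=2, sort_keys=True)
        )

    if "correlate" in config.stages:
        bundle.kendall = kendall_matrix(filtered, variables=list(VARIABLE_ORDER))
        bundle.kendall.to_csv(out / "kendall.csv")

    bundle.manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "regions": regions,
        "variables": [s.name for s in specs],
        "n_cells": int(len(cells)),
        "n_cells_filtered": int(len(filtered)),
        "n_histograms": len(bundle.histograms),
    }
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True))
    return bundle


def bundle_importance_regions(config: RunConfig, regions: list[str]) -> list[str]:
    spec = config.importance_regions
    if isinstance(spec, str):
        if spec == "ALL":
            return regions + [GLOBAL]
        if spec == "GLOBAL":
            return [GLOBAL]
        raise ConfigError("importance_regions must be 'ALL', 'GLOBAL', or a list")
    return list(spec)


def summarize_run(source) -> dict:
    """Condense a completed (possibly partial) run into one JSON-safe summary.

    ``source`` is a RunBundle or an output directory. Missing stages yield
    warnings, not errors.
    """
    warnings: list[str] = []
    if isinstance(source, RunBundle):
        even, fits, imp = source.evenness, source.fits, source.importance
        meta = source.importance_meta
    else:
        root = Path(source)
        def _read(name):
            p = root / name
            return pd.read_csv(p) if p.exists() else None
        even, fits, imp = _read("evenness.csv"), _read("fits.csv"), _read("importance.csv")
        meta_path = root / "importance_meta.json"
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}

    summary: dict = {"warnings": warnings}

    if even is None or len(even) == 0:
        warnings.append("evenness output missing")
    else:
        rows = []
        for region, g in even.groupby("region"):
            frac = g.loc[g["measure"] == FRAC_PROT, "H_prime"].mean()
            quota = g.loc[g["measure"] == AREA_PROT, "H_prime"].mean()
            rows.append({
                "region": region,
                "H_prime_fraction": float(frac),
                "H_prime_quota": float(quota),
                "ratio": float(frac / quota) if quota > 0 else None,
            })
        summary["representativeness"] = rows

    if fits is None or len(fits) == 0:
        warnings.append("regression output missing")
    else:
        sel = fits[fits["selected"] == True]  # noqa: E712  (CSV round-trips bools)
        summary["selected_models"] = [
            {"variable": r.variable, "region": r.region, "family": r.family,
             "pseudo_r2": float(r.pseudo_r2)}
            for r in sel.itertuples()
        ]

    if imp is None or len(imp) == 0:
        warnings.append("importance output missing")
    else:
        ranking = []
        for region, g in imp.groupby("region"):
            g = g.sort_values("percent_importance", ascending=False)
            entry = {
                "region": region,
                "ranking": [
                    {"variable": r.variable, "percent_importance": float(r.percent_importance)}
                    for r in g.itertuples()
                ],
            }
            if region in meta:
                entry["chosen_mtry"] = meta[region]["chosen_mtry"]
                entry["group_averages"] = meta[region]["group_averages"]
            ranking.append(entry)
        summary["importance"] = ranking

    return summary
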