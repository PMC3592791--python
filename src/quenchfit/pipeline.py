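"""End-to-end pipeline: simulate -> segment -> fit -> filter -> summarize -> classify.

A scenario YAML describes the plate (population presets, per-well mixtures,
ladder, nuisance levels); a single global seed drives named per-well
substreams, so a rerun with the same config and seed is bit-identical.  Each
stage reads its predecessor's files from the run directory, and a manifest
records seeds, per-stage counts and SHA-256 hashes of every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import filters, io, phenotype, segment, summarize, synth
from .fit import fit_table

__all__ = ["RunConfig", "run_pipeline", "build_well_specs", "ALL_STAGES"]

log = logging.getLogger("quenchfit")

ALL_STAGES = ("simulate", "segment", "fit", "filter", "summarize", "classify")


@dataclass
class RunConfig:
    scenario: dict | str | Path
    outdir: Path
    seed: int = 0
    stages: tuple = ALL_STAGES
    figures: bool = False

    def load_scenario(self) -> dict:
        if isinstance(self.scenario, dict):
            return self.scenario
        return io.load_scenario(self.scenario)


def _population_spec(name: str, cfg: dict) -> synth.PopulationSpec:
    kwargs = dict(cfg)
    for key in ("slope_range", "dF_range", "baseline_range", "radius_range"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return synth.PopulationSpec(name=name, n_cells=kwargs.pop("n_cells", 0), **kwargs)


def build_well_specs(scenario: dict, seed: int) -> list[synth.WellSpec]:
    presets = {n: c for n, c in scenario.get("populations", {}).items()}
    ladder = tuple(scenario.get("ladder", synth.DEFAULT_LADDER))
    wells = []
    for w in scenario["wells"]:
        mix = w["mix"]
        pops = []
        for pname, frac in mix.items():
            if pname not in presets:
                raise io.FormatError(f"well {w['well_id']}: unknown population {pname!r}")
            pops.append((_population_spec(pname, presets[pname]), float(frac)))
        wells.append(
            synth.WellSpec(
                well_id=w["well_id"],
                populations=pops,
                concentration_ladder=tuple(w.get("ladder", ladder)),
                n_cells=w.get("n_cells"),
                debris_count=int(w.get("debris_count", 0)),
                detach_probability=float(w.get("detach_probability", 0.0)),
                noise_sd_frac=float(w.get("noise_sd_frac", 0.02)),
                seed=io.derive_seed(seed, "well", w["well_id"]),
            )
        )
    return wells


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _well_meta(scenario: dict) -> dict:
    return {w["well_id"]: w for w in scenario["wells"]}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages; returns (and writes) the run manifest."""
    scenario = config.load_scenario()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mode = scenario.get("mode", "traces")
    stages = [s for s in ALL_STAGES if s in config.stages]
    specs = build_well_specs(scenario, config.seed)
    meta = _well_meta(scenario)
    counts: dict = {}

    if "simulate" in stages:
        counts["simulate"] = {}
        for spec in specs:
            if mode == "images":
                series, truth = synth.render_image_series(spec)
                io.write_image_series(series, outdir / "sim" / f"{spec.well_id}.tiff")
            else:
                traces, truth = synth.generate_traces(spec)
                io.write_trace_csv(traces, outdir / "traces" / f"{spec.well_id}.csv")
            (outdir / "sim").mkdir(exist_ok=True)
            truth.to_csv(outdir / "sim" / f"{spec.well_id}_truth.csv", index=False,
                         float_format="%.10g")
            counts["simulate"][spec.well_id] = len(truth)
            log.info("simulate %s: %d objects", spec.well_id, len(truth))

    if "segment" in stages and mode == "images":
        counts["segment"] = {}
        params = segment.SegmentationParams(**scenario.get("segmentation", {}))
        for spec in specs:
            tiff = outdir / "sim" / f"{spec.well_id}.tiff"
            if not tiff.exists():
                raise FileNotFoundError(f"segment stage needs {tiff}; run simulate first")
            series = io.read_image_series(tiff)
            _, objects = segment.segment_reference(series.frames[0], params)
            table = segment.measure_series(objects, series)
            io.write_trace_csv(table, outdir / "traces" / f"{spec.well_id}.csv")
            counts["segment"][spec.well_id] = len(objects)
            log.info("segment %s: %d objects", spec.well_id, len(objects))

    if "fit" in stages:
        counts["fit"] = {}
        for spec in specs:
            tpath = outdir / "traces" / f"{spec.well_id}.csv"
            if not tpath.exists():
                raise FileNotFoundError(f"fit stage needs {tpath}; run simulate/segment first")
            traces = io.read_trace_csv(tpath)
            fits = fit_table(traces)
            io.write_fit_csv(fits, outdir / "fits" / f"{spec.well_id}.csv")
            counts["fit"][spec.well_id] = len(fits)

    if "filter" in stages:
        counts["filter"] = {}
        criteria = filters.FilterCriteria(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in scenario.get("filter", {}).items()
        })
        for spec in specs:
            fpath = outdir / "fits" / f"{spec.well_id}.csv"
            if not fpath.exists():
                raise FileNotFoundError(f"filter stage needs {fpath}; run fit first")
            flagged = filters.apply_filters(io.read_fit_csv(fpath), criteria)
            io.write_fit_csv(flagged, outdir / "filtered" / f"{spec.well_id}.csv")
            report = filters.filter_report(flagged)
            (outdir / "filtered" / f"{spec.well_id}_report.json").write_text(
                json.dumps(report.as_dict(), indent=2, sort_keys=True) + "\n"
            )
            counts["filter"][spec.well_id] = report.n_pass_combined

    if "summarize" in stages:
        summaries = []
        for spec in specs:
            fpath = outdir / "filtered" / f"{spec.well_id}.csv"
            if not fpath.exists():
                raise FileNotFoundError(f"summarize stage needs {fpath}; run filter first")
            summaries.append(summarize.well_summary(pd.read_csv(fpath), spec.well_id))
        (outdir / "summary").mkdir(exist_ok=True)
        pd.DataFrame([s.as_dict() for s in summaries]).to_csv(
            outdir / "summary" / "wells.csv", index=False, float_format="%.10g"
        )
        matrix = summarize.plate_matrix(summaries)
        matrix.to_csv(outdir / "summary" / "plate_ec50.csv", float_format="%.10g")
        if config.figures:
            summarize.render_plate_map(matrix, outdir / "summary" / "plate_ec50.png")
        counts["summarize"] = {s.well_id: s.n_accepted for s in summaries}

    if "classify" in stages:
        train_wells = [w for w, m in meta.items() if m.get("role") == "train"]
        test_wells = [w for w, m in meta.items() if m.get("role") == "classify"]
        if train_wells:
            rows = []
            for w in train_wells:
                flagged = pd.read_csv(outdir / "filtered" / f"{w}.csv")
                acc = flagged[flagged["pass_all"]].copy()
                label = meta[w].get("class") or max(meta[w]["mix"], key=meta[w]["mix"].get)
                acc["label"] = label
                rows.append(acc)
            train = pd.concat(rows, ignore_index=True)
            model = phenotype.train_classifier(
                train, folds=int(scenario.get("cv_folds", 10)),
                seed=io.derive_seed(config.seed, "classify"),
            )
            pdir = outdir / "phenotype"
            pdir.mkdir(exist_ok=True)
            (pdir / "model.json").write_text(model.to_json() + "\n")
            report = {"cv_accuracy_per_class": model.cv_accuracy_per_class,
                      "cv_confusion": model.cv_confusion.tolist(),
                      "classes": model.classes, "fractions": {}}
            for w in test_wells:
                flagged = pd.read_csv(outdir / "filtered" / f"{w}.csv")
                acc = flagged[flagged["pass_all"]]
                labels, fractions = phenotype.classify(model, acc)
                pred = acc[["cell_id"]].copy()
                pred["predicted_class"] = labels
                pred.to_csv(pdir / f"{w}_predictions.csv", index=False)
                report["fractions"][w] = {str(k): float(v) for k, v in fractions.items()}
            (pdir / "report.json").write_text(
                json.dumps(report, indent=2, sort_keys=True) + "\n"
            )
            counts["classify"] = {"n_train": len(train),
                                  "wells_classified": len(test_wells)}

    files = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "scenario_name": scenario.get("name", "unnamed"),
        "seed": config.seed,
        "mode": mode,
        "stages": stages,
        "counts": counts,
        "files": files,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
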