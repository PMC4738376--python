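"""End-to-end orchestration over a cohort directory.

``run_all`` reproduces the full analysis plan on any cohort laid out as a
fixture directory (masks/, tract.nii.gz, atlas.nii.gz + atlas_names.tsv,
behaviour.csv): load and flip, tract lesion loads, the behavioural
regression battery, one VLSM run per measure, atlas labelling of
significant clusters, the sensitivity reruns, and optionally leave-one-out
stability.  A manifest (seed, config echo, input hashes, versions, stage
timings, exclusions) fully determines every numeric output.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import LabelAtlas, label_overlap, read_atlas, tract_intersection
from .stats import (DegenerateDataError, covariate_correlations,
                    load_regression_battery, summarize_cohort)
from .tract import TractMap, cohort_loads
from .vlsm import VlsmConfig, VlsmReport, loo_stability, run_vlsm, sensitivity_configs
from .volumes import (MEASURES, LesionCohort, load_cohort, read_mask,
                      write_volume)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _hash_inputs(cohort_dir: Path) -> dict[str, str]:
    out = {}
    for p in sorted(cohort_dir.rglob("*")):
        if p.is_file() and p.suffix in (".gz", ".nii", ".csv", ".tsv"):
            out[str(p.relative_to(cohort_dir))] = _hash_file(p)
    return out


def _write_vlsm_report(report: VlsmReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_volume(report.overlap_count, out_dir / "overlap_count.nii.gz",
                 dtype=np.int16)
    if report.tmap is not None:
        write_volume(report.tmap.t, out_dir / "tmap.nii.gz", dtype=np.float32)
        labels = np.zeros(report.tmap.t.shape, dtype=np.int16)
        for i, c in enumerate(report.clusters, start=1):
            labels[c.voxels[:, 0], c.voxels[:, 1], c.voxels[:, 2]] = i
        write_volume(report.tmap.t.with_data(labels),
                     out_dir / "clusters.nii.gz", dtype=np.int16)
    report.clusters_frame().to_csv(out_dir / "clusters.csv", index=False)
    with open(out_dir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(report.config), fh, indent=2)
    with open(out_dir / "log.txt", "w") as fh:
        fh.write("\n".join(report.log) + "\n")


def _label_clusters(report: VlsmReport, atlases: list[LabelAtlas],
                    tract: TractMap, out_path: Path) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(report.significant_clusters, start=1):
        for atlas in atlases:
            rep = label_overlap(c.voxels, atlas)
            for r in rep.rows.itertuples():
                rows.append({"cluster": i, "atlas": atlas.atlas_name,
                             "structure": r.structure, "percent": r.percent,
                             "voxels": r.voxels})
        inter = tract_intersection(c.voxels, tract)
        rows.append({"cluster": i, "atlas": "canonical-tract",
                     "structure": "tract", "percent": inter["percent"],
                     "voxels": inter["voxels"]})
    df = pd.DataFrame(rows, columns=["cluster", "atlas", "structure",
                                     "percent", "voxels"])
    df.to_csv(out_path, index=False)
    return df


def run_all(cohort_dir: str | Path, out_dir: str | Path,
            tract_path: str | Path | None = None,
            atlas_specs: list[tuple] | None = None,
            vlsm_config: VlsmConfig | None = None,
            measures: tuple[str, ...] = MEASURES,
            sensitivity: bool = True, loo: bool = False,
            loo_tolerance_mm: float = 1.4) -> dict:
    """Execute the whole analysis plan; returns the manifest (also written
    to ``out_dir/manifest.json``)."""
    cohort_dir = Path(cohort_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = vlsm_config or VlsmConfig()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "vlsm_config": dataclasses.asdict(config),
        "inputs": _hash_inputs(cohort_dir),
        "timings_s": {},
        "stages": {},
    }

    def stage(name):
        t0 = time.perf_counter()
        def done(**info):
            manifest["timings_s"][name] = round(time.perf_counter() - t0, 3)
            manifest["stages"][name] = info
        return done

    done = stage("load")
    cohort = load_cohort(cohort_dir / "masks", cohort_dir / "behaviour.csv")
    manifest["exclusions"] = cohort.exclusions
    done(n_subjects=len(cohort))

    tract_path = Path(tract_path) if tract_path else cohort_dir / "tract.nii.gz"
    tract = TractMap.from_mask(read_mask(tract_path, cohort.grid))
    if atlas_specs is None:
        atlas_specs = [(cohort_dir / "atlas.nii.gz",
                        cohort_dir / "atlas_names.tsv", "atlas")]
    atlases = [read_atlas(v, n, name) for v, n, name in atlas_specs]

    done = stage("loads")
    loads = cohort_loads(cohort, tract)
    loads.to_csv(out / "loads.csv", index=False)
    done(n_flagged=int((loads["status"] != "ok").sum()))

    done = stage("descriptives")
    summaries = summarize_cohort(cohort)
    summaries["covariates"].to_csv(out / "covariate_summary.csv")
    summaries["measures"].to_csv(out / "measure_summary.csv")
    covariate_correlations(cohort).to_csv(out / "covariate_correlations.csv")
    done()

    done = stage("load_regressions")
    try:
        battery = load_regression_battery(cohort, loads)
        for m, res in battery.items():
            res.table.to_csv(out / f"load_regression_{m}.csv")
        done(measures=list(battery))
    except DegenerateDataError as exc:
        done(skipped=str(exc))

    sig_by_measure: dict[str, VlsmReport] = {}
    for m in measures:
        done = stage(f"vlsm_{m}")
        report = run_vlsm(cohort, m, config)
        _write_vlsm_report(report, out / f"vlsm_{m}")
        _label_clusters(report, atlases, tract, out / f"vlsm_{m}" / "labels.csv")
        if report.significant_clusters:
            sig_by_measure[m] = report
        done(n_clusters=len(report.clusters),
             n_significant=len(report.significant_clusters))

    if sensitivity:
        for m, ref in sig_by_measure.items():
            for name, cfg in sensitivity_configs(config).items():
                done = stage(f"sensitivity_{m}_{name}")
                rep = run_vlsm(cohort, m, cfg)
                _write_vlsm_report(rep, out / f"sensitivity_{m}" / name)
                done(n_significant=len(rep.significant_clusters))

    if loo:
        for m, ref in sig_by_measure.items():
            done = stage(f"loo_{m}")
            folds = loo_stability(cohort, m, config,
                                  tolerance_mm=loo_tolerance_mm, reference=ref)
            folds.to_csv(out / f"loo_{m}.csv", index=False)
            done(n_within=int(folds["within_tolerance"].sum()),
                 n_folds=len(folds))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def run_side_split(cohort_dir: str | Path, out_dir: str | Path,
                   vlsm_config: VlsmConfig | None = None,
                   measures: tuple[str, ...] = MEASURES) -> dict:
    """Rerun the VLSM stage separately on the left- and right-sided
    subsets (masks stay in the flipped common space; only the subjects
    differ).  Subsets too small to form a search volume are skipped."""
    cohort_dir = Path(cohort_dir)
    out = Path(out_dir)
    config = vlsm_config or VlsmConfig()
    cohort = load_cohort(cohort_dir / "masks", cohort_dir / "behaviour.csv")
    result: dict = {"subsets": {}}
    for side in ("left", "right"):
        keep = [i for i, r in enumerate(cohort.records) if r.side == side]
        if len(keep) < config.min_lesioned + 2:
            result["subsets"][side] = {"skipped": f"only {len(keep)} subjects"}
            continue
        sub = cohort.subset(keep)
        info: dict = {"n_subjects": len(sub)}
        for m in measures:
            report = run_vlsm(sub, m, config)
            _write_vlsm_report(report, out / side / f"vlsm_{m}")
            info[f"vlsm_{m}_significant"] = len(report.significant_clusters)
        result["subsets"][side] = info
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "side_split.json", "w") as fh:
        json.dump(result, fh, indent=2)
    return result
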