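"""End-to-end orchestration: simulate -> measure -> QC/Z -> hits -> secondary.

A single :class:`RunConfig` drives the whole screen.  Every stochastic
stage derives its seed deterministically from the global seed and the
stage name, so the same config always yields byte-identical artifacts.
Fast mode simulates well-level tables directly and scales to the full
library; image mode renders and quantifies microscopy images and
defaults to a reduced plate count for desk-scale runs.

All intermediate artifacts (plate map, well table, QC report, Z tables,
scored table, hit list, secondary results) are persisted, and the run
report is re-derivable from them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .layout import (ROLE_DARK, generate_layout, layouts_to_frame)
from .synthdata import (GroundTruth, make_ground_truth, planted_ids,
                        simulate_secondary_assay, simulate_well_table)
from .render import ImagingParams, render_well_image
from .imaging import (ClassifierParams, SegmentationParams, classify_nuclei,
                      fit_thresholds, measure_well, measurements_to_frame,
                      segment_nuclei)
from .platestats import QCParams, qc_and_zscore, write_qc_report
from .hitcall import (HitCallingConfig, aggregate_replicates, rank_and_filter,
                      scores_to_frame)
from .secondary import results_to_frame, two_way_test

logger = logging.getLogger("hcsprotect")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 2_654_435_761 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Everything a screen run needs; JSON round-trippable."""

    seed: int = 0
    mode: str = "fast"                    # "fast" or "images"
    n_mirnas: int = 1268
    replicates: int = 3
    n_protective: int = 0
    protective_effect: float = 0.5
    n_deleterious: int = 0
    deleterious_effect: float = 1.5
    baseline_dark: float = 0.05
    baseline_light: float = 0.40
    noise_sd: float = 0.05
    batch_offset_sd: float = 0.02
    annotation_fraction: float = 0.6      # of the library, plus planted hits
    min_nuclei: int = 50
    image_plates: int = 1                 # plates rendered in image mode
    run_secondary: bool = True
    secondary_cells_per_well: int = 60_000
    secondary_replicates: int = 3
    qc: QCParams = field(default_factory=QCParams)
    hits: HitCallingConfig = field(default_factory=HitCallingConfig)
    imaging: ImagingParams = field(default_factory=ImagingParams)

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        for key, sub in (("qc", QCParams), ("hits", HitCallingConfig),
                         ("imaging", ImagingParams)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunReport:
    config: dict
    version: str
    plate_qc: list[dict]
    stage_counts: dict
    shortlist: list[str]
    protective: list[str]
    deleterious: list[str]
    secondary: list[dict]
    ground_truth_summary: dict

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _measure_plate_from_images(layout, truth: GroundTruth,
                               config: RunConfig) -> pd.DataFrame:
    """Render and quantify every well of one plate (image mode)."""
    seg = SegmentationParams()
    rendered = {}
    for well in sorted(layout.role_map):
        role = layout.role_map[well]
        if role == "empty":
            continue
        seed = stage_seed(config.seed, f"image:{layout.plate_id}:{well}")
        rendered[well] = render_well_image(
            layout.mirna_map.get(well), role != ROLE_DARK, truth,
            config.imaging, seed, image_id=f"{layout.plate_id}_{well}")

    # Fit classifier thresholds from this plate's dark-control nuclei.
    reference = []
    segmented = {}
    for well, rw in rendered.items():
        records = segment_nuclei(rw.image, seg)
        segmented[well] = records
        if layout.role_map[well] == ROLE_DARK:
            reference.extend(records)
    thresholds = fit_thresholds(reference)

    measurements = []
    for well, records in segmented.items():
        labelled = classify_nuclei(
            records, ClassifierParams(thresholds=thresholds))
        measurements.append(measure_well(
            labelled, plate_id=layout.plate_id, well=well,
            role=layout.role_map[well], mirna_id=layout.mirna_map.get(well),
            min_nuclei=config.min_nuclei))
    frame = measurements_to_frame(measurements)
    frame["replicate"] = layout.replicate_index
    return frame


def run_screen(config: RunConfig, outdir) -> RunReport:
    """Run the full screen and persist every intermediate artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    layouts = generate_layout(config.n_mirnas, config.replicates,
                              stage_seed(config.seed, "layout"))
    platemap = layouts_to_frame(layouts)
    platemap.to_csv(outdir / "platemap.csv", index=False)
    mirna_ids = sorted({m for lay in layouts for m in lay.mirna_map.values()})

    truth = make_ground_truth(
        mirna_ids, stage_seed(config.seed, "truth"),
        n_protective=config.n_protective,
        protective_effect=config.protective_effect,
        n_deleterious=config.n_deleterious,
        deleterious_effect=config.deleterious_effect,
        baseline_dark=config.baseline_dark,
        baseline_light=config.baseline_light)

    # Annotation membership: a random library subset plus every planted hit,
    # so annotation filtering never hides a true effect by construction.
    ann_rng = np.random.default_rng(stage_seed(config.seed, "annotation"))
    n_ann = int(round(config.annotation_fraction * len(mirna_ids)))
    annotation = set(ann_rng.choice(mirna_ids, size=n_ann, replace=False))
    annotation |= set(planted_ids(truth, "protective"))
    annotation |= set(planted_ids(truth, "deleterious"))
    (outdir / "annotation.txt").write_text(
        "\n".join(sorted(annotation)) + "\n")

    if config.mode == "fast":
        well_table = simulate_well_table(
            layouts, truth, config.noise_sd,
            stage_seed(config.seed, "wells"),
            batch_offset_sd=config.batch_offset_sd)
    elif config.mode == "images":
        use = layouts[:config.image_plates * config.replicates]
        frames = [_measure_plate_from_images(lay, truth, config)
                  for lay in use]
        well_table = pd.concat(frames, ignore_index=True)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    well_table.to_csv(outdir / "well_table.csv", index=False)

    qcs, zframe = qc_and_zscore(well_table, config.qc)
    write_qc_report(qcs, outdir / "qc.json")
    zframe.to_csv(outdir / "zscores.csv", index=False)
    failed = [qc.plate_id for qc in qcs if not qc.passed]
    if failed:
        logger.warning("plates failing QC (excluded): %s", failed)

    ztables = [grp.drop(columns=["replicate"])
               for _, grp in zframe.groupby("replicate", sort=True)]
    scores = aggregate_replicates(ztables)
    scores_frame_pre = len(scores)
    hit_config = config.hits
    if hit_config.min_replicates > config.replicates:
        hit_config = dataclasses.replace(hit_config,
                                         min_replicates=config.replicates)
    hits = rank_and_filter(scores, annotation, hit_config)
    scores_to_frame(scores).to_csv(outdir / "scores.csv", index=False)
    hits.to_json(outdir / "hits.json")
    for stage in ("n_scored", "n_protective_cutoff", "n_after_annotation",
                  "n_shortlist"):
        logger.info("hit calling %s = %d", stage, hits.provenance[stage])

    secondary_results = []
    if config.run_secondary and hits.shortlist:
        effects = {m: truth.effect_map.get(m, 1.0) for m in hits.shortlist}
        counts = simulate_secondary_assay(
            effects, config.baseline_dark, config.baseline_light,
            config.secondary_cells_per_well, config.secondary_replicates,
            stage_seed(config.seed, "secondary"))
        counts.to_csv(outdir / "secondary_counts.csv", index=False)
        for mid in hits.shortlist:
            res = two_way_test(counts[counts["mirna_id"] == mid])
            secondary_results.append(res)
        results_to_frame(secondary_results).to_csv(
            outdir / "secondary_results.csv", index=False)

    truth_summary = {
        "n_mirnas": len(mirna_ids),
        "baseline_dark": truth.baseline_dying_dark,
        "baseline_light": truth.baseline_dying_light,
        "planted_protective": planted_ids(truth, "protective"),
        "planted_deleterious": planted_ids(truth, "deleterious"),
    }
    (outdir / "ground_truth.json").write_text(json.dumps({
        **truth_summary, "effect_map": truth.effect_map,
        "seed": truth.seed}, indent=2, sort_keys=True))

    report = RunReport(
        config=asdict(config),
        version=__version__,
        plate_qc=[qc.to_dict() for qc in qcs],
        stage_counts={**{k: v for k, v in hits.provenance.items()
                         if isinstance(v, int)},
                      "n_plates": len(qcs),
                      "n_plates_failed_qc": len(failed),
                      "n_scores_input": scores_frame_pre},
        shortlist=hits.shortlist,
        protective=hits.protective,
        deleterious=hits.deleterious,
        secondary=[{
            "mirna_id": r.mirna_id,
            "fc_mimic_mean": r.fc_mimic_mean,
            "fc_negative_mean": r.fc_negative_mean,
            "p_interaction": r.p_values["interaction"],
            "significant": r.significant,
            "effect_direction": r.effect_direction,
        } for r in secondary_results],
        ground_truth_summary=truth_summary,
    )
    report.to_json(outdir / "report.json")
    return report
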