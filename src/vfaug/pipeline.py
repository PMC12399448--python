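"""End-to-end pipeline: phantoms -> per-class diffusion -> curation ->
augmentation scenarios -> evaluation -> aggregated report bundle.

Every stage logs its seed, the config hash and its runtime; the resolved
config is serialized into the output directory so each artifact records
exactly what produced it. Rerunning with the same config reproduces all
deterministic outputs. No stage touches the network.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .curation import CurationThresholds, curate, default_sharpness_threshold
from .datasets import LABELS, ClassDistribution, ImageDataset
from .ddpm import DiffusionTrainConfig, build_schedule, sample_images, train_ddpm
from .experiments import ClassifierTrainConfig, derive_seed, run_experiment_grid
from .io import save_checkpoint, write_dataset, write_train_log
from .metrics import PCAFeatureExtractor, fid_between
from .phantom import PhantomStyle, generate_dataset

log = logging.getLogger("vfaug")


def _stage(name: str, config: PipelineConfig):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.time()
            log.info("stage=%s start seed=%d config=%s", name,
                     derive_seed(config.seed, name), config.config_hash())
            return self

        def __exit__(self, *exc):
            log.info("stage=%s done runtime=%.1fs", name, time.time() - self.t0)
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig, output_root: str | Path | None = None) -> dict:
    """Execute the full workflow and write a report bundle.

    Returns a summary dict with paths and headline tables. Any stage error
    aborts with the stage name; partial outputs stay on disk.
    """
    out = Path(output_root or config.output_root)
    out.mkdir(parents=True, exist_ok=True)
    config.dump_yaml(out / "config.yaml")
    (out / "seeds.json").write_text(json.dumps({
        "global_seed": config.seed,
        "stage_seeds": {s: derive_seed(config.seed, s)
                        for s in ("phantom", "ddpm", "sample", "curate", "grid")},
        "config_hash": config.config_hash(),
    }, indent=2))

    with _stage("phantom", config):
        counts = (ClassDistribution.original_study()
                  if config.phantom.counts == "study_original"
                  else ClassDistribution(config.phantom.counts))
        style = PhantomStyle(
            image_size=config.ddpm.input_size,
            rotation_deg=config.phantom.rotation_deg,
            gain_range=config.phantom.gain_range,
            noise_sigma=config.phantom.noise_sigma,
        )
        original = generate_dataset(counts, seed=derive_seed(config.seed, "phantom"),
                                    image_size=config.ddpm.input_size, style=style)
        write_dataset(original, out / "original")

    synth_parts: list[ImageDataset] = []
    for label in LABELS:
        per_class = original.filter_labels([label])
        if len(per_class) == 0:
            continue
        with _stage(f"ddpm[{label}]", config):
            cfg = DiffusionTrainConfig(
                epochs=config.ddpm.epochs, steps=config.ddpm.steps,
                learning_rate=config.ddpm.learning_rate,
                batch_size=config.ddpm.batch_size,
                input_size=config.ddpm.input_size, T=config.ddpm.T,
                s=config.ddpm.s, base_channels=config.ddpm.base_channels,
                seed=derive_seed(config.seed, "ddpm", label),
            )
            model = train_ddpm(per_class, cfg)
            save_checkpoint(model, out / "checkpoints" / f"ddpm-{label}.npz")
            write_train_log(model, out / "checkpoints" / f"ddpm-{label}-loss.csv")
            schedule = build_schedule(cfg.T, cfg.s)
            synth_parts.append(sample_images(
                model, schedule, n=config.ddpm.samples_per_class,
                seed=derive_seed(config.seed, "sample", label), label=label))
    synthetic_raw = synth_parts[0]
    for part in synth_parts[1:]:
        synthetic_raw = synthetic_raw.concat(part)
    write_dataset(synthetic_raw, out / "synthetic_raw")

    with _stage("curate", config):
        if config.curation.enabled:
            thresholds = CurationThresholds(
                sharpness_min=default_sharpness_threshold(
                    original, config.curation.sharpness_quantile),
                require_two_folds=config.curation.require_two_folds,
            )
            synthetic, report = curate(synthetic_raw, thresholds)
            (out / "curation_report.json").write_text(report.to_json())
            rejected = synthetic_raw.subset(report.rejected)
            if len(rejected):
                write_dataset(rejected, out / "rejected")
            # the scenario grid needs >=2 classes of synthetic images per
            # task; if curation was stricter than that (e.g. an undertrained
            # generator), keep the raw set so the run still completes
            from .datasets import PATHOLOGY_LABELS as _PL

            n_path = len({l for l in synthetic.labels if l in _PL})
            covers_binary = ("binary" not in config.experiments.tasks
                             or "without_pathology" in set(synthetic.labels))
            if len(synthetic) == 0 or n_path < 2 or not covers_binary:
                log.warning(
                    "curation retained %d images covering %d pathology classes; "
                    "continuing with the raw synthetic set", len(synthetic), n_path)
                synthetic = synthetic_raw
        else:
            synthetic = synthetic_raw
        write_dataset(synthetic, out / "synthetic")

    with _stage("fid", config):
        fid_rows = []
        if config.evaluation.compute_fid:
            extractor = PCAFeatureExtractor(config.evaluation.fid_components).fit(original)
            for label in LABELS:
                real_c = original.filter_labels([label])
                synth_c = synthetic.filter_labels([label])
                if len(real_c) >= 2 and len(synth_c) >= 2:
                    res = fid_between(real_c, synth_c, extractor)
                    fid_rows.append({"label": label, "fid": res.value,
                                     "extractor": res.extractor})
            pd.DataFrame(fid_rows).to_csv(out / "fid_per_class.csv", index=False)

    with _stage("grid", config):
        exp = config.experiments
        grid = run_experiment_grid(
            original, synthetic,
            scenarios=tuple(exp.scenarios) + ("original_only_baseline",),
            tasks=tuple(exp.tasks), repeats=exp.repeats,
            seed=derive_seed(config.seed, "grid"),
            config=ClassifierTrainConfig(
                batch_size=exp.batch_size, learning_rate=exp.learning_rate,
                epochs=exp.epochs, validation_fraction=exp.validation_fraction,
                backbone=exp.backbone, warm_start=exp.warm_start,
                base_channels=exp.base_channels, seed=config.seed,
            ),
        )
        tables = {}
        for task in exp.tasks:
            table = grid.table(task)
            table.to_csv(out / f"metrics_{task}.csv")
            tables[task] = table
        machine = {
            f"{scenario}/{task}": agg.reset_index().to_dict(orient="records")
            for (scenario, task), agg in grid.aggregated.items()
        }
        (out / "metrics.json").write_text(json.dumps(machine, indent=2))

    return {
        "output_root": str(out),
        "n_original": len(original),
        "n_synthetic_raw": len(synthetic_raw),
        "n_synthetic": len(synthetic),
        "fid_per_class": fid_rows,
        "tables": tables,
        "config_hash": config.config_hash(),
    }
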