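"""End-to-end experiment orchestration: split -> build -> train ->
threshold -> classify -> report, with all artifacts written to disk."""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np

from . import classifier, data, evaluation, models, synthetic
from .config import RunConfig

logger = logging.getLogger(__name__)


def _substream_seeds(global_seed: int, n: int = 4) -> list[int]:
    """Named substream seeds derived from the global seed (init, split,
    training, synthesis), each below 2**31."""
    ss = np.random.SeedSequence(global_seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def run_synthetic_benchmark(variant: str = "bvcae", beta: float = 5.0,
                            n_hidden_layers: int = 4, seed: int = 0,
                            n_train: int = 300, n_val: int = 100,
                            n_test_each: int = 100) -> evaluation.EvaluationReport:
    """Train-on-normals recovery benchmark on synthetic radiographs.

    Generates pseudo-radiographs with the generator defaults, trains the
    requested variant on ``n_train`` normal images under the reference
    schedule (10 epochs, lr 0.1 decayed 0.2x every 3 epochs, momentum
    0.9, batch 32), fits the max-validation-error threshold, and
    evaluates on a balanced test set of ``n_test_each`` held-out normals
    and ``n_test_each`` anomalous images. One ``seed`` drives synthesis,
    initialisation and training via independent substreams.
    """
    synth_seed, init_seed, train_seed, _ = _substream_seeds(seed)
    scfg = synthetic.SynthConfig(n_normal=n_train + n_val + n_test_each,
                                 n_anomalous=n_test_each, seed=synth_seed)
    normals = synthetic.generate_normal(scfg)
    anoms = synthetic.generate_anomalous(scfg)

    def rads(arr, label, tag):
        return [data.Radiograph(a, f"{tag}{i:05d}", label)
                for i, a in enumerate(arr)]

    split = data.DatasetSplit(
        train=rads(normals[:n_train], "negative", "train"),
        validation=rads(normals[n_train:n_train + n_val], "negative", "val"),
        test_same=rads(normals[n_train + n_val:], "negative", "testn"),
        test_other=rads(anoms, "positive", "testa"),
        scenario="train_neg")
    spec = models.ModelSpec(variant, n_hidden_layers, beta=beta)
    model = models.build_model(spec, seed=init_seed)
    model, _ = classifier.train(model, split,
                                classifier.TrainingConfig(seed=train_seed))
    threshold = classifier.fit_threshold(model, split.validation)
    test = [*split.test_same, *split.test_other]
    decisions = classifier.classify(model, threshold, test, "train_neg")
    truths = {im.source_id: im.label for im in test}
    tag = f"{variant}(beta={beta})" if variant == "bvcae" else variant
    return evaluation.evaluate(decisions, truths, model_tag=tag,
                               scenario="train_neg")


def run_experiment(cfg: RunConfig, images: list[data.Radiograph] | None = None
                   ) -> dict:
    """Execute the full pipeline described by a resolved RunConfig.

    ``images`` may be supplied directly (e.g. synthetic data); otherwise
    they are loaded from ``cfg.data['root']``. Writes checkpoint,
    training log, decisions CSV, report and the resolved config into
    ``cfg.eval['out_dir']`` and returns the in-memory artifacts.
    """
    out_dir = Path(cfg.eval.get("out_dir", "pneumoscope_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text(cfg.to_yaml())

    init_seed, split_seed, train_seed, _ = _substream_seeds(cfg.global_seed)
    scenario = cfg.data.get("scenario", "train_pos")

    logger.info("stage=load")
    if images is None:
        images = data.load_directory(cfg.data["root"],
                                     cfg.data.get("label_map"))
    logger.info("stage=split scenario=%s n=%d", scenario, len(images))
    split = data.make_split(images, scenario,
                            seed=cfg.data.get("seed", split_seed))

    logger.info("stage=build variant=%s", cfg.model_spec().variant)
    model = models.build_model(cfg.model_spec(), seed=init_seed)

    logger.info("stage=train n_train=%d", len(split.train))
    tc = cfg.training_config()
    if "seed" not in cfg.training:
        tc = classifier.TrainingConfig(
            **{**tc.__dict__, "seed": train_seed})
    model, log = classifier.train(model, split, tc)
    with open(out_dir / "training_log.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch", "lr", "train_loss", "val_loss"])
        for rec in log:
            w.writerow([rec.epoch, f"{rec.lr:.10g}",
                        f"{rec.train_loss:.10g}", f"{rec.val_loss:.10g}"])
    models.save_checkpoint(model, init_seed, out_dir / "model.ckpt.npz")

    logger.info("stage=threshold n_val=%d", len(split.validation))
    threshold = classifier.fit_threshold(model, split.validation)

    logger.info("stage=classify")
    test_images = [*split.test_same, *split.test_other]
    decisions = classifier.classify(model, threshold, test_images, scenario)
    with open(out_dir / "decisions.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source_id", "error", "threshold", "is_anomaly",
                    "predicted_label"])
        for d in decisions:
            w.writerow([d.source_id, f"{d.error:.10g}", f"{d.threshold:.10g}",
                        d.is_anomaly, d.predicted_label])

    logger.info("stage=report")
    truths = {im.source_id: im.label for im in test_images}
    spec = cfg.model_spec()
    report = evaluation.evaluate(decisions, truths,
                                 model_tag=spec.variant, scenario=scenario)
    (out_dir / "report.txt").write_text(
        evaluation.render_report([report]) + "\n")
    (out_dir / "report.json").write_text(
        evaluation.reports_to_json([report]) + "\n")
    return {"split": split, "model": model, "threshold": threshold,
            "decisions": decisions, "report": report, "log": log,
            "out_dir": out_dir}
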