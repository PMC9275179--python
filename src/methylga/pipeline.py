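"""End-to-end orchestration: preprocess -> per-cancer feature selection ->
common-feature intersection -> binary + pan-class training -> evaluation.

Stages write their artifacts under the run's output directory together
with a manifest recording the config hash and every derived seed, so any
artifact traces back to the exact configuration that produced it and any
stage can be re-run individually from cached upstream artifacts.

Seeding is a hash chain: the master seed spawns one seed per (stage,
cohort) via :class:`numpy.random.SeedSequence`, and the outer GA spawns
per-chromosome seeds the same way, so sequential and concurrent runs
agree bit for bit.

Feature selection runs on the malignant samples of the training split
only (the clustering objective presumes a cohort with an established
cancer history); the classifiers consume the cross-cancer intersection
mask.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from sklearn.model_selection import train_test_split

from . import metrics as metrics_mod
from .ilga import IlgaConfig
from .methyl_data import (BetaMatrix, filter_samples, impute_missing,
                          read_beta_csv, read_labels_csv, write_beta_csv)
from .mlp import (FittedModel, MlpSpec, grid_search,
                  predictions_frame, train_model)
from .olga import (FeatureMask, OlgaConfig, common_features, reduction_report,
                   run_olga)
from .platforms import Platform, get_platform

__all__ = ["RunConfig", "run_pipeline", "replicate_runs", "summarise_counts",
           "derive_seed"]

log = logging.getLogger("methylga")

BENIGN_CLASS = "Normal"


def derive_seed(master: int, *key: int | str) -> int:
    """Stable child seed from the master seed and a stage/cohort key."""
    parts = tuple(zlib.crc32(k.encode()) if isinstance(k, str) else int(k)
                  for k in key)
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=parts)
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    cohorts: dict[str, dict[str, str]]  # cancer type -> {matrix, labels}
    platform: str = "custom"
    n_loci: int | None = None
    rejection_threshold: float | None = None  # required for custom platforms
    split_fraction: float = 0.70
    master_seed: int = 0
    threads: int = 1
    output_dir: str = "run"
    olga: OlgaConfig = field(default_factory=OlgaConfig)
    binary_hidden: tuple[int, ...] = (512,)
    pan_hidden: tuple[int, ...] = (256, 128)
    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 32
    use_grid_search: bool = False
    grid_learning_rates: tuple[float, ...] = (0.1, 0.01, 0.001)
    grid_layer_sizes: tuple[int, ...] = (512, 256, 128, 64)
    grid_layer_counts: tuple[int, ...] = (1, 2, 4)

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if not self.cohorts:
            raise ValueError("at least one cohort is required")

    @property
    def resolved_platform(self) -> Platform:
        return get_platform(self.platform, self.n_loci)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        olga_raw = raw.pop("olga", {})
        ilga_raw = raw.pop("ilga", {})
        olga = OlgaConfig(ilga_config=IlgaConfig(**ilga_raw), **olga_raw)
        for key in ("binary_hidden", "pan_hidden", "grid_learning_rates",
                    "grid_layer_sizes", "grid_layer_counts"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(olga=olga, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_jsonable(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if k != "olga"}
        out = {k: list(v) if isinstance(v, tuple) else v for k, v in out.items()}
        out["olga"] = {**{k: v for k, v in self.olga.__dict__.items()
                          if k != "ilga_config"},
                       "ilga": dict(self.olga.ilga_config.__dict__)}
        return out


def _load_cohort(config: RunConfig, name: str) -> BetaMatrix:
    paths = config.cohorts[name]
    labels = read_labels_csv(paths["labels"])
    matrix = read_beta_csv(paths["matrix"], platform=config.resolved_platform,
                           labels=labels)
    missing = [s for s in matrix.sample_ids if s not in labels.index]
    if missing:
        raise ValueError(f"cohort {name}: samples without labels: {missing[:5]}")
    return matrix


def _preprocess(config: RunConfig, name: str, outdir: Path) -> BetaMatrix:
    matrix = _load_cohort(config, name)
    result = filter_samples(matrix, threshold=config.rejection_threshold)
    result.write_log(outdir / f"{name}.rejected.tsv")
    clean = impute_missing(result.matrix)
    write_beta_csv(clean, outdir / f"{name}.preprocessed.csv")
    log.info("preprocess %s: %d/%d samples retained", name,
             clean.n_samples, matrix.n_samples)
    return clean


def _split(matrix: BetaMatrix, fraction: float, seed: int,
           ) -> tuple[list[str], list[str]]:
    """Stratified train/test sample-id split (by malignant flag)."""
    ids = matrix.sample_ids
    strata = matrix.labels.loc[ids, "malignant"].to_numpy()
    if min(np.bincount(strata.astype(int), minlength=2)) < 2:
        strata = None  # cannot stratify a near-constant cohort
    train, test = train_test_split(ids, train_size=fraction, random_state=seed,
                                   stratify=strata, shuffle=True)
    return list(train), list(test)


@dataclass
class PipelineArtifacts:
    masks: dict[str, FeatureMask]
    common_mask: FeatureMask
    binary_model: FittedModel
    pan_model: FittedModel
    binary_report: metrics_mod.ClassificationReport
    pan_report: metrics_mod.ClassificationReport
    manifest: dict


def run_pipeline(config: RunConfig) -> PipelineArtifacts:
    """Execute every stage in order and write all artifacts + manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_jsonable(),
                      "config_hash": config.config_hash(),
                      "seeds": {}, "artifacts": [], "stages": []}
    t0 = time.time()

    def record(stage: str, *artifacts: str) -> None:
        manifest["stages"].append({"stage": stage,
                                   "elapsed_s": round(time.time() - t0, 3)})
        manifest["artifacts"].extend(artifacts)

    def fail(stage: str, exc: Exception) -> Exception:
        log.error("pipeline halted at stage %r: %s", stage, exc)
        return RuntimeError(f"stage {stage!r} failed: {exc}")

    # --- preprocess -------------------------------------------------------
    cohorts: dict[str, BetaMatrix] = {}
    try:
        for name in sorted(config.cohorts):
            cohorts[name] = _preprocess(config, name, outdir)
            record("preprocess", f"{name}.preprocessed.csv", f"{name}.rejected.tsv")
    except Exception as exc:
        raise fail("preprocess", exc) from exc

    # --- split ------------------------------------------------------------
    splits: dict[str, tuple[list[str], list[str]]] = {}
    for name, matrix in cohorts.items():
        seed = derive_seed(config.master_seed, "split", name)
        manifest["seeds"][f"split/{name}"] = seed
        splits[name] = _split(matrix, config.split_fraction, seed)

    # --- per-cancer feature selection ------------------------------------
    masks: dict[str, FeatureMask] = {}
    try:
        for name, matrix in cohorts.items():
            train_ids, _ = splits[name]
            flags = matrix.labels.loc[train_ids, "malignant"]
            cancer_ids = [s for s in train_ids if flags[s]]
            selector_data = matrix.select_samples(
                [matrix.sample_index(s) for s in cancer_ids])
            seed = derive_seed(config.master_seed, "select", name)
            manifest["seeds"][f"select/{name}"] = seed
            olga_cfg = replace(config.olga, seed=seed, n_jobs=config.threads)
            result = run_olga(selector_data, olga_cfg)
            masks[name] = result.best_mask
            n_sel, pct = reduction_report(result.best_mask)
            log.info("select %s: %d loci selected (%.1f%% reduction)",
                     name, n_sel, pct)
            result.best_mask.write_locus_ids(outdir / f"{name}.mask.txt",
                                             matrix.locus_ids)
            result.history.to_csv(outdir / f"{name}.select_history.csv",
                                  index=False)
            record("select", f"{name}.mask.txt", f"{name}.select_history.csv")
    except Exception as exc:
        raise fail("select", exc) from exc

    # --- intersection -----------------------------------------------------
    try:
        common = common_features([masks[name] for name in sorted(masks)])
        any_matrix = next(iter(cohorts.values()))
        common.write_locus_ids(outdir / "common.mask.txt", any_matrix.locus_ids)
        log.info("common features: %d loci", common.n_selected)
        record("intersect", "common.mask.txt")
    except Exception as exc:
        raise fail("intersect", exc) from exc

    # --- assemble training/testing frames --------------------------------
    def stack(ids_of: int) -> tuple[np.ndarray, list[str], list[str], list[str]]:
        X_parts, binary_y, pan_y, all_ids = [], [], [], []
        for name in sorted(cohorts):
            matrix = cohorts[name]
            ids = splits[name][ids_of]
            X_parts.append(matrix.values[[matrix.sample_index(s) for s in ids]])
            flags = matrix.labels.loc[ids, "malignant"]
            binary_y += ["Malignant" if flags[s] else "Benign" for s in ids]
            pan_y += [name if flags[s] else BENIGN_CLASS for s in ids]
            all_ids += list(ids)
        return np.vstack(X_parts), binary_y, pan_y, all_ids

    X_train, bin_train, pan_train, _ = stack(0)
    X_test, bin_test, pan_test, test_ids = stack(1)

    # --- training ---------------------------------------------------------
    def fit(y_train: list[str], hidden: tuple[int, ...], tag: str) -> FittedModel:
        classes = tuple(sorted(set(y_train)))
        seed = derive_seed(config.master_seed, "train", tag)
        manifest["seeds"][f"train/{tag}"] = seed
        if config.use_grid_search:
            Xa, Xb, ya, yb = train_test_split(
                X_train, y_train, train_size=0.8, random_state=seed,
                stratify=y_train, shuffle=True)
            spec, _ = grid_search(
                Xa, ya, Xb, yb, classes,
                learning_rates=config.grid_learning_rates,
                layer_sizes=config.grid_layer_sizes,
                layer_counts=config.grid_layer_counts,
                epochs=max(10, config.epochs // 4),
                batch_size=config.batch_size, seed=seed,
                feature_mask=common)
        else:
            spec = MlpSpec(X_train.shape[1], hidden, classes,
                           learning_rate=config.learning_rate)
        model = train_model(X_train, y_train, spec, epochs=config.epochs,
                            batch_size=config.batch_size, seed=seed,
                            feature_mask=common)
        model.save(outdir / f"{tag}.model")
        return model

    try:
        binary_model = fit(bin_train, config.binary_hidden, "binary")
        pan_model = fit(pan_train, config.pan_hidden, "pan")
        record("train", "binary.model.json", "binary.model.npz",
               "pan.model.json", "pan.model.npz")
    except Exception as exc:
        raise fail("train", exc) from exc

    # --- evaluation -------------------------------------------------------
    def evaluate(model: FittedModel, y_test: list[str], tag: str,
                 ) -> metrics_mod.ClassificationReport:
        scores = model.predict_proba(X_test)
        preds = model.predict(X_test)
        predictions_frame(model, X_test, test_ids).to_csv(
            outdir / f"{tag}.predictions.csv", index=False,
            float_format="%.6g")
        report = metrics_mod.classification_report(
            y_test, preds, scores=scores, classes=model.spec.classes)
        report.save(outdir / f"{tag}.report.json")
        pd.DataFrame(report.heatmap, index=report.confusion.classes,
                     columns=report.confusion.classes).to_csv(
            outdir / f"{tag}.heatmap.csv", float_format="%.10g")
        if report.roc is not None:
            report.write_roc_tsv(outdir / f"{tag}.roc.tsv")
        log.info("%s model: accuracy %.3f, MCC %+.3f", tag,
                 report.overall_accuracy, report.mcc)
        return report

    try:
        binary_report = evaluate(binary_model, bin_test, "binary")
        pan_report = evaluate(pan_model, pan_test, "pan")
        record("evaluate", "binary.report.json", "pan.report.json",
               "binary.heatmap.csv", "pan.heatmap.csv",
               "binary.roc.tsv", "pan.roc.tsv")
    except Exception as exc:
        raise fail("evaluate", exc) from exc

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return PipelineArtifacts(masks, common, binary_model, pan_model,
                             binary_report, pan_report, manifest)


@dataclass
class ReplicateSummary:
    per_replicate_counts: list[int]
    mean_count: float
    ci_half_width: float            # absolute, 95% t-interval
    normalized_ci_percent: float    # half-width / mean, in percent


def summarise_counts(counts: Sequence[int]) -> ReplicateSummary:
    """Textbook 95% t-interval over replicate selected-feature counts:
    half-width ``t_{0.975, n-1} * sd / sqrt(n)``, also normalized as a
    percentage of the mean (how selector stability is usually quoted)."""
    n = len(counts)
    mean = float(np.mean(counts))
    sd = float(np.std(counts, ddof=1))
    t = float(stats.t.ppf(0.975, n - 1))
    half = t * sd / np.sqrt(n)
    normalized = 100.0 * half / mean if mean > 0 else 0.0
    return ReplicateSummary(list(counts), mean, float(half), float(normalized))


def replicate_runs(data: BetaMatrix, olga_config: OlgaConfig,
                   n_replicates: int = 5, master_seed: int = 0,
                   ) -> ReplicateSummary:
    """Run the feature selector repeatedly with derived seeds and summarise
    the selected-feature counts with a normalized 95% confidence interval."""
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    counts = []
    for r in range(n_replicates):
        cfg = replace(olga_config, seed=derive_seed(master_seed, "replicate", r))
        counts.append(run_olga(data, cfg).best_mask.n_selected)
    return summarise_counts(counts)
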