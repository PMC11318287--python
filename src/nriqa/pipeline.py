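"""End-to-end orchestration of the quality-assessment pipeline.

Stage order: (synthetic dataset or image/truth-table load) -> hybrid
denoise -> run-length texture features -> deep features -> fusion and
train-partition min-max normalization -> reptile-search feature
selection -> optional hyperparameter tuning -> fuzzy-network training on
the training partition -> prediction on the test partition ->
correlation/error report.  Every stage's outputs land in a run directory
with a JSON manifest (config hash, seeds, stage log) so a run can be
reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import deepfeat, denoise, evaluate, mrsa, phantom, sdbfn, texture
from .errors import ConfigurationError

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger("nriqa")


def _from_mapping(cls, data: dict, context: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    valid = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    unknown = set(data) - valid
    if unknown:
        raise ConfigurationError(f"unknown keys in {context}: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class SimulateBlock:
    """Synthetic dataset settings; used when no image directory is given."""

    n: int = 200
    variances: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)
    size: int = 64
    n_ellipses: int = 4
    texture_strength: float = 0.3
    noise_model: str = "gaussian"


@dataclass(frozen=True)
class DenoiseBlock:
    spatial_sigma: float = 1.5
    range_sigma: float = 0.1
    radius: int = 3
    window: int = 5
    noise_variance_override: float | None = None

    def bilateral(self) -> denoise.BilateralConfig:
        return denoise.BilateralConfig(self.spatial_sigma, self.range_sigma, self.radius)

    def wiener(self) -> denoise.WienerConfig:
        return denoise.WienerConfig(self.window, self.noise_variance_override)


@dataclass(frozen=True)
class TextureBlock:
    n_levels: int = 16
    directions: tuple[int, ...] = texture.DIRECTIONS


@dataclass(frozen=True)
class DeepfeatBlock:
    backend: str = "default"
    output_dim: int = 64
    seed: int = 0


@dataclass(frozen=True)
class MrsaBlock:
    enabled: bool = True
    pop_size: int = 10
    n_max: int = 40
    alpha: float = 0.1
    beta: float = 0.1
    w_err: float = 0.99
    w_size: float = 0.01
    n_validate: int = 10
    seed: int = 0


@dataclass(frozen=True)
class SdbfnBlock:
    hidden_sizes: tuple[int, ...] = (32, 16)
    p_norm: float = 2.0
    kappa1: float = 0.1
    kappa2: float = 0.1
    epochs: int = 20
    label_threshold: float = 0.5
    tune: bool = False
    seed: int = 0

    def config(self) -> sdbfn.SdbfnConfig:
        return sdbfn.SdbfnConfig(
            hidden_sizes=self.hidden_sizes,
            p_norm=self.p_norm,
            kappa1=self.kappa1,
            kappa2=self.kappa2,
            label_threshold=self.label_threshold,
        )


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    out_dir: str = "runs/latest"
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.75, 0.15, 0.10)
    image_dir: str | None = None
    truth_table: str | None = None
    simulate: SimulateBlock | None = field(default_factory=SimulateBlock)
    denoise: DenoiseBlock = field(default_factory=DenoiseBlock)
    texture: TextureBlock = field(default_factory=TextureBlock)
    deepfeat: DeepfeatBlock = field(default_factory=DeepfeatBlock)
    mrsa: MrsaBlock = field(default_factory=MrsaBlock)
    sdbfn: SdbfnBlock = field(default_factory=SdbfnBlock)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        blocks = {
            "simulate": SimulateBlock,
            "denoise": DenoiseBlock,
            "texture": TextureBlock,
            "deepfeat": DeepfeatBlock,
            "mrsa": MrsaBlock,
            "sdbfn": SdbfnBlock,
        }
        for key, block_cls in blocks.items():
            if key in data and isinstance(data[key], dict):
                block = dict(data[key])
                for tup_key in ("variances", "directions", "hidden_sizes"):
                    if tup_key in block and isinstance(block[tup_key], list):
                        block[tup_key] = tuple(block[tup_key])
                data[key] = _from_mapping(block_cls, block, key)
        if "split_fractions" in data and isinstance(data["split_fractions"], list):
            data["split_fractions"] = tuple(data["split_fractions"])
        return _from_mapping(cls, data, "pipeline config")


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:16]


def _load_real_dataset(config: PipelineConfig):
    from .io import read_image

    table = pd.read_csv(config.truth_table)
    required = {"image_path", "true_score"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigurationError(f"truth table missing columns: {sorted(missing)}")
    base = Path(config.image_dir or ".")
    missing_paths = [
        str(base / p) for p in table["image_path"] if not (base / p).exists()
    ]
    if missing_paths:
        raise ConfigurationError(f"missing input images: {missing_paths}")
    images = [read_image(base / p) for p in table["image_path"]]
    scores = table["true_score"].to_numpy(dtype=float)
    if "partition" in table.columns:
        partitions = list(table["partition"])
    else:
        _, realized = phantom.split_sizes(len(images), config.split_fractions)
        rng = np.random.default_rng(config.seed)
        order = rng.permutation(len(images))
        partitions = [""] * len(images)
        start = 0
        for part, count in zip(phantom.PARTITIONS, realized):
            for idx in order[start : start + count]:
                partitions[idx] = part
            start += count
    return images, scores, partitions


def run_pipeline(config: PipelineConfig) -> evaluate.EvaluationReport:
    """Execute all stages and return the test-partition evaluation report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_log: list[dict] = []

    def log_stage(name: str, t0: float, **info) -> None:
        entry = {"stage": name, "seconds": round(time.time() - t0, 3), **info}
        stage_log.append(entry)
        logger.info("stage %s done in %.2fs %s", name, entry["seconds"], info)

    # --- data -----------------------------------------------------------
    t0 = time.time()
    if config.image_dir or config.truth_table:
        if not (config.image_dir and config.truth_table):
            raise ConfigurationError(
                "image_dir and truth_table must be supplied together"
            )
        images, scores, partitions = _load_real_dataset(config)
    elif config.simulate is not None:
        sim = config.simulate
        spec = phantom.SplitSpec(config.split_fractions, sim.n)
        phantoms, partitions = phantom.make_dataset(
            sim.n,
            list(sim.variances),
            spec,
            seed=config.seed,
            size=sim.size,
            n_ellipses=sim.n_ellipses,
            texture_strength=sim.texture_strength,
            noise_model=sim.noise_model,
        )
        images = [p.image for p in phantoms]
        scores = np.array([p.true_score for p in phantoms])
    else:
        raise ConfigurationError("either image inputs or a simulate block is required")
    log_stage("data", t0, n=len(images))

    # --- denoise --------------------------------------------------------
    t0 = time.time()
    bcfg, wcfg = config.denoise.bilateral(), config.denoise.wiener()
    denoised = [denoise.hybrid_denoise(img, bcfg, wcfg) for img in images]
    log_stage("denoise", t0)

    # --- features -------------------------------------------------------
    t0 = time.time()
    tex_rows = [
        texture.texture_feature_vector(
            img, config.texture.n_levels, config.texture.directions
        )
        for img in denoised
    ]
    backend = deepfeat.RandomProjectionConvBackend(
        output_dim=config.deepfeat.output_dim, seed=config.deepfeat.seed
    )
    deep_rows = [deepfeat.extract_deep_features(img, backend) for img in denoised]
    fused = pd.DataFrame(
        [deepfeat.fuse_features(t, d) for t, d in zip(tex_rows, deep_rows)]
    )
    log_stage("features", t0, n_features=fused.shape[1])

    partitions = np.asarray(partitions)
    train_mask = partitions == "train"
    test_mask = partitions == "test"
    val_mask = partitions == "validation"
    normalizer = deepfeat.MinMaxNormalizer().fit(fused[train_mask])
    norm = normalizer.transform(fused)
    norm.to_csv(out / "features.csv", index=False)

    # --- feature selection ---------------------------------------------
    t0 = time.time()
    if config.mrsa.enabled:
        d = norm.shape[1]
        mparams = mrsa.MrsaParams(
            pop_size=config.mrsa.pop_size,
            dim=d,
            lower=np.zeros(d),
            upper=np.ones(d),
            n_max=config.mrsa.n_max,
            alpha=config.mrsa.alpha,
            beta=config.mrsa.beta,
            seed=config.mrsa.seed + config.seed,
        )
        result = mrsa.select_features(
            norm[train_mask].to_numpy(),
            scores[train_mask],
            evaluator=mrsa.make_sdbfn_cv_evaluator(seed=config.seed),
            params=mparams,
            w_err=config.mrsa.w_err,
            w_size=config.mrsa.w_size,
        )
        # the search fitness is a cheap, noisy CV estimate, so the winning
        # mask is selected with an optimistic bias (winner's curse over
        # hundreds of candidates); re-rank the leading distinct masks with
        # a low-variance full-fidelity cross-validation before committing
        mask = result.mask
        if len(result.candidates) > 1:
            hi_fi = mrsa.make_sdbfn_cv_evaluator(
                n_splits=10,
                epochs=config.sdbfn.epochs,
                seed=config.sdbfn.seed + config.seed,
            )
            X_tr, y_tr = norm[train_mask].to_numpy(), scores[train_mask]
            # block-level ablation baselines always compete: texture block,
            # deep block, and the full fused vector
            is_texture = np.array(
                [c in texture.FEATURE_NAMES for c in norm.columns]
            )
            pool = [cand for _, cand in result.candidates[: config.mrsa.n_validate]]
            pool += [is_texture, ~is_texture, np.ones(d, dtype=bool)]
            best_err = np.inf
            for cand in pool:
                if not cand.any():
                    continue
                err = hi_fi(X_tr[:, cand], y_tr)
                if err < best_err:
                    best_err = err
                    mask = cand
    else:
        mask = np.ones(norm.shape[1], dtype=bool)
    selected = norm.loc[:, mask]
    selected.to_csv(out / "selected_features.csv", index=False)
    log_stage("select", t0, n_selected=int(mask.sum()))

    # --- train / predict ------------------------------------------------
    t0 = time.time()
    cfg = config.sdbfn.config()
    if config.sdbfn.tune:
        val_mask = partitions == "validation"
        space = {"kappa1": (0.01, 0.5), "kappa2": (0.01, 0.5)}
        best, _ = mrsa.tune_sdbfn(
            space,
            (selected[train_mask].to_numpy(), scores[train_mask]),
            (selected[val_mask].to_numpy(), scores[val_mask]),
            epochs=max(2, config.sdbfn.epochs // 4),
            seed=config.sdbfn.seed + config.seed,
        )
        cfg = sdbfn.SdbfnConfig(
            hidden_sizes=cfg.hidden_sizes,
            p_norm=cfg.p_norm,
            kappa1=float(np.clip(best["kappa1"], 1e-3, 0.999)),
            kappa2=float(np.clip(best["kappa2"], 1e-3, 0.999)),
            label_threshold=cfg.label_threshold,
        )
    model = sdbfn.train(
        cfg,
        selected[train_mask].to_numpy(),
        scores[train_mask],
        epochs=config.sdbfn.epochs,
        seed=config.sdbfn.seed + config.seed,
    )
    sdbfn.save_model(model, out / "model.json")
    predicted = sdbfn.predict_scores(model, selected[test_mask].to_numpy())
    log_stage("train_predict", t0, n_rules=len(model.rules))

    # --- evaluate -------------------------------------------------------
    report = evaluate.evaluate_model(predicted, scores[test_mask])
    report.to_json(out / "report.json")
    pd.DataFrame(
        {"predicted": predicted, "true_score": scores[test_mask]}
    ).to_csv(out / "predictions.csv", index=False)

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": stage_log,
        "n_features_selected": int(mask.sum()),
        "report": json.loads(report.to_json()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report
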