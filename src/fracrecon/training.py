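"""Experiment orchestration: variants, cross-validation, checkpoints.

Three network variants are compared:

* ``3dreconnet``      — two output classes (background / bone);
* ``3dreconnet-ac``   — three classes, adding the fracture-gap auxiliary
  class to the ground truth;
* ``fracreconnet``    — the three-class network additionally trained on
  fractured samples manufactured from intact bone by the augmentation
  engine.

Sample types are stratified across folds; metrics follow the
aux-merged-into-background convention of :mod:`fracrecon.metrics`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .augmentation import RoughSurfaceParams, augment_sample
from .auxiliary import build_labels, synthesize_auxiliary
from .drr import judet_pair, pair_to_array
from .estimator import FracReconNet
from .metrics import EvalResult, evaluate_cohort, paired_ttest
from .model import target_to_volume, volume_to_target
from .phantoms import PhantomParams, make_cohort, region_map
from .volumes import FragmentSet, IntensityVolume, LabelVolume

VARIANTS = ("3dreconnet", "3dreconnet-ac", "fracreconnet")


@dataclass
class StudySample:
    """One cohort member with everything training and augmentation need."""

    volume: IntensityVolume
    fragments: FragmentSet
    type_tag: str
    params: PhantomParams
    sample_id: str

    def labels(self, with_aux: bool, aux_radius: int = 2) -> LabelVolume:
        aux = None
        if with_aux and self.fragments.n > 1:
            aux = synthesize_auxiliary(self.fragments, aux_radius)
        return build_labels(self.fragments, aux)

    def arrays(
        self, n_classes: int, rotational_error_deg: float = 0.0, aux_radius: int = 2
    ) -> tuple[np.ndarray, np.ndarray]:
        x = pair_to_array(judet_pair(self.volume, rotational_error_deg))
        y = volume_to_target(self.labels(n_classes == 3, aux_radius).data)
        return x, y


def make_study_cohort(
    n_intact: int,
    n_fractured: int,
    grid: int = 32,
    seed: int = 0,
    surface_params: RoughSurfaceParams | None = None,
) -> list[StudySample]:
    """Intact phantoms plus nondisplaced fractured ones made by augmentation."""
    base = PhantomParams.default_for_shape((grid, grid, grid))
    raw = make_cohort(n_intact + n_fractured, seed=seed, base_params=base)
    samples: list[StudySample] = []
    sp = surface_params or RoughSurfaceParams(
        extent=grid, rms=1.0 + grid / 64.0, thickness=2.0
    )
    for i, cs in enumerate(raw):
        if i < n_intact:
            samples.append(
                StudySample(cs.volume, cs.fragments, "intact", cs.params, cs.sample_id)
            )
        else:
            boxes = region_map(cs.params)
            aug = augment_sample(
                cs.volume,
                cs.fragments.fragments[0],
                boxes,
                surface_params=sp,
                seed=cs.params.seed,
            )
            samples.append(
                StudySample(
                    aug.volume, aug.fragments, aug.type_tag, cs.params, cs.sample_id
                )
            )
    return samples


def stratified_kfold(type_tags: list[str], k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold index per sample; each type spread across folds as evenly as possible."""
    tags = np.asarray(type_tags)
    for tag in np.unique(tags):
        if (tags == tag).sum() < k:
            raise ValueError(
                f"sample type {tag!r} has fewer than k={k} samples"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(tags), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(tags)), tags)):
        folds[test_idx] = f
    return folds


@dataclass
class ExperimentConfig:
    """End-to-end study configuration at phantom scale."""

    variants: tuple[str, ...] = VARIANTS
    n_intact: int = 6
    n_fractured: int = 6
    grid: int = 32
    folds: int = 2
    seed: int = 0
    augmentation_ratio: float = 1.0
    rotational_errors: tuple[float, ...] = ()
    aux_radius: int = 2
    estimator_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in self.variants:
            if v not in VARIANTS:
                raise ValueError(f"unknown variant {v!r}; expected one of {VARIANTS}")


def variant_n_classes(variant: str) -> int:
    return 2 if variant == "3dreconnet" else 3


def make_estimator(variant: str, cfg: ExperimentConfig, seed: int) -> FracReconNet:
    params = dict(
        image_size=cfg.grid,
        n_classes=variant_n_classes(variant),
        random_state=seed,
    )
    params.update(cfg.estimator_params)
    params["n_classes"] = variant_n_classes(variant)
    return FracReconNet(**params)


def augmented_training_samples(
    train: list[StudySample], cfg: ExperimentConfig, seed: int
) -> list[StudySample]:
    """Manufacture extra nondisplaced fractures from intact training samples."""
    intact = [s for s in train if s.type_tag == "intact"]
    n_extra = int(round(cfg.augmentation_ratio * len(intact)))
    rng = np.random.default_rng(seed)
    sp = RoughSurfaceParams(
        extent=cfg.grid, rms=1.0 + cfg.grid / 64.0, thickness=2.0
    )
    extra = []
    for j in range(n_extra):
        src = intact[j % len(intact)]
        draw_seed = int(rng.integers(0, 2**31 - 1))
        aug = augment_sample(
            src.volume,
            src.fragments.fragments[0],
            region_map(src.params),
            surface_params=sp,
            seed=draw_seed,
        )
        extra.append(
            StudySample(
                aug.volume,
                aug.fragments,
                aug.type_tag,
                src.params,
                f"{src.sample_id}_aug{j}",
            )
        )
    return extra


@dataclass
class ExperimentResult:
    per_variant: dict[str, EvalResult]
    fold_means: pd.DataFrame      # variant, fold, miou, massd
    ttests: pd.DataFrame | None
    rotational: pd.DataFrame | None


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Cross-validated comparison of the requested variants.

    Per fold and variant: build the training arrays (with augmentation for
    ``fracreconnet``), fit, predict the held-out samples, and score them
    with the aux-merged convention.  Per-fold mean IoU/ASSD feed the paired
    t-tests when at least two folds ran.
    """
    cohort = make_study_cohort(cfg.n_intact, cfg.n_fractured, cfg.grid, cfg.seed)
    tags = [s.type_tag for s in cohort]
    folds = stratified_kfold(tags, cfg.folds, cfg.seed)
    collected: dict[str, dict] = {
        v: {"preds": [], "gts": [], "tags": [], "ids": []} for v in cfg.variants
    }
    fold_rows = []
    rot_rows = []
    for f in range(cfg.folds):
        test = [s for s, ff in zip(cohort, folds) if ff == f]
        train = [s for s, ff in zip(cohort, folds) if ff != f]
        for variant in cfg.variants:
            ncls = variant_n_classes(variant)
            train_samples = list(train)
            if variant == "fracreconnet":
                train_samples += augmented_training_samples(
                    train, cfg, seed=cfg.seed * 1000 + f
                )
            X = np.stack([s.arrays(ncls, aux_radius=cfg.aux_radius)[0] for s in train_samples])
            y = np.stack([s.arrays(ncls, aux_radius=cfg.aux_radius)[1] for s in train_samples])
            est = make_estimator(variant, cfg, seed=cfg.seed + f)
            est.fit(X, y)
            Xt = np.stack([s.arrays(ncls, aux_radius=cfg.aux_radius)[0] for s in test])
            preds = est.predict(Xt)
            spacing = test[0].volume.spacing
            pred_vols = [
                LabelVolume(target_to_volume(p), spacing) for p in preds
            ]
            gt_vols = [s.labels(ncls == 3, cfg.aux_radius) for s in test]
            res = evaluate_cohort(
                pred_vols, gt_vols, [s.type_tag for s in test],
                [s.sample_id for s in test],
            )
            collected[variant]["preds"] += pred_vols
            collected[variant]["gts"] += gt_vols
            collected[variant]["tags"] += [s.type_tag for s in test]
            collected[variant]["ids"] += [s.sample_id for s in test]
            fold_rows.append(
                {
                    "variant": variant,
                    "fold": f,
                    "miou": res.per_sample["iou"].mean(),
                    "massd": res.per_sample["assd"].mean(),
                }
            )
            if cfg.rotational_errors and variant == cfg.variants[-1]:
                for err in cfg.rotational_errors:
                    Xe = np.stack([s.arrays(ncls, err, cfg.aux_radius)[0] for s in test])
                    pe = est.predict(Xe)
                    pe_vols = [LabelVolume(target_to_volume(p), spacing) for p in pe]
                    re = evaluate_cohort(
                        pe_vols, gt_vols, [s.type_tag for s in test],
                        [s.sample_id for s in test],
                    )
                    rot_rows.append(
                        {
                            "variant": variant,
                            "fold": f,
                            "error_deg": err,
                            "miou": re.per_sample["iou"].mean(),
                            "massd": re.per_sample["assd"].mean(),
                        }
                    )
    per_variant = {
        v: evaluate_cohort(d["preds"], d["gts"], d["tags"], d["ids"])
        for v, d in collected.items()
    }
    fold_means = pd.DataFrame(fold_rows)
    ttests = None
    if cfg.folds >= 2 and len(cfg.variants) >= 2:
        rows = []
        for i, va in enumerate(cfg.variants):
            for vb in cfg.variants[i + 1 :]:
                for metric in ("miou", "massd"):
                    a = fold_means.query("variant == @va").sort_values("fold")[metric]
                    b = fold_means.query("variant == @vb").sort_values("fold")[metric]
                    t, p = paired_ttest(a.to_numpy(), b.to_numpy())
                    rows.append(
                        {"a": va, "b": vb, "metric": metric, "t": t, "p": p}
                    )
        ttests = pd.DataFrame(rows)
    rotational = pd.DataFrame(rot_rows) if rot_rows else None
    return ExperimentResult(per_variant, fold_means, ttests, rotational)


# ---------------------------------------------------------------------------
# checkpoints & inference
# ---------------------------------------------------------------------------

def save_checkpoint(est: FracReconNet, path: str | Path) -> None:
    """Persist estimator params and network weights (npz + JSON manifest)."""
    est._check_fitted()
    path = Path(path)
    weights = {f"p{i}": p.data for i, p in enumerate(est.net_.parameters())}
    np.savez(path.with_suffix(".npz"), **weights)
    manifest = {
        "estimator_params": est.get_params(),
        "network_seed": est.network_config_.seed,
        "n_weights": len(weights),
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(path: str | Path) -> FracReconNet:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    est = FracReconNet(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in manifest["estimator_params"].items()
    })
    est.network_config_ = est._network_config(manifest["network_seed"])
    from .model import ReconNet3D

    est.net_ = ReconNet3D(est.network_config_)
    data = np.load(path.with_suffix(".npz"))
    params = est.net_.parameters()
    if len(params) != manifest["n_weights"]:
        raise ValueError("checkpoint does not match the configured network")
    for i, p in enumerate(params):
        p.data = data[f"p{i}"].astype(p.data.dtype)
    est.history_ = []
    est.loss_curve_ = []
    return est


def infer(
    est: FracReconNet, pair_array: np.ndarray, spacing=(1.0, 1.0, 1.0)
) -> tuple[LabelVolume, np.ndarray]:
    """Forward pass on one radiograph pair → (label volume, class probabilities)."""
    probs = est.predict_proba(pair_array[None])[0]
    labels = probs.argmax(axis=0).astype(np.uint8)
    return LabelVolume(target_to_volume(labels), spacing), probs
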