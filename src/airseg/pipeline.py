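"""End-to-end two-stage experiment on synthetic phantoms.

Glues the pieces together in the order the method prescribes: preprocess
(normalize + resample), train the coarse model on soft targets, build
leakage-free coarse hints by k-fold cross-validation, train the fine
patch-based model on hint-augmented inputs, and evaluate the held-out
subjects (airway Dice and morphometry against the configured ground truth).

The defaults are the desk-scale operating point: 12 phantoms at 64^3 / 1 mm,
coarse stage at 2 mm, fine stage at 1 mm, a base-8 depth-3 U-Net and 32^3
patches.  The production-scale settings (1.0 / 0.25 mm, 144^3 patches,
100 / 40 epochs) use the same code path.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from .hints import FoldModel, concat_hint, generate_hints, kfold_split
from .infer import PipelineConfig, predict_volume
from .morphometry import AirwayMetrics, measure_airway
from .net3d import ModelConfig, UNet3D
from .phantom import PhantomConfig, airway_bounds, generate_phantom_dataset
from .targets import make_fine_targets, make_soft_targets
from .train import AugmentConfig, TrainConfig, split_dataset, train_stage
from .volumes import AIRWAY_CLASS, Volume, normalize_intensity, resample


@dataclass
class ExperimentConfig:
    """Scale and schedule of one full training + evaluation run."""

    n_phantoms: int = 12
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    coarse_spacing: float = 2.0
    fine_spacing: float = 1.0
    base_channels: int = 8
    depth: int = 3
    patch_size: int = 32
    overlap: int = 16
    coarse_epochs: int = 15
    fine_epochs: int = 10
    k_folds: int = 3
    seed: int = 0


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap 2|A&B| / (|A| + |B|) between two binary masks."""
    inter = np.count_nonzero(pred & truth)
    total = np.count_nonzero(pred) + np.count_nonzero(truth)
    return 2.0 * inter / total if total else 1.0


def run_experiment(cfg: ExperimentConfig | None = None,
                   progress: bool = False) -> dict:
    """Run the full pipeline at the configured scale; returns a result dict
    with the trained models, per-stage logs and held-out evaluation."""
    cfg = cfg or ExperimentConfig()
    t0 = time.time()
    rng_seed = cfg.seed

    # --- data -------------------------------------------------------------
    cohort = generate_phantom_dataset(cfg.n_phantoms, cfg.phantom, seed=rng_seed)
    subjects = {}
    for sid, vol, lab, pcfg in cohort:
        norm = normalize_intensity(vol)
        subjects[sid] = {
            "coarse_img": resample(norm, cfg.coarse_spacing),
            "soft": make_soft_targets(lab, cfg.coarse_spacing),
            "fine_img": resample(norm, cfg.fine_spacing),
            "fine_lab": make_fine_targets(lab, cfg.fine_spacing),
            "native": vol,
            "labels": lab,
            "phantom_cfg": pcfg,
        }
    ids = [sid for sid, *_ in cohort]
    train_ids, dev_ids, test_ids = split_dataset(ids, seed=rng_seed)
    if progress:
        print(f"split: train={train_ids} dev={dev_ids} test={test_ids}", flush=True)

    def coarse_pairs(sids):
        return [(subjects[s]["coarse_img"].data, subjects[s]["soft"].probs)
                for s in sids]

    coarse_tc = TrainConfig(epochs=cfg.coarse_epochs, seed=rng_seed,
                            patch_size=cfg.patch_size)

    # --- coarse full-data model (used at test time) -------------------------
    coarse_model = UNet3D(ModelConfig("coarse", base_channels=cfg.base_channels,
                                      depth=cfg.depth),
                          rng=np.random.default_rng(rng_seed))
    coarse_log = train_stage(
        {"train": coarse_pairs(train_ids), "dev": coarse_pairs(dev_ids)},
        coarse_tc, "coarse", coarse_model, progress=progress)

    # --- fold models for leakage-free hints ---------------------------------
    assignment = kfold_split(train_ids, cfg.k_folds, seed=rng_seed)
    fold_models = {}
    for f in range(cfg.k_folds):
        fit_ids = assignment.training_ids_for_fold(f)
        model = UNet3D(ModelConfig("coarse", base_channels=cfg.base_channels,
                                   depth=cfg.depth),
                       rng=np.random.default_rng(rng_seed + 1000 + f))
        train_stage({"train": coarse_pairs(fit_ids),
                     "dev": coarse_pairs(dev_ids)},
                    replace(coarse_tc, seed=rng_seed + 1000 + f),
                    "coarse", model, progress=progress)
        fold_models[f] = FoldModel(model, frozenset(fit_ids))

    # --- hints --------------------------------------------------------------
    fine_shapes = {s: subjects[s]["fine_img"].shape for s in ids}
    hints = generate_hints(
        {s: subjects[s]["coarse_img"] for s in train_ids}, assignment,
        fold_models, cfg.fine_spacing,
        output_shapes=fine_shapes)
    # dev/test hints come from the full-data coarse model (never trained on them)
    from .infer import predict_whole_volume
    from .hints import interpolate_hint
    for s in dev_ids + test_ids:
        probs = predict_whole_volume(coarse_model, subjects[s]["coarse_img"].data)
        hints[s] = interpolate_hint(probs, subjects[s]["coarse_img"].spacing,
                                    cfg.fine_spacing, fine_shapes[s])

    def fine_pairs(sids):
        return [(concat_hint(subjects[s]["fine_img"], hints[s]),
                 subjects[s]["fine_lab"].labels) for s in sids]

    # --- fine model ---------------------------------------------------------
    fine_tc = TrainConfig(epochs=cfg.fine_epochs, seed=rng_seed + 1,
                          patch_size=cfg.patch_size)
    fine_model = UNet3D(ModelConfig("fine", base_channels=cfg.base_channels,
                                    depth=cfg.depth),
                        rng=np.random.default_rng(rng_seed + 2))
    fine_log = train_stage(
        {"train": fine_pairs(train_ids), "dev": fine_pairs(dev_ids)},
        fine_tc, "fine", fine_model, progress=progress)

    # --- held-out evaluation ------------------------------------------------
    pipe_cfg = PipelineConfig(coarse_spacing=cfg.coarse_spacing,
                              fine_spacing=cfg.fine_spacing,
                              patch_size=cfg.patch_size, overlap=cfg.overlap)
    evaluations = []
    for s in test_ids:
        pred = predict_volume(subjects[s]["native"], coarse_model, fine_model,
                              pipe_cfg)
        truth = subjects[s]["fine_lab"]
        d = dice(pred.labels == AIRWAY_CLASS, truth.labels == AIRWAY_CLASS)
        pcfg = subjects[s]["phantom_cfg"]
        # measure between axial bounds, as the landmark planes delimit the
        # pharyngeal air column clinically — the tube's open ends are cut off
        bounds = airway_bounds(pcfg)
        truth_metrics = measure_airway(truth, bounds)
        try:
            metrics = measure_airway(pred, bounds)
        except ValueError:  # degenerate prediction: no airway found in bounds
            metrics = AirwayMetrics(0.0, 0.0, 0.0, bounds.inferior_z)
        waist_truth = float(np.pi * pcfg.waist_radius_mm**2)
        evaluations.append({
            "subject": s,
            "airway_dice": d,
            "pred_metrics": metrics,
            "truth_metrics": truth_metrics,
            "configured_waist_csa_mm2": waist_truth,
            "waist_csa_rel_error": abs(metrics.min_csa_mm2 - waist_truth) / waist_truth,
            "prediction": pred,
        })
        if progress:
            print(f"[eval] {s}: dice={d:.3f} "
                  f"minCSA={metrics.min_csa_mm2:.1f} (truth {waist_truth:.1f})",
                  flush=True)

    return {
        "config": cfg,
        "split": (train_ids, dev_ids, test_ids),
        "coarse_model": coarse_model,
        "fine_model": fine_model,
        "fold_models": fold_models,
        "fold_assignment": assignment,
        "coarse_log": coarse_log,
        "fine_log": fine_log,
        "evaluations": evaluations,
        "runtime_s": time.time() - t0,
    }
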