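"""Localizer-phase analysis: the online training pipeline.

Consumes the localizer volumes in acquisition order, exactly as the
real-time system would: optional rigid motion correction to the first
volume, incremental GLM accumulator updates with every image, then — once
the last localizer volume has arrived — t-map computation, voxel selection,
batch detrending/normalization of the selected series, and SVM training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from covisa.classifier import (
    AttnClassifier,
    SvmConfig,
    build_training_set,
    classify,
    train,
)
from covisa.detrend import DetrendConfig, VoxelNormalizer, fit_normalizer
from covisa.features import FeatureMask, select_features
from covisa.glm import GlmState, design_matrix, standard_contrasts
from covisa.motion import RegistrationConfig, RigidTransform, correct_volume
from covisa.simulate import CueSchedule, Hrf, ScanProtocol


@dataclass
class LocalizerResult:
    """Everything the control phase needs, frozen at end of localizer."""

    mask: FeatureMask
    normalizer: VoxelNormalizer
    model: AttnClassifier
    template: np.ndarray
    t_maps: dict[str, np.ndarray]
    glm: GlmState
    transforms: list[RigidTransform]
    training_accuracy: float


def run_localizer(
    volumes,
    schedule: CueSchedule,
    protocol: ScanProtocol,
    hrf: Hrf,
    svm_config: SvmConfig = SvmConfig(),
    detrend_config: DetrendConfig = DetrendConfig(),
    registration_config: RegistrationConfig = RegistrationConfig(),
    top_k_per_map: int = 500,
    min_cluster: int = 5,
    connectivity: int = 6,
    motion_correct: bool = False,
    convolve_regressors: bool = True,
    seed: int = 0,
) -> LocalizerResult:
    """Run the full localizer pipeline on an iterable of 3-D volumes."""
    X = design_matrix(schedule, hrf, protocol.n_localizer, convolve=convolve_regressors)
    glm: GlmState | None = None
    template: np.ndarray | None = None
    corrected: list[np.ndarray] = []
    transforms: list[RigidTransform] = []

    for v, vol in enumerate(volumes):
        if template is None:
            template = np.asarray(vol, dtype=float)
            corrected.append(template)
            transforms.append(RigidTransform.identity())
        elif motion_correct:
            fixed, t = correct_volume(
                vol, template, registration_config, seed=seed + v,
                voxel_mm=protocol.voxel_mm,
            )
            corrected.append(fixed)
            transforms.append(t)
        else:
            corrected.append(np.asarray(vol, dtype=float))
            transforms.append(RigidTransform.identity())
        if glm is None:
            glm = GlmState(corrected[-1].size)
        glm.update(X[v], corrected[-1].ravel())
    if glm is None or glm.n_seen != protocol.n_localizer:
        raise ValueError(
            f"expected {protocol.n_localizer} localizer volumes, "
            f"got {0 if glm is None else glm.n_seen}"
        )

    contrasts = standard_contrasts()
    shape = tuple(protocol.matrix)
    t_maps = {c.name: glm.t_map(c).reshape(shape) for c in contrasts}
    mask = select_features(
        [t_maps[c.name] for c in contrasts],
        k=top_k_per_map,
        min_cluster=min_cluster,
        connectivity=connectivity,
    )

    series = np.stack([mask.extract(vol) for vol in corrected], axis=0)
    # voxels with no temporal variance cannot be z-scored; drop them
    from covisa.detrend import zero_variance_voxels

    bad = zero_variance_voxels(series, detrend_config)
    if bad.size:
        keep = np.setdiff1d(np.arange(mask.size), bad)
        mask = FeatureMask(
            shape=mask.shape,
            voxel_indices=mask.voxel_indices[keep],
            cluster_labels=mask.cluster_labels[keep],
        )
        series = series[:, keep]
    normalizer, train_feats = fit_normalizer(series, detrend_config)

    examples = build_training_set(schedule, train_feats, svm_config)
    model = train(examples, svm_config)
    Xtr, labels = examples
    pred = [classify(model, x) for x in Xtr]
    accuracy = float(np.mean([p == t for p, t in zip(pred, labels)]))

    return LocalizerResult(
        mask=mask,
        normalizer=normalizer,
        model=model,
        template=template,
        t_maps=t_maps,
        glm=glm,
        transforms=transforms,
        training_accuracy=accuracy,
    )


def leave_trial_out_accuracy(
    schedule: CueSchedule,
    train_feats: np.ndarray,
    svm_config: SvmConfig = SvmConfig(),
) -> float:
    """Cross-validated localizer accuracy, leaving out one trial at a time.

    For each trial, the classifier is retrained without that trial's
    (lagged) volumes and evaluated on them; chance level is 25%.
    """
    X, labels = build_training_set(schedule, train_feats, svm_config)
    lag = svm_config.label_lag_volumes
    # map each retained row back to its source trial
    states = schedule.states()
    rows = [v for v in range(len(states)) if v - lag >= 0]
    trial_of_row = np.empty(len(rows), dtype=int)
    for i, v in enumerate(rows):
        for k, t in enumerate(schedule.trials):
            if t.start_volume <= v - lag < t.start_volume + t.length_volumes:
                trial_of_row[i] = k
                break
    hits = 0
    for k in range(len(schedule.trials)):
        test = trial_of_row == k
        if not test.any():
            continue
        keep = ~test
        model = train((X[keep], [l for l, m in zip(labels, keep) if m]), svm_config)
        for x, truth in zip(X[test], [l for l, m in zip(labels, test) if m]):
            hits += int(classify(model, x) == truth)
    return hits / len(labels)
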