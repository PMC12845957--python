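"""End-to-end orchestration: corpus -> windows -> splits -> features -> model -> report.

This is the programmatic face of the tool: the CLI subcommands, the example
scripts and the acceptance checks all call through here.  Stages can also be
run individually via the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import evaluation, features, models, segmentation, synthetic, training
from .augmentation import AugmentConfig, expand_training
from .segmentation import DEFAULT_MAX_SEGMENTS, Segment

LABEL_INDEX = {name: i for i, name in enumerate(evaluation.CLASSES)}


def corpus_to_segments(
    clips, seed: int = 0, max_segments: int | None = DEFAULT_MAX_SEGMENTS
) -> tuple[dict[str, list[Segment]], segmentation.SplitManifest]:
    """Window every source, cap over-long ones, and split by source.

    All sources participate in the split (including those too short to yield
    a window), so split ratios refer to sources as collected.
    """
    per_source: dict[str, list[Segment]] = {}
    for clip in clips:
        per_source[clip.source_id] = segmentation.cap_source(
            segmentation.window_clip(clip), max_segments
        )
    manifest = segmentation.assign_splits(sorted(per_source), seed=seed)
    by_split: dict[str, list[Segment]] = {s: [] for s in segmentation.SPLITS}
    for sid, segs in sorted(per_source.items()):
        by_split[manifest.split_of(sid)].extend(segs)
    rows = [
        {"source_id": s.source_id, "split": split}
        for split, segs in by_split.items()
        for s in segs
    ]
    leaks = segmentation.check_no_leakage(manifest, rows)
    assert not leaks, f"source split produced leakage: {leaks}"
    return by_split, manifest


def featurize_segments(
    segments: list[Segment], kind: str = "mel", params: features.SpectroParams = features.SpectroParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Segments -> (images, integer labels) arrays ready for training."""
    x = np.stack(
        [features.featurize_segment(s, kind=kind, params=params).pixels for s in segments]
    ).astype(np.float32)
    y = np.array([LABEL_INDEX[s.label] for s in segments], dtype=np.int64)
    return x, y


def run_experiment(
    synth_params: synthetic.SynthParams | None = None,
    feature: str = "mel",
    architecture: str = "cnn",
    augment: bool = True,
    train_cfg: training.TrainConfig | None = None,
    seed: int = 0,
    verbose: bool = False,
) -> dict:
    """The full study loop on a synthetic corpus; returns report + artifacts.

    The seed drives corpus generation, the source split, augmentation draws,
    weight initialization and training-time randomness.
    """
    if synth_params is None:
        synth_params = synthetic.SynthParams(seed=seed)
    clips, corpus_manifest = synthetic.synth_corpus(synth_params)
    by_split, split_manifest = corpus_to_segments(clips, seed=seed)
    train_segments = by_split["train"]
    if augment:
        aug_cfg = AugmentConfig(seed=seed)
        split_of = split_manifest.assignment
        train_segments, aug_records = expand_training(train_segments, aug_cfg, split_of=split_of)
    else:
        aug_records = []

    x_train, y_train = featurize_segments(train_segments, kind=feature)
    x_val, y_val = featurize_segments(by_split["val"], kind=feature)
    x_test, y_test = featurize_segments(by_split["test"], kind=feature)

    if architecture == "cnn":
        model = models.build_cnn(seed=seed)
        cfg = train_cfg or training.CNN_TRAIN
    elif architecture == "vit":
        model = models.build_vit(seed=seed)
        cfg = train_cfg or training.VIT_TRAIN
    else:
        raise ValueError(f"unknown architecture {architecture!r}")
    cfg = replace(cfg, seed=seed)
    model, history = training.train(model, (x_train, y_train), (x_val, y_val), cfg, verbose=verbose)

    probs = training.predict(model, x_test)
    true_labels = [evaluation.CLASSES[i] for i in y_test]
    results = evaluation.evaluate_predictions(true_labels, probs)
    return {
        "model": model,
        "history": history,
        "report": results["report"],
        "confusion": results["confusion"],
        "curves": results["curves"],
        "split_manifest": split_manifest,
        "corpus_manifest": corpus_manifest,
        "counts": {
            "train": len(train_segments),
            "val": len(by_split["val"]),
            "test": len(by_split["test"]),
        },
        "augment_records": aug_records,
    }


def sliding_window_predict(model, clip, feature: str = "mel") -> list[dict]:
    """Apply the 6 s / 3 s sliding window to an arbitrary-length clip.

    Returns one record per window with its start time and humpback
    probability - the real-time monitoring pattern (a fresh prediction
    every three seconds).
    """
    segments = segmentation.window_clip(clip)
    out = []
    for seg in segments:
        img = features.featurize_segment(seg, kind=feature)
        p = training.predict(model, img.pixels[None])[0]
        out.append(
            {
                "start_s": seg.start_s,
                "p_humpback": float(p[LABEL_INDEX["humpback"]]),
                "p_no_call": float(p[LABEL_INDEX["no_call"]]),
            }
        )
    return out
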