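"""Augmentation-size experiment driver.

For each repeat the train/test split is re-drawn, the feature scaler and
the per-target conditional WGAN are fitted on the training rows only, each
augmentation size is gated and appended, and each classifier is trained
and scored on the held-out rows.  Test rows are never augmented, never
seen by the GAN and never used to fit the scaler.

Reported cells follow the "real + fake" convention, e.g. ``1152 + 5000``
for the full-geometry training set with 5000 generated rows.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import DNNSpec, SVMSpec, evaluate_accuracy, train_dnn, train_svm
from .features import FeatureScaler
from .gan import CWGANConfig, ConditionalWGAN, augment_trainset
from .io import split_train_test

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "run_experiment",
    "format_report",
]

log = logging.getLogger(__name__)

TARGETS = ("arousal", "valence")


def _subseed(base: int, *keys) -> int:
    """Stable sub-seed below 2**31 derived from a base seed and keys."""
    text = ":".join([str(int(base))] + [str(k) for k in keys])
    return zlib.crc32(text.encode()) % (2**31 - 1)


@dataclass(frozen=True)
class ExperimentConfig:
    """Settings of the repeated augmentation experiment.

    ``sizes`` entries are either integers (number of generated rows) or the
    string ``"1x"`` meaning "as many generated rows as training rows".
    """

    sizes: tuple = (0, "1x", 5000)
    repeats: int = 10
    base_seed: int = 0
    targets: tuple[str, ...] = TARGETS
    classifiers: tuple[str, ...] = ("svm", "dnn")
    test_fraction: float = 0.1
    cwgan: CWGANConfig = field(default_factory=CWGANConfig)
    dnn: DNNSpec = field(default_factory=DNNSpec)
    svm: SVMSpec = field(default_factory=SVMSpec)
    gate: bool = True

    def validate(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        for s in self.sizes:
            if s != "1x" and int(s) < 0:
                raise ValueError(f"augmentation size must be >= 0 or '1x', got {s!r}")
        for t in self.targets:
            if t not in TARGETS:
                raise ValueError(f"unknown target {t!r}")
        for c in self.classifiers:
            if c not in ("svm", "dnn"):
                raise ValueError(f"unknown classifier {c!r}")

    def resolve_size(self, size, n_train: int) -> int:
        return n_train if size == "1x" else int(size)


@dataclass
class ExperimentReport:
    """Per-repeat cell results plus aggregation helpers."""

    cells: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Mean accuracy +/- std (population std, so one repeat gives 0)
        per (classifier, target, augmentation size)."""
        g = self.cells.groupby(
            ["classifier", "target", "n_train", "n_fake"], sort=False
        )["accuracy"]
        out = g.agg(
            mean_accuracy="mean",
            std_accuracy=lambda a: float(np.std(a, ddof=0)),
            repeats="count",
        ).reset_index()
        out["augmented"] = (
            out["n_train"].astype(str) + " + " + out["n_fake"].astype(str)
        )
        return out[
            ["classifier", "target", "augmented", "n_train", "n_fake",
             "mean_accuracy", "std_accuracy", "repeats"]
        ]

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "ExperimentReport":
        return ExperimentReport(pd.read_csv(path))


def _train_one(name: str, X, y, seed: int, cfg: ExperimentConfig):
    if name == "svm":
        spec = SVMSpec(kernel=cfg.svm.kernel, C=cfg.svm.C, seed=seed)
        return train_svm(X, y, spec)
    spec = DNNSpec(
        hidden=cfg.dnn.hidden, dropout=cfg.dnn.dropout, epochs=cfg.dnn.epochs,
        batch_size=cfg.dnn.batch_size, learning_rate=cfg.dnn.learning_rate,
        seed=seed,
    )
    return train_dnn(X, y, spec)


def run_experiment(
    features: pd.DataFrame, labels: pd.DataFrame,
    cfg: ExperimentConfig = ExperimentConfig(),
) -> ExperimentReport:
    """Run the full repeated experiment on a feature matrix and its binary
    label table (columns ``arousal`` and ``valence``).

    Returns an :class:`ExperimentReport`; ``report.summary()`` mirrors the
    mean-accuracy +/- std layout of the augmentation-size tables.
    """
    cfg.validate()
    features = pd.DataFrame(features)
    labels = pd.DataFrame(labels)
    if len(features) != len(labels):
        raise ValueError("feature and label row counts disagree")
    for t in cfg.targets:
        if t not in labels.columns:
            raise ValueError(f"labels are missing the {t!r} column")
        if labels[t].nunique() < 2:
            raise ValueError(f"target {t!r} has a single class in the dataset")
    n = len(features)
    rows = []
    for r in range(cfg.repeats):
        split_seed = _subseed(cfg.base_seed, "split", r)
        split = split_train_test(n, cfg.test_fraction, seed=split_seed)
        tr, te = split.train_ids, split.test_ids
        scaler = FeatureScaler().fit(features.iloc[tr])
        Xn_te = scaler.transform(features.iloc[te])
        n_train = tr.size
        resolved = [cfg.resolve_size(s, n_train) for s in cfg.sizes]
        log.info("repeat %d/%d: split seed %d, train %d / test %d",
                 r + 1, cfg.repeats, split_seed, n_train, te.size)
        for target in cfg.targets:
            y_tr = labels[target].to_numpy()[tr]
            y_te = labels[target].to_numpy()[te]
            model = None
            if any(nf > 0 for nf in resolved):
                gan_cfg = dataclasses.replace(
                    cfg.cwgan, seed=_subseed(cfg.base_seed, "gan", r, target)
                )
                model = ConditionalWGAN(gan_cfg).fit(
                    scaler.transform(features.iloc[tr]), y_tr,
                    scaler=scaler, condition_name=target,
                )
            for size, n_fake in zip(cfg.sizes, resolved):
                try:
                    if n_fake > 0:
                        aug_feats, aug_y, report = augment_trainset(
                            features.iloc[tr], y_tr, model, n_fake,
                            gate=cfg.gate,
                            seed=_subseed(cfg.base_seed, "sample", r, target, n_fake),
                        )
                    else:
                        aug_feats, aug_y, report = features.iloc[tr], y_tr, None
                    Xn_aug = scaler.transform(aug_feats)
                    for clf_name in cfg.classifiers:
                        clf_seed = _subseed(
                            cfg.base_seed, "clf", clf_name, r, target, n_fake
                        )
                        clf = _train_one(clf_name, Xn_aug, aug_y, clf_seed, cfg)
                        acc = evaluate_accuracy(clf, Xn_te, y_te)
                        rows.append({
                            "classifier": clf_name,
                            "target": target,
                            "n_train": int(n_train),
                            "n_fake": int(n_fake),
                            "repeat": r,
                            "seed": clf_seed,
                            "accuracy": acc,
                            "gate_passed": (
                                bool(report.passed) if report is not None else True
                            ),
                            "gate_distance": (
                                float(report.distance) if report is not None else 0.0
                            ),
                            "gate_threshold": (
                                float(report.threshold) if report is not None else 0.0
                            ),
                            "n_rows_used": int(len(aug_feats)),
                        })
                except Exception as exc:
                    raise RuntimeError(
                        f"experiment cell failed (repeat={r}, target={target}, "
                        f"n_fake={n_fake}): {exc}"
                    ) from exc
    return ExperimentReport(pd.DataFrame(rows))


def format_report(report: ExperimentReport) -> str:
    """Plain-text table of the aggregated report, one row per cell, with
    accuracies rendered to one decimal ("71.9 % ± 4.8")."""
    summary = report.summary()
    if summary.empty:
        raise ValueError("report is empty")
    lines = [
        f"{'classifier':<10} {'target':<8} {'augmented':<16} "
        f"{'mean accuracy':<18} repeats"
    ]
    for _, row in summary.iterrows():
        acc = f"{row.mean_accuracy:.1f} % ± {row.std_accuracy:.1f}"
        lines.append(
            f"{row.classifier:<10} {row.target:<8} {row.augmented:<16} "
            f"{acc:<18} {int(row.repeats)}"
        )
    return "\n".join(lines)
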