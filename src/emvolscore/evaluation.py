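"""Fit evaluation: ALCPS pose deviation and ROC/AUC/precision harness.

A candidate rigid fit is compared against a reference pose through the
arc length of the component placement score,

    ALCPS = 2π · r · θ / 360,

where ``r`` (Å) is the translation magnitude and ``θ`` (degrees) the
rotation angle of the relative transform ``reference⁻¹ ∘ fit``.  For maps
with point-group symmetry the minimum over all symmetry-equivalent
references is taken.  Fits with ALCPS below a (log10) threshold count as
correct; any score can then be assessed by how well it separates correct
from incorrect fits — ROC curve, AUC, and accuracy/precision at the
best-accuracy score threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .volume_io import RigidTransform

__all__ = [
    "FitEnsemble",
    "RocResult",
    "relative_pose",
    "alcps",
    "log_alcps",
    "symmetry_operators",
    "label_fits",
    "roc",
]


def relative_pose(
    fit: RigidTransform, reference: RigidTransform
) -> tuple[float, float]:
    """Translation magnitude (Å) and rotation angle (degrees) of ref⁻¹∘fit."""
    delta = reference.inverse().compose(fit)
    r = float(np.linalg.norm(delta.translation))
    cos_theta = (np.trace(delta.rotation) - 1.0) / 2.0
    theta = math.degrees(math.acos(min(1.0, max(-1.0, cos_theta))))
    return r, theta


def symmetry_operators(group: str) -> list[np.ndarray]:
    """Rotation matrices of a point group named Cn, Dn, T, O or I.

    Cn/Dn use the z axis as the principal axis (scipy's convention).
    """
    rots = Rotation.create_group(group.upper())
    mats = rots.as_matrix()
    if mats.ndim == 2:
        mats = mats[None]
    return list(mats)


def alcps(
    fit: RigidTransform,
    reference: RigidTransform,
    symmetry_ops: list[np.ndarray] | None = None,
) -> float:
    """Arc-length component placement score, minimized over symmetry.

    ``2π r θ / 360`` evaluated for the pose relative to every
    symmetry-equivalent reference ``s ∘ reference``; the smallest value is
    returned.  0 means the fit reproduces the reference (possibly up to a
    symmetry operation).
    """
    ops = symmetry_ops if symmetry_ops is not None else [np.eye(3)]
    best = math.inf
    for s in ops:
        s = np.asarray(s, dtype=float)
        ref_s = RigidTransform(s @ reference.rotation, s @ reference.translation)
        r, theta = relative_pose(fit, ref_s)
        best = min(best, 2.0 * math.pi * r * theta / 360.0)
    return best


def log_alcps(value: float, floor: float = -2.0) -> float:
    """log10 of an ALCPS value, floored (an exact 0 maps to the floor)."""
    if value < 0:
        raise ValueError("ALCPS cannot be negative")
    if value == 0.0:
        return floor
    return max(math.log10(value), floor)


@dataclass
class FitEnsemble:
    """A reference pose with candidate fits and their ALCPS deviations."""

    reference: RigidTransform
    fits: list[RigidTransform]
    symmetry_ops: list[np.ndarray] = field(default_factory=lambda: [np.eye(3)])
    alcps_values: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not any(np.allclose(op, np.eye(3)) for op in self.symmetry_ops):
            raise ValueError("symmetry operators must include the identity")

    def compute_alcps(self) -> np.ndarray:
        self.alcps_values = np.array(
            [alcps(f, self.reference, self.symmetry_ops) for f in self.fits]
        )
        return self.alcps_values

    def log_alcps(self, floor: float = -2.0) -> np.ndarray:
        if self.alcps_values is None:
            self.compute_alcps()
        return np.array([log_alcps(v, floor) for v in self.alcps_values])

    # -- JSON round trip --------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "reference": self.reference.to_dict(),
            "fits": [f.to_dict() for f in self.fits],
            "symmetry_ops": [op.tolist() for op in self.symmetry_ops],
        }
        if self.alcps_values is not None:
            d["alcps"] = [float(v) for v in self.alcps_values]
        if self.labels is not None:
            d["labels"] = [bool(v) for v in self.labels]
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "FitEnsemble":
        ops = [np.asarray(op, dtype=float) for op in d.get("symmetry_ops", [np.eye(3)])]
        ens = cls(
            reference=RigidTransform.from_dict(d["reference"]),
            fits=[RigidTransform.from_dict(f) for f in d["fits"]],
            symmetry_ops=ops,
        )
        if "alcps" in d:
            ens.alcps_values = np.asarray(d["alcps"], dtype=float)
        if "labels" in d:
            ens.labels = np.asarray(d["labels"], dtype=bool)
        return ens

    @classmethod
    def from_json(cls, path: str | Path) -> "FitEnsemble":
        return cls.from_dict(json.loads(Path(path).read_text()))


def label_fits(ensemble: FitEnsemble, log_alcps_threshold: float) -> FitEnsemble:
    """Mark fits correct when their log10(ALCPS) is at or below threshold."""
    ensemble.labels = ensemble.log_alcps() <= log_alcps_threshold
    return ensemble


@dataclass
class RocResult:
    """ROC sweep of one score against correct/incorrect labels."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    best_accuracy_threshold: float
    accuracy_at_best: float
    precision_at_best: float

    def to_dict(self) -> dict:
        return {
            "auc": float(self.auc),
            "best_accuracy_threshold": float(self.best_accuracy_threshold),
            "accuracy_at_best": float(self.accuracy_at_best),
            "precision_at_best": float(self.precision_at_best),
        }

    def curve_csv(self, path: str | Path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.thresholds, self.fpr, self.tpr]),
            delimiter=",",
            header="threshold,fpr,tpr",
            comments="",
        )


def roc(scores, labels) -> RocResult:
    """ROC curve, AUC and best-accuracy operating point for a score.

    Fits with score strictly greater than a threshold are called positive;
    the threshold sweeps over all observed score values plus ±inf so the
    curve spans (0,0) to (1,1).  AUC is the trapezoidal integral of TPR
    over FPR, which with this sweep equals the Mann–Whitney U statistic
    normalized by n₊·n₋ (ties get half credit).  Precision is reported at
    the threshold with maximal accuracy, ties broken toward higher
    precision.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1D vectors of equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative label")
    thr = np.concatenate([[np.inf], np.sort(np.unique(s))[::-1], [-np.inf]])
    pos = s[None, :] > thr[:, None]
    tp = (pos & y[None, :]).sum(axis=1).astype(float)
    fp = (pos & ~y[None, :]).sum(axis=1).astype(float)
    tpr = tp / n_pos
    fpr = fp / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    tn = n_neg - fp
    fn = n_pos - tp
    accuracy = (tp + tn) / (n_pos + n_neg)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
    best_acc = accuracy.max()
    candidates = np.flatnonzero(accuracy >= best_acc - 1e-12)
    best = candidates[np.argmax(precision[candidates])]
    return RocResult(
        thresholds=thr,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        best_accuracy_threshold=float(thr[best]),
        accuracy_at_best=float(accuracy[best]),
        precision_at_best=float(precision[best]),
    )
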