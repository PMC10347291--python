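"""Accuracy assessment: stratified validation points and the confusion matrix.

Validation points are drawn by stratified random sampling on the *predicted*
layers (the rice mask and its complement), truth labels attached from a
reference source, and agreement summarised as a 2x2 confusion matrix with
user/producer accuracy, overall accuracy and Cohen's kappa.

Internally counts are stored rows = truth x columns = predicted with class
order (other, rice); ``to_table()`` emits the conventional remote-sensing
report layout (rows = classification result, columns = reference).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .extraction import RiceMask
from .raster import Grid, require_aligned

CLASSES = ("other", "rice")


@dataclass
class ValidationPoint:
    x: float
    y: float
    predicted: str
    truth: str | None = None


def stratified_sample(rice: RiceMask, n_rice: int, n_other: int, seed: int,
                      valid: Grid | None = None) -> list[ValidationPoint]:
    """Sample pixel-center points: ``n_rice`` from the mask, ``n_other`` off it.

    Uniform without replacement within each stratum; deterministic per seed.
    ``valid`` optionally restricts the non-rice stratum to pixels that carry
    data (e.g. the valid footprint of the DiffNDVI grid).
    """
    mask = rice.mask.values == 1
    other = ~mask
    if valid is not None:
        require_aligned(rice.mask, valid)
        other &= valid.valid_mask()
    rng = np.random.default_rng(seed)
    points: list[ValidationPoint] = []
    for label, stratum, n in (("rice", mask, n_rice), ("other", other, n_other)):
        rows, cols = np.nonzero(stratum)
        if rows.size < n:
            raise ValueError(
                f"stratum '{label}' has only {rows.size} pixels, {n} requested"
            )
        pick = rng.choice(rows.size, size=n, replace=False)
        xs, ys = rice.mask.transform.xy(rows[pick], cols[pick])
        points.extend(
            ValidationPoint(x=float(px), y=float(py), predicted=label)
            for px, py in zip(xs, ys)
        )
    return points


def assign_truth(points: Iterable[ValidationPoint], truth_rice: Grid) -> list[ValidationPoint]:
    """Label points from a binary truth raster (1 = rice)."""
    out = []
    for p in points:
        row, col = truth_rice.transform.rowcol(p.x, p.y)
        r, c = int(row), int(col)
        if not (0 <= r < truth_rice.shape[0] and 0 <= c < truth_rice.shape[1]):
            raise ValueError(f"point ({p.x}, {p.y}) falls outside the truth raster")
        p.truth = "rice" if truth_rice.values[r, c] == 1 else "other"
        out.append(p)
    return out


class ConfusionMatrix:
    """2x2 confusion matrix over classes (other, rice) with derived metrics."""

    def __init__(self, counts):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (2, 2) or (counts < 0).any():
            raise ValueError("counts must be a non-negative 2x2 array")
        if counts.sum() == 0:
            raise ValueError("confusion matrix is empty")
        self.counts = counts  # rows = truth, cols = predicted

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_points(cls, points: Sequence[ValidationPoint]) -> "ConfusionMatrix":
        points = list(points)
        if not points:
            raise ValueError("no validation points")
        counts = np.zeros((2, 2), dtype=np.int64)
        for p in points:
            if p.truth is None:
                raise ValueError("every validation point needs a truth label")
            counts[CLASSES.index(p.truth), CLASSES.index(p.predicted)] += 1
        return cls(counts)

    @classmethod
    def from_labels(cls, truth, predicted) -> "ConfusionMatrix":
        truth = np.asarray(truth).astype(bool).ravel()
        predicted = np.asarray(predicted).astype(bool).ravel()
        counts = np.zeros((2, 2), dtype=np.int64)
        for t in (0, 1):
            for p in (0, 1):
                counts[t, p] = np.count_nonzero((truth == t) & (predicted == p))
        return cls(counts)

    @classmethod
    def from_prediction_table(cls, table) -> "ConfusionMatrix":
        """Build from the report layout: rows = predicted, columns = truth."""
        return cls(np.asarray(table, dtype=np.int64).T)

    # -- derived metrics -------------------------------------------------------
    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def truth_totals(self) -> dict[str, int]:
        return dict(zip(CLASSES, (int(v) for v in self.counts.sum(axis=1))))

    @property
    def predicted_totals(self) -> dict[str, int]:
        return dict(zip(CLASSES, (int(v) for v in self.counts.sum(axis=0))))

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    @property
    def user_accuracy(self) -> dict[str, float]:
        """Per predicted class: fraction of predictions that are correct."""
        col = self.counts.sum(axis=0)
        return {
            c: float(self.counts[i, i] / col[i]) if col[i] else float("nan")
            for i, c in enumerate(CLASSES)
        }

    @property
    def producer_accuracy(self) -> dict[str, float]:
        """Per truth class: fraction of reference points found."""
        row = self.counts.sum(axis=1)
        return {
            c: float(self.counts[i, i] / row[i]) if row[i] else float("nan")
            for i, c in enumerate(CLASSES)
        }

    @property
    def expected_agreement(self) -> float:
        row = self.counts.sum(axis=1)
        col = self.counts.sum(axis=0)
        return float((row * col).sum() / self.total**2)

    @property
    def kappa(self) -> float:
        """Cohen's kappa; NaN when chance agreement is 1 (single-cell matrix)."""
        pe = self.expected_agreement
        if pe >= 1.0 - 1e-15:
            return float("nan")
        return (self.overall_accuracy - pe) / (1.0 - pe)

    # -- reporting -------------------------------------------------------------
    def to_table(self) -> pd.DataFrame:
        """Report layout: rows = classification result, columns = reference."""
        t = self.counts.T  # rows predicted, cols truth
        df = pd.DataFrame(t, index=["C_others", "C_rice"], columns=["C_others", "C_rice"])
        df["Total"] = df.sum(axis=1)
        ua = self.user_accuracy
        df["U_Accuracy"] = [ua["other"], ua["rice"]]
        totals = [self.truth_totals["other"], self.truth_totals["rice"], self.total, np.nan]
        pa = self.producer_accuracy
        df.loc["Total"] = totals
        df.loc["P_Accuracy"] = [pa["other"], pa["rice"], np.nan, self.overall_accuracy]
        return df

    def summary(self) -> str:
        return (
            f"overall accuracy {100 * self.overall_accuracy:.2f}%  "
            f"kappa {self.kappa:.2f}\n"
            f"producer accuracy: rice {100 * self.producer_accuracy['rice']:.2f}%, "
            f"other {100 * self.producer_accuracy['other']:.2f}%\n"
            f"user accuracy: rice {self.user_accuracy['rice']:.2f}, "
            f"other {self.user_accuracy['other']:.2f}"
        )


def confusion_matrix(points: Sequence[ValidationPoint]) -> ConfusionMatrix:
    """Tabulate labelled validation points into a 2x2 confusion matrix."""
    return ConfusionMatrix.from_points(points)


def accuracy_metrics(cm: ConfusionMatrix) -> dict:
    """Full-precision metric dictionary for machine-readable reports."""
    return {
        "overall_accuracy": cm.overall_accuracy,
        "kappa": cm.kappa,
        "user_accuracy": cm.user_accuracy,
        "producer_accuracy": cm.producer_accuracy,
        "truth_totals": cm.truth_totals,
        "predicted_totals": cm.predicted_totals,
        "total": cm.total,
        "counts_truth_by_predicted": cm.counts.tolist(),
    }
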