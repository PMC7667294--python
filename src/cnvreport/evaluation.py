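"""Performance statistics for variant and corpus classification.

Binary metrics treat pathogenic/likely-pathogenic (pCNV) as the positive
class and are computed directly from confusion counts, including Cohen's
kappa from the marginals.  Display rounding is half-up to one decimal
percent; raw values are retained.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("all-zero confusion counts")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class BinaryMetrics:
    """All values are raw percentages; None marks an undefined ratio."""

    accuracy: float
    PPV: float | None
    NPV: float | None
    sensitivity: float | None
    specificity: float | None
    FPR: float | None
    FNR: float | None
    kappa: float | None

    def rounded(self, ndigits: int = 1) -> dict[str, float | None]:
        """Half-up display rounding, the convention of printed report tables."""
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                out[f.name] = None
            else:
                q = decimal.Decimal(10) ** -ndigits
                out[f.name] = float(
                    decimal.Decimal(repr(v)).quantize(q, rounding=decimal.ROUND_HALF_UP)
                )
        return out

    def to_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def cohens_kappa(counts: ConfusionCounts) -> float | None:
    """Chance-corrected agreement from the confusion marginals."""
    n = counts.total
    po = (counts.TP + counts.TN) / n
    pe = (
        (counts.TP + counts.FP) * (counts.TP + counts.FN)
        + (counts.TN + counts.FN) * (counts.TN + counts.FP)
    ) / (n * n)
    if pe == 1.0:
        return None  # only one class present on both margins
    return 100.0 * (po - pe) / (1.0 - pe)


def confusion_metrics(counts: ConfusionCounts) -> BinaryMetrics:
    return BinaryMetrics(
        accuracy=100.0 * (counts.TP + counts.TN) / counts.total,
        PPV=_ratio(counts.TP, counts.TP + counts.FP),
        NPV=_ratio(counts.TN, counts.TN + counts.FN),
        sensitivity=_ratio(counts.TP, counts.TP + counts.FN),
        specificity=_ratio(counts.TN, counts.TN + counts.FP),
        FPR=_ratio(counts.FP, counts.FP + counts.TN),
        FNR=_ratio(counts.FN, counts.FN + counts.TP),
        kappa=cohens_kappa(counts),
    )


def per_class_prf(
    pred_labels: list, gold_labels: list, classes: list | None = None
) -> pd.DataFrame:
    """One-vs-rest precision/recall/F1 per class plus an unweighted macro row.

    Classes absent from both predictions and gold are excluded from the
    macro average, with a warning.
    """
    pred = [str(x) for x in pred_labels]
    gold = [str(x) for x in gold_labels]
    if len(pred) != len(gold):
        raise ValueError("prediction/gold length mismatch")
    if classes is None:
        classes = sorted(set(gold) | set(pred))
    classes = [str(c) for c in classes]
    present = [c for c in classes if c in set(gold) | set(pred)]
    missing = [c for c in classes if c not in present]
    if missing:
        warnings.warn(
            f"classes absent from predictions and gold excluded from macro: {missing}"
        )
    p, r, f1, support = precision_recall_fscore_support(
        gold, pred, labels=present, zero_division=0
    )
    rows = {
        c: {"precision": p[i], "recall": r[i], "f1": f1[i], "support": int(support[i])}
        for i, c in enumerate(present)
    }
    rows["macro"] = {
        "precision": float(np.mean(p)),
        "recall": float(np.mean(r)),
        "f1": float(np.mean(f1)),
        "support": int(support.sum()),
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def macro_f1(pred_labels: list, gold_labels: list, classes: list | None = None) -> float:
    return float(per_class_prf(pred_labels, gold_labels, classes).loc["macro", "f1"])
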