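"""Validation arithmetic: confusion matrix, per-class and weighted metrics,
hold-out probability summaries, per-variable class contrasts.

Orientation convention: the invasive target species is the positive class.
The dual orientation (native = positive) is the same matrix with TP<->TN
and FP<->FN swapped.

Per-class metrics::

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    f1        = 2 * precision * recall / (precision + recall)

and the observation-weighted totals combine the two orientations with the
observed class sizes as weights:

    x_bar = (x_inv * n_inv + x_nat * n_nat) / (n_inv + n_nat)

Zero denominators yield *undefined* (NaN with a flag), never zero and never
an exception — silent zeros would corrupt the weighted means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats

from .geodata_io import INVASIVE, NATIVE, FeatureTable

_LABELS = (INVASIVE, NATIVE)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, as used in the report tables."""
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts, invasive = positive orientation."""

    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FN", "FP", "TN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN

    def swapped(self) -> "ConfusionMatrix":
        """The dual orientation with native as the positive class."""
        return ConfusionMatrix(TP=self.TN, FN=self.FP, FP=self.FN, TN=self.TP)


@dataclass(frozen=True)
class ClassMetrics:
    precision: float  # NaN when undefined
    recall: float
    f1: float
    n: int  # observed class size, TP + FN

    @property
    def defined(self) -> bool:
        return not (math.isnan(self.precision) or math.isnan(self.recall)
                    or math.isnan(self.f1))


@dataclass(frozen=True)
class WeightedMetrics:
    precision: float
    recall: float
    f1: float
    n_invasive: int
    n_native: int


@dataclass(frozen=True)
class ProbabilitySummary:
    n: int
    median: float
    q1: float
    q3: float
    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]


def confusion(observed: Sequence[str], predicted: Sequence[str]
              ) -> ConfusionMatrix:
    """Exact confusion counts from invasive/native label sequences."""
    observed = list(observed)
    predicted = list(predicted)
    if len(observed) != len(predicted):
        raise ValueError(f"label sequences differ in length: "
                         f"{len(observed)} vs {len(predicted)}")
    foreign = {l for l in (*observed, *predicted) if l not in _LABELS}
    if foreign:
        raise ValueError(f"foreign labels {sorted(foreign)}; "
                         f"expected {_LABELS}")
    obs = np.asarray(observed)
    pred = np.asarray(predicted)
    return ConfusionMatrix(
        TP=int(((obs == INVASIVE) & (pred == INVASIVE)).sum()),
        FN=int(((obs == INVASIVE) & (pred == NATIVE)).sum()),
        FP=int(((obs == NATIVE) & (pred == INVASIVE)).sum()),
        TN=int(((obs == NATIVE) & (pred == NATIVE)).sum()),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Precision, recall, f1 for the positive class of the given orientation."""
    precision = _ratio(cm.TP, cm.TP + cm.FP)
    recall = _ratio(cm.TP, cm.TP + cm.FN)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = math.nan  # zero denominator -> undefined, never silently 0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ClassMetrics(precision=precision, recall=recall, f1=f1,
                        n=cm.TP + cm.FN)


def weighted_metrics(m_invasive: ClassMetrics, m_native: ClassMetrics
                     ) -> WeightedMetrics:
    """Observation-weighted mean of the two class orientations."""
    n_inv, n_nat = m_invasive.n, m_native.n
    if n_inv + n_nat == 0:
        raise ValueError("zero total observations")

    def w(a: float, b: float) -> float:
        return (a * n_inv + b * n_nat) / (n_inv + n_nat)

    return WeightedMetrics(
        precision=w(m_invasive.precision, m_native.precision),
        recall=w(m_invasive.recall, m_native.recall),
        f1=w(m_invasive.f1, m_native.f1),
        n_invasive=n_inv, n_native=n_nat,
    )


def evaluate_labels(observed: Sequence[str], predicted: Sequence[str]
                    ) -> dict:
    """Confusion matrix (both orientations) + per-class + weighted metrics."""
    cm = confusion(observed, predicted)
    m_inv = class_metrics(cm)
    m_nat = class_metrics(cm.swapped())
    return {"confusion": cm, "invasive": m_inv, "native": m_nat,
            "weighted": weighted_metrics(m_inv, m_nat)}


def weighted_f1(observed: Sequence[str], predicted: Sequence[str]) -> float:
    """Observation-weighted f1 as a *score* (degenerate class f1 counts 0).

    Report tables keep the undefined (NaN) convention of
    :func:`class_metrics`; this helper exists for contexts needing a total
    order over classifiers (selection fitness, Monte-Carlo summaries),
    where a class the model never predicts contributes 0, the standard
    scoring convention.
    """
    cm = confusion(observed, predicted)
    parts = []
    weights = []
    for oriented in (cm, cm.swapped()):
        m = class_metrics(oriented)
        parts.append(0.0 if math.isnan(m.f1) else m.f1)
        weights.append(m.n)
    if sum(weights) == 0:
        raise ValueError("zero total observations")
    return (parts[0] * weights[0] + parts[1] * weights[1]) / sum(weights)


# ---------------------------------------------------------------------------
# Hold-out probability summary


def summarize_probabilities(probs: Sequence[float], bins: int = 10
                            ) -> ProbabilitySummary:
    p = np.asarray(list(probs), dtype=float)
    if p.size == 0:
        raise ValueError("no probabilities to summarize")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    q1, med, q3 = np.percentile(p, [25, 50, 75])  # linear interpolation
    counts, edges = np.histogram(p, bins=bins, range=(0.0, 1.0))
    return ProbabilitySummary(n=int(p.size), median=float(med),
                              q1=float(q1), q3=float(q3),
                              bin_edges=tuple(edges.tolist()),
                              counts=tuple(int(c) for c in counts))


def probability_summary(model, table: FeatureTable, bins: int = 10
                        ) -> ProbabilitySummary:
    """Median/IQR/histogram of predicted probabilities at hold-out presences."""
    if len(table) == 0:
        raise ValueError("empty hold-out table")
    probs = model.predict_probability(table)
    return summarize_probabilities(probs, bins=bins)


# ---------------------------------------------------------------------------
# Per-variable class contrast


def class_contrast(table: FeatureTable, variable: str) -> dict:
    """Unpaired two-sided Wilcoxon-Mann-Whitney test between the classes.

    Exact null distribution when both groups have n <= 20 (and no ties
    force the approximation); otherwise the tie-corrected normal
    approximation.  Returns the U statistic, the two-sided p-value and
    per-class sample summaries.
    """
    if variable not in table.variables:
        raise ValueError(f"variable {variable!r} not in table "
                         f"{table.variables}")
    inv = table.data.loc[table.data["label"] == INVASIVE, variable].to_numpy()
    nat = table.data.loc[table.data["label"] == NATIVE, variable].to_numpy()
    if inv.size == 0 or nat.size == 0:
        raise ValueError(f"variable {variable!r}: a class has zero values")
    method = "exact" if (inv.size <= 20 and nat.size <= 20) else "asymptotic"
    res = stats.mannwhitneyu(inv, nat, alternative="two-sided", method=method)
    summary = {
        cls: {"n": int(v.size), "median": float(np.median(v)),
              "mean": float(v.mean())}
        for cls, v in ((INVASIVE, inv), (NATIVE, nat))
    }
    return {"variable": variable, "U": float(res.statistic),
            "p_value": float(min(res.pvalue, 1.0)), "method": method,
            "classes": summary}


def contrast_table(table: FeatureTable) -> list[dict]:
    """Class contrast for every variable in the table."""
    return [class_contrast(table, v) for v in table.variables]
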