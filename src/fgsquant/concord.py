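"""Agreement between NIRF signal and histology.

Spatial agreement is the Dice coefficient between the fluorescent area and
the histologically confirmed tumor area. Categorical agreement treats
histology as the gold standard per section (neoplastic / non-neoplastic)
against the NIRF call (positive / negative), yielding a contingency table
and sensitivity / specificity / accuracy with exact Clopper-Pearson CIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import scipy.stats
from skimage import morphology
from statsmodels.stats.proportion import proportion_confint

from fgsquant.exceptions import UndefinedStatisticError
from fgsquant.roiquant import MFIStats


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 at 1 dp rounds to 0.1, not 0.0)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """Per-section counts of NIRF call vs histologic truth."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("contingency counts must be >= 0")
        if self.total < 1:
            raise ValueError("contingency table must contain at least one section")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class AccuracySummary:
    """Diagnostic accuracy estimates as percentages rounded half-up to 1 dp.

    ``ci`` maps estimate name to (low, high) percent bounds; ``raw`` keeps the
    unrounded fractions for downstream computation.
    """

    sensitivity: float
    specificity: float
    accuracy: float
    tp_share: float
    tn_share: float
    fp_rate: float
    ci: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)
    ci_method: str = "clopper-pearson"


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) between two boolean rasters."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise UndefinedStatisticError("Dice undefined: both masks are empty")
    return 2.0 * int(np.logical_and(a, b).sum()) / (na + nb)


def nirf_positive_mask(intensity: np.ndarray, background: MFIStats, k: float = 3.0,
                       min_area: int = 25) -> np.ndarray:
    """Pixels fluorescing above background mean + k·SD, de-speckled.

    This operationalizes the visual positive/negative reading of an IR image:
    a pixel is positive when it clearly exceeds the background distribution,
    and isolated specks below ``min_area`` pixels are discarded.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    if not np.isfinite(background.sd):
        raise ValueError("background SD must be finite")
    thresh = background.mean + k * background.sd
    mask = np.asarray(intensity, dtype=float) > thresh
    if min_area > 1:
        # keep objects of at least min_area pixels
        mask = morphology.remove_small_objects(mask, max_size=min_area - 1)
    return mask


def classify_section(nirf_call: str, histology_label: str) -> str:
    """TP/TN/FP/FN for one section from the NIRF call and the histologic label."""
    if nirf_call not in ("positive", "negative"):
        raise ValueError(f"unknown NIRF call {nirf_call!r}")
    if histology_label not in ("neoplastic", "non-neoplastic"):
        raise ValueError(f"unknown histology label {histology_label!r}")
    positive = nirf_call == "positive"
    neoplastic = histology_label == "neoplastic"
    if positive and neoplastic:
        return "TP"
    if positive:
        return "FP"
    if neoplastic:
        return "FN"
    return "TN"


def tabulate_sections(calls_and_labels) -> ContingencyTable:
    """Fold an iterable of (nirf_call, histology_label) pairs into counts."""
    counts = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
    for call, label in calls_and_labels:
        counts[classify_section(call, label)] += 1
    return ContingencyTable(tp=counts["TP"], tn=counts["TN"],
                            fp=counts["FP"], fn=counts["FN"])


def _exact_ci_pct(count: int, nobs: int, ci_level: float) -> tuple[float, float]:
    lo, hi = proportion_confint(count, nobs, alpha=1 - ci_level, method="beta")
    return round_half_up(100 * float(lo)), round_half_up(100 * float(hi))


def accuracy_summary(table: ContingencyTable, ci_level: float = 0.95) -> AccuracySummary:
    """Sensitivity, specificity, accuracy and call shares with exact CIs.

    sensitivity = tp/(tp+fn); specificity = tn/(tn+fp);
    accuracy = (tp+tn)/total; tp_share and tn_share are shares of the correct
    calls; fp_rate = fp/total. Estimates are percentages rounded half-up to
    1 decimal; exact Clopper-Pearson CIs; unrounded fractions kept in ``raw``.
    """
    if table.tp + table.fn < 1:
        raise UndefinedStatisticError("sensitivity undefined: no neoplastic sections")
    if table.tn + table.fp < 1:
        raise UndefinedStatisticError("specificity undefined: no non-neoplastic sections")
    n_correct = table.tp + table.tn
    if n_correct < 1:
        raise UndefinedStatisticError("call shares undefined: no correct calls")
    raw = {
        "sensitivity": table.tp / (table.tp + table.fn),
        "specificity": table.tn / (table.tn + table.fp),
        "accuracy": n_correct / table.total,
        "tp_share": table.tp / n_correct,
        "tn_share": table.tn / n_correct,
        "fp_rate": table.fp / table.total,
    }
    ci = {
        "sensitivity": _exact_ci_pct(table.tp, table.tp + table.fn, ci_level),
        "specificity": _exact_ci_pct(table.tn, table.tn + table.fp, ci_level),
        "accuracy": _exact_ci_pct(n_correct, table.total, ci_level),
        "fp_rate": _exact_ci_pct(table.fp, table.total, ci_level),
    }
    pct = {k: round_half_up(100 * v) for k, v in raw.items()}
    return AccuracySummary(
        sensitivity=pct["sensitivity"],
        specificity=pct["specificity"],
        accuracy=pct["accuracy"],
        tp_share=pct["tp_share"],
        tn_share=pct["tn_share"],
        fp_rate=pct["fp_rate"],
        ci=ci,
        raw=raw,
    )


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher's exact p for the 2x2 call-vs-truth table."""
    _, p = scipy.stats.fisher_exact(
        [[table.tp, table.fn], [table.fp, table.tn]], alternative="two-sided"
    )
    return float(p)
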