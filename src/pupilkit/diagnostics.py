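"""Diagnostic-accuracy evaluation of labeled RAPD scores.

A set of one-tailed scores with case/control labels is evaluated as a binary
classifier: the positive call is ``score >= threshold`` (higher scores mean a
more asymmetric, more suspect reflex).  The module provides the ROC sweep,
trapezoidal AUROC (identical to the rank/pair-counting estimator), the Youden
J operating point, the standard confusion-matrix metrics plus the Matthews
correlation coefficient, and the two confirmatory re-analyses: severity
stratification with control subsampling, and reallocation of sub-quartile
case scores to the control group (compensating for clinical over-diagnosis of
physiologic interocular asymmetry).

The threshold conventions are pinned exactly (>= rule, infinite sentinels,
descending sweep, Youden ties broken toward the smallest threshold, i.e.
maximal sensitivity), so the sweep is implemented directly on numpy;
scikit-learn serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClassificationMetrics",
    "DiagnosticReport",
    "roc_curve",
    "auroc",
    "youden_cutoff",
    "classification_metrics",
    "confusion_at",
    "stratify_by_grade",
    "reorganize_low_scores",
    "DiagnosticModel",
    "DiagnosticResults",
    "evaluate_table",
]

CASE, CONTROL = "case", "control"


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    is_case = labels == CASE
    is_ctrl = labels == CONTROL
    if not np.all(is_case | is_ctrl):
        bad = labels[~(is_case | is_ctrl)][0]
        raise ValueError(f"labels must be 'case' or 'control', got {bad!r}")
    cases, ctrls = scores[is_case], scores[is_ctrl]
    if len(cases) == 0 or len(ctrls) == 0:
        raise ValueError("need at least one case and one control")
    return cases, ctrls


def roc_curve(scores, labels) -> pd.DataFrame:
    """ROC sweep over the distinct score values plus infinite sentinels.

    Returns a frame with columns ``threshold`` (descending, starting at +inf
    and ending at -inf), ``sensitivity`` and ``fpr`` (1 - specificity), under
    the rule score >= threshold -> positive.
    """
    cases, ctrls = _split(scores, labels)
    thresholds = np.concatenate(
        ([np.inf], np.unique(np.concatenate((cases, ctrls)))[::-1], [-np.inf])
    )
    cs = np.sort(cases)
    ns = np.sort(ctrls)
    # count of scores >= t via searchsorted on the sorted arrays
    tp = len(cs) - np.searchsorted(cs, thresholds, side="left")
    fp = len(ns) - np.searchsorted(ns, thresholds, side="left")
    return pd.DataFrame(
        {
            "threshold": thresholds,
            "sensitivity": tp / len(cs),
            "fpr": fp / len(ns),
        }
    )


def auroc(roc_points: pd.DataFrame) -> float:
    """Trapezoidal area under the (fpr, sensitivity) polyline.

    Equal to the rank-based pair-counting estimator
    P(case > control) + 0.5 P(tie) exactly.
    """
    fpr = roc_points["fpr"].to_numpy()
    sens = roc_points["sensitivity"].to_numpy()
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(sens[order], fpr[order]))


def youden_cutoff(roc_points: pd.DataFrame) -> tuple[float, float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties are broken toward the smallest threshold (maximal sensitivity: a
    missed RAPD costs more than a false positive).  Infinite sentinels are
    never reported as cutoffs unless they are the only rows.
    Returns (threshold, sensitivity, specificity).
    """
    pts = roc_points[np.isfinite(roc_points["threshold"])]
    if pts.empty:
        pts = roc_points
    j = pts["sensitivity"].to_numpy() - pts["fpr"].to_numpy()
    best = j.max()
    candidates = pts[np.isclose(j, best)]
    row = candidates.loc[candidates["threshold"].idxmin()]
    return float(row["threshold"]), float(row["sensitivity"]), float(1.0 - row["fpr"])


@dataclass(frozen=True)
class ClassificationMetrics:
    """Confusion-matrix summary statistics (fractions, not percent)."""

    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    mcc: float
    #: names of metrics whose denominator was zero (reported as 0 by convention)
    zero_denominator: tuple[str, ...] = ()

    def to_dict(self, percent: bool = False) -> dict:
        scale = 100.0 if percent else 1.0
        return {
            "sensitivity": self.sensitivity * scale,
            "specificity": self.specificity * scale,
            "accuracy": self.accuracy * scale,
            "precision": self.precision * scale,
            "mcc": self.mcc,
            "zero_denominator": list(self.zero_denominator),
        }


def classification_metrics(tp: int, fp: int, tn: int, fn: int) -> ClassificationMetrics:
    """Sensitivity, specificity, accuracy, precision and MCC from a 2x2 table.

    mcc = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)); any metric
    with a zero denominator is 0 by convention and listed in
    ``zero_denominator``.
    """
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion-matrix counts must be >= 0")
    total = sum(counts)
    if total == 0:
        raise ValueError("confusion matrix is empty")
    flagged: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            flagged.append(name)
            return 0.0
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    acc = (tp + tn) / total
    prec = ratio(tp, tp + fp, "precision")
    mcc_den = float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if mcc_den == 0:
        flagged.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(mcc_den)
    return ClassificationMetrics(sens, spec, acc, prec, float(mcc), tuple(flagged))


def confusion_at(scores, labels, threshold: float) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) under the rule score >= threshold -> positive."""
    cases, ctrls = _split(scores, labels)
    tp = int((cases >= threshold).sum())
    fn = len(cases) - tp
    fp = int((ctrls >= threshold).sum())
    tn = len(ctrls) - fp
    return tp, fp, tn, fn


def stratify_by_grade(
    table: pd.DataFrame,
    seed: int,
    mild_grades: tuple[int, ...] = (1, 2),
) -> dict[str, pd.DataFrame | None]:
    """Split cases by clinical severity and pair each stratum with a matched
    random control sample.

    Mild = grades 1-2; moderate-or-worse = grades >= 3.  Controls are sampled
    uniformly without replacement to the stratum's case count, seeded.  A
    stratum with no cases maps to None; more cases than controls is an error
    (sampling with replacement is refused).
    """
    _require_columns(table, ("score", "label", "grade"))
    cases = table[table["label"] == CASE]
    controls = table[table["label"] == CONTROL]
    rng = np.random.default_rng(seed)
    out: dict[str, pd.DataFrame | None] = {}
    strata = {
        "mild": cases[cases["grade"].isin(mild_grades)],
        "moderate": cases[cases["grade"] >= 3],
    }
    for name, sub in strata.items():
        if sub.empty:
            out[name] = None
            continue
        if len(sub) > len(controls):
            raise ValueError(
                f"{name} stratum has {len(sub)} cases but only "
                f"{len(controls)} controls; refusing to sample with replacement"
            )
        picked = rng.choice(len(controls), size=len(sub), replace=False)
        out[name] = pd.concat(
            [sub, controls.iloc[np.sort(picked)]], ignore_index=True
        )
    return out


def reorganize_low_scores(
    table: pd.DataFrame,
    quantile: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Reallocate the lowest-scoring cases evenly to the control group.

    Cases whose score is <= the case-cohort ``quantile`` (type-7 linear
    interpolation) are shuffled with the seeded generator; the first half
    (rounding down) are relabeled as controls (grade set to 0), the rest stay
    cases.  This compensates for clinical over-diagnosis of physiologic
    interocular asymmetry.  Total subject count is unchanged.
    """
    if not (0 < quantile < 1):
        raise ValueError("quantile must be in (0, 1)")
    _require_columns(table, ("score", "label"))
    out = table.reset_index(drop=True).copy()
    case_scores = out.loc[out["label"] == CASE, "score"]
    if case_scores.empty:
        raise ValueError("no cases present")
    cutoff = float(np.quantile(case_scores.to_numpy(dtype=float), quantile))
    low_idx = out.index[(out["label"] == CASE) & (out["score"] <= cutoff)].to_numpy()
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(low_idx)
    moved = shuffled[: len(shuffled) // 2]
    out.loc[moved, "label"] = CONTROL
    if "grade" in out.columns:
        out.loc[moved, "grade"] = 0
    info = {
        "cutoff": cutoff,
        "n_low": int(len(low_idx)),
        "n_moved": int(len(moved)),
    }
    return out, info


def _require_columns(table: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"score table is missing columns: {missing}")


@dataclass
class DiagnosticReport:
    """One evaluated score set: ROC, AUROC, Youden operating point and the
    confusion metrics at that point (percent scale)."""

    n_cases: int
    n_controls: int
    roc_points: pd.DataFrame
    auroc: float
    youden_cutoff: float
    sensitivity_pct: float
    specificity_pct: float
    accuracy_pct: float
    precision_pct: float
    mcc: float
    zero_denominator: tuple[str, ...] = ()

    def to_dict(self, include_roc: bool = True) -> dict:
        d = {
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "auroc": self.auroc,
            "youden_cutoff": self.youden_cutoff,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "accuracy_pct": self.accuracy_pct,
            "precision_pct": self.precision_pct,
            "mcc": self.mcc,
            "zero_denominator": list(self.zero_denominator),
        }
        if include_roc:
            d["roc_points"] = self.roc_points.replace(
                {np.inf: "inf", -np.inf: "-inf"}
            ).to_dict(orient="records")
        return d


class DiagnosticModel:
    """Evaluate labeled one-tailed RAPD scores as a binary classifier.

    Parameters
    ----------
    table:
        DataFrame with at least ``score`` and ``label`` ('case'/'control')
        columns; ``subject_id`` and ``grade`` (Bell 1-5, 0 for controls)
        enable the stratified and reallocation analyses.
    """

    def __init__(self, table: pd.DataFrame):
        _require_columns(table, ("score", "label"))
        self.table = table.reset_index(drop=True)
        _split(self.table["score"], self.table["label"])  # validates labels

    @classmethod
    def from_csv(cls, path) -> "DiagnosticModel":
        return cls(pd.read_csv(path))

    def fit(self, threshold: float | None = None) -> "DiagnosticResults":
        """Sweep the ROC and evaluate at the Youden point (or a fixed
        ``threshold`` if given)."""
        scores = self.table["score"].to_numpy(dtype=float)
        labels = self.table["label"].to_numpy()
        roc = roc_curve(scores, labels)
        area = auroc(roc)
        if threshold is None:
            cut, _, _ = youden_cutoff(roc)
        else:
            cut = float(threshold)
        tp, fp, tn, fn = confusion_at(scores, labels, cut)
        m = classification_metrics(tp, fp, tn, fn)
        report = DiagnosticReport(
            n_cases=tp + fn,
            n_controls=tn + fp,
            roc_points=roc,
            auroc=area,
            youden_cutoff=cut,
            sensitivity_pct=m.sensitivity * 100,
            specificity_pct=m.specificity * 100,
            accuracy_pct=m.accuracy * 100,
            precision_pct=m.precision * 100,
            mcc=m.mcc,
            zero_denominator=m.zero_denominator,
        )
        return DiagnosticResults(self, report, (tp, fp, tn, fn))


@dataclass
class DiagnosticResults:
    """Fitted diagnostic evaluation; carries the report and confusion counts."""

    model: DiagnosticModel
    report: DiagnosticReport
    confusion: tuple[int, int, int, int]

    def __getattr__(self, name):
        # delegate report fields (auroc, mcc, ...) for convenience
        try:
            return getattr(self.report, name)
        except AttributeError:
            raise AttributeError(name) from None

    def summary(self) -> str:
        r = self.report
        tp, fp, tn, fn = self.confusion
        lines = [
            "Diagnostic evaluation of one-tailed RAPD scores",
            "=" * 48,
            f"subjects            {r.n_cases} cases / {r.n_controls} controls",
            f"AUROC               {r.auroc:.3f}",
            f"Youden cutoff       score >= {r.youden_cutoff:.3f}",
            f"sensitivity         {r.sensitivity_pct:.1f}%",
            f"specificity         {r.specificity_pct:.1f}%",
            f"accuracy            {r.accuracy_pct:.1f}%",
            f"precision           {r.precision_pct:.1f}%",
            f"MCC                 {r.mcc:.3f}",
            f"confusion (tp fp tn fn)  {tp} {fp} {tn} {fn}",
        ]
        if r.zero_denominator:
            lines.append(f"zero-denominator metrics: {', '.join(r.zero_denominator)}")
        return "\n".join(lines)

    def plot_roc(self, ax=None, label: str | None = None):
        from .plotting import plot_roc

        return plot_roc(self.report, ax=ax, label=label)


def evaluate_table(
    table: pd.DataFrame,
    seed: int = 0,
    quantile: float = 0.25,
) -> dict[str, DiagnosticReport | None]:
    """The four-row evaluation: overall, mild-only, moderate-or-worse-only
    (each with matched control subsampling), and with sub-quantile case
    scores reallocated to controls.  Without a usable grade column only the
    overall and reorganized rows are produced.
    """
    out: dict[str, DiagnosticReport | None] = {
        "overall": DiagnosticModel(table).fit().report
    }
    has_grades = "grade" in table.columns and (
        table.loc[table["label"] == CASE, "grade"].fillna(0) > 0
    ).any()
    if has_grades:
        for name, sub in stratify_by_grade(table, seed=seed).items():
            out[name] = DiagnosticModel(sub).fit().report if sub is not None else None
    relabeled, _ = reorganize_low_scores(table, quantile=quantile, seed=seed)
    out["reorganized"] = DiagnosticModel(relabeled).fit().report
    return out
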