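"""Benchmark bookkeeping: confusion counts and detection statistics.

Genes of an annotated cluster carry one of five roles: ``core`` (the
backbone enzyme used as the detection anchor), ``biosynthetic`` (pathway
enzymes), ``further_essential`` (required transporters, transcription
factors, resistance genes), ``gap`` (co-localized but uninvolved), and
``extra`` (outside the cluster borders).  Detection quality is scored in two
modes: *essential* treats biosynthetic plus further-essential genes as
positives; *biosynthetic* scores only the biosynthetic genes and drops the
further-essential genes from all four counts.  Gap and extra genes are the
negatives in both modes, so specificity-side statistics coincide across
modes.  Core genes are the detection anchor and are never counted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

__all__ = [
    "GeneAnnotation",
    "ConfusionCounts",
    "MetricsReport",
    "ROLES",
    "confusion_counts",
    "metrics",
    "derived_statistics",
    "percent_correct",
    "read_annotations",
    "write_annotations",
]

ROLES = ("core", "biosynthetic", "further_essential", "gap", "extra")
_ESSENTIAL = {"biosynthetic", "further_essential"}
_NEGATIVE = {"gap", "extra"}


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    mode: str = "essential"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts must not all be zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """The twelve detection statistics plus the conventional NIR variant.

    ``no_information_rate`` is the majority-class share (the accuracy of
    always guessing the larger class); the textbook complement is also
    reported as ``minority_class_share`` under its own name.
    """

    sensitivity: float
    specificity: float
    precision: float
    npv: float
    fpr: float
    fdr: float
    fnr: float
    accuracy: float
    f1: float
    mcc: float
    normalized_mcc: float
    no_information_rate: float
    minority_class_share: float = float("nan")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_frame(self) -> pd.DataFrame:
        names = {
            "sensitivity": "Sensitivity",
            "specificity": "Specificity",
            "precision": "Precision",
            "npv": "Negative Predictive Value",
            "fpr": "False Positive Rate",
            "fdr": "False Discovery Rate",
            "fnr": "False Negative Rate",
            "accuracy": "Accuracy",
            "f1": "F1 Score",
            "mcc": "Matthews Correlation Coefficient",
            "normalized_mcc": "Normalized Matthews Correlation Coefficient",
            "no_information_rate": "No-information error rate ni",
        }
        data = asdict(self)
        return pd.DataFrame(
            {"statistic": list(names.values()),
             "value": [data[k] for k in names]}
        )


def confusion_counts(
    detected: set[str],
    annotations: list[GeneAnnotation],
    mode: str = "essential",
) -> ConfusionCounts:
    """TP/FP/TN/FN of a detected-gene set against role annotations.

    ``mode="essential"``: positives are biosynthetic + further-essential
    genes.  ``mode="biosynthetic"``: positives are biosynthetic genes only
    and further-essential genes leave the contingency table entirely.
    Core genes never enter any count; every detected gene must be annotated.
    """
    if mode not in ("essential", "biosynthetic"):
        raise ValueError(f"unknown mode {mode!r}")
    role_of = {a.gene_id: a.role for a in annotations}
    if len(role_of) != len(annotations):
        raise ValueError("duplicate gene ids in annotations")
    unknown = set(detected) - set(role_of)
    if unknown:
        raise ValueError(f"detected genes without annotation: {sorted(unknown)}")

    if mode == "essential":
        positives = {g for g, r in role_of.items() if r in _ESSENTIAL}
    else:
        positives = {g for g, r in role_of.items() if r == "biosynthetic"}
    negatives = {g for g, r in role_of.items() if r in _NEGATIVE}
    scored = positives | negatives  # cores (and, in biosynthetic mode,
    detected = set(detected) & scored  # further-essential genes) drop out

    return ConfusionCounts(
        tp=len(detected & positives),
        fn=len(positives - detected),
        fp=len(detected & negatives),
        tn=len(negatives - detected),
        mode=mode,
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Standard detection statistics from one confusion quadruple.

    Ratios with a zero denominator come back as NaN.  The Matthews
    correlation coefficient is rescaled to [0, 1] as ``(mcc + 1) / 2``; the
    no-information rate is the majority-class share
    ``max(TP+FN, TN+FP) / total``.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    total = counts.total
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    prec = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    acc = _ratio(tp + tn, total)
    f1 = (
        2 * prec * sens / (prec + sens)
        if math.isfinite(prec) and math.isfinite(sens) and (prec + sens) > 0
        else float("nan")
    )
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else float("nan")
    majority = max(tp + fn, tn + fp)
    return MetricsReport(
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        npv=npv,
        fpr=1.0 - spec,
        fdr=1.0 - prec,
        fnr=1.0 - sens,
        accuracy=acc,
        f1=f1,
        mcc=mcc,
        normalized_mcc=(mcc + 1.0) / 2.0,
        no_information_rate=_ratio(majority, total),
        minority_class_share=_ratio(total - majority, total),
    )


def derived_statistics(
    sensitivity: float, specificity: float, precision: float, mcc: float
) -> dict[str, float]:
    """Dependent detection statistics recomputed from their parent rates.

    Useful for consistency-checking a published report: F1 follows from
    precision and sensitivity, the three error rates are complements, and
    the normalized MCC is an affine rescaling.
    """
    return {
        "f1": 2 * precision * sensitivity / (precision + sensitivity),
        "fpr": 1.0 - specificity,
        "fdr": 1.0 - precision,
        "fnr": 1.0 - sensitivity,
        "normalized_mcc": (mcc + 1.0) / 2.0,
    }


def percent_correct(
    detected: set[str], annotations: list[GeneAnnotation], mode: str = "essential"
) -> float:
    """Share of non-core genes classified correctly (per-cluster helper)."""
    c = confusion_counts(detected, annotations, mode=mode)
    return (c.tp + c.tn) / c.total


def read_annotations(path) -> list[GeneAnnotation]:
    """Read a two-column (gene_id, role) TSV; a header row is optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("annotation TSV needs columns gene_id and role")
    if df.iloc[0, 0] == "gene_id":
        df = df.iloc[1:]
    return [GeneAnnotation(r.iloc[0], r.iloc[1]) for _, r in df.iterrows()]


def write_annotations(annotations: list[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\trole\n")
        for a in annotations:
            fh.write(f"{a.gene_id}\t{a.role}\n")
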