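"""Diagnostic-performance evaluation: exclusions, 2x2 metrics, AUROC,
proportion tests, per-participant agreement, and comparison tables.

The analysis set is formed by removing recordings lacking a rhythm diagnosis
on either modality — uninterpretable reference ECG, insufficient PPG signal
quality, low classification certainty, or other reasons — each record counted
once under the first applicable reason in that fixed priority order.
Metrics are computed from 2x2 tables under two positive-class definitions:
AF only (flutter-labelled records excluded) and AF/AFL grouped together.
Confidence intervals are Wilson score intervals, which remain well-behaved
for proportions near 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

AF_ONLY = "AF_only"
AF_OR_AFL = "AF_or_AFL"

EXCLUSION_REASONS = ["ecg_insufficient", "ppg_insufficient", "low_certainty", "other"]

METRIC_NAMES = ["sensitivity", "specificity", "accuracy", "ppv", "npv", "f1"]


@dataclass
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int
    positive_definition: str = AF_ONLY

    def __post_init__(self) -> None:
        for v in (self.tp, self.fp, self.tn, self.fn):
            if v < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricCI:
    value: float  # percent
    ci_low: float
    ci_high: float
    k: int  # numerator count
    n: int  # denominator count

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.value, self.ci_low, self.ci_high)


@dataclass
class DiagnosticReport:
    ct: ConfusionTable
    metrics: dict[str, MetricCI | None]
    auroc: float | None
    ledger: dict[str, int]
    n_analyzed: int
    n_total: int
    n_subjects: int | None = None
    positive_definition: str = AF_ONLY
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "positive_definition": self.positive_definition,
            "n_total": self.n_total,
            "n_analyzed": self.n_analyzed,
            "n_subjects": self.n_subjects,
            "confusion": {
                "tp": self.ct.tp, "fp": self.ct.fp,
                "tn": self.ct.tn, "fn": self.ct.fn,
            },
            "metrics": {
                k: (None if v is None else
                    {"value": v.value, "ci_low": v.ci_low, "ci_high": v.ci_high,
                     "k": v.k, "n": v.n})
                for k, v in self.metrics.items()
            },
            "auroc": self.auroc,
            "exclusions": dict(self.ledger),
            **self.extra,
        }

    def to_markdown(self) -> str:
        lines = [
            f"| metric | % (95% CI) |",
            f"|---|---|",
        ]
        for name in METRIC_NAMES:
            m = self.metrics.get(name)
            cell = (
                "undefined" if m is None
                else f"{m.value:.1f} [{m.ci_low:.1f}-{m.ci_high:.1f}]"
            )
            lines.append(f"| {name} | {cell} |")
        if self.auroc is not None:
            lines.append(f"| auroc | {self.auroc:.3f} |")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Exclusion pipeline
# ---------------------------------------------------------------------------


def apply_exclusions(
    records: pd.DataFrame, gate: float = 0.9
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign exclusion reasons in fixed priority order and split the input.

    `records` needs columns ``ecg_label``, ``ppg_sufficient``; ``certainty``
    (NaN when no classification was produced) and optionally ``pred_label``.
    Priority: uninterpretable ECG -> insufficient PPG -> low certainty ->
    other (sufficient PPG but no classification).  Returns (analysis set,
    ledger); ledger counts + len(analysis set) == len(records) always.
    """
    df = records.copy()
    certainty = df["certainty"] if "certainty" in df else pd.Series(np.nan, index=df.index)

    reason = pd.Series("none", index=df.index, dtype=object)
    no_classification = certainty.isna()
    reason[no_classification] = "other"
    reason[(reason == "none") & (certainty < gate)] = "low_certainty"
    reason[~df["ppg_sufficient"].astype(bool)] = "ppg_insufficient"
    reason[df["ecg_label"] == "INSUFFICIENT"] = "ecg_insufficient"

    df["exclusion_reason"] = reason
    ledger = {r: int((reason == r).sum()) for r in EXCLUSION_REASONS}
    analysis = df[reason == "none"].reset_index(drop=True)
    return analysis, ledger


def confusion_from_records(
    analysis: pd.DataFrame, positive_definition: str = AF_ONLY
) -> tuple[ConfusionTable, pd.DataFrame]:
    """Dichotomize analyzed records and count the 2x2 table.

    Under ``AF_only`` records whose reference label is AFL are dropped and
    positive = AF; under ``AF_or_AFL`` positive = {AF, AFL} grouped.
    Returns the table and the dichotomized record set used for it.
    """
    df = analysis
    if positive_definition == AF_ONLY:
        df = df[df["ecg_label"] != "AFL"]
        ref_pos = df["ecg_label"] == "AF"
        pred_pos = df["pred_label"] == "AF"
    elif positive_definition == AF_OR_AFL:
        ref_pos = df["ecg_label"].isin(["AF", "AFL"])
        pred_pos = df["pred_label"].isin(["AF", "AFL"])
    else:
        raise ValueError(f"unknown positive definition {positive_definition!r}")
    ct = ConfusionTable(
        tp=int((ref_pos & pred_pos).sum()),
        fp=int((~ref_pos & pred_pos).sum()),
        tn=int((~ref_pos & ~pred_pos).sum()),
        fn=int((ref_pos & ~pred_pos).sum()),
        positive_definition=positive_definition,
    )
    out = df.copy()
    out["ref_pos"] = ref_pos
    out["pred_pos"] = pred_pos
    return ct, out


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def _wilson_pct(k: int, n: int) -> MetricCI | None:
    if n == 0:
        return None
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return MetricCI(100.0 * k / n, 100.0 * lo, 100.0 * hi, k, n)


def compute_metrics(ct: ConfusionTable) -> dict[str, MetricCI | None]:
    """Se/Sp/Acc/PPV/NPV/F1 as percentages with Wilson 95% CIs.

    A metric with an empty margin is reported as None (undefined), never 0.
    The F1 interval uses the Wilson interval on F1's own effective counts,
    F1 = 2TP / (2TP + FP + FN).
    """
    m = {
        "sensitivity": _wilson_pct(ct.tp, ct.tp + ct.fn),
        "specificity": _wilson_pct(ct.tn, ct.tn + ct.fp),
        "accuracy": _wilson_pct(ct.tp + ct.tn, ct.total),
        "ppv": _wilson_pct(ct.tp, ct.tp + ct.fp),
        "npv": _wilson_pct(ct.tn, ct.tn + ct.fn),
        "f1": _wilson_pct(2 * ct.tp, 2 * ct.tp + ct.fp + ct.fn),
    }
    return m


def f1_from_se_ppv(se_pct: float, ppv_pct: float) -> float:
    """Harmonic mean of sensitivity and PPV, in percent."""
    if se_pct + ppv_pct == 0:
        return 0.0
    return 2.0 * se_pct * ppv_pct / (se_pct + ppv_pct)


def compute_auroc(scores, labels) -> float:
    """Rank-statistic (Mann-Whitney) AUROC; ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: one class absent")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compare_proportions(
    k1: int, n1: int, k2: int, n2: int, method: str = "chi2"
) -> tuple[float, float]:
    """Two-sided comparison of k1/n1 vs k2/n2; returns (p, statistic).

    Default is the Pearson chi-square test on the 2x2 table without
    continuity correction; Fisher's exact test is available for tables with
    small expected counts (statistic reported as the odds ratio).
    """
    if n1 < 1 or n2 < 1 or k1 > n1 or k2 > n2:
        raise ValueError("need 0 <= k <= n and n >= 1")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if method == "fisher":
        odds, p = stats.fisher_exact(table)
        return float(p), float(odds)
    col_sums = table.sum(axis=0)
    if np.any(col_sums == 0):
        # degenerate margin: identical column structure, no evidence of difference
        return 1.0, 0.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p), float(chi2)


# ---------------------------------------------------------------------------
# Per-participant agreement
# ---------------------------------------------------------------------------


def per_participant_agreement(analysis: pd.DataFrame) -> dict:
    """Subject-level agreement of PPG classification with the reference,
    dichotomized SR vs AF (flutter-labelled records excluded).
    """
    df = analysis[analysis["ecg_label"] != "AFL"]
    dis = (
        ((df["ecg_label"] == "AF") != (df["pred_label"] == "AF"))
        .groupby(df["subject_id"])
        .sum()
    )
    return {
        "n_subjects": int(dis.size),
        "full_agreement": int((dis == 0).sum()),
        "at_most_one_disagreement": int((dis <= 1).sum()),
        "disagreements_per_subject": {k: int(v) for k, v in dis.items()},
    }


# ---------------------------------------------------------------------------
# Report assembly and comparisons
# ---------------------------------------------------------------------------


def build_report(
    records: pd.DataFrame,
    gate: float = 0.9,
    positive_definition: str = AF_ONLY,
    score_column: str | None = None,
) -> DiagnosticReport:
    """Full pipeline: exclusions -> 2x2 table -> metrics (+AUROC if scores).

    ``score_column`` names the positive-class posterior used for AUROC,
    computed over the analyzed (post-exclusion) record set.
    """
    analysis, ledger = apply_exclusions(records, gate=gate)
    ct, dich = confusion_from_records(analysis, positive_definition)
    metrics = compute_metrics(ct)
    auroc = None
    if score_column is not None and score_column in dich:
        ref = dich["ref_pos"].to_numpy()
        if ref.any() and (~ref).any():
            auroc = compute_auroc(dich[score_column].to_numpy(), ref)
    n_subjects = (
        int(records["subject_id"].nunique()) if "subject_id" in records else None
    )
    return DiagnosticReport(
        ct=ct,
        metrics=metrics,
        auroc=auroc,
        ledger=ledger,
        n_analyzed=int(len(analysis)),
        n_total=int(len(records)),
        n_subjects=n_subjects,
        positive_definition=positive_definition,
    )


COMPARISON_ROWS = [
    "participants",
    "recordings",
    "insufficient_quality",
    "low_certainty",
    "sensitivity",
    "specificity",
    "accuracy",
    "ppv",
    "npv",
]


def comparison_report(
    report_a: DiagnosticReport, report_b: DiagnosticReport
) -> dict:
    """Side-by-side table of two diagnostic reports with per-metric p-values.

    Shaped like the published before/after-revision comparison: participant
    and recording counts, exclusion proportions, then each metric with its CI
    and a chi-square p-value computed from the underlying correct/incorrect
    counts of the two reports.
    """
    if report_a.positive_definition != report_b.positive_definition:
        raise ValueError("reports use different positive-class definitions")

    def prop_row(k_a, n_a, k_b, n_b):
        p, chi2 = compare_proportions(k_a, n_a, k_b, n_b)
        return {
            "a": {"k": k_a, "n": n_a, "pct": 100.0 * k_a / n_a if n_a else None},
            "b": {"k": k_b, "n": n_b, "pct": 100.0 * k_b / n_b if n_b else None},
            "p": p,
            "chi2": chi2,
        }

    rows: dict[str, dict] = {
        "participants": {"a": report_a.n_subjects, "b": report_b.n_subjects},
        "recordings": {"a": report_a.n_total, "b": report_b.n_total},
        "insufficient_quality": prop_row(
            report_a.ledger["ppg_insufficient"], report_a.n_total,
            report_b.ledger["ppg_insufficient"], report_b.n_total,
        ),
        "low_certainty": prop_row(
            report_a.ledger["low_certainty"], report_a.n_total,
            report_b.ledger["low_certainty"], report_b.n_total,
        ),
    }
    for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
        ma, mb = report_a.metrics[name], report_b.metrics[name]
        if ma is None or mb is None:
            rows[name] = {"a": None, "b": None, "p": None}
            continue
        row = prop_row(ma.k, ma.n, mb.k, mb.n)
        row["a"]["ci"] = [ma.ci_low, ma.ci_high]
        row["b"]["ci"] = [mb.ci_low, mb.ci_high]
        rows[name] = row
    return rows


def comparison_markdown(rows: dict) -> str:
    lines = ["| quantity | group A | group B | P |", "|---|---|---|---|"]
    for name in COMPARISON_ROWS:
        r = rows.get(name)
        if r is None:
            continue
        if name in ("participants", "recordings"):
            lines.append(f"| {name} | {r['a']} | {r['b']} | - |")
            continue

        def cell(side):
            if side is None or side.get("pct") is None:
                return "undefined"
            s = f"{side['pct']:.1f}% ({side['k']}/{side['n']})"
            if "ci" in side:
                s += f" [{side['ci'][0]:.1f}-{side['ci'][1]:.1f}]"
            return s

        p = "-" if r.get("p") is None else f"{r['p']:.4g}"
        lines.append(f"| {name} | {cell(r.get('a'))} | {cell(r.get('b'))} | {p} |")
    return "\n".join(lines)
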