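"""Cohort aggregation into tissue-level body-map statistics.

Per-sample expression profiles are grouped by tissue and summarized as
per-metric medians, threshold positivity fractions (share of samples
strictly above a threshold, 1 RPKM by default), and high-expression
outlier flags.  Proteasome abundance is summarized by the median of
the three constitutive proteolytic subunits (PSMB5/6/7) and the median
of the three cytokine-inducible immunoproteasome subunits
(PSMB8/9/10).  Associations between metrics are measured with
Spearman's rank correlation, either across tissue medians (the
body-map view) or across individual samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from hlaquant.expression_quant import SampleExpressionProfile, profiles_to_cohort_rows

#: Metric pairs correlated across tissue medians by default.
DEFAULT_CORRELATION_PAIRS = (
    ("proteasome_immuno", "classII_composite"),
    ("proteasome_immuno", "classI_classical"),
    ("PSMB9", "TAP1"),
)


@dataclass(frozen=True)
class CorrelationResult:
    """A Spearman rank correlation between two metrics over n observations."""

    metric_x: str
    metric_y: str
    rho: float
    n: int


@dataclass
class TissueSummary:
    """Per-tissue medians, positivity and outliers for every metric."""

    tissue: str
    n_samples: int
    median_per_metric: dict[str, float] = field(default_factory=dict)
    positivity: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    outlier_ids: list[str] = field(default_factory=list)


@dataclass
class BodyMapTable:
    """The aggregated body map: tissue summaries plus cross-tissue correlations."""

    tissues: dict[str, TissueSummary] = field(default_factory=dict)
    correlations: list[CorrelationResult] = field(default_factory=list)
    positivity_threshold: float = 1.0
    outlier_metric: str = "classI_classical"
    outlier_threshold: float = math.inf

    def tissue_medians(self, metric: str) -> dict[str, float]:
        return {
            t: s.median_per_metric[metric]
            for t, s in self.tissues.items()
            if metric in s.median_per_metric
        }


def median(values: Sequence[float]) -> float:
    """Middle order statistic (mean of the two middle values for even n)."""
    if len(values) == 0:
        raise ValueError("median of an empty collection is undefined")
    return float(np.median(np.asarray(values, dtype=float)))


def positivity_fraction(
    values: Sequence[float], threshold: float = 1.0
) -> tuple[int, int, int]:
    """Count samples strictly above ``threshold``; percent to nearest integer.

    Returns ``(k, n, percent)`` with ``percent = round(100 * k / n)``.
    Strict inequality means samples sitting exactly at the threshold do
    not count as positive.
    """
    n = len(values)
    if n == 0:
        raise ValueError("positivity fraction of an empty collection is undefined")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    k = sum(1 for v in values if v > threshold)
    percent = int(round(100.0 * k / n))
    return k, n, percent


def flag_outliers(
    values_by_id: Mapping[str, float], threshold: float
) -> list[str]:
    """Sample ids whose metric strictly exceeds ``threshold``, sorted."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return sorted(i for i, v in values_by_id.items() if v > threshold)


def proteasome_summary(
    psmb5: float, psmb6: float, psmb7: float,
    psmb8: float, psmb9: float, psmb10: float,
) -> tuple[float, float]:
    """Median-of-subunits summaries of the two proteasome types.

    The constitutive proteasome is approximated by the median RPKM of
    its proteolytic subunits beta5/beta1/beta2 (PSMB5, PSMB6, PSMB7);
    the immunoproteasome by the median of the inducible subunits
    PSMB8 (LMP7), PSMB9 (LMP2) and PSMB10 (LMP10).
    """
    values = (psmb5, psmb6, psmb7, psmb8, psmb9, psmb10)
    if any(v < 0 for v in values):
        raise ValueError("proteasome subunit RPKMs must be non-negative")
    return median([psmb5, psmb6, psmb7]), median([psmb8, psmb9, psmb10])


def spearman(x: Sequence[float], y: Sequence[float],
             metric_x: str = "x", metric_y: str = "y") -> CorrelationResult:
    """Spearman's rank correlation (ties get average ranks)."""
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError("Spearman correlation requires at least 3 observations")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = sps.spearmanr(xa, ya).statistic
    return CorrelationResult(metric_x=metric_x, metric_y=metric_y,
                             rho=float(rho), n=len(x))


def build_bodymap(
    profiles: Sequence[SampleExpressionProfile],
    manifest: Mapping[str, str] | None = None,
    metrics: Sequence[str] | None = None,
    positivity_threshold: float = 1.0,
    outlier_metric: str = "classI_classical",
    outlier_threshold: float = math.inf,
    correlation_pairs: Sequence[tuple[str, str]] = DEFAULT_CORRELATION_PAIRS,
) -> BodyMapTable:
    """Aggregate a cohort of sample profiles into a body-map table.

    ``manifest`` maps sample id to tissue label and overrides any
    tissue already stored on the profile; every manifest sample must
    exist in the cohort.  Cross-metric Spearman correlations are
    computed over tissue medians (n = number of tissues) for each
    configured pair present in the data; pairs with fewer than three
    tissues or a constant vector are reported as NaN.
    """
    if not profiles:
        raise ValueError("cannot build a body map from an empty cohort")
    by_id = {p.sample: p for p in profiles}
    if manifest is not None:
        unknown = set(manifest) - set(by_id)
        if unknown:
            raise KeyError(f"manifest references unknown sample(s): {sorted(unknown)}")

    df = pd.DataFrame(profiles_to_cohort_rows(list(profiles)))
    if manifest is not None:
        df["tissue"] = df["sample"].map(dict(manifest)).fillna(df["tissue"])
    if (df["tissue"] == "").any():
        missing = df.loc[df["tissue"] == "", "sample"].tolist()
        raise ValueError(f"samples without a tissue label: {missing}")

    metric_cols = [
        c for c in df.columns
        if c not in ("sample", "tissue") and pd.api.types.is_numeric_dtype(df[c])
    ]
    if metrics is not None:
        metric_cols = [c for c in metric_cols if c in metrics]

    table = BodyMapTable(
        positivity_threshold=positivity_threshold,
        outlier_metric=outlier_metric,
        outlier_threshold=outlier_threshold,
    )
    for tissue, sub in df.groupby("tissue", sort=True):
        summary = TissueSummary(tissue=str(tissue), n_samples=len(sub))
        for metric in metric_cols:
            col = sub[metric].dropna()
            if col.empty:
                continue
            summary.median_per_metric[metric] = median(col.tolist())
            summary.positivity[metric] = positivity_fraction(
                col.tolist(), positivity_threshold
            )
        if outlier_metric in sub.columns and math.isfinite(outlier_threshold):
            summary.outlier_ids = flag_outliers(
                dict(zip(sub["sample"], sub[outlier_metric].fillna(0.0))),
                outlier_threshold,
            )
        table.tissues[str(tissue)] = summary

    for mx, my in correlation_pairs:
        med_x = table.tissue_medians(mx)
        med_y = table.tissue_medians(my)
        common = sorted(set(med_x) & set(med_y))
        if len(common) < 3:
            table.correlations.append(
                CorrelationResult(metric_x=mx, metric_y=my, rho=float("nan"), n=len(common))
            )
            continue
        x = [med_x[t] for t in common]
        y = [med_y[t] for t in common]
        try:
            table.correlations.append(spearman(x, y, metric_x=mx, metric_y=my))
        except ValueError:
            table.correlations.append(
                CorrelationResult(metric_x=mx, metric_y=my, rho=float("nan"), n=len(common))
            )
    return table


def per_sample_correlation(
    profiles: Sequence[SampleExpressionProfile],
    metric_x: str,
    metric_y: str,
) -> CorrelationResult:
    """Spearman correlation of two metrics across individual samples.

    This is the within-individuals view (e.g. PSMB9 vs TAP1 across all
    samples), as opposed to the cross-tissue median correlation in
    :func:`build_bodymap`.
    """
    x, y = [], []
    for p in profiles:
        vx, vy = p.metric(metric_x), p.metric(metric_y)
        if vx is None or vy is None:
            continue
        x.append(vx)
        y.append(vy)
    return spearman(x, y, metric_x=metric_x, metric_y=metric_y)


def bodymap_to_frame(table: BodyMapTable) -> pd.DataFrame:
    """Tissue x metric median matrix with positivity columns."""
    rows = []
    for tissue, s in sorted(table.tissues.items()):
        row: dict[str, object] = {"tissue": tissue, "n_samples": s.n_samples}
        for metric, m in s.median_per_metric.items():
            row[f"median_{metric}"] = m
        for metric, (k, n, pct) in s.positivity.items():
            row[f"positive_{metric}"] = f"{k}/{n}"
            row[f"positive_pct_{metric}"] = pct
        row["outliers"] = ",".join(s.outlier_ids)
        rows.append(row)
    return pd.DataFrame(rows)


def correlations_to_frame(table: BodyMapTable) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"metric_x": c.metric_x, "metric_y": c.metric_y, "rho": c.rho, "n": c.n}
            for c in table.correlations
        ]
    )


def plot_proteasome_panel(table: BodyMapTable, path: str) -> None:
    """Bar panel of constitutive vs immunoproteasome medians per tissue,
    sorted by ascending immunoproteasome expression."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    const = table.tissue_medians("proteasome_constitutive")
    immuno = table.tissue_medians("proteasome_immuno")
    tissues = sorted(set(const) & set(immuno), key=lambda t: immuno[t])
    if not tissues:
        raise ValueError("no tissues with proteasome summaries to plot")
    x = np.arange(len(tissues))
    fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(tissues)), 4))
    ax.bar(x - 0.2, [const[t] for t in tissues], width=0.4,
           label="constitutive (PSMB5/6/7)", color="firebrick")
    ax.bar(x + 0.2, [immuno[t] for t in tissues], width=0.4,
           label="immuno (PSMB8/9/10)", color="steelblue")
    ax.set_xticks(x)
    ax.set_xticklabels(tissues, rotation=90)
    ax.set_ylabel("median RPKM")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
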