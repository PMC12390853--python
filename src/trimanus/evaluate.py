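"""Batch evaluation: condition summaries, percent changes, paired statistics.

Improvement percentages respect each metric's direction (higher-better vs
lower-better).  Paired comparisons are normality-gated (Shapiro-Wilk ->
paired t with Cohen's d, else Wilcoxon with rank-biserial correlation) and
judged at the Bonferroni-adjusted alpha of 0.05/6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

N_PRIMARY_METRICS = 6
BONFERRONI_ALPHA = 0.05 / N_PRIMARY_METRICS

#: direction conventions for the six primary trial metrics
METRIC_DIRECTIONS = {
    "tasks_completed": "higher",
    "spatial_error_mm": "lower",
    "movement_efficiency": "higher",
    "cognitive_load": "lower",
    "task_success": "higher",
    "control_precision": "higher",
}


class EvaluationError(ValueError):
    pass


def percent_change(baseline: float, treatment: float, direction: str = "higher",
                   ndigits: int | None = None) -> float:
    """Directional improvement percentage relative to baseline."""
    if baseline == 0:
        raise EvaluationError("baseline is zero; percent change undefined")
    if direction not in ("higher", "lower"):
        raise EvaluationError(f"unknown direction {direction!r}")
    if direction == "higher":
        value = 100.0 * (treatment - baseline) / baseline
    else:
        value = 100.0 * (baseline - treatment) / baseline
    return round(value, ndigits) if ndigits is not None else value


def cohens_d_from_t(t_value: float, n: int) -> float:
    """Paired-design effect size d = t / sqrt(n)."""
    if n < 2:
        raise EvaluationError("n must be >= 2")
    return t_value / math.sqrt(n)


@dataclass
class ComparisonResult:
    test: str                  # 'paired-t' | 'wilcoxon' | 'degenerate'
    statistic: float
    p_value: float
    effect_size: float | None
    effect_name: str
    n: int
    alpha: float = BONFERRONI_ALPHA
    normal: bool | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def paired_compare(a, b, alpha: float = BONFERRONI_ALPHA,
                   normality_alpha: float = 0.05) -> ComparisonResult:
    """Normality-gated paired comparison of two equal-length samples."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) != len(b):
        raise EvaluationError("samples must be paired (equal length)")
    if len(a) < 3:
        raise EvaluationError("need at least 3 pairs")
    diff = b - a
    n = len(diff)
    if np.allclose(diff, diff[0]):
        # zero-variance differences: t and d are undefined or infinite
        if abs(diff[0]) < 1e-300:
            return ComparisonResult("degenerate", 0.0, 1.0, 0.0, "d", n, alpha)
        return ComparisonResult("degenerate", math.inf, 0.0, math.inf, "d", n, alpha)
    _, p_norm = stats.shapiro(diff)
    normal = p_norm > normality_alpha
    if normal:
        t_stat, p = stats.ttest_rel(b, a)
        d = float(diff.mean() / diff.std(ddof=1))
        return ComparisonResult("paired-t", float(t_stat), float(p), d, "d",
                                n, alpha, normal)
    res = stats.wilcoxon(b, a)
    ranks = stats.rankdata(np.abs(diff[diff != 0]))
    signs = np.sign(diff[diff != 0])
    w_plus = float(ranks[signs > 0].sum())
    w_minus = float(ranks[signs < 0].sum())
    rank_biserial = (w_plus - w_minus) / (w_plus + w_minus)
    return ComparisonResult("wilcoxon", float(res.statistic), float(res.pvalue),
                            rank_biserial, "rank-biserial", n, alpha, normal)


def summarize(results: pd.DataFrame, baseline: str = "two_hand",
              treatment: str = "tri_manual",
              directions: dict[str, str] | None = None,
              paired: bool = True) -> pd.DataFrame:
    """Per-metric condition means/SDs, improvements and paired statistics.

    ``results`` is tidy: one row per trial with a ``condition`` column and
    one numeric column per metric.
    """
    if results.empty:
        raise EvaluationError("no results to summarize")
    directions = directions or METRIC_DIRECTIONS
    metrics = [c for c in results.columns
               if c not in ("condition", "trial") and
               np.issubdtype(results[c].dtype, np.number)]
    rows = []
    for metric in metrics:
        base = results.loc[results["condition"] == baseline, metric].dropna().to_numpy()
        treat = results.loc[results["condition"] == treatment, metric].dropna().to_numpy()
        if len(base) == 0 or len(treat) == 0:
            # metric undefined for a condition (e.g. virtual-hand smoothness
            # in the two-hand baseline): report it without statistics
            rows.append({"metric": metric, "direction": directions.get(metric, "higher"),
                         "baseline_mean": np.nan, "baseline_sd": np.nan,
                         "treatment_mean": np.nan, "treatment_sd": np.nan,
                         "improvement_pct": np.nan})
            continue
        direction = directions.get(metric, "higher")
        row = {
            "metric": metric,
            "direction": direction,
            "baseline_mean": float(base.mean()),
            "baseline_sd": float(base.std(ddof=1)) if len(base) > 1 else np.nan,
            "treatment_mean": float(treat.mean()),
            "treatment_sd": float(treat.std(ddof=1)) if len(treat) > 1 else np.nan,
        }
        try:
            row["improvement_pct"] = percent_change(
                row["baseline_mean"], row["treatment_mean"], direction, ndigits=1)
        except EvaluationError:
            row["improvement_pct"] = np.nan
        if paired and len(base) == len(treat) and len(base) >= 3:
            cmp = paired_compare(base, treat)
            row.update(test=cmp.test, statistic=cmp.statistic, p_value=cmp.p_value,
                       effect_size=cmp.effect_size, effect_name=cmp.effect_name,
                       significant=cmp.significant)
        rows.append(row)
    return pd.DataFrame(rows)


# -- printed-value consistency checks ---------------------------------------

def _fixture_path(name: str) -> Path:
    return Path(resources.files("trimanus.data") / name)


def load_reference_metrics(path=None) -> pd.DataFrame:
    path = path or _fixture_path("reference_metrics.tsv")
    return pd.read_csv(path, sep="\t")


def load_reference_subscales(path=None) -> pd.DataFrame:
    path = path or _fixture_path("reference_subscales.tsv")
    return pd.read_csv(path, sep="\t")


def consistency_check(reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute improvement % and effect sizes from printed means/statistics.

    Returns the reference table augmented with computed values and
    match flags at the printed precision (1 d.p. for percentages,
    2 d.p. for d).
    """
    ref = reference if reference is not None else load_reference_metrics()
    out = ref.copy()
    out["computed_improvement"] = [
        percent_change(row.baseline_mean, row.treatment_mean, row.direction, ndigits=1)
        for row in ref.itertuples()]
    out["improvement_match"] = np.isclose(
        out["computed_improvement"], out["printed_improvement"], atol=1e-9)
    computed_d = []
    for row in ref.itertuples():
        if pd.isna(row.t_value):
            computed_d.append(np.nan)
        else:
            computed_d.append(round(cohens_d_from_t(row.t_value, int(row.n)), 2))
    out["computed_d"] = computed_d
    out["d_match"] = [
        (pd.isna(c) and pd.isna(p)) or (not pd.isna(c) and np.isclose(c, p))
        for c, p in zip(out["computed_d"], out["printed_d"])]
    return out


def subscale_check(reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Signed percent changes of workload subscales from printed means."""
    ref = reference if reference is not None else load_reference_subscales()
    out = ref.copy()
    computed = []
    for row in ref.itertuples():
        # signed change: negative = reduction relative to baseline
        change = percent_change(row.baseline_mean, row.treatment_mean,
                                "higher", ndigits=1)
        computed.append(change)
    out["computed_change"] = computed
    out["match"] = np.isclose(out["computed_change"], out["printed_change"], atol=1e-9)
    return out


def write_report(table: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")
    txt = path.with_suffix(".txt")
    txt.write_text(table.to_string(index=False) + "\n")


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
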