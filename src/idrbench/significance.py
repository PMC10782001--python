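"""Resampling-based significance testing between predictors.

Robustness of a difference between two methods is assessed over 20
resampled protein subsets rather than a single dataset-level value:

* ``disjoint_5pct`` — the protein ids are shuffled once and sliced into
  20 disjoint subsets of ~5% each (used for residue-level and content
  comparisons);
* ``sampled_20pct`` — 20 subsets of 20% of the proteins, each drawn
  independently without replacement (used for the fully-disordered
  evaluation, whose positive class is small; 20 subsets of 20% cannot be
  disjoint, so small overlaps are accepted).

The metric is recomputed on each subset, giving paired 20-value series
per method.  The paired differences are gated through an
Anderson-Darling normality test at p = 0.05: a paired t-test when
normality is not rejected, a two-sided Wilcoxon signed-rank test
otherwise.  Verdicts are reported as '+' / '-' / '=' at alpha = 0.05 with
no multiple-testing correction (each comparison is tested at its own
nominal level).
"""

from __future__ import annotations

import math
from typing import Callable, Dict, Iterable, List, Sequence

import numpy as np
from scipy import stats

from .errors import ParameterError, UndefinedMetricError
from .types import SubsetPlan, Verdict

ALPHA = 0.05

#: Metrics where smaller values are better (verdict orientation).
LOWER_IS_BETTER = {"mae"}


def make_subsets(ids: Sequence[str], mode: str, seed: int) -> SubsetPlan:
    """Build the 20-subset resampling plan; deterministic under a seed."""
    ids = list(ids)
    n = len(ids)
    rng = np.random.default_rng(seed)
    if mode == "disjoint_5pct":
        if n < 20:
            raise ParameterError(f"disjoint mode needs >= 20 proteins, got {n}")
        order = rng.permutation(n)
        base, rem = divmod(n, 20)
        subsets = []
        offset = 0
        for k in range(20):
            size = base + (1 if k < rem else 0)
            subsets.append([ids[i] for i in order[offset:offset + size]])
            offset += size
    elif mode == "sampled_20pct":
        size = math.ceil(0.2 * n)
        if size < 1:
            raise ParameterError("empty subsets")
        subsets = [
            [ids[i] for i in rng.choice(n, size=size, replace=False)]
            for _ in range(20)
        ]
    else:
        raise ParameterError(f"unknown subset mode {mode!r}")
    return SubsetPlan(mode=mode, subsets=subsets, seed=seed)


def subset_metric_series(plan: SubsetPlan,
                         evaluator: Callable[[List[str]], float]) -> np.ndarray:
    """Evaluate a metric on each subset; degenerate subsets become NaN.

    ``evaluator`` receives a list of protein ids and returns the metric on
    those proteins pooled; it raises :class:`UndefinedMetricError` when
    the subset is degenerate (e.g. single-class for AUC).  Raises when
    every subset is degenerate.
    """
    values = np.full(len(plan.subsets), np.nan)
    for k, subset in enumerate(plan.subsets):
        try:
            values[k] = evaluator(subset)
        except UndefinedMetricError:
            continue
    if np.isnan(values).all():
        raise UndefinedMetricError("metric undefined on every subset")
    return values


def _differences_normal(diffs: np.ndarray) -> bool:
    """Anderson-Darling gate at the 5% level on the paired differences."""
    if np.ptp(diffs) == 0:
        return True  # constant differences: handled by the caller
    try:
        result = stats.anderson(diffs, dist="norm", method="interpolate")
        return bool(result.pvalue >= ALPHA)
    except TypeError:  # older scipy: compare against tabulated critical values
        result = stats.anderson(diffs, dist="norm")
        idx = int(np.where(np.isclose(result.significance_level, 5.0))[0][0])
        return bool(result.statistic < result.critical_values[idx])


def paired_verdict(series_a: Sequence[float], series_b: Sequence[float],
                   method_a: str = "A", method_b: str = "B",
                   alpha: float = ALPHA,
                   higher_is_better: bool = True) -> Verdict:
    """Compare two paired metric series and return a '+'/'-'/'=' verdict.

    Subset pairs where either value is NaN are dropped.  All-zero
    differences yield '=' with p = 1 by convention; constant nonzero
    differences fall through to the Wilcoxon branch (the t statistic is
    undefined at zero variance).
    """
    a = np.asarray(series_a, dtype=np.float64)
    b = np.asarray(series_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ParameterError("paired series must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 5:
        raise ParameterError(f"need >= 5 valid pairs, got {a.size}")
    diffs = a - b
    if not diffs.any():
        return Verdict(method_a=method_a, method_b=method_b, symbol="=",
                       p_value=1.0, test_used="paired_t")
    if np.ptp(diffs) > 0 and _differences_normal(diffs):
        test_used = "paired_t"
        p_value = float(stats.ttest_rel(a, b).pvalue)
    else:
        test_used = "wilcoxon"
        p_value = float(stats.wilcoxon(a, b).pvalue)
    if p_value < alpha:
        a_is_better = (np.mean(diffs) > 0) == higher_is_better
        symbol = "+" if a_is_better else "-"
    else:
        symbol = "="
    return Verdict(method_a=method_a, method_b=method_b, symbol=symbol,
                   p_value=p_value, test_used=test_used)


def verdict_row(verdicts: Iterable[Verdict]) -> str:
    """Render verdict symbols in the 'x|y|z' cell notation."""
    return "|".join(v.symbol for v in verdicts)


def compare_methods(plan: SubsetPlan,
                    evaluators: Dict[str, Callable[[List[str]], float]],
                    reference_methods: Sequence[str],
                    metric: str = "") -> Dict[str, Dict[str, Verdict]]:
    """Verdicts of each reference method against every other method.

    Returns ``{method: {reference: Verdict}}`` where each verdict is taken
    from the reference method's perspective ('+' means the reference is
    significantly better than the method).
    """
    series = {}
    for m, ev in evaluators.items():
        try:
            series[m] = subset_metric_series(plan, ev)
        except UndefinedMetricError:
            continue  # metric undefined on every subset for this method
    higher = metric not in LOWER_IS_BETTER
    out: Dict[str, Dict[str, Verdict]] = {}
    for method in evaluators:
        out[method] = {}
        for ref in reference_methods:
            if ref == method or ref not in series or method not in series:
                continue
            try:
                out[method][ref] = paired_verdict(
                    series[ref], series[method],
                    method_a=ref, method_b=method,
                    higher_is_better=higher,
                )
            except ParameterError:
                # too few jointly-defined subsets: comparison not testable
                continue
    return out
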