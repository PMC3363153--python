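"""Model comparison with Pearson correlations and Fisher-z intervals.

Predictions are compared pairwise and against reference values separately
on the training (known-phenotype) and validation (masked-phenotype)
individuals. Confidence intervals use the Fisher z transform:
tanh(atanh(r) +/- z_{1-alpha/2} / sqrt(n - 3)); two-sided p-values come
from t = r sqrt((n-2)/(1-r^2)) on n - 2 degrees of freedom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CorrelationResult
from .errors import ValidationError


def fisher_interval(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation from (r, n) alone."""
    if not -1.0 < r < 1.0:
        raise ValidationError(f"r must lie strictly inside (-1, 1), got {r}")
    if n < 4:
        raise ValidationError(f"need n >= 4, got {n}")
    z = np.arctanh(r)
    half = stats.norm.ppf(1.0 - alpha / 2.0) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def pearson_with_ci(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05, label: str = ""
) -> CorrelationResult:
    """Sample Pearson correlation with Fisher-z CI and t-test p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("need two equal-length 1-D vectors")
    n = x.size
    if n < 4:
        raise ValidationError(f"need at least 4 pairs for a correlation CI, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")

    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:  # degenerate: perfectly collinear
        return CorrelationResult(label=label, r=r, n=n, ci_low=r, ci_high=r, p_value=0.0, alpha=alpha)

    ci_low, ci_high = fisher_interval(r, n, alpha)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(label=label, r=r, n=n, ci_low=ci_low, ci_high=ci_high, p_value=p, alpha=alpha)


def correlation_table(
    predictions: dict[str, np.ndarray],
    reference: np.ndarray | None,
    known_mask: np.ndarray,
    alpha: float = 0.05,
    reference_label: str = "true",
) -> pd.DataFrame:
    """All pairwise correlations among reference and model predictions.

    Computed separately on the known-phenotype and masked (validation)
    individuals. Returns a long-form frame with one row per
    (mask, series_a, series_b) pair, a <= b in column order, including the
    diagonal (r = 1 by definition).
    """
    series: dict[str, np.ndarray] = {}
    if reference is not None:
        series[reference_label] = np.asarray(reference, dtype=np.float64)
    for name, values in predictions.items():
        series[name] = np.asarray(values, dtype=np.float64)
    labels = list(series)

    known_mask = np.asarray(known_mask, dtype=bool)
    masks = {"known": known_mask, "unknown": ~known_mask}
    rows = []
    for mask_name, mask in masks.items():
        if mask.sum() < 4:
            continue
        for i, a in enumerate(labels):
            for b in labels[i:]:
                if a == b:
                    res = CorrelationResult(
                        label=f"{a}~{b}", r=1.0, n=int(mask.sum()),
                        ci_low=1.0, ci_high=1.0, p_value=0.0, alpha=alpha,
                    )
                else:
                    res = pearson_with_ci(
                        series[a][mask], series[b][mask], alpha=alpha, label=f"{a}~{b}"
                    )
                rows.append(
                    {
                        "mask": mask_name,
                        "a": a,
                        "b": b,
                        "r": res.r,
                        "n": res.n,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "p_value": res.p_value,
                        "significant": res.significant,
                    }
                )
    return pd.DataFrame(rows)


def format_correlation_matrix(table: pd.DataFrame, labels: list[str]) -> pd.DataFrame:
    """Square display matrix: lower triangle = known set, upper = validation.

    Cells read "r(lo, hi)"; the diagonal is 1. Pairs missing from ``table``
    (e.g. a model that was not run) are shown as "absent".
    """
    def lookup(mask: str, a: str, b: str) -> str:
        x, y = (a, b) if labels.index(a) <= labels.index(b) else (b, a)
        hit = table[(table["mask"] == mask) & (table["a"] == x) & (table["b"] == y)]
        if hit.empty:
            return "absent"
        row = hit.iloc[0]
        return f"{row['r']:.4f}({row['ci_low']:.4f}, {row['ci_high']:.4f})"

    out = pd.DataFrame(index=labels, columns=labels, dtype=object)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i == j:
                out.loc[a, b] = "1"
            elif i > j:  # lower triangle: known-phenotype individuals
                out.loc[a, b] = lookup("known", a, b)
            else:  # upper triangle: validation individuals
                out.loc[a, b] = lookup("unknown", a, b)
    return out
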