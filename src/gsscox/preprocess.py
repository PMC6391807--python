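"""Expression-matrix filtering and predictor standardization.

The gene filter applies three rules in order to a samples x genes matrix of
nonnegative expression values:

1. low expression: drop genes whose expression (by default the per-gene
   maximum across samples; configurable to the mean) is below a threshold
   (default 10);
2. zero inflation: drop genes with more than a given fraction of zero
   values (default 30%);
3. low variability: among the remaining genes, keep those whose coefficient
   of variation (sd/mean, sample sd) exceeds the given quantile (default
   the 20% quantile) of the remaining genes' CVs.

Attrition at each step is recorded so a pipeline can report it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FilterSpec", "filter_genes", "standardize"]


@dataclass(frozen=True)
class FilterSpec:
    min_expression: float = 10.0
    max_zero_fraction: float = 0.30
    cv_quantile: float = 0.20
    expression_summary: str = "max"     # per-gene summary for rule 1

    def __post_init__(self) -> None:
        if not (0 <= self.max_zero_fraction <= 1) or not (0 <= self.cv_quantile <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.expression_summary not in ("max", "mean"):
            raise ValueError("expression_summary must be 'max' or 'mean'")


def filter_genes(expr: pd.DataFrame, spec: FilterSpec | None = None):
    """Apply the three filtering rules; returns (filtered frame, report).

    ``expr`` is samples x genes with gene names as columns.  The report
    maps each rule to the number of genes it removed.
    """
    spec = spec or FilterSpec()
    if not isinstance(expr, pd.DataFrame):
        expr = pd.DataFrame(np.asarray(expr, dtype=float))
    vals = expr.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("expression values must be nonnegative")
    report = {}

    summary = vals.max(axis=0) if spec.expression_summary == "max" else vals.mean(axis=0)
    keep = summary >= spec.min_expression
    report["low_expression"] = int((~keep).sum())

    zero_frac = (vals == 0).mean(axis=0)
    drop = (zero_frac > spec.max_zero_fraction) & keep
    report["zero_fraction"] = int(drop.sum())
    keep &= ~drop

    sub = vals[:, keep]
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sub.std(axis=0, ddof=1) / sub.mean(axis=0)
    cv = np.nan_to_num(cv, nan=0.0, posinf=np.inf)
    if spec.cv_quantile > 0 and cv.size:
        cut = np.quantile(cv, spec.cv_quantile)
        keep_cv = cv > cut
    else:
        keep_cv = np.ones(cv.size, dtype=bool)
    report["low_cv"] = int((~keep_cv).sum())

    cols = np.asarray(expr.columns)[keep][keep_cv]
    out = expr.loc[:, cols]
    if out.shape[1] == 0:
        raise ValueError(f"no genes survive filtering; per-rule attrition: {report}")
    report["retained"] = out.shape[1]
    return out, report


def standardize(X):
    """Column-standardize to mean 0, sd 1 (sample sd, n - 1 denominator).

    Returns ``(X_std, means, sds)`` so coefficients can be mapped back to
    the raw scale.  Errors on constant columns, naming the first offender.
    """
    if isinstance(X, pd.DataFrame):
        Z, mu, sd = standardize(X.to_numpy(dtype=float))
        return pd.DataFrame(Z, index=X.index, columns=X.columns), mu, sd
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"column {bad} is constant; remove it before standardizing")
    return (X - mu) / sd, mu, sd
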