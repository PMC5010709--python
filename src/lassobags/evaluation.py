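"""Prediction and estimation metrics for one replicate.

* PMSE — mean squared prediction error on held-out data (D3);
* PRPMSE — 100 x PMSE(substituted model) / PMSE(baseline model); values
  below 100 mean the substitution improved prediction;
* a paired bootstrap percentile CI for the PMSE ratio, and the
  "favorable substitution" flag (interval contains 1 or lies below it);
* MISE — integrated squared error of the fitted regression function
  under the covariate law, (bhat - b)' Sigma (bhat - b), computable in
  simulation mode where the generating coefficients are known;
* selection composition — how many (and what fraction of) final-model
  variables the expert flagged as biologically relevant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import Dataset, RelevanceMap
from .penalized import FinalModel, predict

__all__ = [
    "EvalReport",
    "pmse",
    "prpmse",
    "bootstrap_ratio_ci",
    "mise",
    "coefficient_sse",
    "selection_composition",
]

log = logging.getLogger(__name__)


@dataclass
class EvalReport:
    """All metrics for one (baseline model, substituted model) pair on one
    replicate.  ``ci`` is on the raw-ratio scale (1.0 = parity)."""

    method: str
    pmse_base: float
    pmse_sub: float
    prpmse_pct: float
    ci: tuple[float, float] | None
    favorable: bool | None
    mise_base: float | None
    mise_sub: float | None
    n_selected: int
    n_relevant_selected: int
    pct_relevant: float

    def __post_init__(self) -> None:
        if self.ci is not None and self.ci[0] > self.ci[1]:
            raise ValueError("CI lower bound exceeds upper bound")


def pmse(model: FinalModel, data: Dataset) -> float:
    """Mean squared prediction error of the model on the given data."""
    if data.n == 0:
        raise ValueError("empty evaluation data")
    resid = data.y - predict(model, data)
    return float(np.mean(resid**2))


def prpmse(sub: FinalModel, base: FinalModel, data: Dataset) -> float:
    """100 x PMSE(sub) / PMSE(base) on the same validation data."""
    denom = pmse(base, data)
    if denom == 0:
        raise ZeroDivisionError("baseline model has zero PMSE")
    return 100.0 * pmse(sub, data) / denom


def bootstrap_ratio_ci(
    sub: FinalModel,
    base: FinalModel,
    data: Dataset,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[tuple[float, float], bool]:
    """Paired bootstrap percentile interval for the PMSE ratio.

    Rows of the validation data are resampled with replacement; both
    models are evaluated on the same resample so the interval reflects
    the ratio, not independent noise in each PMSE.  Degenerate resamples
    (zero baseline PMSE) are redrawn.  Returns the interval on the raw
    ratio scale and the favorable flag: lower bound <= 1.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    se_sub = (data.y - predict(sub, data)) ** 2
    se_base = (data.y - predict(base, data)) ** 2
    rng = np.random.default_rng(seed)
    n = data.n
    idx = rng.integers(0, n, size=(B, n))
    num = se_sub[idx].mean(axis=1)
    den = se_base[idx].mean(axis=1)
    bad = den == 0
    guard = 0
    while bad.any():
        guard += 1
        if guard > 100:
            raise RuntimeError("could not draw non-degenerate bootstrap resamples")
        log.info("redrawing %d degenerate bootstrap resamples", int(bad.sum()))
        redo = rng.integers(0, n, size=(int(bad.sum()), n))
        num[bad] = se_sub[redo].mean(axis=1)
        den[bad] = se_base[redo].mean(axis=1)
        bad = den == 0
    ratios = num / den
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(ratios, [alpha, 100.0 - alpha])
    return (float(lo), float(hi)), bool(lo <= 1.0)


def _embed(model: FinalModel, var_ids: list[str]) -> np.ndarray:
    pos = {v: i for i, v in enumerate(var_ids)}
    full = np.zeros(len(var_ids))
    for v, c in zip(model.variables, model.coefficients):
        if v not in pos:
            raise ValueError(f"model variable {v!r} not among var_ids")
        full[pos[v]] = c
    return full


def mise(
    model: FinalModel,
    true_beta: np.ndarray,
    cov: np.ndarray,
    var_ids: list[str],
) -> float:
    """Integrated squared error of the fitted regression function under
    the covariate distribution: (bhat - b)' Sigma (bhat - b), with the
    model coefficients embedded in P-space (zeros elsewhere).  With an
    identity covariance this is the coefficient sum of squared errors.
    """
    true_beta = np.asarray(true_beta, dtype=float)
    if true_beta.shape[0] != len(var_ids) or cov.shape != (len(var_ids), len(var_ids)):
        raise ValueError("dimension mismatch between beta, covariance and var_ids")
    diff = _embed(model, var_ids) - true_beta
    return float(diff @ cov @ diff)


def coefficient_sse(model: FinalModel, true_beta: np.ndarray, var_ids: list[str]) -> float:
    """Plain sum of squared coefficient errors (MISE under independence);
    reported alongside MISE for transparency."""
    diff = _embed(model, var_ids) - np.asarray(true_beta, dtype=float)
    return float(diff @ diff)


def selection_composition(
    variables: list[str], relevance: RelevanceMap
) -> tuple[int, int, float]:
    """(count, relevant count, relevant percentage) of a variable list.

    The percentage of an empty list is NaN (no composition to speak of).
    """
    missing = relevance.missing_from(variables)
    if missing:
        raise ValueError(f"relevance label missing for {missing[0]!r}")
    n_sel = len(variables)
    n_rel = sum(1 for v in variables if relevance[v])
    pct = 100.0 * n_rel / n_sel if n_sel else float("nan")
    return n_sel, n_rel, pct
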