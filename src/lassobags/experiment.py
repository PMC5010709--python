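"""Replicate-level and study-level orchestration of the full pipeline.

One replicate: simulate a dataset, split it D1/D2/D3, select variables
on D1 by (adaptive) lasso with cross-validated penalty, build bags on
D1, label the shortlist with the oracle relevance map, apply the
substitution rules, refit both the baseline and the substituted variable
sets by OLS on D2, and score everything on D3.

A study aggregates many replicates into a summary table (means and
standard deviations of selection composition, PMSE, PRPMSE, the
favorable-substitution rate and MISE, per method), and a sensitivity
sweep repeats the study over a grid of bag sizes q and correlation
thresholds with identical replicate seeds in every cell, so differences
between cells are attributable to the parameter alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .bags import (RULE_B1, RULE_B2, RULE_B3, bag_correlation_threshold,
                   bag_correlation_topq, bag_mse_topq)
from .containers import Dataset, RelevanceMap
from .evaluation import (EvalReport, bootstrap_ratio_ci, mise, pmse,
                         selection_composition)
from .penalized import (SelectionResult, fit_adaptive_lasso_cv, fit_lasso_cv,
                        initial_weights, refit_ols)
from .substitution import apply_substitutions
from .synthetic import SimConfig, build_covariance, simulate_dataset, split_three_way

__all__ = [
    "ExperimentConfig",
    "SummaryTable",
    "ExperimentError",
    "run_replicate",
    "run_experiment",
    "sensitivity_sweep",
]

log = logging.getLogger(__name__)

BASELINE = "baseline"

_METRIC_ROWS = [
    "avg_n_selected",
    "avg_n_relevant",
    "avg_pct_relevant",
    "sd_pct_relevant",
    "avg_pmse",
    "avg_prpmse",
    "sd_prpmse",
    "favorable_pct",
    "sd_favorable",
    "avg_mise",
]


class ExperimentError(RuntimeError):
    """Raised when too many replicates fail for the summary to be valid."""


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce a simulation study."""

    sim: SimConfig = field(default_factory=SimConfig)
    stage1_method: str = "adaptive_lasso"
    weight_scheme: str = "lasso_init"
    bag_rules: tuple[str, ...] = (RULE_B1, RULE_B2, RULE_B3)
    q: int = 20
    threshold: float = 0.25
    k_folds: int = 5
    n_runs: int = 100
    bootstrap_B: int = 1000
    m: int | None = None
    standardize: str = "per_portion"
    ranking: str = "signed"
    master_seed: int = 0
    max_failure_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.stage1_method not in ("lasso", "adaptive_lasso"):
            raise ValueError("stage1_method must be 'lasso' or 'adaptive_lasso'")
        unknown = set(self.bag_rules) - {RULE_B1, RULE_B2, RULE_B3}
        if unknown:
            raise ValueError(f"unknown bag rules: {sorted(unknown)}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


def _sub_seeds(replicate_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds from one replicate seed (kept below
    2**31 so they are portable as plain ints)."""
    state = np.random.SeedSequence(replicate_seed).generate_state(4)
    names = ("generate", "split", "cv", "bootstrap")
    return {k: int(s) & 0x7FFFFFFF for k, s in zip(names, state)}


def _build_bags(rule: str, sel: SelectionResult, d1: Dataset, config: ExperimentConfig):
    if rule == RULE_B1:
        return bag_correlation_topq(sel, d1, config.q, config.ranking)
    if rule == RULE_B2:
        return bag_correlation_threshold(sel, d1, config.threshold, config.ranking)
    if rule == RULE_B3:
        return bag_mse_topq(sel, d1, config.q)
    raise ValueError(rule)


def stage1_select(d1: Dataset, config: ExperimentConfig, seed: int) -> SelectionResult:
    if config.stage1_method == "adaptive_lasso":
        w = initial_weights(d1, config.weight_scheme, k=config.k_folds, seed=seed)
        return fit_adaptive_lasso_cv(d1, config.k_folds, w, seed)
    return fit_lasso_cv(d1, config.k_folds, seed)


def run_replicate(
    config: ExperimentConfig,
    replicate_seed: int,
    cov: np.ndarray | None = None,
) -> dict[str, EvalReport]:
    """Execute the full pipeline once; returns one report per method
    (the stage-1 baseline plus each configured bag rule)."""
    seeds = _sub_seeds(replicate_seed)
    sim_cfg = config.sim.replicate(seeds["generate"])
    data, true_beta, relevance = simulate_dataset(sim_cfg)
    split = split_three_way(data, config.m, seeds["split"], config.standardize)

    sel = stage1_select(split.d1, config, seeds["cv"])
    base_model = refit_ols(sel.selected, split.d2, "d2")
    if cov is None:
        cov = build_covariance(sim_cfg)
    base_pmse = pmse(base_model, split.d3)
    base_mise = mise(base_model, true_beta, cov, data.var_ids)
    n_sel, n_rel, pct = selection_composition(sel.selected, relevance)

    reports = {
        BASELINE: EvalReport(
            method=config.stage1_method,
            pmse_base=base_pmse,
            pmse_sub=base_pmse,
            prpmse_pct=100.0,
            ci=None,
            favorable=None,
            mise_base=base_mise,
            mise_sub=base_mise,
            n_selected=n_sel,
            n_relevant_selected=n_rel,
            pct_relevant=pct,
        )
    }
    for ri, rule in enumerate(config.bag_rules):
        bags = _build_bags(rule, sel, split.d1, config)
        subres = apply_substitutions(sel, bags, relevance)
        model = refit_ols(subres.final_variables, split.d2, "d2")
        sub_pmse = pmse(model, split.d3)
        ci, favorable = bootstrap_ratio_ci(
            model, base_model, split.d3,
            B=config.bootstrap_B, seed=seeds["bootstrap"] + ri,
        )
        s_sel, s_rel, s_pct = selection_composition(subres.final_variables, relevance)
        reports[rule] = EvalReport(
            method=rule,
            pmse_base=base_pmse,
            pmse_sub=sub_pmse,
            prpmse_pct=100.0 * sub_pmse / base_pmse,
            ci=ci,
            favorable=favorable,
            mise_base=base_mise,
            mise_sub=mise(model, true_beta, cov, data.var_ids),
            n_selected=s_sel,
            n_relevant_selected=s_rel,
            pct_relevant=s_pct,
        )
    return reports


@dataclass
class SummaryTable:
    """Aggregate of a study: one column per method, one row per metric,
    plus the per-replicate records behind it."""

    summary: pd.DataFrame
    replicates: pd.DataFrame
    config: ExperimentConfig
    failures: list[tuple[int, str]] = field(default_factory=list)

    def value(self, metric: str, method: str) -> float:
        return float(self.summary.loc[metric, method])


def _replicate_rows(i: int, reports: dict[str, EvalReport]) -> list[dict]:
    rows = []
    for method, r in reports.items():
        rows.append(
            {
                "replicate": i,
                "method": method,
                "n_selected": r.n_selected,
                "n_relevant": r.n_relevant_selected,
                "pct_relevant": r.pct_relevant,
                "pmse": r.pmse_sub,
                "prpmse": r.prpmse_pct,
                "favorable": r.favorable,
                "ci_lo": None if r.ci is None else r.ci[0],
                "ci_hi": None if r.ci is None else r.ci[1],
                "mise": r.mise_sub,
            }
        )
    return rows


def _aggregate(rep_df: pd.DataFrame, methods: Sequence[str]) -> pd.DataFrame:
    out = pd.DataFrame(index=_METRIC_ROWS, columns=list(methods), dtype=float)
    for method in methods:
        g = rep_df[rep_df["method"] == method]
        fav = g["favorable"].astype(float) * 100.0 if g["favorable"].notna().any() else None
        out.loc["avg_n_selected", method] = g["n_selected"].mean()
        out.loc["avg_n_relevant", method] = g["n_relevant"].mean()
        out.loc["avg_pct_relevant", method] = np.nanmean(g["pct_relevant"])
        out.loc["sd_pct_relevant", method] = np.nanstd(g["pct_relevant"], ddof=1) if len(g) > 1 else np.nan
        out.loc["avg_pmse", method] = g["pmse"].mean()
        out.loc["avg_prpmse", method] = g["prpmse"].mean()
        out.loc["sd_prpmse", method] = g["prpmse"].std(ddof=1) if len(g) > 1 else np.nan
        out.loc["favorable_pct", method] = np.nan if fav is None else fav.mean()
        out.loc["sd_favorable", method] = (
            np.nan if fav is None or len(g) < 2 else fav.std(ddof=1)
        )
        out.loc["avg_mise", method] = g["mise"].mean()
    return out


def run_experiment(config: ExperimentConfig, progress: bool = False) -> SummaryTable:
    """Run ``n_runs`` independent replicates (seeds master_seed + index)
    and aggregate them.  Replicates that raise are recorded and skipped;
    more than ``max_failure_fraction`` of them failing invalidates the
    study."""
    cov = build_covariance(config.sim)
    rows: list[dict] = []
    failures: list[tuple[int, str]] = []
    for i in range(config.n_runs):
        try:
            reports = run_replicate(config, config.master_seed + i, cov)
        except Exception as exc:  # noqa: BLE001 - failure policy: log and skip
            log.warning("replicate %d failed: %s", i, exc)
            failures.append((i, str(exc)))
            continue
        rows.extend(_replicate_rows(i, reports))
        if progress and (i + 1) % 10 == 0:
            log.info("completed %d/%d replicates", i + 1, config.n_runs)
    if len(failures) > config.max_failure_fraction * config.n_runs:
        raise ExperimentError(
            f"{len(failures)}/{config.n_runs} replicates failed: {failures[:3]}"
        )
    rep_df = pd.DataFrame(rows).sort_values(["replicate", "method"]).reset_index(drop=True)
    methods = [BASELINE] + [r for r in config.bag_rules]
    return SummaryTable(_aggregate(rep_df, methods), rep_df, config, failures)


def sensitivity_sweep(
    config: ExperimentConfig,
    q_values: Sequence[int],
    thresholds: Sequence[float],
) -> dict[tuple[int, float], SummaryTable]:
    """One study per (q, threshold) grid cell, all with the same master
    seed so every cell sees identical data and stage-1 selections."""
    if not q_values or not thresholds:
        raise ValueError("q_values and thresholds must be nonempty")
    out: dict[tuple[int, float], SummaryTable] = {}
    for q in q_values:
        for thr in thresholds:
            cell = replace(config, q=int(q), threshold=float(thr))
            out[(int(q), float(thr))] = run_experiment(cell)
    return out
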