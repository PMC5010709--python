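"""Bags of substitute covariates around each stage-1 selected variable.

For every covariate j in the selected set S, a *bag* collects candidate
substitutes scored on the stage-1 data D1:

* B1 — the q covariates most correlated with j;
* B2 — every covariate whose correlation with j reaches a threshold
  (default 0.25);
* B3 — the q covariates giving the smallest residual mean squared error
  when swapped for j in the OLS of y on S.

The union of all bags and owners is the shortlist handed to the domain
expert for binary relevance labelling; it is typically far smaller than P.

Correlations are signed Pearson by default (the benchmark design has
positive block correlations); ranking by absolute value is available via
``ranking="absolute"``.  Ties are broken toward the lower variable index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import Dataset
from .penalized import SelectionResult

__all__ = [
    "Bag",
    "BagCollection",
    "bag_correlation_topq",
    "bag_correlation_threshold",
    "bag_mse_topq",
    "mse_ratio",
    "shortlist_union",
]

log = logging.getLogger(__name__)

RULE_B1 = "B1"
RULE_B2 = "B2"
RULE_B3 = "B3"


@dataclass
class Bag:
    """Candidate substitutes for one selected covariate.

    ``members`` are (variable id, score) pairs sorted best-first:
    descending correlation for B1/B2, ascending replacement MSE for B3.
    """

    owner: str
    members: list[tuple[str, float]]
    rule: str
    param: float

    def member_ids(self) -> list[str]:
        return [m for m, _ in self.members]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class BagCollection:
    """One bag per selected covariate, in S order."""

    bags: dict[str, Bag]
    rule: str
    param: float
    extras: dict = field(default_factory=dict)

    def owners(self) -> list[str]:
        return list(self.bags)

    def shortlist(self) -> list[str]:
        return shortlist_union(self)


def _corr_columns(data: Dataset, owner_idx: np.ndarray) -> np.ndarray:
    """Pearson correlations of every variable with each owner column;
    shape (P, len(owner_idx))."""
    X = data.X - data.X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = X / sd
    return Z.T @ Z[:, owner_idx] / data.n


def _rank_key(scores: np.ndarray, ranking: str) -> np.ndarray:
    if ranking == "signed":
        return -scores
    if ranking == "absolute":
        return -np.abs(scores)
    raise ValueError("ranking must be 'signed' or 'absolute'")


def bag_correlation_topq(
    S: SelectionResult, data: Dataset, q: int, ranking: str = "signed"
) -> BagCollection:
    """B1: the q most correlated covariates per selected variable."""
    if q < 0:
        raise ValueError("q must be >= 0")
    p = data.p
    if q >= p:
        warnings.warn(f"q={q} >= P={p}: capped at P-1")
        q = p - 1
    owner_idx = np.array([data.column_index(v) for v in S.selected], dtype=int)
    corr = _corr_columns(data, owner_idx) if owner_idx.size else np.empty((p, 0))
    bags: dict[str, Bag] = {}
    for col, owner in enumerate(S.selected):
        scores = corr[:, col]
        key = _rank_key(scores, ranking).copy()
        key[owner_idx[col]] = np.inf  # owner never in its own bag
        order = np.lexsort((np.arange(p), key))[:q]
        bags[owner] = Bag(owner, [(data.var_ids[j], float(scores[j])) for j in order],
                          RULE_B1, float(q))
    return BagCollection(bags, RULE_B1, float(q))


def bag_correlation_threshold(
    S: SelectionResult, data: Dataset, threshold: float = 0.25, ranking: str = "signed"
) -> BagCollection:
    """B2: every covariate whose correlation with the owner reaches the
    threshold; bag sizes vary per owner."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    p = data.p
    owner_idx = np.array([data.column_index(v) for v in S.selected], dtype=int)
    corr = _corr_columns(data, owner_idx) if owner_idx.size else np.empty((p, 0))
    bags: dict[str, Bag] = {}
    for col, owner in enumerate(S.selected):
        scores = corr[:, col]
        value = scores if ranking == "signed" else np.abs(scores)
        ok = value >= threshold
        ok[owner_idx[col]] = False
        js = np.flatnonzero(ok)
        order = js[np.lexsort((js, _rank_key(scores, ranking)[js]))]
        bags[owner] = Bag(owner, [(data.var_ids[j], float(scores[j])) for j in order],
                          RULE_B2, float(threshold))
    return BagCollection(bags, RULE_B2, float(threshold))


def _qr_basis(A: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (economic QR, rank-safe)."""
    Q, R = np.linalg.qr(A)
    diag = np.abs(np.diag(R))
    keep = diag > 1e-10 * max(1.0, diag.max(initial=0.0))
    return Q[:, keep]


def _replacement_mse(
    S_vars: list[str], owner: str, data: Dataset, candidates: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Residual MSE of the OLS of y on S with ``owner`` swapped for each
    candidate column, computed by projecting out span(1, S \\ owner).

    Returns (mse per candidate, validity mask, MSE of the unmodified S
    model).  A candidate collinear with the retained columns is marked
    invalid.
    """
    n = data.n
    others = [v for v in S_vars if v != owner]
    A = np.column_stack([np.ones(n), data.columns(others)]) if others else np.ones((n, 1))
    Q = _qr_basis(A)
    y_res = data.y - Q @ (Q.T @ data.y)
    rss_reduced = float(y_res @ y_res)

    Xc = data.X[:, candidates]
    R = Xc - Q @ (Q.T @ Xc)
    den = np.einsum("ij,ij->j", R, R)
    num = (R.T @ y_res) ** 2
    valid = den > 1e-10 * n
    rss = np.where(valid, rss_reduced - np.divide(num, den, out=np.zeros_like(num),
                                                  where=valid), np.inf)
    mse = np.clip(rss, 0.0, None) / n

    x_own = data.X[:, data.column_index(owner)]
    r_own = x_own - Q @ (Q.T @ x_own)
    d_own = float(r_own @ r_own)
    rss_own = rss_reduced - (float(r_own @ y_res) ** 2 / d_own if d_own > 1e-10 * n else 0.0)
    return mse, valid, max(rss_own, 0.0) / n


def bag_mse_topq(S: SelectionResult, data: Dataset, q: int) -> BagCollection:
    """B3: the q candidates with smallest replacement-OLS MSE per owner.

    Candidates are the non-selected covariates (a covariate already in S
    cannot stand in for another).  The unmodified-model MSE is stored in
    ``extras["base_mse"]`` so MSE ratios can be reproduced from the
    collection alone.
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    if len(S.selected) >= data.n:
        raise ValueError("|S| must be smaller than the number of rows for OLS")
    sel_set = set(S.selected)
    candidates = np.array([j for j, v in enumerate(data.var_ids) if v not in sel_set],
                          dtype=int)
    if q > candidates.size:
        warnings.warn(f"q={q} exceeds candidate pool ({candidates.size}): capped")
        q = candidates.size
    bags: dict[str, Bag] = {}
    base_mse: dict[str, float] = {}
    for owner in S.selected:
        mse, valid, own_mse = _replacement_mse(S.selected, owner, data, candidates)
        if not valid.all():
            skipped = [data.var_ids[candidates[j]] for j in np.flatnonzero(~valid)]
            log.info("owner %s: skipped rank-deficient candidates %s", owner, skipped[:5])
        order = np.lexsort((candidates, mse))[:q]
        bags[owner] = Bag(owner,
                          [(data.var_ids[candidates[j]], float(mse[j])) for j in order
                           if valid[j]],
                          RULE_B3, float(q))
        base_mse[owner] = own_mse
    return BagCollection(bags, RULE_B3, float(q), extras={"base_mse": base_mse})


def mse_ratio(bag_member: str, owner: str, S: SelectionResult, data: Dataset) -> float:
    """Replacement MSE over the MSE of the unmodified S model.

    A ratio below one means the substitute improves the stage-1 fit —
    particularly appealing candidates.
    """
    if owner not in S.selected:
        raise ValueError(f"{owner!r} is not in the selected set")
    if bag_member == owner:
        return 1.0
    cand = np.array([data.column_index(bag_member)])
    mse, valid, _ = _replacement_mse(S.selected, owner, data, cand)
    if not valid[0]:
        raise ValueError(f"candidate {bag_member!r} collinear with retained columns")
    full = np.column_stack([np.ones(data.n), data.columns(S.selected)])
    Q = _qr_basis(full)
    y_res = data.y - Q @ (Q.T @ data.y)
    base = float(y_res @ y_res) / data.n
    if base <= 0:
        raise ZeroDivisionError("original model has zero residual MSE")
    return float(mse[0]) / base


def shortlist_union(bags: BagCollection) -> list[str]:
    """Deduplicated union of owners and bag members: owners first (in S
    order), then members by first appearance.  This is the elicitation
    worksheet content."""
    seen: set[str] = set()
    out: list[str] = []
    for owner in bags.bags:
        if owner not in seen:
            seen.add(owner)
            out.append(owner)
    for bag in bags.bags.values():
        for member, _ in bag.members:
            if member not in seen:
                seen.add(member)
                out.append(member)
    return out
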