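"""Plain-text serialization: TSV datasets, CSV relevance labels and
elicitation worksheets, YAML configs, JSON results."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bags import Bag, BagCollection
from .containers import Dataset, RelevanceMap
from .penalized import FinalModel, SelectionResult
from .substitution import SubstitutionResult
from .synthetic import Block, SimConfig

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_relevance",
    "read_relevance",
    "write_sim_config",
    "read_sim_config",
    "write_selection",
    "read_selection",
    "write_final_model",
    "read_final_model",
    "write_worksheet",
    "read_worksheet",
    "write_substitution",
]


def write_dataset(data: Dataset, x_path: str | Path, y_path: str | Path) -> None:
    """Covariates as TSV (first column ``sample``, header of variable
    ids); response as a one-column file."""
    df = pd.DataFrame(data.X, columns=data.var_ids)
    df.insert(0, "sample", [f"s{i + 1}" for i in range(data.n)])
    df.to_csv(x_path, sep="\t", index=False)
    pd.DataFrame({"y": data.y}).to_csv(y_path, index=False)


def read_dataset(x_path: str | Path, y_path: str | Path) -> Dataset:
    df = pd.read_csv(x_path, sep="\t")
    var_ids = [c for c in df.columns if c != "sample"]
    y = pd.read_csv(y_path)["y"].to_numpy(dtype=float)
    return Dataset(df[var_ids].to_numpy(dtype=float), y, var_ids)


def write_relevance(relevance: RelevanceMap, path: str | Path) -> None:
    pd.DataFrame(
        {"variable_id": list(relevance.labels),
         "relevant": [int(v) for v in relevance.labels.values()]}
    ).to_csv(path, index=False)


def read_relevance(path: str | Path) -> RelevanceMap:
    df = pd.read_csv(path)
    return RelevanceMap(dict(zip(df["variable_id"].astype(str), df["relevant"].astype(int))))


def write_sim_config(config: SimConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["block_spec"] = [
        {"true_vars": list(b.true_vars), "relevant_vars": list(b.relevant_vars), "rho": b.rho}
        for b in config.block_spec
    ]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_sim_config(path: str | Path) -> SimConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["block_spec"] = [
        Block(tuple(b["true_vars"]), tuple(b["relevant_vars"]), float(b["rho"]))
        for b in d.get("block_spec", [])
    ]
    return SimConfig(**d)


def _dump_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1))


def write_selection(sel: SelectionResult, path: str | Path, seed: int | None = None) -> None:
    _dump_json(
        {
            "method": sel.method,
            "selected": sel.selected,
            "coefficients": [float(c) for c in sel.coefficients],
            "intercept": sel.intercept,
            "lambda": sel.lambda_,
            "weights": {v: (None if not np.isfinite(w) else float(w))
                        for v, w in zip(sel.var_ids, sel.weights)},
            "seed": seed,
        },
        path,
    )


def read_selection(path: str | Path) -> SelectionResult:
    d = json.loads(Path(path).read_text())
    var_ids = list(d["weights"])
    weights = np.array([np.inf if w is None else w for w in d["weights"].values()])
    return SelectionResult(
        selected=d["selected"],
        coefficients=np.asarray(d["coefficients"], dtype=float),
        intercept=float(d["intercept"]),
        lambda_=float(d["lambda"]),
        weights=weights,
        method=d["method"],
        var_ids=var_ids,
    )


def write_final_model(model: FinalModel, path: str | Path) -> None:
    _dump_json(
        {
            "variables": model.variables,
            "coefficients": [float(c) for c in model.coefficients],
            "intercept": model.intercept,
            "fit_portion": model.fit_portion,
            "dropped": model.dropped,
        },
        path,
    )


def read_final_model(path: str | Path) -> FinalModel:
    d = json.loads(Path(path).read_text())
    return FinalModel(
        d["variables"], np.asarray(d["coefficients"], dtype=float),
        float(d["intercept"]), d.get("fit_portion", ""), d.get("dropped", []),
    )


def write_worksheet(bags: BagCollection, path: str | Path) -> None:
    """Elicitation worksheet: one row per (owner, candidate) with the bag
    score, plus one rank-0 row per owner itself.  The ``relevant`` column
    is left blank for the expert to fill with 0/1."""
    rows = []
    for owner, bag in bags.bags.items():
        rows.append({"owner": owner, "rule": bag.rule, "rank": 0,
                     "candidate": owner, "score": "", "relevant": ""})
        for rank, (member, score) in enumerate(bag.members, start=1):
            rows.append({"owner": owner, "rule": bag.rule, "rank": rank,
                         "candidate": member, "score": score, "relevant": ""})
    pd.DataFrame(rows, columns=["owner", "rule", "rank", "candidate", "score", "relevant"]
                 ).to_csv(path, index=False)


def read_worksheet(path: str | Path) -> RelevanceMap:
    """Read back a completed worksheet; any blank ``relevant`` cell is an
    incomplete elicitation and aborts with the offending candidate."""
    df = pd.read_csv(path)
    labels: dict[str, bool] = {}
    for _, row in df.iterrows():
        cand = str(row["candidate"])
        val = row["relevant"]
        if pd.isna(val) or str(val).strip() == "":
            raise ValueError(f"worksheet incomplete: no relevance label for {cand!r}")
        flag = bool(int(val))
        if cand in labels and labels[cand] != flag:
            raise ValueError(f"conflicting relevance labels for {cand!r}")
        labels[cand] = flag
    return RelevanceMap(labels)


def write_substitution(result: SubstitutionResult, path: str | Path) -> None:
    _dump_json(
        {
            "final_variables": result.final_variables,
            "records": [dataclasses.asdict(r) for r in result.records],
        },
        path,
    )
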