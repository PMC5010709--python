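"""Core data containers shared across the pipeline.

A :class:`Dataset` holds a standardized covariate matrix together with a
centered response; a :class:`RelevanceMap` carries the expert's binary
biological-relevance labels; a :class:`ThreeWaySplit` is the D1/D2/D3
partition used by the two-stage selection workflow (D1: shortlisting,
D2: final fit, D3: validation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np


@dataclass
class Dataset:
    """Covariate matrix, response and variable identifiers.

    Columns of ``X`` are expected to be standardized (mean 0, unit variance)
    and ``y`` centered; :meth:`standardized` produces such a view from raw
    inputs.  No standardization is forced at construction so raw data can be
    carried through I/O unchanged.
    """

    X: np.ndarray
    y: np.ndarray
    var_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.var_ids = list(self.var_ids)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-d array")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]} entries"
            )
        if self.X.shape[1] != len(self.var_ids):
            raise ValueError(
                f"X has {self.X.shape[1]} columns but {len(self.var_ids)} ids given"
            )
        if len(set(self.var_ids)) != len(self.var_ids):
            raise ValueError("variable identifiers must be unique")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def column_index(self, var_id: str) -> int:
        try:
            return self._index[var_id]
        except AttributeError:
            self._index = {v: i for i, v in enumerate(self.var_ids)}
            return self._index[var_id]

    def columns(self, var_ids: Sequence[str]) -> np.ndarray:
        idx = [self.column_index(v) for v in var_ids]
        return self.X[:, idx]

    def standardized(self) -> "Dataset":
        """Return a copy with columns scaled to mean 0 / sample variance 1
        (``ddof=1``) and ``y`` centered.

        A constant column cannot be scaled; it is centered only and a
        warning is issued.
        """
        X = self.X - self.X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        degenerate = sd <= 0
        if degenerate.any():
            bad = [self.var_ids[i] for i in np.flatnonzero(degenerate)]
            warnings.warn(f"constant columns left unscaled: {bad[:5]}...")
            sd = np.where(degenerate, 1.0, sd)
        return Dataset(X / sd, self.y - self.y.mean(), list(self.var_ids))

    def take_rows(self, idx: np.ndarray) -> "Dataset":
        return Dataset(self.X[idx], self.y[idx], list(self.var_ids))


@dataclass
class RelevanceMap:
    """Binary expert labels: variable identifier -> biologically relevant?"""

    labels: Mapping[str, bool]

    def __post_init__(self) -> None:
        self.labels = {str(k): bool(v) for k, v in dict(self.labels).items()}

    def __getitem__(self, var_id: str) -> bool:
        return self.labels[var_id]

    def __contains__(self, var_id: str) -> bool:
        return var_id in self.labels

    def __len__(self) -> int:
        return len(self.labels)

    def relevant_ids(self) -> list[str]:
        return [v for v, flag in self.labels.items() if flag]

    def missing_from(self, var_ids: Iterable[str]) -> list[str]:
        return [v for v in var_ids if v not in self.labels]

    def restrict(self, var_ids: Iterable[str]) -> "RelevanceMap":
        return RelevanceMap({v: self.labels[v] for v in var_ids})


@dataclass
class ThreeWaySplit:
    """D1/D2/D3 partition of a dataset.

    ``index_map`` records, for each portion, the original row indices in the
    parent dataset so that a split is fully auditable and reproducible.
    """

    d1: Dataset
    d2: Dataset
    d3: Dataset
    index_map: dict[str, np.ndarray] = field(default_factory=dict)

    def portions(self) -> dict[str, Dataset]:
        return {"d1": self.d1, "d2": self.d2, "d3": self.d3}
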