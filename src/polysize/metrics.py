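"""Error metrics, dataset splitting, and worst-group error decomposition.

MAPE is both the training loss and the headline metric: particle sizes span
roughly 35–850 nm, and a relative loss keeps small particles from being
drowned out by large ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ShapeError, ValidationError

__all__ = [
    "mape",
    "rmse",
    "split_dataset",
    "worst_group_analysis",
    "WorstGroupResult",
]

#: grouping keys used for the error decomposition (column → human label)
DEFAULT_GROUPING_KEYS = ("dp", "conc_gL", "additive")


def _check_pair(y_hat, y):
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_hat.shape != y.shape:
        raise ShapeError(f"shape mismatch: predictions {y_hat.shape} vs truth {y.shape}")
    if y.size < 1:
        raise ValidationError("need at least one observation")
    return y_hat, y


def mape(y_hat, y) -> float:
    """Mean absolute percentage error, in percent: 100/n · Σ |ŷ−y|/y."""
    y_hat, y = _check_pair(y_hat, y)
    if (y <= 0).any():
        raise ValidationError("MAPE requires strictly positive reference sizes")
    return float(100.0 * np.mean(np.abs(y_hat - y) / y))


def rmse(y_hat, y) -> float:
    """Root-mean-square error in the units of y (nm)."""
    y_hat, y = _check_pair(y_hat, y)
    return float(np.sqrt(np.mean((y_hat - y) ** 2)))


def split_dataset(data: pd.DataFrame, ratio: float = 0.8, seed: int = 0):
    """Reproducible random split into (train, validation).

    The training set receives ``floor(ratio · n)`` records (2813 → 2250 + 563);
    the two frames are disjoint, exhaustive and keep their original index.
    """
    n = len(data)
    if n < 5:
        raise ValidationError(f"need at least 5 records to split, got {n}")
    if not 0.0 < ratio < 1.0:
        raise ValidationError(f"ratio must be in (0, 1), got {ratio}")
    n_train = int(np.floor(ratio * n))
    if n_train == 0 or n_train == n:
        raise ValidationError(f"degenerate split: {n_train}/{n - n_train}")
    perm = np.random.default_rng(seed).permutation(n)
    return data.iloc[np.sort(perm[:n_train])], data.iloc[np.sort(perm[n_train:])]


@dataclass
class WorstGroupResult:
    """Outcome of the worst-performing-group decomposition."""

    key: str
    value: object
    n_worst: int
    mape_overall: float
    mape_worst: float
    mape_excluding: float
    table: pd.DataFrame  # per-group MAPE across all keys

    @property
    def label(self) -> str:
        return f"{self.key} = {self.value}"


def worst_group_analysis(
    y_hat, records: pd.DataFrame, keys=DEFAULT_GROUPING_KEYS
) -> WorstGroupResult | None:
    """Locate the parameter group carrying the largest share of the error.

    Records are grouped by each key's exact recorded value (groups correspond
    to discrete synthesis/formulation batches); the group with maximal MAPE
    over all keys is the "worst performing group".  Ties break toward the
    larger group, then lexicographically by label.  With fewer than two
    distinct groups under every key the analysis is skipped with a notice.
    """
    y_hat = np.asarray(y_hat, dtype=float)
    y = records["size_nm"].to_numpy(dtype=float)
    if y_hat.shape[0] != len(records):
        raise ShapeError(
            f"{y_hat.shape[0]} predictions for {len(records)} records"
        )
    rows = []
    for key in keys:
        values = records[key]
        if values.nunique() < 2:
            continue
        for val, idx in records.groupby(key, sort=True).groups.items():
            loc = records.index.get_indexer(idx)
            rows.append(
                {
                    "key": key,
                    "value": val,
                    "n": len(loc),
                    "mape": mape(y_hat[loc], y[loc]),
                }
            )
    if not rows:
        warnings.warn(
            "worst-group analysis skipped: fewer than two groups under every key",
            stacklevel=2,
        )
        return None
    table = pd.DataFrame(rows)
    order = table.sort_values(
        by=["mape", "n", "key", "value"],
        ascending=[False, False, True, True],
        key=lambda c: c.astype(str) if c.name == "value" else c,
    )
    top = order.iloc[0]
    worst_mask = (records[top["key"]] == top["value"]).to_numpy()
    overall = mape(y_hat, y)
    excluding = (
        mape(y_hat[~worst_mask], y[~worst_mask]) if (~worst_mask).any() else float("nan")
    )
    return WorstGroupResult(
        key=str(top["key"]),
        value=top["value"],
        n_worst=int(top["n"]),
        mape_overall=overall,
        mape_worst=float(top["mape"]),
        mape_excluding=excluding,
        table=table.reset_index(drop=True),
    )
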