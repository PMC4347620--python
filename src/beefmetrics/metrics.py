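"""Evaluation metrics and the repeated random split protocol.

Segmentation quality is scored against a manual reference mask by

* relative area error   e1 = |A_auto - A_manual| / A_manual
* concordance           e2 = 1 - A_inter / A_union  (1 - Jaccard overlap)

and regression quality by RMSE and the squared Pearson correlation.  The
split protocol draws repeated random 2/3-1/3 train/test partitions (optionally
grouped, e.g. per animal) and summarizes per-split metrics, including the
fraction of cases with errors under configurable thresholds.
"""

from __future__ import annotations

from collections.abc import Callable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RegressionEval",
    "relative_area_error",
    "concordance",
    "regression_eval",
    "train_test_sizes",
    "split_indices",
    "evaluate_protocol",
    "fraction_under",
]


@dataclass(frozen=True)
class RegressionEval:
    rmse: float
    r2: float


def relative_area_error(area_auto: float, area_manual: float) -> float:
    """e1 = |A_auto - A_manual| / A_manual (error magnitude, scale-invariant)."""
    if area_manual <= 0:
        raise ValueError("manual reference area must be positive")
    return abs(area_auto - area_manual) / area_manual


def concordance(mask_auto: np.ndarray, mask_manual: np.ndarray) -> float:
    """e2 = 1 - |A intersect B| / |A union B|; 0 for identical, 1 for disjoint."""
    a = np.asarray(mask_auto, dtype=bool)
    b = np.asarray(mask_manual, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("both masks are empty; concordance is undefined")
    inter = np.logical_and(a, b).sum()
    return 1.0 - inter / union


def regression_eval(pred: Sequence[float], truth: Sequence[float]) -> RegressionEval:
    """Root-mean-square error and squared Pearson correlation of paired values."""
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(truth, dtype=np.float64)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError("pred and truth must be 1-D and paired")
    if p.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.ptp(t) == 0:
        raise ValueError("truth is constant; r2 is undefined")
    rmse = float(np.sqrt(np.mean((p - t) ** 2)))
    if np.ptp(p) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(p, t)[0, 1] ** 2)
    return RegressionEval(rmse=rmse, r2=r2)


def train_test_sizes(n: int, train_fraction: float = 2.0 / 3.0) -> tuple[int, int]:
    """Sizes of the train/test partition: training strictly exceeds the fraction.

    train = floor(n * f) + 1 capped at n - 1; with n = 153 and f = 2/3 this is
    the conventional 103 / 50 split.
    """
    if n < 3:
        raise ValueError("need at least 3 items to split")
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must lie in (0, 1)")
    train = min(int(np.floor(n * train_fraction)) + 1, n - 1)
    return train, n - train


def split_indices(
    n: int,
    rng: np.random.Generator,
    train_fraction: float = 2.0 / 3.0,
    groups: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One random train/test index partition, optionally grouped.

    With ``groups`` given (length n), whole groups go to one side or the
    other and the fraction applies to the number of groups.
    """
    if groups is None:
        train_n, _ = train_test_sizes(n, train_fraction)
        perm = rng.permutation(n)
        return np.sort(perm[:train_n]), np.sort(perm[train_n:])
    groups = np.asarray(groups)
    if groups.shape[0] != n:
        raise ValueError("groups must have length n")
    uniq = np.unique(groups)
    g_train, _ = train_test_sizes(len(uniq), train_fraction)
    perm = rng.permutation(len(uniq))
    train_groups = uniq[perm[:g_train]]
    train_mask = np.isin(groups, train_groups)
    return np.flatnonzero(train_mask), np.flatnonzero(~train_mask)


def fraction_under(errors: Sequence[float], threshold: float) -> float:
    """Fraction of error values strictly below a threshold."""
    e = np.asarray(errors, dtype=np.float64)
    if e.size == 0:
        raise ValueError("no errors given")
    return float(np.mean(e < threshold))


def evaluate_protocol(
    n_items: int,
    metric_fn: Callable[[np.ndarray, np.ndarray], dict],
    split_fraction: float = 2.0 / 3.0,
    repetitions: int = 100,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> pd.DataFrame:
    """Repeated random split protocol.

    Calls ``metric_fn(train_idx, test_idx)`` for ``repetitions`` seeded random
    partitions and collects the returned metric dicts into a DataFrame (one
    row per repetition, plus train/test sizes).  Same seed, same splits.
    """
    if n_items < 3:
        raise ValueError("dataset must have at least 3 items")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(repetitions):
        tr, te = split_indices(n_items, rng, split_fraction, groups)
        row = {"repetition": rep, "n_train": len(tr), "n_test": len(te)}
        row.update(metric_fn(tr, te))
        rows.append(row)
    return pd.DataFrame(rows)
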