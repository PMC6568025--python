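"""Feature ranking by joint mutual information maximization (JMIM).

Continuous features are discretized into equal-frequency bins and mutual
information is estimated with the plug-in (maximum-likelihood) estimator in
bits.  JMIM picks the feature with maximal marginal MI first, then greedily
adds the feature whose *minimum* joint MI with any already-selected feature
and the class label is largest — a max-min criterion that rewards relevance
while penalizing redundancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SelectionResult",
    "discretize",
    "mutual_information",
    "joint_mutual_information",
    "jmim_rank",
]

DEFAULT_BINS = 4


@dataclass
class SelectionResult:
    """Greedy JMIM ranking: feature names and their selection criterion.

    The first criterion value is the marginal MI of the first-selected
    feature; subsequent values are min-over-selected joint MI (bits).
    """

    ordered_features: list[str] = field(default_factory=list)
    criterion_values: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "ordered_features": list(self.ordered_features),
            "criterion_values": [float(v) for v in self.criterion_values],
        }


def discretize(values, n_bins: int = DEFAULT_BINS) -> np.ndarray:
    """Equal-frequency bin codes in {0..n_bins-1}.

    Bin edges are the 1/n_bins .. (n_bins-1)/n_bins sample quantiles
    (linear interpolation); ties share a code and codes are monotone in
    the values.  A constant input maps to all zeros.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("values must be a non-empty 1-D sequence")
    edges = np.quantile(values, np.arange(1, n_bins) / n_bins)
    return np.searchsorted(edges, values, side="left").astype(np.int64)


def _codes(x) -> np.ndarray:
    x = np.asarray(x)
    _, inv = np.unique(x, return_inverse=True)
    return inv


def mutual_information(x, y) -> float:
    """Plug-in estimate of I(X;Y) in bits from paired discrete codes."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("x and y must be non-empty sequences of equal length")
    xi = _codes(x)
    yi = _codes(y)
    kx = xi.max() + 1
    ky = yi.max() + 1
    counts = np.zeros((kx, ky), dtype=float)
    np.add.at(counts, (xi, yi), 1.0)
    n = x.size
    pxy = counts / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    ratio = pxy[nz] / (px @ py)[nz]
    return float(np.sum(pxy[nz] * np.log2(ratio)))


def joint_mutual_information(xi, xj, y) -> float:
    """I((Xi, Xj); Y) in bits, treating the pair as one product-coded variable."""
    xi = np.asarray(xi)
    xj = np.asarray(xj)
    y = np.asarray(y)
    if not (xi.shape == xj.shape == y.shape):
        raise ValueError("xi, xj and y must have equal length")
    ci = _codes(xi)
    cj = _codes(xj)
    pair = ci * (cj.max() + 1) + cj
    return mutual_information(pair, y)


def jmim_rank(
    table: pd.DataFrame,
    label,
    k: int | None = None,
    n_bins: int = DEFAULT_BINS,
    discrete_features: tuple[str, ...] = ("doses_per_day",),
    min_criterion: float | None = None,
) -> SelectionResult:
    """Greedy JMIM ranking of the columns of ``table`` against ``label``.

    ``discrete_features`` are coded by their distinct values instead of
    binning.  Ties in the argmax are broken by column order.  ``k`` limits
    the number of selected features (default: all); ``min_criterion``
    optionally stops selection once the criterion drops below it.
    """
    label = np.asarray(label)
    classes = np.unique(label)
    if classes.size < 2:
        raise ValueError("degenerate labels")
    features = list(table.columns)
    if k is None:
        k = len(features)
    if not 1 <= k <= len(features):
        raise ValueError("k must be in [1, number of features]")
    y = _codes(label)
    coded = {
        f: (_codes(table[f].to_numpy()) if f in discrete_features
            else discretize(table[f].to_numpy(), n_bins=n_bins))
        for f in features
    }

    result = SelectionResult()
    marginal = {f: mutual_information(coded[f], y) for f in features}
    first = max(features, key=lambda f: marginal[f])  # max is stable: first wins ties
    result.ordered_features.append(first)
    result.criterion_values.append(marginal[first])

    remaining = [f for f in features if f != first]
    while remaining and len(result.ordered_features) < k:
        best_f, best_v = None, -np.inf
        for f in remaining:
            v = min(
                joint_mutual_information(coded[f], coded[s], y)
                for s in result.ordered_features
            )
            if v > best_v:
                best_f, best_v = f, v
        if min_criterion is not None and best_v < min_criterion:
            break
        result.ordered_features.append(best_f)
        result.criterion_values.append(best_v)
        remaining.remove(best_f)
    return result
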