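"""Permutation inference for network-structured data (QAP).

Field networks violate the independence assumptions of classical tests:
nest attributes are autocorrelated through the trail structure.  The
quadratic assignment procedure sidesteps this by holding the network
structure fixed and permuting the nest labels — i.e. reassigning the
per-nest attribute bundles uniformly at random over the nodes — and
recomputing the test statistic on each permutation.  Quantities that are
derived from both structure and attributes (trail strength, foraging
differential, weighted degree, ...) must be recomputed inside the
statistic after each permutation, never permuted directly; statistics
here are therefore callables that receive the permutation and do their
own recomputation.

For data pooled over several colonies, permutations are blocked: each
colony's labels are shuffled independently and no attribute ever crosses
a colony boundary.

The permutation p-value uses the add-one convention
``p = (1 + #extreme) / (1 + N)`` which is never zero and is exact under
exchangeability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .errors import DomainError, PolydomyError, UndefinedStatisticError

__all__ = [
    "QAPResult",
    "permute_node_labels",
    "blocked_permutation",
    "qap_test",
    "bonferroni",
    "correlation_statistic",
    "group_contrast_statistic",
]

_QUANTILES = (0.01, 0.05, 0.25, 0.5, 0.75, 0.95, 0.99)


@dataclass(frozen=True)
class QAPResult:
    """Outcome of one QAP permutation test."""

    statistic_name: str
    observed: float
    n_permutations: int
    p_value: float
    alternative: str  # "greater", "less" or "two-sided"
    seed: Optional[int]
    blocked: bool
    permutation_quantiles: dict[float, float] = field(default_factory=dict)
    null_values: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    n_resampled: int = 0


def _block_sizes(blocks) -> list[int]:
    sizes = []
    for b in blocks:
        if isinstance(b, (int, np.integer)):
            sizes.append(int(b))
        elif hasattr(b, "nests"):
            sizes.append(len(b.nests))
        elif hasattr(b, "nest_ids"):
            sizes.append(len(b.nest_ids))
        else:
            sizes.append(len(b))
    if any(s < 1 for s in sizes):
        raise DomainError(f"block sizes must be >= 1, got {sizes}")
    return sizes


def permute_node_labels(block, rng: np.random.Generator) -> np.ndarray:
    """A uniformly random relabelling of one colony's nests.

    Returns an index array ``perm`` such that the attribute bundle of the
    nest at position ``perm[i]`` is reassigned to position ``i``; the
    edges are untouched.  ``block`` may be a nest count or a network.
    """
    (n,) = _block_sizes([block])
    return rng.permutation(n)


def blocked_permutation(
    blocks: Sequence, rng: np.random.Generator
) -> list[np.ndarray]:
    """Independent within-colony relabellings; nothing crosses a colony."""
    return [rng.permutation(n) for n in _block_sizes(blocks)]


def _identity(sizes: list[int]) -> list[np.ndarray]:
    return [np.arange(n) for n in sizes]


def qap_test(
    statistic: Callable[[list[np.ndarray]], float],
    blocks: Sequence,
    n_permutations: int = 1000,
    alternative: str = "two-sided",
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    statistic_name: str = "statistic",
    max_resample_factor: int = 10,
) -> QAPResult:
    """Node-label permutation test of an arbitrary network statistic.

    ``statistic`` is called with a list of per-colony permutation index
    arrays (identity for the observed value) and must return a float,
    recomputing any structure-dependent derived quantities itself.  A
    permutation on which the statistic is undefined (raises
    :class:`UndefinedStatisticError` or returns NaN) is resampled, up to
    ``max_resample_factor * n_permutations`` total draws.

    ``alternative="two-sided"`` compares magnitudes (|null| >= |observed|),
    which is sign-flip invariant and appropriate for statistics centred
    at zero under the null; use ``"greater"`` for one-sided statistics
    such as F ratios.
    """
    if n_permutations < 1:
        raise DomainError("n_permutations must be >= 1")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    sizes = _block_sizes(blocks)

    observed = float(statistic(_identity(sizes)))
    if np.isnan(observed):
        raise UndefinedStatisticError(
            f"{statistic_name}: statistic undefined on observed data"
        )

    null = np.empty(n_permutations)
    draws = 0
    filled = 0
    budget = max_resample_factor * n_permutations
    while filled < n_permutations:
        if draws >= budget:
            raise PolydomyError(
                f"{statistic_name}: statistic undefined on too many "
                f"permutations ({draws - filled} of {draws} draws)"
            )
        perms = blocked_permutation(sizes, rng)
        draws += 1
        try:
            value = float(statistic(perms))
        except UndefinedStatisticError:
            continue
        if np.isnan(value):
            continue
        null[filled] = value
        filled += 1

    if alternative == "greater":
        extreme = int(np.sum(null >= observed))
    elif alternative == "less":
        extreme = int(np.sum(null <= observed))
    else:
        extreme = int(np.sum(np.abs(null) >= abs(observed)))
    p = (1 + extreme) / (1 + n_permutations)
    quantiles = {
        q: float(v) for q, v in zip(_QUANTILES, np.quantile(null, _QUANTILES))
    }
    return QAPResult(
        statistic_name=statistic_name,
        observed=observed,
        n_permutations=n_permutations,
        p_value=p,
        alternative=alternative,
        seed=seed,
        blocked=len(sizes) > 1,
        permutation_quantiles=quantiles,
        null_values=null,
        n_resampled=draws - n_permutations,
    )


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> list[float]:
    """Bonferroni-adjusted p-values: min(1, p*m) for a family of m tests."""
    p = list(p_values)
    if m is None:
        m = len(p)
    if m < len(p):
        raise DomainError(f"family size m={m} smaller than number of p-values {len(p)}")
    for v in p:
        if not 0 < v <= 1:
            raise DomainError(f"p-value outside (0, 1]: {v}")
    return [min(1.0, v * m) for v in p]


def correlation_statistic(x, y, method: str = "pearson") -> float:
    """Pearson or Spearman correlation coefficient (coefficient only).

    Wrap in :func:`qap_test` for significance.  Zero variance in either
    variable makes the coefficient undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be equal-length 1-D")
    if x.size < 3:
        raise DomainError(f"correlation needs n >= 3, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DomainError("correlation requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def group_contrast_statistic(values, groups) -> float:
    """One-way between-group F statistic (between MS / within MS).

    Wrap in :func:`qap_test` (alternative="greater") for significance.
    Zero within-group variance makes F undefined.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape or values.ndim != 1:
        raise DomainError("values and groups must be equal-length 1-D")
    labels = np.unique(groups)
    if labels.size < 2:
        raise DomainError(f"need >= 2 groups, got {labels.size}")
    samples = [values[groups == g] for g in labels]
    if any(s.size < 1 for s in samples):
        raise DomainError("every group needs at least one observation")
    if values.size - labels.size < 1:
        raise DomainError("no within-group degrees of freedom")
    grand = values.mean()
    ss_within = sum(float(((s - s.mean()) ** 2).sum()) for s in samples)
    if ss_within == 0:
        raise UndefinedStatisticError("zero within-group variance: F undefined")
    f = stats.f_oneway(*samples).statistic
    # f_oneway returns nan when a group is constant but others vary; the
    # explicit guard above catches the truly degenerate case only.
    if np.isnan(f):
        ss_between = sum(s.size * (s.mean() - grand) ** 2 for s in samples)
        df_b, df_w = labels.size - 1, values.size - labels.size
        f = (ss_between / df_b) / (ss_within / df_w)
    return float(f)
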