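"""Nonparametric statistics: Steel many-to-one test, Spearman rank correlation, CV.

The Steel test compares each of k treatment groups against a shared
control on Wilcoxon rank sums (midranks for ties) while controlling the
family-wise error through the joint distribution of the maximum
standardized statistic.  Instead of the classical equicorrelated-normal
critical values, the reference distribution here is the permutation
distribution of the maximum statistic under joint relabelling of all
groups: exact enumeration when the number of distinct arrangements is
small, seeded Monte Carlo otherwise.  This is exact at the study's small
group sizes and strictly valid under ties.

Note the intrinsic discreteness at very small samples: with four
observations per group the attainable rank statistics are few, so the
smallest attainable adjusted p-value may exceed conventional alpha levels
when several treatments are tested at once (see
``min_attainable_adjusted_p`` on the result).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupData",
    "SteelResult",
    "steel_test",
    "spearman_correlation",
    "coefficient_of_variation",
]


@dataclass(frozen=True)
class GroupData:
    """A control group and named treatment groups of measurements."""

    control: np.ndarray
    treatments: "dict[str, np.ndarray]"

    def __post_init__(self) -> None:
        control = np.asarray(self.control, dtype=float)
        if control.size < 2:
            raise ValueError("control group must contain at least 2 measurements")
        treatments = {k: np.asarray(v, dtype=float) for k, v in self.treatments.items()}
        if not treatments:
            raise ValueError("at least one treatment group is required")
        for name, values in treatments.items():
            if values.size < 1:
                raise ValueError(f"treatment {name!r} is empty")
        object.__setattr__(self, "control", control)
        object.__setattr__(self, "treatments", treatments)


@dataclass(frozen=True)
class SteelResult:
    """Per-treatment standardized rank statistics and adjusted p-values."""

    statistics: "dict[str, float]"
    p_values: "dict[str, float]"
    flags: "dict[str, str]"
    method: str  # "exact_permutation" | "monte_carlo"
    n_arrangements: int
    alternative: str
    min_attainable_adjusted_p: float

    def __post_init__(self) -> None:
        for name, p in self.p_values.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"p-value for {name!r} out of [0, 1]: {p}")


def _normalize_alternative(alternative: str) -> str:
    alt = alternative.replace("_", "-").lower()
    if alt not in ("two-sided", "less", "greater"):
        raise ValueError(f"alternative must be two_sided, less or greater, got {alternative!r}")
    return alt


def _rank_rows(a: np.ndarray, has_ties: bool) -> np.ndarray:
    if has_ties:
        return sps.rankdata(a, axis=1)
    order = np.argsort(a, axis=1, kind="stable")
    ranks = np.empty_like(order)
    put = np.arange(1, a.shape[1] + 1)
    rows = np.arange(a.shape[0])[:, None]
    ranks[rows, order] = put
    return ranks.astype(float)


def _pair_z(arr: np.ndarray, n0: int, sl: slice, has_ties: bool) -> np.ndarray:
    """Standardized rank-sum of one treatment vs control, row-wise."""
    sub = np.concatenate([arr[:, :n0], arr[:, sl]], axis=1)
    ni = sub.shape[1] - n0
    n_tot = sub.shape[1]
    ranks = _rank_rows(sub, has_ties)
    w = ranks[:, n0:].sum(axis=1)
    expect = ni * (n_tot + 1) / 2.0
    sigma2 = (ranks**2).mean(axis=1) - ((n_tot + 1) / 2.0) ** 2
    var = n0 * ni * sigma2 / (n_tot - 1)
    z = np.zeros(arr.shape[0])
    ok = var > 1e-12
    z[ok] = (w[ok] - expect) / np.sqrt(var[ok])
    if not np.all(ok):
        warnings.warn("all measurements tied within a comparison; statistic set to 0", stacklevel=3)
    return z


def _assignments(indices: "tuple[int, ...]", sizes: "list[int]"):
    if len(sizes) == 1:
        yield indices
        return
    head = sizes[0]
    for comb in itertools.combinations(indices, head):
        taken = set(comb)
        rest = tuple(i for i in indices if i not in taken)
        for tail in _assignments(rest, sizes[1:]):
            yield comb + tail


def _n_arrangements(sizes: Sequence[int]) -> int:
    total = sum(sizes)
    n = 1
    for s in sizes:
        n *= math.comb(total, s)
        total -= s
    return n


def steel_test(
    data: GroupData,
    alternative: str = "two-sided",
    max_exact: int = 10000,
    n_permutations: int = 10000,
    seed: "int | None" = None,
) -> SteelResult:
    """Steel many-to-one rank test with permutation family-wise adjustment.

    For each treatment the adjusted p-value is the permutation probability
    that the maximum standardized statistic across all treatments reaches
    the treatment's observed statistic.  ``alternative='greater'`` tests
    treatments shifted above control.  Monte Carlo mode (used when the
    number of distinct joint arrangements exceeds ``max_exact``) requires
    an explicit seed and at least 10^4 draws.
    """
    alt = _normalize_alternative(alternative)
    pooled = np.concatenate([data.control, *data.treatments.values()])
    sizes = [data.control.size] + [v.size for v in data.treatments.values()]
    n0 = sizes[0]
    slices = []
    offset = n0
    for s in sizes[1:]:
        slices.append(slice(offset, offset + s))
        offset += s
    has_ties = np.unique(pooled).size < pooled.size

    n_arr_total = _n_arrangements(sizes)
    if n_arr_total <= max_exact:
        method = "exact_permutation"
        idx = np.array(list(_assignments(tuple(range(pooled.size)), sizes)))
        arr = pooled[idx]
        n_used = arr.shape[0]
    else:
        method = "monte_carlo"
        if seed is None:
            raise ValueError("Monte-Carlo mode requires an explicit seed")
        if n_permutations < 10_000:
            raise ValueError("Monte-Carlo mode requires at least 10^4 permutations")
        rng = np.random.default_rng(seed)
        perm = np.argsort(rng.random((n_permutations, pooled.size)), axis=1)
        arr = pooled[perm]
        n_used = n_permutations

    def scores(z: np.ndarray) -> np.ndarray:
        if alt == "two-sided":
            return np.abs(z)
        if alt == "greater":
            return z
        return -z

    obs_row = pooled[None, :]
    z_obs = np.array([_pair_z(obs_row, n0, sl, has_ties)[0] for sl in slices])
    s_obs = scores(z_obs)

    null_scores = np.stack([scores(_pair_z(arr, n0, sl, has_ties)) for sl in slices])
    null_max = null_scores.max(axis=0)

    p_values = {}
    statistics = {}
    flags = {}
    eps = 1e-9
    for name, z, s in zip(data.treatments, z_obs, s_obs):
        count = int(np.count_nonzero(null_max >= s - eps))
        if method == "exact_permutation":
            p = count / n_used
        else:
            p = (1 + count) / (1 + n_used)
        statistics[name] = float(z)
        p_values[name] = float(min(p, 1.0))
        flags[name] = "**" if p < 0.01 else ("*" if p < 0.05 else "")

    max_score = float(null_max.max())
    count_top = int(np.count_nonzero(null_max >= max_score - eps))
    min_p = count_top / n_used if method == "exact_permutation" else (1 + count_top) / (1 + n_used)

    return SteelResult(
        statistics=statistics,
        p_values=p_values,
        flags=flags,
        method=method,
        n_arrangements=n_used,
        alternative=alt,
        min_attainable_adjusted_p=float(min(min_p, 1.0)),
    )


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> "tuple[float, float]":
    """Spearman rho on midranks and its square.

    Returns (nan, nan) with a warning when either vector is constant
    (rank correlation undefined, not zero).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if xa.size < 3:
        raise ValueError("at least 3 paired observations are required")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        warnings.warn("constant input: Spearman correlation is undefined", stacklevel=2)
        return (math.nan, math.nan)
    rho = float(sps.spearmanr(xa, ya).statistic)
    return rho, rho**2


def coefficient_of_variation(values: Sequence[float], dispersion: str = "sem") -> float:
    """CV in percent: 100 x (SEM or SD) / mean, with SEM = SD / sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("at least 2 values are required")
    mean = v.mean()
    if mean == 0:
        raise ValueError("mean is zero; CV undefined")
    sd = v.std(ddof=1)
    if dispersion == "sd":
        disp = sd
    elif dispersion == "sem":
        disp = sd / math.sqrt(v.size)
    else:
        raise ValueError(f"dispersion must be 'sem' or 'sd', got {dispersion!r}")
    return 100.0 * disp / mean
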