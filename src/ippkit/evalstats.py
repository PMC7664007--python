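"""Evaluation metrics and inference for the phenotyping pipeline.

* ``qseg`` — segmentation quality: Jaccard overlap of predicted and
  reference vegetation pixels, in [0, 1].
* ``pearson_validation`` — product-moment correlation of estimated against
  manually measured trait values, with the regression line reported
  alongside so both the correlation and regression readings of R2 are
  available.
* ``group_effect_lrt`` — Gaussian one-way likelihood-ratio test for a group
  effect on a scalar trait.
* ``permanova`` / ``permanova_pairwise`` — permutational multivariate
  ANOVA on an outline dissimilarity matrix (pseudo-F from the distance
  decomposition, permutation p-values, exhaustive when feasible for two
  groups, Bonferroni-adjusted across pairs).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import InvalidInputError, InvalidMatrixError, UndefinedMetricError
from .outline import DistanceMatrix

__all__ = [
    "qseg",
    "ValidationResult",
    "pearson_validation",
    "group_effect_lrt",
    "PermanovaResult",
    "pseudo_f",
    "permanova",
    "permanova_pairwise",
]

EXHAUSTIVE_LIMIT = 20_000


def qseg(pred: np.ndarray, ref: np.ndarray, include_background: bool = False) -> float:
    """Segmentation quality score in [0, 1].

    Default: Jaccard overlap of the vegetation pixels,
    ``|A ∩ B| / |A ∪ B|``.  With ``include_background=True`` the strict
    agreement-over-all-pixels variant (pixel accuracy) is returned instead,
    for sensitivity checks.
    """
    a = np.asarray(pred, dtype=bool)
    b = np.asarray(ref, dtype=bool)
    if a.shape != b.shape:
        raise InvalidInputError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if include_background:
        return float((a == b).sum() / a.size)
    union = int((a | b).sum())
    if union == 0:
        raise UndefinedMetricError("qseg undefined: both masks are empty")
    return float((a & b).sum() / union)


class ValidationResult(NamedTuple):
    r: float
    p: float
    r_squared: float
    slope: float
    intercept: float
    n: int


def pearson_validation(x, y) -> ValidationResult:
    """Pearson correlation of estimates x against manual measurements y.

    Returns r and the two-sided t-based p-value, plus r2 and the ordinary
    least-squares line of y on x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be paired 1-D arrays")
    if x.size < 3:
        raise InvalidInputError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InvalidInputError("non-finite values in input")
    r, p = stats.pearsonr(x, y)
    reg = stats.linregress(x, y)
    return ValidationResult(float(r), float(p), float(r) ** 2, float(reg.slope), float(reg.intercept), x.size)


def group_effect_lrt(values, groups) -> tuple[float, int, float]:
    """Gaussian one-way likelihood-ratio test for a group effect.

    Compares the group-means model against the grand-mean model under a
    Gaussian likelihood with MLE variance:
    ``LR = n * log(sse_null / sse_full)``, referred to chi-square with
    ``n_groups - 1`` degrees of freedom.  Returns (statistic, df, p).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape != g.shape or v.ndim != 1:
        raise InvalidInputError("values and groups must be paired 1-D arrays")
    uniq = np.unique(g)
    k, n = uniq.size, v.size
    if k < 2:
        raise InvalidInputError("need at least 2 groups")
    if n - k < 2:
        raise InvalidInputError("need at least 2 residual degrees of freedom")
    sse_null = float(((v - v.mean()) ** 2).sum())
    sse_full = 0.0
    for u in uniq:
        sub = v[g == u]
        sse_full += float(((sub - sub.mean()) ** 2).sum())
    if sse_full <= 0 or sse_null <= 0:
        raise InvalidInputError("zero residual variance: LRT undefined")
    stat = n * math.log(sse_null / sse_full)
    df = k - 1
    return stat, df, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    """Pairwise PERMANOVA outcome for one group pair."""

    group_a: str
    group_b: str
    f: float
    p: float
    p_adjusted: float
    n_permutations: int
    method: str  # "exhaustive" | "sampled"
    seed: int | None


def _check_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InvalidMatrixError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise InvalidMatrixError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-9):
        raise InvalidMatrixError("distance matrix must have a zero diagonal")
    if (d < -1e-12).any():
        raise InvalidMatrixError("distances must be nonnegative")
    return d


def _ss_within(d2: np.ndarray, membership: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Within-group sum of squares for a batch of label assignments.

    ``membership`` is (B, n) integer group codes; returns SS_within per row.
    """
    ss = np.zeros(membership.shape[0])
    for g, n_g in enumerate(sizes):
        z = (membership == g).astype(float)
        ss += np.einsum("bi,ij,bj->b", z, d2, z) / (2.0 * n_g)
    return ss


def pseudo_f(d: np.ndarray, groups) -> float:
    """PERMANOVA pseudo-F from the distance decomposition.

    ``F = (SS_between / (k-1)) / (SS_within / (n-k))`` with sums of squares
    obtained directly from squared distances (equivalently from the
    Gower-centred inner-product matrix).
    """
    d = _check_distance_matrix(d)
    codes, sizes = _group_codes(groups)
    n, k = codes.size, sizes.size
    if k < 2:
        raise InvalidInputError("need at least 2 groups")
    d2 = d**2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = float(_ss_within(d2, codes[None, :], sizes)[0])
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return math.inf
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def _group_codes(groups) -> tuple[np.ndarray, np.ndarray]:
    g = np.asarray(groups)
    uniq, codes = np.unique(g, return_inverse=True)
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise InvalidInputError("every group needs at least 2 samples")
    return codes, sizes


def permanova(
    d: np.ndarray,
    groups,
    n_permutations: int = 9999,
    seed: int | None = 0,
    exhaustive_limit: int = EXHAUSTIVE_LIMIT,
) -> tuple[float, float, int, str]:
    """One PERMANOVA test of group labels against a distance matrix.

    For two groups with at most ``exhaustive_limit`` distinct label
    arrangements the permutation distribution is enumerated exactly and
    ``p = #{F_perm >= F_obs} / N_arrangements`` (the identity arrangement
    included); otherwise ``n_permutations`` random label shuffles are drawn
    and ``p = (#{F_perm >= F_obs} + 1) / (n_permutations + 1)``.

    Returns ``(F, p, n_used, method)``.
    """
    d = _check_distance_matrix(d)
    codes, sizes = _group_codes(groups)
    n, k = codes.size, sizes.size
    if k < 2:
        raise InvalidInputError("need at least 2 groups")
    d2 = d**2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    def f_from_ssw(ssw: np.ndarray) -> np.ndarray:
        ssb = ss_total - ssw
        with np.errstate(divide="ignore", invalid="ignore"):
            return (ssb / (k - 1)) / (ssw / (n - k))

    f_obs = float(f_from_ssw(_ss_within(d2, codes[None, :], sizes))[0])

    n_arrangements = math.comb(n, int(sizes[0])) if k == 2 else None
    if k == 2 and n_arrangements <= exhaustive_limit:
        combos = list(itertools.combinations(range(n), int(sizes[0])))
        membership = np.ones((len(combos), n), dtype=int)
        for row, idx in enumerate(combos):
            membership[row, list(idx)] = 0
        f_all = f_from_ssw(_ss_within(d2, membership, sizes))
        p = float((f_all >= f_obs - 1e-12).sum() / len(combos))
        return f_obs, p, len(combos), "exhaustive"

    rng = np.random.default_rng(seed)
    perm = np.array([rng.permutation(codes) for _ in range(n_permutations)])
    f_perm = f_from_ssw(_ss_within(d2, perm, sizes))
    p = float(((f_perm >= f_obs - 1e-12).sum() + 1) / (n_permutations + 1))
    return f_obs, p, n_permutations, "sampled"


def permanova_pairwise(
    d: DistanceMatrix | np.ndarray,
    groups: Sequence[str] | None = None,
    n_permutations: int = 9999,
    seed: int | None = 0,
) -> list[PermanovaResult]:
    """Pairwise PERMANOVA across all group pairs with Bonferroni adjustment."""
    if isinstance(d, DistanceMatrix):
        matrix = d.matrix
        if groups is None:
            groups = d.groups
    else:
        matrix = np.asarray(d, dtype=float)
    if groups is None:
        raise InvalidInputError("group labels are required")
    matrix = _check_distance_matrix(matrix)
    g = np.asarray(groups)
    if g.size != matrix.shape[0]:
        raise InvalidInputError("groups do not match matrix size")
    uniq = [str(u) for u in np.unique(g)]
    pairs = list(itertools.combinations(uniq, 2))
    results = []
    for i, (ga, gb) in enumerate(pairs):
        sel = np.isin(g.astype(str), (ga, gb))
        sub = matrix[np.ix_(sel, sel)]
        sub_groups = g[sel]
        pair_seed = None if seed is None else seed + i
        f, p, n_used, method = permanova(sub, sub_groups, n_permutations, pair_seed)
        results.append(
            PermanovaResult(
                group_a=ga,
                group_b=gb,
                f=f,
                p=p,
                p_adjusted=min(1.0, p * len(pairs)),
                n_permutations=n_used,
                method=method,
                seed=pair_seed,
            )
        )
    return results
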