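"""Between-group discrepancy statistics D_k and their p-values.

Three interchangeable measures of how strongly a TMB categorization
separates the per-patient joint favorable-prognosis probabilities:

* :func:`anova_distance` — variance-ratio F statistic (one-way ANOVA),
  p from the upper tail of F(k, n-k-1);
* :func:`rank_distance` — Kruskal-Wallis-type rank statistic, p from the
  upper tail of chi^2(k);
* :func:`similarity_distance` — ANOSIM-style rank statistic on an n x n
  patient-distance matrix, (r_between - r_within) / (n(n-1)/4) in
  [-1, 1], p by a seeded label permutation test.

The minimal-p threshold search treats these uniformly through
:class:`DiscrepancyResult`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DiscrepancyResult",
    "DiscrepancyError",
    "anova_distance",
    "rank_distance",
    "similarity_matrix",
    "similarity_distance",
]


class DiscrepancyError(ValueError):
    """Raised for degenerate group structures (empty groups etc.)."""


@dataclass(frozen=True)
class DiscrepancyResult:
    """A discrepancy statistic with its reference distribution p-value."""

    D: float
    method: str
    p_value: float
    df: tuple[int, ...] = ()
    n_perm: int = 0
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "D": self.D,
            "method": self.method,
            "p_value": self.p_value,
            "df": list(self.df),
            "n_perm": self.n_perm,
            "note": self.note,
        }


def _group_split(values: np.ndarray, labels: np.ndarray):
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise DiscrepancyError("need at least 2 non-empty groups")
    return [values[labels == g] for g in uniq]


def anova_distance(p_values: Sequence[float], labels: Sequence[int]) -> DiscrepancyResult:
    """Variance-ratio discrepancy: D = (SS_b/k) / (SS_w/(n-k-1)).

    ``SS_b = sum_j n_j (pbar_j - pbar)^2`` and ``SS_w`` the within-group
    sum of squares; under the usual one-way-ANOVA assumptions D follows
    F(k, n-k-1) and the p-value is its upper tail.
    """
    p = np.asarray(p_values, dtype=float)
    groups = _group_split(p, np.asarray(labels))
    n = len(p)
    k = len(groups) - 1
    if n - k - 1 < 1:
        raise DiscrepancyError(f"n - k - 1 = {n - k - 1} < 1: too few patients")
    grand = p.mean()
    ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df = (k, n - k - 1)
    if ss_w <= 0.0:
        if ss_b > 0.0:
            return DiscrepancyResult(
                np.inf, "anova", 0.0, df, note="zero within-group variance"
            )
        return DiscrepancyResult(0.0, "anova", 1.0, df, note="all values identical")
    D = (ss_b / k) / (ss_w / (n - k - 1))
    return DiscrepancyResult(float(D), "anova", float(stats.f.sf(D, *df)), df)


def rank_distance(
    p_values: Sequence[float],
    labels: Sequence[int],
    tie_correction: bool = False,
) -> DiscrepancyResult:
    """Kruskal-Wallis-type rank discrepancy.

    All n probabilities are ranked with ties averaged;
    ``D = 12/(n(n+1)) * sum_j RA_j^2/n_j - 3(n+1)`` with ``RA_j`` the
    rank sum of group j.  The p-value uses the upper tail of chi^2(k),
    an approximation trusted when every group exceeds 5 observations
    (a warning is issued otherwise).  The classical tie-correction
    divisor is available but off by default.
    """
    p = np.asarray(p_values, dtype=float)
    labels = np.asarray(labels)
    groups = _group_split(p, labels)
    n = len(p)
    k = len(groups) - 1
    sizes = np.array([len(g) for g in groups])
    if sizes.min() <= 5:
        warnings.warn(
            "some subgroup has <= 5 observations; the chi^2 approximation "
            "of the rank statistic is unreliable",
            stacklevel=2,
        )
    ranks = stats.rankdata(p)
    uniq = np.unique(labels)
    ra = np.array([ranks[labels == g].sum() for g in uniq])
    D = 12.0 / (n * (n + 1)) * float((ra**2 / sizes).sum()) - 3.0 * (n + 1)
    note = ""
    if tie_correction:
        _, counts = np.unique(p, return_counts=True)
        corr = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
        if corr <= 0:
            return DiscrepancyResult(0.0, "rank", 1.0, (k,), note="all values tied")
        D /= corr
        note = "tie-corrected"
    D = max(D, 0.0) if abs(D) < 1e-12 else D  # clean up -0.0 from tie algebra
    return DiscrepancyResult(float(D), "rank", float(stats.chi2.sf(D, k)), (k,), note=note)


def similarity_matrix(
    p_vectors: np.ndarray,
    metric: str = "euclidean",
    V: np.ndarray | None = None,
    minkowski_p: float = 2.0,
) -> np.ndarray:
    """n x n patient-distance matrix over scalar or 2-vector probabilities.

    ``metric="mahalanobis"`` requires 2-vector inputs and uses
    ``d_il = sqrt((p_i - p_l) V^{-1} (p_i - p_l)^T)`` with ``V`` the
    sample covariance of the vectors by default.
    """
    X = np.asarray(p_vectors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if metric == "euclidean":
        d = pdist(X, metric="euclidean")
    elif metric == "minkowski":
        d = pdist(X, metric="minkowski", p=minkowski_p)
    elif metric == "mahalanobis":
        if X.shape[1] < 2:
            raise DiscrepancyError(
                "mahalanobis distance needs 2-vector probabilities; use "
                "euclidean for scalars"
            )
        if V is None:
            V = np.cov(X, rowvar=False)
        V = np.asarray(V, dtype=float)
        try:
            VI = np.linalg.inv(V)
        except np.linalg.LinAlgError as exc:
            raise DiscrepancyError(
                "singular covariance V; add a ridge or use euclidean"
            ) from exc
        if np.linalg.eigvalsh(V).min() <= 0:
            raise DiscrepancyError(
                "covariance V is not positive definite; add a ridge or use "
                "euclidean"
            )
        d = pdist(X, metric="mahalanobis", VI=VI)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return squareform(d)


def similarity_distance(
    dist_matrix: np.ndarray,
    labels: Sequence[int],
    n_perm: int = 9999,
    seed: int | np.random.Generator | None = None,
) -> DiscrepancyResult:
    """ANOSIM-style rank discrepancy on a patient-distance matrix.

    All n(n-1)/2 pairwise distances are ranked (ties averaged);
    ``D = (r_b - r_w) / (n(n-1)/4)`` with ``r_b``/``r_w`` the mean rank
    of between-/within-group pairs.  D lies in [-1, 1].  The p-value is
    a permutation test over label reassignments holding group sizes
    fixed, with the add-one estimator ``(1 + #{D_perm >= D_obs}) /
    (1 + n_perm)``.
    """
    Dm = np.asarray(dist_matrix, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    if n < 4:
        raise DiscrepancyError("similarity test needs n >= 4")
    if Dm.shape != (n, n):
        raise DiscrepancyError("distance matrix shape does not match labels")
    if len(np.unique(labels)) < 2:
        raise DiscrepancyError("need at least 2 groups")
    iu, ju = np.triu_indices(n, k=1)
    ranks = stats.rankdata(Dm[iu, ju])
    denom = n * (n - 1) / 4.0

    within = labels[iu] == labels[ju]
    if not within.any():
        raise DiscrepancyError(
            "no within-group pairs (all groups singleton); the statistic is "
            "undefined"
        )

    def stat(within_mask: np.ndarray) -> float:
        r_w = ranks[within_mask].mean()
        r_b = ranks[~within_mask].mean() if (~within_mask).any() else r_w
        return (r_b - r_w) / denom

    D_obs = stat(within)

    rng = np.random.default_rng(seed)
    count = 0
    # vectorized permutation batches: recompute the within mask per shuffle
    batch = max(1, min(n_perm, 512))
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perms = np.array([rng.permutation(labels) for _ in range(b)])
        wmask = perms[:, iu] == perms[:, ju]  # (b, n_pairs)
        r_w = (ranks[None, :] * wmask).sum(axis=1) / wmask.sum(axis=1)
        nb = (~wmask).sum(axis=1)
        r_b = np.where(nb > 0, (ranks[None, :] * ~wmask).sum(axis=1) / np.maximum(nb, 1), r_w)
        Dp = (r_b - r_w) / denom
        count += int((Dp >= D_obs - 1e-12).sum())
        done += b
    p = (1 + count) / (1 + n_perm)
    return DiscrepancyResult(float(D_obs), "similarity", float(p), (), n_perm)
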