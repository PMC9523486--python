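"""Minimal-p search over candidate TMB threshold sets.

Candidate cutpoints are distinct observed TMB values inside a
clinically meaningful quantile band (optionally thinned to at most
``max_candidates`` quantile-spaced values).  For a given threshold
count ``k`` every strictly increasing k-subset of candidates is scored
with a between-group discrepancy statistic; the set with the smallest
p-value wins (ties broken by larger D, then smaller thresholds).  The
number of thresholds itself is chosen stepwise: a further subgroup is
added only while it lowers the minimal p-value.

The minimal-p criterion performs no multiplicity correction across
candidates — the selection optimism this induces is deliberate (the
criterion is the method) and is quantified in the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .data_model import Cohort, ThresholdSet, assign_groups
from .discrepancy import (
    DiscrepancyResult,
    anova_distance,
    rank_distance,
    similarity_distance,
    similarity_matrix,
)

__all__ = [
    "SearchConfig",
    "SearchResult",
    "SearchError",
    "enumerate_cuts",
    "search_thresholds",
    "select_k",
    "export_grid",
    "import_grid",
]


class SearchError(RuntimeError):
    """No feasible candidate threshold sets."""


@dataclass(frozen=True)
class SearchConfig:
    """Configuration of the threshold search.

    ``candidate_values`` defaults to the distinct observed TMB values
    between ``quantile_band`` (5th-95th percentiles), thinned to at most
    ``max_candidates`` quantile-spaced values.  ``min_group_size``
    guards the chi^2/F approximations (every subgroup must exceed 5
    observations).
    """

    k_range: tuple[int, ...] = (1, 2, 3, 4)
    candidate_values: tuple[float, ...] | None = None
    quantile_band: tuple[float, float] = (0.05, 0.95)
    max_candidates: int = 20
    min_group_size: int = 6
    method: str = "anova"
    metric: str = "euclidean"
    weights: tuple[float, float] = (1.0, 1.0)
    T0: float | None = None
    n_perm: int = 999
    strategy: str = "exhaustive"
    seed: int | None = None
    anneal_steps: int = 2000

    def __post_init__(self) -> None:
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")
        if self.method not in ("anova", "rank", "similarity"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.strategy not in ("exhaustive", "annealing"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.candidate_values is not None:
            cv = tuple(self.candidate_values)
            if any(cv[i] >= cv[i + 1] for i in range(len(cv) - 1)):
                raise ValueError("candidate_values must be sorted ascending, unique")
            object.__setattr__(self, "candidate_values", cv)


@dataclass
class SearchResult:
    """All scored candidates for one threshold count k, plus the winner."""

    grid: pd.DataFrame  # columns: thresholds (tuple), D, p
    best: ThresholdSet
    best_D: float
    best_p: float
    k: int
    method: str

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "method": self.method,
            "best": list(self.best.thresholds),
            "best_D": self.best_D,
            "best_p": self.best_p,
            "n_candidates": int(len(self.grid)),
        }


def candidate_grid(tmb: np.ndarray, config: SearchConfig) -> np.ndarray:
    """Candidate cutpoints from the observed TMB distribution."""
    if config.candidate_values is not None:
        return np.asarray(config.candidate_values, dtype=float)
    lo, hi = np.quantile(tmb, config.quantile_band)
    vals = np.unique(tmb[(tmb >= lo) & (tmb <= hi)])
    if len(vals) > config.max_candidates:
        qs = np.linspace(0, 1, config.max_candidates)
        vals = np.unique(np.quantile(vals, qs, method="nearest"))
    return vals


def enumerate_cuts(
    config: SearchConfig,
    k: int,
    tmb: np.ndarray | None = None,
) -> Iterator[ThresholdSet]:
    """Yield all strictly increasing k-subsets of the candidate values.

    Ordered threshold vectors make permutations collapse to C(m, k)
    combinations.  When ``tmb`` is given, sets inducing any subgroup
    smaller than ``min_group_size`` are filtered out.
    """
    if config.candidate_values is None:
        if tmb is None:
            raise SearchError("need candidate_values or observed tmb")
        values = candidate_grid(np.asarray(tmb, dtype=float), config)
    else:
        values = np.asarray(config.candidate_values, dtype=float)
    m = len(values)
    if m < k:
        raise SearchError(f"only {m} candidate values for k = {k} thresholds")
    any_yielded = False
    for combo in itertools.combinations(values, k):
        cuts = ThresholdSet.of(combo)
        if tmb is not None:
            labels = assign_groups(tmb, cuts)
            sizes = np.bincount(labels, minlength=k + 2)[1:]
            if sizes.min() < config.min_group_size:
                continue
        any_yielded = True
        yield cuts
    if not any_yielded:
        raise SearchError(
            f"no feasible candidate threshold set for k = {k} under "
            f"min_group_size = {config.min_group_size}"
        )


def _score(
    p_scalar: np.ndarray,
    dist_matrix: np.ndarray | None,
    labels: np.ndarray,
    config: SearchConfig,
    seed: int | None,
) -> DiscrepancyResult:
    if config.method == "anova":
        return anova_distance(p_scalar, labels)
    if config.method == "rank":
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # small-group warning handled by min_group_size
            return rank_distance(p_scalar, labels)
    return similarity_distance(dist_matrix, labels, n_perm=config.n_perm, seed=seed)


def _probability_inputs(probabilities, config: SearchConfig):
    """Extract the scalar p vector and (for similarity) a distance matrix."""
    if isinstance(probabilities, pd.DataFrame):
        p_scalar = probabilities["p"].to_numpy(dtype=float)
        if config.method == "similarity":
            if {"p_R", "p_T"}.issubset(probabilities.columns):
                vecs = probabilities[["p_R", "p_T"]].to_numpy(dtype=float)
            else:
                vecs = p_scalar
            dist = similarity_matrix(vecs, metric=config.metric)
        else:
            dist = None
    else:
        p_scalar = np.asarray(probabilities, dtype=float)
        if p_scalar.ndim == 2:
            dist = similarity_matrix(p_scalar, metric=config.metric) \
                if config.method == "similarity" else None
            p_scalar = p_scalar.prod(axis=1)
        else:
            dist = similarity_matrix(p_scalar, metric=config.metric) \
                if config.method == "similarity" else None
    return p_scalar, dist


def _candidate_seeds(master_seed: int | None, n: int) -> list[int | None]:
    if master_seed is None:
        return [None] * n
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def search_thresholds(
    cohort: Cohort | np.ndarray,
    probabilities,
    config: SearchConfig,
    k: int,
) -> SearchResult:
    """Score every feasible k-threshold candidate and return the argmin-p set.

    ``probabilities`` is the per-patient joint-probability table from
    :func:`tmbcat.joint_model.joint_probabilities` (or a plain vector).
    The ``annealing`` strategy explores the same space stochastically
    for large C(m, k); ``exhaustive`` is the default and is globally
    optimal on the candidate grid.
    """
    tmb = cohort.tmb if isinstance(cohort, Cohort) else np.asarray(cohort, dtype=float)
    p_scalar, dist = _probability_inputs(probabilities, config)
    if len(p_scalar) != len(tmb):
        raise ValueError("probabilities and cohort sizes differ")

    candidates = list(enumerate_cuts(config, k, tmb))
    if config.strategy == "annealing" and len(candidates) > config.anneal_steps:
        return _anneal(tmb, p_scalar, dist, config, k, candidates)

    seeds = _candidate_seeds(config.seed, len(candidates))
    rows = []
    for cuts, s in zip(candidates, seeds):
        labels = assign_groups(tmb, cuts)
        res = _score(p_scalar, dist, labels, config, s)
        rows.append((cuts.thresholds, res.D, res.p_value))
    grid = pd.DataFrame(rows, columns=["thresholds", "D", "p"])
    best_i = _argbest(grid)
    best = ThresholdSet.of(grid.loc[best_i, "thresholds"])
    return SearchResult(
        grid=grid,
        best=best,
        best_D=float(grid.loc[best_i, "D"]),
        best_p=float(grid.loc[best_i, "p"]),
        k=k,
        method=config.method,
    )


def _argbest(grid: pd.DataFrame) -> int:
    """Minimal p; ties -> larger D, then lexicographically smaller thresholds."""
    order = sorted(
        grid.index,
        key=lambda i: (grid.loc[i, "p"], -grid.loc[i, "D"], grid.loc[i, "thresholds"]),
    )
    return order[0]


def _anneal(tmb, p_scalar, dist, config: SearchConfig, k, candidates) -> SearchResult:
    """Seeded simulated annealing over the feasible candidate list.

    States are index-tuples into the sorted candidate values; proposals
    move one threshold to a nearby candidate (occasionally jumping to a
    random state), annealing on -log p.  Restarts split the step budget.
    """
    rng = np.random.default_rng(config.seed)
    feasible = {tuple(c.thresholds): i for i, c in enumerate(candidates)}
    values = sorted({v for c in candidates for v in c.thresholds})
    pos = {v: j for j, v in enumerate(values)}
    seeds = _candidate_seeds(config.seed, len(candidates))
    cache: dict[int, tuple[float, float]] = {}

    def get(i: int) -> tuple[float, float]:
        if i not in cache:
            labels = assign_groups(tmb, candidates[i])
            res = _score(p_scalar, dist, labels, config, seeds[i])
            cache[i] = (res.p_value, res.D)
        return cache[i]

    def propose(state: tuple[float, ...]) -> tuple[float, ...] | None:
        if rng.random() < 0.1:  # occasional global jump
            return candidates[int(rng.integers(len(candidates)))].thresholds
        idx = [pos[v] for v in state]
        j = int(rng.integers(k))
        idx[j] += int(rng.choice([-2, -1, 1, 2]))
        if not (0 <= idx[j] < len(values)):
            return None
        new = tuple(values[i] for i in idx)
        if any(new[i] >= new[i + 1] for i in range(k - 1)):
            return None
        return new if new in feasible else None

    n_restarts = 3
    steps = max(1, config.anneal_steps // n_restarts)
    best = int(rng.integers(len(candidates)))
    for _ in range(n_restarts):
        cur = int(rng.integers(len(candidates)))
        temps = np.geomspace(2.0, 1e-3, steps)
        for t in temps:
            new_state = propose(candidates[cur].thresholds)
            if new_state is None:
                continue
            nxt = feasible[new_state]
            dp = np.log(max(get(nxt)[0], 1e-300)) - np.log(max(get(cur)[0], 1e-300))
            if dp <= 0 or rng.random() < np.exp(-dp / t):
                cur = nxt
            if get(cur)[0] < get(best)[0]:
                best = cur
    rows = [(candidates[i].thresholds, cache[i][1], cache[i][0]) for i in sorted(cache)]
    grid = pd.DataFrame(rows, columns=["thresholds", "D", "p"])
    return SearchResult(
        grid=grid,
        best=candidates[best],
        best_D=float(get(best)[1]),
        best_p=float(get(best)[0]),
        k=k,
        method=config.method,
    )


def select_k(
    results: Mapping[int, SearchResult],
) -> tuple[int, ThresholdSet, dict[int, float]]:
    """Stepwise choice of the number of thresholds.

    Starting from the smallest k, move to k+1 only while the minimal
    p-value decreases; stop at the first non-improvement.  Returns the
    chosen k, its threshold set, and the best-p trace per k.
    """
    ks = sorted(results)
    if not ks:
        raise ValueError("no search results given")
    trace = {k: results[k].best_p for k in ks}
    chosen = ks[0]
    for a, b in zip(ks, ks[1:]):
        if b != a + 1:
            break
        if results[b].best_p < results[a].best_p:
            chosen = b
        else:
            break
    return chosen, results[chosen].best, trace


def export_grid(result_k1: SearchResult, result_k2: SearchResult) -> pd.DataFrame:
    """Triangular-grid table of (threshold1, threshold2, p).

    Pairs from the k = 2 search fill the triangle; k = 1 results lie on
    the hypotenuse with the convention threshold1 = threshold2.
    """
    if result_k1.k != 1 or result_k2.k != 2:
        raise ValueError("export_grid needs a k=1 and a k=2 SearchResult")
    rows = [
        (t[0], t[0], D, p, 1) for t, D, p in result_k1.grid.itertuples(index=False)
    ] + [
        (t[0], t[1], D, p, 2) for t, D, p in result_k2.grid.itertuples(index=False)
    ]
    return pd.DataFrame(rows, columns=["threshold1", "threshold2", "D", "p", "k"])


def import_grid(grid: pd.DataFrame) -> tuple[int, ThresholdSet, float]:
    """Recover the best selection from an exported triangular grid."""
    g = grid.copy()
    g["thresholds"] = [
        (t1,) if k == 1 else (t1, t2)
        for t1, t2, k in zip(g["threshold1"], g["threshold2"], g["k"])
    ]
    i = _argbest(g[["thresholds", "D", "p"]].reset_index(drop=True))
    row = g.reset_index(drop=True).loc[i]
    cuts = ThresholdSet.of(row["thresholds"])
    return int(row["k"]), cuts, float(row["p"])
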