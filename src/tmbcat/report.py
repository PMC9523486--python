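"""Subgroup reporting and the end-to-end categorization pipeline.

Once a TMB categorization is chosen, subgroups are summarized the way
an immuno-oncology reader expects: per-group objective response rate,
Kaplan-Meier curves with median survival (the string token ``"inf"``
when the median is not reached), a log-rank test across groups, a
Mann-Whitney U test on response, and the joint p-value of the chosen
discrepancy method.

:func:`run_pipeline` chains the full procedure: (corrected) joint-model
fit -> per-patient joint probabilities -> per-k minimal-p search ->
stepwise choice of k -> subgroup report, deterministically from
(input, config, seed).
"""

from __future__ import annotations

import json
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .data_model import Cohort, ThresholdSet, assign_groups, read_cohort
from .discrepancy import rank_distance
from .error_correction import ErrorModel, fit_corrected_joint_model
from .joint_model import FitOptions, fit_joint_model, joint_probabilities
from .threshold_search import SearchConfig, SearchResult, search_thresholds, select_k

__all__ = [
    "KMEstimate",
    "SubgroupReport",
    "PipelineConfig",
    "PipelineResult",
    "km_estimate",
    "logrank_test",
    "mannwhitney_orr",
    "run_pipeline",
]


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray
    survival: np.ndarray
    median: float  # np.inf when not reached

    def at(self, t: float | np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        vals = np.concatenate([[1.0], self.survival])
        return vals[idx]


def km_estimate(times: Sequence[float], deltas: Sequence[int]) -> KMEstimate:
    """Kaplan-Meier estimator; median is the first time S(t) <= 0.5."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(deltas, dtype=int))
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = t > 0
    t, s = t[keep], s[keep]
    below = np.nonzero(s <= 0.5 + 1e-9)[0]  # median: first time S(t) <= 0.5
    median = float(t[below[0]]) if len(below) else np.inf
    return KMEstimate(t, s, median)


def logrank_test(
    times: Sequence[float], deltas: Sequence[int], labels: Sequence[int]
) -> tuple[float, float]:
    """(k+1)-sample log-rank chi^2 statistic and p-value (k df)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    res = multivariate_logrank_test(
        np.asarray(times, dtype=float), labels, np.asarray(deltas, dtype=int)
    )
    return float(res.test_statistic), float(res.p_value)


def mannwhitney_orr(
    R_values: Sequence[int], labels: Sequence[int]
) -> tuple[float, float]:
    """Mann-Whitney U on the binary response between groups.

    Two groups: normal-approximation p with tie correction (responses
    are binary, so ties are heavy).  More than two groups: falls back to
    the rank discrepancy (Kruskal-Wallis form), returning (D, p).
    """
    R = np.asarray(R_values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if any((labels == g).sum() == 0 for g in uniq) or len(uniq) < 2:
        raise ValueError("need at least 2 non-empty groups")
    if len(uniq) == 2:
        a = R[labels == uniq[0]]
        b = R[labels == uniq[1]]
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = rank_distance(R, labels)
    return float(res.D), float(res.p_value)


@dataclass
class SubgroupReport:
    """Per-subgroup efficacy summary plus across-group tests."""

    table: pd.DataFrame  # group, n, orr_pct, median_survival, km
    logrank_stat: float
    logrank_p: float
    mw_stat: float
    mw_p: float
    joint_p: float
    joint_method: str

    def to_dict(self) -> dict:
        tab = []
        for _, row in self.table.iterrows():
            tab.append(
                {
                    "group": int(row["group"]),
                    "n": int(row["n"]),
                    "orr_pct": float(row["orr_pct"]),
                    "median_survival": "inf"
                    if np.isinf(row["median_survival"])
                    else float(row["median_survival"]),
                }
            )
        return {
            "groups": tab,
            "logrank_stat": self.logrank_stat,
            "logrank_p": self.logrank_p,
            "mannwhitney_stat": self.mw_stat,
            "mannwhitney_p": self.mw_p,
            "joint_p": self.joint_p,
            "joint_method": self.joint_method,
        }


def subgroup_report(
    cohort: Cohort,
    cuts: ThresholdSet,
    joint_p: float,
    joint_method: str,
) -> SubgroupReport:
    labels = assign_groups(cohort, cuts)
    rows = []
    for g in np.unique(labels):
        mask = labels == g
        km = km_estimate(cohort.T[mask], cohort.delta[mask])
        rows.append(
            {
                "group": int(g),
                "n": int(mask.sum()),
                "orr_pct": 100.0 * cohort.R[mask].sum() / mask.sum(),
                "median_survival": km.median,
                "km": km,
            }
        )
    lr_stat, lr_p = logrank_test(cohort.T, cohort.delta, labels)
    mw_stat, mw_p = mannwhitney_orr(cohort.R, labels)
    return SubgroupReport(
        table=pd.DataFrame(rows),
        logrank_stat=lr_stat,
        logrank_p=lr_p,
        mw_stat=mw_stat,
        mw_p=mw_p,
        joint_p=joint_p,
        joint_method=joint_method,
    )


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings (YAML/JSON serializable)."""

    search: SearchConfig = field(default_factory=SearchConfig)
    fit: FitOptions = field(default_factory=FitOptions)
    sigma_e: float = 0.0
    correction_method: str = "calibration"
    prob_mode: str = "eb"
    T0: float | None = None

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "search" in d:
            s = dict(d["search"])
            for key in ("k_range", "candidate_values", "quantile_band", "weights"):
                if key in s and s[key] is not None:
                    s[key] = tuple(s[key])
            d["search"] = SearchConfig(**s)
        if "fit" in d:
            d["fit"] = FitOptions(**d["fit"])
        return cls(**d)


@dataclass
class PipelineResult:
    """Artifacts of one full pipeline run."""

    fit_summary: dict
    probabilities: pd.DataFrame
    results: dict[int, SearchResult]
    k: int
    cuts: ThresholdSet
    p_trace: dict[int, float]
    report: SubgroupReport

    def to_dict(self) -> dict:
        return {
            "fit": self.fit_summary,
            "k": self.k,
            "thresholds": list(self.cuts.thresholds),
            "p_trace": {str(k): v for k, v in self.p_trace.items()},
            "per_k": {str(k): r.to_dict() for k, r in self.results.items()},
            "report": self.report.to_dict(),
        }


def _log(msg: str) -> None:
    print(f"[tmbcat] {msg}", file=sys.stderr)


def run_pipeline(
    cohort: Cohort | str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    verbose: bool = True,
) -> PipelineResult:
    """Execute the full TMB categorization pipeline.

    Stages: (error-corrected) joint-model fit; per-patient joint
    probabilities; exhaustive minimal-p search for each k in
    ``config.search.k_range`` (stopping early once adding a threshold no
    longer lowers the minimal p); stepwise choice of k; subgroup report.
    When ``out_dir`` is given, machine-readable JSON/CSV artifacts are
    written there.
    """
    config = config or PipelineConfig()
    if not isinstance(cohort, Cohort):
        cohort = read_cohort(cohort)
    log = _log if verbose else (lambda m: None)

    log(f"fitting joint model (n={cohort.n}, sigma_e={config.sigma_e})")
    if config.sigma_e > 0:
        fit = fit_corrected_joint_model(
            cohort, ErrorModel(config.sigma_e), config.fit, method=config.correction_method
        )
    else:
        fit = fit_joint_model(cohort, config.fit)

    T0 = config.T0 if config.T0 is not None else config.search.T0
    probs = joint_probabilities(
        fit, T0=T0, mode=config.prob_mode, weights=config.search.weights
    )
    log(f"joint probabilities computed (mode={config.prob_mode}, T0={T0 or fit.T_median:.3g})")

    results: dict[int, SearchResult] = {}
    prev_p = np.inf
    for k in sorted(config.search.k_range):
        try:
            res = search_thresholds(cohort, probs, config.search, k)
        except Exception as exc:
            log(f"k={k}: search infeasible ({exc}); stopping")
            break
        results[k] = res
        log(f"k={k}: best p={res.best_p:.4g} at {res.best.thresholds}")
        if res.best_p >= prev_p:
            break  # adding a subgroup no longer improves the minimal p
        prev_p = res.best_p
    if not results:
        raise RuntimeError("threshold search failed for every k in k_range")

    k_opt, cuts, trace = select_k(results)
    log(f"selected k={k_opt}, thresholds={cuts.thresholds}")
    rep = subgroup_report(cohort, cuts, results[k_opt].best_p, config.search.method)

    fit_summary = {
        "beta": fit.beta.tolist(),
        "alpha": fit.alpha,
        "gamma": fit.gamma,
        "Sigma": fit.Sigma.tolist(),
        "converged": fit.converged,
        "method": fit.method,
        "n_iter": fit.n_iter,
    }
    result = PipelineResult(fit_summary, probs, results, k_opt, cuts, trace, rep)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "result.json", "w") as fh:
            json.dump(result.to_dict(), fh, indent=1)
        probs.to_csv(out_dir / "joint_probabilities.csv", index=False)
        for k, res in results.items():
            g = res.grid.copy()
            g["thresholds"] = [";".join(f"{t:g}" for t in tt) for tt in g["thresholds"]]
            g.to_csv(out_dir / f"grid_k{k}.csv", index=False)
        km_rows = []
        for _, row in rep.table.iterrows():
            km = row["km"]
            for t, s in zip(km.times, km.survival):
                km_rows.append({"group": row["group"], "time": t, "survival": s})
        pd.DataFrame(km_rows).to_csv(out_dir / "km_curves.csv", index=False)
        log(f"artifacts written to {out_dir}")
    return result
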