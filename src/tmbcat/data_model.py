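"""Core domain types for TMB-categorization cohorts.

A cohort is a collection of per-patient records, each holding the two
immunotherapy endpoints — tumor response ``R`` (1 = CR/PR, 0 = SD/PD under
RECIST) and right-censored event time ``(T, delta)`` in months — together
with the observed tumor mutation burden (TMB, mut/Mb).  A ``ThresholdSet``
is an ordered vector of TMB cutpoints that partitions a cohort into
``k + 1`` risk subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "Cohort",
    "ThresholdSet",
    "CohortError",
    "read_cohort",
    "write_cohort",
    "assign_groups",
    "group_sizes",
]

#: default column names for cohort tables; override via the ``dialect``
#: argument of :func:`read_cohort`.
DEFAULT_DIALECT: dict[str, str] = {
    "id": "id",
    "R": "R",
    "T": "T",
    "delta": "delta",
    "tmb": "tmb",
    "tmb_sd": "tmb_sd",
}


class CohortError(ValueError):
    """Raised for malformed cohort tables or invalid domain values."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient's endpoints and observed TMB.

    Attributes
    ----------
    id : str
        Unique patient identifier.
    R : int
        Tumor response, 1 for CR/PR, 0 for SD/PD.
    T : float
        Observed time in months, ``min(T*, C)`` with ``T*`` the latent
        event time and ``C`` the censoring time.
    delta : int
        Event indicator; 1 means the event was observed at ``T``,
        0 means censored at ``T``.
    tmb : float
        Observed TMB in mutations per megabase (non-negative).
    """

    id: str
    R: int
    T: float
    delta: int
    tmb: float

    def __post_init__(self) -> None:
        if self.R not in (0, 1):
            raise CohortError(f"patient {self.id!r}: R must be 0 or 1, got {self.R!r}")
        if self.delta not in (0, 1):
            raise CohortError(
                f"patient {self.id!r}: delta must be 0 or 1, got {self.delta!r}"
            )
        if not np.isfinite(self.T) or self.T <= 0:
            raise CohortError(
                f"patient {self.id!r}: T must be finite and positive, got {self.T!r}"
            )
        if not np.isfinite(self.tmb) or self.tmb < 0:
            raise CohortError(
                f"patient {self.id!r}: tmb must be finite and >= 0, got {self.tmb!r}"
            )


@dataclass(frozen=True)
class Cohort:
    """Ordered collection of :class:`PatientRecord` with unique ids."""

    records: tuple[PatientRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise CohortError("a cohort needs at least 2 patients")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate patient ids: {dup}")

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    # array views used throughout the fitting code -------------------------
    @property
    def ids(self) -> np.ndarray:
        return np.array([r.id for r in self.records], dtype=object)

    @property
    def R(self) -> np.ndarray:
        return np.array([r.R for r in self.records], dtype=float)

    @property
    def T(self) -> np.ndarray:
        return np.array([r.T for r in self.records], dtype=float)

    @property
    def delta(self) -> np.ndarray:
        return np.array([r.delta for r in self.records], dtype=float)

    @property
    def tmb(self) -> np.ndarray:
        return np.array([r.tmb for r in self.records], dtype=float)

    @classmethod
    def from_arrays(
        cls,
        ids: Sequence[str] | None,
        R: Sequence[int],
        T: Sequence[float],
        delta: Sequence[int],
        tmb: Sequence[float],
    ) -> "Cohort":
        n = len(R)
        if ids is None:
            ids = [f"P{i + 1:04d}" for i in range(n)]
        recs = tuple(
            PatientRecord(str(ids[i]), int(R[i]), float(T[i]), int(delta[i]), float(tmb[i]))
            for i in range(n)
        )
        return cls(recs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "R": self.R.astype(int),
                "T": self.T,
                "delta": self.delta.astype(int),
                "tmb": self.tmb,
            }
        )

    def with_tmb(self, tmb: Sequence[float]) -> "Cohort":
        """Return a copy with TMB values replaced (e.g. after calibration)."""
        tmb = np.asarray(tmb, dtype=float)
        if tmb.shape != (self.n,):
            raise CohortError("replacement tmb must have one value per patient")
        recs = tuple(
            PatientRecord(r.id, r.R, r.T, r.delta, float(t))
            for r, t in zip(self.records, tmb)
        )
        return Cohort(recs)


@dataclass(frozen=True)
class ThresholdSet:
    """Ordered, strictly increasing vector of k TMB thresholds.

    Induces ``k + 1`` subgroups with the half-open convention: a patient
    whose TMB equals a threshold belongs to the *upper* group ("TMB-high"
    conventionally means TMB >= cutoff).
    """

    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        t = self.thresholds
        if len(t) < 1:
            raise CohortError("a ThresholdSet needs at least one threshold")
        if any(not np.isfinite(v) for v in t):
            raise CohortError("thresholds must be finite")
        if any(t[i] >= t[i + 1] for i in range(len(t) - 1)):
            raise CohortError(f"thresholds must be strictly increasing: {t}")

    @property
    def k(self) -> int:
        return len(self.thresholds)

    @classmethod
    def of(cls, values: Iterable[float]) -> "ThresholdSet":
        return cls(tuple(float(v) for v in values))


def assign_groups(tmb: "Cohort | Sequence[float]", cuts: ThresholdSet) -> np.ndarray:
    """Assign each patient a subgroup label in ``{1, ..., k + 1}``.

    Group 1 is ``(-inf, t1)``; group ``j + 1`` is ``[t_j, t_{j+1})``;
    group ``k + 1`` is ``[t_k, inf)``.  Labels are monotone in TMB.
    """
    if isinstance(tmb, Cohort):
        tmb = tmb.tmb
    x = np.asarray(tmb, dtype=float)
    return np.searchsorted(np.asarray(cuts.thresholds), x, side="right") + 1


def group_sizes(labels: np.ndarray, n_groups: int) -> np.ndarray:
    """Counts per group label 1..n_groups (zeros kept for empty groups)."""
    return np.bincount(np.asarray(labels, dtype=int), minlength=n_groups + 1)[1:]


def read_cohort(
    path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> Cohort:
    """Read a cohort table from CSV/TSV.

    Parameters
    ----------
    path : path-like
        File with one row per patient.
    dialect : mapping, optional
        Maps canonical field names (``id``, ``R``, ``T``, ``delta``,
        ``tmb``) to the column names used in the file.
    sep : str, optional
        Field separator; inferred from the file extension by default
        (``.tsv``/``.txt`` -> tab, otherwise comma).

    Raises
    ------
    CohortError
        If a required column is missing, or any row holds a non-parseable
        or out-of-domain value (the error names the offending rows).
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)

    required = ["id", "R", "T", "delta", "tmb"]
    missing = [cols[f] for f in required if cols[f] not in df.columns]
    if missing:
        raise CohortError(f"missing required column(s) {missing} in {path}")

    problems: list[str] = []
    records: list[PatientRecord] = []
    for idx, row in df.iterrows():
        try:
            raw = {f: row[cols[f]] for f in required}
            if any(pd.isna(v) for v in raw.values()):
                raise CohortError("missing required field")
            records.append(
                PatientRecord(
                    id=str(raw["id"]),
                    R=int(raw["R"]),
                    T=float(raw["T"]),
                    delta=int(raw["delta"]),
                    tmb=float(raw["tmb"]),
                )
            )
        except (CohortError, TypeError, ValueError) as exc:
            problems.append(f"row {idx}: {exc}")
    if problems:
        raise CohortError(
            "rejected rows in cohort file:\n  " + "\n  ".join(problems)
        )
    return Cohort(tuple(records))


def write_cohort(cohort: Cohort, path, sep: str | None = None) -> None:
    """Write a cohort to CSV/TSV (round-trips with :func:`read_cohort`)."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    cohort.to_frame().to_csv(path, sep=sep, index=False)
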