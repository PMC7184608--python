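"""Synthetic behavioral cohorts with the structure of the study's
descriptive table: per-subject working-memory (AOSPAN absolute) scores,
per-condition workload-index means, planning times and error counts.

Defaults reproduce the *structure* of the published descriptives — a
21-subject cohort whose AOSPAN absolute scores straddle a median near
43, workload-index means around 57–65 index points, log-normal planning
times, and right-skewed (zero-inflated) error counts — without claiming
the underlying human data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import median_split

__all__ = [
    "CONDITIONS",
    "TOH_CONDITIONS",
    "LEARNING_CONDITIONS",
    "MAIN_CONDITIONS",
    "SubjectRecord",
    "CohortSpec",
    "generate_cohort",
    "cohort_to_dataframe",
    "cohort_to_json",
    "cohort_from_json",
]

LEARNING_CONDITIONS = ("toh_learning_5", "toh_learning_6", "toh_learning_7")
MAIN_CONDITIONS = ("toh_main_7", "toh_main_11", "toh_main_15")
TOH_CONDITIONS = LEARNING_CONDITIONS + MAIN_CONDITIONS
CONDITIONS = ("aospan_whole", "toh_whole") + TOH_CONDITIONS

# (mean, SD) of the DFHM index per condition and WM-capacity group; the
# whole-task rows are cohort-level (identical for both groups).
DEFAULT_INDEX_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "aospan_whole": {"lower": (57.5, 6.0), "higher": (57.5, 6.0)},
    "toh_whole": {"lower": (62.5, 7.4), "higher": (62.5, 7.4)},
    "toh_learning_5": {"lower": (63.0, 6.9), "higher": (65.4, 10.3)},
    "toh_learning_6": {"lower": (62.9, 7.8), "higher": (61.8, 11.1)},
    "toh_learning_7": {"lower": (64.9, 8.1), "higher": (60.7, 9.0)},
    "toh_main_7": {"lower": (63.9, 8.0), "higher": (60.2, 10.7)},
    "toh_main_11": {"lower": (63.4, 6.1), "higher": (63.1, 11.4)},
    "toh_main_15": {"lower": (64.3, 5.8), "higher": (64.4, 10.0)},
}

# (mean, SD) of planning time in seconds, natural scale, TOH trials only.
DEFAULT_PLANNING_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "toh_learning_5": {"lower": (22.5, 16.2), "higher": (20.5, 12.2)},
    "toh_learning_6": {"lower": (14.1, 9.6), "higher": (16.2, 11.8)},
    "toh_learning_7": {"lower": (20.3, 13.4), "higher": (15.7, 11.2)},
    "toh_main_7": {"lower": (10.9, 7.8), "higher": (15.3, 9.7)},
    "toh_main_11": {"lower": (20.1, 17.7), "higher": (16.5, 13.4)},
    "toh_main_15": {"lower": (18.8, 10.4), "higher": (19.4, 15.7)},
}

# mean error (restart) counts per TOH trial and group.
DEFAULT_ERROR_MEANS: dict[str, dict[str, float]] = {
    "toh_learning_5": {"lower": 1.2, "higher": 0.9},
    "toh_learning_6": {"lower": 0.6, "higher": 0.5},
    "toh_learning_7": {"lower": 1.0, "higher": 0.6},
    "toh_main_7": {"lower": 0.2, "higher": 0.2},
    "toh_main_11": {"lower": 1.1, "higher": 0.6},
    "toh_main_15": {"lower": 2.6, "higher": 1.0},
}


@dataclass
class SubjectRecord:
    subject_id: int
    aospan_score: int
    wm_group: str  # "lower" | "higher", recomputable from scores
    index: dict[str, float]
    planning_time: dict[str, float]
    errors: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "aospan_score": self.aospan_score,
            "wm_group": self.wm_group,
            "index": self.index,
            "planning_time": self.planning_time,
            "errors": self.errors,
        }


@dataclass(frozen=True)
class CohortSpec:
    """Distributional parameters of a synthetic cohort.

    ``index_rho`` is the within-subject correlation of the workload index
    across conditions (a shared subject-level random effect): repeated
    measures on the same head are not independent, and the paired task
    contrast is only as sensitive as this correlation makes it.
    """

    n_subjects: int = 21
    index_params: dict = field(default_factory=lambda: DEFAULT_INDEX_PARAMS)
    planning_params: dict = field(default_factory=lambda: DEFAULT_PLANNING_PARAMS)
    error_means: dict = field(default_factory=lambda: DEFAULT_ERROR_MEANS)
    error_zero_inflation: float = 0.4
    index_rho: float = 0.6
    aospan_center: float = 43.0
    aospan_sd: float = 12.0
    aospan_score_range: tuple[int, int] = (0, 75)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not 0 <= self.index_rho < 1:
            raise ValueError("index_rho must lie in [0, 1)")
        if not 0 <= self.error_zero_inflation < 1:
            raise ValueError("error_zero_inflation must lie in [0, 1)")
        for cond, groups in self.index_params.items():
            for grp, (m, s) in groups.items():
                if not (0 <= m <= 100) or s < 0:
                    raise ValueError(f"bad index params for {cond}/{grp}")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Natural-scale (mean, sd) → log-scale (mu, sigma)."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _draw_distinct_scores(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    """Integer scores, made pairwise distinct whenever the range allows it
    (distinctness forces the clean below-median split at odd n)."""
    lo, hi = spec.aospan_score_range
    scores = np.round(rng.normal(spec.aospan_center, spec.aospan_sd, spec.n_subjects))
    scores = np.clip(scores, lo, hi).astype(int)
    if spec.n_subjects > hi - lo + 1:
        return scores  # not enough integers to deduplicate
    seen: set[int] = set()
    for i in range(scores.size):
        s = int(scores[i])
        if s in seen:
            # nearest free integer, preferring the smaller offset
            for offset in range(1, hi - lo + 1):
                for cand in (s + offset, s - offset):
                    if lo <= cand <= hi and cand not in seen:
                        s = cand
                        break
                else:
                    continue
                break
        scores[i] = s
        seen.add(s)
    return scores


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw a cohort of :class:`SubjectRecord` from a :class:`CohortSpec`.

    WM-capacity groups are assigned by the strictly-below-median rule on the
    AOSPAN absolute scores, then every per-condition quantity is drawn from
    that group's parameters. Workload-index draws share a per-subject random
    effect (correlation ``index_rho`` across conditions); planning times are
    log-normal; error counts are zero-inflated Poisson.
    """
    rng = np.random.default_rng(spec.seed)
    scores = _draw_distinct_scores(rng, spec)
    labels, _ = median_split(scores)
    a, b = np.sqrt(spec.index_rho), np.sqrt(1.0 - spec.index_rho)
    records: list[SubjectRecord] = []
    for sid in range(spec.n_subjects):
        grp = str(labels[sid])
        z_subject = rng.standard_normal()
        index: dict[str, float] = {}
        for cond in CONDITIONS:
            m, s = spec.index_params[cond][grp]
            val = m + s * (a * z_subject + b * rng.standard_normal())
            index[cond] = float(np.clip(val, 0.0, 100.0))
        planning: dict[str, float] = {}
        for cond, groups in spec.planning_params.items():
            m, s = groups[grp]
            if s == 0:
                planning[cond] = float(m)
            else:
                mu, sigma = _lognormal_params(m, s)
                planning[cond] = float(rng.lognormal(mu, sigma))
        errors: dict[str, int] = {}
        for cond, groups in spec.error_means.items():
            mean = groups[grp]
            lam = mean / (1.0 - spec.error_zero_inflation)
            if rng.random() < spec.error_zero_inflation:
                errors[cond] = 0
            else:
                errors[cond] = int(rng.poisson(lam))
        records.append(
            SubjectRecord(
                subject_id=sid,
                aospan_score=int(scores[sid]),
                wm_group=grp,
                index=index,
                planning_time=planning,
                errors=errors,
            )
        )
    return records


def cohort_to_dataframe(records: list[SubjectRecord]) -> pd.DataFrame:
    """Tidy long format: subject, group, condition, measure, value."""
    rows = []
    for r in records:
        for cond, v in r.index.items():
            rows.append((r.subject_id, r.wm_group, cond, "index", v))
        for cond, v in r.planning_time.items():
            rows.append((r.subject_id, r.wm_group, cond, "planning_time", v))
        for cond, v in r.errors.items():
            rows.append((r.subject_id, r.wm_group, cond, "errors", float(v)))
        rows.append((r.subject_id, r.wm_group, "aospan_whole", "aospan_score",
                     float(r.aospan_score)))
    return pd.DataFrame(rows, columns=["subject", "group", "condition", "measure", "value"])


def cohort_to_json(records: list[SubjectRecord], path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in records], fh, indent=1)


def cohort_from_json(path) -> list[SubjectRecord]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        SubjectRecord(
            subject_id=int(d["subject_id"]),
            aospan_score=int(d["aospan_score"]),
            wm_group=d["wm_group"],
            index={k: float(v) for k, v in d["index"].items()},
            planning_time={k: float(v) for k, v in d["planning_time"].items()},
            errors={k: int(v) for k, v in d["errors"].items()},
        )
        for d in payload
    ]
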