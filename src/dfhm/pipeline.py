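"""End-to-end orchestration: synthesize → condition → DFHM → classify →
index → per-condition averages → statistics, from one config, with a
reproducible report.

The per-subject session is laid out as a baseline segment followed by
one interval per condition (AOSPAN, then the six TOH trials). Each TOH
interval's duration is derived from the subject's behavioral record
(planning time plus executed moves at a fixed pace, restarts included),
so the EEG-task alignment comes from the behavioral data rather than
being fixed a priori.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import classify as clf
from .cohort import (
    CONDITIONS,
    LEARNING_CONDITIONS,
    MAIN_CONDITIONS,
    TOH_CONDITIONS,
    CohortSpec,
    SubjectRecord,
    generate_cohort,
)
from .features import DFHMExtractor
from .montage import standard_montage
from .preprocess import (
    RejectionCriteria,
    bandpass,
    decompose_ica,
    reject_artifacts,
    surface_laplacian,
    to_average_reference,
)
from .stats import (
    TestReport,
    bonferroni_posthoc,
    dunn_bonferroni,
    friedman_test,
    log_transform,
    mixed_anova,
    shapiro_gate,
    wilcoxon_signed_rank,
)
from .synthetic import (
    GeneratorConfig,
    WorkloadProfile,
    generate_eeg,
    generate_labeled_dfhm,
    profile_for_index,
)

__all__ = ["RunConfig", "RunReport", "run_all", "make_table1", "analyze_cohort"]

MIN_MOVES = {
    "toh_learning_5": 5,
    "toh_learning_6": 6,
    "toh_learning_7": 7,
    "toh_main_7": 7,
    "toh_main_11": 11,
    "toh_main_15": 15,
}


@dataclass(frozen=True)
class RunConfig:
    """Every tunable of an end-to-end run, in one place."""

    seed: int = 0
    n_subjects: int = 21
    # EEG branch
    use_eeg: bool = True
    sample_rate: float = 500.0
    noise_sd: float = 5.0
    artifact_rate: float = 0.0
    baseline_duration: float = 60.0
    aospan_duration: float = 30.0
    move_interval: float = 1.5  # seconds per executed move in the session layout
    max_condition_duration: float = 60.0
    min_condition_duration: float = 5.0
    filter_low: float = 0.5
    filter_high: float = 40.0
    filter_order: int = 100
    run_ica: bool = True
    ica_corr_threshold: float = 0.7
    # segmentation / features / index
    segment_length: float = 1.0
    segment_step: float = 0.5
    index_window: float = 6.0
    taper: str = "rect"
    # classifier calibration
    calibration_n_per_class: int = 200
    calibration_separation: float = 10.0
    chance_guard: float = 0.45  # CV accuracy below this → withhold statistics
    kernel: str = "rbf"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = str(path)
        if path.endswith(".toml"):
            import tomllib

            with open(path, "rb") as fh:
                payload = tomllib.load(fh)
        else:
            with open(path) as fh:
                payload = json.load(fh)
        return cls(**payload)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    config: dict
    config_hash: str
    subject_table: pd.DataFrame
    table1: pd.DataFrame
    stats: dict[str, dict]
    flags: list[str]
    stage_log: list[str]
    versions: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "config": self.config,
            "config_hash": self.config_hash,
            "subject_table": self.subject_table.to_dict(orient="records"),
            "table1": self.table1.to_dict(orient="records"),
            "stats": self.stats,
            "flags": self.flags,
            "stage_log": self.stage_log,
            "versions": self.versions,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


def _session_intervals(record: SubjectRecord, cfg: RunConfig) -> dict[str, tuple[float, float]]:
    """Condition intervals derived from the subject's behavioral record."""
    t = cfg.baseline_duration
    intervals = {"aospan_whole": (t, t + cfg.aospan_duration)}
    t += cfg.aospan_duration
    toh_start = t
    for cond in TOH_CONDITIONS:
        dur = record.planning_time[cond] + cfg.move_interval * (
            MIN_MOVES[cond] + 2 * record.errors[cond]
        )
        dur = float(np.clip(dur, cfg.min_condition_duration, cfg.max_condition_duration))
        intervals[cond] = (t, t + dur)
        t += dur
    intervals["toh_whole"] = (toh_start, t)
    return intervals


def _session_profile(
    record: SubjectRecord, intervals: dict[str, tuple[float, float]], cfg: RunConfig, seed: int
) -> WorkloadProfile:
    """Concatenate the baseline segment and per-condition latent profiles."""
    breaks = [0.0]
    levels: list[str] = []
    # generic baseline segment: held at the middle level
    breaks.append(cfg.baseline_duration)
    levels.append("moderate")
    ordered = ["aospan_whole"] + list(TOH_CONDITIONS)
    for k, cond in enumerate(ordered):
        t0, t1 = intervals[cond]
        sub = profile_for_index(
            record.index[cond], t1 - t0, step=cfg.segment_step, seed=seed + 17 * k
        )
        for b, lv in zip(sub.breaks[1:], sub.levels):
            breaks.append(t0 + b)
            levels.append(lv)
    return WorkloadProfile(breaks=tuple(breaks), levels=tuple(levels))


def _eeg_condition_indices(
    record: SubjectRecord, cfg: RunConfig, model: clf.WorkloadClassifier, seed: int
) -> dict[str, float]:
    """Full EEG branch for one subject: synthesize, condition, index, average."""
    intervals = _session_intervals(record, cfg)
    profile = _session_profile(record, intervals, cfg, seed)
    gen = GeneratorConfig(
        sample_rate=cfg.sample_rate,
        noise_sd=cfg.noise_sd,
        artifact_rate=cfg.artifact_rate,
        seed=seed,
    )
    rec = bandpass(
        generate_eeg(profile, gen), cfg.filter_low, cfg.filter_high, cfg.filter_order
    )
    if cfg.run_ica:
        decomp = decompose_ica(rec, seed=seed)
        rec = reject_artifacts(
            rec, decomp, RejectionCriteria(corr_threshold=cfg.ica_corr_threshold)
        )
    rec = to_average_reference(surface_laplacian(rec))
    extractor = DFHMExtractor(
        length=cfg.segment_length,
        step=cfg.segment_step,
        baseline_window=cfg.baseline_duration,
        taper=cfg.taper,
        enforce_preprocessing=cfg.run_ica,
    )
    X = extractor.fit(rec).transform(rec)
    labels = clf.classify(model, X, extractor.times_)
    series = clf.workload_index(labels, window=cfg.index_window)
    return clf.condition_average(series, intervals)


def analyze_cohort(table: pd.DataFrame) -> dict[str, dict]:
    """The statistical battery over a per-subject condition table.

    ``table`` columns: subject, group, condition, index, planning_time,
    errors (the latter two NaN outside TOH conditions). Every normality
    gate decision is logged in the corresponding report.
    """
    out: dict[str, dict] = {}

    def _pivot(measure: str, conds) -> pd.DataFrame:
        sub = table[table["condition"].isin(conds)]
        return sub.pivot_table(index="subject", columns="condition", values=measure)

    # -- hypothesis 1: TOH vs AOSPAN workload ------------------------------
    wide = _pivot("index", ["toh_whole", "aospan_whole"])
    diffs = wide["toh_whole"] - wide["aospan_whole"]
    gate, gate_rep = shapiro_gate(diffs)
    out["h1_gate"] = gate_rep.to_dict() | {"decision": gate}
    if gate == "non-normal":
        rep = wilcoxon_signed_rank(wide["aospan_whole"], wide["toh_whole"])
    else:
        from scipy import stats as sps

        t, p = sps.ttest_rel(wide["toh_whole"], wide["aospan_whole"])
        rep = TestReport(name="paired-t", statistic=float(t),
                         df=(len(wide) - 1,), p=float(p))
    rep.extras["direction"] = (
        "toh>aospan" if wide["toh_whole"].mean() > wide["aospan_whole"].mean()
        else "aospan>=toh"
    )
    out["h1_task_contrast"] = rep.to_dict()

    # -- hypotheses 2/3: learning and main phase ---------------------------
    groups = table.drop_duplicates("subject").set_index("subject")["group"]
    for phase, conds in (("learning", LEARNING_CONDITIONS), ("main", MAIN_CONDITIONS)):
        sub = table[table["condition"].isin(conds)].copy()

        anova = mixed_anova(sub, dv="index")
        anova.posthoc = bonferroni_posthoc(sub, dv="index", between="group")
        out[f"{phase}_index_anova"] = anova.to_dict()

        plog = sub.copy()
        plog["log_planning"] = log_transform(plog["planning_time"])
        gate_p, gate_rep_p = shapiro_gate(
            plog.pivot_table(index="subject", columns="condition",
                             values="log_planning").iloc[:, 0]
        )
        out[f"{phase}_planning_gate"] = gate_rep_p.to_dict() | {"decision": gate_p}
        anova_p = mixed_anova(plog, dv="log_planning")
        out[f"{phase}_planning_anova"] = anova_p.to_dict()

        for grp in sorted(sub["group"].unique()):
            ids = groups[groups == grp].index
            mat = (
                sub[sub["subject"].isin(ids)]
                .pivot_table(index="subject", columns="condition", values="errors")
                .reindex(columns=list(conds))
                .to_numpy()
            )
            fr = friedman_test(mat)
            fr.posthoc = dunn_bonferroni(mat)
            out[f"{phase}_errors_friedman_{grp}"] = fr.to_dict()
    return out


def _descriptive_cell(x: pd.Series) -> str:
    return (
        f"{x.mean():.1f} ± {x.std(ddof=1):.1f}, "
        f"{x.median():.1f} [{x.min():.1f}, {x.max():.1f}]"
    )


def make_table1(subject_table: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table shaped like the study's Table 1.

    Whole-task rows pool all subjects; each TOH trial row is split by
    WM-capacity group. Cells show mean ± SD, median [min, max]; a condition
    with no data gets an explicit gap marker.
    """
    if subject_table.empty:
        raise ValueError("empty cohort")
    rows = []
    for cond in CONDITIONS:
        sub = subject_table[subject_table["condition"] == cond]
        split = (
            [("all", sub)]
            if cond in ("aospan_whole", "toh_whole")
            else [(g, sub[sub["group"] == g]) for g in ("lower", "higher")]
        )
        for grp, chunk in split:
            row = {"condition": cond, "group": grp, "n": int(chunk["subject"].nunique())}
            for measure in ("index", "planning_time", "errors"):
                vals = chunk[measure].dropna() if measure in chunk else pd.Series(dtype=float)
                row[measure] = _descriptive_cell(vals) if len(vals) else "—"
            rows.append(row)
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> RunReport:
    """Execute every stage in the canonical order and assemble the report."""
    import sklearn

    from . import __version__

    log: list[str] = []
    flags: list[str] = []

    # stage 1: classifier calibration
    Xc, yc = generate_labeled_dfhm(
        config.calibration_n_per_class,
        config.calibration_separation,
        dim=14,
        seed=config.seed + 10,
    )
    model = clf.train(Xc, yc, seed=config.seed, kernel=config.kernel)
    log.append(f"calibration: cv_accuracy={model.cv_accuracy_:.3f}, C={model.C_}")
    withheld = model.cv_accuracy_ is not None and model.cv_accuracy_ < config.chance_guard
    if withheld:
        flags.append(
            "chance-level classification on calibration data; "
            "statistical conclusions withheld"
        )

    # stage 2: cohort
    cohort = generate_cohort(CohortSpec(n_subjects=config.n_subjects, seed=config.seed + 20))
    sizes = pd.Series([r.wm_group for r in cohort]).value_counts().to_dict()
    log.append(f"cohort: n={config.n_subjects}, groups={sizes}")

    # stage 3: per-subject EEG branch (or the behavioral draw directly)
    rows = []
    for i, record in enumerate(cohort):
        if config.use_eeg:
            idx = _eeg_condition_indices(record, config, model, seed=config.seed + 1000 + i)
        else:
            idx = record.index
        for cond in CONDITIONS:
            rows.append(
                {
                    "subject": record.subject_id,
                    "group": record.wm_group,
                    "condition": cond,
                    "index": idx[cond],
                    "planning_time": record.planning_time.get(cond, np.nan),
                    "errors": float(record.errors[cond]) if cond in record.errors else np.nan,
                    "aospan_score": record.aospan_score,
                }
            )
    subject_table = pd.DataFrame(rows)
    log.append(f"eeg branch: {'on' if config.use_eeg else 'off (behavioral draw)'}")

    # stage 4: descriptives and statistics
    table1 = make_table1(subject_table)
    stats = {} if withheld else analyze_cohort(subject_table)
    log.append("stats: " + ("withheld" if withheld else f"{len(stats)} reports"))

    return RunReport(
        config=asdict(config),
        config_hash=config.hash(),
        subject_table=subject_table,
        table1=table1,
        stats=stats,
        flags=flags,
        stage_log=log,
        versions={"dfhm": __version__, "sklearn": sklearn.__version__,
                  "numpy": np.__version__},
    )
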