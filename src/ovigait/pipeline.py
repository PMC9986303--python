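"""Study orchestration: simulate/load -> condition -> events -> kinematics -> stats.

``run_study`` reproduces the full analysis of a multi-session walking study
as one deterministic, config-driven run: it assembles a per-session study
table (from synthetic cohorts or from trial files), computes baseline
repeatability (ICC, raw and velocity-adjusted), pre/post mixed-model
contrasts, neuroscore summaries, and the post-stroke correlation PCA, and
writes every result with the configuration hash for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .events import EventSpec, detect_trial_events, extract_cycle
from .io import (
    BASELINE_SESSIONS, StudyTable, Trial, ValidationError, load_trial,
)
from .kinematics import trial_study_rows
from .neuroscore import load_score_sheets, scores_frame, subscore_summary
from .preprocess import FilterSpec, preprocess_trial
from .stats import (
    compare_groups, fit_prepost_lmm, icc_ak, pca_pipeline, velocity_adjust,
)

log = logging.getLogger("ovigait")

#: Measures carried through the default stats plan.
DEFAULT_ICC_MEASURES = (
    "mean_forward_velocity", "head_to_T1_vertical",
    "stance_duration", "swing_duration", "stride_duration",
)
DEFAULT_LMM_MEASURES = ("stance_duration", "swing_duration", "stride_duration")


@dataclass
class RunConfig:
    """Serializable description of one study run."""

    out_dir: str = "ovigait_run"
    seed: int = 0
    sessions: tuple[str, ...] = ("B1", "B2", "B3", "D3")
    baseline_sessions: tuple[str, ...] = BASELINE_SESSIONS
    post_session: str = "D3"
    n_animals: int = 24
    n_trials: int = 5
    simulate: bool = True
    trajectories: bool = False
    trial_dir: str | None = None          # used when simulate is False
    score_file: str | None = None
    filter_order: int = 4
    filter_cutoff: float = 10.0
    speed_threshold: float = 0.05
    min_phase_duration: float = 0.1
    max_lateral_range: float = 0.5        # m; straight-line walking guard
    icc_measures: tuple[str, ...] = DEFAULT_ICC_MEASURES
    lmm_measures: tuple[str, ...] = DEFAULT_LMM_MEASURES
    icc_bootstrap: int = 0                # 0 -> parametric CIs

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(order=self.filter_order, cutoff=self.filter_cutoff)

    def event_spec(self) -> EventSpec:
        return EventSpec(speed_threshold=self.speed_threshold,
                         min_phase_duration=self.min_phase_duration)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("sessions", "baseline_sessions", "icc_measures", "lmm_measures"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def straight_line_ok(trial: Trial, max_range_m: float) -> bool:
    """Trial-exclusion heuristic: T1's lateral range must stay bounded."""
    x = trial.marker("T1").positions[:, trial.axes.lateral]
    x = x[np.isfinite(x)]
    return bool((x.max() - x.min()) / 1000.0 <= max_range_m)


def process_trial(
    trial: Trial,
    filter_spec: FilterSpec = FilterSpec(),
    event_spec: EventSpec = EventSpec(),
) -> StudyTable:
    """Condition one trial, extract one cycle per limb, measure everything."""
    conditioned, _ = preprocess_trial(trial, filter_spec)
    events = detect_trial_events(conditioned, event_spec)
    ax = conditioned.axes
    cycles = {}
    for limb, evs in events.items():
        if len(evs) < 2:
            log.warning("%s/%s %s: no complete cycle; limb skipped",
                        trial.animal_id, trial.session, limb)
            continue
        hoof = conditioned.marker(f"DPHAL_{limb}")
        centre = float(np.mean(hoof.positions[:, ax.progression])) / 1000.0
        cycles[limb] = extract_cycle(evs, conditioned, limb, centre)
    return trial_study_rows(conditioned, cycles, event_spec)


def _measured_from_trials(trials: dict, config: RunConfig) -> StudyTable:
    tables = []
    excluded = 0
    for (animal, session, i), trial in sorted(trials.items()):
        if not straight_line_ok(trial, config.max_lateral_range):
            excluded += 1
            log.info("excluded %s/%s trial %d: lateral deviation", animal, session, i)
            continue
        tables.append(process_trial(trial, config.filter_spec(),
                                    config.event_spec()).df)
    if excluded:
        log.info("excluded %d trials by the straight-line rule", excluded)
    df = pd.concat(tables, ignore_index=True)
    mean = (df.groupby(["animal", "session", "limb", "measure", "units"],
                       sort=False, dropna=False)["value"].mean().reset_index())
    return StudyTable(mean[["animal", "session", "limb", "measure",
                            "value", "units"]])


def _icc_tables(table: StudyTable, config: RunConfig, seed: int) -> pd.DataFrame:
    rows = []
    for adjusted in (False, True):
        t = table
        for measure in config.icc_measures:
            if adjusted:
                if measure == "mean_forward_velocity":
                    continue
                t = velocity_adjust(table, measure)
            df = t.df
            sub = df[df["measure"] == measure]
            for limb, grp in sub.groupby("limb", dropna=False):
                wide = grp.pivot_table(index="animal", columns="session",
                                       values="value")
                cols = [s for s in config.baseline_sessions if s in wide.columns]
                if len(cols) < 2:
                    continue
                wide = wide[cols].dropna()
                if len(wide) < 3:
                    continue
                res = icc_ak(
                    wide,
                    ci_method="bootstrap" if config.icc_bootstrap else "parametric",
                    n_boot=config.icc_bootstrap or 2000,
                    seed=seed,
                )
                rows.append({
                    "measure": measure, "limb": limb,
                    "adjusted_for_velocity": adjusted,
                    "icc": res.icc, "ci_low": res.ci_low, "ci_high": res.ci_high,
                    "n": res.n_subjects, "k": res.k_raters,
                })
    return pd.DataFrame(rows)


def _lmm_tables(table: StudyTable, config: RunConfig) -> pd.DataFrame:
    rows = []
    for measure in config.lmm_measures:
        for limbs in (("FL_L", "FL_R"), ("HL_L", "HL_R")):
            present = set(table.df[table.df["measure"] == measure]["limb"])
            if not set(limbs) <= present:
                continue
            for adjusted in (False, True):
                try:
                    res = fit_prepost_lmm(
                        table, measure, limbs=limbs, adjust_velocity=adjusted,
                        baseline_sessions=config.baseline_sessions,
                        post_session=config.post_session,
                    )
                except ValidationError as exc:
                    log.warning("LMM %s %s: %s", measure, limbs, exc)
                    continue
                for _, c in res.contrasts.iterrows():
                    rows.append({
                        "measure": measure, "limb": c["limb"],
                        "adjusted_for_velocity": adjusted,
                        "estimate": c["estimate"], "ci_low": c["ci_low"],
                        "ci_high": c["ci_high"], "p": c["p"],
                        "animal_variance": res.animal_variance,
                        "residual_variance": res.residual_variance,
                    })
    return pd.DataFrame(rows)


def _pca_inputs(table: StudyTable, neuro: pd.DataFrame,
                infarcts: pd.Series, config: RunConfig) -> pd.DataFrame:
    """Post-stroke per-animal variable table for the correlation PCA."""
    df = table.df
    post = df[df["session"] == config.post_session]
    cols = {}
    def grab(measure, limb, name):
        sub = post[(post["measure"] == measure) & (post["limb"] == limb)]
        cols[name] = sub.set_index("animal")["value"]

    grab("mean_forward_velocity", "", "mean_velocity")
    grab("head_to_T1_vertical", "", "mean_head_to_T1")
    grab("stance_duration", "FL_L", "stance_duration_left")
    grab("swing_duration", "FL_L", "swing_duration_left")
    grab("swing_duration", "FL_R", "swing_duration_right")
    out = pd.DataFrame(cols)
    totals = (neuro[neuro["session"] == config.post_session]
              .set_index("animal")["total"])
    out["total_neuroscore"] = totals
    out["infarct_volume"] = infarcts
    return out.dropna()


@dataclass
class StudyReport:
    config: RunConfig
    measured: StudyTable
    icc: pd.DataFrame
    lmm: pd.DataFrame | None
    neuro_summary: pd.DataFrame | None
    neuro_tests: pd.DataFrame | None
    pca: object | None

    def write(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        h = self.config.config_hash()
        with open(out_dir / "config.json", "w") as fh:
            json.dump({"config_hash": h, **self.config.to_dict()}, fh,
                      indent=2, default=list)
        self.measured.to_csv(out_dir / "study_table.csv")
        for name, df in (("icc.csv", self.icc), ("lmm_contrasts.csv", self.lmm),
                         ("neuroscore_summary.csv", self.neuro_summary),
                         ("neuroscore_tests.csv", self.neuro_tests)):
            if df is not None and len(df):
                df.assign(config_hash=h).to_csv(out_dir / name, index=False)
        if self.pca is not None:
            payload = {
                "config_hash": h,
                "retained_variables": self.pca.retained_variables,
                "kmo_overall": self.pca.kmo_overall,
                "kmo_per_variable": self.pca.kmo_per_variable.to_dict(),
                "bartlett": {"chi2": self.pca.bartlett_chi2,
                             "df": self.pca.bartlett_df,
                             "p": self.pca.bartlett_p},
                "eigenvalues": self.pca.eigenvalues.tolist(),
                "pct_variance": self.pca.pct_variance.tolist(),
                "n_components": self.pca.n_components,
                "loadings": self.pca.loadings.round(6).to_dict(),
                "pruned": self.pca.pruned,
                "kmo_excluded": self.pca.kmo_excluded,
            }
            with open(out_dir / "pca.json", "w") as fh:
                json.dump(payload, fh, indent=2)
        with open(out_dir / "report.md", "w") as fh:
            fh.write(self.markdown())

    def markdown(self) -> str:
        lines = [f"# Study run `{self.config.config_hash()}`", ""]
        lines.append(f"- animals: {self.config.n_animals}, sessions: "
                     f"{', '.join(self.config.sessions)}")
        lines.append(f"- measures in table: "
                     f"{self.measured.df['measure'].nunique()}")
        if len(self.icc):
            mod = self.icc[~self.icc["adjusted_for_velocity"]]
            lines += ["", "## Baseline repeatability (unadjusted ICC)", ""]
            for _, r in mod.iterrows():
                limb = r['limb'] or 'global'
                lines.append(f"- {r['measure']} [{limb}]: ICC {r['icc']:.2f} "
                             f"(95% CI {r['ci_low']:.2f} to {r['ci_high']:.2f})")
        if self.lmm is not None and len(self.lmm):
            lines += ["", "## Post-minus-pre contrasts (LMM)", ""]
            for _, r in self.lmm[~self.lmm["adjusted_for_velocity"]].iterrows():
                lines.append(f"- {r['measure']} [{r['limb']}]: "
                             f"{r['estimate']:.3f} (95% CI {r['ci_low']:.3f} "
                             f"to {r['ci_high']:.3f}), p={r['p']:.2g}")
        else:
            lines += ["", "## Post-minus-pre contrasts", "",
                      "skipped: no post-stroke session in this run"]
        if self.pca is not None:
            lines += ["", "## Principal component analysis", "",
                      "```", self.pca.summary(), "```"]
        return "\n".join(lines) + "\n"


def run_study(config: RunConfig) -> StudyReport:
    """Execute the full pipeline described by ``config`` (deterministic)."""
    rng_seed = int(config.seed)
    out_dir = Path(config.out_dir)
    neuro_frame = None
    neuro_summary = None
    neuro_tests = None
    infarcts = pd.Series(dtype=float)

    if config.simulate:
        cohort = synthetic.generate_cohort(
            n_animals=config.n_animals,
            sessions=config.sessions,
            effect_post=(synthetic.POST_STROKE_DAY3
                         if config.post_session in config.sessions else None),
            n_trials=config.n_trials,
            trajectories=config.trajectories,
            seed=rng_seed,
        )
        if config.trajectories:
            measured = _measured_from_trials(cohort.trials, config)
        else:
            measured = cohort.measured
        scores = load_score_sheets(cohort.neuroscores)
        infarcts = cohort.infarct_volumes
    else:
        if not config.trial_dir:
            raise ValidationError("trial_dir required when simulate is false")
        trials = {}
        for path in sorted(Path(config.trial_dir).glob("*.tsv")):
            trial = load_trial(path)
            key = (trial.animal_id, trial.session)
            trials[(trial.animal_id, trial.session,
                    sum(1 for k in trials if k[:2] == key))] = trial
        measured = _measured_from_trials(trials, config)
        scores = None
        if config.score_file:
            scores = load_score_sheets(pd.read_csv(config.score_file))

    if scores:
        neuro_frame = scores_frame(scores)
        if config.post_session in set(neuro_frame["session"]):
            neuro_summary = subscore_summary(
                scores, config.baseline_sessions, config.post_session)
            rows = []
            for sub, grp in neuro_summary.groupby("subscore"):
                stat, p = compare_groups(
                    [grp["mean_baseline"].to_numpy(), grp["post"].to_numpy()],
                    "mann_whitney")
                diff = grp["post"] - grp["mean_baseline"]
                rows.append({"subscore": sub, "median_difference": diff.median(),
                             "U": stat, "p": p})
            neuro_tests = pd.DataFrame(rows)

    icc = _icc_tables(measured, config, rng_seed)
    has_post = config.post_session in set(measured.df["session"])
    lmm = _lmm_tables(measured, config) if has_post else None
    pca = None
    if has_post and neuro_frame is not None and len(infarcts):
        inputs = _pca_inputs(measured, neuro_frame, infarcts, config)
        if len(inputs) >= 3:
            pca = pca_pipeline(inputs, sign_anchor="total_neuroscore")

    report = StudyReport(config=config, measured=measured, icc=icc, lmm=lmm,
                         neuro_summary=neuro_summary, neuro_tests=neuro_tests,
                         pca=pca)
    report.write(out_dir)
    return report
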