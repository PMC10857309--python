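"""End-to-end orchestration: simulate -> analyze -> report.

The analyze stage turns a dataset directory (per-subject event log plus
one gaze CSV per tracker) into a results directory of tidy CSV tables:

    qc_trials.csv        per-trial validity counts and exclusion reasons
    mean_curves.csv      grand-average V(t) per tracker x condition
    subject_curves.csv   per-subject condition-average V(t)
    window_summary.csv   initial/peak/delay means +- SD per condition
    subject_mi.csv       per-subject T, D and modulation index
    peak_scatter.csv     per-subject target vs distractor peak response
    quadrant_counts.csv  cross-tracker modulation-index sign table
    ttests.csv           two-tailed t contrasts, trial- and subject-level
    slopes.csv           OLS response slope of the mean curves

Figures are rendered from the exported CSVs, never from in-memory
state, so they are reproducible from the artifacts alone.  Every
excluded trial or subject appears in a QC table with a reason; nothing
is dropped silently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocessing as prep
from . import synth
from .errors import DataError, ReportError
from .gaze_io import EventLog, GazeRecording, GeometryConfig, read_event_log, read_gaze_csv
from .vergence import ModulationCurve, condition_average, delta_gamma, relative_modulation
from .window_stats import (
    WindowDefinition,
    SubjectSummary,
    response_slope,
    sign_quadrant_counts,
    subject_modulation_index,
    two_tailed_t,
    window_mean,
)

log = logging.getLogger(__name__)

def _read_csv(path: Path) -> pd.DataFrame:
    """Read a result CSV, treating a header-less empty file as an empty table."""
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


RESULT_FILES = (
    "qc_trials.csv", "mean_curves.csv", "subject_curves.csv", "window_summary.csv",
    "subject_mi.csv", "peak_scatter.csv", "quadrant_counts.csv", "ttests.csv",
    "slopes.csv",
)


@dataclass
class AnalysisConfig:
    """Bundle of every tunable the analysis stages consume."""

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    windows: WindowDefinition = field(default_factory=WindowDefinition)
    epoch_window: tuple[float, float] = prep.DEFAULT_EPOCH_WINDOW
    norm_window: tuple[float, float] = (0.0, 2000.0)
    exclusion_threshold: int = prep.EXCLUSION_THRESHOLD
    equal_var_ttest: bool = False
    trackers: tuple[str, ...] = ("ET", "WC")
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geometry"] = self.geometry.to_dict()
        d["windows"] = {k: list(v) for k, v in dataclasses.asdict(self.windows).items()}
        d["epoch_window"] = list(self.epoch_window)
        d["norm_window"] = list(self.norm_window)
        d["trackers"] = list(self.trackers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kw = dict(d)
        if "geometry" in kw:
            kw["geometry"] = GeometryConfig.from_dict(kw["geometry"])
        if "windows" in kw:
            kw["windows"] = WindowDefinition(**{k: tuple(v) for k, v in kw["windows"].items()})
        for key in ("epoch_window", "norm_window"):
            if key in kw:
                kw[key] = tuple(kw[key])
        if "trackers" in kw:
            kw["trackers"] = tuple(kw["trackers"])
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in kw.items() if k in known})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# simulate

def run_simulate(
    config: AnalysisConfig,
    params: synth.SimulationParams | None = None,
    outdir: str | Path = "dataset",
) -> Path:
    """Simulate a cohort and write it (plus a manifest) to ``outdir``."""
    params = params or synth.SimulationParams(seed=config.seed)
    cohort = synth.simulate_cohort(params, config.geometry)
    out = synth.write_cohort(cohort, outdir)
    log.info("simulated %d subjects x %d trackers into %s",
             params.n_subjects, len(params.trackers), out)
    return out


# ---------------------------------------------------------------------------
# analyze

def load_dataset(data_dir: str | Path, trackers: tuple[str, ...]) -> dict:
    """Load a dataset directory into per-subject event logs and recordings."""
    data_dir = Path(data_dir)
    subjects = sorted(p.name for p in data_dir.iterdir() if p.is_dir())
    if not subjects:
        raise DataError(f"no subject directories under {data_dir}")
    events: dict[str, EventLog] = {}
    recordings: dict[tuple[str, str], GazeRecording] = {}
    for subject_id in subjects:
        sdir = data_dir / subject_id
        events[subject_id] = read_event_log(sdir / "events.csv")
        for tracker_id in trackers:
            recordings[(subject_id, tracker_id)] = read_gaze_csv(
                sdir / f"gaze_{tracker_id}.csv", tracker_id, subject_id)
    return {"subjects": subjects, "events": events, "recordings": recordings}


def curves_for_recording(
    recording: GazeRecording,
    events: EventLog,
    config: AnalysisConfig,
) -> tuple[list[ModulationCurve], list[prep.TrialEpoch]]:
    """Epoch one recording and normalise every retained trial into V(t)."""
    epochs = prep.build_epochs(
        recording, events, config.geometry,
        epoch_window=config.epoch_window, threshold=config.exclusion_threshold,
    )
    grid = prep.uniform_grid(config.epoch_window, recording.nominal_rate)
    onset_index = int(np.argmin(np.abs(grid)))
    curves = [
        relative_modulation(
            e.gamma, e.t_rel, onset_index, config.norm_window,
            condition=e.condition, subject_id=e.subject_id,
            tracker_id=e.tracker_id, trial_index=e.trial_index,
        )
        for e in epochs if not e.excluded
    ]
    return curves, epochs


def _subject_tables(summaries: list[SubjectSummary]) -> tuple[pd.DataFrame, pd.DataFrame]:
    mi_rows, scatter_rows = [], []
    for s in summaries:
        mi_rows.append(
            {
                "subject_id": s.subject_id, "tracker_id": s.tracker_id,
                "n_target": s.n_target, "n_distractor": s.n_distractor,
                "T": s.T, "D": s.D, "mi": s.mi, "reason": s.reason,
            }
        )
        scatter_rows.append(
            {
                "subject_id": s.subject_id, "tracker_id": s.tracker_id,
                "peak_target": s.window_means.get("target", {}).get("peak", math.nan),
                "peak_distractor": s.window_means.get("distractor", {}).get("peak", math.nan),
            }
        )
    return pd.DataFrame(mi_rows), pd.DataFrame(scatter_rows)


def _window_summary(
    trial_curves: dict, summaries: list[SubjectSummary], windows: WindowDefinition
) -> pd.DataFrame:
    """Table-1-style summary: mean +- SD per tracker x condition x window.

    SDs are reported both across trials (pooled) and across subjects,
    since either convention is defensible for a summary table.
    """
    rows = []
    for (tracker_id, condition), curves in sorted(trial_curves.items()):
        for name, win in windows.named().items():
            vals = np.array([window_mean(c, win) for c in curves])
            subj_means = [
                s.window_means[condition][name]
                for s in summaries
                if s.tracker_id == tracker_id and not math.isnan(
                    s.window_means.get(condition, {}).get(name, math.nan))
            ]
            rows.append(
                {
                    "tracker_id": tracker_id, "condition": condition, "window": name,
                    "mean_trials": vals.mean() if len(vals) else math.nan,
                    "sd_trials": vals.std(ddof=1) if len(vals) > 1 else math.nan,
                    "n_trials": len(vals),
                    "mean_subjects": np.mean(subj_means) if subj_means else math.nan,
                    "sd_subjects": np.std(subj_means, ddof=1) if len(subj_means) > 1 else math.nan,
                    "n_subjects": len(subj_means),
                }
            )
    return pd.DataFrame(rows)


def _ttest_table(
    trial_curves: dict, summaries: list[SubjectSummary], mi_df: pd.DataFrame,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Two-tailed t contrasts at both trial and subject level.

    Trial-level samples are per-trial window means; subject-level
    samples are per-subject means of the same quantity.
    """
    windows = config.windows
    rows = []

    def trial_vals(tracker, cond, win):
        curves = trial_curves.get((tracker, cond), [])
        return np.array([window_mean(c, win) for c in curves])

    def subj_vals(tracker, cond, name):
        return np.array([
            s.window_means[cond][name] for s in summaries
            if s.tracker_id == tracker
            and not math.isnan(s.window_means.get(cond, {}).get(name, math.nan))
        ])

    def add(contrast, level, a, b, paired):
        if len(a) < 2 or len(b) < 2:
            return
        t, p = two_tailed_t(a, b, paired=paired, equal_var=config.equal_var_ttest)
        rows.append({"contrast": contrast, "level": level, "paired": paired,
                     "t": t, "p": p, "n_a": len(a), "n_b": len(b)})

    for tracker in config.trackers:
        wn = windows.named()
        add(f"{tracker}: target peak vs target initial", "trial",
            trial_vals(tracker, "target", wn["peak"]),
            trial_vals(tracker, "target", wn["initial"]), paired=False)
        add(f"{tracker}: target delay vs target initial", "trial",
            trial_vals(tracker, "target", wn["delay"]),
            trial_vals(tracker, "target", wn["initial"]), paired=False)
        add(f"{tracker}: target peak vs distractor peak", "trial",
            trial_vals(tracker, "target", wn["peak"]),
            trial_vals(tracker, "distractor", wn["peak"]), paired=False)
        for name in wn:
            add(f"{tracker}: target {name} vs distractor {name}", "subject",
                subj_vals(tracker, "target", name),
                subj_vals(tracker, "distractor", name), paired=False)

    if len(config.trackers) >= 2:
        t1, t2 = config.trackers[:2]
        for name in windows.named():
            add(f"{t1} vs {t2}: target {name}", "subject",
                subj_vals(t1, "target", name), subj_vals(t2, "target", name),
                paired=False)
        wide = mi_df.pivot(index="subject_id", columns="tracker_id", values="mi").dropna()
        if len(wide) >= 2 and t1 in wide and t2 in wide:
            add(f"{t1} vs {t2}: modulation index", "subject",
                wide[t1].to_numpy(), wide[t2].to_numpy(), paired=True)
    return pd.DataFrame(rows)


def run_analyze(
    config: AnalysisConfig, data_dir: str | Path, outdir: str | Path = "results",
) -> Path:
    """Run the full analysis over a dataset directory; write result tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = load_dataset(data_dir, config.trackers)

    qc_frames, curve_rows, subj_curve_rows = [], [], []
    trial_curves: dict[tuple[str, str], list[ModulationCurve]] = {}
    summaries: list[SubjectSummary] = []

    for subject_id in ds["subjects"]:
        events = ds["events"][subject_id]
        for tracker_id in config.trackers:
            rec = ds["recordings"][(subject_id, tracker_id)]
            curves, epochs = curves_for_recording(rec, events, config)
            qc_frames.append(prep.qc_table(epochs))
            by_cond = {
                cond: [c for c in curves if c.condition == cond]
                for cond in ("target", "distractor")
            }
            for cond, cs in by_cond.items():
                trial_curves.setdefault((tracker_id, cond), []).extend(cs)
                if cs:
                    avg = condition_average(cs, cond)
                    for t, v in zip(avg.t_rel, avg.v):
                        subj_curve_rows.append(
                            {"subject_id": subject_id, "tracker_id": tracker_id,
                             "condition": cond, "t_rel": t, "v": v,
                             "n_trials": avg.n_trials})
            summary = subject_modulation_index(
                by_cond["target"], by_cond["distractor"], config.windows)
            summary.subject_id, summary.tracker_id = subject_id, tracker_id
            if summary.reason:
                log.warning("%s/%s: %s", subject_id, tracker_id, summary.reason)
            summaries.append(summary)

    slope_rows = []
    for (tracker_id, cond), curves in sorted(trial_curves.items()):
        if not curves:
            continue
        avg = condition_average(curves, cond)
        for t, v in zip(avg.t_rel, avg.v):
            curve_rows.append({"tracker_id": tracker_id, "condition": cond,
                               "t_rel": t, "v": v, "n_trials": avg.n_trials})
        # slope over the full post-onset analysis span, per mean curve,
        # both on V(t) (1/ms) and on the recovered gamma-gamma0 (deg/ms)
        win = (0.0, config.windows.delay[1])
        gamma_curve = ModulationCurve(
            avg.t_rel, delta_gamma(avg), avg.gamma0, 1.0, cond, avg.n_trials)
        slope_rows.append(
            {"tracker_id": tracker_id, "condition": cond,
             "window_start": win[0], "window_end": win[1],
             "slope_v_per_ms": response_slope(avg, win),
             "slope_deg_per_ms": response_slope(gamma_curve, win),
             "n_trials": avg.n_trials})

    mi_df, scatter_df = _subject_tables(summaries)
    window_df = _window_summary(trial_curves, summaries, config.windows)
    ttest_df = _ttest_table(trial_curves, summaries, mi_df, config)

    quad_rows = []
    if len(config.trackers) >= 2:
        t1, t2 = config.trackers[:2]
        wide = mi_df.pivot(index="subject_id", columns="tracker_id", values="mi")
        pairs = list(zip(wide.get(t1, pd.Series(dtype=float)),
                         wide.get(t2, pd.Series(dtype=float))))
        q = sign_quadrant_counts(pairs)
        f1, f2 = q.fraction_positive()
        quad_rows.append(
            {"tracker_1": t1, "tracker_2": t2,
             "both_positive": q.both_positive, "first_only": q.first_only,
             "second_only": q.second_only, "neither": q.neither,
             "n_missing": q.n_missing,
             "frac_positive_1": f1, "frac_positive_2": f2})

    tables = {
        "qc_trials.csv": pd.concat(qc_frames, ignore_index=True),
        "mean_curves.csv": pd.DataFrame(curve_rows),
        "subject_curves.csv": pd.DataFrame(subj_curve_rows),
        "window_summary.csv": window_df,
        "subject_mi.csv": mi_df,
        "peak_scatter.csv": scatter_df,
        "quadrant_counts.csv": pd.DataFrame(quad_rows),
        "ttests.csv": ttest_df,
        "slopes.csv": pd.DataFrame(slope_rows),
    }
    for name, df in tables.items():
        df.to_csv(outdir / name, index=False, float_format="%.10g")
    with open(outdir / "analysis_config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)
    make_figures(outdir)
    log.info("analysis written to %s", outdir)
    return outdir


# ---------------------------------------------------------------------------
# figures (from exported CSVs only)

def make_figures(results_dir: str | Path) -> list[Path]:
    """Render the standard figures from the result CSVs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results_dir = Path(results_dir)
    figdir = results_dir / "figures"
    figdir.mkdir(exist_ok=True)
    out = []

    curves = _read_csv(results_dir / "mean_curves.csv")
    if len(curves):
        trackers = sorted(curves["tracker_id"].unique())
        fig, axes = plt.subplots(1, len(trackers), figsize=(5 * len(trackers), 3.4),
                                 sharey=True, squeeze=False)
        for ax, tracker in zip(axes[0], trackers):
            for cond, color in (("target", "crimson"), ("distractor", "steelblue")):
                sub = curves[(curves.tracker_id == tracker) & (curves.condition == cond)]
                ax.plot(sub.t_rel, sub.v, color=color, label=cond)
            ax.axvline(0, color="gray", lw=0.7)
            ax.set(title=tracker, xlabel="time from stimulus onset (ms)")
            ax.legend(frameon=False)
        axes[0][0].set_ylabel("mean V(t)")
        fig.tight_layout()
        p = figdir / "mean_curves.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        out.append(p)

    scatter = _read_csv(results_dir / "peak_scatter.csv")
    trackers_present = sorted(scatter["tracker_id"].unique()) if len(scatter) else []
    for tracker in trackers_present:
        sub = scatter[scatter.tracker_id == tracker].dropna()
        if not len(sub):
            continue
        fig, ax = plt.subplots(figsize=(3.6, 3.6))
        ax.scatter(sub.peak_distractor, sub.peak_target, s=18, color="k")
        lim = max(sub[["peak_target", "peak_distractor"]].abs().max().max() * 1.1, 0.05)
        ax.plot([-lim, lim], [-lim, lim], color="gray", lw=0.7)
        ax.set(xlabel="distractor peak V", ylabel="target peak V", title=tracker,
               xlim=(-lim, lim), ylim=(-lim, lim))
        fig.tight_layout()
        p = figdir / f"peak_scatter_{tracker}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        out.append(p)

    mi = _read_csv(results_dir / "subject_mi.csv")
    quad = _read_csv(results_dir / "quadrant_counts.csv")
    if len(quad):
        t1, t2 = quad.loc[0, "tracker_1"], quad.loc[0, "tracker_2"]
        wide = mi.pivot(index="subject_id", columns="tracker_id", values="mi").dropna()
        if len(wide):
            fig, ax = plt.subplots(figsize=(3.6, 3.6))
            ax.scatter(wide[t1], wide[t2], s=18, color="k")
            ax.axhline(0, color="gray", lw=0.7)
            ax.axvline(0, color="gray", lw=0.7)
            ax.set(xlabel=f"mi ({t1})", ylabel=f"mi ({t2})")
            fig.tight_layout()
            p = figdir / "mi_scatter.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# report

def _fmt(x: float, nd: int = 4) -> str:
    return "nan" if (isinstance(x, float) and math.isnan(x)) else f"{x:.{nd}f}"


def run_report(results_dir: str | Path, out_path: str | Path | None = None) -> Path:
    """Assemble a deterministic markdown summary from the result tables."""
    results_dir = Path(results_dir)
    for name in ("window_summary.csv", "subject_mi.csv", "ttests.csv"):
        if not (results_dir / name).exists():
            raise ReportError(f"missing result file: {name}")
    window_df = _read_csv(results_dir / "window_summary.csv")
    mi_df = _read_csv(results_dir / "subject_mi.csv")
    ttest_df = _read_csv(results_dir / "ttests.csv")
    quad_path = results_dir / "quadrant_counts.csv"
    quad_df = _read_csv(quad_path) if quad_path.exists() else pd.DataFrame()
    qc_path = results_dir / "qc_trials.csv"
    qc_df = _read_csv(qc_path) if qc_path.exists() else pd.DataFrame()

    lines = ["# Cognitive vergence analysis report", ""]

    for tracker in sorted(window_df["tracker_id"].unique()):
        lines += [f"## Tracker {tracker}", ""]
        if len(qc_df):
            sub = qc_df[qc_df.tracker_id == tracker]
            lines += [
                f"- trials analysed: {int((~sub.excluded).sum())} retained, "
                f"{int(sub.excluded.sum())} excluded "
                f"(exclusion rate {_fmt(sub.excluded.mean(), 3)})",
                "",
            ]
        lines += ["| condition | initial | peak | delay |", "|---|---|---|---|"]
        wsub = window_df[window_df.tracker_id == tracker]
        for cond in ("target", "distractor"):
            row = {w: wsub[(wsub.condition == cond) & (wsub.window == w)] for w in
                   ("initial", "peak", "delay")}
            cells = [
                f"{_fmt(float(r['mean_trials'].iloc[0]))} ± {_fmt(float(r['sd_trials'].iloc[0]))}"
                if len(r) else "–" for r in row.values()
            ]
            lines.append(f"| {cond} | " + " | ".join(cells) + " |")
        lines.append("")
        msub = mi_df[(mi_df.tracker_id == tracker)]
        mi_vals = msub["mi"].dropna()
        n_undef = int(msub["mi"].isna().sum())
        if len(mi_vals):
            lines += [
                f"- modulation index: mean {_fmt(mi_vals.mean())} ± {_fmt(mi_vals.std(ddof=1))} "
                f"(n = {len(mi_vals)}, undefined = {n_undef}); "
                f"positive in {_fmt((mi_vals > 0).mean(), 3)} of subjects",
                "",
            ]

    if len(quad_df):
        q = quad_df.iloc[0]
        lines += [
            "## Cross-tracker modulation-index signs", "",
            f"- both positive: {int(q.both_positive)}",
            f"- {q.tracker_1} only: {int(q.first_only)}",
            f"- {q.tracker_2} only: {int(q.second_only)}",
            f"- neither: {int(q.neither)}",
            f"- missing either: {int(q.n_missing)}",
            f"- fraction positive {q.tracker_1}: {_fmt(q.frac_positive_1, 3)}, "
            f"{q.tracker_2}: {_fmt(q.frac_positive_2, 3)}",
            "",
        ]

    lines += ["## Two-tailed t-tests", "",
              "| contrast | level | t | p | n |", "|---|---|---|---|---|"]
    for row in ttest_df.itertuples(index=False):
        lines.append(
            f"| {row.contrast} | {row.level} | {_fmt(row.t, 3)} | {_fmt(row.p, 4)} "
            f"| {int(row.n_a)}/{int(row.n_b)} |")
    lines.append("")

    out_path = Path(out_path) if out_path else results_dir / "report.md"
    out_path.write_text("\n".join(lines))
    return out_path
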