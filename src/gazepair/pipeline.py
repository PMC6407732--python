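"""End-to-end analysis pipeline: events -> coordination -> statistics.

``run_pipeline`` consumes a session manifest written by
:func:`gazepair.io.write_session` (or by any recording software emitting
the same schemas), processes every trial through the event and
coordination layers, and writes tidy CSV outputs plus a run log. A
failing trial is logged and skipped; the pipeline continues and reports a
failure summary instead of aborting.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import coordination, events, grid as grid_mod, io, stats
from .aoi import flicker_metric
from .errors import GazepairError


@dataclass
class PipelineResult:
    out_dir: Path
    trial_metrics: pd.DataFrame
    condition_summary: pd.DataFrame
    entropy_table: pd.DataFrame
    comparisons: pd.DataFrame
    overlap_curves: pd.DataFrame
    failures: list = field(default_factory=list)

    @property
    def n_failures(self) -> int:
        return len(self.failures)


def _analyze_participant_trial(stream, partner_log, record, grid, detector):
    fixations = events.detect_fixations(stream, **detector)
    dwells = events.build_dwells(fixations, grid)
    params = events.eye_movement_params(fixations, dwells, record.rt)
    row = {
        "rt_s": record.rt,
        "correct": int(record.correct),
        "n_fixations": len(fixations),
        "n_dwells": len(dwells),
        "median_fixation_duration_s": params.median_fixation_duration,
        "median_saccade_amplitude_deg": params.median_saccade_amplitude,
        "dwell_rate_hz": params.dwell_rate,
        "median_transition_amplitude_deg": params.median_transition_amplitude,
        "overlooked_target": int(events.overlooked_target(dwells, record.target_hex)),
    }
    if partner_log is not None and len(dwells) > 0:
        row["overlap_proportion"] = coordination.dwell_overlap_proportion(dwells, partner_log)
        row["flicker_proportion"] = flicker_metric(partner_log)
    return row, dwells


def run_pipeline(
    manifest_path,
    out_dir,
    detector: dict | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> PipelineResult:
    """Run the full analysis over a session manifest and write tidy outputs.

    Outputs in ``out_dir``: ``trial_metrics.csv`` (one row per
    participant x trial), ``condition_summary.csv`` (performance and
    blind baseline), ``entropy.csv`` (dwell-distribution and transition
    entropies per condition x participant), ``comparisons.csv``
    (Wilcoxon / Kruskal-Wallis results), ``overlap_curves.csv``
    (aggregated cumulative overlap per condition), and ``run.log``.
    Deterministic for fixed inputs and seed.
    """
    detector = detector or {}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = io.read_manifest(manifest_path)
    base = Path(manifest["_base"])
    grid = grid_mod.read_grid_config(base / manifest["grid_config"])
    trial_log = io.read_trial_log(base / manifest["trial_log"])

    log_lines = [
        f"gazepair pipeline run at {datetime.datetime.now().isoformat()}",
        f"manifest: {manifest_path}",
        f"master_seed: {manifest['master_seed']}  analysis_seed: {seed}",
        f"detector: {detector or 'defaults'}  n_boot: {n_boot}",
    ]
    failures: list = []
    metric_rows: list[dict] = []
    dwell_store: dict[tuple, list] = {}  # (condition, participant) -> [dwell seqs]
    overlap_curves: dict[str, list] = {}
    records: dict[tuple, list] = {}  # (condition,) -> TrialRecord-likes

    def _record_from_row(row):
        from .data import TrialRecord

        return TrialRecord(
            condition=row["condition"],
            target_hex=int(row["target_hex"]),
            responder=row["responder"] or None,
            response_hex=int(row["response_hex"]) if row["response_hex"] >= 0 else None,
            rt=float(row["rt_s"]),
            correct=bool(row["correct"]),
            points_delta=int(row["points_delta"]),
        )

    # Individual condition ---------------------------------------------------
    for participant, entries in manifest.get("individual", {}).items():
        sub = trial_log[
            (trial_log["condition"] == "individual")
            & (trial_log["participant"] == participant)
        ].set_index("trial")
        for entry in entries:
            trial = entry["trial"]
            try:
                record = _record_from_row(sub.loc[trial])
                stream = io.read_gaze_csv(base / entry["gaze"], participant, trial)
                row, dwells = _analyze_participant_trial(stream, None, record, grid, detector)
                row.update(condition="individual", participant=participant, trial=trial)
                metric_rows.append(row)
                dwell_store.setdefault(("individual", participant), []).append(dwells)
                records.setdefault(("individual",), []).append(record)
            except (GazepairError, KeyError) as exc:
                failures.append(("individual", participant, trial, repr(exc)))

    # Paired conditions ------------------------------------------------------
    for cond, entries in manifest.get("pairs", {}).items():
        sub = trial_log[
            (trial_log["condition"] == cond) & (trial_log["participant"] == "pair")
        ].set_index("trial")
        for entry in entries:
            trial = entry["trial"]
            try:
                record = _record_from_row(sub.loc[trial])
                stream_a = io.read_gaze_csv(base / entry["gaze_a"], "a", trial)
                stream_b = io.read_gaze_csv(base / entry["gaze_b"], "b", trial)
                hl_a = io.read_highlight_csv(base / entry["highlight_a"])
                hl_b = io.read_highlight_csv(base / entry["highlight_b"])
                per_part = {}
                for participant, stream, partner_log in (
                    ("a", stream_a, hl_b),
                    ("b", stream_b, hl_a),
                ):
                    row, dwells = _analyze_participant_trial(
                        stream, partner_log, record, grid, detector
                    )
                    row.update(condition=cond, participant=participant, trial=trial)
                    metric_rows.append(row)
                    dwell_store.setdefault((cond, participant), []).append(dwells)
                    per_part[participant] = dwells
                records.setdefault((cond,), []).append(record)
                curve = coordination.cumulative_overlap_curve(
                    coordination.own_inspections(per_part["a"]),
                    coordination.partner_inspections(hl_b),
                    duration=record.rt,
                )
                overlap_curves.setdefault(cond, []).append(curve)
            except (GazepairError, KeyError) as exc:
                failures.append((cond, "pair", trial, repr(exc)))

    trial_metrics = pd.DataFrame(metric_rows)

    # Condition summaries and blind baseline ---------------------------------
    summary_rows = []
    for (cond,), recs in records.items():
        perf = coordination.performance_summary(recs)
        summary_rows.append(
            {
                "condition": cond,
                "median_rt_s": perf.median_rt,
                "error_rate": perf.error_rate,
                "targets_per_second_hz": perf.targets_per_second,
                "n_trials": perf.n_trials,
            }
        )
    indiv = manifest.get("individual", {})
    if len(indiv) == 2:
        labels = sorted(indiv)
        per_label = {
            lab: [
                _record_from_row(r)
                for _, r in trial_log[
                    (trial_log["condition"] == "individual")
                    & (trial_log["participant"] == lab)
                ].iterrows()
            ]
            for lab in labels
        }
        baseline = coordination.blind_baseline(
            per_label[labels[0]], per_label[labels[1]], *labels
        )
        if baseline.n_matched:
            perf = coordination.performance_summary(baseline.trials)
            summary_rows.append(
                {
                    "condition": "blind_baseline",
                    "median_rt_s": perf.median_rt,
                    "error_rate": perf.error_rate,
                    "targets_per_second_hz": perf.targets_per_second,
                    "n_trials": perf.n_trials,
                }
            )
        log_lines.append(f"blind baseline matched trials: {baseline.n_matched}")
    condition_summary = pd.DataFrame(summary_rows)

    # Entropies per condition x participant ----------------------------------
    entropy_rows = []
    for (cond, participant), seqs in dwell_store.items():
        dc = coordination.dwell_counts(seqs, grid.n_elements)
        tm = coordination.transition_counts(seqs, grid.n_elements)
        if dc.sum() == 0 or tm.sum() == 0:
            continue
        te = coordination.transition_entropy(tm)
        entropy_rows.append(
            {
                "condition": cond,
                "participant": participant,
                "h_dwell_bits": coordination.dwell_distribution_entropy(dc),
                "h_transition_conditional_bits": te.conditional,
                "h_transition_joint_bits": te.joint,
                "n_dwells": int(dc.sum()),
                "n_transitions": int(tm.sum()),
            }
        )
    entropy_table = pd.DataFrame(entropy_rows)

    # Condition comparisons --------------------------------------------------
    comparison_rows = []
    if not trial_metrics.empty:
        conds = [c for c in trial_metrics["condition"].unique()]
        if len(conds) >= 2:
            rt_groups = [
                trial_metrics.loc[trial_metrics["condition"] == c, "rt_s"].to_numpy()
                for c in conds
            ]
            comparison_rows.append(
                {
                    "comparison": "rt across " + "/".join(conds),
                    "test": "kruskal_eta2",
                    "result": stats.kruskal_eta2(*rt_groups),
                }
            )
        paired = [c for c in conds if c in ("collaborate", "compete")]
        if len(paired) == 2:
            med = trial_metrics.pivot_table(
                index="trial", columns="condition", values="dwell_rate_hz", aggfunc="mean"
            ).dropna()
            if len(med) >= 5:
                comparison_rows.append(
                    {
                        "comparison": "dwell rate collaborate vs compete",
                        "test": "wilcoxon_psdep",
                        "result": stats.wilcoxon_psdep(
                            med["compete"].to_numpy(), med["collaborate"].to_numpy()
                        ),
                    }
                )
    comparisons = (
        stats.comparison_table(comparison_rows) if comparison_rows else pd.DataFrame()
    )

    # Aggregated overlap curves ----------------------------------------------
    curve_rows = []
    for cond, curves in overlap_curves.items():
        agg = coordination.aggregate_overlap_curves(curves, n_boot=n_boot, seed=seed)
        curve_rows.append(
            pd.DataFrame(
                {
                    "condition": cond,
                    "time_s": agg.time,
                    "mean": agg.mean,
                    "lo": agg.lo,
                    "hi": agg.hi,
                    "n_alive": agg.n_alive,
                }
            )
        )
    overlap_table = pd.concat(curve_rows, ignore_index=True) if curve_rows else pd.DataFrame()

    # Write outputs ----------------------------------------------------------
    trial_metrics.to_csv(out / "trial_metrics.csv", index=False)
    condition_summary.to_csv(out / "condition_summary.csv", index=False)
    entropy_table.to_csv(out / "entropy.csv", index=False)
    comparisons.to_csv(out / "comparisons.csv", index=False)
    overlap_table.to_csv(out / "overlap_curves.csv", index=False)
    if failures:
        log_lines.append(f"FAILED trials ({len(failures)}):")
        log_lines.extend(f"  {cond}/{who} trial {trial}: {msg}" for cond, who, trial, msg in failures)
    else:
        log_lines.append("all trials processed")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")

    return PipelineResult(
        out_dir=out,
        trial_metrics=trial_metrics,
        condition_summary=condition_summary,
        entropy_table=entropy_table,
        comparisons=comparisons,
        overlap_curves=overlap_table,
        failures=failures,
    )
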