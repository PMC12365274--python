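"""End-to-end orchestration: simulate/load -> detect -> validate -> classify
-> aggregate -> test, with per-stage logging and reproducible seeding.

Every stage's row counts and every exclusion are logged; a fixed (config,
seed) pair reproduces the full artifact bundle bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import behaviour, classify, events, validate
from .design import DesignSpec, TrialDesign, designs_to_frame, frame_to_designs
from .events import DetectorParams
from .geometry import GazeTrial, ScreenGeometry, read_gaze_table, write_gaze_table
from .simulate import (FeatureLayout, ParticipantSession, SimulationTruth,
                       iter_simulated_participants, simulate_trial, simulate_response)
from .stats import IncompleteDesignError, RepeatedMeasuresAnova, paired_posthocs
from .validate import ValidationParams

log = logging.getLogger("gazeshift")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "make_fixtures"]


@dataclass
class PipelineConfig:
    mode: str = "simulate"                      # "simulate" | "analyze"
    spec: DesignSpec = field(default_factory=DesignSpec.exp1)
    truth: SimulationTruth = field(default_factory=SimulationTruth)
    layout: FeatureLayout = field(default_factory=FeatureLayout)
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry.exp1)
    detector: DetectorParams = field(default_factory=DetectorParams)
    validation: ValidationParams = field(default_factory=ValidationParams)
    classification: "classify.ClassificationParams" = field(
        default_factory=lambda: classify.ClassificationParams())
    n_participants: int = 4
    seed: int = 0
    save_gaze: bool = False
    design_path: str | None = None              # analyze mode inputs
    gaze_path: str | None = None
    response_path: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "analyze":
            for name in ("design_path", "gaze_path", "response_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"analyze mode requires existing {name} ({p})")

    @property
    def factors(self) -> list[str]:
        pairs = [("emotion", self.spec.emotions),
                 ("orientation", self.spec.orientations),
                 ("presentation_time_ms", self.spec.presentation_times_ms),
                 ("initial_fixation", self.spec.fixation_locations)]
        return [name for name, levels in pairs if len(levels) > 1]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = dict(raw)
        for key, typ in (("spec", DesignSpec), ("truth", SimulationTruth),
                         ("layout", FeatureLayout), ("geometry", ScreenGeometry),
                         ("detector", DetectorParams), ("validation", ValidationParams),
                         ("classification", classify.ClassificationParams)):
            if key in kw and isinstance(kw[key], dict):
                sub = kw[key]
                for f in ("emotions", "orientations", "presentation_times_ms",
                          "fixation_locations", "latency_window_ms", "trial_span_ms",
                          "outlier_offset_range_sd", "baseline_window_ms",
                          "blink_exclusion_window_ms", "window_ms"):
                    if f in sub and isinstance(sub[f], list):
                        sub[f] = tuple(sub[f])
                if "confusion" in sub:
                    sub["confusion"] = np.asarray(sub["confusion"], dtype=float)
                kw[key] = typ(**sub)
        return cls(**kw)


@dataclass
class PipelineResult:
    outcomes: pd.DataFrame                # one row per trial
    cell_summaries: pd.DataFrame          # per participant x cell
    hu: pd.DataFrame                      # unbiased hit rates
    anovas: dict[str, pd.DataFrame]
    posthocs: dict[str, pd.DataFrame]
    run_log: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.outcomes.to_csv(out / "outcomes.csv", index=False)
        self.cell_summaries.to_csv(out / "cell_summaries.csv", index=False)
        self.hu.to_csv(out / "hu.csv", index=False)
        for name, tab in self.anovas.items():
            tab.to_csv(out / f"anova_{name}.csv", index=False)
        for name, tab in self.posthocs.items():
            tab.to_csv(out / f"posthoc_{name}.csv", index=False)
        with open(out / "run.json", "w") as fh:
            json.dump(self.run_log, fh, indent=2, default=str)


def _process_participant(session_trials: Sequence[GazeTrial], detector: DetectorParams,
                         validation: ValidationParams,
                         classification: "classify.ClassificationParams") -> pd.DataFrame:
    """Detect events, validate and classify one participant's trials."""
    blinks_all, first_rows = [], []
    for trial in session_trials:
        blinks = events.detect_blinks(trial, detector)
        saccades = events.detect_saccades(trial, detector, blinks=blinks)
        blinks_all.append(blinks)
        first = classify.first_saccade(saccades, classification)
        d = trial.design
        cat = classify.classify_direction(first, d.initial_fixation, d.orientation,
                                          classification)
        first_rows.append({
            "participant": trial.participant_id, "trial": trial.trial_index,
            "emotion": d.emotion, "orientation": d.orientation,
            "presentation_time_ms": d.presentation_time_ms,
            "initial_fixation": d.initial_fixation,
            "first_saccade_category": cat,
            "first_saccade_onset_ms": np.nan if first is None else first.onset_ms,
            "first_saccade_vertical_deg": np.nan if first is None
            else first.vertical_component_deg,
            "end_x_deg": np.nan if first is None else first.end_deg[0],
            "end_y_deg": np.nan if first is None else first.end_deg[1],
        })
    verdicts = validate.validate_trials(session_trials, blinks_all, validation)
    out = verdicts.merge(pd.DataFrame(first_rows), on=["participant", "trial"])
    # category is defined only for valid trials
    out.loc[~out["valid"], "first_saccade_category"] = pd.NA
    return out


def _iter_sessions(config: PipelineConfig):
    if config.mode == "simulate":
        yield from iter_simulated_participants(
            config.spec, config.n_participants, config.truth, config.layout,
            config.geometry, config.seed)
        return
    designs = frame_to_designs(pd.read_csv(config.design_path))
    by_key = {(t.participant_id, t.trial_index): t for t in designs}
    trials = read_gaze_table(config.gaze_path, config.geometry, designs=by_key)
    responses = pd.read_csv(config.response_path)
    for pid in sorted({t.participant_id for t in trials}):
        p_trials = [t for t in trials if t.participant_id == pid]
        labels = responses[responses["participant"].astype(str) == pid].copy()
        yield ParticipantSession(pid, [t.design for t in p_trials], p_trials, labels)


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Execute the full analysis and return the artifact bundle."""
    outcome_frames = []
    gaze_sink = [] if (config.save_gaze and out_dir is not None) else None
    all_designs, all_responses = [], []

    for session in _iter_sessions(config):
        outc = _process_participant(session.trials, config.detector,
                                    config.validation, config.classification)
        resp = session.labels.loc[:, ["participant", "trial", "response", "rt_ms"]] \
            if "response" in session.labels.columns else None
        if resp is not None:
            outc = outc.merge(resp.assign(participant=resp["participant"].astype(str)),
                              on=["participant", "trial"], how="left")
            outc["correct"] = outc["response"] == outc["emotion"]
        log.info("participant %s: %d trials, %d valid", session.participant_id,
                 len(outc), int(outc["valid"].sum()))
        outcome_frames.append(outc)
        all_designs.extend(session.designs)
        if resp is not None:
            all_responses.append(resp)
        if gaze_sink is not None:
            gaze_sink.extend(session.trials)

    outcomes = pd.concat(outcome_frames, ignore_index=True)
    kept, excluded, fractions = validate.filter_participants(outcomes, config.validation)
    pct_excluded = float(100.0 * (1.0 - fractions["valid_fraction"]).mean())
    log.info("kept %d participants, excluded %s; mean %% trials excluded %.1f",
             len(kept), excluded or "none", pct_excluded)

    analysed = outcomes[outcomes["participant"].isin(kept)]
    factors = config.factors
    cells = classify.aggregate_cells(analysed, factors)
    confusion = behaviour.confusion_from_outcomes(
        analysed, [f for f in factors if f != "emotion"])
    hu = behaviour.hu_table(confusion, [f for f in factors if f != "emotion"])

    anovas, posthocs = {}, {}
    if len(kept) >= 2:
        try:
            res = RepeatedMeasuresAnova(cells, "proportion_toward", factors,
                                        "participant").fit()
            anovas["saccade_proportion"] = res.table
        except IncompleteDesignError as err:
            log.warning("saccade-proportion ANOVA skipped: %s", err)
        if "response" in analysed.columns and analysed["response"].notna().any():
            try:
                res = RepeatedMeasuresAnova(hu, "hu", factors, "participant").fit()
                anovas["unbiased_hit_rate"] = res.table
            except IncompleteDesignError as err:
                log.warning("hit-rate ANOVA skipped: %s", err)
        by_emotion = cells.groupby(["participant", "emotion"], observed=True)[
            "proportion_toward"].mean().reset_index()
        posthocs["emotion"] = paired_posthocs(by_emotion, "proportion_toward",
                                              "participant", "emotion")

    run_log = {
        "mode": config.mode, "seed": config.seed,
        "n_participants_in": int(fractions.shape[0]),
        "participants_kept": kept, "participants_excluded": excluded,
        "n_trials": int(len(outcomes)),
        "n_valid_trials": int(outcomes["valid"].sum()),
        "mean_pct_trials_excluded": pct_excluded,
        "exclusion_reasons": outcomes["exclusion_reason"].value_counts().to_dict(),
    }
    result = PipelineResult(outcomes, cells, hu, anovas, posthocs, run_log)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.write(out)
        designs_to_frame(all_designs).to_csv(out / "designs.csv", index=False)
        if all_responses:
            pd.concat(all_responses, ignore_index=True).to_csv(
                out / "responses.csv", index=False)
        if gaze_sink is not None:
            write_gaze_table(gaze_sink, out / "gaze.csv")
    return result


def make_fixtures(seed: int = 0, n_participants: int = 2
                  ) -> tuple[list[ParticipantSession], PipelineConfig]:
    """Deterministic tiny session (2 participants x 24 trials) for tests/docs.

    Forces at least one blink-excluded, one baseline-outlier, one toward and
    one opposite trial per participant, so every downstream code path runs.
    """
    spec = DesignSpec(orientations=("upright",), presentation_times_ms=(150,),
                      fixation_locations=("eyes", "mouth"), trials_per_cell=4,
                      faces_per_sex_per_cell=2, blocks=1)
    truth = SimulationTruth(p_toward=0.35)
    layout, geometry = FeatureLayout(), ScreenGeometry.exp1()
    config = PipelineConfig(spec=spec, truth=truth, layout=layout, geometry=geometry,
                            n_participants=n_participants, seed=seed)
    forced = {1: {"saccade": "toward"}, 2: {"saccade": "opposite"},
              3: {"blink": True}, 4: {"baseline_outlier": True}}
    sessions = []
    for p_idx in range(n_participants):
        pid = f"p{p_idx + 1:02d}"
        from .design import build_design
        designs = build_design(spec, np.random.SeedSequence([seed, p_idx, 0]),
                               participant_id=pid)
        trials, rows = [], []
        for trial_idx, d in enumerate(designs, start=1):
            ss = np.random.SeedSequence([seed, p_idx, 1, trial_idx])
            g_ss, r_ss = ss.spawn(2)
            gt, lab = simulate_trial(d, truth, layout, geometry,
                                     np.random.default_rng(g_ss),
                                     inject=forced.get(trial_idx))
            resp, rt = simulate_response(d, truth, np.random.default_rng(r_ss))
            lab.response, lab.rt_ms = resp, rt
            trials.append(gt)
            rows.append(lab.__dict__ | {"emotion": d.emotion,
                                        "initial_fixation": d.initial_fixation,
                                        "correct": resp == d.emotion})
        labels = pd.DataFrame(rows).rename(
            columns={"participant_id": "participant", "trial_index": "trial"})
        sessions.append(ParticipantSession(pid, designs, trials, labels))
    return sessions, config
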