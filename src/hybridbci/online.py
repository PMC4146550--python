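"""Closed-loop trial machinery: CopyTask and FreeMode.

CopyTask: trials are cued with a known class, the accumulated classifier
output gives continuous feedback, correctness is judged by the *sign* of
the accumulated output (no threshold), and after every trial both branch
LDAs are adapted with the known label.  No game actions are emitted.

FreeMode: cues are question marks (class unknown), the accumulated output
is gated by a decision threshold -- sub-threshold trials are "noDecision"
and emit nothing -- and every decided action is applied to the game.  No
adaptation is performed.

The classifier is evaluated on a sliding 1 s window every 100 ms within
the trial; the trial's accumulated output is the mean of these frame
scores.  All online filtering is causal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .classifiers import (
    NO_DECISION,
    DecisionPolicy,
    LDAModel,
    MetaClassifier,
    ShrinkageLDA,
    combine,
    decide,
    lda_score,
)
from .connect4 import Action, GameState, apply_action
from .eeg import BandDefinition, EpochSet, Recording, epoch
from .features import SpatialFilterBank, csp_logvar, fit_csp, logvar_features, lrp_features
from .preprocess import FilterSpec, bandpass, baseline_correct

__all__ = [
    "PipelineConfig",
    "TrialOutcome",
    "SessionLog",
    "HybridPipeline",
    "accumulate",
    "run_copy_task",
    "run_free_mode",
]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one session's processing."""

    osc_band: BandDefinition = field(
        default_factory=lambda: BandDefinition(8.0, 12.0, "alpha")
    )
    slow_band: BandDefinition = field(
        default_factory=lambda: BandDefinition(0.2, 4.0, "lrp")
    )
    osc_interval: tuple[float, float] = (500.0, 4500.0)  # ms within trial
    lrp_interval: tuple[float, float] = (2000.0, 5000.0)
    baseline_interval: tuple[float, float] = (-300.0, 0.0)
    trial_len: float = 5.0  # seconds
    n_csp: int = 6
    filter_order: int = 5
    adaptation_rate: float = 0.03
    theta: float = 0.0
    active_output: str = "combined"
    frame_window: float = 1.0  # seconds
    frame_step: float = 0.1
    cv_folds: int = 5
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["osc_band"] = [self.osc_band.lo, self.osc_band.hi]
        d["slow_band"] = [self.slow_band.lo, self.slow_band.hi]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("osc_band", "slow_band"):
            if key in d and not isinstance(d[key], BandDefinition):
                lo, hi = d[key][:2]
                d[key] = BandDefinition(float(lo), float(hi))
        for key in ("osc_interval", "lrp_interval", "baseline_interval"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TrialOutcome:
    cue: int  # 1, 2, or 0 for unknown
    accumulated: float
    decision: str  # action name or NO_DECISION
    correct: bool | None  # None when cue unknown or noDecision
    t_start: float  # seconds on the session clock
    t_end: float

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")


@dataclass
class SessionLog:
    outcomes: list[TrialOutcome]
    mode: str  # "CopyTask" | "FreeMode"
    pauses: float = 0.0  # total non-trial seconds within the session span
    config: dict = field(default_factory=dict)

    @property
    def elapsed(self) -> float:
        """Session span in seconds, pauses and noDecision time included."""
        if not self.outcomes:
            return 0.0
        return self.outcomes[-1].t_end - self.outcomes[0].t_start

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(o) for o in self.outcomes])

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def accumulate(scores) -> float:
    """Trial-level output: mean of the frame-wise classifier outputs."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("cannot accumulate an empty score sequence")
    return float(scores.mean())


class HybridPipeline:
    """The two-branch classification pipeline of the hybrid system.

    fit() trains, from a labeled (CopyTask) recording: CSP + shrinkage
    LDA on the band-passed oscillatory branch, and a shrinkage LDA on
    slow-potential mean amplitudes; branch outputs are scale-normalized
    and combined with weights proportional to each branch's
    cross-validated accuracy above chance.
    """

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()

    # -- training ----------------------------------------------------------

    def fit(self, rec: Recording) -> "HybridPipeline":
        cfg = self.config
        ep_osc, ep_slow = self._branch_epochs(rec)
        y = ep_osc.labels

        self.bank_ = fit_csp(ep_osc, cfg.osc_interval, n_components=cfg.n_csp)
        X_osc = csp_logvar(ep_osc, self.bank_, cfg.osc_interval)
        self.lda_osc_ = ShrinkageLDA(adaptation_rate=cfg.adaptation_rate)
        self.lda_osc_.fit(X_osc, y)

        X_slow = lrp_features(ep_slow, cfg.lrp_interval)
        self.lda_slow_ = ShrinkageLDA(adaptation_rate=cfg.adaptation_rate)
        self.lda_slow_.fit(X_slow, y)

        from .evaluation import crossval_accuracy  # local: avoids cycle

        mask = ep_osc.time_mask(cfg.osc_interval)
        acc_osc = crossval_accuracy(
            ep_osc.data[:, :, mask], y, n_folds=cfg.cv_folds,
            n_csp=cfg.n_csp, seed=cfg.seed,
        ).mean_accuracy
        acc_slow = crossval_accuracy(
            X_slow, y, n_folds=cfg.cv_folds, seed=cfg.seed
        ).mean_accuracy
        self.cv_accuracies_ = (acc_osc, acc_slow)
        self.meta_ = MetaClassifier.from_cv_accuracies(
            acc_osc, acc_slow,
            scales=(self.lda_osc_.score_scale_, self.lda_slow_.score_scale_),
            active_output=cfg.active_output,
        )
        return self

    def _branch_epochs(self, rec: Recording) -> tuple[EpochSet, EpochSet]:
        """Causally filtered, epoched views for the two branches."""
        cfg = self.config
        filt_osc, filt_slow = self._filter_stream(rec)
        window = (0.0, cfg.trial_len * 1000.0)
        cues = ("class1", "class2")
        ep_osc = epoch(filt_osc, cues, window)
        ep_slow = epoch(filt_slow, cues, (cfg.baseline_interval[0], window[1]))
        ep_slow = baseline_correct(ep_slow, cfg.baseline_interval)
        return ep_osc, ep_slow

    def _filter_stream(self, rec: Recording) -> tuple[Recording, Recording]:
        cfg = self.config
        spec_osc = FilterSpec("bandpass", cfg.osc_band, cfg.filter_order, "causal")
        spec_slow = FilterSpec("bandpass", cfg.slow_band, cfg.filter_order, "causal")
        return bandpass(rec, spec_osc), bandpass(rec, spec_slow)

    # -- online scoring ----------------------------------------------------

    def _frame_scores(
        self, filt_osc: Recording, filt_slow: Recording, onset: int,
        baseline: np.ndarray,
    ) -> np.ndarray:
        """Combined classifier output on sliding windows within one trial."""
        cfg = self.config
        fs = filt_osc.fs
        win = int(round(cfg.frame_window * fs))
        step = max(1, int(round(cfg.frame_step * fs)))
        trial_s = int(round(cfg.trial_len * fs))
        scores = []
        for stop in range(win, trial_s + 1, step):
            seg_osc = filt_osc.signal[None, :, onset + stop - win: onset + stop]
            seg_slow = (
                filt_slow.signal[:, onset + stop - win: onset + stop]
                - baseline[:, None]
            )
            f_osc = logvar_features(seg_osc, self.bank_)[0]
            f_slow = seg_slow.mean(axis=1)
            s_osc = lda_score(self.lda_osc_.model_, f_osc)
            s_slow = lda_score(self.lda_slow_.model_, f_slow)
            scores.append(combine(self.meta_, s_osc, s_slow))
        return np.asarray(scores)

    def _trial_features(
        self, filt_osc: Recording, filt_slow: Recording, onset: int,
        baseline: np.ndarray,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Features over the full classification intervals (for adaptation)."""
        cfg = self.config
        fs = filt_osc.fs

        def seg(rec_f, interval):
            a = onset + int(round(interval[0] * fs / 1000.0))
            b = onset + int(round(interval[1] * fs / 1000.0))
            return rec_f.signal[:, a:b]

        x_osc = logvar_features(seg(filt_osc, cfg.osc_interval)[None], self.bank_)[0]
        x_slow = (seg(filt_slow, cfg.lrp_interval) - baseline[:, None]).mean(axis=1)
        return x_osc, x_slow

    def _baseline(self, filt_slow: Recording, onset: int) -> np.ndarray:
        cfg = self.config
        fs = filt_slow.fs
        a = onset + int(round(cfg.baseline_interval[0] * fs / 1000.0))
        b = onset + int(round(cfg.baseline_interval[1] * fs / 1000.0))
        a = max(a, 0)
        if b <= a:
            return np.zeros(filt_slow.n_channels)
        return filt_slow.signal[:, a:b].mean(axis=1)

    # -- persistence -------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> dict:
        d = {
            "config": self.config.to_dict(),
            "bank": self.bank_.to_json(),
            "lda_osc": self.lda_osc_.model_.to_json(),
            "lda_slow": self.lda_slow_.model_.to_json(),
            "meta": {
                "weights": list(self.meta_.weights),
                "scales": list(self.meta_.scales),
                "active_output": self.meta_.active_output,
            },
            "cv_accuracies": list(getattr(self, "cv_accuracies_", (None, None))),
        }
        if path is not None:
            Path(path).write_text(json.dumps(d))
        return d

    @classmethod
    def from_json(cls, src: dict | str | Path) -> "HybridPipeline":
        if not isinstance(src, dict):
            src = json.loads(Path(src).read_text())
        pipe = cls(PipelineConfig.from_dict(src["config"]))
        pipe.bank_ = SpatialFilterBank.from_json(src["bank"])
        for attr, key in (("lda_osc_", "lda_osc"), ("lda_slow_", "lda_slow")):
            est = ShrinkageLDA(adaptation_rate=pipe.config.adaptation_rate)
            est.model_ = LDAModel.from_json(src[key])
            from .classifiers import AdaptationState

            est.adaptation_ = AdaptationState(rate=pipe.config.adaptation_rate)
            est.classes_ = np.array([1, 2])
            est.score_scale_ = 1.0
            pipe.__setattr__(attr, est)
        m = src["meta"]
        pipe.lda_osc_.score_scale_ = m["scales"][0]
        pipe.lda_slow_.score_scale_ = m["scales"][1]
        pipe.meta_ = MetaClassifier(
            weights=tuple(m["weights"]), scales=tuple(m["scales"]),
            active_output=m["active_output"],
        )
        return pipe


def _session_trials(stream: Recording, pipeline: HybridPipeline, cues):
    """Yield (marker, onset) for cue markers whose trial fits the stream."""
    cfg = pipeline.config
    trial_s = int(round(cfg.trial_len * stream.fs))
    usable = []
    truncated = 0
    for m in stream.markers:
        if m.label not in cues:
            continue
        if m.sample + trial_s > stream.n_samples:
            truncated += 1
            continue
        usable.append(m)
    if truncated:
        warnings.warn(
            f"stream shorter than cue schedule: {truncated} trial(s) truncated",
            stacklevel=3,
        )
    return usable


def run_copy_task(
    stream: Recording, pipeline: HybridPipeline, adaptation: bool = True
) -> SessionLog:
    """Run the cued, labeled, adaptive phase on a continuous stream.

    Correctness is sign-based: a trial is correct when the accumulated
    output points toward the cued class (negative = class 1).  With
    *adaptation* both branch LDAs receive a labeled per-trial update.
    """
    cfg = pipeline.config
    filt_osc, filt_slow = pipeline._filter_stream(stream)
    outcomes = []
    for m in _session_trials(stream, pipeline, ("class1", "class2")):
        onset = m.sample
        baseline = pipeline._baseline(filt_slow, onset)
        frames = pipeline._frame_scores(filt_osc, filt_slow, onset, baseline)
        acc = accumulate(frames)
        cue = 1 if m.label == "class1" else 2
        predicted = 2 if acc > 0 else 1
        outcomes.append(
            TrialOutcome(
                cue=cue,
                accumulated=acc,
                decision="sign",
                correct=bool(predicted == cue),
                t_start=onset / stream.fs,
                t_end=onset / stream.fs + cfg.trial_len,
            )
        )
        if adaptation:
            x_osc, x_slow = pipeline._trial_features(
                filt_osc, filt_slow, onset, baseline
            )
            pipeline.lda_osc_.adapt_one(x_osc, cue)
            pipeline.lda_slow_.adapt_one(x_slow, cue)
    pauses = _pause_time(outcomes)
    return SessionLog(
        outcomes=outcomes, mode="CopyTask", pauses=pauses,
        config=cfg.to_dict(),
    )


def run_free_mode(
    stream: Recording,
    pipeline: HybridPipeline,
    policy: DecisionPolicy,
    game: GameState | None = None,
    true_labels: np.ndarray | None = None,
    opponent=None,
) -> tuple[SessionLog, GameState]:
    """Threshold-gated free control of the game; never adapts.

    Trials are cued by "question" markers.  noDecision trials emit no
    action; decided actions are applied to the game (illegal placements
    are dropped by the game engine itself).  *true_labels*, when the user
    could report intents, fills in per-trial correctness.  *opponent* is
    an optional ``(board, player, rng) -> column`` policy that answers
    each successful user coin placement; pass a seeded closure for
    reproducibility.
    """
    opponent_rng = np.random.default_rng(0)
    cfg = pipeline.config
    game = game or GameState()
    filt_osc, filt_slow = pipeline._filter_stream(stream)
    n_adapt_before = (
        pipeline.lda_osc_.adaptation_.n_updates
        + pipeline.lda_slow_.adaptation_.n_updates
    )
    outcomes = []
    action_of = {
        policy.action_negative: Action.SELECT_NEXT_COLUMN,
        policy.action_positive: Action.PLACE_COIN,
    }
    for i, m in enumerate(_session_trials(stream, pipeline, ("question",))):
        onset = m.sample
        baseline = pipeline._baseline(filt_slow, onset)
        frames = pipeline._frame_scores(filt_osc, filt_slow, onset, baseline)
        acc = accumulate(frames)
        decision = decide(policy, acc)
        cue = 0
        correct: bool | None = None
        if true_labels is not None and i < len(true_labels):
            cue = int(true_labels[i])
            if decision != NO_DECISION:
                wanted = (
                    policy.action_negative if cue == 1 else policy.action_positive
                )
                correct = decision == wanted
        if decision != NO_DECISION and game.status == "ongoing":
            user = game.to_move
            game = apply_action(game, action_of[decision])
            if (
                opponent is not None
                and game.status == "ongoing"
                and game.to_move != user
            ):
                from .connect4 import drop_coin, winner_check

                col = opponent(game.board, game.to_move, opponent_rng)
                board = drop_coin(game.board, col, game.to_move)
                game = GameState(
                    board=board, to_move=user, cursor=game.cursor,
                    status=winner_check(board),
                )
        outcomes.append(
            TrialOutcome(
                cue=cue, accumulated=acc, decision=decision, correct=correct,
                t_start=onset / stream.fs,
                t_end=onset / stream.fs + cfg.trial_len,
            )
        )
    n_adapt_after = (
        pipeline.lda_osc_.adaptation_.n_updates
        + pipeline.lda_slow_.adaptation_.n_updates
    )
    assert n_adapt_after == n_adapt_before, "FreeMode must not adapt"
    log = SessionLog(
        outcomes=outcomes, mode="FreeMode", pauses=_pause_time(outcomes),
        config=cfg.to_dict(),
    )
    return log, game


def _pause_time(outcomes: list[TrialOutcome]) -> float:
    if len(outcomes) < 2:
        return 0.0
    span = outcomes[-1].t_end - outcomes[0].t_start
    return float(span - sum(o.t_end - o.t_start for o in outcomes))
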