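"""Turning class probabilities into suggestions and learning from feedback.

The decision rule is selective: with winning probability ``p_max``,

* ``p_max < tBG``  -> suggest the background class,
* ``p_max >= tAOI`` -> suggest the winning AOI (ties to lowest index),
* otherwise        -> abstain (only reachable when ``tBG < tAOI``).

A trust slider lowers the confidence cut points so that more suggestions
surface as high confidence.  Confirm/correct feedback feeds the labeled
pool; every 10 new non-background samples a warm-start retrain is
launched, with at most one retrain in flight and a single coalesced
pending trigger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io import AOISchema, FixationRecord, FramesSource, extract_patch
from .fewshot import FewShotReconstructionClassifier, LabeledPool

__all__ = [
    "ABSTAIN", "ThresholdConfig", "Suggestion", "EngineState",
    "decide", "thresholds_from_trust", "confidence_level",
    "suggest_all", "record_feedback", "swap_model",
    "run_simulated_session", "SessionLog",
]

#: sentinel label for a withheld suggestion
ABSTAIN = "__abstain__"

RETRAIN_EVERY = 10


@dataclass(frozen=True)
class ThresholdConfig:
    """Background / AOI decision thresholds plus the trust level."""

    t_bg: float = 0.4
    t_aoi: float = 0.4
    trust: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.t_bg <= 1.0 and 0.0 <= self.t_aoi <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")
        if self.t_bg > self.t_aoi:
            raise ValueError("t_bg must not exceed t_aoi")
        if not (0.0 <= self.trust <= 1.0):
            raise ValueError("trust must lie in [0, 1]")


@dataclass(frozen=True)
class Suggestion:
    fixation_id: int
    label: str                   # AOI name, bg name, or ABSTAIN
    probability: float           # winning AOI probability p_max
    confidence: str              # high | medium | low | none


def decide(p: np.ndarray, cfg: ThresholdConfig, schema: AOISchema) -> str:
    """Map a probability vector over AOI classes to a suggested label."""
    p = np.asarray(p, dtype=float)
    p_max = float(p.max())
    if p_max < cfg.t_bg:
        return schema.bg_name
    if p_max >= cfg.t_aoi:
        return schema.aoi_names[int(np.argmax(p))]
    return ABSTAIN


def thresholds_from_trust(trust: float) -> tuple:
    """Confidence cut points ``(c_high, c_mid)`` as a decreasing function
    of trust: c_high = 0.9 - 0.3*trust, c_mid = 0.6 - 0.2*trust."""
    if not 0.0 <= trust <= 1.0:
        raise ValueError("trust must lie in [0, 1]")
    return 0.9 - 0.3 * trust, 0.6 - 0.2 * trust


def confidence_level(p_max: float, cuts: tuple) -> str:
    c_high, c_mid = cuts
    if p_max >= c_high:
        return "high"
    if p_max >= c_mid:
        return "medium"
    return "low"


def _make_suggestion(fixation_id: int, p: np.ndarray, cfg: ThresholdConfig,
                     schema: AOISchema) -> Suggestion:
    label = decide(p, cfg, schema)
    p_max = float(np.max(p))
    if label == ABSTAIN:
        conf = "none"
    else:
        cuts = thresholds_from_trust(cfg.trust)
        # a background call is confident when the AOI evidence is weak
        score = 1.0 - p_max if label == schema.bg_name else p_max
        conf = confidence_level(score, cuts)
    return Suggestion(fixation_id=fixation_id, label=label,
                      probability=p_max, confidence=conf)


def suggest_all(fixations: Sequence[FixationRecord], frames: FramesSource,
                model: FewShotReconstructionClassifier, cfg: ThresholdConfig,
                patch_size: int | None = None) -> tuple:
    """Suggestions for every fixation plus per-confidence summary counts.

    The counts cover non-abstain suggestions only and therefore sum to the
    number of issued suggestions.
    """
    size = patch_size or model.config.patch_size
    suggestions = []
    counts = {"high": 0, "medium": 0, "low": 0}
    if fixations:
        patches = np.stack([extract_patch(frames, f, size) for f in fixations])
        probs = model.predict_proba(patches)
        for f, p in zip(fixations, probs):
            s = _make_suggestion(f.fixation_id, p, cfg, model.schema)
            suggestions.append(s)
            if s.confidence != "none":
                counts[s.confidence] += 1
    return suggestions, counts


@dataclass
class EngineState:
    """Mutable state of the interactive loop.

    ``train_fn`` receives the pool and either returns a trained model
    (synchronous) or ``None`` (asynchronous stub); in the latter case the
    caller must deliver the result through :func:`swap_model` /
    ``complete_retrain``.  At most one retrain is in flight; triggers that
    fire meanwhile coalesce into a single pending one.
    """

    model: FewShotReconstructionClassifier
    pool: LabeledPool
    train_fn: Callable | None = None
    counter: int = 0
    retrain_in_flight: bool = False
    pending_trigger: bool = False
    retrains_launched: int = 0

    def _launch(self) -> None:
        self.counter = 0
        self.retrain_in_flight = True
        self.retrains_launched += 1
        if self.train_fn is not None:
            trained = self.train_fn(self.pool)
            if trained is not None:
                self.complete_retrain(trained)

    def complete_retrain(self, trained: FewShotReconstructionClassifier) -> None:
        self.model = trained
        self.retrain_in_flight = False
        if self.pending_trigger:
            self.pending_trigger = False
            self._launch()


def record_feedback(state: EngineState, fixation_id: int, final_label: str,
                    patch: np.ndarray) -> EngineState:
    """Ingest one confirmed/corrected label.

    Non-background labels enter the pool (re-annotation replaces the
    entry).  Every ``RETRAIN_EVERY`` newly pooled samples a retrain is
    launched, or queued if one is already running.
    """
    status = state.pool.set_feedback(fixation_id, final_label, patch)
    if status == "added":
        state.counter += 1
        if state.counter >= RETRAIN_EVERY:
            if state.retrain_in_flight:
                state.pending_trigger = True
                state.counter = 0
            else:
                state._launch()
    return state


def swap_model(state: EngineState, trained: FewShotReconstructionClassifier) -> EngineState:
    """Install newly trained weights for subsequent suggestions."""
    state.complete_retrain(trained)
    return state


@dataclass
class SessionLog:
    """Replay log of a simulated annotation session."""

    records: pd.DataFrame         # one row per fixation, in order
    chunk_size: int = 100

    def chunk_accuracies(self) -> np.ndarray:
        """Suggestion accuracy per consecutive chunk of fixations."""
        correct = self.records["correct"].to_numpy()
        n = len(correct)
        edges = range(0, n, self.chunk_size)
        return np.array([correct[a:a + self.chunk_size].mean() for a in edges])

    @property
    def suggestion_accuracy(self) -> float:
        return float(self.records["correct"].mean())

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def run_simulated_session(benchmark, model: FewShotReconstructionClassifier,
                          cfg: ThresholdConfig, seed: int = 0,
                          train_epochs: int | None = None,
                          retrain: bool = True) -> SessionLog:
    """Replay an annotation task with a confirm-if-correct oracle policy.

    The policy confirms a suggestion that matches ground truth and corrects
    it to ground truth otherwise, so final annotations always equal truth.
    All feedback flows through :func:`record_feedback`; retrains are
    synchronous 30-epoch warm starts, each anchored at the weights the
    session began with rather than chained from the previous retrain.
    Chaining lets drift accumulate over tens of retrains and erodes
    background rejection (a property the episodic loss carries no signal
    for); anchoring bounds the drift to a single refit while the support
    set still grows with every batch of feedback.
    """
    schema = model.schema
    frames = benchmark.frames
    size = model.config.patch_size
    anchor = model.get_weights()

    def train_fn(pool):
        return model.fit(pool, init=anchor, epochs=train_epochs)

    state = EngineState(model=model, pool=benchmark.pool,
                        train_fn=train_fn if retrain else None)
    rows = []
    for f, truth in zip(benchmark.task_fixations, benchmark.task_labels):
        patch = extract_patch(frames, f, size)
        p = state.model.predict_proba(patch[None])[0]
        s = _make_suggestion(f.fixation_id, p, cfg, schema)
        correct = s.label == truth
        record_feedback(state, f.fixation_id, truth, patch)
        rows.append({
            "fixation_id": f.fixation_id,
            "suggested_label": s.label,
            "probability": s.probability,
            "confidence": s.confidence,
            "final_label": truth,
            "correct": correct,
            "pool_size": len(state.pool),
            "model_version": state.model.version,
        })
    return SessionLog(records=pd.DataFrame(rows))
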