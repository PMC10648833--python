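"""End-to-end orchestration: simulate -> train -> adapt -> evaluate.

The central experiment compares two arms over a drifting session stream:

* the **adaptive** arm runs the full maintenance loop — sessions are
  relabeled (by a simulated, optionally imperfect, user oracle), staged into
  the bounded store, mean-vector selection and classifier refits fire on the
  policy triggers, and fine-tune requests update the extractor followed by
  re-embedding of the whole store;
* the **frozen** arm keeps the tick-0 extractor and classifier untouched.

Both arms are scored each tick on held-out sessions generated that tick and
never ingested, so adaptation is always evaluated on unseen data from the
current state of the world.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import store as _store
from .classifiers import ClassifierSpec, FittedClassifier, fit as fit_classifier
from .evaluation import EvaluationReport, full_report
from .extractor import ConvEmbedder, EmbeddingDataset, TrainConfig, fine_tune, staged_train
from .store import EmbeddingStore, RetrainPolicy
from .world import AppearanceGenotype, DriftScenario, generate_population, generate_stream, render_frame


def identify(image: np.ndarray, extractor, classifier: FittedClassifier):
    """Single-image inference: embed, then classify the embedding."""
    return classifier.predict(extractor.embed(image))


@dataclass
class ExperimentResult:
    """Per-tick accuracy series for both arms plus audit artifacts."""

    ticks: list[int]
    adaptive_accuracy: list[float]
    frozen_accuracy: list[float]
    frame_results: pd.DataFrame  # tick, identity_id, session_id, correct per arm
    journal: list[str]
    adaptive_report: EvaluationReport | None
    frozen_report: EvaluationReport | None
    store: EmbeddingStore = field(repr=False, default=None)

    def final_quarter_mean(self, arm: str) -> float:
        series = self.adaptive_accuracy if arm == "adaptive" else self.frozen_accuracy
        quarter = max(1, len(series) // 4)
        return float(np.mean(series[-quarter:]))

    def identity_accuracy(self, arm: str, identity_id: str) -> float:
        """Per-frame accuracy of one arm restricted to one identity's sessions."""
        col = "correct_adaptive" if arm == "adaptive" else "correct_frozen"
        rows = self.frame_results[self.frame_results.identity_id == identity_id]
        if rows.empty:
            raise ValueError(f"no evaluated frames for identity {identity_id!r}")
        return float(rows[col].mean())


def _registration_images(genotype: AppearanceGenotype, age: float, n_images: int,
                         rng: np.random.Generator, size, noise_sigma: float):
    """Simulated user photo shoot: n frames at the identity's current age."""
    return [
        render_frame(genotype, age, int(rng.integers(0, 2**31 - 1)),
                     size=size, noise_sigma=noise_sigma)
        for _ in range(n_images)
    ]


def run_drift_experiment(
    scenario: DriftScenario,
    policy: RetrainPolicy,
    config: TrainConfig,
    seed: int,
    *,
    population: list[AppearanceGenotype] | None = None,
    n_identities: int = 5,
    frames_per_session: int = 3,
    sessions_per_tick: int = 5,
    eval_sessions_per_tick: int = 3,
    registration_images: int = 10,
    classifier_spec: ClassifierSpec | None = None,
    noise_sigma: float = 0.02,
    relabel_error_rate: float = 0.0,
) -> ExperimentResult:
    """Replay a drift scenario with an adaptive and a frozen arm.

    Tick 0 bootstraps both arms identically: registration photos of every
    initially present identity train the extractor (staged curriculum) and
    fit the classifier.  The stream is then replayed tick by tick; only the
    adaptive arm ingests, selects, refits and fine-tunes.  The user
    relabeling oracle returns ground-truth session labels, except with
    probability ``relabel_error_rate`` per session (a uniformly wrong label).
    """
    rng = np.random.default_rng(seed)
    classifier_spec = classifier_spec or ClassifierSpec("svm", kernel="linear", seed=seed)
    size = (config.input_size, config.input_size)
    if population is None:
        population = generate_population(n_identities, seed)
    genotypes = {g.identity_id: g for g in population}
    added_later = {ident for _, kind, ident in scenario.population_events if kind == "add"}
    initial_ids = [g.identity_id for g in population if g.identity_id not in added_later]
    if len(initial_ids) < 2:
        raise ValueError("the experiment needs at least 2 identities at tick 0")

    # ---- tick-0 bootstrap -------------------------------------------------
    reg_images = {
        ident: _registration_images(genotypes[ident], 0.0, registration_images,
                                    rng, size, noise_sigma)
        for ident in initial_ids
    }
    boot_images = np.asarray([img for ident in initial_ids for img in reg_images[ident]])
    boot_labels = np.asarray([ident for ident in initial_ids
                              for _ in range(registration_images)])
    extractor_adaptive = ConvEmbedder(input_size=config.input_size, seed=config.seed)
    extractor_adaptive, _ = staged_train(
        extractor_adaptive, EmbeddingDataset(boot_images, boot_labels), config)
    extractor_frozen = copy.deepcopy(extractor_adaptive)

    memory = EmbeddingStore(capacity=policy.capacity)
    for ident in initial_ids:
        _store.register_identity(memory, ident, reg_images[ident],
                                 extractor_adaptive, tick=0)
    classifier_adaptive = _store.refit_classifier(memory, classifier_spec)
    classifier_frozen = classifier_adaptive

    # ---- streams ----------------------------------------------------------
    ingest_stream = generate_stream(
        population, scenario, frames_per_session=frames_per_session,
        sessions_per_tick=sessions_per_tick, seed=int(rng.integers(0, 2**31 - 1)),
        size=size, noise_sigma=noise_sigma)
    eval_stream = generate_stream(
        population, scenario, frames_per_session=frames_per_session,
        sessions_per_tick=eval_sessions_per_tick, seed=int(rng.integers(0, 2**31 - 1)),
        size=size, noise_sigma=noise_sigma)
    ingest_by_tick: dict[int, list] = {}
    for session in ingest_stream:
        ingest_by_tick.setdefault(session.tick, []).append(session)
    eval_by_tick: dict[int, list] = {}
    for session in eval_stream:
        eval_by_tick.setdefault(session.tick, []).append(session)

    events_by_tick: dict[int, list] = {}
    for tick, kind, ident in scenario.population_events:
        events_by_tick.setdefault(tick, []).append((kind, ident))

    ticks, adaptive_acc, frozen_acc = [], [], []
    frame_rows = []
    for tick in range(scenario.duration):
        age = tick * scenario.morph_rate
        # population churn: only the adaptive arm reacts
        for kind, ident in events_by_tick.get(tick, []):
            if kind == "add":
                photos = _registration_images(genotypes[ident], age, registration_images,
                                              rng, size, noise_sigma)
                _store.register_identity(memory, ident, photos, extractor_adaptive,
                                         tick=tick)
            else:
                _store.deregister_identity(memory, ident)
            if len(memory.identities()) >= 2:
                classifier_adaptive = _store.refit_classifier(memory, classifier_spec)

        # user relabeling + ingestion (adaptive arm only)
        for session in ingest_by_tick.get(tick, []):
            label = session.identity_id
            if relabel_error_rate > 0 and rng.random() < relabel_error_rate:
                others = [i for i in memory.identities() if i != label]
                if others:
                    label = others[int(rng.integers(len(others)))]
            if label in memory.bounded:
                _store.ingest_labeled_session(memory, session, label, extractor_adaptive)

        if tick % policy.period == 0:
            memory, actions = _store.maybe_adapt(memory, policy, classifier_spec,
                                                 extractor_adaptive)
            for action in actions:
                if action.kind == "refit":
                    classifier_adaptive = action.detail["classifier"]
                elif action.kind == "fine_tune":
                    images, labels = memory.training_images()
                    if len(np.unique(labels)) >= 2:
                        extractor_adaptive, _ = fine_tune(
                            extractor_adaptive, EmbeddingDataset(images, labels), config)
                        _store.reembed_store(memory, extractor_adaptive)
                        classifier_adaptive = _store.refit_classifier(memory,
                                                                      classifier_spec)

        # held-out evaluation of both arms
        n_correct = {"adaptive": 0, "frozen": 0}
        n_frames = 0
        for session in eval_by_tick.get(tick, []):
            frames = np.asarray(session.frames)
            pred_a, _ = classifier_adaptive.predict_batch(
                extractor_adaptive.embed_batch(frames))
            pred_f, _ = classifier_frozen.predict_batch(
                extractor_frozen.embed_batch(frames))
            for k in range(len(frames)):
                correct_a = pred_a[k] == session.identity_id
                correct_f = pred_f[k] == session.identity_id
                n_correct["adaptive"] += correct_a
                n_correct["frozen"] += correct_f
                n_frames += 1
                frame_rows.append({
                    "tick": tick, "identity_id": session.identity_id,
                    "session_id": session.session_id,
                    "correct_adaptive": bool(correct_a),
                    "correct_frozen": bool(correct_f),
                })
        if n_frames:
            ticks.append(tick)
            adaptive_acc.append(n_correct["adaptive"] / n_frames)
            frozen_acc.append(n_correct["frozen"] / n_frames)

    frame_results = pd.DataFrame(frame_rows)

    # final held-out report per arm, from the last tick with evaluations
    adaptive_report = frozen_report = None
    last_tick = ticks[-1] if ticks else None
    if last_tick is not None:
        final_sessions = eval_by_tick[last_tick]
        final_frames = np.asarray([f for s in final_sessions for f in s.frames])
        final_labels = np.asarray([s.identity_id for s in final_sessions
                                   for _ in s.frames])
        if len(np.unique(final_labels)) >= 2:
            adaptive_report = full_report(
                classifier_adaptive, extractor_adaptive.embed_batch(final_frames),
                final_labels)
            frozen_report = full_report(
                classifier_frozen, extractor_frozen.embed_batch(final_frames),
                final_labels)

    return ExperimentResult(
        ticks=ticks,
        adaptive_accuracy=adaptive_acc,
        frozen_accuracy=frozen_acc,
        frame_results=frame_results,
        journal=list(memory.journal),
        adaptive_report=adaptive_report,
        frozen_report=frozen_report,
        store=memory,
    )
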