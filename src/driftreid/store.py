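"""Bounded per-identity embedding memory with drift-adaptive maintenance.

The store is the system's long-term memory: for each registered identity it
keeps at most N embedding records (the identity's gallery).  New labeled
sessions are staged; once an identity has accumulated M staged records, the
class mean of (gallery union staged) is computed and the N records closest
to that mean are retained — outliers and stale exemplars fall away.  After
any such selection the classifier is refitted.  When every registered
identity has accumulated C litter-box records since the last fine-tune, a
fine-tune of the feature extractor is requested; afterwards the whole store
is re-embedded with the updated extractor.

Retraining is periodic and label-driven — there is no drift-detection
statistic; the policy triggers (T, M, N, C) alone govern adaptation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classifiers as _classifiers
from .world import SessionRecord


@dataclass(frozen=True)
class RetrainPolicy:
    """Adaptation triggers and capacities.

    ``period`` (T) is the relabeling cadence in ticks; ``per_identity_trigger``
    (M) the staged-record count that triggers gallery selection;
    ``capacity`` (N) the per-identity gallery bound; ``finetune_trigger`` (C)
    the per-identity litter-box record count (since the last fine-tune) that,
    once reached by every registered identity, requests extractor fine-tuning.
    """

    period: int = 1
    per_identity_trigger: int = 20
    capacity: int = 200
    finetune_trigger: int = 500

    def __post_init__(self) -> None:
        if min(self.period, self.per_identity_trigger, self.capacity,
               self.finetune_trigger) < 1:
            raise ValueError("all policy values must be positive")


@dataclass
class EmbeddingRecord:
    """One stored embedding plus its provenance and source image."""

    vector: np.ndarray
    identity_id: str
    session_id: str
    tick: int
    origin: str  # "registration" | "litterbox"
    image: np.ndarray | None = None

    @property
    def uid(self) -> str:
        return f"{self.session_id}:{self.tick}:{self.origin}:{self._ordinal}"

    _ordinal: int = 0


@dataclass
class Action:
    """One journal-able store event."""

    kind: str  # register | deregister | ingest | select | refit | fine_tune
    identity_id: str | None = None
    detail: dict = field(default_factory=dict)

    def to_journal_line(self) -> str:
        return json.dumps({"kind": self.kind, "identity_id": self.identity_id,
                           **self.detail}, sort_keys=True)


class RegistrationError(ValueError):
    pass


class EmbeddingStore:
    """Per-identity bounded record collections plus staging and counters."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self.bounded: dict[str, list[EmbeddingRecord]] = {}
        self.staged: dict[str, list[EmbeddingRecord]] = {}
        self.litter_counts: dict[str, int] = {}
        self.journal: list[str] = []
        self._next_ordinal = 0

    # -- bookkeeping --------------------------------------------------------
    def identities(self) -> list[str]:
        return sorted(self.bounded)

    def count(self, identity_id: str) -> int:
        return len(self.bounded.get(identity_id, []))

    def staged_count(self, identity_id: str) -> int:
        return len(self.staged.get(identity_id, []))

    def _log(self, action: Action) -> None:
        self.journal.append(action.to_journal_line())

    def _new_record(self, **kwargs) -> EmbeddingRecord:
        record = EmbeddingRecord(**kwargs)
        record._ordinal = self._next_ordinal
        self._next_ordinal += 1
        return record

    # -- training-set view --------------------------------------------------
    def gallery(self) -> tuple[np.ndarray, np.ndarray]:
        """All bounded embeddings and labels, for classifier fitting."""
        vectors, labels = [], []
        for ident in self.identities():
            for record in self.bounded[ident]:
                vectors.append(record.vector)
                labels.append(ident)
        if not vectors:
            raise ValueError("store holds no records")
        return np.asarray(vectors), np.asarray(labels)

    def training_images(self) -> tuple[np.ndarray, np.ndarray]:
        """Source images and labels of all bounded records, for fine-tuning."""
        images, labels = [], []
        for ident in self.identities():
            for record in self.bounded[ident]:
                if record.image is None:
                    raise RuntimeError("record lacks its source image")
                images.append(record.image)
                labels.append(ident)
        return np.asarray(images), np.asarray(labels)

    # -- persistence --------------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        """Persist vectors as an array archive plus a CSV index and journal."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        vectors, rows = [], []
        for ident in self.identities():
            for record in self.bounded[ident]:
                rows.append({"identity_id": ident, "session_id": record.session_id,
                             "tick": record.tick, "origin": record.origin})
                vectors.append(record.vector)
        np.savez(out_dir / "vectors.npz",
                 vectors=np.asarray(vectors) if vectors else np.zeros((0, 1)))
        pd.DataFrame(rows).to_csv(out_dir / "index.csv", index=False)
        (out_dir / "journal.log").write_text("\n".join(self.journal) + "\n")


# ---------------------------------------------------------------------------
# operations


def register_identity(store: EmbeddingStore, identity_id: str,
                      images: Sequence[np.ndarray], extractor,
                      tick: int = 0) -> EmbeddingStore:
    """Add a new identity from user-supplied photos.

    All images are embedded as origin="registration" records; if they exceed
    the capacity, mean-vector selection bounds them immediately.  The
    identity becomes predictable after the next classifier refit.
    """
    if identity_id in store.bounded:
        raise RegistrationError(f"identity {identity_id!r} already registered")
    if len(images) == 0:
        raise ValueError("registration requires at least one image")
    vectors = extractor.embed_batch(np.asarray(images))
    records = [
        store._new_record(vector=v, identity_id=identity_id,
                          session_id=f"registration_{identity_id}", tick=tick,
                          origin="registration", image=np.asarray(img))
        for v, img in zip(vectors, images)
    ]
    if len(records) > store.capacity:
        keep = select_indices([r.vector for r in records], [], store.capacity)
        records = [records[i] for i in keep]
    store.bounded[identity_id] = records
    store.staged[identity_id] = []
    store.litter_counts[identity_id] = 0
    store._log(Action("register", identity_id, {"n_images": len(images)}))
    return store


def deregister_identity(store: EmbeddingStore, identity_id: str) -> EmbeddingStore:
    """Remove an identity and every record belonging to it."""
    if identity_id not in store.bounded:
        raise ValueError(f"unknown identity {identity_id!r}")
    del store.bounded[identity_id]
    store.staged.pop(identity_id, None)
    store.litter_counts.pop(identity_id, None)
    store._log(Action("deregister", identity_id))
    return store


def ingest_labeled_session(store: EmbeddingStore, session: SessionRecord,
                           corrected_identity: str, extractor) -> EmbeddingStore:
    """Stage every frame of a user-relabeled session under one identity.

    Sessions are labeled atomically: the corrected identity applies to all
    frames.  Staged records await the next M-triggered selection.
    """
    if corrected_identity not in store.bounded:
        raise ValueError(f"identity {corrected_identity!r} is not registered")
    vectors = extractor.embed_batch(np.asarray(session.frames))
    for v, img in zip(vectors, session.frames):
        store.staged[corrected_identity].append(
            store._new_record(vector=v, identity_id=corrected_identity,
                              session_id=session.session_id, tick=session.tick,
                              origin="litterbox", image=np.asarray(img)))
    store.litter_counts[corrected_identity] += len(session.frames)
    store._log(Action("ingest", corrected_identity,
                      {"session_id": session.session_id,
                       "n_frames": len(session.frames)}))
    return store


def select_indices(existing: Sequence[np.ndarray], incoming: Sequence[np.ndarray],
                   capacity: int) -> list[int]:
    """Indices (into existing + incoming) of the records kept by selection.

    The reference point is the arithmetic mean of the union; the
    min(capacity, union size) vectors nearest to it (Euclidean) are kept,
    ties broken by earlier input position; indices are returned in
    selection (distance) order.
    """
    if capacity < 1:
        raise ValueError("capacity must be >= 1")
    union = [np.asarray(v, dtype=float) for v in existing] + \
            [np.asarray(v, dtype=float) for v in incoming]
    if not union:
        raise ValueError("cannot select from an empty union")
    stacked = np.asarray(union)
    mean = stacked.mean(axis=0)
    distances = np.linalg.norm(stacked - mean, axis=1)
    order = np.argsort(distances, kind="stable")
    return order[: min(capacity, len(union))].tolist()


def select_embeddings(existing: Sequence[np.ndarray], incoming: Sequence[np.ndarray],
                      capacity: int) -> list[np.ndarray]:
    """Mean-vector selection: the vectors nearest the union mean, bounded at N."""
    union = list(existing) + list(incoming)
    return [np.asarray(union[i], dtype=float)
            for i in select_indices(existing, incoming, capacity)]


def maybe_adapt(store: EmbeddingStore, policy: RetrainPolicy,
                classifier_spec, extractor) -> tuple[EmbeddingStore, list[Action]]:
    """Run the policy's triggers; return the actions taken.

    For each identity with at least M staged records, mean-vector selection
    replaces its gallery (capacity N); after any selection the classifier is
    refitted on the updated galleries (the fitted classifier rides on the
    refit action).  If every registered identity has accumulated at least C
    litter-box records since the last fine-tune, a fine_tune action is
    emitted (the caller owns the actual extractor update and re-embedding).
    """
    actions: list[Action] = []
    selected_any = False
    for ident in store.identities():
        staged = store.staged.get(ident, [])
        if len(staged) < policy.per_identity_trigger:
            continue
        pool = store.bounded[ident] + staged
        keep = select_indices([r.vector for r in store.bounded[ident]],
                              [r.vector for r in staged], policy.capacity)
        store.bounded[ident] = [pool[i] for i in keep]
        store.staged[ident] = []
        selected_any = True
        action = Action("select", ident,
                        {"kept": [pool[i].uid for i in keep], "pool": len(pool)})
        actions.append(action)
        store._log(action)
    if selected_any and len(store.identities()) >= 2:
        vectors, labels = store.gallery()
        fitted = _classifiers.fit(classifier_spec, vectors, labels)
        action = Action("refit", None, {"n_records": len(labels)})
        action.detail["classifier"] = fitted
        actions.append(action)
        store._log(Action("refit", None, {"n_records": len(labels)}))
    idents = store.identities()
    if idents and all(store.litter_counts[i] >= policy.finetune_trigger for i in idents):
        for ident in idents:
            store.litter_counts[ident] = 0
        action = Action("fine_tune", None, {"identities": idents})
        actions.append(action)
        store._log(action)
    return store, actions


def reembed_store(store: EmbeddingStore, extractor) -> EmbeddingStore:
    """Recompute every record's vector with the current extractor.

    Counts and identities are untouched; requires each record to retain its
    source image.
    """
    for collection in (store.bounded, store.staged):
        for ident, records in collection.items():
            if not records:
                continue
            images = []
            for record in records:
                if record.image is None:
                    raise RuntimeError(f"record for {ident!r} lacks its source image")
                images.append(record.image)
            vectors = extractor.embed_batch(np.asarray(images))
            for record, vector in zip(records, vectors):
                record.vector = vector
    store._log(Action("reembed", None))
    return store


def refit_classifier(store: EmbeddingStore, classifier_spec):
    """Fit the bank classifier on the store's current galleries."""
    vectors, labels = store.gallery()
    return _classifiers.fit(classifier_spec, vectors, labels)
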