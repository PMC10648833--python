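"""Adaptive store: selection, lifecycle, triggers and capacity invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import driftreid as dr
from driftreid.store import (
    EmbeddingStore,
    RegistrationError,
    RetrainPolicy,
    maybe_adapt,
    refit_classifier,
    select_indices,
)
from driftreid.classifiers import ClassifierSpec

from conftest import make_session


def selection_oracle(existing, incoming, capacity):
    """Exhaustive sort-by-distance-to-mean reference implementation."""
    union = [np.asarray(v, float) for v in list(existing) + list(incoming)]
    mean = np.mean(union, axis=0)
    ranked = sorted(range(len(union)),
                    key=lambda i: (float(np.linalg.norm(union[i] - mean)), i))
    return ranked[: min(capacity, len(union))]


@pytest.fixture()
def small_store(cheap_embedder):
    rng = np.random.default_rng(0)
    store = EmbeddingStore(capacity=10)
    for ident in ("A", "B"):
        images = [rng.random((16, 16, 3)) for _ in range(4)]
        dr.register_identity(store, ident, images, cheap_embedder)
    return store


class TestSelection:
    def test_worked_example_drops_outlier(self):
        existing = [np.array([0.0, 0.0]), np.array([0.0, 2.0])]
        incoming = [np.array([0.0, 1.0]), np.array([10.0, 0.0])]
        kept = dr.select_embeddings(existing, incoming, 3)
        kept_tuples = {tuple(v) for v in kept}
        assert kept_tuples == {(0.0, 1.0), (0.0, 0.0), (0.0, 2.0)}
        # selection order: nearest to the mean first
        assert tuple(kept[0]) == (0.0, 1.0)

    def test_capacity_slack_returns_union(self):
        vectors = [np.array([float(i), 0.0]) for i in range(4)]
        kept = dr.select_embeddings(vectors, [], 100)
        assert len(kept) == 4

    def test_ties_broken_by_input_order(self):
        vectors = [np.array([1.0, 1.0])] * 4
        assert select_indices(vectors[:2], vectors[2:], 2) == [0, 1]

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError):
            dr.select_embeddings([], [], 3)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            dim = int(rng.integers(2, 16))
            n_existing = int(rng.integers(0, 20))
            n_incoming = int(rng.integers(1, 20))
            existing = [rng.normal(size=dim) for _ in range(n_existing)]
            incoming = [rng.normal(size=dim) for _ in range(n_incoming)]
            capacity = int(rng.integers(1, 25))
            assert select_indices(existing, incoming, capacity) == \
                selection_oracle(existing, incoming, capacity)

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_far_outlier_never_selected(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 12))
        cluster = rng.normal(size=(k, 8))
        centroid = cluster.mean(axis=0)
        diameter = max(np.linalg.norm(a - b) for a in cluster for b in cluster)
        direction = rng.normal(size=8)
        direction /= np.linalg.norm(direction)
        outlier = centroid + direction * max(10 * diameter, 1.0)
        kept = select_indices(list(cluster), [outlier], k)
        assert k not in kept  # the outlier is the last input index


class TestLifecycle:
    def test_register_counts_and_duplicate_rejected(self, small_store, cheap_embedder):
        assert small_store.count("A") == 4
        with pytest.raises(RegistrationError):
            dr.register_identity(small_store, "A", [np.zeros((16, 16, 3))],
                                 cheap_embedder)
        assert small_store.count("A") == 4

    def test_register_empty_rejected(self, small_store, cheap_embedder):
        with pytest.raises(ValueError):
            dr.register_identity(small_store, "C", [], cheap_embedder)

    def test_deregister_removes_only_that_identity(self, small_store):
        dr.deregister_identity(small_store, "A")
        assert small_store.count("A") == 0
        assert "A" not in small_store.bounded
        assert small_store.count("B") == 4

    def test_deregister_unknown_rejected(self, small_store):
        with pytest.raises(ValueError):
            dr.deregister_identity(small_store, "Z")

    def test_reregister_after_deregister_keeps_only_new(self, small_store, cheap_embedder):
        dr.deregister_identity(small_store, "A")
        rng = np.random.default_rng(5)
        dr.register_identity(small_store, "A",
                             [rng.random((16, 16, 3)) for _ in range(2)], cheap_embedder)
        assert small_store.count("A") == 2

    def test_deregistered_identity_never_predicted(self, cheap_embedder):
        rng = np.random.default_rng(3)
        store = EmbeddingStore(capacity=20)
        images = {}
        for ident in ("A", "B", "C"):
            images[ident] = [rng.random((16, 16, 3)) for _ in range(6)]
            dr.register_identity(store, ident, images[ident], cheap_embedder)
        dr.deregister_identity(store, "B")
        classifier = refit_classifier(store, ClassifierSpec("knn", k=3))
        assert "B" not in classifier.class_set
        for ident in ("A", "B", "C"):
            for image in images[ident]:
                predicted, _ = classifier.predict(cheap_embedder.embed(image))
                assert predicted != "B"

    def test_registration_end_to_end_prediction(self, trained_extractor, population):
        """Registered identities are recovered after refit on a trained metric."""
        rng = np.random.default_rng(6)
        store = EmbeddingStore(capacity=50)
        probes = {}
        for genotype in population:
            imgs = [dr.render_frame(genotype, 0.0, int(rng.integers(2**31)),
                                    size=(32, 32)) for _ in range(8)]
            dr.register_identity(store, genotype.identity_id, imgs, trained_extractor)
            probes[genotype.identity_id] = imgs[0]
        classifier = refit_classifier(store, ClassifierSpec("svm", kernel="linear"))
        for ident, image in probes.items():
            predicted, _ = classifier.predict(trained_extractor.embed(image))
            assert predicted == ident


class TestIngestAndAdapt:
    def test_session_frames_staged_atomically(self, small_store, cheap_embedder):
        session = make_session("A", n_frames=7, seed=1)
        dr.ingest_labeled_session(small_store, session, "A", cheap_embedder)
        assert small_store.staged_count("A") == 7
        assert all(r.identity_id == "A" and r.session_id == session.session_id
                   for r in small_store.staged["A"])

    def test_relabeled_session_goes_to_corrected_identity(self, small_store,
                                                          cheap_embedder):
        session = make_session("B", n_frames=3, seed=2)
        dr.ingest_labeled_session(small_store, session, "A", cheap_embedder)
        assert small_store.staged_count("A") == 3
        assert small_store.staged_count("B") == 0

    def test_staged_counts_additive(self, small_store, cheap_embedder):
        dr.ingest_labeled_session(small_store, make_session("A", 3, seed=3), "A",
                                  cheap_embedder)
        dr.ingest_labeled_session(small_store, make_session("A", 4, seed=4), "A",
                                  cheap_embedder)
        assert small_store.staged_count("A") == 7

    def test_unknown_identity_rejected(self, small_store, cheap_embedder):
        with pytest.raises(ValueError):
            dr.ingest_labeled_session(small_store, make_session("Z", 2), "Z",
                                      cheap_embedder)

    def test_below_trigger_no_selection(self, small_store, cheap_embedder):
        policy = RetrainPolicy(per_identity_trigger=5, capacity=10, finetune_trigger=100)
        dr.ingest_labeled_session(small_store, make_session("A", 4, seed=5), "A",
                                  cheap_embedder)
        _, actions = maybe_adapt(small_store, policy, ClassifierSpec("knn", k=3),
                                 cheap_embedder)
        assert not any(a.kind == "select" for a in actions)
        assert small_store.staged_count("A") == 4

    def test_trigger_selects_and_respects_capacity(self, small_store, cheap_embedder):
        policy = RetrainPolicy(per_identity_trigger=5, capacity=6, finetune_trigger=100)
        dr.ingest_labeled_session(small_store, make_session("A", 5, seed=6), "A",
                                  cheap_embedder)
        _, actions = maybe_adapt(small_store, policy, ClassifierSpec("knn", k=3),
                                 cheap_embedder)
        kinds = [a.kind for a in actions]
        assert "select" in kinds and "refit" in kinds
        assert small_store.count("A") == 6  # capacity bound hit exactly
        assert small_store.staged_count("A") == 0

    def test_finetune_requires_all_identities_at_C(self, small_store, cheap_embedder):
        policy = RetrainPolicy(per_identity_trigger=100, capacity=10, finetune_trigger=5)
        dr.ingest_labeled_session(small_store, make_session("A", 6, seed=7), "A",
                                  cheap_embedder)
        _, actions = maybe_adapt(small_store, policy, ClassifierSpec("knn", k=3),
                                 cheap_embedder)
        assert not any(a.kind == "fine_tune" for a in actions)
        dr.ingest_labeled_session(small_store, make_session("B", 6, seed=8), "B",
                                  cheap_embedder)
        _, actions = maybe_adapt(small_store, policy, ClassifierSpec("knn", k=3),
                                 cheap_embedder)
        assert sum(a.kind == "fine_tune" for a in actions) == 1
        # counters reset after the request
        assert all(c == 0 for c in small_store.litter_counts.values())


class TestReembed:
    def test_unchanged_extractor_is_idempotent(self, small_store, cheap_embedder):
        before = {ident: [r.vector.copy() for r in records]
                  for ident, records in small_store.bounded.items()}
        dr.reembed_store(small_store, cheap_embedder)
        for ident, vectors in before.items():
            for old, record in zip(vectors, small_store.bounded[ident]):
                np.testing.assert_allclose(record.vector, old, atol=1e-6)

    def test_counts_preserved_and_vectors_change_with_new_weights(self, small_store):
        counts = {i: small_store.count(i) for i in small_store.identities()}
        other = dr.RandomProjectionEmbedder(input_size=16, seed=99)
        dr.reembed_store(small_store, other)
        assert {i: small_store.count(i) for i in small_store.identities()} == counts
        # compare against fresh embeddings from the original embedder
        changed = False
        for records in small_store.bounded.values():
            for record in records:
                original = dr.RandomProjectionEmbedder(16, seed=11).embed(record.image)
                if not np.allclose(record.vector, original, atol=1e-9):
                    changed = True
        assert changed


def test_capacity_and_session_atomicity_under_random_sequences(cheap_embedder):
    """Randomized ingest/adapt/register/deregister stress, 25 scenarios."""
    for scenario_seed in range(25):
        rng = np.random.default_rng(scenario_seed)
        capacity = int(rng.integers(3, 8))
        policy = RetrainPolicy(per_identity_trigger=int(rng.integers(2, 6)),
                               capacity=capacity,
                               finetune_trigger=int(rng.integers(5, 15)))
        store = EmbeddingStore(capacity=capacity)
        idents = ["A", "B", "C"]
        for ident in idents:
            dr.register_identity(store, ident,
                                 [rng.random((16, 16, 3))
                                  for _ in range(int(rng.integers(1, capacity + 1)))],
                                 cheap_embedder)
        for step in range(15):
            op = rng.random()
            active = store.identities()
            if op < 0.6 and active:
                ident = active[int(rng.integers(len(active)))]
                session = make_session(ident, int(rng.integers(1, 5)),
                                       seed=scenario_seed * 100 + step)
                dr.ingest_labeled_session(store, session, ident, cheap_embedder)
                # session atomicity: all frames of the session share one label
                staged = [r for r in store.staged[ident]
                          if r.session_id == session.session_id]
                assert len({r.identity_id for r in staged}) == 1
            elif op < 0.8:
                maybe_adapt(store, policy, ClassifierSpec("knn", k=1), cheap_embedder)
            elif op < 0.9 and len(active) > 2:
                dr.deregister_identity(store, active[int(rng.integers(len(active)))])
            for ident in store.identities():
                assert store.count(ident) <= capacity
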