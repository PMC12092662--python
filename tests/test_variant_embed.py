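import numpy as np
import pytest

from metach import (VariantEmbedder, patient_variant_embedding,
                    tokenize_variant)
from metach.embeddings import INFER, TRAIN
from metach.errors import (AggregationError, EmptyInputError, StateError,
                           TrainingError)

from conftest import make_record, two_signature_config

CTX21 = "ACGTACGTACTTACGTACGTA"


class TestTokenizeVariant:
    def test_kmer_count_follows_length_formula(self):
        """For a 21-char context, sum over k of (L-k+1) gives 74 k-mers."""
        rec = make_record(context=CTX21)
        toks = tokenize_variant(rec, TRAIN)
        kmers = [t for t in toks if t.startswith("kmer:")]
        assert len(kmers) == sum(21 - k + 1 for k in (2, 3, 4, 5)) == 74
        assert len(toks) == 77  # + var + gene + ctype

    def test_inference_excludes_cancer_type(self):
        rec = make_record(context=CTX21)
        toks = tokenize_variant(rec, INFER)
        assert len(toks) == 76
        assert not any(t.startswith("ctype:") for t in toks)

    def test_kmers_with_n_dropped(self):
        rec = make_record(context="NN")
        toks = tokenize_variant(rec, TRAIN)
        assert not any(t.startswith("kmer:") for t in toks)
        assert any(t.startswith("var:") for t in toks)
        assert any(t.startswith("gene:") for t in toks)

    def test_unknown_cancer_type_never_tokenized(self):
        rec = make_record(context=CTX21, cancer_type="UNKNOWN")
        assert not any(t.startswith("ctype:")
                       for t in tokenize_variant(rec, TRAIN))

    def test_empty_bag_is_an_error(self):
        rec = make_record(context=None, gene="")
        with pytest.raises(EmptyInputError):
            tokenize_variant(rec, TRAIN)


def _toy_records(n_patients=12, per_patient=4, seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    for p in range(n_patients):
        for j in range(per_patient):
            ctx = "".join(rng.choice(list("ACGT"), size=21))
            recs.append(make_record(
                patient=f"P{p}", pos=100 + 30 * (p * per_patient + j),
                ref="C", alt="T", context=ctx[:10] + "T" + ctx[11:],
                gene=f"G{j % 3}"))
    return recs


class TestVariantEmbedderTraining:
    def test_zero_epochs_returns_initialization(self):
        recs = _toy_records()
        model = VariantEmbedder(epochs=0, seed=3).fit(recs)
        assert model.loss_history_ == []
        init = np.random.default_rng(3).uniform(
            -1 / model.dim, 1 / model.dim, size=model.vectors_.shape)
        np.testing.assert_array_equal(model.vectors_, init)

    def test_fixed_seed_is_run_to_run_identical(self):
        recs = _toy_records()
        a = VariantEmbedder(epochs=2, seed=7).fit(recs)
        b = VariantEmbedder(epochs=2, seed=7).fit(recs)
        np.testing.assert_array_equal(a.vectors_, b.vectors_)
        assert a.loss_history_ == b.loss_history_

    def test_requires_a_multi_variant_patient(self):
        recs = [make_record(patient=f"P{i}", pos=100 + i, context=CTX21)
                for i in range(5)]
        with pytest.raises(TrainingError):
            VariantEmbedder().fit(recs)

    def test_vocabulary_respects_min_count(self):
        recs = _toy_records()
        model = VariantEmbedder(epochs=0, min_count=2).fit(recs)
        # var: identity tokens are singletons here, so none survive
        assert not any(t.startswith("var:") for t in model.vocabulary_)
        assert all(c >= 2 for c in model.counts_.values())

    def test_loss_trajectory_non_increasing_on_toy_data(self):
        recs = _toy_records(n_patients=15, per_patient=4)
        model = VariantEmbedder(epochs=4, learning_rate=0.02, seed=1).fit(recs)
        assert model.loss_history_[-1] <= model.loss_history_[0]
        assert np.all(np.isfinite(model.vectors_))

    def test_training_preserves_dimension_and_finiteness(self):
        recs = _toy_records()
        model = VariantEmbedder(epochs=2, seed=0).fit(recs)
        assert model.vectors_.shape[1] == 128
        assert np.all(np.isfinite(model.vectors_))


class TestEmbedVariant:
    def _manual_model(self, tokens):
        model = VariantEmbedder(dim=4)
        model.vocabulary_ = {t: i for i, t in enumerate(tokens)}
        model.counts_ = {t: 2 for t in tokens}
        model.vectors_ = np.arange(4 * len(tokens), dtype=float).reshape(len(tokens), 4)
        model.loss_history_ = []
        return model

    def test_single_in_vocabulary_token(self):
        model = self._manual_model(["gene:TP53"])
        rec = make_record(context=None, gene="TP53")
        vec, oov = model.embed(rec)
        np.testing.assert_array_equal(vec, model.vectors_[0])
        assert not oov

    def test_mean_of_two_tokens_matches_arithmetic(self):
        rec = make_record(context=None, gene="TP53")
        model = self._manual_model(["gene:TP53", "var:chr1:100:C:T"])
        vec, _ = model.embed(rec)
        np.testing.assert_allclose(
            vec, (model.vectors_[0] + model.vectors_[1]) / 2)

    def test_out_of_vocabulary_gives_flagged_zero_vector(self):
        model = self._manual_model(["gene:OTHER"])
        vec, oov = model.embed(make_record(context=None, gene="TP53"))
        assert oov and vec.shape == (4,) and not vec.any()

    def test_inference_independent_of_cancer_type(self):
        recs = _toy_records()
        model = VariantEmbedder(epochs=1, seed=0).fit(recs)
        rec = recs[0]
        a, _ = model.embed(rec)
        b, _ = model.embed(rec.with_(cancer_type="PANCREAS"))
        np.testing.assert_array_equal(a, b)

    def test_unfitted_model_raises(self):
        with pytest.raises(StateError):
            VariantEmbedder().embed(make_record(context=CTX21))


class TestClassGeometry:
    def test_within_class_similarity_exceeds_cross_class(self):
        """Two divergent signature classes separate in Ev space."""
        from metach import simulate_cohort
        cohort = simulate_cohort(two_signature_config(seed=21, n_patients=60))
        model = VariantEmbedder(epochs=6, seed=0).fit(cohort.records)
        E = model.transform(cohort.records)
        E /= np.clip(np.linalg.norm(E, axis=1, keepdims=True), 1e-12, None)
        y = np.array([r.is_ch for r in cohort.records])
        S = E @ E.T
        np.fill_diagonal(S, np.nan)
        within = (np.nanmean(S[np.ix_(y, y)]) + np.nanmean(S[np.ix_(~y, ~y)])) / 2
        cross = np.nanmean(S[np.ix_(y, ~y)])
        assert within - cross >= 0.1


class TestPatientVariantEmbedding:
    def test_single_vector_identity_and_symmetry(self):
        v = np.arange(5.0)
        np.testing.assert_array_equal(patient_variant_embedding([v]), v)
        np.testing.assert_array_equal(patient_variant_embedding([v, -v]),
                                      np.zeros(5))

    def test_matches_numpy_mean_oracle(self):
        rng = np.random.default_rng(0)
        vs = rng.standard_normal((7, 128))
        np.testing.assert_allclose(patient_variant_embedding(list(vs)),
                                   vs.mean(axis=0), rtol=0, atol=1e-12)

    def test_empty_list_raises(self):
        with pytest.raises(AggregationError):
            patient_variant_embedding([])


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        recs = _toy_records()
        model = VariantEmbedder(epochs=1, seed=2).fit(recs)
        model.save(tmp_path / "ve")
        back = VariantEmbedder.load(tmp_path / "ve")
        assert back.vocabulary_ == model.vocabulary_
        np.testing.assert_allclose(back.vectors_, model.vectors_)
        np.testing.assert_array_equal(back.transform(recs[:5]),
                                      model.transform(recs[:5]))
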