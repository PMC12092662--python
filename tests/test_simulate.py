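import numpy as np
import pytest

from metach import (CohortConfig, attach_contexts, simulate_cohort,
                    train_test_split_by_patient)
from metach.errors import ConfigurationError, SplitError
from metach.metrics import compute_auroc
from metach.variants import CH_NON_ONCOGENIC, CH_ONCOGENIC, TUMOR


class TestSimulateCohort:
    def test_degenerate_mixture_all_tumor(self):
        cfg = CohortConfig(n_patients=20, seed=1, class_mix={
            TUMOR: 1.0, CH_ONCOGENIC: 0.0, CH_NON_ONCOGENIC: 0.0})
        cohort = simulate_cohort(cfg)
        assert all(r.label == TUMOR for r in cohort.records)

    def test_count_matches_negative_binomial_theory_and_reruns(self):
        cfg = CohortConfig(n_patients=200, variants_per_patient_mean=8.0, seed=5)
        n1 = len(simulate_cohort(cfg).records)
        n2 = len(simulate_cohort(CohortConfig(n_patients=200,
                                              variants_per_patient_mean=8.0,
                                              seed=5)).records)
        assert n1 == n2  # exact reproducibility under the seed
        mu, r = 8.0, cfg.variants_per_patient_dispersion
        var = 200 * (mu + mu ** 2 / r)
        assert abs(n1 - 1600) <= 3 * np.sqrt(var)

    def test_signature_concentration_shows_in_contexts(self):
        """CH signature on C>T at NCG: center of context reads N-T-G."""
        cfg = CohortConfig(n_patients=60, seed=3)
        cohort = simulate_cohort(cfg)
        ch = [r for r in cohort.records if r.label == CH_ONCOGENIC]
        assert len(ch) > 30
        hits = sum(r.context[9:12] in {"ATG", "CTG", "GTG", "TTG"} for r in ch)
        assert hits / len(ch) >= 0.9

    def test_contexts_reproducible_from_emitted_contigs(self, default_cohort):
        stripped = [r.with_(context=None) for r in default_cohort.records[:200]]
        redone = attach_contexts(stripped, default_cohort.contigs)
        for orig, new in zip(default_cohort.records[:200], redone):
            assert new.context == orig.context

    def test_label_prevalence_and_vaf_means_converge(self):
        cfg = CohortConfig(n_patients=300, seed=9)
        recs = simulate_cohort(cfg).records
        n = len(recs)
        for cls, p in cfg.class_mix.items():
            frac = sum(r.label == cls for r in recs) / n
            assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n) + 0.02
        for cls, (a, b) in cfg.vaf_models.items():
            vafs = [r.vaf for r in recs if r.label == cls]
            se = np.std(vafs, ddof=1) / np.sqrt(len(vafs))
            assert abs(np.mean(vafs) - a / (a + b)) <= 4 * se

    def test_duplicate_rate_produces_repeated_keys(self):
        cfg = CohortConfig(n_patients=60, seed=2, duplicate_rate=0.2)
        recs = simulate_cohort(cfg).records
        keys = [(r.chrom, r.pos, r.ref, r.alt) for r in recs]
        assert len(set(keys)) < len(keys)

    def test_annotation_table_shape_and_missingness(self, default_cohort):
        ann = default_cohort.annotation
        assert len(default_cohort.channel_names) == 37
        vals = ann[default_cohort.channel_names].apply(
            lambda c: c.astype(float))
        frac_missing = vals.isna().to_numpy().mean()
        assert 0.1 < frac_missing < 0.3

    @pytest.mark.parametrize("bad", [
        {"class_mix": {TUMOR: 0.7, CH_ONCOGENIC: 0.7, CH_NON_ONCOGENIC: 0.0}},
        {"vaf_models": {TUMOR: (0.0, 1.0), CH_ONCOGENIC: (1.5, 30.0),
                        CH_NON_ONCOGENIC: (1.2, 40.0)}},
        {"functional_missing_rate": 1.5},
        {"n_patients": 0},
    ])
    def test_invalid_config_fails_before_sampling(self, bad):
        with pytest.raises(ConfigurationError):
            simulate_cohort(CohortConfig(**bad))

    def test_signature_divergence_monotone_separability(self):
        """Blending class signatures toward a shared mixture can only lower
        the separability of a trinucleotide-count classifier."""
        shared = {"A[C>T]A": 0.25, "C[C>A]C": 0.25, "G[T>C]G": 0.25,
                  "T[C>G]T": 0.25}
        distinct_t = {"C[C>A]A": 0.5, "A[C>A]C": 0.5}
        distinct_c = {"A[C>T]G": 0.5, "C[C>T]G": 0.5}

        def blend(distinct, delta):
            out = {k: (1 - delta) * v for k, v in shared.items()}
            for k, v in distinct.items():
                out[k] = out.get(k, 0.0) + delta * v
            return out

        aurocs = []
        for delta in (0.1, 0.5, 1.0):
            cfg = CohortConfig(
                n_patients=150, seed=13,
                class_mix={TUMOR: 0.5, CH_ONCOGENIC: 0.5, CH_NON_ONCOGENIC: 0.0},
                signature_profiles={TUMOR: blend(distinct_t, delta),
                                    CH_ONCOGENIC: blend(distinct_c, delta),
                                    CH_NON_ONCOGENIC: {"A[T>C]A": 1.0}})
            recs = simulate_cohort(cfg).records
            tris = sorted({r.context[9:12] for r in recs})
            X = np.array([[r.context[9:12] == t for t in tris] for r in recs], float)
            y = np.array([r.label == CH_ONCOGENIC for r in recs], int)
            from sklearn.linear_model import LogisticRegression
            from sklearn.model_selection import cross_val_predict
            p = cross_val_predict(LogisticRegression(max_iter=1000), X, y,
                                  cv=3, method="predict_proba")[:, 1]
            aurocs.append(compute_auroc(p, y))
        assert aurocs[0] <= aurocs[1] + 0.03 <= aurocs[2] + 0.06


class TestSplitByPatient:
    def _records(self, n_patients):
        from conftest import make_record
        return [make_record(patient=f"P{i}", pos=100 + 10 * i + j)
                for i in range(n_patients) for j in range(3)]

    def test_even_split_partitions_patients(self):
        train, test = train_test_split_by_patient(self._records(10), 0.5, seed=0)
        tp = {r.patient_id for r in train}
        sp = {r.patient_id for r in test}
        assert len(tp) == 5 and len(sp) == 5 and not (tp & sp)

    def test_rounds_toward_train_but_keeps_one_test_patient(self):
        train, test = train_test_split_by_patient(self._records(10), 0.99, seed=0)
        assert len({r.patient_id for r in train}) == 9
        assert len({r.patient_id for r in test}) == 1

    def test_deterministic_under_seed(self):
        recs = self._records(12)
        a = train_test_split_by_patient(recs, 0.7, seed=5)
        b = train_test_split_by_patient(recs, 0.7, seed=5)
        assert a == b

    def test_too_few_patients(self):
        with pytest.raises(SplitError):
            train_test_split_by_patient(self._records(1), 0.5, seed=0)
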