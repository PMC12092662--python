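"""End-to-end three-stage classifier: embeddings -> base classifiers -> stacker.

:class:`MetaCHClassifier` binds the stages together:

1. self-supervised variant embeddings (contrastive, k-mer/gene/cancer-type
   tokens) and CBMG gene embeddings, trained on the supplied cohort(s);
2. three base classifiers — the cfDNA-based classifier (full feature set,
   patient-grouped stratified folds) and two sequence-based classifiers
   trained on deduplicated three-class data (CH-oncogenic vs rest,
   CH-non-oncogenic vs rest);
3. a logistic-regression meta-classifier stacked on the out-of-fold
   S_cfDNA and the sequence scores, reusing the cfDNA fold assignments.

``predict_scores`` returns per-variant S_cfDNA, S_Sequence1, S_Sequence2 and
the final S_Meta, the probability of blood (CH) origin.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .boosting import GradientBoostedClassifierCV, ScoreTriple
from .embeddings import GeneEmbedder, VariantEmbedder
from .errors import LabelError, StateError
from .features import CFDNA, SEQUENCE, FeatureAssembler
from .functional import FunctionalImputer, annotation_from_dataframe
from .metrics import compute_aupr, compute_auroc
from .variants import (CH_NON_ONCOGENIC, CH_ONCOGENIC, TUMOR, VariantRecord,
                       deduplicate_within_dataset, filter_unknown_significance,
                       variant_key)


def stage_seed(seed: int, stage: str) -> int:
    """Derive an independent, reproducible seed for one pipeline stage."""
    return (zlib.crc32(stage.encode()) ^ seed) % (2 ** 31)


class MetaCHClassifier(BaseEstimator, ClassifierMixin):
    """Stacked variant-origin classifier (CH = 1, tumor = 0).

    Parameters mirror the stage defaults; ``seed`` fans out to per-stage
    derived seeds so each stage is independently reproducible.
    """

    def __init__(self, variant_dim: int = 128, gene_dim: int = 8,
                 variant_epochs: int = 5, gene_epochs: int = 20,
                 k_neg: int = 10, min_token_count: int = 2,
                 param_grid: dict | None = None, n_splits: int = 5,
                 seed: int = 0):
        self.variant_dim = variant_dim
        self.gene_dim = gene_dim
        self.variant_epochs = variant_epochs
        self.gene_epochs = gene_epochs
        self.k_neg = k_neg
        self.min_token_count = min_token_count
        self.param_grid = param_grid
        self.n_splits = n_splits
        self.seed = seed

    # -- training ---------------------------------------------------------
    def fit(self, records: list[VariantRecord], y=None, annotation=None,
            seq_records: list[VariantRecord] | None = None) -> "MetaCHClassifier":
        """Train all three stages.

        ``records`` is the cfDNA-style labeled table (binary or three-class
        labels; UNKNOWN rows are dropped).  ``seq_records`` is the
        three-class sequence-training table; when omitted, ``records`` plays
        both roles (they must then carry three-class labels).  ``annotation``
        is an optional functional-score table (DataFrame or key->vector map).
        """
        cf_records = filter_unknown_significance(list(records))
        if not cf_records:
            raise LabelError(
                "label filtering left no training records: every row is "
                "UNKNOWN (is the label column present?)")
        seq_input = list(seq_records) if seq_records is not None else list(records)
        seq_recs = deduplicate_within_dataset(filter_unknown_significance(seq_input))
        for cls in (TUMOR, CH_ONCOGENIC, CH_NON_ONCOGENIC):
            if not any(r.label == cls for r in seq_recs):
                raise LabelError(f"sequence-training data lacks class {cls}")

        embed_corpus = cf_records if seq_records is None else cf_records + seq_recs
        self.variant_embedder_ = VariantEmbedder(
            dim=self.variant_dim, epochs=self.variant_epochs, k_neg=self.k_neg,
            min_count=self.min_token_count,
            seed=stage_seed(self.seed, "variant_embedding")).fit(embed_corpus)
        self.gene_embedder_ = GeneEmbedder(
            dim=self.gene_dim, epochs=self.gene_epochs,
            seed=stage_seed(self.seed, "gene_embedding")).fit(embed_corpus)

        self.functional_imputer_ = None
        if annotation is not None:
            if isinstance(annotation, pd.DataFrame):
                annotation = annotation_from_dataframe(annotation)
            training_keys = {variant_key(r) for r in embed_corpus}
            channels = None  # channel order comes from the table itself
            imp = FunctionalImputer(channel_names=channels)
            any_vec = next(iter(annotation.values()))
            imp.channel_names = [f"fscore_{i:02d}" for i in range(1, len(any_vec.values) + 1)]
            self.functional_imputer_ = imp.fit(annotation, training_keys)

        # stage 2a: cfDNA-based classifier (patient-grouped stratified folds)
        self.cfdna_assembler_ = FeatureAssembler(
            kind=CFDNA, variant_embedder=self.variant_embedder_,
            gene_embedder=self.gene_embedder_,
            functional_imputer=self.functional_imputer_).fit(cf_records)
        X_cf = self.cfdna_assembler_.transform(cf_records)
        y_cf = np.array([int(r.is_ch) for r in cf_records])
        groups = np.array([r.patient_id for r in cf_records])
        self.cfdna_clf_ = GradientBoostedClassifierCV(
            param_grid=self.param_grid, n_splits=self.n_splits,
            seed=stage_seed(self.seed, "cfdna_classifier")).fit(
                X_cf, y_cf, groups=groups)

        # stage 2b: sequence-based classifiers on deduplicated 3-class data
        self.sequence_assembler_ = FeatureAssembler(
            kind=SEQUENCE, variant_embedder=self.variant_embedder_,
            gene_embedder=self.gene_embedder_,
            functional_imputer=self.functional_imputer_).fit(seq_recs)
        X_seq = self.sequence_assembler_.transform(seq_recs)
        y3 = np.array([r.label for r in seq_recs])
        seq_folds = np.empty(len(y3), dtype=int)
        splitter = StratifiedKFold(n_splits=self.n_splits, shuffle=True,
                                   random_state=stage_seed(self.seed, "sequence_folds"))
        for k, (_, test_idx) in enumerate(splitter.split(X_seq, y3)):
            seq_folds[test_idx] = k
        self.seq1_clf_ = GradientBoostedClassifierCV(
            param_grid=self.param_grid, n_splits=self.n_splits,
            seed=stage_seed(self.seed, "sequence1_classifier")).fit(
                X_seq, (y3 == CH_ONCOGENIC).astype(int), folds=seq_folds)
        self.seq2_clf_ = GradientBoostedClassifierCV(
            param_grid=self.param_grid, n_splits=self.n_splits,
            seed=stage_seed(self.seed, "sequence2_classifier")).fit(
                X_seq, (y3 == CH_NON_ONCOGENIC).astype(int), folds=seq_folds)

        # stage 3: stack on out-of-fold S_cfDNA + sequence scores
        X_cf_seq = self.sequence_assembler_.transform(cf_records)
        s1 = self.seq1_clf_.predict_proba(X_cf_seq)[:, 1]
        s2 = self.seq2_clf_.predict_proba(X_cf_seq)[:, 1]
        X_meta = np.column_stack([self.cfdna_clf_.oof_scores_, s1, s2])
        from .meta import MetaClassifier

        self.meta_clf_ = MetaClassifier().fit(
            X_meta, y_cf, folds=self.cfdna_clf_.fold_assignments_,
            provenance=np.ones(len(y_cf), dtype=bool))

        self.oof_triples_ = X_meta
        self.classes_ = np.array([0, 1])
        self.cv_report_ = {
            "cfdna": self.cfdna_clf_.cv_metrics_,
            "sequence1": self.seq1_clf_.cv_metrics_,
            "sequence2": self.seq2_clf_.cv_metrics_,
            "meta": self.meta_clf_.cv_metrics_,
            "base_on_cfdna_set": {
                "cfdna_oof_auroc": self.cfdna_clf_.cv_metrics_["pooled_auroc"],
                "cfdna_oof_aupr": self.cfdna_clf_.cv_metrics_["pooled_aupr"],
                "seq1_auroc": compute_auroc(s1, y_cf),
                "seq1_aupr": compute_aupr(s1, y_cf),
                "seq2_auroc": compute_auroc(s2, y_cf),
                "seq2_aupr": compute_aupr(s2, y_cf),
            },
        }
        return self

    # -- inference --------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "meta_clf_"):
            raise StateError("MetaCHClassifier is not fitted")

    def predict_scores(self, records: list[VariantRecord],
                       annotation=None) -> pd.DataFrame:
        """Per-variant S_cfDNA, S_Sequence1, S_Sequence2 and S_Meta.

        Row order follows the input.  Cancer type is already excluded from
        inference-mode variant tokenization; an optional ``annotation`` table
        provides functional scores for the new variants (training medians
        fill everything else).
        """
        self._check_fitted()
        if annotation is not None and self.functional_imputer_ is not None:
            if isinstance(annotation, pd.DataFrame):
                annotation = annotation_from_dataframe(annotation)
            self.functional_imputer_.set_annotation(annotation)
        X_cf = self.cfdna_assembler_.transform(records)
        X_seq = self.sequence_assembler_.transform(records)
        s_cf = self.cfdna_clf_.predict_proba(X_cf)[:, 1]
        s1 = self.seq1_clf_.predict_proba(X_seq)[:, 1]
        s2 = self.seq2_clf_.predict_proba(X_seq)[:, 1]
        s_meta = self.meta_clf_.predict_proba(np.column_stack([s_cf, s1, s2]))[:, 1]
        return pd.DataFrame({"S_cfDNA": s_cf, "S_Sequence1": s1,
                             "S_Sequence2": s2, "S_Meta": s_meta})

    def score_variants(self, records: list[VariantRecord]) -> list[ScoreTriple]:
        """Base-classifier score triples, one per record, deterministic."""
        df = self.predict_scores(records)
        return [ScoreTriple(s_cfdna=row.S_cfDNA, s_seq1=row.S_Sequence1,
                            s_seq2=row.S_Sequence2)
                for row in df.itertuples(index=False)]

    def predict_proba(self, records: list[VariantRecord]) -> np.ndarray:
        pos = self.predict_scores(records)["S_Meta"].to_numpy()
        return np.column_stack([1.0 - pos, pos])

    def predict(self, records: list[VariantRecord]) -> np.ndarray:
        return (self.predict_proba(records)[:, 1] >= 0.5).astype(int)

    # -- persistence ------------------------------------------------------
    def save(self, outdir) -> None:
        """Persist the five model artifacts (metk, 3 base classifiers, meta)."""
        self._check_fitted()
        outdir = Path(outdir)
        metk = outdir / "metk"
        self.variant_embedder_.save(metk / "variant_embedder")
        self.gene_embedder_.save(metk / "gene_embedder")
        feats = {
            "cancer_types": self.cfdna_assembler_.cancer_types_,
            "vaf_median": self.cfdna_assembler_.vaf_median_,
            "sequence_cancer_types": self.sequence_assembler_.cancer_types_,
            "functional": None if self.functional_imputer_ is None else {
                "channel_names": self.functional_imputer_.channel_names_,
                "medians": self.functional_imputer_.medians_.tolist(),
            },
            "params": self.get_params(),
        }
        (metk / "features.json").write_text(json.dumps(feats, indent=2))
        self.cfdna_clf_.save(outdir / "cfdna")
        self.seq1_clf_.save(outdir / "sequence1")
        self.seq2_clf_.save(outdir / "sequence2")
        self.meta_clf_.save(outdir / "meta.json")

    @classmethod
    def load(cls, outdir) -> "MetaCHClassifier":
        from .meta import MetaClassifier

        outdir = Path(outdir)
        feats = json.loads((outdir / "metk" / "features.json").read_text())
        obj = cls(**feats["params"])
        obj.variant_embedder_ = VariantEmbedder.load(outdir / "metk" / "variant_embedder")
        obj.gene_embedder_ = GeneEmbedder.load(outdir / "metk" / "gene_embedder")
        obj.functional_imputer_ = None
        if feats["functional"] is not None:
            imp = FunctionalImputer(channel_names=feats["functional"]["channel_names"])
            imp.channel_names_ = feats["functional"]["channel_names"]
            imp.medians_ = np.asarray(feats["functional"]["medians"])
            imp.annotation_ = {}
            obj.functional_imputer_ = imp
        for attr, kind, key in (("cfdna_assembler_", CFDNA, "cancer_types"),
                                ("sequence_assembler_", SEQUENCE, "sequence_cancer_types")):
            asm = FeatureAssembler(kind=kind, variant_embedder=obj.variant_embedder_,
                                   gene_embedder=obj.gene_embedder_,
                                   functional_imputer=obj.functional_imputer_)
            asm.cancer_types_ = feats[key]
            asm.vaf_median_ = feats["vaf_median"]
            asm._build_layout()
            setattr(obj, attr, asm)
        obj.cfdna_clf_ = GradientBoostedClassifierCV.load(outdir / "cfdna")
        obj.seq1_clf_ = GradientBoostedClassifierCV.load(outdir / "sequence1")
        obj.seq2_clf_ = GradientBoostedClassifierCV.load(outdir / "sequence2")
        obj.meta_clf_ = MetaClassifier.load(outdir / "meta.json")
        obj.classes_ = np.array([0, 1])
        return obj
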