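"""Self-supervised variant embeddings (Ev) via contrastive learning.

A variant entity is described by a bag of namespaced tokens: overlapping
2-5-mers of its alt-centered sequence context (``kmer:``), its own identity
(``var:``), its gene (``gene:``) and — during training only — its cancer type
(``ctype:``).  A patient is a bag of variants; training maximizes the cosine
similarity between the bag embeddings of variants co-occurring in the same
patient while pushing away randomly sampled variants from other patients,
with a margin-ranking hinge loss (a StarSpace-style objective).

The embedding of a variant is the mean of its in-vocabulary token vectors.
Cancer type is excluded from inference-mode bags so the embeddings
generalize across datasets; variant-identity tokens naturally fall out of
vocabulary for unseen variants, leaving k-mer and gene tokens to carry the
signal.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ..errors import (AggregationError, EmptyInputError, NumericalError,
                      StateError, TrainingError)
from ..variants import UNKNOWN, VariantRecord, variant_key

TRAIN = "TRAIN"
INFER = "INFER"

_KMER_SIZES = (2, 3, 4, 5)
_DNA = frozenset("ACGT")


def tokenize_variant(record: VariantRecord, mode: str) -> list[str]:
    """Token bag for one variant.

    All overlapping substrings of the context of lengths 2-5 (k-mers
    containing any non-ACGT character are dropped), plus the variant-identity
    token, the gene token, and — in TRAIN mode only, when known — the
    cancer-type token.
    """
    if mode not in (TRAIN, INFER):
        raise ValueError(f"mode must be TRAIN or INFER, got {mode!r}")
    if not record.context and not record.gene:
        raise EmptyInputError(f"variant {variant_key(record)} has neither context nor gene")
    tokens: list[str] = []
    ctx = record.context or ""
    for k in _KMER_SIZES:
        for i in range(len(ctx) - k + 1):
            kmer = ctx[i:i + k]
            if set(kmer) <= _DNA:
                tokens.append(f"kmer:{kmer}")
    tokens.append(f"var:{variant_key(record)}")
    if record.gene:
        tokens.append(f"gene:{record.gene}")
    if mode == TRAIN and record.cancer_type and record.cancer_type != UNKNOWN:
        tokens.append(f"ctype:{record.cancer_type}")
    return tokens


class VariantEmbedder(BaseEstimator, TransformerMixin):
    """StarSpace-style contrastive embedder over patient bags of variants.

    Parameters
    ----------
    dim : embedding dimension (|Ev|), default 128.
    epochs, learning_rate : SGD schedule; the learning rate decays linearly
        per step.
    margin : hinge margin m in max(0, m - sim(a,p) + sim(a,n)).
    k_neg : negatives sampled per (anchor, positive) pair, uniformly from
        variants of other patients.
    min_count : tokens seen fewer times than this are excluded from the
        vocabulary (variant-identity tokens are usually singletons and thus
        drop out, by design).
    seed : seeds initialization, pair shuffling and negative sampling.

    Attributes (fitted)
    -------------------
    vocabulary_ : dict token -> row index
    counts_ : dict token -> training count
    vectors_ : (V, dim) float array
    loss_history_ : mean hinge loss per epoch
    """

    def __init__(self, dim: int = 128, epochs: int = 5, learning_rate: float = 0.05,
                 margin: float = 0.05, k_neg: int = 10, min_count: int = 2,
                 seed: int = 0):
        self.dim = dim
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.margin = margin
        self.k_neg = k_neg
        self.min_count = min_count
        self.seed = seed

    # -- fitting ----------------------------------------------------------
    def fit(self, records: list[VariantRecord], y=None) -> "VariantEmbedder":
        rng = np.random.default_rng(self.seed)
        bags = [tokenize_variant(r, TRAIN) for r in records]
        counts: dict[str, int] = {}
        for bag in bags:
            for tok in bag:
                counts[tok] = counts.get(tok, 0) + 1
        vocab = {tok: i for i, tok in enumerate(sorted(
            t for t, c in counts.items() if c >= self.min_count))}
        self.vocabulary_ = vocab
        self.counts_ = {t: counts[t] for t in vocab}
        self.vectors_ = rng.uniform(-1.0 / self.dim, 1.0 / self.dim,
                                    size=(len(vocab), self.dim))
        self.loss_history_: list[float] = []

        # per-variant in-vocabulary token index arrays (TRAIN bags)
        idx = [np.array([vocab[t] for t in bag if t in vocab], dtype=np.intp)
               for bag in bags]
        patient_code = {p: i for i, p in enumerate(sorted({r.patient_id for r in records}))}
        patient_of = np.array([patient_code[r.patient_id] for r in records])
        # ordered within-patient pairs
        by_patient: dict[str, list[int]] = {}
        for i, r in enumerate(records):
            by_patient.setdefault(r.patient_id, []).append(i)
        pairs = [(a, p)
                 for pid in sorted(by_patient)
                 for a in by_patient[pid]
                 for p in by_patient[pid]
                 if a != p and len(idx[a]) and len(idx[p])]
        if not pairs:
            raise TrainingError("no patient contributes >= 2 variants with tokens")
        pairs = np.array(pairs, dtype=np.intp)
        n = len(records)
        total_steps = max(1, self.epochs * len(pairs))
        step = 0
        V = self.vectors_
        for epoch in range(self.epochs):
            order = rng.permutation(len(pairs))
            epoch_loss = 0.0
            for a, p in pairs[order]:
                lr = self.learning_rate * max(1e-4, 1.0 - step / total_steps)
                step += 1
                # sample negatives from other patients (reject same patient)
                negs = rng.integers(0, n, size=self.k_neg)
                bad = patient_of[negs] == patient_of[a]
                tries = 0
                while bad.any() and tries < 20:
                    negs[bad] = rng.integers(0, n, size=int(bad.sum()))
                    bad = patient_of[negs] == patient_of[a]
                    tries += 1
                negs = negs[~bad]
                negs = negs[[len(idx[g]) > 0 for g in negs]]
                if len(negs) == 0:
                    continue
                ia, ip = idx[a], idx[p]
                ea = V[ia].mean(axis=0)
                ep = V[ip].mean(axis=0)
                na, npn = np.linalg.norm(ea), np.linalg.norm(ep)
                if na == 0 or npn == 0:
                    continue
                s_ap = float(ea @ ep) / (na * npn)
                grads_a = np.zeros(self.dim)
                grad_p = np.zeros(self.dim)
                n_active = 0
                # d cos(u,v)/du = v/(|u||v|) - cos * u/|u|^2
                d_ap_da = ep / (na * npn) - s_ap * ea / (na * na)
                d_ap_dp = ea / (na * npn) - s_ap * ep / (npn * npn)
                for g in negs:
                    ig = idx[g]
                    eg = V[ig].mean(axis=0)
                    ng = np.linalg.norm(eg)
                    if ng == 0:
                        continue
                    s_an = float(ea @ eg) / (na * ng)
                    loss = self.margin - s_ap + s_an
                    epoch_loss += max(0.0, loss)
                    if loss <= 0.0:
                        continue
                    n_active += 1
                    d_an_da = eg / (na * ng) - s_an * ea / (na * na)
                    d_an_dg = ea / (na * ng) - s_an * eg / (ng * ng)
                    grads_a += (-d_ap_da + d_an_da)
                    grad_p += -d_ap_dp
                    np.add.at(V, ig, -lr * d_an_dg / len(ig))
                if n_active:
                    np.add.at(V, ia, -lr * grads_a / len(ia))
                    np.add.at(V, ip, -lr * grad_p / len(ip))
            mean_loss = epoch_loss / max(1, len(pairs) * self.k_neg)
            if not np.isfinite(mean_loss) or not np.all(np.isfinite(V)):
                raise NumericalError(f"non-finite loss/vectors at epoch {epoch}")
            self.loss_history_.append(mean_loss)
        return self

    # -- inference --------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "vectors_"):
            raise StateError("VariantEmbedder is not fitted")

    def embed(self, record: VariantRecord) -> tuple[np.ndarray, bool]:
        """Inference-mode embedding; returns (vector, out_of_vocabulary)."""
        self._check_fitted()
        ids = [self.vocabulary_[t] for t in tokenize_variant(record, INFER)
               if t in self.vocabulary_]
        if not ids:
            return np.zeros(self.dim), True
        return self.vectors_[np.array(ids, dtype=np.intp)].mean(axis=0), False

    def transform(self, records: list[VariantRecord]) -> np.ndarray:
        self._check_fitted()
        return np.vstack([self.embed(r)[0] for r in records]) if records \
            else np.empty((0, self.dim))

    # -- persistence ------------------------------------------------------
    def save(self, outdir) -> None:
        self._check_fitted()
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tokens = sorted(self.vocabulary_, key=self.vocabulary_.get)
        with open(outdir / "vocabulary.tsv", "w") as fh:
            fh.write("token\tcount\n")
            for t in tokens:
                fh.write(f"{t}\t{self.counts_[t]}\n")
        np.savetxt(outdir / "vectors.tsv", self.vectors_, delimiter="\t")
        manifest = {"kind": "variant_embedding", "dim": self.dim,
                    "epochs": self.epochs, "learning_rate": self.learning_rate,
                    "margin": self.margin, "k_neg": self.k_neg,
                    "min_count": self.min_count, "seed": self.seed,
                    "loss_history": self.loss_history_}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, outdir) -> "VariantEmbedder":
        outdir = Path(outdir)
        manifest = json.loads((outdir / "manifest.json").read_text())
        model = cls(dim=manifest["dim"], epochs=manifest["epochs"],
                    learning_rate=manifest["learning_rate"],
                    margin=manifest["margin"], k_neg=manifest["k_neg"],
                    min_count=manifest["min_count"], seed=manifest["seed"])
        tokens, cnts = [], []
        with open(outdir / "vocabulary.tsv") as fh:
            next(fh)
            for line in fh:
                t, c = line.rstrip("\n").split("\t")
                tokens.append(t)
                cnts.append(int(c))
        model.vocabulary_ = {t: i for i, t in enumerate(tokens)}
        model.counts_ = dict(zip(tokens, cnts))
        model.vectors_ = np.loadtxt(outdir / "vectors.tsv", delimiter="\t",
                                    ndmin=2)
        model.loss_history_ = manifest["loss_history"]
        return model


def embed_variant(record: VariantRecord, model: VariantEmbedder) -> np.ndarray:
    """Ev for one record: mean of in-vocabulary token vectors (zeros if OOV)."""
    return model.embed(record)[0]


def patient_variant_embedding(variant_embeddings) -> np.ndarray:
    """Epv: element-wise mean of a patient's variant embeddings."""
    arr = np.asarray(variant_embeddings, dtype=float)
    if arr.size == 0:
        raise AggregationError("cannot average an empty set of variant embeddings")
    return arr.mean(axis=0)
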