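"""Continuous Bag-of-Mutated-Genes (CBMG) gene embeddings (Eg).

Each patient is a bag (set) of mutated genes, analogous to a sentence of
words.  Training is CBOW with negative sampling: per epoch, each gene of a
bag serves once as the target (in seeded-shuffled order); the context vector
is the mean of the input vectors of the remaining genes; the objective

    log sigma(c . o_t) + sum_neg log sigma(-c . o_n)

is ascended by SGD on both vector tables, with negatives drawn from the
gene unigram distribution raised to the 0.75 power.  Eg(gene) is the input
vector; patients with a single distinct gene contribute no training targets.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ..errors import AggregationError, StateError, TrainingError
from ..variants import VariantRecord


def build_gene_bags(records: list[VariantRecord]) -> dict[str, set[str]]:
    """Per-patient deduplicated gene sets (within-patient multiplicity ignored)."""
    bags: dict[str, set[str]] = {}
    for rec in records:
        bags.setdefault(rec.patient_id, set()).add(rec.gene)
    return bags


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


class GeneEmbedder(BaseEstimator, TransformerMixin):
    """CBOW-with-negative-sampling embedder over patient gene bags.

    Attributes (fitted): ``vocabulary_`` (gene -> index), ``counts_``,
    ``input_vectors_`` and ``output_vectors_`` ((V, dim) arrays),
    ``objective_history_`` (mean log-likelihood per epoch, ascending on
    well-behaved corpora).
    """

    def __init__(self, dim: int = 8, epochs: int = 20, learning_rate: float = 0.025,
                 k_neg: int = 5, min_count: int = 1, neg_power: float = 0.75,
                 seed: int = 0):
        self.dim = dim
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.k_neg = k_neg
        self.min_count = min_count
        self.neg_power = neg_power
        self.seed = seed

    def fit(self, bags: Mapping[str, set] | list[VariantRecord], y=None) -> "GeneEmbedder":
        if isinstance(bags, list):
            bags = build_gene_bags(bags)
        rng = np.random.default_rng(self.seed)
        counts: dict[str, int] = {}
        for genes in bags.values():
            for g in genes:
                counts[g] = counts.get(g, 0) + 1
        vocab = {g: i for i, g in enumerate(sorted(
            g for g, c in counts.items() if c >= self.min_count))}
        if not vocab:
            raise TrainingError("empty gene vocabulary")
        self.vocabulary_ = vocab
        self.counts_ = {g: counts[g] for g in vocab}
        V = len(vocab)
        self.input_vectors_ = rng.uniform(-1.0 / self.dim, 1.0 / self.dim, (V, self.dim))
        self.output_vectors_ = rng.uniform(-1.0 / self.dim, 1.0 / self.dim, (V, self.dim))
        self.objective_history_: list[float] = []

        bag_idx = []
        for pid in sorted(bags):
            ids = sorted(vocab[g] for g in bags[pid] if g in vocab)
            if len(ids) >= 2:
                bag_idx.append(np.array(ids, dtype=np.intp))
        if not bag_idx:
            raise TrainingError("no patient has >= 2 distinct in-vocabulary genes")

        freq = np.array([self.counts_[g] for g in sorted(vocab, key=vocab.get)],
                        dtype=float) ** self.neg_power
        neg_p = freq / freq.sum()

        Win, Wout = self.input_vectors_, self.output_vectors_
        total_steps = max(1, self.epochs * sum(len(b) for b in bag_idx))
        step = 0
        for _epoch in range(self.epochs):
            obj, n_terms = 0.0, 0
            for ids in bag_idx:
                order = rng.permutation(len(ids))
                for t in order:
                    lr = self.learning_rate * max(1e-4, 1.0 - step / total_steps)
                    step += 1
                    target = ids[t]
                    ctx_ids = np.delete(ids, t)
                    ctx = Win[ctx_ids].mean(axis=0)
                    negs = rng.choice(len(neg_p), size=self.k_neg, p=neg_p)
                    grad_ctx = np.zeros(self.dim)
                    g_pos = _sigmoid(float(ctx @ Wout[target]))
                    obj += np.log(max(g_pos, 1e-12))
                    grad_ctx += (1.0 - g_pos) * Wout[target]
                    Wout[target] += lr * (1.0 - g_pos) * ctx
                    for n_id in negs:
                        g_neg = _sigmoid(float(ctx @ Wout[n_id]))
                        obj += np.log(max(1.0 - g_neg, 1e-12))
                        grad_ctx -= g_neg * Wout[n_id]
                        Wout[n_id] -= lr * g_neg * ctx
                    n_terms += 1 + self.k_neg
                    Win[ctx_ids] += lr * grad_ctx / len(ctx_ids)
            self.objective_history_.append(obj / max(1, n_terms))
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "input_vectors_"):
            raise StateError("GeneEmbedder is not fitted")

    def embed(self, gene: str) -> tuple[np.ndarray, bool]:
        """Eg for one gene; returns (vector, out_of_vocabulary)."""
        self._check_fitted()
        idx = self.vocabulary_.get(gene)
        if idx is None:
            return np.zeros(self.dim), True
        return self.input_vectors_[idx].copy(), False

    def transform(self, genes: list[str]) -> np.ndarray:
        self._check_fitted()
        return np.vstack([self.embed(g)[0] for g in genes]) if genes \
            else np.empty((0, self.dim))

    def save(self, outdir) -> None:
        self._check_fitted()
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        genes = sorted(self.vocabulary_, key=self.vocabulary_.get)
        with open(outdir / "vocabulary.tsv", "w") as fh:
            fh.write("gene\tcount\n")
            for g in genes:
                fh.write(f"{g}\t{self.counts_[g]}\n")
        np.savetxt(outdir / "input_vectors.tsv", self.input_vectors_, delimiter="\t")
        np.savetxt(outdir / "output_vectors.tsv", self.output_vectors_, delimiter="\t")
        manifest = {"kind": "gene_embedding", "dim": self.dim, "epochs": self.epochs,
                    "learning_rate": self.learning_rate, "k_neg": self.k_neg,
                    "min_count": self.min_count, "neg_power": self.neg_power,
                    "seed": self.seed, "objective_history": self.objective_history_}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, outdir) -> "GeneEmbedder":
        outdir = Path(outdir)
        manifest = json.loads((outdir / "manifest.json").read_text())
        model = cls(dim=manifest["dim"], epochs=manifest["epochs"],
                    learning_rate=manifest["learning_rate"], k_neg=manifest["k_neg"],
                    min_count=manifest["min_count"], neg_power=manifest["neg_power"],
                    seed=manifest["seed"])
        genes, cnts = [], []
        with open(outdir / "vocabulary.tsv") as fh:
            next(fh)
            for line in fh:
                g, c = line.rstrip("\n").split("\t")
                genes.append(g)
                cnts.append(int(c))
        model.vocabulary_ = {g: i for i, g in enumerate(genes)}
        model.counts_ = dict(zip(genes, cnts))
        model.input_vectors_ = np.loadtxt(outdir / "input_vectors.tsv",
                                          delimiter="\t", ndmin=2)
        model.output_vectors_ = np.loadtxt(outdir / "output_vectors.tsv",
                                           delimiter="\t", ndmin=2)
        model.objective_history_ = manifest["objective_history"]
        return model


def embed_gene(gene: str, model: GeneEmbedder) -> np.ndarray:
    """Eg for one gene symbol (zeros when out of vocabulary)."""
    return model.embed(gene)[0]


def patient_gene_embedding(gene_embeddings) -> np.ndarray:
    """Epg: element-wise mean of a patient's gene embeddings."""
    arr = np.asarray(gene_embeddings, dtype=float)
    if arr.size == 0:
        raise AggregationError("cannot average an empty set of gene embeddings")
    return arr.mean(axis=0)
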