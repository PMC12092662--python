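"""Synthetic cfDNA cohort generator.

Emulates the statistical structure the classifier stack assumes, so every
stage is exercisable at desk scale without any external download:

* patients are bags of variants; each patient has a latent class propensity
  (a Dirichlet draw around the cohort-level class mix), reflecting that some
  patients are CH-heavy (high clonal-hematopoiesis burden) while others are
  dominated by tumor shedding;
* each variant class (tumor / CH-oncogenic / CH-non-oncogenic) has its own
  trinucleotide-substitution signature mixture, gene usage weights with
  co-occurrence modules, and Beta-distributed VAF model;
* gene co-occurrence modules are patient-level latent binary factors: an
  active module multiplies the usage weights of its member genes, giving the
  gene-embedding model a recoverable structure;
* a 37-channel functional-annotation block with class-dependent means,
  cell-level missingness and whole-variant dropout mimics scores available
  only for (most) non-synonymous variants.

One contig is emitted per gene, and the reference bases around each sampled
position are made consistent with the variant's signature-drawn trinucleotide,
so :func:`metach.io.attach_contexts` reproduces each variant's context from
the emitted FASTA.  All randomness flows from a single seeded generator;
a fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, SplitError
from .io import attach_contexts, write_fasta, write_variant_table
from .variants import CH_NON_ONCOGENIC, CH_ONCOGENIC, TUMOR, VariantRecord

_SIG_RE = re.compile(r"^([ACGT])\[([ACGT])>([ACGT])\]([ACGT])$")

CLASSES = (TUMOR, CH_ONCOGENIC, CH_NON_ONCOGENIC)


def default_signature_profiles() -> dict[str, dict[str, float]]:
    """Per-class trinucleotide-substitution mixtures.

    Tumor variants lean on smoking-like C>A substitutions; CH-oncogenic
    variants on the aging-associated C>T-at-CpG pattern; CH-non-oncogenic
    variants on a clock-like T>C pattern.
    """
    return {
        TUMOR: {
            "C[C>A]A": 0.30, "A[C>A]C": 0.20, "T[C>A]T": 0.15,
            "G[T>G]T": 0.15, "C[T>A]G": 0.20,
        },
        CH_ONCOGENIC: {
            "A[C>T]G": 0.35, "C[C>T]G": 0.25, "G[C>T]G": 0.20, "T[C>T]G": 0.20,
        },
        CH_NON_ONCOGENIC: {
            "A[T>C]A": 0.30, "C[T>C]T": 0.25, "G[T>C]C": 0.25, "T[T>C]G": 0.20,
        },
    }


def default_gene_sets() -> dict[str, dict[str, float]]:
    return {
        TUMOR: {
            "TP53": 3.0, "KRAS": 2.0, "EGFR": 2.0, "PIK3CA": 2.0,
            "BRAF": 1.0, "APC": 1.0, "PTEN": 1.0, "ERBB2": 1.0,
        },
        CH_ONCOGENIC: {
            "DNMT3A": 3.0, "TET2": 2.5, "ASXL1": 2.0, "JAK2": 1.0,
            "PPM1D": 1.0, "SF3B1": 1.0, "SRSF2": 1.0,
        },
        CH_NON_ONCOGENIC: {
            "DNMT3A": 1.0, "TET2": 0.8, "ATM": 1.5, "CHEK2": 1.2,
            "GNB1": 1.0, "CBL": 1.0,
        },
    }


def default_gene_modules() -> dict[str, list[list[str]]]:
    return {
        TUMOR: [["KRAS", "APC"], ["EGFR", "ERBB2"]],
        CH_ONCOGENIC: [["DNMT3A", "TET2"]],
        CH_NON_ONCOGENIC: [["ATM", "CHEK2"]],
    }


def default_functional_model(n_channels: int = 37) -> dict[str, dict[str, list[float]]]:
    """Class-conditional means/sds per channel.

    Channels 1-12 behave like deleteriousness predictors (high for oncogenic
    CH drivers, low for benign CH variants); channels 13-20 like tumor-driver
    scores; the rest are uninformative noise channels.
    """
    model = {}
    for cls in CLASSES:
        mean = [0.0] * n_channels
        if cls == CH_ONCOGENIC:
            for i in range(0, min(12, n_channels)):
                mean[i] = 1.0
        elif cls == CH_NON_ONCOGENIC:
            for i in range(0, min(12, n_channels)):
                mean[i] = -0.8
        elif cls == TUMOR:
            for i in range(12, min(20, n_channels)):
                mean[i] = 0.6
        model[cls] = {"mean": mean, "sd": [1.0] * n_channels}
    return model


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    The cohort-level class mix defaults to roughly one third tumor and two
    thirds CH variants, the balance typical of matched-WBC-annotated cfDNA
    ground truth; CH VAFs sit lower than tumor VAFs.
    """

    n_patients: int = 400
    variants_per_patient_mean: float = 8.0
    variants_per_patient_dispersion: float = 8.0
    class_mix: dict = field(default_factory=lambda: {
        TUMOR: 0.40, CH_ONCOGENIC: 0.35, CH_NON_ONCOGENIC: 0.25})
    patient_mix_concentration: float = 1.0
    signature_profiles: dict = field(default_factory=default_signature_profiles)
    gene_sets: dict = field(default_factory=default_gene_sets)
    gene_modules: dict = field(default_factory=default_gene_modules)
    module_activation_prob: float = 0.3
    module_boost: float = 5.0
    vaf_models: dict = field(default_factory=lambda: {
        TUMOR: (2.0, 10.0), CH_ONCOGENIC: (1.5, 30.0), CH_NON_ONCOGENIC: (1.2, 40.0)})
    cancer_types: dict = field(default_factory=lambda: {
        "NSCLC": 0.40, "BREAST": 0.35, "PROSTATE": 0.25})
    n_functional_channels: int = 37
    functional_score_model: dict | None = None
    functional_missing_rate: float = 0.2
    annotation_dropout: float = 0.1
    duplicate_rate: float = 0.0
    contig_length: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.functional_score_model is None:
            self.functional_score_model = default_functional_model(self.n_functional_channels)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not math.isclose(sum(self.class_mix.values()), 1.0, abs_tol=1e-9):
            raise ConfigurationError("class_mix must sum to 1")
        if any(p < 0 for p in self.class_mix.values()):
            raise ConfigurationError("class_mix proportions must be non-negative")
        for cls, profile in self.signature_profiles.items():
            if not profile:
                raise ConfigurationError(f"empty signature profile for {cls}")
            if not math.isclose(sum(profile.values()), 1.0, abs_tol=1e-9):
                raise ConfigurationError(f"signature profile for {cls} must sum to 1")
            for entry in profile:
                m = _SIG_RE.match(entry)
                if m is None or m.group(2) == m.group(3):
                    raise ConfigurationError(f"bad signature entry {entry!r} for {cls}")
        for cls, (a, b) in self.vaf_models.items():
            if a <= 0 or b <= 0:
                raise ConfigurationError(f"Beta parameters for {cls} must be positive")
        for name, rate in (("functional_missing_rate", self.functional_missing_rate),
                           ("annotation_dropout", self.annotation_dropout),
                           ("duplicate_rate", self.duplicate_rate),
                           ("module_activation_prob", self.module_activation_prob)):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for cls, mix in self.class_mix.items():
            if mix > 0 and not self.gene_sets.get(cls):
                raise ConfigurationError(f"class {cls} has positive mix but no gene set")
            if mix > 0 and cls not in self.signature_profiles:
                raise ConfigurationError(f"class {cls} has positive mix but no signature profile")
            if mix > 0 and cls not in self.vaf_models:
                raise ConfigurationError(f"class {cls} has positive mix but no VAF model")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["vaf_models"] = {k: list(v) for k, v in self.vaf_models.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "vaf_models" in d:
            d["vaf_models"] = {k: tuple(v) for k, v in d["vaf_models"].items()}
        return cls(**d)


def two_signature_config(seed: int, n_patients: int = 120) -> CohortConfig:
    """Two well-separated classes (tumor vs CH-oncogenic) with near-pure patients.

    Mirrors the structure of real embedding-training corpora, where
    blood-derived and tumor-derived variants come from separate cohorts, so
    within-patient co-occurrence carries a strong class signal.  Used for
    embedding-geometry checks.
    """
    return CohortConfig(
        n_patients=n_patients, seed=seed, patient_mix_concentration=0.25,
        class_mix={TUMOR: 0.5, CH_ONCOGENIC: 0.5, CH_NON_ONCOGENIC: 0.0},
    )


def gene_driven_config(seed: int, n_patients: int = 250) -> CohortConfig:
    """Cohort where gene identity carries most of the origin signal.

    Class signatures share 85% of their mass, VAF models overlap, and the
    functional-score shifts are damped, while CH usage concentrates in the
    three canonical CH genes (DNMT3A, TET2, ASXL1) with a little tumor
    usage of the same genes.  Removing the canonical genes then measurably
    lowers auROC while the remaining variants stay classifiable — the
    desk-scale analog of the canonical-CH-gene removal analysis.
    """
    shared = {"A[C>T]A": 0.2, "C[C>A]C": 0.2, "G[T>C]G": 0.2,
              "T[C>G]T": 0.2, "A[T>C]C": 0.2}

    def blend(distinct, delta=0.15):
        out = {k: (1 - delta) * v for k, v in shared.items()}
        for k, v in distinct.items():
            out[k] = out.get(k, 0.0) + delta * v
        return out

    signatures = {
        TUMOR: blend({"C[C>A]A": 0.5, "A[C>A]C": 0.5}),
        CH_ONCOGENIC: blend({"A[C>T]G": 0.5, "C[C>T]G": 0.5}),
        CH_NON_ONCOGENIC: blend({"A[T>C]A": 0.5, "T[T>C]G": 0.5}),
    }
    gene_sets = {
        TUMOR: {"TP53": 3.0, "KRAS": 2.0, "EGFR": 2.0, "PIK3CA": 1.5,
                "BRAF": 1.0, "APC": 1.0, "ATM": 0.5, "CHEK2": 0.5,
                "JAK2": 0.3, "DNMT3A": 0.15, "TET2": 0.1, "ASXL1": 0.1},
        CH_ONCOGENIC: {"DNMT3A": 4.0, "TET2": 3.0, "ASXL1": 2.0,
                       "JAK2": 0.8, "PPM1D": 0.8, "TP53": 0.4},
        CH_NON_ONCOGENIC: {"DNMT3A": 2.5, "TET2": 2.0, "ASXL1": 1.5,
                           "ATM": 0.8, "CHEK2": 0.8, "GNB1": 0.5},
    }
    functional = default_functional_model()
    for cls in functional:
        functional[cls]["mean"] = [0.15 * m for m in functional[cls]["mean"]]
    return CohortConfig(
        n_patients=n_patients, seed=seed, signature_profiles=signatures,
        gene_sets=gene_sets,
        vaf_models={TUMOR: (1.5, 22.0), CH_ONCOGENIC: (1.5, 30.0),
                    CH_NON_ONCOGENIC: (1.2, 40.0)},
        functional_score_model=functional,
    )


CANONICAL_CH_GENES = frozenset({"DNMT3A", "TET2", "ASXL1"})


@dataclass
class SimulatedCohort:
    records: list[VariantRecord]
    contigs: dict[str, str]
    annotation: pd.DataFrame
    config: CohortConfig

    @property
    def channel_names(self) -> list[str]:
        return [c for c in self.annotation.columns if c.startswith("fscore_")]


def functional_channel_names(n: int = 37) -> list[str]:
    return [f"fscore_{i:02d}" for i in range(1, n + 1)]


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Sample one cohort; fixed seed implies byte-identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    classes = [c for c in CLASSES if config.class_mix.get(c, 0.0) > 0]
    mix = np.array([config.class_mix[c] for c in classes])
    mix = mix / mix.sum()

    genes = sorted({g for cls in classes for g in config.gene_sets[cls]})
    bases = np.array(list("ACGT"))
    contig_arrays = {
        g: rng.choice(bases, size=config.contig_length) for g in genes
    }
    contig_name = {g: f"ctg_{g}" for g in genes}
    used_positions: dict[str, set[int]] = {g: set() for g in genes}

    ct_names = sorted(config.cancer_types)
    ct_weights = np.array([config.cancer_types[c] for c in ct_names], dtype=float)
    ct_weights = ct_weights / ct_weights.sum()

    mu = config.variants_per_patient_mean
    r = config.variants_per_patient_dispersion
    nb_p = r / (r + mu)

    # signature tables per class, parsed once
    sig_tables = {}
    for cls in classes:
        entries = sorted(config.signature_profiles[cls].items())
        probs = np.array([p for _, p in entries], dtype=float)
        parsed = [_SIG_RE.match(e).groups() for e, _ in entries]
        sig_tables[cls] = (parsed, probs / probs.sum())

    records: list[VariantRecord] = []
    emitted: list[VariantRecord] = []  # pool for duplicate sampling
    margin = 15  # keeps full 10-bp flanks inside the contig

    for pi in range(config.n_patients):
        patient = f"P{pi + 1:04d}"
        cancer_type = ct_names[rng.choice(len(ct_names), p=ct_weights)]
        if len(classes) > 1 and config.patient_mix_concentration is not None:
            alpha = config.patient_mix_concentration * mix * len(classes)
            patient_mix = rng.dirichlet(alpha)
        else:
            patient_mix = mix
        active: dict[str, np.ndarray] = {}
        for cls in classes:
            modules = config.gene_modules.get(cls, [])
            active[cls] = rng.random(len(modules)) < config.module_activation_prob
        n_var = max(1, int(rng.negative_binomial(r, nb_p)))
        for _ in range(n_var):
            cls = classes[rng.choice(len(classes), p=patient_mix)]
            if config.duplicate_rate > 0 and emitted and rng.random() < config.duplicate_rate:
                src = emitted[rng.integers(len(emitted))]
                a, b = config.vaf_models[src.label]
                rec = src.with_(patient_id=patient, cancer_type=cancer_type,
                                vaf=float(rng.beta(a, b)))
                records.append(rec)
                continue
            weights = dict(config.gene_sets[cls])
            for mod, is_active in zip(config.gene_modules.get(cls, []), active[cls]):
                if is_active:
                    for g in mod:
                        if g in weights:
                            weights[g] *= config.module_boost
            gnames = sorted(weights)
            gw = np.array([weights[g] for g in gnames], dtype=float)
            gene = gnames[rng.choice(len(gnames), p=gw / gw.sum())]
            parsed, probs = sig_tables[cls]
            left, ref, alt, right = parsed[rng.choice(len(parsed), p=probs)]
            # sample a position with >=3 bp separation from previous variants
            pos = None
            for _attempt in range(1000):
                cand = int(rng.integers(margin, config.contig_length - margin))
                if all(abs(cand - u) > 2 for u in used_positions[gene]):
                    pos = cand
                    break
            if pos is None:
                raise ConfigurationError(
                    f"contig for {gene} too crowded; increase contig_length")
            used_positions[gene].add(pos)
            arr = contig_arrays[gene]
            arr[pos - 2], arr[pos - 1], arr[pos] = left, ref, right
            a, b = config.vaf_models[cls]
            rec = VariantRecord(
                patient_id=patient, chrom=contig_name[gene], pos=pos, ref=ref,
                alt=alt, gene=gene, cancer_type=cancer_type,
                vaf=float(rng.beta(a, b)), label=cls,
            )
            records.append(rec)
            emitted.append(rec)

    contigs = {contig_name[g]: "".join(contig_arrays[g]) for g in genes}
    records = attach_contexts(records, contigs, flank=10)

    annotation = _sample_annotation(records, config, rng)
    return SimulatedCohort(records=records, contigs=contigs,
                           annotation=annotation, config=config)


def _sample_annotation(records, config, rng) -> pd.DataFrame:
    channels = functional_channel_names(config.n_functional_channels)
    seen: set[tuple] = set()
    rows = []
    for rec in records:
        key = (rec.chrom, rec.pos, rec.ref, rec.alt)
        if key in seen:
            continue
        seen.add(key)
        if rng.random() < config.annotation_dropout:
            continue
        model = config.functional_score_model[rec.label]
        mean = np.asarray(model["mean"], dtype=float)
        sd = np.asarray(model["sd"], dtype=float)
        values = mean + sd * rng.standard_normal(len(channels))
        mask = rng.random(len(channels)) < config.functional_missing_rate
        values = values.astype(object)
        values[mask] = np.nan
        rows.append({"Chromosome": rec.chrom, "Start_Position": rec.pos,
                     "Reference_Allele": rec.ref, "Tumor_Seq_Allele2": rec.alt,
                     **dict(zip(channels, values))})
    return pd.DataFrame(rows, columns=["Chromosome", "Start_Position",
                                       "Reference_Allele", "Tumor_Seq_Allele2", *channels])


def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, Path]:
    """Write the MAF-like table, FASTA contigs, annotation TSV and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": outdir / "variants.tsv",
        "reference": outdir / "reference.fasta",
        "annotation": outdir / "functional_scores.tsv",
        "config": outdir / "cohort_config.yaml",
    }
    write_variant_table(cohort.records, paths["variants"])
    write_fasta(cohort.contigs, paths["reference"])
    ann = cohort.annotation.copy()
    ann.to_csv(paths["annotation"], sep="\t", index=False, na_rep="")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cohort.config.to_dict(), fh, sort_keys=True)
    return paths


def train_test_split_by_patient(records: list[VariantRecord], fraction: float,
                                seed: int) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Partition records so every patient falls wholly on one side.

    ``fraction`` is the target share of patients in the training side; the
    patient count rounds toward train but always leaves at least one test
    patient.  Deterministic under ``seed``.
    """
    if not 0.0 < fraction < 1.0:
        raise SplitError("fraction must lie strictly between 0 and 1")
    patients = sorted({r.patient_id for r in records})
    if len(patients) < 2:
        raise SplitError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_train = max(1, min(len(patients) - 1, int(math.ceil(fraction * len(patients)))))
    train_ids = {patients[i] for i in order[:n_train]}
    train = [r for r in records if r.patient_id in train_ids]
    test = [r for r in records if r.patient_id not in train_ids]
    return train, test
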