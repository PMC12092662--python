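import numpy as np
import pytest

from metach import CohortConfig, VariantRecord, simulate_cohort
from metach.simulate import two_signature_config  # noqa: F401  (fixture helper)
from metach.variants import CH_NON_ONCOGENIC, CH_ONCOGENIC, TUMOR


def make_record(patient="P1", chrom="chr1", pos=100, ref="C", alt="T",
                gene="TP53", cancer_type="NSCLC", vaf=0.05,
                context=None, label=TUMOR, **kw):
    return VariantRecord(patient_id=patient, chrom=chrom, pos=pos, ref=ref,
                         alt=alt, gene=gene, cancer_type=cancer_type, vaf=vaf,
                         context=context, label=label, **kw)


@pytest.fixture(scope="session")
def default_cohort():
    """One small cohort under the default study conditions, shared read-only."""
    return simulate_cohort(CohortConfig(n_patients=80, seed=11))


@pytest.fixture()
def snv_context_record():
    """SNV with a full 21-character alt-centered context window."""
    return make_record(context="AAAAAAAAAATGGGGGGGGGG", pos=11)
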