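import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_record(snp_id="rs1", chrom="1", pos=1_000_000, effect_allele="A",
                other_allele="G", eaf=0.3, beta=0.1, se=0.02, pvalue=1e-6,
                n=18_340.0):
    from tsmr.gwas_io import SummaryStatRecord
    return SummaryStatRecord(snp_id=snp_id, chrom=chrom, pos=pos,
                             effect_allele=effect_allele,
                             other_allele=other_allele, eaf=eaf, beta=beta,
                             se=se, pvalue=pvalue, n=n)
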