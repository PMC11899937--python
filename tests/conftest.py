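import pytest
from hypothesis import settings

from prs_ldl.variant_model import GenotypeCall, SampleGenotypes, load_builtin_panel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

RSIDS = ("rs629301", "rs1367117", "rs11220462", "rs6511720", "rs1800562",
         "rs429358", "rs7412")


@pytest.fixture(scope="session")
def panel():
    return load_builtin_panel("futema2015_modified")


def make_sample(sample_id, *genotypes):
    """Build a 7-SNP sample from 'X/Y' strings in panel order
    (CELSR2, APOB, ST3GAL4, LDLR, HFE, rs429358, rs7412); None = missing."""
    sample = SampleGenotypes(sample_id)
    for rsid, gt in zip(RSIDS, genotypes):
        if gt is None:
            sample.add(GenotypeCall.missing(rsid))
        else:
            a, b = gt.split("/")
            sample.add(GenotypeCall(rsid, a, b))
    return sample


@pytest.fixture
def make_sample_fn():
    return make_sample
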