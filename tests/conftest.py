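import numpy as np
import pytest

from csia_trophic import AAProfile, SampleRecord, TDFConfig


@pytest.fixture
def cfg():
    return TDFConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20200415)


def make_record(sample_id="S1", species="Thin-billed prion", tissue="feather",
                period="moult", glx=None, phe=None, d13c=None, d15n=None, **kw):
    aa = {}
    if glx is not None:
        aa["Glx"] = glx
    if phe is not None:
        aa["Phe"] = phe
    return SampleRecord(
        sample_id=sample_id,
        species=species,
        tissue=tissue,
        period=period,
        aa=AAProfile(aa),
        d13C_bulk=d13c,
        d15N_bulk=d15n,
        **kw,
    )
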