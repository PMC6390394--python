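import numpy as np
import pytest

from twinkit.data_model import Family, Sex, TwinDataset, Zygosity


def make_family(fid, zyg, traits, age=20.0):
    zyg = Zygosity(zyg)
    if zyg in (Zygosity.MZM, Zygosity.DZM):
        s1 = s2 = Sex.M
    elif zyg in (Zygosity.MZF, Zygosity.DZF):
        s1 = s2 = Sex.F
    else:
        s1, s2 = Sex.M, Sex.F
    return Family(fid, zyg, s1, s2, age, np.asarray(traits, dtype=float))


@pytest.fixture
def toy_dataset():
    fams = [
        make_family("f1", "MZm", [[0.2, 0.5], [0.3, 0.4]]),
        make_family("f2", "DOS", [[0.1, 0.9], [0.6, 0.2]], age=25.0),
        make_family("f3", "MZf", [[0.7, 0.1], [0.8, 0.15]], age=15.0),
    ]
    return TwinDataset(fams, ("TE", "SE"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
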