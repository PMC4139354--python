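import pytest

import popcap as pc


@pytest.fixture(scope="session")
def obs():
    return pc.load_observations()


def make_spec(law="oc", r=1.5e-13, L=3.9684e10, a=0.0, b=0.0,
              P0=2.25e8, K0=2.26e8, t0=1, t_end=2500, r_max=None):
    return pc.ModelSpec(
        law=law,
        rates=pc.RateParameters(r_soc=r, r_max=r_max),
        structure=pc.StructuralParameters(L=L, a=a, b=b),
        init=pc.InitialConditions(t0=t0, P0=P0, K0=K0),
        t_end=t_end,
    )


@pytest.fixture
def oc_spec():
    return make_spec()
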