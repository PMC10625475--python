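import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

from msecif import PairSpec, build_vocabulary, make_toy_complex


@pytest.fixture(scope="session")
def vocab5():
    return build_vocabulary("five_element")


@pytest.fixture(scope="session")
def vocab6():
    return build_vocabulary("six_element")


@pytest.fixture(scope="session")
def worked_example_paths(tmp_path_factory):
    """The printed worked-example geometry: three N;3;2;1;0 protein atoms at
    2, 3 and 4 Angstrom from O;2;1;1;0 ligand atoms."""
    out = tmp_path_factory.mktemp("worked_example")
    specs = [PairSpec("N;3;2;1;0", "O;2;1;1;0", d) for d in (2.0, 3.0, 4.0)]
    return make_toy_complex(specs, out)
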