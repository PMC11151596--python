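import pytest

import kcatscreen as ks


@pytest.fixture(scope="session")
def toy_spec():
    return ks.ToyStructureSpec(
        n_residues=12,
        planted_salt_bridges=[(2, 5, 3.5)],
        planted_hbonds=[(3, 9, 2.84)],
        buried_sites=[7],
        seed=11,
    )


@pytest.fixture(scope="session")
def toy_structure(toy_spec):
    return ks.make_toy_structure(toy_spec)


@pytest.fixture(scope="session")
def toy_pdb(toy_spec, tmp_path_factory):
    path = tmp_path_factory.mktemp("pdb") / "toy.pdb"
    ks.make_toy_structure(toy_spec, path=path)
    return path


@pytest.fixture
def small_seq():
    return ks.ProteinSequence("toy", "MRQAKW")
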