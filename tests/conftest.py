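import pytest

from helixsurvey import TorsionTriple, build_peptide

ALPHA = (-57.0, -47.0)
THREE_TEN = (-49.0, -26.0)
CONSENSUS = (-62.0, -43.0)
EXTENDED = (-120.0, 120.0)

FIXTURE_SPEC = [
    ("alpha", ALPHA, 1.2),
    ("nhelix", CONSENSUS, 1.3),
    ("threeten", THREE_TEN, 1.8),
    ("mdavg", (-72.78, -33.43), 2.6),
    ("extended", EXTENDED, 3.2),
]


def helix12(phi, psi, geometry="engh_huber", length=12):
    return build_peptide(
        "A" * length, [TorsionTriple(phi, psi, 180.0)] * length, geometry=geometry
    )


@pytest.fixture(scope="session")
def alpha_helix():
    return helix12(*ALPHA)


@pytest.fixture(scope="session")
def consensus_helix():
    return helix12(*CONSENSUS)


@pytest.fixture(scope="session")
def threeten_helix():
    return helix12(*THREE_TEN)


@pytest.fixture(scope="session")
def extended_strand():
    return helix12(*EXTENDED)


@pytest.fixture(scope="session")
def fixture_archive(tmp_path_factory):
    from helixsurvey import generate_fixture_archive

    out = tmp_path_factory.mktemp("archive")
    generate_fixture_archive(FIXTURE_SPEC, out)
    return out
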