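import numpy as np
import pytest

from fretscreen.chem import default_registry
from fretscreen.library import PositionalLibrary, LibraryPosition, packaged_library

PARENT = "KY(NO2)TESESRGK(Abz)IYYKKG"
DECODED_HIT = "KY(NO2)SEGESRGK(Abz)JYFKKG"
CURRENT = "Abz-TESE↓SRGAIY-Dpa-KK-NH2"


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def fig4a():
    return packaged_library("adamts5_fig4a")


@pytest.fixture
def toy_library():
    """A 2x3x2 = 12-member library of natural residues."""
    return PositionalLibrary(
        positions=(
            LibraryPosition("P1", ("A", "G")),
            LibraryPosition("P1'", ("S", "T", "V")),
            LibraryPosition("P2'", ("K", "R")),
        ),
        scissile_index=1,
    )


def random_member(rng: np.random.Generator, library: PositionalLibrary):
    """One uniformly drawn member of a positional library."""
    opts = library.resolved_options()
    from fretscreen.chem import Peptide

    combo = tuple(col[rng.integers(len(col))] for col in opts)
    return Peptide(residues=combo, cleavage_marker=library.scissile_index)
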