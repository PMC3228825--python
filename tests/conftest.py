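import pytest

import forkasym as fa
from forkasym import datafiles


@pytest.fixture(scope="session")
def geometry() -> fa.LocusGeometry:
    """Reporter locus left of a highly efficient origin (leftward fork)."""
    return fa.LocusGeometry(start=0, end=1600, origin_pos=5000)


@pytest.fixture(scope="session")
def roles(geometry) -> fa.StrandRoleMap:
    return fa.nascent_strand_roles(geometry)


@pytest.fixture(scope="session")
def reference() -> str:
    return fa.load_reference()


@pytest.fixture(scope="session")
def mutant_table() -> fa.MispairCountTable:
    """Observed polδ-L591M strand-bias counts (both orientations)."""
    return fa.MispairCountTable.from_tsv(datafiles.poldelta_mutant_counts_path())


@pytest.fixture(scope="session")
def control_table() -> fa.MispairCountTable:
    """Observed polδ+ control counts (no strand bias)."""
    return fa.MispairCountTable.from_tsv(datafiles.poldelta_wt_counts_path())


@pytest.fixture(scope="session")
def prior() -> fa.InVitroBiasPrior:
    return fa.InVitroBiasPrior.default()
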