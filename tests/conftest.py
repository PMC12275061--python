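import numpy as np
import pytest

from alascreen.msa import write_msa
from alascreen.screen import write_ligand_table
from alascreen.site import write_reference_complex
from alascreen.synth import FixtureSpec, make_toy_complex, make_toy_library, make_toy_msa


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_spec():
    return FixtureSpec(
        n_residues=48, n_msa_rows=12, n_site_residues=14, n_actives=35, seed=42
    )


@pytest.fixture(scope="session")
def toy_inputs(toy_spec, tmp_path_factory):
    """Fixture files on disk in standard formats, read back by the real readers.

    The MSA query row is replaced by the complex's sequence so the site maps
    one-to-one onto the query.
    """
    out = tmp_path_factory.mktemp("fixtures")
    gen = np.random.default_rng(toy_spec.seed)
    complex_, query = make_toy_complex(toy_spec, gen)
    msa = make_toy_msa(toy_spec, gen)
    msa.rows[0] = ("query", query)
    library = make_toy_library(toy_spec, gen)
    write_msa(msa, out / "msa.a3m")
    write_reference_complex(complex_, out / "holo.pdb")
    write_ligand_table(library, out / "library.csv")
    return {
        "dir": out,
        "msa_path": out / "msa.a3m",
        "holo_pdb_path": out / "holo.pdb",
        "ligand_table_path": out / "library.csv",
        "complex": complex_,
        "query": query,
        "msa": msa,
        "library": library,
        "spec": toy_spec,
    }
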