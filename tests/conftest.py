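import numpy as np
import pytest

from ssp.aaindex import AMINO_ACIDS, AAIndexScale, load_default_indices
from ssp.phylo import MainPath


@pytest.fixture(scope="session")
def table():
    return load_default_indices()


@pytest.fixture(scope="session")
def mw_scale(table):
    """Molecular-weight scale: handy because its residue ordering is obvious."""
    return table["FASG760101"]


def make_path(columns: list[str], edges: list[float] | None = None) -> MainPath:
    """Build a MainPath from per-site column strings (root-first).

    ``columns[s][k]`` is the residue at site ``s`` for node ``k``; unit edge
    lengths unless given.
    """
    n_nodes = len(columns[0])
    assert all(len(c) == n_nodes for c in columns)
    seqs = ["".join(col[k] for col in columns) for k in range(n_nodes)]
    if edges is None:
        edges = [1.0] * (n_nodes - 1)
    names = [f"N{i}" for i in range(n_nodes - 1)] + ["target"]
    return MainPath(
        nodes=tuple(names),
        edge_lengths=tuple(edges),
        aligned_sequences=tuple(seqs),
    )


def linear_scale(accession: str, values: dict[str, float]) -> AAIndexScale:
    """A synthetic descriptor scale for controlled-value tests; residues not
    named get large distinct filler values out of the way."""
    full = {a: 1000.0 + i for i, a in enumerate(AMINO_ACIDS)}
    full.update(values)
    return AAIndexScale(accession, "synthetic test scale", "Test", full)
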