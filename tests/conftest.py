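import numpy as np
import pytest

from pairdca import AlignmentMatrix
from pairdca.alphabet import Q


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_alignment(rng, m, l, include_gaps=True):
    """Uniform random alignment over the full (or gapless) alphabet."""
    low = 0 if include_gaps else 1
    mat = rng.integers(low, Q, size=(m, l), dtype=np.uint8)
    return AlignmentMatrix(mat, [f"s{i}" for i in range(m)])


@pytest.fixture
def make_random_alignment(rng):
    def _make(m, l, include_gaps=True):
        return random_alignment(rng, m, l, include_gaps)

    return _make


def format_pdb_atom(serial, name, resname, chain, resseq, x, y, z, element):
    """One fixed-column ATOM record (strict-parser compatible)."""
    return (
        f"ATOM  {serial:>5d} {name:<4s} {resname:>3s} {chain:1s}{resseq:>4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def write_pdb(path, atoms):
    """Write ATOM records from (name, resname, chain, resseq, xyz, element)."""
    lines = [
        format_pdb_atom(i + 1, name, resname, chain, resseq, *xyz, element)
        for i, (name, resname, chain, resseq, xyz, element) in enumerate(atoms)
    ]
    path.write_text("\n".join(lines) + "\nEND\n")
    return path
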