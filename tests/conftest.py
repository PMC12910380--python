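import numpy as np
import pytest

from teao.msa_io import Alignment


@pytest.fixture
def toy_aln() -> Alignment:
    """Four sequences, eight columns, mixing conserved / variable / gappy."""
    return Alignment(
        ids=("s1", "s2", "s3", "s4"),
        sequences=(
            "ACDEFGHI",
            "ACDEFGHK",
            "ACDWFG-I",
            "ACDWXG-I",
        ),
    )


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="aln.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for ident, seq in records:
                fh.write(f">{ident}\n{seq}\n")
        return path

    return _write


def random_alignment(rng: np.random.Generator, n: int, L: int,
                     gap_p: float = 0.1, ambig_p: float = 0.05) -> Alignment:
    """Unstructured random alignment with gaps and ambiguity codes."""
    letters = "ACDEFGHIKLMNPQRSTVWY"
    rows = []
    for i in range(n):
        chars = []
        for _ in range(L):
            u = rng.random()
            if u < gap_p:
                chars.append("-")
            elif u < gap_p + ambig_p:
                chars.append(rng.choice(list("XBZJUO")))
            else:
                chars.append(letters[rng.integers(20)])
        rows.append("".join(chars))
    return Alignment(
        ids=tuple(f"r{i}" for i in range(n)), sequences=tuple(rows)
    )
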