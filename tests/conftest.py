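from __future__ import annotations

import numpy as np
import pytest

from lorete.te_library import TEConsensus, TELibrary

BASES = "ACGT"


def rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def small_library() -> TELibrary:
    """Tiny deterministic library: two LTRs, one LINE, one DNA family."""
    r = np.random.default_rng(77)
    return TELibrary(
        entries=[
            TEConsensus("ltrA", "LTR", rand_seq(r, 1200), 4),
            TEConsensus("ltrB", "LTR", rand_seq(r, 1500), 5),
            TEConsensus("lineA", "LINE", rand_seq(r, 800), "unknown"),
            TEConsensus("dnaA", "DNA", rand_seq(r, 600), 8),
        ]
    )


@pytest.fixture()
def library_files(tmp_path, small_library):
    from lorete.te_library import write_te_library

    fasta = tmp_path / "lib.fa"
    annot = tmp_path / "lib.tsv"
    write_te_library(small_library, fasta, annot)
    return fasta, annot
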