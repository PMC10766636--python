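import numpy as np
import pytest

from mitopop.sequence_core import Alignment

BASES = "ACGT"


def random_alignment(rng: np.random.Generator, n: int, L: int,
                     missing_frac: float = 0.0, n_variants: int | None = None) -> Alignment:
    """Random alignment built from a founder plus per-sequence mutations."""
    founder = rng.integers(0, 4, size=L)
    seqs = []
    for i in range(n):
        seq = founder.copy()
        k = rng.poisson(3) if n_variants is None else n_variants
        for site in rng.choice(L, size=min(k, L), replace=False):
            seq[site] = (seq[site] + rng.integers(1, 4)) % 4
        chars = [BASES[b] for b in seq]
        if missing_frac > 0:
            for site in np.flatnonzero(rng.random(L) < missing_frac):
                chars[site] = "N" if rng.random() < 0.5 else "-"
        seqs.append("".join(chars))
    ids = [f"s{i:03d}" for i in range(n)]
    return Alignment(sample_ids=ids, seqs=seqs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def small_alignment():
    return Alignment(
        sample_ids=["a", "b", "c", "d"],
        seqs=["ACGTACGTAC", "ACGTACGTAC", "ACGAACGTAC", "TCGAACGTNC"],
    )
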