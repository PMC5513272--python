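import numpy as np
import pytest

from poolmhc.diversity import BarcodePanel
from poolmhc.simulate import default_loci


@pytest.fixture(scope="session")
def loci():
    return default_loci()


@pytest.fixture(scope="session")
def references(loci):
    return {name: spec.reference_sequence for name, spec in loci.items()}


def random_panel(rng, n_max=20, length_max=60, barcode="b1", locus="toy"):
    """Small random aligned panel (in-frame length) for oracle comparisons."""
    length = 3 * int(rng.integers(4, length_max // 3 + 1))
    n_reads = int(rng.integers(4, n_max + 1))
    n_var = int(rng.integers(2, min(6, n_reads) + 1))
    base = rng.choice(list("ACGT"), size=length)
    seqs = set()
    while len(seqs) < n_var:
        s = base.copy()
        nmut = int(rng.integers(1, max(2, length // 6)))
        pos = rng.choice(length, size=nmut, replace=False)
        for p in pos:
            s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
        seqs.add("".join(s))
    seqs = sorted(seqs)
    counts = rng.multinomial(n_reads - n_var, np.ones(n_var) / n_var) + 1
    return BarcodePanel(barcode, locus, seqs, counts)


@pytest.fixture
def panel_factory():
    return random_panel
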