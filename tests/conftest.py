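import numpy as np
import pytest

from regcompare.io_formats import GenomicInterval, Peak
from regcompare.synthetic import make_genome_pair


def random_peaks(rng, n, chrom="chr1", span=10_000, max_len=400, prefix="p"):
    """Random peak list for oracle comparisons."""
    peaks = []
    for i in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(20, max_len))
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, start, start + length),
                name=f"{prefix}{i}",
                fold_enrichment=float(np.round(rng.uniform(1, 20), 3)),
                summit_offset=length // 2,
            )
        )
    return peaks


@pytest.fixture(scope="session")
def small_genome():
    """A 3-chromosome genome pair with planted elements, reused across tests."""
    return make_genome_pair(
        seed=11, n_chrom=3, chrom_len=600_000, n_genes=60,
        conserved_frac=0.9, n_elements=120, element_conserved_frac=0.3,
    )
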