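import numpy as np
import pytest

from crmkit.genome import GeneModel, GenomeLayout
from crmkit.intervals import Peak, PeakSet
from crmkit.synthetic import SimulationConfig, generate


def random_peakset(rng, layout, n, max_len=500, scores=False, prefix="p"):
    chroms = layout.chromosomes
    peaks = []
    for i in range(n):
        c = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, layout[c] - length))
        peaks.append(
            Peak(
                c,
                start,
                start + length,
                f"{prefix}{i}",
                float(rng.integers(1, 1000)) if scores else None,
                int(rng.integers(0, length)) if rng.random() < 0.5 else None,
            )
        )
    return PeakSet(peaks, "random", layout)


def random_genes(rng, layout, n):
    genes = []
    chroms = layout.chromosomes
    for i in range(n):
        c = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(300, 5000))
        start = int(rng.integers(0, layout[c] - length))
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(rng.integers(1, 4))
        if k == 1:
            exons = ((start, start + length),)
        else:
            cuts = np.sort(rng.choice(np.arange(1, length), 2 * (k - 1), replace=False))
            bounds = np.concatenate([[0], cuts, [length]])
            exons = tuple(
                (start + int(bounds[2 * j]), start + int(bounds[2 * j + 1])) for j in range(k)
            )
        genes.append(GeneModel(f"g{i:03d}", c, strand, start, start + length, exons))
    return genes


@pytest.fixture(scope="session")
def layout():
    return GenomeLayout({"chr1": 100_000, "chr2": 60_000})


@pytest.fixture(scope="session")
def default_dataset():
    """The default study-conditions simulation (seed 1), shared across tests."""
    return generate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A scaled-down simulation for fast pipeline smoke tests."""
    cfg = SimulationConfig(
        seed=7,
        chromosome_lengths={"chr1": 400_000, "chr2": 300_000},
        n_genes=120,
        cluster_counts={"I": 30, "II": 15, "III": 80, "IV": 30},
        reads_per_library=20_000,
        spike_chromosome_length=100_000,
        n_spike_peaks=20,
    )
    return generate(cfg)
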