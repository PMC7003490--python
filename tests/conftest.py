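import numpy as np
import pytest

from chromgex import genome_model as gm
from chromgex.synthetic_fixtures import FixtureSpec, generate_fixture, worked_example


def random_instance(rng, n_genes=None, n_peaks=None, n_chroms=2, chrom_len=1_000_000):
    """Random genes and peaks for linkage oracle checks."""
    n_genes = n_genes or int(rng.integers(5, 80))
    n_peaks = n_peaks or int(rng.integers(20, 400))
    chroms = [f"chr{i+1}" for i in range(n_chroms)]
    genes = []
    for i in range(n_genes):
        chrom = chroms[int(rng.integers(0, n_chroms))]
        tss = int(rng.integers(30_000, chrom_len - 30_000))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            genes.append(gm.Gene(f"G{i:04d}", chrom, "+", tss, tss + 2000,
                                 transcript_starts=(tss,)))
        else:
            genes.append(gm.Gene(f"G{i:04d}", chrom, "-", tss - 2000, tss,
                                 transcript_starts=(tss,)))
    peaks = []
    for _ in range(n_peaks):
        chrom = chroms[int(rng.integers(0, n_chroms))]
        start = int(rng.integers(0, chrom_len - 1000))
        length = int(rng.integers(50, 800))
        peaks.append(gm.Peak(gm.GenomicInterval(chrom, start, start + length),
                             signal=float(rng.uniform(0, 10))))
    return genes, peaks


@pytest.fixture(scope="session")
def tiny_example():
    return worked_example()


@pytest.fixture(scope="session")
def small_bundle():
    """A small planted fixture shared across tests (generated once)."""
    spec = FixtureSpec(n_chroms=2, chrom_length=1_500_000, n_genes=400,
                       n_tfs=12, n_loops=200, n_peaks=1600, seed=7)
    return generate_fixture(spec)


@pytest.fixture(scope="session")
def small_bundle_files(tmp_path_factory):
    """The same small fixture written to disk for reader round-trips."""
    outdir = tmp_path_factory.mktemp("fixture")
    spec = FixtureSpec(n_chroms=2, chrom_length=1_500_000, n_genes=400,
                       n_tfs=12, n_loops=200, n_peaks=1600, seed=7)
    return generate_fixture(spec, outdir)
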