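import numpy as np
import pandas as pd
import pytest

from curdscan.model import GenotypeMatrix, GroupAssignment


def build_matrix(
    calls,
    positions=None,
    chrom="chr1",
    sample_prefix="s",
    contig_length=None,
    ref="A",
    alt="G",
):
    """Construct a one-chromosome GenotypeMatrix from a call array.

    ``calls`` is (n_samples, n_sites) with codes in {-1, 0, 1, 2}.
    """
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * n_sites,
            "pos": list(positions),
            "ref": [ref] * n_sites,
            "alt": [alt] * n_sites,
        }
    )
    lengths = {chrom: contig_length or int(max(positions, default=1))}
    samples = [f"{sample_prefix}{i + 1}" for i in range(n_samples)]
    return GenotypeMatrix(samples, sites, calls, lengths)


def two_group_assignment(matrix, n_a):
    """First n_a samples -> group A, the rest -> group B."""
    mapping = {}
    for i, s in enumerate(matrix.sample_ids):
        mapping[s] = "A" if i < n_a else "B"
    return GroupAssignment(mapping)


@pytest.fixture(scope="session")
def toy_genome(tmp_path_factory):
    """A small random genome + annotation with genes on both strands."""
    from curdscan import simulate

    d = tmp_path_factory.mktemp("genome")
    config = simulate.SimulationConfig(
        seed=7,
        chromosome_lengths={"chr1": 120_000, "chr2": 60_000},
        genes_per_chromosome=25,
    )
    fasta = str(d / "genome.fa")
    gff = str(d / "genes.gff3")
    simulate.make_toy_genome(config, fasta, gff)
    return fasta, gff, config


@pytest.fixture(scope="session")
def sweep_cohort():
    """10-Mb cohort with one planted 300-kb divergent block (gap 0.8)."""
    from curdscan import simulate

    config = simulate.SimulationConfig(
        seed=11,
        chromosome_lengths={"chr1": 10_000_000},
        snp_per_kb=30.0,
        group_sizes={"Curdless": 20, "WhiteCurd": 20},
        drift={"Curdless": 0.06, "WhiteCurd": 0.12},
        sweep_blocks=[
            simulate.SweepBlock(
                "chr1", 4_850_001, 5_150_000, "WhiteCurd", "Curdless", 0.8
            )
        ],
    )
    matrix, groups, truth = simulate.simulate_groups(config)
    return matrix, groups, config
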