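import numpy as np
import pandas as pd
import pytest

from etiofoot import (ExpressionMatrix, GeneAnnotation, GeneModel,
                      GenomeSequence)
from etiofoot.core import CutProfile
from etiofoot.synthetic import SyntheticScenario, default_scenario


@pytest.fixture(scope="session")
def small_scenario():
    return default_scenario(seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    """One fully generated small synthetic dataset shared across tests."""
    from etiofoot import (generate_genome_and_annotation,
                          generate_motif_landscape, simulate_cut_profiles)
    genome, annotation, truth = generate_genome_and_annotation(small_scenario)
    genome, pwms, group_map, truth = generate_motif_landscape(
        small_scenario, genome, annotation, truth)
    profiles, control = simulate_cut_profiles(
        small_scenario, genome, annotation, truth, times=(0.0, 2.0))
    return dict(genome=genome, annotation=annotation, truth=truth,
                pwms=pwms, group_map=group_map, profiles=profiles,
                control=control)


def make_profile(fwd, rev, chrom="chr1", **meta):
    fwd = np.asarray(fwd, dtype=np.int64)
    rev = np.asarray(rev, dtype=np.int64)
    return CutProfile("test", {chrom: {"+": fwd, "-": rev}}, **meta)


@pytest.fixture
def plus_gene():
    g = GeneModel("gA", "chr1", "+", 5000, 6050)
    g.five_utr = [(5000, 5100)]
    g.cds = [(5100, 5400), (5550, 5850)]
    g.introns = [(5400, 5550)]
    g.three_utr = [(5850, 6050)]
    return g


@pytest.fixture
def minus_gene():
    g = GeneModel("gB", "chr1", "-", 9000, 10050)
    g.three_utr = [(9000, 9200)]
    g.cds = [(9200, 9500), (9650, 9950)]
    g.introns = [(9500, 9650)]
    g.five_utr = [(9950, 10050)]
    return g


@pytest.fixture
def toy_matrix():
    values = pd.DataFrame(
        {"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]},
        index=["g1", "g2", "g3"])
    metadata = pd.DataFrame(
        {"species": ["A", "A"], "time_point": [0.0, 24.0], "replicate": [0, 0]},
        index=["s1", "s2"])
    return ExpressionMatrix(values, metadata)
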