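import numpy as np
import pytest

from nccmscan.constraint import ConstraintTrack
from nccmscan.models import GeneModel, GenomeModel
from nccmscan.simulate import SimConfig, generate_study


@pytest.fixture
def toy_genome():
    """Two hand-built genes on a 10 kbp chromosome, for oracle checks."""
    gene_a = GeneModel(
        gene_id="GA", chrom="chrT", strand="+", start=1000, end=2000,
        exons=[(1000, 1300), (1700, 2000)],
        cds=[(1100, 1300), (1700, 1900)],
        utr5=[(1000, 1100)], utr3=[(1900, 2000)],
        is_key=True,
    )
    gene_b = GeneModel(  # intronless, fully coding, minus strand
        gene_id="GB", chrom="chrT", strand="-", start=2500, end=3000,
        exons=[(2500, 3000)], cds=[(2500, 3000)],
    )
    return GenomeModel(
        chromosomes=[("chrT", 10_000)],
        genes=[gene_a, gene_b],
        lincrnas=[("chrT", 4000, 4500, "LINC0")],
    )


@pytest.fixture
def toy_track(toy_genome):
    """Blocky score array: constrained (>=2) on [500,1500) and [2200,2700)."""
    scores = np.full(10_000, -1.0, dtype=np.float32)
    scores[500:1500] = 3.0
    scores[2200:2700] = 2.0
    return ConstraintTrack({"chrT": scores})


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by read-only tests."""
    cfg = SimConfig(
        seed=11, n_chromosomes=2, chrom_length=600_000, n_genes=12,
        n_key_genes=3, flank=15_000, base_mut_rate=2e-5, n_samples=10,
    )
    genome, seqs, track, cohort, tracks, pfms = generate_study(cfg)
    return dict(config=cfg, genome=genome, sequences=seqs, track=track,
                cohort=cohort, tracks=tracks, pfms=pfms)
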