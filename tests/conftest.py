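import numpy as np
import pytest

from napscape.genome import GenomeAssembly, Replicon


@pytest.fixture
def toy_assembly() -> GenomeAssembly:
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    return GenomeAssembly([Replicon("chr", seq, circular=False)])


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study shared by read-only tests."""
    from napscape import simulate as sim

    assembly, genes, truth = sim.simulate_genome(
        n_replicons=1, lengths=(120_000,),
        at_tracts=[(4000, 0.30)] * 4, n_genes=200, seed=11,
        sigma_factors={"SigE": (60, 0.9), "SigA": (60, 0.6)},
    )
    chip = sim.simulate_chip_counts(assembly, truth, seed=12)
    return assembly, genes, truth, chip
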