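import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from chemevolve import lineage as ln
from chemevolve import pipeline as pl
from chemevolve import synthdata as sd


@pytest.fixture(scope="session")
def demo_truth():
    """Deterministic clonal-interference scenario: two competing lineages,
    each with a nested second sweep and a hitchhiking co-marker."""
    return sd.simulate_chemostat_evolution(pl.gnp_demo_sim_config(deterministic=True))


@pytest.fixture(scope="session")
def noiseless_trajectories(demo_truth):
    obs = sd.observe_allele_frequencies(
        demo_truth,
        sd.ObservationModel(
            mode="sanger", noise_sd=0.0, detection_floor=0.0, read_depth=10**7
        ),
        seed=0,
    )
    return ln.trajectories_from_table(obs)


def make_trajectory(mutation_id, freqs, grid=(24, 61, 102, 137, 173, 213, 250),
                    final=None, locus=None, clones=None):
    return ln.AlleleTrajectory(
        mutation_id=mutation_id,
        locus=locus or mutation_id,
        freq_by_generation=dict(zip(grid, freqs)),
        final_deepseq_freq=final if final is not None else float(freqs[-1]),
        clone_memberships=frozenset(clones) if clones else None,
    )
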