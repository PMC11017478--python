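import numpy as np
import pytest

from cavecharr.containers import GenotypeTable
from cavecharr.synthetic_data import (
    SimulationConfig,
    simulate_colonization,
    simulate_environment,
    simulate_landmarks,
    simulate_phenotypes,
    simulate_source_frequencies,
    trait_params_for_proportions,
)


def make_genotypes(pop_calls, loci=None):
    """Build a GenotypeTable from {pop: [[(a, b) or None per locus], ...]}."""
    n_loci = len(next(iter(pop_calls.values()))[0])
    loci = loci or [f"L{k + 1}" for k in range(n_loci)]
    rows, pops, ids = [], [], []
    k = 0
    for pop, individuals in pop_calls.items():
        for calls in individuals:
            row = np.zeros((n_loci, 2), dtype=np.int64)
            for l, call in enumerate(calls):
                if call is not None:
                    row[l] = call
            rows.append(row)
            pops.append(pop)
            ids.append(f"ind{k}")
            k += 1
    return GenotypeTable(np.stack(rows), np.array(pops, dtype=object),
                         np.array(ids, dtype=object), loci)


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study shared across tests (6 caves, modest drift)."""
    cfg = SimulationConfig(
        n_populations=6, samples_per_pop=25, generations=20, pop_size=50,
        founders_per_pop=25, source_samples={"Lake": 30},
        migration_pairs=[("C1", "C2", 4), ("C4", "C5", 4)],
    )
    src = simulate_source_frequencies(cfg.loci, seed=11)
    gt, truth = simulate_colonization(src, cfg, seed=12)
    env = simulate_environment(6, None, seed=13)
    tp = trait_params_for_proportions(0.3, 0.4, 0.3, env, var_resid=1.0)
    phen = simulate_phenotypes(truth, env, 20, tp, seed=14)
    lms = simulate_landmarks(phen, noise_sd=0.01, seed=15)
    return {"config": cfg, "genotypes": gt, "truth": truth, "env": env,
            "phenotypes": phen, "landmarks": lms}
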