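import numpy as np
import pytest

from multihit.cohort import CohortLabels, MutationMatrix


def make_cohort(profiles: dict[str, set[str]], tumor_prefix: str = "t"):
    """Build (matrix, labels) from per-sample mutated-gene sets.

    Sample ids starting with tumor_prefix are tumors, the rest normals.
    """
    samples = sorted(profiles)
    genes = sorted({g for gs in profiles.values() for g in gs})
    data = np.zeros((len(samples), len(genes)), dtype=np.int8)
    for i, s in enumerate(samples):
        for g in profiles[s]:
            data[i, genes.index(g)] = 1
    status = {s: ("tumor" if s.startswith(tumor_prefix) else "normal")
              for s in samples}
    return MutationMatrix(samples, genes, data), CohortLabels(status)


@pytest.fixture
def five_sample_cohort():
    """Tumors t1:{A,B}, t2:{A}, t3:{B}; normals n1:{A,B}, n2:{}."""
    return make_cohort({
        "t1": {"A", "B"}, "t2": {"A"}, "t3": {"B"},
        "n1": {"A", "B"}, "n2": set(),
    })


@pytest.fixture
def random_instance():
    """Factory for small random cohorts solvable by the brute-force oracle."""
    def _make(seed: int, n_genes: int = 10, n_t: int = 8, n_n: int = 6,
              density: float = 0.35):
        rng = np.random.default_rng(seed)
        genes = [f"g{j:02d}" for j in range(n_genes)]
        samples = [f"t{i:02d}" for i in range(n_t)] + \
                  [f"n{i:02d}" for i in range(n_n)]
        data = (rng.random((len(samples), n_genes)) < density).astype(np.int8)
        # every tumor needs >= 2 mutated genes to be coverable
        for i in range(n_t):
            while data[i].sum() < 2:
                data[i, rng.integers(n_genes)] = 1
        status = {s: ("tumor" if s.startswith("t") else "normal")
                  for s in samples}
        return MutationMatrix(samples, genes, data), CohortLabels(status)
    return _make
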