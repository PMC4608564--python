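import numpy as np
import pytest

import cgnma
from cgnma import (
    CoarseGrainConfig,
    FixtureSpec,
    build_hessian,
    infer_topology,
    make_peptide,
    preset_rules,
    select_sites,
)


@pytest.fixture(scope="session")
def small_globule():
    """40-residue compact globule with side-chain stubs (shared, read-only)."""
    return make_peptide(FixtureSpec(40, "compact-globule", "stub3", 0.05, 7))


@pytest.fixture(scope="session")
def small_system(small_globule):
    """(structure, topology, all-atom Hessian, CA selection) bundle."""
    rules = preset_rules("ssnma_like")
    topo = infer_topology(small_globule, nonbonded_cutoff=rules.cutoff)
    H = build_hessian(small_globule, topo, rules)
    K = select_sites(small_globule, "calpha")
    return small_globule, topo, H, K


@pytest.fixture(scope="session")
def exact_cg(small_system):
    _, _, H, K = small_system
    return cgnma.schur_project_exact(H, K)


def build_system(n_residues, seed, geometry="compact-globule", sidechain="stub3",
                 jitter=0.05, model="ssnma_like"):
    rules = preset_rules(model)
    s = make_peptide(FixtureSpec(n_residues, geometry, sidechain, jitter, seed))
    topo = infer_topology(s, nonbonded_cutoff=rules.cutoff)
    H = build_hessian(s, topo, rules)
    K = select_sites(s, "calpha")
    return s, topo, H, K


def random_plan(structure, K, rng, n_groups):
    """Randomized removal grouping (for oracle-equivalence property tests)."""
    import cgnma as cg

    kept = set(K.kept_indices)
    removed = np.array([i for i in range(len(structure)) if i not in kept])
    rng.shuffle(removed)
    parts = np.array_split(removed, n_groups)
    groups = sorted([np.sort(p) for p in parts if len(p)], key=len, reverse=True)
    return cg.RemovalPlan(K=K, groups=groups)
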