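import numpy as np
import pytest

from spatialnb.popdata_io import Dataset, GenotypeTable, Individual, Locus, Patch


def make_table(calls, clutches=None, patches=None, locus_names=None, species=None):
    """Small genotype table from a nested list of (a1, a2) per individual."""
    calls = np.asarray(calls, dtype=np.int32)
    n, L = calls.shape[:2]
    clutches = clutches or [f"c{i}" for i in range(n)]
    patches = patches or ["P1"] * n
    species = species or ["target"] * n
    inds = [
        Individual(f"i{i}", clutches[i], patches[i], species[i]) for i in range(n)
    ]
    loci = []
    for j in range(L):
        observed = {int(a) for a in calls[:, j, :].ravel() if a != -1}
        loci.append(Locus(locus_names[j] if locus_names else f"L{j}", frozenset(observed or {1})))
    return GenotypeTable(inds, loci, calls)


def make_dataset(table, coords=None):
    pids = sorted({i.patch_id for i in table.individuals})
    coords = coords or {p: (100.0 * k, 0.0) for k, p in enumerate(pids)}
    patches = [Patch(p, *coords[p]) for p in pids]
    return Dataset(table, patches)


@pytest.fixture(scope="session")
def small_metapop():
    """Weakly structured 6-patch metapopulation with truth, shared by tests."""
    from spatialnb.synthpop import SimConfig, simulate_metapopulation

    xy = np.array(
        [(137, 162), (469, 128), (771, 180), (158, 437), (422, 489), (760, 441)], float
    )
    cfg = SimConfig(
        n_patches=6,
        extent=(900.0, 600.0),
        patch_xy=xy,
        males_per_patch=15,
        females_per_patch=15,
        sigma=110.0,
        n_generations=10,
        seed=42,
    )
    return simulate_metapopulation(cfg)


@pytest.fixture(scope="session")
def panmictic_pop():
    """Single random-mating patch with known parents."""
    from spatialnb.synthpop import SimConfig, simulate_metapopulation

    cfg = SimConfig(
        n_patches=1,
        extent=(100.0, 100.0),
        males_per_patch=25,
        females_per_patch=25,
        n_generations=5,
        eggs_per_clutch=6,
        eggs_sampled_per_clutch=2,
        seed=7,
    )
    return simulate_metapopulation(cfg)
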