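"""Forward-time, spatially explicit metapopulation simulator.

Emulates a pond-breeding amphibian system: discrete breeding patches inside
a small (~2 km) extent, limited parent-offspring dispersal (axial SD sigma,
Gaussian), one clutch per female per season, polyandrous clutches, and an
egg-sampling scheme capped per patch.  Runs discrete non-overlapping
generations to quasi-equilibrium so that isolation-by-distance and weak
patch differentiation (FST ~ 0.01-0.02) emerge, then lays one final cohort
of egg clutches from which the sample is drawn.  Each patch has a fixed
per-sex carrying capacity: eggs disperse from the natal patch and compete
for the recruitment slots of the patch they land in, so demes regulate
locally and gene flow happens through egg dispersal.

All ground truth (pedigree, per-patch parent counts, density, sigma) is
retained in :class:`SimTruth` so estimator recovery can be measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .popdata_io import (
    MISSING,
    NON_TARGET,
    TARGET,
    Dataset,
    GenotypeTable,
    Individual,
    Locus,
    Patch,
)

logger = logging.getLogger("spatialnb")


def rng_for(seed: int, label: str) -> np.random.Generator:
    """Stage-local random stream derived from a run seed and a stable label."""
    import zlib

    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())]))


@dataclass
class SimConfig:
    """Configuration of the spatial metapopulation simulation.

    Distances are metres.  Defaults emulate the study system the package
    targets: ~25 breeding patches in a 2 km x 1 km extent, axial dispersal
    SD sigma = 115 m (breeding-window radius 2*sigma = 230 m), 13
    microsatellite-like loci with up to 8 alleles, one clutch per female,
    weak polyandry (1 + Poisson(0.5) fathers per clutch), and a sampling
    scheme of at most 50 clutches per patch with 2 genotyped eggs each.
    """

    n_patches: int = 25
    extent: tuple = (2000.0, 1000.0)
    patch_xy: np.ndarray | None = None  # (n_patches, 2), overrides random layout
    males_per_patch: int = 40
    females_per_patch: int = 40
    sigma: float = 115.0
    n_generations: int = 20
    n_loci: int = 13
    n_alleles: int = 8
    dirichlet_alpha: float | None = None  # None = uniform initial frequencies
    polyandry_lambda: float = 0.5  # fathers per clutch = 1 + Poisson(lambda)
    fathers_per_clutch: int | None = None  # fixed father count, overrides lambda
    eggs_per_clutch: int = 10  # eggs laid (available for sampling)
    max_clutches_sampled: int = 50
    eggs_sampled_per_clutch: int = 2
    epsilon: float = 0.0  # genotyping error rate per call
    null_freqs: Sequence | None = None  # per-locus null allele frequency
    nontarget_fraction: float = 0.0  # expected fraction of non-target clutches
    seed: int = 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.polyandry_lambda < 0:
            raise ValueError("polyandry_lambda must be >= 0")
        for name in ("epsilon", "nontarget_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.eggs_sampled_per_clutch > self.eggs_per_clutch:
            raise ValueError("cannot sample more eggs per clutch than are laid")


@dataclass
class Clutch:
    """One female's clutch of a single season."""

    id: str
    patch_id: str
    mother: str
    fathers: list  # male ids; eggs draw their father uniformly from these
    species: str = TARGET
    n_eggs: int = 0


@dataclass
class SimPopulation:
    """Final-season breeding state: adults plus the clutches they produced."""

    config: SimConfig
    patches: list
    male_ids: list
    female_ids: list
    male_genotypes: np.ndarray  # (n_males, L, 2)
    female_genotypes: np.ndarray
    clutches: list = field(default_factory=list)
    loci: list = field(default_factory=list)

    @property
    def n_adults(self) -> int:
        return len(self.male_ids) + len(self.female_ids)


@dataclass
class SimTruth:
    """Simulator ground truth for estimator-recovery checks."""

    sigma: float
    density: float  # adults per square metre of the extent
    pedigree: dict = field(default_factory=dict)  # egg id -> (mother id, father id)
    patch_parents: dict = field(default_factory=dict)  # patch -> dict(Nm, Nf, Np)
    clutch_species: dict = field(default_factory=dict)
    n_adults: int = 0

    def n_parents(self, individual_ids) -> int:
        """Number of distinct true parents of the given sampled eggs."""
        parents = set()
        for i in individual_ids:
            m, f = self.pedigree[i]
            parents.add(m)
            parents.add(f)
        return len(parents)

    def parent_counts(self, individual_ids) -> dict:
        mothers, fathers = set(), set()
        for i in individual_ids:
            m, f = self.pedigree[i]
            mothers.add(m)
            fathers.add(f)
        return {"Nf": len(mothers), "Nm": len(fathers), "Np": len(mothers | fathers)}


# ----------------------------------------------------------------------
# core simulation
# ----------------------------------------------------------------------

def _initial_genotypes(rng, n, config) -> np.ndarray:
    """HWE draws from per-locus initial allele frequencies."""
    labels = 100 + 2 * np.arange(config.n_alleles)  # microsatellite-like sizes
    genos = np.empty((n, config.n_loci, 2), dtype=np.int32)
    for l in range(config.n_loci):
        if config.dirichlet_alpha is not None:
            freqs = rng.dirichlet(np.full(config.n_alleles, config.dirichlet_alpha))
        else:
            freqs = np.full(config.n_alleles, 1.0 / config.n_alleles)
        genos[:, l, :] = rng.choice(labels, size=(n, 2), p=freqs)
    return genos


def _mendelian(rng, genos, parent_idx) -> np.ndarray:
    """One gamete per (offspring, locus) from each parent row."""
    g = genos[parent_idx]  # (n_off, L, 2)
    pick = rng.integers(0, 2, size=g.shape[:2])
    return np.take_along_axis(g, pick[:, :, None], axis=2)[:, :, 0]


def _choose_fathers(rng, weights, k):
    """k distinct males with probability proportional to the kernel weights."""
    nz = np.flatnonzero(weights)
    k = min(k, nz.size)
    p = weights[nz] / weights[nz].sum()
    return nz[rng.choice(nz.size, size=k, replace=False, p=p, shuffle=False)]


def simulate_metapopulation(config: SimConfig) -> tuple:
    """Run the simulation and sample eggs per the configured scheme.

    Returns ``(dataset, truth)``.  Use :func:`breed_population` +
    :func:`sample_eggs` for finer control over the final season.
    """
    pop = breed_population(config)
    dataset = sample_eggs(
        pop,
        max_clutches=config.max_clutches_sampled,
        eggs_per_clutch=config.eggs_sampled_per_clutch,
        seed=config.seed,
    )
    truth = _build_truth(pop, dataset)
    if config.epsilon > 0 or config.null_freqs is not None:
        dataset = inject_artifacts(
            dataset, config.epsilon, config.null_freqs, seed=config.seed
        )
    return dataset, truth


def breed_population(config: SimConfig) -> SimPopulation:
    """Burn in the metapopulation and lay the final cohort of clutches."""
    rng = rng_for(config.seed, "synthpop")
    if config.patch_xy is not None:
        pxy = np.asarray(config.patch_xy, dtype=float)
        if pxy.shape != (config.n_patches, 2):
            raise ValueError("patch_xy shape does not match n_patches")
    else:
        pxy = rng.uniform([0, 0], list(config.extent), size=(config.n_patches, 2))
    patch_ids = [f"P{k + 1:02d}" for k in range(config.n_patches)]

    male_loc = np.repeat(pxy, config.males_per_patch, axis=0)
    female_loc = np.repeat(pxy, config.females_per_patch, axis=0)
    male_g = _initial_genotypes(rng, len(male_loc), config)
    female_g = _initial_genotypes(rng, len(female_loc), config)
    two_sigma_sq = 2.0 * config.sigma**2

    def season(male_loc, female_loc):
        """Mate choice for every female; returns per-clutch father index lists."""
        d2 = cdist(female_loc, male_loc, "sqeuclidean")
        w = np.exp(-d2 / two_sigma_sq)
        if config.fathers_per_clutch is not None:
            ks = np.full(len(female_loc), config.fathers_per_clutch)
        else:
            ks = 1 + rng.poisson(config.polyandry_lambda, size=len(female_loc))
        return [_choose_fathers(rng, w[i], ks[i]) for i in range(len(female_loc))]

    for _ in range(config.n_generations):
        if len(female_loc) == 0 or len(male_loc) == 0:
            raise RuntimeError("population went extinct during burn-in")
        fathers_per_clutch = season(male_loc, female_loc)
        # breeding patch of each female = nearest patch to her location
        breed_patch = np.argmin(cdist(female_loc, pxy), axis=1)
        # lay eggs: fecundity eggs per clutch, father drawn per egg
        fec = config.eggs_per_clutch
        mother_idx = np.repeat(np.arange(len(female_loc)), fec)
        ks = np.array([len(f) for f in fathers_per_clutch])
        pick = np.floor(rng.random(mother_idx.size) * ks[mother_idx]).astype(int)
        father_idx = np.array(
            [fathers_per_clutch[m][k] for m, k in zip(mother_idx, pick)]
        )
        egg_g = np.stack(
            [
                _mendelian(rng, female_g, mother_idx),
                _mendelian(rng, male_g, father_idx),
            ],
            axis=2,
        )
        # dispersal from the natal patch, then local density regulation:
        # each patch recruits up to its per-sex capacity from eggs landing there
        loc = pxy[breed_patch[mother_idx]] + rng.normal(
            0.0, config.sigma, size=(mother_idx.size, 2)
        )
        loc = np.clip(loc, [0, 0], list(config.extent))
        natal = np.argmin(cdist(loc, pxy), axis=1)
        is_male = rng.random(mother_idx.size) < 0.5
        keep_m, keep_f = [], []
        for p in range(config.n_patches):
            for sex_mask, cap, keep in (
                (is_male, config.males_per_patch, keep_m),
                (~is_male, config.females_per_patch, keep_f),
            ):
                pool = np.flatnonzero((natal == p) & sex_mask)
                if pool.size > cap:
                    pool = pool[rng.choice(pool.size, size=cap, replace=False)]
                keep.extend(pool.tolist())
        keep_m, keep_f = np.array(keep_m, int), np.array(keep_f, int)
        male_g, female_g = egg_g[keep_m], egg_g[keep_f]
        male_loc, female_loc = loc[keep_m], loc[keep_f]

    # final season: lay clutches (kept with father sets; eggs drawn at sampling)
    fathers_per_clutch = season(male_loc, female_loc)
    breed_patch = np.argmin(cdist(female_loc, pxy), axis=1)
    empty = set(range(config.n_patches)) - set(breed_patch.tolist())
    if empty:
        logger.info("patches without breeding females this season: %d", len(empty))

    male_ids = [f"M{i:04d}" for i in range(len(male_loc))]
    female_ids = [f"F{i:04d}" for i in range(len(female_loc))]
    clutches = []
    for i in range(len(female_loc)):
        pid = patch_ids[breed_patch[i]]
        clutches.append(
            Clutch(
                id=f"{pid}_c{i:04d}",
                patch_id=pid,
                mother=female_ids[i],
                fathers=[male_ids[j] for j in fathers_per_clutch[i]],
                species=TARGET,
                n_eggs=config.eggs_per_clutch,
            )
        )
    # phantom non-target clutches: counted and sampled but never genotyped
    if config.nontarget_fraction > 0:
        f = config.nontarget_fraction
        per_patch = {}
        for c in clutches:
            per_patch[c.patch_id] = per_patch.get(c.patch_id, 0) + 1
        for pid, n_t in per_patch.items():
            n_phantom = rng.poisson(n_t * f / (1.0 - f))
            for k in range(n_phantom):
                clutches.append(
                    Clutch(
                        id=f"{pid}_x{k:03d}",
                        patch_id=pid,
                        mother="",
                        fathers=[],
                        species=NON_TARGET,
                        n_eggs=config.eggs_per_clutch,
                    )
                )
    labels = 100 + 2 * np.arange(config.n_alleles)
    loci = [
        Locus(f"L{l + 1:02d}", frozenset(int(a) for a in labels))
        for l in range(config.n_loci)
    ]
    patches = [Patch(pid, float(x), float(y)) for pid, (x, y) in zip(patch_ids, pxy)]
    return SimPopulation(
        config=config,
        patches=patches,
        male_ids=male_ids,
        female_ids=female_ids,
        male_genotypes=male_g,
        female_genotypes=female_g,
        clutches=clutches,
        loci=loci,
    )


def sample_eggs(
    pop: SimPopulation,
    max_clutches: int = 50,
    eggs_per_clutch: int = 2,
    seed: int = 0,
) -> Dataset:
    """Draw the egg sample: a uniform clutch subset per patch, a fixed number
    of eggs per clutch, Mendelian genotypes per egg.

    Non-target clutches enter the clutch census and the per-patch species
    fraction but contribute no genotypes.
    """
    config = pop.config
    if eggs_per_clutch > config.eggs_per_clutch:
        raise ValueError(
            f"requested {eggs_per_clutch} eggs per clutch but clutches hold "
            f"{config.eggs_per_clutch}"
        )
    rng = rng_for(seed, "sample_eggs")
    mother_row = {m: i for i, m in enumerate(pop.female_ids)}
    father_row = {m: i for i, m in enumerate(pop.male_ids)}

    by_patch: dict = {}
    for c in pop.clutches:
        by_patch.setdefault(c.patch_id, []).append(c)

    individuals, rows, pedigree = [], [], {}
    patch_meta = {}
    for patch in pop.patches:
        cs = by_patch.get(patch.id, [])
        n_sampled = min(max_clutches, len(cs))
        idx = rng.choice(len(cs), size=n_sampled, replace=False) if cs else []
        sampled = [cs[i] for i in sorted(idx)]
        n_target_sampled = sum(1 for c in sampled if c.species == TARGET)
        patch_meta[patch.id] = dict(
            n_counted=len(cs),
            n_sampled=n_sampled,
            pct_target=(n_target_sampled / n_sampled) if n_sampled else None,
        )
        for c in sampled:
            if c.species != TARGET:
                continue
            fathers = [father_row[f] for f in c.fathers]
            egg_fathers = rng.integers(0, len(fathers), size=eggs_per_clutch)
            m_row = mother_row[c.mother]
            for e, fi in enumerate(egg_fathers):
                egg_id = f"{c.id}_{e + 1}"
                individuals.append(
                    Individual(egg_id, c.id, c.patch_id, species=TARGET)
                )
                mg = pop.female_genotypes[m_row]
                fg = pop.male_genotypes[fathers[fi]]
                gam_m = mg[np.arange(config.n_loci), rng.integers(0, 2, config.n_loci)]
                gam_f = fg[np.arange(config.n_loci), rng.integers(0, 2, config.n_loci)]
                rows.append(np.stack([gam_m, gam_f], axis=1))
                pedigree[egg_id] = (c.mother, c.fathers[fi])

    calls = (
        np.array(rows, dtype=np.int32)
        if rows
        else np.empty((0, config.n_loci, 2), np.int32)
    )
    table = GenotypeTable(individuals, pop.loci, calls)
    patches = [
        Patch(
            p.id,
            p.x,
            p.y,
            n_clutches_counted=patch_meta[p.id]["n_counted"],
            n_clutches_sampled=patch_meta[p.id]["n_sampled"],
            pct_target_species=patch_meta[p.id]["pct_target"],
        )
        for p in pop.patches
    ]
    provenance = {"simulated": True, "seed": seed, "sigma": config.sigma}
    ds = Dataset(table, patches, provenance)
    ds.provenance["pedigree"] = pedigree
    return ds


def _build_truth(pop: SimPopulation, dataset: Dataset) -> SimTruth:
    pedigree = dataset.provenance.get("pedigree", {})
    area = pop.config.extent[0] * pop.config.extent[1]
    truth = SimTruth(
        sigma=pop.config.sigma,
        density=pop.n_adults / area,
        pedigree=dict(pedigree),
        clutch_species={c.id: c.species for c in pop.clutches},
        n_adults=pop.n_adults,
    )
    for patch in pop.patches:
        ids = [
            i.id for i in dataset.genotypes.individuals if i.patch_id == patch.id
        ]
        truth.patch_parents[patch.id] = truth.parent_counts(ids) if ids else {
            "Nf": 0,
            "Nm": 0,
            "Np": 0,
        }
    return truth


# ----------------------------------------------------------------------
# genotyping artifacts
# ----------------------------------------------------------------------

def inject_artifacts(
    dataset: Dataset,
    epsilon: float = 0.0,
    null_freqs: Sequence | None = None,
    seed: int = 0,
) -> Dataset:
    """Overlay genotyping error and null alleles on a clean dataset.

    With probability ``epsilon`` a call is replaced by a random genotype
    drawn from its patch's allele frequencies.  A null allele of frequency
    ``nu`` at a locus silently replaces each allele copy: one null copy
    makes a heterozygote look like a visible-allele homozygote, two null
    copies make the call missing.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    table = dataset.genotypes
    calls = table.calls.copy()
    rng = rng_for(seed, "inject_artifacts")
    patch_ids = np.array(table.patch_ids)

    if epsilon > 0:
        for pid in np.unique(patch_ids):
            rows = np.flatnonzero(patch_ids == pid)
            for l in range(table.n_loci):
                freqs = table.allele_frequencies(l, subset=rows)
                if not freqs:
                    continue
                alleles = np.array(sorted(freqs))
                p = np.array([freqs[a] for a in alleles])
                hit = rows[rng.random(rows.size) < epsilon]
                if hit.size:
                    calls[hit, l, :] = np.sort(
                        rng.choice(alleles, size=(hit.size, 2), p=p), axis=1
                    )

    if null_freqs is not None:
        null_freqs = np.asarray(null_freqs, dtype=float)
        if null_freqs.shape != (table.n_loci,):
            raise ValueError("null_freqs must have one entry per locus")
        if ((null_freqs < 0) | (null_freqs > 1)).any():
            raise ValueError("null frequencies must lie in [0, 1]")
        for l in range(table.n_loci):
            nu = null_freqs[l]
            if nu == 0:
                continue
            typed = calls[:, l, 0] != MISSING
            nulled = rng.random((table.n_individuals, 2)) < nu
            both = typed & nulled.all(axis=1)
            one = typed & (nulled.sum(axis=1) == 1)
            calls[both, l, :] = MISSING
            rows = np.flatnonzero(one)
            visible_slot = np.argmin(nulled[rows], axis=1)
            vis = calls[rows, l, visible_slot]
            calls[rows, l, 0] = vis
            calls[rows, l, 1] = vis

    new_table = GenotypeTable(table.individuals, table.loci, calls)
    prov = dict(dataset.provenance)
    prov["artifacts"] = {
        "epsilon": epsilon,
        "null_freqs": None if null_freqs is None else list(map(float, null_freqs)),
    }
    return Dataset(new_table, dataset.patches, prov)
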