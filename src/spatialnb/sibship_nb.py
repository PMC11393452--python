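"""Sibship reconstruction and the dyad-frequency estimator of Nb.

Pairs of sampled eggs are classified as full sibs (FS), half sibs (HS) or
unrelated (U) from pairwise genotype likelihoods under the IBD-coefficient
triples FS = (0.25, 0.5, 0.25), HS = (0.5, 0.5, 0), U = (1, 0, 0),
multiplied across loci with a per-locus error mixture.  Eggs of the same
clutch are known maternal sibs (one clutch per female), which enters the
pair prior; cross-clutch pairs that look like full sibs would imply a
shared mother across clutches and are demoted to paternal half sibs.

The dyad frequencies Q_FS and Q_HS over all pairs feed the dyad-frequency
equation

    1/Nb = ((1 + 3*alpha)/4) * (Q_HS + 2*Q_FS) - (alpha/2) * (1/Nm + 1/Nf)

where alpha is the within-individual deviation from Hardy-Weinberg
(close to zero under random mating) and Nm, Nf the numbers of inferred
fathers and mothers.  With alpha = 0 and random-mating dyad frequencies
this reduces to Nb = 4*Nm*Nf/(Nm + Nf).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .popdata_io import MISSING, Dataset, GenotypeTable
from .synthpop import rng_for

FS, HS, UN = 0, 1, 2
_KAPPA = {FS: (0.25, 0.5, 0.25), HS: (0.5, 0.5, 0.0), UN: (1.0, 0.0, 0.0)}


@dataclass
class SibshipResult:
    posteriors: dict = field(default_factory=dict)  # (id_a, id_b) -> (pFS, pHS, pU)
    classification: dict = field(default_factory=dict)  # (id_a, id_b) -> "FS"/"HS"/"U"
    families: list = field(default_factory=list)  # full-sib families (lists of ids)
    n_mothers: int = 0  # Nf = number of clutches (one clutch per female)
    n_fathers: int = 0  # Nm = paternal clusters
    q_fs: float = 0.0
    q_hs: float = 0.0
    alpha: float = 0.0
    threshold: float = 0.90

    @property
    def n_parents(self) -> int:
        return self.n_mothers + self.n_fathers

    def nb(self) -> float:
        return sibship_nb(self.q_hs, self.q_fs, self.alpha, self.n_fathers, self.n_mothers)


# ----------------------------------------------------------------------
# pairwise likelihoods
# ----------------------------------------------------------------------

def _genotype_codes(table: GenotypeTable, locus: int):
    """Observed genotypes at a locus -> integer codes; missing -> last code."""
    calls = table.calls[:, locus, :]
    genos = sorted({(int(a), int(b)) for a, b in calls if a != MISSING})
    code = {g: i for i, g in enumerate(genos)}
    n_codes = len(genos)
    vec = np.full(table.n_individuals, n_codes, dtype=int)  # missing slot
    for i, (a, b) in enumerate(calls):
        if a != MISSING:
            vec[i] = code[(int(a), int(b))]
    return genos, vec, n_codes


def _pair_prob_tables(genos, freqs, epsilon):
    """P(G1, G2 | R) lookup tables, one (G+1, G+1) matrix per relationship.

    The extra last row/column absorbs missing calls with probability 1 so a
    locus untyped in either member contributes nothing to the product.
    Errors mix each relationship likelihood with the independence product:
    a mis-typed genotype is uninformative about IBD.
    """
    g = len(genos)
    p_g = np.array([_hwe_geno_prob(a, b, freqs) for a, b in genos])

    # transition P(G2 | one gene IBD with G1)
    trans = np.zeros((g, g))
    for i, (a, b) in enumerate(genos):
        for j, (c, d) in enumerate(genos):
            t = 0.0
            for shared in (a, b):
                if c == d:
                    t += 0.5 * (freqs.get(c, 0.0) if shared == c else 0.0)
                else:
                    if shared == c:
                        t += 0.5 * freqs.get(d, 0.0)
                    if shared == d:
                        t += 0.5 * freqs.get(c, 0.0)
            trans[i, j] = t
    ident = np.eye(g)
    indep = np.outer(p_g, p_g)
    share1 = p_g[:, None] * trans
    share2 = p_g[:, None] * ident
    ok = (1.0 - epsilon) ** 2
    tables = {}
    for rel, (k0, k1, k2) in _KAPPA.items():
        clean = k0 * indep + k1 * share1 + k2 * share2
        noisy = ok * clean + (1.0 - ok) * indep
        t = np.ones((g + 1, g + 1))
        t[:g, :g] = noisy
        tables[rel] = t
    return tables


def _hwe_geno_prob(a, b, freqs):
    pa, pb = freqs.get(a, 0.0), freqs.get(b, 0.0)
    return pa * pa if a == b else 2 * pa * pb


def dyad_likelihood(
    table: GenotypeTable,
    i: int,
    j: int,
    epsilon: float = 1e-4,
    prior=(1 / 3, 1 / 3, 1 / 3),
) -> np.ndarray:
    """Posterior over (FS, HS, U) for one pair of individuals.

    Allele frequencies are taken from the full table; the prior can encode
    known maternity (same-clutch pairs are at least maternal half sibs).
    """
    shared = ~(table.missing_mask[i] | table.missing_mask[j])
    if not shared.any():
        raise ValueError("pair shares no typed loci")
    log_l = np.zeros(3)
    for l in np.flatnonzero(shared):
        genos, vec, _ = _genotype_codes(table, l)
        freqs = table.allele_frequencies(l)
        tables = _pair_prob_tables(genos, freqs, epsilon)
        for rel in (FS, HS, UN):
            log_l[rel] += np.log(max(tables[rel][vec[i], vec[j]], 1e-300))
    post = np.asarray(prior, dtype=float) * np.exp(log_l - log_l.max())
    return post / post.sum()


def _all_pair_posteriors(table: GenotypeTable, epsilon: float):
    """Vectorised per-locus log-likelihood accumulation over all pairs."""
    n = table.n_individuals
    log_l = np.zeros((3, n, n))
    for l in range(table.n_loci):
        genos, vec, n_codes = _genotype_codes(table, l)
        if not genos:
            continue
        freqs = table.allele_frequencies(l)
        tables = _pair_prob_tables(genos, freqs, epsilon)
        for rel in (FS, HS, UN):
            log_l[rel] += np.log(np.maximum(tables[rel][np.ix_(vec, vec)], 1e-300))
    return log_l


# ----------------------------------------------------------------------
# reconstruction
# ----------------------------------------------------------------------

def reconstruct_families(
    data,
    threshold: float = 0.90,
    epsilon: float = 1e-4,
    alpha: float = 0.0,
    store_pairs: bool | None = None,
    seed: int = 0,
) -> SibshipResult:
    """Classify all dyads and derive families, parent counts and Q's.

    Mothers are clutches (one clutch per female; merging clutches is
    forbidden).  Fathers are connected components of the paternal-sharing
    graph: same-clutch pairs classified FS share a father, as do
    cross-clutch pairs whose FS posterior clears the threshold (demoted to
    paternal half sibs).  Q_FS and Q_HS are hard-classification dyad
    frequencies over all pairs.
    """
    table = data.genotypes if isinstance(data, Dataset) else data
    n = table.n_individuals
    if n < 2:
        raise ValueError("need at least 2 individuals")
    ids = table.individual_ids
    clutch = np.array(table.clutch_ids)
    log_l = _all_pair_posteriors(table, epsilon)

    same = clutch[:, None] == clutch[None, :]
    # pair priors: same-clutch pairs are at least maternal sibs
    prior = np.where(same[None], np.array([0.5, 0.5, 0.0])[:, None, None], 1.0 / 3.0)
    m = log_l.max(axis=0)
    post = prior * np.exp(log_l - m[None])
    post /= post.sum(axis=0, keepdims=True)

    iu, ju = np.triu_indices(n, k=1)
    p_fs = post[FS, iu, ju]
    p_hs = post[HS, iu, ju]
    same_u = same[iu, ju]
    pass_fs = p_fs > threshold

    # hard classification at the threshold over all pairs
    labels = np.full(iu.size, UN, dtype=np.int8)
    labels[same_u] = HS  # maternal half sibs at minimum
    labels[same_u & pass_fs] = FS
    labels[~same_u & pass_fs] = HS  # demoted cross-clutch "FS": shared father
    labels[~same_u & ~pass_fs & (p_hs > threshold)] = HS

    result = SibshipResult(alpha=alpha, threshold=threshold)
    n_pairs = iu.size
    result.q_fs = float((labels == FS).sum() / n_pairs)
    result.q_hs = float((labels == HS).sum() / n_pairs)

    fs_graph = nx.Graph()
    father_graph = nx.Graph()
    fs_graph.add_nodes_from(ids)
    father_graph.add_nodes_from(ids)
    for k in np.flatnonzero(same_u & pass_fs):
        fs_graph.add_edge(ids[iu[k]], ids[ju[k]])
        father_graph.add_edge(ids[iu[k]], ids[ju[k]])
    for k in np.flatnonzero(~same_u & pass_fs):
        father_graph.add_edge(ids[iu[k]], ids[ju[k]])

    if store_pairs is None:
        store_pairs = n <= 400
    if store_pairs:
        names = ("FS", "HS", "U")
        for k in range(iu.size):
            key = (ids[iu[k]], ids[ju[k]])
            result.posteriors[key] = tuple(post[:, iu[k], ju[k]])
            result.classification[key] = names[labels[k]]

    result.families = [sorted(c) for c in nx.connected_components(fs_graph)]
    result.families.sort()
    result.n_mothers = len(set(table.clutch_ids))
    result.n_fathers = nx.number_connected_components(father_graph)
    return result


# ----------------------------------------------------------------------
# the dyad-frequency equation
# ----------------------------------------------------------------------

def sibship_nb(q_hs: float, q_fs: float, alpha: float = 0.0, nm=None, nf=None) -> float:
    """Dyad-frequency Nb; +inf when the drift signal is non-positive."""
    for q in (q_hs, q_fs):
        if not 0.0 <= q <= 1.0:
            raise ValueError("dyad frequencies must lie in [0, 1]")
    if q_fs + q_hs > 1.0 + 1e-12:
        raise ValueError("Q_FS + Q_HS cannot exceed 1")
    if alpha != 0.0:
        if not nm or not nf:
            raise ValueError("alpha != 0 requires Nm and Nf")
        correction = (alpha / 2.0) * (1.0 / nm + 1.0 / nf)
    else:
        correction = 0.0
    inv = ((1.0 + 3.0 * alpha) / 4.0) * (q_hs + 2.0 * q_fs) - correction
    if inv <= 0:
        return np.inf
    return 1.0 / inv


def sibship_nb_ci(
    data,
    n_boot: int = 500,
    threshold: float = 0.90,
    epsilon: float = 1e-4,
    alpha: float = 0.0,
    seed: int = 0,
) -> tuple:
    """Point estimate and percentile bootstrap CI over clutches.

    Clutches are resampled with replacement; each replicate reruns the
    classification on the resampled individuals (clutch copies keep their
    eggs together, preserving the maternal prior).
    """
    table = data.genotypes if isinstance(data, Dataset) else data
    base = reconstruct_families(table, threshold=threshold, epsilon=epsilon, alpha=alpha)
    point = base.nb()
    clutches = sorted(set(table.clutch_ids))
    by_clutch = {}
    for i, c in enumerate(table.clutch_ids):
        by_clutch.setdefault(c, []).append(i)
    rng = rng_for(seed, "sibship_boot")
    reps = []
    for _ in range(n_boot):
        picked = rng.choice(len(clutches), size=len(clutches), replace=True)
        rows, new_inds = [], []
        for copy_idx, ci in enumerate(picked):
            for r in by_clutch[clutches[ci]]:
                ind = table.individuals[r]
                rows.append(r)
                new_inds.append(
                    type(ind)(
                        id=f"{ind.id}#b{copy_idx}",
                        clutch_id=f"{ind.clutch_id}#b{copy_idx}",
                        patch_id=ind.patch_id,
                        species=ind.species,
                    )
                )
        boot_table = GenotypeTable(new_inds, table.loci, table.calls[rows])
        res = reconstruct_families(boot_table, threshold=threshold, epsilon=epsilon, alpha=alpha)
        reps.append(res.nb())
    reps = np.array(reps)
    finite = reps[np.isfinite(reps)]
    if finite.size == 0:
        return point, (np.inf, np.inf)
    lo = float(np.percentile(reps, 2.5)) if np.isfinite(reps).all() else float(np.percentile(finite, 2.5))
    hi = float(np.percentile(reps, 97.5)) if np.isfinite(reps).all() else np.inf
    return point, (min(lo, point), max(hi, point) if np.isfinite(hi) else np.inf)


def estimate_parents_and_sexratio(results) -> tuple:
    """Per-window parent counts and the pooled mother fraction.

    ``results`` maps window ids to :class:`SibshipResult`; returns
    ``(np_per_window, mean_female_fraction)`` where the fraction averages
    Nf/Np across windows (used downstream as the population sex ratio).
    """
    if not results:
        raise ValueError("no window results")
    np_per_window, ratios = {}, []
    for wid, res in results.items():
        if res.n_parents == 0:
            raise ValueError(f"window {wid!r} has zero inferred parents")
        np_per_window[wid] = res.n_parents
        ratios.append(res.n_mothers / res.n_parents)
    return np_per_window, float(np.mean(ratios))
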