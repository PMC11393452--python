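"""Spatial genetic structure diagnostics.

Individual-level pairwise Moran's I and its distance-class autocorrelogram
(permutation-tested), spatial PCA with global/local Monte Carlo tests,
contiguity-constrained patch grouping, Weir-Cockerham theta (FST) with
bootstrap CIs over loci, and Nei's multilocus FIS.

Individuals inherit their patch coordinates; all distances are planar
Euclidean metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.special import ndtr, ndtri
from sklearn.cluster import AgglomerativeClustering
from sklearn.neighbors import kneighbors_graph

from .popdata_io import MISSING, Dataset
from .synthpop import rng_for


# ----------------------------------------------------------------------
# allele-frequency matrix
# ----------------------------------------------------------------------

def _individual_freq_matrix(table, impute: bool = True):
    """Individuals x (locus, allele) matrix of within-individual allele
    frequencies (0, 0.5, 1), with column sample frequencies.

    Missing calls are set to the column mean (zero contribution to any
    centred cross-product) when ``impute`` is on.
    """
    cols, freqs = [], []
    for l in range(table.n_loci):
        alleles = sorted(table.loci[l].alleles)
        if len(alleles) < 2:
            continue
        calls = table.calls[:, l, :]
        typed = calls[:, 0] != MISSING
        if typed.sum() == 0 or len({int(a) for a in calls[typed].ravel()}) < 2:
            continue
        for a in alleles:
            x = (calls == a).sum(axis=1) / 2.0
            p = float(x[typed].mean())
            if impute:
                x = np.where(typed, x, p)
            else:
                x = np.where(typed, x, np.nan)
            cols.append(x)
            freqs.append(p)
    if not cols:
        raise ValueError("no polymorphic loci")
    return np.array(cols).T, np.array(freqs)


# ----------------------------------------------------------------------
# Moran's I between individuals
# ----------------------------------------------------------------------

def pairwise_moran(data) -> np.ndarray:
    """Symmetric matrix of pairwise Moran's I between individuals.

    I_ab = sum_{l,i} z_a z_b / sum_{l,i} mean_c z_c^2 with z the centred
    within-individual allele frequency; the denominator is the mean
    individual variance, which makes the mean over all ordered pairs a != b
    exactly -1/(n-1).
    """
    table = data.genotypes if isinstance(data, Dataset) else data
    if table.n_individuals < 3:
        raise ValueError("need at least 3 individuals")
    X, p = _individual_freq_matrix(table)
    Z = X - X.mean(axis=0)
    denom = (Z**2).sum() / table.n_individuals
    if denom == 0:
        raise ValueError("no genetic variance among individuals")
    return (Z @ Z.T) / denom


@dataclass
class Autocorrelogram:
    bounds: np.ndarray  # class upper bounds (metres), len = n_classes
    mean_distance: np.ndarray  # mean pairwise distance per class
    moran: np.ndarray  # mean pairwise I per class
    p_values: np.ndarray
    n_pairs: np.ndarray
    zero_crossing: float | None = None  # metres, linear interpolation
    max_significant_distance: float | None = None

    def significant_positive(self, alpha=0.05) -> np.ndarray:
        return (self.moran > 0) & (self.p_values <= alpha)


def autocorrelogram(
    data: Dataset,
    n_classes: int = 10,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> Autocorrelogram:
    """Distance-class autocorrelogram of pairwise Moran's I.

    Class bounds sit at the deciles of the pairwise distance distribution,
    giving approximately equal pair counts per class; same-patch pairs
    (distance 0) fall in the first class.  Per-class two-sided p-values
    come from permuting individual locations; the zero-crossing distance is
    interpolated between the last positive and first non-positive class
    means.
    """
    coords = data.coordinates()
    I = pairwise_moran(data)
    n = coords.shape[0]
    d = pdist(coords)
    if np.unique(d).size < n_classes:
        raise ValueError("fewer distinct pairwise distances than classes")
    qs = np.quantile(d, np.linspace(0, 1, n_classes + 1)[1:])
    qs[-1] = d.max()
    cls = np.searchsorted(qs, d, side="left")  # 0..n_classes-1
    iu = np.triu_indices(n, k=1)
    cls_matrix = np.zeros((n, n), dtype=int)
    cls_matrix[iu] = cls
    cls_matrix = cls_matrix + cls_matrix.T

    pair_i = I[iu]
    obs = np.array([pair_i[cls == c].mean() for c in range(n_classes)])
    n_pairs = np.array([(cls == c).sum() for c in range(n_classes)])
    mean_dist = np.array([d[cls == c].mean() for c in range(n_classes)])

    p = np.full(n_classes, np.nan)
    if n_perm > 0:
        rng = rng_for(seed, "autocorrelogram")
        ge = np.zeros(n_classes)
        le = np.zeros(n_classes)
        flat_cls = cls_matrix[iu]
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Ip = I[np.ix_(perm, perm)][iu]
            sums = np.bincount(flat_cls, weights=Ip, minlength=n_classes)
            means = sums / n_pairs
            ge += means >= obs - 1e-12
            le += means <= obs + 1e-12
        p = 2.0 * np.minimum(ge + 1, le + 1) / (n_perm + 1)
        p = np.minimum(p, 1.0)

    zero_crossing = None
    pos = obs > 0
    if pos[0]:
        idx = np.flatnonzero(~pos)
        if idx.size:
            j = idx[0]
            x0, x1 = mean_dist[j - 1], mean_dist[j]
            y0, y1 = obs[j - 1], obs[j]
            zero_crossing = float(x0 + (0.0 - y0) * (x1 - x0) / (y1 - y0))
        else:
            zero_crossing = None  # never crosses within observed range
    max_sig = None
    if n_perm > 0:
        sig = (obs > 0) & (p <= alpha)
        if sig.any():
            max_sig = float(qs[np.flatnonzero(sig).max()])
    return Autocorrelogram(
        bounds=qs,
        mean_distance=mean_dist,
        moran=obs,
        p_values=p,
        n_pairs=n_pairs,
        zero_crossing=zero_crossing,
        max_significant_distance=max_sig,
    )


# ----------------------------------------------------------------------
# spatial PCA
# ----------------------------------------------------------------------

@dataclass
class SpcaResult:
    eigenvalues: np.ndarray  # sorted descending (signed)
    scores: np.ndarray  # individuals x axes
    lagged_scores: np.ndarray
    global_p: float | None
    local_p: float | None
    d_max: float
    connected: bool
    moran_bounds: tuple = (np.nan, np.nan)


def _row_normalized_w(coords: np.ndarray, d_max: float) -> np.ndarray:
    D = squareform(pdist(coords))
    A = ((D > 0) & (D <= d_max)).astype(float)
    rs = A.sum(axis=1)
    W = np.divide(A, rs[:, None], out=np.zeros_like(A), where=rs[:, None] > 0)
    return W


def spca(
    data: Dataset,
    d_max: float = 1000.0,
    n_perm: int = 999,
    seed: int = 0,
    n_axes: int = 4,
) -> SpcaResult:
    """Spatial PCA: eigen-decomposition of (1/n) X' W_sym X.

    X is the column-centred individual allele-frequency matrix and W the
    row-normalised adjacency of the neighbourhood-by-distance graph
    (edge iff 0 < d <= d_max).  Each eigenvalue factors exactly into
    variance x Moran's I of its score, so large positive eigenvalues are
    global (positively autocorrelated) structures, large negative ones
    local (negatively autocorrelated) structures.  Monte Carlo tests
    permute individual locations and compare the extreme eigenvalues.
    """
    table = data.genotypes
    coords = data.coordinates()
    n = coords.shape[0]
    X, _ = _individual_freq_matrix(table)
    X = X - X.mean(axis=0)
    W = _row_normalized_w(coords, d_max)
    connected = bool((W.sum(axis=1) > 0).all())

    def eig(Wmat):
        M = X.T @ ((Wmat + Wmat.T) / 2.0) @ X / n
        vals, vecs = np.linalg.eigh(M)
        order = np.argsort(vals)[::-1]
        return vals[order], vecs[:, order]

    vals, vecs = eig(W)
    keep = list(range(min(n_axes, vals.size))) + list(
        range(max(vals.size - n_axes, 0), vals.size)
    )
    keep = sorted(set(keep))
    scores = X @ vecs[:, keep]
    lagged = W @ scores

    global_p = local_p = None
    if n_perm > 0:
        rng = rng_for(seed, "spca")
        obs_max, obs_min = float(vals.max()), float(vals.min())
        ge = le = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Wp = W[np.ix_(perm, perm)]
            pv, _ = eig(Wp)
            ge += pv.max() >= obs_max - 1e-15
            le += pv.min() <= obs_min + 1e-15
        global_p = (1 + ge) / (n_perm + 1)
        local_p = (1 + le) / (n_perm + 1)
    return SpcaResult(
        eigenvalues=vals,
        scores=scores,
        lagged_scores=lagged,
        global_p=global_p,
        local_p=local_p,
        d_max=d_max,
        connected=connected,
    )


def group_patches(
    data: Dataset,
    spca_result: SpcaResult,
    k: int,
    n_neighbors: int = 3,
) -> dict:
    """Cluster patches into k spatially contiguous groups from sPCA scores.

    Patch features are the mean lagged scores of the leading global axes
    (up to k-1 of them, the contrasts needed to separate k groups) plus the
    leading local axis, averaged over the patch's individuals; clustering
    is agglomerative (Ward) with a k-nearest-neighbour contiguity
    constraint on patch centroids.
    """
    patch_ids = sorted({i.patch_id for i in data.genotypes.individuals})
    if k > len(patch_ids):
        raise ValueError("k exceeds the number of sampled patches")
    ind_patch = np.array(data.genotypes.patch_ids)
    lag = spca_result.lagged_scores
    n_kept = lag.shape[1]
    n_global = min(max(k - 1, 1), max(n_kept - 1, 1))
    axes = list(range(n_global))
    if n_kept > n_global:
        axes.append(n_kept - 1)
    feats, coords = [], []
    pm = data.patch_map
    for pid in patch_ids:
        rows = np.flatnonzero(ind_patch == pid)
        feats.append(lag[rows][:, axes].mean(axis=0))
        coords.append(pm[pid].xy)
    feats = np.array(feats)
    coords = np.array(coords)
    if k == len(patch_ids):
        return {pid: i for i, pid in enumerate(patch_ids)}
    conn = kneighbors_graph(
        coords, n_neighbors=min(n_neighbors, len(patch_ids) - 1), include_self=False
    )
    labels = AgglomerativeClustering(
        n_clusters=k, connectivity=conn, linkage="ward"
    ).fit_predict(feats)
    return {pid: int(lab) for pid, lab in zip(patch_ids, labels)}


# ----------------------------------------------------------------------
# Weir-Cockerham theta
# ----------------------------------------------------------------------

@dataclass
class DifferentiationResult:
    theta: float
    ci: tuple
    pairwise: dict = field(default_factory=dict)  # (pa, pb) -> (theta, ci, significant)
    fis: float | None = None
    loci: list = field(default_factory=list)
    patches: list = field(default_factory=list)


def _wc_components(table, patch_labels: np.ndarray):
    """Per-locus summed Weir-Cockerham variance components (a, a+b+c)."""
    comps = []
    patches = np.unique(patch_labels)
    r = patches.size
    for l in range(table.n_loci):
        calls = table.calls[:, l, :]
        typed = calls[:, 0] != MISSING
        ns, ps, hs = [], [], []
        alleles = sorted(table.loci[l].alleles)
        for pid in patches:
            rows = typed & (patch_labels == pid)
            c = calls[rows]
            ni = c.shape[0]
            if ni == 0:
                continue
            ns.append(ni)
            ps.append([(c == a).sum() / (2.0 * ni) for a in alleles])
            hs.append([((c[:, 0] == a) ^ (c[:, 1] == a)).mean() for a in alleles])
        ns = np.array(ns, dtype=float)
        if ns.size < 2 or ns.sum() == 0:
            comps.append((0.0, 0.0))
            continue
        ps = np.array(ps)  # pops x alleles
        hs = np.array(hs)
        ri = ns.size
        nbar = ns.mean()
        nc = (ns.sum() - (ns**2).sum() / ns.sum()) / (ri - 1)
        a_sum = abc_sum = 0.0
        for ai in range(len(alleles)):
            p = ps[:, ai]
            h = hs[:, ai]
            pbar = (ns * p).sum() / ns.sum()
            s2 = (ns * (p - pbar) ** 2).sum() / ((ri - 1) * nbar)
            hbar = (ns * h).sum() / ns.sum()
            if nbar <= 1:
                continue
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - ((ri - 1) / ri) * s2 - hbar / 4.0) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - ((ri - 1) / ri) * s2
                - ((2 * nbar - 1) / (4 * nbar)) * hbar
            )
            c_comp = hbar / 2.0
            a_sum += a
            abc_sum += a + b + c_comp
        comps.append((a_sum, abc_sum))
    return np.array(comps)


def _ratio(comps: np.ndarray) -> float:
    num = comps[:, 0].sum()
    den = comps[:, 1].sum()
    return float(num / den) if den > 0 else np.nan


def _bc_percentile_ci(boot: np.ndarray, point: float, alpha=0.05) -> tuple:
    """Bias-corrected percentile bootstrap interval."""
    boot = boot[np.isfinite(boot)]
    if boot.size == 0:
        return (np.nan, np.nan)
    frac = np.clip((boot < point).mean(), 1e-6, 1 - 1e-6)
    z0 = ndtri(frac)
    zlo, zhi = ndtri(alpha / 2), ndtri(1 - alpha / 2)
    lo = float(np.quantile(boot, ndtr(2 * z0 + zlo)))
    hi = float(np.quantile(boot, ndtr(2 * z0 + zhi)))
    return (min(lo, point), max(hi, point))


def wc_fst(
    data: Dataset,
    min_n: int = 5,
    n_boot: int = 1000,
    seed: int = 0,
    pairwise: bool = True,
) -> DifferentiationResult:
    """Weir-Cockerham theta among patches with >= min_n individuals.

    Multilocus theta is the ratio of summed variance components
    a / (a + b + c); CIs are bias-corrected percentile bootstraps over
    loci; a pair is flagged significant when its CI excludes zero.
    """
    table = data.genotypes
    patch_labels = np.array(table.patch_ids)
    counts = {p: (patch_labels == p).sum() for p in set(patch_labels)}
    eligible = sorted(p for p, c in counts.items() if c >= min_n)
    if len(eligible) < 2:
        raise ValueError("fewer than 2 patches pass the min_n filter")
    mask = np.isin(patch_labels, eligible)
    sub = table.subset(mask)
    labels = np.array(sub.patch_ids)
    comps = _wc_components(sub, labels)
    theta = _ratio(comps)
    rng = rng_for(seed, "wc_fst")
    L = comps.shape[0]
    boot = np.array(
        [_ratio(comps[rng.integers(0, L, size=L)]) for _ in range(n_boot)]
    )
    result = DifferentiationResult(
        theta=theta,
        ci=_bc_percentile_ci(boot, theta),
        fis=nei_fis(sub),
        loci=[l.name for l in sub.loci],
        patches=eligible,
    )
    if pairwise:
        for i in range(len(eligible)):
            for j in range(i + 1, len(eligible)):
                pm = np.isin(labels, [eligible[i], eligible[j]])
                c2 = _wc_components(sub.subset(pm), labels[pm])
                t2 = _ratio(c2)
                b2 = np.array(
                    [_ratio(c2[rng.integers(0, L, size=L)]) for _ in range(n_boot)]
                )
                ci = _bc_percentile_ci(b2, t2)
                sig = bool(ci[0] > 0 or ci[1] < 0)
                result.pairwise[(eligible[i], eligible[j])] = (t2, ci, sig)
    return result


def nei_fis(data) -> float:
    """Nei's multilocus FIS = 1 - sum(H_obs) / sum(H_exp).

    H_exp is the unbiased within-sample gene diversity
    n/(n-1) * (1 - sum p^2); numerators and denominators are pooled across
    loci before the ratio.
    """
    table = data.genotypes if isinstance(data, Dataset) else data
    num = den = 0.0
    any_poly = False
    for l in range(table.n_loci):
        calls = table.calls[:, l, :]
        typed = calls[:, 0] != MISSING
        n = int(typed.sum())
        if n < 2:
            continue
        c = calls[typed]
        freqs = np.array(list(table.allele_frequencies(l, subset=np.flatnonzero(typed)).values()))
        h_exp = (n / (n - 1)) * (1.0 - (freqs**2).sum())
        if h_exp <= 0:
            continue
        any_poly = True
        h_obs = float((c[:, 0] != c[:, 1]).mean())
        num += h_obs
        den += h_exp
    if not any_poly or den == 0:
        raise ValueError("no heterozygosity definable at any locus")
    return float(1.0 - num / den)


def prune_full_sibs(data: Dataset, sibship_result) -> Dataset:
    """Keep one individual per full-sib family (the lexicographically first)."""
    keep = [sorted(f)[0] for f in sibship_result.families]
    return data.subset_individuals(keep)
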