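"""Sampling-window construction and metapopulation-level Nb.

Buffers of increasing radius around each breeding patch define nested
sampling windows; duplicate windows (identical patch sets) are removed,
keeping the smallest radius.  Per window the pipeline computes LD Nb,
sibship Nb, the inferred number of parents, the census-derived number of
potential breeding adults (NA) and FIS, yielding the estimate-versus-
radius/sample-size curves that expose mixture-LD bias.  Three
metapopulation-Nb estimators are provided: the sum of local estimates, the
island-model correction sum/(1 - FST), and extrapolation from a single
breeding window (local Nb x number of neighbourhoods).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

from .ld_nb import LdNbEstimate, ld_nb
from .popdata_io import Dataset
from .sibship_nb import reconstruct_families
from .spatial_structure import Autocorrelogram, nei_fis
from .synthpop import rng_for

logger = logging.getLogger("spatialnb")


@dataclass(frozen=True)
class Window:
    id: str
    focal: str  # focal patch id, or "random"/"full"
    radius: float
    patch_ids: frozenset

    def member_ids(self, dataset: Dataset) -> list:
        return [
            i.id
            for i in dataset.genotypes.individuals
            if i.patch_id in self.patch_ids
        ]


def build_windows(
    patches,
    radii=None,
    include_full: bool = True,
) -> list:
    """Deduplicated buffer windows around every patch.

    For each (focal patch, radius) the member set is all patches whose
    centroid lies within the radius (the focal patch always included).
    Windows with identical patch sets are collapsed to the smallest radius;
    ties keep the lexicographically smallest focal id.  One full window
    containing every patch is appended (and deduplicated like the rest).
    """
    patches = list(patches)
    if not patches:
        raise ValueError("no patches")
    radii = list(radii) if radii is not None else [100.0 * k for k in range(1, 11)]
    xy = np.array([p.xy for p in patches])
    ids = [p.id for p in patches]
    D = cdist(xy, xy)
    best: dict = {}

    def consider(pset, focal, radius):
        cur = best.get(pset)
        if cur is None or (radius, focal) < cur:
            best[pset] = (radius, focal)

    for fi, fid in enumerate(ids):
        for r in sorted(radii):
            members = frozenset(ids[j] for j in np.flatnonzero(D[fi] <= r))
            consider(members, fid, float(r))
    if include_full:
        full_radius = float(np.ceil(D.max())) if len(ids) > 1 else float(min(radii))
        consider(frozenset(ids), "full", full_radius)
    windows = [
        Window(id=f"w{k:03d}", focal=focal, radius=radius, patch_ids=pset)
        for k, (pset, (radius, focal)) in enumerate(
            sorted(best.items(), key=lambda kv: (kv[1][0], kv[1][1], sorted(kv[0])))
        )
    ]
    return windows


def estimate_na(window: Window, dataset: Dataset, female_fraction: float) -> float:
    """Potential breeding adults in a window from the clutch census.

    Mothers = counted clutches x fraction of sampled clutches identified as
    the target species, summed over member patches; NA = mothers divided by
    the population female fraction.  Reported unrounded.
    """
    if not 0.0 < female_fraction < 1.0:
        raise ValueError("female_fraction must lie in (0, 1)")
    pm = dataset.patch_map
    mothers = 0.0
    for pid in window.patch_ids:
        p = pm[pid]
        if p.n_clutches_counted is None:
            continue
        pct = p.pct_target_species if p.pct_target_species is not None else 0.0
        mothers += p.n_clutches_counted * pct
    return mothers / female_fraction


@dataclass
class WindowEstimate:
    window: Window
    n: int
    ld: LdNbEstimate | None = None
    sibship_nb: float = np.nan
    n_parents: int = 0
    na: float = np.nan
    fis: float = np.nan
    skipped: str | None = None

    @property
    def ratio_nb_na(self) -> float:
        if self.ld is None or not np.isfinite(self.ld.nb_point) or not self.na:
            return np.nan
        return self.ld.nb_point / self.na


def window_profile(
    dataset: Dataset,
    windows,
    female_fraction: float = 0.48,
    pcrit: float = 0.02,
    min_individuals: int = 6,
    fs_threshold: float = 0.90,
    epsilon: float = 1e-4,
) -> list:
    """Per-window estimates (LD Nb, sibship Nb, Np, NA, FIS).

    Windows with fewer than ``min_individuals`` genotyped eggs are skipped
    with a reason; estimates without finite upper confidence limits are
    kept in the output but flagged so curve analyses can exclude them.
    """
    out = []
    for w in windows:
        ids = w.member_ids(dataset)
        est = WindowEstimate(window=w, n=len(ids))
        if len(ids) < min_individuals:
            est.skipped = f"only {len(ids)} individuals (< {min_individuals})"
            out.append(est)
            continue
        sub = dataset.subset_individuals(ids)
        try:
            est.ld = ld_nb(sub, pcrit=pcrit)
        except ValueError as exc:
            est.skipped = f"LD estimator: {exc}"
        try:
            sib = reconstruct_families(sub, threshold=fs_threshold, epsilon=epsilon, store_pairs=False)
            est.sibship_nb = sib.nb()
            est.n_parents = sib.n_parents
        except ValueError as exc:
            logger.debug("window %s sibship failed: %s", w.id, exc)
        est.na = estimate_na(w, dataset, female_fraction)
        try:
            est.fis = nei_fis(sub)
        except ValueError:
            pass
        out.append(est)
    return out


def profile_table(estimates) -> pd.DataFrame:
    """Tidy per-window table of the profile (one row per window)."""
    rows = []
    for e in estimates:
        rows.append(
            dict(
                window=e.window.id,
                focal=e.window.focal,
                radius=e.window.radius,
                n_patches=len(e.window.patch_ids),
                n=e.n,
                ld_nb=e.ld.nb_point if e.ld else np.nan,
                ld_ci_low=e.ld.ci_low if e.ld else np.nan,
                ld_ci_high=e.ld.ci_high if e.ld else np.nan,
                ld_finite_ci=bool(e.ld.finite_ci) if e.ld else False,
                sibship_nb=e.sibship_nb,
                n_parents=e.n_parents,
                na=e.na,
                fis=e.fis,
                ratio_nb_na=e.ratio_nb_na,
                skipped=e.skipped or "",
            )
        )
    return pd.DataFrame(rows)


@dataclass
class MetaNbEstimate:
    method: str  # sum_local | island | extrapolation
    value: float
    inputs: dict = field(default_factory=dict)


def meta_nb(local_nb=None, fst: float | None = None, k: int | None = None, mode: str = "island") -> MetaNbEstimate:
    """Metapopulation Nb from local estimates.

    sum_local: sum of finite local Nb.  island: sum / (1 - FST), the
    island-model upward correction for among-deme structure.
    extrapolation: one local (breeding-window) Nb times the number of
    neighbourhoods k.
    """
    if mode in ("sum_local", "island"):
        locals_arr = np.asarray(list(local_nb), dtype=float)
        finite = locals_arr[np.isfinite(locals_arr)]
        if finite.size == 0:
            raise ValueError("no finite local estimates")
        total = float(finite.sum())
        if mode == "sum_local":
            return MetaNbEstimate("sum_local", total, {"locals": finite.tolist()})
        if fst is None or not (0.0 <= fst < 1.0):
            raise ValueError("island mode requires FST in [0, 1)")
        return MetaNbEstimate(
            "island", total / (1.0 - fst), {"locals": finite.tolist(), "fst": fst}
        )
    if mode == "extrapolation":
        (local,) = list(local_nb) if np.iterable(local_nb) else ([local_nb],)
        if k is None or k <= 0:
            raise ValueError("extrapolation requires k > 0")
        return MetaNbEstimate("extrapolation", float(local) * k, {"local": float(local), "k": k})
    raise ValueError(f"unknown mode {mode!r}")


def neighbourhood_size(sigma: float, density: float) -> float:
    """Wright's neighbourhood size Nn = 4 * pi * sigma^2 * D.

    The area of a circle of radius 2*sigma (the breeding window) times the
    effective density of adults.
    """
    if sigma < 0 or density < 0:
        raise ValueError("sigma and density must be non-negative")
    return float(4.0 * np.pi * sigma**2 * density)


def breeding_window_from_autocorr(ac: Autocorrelogram) -> tuple:
    """(diameter, radius) of the breeding window from the autocorrelogram.

    The diameter is the distance at which positive spatial autocorrelation
    decays to zero; half of it approximates 2*sigma, the radius within
    which mating is near-random.
    """
    if ac.moran.size == 0 or ac.moran[0] <= 0:
        raise ValueError("no positive autocorrelation in the first distance class")
    if ac.zero_crossing is None:
        raise ValueError("autocorrelogram has no zero crossing")
    d = float(ac.zero_crossing)
    return d, d / 2.0


def default_n_neighbourhoods(dataset: Dataset, window_radius: float) -> int:
    """Heuristic k: occupied area (patch convex hull) over breeding-window area."""
    xy = np.array([p.xy for p in dataset.patches])
    if xy.shape[0] < 3:
        return 1
    area = ConvexHull(xy).volume  # 2-D hull: volume == area
    k = int(np.ceil(area / (np.pi * window_radius**2)))
    return max(k, 1)


@dataclass
class RandomWindowResult:
    per_replicate: pd.DataFrame  # buffer, rep, n, nb, finite flags, extrapolated
    n_nonfinite: int
    k: int
    mean_extrapolated: float
    sd_extrapolated: float


def random_window_sampling(
    dataset: Dataset,
    radius: float = 230.0,
    n_samples: int = 50,
    n_buffers: int = 10,
    n_reps: int = 10,
    min_patches: int = 2,
    k: int | None = None,
    pcrit: float = 0.02,
    seed: int = 0,
    max_rejections: int = 10_000,
) -> RandomWindowResult:
    """Minimal-effort survey emulation: random breeding-window buffers.

    Buffer centres are rejection-sampled uniformly in the patch bounding
    box until ``n_buffers`` qualify (>= n_samples genotyped eggs in more
    than one patch).  Within each buffer, ``n_samples`` eggs are drawn at
    random, LD Nb computed, and extrapolated to the metapopulation as
    Nb x k neighbourhoods; non-finite estimates are counted and excluded
    from the summary mean.
    """
    rng = rng_for(seed, "random_windows")
    xy = np.array([p.xy for p in dataset.patches])
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    ind_patch = np.array(dataset.genotypes.patch_ids)
    ids = np.array(dataset.genotypes.individual_ids)
    if k is None:
        k = default_n_neighbourhoods(dataset, radius)

    buffers = []
    tries = 0
    while len(buffers) < n_buffers:
        if tries >= max_rejections:
            raise RuntimeError(
                f"found only {len(buffers)} qualifying buffers after "
                f"{max_rejections} rejections"
            )
        tries += 1
        centre = rng.uniform(lo, hi)
        member = np.flatnonzero(np.linalg.norm(xy - centre, axis=1) <= radius)
        member_ids = {dataset.patches[j].id for j in member}
        rows = np.flatnonzero(np.isin(ind_patch, list(member_ids)))
        if len(member_ids) >= min_patches and rows.size >= n_samples:
            buffers.append((centre, rows))

    records = []
    n_nonfinite = 0
    for b, (centre, rows) in enumerate(buffers):
        for rep in range(n_reps):
            take = rng.choice(rows, size=n_samples, replace=False)
            sub = dataset.subset_individuals(ids[take].tolist())
            try:
                est = ld_nb(sub, pcrit=pcrit)
                nb = est.nb_point
                finite_ci = est.finite_ci
            except ValueError:
                nb, finite_ci = np.nan, False
            usable = bool(np.isfinite(nb)) and finite_ci
            if not usable:
                n_nonfinite += 1
            records.append(
                dict(
                    buffer=b,
                    rep=rep,
                    x=centre[0],
                    y=centre[1],
                    n=n_samples,
                    nb=nb,
                    finite_ci=finite_ci,
                    usable=usable,
                    extrapolated=nb * k if usable else np.nan,
                )
            )
    df = pd.DataFrame(records)
    vals = df.loc[df.usable, "extrapolated"]
    return RandomWindowResult(
        per_replicate=df,
        n_nonfinite=n_nonfinite,
        k=k,
        mean_extrapolated=float(vals.mean()) if len(vals) else np.nan,
        sd_extrapolated=float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
    )


def radius_bias_profile(dataset: Dataset, estimates, truth) -> float:
    """Spearman correlation of window radius with LD-Nb/true-parent ratio.

    Ratios are averaged over the finite-estimate windows at each radius; a
    negative value is the signature of mixture-LD bias growing with the
    sampling window.  Requires simulator truth for the parent counts.
    """
    by_radius: dict = {}
    for e in estimates:
        if e.ld is None or not np.isfinite(e.ld.nb_point) or e.skipped:
            continue
        n_true = truth.n_parents(e.window.member_ids(dataset))
        if n_true:
            by_radius.setdefault(e.window.radius, []).append(e.ld.nb_point / n_true)
    radii = sorted(by_radius)
    if len(radii) < 3:
        raise ValueError("too few radii with finite estimates")
    ratios = [float(np.mean(by_radius[r])) for r in radii]
    rho, _ = spearmanr(radii, ratios)
    return float(rho)
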