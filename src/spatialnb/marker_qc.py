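"""Marker quality control for codominant loci.

Per (locus, patch): an exact Hardy-Weinberg test (complete enumeration of
genotype tables conditional on allele counts when the table space is small,
Monte Carlo otherwise) and a null-allele frequency estimate by
expectation-maximisation.  Per locus pair: a permutation test of the
composite r^2 statistic.  Filters drop monomorphic and uncallable loci and
loci that repeatedly fail Bonferroni-corrected HWE or show high null-allele
frequencies, the usual microsatellite retention rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.special import gammaln
from scipy import stats

from .popdata_io import MISSING, Dataset, GenotypeTable
from .synthpop import rng_for

_LOG2 = np.log(2.0)
_TABLE_CAP = 100_000


# ----------------------------------------------------------------------
# exact HWE test
# ----------------------------------------------------------------------

def _genotype_counts(table: GenotypeTable, locus: int, subset=None) -> dict:
    calls = table.calls[:, locus, :]
    if subset is not None:
        calls = calls[np.asarray(subset)]
    calls = calls[calls[:, 0] != MISSING]
    counts: dict = {}
    for a1, a2 in calls:
        key = (int(a1), int(a2))
        counts[key] = counts.get(key, 0) + 1
    return counts


def _log_table_prob(het: int, genotype_counts: np.ndarray, n: int, allele_counts: np.ndarray) -> float:
    """log P(genotype table | allele counts) under the exact HWE null."""
    return float(
        gammaln(n + 1)
        + gammaln(allele_counts + 1).sum()
        + het * _LOG2
        - gammaln(2 * n + 1)
        - gammaln(genotype_counts + 1).sum()
    )


def _enumerate_tables(m: np.ndarray, cap: int = _TABLE_CAP):
    """All genotype tables with the given allele counts, or None if > cap.

    Yields (het_count, array of genotype cell counts).
    """
    k = m.size
    out = []
    cells = np.zeros((k, k), dtype=int)

    def rec(i, residual):
        if len(out) > cap:
            raise OverflowError
        if i == k:
            upper = cells[np.triu_indices(k)]
            het = int(cells.sum() - np.trace(cells))  # off-diagonal entries
            out.append((het, upper.copy()))
            return
        # choose off-diagonal pairings of allele i with j > i, then the
        # homozygote count is forced by the residual (must be even)
        def rec_row(j, left):
            if j == k:
                if left % 2 == 0:
                    cells[i, i] = left // 2
                    rec(i + 1, residual)
                    cells[i, i] = 0
                return
            top = min(left, residual[j])
            for x in range(top + 1):
                cells[i, j] = x
                residual[j] -= x
                rec_row(j + 1, left - x)
                residual[j] += x
            cells[i, j] = 0

        rec_row(i + 1, residual[i])

    try:
        rec(0, m.copy())
    except OverflowError:
        return None
    return out


def _hwe_mc(alleles: np.ndarray, log_p_obs: float, n_mc: int, rng, k: int) -> float:
    """Monte Carlo exact test: shuffle the allele vector into diploid pairs."""
    n = alleles.size // 2
    count = 0
    batch = max(1, min(n_mc, 20_000))
    done = 0
    tol = 1e-9
    while done < n_mc:
        b = min(batch, n_mc - done)
        draws = np.tile(alleles, (b, 1))
        draws = rng.permuted(draws, axis=1)
        a1, a2 = draws[:, ::2], draws[:, 1::2]
        het = (a1 != a2).sum(axis=1)
        lo = np.minimum(a1, a2)
        hi = np.maximum(a1, a2)
        code = lo * k + hi
        flat = (np.arange(b)[:, None] * (k * k) + code).ravel()
        cnt = np.bincount(flat, minlength=b * k * k).reshape(b, k * k)
        log_p = het * _LOG2 - gammaln(cnt + 1).sum(axis=1)
        # constant terms cancel against the observed statistic
        count += int((log_p <= log_p_obs + tol).sum())
        done += b
    return (1 + count) / (n_mc + 1)


def hwe_test(
    table: GenotypeTable,
    locus: int,
    subset=None,
    n_mc: int = 100_000,
    seed: int = 0,
) -> float:
    """Exact test of Hardy-Weinberg proportions at one locus.

    The p-value is the null probability of genotype tables at most as
    probable as the observed one, conditional on the allele counts
    (probability ordering).  Complete enumeration is used when the table
    space is small (<= 1e5 tables); otherwise Monte Carlo shuffling of the
    allele vector, deterministic under ``seed``.  A monomorphic locus is
    defined to have p = 1.
    """
    counts = _genotype_counts(table, locus, subset)
    n = sum(counts.values())
    if n < 2:
        raise ValueError("need at least 2 genotyped individuals")
    alleles = sorted({a for g in counts for a in g})
    if len(alleles) < 2:
        return 1.0
    index = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    m = np.zeros(k, dtype=int)
    obs_cells = np.zeros((k, k), dtype=int)
    for (a1, a2), c in counts.items():
        i, j = index[a1], index[a2]
        m[i] += c
        m[j] += c
        obs_cells[min(i, j), max(i, j)] += c
    het_obs = int(sum(c for (a1, a2), c in counts.items() if a1 != a2))
    obs_upper = obs_cells[np.triu_indices(k)]
    log_p_obs_full = _log_table_prob(het_obs, obs_upper, n, m)

    # complete enumeration only where the table space is certainly small
    tables = _enumerate_tables(m) if (n <= 15 and k <= 4) else None
    if tables is not None:
        tol = 1e-9
        p = 0.0
        for het, cells in tables:
            lp = _log_table_prob(het, cells, n, m)
            if lp <= log_p_obs_full + tol:
                p += np.exp(lp)
        return float(min(p, 1.0))

    # Monte Carlo: compare only the table-dependent part of log P
    log_p_obs = het_obs * _LOG2 - float(gammaln(obs_upper + 1).sum())
    vec = np.repeat(np.arange(k), m)
    rng = rng_for(seed, f"hwe:{locus}")
    return _hwe_mc(vec, log_p_obs, n_mc, rng, k)


# ----------------------------------------------------------------------
# null-allele EM
# ----------------------------------------------------------------------

def null_allele_em(
    genotype_counts: dict,
    n_missing: int = 0,
    include_missing: bool = True,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    return_loglik: bool = False,
):
    """EM estimate of the null-allele frequency at one locus under HWE.

    ``genotype_counts`` maps unordered visible genotypes ``(a1, a2)`` to
    counts.  An observed homozygote a/a is a mixture of true a/a and
    a/null; with ``include_missing`` the missing class is modelled as
    null/null homozygotes, otherwise missing individuals are excluded and
    the null/null class is treated as truncated (phantom counts in the
    E-step).  Iterates until the largest frequency change is below ``tol``.
    """
    if not genotype_counts and (n_missing == 0 or not include_missing):
        raise ValueError("no observations at this locus")
    alleles = sorted({a for g in genotype_counts for a in g})
    if not alleles:
        raise ValueError("all observations missing: no visible alleles")
    index = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    het = np.zeros((k, k))
    hom = np.zeros(k)
    for (a1, a2), c in genotype_counts.items():
        if a1 == a2:
            hom[index[a1]] += c
        else:
            het[index[a1], index[a2]] += c
    het_counts = het + het.T
    n_obs = int(sum(genotype_counts.values()))
    n_tot = n_obs + (n_missing if include_missing else 0)

    freqs = np.full(k + 1, 1.0 / (k + 1))  # visible alleles + null (last)
    loglik = []
    for _ in range(max_iter):
        p, p0 = freqs[:k], freqs[k]
        if return_loglik:
            ll = 0.0
            for i in range(k):
                if hom[i]:
                    ll += hom[i] * np.log(p[i] ** 2 + 2 * p[i] * p0)
                for j in range(i + 1, k):
                    if het[i, j] + het[j, i]:
                        ll += (het[i, j] + het[j, i]) * np.log(2 * p[i] * p[j])
            if include_missing and n_missing:
                ll += n_missing * np.log(p0**2)
            if not include_missing:
                ll -= n_obs * np.log(1.0 - p0**2)
            loglik.append(ll)
        # E-step: expected allele copies
        counts = het_counts.sum(axis=1).astype(float)  # from heterozygotes
        denom = p**2 + 2 * p * p0
        with np.errstate(invalid="ignore", divide="ignore"):
            share_null = np.where(denom > 0, 2 * p * p0 / denom, 0.0)
        counts += hom * (2.0 - share_null)  # visible copies in observed homs
        null_copies = float((hom * share_null).sum())
        n_eff = float(n_tot)
        if include_missing:
            null_copies += 2.0 * n_missing
        elif p0 > 0:
            phantom = n_obs * p0**2 / (1.0 - p0**2)
            null_copies += 2.0 * phantom
            n_eff += phantom
        total = counts.sum() + null_copies
        new = np.append(counts, null_copies) / total
        delta = np.abs(new - freqs).max()
        freqs = new
        if delta < tol:
            break
    null_freq = float(freqs[k])
    if return_loglik:
        return null_freq, np.array(loglik)
    return null_freq


def null_allele_from_table(
    table: GenotypeTable, locus: int, subset=None, include_missing: bool = True
) -> float:
    counts = _genotype_counts(table, locus, subset)
    calls = table.calls[:, locus, 0]
    if subset is not None:
        calls = calls[np.asarray(subset)]
    n_missing = int((calls == MISSING).sum())
    return null_allele_em(counts, n_missing, include_missing=include_missing)


# ----------------------------------------------------------------------
# interlocus LD permutation test
# ----------------------------------------------------------------------

def interlocus_ld_test(
    table: GenotypeTable,
    locus_a: int,
    locus_b: int,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Permutation p-value for association between two loci.

    The statistic is the mean composite r^2 over all allele pairs with
    non-zero dosage variance in the pairwise-complete subset; the null is
    generated by shuffling one locus's genotypes across individuals.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    typed = ~table.missing_mask
    mask = typed[:, locus_a] & typed[:, locus_b]
    s = int(mask.sum())
    if s < 5:
        raise ValueError("fewer than 5 overlapping genotyped individuals")

    def z_matrix(locus):
        alleles = sorted(table.loci[locus].alleles)
        D = np.stack(
            [(table.calls[mask, locus, :] == a).sum(axis=1).astype(float) for a in alleles],
            axis=1,
        )
        sd = D.std(axis=0)
        keep = sd > 0
        if not keep.any():
            raise ValueError("monomorphic locus in overlap subset")
        return (D[:, keep] - D[:, keep].mean(axis=0)) / sd[keep]

    Za, Zb = z_matrix(locus_a), z_matrix(locus_b)

    def stat(Zb_perm):
        R = (Za.T @ Zb_perm) / s
        return float((R * R).mean())

    observed = stat(Zb)
    rng = rng_for(seed, f"ldtest:{locus_a}:{locus_b}")
    exceed = 0
    for _ in range(n_perm):
        exceed += stat(Zb[rng.permutation(s)]) >= observed - 1e-12
    return (1 + exceed) / (n_perm + 1)


# ----------------------------------------------------------------------
# report and filters
# ----------------------------------------------------------------------

@dataclass
class QcThresholds:
    alpha: float = 0.05  # family-wise level before Bonferroni division
    max_hwe_failures: int = 2  # failures tolerated across patches (m)
    null_threshold: float = 0.20
    max_null_failures: int = 1  # patches tolerated above null_threshold (k)
    min_patch_n: int = 5  # individuals required for a per-patch test


@dataclass
class QcReport:
    hwe_p: dict = field(default_factory=dict)  # (locus, patch) -> p
    null_freq: dict = field(default_factory=dict)  # (locus, patch) -> estimate
    ld_p: dict = field(default_factory=dict)  # (locusA, locusB) -> p
    monomorphic: set = field(default_factory=set)
    uncallable: set = field(default_factory=set)
    loci: list = field(default_factory=list)
    n_tests: int = 0
    decisions: dict = field(default_factory=dict)  # locus -> (retained, reason)


def run_qc(
    dataset: Dataset,
    n_mc: int = 20_000,
    n_perm: int = 2_000,
    thresholds: QcThresholds | None = None,
    exclude_ids=None,
    seed: int = 0,
) -> QcReport:
    """Full QC sweep: per-patch HWE and null-allele tests, interlocus LD.

    ``exclude_ids`` removes individuals first (e.g. one member of each
    full-sib pair) so family sampling does not masquerade as HWE failure.
    """
    thresholds = thresholds or QcThresholds()
    table = dataset.genotypes
    if exclude_ids:
        keep = [i.id for i in table.individuals if i.id not in set(exclude_ids)]
        table = table.subset_ids(keep)
    patch_arr = np.array(table.patch_ids)
    report = QcReport(loci=[l.name for l in table.loci])
    typed = ~table.missing_mask
    for j, locus in enumerate(table.loci):
        if typed[:, j].sum() == 0:
            report.uncallable.add(locus.name)
            continue
        observed = {
            int(a) for a in table.calls[typed[:, j], j, :].ravel()
        }
        if len(observed) < 2:
            report.monomorphic.add(locus.name)
            continue
        for pid in sorted(set(patch_arr)):
            rows = np.flatnonzero(patch_arr == pid)
            rows = rows[typed[rows, j]]
            if rows.size < thresholds.min_patch_n:
                continue
            if len({int(a) for a in table.calls[rows, j, :].ravel()}) < 2:
                continue
            report.hwe_p[(locus.name, pid)] = hwe_test(
                table, j, subset=rows, n_mc=n_mc, seed=seed
            )
            report.null_freq[(locus.name, pid)] = null_allele_from_table(
                table, j, subset=rows
            )
    report.n_tests = len(report.hwe_p)
    usable = [
        j
        for j, l in enumerate(table.loci)
        if l.name not in report.monomorphic and l.name not in report.uncallable
    ]
    for a, b in combinations(usable, 2):
        pvals = []
        for pid in sorted(set(patch_arr)):
            rows = np.flatnonzero(patch_arr == pid)
            sub = table.subset(rows)
            try:
                pvals.append(interlocus_ld_test(sub, a, b, n_perm=n_perm, seed=seed))
            except ValueError:
                continue
        if pvals:  # Fisher combination across patches
            chi2 = -2.0 * np.log(pvals).sum()
            report.ld_p[(table.loci[a].name, table.loci[b].name)] = float(
                stats.chi2.sf(chi2, df=2 * len(pvals))
            )
    apply_locus_filters(report, thresholds)
    return report


def apply_locus_filters(report: QcReport, thresholds: QcThresholds | None = None) -> list:
    """Decide per-locus retention; returns the retained locus names.

    Drops monomorphic and uncallable loci; drops loci failing
    Bonferroni-corrected HWE in more than ``max_hwe_failures`` patches or
    exceeding the null-allele threshold in more than ``max_null_failures``
    patches.  The Bonferroni denominator is the number of HWE tests
    actually performed.
    """
    thresholds = thresholds or QcThresholds()
    n_tests = max(report.n_tests, 1)
    cutoff = thresholds.alpha / n_tests
    retained = []
    for locus in report.loci:
        if locus in report.monomorphic:
            report.decisions[locus] = (False, "monomorphic")
            continue
        if locus in report.uncallable:
            report.decisions[locus] = (False, "uncallable")
            continue
        hwe_fail = sum(
            1 for (l, _), p in report.hwe_p.items() if l == locus and p < cutoff
        )
        null_fail = sum(
            1
            for (l, _), nu in report.null_freq.items()
            if l == locus and nu > thresholds.null_threshold
        )
        if hwe_fail > thresholds.max_hwe_failures:
            report.decisions[locus] = (
                False,
                f"HWE failures in {hwe_fail} patches (Bonferroni {cutoff:.2e})",
            )
        elif null_fail > thresholds.max_null_failures:
            report.decisions[locus] = (
                False,
                f"null-allele frequency > {thresholds.null_threshold} in "
                f"{null_fail} patches",
            )
        else:
            report.decisions[locus] = (True, "retained")
            retained.append(locus)
    return retained
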