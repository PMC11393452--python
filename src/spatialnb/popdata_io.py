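"""Data model and I/O for microsatellite metapopulation datasets.

Genotypes are diploid codominant allele calls (fragment sizes) for eggs
sampled from discrete breeding patches.  A patch is a point in a planar,
metric coordinate frame; every individual (egg) belongs to a clutch and
every clutch to a patch, so individuals inherit their patch's coordinates.

The genepop dialect supported here is the classic one used for
microsatellites: a title line, one locus name per line (or a single
comma-separated line), ``Pop`` separators, and rows ``id , a1a2 a1a2 ...``
with fixed-width 2- or 3-digit allele codes where an all-zero code means
missing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("spatialnb")

MISSING = -1  # internal sentinel in the calls array, never a valid allele label

TARGET = "target"
NON_TARGET = "non_target"


class GenepopParseError(ValueError):
    """Raised for malformed genepop input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Locus:
    """A codominant locus with its observed allele labels."""

    name: str
    alleles: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if len(self.alleles) < 1:
            raise ValueError(f"locus {self.name!r} has no alleles")

    @property
    def is_monomorphic(self) -> bool:
        return len(self.alleles) < 2


@dataclass
class Individual:
    id: str
    clutch_id: str
    patch_id: str
    species: str = TARGET
    sex: str | None = None  # simulated truth only

    def __post_init__(self):
        if self.species not in (TARGET, NON_TARGET):
            raise ValueError(f"unknown species label {self.species!r}")


@dataclass(frozen=True)
class Patch:
    """A breeding patch: a point location plus clutch-census metadata."""

    id: str
    x: float
    y: float
    n_clutches_counted: int | None = None
    n_clutches_sampled: int = 0
    pct_target_species: float | None = None

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"patch {self.id!r} has non-finite coordinates")
        if (
            self.n_clutches_counted is not None
            and self.n_clutches_sampled > self.n_clutches_counted
        ):
            raise ValueError(
                f"patch {self.id!r}: sampled clutches ({self.n_clutches_sampled}) "
                f"exceed counted ({self.n_clutches_counted})"
            )
        if self.pct_target_species is not None and not (
            0.0 <= self.pct_target_species <= 1.0
        ):
            raise ValueError(f"patch {self.id!r}: pct_target_species outside [0,1]")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


class GenotypeTable:
    """Individuals x loci diploid allele calls with an explicit missing mask.

    Parameters
    ----------
    individuals
        Ordered individuals.
    loci
        Ordered loci; allele sets are extended to cover observed calls.
    calls
        Integer array of shape ``(n_individuals, n_loci, 2)``; ``MISSING``
        (in both slots) marks a missing call.  Allele pairs are unordered;
        they are canonicalized smaller-first internally.
    """

    def __init__(
        self,
        individuals: Sequence[Individual],
        loci: Sequence[Locus],
        calls: np.ndarray,
    ):
        calls = np.asarray(calls, dtype=np.int32)
        if calls.shape != (len(individuals), len(loci), 2):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"({len(individuals)}, {len(loci)}, 2)"
            )
        half_missing = (calls == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("half-missing calls are not representable")
        calls = np.sort(calls, axis=2)  # canonical smaller-first
        self.individuals = list(individuals)
        self.calls = calls
        # extend locus allele sets with observed alleles
        self.loci = []
        for j, locus in enumerate(loci):
            observed = set(int(a) for a in calls[:, j, :].ravel() if a != MISSING)
            self.loci.append(Locus(locus.name, frozenset(locus.alleles | observed)))
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids")

    # -- basic shape ----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    @property
    def individual_ids(self) -> list:
        return [ind.id for ind in self.individuals]

    @property
    def patch_ids(self) -> list:
        return [ind.patch_id for ind in self.individuals]

    @property
    def clutch_ids(self) -> list:
        return [ind.clutch_id for ind in self.individuals]

    # -- derived views --------------------------------------------------
    def allele_counts(self, locus_index: int, subset=None) -> dict:
        """Observed allele counts at one locus (optionally over a row subset)."""
        a = self.calls[:, locus_index, :]
        if subset is not None:
            a = a[np.asarray(subset)]
        a = a[a[:, 0] != MISSING]
        labels, counts = np.unique(a.ravel(), return_counts=True)
        return {int(l): int(c) for l, c in zip(labels, counts)}

    def allele_frequencies(self, locus_index: int, subset=None) -> dict:
        counts = self.allele_counts(locus_index, subset)
        tot = sum(counts.values())
        if tot == 0:
            return {}
        return {a: c / tot for a, c in counts.items()}

    def dosage(self, locus_index: int, allele: int) -> np.ndarray:
        """Copy-number (0/1/2) of ``allele`` per individual; NaN where missing."""
        a = self.calls[:, locus_index, :]
        d = (a == allele).sum(axis=1).astype(float)
        d[a[:, 0] == MISSING] = np.nan
        return d

    def subset(self, indices) -> "GenotypeTable":
        """New table restricted to the given individual row indices."""
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        inds = [replace(self.individuals[i]) for i in indices]
        return GenotypeTable(inds, self.loci, self.calls[indices])

    def subset_ids(self, ids: Iterable) -> "GenotypeTable":
        wanted = set(ids)
        idx = [i for i, ind in enumerate(self.individuals) if ind.id in wanted]
        return GenotypeTable([self.individuals[i] for i in idx], self.loci, self.calls[idx])

    def drop_loci(self, names: Iterable) -> "GenotypeTable":
        drop = set(names)
        keep = [j for j, l in enumerate(self.loci) if l.name not in drop]
        return GenotypeTable(
            self.individuals, [self.loci[j] for j in keep], self.calls[:, keep, :]
        )

    def keep_loci(self, names: Sequence) -> "GenotypeTable":
        order = {n: k for k, n in enumerate(names)}
        keep = sorted(
            (j for j, l in enumerate(self.loci) if l.name in order),
            key=lambda j: order[self.loci[j].name],
        )
        return GenotypeTable(
            self.individuals, [self.loci[j] for j in keep], self.calls[:, keep, :]
        )


@dataclass
class Dataset:
    """A genotype table joined to its spatial sampling frame."""

    genotypes: GenotypeTable
    patches: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        known = {p.id for p in self.patches}
        for ind in self.genotypes.individuals:
            if ind.patch_id not in known:
                raise ValueError(
                    f"individual {ind.id!r} references unknown patch {ind.patch_id!r}"
                )

    @property
    def patch_map(self) -> dict:
        return {p.id: p for p in self.patches}

    def coordinates(self) -> np.ndarray:
        """Per-individual (x, y), inherited from the individual's patch."""
        pm = self.patch_map
        return np.array(
            [pm[i.patch_id].xy for i in self.genotypes.individuals], dtype=float
        )

    def subset_individuals(self, ids: Iterable) -> "Dataset":
        return Dataset(self.genotypes.subset_ids(ids), self.patches, dict(self.provenance))

    def subset_patches(self, patch_ids: Iterable) -> "Dataset":
        wanted = set(patch_ids)
        mask = np.array([i.patch_id in wanted for i in self.genotypes.individuals])
        return Dataset(self.genotypes.subset(mask), self.patches, dict(self.provenance))


# ----------------------------------------------------------------------
# genepop reading / writing
# ----------------------------------------------------------------------

def _default_clutch_from_id(ind_id: str) -> str:
    """Clutch id convention: everything before the last ``_`` suffix."""
    head, sep, tail = ind_id.rpartition("_")
    return head if sep else ind_id


def read_genepop(
    path,
    patch_name_map: Mapping[int, str] | None = None,
    clutch_from_id: Callable[[str], str] = _default_clutch_from_id,
) -> GenotypeTable:
    """Read a genepop file into a :class:`GenotypeTable`.

    Pop sections become patches, named ``pop01``, ``pop02``, ... in file
    order unless ``patch_name_map`` maps section indices (0-based) to names.
    Allele-code width (2 vs 3 digits per allele) is auto-detected from the
    first genotype row.  All-zero allele codes are missing data.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopParseError("empty file")
    # locus names: either comma-separated on line 2, or one per line until "Pop"
    locus_names: list[str] = []
    i = 1
    if i < len(lines) and "," in lines[i] and lines[i].strip().lower() != "pop":
        locus_names = [t.strip() for t in lines[i].split(",") if t.strip()]
        i += 1
    else:
        while i < len(lines) and lines[i].strip().lower() != "pop":
            name = lines[i].strip()
            if name:
                locus_names.append(name)
            i += 1
    if not locus_names:
        raise GenepopParseError("no locus names found", line=2)

    individuals: list[Individual] = []
    rows: list[list[tuple]] = []
    width: int | None = None
    section = -1
    seen_rows_in_section = True
    while i < len(lines):
        raw = lines[i]
        stripped = raw.strip()
        i += 1
        if not stripped:
            continue
        if stripped.lower() == "pop":
            if not seen_rows_in_section:
                raise GenepopParseError("empty Pop section", line=i - 1)
            section += 1
            seen_rows_in_section = False
            continue
        if section < 0:
            raise GenepopParseError("genotype row before first Pop", line=i)
        if "," not in stripped:
            raise GenepopParseError("expected 'id , genotypes' row", line=i)
        ind_id, _, geno_part = stripped.partition(",")
        ind_id = ind_id.strip()
        tokens = geno_part.split()
        if len(tokens) != len(locus_names):
            raise GenepopParseError(
                f"expected {len(locus_names)} genotypes, got {len(tokens)}", line=i
            )
        if width is None:
            w = len(tokens[0])
            if w not in (4, 6):
                raise GenepopParseError(
                    f"cannot detect allele width from token {tokens[0]!r}", line=i
                )
            width = w // 2
        calls_row = []
        for tok in tokens:
            if len(tok) != 2 * width or not tok.isdigit():
                raise GenepopParseError(f"bad genotype token {tok!r}", line=i)
            a1, a2 = int(tok[:width]), int(tok[width:])
            if a1 == 0 or a2 == 0:
                calls_row.append((MISSING, MISSING))
            else:
                calls_row.append((a1, a2))
        patch = (
            patch_name_map[section]
            if patch_name_map and section in patch_name_map
            else f"pop{section + 1:02d}"
        )
        individuals.append(
            Individual(id=ind_id, clutch_id=clutch_from_id(ind_id), patch_id=patch)
        )
        rows.append(calls_row)
        seen_rows_in_section = True
    if section < 0:
        raise GenepopParseError("no Pop section found")
    if not seen_rows_in_section:
        raise GenepopParseError("empty Pop section", line=len(lines))
    calls = np.array(rows, dtype=np.int32)
    loci = []
    for j, name in enumerate(locus_names):
        observed = set(int(a) for a in calls[:, j, :].ravel() if a != MISSING)
        loci.append(Locus(name, frozenset(observed) if observed else frozenset({1})))
    return GenotypeTable(individuals, loci, calls)


def write_genepop(table: GenotypeTable, path, digits: int = 3, title: str = "spatialnb export"):
    """Write a :class:`GenotypeTable` as genepop with fixed-width allele codes.

    Individuals are grouped into Pop sections by patch in input order;
    allele pairs are written smaller-first; missing calls are all zeros.
    """
    limit = 10 ** digits
    for locus in table.loci:
        bad = [a for a in locus.alleles if not (0 < a < limit)]
        if bad:
            raise ValueError(
                f"locus {locus.name!r}: allele label {bad[0]} does not fit in "
                f"{digits} digits"
            )
    if table.n_individuals == 0:
        raise ValueError("refusing to write a genepop file with zero Pop sections")
    out = [title]
    out.extend(l.name for l in table.loci)
    current_patch = object()
    for i, ind in enumerate(table.individuals):
        if ind.patch_id != current_patch:
            out.append("Pop")
            current_patch = ind.patch_id
        toks = []
        for j in range(table.n_loci):
            a1, a2 = table.calls[i, j]
            if a1 == MISSING:
                toks.append("0" * (2 * digits))
            else:
                toks.append(f"{a1:0{digits}d}{a2:0{digits}d}")
        out.append(f"{ind.id} , " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


# ----------------------------------------------------------------------
# side tables and dataset assembly
# ----------------------------------------------------------------------

def read_patch_table(path) -> list:
    """Patch CSV with columns id,x,y,n_counted,n_sampled,pct_target."""
    df = pd.read_csv(path, dtype={"id": str})
    patches = []
    for _, row in df.iterrows():
        counted = row.get("n_counted")
        patches.append(
            Patch(
                id=str(row["id"]),
                x=float(row["x"]),
                y=float(row["y"]),
                n_clutches_counted=None if pd.isna(counted) else int(counted),
                n_clutches_sampled=int(row.get("n_sampled", 0) or 0),
                pct_target_species=(
                    None if pd.isna(row.get("pct_target")) else float(row["pct_target"])
                ),
            )
        )
    return patches


def read_clutch_table(path) -> pd.DataFrame:
    """Clutch CSV with columns clutch_id,patch_id,species."""
    df = pd.read_csv(path, dtype=str)
    required = {"clutch_id", "patch_id", "species"}
    if not required.issubset(df.columns):
        raise ValueError(f"clutch table must have columns {sorted(required)}")
    return df


def assemble_dataset(
    table: GenotypeTable,
    patches: Sequence[Patch] | pd.DataFrame,
    clutch_table: pd.DataFrame | None = None,
    provenance: dict | None = None,
) -> Dataset:
    """Join genotypes, patches and clutch labels into a validated Dataset.

    Clutch rows override each individual's patch assignment and species
    label; individuals of the non-target species are dropped (with a logged
    count), emulating molecular species identification before genotyping.
    """
    if isinstance(patches, pd.DataFrame):
        patches = [
            Patch(
                id=str(r["id"]),
                x=float(r["x"]),
                y=float(r["y"]),
                n_clutches_counted=None if pd.isna(r.get("n_counted")) else int(r["n_counted"]),
                n_clutches_sampled=int(r.get("n_sampled", 0) or 0),
                pct_target_species=None if pd.isna(r.get("pct_target")) else float(r["pct_target"]),
            )
            for _, r in patches.iterrows()
        ]
    patches = list(patches)
    patch_ids = {p.id for p in patches}
    if clutch_table is not None:
        info = clutch_table.set_index("clutch_id")
        orphans = set(info["patch_id"]) - patch_ids
        if orphans:
            raise ValueError(f"clutch table references unknown patches: {sorted(orphans)}")
        new_inds, keep_rows = [], []
        n_dropped = 0
        for i, ind in enumerate(table.individuals):
            if ind.clutch_id not in info.index:
                raise ValueError(f"individual {ind.id!r}: orphan clutch {ind.clutch_id!r}")
            row = info.loc[ind.clutch_id]
            species = row["species"]
            if species == NON_TARGET:
                n_dropped += 1
                continue
            new_inds.append(
                Individual(ind.id, ind.clutch_id, str(row["patch_id"]), species, ind.sex)
            )
            keep_rows.append(i)
        if n_dropped:
            logger.info("species filter dropped %d non-target individuals", n_dropped)
        if not new_inds:
            logger.warning("species filter removed every individual")
            table = GenotypeTable([], table.loci, np.empty((0, table.n_loci, 2), np.int32))
        else:
            table = GenotypeTable(new_inds, table.loci, table.calls[keep_rows])
    else:
        missing = {i.patch_id for i in table.individuals} - patch_ids
        if missing:
            raise ValueError(f"genotypes reference unknown patches: {sorted(missing)}")
    return Dataset(table, patches, provenance or {})


def write_manifest(dataset: Dataset, path):
    manifest = {
        "n_individuals": dataset.genotypes.n_individuals,
        "n_loci": dataset.genotypes.n_loci,
        "loci": [l.name for l in dataset.genotypes.loci],
        "patches": [p.id for p in dataset.patches],
        "provenance": dataset.provenance,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
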