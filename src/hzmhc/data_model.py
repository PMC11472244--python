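"""Core containers, file I/O and admixture-based filters.

The central object is a binary presence/absence genotype matrix: rows are
individuals, columns are MHC alleles, a cell is 1 if the individual carries
at least one copy of the allele.  Because MHC amplicon genotyping cannot
assign alleles to loci or count copies, every downstream analysis treats
each allele column as an independent dominant marker.

Individuals carry a genome-wide admixture proportion (Q-score in [0, 1])
estimated externally; two filters based on it precede every test:
individuals with Q above a threshold (default 3%) are considered admixed,
and whole localities whose mean Q reaches 5% are excluded from the
allele-sharing comparison.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "MhcClass",
    "ZoneCategory",
    "BinaryGenotypeMatrix",
    "IndividualRecord",
    "ZoneConfig",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_metadata",
    "filter_nonadmixed",
    "summarize_diversity",
    "rarefied_richness",
]


class MhcClass(str, enum.Enum):
    I = "I"
    II = "II"


class ZoneCategory(str, enum.Enum):
    NEAR = "near"
    FAR = "far"
    HYBRID_ZONE = "hybrid_zone"
    UNASSIGNED = "unassigned"


@dataclass
class BinaryGenotypeMatrix:
    """Individuals x alleles presence/absence matrix.

    Parameters
    ----------
    individual_ids : sequence of str
        Unique row identifiers.
    allele_ids : sequence of str
        Unique column identifiers.
    presence : ndarray of shape (n_individuals, n_alleles)
        0/1 entries; stored as ``int8``.
    mhc_class : MhcClass, optional
        Which MHC class the alleles belong to.
    """

    individual_ids: list[str]
    allele_ids: list[str]
    presence: np.ndarray
    mhc_class: MhcClass | None = None

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence)
        if self.presence.ndim != 2:
            raise ValueError("presence must be a 2-D array")
        if self.presence.shape != (len(self.individual_ids), len(self.allele_ids)):
            raise ValueError(
                f"presence shape {self.presence.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.allele_ids)} alleles"
            )
        if not np.isin(self.presence, (0, 1)).all():
            raise ValueError("presence entries must be exactly 0 or 1")
        self.presence = self.presence.astype(np.int8)
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual_ids")
        if len(set(self.allele_ids)) != len(self.allele_ids):
            raise ValueError("duplicate allele_ids")

    @property
    def n_individuals(self) -> int:
        return self.presence.shape[0]

    @property
    def n_alleles(self) -> int:
        return self.presence.shape[1]

    def subset_individuals(self, ids: Iterable[str], drop_empty_alleles: bool = False) -> "BinaryGenotypeMatrix":
        """Return the sub-matrix for ``ids`` (kept in the given order).

        With ``drop_empty_alleles`` allele columns absent from every retained
        individual are removed — applied per-analysis, not globally.
        """
        index = {iid: k for k, iid in enumerate(self.individual_ids)}
        ids = list(ids)
        missing = [i for i in ids if i not in index]
        if missing:
            raise KeyError(f"individuals not in matrix: {missing[:5]}")
        rows = [index[i] for i in ids]
        pres = self.presence[rows, :]
        alleles = list(self.allele_ids)
        if drop_empty_alleles:
            keep = pres.sum(axis=0) > 0
            pres = pres[:, keep]
            alleles = [a for a, k in zip(alleles, keep) if k]
        return BinaryGenotypeMatrix(ids, alleles, pres, self.mhc_class)

    def allele_set(self, ids: Iterable[str] | None = None) -> set[str]:
        """Pooled set of alleles observed in the given individuals (default: all)."""
        if ids is None:
            pres = self.presence
        else:
            pres = self.subset_individuals(ids).presence
        observed = pres.sum(axis=0) > 0
        return {a for a, k in zip(self.allele_ids, observed) if k}


@dataclass
class IndividualRecord:
    """Per-individual metadata consumed alongside a genotype matrix."""

    individual_id: str
    species: str
    locality_id: str
    transect_position_km: float | None = None
    q_score: float | None = None
    zone_category: ZoneCategory = ZoneCategory.UNASSIGNED
    q_inferred: bool = False  # q assigned 0/1 from a pure locality, not estimated

    def __post_init__(self) -> None:
        if self.q_score is not None and not (0.0 <= self.q_score <= 1.0):
            raise ValueError(f"q_score {self.q_score} outside [0, 1] for {self.individual_id}")
        if isinstance(self.zone_category, str):
            self.zone_category = ZoneCategory(self.zone_category)


@dataclass
class ZoneConfig:
    """Per-hybrid-zone configuration.

    ``admixed_threshold`` — individuals with Q strictly above it are admixed
    (default 0.03).  ``pure_locality_threshold`` — localities whose mean Q is
    not strictly below it are excluded from the sharing test (default 0.05).
    ``less_diverse_species`` orients the cline-center shift and the genomic
    cline alpha sign.
    """

    species_pair: tuple[str, str]
    less_diverse_species: str
    admixed_threshold: float = 0.03
    pure_locality_threshold: float = 0.05
    near_far_boundary_km: float | None = None

    def __post_init__(self) -> None:
        if self.less_diverse_species not in self.species_pair:
            raise ValueError("less_diverse_species must be one of species_pair")
        for t in (self.admixed_threshold, self.pure_locality_threshold):
            if not (0.0 < t < 1.0):
                raise ValueError(f"threshold {t} outside (0, 1)")

    @property
    def more_diverse_species(self) -> str:
        a, b = self.species_pair
        return b if self.less_diverse_species == a else a


# ---------------------------------------------------------------------------
# I/O


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_genotype_matrix(path: str | Path, mhc_class: MhcClass | str | None = None) -> BinaryGenotypeMatrix:
    """Read a presence/absence matrix from delimited text.

    Layout: header row of allele IDs, first column individual IDs, body of
    0/1.  Tab or comma delimiter is auto-detected.  All-zero allele columns
    are dropped with a warning; any non-binary cell is an error naming its
    row and column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), index_col=0, dtype=str)
    individual_ids = [str(i) for i in df.index]
    allele_ids = [str(c) for c in df.columns]
    values = df.to_numpy()
    bad = ~np.isin(values, ("0", "1"))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-binary cell {values[r, c]!r} at individual {individual_ids[r]!r}, "
            f"allele {allele_ids[c]!r} in {path}"
        )
    presence = values.astype(np.int8)
    empty = presence.sum(axis=0) == 0
    if empty.any():
        dropped = [a for a, e in zip(allele_ids, empty) if e]
        warnings.warn(f"dropping {len(dropped)} all-zero allele column(s): {dropped[:5]}")
        presence = presence[:, ~empty]
        allele_ids = [a for a, e in zip(allele_ids, empty) if not e]
    if mhc_class is not None:
        mhc_class = MhcClass(mhc_class)
    return BinaryGenotypeMatrix(individual_ids, allele_ids, presence, mhc_class)


def write_genotype_matrix(matrix: BinaryGenotypeMatrix, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(matrix.presence, index=matrix.individual_ids, columns=matrix.allele_ids)
    df.index.name = "individual_id"
    df.to_csv(path, sep=sep)


_META_COLUMNS = ["individual_id", "species", "locality_id", "position_km", "q_score", "category"]


def read_metadata(path: str | Path) -> list[IndividualRecord]:
    """Read the per-individual metadata TSV.

    Expected columns: individual_id, species, locality_id, position_km,
    q_score, category.  Empty position/Q cells become missing values; the
    optional boolean column ``q_inferred`` marks Q-scores assigned rather
    than estimated.
    """
    df = pd.read_csv(path, sep=_sniff_delimiter(Path(path)))
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata file missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            IndividualRecord(
                individual_id=str(row["individual_id"]),
                species=str(row["species"]),
                locality_id=str(row["locality_id"]),
                transect_position_km=None if pd.isna(row["position_km"]) else float(row["position_km"]),
                q_score=None if pd.isna(row["q_score"]) else float(row["q_score"]),
                zone_category=ZoneCategory(row["category"]) if not pd.isna(row["category"]) else ZoneCategory.UNASSIGNED,
                q_inferred=bool(row.get("q_inferred", False)),
            )
        )
    if len({r.individual_id for r in records}) != len(records):
        raise ValueError("duplicate individual_id in metadata")
    return records


def write_metadata(records: Sequence[IndividualRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in records],
            "species": [r.species for r in records],
            "locality_id": [r.locality_id for r in records],
            "position_km": [r.transect_position_km for r in records],
            "q_score": [r.q_score for r in records],
            "category": [r.zone_category.value for r in records],
            "q_inferred": [r.q_inferred for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filters


def filter_nonadmixed(individuals: Sequence[IndividualRecord], cfg: ZoneConfig) -> list[IndividualRecord]:
    """Keep nonadmixed individuals from essentially pure localities.

    The Q-score is the genome-wide ancestry proportion from one reference
    species, so an individual's admixture is its distance from its own pure
    end: min(q, 1 - q).  An individual is admixed when that value is
    strictly greater than ``cfg.admixed_threshold``; a locality qualifies
    when the mean admixture of its individuals is strictly below
    ``cfg.pure_locality_threshold``.  Individuals flagged ``q_inferred``
    carry their assigned Q (0 or 1).  The result is a subset of the input
    and the filter is idempotent.
    """
    with_q = [r for r in individuals if r.q_score is not None]
    if not with_q:
        raise ValueError("no individuals with Q-scores (or inferred Q) to filter")

    def admix(r: IndividualRecord) -> float:
        return min(r.q_score, 1.0 - r.q_score)

    loc_mean: dict[str, float] = {}
    for loc in {r.locality_id for r in with_q}:
        qs = [admix(r) for r in with_q if r.locality_id == loc]
        loc_mean[loc] = float(np.mean(qs))
    kept = [
        r
        for r in with_q
        if admix(r) <= cfg.admixed_threshold and loc_mean[r.locality_id] < cfg.pure_locality_threshold
    ]
    if not kept:
        raise ValueError(
            "all individuals filtered out as admixed or from admixed localities; "
            "review admixed_threshold / pure_locality_threshold"
        )
    return kept


# ---------------------------------------------------------------------------
# Diversity summaries


def rarefied_richness(presence: np.ndarray, n_sub: int) -> float:
    """Expected number of distinct alleles in a random subsample of ``n_sub``
    individuals, by the hypergeometric expectation over allele columns.

    For an allele observed in ``m`` of ``n`` individuals the probability of
    appearing in a subsample of size ``n_sub`` is ``1 - C(n-m, n_sub)/C(n, n_sub)``;
    summing over alleles gives the expectation, identical to averaging
    richness over all C(n, n_sub) subsets.
    """
    presence = np.asarray(presence)
    n = presence.shape[0]
    if not (1 <= n_sub <= n):
        raise ValueError(f"subsample size {n_sub} outside [1, {n}]")
    m = presence.sum(axis=0)
    # P(allele missing from subsample) = hypergeom pmf of drawing 0 carriers
    p_missing = hypergeom.pmf(0, n, m, n_sub)
    return float(np.sum(1.0 - p_missing))


def summarize_diversity(
    matrix: BinaryGenotypeMatrix, species_of: dict[str, str]
) -> pd.DataFrame:
    """Per-species allele counts, mean alleles per individual, and allelic
    richness rarefied to the smallest per-species sample size."""
    groups: dict[str, list[str]] = {}
    for iid in matrix.individual_ids:
        if iid not in species_of:
            raise KeyError(f"individual {iid!r} has no species assignment")
        groups.setdefault(species_of[iid], []).append(iid)
    if not groups:
        raise ValueError("empty species partition")
    n_min = min(len(ids) for ids in groups.values())
    rows = []
    for sp, ids in sorted(groups.items()):
        sub = matrix.subset_individuals(ids, drop_empty_alleles=True)
        rows.append(
            {
                "species": sp,
                "n_individuals": sub.n_individuals,
                "n_alleles_total": sub.n_alleles,
                "alleles_per_individual": float(sub.presence.sum(axis=1).mean()),
                "rarefied_richness": rarefied_richness(sub.presence, n_min),
                "rarefaction_n": n_min,
            }
        )
    return pd.DataFrame(rows)
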