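"""Shared data model and TSV input/output.

All tables are plain tab-separated text, UTF-8, with ``#`` comment lines
ignored. Genotypes are unphased allele pairs of small positive integers;
the token ``ND`` ("not determined") marks a missing call. Physical
coordinates are 1-based megabase-pair (Mbp) positions on a linkage group,
with closed intervals throughout.
"""
from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GenotypeParseError, InvalidConfigError, ReferenceError_

#: sentinel allele value for a missing call; printed as "ND"
MISSING = 0

SEX_LABELS = ("male", "female", "unknown")
ROLES = ("offspring", "sire", "dam", "candidate")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


# ---------------------------------------------------------------------------
# MarkerMap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerMap:
    """Ordered physical map of markers: id, linkage group, position (Mbp)."""

    df: pd.DataFrame  # columns: marker_id, linkage_group, position_mbp

    def __post_init__(self):
        df = self.df
        required = {"marker_id", "linkage_group", "position_mbp"}
        if not required.issubset(df.columns):
            raise GenotypeParseError(
                f"marker map needs columns {sorted(required)}, got {list(df.columns)}")
        if df["marker_id"].duplicated().any():
            dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise InvalidConfigError(f"duplicate marker_id {dup!r} in marker map")
        if (df["position_mbp"].astype(float) < 0).any():
            raise InvalidConfigError("marker positions must be non-negative")
        for lg, sub in df.groupby("linkage_group", sort=False):
            pos = sub["position_mbp"].astype(float).to_numpy()
            order = np.argsort(pos, kind="stable")
            if not np.all(np.diff(pos[order]) > 0):
                raise InvalidConfigError(
                    f"marker positions on {lg} are not strictly ordered")

    @property
    def marker_ids(self) -> list[str]:
        return list(self.df["marker_id"])

    def position(self, marker_id: str) -> float:
        sub = self.df.loc[self.df["marker_id"] == marker_id, "position_mbp"]
        if sub.empty:
            raise ReferenceError_(f"marker {marker_id!r} absent from map")
        return float(sub.iloc[0])

    def linkage_group(self, marker_id: str) -> str:
        sub = self.df.loc[self.df["marker_id"] == marker_id, "linkage_group"]
        if sub.empty:
            raise ReferenceError_(f"marker {marker_id!r} absent from map")
        return str(sub.iloc[0])

    def ordered(self) -> "MarkerMap":
        """Map sorted by (linkage group appearance order, position)."""
        df = self.df.copy()
        df["position_mbp"] = df["position_mbp"].astype(float)
        lg_order = {lg: i for i, lg in enumerate(df["linkage_group"].unique())}
        df = df.sort_values(
            by=["linkage_group", "position_mbp"],
            key=lambda s: s.map(lg_order) if s.name == "linkage_group" else s,
            kind="stable",
        ).reset_index(drop=True)
        return MarkerMap(df)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, float]]) -> "MarkerMap":
        df = pd.DataFrame(records, columns=["marker_id", "linkage_group", "position_mbp"])
        df["position_mbp"] = df["position_mbp"].astype(float)
        return cls(df)

    @classmethod
    def read(cls, path) -> "MarkerMap":
        df = _read_tsv(path)
        df["position_mbp"] = pd.to_numeric(df["position_mbp"], errors="raise")
        return cls(df)

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GenotypeTable
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Individual:
    id: str
    family: str = "F1"
    sex: str = "unknown"  # male / female / unknown
    role: str = "offspring"  # offspring / sire / dam / candidate


def format_call(call: tuple[int, int]) -> str:
    """Format an unphased allele pair: ``ND`` when missing, the compact
    two-digit convention (``11``, ``12``, ``22``) when both alleles are
    single digits, otherwise ``a/b``."""
    a, b = call
    if a == MISSING or b == MISSING:
        return "ND"
    a, b = sorted((int(a), int(b)))
    if a <= 9 and b <= 9:
        return f"{a}{b}"
    return f"{a}/{b}"


def parse_call(token: str) -> tuple[int, int]:
    token = token.strip()
    if token in ("ND", "", "NA"):
        return (MISSING, MISSING)
    try:
        if "/" in token:
            a_s, b_s = token.split("/")
            a, b = int(a_s), int(b_s)
        elif len(token) == 2 and token.isdigit():
            a, b = int(token[0]), int(token[1])
        else:
            raise ValueError
    except ValueError:
        raise GenotypeParseError(f"malformed genotype token {token!r}") from None
    if a <= 0 or b <= 0:
        raise GenotypeParseError(f"allele values must be positive in {token!r}")
    return (min(a, b), max(a, b))


@dataclass(frozen=True)
class GenotypeTable:
    """Individuals x ordered markers with unphased integer allele pairs.

    ``calls`` has shape (n_individuals, n_markers, 2); a missing call is
    ``(0, 0)``. Marker order follows the associated :class:`MarkerMap`
    when one is attached.
    """

    individuals: tuple[Individual, ...]
    markers: tuple[str, ...]
    calls: np.ndarray
    marker_map: MarkerMap | None = None

    def __post_init__(self):
        calls = np.asarray(self.calls, dtype=np.int32)
        object.__setattr__(self, "calls", calls)
        if calls.shape != (len(self.individuals), len(self.markers), 2):
            raise InvalidConfigError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers")
        if calls.size and calls.min() < 0:
            raise InvalidConfigError("allele values must be >= 0 (0 = missing)")
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise InvalidConfigError(f"duplicate individual id {dup!r}")

    # -- accessors ----------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def individual_ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def index_of(self, individual_id: str) -> int:
        for i, ind in enumerate(self.individuals):
            if ind.id == individual_id:
                return i
        raise ReferenceError_(f"individual {individual_id!r} not in table")

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.markers.index(marker_id)
        except ValueError:
            raise ReferenceError_(f"marker {marker_id!r} not in table") from None

    def call(self, individual_id: str, marker_id: str) -> tuple[int, int]:
        c = self.calls[self.index_of(individual_id), self.marker_index(marker_id)]
        return (int(c[0]), int(c[1]))

    def is_missing(self, i: int, j: int) -> bool:
        return MISSING in self.calls[i, j]

    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.family, None)
        return list(seen)

    def subset_family(self, family: str) -> "GenotypeTable":
        keep = [i for i, ind in enumerate(self.individuals) if ind.family == family]
        return GenotypeTable(
            tuple(self.individuals[i] for i in keep),
            self.markers, self.calls[keep], self.marker_map)

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeTable":
        keep = [self.index_of(i) for i in ids]
        return GenotypeTable(
            tuple(self.individuals[i] for i in keep),
            self.markers, self.calls[keep], self.marker_map)

    # -- IO -----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, ind in enumerate(self.individuals):
            row = {"individual": ind.id, "family": ind.family,
                   "sex": ind.sex, "role": ind.role}
            for j, m in enumerate(self.markers):
                row[m] = format_call(tuple(self.calls[i, j]))
            rows.append(row)
        cols = ["individual", "family", "sex", "role", *self.markers]
        return pd.DataFrame(rows, columns=cols)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_genotypes(path, marker_map: MarkerMap) -> GenotypeTable:
    """Read a genotype TSV and order its markers by the map.

    The header row holds marker ids after the ``individual``, ``family``,
    ``sex`` (and optional ``role``) columns. Marker ids absent from the
    map are rejected; ``ND`` parses as missing.
    """
    df = _read_tsv(path)
    meta_cols = [c for c in ("individual", "family", "sex", "role") if c in df.columns]
    if "individual" not in meta_cols:
        raise GenotypeParseError("genotype file needs an 'individual' column")
    marker_cols = [c for c in df.columns if c not in meta_cols]
    known = set(marker_map.marker_ids)
    for m in marker_cols:
        if m not in known:
            raise ReferenceError_(f"marker {m!r} absent from marker map")
    # order markers as in the (lg, position)-ordered map
    ordered_ids = [m for m in marker_map.ordered().marker_ids if m in marker_cols]

    individuals = []
    calls = np.zeros((len(df), len(ordered_ids), 2), dtype=np.int32)
    for i, (_, row) in enumerate(df.iterrows()):
        individuals.append(Individual(
            id=str(row["individual"]),
            family=str(row.get("family", "F1") or "F1"),
            sex=str(row.get("sex", "unknown") or "unknown"),
            role=str(row.get("role", "offspring") or "offspring"),
        ))
        for j, m in enumerate(ordered_ids):
            try:
                calls[i, j] = parse_call(str(row[m]))
            except GenotypeParseError as exc:
                raise GenotypeParseError(
                    f"{exc} (individual {row['individual']!r}, marker {m!r})"
                ) from None
    return GenotypeTable(tuple(individuals), tuple(ordered_ids), calls, marker_map)


# ---------------------------------------------------------------------------
# OrthologyMap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrthologyMap:
    """Gene -> (linkage group, position) placements on the orthologous
    physical reference, with per-LG gene totals Gi and the global total Gt."""

    df: pd.DataFrame  # columns: gene_id, linkage_group, position_mbp

    def __post_init__(self):
        df = self.df
        required = {"gene_id", "linkage_group", "position_mbp"}
        if not required.issubset(df.columns):
            raise GenotypeParseError(
                f"orthology map needs columns {sorted(required)}")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise InvalidConfigError(
                f"gene {dup!r} appears more than once in the orthology map")

    @property
    def gene_total(self) -> int:
        """Gt: total number of genes across all linkage groups."""
        return len(self.df)

    @property
    def lg_gene_counts(self) -> pd.Series:
        """Gi per linkage group; sums to Gt."""
        return self.df.groupby("linkage_group", sort=False).size()

    def linkage_group_of(self, gene_id: str) -> str | None:
        sub = self.df.loc[self.df["gene_id"] == gene_id, "linkage_group"]
        return None if sub.empty else str(sub.iloc[0])

    def genes_in(self, lg: str, start: float | None = None,
                 end: float | None = None) -> list[str]:
        sub = self.df[self.df["linkage_group"] == lg]
        if start is not None:
            pos = sub["position_mbp"].astype(float)
            sub = sub[(pos >= start) & (pos <= end)]
        return list(sub["gene_id"])

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, float]]) -> "OrthologyMap":
        df = pd.DataFrame(records, columns=["gene_id", "linkage_group", "position_mbp"])
        df["position_mbp"] = df["position_mbp"].astype(float)
        return cls(df)

    @classmethod
    def read(cls, path) -> "OrthologyMap":
        df = _read_tsv(path)
        df["position_mbp"] = pd.to_numeric(df["position_mbp"], errors="raise")
        return cls(df)

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def read_orthology(path) -> OrthologyMap:
    return OrthologyMap.read(path)


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray  # shape (n_genes, n_samples), int64

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.dtype.kind == "f":
            if not np.all(np.isfinite(counts)) or np.any(counts % 1 != 0):
                raise GenotypeParseError("counts must be integers")
        counts = counts.astype(np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise InvalidConfigError("count matrix shape mismatch")
        if counts.size and counts.min() < 0:
            raise GenotypeParseError("negative count encountered")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InvalidConfigError("duplicate gene id in count matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InvalidConfigError("duplicate sample id in count matrix")

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-sample total counts (column sums)."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.gene_ids),
                            columns=list(self.sample_ids))

    def write(self, path) -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "CountMatrix":
        df = _read_tsv(path)
        if df.shape[1] < 2:
            raise GenotypeParseError("count matrix needs gene ids plus >=1 sample")
        gene_col = df.columns[0]
        genes = tuple(df[gene_col])
        samples = tuple(df.columns[1:])
        try:
            values = df[list(samples)].apply(pd.to_numeric, errors="raise").to_numpy()
        except (ValueError, TypeError) as exc:
            raise GenotypeParseError(f"non-numeric count token: {exc}") from None
        if np.any(values % 1 != 0):
            bad = np.argwhere(values % 1 != 0)[0]
            raise GenotypeParseError(
                f"non-integer count {values[tuple(bad)]} at gene "
                f"{genes[bad[0]]!r}, sample {samples[bad[1]]!r}")
        return cls(genes, samples, values)


def read_counts(path) -> CountMatrix:
    return CountMatrix.read(path)


# ---------------------------------------------------------------------------
# validation entry point (used by the CLI `validate` subcommand)
# ---------------------------------------------------------------------------

def validate_file(path, kind: str, marker_map: MarkerMap | None = None) -> str:
    """Check a file against its schema; return a one-line report or raise."""
    path = Path(path)
    if kind == "markers":
        m = MarkerMap.read(path)
        return f"{path.name}: marker map OK ({len(m.df)} markers, " \
               f"{m.df['linkage_group'].nunique()} linkage groups)"
    if kind == "genotypes":
        if marker_map is None:
            raise InvalidConfigError("genotype validation needs a marker map")
        t = read_genotypes(path, marker_map)
        n_missing = int(np.sum(t.calls[:, :, 0] == MISSING))
        return f"{path.name}: genotypes OK ({t.n_individuals} individuals, " \
               f"{len(t.markers)} markers, {n_missing} missing calls)"
    if kind == "orthology":
        o = OrthologyMap.read(path)
        return f"{path.name}: orthology OK (Gt={o.gene_total}, " \
               f"{len(o.lg_gene_counts)} linkage groups)"
    if kind == "counts":
        c = CountMatrix.read(path)
        return f"{path.name}: counts OK ({len(c.gene_ids)} genes x " \
               f"{len(c.sample_ids)} samples)"
    raise InvalidConfigError(f"unknown file kind {kind!r}")
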