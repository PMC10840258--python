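"""Reading, writing and filtering of OTU count tables.

An OTU table is the microbiome analogue of a document-term matrix: rows are
biological samples ("documents"), columns are OTUs ("terms"), and each cell
holds a read count.  This module owns the table container, the per-sample
metadata contract, and the standard pre-processing steps used throughout the
package: rarefaction to a common depth, subject-level contamination exclusion,
first-visit filtering, taxonomic aggregation, sample intersection between
niches, and the arcsinh variance-stabilizing transform.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "OtuTable",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "rarefy",
    "filter_contamination",
    "first_visit",
    "arcsinh_transform",
    "parse_lineage",
    "taxon_labels",
    "aggregate_taxa",
    "intersect_samples",
]

#: Taxonomic ranks in lineage order, with their greengenes-style prefixes.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_PREFIXES = {"k": "kingdom", "p": "phylum", "c": "class", "o": "order",
             "f": "family", "g": "genus", "s": "species"}
_RANK_TO_PREFIX = {v: k for k, v in _PREFIXES.items()}

#: Required metadata columns.  ``visit`` is optional.
METADATA_COLUMNS = ("sample_id", "subject_id", "niche")


@dataclass
class OtuTable:
    """Samples x OTUs integer count matrix with optional taxonomy.

    Parameters
    ----------
    counts
        Non-negative integer matrix, shape ``(S, V)``.
    sample_ids, otu_ids
        Unique row / column identifiers.
    taxonomy
        Optional per-OTU lineage strings, semicolon-separated and
        rank-prefixed (``k__Bacteria;p__Firmicutes;...;g__Streptococcus``).
        Partial lineages are allowed.
    """

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    taxonomy: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        S, V = self.counts.shape
        if len(self.sample_ids) != S:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {S} rows")
        if len(self.otu_ids) != V:
            raise ValueError(f"{len(self.otu_ids)} OTU ids for {V} columns")
        for name, ids in (("sample", self.sample_ids), ("OTU", self.otu_ids)):
            dup = _duplicates(ids)
            if dup:
                raise ValueError(f"duplicate {name} ids: {sorted(dup)[:5]}")
        if self.taxonomy is not None and len(self.taxonomy) != V:
            raise ValueError("taxonomy length must match number of OTUs")

    # -- convenience ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> np.ndarray:
        """Per-sample read totals."""
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        depths = self.depths().astype(float)
        if np.any(depths == 0):
            raise ValueError("cannot compute relative abundance of empty samples")
        return self.counts / depths[:, None]

    def select_samples(self, index: Sequence[int] | np.ndarray) -> "OtuTable":
        index = np.asarray(index)
        return replace(
            self,
            counts=self.counts[index],
            sample_ids=[self.sample_ids[i] for i in index],
            otu_ids=list(self.otu_ids),
            taxonomy=None if self.taxonomy is None else list(self.taxonomy),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)


def _duplicates(ids: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for i in ids:
        (dup if i in seen else seen).add(i)
    return dup


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _looks_like_lineage(name: str) -> bool:
    return "__" in name and ";" in name


def read_count_table(
    path: str | Path,
    rows_are_samples: bool = True,
    taxonomy_path: str | Path | None = None,
) -> OtuTable:
    """Read a tab-separated count table.

    The file must have one header row and one ID column; cells are
    non-negative integers.  If OTU identifiers themselves are
    rank-prefixed lineages (``k__...;g__...``) they double as taxonomy.
    A companion two-column TSV (``otu_id<TAB>lineage``) may be supplied
    via ``taxonomy_path``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if not rows_are_samples:
        df = df.T
    values = np.empty(df.shape, dtype=np.int64)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            try:
                v = int(cell)
                if v < 0:
                    raise ValueError
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-integer or negative count {cell!r} at row "
                    f"{df.index[i]!r}, column {df.columns[j]!r} in {path}"
                ) from None
            values[i, j] = v
    otu_ids = [str(c) for c in df.columns]
    taxonomy: list[str] | None = None
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t", index_col=0, header=None,
                          names=["otu_id", "lineage"], dtype=str)
        taxonomy = [str(tax["lineage"].get(o, "")) or None for o in otu_ids]  # type: ignore[misc]
        taxonomy = [t if t and t != "None" else "" for t in taxonomy]
    elif all(_looks_like_lineage(o) for o in otu_ids):
        taxonomy = list(otu_ids)
    return OtuTable(values, [str(s) for s in df.index], otu_ids, taxonomy)


def write_count_table(table: OtuTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (columns: sample_id, subject_id, niche[, visit])."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str,
                                              "niche": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    dup = _duplicates(meta["sample_id"])
    if dup:
        raise ValueError(f"duplicate sample ids in metadata: {sorted(dup)[:5]}")
    return meta


def align_metadata(table: OtuTable, meta: pd.DataFrame) -> pd.DataFrame:
    """Return metadata rows in the table's sample order; error on gaps."""
    meta = meta.set_index("sample_id", drop=False)
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing[:5]}")
    return meta.loc[table.sample_ids].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Filters and transforms
# ---------------------------------------------------------------------------

def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each retained sample's reads are drawn as a multivariate hypergeometric
    draw from its observed counts.  Samples with fewer than ``depth`` reads
    are dropped, as are OTU columns left with zero total count.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.depths()
    keep = totals >= depth
    if not np.any(keep):
        raise ValueError("empty table: all samples below rarefaction depth")
    rows = []
    for i in np.flatnonzero(keep):
        row = table.counts[i]
        if totals[i] == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    counts = np.asarray(rows, dtype=np.int64)
    sample_ids = [table.sample_ids[i] for i in np.flatnonzero(keep)]
    col_keep = counts.sum(axis=0) > 0
    return OtuTable(
        counts[:, col_keep],
        sample_ids,
        [o for o, k in zip(table.otu_ids, col_keep) if k],
        None if table.taxonomy is None
        else [t for t, k in zip(table.taxonomy, col_keep) if k],
    )


def parse_lineage(lineage: str | None) -> dict[str, str]:
    """Parse ``k__Bacteria;p__...`` into a rank -> name mapping.

    Empty fields (``g__``) and unknown prefixes are ignored.
    """
    out: dict[str, str] = {}
    if not lineage:
        return out
    for part in str(lineage).split(";"):
        part = part.strip()
        if "__" in part:
            prefix, _, name = part.partition("__")
            rank = _PREFIXES.get(prefix.strip().lower())
            if rank and name:
                out[rank] = name.strip()
        elif part:
            # unprefixed component: assign by position only if unambiguous
            continue
    return out


def taxon_labels(
    otu_ids: Sequence[str],
    taxonomy: Sequence[str] | None,
    rank: str | None = None,
) -> list[str]:
    """Per-OTU display label.

    With ``rank`` given, the name at that rank; OTUs not classified that far
    keep their lowest available (higher-level) name, prefixed with its rank.
    With ``rank=None`` the lowest available rank is used.  OTUs with no
    taxonomy fall back to their own id.
    """
    if rank is not None and rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = []
    for i, otu in enumerate(otu_ids):
        lineage = parse_lineage(taxonomy[i]) if taxonomy is not None else {}
        if not lineage:
            labels.append(str(otu))
            continue
        if rank is not None and rank in lineage:
            labels.append(lineage[rank])
            continue
        # lowest available rank at or above the requested one
        limit = RANKS.index(rank) if rank is not None else len(RANKS) - 1
        chosen = None
        for r in RANKS[: limit + 1]:
            if r in lineage:
                chosen = r
        if chosen is None:
            labels.append(str(otu))
        else:
            labels.append(f"{_RANK_TO_PREFIX[chosen]}__{lineage[chosen]}")
    return labels


def filter_contamination(
    table: OtuTable,
    meta: pd.DataFrame,
    taxon: str,
    threshold: float,
    oral_niches: Sequence[str],
) -> tuple[OtuTable, list[str]]:
    """Subject-level exclusion of likely contaminated individuals.

    A subject is excluded (all of their samples removed) when, in at least
    one of their samples from an oral niche, the relative abundance of
    ``taxon`` is strictly greater than ``threshold``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    meta = align_metadata(table, meta)
    cols = _taxon_columns(table, taxon)
    rel = table.relative_abundance()[:, cols].sum(axis=1)
    oral = meta["niche"].isin(list(oral_niches)).to_numpy()
    flagged = (rel > threshold) & oral
    excluded = sorted(set(meta.loc[flagged, "subject_id"]))
    keep = ~meta["subject_id"].isin(excluded).to_numpy()
    return table.select_samples(np.flatnonzero(keep)), excluded


def _taxon_columns(table: OtuTable, taxon: str) -> np.ndarray:
    if table.taxonomy is None:
        raise ValueError("table has no taxonomy; cannot resolve taxon names")
    target = taxon.lower()
    hits = []
    for j, lineage in enumerate(table.taxonomy):
        names = {v.lower() for v in parse_lineage(lineage).values()}
        if target in names:
            hits.append(j)
    if not hits:
        raise ValueError(f"taxon {taxon!r} not found at any rank")
    return np.asarray(hits)


def first_visit(table: OtuTable, meta: pd.DataFrame) -> OtuTable:
    """Keep only each subject's earliest-visit samples."""
    meta = align_metadata(table, meta)
    if "visit" not in meta.columns:
        raise ValueError("metadata has no 'visit' column")
    visits = pd.to_numeric(meta["visit"], errors="coerce")
    if visits.isna().any():
        bad = meta.loc[visits.isna(), "sample_id"].tolist()
        raise ValueError(f"missing visit values for samples: {bad[:10]}")
    first = visits.groupby(meta["subject_id"]).transform("min")
    keep = (visits == first).to_numpy()
    return table.select_samples(np.flatnonzero(keep))


def arcsinh_transform(matrix: np.ndarray) -> np.ndarray:
    """Entrywise inverse hyperbolic sine, ln(x + sqrt(x^2 + 1)).

    Behaves like log(2x) for large counts while remaining defined (and
    smooth) at zero, which makes it the standard variance-stabilizing
    choice for count covariates.
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix must be finite")
    return np.arcsinh(matrix)


def aggregate_taxa(table: OtuTable, rank: str) -> OtuTable:
    """Sum OTU columns sharing a name at ``rank``.

    OTUs not classified to ``rank`` are grouped under their lowest
    available higher-level name; per-sample totals are conserved.
    """
    labels = taxon_labels(table.otu_ids, table.taxonomy, rank=rank)
    frame = table.to_frame()
    frame.columns = labels
    agg = frame.T.groupby(level=0, sort=True).sum().T
    return OtuTable(
        agg.to_numpy(dtype=np.int64),
        list(table.sample_ids),
        [str(c) for c in agg.columns],
        None,
    )


def intersect_samples(
    a: OtuTable,
    meta_a: pd.DataFrame,
    b: OtuTable,
    meta_b: pd.DataFrame,
) -> tuple[OtuTable, OtuTable, list[str]]:
    """Restrict two niche tables to subjects present in both.

    Returns ``(a', b', subjects)`` with rows of both tables in the same
    (sorted) subject order; the shared subject list is returned so callers
    can align further metadata.  When a subject has several samples in a
    niche, the first in table order is used.
    """
    meta_a = align_metadata(a, meta_a)
    meta_b = align_metadata(b, meta_b)
    subj_a = meta_a["subject_id"].tolist()
    subj_b = meta_b["subject_id"].tolist()
    common = sorted(set(subj_a) & set(subj_b))
    if not common:
        raise ValueError("no subjects present in both niches")
    idx_a = [subj_a.index(s) for s in common]
    idx_b = [subj_b.index(s) for s in common]
    return a.select_samples(idx_a), b.select_samples(idx_b), common
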