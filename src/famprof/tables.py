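"""OTU-table data model and readers/writers.

The central object is :class:`OtuTable`: an integer count matrix
(OTU x sample) with per-OTU taxonomic assignments and a marker tag
(16S V3V4, rpoB, ...).  Tables are serialized as TSV with an optional
trailing ``taxonomy`` column whose cells use a fixed dialect::

    d__Bacteria(1.00);p__Proteobacteria(0.99);...;g__Pseudomonas(0.97);s__unassigned

Confidences are optional on read (``g__Pseudomonas`` parses with
confidence 1.0, Silva-style), so existing ``k__;p__;...`` lineage strings
load without modification.  A minimal sparse BIOM-1.0-style JSON
reader/writer is provided for interoperability.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RANKS: tuple[str, ...] = (
    "domain", "phylum", "class", "order", "family", "genus", "species",
)
RANK_PREFIXES: dict[str, str] = dict(zip(RANKS, "dpcofgs"))
_PREFIX_TO_RANK = {v: k for k, v in RANK_PREFIXES.items()}
# Silva/QIIME lineage strings use k__ for the top rank.
_PREFIX_TO_RANK["k"] = "domain"

UNASSIGNED = "unassigned"

MARKERS = ("V3V4", "rpoB", "other")


class OtuTableError(ValueError):
    """Raised for malformed tables or table files."""


@dataclass
class TaxonAssignment:
    """Per-OTU taxonomy: a label and a confidence in [0, 1] per rank.

    Ranks below the first unassigned rank must themselves be unassigned
    (a lineage cannot resume after a gap).
    """

    ranks: dict[str, str] = field(default_factory=dict)
    confidence: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ranks = {r: self.ranks.get(r, UNASSIGNED) or UNASSIGNED for r in RANKS}
        conf = {}
        for r in RANKS:
            c = float(self.confidence.get(r, 1.0))
            if not 0.0 <= c <= 1.0:
                raise OtuTableError(f"confidence for rank {r!r} not in [0,1]: {c}")
            conf[r] = c
        seen_gap = False
        for r in RANKS:
            if ranks[r] == UNASSIGNED:
                seen_gap = True
            elif seen_gap:
                raise OtuTableError(
                    f"rank {r!r} assigned below an unassigned rank: {ranks}"
                )
        self.ranks = ranks
        self.confidence = conf

    # -- queries ---------------------------------------------------------
    def label_at(self, rank: str) -> str:
        _check_rank(rank)
        return self.ranks[rank]

    def is_assigned(self, rank: str, min_confidence: float = 0.0) -> bool:
        _check_rank(rank)
        return (
            self.ranks[rank] != UNASSIGNED
            and self.confidence[rank] >= min_confidence
        )

    def lowest_assigned(self, min_confidence: float = 0.0) -> tuple[str, str] | None:
        """(rank, label) of the deepest rank assigned at the confidence, or None."""
        for rank in reversed(RANKS):
            if self.is_assigned(rank, min_confidence):
                return rank, self.ranks[rank]
        return None

    # -- serialization ---------------------------------------------------
    def to_string(self) -> str:
        parts = []
        for rank in RANKS:
            label = self.ranks[rank]
            if label == UNASSIGNED:
                parts.append(f"{RANK_PREFIXES[rank]}__{UNASSIGNED}")
            else:
                parts.append(
                    f"{RANK_PREFIXES[rank]}__{label}({self.confidence[rank]:.4f})"
                )
        return ";".join(parts)

    @classmethod
    def from_string(cls, text: str) -> "TaxonAssignment":
        """Parse the canonical dialect or permissive Silva-style strings."""
        ranks: dict[str, str] = {}
        conf: dict[str, float] = {}
        tokens = [t.strip() for t in text.strip().strip(";").split(";") if t.strip()]
        for pos, token in enumerate(tokens):
            if "__" in token:
                prefix, rest = token.split("__", 1)
                rank = _PREFIX_TO_RANK.get(prefix.strip().lower())
                if rank is None:
                    raise OtuTableError(f"unknown rank prefix in token {token!r}")
            else:  # bare labels: positional
                if pos >= len(RANKS):
                    raise OtuTableError(f"too many taxonomy tokens in {text!r}")
                rank, rest = RANKS[pos], token
            rest = rest.strip()
            if rest.endswith(")") and "(" in rest:
                label, conf_str = rest[:-1].rsplit("(", 1)
                try:
                    c = float(conf_str)
                except ValueError as exc:
                    raise OtuTableError(
                        f"bad confidence {conf_str!r} in token {token!r}"
                    ) from exc
            else:
                label, c = rest, 1.0
            label = label.strip()
            if label and label.lower() != UNASSIGNED:
                ranks[rank] = label
                conf[rank] = c
        return cls(ranks=ranks, confidence=conf)

    @classmethod
    def unassigned(cls) -> "TaxonAssignment":
        return cls()


def _check_rank(rank: str) -> None:
    if rank not in RANKS:
        raise OtuTableError(f"unknown rank {rank!r}; expected one of {RANKS}")


@dataclass
class SampleMeta:
    """Metadata for one sequencing sample (technical replicate)."""

    sample_id: str
    sample_class: str = "IJ"          # IJ | insect | control
    host_species: str = ""
    strain: str = ""
    batch: str = ""
    laboratory: str = ""
    marker: str = "other"
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.sample_class not in ("IJ", "insect", "control"):
            raise OtuTableError(
                f"sample_class must be IJ/insect/control, got {self.sample_class!r}"
            )
        if self.sample_class == "control" and (
            self.host_species or self.strain
        ):
            raise OtuTableError(
                f"control sample {self.sample_id!r} must have empty host fields"
            )


@dataclass
class OtuTable:
    """Integer OTU x sample count matrix with taxonomy and a marker tag."""

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, TaxonAssignment] = field(default_factory=dict)
    marker: str = "other"

    def __post_init__(self) -> None:
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise OtuTableError("counts must be integers (fractional cell found)")
        counts = counts.astype(np.int64, copy=False).reshape(
            len(self.otu_ids), len(self.sample_ids)
        )
        if counts.size and counts.min() < 0:
            i, j = np.argwhere(counts < 0)[0]
            raise OtuTableError(
                f"negative count at OTU {self.otu_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise OtuTableError("duplicate OTU ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise OtuTableError("duplicate sample ids")
        self.counts = counts
        # every OTU gets a taxonomy entry, defaulting to all-unassigned
        self.taxonomy = {
            o: self.taxonomy.get(o, TaxonAssignment.unassigned())
            for o in self.otu_ids
        }

    # -- basic views -----------------------------------------------------
    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def grand_total(self) -> int:
        return int(self.counts.sum())

    def sample_totals(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=0), index=self.sample_ids)

    def otu_totals(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=1), index=self.otu_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def copy(self) -> "OtuTable":
        return OtuTable(
            otu_ids=list(self.otu_ids),
            sample_ids=list(self.sample_ids),
            counts=self.counts.copy(),
            taxonomy={o: replace(t) for o, t in self.taxonomy.items()},
            marker=self.marker,
        )

    # -- subsetting ------------------------------------------------------
    def select_otus(self, keep: Iterable[str]) -> "OtuTable":
        keep = set(keep)
        unknown = keep - set(self.otu_ids)
        if unknown:
            raise OtuTableError(f"unknown OTU ids: {sorted(unknown)}")
        idx = [i for i, o in enumerate(self.otu_ids) if o in keep]
        ids = [self.otu_ids[i] for i in idx]
        return OtuTable(
            otu_ids=ids,
            sample_ids=list(self.sample_ids),
            counts=self.counts[idx, :],
            taxonomy={o: self.taxonomy[o] for o in ids},
            marker=self.marker,
        )

    def select_samples(self, keep: Sequence[str]) -> "OtuTable":
        unknown = set(keep) - set(self.sample_ids)
        if unknown:
            raise OtuTableError(f"unknown sample ids: {sorted(unknown)}")
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in keep]
        return OtuTable(
            otu_ids=list(self.otu_ids),
            sample_ids=list(keep),
            counts=self.counts[:, idx],
            taxonomy=dict(self.taxonomy),
            marker=self.marker,
        )


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample proportions (columns sum to 1).

    Raises on any sample with zero total reads, naming the sample.
    """
    totals = table.counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise OtuTableError(
            f"sample {table.sample_ids[zero[0]]!r} has zero total count; "
            "cannot compute relative abundance"
        )
    props = table.counts / totals[np.newaxis, :]
    return pd.DataFrame(props, index=table.otu_ids, columns=table.sample_ids)


def aggregate_by_rank(
    table: OtuTable, rank: str, min_confidence: float = 0.9
) -> OtuTable:
    """Sum counts of OTUs sharing a taxon label at ``rank``.

    OTUs unassigned at the rank, or assigned with confidence below
    ``min_confidence``, pool into a reserved ``unassigned`` row (kept last).
    Per-sample totals are conserved exactly (integer sums).
    """
    _check_rank(rank)
    groups: dict[str, list[int]] = {}
    rep_taxonomy: dict[str, TaxonAssignment] = {}
    for i, otu in enumerate(table.otu_ids):
        tax = table.taxonomy[otu]
        if tax.is_assigned(rank, min_confidence):
            label = tax.label_at(rank)
        else:
            label = UNASSIGNED
        groups.setdefault(label, []).append(i)
        if label not in rep_taxonomy and label != UNASSIGNED:
            rep_taxonomy[label] = _truncate_to_rank(tax, rank)

    labels = [lab for lab in groups if lab != UNASSIGNED]
    if UNASSIGNED in groups:
        labels.append(UNASSIGNED)
    counts = np.vstack(
        [table.counts[groups[lab], :].sum(axis=0) for lab in labels]
    ) if labels else np.zeros((0, table.n_samples), dtype=np.int64)
    taxonomy = {
        lab: rep_taxonomy.get(lab, TaxonAssignment.unassigned()) for lab in labels
    }
    return OtuTable(
        otu_ids=labels,
        sample_ids=list(table.sample_ids),
        counts=counts,
        taxonomy=taxonomy,
        marker=table.marker,
    )


def _truncate_to_rank(tax: TaxonAssignment, rank: str) -> TaxonAssignment:
    cut = RANKS.index(rank)
    ranks = {r: tax.ranks[r] for r in RANKS[: cut + 1]}
    conf = {r: tax.confidence[r] for r in RANKS[: cut + 1]}
    return TaxonAssignment(ranks=ranks, confidence=conf)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_otu_table(path: str | Path, marker: str = "other") -> OtuTable:
    """Read a TSV OTU table: first column OTU id, optional final ``taxonomy``
    column, all other columns integer counts per sample."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns.size < 1:
        raise OtuTableError(f"{path}: empty table file")
    otu_col = df.columns[0]
    has_tax = df.columns.size > 1 and df.columns[-1].lower() == "taxonomy"
    sample_cols = list(df.columns[1 : -1 if has_tax else None])
    otu_ids = df[otu_col].tolist()

    counts = np.zeros((len(otu_ids), len(sample_cols)), dtype=np.int64)
    for j, col in enumerate(sample_cols):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise OtuTableError(
                f"{path}: malformed numeric cell {df[col].iloc[i]!r} "
                f"at OTU {otu_ids[i]!r}, sample column {col!r}"
            )
        vals = numeric.to_numpy()
        if not np.all(np.mod(vals, 1) == 0):
            i = int(np.flatnonzero(np.mod(vals, 1) != 0)[0])
            raise OtuTableError(
                f"{path}: fractional count {vals[i]} at OTU {otu_ids[i]!r}, "
                f"sample column {col!r}"
            )
        if vals.size and vals.min() < 0:
            i = int(np.flatnonzero(vals < 0)[0])
            raise OtuTableError(
                f"{path}: negative count at OTU {otu_ids[i]!r}, column {col!r}"
            )
        counts[:, j] = vals.astype(np.int64)

    taxonomy = {}
    if has_tax:
        for otu, text in zip(otu_ids, df[df.columns[-1]]):
            taxonomy[otu] = TaxonAssignment.from_string(text) if text else (
                TaxonAssignment.unassigned()
            )
    return OtuTable(
        otu_ids=otu_ids,
        sample_ids=sample_cols,
        counts=counts,
        taxonomy=taxonomy,
        marker=marker,
    )


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write the TSV dialect accepted by :func:`read_otu_table`."""
    path = Path(path)
    with open(path, "w") as fh:
        header = ["otu_id", *table.sample_ids, "taxonomy"]
        fh.write("\t".join(header) + "\n")
        for i, otu in enumerate(table.otu_ids):
            row = [otu, *(str(int(c)) for c in table.counts[i, :])]
            row.append(table.taxonomy[otu].to_string())
            fh.write("\t".join(row) + "\n")


def read_sample_metadata(path: str | Path) -> dict[str, SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "sample_class"}
    missing = required - set(df.columns)
    if missing:
        raise OtuTableError(f"{path}: missing metadata columns {sorted(missing)}")
    metas: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in metas:
            raise OtuTableError(f"{path}: duplicate sample id {sid!r}")
        metas[sid] = SampleMeta(
            sample_id=sid,
            sample_class=row["sample_class"],
            host_species=row.get("host_species", ""),
            strain=row.get("strain", ""),
            batch=row.get("batch", ""),
            laboratory=row.get("laboratory", ""),
            marker=row.get("marker", "other"),
            replicate=int(row["replicate"]) if row.get("replicate", "") else 0,
        )
    return metas


def write_sample_metadata(metas: Mapping[str, SampleMeta], path: str | Path) -> None:
    cols = [
        "sample_id", "sample_class", "host_species", "strain",
        "batch", "laboratory", "marker", "replicate",
    ]
    rows = [
        [m.sample_id, m.sample_class, m.host_species, m.strain,
         m.batch, m.laboratory, m.marker, str(m.replicate)]
        for m in metas.values()
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# BIOM-1.0-compatible sparse JSON
# ---------------------------------------------------------------------------

def read_biom_json(path: str | Path, marker: str = "other") -> OtuTable:
    with open(path) as fh:
        doc = json.load(fh)
    rows = doc["rows"]
    cols = doc["columns"]
    n, m = doc["shape"]
    counts = np.zeros((n, m), dtype=np.int64)
    if doc.get("matrix_type", "sparse") == "sparse":
        for i, j, v in doc["data"]:
            counts[int(i), int(j)] = int(v)
    else:
        counts[:] = np.asarray(doc["data"], dtype=np.int64)
    taxonomy = {}
    otu_ids = []
    for r in rows:
        otu_ids.append(r["id"])
        meta = r.get("metadata") or {}
        tax = meta.get("taxonomy")
        if isinstance(tax, list):
            tax = ";".join(tax)
        if tax:
            taxonomy[r["id"]] = TaxonAssignment.from_string(tax)
    return OtuTable(
        otu_ids=otu_ids,
        sample_ids=[c["id"] for c in cols],
        counts=counts,
        taxonomy=taxonomy,
        marker=marker,
    )


def write_biom_json(table: OtuTable, path: str | Path) -> None:
    nz = np.argwhere(table.counts > 0)
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "famprof",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [table.n_otus, table.n_samples],
        "rows": [
            {"id": o, "metadata": {"taxonomy": table.taxonomy[o].to_string()}}
            for o in table.otu_ids
        ],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": [
            [int(i), int(j), int(table.counts[i, j])] for i, j in nz
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
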