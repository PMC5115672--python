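"""Community-matrix data model and delimited-text / GraphML input-output.

The central container is :class:`CommunityMatrix`: a dense non-negative
integer table of sequencing read counts (samples as rows, OTUs as columns)
optionally joined to per-sample metadata describing the sampling design
(depth class, horizontal position, replicate, negative-control status).
All on-disk formats are plain text: TSV/CSV for matrices and metadata,
TSV or GraphML for association-network edge lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CommunityMatrix",
    "SampleMeta",
    "OtuAnnotation",
    "read_community_table",
    "write_community_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_otu_annotations",
    "read_edge_table",
    "write_edge_table",
]

#: metadata columns every sample table must provide
REQUIRED_METADATA_COLUMNS = (
    "sample_id",
    "depth_class",
    "depth_value_cm",
    "horizontal_position_m",
    "replicate_id",
    "is_negative_control",
)


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample description of where and how a soil sample was taken.

    ``depth_value_cm`` is signed relative to the organic/mineral (O-A)
    horizon boundary: positive above the boundary (O horizon), negative
    below it (A horizon and deeper).  ``depth_class`` is the categorical
    label of the sampling depth; classes are ordered from shallowest to
    deepest by decreasing ``depth_value_cm``.
    """

    sample_id: str
    depth_class: str
    depth_value_cm: float
    horizontal_position_m: float
    replicate_id: int
    is_negative_control: bool = False
    extra: Mapping[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class OtuAnnotation:
    """Taxonomy / functional-guild annotation attached to an OTU id."""

    otu_id: str
    taxonomy: str = ""
    guild: str = "unassigned"

    def lowest_rank(self) -> str:
        """Last non-empty rank of a ``;``-separated lineage string."""
        parts = [p.strip() for p in self.taxonomy.split(";") if p.strip()]
        return parts[-1] if parts else "unidentified"


class CommunityMatrix:
    """Samples x OTUs read-count matrix with optional sample metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, index = sample ids,
        columns = OTU ids.
    samples
        Optional list of :class:`SampleMeta`, one per matrix row.  When
        present it must cover exactly the matrix's sample ids.
    """

    def __init__(self, counts: pd.DataFrame, samples: Sequence[SampleMeta] | None = None):
        self.counts = self._validate_counts(counts.copy())
        self.samples: list[SampleMeta] | None = None
        if samples is not None:
            self._attach(list(samples))

    @staticmethod
    def _validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU ids: {dups}")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                bad = np.argwhere(~np.isfinite(values) | (values != np.floor(values)))
                r, c = bad[0]
                raise ValueError(
                    f"non-integral count at sample {counts.index[r]!r}, OTU {counts.columns[c]!r}"
                )
            counts = counts.astype(np.int64)
            values = counts.to_numpy()
        if values.size and (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at sample {counts.index[r]!r}, OTU {counts.columns[c]!r}"
            )
        return counts

    def _attach(self, samples: list[SampleMeta]) -> None:
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in metadata")
        meta_ids = set(ids)
        matrix_ids = set(self.counts.index)
        missing = matrix_ids - meta_ids
        if missing:
            raise ValueError(f"samples in matrix missing from metadata: {sorted(missing)[:5]}")
        by_id = {s.sample_id: s for s in samples}
        self.samples = [by_id[sid] for sid in self.counts.index]

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def meta(self, sample_id: str) -> SampleMeta:
        if self.samples is None:
            raise ValueError("matrix carries no sample metadata")
        return self.samples[self.counts.index.get_loc(sample_id)]

    def metadata_frame(self) -> pd.DataFrame:
        """Sample metadata as a DataFrame aligned with the matrix rows."""
        if self.samples is None:
            raise ValueError("matrix carries no sample metadata")
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "depth_class": [s.depth_class for s in self.samples],
                "depth_value_cm": [s.depth_value_cm for s in self.samples],
                "horizontal_position_m": [s.horizontal_position_m for s in self.samples],
                "replicate_id": [s.replicate_id for s in self.samples],
                "is_negative_control": [s.is_negative_control for s in self.samples],
            }
        ).set_index("sample_id", drop=False)

    def with_metadata(self, samples: Iterable[SampleMeta]) -> "CommunityMatrix":
        return CommunityMatrix(self.counts, list(samples))

    def subset(self, sample_ids: Sequence[str] | None = None, otu_ids: Sequence[str] | None = None) -> "CommunityMatrix":
        counts = self.counts
        if sample_ids is not None:
            counts = counts.loc[list(sample_ids)]
        if otu_ids is not None:
            counts = counts[list(otu_ids)]
        samples = None
        if self.samples is not None:
            keep = set(counts.index)
            samples = [s for s in self.samples if s.sample_id in keep]
        return CommunityMatrix(counts, samples)

    def depth_classes(self) -> list[str]:
        """Depth-class labels ordered shallowest to deepest (non-control samples)."""
        if self.samples is None:
            raise ValueError("matrix carries no sample metadata")
        pairs = {
            (s.depth_class, s.depth_value_cm) for s in self.samples if not s.is_negative_control
        }
        return [c for c, _ in sorted(pairs, key=lambda p: -p[1])]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CommunityMatrix):
            return NotImplemented
        return self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return f"CommunityMatrix({self.n_samples} samples x {self.n_otus} OTUs)"


# ---------------------------------------------------------------------------
# delimited-text readers / writers
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise ValueError(f"cannot sniff delimiter of {path}: expected tab or comma in header")


def read_community_table(
    path: str | Path,
    orientation: str = "rows-are-samples",
    delimiter: str | None = None,
) -> CommunityMatrix:
    """Read a delimited read-count table into a :class:`CommunityMatrix`.

    ``orientation`` declares the on-disk layout (``rows-are-samples`` or
    ``rows-are-otus``); the returned matrix is always samples x OTUs.
    Cells must parse as non-negative integers; missing cells are an error.
    """
    path = Path(path)
    if orientation not in ("rows-are-samples", "rows-are-otus"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.isna().any().any():
        mask = df.isna()
        r = mask.any(axis=1).idxmax()
        c = mask.loc[r].idxmax()
        raise ValueError(f"missing cell at row {r!r}, column {c!r} in {path}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric cell at row {bad.index[0]!r}, column {col!r} in {path}"
            )
    if orientation == "rows-are-otus":
        df = df.T
    return CommunityMatrix(df)


def write_community_table(
    matrix: CommunityMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.counts.to_csv(path, sep=delimiter, index_label="sample_id", lineterminator="\n")


def _parse_bool(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1", "t", "yes"):
        return True
    if s in ("false", "0", "f", "no"):
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def read_sample_metadata(path: str | Path, delimiter: str | None = None) -> list[SampleMeta]:
    """Read per-sample metadata; extra columns are kept as opaque attributes."""
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "depth_class": str})
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata file {path} missing required columns: {missing}")
    extra_cols = [c for c in df.columns if c not in REQUIRED_METADATA_COLUMNS]
    records = []
    for _, row in df.iterrows():
        records.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                depth_class=str(row["depth_class"]),
                depth_value_cm=float(row["depth_value_cm"]),
                horizontal_position_m=float(row["horizontal_position_m"]),
                replicate_id=int(row["replicate_id"]),
                is_negative_control=_parse_bool(row["is_negative_control"]),
                extra={c: row[c] for c in extra_cols},
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample ids in {path}")
    return records


def write_sample_metadata(samples: Sequence[SampleMeta], path: str | Path, delimiter: str = "\t") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "depth_class": s.depth_class,
            "depth_value_cm": s.depth_value_cm,
            "horizontal_position_m": s.horizontal_position_m,
            "replicate_id": s.replicate_id,
            "is_negative_control": s.is_negative_control,
        }
        row.update(s.extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False, lineterminator="\n")


def read_otu_annotations(path: str | Path, delimiter: str | None = None) -> list[OtuAnnotation]:
    """Read OTU taxonomy/guild annotations (columns: otu_id, taxonomy, guild)."""
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    if "otu_id" not in df.columns:
        raise ValueError(f"annotation file {path} lacks an otu_id column")
    seen: set[str] = set()
    out = []
    for _, row in df.iterrows():
        oid = str(row["otu_id"])
        if oid in seen:
            raise ValueError(f"duplicate annotation for OTU {oid!r}")
        seen.add(oid)
        out.append(
            OtuAnnotation(
                otu_id=oid,
                taxonomy=str(row.get("taxonomy", "") or ""),
                guild=str(row.get("guild", "") or "unassigned") or "unassigned",
            )
        )
    return out


# ---------------------------------------------------------------------------
# association-network edge tables
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = ("otu_a", "otu_b", "weight", "sign", "method")


def _sorted_edges(graph) -> list[tuple[str, str, float, str]]:
    edges = []
    for a, b, w, sign in graph.edges:
        a, b = (a, b) if a <= b else (b, a)
        edges.append((a, b, float(w), sign))
    return sorted(edges, key=lambda e: (e[0], e[1]))


def write_edge_table(graph, path: str | Path, format: str = "tsv") -> None:
    """Write an association graph as a TSV edge list or GraphML.

    Edge order is deterministic (lexicographic by otu_a then otu_b); the
    TSV dialect has columns otu_a, otu_b, weight, sign, method.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    edges = _sorted_edges(graph)
    if format == "tsv":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(_EDGE_COLUMNS) + "\n")
            for a, b, w, sign in edges:
                fh.write(f"{a}\t{b}\t{w:.12g}\t{sign}\t{graph.method}\n")
    elif format == "graphml":
        g = nx.Graph()
        g.add_nodes_from(sorted(graph.nodes))
        for a, b, w, sign in edges:
            g.add_edge(a, b, weight=w, sign=sign, method=graph.method)
        nx.write_graphml(g, path, named_key_ids=True)
    else:
        raise ValueError(f"unknown edge-table format {format!r}")


def read_edge_table(path: str | Path, format: str = "tsv"):
    """Read an edge table written by :func:`write_edge_table`."""
    from .cooccur import AssociationGraph

    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"otu_a": str, "otu_b": str})
        for col in _EDGE_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"edge table {path} missing column {col!r}")
        edges = [
            (str(r.otu_a), str(r.otu_b), float(r.weight), str(r.sign)) for r in df.itertuples()
        ]
        nodes = sorted({e[0] for e in edges} | {e[1] for e in edges})
        method = str(df["method"].iloc[0]) if len(df) else "log-ratio-correlation"
    elif format == "graphml":
        g = nx.read_graphml(path)
        edges = [
            (str(a), str(b), float(d["weight"]), str(d["sign"])) for a, b, d in g.edges(data=True)
        ]
        nodes = sorted(str(n) for n in g.nodes)
        method = edges[0][3] if False else (
            next((d["method"] for _, _, d in g.edges(data=True)), "log-ratio-correlation")
        )
    else:
        raise ValueError(f"unknown edge-table format {format!r}")
    return AssociationGraph(nodes=nodes, edges=edges, method=method)
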