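"""Tabular, ontology and graph I/O.

Canonical dialect is TSV (tab separator, UTF-8, "." decimal); CSV is accepted
via ``sep=","`` or a ``.csv`` extension.  Annotation inputs may be plain
3-column TSV or a GAF 2.1 subset (aspect "P" rows only).  Ontology levels are
computed from OBO ``is_a`` edges with the root at level 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

WT = "WT"
KO = "KO"
CONDITIONS = (WT, KO)

GAF_N_COLUMNS = 17
_GAF_ASPECT_COL = 8  # 0-based; "P" = biological process


class TableFormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix with per-sample condition labels.

    ``values`` holds non-negative normalized abundances (e.g. averaged read
    measures), genes as rows.  ``condition_of`` maps every sample id to
    ``"WT"`` or ``"KO"``.
    """

    values: pd.DataFrame
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        self.values.index.name = "gene_id"
        idx = self.values.index
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise TableFormatError(f"duplicate gene id: {dup!r}")
        missing = [s for s in self.values.columns if s not in self.condition_of]
        if missing:
            raise TableFormatError(
                f"samples absent from condition map: {missing}"
            )
        bad = {c for c in self.condition_of.values()} - set(CONDITIONS)
        if bad:
            raise TableFormatError(f"unknown condition labels: {sorted(bad)}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise TableFormatError("expression values must be finite")
        if (arr < 0).any():
            raise TableFormatError("expression values must be non-negative")
        for cond in CONDITIONS:
            if not self.samples(cond):
                raise TableFormatError(f"no replicate for condition {cond}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples(self, condition: str) -> list[str]:
        return [s for s in self.values.columns
                if self.condition_of[s] == condition]


@dataclass
class AnnotationTable:
    """Gene -> GO:BP term records, unique on (gene_id, term_id)."""

    records: pd.DataFrame  # columns: gene_id, term_id, term_name
    level_of: dict[str, int] = field(default_factory=dict)

    _ID_COLUMN = "gene_id"

    def __post_init__(self) -> None:
        cols = [self._ID_COLUMN, "term_id", "term_name"]
        self.records = (
            self.records[cols]
            .drop_duplicates(subset=[self._ID_COLUMN, "term_id"])
            .reset_index(drop=True)
        )

    def terms_of(self, gene_id: str) -> set[str]:
        r = self.records
        return set(r.loc[r[self._ID_COLUMN] == gene_id, "term_id"])

    def term_ids(self) -> set[str]:
        return set(self.records["term_id"])

    def restrict_genes(self, gene_ids) -> "AnnotationTable":
        keep = self.records[self._ID_COLUMN].isin(set(gene_ids))
        return type(self)(self.records[keep].copy(), dict(self.level_of))

    def restrict_levels(self, level: int) -> "AnnotationTable":
        """Keep only terms at the given ontology level (root = level 1)."""
        keep = self.records["term_id"].map(
            lambda t: self.level_of.get(t) == level
        )
        return type(self)(self.records[keep].copy(), dict(self.level_of))

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class IPAnnotationTable(AnnotationTable):
    """Interacting-protein -> GO:BP term records (column ``ip_id``)."""

    _ID_COLUMN = "ip_id"


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path,
    condition_of: Mapping[str, str],
    sep: str | None = None,
) -> ExpressionMatrix:
    """Read a gene x sample table whose first column is ``gene_id``.

    Raises :class:`TableFormatError` naming the offending cell for duplicate
    gene ids, non-numeric values, or samples missing from ``condition_of``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str)
    if df.columns[0] != "gene_id":
        raise TableFormatError(
            f"{path}: first column must be 'gene_id', got {df.columns[0]!r}"
        )
    df = df.set_index("gene_id")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise TableFormatError(
                f"{path}: non-numeric value at gene {row!r}, sample {col!r}"
            )
        df[col] = converted
    return ExpressionMatrix(df.astype(float), dict(condition_of))


def write_expression(m: ExpressionMatrix, path: str | Path,
                     sep: str | None = None) -> None:
    path = Path(path)
    m.values.to_csv(path, sep=_sep_for(path, sep), index_label="gene_id")


def _read_annotation_records(
    path: Path, fmt: str, id_column: str, sep: str | None
) -> pd.DataFrame:
    if fmt == "tsv":
        df = pd.read_csv(
            path, sep=_sep_for(path, sep), dtype=str, header=None,
            comment="#", skip_blank_lines=True,
        )
        # accept an optional header row
        first = df.iloc[0]
        if first.iloc[0] in (id_column, "gene", "gene_id", "ip", "ip_id"):
            df = df.iloc[1:]
        if df.shape[1] < 2:
            raise TableFormatError(f"{path}: need >=2 columns (id, term)")
        if df.shape[1] == 2:
            df[2] = ""
        df = df.iloc[:, :3]
        df.columns = [id_column, "term_id", "term_name"]
        return df.fillna({"term_name": ""}).reset_index(drop=True)
    if fmt == "gaf":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("!"):
                    continue
                parts = line.split("\t")
                if len(parts) != GAF_N_COLUMNS:
                    raise TableFormatError(
                        f"{path}:{lineno}: GAF row has {len(parts)} columns, "
                        f"expected {GAF_N_COLUMNS}"
                    )
                if parts[_GAF_ASPECT_COL] != "P":
                    continue
                term = parts[4]
                if not (term.startswith("GO:") and len(term) == 10
                        and term[3:].isdigit()):
                    raise TableFormatError(
                        f"{path}:{lineno}: malformed GO id {term!r}"
                    )
                # DB object symbol (col 3) is the gene label; col 10 holds
                # name/synonyms, first token used as the display name
                name = parts[9].split("|")[0] if parts[9] else ""
                rows.append((parts[2], term, name))
        return pd.DataFrame(rows, columns=[id_column, "term_id", "term_name"])
    raise ValueError(f"unknown annotation format: {fmt!r}")


def read_annotations(path: str | Path, fmt: str = "tsv",
                     sep: str | None = None) -> AnnotationTable:
    """Read gene->BP annotations from 3-column TSV or GAF 2.1 (aspect P)."""
    return AnnotationTable(
        _read_annotation_records(Path(path), fmt, "gene_id", sep)
    )


def read_ip_annotations(path: str | Path, fmt: str = "tsv",
                        sep: str | None = None) -> IPAnnotationTable:
    """Read interacting-protein->BP annotations (same formats)."""
    return IPAnnotationTable(
        _read_annotation_records(Path(path), fmt, "ip_id", sep)
    )


def write_annotations(ann: AnnotationTable, path: str | Path) -> None:
    ann.records.to_csv(path, sep="\t", index=False, header=False)


def obo_term_levels(path: str | Path,
                    namespace: str = "biological_process") -> dict[str, int]:
    """Depth stratum of every ontology term below the namespace root.

    Only ``is_a`` edges are traversed, obsolete terms and terms outside
    ``namespace`` are dropped.  The root (a retained term with no retained
    ``is_a`` parent) has level 1; every other term gets 1 + the minimum level
    among its ``is_a`` parents, i.e. the shortest is_a path from the root
    plus one.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    keep = {
        n for n, data in graph.nodes(data=True)
        if data.get("namespace", namespace) == namespace
    }
    child_to_parent = nx.DiGraph()
    child_to_parent.add_nodes_from(keep)
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a" and child in keep and parent in keep:
            child_to_parent.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(child_to_parent):
        cycle = nx.find_cycle(child_to_parent)
        raise TableFormatError(f"cyclic is_a relations: {cycle}")
    roots = [n for n in keep if child_to_parent.out_degree(n) == 0]
    levels: dict[str, int] = {}
    # BFS downwards from the roots over reversed is_a edges
    frontier = roots
    depth = 1
    while frontier:
        nxt = []
        for node in frontier:
            if node not in levels:
                levels[node] = depth
                nxt.extend(child_to_parent.predecessors(node))
        frontier = nxt
        depth += 1
    return levels


def write_graphml(net, path: str | Path) -> None:
    """Export a bipartite network as directed GraphML.

    Nodes carry attribute ``part`` in {"gene", "bp"}; edges carry ``weight``.
    """
    nx.write_graphml(net.graph, path)


def read_graphml(path: str | Path, condition: str = WT):
    from .bpnet import BipartiteNet

    g = nx.read_graphml(path)
    if not g.is_directed():
        g = g.to_directed()
    out = nx.DiGraph()
    for node, data in g.nodes(data=True):
        out.add_node(node, part=data.get("part", "gene"))
    for u, v, data in g.edges(data=True):
        out.add_edge(u, v, weight=float(data.get("weight", 1.0)))
    return BipartiteNet(condition=condition, graph=out)


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    """Write a per-gene report TSV (one row per gene, header included).

    Infinite rates of change print as ``inf``/``-inf``.
    """
    report.to_csv(path, sep="\t", index=False)


def read_condition_map(path: str | Path) -> dict[str, str]:
    """Read a sample->condition map from YAML ({sample: WT|KO})."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise TableFormatError(f"{path}: expected a mapping sample->condition")
    return {str(k): str(v) for k, v in data.items()}
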