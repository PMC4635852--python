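"""Readers and writers for every external format the pipeline touches.

Formats handled: plain TSV expression matrices (genes in rows, samples in
columns), GEO series-matrix text files, GMT gene-set collections,
tab-delimited interaction edge lists, and GraphML/SIF graph exports for
Cytoscape.  No statistics live here; readers validate and reject malformed
input rather than silently repairing it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "Interaction",
    "InteractionTable",
    "INTERACTION_KINDS",
    "INTERACTION_ROLES",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_group_map",
    "write_group_map",
    "read_series_matrix",
    "read_gmt",
    "write_gmt",
    "read_interactions",
    "write_interactions",
    "write_graphml",
    "write_sif",
    "collapse_probes",
]

UNGROUPED = "ungrouped"

INTERACTION_KINDS = ("ppi", "regulatory", "drug_target")
INTERACTION_ROLES = ("activator", "repressor", "product")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2 intensities with sample group labels.

    Parameters
    ----------
    gene_ids, sample_ids : list of str
        Unique row and column identifiers, in matrix order.
    values : ndarray of shape (n_genes, n_samples)
        Finite log2 intensity values.
    groups : dict
        Maps every sample id to a free-string group label (e.g. "TCMR",
        "Control"); samples without a known group carry ``"ungrouped"``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene ID")
        _check_unique(self.sample_ids, "sample ID")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        groups = dict(self.groups)
        unknown = set(groups) - set(self.sample_ids)
        if unknown:
            raise FormatError(f"group labels for unknown samples: {sorted(unknown)}")
        self.groups = {s: groups.get(s, UNGROUPED) for s in self.sample_ids}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, groups: dict[str, str] | None = None
                   ) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
            groups=groups or {},
        )

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        keep = [idx[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), self.sample_ids,
                                self.values[keep, :], self.groups)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        keep = [idx[s] for s in sample_ids]
        return ExpressionMatrix(self.gene_ids, list(sample_ids),
                                self.values[:, keep],
                                {s: self.groups[s] for s in sample_ids})

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    """An ordered collection of named gene sets (GMT semantics)."""

    sets: list[GeneSet]

    def __post_init__(self) -> None:
        _check_unique([s.set_id for s in self.sets], "gene-set ID")
        for s in self.sets:
            if not s.members:
                raise FormatError(f"gene set {s.set_id!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)


@dataclass(frozen=True)
class Interaction:
    source: str
    target: str
    kind: str
    role: str | None = None
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in INTERACTION_KINDS:
            raise FormatError(f"unknown interaction kind {self.kind!r}")
        if self.role is not None and self.role not in INTERACTION_ROLES:
            raise FormatError(f"unknown role {self.role!r}")
        if self.kind == "drug_target" and self.source == self.target:
            raise FormatError(f"drug_target self-loop on {self.source!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise FormatError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class InteractionTable:
    """Typed edge list.  ppi edges are undirected; regulatory and
    drug_target edges run source -> target."""

    edges: list[Interaction]

    def of_kind(self, kind: str) -> list[Interaction]:
        if kind not in INTERACTION_KINDS:
            raise FormatError(f"unknown interaction kind {kind!r}")
        return [e for e in self.edges if e.kind == kind]

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)


# ---------------------------------------------------------------------------
# expression TSV

def read_group_map(path) -> dict[str, str]:
    """Read a two-column TSV mapping sample id -> group label."""
    groups: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"group map line {lineno}: expected 2 columns")
            if parts[0] in groups:
                raise FormatError(f"group map line {lineno}: duplicate sample {parts[0]!r}")
            groups[parts[0]] = parts[1]
    return groups


def write_group_map(groups: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


def _parse_expression_table(text: str, origin: str) -> pd.DataFrame:
    if not text.strip():
        raise FormatError(f"{origin}: empty file")
    try:
        frame = pd.read_csv(io.StringIO(text), sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise FormatError(f"{origin}: cannot parse table: {exc}") from exc
    if frame.shape[1] == 0:
        raise FormatError(f"{origin}: no sample columns")
    frame.index = frame.index.map(str)
    dup = frame.index[frame.index.duplicated()]
    if len(dup):
        raise FormatError(f"{origin}: duplicate gene ID {dup[0]!r}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        gene = numeric.index[numeric.isna().any(axis=1)][0]
        col = numeric.columns[numeric.loc[gene].isna()][0]
        raise FormatError(
            f"{origin}: non-numeric or missing value at gene {gene!r}, sample {col!r}")
    return numeric


def read_expression_tsv(path, group_map_path=None) -> ExpressionMatrix:
    """Read an expression matrix from TSV (header = sample ids, first
    column = gene ids), optionally attaching groups from a two-column TSV.

    Samples missing from the group map get the label ``"ungrouped"``.
    """
    with open(path) as fh:
        text = fh.read()
    frame = _parse_expression_table(text, str(path))
    groups = read_group_map(group_map_path) if group_map_path else {}
    groups = {s: g for s, g in groups.items() if s in frame.columns}
    return ExpressionMatrix.from_frame(frame, groups)


def write_expression_tsv(matrix: ExpressionMatrix, path, float_format: str = "%.6g"
                         ) -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format=float_format,
                             index_label="gene_id")


# ---------------------------------------------------------------------------
# GEO series matrix

def read_series_matrix(path, group_key: str | None = None) -> ExpressionMatrix:
    """Parse a GEO series-matrix text file into an :class:`ExpressionMatrix`.

    Metadata lines start with ``!``; the expression table sits between
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end``.  When
    *group_key* is given, ``!Sample_characteristics`` entries of the form
    ``"key: value"`` with a matching key become the sample group labels.
    """
    meta: list[list[str]] = []
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table, saw_begin = True, True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table, saw_end = False, True
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!"):
                meta.append([f.strip('"') for f in line.split("\t")])
    if not (saw_begin and saw_end):
        raise FormatError(
            f"{path}: missing !series_matrix_table_begin/!series_matrix_table_end")
    text = "\n".join(line.replace('"', "") for line in table_lines if line)
    frame = _parse_expression_table(text, str(path))

    groups: dict[str, str] = {}
    if group_key is not None:
        sample_ids: list[str] | None = None
        for row in meta:
            if row and row[0] == "!Sample_geo_accession":
                sample_ids = row[1:]
        for row in meta:
            if row and row[0].startswith("!Sample_characteristics") and sample_ids:
                for sid, entry in zip(sample_ids, row[1:]):
                    key, _, value = entry.partition(":")
                    if key.strip() == group_key:
                        groups[sid] = value.strip()
        groups = {s: g for s, g in groups.items() if s in frame.columns}
    return ExpressionMatrix.from_frame(frame, groups)


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one gene set per line, tab-delimited
    ``set_id  description  member  member ...``."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"fields, got {len(parts)}")
            members = frozenset(p for p in parts[2:] if p)
            if not members:
                raise FormatError(f"{path}: line {lineno}: gene set has no members")
            sets.append(GeneSet(parts[0], parts[1], members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.set_id, s.description, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# interaction tables

def read_interactions(path, kind: str) -> InteractionTable:
    """Read a tab-delimited edge list: source, target, [role], [confidence].

    The third column is interpreted as a role when it matches a known role
    token, otherwise as a confidence value.  Confidence defaults to 1.0.
    """
    if kind not in INTERACTION_KINDS:
        raise FormatError(f"unknown interaction kind {kind!r}")
    edges: list[Interaction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno}: expected >= 2 columns")
            role: str | None = None
            confidence = 1.0
            rest = parts[2:]
            if rest:
                token = rest[0]
                if token in INTERACTION_ROLES:
                    role = token
                    rest = rest[1:]
                elif token == "":
                    rest = rest[1:]  # explicit empty role column
                else:
                    try:
                        float(token)  # a bare confidence column
                    except ValueError:
                        raise FormatError(
                            f"{path}: line {lineno}: unknown role token {token!r}"
                        ) from None
            if rest and rest[0] != "":
                try:
                    confidence = float(rest[0])
                except ValueError:
                    raise FormatError(
                        f"{path}: line {lineno}: bad confidence {rest[0]!r}"
                    ) from None
            try:
                edges.append(Interaction(parts[0], parts[1], kind, role, confidence))
            except FormatError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return InteractionTable(edges)


def write_interactions(table: InteractionTable, path) -> None:
    with open(path, "w") as fh:
        for e in table:
            fh.write(f"{e.source}\t{e.target}\t{e.role or ''}\t{e.confidence:g}\n")


# ---------------------------------------------------------------------------
# graph exports

def write_graphml(nodes_with_attrs, edges_with_attrs, path,
                  directed: bool = False) -> None:
    """Write a GraphML file from ``(node_id, attrs)`` and
    ``(source, target, attrs)`` sequences.

    Node ids must be unique and every edge endpoint must be a declared node;
    attribute values must be scalars (GraphML cannot hold containers).
    """
    graph: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    for node_id, attrs in nodes_with_attrs:
        if node_id in graph:
            raise FormatError(f"duplicate node ID {node_id!r}")
        _check_scalar_attrs(attrs, node_id)
        graph.add_node(node_id, **attrs)
    for source, target, attrs in edges_with_attrs:
        for end in (source, target):
            if end not in graph:
                raise FormatError(f"edge references unknown node {end!r}")
        _check_scalar_attrs(attrs, f"{source}->{target}")
        graph.add_edge(source, target, **attrs)
    nx.write_graphml(graph, path)


def _check_scalar_attrs(attrs: dict, owner) -> None:
    for key, value in attrs.items():
        if not isinstance(value, (str, int, float, bool, np.integer, np.floating)):
            raise FormatError(
                f"attribute {key!r} of {owner!r} is not scalar: {type(value).__name__}")


def graph_to_graphml(graph: nx.Graph, path) -> None:
    """Write an existing networkx graph (list/set attributes joined as text)."""
    clean = graph.copy()
    for _, attrs in clean.nodes(data=True):
        for k, v in list(attrs.items()):
            if isinstance(v, (list, tuple, set, frozenset)):
                attrs[k] = ";".join(sorted(map(str, v)))
    for _, _, attrs in clean.edges(data=True):
        for k, v in list(attrs.items()):
            if isinstance(v, (list, tuple, set, frozenset)):
                attrs[k] = ";".join(sorted(map(str, v)))
    nx.write_graphml(clean, path)


def write_sif(edges, path) -> None:
    """Write a Cytoscape SIF file from ``(source, kind, target)`` triples."""
    with open(path, "w") as fh:
        for source, kind, target in edges:
            fh.write(f"{source}\t{kind}\t{target}\n")


# ---------------------------------------------------------------------------
# probe collapsing

def collapse_probes(matrix: ExpressionMatrix, probe_to_gene: dict[str, str],
                    strategy: str = "max_cv") -> ExpressionMatrix:
    """Collapse probe-level rows to gene symbols.

    ``max_cv`` keeps, for each gene symbol, the probe with the highest
    coefficient of variation (most informative under a CV-centric filter).
    Probes absent from the mapping are dropped.
    """
    if strategy != "max_cv":
        raise ValueError(f"unknown collapse strategy {strategy!r}")
    means = matrix.values.mean(axis=1)
    sds = matrix.values.std(axis=1, ddof=1) if matrix.n_samples > 1 else np.zeros(
        matrix.n_genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvs = np.where(means > 0, sds / means, -np.inf)
    best: dict[str, tuple[float, int]] = {}
    for i, probe in enumerate(matrix.gene_ids):
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        if gene not in best or cvs[i] > best[gene][0]:
            best[gene] = (cvs[i], i)
    genes = sorted(best)
    rows = [best[g][1] for g in genes]
    return ExpressionMatrix(genes, matrix.sample_ids, matrix.values[rows, :],
                            matrix.groups)
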