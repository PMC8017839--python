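"""Readers, writers and core containers for association and similarity data.

The pipeline's central object is the binary lncRNA x disease association
matrix built from a curated association list (one lncRNA/disease pair per
row, with an optional dysfunction-type annotation that is carried along but
never used downstream).  Disease ontologies arrive as plain child->parent
edge lists and are validated to be rooted DAGs at load time.  All real-valued
matrices travel as labelled TSV files so every intermediate artifact of the
pipeline is inspectable with standard tools.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("ipcarf")

# Header names recognised when auto-detecting a header row in association
# lists (case-insensitive, surrounding whitespace ignored).
_KNOWN_HEADER_FIELDS = {
    "lncrna name", "lncrna", "lnc", "lncrna_name",
    "disease name", "disease", "disease_name",
    "dysfunction type", "dysfunction", "dysfunction_type",
}

_WS_RUN = re.compile(r"\s+")


class DataError(ValueError):
    """Raised for malformed input files or invalid containers."""


def normalize_name(name: str, lowercase: bool = True) -> str:
    """Trim, collapse internal whitespace runs and (optionally) lower-case."""
    out = _WS_RUN.sub(" ", name.strip())
    return out.lower() if lowercase else out


@dataclass(frozen=True)
class AssociationRecord:
    lncrna: str
    disease: str
    dysfunction: Optional[str] = None


@dataclass
class AssociationTable:
    """Deduplicated list of (lncRNA, disease) association records."""

    records: list[AssociationRecord]

    def __post_init__(self) -> None:
        for rec in self.records:
            if not rec.lncrna or not rec.disease:
                raise DataError("association records must have non-empty names")

    def __len__(self) -> int:
        return len(self.records)

    def pairs(self) -> list[tuple[str, str]]:
        return [(r.lncrna, r.disease) for r in self.records]


@dataclass
class AssociationMatrix:
    """Binary adjacency between ``n`` lncRNAs (rows) and ``m`` diseases (columns)."""

    values: np.ndarray
    lnc_labels: list[str]
    dis_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.lnc_labels), len(self.dis_labels)):
            raise DataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.lnc_labels)} lncRNA / {len(self.dis_labels)} disease labels"
            )
        if len(set(self.lnc_labels)) != len(self.lnc_labels):
            raise DataError("duplicate lncRNA labels")
        if len(set(self.dis_labels)) != len(self.dis_labels):
            raise DataError("duplicate disease labels")
        if not np.isin(self.values, (0, 1)).all():
            raise DataError("association matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)

    @property
    def n_lnc(self) -> int:
        return len(self.lnc_labels)

    @property
    def n_dis(self) -> int:
        return len(self.dis_labels)

    def lnc_index(self, label: str) -> int:
        try:
            return self.lnc_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown lncRNA label: {label!r}") from None

    def dis_index(self, label: str) -> int:
        try:
            return self.dis_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown disease label: {label!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.lnc_labels, columns=self.dis_labels)


@dataclass
class DiseaseOntology:
    """A rooted DAG of disease terms with child->parent edges."""

    terms: set[str]
    edges: set[tuple[str, str]]
    roots: set[str] = field(init=False)

    def __post_init__(self) -> None:
        for child, parent in self.edges:
            if child not in self.terms or parent not in self.terms:
                raise DataError(f"edge ({child!r}, {parent!r}) references unknown term")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise DataError(f"ontology contains a cycle: {cycle}")
        has_parent = {c for c, _ in self.edges}
        self.roots = self.terms - has_parent

    def graph(self) -> nx.DiGraph:
        """Child->parent digraph over all terms (isolated terms included)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.edges)
        return g

    def parents(self, term: str) -> set[str]:
        return {p for c, p in self.edges if c == term}


@dataclass
class LabelledMatrix:
    """Real matrix with ordered row/column labels (TSV carrier type)."""

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise DataError("matrix shape does not match label counts")
        if not np.isfinite(self.values).all():
            raise DataError("matrix entries must be finite")


# ---------------------------------------------------------------------------
# association lists
# ---------------------------------------------------------------------------

def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def _looks_like_header(fields: Sequence[str]) -> bool:
    return any(f.strip().lower() in _KNOWN_HEADER_FIELDS for f in fields)


def load_associations(path: str | Path, lowercase: bool = True) -> AssociationTable:
    """Read a TSV/CSV association list into a deduplicated table.

    The file must have at least two columns (lncRNA name, disease name); a
    third column, if present, is kept as the dysfunction type.  A header row
    is auto-detected by matching known column names.
    """
    path = Path(path)
    if not path.is_file():
        raise DataError(f"association file not found: {path}")
    raw_lines = path.read_text(encoding="utf-8").splitlines()
    lines = [(i + 1, ln) for i, ln in enumerate(raw_lines) if ln.strip()]
    if not lines:
        raise DataError(f"association file is empty: {path}")

    delim = _detect_delimiter(lines[0][1])
    bad: list[int] = []
    records: list[AssociationRecord] = []
    seen: set[tuple[str, str]] = set()
    n_read = 0
    for pos, (lineno, line) in enumerate(lines):
        fields = line.split(delim)
        if pos == 0 and _looks_like_header(fields):
            continue
        if len(fields) < 2:
            bad.append(lineno)
            continue
        n_read += 1
        lnc = normalize_name(fields[0], lowercase)
        dis = normalize_name(fields[1], lowercase)
        dysf = normalize_name(fields[2], lowercase) if len(fields) > 2 and fields[2].strip() else None
        if not lnc or not dis:
            bad.append(lineno)
            continue
        if (lnc, dis) in seen:
            continue
        seen.add((lnc, dis))
        records.append(AssociationRecord(lnc, dis, dysf))
    if bad:
        raise DataError(f"rows with fewer than 2 fields at line(s): {bad}")
    logger.info("read %d association rows from %s (%d unique pairs)", n_read, path, len(records))
    return AssociationTable(records)


def build_association_matrix(table: AssociationTable) -> AssociationMatrix:
    """Build the binary n x m adjacency; labels sorted lexicographically."""
    if not table.records:
        raise DataError("cannot build a matrix from an empty association table")
    lnc_labels = sorted({r.lncrna for r in table.records})
    dis_labels = sorted({r.disease for r in table.records})
    li = {l: i for i, l in enumerate(lnc_labels)}
    di = {d: j for j, d in enumerate(dis_labels)}
    values = np.zeros((len(lnc_labels), len(dis_labels)), dtype=np.int8)
    for r in table.records:
        values[li[r.lncrna], di[r.disease]] = 1
    return AssociationMatrix(values, lnc_labels, dis_labels)


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------

def load_ontology(path: str | Path) -> DiseaseOntology:
    """Read a child<TAB>parent edge list; '#' comment lines are skipped."""
    path = Path(path)
    if not path.is_file():
        raise DataError(f"ontology file not found: {path}")
    edges: set[tuple[str, str]] = set()
    terms: set[str] = set()
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        fields = s.split("\t")
        if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
            raise DataError(f"ontology line {lineno} is not 'child<TAB>parent': {line!r}")
        child, parent = fields[0].strip(), fields[1].strip()
        edges.add((child, parent))
        terms.update((child, parent))
    onto = DiseaseOntology(terms=terms, edges=edges)
    logger.info("loaded ontology: %d terms, %d edges, %d root(s)",
                len(onto.terms), len(onto.edges), len(onto.roots))
    return onto


def write_ontology(onto: DiseaseOntology, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# child\tparent\n")
        for child, parent in sorted(onto.edges):
            fh.write(f"{child}\t{parent}\n")


# ---------------------------------------------------------------------------
# labelled matrices
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path) -> LabelledMatrix:
    """Read a labelled TSV matrix (header row + first label column)."""
    path = Path(path)
    if not path.is_file():
        raise DataError(f"matrix file not found: {path}")
    lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if len(lines) < 2:
        raise DataError(f"matrix file too short: {path}")
    header = lines[0].split("\t")
    col_labels = [c.strip() for c in header[1:]]
    width = len(col_labels)
    row_labels: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], 2):
        fields = line.split("\t")
        if len(fields) != width + 1:
            raise DataError(f"ragged row at line {lineno}: expected {width + 1} fields, got {len(fields)}")
        row_labels.append(fields[0].strip())
        try:
            rows.append([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise DataError(f"non-numeric cell at line {lineno}: {exc}") from None
    return LabelledMatrix(np.array(rows, dtype=float), row_labels, col_labels)


def write_matrix(matrix: LabelledMatrix, path: str | Path) -> None:
    """Write a labelled matrix as TSV; round-trips to 12 significant digits."""
    path = Path(path)
    df = pd.DataFrame(matrix.values, index=matrix.row_labels, columns=matrix.col_labels)
    df.to_csv(path, sep="\t", float_format="%.12g", index_label="")


def write_association_matrix(A: AssociationMatrix, path: str | Path) -> None:
    write_matrix(LabelledMatrix(A.values.astype(float), A.lnc_labels, A.dis_labels), path)


def read_association_matrix(path: str | Path) -> AssociationMatrix:
    m = read_matrix(path)
    return AssociationMatrix(m.values.astype(np.int8), m.row_labels, m.col_labels)
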