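"""Readers and writers for every on-disk format the pipeline touches.

Formats are deliberately plain text: tab-separated count matrices with a
sidecar file of per-sample total mapped reads, GMT gene sets, GraphML plus a
tab-separated edge list for networks, and tab-separated report tables.
Parsers validate strictly and report the offending line number instead of
silently coercing malformed input. Gene identifiers are opaque,
case-sensitive strings; no symbol/accession mapping is attempted. All files
are UTF-8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: float rendering used by every report table (6 significant digits)
FLOAT_FORMAT = "%.6g"


class FormatError(ValueError):
    """Malformed input file (wrong shape, duplicate ids, bad values)."""


class ValidationError(ValueError):
    """Inconsistent in-memory data or configuration."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene-level read counts for a set of single-library samples.

    Parameters
    ----------
    counts
        Integer DataFrame, genes x samples; index holds gene ids, columns
        sample ids.
    lengths
        Transcript length in bp per gene (same index as ``counts``). This is
        the ``L`` of the RPKM formula.
    totals
        Total mapped reads per sample (same order as ``counts`` columns), the
        ``N`` of the RPKM formula. Totals may exceed the column sums because
        they include reads mapped outside the quantified gene set.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    totals: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if not self.lengths.index.equals(self.counts.index):
            raise ValidationError("gene_lengths index does not match counts")
        if not self.totals.index.equals(self.counts.columns):
            raise ValidationError("totals index does not match counts columns")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative counts")
        if (self.lengths.to_numpy() <= 0).any():
            bad = self.lengths.index[self.lengths.to_numpy() <= 0][0]
            raise ValidationError(f"non-positive gene length for {bad!r}")
        if (self.totals.to_numpy() <= 0).any():
            bad = self.totals.index[self.totals.to_numpy() <= 0][0]
            raise ValidationError(f"non-positive total mapped reads for {bad!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class GeneSetCollection:
    """Named gene sets (GO terms, KEGG pathways or custom collections).

    ``terms`` maps term id -> (description, namespace, member ids). Namespace
    is a free tag, conventionally ``GO``, ``KEGG`` or ``custom``.
    """

    terms: dict[str, tuple[str, str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, (_, _, members) in self.terms.items():
            if len(members) < 1:
                raise ValidationError(f"term {tid!r} has no members")

    def namespaces(self) -> list[str]:
        return sorted({ns for _, ns, _ in self.terms.values()})

    def in_namespace(self, namespace: str | None) -> dict[str, tuple[str, str, frozenset[str]]]:
        if namespace is None:
            return dict(self.terms)
        return {t: v for t, v in self.terms.items() if v[1] == namespace}

    def annotated_genes(self, namespace: str | None = None) -> frozenset[str]:
        """Union of members over all terms (optionally one namespace)."""
        out: set[str] = set()
        for _, (_, ns, members) in self.terms.items():
            if namespace is None or ns == namespace:
                out |= members
        return frozenset(out)

    def members(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][2]

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class MechanismGeneList:
    """Curated genes tied to known pathologic mechanisms (e.g. calcium
    overload, oxygen-radical production after oxygen-glucose deprivation)."""

    gene_ids: frozenset[str]

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_ids

    def __len__(self) -> int:
        return len(self.gene_ids)


# ---------------------------------------------------------------------------
# counts + totals
# ---------------------------------------------------------------------------


def write_counts(cm: CountMatrix, path: str | Path, totals_path: str | Path) -> None:
    """Write a count matrix and its totals sidecar.

    Counts file columns: gene_id, length_bp, then one integer column per
    sample. Totals file columns: sample_id, total_mapped_reads.
    """
    path, totals_path = Path(path), Path(totals_path)
    df = pd.DataFrame({"gene_id": cm.gene_ids, "length_bp": cm.lengths.to_numpy()})
    for s in cm.sample_ids:
        df[s] = cm.counts[s].to_numpy()
    df.to_csv(path, sep="\t", index=False)
    tot = pd.DataFrame(
        {"sample_id": cm.sample_ids, "total_mapped_reads": cm.totals.to_numpy()}
    )
    tot.to_csv(totals_path, sep="\t", index=False)


def read_counts(path: str | Path, totals_path: str | Path) -> CountMatrix:
    """Read and validate a count matrix written by :func:`write_counts`.

    Raises :class:`FormatError` naming the line number for duplicate gene
    ids, non-integer counts, or samples missing from the totals file.
    """
    path, totals_path = Path(path), Path(totals_path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[0] != "gene_id" or header[1] != "length_bp":
            raise FormatError(f"{path}:1: expected header gene_id<TAB>length_bp<TAB>samples...")
        samples = header[2:]
        if len(set(samples)) != len(samples):
            raise FormatError(f"{path}:1: duplicate sample id in header")
        gene_ids: list[str] = []
        seen: set[str] = set()
        lengths: list[int] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            gid = fields[0]
            if gid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gid!r}")
            seen.add(gid)
            try:
                length = int(fields[1])
                vals = [int(v) for v in fields[2:]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer value ({exc})") from exc
            if length <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive length for {gid!r}")
            if any(v < 0 for v in vals):
                raise FormatError(f"{path}:{lineno}: negative count for {gid!r}")
            gene_ids.append(gid)
            lengths.append(length)
            rows.append(vals)

    totals = _read_totals(totals_path)
    missing = [s for s in samples if s not in totals]
    if missing:
        raise FormatError(f"{totals_path}: no total mapped reads for sample {missing[0]!r}")
    counts = pd.DataFrame(
        np.asarray(rows, dtype=np.int64).reshape(len(gene_ids), len(samples)),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=samples,
    )
    return CountMatrix(
        counts=counts,
        lengths=pd.Series(lengths, index=counts.index, name="length_bp"),
        totals=pd.Series([totals[s] for s in samples], index=counts.columns,
                         name="total_mapped_reads"),
    )


def _read_totals(path: Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["sample_id", "total_mapped_reads"]:
            raise FormatError(f"{path}:1: expected header sample_id<TAB>total_mapped_reads")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields")
            sid = fields[0]
            if sid in out:
                raise FormatError(f"{path}:{lineno}: duplicate sample id {sid!r}")
            try:
                tot = int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer total ({exc})") from exc
            if tot <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive total for {sid!r}")
            out[sid] = tot
    return out


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    """Write gene sets in GMT format (term, description, members...).

    The namespace tag is appended to the description after ``|`` so a
    round-trip through :func:`read_gmt` preserves it.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for tid in sorted(sets.terms):
            desc, ns, members = sets.terms[tid]
            fh.write("\t".join([tid, f"{desc}|{ns}", *sorted(members)]) + "\n")


def read_gmt(path: str | Path, namespace: str | None = None) -> GeneSetCollection:
    """Read a GMT file.

    Duplicate member ids within a line are dropped with a logged warning;
    duplicate term ids are an error. A ``|namespace`` suffix on the
    description field (as written by :func:`write_gmt`) is honoured unless
    ``namespace`` overrides it; otherwise the namespace defaults to
    ``custom``.
    """
    path = Path(path)
    terms: dict[str, tuple[str, str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            tid, desc = fields[0], fields[1]
            if tid in terms:
                raise FormatError(f"{path}:{lineno}: duplicate term id {tid!r}")
            members = fields[2:]
            uniq = list(dict.fromkeys(members))
            if len(uniq) != len(members):
                logger.warning(
                    "%s:%d: term %s has duplicate member ids; duplicates dropped",
                    path, lineno, tid,
                )
            ns = namespace
            if ns is None:
                desc, _, tag = desc.rpartition("|")
                if desc:
                    ns = tag
                else:
                    desc, ns = tag, "custom"
            terms[tid] = (desc, ns, frozenset(uniq))
    return GeneSetCollection(terms=terms)


# ---------------------------------------------------------------------------
# gene lists
# ---------------------------------------------------------------------------


def read_gene_list(path: str | Path) -> MechanismGeneList:
    """Read a plain-text gene list, one id per line; ``#`` starts a comment."""
    genes: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            g = line.split("#", 1)[0].strip()
            if g:
                genes.add(g)
    return MechanismGeneList(gene_ids=frozenset(genes))


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(set(genes)):
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------


def write_network(net, path: str | Path, edge_list_path: str | Path | None = None) -> None:
    """Export a co-expression network as GraphML plus a TSV edge list.

    Node attributes: gene id (the node key), ``degree``, ``core_number`` and,
    when attached by the pipeline, ``log2_ratio``. Edge attributes: ``r``
    (signed Pearson correlation) and ``p`` (correlation-test p-value).
    ``edge_list_path`` defaults to ``path`` with an ``.edges.tsv`` suffix.
    """
    path = Path(path)
    g = nx.Graph()
    for node in sorted(net.graph.nodes):
        attrs = {
            "degree": int(net.degree[node]),
            "core_number": int(net.core_number[node]),
        }
        extra = net.graph.nodes[node]
        if "log2_ratio" in extra:
            attrs["log2_ratio"] = float(extra["log2_ratio"])
        g.add_node(node, **attrs)
    for a, b, data in net.graph.edges(data=True):
        g.add_edge(a, b, r=float(data["r"]), p=float(data["p"]))
    nx.write_graphml(g, path)

    if edge_list_path is None:
        edge_list_path = path.with_suffix(".edges.tsv")
    rows = [
        (min(a, b), max(a, b), data["r"], data["p"])
        for a, b, data in net.graph.edges(data=True)
    ]
    rows.sort()
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p"])
    df.to_csv(edge_list_path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a TSV edge list written by :func:`write_network`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    expected = ["gene_a", "gene_b", "r", "p"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return df


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a report table as TSV with 6-significant-digit floats."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path, str_columns: tuple[str, ...] = ("gene_id", "term_id")) -> pd.DataFrame:
    dtype: Mapping[str, type] = {c: str for c in str_columns}
    return pd.read_csv(path, sep="\t", dtype=dtype)
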