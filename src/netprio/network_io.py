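"""Weighted functional gene network and gene annotation I/O.

A functional genomic network (FGN) is an undirected gene graph whose edge
weights, in [0, 1], are posterior probabilities that two genes participate in
the same biological process.  Thresholded "top edge" dumps of such networks
(gene, gene, weight per line) are the expected input; an absent edge means
weight 0, which is exactly the semantics used when rows of the adjacency
matrix serve as feature vectors for classification.

Gene annotations carry the coordinates needed to assign SNP association
signals to nearby genes.  Internally coordinates are 1-based closed intervals
(the convention of mouse genome browser positions); BED input is converted on
load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GeneAnnotation",
    "FunctionalNetwork",
    "NetworkFormatError",
    "AnnotationFormatError",
    "GeneLookupError",
    "load_edge_list",
    "write_edge_list",
    "load_gene_annotations",
    "feature_vector",
]


class NetworkFormatError(ValueError):
    """Malformed edge-list input (bad weight, conflicting duplicate...)."""


class AnnotationFormatError(ValueError):
    """Malformed gene annotation input."""


class GeneLookupError(KeyError):
    """A requested gene is absent from the network."""


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene body location; ``start``/``end`` are 1-based, closed."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationFormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 0 or self.end < 0:
            raise AnnotationFormatError(f"gene {self.gene_id}: negative coordinate")

    def distance_to(self, pos: int) -> int:
        """Distance from a position to the gene body (0 if inside)."""
        if pos < self.start:
            return self.start - pos
        if pos > self.end:
            return pos - self.end
        return 0


class FunctionalNetwork:
    """Undirected weighted gene graph with weights in [0, 1].

    Nodes are held in lexicographic order so that every matrix built from the
    network is deterministic.  Absent edges have weight 0 and self-edges are
    disallowed.
    """

    def __init__(
        self,
        edges: Mapping[tuple[str, str], float],
        extra_nodes: Iterable[str] = (),
    ) -> None:
        adj: dict[str, dict[str, float]] = {}
        canonical: dict[tuple[str, str], float] = {}
        for (a, b), w in edges.items():
            if a == b:
                raise NetworkFormatError(f"self-loop on {a!r}")
            if not (0.0 <= w <= 1.0):
                raise NetworkFormatError(f"edge ({a}, {b}) weight {w} outside [0, 1]")
            key = (a, b) if a <= b else (b, a)
            prev = canonical.get(key)
            if prev is not None and prev != w:
                raise NetworkFormatError(
                    f"conflicting duplicate edge ({key[0]}, {key[1]}): {prev} vs {w}"
                )
            canonical[key] = w
            adj.setdefault(a, {})[b] = w
            adj.setdefault(b, {})[a] = w
        for n in extra_nodes:
            adj.setdefault(n, {})
        self._adj = adj
        self._edges = canonical
        self._nodes: tuple[str, ...] = tuple(sorted(adj))
        self._index = {g: i for i, g in enumerate(self._nodes)}

    # -- basic accessors ---------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, gene: str) -> bool:
        return gene in self._adj

    def edges(self) -> Mapping[tuple[str, str], float]:
        """Canonical (a <= b) edge → weight mapping."""
        return dict(self._edges)

    def weight(self, a: str, b: str) -> float:
        """Edge weight, 0 when no edge (including a == b)."""
        for g in (a, b):
            if g not in self._adj:
                raise GeneLookupError(f"gene {g!r} not in network")
        if a == b:
            return 0.0
        return self._adj[a].get(b, 0.0)

    def neighbors(self, gene: str) -> Mapping[str, float]:
        if gene not in self._adj:
            raise GeneLookupError(f"gene {gene!r} not in network")
        return self._adj[gene]

    def subgraph_edges(
        self, genes: Sequence[str]
    ) -> list[tuple[str, str, float]]:
        """Edges of the induced subgraph, canonically ordered and sorted."""
        keep = set(genes)
        out = [
            (a, b, w)
            for (a, b), w in self._edges.items()
            if a in keep and b in keep
        ]
        out.sort()
        return out


# -- edge list I/O ---------------------------------------------------------


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def load_edge_list(path: str | Path, delimiter: str | None = None) -> FunctionalNetwork:
    """Read a 3-column (gene, gene, weight) edge list.

    ``delimiter=None`` splits on any whitespace (tabs or spaces).  A header
    line is auto-detected by a non-numeric third field on the first line.
    Duplicate edges with identical weights are de-duplicated silently;
    conflicting weights, out-of-range weights and short rows raise
    :class:`NetworkFormatError` naming the offending line.  Self-loops are
    dropped with a warning.
    """
    path = Path(path)
    edges: dict[tuple[str, str], float] = {}
    n_self = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(delimiter)
            if len(fields) < 3:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected ≥3 fields, got {len(fields)}"
                )
            if lineno == 1 and not _is_number(fields[2]):
                continue  # header
            a, b, wtok = fields[0], fields[1], fields[2]
            if not _is_number(wtok):
                raise NetworkFormatError(f"{path}:{lineno}: weight {wtok!r} not numeric")
            w = float(wtok)
            if not (0.0 <= w <= 1.0):
                raise NetworkFormatError(
                    f"{path}:{lineno}: weight {w} outside [0, 1]"
                )
            if a == b:
                n_self += 1
                continue
            key = (a, b) if a <= b else (b, a)
            prev = edges.get(key)
            if prev is not None and prev != w:
                raise NetworkFormatError(
                    f"{path}:{lineno}: conflicting duplicate edge "
                    f"({key[0]}, {key[1]}): {prev} vs {w}"
                )
            edges[key] = w
    if n_self:
        logger.warning("%s: dropped %d self-loop(s)", path, n_self)
    net = FunctionalNetwork(edges)
    logger.info("%s: %d nodes, %d edges", path, net.n_nodes, net.n_edges)
    return net


def write_edge_list(net: FunctionalNetwork, path: str | Path, delimiter: str = "\t") -> None:
    """Write the network back out, one canonical edge per line."""
    path = Path(path)
    with path.open("w") as fh:
        for (a, b), w in sorted(net.edges().items()):
            fh.write(f"{a}{delimiter}{b}{delimiter}{w:g}\n")


# -- annotations -----------------------------------------------------------


def load_gene_annotations(
    path: str | Path, format: str = "tsv"
) -> list[GeneAnnotation]:
    """Read gene annotations in ``bed``, ``tsv`` or ``gff`` form.

    BED is 0-based half-open with gene_id in column 4 and is converted to the
    internal 1-based closed convention; the TSV dialect is
    (gene_id, chrom, start, end), already 1-based closed; the GFF subset uses
    columns 1/4/5 and an ``ID=`` attribute.  Duplicate gene ids raise.
    """
    path = Path(path)
    if format not in {"bed", "tsv", "gff", "gff-subset"}:
        raise ValueError(f"unknown annotation format {format!r}")
    records: list[GeneAnnotation] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if format == "bed":
                    chrom, start0, end, gid = fields[0], fields[1], fields[2], fields[3]
                    rec = GeneAnnotation(gid, chrom, int(start0) + 1, int(end))
                elif format in ("gff", "gff-subset"):
                    chrom, start, end, attrs = fields[0], fields[3], fields[4], fields[8]
                    gid = None
                    for kv in attrs.replace(" ", "").split(";"):
                        if kv.startswith("ID="):
                            gid = kv[3:]
                            break
                    if gid is None:
                        raise AnnotationFormatError("missing ID= attribute")
                    rec = GeneAnnotation(gid, chrom, int(start), int(end))
                else:  # tsv
                    gid, chrom, start, end = fields[0], fields[1], fields[2], fields[3]
                    if lineno == 1 and not (_is_number(start) and _is_number(end)):
                        continue  # header
                    rec = GeneAnnotation(gid, chrom, int(start), int(end))
            except (IndexError, ValueError) as exc:
                if isinstance(exc, AnnotationFormatError):
                    raise AnnotationFormatError(f"{path}:{lineno}: {exc}") from None
                raise AnnotationFormatError(f"{path}:{lineno}: {exc}") from None
            records.append(rec)
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.gene_id] = seen.get(rec.gene_id, 0) + 1
    dups = sorted(g for g, c in seen.items() if c > 1)
    if dups:
        raise AnnotationFormatError(f"{path}: duplicate gene_id(s): {', '.join(dups)}")
    if not records:
        logger.warning("%s: no annotation records found", path)
    return records


def write_gene_annotations(records: Sequence[GeneAnnotation], path: str | Path) -> None:
    """Write annotations as 4-column TSV (gene_id, chrom, start, end)."""
    with Path(path).open("w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.chrom}\t{r.start}\t{r.end}\n")


# -- feature construction --------------------------------------------------


def feature_vector(
    net: FunctionalNetwork, gene: str, positives: Sequence[str]
) -> np.ndarray:
    """Connectivity feature vector of ``gene`` against ordered ``positives``.

    Entry *i* is the network weight between ``gene`` and ``positives[i]``
    (0 when unconnected); a gene's entry against itself is 0.
    """
    if gene not in net:
        raise GeneLookupError(f"gene {gene!r} not in network")
    nbrs = net.neighbors(gene)
    vec = np.zeros(len(positives))
    for i, p in enumerate(positives):
        if p not in net:
            raise GeneLookupError(f"positive {p!r} not in network")
        if p != gene:
            vec[i] = nbrs.get(p, 0.0)
    return vec
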