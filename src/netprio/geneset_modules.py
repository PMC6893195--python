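"""Trait gene sets and their decomposition into trainable functional modules.

Gene sets attached to a trait term (e.g. "anaphylaxis") are often far larger
than the few hundred genes at which network-based SVM classifiers perform
best.  Large sets are therefore decomposed into functional modules by
community detection on the subnetwork they induce in the functional genomic
network: greedy modularity maximization (Clauset–Newman–Moore "fast greedy",
weighted), applied recursively until every module has fewer than ``max_size``
genes (default 400 — a 300-gene ceiling over-fragments typical sets).
Each resulting module is one SVM training unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import igraph as ig

from .network_io import FunctionalNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "FunctionalModule",
    "Partition",
    "load_gene_sets",
    "exclude_genes",
    "fast_greedy_partition",
    "iterative_cluster",
    "write_modules",
    "read_modules",
]


@dataclass(frozen=True)
class GeneSet:
    """A named set of trait-associated genes."""

    term: str
    genes: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.term!r} is empty")


@dataclass(frozen=True)
class FunctionalModule:
    """One ≤400-gene cluster of a term gene set; the SVM training unit."""

    term: str
    module_index: int
    genes: frozenset[str]


@dataclass
class Partition:
    """A community assignment with its (weighted) modularity."""

    assignment: dict[str, int]
    modularity: float

    def communities(self) -> list[list[str]]:
        """Communities as sorted gene lists, in label order."""
        out: dict[int, list[str]] = {}
        for g, lab in self.assignment.items():
            out.setdefault(lab, []).append(g)
        return [sorted(out[lab]) for lab in sorted(out)]


def load_gene_sets(directory: str | Path) -> list[GeneSet]:
    """Load every ``*.txt`` file in a directory as one gene set.

    One gene symbol/ID per line; the file stem becomes the term.  Duplicate
    lines are de-duplicated with a logged count; files with no valid lines
    are skipped with a warning; an empty directory is an error.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.txt"))
    if not files:
        raise FileNotFoundError(f"no *.txt gene set files in {directory}")
    sets: list[GeneSet] = []
    for f in files:
        lines = [ln.strip() for ln in f.read_text(encoding="utf-8").splitlines()]
        lines = [ln for ln in lines if ln and not ln.startswith("#")]
        genes = frozenset(lines)
        if not genes:
            logger.warning("%s: no valid gene lines, set skipped", f)
            continue
        n_dup = len(lines) - len(genes)
        if n_dup:
            logger.warning("%s: %d duplicate line(s) removed", f, n_dup)
        sets.append(GeneSet(term=f.stem, genes=genes, provenance=str(f)))
    if not sets:
        raise FileNotFoundError(f"no non-empty gene set files in {directory}")
    return sets


def exclude_genes(gs: GeneSet, excluded: Iterable[str]) -> GeneSet:
    """Remove genes (e.g. positional candidates) from a training set.

    Removing the locus genes before training prevents the classifiers from
    trivially memorizing the genes they are later asked to score.  Raises if
    nothing remains.
    """
    excluded = set(excluded)
    remaining = frozenset(gs.genes - excluded)
    n_removed = len(gs.genes) - len(remaining)
    if not remaining:
        raise ValueError(
            f"term {gs.term!r}: all {len(gs.genes)} genes excluded; untrainable"
        )
    if n_removed:
        logger.info("term %s: excluded %d gene(s) from training", gs.term, n_removed)
    prov = gs.provenance
    if n_removed:
        prov = (prov + "; " if prov else "") + f"excluded {n_removed} genes"
    return GeneSet(term=gs.term, genes=remaining, provenance=prov)


def fast_greedy_partition(net: FunctionalNetwork, genes: Iterable[str]) -> Partition:
    """Weighted fast-greedy (CNM) community detection on an induced subgraph.

    Builds the subgraph of the functional network induced by ``genes``
    (members absent from the network are dropped with a log line), runs
    greedy agglomerative modularity maximization on edge weights, and returns
    the maximum-modularity cut of the merge dendrogram.  An edgeless subgraph
    yields a single community with a warning.
    """
    genes = set(genes)
    present = sorted(g for g in genes if g in net)
    n_absent = len(genes) - len(present)
    if n_absent:
        logger.info("partition: %d gene(s) absent from network, excluded", n_absent)
    if len(present) < 2:
        raise ValueError("need ≥2 genes present in the network to partition")
    edges = net.subgraph_edges(present)
    if not edges:
        logger.warning("induced subgraph has no edges; single community returned")
        return Partition({g: 0 for g in present}, 0.0)
    idx = {g: i for i, g in enumerate(present)}
    g = ig.Graph(
        n=len(present),
        edges=[(idx[a], idx[b]) for a, b, _ in edges],
        edge_attrs={"weight": [w for _, _, w in edges]},
    )
    dendro = g.community_fastgreedy(weights="weight")
    clustering = dendro.as_clustering()
    membership = clustering.membership
    modularity = g.modularity(membership, weights="weight")
    return Partition({gene: membership[idx[gene]] for gene in present}, modularity)


def iterative_cluster(
    net: FunctionalNetwork, gs: GeneSet, max_size: int = 400
) -> list[FunctionalModule]:
    """Split a gene set into functional modules of fewer than ``max_size`` genes.

    The set is first mapped onto the network (absent genes dropped, logged).
    If the mapped set is already below ``max_size`` it becomes a single
    module.  Otherwise fast-greedy partitioning is applied recursively to
    every community of size ≥ ``max_size``; a community the algorithm cannot
    split (one community returned) is accepted as-is with a warning, which
    guarantees termination.  Module indices are assigned in discovery order,
    starting at 1.
    """
    if max_size < 2:
        raise ValueError("max_size must be ≥ 2")
    mapped = sorted(g for g in gs.genes if g in net)
    n_absent = len(gs.genes) - len(mapped)
    if n_absent:
        logger.info(
            "term %s: %d/%d genes absent from network", gs.term, n_absent, len(gs.genes)
        )
    if not mapped:
        raise ValueError(f"term {gs.term!r}: no genes present in the network")

    modules: list[FunctionalModule] = []
    queue: list[list[str]] = [mapped]
    next_index = 1
    while queue:
        group = queue.pop(0)
        if len(group) < max_size or len(group) < 2:
            modules.append(
                FunctionalModule(gs.term, next_index, frozenset(group))
            )
            next_index += 1
            continue
        part = fast_greedy_partition(net, group)
        comms = part.communities()
        if len(comms) == 1:
            logger.warning(
                "term %s: %d-gene community unsplittable; kept oversize",
                gs.term,
                len(group),
            )
            modules.append(FunctionalModule(gs.term, next_index, frozenset(group)))
            next_index += 1
            continue
        queue = comms + queue  # depth-first: refine this set before siblings
    for m in modules:
        if len(m.genes) < 10:
            logger.warning(
                "term %s module %d has only %d genes; SVM training may be unstable",
                m.term,
                m.module_index,
                len(m.genes),
            )
    return modules


def write_modules(modules: Sequence[FunctionalModule], path: str | Path) -> None:
    """TSV dump: one (term, module_index, gene_id) row per member gene."""
    with Path(path).open("w") as fh:
        fh.write("term\tmodule_index\tgene_id\n")
        for m in modules:
            for g in sorted(m.genes):
                fh.write(f"{m.term}\t{m.module_index}\t{g}\n")


def read_modules(path: str | Path) -> list[FunctionalModule]:
    groups: dict[tuple[str, int], set[str]] = {}
    with Path(path).open() as fh:
        header = fh.readline()
        if not header.startswith("term\t"):
            raise ValueError(f"{path}: missing module TSV header")
        for line in fh:
            term, idx, gene = line.rstrip("\n").split("\t")
            groups.setdefault((term, int(idx)), set()).add(gene)
    return [
        FunctionalModule(term, idx, frozenset(genes))
        for (term, idx), genes in sorted(groups.items())
    ]
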