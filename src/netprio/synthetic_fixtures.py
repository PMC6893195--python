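"""Synthetic inputs with the statistical structure the method assumes.

Three generators produce a self-contained, seeded test world:

* a planted-partition functional network — modules of genes densely
  connected by high Beta-distributed weights (mean 0.8) over a sparse
  low-weight background (mean 0.05), mimicking a thresholded "top edges"
  network dump;
* trait gene sets built from planted modules plus configurable noise genes,
  standing in for curated term lists;
* an inbred strain cohort — haplotype-structured genotypes derived from a
  few ancestral prototypes (inducing non-trivial kinship), one causal SNP
  inside the body of a module gene in the locus, and a binary phenotype
  whose probability rises from ``background_rate`` to ``penetrance`` on the
  alternate allele.

Genes are laid out along one chromosome in a seeded shuffled order, so
module membership is independent of position (as in real genomes); the
locus is a contiguous coordinate window and its genes are the positional
candidates.  Everything is byte-reproducible from (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network_io import (
    FunctionalNetwork,
    GeneAnnotation,
    write_edge_list,
    write_gene_annotations,
)
from .geneset_modules import GeneSet
from .association import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FixtureConfig",
    "FixtureTruth",
    "generate_network",
    "generate_gene_sets",
    "generate_cohort",
    "write_fixture",
]

GENE_SPACING = 100_000  # bp between gene starts
GENE_LENGTH = 20_000  # bp gene body
BETA_CONCENTRATION = 10.0  # a+b for edge-weight Beta draws


@dataclass
class FixtureConfig:
    """Stated world of the synthetic benchmark.

    Defaults: a 2000-gene network with three planted 150-gene modules
    (within-module weight mean 0.8 vs 0.05 background, background mean
    degree 50, matching a thresholded functional network); gene sets with
    10% noise genes; a 23-strain panel (the size of a typical inbred strain
    survey) typed at ``n_snps`` locus SNPs plus as many background SNPs for
    kinship; a near-Mendelian binary trait (penetrance 0.9 vs 0.05
    background).
    """

    n_genes: int = 2000
    n_modules: int = 3
    module_size: int = 150
    within_weight_mean: float = 0.8
    between_weight_mean: float = 0.05
    mean_degree: float = 50.0
    geneset_noise_frac: float = 0.1
    n_strains: int = 23
    n_snps: int = 400
    chrom: str = "chr1"
    locus: tuple[str, int, int] = ("chr1", 45_000_000, 55_000_000)
    causal_gene_index: int | None = None
    penetrance: float = 0.9
    background_rate: float = 0.05
    n_haplotype_groups: int = 4
    snps_per_block: int = 25
    haplotype_divergence: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size * self.n_modules > self.n_genes:
            raise ValueError("module_size × n_modules exceeds n_genes")
        if not (0 <= self.background_rate < self.penetrance <= 1):
            raise ValueError("need background_rate < penetrance, both in [0, 1]")
        for frac in (self.within_weight_mean, self.between_weight_mean):
            if not (0 < frac < 1):
                raise ValueError("weight means must lie in (0, 1)")
        if not (0 <= self.geneset_noise_frac <= 1):
            raise ValueError("geneset_noise_frac must lie in [0, 1]")
        if isinstance(self.locus, list):
            self.locus = tuple(self.locus)  # type: ignore[assignment]


@dataclass
class FixtureTruth:
    """Planted ground truth used by recovery tests."""

    module_membership: dict[str, int | None]
    causal_gene: str
    causal_snp: str | None = None


def _gene_ids(cfg: FixtureConfig) -> list[str]:
    width = len(str(cfg.n_genes - 1))
    return [f"g{i:0{width}d}" for i in range(cfg.n_genes)]


def gene_annotation_for(cfg: FixtureConfig, index: int) -> GeneAnnotation:
    """Deterministic coordinates: genes tile the chromosome every 100 kb."""
    start = 1 + index * GENE_SPACING
    return GeneAnnotation(_gene_ids(cfg)[index], cfg.chrom, start, start + GENE_LENGTH - 1)


def _beta_params(mean: float) -> tuple[float, float]:
    return mean * BETA_CONCENTRATION, (1.0 - mean) * BETA_CONCENTRATION


def _locus_gene_indices(cfg: FixtureConfig) -> list[int]:
    chrom, lo, hi = cfg.locus
    if chrom != cfg.chrom:
        raise ValueError("locus chromosome differs from fixture chromosome")
    out = []
    for i in range(cfg.n_genes):
        start = 1 + i * GENE_SPACING
        end = start + GENE_LENGTH - 1
        if start <= hi and end >= lo:
            out.append(i)
    if not out:
        raise ValueError("locus contains no genes")
    return out


def generate_network(cfg: FixtureConfig) -> tuple[FunctionalNetwork, FixtureTruth]:
    """Planted-partition weighted network plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    ids = _gene_ids(cfg)
    n = cfg.n_genes

    # module membership over a seeded permutation: position-independent
    perm = rng.permutation(n)
    membership: dict[str, int | None] = {g: None for g in ids}
    module_members: list[list[int]] = []
    for m in range(cfg.n_modules):
        block = sorted(perm[m * cfg.module_size : (m + 1) * cfg.module_size])
        module_members.append(block)
        for i in block:
            membership[ids[i]] = m

    # the causal gene: a module-0 gene inside the locus (forced if needed)
    locus_idx = _locus_gene_indices(cfg)
    if cfg.causal_gene_index is not None:
        causal_idx = cfg.causal_gene_index
        if causal_idx not in locus_idx:
            raise ValueError("causal_gene_index lies outside the locus")
        if membership[ids[causal_idx]] is None:
            raise ValueError("causal_gene_index is not a planted-module gene")
    else:
        in_locus = [i for i in module_members[0] if i in set(locus_idx)]
        if in_locus:
            causal_idx = in_locus[0]
        else:  # swap a locus gene into module 0
            swap_in = locus_idx[len(locus_idx) // 2]
            swap_out = module_members[0][0]
            membership[ids[swap_out]] = None
            membership[ids[swap_in]] = 0
            module_members[0] = sorted(
                [i for i in module_members[0] if i != swap_out] + [swap_in]
            )
            causal_idx = swap_in

    edges: dict[tuple[str, str], float] = {}
    aw, bw = _beta_params(cfg.within_weight_mean)
    for block in module_members:
        k = len(block)
        ws = rng.beta(aw, bw, size=k * (k - 1) // 2)
        t = 0
        for ii in range(k):
            for jj in range(ii + 1, k):
                a, b = ids[block[ii]], ids[block[jj]]
                edges[(a, b) if a <= b else (b, a)] = float(ws[t])
                t += 1

    # sparse background: mean background degree = cfg.mean_degree
    n_bg = int(n * cfg.mean_degree / 2)
    ab, bb = _beta_params(cfg.between_weight_mean)
    i_idx = rng.integers(0, n, size=int(n_bg * 1.3))
    j_idx = rng.integers(0, n, size=int(n_bg * 1.3))
    ws = rng.beta(ab, bb, size=len(i_idx))
    added = 0
    for i, j, w in zip(i_idx, j_idx, ws):
        if added >= n_bg:
            break
        if i == j:
            continue
        a, b = ids[i], ids[j]
        key = (a, b) if a <= b else (b, a)
        if key in edges:
            continue
        edges[key] = float(w)
        added += 1

    net = FunctionalNetwork(edges, extra_nodes=ids)
    truth = FixtureTruth(module_membership=membership, causal_gene=ids[causal_idx])
    logger.info(
        "fixture network: %d nodes, %d edges, causal gene %s",
        net.n_nodes,
        net.n_edges,
        truth.causal_gene,
    )
    return net, truth


def generate_gene_sets(cfg: FixtureConfig, truth: FixtureTruth) -> list[GeneSet]:
    """One trait term per planted module, plus uniform noise genes.

    Term *k*'s set is module *k* plus ``geneset_noise_frac × module_size``
    genes drawn uniformly from outside that module; the causal gene's module
    is module 0, so it is always covered by ≥1 term.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    ids = sorted(truth.module_membership)
    sets = []
    for m in range(cfg.n_modules):
        members = sorted(g for g, lab in truth.module_membership.items() if lab == m)
        non_members = [g for g in ids if truth.module_membership[g] != m]
        n_noise = int(round(cfg.geneset_noise_frac * len(members)))
        noise = (
            [non_members[i] for i in rng.choice(len(non_members), n_noise, replace=False)]
            if n_noise
            else []
        )
        sets.append(
            GeneSet(
                term=f"term{m}",
                genes=frozenset(members) | frozenset(noise),
                provenance=f"planted module {m} + {n_noise} noise genes",
            )
        )
    return sets


def generate_cohort(
    cfg: FixtureConfig, truth: FixtureTruth
) -> tuple[GenotypeMatrix, pd.Series, list[GeneAnnotation]]:
    """Strain panel, binary phenotype, and gene annotations.

    Genotypes are mosaic haplotypes: position-sorted SNPs are grouped into
    blocks of ``snps_per_block``, and within each block every strain copies
    one of ``n_haplotype_groups`` ancestral prototypes (re-drawn per block,
    emulating historical recombination) with ``haplotype_divergence``
    per-SNP noise.  Linkage is therefore local — proxies of the causal SNP
    occur only inside its own block — while shared ancestry across blocks
    induces non-trivial kinship.  ``n_snps`` SNPs tile the locus (one forced
    into the causal gene's body, alternate allele carried by half the
    haplotype groups) and another ``n_snps`` tile the rest of the chromosome
    for kinship estimation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    ids = _gene_ids(cfg)
    annotations = [gene_annotation_for(cfg, i) for i in range(cfg.n_genes)]
    chrom_len = cfg.n_genes * GENE_SPACING + GENE_LENGTH
    _, lo, hi = cfg.locus

    locus_pos = np.sort(rng.integers(lo, hi + 1, size=cfg.n_snps))
    causal_gene_ann = next(a for a in annotations if a.gene_id == truth.causal_gene)
    causal_pos = (causal_gene_ann.start + causal_gene_ann.end) // 2
    locus_pos[np.argmin(np.abs(locus_pos - causal_pos))] = causal_pos
    locus_pos = np.sort(locus_pos)
    causal_j = int(np.where(locus_pos == causal_pos)[0][0])

    outside = rng.integers(1, chrom_len, size=cfg.n_snps * 3)
    outside = np.sort(outside[(outside < lo) | (outside > hi)][: cfg.n_snps])

    positions = np.concatenate([outside, locus_pos])
    order = np.argsort(positions, kind="stable")
    positions = positions[order]
    n_total = len(positions)

    strains = [f"S{k:02d}" for k in range(cfg.n_strains)]
    n_blocks = max(1, int(np.ceil(n_total / cfg.snps_per_block)))
    block_of = np.minimum(np.arange(n_total) // cfg.snps_per_block, n_blocks - 1)
    # per-block ancestry: each strain copies one prototype per block
    groups = rng.integers(
        0, cfg.n_haplotype_groups, size=(cfg.n_strains, n_blocks)
    )
    proto = rng.integers(
        0, 2, size=(cfg.n_haplotype_groups, n_total)
    ).astype(float)
    calls = proto[groups[:, block_of], np.arange(n_total)[None, :]]
    flips = rng.random((cfg.n_strains, n_total)) < cfg.haplotype_divergence
    calls = np.where(flips, 1.0 - calls, calls)

    snp_ids = np.array([f"snp{k:05d}" for k in range(n_total)])
    # locate the causal SNP after the global sort
    causal_flat = len(outside) + causal_j
    causal_col = int(np.where(order == causal_flat)[0][0])
    # balanced causal allele: half the haplotype groups carry the alternate,
    # following the causal SNP's own block ancestry (local LD only)
    alt_groups = set(range(max(1, cfg.n_haplotype_groups // 2)))
    causal_groups = groups[:, block_of[causal_col]]
    calls[:, causal_col] = np.array(
        [1.0 if gg in alt_groups else 0.0 for gg in causal_groups]
    )
    if len(np.unique(calls[:, causal_col])) < 2:  # pathological draw: force split
        calls[: cfg.n_strains // 2, causal_col] = 1.0
        calls[cfg.n_strains // 2 :, causal_col] = 0.0

    prob = np.where(
        calls[:, causal_col] == 1.0, cfg.penetrance, cfg.background_rate
    )
    phenotype = pd.Series(
        (rng.random(cfg.n_strains) < prob).astype(float), index=strains
    )

    snps = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": cfg.chrom,
            "pos": positions.astype(int),
        }
    )
    g = GenotypeMatrix(strains=strains, snps=snps, calls=calls)
    truth.causal_snp = str(snp_ids[causal_col])
    logger.info(
        "fixture cohort: %d strains, %d SNPs (%d in locus), causal SNP %s",
        cfg.n_strains,
        n_total,
        len(locus_pos),
        truth.causal_snp,
    )
    return g, phenotype, annotations


def write_fixture(cfg: FixtureConfig, out_dir: str | Path) -> FixtureTruth:
    """Materialize a complete fixture directory in the pipeline's file formats."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    net, truth = generate_network(cfg)
    gene_sets = generate_gene_sets(cfg, truth)
    genotypes, phenotype, annotations = generate_cohort(cfg, truth)

    write_edge_list(net, out_dir / "network.tsv")
    gs_dir = out_dir / "gene_sets"
    gs_dir.mkdir(exist_ok=True)
    for gs in gene_sets:
        (gs_dir / f"{gs.term}.txt").write_text(
            "\n".join(sorted(gs.genes)) + "\n", encoding="utf-8"
        )
    write_gene_annotations(annotations, out_dir / "annotations.tsv")

    gdf = genotypes.snps.copy()
    for k, s in enumerate(genotypes.strains):
        gdf[s] = genotypes.calls[k]
    gdf.to_csv(out_dir / "genotypes.tsv", sep="\t", index=False)
    phenotype.rename_axis("strain").rename("value").to_frame().to_csv(
        out_dir / "phenotype.tsv", sep="\t"
    )

    (out_dir / "truth.json").write_text(
        json.dumps(
            {
                "causal_gene": truth.causal_gene,
                "causal_snp": truth.causal_snp,
                "module_membership": truth.module_membership,
            },
            indent=1,
        )
    )
    cfg_dict = asdict(cfg)
    cfg_dict["locus"] = list(cfg.locus)
    (out_dir / "fixture.yaml").write_text(yaml.safe_dump(cfg_dict))
    return truth
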