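"""End-to-end orchestration: files in, ranked candidate genes out.

The pipeline wires the stages together in the order the method runs:
load network/annotations/gene sets → exclude positional candidates from
training sets → cluster each set into ≤400-gene modules → train an SVM
ensemble per module and calibrate per-gene FPRs → functional score (max
−log10 FPR over modules) → mixed-model SNP scan (or precomputed p-values)
→ assign SNPs to nearest genes within 1 Mb → combined score + Pareto
front → ranked outputs.

Every stage writes an intermediate TSV into the output directory and logs
its counts, so single stages can be re-run and inspected.  A single master
seed deterministically derives per-module, per-run sub-seeds; reruns with
the same config are bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import geneset_modules as gsm
from . import integration as integ
from . import network_io as nio
from . import svm_ensemble as svm

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "positional_candidates"]


@dataclass
class PipelineConfig:
    """Paths and parameters for one full run."""

    network: str
    gene_sets_dir: str
    annotations: str
    locus: tuple[str, int, int]
    out_dir: str
    seed: int
    genotypes: str | None = None
    phenotype: str | None = None
    snp_pvalues: str | None = None
    annotation_format: str = "tsv"
    n_runs: int = 100
    folds: int = 10
    max_size: int = 400
    max_refinements: int = 5
    alpha: float = 0.05
    bonferroni_n: int | None = None  # default: number of SNPs scanned
    kinship_exclude_locus: bool = True
    scan_locus_only: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        raw: dict[str, Any] = (
            json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        )
        raw["locus"] = tuple(raw["locus"])
        cfg = cls(**raw)
        cfg.validate(base=path.parent)
        return cfg

    def validate(self, base: Path | None = None) -> None:
        """Check that every referenced input exists before any compute."""

        def resolve(p: str) -> Path:
            q = Path(p)
            if not q.is_absolute() and base is not None:
                q = base / q
            return q

        for name in ("network", "gene_sets_dir", "annotations"):
            p = resolve(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"config {name}: {p} does not exist")
            setattr(self, name, str(p))
        if self.snp_pvalues is None and (
            self.genotypes is None or self.phenotype is None
        ):
            raise ValueError(
                "config must provide either snp_pvalues or genotypes+phenotype"
            )
        for name in ("genotypes", "phenotype", "snp_pvalues"):
            val = getattr(self, name)
            if val is not None:
                p = resolve(val)
                if not p.exists():
                    raise FileNotFoundError(f"config {name}: {p} does not exist")
                setattr(self, name, str(p))
        if self.seed is None:
            raise ValueError("config must set a seed")


def positional_candidates(
    annotations: list[nio.GeneAnnotation], locus: tuple[str, int, int]
) -> list[nio.GeneAnnotation]:
    """Genes whose body overlaps the locus interval."""
    chrom, lo, hi = locus
    return [
        a for a in annotations if a.chrom == chrom and a.start <= hi and a.end >= lo
    ]


def _module_seed(master: int, term_index: int, module_index: int) -> np.random.Generator:
    # counter-based: adding modules never perturbs other modules' randomness
    return np.random.default_rng(
        np.random.SeedSequence([int(master), term_index, module_index])
    )


def run_pipeline(cfg: PipelineConfig) -> integ.GeneScoreTable:
    """Run every stage and return the ranked combined-score table."""
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "load_network"
    try:
        net = nio.load_edge_list(cfg.network)
        annotations = nio.load_gene_annotations(
            cfg.annotations, format=cfg.annotation_format
        )
        ann_by_id = {a.gene_id: a for a in annotations}
        candidates = positional_candidates(annotations, cfg.locus)
        if not candidates:
            raise ValueError(f"no genes overlap locus {cfg.locus}")
        cand_ids = [a.gene_id for a in candidates]
        logger.info("stage %s: %d positional candidates", stage, len(cand_ids))

        stage = "gene_sets"
        gene_sets = gsm.load_gene_sets(cfg.gene_sets_dir)
        training_sets = [gsm.exclude_genes(gs, set(cand_ids)) for gs in gene_sets]

        stage = "cluster"
        all_modules: list[gsm.FunctionalModule] = []
        for gs in training_sets:
            all_modules.extend(gsm.iterative_cluster(net, gs, max_size=cfg.max_size))
        gsm.write_modules(all_modules, out_dir / "modules.tsv")
        logger.info("stage %s: %d modules from %d terms", stage, len(all_modules),
                    len(training_sets))

        stage = "train"
        universe = list(net.nodes)
        ensembles: list[svm.EnsembleScores] = []
        term_index = {gs.term: i for i, gs in enumerate(training_sets)}
        for mod in all_modules:
            rng = _module_seed(cfg.seed, term_index[mod.term], mod.module_index)
            ensembles.append(
                svm.train_ensemble(
                    net,
                    mod,
                    universe,
                    n_runs=cfg.n_runs,
                    rng=rng,
                    folds=cfg.folds,
                    max_refinements=cfg.max_refinements,
                )
            )
        svm.write_module_scores(ensembles, out_dir / "module_scores.tsv")

        stage = "functional_score"
        per_module_fpr = {
            (es.module.term, es.module.module_index): es.fpr for es in ensembles
        }
        func = integ.functional_score(per_module_fpr, genes=cand_ids)

        stage = "association"
        if cfg.snp_pvalues is not None:
            res = assoc.load_snp_pvalues(cfg.snp_pvalues)
        else:
            genotypes = assoc.load_genotypes(cfg.genotypes)
            phenotype = assoc.load_phenotype(cfg.phenotype)
            kin = assoc.compute_kinship(
                genotypes,
                exclude_region=cfg.locus if cfg.kinship_exclude_locus else None,
            )
            mask = genotypes.region_mask(cfg.locus) if cfg.scan_locus_only else None
            res = assoc.snp_lrt_scan(phenotype, genotypes, kin, snp_mask=mask)
        n_tests = cfg.bonferroni_n or len(res.per_snp)
        res.threshold = assoc.bonferroni_threshold(cfg.alpha, n_tests)
        assoc.write_snp_results(res, out_dir / "snp_pvalues.tsv")
        n_sig = int((res.per_snp["p_value"] <= res.threshold).sum())
        logger.info(
            "stage %s: %d SNPs scanned, %d significant at %.3g",
            stage, len(res.per_snp), n_sig, res.threshold,
        )

        stage = "assign_snps"
        res = assoc.assign_snps_to_genes(res, candidates)
        assoc.write_gene_results(res, out_dir / "gene_association.tsv")

        stage = "combined_score"
        scored = {g for es in ensembles for g in es.mean_score}
        table = integ.combined_score(
            func,
            res.per_gene,
            cand_ids,
            locus=cfg.locus,
            per_module=per_module_fpr,
            scored_genes=scored,
        )

        stage = "write_outputs"
        integ.write_ranked_outputs(
            table,
            out_dir,
            annotations=ann_by_id,
            snp_table=res.per_snp,
            threshold=res.threshold,
        )
        logger.info("pipeline complete: %d ranked genes", len(table.rows))
        return table
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
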