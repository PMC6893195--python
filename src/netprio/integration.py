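"""Combined gene scores and Pareto-front candidate selection.

Two lines of evidence meet here for every positional candidate gene in a
locus: a functional score, max over all trained modules of -log10(FPR_SVM),
and a positional score, max over assigned SNPs of -log10(p) from the
mixed-model scan.  Each term is normalized by its maximum over the
positional candidates and the combined gene score is their sum,

    S_cg = -log10(p) / max_cand(-log10(p))
         + -log10(FPR) / max_cand(-log10(FPR)),

so S_cg lies in [0, 2] and a gene attaining both maxima scores exactly 2.
The Pareto front — genes not strictly dominated in the two normalized
coordinates — marks the frontier of best trade-off candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network_io import GeneAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "GeneScoreRow",
    "GeneScoreTable",
    "functional_score",
    "combined_score",
    "pareto_front",
    "write_ranked_outputs",
    "read_ranked_genes",
]

#: module FPR at or below this gets the high-confidence flag in the matrix
MODULE_FLAG_FPR = 0.2


@dataclass
class GeneScoreRow:
    gene_id: str
    neglog10_p: float
    neglog10_fpr: float
    norm_positional: float
    norm_functional: float
    s_cg: float
    pareto: bool = False
    not_in_network: bool = False
    per_module_scores: dict[tuple[str, int], float] = field(default_factory=dict)


@dataclass
class GeneScoreTable:
    """Positional candidates ranked by combined score (ties by gene_id)."""

    rows: list[GeneScoreRow]
    locus: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        self.rows.sort(key=lambda r: (-r.s_cg, r.gene_id))

    def row(self, gene_id: str) -> GeneScoreRow:
        for r in self.rows:
            if r.gene_id == gene_id:
                return r
        raise KeyError(gene_id)

    def rank(self, gene_id: str) -> int:
        """1-based rank of a gene in the S_cg ordering."""
        for i, r in enumerate(self.rows, start=1):
            if r.gene_id == gene_id:
                return i
        raise KeyError(gene_id)


def functional_score(
    per_module_fpr: Mapping[tuple[str, int], Mapping[str, float]],
    genes: Sequence[str] | None = None,
) -> dict[str, float]:
    """Per-gene functional score: max of -log10(FPR) over all modules.

    Taking the max rewards a strong association with a single module over
    uniformly lukewarm association with many.  Genes scored by no module
    (absent from the network) get 0.  FPRs must be strictly positive — the
    upstream floor guarantees this.
    """
    if not per_module_fpr:
        raise ValueError("no modules scored")
    out: dict[str, float] = {}
    for key, fprs in per_module_fpr.items():
        for g, fpr in fprs.items():
            if fpr <= 0:
                raise ValueError(f"module {key}: non-positive FPR for {g}")
            score = -np.log10(fpr)
            if score > out.get(g, -np.inf):
                out[g] = float(score)
    if genes is not None:
        missing = [g for g in genes if g not in out]
        if missing:
            logger.info("%d gene(s) not scored by any module (score 0)", len(missing))
        out = {g: out.get(g, 0.0) for g in genes}
    return out


def combined_score(
    func: Mapping[str, float],
    pos: Mapping[str, float],
    candidates: Sequence[str],
    locus: tuple[str, int, int] | None = None,
    per_module: Mapping[tuple[str, int], Mapping[str, float]] | None = None,
    scored_genes: set[str] | None = None,
) -> GeneScoreTable:
    """Normalize both evidence terms over the candidates and sum them.

    ``func`` and ``pos`` are raw -log10 scores (missing candidates count as
    0).  Each term is divided by its maximum over the candidates; a zero
    maximum zeroes that term for every gene with a warning.  ``per_module``
    optionally carries per-module FPRs, recorded per row as -log10(FPR).
    ``scored_genes`` marks which genes the network could score at all.
    """
    if not candidates:
        raise ValueError("no positional candidates")
    cand = sorted(set(candidates))
    f_raw = np.array([float(func.get(g, 0.0)) for g in cand])
    p_raw = np.array([float(pos.get(g, 0.0)) for g in cand])
    f_max = f_raw.max()
    p_max = p_raw.max()
    if f_max <= 0:
        logger.warning("max functional score over candidates is 0; term zeroed")
        f_norm = np.zeros_like(f_raw)
    else:
        f_norm = f_raw / f_max
    if p_max <= 0:
        logger.warning("max positional score over candidates is 0; term zeroed")
        p_norm = np.zeros_like(p_raw)
    else:
        p_norm = p_raw / p_max
    rows = []
    for i, g in enumerate(cand):
        pm: dict[tuple[str, int], float] = {}
        if per_module:
            for key, fprs in per_module.items():
                if g in fprs:
                    pm[key] = float(-np.log10(fprs[g]))
        rows.append(
            GeneScoreRow(
                gene_id=g,
                neglog10_p=float(p_raw[i]),
                neglog10_fpr=float(f_raw[i]),
                norm_positional=float(p_norm[i]),
                norm_functional=float(f_norm[i]),
                s_cg=float(p_norm[i] + f_norm[i]),
                not_in_network=(scored_genes is not None and g not in scored_genes),
                per_module_scores=pm,
            )
        )
    table = GeneScoreTable(rows=rows, locus=locus)
    pareto_front(table)
    return table


def pareto_front(table: GeneScoreTable) -> list[str]:
    """Flag and return the genes not strictly dominated in the score plane.

    Gene g is on the front iff no other gene is ≥ g in both normalized
    coordinates and > in at least one.  Duplicated points dominate each
    other in neither direction and can share the front.
    """
    if not table.rows:
        raise ValueError("empty score table")
    pts = sorted(
        table.rows, key=lambda r: (-r.norm_positional, -r.norm_functional, r.gene_id)
    )
    front: list[str] = []
    best_func_prev = -np.inf  # max functional among strictly larger positional
    i = 0
    while i < len(pts):
        j = i
        while j < len(pts) and pts[j].norm_positional == pts[i].norm_positional:
            j += 1
        group = pts[i:j]
        group_max = max(r.norm_functional for r in group)
        for r in group:
            r.pareto = r.norm_functional == group_max and r.norm_functional > best_func_prev
        best_func_prev = max(best_func_prev, group_max)
        i = j
    for r in table.rows:
        if r.pareto:
            front.append(r.gene_id)
    return front


# -- outputs ---------------------------------------------------------------


def _table_frame(
    table: GeneScoreTable,
    annotations: Mapping[str, GeneAnnotation] | None = None,
) -> pd.DataFrame:
    rows = []
    for r in table.rows:
        ann = annotations.get(r.gene_id) if annotations else None
        rows.append(
            {
                "gene_id": r.gene_id,
                "chrom": ann.chrom if ann else "",
                "start": ann.start if ann else "",
                "end": ann.end if ann else "",
                "neglog10_p": r.neglog10_p,
                "neglog10_fpr": r.neglog10_fpr,
                "norm_positional": r.norm_positional,
                "norm_functional": r.norm_functional,
                "s_cg": r.s_cg,
                "pareto": r.pareto,
                "not_in_network": r.not_in_network,
            }
        )
    return pd.DataFrame(rows)


def write_ranked_outputs(
    table: GeneScoreTable,
    out_dir: str | Path,
    annotations: Mapping[str, GeneAnnotation] | None = None,
    snp_table: pd.DataFrame | None = None,
    threshold: float | None = None,
) -> dict[str, Path]:
    """Write ranked genes, the gene × module score matrix, and the SNP track.

    The module matrix carries, per module, the -log10(FPR) functional term,
    a flag column marking FPR ≤ 0.2 (high-confidence functional association),
    and a per-module combined score (positional term + that module's
    normalized functional term).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ranked = out_dir / "ranked_genes.tsv"
    _table_frame(table, annotations).to_csv(ranked, sep="\t", index=False)
    paths["ranked_genes"] = ranked

    module_keys = sorted({k for r in table.rows for k in r.per_module_scores})
    if not module_keys:
        logger.warning("no module scores present; module matrix has 0 module columns")
    f_max = max((r.neglog10_fpr for r in table.rows), default=0.0)
    flag_score = -np.log10(MODULE_FLAG_FPR)
    mat_rows = []
    for r in table.rows:
        row: dict[str, object] = {"gene_id": r.gene_id, "s_cg": r.s_cg}
        for term, idx in module_keys:
            s = r.per_module_scores.get((term, idx))
            col = f"{term}.m{idx}"
            row[f"{col}.neglog10_fpr"] = "" if s is None else s
            row[f"{col}.flag"] = "" if s is None else ("*" if s >= flag_score else "")
            if s is None or f_max <= 0:
                row[f"{col}.s_cg"] = ""
            else:
                row[f"{col}.s_cg"] = r.norm_positional + s / f_max
        mat_rows.append(row)
    matrix = out_dir / "module_matrix.tsv"
    pd.DataFrame(mat_rows).to_csv(matrix, sep="\t", index=False)
    paths["module_matrix"] = matrix

    track = out_dir / "snp_track.tsv"
    if snp_table is not None:
        df = snp_table.copy()
        df["neglog10_p"] = -np.log10(np.maximum(df["p_value"].to_numpy(), 1e-300))
        if threshold is not None:
            df["significant"] = df["p_value"] <= threshold
        df.to_csv(track, sep="\t", index=False)
    else:
        pd.DataFrame(
            columns=["snp_id", "chrom", "pos", "p_value", "neglog10_p"]
        ).to_csv(track, sep="\t", index=False)
    paths["snp_track"] = track
    return paths


def read_ranked_genes(path: str | Path) -> GeneScoreTable:
    """Re-load a ranked_genes.tsv written by :func:`write_ranked_outputs`."""
    df = pd.read_csv(path, sep="\t")
    rows = [
        GeneScoreRow(
            gene_id=str(r.gene_id),
            neglog10_p=float(r.neglog10_p),
            neglog10_fpr=float(r.neglog10_fpr),
            norm_positional=float(r.norm_positional),
            norm_functional=float(r.norm_functional),
            s_cg=float(r.s_cg),
            pareto=bool(r.pareto),
            not_in_network=bool(r.not_in_network),
        )
        for r in df.itertuples(index=False)
    ]
    return GeneScoreTable(rows=rows)
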