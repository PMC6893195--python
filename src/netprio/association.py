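"""Mixed-model SNP association and per-gene positional scores.

An inbred strain panel is scanned SNP-by-SNP for association with a (here
binary, treated as quantitative) phenotype under the linear mixed model

    y = X b + u + e,   u ~ N(0, sg2 * K),   e ~ N(0, se2 * I),

where K is a strain kinship matrix.  Modelling relatedness as a random
effect controls the inflated false-association rate caused by population
structure.  K is estimated as identity-by-state proportions, *excluding*
the SNPs of the locus under test so that the tested signal does not absorb
itself into the covariance ("proximal contamination").

Each SNP is tested by a maximum-likelihood likelihood-ratio test: the model
is profiled over the variance ratio delta = se2/sg2 via a single
eigendecomposition of K plus 1-D optimization (grid + golden-section),
the LRT statistic 2*(ll_full - ll_null) is referred to chi-square(1), and a
Bonferroni threshold declares significance.  SNP p-values are reduced to a
per-gene positional score: each SNP is assigned to the nearest gene body
within 1 Mb, and a gene's score is the maximum -log10(p) over its SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .network_io import GeneAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "AssociationResult",
    "load_genotypes",
    "load_phenotype",
    "load_snp_pvalues",
    "compute_kinship",
    "lmm_ml_loglik",
    "snp_lrt_scan",
    "bonferroni_threshold",
    "assign_snps_to_genes",
]

P_FLOOR = 1e-300  # p-values floored here before -log10
_DELTA_GRID = np.logspace(-5, 5, 64)
_SIGMA_FLOOR = 1e-12


@dataclass
class GenotypeMatrix:
    """Biallelic inbred calls: rows = strains, columns = SNPs (0/1/NaN)."""

    strains: list[str]
    snps: pd.DataFrame  # columns: snp_id, chrom, pos
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.strains), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.strains)} strains, {len(self.snps)} SNPs)"
            )
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"SNP positions not sorted within {chrom}")

    def region_mask(self, region: tuple[str, int, int] | None) -> np.ndarray:
        """Boolean mask of SNPs inside (chrom, start, end), inclusive."""
        if region is None:
            return np.zeros(len(self.snps), dtype=bool)
        chrom, start, end = region
        return (
            (self.snps["chrom"] == chrom)
            & (self.snps["pos"] >= start)
            & (self.snps["pos"] <= end)
        ).to_numpy()


@dataclass
class KinshipMatrix:
    """Symmetric strain-by-strain identity-by-state proportions in [0, 1]."""

    strains: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.strains), len(self.strains)):
            raise ValueError("kinship shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("kinship not symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("kinship values outside [0, 1]")
        self.values = v


@dataclass
class AssociationResult:
    """Per-SNP mixed-model p-values plus the per-gene reduction."""

    per_snp: pd.DataFrame  # snp_id, chrom, pos, p_value, flag
    threshold: float | None = None
    per_gene: dict[str, float] = field(default_factory=dict)
    gene_detail: pd.DataFrame | None = None  # gene_id, n_snps, best_snp, max_neglog10p
    n_unassigned: int = 0


# -- input formats ---------------------------------------------------------


def load_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a genotype TSV: rows = SNPs (snp_id, chrom, pos, strain columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["snp_id", "chrom", "pos"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: first columns must be {required}")
    strains = list(df.columns[3:])
    if not strains:
        raise ValueError(f"{path}: no strain columns")
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    calls = (
        df[strains]
        .apply(pd.to_numeric, errors="coerce")
        .to_numpy(dtype=float)
        .T
    )
    snps = df[required].copy()
    return GenotypeMatrix(strains=strains, snps=snps, calls=calls)


def load_phenotype(path: str | Path) -> pd.Series:
    """Read a 2-column (strain, value) TSV into a Series indexed by strain."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (strain, value)")
    s = pd.Series(
        pd.to_numeric(df.iloc[:, 1]).to_numpy(), index=df.iloc[:, 0].astype(str)
    )
    if s.isna().any():
        raise ValueError(f"{path}: non-numeric phenotype values")
    return s


def load_snp_pvalues(path: str | Path) -> AssociationResult:
    """Read a precomputed association table (snp_id, chrom, pos, p)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    cols = {c.lower(): c for c in df.columns}
    for need in ("snp_id", "chrom", "pos"):
        if need not in cols:
            raise ValueError(f"{path}: missing column {need}")
    pcol = cols.get("p") or cols.get("p_value")
    if pcol is None:
        raise ValueError(f"{path}: missing p-value column ('p' or 'p_value')")
    out = pd.DataFrame(
        {
            "snp_id": df[cols["snp_id"]].astype(str),
            "chrom": df[cols["chrom"]].astype(str),
            "pos": df[cols["pos"]].astype(int),
            "p_value": pd.to_numeric(df[pcol]),
            "flag": "",
        }
    )
    bad = ~((out["p_value"] > 0) & (out["p_value"] <= 1))
    if bad.any():
        raise ValueError(f"{path}: {int(bad.sum())} p-values outside (0, 1]")
    return AssociationResult(per_snp=out)


# -- kinship ---------------------------------------------------------------


def compute_kinship(
    g: GenotypeMatrix, exclude_region: tuple[str, int, int] | None = None
) -> KinshipMatrix:
    """Pairwise-complete identity-by-state kinship, excluding a region.

    K[i, j] is the fraction of SNPs (outside ``exclude_region``, non-missing
    in both strains) at which strains i and j carry the same allele.
    """
    keep = ~g.region_mask(exclude_region)
    if not keep.any():
        raise ValueError("all SNPs fall inside the excluded region")
    calls = g.calls[:, keep]
    valid = ~np.isnan(calls)
    if not valid.any(axis=1).all():
        bad = [s for s, ok in zip(g.strains, valid.any(axis=1)) if not ok]
        raise ValueError(f"strain(s) with all-missing calls: {bad}")
    a = np.where(valid, calls, 0.0)
    c = np.where(valid, 1.0 - calls, 0.0)
    matches = a @ a.T + c @ c.T
    denom = valid.astype(float) @ valid.astype(float).T
    if (denom == 0).any():
        raise ValueError("a strain pair shares no genotyped SNPs")
    k = matches / denom
    k = np.clip((k + k.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(k, 1.0)
    logger.info(
        "kinship from %d SNPs (%d excluded)", int(keep.sum()), int((~keep).sum())
    )
    return KinshipMatrix(strains=list(g.strains), values=k)


# -- mixed model -----------------------------------------------------------


def _psd_eigh(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    K = (K + K.T) / 2.0
    lam, U = np.linalg.eigh(K)
    if lam.min() < -1e-8:
        logger.info("kinship eigenvalues clipped at 0 (min %.3g)", lam.min())
    lam = np.clip(lam, 0.0, None)
    return lam, U


def _ml_loglik_at_delta(
    ytil: np.ndarray, Xtil: np.ndarray, lam: np.ndarray, delta: float
) -> float:
    n = len(ytil)
    d = lam + delta
    w = 1.0 / d
    XtWX = (Xtil * w[:, None]).T @ Xtil
    XtWy = (Xtil * w[:, None]).T @ ytil
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        raise ValueError("singular fixed-effect design") from None
    r = ytil - Xtil @ beta
    sg2 = max(float(np.mean(r * r * w)), _SIGMA_FLOOR)
    return float(-0.5 * (n * np.log(2 * np.pi * sg2) + np.sum(np.log(d)) + n))


def _profile_ml(
    ytil: np.ndarray, Xtil: np.ndarray, lam: np.ndarray
) -> tuple[float, float]:
    """Maximize the ML log-likelihood over delta on a log grid + refinement."""
    if np.linalg.matrix_rank(Xtil) < Xtil.shape[1]:
        raise ValueError("singular fixed-effect design")
    lls = np.array([_ml_loglik_at_delta(ytil, Xtil, lam, d) for d in _DELTA_GRID])
    i = int(np.argmax(lls))
    lo = _DELTA_GRID[max(i - 1, 0)]
    hi = _DELTA_GRID[min(i + 1, len(_DELTA_GRID) - 1)]
    res = optimize.minimize_scalar(
        lambda t: -_ml_loglik_at_delta(ytil, Xtil, lam, float(np.exp(t))),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    delta = float(np.exp(res.x))
    ll = -float(res.fun)
    if lls[i] > ll:  # grid point beat the refinement (flat likelihood)
        ll, delta = float(lls[i]), float(_DELTA_GRID[i])
    if i in (0, len(_DELTA_GRID) - 1):
        logger.debug("delta at grid boundary (%.3g)", delta)
    return ll, delta


def lmm_ml_loglik(
    y: np.ndarray, X: np.ndarray, K: KinshipMatrix | np.ndarray
) -> tuple[float, float]:
    """Maximum-likelihood fit of the kinship mixed model.

    Returns ``(loglik, delta)`` where ``delta = se2/sg2`` maximizes the
    profiled Gaussian likelihood.  K is symmetrized and eigenvalue-clipped
    at 0 if needed.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    if X.shape[0] != len(y):
        raise ValueError("design/phenotype dimension mismatch")
    if not np.isfinite(y).all():
        raise ValueError("non-finite phenotype values")
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    if Kv.shape != (len(y), len(y)):
        raise ValueError("kinship dimension mismatch")
    lam, U = _psd_eigh(Kv)
    return _profile_ml(U.T @ y, U.T @ X, lam)


def snp_lrt_scan(
    y: pd.Series | np.ndarray,
    g: GenotypeMatrix,
    K: KinshipMatrix,
    snp_mask: np.ndarray | None = None,
) -> AssociationResult:
    """Likelihood-ratio mixed-model scan over SNPs.

    For each SNP the ML log-likelihood of intercept+genotype is compared to
    the intercept-only null under the same kinship; 2*(ll1 - ll0) is referred
    to chi-square with 1 df.  Monomorphic SNPs and SNPs with <3 informative
    strains get p = 1 with a flag; SNPs with missing calls among phenotyped
    strains are dropped (count logged).  ``snp_mask`` restricts the scan to a
    subset of SNP columns (e.g. the locus).
    """
    if isinstance(y, pd.Series):
        missing = [s for s in g.strains if s not in y.index]
        if missing:
            raise ValueError(f"phenotype missing for strain(s): {missing[:5]}")
        yv = y.loc[g.strains].to_numpy(dtype=float)
    else:
        yv = np.asarray(y, dtype=float).ravel()
        if len(yv) != len(g.strains):
            raise ValueError("phenotype length != number of strains")
    if list(K.strains) != list(g.strains):
        raise ValueError("kinship strains not aligned with genotype strains")
    if not np.isfinite(yv).all():
        raise ValueError("non-finite phenotype values")

    lam, U = _psd_eigh(K.values)
    ytil = U.T @ yv
    ones = np.ones((len(yv), 1))
    Xtil_null = U.T @ ones
    ll0, _ = _profile_ml(ytil, Xtil_null, lam)

    idx = np.arange(len(g.snps)) if snp_mask is None else np.flatnonzero(snp_mask)
    rows = []
    n_dropped_na = 0
    for j in idx:
        snp = g.snps.iloc[j]
        x = g.calls[:, j]
        if np.isnan(x).any():
            n_dropped_na += 1
            continue
        flag = ""
        counts = np.unique(x)
        if len(counts) < 2:
            p, flag = 1.0, "monomorphic"
        elif len(x) < 3:
            p, flag = 1.0, "too_few_strains"
        else:
            X = np.column_stack([np.ones_like(x), x])
            ll1, _ = _profile_ml(ytil, U.T @ X, lam)
            lrt = max(0.0, 2.0 * (ll1 - ll0))
            p = float(stats.chi2.sf(lrt, df=1))
            p = min(max(p, P_FLOOR), 1.0)
        rows.append((snp["snp_id"], snp["chrom"], int(snp["pos"]), p, flag))
    if n_dropped_na:
        logger.info("scan: %d SNP(s) dropped for missing calls", n_dropped_na)
    per_snp = pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "p_value", "flag"]
    )
    return AssociationResult(per_snp=per_snp)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha {alpha} outside (0, 1]")
    if n_tests < 1:
        raise ValueError(f"n_tests must be ≥ 1, got {n_tests}")
    return alpha / n_tests


def assign_snps_to_genes(
    res: AssociationResult,
    genes: Sequence[GeneAnnotation],
    max_dist: int = 1_000_000,
) -> AssociationResult:
    """Assign each SNP to the nearest gene body within ``max_dist``.

    Distance to a gene is 0 inside the gene body, otherwise the gap to the
    nearest edge; equidistant ties go to the gene with the smaller start
    coordinate.  A gene's positional score is the maximum -log10(p) over its
    assigned SNPs (0 when none); SNPs with no gene within range, or on a
    chromosome without genes, stay unassigned (counted).
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for rec in genes:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    for recs in by_chrom.values():
        recs.sort(key=lambda r: (r.start, r.end, r.gene_id))

    assigned_gene: list[str] = []
    n_unassigned = 0
    for snp in res.per_snp.itertuples(index=False):
        cands = by_chrom.get(snp.chrom)
        best: tuple[int, int, str] | None = None  # (dist, start, gene_id)
        if cands:
            for rec in cands:
                d = rec.distance_to(int(snp.pos))
                key = (d, rec.start, rec.gene_id)
                if best is None or key < best:
                    best = key
        if best is None or best[0] > max_dist:
            assigned_gene.append("")
            n_unassigned += 1
        else:
            assigned_gene.append(best[2])
    per_snp = res.per_snp.copy()
    per_snp["assigned_gene"] = assigned_gene
    if n_unassigned:
        logger.info("%d SNP(s) not assigned to any gene", n_unassigned)

    per_gene: dict[str, float] = {rec.gene_id: 0.0 for rec in genes}
    detail_rows = []
    grouped = per_snp[per_snp["assigned_gene"] != ""].groupby("assigned_gene")
    best_by_gene: dict[str, tuple[float, str, int]] = {}
    for gid, grp in grouped:
        neglog = -np.log10(np.maximum(grp["p_value"].to_numpy(), P_FLOOR))
        i = int(np.argmax(neglog))
        best_by_gene[gid] = (float(neglog[i]), str(grp["snp_id"].iloc[i]), len(grp))
    for rec in genes:
        score, best_snp, n_snps = best_by_gene.get(rec.gene_id, (0.0, "", 0))
        per_gene[rec.gene_id] = score
        detail_rows.append((rec.gene_id, n_snps, best_snp, score))
    gene_detail = pd.DataFrame(
        detail_rows, columns=["gene_id", "n_snps", "best_snp", "max_neglog10p"]
    )
    return replace(
        res,
        per_snp=per_snp,
        per_gene=per_gene,
        gene_detail=gene_detail,
        n_unassigned=n_unassigned,
    )


def write_snp_results(res: AssociationResult, path: str | Path) -> None:
    """Per-SNP TSV with p-values and a significance column."""
    df = res.per_snp.copy()
    if res.threshold is not None:
        df["significant"] = df["p_value"] <= res.threshold
    df.to_csv(path, sep="\t", index=False)


def write_gene_results(res: AssociationResult, path: str | Path) -> None:
    if res.gene_detail is None:
        raise ValueError("assign_snps_to_genes has not been run")
    res.gene_detail.to_csv(path, sep="\t", index=False)
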