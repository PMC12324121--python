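"""Polygenic index construction and trio genotype auditing.

A polygenic index (PGI) is a weighted sum of trait-associated effect-allele
dosages. This module reads GWAS summary statistics (dropping
strand-ambiguous variants), selects variants by p-value threshold, scores
genotype matrices (weighted by the GWAS effect size, or unweighted by its
sign), standardizes scores against the complete-trio reference subsample,
and audits trio genotype consistency via the Mendelian-error rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SumStats",
    "PGISet",
    "read_sumstats",
    "select_snps",
    "score",
    "standardize_pgi",
    "mendelian_error_rate",
]

log = logging.getLogger(__name__)

_VALID_ALLELES = {"A", "C", "G", "T"}
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}
_REQUIRED_COLS = ("SNP", "A1", "A2", "BETA", "P")


@dataclass
class SumStats:
    """Per-variant effect-allele weights from a GWAS.

    ``table`` columns: SNP (variant id), A1 (effect allele), A2 (other
    allele), BETA (effect per A1 allele), P (association p-value).
    ``n_ambiguous_dropped`` counts strand-symmetric (A/T, C/G) variants
    removed at read time; ``clumped`` records whether LD clumping was
    applied (never, here: simulated SNPs are LD-free).
    """

    table: pd.DataFrame
    n_ambiguous_dropped: int = 0
    clumped: bool = False

    def __post_init__(self):
        missing = [c for c in _REQUIRED_COLS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        t = self.table
        bad = ~(t["A1"].isin(_VALID_ALLELES) & t["A2"].isin(_VALID_ALLELES))
        if bad.any():
            raise ValueError(
                f"invalid alleles for variants: {t.loc[bad, 'SNP'].tolist()[:5]}")
        if ((t["P"] <= 0) | (t["P"] > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        dup = t["SNP"][t["SNP"].duplicated()].unique()
        if len(dup):
            raise ValueError(f"duplicate variant ids: {list(dup)[:10]}")

    def __len__(self) -> int:
        return len(self.table)


def read_sumstats(path: str) -> SumStats:
    """Read whitespace/tab-delimited summary statistics with a header.

    Strand-ambiguous rows (A/T or C/G allele pairs) are dropped and counted;
    extra columns are tolerated. Missing required columns or duplicated
    variant ids raise ``ValueError``.
    """
    table = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in _REQUIRED_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    pairs = table.apply(lambda r: frozenset((r["A1"], r["A2"])), axis=1) \
        if len(table) else pd.Series([], dtype=object)
    ambiguous = pairs.map(lambda p: p in _AMBIGUOUS) if len(table) \
        else pd.Series([], dtype=bool)
    n_dropped = int(ambiguous.sum()) if len(table) else 0
    table = table.loc[~ambiguous].reset_index(drop=True) if len(table) else table
    return SumStats(table=table, n_ambiguous_dropped=n_dropped)


def select_snps(sumstats: SumStats, p_threshold: float = 5e-8) -> SumStats:
    """Retain variants with ``P < p_threshold`` (strict inequality).

    LD clumping is not performed — the synthetic SNPs are independent — and
    the result carries ``clumped=False`` so users of real data know the gap.
    """
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError("p_threshold must be in (0, 1]")
    kept = sumstats.table[sumstats.table["P"] < p_threshold].reset_index(drop=True)
    return SumStats(table=kept,
                    n_ambiguous_dropped=sumstats.n_ambiguous_dropped,
                    clumped=False)


def score(genotypes: np.ndarray, snp_ids, sumstats: SumStats,
          weighted: bool = True, counted_alleles=None) -> np.ndarray:
    """Raw PGI: ``sum_j beta_j g_ij`` (weighted) or ``sum_j sign(beta_j) g_ij``.

    ``genotypes`` is persons x SNPs with dosages counting ``counted_alleles``
    (defaults to the summary-statistics effect allele). When the counted
    allele is the GWAS other allele the dosage is flipped to ``2 - g`` (the
    flip is logged); any other mismatch is an error, as is a summary-
    statistics variant absent from the genotype matrix.
    """
    if len(sumstats) == 0:
        raise ValueError("no variants in summary statistics; nothing to score")
    snp_ids = np.asarray(snp_ids)
    genotypes = np.asarray(genotypes)
    pos = {s: i for i, s in enumerate(snp_ids)}
    missing = [s for s in sumstats.table["SNP"] if s not in pos]
    if missing:
        raise KeyError(f"variants absent from genotypes: {missing[:10]}")
    idx = np.array([pos[s] for s in sumstats.table["SNP"]])
    G = genotypes[:, idx].astype(float)
    if counted_alleles is not None:
        counted = np.asarray(counted_alleles)[idx]
        a1 = sumstats.table["A1"].to_numpy()
        a2 = sumstats.table["A2"].to_numpy()
        flip = counted == a2
        ok = flip | (counted == a1)
        if not ok.all():
            bad = sumstats.table["SNP"].to_numpy()[~ok]
            raise ValueError(f"counted allele matches neither GWAS allele "
                             f"for: {bad[:10].tolist()}")
        if flip.any():
            log.info("flipped dosage orientation (2 - g) for %d variants",
                     int(flip.sum()))
            G[:, flip] = 2.0 - G[:, flip]
    beta = sumstats.table["BETA"].to_numpy(dtype=float)
    w = beta if weighted else np.sign(beta)
    return G @ w


@dataclass
class PGISet:
    """Raw and reference-standardized polygenic scores for a set of persons."""

    raw: np.ndarray
    standardized: np.ndarray
    n_snps_used: int
    weighted: bool = True
    p_threshold: float | None = None
    reference_mean: float = field(default=np.nan)
    reference_sd: float = field(default=np.nan)


def standardize_pgi(raw: np.ndarray, reference_mask=None,
                    n_snps_used: int = 0, weighted: bool = True,
                    p_threshold: float | None = None) -> PGISet:
    """Scale scores to mean 0, SD 1 in the reference subsample.

    Reference moments are plain (not survey-weighted) mean/SD over
    ``reference_mask`` (default: all persons) and are applied to everyone,
    so persons outside the reference keep their offset relative to it.
    """
    raw = np.asarray(raw, dtype=float)
    mask = np.ones(len(raw), dtype=bool) if reference_mask is None \
        else np.asarray(reference_mask, dtype=bool)
    ref = raw[mask]
    if len(ref) < 2:
        raise ValueError("reference subsample must contain >= 2 persons")
    mu, sd = float(np.mean(ref)), float(np.std(ref))
    if sd == 0.0:
        raise ValueError("reference scores have zero variance")
    return PGISet(raw=raw, standardized=(raw - mu) / sd,
                  n_snps_used=n_snps_used, weighted=weighted,
                  p_threshold=p_threshold, reference_mean=mu,
                  reference_sd=sd)


def mendelian_error_rate(geno_mother: np.ndarray, geno_father: np.ndarray,
                         geno_child: np.ndarray) -> dict:
    """Per-family percentage of SNPs with Mendelian-impossible genotypes.

    A SNP is in error for a family iff the child dosage cannot be formed by
    one allele from each parent. A parent with dosage 2 must transmit the
    effect allele and one with dosage 0 cannot, so the feasible child range
    is ``[1(gm=2) + 1(gf=2), 2 - 1(gm=0) - 1(gf=0)]``; any child dosage
    outside it is an error (this covers parents 0/0 with child >= 1, parents
    0/2 with child != 1, etc.). Returns per-family rates (%) and the cohort
    mean/median/max.
    """
    mats = []
    for g, who in ((geno_mother, "mother"), (geno_father, "father"),
                   (geno_child, "child")):
        if g is None:
            raise ValueError(f"missing {who} genotypes")
        g = np.atleast_2d(np.asarray(g))
        if not np.isin(g, (0, 1, 2)).all():
            raise ValueError(f"{who} dosages must be in {{0, 1, 2}}")
        mats.append(g)
    gm, gf, gc = mats
    if not gm.shape == gf.shape == gc.shape:
        raise ValueError("genotype matrices must share a shape")
    lo = (gm == 2).astype(int) + (gf == 2).astype(int)
    hi = 2 - (gm == 0).astype(int) - (gf == 0).astype(int)
    err = (gc < lo) | (gc > hi)
    per_family = 100.0 * err.mean(axis=1)
    return {
        "per_family_pct": per_family,
        "mean_pct": float(np.mean(per_family)),
        "median_pct": float(np.median(per_family)),
        "max_pct": float(np.max(per_family)),
    }
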