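"""Relative sweep ages and multinucleotide-mutation (MNM) evidence.

Sweep age proxy: a hard sweep clears linked variation; new mutations then
accumulate with time. The ratio of segregating tetraploid SNPs strictly
between a gene's first and last candidate amino-acid substitution (candidate
sites excluded) to that span in base pairs therefore ranks sweeps from
oldest (highest ratio) to youngest.

MNM evidence: a single multinucleotide mutational event yields closely
spaced substitutions with a transversion excess. Two tests per gene:
consecutive candidate spacings versus genomewide missense spacings
(Wilcoxon rank-sum) and the candidate transversion fraction versus the
genomewide fraction (two-proportion z test, one-sided for excess).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

_TRANSITIONS = ({"A", "G"}, {"C", "T"})
EXACT_WILCOXON_MAX = 20  # below this many observations, use the exact test


@dataclass
class SweepAgeResult:
    gene_id: str
    span_bp: int | None
    n_accumulated: int | None
    ratio: float | None
    reason: str | None = None
    rank: int | None = None


def sweep_age(gene_id: str, candidate_positions: np.ndarray,
              tetraploid_segregating_positions: np.ndarray) -> SweepAgeResult:
    """Accumulated-polymorphism ratio over the candidate span of one gene."""
    cand = np.unique(np.asarray(candidate_positions, dtype=np.int64))
    if cand.size < 2:
        return SweepAgeResult(gene_id, None, None, None,
                              reason="fewer than 2 candidate positions")
    lo, hi = int(cand.min()), int(cand.max())
    span = hi - lo
    seg = np.asarray(tetraploid_segregating_positions, dtype=np.int64)
    inside = (seg > lo) & (seg < hi) & ~np.isin(seg, cand)
    count = int(inside.sum())
    return SweepAgeResult(gene_id, span, count, count / span)


def rank_sweeps(results: list[SweepAgeResult]) -> list[SweepAgeResult]:
    """Rank genes by descending ratio; rank 1 = oldest. Ties share min-rank."""
    scored = [r for r in results if r.ratio is not None]
    ratios = np.array([r.ratio for r in scored])
    # min-rank for ties: 1 + number of strictly larger ratios
    ranks = np.array([1 + int((ratios > r).sum()) for r in ratios], dtype=int)
    if len(set(ranks)) != len(ranks):
        log.info("rank_sweeps: ties present; min-rank assigned")
    for r, rk in zip(scored, ranks):
        r.rank = int(rk)
    return sorted(results, key=lambda r: (r.rank is None, r.rank))


def consecutive_distances(positions: np.ndarray) -> np.ndarray:
    """Distances between consecutive sorted positions within one gene."""
    pos = np.sort(np.unique(np.asarray(positions, dtype=np.int64)))
    return np.diff(pos)


def is_transversion(ref: str, alt: str) -> bool:
    """True unless {ref, alt} is a purine-purine or pyrimidine-pyrimidine pair."""
    pair = {ref.upper(), alt.upper()}
    if len(pair) != 2 or not pair <= {"A", "C", "G", "T"}:
        raise ValueError(f"not a SNP allele pair: {ref}/{alt}")
    return pair not in _TRANSITIONS


def spacing_test(candidate_distances: np.ndarray,
                 genomewide_distances: np.ndarray) -> dict:
    """Wilcoxon rank-sum comparison of candidate vs genomewide spacings.

    Exact null distribution below EXACT_WILCOXON_MAX total observations
    (falling back to the asymptotic form when ties forbid it), otherwise the
    normal approximation with tie correction. Two-sided p.
    """
    cand = np.asarray(candidate_distances, dtype=float)
    gw = np.asarray(genomewide_distances, dtype=float)
    if cand.size < 2:
        return {"p": None, "median_candidate": None,
                "median_genomewide": float(np.median(gw)) if gw.size else None,
                "skipped": True}
    method = "exact" if cand.size + gw.size < EXACT_WILCOXON_MAX else "asymptotic"
    try:
        res = stats.mannwhitneyu(cand, gw, alternative="two-sided", method=method)
    except ValueError:
        res = stats.mannwhitneyu(cand, gw, alternative="two-sided",
                                 method="asymptotic")
    return {"p": float(res.pvalue), "median_candidate": float(np.median(cand)),
            "median_genomewide": float(np.median(gw)), "skipped": False}


def tstv_excess_test(k_tv: int, n: int, k_tv_gw: int, n_gw: int) -> dict:
    """Two-proportion z test for transversion excess over the genomewide rate.

    Pooled-variance z; one-sided p for candidate excess plus the two-sided p.
    z is None when the pooled proportion is 0 or 1.
    """
    if n < 1 or n_gw < 1:
        raise ValueError("both groups need at least one SNP")
    p1 = k_tv / n
    p2 = k_tv_gw / n_gw
    pooled = (k_tv + k_tv_gw) / (n + n_gw)
    if pooled in (0.0, 1.0):
        return {"z": None, "p_one_sided": None, "p_two_sided": None,
                "tv_fraction": p1, "tv_fraction_genomewide": p2}
    se = np.sqrt(pooled * (1 - pooled) * (1 / n + 1 / n_gw))
    z = (p1 - p2) / se
    p_one = float(stats.norm.sf(z))
    p_two = float(2 * stats.norm.sf(abs(z)))
    return {"z": float(z), "p_one_sided": p_one, "p_two_sided": p_two,
            "tv_fraction": p1, "tv_fraction_genomewide": p2}


@dataclass
class MNMReport:
    gene_id: str
    distances: list[int]
    median_distance_bp: float | None
    genomewide_median_bp: float | None
    spacing_p: float | None
    n_transversions: int
    n_transitions: int
    genomewide_tv_fraction: float
    tstv_z: float | None
    tstv_p: float | None
    mnm_flag: bool


def mnm_report(
    gene_id: str,
    candidate_positions: np.ndarray,
    candidate_alleles: list[tuple[str, str]],
    genomewide_distances: np.ndarray,
    k_tv_gw: int,
    n_gw: int,
    alpha: float = 0.01,
) -> MNMReport:
    """Per-gene MNM evidence: spacing and transversion-excess tests.

    ``mnm_flag`` requires both tests below ``alpha`` (spacing two-sided in
    the short direction is implied by the median comparison; the tv test is
    one-sided for excess).
    """
    dists = consecutive_distances(candidate_positions)
    sp = spacing_test(dists, genomewide_distances)
    tv_flags = [is_transversion(r, a) for r, a in candidate_alleles]
    k_tv = sum(tv_flags)
    n = len(tv_flags)
    tv = tstv_excess_test(k_tv, n, k_tv_gw, n_gw) if n else {
        "z": None, "p_one_sided": None, "p_two_sided": None,
        "tv_fraction": 0.0, "tv_fraction_genomewide": k_tv_gw / max(n_gw, 1)}
    shorter = (sp["median_candidate"] is not None
               and sp["median_genomewide"] is not None
               and sp["median_candidate"] < sp["median_genomewide"])
    flag = (not sp["skipped"] and sp["p"] is not None and sp["p"] < alpha
            and shorter
            and tv["p_one_sided"] is not None and tv["p_one_sided"] < alpha)
    return MNMReport(
        gene_id, [int(d) for d in dists], sp["median_candidate"],
        sp["median_genomewide"], sp["p"], k_tv, n - k_tv,
        tv["tv_fraction_genomewide"], tv["z"], tv["p_one_sided"], flag,
    )


def mnm_scan(
    candidates: pd.DataFrame,
    missense_table: pd.DataFrame,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """MNM reports for every gene with >= 2 candidate sites.

    ``candidates`` has columns gene, pos, ref, alt (candidate amino-acid
    substitutions, one contrast); ``missense_table`` has gene, pos, ref, alt
    for all missense sites genomewide (the spacing and ts/tv background).
    """
    gw_dists = np.concatenate([
        consecutive_distances(sub["pos"].to_numpy())
        for _, sub in missense_table.groupby("gene")
    ]) if len(missense_table) else np.array([])
    tv_gw = sum(
        is_transversion(r, a)
        for r, a in zip(missense_table["ref"], missense_table["alt"])
    )
    n_gw = len(missense_table)
    rows = []
    for gene, sub in candidates.groupby("gene"):
        if len(sub) < 2:
            continue
        rep = mnm_report(
            str(gene), sub["pos"].to_numpy(),
            list(zip(sub["ref"], sub["alt"])),
            gw_dists, tv_gw, n_gw, alpha,
        )
        rows.append({
            "gene": rep.gene_id,
            "n_candidates": len(sub),
            "median_distance_bp": rep.median_distance_bp,
            "genomewide_median_bp": rep.genomewide_median_bp,
            "spacing_p": rep.spacing_p,
            "n_transversions": rep.n_transversions,
            "n_transitions": rep.n_transitions,
            "genomewide_tv_fraction": rep.genomewide_tv_fraction,
            "tstv_z": rep.tstv_z,
            "tstv_p": rep.tstv_p,
            "mnm_flag": rep.mnm_flag,
        })
    return pd.DataFrame(rows)


__all__ = [
    "SweepAgeResult", "sweep_age", "rank_sweeps", "consecutive_distances",
    "is_transversion", "spacing_test", "tstv_excess_test", "MNMReport",
    "mnm_report", "mnm_scan",
]
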