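"""De novo versus standing variation: screens, HAF, Hamming distance/diameter.

A gene's candidate amino-acid substitutions define a haplotype. Three
criteria must all point toward de novo origin of the tetraploid haplotype:

A. at least one candidate derived allele is absent from every diploid
   individual in the full (unsubsampled) diploid panel;
B. no diploid individual carries the derived allele at *every* candidate
   site simultaneously (genotype co-occurrence stands in for phased
   haplotypes, which short-read mixed-ploidy data cannot deliver);
C. the diploid-tetraploid Hamming distance exceeds the Hamming diameter of
   the diploids, i.e. the tetraploid haplotype is more different from every
   diploid than any two diploids are from each other.

Genotypic distances are deliberately coarse lookup tables over dosage pairs
(a conservative "clearly different" call): diploid pairs are distant only as
opposite homozygotes; tetraploid pairs only when dosages differ by >= 3;
cross-ploidy pairs only when the diploid is homozygous and the tetraploid
carries at most one copy of the diploid's allele.

Haplotype allele frequencies are reconstructed per population from M_i, the
population frequency of the allele that is major in the combined sample:
HAFd = min M_i (ancestral, diploid-like), HAFa = 1 - max M_i (derived,
tetraploid-like), HAFr = 1 - HAFd - HAFa (recombinants).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

# distance-1 dosage pairs, transcribed pair lists (derived-allele dosage)
_DIPLOID_PAIRS = {(2, 0), (0, 2)}
_TETRAPLOID_PAIRS = {(4, 0), (3, 0), (4, 1), (0, 4), (0, 3), (1, 4)}
_CROSS_PAIRS = {(2, 0), (2, 1), (0, 4), (0, 3)}  # (diploid dosage, tetraploid dosage)


def genotypic_distance(d1: int, ploidy1: int, d2: int, ploidy2: int) -> int:
    """0/1 distance between two dosage genotypes; missing contributes 0."""
    if d1 == MISSING or d2 == MISSING:
        return 0
    for d, p in ((d1, ploidy1), (d2, ploidy2)):
        if not 0 <= d <= p:
            raise ValueError(f"dosage {d} invalid for ploidy {p}")
    if ploidy1 == 2 and ploidy2 == 2:
        return int((d1, d2) in _DIPLOID_PAIRS)
    if ploidy1 == 4 and ploidy2 == 4:
        return int((d1, d2) in _TETRAPLOID_PAIRS)
    if ploidy1 == 2 and ploidy2 == 4:
        return int((d1, d2) in _CROSS_PAIRS)
    if ploidy1 == 4 and ploidy2 == 2:
        return int((d2, d1) in _CROSS_PAIRS)
    raise ValueError(f"unsupported ploidy pair ({ploidy1}, {ploidy2})")


def hamming_distance(d1: np.ndarray, ploidy1: int, d2: np.ndarray, ploidy2: int) -> int:
    """Sum of genotypic distances across the candidate sites of a gene."""
    if len(d1) != len(d2):
        raise ValueError("genotype vectors differ in length")
    return sum(
        genotypic_distance(int(a), ploidy1, int(b), ploidy2)
        for a, b in zip(d1, d2)
    )


def hamming_diameter(dosages: np.ndarray, ploidies: np.ndarray) -> int:
    """Maximum pairwise Hamming distance within a group (0 for size <= 1)."""
    n = dosages.shape[1]
    best = 0
    for i in range(n):
        for j in range(i + 1, n):
            d = hamming_distance(dosages[:, i], int(ploidies[i]),
                                 dosages[:, j], int(ploidies[j]))
            best = max(best, d)
    return best


def cross_ploidy_distance(dip: np.ndarray, tet: np.ndarray,
                          statistic: str = "min") -> int:
    """Diploid-tetraploid Hamming distance over all cross pairs.

    ``min`` (default) is the conservative choice: if even the closest
    diploid-tetraploid pair exceeds the diploid diameter, no sampled diploid
    haplotype approaches the tetraploid one. ``median`` is also available.
    """
    dists = [
        hamming_distance(dip[:, i], 2, tet[:, j], 4)
        for i in range(dip.shape[1])
        for j in range(tet.shape[1])
    ]
    if not dists:
        raise ValueError("cross-ploidy distance needs both groups non-empty")
    if statistic == "min":
        return int(min(dists))
    if statistic == "median":
        return int(np.median(dists))
    raise ValueError(f"unknown statistic {statistic!r}")


def reconstruct_haf(m_vector) -> tuple[float, float, float]:
    """(HAFd, HAFa, HAFr) from the per-site major-allele frequencies M_i."""
    m = np.asarray(m_vector, dtype=float)
    if m.size == 0:
        raise ValueError("empty M vector")
    if np.any((m < 0) | (m > 1)):
        raise ValueError("M_i must lie in [0, 1]")
    hafd = float(m.min())
    hafa = float(1.0 - m.max())
    hafr = 1.0 - hafd - hafa
    return hafd, hafa, hafr


def standing_screen(gm_diploid: GenotypeMatrix,
                    candidate_keys: list[tuple[str, int]]) -> pd.DataFrame:
    """Presence of each tetraploid-derived candidate allele among diploids.

    ``present`` means at least one diploid individual carries >= 1 copy of
    the derived allele in the full diploid panel.
    """
    index = gm_diploid.variant_index()
    dd = gm_diploid.derived_dosage()
    rows = []
    for key in candidate_keys:
        if key not in index:
            raise KeyError(f"candidate site {key} absent from the diploid matrix")
        row = dd[index[key]]
        carriers = int(((row != MISSING) & (row >= 1)).sum())
        rows.append({"chrom": key[0], "pos": key[1],
                     "present": carriers > 0, "carrier_count": carriers})
    return pd.DataFrame(rows)


@dataclass
class HammingReport:
    gene_id: str
    n_sites: int
    diameter_diploid: int
    diameter_tetraploid: int
    distance_between: int
    de_novo_supported: bool  # distance_between > diameter_diploid


@dataclass
class DeNovoVerdict:
    gene_id: str
    criterion_A_absent_aas: bool
    criterion_B_absent_haplotype: bool
    criterion_C_distance_exceeds_diameter: bool

    @property
    def verdict(self) -> bool:
        return (self.criterion_A_absent_aas
                and self.criterion_B_absent_haplotype
                and self.criterion_C_distance_exceeds_diameter)


def _gene_matrices(gm: GenotypeMatrix, keys: list[tuple[str, int]]):
    index = gm.variant_index()
    missing_keys = [k for k in keys if k not in index]
    if missing_keys:
        raise KeyError(f"candidate sites absent from matrix: {missing_keys[:3]}")
    rows = np.array([index[k] for k in keys])
    dd = gm.derived_dosage()[rows]
    ploidies = gm.ploidy
    return dd, ploidies


def gene_hamming_report(gm: GenotypeMatrix, gene_id: str,
                        candidate_keys: list[tuple[str, int]],
                        statistic: str = "min") -> HammingReport:
    """Hamming diameters and the between-ploidy distance for one gene.

    Individuals missing more than half of the gene's candidate sites are
    excluded from the analysis; remaining missing genotypes contribute 0.
    """
    dd, ploidies = _gene_matrices(gm, candidate_keys)
    n_sites = len(candidate_keys)
    keep = (dd == MISSING).sum(axis=0) <= n_sites / 2
    dd = dd[:, keep]
    ploidies = ploidies[keep]
    dip = dd[:, ploidies == 2]
    tet = dd[:, ploidies == 4]
    diam_dip = hamming_diameter(dip, np.full(dip.shape[1], 2))
    diam_tet = hamming_diameter(tet, np.full(tet.shape[1], 4))
    between = cross_ploidy_distance(dip, tet, statistic)
    return HammingReport(gene_id, n_sites, diam_dip, diam_tet, between,
                         between > diam_dip)


def haplotype_presence_in_diploids(gm_diploid: GenotypeMatrix,
                                   candidate_keys: list[tuple[str, int]]) -> int:
    """Number of diploids carrying the derived allele at every candidate site.

    Missing genotypes cannot assert carriage and count as non-carrying.
    """
    dd, _ = _gene_matrices(gm_diploid, candidate_keys)
    carries = (dd != MISSING) & (dd >= 1)
    return int(carries.all(axis=0).sum())


def de_novo_verdict(gene_id: str, screen: pd.DataFrame,
                    n_full_haplotype_diploids: int,
                    report: HammingReport) -> DeNovoVerdict:
    """Combine the three criteria; the verdict is their conjunction."""
    if screen.empty:
        raise ValueError(f"gene {gene_id}: no candidate sites to judge")
    a = bool((~screen["present"]).any())
    b = n_full_haplotype_diploids == 0
    c = report.distance_between > report.diameter_diploid
    return DeNovoVerdict(gene_id, a, b, c)


def haf_table(gm: GenotypeMatrix, gene_id: str,
              candidate_keys: list[tuple[str, int]],
              group_by: str = "population") -> pd.DataFrame:
    """Reconstructed haplotype frequencies per population (or lineage).

    The major allele at each site is fixed once in the combined sample, then
    its frequency M_i is computed per group and reduced to HAFd/HAFa/HAFr.
    """
    dd, ploidies = _gene_matrices(gm, candidate_keys)
    nonmiss = dd != MISSING
    an = (nonmiss * ploidies[None, :]).sum(axis=1)
    ac = np.where(nonmiss, dd, 0).sum(axis=1)
    derived_is_major = ac / np.maximum(an, 1) > 0.5

    groups: dict[str, list[int]] = {}
    for i, ind in enumerate(gm.individuals):
        groups.setdefault(getattr(ind, group_by), []).append(i)
    rows = []
    for name in groups:
        cols = np.asarray(groups[name], dtype=np.intp)
        sub = dd[:, cols]
        sub_nonmiss = sub != MISSING
        g_an = (sub_nonmiss * ploidies[cols][None, :]).sum(axis=1)
        g_ac = np.where(sub_nonmiss, sub, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_derived = np.where(g_an > 0, g_ac / np.maximum(g_an, 1), np.nan)
        m = np.where(derived_is_major, f_derived, 1.0 - f_derived)
        m = m[np.isfinite(m)]
        if m.size == 0:
            continue
        hafd, hafa, hafr = reconstruct_haf(m)
        rows.append({"gene": gene_id, group_by: name, "HAFd": hafd,
                     "HAFa": hafa, "HAFr": hafr, "n_sites": int(m.size)})
    return pd.DataFrame(rows)


def rarefaction_curve(gm_diploid: GenotypeMatrix, site_mask: np.ndarray,
                      sample_sizes: list[int], n_reps: int,
                      seed: int) -> pd.DataFrame:
    """Mean fraction of segregating diploid variants recovered by subsamples.

    For each sample size s, averages over ``n_reps`` random subsets of s
    individuals the fraction (variants segregating in the subset) /
    (variants segregating in the full panel).
    """
    rng = np.random.default_rng(seed)
    dd = gm_diploid.derived_dosage()[np.flatnonzero(site_mask)]
    nonmiss = dd != MISSING
    seg_full = (np.where(nonmiss, dd, 0) > 0).any(axis=1)
    denom = int(seg_full.sum())
    if denom == 0:
        raise ValueError("no segregating variants in the full diploid panel")
    n_ind = dd.shape[1]
    rows = []
    for s in sample_sizes:
        if s > n_ind:
            raise ValueError(f"subsample of {s} exceeds panel of {n_ind}")
        fracs = []
        for _ in range(n_reps):
            cols = rng.choice(n_ind, size=s, replace=False)
            sub = dd[np.ix_(seg_full, cols)]
            seg = ((sub != MISSING) & (sub > 0)).any(axis=1)
            fracs.append(seg.sum() / denom)
        rows.append({"sample_size": s, "mean_fraction": float(np.mean(fracs)),
                     "n_reps": n_reps})
    return pd.DataFrame(rows)


__all__ = [
    "genotypic_distance", "hamming_distance", "hamming_diameter",
    "cross_ploidy_distance", "reconstruct_haf", "standing_screen",
    "HammingReport", "DeNovoVerdict", "gene_hamming_report",
    "haplotype_presence_in_diploids", "de_novo_verdict", "haf_table",
    "rarefaction_curve",
]
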