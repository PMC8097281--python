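"""Allele-frequency machinery, polarization, diversity and differentiation.

Implements the genotype filters (depth > 8, per-group missingness < 0.5),
chromosome-count subsampling, outgroup/minor-allele polarization, grouped
derived-allele frequencies, per-site nucleotide diversity, Tajima's D,
per-SNP Hudson F_ST (Bhatia ratio-of-estimates form), allele-frequency
difference and empirical neutral quantiles.

F_ST is computed per SNP rather than in windows: the outlier unit of the
downstream scan is the single amino-acid substitution. Negative F_ST values
are retained (they only matter below the outlier threshold) and chromosome
counts are the post-filter called-chromosome counts AN, not nominal sample
sizes, since missingness varies by site.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .datamodel import MISSING, GenotypeMatrix, Variant

log = logging.getLogger(__name__)


@dataclass
class FrequencyTable:
    """Derived-allele counts per (variant, group).

    ``f`` is AC/AN, NaN where AN == 0.
    """

    variants: list[Variant]
    groups: list[str]
    ac: np.ndarray  # (n_variants, n_groups) int
    an: np.ndarray  # (n_variants, n_groups) int

    @property
    def f(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.an > 0, self.ac / np.maximum(self.an, 1), np.nan)

    def group_index(self, group: str) -> int:
        return self.groups.index(group)

    def group_f(self, group: str) -> np.ndarray:
        return self.f[:, self.group_index(group)]

    def group_an(self, group: str) -> np.ndarray:
        return self.an[:, self.group_index(group)]


@dataclass
class DiversityResult:
    group: str
    pi: float
    tajima_d: float | None
    S: int
    n_sites: int
    n_chromosomes: int


def apply_genotype_filters(
    gm: GenotypeMatrix,
    min_depth: int = 8,
    max_missing: float = 0.5,
    grouping: dict[str, list[int]] | None = None,
) -> GenotypeMatrix:
    """Mask low-depth genotypes and drop variants with excess missingness.

    Genotypes with read depth <= ``min_depth`` are set missing (strictly
    greater depths are kept). Variants whose missing fraction is
    >= ``max_missing`` in any group are removed. ``grouping`` maps group name
    to individual column indices; default is one group per lineage.
    """
    if grouping is None:
        grouping = {}
        for i, ind in enumerate(gm.individuals):
            grouping.setdefault(ind.lineage, []).append(i)
    for name, idx in grouping.items():
        if len(idx) == 0:
            raise ValueError(f"empty group {name!r} in genotype filter")

    dosage = gm.dosage.copy()
    dosage[gm.depth <= min_depth] = MISSING
    keep = np.ones(gm.n_variants, dtype=bool)
    for idx in grouping.values():
        cols = np.asarray(idx, dtype=np.intp)
        miss_frac = (dosage[:, cols] == MISSING).mean(axis=1)
        keep &= miss_frac < max_missing
    filtered = GenotypeMatrix(gm.variants, gm.individuals, dosage, gm.depth.copy())
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("genotype filter dropped %d of %d variants", n_dropped, gm.n_variants)
    return filtered.take_variants(np.flatnonzero(keep))


def subsample_chromosomes(
    gm: GenotypeMatrix,
    group_indices: list[int],
    target_chromosomes: int,
    rule: str = "highest_depth",
    seed: int | None = None,
) -> np.ndarray:
    """Pick individuals from a group until their summed ploidy hits the target.

    Returns the selected column indices. ``rule`` is ``highest_depth`` (mean
    depth over all sites, ties by index) or ``random`` (requires ``seed``).
    """
    ploidies = np.array([gm.individuals[i].ploidy for i in group_indices])
    p = int(ploidies[0])
    if not (ploidies == p).all():
        raise ValueError("subsampling group mixes ploidies")
    if target_chromosomes % p != 0:
        raise ValueError(
            f"target of {target_chromosomes} chromosomes not representable "
            f"with ploidy-{p} individuals"
        )
    n_needed = target_chromosomes // p
    if n_needed > len(group_indices):
        raise ValueError(
            f"group of {len(group_indices)} individuals cannot supply "
            f"{target_chromosomes} chromosomes"
        )
    if rule == "highest_depth":
        mean_depth = gm.depth[:, group_indices].mean(axis=0)
        order = np.lexsort((np.arange(len(group_indices)), -mean_depth))
    elif rule == "random":
        if seed is None:
            raise ValueError("random subsampling rule requires a seed")
        order = np.random.default_rng(seed).permutation(len(group_indices))
    else:
        raise ValueError(f"unknown subsampling rule {rule!r}")
    chosen = sorted(np.asarray(group_indices)[order[:n_needed]])
    return np.array(chosen, dtype=np.intp)


def polarize(
    gm: GenotypeMatrix,
    outgroup_states: dict[tuple[str, int], str] | None = None,
) -> GenotypeMatrix:
    """Set the derived allele of each variant.

    The derived allele is the one absent from the outgroup consensus state;
    where the outgroup is uninformative, the overall minor-frequency allele
    is taken as derived. Exact 50/50 ties resolve to ALT (logged).
    """
    outgroup_states = outgroup_states or {}
    pl = gm.ploidy[None, :]
    nonmiss = gm.dosage != MISSING
    ac = np.where(nonmiss, gm.dosage, 0).sum(axis=1)
    an = (nonmiss * pl).sum(axis=1)
    n_ties = 0
    variants = []
    for v, var in enumerate(gm.variants):
        state = outgroup_states.get(var.key)
        if state == var.ref_allele:
            derived = "alt"
        elif state == var.alt_allele:
            derived = "ref"
        else:
            if an[v] == 0:
                derived = "alt"
            else:
                f_alt = ac[v] / an[v]
                if f_alt > 0.5:
                    derived = "ref"
                else:
                    if f_alt == 0.5:
                        n_ties += 1
                    derived = "alt"
        variants.append(Variant(var.chrom, var.pos, var.ref_allele,
                                var.alt_allele, derived))
    if n_ties:
        log.info("polarize: %d exact 0.5 ties resolved to ALT", n_ties)
    return GenotypeMatrix(variants, gm.individuals, gm.dosage.copy(), gm.depth.copy())


def group_frequencies(
    gm: GenotypeMatrix, grouping: dict[str, list[int]]
) -> FrequencyTable:
    """Derived AC/AN per group; AC sums derived dosage over non-missing
    genotypes, AN sums ploidy over non-missing genotypes."""
    dd = gm.derived_dosage()
    pl = gm.ploidy[None, :]
    groups = list(grouping)
    ac = np.zeros((gm.n_variants, len(groups)), dtype=np.int64)
    an = np.zeros_like(ac)
    for g, name in enumerate(groups):
        cols = np.asarray(grouping[name], dtype=np.intp)
        sub = dd[:, cols]
        nonmiss = sub != MISSING
        ac[:, g] = np.where(nonmiss, sub, 0).sum(axis=1)
        an[:, g] = (nonmiss * pl[:, cols]).sum(axis=1)
    return FrequencyTable(list(gm.variants), groups, ac, an)


def site_pi(ac, an):
    """Unbiased per-site heterozygosity 2j(n-j)/(n(n-1)).

    Accepts scalars or arrays; NaN where AN < 2.
    """
    ac = np.asarray(ac, dtype=float)
    an = np.asarray(an, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * ac * (an - ac) / (an * (an - 1.0))
    pi = np.where(an >= 2, pi, np.nan)
    return float(pi) if pi.ndim == 0 else pi


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "e1": e1, "e2": e2}


def tajimas_d(S: int, pi_sum: float, n: int) -> float | None:
    """Tajima's (1989) D from the segregating-site count, the summed per-site
    heterozygosity and the (constant) chromosome count ``n``.

    Returns None when S == 0 (statistic undefined).
    """
    if n < 2:
        raise ValueError("Tajima's D needs at least 2 chromosomes")
    if S == 0:
        return None
    k = _tajima_constants(n)
    theta_w = S / k["a1"]
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return (pi_sum - theta_w) / math.sqrt(var)


def hudson_fst(p1, n1, p2, n2):
    """Per-SNP Hudson F_ST, ratio-of-estimates form.

    N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    D = p1(1-p2) + p2(1-p1); returns N/D, NaN when D == 0. ``n`` are
    chromosome counts (>= 2). Vectorized over arrays.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 <= 1) or np.any(n2 <= 1):
        raise ValueError("hudson_fst requires chromosome counts > 1")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den != 0, num / np.where(den != 0, den, 1.0), np.nan)
    return float(fst) if fst.ndim == 0 else fst


def afd(p1, p2):
    """Absolute allele-frequency difference |p1 - p2|."""
    out = np.abs(np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float))
    return float(out) if out.ndim == 0 else out


def neutral_quantile(values: np.ndarray, q: float = 0.99) -> float:
    """Empirical quantile (type-7 linear interpolation) of a neutral
    distribution, NaNs removed. Warns below 100 values."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("neutral_quantile: no finite values")
    if values.size < 100:
        log.warning("neutral_quantile: only %d values; threshold is noisy", values.size)
    return float(np.quantile(values, q))


def diversity(
    gm: GenotypeMatrix,
    group_indices: list[int],
    site_mask: np.ndarray,
    group_name: str = "",
) -> DiversityResult:
    """Genomewide pi, Tajima's D and S for one group over the masked sites
    (typically 4-fold degenerate synonymous sites).

    Tajima's D requires a constant chromosome count, so sites with residual
    missingness inside the group are dropped for the statistic.
    """
    cols = np.asarray(group_indices, dtype=np.intp)
    sub = gm.take_individuals(cols).take_variants(np.flatnonzero(site_mask))
    dd = sub.derived_dosage()
    pl = sub.ploidy[None, :]
    nonmiss = dd != MISSING
    ac = np.where(nonmiss, dd, 0).sum(axis=1)
    an = (nonmiss * pl).sum(axis=1)
    pi_sites = site_pi(ac, an)
    pi_mean = float(np.nanmean(pi_sites)) if pi_sites.size else 0.0

    full = nonmiss.all(axis=1)
    n_chrom = int(pl.sum())
    seg = full & (ac > 0) & (ac < an)
    S = int(seg.sum())
    pi_sum = float(np.nansum(pi_sites[seg])) if S else 0.0
    d = tajimas_d(S, pi_sum, n_chrom) if n_chrom >= 2 and S > 0 else None
    return DiversityResult(group_name, pi_mean, d, S, int(site_mask.sum()), n_chrom)


__all__ = [
    "FrequencyTable", "DiversityResult", "apply_genotype_filters",
    "subsample_chromosomes", "polarize", "group_frequencies", "site_pi",
    "tajimas_d", "hudson_fst", "afd", "neutral_quantile", "diversity",
]
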