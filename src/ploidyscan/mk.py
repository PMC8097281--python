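"""Modified McDonald-Kreitman test for recently diverged mixed-ploidy groups.

Classical MK divergence counts assume fixed differences between species.
Between a young autotetraploid and its diploid source there are essentially
no fixed differences, so "divergent" sites are instead defined as the upper
1% outliers of the diploid-tetraploid allele-frequency difference (AFD); the
remaining sites are polymorphisms. Rare variants (overall derived frequency
below 0.15 across the combined panel) are excluded to limit the footprint of
slightly deleterious segregating mutations.

alpha = 1 - (Ds * Pn) / (Dn * Ps) estimates the proportion of divergence
driven by positive selection; significance comes from a two-sided Fisher's
exact test on the 2x2 count table (the per-gene counts are small).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import EFFECT_MISSENSE, EFFECT_SYNONYMOUS

log = logging.getLogger(__name__)

CLASS_DIVERGENT = "divergent"
CLASS_POLYMORPHIC = "polymorphic"
CLASS_EXCLUDED = "excluded"


@dataclass
class MKResult:
    gene_id: str
    Dn: int
    Ds: int
    Pn: int
    Ps: int
    alpha: float | None
    p_value: float | None
    afd_threshold_used: float
    af_min_used: float


def classify_mk_sites(
    f_diploid: np.ndarray,
    f_tetraploid: np.ndarray,
    f_overall: np.ndarray,
    effect: np.ndarray,
    afd_quantile: float = 0.99,
    af_min: float = 0.15,
    afd_threshold: float | None = None,
) -> tuple[np.ndarray, float]:
    """Assign divergent / polymorphic / excluded to every site.

    Only synonymous and missense sites are classified (others are excluded).
    Sites with overall derived frequency < ``af_min`` are excluded; of the
    rest, sites whose AFD exceeds the genomewide upper-``afd_quantile``
    threshold are divergent, the remainder polymorphic. The threshold is
    recomputed from the data at hand unless ``afd_threshold`` overrides it.
    Returns (classes, threshold).
    """
    effect = np.asarray(effect)
    coding = (effect == EFFECT_SYNONYMOUS) | (effect == EFFECT_MISSENSE)
    afd_vals = np.abs(np.asarray(f_diploid, float) - np.asarray(f_tetraploid, float))
    usable = coding & np.isfinite(afd_vals) & np.isfinite(f_overall)
    passing = usable & (np.asarray(f_overall, float) >= af_min)
    if afd_threshold is None:
        vals = afd_vals[passing]
        if vals.size == 0:
            raise ValueError("no sites pass the MK frequency filter")
        afd_threshold = float(np.quantile(vals, afd_quantile))
    classes = np.full(effect.shape, CLASS_EXCLUDED, dtype=object)
    classes[passing & (afd_vals > afd_threshold)] = CLASS_DIVERGENT
    classes[passing & (afd_vals <= afd_threshold)] = CLASS_POLYMORPHIC
    return classes, afd_threshold


def mk_alpha(Dn: int, Ds: int, Pn: int, Ps: int) -> tuple[float | None, float | None]:
    """alpha = 1 - (Ds*Pn)/(Dn*Ps) with a two-sided Fisher's exact p value.

    alpha is None when Dn == 0 or Ps == 0 (ratio undefined); the p value is
    still computed whenever the table is non-degenerate.
    """
    for v in (Dn, Ds, Pn, Ps):
        if v < 0:
            raise ValueError("MK counts must be non-negative")
    alpha = None
    if Dn > 0 and Ps > 0:
        alpha = 1.0 - (Ds * Pn) / (Dn * Ps)
    p = None
    if Dn + Ds + Pn + Ps > 0:
        _, p = stats.fisher_exact([[Dn, Ds], [Pn, Ps]], alternative="two-sided")
        p = float(p)
    return alpha, p


def mk_scan(
    site_table: pd.DataFrame,
    afd_quantile: float = 0.99,
    af_min: float = 0.15,
    afd_threshold: float | None = None,
) -> pd.DataFrame:
    """Per-gene MK counts plus a pooled genomewide row.

    ``site_table`` needs columns gene, effect, f_diploid, f_tetraploid,
    f_overall. Genes with zero classified sites yield all-zero counts and a
    null alpha.
    """
    classes, thr = classify_mk_sites(
        site_table["f_diploid"].to_numpy(),
        site_table["f_tetraploid"].to_numpy(),
        site_table["f_overall"].to_numpy(),
        site_table["effect"].to_numpy(),
        afd_quantile, af_min, afd_threshold,
    )
    df = site_table.copy()
    df["mk_class"] = classes
    is_mis = df["effect"].to_numpy() == EFFECT_MISSENSE

    def _counts(mask: np.ndarray) -> tuple[int, int, int, int]:
        div = (classes == CLASS_DIVERGENT) & mask
        poly = (classes == CLASS_POLYMORPHIC) & mask
        return (int((div & is_mis).sum()), int((div & ~is_mis).sum()),
                int((poly & is_mis).sum()), int((poly & ~is_mis).sum()))

    rows = []
    for gene, idx in df.groupby("gene").indices.items():
        mask = np.zeros(len(df), dtype=bool)
        mask[idx] = True
        Dn, Ds, Pn, Ps = _counts(mask)
        alpha, p = mk_alpha(Dn, Ds, Pn, Ps)
        rows.append(MKResult(str(gene), Dn, Ds, Pn, Ps, alpha, p, thr, af_min))
    Dn, Ds, Pn, Ps = _counts(np.ones(len(df), dtype=bool))
    alpha, p = mk_alpha(Dn, Ds, Pn, Ps)
    rows.append(MKResult("genomewide", Dn, Ds, Pn, Ps, alpha, p, thr, af_min))
    out = pd.DataFrame([r.__dict__ for r in rows])
    return out


__all__ = [
    "CLASS_DIVERGENT", "CLASS_POLYMORPHIC", "CLASS_EXCLUDED", "MKResult",
    "classify_mk_sites", "mk_alpha", "mk_scan",
]
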