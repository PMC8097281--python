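"""Modified FineMAV score, F_ST x FineMAV outlier calling, gene-set enrichment.

The per-site score combines the derived-allele frequency, the derived allele
purity DAP = max_l f_l / sum_l f_l raised to an exponent (default 3.5), and a
functional deleteriousness score — either the Grantham physicochemical
distance of the amino-acid pair or the rescaled SIFT score (1 - raw, so 1 is
most deleterious). A site is a final candidate when it exceeds the
synonymous-SNP 99% F_ST quantile for its contrast *and* the genomewide 1%
FineMAV quantile for Grantham *and* for SIFT (sites with no SIFT database
entry are judged on Grantham alone).

Frequency groups for the DAP term follow the contrast: the diploid-lineage
scan uses the five diploid lineages, the ploidy scan uses the pooled diploid
group versus the tetraploid lineage. Purity is therefore measured among the
populations actually being contrasted, which keeps alleles shared between a
diploid lineage and the tetraploids (parallel sweeps) scoreable in both
scans.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    EFFECT_MISSENSE, EFFECT_SYNONYMOUS, GranthamMatrix, SiftTable,
)
from .popgen import FrequencyTable, hudson_fst, neutral_quantile

log = logging.getLogger(__name__)

DAP_EXPONENT = 3.5


def rescale_sift(raw):
    """Flip the raw SIFT score so 1 is most deleterious, 0 most tolerated."""
    arr = np.asarray(raw, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("raw SIFT scores must lie in [0, 1]")
    out = 1.0 - arr
    return float(out) if out.ndim == 0 else out


def dap(f_vector) -> float:
    """Derived allele purity max(f)/sum(f); NaN when all frequencies are 0."""
    f = np.asarray(f_vector, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("group frequencies must lie in [0, 1]")
    total = f.sum()
    if total == 0:
        return float("nan")
    return float(f.max() / total)


def finemav_score(f_vector, functional_score: float,
                  exponent: float = DAP_EXPONENT) -> tuple[float, int]:
    """FineMAV score f_max * DAP^exponent * functional, and the arg-max group.

    Ties on f_max resolve to the lowest group index. Returns (NaN, -1) when
    every group frequency is zero.
    """
    if functional_score < 0:
        raise ValueError("functional score must be non-negative")
    f = np.asarray(f_vector, dtype=float)
    purity = dap(f)
    if np.isnan(purity):
        return float("nan"), -1
    top = int(np.argmax(f))
    return float(f[top] * purity**exponent * functional_score), top


def finemav_matrix(freq_matrix: np.ndarray, functional: np.ndarray,
                   exponent: float = DAP_EXPONENT) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized scores over a (n_groups, n_sites) frequency matrix.

    ``functional`` may contain NaN (score unavailable); result is NaN there
    and where all group frequencies are zero or missing.
    """
    f = np.asarray(freq_matrix, dtype=float)
    total = np.nansum(f, axis=0)
    fmax = np.nanmax(np.where(np.isnan(f), -1.0, f), axis=0)
    top = np.nanargmax(np.where(np.isnan(f), -1.0, f), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        purity = np.where(total > 0, fmax / np.where(total > 0, total, 1.0), np.nan)
        scores = fmax * purity**exponent * functional
    scores = np.where(total > 0, scores, np.nan)
    return scores, top


def outlier_threshold(scores: np.ndarray, quantile: float = 0.99) -> float:
    """Genomewide outlier threshold over sites with non-null scores."""
    vals = np.asarray(scores, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no finite scores to take a quantile over")
    return float(np.quantile(vals, quantile))


def call_candidates(site_table: pd.DataFrame, fst_threshold: float,
                    finemav_quantile: float = 0.99) -> pd.DataFrame:
    """Flag F_ST and FineMAV outliers and their overlap.

    ``site_table`` holds one missense site per row with columns ``fst``,
    ``finemav_grantham`` and ``finemav_sift`` (NaN = no SIFT entry). Adds the
    outlier flags and ``is_candidate``; candidacy requires the F_ST outlier,
    the Grantham-FineMAV outlier, and the SIFT-FineMAV outlier whenever a
    SIFT score exists.
    """
    if site_table.empty:
        raise ValueError("empty site table")
    df = site_table.copy()
    g_thr = outlier_threshold(df["finemav_grantham"].to_numpy(), finemav_quantile)
    s_vals = df["finemav_sift"].to_numpy(dtype=float)
    s_thr = (outlier_threshold(s_vals, finemav_quantile)
             if np.isfinite(s_vals).any() else np.nan)
    df["fst_outlier"] = df["fst"] > fst_threshold
    df["finemav_grantham_outlier"] = df["finemav_grantham"] > g_thr
    sift_known = np.isfinite(s_vals)
    df["finemav_sift_outlier"] = np.where(sift_known, s_vals > s_thr, np.nan)
    df["is_candidate"] = (
        df["fst_outlier"]
        & df["finemav_grantham_outlier"]
        & (~sift_known | (s_vals > (s_thr if np.isfinite(s_thr) else np.inf)))
    )
    df.attrs["grantham_threshold"] = g_thr
    df.attrs["sift_threshold"] = s_thr
    return df


def gene_set_enrichment(candidate_genes: set[str], focus_set: set[str],
                        universe: set[str]) -> tuple[float, float]:
    """Two-sided Fisher's exact test for focus-set excess among candidates."""
    if not universe:
        raise ValueError("empty gene universe")
    if not (focus_set & universe):
        raise ValueError("focus set disjoint from the gene universe")
    cand = candidate_genes & universe
    focus = focus_set & universe
    a = len(cand & focus)
    b = len(focus - cand)
    c = len(cand - focus)
    d = len(universe - focus - cand)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


# ---------------------------------------------------------------------------
# scan driver


@dataclass
class ScanResult:
    """Per-contrast candidate tables plus the thresholds used."""

    candidates: pd.DataFrame  # one row per (contrast, missense site)
    thresholds: pd.DataFrame  # per contrast: fst_threshold, finemav thresholds
    diploid_lineages: list[str]
    tetraploid_lineage: str

    def candidate_sites(self, contrast_kind: str | None = None) -> pd.DataFrame:
        df = self.candidates[self.candidates["is_candidate"]]
        if contrast_kind is not None:
            df = df[df["contrast_kind"] == contrast_kind]
        return df


def _functional_arrays(ann: pd.DataFrame, grantham: GranthamMatrix,
                       sift: SiftTable) -> tuple[np.ndarray, np.ndarray]:
    n = len(ann)
    g = np.full(n, np.nan)
    s = np.full(n, np.nan)
    for i, row in enumerate(ann.itertuples(index=False)):
        if row.effect != EFFECT_MISSENSE:
            continue
        g[i] = grantham.score(row.aa_ref, row.aa_alt)
        raw = sift.get(row.chrom, row.pos)
        if raw is not None:
            s[i] = rescale_sift(raw)
    return g, s


def run_selection_scan(
    freq: FrequencyTable,
    ann: pd.DataFrame,
    grantham: GranthamMatrix,
    sift: SiftTable,
    diploid_lineages: list[str],
    tetraploid_lineage: str,
    fst_quantile: float = 0.99,
    finemav_quantile: float = 0.99,
    exponent: float = DAP_EXPONENT,
) -> ScanResult:
    """Run the ploidy contrast and all diploid pairwise contrasts.

    ``freq`` is the per-lineage derived-allele frequency table of the
    subsampled, filtered, polarized panel; ``ann`` is the annotation frame
    aligned row-for-row with ``freq.variants``.
    """
    if len(ann) != len(freq.variants):
        raise ValueError("annotation frame not aligned with frequency table")
    eff = ann["effect"].to_numpy()
    is_mis = eff == EFFECT_MISSENSE
    is_syn = eff == EFFECT_SYNONYMOUS
    g_scores, s_scores = _functional_arrays(ann, grantham, sift)

    lineage_f = {lin: freq.group_f(lin) for lin in freq.groups}
    lineage_an = {lin: freq.group_an(lin) for lin in freq.groups}

    # pooled diploids
    dip_idx = [freq.group_index(l) for l in diploid_lineages]
    dip_ac = freq.ac[:, dip_idx].sum(axis=1)
    dip_an = freq.an[:, dip_idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dip_f = np.where(dip_an > 0, dip_ac / np.maximum(dip_an, 1), np.nan)

    contrasts: list[dict] = []
    tet_f = lineage_f[tetraploid_lineage]
    tet_an = lineage_an[tetraploid_lineage]
    contrasts.append({
        "name": f"diploids_vs_{tetraploid_lineage}",
        "kind": "ploidy",
        "f1": dip_f, "n1": dip_an, "f2": tet_f, "n2": tet_an,
        "dap_groups": ["diploids", tetraploid_lineage],
        "dap_matrix": np.vstack([dip_f, tet_f]),
    })
    dip_matrix = np.vstack([lineage_f[l] for l in diploid_lineages])
    for l1, l2 in itertools.combinations(diploid_lineages, 2):
        contrasts.append({
            "name": f"{l1}_vs_{l2}",
            "kind": "diploid_pair",
            "f1": lineage_f[l1], "n1": lineage_an[l1],
            "f2": lineage_f[l2], "n2": lineage_an[l2],
            "dap_groups": diploid_lineages,
            "dap_matrix": dip_matrix,
        })

    # FineMAV tables are shared within a scan kind (one per grouping)
    finemav_cache: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    rows = []
    thr_rows = []
    for c in contrasts:
        ok = np.ones(len(eff), dtype=bool)
        n1 = np.maximum(c["n1"], 2)
        n2 = np.maximum(c["n2"], 2)
        usable = (c["n1"] > 1) & (c["n2"] > 1)
        fst = np.where(
            usable,
            hudson_fst(np.nan_to_num(c["f1"]), n1, np.nan_to_num(c["f2"]), n2),
            np.nan,
        )
        fst_thr = neutral_quantile(fst[is_syn & usable], fst_quantile)

        key = c["kind"]
        if key not in finemav_cache:
            gs, top = finemav_matrix(c["dap_matrix"], g_scores, exponent)
            ss, _ = finemav_matrix(c["dap_matrix"], s_scores, exponent)
            finemav_cache[key] = (gs, ss, top)
        gs, ss, top = finemav_cache[key]

        sub = ann.loc[is_mis, ["chrom", "pos", "gene", "aa_pos", "aa_ref", "aa_alt"]].copy()
        sub["contrast"] = c["name"]
        sub["contrast_kind"] = c["kind"]
        sub["f_group1"] = c["f1"][is_mis]
        sub["f_group2"] = c["f2"][is_mis]
        sub["fst"] = fst[is_mis]
        sub["finemav_grantham"] = gs[is_mis]
        sub["finemav_sift"] = ss[is_mis]
        sub["top_group"] = np.asarray(c["dap_groups"], dtype=object)[top[is_mis]]
        called = call_candidates(sub, fst_thr, finemav_quantile)
        rows.append(called)
        thr_rows.append({
            "contrast": c["name"],
            "kind": c["kind"],
            "fst_threshold": fst_thr,
            "grantham_threshold": called.attrs["grantham_threshold"],
            "sift_threshold": called.attrs["sift_threshold"],
        })

    candidates = pd.concat(rows, ignore_index=True)
    thresholds = pd.DataFrame(thr_rows)
    return ScanResult(candidates, thresholds, list(diploid_lineages), tetraploid_lineage)


__all__ = [
    "DAP_EXPONENT", "rescale_sift", "dap", "finemav_score", "finemav_matrix",
    "outlier_threshold", "call_candidates", "gene_set_enrichment",
    "ScanResult", "run_selection_scan",
]
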