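"""End-to-end orchestration of the mixed-ploidy selection-scan pipeline.

Stages (run in order by :func:`run_all`): genotype filtering, polarization,
chromosome subsampling, grouped frequencies, diversity, the F_ST/FineMAV
scan, candidate calling, gene-set enrichment, the MK test, the de novo /
standing haplotype analysis, sweep ages, MNM evidence and the conservation
comparison. Every output is a TSV/JSON written with deterministic ordering
and formatting, so identical configs produce byte-identical output trees.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conservation as cons
from . import datamodel as dm
from . import finemav, haplotypes, mk, popgen, sweeps
from .datamodel import EFFECT_MISSENSE, GenotypeMatrix
from .simulate import BUNDLE_FILES

log = logging.getLogger(__name__)

STAGES = [
    "filter", "polarize", "subsample", "frequencies", "diversity",
    "fst_finemav", "candidates", "enrichment", "mk",
    "denovo", "sweep_age", "mnm", "conservation",
]

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline in one place."""

    bundle_dir: str
    output_dir: str
    fst_quantile: float = 0.99
    finemav_quantile: float = 0.99
    dap_exponent: float = 3.5
    af_min: float = 0.15
    afd_quantile: float = 0.99
    afd_threshold: float | None = None  # override; default recomputed
    min_depth: int = 8
    max_missing: float = 0.5
    diploid_target_chromosomes: int = 32
    tetraploid_target_chromosomes: int = 160
    subsample_rule: str = "highest_depth"
    cross_distance_statistic: str = "median"
    mnm_alpha: float = 0.01
    rarefaction_sizes: tuple[int, ...] = (5, 10, 20, 40, 60, 80)
    rarefaction_reps: int = 20
    msa_reference: str = "A_lyrata"
    tetraploid_lineage: str = "tetraploid"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fst_quantile", "finemav_quantile", "afd_quantile"):
            q = getattr(self, name)
            if not 0.0 < q < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {q}")
        if self.dap_exponent <= 0:
            raise ValueError("dap_exponent must be positive")
        if not 0.0 <= self.af_min < 1.0:
            raise ValueError("af_min must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "rarefaction_sizes" in payload:
            payload["rarefaction_sizes"] = tuple(payload["rarefaction_sizes"])
        return cls(**payload)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths excluded, so runs of the
        same analysis into different directories hash identically)."""
        payload = dataclasses.asdict(self)
        payload.pop("bundle_dir")
        payload.pop("output_dir")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
        )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


@dataclass
class PipelineState:
    """Shared intermediate products between stages."""

    config: PipelineConfig
    popmap: list[dm.Individual]
    gm_full: GenotypeMatrix          # filtered + polarized, full panel
    gm_scan: GenotypeMatrix          # subsampled panel for the scans
    ann: pd.DataFrame                # aligned with gm rows by (chrom, pos)
    ann_scan: pd.DataFrame
    genes: list[dm.GeneModel]
    grantham: dm.GranthamMatrix
    sift: dm.SiftTable
    msa_dir: Path | None
    freq: popgen.FrequencyTable
    diploid_lineages: list[str]
    counts: dict[str, dict]
    msas: dict[str, dm.ProteinAlignment] | None = None

    def alignment(self, gene: str) -> dm.ProteinAlignment:
        if self.msas is not None:
            if gene not in self.msas:
                raise PipelineError(f"no alignment for gene {gene!r}")
            return self.msas[gene]
        fasta = (self.msa_dir or Path(".")) / f"{gene}.fasta"
        if not fasta.exists():
            raise PipelineError(f"missing alignment {fasta}")
        return dm.read_msa(fasta, self.config.msa_reference)


def _align_annotations(gm: GenotypeMatrix, ann_df: pd.DataFrame) -> pd.DataFrame:
    keyed = ann_df.set_index(["chrom", "pos"])
    rows = []
    for v in gm.variants:
        if v.key in keyed.index:
            row = keyed.loc[v.key]
            rows.append({"chrom": v.chrom, "pos": v.pos, **row.to_dict()})
        else:
            rows.append({"chrom": v.chrom, "pos": v.pos, "gene": None,
                         "effect": "other", "aa_pos": None, "aa_ref": None,
                         "aa_alt": None, "fourfold": False,
                         "ref": v.ref_allele, "alt": v.alt_allele})
    return pd.DataFrame(rows)


def prepare(config: PipelineConfig) -> PipelineState:
    """Load the bundle and run filter -> polarize -> subsample -> frequencies."""
    bundle = Path(config.bundle_dir)
    popmap = dm.read_popmap(bundle / BUNDLE_FILES["popmap"])
    gm = dm.read_vcf(bundle / BUNDLE_FILES["vcf"], popmap)
    ann_df = dm.annotations_frame(dm.read_annotations(bundle / BUNDLE_FILES["annotations"]))
    genes = dm.read_gene_models(bundle / BUNDLE_FILES["genes"])
    grantham = dm.read_grantham(bundle / BUNDLE_FILES["grantham"])
    sift = dm.read_sift(bundle / BUNDLE_FILES["sift"])
    return prepare_from_objects(
        config, popmap, gm, ann_df, genes, grantham, sift,
        msa_dir=bundle / BUNDLE_FILES["msa_dir"],
    )


def prepare_from_bundle(config: PipelineConfig, bundle) -> PipelineState:
    """Prepare directly from an in-memory :class:`ploidyscan.simulate.Bundle`."""
    return prepare_from_objects(
        config, bundle.individuals, bundle.genotypes,
        dm.annotations_frame(bundle.annotations), bundle.genes,
        bundle.grantham, bundle.sift, msas=bundle.msas,
    )


def prepare_from_objects(
    config: PipelineConfig,
    popmap: list[dm.Individual],
    gm: GenotypeMatrix,
    ann_df: pd.DataFrame,
    genes: list[dm.GeneModel],
    grantham: dm.GranthamMatrix,
    sift: dm.SiftTable,
    msa_dir: Path | None = None,
    msas: dict[str, dm.ProteinAlignment] | None = None,
) -> PipelineState:
    """Filter -> polarize -> subsample -> frequencies over loaded objects."""
    counts: dict[str, dict] = {}

    n_before = gm.n_variants
    gm = popgen.apply_genotype_filters(gm, config.min_depth, config.max_missing)
    counts["filter"] = {"variants_in": n_before, "variants_out": gm.n_variants}

    outgroup = {}
    for v in gm.variants:
        if v.derived_allele == "alt":
            outgroup[v.key] = v.ref_allele
        elif v.derived_allele == "ref":
            outgroup[v.key] = v.alt_allele
    gm = popgen.polarize(gm, outgroup)
    counts["polarize"] = {
        "outgroup_informed": len(outgroup),
        "minor_allele_rule": gm.n_variants - len(outgroup),
    }

    lineage_cols: dict[str, list[int]] = {}
    for i, ind in enumerate(gm.individuals):
        lineage_cols.setdefault(ind.lineage, []).append(i)
    diploid_lineages = sorted(
        l for l in lineage_cols if l != config.tetraploid_lineage
    )
    if config.tetraploid_lineage not in lineage_cols:
        raise PipelineError(
            f"tetraploid lineage {config.tetraploid_lineage!r} absent from popmap"
        )
    chosen: list[int] = []
    for lin in diploid_lineages:
        chosen.extend(popgen.subsample_chromosomes(
            gm, lineage_cols[lin], config.diploid_target_chromosomes,
            config.subsample_rule, config.seed,
        ))
    chosen.extend(popgen.subsample_chromosomes(
        gm, lineage_cols[config.tetraploid_lineage],
        config.tetraploid_target_chromosomes, config.subsample_rule, config.seed,
    ))
    gm_scan = gm.take_individuals(sorted(chosen))
    counts["subsample"] = {
        "individuals_full": gm.n_individuals,
        "individuals_scan": gm_scan.n_individuals,
    }

    scan_groups: dict[str, list[int]] = {}
    for i, ind in enumerate(gm_scan.individuals):
        scan_groups.setdefault(ind.lineage, []).append(i)
    freq = popgen.group_frequencies(gm_scan, scan_groups)
    counts["frequencies"] = {"sites": len(freq.variants), "groups": len(freq.groups)}

    ann = _align_annotations(gm, ann_df)
    return PipelineState(
        config, popmap, gm, gm_scan, ann, ann, genes, grantham, sift,
        msa_dir, freq, diploid_lineages, counts, msas,
    )


def _pooled(freq: popgen.FrequencyTable, lineages: list[str]):
    idx = [freq.group_index(l) for l in lineages]
    ac = freq.ac[:, idx].sum(axis=1)
    an = freq.an[:, idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
    return f, an


def stage_diversity(state: PipelineState) -> pd.DataFrame:
    fourfold = state.ann["fourfold"].to_numpy(dtype=bool)
    groups: dict[str, list[int]] = {}
    for i, ind in enumerate(state.gm_scan.individuals):
        groups.setdefault(ind.lineage, []).append(i)
    groups["all_diploids"] = [
        i for i, ind in enumerate(state.gm_scan.individuals) if ind.ploidy == 2
    ]
    rows = []
    for name in sorted(groups):
        res = popgen.diversity(state.gm_scan, groups[name], fourfold, name)
        rows.append({
            "group": name, "pi": res.pi,
            "tajima_d": res.tajima_d if res.tajima_d is not None else np.nan,
            "S": res.S, "n_sites": res.n_sites,
            "n_chromosomes": res.n_chromosomes,
        })
    return pd.DataFrame(rows)


def stage_scan(state: PipelineState) -> finemav.ScanResult:
    return finemav.run_selection_scan(
        state.freq, state.ann, state.grantham, state.sift,
        state.diploid_lineages, state.config.tetraploid_lineage,
        state.config.fst_quantile, state.config.finemav_quantile,
        state.config.dap_exponent,
    )


def stage_enrichment(state: PipelineState, scan: finemav.ScanResult) -> list[dict]:
    focus = {g.gene_id for g in state.genes if g.in_focus_set}
    universe = {g.gene_id for g in state.genes}
    out = []
    for kind in ("ploidy", "diploid_pair"):
        cand = set(scan.candidate_sites(kind)["gene"])
        odds, p = finemav.gene_set_enrichment(cand, focus, universe)
        out.append({
            "contrast_kind": kind, "n_candidate_genes": len(cand),
            "n_focus_candidates": len(cand & focus),
            "odds_ratio": odds, "p_value": p,
        })
    return out


def stage_mk(state: PipelineState) -> pd.DataFrame:
    f_dip, _ = _pooled(state.freq, state.diploid_lineages)
    f_tet = state.freq.group_f(state.config.tetraploid_lineage)
    f_all, _ = _pooled(
        state.freq, state.diploid_lineages + [state.config.tetraploid_lineage]
    )
    table = pd.DataFrame({
        "gene": state.ann["gene"], "effect": state.ann["effect"],
        "f_diploid": f_dip, "f_tetraploid": f_tet, "f_overall": f_all,
    })
    table = table[table["gene"].notna()]
    return mk.mk_scan(table, state.config.afd_quantile, state.config.af_min,
                      state.config.afd_threshold)


def _tetraploid_candidates(scan: finemav.ScanResult,
                           tetraploid_lineage: str) -> pd.DataFrame:
    cand = scan.candidate_sites("ploidy")
    return cand[cand["top_group"] == tetraploid_lineage]


def stage_denovo(state: PipelineState, scan: finemav.ScanResult):
    """Standing screen, HAF, Hamming report and the three-criterion verdict."""
    cfg = state.config
    cand = _tetraploid_candidates(scan, cfg.tetraploid_lineage)
    dip_cand_keys = set(
        zip(scan.candidate_sites("diploid_pair")["chrom"],
            scan.candidate_sites("diploid_pair")["pos"])
    )
    dip_idx = state.gm_full.individual_indices(lambda ind: ind.ploidy == 2)
    gm_dip = state.gm_full.take_individuals(dip_idx)

    verdict_rows, haf_rows, hamming_rows, screen_rows = [], [], [], []
    for gene, sub in sorted(cand.groupby("gene"), key=lambda kv: kv[0]):
        keys = sorted(set(zip(sub["chrom"], sub["pos"])))
        screen = haplotypes.standing_screen(gm_dip, keys)
        screen.insert(0, "gene", gene)
        screen["shared_with_diploid_scan"] = [
            k in dip_cand_keys for k in keys
        ]
        screen_rows.append(screen)
        n_full = haplotypes.haplotype_presence_in_diploids(gm_dip, keys)
        report = haplotypes.gene_hamming_report(
            state.gm_full, gene, keys, cfg.cross_distance_statistic
        )
        verdict = haplotypes.de_novo_verdict(gene, screen, n_full, report)
        verdict_rows.append({
            "gene": gene, "n_candidate_sites": len(keys),
            "criterion_A_absent_aas": verdict.criterion_A_absent_aas,
            "criterion_B_absent_haplotype": verdict.criterion_B_absent_haplotype,
            "criterion_C_distance_exceeds_diameter":
                verdict.criterion_C_distance_exceeds_diameter,
            "verdict_de_novo": verdict.verdict,
            "n_diploids_with_full_haplotype": n_full,
        })
        hamming_rows.append({
            "gene": gene, "n_sites": report.n_sites,
            "diameter_diploid": report.diameter_diploid,
            "diameter_tetraploid": report.diameter_tetraploid,
            "distance_between": report.distance_between,
        })
        haf_rows.append(haplotypes.haf_table(state.gm_full, gene, keys))

    site_mask = np.ones(gm_dip.n_variants, dtype=bool)
    sizes = [s for s in cfg.rarefaction_sizes if s <= gm_dip.n_individuals]
    if gm_dip.n_individuals not in sizes:
        sizes.append(gm_dip.n_individuals)
    rarefaction = haplotypes.rarefaction_curve(
        gm_dip, site_mask, sizes, cfg.rarefaction_reps, cfg.seed
    )
    verdicts = pd.DataFrame(verdict_rows)
    haf = (pd.concat(haf_rows, ignore_index=True)
           if haf_rows else pd.DataFrame())
    hamming = pd.DataFrame(hamming_rows)
    screens = (pd.concat(screen_rows, ignore_index=True)
               if screen_rows else pd.DataFrame())
    return verdicts, haf, hamming, screens, rarefaction


def stage_sweep_age(state: PipelineState, scan: finemav.ScanResult) -> pd.DataFrame:
    cfg = state.config
    cand = _tetraploid_candidates(scan, cfg.tetraploid_lineage)
    tet_f = state.freq.group_f(cfg.tetraploid_lineage)
    seg_mask = np.isfinite(tet_f) & (tet_f > 0) & (tet_f < 1)
    positions = np.array([v.pos for v in state.freq.variants])
    chroms = np.array([v.chrom for v in state.freq.variants])
    results = []
    for gene, sub in sorted(cand.groupby("gene"), key=lambda kv: kv[0]):
        chrom = sub["chrom"].iloc[0]
        seg_pos = positions[seg_mask & (chroms == chrom)]
        results.append(sweeps.sweep_age(str(gene), sub["pos"].to_numpy(), seg_pos))
    ranked = sweeps.rank_sweeps(results)
    return pd.DataFrame([
        {"gene": r.gene_id, "span_bp": r.span_bp,
         "n_accumulated": r.n_accumulated, "ratio": r.ratio,
         "rank": r.rank, "reason": r.reason}
        for r in ranked
    ])


def stage_mnm(state: PipelineState, scan: finemav.ScanResult) -> pd.DataFrame:
    cand = _tetraploid_candidates(scan, state.config.tetraploid_lineage)
    mis = state.ann[state.ann["effect"] == EFFECT_MISSENSE]
    missense_table = mis[["gene", "pos", "ref", "alt"]].dropna(subset=["gene"])
    cand_table = cand[["gene", "pos"]].merge(
        state.ann[["pos", "ref", "alt"]], on="pos", how="left"
    )
    return sweeps.mnm_scan(cand_table, missense_table, state.config.mnm_alpha)


def stage_conservation(state: PipelineState, scan: finemav.ScanResult):
    """PAI of tetraploid-exclusive vs diploid-scan candidate sites."""
    cfg = state.config
    tet_cand = _tetraploid_candidates(scan, cfg.tetraploid_lineage)
    dip_cand = scan.candidate_sites("diploid_pair")
    dip_keys = set(zip(dip_cand["chrom"], dip_cand["pos"]))
    tet_excl = tet_cand[
        [k not in dip_keys for k in zip(tet_cand["chrom"], tet_cand["pos"])]
    ]
    tables = []
    for label, cand in (("tetraploid", tet_excl), ("diploid", dip_cand)):
        for gene, sub in sorted(cand.groupby("gene"), key=lambda kv: kv[0]):
            aln = state.alignment(str(gene))
            tab = cons.conservation_table(
                aln, str(gene), [int(p) for p in sub["aa_pos"].dropna().unique()]
            )
            tab.insert(0, "candidate_set", label)
            tables.append(tab)
    table = (pd.concat(tables, ignore_index=True)
             if tables else pd.DataFrame(columns=["candidate_set", "pai"]))
    tet_pai = table.loc[table["candidate_set"] == "tetraploid", "pai"].to_numpy()
    dip_pai = table.loc[table["candidate_set"] == "diploid", "pai"].to_numpy()
    summary = None
    if tet_pai.size and dip_pai.size:
        summary = cons.conservation_compare(tet_pai, dip_pai)
    return table, summary


def run_all(config: PipelineConfig) -> RunManifest:
    """Run every stage and write all outputs under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        version = metadata.version("ploidyscan")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    manifest = RunManifest(config.config_hash(), version)
    state = prepare(config)
    manifest.stages.update(state.counts)

    current = "diversity"
    try:
        div = stage_diversity(state)
        _write_tsv(div, out / "diversity.tsv")
        manifest.stages["diversity"] = {"rows": len(div)}

        current = "fst_finemav"
        scan = stage_scan(state)
        _write_tsv(scan.thresholds, out / "thresholds.tsv")
        manifest.stages["fst_finemav"] = {"contrasts": len(scan.thresholds)}

        current = "candidates"
        _write_tsv(scan.candidates, out / "candidates.tsv")
        n_cand = int(scan.candidates["is_candidate"].sum())
        manifest.stages["candidates"] = {
            "rows": len(scan.candidates), "candidates": n_cand,
        }

        current = "enrichment"
        enrich = stage_enrichment(state, scan)
        (out / "enrichment.json").write_text(
            json.dumps(enrich, indent=1, sort_keys=True)
        )
        manifest.stages["enrichment"] = {"contrast_kinds": len(enrich)}

        current = "mk"
        mk_table = stage_mk(state)
        _write_tsv(mk_table, out / "mk.tsv")
        manifest.stages["mk"] = {"rows": len(mk_table)}

        current = "denovo"
        verdicts, haf, hamming, screens, rarefaction = stage_denovo(state, scan)
        _write_tsv(verdicts, out / "denovo_verdicts.tsv")
        _write_tsv(haf, out / "haf.tsv")
        _write_tsv(hamming, out / "hamming.tsv")
        _write_tsv(screens, out / "standing_screen.tsv")
        _write_tsv(rarefaction, out / "rarefaction.tsv")
        manifest.stages["denovo"] = {"genes": len(verdicts)}

        current = "sweep_age"
        ages = stage_sweep_age(state, scan)
        _write_tsv(ages, out / "sweep_age.tsv")
        manifest.stages["sweep_age"] = {"genes": len(ages)}

        current = "mnm"
        mnm_table = stage_mnm(state, scan)
        _write_tsv(mnm_table, out / "mnm.tsv")
        manifest.stages["mnm"] = {"genes": len(mnm_table)}

        current = "conservation"
        ctable, csummary = stage_conservation(state, scan)
        _write_tsv(ctable, out / "conservation.tsv")
        (out / "conservation_summary.json").write_text(
            json.dumps(csummary, indent=1, sort_keys=True)
        )
        manifest.stages["conservation"] = {"rows": len(ctable)}
    except Exception as exc:
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc

    manifest.to_json(out / "manifest.json")
    return manifest


__all__ = [
    "STAGES", "PipelineConfig", "PipelineError", "RunManifest",
    "PipelineState", "prepare", "prepare_from_bundle",
    "prepare_from_objects", "stage_diversity", "stage_scan",
    "stage_enrichment", "stage_mk", "stage_denovo", "stage_sweep_age",
    "stage_mnm", "stage_conservation", "run_all",
]
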