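"""Synthetic mixed-ploidy datasets with planted ground truth.

The generator emulates a range-wide resequencing panel of a
diploid/autotetraploid species complex: five diploid lineages plus one
autotetraploid lineage, each lineage split into populations, with
hierarchical allele frequencies (a Balding-Nichols drift model around a
neutral-like ancestral spectrum), planted selective sweeps (de novo,
standing or parallel), multinucleotide-mutation (MNM) clusters, per-variant
annotations, SIFT scores, ortholog protein alignments and a machine-readable
truth record for recovery tests.

Key modelling choices
---------------------
* Tetraploids are autotetraploid with tetrasomic inheritance: dosages are
  Binomial(4, f). No disomic mode exists.
* A planted sweep is a single haplotype: every individual draws one
  haplotype count per gene and carries the derived allele at *all* planted
  sites of that gene with that dosage. This is what makes haplotype
  co-occurrence, HAF reconstruction and the Hamming criteria meaningful.
* ``de_novo`` sweeps set the diploid haplotype frequency exactly to zero, so
  planted sites are guaranteed absent from every diploid genotype.
* Sweeps clear segregating tetraploid variation between the first and last
  planted site and then re-seed ``age_mutations`` post-sweep variants, so
  older sweeps carry more accumulated polymorphism (the sweep-age proxy).
* SIFT scores are anti-correlated with the planted constraint class
  (conserved sites get low raw SIFT = deleterious), and planted amino-acid
  pairs are drawn from the high-Grantham tail, so both functional scores
  agree on planted candidates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import datamodel as dm
from .datamodel import (
    EFFECT_MISSENSE, EFFECT_OTHER, EFFECT_SYNONYMOUS, MISSING,
    GeneModel, GenotypeMatrix, Individual, ProteinAlignment, SiftTable,
    Variant, VariantAnnotation,
)

log = logging.getLogger(__name__)

TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSION_PARTNERS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}

CONSTRAINT_SUB_PROB = {"fixed": 0.0, "conserved": 0.02, "neutral": 0.35}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    lineage: str
    ploidy: int
    n_individuals: int


@dataclass
class SweepPlan:
    gene_id: str
    mode: str  # de_novo | standing | parallel | none
    n_candidate_aas: int
    target_freq: float
    source_lineage: str | None = None  # standing/parallel diploid lineage
    standing_range: tuple[float, float] = (0.02, 0.15)
    age_mutations: int = 2

    def __post_init__(self) -> None:
        if self.mode not in ("de_novo", "standing", "parallel", "none"):
            raise SimulationError(f"unknown sweep mode {self.mode!r}")
        if not 0.5 < self.target_freq <= 1.0:
            raise SimulationError("sweep target_freq must be in (0.5, 1]")


@dataclass
class MnmPlan:
    gene_id: str
    cluster_size: int
    max_spacing_bp: int = 19
    transversion_prob: float = 0.95
    target_freq: float = 0.9

    def __post_init__(self) -> None:
        if not self.max_spacing_bp < 20:
            raise SimulationError("MNM clusters use spacings < 20 bp")


def _default_populations() -> list[PopulationSpec]:
    pops: list[PopulationSpec] = []
    diploid_lineages = {
        "Pannonian": 2, "Dinaric": 3, "Baltic": 3,
        "SE_Carpathian": 3, "W_Carpathian": 3,
    }
    for lin, n_pops in diploid_lineages.items():
        for k in range(n_pops):
            pops.append(PopulationSpec(f"{lin}_p{k}", lin, 2, 8))
    for k in range(11):
        pops.append(PopulationSpec(f"tetra_p{k:02d}", "tetraploid", 4, 4))
    return pops


def _default_sweeps() -> list[SweepPlan]:
    return [
        SweepPlan("gene_000", "de_novo", 5, 0.9, age_mutations=4),
        SweepPlan("gene_001", "de_novo", 5, 0.9, age_mutations=1),
        SweepPlan("gene_002", "standing", 4, 0.9, source_lineage="W_Carpathian"),
        SweepPlan("gene_003", "standing", 4, 0.9, source_lineage="Dinaric"),
        SweepPlan("gene_004", "parallel", 4, 0.9, source_lineage="Pannonian"),
    ]


def _default_mnm() -> list[MnmPlan]:
    return [MnmPlan("gene_005", 8, 19, 0.95)]


@dataclass
class SimConfig:
    """Generator configuration; defaults are the package's study conditions."""

    n_genes: int = 150
    n_sites_per_gene: int = 60
    gene_length: int = 3000
    gene_spacing: int = 2000
    chrom: str = "scaffold_1"
    lineage_divergence: dict[str, float] = field(default_factory=lambda: {
        "Pannonian": 0.15, "Dinaric": 0.15, "Baltic": 0.15,
        "SE_Carpathian": 0.15, "W_Carpathian": 0.15, "tetraploid": 0.15,
    })
    populations: list[PopulationSpec] = field(default_factory=_default_populations)
    sweep_plan: list[SweepPlan] = field(default_factory=_default_sweeps)
    mnm_plan: list[MnmPlan] = field(default_factory=_default_mnm)
    depth_mean: float = 25.0
    missing_rate: float = 0.05
    seed: int = 0
    n_grid: int = 200  # ancestral spectrum truncation 1/(2*n_grid)
    p_missense: float = 0.55
    p_synonymous: float = 0.30
    fourfold_frac: float = 0.7  # of synonymous sites
    tv_background: float = 1.0 / 3.0
    sift_absent_rate: float = 0.10
    conserved_background: float = 0.4
    msa_species: int = 17
    msa_gap_rate: float = 0.02
    n_focus_neutral: int = 4  # neutral genes padded into the focus gene set
    generate_msas: bool = True
    tetraploid_lineage: str = "tetraploid"

    def __post_init__(self) -> None:
        for lin, f in self.lineage_divergence.items():
            if not 0.0 < f < 1.0:
                raise SimulationError(f"lineage {lin}: drift F must be in (0,1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SimulationError("missing_rate must be in [0,1)")
        planned = [p.gene_id for p in self.sweep_plan] + [m.gene_id for m in self.mnm_plan]
        if len(set(planned)) != len(planned):
            raise SimulationError("a gene may appear in at most one plan entry")

    @property
    def lineages(self) -> list[str]:
        return list(self.lineage_divergence)

    @property
    def diploid_lineages(self) -> list[str]:
        return [l for l in self.lineages if l != self.tetraploid_lineage]

    def gene_ids(self) -> list[str]:
        return [f"gene_{i:03d}" for i in range(self.n_genes)]

    def gene_interval(self, gene_index: int) -> tuple[int, int]:
        start = 1 + gene_index * (self.gene_length + self.gene_spacing)
        return start, start + self.gene_length - 1


# ---------------------------------------------------------------------------
# truth record


@dataclass
class TruthSite:
    chrom: str
    pos: int
    gene_id: str
    aa_pos: int
    ref: str
    alt: str
    lineage_freqs: dict[str, float]
    constraint: str
    is_transversion: bool


@dataclass
class TruthGene:
    gene_id: str
    mode: str
    sites: list[TruthSite]
    source_lineage: str | None
    age_mutations: int
    mnm_cluster: bool
    accumulated_positions: list[int]


@dataclass
class TruthRecord:
    lineages: list[str]
    tetraploid_lineage: str
    genes: dict[str, TruthGene]

    def planted_sites(self, modes: tuple[str, ...] | None = None) -> list[TruthSite]:
        out = []
        for g in self.genes.values():
            if modes is None or g.mode in modes:
                out.extend(g.sites)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "lineages": self.lineages,
            "tetraploid_lineage": self.tetraploid_lineage,
            "genes": {
                gid: dataclasses.asdict(g) for gid, g in sorted(self.genes.items())
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        payload = json.loads(Path(path).read_text())
        genes = {}
        for gid, g in payload["genes"].items():
            sites = [TruthSite(**s) for s in g.pop("sites")]
            genes[gid] = TruthGene(sites=sites, **g)
        return cls(payload["lineages"], payload["tetraploid_lineage"], genes)


# ---------------------------------------------------------------------------
# core operations


def simulate_frequencies(cfg: SimConfig, rng: np.random.Generator | None = None,
                         n_sites: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Draw the lineage x site derived-allele frequency matrix.

    The ancestral frequency p follows a neutral-like 1/p spectrum truncated
    to [1/(2*n_grid), 1 - 1/(2*n_grid)]; each lineage then draws
    Beta(p(1-F)/F, (1-p)(1-F)/F) around it (Balding-Nichols drift).
    Returns ``(freqs, ancestral)`` with freqs of shape (n_lineages, n_sites).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    if n_sites is None:
        n_sites = cfg.n_genes * cfg.n_sites_per_gene
    lo = 1.0 / (2 * cfg.n_grid)
    hi = 1.0 - lo
    u = rng.random(n_sites)
    p = lo * (hi / lo) ** u  # density proportional to 1/p on [lo, hi]
    freqs = np.empty((len(cfg.lineages), n_sites))
    for row, lin in enumerate(cfg.lineages):
        F = cfg.lineage_divergence[lin]
        a = p * (1 - F) / F
        b = (1 - p) * (1 - F) / F
        freqs[row] = rng.beta(a, b)
    return freqs, p


def plant_sweep(
    freqs: np.ndarray,
    lineage_names: list[str],
    candidate_idx: np.ndarray,
    mode: str,
    target_freq: float,
    rng: np.random.Generator,
    tetraploid_lineage: str = "tetraploid",
    source_lineage: str | None = None,
    standing_range: tuple[float, float] = (0.02, 0.15),
) -> dict[str, float]:
    """Overwrite lineage frequencies at the planted candidate sites.

    Returns the per-lineage haplotype frequency of the swept allele. The
    frequency is identical across a gene's candidate sites because the sweep
    is a single haplotype. ``mode='none'`` leaves ``freqs`` untouched.
    """
    hap = {lin: 0.0 for lin in lineage_names}
    if mode == "none":
        return hap
    tet = lineage_names.index(tetraploid_lineage)
    hap[tetraploid_lineage] = target_freq
    if mode == "standing":
        if source_lineage is None:
            raise SimulationError("standing sweep needs a source lineage")
        lo, hi = standing_range
        hap[source_lineage] = float(rng.uniform(lo, hi))
    elif mode == "parallel":
        if source_lineage is None:
            raise SimulationError("parallel sweep needs a designated diploid lineage")
        hap[source_lineage] = target_freq
    for row, lin in enumerate(lineage_names):
        freqs[row, candidate_idx] = hap[lin]
    return hap


def plant_mnm(
    gene_start: int,
    gene_end: int,
    cluster_size: int,
    max_spacing_bp: int,
    transversion_prob: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Choose clustered candidate positions and their transversion flags.

    Consecutive spacings are multiples of 3 (distinct codons) bounded by
    ``max_spacing_bp``. Returns (positions, is_transversion).
    """
    max_step = max_spacing_bp // 3
    if max_step < 1:
        raise SimulationError("max_spacing_bp must allow a 3 bp codon step")
    gaps = 3 * rng.integers(1, max_step + 1, size=cluster_size - 1)
    span = int(gaps.sum())
    if gene_end - gene_start < span:
        raise SimulationError("gene too short for the requested MNM cluster")
    start = int(rng.integers(gene_start, gene_end - span + 1))
    positions = np.concatenate([[start], start + np.cumsum(gaps)])
    is_tv = rng.random(cluster_size) < transversion_prob
    return positions.astype(np.int64), is_tv


def sample_genotypes(
    freqs: np.ndarray,
    variants: list[Variant],
    individuals: list[Individual],
    lineage_names: list[str],
    depth_mean: float,
    missing_rate: float,
    rng: np.random.Generator,
    linked_blocks: list[tuple[np.ndarray, dict[str, float]]] | None = None,
) -> GenotypeMatrix:
    """Binomial dosage sampling with Poisson depth and missingness.

    ``dosage[v,i] ~ Binomial(ploidy_i, f_lineage(i),v)``. For every linked
    block (a swept gene), each individual draws a single haplotype count that
    is reused across the block's sites. Genotypes become missing with
    probability ``missing_rate`` and always when depth <= 8.
    """
    n_sites = freqs.shape[1]
    n_ind = len(individuals)
    lineage_row = {lin: r for r, lin in enumerate(lineage_names)}
    dosage = np.zeros((n_sites, n_ind), dtype=np.int16)
    for i, ind in enumerate(individuals):
        f = freqs[lineage_row[ind.lineage]]
        dosage[:, i] = rng.binomial(ind.ploidy, f)
    if linked_blocks:
        for site_idx, hap_freq in linked_blocks:
            for i, ind in enumerate(individuals):
                h = rng.binomial(ind.ploidy, hap_freq[ind.lineage])
                dosage[site_idx, i] = h
    depth = rng.poisson(depth_mean, size=(n_sites, n_ind)).astype(np.int32)
    miss = (rng.random((n_sites, n_ind)) < missing_rate) | (depth <= 8)
    dosage[miss] = MISSING
    return GenotypeMatrix(list(variants), list(individuals), dosage, depth)


def simulate_msa(
    n_species: int,
    site_constraint: list[str],
    rng: np.random.Generator,
    reference_protein: str,
    reference_name: str = "A_lyrata",
    gap_rate: float = 0.02,
) -> ProteinAlignment:
    """Ortholog alignment with per-column constraint classes.

    ``conserved`` and ``neutral`` columns substitute away from the reference
    with the class's probability; ``free`` columns draw residues uniformly
    from the 20 states. Gaps appear at ``gap_rate`` in non-reference rows;
    the reference row stays ungapped.
    """
    L = len(reference_protein)
    if len(site_constraint) != L:
        raise SimulationError("site_constraint length must match the protein")
    aas = np.array(list(dm.AMINO_ACIDS))
    ref = np.array(list(reference_protein))
    seqs = {reference_name: reference_protein}
    for s in range(n_species - 1):
        row = ref.copy()
        for j, cls in enumerate(site_constraint):
            if cls == "free":
                row[j] = aas[rng.integers(20)]
            else:
                if rng.random() < CONSTRAINT_SUB_PROB[cls]:
                    choices = aas[aas != ref[j]]
                    row[j] = choices[rng.integers(len(choices))]
        gaps = rng.random(L) < gap_rate
        row[gaps] = "-"
        seqs[f"sp_{s + 1:02d}"] = "".join(row)
    return ProteinAlignment(seqs, reference_name)


# ---------------------------------------------------------------------------
# full bundle


@dataclass
class Bundle:
    config: SimConfig
    genotypes: GenotypeMatrix
    individuals: list[Individual]
    annotations: list[VariantAnnotation]
    genes: list[GeneModel]
    truth: TruthRecord
    sift: SiftTable
    msas: dict[str, ProteinAlignment]
    grantham: dm.GranthamMatrix


def _make_individuals(cfg: SimConfig) -> list[Individual]:
    out = []
    for pop in cfg.populations:
        for k in range(pop.n_individuals):
            out.append(Individual(f"{pop.name}_{k}", pop.name, pop.lineage, pop.ploidy))
    return out


def _alt_for_ref(ref: str, is_tv: bool, rng: np.random.Generator) -> str:
    if is_tv:
        pair = TRANSVERSION_PARTNERS[ref]
        return pair[int(rng.integers(2))]
    return TRANSITION_PARTNER[ref]


def generate_bundle(cfg: SimConfig) -> Bundle:
    """Build the full in-memory dataset bundle deterministically."""
    rng = np.random.default_rng(cfg.seed)
    individuals = _make_individuals(cfg)
    grantham = dm.read_grantham()
    high_pairs = [
        (a, b)
        for a in dm.AMINO_ACIDS
        for b in dm.AMINO_ACIDS
        if a != b and grantham.score(a, b) >= 180
    ]
    gene_ids = cfg.gene_ids()
    sweep_by_gene = {p.gene_id: p for p in cfg.sweep_plan}
    mnm_by_gene = {p.gene_id: p for p in cfg.mnm_plan}
    unknown = (set(sweep_by_gene) | set(mnm_by_gene)) - set(gene_ids)
    if unknown:
        raise SimulationError(f"plan references unknown genes: {sorted(unknown)}")

    prot_len = cfg.gene_length // 3
    nt = np.array(list("ACGT"))

    positions_per_gene: dict[str, np.ndarray] = {}
    candidate_pos: dict[str, np.ndarray] = {}
    mnm_tv: dict[str, np.ndarray] = {}
    for gi, gid in enumerate(gene_ids):
        start, end = cfg.gene_interval(gi)
        if gid in mnm_by_gene:
            plan = mnm_by_gene[gid]
            cpos, is_tv = plant_mnm(start, end, plan.cluster_size,
                                    plan.max_spacing_bp, plan.transversion_prob, rng)
            n_rest = cfg.n_sites_per_gene - plan.cluster_size
            pool = np.setdiff1d(np.arange(start, end + 1), cpos)
            rest = rng.choice(pool, size=n_rest, replace=False)
            pos = np.sort(np.concatenate([cpos, rest]))
            candidate_pos[gid] = cpos
            mnm_tv[gid] = is_tv
        else:
            pos = np.sort(rng.choice(np.arange(start, end + 1),
                                     size=cfg.n_sites_per_gene, replace=False))
            if gid in sweep_by_gene and sweep_by_gene[gid].mode != "none":
                plan = sweep_by_gene[gid]
                if plan.n_candidate_aas > cfg.n_sites_per_gene:
                    raise SimulationError(
                        f"{gid}: cannot plant {plan.n_candidate_aas} candidate "
                        f"sites among {cfg.n_sites_per_gene}"
                    )
                candidate_pos[gid] = np.sort(
                    rng.choice(pos, size=plan.n_candidate_aas, replace=False)
                )
        positions_per_gene[gid] = pos

    # flatten layout
    all_gene: list[str] = []
    all_pos: list[int] = []
    for gid in gene_ids:
        all_gene.extend([gid] * cfg.n_sites_per_gene)
        all_pos.extend(positions_per_gene[gid].tolist())
    all_pos_arr = np.array(all_pos)
    n_sites = len(all_pos)
    site_index = {(cfg.chrom, p): i for i, p in enumerate(all_pos)}

    # effects: planted candidate sites are forced missense
    planted_mask = np.zeros(n_sites, dtype=bool)
    for gid, cpos in candidate_pos.items():
        for p in cpos:
            planted_mask[site_index[(cfg.chrom, int(p))]] = True
    effect = np.where(
        rng.random(n_sites) < cfg.p_missense, EFFECT_MISSENSE,
        np.where(rng.random(n_sites) < cfg.p_synonymous / (1 - cfg.p_missense),
                 EFFECT_SYNONYMOUS, EFFECT_OTHER),
    ).astype(object)
    effect[planted_mask] = EFFECT_MISSENSE
    fourfold = (effect == EFFECT_SYNONYMOUS) & (rng.random(n_sites) < cfg.fourfold_frac)

    # frequencies + sweep planting
    freqs, _ancestral = simulate_frequencies(cfg, rng, n_sites=n_sites)
    lineages = cfg.lineages
    linked_blocks: list[tuple[np.ndarray, dict[str, float]]] = []
    hap_freqs: dict[str, dict[str, float]] = {}
    accumulated: dict[str, list[int]] = {}
    mnm_sweep_target = {p.gene_id: p.target_freq for p in cfg.mnm_plan}

    def _plant(gid: str, mode: str, target: float, source: str | None,
               standing_range: tuple[float, float], age: int) -> None:
        cpos = candidate_pos[gid]
        cidx = np.array([site_index[(cfg.chrom, int(p))] for p in cpos])
        hap = plant_sweep(freqs, lineages, cidx, mode, target, rng,
                          cfg.tetraploid_lineage, source, standing_range)
        hap_freqs[gid] = hap
        linked_blocks.append((cidx, hap))
        # hard sweep clears linked tetraploid variation inside the span,
        # then age_mutations post-sweep variants re-seed it
        gmask = np.array([g == gid for g in all_gene])
        interior = gmask & (all_pos_arr > cpos.min()) & (all_pos_arr < cpos.max())
        interior[cidx] = False
        tet_row = lineages.index(cfg.tetraploid_lineage)
        idx_interior = np.flatnonzero(interior)
        freqs[tet_row, idx_interior] = 0.0
        n_new = min(age, idx_interior.size)
        new_idx = rng.choice(idx_interior, size=n_new, replace=False) if n_new else []
        accumulated[gid] = sorted(int(all_pos_arr[i]) for i in new_idx)
        for i in new_idx:
            freqs[tet_row, i] = rng.uniform(0.1, 0.3)

    for plan in cfg.sweep_plan:
        if plan.mode == "none":
            hap_freqs[plan.gene_id] = {lin: 0.0 for lin in lineages}
            accumulated[plan.gene_id] = []
            continue
        _plant(plan.gene_id, plan.mode, plan.target_freq, plan.source_lineage,
               plan.standing_range, plan.age_mutations)
    for plan in cfg.mnm_plan:
        _plant(plan.gene_id, "de_novo", plan.target_freq, None, (0, 0), 0)

    # alleles: ref = ancestral, alt = derived; transversion-controlled
    refs = nt[rng.integers(4, size=n_sites)]
    is_tv = rng.random(n_sites) < cfg.tv_background
    for gid, tv_flags in mnm_tv.items():
        for p, tv in zip(candidate_pos[gid], tv_flags):
            is_tv[site_index[(cfg.chrom, int(p))]] = tv
    alts = np.array([_alt_for_ref(r, t, rng) for r, t in zip(refs, is_tv)])

    variants = [
        Variant(cfg.chrom, int(p), str(r), str(a), "alt")
        for p, r, a in zip(all_pos, refs, alts)
    ]

    # proteins, amino-acid pairs, constraint classes
    protein_seq: dict[str, np.ndarray] = {}
    constraint: dict[str, np.ndarray] = {}
    aas = np.array(list(dm.AMINO_ACIDS))
    for gid in gene_ids:
        protein_seq[gid] = aas[rng.integers(20, size=prot_len)]
        cls = np.where(rng.random(prot_len) < cfg.conserved_background,
                       "conserved", "neutral").astype(object)
        constraint[gid] = cls

    gene_start = {gid: cfg.gene_interval(gi)[0] for gi, gid in enumerate(gene_ids)}
    aa_pos_of = lambda gid, pos: (pos - gene_start[gid]) // 3 + 1

    # planted sites: high-Grantham pair + constraint by sweep provenance
    parallel_genes = {p.gene_id for p in cfg.sweep_plan if p.mode == "parallel"}
    planted_pair: dict[int, tuple[str, str]] = {}
    for gid, cpos in candidate_pos.items():
        want = "neutral" if gid in parallel_genes else "conserved"
        for p in cpos:
            i = site_index[(cfg.chrom, int(p))]
            ap = aa_pos_of(gid, int(p))
            pair = high_pairs[int(rng.integers(len(high_pairs)))]
            protein_seq[gid][ap - 1] = pair[0]
            planted_pair[i] = pair
            constraint[gid][ap - 1] = want

    annotations: list[VariantAnnotation] = []
    for i, gid in enumerate(all_gene):
        var = variants[i]
        eff = effect[i]
        if eff == EFFECT_MISSENSE:
            ap = int(aa_pos_of(gid, var.pos))
            if i in planted_pair:
                aa_ref, aa_alt = planted_pair[i]
            else:
                aa_ref = str(protein_seq[gid][ap - 1])
                others = aas[aas != aa_ref]
                aa_alt = str(others[rng.integers(len(others))])
            annotations.append(VariantAnnotation(var, gid, eff, ap, aa_ref, aa_alt, False))
        else:
            annotations.append(
                VariantAnnotation(var, gid, eff, None, None, None, bool(fourfold[i]))
            )

    # SIFT: anti-correlated with constraint; some entries absent
    sift_scores: dict[tuple[str, int], float] = {}
    for i, ann in enumerate(annotations):
        if ann.effect != EFFECT_MISSENSE:
            continue
        if i in planted_pair:
            raw = rng.uniform(0.0, 0.05)
        else:
            gid = all_gene[i]
            cls = constraint[gid][ann.aa_pos - 1]
            raw = rng.uniform(0.05, 0.6) if cls == "conserved" else rng.uniform(0.3, 1.0)
        if rng.random() >= cfg.sift_absent_rate:
            sift_scores[(cfg.chrom, ann.variant.pos)] = round(float(raw), 6)
    sift = SiftTable(sift_scores)

    genotypes = sample_genotypes(
        freqs, variants, individuals, lineages, cfg.depth_mean,
        cfg.missing_rate, rng, linked_blocks,
    )

    # MSAs
    msas = {}
    if cfg.generate_msas:
        for gid in gene_ids:
            n_species = int(rng.integers(13, cfg.msa_species + 1))
            msas[gid] = simulate_msa(
                n_species, list(constraint[gid]), rng,
                "".join(protein_seq[gid]), gap_rate=cfg.msa_gap_rate,
            )

    # gene models + focus set
    focus = set(candidate_pos) | {
        p.gene_id for p in cfg.sweep_plan
    }
    neutral_ids = [g for g in gene_ids if g not in focus]
    focus |= set(neutral_ids[-cfg.n_focus_neutral:]) if cfg.n_focus_neutral else set()
    genes = [
        GeneModel(gid, cfg.chrom, *cfg.gene_interval(gi), gid in focus)
        for gi, gid in enumerate(gene_ids)
    ]

    # truth record
    truth_genes: dict[str, TruthGene] = {}
    mode_of = {p.gene_id: p.mode for p in cfg.sweep_plan}
    src_of = {p.gene_id: p.source_lineage for p in cfg.sweep_plan}
    age_of = {p.gene_id: p.age_mutations for p in cfg.sweep_plan}
    for plan in cfg.mnm_plan:
        mode_of[plan.gene_id] = "de_novo"
        src_of[plan.gene_id] = None
        age_of[plan.gene_id] = 0
    for gid in sorted(set(mode_of) | set(candidate_pos)):
        sites = []
        for p in candidate_pos.get(gid, np.array([], dtype=int)):
            i = site_index[(cfg.chrom, int(p))]
            ap = int(aa_pos_of(gid, int(p)))
            sites.append(TruthSite(
                cfg.chrom, int(p), gid, ap, str(refs[i]), str(alts[i]),
                {lin: float(f) for lin, f in hap_freqs.get(gid, {}).items()},
                str(constraint[gid][ap - 1]), bool(is_tv[i]),
            ))
        truth_genes[gid] = TruthGene(
            gid, mode_of[gid], sites, src_of.get(gid),
            age_of.get(gid, 0), gid in mnm_by_gene, accumulated.get(gid, []),
        )
    truth = TruthRecord(lineages, cfg.tetraploid_lineage, truth_genes)

    return Bundle(cfg, genotypes, individuals, annotations, genes, truth,
                  sift, msas, grantham)


BUNDLE_FILES = {
    "vcf": "variants.vcf",
    "annotations": "annotations.tsv",
    "popmap": "popmap.tsv",
    "sift": "sift.tsv",
    "grantham": "grantham.tsv",
    "genes": "genes.tsv",
    "truth": "truth.json",
    "msa_dir": "msa",
}


def emit_dataset(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the whole bundle to ``outdir``; returns the artifact paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = generate_bundle(cfg)
    paths = {k: outdir / v for k, v in BUNDLE_FILES.items()}
    dm.write_vcf(bundle.genotypes, paths["vcf"])
    dm.write_annotations(bundle.annotations, paths["annotations"])
    with open(paths["popmap"], "w") as fh:
        fh.write("id\tpopulation\tlineage\tploidy\n")
        for ind in bundle.individuals:
            fh.write(f"{ind.id}\t{ind.population}\t{ind.lineage}\t{ind.ploidy}\n")
    dm.write_sift(bundle.sift, paths["sift"])
    dm.write_grantham(bundle.grantham, paths["grantham"])
    dm.write_gene_models(bundle.genes, paths["genes"])
    bundle.truth.to_json(paths["truth"])
    paths["msa_dir"].mkdir(exist_ok=True)
    for gid, aln in sorted(bundle.msas.items()):
        dm.write_msa(aln, paths["msa_dir"] / f"{gid}.fasta")
    return paths


def load_bundle(outdir: str | Path) -> Bundle:
    """Re-read an emitted bundle through the datamodel readers."""
    outdir = Path(outdir)
    popmap = dm.read_popmap(outdir / BUNDLE_FILES["popmap"])
    gm = dm.read_vcf(outdir / BUNDLE_FILES["vcf"], popmap)
    annotations = dm.read_annotations(outdir / BUNDLE_FILES["annotations"])
    genes = dm.read_gene_models(outdir / BUNDLE_FILES["genes"])
    truth = TruthRecord.from_json(outdir / BUNDLE_FILES["truth"])
    sift = dm.read_sift(outdir / BUNDLE_FILES["sift"])
    grantham = dm.read_grantham(outdir / BUNDLE_FILES["grantham"])
    msas = {}
    for fasta in sorted((outdir / BUNDLE_FILES["msa_dir"]).glob("*.fasta")):
        msas[fasta.stem] = dm.read_msa(fasta, "A_lyrata")
    return Bundle(SimConfig(), gm, popmap, annotations, genes, truth, sift,
                  msas, grantham)


__all__ = [
    "SimConfig", "PopulationSpec", "SweepPlan", "MnmPlan", "TruthRecord",
    "TruthGene", "TruthSite", "Bundle", "SimulationError",
    "simulate_frequencies", "plant_sweep", "plant_mnm", "sample_genotypes",
    "simulate_msa", "generate_bundle", "emit_dataset", "load_bundle",
]
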