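"""Domain types and readers/writers for the external file formats.

Everything downstream (filters, scans, MK test, haplotype analyses) consumes
the in-memory containers defined here: a :class:`GenotypeMatrix` of per-site
ALT-allele dosages with per-individual ploidy, typed variant annotations, the
Grantham physicochemical-distance matrix, per-variant SIFT scores and ortholog
protein alignments.

Conventions
-----------
* Coordinates are VCF-style: 1-based positions, gene intervals 1-based
  inclusive.
* Only biallelic SNPs are kept; indels and multiallelic records are skipped
  (a skip counter is logged).
* A genotype with any missing allele call (``.``) is fully missing and is
  excluded from every frequency denominator (AC/AN semantics).
* Genotypes are treated as unphased throughout; no phasing is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import AlignIO

log = logging.getLogger(__name__)

MISSING = -1  #: dosage sentinel for a missing genotype

AMINO_ACIDS = tuple("ARNDCQEGHILKMFPSTWYV")

EFFECT_SYNONYMOUS = "synonymous"
EFFECT_MISSENSE = "missense"
EFFECT_OTHER = "other"

_NUCLEOTIDES = frozenset("ACGT")


class DataModelError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass(frozen=True)
class Individual:
    """One sampled plant with its population, lineage and ploidy (2 or 4)."""

    id: str
    population: str
    lineage: str
    ploidy: int

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 4):
            raise DataModelError(
                f"individual {self.id!r}: ploidy must be 2 or 4, got {self.ploidy}"
            )


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP; ``derived_allele`` is 'ref', 'alt' or 'unknown'."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    derived_allele: str = "unknown"

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise DataModelError(f"{self.chrom}:{self.pos}: REF equals ALT")
        if self.derived_allele not in ("ref", "alt", "unknown"):
            raise DataModelError(
                f"{self.chrom}:{self.pos}: bad derived_allele {self.derived_allele!r}"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class GenotypeMatrix:
    """Dosage and depth matrices of shape (n_variants, n_individuals).

    ``dosage[v, i]`` is the count of the ALT allele in individual *i*'s
    genotype at variant *v* (0..ploidy), or :data:`MISSING`.
    """

    variants: list[Variant]
    individuals: list[Individual]
    dosage: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        nv, ni = len(self.variants), len(self.individuals)
        if self.dosage.shape != (nv, ni) or self.depth.shape != (nv, ni):
            raise DataModelError(
                f"matrix shape mismatch: {self.dosage.shape} vs ({nv}, {ni})"
            )
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        pl = self.ploidy[None, :]
        ok = (self.dosage == MISSING) | (
            (self.dosage >= 0) & (self.dosage <= pl)
        )
        if not ok.all():
            v, i = np.argwhere(~ok)[0]
            raise DataModelError(
                f"dosage {self.dosage[v, i]} out of range for ploidy "
                f"{self.individuals[i].ploidy} at {self.variants[v].chrom}:"
                f"{self.variants[v].pos}, sample {self.individuals[i].id}"
            )

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def ploidy(self) -> np.ndarray:
        return np.array([ind.ploidy for ind in self.individuals], dtype=np.int16)

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def derived_dosage(self) -> np.ndarray:
        """Dosage of the derived allele (requires polarized variants).

        Variants with unknown polarity raise; missing stays :data:`MISSING`.
        """
        out = self.dosage.copy()
        pl = self.ploidy[None, :]
        for v, var in enumerate(self.variants):
            if var.derived_allele == "unknown":
                raise DataModelError(
                    f"{var.chrom}:{var.pos}: derived allele unknown; polarize first"
                )
            if var.derived_allele == "ref":
                row = out[v]
                nonmiss = row != MISSING
                row[nonmiss] = pl[0][nonmiss] - row[nonmiss]
        return out

    def take_variants(self, idx: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            [self.variants[i] for i in idx],
            self.individuals,
            self.dosage[idx],
            self.depth[idx],
        )

    def take_individuals(self, idx: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.variants,
            [self.individuals[i] for i in idx],
            self.dosage[:, idx],
            self.depth[:, idx],
        )

    def individual_indices(self, predicate) -> np.ndarray:
        return np.array(
            [i for i, ind in enumerate(self.individuals) if predicate(ind)],
            dtype=np.intp,
        )

    def variant_index(self) -> dict[tuple[str, int], int]:
        return {v.key: i for i, v in enumerate(self.variants)}


@dataclass(frozen=True)
class VariantAnnotation:
    variant: Variant
    gene_id: str
    effect: str
    aa_pos: int | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None
    fourfold: bool = False

    def __post_init__(self) -> None:
        if self.effect == EFFECT_MISSENSE:
            if not (self.aa_pos and self.aa_ref and self.aa_alt):
                raise DataModelError(
                    f"{self.variant.chrom}:{self.variant.pos}: missense "
                    "annotation lacks amino-acid fields"
                )
            if self.aa_ref == self.aa_alt:
                raise DataModelError(
                    f"{self.variant.chrom}:{self.variant.pos}: missense with "
                    "identical amino acids"
                )
        if self.fourfold and self.effect != EFFECT_SYNONYMOUS:
            raise DataModelError(
                f"{self.variant.chrom}:{self.variant.pos}: fourfold site must "
                "be synonymous"
            )


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    in_focus_set: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataModelError(f"gene {self.gene_id}: start > end")


@dataclass
class GranthamMatrix:
    """Symmetric 20x20 physicochemical distance between amino acids."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if list(t.index) != list(t.columns):
            raise DataModelError("Grantham matrix rows/columns disagree")
        arr = t.to_numpy(dtype=float)
        if (arr < 0).any():
            raise DataModelError("Grantham matrix has negative entries")
        if not np.allclose(arr, arr.T):
            raise DataModelError("Grantham matrix is not symmetric")
        if np.diag(arr).any():
            raise DataModelError("Grantham matrix diagonal must be zero")

    def score(self, aa1: str, aa2: str) -> float:
        return float(self.table.at[aa1, aa2])


@dataclass
class SiftTable:
    """Raw SIFT score per variant, 0 = most deleterious; may be absent."""

    scores: dict[tuple[str, int], float]

    def get(self, chrom: str, pos: int) -> float | None:
        return self.scores.get((chrom, pos))


@dataclass
class ProteinAlignment:
    """Named, equal-length aligned amino-acid sequences with '-' gaps."""

    sequences: dict[str, str]
    reference_name: str

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise DataModelError("ragged alignment: sequences differ in length")
        if self.reference_name not in self.sequences:
            raise DataModelError(
                f"reference {self.reference_name!r} absent from alignment"
            )

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def column(self, idx: int) -> str:
        """1-based alignment column."""
        return "".join(s[idx - 1] for s in self.sequences.values())


# ---------------------------------------------------------------------------
# readers / writers


def read_popmap(path: str | Path) -> list[Individual]:
    """Read a TSV with columns id, population, lineage, ploidy."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "population": str, "lineage": str})
    required = {"id", "population", "lineage", "ploidy"}
    if not required.issubset(df.columns):
        raise DataModelError(f"popmap {path}: missing columns {required - set(df.columns)}")
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise DataModelError(f"popmap {path}: duplicate individual id {dup!r}")
    individuals = []
    for row in df.itertuples(index=False):
        ploidy = int(row.ploidy)
        individuals.append(Individual(row.id, row.population, row.lineage, ploidy))
    return individuals


def read_vcf(path: str | Path, popmap: Sequence[Individual]) -> GenotypeMatrix:
    """Read GT/DP from a VCF into a :class:`GenotypeMatrix`.

    Sample order follows the popmap. Multiallelic and indel records are
    skipped (count logged). GT arity must equal the individual's ploidy.
    The optional ``AA`` INFO field (ancestral allele) sets polarity.
    """
    by_id = {ind.id: ind for ind in popmap}
    vcf = pysam.VariantFile(str(path))
    vcf_samples = list(vcf.header.samples)
    unknown = [s for s in vcf_samples if s not in by_id]
    if unknown:
        raise DataModelError(f"VCF sample {unknown[0]!r} not in popmap")
    missing_from_vcf = [i for i in by_id if i not in set(vcf_samples)]
    if missing_from_vcf:
        raise DataModelError(f"popmap individual {missing_from_vcf[0]!r} absent from VCF")
    individuals = [by_id[s] for s in vcf_samples]

    variants: list[Variant] = []
    dosage_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1 \
                or rec.ref not in _NUCLEOTIDES or alts[0] not in _NUCLEOTIDES:
            n_skipped += 1
            continue
        derived = "unknown"
        aa = rec.info.get("AA")
        if aa is not None:
            aa = str(aa)
            if aa == rec.ref:
                derived = "alt"
            elif aa == alts[0]:
                derived = "ref"
        variants.append(Variant(rec.chrom, rec.pos, rec.ref, alts[0], derived))
        drow = np.empty(len(individuals), dtype=np.int16)
        prow = np.empty(len(individuals), dtype=np.int32)
        for i, sample in enumerate(vcf_samples):
            call = rec.samples[sample]
            gt = call.get("GT")
            arity = 0 if gt is None else len(gt)
            if arity not in (0,) and arity != individuals[i].ploidy:
                raise DataModelError(
                    f"{rec.chrom}:{rec.pos} sample {sample}: GT arity {arity} "
                    f"!= ploidy {individuals[i].ploidy}"
                )
            if gt is None or any(a is None for a in gt):
                drow[i] = MISSING
            else:
                drow[i] = sum(1 for a in gt if a == 1)
            dp = call.get("DP")
            prow[i] = 0 if dp is None else int(dp)
        dosage_rows.append(drow)
        depth_rows.append(prow)
    if n_skipped:
        log.info("read_vcf(%s): skipped %d non-biallelic-SNP records", path, n_skipped)
    dosage = np.array(dosage_rows, dtype=np.int16).reshape(len(variants), len(individuals))
    depth = np.array(depth_rows, dtype=np.int32).reshape(len(variants), len(individuals))
    gm = GenotypeMatrix(variants, individuals, dosage, depth)
    gm.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return gm


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT, DP and the AA (ancestral) INFO tag."""
    contigs = sorted({v.chrom for v in gm.variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ind.id for ind in gm.individuals)
            + "\n"
        )
        ploidy = gm.ploidy
        for v, var in enumerate(gm.variants):
            if var.derived_allele == "alt":
                info = f"AA={var.ref_allele}"
            elif var.derived_allele == "ref":
                info = f"AA={var.alt_allele}"
            else:
                info = "."
            fields = [var.chrom, str(var.pos), ".", var.ref_allele,
                      var.alt_allele, ".", "PASS", info, "GT:DP"]
            for i in range(gm.n_individuals):
                d = gm.dosage[v, i]
                p = int(ploidy[i])
                if d == MISSING:
                    gt = "/".join(["."] * p)
                else:
                    gt = "/".join(["0"] * (p - int(d)) + ["1"] * int(d))
                fields.append(f"{gt}:{gm.depth[v, i]}")
            fh.write("\t".join(fields) + "\n")


def read_annotations(path: str | Path) -> list[VariantAnnotation]:
    """Read the variant annotation TSV (chrom, pos, ref, alt, gene, effect,
    aa_pos, aa_ref, aa_alt, fourfold)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str},
                     keep_default_na=False, na_values=[""])
    out = []
    for row in df.itertuples(index=False):
        effect = row.effect if row.effect in (EFFECT_SYNONYMOUS, EFFECT_MISSENSE) else EFFECT_OTHER
        aa_pos = None if pd.isna(row.aa_pos) else int(row.aa_pos)
        aa_ref = None if pd.isna(row.aa_ref) else str(row.aa_ref)
        aa_alt = None if pd.isna(row.aa_alt) else str(row.aa_alt)
        fourfold = str(row.fourfold).lower() in ("true", "1", "yes")
        variant = Variant(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        out.append(VariantAnnotation(variant, str(row.gene), effect,
                                     aa_pos, aa_ref, aa_alt, fourfold))
    return out


def annotations_frame(annotations: Iterable[VariantAnnotation]) -> pd.DataFrame:
    """Flatten annotations into a DataFrame keyed by (chrom, pos)."""
    rows = [
        {
            "chrom": a.variant.chrom,
            "pos": a.variant.pos,
            "ref": a.variant.ref_allele,
            "alt": a.variant.alt_allele,
            "gene": a.gene_id,
            "effect": a.effect,
            "aa_pos": a.aa_pos,
            "aa_ref": a.aa_ref,
            "aa_alt": a.aa_alt,
            "fourfold": a.fourfold,
        }
        for a in annotations
    ]
    return pd.DataFrame(rows)


def write_annotations(annotations: Iterable[VariantAnnotation], path: str | Path) -> None:
    df = annotations_frame(annotations)
    df.to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    return [
        GeneModel(row.gene, row.chrom, int(row.start), int(row.end),
                  bool(row.in_focus_set))
        for row in df.itertuples(index=False)
    ]


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"gene": g.gene_id, "chrom": g.chrom, "start": g.start,
             "end": g.end, "in_focus_set": g.in_focus_set}
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def read_grantham(path: str | Path | None = None) -> GranthamMatrix:
    """Read a whitespace-delimited 20x20 Grantham table; defaults to the
    bundled copy of the published matrix."""
    if path is None:
        ref = resources.files("ploidyscan.data").joinpath("grantham.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep=r"\s+", index_col=0)
    else:
        df = pd.read_csv(path, sep=r"\s+", index_col=0)
    return GranthamMatrix(df)


def write_grantham(matrix: GranthamMatrix, path: str | Path) -> None:
    matrix.table.to_csv(path, sep="\t", index_label="AA")


def read_sift(path: str | Path) -> SiftTable:
    """Read a per-variant SIFT TSV (chrom, pos, sift); NA rows are absent."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    scores: dict[tuple[str, int], float] = {}
    for row in df.itertuples(index=False):
        if pd.isna(row.sift):
            continue
        s = float(row.sift)
        if not 0.0 <= s <= 1.0:
            raise DataModelError(f"SIFT score {s} outside [0,1] at {row.chrom}:{row.pos}")
        scores[(str(row.chrom), int(row.pos))] = s
    return SiftTable(scores)


def write_sift(table: SiftTable, path: str | Path) -> None:
    rows = [
        {"chrom": c, "pos": p, "sift": s}
        for (c, p), s in sorted(table.scores.items())
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "sift"]).to_csv(path, sep="\t", index=False)


def read_msa(path: str | Path, reference_name: str) -> ProteinAlignment:
    """Read a FASTA protein MSA; raises on ragged input."""
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise DataModelError(f"MSA {path}: {exc}") from exc
    seqs = {rec.id: str(rec.seq).upper() for rec in aln}
    return ProteinAlignment(seqs, reference_name)


def write_msa(alignment: ProteinAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in alignment.sequences.items():
            fh.write(f">{name}\n{seq}\n")


__all__ = [
    "MISSING", "AMINO_ACIDS", "EFFECT_SYNONYMOUS", "EFFECT_MISSENSE",
    "EFFECT_OTHER", "DataModelError", "Individual", "Variant",
    "GenotypeMatrix", "VariantAnnotation", "GeneModel", "GranthamMatrix",
    "SiftTable", "ProteinAlignment", "read_popmap", "read_vcf", "write_vcf",
    "read_annotations", "annotations_frame", "write_annotations",
    "read_gene_models", "write_gene_models", "read_grantham",
    "write_grantham", "read_sift", "write_sift", "read_msa", "write_msa",
]
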