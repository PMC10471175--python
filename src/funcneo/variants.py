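"""Somatic-variant expression filtering.

Tumor-versus-normal exome comparison yields a large set of somatic variants,
only a fraction of which are credible immunogen sources.  The cascade applied
here narrows them in three tiers:

1. **coding** — keep variants annotated to coding sequence;
2. **expressed** — require at least one tumor-RNA read carrying the variant
   base, i.e. the mutant allele is actually transcribed;
3. **strict** — require a variant allele frequency (VAF) of at least 20% in
   tumor RNA together with at least 10 variant-supporting RNA reads, so that
   downstream peptide synthesis is spent only on well-expressed mutations.

All thresholds are parameters; the defaults are the screening thresholds
stated above.  VAF is computed from RNA counts (``rna_alt_reads /
rna_depth``): the expression thresholds are anchored to the tumor RNA sample,
not to DNA allele fractions, which are carried but unused by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

__all__ = [
    "VariantClass",
    "SomaticVariant",
    "CascadeSummary",
    "CODING_CLASSES",
    "PROTEIN_ALTERING_CLASSES",
    "filter_coding",
    "filter_rna_expressed",
    "filter_strict",
    "cascade_summary",
    "read_variant_table",
    "write_variant_table",
    "read_vcf",
]

VariantClass = Literal[
    "missense", "synonymous", "inframe_indel", "frameshift", "splice_region", "noncoding"
]

VARIANT_CLASSES: frozenset[str] = frozenset(
    {"missense", "synonymous", "inframe_indel", "frameshift", "splice_region", "noncoding"}
)

#: Default coding set: every annotated class except noncoding.  Synonymous and
#: splice-region variants count as "in coding sequences" for the first tier;
#: only protein-altering classes proceed to peptide design downstream.
CODING_CLASSES: frozenset[str] = frozenset(VARIANT_CLASSES - {"noncoding"})

PROTEIN_ALTERING_CLASSES: frozenset[str] = frozenset({"missense", "inframe_indel", "frameshift"})


class VariantValidationError(ValueError):
    """A variant record violates a structural invariant."""


@dataclass(frozen=True)
class SomaticVariant:
    """One annotated somatic variant with DNA and RNA allele read evidence.

    ``protein_position`` / ``aa_ref`` / ``aa_alt`` are required for
    protein-altering classes (missense, inframe_indel, frameshift) and
    forbidden for noncoding variants.
    """

    variant_id: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    variant_class: str
    gene_symbol: str = ""
    transcript_id: str = ""
    protein_position: Optional[int] = None
    aa_ref: Optional[str] = None
    aa_alt: Optional[str] = None
    dna_alt_reads: int = 0
    dna_ref_reads: int = 0
    rna_alt_reads: int = 0
    rna_depth: int = 0

    def __post_init__(self) -> None:
        if not self.variant_class:
            raise VariantValidationError(f"variant {self.variant_id!r}: missing variant_class")
        if self.variant_class not in VARIANT_CLASSES:
            raise VariantValidationError(
                f"variant {self.variant_id!r}: unknown variant_class {self.variant_class!r}"
            )
        if self.position < 1:
            raise VariantValidationError(f"variant {self.variant_id!r}: position must be >= 1")
        for name in ("dna_alt_reads", "dna_ref_reads", "rna_alt_reads", "rna_depth"):
            if getattr(self, name) < 0:
                raise VariantValidationError(f"variant {self.variant_id!r}: {name} must be >= 0")
        if self.rna_alt_reads > self.rna_depth:
            raise VariantValidationError(
                f"variant {self.variant_id!r}: rna_alt_reads ({self.rna_alt_reads}) exceeds "
                f"rna_depth ({self.rna_depth})"
            )
        if self.variant_class in PROTEIN_ALTERING_CLASSES:
            if self.protein_position is None or self.aa_ref is None or self.aa_alt is None:
                raise VariantValidationError(
                    f"variant {self.variant_id!r}: protein_position/aa_ref/aa_alt required for "
                    f"{self.variant_class} variants"
                )
        if self.variant_class == "noncoding" and (
            self.protein_position is not None or self.aa_ref is not None or self.aa_alt is not None
        ):
            raise VariantValidationError(
                f"variant {self.variant_id!r}: protein-level fields are not allowed on "
                "noncoding variants"
            )

    @property
    def rna_vaf(self) -> Optional[float]:
        """RNA variant allele frequency; None when the site has no RNA coverage."""
        if self.rna_depth == 0:
            return None
        return self.rna_alt_reads / self.rna_depth

    @property
    def is_protein_altering(self) -> bool:
        return self.variant_class in PROTEIN_ALTERING_CLASSES


@dataclass(frozen=True)
class CascadeSummary:
    """Variant counts after each tier of the expression-filter cascade."""

    n_total: int
    n_coding: int
    n_expressed: int
    n_strict: int

    def __post_init__(self) -> None:
        if not (self.n_total >= self.n_coding >= self.n_expressed >= self.n_strict >= 0):
            raise VariantValidationError(
                f"cascade counts must be non-increasing and non-negative, got "
                f"({self.n_total}, {self.n_coding}, {self.n_expressed}, {self.n_strict})"
            )

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n_total, self.n_coding, self.n_expressed, self.n_strict)


def filter_coding(
    variants: Sequence[SomaticVariant],
    coding_classes: Iterable[str] = CODING_CLASSES,
) -> list[SomaticVariant]:
    """Keep variants whose class is in the coding set, preserving input order."""
    coding = frozenset(coding_classes)
    return [v for v in variants if v.variant_class in coding]


def filter_rna_expressed(
    variants: Sequence[SomaticVariant], min_alt_reads: int = 1
) -> list[SomaticVariant]:
    """Keep variants supported by at least ``min_alt_reads`` tumor-RNA reads of the variant base."""
    if min_alt_reads < 0:
        raise ValueError(f"min_alt_reads must be non-negative, got {min_alt_reads}")
    return [v for v in variants if v.rna_alt_reads >= min_alt_reads]


def filter_strict(
    variants: Sequence[SomaticVariant],
    min_vaf: float = 0.20,
    min_reads: int = 10,
    strict_reads_mode: Literal["alt", "depth"] = "alt",
) -> list[SomaticVariant]:
    """Keep variants with RNA VAF >= ``min_vaf`` and at least ``min_reads`` RNA reads.

    ``strict_reads_mode`` selects whether the read-count floor applies to
    variant-supporting reads (``"alt"``, default) or to total site depth
    (``"depth"``).  Variants with zero RNA depth have no defined VAF and are
    removed, not treated as errors.  Both thresholds are inclusive.
    """
    if not 0.0 <= min_vaf <= 1.0:
        raise ValueError(f"min_vaf must lie in [0, 1], got {min_vaf}")
    if strict_reads_mode not in ("alt", "depth"):
        raise ValueError(f"strict_reads_mode must be 'alt' or 'depth', got {strict_reads_mode!r}")
    kept = []
    for v in variants:
        vaf = v.rna_vaf
        if vaf is None or vaf < min_vaf:
            continue
        reads = v.rna_alt_reads if strict_reads_mode == "alt" else v.rna_depth
        if reads >= min_reads:
            kept.append(v)
    return kept


def cascade_summary(
    variants: Sequence[SomaticVariant],
    coding_classes: Iterable[str] = CODING_CLASSES,
    min_alt_reads: int = 1,
    min_vaf: float = 0.20,
    min_reads: int = 10,
    strict_reads_mode: Literal["alt", "depth"] = "alt",
) -> CascadeSummary:
    """Sequentially compose the three filters and report per-tier counts."""
    coding = filter_coding(variants, coding_classes)
    expressed = filter_rna_expressed(coding, min_alt_reads)
    strict = filter_strict(expressed, min_vaf, min_reads, strict_reads_mode)
    return CascadeSummary(len(variants), len(coding), len(expressed), len(strict))


# ---------------------------------------------------------------------------
# Tab-delimited I/O

_TABLE_COLUMNS = [
    "variant_id", "chrom", "pos", "ref", "alt", "class", "gene", "transcript",
    "protein_pos", "aa_ref", "aa_alt", "dna_alt", "dna_ref", "rna_alt", "rna_depth",
]


def _variant_to_row(v: SomaticVariant) -> dict:
    return {
        "variant_id": v.variant_id,
        "chrom": v.chromosome,
        "pos": v.position,
        "ref": v.ref_allele,
        "alt": v.alt_allele,
        "class": v.variant_class,
        "gene": v.gene_symbol,
        "transcript": v.transcript_id,
        "protein_pos": v.protein_position if v.protein_position is not None else "NA",
        "aa_ref": v.aa_ref if v.aa_ref is not None else "NA",
        "aa_alt": v.aa_alt if v.aa_alt is not None else "NA",
        "dna_alt": v.dna_alt_reads,
        "dna_ref": v.dna_ref_reads,
        "rna_alt": v.rna_alt_reads,
        "rna_depth": v.rna_depth,
    }


def variants_to_frame(variants: Sequence[SomaticVariant]) -> pd.DataFrame:
    return pd.DataFrame([_variant_to_row(v) for v in variants], columns=_TABLE_COLUMNS)


def write_variant_table(variants: Sequence[SomaticVariant], path) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)


def _opt_int(value) -> Optional[int]:
    if pd.isna(value) or value == "NA" or value == "":
        return None
    return int(value)


def _opt_str(value) -> Optional[str]:
    if pd.isna(value) or value == "NA" or value == "":
        return None
    return str(value)


def read_variant_table(path) -> list[SomaticVariant]:
    """Read the canonical tab-delimited variant table."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise VariantValidationError(f"variant table is missing columns: {missing}")
    out = []
    for row in df.to_dict("records"):
        out.append(
            SomaticVariant(
                variant_id=str(row["variant_id"]),
                chromosome=str(row["chrom"]),
                position=int(row["pos"]),
                ref_allele=str(row["ref"]),
                alt_allele=str(row["alt"]),
                variant_class=str(row["class"]),
                gene_symbol=str(row["gene"]),
                transcript_id=str(row["transcript"]),
                protein_position=_opt_int(row["protein_pos"]),
                aa_ref=_opt_str(row["aa_ref"]),
                aa_alt=_opt_str(row["aa_alt"]),
                dna_alt_reads=int(row["dna_alt"]),
                dna_ref_reads=int(row["dna_ref"]),
                rna_alt_reads=int(row["rna_alt"]),
                rna_depth=int(row["rna_depth"]),
            )
        )
    return out


def read_vcf(
    vcf_path,
    rna_counts_path,
    class_info_key: str = "CSQ_CLASS",
    sample_index: int = 0,
) -> list[SomaticVariant]:
    """Import variants from a VCF 4.x file plus a companion RNA-count table.

    Per-sample ``AD`` supplies the DNA ref/alt read counts; the consequence
    class is read from INFO key ``class_info_key``.  RNA evidence comes from a
    two-column tab-delimited table (``site``, ``rna_alt:rna_depth`` or two
    numeric columns) keyed on ``chrom:pos:ref:alt``.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    rna = pd.read_csv(rna_counts_path, sep="\t", dtype={0: str})
    if rna.shape[1] < 3:
        raise VariantValidationError(
            "RNA count table needs columns: site key, rna_alt, rna_depth"
        )
    key_col, alt_col, depth_col = rna.columns[:3]
    rna_map = {
        str(r[key_col]): (int(r[alt_col]), int(r[depth_col])) for _, r in rna.iterrows()
    }

    out = []
    for i, rec in enumerate(VCF(str(vcf_path))):
        alt = rec.ALT[0] if rec.ALT else ""
        key = f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
        rna_alt, rna_depth = rna_map.get(key, (0, 0))
        ad = rec.format("AD")
        if ad is not None:
            dna_ref, dna_alt_n = int(ad[sample_index][0]), int(ad[sample_index][1])
        else:
            dna_ref, dna_alt_n = 0, 0
        vclass = rec.INFO.get(class_info_key) or "noncoding"
        vid = rec.ID if rec.ID not in (None, ".") else f"var{i + 1}"
        out.append(
            SomaticVariant(
                variant_id=str(vid),
                chromosome=str(rec.CHROM),
                position=int(rec.POS),
                ref_allele=str(rec.REF),
                alt_allele=str(alt),
                variant_class=str(vclass),
                gene_symbol=str(rec.INFO.get("GENE") or ""),
                transcript_id=str(rec.INFO.get("TRANSCRIPT") or ""),
                protein_position=_opt_int(rec.INFO.get("PROTEIN_POS")),
                aa_ref=_opt_str(rec.INFO.get("AA_REF")),
                aa_alt=_opt_str(rec.INFO.get("AA_ALT")),
                dna_alt_reads=dna_alt_n,
                dna_ref_reads=dna_ref,
                rna_alt_reads=rna_alt,
                rna_depth=rna_depth,
            )
        )
    return out
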