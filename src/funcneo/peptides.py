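"""Mutant long-peptide and minimal-epitope design.

Each well-expressed missense mutation is turned into a pair of 20-mer
peptides: the mutant peptide carries the substituted residue at a chosen
anchor position (by default position 6 or position 15 of the 20-mer), flanked
by wild-type sequence, and the wild-type (WT) counterpart covers the same
window of the reference protein.  Placing the mutation at two different
anchors samples distinct flanking contexts for MHC class I and class II
presentation.  When the requested window would run past a protein terminus it
is shifted minimally to fit, and the realized anchor is recorded — the same
fallback that forces an off-standard anchor near an alternative-splice
boundary.

Longer validated peptides can then be tiled into every 10-mer and 15-mer
window that still contains the mutated residue, to map the minimal epitopes
recognized by CD8+ (short, MHC I) and CD4+ (longer, MHC II) T cells.
Finally, a helper epitope and an effector (CTL) epitope can be tethered into
a single synthetic construct through a triple-alanine (``AAA``) linker.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "ProteinRecord",
    "PeptideCandidate",
    "EpitopeTile",
    "LinkedConstruct",
    "apply_missense",
    "design_long_peptides",
    "tile_minimal_epitopes",
    "build_linked_construct",
    "read_proteome_fasta",
    "write_peptides_fasta",
    "peptides_to_frame",
    "write_peptide_manifest",
    "read_peptide_manifest",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class PeptideDesignError(ValueError):
    """Invalid input to a peptide-design operation."""


class ReferenceMismatchError(PeptideDesignError):
    """The protein residue at the variant position disagrees with the annotation.

    Guards against transcript/annotation drift between the variant table and
    the supplied proteome.
    """

    def __init__(self, protein_id: str, position: int, expected: str, observed: str):
        self.protein_id = protein_id
        self.position = position
        self.expected = expected
        self.observed = observed
        super().__init__(
            f"protein {protein_id!r} position {position}: expected reference residue "
            f"{expected!r} but found {observed!r}"
        )


def _check_sequence(seq: str, what: str) -> None:
    if not seq:
        raise PeptideDesignError(f"{what} sequence must be non-empty")
    bad = set(seq) - _AA_SET
    if bad:
        raise PeptideDesignError(f"{what} sequence contains non-standard residues: {sorted(bad)}")


@dataclass(frozen=True)
class ProteinRecord:
    """A reference or mutant protein (one record per splice isoform)."""

    protein_id: str
    sequence: str
    gene_symbol: str = ""
    isoform_label: str = ""

    def __post_init__(self) -> None:
        _check_sequence(self.sequence, f"protein {self.protein_id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideCandidate:
    """A designed mutant or WT peptide.

    ``anchor`` is the 1-based position of the mutated residue within the
    peptide; ``protein_start`` the 1-based index of the peptide's first
    residue in its source protein.  ``truncated`` marks peptides shortened
    because the whole protein is shorter than the requested length.
    """

    peptide_id: str
    mutation_id: str
    sequence: str
    anchor: int
    is_mutant: bool
    protein_start: int
    isoform_label: str = ""
    truncated: bool = False

    def __post_init__(self) -> None:
        _check_sequence(self.sequence, f"peptide {self.peptide_id!r}")
        if not 1 <= self.anchor <= len(self.sequence):
            raise PeptideDesignError(
                f"peptide {self.peptide_id!r}: anchor {self.anchor} outside 1..{len(self.sequence)}"
            )
        if self.protein_start < 1:
            raise PeptideDesignError(f"peptide {self.peptide_id!r}: protein_start must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class EpitopeTile:
    """A short window of a parent peptide that still contains the anchor residue."""

    tile_id: str
    parent_peptide_id: str
    offset: int  # 1-based start within the parent
    length: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.length:
            raise PeptideDesignError(
                f"tile {self.tile_id!r}: sequence length {len(self.sequence)} != {self.length}"
            )


@dataclass(frozen=True)
class LinkedConstruct:
    """A helper epitope tethered to an effector epitope via a peptide linker."""

    helper_sequence: str
    effector_sequence: str
    linker_sequence: str
    combined_sequence: str

    @property
    def helper_span(self) -> tuple[int, int]:
        """1-based inclusive span of the helper within the combined sequence."""
        return (1, len(self.helper_sequence))

    @property
    def effector_span(self) -> tuple[int, int]:
        start = len(self.helper_sequence) + len(self.linker_sequence) + 1
        return (start, len(self.combined_sequence))


def apply_missense(
    protein: ProteinRecord, protein_position: int, aa_ref: str, aa_alt: str
) -> ProteinRecord:
    """Substitute one residue, verifying the annotated reference residue first."""
    seq = protein.sequence
    if not 1 <= protein_position <= len(seq):
        raise PeptideDesignError(
            f"protein {protein.protein_id!r}: position {protein_position} outside 1..{len(seq)}"
        )
    observed = seq[protein_position - 1]
    if observed != aa_ref:
        raise ReferenceMismatchError(protein.protein_id, protein_position, aa_ref, observed)
    mutated = seq[: protein_position - 1] + aa_alt + seq[protein_position:]
    return replace(protein, sequence=mutated)


def _window_for_anchor(m: int, anchor: int, length: int, protein_len: int) -> tuple[int, int]:
    """1-based (start, realized_anchor) of a length-`length` window placing residue
    ``m`` at ``anchor``, shifted minimally to stay inside the protein."""
    start = m - anchor + 1
    start = max(1, min(start, protein_len - length + 1))
    return start, m - start + 1


def design_long_peptides(
    mutant_protein: ProteinRecord,
    reference_protein: ProteinRecord,
    mut_residue_index: int,
    anchors: Sequence[int] = (6, 15),
    length: int = 20,
    mutation_id: Optional[str] = None,
) -> list[PeptideCandidate]:
    """Design mutant/WT long-peptide pairs around one mutated residue.

    One mutant peptide is emitted per requested anchor, spanning residues
    ``[m - a + 1, m - a + length]`` of the mutant protein, together with the
    WT counterpart over the same window of the reference protein.  Windows
    that would overrun a terminus are shifted minimally to fit (the realized
    anchor is recorded); windows that coincide after shifting are emitted
    once.  Proteins shorter than ``length`` yield a single truncated pair
    covering the whole protein.
    """
    if mutation_id is None:
        mutation_id = mutant_protein.gene_symbol or mutant_protein.protein_id
    plen = len(mutant_protein)
    m = mut_residue_index
    if not 1 <= m <= plen:
        raise PeptideDesignError(
            f"mut_residue_index {m} outside 1..{plen} for protein {mutant_protein.protein_id!r}"
        )
    if any(a > length or a < 1 for a in anchors):
        raise PeptideDesignError(f"anchors {list(anchors)} must lie in 1..{length}")

    truncated = plen < length
    eff_length = min(length, plen)

    seen_windows: set[int] = set()
    out: list[PeptideCandidate] = []
    multi = len(anchors) > 1
    for a in anchors:
        start, realized = _window_for_anchor(m, min(a, eff_length), eff_length, plen)
        if start in seen_windows:
            continue
        seen_windows.add(start)
        mut_seq = mutant_protein.sequence[start - 1 : start - 1 + eff_length]
        wt_seq = reference_protein.sequence[start - 1 : start - 1 + eff_length]
        suffix = f"_a{a}" if multi else ""
        common = dict(
            mutation_id=mutation_id,
            anchor=realized,
            protein_start=start,
            isoform_label=mutant_protein.isoform_label,
            truncated=truncated,
        )
        out.append(
            PeptideCandidate(
                peptide_id=f"Mut_{mutation_id}{suffix}", sequence=mut_seq, is_mutant=True, **common
            )
        )
        out.append(
            PeptideCandidate(
                peptide_id=f"WT_{mutation_id}{suffix}", sequence=wt_seq, is_mutant=False, **common
            )
        )
    return out


def tile_minimal_epitopes(
    parent: PeptideCandidate, lengths: Sequence[int] = (15, 10)
) -> list[EpitopeTile]:
    """Enumerate every window of each requested length that contains the anchor.

    Windows of length L containing anchor position k occupy offsets
    ``max(1, k - L + 1) .. min(len(parent) - L + 1, k)``.  Tiles are numbered
    in order of (length descending, offset ascending), so the longer
    (MHC II-sized) tiles come first.
    """
    plen = len(parent)
    k = parent.anchor
    for L in lengths:
        if L > plen:
            raise PeptideDesignError(
                f"tile length {L} exceeds parent peptide length {plen}"
            )
    tiles: list[EpitopeTile] = []
    idx = 0
    for L in sorted(set(lengths), reverse=True):
        lo = max(1, k - L + 1)
        hi = min(plen - L + 1, k)
        for offset in range(lo, hi + 1):
            idx += 1
            tiles.append(
                EpitopeTile(
                    tile_id=f"{parent.peptide_id}.{idx}",
                    parent_peptide_id=parent.peptide_id,
                    offset=offset,
                    length=L,
                    sequence=parent.sequence[offset - 1 : offset - 1 + L],
                )
            )
    return tiles


def build_linked_construct(
    helper: str, effector: str, linker: str = "AAA"
) -> LinkedConstruct:
    """Tether a helper epitope to an effector epitope via a peptide linker."""
    _check_sequence(helper, "helper")
    _check_sequence(effector, "effector")
    if linker:
        _check_sequence(linker, "linker")
    return LinkedConstruct(
        helper_sequence=helper,
        effector_sequence=effector,
        linker_sequence=linker,
        combined_sequence=helper + linker + effector,
    )


# ---------------------------------------------------------------------------
# FASTA and manifest I/O

def read_proteome_fasta(path) -> list[ProteinRecord]:
    """Read proteins from FASTA; description may carry `gene=SYM isoform=LABEL`."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene, isoform = "", ""
        for token in rec.description.split():
            if token.startswith("gene="):
                gene = token[5:]
            elif token.startswith("isoform="):
                isoform = token[8:]
        out.append(
            ProteinRecord(
                protein_id=rec.id, sequence=str(rec.seq).upper(),
                gene_symbol=gene, isoform_label=isoform,
            )
        )
    return out


def write_proteome_fasta(proteins: Sequence[ProteinRecord], path) -> None:
    records = [
        SeqRecord(
            Seq(p.sequence),
            id=p.protein_id,
            description=f"gene={p.gene_symbol} isoform={p.isoform_label}".strip(),
        )
        for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


def write_peptides_fasta(peptides: Sequence[PeptideCandidate], path) -> None:
    """Write peptides as FASTA; the description carries the design metadata."""
    records = [
        SeqRecord(
            Seq(p.sequence),
            id=p.peptide_id,
            description=(
                f"{p.mutation_id}|anchor={p.anchor}|is_mutant={int(p.is_mutant)}"
                f"|protein_start={p.protein_start}"
            ),
        )
        for p in peptides
    ]
    SeqIO.write(records, str(path), "fasta")


_MANIFEST_COLUMNS = [
    "peptide_id", "mutation_id", "gene", "isoform", "sequence",
    "anchor", "is_mutant", "protein_start", "truncated",
]


def peptides_to_frame(
    peptides: Sequence[PeptideCandidate], gene_by_mutation: Optional[dict] = None
) -> pd.DataFrame:
    gene_by_mutation = gene_by_mutation or {}
    rows = [
        {
            "peptide_id": p.peptide_id,
            "mutation_id": p.mutation_id,
            "gene": gene_by_mutation.get(p.mutation_id, ""),
            "isoform": p.isoform_label,
            "sequence": p.sequence,
            "anchor": p.anchor,
            "is_mutant": int(p.is_mutant),
            "protein_start": p.protein_start,
            "truncated": int(p.truncated),
        }
        for p in peptides
    ]
    return pd.DataFrame(rows, columns=_MANIFEST_COLUMNS)


def write_peptide_manifest(
    peptides: Sequence[PeptideCandidate], path, gene_by_mutation: Optional[dict] = None
) -> None:
    peptides_to_frame(peptides, gene_by_mutation).to_csv(path, sep="\t", index=False)


def read_peptide_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", keep_default_na=False,
        dtype={"peptide_id": str, "mutation_id": str, "gene": str, "isoform": str},
    )
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise PeptideDesignError(f"peptide manifest is missing columns: {missing}")
    return df
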