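"""Mutant long-peptide design, minimal-epitope tiling, linked constructs."""

import random

import pytest

from funcneo.peptides import (
    AMINO_ACIDS,
    PeptideCandidate,
    PeptideDesignError,
    ProteinRecord,
    ReferenceMismatchError,
    apply_missense,
    build_linked_construct,
    design_long_peptides,
    read_proteome_fasta,
    tile_minimal_epitopes,
    write_peptides_fasta,
    write_proteome_fasta,
)


def random_protein(rnd, length, protein_id="p1"):
    return ProteinRecord(protein_id, "".join(rnd.choice(AMINO_ACIDS) for _ in range(length)))


def hamming(a, b):
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


class TestApplyMissense:
    def test_substitutes_exactly_one_residue(self):
        out = apply_missense(ProteinRecord("p", "ACDEF"), 3, "D", "N")
        assert out.sequence == "ACNEF"

    def test_reference_mismatch_reports_both_residues(self):
        with pytest.raises(ReferenceMismatchError) as err:
            apply_missense(ProteinRecord("p", "ACDEF"), 3, "E", "N")
        assert err.value.expected == "E"
        assert err.value.observed == "D"

    def test_position_out_of_range(self):
        with pytest.raises(PeptideDesignError):
            apply_missense(ProteinRecord("p", "ACDEF"), 6, "F", "N")

    def test_hamming_distance_is_one_on_random_proteins(self):
        rnd = random.Random(11)
        for _ in range(50):
            prot = random_protein(rnd, 200)
            pos = rnd.randint(1, 200)
            aa_ref = prot.sequence[pos - 1]
            aa_alt = rnd.choice([a for a in AMINO_ACIDS if a != aa_ref])
            out = apply_missense(prot, pos, aa_ref, aa_alt)
            assert hamming(out.sequence, prot.sequence) == 1
            assert out.sequence[pos - 1] == aa_alt


def design_oracle_check(mutant, reference, m, peptides):
    """Brute-force substring / anchor / single-difference checks."""
    by_window = {}
    for p in peptides:
        source = mutant.sequence if p.is_mutant else reference.sequence
        # substring at the recorded start
        assert source[p.protein_start - 1 : p.protein_start - 1 + len(p)] == p.sequence
        # anchor points at the mutated residue
        assert p.protein_start + p.anchor - 1 == m
        by_window.setdefault((p.protein_start, len(p)), {})[p.is_mutant] = p
    for window, pair in by_window.items():
        assert set(pair) == {True, False}
        mut_p, wt_p = pair[True], pair[False]
        if mutant.sequence[m - 1] != reference.sequence[m - 1]:
            assert hamming(mut_p.sequence, wt_p.sequence) == 1
            diff = [i for i, (a, b) in enumerate(zip(mut_p.sequence, wt_p.sequence), 1) if a != b]
            assert diff == [mut_p.anchor]


class TestDesignLongPeptides:
    @pytest.fixture
    def pair40(self):
        rnd = random.Random(3)
        ref = random_protein(rnd, 40)
        mut = apply_missense(
            ref, 20, ref.sequence[19], rnd.choice([a for a in AMINO_ACIDS if a != ref.sequence[19]])
        )
        return mut, ref

    def test_interior_mutation_two_anchor_windows(self, pair40):
        mut, ref = pair40
        peptides = design_long_peptides(mut, ref, 20, anchors=(6, 15), length=20)
        assert len(peptides) == 4
        mutants = {p.anchor: p for p in peptides if p.is_mutant}
        assert mutants[6].protein_start == 15   # residues 15-34
        assert mutants[15].protein_start == 6   # residues 6-25
        design_oracle_check(mut, ref, 20, peptides)

    def test_n_terminal_shift_realizes_anchor_3(self, pair40):
        mut0, ref = pair40
        mut = apply_missense(
            ref, 3, ref.sequence[2],
            [a for a in AMINO_ACIDS if a != ref.sequence[2]][0],
        )
        peptides = design_long_peptides(mut, ref, 3, anchors=(6, 15), length=20)
        # both anchors clamp to the same window starting at residue 1
        assert len(peptides) == 2
        p = [q for q in peptides if q.is_mutant][0]
        assert (p.protein_start, p.anchor) == (1, 3)
        design_oracle_check(mut, ref, 3, peptides)

    def test_c_terminal_shift_realizes_anchor_18(self, pair40):
        _, ref = pair40
        mut = apply_missense(
            ref, 38, ref.sequence[37],
            [a for a in AMINO_ACIDS if a != ref.sequence[37]][0],
        )
        peptides = design_long_peptides(mut, ref, 38, anchors=(15,), length=20)
        p = [q for q in peptides if q.is_mutant][0]
        assert (p.protein_start, p.anchor) == (21, 18)  # residues 21-40
        design_oracle_check(mut, ref, 38, peptides)

    def test_short_protein_truncates_with_flag(self):
        ref = ProteinRecord("p", "ACDEFGHIKLMNPQ")  # 14 residues < 20
        mut = apply_missense(ref, 7, "H", "Q")
        peptides = design_long_peptides(mut, ref, 7, anchors=(6, 15), length=20)
        assert all(p.truncated and len(p) == 14 for p in peptides)
        assert len(peptides) == 2  # windows coincide

    def test_out_of_range_index(self):
        ref = ProteinRecord("p", "ACDEF" * 10)
        with pytest.raises(PeptideDesignError):
            design_long_peptides(ref, ref, 0)

    def test_shifted_anchor_never_leaves_peptide(self):
        rnd = random.Random(23)
        for _ in range(200):
            length = rnd.randint(20, 60)
            ref = random_protein(rnd, length)
            m = rnd.randint(1, length)
            aa_ref = ref.sequence[m - 1]
            aa_alt = rnd.choice([a for a in AMINO_ACIDS if a != aa_ref])
            mut = apply_missense(ref, m, aa_ref, aa_alt)
            peptides = design_long_peptides(mut, ref, m)
            assert peptides
            for p in peptides:
                assert 1 <= p.anchor <= len(p)
                source = mut.sequence if p.is_mutant else ref.sequence
                assert p.sequence in source
            design_oracle_check(mut, ref, m, peptides)


class TestTiling:
    def parent(self, anchor, length=20):
        rnd = random.Random(5)
        seq = "".join(rnd.choice(AMINO_ACIDS) for _ in range(length))
        return PeptideCandidate(
            peptide_id="Mut_48", mutation_id="48", sequence=seq,
            anchor=anchor, is_mutant=True, protein_start=100,
        )

    def brute_force_offsets(self, parent_len, anchor, L):
        return [
            off
            for off in range(1, parent_len - L + 2)
            if off <= anchor <= off + L - 1
        ]

    def test_ten_mers_anchor_15(self):
        tiles = tile_minimal_epitopes(self.parent(15), lengths=(10,))
        assert [t.offset for t in tiles] == list(range(6, 12))
        assert [t.offset for t in tiles] == self.brute_force_offsets(20, 15, 10)

    def test_anchor_1_single_window(self):
        tiles = tile_minimal_epitopes(self.parent(1), lengths=(10,))
        assert len(tiles) == 1 and tiles[0].offset == 1

    def test_both_lengths_twelve_tiles_numbered_long_first(self):
        parent = self.parent(15)
        tiles = tile_minimal_epitopes(parent, lengths=(10, 15))
        assert len(tiles) == 12
        assert [t.length for t in tiles] == [15] * 6 + [10] * 6
        assert [t.tile_id for t in tiles] == [f"Mut_48.{i}" for i in range(1, 13)]
        for t in tiles:
            assert t.sequence == parent.sequence[t.offset - 1 : t.offset - 1 + t.length]
            assert t.offset <= parent.anchor <= t.offset + t.length - 1

    def test_enumeration_matches_brute_force_everywhere(self):
        for anchor in range(1, 21):
            parent = self.parent(anchor)
            for L in (10, 15):
                tiles = tile_minimal_epitopes(parent, lengths=(L,))
                assert [t.offset for t in tiles] == self.brute_force_offsets(20, anchor, L)

    def test_tile_longer_than_parent_rejected(self):
        with pytest.raises(PeptideDesignError):
            tile_minimal_epitopes(self.parent(3, length=8), lengths=(10,))


class TestLinkedConstruct:
    def test_triple_alanine_linker(self):
        lc = build_linked_construct("HHHHH", "EEEEE")
        assert lc.combined_sequence == "HHHHHAAAEEEEE"
        assert lc.helper_span == (1, 5)
        assert lc.effector_span == (9, 13)

    def test_empty_linker_degenerate(self):
        lc = build_linked_construct("HHHHH", "EEEEE", linker="")
        assert lc.combined_sequence == "HHHHHEEEEE"

    def test_length_identity(self):
        rnd = random.Random(9)
        for _ in range(20):
            h = "".join(rnd.choice(AMINO_ACIDS) for _ in range(rnd.randint(1, 25)))
            e = "".join(rnd.choice(AMINO_ACIDS) for _ in range(rnd.randint(1, 25)))
            lc = build_linked_construct(h, e)
            assert len(lc.combined_sequence) == len(h) + 3 + len(e)

    def test_empty_components_rejected(self):
        with pytest.raises(PeptideDesignError):
            build_linked_construct("", "EEEEE")


class TestFastaIO:
    def test_proteome_roundtrip(self, tmp_path):
        prots = [
            ProteinRecord("p1", "ACDEFGHIKL", gene_symbol="Cltc", isoform_label="iso1"),
            ProteinRecord("p2", "MNPQRSTVWY"),
        ]
        path = tmp_path / "prot.fasta"
        write_proteome_fasta(prots, path)
        back = read_proteome_fasta(path)
        assert [(p.protein_id, p.sequence, p.gene_symbol) for p in back] == [
            ("p1", "ACDEFGHIKL", "Cltc"),
            ("p2", "MNPQRSTVWY", ""),
        ]

    def test_peptide_fasta_carries_design_metadata(self, tmp_path):
        pep = PeptideCandidate(
            peptide_id="Mut_44", mutation_id="44", sequence="ACDEFGHIKL",
            anchor=6, is_mutant=True, protein_start=17,
        )
        path = tmp_path / "pep.fasta"
        write_peptides_fasta([pep], path)
        text = path.read_text()
        assert ">Mut_44" in text
        assert "anchor=6" in text and "protein_start=17" in text
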