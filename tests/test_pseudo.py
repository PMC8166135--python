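import numpy as np
import pytest

from nlrmap.pseudo import (compare_region, detect_events, frameshift_align)
from nlrmap.simulate import _CODONS, revcomp


def back_translate(protein):
    return "".join(_CODONS[aa][0] for aa in protein)


@pytest.fixture(scope="module")
def protein():
    rng = np.random.default_rng(7)
    aas = "ARNDCQEGHIKMFPSTWYVL"
    return "M" + "".join(aas[i] for i in rng.integers(0, 20, 59))


@pytest.fixture(scope="module")
def clean_dna(protein):
    return back_translate(protein)


class TestFrameshiftAlign:
    def test_exact_back_translation_all_matches(self, protein, clean_dna):
        aln = frameshift_align(protein, clean_dna)
        assert all(o.op == "codon_match" for o in aln.ops)
        assert aln.dna_span == (0, len(clean_dna))

    def test_path_conservation(self, protein, clean_dna):
        """Consumed residues equal protein length; ops tile the span."""
        d = clean_dna[:90] + "GT" + clean_dna[91:]
        aln = frameshift_align(protein, d)
        prot_used, dna_used = aln.consumed()
        assert prot_used == len(protein)
        assert dna_used == aln.dna_span[1] - aln.dna_span[0]

    @pytest.mark.parametrize("edit,expected", [
        ("ins1", "+1"), ("ins2", "+2"), ("del1", "-1"), ("del2", "-2"),
    ])
    def test_single_frameshift_recovered(self, protein, clean_dna, edit,
                                         expected):
        pos = 90
        if edit == "ins1":
            d = clean_dna[:pos] + "G" + clean_dna[pos:]
        elif edit == "ins2":
            d = clean_dna[:pos] + "GG" + clean_dna[pos:]
        elif edit == "del1":
            d = clean_dna[:pos] + clean_dna[pos + 1:]
        else:
            d = clean_dna[:pos] + clean_dna[pos + 2:]
        aln = frameshift_align(protein, d)
        fs = [o for o in aln.ops if o.op == "frameshift"]
        assert [o.detail for o in fs] == [expected]
        assert abs(fs[0].dna_start - pos) <= 3

    def test_premature_stop_at_exact_codon(self, protein, clean_dna):
        d = clean_dna[:90] + "TAA" + clean_dna[93:]
        aln = frameshift_align(protein, d)
        stops = [o for o in aln.ops if o.op == "stop_codon"]
        assert [(o.protein_index, o.dna_start) for o in stops] == [(30, 90)]

    def test_multiple_stops_all_counted(self, protein, clean_dna):
        d = list(clean_dna)
        for codon_i in (15, 30, 45):
            d[3 * codon_i:3 * codon_i + 3] = "TGA"
        aln = frameshift_align(protein, "".join(d))
        stops = [o for o in aln.ops if o.op == "stop_codon"]
        assert [o.protein_index for o in stops] == [15, 30, 45]

    def test_whole_codon_deletion_is_protein_gap(self, protein, clean_dna):
        d = clean_dna[:90] + clean_dna[93:]
        aln = frameshift_align(protein, d)
        special = [o for o in aln.ops
                   if o.op not in ("codon_match", "codon_substitution")]
        assert [o.op for o in special] == ["protein_gap"]

    def test_free_flanking_dna_not_penalized(self, protein, clean_dna):
        rng = np.random.default_rng(3)
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        aln_plain = frameshift_align(protein, clean_dna)
        aln_padded = frameshift_align(protein, flank + clean_dna + flank)
        assert aln_padded.score == aln_plain.score
        assert aln_padded.dna_span == (2000, 2000 + len(clean_dna))

    def test_reduces_to_standard_alignment_without_frameshifts(self, protein):
        """Substitution-only DNA: huge frameshift penalty gives the
        protein-protein global alignment score."""
        from Bio import Align
        from Bio.Align import substitution_matrices
        rng = np.random.default_rng(11)
        mutated = list(protein)
        for i in rng.integers(5, 55, size=6):
            mutated[i] = "ARNDCQEGHIKMFPSTWYVL"[rng.integers(0, 20)]
        mutated = "".join(mutated)
        dna = back_translate(mutated)
        aln = frameshift_align(protein, dna, frameshift_penalty=10_000)
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        assert aln.score == aligner.align(protein, mutated)[0].score

    def test_region_too_short_rejected(self, protein):
        with pytest.raises(ValueError, match="too short"):
            frameshift_align(protein, "ATG" * 10)

    def test_short_protein_rejected(self):
        with pytest.raises(ValueError, match="protein"):
            frameshift_align("MKV", "ATG" * 30)


class TestDetectEvents:
    def test_clean_alignment_no_events(self, protein, clean_dna):
        assert detect_events(frameshift_align(protein, clean_dna)) == []

    def test_large_insertion_called_above_threshold(self, protein, clean_dna):
        rng = np.random.default_rng(5)
        ins = "".join("ACGT"[i] for i in rng.integers(0, 4, 7800))
        d = clean_dna[:90] + ins + clean_dna[90:]
        events = detect_events(frameshift_align(protein, d))
        assert [(e.type, e.position) for e in events] == \
            [("large_insertion", 90)]
        assert events[0].detail == "len=7800"

    def test_small_codon_gap_not_large_insertion(self, protein, clean_dna):
        rng = np.random.default_rng(6)
        ins = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        d = clean_dna[:90] + ins + clean_dna[90:]
        events = detect_events(frameshift_align(protein, d),
                               large_insertion_min=1000)
        assert all(e.type != "large_insertion" for e in events)

    def test_events_sorted_by_position(self, protein, clean_dna):
        d = list(clean_dna)
        d[3 * 40:3 * 40 + 3] = "TAA"
        d = "".join(d)
        d = d[:60] + "G" + d[60:]
        events = detect_events(frameshift_align(protein, d))
        positions = [e.position for e in events]
        assert positions == sorted(positions)
        assert {e.type for e in events} == {"frameshift_insertion",
                                            "premature_stop"}


@pytest.fixture(scope="module")
def mapped_panel(mutated_panel):
    from nlrmap import nbarc
    from nlrmap.anchors import build_map
    records = {a.accession_id: nbarc.select_candidates(a.genes)
               for a in mutated_panel.accessions}
    genomes = {a.accession_id: a.sequences
               for a in mutated_panel.accessions}
    chains = {}
    build_map(records, genomes, "acc1", chains_by_accession=chains)
    return records, chains


class TestCompareRegion:
    def _report(self, panel, mapped_panel, ref_gid, qry_acc):
        records, chains = mapped_panel
        rec = next(r for r in records["acc1"] if r.gene_id == ref_gid)
        acc = next(a for a in panel.accessions if a.accession_id == qry_acc)
        return compare_region(rec, qry_acc, acc.sequences, chains[qry_acc])

    def test_untouched_gene_conserved(self, mutated_panel, mapped_panel):
        touched = {(e.accession_id, e.gene_id) for e in mutated_panel.events}
        done = 0
        for acc in mutated_panel.accessions[1:]:
            for g in mutated_panel.reference.genes:
                if (acc.accession_id, g.gene_id) in touched or done >= 3:
                    continue
                rep = self._report(mutated_panel, mapped_panel, g.gene_id,
                                   acc.accession_id)
                assert rep.verdict == "conserved" and not rep.events
                done += 1
        assert done == 3

    def test_planted_stop_pseudogenized(self, mutated_panel, mapped_panel):
        ev = next(e for e in mutated_panel.events
                  if e.event_type == "premature_stop")
        rep = self._report(mutated_panel, mapped_panel, ev.gene_id,
                           ev.accession_id)
        assert rep.verdict == "pseudogenized"
        assert rep.counts()["premature_stop"] >= 1

    def test_deleted_gene_absent(self, mutated_panel, mapped_panel):
        ev = next(e for e in mutated_panel.events
                  if e.event_type == "gene_deletion")
        rep = self._report(mutated_panel, mapped_panel, ev.gene_id,
                           ev.accession_id)
        assert rep.verdict == "absent"

    def test_planted_large_insertion_detected(self, mutated_panel,
                                              mapped_panel):
        ev = next(e for e in mutated_panel.events
                  if e.event_type == "large_insertion")
        rep = self._report(mutated_panel, mapped_panel, ev.gene_id,
                           ev.accession_id)
        assert rep.verdict == "pseudogenized"
        assert rep.counts()["large_insertion"] == 1
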