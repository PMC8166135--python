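import numpy as np
import pytest

from nlrmap.anchors import (AnchorBlock, Chain, ExactMatch, chain_blocks,
                            chains_from_paf, chains_to_paf, find_mums,
                            project_interval)
from nlrmap.genome_io import GenomeSequence
from nlrmap.simulate import revcomp


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestFindMums:
    def test_identical_sequences_single_full_match(self):
        rng = np.random.default_rng(0)
        s = random_seq(rng, 5000)
        ref = GenomeSequence("r", "c", s)
        qry = GenomeSequence("q", "c", s)
        plus = [m for m in find_mums(ref, qry) if m.strand == "+"]
        assert len(plus) == 1
        assert (plus[0].ref_start, plus[0].length) == (0, 5000)
        assert plus[0].qry_start == 0

    def test_no_unique_shared_kmers_empty(self):
        # a pure tandem repeat has no unique k-mers on either strand
        rng = np.random.default_rng(9)
        ref = GenomeSequence("r", "c", "ACGGT" * 200)
        qry = GenomeSequence("q", "c", random_seq(rng, 1000))
        assert find_mums(ref, qry) == []

    def test_snv_splits_into_two_abutting_matches(self):
        rng = np.random.default_rng(1)
        s = random_seq(rng, 4000)
        p = 2000
        s2 = s[:p] + ("A" if s[p] != "A" else "C") + s[p + 1:]
        ref = GenomeSequence("r", "c", s)
        qry = GenomeSequence("q", "c", s2)
        plus = sorted((m for m in find_mums(ref, qry) if m.strand == "+"),
                      key=lambda m: m.ref_start)
        assert len(plus) == 2
        assert plus[0].ref_start == 0 and plus[0].ref_end == p
        assert plus[1].ref_start == p + 1 and plus[1].ref_end == 4000

    def test_reverse_strand_match_found(self):
        rng = np.random.default_rng(2)
        s = random_seq(rng, 3000)
        ref = GenomeSequence("r", "c", s)
        qry = GenomeSequence("q", "c", revcomp(s))
        minus = [m for m in find_mums(ref, qry) if m.strand == "-"]
        assert len(minus) == 1 and minus[0].length == 3000

    def test_repeated_region_produces_no_anchor(self):
        rng = np.random.default_rng(3)
        unique = random_seq(rng, 1000)
        repeat = random_seq(rng, 500)
        s = unique + repeat + repeat
        ref = GenomeSequence("r", "c", s)
        qry = GenomeSequence("q", "c", s)
        plus = [m for m in find_mums(ref, qry) if m.strand == "+"]
        covered = set()
        for m in plus:
            covered.update(range(m.ref_start, m.ref_end))
        # the duplicated block has no 1-to-1 anchors except its borders
        assert not (set(range(1100, 1400)) & covered)

    def test_low_min_length_rejected(self):
        ref = GenomeSequence("r", "c", "ACGT" * 100)
        with pytest.raises(ValueError, match="min_length"):
            find_mums(ref, ref, min_length=8)


class TestChainBlocks:
    def test_collinear_matches_all_kept(self):
        ms = [ExactMatch(0, 0, 100, "+"), ExactMatch(200, 200, 100, "+"),
              ExactMatch(400, 400, 100, "+")]
        chains = chain_blocks(ms, "c", "q", "c")
        assert len(chains) == 1 and len(chains[0].blocks) == 3

    def test_crossing_matches_keep_heavier(self):
        ms = [ExactMatch(0, 500, 80, "+"), ExactMatch(100, 0, 300, "+")]
        chains = chain_blocks(ms, "c", "q", "c")
        blocks = chains[0].blocks
        assert len(blocks) == 1 and blocks[0].ref_start == 100

    def test_insertion_leaves_one_sided_gap(self):
        """8 kb query-only insertion: qry gap ~8 kb, ref gap 0."""
        rng = np.random.default_rng(4)
        left = random_seq(rng, 3000)
        right = random_seq(rng, 3000)
        ins = random_seq(rng, 8000)
        ref = GenomeSequence("r", "c", left + right)
        qry = GenomeSequence("q", "c", left + ins + right)
        chains = chain_blocks(find_mums(ref, qry), "c", "q", "c")
        blocks = sorted(chains[0].blocks, key=lambda b: b.ref_start)
        gaps = [(b2.qry_start - b1.qry_end, b2.ref_start - b1.ref_end)
                for b1, b2 in zip(blocks, blocks[1:])]
        big = [g for g in gaps if g[0] >= 7500]
        assert len(big) == 1
        qgap, rgap = big[0]
        assert qgap == 8000 and rgap == 0


def identity_chain(n=10_000):
    return Chain("c", "q", "c", "+",
                 [AnchorBlock("c", 0, n, "q", "c", 0, n, "+")])


def offset_chain(offset=500, n=10_000):
    return Chain("c", "q", "c", "+",
                 [AnchorBlock("c", offset, n + offset, "q", "c", 0, n, "+")])


class TestProjectInterval:
    def test_identity(self):
        proj = project_interval(identity_chain(), (100, 200))
        assert proj.interval == (100, 200) and proj.flag == "in_block"

    def test_uniform_offset(self):
        proj = project_interval(offset_chain(500), (100, 200))
        assert proj.interval == (600, 700)

    def test_round_trip(self):
        chain = offset_chain(1234)
        fwd = project_interval(chain, (2000, 2400), direction="qry2ref")
        back = project_interval(chain, fwd.interval, direction="ref2qry")
        assert back.interval == (2000, 2400)

    def test_monotone_midpoints(self):
        chain = Chain("c", "q", "c", "+", [
            AnchorBlock("c", 0, 4000, "q", "c", 0, 4000, "+"),
            AnchorBlock("c", 5000, 9000, "q", "c", 4500, 8500, "+"),
        ])
        mids = []
        for lo in range(0, 8000, 400):
            proj = project_interval(chain, (lo, lo + 200))
            if proj.interval:
                mids.append(sum(proj.interval) // 2)
        assert mids == sorted(mids)

    def test_interval_inside_insertion_flagged(self):
        chain = Chain("c", "q", "c", "+", [
            AnchorBlock("c", 0, 3000, "q", "c", 0, 3000, "+"),
            AnchorBlock("c", 3000, 6000, "q", "c", 11000, 14000, "+"),
        ])
        proj = project_interval(chain, (6000, 6700))
        assert proj.flag == "inserted"
        assert proj.interval[0] == proj.interval[1] == 3000

    def test_beyond_bridge_unmapped(self):
        chain = Chain("c", "q", "c", "+", [
            AnchorBlock("c", 0, 1000, "q", "c", 0, 1000, "+"),
            AnchorBlock("c", 500_000, 501_000, "q", "c", 500_000, 501_000, "+"),
        ])
        proj = project_interval(chain, (200_000, 200_100))
        assert proj.flag == "unmapped" and proj.interval is None


class TestPaf:
    def test_round_trip(self):
        chain = Chain("c", "q", "cq", "+", [
            AnchorBlock("c", 0, 1000, "q", "cq", 100, 1100, "+"),
            AnchorBlock("c", 2000, 2500, "q", "cq", 2100, 2600, "+"),
        ])
        text = chains_to_paf([chain], {"c": 10_000, "cq": 10_000})
        back = chains_from_paf(text, "q")
        blocks = back["cq"].blocks
        assert [(b.ref_start, b.ref_end, b.qry_start, b.qry_end)
                for b in blocks] == \
            [(0, 1000, 100, 1100), (2000, 2500, 2100, 2600)]


class TestBuildMapOnPanel:
    def test_identity_panel_maps_everything_to_source(self, clean_panel):
        from nlrmap import nbarc
        from nlrmap.anchors import build_map
        records = {a.accession_id: nbarc.select_candidates(a.genes)
                   for a in clean_panel.accessions}
        genomes = {a.accession_id: a.sequences
                   for a in clean_panel.accessions}
        mapped, unmapped = build_map(records, genomes, "acc1")
        assert not unmapped
        total = sum(len(r) for r in records.values())
        assert len(mapped) == total
        ref_pos = {g.gene_id: (g.start, g.end)
                   for g in clean_panel.reference.genes}
        lineage = {}
        for a in clean_panel.accessions:
            lineage.update(a.lineage)
        for m in mapped:
            src = lineage[m.gene_id]
            assert m.ref_interval == ref_pos[src]

    def test_deleted_gene_simply_missing(self, mutated_panel):
        from nlrmap import nbarc
        from nlrmap.anchors import build_map
        records = {a.accession_id: nbarc.select_candidates(a.genes)
                   for a in mutated_panel.accessions}
        genomes = {a.accession_id: a.sequences
                   for a in mutated_panel.accessions}
        mapped, unmapped = build_map(records, genomes, "acc1")
        deleted = {(e.accession_id, e.gene_id) for e in mutated_panel.events
                   if e.event_type == "gene_deletion"}
        lineage = {}
        for a in mutated_panel.accessions:
            lineage.update(a.lineage)
        mapped_keys = {(m.accession_id, lineage[m.gene_id]) for m in mapped}
        assert not (deleted & mapped_keys)
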