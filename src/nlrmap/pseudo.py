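"""Frameshift-aware protein-to-DNA alignment and pseudogene calling.

To explain copy-number differences mechanistically, an intact protein is
aligned against the syntenic genomic region of another accession in
codon space. The dynamic program allows codon matches/substitutions
(BLOSUM62), whole-codon gaps on either side (affine -11/-1 per codon),
frameshift steps that consume 1, 2, 4 or 5 bases for one residue
(heavy penalty), and stop-codon read-through at a fixed penalty so that
every premature stop along the optimal path is observed, not just the
first. The protein is aligned globally; flanking DNA on both sides is
free (glocal), so padded windows cost nothing.

Events derived from the optimal path: premature stop codons (point
mutations), frameshift insertions/deletions (small InDels), and long
runs of codon-sized DNA gaps (large insertions).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .anchors import Chain, MappedNlr, project_interval
from .genome_io import GenomeSequence
from .nbarc import NlrRecord
from .simulate import revcomp

NEG = -(2 ** 29)

DEFAULT_GAP_OPEN = 11      # per codon, positive penalties
DEFAULT_GAP_EXTEND = 1
DEFAULT_GAP_CAP = 60       # flat cost for long DNA gaps (intron-style)
DEFAULT_FRAMESHIFT = 20
DEFAULT_STOP = 20          # stop-codon read-through penalty
DEFAULT_LARGE_INSERTION_MIN = 1000
DEFAULT_WINDOW_PAD = 10_000

_B62 = substitution_matrices.load("BLOSUM62")

_BASE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODON_AA = {}
from .simulate import _TABLE as _CODON_TABLE  # standard genetic code
for _codon, _aa in _CODON_TABLE.items():
    _CODON_AA[_codon] = _aa
for _stop in ("TAA", "TAG", "TGA"):
    _CODON_AA[_stop] = "*"


@dataclass
class AlignOp:
    op: str               # codon_match | codon_substitution | stop_codon |
    #                       protein_gap | dna_gap | frameshift
    protein_index: int    # 0-based residue index (-1 for dna_gap)
    dna_start: int        # region-local bp offset of consumed DNA
    dna_len: int
    detail: str = ""      # frameshift: "+1","+2","-1","-2"; stop: codon


@dataclass
class ProteinDnaAlignment:
    protein_id: str
    region: tuple[str, str, int, int, str]  # accession, seq_id, start, end, strand
    ops: list[AlignOp]
    score: int
    dna_span: tuple[int, int]  # region-local aligned bp interval

    def consumed(self) -> tuple[int, int]:
        """(protein residues, dna bases) consumed by the operation path."""
        prot = sum(1 for o in self.ops
                   if o.op in ("codon_match", "codon_substitution",
                               "stop_codon", "protein_gap", "frameshift"))
        dna = sum(o.dna_len for o in self.ops)
        return prot, dna

    def match_fraction(self) -> float:
        aligned = sum(1 for o in self.ops
                      if o.op in ("codon_match", "codon_substitution"))
        total = sum(1 for o in self.ops if o.op != "dna_gap")
        return aligned / total if total else 0.0


@dataclass
class PseudogeneEvent:
    type: str             # premature_stop | frameshift_insertion |
    #                       frameshift_deletion | large_insertion
    position: int         # region-local bp
    codon_index: int      # protein coordinate (-1 for large_insertion)
    detail: str = ""


def _codon_aa_track(dna: str) -> list[str]:
    """aa (or '*'/'X') of the codon ending at each position j (j >= 3)."""
    track = ["X"] * (len(dna) + 1)
    for j in range(3, len(dna) + 1):
        track[j] = _CODON_AA.get(dna[j - 3:j], "X")
    return track


def _residue_scores(protein: str, aa_track: list[str],
                    stop_penalty: int) -> dict[str, np.ndarray]:
    """Per-residue vectors of codon scores along the DNA."""
    n1 = len(aa_track)
    vectors: dict[str, np.ndarray] = {}
    distinct = sorted(set(protein))
    codon_aas = sorted(set(aa_track))
    for res in distinct:
        lut = {}
        for ca in codon_aas:
            if ca == "*":
                lut[ca] = -stop_penalty
            elif ca == "X" or res == "X":
                lut[ca] = 0
            else:
                lut[ca] = int(_B62[res, ca])
        vec = np.fromiter((lut[ca] for ca in aa_track), dtype=np.int32,
                          count=n1)
        vec[:3] = NEG  # no full codon ends before position 3
        vectors[res] = vec
    return vectors


def frameshift_align(protein: str, dna: str,
                     gap_open: int = DEFAULT_GAP_OPEN,
                     gap_extend: int = DEFAULT_GAP_EXTEND,
                     gap_cap: int | None = DEFAULT_GAP_CAP,
                     frameshift_penalty: int = DEFAULT_FRAMESHIFT,
                     stop_penalty: int = DEFAULT_STOP,
                     protein_id: str = "",
                     region: tuple = ("", "", 0, 0, "+"),
                     ) -> ProteinDnaAlignment:
    """Optimal codon-space alignment of a protein to a genomic region.

    DNA-gap cost is affine per codon but capped at ``gap_cap``, so a
    multi-kilobase insertion costs a flat amount (like an intron state)
    instead of scaling with its length — otherwise the optimal path
    would thread the protein through the inserted sequence rather than
    bridge it. Ties resolve deterministically: match/substitution is
    preferred over gaps, gaps over frameshifts, and leftmost end point
    wins.
    """
    m, n = len(protein), len(dna)
    if m < 10:
        raise ValueError("protein too short (< 10 aa)")
    if n < 1.5 * m:
        raise ValueError("region too short")

    aa_track = _codon_aa_track(dna)
    res_scores = _residue_scores(protein, aa_track, stop_penalty)
    FS = frameshift_penalty

    best = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    Pg = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    best[0, :] = 0  # leading DNA is free

    classes = [np.arange(c, n + 1, 3) for c in range(3)]

    for i in range(1, m + 1):
        prev = best[i - 1]
        sub = res_scores[protein[i - 1]]
        cand = np.full(n + 1, NEG, dtype=np.int32)
        # codon match / substitution / stop read-through
        np.maximum(cand[3:], prev[:-3] + sub[3:], out=cand[3:])
        # frameshifts: consume 1, 2, 4 or 5 bases for one residue
        np.maximum(cand[1:], prev[:-1] - FS, out=cand[1:])
        np.maximum(cand[2:], prev[:-2] - FS, out=cand[2:])
        np.maximum(cand[4:], prev[:-4] + sub[4:] - FS, out=cand[4:])
        np.maximum(cand[5:], prev[:-5] + sub[5:] - FS, out=cand[5:])
        # protein gap (vertical, affine)
        Pg[i] = np.maximum(prev - gap_open, Pg[i - 1] - gap_extend)
        NQ = np.maximum(cand, Pg[i])
        # dna gap (horizontal, stride 3, affine with cap) via running maxima
        row = NQ.copy()
        for idx in classes:
            if idx.size < 2:
                continue
            u = np.arange(idx.size, dtype=np.int64)
            vals = NQ[idx].astype(np.int64)
            A = vals + gap_extend * u
            runmax = np.maximum.accumulate(A)
            q = runmax[:-1] - gap_open + gap_extend - gap_extend * u[1:]
            if gap_cap is not None:
                flat = np.maximum.accumulate(vals)[:-1] - gap_cap
                q = np.maximum(q, flat)
            tail = idx[1:]
            row[tail] = np.maximum(row[tail], q.astype(np.int32))
        best[i] = row

    end_j = int(np.argmax(best[m]))  # leftmost maximum
    score = int(best[m, end_j])

    ops = _traceback(protein, dna, best, Pg, res_scores, end_j,
                     gap_open, gap_extend, gap_cap, FS)
    dna_start = ops[0].dna_start if ops else end_j
    aln = ProteinDnaAlignment(protein_id, region, ops, score,
                              (dna_start, end_j))
    _check_conservation(aln, m)
    return aln


def _traceback(protein, dna, best, Pg, res_scores, end_j,
               gap_open, gap_extend, gap_cap, FS) -> list[AlignOp]:
    m = len(protein)
    ops: list[AlignOp] = []
    i, j = m, end_j

    def codon_op(i, j, length):
        codon = dna[j - 3:j] if length >= 3 else dna[j - length:j]
        aa = _CODON_AA.get(dna[j - 3:j], "X") if j >= 3 else "X"
        res = protein[i - 1]
        if length in (4, 5):
            shift = "+1" if length == 4 else "+2"
            return AlignOp("frameshift", i - 1, j - length, length, shift)
        if length in (1, 2):
            shift = "-2" if length == 1 else "-1"
            return AlignOp("frameshift", i - 1, j - length, length, shift)
        if aa == "*":
            return AlignOp("stop_codon", i - 1, j - 3, 3, codon)
        if aa == res:
            return AlignOp("codon_match", i - 1, j - 3, 3)
        return AlignOp("codon_substitution", i - 1, j - 3, 3, f"{aa}>{res}")

    while i > 0:
        val = int(best[i, j])
        prev = best[i - 1]
        sub = res_scores[protein[i - 1]]
        # preference: match/substitution > protein gap > dna gap > frameshift
        if j >= 3 and val == int(prev[j - 3] + sub[j]):
            ops.append(codon_op(i, j, 3))
            i, j = i - 1, j - 3
            continue
        if val == int(Pg[i, j]):
            # walk up through the protein-gap run
            while i > 0:
                ops.append(AlignOp("protein_gap", i - 1, j, 0))
                if int(Pg[i, j]) == int(best[i - 1, j] - gap_open):
                    i -= 1
                    break
                i -= 1
            continue
        # dna gap: find the run start s codons back
        found = False
        s = 1
        while j - 3 * s >= 0:
            t = j - 3 * s
            nq_t = _nonq(best, Pg, res_scores, protein, i, t, FS)
            cost = gap_open + gap_extend * (s - 1)
            if gap_cap is not None:
                cost = min(cost, gap_cap)
            if val == nq_t - cost:
                ops.append(AlignOp("dna_gap", -1, t, 3 * s))
                j = t
                found = True
                break
            s += 1
        if found:
            continue
        matched = False
        for length in (2, 1, 4, 5):
            if j >= length:
                extra = int(sub[j]) if length in (4, 5) else 0
                if val == int(prev[j - length]) + extra - FS:
                    ops.append(codon_op(i, j, length))
                    i, j = i - 1, j - length
                    matched = True
                    break
        if not matched:
            raise AssertionError("traceback failed to reproduce the DP score")
    ops.reverse()
    return ops


def _nonq(best, Pg, res_scores, protein, i, j, FS) -> int:
    """Best non-dna-gap candidate value at (i, j)."""
    cands = [int(Pg[i, j])]
    prev = best[i - 1]
    sub = res_scores[protein[i - 1]]
    if j >= 3:
        cands.append(int(prev[j - 3] + sub[j]))
    for length in (1, 2):
        if j >= length:
            cands.append(int(prev[j - length]) - FS)
    for length in (4, 5):
        if j >= length:
            cands.append(int(prev[j - length] + sub[j]) - FS)
    return max(cands)


def _check_conservation(aln: ProteinDnaAlignment, m: int) -> None:
    prot, dna = aln.consumed()
    if prot != m:
        raise AssertionError(
            f"alignment path consumes {prot} residues, protein has {m}")
    if dna != aln.dna_span[1] - aln.dna_span[0]:
        raise AssertionError("alignment path does not tile its DNA span")


def detect_events(aln: ProteinDnaAlignment,
                  large_insertion_min: int = DEFAULT_LARGE_INSERTION_MIN,
                  ) -> list[PseudogeneEvent]:
    """Pseudogenization events along one optimal alignment path."""
    events: list[PseudogeneEvent] = []
    for op in aln.ops:
        if op.op == "stop_codon":
            events.append(PseudogeneEvent("premature_stop", op.dna_start,
                                          op.protein_index, op.detail))
        elif op.op == "frameshift":
            kind = ("frameshift_insertion" if op.detail.startswith("+")
                    else "frameshift_deletion")
            events.append(PseudogeneEvent(kind, op.dna_start,
                                          op.protein_index, op.detail))
        elif op.op == "dna_gap" and op.dna_len >= large_insertion_min:
            events.append(PseudogeneEvent("large_insertion", op.dna_start,
                                          -1, f"len={op.dna_len}"))
    events.sort(key=lambda e: e.position)
    return events


@dataclass
class RegionReport:
    gene_id: str
    qry_accession: str
    verdict: str                      # conserved | pseudogenized | absent
    reason: str = ""
    events: list[PseudogeneEvent] = field(default_factory=list)
    alignment: ProteinDnaAlignment | None = None

    def counts(self) -> dict[str, int]:
        out = {"premature_stop": 0, "frameshift_insertion": 0,
               "frameshift_deletion": 0, "large_insertion": 0}
        for e in self.events:
            out[e.type] += 1
        return out


def compare_region(ref_record: NlrRecord,
                   qry_accession: str,
                   qry_genome: list[GenomeSequence],
                   qry_chains: dict[str, Chain],
                   window_pad: int = DEFAULT_WINDOW_PAD,
                   min_match_fraction: float = 0.5,
                   large_insertion_min: int = DEFAULT_LARGE_INSERTION_MIN,
                   ) -> RegionReport:
    """Align a reference NLR protein into another accession's syntenic region.

    The reference gene interval is projected into the query through the
    accession's anchor chain, padded by ``window_pad`` on both sides,
    and the protein aligned on both strands (better score kept). The
    verdict is ``absent`` when no projection exists, when fewer than
    ``min_match_fraction`` of residues land on matched/substituted
    codons, or when the best alignment does not overlap the projected
    locus (a nearby paralog in the padded window is not the gene);
    ``pseudogenized`` when premature stops or frameshifts are found,
    else ``conserved``.
    """
    gene = ref_record.gene
    chain = None
    for c in qry_chains.values():
        if c.ref_seq_id == gene.seq_id and c.blocks:
            if chain is None or c.weight > chain.weight:
                chain = c
    if chain is None:
        return RegionReport(gene.gene_id, qry_accession, "absent", "no_anchor")
    proj = project_interval(chain, (gene.start, gene.end), direction="ref2qry")
    if proj.interval is None:
        return RegionReport(gene.gene_id, qry_accession, "absent", "no_anchor")
    qseq = next(s for s in qry_genome if s.seq_id == proj.ref_seq_id)
    lo = max(0, proj.interval[0] - window_pad)
    hi = min(len(qseq), proj.interval[1] + window_pad)
    region_dna = qseq.sequence[lo:hi]
    protein = gene.protein
    if not protein:
        return RegionReport(gene.gene_id, qry_accession, "absent", "no_protein")

    best_aln = None
    for strand, dna in (("+", region_dna), ("-", revcomp(region_dna))):
        try:
            aln = frameshift_align(protein, dna, protein_id=gene.gene_id,
                                   region=(qry_accession, qseq.seq_id, lo, hi,
                                           strand))
        except ValueError:
            continue
        if best_aln is None or aln.score > best_aln.score:
            best_aln = aln
    if best_aln is None:
        return RegionReport(gene.gene_id, qry_accession, "absent", "region_too_short")
    if best_aln.match_fraction() < min_match_fraction or best_aln.score <= 0:
        return RegionReport(gene.gene_id, qry_accession, "absent",
                            "no_alignment", alignment=best_aln)
    # the alignment must sit on the projected locus, not on a paralog
    # elsewhere in the padded window
    span = best_aln.dna_span
    if best_aln.region[4] == "-":
        W = hi - lo
        span = (W - span[1], W - span[0])
    margin = max(500, gene.end - gene.start)
    exp_lo = proj.interval[0] - lo - margin
    exp_hi = proj.interval[1] - lo + margin
    if span[1] <= exp_lo or span[0] >= exp_hi:
        return RegionReport(gene.gene_id, qry_accession, "absent",
                            "locus_empty", alignment=best_aln)
    events = detect_events(best_aln, large_insertion_min)
    verdict = "pseudogenized" if events else "conserved"
    return RegionReport(gene.gene_id, qry_accession, verdict,
                        events=events, alignment=best_aln)
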