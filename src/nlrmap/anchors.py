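"""Whole-genome anchoring and projection onto the reference.

Exact unique matches (MUM-style seeds) between a query accession and the
reference are chained into the highest-weight collinear chain per
sequence pair and strand — the 1-to-1 alignment contract of
delta-filter's ``-1`` mode — and query gene positions are projected onto
reference coordinates through the chain. Production whole-genome
aligner output can be substituted via minimal PAF import.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import GenomeSequence
from .nbarc import NlrRecord

MIN_SEED_LENGTH = 12
DEFAULT_MIN_MATCH = 21
DEFAULT_MAX_BRIDGE = 100_000


@dataclass(frozen=True)
class ExactMatch:
    ref_start: int
    qry_start: int   # forward-strand query coordinate of match start
    length: int
    strand: str      # '+' or '-'

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length

    @property
    def qry_end(self) -> int:
        return self.qry_start + self.length


@dataclass(frozen=True)
class AnchorBlock:
    ref_seq_id: str
    ref_start: int
    ref_end: int
    qry_accession: str
    qry_seq_id: str
    qry_start: int
    qry_end: int
    strand: str

    def __post_init__(self):
        if self.ref_end - self.ref_start != self.qry_end - self.qry_start:
            raise ValueError("anchor block sides differ in length")


@dataclass
class Chain:
    ref_seq_id: str
    qry_accession: str
    qry_seq_id: str
    strand: str
    blocks: list[AnchorBlock]

    @property
    def weight(self) -> int:
        return sum(b.ref_end - b.ref_start for b in self.blocks)


@dataclass
class Projection:
    ref_seq_id: str | None
    interval: tuple[int, int] | None
    flag: str  # in_block | inserted | unmapped


@dataclass
class MappedNlr:
    record: NlrRecord
    ref_seq_id: str | None
    ref_interval: tuple[int, int] | None
    flag: str
    subgroup: str | None = None

    @property
    def gene_id(self) -> str:
        return self.record.gene_id

    @property
    def accession_id(self) -> str:
        return self.record.accession_id

    @property
    def mapped(self) -> bool:
        return self.ref_interval is not None


# ---------------------------------------------------------------------------
# Seeding

_LUT = np.full(256, -1, dtype=np.int64)
for i, b in enumerate("ACGT"):
    _LUT[ord(b)] = i


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of all k-mers; windows containing non-ACGT get -1."""
    arr = _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        window = arr[j:j + n]
        codes = (codes << 2) | np.where(window >= 0, window, 0)
        bad |= window < 0
    codes[bad] = -1
    return codes


def _unique_kmers(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    codes = _kmer_codes(seq, k)
    vals, idx, counts = np.unique(codes, return_index=True, return_counts=True)
    keep = (counts == 1) & (vals >= 0)
    return vals[keep], idx[keep]


def _diagonal_runs(rpos: np.ndarray, qpos: np.ndarray, k: int) -> list[tuple[int, int, int]]:
    """Merge co-diagonal consecutive seed positions into maximal runs."""
    if rpos.size == 0:
        return []
    diag = rpos - qpos
    order = np.lexsort((rpos, diag))
    rpos, qpos, diag = rpos[order], qpos[order], diag[order]
    breaks = np.flatnonzero((np.diff(diag) != 0) | (np.diff(rpos) != 1))
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [rpos.size - 1]])
    out = []
    for s, e in zip(starts, ends):
        out.append((int(rpos[s]), int(qpos[s]), int(rpos[e] - rpos[s]) + k))
    return out


def find_mums(ref: GenomeSequence, qry: GenomeSequence,
              min_length: int = DEFAULT_MIN_MATCH) -> list[ExactMatch]:
    """Exact matches >= min_length whose seed k-mers occur once per genome.

    Both strands of the query are searched. Seeds of length
    ``min_length`` that are unique in both sequences are merged along
    diagonals into maximal runs, giving MUM-like 1-to-1 anchors:
    repeated regions (e.g. duplicated genes) produce no anchors.
    """
    if min_length < MIN_SEED_LENGTH:
        raise ValueError(f"min_length below {MIN_SEED_LENGTH} invites spurious matches")
    if not ref.sequence or not qry.sequence:
        raise ValueError("empty sequence")
    k = min_length
    rvals, ridx = _unique_kmers(ref.sequence, k)
    out: list[ExactMatch] = []
    from .simulate import revcomp
    for strand, qseq in (("+", qry.sequence), ("-", revcomp(qry.sequence))):
        qvals, qidx = _unique_kmers(qseq, k)
        common, ri, qi = np.intersect1d(rvals, qvals, assume_unique=True,
                                        return_indices=True)
        if common.size == 0:
            continue
        rpos, qpos = ridx[ri], qidx[qi]
        for rs, qs, length in _diagonal_runs(rpos, qpos, k):
            if strand == "+":
                out.append(ExactMatch(rs, qs, length, "+"))
            else:
                fwd_start = len(qry.sequence) - (qs + length)
                out.append(ExactMatch(rs, fwd_start, length, "-"))
    out.sort(key=lambda m: (m.strand, m.ref_start, m.qry_start))
    return out


# ---------------------------------------------------------------------------
# Chaining


def chain_blocks(matches: list[ExactMatch],
                 ref_seq_id: str = "",
                 qry_accession: str = "",
                 qry_seq_id: str = "") -> list[Chain]:
    """Highest-weight collinear chain per strand (LIS by matched bp).

    Matches must be strictly increasing on both genomes along the chain
    (mirrored on '-'); overlapping or crossing leftovers are discarded.
    """
    chains: list[Chain] = []
    for strand in ("+", "-"):
        ms = [m for m in matches if m.strand == strand]
        if not ms:
            continue
        # order along the reference; for '-' the query must decrease
        ms.sort(key=lambda m: (m.ref_start, m.qry_start))
        n = len(ms)
        weight = [m.length for m in ms]
        best = list(weight)
        prev = [-1] * n
        for i in range(n):
            mi = ms[i]
            for j in range(i):
                mj = ms[j]
                if mj.ref_end > mi.ref_start:
                    continue
                if strand == "+":
                    ok = mj.qry_end <= mi.qry_start
                else:
                    ok = mi.qry_end <= mj.qry_start
                if ok and best[j] + weight[i] > best[i]:
                    best[i] = best[j] + weight[i]
                    prev[i] = j
        end = int(np.argmax(best))
        picked = []
        while end != -1:
            picked.append(ms[end])
            end = prev[end]
        picked.reverse()
        blocks = [AnchorBlock(ref_seq_id, m.ref_start, m.ref_end,
                              qry_accession, qry_seq_id, m.qry_start,
                              m.qry_end, strand) for m in picked]
        chains.append(Chain(ref_seq_id, qry_accession, qry_seq_id, strand, blocks))
    chains.sort(key=lambda c: -c.weight)
    return chains


# ---------------------------------------------------------------------------
# Projection


def _map_point(b: AnchorBlock, q: int) -> int:
    if b.strand == "+":
        return b.ref_start + (q - b.qry_start)
    return b.ref_start + (b.qry_end - 1 - q)


def _map_point_rev(b: AnchorBlock, r: int) -> int:
    if b.strand == "+":
        return b.qry_start + (r - b.ref_start)
    return b.qry_start + (b.ref_end - 1 - r)


def project_interval(chain: Chain, interval: tuple[int, int],
                     max_bridge: int = DEFAULT_MAX_BRIDGE,
                     direction: str = "qry2ref") -> Projection:
    """Project an interval through a chain by its midpoint.

    Midpoint inside an anchor block -> rigid shift by that block's
    offset. Midpoint between two blocks whose source-side gap is
    <= ``max_bridge``: if the target side has room between the flanking
    blocks the midpoint is interpolated proportionally into that room
    (flag "bridged", e.g. a diverged but syntenic stretch); if the
    target side is gapless the material only exists in the source
    genome, and the projection collapses to a zero-length point at the
    bridge, flagged "inserted". Otherwise unmapped.
    """
    if direction not in ("qry2ref", "ref2qry"):
        raise ValueError(direction)
    fwd = direction == "qry2ref"
    blocks = sorted(chain.blocks,
                    key=lambda b: b.qry_start if fwd else b.ref_start)
    lo = [(b.qry_start if fwd else b.ref_start) for b in blocks]
    hi = [(b.qry_end if fwd else b.ref_end) for b in blocks]
    out_seq = chain.ref_seq_id if fwd else chain.qry_seq_id
    mid = (interval[0] + interval[1]) // 2
    length = interval[1] - interval[0]

    import bisect
    i = bisect.bisect_right(lo, mid) - 1
    if i >= 0 and mid < hi[i]:
        b = blocks[i]
        pm = _map_point(b, mid) if fwd else _map_point_rev(b, mid)
        if b.strand == "+":
            start = pm - (mid - interval[0])
        else:
            start = pm - (interval[1] - 1 - mid)
        return Projection(out_seq, (start, start + length), "in_block")
    left = blocks[i] if i >= 0 else None
    right = blocks[i + 1] if i + 1 < len(blocks) else None
    if left is not None and right is not None:
        src_gap = lo[i + 1] - hi[i]
        if src_gap <= max_bridge:
            mapper = _map_point if fwd else _map_point_rev
            edge_l = mapper(left, hi[i] - 1)
            edge_r = mapper(right, lo[i + 1])
            t_lo, t_hi = sorted((edge_l, edge_r))
            t_gap = t_hi - t_lo - 1
            if t_gap <= 0:
                point = t_lo + 1
                return Projection(out_seq, (point, point), "inserted")
            frac = (mid - hi[i]) / src_gap if src_gap > 0 else 0.5
            if left.strand == "-":
                frac = 1.0 - frac
            t_mid = t_lo + 1 + int(frac * t_gap)
            start = t_mid - length // 2
            return Projection(out_seq, (start, start + length), "bridged")
    return Projection(None, None, "unmapped")


# ---------------------------------------------------------------------------
# Map construction


def build_chains(reference_genome: list[GenomeSequence],
                 qry_genome: list[GenomeSequence],
                 qry_accession: str,
                 min_length: int = DEFAULT_MIN_MATCH) -> dict[str, Chain]:
    """Best chain per query sequence against every reference sequence."""
    best: dict[str, Chain] = {}
    for qseq in qry_genome:
        for rseq in reference_genome:
            for chain in chain_blocks(find_mums(rseq, qseq, min_length),
                                      ref_seq_id=rseq.seq_id,
                                      qry_accession=qry_accession,
                                      qry_seq_id=qseq.seq_id):
                cur = best.get(qseq.seq_id)
                if cur is None or chain.weight > cur.weight:
                    best[qseq.seq_id] = chain
    return best


def build_map(records_by_accession: dict[str, list[NlrRecord]],
              genomes_by_accession: dict[str, list[GenomeSequence]],
              reference_accession: str,
              min_length: int = DEFAULT_MIN_MATCH,
              max_bridge: int = DEFAULT_MAX_BRIDGE,
              chains_by_accession: dict[str, dict[str, Chain]] | None = None,
              ) -> tuple[list[MappedNlr], list[MappedNlr]]:
    """Project every accession's NLRs onto the reference coordinate system.

    Reference NLRs map to themselves; query NLRs go through their
    accession's chains. Returns (mapped, unmapped) where unmapped holds
    genes on sequences without any usable anchor chain or outside
    bridgeable gaps.
    """
    if reference_accession not in records_by_accession:
        raise ValueError(f"reference accession {reference_accession!r} not in panel")
    ref_genome = genomes_by_accession[reference_accession]
    mapped: list[MappedNlr] = []
    unmapped: list[MappedNlr] = []
    if chains_by_accession is None:
        chains_by_accession = {}

    for acc, records in sorted(records_by_accession.items()):
        if acc == reference_accession:
            for r in records:
                mapped.append(MappedNlr(r, r.gene.seq_id,
                                        (r.gene.start, r.gene.end), "reference"))
            continue
        chains = chains_by_accession.get(acc)
        if chains is None:
            chains = build_chains(ref_genome, genomes_by_accession[acc], acc,
                                  min_length)
            chains_by_accession[acc] = chains
        for r in records:
            chain = chains.get(r.gene.seq_id)
            if chain is None or not chain.blocks:
                unmapped.append(MappedNlr(r, None, None, "no_chain"))
                continue
            proj = project_interval(chain, (r.gene.start, r.gene.end),
                                    max_bridge=max_bridge)
            if proj.interval is None:
                unmapped.append(MappedNlr(r, None, None, "unmapped"))
            else:
                mapped.append(MappedNlr(r, proj.ref_seq_id, proj.interval,
                                        proj.flag))
    return mapped, unmapped


# ---------------------------------------------------------------------------
# PAF interchange


def chains_to_paf(chains: list[Chain], seq_lengths: dict[str, int]) -> str:
    lines = []
    for c in chains:
        for b in c.blocks:
            length = b.ref_end - b.ref_start
            lines.append("\t".join(map(str, [
                b.qry_seq_id, seq_lengths.get(b.qry_seq_id, 0),
                b.qry_start, b.qry_end, b.strand,
                b.ref_seq_id, seq_lengths.get(b.ref_seq_id, 0),
                b.ref_start, b.ref_end, length, length, 255])))
    return "\n".join(lines) + ("\n" if lines else "")


def chains_from_paf(text: str, qry_accession: str) -> dict[str, Chain]:
    """Minimal PAF -> chains (blocks grouped by query sequence and strand)."""
    grouped: dict[tuple[str, str, str], list[AnchorBlock]] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        f = line.split("\t")
        qname, _qlen, qs, qe, strand, tname, _tlen, ts, te = f[:9]
        block = AnchorBlock(tname, int(ts), int(te), qry_accession, qname,
                            int(qs), int(qe), strand)
        grouped.setdefault((qname, tname, strand), []).append(block)
    best: dict[str, Chain] = {}
    for (qname, tname, strand), blocks in sorted(grouped.items()):
        chain = Chain(tname, qry_accession, qname, strand,
                      sorted(blocks, key=lambda b: b.ref_start))
        cur = best.get(qname)
        if cur is None or chain.weight > cur.weight:
            best[qname] = chain
    return best
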