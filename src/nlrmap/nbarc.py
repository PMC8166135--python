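"""NB-ARC motif scanning and intact/partial NLR classification.

The NB-ARC domain (Pfam PF00931) of plant NLR immune receptors carries
four diagnostic motifs. An NLR candidate is any protein with at least one
motif hit; it is called *intact* when at least three of the four motifs
occur in the canonical architectural order

    P-loop < Kinase2 < GLPL < MHDV

and the span from the first hit to the last covers >= 160 amino acids.
Everything else with a hit is *partial*. Motif detection uses curated
consensus regular expressions by default; position-specific scoring
matrices can be plugged in through the same interface.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

from .genome_io import GeneModel

CANONICAL_ORDER = ("P-loop", "Kinase2", "GLPL", "MHDV")

# Consensus patterns for the four NB-ARC motifs. P-loop is the Walker A
# nucleotide-binding motif G-x(4)-GK[ST]; Kinase2 is the Walker B
# hhhhDD core; GLPL and MHDV are the eponymous ARC-domain motifs.
DEFAULT_MOTIFS: dict[str, str] = {
    "P-loop": r"G.{4}GK[ST]",
    "Kinase2": r"[LIVMF]{3,4}DD",
    "GLPL": r"GLPL[AST]",
    "MHDV": r"MHD[VLIA]",
}

MIN_INTACT_MOTIFS = 3
MIN_NBARC_LENGTH = 160


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int
    end: int
    score: float = 1.0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad motif hit interval [{self.start},{self.end})")


@dataclass
class NlrRecord:
    """A gene that carries at least one NB-ARC motif."""

    gene: GeneModel
    hits: list[MotifHit]
    nbarc_span: tuple[int, int] | None = None
    status: str = "partial"
    subgroup: str | None = None
    evidence: str = ""

    @property
    def gene_id(self) -> str:
        return self.gene.gene_id

    @property
    def accession_id(self) -> str:
        return self.gene.accession_id


def scan_motifs(protein: str, motif_set: dict[str, str] | None = None) -> list[MotifHit]:
    """Find all motif matches in a protein, sorted by start position.

    Overlapping matches of the same motif collapse to the best-scoring
    one (ties resolved leftmost). Pattern matches all score 1, so for the
    default consensus patterns the collapse keeps the leftmost of each
    overlapping run.
    """
    if motif_set is None:
        motif_set = DEFAULT_MOTIFS
    if not motif_set:
        raise ValueError("empty motif set")
    if not protein:
        raise ValueError("empty protein")
    hits: list[MotifHit] = []
    for motif, pattern in motif_set.items():
        raw: list[MotifHit] = []
        for m in re.finditer(pattern, protein):
            raw.append(MotifHit(motif, m.start(), m.end()))
        hits.extend(_collapse_overlaps(raw))
    hits.sort(key=lambda h: (h.start, h.motif))
    return hits


def _collapse_overlaps(hits: list[MotifHit]) -> list[MotifHit]:
    """Collapse overlapping same-motif hits to the best (score, then leftmost)."""
    out: list[MotifHit] = []
    for h in sorted(hits, key=lambda h: (h.start, h.end)):
        if out and h.start < out[-1].end:
            if h.score > out[-1].score:
                out[-1] = h
            continue
        out.append(h)
    return out


def _best_hit_per_motif(hits: list[MotifHit]) -> dict[str, MotifHit]:
    best: dict[str, MotifHit] = {}
    for h in sorted(hits, key=lambda h: (-h.score, h.start, h.end)):
        best.setdefault(h.motif, h)
    return best


def classify_intact(hits: list[MotifHit],
                    protein_length: int,
                    min_motifs: int = MIN_INTACT_MOTIFS,
                    min_length: int = MIN_NBARC_LENGTH) -> tuple[str, tuple[int, int] | None]:
    """Apply the intact-NB-ARC rule to a set of motif hits.

    At most one hit per motif type is used (best score, ties leftmost).
    Intact requires >= ``min_motifs`` distinct motif types whose start
    positions strictly increase along the canonical order, spanning at
    least ``min_length`` amino acids from first hit start to last hit end.
    Returns ``("intact", span)`` or ``("partial", None)``.
    """
    best = _best_hit_per_motif(hits)
    present = [best[m] for m in CANONICAL_ORDER if m in best]
    if len(present) < min_motifs:
        return "partial", None
    starts = [h.start for h in present]
    if any(b <= a for a, b in zip(starts, starts[1:])):
        return "partial", None
    span = (present[0].start, present[-1].end)
    if span[1] > protein_length:
        raise ValueError("motif hit beyond protein length")
    if span[1] - span[0] < min_length:
        return "partial", None
    return "intact", span


def select_candidates(proteome: list[GeneModel],
                      motif_set: dict[str, str] | None = None) -> list[NlrRecord]:
    """Scan a proteome and keep every protein with >= 1 motif hit."""
    records: list[NlrRecord] = []
    for gene in proteome:
        if not gene.protein:
            continue
        hits = scan_motifs(gene.protein, motif_set)
        if not hits:
            continue
        status, span = classify_intact(hits, len(gene.protein))
        records.append(NlrRecord(gene=gene, hits=hits, nbarc_span=span, status=status))
    return records


def extract_nbarc(record: NlrRecord) -> str:
    """The NB-ARC region of an intact NLR (substring at its span)."""
    if record.status != "intact" or record.nbarc_span is None:
        raise ValueError(f"{record.gene_id}: NB-ARC extraction requires an intact record")
    s, e = record.nbarc_span
    return record.gene.protein[s:e]


def catalog_rows(records: list[NlrRecord]) -> list[dict]:
    """TSV-ready summary rows for an NLR catalog."""
    rows = []
    for r in records:
        rows.append({
            "gene_id": r.gene_id,
            "accession": r.accession_id,
            "seq_id": r.gene.seq_id,
            "start": r.gene.start,
            "end": r.gene.end,
            "status": r.status,
            "subgroup": r.subgroup or "unassigned",
            "nbarc_start": r.nbarc_span[0] if r.nbarc_span else "",
            "nbarc_end": r.nbarc_span[1] if r.nbarc_span else "",
            "motifs": ",".join(sorted({h.motif for h in r.hits},
                                      key=CANONICAL_ORDER.index)),
        })
    return rows
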