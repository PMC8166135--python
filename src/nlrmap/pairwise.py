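"""Pairwise protein alignment statistics shared across the pipeline.

"Similarity" throughout the package is the fraction of aligned residue
pairs with a positive BLOSUM62 score (the "positives" convention of
BLASTp); "coverage" of a sequence is the fraction of its residues that
are inside aligned pairs. Both are computed from a single deterministic
Needleman-Wunsch or Smith-Waterman alignment with affine gaps (-11/-1).
"""
from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

GAP_OPEN = -11.0
GAP_EXTEND = -1.0


@lru_cache(maxsize=None)
def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


@lru_cache(maxsize=None)
def _positive_pairs() -> frozenset[tuple[str, str]]:
    mat = substitution_matrices.load("BLOSUM62")
    pos = set()
    for a in mat.alphabet:
        for b in mat.alphabet:
            if mat[a, b] > 0:
                pos.add((a, b))
    return frozenset(pos)


def align_stats(query: str, target: str, mode: str = "global"
                ) -> tuple[float, float, float, float]:
    """Align two proteins and return (similarity, query_cov, target_cov, score).

    similarity = positives / aligned pairs; coverages are aligned pairs
    over each sequence's full length. Empty inputs yield all zeros.
    """
    if not query or not target:
        return 0.0, 0.0, 0.0, 0.0
    aligner = _aligner(mode)
    try:
        aln = next(iter(aligner.align(query, target)))
    except StopIteration:
        return 0.0, 0.0, 0.0, 0.0
    pos_pairs = _positive_pairs()
    aligned = 0
    positives = 0
    q_blocks, t_blocks = aln.aligned
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        for qi, ti in zip(range(qs, qe), range(ts, te)):
            aligned += 1
            if (query[qi], target[ti]) in pos_pairs:
                positives += 1
    if aligned == 0:
        return 0.0, 0.0, 0.0, float(aln.score)
    return (positives / aligned,
            aligned / len(query),
            aligned / len(target),
            float(aln.score))
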