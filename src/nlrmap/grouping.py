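"""NLR subgroup assignment.

Intact NLRs: align NB-ARC domains, trim gap-rich columns, build a
neighbor-joining tree with bootstrap supports, and give each query the
subgroup of the smallest well-supported clade whose labelled reference
members are unanimous. Partial NLRs: a similarity vote against the
intact NB-ARC domains (most matches above similarity/coverage cutoffs).

An externally computed tree (Newick, supports as internal node labels)
can be dropped in via :func:`tree_from_newick` in place of the built-in
NJ + bootstrap route.
"""
from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage

from .nbarc import NlrRecord

AA = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"
_ALPHABET = AA + GAP + "X"
_IDX = {c: i for i, c in enumerate(_ALPHABET)}

DEFAULT_SUPPORT_MIN = 90.0
DEFAULT_MAX_GAP_FRACTION = 0.92


# ---------------------------------------------------------------------------
# Multiple alignment


@dataclass
class Msa:
    """A multiple sequence alignment: equal-length gapped rows."""

    ids: list[str]
    rows: dict[str, str]

    def __post_init__(self):
        lengths = {len(self.rows[i]) for i in self.ids}
        if len(lengths) > 1:
            raise ValueError("MSA rows have unequal lengths")

    @property
    def length(self) -> int:
        return len(self.rows[self.ids[0]]) if self.ids else 0

    def degapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace(GAP, "")

    def to_fasta(self) -> str:
        out = io.StringIO()
        for i in self.ids:
            out.write(f">{i}\n{self.rows[i]}\n")
        return out.getvalue()

    @classmethod
    def from_fasta(cls, path) -> "Msa":
        from .genome_io import read_fasta
        recs = read_fasta(path)
        return cls([r.seq_id for r in recs], {r.seq_id: r.sequence for r in recs})


def _profile_matrix(rows: list[str]) -> np.ndarray:
    """Column-wise symbol counts over the extended alphabet."""
    n_cols = len(rows[0])
    counts = np.zeros((n_cols, len(_ALPHABET)), dtype=np.float64)
    for row in rows:
        for j, c in enumerate(row):
            counts[j, _IDX.get(c, _IDX["X"])] += 1
    return counts


def _score_table() -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    S = np.zeros((len(_ALPHABET), len(_ALPHABET)))
    for a in AA:
        for b in AA:
            S[_IDX[a], _IDX[b]] = mat[a, b]
    S[_IDX[GAP], :len(AA)] = -4.0
    S[:len(AA), _IDX[GAP]] = -4.0
    return S


_S = _score_table()
_PROFILE_GAP = -6.0


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Needleman-Wunsch on column profiles; returns gapped row groups."""
    pa, pb = _profile_matrix(rows_a), _profile_matrix(rows_b)
    na, nb = pa.shape[0], pb.shape[0]
    # mean pairwise substitution score between columns
    score = (pa @ _S @ pb.T) / (len(rows_a) * len(rows_b))
    dp = np.zeros((na + 1, nb + 1))
    dp[1:, 0] = _PROFILE_GAP * np.arange(1, na + 1)
    dp[0, 1:] = _PROFILE_GAP * np.arange(1, nb + 1)
    move = np.zeros((na + 1, nb + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    move[1:, 0] = 1
    move[0, 1:] = 2
    for i in range(1, na + 1):
        diag = dp[i - 1, :-1] + score[i - 1]
        up = dp[i - 1, 1:] + _PROFILE_GAP
        row = dp[i]
        prev = dp[i, 0]
        for j in range(1, nb + 1):
            left = prev + _PROFILE_GAP
            best = diag[j - 1]
            m = 0
            if up[j - 1] > best:
                best, m = up[j - 1], 1
            if left > best:
                best, m = left, 2
            row[j] = prev = best
            move[i, j] = m
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = na, nb
    gap_a = GAP * len(rows_a)
    gap_b = GAP * len(rows_b)
    cols: list[tuple[int, int]] = []  # (col index in a or -1, in b or -1)
    while i > 0 or j > 0:
        m = move[i, j]
        if m == 0 and i > 0 and j > 0:
            cols.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif m == 1 and i > 0:
            cols.append((i - 1, -1))
            i -= 1
        else:
            cols.append((-1, j - 1))
            j -= 1
    cols.reverse()
    a_cols = [c[0] for c in cols]
    b_cols = [c[1] for c in cols]
    for row in rows_a:
        out_a.append("".join(row[c] if c >= 0 else GAP for c in a_cols))
    for row in rows_b:
        out_b.append("".join(row[c] if c >= 0 else GAP for c in b_cols))
    return out_a, out_b


def _kmer_distance(seqs: list[str], k: int = 3) -> np.ndarray:
    sets = [frozenset(s[i:i + k] for i in range(len(s) - k + 1)) for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = len(sets[i] | sets[j])
            shared = len(sets[i] & sets[j])
            d[i, j] = d[j, i] = 1.0 - (shared / union if union else 0.0)
    return d


def progressive_align(seqs: dict[str, str]) -> Msa:
    """Progressive multiple alignment: k-mer guide tree, profile merges.

    Deterministic for fixed input (guide tree from average-linkage
    clustering of 3-mer Jaccard distances; merges follow the linkage
    order). A single sequence comes back as a one-row alignment.
    """
    ids = list(seqs)
    if not ids:
        raise ValueError("no sequences to align")
    if len(ids) == 1:
        return Msa(ids, dict(seqs))
    order = sorted(ids)
    d = _kmer_distance([seqs[i] for i in order])
    if len(order) == 2:
        merges = [(0, 1)]
    else:
        condensed = d[np.triu_indices(len(order), k=1)]
        Z = linkage(condensed, method="average")
        merges = [(int(a), int(b)) for a, b, _, _ in Z]
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([order[i]], [seqs[order[i]]]) for i in range(len(order))
    }
    nxt = len(order)
    for a, b in merges:
        ids_a, rows_a = clusters.pop(a)
        ids_b, rows_b = clusters.pop(b)
        new_a, new_b = _align_profiles(rows_a, rows_b)
        clusters[nxt] = (ids_a + ids_b, new_a + new_b)
        nxt += 1
    (final_ids, final_rows), = clusters.values()
    rows = dict(zip(final_ids, final_rows))
    return Msa([i for i in ids], {i: rows[i] for i in ids})


def trim_columns(msa: Msa, max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION) -> Msa:
    """Drop alignment columns whose gap fraction exceeds the threshold.

    A column is removed when gaps / rows > ``max_gap_fraction`` (strictly
    above; a column at exactly the threshold is kept).
    """
    n = len(msa.ids)
    if n == 0:
        return msa
    keep = []
    for j in range(msa.length):
        gaps = sum(1 for i in msa.ids if msa.rows[i][j] == GAP)
        if gaps / n <= max_gap_fraction:
            keep.append(j)
    if not keep:
        raise ValueError("alignment fully trimmed")
    rows = {i: "".join(msa.rows[i][j] for j in keep) for i in msa.ids}
    return Msa(list(msa.ids), rows)


def _msa_codes(msa: Msa) -> np.ndarray:
    """(rows, columns) byte codes in msa.ids order."""
    return np.vstack([np.frombuffer(msa.rows[i].encode(), dtype=np.uint8)
                      for i in msa.ids])


def identity_distance(msa: Msa) -> tuple[list[str], np.ndarray]:
    """Pairwise identity distance over gap-free columns.

    d(i,j) = 1 - identical / comparable, where comparable columns have a
    residue in both rows. Pairs with zero comparable columns get d = 1
    with a warning.
    """
    ids = list(msa.ids)
    return ids, identity_distance_from_codes(_msa_codes(msa), ids)


def identity_distance_from_codes(codes: np.ndarray,
                                 ids: list[str] | None = None) -> np.ndarray:
    gap = ord(GAP)
    nongap = (codes != gap)
    nongap_f = nongap.astype(np.float64)
    comparable = nongap_f @ nongap_f.T
    identical = np.zeros_like(comparable)
    for sym in np.unique(codes):
        if sym == gap:
            continue
        mask = (codes == sym).astype(np.float64)
        identical += mask @ mask.T
    n = codes.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - identical / comparable
    empty = comparable == 0
    if empty.any() and n > 1:
        off_diag = empty & ~np.eye(n, dtype=bool)
        if off_diag.any():
            names = ids or [str(i) for i in range(n)]
            i, j = np.argwhere(off_diag)[0]
            warnings.warn(f"no comparable columns between {names[i]} and {names[j]}")
    d[empty] = 1.0
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# Trees


@dataclass
class TreeNode:
    name: str = ""
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c._nwk() for c in self.children)
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}:{self.length:.6g}"


def bipartitions(tree: TreeNode) -> dict[frozenset, TreeNode]:
    """Internal-edge bipartitions, keyed by the child-side leaf set."""
    all_leaves = frozenset(tree.leaves())
    out: dict[frozenset, TreeNode] = {}
    for node in tree.walk():
        if node is tree or node.is_leaf():
            continue
        side = frozenset(node.leaves())
        if 2 <= len(side) <= len(all_leaves) - 2:
            out[side] = node
    return out


def nj_tree(ids: list[str], d: np.ndarray) -> TreeNode:
    """Neighbor joining (Saitou-Nei) with deterministic tie-breaking.

    Ties in the Q criterion resolve to the lexicographically smallest
    pair of joined-cluster names, so input order never changes the
    topology. Returns an unrooted tree as a trifurcating root.
    """
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: dict[str, TreeNode] = {i: TreeNode(name=i) for i in ids}
    labels = list(ids)
    D = d.astype(float).copy()
    counter = 0
    while len(labels) > 3:
        n = len(labels)
        totals = D.sum(axis=1)
        Q = (n - 2) * D - totals[:, None] - totals[None, :]
        iu = np.triu_indices(n, k=1)
        qvals = Q[iu]
        qmin = qvals.min()
        ties = np.flatnonzero(np.isclose(qvals, qmin, rtol=0, atol=1e-12))
        best = None
        for t in ties:
            i, j = int(iu[0][t]), int(iu[1][t])
            key = tuple(sorted((labels[i], labels[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        li, lj = labels[i], labels[j]
        dij = D[i, j]
        bi = 0.5 * dij + (totals[i] - totals[j]) / (2 * (n - 2))
        bj = dij - bi
        parent = TreeNode(name=f"_nj{counter}")
        counter += 1
        nodes[li].length = max(bi, 0.0)
        nodes[lj].length = max(bj, 0.0)
        parent.children = [nodes.pop(li), nodes.pop(lj)]
        new_row = 0.5 * (D[i] + D[j] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep],
                       new_row[keep][None, :]])
        D = np.hstack([D, np.append(new_row[keep], 0.0)[:, None]])
        labels = [labels[k] for k in keep] + [parent.name]
        nodes[parent.name] = parent
    # join the last three clusters at an unrooted trifurcation
    la, lb, lc = labels
    da, db, dc = D[0, 1], D[0, 2], D[1, 2]
    root = TreeNode(name="_root")
    nodes[la].length = max(0.5 * (da + db - dc), 0.0)
    nodes[lb].length = max(0.5 * (da + dc - db), 0.0)
    nodes[lc].length = max(0.5 * (db + dc - da), 0.0)
    root.children = [nodes[la], nodes[lb], nodes[lc]]
    return root


def bootstrap_support(msa: Msa, n_reps: int = 1000, seed: int = 0) -> TreeNode:
    """NJ tree from the full alignment, with column-bootstrap supports.

    Each replicate resamples alignment columns with replacement,
    recomputes identity distances and the NJ topology; an internal
    edge's support is the percentage of replicates whose tree contains
    the same bipartition. With ``n_reps=0`` supports stay absent.
    """
    ids, d = identity_distance(msa)
    tree = nj_tree(ids, d)
    if n_reps <= 0:
        return tree
    target = bipartitions(tree)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    codes = _msa_codes(msa)
    L = msa.length
    all_leaves = frozenset(ids)
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        rep_d = identity_distance_from_codes(codes[:, idx], ids)
        rep_tree = nj_tree(ids, rep_d)
        rep_bps = set(bipartitions(rep_tree))
        for bp in counts:
            if bp in rep_bps or frozenset(all_leaves - bp) in rep_bps:
                counts[bp] += 1
    for bp, node in target.items():
        node.support = 100.0 * counts[bp] / n_reps
    return tree


def tree_from_newick(text: str) -> TreeNode:
    """Parse a Newick tree whose internal node labels are supports."""
    from Bio import Phylo

    clade = Phylo.read(io.StringIO(text), "newick").root

    def convert(c) -> TreeNode:
        node = TreeNode(name=c.name or "",
                        length=c.branch_length or 0.0,
                        support=c.confidence)
        if node.support is None and c.clades and c.name:
            try:
                node.support = float(c.name)
                node.name = ""
            except ValueError:
                pass
        node.children = [convert(k) for k in c.clades]
        return node

    return convert(clade)


# ---------------------------------------------------------------------------
# Assignment rules


def assign_intact_groups(tree: TreeNode,
                         reference_labels: dict[str, str],
                         support_min: float = DEFAULT_SUPPORT_MIN) -> dict[str, str | None]:
    """Label query leaves by supported monophyly with labelled references.

    Each unlabelled leaf receives the group of the smallest clade
    (either side of an internal edge with support >= ``support_min``)
    that contains it together with at least one reference, all of whose
    references carry the same label. No such clade -> ``None``.
    """
    all_leaves = frozenset(tree.leaves())
    sides: list[frozenset] = []
    for bp, node in bipartitions(tree).items():
        if node.support is not None and node.support >= support_min:
            sides.append(bp)
            sides.append(frozenset(all_leaves - bp))
    queries = [l for l in sorted(all_leaves) if l not in reference_labels]
    out: dict[str, str | None] = {}
    any_clean = False
    for q in queries:
        best = None
        for side in sides:
            if q not in side:
                continue
            groups = {reference_labels[l] for l in side if l in reference_labels}
            if len(groups) != 1:
                continue
            key = (len(side), tuple(sorted(side)))
            if best is None or key < best[0]:
                best = (key, next(iter(groups)))
        if best is None:
            out[q] = None
        else:
            out[q] = best[1]
            any_clean = True
    if queries and sides and not any_clean:
        warnings.warn("reference labels conflict in every supported clade; "
                      "all queries unassigned")
    return out


def assign_partial_groups(partials: list[NlrRecord],
                          intact_refs: list[tuple[str, str, str]],
                          sim_min: float = 0.5,
                          cov_min: float = 0.3) -> dict[str, str | None]:
    """Similarity vote assigning partial NLRs to intact-NLR groups.

    ``intact_refs`` rows are (ref_id, nbarc_sequence, group). A match is
    a local alignment with similarity >= ``sim_min`` and coverage of the
    reference NB-ARC >= ``cov_min``; the group with the most matches
    wins. Ties go to the group of the single most similar match, then to
    the lexicographically smallest group id.
    """
    from .pairwise import align_stats

    if not intact_refs:
        raise ValueError("no labelled intact references")
    refs = sorted(intact_refs)
    out: dict[str, str | None] = {}
    for rec in partials:
        votes: dict[str, int] = {}
        best_sim: dict[str, float] = {}
        for _rid, nbarc, group in refs:
            sim, _qc, ref_cov, _ = align_stats(rec.gene.protein, nbarc, mode="local")
            if sim >= sim_min and ref_cov >= cov_min:
                votes[group] = votes.get(group, 0) + 1
                best_sim[group] = max(best_sim.get(group, 0.0), sim)
        if not votes:
            out[rec.gene_id] = None
            continue
        ranked = sorted(votes, key=lambda g: (-votes[g], -best_sim[g], g))
        out[rec.gene_id] = ranked[0]
    return out
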