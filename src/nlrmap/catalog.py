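"""Physical clustering, ortholog grouping, and pan-NLR accounting.

Mapped NLRs are merged into physical clusters (consecutive genes on the
reference less than 50 kb apart), ortholog groups are inferred inside
each cluster by reciprocal best hits with at most one member per
accession, and groups are categorized as core (all accessions),
dispensable (two or more, not all) or specific (exactly one).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd

from .anchors import MappedNlr
from .pairwise import align_stats

DEFAULT_CLUSTER_GAP = 50_000
DEFAULT_SIM_MIN = 0.5
DEFAULT_COV_MIN = 0.3


@dataclass
class PhysicalCluster:
    cluster_id: str
    ref_seq_id: str
    interval: tuple[int, int]
    members: list[MappedNlr]

    def counts(self, accession_ids: list[str]) -> dict[str, int]:
        out = {a: 0 for a in accession_ids}
        for m in self.members:
            if m.accession_id in out:
                out[m.accession_id] += 1
        return out


@dataclass
class OrthoGroup:
    group_id: str
    members: list[MappedNlr]
    category: str = ""

    @property
    def accessions(self) -> set[str]:
        return {m.accession_id for m in self.members}


def merge_physical_clusters(mapped: list[MappedNlr],
                            max_gap: int = DEFAULT_CLUSTER_GAP) -> list[PhysicalCluster]:
    """Union mapped NLRs into clusters where consecutive gaps are < max_gap.

    The gap rule is strictly below the threshold ("within 50 kb"): a gap
    of exactly ``max_gap`` starts a new cluster — bedtools-merge
    ``-d`` semantics with distance ``max_gap - 1``.
    """
    usable = [m for m in mapped if m.ref_interval is not None]
    usable.sort(key=lambda m: (m.ref_seq_id, m.ref_interval[0],
                               m.ref_interval[1], m.accession_id, m.gene_id))
    clusters: list[PhysicalCluster] = []
    cur: list[MappedNlr] = []
    cur_end = None
    cur_seq = None

    def flush():
        if cur:
            start = min(m.ref_interval[0] for m in cur)
            end = max(m.ref_interval[1] for m in cur)
            clusters.append(PhysicalCluster(f"c{len(clusters):04d}", cur_seq,
                                            (start, end), list(cur)))

    for m in usable:
        s, e = m.ref_interval
        if cur and m.ref_seq_id == cur_seq and s - cur_end < max_gap:
            cur.append(m)
            cur_end = max(cur_end, e)
        else:
            flush()
            cur = [m]
            cur_seq = m.ref_seq_id
            cur_end = e
    flush()
    return clusters


def _rbh_edges(cluster: PhysicalCluster, sim_min: float, cov_min: float):
    """Reciprocal-best-hit edges between members of different accessions."""
    members = sorted(cluster.members, key=lambda m: (m.accession_id, m.gene_id))
    by_acc: dict[str, list[MappedNlr]] = {}
    for m in members:
        by_acc.setdefault(m.accession_id, []).append(m)
    accs = sorted(by_acc)
    stats: dict[tuple[str, str], tuple[float, float, float, float]] = {}

    def pair_stats(a: MappedNlr, b: MappedNlr):
        key = (a.gene_id, b.gene_id)
        if key not in stats:
            sim, qc, tc, score = align_stats(a.record.gene.protein,
                                             b.record.gene.protein)
            stats[key] = (sim, qc, tc, score)
            stats[(b.gene_id, a.gene_id)] = (sim, tc, qc, score)
        return stats[key]

    # best hits are ranked by alignment score (a sparse high-"positives"
    # alignment at negligible coverage must not outrank the true ortholog)
    edges = []
    for i, A in enumerate(accs):
        for B in accs[i + 1:]:
            best_ab: dict[str, str] = {}
            best_ba: dict[str, str] = {}
            for a in by_acc[A]:
                ranked = sorted(
                    by_acc[B],
                    key=lambda b: (-pair_stats(a, b)[3], b.gene_id))
                if ranked:
                    best_ab[a.gene_id] = ranked[0].gene_id
            for b in by_acc[B]:
                ranked = sorted(
                    by_acc[A],
                    key=lambda a: (-pair_stats(b, a)[3], a.gene_id))
                if ranked:
                    best_ba[b.gene_id] = ranked[0].gene_id
            for a in by_acc[A]:
                bid = best_ab.get(a.gene_id)
                if bid is None or best_ba.get(bid) != a.gene_id:
                    continue
                sim, qc, tc, _score = pair_stats(
                    a, next(m for m in by_acc[B] if m.gene_id == bid))
                if sim >= sim_min and qc >= cov_min and tc >= cov_min:
                    edges.append((a.gene_id, bid, sim))
    return members, edges


def build_ortho_groups(cluster: PhysicalCluster,
                       sim_min: float = DEFAULT_SIM_MIN,
                       cov_min: float = DEFAULT_COV_MIN) -> list[OrthoGroup]:
    """Ortholog groups within one physical cluster.

    Connected components of the RBH graph are split greedily (weakest
    similarity edge first, ties by gene-id pair) until no component has
    two members from one accession; members without qualifying edges
    become singleton groups.
    """
    members, edges = _rbh_edges(cluster, sim_min, cov_min)
    by_id = {m.gene_id: m for m in members}
    G = nx.Graph()
    G.add_nodes_from(by_id)
    for a, b, sim in edges:
        G.add_edge(a, b, sim=sim)

    def has_dup(component: set[str]) -> bool:
        accs = [by_id[g].accession_id for g in component]
        return len(accs) != len(set(accs))

    changed = True
    while changed:
        changed = False
        for comp in list(nx.connected_components(G)):
            if not has_dup(comp):
                continue
            sub_edges = sorted(
                ((G[u][v]["sim"], tuple(sorted((u, v)))) for u, v in
                 G.subgraph(comp).edges),
                key=lambda t: (t[0], t[1]))
            if sub_edges:
                _, (u, v) = sub_edges[0]
                G.remove_edge(u, v)
                changed = True

    groups = []
    comps = sorted(nx.connected_components(G), key=lambda c: sorted(c)[0])
    for k, comp in enumerate(comps):
        mem = sorted((by_id[g] for g in comp),
                     key=lambda m: (m.accession_id, m.gene_id))
        groups.append(OrthoGroup(f"{cluster.cluster_id}_og{k:03d}", mem))
    return groups


def _round1(x: float) -> float:
    return float(Decimal(str(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def categorize(groups: list[OrthoGroup], accession_ids: list[str],
               total_candidates: int | None = None) -> dict:
    """Core/dispensable/specific accounting over all ortholog groups.

    Percentages are taken against ``total_candidates`` (the full NLR
    candidate count including genes that could not be placed on the
    map), rounded half-up to one decimal.
    """
    n_acc = len(accession_ids)
    for g in groups:
        k = len(g.accessions)
        if len(g.members) != k:
            raise ValueError(f"{g.group_id}: more than one member per accession")
        g.category = ("specific" if k == 1 else
                      "core" if k == n_acc else "dispensable")
    genes = {c: 0 for c in ("core", "dispensable", "specific")}
    ngroups = {c: 0 for c in genes}
    specific_by_acc = {a: 0 for a in accession_ids}
    for g in groups:
        genes[g.category] += len(g.members)
        ngroups[g.category] += 1
        if g.category == "specific":
            specific_by_acc[g.members[0].accession_id] += 1
    total_genes = sum(genes.values())
    denom = total_candidates if total_candidates else total_genes
    out = {
        "n_accessions": n_acc,
        "groups": ngroups,
        "genes": genes,
        "specific_by_accession": specific_by_acc,
        "total_categorized": total_genes,
        "total_candidates": denom,
        "pct": {c: _round1(100.0 * genes[c] / denom) for c in genes},
        "pct_categorized": _round1(100.0 * total_genes / denom),
        "pct_specific_by_accession": {
            a: _round1(100.0 * specific_by_acc[a] / denom) for a in accession_ids},
    }
    return out


def pan_core_curve(groups: list[OrthoGroup], accession_ids: list[str],
                   max_exhaustive: int = 6, n_orderings: int = 100,
                   seed: int = 0) -> pd.DataFrame:
    """Pan- and core-group accumulation over accession orderings.

    For each ordering, pan(k) counts groups present in at least one of
    the first k accessions and core(k) groups present in all of them.
    All k! orderings are enumerated up to ``max_exhaustive`` accessions;
    larger panels use ``n_orderings`` seeded random orderings.
    """
    if not accession_ids:
        raise ValueError("need at least one accession")
    memberships = [g.accessions for g in groups]
    if len(accession_ids) <= max_exhaustive:
        orderings = list(permutations(accession_ids))
    else:
        rng = np.random.default_rng(seed)
        orderings = [tuple(rng.permutation(accession_ids))
                     for _ in range(n_orderings)]
    K = len(accession_ids)
    pan = np.zeros((len(orderings), K), dtype=int)
    core = np.zeros_like(pan)
    for oi, order in enumerate(orderings):
        seen: set[str] = set()
        for k in range(K):
            seen.add(order[k])
            pan[oi, k] = sum(1 for m in memberships if m & seen)
            core[oi, k] = sum(1 for m in memberships if seen <= m)
    rows = []
    for k in range(K):
        rows.append({
            "k": k + 1,
            "pan_mean": float(pan[:, k].mean()),
            "pan_min": int(pan[:, k].min()),
            "pan_max": int(pan[:, k].max()),
            "core_mean": float(core[:, k].mean()),
            "core_min": int(core[:, k].min()),
            "core_max": int(core[:, k].max()),
        })
    return pd.DataFrame(rows)
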