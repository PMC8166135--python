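"""Copy-number-variation statistics over physical NLR clusters.

Per-cluster NLR counts across accessions are screened by a standard-
deviation filter (sample SD > 2), tested for departure from equal copy
number with a chi-square goodness-of-fit test, and corrected with
Benjamini-Hochberg FDR. Subgroup composition along the reference is
tested per non-overlapping 1 Mb window with a hypergeometric upper
tail.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .anchors import MappedNlr
from .catalog import PhysicalCluster

DEFAULT_SD_MIN = 2.0
DEFAULT_ALPHA = 0.05
DEFAULT_WINDOW = 1_000_000


@dataclass
class CnvTestResult:
    cluster_id: str
    counts: dict[str, int]
    sd: float
    chi2: float
    df: int
    p: float
    q: float
    significant: bool
    warnings: list[str] = field(default_factory=list)


@dataclass
class WindowEnrichment:
    ref_seq_id: str
    window: tuple[int, int]
    subgroup: str
    k_in_window: int
    n_window: int
    K_genome: int
    N_genome: int
    p: float
    q: float = float("nan")
    enriched: bool = False


def cluster_count_matrix(clusters: list[PhysicalCluster],
                         accession_ids: list[str]) -> pd.DataFrame:
    """Cluster-by-accession member counts, rows in reference order."""
    ordered = sorted(clusters, key=lambda c: (c.ref_seq_id, c.interval[0]))
    rows = {c.cluster_id: c.counts(accession_ids) for c in ordered}
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    if df.empty:
        return pd.DataFrame(columns=accession_ids, dtype=int)
    return df[accession_ids]


def sd_filter(row, sd_min: float = DEFAULT_SD_MIN) -> bool:
    """Retain a cluster iff the sample SD (ddof=1) of its counts > sd_min."""
    arr = np.asarray(row, dtype=float)
    if arr.size < 2:
        raise ValueError("SD filter needs counts from >= 2 accessions")
    return float(arr.std(ddof=1)) > sd_min


def chisq_uniform(row) -> tuple[float, int, float]:
    """Chi-square goodness of fit of counts against equal copy number.

    Expected count for every accession is the row mean; the statistic is
    Sum (o - e)^2 / e on n-1 degrees of freedom.
    """
    arr = np.asarray(row, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("chi-square test requires a positive total count")
    e = arr.mean()
    chi2 = float(((arr - e) ** 2 / e).sum())
    df = arr.size - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (same order as input)."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def detect_cnv_regions(table: pd.DataFrame,
                       alpha: float = DEFAULT_ALPHA,
                       sd_min: float = DEFAULT_SD_MIN) -> list[CnvTestResult]:
    """SD-screen, chi-square-test and FDR-adjust a cluster count table.

    Only SD-retained clusters are tested; BH adjustment runs across the
    tested set, and significance means q < alpha. Clusters with any
    expected count below 5 carry a "low_expected" warning (the
    asymptotic chi-square approximation is rough there).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    results: list[CnvTestResult] = []
    tested: list[CnvTestResult] = []
    for cluster_id, row in table.iterrows():
        counts = {a: int(row[a]) for a in table.columns}
        arr = row.to_numpy(dtype=float)
        sd = float(arr.std(ddof=1))
        if not sd_filter(arr, sd_min) or arr.sum() <= 0:
            results.append(CnvTestResult(str(cluster_id), counts, sd,
                                         float("nan"), arr.size - 1,
                                         float("nan"), float("nan"), False,
                                         ["sd_filtered"]))
            continue
        chi2, df, p = chisq_uniform(arr)
        res = CnvTestResult(str(cluster_id), counts, sd, chi2, df, p,
                            float("nan"), False)
        if arr.mean() < 5:
            res.warnings.append("low_expected")
        results.append(res)
        tested.append(res)
    if tested:
        qvals = bh_adjust([r.p for r in tested])
        for r, q in zip(tested, qvals):
            r.q = float(q)
            r.significant = r.q < alpha
    return results


def results_table(results: list[CnvTestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"cluster_id": r.cluster_id, **r.counts, "sd": r.sd,
               "chi2": r.chi2, "df": r.df, "p": r.p, "q": r.q,
               "significant": r.significant,
               "warnings": ";".join(r.warnings)}
        rows.append(row)
    return pd.DataFrame(rows)


def window_subgroup_enrichment(mapped: list[MappedNlr],
                               seq_lengths: dict[str, int],
                               window: int = DEFAULT_WINDOW,
                               alpha: float = DEFAULT_ALPHA,
                               ) -> list[WindowEnrichment]:
    """Hypergeometric subgroup enrichment per non-overlapping window.

    For each (window, subgroup) with at least one member present, the
    upper-tail probability of drawing k subgroup genes in the window's n
    NLRs from a genome carrying K of N is computed exactly; BH
    correction runs across all emitted tests.
    """
    usable = [m for m in mapped if m.ref_interval is not None
              and m.subgroup not in (None, "", "unassigned")]
    N = len(usable)
    if N == 0:
        return []
    K_by_group: dict[str, int] = {}
    for m in usable:
        K_by_group[m.subgroup] = K_by_group.get(m.subgroup, 0) + 1

    per_window: dict[tuple[str, int], list[MappedNlr]] = {}
    for m in usable:
        mid = (m.ref_interval[0] + m.ref_interval[1]) // 2
        per_window.setdefault((m.ref_seq_id, mid // window), []).append(m)

    tests: list[WindowEnrichment] = []
    for (seq_id, wi) in sorted(per_window):
        members = per_window[(seq_id, wi)]
        n = len(members)
        counts: dict[str, int] = {}
        for m in members:
            counts[m.subgroup] = counts.get(m.subgroup, 0) + 1
        w_lo = wi * window
        w_hi = min((wi + 1) * window, seq_lengths.get(seq_id, (wi + 1) * window))
        for sg in sorted(counts):
            k = counts[sg]
            K = K_by_group[sg]
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            tests.append(WindowEnrichment(seq_id, (w_lo, w_hi), sg,
                                          k, n, K, N, p))
    if tests:
        qvals = bh_adjust([t.p for t in tests])
        for t, q in zip(tests, qvals):
            t.q = float(q)
            t.enriched = t.q < alpha
    return tests
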