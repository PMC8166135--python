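"""End-to-end orchestration: scan -> group -> map -> catalog -> CNV -> pseudo.

The pipeline runs either on a simulated panel (with ground truth carried
along for scoring) or on user-supplied per-accession FASTA + GFF3. Every
stage writes a self-describing TSV into the output directory and the run
ends with a JSON manifest of parameters, seeds and record counts.
"""
from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import anchors, catalog, cnv, grouping, nbarc, pseudo
from .genome_io import read_fasta, read_gff3, write_table
from .simulate import (Accession, MutationConfig, Panel, PanelConfig,
                       simulate_panel)


@dataclass
class PipelineConfig:
    mode: str = "simulate"                 # simulate | user_data
    outdir: str = "nlrmap_out"
    seed: int = 0
    reference_accession: str = "acc1"
    # simulate mode
    panel: PanelConfig = field(default_factory=PanelConfig)
    mutation: MutationConfig = field(default_factory=lambda: MutationConfig(
        snv_rate=0.0005, small_indel_rate=0.00002,
        gene_deletion_prob=0.05, gene_duplication_prob=0.03,
        large_insertion_prob=0.02, premature_stop_prob=0.05))
    n_planted_cnv: int = 1
    # user_data mode: accession_id -> {"fasta": ..., "gff3": ...}
    inputs: dict = field(default_factory=dict)
    known_groups: str | None = None        # TSV gene_id<TAB>group
    imported_tree: str | None = None       # Newick path, supports as labels
    # parameters
    sim_min: float = 0.5
    cov_min: float = 0.3
    cluster_gap: int = 50_000
    sd_min: float = 2.0
    alpha: float = 0.05
    window: int = 1_000_000
    bootstrap_reps: int = 100
    support_min: float = 90.0
    min_match: int = 21
    max_bridge: int = 100_000
    window_pad: int = 10_000
    run_pseudo: bool = True

    def validate(self) -> None:
        if self.mode not in ("simulate", "user_data"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.sim_min <= 1 or not 0 <= self.cov_min <= 1:
            raise ValueError("sim_min/cov_min must be in [0, 1]")
        if self.cluster_gap <= 0 or self.window <= 0:
            raise ValueError("cluster_gap and window must be positive")
        if self.bootstrap_reps < 0:
            raise ValueError("bootstrap_reps must be >= 0")
        if self.mode == "user_data" and not self.inputs:
            raise ValueError("user_data mode needs input paths")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        panel = PanelConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in raw.pop("panel", {}).items()})
        mut_raw = raw.pop("mutation", None)
        kwargs = dict(raw)
        kwargs["panel"] = panel
        if mut_raw is not None:
            kwargs["mutation"] = MutationConfig(
                **{k: tuple(v) if isinstance(v, list) else v
                   for k, v in mut_raw.items()})
        return cls(**kwargs)


@dataclass
class RunResult:
    config: PipelineConfig
    panel: Panel | None
    records: dict[str, list[nbarc.NlrRecord]]
    assignments: dict[str, str | None]
    mapped: list[anchors.MappedNlr]
    unmapped: list[anchors.MappedNlr]
    clusters: list[catalog.PhysicalCluster]
    groups: list[catalog.OrthoGroup]
    summary: dict
    curve: pd.DataFrame
    cnv_results: list[cnv.CnvTestResult]
    enrichment: list[cnv.WindowEnrichment]
    pseudo_reports: list[pseudo.RegionReport]
    manifest: dict


def _load_accessions(config: PipelineConfig) -> tuple[list[Accession], Panel | None]:
    if config.mode == "simulate":
        panel = simulate_panel(config.panel, config.mutation,
                               seed=config.seed,
                               n_planted_cnv=config.n_planted_cnv)
        return panel.accessions, panel
    accs = []
    for acc_id in sorted(config.inputs):
        paths = config.inputs[acc_id]
        genome = read_fasta(paths["fasta"], accession_id=acc_id,
                            validate_genome=True)
        genes = read_gff3(paths["gff3"], genome, accession_id=acc_id)
        accs.append(Accession(acc_id, genome, genes,
                              lineage={g.gene_id: g.gene_id for g in genes}))
    return accs, None


def _reference_labels(config: PipelineConfig, panel: Panel | None,
                      intact_keys: dict[str, nbarc.NlrRecord]) -> dict[str, str]:
    """Leaf-key -> subgroup for labelled reference NLRs."""
    labels: dict[str, str] = {}
    if config.mode == "simulate" and panel is not None:
        ref_acc = panel.reference.accession_id
        for key, rec in intact_keys.items():
            if rec.accession_id == ref_acc:
                truth = panel.subgroup_truth.get(rec.gene_id)
                if truth:
                    labels[key] = truth
    elif config.known_groups:
        table = pd.read_csv(config.known_groups, sep="\t")
        known = dict(zip(table.iloc[:, 0], table.iloc[:, 1]))
        for key, rec in intact_keys.items():
            if rec.gene_id in known:
                labels[key] = known[rec.gene_id]
    return labels


def run(config: PipelineConfig) -> RunResult:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stages: dict[str, dict] = {}

    def mark(stage: str, **info):
        stages[stage] = {"wall_s": round(time.time() - t0, 2), **info}

    accessions, panel = _load_accessions(config)
    accession_ids = [a.accession_id for a in accessions]
    if config.reference_accession not in accession_ids:
        raise ValueError(f"reference accession {config.reference_accession!r} "
                         f"not among {accession_ids}")
    if panel is not None:
        for acc in accessions:
            acc.write(outdir / "genomes")
        write_table([vars(e) for e in panel.events], outdir / "truth_events.tsv")
        write_table(panel.planted_cnv or [],
                    outdir / "planted_cnv.tsv",
                    columns=["cluster", "accession", "n_reference", "n_kept",
                             "n_deleted"])
    mark("load", accessions=len(accessions),
         genes=sum(len(a.genes) for a in accessions))

    # --- NB-ARC scan ------------------------------------------------------
    records: dict[str, list[nbarc.NlrRecord]] = {}
    for acc in accessions:
        records[acc.accession_id] = nbarc.select_candidates(acc.genes)
    all_records = [r for recs in records.values() for r in recs]
    mark("scan", candidates=len(all_records),
         intact=sum(1 for r in all_records if r.status == "intact"))

    # --- subgroup assignment ---------------------------------------------
    intact_keys = {f"{r.accession_id}:{r.gene_id}": r
                   for r in all_records if r.status == "intact"}
    ref_labels = _reference_labels(config, panel, intact_keys)
    assignments: dict[str, str | None] = {}
    if intact_keys and (ref_labels or config.imported_tree):
        if config.imported_tree:
            tree = grouping.tree_from_newick(Path(config.imported_tree).read_text())
        else:
            seqs = {key: nbarc.extract_nbarc(rec)
                    for key, rec in intact_keys.items()}
            msa = grouping.progressive_align(seqs)
            msa = grouping.trim_columns(msa)
            tree = grouping.bootstrap_support(msa, config.bootstrap_reps,
                                              seed=config.seed + 1)
            (outdir / "nbarc_tree.nwk").write_text(tree.newick())
        assigned = grouping.assign_intact_groups(tree, ref_labels,
                                                 config.support_min)
        assignments.update(assigned)
        assignments.update(ref_labels)
        for key, rec in intact_keys.items():
            rec.subgroup = assignments.get(key)
        intact_refs = [(key, nbarc.extract_nbarc(rec), rec.subgroup)
                       for key, rec in intact_keys.items() if rec.subgroup]
        partials = [r for r in all_records if r.status == "partial"]
        if intact_refs and partials:
            votes = grouping.assign_partial_groups(
                partials, intact_refs, config.sim_min, config.cov_min)
            for r in partials:
                r.subgroup = votes.get(r.gene_id)
                assignments[f"{r.accession_id}:{r.gene_id}"] = r.subgroup
    write_table(nbarc.catalog_rows(all_records), outdir / "nlr_catalog.tsv")
    mark("group_assign",
         assigned=sum(1 for v in assignments.values() if v))

    # --- NLR map ----------------------------------------------------------
    genomes = {a.accession_id: a.sequences for a in accessions}
    chain_cache: dict[str, dict[str, anchors.Chain]] = {}
    mapped, unmapped = anchors.build_map(records, genomes,
                                         config.reference_accession,
                                         min_length=config.min_match,
                                         max_bridge=config.max_bridge,
                                         chains_by_accession=chain_cache)
    for m in mapped:
        m.subgroup = m.record.subgroup
    map_rows = [{"gene_id": m.gene_id, "accession": m.accession_id,
                 "ref_seq": m.ref_seq_id, "ref_start": m.ref_interval[0],
                 "ref_end": m.ref_interval[1], "flag": m.flag,
                 "subgroup": m.subgroup or "unassigned"} for m in mapped]
    map_rows += [{"gene_id": m.gene_id, "accession": m.accession_id,
                  "ref_seq": "", "ref_start": "", "ref_end": "",
                  "flag": m.flag, "subgroup": ""} for m in unmapped]
    write_table(map_rows, outdir / "nlr_map.tsv")
    mark("map", mapped=len(mapped), unmapped=len(unmapped))

    # --- clusters, orthologs, categories ---------------------------------
    clusters = catalog.merge_physical_clusters(mapped, config.cluster_gap)
    groups: list[catalog.OrthoGroup] = []
    for cl in clusters:
        groups.extend(catalog.build_ortho_groups(cl, config.sim_min,
                                                 config.cov_min))
    summary = catalog.categorize(groups, accession_ids,
                                 total_candidates=len(all_records))
    curve = catalog.pan_core_curve(groups, accession_ids)
    cluster_rows = [{"cluster_id": c.cluster_id, "ref_seq": c.ref_seq_id,
                     "start": c.interval[0], "end": c.interval[1],
                     "n_members": len(c.members)} for c in clusters]
    write_table(cluster_rows, outdir / "clusters.tsv")
    group_rows = []
    for g in groups:
        row = {"group_id": g.group_id, "category": g.category}
        for a in accession_ids:
            row[a] = ";".join(m.gene_id for m in g.members
                              if m.accession_id == a)
        group_rows.append(row)
    write_table(group_rows, outdir / "ortho_groups.tsv")
    curve.to_csv(outdir / "pan_core_curve.tsv", sep="\t", index=False)
    (outdir / "catalog_summary.json").write_text(json.dumps(summary, indent=2))
    mark("catalog", clusters=len(clusters), groups=len(groups))

    # --- CNV statistics ---------------------------------------------------
    table = cnv.cluster_count_matrix(clusters, accession_ids)
    cnv_results = cnv.detect_cnv_regions(table, config.alpha, config.sd_min)
    cnv.results_table(cnv_results).to_csv(outdir / "cnv_tests.tsv",
                                          sep="\t", index=False)
    cluster_by_id = {c.cluster_id: c for c in clusters}
    with open(outdir / "cnv_significant.bed", "w") as bed:
        for r in cnv_results:
            if r.significant:
                c = cluster_by_id[r.cluster_id]
                bed.write(f"{c.ref_seq_id}\t{c.interval[0]}\t{c.interval[1]}"
                          f"\t{r.cluster_id}\t{r.q:.3g}\n")
    seq_lengths = {s.seq_id: len(s)
                   for s in genomes[config.reference_accession]}
    enrichment = cnv.window_subgroup_enrichment(mapped, seq_lengths,
                                                config.window, config.alpha)
    write_table([vars(e) for e in enrichment], outdir / "window_enrichment.tsv")
    mark("cnv", tested=sum(1 for r in cnv_results if "sd_filtered" not in r.warnings),
         significant=sum(r.significant for r in cnv_results))

    # --- pseudogene scan on significant clusters -------------------------
    reports: list[pseudo.RegionReport] = []
    if config.run_pseudo:
        sig_ids = {r.cluster_id for r in cnv_results if r.significant}
        ref_acc = config.reference_accession
        for cid in sorted(sig_ids):
            cl = cluster_by_id[cid]
            ref_members = [m for m in cl.members if m.accession_id == ref_acc]
            for m in ref_members:
                for acc in accessions:
                    if acc.accession_id == ref_acc:
                        continue
                    chains = chain_cache.get(acc.accession_id, {})
                    reports.append(pseudo.compare_region(
                        m.record, acc.accession_id, acc.sequences, chains,
                        window_pad=config.window_pad))
        rows = []
        for rep in reports:
            counts = rep.counts()
            rows.append({"gene_id": rep.gene_id, "accession": rep.qry_accession,
                         "verdict": rep.verdict, "reason": rep.reason,
                         **{f"n_{k}": v for k, v in counts.items()}})
        write_table(rows, outdir / "pseudogene_reports.tsv",
                    columns=["gene_id", "accession", "verdict", "reason",
                             "n_premature_stop", "n_frameshift_insertion",
                             "n_frameshift_deletion", "n_large_insertion"])
    mark("pseudo", reports=len(reports))

    manifest = {
        "parameters": {k: v for k, v in asdict(config).items()
                       if k not in ("inputs",)},
        "accessions": accession_ids,
        "stages": stages,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    return RunResult(config, panel, records, assignments, mapped, unmapped,
                     clusters, groups, summary, curve, cnv_results,
                     enrichment, reports, manifest)


def report(outdir) -> str:
    """Human-readable summary of a completed run directory."""
    out = Path(outdir)
    lines = []
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError("run manifest missing: stage 'load' incomplete")
    manifest = json.loads(manifest_path.read_text())
    lines.append(f"accessions: {', '.join(manifest['accessions'])}")
    summary_path = out / "catalog_summary.json"
    if not summary_path.exists():
        raise FileNotFoundError("catalog stage output missing")
    s = json.loads(summary_path.read_text())
    lines.append(
        "ortholog catalog: "
        f"core {s['genes']['core']} genes ({s['pct']['core']}%), "
        f"dispensable {s['genes']['dispensable']} ({s['pct']['dispensable']}%), "
        f"specific {s['genes']['specific']} ({s['pct']['specific']}%); "
        f"{s['total_categorized']} of {s['total_candidates']} "
        f"({s['pct_categorized']}%) on the map")
    curve_path = out / "pan_core_curve.tsv"
    if curve_path.exists():
        lines.append("pan/core curve:")
        lines.append(curve_path.read_text().rstrip())
    cnv_path = out / "cnv_tests.tsv"
    if cnv_path.exists():
        df = pd.read_csv(cnv_path, sep="\t")
        sig = df[df["significant"] == True]  # noqa: E712
        lines.append(f"{len(sig)} CNV regions significant "
                     f"(of {int((df['p'].notna()).sum())} tested clusters)")
        for _, row in sig.iterrows():
            lines.append(f"  {row['cluster_id']}: q={row['q']:.3g}")
    planted_path = out / "planted_cnv.tsv"
    if planted_path.exists():
        planted = pd.read_csv(planted_path, sep="\t")
        if len(planted):
            lines.append("planted CNV truth (simulate mode):")
            clusters = pd.read_csv(out / "clusters.tsv", sep="\t")
            lines.append(f"  planted clusters: "
                         f"{sorted(planted['cluster'].unique().tolist())} "
                         f"of {len(clusters)} detected clusters")
    return "\n".join(lines) + "\n"
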