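"""Synthetic multi-accession panels with planted NLR variation.

The generator emulates a small pan-genome panel of one species: a
reference accession whose chromosomes carry physically clustered,
intronless NLR genes, plus derived accessions produced by mutating the
reference with known (logged) events — background SNVs, small InDels,
~8 kb insertions into coding sequence, whole-gene deletions, tandem-ish
duplications, and targeted single-base substitutions that create
premature stop codons. Every event is recorded as a :class:`TruthEvent`
so that classification, mapping, CNV and pseudogene calls can be scored
against ground truth.

Each simulated NLR protein embeds the four NB-ARC motifs (P-loop,
Kinase2, GLPL, MHDV) in canonical order across a span of >= 160 aa;
subgroup identity is realized as subgroup-specific "barcode" linkers
between the motifs, so sequence distances within a subgroup are smaller
than between subgroups.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome_io import (GeneModel, GenomeSequence, extract_protein,
                        spliced_cds)
from . import nbarc

DNA = "ACGT"
STOPS = ("TAA", "TAG", "TGA")

# codons per amino acid (standard code, stops excluded)
_CODONS: dict[str, list[str]] = {}
_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}
for codon, aa in _TABLE.items():
    _CODONS.setdefault(aa, []).append(codon)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MOTIF_CORES = {
    "P-loop": "GMGGVGKT",
    "Kinase2": "LLVLDDV",
    "GLPL": "GLPLA",
    "MHDV": "MHDV",
}
DEFAULT_SUBGROUPS = ("G1", "G2", "G8", "G10", "GT", "GR")
LINKER_LEN = 55
TAIL_LEN = 30
HEAD_LEN = 20
BARCODE_JITTER = 0.03  # per-gene divergence within a subgroup

# Barcode alphabets per subgroup, chosen so that residues of different
# alphabets almost never score positive under BLOSUM62: between-subgroup
# barcode similarity stays far below the 50% "positives" cutoff of the
# partial-NLR vote, while within-subgroup genes share a template and stay
# near-identical.
SUBGROUP_ALPHABETS = ("ILVM", "FYW", "KRQ", "DEN", "STA", "GPHC")

# per-accession keep-fractions for planted CNV clusters; the default is
# the 16:15:1:9:12 copy-number profile of a strongly variable cluster
DEFAULT_CNV_PROFILE = (1.0, 15 / 16, 1 / 16, 9 / 16, 12 / 16)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ConfigError(ValueError):
    pass


@dataclass
class PanelConfig:
    """Layout of the simulated reference accession and panel."""

    n_accessions: int = 5
    n_chromosomes: int = 2
    chromosome_length: int = 700_000
    n_clusters: int = 8            # total, distributed round-robin over chromosomes
    genes_per_cluster: tuple[int, int] = (4, 8)
    planted_cluster_genes: int = 16   # CNV-planted clusters use this size
    intra_cluster_gap: tuple[int, int] = (3_000, 8_000)
    inter_cluster_gap: tuple[int, int] = (60_000, 90_000)
    margin: int = 15_000
    subgroup_labels: tuple[str, ...] = DEFAULT_SUBGROUPS
    seed: int = 0

    def validate(self) -> None:
        if self.n_accessions < 1 or self.n_chromosomes < 1 or self.n_clusters < 1:
            raise ConfigError("counts must be >= 1")
        if self.genes_per_cluster[0] < 1:
            raise ConfigError("genes_per_cluster must be >= 1")
        for lo, hi in (self.intra_cluster_gap, self.inter_cluster_gap):
            if not (0 < lo <= hi):
                raise ConfigError("gap ranges must be positive")
        if self.intra_cluster_gap[1] >= 50_000:
            raise ConfigError("intra-cluster gaps must stay below 50 kb")
        if self.inter_cluster_gap[0] <= 50_000:
            raise ConfigError("inter-cluster gaps must exceed 50 kb")
        if not self.subgroup_labels:
            raise ConfigError("need at least one subgroup label")


@dataclass
class MutationConfig:
    """Per-accession mutation process applied to the reference."""

    snv_rate: float = 0.0005
    small_indel_rate: float = 0.00002
    large_insertion_prob: float = 0.0
    gene_deletion_prob: float = 0.0
    gene_duplication_prob: float = 0.0
    premature_stop_prob: float = 0.0
    large_insertion_len: tuple[int, int] = (7_500, 8_500)

    def validate(self) -> None:
        for name in ("large_insertion_prob", "gene_deletion_prob",
                     "gene_duplication_prob", "premature_stop_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1]")
        if self.snv_rate < 0 or self.small_indel_rate < 0:
            raise ConfigError("rates must be >= 0")


@dataclass
class TruthEvent:
    accession_id: str
    gene_id: str          # reference lineage gene id ("." for intergenic)
    event_type: str       # snv | small_indel | large_insertion | gene_deletion
    #                       | gene_duplication | premature_stop
    position: int         # reference bp
    seq_id: str
    detail: str = ""


@dataclass
class Accession:
    accession_id: str
    sequences: list[GenomeSequence]
    genes: list[GeneModel]
    lineage: dict[str, str] = field(default_factory=dict)  # gene_id -> ref gene id

    def seq(self, seq_id: str) -> GenomeSequence:
        for s in self.sequences:
            if s.seq_id == seq_id:
                return s
        raise KeyError(seq_id)

    def write(self, outdir) -> None:
        from pathlib import Path
        from .genome_io import write_fasta, write_gff3
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sequences, out / f"{self.accession_id}.fasta")
        write_gff3(self.genes, out / f"{self.accession_id}.gff3")


@dataclass
class Panel:
    config: PanelConfig
    accessions: list[Accession]          # reference first
    subgroup_truth: dict[str, str]       # reference gene id -> subgroup
    cluster_truth: dict[str, int]        # reference gene id -> cluster index
    events: list[TruthEvent]
    planted_cnv: list[dict]              # rows: cluster, accession, kept, deleted

    @property
    def reference(self) -> Accession:
        return self.accessions[0]


# ---------------------------------------------------------------------------
# Reference simulation


def _random_protein(rng: np.random.Generator, n: int, alphabet: str) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _subgroup_template(rng: np.random.Generator, alphabet: str) -> dict[str, str]:
    return {
        "alphabet": alphabet,
        "head": _random_protein(rng, HEAD_LEN, alphabet),
        "linker1": _random_protein(rng, LINKER_LEN, alphabet),
        "linker2": _random_protein(rng, LINKER_LEN, alphabet),
        "linker3": _random_protein(rng, LINKER_LEN, alphabet),
        "tail": _random_protein(rng, TAIL_LEN, alphabet),
    }


def _jitter(seq: str, rng: np.random.Generator, alphabet: str,
            rate: float = BARCODE_JITTER) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = alphabet[rng.integers(0, len(alphabet))]
    return "".join(chars)


def _compose_protein(template: dict[str, str], rng: np.random.Generator) -> str:
    """One gene's protein from a subgroup template, with per-gene jitter.

    Retries until the leftmost hit of each motif is the planted core and
    the intact rule holds, so accidental motif look-alikes in barcode
    segments never corrupt the ground truth.
    """
    ab = template["alphabet"]
    for _ in range(60):
        parts = ["M",
                 _jitter(template["head"], rng, ab),
                 MOTIF_CORES["P-loop"],
                 _jitter(template["linker1"], rng, ab),
                 MOTIF_CORES["Kinase2"],
                 _jitter(template["linker2"], rng, ab),
                 MOTIF_CORES["GLPL"],
                 _jitter(template["linker3"], rng, ab),
                 MOTIF_CORES["MHDV"],
                 _jitter(template["tail"], rng, ab)]
        protein = "".join(parts)
        hits = nbarc.scan_motifs(protein)
        status, span = nbarc.classify_intact(hits, len(protein))
        p_start = 1 + HEAD_LEN
        want_span = (p_start,
                     len(protein) - TAIL_LEN)
        if status == "intact" and span == want_span:
            return protein
    raise RuntimeError("could not compose a clean NLR protein")


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [_CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in protein]
    return "".join(codons) + STOPS[rng.integers(0, 3)]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(DNA[i] for i in rng.integers(0, 4, n))


def simulate_reference(cfg: PanelConfig, accession_id: str = "acc1",
                       planted_clusters: frozenset[int] = frozenset(),
                       ) -> tuple[Accession, dict[str, str], dict[str, int]]:
    """Build the reference accession.

    Returns (accession, subgroup_truth, cluster_truth). Clusters are laid
    out so that consecutive genes within a cluster are separated by less
    than 50 kb and consecutive clusters by more; every NLR protein
    satisfies the intact NB-ARC rule by construction. Clusters listed in
    ``planted_clusters`` (destined for planted CNV) are built with
    ``cfg.planted_cluster_genes`` members — the scale of a strongly
    copy-number-variable NLR cluster — instead of drawing from
    ``genes_per_cluster``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    templates = {
        g: _subgroup_template(rng, SUBGROUP_ALPHABETS[i % len(SUBGROUP_ALPHABETS)])
        for i, g in enumerate(cfg.subgroup_labels)}

    sequences: list[GenomeSequence] = []
    genes: list[GeneModel] = []
    subgroup_truth: dict[str, str] = {}
    cluster_truth: dict[str, int] = {}
    gene_counter = 0
    label_cycle = 0

    clusters_per_chrom = [0] * cfg.n_chromosomes
    for c in range(cfg.n_clusters):
        clusters_per_chrom[c % cfg.n_chromosomes] += 1

    cluster_index = 0
    for chrom_i in range(cfg.n_chromosomes):
        seq_id = f"chr{chrom_i + 1}"
        parts: list[str] = []
        pos = 0

        def emit_bg(n: int):
            nonlocal pos
            parts.append(_random_dna(rng, n))
            pos += n

        emit_bg(cfg.margin)
        for _c in range(clusters_per_chrom[chrom_i]):
            n_genes = int(rng.integers(cfg.genes_per_cluster[0],
                                       cfg.genes_per_cluster[1] + 1))
            if cluster_index in planted_clusters:
                n_genes = cfg.planted_cluster_genes
            for gi in range(n_genes):
                label = cfg.subgroup_labels[label_cycle % len(cfg.subgroup_labels)]
                label_cycle += 1
                gene_rng = np.random.default_rng(
                    (cfg.seed * 100_003 + gene_counter * 7 + 1) % 2**31)
                protein = _compose_protein(templates[label], gene_rng)
                cds = _back_translate(protein, gene_rng)
                strand = "+" if gene_rng.random() < 0.5 else "-"
                genomic = cds if strand == "+" else revcomp(cds)
                gene_id = f"g{gene_counter:04d}"
                gene_counter += 1
                start = pos
                parts.append(genomic)
                pos += len(genomic)
                model = GeneModel(gene_id=gene_id, accession_id=accession_id,
                                  seq_id=seq_id, start=start, end=pos,
                                  strand=strand, exons=[(start, pos)],
                                  protein=protein)
                genes.append(model)
                subgroup_truth[gene_id] = label
                cluster_truth[gene_id] = cluster_index
                if gi < n_genes - 1:
                    emit_bg(int(rng.integers(*cfg.intra_cluster_gap)))
            cluster_index += 1
            if _c < clusters_per_chrom[chrom_i] - 1:
                emit_bg(int(rng.integers(*cfg.inter_cluster_gap)))
        if pos + cfg.margin > cfg.chromosome_length:
            raise ConfigError(
                f"chromosome_length {cfg.chromosome_length} too short: "
                f"layout needs {pos + cfg.margin} bp on {seq_id}")
        emit_bg(cfg.chromosome_length - pos)
        sequences.append(GenomeSequence(accession_id, seq_id, "".join(parts)))

    ref = Accession(accession_id, sequences, genes,
                    lineage={g.gene_id: g.gene_id for g in genes})
    return ref, subgroup_truth, cluster_truth


# ---------------------------------------------------------------------------
# Coordinate liftover through structural edits


class CoordinateLift:
    """Maps reference coordinates through a set of non-overlapping edits.

    Each edit replaces reference interval [start, end) with ``ins``
    inserted bases (pure insertion: start == end).
    """

    def __init__(self, edits: list[tuple[int, int, int]]):
        self.edits = sorted(edits)
        self._starts = [e[0] for e in self.edits]
        deltas = []
        cum = 0
        for s, e, ins in self.edits:
            cum += ins - (e - s)
            deltas.append(cum)
        self._cum = deltas

    def lift(self, x: int) -> int:
        """New coordinate of reference position x (left-biased at edits)."""
        import bisect
        k = bisect.bisect_right(self._starts, x) - 1
        if k < 0:
            return x
        s, e, ins = self.edits[k]
        base = self._cum[k]
        if x < e:  # inside a removed span -> collapse to its start
            return s + (self._cum[k - 1] if k else 0)
        return x + base


def _apply_edits(seq: str, edits: list[tuple[int, int, int, str]]) -> str:
    """Apply non-overlapping (start, end, ins_len, ins_seq) edits."""
    parts = []
    prev = 0
    for s, e, _ins, ins_seq in sorted(edits):
        parts.append(seq[prev:s])
        parts.append(ins_seq)
        prev = e
    parts.append(seq[prev:])
    return "".join(parts)


# ---------------------------------------------------------------------------
# Derived accessions


def _stop_snv_candidates(cds: str, lo: int, hi: int) -> list[tuple[int, int, str]]:
    """Single-base substitutions creating a stop codon.

    Returns (codon_index, offset_in_codon, new_base) for codons in
    [lo, hi); deterministic order.
    """
    out = []
    for k in range(lo, hi):
        codon = cds[3 * k:3 * k + 3]
        if codon in STOPS:
            continue
        for off in range(3):
            for b in DNA:
                if b == codon[off]:
                    continue
                mutated = codon[:off] + b + codon[off + 1:]
                if mutated in STOPS:
                    out.append((k, off, b))
    return out


def derive_accession(reference: Accession,
                     mcfg: MutationConfig,
                     accession_id: str,
                     seed: int,
                     forced_deletions: set[str] | None = None,
                     ) -> tuple[Accession, list[TruthEvent]]:
    """Mutate the reference into a derived accession with logged truth.

    Gene-level events are mutually exclusive per gene (deletion >
    duplication > large insertion > premature stop, decided by a single
    uniform draw); background SNVs and small InDels are drawn per base
    pair genome-wide. Derived gene models are lifted through all
    length-changing edits, and proteins are re-translated from the
    mutated genome.
    """
    mcfg.validate()
    forced_deletions = forced_deletions or set()
    rng = np.random.default_rng(seed)
    events: list[TruthEvent] = []
    new_sequences: list[GenomeSequence] = []
    new_genes: list[GeneModel] = []
    lineage: dict[str, str] = {}

    genes_by_seq: dict[str, list[GeneModel]] = {}
    for g in reference.genes:
        genes_by_seq.setdefault(g.seq_id, []).append(g)

    for chrom in reference.sequences:
        ref_seq = chrom.sequence
        L = len(ref_seq)
        genes = sorted(genes_by_seq.get(chrom.seq_id, []), key=lambda g: g.start)
        seq_list = list(ref_seq)

        deleted: set[str] = set()
        duplicated: list[tuple[GeneModel, int]] = []   # (gene, insert ref pos)
        struct: list[tuple[int, int, int, str]] = []   # start, end, ins_len, ins_seq

        def overlaps_existing(s: int, e: int) -> bool:
            return any(not (e <= a or b <= s) for a, b, _, _ in struct)

        # --- per-gene events ---------------------------------------------
        for idx, g in enumerate(genes):
            u = rng.random()
            forced = g.gene_id in forced_deletions
            p_del = mcfg.gene_deletion_prob
            p_dup = p_del + mcfg.gene_duplication_prob
            p_ins = p_dup + mcfg.large_insertion_prob
            p_stop = p_ins + mcfg.premature_stop_prob
            if forced or u < p_del:
                deleted.add(g.gene_id)
                struct.append((g.start, g.end, 0, ""))
                events.append(TruthEvent(accession_id, g.gene_id, "gene_deletion",
                                         g.start, chrom.seq_id,
                                         f"len={g.end - g.start}"))
            elif u < p_dup:
                nxt = genes[idx + 1].start if idx + 1 < len(genes) else L
                gap = nxt - g.end
                if gap > 600:
                    p = g.end + min(1000, gap // 2)
                    seg = ref_seq[g.start:g.end]
                    if not overlaps_existing(p, p):
                        struct.append((p, p, len(seg), seg))
                        duplicated.append((g, p))
                        events.append(TruthEvent(accession_id, g.gene_id,
                                                 "gene_duplication", p,
                                                 chrom.seq_id,
                                                 f"copy_len={len(seg)}"))
            elif u < p_ins:
                lo, hi = mcfg.large_insertion_len
                n_ins = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
                p = (g.start + g.end) // 2
                ins_seq = _random_dna(rng, n_ins)
                if not overlaps_existing(p, p):
                    struct.append((p, p, n_ins, ins_seq))
                    events.append(TruthEvent(accession_id, g.gene_id,
                                             "large_insertion", p, chrom.seq_id,
                                             f"len={n_ins}"))
            elif u < p_stop:
                cds = spliced_cds(g, chrom)
                n_codons = len(cds) // 3 - 1  # exclude terminal stop
                lo_c, hi_c = max(1, n_codons // 5), max(2, (2 * n_codons) // 5)
                cands = _stop_snv_candidates(cds, lo_c, hi_c)
                if cands:
                    k, off, b = cands[int(rng.integers(0, len(cands)))]
                    cds_off = 3 * k + off
                    if g.strand == "+":
                        gpos = g.start + cds_off
                        new_base = b
                    else:
                        gpos = g.end - 1 - cds_off
                        new_base = b.translate(_COMPLEMENT)
                    seq_list[gpos] = new_base
                    events.append(TruthEvent(accession_id, g.gene_id,
                                             "premature_stop", gpos,
                                             chrom.seq_id,
                                             f"codon={k};base={b}"))

        gene_spans = [(g.start, g.end) for g in genes if g.gene_id not in deleted]

        def in_gene(p: int) -> str:
            for g in genes:
                if g.start <= p < g.end and g.gene_id not in deleted:
                    return g.gene_id
            return "."

        # --- background SNVs ---------------------------------------------
        n_snv = rng.binomial(L, min(mcfg.snv_rate, 1.0)) if mcfg.snv_rate else 0
        if n_snv:
            positions = rng.choice(L, size=n_snv, replace=False)
            for p in sorted(int(x) for x in positions):
                old = seq_list[p]
                if old == "N":
                    continue
                alt = DNA[(DNA.index(old) + int(rng.integers(1, 4))) % 4]
                seq_list[p] = alt
                events.append(TruthEvent(accession_id, in_gene(p), "snv", p,
                                         chrom.seq_id, f"{old}>{alt}"))

        # --- background small InDels -------------------------------------
        n_ind = rng.binomial(L, min(mcfg.small_indel_rate, 1.0)) \
            if mcfg.small_indel_rate else 0
        if n_ind:
            positions = sorted(int(x) for x in rng.choice(L, size=n_ind, replace=False))
            for p in positions:
                ln = int(rng.integers(1, 11))
                if rng.random() < 0.5:  # insertion
                    if overlaps_existing(p, p):
                        continue
                    struct.append((p, p, ln, _random_dna(rng, ln)))
                    events.append(TruthEvent(accession_id, in_gene(p),
                                             "small_indel", p, chrom.seq_id,
                                             f"ins={ln}"))
                else:
                    if p + ln > L or overlaps_existing(p, p + ln):
                        continue
                    if any(s < p < e or s < p + ln <= e or (p <= s and e <= p + ln)
                           for s, e in gene_spans) and in_gene(p) == ".":
                        continue  # do not let intergenic deletions nibble genes
                    struct.append((p, p + ln, 0, ""))
                    events.append(TruthEvent(accession_id, in_gene(p),
                                             "small_indel", p, chrom.seq_id,
                                             f"del={ln}"))

        # --- apply --------------------------------------------------------
        mutated = "".join(seq_list)
        derived_seq = _apply_edits(mutated, struct)
        lift = CoordinateLift([(s, e, i) for s, e, i, _ in struct])
        new_chrom = GenomeSequence(accession_id, chrom.seq_id, derived_seq)
        new_sequences.append(new_chrom)

        for g in genes:
            if g.gene_id in deleted:
                continue
            ns, ne = lift.lift(g.start), lift.lift(g.end)
            gid = f"{accession_id}_{g.gene_id}"
            model = GeneModel(gene_id=gid, accession_id=accession_id,
                              seq_id=chrom.seq_id, start=ns, end=ne,
                              strand=g.strand, exons=[(ns, ne)])
            if model.cds_length % 3 != 0:
                model.flags.append("cds_not_multiple_of_3")
            model.protein = extract_protein(model, new_chrom)
            new_genes.append(model)
            lineage[gid] = g.gene_id
        for dup_i, (g, p) in enumerate(duplicated):
            # lift(p) lands just past the inserted copy
            ins_len = g.end - g.start
            de = lift.lift(p)
            gid = f"{accession_id}_{g.gene_id}_d{dup_i + 1}"
            model = GeneModel(gene_id=gid, accession_id=accession_id,
                              seq_id=chrom.seq_id, start=de - ins_len, end=de,
                              strand=g.strand, exons=[(de - ins_len, de)])
            model.protein = extract_protein(model, new_chrom)
            new_genes.append(model)
            lineage[gid] = g.gene_id

    acc = Accession(accession_id, new_sequences,
                    sorted(new_genes, key=lambda g: (g.seq_id, g.start)), lineage)
    return acc, events


# ---------------------------------------------------------------------------
# Panels


def child_seed(seed: int, k: int) -> int:
    return (seed * 1_000_003 + 7919 * k + 1) % 2**31


def simulate_panel(cfg: PanelConfig,
                   mcfg: MutationConfig | list[MutationConfig],
                   seed: int | None = None,
                   n_planted_cnv: int = 0,
                   cnv_profile: tuple[float, ...] = DEFAULT_CNV_PROFILE,
                   ) -> Panel:
    """Simulate the full panel: reference + derived accessions + truth.

    ``n_planted_cnv`` clusters receive accession-specific gene deletions
    shaping their copy numbers to ``cnv_profile`` (keep-fractions per
    accession, reference first), so per-accession counts differ strongly
    in planted clusters and only through background noise elsewhere.
    """
    cfg.validate()
    if cfg.n_accessions < 2:
        raise ConfigError("a panel needs >= 2 accessions")
    if n_planted_cnv > cfg.n_clusters:
        raise ConfigError("more planted CNV clusters than clusters")
    seed = cfg.seed if seed is None else seed
    cfg = replace(cfg, seed=seed)
    mcfgs = (list(mcfg) if isinstance(mcfg, list)
             else [mcfg] * (cfg.n_accessions - 1))
    if len(mcfgs) != cfg.n_accessions - 1:
        raise ConfigError("need one MutationConfig per derived accession")

    rng = np.random.default_rng(child_seed(seed, 0))
    planted_clusters = sorted(
        int(c) for c in rng.choice(cfg.n_clusters, size=n_planted_cnv,
                                   replace=False)) if n_planted_cnv else []
    ref, subgroup_truth, cluster_truth = simulate_reference(
        cfg, planted_clusters=frozenset(planted_clusters))

    genes_by_cluster: dict[int, list[str]] = {}
    for gid, c in cluster_truth.items():
        genes_by_cluster.setdefault(c, []).append(gid)

    accessions = [ref]
    events: list[TruthEvent] = []
    planted_rows: list[dict] = []
    profile = list(cnv_profile)
    while len(profile) < cfg.n_accessions:
        profile.append(profile[-1])

    forced: dict[str, set[str]] = {}
    for c in planted_clusters:
        members = sorted(genes_by_cluster[c])
        n = len(members)
        for a in range(1, cfg.n_accessions):
            keep = max(1, round(profile[a] * n)) if profile[a] > 0 else 0
            drop = members[keep:]
            acc_id = f"acc{a + 1}"
            forced.setdefault(acc_id, set()).update(drop)
            planted_rows.append({"cluster": c, "accession": acc_id,
                                 "n_reference": n, "n_kept": n - len(drop),
                                 "n_deleted": len(drop)})

    for a in range(1, cfg.n_accessions):
        acc_id = f"acc{a + 1}"
        acc, ev = derive_accession(ref, mcfgs[a - 1], acc_id,
                                   child_seed(seed, a),
                                   forced_deletions=forced.get(acc_id, set()))
        accessions.append(acc)
        events.extend(ev)

    return Panel(cfg, accessions, subgroup_truth, cluster_truth,
                 events, planted_rows)


# ---------------------------------------------------------------------------
# Count-level emulator for statistical calibration


def simulate_cluster_counts(n_clusters: int,
                            genes_per_cluster: tuple[int, int],
                            n_accessions: int,
                            deletion_prob: float,
                            duplication_prob: float,
                            seed: int,
                            planted: dict[int, tuple[float, ...]] | None = None,
                            planted_size: int = 16,
                            ) -> tuple[np.ndarray, list[int]]:
    """Cluster-by-accession NLR counts without sequence simulation.

    The reference accession keeps every gene; each derived accession
    loses genes by binomial thinning at ``deletion_prob`` and gains
    copies at ``duplication_prob`` — the count-level shadow of the full
    generator, used for type-I-error and power calibration at scale.
    Planted clusters follow keep-fraction profiles instead.
    Returns (counts matrix, planted cluster indices).
    """
    rng = np.random.default_rng(seed)
    planted = planted or {}
    counts = np.zeros((n_clusters, n_accessions), dtype=int)
    for c in range(n_clusters):
        n = int(rng.integers(genes_per_cluster[0], genes_per_cluster[1] + 1))
        prof = planted.get(c)
        if prof is not None:
            n = planted_size
        counts[c, 0] = n
        for a in range(1, n_accessions):
            if prof is not None:
                frac = prof[a % len(prof)]
                counts[c, a] = max(1, round(frac * n)) if frac > 0 else 0
            else:
                kept = n - rng.binomial(n, deletion_prob)
                gained = rng.binomial(n, duplication_prob)
                counts[c, a] = kept + gained
    return counts, sorted(planted)
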