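"""Genome and annotation I/O: sequences, gene models, catalogs.

All internal coordinates are 0-based half-open. GFF3 (1-based inclusive)
and BED conventions are converted only at the I/O boundary, so every
downstream interval operation (cluster merging, projection, windowing)
works in a single convention.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

GENOME_ALPHABET = set("ACGTN")


class ParseError(ValueError):
    """Raised for malformed FASTA/GFF3 input."""


@dataclass
class GenomeSequence:
    """One assembled sequence (chromosome or scaffold) of one accession."""

    accession_id: str
    seq_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"empty sequence for {self.seq_id}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A protein-coding gene with its spliced CDS structure.

    ``exons`` are CDS sub-intervals, 0-based half-open, sorted in genomic
    order regardless of strand. ``protein`` is the translation of the
    spliced, strand-corrected CDS (no trailing stop).
    """

    gene_id: str
    accession_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    protein: str = ""
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: bad interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        prev = -1
        for s, e in self.exons:
            if s < prev:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon outside gene interval")
            prev = e

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def read_fasta(path: str | os.PathLike, accession_id: str = "",
               validate_genome: bool = False) -> list[GenomeSequence]:
    """Read a FASTA file into GenomeSequence records (order preserved).

    Sequences are uppercased. With ``validate_genome`` any letter outside
    {A,C,G,T,N} is rejected, which keeps translation downstream
    deterministic. Protein FASTA files are read with the same function,
    just without validation.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise ParseError(f"{path}: record with empty header")
        if not seq:
            raise ParseError(f"{path}: empty record {rec.id!r}")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        if validate_genome:
            bad = set(seq) - GENOME_ALPHABET
            if bad:
                raise ParseError(
                    f"{path}: {rec.id}: unsupported characters {sorted(bad)}")
        seen.add(rec.id)
        records.append(GenomeSequence(accession_id, rec.id, seq))
    return records


def write_fasta(records, path: str | os.PathLike, width: int = 70) -> None:
    """Write GenomeSequence records (or (id, seq) pairs) as FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, GenomeSequence):
                name, seq = rec.seq_id, rec.sequence
            else:
                name, seq = rec
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_gff3(path: str | os.PathLike,
              genome: list[GenomeSequence] | None = None,
              accession_id: str = "") -> list[GeneModel]:
    """Read gene/mRNA/CDS features from GFF3 into GeneModel records.

    One model per gene is returned: when a gene has several mRNAs the one
    with the longest total CDS is kept (ties broken by mRNA id). GFF3
    1-based inclusive coordinates become 0-based half-open. If ``genome``
    is given, proteins are translated from it.
    """
    import gffutils

    seq_by_id = {g.seq_id: g for g in genome} if genome else {}
    try:
        db = gffutils.create_db(str(path), ":memory:",
                                merge_strategy="create_unique",
                                keep_order=True)
    except Exception as exc:  # noqa: BLE001 - surface as a parse error
        raise ParseError(f"{path}: {exc}") from exc

    by_gene: dict[str, list] = {}
    for mrna in db.features_of_type("mRNA"):
        parents = list(db.parents(mrna, featuretype="gene"))
        gid = parents[0].id if parents else mrna.id
        by_gene.setdefault(gid, []).append(mrna)
    # tolerate mRNA-less annotations where CDS hang directly off genes
    for gene in db.features_of_type("gene"):
        if gene.id not in by_gene and list(db.children(gene, featuretype="CDS")):
            by_gene[gene.id] = [gene]

    models: list[GeneModel] = []
    for gid in sorted(by_gene):
        candidates = []
        for mrna in by_gene[gid]:
            cds = sorted((c.start - 1, c.end)
                         for c in db.children(mrna, featuretype="CDS"))
            if not cds:
                continue
            total = sum(e - s for s, e in cds)
            candidates.append((total, mrna.id, cds, mrna))
        if not candidates:
            continue
        candidates.sort(key=lambda t: (-t[0], t[1]))
        _total, _mid, exons, mrna = candidates[0]
        seqid, strand = mrna.seqid, mrna.strand
        if seq_by_id and seqid not in seq_by_id:
            raise ParseError(f"{path}: CDS of {gid} references unknown seq {seqid!r}")
        model = GeneModel(
            gene_id=gid,
            accession_id=accession_id or (seq_by_id[seqid].accession_id if seq_by_id else ""),
            seq_id=seqid,
            start=min(s for s, _ in exons),
            end=max(e for _, e in exons),
            strand=strand,
            exons=exons,
        )
        if model.cds_length % 3 != 0:
            model.flags.append("cds_not_multiple_of_3")
        if seq_by_id:
            model.protein = extract_protein(model, seq_by_id[seqid])
        models.append(model)
    return models


def write_gff3(models: list[GeneModel], path: str | os.PathLike) -> None:
    """Write GeneModels as minimal gene/mRNA/CDS GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda g: (g.seq_id, g.start, g.gene_id)):
            base = f"{m.seq_id}\tnlrmap\t"
            fh.write(base + f"gene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t"
                     f"ID={m.gene_id}\n")
            mid = m.gene_id + ".t1"
            fh.write(base + f"mRNA\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t"
                     f"ID={mid};Parent={m.gene_id}\n")
            phase = 0
            exons = m.exons if m.strand == "+" else m.exons[::-1]
            for s, e in exons:
                fh.write(base + f"CDS\t{s + 1}\t{e}\t.\t{m.strand}\t{phase}\t"
                         f"Parent={mid}\n")
                phase = (3 - ((e - s) - phase) % 3) % 3


def spliced_cds(model: GeneModel, genome: GenomeSequence) -> str:
    """Strand-corrected spliced CDS nucleotide sequence."""
    if model.seq_id != genome.seq_id:
        raise ValueError(f"{model.gene_id} is on {model.seq_id}, not {genome.seq_id}")
    if model.end > len(genome):
        raise ValueError(f"{model.gene_id} extends past end of {genome.seq_id}")
    parts = [genome.sequence[s:e] for s, e in model.exons]
    cds = "".join(parts)
    if model.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def translate_cds(cds: str) -> tuple[str, bool]:
    """Translate a CDS with the standard code, stopping at the first stop.

    Returns (protein, premature) where ``premature`` is True when a stop
    codon occurs before the final codon. A trailing stop is not part of
    the protein. Trailing bases that do not fill a codon are ignored.
    """
    n_codons = len(cds) // 3
    aa = str(Seq(cds[: n_codons * 3]).translate())
    stop_at = aa.find("*")
    if stop_at == -1:
        return aa, False
    return aa[:stop_at], stop_at < n_codons - 1


def extract_protein(model: GeneModel, genome: GenomeSequence) -> str:
    """Translate a gene model from its genome sequence.

    An internal stop before the last codon truncates the protein and
    flags the model ``premature_stop_in_annotation``.
    """
    protein, premature = translate_cds(spliced_cds(model, genome))
    if premature and "premature_stop_in_annotation" not in model.flags:
        model.flags.append("premature_stop_in_annotation")
    return protein


def write_table(records, path: str | os.PathLike, columns=None) -> None:
    """Write a catalog of records (dataframe, dicts, or dataclass-likes) as TSV.

    Header row always present; NA values serialize to empty fields.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = []
        for r in records:
            if isinstance(r, dict):
                rows.append(r)
            else:
                rows.append(vars(r))
        df = pd.DataFrame(rows, columns=columns)
        if df.empty and columns:
            df = pd.DataFrame(columns=columns)
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
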