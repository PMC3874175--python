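"""Gene models, fragment extraction and "conventional gene" classification.

A gene is decomposed into a promoter, numbered coding exons and the introns
between them.  Exons and introns are numbered 1..n in the gene's
transcriptional 5'->3' direction, so the "first intron" is the intron
nearest the start codon on either strand.  All internal coordinates are
0-based half-open; GFF3 I/O converts at the boundary.

A gene is *conventional* when it has no intron in its 5' UTR, a unique
first coding exon, and is not located downstream within an operon.  Genes
failing any criterion are excluded from first-intron analyses because their
first intron is not the intron closest to the transcription start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

PROMOTER_SPAN = 2000  # bp upstream of the start codon, unless a neighbor is closer


@dataclass
class Genome:
    """A set of named chromosome sequences for one species."""

    species_id: str
    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name!r}")

    def fetch(self, chromosome: str, start: int, end: int) -> str:
        seq = self.chromosomes[chromosome]
        if start < 0 or end > len(seq):
            raise ValueError(
                f"interval [{start},{end}) outside chromosome {chromosome} "
                f"(length {len(seq)})"
            )
        return seq[start:end]


@dataclass
class GeneModel:
    """A protein-coding gene: ordered coding exons plus classification inputs.

    ``coding_exons`` are genomic 0-based half-open intervals in ascending
    genomic order regardless of strand.
    """

    gene_id: str
    chromosome: str
    strand: str
    coding_exons: list[tuple[int, int]]
    utr5_introns: int = 0
    alt_first_exons: int = 1
    operon_position: str = "none"  # none | first | downstream

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.coding_exons:
            raise ValueError(f"{self.gene_id}: no coding exons")
        exons = sorted(self.coding_exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping coding exons")
        self.coding_exons = exons

    @property
    def coding_span(self) -> tuple[int, int]:
        return self.coding_exons[0][0], self.coding_exons[-1][1]

    @property
    def start_codon_position(self) -> int:
        """Genomic coordinate of the A of the ATG (0-based).

        For a minus-strand gene this is the last base of the coding span,
        i.e. ``end - 1`` of the highest-coordinate exon.
        """
        if self.strand == "+":
            return self.coding_exons[0][0]
        return self.coding_exons[-1][1] - 1

    @property
    def n_introns(self) -> int:
        return len(self.coding_exons) - 1


@dataclass
class GeneFragment:
    """One promoter, exon or intron of a gene, with strand-corrected sequence."""

    gene_id: str
    kind: str  # promoter | exon | intron
    index: int  # 1-based in transcriptional 5'->3' order
    chromosome: str
    interval: tuple[int, int]
    strand: str
    sequence: str = ""

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]

    @property
    def name(self) -> str:
        return f"{self.gene_id}|{self.kind}|{self.index}"


@dataclass
class ConventionalStatus:
    gene_id: str
    has_utr5_intron: bool
    has_alt_start: bool
    is_operon_downstream: bool

    @property
    def is_conventional(self) -> bool:
        return not (
            self.has_utr5_intron or self.has_alt_start or self.is_operon_downstream
        )


def classify_conventional(gene: GeneModel) -> ConventionalStatus:
    """Flag the three exclusion criteria and derive conventional status."""
    return ConventionalStatus(
        gene_id=gene.gene_id,
        has_utr5_intron=gene.utr5_introns > 0,
        has_alt_start=gene.alt_first_exons > 1,
        is_operon_downstream=gene.operon_position == "downstream",
    )


def load_annotation(
    gff3_path: str, fasta_path: str, species_id: str = "species"
) -> tuple[Genome, list[GeneModel]]:
    """Read a GFF3 + FASTA pair into a :class:`Genome` and gene models.

    Expects ``gene``/``mRNA``/``CDS`` features (``five_prime_UTR`` optional).
    The number of 5'-UTR introns is derived from split five_prime_UTR
    segments; operon membership and alternative-start counts are read from
    the ``operon_position=`` and ``alt_first_exons=`` gene attributes when
    present.  GFF3 1-based closed coordinates are converted to 0-based
    half-open.  Genes with malformed CDS chains are skipped with a warning;
    a feature on a chromosome absent from the FASTA is fatal.
    """
    chromosomes = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")
    }
    genome = Genome(species_id=species_id, chromosomes=chromosomes)

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gf in db.features_of_type("gene"):
        if gf.seqid not in chromosomes:
            raise ValueError(
                f"feature {gf.id} references chromosome {gf.seqid!r} "
                "absent from the FASTA"
            )
        cds = sorted(
            db.children(gf, featuretype="CDS"), key=lambda f: f.start
        )
        if not cds:
            logger.warning("gene %s has no CDS features; skipped", gf.id)
            continue
        exons = [(f.start - 1, f.end) for f in cds]  # GFF3 -> half-open
        utr5 = list(db.children(gf, featuretype="five_prime_UTR"))
        try:
            gene = GeneModel(
                gene_id=gf.id,
                chromosome=gf.seqid,
                strand=gf.strand,
                coding_exons=exons,
                utr5_introns=max(0, len(utr5) - 1),
                alt_first_exons=int(gf.attributes.get("alt_first_exons", ["1"])[0]),
                operon_position=gf.attributes.get("operon_position", ["none"])[0],
            )
        except ValueError as exc:
            logger.warning("gene %s skipped: %s", gf.id, exc)
            continue
        genes.append(gene)
    return genome, genes


def define_promoter(
    gene: GeneModel,
    neighbors: Iterable[GeneModel],
    genome: Genome | None = None,
    span: int = PROMOTER_SPAN,
) -> GeneFragment:
    """Promoter: start codon to up to ``span`` bp upstream, truncated at the
    nearest neighboring gene boundary (its start codon or 3'-end, whichever
    is closer).  A zero-length promoter (abutting neighbor) is retained but
    flagged by its length.
    """
    atg = gene.start_codon_position
    if gene.strand == "+":
        start = max(0, atg - span)
        end = atg
        for nb in neighbors:
            if nb.gene_id == gene.gene_id or nb.chromosome != gene.chromosome:
                continue
            for bound in nb.coding_span:
                if start < bound <= end:
                    start = bound
        if atg - span < 0:
            logger.info("gene %s promoter truncated at chromosome start", gene.gene_id)
    else:
        chrom_len = (
            len(genome.chromosomes[gene.chromosome]) if genome is not None else None
        )
        start = atg + 1
        end = start + span
        if chrom_len is not None and end > chrom_len:
            logger.info("gene %s promoter truncated at chromosome end", gene.gene_id)
            end = chrom_len
        for nb in neighbors:
            if nb.gene_id == gene.gene_id or nb.chromosome != gene.chromosome:
                continue
            for bound in nb.coding_span:
                if start <= bound < end:
                    end = bound
    seq = ""
    if genome is not None and end > start:
        seq = genome.fetch(gene.chromosome, start, end)
        if gene.strand == "-":
            seq = reverse_complement(seq)
    if end == start:
        logger.info("gene %s has a zero-length promoter", gene.gene_id)
    return GeneFragment(
        gene_id=gene.gene_id,
        kind="promoter",
        index=1,
        chromosome=gene.chromosome,
        interval=(start, end),
        strand=gene.strand,
        sequence=seq,
    )


def extract_fragments(gene: GeneModel, genome: Genome) -> list[GeneFragment]:
    """Exon and intron fragments numbered 1..n in transcriptional order.

    On the minus strand the exon/intron nearest the start codon (highest
    genomic coordinate) receives index 1, and every sequence is
    reverse-complemented so it reads 5'->3' in the transcript.
    """
    exons = gene.coding_exons
    introns = [
        (exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)
    ]
    span_start, span_end = gene.coding_span
    chrom_len = len(genome.chromosomes[gene.chromosome])
    if span_start < 0 or span_end > chrom_len:
        raise ValueError(
            f"{gene.gene_id}: coding span outside chromosome {gene.chromosome}"
        )

    def make(kind: str, order: Sequence[tuple[int, int]]) -> list[GeneFragment]:
        ivals = list(order) if gene.strand == "+" else list(order)[::-1]
        out = []
        for idx, (s, e) in enumerate(ivals, start=1):
            seq = genome.fetch(gene.chromosome, s, e)
            if gene.strand == "-":
                seq = reverse_complement(seq)
            out.append(
                GeneFragment(
                    gene_id=gene.gene_id,
                    kind=kind,
                    index=idx,
                    chromosome=gene.chromosome,
                    interval=(s, e),
                    strand=gene.strand,
                    sequence=seq,
                )
            )
        return out

    return make("exon", exons) + make("intron", introns)


def first_intron(fragments: Iterable[GeneFragment]) -> GeneFragment | None:
    for frag in fragments:
        if frag.kind == "intron" and frag.index == 1:
            return frag
    return None


def region_class(fragment: GeneFragment) -> str:
    """Collapse a fragment into the region classes used by binding summaries."""
    if fragment.kind == "promoter":
        return "promoter"
    if fragment.kind == "exon":
        return "exon"
    return "first_intron" if fragment.index == 1 else "other_intron"


def fragments_to_bed(fragments: Iterable[GeneFragment]) -> str:
    """BED6 lines, name = geneid|kind|index, score 0."""
    lines = []
    for f in fragments:
        lines.append(
            f"{f.chromosome}\t{f.interval[0]}\t{f.interval[1]}\t{f.name}\t0\t{f.strand}"
        )
    return "\n".join(lines) + "\n" if lines else ""


def fragments_to_fasta(fragments: Iterable[GeneFragment]) -> str:
    chunks = []
    for f in fragments:
        chunks.append(f">{f.name}\n{f.sequence}\n")
    return "".join(chunks)
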