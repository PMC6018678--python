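"""Genome and annotation I/O: FASTA chromosomes and GFF3 gene models.

Gene models are coding sequences (protein- or RNA-coding) extracted from
1-based inclusive GFF3 coordinates; minus-strand genes carry the
reverse-complemented (coding-strand, 5'->3') sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G/C bases in ``seq``."""
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


@dataclass
class GeneModel:
    """An annotated coding gene on a chromosome.

    Coordinates are 1-based inclusive; ``cds_sequence`` is the coding-strand
    nucleotide sequence 5'->3' (already reverse-complemented for minus-strand
    genes) and has length ``end - start + 1``.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    cds_sequence: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")
        if len(self.cds_sequence) != self.end - self.start + 1:
            raise ValueError(
                f"{self.gene_id}: sequence length {len(self.cds_sequence)} "
                f"does not match span {self.end - self.start + 1}"
            )
        self.cds_sequence = self.cds_sequence.upper()

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into ``{sequence_id: sequence}`` (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# GFF3 feature types accepted as gene models and their biotype tag.
_FEATURE_BIOTYPE = {
    "CDS": "protein_coding",
    "gene": "protein_coding",
    "ncRNA": "rna",
    "rRNA": "rna",
    "tRNA": "rna",
}


def _parse_attributes(column: str) -> dict[str, str]:
    out = {}
    for item in column.strip().split(";"):
        if not item or "=" not in item:
            continue
        key, value = item.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def read_gff3(path) -> list[dict]:
    """Parse GFF3 rows for the supported feature types.

    Returns dicts with keys gene_id, chromosome, start, end, strand, biotype.
    The gene identifier is taken from ``gene_id``, ``locus_tag``, ``ID`` or
    ``Name``, in that order.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}")
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in _FEATURE_BIOTYPE:
                continue
            attributes = _parse_attributes(attrs)
            gene_id = (
                attributes.get("gene_id")
                or attributes.get("locus_tag")
                or attributes.get("ID")
                or attributes.get("Name")
            )
            if gene_id is None:
                raise ValueError(f"{path}: feature at line {lineno} has no identifier")
            rows.append(
                {
                    "gene_id": gene_id,
                    "chromosome": chrom,
                    "start": int(start),
                    "end": int(end),
                    "strand": strand,
                    "biotype": _FEATURE_BIOTYPE[ftype],
                }
            )
    return rows


def load_genes(genome: dict[str, str], annotation) -> list[GeneModel]:
    """Build :class:`GeneModel` objects from a genome dict and a GFF3 path
    (or pre-parsed annotation rows).

    Raises if an annotation row references a chromosome absent from the
    genome or if a gene_id occurs more than once.
    """
    rows = annotation if isinstance(annotation, list) else read_gff3(annotation)
    seen: set[str] = set()
    genes = []
    for row in rows:
        if row["chromosome"] not in genome:
            raise ValueError(
                f"annotation references absent chromosome {row['chromosome']!r}"
            )
        if row["gene_id"] in seen:
            raise ValueError(f"duplicate gene_id {row['gene_id']!r} in annotation")
        seen.add(row["gene_id"])
        chrom_seq = genome[row["chromosome"]]
        segment = chrom_seq[row["start"] - 1 : row["end"]]
        if row["strand"] == "-":
            segment = revcomp(segment)
        genes.append(
            GeneModel(
                gene_id=row["gene_id"],
                chromosome=row["chromosome"],
                start=row["start"],
                end=row["end"],
                strand=row["strand"],
                cds_sequence=segment,
                biotype=row["biotype"],
            )
        )
    return genes
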