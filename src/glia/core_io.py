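"""Domain types and readers/writers for the α-gliadin analysis pipeline.

Sequences live in two thin validated containers (:class:`NucleotideSeq`,
:class:`ProteinSeq`); genes and loci are plain dataclasses.  Internal
coordinates are 0-based half-open throughout; GFF3 is emitted/consumed
1-based inclusive per the format specification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NT_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)  # {TAA, TAG, TGA}


class GliaError(Exception):
    """Base class for pipeline errors."""


class SequenceAlphabetError(GliaError):
    pass


class FastaFormatError(GliaError):
    pass


class Gff3FormatError(GliaError):
    pass


@dataclass(frozen=True)
class NucleotideSeq:
    """A DNA sequence over {A,C,G,T,N}, uppercased on construction (U -> T)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        canonical = self.seq.upper().replace("U", "T")
        object.__setattr__(self, "seq", canonical)
        if not canonical:
            raise SequenceAlphabetError(f"{self.id}: empty nucleotide sequence")
        bad = set(canonical) - NT_ALPHABET
        if bad:
            raise SequenceAlphabetError(
                f"{self.id}: invalid nucleotide characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProteinSeq:
    """A protein sequence; '*' marks a stop and may appear internally only
    for translations of defective reading frames."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        canonical = self.seq.upper()
        object.__setattr__(self, "seq", canonical)
        if not canonical:
            raise SequenceAlphabetError(f"{self.id}: empty protein sequence")
        bad = set(canonical) - AA_ALPHABET
        if bad:
            raise SequenceAlphabetError(
                f"{self.id}: invalid amino-acid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def has_internal_stop(self) -> bool:
        return "*" in self.seq[:-1]


DEFECT_KINDS = ("premature_stop", "frameshift_indel", "te_insertion", "truncation")


@dataclass
class DefectAnnotation:
    """One pseudogenizing lesion.

    ``position`` is a 0-based offset in the (TE-free) CDS.  ``c_to_t`` is
    only meaningful for premature stops and flags the canonical
    glutamine-codon transition CAA/CAG -> TAA/TAG.
    """

    kind: str
    position: int
    detail: str = ""
    c_to_t: bool = False

    def __post_init__(self) -> None:
        if self.kind not in DEFECT_KINDS:
            raise ValueError(f"unknown defect kind: {self.kind}")
        if self.position < 0:
            raise ValueError("defect position must be non-negative")


GENOMES = ("A", "B", "D", "other")


@dataclass
class GeneRecord:
    """One candidate α-gliadin gene on a locus."""

    gene_id: str
    genome: str
    cds: NucleotideSeq
    locus_start: int = 0
    locus_end: int = 0
    strand: str = "+"
    status: str | None = None  # intact | pseudogene | fragment
    defects: list[DefectAnnotation] = field(default_factory=list)
    note: str = ""

    def __post_init__(self) -> None:
        if self.genome not in GENOMES:
            raise ValueError(f"{self.gene_id}: genome must be one of {GENOMES}")
        if self.locus_end <= self.locus_start:
            # default to CDS span when coordinates were not supplied
            if self.locus_start == 0 and self.locus_end == 0:
                self.locus_end = len(self.cds)
            else:
                raise ValueError(f"{self.gene_id}: locus_start must be < locus_end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.status == "intact" and self.defects:
            raise ValueError(f"{self.gene_id}: intact gene cannot carry defects")


@dataclass
class LocusRecord:
    """An ordered, non-overlapping run of genes on one (sub)genome locus."""

    genome: str
    genes: list[GeneRecord] = field(default_factory=list)
    sequence: NucleotideSeq | None = None

    def __post_init__(self) -> None:
        self.genes.sort(key=lambda g: g.locus_start)
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene ids in locus: {dupes}")
        for a, b in zip(self.genes, self.genes[1:]):
            if a.locus_end > b.locus_start:
                raise ValueError(
                    f"overlapping genes {a.gene_id} and {b.gene_id} in locus"
                )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, alphabet: str = "nucleotide"):
    """Read a multi-record FASTA into validated sequence containers.

    Parameters
    ----------
    alphabet : {"nucleotide", "protein"}
        Container type to construct.

    Raises on an empty file and on duplicate record ids (all duplicates are
    listed in the message).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    ids = [r.id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise FastaFormatError(f"{path}: duplicate ids: {dupes}")
    cls = NucleotideSeq if alphabet == "nucleotide" else ProteinSeq
    out = []
    for r in records:
        desc = r.description[len(r.id):].strip() if r.description else ""
        out.append(cls(id=r.id, seq=str(r.seq), description=desc))
    return out


def write_fasta(seqs: Iterable[NucleotideSeq | ProteinSeq], path: str | Path) -> None:
    """Write records wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(s.seq), id=s.id, description=s.description) for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3 (single feature type "gene"; status and defects carried as attributes)


def to_gff3_coords(start: int, end: int) -> tuple[int, int]:
    """Internal 0-based half-open -> GFF3 1-based inclusive."""
    return start + 1, end


def from_gff3_coords(col4: int, col5: int) -> tuple[int, int]:
    """GFF3 1-based inclusive -> internal 0-based half-open."""
    return col4 - 1, col5


def write_gff3(locus: LocusRecord, path: str | Path, source: str = "glia") -> None:
    seqid = locus.sequence.id if locus.sequence is not None else f"locus_{locus.genome}"
    lines = ["##gff-version 3"]
    for g in sorted(locus.genes, key=lambda g: g.locus_start):
        start1, end1 = to_gff3_coords(g.locus_start, g.locus_end)
        attrs = [f"ID={g.gene_id}", f"genome={g.genome}"]
        if g.status is not None:
            attrs.append(f"status={g.status}")
        if g.defects:
            toks = ",".join(
                f"{d.kind}@{d.position}" + (":c_to_t" if d.c_to_t else "")
                for d in g.defects
            )
            attrs.append(f"defects={toks}")
        lines.append(
            "\t".join(
                [
                    seqid,
                    source,
                    "gene",
                    str(start1),
                    str(end1),
                    ".",
                    g.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path, cds_by_id: dict[str, NucleotideSeq] | None = None,
              genome: str = "other") -> LocusRecord:
    """Parse a GFF3 gene file back into a :class:`LocusRecord`.

    ``cds_by_id`` supplies the CDS sequences (GFF3 carries coordinates only);
    absent entries get a placeholder single-N sequence.
    """
    genes: list[GeneRecord] = []
    locus_genome = genome
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise Gff3FormatError(
                f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
            )
        _, _, ftype, c4, c5, _, strand, _, attr_field = cols
        if ftype != "gene":
            continue
        try:
            start, end = from_gff3_coords(int(c4), int(c5))
        except ValueError as exc:
            raise Gff3FormatError(f"{path}:{lineno}: bad coordinates") from exc
        attrs = dict(
            kv.split("=", 1) for kv in attr_field.split(";") if "=" in kv
        )
        gid = attrs.get("ID", f"gene_{lineno}")
        g_genome = attrs.get("genome", "other")
        defects = []
        for tok in filter(None, attrs.get("defects", "").split(",")):
            c_to_t = tok.endswith(":c_to_t")
            tok = tok.removesuffix(":c_to_t")
            kind, pos = tok.split("@")
            defects.append(DefectAnnotation(kind=kind, position=int(pos), c_to_t=c_to_t))
        cds = (cds_by_id or {}).get(gid) or NucleotideSeq(id=gid, seq="N")
        genes.append(
            GeneRecord(
                gene_id=gid,
                genome=g_genome,
                cds=cds,
                locus_start=start,
                locus_end=end,
                strand=strand,
                status=attrs.get("status"),
                defects=defects,
            )
        )
        locus_genome = g_genome if genome == "other" else genome
    return LocusRecord(genome=locus_genome, genes=genes)


# ---------------------------------------------------------------------------
# Translation


def translate(cds: NucleotideSeq, truncate_at_stop: bool = True) -> ProteinSeq:
    """Codon-by-codon translation under the standard genetic code.

    A trailing incomplete codon is dropped with a warning.  Codons containing
    'N' translate to 'X'.  With ``truncate_at_stop`` the product ends at the
    first stop (exclusive); otherwise internal stops are emitted as '*'.
    """
    n = len(cds.seq)
    if n < 3:
        raise GliaError(f"{cds.id}: CDS shorter than one codon")
    if n % 3:
        warnings.warn(
            f"{cds.id}: length {n} not a multiple of 3; trailing "
            f"{n % 3} nt dropped",
            stacklevel=2,
        )
    aas = []
    for i in range(0, n - n % 3, 3):
        codon = cds.seq[i : i + 3]
        if "N" in codon:
            aas.append("X")
        elif codon in STOP_CODONS:
            if truncate_at_stop:
                break
            aas.append("*")
        else:
            aas.append(_STANDARD_TABLE.forward_table[codon])
    return ProteinSeq(id=cds.id, seq="".join(aas), description=cds.description)


_PREFERRED_CODON = {}
for _codon, _aa in _STANDARD_TABLE.forward_table.items():
    # deterministic choice: lexicographically smallest codon per residue,
    # except glutamine where CAA is kept (it sorts first anyway)
    if _aa not in _PREFERRED_CODON or _codon < _PREFERRED_CODON[_aa]:
        _PREFERRED_CODON[_aa] = _codon


def back_translate(protein: ProteinSeq | str, stop: bool = False) -> NucleotideSeq:
    """Deterministic reverse translation (lexicographically smallest codon
    per residue); mainly used to build nucleotide fixtures from peptides."""
    seq = protein.seq if isinstance(protein, ProteinSeq) else protein
    pid = protein.id if isinstance(protein, ProteinSeq) else "back_translated"
    codons = [_PREFERRED_CODON[aa] for aa in seq]
    if stop:
        codons.append("TAA")
    return NucleotideSeq(id=pid, seq="".join(codons))
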