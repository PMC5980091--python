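"""Intact / pseudogene / fragment classification with mechanism attribution.

α-gliadin pseudogenes arise from four mechanisms: premature stop codons
(dominated by C→T transitions turning the glutamine codons CAA/CAG into
TAA/TAG), frameshift indels, transposable-element (TE) insertion, and
truncation.  Mechanism attribution for stops and frameshifts requires an
intact reference paralog; TE detection is library-based, with target-site
duplication (TSD) search and excise-and-rescan handling of nested elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .core_io import (
    DefectAnnotation,
    GeneRecord,
    GliaError,
    LocusRecord,
    NucleotideSeq,
    STOP_CODONS,
    translate,
)
from .phylo import global_align, indel_report

GLN_CODONS = frozenset({"CAA", "CAG"})
GLN_STOPS = {"CAA": "TAA", "CAG": "TAG"}


@dataclass
class ClassificationConfig:
    # intact length window ~ the 30-36 kDa range at ~110 Da/residue
    min_protein_len: int = 250
    max_protein_len: int = 400
    te_min_len: int = 100
    tsd_min: int = 4
    tsd_max: int = 12
    te_min_identity: float = 1.0        # 1.0 = exact; lower uses edit-distance search
    min_alignment_identity: float = 0.5
    fragment_fraction: float = 0.5      # below this fraction of reference => fragment

    def __post_init__(self) -> None:
        if self.min_protein_len >= self.max_protein_len:
            raise ValueError("min_protein_len must be < max_protein_len")
        if self.tsd_min > self.tsd_max:
            raise ValueError("tsd_min must be <= tsd_max")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassificationConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__))


DEFAULT_CONFIG = ClassificationConfig()


def detect_premature_stops(cds: NucleotideSeq) -> list[tuple[int, str]]:
    """In-frame stop codons strictly before the final codon, in order."""
    if len(cds.seq) < 6:
        raise GliaError(f"{cds.id}: CDS too short for stop scanning")
    n_codons = len(cds.seq) // 3
    out = []
    for k in range(n_codons - 1):
        codon = cds.seq[3 * k : 3 * k + 3]
        if codon in STOP_CODONS:
            out.append((k, codon))
    return out


def _aligned_reference_codon(aln, pseudo_offset: int) -> str:
    """Reference residues aligned to the pseudo codon at the given offset."""
    cols = []
    p = 0
    for col, ch in enumerate(aln.aligned_a):
        if ch != "-":
            if pseudo_offset <= p < pseudo_offset + 3:
                cols.append(col)
            p += 1
            if p > pseudo_offset + 3:
                break
    return "".join(
        aln.aligned_b[c] for c in cols if aln.aligned_b[c] != "-"
    )


def attribute_stop_mechanism(
    pseudo_cds: NucleotideSeq,
    reference_cds: NucleotideSeq,
    cfg: ClassificationConfig = DEFAULT_CONFIG,
) -> list[DefectAnnotation]:
    """Annotate each premature stop with the aligned reference codon; flag
    the canonical glutamine-codon transition CAA/CAG -> TAA/TAG as c_to_t."""
    aln = global_align(pseudo_cds, reference_cds)
    if aln.identity < cfg.min_alignment_identity:
        raise GliaError(
            f"{pseudo_cds.id} vs {reference_cds.id}: identity "
            f"{aln.identity:.2f} below {cfg.min_alignment_identity}"
        )
    defects = []
    for codon_idx, stop_codon in detect_premature_stops(pseudo_cds):
        ref_codon = _aligned_reference_codon(aln, 3 * codon_idx)
        c_to_t = ref_codon in GLN_CODONS and stop_codon in ("TAA", "TAG")
        defects.append(
            DefectAnnotation(
                kind="premature_stop",
                position=3 * codon_idx,
                detail=f"{ref_codon or '?'}→{stop_codon}",
                c_to_t=c_to_t,
            )
        )
    return defects


def detect_frameshift(
    pseudo_cds: NucleotideSeq,
    reference_cds: NucleotideSeq,
    cfg: ClassificationConfig = DEFAULT_CONFIG,
) -> list[DefectAnnotation]:
    """Alignment gaps of length not divisible by 3, reported at their CDS
    offset in the pseudogene; in-frame gaps are excluded."""
    aln = global_align(pseudo_cds, reference_cds)
    if aln.identity < cfg.min_alignment_identity:
        raise GliaError(
            f"{pseudo_cds.id} vs {reference_cds.id}: identity "
            f"{aln.identity:.2f} below {cfg.min_alignment_identity}"
        )
    defects = []
    for ev in indel_report(aln):
        if ev.in_frame:
            continue
        # CDS offset in pseudo = non-gap characters of row a before the column
        offset = sum(
            1 for ch in aln.aligned_a[: ev.position] if ch != "-"
        )
        polarity = "del" if ev.inserted_in == "b" else "ins"
        defects.append(
            DefectAnnotation(
                kind="frameshift_indel",
                position=offset,
                detail=f"{polarity}:{ev.length}nt",
            )
        )
    return defects


# ---------------------------------------------------------------------------
# TE insertions


def _find_te_match(seq: str, te_library, cfg: ClassificationConfig):
    """Leftmost full-length library-element match in ``seq``.

    Exact by default; with ``te_min_identity`` < 1 an edit-distance infix
    search (edlib) is used.  Returns (start, end, name) or None.
    """
    best = None
    for te in te_library:
        if len(te.seq) < cfg.te_min_len:
            continue
        if cfg.te_min_identity >= 1.0:
            s = seq.find(te.seq)
            if s < 0:
                continue
            cand = (s, s + len(te.seq), te.id)
        else:
            import edlib

            k = int(len(te.seq) * (1.0 - cfg.te_min_identity))
            res = edlib.align(te.seq, seq, mode="HW", task="locations", k=k)
            if res["editDistance"] < 0:
                continue
            s, e = res["locations"][0]
            cand = (s, e + 1, te.id)
        if best is None or (cand[0], -(cand[1] - cand[0])) < (
            best[0],
            -(best[1] - best[0]),
        ):
            best = cand
    return best


def _find_tsd(seq: str, s: int, e: int, cfg: ClassificationConfig) -> str:
    """Longest direct repeat flanking seq[s:e], length tsd_min..tsd_max."""
    for k in range(cfg.tsd_max, cfg.tsd_min - 1, -1):
        if s - k >= 0 and e + k <= len(seq) and seq[s - k : s] == seq[e : e + k]:
            return seq[s - k : s]
    return ""


def excise_te(
    region: NucleotideSeq,
    te_library: list[NucleotideSeq],
    cfg: ClassificationConfig = DEFAULT_CONFIG,
) -> tuple[NucleotideSeq, list[DefectAnnotation]]:
    """Iteratively excise library TEs (innermost matches first) and report
    each insertion with its TSD.  Positions are in TE-free coordinates.

    Nested structures resolve naturally: an outer element interrupted by an
    inner insertion only becomes matchable after the inner copy is excised;
    the inner event is then re-anchored to the outer insertion point and
    flagged ``nested``.
    """
    seq = region.seq
    events: list[DefectAnnotation] = []
    while True:
        hit = _find_te_match(seq, te_library, cfg)
        if hit is None:
            break
        s, e, name = hit
        tsd = _find_tsd(seq, s, e, cfg)
        span_end = e + len(tsd)  # drop one TSD copy to restore the target site
        removed = span_end - s
        for ev in events:
            if ev.position >= span_end:
                ev.position -= removed
            elif ev.position > s:
                ev.position = s
                if "nested" not in ev.detail:
                    ev.detail += ":nested"
        detail = f"{name}:len={e - s}"
        if tsd:
            detail += f":tsd={tsd}"
        events.append(DefectAnnotation(kind="te_insertion", position=s, detail=detail))
        seq = seq[:s] + seq[span_end:]
    clean = NucleotideSeq(id=region.id, seq=seq, description=region.description)
    return clean, events


def detect_te_insertion(
    region: NucleotideSeq,
    te_library: list[NucleotideSeq],
    cfg: ClassificationConfig = DEFAULT_CONFIG,
) -> list[DefectAnnotation]:
    if not te_library:
        return []
    return excise_te(region, te_library, cfg)[1]


# ---------------------------------------------------------------------------
# Gene classification


def classify_gene(
    gene: GeneRecord,
    reference: GeneRecord | None = None,
    te_library: list[NucleotideSeq] | None = None,
    cfg: ClassificationConfig = DEFAULT_CONFIG,
) -> GeneRecord:
    """Fill ``status`` and ``defects`` on a gene record.  Deterministic and
    idempotent: rerunning on the returned record yields the same result.

    Rules: intact requires an ATG start, a single terminal stop, a
    translated length inside the configured window and no defects; a CDS
    below ``fragment_fraction`` of the reference (or below the minimum
    length with no other defect) is a fragment; everything else is a
    pseudogene carrying all detected defects.
    """
    defects: list[DefectAnnotation] = []
    clean = gene.cds
    if te_library:
        clean, te_defects = excise_te(gene.cds, te_library, cfg)
        defects.extend(te_defects)

    if reference is not None:
        try:
            defects.extend(attribute_stop_mechanism(clean, reference.cds, cfg))
            defects.extend(detect_frameshift(clean, reference.cds, cfg))
        except GliaError:
            # unalignable pair: fall back to reference-free stop detection
            reference = None
    if reference is None and len(clean.seq) >= 6:
        if not any(d.kind == "premature_stop" for d in defects):
            for codon_idx, stop_codon in detect_premature_stops(clean):
                defects.append(
                    DefectAnnotation(
                        kind="premature_stop",
                        position=3 * codon_idx,
                        detail=f"?→{stop_codon}",
                    )
                )

    import warnings

    with warnings.catch_warnings():
        # fragments legitimately end mid-codon; the trailing-codon warning
        # is meant for users translating presumed-complete CDSs
        warnings.simplefilter("ignore", UserWarning)
        prot = translate(clean, truncate_at_stop=True) if len(clean.seq) >= 3 else None
    prot_len = len(prot.seq) if prot else 0

    mechanism_kinds = {d.kind for d in defects}
    note = ""

    if reference is not None and len(clean.seq) < cfg.fragment_fraction * len(
        reference.cds.seq
    ):
        status = "fragment"
        defects.append(
            DefectAnnotation(
                kind="truncation",
                position=len(clean.seq),
                detail="partial coding region",
            )
        )
    elif prot_len < cfg.min_protein_len and not mechanism_kinds:
        status = "fragment"
        defects.append(
            DefectAnnotation(
                kind="truncation", position=len(clean.seq), detail="short coding region"
            )
        )
    else:
        if not clean.seq.startswith("ATG"):
            defects.append(
                DefectAnnotation(kind="truncation", position=0, detail="no_start")
            )
        if len(clean.seq) % 3 == 0 and clean.seq[-3:] not in STOP_CODONS:
            defects.append(
                DefectAnnotation(
                    kind="truncation",
                    position=len(clean.seq),
                    detail="no_terminal_stop",
                )
            )
        if prot is not None and "X" in prot.seq:
            defects.append(
                DefectAnnotation(
                    kind="truncation", position=0, detail="ambiguous_residues"
                )
            )
        if not defects and prot_len > cfg.max_protein_len:
            defects.append(
                DefectAnnotation(
                    kind="truncation", position=0, detail="length_out_of_range"
                )
            )
        status = "intact" if not defects else "pseudogene"
        if {"te_insertion", "premature_stop", "frameshift_indel"} <= {
            d.kind for d in defects
        }:
            note = "mechanism order undeterminable"

    return GeneRecord(
        gene_id=gene.gene_id,
        genome=gene.genome,
        cds=gene.cds,
        locus_start=gene.locus_start,
        locus_end=gene.locus_end,
        strand=gene.strand,
        status=status,
        defects=defects if status != "intact" else [],
        note=note,
    )


def pick_reference(
    gene: GeneRecord, candidates: list[GeneRecord]
) -> GeneRecord | None:
    """Closest intact paralog by alignment identity; ties broken by the
    lexicographically smallest gene_id."""
    intact = [c for c in candidates if c.status == "intact" and c.gene_id != gene.gene_id]
    best: tuple[float, str] | None = None
    best_gene = None
    for c in sorted(intact, key=lambda g: g.gene_id):
        ident = global_align(gene.cds, c.cds).identity
        key = (-ident, c.gene_id)
        if best is None or key < best:
            best = key
            best_gene = c
    return best_gene


def classify_loci(
    loci: list[LocusRecord],
    te_library: list[NucleotideSeq] | None = None,
    reference: GeneRecord | None = None,
    cfg: ClassificationConfig = DEFAULT_CONFIG,
) -> list[LocusRecord]:
    """Classify every gene across one or more loci.

    Without an explicit reference, a first reference-free pass identifies
    intact genes; each remaining gene is then attributed against its
    closest intact paralog, drawn from the pooled intact genes of all loci
    (old shared gene copies find their true homolog on another genome).
    """
    firsts = [
        [classify_gene(g, None, te_library, cfg) for g in locus.genes]
        for locus in loci
    ]
    if reference is None:
        intact = [g for first in firsts for g in first if g.status == "intact"]
    else:
        intact = [reference]
    out_loci = []
    for locus, first in zip(loci, firsts):
        out = []
        for orig, pre in zip(locus.genes, first):
            if pre.status == "intact" or not intact:
                out.append(pre)
                continue
            ref = reference or pick_reference(pre, intact)
            out.append(classify_gene(orig, ref, te_library, cfg))
        out_loci.append(
            LocusRecord(genome=locus.genome, genes=out, sequence=locus.sequence)
        )
    return out_loci


def classify_locus(
    locus: LocusRecord,
    te_library: list[NucleotideSeq] | None = None,
    reference: GeneRecord | None = None,
    cfg: ClassificationConfig = DEFAULT_CONFIG,
) -> LocusRecord:
    """Single-locus convenience wrapper around :func:`classify_loci`."""
    return classify_loci([locus], te_library, reference, cfg)[0]


# ---------------------------------------------------------------------------
# Summaries


@dataclass
class LocusSummary:
    n_genes: int
    n_intact: int
    n_pseudo: int
    n_fragment: int
    mechanism_counts: dict[str, int] = field(default_factory=dict)
    per_genome: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_genes != self.n_intact + self.n_pseudo + self.n_fragment:
            raise ValueError("status counts do not reconcile with n_genes")

    @property
    def pct_pseudo(self) -> int:
        return round(100 * self.n_pseudo / self.n_genes) if self.n_genes else 0

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "n_intact": self.n_intact,
            "n_pseudo": self.n_pseudo,
            "n_fragment": self.n_fragment,
            "pct_pseudo": self.pct_pseudo,
            "mechanism_counts": dict(self.mechanism_counts),
            "per_genome": dict(self.per_genome),
        }


def summarize_locus(loci: LocusRecord | list[LocusRecord]) -> LocusSummary:
    """Counts and integer percentages per status, mechanism and genome.
    Mechanism counts tally pseudogenes carrying each defect kind, so their
    sum may exceed the pseudogene count (a pseudogene can carry several)."""
    if isinstance(loci, LocusRecord):
        loci = [loci]
    genes = [g for l in loci for g in l.genes]
    unclassified = [g.gene_id for g in genes if g.status is None]
    if unclassified:
        raise GliaError(f"unclassified genes present: {unclassified}")
    mech: dict[str, int] = {}
    per_genome: dict[str, dict] = {}
    n_intact = n_pseudo = n_fragment = 0
    for g in genes:
        slot = per_genome.setdefault(
            g.genome, {"n": 0, "intact": 0, "pseudogene": 0, "fragment": 0}
        )
        slot["n"] += 1
        slot[g.status] += 1
        if g.status == "intact":
            n_intact += 1
        elif g.status == "pseudogene":
            n_pseudo += 1
            for kind in {d.kind for d in g.defects}:
                mech[kind] = mech.get(kind, 0) + 1
        else:
            n_fragment += 1
    for slot in per_genome.values():
        slot["pct_pseudo"] = round(100 * slot["pseudogene"] / slot["n"])
    return LocusSummary(
        n_genes=len(genes),
        n_intact=n_intact,
        n_pseudo=n_pseudo,
        n_fragment=n_fragment,
        mechanism_counts=mech,
        per_genome=per_genome,
    )


def classification_report(loci: LocusRecord | list[LocusRecord]) -> pd.DataFrame:
    """Per-gene TSV-ready report: status, defect kinds, positions, c_to_t."""
    if isinstance(loci, LocusRecord):
        loci = [loci]
    rows = []
    for l in loci:
        for g in l.genes:
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "genome": g.genome,
                    "status": g.status,
                    "defect_kinds": ",".join(d.kind for d in g.defects),
                    "defect_positions": ",".join(str(d.position) for d in g.defects),
                    "c_to_t": ",".join(
                        str(d.c_to_t) for d in g.defects if d.kind == "premature_stop"
                    ),
                    "note": g.note,
                }
            )
    return pd.DataFrame(rows)
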