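"""Celiac-disease epitope scanning for α-gliadin proteins.

Counting is overlap-aware: every start position is tested, so the 33-mer
peptide — which tiles three PQPQLPY repeats — yields one DQ2.5-glia-α1a,
two DQ2.5-glia-α1b and three DQ2.5-glia-α2 hits.  Non-overlapping
(regex-style) matching would undercount and is deliberately not used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .core_io import ProteinSeq

#: The proteolysis-resistant 33-residue toxic peptide:
#: LQLQPF + (PQPQLPY x 3) + PQPQPF.
THIRTY_THREE_MER = "LQLQPFPQPQLPYPQPQLPYPQPQLPYPQPQPF"

#: CSTT, a motif near the C-terminus of α-gliadins that lack DQ2.5 epitopes.
CSTT_MOTIF = "CSTT"


@dataclass
class EpitopeCatalog:
    """Named epitope peptides plus the immunodominant subset."""

    entries: dict[str, str]
    immunodominant: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name, pep in self.entries.items():
            if not pep:
                raise ValueError(f"empty peptide for epitope {name}")
            self.entries[name] = pep.upper()
        unknown = self.immunodominant - set(self.entries)
        if unknown:
            raise ValueError(f"immunodominant names not in catalog: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EpitopeCatalog":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            entries=dict(data["entries"]),
            immunodominant=set(data.get("immunodominant", [])),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "entries": dict(self.entries),
                    "immunodominant": sorted(self.immunodominant),
                },
                allow_unicode=True,
            )
        )


#: The major DQ2.5/DQ8-restricted α-gliadin T-cell epitopes.  DQ8-glia-α1 and
#: DQ8.5-glia-α1 share one peptide and are reported as a single column.
DEFAULT_CATALOG = EpitopeCatalog(
    entries={
        "DQ2.5-glia-a1a": "PFPQPQLPY",
        "DQ2.5-glia-a1b": "PYPQPQLPY",
        "DQ2.5-glia-a2": "PQPQLPYPQ",
        "DQ2.5-glia-a3": "FRPQQPYPQ",
        "DQ8-glia-a1": "QGSFQPSQQ",
    },
    immunodominant={"DQ2.5-glia-a1a", "DQ2.5-glia-a2"},
)

DQ8_NAMES = frozenset({"DQ8-glia-a1"})


@dataclass
class EpitopeProfile:
    gene_id: str
    counts: dict[str, int]
    has_33mer: bool
    has_cstt: bool

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def count_overlapping(seq: str, motif: str) -> int:
    """Occurrences of ``motif`` in ``seq`` counting overlaps."""
    m = len(motif)
    return sum(1 for i in range(len(seq) - m + 1) if seq[i : i + m] == motif)


def detect_33mer(protein: ProteinSeq, max_mismatch: int = 0) -> list[int]:
    """All start positions where the 33-mer matches with at most
    ``max_mismatch`` substitutions (Hamming scan)."""
    hits = []
    seq, pep = protein.seq, THIRTY_THREE_MER
    for i in range(len(seq) - len(pep) + 1):
        mism = 0
        for a, b in zip(seq[i : i + len(pep)], pep):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            hits.append(i)
    return hits


def detect_cstt(protein: ProteinSeq, window: int = 15) -> bool:
    """True iff CSTT occurs within the final ``window`` residues."""
    return CSTT_MOTIF in protein.seq[-window:]


def scan_epitopes(
    protein: ProteinSeq, catalog: EpitopeCatalog | None = None
) -> EpitopeProfile:
    """Overlap-aware epitope counts plus 33-mer and CSTT flags."""
    catalog = catalog or DEFAULT_CATALOG
    counts = {
        name: count_overlapping(protein.seq, pep)
        for name, pep in catalog.entries.items()
    }
    return EpitopeProfile(
        gene_id=protein.id,
        counts=counts,
        has_33mer=bool(detect_33mer(protein)),
        has_cstt=detect_cstt(protein),
    )


def epitope_table(
    proteins: list[ProteinSeq],
    catalog: EpitopeCatalog | None = None,
    genome_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One row per protein: per-epitope counts, 33-mer and CSTT flags, total.

    With ``genome_of`` a ``genome`` column is added so per-genome summaries
    can be grouped downstream.
    """
    catalog = catalog or DEFAULT_CATALOG
    rows = []
    for p in proteins:
        prof = scan_epitopes(p, catalog)
        row = {"gene_id": p.id, **prof.counts,
               "has_33mer": prof.has_33mer, "has_cstt": prof.has_cstt,
               "total": prof.total}
        if genome_of:
            row["genome"] = genome_of.get(p.id, "other")
        rows.append(row)
    return pd.DataFrame(rows)


def epitope_bearing_fraction(table: pd.DataFrame) -> float:
    """Percentage of proteins carrying at least one epitope, one decimal."""
    return round(100.0 * (table["total"] > 0).mean(), 1)


def cstt_consistency_check(
    table: pd.DataFrame, catalog: EpitopeCatalog | None = None
) -> list[str]:
    """Proteins that carry CSTT together with any non-DQ8 epitope.

    An empty list reproduces the published observation that CSTT occurs only
    in proteins lacking DQ2.5 epitopes.
    """
    catalog = catalog or DEFAULT_CATALOG
    non_dq8 = [n for n in catalog.entries if n not in DQ8_NAMES]
    mask = table["has_cstt"] & (table[non_dq8].sum(axis=1) > 0)
    return table.loc[mask, "gene_id"].tolist()
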