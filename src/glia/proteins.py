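"""α-gliadin protein architecture: domain segmentation, polyQ counting,
CSTT, and predicted molecular weight / isoelectric point.

The canonical architecture is
``signal peptide | repetitive domain | polyQ I | unique I | polyQ II | unique II``.
PolyQ tracts are delimited by a seed-and-merge rule (runs of >=4 Q seeded,
seeds separated by <=2 non-Q residues merged, tract trimmed to start/end
on Q), which permits the interrupted tracts seen in real α-gliadins; the
rule's thresholds live in :class:`SegmentationConfig` so alternatives can
be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.SeqUtils import molecular_weight as _bp_molecular_weight

from .core_io import GliaError, ProteinSeq
from .epitopes import detect_cstt

WATER_MW = 18.0153  # average mass of one water, Da


class NonCanonicalArchitectureError(GliaError):
    """Raised when a protein lacks the two qualifying polyQ tracts."""


@dataclass(frozen=True)
class SegmentationConfig:
    signal_len: int = 20          # residues; α-gliadin signal peptides are conserved
    seed_min_q: int = 4           # minimum Q-run to seed a tract
    merge_gap: int = 2            # max non-Q residues bridged when merging runs
    merge_min_run: int = 2        # shortest Q-run absorbed into a tract; single
                                  # glutamines belong to the repeat vocabulary
    polyq1_min_q: int = 8         # qualifying Q count for polyQ I
    polyq2_min_q: int = 5         # qualifying Q count for polyQ II


DEFAULT_SEGMENTATION = SegmentationConfig()


@dataclass
class DomainSegmentation:
    """Half-open residue intervals tiling the protein, plus tract Q counts
    (number of Q residues in the tract, not tract length)."""

    signal_peptide: tuple[int, int]
    repetitive: tuple[int, int]
    polyQ_I: tuple[int, int]
    unique_I: tuple[int, int]
    polyQ_II: tuple[int, int]
    unique_II: tuple[int, int]
    q_count_I: int
    q_count_II: int

    def intervals(self) -> list[tuple[int, int]]:
        return [
            self.signal_peptide,
            self.repetitive,
            self.polyQ_I,
            self.unique_I,
            self.polyQ_II,
            self.unique_II,
        ]


def _find_tracts(seq: str, cfg: SegmentationConfig) -> list[tuple[int, int]]:
    """Q-tract intervals after seeding, merging and trimming.

    Maximal Q-runs of length >= ``merge_min_run`` are clustered whenever
    separated by <= ``merge_gap`` non-Q residues; a cluster is a tract iff
    it contains at least one seed run (>= ``seed_min_q``).  Clusters start
    and end on Q by construction, so trimming is implicit.
    """
    import re

    runs = [(m.start(), m.end()) for m in re.finditer(r"Q+", seq)]
    material = [r for r in runs if r[1] - r[0] >= cfg.merge_min_run]
    clusters: list[list[int]] = []
    for s, e in material:
        if clusters and s - clusters[-1][1] <= cfg.merge_gap:
            clusters[-1][1] = e
        else:
            clusters.append([s, e])
    return [
        (a, b)
        for a, b in clusters
        if any(a <= s and e <= b and e - s >= cfg.seed_min_q for s, e in runs)
    ]


def segment_domains(
    protein: ProteinSeq, cfg: SegmentationConfig = DEFAULT_SEGMENTATION
) -> DomainSegmentation:
    """Segment an intact α-gliadin-like protein into its six domains."""
    seq = protein.seq.rstrip("*")
    if len(seq) <= cfg.signal_len:
        raise NonCanonicalArchitectureError(
            f"{protein.id}: shorter than the signal peptide"
        )
    tracts = _find_tracts(seq, cfg)

    def q_count(t: tuple[int, int]) -> int:
        return seq[t[0] : t[1]].count("Q")

    after_signal = [t for t in tracts if t[0] >= cfg.signal_len]
    tract1 = next((t for t in after_signal if q_count(t) >= cfg.polyq1_min_q), None)
    tract2 = None
    if tract1 is not None:
        tract2 = next(
            (t for t in after_signal if t[0] >= tract1[1] and q_count(t) >= cfg.polyq2_min_q),
            None,
        )
    if tract1 is None or tract2 is None:
        raise NonCanonicalArchitectureError(
            f"{protein.id}: non-canonical architecture (fewer than two "
            f"qualifying polyQ tracts)"
        )
    return DomainSegmentation(
        signal_peptide=(0, cfg.signal_len),
        repetitive=(cfg.signal_len, tract1[0]),
        polyQ_I=tract1,
        unique_I=(tract1[1], tract2[0]),
        polyQ_II=tract2,
        unique_II=(tract2[1], len(seq)),
        q_count_I=q_count(tract1),
        q_count_II=q_count(tract2),
    )


def round_half_up(x: float) -> int:
    import math

    return math.floor(x + 0.5)


def count_polyq_table(
    proteins: list[ProteinSeq],
    genome_of: dict[str, str],
    cfg: SegmentationConfig = DEFAULT_SEGMENTATION,
) -> pd.DataFrame:
    """Per-genome polyQ statistics: half-up-rounded integer mean, min and max
    of the Q counts in both tracts.  Empty genome groups are omitted."""
    rows = []
    for p in proteins:
        seg = segment_domains(p, cfg)
        rows.append(
            {
                "gene_id": p.id,
                "genome": genome_of.get(p.id, "other"),
                "q_count_I": seg.q_count_I,
                "q_count_II": seg.q_count_II,
            }
        )
    df = pd.DataFrame(rows)
    return polyq_stats_from_counts(df)


def polyq_stats_from_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Genome-wise summary from a table with genome/q_count_I/q_count_II."""
    out = []
    for genome, grp in df.groupby("genome"):
        out.append(
            {
                "genome": genome,
                "n": len(grp),
                "q1_mean": round_half_up(grp["q_count_I"].mean()),
                "q1_min": int(grp["q_count_I"].min()),
                "q1_max": int(grp["q_count_I"].max()),
                "q2_mean": round_half_up(grp["q_count_II"].mean()),
                "q2_min": int(grp["q_count_II"].min()),
                "q2_max": int(grp["q_count_II"].max()),
            }
        )
    return pd.DataFrame(out).set_index("genome")


# ---------------------------------------------------------------------------
# Physicochemical prediction


@dataclass(frozen=True)
class PkaSet:
    """Fixed pKa values used by the Henderson–Hasselbalch charge model."""

    n_term: float = 8.6
    c_term: float = 3.6
    side_chains_acidic: tuple = (("C", 8.5), ("D", 3.9), ("E", 4.1), ("Y", 10.1))
    side_chains_basic: tuple = (("H", 6.5), ("K", 10.8), ("R", 12.5))


DEFAULT_PKA = PkaSet()


@dataclass
class PhyschemResult:
    mw: float
    pi: float
    includes_signal_peptide: bool

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("MW must be positive")
        if not 0 < self.pi < 14:
            raise ValueError("pI must lie in (0, 14)")


def compute_mw(
    protein: ProteinSeq,
    include_signal: bool = True,
    cfg: SegmentationConfig = DEFAULT_SEGMENTATION,
) -> float:
    """Average-isotope molecular weight in Da (residue masses + one water)."""
    seq = protein.seq.rstrip("*")
    if not include_signal:
        seq = seq[cfg.signal_len :]
    bad = set(seq) - set("ACDEFGHIKLMNPQRSTVWY")
    if bad:
        raise GliaError(f"{protein.id}: nonstandard residues {sorted(bad)}")
    return float(_bp_molecular_weight(seq, seq_type="protein", monoisotopic=False))


def net_charge(seq: str, ph: float, pka: PkaSet = DEFAULT_PKA) -> float:
    """Henderson–Hasselbalch net charge at a given pH."""

    def pos(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pk))

    def neg(pk: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pk - ph))

    charge = pos(pka.n_term) + neg(pka.c_term)
    for aa, pk in pka.side_chains_basic:
        charge += seq.count(aa) * pos(pk)
    for aa, pk in pka.side_chains_acidic:
        charge += seq.count(aa) * neg(pk)
    return charge


def compute_pi(
    protein: ProteinSeq, pka: PkaSet = DEFAULT_PKA, tol: float = 1e-4
) -> float:
    """Isoelectric point by bisection on [0, 14].

    Net charge is strictly decreasing in pH, so the root is unique.
    """
    seq = protein.seq.rstrip("*")
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(seq, mid, pka)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def physchem(
    protein: ProteinSeq,
    include_signal: bool = True,
    cfg: SegmentationConfig = DEFAULT_SEGMENTATION,
    pka: PkaSet = DEFAULT_PKA,
) -> PhyschemResult:
    return PhyschemResult(
        mw=compute_mw(protein, include_signal=include_signal, cfg=cfg),
        pi=compute_pi(protein, pka=pka),
        includes_signal_peptide=include_signal,
    )


def protein_report(
    proteins: list[ProteinSeq],
    genome_of: dict[str, str] | None = None,
    cfg: SegmentationConfig = DEFAULT_SEGMENTATION,
) -> pd.DataFrame:
    """Per-protein characteristics table: MW, pI, polyQ counts, CSTT flag."""
    rows = []
    for p in proteins:
        row: dict = {"gene_id": p.id}
        if genome_of:
            row["genome"] = genome_of.get(p.id, "other")
        row["mw"] = round(compute_mw(p), 1)
        row["pi"] = round(compute_pi(p), 2)
        try:
            seg = segment_domains(p, cfg)
            row["q_count_I"] = seg.q_count_I
            row["q_count_II"] = seg.q_count_II
        except NonCanonicalArchitectureError:
            row["q_count_I"] = row["q_count_II"] = pd.NA
        row["has_cstt"] = detect_cstt(p)
        rows.append(row)
    return pd.DataFrame(rows)
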