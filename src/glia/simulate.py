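"""Synthetic α-gliadin locus generator with fully tracked ground truth.

The generator emulates the statistical structure of the real gene family:
tandemly duplicated ~900-bp intron-less CDSs (signal peptide, repetitive
domain built from epitope-bearing and epitope-free repeat units, two
polyglutamine tracts interleaved with two unique domains), ~45%
pseudogenization dominated by C→T stop-gains at glutamine codons, TE
insertions flanked by short direct repeats, in-frame 21-nt indels in the
repetitive region (the 33-mer origin scenario), and log-scale expression
divergence with pseudogenes strongly down-weighted.

Every planted event is recorded in a :class:`SyntheticTruth` ledger so that
each pipeline stage can be tested for exact recovery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_io import GeneRecord, GliaError, LocusRecord, NucleotideSeq, STOP_CODONS
from .expression import CountTable

_CODONS: dict[str, list[str]] = {}
from .core_io import _STANDARD_TABLE  # noqa: E402

for _codon, _aa in _STANDARD_TABLE.forward_table.items():
    _CODONS.setdefault(_aa, []).append(_codon)
for _aa in _CODONS:
    _CODONS[_aa].sort()

GLN_CODONS = ("CAA", "CAG")

#: Signal peptide used by every synthetic gene (20 hydrophobic-core residues).
SIGNAL_PEPTIDE = "MKTFLILALLAIVATTATTA"

#: Repeat-unit vocabulary for the repetitive domain.  Epitope units are the
#: canonical CD epitopes; filler units are scrambled epitope-free variants
#: chosen to contain no glutamine run of 4 (so they never seed a polyQ tract).
EPITOPE_UNITS = {
    "a1a": "PFPQPQLPY",
    "a3": "FRPQQPYPQ",
}
#: 33-mer context lacking one internal PQPQLPY repeat (26 residues); a single
#: in-frame 21-nt insertion of one more repeat unit turns it into the 33-mer.
CONTEXT_26MER = "LQLQPFPQPQLPYPQPQLPYPQPQPF"
REPEAT_UNIT_7 = "PQPQLPY"
FILLER_UNITS = ("QPQNPSQPY", "LPYSQPQPF", "QPFPLQPYS", "NPSQQPFPY")
# invented low-charge unique domains, balanced so that full preproteins land
# in the 30-36 kDa / pI 6-8 window typical of the family
UNIQUE_I = (
    "NIQVDPSGEVIESLVLRTLPNMCNVYIPPYSNAPSLTIASGIFGTNDEVMSQLALETLP"
)
UNIQUE_II_CORE = "VLGIGGTNHAVDLEIRNAVEMLESSNIALGSLVHLMARN"
CSTT_TAIL = "QQCSTTIAPFGIFGTN"   # CSTT lands inside the final 15 residues
PLAIN_TAIL = "QQYPSSIAPFGIFGTN"

MECHANISMS = ("c_to_t_stop", "frameshift", "te_insertion", "truncation")


@dataclass
class SimulationConfig:
    seed: int = 0
    # gene counts per genome; the B locus carries the most copies
    n_genes: dict = field(default_factory=lambda: {"A": 9, "B": 25, "D": 10})
    n_shared_ancestral: int = 1        # genes shared across genomes (old copies)
    substitution_rate: float = 0.02    # per-site fraction per duplication
    genome_divergence: float = 0.04    # divergence of each genome's ancestor
    shared_divergence: float = 0.005   # divergence of the shared ancestral copies
    p_pseudogenization: float = 0.45
    mechanism_mix: dict = field(
        default_factory=lambda: {
            # 13 substitution : 1 frameshift : 3 TE : 4 truncation of 21
            "c_to_t_stop": 13 / 21,
            "frameshift": 1 / 21,
            "te_insertion": 3 / 21,
            "truncation": 4 / 21,
        }
    )
    compound_fraction: float = 0.0     # pseudogenes planted with TE+stop+frameshift
    polyq1_range: tuple = (11, 36)
    polyq2_range: tuple = (6, 45)
    # combined tract budget: the family's observed q1+q2 extremes; draws
    # outside are resampled so copies never stack both per-tract maxima
    q_total_range: tuple = (18, 64)
    p_dq8: dict = field(default_factory=lambda: {"A": 0.3, "B": 0.2, "D": 0.8})
    # intergenic spacer means (nt), 1/10 of the real locus scale
    spacer_mean: dict = field(default_factory=lambda: {"A": 7000, "B": 1000, "D": 4000})
    spacer_scale: float = 1.0
    p_spacer_te: float = 0.3
    tsd_len: int = 8
    p_21nt_indel: float = 0.0          # extra in-frame repeat-unit indels
    plant_33mer: bool = True           # one D-genome gene gains the 33-mer
    p_cstt: dict = field(default_factory=lambda: {"A": 0.25, "B": 1.0, "D": 0.35})
    te_library: list | None = None
    # expression model (natural-log scale)
    expr_log_mean: float = 4.0
    expr_log_sd: float = 1.0
    pseudogene_penalty: float = 0.01
    read_len: int = 100
    read_error_rate: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.mechanism_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("mechanism mix must sum to 1")
        if not 0 <= self.p_pseudogenization <= 1:
            raise ValueError("p_pseudogenization must lie in [0,1]")
        for r in (self.polyq1_range, self.polyq2_range):
            if r[0] >= r[1]:
                raise ValueError("polyQ ranges must be non-degenerate")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("polyq1_range", "polyq2_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["polyq1_range"] = list(self.polyq1_range)
        data["polyq2_range"] = list(self.polyq2_range)
        Path(path).write_text(yaml.safe_dump(data))


def default_te_library(seed: int = 1) -> list[NucleotideSeq]:
    """Four deterministic random elements named after the TE families that
    populate real Gli-2 intergenic regions."""
    rng = np.random.default_rng(seed)
    lib = []
    for name, length in (("Manor", 400), ("Ada", 550), ("Sabrina", 700), ("Hawi", 300)):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        lib.append(NucleotideSeq(id=name, seq=seq))
    return lib


# ---------------------------------------------------------------------------
# Truth ledger


@dataclass
class GeneTruth:
    gene_id: str
    genome: str
    status: str                        # intact | pseudogene | fragment
    mechanisms: list[str] = field(default_factory=list)
    defect_positions: list[int] = field(default_factory=list)
    epitope_counts: dict = field(default_factory=dict)
    has_33mer: bool = False
    has_cstt: bool = False
    q_count_I: int | None = None
    q_count_II: int | None = None
    parent: str | None = None
    expression: float | None = None


@dataclass
class SyntheticTruth:
    genes: dict[str, GeneTruth] = field(default_factory=dict)
    duplication_history: dict[str, str | None] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.genes.values():
            rows.append(
                {
                    "gene_id": t.gene_id,
                    "genome": t.genome,
                    "status": t.status,
                    "mechanisms": ",".join(t.mechanisms),
                    "defect_positions": ",".join(map(str, t.defect_positions)),
                    "has_33mer": t.has_33mer,
                    "has_cstt": t.has_cstt,
                    "q_count_I": t.q_count_I,
                    "q_count_II": t.q_count_II,
                    "parent": t.parent,
                    "expression": t.expression,
                    **{f"n_{k}": v for k, v in t.epitope_counts.items()},
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {gid: dataclasses.asdict(t) for gid, t in self.genes.items()},
                indent=1,
                default=str,
            )
        )


@dataclass
class SimulatedLoci:
    loci: dict[str, LocusRecord]
    truth: SyntheticTruth
    te_library: list[NucleotideSeq]

    def all_genes(self) -> list[GeneRecord]:
        return [g for l in self.loci.values() for g in l.genes]


# ---------------------------------------------------------------------------
# Building blocks

_EPITOPE_PEPS = {
    "a1a": "PFPQPQLPY",
    "a1b": "PYPQPQLPY",
    "a2": "PQPQLPYPQ",
    "a3": "FRPQQPYPQ",
    "dq8": "QGSFQPSQQ",
}


def _count(seq: str, pep: str) -> int:
    return sum(1 for i in range(len(seq) - len(pep) + 1) if seq[i : i + len(pep)] == pep)


def _encode(protein: str, rng: np.random.Generator) -> str:
    """Random synonymous codon choice per residue."""
    return "".join(
        _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein
    )


@dataclass
class _CleanGene:
    """Pre-pseudogenization state of a lineage copy (always a valid ORF)."""

    seq: str
    tract1: tuple[int, int]   # nt interval of polyQ I within the CDS
    tract2: tuple[int, int]


#: fillers per genome, chosen so every genome's repetitive domain is ~99
#: residues regardless of its epitope-unit content (B has no DQ2.5 units)
_N_FILLER = {"A": 9, "B": 11, "D": 6}


def _draw_q(rng: np.random.Generator, cfg) -> tuple[int, int]:
    """Joint polyQ draw: per-tract uniform, resampled to the total budget."""
    for _ in range(200):
        q1 = int(rng.integers(cfg.polyq1_range[0], cfg.polyq1_range[1] + 1))
        q2 = int(rng.integers(cfg.polyq2_range[0], cfg.polyq2_range[1] + 1))
        if cfg.q_total_range[0] <= q1 + q2 <= cfg.q_total_range[1]:
            return q1, q2
    return cfg.polyq1_range[0], cfg.polyq2_range[0]


def _build_ancestral_protein(genome: str, rng: np.random.Generator, cfg) -> tuple[str, str]:
    """(repetitive-domain string, dq8 unit) for one genome's ancestor."""
    units: list[str] = []
    if genome == "D":
        units.append(CONTEXT_26MER)
    if genome in ("A", "D"):
        units.append(EPITOPE_UNITS["a1a"])
        units.append(EPITOPE_UNITS["a3"])
    for _ in range(_N_FILLER[genome]):
        units.append(FILLER_UNITS[rng.integers(len(FILLER_UNITS))])
    order = rng.permutation(len(units))
    if genome == "D":
        # keep the 33-mer context first so its position is stable
        order = [0] + [int(i) for i in order if i != 0]
    rep = "".join(units[int(i)] for i in order)
    if rng.random() < cfg.p_dq8.get(genome, 0.3):
        dq8 = "QGSFQPSQQ"
    else:
        # length-compensating filler keeps the preprotein size stable
        dq8 = ""
        rep += FILLER_UNITS[rng.integers(len(FILLER_UNITS))]
    return rep, dq8


def build_ancestral_gene(
    cfg: SimulationConfig, genome: str = "A", rng: np.random.Generator | None = None
) -> tuple[NucleotideSeq, _CleanGene]:
    """Assemble the ancestral CDS for one genome and return it together with
    the polyQ tract coordinates (the seed of the truth ledger)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    rep, dq8 = _build_ancestral_protein(genome, rng, cfg)
    q1, q2 = _draw_q(rng, cfg)
    tail = CSTT_TAIL if rng.random() < cfg.p_cstt.get(genome, 0.3) else PLAIN_TAIL
    parts = [
        SIGNAL_PEPTIDE,
        rep + "VPL",  # junction: the repetitive domain never abuts the tract on a Q
        "Q" * q1,
        UNIQUE_I,
        "Q" * q2,
        UNIQUE_II_CORE + dq8 + tail,
    ]
    protein = "".join(parts)
    offs = np.cumsum([0] + [len(p) for p in parts])
    # tracts are encoded as homogeneous CAA runs: the codon mix inside a
    # microsatellite carries no signal for any downstream analysis, and a
    # uniform tract guarantees that tract-length differences between copies
    # align as one contiguous in-frame gap
    t1 = (int(offs[2]) * 3, int(offs[3]) * 3)
    t2 = (int(offs[4]) * 3, int(offs[5]) * 3)
    cds = _encode(protein, rng) + "TAA"
    cds = cds[: t1[0]] + "CAA" * q1 + cds[t1[1] :]
    cds = cds[: t2[0]] + "CAA" * q2 + cds[t2[1] :]
    clean = _CleanGene(seq=cds, tract1=t1, tract2=t2)
    return NucleotideSeq(id=f"ancestral_{genome}", seq=cds), clean


def _orf_ok(seq: str) -> bool:
    if len(seq) % 3 or not seq.startswith("ATG") or seq[-3:] not in STOP_CODONS:
        return False
    return not any(
        seq[i : i + 3] in STOP_CODONS for i in range(0, len(seq) - 3, 3)
    )


def _mutate_safe(
    state: _CleanGene,
    rate: float,
    rng: np.random.Generator,
    tries: int = 60,
    protect: tuple[int, int] | None = None,
) -> _CleanGene:
    """Point substitutions at the given per-site rate, excluding the polyQ
    tracts, the first/last codon, and an optional protected interval,
    redrawn until the ORF stays valid.

    Tract positions are exempt so planted polyQ counts remain exact truth;
    tract-length variation is modeled by the per-copy resize instead.
    """
    seq = state.seq
    n_sub = rng.binomial(len(seq), rate)
    # tracts are shielded with a one-codon margin: a substitution directly
    # adjacent to a tract could create a glutamine that extends the run
    eligible = [
        i
        for i in range(3, len(seq) - 3)
        if not (state.tract1[0] - 3 <= i < state.tract1[1] + 3)
        and not (state.tract2[0] - 3 <= i < state.tract2[1] + 3)
        and not (protect and protect[0] <= i < protect[1])
    ]
    for _ in range(tries):
        pos = rng.choice(len(eligible), size=min(n_sub, len(eligible)), replace=False)
        chars = list(seq)
        for p in pos:
            i = eligible[int(p)]
            alt = [b for b in "ACGT" if b != chars[i]]
            chars[i] = alt[rng.integers(3)]
        cand = "".join(chars)
        if _orf_ok(cand):
            return _CleanGene(seq=cand, tract1=state.tract1, tract2=state.tract2)
    return state  # give up mutating rather than emit a broken ORF


def _resize_tract(state: _CleanGene, which: int, target_q: int,
                  rng: np.random.Generator) -> _CleanGene:
    """In-frame insertion/deletion of glutamine codons at the tract centre so
    each copy draws its own polyQ length (microsatellite-style variation)."""
    t = state.tract1 if which == 1 else state.tract2
    cur_q = (t[1] - t[0]) // 3
    delta = target_q - cur_q
    if delta == 0:
        return state
    if delta > 0:
        seq = state.seq[: t[0]] + "CAA" * delta + state.seq[t[0] :]
    else:
        seq = state.seq[: t[0]] + state.seq[t[0] - 3 * delta :]
    shift = 3 * delta
    t_new = (t[0], t[1] + shift)
    if which == 1:
        return _CleanGene(seq=seq, tract1=t_new,
                          tract2=(state.tract2[0] + shift, state.tract2[1] + shift))
    return _CleanGene(seq=seq, tract1=state.tract1, tract2=t_new)


def _insert_repeat_unit(
    state: _CleanGene, rng: np.random.Generator, at_first: bool = False
) -> _CleanGene:
    """In-frame 21-nt insertion duplicating one PQPQLPY unit in the
    repetitive domain (nucleotide-exact copy, so the alignment gap is 21 nt)."""
    prot_prefix_len = state.tract1[0] // 3
    # locate a PQPQLPY occurrence upstream of polyQ I
    from .core_io import translate as _tr

    prot = _tr(NucleotideSeq(id="tmp", seq=state.seq), truncate_at_stop=True).seq
    hits = [
        i
        for i in range(len(SIGNAL_PEPTIDE), prot_prefix_len - len(REPEAT_UNIT_7))
        if prot[i : i + 7] == REPEAT_UNIT_7
    ]
    if not hits:
        return state
    aa = hits[0] if at_first else hits[int(rng.integers(len(hits)))]
    nt = aa * 3
    unit_nt = state.seq[nt : nt + 21]
    seq = state.seq[: nt + 21] + unit_nt + state.seq[nt + 21 :]
    return _CleanGene(
        seq=seq,
        tract1=(state.tract1[0] + 21, state.tract1[1] + 21),
        tract2=(state.tract2[0] + 21, state.tract2[1] + 21),
    )


def _apply_mechanism(
    seq: str,
    mechanism: str,
    rng: np.random.Generator,
    te_library: list[NucleotideSeq],
    tsd_len: int,
    exclude: tuple[tuple[int, int], ...] = (),
) -> tuple[str, int, str]:
    """Apply one pseudogenizing mechanism; returns (mutated_seq, position, detail).

    ``exclude`` intervals (the polyQ tracts) are avoided when planting the
    stop-gain: inside a homopolymeric tract the aligned reference codon is
    ambiguous, so recovery there would not be a fair test of attribution.
    """
    n = len(seq)
    if mechanism == "c_to_t_stop":
        gln = [
            k
            for k in range(1, n // 3 - 1)
            if seq[3 * k : 3 * k + 3] in GLN_CODONS
            and not any(s <= 3 * k < e for s, e in exclude)
        ]
        if not gln:
            raise GliaError("no glutamine codon available for stop-gain")
        k = gln[int(rng.integers(len(gln)))]
        codon = seq[3 * k : 3 * k + 3]
        mutated = seq[: 3 * k] + "T" + seq[3 * k + 1 :]
        return mutated, 3 * k, f"{codon}→T{codon[1:]}"
    if mechanism == "frameshift":
        p = int(rng.integers(90, n - 180))
        if rng.random() < 0.5:
            size = int(rng.integers(1, 3))
            return seq[:p] + seq[p + size :], p, f"del:{size}nt"
        size = int(rng.integers(1, 3))
        ins = "".join("ACGT"[rng.integers(4)] for _ in range(size))
        return seq[:p] + ins + seq[p:], p, f"ins:{size}nt"
    if mechanism == "te_insertion":
        if not te_library:
            raise GliaError("te_insertion requested with an empty TE library")
        te = te_library[int(rng.integers(len(te_library)))]
        p = 3 * int(rng.integers(30, (n - 60) // 3))
        mutated = seq[: p + tsd_len] + te.seq + seq[p:]
        # recorded position = TE start in TE-free coordinates (after the
        # left copy of the duplicated target site)
        return mutated, p + tsd_len, f"{te.id}:tsd={seq[p:p+tsd_len]}"
    if mechanism == "truncation":
        frac = rng.uniform(0.2, 0.45)
        cut = 3 * (max(90, int(n * frac)) // 3)
        return seq[:cut], cut, f"kept {cut}nt"
    raise ValueError(f"unknown mechanism {mechanism}")


def _gene_truth(gid: str, genome: str, final_seq: str, status: str,
                mechanisms: list[str], positions: list[int],
                clean: _CleanGene | None, parent: str | None) -> GeneTruth:
    import warnings

    from .core_io import translate as _tr

    prot = ""
    if len(final_seq) >= 3:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # fragments end mid-codon
            prot = _tr(
                NucleotideSeq(id=gid, seq=final_seq), truncate_at_stop=True
            ).seq
    counts = {k: _count(prot, pep) for k, pep in _EPITOPE_PEPS.items()}
    from .epitopes import THIRTY_THREE_MER

    t = GeneTruth(
        gene_id=gid,
        genome=genome,
        status=status,
        mechanisms=mechanisms,
        defect_positions=positions,
        epitope_counts=counts,
        has_33mer=_count(prot, THIRTY_THREE_MER) > 0,
        has_cstt="CSTT" in prot[-15:],
        parent=parent,
    )
    if status == "intact" and clean is not None:
        t.q_count_I = (clean.tract1[1] - clean.tract1[0]) // 3
        t.q_count_II = (clean.tract2[1] - clean.tract2[0]) // 3
    return t


def evolve_locus(cfg: SimulationConfig) -> SimulatedLoci:
    """Simulate the three homeologous loci with planted, truth-tracked events."""
    rng = np.random.default_rng(cfg.seed)
    te_library = (
        cfg.te_library if cfg.te_library is not None else default_te_library(cfg.seed + 1)
    )
    if cfg.mechanism_mix.get("te_insertion", 0) > 0 and not te_library:
        raise GliaError("te_insertion in mechanism mix but TE library is empty")
    mech_names = list(cfg.mechanism_mix)
    mech_probs = np.array([cfg.mechanism_mix[m] for m in mech_names])

    truth = SyntheticTruth()
    loci: dict[str, LocusRecord] = {}
    _, base_clean = build_ancestral_gene(cfg, "D", rng)  # shared ancestor pool

    # the 33-mer context occupies a fixed interval just after the signal
    # peptide in D-genome ancestors; it is shielded from point substitution
    # so the planted 33-mer-origin scenario stays intact at the nt level
    ctx_nt = (3 * len(SIGNAL_PEPTIDE), 3 * (len(SIGNAL_PEPTIDE) + len(CONTEXT_26MER)))

    for genome in ("A", "B", "D"):
        protect = ctx_nt if genome == "D" else None
        _, anc_clean = build_ancestral_gene(cfg, genome, rng)
        anc_clean = _mutate_safe(anc_clean, cfg.genome_divergence, rng, protect=protect)
        lineage: list[tuple[str, _CleanGene]] = [(None, anc_clean)]
        genes: list[GeneRecord] = []
        cursor = 0
        pieces: list[str] = []
        planted_33mer = False
        n_copies = cfg.n_genes.get(genome, 0) + cfg.n_shared_ancestral
        for i in range(1, n_copies + 1):
            gid = f"a{genome}{i}"
            shared = i > cfg.n_genes.get(genome, 0)
            if shared:
                parent_id, parent_state = None, base_clean
                state = _mutate_safe(parent_state, cfg.shared_divergence, rng)
            else:
                parent_id, parent_state = lineage[int(rng.integers(len(lineage)))]
                state = _mutate_safe(
                    parent_state, cfg.substitution_rate, rng, protect=protect
                )
                q1, q2 = _draw_q(rng, cfg)
                state = _resize_tract(state, 1, q1, rng)
                state = _resize_tract(state, 2, q2, rng)
            if cfg.p_21nt_indel and rng.random() < cfg.p_21nt_indel:
                state = _insert_repeat_unit(state, rng)
            if cfg.plant_33mer and genome == "D" and not planted_33mer and not shared:
                state = _insert_repeat_unit(state, rng, at_first=True)
                planted_33mer = True
            lineage.append((gid, state))

            mechanisms: list[str] = []
            positions: list[int] = []
            final_seq = state.seq
            if rng.random() < cfg.p_pseudogenization:
                if cfg.compound_fraction and rng.random() < cfg.compound_fraction:
                    chosen = ["te_insertion", "c_to_t_stop", "frameshift"]
                else:
                    chosen = [mech_names[int(rng.choice(len(mech_names), p=mech_probs))]]
                for mech in chosen:
                    final_seq, pos, detail = _apply_mechanism(
                        final_seq, mech, rng, te_library, cfg.tsd_len,
                        exclude=(state.tract1, state.tract2),
                    )
                    mechanisms.append(mech)
                    positions.append(pos)
            status = (
                "intact"
                if not mechanisms
                else ("fragment" if mechanisms == ["truncation"] else "pseudogene")
            )
            t = _gene_truth(
                gid, genome, final_seq, status, mechanisms, positions,
                state if status == "intact" else None, parent_id,
            )
            truth.genes[gid] = t
            truth.duplication_history[gid] = parent_id

            spacer_len = max(
                200,
                int(rng.normal(cfg.spacer_mean[genome] * cfg.spacer_scale,
                               cfg.spacer_mean[genome] * cfg.spacer_scale / 5)),
            )
            spacer = "".join(rng.choice(list("ACGT"), size=spacer_len))
            if rng.random() < cfg.p_spacer_te:
                te = te_library[int(rng.integers(len(te_library)))]
                p = int(rng.integers(cfg.tsd_len, spacer_len - cfg.tsd_len))
                spacer = spacer[: p + cfg.tsd_len] + te.seq + spacer[p:]
            pieces.append(spacer)
            cursor += len(spacer)
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    genome=genome,
                    cds=NucleotideSeq(id=gid, seq=final_seq),
                    locus_start=cursor,
                    locus_end=cursor + len(final_seq),
                    strand="+",
                )
            )
            pieces.append(final_seq)
            cursor += len(final_seq)
        locus_seq = NucleotideSeq(id=f"locus_{genome}", seq="".join(pieces))
        loci[genome] = LocusRecord(genome=genome, genes=genes, sequence=locus_seq)
    return SimulatedLoci(loci=loci, truth=truth, te_library=te_library)


# ---------------------------------------------------------------------------
# Read simulation


def simulate_reads(
    sim: SimulatedLoci,
    cfg: SimulationConfig,
    seed: int | None = None,
    sample: str = "20SE",
) -> tuple[list[NucleotideSeq], CountTable]:
    """Draw per-gene expression (log-normal, pseudogenes and fragments scaled
    by the penalty factor), sample uniform fixed-length reads from each CDS,
    and return the reads together with the true count table.

    Read headers carry the source gene id (``<gene>:<k>``) for truth tracking.
    """
    rng = np.random.default_rng(cfg.seed + 7 if seed is None else seed)
    reads: list[NucleotideSeq] = []
    counts: dict[str, int] = {}
    lengths: dict[str, int] = {}
    for g in sim.all_genes():
        t = sim.truth.genes[g.gene_id]
        level = float(np.exp(rng.normal(cfg.expr_log_mean, cfg.expr_log_sd)))
        if t.status != "intact":
            level *= cfg.pseudogene_penalty
        t.expression = level
        n_reads = int(rng.poisson(level))
        L = len(g.cds)
        lengths[g.gene_id] = L
        if L <= cfg.read_len:
            n_reads = 0
        counts[g.gene_id] = n_reads
        for k in range(n_reads):
            start = int(rng.integers(0, L - cfg.read_len + 1))
            seq = list(g.cds.seq[start : start + cfg.read_len])
            if cfg.read_error_rate:
                for j in range(len(seq)):
                    if rng.random() < cfg.read_error_rate:
                        seq[j] = "ACGT"[rng.integers(4)]
            reads.append(
                NucleotideSeq(id=f"{g.gene_id}:{k}", seq="".join(seq))
            )
    total = sum(counts.values())
    table = CountTable(
        counts=pd.DataFrame({sample: pd.Series(counts)}),
        lengths=pd.Series(lengths),
        total_mapped=pd.Series({sample: total}),
    )
    return reads, table


def expression_fixture(
    gliadin_pct_of_genes: float = 23.0,
    gliadin_pct_of_total: float = 13.9,
    n_gliadin: int = 26,
    mapped_to_genes: int = 1_000_000,
    seed: int = 0,
) -> tuple[CountTable, list[str]]:
    """A count table planted so that the α-gliadin transcript share is
    ``gliadin_pct_of_genes`` of reads mapped to annotated genes and
    ``gliadin_pct_of_total`` of all reads."""
    rng = np.random.default_rng(seed)
    gliadin_total = int(round(mapped_to_genes * gliadin_pct_of_genes / 100.0))
    weights = rng.dirichlet(np.ones(n_gliadin))
    gl_counts = np.floor(weights * gliadin_total).astype(int)
    gl_counts[0] += gliadin_total - gl_counts.sum()
    gl_ids = [f"aG{i+1}" for i in range(n_gliadin)]
    other = mapped_to_genes - gliadin_total
    counts = pd.Series(dict(zip(gl_ids, gl_counts)) | {"other_genes": other})
    total_reads = int(round(gliadin_total * 100.0 / gliadin_pct_of_total))
    table = CountTable(
        counts=pd.DataFrame({"20SE": counts}),
        lengths=pd.Series({g: 900 for g in gl_ids} | {"other_genes": 1500}),
        total_mapped=pd.Series({"20SE": total_reads}),
    )
    return table, gl_ids
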