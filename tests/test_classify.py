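"""Pseudogene detection, mechanism attribution, TE excision, summaries."""

import numpy as np
import pytest

from glia.classify import (
    ClassificationConfig,
    attribute_stop_mechanism,
    classification_report,
    classify_gene,
    classify_loci,
    detect_frameshift,
    detect_premature_stops,
    detect_te_insertion,
    excise_te,
    pick_reference,
    summarize_locus,
)
from glia.core_io import (
    GeneRecord,
    GliaError,
    LocusRecord,
    NucleotideSeq,
    STOP_CODONS,
    translate,
)
from glia.simulate import SimulationConfig, build_ancestral_gene, default_te_library


@pytest.fixture(scope="module")
def intact_cds():
    cds, _ = build_ancestral_gene(SimulationConfig(seed=42), genome="A")
    return cds


def brute_force_stops(seq: str) -> list[tuple[int, str]]:
    """Independent oracle: check every frame-0 codon except the last."""
    out = []
    n_codons = len(seq) // 3
    for k in range(n_codons):
        codon = seq[3 * k : 3 * k + 3]
        if codon in ("TAA", "TAG", "TGA") and k < n_codons - 1:
            out.append((k, codon))
    return out


class TestPrematureStops:
    def test_terminator_not_premature(self):
        cds = NucleotideSeq(id="x", seq="ATGAAATAATTTTGA")
        assert detect_premature_stops(cds) == [(2, "TAA")]

    def test_intact_gene_clean(self, intact_cds):
        assert detect_premature_stops(intact_cds) == []

    def test_planted_stop_recovered(self, intact_cds):
        seq = intact_cds.seq
        assert seq[150:153] not in STOP_CODONS
        mutated = seq[:150] + "TAG" + seq[153:]
        stops = detect_premature_stops(NucleotideSeq(id="m", seq=mutated))
        assert (50, "TAG") in stops

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(2, 40))
            seq = "".join(rng.choice(list("ACGT"), size=3 * n))
            got = detect_premature_stops(NucleotideSeq(id="r", seq=seq))
            assert got == brute_force_stops(seq)

    def test_too_short_errors(self):
        with pytest.raises(GliaError):
            detect_premature_stops(NucleotideSeq(id="x", seq="ATG"))


class TestStopMechanism:
    def test_cag_to_tag_is_c_to_t(self, intact_cds):
        seq = intact_cds.seq
        cag = next(
            k for k in range(10, len(seq) // 3 - 1) if seq[3 * k : 3 * k + 3] == "CAG"
        )
        pseudo = NucleotideSeq(
            id="p", seq=seq[: 3 * cag] + "TAG" + seq[3 * cag + 3 :]
        )
        defects = attribute_stop_mechanism(pseudo, intact_cds)
        assert len(defects) == 1
        d = defects[0]
        assert (d.position, d.detail, d.c_to_t) == (3 * cag, "CAG→TAG", True)

    def test_tgg_to_tga_not_c_to_t(self):
        ref = NucleotideSeq(id="r", seq="ATG" + "TGG" + "AAA" * 20 + "TAA")
        obs = NucleotideSeq(id="o", seq="ATG" + "TGA" + "AAA" * 20 + "TAA")
        (d,) = attribute_stop_mechanism(obs, ref)
        assert d.detail == "TGG→TGA" and not d.c_to_t

    def test_ten_planted_caa_to_taa_all_recovered(self, intact_cds):
        seq = intact_cds.seq
        caa = [
            k for k in range(5, len(seq) // 3 - 1) if seq[3 * k : 3 * k + 3] == "CAA"
        ][:10]
        assert len(caa) == 10
        mutated = list(seq)
        for k in caa:
            mutated[3 * k] = "T"
        pseudo = NucleotideSeq(id="p", seq="".join(mutated))
        defects = attribute_stop_mechanism(pseudo, intact_cds)
        hits = {d.position for d in defects if d.c_to_t and d.detail == "CAA→TAA"}
        assert {3 * k for k in caa} <= hits

    def test_unalignable_pair_errors(self):
        a = NucleotideSeq(id="a", seq="ATG" + "CCC" * 40 + "TAA")
        b = NucleotideSeq(id="b", seq="ATG" + "GAT" * 40 + "TAA")
        with pytest.raises(GliaError, match="identity"):
            attribute_stop_mechanism(a, b)


class TestFrameshift:
    def test_single_deletion_detected(self, intact_cds):
        seq = intact_cds.seq
        pseudo = NucleotideSeq(id="p", seq=seq[:200] + seq[201:])
        defects = detect_frameshift(pseudo, intact_cds)
        assert len(defects) == 1
        assert defects[0].kind == "frameshift_indel"
        assert abs(defects[0].position - 200) <= 3

    def test_21nt_indel_is_in_frame(self, intact_cds):
        seq = intact_cds.seq
        pseudo = NucleotideSeq(id="p", seq=seq[:210] + seq[231:])
        assert detect_frameshift(pseudo, intact_cds) == []

    def test_two_frameshifts_reported(self, intact_cds):
        seq = intact_cds.seq
        mutated = seq[:150] + "GT" + seq[150:400] + seq[401:]
        defects = detect_frameshift(NucleotideSeq(id="p", seq=mutated), intact_cds)
        assert len(defects) == 2
        kinds = {d.detail.split(":")[0] for d in defects}
        assert kinds == {"ins", "del"}


class TestTeInsertion:
    def _plant(self, cds, te, pos, tsd_len=8):
        seq = cds.seq
        return NucleotideSeq(
            id=cds.id, seq=seq[: pos + tsd_len] + te.seq + seq[pos:]
        )

    def test_te_with_tsd_reported(self, intact_cds):
        lib = default_te_library(3)
        region = self._plant(intact_cds, lib[0], 240)
        (d,) = detect_te_insertion(region, lib)
        assert d.kind == "te_insertion"
        assert d.position == 248
        assert f"tsd={intact_cds.seq[240:248]}" in d.detail
        assert lib[0].id in d.detail

    def test_excision_restores_original(self, intact_cds):
        lib = default_te_library(3)
        region = self._plant(intact_cds, lib[1], 300)
        clean, defects = excise_te(region, lib)
        assert clean.seq == intact_cds.seq
        assert len(defects) == 1

    def test_no_library_match(self, intact_cds):
        assert detect_te_insertion(intact_cds, default_te_library(3)) == []

    def test_nested_insertion_both_reported(self, intact_cds):
        lib = default_te_library(3)
        outer, inner = lib[0], lib[1]
        region = self._plant(intact_cds, outer, 240)
        # plant the inner element inside the outer element's body
        seq = region.seq
        cut = 248 + 100
        region = NucleotideSeq(id="n", seq=seq[: cut + 8] + inner.seq + seq[cut:])
        clean, defects = excise_te(region, lib)
        assert clean.seq == intact_cds.seq
        assert len(defects) == 2
        names = {d.detail.split(":")[0] for d in defects}
        assert names == {outer.id, inner.id}
        assert any("nested" in d.detail for d in defects)


class TestClassifyGene:
    def _record(self, cds, gid="g1"):
        return GeneRecord(gene_id=gid, genome="A", cds=cds)

    def test_clean_gene_is_intact(self, intact_cds):
        g = classify_gene(self._record(intact_cds))
        assert g.status == "intact" and g.defects == []

    def test_truncated_gene_is_fragment(self, intact_cds):
        cut = 3 * int(0.4 * len(intact_cds.seq) / 3)
        frag = NucleotideSeq(id="f", seq=intact_cds.seq[:cut])
        g = classify_gene(self._record(frag), reference=self._record(intact_cds, "ref"))
        assert g.status == "fragment"
        assert any(d.kind == "truncation" for d in g.defects)

    def test_compound_defects_all_listed(self, intact_cds):
        lib = default_te_library(3)
        seq = intact_cds.seq
        seq = seq[:150] + "TAG" + seq[153:]          # stop
        seq = seq[:400] + seq[401:]                   # 1-nt deletion
        seq = seq[:248] + lib[0].seq + seq[240:248] + seq[248:]  # TE after TSD copy
        g = classify_gene(
            self._record(NucleotideSeq(id="c", seq=seq)),
            reference=self._record(intact_cds, "ref"),
            te_library=lib,
        )
        assert g.status == "pseudogene"
        kinds = {d.kind for d in g.defects}
        assert {"te_insertion", "premature_stop", "frameshift_indel"} <= kinds
        assert g.note == "mechanism order undeterminable"

    def test_no_start_is_pseudogene(self, intact_cds):
        seq = "CTG" + intact_cds.seq[3:]
        g = classify_gene(self._record(NucleotideSeq(id="ns", seq=seq)))
        assert g.status == "pseudogene"
        assert any(d.detail == "no_start" for d in g.defects)

    def test_idempotent_and_deterministic(self, intact_cds):
        seq = intact_cds.seq[:150] + "TAA" + intact_cds.seq[153:]
        rec = self._record(NucleotideSeq(id="p", seq=seq))
        ref = self._record(intact_cds, "ref")
        g1 = classify_gene(rec, reference=ref)
        g2 = classify_gene(g1, reference=ref)
        assert g1.status == g2.status
        assert [(d.kind, d.position) for d in g1.defects] == [
            (d.kind, d.position) for d in g2.defects
        ]


class TestSummaries:
    def test_counts_reconcile(self, classified47):
        summary = summarize_locus(classified47)
        assert summary.n_genes == 47
        assert summary.n_genes == summary.n_intact + summary.n_pseudo + summary.n_fragment
        per_genome_total = sum(v["n"] for v in summary.per_genome.values())
        assert per_genome_total == 47

    def test_pseudo_fraction_rounding(self):
        cds = NucleotideSeq(id="c", seq="ATG" + "AAA" * 99 + "TAA")
        genes = []
        for i in range(47):
            status = "pseudogene" if i < 21 else "intact"
            defects = (
                [DefectFactory()] if status == "pseudogene" else []
            )
            genes.append(
                GeneRecord(
                    gene_id=f"g{i}", genome="A", cds=cds,
                    locus_start=400 * i, locus_end=400 * i + 300,
                    status=status, defects=defects,
                )
            )
        summary = summarize_locus(LocusRecord(genome="A", genes=genes))
        assert summary.n_pseudo == 21 and summary.pct_pseudo == 45

    def test_all_intact_locus(self, intact_cds):
        g = GeneRecord(gene_id="g", genome="A", cds=intact_cds, status="intact")
        summary = summarize_locus(LocusRecord(genome="A", genes=[g]))
        assert summary.n_pseudo == 0 and summary.pct_pseudo == 0

    def test_unclassified_gene_errors(self, intact_cds):
        g = GeneRecord(gene_id="g", genome="A", cds=intact_cds)
        with pytest.raises(GliaError, match="unclassified"):
            summarize_locus(LocusRecord(genome="A", genes=[g]))

    def test_report_has_row_per_gene(self, classified47):
        report = classification_report(classified47)
        assert len(report) == 47
        assert set(report["status"]) <= {"intact", "pseudogene", "fragment"}


def DefectFactory():
    from glia.core_io import DefectAnnotation

    return DefectAnnotation(kind="premature_stop", position=30, detail="CAA→TAA",
                            c_to_t=True)


class TestReferenceSelection:
    def test_closest_intact_paralog_with_tie_break(self, intact_cds):
        ref_a = GeneRecord(gene_id="aA1", genome="A", cds=intact_cds, status="intact")
        ref_b = GeneRecord(gene_id="aA2", genome="A", cds=intact_cds, status="intact")
        query = GeneRecord(gene_id="q", genome="A", cds=intact_cds)
        # identical candidates: lexicographically smallest id wins
        assert pick_reference(query, [ref_b, ref_a]).gene_id == "aA1"
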