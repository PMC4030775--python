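"""Rarity/conservation filters, consequence classification, regulatory
proximity, exon-skip arithmetic."""
import numpy as np
import pytest

from epitrio.annotation_filters import (
    AnnotationRecord,
    TranscriptModel,
    classify_consequence,
    conservation_pass,
    exon_skip_effect,
    rarity_filter,
    regulatory_candidate,
)
from epitrio.formats_io import GenomeIntervals, GenomicInterval, SequenceStore, VariantSite
from epitrio.synthetic_data import ScenarioSpec, _build_transcript, _generate_sequence
from epitrio.trio_models import ModelConfig

CFG = ModelConfig()


def ann(**kw):
    return AnnotationRecord(key="chr1:1:A:G", **kw)


class TestRarityFilter:
    def test_all_bounds_satisfied_keeps(self):
        a = ann(af_by_resource={"1000G": 0.004, "ESP": 0.004}, internal_het=5)
        assert rarity_filter(a, "simple_recessive", CFG) == (True, None)

    def test_frequency_above_cutoff_drops(self):
        a = ann(af_by_resource={"1000G": 0.006})
        keep, reason = rarity_filter(a, "simple_recessive", CFG)
        assert not keep and reason.startswith("frequency")

    @pytest.mark.parametrize(
        "kw, expected_keep",
        [
            ({"af_by_resource": {"1000G": 0.005}}, True),  # strict >
            ({"internal_het": 6}, False),
            ({"internal_hom": 1}, False),
            ({"internal_hemi": 1}, False),
        ],
    )
    def test_boundaries(self, kw, expected_keep):
        assert rarity_filter(ann(**kw), "compound_het", CFG)[0] == expected_keep

    def test_de_novo_model_requires_novelty(self):
        assert rarity_filter(ann(seen_in=frozenset({"ESP"})), "de_novo", CFG)[0] is False
        assert rarity_filter(ann(), "de_novo", CFG)[0] is True
        # population AF does not matter under the de novo rule, only presence
        a = ann(af_by_resource={"1000G": 0.5})
        assert rarity_filter(a, "de_novo", CFG)[0] is True

    def test_missing_annotation_treated_as_novel(self):
        assert rarity_filter(None, "de_novo", CFG) == (True, None)
        assert rarity_filter(None, "simple_recessive", CFG) == (True, None)

    def test_random_records_match_literal_clause_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            a = ann(
                af_by_resource={"1000G": rng.random() * 0.01, "ESP": rng.random() * 0.01},
                internal_het=int(rng.integers(0, 8)),
                internal_hom=int(rng.integers(0, 2)),
                internal_hemi=int(rng.integers(0, 2)),
            )
            expected = not (
                any(v > 0.005 for v in a.af_by_resource.values())
                or a.internal_hom > 0
                or a.internal_hemi > 0
                or a.internal_het > 5
            )
            assert rarity_filter(a, "simple_recessive", CFG)[0] == expected

    def test_seen_in_monotone(self):
        """Adding a resource to seen_in can only change keep -> drop."""
        base = ann()
        assert rarity_filter(base, "de_novo", CFG)[0]
        worse = ann(seen_in=frozenset({"WGS500"}))
        assert not rarity_filter(worse, "de_novo", CFG)[0]


class TestConservationPass:
    def test_single_gerp_clause(self):
        assert conservation_pass(ann(gerp=2.1)) is True

    def test_phastcons_boundary_is_strict(self):
        assert conservation_pass(ann(phastcons=0.95)) is False
        assert conservation_pass(ann(phastcons=0.951)) is True

    def test_elements_alone_suffice(self):
        assert conservation_pass(ann(in_gerp_element=True)) is True
        assert conservation_pass(ann(in_phastcons_element=True)) is True

    def test_missing_everything_fails(self):
        assert conservation_pass(ann()) is False
        assert conservation_pass(None) is False

    def test_random_tuples_match_disjunction_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            a = ann(
                gerp=float(rng.normal(1, 2)) if rng.random() < 0.8 else None,
                phylop=float(rng.normal(1, 2)) if rng.random() < 0.8 else None,
                phastcons=float(rng.random()) if rng.random() < 0.8 else None,
                in_gerp_element=bool(rng.random() < 0.2),
                in_phastcons_element=bool(rng.random() < 0.2),
            )
            expected = (
                (a.gerp is not None and a.gerp > 2)
                or (a.phylop is not None and a.phylop > 2)
                or (a.phastcons is not None and a.phastcons > 0.95)
                or a.in_gerp_element
                or a.in_phastcons_element
            )
            assert conservation_pass(a) == expected


# ---------------------------------------------------------------------------
# Consequence classification against generated transcripts
# ---------------------------------------------------------------------------

def _tx_with_sequence(gene="PIGQ", strand=None, rng_seed=0):
    spec = ScenarioSpec.for_gene("simple_recessive_roh", gene)
    if strand is not None:
        spec = spec.model_copy(update={"strand": strand})
    tx = _build_transcript(spec)
    seqs = SequenceStore()
    _generate_sequence(tx, seqs, np.random.default_rng(rng_seed))
    return tx, seqs


def _snv(chrom, pos1, ref, alt):
    return VariantSite(chrom=chrom, pos=pos1, ref=ref, alts=(alt,))


class TestClassifyConsequence:
    def test_acceptor_minus2_of_exon3_plus_strand(self):
        """The -2 acceptor substitution before exon 3 labels as c.690-2A>G."""
        tx, seqs = _tx_with_sequence("PIGQ")
        ex3 = tx.exons[2]
        pos1 = ex3.start - 2 + 1  # -2 intronic position, 1-based
        seqs.set_base(tx.chrom, pos1, "A")
        call = classify_consequence(_snv(tx.chrom, pos1, "A", "G"), tx, seqs)
        assert call.consequence == "splice_acceptor"
        assert call.label == "c.690-2A>G"

    def test_acceptor_minus1_minus_strand_mirrored(self):
        """On a minus-strand transcript the -1 acceptor lies just *after* the
        exon's genomic end; hand-computed mirrored coordinates."""
        tx, seqs = _tx_with_sequence("SCN2A", strand="-")
        ex2 = tx.exons[1]  # transcription order
        pos1 = ex2.end + 1  # genomic position just past the exon end, 1-based
        seqs.set_base(tx.chrom, pos1, "C")  # genomic C = transcription-sense G
        call = classify_consequence(_snv(tx.chrom, pos1, "C", "T"), tx, seqs)
        assert call.consequence == "splice_acceptor"
        assert call.label.endswith("-1G>A")

    def test_donor_positions(self):
        tx, seqs = _tx_with_sequence("PIGQ")
        ex1 = tx.exons[0]
        for offset in (1, 2):
            pos1 = ex1.end + offset
            ref = seqs.get_base(tx.chrom, pos1)
            alt = "A" if ref != "A" else "C"
            call = classify_consequence(_snv(tx.chrom, pos1, ref, alt), tx, seqs)
            assert call.consequence == "splice_donor"

    def _force_codon(self, tx, seqs, codon_number, codon):
        cds = tx.cds_positions()
        cpos = cds[3 * codon_number : 3 * codon_number + 3]
        for p, b in zip(cpos, codon):
            base = b if tx.strand == "+" else {"A": "T", "C": "G", "G": "C", "T": "A"}[b]
            seqs.set_base(tx.chrom, p + 1, base)
        return cpos

    def test_synonymous_snv(self):
        """GCT -> GCC both encode Ala."""
        tx, seqs = _tx_with_sequence("PIGQ")
        cpos = self._force_codon(tx, seqs, 50, "GCT")
        call = classify_consequence(_snv(tx.chrom, cpos[2] + 1, "T", "C"), tx, seqs)
        assert call.consequence == "synonymous"

    def test_missense_snv_both_strands(self):
        """GCT -> GAT (Ala -> Asp), classified identically on either strand."""
        for strand, gene in (("+", "PIGQ"), ("-", "SCN2A")):
            tx, seqs = _tx_with_sequence(gene, strand=strand)
            cpos = self._force_codon(tx, seqs, 50, "GCT")
            ref = "C" if strand == "+" else "G"
            alt = "A" if strand == "+" else "T"
            call = classify_consequence(_snv(tx.chrom, cpos[1] + 1, ref, alt), tx, seqs)
            assert call.consequence == "nonsynonymous", strand

    def test_stop_gain(self):
        """TAC (Tyr) -> TAA (stop)."""
        tx, seqs = _tx_with_sequence("PIGQ")
        cpos = self._force_codon(tx, seqs, 60, "TAC")
        call = classify_consequence(_snv(tx.chrom, cpos[2] + 1, "C", "A"), tx, seqs)
        assert call.consequence == "stop_gain"

    def test_indel_frame_logic(self):
        tx, seqs = _tx_with_sequence("PIGQ")
        cds = tx.cds_positions()
        pos1 = cds[30] + 1
        ref3 = seqs.fetch(tx.chrom, pos1 - 1, pos1 + 3)
        frameshift = classify_consequence(
            VariantSite(chrom=tx.chrom, pos=pos1, ref=ref3[:2], alts=(ref3[0],)), tx, seqs
        )
        assert frameshift.consequence == "frameshift_indel"
        inframe = classify_consequence(
            VariantSite(chrom=tx.chrom, pos=pos1, ref=ref3, alts=(ref3[0],)), tx, seqs
        )
        assert inframe.consequence == "inframe_indel"

    def test_deep_intron_is_noncoding(self):
        tx, seqs = _tx_with_sequence("PIGQ")
        pos1 = tx.exons[0].end + 400  # mid-intron
        ref = seqs.get_base(tx.chrom, pos1)
        alt = "A" if ref != "A" else "C"
        call = classify_consequence(_snv(tx.chrom, pos1, ref, alt), tx, seqs)
        assert call.consequence == "noncoding"

    def test_reference_mismatch_raises(self):
        tx, seqs = _tx_with_sequence("PIGQ")
        cds = tx.cds_positions()
        pos1 = cds[10] + 1
        ref = seqs.get_base(tx.chrom, pos1)
        wrong = "A" if ref != "A" else "C"
        with pytest.raises(ValueError, match="reference mismatch"):
            classify_consequence(_snv(tx.chrom, pos1, wrong, ref), tx, seqs)


class TestExonSkipEffect:
    def test_fully_coding_132nt_exon_is_inframe_44aa(self):
        """Skipping a 132-nt coding exon deletes 44 amino acids in frame."""
        tx, _ = _tx_with_sequence("PIGQ")
        assert exon_skip_effect(tx, 3) == (True, 44, 132)

    def test_100nt_exon_is_out_of_frame(self):
        exons = (
            GenomicInterval("chr1", 1000, 1100),
            GenomicInterval("chr1", 2000, 2100),
            GenomicInterval("chr1", 3000, 3101),
        )
        tx = TranscriptModel("G", "T", "chr1", "+", exons, 1000, 3101)
        in_frame, aa, nt = exon_skip_effect(tx, 2)
        assert (in_frame, aa, nt) == (False, None, 100)

    def test_exon_half_in_cds(self):
        """120-nt exon with 60 coding nt: in-frame deletion of 20 aa."""
        exons = (
            GenomicInterval("chr1", 1000, 1120),
            GenomicInterval("chr1", 2000, 2120),
        )
        tx = TranscriptModel("G", "T", "chr1", "+", exons, 1060, 2120)
        assert exon_skip_effect(tx, 1) == (True, 20, 60)

    def test_untranslated_exon_warns(self):
        exons = (
            GenomicInterval("chr1", 1000, 1100),
            GenomicInterval("chr1", 2000, 2099),
        )
        tx = TranscriptModel("G", "T", "chr1", "+", exons, 2000, 2099)
        with pytest.warns(UserWarning, match="untranslated"):
            assert exon_skip_effect(tx, 1) == (True, 0, 0)

    def test_out_of_range_index(self):
        tx, _ = _tx_with_sequence("PIGQ")
        with pytest.raises(IndexError):
            exon_skip_effect(tx, 6)


class TestRegulatoryCandidate:
    def _setup(self):
        reg = GenomeIntervals([GenomicInterval("chr2", 100_000, 101_000, "regA")])
        spans = {"SCN2A": GenomicInterval("chr2", 110_500, 150_000)}
        conserved = ann(gerp=4.0)
        return reg, spans, conserved

    def test_conserved_variant_in_region_10kb_upstream(self):
        reg, spans, conserved = self._setup()
        site = _snv("chr2", 100_500, "A", "G")
        hit = regulatory_candidate(site, conserved, reg, spans)
        assert hit is not None and hit.gene == "SCN2A"
        assert hit.distance_bp == 10_001

    def test_50kb_window_boundary(self):
        reg = GenomeIntervals([GenomicInterval("chr2", 0, 300_000)])
        spans = {"G": GenomicInterval("chr2", 100_000, 100_010)}
        conserved = ann(gerp=4.0)
        # span's last base is pos0 100_009; distance measured from there
        at_limit = _snv("chr2", 150_010, "A", "G")  # pos0 150_009: 50_000 away
        assert regulatory_candidate(at_limit, conserved, reg, spans) is not None
        past_limit = _snv("chr2", 150_011, "A", "G")  # 50_001 away
        assert regulatory_candidate(past_limit, conserved, reg, spans) is None

    def test_requires_conservation_and_region(self):
        reg, spans, conserved = self._setup()
        inside = _snv("chr2", 100_500, "A", "G")
        assert regulatory_candidate(inside, ann(), reg, spans) is None  # not conserved
        outside = _snv("chr2", 105_000, "A", "G")  # conserved but no region
        assert regulatory_candidate(outside, conserved, reg, spans) is None

    def test_random_placements_match_linear_distance_oracle(self):
        rng = np.random.default_rng(5)
        reg = GenomeIntervals([GenomicInterval("chr2", 0, 1_000_000)])
        spans = {
            f"G{i}": GenomicInterval("chr2", int(s), int(s) + 5_000)
            for i, s in enumerate(rng.integers(0, 950_000, 20))
        }
        conserved = ann(gerp=4.0)
        for pos in rng.integers(1, 1_000_000, 1000):
            site = _snv("chr2", int(pos), "A", "G")
            hit = regulatory_candidate(site, conserved, reg, spans)
            dists = {g: s.distance_to(int(pos) - 1) for g, s in spans.items()}
            best = min(dists.values())
            if best <= 50_000:
                assert hit is not None and dists[hit.gene] == best
            else:
                assert hit is None
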