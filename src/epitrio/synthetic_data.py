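"""Seeded trio simulator with planted truth.

Generates the full input bundle for the prioritization pipeline — a
multi-sample trio VCF with genotype likelihoods, annotation tables,
transcript models, regulatory intervals and reference-sequence windows —
together with a :class:`TruthSet` naming every planted event, so each
pipeline stage can be tested without external downloads.

Model, per chromosome:

* segregating sites are placed uniformly at ``site_density`` sites/bp with
  population allele frequencies drawn from a Beta distribution clipped to
  [0.01, 0.99] (common standing variation; rare events are planted
  explicitly);
* parental haplotypes are Bernoulli(AF) draws per site, so parental
  genotypes are Hardy-Weinberg; the child receives one transmitted
  haplotype from each parent (no recombination model — nothing downstream
  uses linkage except UPD/ROH contiguity, which is planted explicitly);
* de novo mutations are planted as Poisson with mean 2 x total length x mu
  at positions monomorphic in the parents;
* genotype likelihoods come from a read model: depth ~ Poisson(mean_depth),
  alt reads ~ Binomial(depth, p) with p in {eps, 1/2, 1-eps} per true
  genotype and per-read error eps; the call is the GL argmax. Genotype
  errors are injected by drawing the reads from a wrong genotype at a
  reduced depth, so erroneous calls carry correspondingly weak likelihood
  margins;
* planted isodisomy copies one parental haplotype into both child
  homologues of a chromosome; planted ROH gives the parents a shared
  haplotype segment so the child is autozygous yet Mendelian-consistent.

Planted scenario sites (the Table-1-style causal configurations) are
exempt from the genotype-error model: errors stress the background
genome, the scenarios test the intended decision logic.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field

from .annotation_filters import (
    AnnotationRecord,
    TranscriptModel,
    write_annotation_table,
    write_transcripts_bed12,
    DEFAULT_CANDIDATE_GENES,
)
from .formats_io import (
    GenomicInterval,
    GenotypeCall,
    Pedigree,
    SequenceStore,
    TrioRecord,
    VariantSite,
    is_x_chromosome,
    write_intervals,
    write_pedigree,
    write_trio_vcf,
)

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

ScenarioKind = Literal[
    "de_novo_coding",
    "simple_recessive_roh",
    "recessive_via_paternal_upd",
    "de_novo_splice",
    "compound_het",
    "x_linked",
]


def mini_chrom_lengths(chrom_bp: int = 5_000_000) -> dict[str, int]:
    """Miniature genome: 22 autosomes + X, 5 Mb each, for desk-scale runs."""
    lengths = {f"chr{i}": chrom_bp for i in range(1, 23)}
    lengths["chrX"] = chrom_bp
    return lengths


#: hg19-proportioned chromosome lengths (Mb, autosomes + X)
_HG19_MB = {
    "chr1": 249, "chr2": 243, "chr3": 198, "chr4": 191, "chr5": 181,
    "chr6": 171, "chr7": 159, "chr8": 146, "chr9": 141, "chr10": 136,
    "chr11": 135, "chr12": 134, "chr13": 115, "chr14": 107, "chr15": 103,
    "chr16": 90, "chr17": 81, "chr18": 78, "chr19": 59, "chr20": 63,
    "chr21": 48, "chr22": 51, "chrX": 155,
}


def full_genome_lengths(total_bp: float = 3.0e9) -> dict[str, int]:
    """Chromosome lengths proportioned like hg19 and scaled to total_bp.

    The total is the haploid genome length L entering the expected de novo
    count 2 x L x mu, so simulation-scale expectations match the analytic
    value computed with the same L.
    """
    raw_total = sum(_HG19_MB.values())
    lengths = {c: int(round(mb / raw_total * total_bp)) for c, mb in _HG19_MB.items()}
    lengths["chr1"] += int(total_bp) - sum(lengths.values())  # exact total
    return lengths


# gene -> (chrom, strand, anchor of the transcript span, 0-based)
GENE_PLACEMENTS: dict[str, tuple[str, str, int]] = {
    "KCNQ2": ("chr20", "+", 2_000_000),
    "SCN2A": ("chr2", "-", 2_000_000),
    "KCNT1": ("chr9", "+", 2_000_000),
    "PIGQ": ("chr16", "+", 2_450_000),
    "CSNK1G1": ("chr15", "+", 2_000_000),
    "CBL": ("chr11", "+", 2_000_000),
    "SCN1A": ("chr2", "+", 3_500_000),
    "CDKL5": ("chrX", "+", 2_000_000),
    "STXBP1": ("chr9", "+", 3_200_000),
    "SPTAN1": ("chr9", "+", 3_600_000),
}

_EXON_SIZES = (250, 439, 132, 201, 300)
_INTRON_SIZES = (800, 600, 700, 900)
_CDS_LEN = 1200  # multiple of 3; spans exons 1-4 fully and part of exon 5


class SimulationError(ValueError):
    """Invalid simulation configuration (e.g. scenario on an unknown chromosome)."""


class ScenarioSpec(BaseModel):
    """One planted causal configuration (Table-1-style)."""

    kind: ScenarioKind
    gene: str
    chrom: str
    strand: str = "+"
    anchor: int = 2_000_000
    roh_length_bp: int = 2_000_000
    upd_parent: Literal["father", "mother"] = "father"
    exon_index: int = 3
    acceptor_offset: int = 2  # bp into the intron before the exon
    codon_number: int = 150  # 0-based codon index for missense planting

    @classmethod
    def for_gene(cls, kind: ScenarioKind, gene: str, **kw) -> "ScenarioSpec":
        chrom, strand, anchor = GENE_PLACEMENTS[gene]
        return cls(kind=kind, gene=gene, chrom=chrom, strand=strand, anchor=anchor, **kw)


def table1_scenarios() -> list[ScenarioSpec]:
    """The six causal configurations of the sequenced trios.

    Two de novo missense ion-channel mutations (KCNQ2, SCN2A), a recessive
    variant homozygous through paternal chr9 isodisomy (KCNT1), a simple
    recessive splice-acceptor variant inside a 2 Mb homozygous region
    (PIGQ), a de novo missense (CSNK1G1) and a de novo splice-acceptor
    variant (CBL).
    """
    return [
        ScenarioSpec.for_gene("de_novo_coding", "KCNQ2"),
        ScenarioSpec.for_gene("recessive_via_paternal_upd", "KCNT1"),
        ScenarioSpec.for_gene("de_novo_coding", "SCN2A"),
        ScenarioSpec.for_gene("simple_recessive_roh", "PIGQ", exon_index=3, acceptor_offset=2),
        ScenarioSpec.for_gene("de_novo_coding", "CSNK1G1"),
        ScenarioSpec.for_gene("de_novo_splice", "CBL", exon_index=4, acceptor_offset=1),
    ]


class SimulationConfig(BaseModel):
    """All knobs of the trio simulator; a fixed seed gives byte-identical output."""

    seed: int = 0
    chrom_lengths: dict[str, int] = Field(default_factory=mini_chrom_lengths)
    site_density: float = Field(default=1e-3, ge=0)
    af_alpha: float = 0.5
    af_beta: float = 2.0  # skewed to low frequencies, like a real site spectrum
    af_min: float = 0.01
    mu: float = Field(default=1.18e-8, ge=0)
    genotype_error_rate: float = Field(default=0.0, ge=0, le=1)
    mean_depth: float = 40.0
    read_error: float = 0.01
    error_depth_factor: float = 0.25
    child_sex: Literal["male", "female"] = "male"
    upd_chrom: Optional[str] = None
    upd_parent: Literal["father", "mother"] = "father"
    scenarios: list[ScenarioSpec] = Field(default_factory=list)


@dataclass
class CausalTruth:
    key: str
    chrom: str
    gene: str
    kind: str
    expected_model: str
    expected_consequence: str
    partner_key: Optional[str] = None


@dataclass
class TruthSet:
    """Every planted event, locatable in the emitted VCF by variant key."""

    de_novo: list[str] = field(default_factory=list)
    causal: list[CausalTruth] = field(default_factory=list)
    upd: list[dict] = field(default_factory=list)  # {"chrom", "parent"}
    roh: list[dict] = field(default_factory=list)  # {"chrom", "start", "end"}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        raw = json.loads(Path(path).read_text())
        return cls(
            de_novo=raw["de_novo"],
            causal=[CausalTruth(**c) for c in raw["causal"]],
            upd=raw["upd"],
            roh=raw["roh"],
        )


def draw_planted_de_novo_count(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    """Count-only mode: the Poisson draw the simulator would plant.

    Mean = 2 x total chromosome length x mu (two transmitted haplotypes).
    """
    mean = 2.0 * sum(cfg.chrom_lengths.values()) * cfg.mu
    return int(rng.poisson(mean))


# ---------------------------------------------------------------------------
# Transcript + sequence construction
# ---------------------------------------------------------------------------

def _build_transcript(spec: ScenarioSpec) -> TranscriptModel:
    sizes = list(_EXON_SIZES)
    introns = list(_INTRON_SIZES)
    if spec.strand == "-":
        genomic_sizes, genomic_introns = sizes[::-1], introns[::-1]
    else:
        genomic_sizes, genomic_introns = sizes, introns
    exons_genomic = []
    pos = spec.anchor
    for i, size in enumerate(genomic_sizes):
        exons_genomic.append(GenomicInterval(spec.chrom, pos, pos + size))
        pos += size + (genomic_introns[i] if i < len(genomic_introns) else 0)
    exons_tx = exons_genomic if spec.strand == "+" else exons_genomic[::-1]
    coding: list[int] = []
    for ex in exons_tx:
        rng_ = range(ex.start, ex.end) if spec.strand == "+" else range(ex.end - 1, ex.start - 1, -1)
        for p in rng_:
            coding.append(p)
            if len(coding) == _CDS_LEN:
                break
        if len(coding) == _CDS_LEN:
            break
    return TranscriptModel(
        gene=spec.gene,
        transcript_id=f"TX_{spec.gene}",
        chrom=spec.chrom,
        strand=spec.strand,
        exons=tuple(exons_tx),
        cds_start=min(coding),
        cds_end=max(coding) + 1,
    )


def _generate_sequence(tx: TranscriptModel, seqs: SequenceStore, rng: np.random.Generator,
                       flank: int = 200) -> None:
    span = tx.span
    start1 = max(1, span.start - flank + 1)
    length = span.end + flank - (start1 - 1)
    seq = "".join(BASES[i] for i in rng.integers(0, 4, length))
    seqs.add(tx.chrom, start1, seq)


def _plant_missense(tx: TranscriptModel, seqs: SequenceStore, codon_number: int
                    ) -> tuple[int, str, str]:
    """Force codon GCT (Ala) and return a middle-base missense (pos1, ref, alt).

    The substitution is C>A in transcription sense (GCT->GAT, Ala->Asp).
    """
    cds = tx.cds_positions()
    cpos = cds[3 * codon_number : 3 * codon_number + 3]
    for p, sense_base in zip(cpos, "GCT"):
        base = sense_base if tx.strand == "+" else COMPLEMENT[sense_base]
        seqs.set_base(tx.chrom, p + 1, base)
    p = cpos[1]
    if tx.strand == "+":
        ref, alt = "C", "A"
    else:
        ref, alt = "G", "T"
    return p + 1, ref, alt


def _plant_splice_acceptor(tx: TranscriptModel, seqs: SequenceStore, exon_index: int,
                           offset: int) -> tuple[int, str, str]:
    """Disrupt the acceptor dinucleotide before an exon; returns (pos1, ref, alt).

    offset 2 gives an A>G at the -2 position; offset 1 a G>A at -1 (the
    canonical AG acceptor, transcription sense).
    """
    ex = tx.exons[exon_index - 1]
    if tx.strand == "+":
        pos0 = ex.start - offset
    else:
        pos0 = ex.end - 1 + offset
    sense_ref = "A" if offset == 2 else "G"
    sense_alt = "G" if offset == 2 else "A"
    ref = sense_ref if tx.strand == "+" else COMPLEMENT[sense_ref]
    alt = sense_alt if tx.strand == "+" else COMPLEMENT[sense_alt]
    seqs.set_base(tx.chrom, pos0 + 1, ref)
    return pos0 + 1, ref, alt


@dataclass
class _Planted:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    dosages: tuple[int, int, int]  # child, father, mother (alt-allele counts)
    gene: str
    kind: str
    expected_model: str
    expected_consequence: str
    pair_tag: Optional[int] = None  # links compound-het mates


def _plant_scenarios(
    scenarios: list[ScenarioSpec],
    transcripts: dict[str, TranscriptModel],
    seqs: SequenceStore,
    chrom_lengths: dict[str, int],
) -> tuple[list[_Planted], list[dict], list[dict]]:
    planted: list[_Planted] = []
    upd: list[dict] = []
    roh: list[dict] = []
    for spec in scenarios:
        if spec.chrom not in chrom_lengths:
            raise SimulationError(f"scenario {spec.kind} references unknown chromosome {spec.chrom}")
        tx = transcripts[spec.gene]
        if spec.kind in ("de_novo_coding",):
            pos, ref, alt = _plant_missense(tx, seqs, spec.codon_number)
            planted.append(_Planted(spec.chrom, pos, ref, alt, (1, 0, 0), spec.gene,
                                    spec.kind, "de_novo", "nonsynonymous"))
        elif spec.kind == "de_novo_splice":
            pos, ref, alt = _plant_splice_acceptor(tx, seqs, spec.exon_index, spec.acceptor_offset)
            planted.append(_Planted(spec.chrom, pos, ref, alt, (1, 0, 0), spec.gene,
                                    spec.kind, "de_novo", "splice_acceptor"))
        elif spec.kind == "recessive_via_paternal_upd":
            if is_x_chromosome(spec.chrom):
                raise SimulationError("isodisomy planting is not supported on chrX")
            pos, ref, alt = _plant_missense(tx, seqs, spec.codon_number)
            dos = (2, 1, 0) if spec.upd_parent == "father" else (2, 0, 1)
            planted.append(_Planted(spec.chrom, pos, ref, alt, dos, spec.gene,
                                    spec.kind, "simple_recessive", "nonsynonymous"))
            upd.append({"chrom": spec.chrom, "parent": spec.upd_parent})
        elif spec.kind == "simple_recessive_roh":
            pos, ref, alt = _plant_splice_acceptor(tx, seqs, spec.exon_index, spec.acceptor_offset)
            planted.append(_Planted(spec.chrom, pos, ref, alt, (2, 1, 1), spec.gene,
                                    spec.kind, "simple_recessive", "splice_acceptor"))
            span = tx.span
            mid = (span.start + span.end) // 2
            half = spec.roh_length_bp // 2
            start = max(1, mid - half)
            roh.append({"chrom": spec.chrom, "start": start, "end": start + spec.roh_length_bp})
        elif spec.kind == "compound_het":
            pos_a, ref_a, alt_a = _plant_missense(tx, seqs, spec.codon_number)
            pos_b, ref_b, alt_b = _plant_missense(tx, seqs, spec.codon_number + 100)
            tag = len(planted)
            planted.append(_Planted(spec.chrom, pos_a, ref_a, alt_a, (1, 1, 0), spec.gene,
                                    spec.kind, "compound_het", "nonsynonymous", pair_tag=tag))
            planted.append(_Planted(spec.chrom, pos_b, ref_b, alt_b, (1, 0, 1), spec.gene,
                                    spec.kind, "compound_het", "nonsynonymous", pair_tag=tag))
        elif spec.kind == "x_linked":
            if not is_x_chromosome(spec.chrom):
                raise SimulationError("x_linked scenario must be on chrX")
            pos, ref, alt = _plant_missense(tx, seqs, spec.codon_number)
            planted.append(_Planted(spec.chrom, pos, ref, alt, (2, 0, 1), spec.gene,
                                    spec.kind, "x_linked", "nonsynonymous"))
        else:  # pragma: no cover
            raise SimulationError(f"unknown scenario kind {spec.kind}")
    return planted, upd, roh


# ---------------------------------------------------------------------------
# Genotype-likelihood read model
# ---------------------------------------------------------------------------

def _read_model_calls(
    dosages: np.ndarray,  # (3, n) true alt-allele counts in {0,1,2}
    hemi: np.ndarray,  # (3,) bool, per-sample hemizygosity on this chromosome
    exempt: np.ndarray,  # (n,) bool, sites exempt from error injection
    cfg: SimulationConfig,
    rng: np.random.Generator,
):
    """Simulate reads and return (called dosages, GLs (3,n,3), depth, alt reads)."""
    n = dosages.shape[1]
    depth = rng.poisson(cfg.mean_depth, size=(3, n)).astype(np.int64)
    err = rng.random((3, n)) < cfg.genotype_error_rate
    err &= ~exempt[None, :]
    g_src = dosages.copy()
    if err.any():
        wrong = (dosages + rng.integers(1, 3, size=(3, n))) % 3
        wrong = np.where(hemi[:, None] & err, 2 - dosages, wrong)  # hemizygous: 0 <-> 2
        g_src = np.where(err, wrong, dosages)
        depth[err] = np.maximum(
            1, rng.poisson(cfg.mean_depth * cfg.error_depth_factor, size=int(err.sum()))
        )
    eps = cfg.read_error
    p_alt = np.array([eps, 0.5, 1.0 - eps])[g_src]
    alt_reads = rng.binomial(depth, p_alt)
    ref_reads = depth - alt_reads
    lp = np.log10([eps, 0.5, 1.0 - eps])
    lq = np.log10([1.0 - eps, 0.5, eps])
    gl = alt_reads[..., None] * lp + ref_reads[..., None] * lq  # (3, n, 3)
    gl -= gl.max(axis=-1, keepdims=True)
    called = gl.argmax(axis=-1)
    called = np.where(hemi[:, None] & (called == 1), 2 * (alt_reads > ref_reads), called)
    return called, gl, depth, alt_reads, err


_DOSAGE_TO_ALLELES = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


# ---------------------------------------------------------------------------
# Main entry point
# ---------------------------------------------------------------------------

@dataclass
class SimulatedTrio:
    config: SimulationConfig
    pedigree: Pedigree
    records: list[TrioRecord]
    transcripts: list[TranscriptModel]
    sequences: SequenceStore
    annotations: dict[str, AnnotationRecord]
    regulatory: list[GenomicInterval]
    gene_list: list[str]
    truth: TruthSet
    #: (variant key, role) of every error-injected call — diagnostic only
    error_calls: list[tuple[str, str]] = field(default_factory=list)

    def write(self, outdir) -> dict[str, Path]:
        """Emit the standard file bundle; returns the path of each artifact."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "trio.vcf",
            "ped": outdir / "trio.ped",
            "annotations": outdir / "annotations.tsv",
            "transcripts": outdir / "transcripts.bed",
            "regulatory": outdir / "regulatory.bed",
            "genes": outdir / "genes.txt",
            "reference": outdir / "reference.fa",
            "truth": outdir / "truth.json",
            "config": outdir / "sim_config.json",
        }
        write_trio_vcf(self.records, paths["vcf"], self.pedigree, self.config.chrom_lengths)
        write_pedigree(self.pedigree, paths["ped"])
        write_annotation_table(self.annotations.values(), paths["annotations"])
        write_transcripts_bed12(self.transcripts, paths["transcripts"])
        write_intervals(self.regulatory, paths["regulatory"])
        paths["genes"].write_text("\n".join(self.gene_list) + "\n")
        self.sequences.to_fasta(paths["reference"])
        self.truth.to_json(paths["truth"])
        paths["config"].write_text(self.config.model_dump_json(indent=1) + "\n")
        return paths


def simulate_trio(cfg: SimulationConfig) -> SimulatedTrio:
    """Generate a complete seeded trio dataset with planted truth."""
    rng = np.random.default_rng(cfg.seed)
    pedigree = Pedigree("CHILD", "FATHER", "MOTHER", cfg.child_sex)

    # transcripts + reference windows for every scenario gene
    seqs = SequenceStore()
    transcripts: dict[str, TranscriptModel] = {}
    for spec in cfg.scenarios:
        if spec.gene in transcripts:
            raise SimulationError(f"two scenarios target gene {spec.gene}")
        tx = _build_transcript(spec)
        _generate_sequence(tx, seqs, rng)
        transcripts[spec.gene] = tx

    planted, upd_events, roh_events = _plant_scenarios(
        cfg.scenarios, transcripts, seqs, cfg.chrom_lengths
    )
    if cfg.upd_chrom is not None:
        if is_x_chromosome(cfg.upd_chrom):
            raise SimulationError("isodisomy planting is not supported on chrX")
        upd_events.append({"chrom": cfg.upd_chrom, "parent": cfg.upd_parent})
    upd_by_chrom = {e["chrom"]: e["parent"] for e in upd_events}
    roh_by_chrom: dict[str, list[dict]] = {}
    for e in roh_events:
        roh_by_chrom.setdefault(e["chrom"], []).append(e)
    planted_by_chrom: dict[str, list[_Planted]] = {}
    for p in planted:
        planted_by_chrom.setdefault(p.chrom, []).append(p)
    seen_pos = set()
    for p in planted:
        if (p.chrom, p.pos) in seen_pos:
            raise SimulationError(f"scenario collision at {p.chrom}:{p.pos}")
        seen_pos.add((p.chrom, p.pos))

    total_len = sum(cfg.chrom_lengths.values())
    n_dn_total = int(rng.poisson(2.0 * total_len * cfg.mu))
    chroms = list(cfg.chrom_lengths)
    weights = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    dn_counts = rng.multinomial(n_dn_total, weights / weights.sum())

    records: list[TrioRecord] = []
    annotations: dict[str, AnnotationRecord] = {}
    truth = TruthSet()
    truth.upd = list(upd_events)
    truth.roh = [dict(e) for e in roh_events]
    pair_keys: dict[int, list[str]] = {}
    error_calls: list[tuple[str, str]] = []

    child_is_male = cfg.child_sex == "male"

    for ci, chrom in enumerate(chroms):
        L = cfg.chrom_lengths[chrom]
        on_x = is_x_chromosome(chrom)
        n_bg = int(round(L * cfg.site_density))
        positions = np.sort(rng.choice(L, size=min(n_bg, L), replace=False)) + 1
        n = len(positions)
        af = np.clip(rng.beta(cfg.af_alpha, cfg.af_beta, n), cfg.af_min, 1 - cfg.af_min)

        mother_h = rng.random((2, n)) < af
        mt = int(rng.integers(0, 2))
        if on_x:
            father_h1 = rng.random(n) < af
            father_dos = 2 * father_h1.astype(np.int64)
        else:
            father_h = rng.random((2, n)) < af
            ft = int(rng.integers(0, 2))

        # planted ROH: the parents share an ancestral haplotype over the region
        for region in roh_by_chrom.get(chrom, []):
            mask = (positions >= region["start"]) & (positions < region["end"])
            if not on_x:
                mother_h[mt][mask] = father_h[ft][mask]

        if on_x:
            if child_is_male:
                child_dos = 2 * mother_h[mt].astype(np.int64)
            else:
                child_dos = father_h1.astype(np.int64) + mother_h[mt].astype(np.int64)
        else:
            child_pat = father_h[ft].copy()
            child_mat = mother_h[mt].copy()
            parent = upd_by_chrom.get(chrom)
            if parent == "father":
                child_pat = child_mat = father_h[ft]
            elif parent == "mother":
                child_pat = child_mat = mother_h[mt]
            child_dos = child_pat.astype(np.int64) + child_mat.astype(np.int64)

        if not on_x:
            father_dos = father_h.sum(axis=0).astype(np.int64)
        mother_dos = mother_h.sum(axis=0).astype(np.int64)

        # keep only sites polymorphic in the trio
        keep = (child_dos + father_dos + mother_dos) > 0
        positions = positions[keep]
        af = af[keep]
        child_dos, father_dos, mother_dos = child_dos[keep], father_dos[keep], mother_dos[keep]

        # ref/alt bases: from the sequence store where covered, random elsewhere
        n = len(positions)
        ref_idx = rng.integers(0, 4, n)
        alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4
        refs = [BASES[i] for i in ref_idx]
        alts = [BASES[i] for i in alt_idx]
        for i, pos in enumerate(positions):
            if seqs.covers(chrom, int(pos)):
                refs[i] = seqs.get_base(chrom, int(pos))
                if alts[i] == refs[i]:
                    alts[i] = BASES[(BASES.index(refs[i]) + 1) % 4]

        tags = ["background"] * n  # background | de_novo | causal
        planted_here = {p.pos: p for p in planted_by_chrom.get(chrom, [])}

        # Poisson de novo sites at positions monomorphic in the parents
        taken = set(int(p) for p in positions) | set(planted_here)
        dn_positions = []
        for _ in range(int(dn_counts[ci])):
            while True:
                pos = int(rng.integers(1, L + 1))
                if pos not in taken:
                    taken.add(pos)
                    dn_positions.append(pos)
                    break

        extra_pos, extra_ref, extra_alt, extra_dos, extra_tag, extra_planted = [], [], [], [], [], []
        for pos in dn_positions:
            if seqs.covers(chrom, pos):
                ref = seqs.get_base(chrom, pos)
            else:
                ref = BASES[int(rng.integers(0, 4))]
            alt = BASES[(BASES.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
            child = 2 if (on_x and child_is_male) else 1
            extra_pos.append(pos)
            extra_ref.append(ref)
            extra_alt.append(alt)
            extra_dos.append((child, 0, 0))
            extra_tag.append("de_novo")
            extra_planted.append(None)
        for pos, p in planted_here.items():
            extra_pos.append(pos)
            extra_ref.append(p.ref)
            extra_alt.append(p.alt)
            extra_dos.append(p.dosages)
            extra_tag.append("causal")
            extra_planted.append(p)

        # drop background sites colliding with extras, then merge + sort
        collide = {int(p) for p in extra_pos}
        keep_idx = [i for i in range(n) if int(positions[i]) not in collide]
        all_pos = [int(positions[i]) for i in keep_idx] + [int(p) for p in extra_pos]
        all_ref = [refs[i] for i in keep_idx] + extra_ref
        all_alt = [alts[i] for i in keep_idx] + extra_alt
        all_af = [float(af[i]) for i in keep_idx] + [0.0] * len(extra_pos)
        all_tag = [tags[i] for i in keep_idx] + extra_tag
        all_dc = [int(child_dos[i]) for i in keep_idx] + [d[0] for d in extra_dos]
        all_df = [int(father_dos[i]) for i in keep_idx] + [d[1] for d in extra_dos]
        all_dm = [int(mother_dos[i]) for i in keep_idx] + [d[2] for d in extra_dos]
        all_planted = [None] * len(keep_idx) + extra_planted
        order = np.argsort(all_pos, kind="stable")

        pos_arr = np.array([all_pos[i] for i in order])
        dos_arr = np.array([[all_dc[i] for i in order],
                            [all_df[i] for i in order],
                            [all_dm[i] for i in order]])
        tag_arr = [all_tag[i] for i in order]
        ref_arr = [all_ref[i] for i in order]
        alt_arr = [all_alt[i] for i in order]
        af_arr = [all_af[i] for i in order]
        planted_arr = [all_planted[i] for i in order]

        hemi = np.array([
            on_x and child_is_male,
            on_x,
            False,
        ])
        exempt = np.array([t == "causal" for t in tag_arr])
        called, gl, depth, alt_reads, err_mask = _read_model_calls(dos_arr, hemi, exempt, cfg, rng)

        qual = np.minimum(5000.0, -10.0 * gl[:, :, 0].sum(axis=0))
        qd = qual / np.maximum(1, depth.sum(axis=0))

        for i in range(len(pos_arr)):
            pos = int(pos_arr[i])
            site = VariantSite(
                chrom=chrom,
                pos=pos,
                ref=ref_arr[i],
                alts=(alt_arr[i],),
                qual=round(float(qual[i]), 2),
                site_info={"QD": round(float(qd[i]), 2)},
            )
            calls = {}
            for s, (role, sid) in enumerate(
                (("child", pedigree.child_id), ("father", pedigree.father_id),
                 ("mother", pedigree.mother_id))
            ):
                calls[role] = GenotypeCall(
                    sample_id=sid,
                    alleles=_DOSAGE_TO_ALLELES[int(called[s, i])],
                    gl=tuple(round(float(v), 4) for v in gl[s, i]),
                    depth=int(depth[s, i]),
                    allele_depths=(int(depth[s, i] - alt_reads[s, i]), int(alt_reads[s, i])),
                    hemizygous=bool(hemi[s]),
                )
            rec = TrioRecord(site=site, child=calls["child"], father=calls["father"],
                             mother=calls["mother"])
            records.append(rec)

            key = site.key
            for s, role in enumerate(("child", "father", "mother")):
                if err_mask[s, i]:
                    error_calls.append((key, role))
            tag = tag_arr[i]
            if tag == "background":
                f = round(af_arr[i], 4)
                annotations[key] = AnnotationRecord(
                    key=key,
                    seen_in=frozenset({"WGS500", "1000G", "ESP"}),
                    af_by_resource={"1000G": f, "ESP": f},
                    internal_het=int(round(2 * 294 * f * (1 - f))),
                    internal_hom=int(round(294 * f * f)),
                    internal_hemi=int(round(100 * f)) if on_x else 0,
                    gerp=round(float(rng.normal(0.0, 1.5)), 2),
                    phylop=round(float(rng.normal(0.0, 1.2)), 2),
                    phastcons=round(float(rng.random() * 0.9), 3),
                    in_gerp_element=bool(rng.random() < 0.02),
                    in_phastcons_element=bool(rng.random() < 0.02),
                )
            else:
                annotations[key] = AnnotationRecord(
                    key=key,
                    seen_in=frozenset(),
                    af_by_resource={},
                    gerp=4.5,
                    phylop=3.2,
                    phastcons=0.99,
                )
                if tag == "de_novo":
                    truth.de_novo.append(key)
                else:
                    p = planted_arr[i]
                    ct = CausalTruth(
                        key=key, chrom=chrom, gene=p.gene, kind=p.kind,
                        expected_model=p.expected_model,
                        expected_consequence=p.expected_consequence,
                    )
                    truth.causal.append(ct)
                    if p.expected_model == "de_novo":
                        truth.de_novo.append(key)
                    if p.pair_tag is not None:
                        pair_keys.setdefault(p.pair_tag, []).append(key)

    # link compound-het mates
    for keys in pair_keys.values():
        if len(keys) == 2:
            for ct in truth.causal:
                if ct.key in keys:
                    ct.partner_key = keys[0] if ct.key == keys[1] else keys[1]

    regulatory = []
    for gene, tx in sorted(transcripts.items()):
        span = tx.span
        if span.start - 15_000 > 0:
            regulatory.append(
                GenomicInterval(tx.chrom, span.start - 15_000, span.start - 14_000,
                                label=f"reg_{gene}")
            )

    return SimulatedTrio(
        config=cfg,
        pedigree=pedigree,
        records=records,
        transcripts=[transcripts[g] for g in sorted(transcripts)],
        sequences=seqs,
        annotations=annotations,
        regulatory=regulatory,
        gene_list=list(DEFAULT_CANDIDATE_GENES),
        truth=truth,
        error_calls=error_calls,
    )


# ---------------------------------------------------------------------------
# Targeted-screen cohort fixtures
# ---------------------------------------------------------------------------

def simulate_screen_cohort(
    n_samples: int,
    rng: np.random.Generator,
    genes: tuple[str, ...] = ("KCNT1", "PIGQ", "CBL", "CSNK1G1"),
    variants_per_gene: int = 4,
):
    """Clean targeted-resequencing cohort: QC-passing records that are all
    either present in controls or common, so both screen models return no
    candidates. Planted positives are added by the caller."""
    from .cohort_screen import ScreenRecord

    records = []
    consequences = ["nonsynonymous", "synonymous", "nonsynonymous", "splice_donor"]
    for s in range(n_samples):
        sample = f"AUS_{s:03d}"
        for g, gene in enumerate(genes):
            for v in range(variants_per_gene):
                if rng.random() > 0.3:
                    continue
                pos = 1_000_000 + g * 100_000 + v * 1_000
                depth = 25 + int(rng.integers(0, 200))
                alt = depth // 2
                records.append(
                    ScreenRecord(
                        sample_id=sample,
                        key=f"chr{g + 1}:{pos}:A:G",
                        chrom=f"chr{g + 1}",
                        pos=pos,
                        qual=float(30 + rng.integers(0, 1000)),
                        qd=float(5 + rng.integers(0, 30)),
                        depth=depth,
                        allele_depths=(depth - alt, alt),
                        gt_class="het",
                        consequence=consequences[v % len(consequences)],
                        gene=gene,
                        control_af=float(0.01 + 0.2 * rng.random()),
                        present_in_controls=True,
                    )
                )
    return records
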