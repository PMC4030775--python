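"""Frequency/cohort exclusion, consequence classification, conservation and
regulatory prioritization, and exon-skip effect calculation.

Rarity rules (strict inequalities throughout):

* de novo model — drop any variant previously observed in a configured
  population resource (novelty requirement);
* recessive-type models — drop when any resource allele frequency exceeds
  0.005, when the internal cohort contains any homozygote or hemizygote,
  or more than five heterozygotes.

A position counts as evolutionarily conserved when GERP > 2 or phyloP > 2
or phastCons > 0.95, or when it lies in a GERP or phastCons constrained
element. Missing scores fail their clause; a wholly unannotated variant is
treated as novel (passes rarity) and non-conserved.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio.Seq import Seq

from .formats_io import GenomeIntervals, GenomicInterval, VariantSite
from .trio_models import ModelConfig

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

CONSEQUENCE_CLASSES = (
    "synonymous",
    "nonsynonymous",
    "stop_gain",
    "stop_loss",
    "splice_acceptor",
    "splice_donor",
    "frameshift_indel",
    "inframe_indel",
    "noncoding",
)

#: consequence classes treated as protein-altering in the coding prioritization
CODING_CLASSES = frozenset(
    {
        "nonsynonymous",
        "stop_gain",
        "stop_loss",
        "splice_acceptor",
        "splice_donor",
        "frameshift_indel",
        "inframe_indel",
    }
)


class TranscriptModelError(ValueError):
    """Transcript geometry is internally inconsistent."""


@dataclass
class AnnotationRecord:
    """Per-variant population, cohort and conservation annotation."""

    key: str
    seen_in: frozenset[str] = frozenset()
    af_by_resource: dict[str, float] = field(default_factory=dict)
    internal_het: int = 0
    internal_hom: int = 0
    internal_hemi: int = 0
    gerp: Optional[float] = None
    phylop: Optional[float] = None
    phastcons: Optional[float] = None
    in_gerp_element: bool = False
    in_phastcons_element: bool = False

    def __post_init__(self):
        for res, af in self.af_by_resource.items():
            if af is not None and not (0.0 <= af <= 1.0):
                raise ValueError(f"frequency out of [0,1] for {res}: {af}")
        if min(self.internal_het, self.internal_hom, self.internal_hemi) < 0:
            raise ValueError("cohort counts must be >= 0")


@dataclass(frozen=True)
class TranscriptModel:
    """Gene/transcript geometry; exons ordered 5'->3' in transcription order."""

    gene: str
    transcript_id: str
    chrom: str
    strand: str  # '+' | '-'
    exons: tuple[GenomicInterval, ...]
    cds_start: int  # genomic, 0-based inclusive
    cds_end: int  # genomic, 0-based exclusive

    def __post_init__(self):
        if self.strand not in "+-":
            raise TranscriptModelError(f"strand must be +/-, got {self.strand!r}")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise TranscriptModelError(f"overlapping exons in {self.transcript_id}")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise TranscriptModelError(
                f"exons of {self.transcript_id} not in transcription order"
            )
        span = self.span
        if not (span.start <= self.cds_start < self.cds_end <= span.end):
            raise TranscriptModelError(f"CDS bounds outside exon span in {self.transcript_id}")

    @property
    def span(self) -> GenomicInterval:
        start = min(e.start for e in self.exons)
        end = max(e.end for e in self.exons)
        return GenomicInterval(self.chrom, start, end, label=self.gene)

    def cds_positions(self) -> list[int]:
        """Genomic 0-based positions of coding bases, in transcription order."""
        genomic = sorted(self.exons, key=lambda e: e.start)
        positions: list[int] = []
        for ex in genomic:
            s, e = max(ex.start, self.cds_start), min(ex.end, self.cds_end)
            positions.extend(range(s, e))
        if self.strand == "-":
            positions.reverse()
        return positions


@dataclass(frozen=True)
class ConsequenceCall:
    consequence: str
    gene: str
    transcript_id: str
    label: str

    def __post_init__(self):
        if self.consequence not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def is_coding(self) -> bool:
        return self.consequence in CODING_CLASSES


# ---------------------------------------------------------------------------
# Rarity / conservation filters
# ---------------------------------------------------------------------------

def rarity_filter(
    ann: Optional[AnnotationRecord], model: str, cfg: ModelConfig
) -> tuple[bool, Optional[str]]:
    """(keep, drop_reason). Absent annotation is treated as novel (keep)."""
    if ann is None:
        return True, None
    if model == "de_novo":
        if ann.seen_in:
            return False, "seen_in:" + ",".join(sorted(ann.seen_in))
        return True, None
    for resource in sorted(ann.af_by_resource):
        af = ann.af_by_resource[resource]
        if af is not None and af > cfg.max_population_af:
            return False, f"frequency:{resource}"
    if ann.internal_hom > 0:
        return False, "internal_hom"
    if ann.internal_hemi > 0:
        return False, "internal_hemi"
    if ann.internal_het > cfg.max_internal_het:
        return False, "internal_het"
    return True, None


def conservation_pass(ann: Optional[AnnotationRecord]) -> bool:
    """GERP > 2 or phyloP > 2 or phastCons > 0.95 or in a constrained element."""
    if ann is None:
        return False
    return (
        (ann.gerp is not None and ann.gerp > 2)
        or (ann.phylop is not None and ann.phylop > 2)
        or (ann.phastcons is not None and ann.phastcons > 0.95)
        or ann.in_gerp_element
        or ann.in_phastcons_element
    )


# ---------------------------------------------------------------------------
# Consequence classification
# ---------------------------------------------------------------------------

def classify_consequence(
    site: VariantSite,
    tx: TranscriptModel,
    sequences,
    splice_margin: int = 2,
) -> ConsequenceCall:
    """Classify a biallelic variant against one transcript, strand-aware.

    ``sequences`` is any object with ``get_base(chrom, pos1)`` (e.g. a
    :class:`~epitrio.formats_io.SequenceStore`). SNVs in the CDS are
    translated against the reference codon; variants at the first two
    intronic positions flanking an internal exon boundary (transcription
    orientation) are splice_acceptor / splice_donor; coding indels are
    frameshift or in-frame by length modulo 3; everything else is noncoding.
    """
    pos0 = site.pos - 1
    ref, alt = site.ref.upper(), site.alts[0].upper()
    n_exons = len(tx.exons)

    for i, ex in enumerate(tx.exons):  # transcription order
        if tx.strand == "+":
            acceptor = range(ex.start - splice_margin, ex.start)
            donor = range(ex.end, ex.end + splice_margin)
        else:
            acceptor = range(ex.end, ex.end + splice_margin)
            donor = range(ex.start - splice_margin, ex.start)
        if i > 0 and pos0 in acceptor:
            return ConsequenceCall(
                "splice_acceptor", tx.gene, tx.transcript_id,
                _splice_label(tx, i, pos0, ref, alt, acceptor=True),
            )
        if i < n_exons - 1 and pos0 in donor:
            return ConsequenceCall(
                "splice_donor", tx.gene, tx.transcript_id,
                _splice_label(tx, i, pos0, ref, alt, acceptor=False),
            )

    cds = tx.cds_positions()
    if len(cds) % 3 != 0:
        raise TranscriptModelError(
            f"CDS length {len(cds)} of {tx.transcript_id} is not a multiple of 3"
        )
    cds_index = {p: i for i, p in enumerate(cds)}

    if len(ref) != len(alt):  # indel
        affected = set(range(pos0, pos0 + max(len(ref), 1)))
        if affected & cds_index.keys():
            delta = abs(len(alt) - len(ref))
            cls = "frameshift_indel" if delta % 3 else "inframe_indel"
            return ConsequenceCall(cls, tx.gene, tx.transcript_id, f"c.{ref}>{alt}")
        return ConsequenceCall("noncoding", tx.gene, tx.transcript_id, ".")

    if pos0 not in cds_index:
        return ConsequenceCall("noncoding", tx.gene, tx.transcript_id, ".")

    i = cds_index[pos0]
    codon_start = 3 * (i // 3)
    codon_pos = cds[codon_start : codon_start + 3]
    bases = [sequences.get_base(tx.chrom, p + 1).upper() for p in codon_pos]
    if tx.strand == "-":
        bases = [COMPLEMENT[b] for b in bases]
    ref_t = ref if tx.strand == "+" else COMPLEMENT[ref]
    alt_t = alt if tx.strand == "+" else COMPLEMENT[alt]
    offset = i - codon_start
    if bases[offset] != ref_t:
        raise ValueError(
            f"reference mismatch at {tx.chrom}:{site.pos}: transcript sequence has "
            f"{bases[offset]} (transcript strand), variant ref is {ref_t}"
        )
    codon_ref = "".join(bases)
    codon_alt = "".join(alt_t if j == offset else b for j, b in enumerate(bases))
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    label = f"c.{i + 1}{ref_t}>{alt_t}"
    if aa_alt == aa_ref:
        cls = "synonymous"
    elif aa_alt == "*":
        cls = "stop_gain"
    elif aa_ref == "*":
        cls = "stop_loss"
    else:
        cls = "nonsynonymous"
    return ConsequenceCall(cls, tx.gene, tx.transcript_id, label)


def _splice_label(tx: TranscriptModel, exon_i: int, pos0: int, ref: str, alt: str, acceptor: bool) -> str:
    """HGVS-like label, e.g. c.690-2A>G for an acceptor-site substitution."""
    cds = tx.cds_positions()
    cds_index = {p: i for i, p in enumerate(cds)}
    ex = tx.exons[exon_i]
    if tx.strand == "+":
        dist = (ex.start - pos0) if acceptor else (pos0 - (ex.end - 1))
        anchor_pos = ex.start if acceptor else ex.end - 1
        ref_t, alt_t = ref, alt
    else:
        dist = (pos0 - (ex.end - 1)) if acceptor else (ex.start - pos0)
        anchor_pos = ex.end - 1 if acceptor else ex.start
        ref_t, alt_t = COMPLEMENT.get(ref, "N"), COMPLEMENT.get(alt, "N")
    anchor = cds_index.get(anchor_pos)
    sign = "-" if acceptor else "+"
    if anchor is None:
        return f"splice_{'acceptor' if acceptor else 'donor'}(exon{exon_i + 1}){sign}{dist}"
    return f"c.{anchor + 1}{sign}{dist}{ref_t}>{alt_t}"


def classify_against_transcripts(
    site: VariantSite,
    transcripts: Iterable[TranscriptModel],
    sequences,
    splice_margin: int = 2,
) -> Optional[ConsequenceCall]:
    """Most severe consequence across overlapping transcripts, or None."""
    severity = {c: i for i, c in enumerate(CONSEQUENCE_CLASSES)}
    best: Optional[ConsequenceCall] = None
    pos0 = site.pos - 1
    for tx in transcripts:
        span = tx.span
        if tx.chrom != site.chrom:
            continue
        if not (span.start - splice_margin <= pos0 < span.end + splice_margin):
            continue
        call = classify_consequence(site, tx, sequences, splice_margin)
        rank = (call.is_coding, -severity[call.consequence])
        if best is None or rank > (best.is_coding, -severity[best.consequence]):
            best = call
    return best


# ---------------------------------------------------------------------------
# Regulatory screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegulatoryHit:
    """A conserved variant in a regulatory region near a candidate gene."""

    gene: str
    distance_bp: int
    interval: GenomicInterval


def regulatory_candidate(
    site: VariantSite,
    ann: Optional[AnnotationRecord],
    regulatory: GenomeIntervals,
    gene_spans: dict[str, GenomicInterval],
    window: int = 50_000,
) -> Optional[RegulatoryHit]:
    """Conserved + inside a regulatory interval + within `window` bp of a
    candidate gene span (distance 0 inside the span). Returns the nearest
    qualifying gene."""
    if not conservation_pass(ann):
        return None
    pos0 = site.pos - 1
    hits = regulatory.query_point(site.chrom, pos0)
    if not hits:
        return None
    best: Optional[RegulatoryHit] = None
    for gene in sorted(gene_spans):
        span = gene_spans[gene]
        if span.chrom != site.chrom:
            continue
        d = span.distance_to(pos0)
        if d <= window and (best is None or d < best.distance_bp):
            best = RegulatoryHit(gene=gene, distance_bp=d, interval=hits[0])
    return best


# ---------------------------------------------------------------------------
# Exon-skip effect
# ---------------------------------------------------------------------------

def exon_skip_effect(tx: TranscriptModel, exon_index: int) -> tuple[bool, Optional[int], int]:
    """Effect of skipping one exon: (in_frame, aa_deleted, coding_nt_removed).

    ``exon_index`` is 1-based in transcription order. A 132-nt fully coding
    exon gives (True, 44, 132): an in-frame deletion of 44 amino acids.
    """
    if not (1 <= exon_index <= len(tx.exons)):
        raise IndexError(f"exon_index {exon_index} outside 1..{len(tx.exons)}")
    ex = tx.exons[exon_index - 1]
    nt = max(0, min(ex.end, tx.cds_end) - max(ex.start, tx.cds_start))
    if nt == 0:
        warnings.warn(
            f"exon {exon_index} of {tx.transcript_id} is entirely untranslated",
            stacklevel=2,
        )
        return True, 0, 0
    in_frame = nt % 3 == 0
    return in_frame, (nt // 3 if in_frame else None), nt


# ---------------------------------------------------------------------------
# Tables and transcript files
# ---------------------------------------------------------------------------

_ANN_COLUMNS = [
    "key", "seen_in", "af_1000G", "af_ESP", "internal_het", "internal_hom",
    "internal_hemi", "gerp", "phylop", "phastcons", "in_gerp_element",
    "in_phastcons_element",
]


def write_annotation_table(records: Iterable[AnnotationRecord], path) -> None:
    rows = []
    for ann in records:
        rows.append({
            "key": ann.key,
            "seen_in": ",".join(sorted(ann.seen_in)) if ann.seen_in else ".",
            "af_1000G": ann.af_by_resource.get("1000G", ""),
            "af_ESP": ann.af_by_resource.get("ESP", ""),
            "internal_het": ann.internal_het,
            "internal_hom": ann.internal_hom,
            "internal_hemi": ann.internal_hemi,
            "gerp": "" if ann.gerp is None else ann.gerp,
            "phylop": "" if ann.phylop is None else ann.phylop,
            "phastcons": "" if ann.phastcons is None else ann.phastcons,
            "in_gerp_element": int(ann.in_gerp_element),
            "in_phastcons_element": int(ann.in_phastcons_element),
        })
    pd.DataFrame(rows, columns=_ANN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotation_table(path) -> dict[str, AnnotationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"key": str, "seen_in": str})
    out: dict[str, AnnotationRecord] = {}
    for row in df.itertuples(index=False):
        seen = frozenset() if (pd.isna(row.seen_in) or row.seen_in == ".") else frozenset(
            row.seen_in.split(",")
        )
        afs = {}
        for res, col in (("1000G", row.af_1000G), ("ESP", row.af_ESP)):
            if not pd.isna(col):
                afs[res] = float(col)
        def opt(v):
            return None if pd.isna(v) else float(v)
        ann = AnnotationRecord(
            key=row.key,
            seen_in=seen,
            af_by_resource=afs,
            internal_het=int(row.internal_het),
            internal_hom=int(row.internal_hom),
            internal_hemi=int(row.internal_hemi),
            gerp=opt(row.gerp),
            phylop=opt(row.phylop),
            phastcons=opt(row.phastcons),
            in_gerp_element=bool(row.in_gerp_element),
            in_phastcons_element=bool(row.in_phastcons_element),
        )
        out[ann.key] = ann
    return out


def write_transcripts_bed12(transcripts: Iterable[TranscriptModel], path) -> None:
    """BED12: name is GENE|TRANSCRIPT, thickStart/thickEnd is the CDS."""
    with open(path, "w") as fh:
        for tx in transcripts:
            genomic = sorted(tx.exons, key=lambda e: e.start)
            start = genomic[0].start
            end = genomic[-1].end
            sizes = ",".join(str(len(e)) for e in genomic)
            starts = ",".join(str(e.start - start) for e in genomic)
            fh.write(
                "\t".join([
                    tx.chrom, str(start), str(end), f"{tx.gene}|{tx.transcript_id}",
                    "0", tx.strand, str(tx.cds_start), str(tx.cds_end), "0",
                    str(len(genomic)), sizes, starts,
                ]) + "\n"
            )


def read_transcripts_bed12(path) -> list[TranscriptModel]:
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise ValueError(f"{path}:{lineno}: BED12 needs 12 columns")
        chrom, start = f[0], int(f[1])
        name = f[3]
        gene, _, txid = name.partition("|")
        strand = f[5]
        cds_start, cds_end = int(f[6]), int(f[7])
        sizes = [int(s) for s in f[10].rstrip(",").split(",")]
        offsets = [int(s) for s in f[11].rstrip(",").split(",")]
        exons = [
            GenomicInterval(chrom, start + off, start + off + size)
            for off, size in zip(offsets, sizes)
        ]
        if strand == "-":
            exons = exons[::-1]
        out.append(
            TranscriptModel(
                gene=gene, transcript_id=txid or gene, chrom=chrom, strand=strand,
                exons=tuple(exons), cds_start=cds_start, cds_end=cds_end,
            )
        )
    return out


def read_gene_list(path) -> list[str]:
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


def gene_spans(transcripts: Iterable[TranscriptModel]) -> dict[str, GenomicInterval]:
    """Per-gene union span across its transcripts."""
    spans: dict[str, GenomicInterval] = {}
    for tx in transcripts:
        span = tx.span
        prev = spans.get(tx.gene)
        if prev is None:
            spans[tx.gene] = span
        else:
            spans[tx.gene] = GenomicInterval(
                span.chrom, min(prev.start, span.start), max(prev.end, span.end), label=tx.gene
            )
    return spans


#: the default candidate-gene panel for the regulatory screen
DEFAULT_CANDIDATE_GENES = [
    "KCNQ2", "SCN2A", "SCN1A", "SPTAN1", "SRGAP2", "MAGI1", "PLCB1", "STXBP1",
    "PNPO", "PCDH19", "GRIN2A", "MAPK10", "CDKL5", "SLC25A22", "ERBB4", "ARX",
]
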