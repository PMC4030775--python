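"""Per-trio prioritization workflow: inheritance models -> GLR -> rarity ->
consequence/conservation/regulatory prioritization -> UPD/ROH scan.

The UPD scan always runs; on an isodisomy verdict the recessive model is
re-run restricted to that chromosome with the homozygosity requirement
kept but without requiring the non-contributing parent to be
heterozygous — the configuration a duplicated single-parent haplotype
produces (such sites are Mendelian-inconsistent and invisible to the
standard recessive rule).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .annotation_filters import (
    AnnotationRecord,
    ConsequenceCall,
    TranscriptModel,
    classify_against_transcripts,
    conservation_pass,
    gene_spans,
    rarity_filter,
    regulatory_candidate,
)
from .formats_io import GenomeIntervals, GenomicInterval, Pedigree, TrioRecord, is_x_chromosome
from .trio_models import (
    CandidateVariant,
    ModelConfig,
    de_novo_genotype_config,
    detect_compound_het,
    detect_de_novo,
    detect_simple_recessive,
    detect_x_linked,
    glr_passes,
)
from .upd_roh import ROHConfig, ROHSegment, UPDConfig, UPDReport, call_isodisomy, find_roh


@dataclass
class StageCounts:
    """Ordered per-stage accounting: (stage name, variants in, variants out)."""

    entries: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {stage}: out ({n_out}) > in ({n_in})")
        self.entries.append((stage, n_in, n_out))

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {stage: (n_in, n_out) for stage, n_in, n_out in self.entries}


@dataclass
class PipelineResult:
    candidates: list[CandidateVariant]
    de_novo_sites: list[CandidateVariant]  # genome-wide, after GLR + novelty
    upd_reports: dict[str, UPDReport]
    roh: list[ROHSegment]
    stage_counts: StageCounts

    def by_model(self, model: str) -> list[CandidateVariant]:
        return [c for c in self.candidates if c.model == model]

    @property
    def keys_by_model(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for c in self.candidates:
            out.setdefault(c.model, []).append(c.key)
        return out


def _chrom_sort_key(chrom: str):
    body = chrom[3:] if chrom.startswith("chr") else chrom
    return (0, int(body)) if body.isdigit() else (1, body)


def _sorted_records(records: Iterable[TrioRecord]) -> list[TrioRecord]:
    return sorted(
        records,
        key=lambda r: (_chrom_sort_key(r.site.chrom), r.site.pos, r.site.ref, r.site.alts),
    )


def run_pipeline(
    records: Iterable[TrioRecord],
    pedigree: Pedigree,
    annotations: dict[str, AnnotationRecord],
    transcripts: Sequence[TranscriptModel],
    regulatory: GenomeIntervals | Iterable[GenomicInterval],
    gene_list: Sequence[str],
    sequences,
    cfg: Optional[ModelConfig] = None,
    upd_cfg: Optional[UPDConfig] = None,
    roh_cfg: Optional[ROHConfig] = None,
    regulatory_window: int = 50_000,
) -> PipelineResult:
    """Execute the full per-trio cascade; deterministic and order-invariant."""
    cfg = cfg or ModelConfig()
    upd_cfg = upd_cfg or UPDConfig()
    roh_cfg = roh_cfg or ROHConfig()
    if not isinstance(regulatory, GenomeIntervals):
        regulatory = GenomeIntervals(regulatory)

    records = _sorted_records(records)
    complete = [r for r in records if not r.any_missing]
    counts = StageCounts()
    counts.add("input", len(records), len(records))
    counts.add("complete_genotypes", len(records), len(complete))

    tx_by_chrom: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        tx_by_chrom.setdefault(tx.chrom, []).append(tx)

    def classify(rec: TrioRecord) -> Optional[ConsequenceCall]:
        txs = tx_by_chrom.get(rec.site.chrom, [])
        if not txs:
            return None
        return classify_against_transcripts(rec.site, txs, sequences)

    def annotate_rarity(cand: CandidateVariant, model: str) -> bool:
        ann = annotations.get(cand.key)
        keep, reason = rarity_filter(ann, model, cfg)
        cand.evidence.append(("rarity", reason if reason else "novel/rare", keep))
        return keep

    def annotate_consequence(cand: CandidateVariant) -> bool:
        call = classify(cand.record)
        if call is None or not call.is_coding:
            label = "noncoding" if call is None else call.consequence
            cand.evidence.append(("consequence", label, False))
            return False
        cand.gene = cand.gene or call.gene
        cand.evidence.append(("consequence", f"{call.consequence}:{call.label}", True))
        ann = annotations.get(cand.key)
        cand.evidence.append(("conserved", conservation_pass(ann), True))
        return True

    candidates: list[CandidateVariant] = []

    # ----- de novo cascade -------------------------------------------------
    dn_config = [r for r in complete if de_novo_genotype_config(r)]
    counts.add("de_novo:genotype_config", len(complete), len(dn_config))
    dn_glr = [c for c in (detect_de_novo(r, cfg) for r in dn_config) if c is not None]
    counts.add("de_novo:glr", len(dn_config), len(dn_glr))
    dn_novel = [c for c in dn_glr if annotate_rarity(c, "de_novo")]
    counts.add("de_novo:novelty", len(dn_glr), len(dn_novel))
    dn_coding = [c for c in dn_novel if annotate_consequence(c)]
    counts.add("de_novo:coding", len(dn_novel), len(dn_coding))
    candidates.extend(dn_coding)

    # ----- simple recessive cascade ----------------------------------------
    rec_config = [
        c for c in (detect_simple_recessive(r, cfg) for r in complete) if c is not None
    ]
    counts.add("recessive:genotype_config", len(complete), len(rec_config))
    rec_glr = [
        c for c in rec_config if all(glr_passes(call, cfg) for call in c.record.calls)
    ]
    counts.add("recessive:glr", len(rec_config), len(rec_glr))
    rec_rare = [c for c in rec_glr if annotate_rarity(c, "simple_recessive")]
    counts.add("recessive:rarity", len(rec_glr), len(rec_rare))
    rec_coding = [c for c in rec_rare if annotate_consequence(c)]
    counts.add("recessive:coding", len(rec_rare), len(rec_coding))

    # ----- compound het cascade --------------------------------------------
    ch_pool = []
    for r in complete:
        if r.child.gt_class != "het":
            continue
        f, m = r.father.gt_class, r.mother.gt_class
        if {f, m} == {"het", "hom_ref"}:
            ch_pool.append(r)
    counts.add("compound_het:genotype_config", len(complete), len(ch_pool))
    ch_glr = [r for r in ch_pool if all(glr_passes(call, cfg) for call in r.calls)]
    counts.add("compound_het:glr", len(ch_pool), len(ch_glr))
    ch_rare = []
    for r in ch_glr:
        keep, _ = rarity_filter(annotations.get(r.key), "compound_het", cfg)
        if keep:
            ch_rare.append(r)
    counts.add("compound_het:rarity", len(ch_glr), len(ch_rare))
    by_gene: dict[str, list[TrioRecord]] = {}
    coding_calls: dict[str, ConsequenceCall] = {}
    for r in ch_rare:
        call = classify(r)
        if call is not None and call.is_coding:
            by_gene.setdefault(call.gene, []).append(r)
            coding_calls[r.key] = call
    n_coding = sum(len(v) for v in by_gene.values())
    counts.add("compound_het:coding", len(ch_rare), n_coding)
    ch_candidates: list[CandidateVariant] = []
    for gene in sorted(by_gene):
        for a, b in detect_compound_het(by_gene[gene], cfg, gene=gene):
            for cand in (a, b):
                call = coding_calls[cand.key]
                cand.evidence.append(
                    ("consequence", f"{call.consequence}:{call.label}", True)
                )
                ch_candidates.append(cand)
    counts.add("compound_het:paired", n_coding, len({c.key for c in ch_candidates}))
    candidates.extend(rec_coding)
    candidates.extend(ch_candidates)

    # ----- X-linked cascade -------------------------------------------------
    if pedigree.child_sex == "male":
        x_records = [r for r in complete if is_x_chromosome(r.site.chrom)]
        x_config = [
            c for c in (detect_x_linked(r, pedigree, cfg) for r in x_records)
            if c is not None
        ]
        counts.add("x_linked:genotype_config", len(x_records), len(x_config))
        x_glr = [
            c for c in x_config if all(glr_passes(call, cfg) for call in c.record.calls)
        ]
        counts.add("x_linked:glr", len(x_config), len(x_glr))
        x_rare = [c for c in x_glr if annotate_rarity(c, "x_linked")]
        counts.add("x_linked:rarity", len(x_glr), len(x_rare))
        x_coding = [c for c in x_rare if annotate_consequence(c)]
        counts.add("x_linked:coding", len(x_rare), len(x_coding))
        candidates.extend(x_coding)

    # ----- regulatory screen ------------------------------------------------
    spans = {
        g: s for g, s in gene_spans(transcripts).items() if g in set(gene_list)
    }
    coding_ids = {id(c) for c in dn_coding} | {id(c) for c in rec_coding}
    reg_pool = [c for c in dn_novel + rec_rare if id(c) not in coding_ids]
    reg_candidates: list[CandidateVariant] = []
    for cand in reg_pool:
        hit = regulatory_candidate(
            cand.record.site, annotations.get(cand.key), regulatory, spans,
            window=regulatory_window,
        )
        if hit is None:
            continue
        reg = CandidateVariant(
            record=cand.record,
            model="regulatory",
            gene=hit.gene,
            evidence=list(cand.evidence)
            + [
                ("underlying_model", cand.model, True),
                ("regulatory_region", hit.interval.label or "region", True),
                ("gene_distance_bp", hit.distance_bp, True),
            ],
        )
        reg_candidates.append(reg)
    counts.add("regulatory:screen", len(reg_pool), len(reg_candidates))
    candidates.extend(reg_candidates)

    # ----- UPD / ROH scan (always runs) ------------------------------------
    by_chrom: dict[str, list[TrioRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.site.chrom, []).append(r)
    upd_reports: dict[str, UPDReport] = {}
    roh_segments: list[ROHSegment] = []
    male_child = pedigree.child_sex == "male"
    for chrom in sorted(by_chrom, key=_chrom_sort_key):
        chrom_records = by_chrom[chrom]
        if is_x_chromosome(chrom) and male_child:
            # hemizygous X is homozygous by construction; not evaluable
            report = call_isodisomy(chrom, chrom_records, upd_cfg)
            report.verdict = "none"
            report.note = "chrX hemizygous in male child; isodisomy not evaluated"
            upd_reports[chrom] = report
            continue
        upd_reports[chrom] = call_isodisomy(chrom, chrom_records, upd_cfg)
        roh_segments.extend(find_roh(chrom_records, roh_cfg))

    # ----- UPD-triggered recessive rescan -----------------------------------
    existing = {(c.model, c.key) for c in candidates}
    rescan_candidates: list[CandidateVariant] = []
    n_rescan_pool = 0
    for chrom, report in upd_reports.items():
        if report.verdict == "none":
            continue
        parent_role = "father" if report.verdict == "paternal_isodisomy" else "mother"
        pool = [r for r in complete if r.site.chrom == chrom]
        n_rescan_pool += len(pool)
        for r in pool:
            contributing = r.father if parent_role == "father" else r.mother
            if r.child.gt_class != "hom_alt" or not contributing.carries_alt:
                continue
            if not (glr_passes(r.child, cfg) and glr_passes(contributing, cfg)):
                continue
            cand = CandidateVariant(
                record=r,
                model="simple_recessive",
                evidence=[
                    ("upd_rescan", f"{chrom}:{report.verdict}", True),
                    ("genotype_config",
                     f"child hom-alt / {parent_role} carries alt", True),
                ],
            )
            if not annotate_rarity(cand, "simple_recessive"):
                continue
            if not annotate_consequence(cand):
                continue
            if ("simple_recessive", cand.key) in existing:
                continue
            rescan_candidates.append(cand)
            existing.add(("simple_recessive", cand.key))
    counts.add("upd_rescan", n_rescan_pool, len(rescan_candidates))
    candidates.extend(rescan_candidates)

    # annotate recessive candidates inside ROH segments
    roh_by_chrom: dict[str, list[ROHSegment]] = {}
    for seg in roh_segments:
        roh_by_chrom.setdefault(seg.chrom, []).append(seg)
    for cand in candidates:
        if cand.model != "simple_recessive":
            continue
        for seg in roh_by_chrom.get(cand.record.site.chrom, []):
            if seg.start <= cand.record.site.pos <= seg.end:
                cand.evidence.append(("in_roh", f"{seg.chrom}:{seg.start}-{seg.end}", True))
                break

    return PipelineResult(
        candidates=candidates,
        de_novo_sites=dn_novel,
        upd_reports=upd_reports,
        roh=roh_segments,
        stage_counts=counts,
    )


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

def write_candidate_report(candidates: Sequence[CandidateVariant], path) -> None:
    """Tab-separated candidate table, grouped by model, with evidence trails."""
    order = {m: i for i, m in enumerate(
        ("de_novo", "simple_recessive", "compound_het", "x_linked", "regulatory")
    )}
    rows = sorted(candidates, key=lambda c: (order.get(c.model, 99), c.key))
    with open(path, "w") as fh:
        fh.write("model\tkey\tgene\tpartner\tchild_gt\tfather_gt\tmother_gt\tevidence\n")
        for c in rows:
            ev = ";".join(f"{name}={value}({'+' if ok else '-'})" for name, value, ok in c.evidence)
            fh.write(
                f"{c.model}\t{c.key}\t{c.gene or '.'}\t{c.partner or '.'}\t"
                f"{c.record.child.gt_class}\t{c.record.father.gt_class}\t"
                f"{c.record.mother.gt_class}\t{ev}\n"
            )


def write_run_summary(result: PipelineResult, path) -> None:
    summary = {
        "n_candidates": len(result.candidates),
        "candidates_by_model": {
            m: sorted(keys) for m, keys in result.keys_by_model.items()
        },
        "n_de_novo_sites": len(result.de_novo_sites),
        "upd_verdicts": {c: r.verdict for c, r in result.upd_reports.items()},
        "roh": [
            {"chrom": s.chrom, "start": s.start, "end": s.end, "n_hom": s.n_hom}
            for s in result.roh
        ],
        "stage_counts": [
            {"stage": s, "in": i, "out": o} for s, i, o in result.stage_counts.entries
        ],
    }
    Path(path).write_text(json.dumps(summary, indent=1) + "\n")
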