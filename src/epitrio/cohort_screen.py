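"""Targeted-resequencing screen: variant QC cascade and model-based selection.

The QC cascade removes the classic capture/PCR artifact classes seen in
molecular-inversion-probe (MIP) resequencing: skewed allele balance on het
calls (> 0.70 of reads on the major allele), low site quality (QUAL < 30),
low quality-by-depth (QD < 5), thin coverage (< 25x), variant clusters
(>= 3 calls inside any 10 bp window) and calls inside or abutting reference
homopolymer runs (>= 5 identical bases). All thresholds are strict
inequalities, so boundary values (AB = 0.70, QUAL = 30, QD = 5, DP = 25)
pass.

Candidate selection then applies the inheritance model: dominant/de novo
candidates must be absent from the control resource; recessive candidates
need a control frequency < 1% and two qualifying alleles in the gene
(a homozygote, or two distinct surviving variants). Only protein-altering
classes (non-synonymous, splice-site, frameshift, stop) are considered.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from pydantic import BaseModel, Field

QUALIFYING_CONSEQUENCES = frozenset(
    {
        "nonsynonymous",
        "splice_acceptor",
        "splice_donor",
        "frameshift_indel",
        "stop_gain",
        "stop_loss",
    }
)

#: fixed clause evaluation order for reporting
QC_CLAUSES = ("allele_balance", "qual", "qd", "depth", "cluster", "homopolymer")


class ScreenConfig(BaseModel):
    ab_max: float = Field(default=0.70, gt=0.5, le=1.0)
    qual_min: float = Field(default=30.0, gt=0)
    qd_min: float = Field(default=5.0, gt=0)
    depth_min: int = Field(default=25, gt=0)
    cluster_window_bp: int = Field(default=10, gt=0)
    cluster_count: int = Field(default=3, gt=0)
    homopolymer_min: int = Field(default=5, gt=0)
    recessive_af_max: float = Field(default=0.01, gt=0)


@dataclass(frozen=True)
class ScreenRecord:
    """One sample's called variant in the targeted screen."""

    sample_id: str
    key: str  # chrom:pos:ref:alt
    chrom: str
    pos: int  # 1-based
    qual: float
    qd: float
    depth: int
    allele_depths: tuple[int, ...]
    gt_class: str  # het | hom_alt
    consequence: str
    gene: str
    control_af: float = 0.0
    present_in_controls: bool = False

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not (0.0 <= self.control_af <= 1.0):
            raise ValueError("control_af must be in [0,1]")


@dataclass
class QCResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)  # triggered clauses, in order
    unevaluable: list[str] = field(default_factory=list)


def allele_balance(rec: ScreenRecord) -> Optional[float]:
    """Fraction of reads supporting the major allele of a het call."""
    total = sum(rec.allele_depths)
    if total == 0:
        return None
    return max(rec.allele_depths) / total


def _homopolymer_hit(context: str, context_start: int, pos: int, min_run: int) -> bool:
    """Variant inside or immediately adjacent to a reference run >= min_run."""
    i = 0
    n = len(context)
    while i < n:
        j = i
        while j < n and context[j] == context[i]:
            j += 1
        if j - i >= min_run:
            run_start = context_start + i  # 1-based
            run_end = context_start + j - 1
            if run_start - 1 <= pos <= run_end + 1:
                return True
        i = j
    return False


def _cluster_hit(pos: int, neighbors: Iterable[int], window: int, count: int) -> bool:
    """>= count variant positions (incl. this one) within any window-bp span."""
    pts = sorted(set(neighbors) | {pos})
    for i in range(len(pts)):
        j = i + count - 1
        if j >= len(pts):
            break
        if pts[j] - pts[i] + 1 <= window and pts[i] <= pos <= pts[j]:
            return True
    return False


def qc_filter(
    rec: ScreenRecord,
    context: Optional[str],
    context_start: Optional[int],
    neighbors: Iterable[int],
    cfg: Optional[ScreenConfig] = None,
) -> QCResult:
    """Evaluate the six QC clauses; any triggered clause fails the record.

    ``context`` is the reference sequence window around the variant (with
    ``context_start`` its 1-based genomic position); if missing, the
    homopolymer clause is marked unevaluable and does not fail the record.
    ``neighbors`` are nearby variant positions on the same chromosome.
    """
    cfg = cfg or ScreenConfig()
    result = QCResult(passed=True)

    ab = allele_balance(rec) if rec.gt_class == "het" else None
    if rec.gt_class == "het" and ab is None:
        result.unevaluable.append("allele_balance")
    elif ab is not None and ab > cfg.ab_max:
        result.reasons.append("allele_balance")

    if rec.qual < cfg.qual_min:
        result.reasons.append("qual")
    if rec.qd < cfg.qd_min:
        result.reasons.append("qd")
    if rec.depth < cfg.depth_min:
        result.reasons.append("depth")

    if _cluster_hit(rec.pos, neighbors, cfg.cluster_window_bp, cfg.cluster_count):
        result.reasons.append("cluster")

    if context is None or context_start is None:
        result.unevaluable.append("homopolymer")
    elif _homopolymer_hit(context, context_start, rec.pos, cfg.homopolymer_min):
        result.reasons.append("homopolymer")

    result.passed = not result.reasons
    return result


@dataclass(frozen=True)
class ScreenCandidate:
    sample_id: str
    gene: str
    model: str  # dominant | recessive
    variant_keys: tuple[str, ...]


def select_candidates(
    records: Sequence[ScreenRecord],
    model: str,
    cfg: Optional[ScreenConfig] = None,
) -> list[ScreenCandidate]:
    """Model-based selection among QC-passing records of one or more genes.

    dominant: each protein-altering variant absent from controls is a
    candidate. recessive: per sample and gene, a protein-altering
    homozygote with control AF < 1%, or two distinct such surviving
    variants, forms a candidate.
    """
    if model not in ("dominant", "recessive"):
        raise ValueError(f"model must be dominant/recessive, got {model!r}")
    cfg = cfg or ScreenConfig()
    qualifying = [r for r in records if r.consequence in QUALIFYING_CONSEQUENCES]
    out: list[ScreenCandidate] = []
    if model == "dominant":
        for rec in qualifying:
            if not rec.present_in_controls:
                out.append(
                    ScreenCandidate(rec.sample_id, rec.gene, "dominant", (rec.key,))
                )
        return out
    # recessive
    by_sample_gene: dict[tuple[str, str], list[ScreenRecord]] = {}
    for rec in qualifying:
        if rec.control_af < cfg.recessive_af_max:
            by_sample_gene.setdefault((rec.sample_id, rec.gene), []).append(rec)
    for (sample, gene), recs in sorted(by_sample_gene.items()):
        homs = [r for r in recs if r.gt_class == "hom_alt"]
        hets = sorted({r.key for r in recs if r.gt_class == "het"})
        for hom in homs:
            out.append(ScreenCandidate(sample, gene, "recessive", (hom.key,)))
        if len(hets) >= 2:
            out.append(ScreenCandidate(sample, gene, "recessive", tuple(hets)))
    return out


def write_screen_report(
    records: Sequence[ScreenRecord],
    results: Sequence[QCResult],
    path,
) -> None:
    """Tab-separated QC audit: one row per record, one column per clause."""
    with open(path, "w") as fh:
        fh.write("sample\tkey\tgene\tpassed\t" + "\t".join(QC_CLAUSES) + "\n")
        for rec, res in zip(records, results):
            cells = []
            for clause in QC_CLAUSES:
                if clause in res.reasons:
                    cells.append("FAIL")
                elif clause in res.unevaluable:
                    cells.append("NA")
                else:
                    cells.append("ok")
            fh.write(
                f"{rec.sample_id}\t{rec.key}\t{rec.gene}\t"
                f"{'PASS' if res.passed else 'FAIL'}\t" + "\t".join(cells) + "\n"
            )
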