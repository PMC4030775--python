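"""Uniparental-isodisomy detection and runs-of-homozygosity scanning.

Isodisomy (both homologues inherited as two copies of one parental
haplotype) leaves two chromosome-wide footprints in trio genotypes:

* Mendelian inconsistencies whose configurations are explicable by a
  single parent's allele pool duplicated (e.g. child 1/1, father 0/1,
  mother 0/0: the father's alt, twice, explains the child);
* near-complete homozygosity of the child's variant calls, summarized as
  the proportion of homozygous calls in 500 kb windows.

A chromosome is called paternal (maternal) isodisomy when the median
window homozygosity, the fraction of single-parent-explicable errors and
the absolute error count all clear their thresholds. Heterodisomy (two
different homologues from one parent) is not detectable from
homozygosity alone and is out of scope; the report notes only isodisomy.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from pydantic import BaseModel, Field

from .formats_io import TrioRecord

MendelianStatus = str  # consistent | inconsistent | uninformative
ParentSupport = str  # paternal_only | maternal_only | either | neither


class UPDConfig(BaseModel):
    """Thresholds of the isodisomy caller (all configurable).

    window_bp: homozygosity window size.
    hom_median_min: minimum median window homozygosity fraction.
    support_min: minimum fraction of inconsistent sites explicable by the
        implicated parent alone.
    count_min: minimum inconsistent-site count per chromosome.
    min_informative_sites: below this, the verdict is none with an
        "insufficient data" note.
    """

    window_bp: int = Field(default=500_000, gt=0)
    hom_median_min: float = 0.98
    support_min: float = 0.95
    count_min: int = 50
    min_informative_sites: int = 200


class ROHConfig(BaseModel):
    min_length_bp: int = Field(default=1_000_000, gt=0)
    het_tolerance: int = Field(default=2, ge=0)


@dataclass(frozen=True)
class MendelianCheck:
    key: str
    status: MendelianStatus
    parent_support: Optional[ParentSupport] = None


@dataclass
class UPDReport:
    chrom: str
    n_sites: int  # informative sites on the chromosome
    n_inconsistent: int
    paternal_support_fraction: float
    maternal_support_fraction: float
    window_hom_fractions: list[tuple[int, Optional[float]]]
    verdict: str  # none | paternal_isodisomy | maternal_isodisomy
    note: str = ""

    @property
    def median_window_hom(self) -> Optional[float]:
        vals = sorted(f for _, f in self.window_hom_fractions if f is not None)
        if not vals:
            return None
        mid = len(vals) // 2
        if len(vals) % 2:
            return vals[mid]
        return 0.5 * (vals[mid - 1] + vals[mid])


@dataclass(frozen=True)
class ROHSegment:
    chrom: str
    start: int  # 1-based position of first homozygous call
    end: int  # 1-based position of last homozygous call
    n_hom: int
    n_het_tolerated: int

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Mendelian transmission check
# ---------------------------------------------------------------------------

def _single_parent_explains(parent_pool: tuple[int, ...], child: tuple[int, ...]) -> bool:
    """Can two draws (with replacement) from one parent produce the child?"""
    child_ms = tuple(sorted(child))
    for x, y in itertools.product(parent_pool, repeat=2):
        if tuple(sorted((x, y))) == child_ms:
            return True
    return False


def check_mendelian(record: TrioRecord) -> MendelianCheck:
    """Classify a trio genotype as consistent / inconsistent / uninformative.

    Inconsistent means no pair (one allele from each parent) produces the
    child genotype. ``parent_support`` marks which single parent's allele
    pool, duplicated, could alone explain the child; hemizygous male-X
    children are checked against the mother alone.
    """
    key = record.key
    child, father, mother = record.child, record.father, record.mother
    if record.any_missing:
        return MendelianCheck(key, "uninformative")
    if all(c.gt_class == "hom_ref" for c in record.calls):
        return MendelianCheck(key, "uninformative")  # monomorphic in the trio

    fp, mp = father.allele_pool, mother.allele_pool

    if child.hemizygous:
        allele = child.alleles[0]
        consistent = allele in mp  # single X inherited from the mother
        pat = allele in fp
        mat = allele in mp
    else:
        child_ms = tuple(sorted(child.alleles))
        consistent = any(
            tuple(sorted((p, m))) == child_ms for p, m in itertools.product(fp, mp)
        )
        pat = _single_parent_explains(fp, child.alleles)
        mat = _single_parent_explains(mp, child.alleles)

    support = {
        (True, True): "either",
        (True, False): "paternal_only",
        (False, True): "maternal_only",
        (False, False): "neither",
    }[(pat, mat)]
    status = "consistent" if consistent else "inconsistent"
    return MendelianCheck(key, status, support)


# ---------------------------------------------------------------------------
# Windowed homozygosity
# ---------------------------------------------------------------------------

def _hom_informative(record: TrioRecord) -> Optional[bool]:
    """True/False if the child call is informative for homozygosity, else None.

    Informative = child carries at least one alt allele (the variant calls a
    genome screen actually sees); the fraction is hom-alt over alt-carrying.
    """
    c = record.child
    if c.missing or not c.carries_alt:
        return None
    return c.gt_class == "hom_alt"


def homozygosity_windows(
    records: Sequence[TrioRecord], window_bp: int = 500_000
) -> list[tuple[int, Optional[float]]]:
    """Per-window (start position, homozygous fraction) along one chromosome.

    Windows tile from the chromosome's first variant position. Windows with
    zero informative calls get fraction None (e.g. centromere gaps), not 0.
    """
    if not records:
        return []
    positions = [r.site.pos for r in records]
    if positions != sorted(positions):
        records = sorted(records, key=lambda r: r.site.pos)
        positions = [r.site.pos for r in records]
    origin = positions[0]
    n_windows = (positions[-1] - origin) // window_bp + 1
    hom = [0] * n_windows
    informative = [0] * n_windows
    for rec in records:
        flag = _hom_informative(rec)
        if flag is None:
            continue
        w = (rec.site.pos - origin) // window_bp
        informative[w] += 1
        hom[w] += int(flag)
    out: list[tuple[int, Optional[float]]] = []
    for w in range(n_windows):
        start = origin + w * window_bp
        frac = hom[w] / informative[w] if informative[w] else None
        out.append((start, frac))
    return out


# ---------------------------------------------------------------------------
# Isodisomy calling
# ---------------------------------------------------------------------------

def call_isodisomy(
    chrom: str,
    records: Sequence[TrioRecord],
    cfg: Optional[UPDConfig] = None,
) -> UPDReport:
    """Per-chromosome isodisomy verdict from Mendelian errors + homozygosity."""
    cfg = cfg or UPDConfig()
    records = sorted(records, key=lambda r: r.site.pos)
    checks = [check_mendelian(r) for r in records]
    informative = [c for c in checks if c.status != "uninformative"]
    inconsistent = [c for c in informative if c.status == "inconsistent"]
    n_inc = len(inconsistent)
    if n_inc:
        pat_frac = sum(c.parent_support in ("paternal_only", "either") for c in inconsistent) / n_inc
        mat_frac = sum(c.parent_support in ("maternal_only", "either") for c in inconsistent) / n_inc
    else:
        pat_frac = mat_frac = 0.0
    windows = homozygosity_windows(records, cfg.window_bp)
    report = UPDReport(
        chrom=chrom,
        n_sites=len(informative),
        n_inconsistent=n_inc,
        paternal_support_fraction=pat_frac,
        maternal_support_fraction=mat_frac,
        window_hom_fractions=windows,
        verdict="none",
    )
    if len(informative) < cfg.min_informative_sites:
        report.note = "insufficient data"
        return report
    med = report.median_window_hom
    if med is None or med < cfg.hom_median_min or n_inc < cfg.count_min:
        return report
    if pat_frac >= cfg.support_min:
        report.verdict = "paternal_isodisomy"
    elif mat_frac >= cfg.support_min:
        report.verdict = "maternal_isodisomy"
    return report


# ---------------------------------------------------------------------------
# Runs of homozygosity
# ---------------------------------------------------------------------------

def _roh_informative(record: TrioRecord) -> Optional[bool]:
    """True if the child call is heterozygous, False if homozygous-alt, None
    if uninformative. Like the UPD windows, only the child's own variant
    (alt-carrying) calls count: outside an ROH most such calls are
    heterozygous, which is what localizes segment boundaries."""
    c = record.child
    if c.missing or not c.carries_alt:
        return None
    return c.gt_class == "het"


def find_roh(
    records: Sequence[TrioRecord],
    cfg: Optional[ROHConfig] = None,
) -> list[ROHSegment]:
    """Maximal homozygous segments with at most ``het_tolerance`` het calls.

    Greedy left-to-right scan: a segment opens at a homozygous call,
    extends until one more het would exceed the tolerance, and is trimmed
    to its outermost homozygous calls. Segments are non-overlapping; only
    segments spanning at least ``min_length_bp`` are reported.
    """
    cfg = cfg or ROHConfig()
    records = sorted(records, key=lambda r: r.site.pos)
    calls: list[tuple[int, bool]] = []  # (pos, is_het)
    for rec in records:
        flag = _roh_informative(rec)
        if flag is not None:
            calls.append((rec.site.pos, flag))
    segments: list[ROHSegment] = []
    n = len(calls)
    i = 0
    chrom = records[0].site.chrom if records else ""
    while i < n:
        if calls[i][1]:  # het: cannot open a segment
            i += 1
            continue
        j = i
        hets = 0
        while j < n:
            if calls[j][1]:
                if hets + 1 > cfg.het_tolerance:
                    break
                hets += 1
            j += 1
        # trim trailing hets
        k = j - 1
        while calls[k][1]:
            hets -= 1
            k -= 1
        start, end = calls[i][0], calls[k][0]
        if end - start >= cfg.min_length_bp:
            n_hom = sum(1 for p, h in calls[i : k + 1] if not h)
            segments.append(
                ROHSegment(chrom=chrom, start=start, end=end, n_hom=n_hom, n_het_tolerated=hets)
            )
        i = j + 1  # resume past the tolerance-breaking het
    return segments


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

def write_upd_reports(reports: Iterable[UPDReport], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tn_informative\tn_inconsistent\tpaternal_support\t"
            "maternal_support\tmedian_window_hom\tverdict\tnote\n"
        )
        for r in reports:
            med = "" if r.median_window_hom is None else f"{r.median_window_hom:.4f}"
            fh.write(
                f"{r.chrom}\t{r.n_sites}\t{r.n_inconsistent}\t"
                f"{r.paternal_support_fraction:.4f}\t{r.maternal_support_fraction:.4f}\t"
                f"{med}\t{r.verdict}\t{r.note}\n"
            )


def write_window_fractions(reports: Iterable[UPDReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\twindow_start\thom_fraction\n")
        for r in reports:
            for start, frac in r.window_hom_fractions:
                val = "NA" if frac is None else f"{frac:.4f}"
                fh.write(f"{r.chrom}\t{start}\t{val}\n")


def write_roh_bed(segments: Iterable[ROHSegment], path) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(
                f"{seg.chrom}\t{seg.start - 1}\t{seg.end}\t"
                f"hom={seg.n_hom};het={seg.n_het_tolerated}\n"
            )
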