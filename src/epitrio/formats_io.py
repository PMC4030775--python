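"""File formats and domain records for trio variant analysis.

Coordinate conventions: VCF positions are 1-based; BED files and all
in-memory :class:`GenomicInterval` objects are 0-based half-open. The
conversion between the two happens in this module and nowhere else.

The multi-sample VCF reader binds sample columns to pedigree roles
(child / father / mother), decomposes multiallelic rows into biallelic
records with genotype indices remapped, and flags hemizygous calls
(male child and father on chromosome X) instead of modelling mixed
ploidy in the FORMAT arrays.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
from cyvcf2 import VCF
from intervaltree import IntervalTree


class VcfConfigError(ValueError):
    """A fatal input-configuration problem (e.g. pedigree sample not in header)."""


class VcfRecordError(ValueError):
    """A malformed VCF record; the message names the offending record."""


def is_x_chromosome(chrom: str) -> bool:
    return chrom.lstrip("chr").lstrip("Chr").upper() == "X" or chrom in ("chrX", "X")


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSite:
    """One biallelic variant site (after decomposition)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: Optional[float] = None
    site_info: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for allele in (self.ref, *self.alts):
            if not allele or any(b not in "ACGTN" for b in allele.upper()):
                raise ValueError(f"invalid allele {allele!r} at {self.chrom}:{self.pos}")

    @property
    def alt(self) -> str:
        return self.alts[0]

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alts[0]}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alts[0]) == 1


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at a site, with log10 likelihoods.

    ``gl`` is ordered (hom-ref, het, hom-alt) in log10 units, max-normalized
    to 0 by convention. ``hemizygous`` marks male-X calls that are
    diploid-coded (0/0 or 1/1) but carry a single physical allele.
    """

    sample_id: str
    alleles: tuple[Optional[int], Optional[int]]
    gl: Optional[tuple[float, ...]] = None
    depth: Optional[int] = None
    allele_depths: Optional[tuple[int, ...]] = None
    hemizygous: bool = False

    @property
    def missing(self) -> bool:
        return self.alleles[0] is None or self.alleles[1] is None

    @property
    def gt_class(self) -> str:
        if self.missing:
            return "missing"
        a, b = self.alleles
        if a == 0 and b == 0:
            return "hom_ref"
        if a == b:
            return "hom_alt"
        return "het"

    @property
    def n_alt(self) -> int:
        if self.missing:
            return 0
        return sum(1 for a in self.alleles if a != 0)

    @property
    def carries_alt(self) -> bool:
        return not self.missing and self.n_alt > 0

    @property
    def allele_pool(self) -> tuple[int, ...]:
        """Distinct alleles this individual could transmit."""
        if self.missing:
            return ()
        if self.hemizygous:
            return (self.alleles[0],)
        return tuple(sorted(set(self.alleles)))


@dataclass(frozen=True)
class TrioRecord:
    """One variant site with the child's, father's and mother's calls."""

    site: VariantSite
    child: GenotypeCall
    father: GenotypeCall
    mother: GenotypeCall

    def __post_init__(self):
        ids = {self.child.sample_id, self.father.sample_id, self.mother.sample_id}
        if len(ids) != 3:
            raise ValueError("child/father/mother sample ids must be distinct")

    @property
    def key(self) -> str:
        return self.site.key

    @property
    def calls(self) -> tuple[GenotypeCall, GenotypeCall, GenotypeCall]:
        return (self.child, self.father, self.mother)

    @property
    def any_missing(self) -> bool:
        return any(c.missing for c in self.calls)


@dataclass(frozen=True)
class Pedigree:
    child_id: str
    father_id: str
    mother_id: str
    child_sex: str  # "male" | "female"

    def __post_init__(self):
        if len({self.child_id, self.father_id, self.mother_id}) != 3:
            raise ValueError("pedigree sample ids must be distinct")
        if self.child_sex not in ("male", "female"):
            raise ValueError(f"child_sex must be male/female, got {self.child_sex!r}")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    label: Optional[str] = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end

    def distance_to(self, pos0: int) -> int:
        """bp distance from a 0-based point to this interval (0 if inside)."""
        if pos0 < self.start:
            return self.start - pos0
        if pos0 >= self.end:
            return pos0 - (self.end - 1)
        return 0


# ---------------------------------------------------------------------------
# Pedigree file (PED dialect: fam, id, father, mother, sex, phenotype)
# ---------------------------------------------------------------------------

def read_pedigree(path: str | Path) -> Pedigree:
    """Read a PED-style file and return the single child-parent trio in it.

    The child is the row whose father and mother columns are both non-zero.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 5:
            raise ValueError(f"PED line needs >=5 columns: {line!r}")
        rows.append(parts)
    children = [r for r in rows if r[2] not in ("0", ".") and r[3] not in ("0", ".")]
    if len(children) != 1:
        raise ValueError(f"expected exactly one child row in pedigree, found {len(children)}")
    fam, cid, fid, mid, sex = children[0][:5]
    sex_name = {"1": "male", "2": "female"}.get(sex)
    if sex_name is None:
        raise ValueError(f"child sex must be coded 1 (male) or 2 (female), got {sex!r}")
    return Pedigree(child_id=cid, father_id=fid, mother_id=mid, child_sex=sex_name)


def write_pedigree(ped: Pedigree, path: str | Path, family: str = "FAM1") -> None:
    sex_code = "1" if ped.child_sex == "male" else "2"
    lines = [
        f"{family}\t{ped.father_id}\t0\t0\t1\t1",
        f"{family}\t{ped.mother_id}\t0\t0\t2\t1",
        f"{family}\t{ped.child_id}\t{ped.father_id}\t{ped.mother_id}\t{sex_code}\t2",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Interval collections (BED)
# ---------------------------------------------------------------------------

class GenomeIntervals:
    """Per-chromosome interval trees queryable by point and by range."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
        self._n += 1

    def query_point(self, chrom: str, pos0: int) -> list[GenomicInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((hit.data for hit in tree.at(pos0)), key=lambda g: (g.start, g.end))

    def query_range(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((hit.data for hit in tree.overlap(start, end)), key=lambda g: (g.start, g.end))

    def __len__(self) -> int:
        return self._n

    def __iter__(self) -> Iterator[GenomicInterval]:
        for tree in self._trees.values():
            for hit in sorted(tree):
                yield hit.data


def read_intervals(path: str | Path) -> GenomeIntervals:
    """Read a >=3-column BED file (0-based half-open) into a queryable collection."""
    out = GenomeIntervals()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: BED needs >=3 columns")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        if start >= end:
            raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
        label = parts[3] if len(parts) > 3 else None
        out.add(GenomicInterval(chrom, start, end, label))
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            label = iv.label if iv.label is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")


# ---------------------------------------------------------------------------
# Reference sequence windows
# ---------------------------------------------------------------------------

class SequenceStore:
    """Reference bases for selected genomic windows.

    Holds sequence only where the analysis needs it (transcript
    neighbourhoods in the simulated datasets, or arbitrary contigs loaded
    from FASTA). Coordinates are 1-based at the API surface to match VCF.
    """

    def __init__(self):
        self._segments: dict[str, list[tuple[int, bytearray]]] = {}

    def add(self, chrom: str, start1: int, seq: str) -> None:
        self._segments.setdefault(chrom, []).append((start1, bytearray(seq.encode())))
        self._segments[chrom].sort(key=lambda t: t[0])

    def set_base(self, chrom: str, pos1: int, base: str) -> None:
        seg = self._find(chrom, pos1)
        if seg is None:
            raise KeyError(f"no sequence stored covering {chrom}:{pos1}")
        start1, buf = seg
        buf[pos1 - start1] = ord(base)

    def _find(self, chrom: str, pos1: int):
        for start1, buf in self._segments.get(chrom, []):
            if start1 <= pos1 < start1 + len(buf):
                return start1, buf
        return None

    def get_base(self, chrom: str, pos1: int) -> str:
        seg = self._find(chrom, pos1)
        if seg is None:
            raise KeyError(f"no sequence stored covering {chrom}:{pos1}")
        start1, buf = seg
        return chr(buf[pos1 - start1])

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        """0-based half-open fetch (pysam/pyfaidx-style)."""
        return "".join(self.get_base(chrom, p + 1) for p in range(start0, end0))

    def covers(self, chrom: str, pos1: int) -> bool:
        return self._find(chrom, pos1) is not None

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._segments):
                for start1, buf in self._segments[chrom]:
                    end1 = start1 + len(buf) - 1
                    fh.write(f">{chrom}:{start1}-{end1}\n")
                    seq = buf.decode()
                    for i in range(0, len(seq), 70):
                        fh.write(seq[i : i + 70] + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SequenceStore":
        store = cls()
        name, chunks = None, []
        def flush():
            if name is None:
                return
            chrom, span = name.rsplit(":", 1)
            start1 = int(span.split("-")[0])
            store.add(chrom, start1, "".join(chunks))
        for line in Path(path).read_text().splitlines():
            if line.startswith(">"):
                flush()
                name, chunks = line[1:].split()[0], []
            elif line.strip():
                chunks.append(line.strip())
        flush()
        return store


# ---------------------------------------------------------------------------
# Trio VCF reading
# ---------------------------------------------------------------------------

_PL_MISSING = -2_000_000_000  # below cyvcf2's int32 sentinel


def _gl_matrix(variant, n_samples: int):
    """Per-sample genotype log10-likelihoods from GL or PL, else None."""
    gl = variant.format("GL")
    if gl is not None:
        arr = np.asarray(gl, dtype=float)
        arr[arr < -1e7] = np.nan
        return arr
    pl = variant.format("PL")
    if pl is not None:
        arr = np.asarray(pl, dtype=float)
        arr[arr < -1e8] = np.nan  # int32 missing sentinel
        return arr / -10.0
    return None


def _log10sumexp(vals) -> float:
    m = max(vals)
    if not math.isfinite(m):
        return m
    return m + math.log10(sum(10.0 ** (v - m) for v in vals))


def _collapse_gl(glrow, alt_index: int, n_alleles: int) -> Optional[tuple[float, ...]]:
    """Marginalize a multiallelic GL vector onto dosage of one alt allele.

    Likelihood mass of genotypes carrying 0/1/2 copies of ``alt_index`` is
    pooled (log-sum) into a biallelic 3-vector, renormalized to max 0.
    Biallelic rows are passed through untouched so round-trips are exact.
    """
    if glrow is None:
        return None
    vals = [v for v in glrow if np.isfinite(v)]
    if len(vals) < 2:
        return None
    if n_alleles == 2:
        if len(glrow) < 3 or not all(np.isfinite(v) for v in glrow[:3]):
            return None
        return tuple(float(v) for v in glrow[:3])
    buckets: list[list[float]] = [[], [], []]
    for l in range(n_alleles):
        for j in range(l + 1):
            idx = l * (l + 1) // 2 + j
            if idx >= len(glrow):
                return None
            v = glrow[idx]
            if np.isfinite(v):
                buckets[(j == alt_index) + (l == alt_index)].append(float(v))
    if any(not b for b in buckets):
        return None
    out = [_log10sumexp(b) for b in buckets]
    top = max(out)
    return tuple(v - top for v in out)


def read_trio_vcf(path: str | Path, pedigree: Pedigree) -> Iterator[TrioRecord]:
    """Stream coordinate-sorted, biallelic-decomposed TrioRecords from a VCF.

    Multiallelic rows yield one record per alt allele with genotype indices
    remapped (other alts collapse to the reference class). Records with a
    missing genotype are emitted with the call flagged missing, never
    dropped.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    roles = {"child": pedigree.child_id, "father": pedigree.father_id, "mother": pedigree.mother_id}
    absent = [sid for sid in roles.values() if sid not in samples]
    if absent:
        raise VcfConfigError(f"pedigree sample(s) {absent} not in VCF header samples {samples}")
    col = {role: samples.index(sid) for role, sid in roles.items()}

    prev: tuple[str, int] | None = None
    for recno, v in enumerate(vcf, 1):
        if prev is not None and v.CHROM == prev[0] and v.POS < prev[1]:
            raise VcfRecordError(
                f"VCF not coordinate-sorted at record {recno} ({v.CHROM}:{v.POS})"
            )
        prev = (v.CHROM, v.POS)
        try:
            yield from _decompose(v, pedigree, col)
        except VcfRecordError:
            raise
        except Exception as exc:  # pragma: no cover - defensive wrapper
            raise VcfRecordError(
                f"malformed VCF record {recno} at {v.CHROM}:{v.POS}: {exc}"
            ) from exc


def _decompose(v, pedigree: Pedigree, col: dict[str, int]) -> Iterator[TrioRecord]:
    alts = list(v.ALT)
    if not alts:
        return
    n_alleles = 1 + len(alts)
    glmat = _gl_matrix(v, len(col))
    depths = v.format("DP")
    ads = v.format("AD")
    qd = v.INFO.get("QD")
    site_info = {} if qd is None else {"QD": float(qd)}
    on_x = is_x_chromosome(v.CHROM)

    for k in range(1, n_alleles):
        site = VariantSite(
            chrom=v.CHROM,
            pos=v.POS,
            ref=v.REF,
            alts=(alts[k - 1],),
            qual=None if v.QUAL is None else float(v.QUAL),
            site_info=dict(site_info),
        )
        calls = {}
        for role, i in col.items():
            raw = v.genotypes[i]
            raw_alleles = [a for a in raw[:-1]]  # last element is the phased flag
            if len(raw_alleles) == 1:
                raw_alleles = raw_alleles * 2
            mapped = tuple(
                None if a < 0 else (1 if a == k else 0) for a in raw_alleles[:2]
            )
            gl = _collapse_gl(None if glmat is None else glmat[i], k, n_alleles)
            depth = None
            if depths is not None:
                d = int(depths[i][0]) if np.ndim(depths[i]) else int(depths[i])
                depth = d if d >= 0 else None
            allele_depths = None
            if ads is not None:
                row = np.atleast_1d(ads[i])
                if len(row) >= n_alleles and row[0] >= 0:
                    allele_depths = (int(row[0]), int(row[k]))
            sample_id = {"child": pedigree.child_id, "father": pedigree.father_id,
                         "mother": pedigree.mother_id}[role]
            hemi = on_x and (role == "father" or (role == "child" and pedigree.child_sex == "male"))
            calls[role] = GenotypeCall(
                sample_id=sample_id,
                alleles=mapped,
                gl=gl,
                depth=depth,
                allele_depths=allele_depths,
                hemizygous=hemi,
            )
        yield TrioRecord(site=site, child=calls["child"], father=calls["father"], mother=calls["mother"])


# ---------------------------------------------------------------------------
# Trio VCF writing
# ---------------------------------------------------------------------------

def write_trio_vcf(
    records: Iterable[TrioRecord],
    path: str | Path,
    pedigree: Pedigree,
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write biallelic TrioRecords as a VCF 4.2 file (GT:GL:DP:AD)."""
    lines = ["##fileformat=VCFv4.2", "##source=epitrio"]
    if contig_lengths:
        for chrom, length in contig_lengths.items():
            lines.append(f"##contig=<ID={chrom},length={length}>")
    lines += [
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GL,Number=G,Type=Float,Description="Log10 genotype likelihoods">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join([pedigree.child_id, pedigree.father_id, pedigree.mother_id]),
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for rec in records:
            fh.write(_format_record(rec) + "\n")


def _format_call(call: GenotypeCall) -> str:
    if call.missing:
        gt = "./."
    else:
        gt = f"{call.alleles[0]}/{call.alleles[1]}"
    gl = "." if call.gl is None else ",".join(f"{v:.9g}" for v in call.gl)
    dp = "." if call.depth is None else str(call.depth)
    ad = "." if call.allele_depths is None else ",".join(str(d) for d in call.allele_depths)
    return f"{gt}:{gl}:{dp}:{ad}"


def _format_record(rec: TrioRecord) -> str:
    site = rec.site
    qual = "." if site.qual is None else f"{site.qual:.6g}"
    qd = site.site_info.get("QD")
    info = "." if qd is None else f"QD={qd:.6g}"
    fields = [
        site.chrom,
        str(site.pos),
        ".",
        site.ref,
        site.alts[0],
        qual,
        ".",
        info,
        "GT:GL:DP:AD",
        _format_call(rec.child),
        _format_call(rec.father),
        _format_call(rec.mother),
    ]
    return "\t".join(fields)
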