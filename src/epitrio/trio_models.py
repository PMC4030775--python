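"""Inheritance models over trio genotypes and the genotype-likelihood-ratio filter.

Four models are screened in every family: de novo (child het, both parents
hom-ref), simple recessive (child hom-alt, both parents het), compound
heterozygous (two coding variants in one gene, one inherited from each
heterozygous parent) and, for male children, X-linked hemizygous.

Genotype confidence is measured by the genotype likelihood ratio (GLR):
log10 L(second-best genotype) - log10 L(best genotype), a value <= 0. A
call passes when the ratio is at or below the configured threshold
(default -5, i.e. the best genotype is at least 10^5-fold more likely than
the runner-up).
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from pydantic import BaseModel, Field, model_validator

from .formats_io import GenotypeCall, Pedigree, TrioRecord, is_x_chromosome

#: evidence entries are (filter name, observed value, verdict)
Evidence = list[tuple[str, object, bool]]

MODELS = ("de_novo", "simple_recessive", "compound_het", "x_linked", "regulatory")


class ModelConfig(BaseModel):
    """Thresholds of the per-trio filtering cascade.

    glr_threshold: log10 GLR cutoff; calls pass at or below it.
    max_population_af: population allele-frequency cutoff for the
        recessive-type models (strict >).
    max_internal_het: maximum tolerated het carriers in the internal cohort.
    internal_cohort_n: size of the internal comparison cohort.
    mu: de novo mutation rate per bp per generation.
    haploid_genome_length: bp of one haploid genome, used for the expected
        de novo count.
    """

    glr_threshold: float = -5.0
    max_population_af: float = Field(default=0.005, ge=0.0, le=1.0)
    max_internal_het: int = Field(default=5, ge=0)
    internal_cohort_n: int = Field(default=294, ge=1)
    mu: float = Field(default=1.18e-8, ge=0.0)
    haploid_genome_length: float = Field(default=3.0e9, gt=0.0)

    @model_validator(mode="after")
    def _check(self):
        if self.glr_threshold >= 0:
            raise ValueError("glr_threshold must be negative")
        return self


@dataclass
class CandidateVariant:
    """A variant surviving one inheritance model, with its evidence trail."""

    record: TrioRecord
    model: str
    gene: Optional[str] = None
    partner: Optional[str] = None  # compound-het mate's variant key
    evidence: Evidence = field(default_factory=list)

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")

    @property
    def key(self) -> str:
        return self.record.key


def genotype_likelihood_ratio(call: GenotypeCall) -> Optional[float]:
    """log10 L(second-best) - log10 L(best), or None if uninformative.

    An all-equal GL vector returns 0 (which never passes a negative
    threshold); fewer than two finite entries returns None.
    """
    if call.gl is None:
        return None
    finite = sorted((v for v in call.gl if math.isfinite(v)), reverse=True)
    if len(finite) < 2:
        return None
    return finite[1] - finite[0]


def glr_passes(call: GenotypeCall, cfg: ModelConfig) -> bool:
    ratio = genotype_likelihood_ratio(call)
    return ratio is not None and ratio <= cfg.glr_threshold


def _glr_evidence(record: TrioRecord, cfg: ModelConfig) -> tuple[bool, Evidence]:
    ev: Evidence = []
    all_pass = True
    for role, call in zip(("child", "father", "mother"), record.calls):
        ratio = genotype_likelihood_ratio(call)
        ok = ratio is not None and ratio <= cfg.glr_threshold
        ev.append((f"glr_{role}", ratio, ok))
        all_pass &= ok
    return all_pass, ev


def detect_de_novo(record: TrioRecord, cfg: ModelConfig) -> Optional[CandidateVariant]:
    """Child het, both parents hom-ref, GLR passing in all three individuals."""
    if record.any_missing:
        return None
    config_ok = (
        record.child.gt_class == "het"
        and record.father.gt_class == "hom_ref"
        and record.mother.gt_class == "hom_ref"
    )
    if not config_ok:
        return None
    glr_ok, glr_ev = _glr_evidence(record, cfg)
    if not glr_ok:
        return None
    ev: Evidence = [("genotype_config", "child het / parents hom-ref", True)]
    ev.extend(glr_ev)
    return CandidateVariant(record=record, model="de_novo", evidence=ev)


def de_novo_genotype_config(record: TrioRecord) -> bool:
    """Genotype configuration of the de novo model, before any GLR filter."""
    return (
        not record.any_missing
        and record.child.gt_class == "het"
        and record.father.gt_class == "hom_ref"
        and record.mother.gt_class == "hom_ref"
    )


def detect_simple_recessive(record: TrioRecord, cfg: ModelConfig) -> Optional[CandidateVariant]:
    """Child hom-alt with both parents heterozygous."""
    if record.any_missing:
        return None
    if not (
        record.child.gt_class == "hom_alt"
        and record.father.gt_class == "het"
        and record.mother.gt_class == "het"
    ):
        return None
    ev: Evidence = [
        ("genotype_config", "child hom-alt / parents het", True),
        ("gt_child", record.child.gt_class, True),
        ("gt_father", record.father.gt_class, True),
        ("gt_mother", record.mother.gt_class, True),
    ]
    return CandidateVariant(record=record, model="simple_recessive", evidence=ev)


def _compound_het_origin(record: TrioRecord) -> Optional[str]:
    """Parental origin of a candidate compound-het member, from genotypes alone.

    Paternal: child het, father het, mother hom-ref. Maternal: mirrored.
    Both-parents-het configurations are phase-uninformative and excluded.
    """
    if record.any_missing or record.child.gt_class != "het":
        return None
    f, m = record.father.gt_class, record.mother.gt_class
    if f == "het" and m == "hom_ref":
        return "paternal"
    if m == "het" and f == "hom_ref":
        return "maternal"
    return None


def detect_compound_het(
    records: Iterable[TrioRecord], cfg: ModelConfig, gene: Optional[str] = None
) -> list[tuple[CandidateVariant, CandidateVariant]]:
    """Pair phase-informative coding variants of one gene across parental origins.

    Emits every unordered (paternal, maternal) pair; both members carry the
    partner's variant key.
    """
    paternal, maternal = [], []
    for rec in records:
        origin = _compound_het_origin(rec)
        if origin == "paternal":
            paternal.append(rec)
        elif origin == "maternal":
            maternal.append(rec)
    pairs = []
    for pa, ma in itertools.product(paternal, maternal):
        ev_a: Evidence = [("compound_het_origin", "paternal", True), ("partner", ma.key, True)]
        ev_b: Evidence = [("compound_het_origin", "maternal", True), ("partner", pa.key, True)]
        a = CandidateVariant(record=pa, model="compound_het", gene=gene, partner=ma.key, evidence=ev_a)
        b = CandidateVariant(record=ma, model="compound_het", gene=gene, partner=pa.key, evidence=ev_b)
        pairs.append((a, b))
    return pairs


def detect_x_linked(
    record: TrioRecord, pedigree: Pedigree, cfg: ModelConfig
) -> Optional[CandidateVariant]:
    """Male child hemizygous alt, mother het, father hemizygous ref.

    Only applies on chromosome X; the female X-recessive case is covered by
    the autosomal-style recessive rule applied to X.
    """
    if not is_x_chromosome(record.site.chrom):
        raise VcfModelError(
            f"x-linked model applied to autosome {record.site.chrom}"
        )
    if pedigree.child_sex != "male":
        return None
    if record.any_missing:
        return None
    if not (
        record.child.gt_class == "hom_alt"  # diploid-coded hemizygous alt
        and record.mother.gt_class == "het"
        and record.father.gt_class == "hom_ref"
    ):
        return None
    ev: Evidence = [
        ("child_sex", pedigree.child_sex, True),
        ("genotype_config", "child hemi-alt / mother het / father hemi-ref", True),
    ]
    return CandidateVariant(record=record, model="x_linked", evidence=ev)


class VcfModelError(ValueError):
    """Model applied outside its domain (e.g. X-linked model on an autosome)."""


def expected_de_novo_count(cfg: ModelConfig) -> float:
    """Expected de novo mutations per child: 2 x haploid length x mu.

    The factor 2 counts the two transmitted haplotypes. With the defaults
    (mu = 1.18e-8, L = 3.0e9) this is 70.8, i.e. "about 70" per genome.
    """
    return 2.0 * cfg.haploid_genome_length * cfg.mu
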