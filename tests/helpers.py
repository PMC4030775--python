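"""Shared factories and independent brute-force oracles for the test suite."""
from __future__ import annotations

import itertools

from epitrio.formats_io import GenotypeCall, Pedigree, TrioRecord, VariantSite

GT_ALLELES = {
    "hom_ref": (0, 0),
    "het": (0, 1),
    "hom_alt": (1, 1),
    "missing": (None, None),
}

#: strong, unambiguous GL vectors per called genotype (log10, max-normalized)
GL_FOR = {
    "hom_ref": (0.0, -10.0, -20.0),
    "het": (-10.0, 0.0, -10.0),
    "hom_alt": (-20.0, -10.0, 0.0),
    "missing": None,
}

PEDIGREE = Pedigree("CHILD", "FATHER", "MOTHER", "male")
PEDIGREE_FEMALE = Pedigree("CHILD", "FATHER", "MOTHER", "female")


def make_call(sample_id, gt, gl="auto", hemizygous=False, depth=30):
    if gl == "auto":
        gl = GL_FOR[gt]
    return GenotypeCall(
        sample_id=sample_id,
        alleles=GT_ALLELES[gt],
        gl=gl,
        depth=depth,
        allele_depths=(depth // 2, depth - depth // 2),
        hemizygous=hemizygous,
    )


def make_trio(
    child,
    father,
    mother,
    chrom="chr1",
    pos=100,
    ref="A",
    alt="G",
    child_gl="auto",
    father_gl="auto",
    mother_gl="auto",
    hemizygous=False,
):
    """Build a TrioRecord from genotype-class names (hom_ref/het/hom_alt/missing)."""
    site = VariantSite(chrom=chrom, pos=pos, ref=ref, alts=(alt,))
    return TrioRecord(
        site=site,
        child=make_call("CHILD", child, child_gl, hemizygous=hemizygous),
        father=make_call("FATHER", father, father_gl, hemizygous=hemizygous),
        mother=make_call("MOTHER", mother, mother_gl),
    )


GT_CLASSES = ("hom_ref", "het", "hom_alt")


def mendelian_oracle(child_gt, father_gt, mother_gt):
    """Brute force over the four transmission choices per configuration.

    Returns (status, parent_support) like check_mendelian, for non-missing
    diploid genotypes; the all-hom-ref configuration is 'uninformative'.
    """
    if "missing" in (child_gt, father_gt, mother_gt):
        return "uninformative", None
    if child_gt == father_gt == mother_gt == "hom_ref":
        return "uninformative", None
    child = tuple(sorted(GT_ALLELES[child_gt]))
    father = GT_ALLELES[father_gt]
    mother = GT_ALLELES[mother_gt]
    consistent = any(
        tuple(sorted((p, m))) == child for p in father for m in mother
    )

    def alone(parent):
        return any(
            tuple(sorted((x, y))) == child
            for x, y in itertools.product(parent, repeat=2)
        )

    pat, mat = alone(father), alone(mother)
    support = {
        (True, True): "either",
        (True, False): "paternal_only",
        (False, True): "maternal_only",
        (False, False): "neither",
    }[(pat, mat)]
    return ("consistent" if consistent else "inconsistent"), support
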