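"""RFLP genotype calling and population-genetic summaries.

Three restriction assays discriminate the loci that drive warfarin dose
variability here:

* ``CYP2C9_star2_AvaII`` — a 454 bp exon-3 amplicon; AvaII cuts the
  wild-type (*1) allele into 397 + 57 bp, the *2 allele stays uncut.
* ``CYP2C9_star3_KpnI`` — a 105 bp exon-7 amplicon; KpnI cuts the variant
  (*3) allele into 85 + 20 bp, the wild-type stays uncut.
* ``VKORC1_1639_MspI`` — a 290 bp promoter amplicon; MspI cuts the
  wild-type G allele into 167 + 123 bp, the -1639A allele stays uncut.

A homozygote shows only one pattern (cut or uncut); a heterozygote shows
both.  Fragments below gel resolution (< 60 bp on 2.5-3.5% agarose) may be
absent from an observation; a pattern missing only such fragments still
calls when unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

GENOTYPE_CLASSES = ("hom_ref", "het", "hom_var")

#: fragments shorter than this routinely run off the gel and may go unobserved
GEL_RESOLUTION_BP = 60


@dataclass(frozen=True)
class RflpAssay:
    """One restriction-digest genotyping assay."""

    name: str
    amplicon_bp: int
    cut_fragments_bp: frozenset[int]
    cut_allele: str  # "wild_type" or "variant": which allele the enzyme cuts

    def __post_init__(self):
        if sum(self.cut_fragments_bp) != self.amplicon_bp:
            raise ValueError(
                f"{self.name}: cut fragments {sorted(self.cut_fragments_bp)} "
                f"do not sum to amplicon {self.amplicon_bp}")
        if self.cut_allele not in ("wild_type", "variant"):
            raise ValueError(f"cut_allele must be wild_type/variant, got {self.cut_allele!r}")


ASSAYS: dict[str, RflpAssay] = {
    "CYP2C9_star2_AvaII": RflpAssay("CYP2C9_star2_AvaII", 454, frozenset({397, 57}), "wild_type"),
    "CYP2C9_star3_KpnI": RflpAssay("CYP2C9_star3_KpnI", 105, frozenset({85, 20}), "variant"),
    "VKORC1_1639_MspI": RflpAssay("VKORC1_1639_MspI", 290, frozenset({167, 123}), "wild_type"),
}


class NoCall(ValueError):
    """The observed fragment set does not resolve to a genotype."""


def _pattern_for(assay: RflpAssay, cut: bool, het: bool) -> frozenset[int]:
    if het:
        return frozenset({assay.amplicon_bp}) | assay.cut_fragments_bp
    return assay.cut_fragments_bp if cut else frozenset({assay.amplicon_bp})


def call_rflp_genotype(assay: RflpAssay, observed_fragments_bp) -> str:
    """Call hom_ref / het / hom_var from an observed fragment-length set.

    Cut-pattern-only means homozygous for the allele the enzyme cuts,
    uncut-only homozygous for the other, both patterns heterozygous; the
    assay's ``cut_allele`` orients the call to reference/variant.  Fragments
    under the gel-resolution bound are optional.  Raises :class:`NoCall`
    with a diagnostic for empty, unrecognized or ambiguous observations.
    """
    observed = frozenset(int(f) for f in observed_fragments_bp)
    if not observed:
        raise NoCall(f"{assay.name}: empty fragment set")
    legal = frozenset({assay.amplicon_bp}) | assay.cut_fragments_bp
    unknown = observed - legal
    if unknown:
        raise NoCall(f"{assay.name}: unrecognized fragment length(s) {sorted(unknown)}")

    # cut homozygote / uncut homozygote / heterozygote, before allele orientation
    candidates = []
    for cut, het in ((True, False), (False, False), (False, True)):
        pattern = _pattern_for(assay, cut, het)
        required = frozenset(f for f in pattern if f >= GEL_RESOLUTION_BP)
        if required <= observed <= pattern:
            candidates.append((cut or het, het))
    if len(candidates) != 1:
        raise NoCall(f"{assay.name}: pattern {sorted(observed)} is "
                     f"{'ambiguous' if candidates else 'inconsistent with every genotype'}")
    cut_present, het = candidates[0]
    if het:
        return "het"
    cut_is_variant = assay.cut_allele == "variant"
    if cut_present:
        return "hom_var" if cut_is_variant else "hom_ref"
    return "hom_ref" if cut_is_variant else "hom_var"


def fragments_for_genotype(assay: RflpAssay, genotype_class: str) -> frozenset[int]:
    """Full (resolution-unlimited) fragment pattern produced by a genotype."""
    if genotype_class not in GENOTYPE_CLASSES:
        raise ValueError(f"unknown genotype class {genotype_class!r}")
    if genotype_class == "het":
        return _pattern_for(assay, cut=False, het=True)
    cut = (genotype_class == "hom_var") == (assay.cut_allele == "variant")
    return _pattern_for(assay, cut=cut, het=False)


def cyp2c9_diplotype(star2_class: str, star3_class: str) -> str:
    """Combine the *2 (AvaII) and *3 (KpnI) assay calls into an IWPC diplotype."""
    n2 = GENOTYPE_CLASSES.index(star2_class)  # copies of *2
    n3 = GENOTYPE_CLASSES.index(star3_class)  # copies of *3
    if n2 + n3 > 2:
        raise ValueError(f"inconsistent assay calls: {n2} copies of *2 and {n3} of *3")
    table = {(0, 0): "*1/*1", (1, 0): "*1/*2", (0, 1): "*1/*3",
             (2, 0): "*2/*2", (1, 1): "*2/*3", (0, 2): "*3/*3"}
    return table[(n2, n3)]


def vkorc1_genotype(msp_class: str) -> str:
    """Map the MspI assay call to the -1639 G/A genotype string."""
    return {"hom_ref": "GG", "het": "GA", "hom_var": "AA"}[msp_class]


# ---------------------------------------------------------------------------
# Frequencies and Hardy-Weinberg

@dataclass(frozen=True)
class GenotypeCounts:
    """Per-locus genotype counts: (homozygous reference, heterozygous, homozygous variant)."""

    locus: str
    hom_ref: int
    het: int
    hom_var: int

    def __post_init__(self):
        if min(self.hom_ref, self.het, self.hom_var) < 0:
            raise ValueError("genotype counts must be >= 0")

    @property
    def total(self) -> int:
        return self.hom_ref + self.het + self.hom_var

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.hom_ref, self.het, self.hom_var)


@dataclass(frozen=True)
class HweResult:
    chi_square: float
    df: int
    p_value: float
    expected_counts: tuple[float, float, float]
    monomorphic: bool = False


def genotype_frequencies(counts: GenotypeCounts) -> tuple[float, float, float]:
    """Relative genotype frequencies; they sum to 1 before any rounding."""
    n = counts.total
    if n <= 0:
        raise ValueError("total count must be > 0")
    return tuple(c / n for c in counts.as_tuple())


def allele_frequencies(counts: GenotypeCounts) -> tuple[float, float]:
    """(reference, variant) allele frequencies by direct allele counting."""
    n = counts.total
    if n <= 0:
        raise ValueError("total count must be > 0")
    q = (counts.het + 2 * counts.hom_var) / (2 * n)
    return (1.0 - q, q)


def hwe_chi_square(counts: GenotypeCounts) -> HweResult:
    """Pearson chi-square goodness-of-fit test of Hardy-Weinberg proportions.

    Expected counts are n*(p^2, 2pq, q^2) from the observed allele
    frequencies; one degree of freedom (three classes, one estimated allele
    frequency); no continuity correction.  A monomorphic locus has no
    testable departure and is returned flagged with statistic 0 and p 1.
    """
    n = counts.total
    if n <= 0:
        raise ValueError("total count must be > 0")
    p, q = allele_frequencies(counts)
    if p == 0.0 or q == 0.0:
        expected = (n * p * p, 2 * n * p * q, n * q * q)
        return HweResult(0.0, 1, 1.0, expected, monomorphic=True)
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(counts.as_tuple(), expected))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HweResult(float(chi2), 1, p_value, expected)


def count_genotypes(cohort, locus: str) -> GenotypeCounts:
    """Tally a cohort's diplotype/genotype strings into per-class counts.

    ``locus`` is "cyp2c9" (counting *2 carriage: *1/*1 and *1/*3 as
    reference, *2 heterozygotes as het, *2/*2 as variant homozygote) or
    "vkorc1" (GG/GA/AA).  Patients with an unknown genotype are excluded.
    """
    if locus == "cyp2c9":
        classes = {"*1/*1": 0, "*1/*3": 0, "*3/*3": 0, "*1/*2": 1, "*2/*3": 1, "*2/*2": 2}
        label = "CYP2C9_star2"
    elif locus == "vkorc1":
        classes = {"GG": 0, "GA": 1, "AA": 2}
        label = "VKORC1_1639"
    else:
        raise ValueError(f"unknown locus {locus!r}")
    tallies = [0, 0, 0]
    for p in cohort:
        g = getattr(p, locus)
        if g == "unknown":
            continue
        tallies[classes[g]] += 1
    return GenotypeCounts(label, *tallies)


# ---------------------------------------------------------------------------
# Fragment-observation CSV interface

def read_fragment_observations(path) -> dict[str, dict[str, frozenset[int]]]:
    """Read a fragment CSV (patient_id, assay, comma-joined fragment sizes)."""
    import csv

    observations: dict[str, dict[str, frozenset[int]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"patient_id", "assay", "fragments_bp"}
        if not required <= set(reader.fieldnames or []):
            raise ValueError(f"{path}: fragment CSV needs columns {sorted(required)}")
        for row in reader:
            if row["assay"] not in ASSAYS:
                raise ValueError(f"{path}: unknown assay {row['assay']!r}")
            frags = frozenset(int(x) for x in row["fragments_bp"].split(",") if x.strip())
            observations.setdefault(row["patient_id"], {})[row["assay"]] = frags
    return observations


def genotypes_from_fragments(per_assay: dict[str, frozenset[int]]) -> tuple[str, str]:
    """Decode one patient's (cyp2c9 diplotype, vkorc1 genotype) from assay observations.

    An assay with no observation yields "unknown" for its locus; for CYP2C9
    both the *2 and *3 assays are needed.
    """
    try:
        star2 = call_rflp_genotype(ASSAYS["CYP2C9_star2_AvaII"],
                                   per_assay["CYP2C9_star2_AvaII"])
        star3 = call_rflp_genotype(ASSAYS["CYP2C9_star3_KpnI"],
                                   per_assay["CYP2C9_star3_KpnI"])
        cyp = cyp2c9_diplotype(star2, star3)
    except KeyError:
        cyp = "unknown"
    try:
        vko = vkorc1_genotype(call_rflp_genotype(ASSAYS["VKORC1_1639_MspI"],
                                                 per_assay["VKORC1_1639_MspI"]))
    except KeyError:
        vko = "unknown"
    return cyp, vko
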