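"""Two-mutation intragenic model for tissue-specific anthocyanin loss.

Purple pigmentation of zoysiagrass stolons and seed heads is governed by a
single MYC-bHLH transcription factor of the MBW (MYB-bHLH-WD40) activation
complex.  Two SNPs in the gene segregate in the Meyer x PI 231146 crosses:

* ``SNP_917`` (G -> A, last base of exon 7): the A allele causes intron
  retention and a nonfunctional protein.  Homozygous AA plants lose
  anthocyanins in *all* tissues (green stolons and seed heads).
* ``SNP_632`` (G -> T, exon 3, Ala -> Ser in the MYB-interacting N-terminal
  domain): the T allele weakens binding to a seed-head-specific MYB, so its
  effect is confined to seed heads.

Seed heads are green when no functional, seed-head-competent protein can be
made: genotype AA at SNP_917, or TT at SNP_632, or simultaneous
heterozygosity GA/GT (at full linkage each haplotype then carries one of the
two lesions).  Stolons are green only for AA at SNP_917.

The module provides exact cross expectations (rational probabilities at
intragenic recombination r = 0), hypothesis-consistency checks against
observed genotype/phenotype tables, and in-silico CAPS genotyping.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping

import pandas as pd

GREEN, PURPLE = "green", "purple"

#: numeric phenotype coding used in the field sheets: green = 1, purple = 2
PHENOTYPE_CODE = {GREEN: 1, PURPLE: 2}

_ALLELES_632 = ("G", "T")
_ALLELES_917 = ("G", "A")


@dataclass(frozen=True, order=True)
class GeneHaplotype:
    """One chromosome's alleles at (SNP_632, SNP_917)."""

    allele_632: str
    allele_917: str

    def __post_init__(self) -> None:
        if self.allele_632 not in _ALLELES_632:
            raise ValueError(f"SNP_632 allele must be in {_ALLELES_632}")
        if self.allele_917 not in _ALLELES_917:
            raise ValueError(f"SNP_917 allele must be in {_ALLELES_917}")


@dataclass(frozen=True)
class GeneDiplotype:
    """Unordered pair of gene haplotypes."""

    hap1: GeneHaplotype
    hap2: GeneHaplotype

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneDiplotype):
            return NotImplemented
        return {self.hap1, self.hap2} == {other.hap1, other.hap2} or (
            self.hap1 == other.hap2 and self.hap2 == other.hap1
        ) or (self.hap1, self.hap2) == (other.hap1, other.hap2)

    def __hash__(self) -> int:
        return hash(frozenset([(self.hap1, self.hap2), (self.hap2, self.hap1)]))

    @property
    def g632(self) -> str:
        return "".join(sorted((self.hap1.allele_632, self.hap2.allele_632)))

    @property
    def g917(self) -> str:
        a = sorted((self.hap1.allele_917, self.hap2.allele_917))
        return "".join(a if a != ["A", "G"] else ["G", "A"])  # conventional GA

    @property
    def haplotypes(self) -> tuple[GeneHaplotype, GeneHaplotype]:
        return (self.hap1, self.hap2)


def diplotype(h1: tuple[str, str], h2: tuple[str, str]) -> GeneDiplotype:
    """Build a diplotype from two (allele_632, allele_917) tuples."""
    return GeneDiplotype(GeneHaplotype(*h1), GeneHaplotype(*h2))


#: reference accessions (phase at the gene): Meyer is heterozygous for the
#: SNP_917 intron-retention allele, PI 231146 for the SNP_632 missense allele,
#: and F1-19 (the selfed F1 behind the F2 population) carries Meyer's lesion.
MEYER = diplotype(("G", "G"), ("G", "A"))
PI_231146 = diplotype(("G", "G"), ("T", "G"))
F1_19 = diplotype(("G", "G"), ("G", "A"))
WILD_TYPE = diplotype(("G", "G"), ("G", "G"))


@dataclass(frozen=True)
class PhenotypePair:
    stolon: str
    seed_head: str

    def coded(self) -> tuple[int, int]:
        return (PHENOTYPE_CODE[self.stolon], PHENOTYPE_CODE[self.seed_head])


def phenotype_from_diplotype(d: GeneDiplotype) -> PhenotypePair:
    """Deterministic (fully penetrant) phenotype rules of the two-SNP model.

    Stolons are green iff SNP_917 is homozygous variant (AA).  Seed heads
    are green iff SNP_917 is AA, or SNP_632 is TT, or the plant is
    heterozygous at both SNPs (GA and GT).
    """
    g917, g632 = d.g917, d.g632
    stolon = GREEN if g917 == "AA" else PURPLE
    seed_green = g917 == "AA" or g632 == "TT" or (g917 == "GA" and g632 == "GT")
    return PhenotypePair(stolon, GREEN if seed_green else PURPLE)


def _gametes(d: GeneDiplotype, r) -> dict[GeneHaplotype, Fraction]:
    """Gamete haplotype distribution with intragenic recombination rate r."""
    h1, h2 = d.hap1, d.hap2
    parental = (1 - r) / 2
    recomb = r / 2
    out: dict[GeneHaplotype, object] = {}
    for hap, p in [
        (h1, parental),
        (h2, parental),
        (GeneHaplotype(h1.allele_632, h2.allele_917), recomb),
        (GeneHaplotype(h2.allele_632, h1.allele_917), recomb),
    ]:
        out[hap] = out.get(hap, 0) + p
    return out


@dataclass
class CrossExpectation:
    """Offspring diplotype/phenotype distribution for one cross design."""

    diplotype_probs: dict[GeneDiplotype, object]
    phenotype_probs: dict[PhenotypePair, object]

    def p_green(self, tissue: str):
        total = 0
        for ph, p in self.phenotype_probs.items():
            if getattr(ph, tissue) == GREEN:
                total += p
        return total

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for d, p in self.diplotype_probs.items():
            ph = phenotype_from_diplotype(d)
            rows.append(
                {"g632": d.g632, "g917": d.g917, "probability": p,
                 "stolon": ph.stolon, "seed_head": ph.seed_head}
            )
        return pd.DataFrame(rows)


def cross_expectations(
    p1: GeneDiplotype,
    p2: GeneDiplotype | None = None,
    selfed: bool = False,
    r_intragenic=Fraction(0),
) -> CrossExpectation:
    """Exact offspring distribution of a cross (or selfing) at the gene.

    Gametes recombine between the two SNPs at rate ``r_intragenic``
    (default 0: the SNPs sit ~1.7 kb apart in one gene).  With a Fraction
    rate the probabilities are exact rationals.
    """
    if selfed:
        p2 = p1
    if p2 is None:
        raise ValueError("provide a second parent or set selfed=True")
    if not (0 <= float(r_intragenic) <= 0.5):
        raise ValueError("r_intragenic must lie in [0, 0.5]")
    g1, g2 = _gametes(p1, r_intragenic), _gametes(p2, r_intragenic)
    dip_probs: dict[GeneDiplotype, object] = {}
    for h1, q1 in g1.items():
        for h2, q2 in g2.items():
            d = GeneDiplotype(h1, h2)
            dip_probs[d] = dip_probs.get(d, 0) + q1 * q2
    ph_probs: dict[PhenotypePair, object] = {}
    for d, p in dip_probs.items():
        ph = phenotype_from_diplotype(d)
        ph_probs[ph] = ph_probs.get(ph, 0) + p
    return CrossExpectation(dip_probs, ph_probs)


# ---------------------------------------------------------------------------
# Hypothesis testing against observed genotype/phenotype tables
# ---------------------------------------------------------------------------

def test_hypotheses(genotypes: pd.DataFrame, phenotypes: Iterable[str]) -> pd.DataFrame:
    """Score each plant against the two candidate genetic architectures.

    ``genotypes`` needs columns ``g632`` and ``g917`` (unphased, e.g. "GT",
    "GA"); ``phenotypes`` is the seed-head colour per plant ("green" /
    "purple").  Hypothesis 1 (second mutation in the same gene, full
    linkage) predicts green seed heads exactly for plants heterozygous at
    both SNPs (or AA at SNP_917, or TT at SNP_632).  Hypothesis 2 (a linked
    second gene) predicts green only when the second-mutation marker is
    homozygous (TT at SNP_632 serves as its proxy) or SNP_917 is AA.

    Returns a per-plant frame with consistency flags plus summary counts in
    ``DataFrame.attrs["summary"]``.
    """
    phen = list(phenotypes)
    if len(phen) != len(genotypes):
        raise ValueError("genotype and phenotype tables are not aligned")
    rows = []
    for (_, g), ph in zip(genotypes.iterrows(), phen):
        g632, g917 = g["g632"], g["g917"]
        h1_green = g917 == "AA" or g632 == "TT" or (g917 == "GA" and g632 == "GT")
        h2_green = g917 == "AA" or g632 == "TT"
        obs_green = ph == GREEN
        rows.append(
            {
                "g632": g632, "g917": g917, "seed_head": ph,
                "consistent_h1": h1_green == obs_green,
                "consistent_h2": h2_green == obs_green,
            }
        )
    out = pd.DataFrame(rows, index=genotypes.index)
    out["inconsistent_both"] = ~out["consistent_h1"] & ~out["consistent_h2"]
    out.attrs["summary"] = {
        "n": len(out),
        "h1_inconsistent": int((~out["consistent_h1"]).sum()),
        "h2_inconsistent": int((~out["consistent_h2"]).sum()),
        "inconsistent_both": int(out["inconsistent_both"].sum()),
    }
    return out


# ---------------------------------------------------------------------------
# In-silico CAPS genotyping
# ---------------------------------------------------------------------------

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _iupac_regex(pattern: str) -> re.Pattern:
    return re.compile("".join(f"[{IUPAC[b]}]" for b in pattern.upper()))


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CapsAssay:
    """A CAPS (cleaved amplified polymorphic sequence) marker definition.

    ``amplicon`` is the PCR product (IUPAC DNA), ``snp_offset`` the 0-based
    position of the assayed SNP within it, ``allele_bases`` the base each
    allele places there, ``site`` the enzyme recognition pattern (IUPAC)
    and ``cut_offset`` the cut position within the pattern (bases from its
    5' end on the matched strand).
    """

    amplicon: str
    snp_offset: int
    allele_bases: Mapping[str, str]
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not (0 <= self.snp_offset < len(self.amplicon)):
            raise ValueError("snp_offset outside the amplicon")
        if len(self.site) < 4:
            raise ValueError("recognition pattern must be at least 4 bases")
        if not (0 <= self.cut_offset <= len(self.site)):
            raise ValueError("cut_offset outside the recognition pattern")


def caps_digest(assay: CapsAssay, allele: str) -> list[int]:
    """Fragment lengths after a complete digest of one allele's amplicon.

    The double-stranded recognition site is matched with IUPAC ambiguity in
    both orientations (overlapping occurrences included); each site
    occurrence produces one double-strand break, placed at the top-strand
    cut offset.  For a palindromic site (e.g. DdeI's CTNAG) the forward and
    reverse readings coincide and are cut once.
    """
    base = assay.allele_bases[allele]
    seq = (assay.amplicon[: assay.snp_offset] + base
           + assay.amplicon[assay.snp_offset + 1:]).upper()
    L, P = len(seq), len(assay.site)
    fwd_hits = set(_finditer_overlapping(_iupac_regex(assay.site), seq))
    rev_hits = set(
        _finditer_overlapping(_iupac_regex(reverse_complement(assay.site)), seq)
    )
    cuts = {m + assay.cut_offset for m in fwd_hits}
    # sites found only in reverse orientation: the enzyme reads 5'->3' on the
    # minus strand, so the top-strand cut sits at m + P - cut_offset
    cuts |= {m + P - assay.cut_offset for m in rev_hits - fwd_hits}
    cuts = sorted(c for c in cuts if 0 < c < L)
    bounds = [0] + cuts + [L]
    return sorted(b - a for a, b in zip(bounds[:-1], bounds[1:]))


def _finditer_overlapping(pattern: re.Pattern, seq: str):
    pos = 0
    while True:
        m = pattern.search(seq, pos)
        if m is None:
            return
        yield m.start()
        pos = m.start() + 1


def caps_genotype(
    fragments_ref: list[int], fragments_alt: list[int], observed: list[int]
) -> str:
    """Call a genotype from an observed band pattern.

    Band patterns are compared as sets of fragment lengths (gels resolve
    sizes, not copy number).  A heterozygote shows the union of both
    alleles' bands; identical allele patterns make the assay
    non-informative.
    """
    ref, alt, obs = set(fragments_ref), set(fragments_alt), set(observed)
    if ref == alt:
        return "non-informative"
    if obs == ref:
        return "hom-ref"
    if obs == alt:
        return "hom-alt"
    if obs == ref | alt:
        return "het"
    return "inconclusive"
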