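"""Controlled vocabularies: the 37-gene mitochondrial inventory and the
sense-codon table of the invertebrate mitochondrial genetic code.

Gene tokens follow MITOS-style lowercase naming.  The two leucine and two
serine tRNAs are distinct tokens: ``trnL1`` = Leu(CUN), ``trnL2`` = Leu(UUR),
``trnS1`` = Ser(AGN), ``trnS2`` = Ser(UCN).  ``CR`` marks the large
non-coding control region; it is a positional landmark, not a gene.
"""

from __future__ import annotations

PCG_TOKENS: tuple[str, ...] = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
)

RRNA_TOKENS: tuple[str, ...] = ("rrnS", "rrnL")

TRNA_TOKENS: tuple[str, ...] = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)

CONTROL_REGION = "CR"

#: The 37 genes expected in a complete record (control region excluded).
GENE_TOKENS: tuple[str, ...] = PCG_TOKENS + RRNA_TOKENS + TRNA_TOKENS

#: Full 38-token vocabulary including the control-region marker.
ALL_TOKENS: tuple[str, ...] = GENE_TOKENS + (CONTROL_REGION,)

CATEGORY_PCG = "PCG"
CATEGORY_RRNA = "rRNA"
CATEGORY_TRNA = "tRNA"
CATEGORY_CR = "control_region"

TOKEN_CATEGORY: dict[str, str] = {
    **{t: CATEGORY_PCG for t in PCG_TOKENS},
    **{t: CATEGORY_RRNA for t in RRNA_TOKENS},
    **{t: CATEGORY_TRNA for t in TRNA_TOKENS},
    CONTROL_REGION: CATEGORY_CR,
}

# ---------------------------------------------------------------------------
# Invertebrate mitochondrial genetic code (NCBI translation table 5).
# Stops are TAA and TAG only; TGA is Trp, ATA is Met, AGA/AGG are sense.
# ---------------------------------------------------------------------------

STOP_CODONS: tuple[str, str] = ("TAA", "TAG")

_BASES = "TCAG"

#: Amino acid of every sense codon under translation table 5.
TABLE5_CODON_AA: dict[str, str] = {}


def _build_table5() -> None:
    # TCAG-ordered 64-codon translation string for NCBI table 5.
    aas = "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSSSSVVVVAAAADDEEGGGG"
    i = 0
    for b1 in _BASES:
        for b2 in _BASES:
            for b3 in _BASES:
                aa = aas[i]
                i += 1
                if aa != "*":
                    TABLE5_CODON_AA[b1 + b2 + b3] = aa


_build_table5()

#: The 62 sense codons, alphabetically ordered (fixed key set for all tables).
SENSE_CODONS: tuple[str, ...] = tuple(sorted(TABLE5_CODON_AA))

assert len(SENSE_CODONS) == 62


def synonymous_families(strict_table5: bool = False) -> dict[str, tuple[str, ...]]:
    """Synonymous-codon families (amino acid -> codons) over the 62 sense codons.

    By default the AGR codons are grouped with the arginine family, the
    convention of common mitogenome codon-usage tools, so family sizes span
    two to six (Leu 6, Ser 6, Arg 6, four-fold boxes, two-fold boxes).  With
    ``strict_table5=True`` the literal table-5 amino-acid assignment is used
    instead (AGR -> Ser, giving an eight-codon serine family and a four-codon
    arginine family).
    """
    assignment = dict(TABLE5_CODON_AA)
    if not strict_table5:
        assignment["AGA"] = "R"
        assignment["AGG"] = "R"
    families: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        families.setdefault(assignment[codon], []).append(codon)
    return {aa: tuple(sorted(cs)) for aa, cs in sorted(families.items())}


#: Default family structure used for RSCU and per-amino-acid comparisons.
DEFAULT_FAMILIES: dict[str, tuple[str, ...]] = synonymous_families()

#: codon -> amino acid under the default family structure.
DEFAULT_CODON_AA: dict[str, str] = {
    c: aa for aa, codons in DEFAULT_FAMILIES.items() for c in codons
}
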