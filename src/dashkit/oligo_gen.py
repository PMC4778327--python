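"""Purchasable oligos and T7 transcription templates for sgRNA synthesis.

For each guide, a 60-mer forward oligo (T7 promoter + 20-mer target + the
first 22 bases of the tracr scaffold) is annealed to a constant 90-mer
(3' end of the sgRNA, opposite strand) through a 19-nt complementary
junction, then filled/amplified with two constant primers into a 131-bp
transcription template.  T7 RNA polymerase initiates at the promoter's
final G (+1), so the sgRNA transcript is the T→U copy of template
positions 17..131: always 114 nt and G-initiated.  No extra G is prepended
and the 20-mer is never mutated for initiation — the +1 G lives in the
promoter constant.
"""

from __future__ import annotations

from dataclasses import dataclass

from dashkit.guide_select import GuidePanel
from dashkit.pam_scan import revcomp

#: 18-nt T7 promoter; transcription initiates at its final G (+1)
T7_PROMOTER_18 = "TAATACGACTCACTATAG"
#: first 22 bases of the tracr scaffold, appended to the 20-mer in the 60-mer
TRACR_22 = "GTTTAAGAGCTATGCTGGAAAC"
#: constant 90-mer: 3' end of the sgRNA on the opposite strand
REV_90 = (
    "AAAAAAAGCACCGACTCGGTGCCACTTTTTCAAGTTGATAACGGACTAGCC"
    "TTATTTAAACTTGCTATGCTGTTTCCAGCATAGCTCTTA"
)
#: amplification primers (forward = promoter; reverse primes the 90-mer 5' end)
AMP_PRIMER_F = "TAATACGACTCACTATAG"
AMP_PRIMER_R = "AAAAAAAGCACCGACTCGGTGC"
#: constant 93-nt template tail downstream of the 20-mer (tracr scaffold + T7 terminator-less poly-T)
TEMPLATE_TAIL_93 = (
    "GTTTAAGAGCTATGCTGGAAACAGCATAGCAAGTTTAAATAAGGCTAGTCC"
    "GTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGCTTTTTTT"
)
#: 0-based template position of the T7 +1 G
T7_PLUS1_POS = 17
SGRNA_LEN = 114


@dataclass(frozen=True)
class OligoSet:
    """The purchasable DNA parts and predicted transcript for one guide."""

    guide_id: str
    fwd60: str
    rev90: str
    template131: str
    amp_primer_f: str
    amp_primer_r: str
    sgrna: str  # RNA alphabet

    def __post_init__(self):
        if len(self.fwd60) != 60 or len(self.rev90) != 90 or len(self.template131) != 131:
            raise ValueError("oligo lengths must be 60 / 90 / 131")
        if not self.template131.startswith(self.amp_primer_f):
            raise ValueError("template must start with the forward primer")
        if not revcomp(self.template131).startswith(self.amp_primer_r):
            raise ValueError("template reverse complement must start with the reverse primer")
        if len(self.sgrna) != SGRNA_LEN or not self.sgrna.startswith("G"):
            raise ValueError("sgRNA must be 114 nt and begin with G")


def make_oligos(n20: str, guide_id: str | None = None) -> OligoSet:
    """Build the oligo set for one 20-mer target.

    ``n20`` must be 20 nt over ACGT.  The assembled template equals
    promoter + n20 + constant tail, which is exactly what annealing the
    60-mer to the 90-mer through their 19-nt overlap and filling produces.
    """
    if len(n20) != 20:
        raise ValueError(f"target must be 20 nt, got {len(n20)}")
    if set(n20) - set("ACGT"):
        raise ValueError(f"target must be ACGT only, got {n20!r}")
    fwd60 = T7_PROMOTER_18 + n20 + TRACR_22
    template131 = T7_PROMOTER_18 + n20 + TEMPLATE_TAIL_93
    sgrna = template131[T7_PLUS1_POS:].replace("T", "U")
    return OligoSet(
        guide_id=guide_id if guide_id is not None else n20,
        fwd60=fwd60,
        rev90=REV_90,
        template131=template131,
        amp_primer_f=AMP_PRIMER_F,
        amp_primer_r=AMP_PRIMER_R,
        sgrna=sgrna,
    )


def make_panel_oligos(panel: GuidePanel) -> list[OligoSet]:
    """One OligoSet per panel site, in panel order."""
    return [make_oligos(s.protospacer, guide_id=s.site_id) for s in panel.sites]


def assemble_by_overlap(fwd: str, rev: str) -> tuple[str, int]:
    """Anneal-and-fill assembly of two oligos on opposite strands.

    Finds the longest suffix of ``fwd`` equal to a prefix of
    ``revcomp(rev)`` and returns ``(filled duplex top strand, overlap
    length)``.  Used as an independent check that the 60/90-mer pair
    reproduces the 131-bp template through its 19-nt junction.
    """
    rc = revcomp(rev)
    for k in range(min(len(fwd), len(rc)), 0, -1):
        if fwd.endswith(rc[:k]):
            return fwd + rc[k:], k
    raise ValueError("oligos share no overlap")
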