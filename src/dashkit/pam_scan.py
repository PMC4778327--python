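"""Exhaustive enumeration of S. pyogenes Cas9 target sites.

A target site is a 20-nt protospacer immediately 5' of an NGG protospacer
adjacent motif (PAM).  Cas9 leaves a blunt double-strand break 3 nt
upstream (5', protospacer side) of the PAM.  Sites are enumerated on both
strands; any site whose 20-mer or PAM contains N is suppressed, since Cas9
specificity is undefined there.

Coordinate conventions (0-based, half-open, forward-reference frame):

* ``+`` strand: protospacer occupies ``[proto_start, proto_start+20)``,
  PAM ``[pam_start, pam_start+3)`` with ``pam_start = proto_start + 20``;
  the cut falls between ``cut_pos-1`` and ``cut_pos`` with
  ``cut_pos = pam_start - 3``.
* ``-`` strand: ``proto_start`` is still the leftmost forward coordinate of
  the 20-mer; the PAM lies to its left (``pam_start = proto_start - 3``)
  and the cut falls between ``pam_start+5`` and ``pam_start+6``.

``protospacer`` and ``pam`` are always reported 5'→3' on the targeted
strand, so ``pam`` matches NGG for both orientations.
"""

from __future__ import annotations

from dataclasses import dataclass

from dashkit.formats import SequenceRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PROTOSPACER_LEN = 20
PAM_LEN = 3
#: cut offset: the blunt cut sits 3 nt 5' of the PAM
CUT_OFFSET = 3


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GuideSite:
    """One candidate protospacer + NGG PAM on a reference sequence."""

    chrom: str
    strand: str  # '+' or '-'
    protospacer: str  # 20 nt, 5'->3' on the targeted strand
    pam: str  # 3 nt, NGG, same orientation
    proto_start: int  # 0-based forward coordinate of leftmost protospacer base
    pam_start: int  # 0-based forward coordinate of leftmost PAM base
    cut_pos: int  # cut falls between cut_pos-1 and cut_pos (forward frame)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != PAM_LEN or self.pam[1:] != "GG":
            raise ValueError(f"PAM must match NGG, got {self.pam!r}")
        if "N" in self.protospacer or "N" in self.pam:
            raise ValueError("protospacer/PAM may not contain N")
        if self.strand == "+":
            ok = self.pam_start == self.proto_start + PROTOSPACER_LEN and \
                self.cut_pos == self.pam_start - CUT_OFFSET
        else:
            ok = self.pam_start == self.proto_start - PAM_LEN and \
                self.cut_pos == self.pam_start + PAM_LEN + CUT_OFFSET
        if not ok:
            raise ValueError("inconsistent site coordinates")

    @property
    def span(self) -> tuple[int, int]:
        """Forward-frame footprint [start, end) of protospacer + PAM."""
        if self.strand == "+":
            return self.proto_start, self.pam_start + PAM_LEN
        return self.pam_start, self.proto_start + PROTOSPACER_LEN

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.proto_start}:{self.strand}"


def find_pam_sites(record: SequenceRecord, strands: str = "both") -> list[GuideSite]:
    """Enumerate every Cas9 target site (20-mer + NGG) in ``record``.

    Parameters
    ----------
    record : SequenceRecord
    strands : '+', '-', or 'both'

    Returns
    -------
    list of GuideSite, sorted by proto_start then strand (+ before -).
    Sequences shorter than 23 nt yield an empty list.  Sites whose 20-mer
    or PAM contains N are suppressed.
    """
    if strands not in ("+", "-", "both"):
        raise ValueError(f"strands must be '+', '-' or 'both', got {strands!r}")
    seq = record.seq
    n = len(seq)
    sites: list[GuideSite] = []
    window = PROTOSPACER_LEN + PAM_LEN
    if n < window:
        return sites

    if strands in ("+", "both"):
        # NGG PAM at [p, p+3): GG at p+1, p+2; protospacer [p-20, p)
        for p in range(PROTOSPACER_LEN, n - PAM_LEN + 1):
            if seq[p + 1] == "G" and seq[p + 2] == "G":
                proto = seq[p - PROTOSPACER_LEN:p]
                pam = seq[p:p + PAM_LEN]
                if "N" in proto or "N" in pam:
                    continue
                sites.append(GuideSite(
                    chrom=record.id, strand="+", protospacer=proto, pam=pam,
                    proto_start=p - PROTOSPACER_LEN, pam_start=p,
                    cut_pos=p - CUT_OFFSET,
                ))

    if strands in ("-", "both"):
        # minus-strand NGG = forward CCN at [q, q+3); protospacer [q+3, q+23)
        for q in range(0, n - window + 1):
            if seq[q] == "C" and seq[q + 1] == "C":
                proto_fwd = seq[q + PAM_LEN:q + window]
                pam_fwd = seq[q:q + PAM_LEN]
                if "N" in proto_fwd or "N" in pam_fwd:
                    continue
                sites.append(GuideSite(
                    chrom=record.id, strand="-",
                    protospacer=revcomp(proto_fwd), pam=revcomp(pam_fwd),
                    proto_start=q + PAM_LEN, pam_start=q,
                    cut_pos=q + PAM_LEN + CUT_OFFSET,
                ))

    sites.sort(key=lambda s: (s.proto_start, 0 if s.strand == "+" else 1))
    return sites


def site_overlaps(site: GuideSite, interval: tuple[int, int]) -> bool:
    """True iff the site footprint intersects the 0-based half-open interval."""
    start, end = site.span
    a, b = interval
    return start < b and a < end
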