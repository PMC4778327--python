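"""Off-target screening of a guide panel against a reference sequence set.

Cas9 requires an intact NGG PAM; mismatch tolerance lives in the 20-mer
protospacer.  The screen therefore enumerates every PAM-adjacent 20-mer on
both strands of every reference record (reusing the PAM scanner) and
reports those within a Hamming-distance budget of any panel guide.  A hit
without NGG is never reported, regardless of 20-mer identity.  Brute-force
guide-by-site comparison is the reference implementation; desk-scale
references keep it tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from dashkit.formats import SequenceRecord
from dashkit.guide_select import GuidePanel
from dashkit.pam_scan import PROTOSPACER_LEN, find_pam_sites

DEFAULT_MAX_MISMATCHES = 4


def hamming20(a: str, b: str) -> int:
    """Hamming distance between two 20-nt strings (positional substitutions)."""
    if len(a) != PROTOSPACER_LEN or len(b) != PROTOSPACER_LEN:
        raise ValueError(f"expected 20-nt inputs, got {len(a)} and {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class OffTargetHit:
    """A PAM-intact reference site within the mismatch budget of a guide."""

    guide_id: str
    chrom: str
    strand: str
    start: int  # 0-based forward coordinate of the 20-mer's leftmost base
    mismatches: int
    pam_intact: bool = True
    gene_id: str | None = None


def find_offtargets(
    panel: GuidePanel,
    reference: list[SequenceRecord],
    max_mm: int = DEFAULT_MAX_MISMATCHES,
    annotation: pd.DataFrame | None = None,
) -> list[OffTargetHit]:
    """Screen every panel guide against every reference record.

    Parameters
    ----------
    panel : GuidePanel (non-empty)
    reference : sequence records to scan (both strands)
    max_mm : maximum protospacer mismatches (PAM must be exact NGG)
    annotation : optional BED-like frame (chrom, start, end, name); a hit
        overlapping an interval gets that interval's name as ``gene_id``.

    Returns one hit per (guide, position, strand); positions whose 20-mer
    or PAM contains N are skipped.
    """
    if len(panel) == 0:
        raise ValueError("panel is empty")
    guides = [(s.site_id, s.protospacer) for s in panel.sites]
    hits: list[OffTargetHit] = []
    for rec in reference:
        for site in find_pam_sites(rec, strands="both"):
            for guide_id, proto in guides:
                mm = hamming20(proto, site.protospacer)
                if mm <= max_mm:
                    gene = None
                    if annotation is not None:
                        s0, e0 = site.span
                        for _, row in annotation.iterrows():
                            if row["chrom"] == rec.id and s0 < row["end"] and row["start"] < e0:
                                gene = row["name"]
                                break
                    hits.append(OffTargetHit(
                        guide_id=guide_id, chrom=rec.id, strand=site.strand,
                        start=site.proto_start, mismatches=mm, gene_id=gene,
                    ))
    return hits


def summarize_by_gene(hits: list[OffTargetHit]) -> pd.DataFrame:
    """Aggregate hits per annotated gene.

    Returns a frame indexed by gene_id with columns n_sites, n_pam_intact,
    n_perfect (0 mismatches) and n_1_4mm (1-4 mismatches).  Hits without a
    gene_id are grouped under '.'.
    """
    cols = ["n_sites", "n_pam_intact", "n_perfect", "n_1_4mm"]
    if not hits:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(
        {
            "gene_id": [h.gene_id if h.gene_id is not None else "." for h in hits],
            "mismatches": [h.mismatches for h in hits],
            "pam_intact": [h.pam_intact for h in hits],
        }
    )
    out = df.groupby("gene_id").agg(
        n_sites=("mismatches", "size"),
        n_pam_intact=("pam_intact", "sum"),
        n_perfect=("mismatches", lambda m: int((m == 0).sum())),
        n_1_4mm=("mismatches", lambda m: int(((m >= 1) & (m <= 4)).sum())),
    )
    out["n_pam_intact"] = out["n_pam_intact"].astype(int)
    return out[cols]


def hits_to_frame(hits: list[OffTargetHit]) -> pd.DataFrame:
    """Tabular view of a hit list for TSV output."""
    return pd.DataFrame(
        [
            (h.guide_id, h.chrom, h.strand, h.start, h.mismatches,
             h.pam_intact, h.gene_id if h.gene_id is not None else ".")
            for h in hits
        ],
        columns=["guide_id", "chrom", "strand", "start", "mismatches",
                 "pam_intact", "gene_id"],
    )
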