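"""Fragment-level depletion simulation and the allele-specific PAM-ablation
model.

Cleavage rule: after tagmentation, only fragments with intact adaptors on
both ends amplify, so a single Cas9 cut anywhere in a fragment removes it
from the final library.  A fragment is *cleavable* iff it carries, on
either strand, a 20-mer within ``max_mm`` mismatches of a panel
protospacer immediately 5' of an intact NGG; each cleavable fragment is
then removed independently with probability ``efficiency``.

Allele model: for a hotspot mutation that destroys the PAM (e.g. a
Gly GGN -> non-Gly change at KRAS G12), the wild-type allele is cleaved
with efficiency ``e`` while the mutant escapes (``e_mut``, default 0).
The post-depletion mutant fraction is the closed form

    m_post = m (1 - e_mut) / (m (1 - e_mut) + (1 - m)(1 - e))

so depletion enriches the mutant by ``m_post / m`` fold.

ddPCR: droplet counts convert to copies-per-droplet via the Poisson
estimator lambda = -ln(1 - n_positive / n_total).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from dashkit.formats import SequenceRecord
from dashkit.guide_select import GuidePanel
from dashkit.offtarget import hamming20
from dashkit.pam_scan import find_pam_sites


@dataclass(frozen=True)
class Fragment:
    """One adaptor-flanked library molecule with a ground-truth label."""

    id: str
    seq: str
    origin: str = "untargeted"  # e.g. targeted/untargeted or wt/mut

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"fragment {self.id!r}: empty sequence")


@dataclass
class DepletionOutcome:
    """Survivors and per-origin survival bookkeeping for one simulated run."""

    survivors: list[Fragment]
    n_input: int
    n_cut: int
    origin_survival: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_input != self.n_cut + len(self.survivors):
            raise ValueError("fragment conservation violated")

    @property
    def survival_fraction(self) -> float:
        return len(self.survivors) / self.n_input if self.n_input else float("nan")


def fragment_is_cleavable(seq: str, protospacers: list[str], max_mm: int = 0) -> bool:
    """True iff the fragment contains a PAM-adjacent 20-mer within
    ``max_mm`` of any panel protospacer (either strand)."""
    rec = SequenceRecord(id="frag", seq=seq)
    if max_mm == 0:
        pool = set(protospacers)
        return any(s.protospacer in pool for s in find_pam_sites(rec))
    return any(
        hamming20(s.protospacer, p) <= max_mm
        for s in find_pam_sites(rec)
        for p in protospacers
    )


def deplete_library(
    fragments: list[Fragment],
    panel: GuidePanel,
    efficiency: float,
    max_mm: int = 0,
    seed: int | np.random.Generator = 0,
) -> DepletionOutcome:
    """Simulate DASH on a fragment library.

    Each cleavable fragment is removed independently with probability
    ``efficiency`` (seeded); non-cleavable fragments always survive.
    Survivors preserve input order.
    """
    if not 0 <= efficiency <= 1:
        raise ValueError("efficiency must be in [0, 1]")
    if len(panel) == 0:
        raise ValueError("panel is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    protospacers = panel.protospacers()
    survivors: list[Fragment] = []
    n_cut = 0
    per_origin_in: dict[str, int] = {}
    per_origin_out: dict[str, int] = {}
    for frag in fragments:
        per_origin_in[frag.origin] = per_origin_in.get(frag.origin, 0) + 1
        cut = fragment_is_cleavable(frag.seq, protospacers, max_mm) and \
            rng.random() < efficiency
        if cut:
            n_cut += 1
        else:
            survivors.append(frag)
            per_origin_out[frag.origin] = per_origin_out.get(frag.origin, 0) + 1
    origin_survival = {
        k: per_origin_out.get(k, 0) / n for k, n in per_origin_in.items()
    }
    return DepletionOutcome(
        survivors=survivors,
        n_input=len(fragments),
        n_cut=n_cut,
        origin_survival=origin_survival,
    )


# ---------------------------------------------------------------------------
# allele-specific depletion (PAM ablation)

@dataclass(frozen=True)
class AlleleModel:
    """Closed-form mutant-allele enrichment under allele-specific cleavage."""

    m: float  # input mutant fraction
    e: float  # wild-type cleavage efficiency
    e_mut: float  # mutant cleavage efficiency
    m_post: float  # post-depletion mutant fraction
    fold: float  # m_post / m (nan when m == 0)


def allele_enrichment(m: float, e: float, e_mut: float = 0.0) -> AlleleModel:
    """Post-depletion mutant fraction when only the wild type is cleavable.

    ``m_post = m(1-e_mut) / (m(1-e_mut) + (1-m)(1-e))``; enrichment fold is
    ``m_post/m``.  Errors when every molecule is cleaved (denominator 0).
    """
    for name, v in (("m", m), ("e", e), ("e_mut", e_mut)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    denom = m * (1 - e_mut) + (1 - m) * (1 - e)
    if denom == 0:
        raise ValueError("all molecules cleaved: post-depletion fraction undefined")
    m_post = m * (1 - e_mut) / denom
    fold = m_post / m if m > 0 else float("nan")
    return AlleleModel(m=m, e=e, e_mut=e_mut, m_post=m_post, fold=fold)


def solve_cleavage_efficiency(m: float, m_post: float, e_mut: float = 0.0) -> float:
    """Invert the allele model: the wild-type efficiency e that maps an
    input mutant fraction ``m`` to an observed post-depletion fraction
    ``m_post``."""
    if not 0 < m < 1 or not 0 < m_post < 1:
        raise ValueError("m and m_post must be in (0, 1)")
    if m_post < m:
        raise ValueError("m_post < m implies negative wild-type depletion")
    a = m * (1 - e_mut)
    e = 1 - a * (1 - m_post) / (m_post * (1 - m))
    return e


# ---------------------------------------------------------------------------
# PAM ablation test for codon variants

def _pam_positions(ctx: str) -> set[tuple[str, int]]:
    """All NGG PAM placements in a context string, as (strand, start).

    On '+', a PAM at ``p`` means GG at ``p+1, p+2``; on '-', forward CCN at
    ``p`` (the CC at ``p, p+1`` is the reverse-complement GG).
    """
    pams = set()
    for p in range(len(ctx) - 2):
        if ctx[p + 1] == "G" and ctx[p + 2] == "G":
            pams.add(("+", p))
        if ctx[p] == "C" and ctx[p + 1] == "C":
            pams.add(("-", p))
    return pams


def is_pam_ablating(
    ref_codon: str,
    alt_codon: str,
    flank5: str = "N",
    flank3: str = "N",
) -> tuple[bool, list[tuple[str, int]]]:
    """Does a codon change destroy a PAM whose GG overlaps the codon?

    Builds the 5-nt context ``flank5 + codon + flank3`` for both alleles
    and enumerates NGG placements on both strands.  Returns ``(ablating,
    lost)`` where ``lost`` lists the (strand, context position) of every
    reference PAM whose GG (or CC on the minus strand) has at least one
    base inside the codon and which is absent from the alternate context.
    A change that only moves the N of NGG never ablates.
    """
    for name, c in (("ref_codon", ref_codon), ("alt_codon", alt_codon)):
        if len(c) != 3 or set(c) - set("ACGT"):
            raise ValueError(f"{name} must be a 3-nt ACGT codon, got {c!r}")
    if len(flank5) != 1 or len(flank3) != 1:
        raise ValueError("flanks must be single bases")
    ref_ctx = flank5 + ref_codon + flank3
    alt_ctx = flank5 + alt_codon + flank3
    codon_pos = {1, 2, 3}
    ref_pams = _pam_positions(ref_ctx)
    alt_pams = _pam_positions(alt_ctx)
    lost = []
    for strand, p in sorted(ref_pams - alt_pams):
        # GG bases sit at p+1, p+2 on '+'; the CC at p, p+1 on '-'
        gg = {p + 1, p + 2} if strand == "+" else {p, p + 1}
        if gg & codon_pos:
            lost.append((strand, p))
    return bool(lost), lost


# ---------------------------------------------------------------------------
# droplet digital PCR

def ddpcr_concentration(n_positive: int, n_total: int) -> float:
    """Copies per droplet from positive-droplet counts (Poisson estimator
    ``lambda = -ln(1 - n_positive/n_total)``).  Saturated wells error."""
    if n_total <= 0 or n_positive < 0:
        raise ValueError("need 0 <= n_positive < n_total")
    if n_positive >= n_total:
        raise ValueError("saturated well: every droplet positive")
    return -math.log(1.0 - n_positive / n_total)


def ddpcr_mutant_fraction(pos_mut: int, pos_wt: int, n_total: int) -> float:
    """Mutant allele fraction lambda_mut / (lambda_mut + lambda_wt)."""
    lam_mut = ddpcr_concentration(pos_mut, n_total)
    lam_wt = ddpcr_concentration(pos_wt, n_total)
    if lam_mut + lam_wt == 0:
        raise ValueError("no template detected in either channel")
    return lam_mut / (lam_mut + lam_wt)


def simulate_droplets(
    lam_mut: float,
    lam_wt: float,
    n_droplets: int,
    seed: int | np.random.Generator = 0,
) -> tuple[int, int]:
    """Seeded Monte-Carlo droplet generation from true per-droplet loads.

    Each droplet receives Poisson(lam) copies per channel; a droplet is
    positive when it holds >= 1 copy.  Returns (n_positive_mut,
    n_positive_wt).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos_mut = int((rng.poisson(lam_mut, n_droplets) > 0).sum())
    pos_wt = int((rng.poisson(lam_wt, n_droplets) > 0).sum())
    return pos_mut, pos_wt
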