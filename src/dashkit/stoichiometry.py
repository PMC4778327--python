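"""Reaction stoichiometry: from sample mass to molar Cas9/sgRNA amounts.

The abundant fraction of a library contributes one Cas9 target site per
``spacing_bp`` of double-stranded DNA.  At 650 g/mol per base pair, the
molar target-site concentration of a reaction is

    target_site_nM = total_ng * abundant_fraction
                     / (spacing_bp * mw_per_bp * volume_ul) * 1e6

Cas9 and sgRNA are dosed as fold excesses over the target sites (Cas9 is
single-turnover in vitro, so large excesses are required for complete
cleavage).  Example: 5 ng of which 90 % is targeted rRNA, 50 bp guide
spacing, 10 uL reaction -> 13.8 nM target sites; 100x Cas9 and 1000x
sgRNA give 1.38 uM and 13.8 uM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: average molar mass of double-stranded DNA, g/mol per base pair
MW_PER_BP = 650.0


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures, half away from zero."""
    if x == 0 or not math.isfinite(x):
        return x
    exp = math.floor(math.log10(abs(x)))
    q = 10.0 ** (exp - sig + 1)
    value = math.copysign(math.floor(abs(x) / q + 0.5) * q, x)
    # clean up binary-float artefacts (27.700000000000003 -> 27.7)
    return round(value, max(0, sig - exp - 1))


@dataclass(frozen=True)
class ReactionPlan:
    """Molar stoichiometry of one depletion reaction."""

    total_ng: float
    abundant_fraction: float
    spacing_bp: int
    volume_ul: float
    cas9_fold: float
    sgrna_fold: float
    mw_per_bp: float
    target_site_nM: float
    cas9_uM: float
    sgrna_uM: float

    def summary(self) -> str:
        """Human-readable plan, concentrations at 3 significant figures."""
        lines = [
            "DASH reaction plan",
            f"  sample:        {self.total_ng} ng, abundant fraction {self.abundant_fraction}",
            f"  guide spacing: {self.spacing_bp} bp  (one site per {self.spacing_bp} bp of substrate)",
            f"  volume:        {self.volume_ul} uL",
            f"  target sites:  {round_sig(self.target_site_nM)} nM",
            f"  Cas9:          {round_sig(self.cas9_uM)} uM  ({self.cas9_fold}x over target)",
            f"  sgRNA:         {round_sig(self.sgrna_uM)} uM  ({self.sgrna_fold}x over target)",
        ]
        return "\n".join(lines)


def plan_reaction(
    total_ng: float,
    abundant_fraction: float,
    spacing_bp: int = 50,
    volume_ul: float = 10.0,
    cas9_fold: float = 100.0,
    sgrna_fold: float = 1000.0,
    mw_per_bp: float = MW_PER_BP,
) -> ReactionPlan:
    """Compute target-site molarity and Cas9/sgRNA amounts for a reaction.

    All inputs must be >= 0 and ``volume_ul`` > 0.  Concentrations are
    stored at full precision; rounding (3 significant figures) happens only
    in :meth:`ReactionPlan.summary`.
    """
    if volume_ul <= 0:
        raise ValueError("volume_ul must be > 0")
    if not 0 <= abundant_fraction <= 1:
        raise ValueError("abundant_fraction must be in [0, 1]")
    if min(total_ng, spacing_bp, cas9_fold, sgrna_fold, mw_per_bp) < 0:
        raise ValueError("inputs must be >= 0")
    # ng -> nmol of sites: mass_ng / (spacing * mw) ; / volume_L -> nM
    target_site_nM = total_ng * abundant_fraction / (spacing_bp * mw_per_bp * volume_ul) * 1e6
    cas9_uM = cas9_fold * target_site_nM / 1000.0
    sgrna_uM = sgrna_fold * target_site_nM / 1000.0
    return ReactionPlan(
        total_ng=total_ng,
        abundant_fraction=abundant_fraction,
        spacing_bp=spacing_bp,
        volume_ul=volume_ul,
        cas9_fold=cas9_fold,
        sgrna_fold=sgrna_fold,
        mw_per_bp=mw_per_bp,
        target_site_nM=target_site_nM,
        cas9_uM=cas9_uM,
        sgrna_uM=sgrna_uM,
    )


def implied_fold(conc_uM: float, plan: ReactionPlan) -> float:
    """Fold excess of a component at ``conc_uM`` over the plan's target sites."""
    if plan.target_site_nM == 0:
        raise ValueError("plan has zero target-site concentration")
    return conc_uM * 1000.0 / plan.target_site_nM
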