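"""Post-depletion evaluation statistics.

Everything downstream of alignment and counting: fpkm, fold changes and
percent reductions, the untargeted-gene enrichment regression, exact
duplicate fraction as a library-complexity proxy, and the replicate-based
off-target flagging procedure (drop noisy genes with replicate SD > 50 %
of the mean, then flag untargeted genes whose log2 fold change falls more
than 2 SD below the mean of the fold-change distribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: genes below this fpkm are annotated low-confidence in flagging output
LOW_CONFIDENCE_FPKM = 15.0


def fpkm(counts: float, gene_length_bp: float, total_mapped: float) -> float:
    """Fragments per kilobase of transcript per million mapped fragments:
    ``counts * 1e9 / (gene_length_bp * total_mapped)``."""
    if gene_length_bp < 1:
        raise ValueError("gene_length_bp must be >= 1")
    if total_mapped < 1:
        raise ValueError("total_mapped must be >= 1")
    return counts * 1e9 / (gene_length_bp * total_mapped)


def fold_change(a: float, b: float) -> float:
    """Fold change b/a (enrichment when b > a, reduction reciprocal)."""
    if a == 0:
        raise ValueError("zero denominator")
    return b / a


def pct_reduction(pre: float, post: float) -> float:
    """Percent reduction ``100 * (1 - post/pre)``."""
    if pre == 0:
        raise ValueError("zero pre-treatment value")
    return 100.0 * (1.0 - post / pre)


def enrichment_fit(untreated, dashed) -> tuple[float, float]:
    """Enrichment of untargeted genes after depletion.

    Fits ``dashed = slope * untreated`` by least squares through the
    origin on linear fpkm; the reported R^2 is computed from the residuals
    of that fit on the log10 scale (expression spans orders of magnitude,
    so goodness of fit is judged in log space while the slope remains a
    literal fold enrichment).

    Requires >= 2 genes with both values > 0; other genes are ignored.
    """
    x = np.asarray(untreated, dtype=float)
    y = np.asarray(dashed, dtype=float)
    keep = (x > 0) & (y > 0)
    x, y = x[keep], y[keep]
    if len(x) < 2:
        raise ValueError("need >= 2 genes with positive fpkm in both samples")
    slope = float(np.dot(x, y) / np.dot(x, x))
    ly = np.log10(y)
    resid = ly - np.log10(slope * x)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, max(0.0, min(1.0, r_squared))


def duplicate_fraction(reads, prefix_len: int | None = None) -> float:
    """Exact-duplicate fraction: ``1 - n_distinct / n_reads``.

    Reads are compared over their first ``prefix_len`` bases (default: the
    whole read).  Accepts strings or objects with a ``seq`` attribute.
    """
    seqs = [r.seq if hasattr(r, "seq") else r for r in reads]
    if not seqs:
        raise ValueError("empty read set")
    if prefix_len is not None:
        seqs = [s[:prefix_len] for s in seqs]
    return 1.0 - len(set(seqs)) / len(seqs)


def flag_offtarget_genes(
    control: pd.DataFrame,
    treated: pd.DataFrame,
    targeted: set[str] | list[str],
) -> pd.DataFrame:
    """Replicate-based off-target depletion screen.

    Parameters
    ----------
    control, treated : DataFrames of fpkm values, genes x replicates
        (>= 2 replicates each, same gene index).
    targeted : gene ids deliberately depleted; excluded from the null
        distribution and never flagged.

    Procedure: genes whose replicate SD exceeds 50 % of the replicate mean
    in either condition are dropped as too noisy to call.  On the
    survivors excluding targeted genes, log2(treated mean / control mean)
    is computed and genes falling below ``mean - 2 SD`` of that
    distribution are flagged.  Genes with control fpkm below 15 are
    annotated low-confidence but still tested.

    Returns a frame indexed by gene id with columns mean_control,
    mean_treated, log2_fc, noisy, targeted, low_confidence, flagged.
    """
    if control.shape[1] < 2 or treated.shape[1] < 2:
        raise ValueError("need >= 2 replicates per condition")
    if not control.index.equals(treated.index):
        treated = treated.reindex(control.index)
        if treated.isna().any().any():
            raise ValueError("control and treated gene sets differ")
    targeted = set(targeted)

    mean_c = control.mean(axis=1)
    mean_t = treated.mean(axis=1)
    sd_c = control.std(axis=1, ddof=1)
    sd_t = treated.std(axis=1, ddof=1)
    # SD > 50 % of mean in either condition -> too noisy to call
    noisy = (sd_c > 0.5 * mean_c) | (sd_t > 0.5 * mean_t)
    is_targeted = control.index.to_series().isin(targeted)

    testable = (~noisy) & (~is_targeted) & (mean_c > 0) & (mean_t > 0)
    l2fc = pd.Series(np.nan, index=control.index)
    l2fc[testable] = np.log2(mean_t[testable] / mean_c[testable])

    null = l2fc[testable]
    flagged = pd.Series(False, index=control.index)
    if len(null) >= 2:
        cutoff = null.mean() - 2.0 * null.std(ddof=1)
        flagged = (l2fc < cutoff) & testable

    return pd.DataFrame({
        "mean_control": mean_c,
        "mean_treated": mean_t,
        "log2_fc": l2fc,
        "noisy": noisy,
        "targeted": is_targeted,
        "low_confidence": mean_c < LOW_CONFIDENCE_FPKM,
        "flagged": flagged,
    })


@dataclass
class DepletionReport:
    """Per-gene and aggregate statistics comparing untreated and DASHed
    libraries."""

    per_gene: pd.DataFrame  # gene_id-indexed: fpkm_untreated, fpkm_dashed, fold_change, targeted
    aggregates: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return self.per_gene

    def summary(self) -> str:
        lines = ["Depletion report"]
        for k, v in self.aggregates.items():
            lines.append(f"  {k}: {v:.4g}" if isinstance(v, float) else f"  {k}: {v}")
        return "\n".join(lines)


def make_depletion_report(
    fpkm_untreated: pd.Series,
    fpkm_dashed: pd.Series,
    targeted: set[str] | list[str],
    dup_frac_untreated: float | None = None,
    dup_frac_dashed: float | None = None,
) -> DepletionReport:
    """Assemble a DepletionReport from per-gene fpkm of a paired run.

    Targeted percentages are each condition's targeted-gene share of total
    fpkm; the enrichment regression runs on untargeted genes only.
    """
    targeted = set(targeted)
    idx = fpkm_untreated.index
    is_t = idx.to_series().isin(targeted)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(fpkm_untreated > 0, fpkm_dashed / fpkm_untreated, np.nan)
    per_gene = pd.DataFrame({
        "fpkm_untreated": fpkm_untreated,
        "fpkm_dashed": fpkm_dashed,
        "fold_change": fc,
        "targeted": is_t,
    })
    pct_un = 100.0 * fpkm_untreated[is_t].sum() / fpkm_untreated.sum()
    pct_da = 100.0 * fpkm_dashed[is_t].sum() / fpkm_dashed.sum()
    aggregates = {
        "targeted_pct_untreated": float(pct_un),
        "targeted_pct_dashed": float(pct_da),
        "pct_reduction": pct_reduction(pct_un, pct_da) if pct_un > 0 else np.nan,
    }
    untgt = ~is_t
    if untgt.sum() >= 2:
        slope, r2 = enrichment_fit(fpkm_untreated[untgt], fpkm_dashed[untgt])
        aggregates["enrichment_slope"] = slope
        aggregates["r_squared"] = r2
    if dup_frac_untreated is not None:
        aggregates["dup_frac_untreated"] = dup_frac_untreated
    if dup_frac_dashed is not None:
        aggregates["dup_frac_dashed"] = dup_frac_dashed
    return DepletionReport(per_gene=per_gene, aggregates=aggregates)
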