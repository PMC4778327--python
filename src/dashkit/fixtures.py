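"""Deterministic synthetic-data generators.

Every module is testable without downloads: these generators emulate the
study conditions of a mitochondrial-rRNA-dominated RNA-Seq library (one
~2.5 kb abundant block holding 61 % of depth for a HeLa-like sample or
90 % for a CSF-like sample, lognormal background gene abundances) and of
wild-type/mutant allele mixtures at a PAM-ablating hotspot codon.  All
randomness flows through ``numpy.random.default_rng(seed)``, so outputs
are bit-reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dashkit.formats import CoverageTrack, SequenceRecord
from dashkit.pam_scan import GuideSite, find_pam_sites, revcomp
from dashkit.depletion_sim import Fragment
from dashkit.metrics import fpkm as _fpkm

#: abundant-region depth share emulating a HeLa-like total-RNA library
HELA_LIKE_FRACTION = 0.61
#: abundant-region depth share emulating a CSF-like amplified-cDNA library
CSF_LIKE_FRACTION = 0.90


@dataclass
class SyntheticDesign:
    """Parameters of one synthetic library."""

    seed: int
    abundant_fraction: float = HELA_LIKE_FRACTION
    abundant_len: int = 2500
    n_background_genes: int = 200
    gc: float = 0.44
    n_fragments: int = 10_000
    fragment_len_mean: float = 200.0
    fragment_len_sd: float = 30.0
    mutant_fraction: float = 0.0  # for allele mixtures: m in {0.1, 0.01, 0.001, 0}
    abundance_sigma: float = 1.0  # lognormal sigma of background weights


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.44) -> str:
    """Random DNA with the given GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def make_transcriptome(
    seed: int,
    abundant_len: int = 2500,
    n_background_genes: int = 200,
    gc: float = 0.44,
    abundant_fraction: float = HELA_LIKE_FRACTION,
    flank: int = 20_000,
    total_depth_bases: int = 2_000_000,
    abundance_sigma: float = 1.0,
) -> tuple[list[SequenceRecord], CoverageTrack, pd.DataFrame]:
    """Synthetic transcriptome with one designated abundant rRNA-like block.

    Returns ``(records, track, gene_table)`` where records[0] is an
    rRNA-carrying chromosome (flank + abundant region + flank) followed by
    background genes; the coverage track over that chromosome concentrates
    ``abundant_fraction`` of its depth in the abundant region; and the
    gene table carries two abundant genes (splitting the block 12S/16S
    style) plus lognormally weighted background genes with counts and
    fpkm.
    """
    rng = np.random.default_rng(seed)
    chrom_len = abundant_len + 2 * flank
    chrom = SequenceRecord(id="chrM_like", seq=random_dna(rng, chrom_len, gc))
    records = [chrom]
    gene_lengths = {}
    # the abundant block splits into a short and a long subunit gene
    len_12s = abundant_len * 2 // 5
    len_16s = abundant_len - len_12s
    gene_lengths["rRNA_small"] = len_12s
    gene_lengths["rRNA_large"] = len_16s
    for i in range(n_background_genes):
        length = int(np.clip(rng.lognormal(7.2, 0.5), 300, 10_000))
        gid = f"gene_{i:04d}"
        records.append(SequenceRecord(id=gid, seq=random_dna(rng, length, gc)))
        gene_lengths[gid] = length

    # per-base depth: abundant_fraction of depth inside the block
    depth = np.zeros(chrom_len, dtype=np.int64)
    mean_in = abundant_fraction * total_depth_bases / abundant_len
    mean_out = (1 - abundant_fraction) * total_depth_bases / (2 * flank)
    depth[:flank] = rng.poisson(mean_out, flank)
    depth[flank:flank + abundant_len] = rng.poisson(mean_in, abundant_len)
    depth[flank + abundant_len:] = rng.poisson(mean_out, flank)
    track = CoverageTrack(chrom=chrom.id, depth=depth)

    # abundance weights: abundant genes share abundant_fraction, background
    # genes split the remainder lognormally
    w_bg = rng.lognormal(0.0, abundance_sigma, n_background_genes)
    w_bg = (1 - abundant_fraction) * w_bg / w_bg.sum()
    weights = np.concatenate((
        [abundant_fraction * len_12s / abundant_len,
         abundant_fraction * len_16s / abundant_len],
        w_bg,
    ))
    n_reads = 1_000_000
    counts = rng.multinomial(n_reads, weights)
    gene_ids = list(gene_lengths)
    table = pd.DataFrame({
        "length_bp": [gene_lengths[g] for g in gene_ids],
        "count": counts,
    }, index=pd.Index(gene_ids, name="gene_id"))
    table["fpkm"] = [
        _fpkm(c, l, n_reads) for c, l in zip(table["count"], table["length_bp"])
    ]
    return records, track, table


def abundant_region_interval(abundant_len: int = 2500, flank: int = 20_000) -> tuple[int, int]:
    """0-based half-open interval of the abundant block on the synthetic
    chromosome (matches make_transcriptome's layout)."""
    return flank, flank + abundant_len


def make_fragments(design: SyntheticDesign) -> list[Fragment]:
    """Tagmentation-style fragment library from a synthetic transcriptome.

    Each fragment originates from the abundant block with probability
    ``design.abundant_fraction`` (label ``targeted``) or from a random
    background gene (label ``untargeted``); lengths are clipped normal.
    """
    # independent stream from the transcriptome's (same seed, distinct key)
    rng = np.random.default_rng((design.seed, 0xF2A6))
    records, _, _ = make_transcriptome(
        design.seed,
        abundant_len=design.abundant_len,
        n_background_genes=design.n_background_genes,
        gc=design.gc,
        abundant_fraction=design.abundant_fraction,
        abundance_sigma=design.abundance_sigma,
    )
    chrom = records[0]
    start0, end0 = abundant_region_interval(design.abundant_len)
    background = records[1:]
    fragments = []
    lengths = np.clip(
        rng.normal(design.fragment_len_mean, design.fragment_len_sd, design.n_fragments),
        60, None,
    ).astype(int)
    targeted = rng.random(design.n_fragments) < design.abundant_fraction
    for i in range(design.n_fragments):
        L = int(lengths[i])
        if targeted[i]:
            src = chrom.seq[start0:end0]
            origin = "targeted"
        else:
            src = background[rng.integers(len(background))].seq
            origin = "untargeted"
        L = min(L, len(src))
        s = int(rng.integers(0, len(src) - L + 1))
        fragments.append(Fragment(id=f"frag_{i:06d}", seq=src[s:s + L], origin=origin))
    return fragments


def make_library_and_panel(
    design: SyntheticDesign,
    spacing_bp: int = 50,
    slack: int = 10,
):
    """One synthetic study: fragments plus the guide panel tiling the
    abundant block of the same transcriptome.

    Returns ``(fragments, panel)``; the panel is selected from the actual
    PAM sites of the seeded chromosome over the abundant region, so
    ``targeted`` fragments are cleavable and ``untargeted`` ones are not.
    """
    from dashkit.guide_select import TargetRegion, select_guides

    records, _, _ = make_transcriptome(
        design.seed,
        abundant_len=design.abundant_len,
        n_background_genes=design.n_background_genes,
        gc=design.gc,
        abundant_fraction=design.abundant_fraction,
        abundance_sigma=design.abundance_sigma,
    )
    chrom = records[0]
    s, e = abundant_region_interval(design.abundant_len)
    region = TargetRegion(chrom=chrom.id, start=s, end=e, peak_depth=1, mean_depth=1.0)
    panel = select_guides(find_pam_sites(chrom), [region],
                          spacing_bp=spacing_bp, slack=slack)
    return make_fragments(design), panel


def make_enrichment_table(
    seed: int,
    n_genes: int = 1000,
    enrichment: float = 2.38,
    noise_sigma: float = 0.15,
    abundance_sigma: float = 0.7,
) -> pd.DataFrame:
    """Paired fpkm table with a planted untargeted-gene enrichment.

    fpkm_untreated is lognormal; fpkm_dashed = enrichment * fpkm_untreated
    * multiplicative mean-1 lognormal noise, so a through-origin least
    squares fit recovers ``enrichment``.  The through-origin estimator is
    an x^2-weighted mean, so its effective sample size is
    ``n / exp(4 * abundance_sigma^2)``; the defaults keep that near 140 of
    1000 genes and the estimator's standard error near 1-2 %.
    """
    rng = np.random.default_rng(seed)
    x = rng.lognormal(2.0, abundance_sigma, n_genes)
    noise = rng.lognormal(-noise_sigma ** 2 / 2, noise_sigma, n_genes)
    y = enrichment * x * noise
    idx = pd.Index([f"gene_{i:04d}" for i in range(n_genes)], name="gene_id")
    return pd.DataFrame({"fpkm_untreated": x, "fpkm_dashed": y}, index=idx)


# ---------------------------------------------------------------------------
# KRAS-like allele mixture (PAM-ablating hotspot)

#: amplification primers flanking the hotspot amplicon
KRAS_PRIMER_F = "TAGCTGTATCGTCAAGGCAC"
KRAS_PRIMER_R = "GGCCTGCTGAAAATGACTGA"
#: probed hotspot core on the top strand (reverse complement of the
#: hydrolysis probes); the G12 glycine codon GGT carries the PAM
_KRAS_CORE_WT = "TGGAGCTGGTGGCGTAGGCA"
_KRAS_CORE_MUT = "TGGAGCTGATGGCGTAGGCA"  # c.35G>A, p.G12D: GGT -> GAT
_LINKER_5 = "ACCTTGACGA"
_LINKER_3 = "TCGATTACAG"

#: top-strand amplicons for the two alleles
KRAS_WT_AMPLICON = KRAS_PRIMER_F + _LINKER_5 + _KRAS_CORE_WT + _LINKER_3 + revcomp(KRAS_PRIMER_R)
KRAS_MUT_AMPLICON = KRAS_PRIMER_F + _LINKER_5 + _KRAS_CORE_MUT + _LINKER_3 + revcomp(KRAS_PRIMER_R)


def kras_g12d_guide() -> GuideSite:
    """The guide whose PAM is ablated by the G12D change.

    Found by scanning the wild-type amplicon for the site whose PAM
    footprint covers the mutated base; the protospacer itself is identical
    between alleles, so specificity comes entirely from the NGG.
    """
    diff = [i for i, (a, b) in enumerate(zip(KRAS_WT_AMPLICON, KRAS_MUT_AMPLICON)) if a != b]
    assert len(diff) == 1
    mut_pos = diff[0]
    wt_sites = find_pam_sites(SequenceRecord(id="kras_wt", seq=KRAS_WT_AMPLICON))
    hits = [s for s in wt_sites if s.pam_start <= mut_pos < s.pam_start + 3]
    ablating = [s for s in hits if s not in find_pam_sites(
        SequenceRecord(id="kras_wt", seq=KRAS_MUT_AMPLICON))]
    if len(ablating) != 1:
        raise AssertionError(f"expected one PAM-ablated site, got {len(ablating)}")
    return ablating[0]


def make_allele_mixture(m: float, n: int, seed: int) -> list[Fragment]:
    """n amplicon fragments with mutant fraction ~ Binomial(n, m)."""
    if not 0 <= m <= 1:
        raise ValueError("m must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    is_mut = rng.random(n) < m
    return [
        Fragment(
            id=f"allele_{i:06d}",
            seq=KRAS_MUT_AMPLICON if is_mut[i] else KRAS_WT_AMPLICON,
            origin="mut" if is_mut[i] else "wt",
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# pseudogene off-target fixture

@dataclass
class PseudogeneFixture:
    """A guide panel plus a degenerate pseudogene copy with known hit counts."""

    guides: list[GuideSite]
    source: SequenceRecord
    pseudogene: SequenceRecord
    annotation: pd.DataFrame
    n_panel: int
    n_pam_intact: int
    n_perfect: int
    n_1_4mm: int


def make_pseudogene_fixture(
    seed: int,
    n_panel: int = 24,
    n_pam_intact: int = 16,
    n_perfect: int = 7,
    region_len: int = 2000,
    gc: float = 0.44,
) -> PseudogeneFixture:
    """Source region + pseudogene copy with engineered divergence.

    Emulates a pseudogene highly homologous to a targeted rRNA region:
    of ``n_panel`` guides drawn from the source, ``n_pam_intact`` keep an
    intact NGG in the pseudogene (``n_perfect`` of them with a perfect
    20-mer, the rest carrying 1-4 protospacer substitutions) and the
    remainder have their PAM destroyed.  Guides are chosen with disjoint,
    well-separated footprints so edits never interact.
    """
    if not n_perfect <= n_pam_intact <= n_panel:
        raise ValueError("need n_perfect <= n_pam_intact <= n_panel")
    rng = np.random.default_rng(seed)
    for attempt in range(50):
        seq = random_dna(rng, region_len, gc)
        src = SequenceRecord(id="rRNA_region", seq=seq)
        plus_sites = [s for s in find_pam_sites(src) if s.strand == "+"]
        chosen: list[GuideSite] = []
        last_end = -10
        for s in plus_sites:
            if s.proto_start >= last_end + 5:
                chosen.append(s)
                last_end = s.pam_start + 3
            if len(chosen) == n_panel:
                break
        if len(chosen) == n_panel:
            break
    else:
        raise RuntimeError("could not place the requested panel")

    pseudo = list(seq)
    n_mm = n_pam_intact - n_perfect
    other = {"A": "C", "C": "A", "G": "T", "T": "A"}
    # sites [n_perfect, n_perfect+n_mm): 1-4 protospacer substitutions
    for k, s in enumerate(chosen[n_perfect:n_perfect + n_mm]):
        n_subs = 1 + k % 4
        pos = rng.choice(20, size=n_subs, replace=False)
        for p in pos:
            i = s.proto_start + int(p)
            pseudo[i] = other[pseudo[i]]
    # sites [n_pam_intact, n_panel): destroy the PAM (GG -> GT)
    for s in chosen[n_pam_intact:]:
        pseudo[s.pam_start + 2] = "T"
    pseudogene = SequenceRecord(id="pseudogene", seq="".join(pseudo))
    annotation = pd.DataFrame(
        [("pseudogene", 0, region_len, "MT_RNR_like_pseudogene")],
        columns=["chrom", "start", "end", "name"],
    )
    return PseudogeneFixture(
        guides=chosen,
        source=src,
        pseudogene=pseudogene,
        annotation=annotation,
        n_panel=n_panel,
        n_pam_intact=n_pam_intact,
        n_perfect=n_perfect,
        n_1_4mm=n_mm,
    )
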