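# Methods

This note records the models, conventions and design choices behind
dashkit, in the spirit of a package methods appendix.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Site model and coordinates

A Cas9 target site is a 20-nt protospacer with an NGG PAM immediately 3′
on the same strand; the blunt double-strand cut falls 3 nt 5′ of the PAM.
All internal coordinates are 0-based half-open on the forward reference
frame; conversion to 1-based happens only in human-readable output.  For
a `+` site, `pam_start = proto_start + 20` and `cut_pos = pam_start − 3`
(the cut lies between `cut_pos − 1` and `cut_pos`).  For a `−` site,
`proto_start` still names the leftmost forward coordinate of the 20-mer,
the PAM sits at `proto_start − 3`, and the cut falls between
`pam_start + 5` and `pam_start + 6`.  The convention is internal: the
depletion simulator uses it only to decide that a fragment has been
severed, so any self-consistent choice gives identical library-level
results.

Sites whose 20-mer or PAM contains N are suppressed (Cas9 specificity on
N is undefined); N is otherwise legal in references.  The scanner is
exhaustive — overlapping and adjacent sites are all reported, and
de-overlapping is the selector's job.

## Region calling and guide selection

High-abundance target regions are maximal runs with depth ≥
`frac_of_max × max(depth)` (default 0.1), merged across gaps shorter
than `merge_gap` (50 bp) and dropped below `min_len` (100 bp).  These
defaults reproduce a single ~2.5 kb block on an rRNA-peak-like profile
and are all overridable.

Panel selection is greedy left-to-right per region, ordered by cut
position with ties broken `+` strand first then lower start: take the
first candidate, then repeatedly the first whose cut position is at
least `spacing_bp − slack` beyond the previous selection.  Defaults are
`spacing_bp = 50` and `slack = 10`, so an "approximately every 50 bp"
tiling is honored when no candidate sits exactly on the grid.  Greedy
selection is deterministic and gives the testable guarantees that panel
size is non-increasing in `spacing_bp` and all selected gaps are
≥ `spacing_bp − slack`.  No sequence-composition filters are applied by
default.

## Off-target screening

Mismatches are counted only on the 20-mer (positional Hamming distance);
the PAM must be an exact NGG — a site whose PAM is lost is never
reported, whatever its 20-mer.  The default budget is 4 mismatches,
matching the observed off-target class for a highly homologous
pseudogene (perfect hits plus hits carrying 1–4 substitutions).
Brute-force guide × site comparison is the reference implementation;
desk-scale references (≲ tens of kb) keep it tractable, and the tests pin
it site-for-site against an independent quadratic window scan.  Weighted
activity scores (CFD/MIT-style) and genome-scale indexing are out of
scope.

## Oligo assembly and the T7 transcript

Each guide's purchasable parts are a variable 60-mer (18-nt T7 promoter
+ 20-mer target + first 22 nt of the tracr scaffold) and a constant
90-mer carrying the remainder of the scaffold on the opposite strand.
They anneal through a 19-nt complementary junction (60 + 90 − 131 = 19)
and fill to a 131-bp transcription template that is, by construction,
promoter + N20 + a constant 93-nt tail.  T7 RNA polymerase initiates at
the promoter's final G (+1 at template position 17, 0-based), so the
predicted sgRNA is the T→U copy of positions 17–130: always 114 nt and
G-initiated.  No extra G is prepended and the 20-mer is never mutated
for initiation, since the +1 G lives in the promoter constant.  The
constants are carried verbatim and checked by string equality in the
tests.

## Stoichiometry

Mass-to-moles assumes one target site per `spacing_bp` of double-stranded
DNA at 650 g/mol per base pair — the standard average dsDNA molar mass,
exposed as a parameter.  Concentrations are kept at full precision and
rounded to 3 significant figures (half away from zero) only at
presentation.  `implied_fold` inverts the dosing relation and round-trips
with `plan_reaction` to floating tolerance, which is property-tested.

## Depletion simulation

Cleavage is fragment-level and all-or-nothing: a fragment is cleavable
iff it contains, on either strand, a PAM-adjacent 20-mer within `max_mm`
of a panel protospacer (default `max_mm = 0`: in vitro cleavage of
mismatched sites is not modeled; off-target *risk* is reported separately
by the screen).  Each cleavable fragment is removed independently with a
single global probability `efficiency` — per-guide efficiencies are not
modeled because no per-guide data exist to calibrate them; a per-guide
override table is accepted.  Fragment conservation
(`n_input = n_cut + survivors`) and seeded determinism are invariants.
For a library with targeted fraction *f*, the expected post-depletion
targeted fraction is the closed form `f(1−e) / (f(1−e) + 1 − f)`; the
simulator is checked against it within 3 binomial standard errors at
n = 10⁴ over an (f, e) grid.

The allele model applies the same logic per allele: with mutant input
fraction *m*, wild-type efficiency *e* and mutant efficiency `e_mut`
(default 0, consistent with a PAM-ablated allele being uncleavable),
`m_post = m(1−e_mut) / (m(1−e_mut) + (1−m)(1−e))`.  Enrichment is
monotone increasing in *e* and decreasing in `e_mut` (property-tested on
grids).  `solve_cleavage_efficiency` inverts the model in closed form;
the tests confirm it against Brent root finding.  Observed mixtures imply
slightly different efficiencies (≈ 97–98 %), so *e* is treated as a free
parameter rather than asserted as one value.

`is_pam_ablating` decides whether a codon change destroys a PAM whose GG
(or CC on the minus strand) has at least one base inside the codon — the
N of NGG never gates, and a substitution confined to the codon can only
ablate through a codon base.  An exhaustive 64-codon × 9-SNV check
against a brute-force enumeration confirms the glycine/proline rule: any
non-synonymous hit to the GG of a GGN (or CC of a CCN) codon ablates.

ddPCR uses the standard Poisson estimator `λ = −ln(1 − p_positive)` per
channel, with saturated wells rejected; the mutant fraction is
`λ_mut/(λ_mut+λ_wt)`.

## Evaluation metrics

`fpkm = counts · 10⁹ / (length_bp · total_mapped)`.  The untargeted-gene
enrichment is a least-squares slope through the origin on **linear**
fpkm, so the slope is literally a fold enrichment; R² is computed from
the residuals of that same fit on the log10 scale, where expression
spanning orders of magnitude makes goodness of fit meaningful.  A pure
log-space fit is a defensible alternative; the linear-through-origin
reading was chosen because a reported slope > 1 on a log-log plot can
only mean a fold factor.

Library complexity is summarized by the exact-duplicate fraction
`1 − n_distinct/n_reads` (optionally over a read prefix); near-duplicate
clustering is deliberately out of scope.

Off-target flagging mirrors the replicate-based screen: genes whose
replicate SD exceeds 50 % of the replicate mean in either condition are
dropped as too noisy; on the survivors, excluding the deliberately
targeted genes, log2(treated mean / control mean) is computed and genes
below `mean − 2 SD` of that distribution are flagged.  The 2-SD rule is
applied to log2 fold changes rather than raw fpkm differences, since the
screened quantity is relative depletion.  Genes under 15 fpkm are
annotated low-confidence but still tested, and targeted genes are never
flagged (they are excluded from the null and reported separately).
Under a null simulation the flagged fraction sits near the expected
~2.3 % lower Gaussian tail.

## Synthetic data: what it emulates and what it does not

`make_transcriptome` builds a chromosome of two 20-kb flanks around a
2.5-kb abundant block plus ~200 background genes (lengths lognormal
around ~1.3 kb, GC 0.44), with a Poisson per-base coverage track placing
a configurable share of depth in the block — 0.61 for a HeLa-like
total-RNA library, 0.90 for a CSF-like amplified-cDNA library — and a
gene table with multinomial counts over lognormal abundance weights.
The flank length is chosen so flank depth sits far below the 10 %-of-max
calling threshold, making region recovery deterministic.
`make_fragments` draws clipped-normal (200 ± 30 bp) fragments from the
block or from background genes with the same abundant fraction, labeled
`targeted`/`untargeted` as ground truth.

`make_enrichment_table` plants a uniform fold enrichment (default 2.38)
under multiplicative mean-1 lognormal noise (σ = 0.15) on lognormal
abundances (σ = 0.7).  Because the through-origin estimator is an
x²-weighted mean, its effective sample size is ≈ n/exp(4σ²_abundance);
the defaults keep that near 140 of 1000 genes and the estimator's
standard error at 1–2 %, so a 5 % recovery check is meaningful rather
than luck.  Real libraries have heavier abundance tails, under which the
same estimator is noisier.

The KRAS-like allele mixture embeds the hotspot context reconstructed
from the printed primer/probe sequences (the probed 20-mer is the
reverse complement of the hydrolysis probes), joined by fixed linkers —
labelled synthetic, not a genomic amplicon.  The wild-type glycine codon
carries the NGG; the G12D change (c.35G>A) destroys it while leaving the
protospacer intact, so allele discrimination in the simulator comes
entirely from the PAM, as in the real assay.  Mixtures are Binomial(n, m)
draws at m ∈ {0.1, 0.01, 0.001, 0}.

The pseudogene fixture constructs a homolog with engineered divergence —
of 24 guides drawn from a source region, 16 keep intact PAMs (7 perfect,
9 with 1–4 protospacer substitutions) and 8 lose theirs — to exercise
the per-gene summary at realistic counts.  It is a constructed stand-in:
reproducing the same counts from the real pseudogene/rRNA pair would
require the original guide list and genome, which desk-scale tests do
not assume.

What passing these tests shows is that the algorithms are correct on
libraries matching their stated generative model; they do not certify
behavior under sequencing error, PCR bias, non-uniform coverage within
the abundant block, or kinetic (time- and concentration-dependent) Cas9
cleavage, none of which are modeled.

## Problem sizes and numerics

Defaults throughout were chosen to run in seconds on one CPU: oracle
cross-checks use 23–2000-nt sequences (100 seeded instances), off-target
oracles 2-kb references × 5 guides, depletion grids 10⁴ fragments, and
droplet simulations 2–5 × 10⁴ droplets.  Stochastic checks assert within
3 standard errors of their sampling distribution; exact checks (scanner,
off-target finder, oligo assembly, greedy selection) assert bit-identical
equality.  Degenerate inputs error loudly: empty sequences, saturated
ddPCR wells, zero reaction volume, all-cleaved allele mixtures,
fewer than 2 replicates or 2 positive fpkm pairs.

## Known limitations

- No guide activity/efficiency scoring; all guides are treated as
  equally active unless a per-guide table is supplied.
- Alternative PAMs (Cas12a, engineered variants) are not supported.
- Optimal (set-cover) panel selection is not attempted; greedy tiling is
  the documented contract.
- The off-target screen is exact brute force; genome-scale references
  need an external indexed tool.
- ddPCR modeling ignores rain (partial droplets) and assumes equal
  droplet volumes.
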