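"""Bundled worked-example measurements for the evaluation metrics.

Small published summary numbers from DASH depletion experiments, shipped
so the metrics operations have concrete inputs: per-patient 12S/16S rRNA
fpkm before and after depletion in three clinical CSF metagenomics cases
(with the matching pathogen read percentages), the HeLa targeted-read
percentages, and the droplet-PCR mutant-allele percentages of the KRAS
G12D wild-type-depletion mixtures.  These are measured inputs, not values
the package computes.
"""

from __future__ import annotations

import io

import pandas as pd

# Three clinical CSF cases: per-condition fpkm of the targeted 12S/16S
# mitochondrial rRNA genes and the read percentage of each case's
# representative pathogenic gene (16S for B. mandrillaris, 18S otherwise).
_CSF_TSV = """\
patient\tpathogen\tfpkm_12s_untreated\tfpkm_12s_dashed\tfpkm_16s_untreated\tfpkm_16s_dashed\tpathogen_pct_untreated\tpathogen_pct_dashed
1\tB. mandrillaris\t298922\t28005\t380073\t93164\t0.028\t0.102
2\tC. neoformans\t361501\t37168\t342857\t93703\t1.5\t15.4
3\tT. solium\t451044\t46993\t317640\t43257\t12.0\t44.3
"""


def csf_depletion_summary() -> pd.DataFrame:
    """The three-patient CSF depletion summary as a DataFrame."""
    return pd.read_csv(io.StringIO(_CSF_TSV), sep="\t").set_index("patient")


#: HeLa library: percent of uniquely mapped reads in the targeted
#: 12S/16S genes before and after depletion
HELA_TARGETED_PCT_UNTREATED = 61.0
HELA_TARGETED_PCT_DASHED = 0.055

#: HeLa dosing: 1 ng input (5x less sample), Cas9/sgRNA reduced 5-fold,
#: targeted fraction ~0.6 instead of 0.9
HELA_TOTAL_NG = 1.0
HELA_ABUNDANT_FRACTION = 0.6
HELA_CAS9_UM = 1.38 / 5.0

#: ddPCR mutant-allele fractions of wild-type-depletion mixtures:
#: input mutant fraction -> observed post-depletion mutant fraction
KRAS_MIXTURES = {0.1: 0.81, 0.01: 0.30, 0.001: 0.06}
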