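"""Published top-20 single-SNP results from the obstructive heart defect
parent-of-origin study being reproduced (569 case families, 877 SNPs in 60
folate-, homocysteine- and transsulfuration-pathway genes).

Each row carries the SNP, its referent/risk alleles, chromosome, gene,
pathway, the imprinting relative risk with its 95% CI (paternally- versus
maternally-derived risk allele), and the likelihood-ratio p-value.  These
printed summary statistics are the only public data from the study (the
genotypes are restricted) and serve as input for validating significance
calling against the panel-wide Bonferroni threshold of 0.05 / 877.
"""

from __future__ import annotations

import pandas as pd

N_SNPS_TESTED = 877
N_CASE_FAMILIES = 569
N_FULL_TRIOS = 220

_COLUMNS = (
    "snp_id", "alleles", "chr", "gene", "pathway",
    "rr", "ci_low", "ci_high", "p_value",
)

_TOP20 = [
    ("rs6812588", "G/A", "4", "RFC1", "folate", 0.11, 0.04, 0.29, 9.16e-7),
    ("rs1762430", "G/A", "10", "MGMT", "transsulfuration", 0.30, 0.17, 0.53, 9.80e-6),
    ("rs9296695", "A/G", "6", "GSTA3", "transsulfuration", 0.34, 0.20, 0.57, 2.28e-5),
    ("rs4712023", "A/G", "6", "GSTA3", "transsulfuration", 0.34, 0.20, 0.58, 3.77e-5),
    ("rs9299871", "A/G", "10", "MGMT", "transsulfuration", 0.22, 0.10, 0.49, 8.81e-5),
    ("rs7541539", "A/C", "1", "MTR", "homocysteine", 0.27, 0.14, 0.53, 8.81e-5),
    ("rs7069462", "A/G", "10", "MGMT", "transsulfuration", 0.20, 0.09, 0.47, 1.02e-4),
    ("rs2273027", "A/G", "17", "SHMT1", "folate", 2.14, 1.46, 3.13, 1.27e-4),
    ("rs12202200", "A/G", "6", "GSTA3", "transsulfuration", 0.36, 0.20, 0.64, 2.79e-4),
    ("rs6577", "C/A", "6", "GSTA2", "transsulfuration", 0.31, 0.16, 0.60, 2.90e-4),
    ("rs7818511", "A/G", "8", "GSR", "transsulfuration", 0.38, 0.22, 0.65, 2.93e-4),
    ("rs600473", "C/A", "5", "BHMT", "homocysteine", 1.87, 1.34, 2.62, 3.19e-4),
    ("rs9382157", "A/G", "6", "GSTA3", "transsulfuration", 0.37, 0.21, 0.65, 4.18e-4),
    ("rs1547177", "A/C", "10", "MGMT", "transsulfuration", 0.35, 0.19, 0.65, 5.67e-4),
    ("rs2152151", "C/G", "10", "MGMT", "transsulfuration", 0.34, 0.18, 0.66, 7.28e-4),
    ("rs2062228", "A/G", "4", "RFC1", "folate", 0.24, 0.10, 0.56, 1.11e-3),
    ("rs2424905", "A/G", "20", "DNMT3B", "homocysteine", 0.55, 0.38, 0.80, 1.31e-3),
    ("rs2363641", "G/A", "14", "GSTZ1", "transsulfuration", 1.90, 1.28, 2.80, 1.46e-3),
    ("rs4796017", "G/A", "17", "NOS2A", "transsulfuration", 1.75, 1.23, 2.50, 2.53e-3),
    ("rs7081756", "C/A", "10", "MAT1A", "homocysteine", 0.54, 0.36, 0.82, 2.54e-3),
]


def top20_results() -> pd.DataFrame:
    """The published top-20 scan rows, ordered by ascending p-value."""
    return pd.DataFrame(_TOP20, columns=_COLUMNS)
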