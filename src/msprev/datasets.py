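"""Published summary tables from the Lazio region MS prevalence study.

These are the printed worked-example inputs the package's operations are
exercised against: age- and gender-specific case counts and denominators on
the prevalence day (2011-12-31), crude and standardized Local Health Unit
(LHU) rates, the data-source overlap decomposition, and the gold-standard
validation counts.  All values are aggregate counts and rates — no
individual-level data.
"""

from __future__ import annotations

import io

import pandas as pd

_AGE_GENDER_CSV = """\
age_band,gender,cases,population
0-14,female,10,377117
0-14,male,8,400174
15-24,female,161,258499
15-24,male,86,272381
25-34,female,786,337250
25-34,male,386,327865
35-44,female,1444,480267
35-44,male,687,451034
45-54,female,1335,458242
45-54,male,628,429264
55-64,female,814,370602
55-64,male,400,337570
65+,female,400,665683
65+,male,232,487060
"""

_LHU_CSV = """\
lhu_id,cases,crude_rate,standardized_rate,ci_low,ci_high,pr,p_value
RM A,742,137.3,134.0,121.4,147.9,1.03,0.604
RM B,1008,147.5,147.5,134.6,161.6,1.13,0.009
RM C,783,147.4,147.6,133.9,162.6,1.13,0.013
RM D,714,129.2,129.5,117.3,143.1,0.99,0.885
RM E,704,140.7,140.8,127.4,155.6,1.08,0.136
RM F,349,114.1,112.9,99.7,127.9,0.87,0.023
RM G,658,136.9,136.8,123.6,151.5,1.05,0.363
RM H,599,110.5,110.0,99.1,122.1,0.84,0.001
Viterbo,345,111.0,112.1,98.9,127.1,0.86,0.017
Rieti,260,165.5,169.6,147.6,194.9,1.30,0.000
Latina,533,95.9,96.3,86.4,107.3,0.74,0.000
Frosinone,682,138.3,140.5,127.0,155.4,1.08,0.151
"""

#: Fig.-2-style source-overlap counts among the 7377 prevalent cases, with the
#: repeat-claim counts among exclusive-source cases where published.
SOURCE_OVERLAP_COUNTS = {
    "total_prevalent": 7377,
    "exclusive_hdr": 1150,
    "exclusive_hdr_multi_claim": 329,
    "exclusive_ter": 1034,
    "exclusive_pharmed": 766,
    "exclusive_pharmed_multi_claim": 599,
}

#: Gold-standard clinic-cohort linkage counts.
VALIDATION_COUNTS = {
    "total": 3881,
    "matched": 3297,
    "missing_id": 171,
    "unmatched_with_id": 413,
}


def load_age_gender_counts() -> pd.DataFrame:
    """Case counts and population denominators by age band x gender."""
    return pd.read_csv(io.StringIO(_AGE_GENDER_CSV))


def load_lhu_table() -> pd.DataFrame:
    """Published per-LHU counts, crude and adjusted rates, PRs and p-values."""
    return pd.read_csv(io.StringIO(_LHU_CSV))
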