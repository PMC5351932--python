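"""Printed demographic summaries of the two-brain-bank post-mortem study.

Per cohort (LNDBB = London Neurodegenerative Diseases Brain Bank, DBCBB =
Douglas-Bell Canada Brain Bank), brain region and diagnosis group: sample
count and age-at-death mean +/- SD, as published in the study's sample
overview table.  These summaries are inputs for recomputing the group
comparison tests; the raw individual-level data are not deposited.
"""

from __future__ import annotations

import io as _io

import pandas as pd

__all__ = ["cohort_age_summaries"]

_AGE_TSV = """\
cohort\tregion\tgroup\tn\tage_mean\tage_sd
LNDBB\tPFC\tcase\t20\t62.05\t15.87
LNDBB\tPFC\tcontrol\t23\t62.04\t18.74
LNDBB\tSTR\tcase\t21\t61.76\t16.61
LNDBB\tSTR\tcontrol\t28\t63.43\t18.16
LNDBB\tHC\tcase\t14\t60.71\t15.93
LNDBB\tHC\tcontrol\t13\t61.92\t17.80
LNDBB\tCER\tcase\t21\t61.76\t16.61
LNDBB\tCER\tcontrol\t23\t61.39\t19.25
DBCBB\tPFC\tcase\t18\t45.50\t16.61
DBCBB\tPFC\tcontrol\t15\t42.27\t14.80
DBCBB\tSTR\tcase\t16\t46.25\t17.10
DBCBB\tSTR\tcontrol\t17\t45.65\t16.82
DBCBB\tCER\tcase\t16\t44.56\t15.84
DBCBB\tCER\tcontrol\t17\t45.65\t16.82
"""


def cohort_age_summaries() -> pd.DataFrame:
    """Age-at-death group summaries per cohort and brain region."""
    return pd.read_csv(_io.StringIO(_AGE_TSV), sep="\t")
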