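"""Reference per-patient results on the Freiburg iEEG cohort.

The 19-patient Freiburg benchmark results of the permutation-entropy /
SVM / firing-power predictor are shipped as a small table: per patient,
sensitivity (fraction), false prediction rate (per hour), mean seizure
prediction horizon (minutes) and the selection distance, for both the
two-step and the one-step firing-power variant.  They serve as fixed
reference input for aggregation — e.g. recomputing the cohort averages
— without access to the underlying recordings.

Note the shipped ``distance`` columns average to 11.46 (two-step) and
22.89 (one-step); these column means are what :func:`cohort_averages`
reports.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

from .evaluation_selection import aggregate_report

__all__ = ["load_benchmark", "cohort_averages"]

_BENCHMARK_CSV = """\
patient,SS_two,FPR_two,SPH_two,dist_two,SS_one,FPR_one,SPH_one,dist_one
1,1.000,0.281,59.00,15.25,0.906,0.406,58.97,18.25
2,0.708,0.042,49.90,29.28,0.708,0.708,56.60,39.45
3,1.000,0.125,63.02,9.26,0.950,0.275,64.52,14.96
4,1.000,0.000,60.17,0.00,1.000,0.000,60.17,0.00
5,0.800,0.525,55.75,36.42,0.825,1.000,58.27,42.94
6,1.000,0.167,59.76,6.67,1.000,1.292,63.01,36.90
7,1.000,0.042,63.26,4.17,1.000,0.458,71.26,25.58
9,1.000,0.000,67.21,0.00,1.000,0.775,67.21,51.67
10,1.000,0.000,75.57,0.00,1.000,0.125,77.52,7.25
11,0.781,0.063,54.23,22.04,0.781,0.250,59.75,23.58
12,1.000,0.125,34.50,26.67,1.000,0.125,34.50,26.67
14,1.000,0.063,48.87,4.65,1.000,0.406,62.74,28.89
15,1.000,0.000,59.38,0.00,1.000,0.438,67.82,15.56
16,0.800,0.200,58.63,24.89,0.800,0.325,64.07,28.28
17,1.000,0.000,77.66,0.00,1.000,0.275,85.46,20.37
18,0.925,0.075,64.29,10.89,0.950,0.250,67.16,10.23
19,0.875,0.250,65.55,17.85,0.906,0.375,62.17,18.44
20,0.975,0.150,79.35,9.70,1.000,0.450,79.54,20.00
21,1.000,0.000,80.53,0.00,1.000,0.100,81.88,5.88
"""


def load_benchmark() -> pd.DataFrame:
    """Per-patient benchmark table, indexed by patient id."""
    return pd.read_csv(StringIO(_BENCHMARK_CSV), index_col="patient")


def cohort_averages() -> pd.DataFrame:
    """Benchmark table with the unweighted cohort-mean row appended."""
    return aggregate_report(load_benchmark())
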