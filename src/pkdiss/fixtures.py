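"""Published reference tables from the six-brand ciprofloxacin rabbit
study, transcribed as machine-readable fixtures.

These summary tables (dissolution factors, noncompartmental and
compartmental parameter means +/- SD, and relative bioavailability)
are used by consistency tests: the raw per-animal data behind them was
never published, so they serve as output-format references and for
desk-checking internal identities (e.g. Cl/F = Dose/AUCinf), not as
refitting targets.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["load_reference_tables", "table1", "table2", "table3", "table4"]

_TABLE1 = """product,f2,f1
A,44.63,13.55
B,66.95,3.56
C,58.17,0.78
D,48.40,3.73
E,58.43,5.90
"""

# noncompartmental parameters, mean and SD per brand (F = reference)
_TABLE2 = """parameter,product,mean,sd
tmax,A,1,0
tmax,B,1,0
tmax,C,1.5,0
tmax,D,1,0
tmax,E,1,0
tmax,F,1,0
cmax,A,11,0.12
cmax,B,10.83,0.13
cmax,C,9.73,0.16
cmax,D,11.64,0.11
cmax,E,10.87,0.11
cmax,F,10.35,0.13
auc_last,A,47.99,0.35
auc_last,B,40.04,0.52
auc_last,C,44.23,0.72
auc_last,D,44.44,0.62
auc_last,E,47.97,0.22
auc_last,F,45.763,0.49
lambda_z,A,0.23,0.01
lambda_z,B,0.23,0.008
lambda_z,C,0.23,0.015
lambda_z,D,0.23,0.01
lambda_z,E,0.21,0.01
lambda_z,F,0.177,0.01
hl_lambda_z,A,3.001,0.19
hl_lambda_z,B,2.99,0.19
hl_lambda_z,C,3.02,0.195
hl_lambda_z,D,3.00,0.18
hl_lambda_z,E,3.33,0.17
hl_lambda_z,F,4.17,0.20
auc_inf,A,57.45,2.07
auc_inf,B,47.42,1.95
auc_inf,C,53.46,2.10
auc_inf,D,52.89,1.54
auc_inf,E,59.58,1.14
auc_inf,F,62.24,1.98
vz_f,A,37.67,1.02
vz_f,B,45.51,0.95
vz_f,C,40.76,1.072
vz_f,D,40.96,1.24
vz_f,E,40.31,1.34
vz_f,F,48.32,0.89
cl_f,A,8.703,0.21
cl_f,B,10.54,0.25
cl_f,C,9.36,0.37
cl_f,D,9.45,0.24
cl_f,E,8.39,0.16
cl_f,F,8.04,0.26
aumc_last,A,138.02,3.12
aumc_last,B,109.93,3.29
aumc_last,C,130.55,4.62
aumc_last,D,124.23,3.65
aumc_last,E,140.69,1.36
aumc_last,F,140.03,3.25
mrt_last,A,2.87,0.04
mrt_last,B,2.74,0.03
mrt_last,C,2.95,0.06
mrt_last,D,2.79,0.04
mrt_last,E,2.93,0.03
mrt_last,F,3.06,0.04
"""

# two-compartment fit parameters, mean and SD per brand
_TABLE3 = """parameter,product,mean,sd
A,A,12.56,0.12
A,B,17.73,0.17
A,C,1.24,0.09
A,D,1.05,0.13
A,E,1.20,0.11
A,F,22.46,0.21
B,A,11.36,0.05
B,B,10.44,0.12
B,C,11.82,0.08
B,D,12.44,0.24
B,E,11.59,0.07
B,F,9.94,0.19
alpha,A,2.01,0.04
alpha,B,2.03,0.05
alpha,C,0.64,0.15
alpha,D,0.24,0.12
alpha,E,0.25,0.06
alpha,F,2.22,0.05
beta,A,0.24,0.005
beta,B,0.23,0.007
beta,C,0.22,0.003
beta,D,0.23,0.004
beta,E,0.21,0.006
beta,F,0.16,0.002
k12,A,0.57,0.02
k12,B,0.62,0.03
k12,C,0.01,0.006
k12,D,0.07,0.003
k12,E,0.01,0.007
k12,F,0.77,0.102
k21,A,1.16,0.24
k21,B,1.28,0.32
k21,C,0.63,0.13
k21,D,0.01,0.003
k21,E,0.24,0.093
k21,F,1.35,0.052
auc_model,A,56.20,1.85
auc_model,B,46.60,2.54
auc_model,C,52.92,2.48
auc_model,D,74.53,3.57
auc_model,E,61.15,4.25
auc_model,F,62.23,3.27
alpha_hl,A,0.37,0.01
alpha_hl,B,0.34,0.05
alpha_hl,C,1.84,0.03
alpha_hl,D,1.56,0.06
alpha_hl,E,3.63,0.02
alpha_hl,F,0.31,0.04
beta_hl,A,3.01,0.25
beta_hl,B,3.07,0.37
beta_hl,C,3.15,0.29
beta_hl,D,2.99,0.21
beta_hl,E,3.43,0.035
beta_hl,F,4.32,0.33
v1_f,A,29.20,2.54
v1_f,B,29.90,2.96
v1_f,C,41.73,3.51
v1_f,D,41.80,3.21
v1_f,E,40.62,3.24
v1_f,F,30.41,3.75
cl_f,A,10.90,0.34
cl_f,B,10.70,0.42
cl_f,C,9.46,0.63
cl_f,D,6.70,0.41
cl_f,E,8.19,0.95
cl_f,F,8.04,0.85
v2_f,A,11.36,0.23
v2_f,B,14.50,0.39
v2_f,C,0.23,0.03
v2_f,D,10.35,0.51
v2_f,E,1.30,0.24
v2_f,F,17.33,1.61
tmax,A,0.54,0.1
tmax,B,0.60,0.3
tmax,C,0.99,0.3
tmax,D,0.56,0.2
tmax,E,0.61,0.09
tmax,F,0.60,0.07
cmax,A,10.89,0.95
cmax,B,10.57,1.73
cmax,C,9.57,0.93
cmax,D,10.49,1.01
cmax,E,10.84,0.57
cmax,F,10.45,0.85
"""

_TABLE4 = """product,fr_percent
A,93.24
B,98.05
C,104.01
D,101.58
E,108.01
"""


def _read(text: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(text))


def table1() -> pd.DataFrame:
    """Dissolution f1/f2 of each generic against the reference."""
    return _read(_TABLE1)


def table2() -> pd.DataFrame:
    """Noncompartmental parameter summaries (long format)."""
    return _read(_TABLE2)


def table3() -> pd.DataFrame:
    """Two-compartment fit parameter summaries (long format)."""
    return _read(_TABLE3)


def table4() -> pd.DataFrame:
    """Relative bioavailability of each generic vs the reference (%)."""
    return _read(_TABLE4)


def load_reference_tables() -> dict[str, pd.DataFrame]:
    """All four reference tables keyed 'table1' .. 'table4'."""
    return {
        "table1": table1(),
        "table2": table2(),
        "table3": table3(),
        "table4": table4(),
    }
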