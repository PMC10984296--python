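"""Published per-patient PK parameter estimates for neonatal IV brivaracetam.

The first-in-neonate brivaracetam trial (six neonates, 0.5 mg/kg b.i.d as
15-min IV infusions) reported individual Bayesian-feedback estimates of
the single-dose PK parameters.  They are reproduced here as the reference
input for summary-statistics checks and worked examples; this package
recomputes only the derived and summary quantities from them, not the
underlying concentration fits (the raw concentrations were not published).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["neonatal_pk_table"]

# One row per patient; units: AUCs h*mg/L, cmax mg/L, tmax min, vd L,
# cl_lph L/h, cl_mlpm mL/min, t_half h.
_ROWS = {
    "auc_0_12": [4.44, 4.54, 4.75, 3.71, 4.72, 4.55],
    "auc_inf": [6.36, 7.05, 7.39, 5.39, 7.68, 6.90],
    "cmax": [0.63, 0.61, 0.63, 0.52, 0.61, 0.62],
    "tmax": [15.00, 15.00, 30.00, 15.00, 15.00, 15.00],
    "vd": [2.18, 2.28, 1.85, 3.97, 2.75, 2.87],
    "cl_lph": [0.22, 0.20, 0.16, 0.39, 0.22, 0.26],
    "cl_mlpm": [3.67, 3.31, 2.71, 6.50, 3.69, 4.35],
    "t_half": [6.87, 7.95, 7.90, 7.06, 8.60, 7.63],
}


def neonatal_pk_table() -> pd.DataFrame:
    """Per-patient published PK parameters, indexed by patient number (1-6)."""
    return pd.DataFrame(_ROWS, index=pd.RangeIndex(1, 7, name="patient"))
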