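"""Bundled reference data.

``load_field_summary`` returns the published group-mean physicochemical and
PAH summary of the salinized, aged PAH-polluted oil-well field survey that the
synthetic generator is patterned on: three sampling regions (GA, GB, GC) at
decreasing distance from the coast, each with a bare (B) and a vegetated (V)
group. Units follow the original survey: EC in mS·cm⁻¹, OM/AN in g·kg⁻¹,
AP in g·kg⁻¹, CAT in µmol·h⁻¹·g⁻¹, TPH in g·kg⁻¹, PAH quantities in mg·kg⁻¹.
"""

from __future__ import annotations

import io

import pandas as pd

_FIELD_SUMMARY_CSV = """\
group,region,cover,pH,pH_sd,EC,EC_sd,OM,OM_sd,CAT,CAT_sd,AN,AN_sd,AP,AP_sd,TPH,TPH_sd,tpah,tpah_sd,lmw,lmw_sd,hmw,hmw_sd,teq_bap,teq_bap_sd
GAB,GA,bare,7.71,0.03,1.25,0.70,132.65,77.84,4.07,0.46,50.37,6.26,7.19,1.96,5.69,7.82,2.30,0.64,0.46,0.05,1.84,0.63,0.39,0.13
GAV,GA,vegetated,7.81,0.08,1.24,1.05,138.00,24.66,4.81,1.16,49.21,6.10,7.20,1.17,2.43,0.89,1.13,0.21,0.38,0.11,0.76,0.10,0.03,0.002
GBB,GB,bare,7.81,0.16,2.06,0.37,169.32,68.35,3.52,0.17,47.48,17.57,7.79,4.45,5.88,7.92,2.04,0.56,0.63,0.07,1.07,0.04,0.11,0.06
GBV,GB,vegetated,7.74,0.09,1.98,1.17,102.27,69.95,3.49,1.09,42.71,18.21,5.86,2.88,2.41,1.23,0.90,0.38,0.27,0.13,0.63,0.26,0.08,0.06
GCB,GC,bare,7.96,0.25,7.23,2.32,19.87,26.10,2.39,0.61,41.25,6.08,4.05,0.94,1.74,2.07,1.77,0.43,0.62,0.25,1.16,0.19,0.15,0.09
GCV,GC,vegetated,7.85,0.22,2.96,1.84,36.95,11.01,3.42,0.36,39.51,16.86,5.60,2.40,0.94,0.19,0.79,0.20,0.21,0.11,0.58,0.10,0.06,0.05
"""

#: Published mean gene copy numbers (copies per gram dry soil) across the survey.
FIELD_GENE_MEANS = {"16S": 4.02e8, "PAH-RHDa": 1.37e6, "C12O": 2.26e5}


def load_field_summary() -> pd.DataFrame:
    """Group-level means ± SD of the field survey, indexed by group code."""
    return pd.read_csv(io.StringIO(_FIELD_SUMMARY_CSV), index_col="group")
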