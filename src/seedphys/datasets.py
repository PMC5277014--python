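"""Bundled summary tables from a two-year cotton management field trial.

These are plot-level *summaries* (treatment means), not raw data: cottonseed
yields, embryo oil/protein composition, fitted embryo-growth traits and the
information-theoretic node-significance ranking of carbohydrate-metabolism
variables.  The trial compared conventional management (CM) against two
integrated management strategies (IMS1, IMS2) at two soil fertility levels
(LF/HF) in 2012-2013.  They serve as worked-example inputs and as fixed
reference points for the validation suite; the raw per-plot records behind
them are emulated by :mod:`seedphys.simulate`.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

__all__ = [
    "cottonseed_yields",
    "embryo_composition",
    "embryo_growth_traits",
    "node_significance",
]

_YIELDS_CSV = """\
year,fertility,management,yield_kg_ha
2012,LF,CM,2274
2012,LF,IMS1,2873
2012,LF,IMS2,3325
2012,HF,CM,2786
2012,HF,IMS1,3155
2012,HF,IMS2,3570
2013,LF,CM,2547
2013,LF,IMS1,3031
2013,LF,IMS2,3006
2013,HF,CM,2910
2013,HF,IMS1,2950
2013,HF,IMS2,3558
"""

_COMPOSITION_CSV = """\
fertility,management,year,protein_content_pct,protein_yield_kg_ha,oil_content_pct,oil_yield_kg_ha
LF,CM,2012,46.08,614,28.47,379
LF,CM,2013,48.12,696,26.65,386
LF,IMS1,2012,44.97,717,29.84,476
LF,IMS1,2013,46.91,774,28.84,476
LF,IMS2,2012,52.46,992,23.69,448
LF,IMS2,2013,52.81,978,24.46,453
HF,CM,2012,50.05,702,25.94,364
HF,CM,2013,47.36,559,28.54,337
HF,IMS1,2012,44.66,804,31.42,566
HF,IMS1,2013,47.02,752,29.77,476
HF,IMS2,2012,52.21,893,23.95,410
HF,IMS2,2013,50.96,879,25.08,433
"""

_GROWTH_CSV = """\
fertility,management,year,daa1,daa2,duration_d,peak_rate_g_d,embryo_weight_100_g,r2
HF,CM,2012,16.6,35.7,19.2,0.197,5.18,0.9514
HF,CM,2013,18.4,39.2,20.8,0.244,6.68,0.9793
HF,IMS1,2012,19.1,38.5,19.4,0.221,5.68,0.9588
HF,IMS1,2013,22.3,44.8,22.5,0.280,7.54,0.9843
HF,IMS2,2012,18.1,38.2,20.1,0.210,5.62,0.9369
HF,IMS2,2013,17.4,38.6,21.2,0.234,6.81,0.9859
LF,CM,2012,15.4,39.0,23.6,0.166,5.22,0.9396
LF,CM,2013,13.2,37.4,24.1,0.156,5.05,0.9504
LF,IMS1,2012,17.2,36.1,18.9,0.204,5.86,0.9005
LF,IMS1,2013,19.6,38.2,18.6,0.258,6.43,0.9452
LF,IMS2,2012,15.6,37.9,22.3,0.191,5.47,0.9348
LF,IMS2,2013,15.9,37.0,21.1,0.187,5.29,0.9206
"""

_NODESIG_CSV = """\
node,nmi_pct,relative_significance,g_stat
susy,47.02,1,98.039
d_fructose,29.05,0.618,60.584
c_inv,19.64,0.418,40.948
sps,11.73,0.249,24.461
d_glucose,10.17,0.216,21.206
pepc,7.54,0.160,15.723
h_atpase,7.19,0.153,14.995
sucrose,3.56,0.076,7.427
"""


def cottonseed_yields() -> pd.DataFrame:
    """Treatment-mean cottonseed yields (kg ha^-1) per year x fertility x management."""
    return pd.read_csv(StringIO(_YIELDS_CSV))


def embryo_composition() -> pd.DataFrame:
    """Embryo protein/oil contents (% of embryo dry mass) and yields (kg ha^-1)."""
    return pd.read_csv(StringIO(_COMPOSITION_CSV))


def embryo_growth_traits() -> pd.DataFrame:
    """Fitted rapid-accumulation traits of 100-embryo weight per treatment."""
    return pd.read_csv(StringIO(_GROWTH_CSV))


def node_significance() -> pd.DataFrame:
    """Published node-significance ranking (NMI %, relative significance, G)
    of carbohydrate-metabolism variables with respect to 100-seed weight
    (n = 96 samples)."""
    return pd.read_csv(StringIO(_NODESIG_CSV))
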