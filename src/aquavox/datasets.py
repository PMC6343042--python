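"""Bundled example data.

``load_fermentation_titers`` returns the published batch-fermentation titers
(g/L, means over replicate fermentations) of the C. acetobutylicum M5
platform strain and M5 expressing wild-type or single-mutant AAD
(aldehyde/alcohol dehydrogenase) from a plasmid.  The titers are measured
inputs from wet-lab fermentations — nothing in this package can recompute
them; they exist so the derived selectivity ratios can be recomputed and
checked.  ``glucose_consumed`` was not published and is left missing, so
butanol yield is flagged undefined for every row.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

__all__ = ["load_fermentation_titers", "load_assay_activities"]

_TITERS_CSV = """\
strain,butanol,acetone,ethanol,butyrate,acetate,glucose_consumed
M5,0.14,0,0.60,24.10,3.37,
M5 (pTHL1-AdhE1),10.01,0,3.31,0.95,8.58,
M5 (pTHL1-N613K),11.66,0,1.68,3.45,9.28,
M5 (pTHL1-M619A),11.40,0,2.32,1.27,9.25,
M5 (pTHL1-M619G),10.71,0,1.07,1.83,6.48,
M5 (pTHL1-Y623L),11.01,0,2.63,0.76,9.49,
"""

_ASSAY_CSV = """\
strain,edh_mU_per_mg,bdh_mU_per_mg
M5 (pTHL1-AdhE1),6.13,12.77
M5 (pTHL1-M619G),7.21,37.40
M5 (pTHL1-N655H),2.66,5.01
M5 (pTHL1-F716L),3.13,5.66
"""


def load_fermentation_titers() -> pd.DataFrame:
    """Measured batch-fermentation titers (g/L) per strain."""
    return pd.read_csv(StringIO(_TITERS_CSV))


def load_assay_activities() -> pd.DataFrame:
    """Measured EDH/BDH specific activities (mU per mg protein) per strain."""
    return pd.read_csv(StringIO(_ASSAY_CSV))
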