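"""Published reference tables used for validation and worked examples.

These are small curated inputs transcribed from the original pan-cancer
study: directional characteristic-protein sets for two cross-cancer
comparisons, and the 26-row drug-response / discriminability concordance
table for actionable gene-histotype pairs.  They let the overlap and
concordance statistics be exercised on real published inputs without the
full TCGA/TCPA dataset.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: RPPA panel size of the pan-cancer protein matrix.
PANEL_SIZE = 120

#: ERBB2/HER2 amplification, characteristic proteins in breast cancer:
#: increased / decreased in amplified cases.
ERBB2_BRCA_UP = frozenset({"HER2_pY1248", "HER2", "ACC1", "EGFR_pY1068"})
ERBB2_BRCA_DOWN = frozenset({"Bcl-2", "PR"})

#: ERBB2/HER2 amplification, characteristic proteins in gastric cancer.
ERBB2_STAD_UP = frozenset({"HER2", "ACC1", "ACC_pS79", "HER2_pY1248", "Cyclin_E1"})
ERBB2_STAD_DOWN = frozenset({"Caspase-7_cleavedD198", "STAT5-alpha"})

#: Three-gene complexity-reduction classes 2 vs 4, characteristic proteins
#: in breast cancer (increased in class 2 / increased in class 4).
GCR24_BRCA_UP2 = frozenset({"ER-alpha", "GATA3", "AR", "ER-alpha_pS118"})
GCR24_BRCA_UP4 = frozenset({"Cyclin_B1", "p53"})

#: Same class pair in endometrial carcinoma.
GCR24_UCEC_UP2 = frozenset({
    "ER-alpha", "Akt_pS473", "Akt_pT308", "E-Cadherin",
    "ER-alpha_pS118", "Claudin-7", "CD49b",
})
GCR24_UCEC_UP4 = frozenset({"p53", "Cyclin_B1", "Cyclin_E1", "IGFBP2"})


def drug_response_concordance() -> pd.DataFrame:
    """The published 26-row concordance table: for each actionable
    gene-histotype pair, whether cell lines with the alteration respond
    differently to the targeted drug (response) and whether the altered
    tumor cases were protein-profile discriminable (discriminable)."""
    ref = resources.files("prodisc") / "data" / "drug_response_concordance.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype=str)
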