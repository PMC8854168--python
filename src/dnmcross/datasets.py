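"""Bundled reference data: published cross-disorder DNM count marginals.

The table below aggregates coding de novo mutation counts from published
trio sequencing studies of five neuropsychiatric disorders — autism
spectrum disorder (ASD), undiagnosed developmental disorder (UDD),
epileptic encephalopathy (EE), intellectual disability (ID), schizophrenia
(SCZ) — a pooled all-disorder row (NPD) and unaffected controls.  It is the
canonical input of the synonymous-normalised burden and contribution
analysis and of the worked examples in the documentation.
"""

from __future__ import annotations

import pandas as pd

from .classify import ClassCountMatrix

#: cohort -> (n_trios, LoF, Dmis, Tmis, synonymous). Pfun = LoF + Dmis is
#: derived, never stored.
_CROSS_DISORDER_COUNTS = {
    "ASD": (6511, 1228, 1633, 3406, 1864),
    "UDD": (4293, 1382, 1898, 2676, 1607),
    "EE": (933, 192, 350, 414, 192),
    "ID": (1022, 309, 366, 447, 248),
    "SCZ": (1094, 136, 217, 450, 241),
    "NPD": (13853, 3247, 4464, 7393, 4152),
    "control": (3391, 411, 662, 1595, 932),
}


def cross_disorder_count_table() -> ClassCountMatrix:
    """Per-cohort DNM class counts of the published five-disorder compilation.

    Rows: the five disorders, the pooled NPD row and the control cohort.
    """
    index = list(_CROSS_DISORDER_COUNTS)
    counts = pd.DataFrame(
        [
            {"LoF": lof, "Dmis": dmis, "Tmis": tmis, "synonymous": syn, "other": 0}
            for (_, lof, dmis, tmis, syn) in _CROSS_DISORDER_COUNTS.values()
        ],
        index=index,
    )
    trios = pd.Series({k: v[0] for k, v in _CROSS_DISORDER_COUNTS.items()})
    return ClassCountMatrix(counts=counts, n_trios=trios)
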