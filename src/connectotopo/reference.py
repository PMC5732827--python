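"""Published group-level findings used as fixed reference inputs.

These are the printed results of the 12-patient vs 24-control T2DM
resting-state connectome study the pipeline re-implements: the per-region
permutation p-values of the three nodal metrics for the 21 regions with
at least one altered metric, and the 13 weakened connections (with mean
functional-connectivity differences and Euclidean centroid distances in
millimetres) identified by the network-based statistic. Regions are
indexed by their 1-based AAL-90 atlas number.

P-values printed as "< 0.001" are stored as the upper bound 0.001; the
only rule applied to them here is the p < 0.05 selection, which either
reading satisfies.
"""
from __future__ import annotations

import pandas as pd

__all__ = [
    "nodal_findings_table",
    "nbs_edge_findings_table",
    "regions_with_altered_nodal_metrics",
    "LONG_RANGE_CUTOFF_MM",
]

LONG_RANGE_CUTOFF_MM = 75.0

# AAL no., region name, p(degree), p(nodal efficiency), p(betweenness), direction
_NODAL_ROWS = [
    (5,  "Left superior frontal gyrus, orbital part",          0.005, 0.004, 0.374, "decreased"),
    (6,  "Right superior frontal gyrus, orbital part",         0.005, 0.001, 0.512, "decreased"),
    (7,  "Left middle frontal gyrus",                          0.073, 0.016, 0.503, "decreased"),
    (9,  "Left middle frontal gyrus, orbital part",            0.007, 0.001, 0.411, "decreased"),
    (15, "Left frontal gyrus, orbital part",                   0.009, 0.005, 0.012, "decreased"),
    (21, "Left olfactory cortex",                              0.005, 0.001, 0.132, "decreased"),
    (22, "Right olfactory cortex",                             0.001, 0.001, 0.530, "decreased"),
    (28, "Right gyrus rectus",                                 0.066, 0.019, 0.510, "decreased"),
    (39, "Left parahippocampal gyrus",                         0.145, 0.099, 0.014, "decreased"),
    (59, "Left superior parietal gyrus",                       0.133, 0.030, 0.030, "decreased"),
    (60, "Right superior parietal gyrus",                      0.108, 0.033, 0.319, "decreased"),
    (69, "Left paracentral lobule",                            0.182, 0.257, 0.017, "decreased"),
    (89, "Left inferior temporal gyrus",                       0.071, 0.035, 0.446, "decreased"),
    (90, "Right inferior temporal gyrus",                      0.017, 0.012, 0.361, "decreased"),
    (13, "Left inferior frontal gyrus, triangular part",       0.343, 0.499, 0.009, "increased"),
    (27, "Left gyrus rectus",                                  0.485, 0.497, 0.037, "increased"),
    (35, "Left posterior cingulate gyrus",                     0.496, 0.505, 0.027, "increased"),
    (44, "Right calcarine fissure and surrounding cortex",     0.129, 0.319, 0.040, "increased"),
    (46, "Right cuneus",                                       0.243, 0.384, 0.031, "increased"),
    (64, "Right supramarginal gyrus",                          0.118, 0.478, 0.042, "increased"),
    (74, "Right lenticular nucleus, putamen",                  0.043, 0.255, 0.489, "increased"),
]

# AAL pair, mean FC difference (patients - controls), centroid distance mm
_EDGE_ROWS = [
    (5,  9,  -0.173,  14.888),
    (5,  15, -0.245,  25.591),
    (5,  39, -0.200,  63.873),
    (5,  59, -0.215, 129.204),
    (7,  59, -0.183,  95.757),
    (7,  60, -0.162, 112.696),
    (9,  22, -0.197,  53.676),
    (9,  59, -0.183, 129.815),
    (15, 22, -0.225,  48.721),
    (15, 59, -0.182, 115.567),
    (15, 60, -0.187, 132.047),
    (22, 39, -0.238,  45.858),
    (22, 89, -0.180,  75.488),
]


def nodal_findings_table() -> pd.DataFrame:
    """Reported nodal-metric p-values for the 21 regions with altered metrics."""
    return pd.DataFrame(
        _NODAL_ROWS,
        columns=["region_id", "region_name", "p_degree", "p_efficiency",
                 "p_betweenness", "direction"],
    )


def nbs_edge_findings_table() -> pd.DataFrame:
    """Reported weakened connections with FC differences and distances."""
    return pd.DataFrame(
        _EDGE_ROWS,
        columns=["region_a", "region_b", "fc_difference", "distance_mm"],
    )


def regions_with_altered_nodal_metrics(alpha: float = 0.05) -> pd.DataFrame:
    """Rows significant at ``alpha`` in at least one of the three nodal metrics."""
    t = nodal_findings_table()
    sel = (t[["p_degree", "p_efficiency", "p_betweenness"]] < alpha).any(axis=1)
    return t[sel].reset_index(drop=True)
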