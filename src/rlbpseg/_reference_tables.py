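"""Bundled reference statistics: ICV-corrected hippocampal volumes
(mean, SD, in cm^3) by diagnostic group, side and segmentation method,
from a published AD/MCI/NC cohort evaluation.  Used as the worked-example
input for the effect-size analysis and as a regression fixture.
"""

from __future__ import annotations

import pandas as pd

METHODS = ["Manual", "NLP", "LBP", "LLL", "JLF", "NLW-ML", "RLBP"]
GROUPS = ["NC", "MCI", "AD"]
SIDES = ["Left", "Right"]

# {group: {side: [(mean, sd) per method, in METHODS order]}}
HIPPOCAMPUS_GROUP_STATS = {
    "NC": {
        "Left": [(3.111, 0.337), (2.971, 0.309), (2.967, 0.291), (2.984, 0.308),
                 (3.111, 0.319), (3.015, 0.307), (3.029, 0.310)],
        "Right": [(3.151, 0.324), (3.076, 0.294), (3.101, 0.296), (3.1145, 0.300),
                  (3.224, 0.314), (3.130, 0.300), (3.143, 0.316)],
    },
    "MCI": {
        "Left": [(2.657, 0.484), (2.567, 0.457), (2.581, 0.471), (2.602, 0.465),
                 (2.668, 0.528), (2.594, 0.473), (2.615, 0.483)],
        "Right": [(2.716, 0.543), (2.678, 0.472), (2.700, 0.481), (2.704, 0.493),
                  (2.774, 0.549), (2.702, 0.497), (2.727, 0.513)],
    },
    "AD": {
        "Left": [(2.403, 0.532), (2.353, 0.415), (2.361, 0.434), (2.352, 0.434),
                 (2.436, 0.489), (2.367, 0.436), (2.365, 0.454)],
        "Right": [(2.528, 0.576), (2.500, 0.435), (2.531, 0.446), (2.524, 0.477),
                  (2.602, 0.502), (2.521, 0.456), (2.516, 0.485)],
    },
}


def group_stats_frame() -> pd.DataFrame:
    """The reference statistics as a tidy frame with columns
    group, side, method, mean, sd."""
    rows = []
    for group, by_side in HIPPOCAMPUS_GROUP_STATS.items():
        for side, cells in by_side.items():
            for method, (mean, sd) in zip(METHODS, cells):
                rows.append({"group": group, "side": side, "method": method,
                             "mean": mean, "sd": sd})
    return pd.DataFrame(rows)
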