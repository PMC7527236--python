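"""Counts-only mode: proportion tests from pre-tabulated altered-step counts.

Published comparisons are reproducible from the printed altered/total counts
alone — no raw per-step data needed. The unpooled-SE two-sample z statistic
is the one that matches the reported values.
"""

from quadgait import compare_counts

table = compare_counts([
    {"pair": "LR_fore", "contrast": "control_vs_silenced",
     "x1": 26, "n1": 480, "x2": 135, "n2": 600},
    {"pair": "LR_hind", "contrast": "control_vs_silenced",
     "x1": 26, "n1": 480, "x2": 177, "n2": 600},
    {"pair": "HLFL_ipsi", "contrast": "control_vs_silenced",
     "x1": 19, "n1": 480, "x2": 17, "n2": 600},
])
print(table[["pair", "pct1", "pct2", "z", "p"]].to_string(index=False))

# Left-right coupling at both girdles is strongly disrupted (|z| >> 2) while
# the homolateral hindlimb-forelimb coupling is spared (|z| ~ 1).
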