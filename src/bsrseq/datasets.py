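"""Worked-example inputs.

Published per-bin DEG counts from a maize waterlogging BSR-seq experiment
(8 tolerant and 10 sensitive inbred lines, untreated vs. 2-day waterlogged
roots).  Four contrasts are tabulated: each pool's waterlogged-vs-normal
response, and the tolerant-vs-sensitive comparison under each condition
(the tolerant pool is the fold-change numerator).  These bin counts serve as
inputs to :func:`bsrseq.expression_deg.degs_from_bin_counts` in worked
examples; the directional and grand totals follow by summation.
"""

from copy import deepcopy

_FOLD_BINS = {
    "tolerant_waterlogged_vs_normal": {
        "up": {"2-10": 136, "10-100": 37, "100-1000": 6, ">1000": 2},
        "down": {"2-10": 154, "10-100": 16, "100-1000": 2, ">1000": 1},
    },
    "sensitive_waterlogged_vs_normal": {
        "up": {"2-10": 400, "10-100": 126, "100-1000": 26, ">1000": 3},
        "down": {"2-10": 446, "10-100": 79, "100-1000": 12, ">1000": 2},
    },
    "tolerant_vs_sensitive_normal": {
        "up": {"2-10": 327, "10-100": 49, "100-1000": 19, ">1000": 3},
        "down": {"2-10": 148, "10-100": 25, "100-1000": 18, ">1000": 4},
    },
    "tolerant_vs_sensitive_waterlogged": {
        "up": {"2-10": 112, "10-100": 39, "100-1000": 23, ">1000": 5},
        "down": {"2-10": 173, "10-100": 48, "100-1000": 29, ">1000": 2},
    },
}


def waterlogging_fold_bins() -> dict:
    """Per-contrast, per-direction fold-change bin counts (fresh copy)."""
    return deepcopy(_FOLD_BINS)
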