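"""Independent reference implementations used as oracles by several test
modules.  These deliberately restate the decision rules and formulas in the
plainest possible form, sharing no code with the package."""

import math

from scipy.special import gammaln

from bsrseq.formats_io import BASES


def naive_classify(pooled: dict, cfg):
    """Straight-line restatement of the SNP-site decision rule."""
    counts = {b: pooled.get(b, 0) for b in BASES}
    total = sum(counts.values())
    assert total > 0
    observed = [b for b in BASES if counts[b] > 0]
    supported = [b for b in observed if counts[b] >= cfg.min_type_reads]
    qualifying = [
        b for b in supported if counts[b] / total >= cfg.min_type_fraction
    ]
    if len(supported) <= 1 and len(observed) >= 2:
        return False, None, "low_type_support"
    if len(qualifying) <= 1:
        return False, None, "monomorphic"
    if len(qualifying) >= 3:
        return False, None, "too_many_types"
    pair = tuple(sorted(qualifying, key=lambda b: (-counts[b], b)))
    if (counts[pair[0]] + counts[pair[1]]) / total < cfg.min_two_type_fraction:
        return False, None, "low_combined_fraction"
    return True, pair, None


def ac_log_pmf(yp, x, n1, n2):
    """Log predictive probability of observing yp tags in library 2 given x
    tags in library 1, written directly from the ratio formula."""
    ratio = n2 / n1
    return (
        yp * math.log(ratio)
        + gammaln(x + yp + 1)
        - gammaln(x + 1)
        - gammaln(yp + 1)
        - (x + yp + 1) * math.log1p(ratio)
    )


def naive_bh(pvals):
    """O(n^2)-style step-up false-discovery-rate adjustment."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    q = [0.0] * n
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvals[i] * n / rank)
        q[i] = running_min
    return q
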