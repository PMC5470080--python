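"""Validation of SNP sites by the two-SNP-type read-support rules.

A validated site must show two and only two SNP-types: each of the two must
be seen in at least ``min_type_reads`` reads and carry at least
``min_type_fraction`` of the pooled site total, and together they must carry
at least ``min_two_type_fraction`` of that total.  Counts are pooled across
both bulks and both conditions before typing (per-condition typing is
available via the ``condition`` argument), because downstream linkage scoring
needs the same two types oriented identically in both bulks.

Failure reasons are assigned with the precedence

1. ``low_type_support`` - at most one type reaches ``min_type_reads`` although
   two or more types were observed;
2. ``monomorphic`` - at most one type satisfies both per-type thresholds
   (including truly single-type sites);
3. ``too_many_types`` - three or more types satisfy both per-type thresholds;
4. ``low_combined_fraction`` - exactly two types qualify but their combined
   reads fall below ``min_two_type_fraction`` of the site total.

so a site receives exactly one reason.  Residual noise types are tolerated
inside the remaining fraction: a lone sequencing-error read never invalidates
an otherwise clean biallelic site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, UndefinedSiteError
from .formats_io import BASES, AlleleCountTable, SiteCounts

REASONS = ("monomorphic", "too_many_types", "low_type_support", "low_combined_fraction")

_PASS = 0
_MONO = 1
_TOO_MANY = 2
_LOW_SUPPORT = 3
_LOW_COMBINED = 4
_NO_READS = 5

_REASON_BY_CODE = {
    _PASS: None,
    _MONO: "monomorphic",
    _TOO_MANY: "too_many_types",
    _LOW_SUPPORT: "low_type_support",
    _LOW_COMBINED: "low_combined_fraction",
    _NO_READS: "no_reads",
}


@dataclass
class SnpFilterConfig:
    """Read-support thresholds for SNP-site validation."""

    min_type_reads: int = 3
    min_type_fraction: float = 0.20
    min_two_type_fraction: float = 0.90

    def __post_init__(self):
        if self.min_type_reads < 0:
            raise ConfigError("min_type_reads must be >= 0")
        for name in ("min_type_fraction", "min_two_type_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if 2 * self.min_type_fraction > 1.0:
            raise ConfigError("min_type_fraction > 0.5 leaves no site able to pass")


@dataclass(frozen=True)
class FilterDecision:
    """Outcome of classifying one site."""

    chrom: str
    pos: int
    passed: bool
    types: Optional[tuple[str, str]]  # the two retained SNP-types when passing
    reason: Optional[str]  # failure reason code otherwise


@dataclass
class FilteredSites:
    """Passing sites with counts collapsed onto their two retained types."""

    table: AlleleCountTable
    decisions: pd.DataFrame  # chrom, pos, passed, type1, type2, reason
    summary: dict[str, int]


def _classify_matrix(counts: np.ndarray, cfg: SnpFilterConfig):
    """Vectorised decision core.

    ``counts`` is (n_sites, 4) pooled base counts.  Returns (code, type1_idx,
    type2_idx) arrays; type indices are -1 for failing sites.
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = counts.sum(axis=1)
    observed = (counts > 0).sum(axis=1)
    supported = counts >= cfg.min_type_reads
    # correctly-rounded division keeps exact decimal boundaries (3/15 >= 0.2)
    safe_total = np.maximum(total, 1)
    frequent = counts / safe_total[:, None] >= cfg.min_type_fraction
    qualify = supported & frequent & (counts > 0)
    n_supported = (supported & (counts > 0)).sum(axis=1)
    n_qualify = qualify.sum(axis=1)

    # top-two qualifying types ordered by (count desc, base asc)
    masked = np.where(qualify, counts, -1)
    order = np.argsort(-masked, axis=1, kind="stable")
    t1 = order[:, 0]
    t2 = order[:, 1]
    combined = np.take_along_axis(counts, order[:, :2], axis=1).sum(axis=1)

    code = np.full(len(counts), _PASS, dtype=np.int64)
    code[(n_supported <= 1) & (observed >= 2)] = _LOW_SUPPORT
    undecided = code == _PASS
    code[undecided & (n_qualify <= 1)] = _MONO
    undecided = code == _PASS
    code[undecided & (n_qualify >= 3)] = _TOO_MANY
    undecided = code == _PASS
    code[undecided & (combined / safe_total < cfg.min_two_type_fraction)] = _LOW_COMBINED
    code[total == 0] = _NO_READS

    t1 = np.where(code == _PASS, t1, -1)
    t2 = np.where(code == _PASS, t2, -1)
    return code, t1, t2


def classify_site(
    site: SiteCounts,
    cfg: SnpFilterConfig | None = None,
    condition: str | None = None,
) -> FilterDecision:
    """Classify one site against the two-SNP-type rules.

    Counts are pooled across all cells (or across bulks within ``condition``
    if given).  A site with zero pooled reads is undefined.
    """
    cfg = cfg or SnpFilterConfig()
    pooled = site.pooled_for(condition)
    counts = np.array([[pooled.get(b, 0) for b in BASES]])
    if counts.sum() == 0:
        raise UndefinedSiteError(f"{site.chrom}:{site.pos} carries no reads")
    code, t1, t2 = _classify_matrix(counts, cfg)
    passed = code[0] == _PASS
    types = (BASES[t1[0]], BASES[t2[0]]) if passed else None
    return FilterDecision(site.chrom, site.pos, bool(passed), types,
                          _REASON_BY_CODE[int(code[0])])


def filter_sites(
    table: AlleleCountTable,
    cfg: SnpFilterConfig | None = None,
    condition: str | None = None,
) -> FilteredSites:
    """Filter a whole table, collapsing passing sites onto their two types.

    Returns the retained table (non-retained base columns zeroed per cell),
    the per-site decisions, and a summary whose values partition the input
    site count.  Sites with zero pooled reads are tallied under ``no_reads``.
    """
    cfg = cfg or SnpFilterConfig()
    pooled = table.pooled(condition)
    if pooled.empty:
        raise ConfigError("cannot filter an empty allele-count table")
    counts = pooled[list(BASES)].to_numpy()
    code, t1, t2 = _classify_matrix(counts, cfg)

    keys = pooled.index.to_frame(index=False)
    decisions = pd.DataFrame(
        {
            "chrom": keys["chrom"],
            "pos": keys["pos"],
            "passed": code == _PASS,
            "type1": [BASES[i] if i >= 0 else None for i in t1],
            "type2": [BASES[i] if i >= 0 else None for i in t2],
            "reason": [_REASON_BY_CODE[int(c)] for c in code],
        }
    )

    summary = {"pass": int((code == _PASS).sum())}
    for c, name in _REASON_BY_CODE.items():
        if name is not None:
            summary[name] = int((code == c).sum())

    kept = decisions[decisions["passed"]][["chrom", "pos", "type1", "type2"]]
    frame = table.frame.merge(kept, on=["chrom", "pos"], how="inner")
    for base in BASES:
        retained = (frame["type1"] == base) | (frame["type2"] == base)
        frame[base] = np.where(retained, frame[base], 0)
    filtered = AlleleCountTable(frame.drop(columns=["type1", "type2"]))
    return FilteredSites(table=filtered, decisions=decisions, summary=summary)
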