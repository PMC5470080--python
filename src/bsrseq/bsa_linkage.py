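"""Bayesian linkage scoring of SNPs between two phenotypic bulks.

The model
---------

At a validated biallelic site, let ``(a_T, b_T)`` be the reads carrying the
two SNP-types in the tolerant bulk and ``(a_S, b_S)`` those in the sensitive
bulk.  Two hypotheses are compared:

* **linked** (H1): each bulk has its own latent allele frequency.  With a
  Beta(alpha, beta) prior on each frequency the marginal likelihood of one
  bulk's counts is the beta-binomial integral
  ``B(a + alpha, b + beta) / B(alpha, beta)`` (binomial coefficients cancel
  between hypotheses and are omitted throughout); H1's likelihood is the
  product of the two bulks' marginals.
* **unlinked** (H0): both bulks share one latent frequency, so the pooled
  counts ``(a_T + a_S, b_T + b_S)`` enter a single beta-binomial marginal.
  A shared free frequency - rather than a fixed 1/2 - is the default null
  because bulks assembled from unrelated inbred lines need not sit at 0.5 at
  unlinked sites; ``null_mode="half"`` restores the fixed-1/2 null.

The posterior linkage probability is ``pi * L1 / (pi * L1 + (1 - pi) * L0)``
with prior linked mass ``pi``, computed in log space.  ``pi`` may be fixed or
estimated from all sites by expectation-maximisation on the two-component
mixture (an empirical-Bayes prior).

SNPs whose posterior strictly exceeds the call threshold (default 0.9) are
the high-probability set; sets from the two growth conditions are intersected
by (chrom, pos, type-pair), and calls are mapped onto gene models and
chromosome totals for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, logit

from .errors import (
    ConfigError,
    DomainError,
    EstimationError,
    UndefinedResultError,
)
from .formats_io import BASES, GeneModel
from .snp_filtering import FilteredSites

_LOG_HALF = float(np.log(0.5))
_MIN_SITES_FOR_EM = 10
_PI_CLAMP = (1e-6, 0.5)


@dataclass
class LinkageModelConfig:
    """Hyperparameters of the two-hypothesis beta-binomial model."""

    prior_linked: float = 0.05
    alpha_linked: float = 1.0
    beta_linked: float = 1.0
    alpha_null: float = 1.0
    beta_null: float = 1.0
    call_threshold: float = 0.9
    null_mode: str = "shared"  # "shared" free frequency or fixed "half"
    em_enabled: bool = False
    em_tol: float = 1e-6
    em_max_iter: int = 100

    def __post_init__(self):
        for name in ("alpha_linked", "beta_linked", "alpha_null", "beta_null"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not 0.0 <= self.prior_linked <= 1.0:
            raise ConfigError("prior_linked must lie in [0, 1]")
        if not 0.0 < self.call_threshold < 1.0:
            raise ConfigError("call_threshold must lie in (0, 1)")
        if self.null_mode not in ("shared", "half"):
            raise ConfigError("null_mode must be 'shared' or 'half'")
        if self.em_tol <= 0 or self.em_max_iter < 1:
            raise ConfigError("em_tol must be > 0 and em_max_iter >= 1")


class BulkCounts(NamedTuple):
    """Reads of the two SNP-types in each bulk at one site, one condition."""

    a_t: int
    b_t: int
    a_s: int
    b_s: int


@dataclass(frozen=True)
class LinkageResult:
    """Per-SNP Bayes factor, posterior, and call flag."""

    log_bf: float
    posterior: float
    high_probability: bool
    chrom: Optional[str] = None
    pos: Optional[int] = None


# ---------------------------------------------------------------------------
# model core
# ---------------------------------------------------------------------------


def log_marginal_beta_binomial(a, b, alpha: float = 1.0, beta: float = 1.0):
    """Log marginal likelihood of counts (a, b) with the frequency integrated out.

    Returns ``log[B(a + alpha, b + beta) / B(alpha, beta)]`` via log-gamma;
    the binomial coefficient is omitted (it cancels between hypotheses).
    Accepts scalars or arrays.
    """
    if alpha <= 0 or beta <= 0:
        raise DomainError("pseudo-counts must be > 0")
    a = np.asarray(a)
    b = np.asarray(b)
    if np.any(a < 0) or np.any(b < 0):
        raise DomainError("counts must be >= 0")
    out = betaln(a + alpha, b + beta) - betaln(alpha, beta)
    return out if out.ndim else float(out)


def log_bayes_factor(a_t, b_t, a_s, b_s, cfg: LinkageModelConfig | None = None):
    """log(L1 / L0) for arrays or scalars of per-bulk type counts."""
    cfg = cfg or LinkageModelConfig()
    l1 = log_marginal_beta_binomial(a_t, b_t, cfg.alpha_linked, cfg.beta_linked) \
        + log_marginal_beta_binomial(a_s, b_s, cfg.alpha_linked, cfg.beta_linked)
    if cfg.null_mode == "shared":
        l0 = log_marginal_beta_binomial(
            np.asarray(a_t) + np.asarray(a_s),
            np.asarray(b_t) + np.asarray(b_s),
            cfg.alpha_null, cfg.beta_null,
        )
    else:  # fixed p = 1/2
        total = np.asarray(a_t) + np.asarray(b_t) + np.asarray(a_s) + np.asarray(b_s)
        l0 = total * _LOG_HALF
    return l1 - l0


def posterior_from_log_bf(log_bf, pi: float):
    """Posterior linked probability from the log Bayes factor and prior mass."""
    if not 0.0 <= pi <= 1.0:
        raise DomainError("prior mass must lie in [0, 1]")
    log_bf = np.asarray(log_bf, dtype=float)
    if pi == 0.0:
        out = np.zeros_like(log_bf)
    elif pi == 1.0:
        out = np.ones_like(log_bf)
    else:
        out = expit(log_bf + logit(pi))
    return out if out.ndim else float(out)


def linkage_posterior(counts: BulkCounts, cfg: LinkageModelConfig | None = None) -> LinkageResult:
    """Score one site: log Bayes factor, posterior, and call flag."""
    cfg = cfg or LinkageModelConfig()
    counts = BulkCounts(*counts)
    if sum(counts) == 0:
        raise UndefinedResultError("no reads in either bulk: posterior undefined")
    lbf = float(log_bayes_factor(*counts, cfg=cfg))
    post = float(posterior_from_log_bf(lbf, cfg.prior_linked))
    return LinkageResult(log_bf=lbf, posterior=post,
                         high_probability=post > cfg.call_threshold)


# ---------------------------------------------------------------------------
# empirical-Bayes prior
# ---------------------------------------------------------------------------


def estimate_prior(
    all_counts: Sequence[BulkCounts] | np.ndarray,
    cfg: LinkageModelConfig | None = None,
) -> tuple[float, dict]:
    """EM estimate of the prior linked mass pi over a collection of sites.

    E-step: per-site posteriors at the current pi.  M-step: pi becomes their
    mean.  Iterates until ``|delta pi| < em_tol`` or ``em_max_iter``; the
    result is clamped to [1e-6, 0.5].  The observed-data log likelihood is
    tracked and verified non-decreasing (the EM guarantee).  Returns
    ``(pi_hat, info)`` where info carries the iteration traces.
    """
    cfg = cfg or LinkageModelConfig()
    arr = np.asarray([tuple(c) for c in all_counts], dtype=np.int64)
    if arr.ndim != 2 or arr.shape[0] < _MIN_SITES_FOR_EM:
        raise EstimationError(
            f"need at least {_MIN_SITES_FOR_EM} sites to estimate the prior; "
            "use a fixed prior_linked instead"
        )
    lbf = np.asarray(
        log_bayes_factor(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], cfg=cfg)
    )
    pi = float(np.clip(cfg.prior_linked, *_PI_CLAMP))
    pi_trace = [pi]
    ll_trace = []
    for _ in range(cfg.em_max_iter):
        # log-likelihood up to the common sum of L0 terms
        ll = float(np.logaddexp(np.log(pi) + lbf, np.log1p(-pi)).sum())
        if ll_trace and ll < ll_trace[-1] - 1e-8 * max(1.0, abs(ll_trace[-1])):
            raise EstimationError("EM log-likelihood decreased; model inputs invalid")
        ll_trace.append(ll)
        post = posterior_from_log_bf(lbf, pi)
        new_pi = float(np.clip(post.mean(), *_PI_CLAMP))
        converged = abs(new_pi - pi) < cfg.em_tol
        pi = new_pi
        pi_trace.append(pi)
        if converged:
            break
    info = {"n_iter": len(ll_trace), "pi_trace": pi_trace, "loglik_trace": ll_trace,
            "converged": converged}
    return pi, info


# ---------------------------------------------------------------------------
# scanning tables
# ---------------------------------------------------------------------------


def linkage_scan(
    filtered: FilteredSites,
    condition: str,
    cfg: LinkageModelConfig | None = None,
    bulks: tuple[str, str] = ("tolerant", "sensitive"),
) -> pd.DataFrame:
    """Score every filtered site for one condition.

    Returns a DataFrame with columns ``chrom, pos, type1, type2, a_t, b_t,
    a_s, b_s, log_bf, posterior, high_probability`` sorted by (chrom, pos).
    When ``cfg.em_enabled`` the prior is re-estimated from this scan's sites
    first.  Sites without reads in either bulk under this condition are
    dropped (their posterior is undefined).
    """
    cfg = cfg or LinkageModelConfig()
    frame = filtered.table.frame
    frame = frame[frame["condition"] == condition]
    if frame.empty:
        raise ConfigError(f"no counts for condition {condition!r}")
    kept = filtered.decisions[filtered.decisions["passed"]][
        ["chrom", "pos", "type1", "type2"]
    ]
    merged = frame.merge(kept, on=["chrom", "pos"], how="inner")
    base_idx = {b: i for i, b in enumerate(BASES)}
    base_mat = merged[list(BASES)].to_numpy()
    rows = np.arange(len(merged))
    merged["a"] = base_mat[rows, merged["type1"].map(base_idx).to_numpy()]
    merged["b"] = base_mat[rows, merged["type2"].map(base_idx).to_numpy()]

    tol = merged[merged["bulk"] == bulks[0]].set_index(["chrom", "pos"])
    sen = merged[merged["bulk"] == bulks[1]].set_index(["chrom", "pos"])
    scan = kept.set_index(["chrom", "pos"]).copy()
    scan["a_t"] = tol["a"].reindex(scan.index).fillna(0).astype(np.int64)
    scan["b_t"] = tol["b"].reindex(scan.index).fillna(0).astype(np.int64)
    scan["a_s"] = sen["a"].reindex(scan.index).fillna(0).astype(np.int64)
    scan["b_s"] = sen["b"].reindex(scan.index).fillna(0).astype(np.int64)
    depth = scan[["a_t", "b_t", "a_s", "b_s"]].sum(axis=1)
    scan = scan[depth > 0]

    lbf = np.asarray(log_bayes_factor(
        scan["a_t"].to_numpy(), scan["b_t"].to_numpy(),
        scan["a_s"].to_numpy(), scan["b_s"].to_numpy(), cfg=cfg,
    ))
    pi = cfg.prior_linked
    if cfg.em_enabled and len(scan) >= _MIN_SITES_FOR_EM:
        pi, _ = estimate_prior(
            scan[["a_t", "b_t", "a_s", "b_s"]].to_numpy(), cfg
        )
    scan["log_bf"] = lbf
    scan["posterior"] = posterior_from_log_bf(lbf, pi)
    scan["high_probability"] = scan["posterior"] > cfg.call_threshold
    scan = scan.reset_index().sort_values(["chrom", "pos"], kind="mergesort")
    scan.attrs["prior_linked"] = pi
    scan.attrs["condition"] = condition
    return scan.reset_index(drop=True)


def call_high_probability(results: pd.DataFrame, threshold: float = 0.9) -> pd.DataFrame:
    """SNPs whose posterior strictly exceeds the threshold, sorted by position."""
    called = results[results["posterior"] > threshold]
    return called.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def intersect_high_probability(
    set_a: pd.DataFrame, set_b: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Exact intersection of two call sets keyed by (chrom, pos, type-pair).

    The type pair is order-insensitive.  Returns the overlap (with both
    posteriors) and a report of per-set-only counts.
    """
    def _keyed(df, tag):
        df = df.copy()
        pair = [
            "/".join(sorted((t1, t2)))
            for t1, t2 in zip(df["type1"], df["type2"])
        ]
        df["type_pair"] = pair
        cols = ["chrom", "pos", "type_pair", "posterior"]
        return df[cols].rename(columns={"posterior": f"posterior_{tag}"})

    a = _keyed(set_a, "a")
    b = _keyed(set_b, "b")
    overlap = a.merge(b, on=["chrom", "pos", "type_pair"], how="inner")
    overlap = overlap.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    report = {
        "n_a": len(a),
        "n_b": len(b),
        "n_overlap": len(overlap),
        "a_only": len(a) - len(overlap),
        "b_only": len(b) - len(overlap),
    }
    return overlap, report


def assign_snps_to_genes(
    snps: pd.DataFrame, genes: Sequence[GeneModel]
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Assign each SNP to every gene whose 1-based span contains it.

    Strand is ignored; a SNP inside two overlapping genes yields one row per
    gene, and a SNP in no gene yields a row with ``gene_id`` None (labelled
    intergenic).  Also returns the histogram {SNP count: number of genes}.
    """
    gene_frame = pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end) for g in genes],
        columns=["gene_id", "gene_chrom", "start", "end"],
    )
    rows = []
    for snp in snps.itertuples():
        hits = gene_frame[
            (gene_frame["gene_chrom"] == snp.chrom)
            & (gene_frame["start"] <= snp.pos)
            & (gene_frame["end"] >= snp.pos)
        ]
        base = {c: getattr(snp, c) for c in snps.columns}
        if hits.empty:
            rows.append({**base, "gene_id": None})
        else:
            for g in hits.itertuples():
                rows.append({**base, "gene_id": g.gene_id})
    annotated = pd.DataFrame(rows, columns=list(snps.columns) + ["gene_id"])
    per_gene = annotated.dropna(subset=["gene_id"]).groupby("gene_id").size()
    histogram: dict[int, int] = per_gene.value_counts().sort_index().to_dict()
    return annotated, {int(k): int(v) for k, v in histogram.items()}


def summarize_by_chromosome(
    snps: pd.DataFrame, chromosomes: Iterable[str] | None = None
) -> dict[str, int]:
    """Per-chromosome counts of a SNP set; listed chromosomes with no calls
    are reported as 0."""
    counts = snps.groupby("chrom").size().to_dict()
    if chromosomes is not None:
        for chrom in chromosomes:
            counts.setdefault(chrom, 0)
    return {k: int(v) for k, v in sorted(counts.items())}
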