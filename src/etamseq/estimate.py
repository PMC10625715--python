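"""Estimators for the deamination model.

Persistent-A probability at a site: pi = 1 - c * s * (1 - m), with c the
sample conversion rate, s the site accessibility and m the methylation
level.  The treated-sample path estimates m given s (from the IVT control);
the FTO path fits (m, s) jointly from the untreated / demethylated pair.
"""

from __future__ import annotations

import math
import warnings
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.special import xlogy

from .model import (
    AccessibilityEstimate,
    EstimationError,
    FTOFit,
    GenomicSite,
    ParameterError,
    ProbeObservation,
    ReadObservation,
    SampleTable,
    SiteCount,
)

__all__ = [
    "filter_reads",
    "count_sites",
    "estimate_conversion_rate",
    "apparent_methylation",
    "raw_accessibility",
    "shrink_accessibility",
    "adjust_methylation",
    "estimate_fto_efficiency",
    "joint_fit_fto",
]


def filter_reads(
    reads: Iterable[ReadObservation], max_unconverted_fraction: float = 0.5
) -> List[ReadObservation]:
    """Drop reads poorly processed by the deaminase.

    A read is removed iff its unconverted fraction (observed A over covered
    reference-A positions) strictly exceeds the threshold.  Reads covering
    no reference A are kept: the fraction is 0/0 and keeping them is
    conservative for coverage.
    """
    if not 0.0 <= max_unconverted_fraction <= 1.0:
        raise ParameterError(
            f"max_unconverted_fraction must be in [0, 1], got {max_unconverted_fraction}"
        )
    kept = []
    for r in reads:
        frac = r.unconverted_fraction
        if frac is None or frac <= max_unconverted_fraction:
            kept.append(r)
    return kept


def count_sites(reads: Iterable[ReadObservation], role: str = "treated") -> SampleTable:
    """Tally observed bases at reference-A positions into per-site counts.

    Callers are expected to have run :func:`filter_reads` first.  Sites
    with zero observations are absent from the table.
    """
    acc: Dict[GenomicSite, List[int]] = {}
    for r in reads:
        for pos, base in zip(r.ref_a_positions, r.observed):
            site = GenomicSite(r.contig, pos, r.strand)
            counts = acc.setdefault(site, [0, 0, 0])
            if base == "A":
                counts[0] += 1
            elif base == "G":
                counts[1] += 1
            else:
                counts[2] += 1
    table = SampleTable(label="counted", role=role)
    for site, (a, g, other) in acc.items():
        table.add(SiteCount(site, a_count=a, g_count=g, other_count=other))
    return table


def estimate_conversion_rate(
    table: SampleTable, min_coverage: int = 20, trim: float = 0.0
) -> float:
    """Sample-level conversion rate from the bulk of A sites.

    Rests on the hypothesis that the overwhelming majority of A sites are
    unmethylated and accessible, so the pooled G fraction estimates c.
    Pooled ratio sum(g)/sum(a+g) over sites with coverage >= min_coverage,
    optionally after symmetric trimming of the per-site conversion
    distribution at fraction ``trim`` (guards against methylated outliers).
    """
    if not 0.0 <= trim < 0.5:
        raise ParameterError(f"trim must be in [0, 0.5), got {trim}")
    counts = [(sc.a_count, sc.g_count) for sc in table if sc.coverage >= min_coverage]
    if not counts:
        raise EstimationError(
            f"no sites with coverage >= {min_coverage} to estimate a conversion rate"
        )
    if trim > 0.0 and len(counts) > 2:
        counts.sort(key=lambda ag: ag[1] / (ag[0] + ag[1]))
        k = int(math.floor(trim * len(counts)))
        if k:
            counts = counts[k:-k]
    a_sum = sum(a for a, _ in counts)
    g_sum = sum(g for _, g in counts)
    return g_sum / (a_sum + g_sum)


def _check_counts_rate(a: int, g: int, c: float) -> None:
    if a < 0 or g < 0:
        raise ParameterError("counts must be non-negative")
    if a + g < 1:
        raise EstimationError("a + g must be >= 1")
    if not 0.0 < c <= 1.0:
        raise ParameterError(f"conversion rate must be in (0, 1], got {c}")


def apparent_methylation(a: int, g: int, c: float) -> float:
    """Binomial MLE of the methylation level before accessibility correction.

    Under pi = m + (1 - m)(1 - c) the unconstrained MLE is
    (a/(a+g) - (1 - c)) / c; clipping to [0, 1] implements the constrained
    argmax over the parameter space.
    """
    _check_counts_rate(a, g, c)
    frac = a / (a + g)
    return float(min(1.0, max(0.0, (frac - (1.0 - c)) / c)))


def raw_accessibility(a: int, g: int, c_control: float) -> float:
    """Per-site accessibility from a modification-free control.

    0 = fully blocked to the deaminase, 1 = fully accessible.  Under
    pi_control = 1 - c * s the MLE is (g/(a+g))/c, clipped to [0, 1].
    """
    _check_counts_rate(a, g, c_control)
    frac = g / (a + g)
    return float(min(1.0, max(0.0, frac / c_control)))


def adjust_methylation(
    apparent_m: float, accessibility: float
) -> Tuple[Optional[float], float]:
    """Accessibility-corrected (true, exposed) methylation levels.

    true_m = clip(apparent_m / s, 0, 1); exposed_m = true_m * s, which is
    algebraically min(apparent_m, s).  A fully blocked site (s = 0) has no
    defined true level and an exposed level of 0.
    """
    if not 0.0 <= apparent_m <= 1.0:
        raise ParameterError(f"apparent_m must be in [0, 1], got {apparent_m}")
    if not 0.0 <= accessibility <= 1.0:
        raise ParameterError(f"accessibility must be in [0, 1], got {accessibility}")
    if accessibility == 0.0:
        return None, 0.0
    true_m = min(1.0, max(0.0, apparent_m / accessibility))
    return true_m, true_m * accessibility


_LAMBDA_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)


def _ols_predict(
    X_train: np.ndarray, y_train: np.ndarray, X_new: np.ndarray
) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X_train, y_train, rcond=None)
    return X_new @ beta


def shrink_accessibility(
    estimates: Sequence[AccessibilityEstimate],
    c_control: float,
    n_train: int = 2000,
    folds: int = 10,
    seed: int = 0,
) -> List[AccessibilityEstimate]:
    """Shrink raw accessibility estimates with a coverage-aware linear model.

    An ordinary-least-squares model predicts the accessibility ratio
    (g/(a+g))/c from the control A and G counts (the A+G column is dropped
    as collinear) plus an intercept, trained on ``n_train`` randomly
    sampled sites.  Regression and blending happen on the unclipped ratio —
    clipping first would censor the sampling noise of near-boundary sites
    and bias the model — and the blend is clipped to [0, 1] at the end:
    shrunken = clip(lambda * predicted + (1 - lambda) * ratio).  lambda is
    picked from {0, 0.1, ..., 1} by k-fold cross-validation: each held-out
    site's counts are split binomially into two half-depth
    pseudo-replicates, the blend built from half 1 is scored against the
    ratio from half 2, so the criterion tracks error to the true
    accessibility up to a lambda-free noise term.  Deterministic under
    ``seed``.
    """
    if len(estimates) < 2:
        raise EstimationError("need at least 2 sites to shrink accessibility")
    if not 0.0 < c_control <= 1.0:
        raise ParameterError(f"conversion rate must be in (0, 1], got {c_control}")
    rng = np.random.default_rng(seed)

    a = np.array([e.control_counts[0] for e in estimates], dtype=float)
    g = np.array([e.control_counts[1] for e in estimates], dtype=float)
    cov = a + g
    if (cov < 1).any():
        raise EstimationError("every accessibility estimate needs control coverage >= 1")
    raw = g / cov / c_control  # unclipped ratio
    X = np.column_stack([np.ones_like(a), a, g])

    k = len(estimates)
    if k < n_train:
        warnings.warn(
            f"only {k} sites available; training the shrinkage model on all of them "
            f"(requested {n_train})",
            stacklevel=2,
        )
        train_idx = np.arange(k)
    else:
        train_idx = rng.choice(k, size=n_train, replace=False)

    # half-split pseudo-replicates for the CV criterion
    a_int = a[train_idx].astype(int)
    g_int = g[train_idx].astype(int)
    a1 = rng.binomial(a_int, 0.5)
    g1 = rng.binomial(g_int, 0.5)
    a2, g2 = a_int - a1, g_int - g1

    n_folds = min(folds, len(train_idx))
    order = rng.permutation(len(train_idx))
    fold_of = np.empty(len(train_idx), dtype=int)
    fold_of[order] = np.arange(len(train_idx)) % n_folds

    sq_err = np.zeros_like(_LAMBDA_GRID)
    for f in range(n_folds):
        held = fold_of == f
        if held.all() or (~held).sum() < 3:
            continue
        pred = _ols_predict(X[train_idx[~held]], raw[train_idx[~held]], X[train_idx[held]])
        n1 = a1[held] + g1[held]
        n2 = a2[held] + g2[held]
        ok = (n1 > 0) & (n2 > 0)
        if not ok.any():
            continue
        raw1 = g1[held][ok] / n1[ok] / c_control
        raw2 = g2[held][ok] / n2[ok] / c_control
        for j, lam in enumerate(_LAMBDA_GRID):
            blend = lam * pred[ok] + (1.0 - lam) * raw1
            sq_err[j] += float(np.sum((blend - raw2) ** 2))
    lam = float(_LAMBDA_GRID[int(np.argmin(sq_err))])

    pred_all = _ols_predict(X[train_idx], raw[train_idx], X)
    shrunken = np.clip(lam * pred_all + (1.0 - lam) * raw, 0.0, 1.0)
    return [
        AccessibilityEstimate(
            site=e.site,
            raw_s=e.raw_s,
            control_counts=e.control_counts,
            shrunken_s=float(s),
        )
        for e, s in zip(estimates, shrunken)
    ]


def _pooled_full_probe_counts(probes: Iterable[ProbeObservation]) -> Tuple[int, int]:
    a = g = 0
    for p in probes:
        if p.designed_m6a_fraction >= 1.0 - 1e-9:
            a += p.a_count
            g += p.g_count
    return a, g


def estimate_fto_efficiency(
    probes_minus: Iterable[ProbeObservation],
    probes_plus: Iterable[ProbeObservation],
    c: float,
) -> float:
    """Upper bound on FTO demethylation efficiency from 100%-m6A spike-ins.

    e = clip(1 - m_plus / m_minus, 0, 1) where the m's are apparent
    methylation estimates on the fully methylated probes before and after
    FTO treatment.
    """
    a_m, g_m = _pooled_full_probe_counts(probes_minus)
    a_p, g_p = _pooled_full_probe_counts(probes_plus)
    if a_m + g_m == 0 or a_p + g_p == 0:
        raise EstimationError("both probe sets must include a designed fraction of 1.0")
    m_minus = apparent_methylation(a_m, g_m, c)
    if m_minus == 0.0:
        raise EstimationError("fully methylated probes report zero methylation in the FTO- sample")
    m_plus = apparent_methylation(a_p, g_p, c)
    return float(min(1.0, max(0.0, 1.0 - m_plus / m_minus)))


def _fto_loglik_grid(
    minus: SiteCount,
    plus: SiteCount,
    c_minus: float,
    c_plus: float,
    e: float,
    m: np.ndarray,
    s: np.ndarray,
) -> np.ndarray:
    M, S = np.meshgrid(m, s, indexing="ij")
    pi_m = 1.0 - c_minus * S * (1.0 - M)
    pi_p = 1.0 - c_plus * S * (1.0 - M * (1.0 - e))
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            xlogy(minus.a_count, pi_m)
            + xlogy(minus.g_count, 1.0 - pi_m)
            + xlogy(plus.a_count, pi_p)
            + xlogy(plus.g_count, 1.0 - pi_p)
        )
    return np.nan_to_num(ll, nan=-np.inf, neginf=-np.inf)


def joint_fit_fto(
    minus: SiteCount,
    plus: SiteCount,
    c_minus: float,
    c_plus: float,
    e: float,
    grid_step: float = 0.005,
) -> FTOFit:
    """Joint MLE of (methylation, accessibility) from an FTO sample pair.

    Maximises the sum of two binomial log-likelihoods with
    pi_minus = 1 - c_minus * s * (1 - m) and
    pi_plus = 1 - c_plus * s * (1 - m (1 - e)) over (m, s) in [0, 1]^2 by a
    dense grid search followed by bounded local refinement.  When the
    surface is flat along the m*s ridge (small e) the maximal-s solution is
    reported — the conservative, "accessible but less methylated", call.
    """
    if minus.coverage < 1 or plus.coverage < 1:
        raise EstimationError("both samples need coverage >= 1")
    for name, c in (("c_minus", c_minus), ("c_plus", c_plus)):
        if not 0.0 < c <= 1.0:
            raise ParameterError(f"{name} must be in (0, 1], got {c}")
    if not 0.0 < e <= 1.0:
        raise EstimationError(
            "FTO efficiency of 0 leaves the model unidentifiable (the two samples "
            "share one likelihood); e must be in (0, 1]"
        )

    axis = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    ll = _fto_loglik_grid(minus, plus, c_minus, c_plus, e, axis, axis)
    best = ll.max()
    ties = np.argwhere(ll >= best - 1e-9)
    # ridge tie-break: maximal s, then minimal m
    order = np.lexsort((ties[:, 0], -ties[:, 1]))
    mi, si = ties[order[0]]
    m0, s0 = float(axis[mi]), float(axis[si])

    def neg_ll(x: np.ndarray) -> float:
        m_, s_ = x
        pi_m = np.clip(1.0 - c_minus * s_ * (1.0 - m_), 1e-12, 1.0 - 1e-12)
        pi_p = np.clip(1.0 - c_plus * s_ * (1.0 - m_ * (1.0 - e)), 1e-12, 1.0 - 1e-12)
        return -(
            xlogy(minus.a_count, pi_m)
            + xlogy(minus.g_count, 1.0 - pi_m)
            + xlogy(plus.a_count, pi_p)
            + xlogy(plus.g_count, 1.0 - pi_p)
        )

    res = minimize(neg_ll, x0=[m0, s0], method="L-BFGS-B", bounds=[(0.0, 1.0), (0.0, 1.0)])
    m_hat, s_hat = float(m0), float(s0)
    loglik = float(best)
    if res.success and -res.fun >= loglik - 1e-9:
        refined_ll = float(
            _fto_loglik_grid(
                minus, plus, c_minus, c_plus, e,
                np.array([res.x[0]]), np.array([res.x[1]])
            )[0, 0]
        )
        # keep the refinement only if it genuinely improves on the grid point
        if refined_ll > loglik:
            m_hat, s_hat = float(res.x[0]), float(res.x[1])
            loglik = refined_ll
    return FTOFit(site=minus.site, m_hat=m_hat, s_hat=s_hat, e_used=float(e), loglik=loglik)
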