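"""Site calling: Fisher persistence tests, BH-FDR and the published filters.

A site is called m6A when it (1) has >= 10 A+G counts in both the treated
and the control sample, (2) passes a one-sided Fisher exact test at
FDR < 0.05 for retaining more persistent A than the control, and (3) shows
an exposed methylation level (true methylation x accessibility) >= 10%.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .estimate import (
    adjust_methylation,
    apparent_methylation,
    joint_fit_fto,
    raw_accessibility,
    shrink_accessibility,
)
from .io import fetch_motif
from .model import (
    AccessibilityEstimate,
    CallParams,
    EstimationError,
    GenomicSite,
    MethylCall,
    ParameterError,
    SampleTable,
)

__all__ = [
    "fisher_persistence_test",
    "bh_adjust",
    "accessibility_from_control",
    "call_sites",
    "quantify_target_site",
]


def fisher_persistence_test(treated: Tuple[int, int], control: Tuple[int, int]) -> float:
    """One-sided Fisher exact p that the treated sample retains more A.

    The alternative is that the treated persistent-A proportion exceeds the
    control's; methylation can only increase persistence, so the test is
    directional.  Computed from the hypergeometric distribution of the 2x2
    table [[a_t, g_t], [a_c, g_c]].
    """
    (a_t, g_t), (a_c, g_c) = treated, control
    if a_t + g_t < 1 or a_c + g_c < 1:
        raise EstimationError("both samples need coverage >= 1")
    _, p = stats.fisher_exact([[a_t, g_t], [a_c, g_c]], alternative="greater")
    return float(min(p, 1.0))


def bh_adjust(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted values, order-preserving."""
    if len(p_values) == 0:
        return []
    _, q, _, _ = multipletests(p_values, method="fdr_bh")
    return [float(x) for x in q]


def accessibility_from_control(
    control: SampleTable,
    shrink: bool = True,
    n_train: int = 2000,
    folds: int = 10,
    seed: int = 0,
) -> Dict[GenomicSite, AccessibilityEstimate]:
    """Raw (optionally shrunken) accessibility for every control site."""
    if control.conversion_rate is None:
        raise EstimationError("control table has no conversion rate set")
    c = control.conversion_rate
    estimates = [
        AccessibilityEstimate(
            site=sc.site,
            raw_s=raw_accessibility(sc.a_count, sc.g_count, c),
            control_counts=(sc.a_count, sc.g_count),
        )
        for sc in control
        if sc.coverage >= 1
    ]
    if shrink and len(estimates) >= 2:
        estimates = shrink_accessibility(estimates, c, n_train=n_train, folds=folds, seed=seed)
    return {e.site: e for e in estimates}


def call_sites(
    treated: SampleTable,
    control: SampleTable,
    accessibility: Optional[Mapping[GenomicSite, AccessibilityEstimate]] = None,
    params: Optional[CallParams] = None,
    *,
    fto_efficiency: Optional[float] = None,
    reference: Optional[Mapping[str, object]] = None,
    seed: int = 0,
) -> List[MethylCall]:
    """Evaluate every eligible site and return it with a pass/fail flag.

    Eligible sites have coverage >= ``params.min_coverage`` in both tables
    and are not excluded.  In ``ivt`` mode accessibility comes from the
    modification-free control (computed here when not supplied); in ``fto``
    mode the control is the FTO-plus table and (m, s) come from the joint
    fit, which needs ``fto_efficiency``.  Evaluated-but-failed sites are
    retained with ``passed=False`` so downstream summaries can use the full
    evaluated set.
    """
    params = params or CallParams()
    if treated.conversion_rate is None or control.conversion_rate is None:
        raise EstimationError("conversion rates must be set on both sample tables")
    c_t, c_c = treated.conversion_rate, control.conversion_rate
    excluded = params.exclusion_sites or frozenset()

    eligible = [
        sc.site
        for sc in treated
        if sc.coverage >= params.min_coverage
        and sc.site not in excluded
        and sc.site in control
        and control.get(sc.site).coverage >= params.min_coverage
    ]
    eligible.sort()
    if not eligible:
        return []

    if params.mode == "ivt" and accessibility is None:
        accessibility = accessibility_from_control(control, seed=seed)
    if params.mode == "fto" and fto_efficiency is None:
        raise ParameterError("fto mode requires an FTO efficiency estimate")

    calls: List[MethylCall] = []
    p_values: List[float] = []
    for site in eligible:
        t, c = treated.get(site), control.get(site)
        apparent = apparent_methylation(t.a_count, t.g_count, c_t)
        if params.mode == "ivt":
            est = accessibility.get(site)
            if est is None:
                continue  # no accessibility estimate possible
            s = est.best
            true_m, exposed = adjust_methylation(apparent, s)
        else:
            fit = joint_fit_fto(t, c, c_t, c_c, fto_efficiency)
            s = fit.s_hat
            true_m = fit.m_hat
            exposed = fit.m_hat * fit.s_hat
        p = fisher_persistence_test((t.a_count, t.g_count), (c.a_count, c.g_count))
        motif = None
        if reference is not None:
            motif = fetch_motif(site, reference)
        calls.append(
            MethylCall(
                site=site,
                apparent_m=apparent,
                accessibility=s,
                true_m=true_m,
                exposed_m=exposed,
                p_value=p,
                q_value=1.0,
                treated_counts=(t.a_count, t.g_count),
                control_counts=(c.a_count, c.g_count),
                motif5=motif,
            )
        )
        p_values.append(p)

    q_values = bh_adjust(p_values)
    for call, q in zip(calls, q_values):
        call.q_value = q
        call.passed = q < params.fdr_threshold and call.exposed_m >= params.exposed_threshold
    return calls


def quantify_target_site(a_fraction: float, c: float) -> float:
    """Single-site stoichiometry from a persistent-A fraction.

    The same background inversion as :func:`apparent_methylation`, applied
    to a fraction from a Sanger trace peak ratio or an amplicon tally:
    clip((a_fraction - (1 - c)) / c, 0, 1).
    """
    if not 0.0 <= a_fraction <= 1.0:
        raise ParameterError(f"a_fraction must be in [0, 1], got {a_fraction}")
    if not 0.0 < c <= 1.0:
        raise ParameterError(f"conversion rate must be in (0, 1], got {c}")
    return float(min(1.0, max(0.0, (a_fraction - (1.0 - c)) / c)))
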