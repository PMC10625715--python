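"""Downstream statistics on a call set.

Motif classification, probe calibration, spatial clustering of sites
against a permutation null, per-transcript methylation load with tertile
binning, and half-life comparison across load bins.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .model import (
    CalibrationFit,
    EstimationError,
    LoadBin,
    ParameterError,
    ValidationError,
)
from .simulate import is_drach

__all__ = [
    "classify_motif",
    "fit_calibration",
    "neighbor_gaps",
    "permutation_gap_null",
    "methylation_load",
    "bin_by_load",
    "compare_half_lives",
    "spike_in_amount",
]


def classify_motif(motif5: str) -> str:
    """"DRACH" or "non-DRACH" for a 5-mer centred on A.

    DRACH: D in {A, G, U}, R in {A, G}, A, C, H in {A, C, U}.
    """
    if len(motif5) != 5:
        raise ValidationError(f"motif must be 5 characters, got {motif5!r}")
    centre = motif5[2].upper()
    if centre != "A":
        raise ValidationError(f"motif centre must be A, got {motif5!r}")
    return "DRACH" if is_drach(motif5) else "non-DRACH"


def fit_calibration(points: Sequence[Tuple[float, float]]) -> CalibrationFit:
    """OLS fit of persistent-A readout against designed m6A fraction."""
    if len(points) < 2:
        raise EstimationError("need at least 2 calibration points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.allclose(x, x[0]):
        raise EstimationError("calibration points need distinct x values")
    res = stats.linregress(x, y)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(points),
    )


def neighbor_gaps(
    site_positions: Mapping[str, Sequence[int]],
) -> Tuple[List[int], Optional[float]]:
    """Pooled within-transcript gaps between neighbouring sites, and median.

    Transcripts with fewer than 2 sites contribute nothing; the median is
    ``None`` when no gaps exist.
    """
    gaps: List[int] = []
    for positions in site_positions.values():
        ordered = sorted(positions)
        gaps.extend(b - a for a, b in zip(ordered, ordered[1:]))
    return gaps, (float(np.median(gaps)) if gaps else None)


def permutation_gap_null(
    all_a_positions: Mapping[str, Sequence[int]],
    motifs: Optional[Mapping[str, Sequence[str]]] = None,
    n_sites: Optional[int] = None,
    mode: str = "unconstrained",
    reps: int = 10,
    seed: int = 0,
    observed_motif_counts: Optional[Mapping[str, int]] = None,
) -> List[float]:
    """Median neighbour gaps under a uniform-placement null.

    Per repetition, ``n_sites`` candidate positions are drawn without
    replacement from the pooled, transcriptome-wide candidate lists.  In
    ``motif_matched`` mode the draw is stratified so the drawn 5-mer
    frequencies equal the observed call-set frequencies given by
    ``observed_motif_counts`` (whose total defines the number drawn).
    Deterministic under ``seed``.
    """
    if mode not in ("unconstrained", "motif_matched"):
        raise ParameterError(f"mode must be 'unconstrained' or 'motif_matched', got {mode!r}")
    rng = np.random.default_rng(seed)

    transcripts: List[str] = []
    positions: List[int] = []
    motif_list: List[str] = []
    for tx, pos_list in all_a_positions.items():
        for i, pos in enumerate(pos_list):
            transcripts.append(tx)
            positions.append(int(pos))
            if motifs is not None:
                motif_list.append(motifs[tx][i])
    total = len(positions)

    if mode == "motif_matched":
        if motifs is None or observed_motif_counts is None:
            raise ParameterError(
                "motif_matched mode needs per-candidate motifs and observed motif counts"
            )
        strata: Dict[str, List[int]] = {}
        for i, m in enumerate(motif_list):
            strata.setdefault(m, []).append(i)
        for motif, want in observed_motif_counts.items():
            have = len(strata.get(motif, []))
            if want > have:
                raise EstimationError(
                    f"motif stratum {motif!r} has {have} candidates but {want} are required"
                )
    else:
        if n_sites is None:
            raise ParameterError("unconstrained mode needs n_sites")
        if n_sites > total:
            raise EstimationError(f"n_sites={n_sites} exceeds {total} candidates")

    medians: List[float] = []
    for _ in range(reps):
        if mode == "unconstrained":
            chosen = rng.choice(total, size=n_sites, replace=False)
        else:
            drawn: List[int] = []
            for motif, want in observed_motif_counts.items():
                idx = strata[motif]
                drawn.extend(rng.choice(idx, size=want, replace=False))
            chosen = np.asarray(drawn)
        per_tx: Dict[str, List[int]] = {}
        for i in chosen:
            per_tx.setdefault(transcripts[i], []).append(positions[i])
        _, med = neighbor_gaps(per_tx)
        medians.append(math.nan if med is None else med)
    return medians


def methylation_load(calls_for_transcript: Iterable[float]) -> float:
    """Total methylation signal on one transcript: the sum of site levels."""
    total = 0.0
    for m in calls_for_transcript:
        if not 0.0 <= m <= 1.0:
            raise ParameterError(f"methylation levels must be in [0, 1], got {m}")
        total += m
    return total


def bin_by_load(loads: Mapping[str, float]) -> List[LoadBin]:
    """Tertile bins of methylated transcripts by ranked load.

    Load-0 transcripts go to the ``none`` bin; the rest are ranked by load
    descending (ties broken by transcript id) and split into high / medium /
    low thirds, remainders assigned top-down so bin sizes differ by at most
    one.
    """
    methylated = sorted(
        ((tx, load) for tx, load in loads.items() if load > 0),
        key=lambda item: (-item[1], item[0]),
    )
    out = [LoadBin(tx, 0.0, "none") for tx, load in sorted(loads.items()) if load == 0]
    n = len(methylated)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    start = 0
    for size, name in zip(sizes, ("high", "medium", "low")):
        for tx, load in methylated[start : start + size]:
            out.append(LoadBin(tx, load, name))
        start += size
    return out


def compare_half_lives(
    bins: Iterable[LoadBin], half_lives: Mapping[str, float]
) -> Dict[str, Dict[str, float]]:
    """Per-bin half-life summaries with a one-tailed rank-sum test.

    Each methylated bin is compared against the unmethylated (``none``)
    reference with a one-tailed Wilcoxon rank-sum (Mann-Whitney U) test
    under the alternative that its half-lives are shorter.  Transcripts
    without a half-life entry are dropped.
    """
    values: Dict[str, List[float]] = {name: [] for name in LoadBin.BINS}
    for b in bins:
        if b.transcript_id in half_lives:
            values[b.bin].append(float(half_lives[b.transcript_id]))
    ref = values["none"]
    if len(ref) < 2:
        raise EstimationError("reference (unmethylated) bin needs >= 2 transcripts with half-lives")
    out: Dict[str, Dict[str, float]] = {}
    for name in LoadBin.BINS:
        vals = values[name]
        if not vals:
            continue
        summary = {
            "n": float(len(vals)),
            "mean": float(np.mean(vals)),
            "median": float(np.median(vals)),
        }
        if name != "none":
            if len(vals) < 2:
                raise EstimationError(f"bin {name!r} needs >= 2 transcripts with half-lives")
            _, p = stats.mannwhitneyu(vals, ref, alternative="less")
            summary["p_value"] = float(p)
        out[name] = summary
    return out


def spike_in_amount(d: float, v: float, c: float, t: float) -> float:
    """Spike-in amount per microgram of total RNA: y = d * v * c / t.

    d: dilution factor; v: volume (uL); c: concentration (attomole/uL);
    t: total RNA mass (ug).
    """
    if t <= 0:
        raise ParameterError(f"total RNA mass must be positive, got {t}")
    return d * v * c / t
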