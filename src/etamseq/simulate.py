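"""Synthetic transcriptomes, reads, count tables and probe sets with known truth.

The generative law for the persistent-A probability at a site is

    pi = 1 - c * s * (1 - m_eff)

where ``c`` is the sample-level conversion rate of the deaminase, ``s`` the
per-site accessibility, and ``m_eff`` the effective methylation level of the
sample role (``m`` for treated / FTO-minus, 0 for the modification-free IVT
control, ``m * (1 - e)`` for the FTO-plus sample demethylated with
efficiency ``e``).  Every estimator in :mod:`etamseq.estimate` inverts this
single factorisation.

Endogenous A-to-I editing is simulated as a persistent G excess present in
every sample role (editing converts A to G before any enzymatic treatment),
so callers see edited sites as highly converted, not methylated.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .model import (
    EtamError,
    GenomicSite,
    ParameterError,
    ProbeObservation,
    ReadObservation,
    SampleTable,
    SiteCount,
)

_DNA = np.array(list("ACGT"))
_D = "AGT"   # D = A, G or U
_R = "AG"    # R = A or G
_H = "ACT"   # H = A, C or U

#: role -> (which conversion rate applies, how m enters)
ROLE_RATES = {"treated": "treated", "ivt": "control", "fto_minus": "treated", "fto_plus": "treated"}


class ConfigError(EtamError):
    """Inconsistent simulation configuration."""


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Distributions are ``(name, *params)`` tuples (JSON lists accepted):

    * methylation: ``("uniform", lo, hi)``, ``("fixed", level)`` or
      ``("levels", [l1, l2, ...])`` (cycled over sites)
    * accessibility: ``("default",)`` — 92% of sites drawn uniform(0.9, 1),
      the remainder uniform(0.2, 0.9) — or ``("fixed", s)`` /
      ``("uniform", lo, hi)``
    * coverage: ``("nbinom", mean, dispersion)``, ``("poisson", mean)``,
      ``("fixed", n)`` or ``("uniform_int", lo, hi)``
    """

    n_transcripts: int = 50
    transcript_length: Union[int, Tuple[int, int]] = 1000
    n_m6a_sites: int = 250
    methylation_distribution: Sequence = ("uniform", 0.0, 1.0)
    accessibility_distribution: Sequence = ("default",)
    conversion_rate_treated: float = 0.99
    conversion_rate_control: float = 0.99
    fto_efficiency: float = 0.9
    coverage_distribution: Sequence = ("nbinom", 50, 5)
    editing_fraction: float = 0.002
    drach_fraction: float = 0.85
    fragment_length: int = 150
    poorly_processed_fraction: float = 0.0
    poorly_processed_conversion: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        rates = {
            "conversion_rate_treated": self.conversion_rate_treated,
            "conversion_rate_control": self.conversion_rate_control,
            "fto_efficiency": self.fto_efficiency,
            "editing_fraction": self.editing_fraction,
            "drach_fraction": self.drach_fraction,
            "poorly_processed_fraction": self.poorly_processed_fraction,
            "poorly_processed_conversion": self.poorly_processed_conversion,
        }
        for name, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_transcripts < 1 or self.n_m6a_sites < 0:
            raise ConfigError("n_transcripts must be >= 1 and n_m6a_sites >= 0")

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**raw)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)
            fh.write("\n")


@dataclass
class SimTruth:
    """Ground truth for every simulated A site.

    ``sites`` has one row per plus-strand A site (>= 2 nt from contig
    ends) with columns: contig, pos, strand, motif5, m (true methylation),
    s (accessibility), is_m6a, is_edited, edit_level.
    """

    sites: pd.DataFrame
    conversion_rates: Dict[str, float]

    def m6a_sites(self) -> pd.DataFrame:
        return self.sites[self.sites["is_m6a"]]

    def site_index(self) -> Dict[GenomicSite, int]:
        return {
            GenomicSite(r.contig, int(r.pos), r.strand): i
            for i, r in enumerate(self.sites.itertuples(index=False))
        }

    def to_tsv(self, path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)


def _lengths(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    tl = config.transcript_length
    if isinstance(tl, int):
        return np.full(config.n_transcripts, tl)
    lo, hi = tl
    return rng.integers(lo, hi + 1, size=config.n_transcripts)


def is_drach(motif5: str) -> bool:
    """DRACH test on a DNA- or RNA-alphabet 5-mer (D R A C H)."""
    m = motif5.upper().replace("U", "T")
    return (
        len(m) == 5
        and m[0] in _D
        and m[1] in _R
        and m[2] == "A"
        and m[3] == "C"
        and m[4] in _H
    )


def _random_drach(rng: np.random.Generator) -> str:
    return (
        _D[rng.integers(len(_D))]
        + _R[rng.integers(len(_R))]
        + "A"
        + "C"
        + _H[rng.integers(len(_H))]
    )


def _random_non_drach(rng: np.random.Generator) -> str:
    while True:
        m = "".join(_DNA[rng.integers(4, size=2)]) + "A" + "".join(_DNA[rng.integers(4, size=2)])
        if not is_drach(m):
            return m


def _draw_methylation(config: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    name, *params = config.methylation_distribution
    if name == "uniform":
        lo, hi = params
        return rng.uniform(lo, hi, size=n)
    if name == "fixed":
        return np.full(n, float(params[0]))
    if name == "levels":
        levels = np.asarray(params[0], dtype=float)
        return levels[np.arange(n) % len(levels)]
    raise ConfigError(f"unknown methylation distribution {name!r}")


def _draw_accessibility(config: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    name, *params = config.accessibility_distribution
    if name == "default":
        high = rng.random(n) < 0.92
        s = np.where(high, rng.uniform(0.9, 1.0, size=n), rng.uniform(0.2, 0.9, size=n))
        return s
    if name == "fixed":
        return np.full(n, float(params[0]))
    if name == "uniform":
        lo, hi = params
        return rng.uniform(lo, hi, size=n)
    raise ConfigError(f"unknown accessibility distribution {name!r}")


def _draw_coverage(config: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    name, *params = config.coverage_distribution
    if name == "fixed":
        return np.full(n, int(params[0]))
    if name == "poisson":
        return rng.poisson(float(params[0]), size=n)
    if name == "nbinom":
        mean, size = float(params[0]), float(params[1])
        p = size / (size + mean)
        return rng.negative_binomial(size, p, size=n)
    if name == "uniform_int":
        lo, hi = params
        return rng.integers(int(lo), int(hi) + 1, size=n)
    raise ConfigError(f"unknown coverage distribution {name!r}")


def simulate_transcriptome(config: SimConfig) -> Tuple[Dict[str, str], SimTruth]:
    """Random transcript sequences plus a full per-A-site truth table.

    m6A sites are planted at least 5 nt apart with their 5-mer context
    overwritten so that a configurable fraction (default 0.85) sit at DRACH
    centres.  All other interior A positions enter the truth table with
    m = 0 so the background is available to conversion-rate estimation and
    null calibration.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0])
    lengths = _lengths(config, rng)
    names = [f"tx{i + 1}" for i in range(config.n_transcripts)]
    seqs: Dict[str, List[str]] = {
        name: list(_DNA[rng.integers(4, size=int(L))]) for name, L in zip(names, lengths)
    }

    # distribute m6A sites over transcripts proportionally to length
    weights = lengths / lengths.sum()
    per_tx = rng.multinomial(config.n_m6a_sites, weights)

    planted: List[Tuple[str, int]] = []
    for name, L, k in zip(names, lengths, per_tx):
        if k == 0:
            continue
        candidates = np.arange(2, int(L) - 2)
        rng.shuffle(candidates)
        chosen: List[int] = []
        for pos in candidates:
            if all(abs(pos - q) >= 5 for q in chosen):
                chosen.append(int(pos))
                if len(chosen) == k:
                    break
        if len(chosen) < k:
            raise ConfigError(
                f"transcript {name}: cannot place {k} m6A sites with 5 nt separation"
            )
        for pos in chosen:
            motif = (
                _random_drach(rng)
                if rng.random() < config.drach_fraction
                else _random_non_drach(rng)
            )
            seqs[name][pos - 2 : pos + 3] = list(motif)
            planted.append((name, pos))

    sequences = {name: "".join(chars) for name, chars in seqs.items()}
    planted_set = set(planted)

    rows = []
    for name in names:
        seq = sequences[name]
        for pos in range(2, len(seq) - 2):
            if seq[pos] != "A":
                continue
            motif = seq[pos - 2 : pos + 3].replace("T", "U")
            rows.append((name, pos, "+", motif, (name, pos) in planted_set))
    df = pd.DataFrame(rows, columns=["contig", "pos", "strand", "motif5", "is_m6a"])

    n_sites = len(df)
    m = np.zeros(n_sites)
    m6a_idx = np.flatnonzero(df["is_m6a"].to_numpy())
    m[m6a_idx] = _draw_methylation(config, rng, len(m6a_idx))
    s = _draw_accessibility(config, rng, n_sites)

    is_edited = np.zeros(n_sites, dtype=bool)
    edit_level = np.zeros(n_sites)
    if config.editing_fraction > 0:
        background = np.flatnonzero(~df["is_m6a"].to_numpy())
        n_edit = int(round(config.editing_fraction * n_sites))
        n_edit = min(n_edit, len(background))
        edited = rng.choice(background, size=n_edit, replace=False)
        is_edited[edited] = True
        edit_level[edited] = rng.uniform(0.3, 0.9, size=n_edit)

    df["m"] = m
    df["s"] = s
    df["is_edited"] = is_edited
    df["edit_level"] = edit_level

    truth = SimTruth(
        sites=df,
        conversion_rates={
            "treated": config.conversion_rate_treated,
            "control": config.conversion_rate_control,
        },
    )
    return sequences, truth


def _effective_m(truth: SimTruth, config: SimConfig, role: str) -> np.ndarray:
    m = truth.sites["m"].to_numpy(copy=True)
    if role == "ivt":
        m = np.zeros_like(m)
    elif role == "fto_plus":
        m = m * (1.0 - config.fto_efficiency)
    elif role not in ("treated", "fto_minus"):
        raise ConfigError(f"unknown sample role {role!r}")
    # editing wipes out methylation and adds a persistent G excess everywhere
    m[truth.sites["is_edited"].to_numpy()] = 0.0
    return m


def persistent_a_probability(truth: SimTruth, config: SimConfig, role: str) -> np.ndarray:
    """Per-site pi = (1 - edit_level) * (1 - c * s * (1 - m_eff))."""
    c = (
        config.conversion_rate_control
        if ROLE_RATES[role] == "control"
        else config.conversion_rate_treated
    )
    s = truth.sites["s"].to_numpy()
    m_eff = _effective_m(truth, config, role)
    pi = 1.0 - c * s * (1.0 - m_eff)
    return (1.0 - truth.sites["edit_level"].to_numpy()) * pi


def simulate_counts(truth: SimTruth, config: SimConfig, role: str) -> SampleTable:
    """Binomial per-site A/G counts for one sample role.

    Coverage is drawn from ``config.coverage_distribution``; the A count is
    binomial(coverage, pi) with pi from :func:`persistent_a_probability`.
    Sites drawn with zero coverage are omitted (unobserved).
    """
    if role not in ROLE_RATES:
        raise ConfigError(f"unknown sample role {role!r}")
    role_tag = list(ROLE_RATES).index(role)
    rng = np.random.default_rng([config.seed, 1, role_tag])
    pi = persistent_a_probability(truth, config, role)
    n = _draw_coverage(config, rng, len(pi))
    a = rng.binomial(n, pi)
    table = SampleTable(label=f"sim_{role}", role=role)
    for row, ni, ai in zip(truth.sites.itertuples(index=False), n, a):
        if ni == 0:
            continue
        site = GenomicSite(row.contig, int(row.pos), row.strand)
        table.add(SiteCount(site, a_count=int(ai), g_count=int(ni - ai)))
    return table


def simulate_reads(
    truth: SimTruth, config: SimConfig, role: str = "treated"
) -> List[ReadObservation]:
    """Fragment-level observations tiling the transcripts.

    Reads of ``fragment_length`` start uniformly within each transcript;
    every covered truth A site is observed as A with the per-site
    probability pi, else G.  A ``poorly_processed_fraction`` of reads has
    its conversion suppressed to ``poorly_processed_conversion`` (these are
    the reads the >50%-unconverted filter should remove).  The number of
    reads per transcript is set so that interior sites match the mean of
    the configured coverage distribution.
    """
    rng = np.random.default_rng([config.seed, 2])
    pi = persistent_a_probability(truth, config, role)
    c = (
        config.conversion_rate_control
        if ROLE_RATES[role] == "control"
        else config.conversion_rate_treated
    )
    # pi under suppressed conversion: scale the conversion factor c -> c_low
    s = truth.sites["s"].to_numpy()
    m_eff = _effective_m(truth, config, role)
    pi_low = (1.0 - truth.sites["edit_level"].to_numpy()) * (
        1.0 - config.poorly_processed_conversion * s * (1.0 - m_eff)
    )

    name, *params = config.coverage_distribution
    mean_cov = {
        "fixed": lambda: float(params[0]),
        "poisson": lambda: float(params[0]),
        "nbinom": lambda: float(params[0]),
        "uniform_int": lambda: (float(params[0]) + float(params[1])) / 2.0,
    }
    if name not in mean_cov:
        raise ConfigError(f"unknown coverage distribution {name!r}")
    target = mean_cov[name]()

    by_tx: Dict[str, List[int]] = {}
    idx_of: Dict[Tuple[str, int], int] = {}
    for i, row in enumerate(truth.sites.itertuples(index=False)):
        by_tx.setdefault(row.contig, []).append(int(row.pos))
        idx_of[(row.contig, int(row.pos))] = i

    reads: List[ReadObservation] = []
    counter = 0
    for contig, positions in by_tx.items():
        positions = sorted(positions)
        pos_arr = np.asarray(positions)
        L = max(positions) + 3  # sequence length lower bound; tiling only needs span
        frag = min(config.fragment_length, L)
        n_starts = max(L - frag, 0) + 1
        # interior sites then see n_reads * frag / n_starts ~= target coverage
        n_reads = int(np.ceil(target * n_starts / frag))
        starts = rng.integers(0, n_starts, size=n_reads)
        poorly = rng.random(n_reads) < config.poorly_processed_fraction
        for start, bad in zip(starts, poorly):
            lo = np.searchsorted(pos_arr, start, side="left")
            hi = np.searchsorted(pos_arr, start + frag, side="left")
            covered = pos_arr[lo:hi]
            p = pi_low if bad else pi
            obs = [
                "A" if rng.random() < p[idx_of[(contig, int(pos))]] else "G"
                for pos in covered
            ]
            counter += 1
            reads.append(
                ReadObservation(
                    read_id=f"r{counter}",
                    umi=f"{counter:08x}",
                    contig=contig,
                    strand="+",
                    ref_a_positions=[int(p_) for p_ in covered],
                    observed=obs,
                )
            )
    return reads


def simulate_probes(
    designed_fractions: Sequence[float],
    reads_per_probe: int,
    conversion_rate: float,
    seed: int,
) -> List[ProbeObservation]:
    """Spike-in probe counts: A ~ binomial(n, f + (1 - f)(1 - c)).

    Probes are fully accessible by construction (short unstructured oligos),
    so the persistent-A probability is the designed m6A fraction plus the
    conversion failure background.
    """
    if not 0.0 < conversion_rate <= 1.0:
        raise ParameterError(f"conversion rate must be in (0, 1], got {conversion_rate}")
    rng = np.random.default_rng([seed, 3])
    out = []
    for f in designed_fractions:
        if not 0.0 <= f <= 1.0:
            raise ParameterError(f"designed fraction must be in [0, 1], got {f}")
        p = f + (1.0 - f) * (1.0 - conversion_rate)
        a = int(rng.binomial(reads_per_probe, p))
        out.append(
            ProbeObservation(
                probe_id=f"probe_m6a_{int(round(100 * f))}",
                designed_m6a_fraction=float(f),
                a_count=a,
                g_count=reads_per_probe - a,
            )
        )
    return out
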