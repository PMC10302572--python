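"""Steady-state cell-cycle model and replication run-out simulation.

For a steady-state bacterial population with replication period ``C``
(initiation to termination), division delay ``D`` (termination to
division) and doubling time ``tau``, the population-averaged number of
chromosomal replication origins (*oriC*) per cell is

    o_bar = 2 ** ((C + D) / tau),

the classic consequence of overlapping cell cycles: when C + D exceeds
tau, new rounds of replication begin before old ones finish and cells
carry 2^k origins.  For fast-growing *E. coli*, C ≈ 40 min and
D ≈ 20 min.

A *run-out* experiment measures o_bar without a microscope: cephalexin
blocks division and rifamycin blocks new initiations, ongoing rounds
complete, and the number of fully replicated chromosomes per cell
afterwards equals the number of origins at the moment of drug addition.
:func:`simulate_runout` samples cells from the steady-state age
distribution and applies exactly this counting rule;
:func:`simulate_dna_histogram` and :func:`estimate_mean_origins` model
the DNA-dye flow-cytometry readout and its peak-assignment analysis.

Initiation timing is treated as deterministic (no initiation-age noise)
and every origin completes during run-out, so origin counts are exact
powers of two by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rng import substream

__all__ = [
    "CellCycleParams",
    "RunoutResult",
    "OriginEstimate",
    "mean_origins_closed_form",
    "origins_for_growth_rates",
    "calibrated_c_plus_d",
    "sample_steady_state_ages",
    "simulate_runout",
    "simulate_dna_histogram",
    "estimate_mean_origins",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class CellCycleParams:
    """C, D and doubling time in minutes; growth rate derived as ln2/tau."""

    tau_min: float
    c_min: float = 40.0
    d_min: float = 20.0

    def __post_init__(self) -> None:
        if self.tau_min <= 0 or self.c_min <= 0 or self.d_min <= 0:
            raise ValueError("C, D and tau must all be positive")

    @property
    def growth_rate_per_h(self) -> float:
        return 60.0 * LN2 / self.tau_min

    @classmethod
    def from_growth_rate(
        cls, growth_rate_per_h: float, c_min: float = 40.0, d_min: float = 20.0
    ) -> "CellCycleParams":
        if growth_rate_per_h <= 0:
            raise ValueError("growth rate must be positive")
        return cls(tau_min=60.0 * LN2 / growth_rate_per_h, c_min=c_min, d_min=d_min)


@dataclass(frozen=True)
class RunoutResult:
    """Distribution of post-run-out fully-replicated chromosome counts.

    ``origin_counts`` maps each observed count (a power of two) to its
    population fraction; fractions sum to 1 and ``mean_origins`` is
    their weighted mean.
    """

    origin_counts: dict[int, float]
    mean_origins: float
    n_cells: int

    def __post_init__(self) -> None:
        fracs = np.array(list(self.origin_counts.values()))
        if fracs.size and not math.isclose(fracs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("origin-count fractions must sum to 1")
        for k in self.origin_counts:
            if k < 1 or (k & (k - 1)) != 0:
                raise ValueError(f"origin count {k} is not a power of two")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.origin_counts.items()),
            columns=["origin_count", "fraction"],
        )


def mean_origins_closed_form(params: CellCycleParams) -> float:
    """o_bar = 2**((C+D)/tau) — the analytic steady-state origin number."""
    return 2.0 ** ((params.c_min + params.d_min) / params.tau_min)


def origins_for_growth_rates(
    growth_rates_per_h, c_plus_d_min: float = 60.0
) -> np.ndarray:
    """Closed-form o_bar for each growth rate at a fixed C+D (minutes)."""
    lam = np.asarray(growth_rates_per_h, dtype=float)
    if np.any(lam <= 0) or c_plus_d_min <= 0:
        raise ValueError("growth rates and C+D must be positive")
    tau_min = 60.0 * LN2 / lam
    return 2.0 ** (c_plus_d_min / tau_min)


def calibrated_c_plus_d(
    endpoint_ratio: float, growth_rate_hi: float, growth_rate_lo: float
) -> float:
    """Effective C+D (minutes) matching a measured o_bar ratio between two conditions.

    Solves 2**((C+D)(lam_hi - lam_lo)/ln2) = ratio.  Used to anchor the
    per-condition origin numbers to a measured fastest/slowest-condition
    ratio (e.g. a 2-fold run-out ratio between glucose- and
    glutamine-grown cells) when per-condition run-outs are not available.
    """
    if endpoint_ratio <= 0 or growth_rate_hi <= growth_rate_lo:
        raise ValueError("need ratio > 0 and growth_rate_hi > growth_rate_lo")
    return 60.0 * LN2 * math.log2(endpoint_ratio) / (growth_rate_hi - growth_rate_lo)


def sample_steady_state_ages(
    tau_min: float, n_cells: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample cell ages from the steady-state age distribution.

    In a steady-state exponential population the age density on
    [0, tau] is f(a) = (2 ln2 / tau) * 2**(-a/tau): newborns are twice
    as frequent as dividing cells.  Sampling is by inverse CDF,
    a = -tau * log2(1 - u/2).
    """
    u = rng.uniform(0.0, 1.0, size=n_cells)
    return -tau_min * np.log2(1.0 - u / 2.0)


def simulate_runout(
    params: CellCycleParams, n_cells: int, rng_seed: int | np.random.Generator = 0
) -> RunoutResult:
    """Simulate a run-out experiment on ``n_cells`` steady-state cells.

    With (C+D)/tau = n + x (n integer, 0 <= x < 1), a cell of age a
    carries 2**(n+1) origins if a > tau*(1-x) (it has passed this
    cycle's initiation) and 2**n otherwise.  The origin count at drug
    addition equals the fully replicated chromosome count after
    run-out.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else substream(rng_seed, "runout")
    )
    total = (params.c_min + params.d_min) / params.tau_min
    n_full = int(math.floor(total))
    x = total - n_full
    ages = sample_steady_state_ages(params.tau_min, n_cells, rng)
    high = ages > params.tau_min * (1.0 - x) if x > 0 else np.zeros(n_cells, bool)
    counts = np.where(high, 2 ** (n_full + 1), 2**n_full)
    values, freq = np.unique(counts, return_counts=True)
    fractions = {int(v): float(f) / n_cells for v, f in zip(values, freq)}
    return RunoutResult(
        origin_counts=fractions,
        mean_origins=float(counts.mean()),
        n_cells=n_cells,
    )


def simulate_dna_histogram(
    result: RunoutResult,
    cv: float,
    n_events: int,
    rng_seed: int | np.random.Generator = 0,
    n_bins: int = 256,
) -> pd.DataFrame:
    """Flow-cytometry-style DNA histogram of a run-out sample.

    Each event's fluorescence is its chromosome count times
    (1 + Gaussian noise of coefficient of variation ``cv``), binned into
    ``n_bins`` equal bins.  Returns a DataFrame with ``bin_center`` (in
    chromosome equivalents) and ``count`` columns; counts sum to
    ``n_events``.
    """
    if not 0.0 <= cv < 0.5:
        raise ValueError("cv must be in [0, 0.5)")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else substream(rng_seed, "dna_histogram")
    )
    ks = np.array(sorted(result.origin_counts))
    probs = np.array([result.origin_counts[int(k)] for k in ks])
    counts = rng.choice(ks, size=n_events, p=probs).astype(float)
    fluor = counts * (1.0 + rng.normal(0.0, cv, size=n_events)) if cv > 0 else counts
    hi = float(ks.max()) * (1.0 + max(6.0 * cv, 0.05))
    hist, edges = np.histogram(fluor, bins=n_bins, range=(0.0, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"bin_center": centers, "count": hist})


@dataclass(frozen=True)
class OriginEstimate:
    """Mean-origin estimate recovered from a DNA histogram."""

    mean_origins: float
    fractions: dict[int, float]
    low_confidence: bool


def estimate_mean_origins(histogram: pd.DataFrame) -> OriginEstimate:
    """Recover o_bar from a DNA histogram by nearest-peak assignment.

    Events are assigned to the nearest 2**k peak center in log2
    fluorescence space (multiplicative dye/instrument noise is symmetric
    there); o_bar is the count-weighted mean of the assigned peaks.  If
    the within-peak spread in log2 exceeds 0.25 — peaks less than ~4
    sigma apart — the estimate is flagged low-confidence.
    """
    centers = np.asarray(histogram["bin_center"], dtype=float)
    counts = np.asarray(histogram["count"], dtype=float)
    mask = (counts > 0) & (centers > 0)
    if not mask.any():
        raise ValueError("histogram has no positive-fluorescence events")
    centers, counts = centers[mask], counts[mask]
    log2c = np.log2(centers)
    k = np.rint(log2c).astype(int)
    k = np.maximum(k, 0)
    total = counts.sum()
    fractions: dict[int, float] = {}
    for kk in np.unique(k):
        fractions[int(2**kk)] = float(counts[k == kk].sum() / total)
    mean = float(sum(peak * frac for peak, frac in fractions.items()))
    dev = log2c - k
    rms = float(np.sqrt(np.sum(counts * dev**2) / total))
    return OriginEstimate(
        mean_origins=mean, fractions=fractions, low_confidence=rms > 0.25
    )
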