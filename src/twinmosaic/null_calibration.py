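"""False-positive calibration of the ARD threshold under the binomial null.

Null model: both co-twins are truly heterozygous (allele fraction 0.5) at
every locus, and read counts on each platform are independent binomial
draws — ``Binomial(depth_hi, 0.5)`` at the high-depth platform and
``Binomial(depth_lo, 0.5)`` at the low-depth platform, per twin.  A locus
is a false positive when the absolute between-twin allelic-ratio
difference exceeds the threshold on *both* platforms simultaneously
(magnitudes only; sign agreement is not required by default, matching the
thresholding step it calibrates before sign classification).

Two routes are provided and cross-checked:

- :func:`simulate_fp_rate` — Monte Carlo over replicates of many loci,
  mirroring a simulation study at the scale of a real twin pair's
  heterozygous set;
- :func:`exact_fp_rate` — exact enumeration: the difference of two
  independent ``Binomial(d, 0.5)`` counts, shifted by ``d``, is
  ``Binomial(2d, 0.5)``, so each platform's tail probability is an exact
  binomial tail sum and the two platforms multiply by independence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import binom

__all__ = ["CalibrationConfig", "CalibrationResult", "simulate_fp_rate",
           "exact_fp_rate", "fp_curve", "write_curve_tsv", "plot_fp_curve"]


@dataclass(frozen=True)
class CalibrationConfig:
    """Parameters of the null simulation.

    Defaults mirror the calibration conditions of a dual-platform twin
    study: fixed read depths 40 and 13, ARD threshold 0.25, replicates of
    893,581 loci (the average per-pair heterozygous count being emulated),
    1,000 replicates.  ``depth_model`` may be ``"fixed"`` or ``"poisson"``
    (per-locus depths Poisson with the given means, truncated at >= 1).
    ``require_sign_match`` additionally demands equal ARD signs across
    platforms — a sensitivity switch, off by default.
    """

    depth_hi: int = 40
    depth_lo: int = 13
    threshold: float = 0.25
    n_loci: int = 893_581
    n_sims: int = 1_000
    seed: int = 0
    depth_model: str = "fixed"
    require_sign_match: bool = False

    def __post_init__(self) -> None:
        if self.depth_hi < 1 or self.depth_lo < 1:
            raise ValueError("depths must be >= 1")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if self.n_loci < 1 or self.n_sims < 1:
            raise ValueError("n_loci and n_sims must be >= 1")
        if self.depth_model not in ("fixed", "poisson"):
            raise ValueError("depth_model must be 'fixed' or 'poisson'")


@dataclass
class CalibrationResult:
    """Monte Carlo estimate with its exact-enumeration companion."""

    fp_rate: float
    per_sim: np.ndarray
    mc_se: float
    exact_rate: float | None
    config: CalibrationConfig


def _truncated_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    d = rng.poisson(mean, size)
    while True:
        zero = d == 0
        if not zero.any():
            return d
        d[zero] = rng.poisson(mean, int(zero.sum()))


def simulate_fp_rate(config: CalibrationConfig) -> CalibrationResult:
    """Monte Carlo false-positive rate of the dual-platform ARD threshold.

    Per locus draws kA, kB ~ Binomial(depth_hi, 0.5) and mA, mB ~
    Binomial(depth_lo, 0.5) independently and flags the locus iff
    |kA − kB| / depth_hi > t and |mA − mB| / depth_lo > t (strict).
    Returns the flagged fraction averaged over ``n_sims`` replicates,
    reproducible from ``seed``.
    """
    rng = np.random.default_rng(config.seed)
    t = config.threshold
    fractions = np.empty(config.n_sims)
    for s in range(config.n_sims):
        if config.depth_model == "fixed":
            d_hi = config.depth_hi
            d_lo = config.depth_lo
        else:
            d_hi = _truncated_poisson(rng, config.depth_hi, config.n_loci)
            d_lo = _truncated_poisson(rng, config.depth_lo, config.n_loci)
        ka = rng.binomial(d_hi, 0.5, config.n_loci)
        kb = rng.binomial(d_hi, 0.5, config.n_loci)
        ma = rng.binomial(d_lo, 0.5, config.n_loci)
        mb = rng.binomial(d_lo, 0.5, config.n_loci)
        d_hi_arr = np.broadcast_to(np.asarray(d_hi), (config.n_loci,))
        d_lo_arr = np.broadcast_to(np.asarray(d_lo), (config.n_loci,))
        diff_hi = ka - kb
        diff_lo = ma - mb
        flag = (np.abs(diff_hi) / d_hi_arr > t) & (np.abs(diff_lo) / d_lo_arr > t)
        if config.require_sign_match:
            flag &= diff_hi * diff_lo > 0
        fractions[s] = flag.mean()
    exact = None
    if config.depth_model == "fixed":
        exact = exact_fp_rate(config.depth_hi, config.depth_lo, t,
                              require_sign_match=config.require_sign_match)
    mc_se = float(fractions.std(ddof=1) / math.sqrt(config.n_sims)) \
        if config.n_sims > 1 else 0.0
    return CalibrationResult(float(fractions.mean()), fractions, mc_se, exact, config)


def _one_platform_tails(depth: int, threshold: float) -> tuple[float, float]:
    """(P(D > t·d), P(|D| > t·d)) for D the difference of two independent
    Binomial(depth, 0.5) counts; D + depth ~ Binomial(2·depth, 0.5)."""
    cut = threshold * depth
    # strict inequality on integers: |D| > cut  <=>  |D| >= floor(cut) + 1,
    # stepping past cut itself when it is (numerically) an integer
    k_min = math.floor(cut + 1e-9) + 1
    if k_min > depth:
        return 0.0, 0.0
    upper = float(binom.sf(depth + k_min - 1, 2 * depth, 0.5))
    return upper, 2.0 * upper  # symmetry of Binomial(2d, 1/2) about d


def exact_fp_rate(depth_hi: int, depth_lo: int, threshold: float,
                  require_sign_match: bool = False) -> float:
    """Exact per-locus false-positive probability of the dual threshold.

    Product of the two platforms' exact two-sided tail probabilities
    P(|D_d|/d > t); with ``require_sign_match`` the one-sided tails
    multiply and the two concordant sign patterns sum.
    """
    if depth_hi < 1 or depth_lo < 1:
        raise ValueError("depths must be >= 1")
    up_hi, two_hi = _one_platform_tails(depth_hi, threshold)
    up_lo, two_lo = _one_platform_tails(depth_lo, threshold)
    if require_sign_match:
        return 2.0 * up_hi * up_lo
    return two_hi * two_lo


def enumerate_fp_rate(depth_hi: int, depth_lo: int, threshold: float) -> float:
    """Brute-force enumeration over all (kA, kB, mA, mB) outcome pairs.

    Independent oracle for :func:`exact_fp_rate`; quadratic in depth, use
    at small depths or once per configuration.
    """
    def one(d: int) -> float:
        k = np.arange(d + 1)
        p = binom.pmf(k, d, 0.5)
        grid = np.abs(k[:, None] - k[None, :]) / d
        return float(np.outer(p, p)[grid > threshold].sum())

    return one(depth_hi) * one(depth_lo)


def fp_curve(depth_hi: int, depth_lo: int, thresholds: Sequence[float],
             sim_config: CalibrationConfig | None = None) -> "pd.DataFrame":
    """Exact (and optionally simulated) false-positive rate per threshold.

    ``thresholds`` must be sorted ascending.  When ``sim_config`` is given,
    a Monte Carlo column is filled by re-running the simulation at each
    threshold (same seed, so the exact column is the smoothness reference).
    """
    import pandas as pd

    ts = list(thresholds)
    if any(b < a for a, b in zip(ts, ts[1:])):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for t in ts:
        exact = exact_fp_rate(depth_hi, depth_lo, t)
        simulated = np.nan
        if sim_config is not None:
            cfg = replace(sim_config, depth_hi=depth_hi, depth_lo=depth_lo,
                          threshold=t)
            simulated = simulate_fp_rate(cfg).fp_rate
        rows.append((t, exact, simulated))
    return pd.DataFrame(rows, columns=["threshold", "exact_rate", "simulated_rate"])


def write_curve_tsv(curve, path: str | Path) -> None:
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# twinmosaic={__version__}\n")
        curve.to_csv(fh, sep="\t", index=False)


def plot_fp_curve(curve, path: str | Path, reference_level: float = 0.05) -> None:
    """Threshold vs false-positive fraction with a dotted reference line
    (default 5%)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["threshold"], curve["exact_rate"], "-o", label="exact", ms=3)
    if curve["simulated_rate"].notna().any():
        ax.plot(curve["threshold"], curve["simulated_rate"], "s",
                label="simulated", ms=3, alpha=0.7)
    ax.axhline(reference_level, color="red", ls=":", label=f"{reference_level:.0%}")
    ax.set_xlabel("minimum allelic-ratio difference (both platforms)")
    ax.set_ylabel("false-positive fraction")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
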