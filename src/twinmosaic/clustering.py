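"""Permutation tests for positional clustering (hotspots) of candidate loci.

Candidate mosaic loci that sit unusually close to one another — within the
same pair of twins or across two independent twin pairs — indicate
mutational hotspots.  The null distribution is built by repeatedly drawing
the same number of loci uniformly without replacement from the background
(reference) set of heterozygous loci and recounting close pairs.

Distances are same-chromosome only, between unordered position pairs, with
window bounds inclusive on both ends; distance 0 (identical positions) is
never counted (windows start at >= 1 bp).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["DistanceWindow", "ClusterTestResult", "pairwise_window_counts",
           "within_pair_cluster_test", "between_pair_cluster_test",
           "DEFAULT_WINDOWS", "write_cluster_tsv"]


@dataclass(frozen=True)
class DistanceWindow:
    """Inclusive base-pair distance bounds [lo_bp, hi_bp]."""

    lo_bp: int
    hi_bp: int

    def __post_init__(self) -> None:
        if not 1 <= self.lo_bp <= self.hi_bp:
            raise ValueError(f"need 1 <= lo_bp <= hi_bp, got [{self.lo_bp}, {self.hi_bp}]")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.lo_bp}-{self.hi_bp}"


#: The distance bands conventionally reported for hotspot enrichment.
DEFAULT_WINDOWS = (DistanceWindow(101, 500), DistanceWindow(501, 1_000),
                   DistanceWindow(1_001, 5_000), DistanceWindow(5_001, 10_000))


@dataclass
class ClusterTestResult:
    window: DistanceWindow
    observed: int
    perm_mean: float
    fold_change: float  # NaN when perm_mean == 0
    p_perm: float
    n_perm: int


Positions = Mapping[str, np.ndarray] | pd.DataFrame


def _by_chrom(positions: Positions) -> dict[str, np.ndarray]:
    """Normalise to chrom -> sorted unique int64 positions."""
    if isinstance(positions, pd.DataFrame):
        out = {str(c): np.unique(g["pos"].to_numpy(dtype=np.int64))
               for c, g in positions.groupby("chrom", sort=False)}
    else:
        out = {str(c): np.unique(np.asarray(p, dtype=np.int64))
               for c, p in positions.items()}
    return {c: p for c, p in out.items() if len(p)}


def pairwise_window_counts(positions: Positions, window: DistanceWindow) -> int:
    """Number of unordered same-chromosome pairs at distance within the window.

    ``positions`` is either a frame with ``chrom``/``pos`` columns or a
    mapping chrom -> positions; duplicates are collapsed.
    """
    total = 0
    for arr in _by_chrom(positions).values():
        # for each locus, count later loci in [p + lo, p + hi]
        hi_idx = np.searchsorted(arr, arr + window.hi_bp, side="right")
        lo_idx = np.searchsorted(arr, arr + window.lo_bp, side="left")
        total += int((hi_idx - lo_idx).sum())
    return total


def _neighbor_hit_count(query: dict[str, np.ndarray], target: dict[str, np.ndarray],
                        window: DistanceWindow) -> int:
    """Number of query loci with >= 1 target locus at in-window distance."""
    total = 0
    for chrom, q in query.items():
        t = target.get(chrom)
        if t is None:
            continue
        right = (np.searchsorted(t, q + window.hi_bp, side="right")
                 > np.searchsorted(t, q + window.lo_bp, side="left"))
        left = (np.searchsorted(t, q - window.lo_bp, side="right")
                > np.searchsorted(t, q - window.hi_bp, side="left"))
        total += int((right | left).sum())
    return total


def _flatten(by_chrom: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    chroms = np.concatenate([np.full(len(p), c, dtype=object)
                             for c, p in by_chrom.items()]) if by_chrom else np.array([], object)
    pos = np.concatenate(list(by_chrom.values())) if by_chrom else np.array([], np.int64)
    return chroms, pos


def _check_subset(cand: dict[str, np.ndarray], back: dict[str, np.ndarray],
                  what: str) -> None:
    for chrom, p in cand.items():
        b = back.get(chrom)
        if b is None or not np.isin(p, b).all():
            raise ValueError(f"{what}: candidate loci must be a subset of the background")


def _resample(rng: np.random.Generator, chroms: np.ndarray, pos: np.ndarray,
              k: int) -> dict[str, np.ndarray]:
    idx = rng.choice(len(pos), size=k, replace=False)
    sel_c, sel_p = chroms[idx], pos[idx]
    out: dict[str, np.ndarray] = {}
    for c in np.unique(sel_c):
        out[str(c)] = np.sort(sel_p[sel_c == c])
    return out


def within_pair_cluster_test(candidates: Positions, background: Positions,
                             windows: Sequence[DistanceWindow] = DEFAULT_WINDOWS,
                             n_perm: int = 1_000, seed: int = 0,
                             ) -> list[ClusterTestResult]:
    """Permutation test for within-pair clustering of candidate loci.

    Observed statistic per window: unordered candidate pairs at in-window
    distance.  Null: ``n_perm`` draws of |candidates| loci uniformly
    without replacement from the background, recounted; the one-sided
    (enrichment) p-value uses the add-one estimator
    ``(1 + #{perm >= obs}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cand = _by_chrom(candidates)
    back = _by_chrom(background)
    _check_subset(cand, back, "within_pair_cluster_test")
    n_cand = sum(len(p) for p in cand.values())
    chroms, pos = _flatten(back)
    if len(pos) < n_cand:
        raise ValueError("background smaller than candidate set")
    rng = np.random.default_rng(seed)
    observed = [pairwise_window_counts(cand, w) for w in windows]
    perm = np.zeros((n_perm, len(windows)), dtype=np.int64)
    for i in range(n_perm):
        sample = _resample(rng, chroms, pos, n_cand)
        for j, w in enumerate(windows):
            perm[i, j] = pairwise_window_counts(sample, w)
    return _summarise(windows, observed, perm, n_perm)


def between_pair_cluster_test(candidates_1: Positions, candidates_2: Positions,
                              background_2: Positions,
                              windows: Sequence[DistanceWindow] = DEFAULT_WINDOWS,
                              n_perm: int = 1_000, seed: int = 0,
                              background_1: Positions | None = None,
                              resample_both: bool = False,
                              ) -> list[ClusterTestResult]:
    """Permutation test for co-location of candidates across two twin pairs.

    Observed statistic per window: number of pair-1 candidate loci with at
    least one pair-2 candidate at in-window same-chromosome distance.
    Null: pair-2 candidates resampled from pair-2's background (pair 1
    fixed); with ``resample_both`` pair 1 is also resampled from
    ``background_1``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    c1 = _by_chrom(candidates_1)
    c2 = _by_chrom(candidates_2)
    b2 = _by_chrom(background_2)
    _check_subset(c2, b2, "between_pair_cluster_test")
    n2 = sum(len(p) for p in c2.values())
    chroms2, pos2 = _flatten(b2)
    if len(pos2) < n2:
        raise ValueError("background_2 smaller than candidates_2")
    if resample_both:
        if background_1 is None:
            raise ValueError("resample_both requires background_1")
        b1 = _by_chrom(background_1)
        _check_subset(c1, b1, "between_pair_cluster_test")
        chroms1, pos1 = _flatten(b1)
    n1 = sum(len(p) for p in c1.values())
    rng = np.random.default_rng(seed)
    observed = [_neighbor_hit_count(c1, c2, w) for w in windows]
    perm = np.zeros((n_perm, len(windows)), dtype=np.int64)
    for i in range(n_perm):
        s2 = _resample(rng, chroms2, pos2, n2)
        s1 = _resample(rng, chroms1, pos1, n1) if resample_both else c1
        for j, w in enumerate(windows):
            perm[i, j] = _neighbor_hit_count(s1, s2, w)
    return _summarise(windows, observed, perm, n_perm)


def _summarise(windows: Sequence[DistanceWindow], observed: Sequence[int],
               perm: np.ndarray, n_perm: int) -> list[ClusterTestResult]:
    results = []
    for j, w in enumerate(windows):
        mean = float(perm[:, j].mean())
        fold = observed[j] / mean if mean > 0 else float("nan")
        p = (1 + int((perm[:, j] >= observed[j]).sum())) / (n_perm + 1)
        results.append(ClusterTestResult(w, int(observed[j]), mean, fold, p, n_perm))
    return results


def write_cluster_tsv(results: Sequence[ClusterTestResult], path: str | Path) -> None:
    from . import __version__

    rows = [(str(r.window), r.observed, r.perm_mean, r.fold_change, r.p_perm, r.n_perm)
            for r in results]
    df = pd.DataFrame(rows, columns=["window_bp", "observed", "perm_mean",
                                     "fold_change", "p_perm", "n_perm"])
    with open(path, "w") as fh:
        fh.write(f"# twinmosaic={__version__}\n")
        df.to_csv(fh, sep="\t", index=False)
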