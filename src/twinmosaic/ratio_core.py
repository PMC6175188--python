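"""Allelic ratios, between-twin differences, and the candidate filter chain.

The detection chain, applied in this fixed order to the joint four-track
table from :func:`twinmosaic.io_formats.join_tracks`:

1. region restriction — keep loci inside the high-confidence inclusion
   mask and outside the repeat exclusion mask;
2. drop loci where both co-twins are homozygous reference (no detectable
   between-twin difference can exist there);
3. clear-call filter — keep loci where at least one co-twin is clearly
   non-mosaic, i.e. that twin's allelic ratio lies within a tolerance
   (default 0.05, strict) of the same canonical genotype value 0, 0.5 or 1
   on *both* platforms;
4. threshold filter — keep loci whose absolute allelic-ratio difference
   exceeds a threshold (default 0.25, strict) on both platforms;
5. classify each survivor as *matching* (ARD same sign on both platforms)
   or *nonmatching* (opposite signs); an exactly-zero ARD on either
   platform leaves the sign undefined and the locus out of both tallies.

Matching in excess of 50% is the detection signal: under pure sampling
noise the two platforms' ARD signs are independent coin flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import RegionSet, TRACK_TAGS

__all__ = [
    "FilterParams", "CandidateSet", "allelic_ratio", "ard", "filter_regions",
    "drop_double_homref", "clear_call_filter", "threshold_filter",
    "classify_matching", "detect", "write_candidates_tsv",
]

#: Order of the named stages recorded in ``CandidateSet.stage_counts``.
STAGE_ORDER = ["input", "regions", "not_double_homref", "clear_call",
               "threshold", "sign_defined"]


@dataclass(frozen=True)
class FilterParams:
    """Tunable thresholds of the filter chain.

    ``ard_threshold``: minimum absolute allelic-ratio difference required on
    both platforms (strict ``>``).  ``clear_call_tolerance``: maximum
    distance (strict ``<``) of a clear co-twin's ratio from a canonical
    genotype ratio.
    """

    ard_threshold: float = 0.25
    clear_call_tolerance: float = 0.05
    canonical_ratios: tuple[float, ...] = (0.0, 0.5, 1.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.ard_threshold <= 1.0:
            raise ValueError(f"ard_threshold must be in [0, 1], got {self.ard_threshold}")
        if not 0.0 <= self.clear_call_tolerance < 0.25:
            raise ValueError(
                f"clear_call_tolerance must be in [0, 0.25), got {self.clear_call_tolerance}")


@dataclass
class CandidateSet:
    """Loci surviving the filter chain, with matching classification.

    ``sites`` carries a ``matching`` column with values ``"matching"``,
    ``"nonmatching"`` or ``"undefined"``.  ``n_total = n_match +
    n_nonmatch`` (undefined-sign loci are excluded from the tally);
    ``stage_counts`` records the locus count after each named stage.
    """

    sites: pd.DataFrame
    stage_counts: dict[str, int] = field(default_factory=dict)
    n_match: int = 0
    n_nonmatch: int = 0

    @property
    def n_total(self) -> int:
        return self.n_match + self.n_nonmatch

    @property
    def matching_fraction(self) -> float:
        return self.n_match / self.n_total if self.n_total else float("nan")


def allelic_ratio(ref_count: int, alt_count: int) -> float:
    """alt / (ref + alt); the allelic ratio of one locus in one track.

    0 means only reference reads, 0.5 a balanced heterozygote, 1 only
    alternative reads.  Zero total depth is an error — callers exclude
    zero-depth loci at join time.
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be non-negative")
    depth = ref_count + alt_count
    if depth == 0:
        raise ZeroDivisionError("allelic ratio undefined at zero total depth")
    return alt_count / depth


def ard(r_a: float, r_b: float) -> float:
    """Allelic-ratio difference, twin A minus twin B; antisymmetric in [-1, 1]."""
    if not (0.0 <= r_a <= 1.0 and 0.0 <= r_b <= 1.0):
        raise ValueError("allelic ratios must lie in [0, 1]")
    return r_a - r_b


def filter_regions(sites: pd.DataFrame, include: RegionSet | None = None,
                   exclude: RegionSet | None = None) -> pd.DataFrame:
    """Keep sites inside ``include`` (if given) and outside ``exclude`` (if given)."""
    keep = np.ones(len(sites), dtype=bool)
    if include is not None:
        keep &= include.contains_frame(sites)
    if exclude is not None:
        keep &= ~exclude.contains_frame(sites)
    return sites.loc[keep].reset_index(drop=True)


def _twin_is_homref(sites: pd.DataFrame, twin: str) -> np.ndarray:
    """Twin-level hom-ref call: genotype calls when any track has one, else
    zero alt reads on all of that twin's tracks."""
    tags = [t for t in TRACK_TAGS if t.startswith(twin)]
    gt = np.stack([sites[f"gt_{t}"].to_numpy() for t in tags])
    alt = np.stack([sites[f"alt_{t}"].to_numpy() for t in tags])
    informative = gt != "missing"
    any_info = informative.any(axis=0)
    # with genotype information: hom_ref iff every informative call is hom_ref
    called_homref = np.where(informative, gt == "hom_ref", True).all(axis=0)
    # fallback: no alt evidence on any track
    no_alt = (alt == 0).all(axis=0)
    return np.where(any_info, called_homref, no_alt)


def drop_double_homref(sites: pd.DataFrame) -> pd.DataFrame:
    """Drop loci where both co-twins are homozygous reference.

    Such loci by definition carry no detectable between-twin difference.
    """
    drop = _twin_is_homref(sites, "a") & _twin_is_homref(sites, "b")
    return sites.loc[~drop].reset_index(drop=True)


def _twin_is_clear(sites: pd.DataFrame, twin: str, params: FilterParams) -> np.ndarray:
    r_hi = sites[f"r_{twin}_hi"].to_numpy()
    r_lo = sites[f"r_{twin}_lo"].to_numpy()
    tol = params.clear_call_tolerance
    clear = np.zeros(len(sites), dtype=bool)
    # the same canonical value must fit on both platforms
    for c in params.canonical_ratios:
        clear |= (np.abs(r_hi - c) < tol) & (np.abs(r_lo - c) < tol)
    return clear


def clear_call_filter(sites: pd.DataFrame, params: FilterParams) -> pd.DataFrame:
    """Keep loci where at least one co-twin is clearly non-mosaic.

    A co-twin is *clear* when its allelic ratio is within
    ``clear_call_tolerance`` (strict) of the same canonical ratio
    (0, 0.5 or 1) on both platforms.
    """
    keep = _twin_is_clear(sites, "a", params) | _twin_is_clear(sites, "b", params)
    return sites.loc[keep].reset_index(drop=True)


def threshold_filter(sites: pd.DataFrame, params: FilterParams) -> pd.DataFrame:
    """Keep loci with |ARD| strictly above the threshold on both platforms."""
    t = params.ard_threshold
    keep = (np.abs(sites["ard_hi"].to_numpy()) > t) & \
           (np.abs(sites["ard_lo"].to_numpy()) > t)
    return sites.loc[keep].reset_index(drop=True)


def classify_matching(sites: pd.DataFrame) -> tuple[pd.DataFrame, int, int]:
    """Attach the matching flag; return (sites, n_match, n_nonmatch).

    Matching: the two platforms' ARDs have the same sign (their product is
    positive).  Nonmatching: opposite signs.  An exactly-zero ARD on either
    platform leaves the sign undefined; the locus is flagged ``undefined``
    and excluded from both counts.
    """
    sites = sites.copy()
    prod = sites["ard_hi"].to_numpy() * sites["ard_lo"].to_numpy()
    flag = np.where(prod > 0, "matching", np.where(prod < 0, "nonmatching", "undefined"))
    sites["matching"] = flag
    return sites, int((flag == "matching").sum()), int((flag == "nonmatching").sum())


def detect(sites: pd.DataFrame, params: FilterParams | None = None,
           include: RegionSet | None = None,
           exclude: RegionSet | None = None) -> CandidateSet:
    """Run the full filter chain and return the classified candidate set."""
    params = params or FilterParams()
    counts = {"input": len(sites)}
    sites = filter_regions(sites, include, exclude)
    counts["regions"] = len(sites)
    sites = drop_double_homref(sites)
    counts["not_double_homref"] = len(sites)
    sites = clear_call_filter(sites, params)
    counts["clear_call"] = len(sites)
    sites = threshold_filter(sites, params)
    counts["threshold"] = len(sites)
    sites, n_match, n_nonmatch = classify_matching(sites)
    counts["sign_defined"] = n_match + n_nonmatch
    return CandidateSet(sites, counts, n_match, n_nonmatch)


CANDIDATE_COLUMNS = ["chrom", "pos", "ref", "alt", "r_a_hi", "r_b_hi",
                     "r_a_lo", "r_b_lo", "ard_hi", "ard_lo", "matching"]


def write_candidates_tsv(candidates: CandidateSet, path: str | Path,
                         params: FilterParams | None = None) -> None:
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# twinmosaic={__version__}\n")
        if params is not None:
            fh.write(f"# ard_threshold={params.ard_threshold}\n")
            fh.write(f"# clear_call_tolerance={params.clear_call_tolerance}\n")
        candidates.sites[CANDIDATE_COLUMNS].to_csv(fh, sep="\t", index=False)
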