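"""Input/output and the four-track locus join.

The pipeline compares read counts for two co-twins (individuals ``A`` and
``B``) each sequenced on two platforms (``high_depth``, nominally ~40X, and
``low_depth``, nominally ~13X).  This module reads per-sample allele counts
from VCF or plain TSV into :class:`SampleTrack` objects, reads BED interval
masks into :class:`RegionSet`, and intersects the four tracks into a single
joint table of biallelic SNV loci with per-track allelic ratios and the
between-twin allelic-ratio differences (ARD) on each platform.

Coordinate conventions: VCF/TSV positions are 1-based; BED intervals are
0-based half-open.  All internal locus keys are 1-based
``(chrom, pos, ref, alt)`` tuples.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from . import __version__

logger = logging.getLogger(__name__)

PLATFORMS = ("high_depth", "low_depth")
GENOTYPES = ("hom_ref", "het", "hom_alt", "missing")
_BASES = frozenset("ACGT")

#: Columns of a SampleTrack's underlying frame.
TRACK_COLUMNS = ["chrom", "pos", "ref", "alt", "ref_count", "alt_count", "genotype"]


class FormatError(ValueError):
    """A malformed input file (bad row, bad coordinates, missing fields)."""


@dataclass(frozen=True)
class CountRecord:
    """Allele read counts for one biallelic SNV locus in one sample/platform."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    ref_count: int
    alt_count: int
    genotype_call: str = "missing"

    def __post_init__(self) -> None:
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise FormatError(
                f"{self.chrom}:{self.pos}: alleles must be single bases A/C/G/T, "
                f"got {self.ref_allele!r}>{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise FormatError(f"{self.chrom}:{self.pos}: ref and alt alleles are equal")
        if self.pos < 1:
            raise FormatError(f"position must be >= 1, got {self.pos}")
        if self.ref_count < 0 or self.alt_count < 0:
            raise FormatError(
                f"{self.chrom}:{self.pos}: negative read count "
                f"({self.ref_count}, {self.alt_count})"
            )
        if self.genotype_call not in GENOTYPES:
            raise FormatError(f"unknown genotype call {self.genotype_call!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class SampleTrack:
    """All count records for one individual on one platform.

    Records are stored as a pandas frame with :data:`TRACK_COLUMNS`; locus
    keys ``(chrom, pos, ref, alt)`` are unique within a track.
    """

    individual_id: str
    platform: str
    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=TRACK_COLUMNS))
    skip_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"platform must be one of {PLATFORMS}, got {self.platform!r}")
        if list(self.df.columns) != TRACK_COLUMNS:
            self.df = self.df.reindex(columns=TRACK_COLUMNS)
        dup = self.df.duplicated(subset=["chrom", "pos", "ref", "alt"])
        if dup.any():
            first = self.df.loc[dup.idxmax()]
            raise FormatError(
                f"duplicated locus key in track {self.individual_id}/{self.platform}: "
                f"{first.chrom}:{first.pos} {first.ref}>{first.alt}"
            )

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> Iterator[CountRecord]:
        for row in self.df.itertuples(index=False):
            yield CountRecord(row.chrom, int(row.pos), row.ref, row.alt,
                              int(row.ref_count), int(row.alt_count), row.genotype)

    @classmethod
    def from_records(cls, individual_id: str, platform: str,
                     records: Iterable[CountRecord],
                     skip_counts: dict[str, int] | None = None) -> "SampleTrack":
        rows = [(r.chrom, r.pos, r.ref_allele, r.alt_allele,
                 r.ref_count, r.alt_count, r.genotype_call) for r in records]
        df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
        return cls(individual_id, platform, df, skip_counts or {})


@dataclass
class RegionSet:
    """Per-chromosome merged intervals, 0-based half-open.

    A 1-based position ``p`` is a member iff ``p - 1`` lies in some interval.
    """

    #: chrom -> (starts, ends) as sorted, merged, non-overlapping arrays.
    intervals: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, triples: Iterable[tuple[str, int, int]]) -> "RegionSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in triples:
            if start < 0 or start >= end:
                raise FormatError(f"bad interval {chrom}:{start}-{end} (need 0 <= start < end)")
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            out: list[list[int]] = []
            for s, e in ivs:
                if out and s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            arr = np.asarray(out, dtype=np.int64)
            merged[chrom] = (arr[:, 0].copy(), arr[:, 1].copy())
        return cls(merged)

    def contains(self, chrom: str, pos: int | np.ndarray) -> np.ndarray | bool:
        """Membership of 1-based position(s) on one chromosome."""
        scalar = np.isscalar(pos)
        p0 = np.atleast_1d(np.asarray(pos, dtype=np.int64)) - 1
        if chrom not in self.intervals:
            res = np.zeros(p0.shape, dtype=bool)
        else:
            starts, ends = self.intervals[chrom]
            idx = np.searchsorted(starts, p0, side="right") - 1
            res = (idx >= 0) & (p0 < ends[np.clip(idx, 0, len(ends) - 1)])
        return bool(res[0]) if scalar else res

    def contains_frame(self, df: pd.DataFrame) -> np.ndarray:
        """Vectorised membership for a frame with ``chrom`` and ``pos`` columns."""
        out = np.zeros(len(df), dtype=bool)
        for chrom, sub in df.groupby("chrom", sort=False):
            out[df.index.get_indexer(sub.index)] = self.contains(
                str(chrom), sub["pos"].to_numpy())
        return out

    def subtract(self, other: "RegionSet") -> "RegionSet":
        """Interval difference self \\ other."""
        triples: list[tuple[str, int, int]] = []
        for chrom, (starts, ends) in self.intervals.items():
            if chrom not in other.intervals:
                triples.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
                continue
            o_starts, o_ends = other.intervals[chrom]
            for s, e in zip(starts, ends):
                cur = int(s)
                lo = np.searchsorted(o_ends, cur, side="right")
                for os_, oe in zip(o_starts[lo:], o_ends[lo:]):
                    if os_ >= e:
                        break
                    if os_ > cur:
                        triples.append((chrom, cur, int(os_)))
                    cur = max(cur, int(oe))
                    if cur >= e:
                        break
                if cur < e:
                    triples.append((chrom, cur, int(e)))
        return RegionSet.from_intervals(triples)

    def total_bp(self) -> int:
        return int(sum((e - s).sum() for s, e in self.intervals.values()))

    def is_empty(self) -> bool:
        return not self.intervals

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                starts, ends = self.intervals[chrom]
                for s, e in zip(starts, ends):
                    fh.write(f"{chrom}\t{s}\t{e}\n")


def read_regions_bed(path: str | Path) -> RegionSet:
    """Read a BED3+ file into a merged :class:`RegionSet`.

    Overlapping intervals are merged; ``start >= end`` raises with the line
    number.  Track/browser/comment lines are skipped.
    """
    triples: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}:{lineno}: bad interval {chrom}:{start}-{end} "
                    f"(need 0 <= start < end)")
            triples.append((chrom, start, end))
    return RegionSet.from_intervals(triples)


# ---------------------------------------------------------------------------
# count tables


def _normalise_gt(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "missing"
    s = str(value).strip().lower()
    if s in ("", "nan", ".", "missing"):
        return "missing"
    if s not in GENOTYPES:
        raise FormatError(f"unknown genotype label {value!r}")
    return s


def read_counts_from_tsv(path: str | Path, individual_id: str | None = None,
                         platform: str | None = None) -> SampleTrack:
    """Read a count table (chrom, pos, ref, alt, ref_count, alt_count[, genotype]).

    Lines starting with ``#`` are metadata; ``# individual=X`` and
    ``# platform=Y`` written by :func:`write_counts_tsv` are honoured unless
    overridden by the arguments.  Positions are 1-based.
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        text = fh.read()
    data_lines: list[str] = []
    line_numbers: list[int] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body and " " not in body.split("=")[0]:
                k, _, v = body.partition("=")
                meta[k.strip()] = v.strip()
            continue
        if line.strip():
            data_lines.append(line)
            line_numbers.append(lineno)
    individual_id = individual_id or meta.get("individual", "unknown")
    platform = platform or meta.get("platform", "high_depth")
    if not data_lines:
        raise FormatError(f"{path}: empty file (no header)")
    try:
        df = pd.read_csv(io.StringIO("\n".join(data_lines)), sep="\t", dtype={"chrom": str})
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed table ({exc})") from exc
    required = ["chrom", "pos", "ref", "alt", "ref_count", "alt_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if "genotype" not in df.columns:
        df["genotype"] = "missing"
    records: list[CountRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(CountRecord(str(row.chrom), int(row.pos), str(row.ref),
                                       str(row.alt), int(row.ref_count),
                                       int(row.alt_count), _normalise_gt(row.genotype)))
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path}:{line_numbers[i + 1]}: {exc}") from exc
    return SampleTrack.from_records(individual_id, platform, records)


def write_counts_tsv(track: SampleTrack, path: str | Path,
                     extra_meta: dict[str, str] | None = None) -> None:
    """Write a track to TSV with a metadata header (tool version, labels)."""
    with open(path, "w") as fh:
        fh.write(f"# twinmosaic={__version__}\n")
        fh.write(f"# individual={track.individual_id}\n")
        fh.write(f"# platform={track.platform}\n")
        for k, v in (extra_meta or {}).items():
            fh.write(f"# {k}={v}\n")
        track.df.to_csv(fh, sep="\t", index=False,
                        header=["chrom", "pos", "ref", "alt",
                                "ref_count", "alt_count", "genotype"])


def read_counts_from_vcf(path: str | Path, sample_name: str,
                         platform: str) -> SampleTrack:
    """Read per-sample allele depths from a VCF into a :class:`SampleTrack`.

    Keeps biallelic SNVs with a non-missing AD annotation for the sample;
    multi-allelic records, indels/MNVs and missing-depth records are skipped
    and tallied in ``skip_counts``.  The genotype call is taken from GT when
    present, else ``missing``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if sample_name not in vcf.samples:
        raise FormatError(
            f"{path}: sample {sample_name!r} not found; available: {vcf.samples}")
    si = vcf.samples.index(sample_name)
    skip = {"multiallelic": 0, "not_snv": 0, "missing_depth": 0}
    records: list[CountRecord] = []
    gt_map = {0: "hom_ref", 1: "het", 3: "hom_alt"}  # cyvcf2 gt_types codes
    saw_ad = False
    for var in vcf:
        if len(var.ALT) != 1:
            skip["multiallelic"] += 1
            continue
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            skip["not_snv"] += 1
            continue
        ad = var.format("AD")
        if ad is None:
            skip["missing_depth"] += 1
            continue
        saw_ad = True
        ref_n, alt_n = int(ad[si][0]), int(ad[si][1])
        if ref_n < 0 or alt_n < 0:  # cyvcf2 encodes missing as negative
            skip["missing_depth"] += 1
            continue
        gt = gt_map.get(int(var.gt_types[si]), "missing")
        records.append(CountRecord(var.CHROM, int(var.POS), ref, alt, ref_n, alt_n, gt))
    if not saw_ad and (skip["missing_depth"] > 0 or records == []):
        if skip["missing_depth"] > 0:
            raise FormatError(
                f"{path}: no AD (allele depth) FORMAT annotation found for any record")
    return SampleTrack.from_records(sample_name, platform, records, skip)


# ---------------------------------------------------------------------------
# the four-track join

#: Column layout of the joint-site frame produced by :func:`join_tracks`.
JOINT_KEY = ["chrom", "pos", "ref", "alt"]
TRACK_TAGS = ("a_hi", "b_hi", "a_lo", "b_lo")


@dataclass
class JoinStats:
    """Bookkeeping for :func:`join_tracks`."""

    input_sizes: dict[str, int]
    n_intersection: int
    n_allele_mismatch: int
    n_zero_depth: int
    n_joint: int


def join_tracks(a_hi: SampleTrack, b_hi: SampleTrack,
                a_lo: SampleTrack, b_lo: SampleTrack,
                return_stats: bool = False):
    """Intersect four tracks into a joint-site frame.

    Only loci present in all four tracks survive.  A shared ``(chrom, pos)``
    whose ref/alt alleles disagree between tracks is excluded (no comparable
    ratio exists) and counted.  Loci with zero total depth in any track are
    excluded (ratio undefined).  The output frame carries, per track tag in
    :data:`TRACK_TAGS`: ``ref_<tag>``, ``alt_<tag>``, ``depth_<tag>``,
    ``gt_<tag>``, ``r_<tag>``; plus ``ard_hi = r_a_hi - r_b_hi`` and
    ``ard_lo = r_a_lo - r_b_lo`` (twin A minus twin B on both platforms).
    """
    tracks = {"a_hi": a_hi, "b_hi": b_hi, "a_lo": a_lo, "b_lo": b_lo}
    frames = {}
    for tag, tr in tracks.items():
        df = tr.df.rename(columns={"ref_count": f"ref_{tag}", "alt_count": f"alt_{tag}",
                                   "genotype": f"gt_{tag}"})
        frames[tag] = df
    # positional intersection (chrom, pos) vs full-key intersection: loci in
    # the former but not the latter carry a ref/alt disagreement (D3-style
    # exclusion — no comparable ratio across tracks).
    pos_keys = None
    for tag in TRACK_TAGS:
        keys = frames[tag][["chrom", "pos"]].drop_duplicates()
        pos_keys = keys if pos_keys is None else pos_keys.merge(keys, on=["chrom", "pos"])
    n_inter = len(pos_keys)
    full = frames["a_hi"]
    for tag in ("b_hi", "a_lo", "b_lo"):
        full = full.merge(frames[tag], on=JOINT_KEY, how="inner")
    n_mismatch = n_inter - len(full[["chrom", "pos"]].drop_duplicates())
    if n_mismatch:
        logger.info("join_tracks: excluded %d loci with ref/alt disagreement", n_mismatch)
    for tag in TRACK_TAGS:
        full[f"depth_{tag}"] = full[f"ref_{tag}"] + full[f"alt_{tag}"]
    nonzero = np.ones(len(full), dtype=bool)
    for tag in TRACK_TAGS:
        nonzero &= full[f"depth_{tag}"].to_numpy() > 0
    n_zero = int((~nonzero).sum())
    if n_zero:
        logger.info("join_tracks: excluded %d loci with a zero-depth track", n_zero)
    full = full.loc[nonzero].reset_index(drop=True)
    for tag in TRACK_TAGS:
        full[f"r_{tag}"] = full[f"alt_{tag}"] / full[f"depth_{tag}"]
    # single-division ARD: algebraically r_a - r_b, but exact at threshold
    # boundaries (e.g. a count difference of exactly 10 at equal depth 40
    # yields 0.25 exactly, not 0.25 + one ulp as the float subtraction would)
    for plat in ("hi", "lo"):
        da = full[f"depth_a_{plat}"].to_numpy(dtype=np.float64)
        db = full[f"depth_b_{plat}"].to_numpy(dtype=np.float64)
        aa = full[f"alt_a_{plat}"].to_numpy(dtype=np.float64)
        ab = full[f"alt_b_{plat}"].to_numpy(dtype=np.float64)
        full[f"ard_{plat}"] = (aa * db - ab * da) / (da * db)
    stats = JoinStats({t: len(tr) for t, tr in tracks.items()},
                      n_inter, n_mismatch, n_zero, len(full))
    if return_stats:
        return full, stats
    return full
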