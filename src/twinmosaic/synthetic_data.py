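"""Synthetic twin-pair, dual-platform read-count datasets with ground truth.

Emulates the data structure of a mosaicism study in monozygotic co-twins:
two individuals ("A", "B") sharing germline genotypes at every variant
locus, each sequenced on a high-depth (~40X) and a low-depth (~13X)
platform; a high-confidence inclusion mask and a repeat-style exclusion
mask; per-locus consequence-category labels; and planted twin-specific
mosaic loci.

Mosaic dosage model: a postzygotic SNV present in a cell fraction ``f``
occupies one haplotype of the carrier cells, so it shifts the carrier
twin's true alternative-allele fraction by ``f/2`` — a gain event takes a
homozygous-reference locus from 0 to ``f/2``, a loss/shift event moves a
heterozygous locus from 0.5 by ``±f/2`` (clamped to [0, 1]).  Read counts
are then binomial draws around the true fraction at the realised per-track
depth, optionally through a symmetric per-read error rate.

Everything is reproducible from the single ``seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import AnnotationTable, VEP_CATEGORIES, write_annotations_tsv
from .io_formats import RegionSet, SampleTrack, TRACK_COLUMNS, write_counts_tsv

__all__ = ["HotspotSpec", "GeneratorConfig", "SyntheticDataset",
           "generate_twin_dataset", "generate_null_dataset", "export_dataset",
           "DEFAULT_CATEGORY_BASELINE"]

#: Baseline per-category label probabilities among background heterozygous
#: loci (multi-label, so they need not sum to 1); values follow the
#: genome-wide consequence-frequency profile of a whole-genome variant set.
DEFAULT_CATEGORY_BASELINE: dict[str, float] = {
    "intronic": 0.554, "intergenic": 0.351, "modifier": 0.997,
    "low_impact": 0.009, "moderate_impact": 0.006, "high_impact": 0.0003,
    "noncoding": 0.324, "synonymous": 0.007, "missense": 0.006,
    "regulatory": 0.091, "tf_binding": 0.007, "protein_coding": 0.492,
    "utr3": 0.017, "utr5": 0.004,
}

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """An infeasible or inconsistent generator configuration."""


@dataclass(frozen=True)
class HotspotSpec:
    """Positional hotspots for planted mosaics.

    ``mosaic_fraction`` of the planted mosaic loci are placed inside
    ``count`` spans of ``span_bp`` base pairs; ``centers`` (chrom, 1-based
    start) may be supplied to co-locate hotspots across datasets.
    """

    count: int = 0
    span_bp: int = 10_000
    mosaic_fraction: float = 0.0
    centers: tuple[tuple[str, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.count < 0 or self.span_bp < 1:
            raise ConfigError("hotspot count must be >= 0 and span_bp >= 1")
        if not 0.0 <= self.mosaic_fraction <= 1.0:
            raise ConfigError("hotspot mosaic_fraction must be in [0, 1]")
        if self.mosaic_fraction > 0 and self.count == 0 and self.centers is None:
            raise ConfigError("hotspot mosaic_fraction > 0 needs count > 0 or centers")


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic twin experiment.

    Defaults: 100,000 variant loci on two chromosomes with 200 planted
    twin-specific mosaics at cell fraction 1.0 (a full-body difference,
    expected |ARD| ~ 0.5 at heterozygous-state loci), germline genotype
    split 0.2/0.6/0.2 (hom-ref both / het / hom-alt), platform depths 40X
    and 13X drawn Poisson (truncated >= 1), no sequencing error, and the
    14-category consequence universe at its baseline prevalences.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 40_000_000, "chr2": 30_000_000})
    n_loci: int = 100_000
    genotype_freqs: tuple[float, float, float] = (0.2, 0.6, 0.2)
    n_mosaic: int = 200
    mosaic_cell_fraction: float = 1.0
    mutated_twin_prob: float = 0.5
    hotspots: HotspotSpec = field(default_factory=HotspotSpec)
    depth_hi: float = 40.0
    depth_lo: float = 13.0
    depth_model: str = "poisson"
    error_rate: float = 0.0
    genotype_mode: str = "called"  # "called" | "missing"
    include_fraction: float = 0.77
    exclude_fraction: float = 0.05
    category_baseline: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_BASELINE))
    category_multipliers: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ConfigError("n_loci must be >= 1")
        if not 0 <= self.n_mosaic <= self.n_loci:
            raise ConfigError("need 0 <= n_mosaic <= n_loci")
        gf = self.genotype_freqs
        if len(gf) != 3 or any(p < 0 for p in gf) or abs(sum(gf) - 1.0) > 1e-9:
            raise ConfigError("genotype_freqs must be 3 non-negative values summing to 1")
        if not 0.0 < self.mosaic_cell_fraction <= 1.0:
            raise ConfigError("mosaic_cell_fraction must be in (0, 1]")
        if not 0.0 <= self.mutated_twin_prob <= 1.0:
            raise ConfigError("mutated_twin_prob must be in [0, 1]")
        if self.depth_hi < 1 or self.depth_lo < 1:
            raise ConfigError("mean depths must be >= 1")
        if self.depth_model not in ("fixed", "poisson"):
            raise ConfigError("depth_model must be 'fixed' or 'poisson'")
        if not 0.0 <= self.error_rate < 0.5:
            raise ConfigError("error_rate must be in [0, 0.5)")
        if self.genotype_mode not in ("called", "missing"):
            raise ConfigError("genotype_mode must be 'called' or 'missing'")
        if not 0.0 < self.include_fraction <= 1.0:
            raise ConfigError("include_fraction must be in (0, 1]")
        if not 0.0 <= self.exclude_fraction < 1.0:
            raise ConfigError("exclude_fraction must be in [0, 1)")
        unknown = set(self.category_baseline) - set(VEP_CATEGORIES)
        unknown |= set(self.category_multipliers) - set(VEP_CATEGORIES)
        if unknown:
            raise ConfigError(f"unknown categories {sorted(unknown)}")


@dataclass
class SyntheticDataset:
    """Four tracks + masks + annotations + truth, as one bundle."""

    a_hi: SampleTrack
    b_hi: SampleTrack
    a_lo: SampleTrack
    b_lo: SampleTrack
    include: RegionSet
    exclude: RegionSet
    annotations: AnnotationTable
    truth: pd.DataFrame
    config: GeneratorConfig

    @property
    def tracks(self) -> tuple[SampleTrack, SampleTrack, SampleTrack, SampleTrack]:
        return (self.a_hi, self.b_hi, self.a_lo, self.b_lo)


# ---------------------------------------------------------------------------
# region construction and position sampling


def _make_masks(config: GeneratorConfig, rng: np.random.Generator
                ) -> tuple[RegionSet, RegionSet]:
    block = 1_000_000
    include: list[tuple[str, int, int]] = []
    for chrom, length in config.chrom_lengths.items():
        starts = np.arange(0, length, block)
        keep = rng.random(len(starts)) < config.include_fraction
        if not keep.any():
            keep[rng.integers(len(starts))] = True
        for s in starts[keep]:
            include.append((chrom, int(s), int(min(s + block, length))))
    inc = RegionSet.from_intervals(include)
    repeat_span = 500
    n_repeats = max(1, int(config.exclude_fraction * inc.total_bp() / repeat_span))
    exclude: list[tuple[str, int, int]] = []
    for chrom, length in config.chrom_lengths.items():
        n_chr = max(1, int(n_repeats * length / sum(config.chrom_lengths.values())))
        s = rng.integers(0, max(1, length - repeat_span), n_chr)
        exclude.extend((chrom, int(x), int(x + repeat_span)) for x in s)
    return inc, RegionSet.from_intervals(exclude)


def _sample_positions(allowed: RegionSet, n: int, rng: np.random.Generator,
                      forbidden: set[tuple[str, int]] | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Draw n unique (chrom, 1-based pos) uniformly from an interval set."""
    chroms, starts, lengths = [], [], []
    for chrom, (s, e) in allowed.intervals.items():
        chroms.extend([chrom] * len(s))
        starts.extend(s.tolist())
        lengths.extend((e - s).tolist())
    lengths = np.asarray(lengths, dtype=np.int64)
    starts = np.asarray(starts, dtype=np.int64)
    chroms = np.asarray(chroms, dtype=object)
    total = int(lengths.sum())
    if total < n:
        raise ConfigError(f"cannot place {n} unique loci in {total} allowed bp")
    cum = np.concatenate([[0], np.cumsum(lengths)])
    seen: set[tuple[str, int]] = set(forbidden or ())
    out_c: list[str] = []
    out_p: list[int] = []
    while len(out_p) < n:
        m = max(1024, 2 * (n - len(out_p)))
        offs = rng.integers(0, total, m)
        iv = np.searchsorted(cum, offs, side="right") - 1
        pos = starts[iv] + (offs - cum[iv]) + 1  # 1-based
        for c, p in zip(chroms[iv], pos):
            key = (str(c), int(p))
            if key in seen:
                continue
            seen.add(key)
            out_c.append(key[0])
            out_p.append(key[1])
            if len(out_p) == n:
                break
    return np.asarray(out_c, dtype=object), np.asarray(out_p, dtype=np.int64)


def _place_hotspot_mosaics(config: GeneratorConfig, allowed: RegionSet,
                           rng: np.random.Generator, n_in_hot: int
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positions for hotspot-resident mosaics; returns (chrom, pos, hotspot_id)."""
    spec = config.hotspots
    if spec.centers is not None:
        centers = list(spec.centers)
    else:
        c, p = _sample_positions(allowed, spec.count, rng)
        centers = list(zip(c.tolist(), p.tolist()))
    if not centers:
        raise ConfigError("hotspot placement requested but no hotspot centers")
    per = np.full(len(centers), n_in_hot // len(centers), dtype=int)
    per[: n_in_hot % len(centers)] += 1
    out_c, out_p, out_id = [], [], []
    for hid, ((chrom, center), k) in enumerate(zip(centers, per)):
        if k == 0:
            continue
        span = RegionSet.from_intervals(
            [(chrom, max(0, center - 1), center - 1 + spec.span_bp)])
        local = span if allowed.is_empty() else _intersect(span, allowed)
        if local.total_bp() < k:
            raise ConfigError(
                f"hotspot at {chrom}:{center} (span {spec.span_bp} bp) cannot "
                f"hold {k} unique mosaic loci")
        c, p = _sample_positions(local, k, rng)
        out_c.extend(c.tolist())
        out_p.extend(p.tolist())
        out_id.extend([hid] * k)
    return (np.asarray(out_c, dtype=object), np.asarray(out_p, dtype=np.int64),
            np.asarray(out_id, dtype=int))


def _intersect(a: RegionSet, b: RegionSet) -> RegionSet:
    # A ∩ B = A \ (A \ B)
    return a.subtract(a.subtract(b))


# ---------------------------------------------------------------------------
# main generator


def generate_twin_dataset(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Generate the full bundle: four tracks, masks, annotations, truth."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    include, exclude = _make_masks(config, rng)
    allowed = include.subtract(exclude)

    n_in_hot = 0
    hot_c = np.array([], dtype=object)
    hot_p = np.array([], dtype=np.int64)
    hot_id = np.array([], dtype=int)
    if config.hotspots.mosaic_fraction > 0 and config.n_mosaic > 0:
        n_in_hot = int(round(config.n_mosaic * config.hotspots.mosaic_fraction))
        if n_in_hot:
            hot_c, hot_p, hot_id = _place_hotspot_mosaics(config, allowed, rng, n_in_hot)

    n_rest = config.n_loci - n_in_hot
    forbidden = set(zip(hot_c.tolist(), hot_p.tolist()))
    rest_c, rest_p = _sample_positions(allowed, n_rest, rng, forbidden)

    chrom = np.concatenate([hot_c, rest_c])
    pos = np.concatenate([hot_p, rest_p])
    hotspot = np.full(config.n_loci, -1, dtype=int)
    hotspot[:n_in_hot] = hot_id

    # mosaic flags: hotspot loci are mosaic by construction; the remainder
    # of the planted mosaics are drawn from the non-hotspot loci
    is_mosaic = np.zeros(config.n_loci, dtype=bool)
    is_mosaic[:n_in_hot] = True
    n_free = config.n_mosaic - n_in_hot
    if n_free:
        free_idx = rng.choice(np.arange(n_in_hot, config.n_loci), n_free, replace=False)
        is_mosaic[free_idx] = True

    # germline genotypes shared by the co-twins
    geno_idx = rng.choice(3, config.n_loci, p=list(config.genotype_freqs))
    geno = np.array(["hom_ref", "het", "hom_alt"])[geno_idx]
    base_frac = np.array([0.0, 0.5, 1.0])[geno_idx]

    # mosaic dosage shifts of f/2 in the carrier twin
    f2 = config.mosaic_cell_fraction / 2.0
    shift = np.zeros(config.n_loci)
    m = is_mosaic
    shift[m & (geno == "hom_ref")] = f2
    shift[m & (geno == "hom_alt")] = -f2
    het_m = m & (geno == "het")
    shift[het_m] = np.where(rng.random(int(het_m.sum())) < 0.5, f2, -f2)

    mutated_a = rng.random(config.n_loci) < config.mutated_twin_prob
    frac_a = np.clip(base_frac + np.where(m & mutated_a, shift, 0.0), 0.0, 1.0)
    frac_b = np.clip(base_frac + np.where(m & ~mutated_a, shift, 0.0), 0.0, 1.0)

    # alleles
    ref_i = rng.integers(0, 4, config.n_loci)
    alt_i = (ref_i + rng.integers(1, 4, config.n_loci)) % 4
    ref = _BASES[ref_i]
    alt = _BASES[alt_i]

    # read counts per track
    e = config.error_rate

    def draw(frac: np.ndarray, mean_depth: float) -> tuple[np.ndarray, np.ndarray]:
        if config.depth_model == "fixed":
            depth = np.full(config.n_loci, int(round(mean_depth)))
        else:
            depth = rng.poisson(mean_depth, config.n_loci)
            while (depth == 0).any():
                z = depth == 0
                depth[z] = rng.poisson(mean_depth, int(z.sum()))
        p_eff = frac * (1 - e) + (1 - frac) * e
        alt_n = rng.binomial(depth, p_eff)
        return depth - alt_n, alt_n

    counts = {
        ("A", "high_depth"): draw(frac_a, config.depth_hi),
        ("B", "high_depth"): draw(frac_b, config.depth_hi),
        ("A", "low_depth"): draw(frac_a, config.depth_lo),
        ("B", "low_depth"): draw(frac_b, config.depth_lo),
    }

    def call_genotype(ref_n: np.ndarray, alt_n: np.ndarray) -> np.ndarray:
        if config.genotype_mode == "missing":
            return np.full(config.n_loci, "missing", dtype=object)
        r = alt_n / (ref_n + alt_n)
        return np.where(r < 0.15, "hom_ref",
                        np.where(r > 0.85, "hom_alt", "het")).astype(object)

    order = np.lexsort((pos, chrom.astype(str)))

    def make_track(ind: str, platform: str) -> SampleTrack:
        ref_n, alt_n = counts[(ind, platform)]
        df = pd.DataFrame({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "ref_count": ref_n, "alt_count": alt_n,
            "genotype": call_genotype(ref_n, alt_n),
        }).iloc[order].reset_index(drop=True)
        return SampleTrack(ind, platform, df[TRACK_COLUMNS])

    # consequence categories, enriched among mosaic loci
    labels: dict[tuple[str, int, str, str], frozenset[str]] = {}
    cat_draws = {}
    for cat in VEP_CATEGORIES:
        p0 = config.category_baseline.get(cat, 0.0)
        mult = config.category_multipliers.get(cat, 1.0)
        p_vec = np.where(is_mosaic, np.clip(p0 * mult, 0.0, 1.0), p0)
        cat_draws[cat] = rng.random(config.n_loci) < p_vec
    for i in range(config.n_loci):
        cats = frozenset(c for c in VEP_CATEGORIES if cat_draws[c][i])
        labels[(str(chrom[i]), int(pos[i]), str(ref[i]), str(alt[i]))] = cats
    annotations = AnnotationTable(labels, VEP_CATEGORIES)

    truth = pd.DataFrame({
        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
        "genotype": geno, "is_mosaic": is_mosaic,
        "mutated_twin": np.where(is_mosaic, np.where(mutated_a, "A", "B"), ""),
        "true_frac_a": frac_a, "true_frac_b": frac_b,
        "hotspot_id": hotspot,
        "categories": [",".join(sorted(annotations.categories_of(
            (str(chrom[i]), int(pos[i]), str(ref[i]), str(alt[i])))))
            for i in range(config.n_loci)],
    }).iloc[order].reset_index(drop=True)

    return SyntheticDataset(
        make_track("A", "high_depth"), make_track("B", "high_depth"),
        make_track("A", "low_depth"), make_track("B", "low_depth"),
        include, exclude, annotations, truth, config)


def generate_null_dataset(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """The same generator with no planted mosaics (n_mosaic = 0)."""
    config = config or GeneratorConfig()
    config = dataclasses.replace(config, n_mosaic=0,
                                 hotspots=dataclasses.replace(
                                     config.hotspots, mosaic_fraction=0.0))
    return generate_twin_dataset(config)


def export_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Write the bundle as plain-text files; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for track, name in zip(dataset.tracks, ("a_hi", "b_hi", "a_lo", "b_lo")):
        p = outdir / f"counts_{name}.tsv"
        write_counts_tsv(track, p)
        paths[f"counts_{name}"] = str(p)
    dataset.include.to_bed(outdir / "include.bed")
    dataset.exclude.to_bed(outdir / "exclude.bed")
    paths["include_bed"] = str(outdir / "include.bed")
    paths["exclude_bed"] = str(outdir / "exclude.bed")
    write_annotations_tsv(dataset.annotations, outdir / "annotations.tsv")
    paths["annotations"] = str(outdir / "annotations.tsv")
    dataset.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    paths["truth"] = str(outdir / "truth.tsv")
    cfg = dataclasses.asdict(dataset.config)
    cfg["hotspots"] = dataclasses.asdict(dataset.config.hotspots)
    with open(outdir / "generator_config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, default=str)
    paths["config"] = str(outdir / "generator_config.json")
    return paths
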