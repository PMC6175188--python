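"""Shared fixtures: small synthetic datasets and hand-built joint frames."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from twinmosaic import io_formats, synthetic_data
from twinmosaic.io_formats import TRACK_TAGS


def make_joint(rows):
    """Build a joint-site frame from compact row tuples.

    Each row: (chrom, pos, (ref_a_hi, alt_a_hi), (ref_b_hi, alt_b_hi),
    (ref_a_lo, alt_a_lo), (ref_b_lo, alt_b_lo)[, genotypes dict]).
    """
    records = []
    for row in rows:
        chrom, pos, *counts = row
        gts = counts.pop() if len(counts) == 5 else {}
        rec = {"chrom": chrom, "pos": pos, "ref": "A", "alt": "G"}
        for tag, (ref_n, alt_n) in zip(TRACK_TAGS, counts):
            rec[f"ref_{tag}"] = ref_n
            rec[f"alt_{tag}"] = alt_n
            rec[f"depth_{tag}"] = ref_n + alt_n
            rec[f"gt_{tag}"] = gts.get(tag, "missing")
        records.append(rec)
    df = pd.DataFrame(records)
    for tag in TRACK_TAGS:
        df[f"r_{tag}"] = df[f"alt_{tag}"] / df[f"depth_{tag}"]
    for plat in ("hi", "lo"):
        da = df[f"depth_a_{plat}"].to_numpy(float)
        db = df[f"depth_b_{plat}"].to_numpy(float)
        df[f"ard_{plat}"] = (df[f"alt_a_{plat}"].to_numpy(float) * db
                             - df[f"alt_b_{plat}"].to_numpy(float) * da) / (da * db)
    return df


def make_track(individual, platform, loci):
    """loci: iterable of (chrom, pos, ref, alt, ref_count, alt_count[, genotype])."""
    rows = []
    for locus in loci:
        gt = locus[6] if len(locus) > 6 else "missing"
        rows.append(locus[:6] + (gt,))
    df = pd.DataFrame(rows, columns=io_formats.TRACK_COLUMNS)
    return io_formats.SampleTrack(individual, platform, df)


@pytest.fixture(scope="session")
def planted_dataset():
    """Default-condition dataset: 200 mosaics at f = 1.0 among 100,000 loci."""
    return synthetic_data.generate_twin_dataset(synthetic_data.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def planted_joint(planted_dataset):
    ds = planted_dataset
    return io_formats.join_tracks(ds.a_hi, ds.b_hi, ds.a_lo, ds.b_lo)


@pytest.fixture(scope="session")
def small_null_dataset():
    """Fast no-mosaic dataset for calibration-style checks."""
    cfg = synthetic_data.GeneratorConfig(
        chrom_lengths={"chr1": 10_000_000}, n_loci=30_000, n_mosaic=0,
        genotype_freqs=(0.1, 0.8, 0.1), depth_model="fixed", seed=23)
    return synthetic_data.generate_null_dataset(cfg)
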