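"""Functional-category enrichment of candidate loci and the negative control.

Each locus may carry several consequence-category labels (VEP-style:
intronic, regulatory, 5' UTR, ...).  Per category, a one-sided Fisher
exact test compares the candidate loci against the rest of the background
heterozygous set (background minus candidates, so the 2x2 strata are
disjoint), and Benjamini–Hochberg step-up control is applied across the
category family.  Reported per-stratum counts use the *full* background so
percentages read like a conventional annotation summary.

The negative control repeats the entire selection + enrichment on the two
platforms of a single individual: any between-platform ARD is noise, so no
enrichment is expected there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .io_formats import SampleTrack
from .ratio_core import FilterParams

__all__ = ["VEP_CATEGORIES", "AnnotationTable", "EnrichmentRow",
           "category_enrichment", "bh_adjust", "control_comparison",
           "ControlComparisonResult", "read_annotations_tsv",
           "write_annotations_tsv", "write_enrichment_tsv"]

#: Default category universe: the 14 VEP-style consequence labels.
VEP_CATEGORIES = (
    "intronic", "intergenic", "modifier", "low_impact", "moderate_impact",
    "high_impact", "noncoding", "synonymous", "missense", "regulatory",
    "tf_binding", "protein_coding", "utr3", "utr5",
)

LocusKey = tuple[str, int, str, str]


@dataclass
class AnnotationTable:
    """Multi-label consequence annotations: locus key -> set of categories."""

    labels: dict[LocusKey, frozenset[str]] = field(default_factory=dict)
    universe: tuple[str, ...] = VEP_CATEGORIES

    def __post_init__(self) -> None:
        uni = set(self.universe)
        for key, cats in self.labels.items():
            unknown = cats - uni
            if unknown:
                raise ValueError(f"locus {key}: labels {sorted(unknown)} "
                                 f"outside the declared universe")

    def categories_of(self, key: LocusKey) -> frozenset[str]:
        return self.labels.get(key, frozenset())

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class EnrichmentRow:
    """One category's 2x2 summary.

    ``k_cand``/``n_cand`` count within candidates, ``k_back``/``n_back``
    within the *full* background; the test itself contrasts candidates
    against background-minus-candidates.
    """

    category: str
    k_cand: int
    n_cand: int
    k_back: int
    n_back: int
    odds_ratio: float
    p_raw: float
    q_fdr: float


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adjusted_(i) = min over j >= i of p_(j) * m / j on the ascending sort,
    capped at 1; ties share the step-up value.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _as_keys(loci: Iterable) -> set[LocusKey]:
    if isinstance(loci, pd.DataFrame):
        return set(map(tuple, loci[["chrom", "pos", "ref", "alt"]].itertuples(index=False)))
    return {tuple(k) for k in loci}


def keys_from_frame(df: pd.DataFrame) -> set[LocusKey]:
    """Locus-key set of a joint-site or track frame."""
    return _as_keys(df)


def category_enrichment(candidates: Iterable, background: Iterable,
                        annotations: AnnotationTable) -> list[EnrichmentRow]:
    """Per-category Fisher enrichment of candidates within the background.

    One-sided (greater) Fisher exact test on the 2x2 table
    (candidate vs background-minus-candidate) x (in-category vs not); odds
    ratio by cross-product, with 0.5 added to every cell only when some
    cell is zero.  ``q_fdr`` is BH-adjusted across the annotation universe.
    """
    cand = _as_keys(candidates)
    back = _as_keys(background)
    if not cand:
        raise ValueError("empty candidate set")
    if not cand <= back:
        raise ValueError("candidates must be a subset of the background")
    rest = back - cand
    n_cand, n_back, n_rest = len(cand), len(back), len(rest)
    rows: list[tuple[str, int, int, float, float]] = []
    for cat in annotations.universe:
        k_cand = sum(1 for k in cand if cat in annotations.categories_of(k))
        k_rest = sum(1 for k in rest if cat in annotations.categories_of(k))
        k_back = k_cand + k_rest
        table = np.array([[k_cand, n_cand - k_cand],
                          [k_rest, n_rest - k_rest]], dtype=float)
        _, p = fisher_exact(table, alternative="greater")
        if (table == 0).any():
            table = table + 0.5
        odds = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
        rows.append((cat, k_cand, k_back, float(odds), float(p)))
    q = bh_adjust([r[4] for r in rows])
    return [EnrichmentRow(cat, k_cand, n_cand, k_back, n_back, odds, p, float(qi))
            for (cat, k_cand, k_back, odds, p), qi in zip(rows, q)]


@dataclass
class ControlComparisonResult:
    """Outcome of the same-individual platform-vs-platform control."""

    individual_id: str
    n_background: int
    n_selected: int
    enrichment: EnrichmentRow | None  # None when no locus was selected


def control_comparison(track_hi: SampleTrack, track_lo: SampleTrack,
                       params: FilterParams, annotations: AnnotationTable,
                       category: str) -> ControlComparisonResult:
    """Same-individual negative control for the enrichment analysis.

    Joins one individual's two platforms, computes the between-platform
    allelic-ratio difference, applies the analogues of the clear-call
    filter (either platform's ratio within tolerance of a canonical value)
    and the ARD threshold (strict, single contrast), then runs the Fisher
    test of the selected loci against the joined background for one
    category.  Differences between two measurements of the same DNA are
    noise, so a calibrated pipeline shows no enrichment here.
    """
    if track_hi.individual_id != track_lo.individual_id:
        raise ValueError("control comparison requires two tracks of the same individual")
    if category not in annotations.universe:
        raise ValueError(f"category {category!r} not in the annotation universe")
    hi = track_hi.df.rename(columns={"ref_count": "ref_hi", "alt_count": "alt_hi",
                                     "genotype": "gt_hi"})
    lo = track_lo.df.rename(columns={"ref_count": "ref_lo", "alt_count": "alt_lo",
                                     "genotype": "gt_lo"})
    joint = hi.merge(lo, on=["chrom", "pos", "ref", "alt"], how="inner")
    depth_hi = joint["ref_hi"] + joint["alt_hi"]
    depth_lo = joint["ref_lo"] + joint["alt_lo"]
    joint = joint.loc[(depth_hi > 0) & (depth_lo > 0)].reset_index(drop=True)
    # hom-ref on both platforms: no detectable difference, mirror the
    # double-hom-ref drop of the twin contrast
    gt = joint[["gt_hi", "gt_lo"]].to_numpy()
    informative = gt != "missing"
    called_homref = np.where(informative, gt == "hom_ref", True).all(axis=1)
    no_alt = (joint[["alt_hi", "alt_lo"]].to_numpy() == 0).all(axis=1)
    homref = np.where(informative.any(axis=1), called_homref, no_alt)
    joint = joint.loc[~homref].reset_index(drop=True)
    d_hi = (joint["ref_hi"] + joint["alt_hi"]).to_numpy(dtype=np.float64)
    d_lo = (joint["ref_lo"] + joint["alt_lo"]).to_numpy(dtype=np.float64)
    r_hi = joint["alt_hi"] / (joint["ref_hi"] + joint["alt_hi"])
    r_lo = joint["alt_lo"] / (joint["ref_lo"] + joint["alt_lo"])
    # single-division ARD, exact at strict-threshold boundaries
    ard = (joint["alt_hi"].to_numpy(np.float64) * d_lo
           - joint["alt_lo"].to_numpy(np.float64) * d_hi) / (d_hi * d_lo)
    tol = params.clear_call_tolerance
    clear = np.zeros(len(joint), dtype=bool)
    for c in params.canonical_ratios:
        clear |= np.abs(r_hi.to_numpy() - c) < tol
        clear |= np.abs(r_lo.to_numpy() - c) < tol
    selected = clear & (np.abs(ard) > params.ard_threshold)
    back_keys = keys_from_frame(joint)
    sel_keys = keys_from_frame(joint.loc[selected])
    if not sel_keys:
        return ControlComparisonResult(track_hi.individual_id, len(back_keys), 0, None)
    rows = category_enrichment(sel_keys, back_keys, annotations)
    row = next(r for r in rows if r.category == category)
    # single-category control: report the raw p as its own family
    row = EnrichmentRow(row.category, row.k_cand, row.n_cand, row.k_back,
                        row.n_back, row.odds_ratio, row.p_raw, row.p_raw)
    return ControlComparisonResult(track_hi.individual_id, len(back_keys),
                                   len(sel_keys), row)


# ---------------------------------------------------------------------------
# serialisation


def read_annotations_tsv(path: str | Path,
                         universe: Sequence[str] = VEP_CATEGORIES) -> AnnotationTable:
    """Annotation TSV: chrom, pos, ref, alt, categories (comma-separated)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    labels: dict[LocusKey, frozenset[str]] = {}
    for row in df.itertuples(index=False):
        cats = frozenset(c.strip() for c in str(row.categories).split(",")
                         if c.strip() and c.strip().lower() != "nan")
        labels[(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))] = cats
    return AnnotationTable(labels, tuple(universe))


def write_annotations_tsv(annotations: AnnotationTable, path: str | Path) -> None:
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# twinmosaic={__version__}\n")
        fh.write("chrom\tpos\tref\talt\tcategories\n")
        for (chrom, pos, ref, alt), cats in sorted(annotations.labels.items()):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{','.join(sorted(cats))}\n")


def write_enrichment_tsv(rows: Sequence[EnrichmentRow], path: str | Path) -> None:
    from . import __version__

    df = pd.DataFrame([{
        "category": r.category,
        "pct_background": 100.0 * r.k_back / r.n_back if r.n_back else float("nan"),
        "pct_candidates": 100.0 * r.k_cand / r.n_cand if r.n_cand else float("nan"),
        "k_cand": r.k_cand, "n_cand": r.n_cand,
        "k_back": r.k_back, "n_back": r.n_back,
        "odds_ratio": r.odds_ratio, "p_raw": r.p_raw, "q_fdr": r.q_fdr,
    } for r in rows])
    with open(path, "w") as fh:
        fh.write(f"# twinmosaic={__version__}\n")
        df.to_csv(fh, sep="\t", index=False)
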