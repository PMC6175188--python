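"""Fisher category enrichment, BH-FDR, and the same-individual control."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import hypergeom

from conftest import make_track
from twinmosaic import synthetic_data
from twinmosaic.enrichment import (AnnotationTable, VEP_CATEGORIES, bh_adjust,
                                   category_enrichment, control_comparison,
                                   keys_from_frame)
from twinmosaic.io_formats import join_tracks
from twinmosaic.ratio_core import FilterParams, detect


def hypergeom_tail_oracle(k_cand, n_cand, k_rest, n_rest):
    """One-sided enrichment p by direct hypergeometric tail summation."""
    N = n_cand + n_rest
    K = k_cand + k_rest
    return float(sum(hypergeom.pmf(x, N, K, n_cand)
                     for x in range(k_cand, min(K, n_cand) + 1)))


def _table(loci_cats):
    labels = {(f"chr1", i + 1, "A", "G"): frozenset(cats)
              for i, cats in enumerate(loci_cats)}
    return AnnotationTable(labels, VEP_CATEGORIES)


def _keys(n, offset=0):
    return {("chr1", i + 1 + offset, "A", "G") for i in range(n)}


class TestCategoryEnrichment:
    def test_p_equals_hypergeometric_tail_oracle(self):
        # 10/100 candidates vs 100/9900 background-rest in the category
        cats = [{"intronic"}] * 10 + [set()] * 90 \
            + [{"intronic"}] * 100 + [set()] * 9_800
        ann = _table(cats)
        cand = _keys(100)
        back = _keys(10_000)
        row = next(r for r in category_enrichment(cand, back, ann)
                   if r.category == "intronic")
        assert row.p_raw == pytest.approx(
            hypergeom_tail_oracle(10, 100, 100, 9_900), rel=1e-9)
        assert row.k_cand == 10 and row.k_back == 110

    @pytest.mark.parametrize("k_cand,n_cand,k_rest,n_rest", [
        (3, 20, 15, 200), (0, 10, 5, 50), (8, 8, 2, 30), (25, 60, 400, 9_000),
    ])
    def test_oracle_agreement_across_tables(self, k_cand, n_cand, k_rest, n_rest):
        cats = ([{"missense"}] * k_cand + [set()] * (n_cand - k_cand)
                + [{"missense"}] * k_rest + [set()] * (n_rest - k_rest))
        ann = _table(cats)
        row = next(r for r in category_enrichment(_keys(n_cand),
                                                  _keys(n_cand + n_rest), ann)
                   if r.category == "missense")
        assert row.p_raw == pytest.approx(
            hypergeom_tail_oracle(k_cand, n_cand, k_rest, n_rest), rel=1e-9)

    def test_identical_proportions_not_enriched(self):
        cats = [{"regulatory"}] * 10 + [set()] * 90 \
            + [{"regulatory"}] * 90 + [set()] * 810
        row = next(r for r in category_enrichment(_keys(100), _keys(1_000),
                                                  _table(cats))
                   if r.category == "regulatory")
        assert row.odds_ratio == pytest.approx(1.0)
        assert row.p_raw >= 0.5

    def test_absent_category_gives_p_one(self):
        cats = [{"intronic"}] * 100
        row = next(r for r in category_enrichment(_keys(10), _keys(100),
                                                  _table(cats))
                   if r.category == "utr5")
        assert row.k_cand == 0 and row.p_raw == 1.0

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            category_enrichment(set(), _keys(10), _table([set()] * 10))

    def test_candidates_must_be_subset(self):
        with pytest.raises(ValueError, match="subset"):
            category_enrichment(_keys(5, offset=100), _keys(10), _table([set()] * 10))


# Printed enrichment p-values of the two twin pairs (14 consequence
# categories each) and the FDR-corrected columns they were published with.
RAW_40 = [9.46e-05, 1.0, 0.338, 1.79e-09, 1.57e-05, 0.0978, 1.52e-03,
          2.06e-04, 1.57e-05, 4.37e-91, 8.10e-18, 4.52e-13, 0.0118, 1.15e-57]
FDR_40 = [1.66e-04, 1.0, 0.364, 5.01e-09, 3.14e-05, 0.114, 2.13e-03,
          3.20e-04, 3.14e-05, 6.12e-91, 3.78e-17, 1.582e-12, 0.015, 8.05e-57]
RAW_100 = [5.39e-05, 1.0, 0.840, 1.80e-05, 5.15e-04, 0.0915, 2.80e-04,
           5.71e-04, 5.15e-04, 4.66e-93, 7.68e-15, 1.42e-16, 6.75e-04, 7.94e-33]
FDR_100 = [1.26e-04, 1.0, 0.905, 5.04e-05, 7.99e-04, 0.107, 5.60e-04,
           7.99e-04, 7.99e-04, 6.52e-92, 2.69e-14, 6.63e-16, 8.59e-04, 5.56e-32]
# index 9 ("regulatory") of the younger pair's FDR column is internally
# inconsistent with BH applied to its raw column (it would be 6.12e-90,
# i.e. raw x 14 at rank 1, as the older pair's rank-1 cell is) — skipped.
INCONSISTENT_40 = {9}


class TestBhAdjust:
    def test_reproduces_younger_pair_fdr_column(self):
        adj = bh_adjust(RAW_40)
        for i, (a, printed) in enumerate(zip(adj, FDR_40)):
            if i in INCONSISTENT_40:
                continue
            assert a == pytest.approx(printed, rel=0.01), f"row {i}"

    def test_reproduces_older_pair_fdr_column_including_threeway_tie(self):
        adj = bh_adjust(RAW_100)
        for i, (a, printed) in enumerate(zip(adj, FDR_100)):
            assert a == pytest.approx(printed, rel=0.01), f"row {i}"
        # the three categories sharing raw step-up value 7.99e-04
        tied = [adj[i] for i in (4, 7, 8)]
        assert len({round(v, 12) for v in tied}) == 1

    def test_ties_all_equal_inputs_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 6), [0.2] * 6)

    def test_single_input_unchanged(self):
        assert bh_adjust([0.031])[0] == pytest.approx(0.031)

    def test_monotone_on_sorted_inputs_dominates_raw_and_capped(self):
        p = np.sort(np.random.default_rng(1).uniform(size=30))
        adj = bh_adjust(p)
        assert (np.diff(adj) >= -1e-15).all()
        assert (adj >= p).all() and (adj <= 1.0).all()
        # a fully tied vector is a fixed point of the step-up
        np.testing.assert_allclose(bh_adjust([0.3] * 5), bh_adjust(bh_adjust([0.3] * 5)))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestControlComparison:
    def _individual_tracks(self, seed, n=4_000, het_frac=0.9):
        """One individual's two platforms: identical DNA, independent reads."""
        rng = np.random.default_rng(seed)
        frac = np.where(rng.random(n) < het_frac, 0.5,
                        np.where(rng.random(n) < 0.5, 0.0, 1.0))
        loci = []
        for platform, depth in (("high_depth", 40), ("low_depth", 13)):
            alt = rng.binomial(depth, frac)
            loci.append([("chr1", i + 1, "A", "G", int(depth - a), int(a))
                         for i, a in enumerate(alt)])
        hi = make_track("I", "high_depth", loci[0])
        lo = make_track("I", "low_depth", loci[1])
        cats = [{"intronic"} if rng.random() < 0.5 else set() for _ in range(n)]
        ann = AnnotationTable({("chr1", i + 1, "A", "G"): frozenset(c)
                               for i, c in enumerate(cats)}, VEP_CATEGORIES)
        return hi, lo, ann

    def test_identical_tracks_select_nothing(self):
        hi, _, ann = self._individual_tracks(0)
        lo = make_track("I", "low_depth", [
            ("chr1", int(r.pos), r.ref, r.alt, int(r.ref_count), int(r.alt_count))
            for r in hi.df.itertuples(index=False)])
        res = control_comparison(hi, lo, FilterParams(), ann, "intronic")
        assert res.n_selected == 0 and res.enrichment is None

    def test_different_individuals_rejected(self):
        hi, lo, ann = self._individual_tracks(1)
        lo.individual_id = "J"
        with pytest.raises(ValueError):
            control_comparison(hi, lo, FilterParams(), ann, "intronic")

    def test_null_control_p_values_calibrated(self):
        """Across 20 seeds of pure platform noise, p <= 0.05 occurs at a
        rate compatible with (and, the test being discrete, at most) the
        nominal level."""
        from scipy.stats import binom
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            hi, lo, ann = self._individual_tracks(100 + seed)
            res = control_comparison(hi, lo, FilterParams(), ann, "intronic")
            if res.enrichment is not None and res.enrichment.p_raw <= 0.05:
                hits += 1
        assert hits <= binom.ppf(0.995, n_seeds, 0.05)

    def test_twin_contrast_enriched_but_self_contrast_not(self):
        """Planted mosaics with category enrichment light up the twin-vs-twin
        test; the platform-vs-platform control on the same data stays null."""
        cfg = synthetic_data.GeneratorConfig(
            chrom_lengths={"chr1": 20_000_000}, n_loci=30_000, n_mosaic=300,
            category_multipliers={"regulatory": 3.0}, depth_model="fixed",
            seed=77)
        ds = synthetic_data.generate_twin_dataset(cfg)
        joint = join_tracks(ds.a_hi, ds.b_hi, ds.a_lo, ds.b_lo)
        cand = detect(joint, FilterParams())
        background = keys_from_frame(joint)
        rows = category_enrichment(keys_from_frame(cand.sites), background,
                                   ds.annotations)
        twin_p = next(r.p_raw for r in rows if r.category == "regulatory")
        ctrl = control_comparison(ds.a_hi, ds.a_lo, FilterParams(),
                                  ds.annotations, "regulatory")
        assert twin_p < 1e-6
        assert ctrl.enrichment is None or ctrl.enrichment.p_raw > 0.05


class TestEnrichmentRecovery:
    def test_enriched_category_ranks_first_in_most_seeds(self):
        """A 3x mosaic multiplier on one category makes it the top-ranked
        (lowest q) category in at least 9 of 10 generator seeds."""
        wins = 0
        for seed in range(10):
            cfg = synthetic_data.GeneratorConfig(
                chrom_lengths={"chr1": 20_000_000}, n_loci=20_000, n_mosaic=200,
                category_multipliers={"regulatory": 3.0}, seed=300 + seed)
            ds = synthetic_data.generate_twin_dataset(cfg)
            truth = ds.truth
            cand = set(map(tuple, truth.loc[truth.is_mosaic,
                                            ["chrom", "pos", "ref", "alt"]]
                           .itertuples(index=False)))
            back = set(map(tuple, truth[["chrom", "pos", "ref", "alt"]]
                           .itertuples(index=False)))
            rows = category_enrichment(cand, back, ds.annotations)
            best = min(rows, key=lambda r: (r.q_fdr, r.p_raw))
            wins += best.category == "regulatory"
        assert wins >= 9
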