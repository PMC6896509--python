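"""Windowed top-SNP selection, LD pruning, MAF filtering, harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqblup.gwas import GwasResult
from seqblup.io_formats import GenotypeMatrix, VariantTable
from seqblup.variant_selection import (TopSnpSet, harmonize_with_array,
                                       ld_prune, maf_filter,
                                       select_window_tops)

from conftest import make_genotypes


def toy_gwas(rows):
    """rows: list of (variant_id, chrom, pos, p)."""
    df = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos_bp", "p_value"])
    df["beta"] = 0.1
    df["se"] = 0.05
    df["maf_discovery"] = 0.2
    df["n_used"] = 100
    df["reason"] = ""
    vt = VariantTable(df[["variant_id", "chrom", "pos_bp"]].assign(
        allele_a1="A", allele_a2="G"))
    return GwasResult(df), vt


def brute_force_windows(rows, window, step, p_thresh):
    """Independent enumeration of sliding windows and their best SNP."""
    out = []
    df = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos_bp", "p_value"])
    for chrom, sub in df.groupby("chrom"):
        start = 1
        last = sub["pos_bp"].max()
        while start <= last:
            inw = sub[(sub["pos_bp"] >= start) & (sub["pos_bp"] < start + window)
                      & (sub["p_value"] < p_thresh)]
            if len(inw):
                best = inw.sort_values(["p_value", "pos_bp", "variant_id"]).iloc[0]
                if best["variant_id"] not in out:
                    out.append(best["variant_id"])
            start += step
    return out


class TestWindowTops:
    def test_spec_worked_example(self):
        rows = [("a", "1", 10_000, 1e-4), ("b", "1", 60_000, 1e-5),
                ("c", "1", 120_000, 0.5)]
        gw, vt = toy_gwas(rows)
        tops = select_window_tops(gw, vt, 100_000, 50_000, 1e-3)
        assert tops.variant_ids == ["b"]
        assert ("b", "DUPLICATE_WINDOW") in tops.removed

    def test_no_significant_snps_empty(self):
        gw, vt = toy_gwas([("a", "1", 500, 0.01), ("b", "1", 900, 0.2)])
        tops = select_window_tops(gw, vt, 100_000, 50_000, 1e-3)
        assert tops.variant_ids == []

    def test_tie_breaks_to_smaller_position(self):
        gw, vt = toy_gwas([("near", "1", 2_000, 1e-5), ("far", "1", 9_000, 1e-5)])
        tops = select_window_tops(gw, vt, 100_000, 50_000, 1e-3)
        assert tops.variant_ids == ["near"]

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(0)
        for rep in range(10):
            rows = []
            for j in range(40):
                rows.append((f"v{j}", str(rng.integers(1, 3)),
                             int(rng.integers(1, 400_000)),
                             float(10 ** rng.uniform(-6, 0))))
            rows = (pd.DataFrame(rows, columns=["variant_id", "chrom",
                                                "pos_bp", "p_value"])
                    .sort_values(["chrom", "pos_bp"]))
            rows = rows.drop_duplicates(subset=["chrom", "pos_bp"])
            tup = list(rows.itertuples(index=False, name=None))
            gw, vt = toy_gwas(tup)
            tops = select_window_tops(gw, vt, 100_000, 50_000, 1e-3)
            assert tops.variant_ids == brute_force_windows(
                tup, 100_000, 50_000, 1e-3)

    def test_bad_window_rejected(self):
        gw, vt = toy_gwas([("a", "1", 5, 1e-4)])
        with pytest.raises(ValueError):
            select_window_tops(gw, vt, 0, 50_000, 1e-3)


def candidate_set(ids, pvals):
    return TopSnpSet(list(ids), {v: {"window_start": 1, "window_end": 2,
                                     "p_value": p}
                                 for v, p in zip(ids, pvals)})


class TestLdPrune:
    def test_perfect_copies_keep_most_significant(self):
        g = make_genotypes(60, 2, seed=1)
        g.dosage[:, 1] = g.dosage[:, 0]
        tops = candidate_set(["v0", "v1"], [1e-6, 1e-5])
        pruned = ld_prune(tops, g, r2_max=0.95)
        assert pruned.variant_ids == ["v0"]
        assert ("v1", "LD_PRUNED") in pruned.removed

    def test_pair_below_threshold_both_kept(self):
        rng = np.random.default_rng(4)
        g = make_genotypes(4000, 2, seed=4)
        # r^2 ~ 0.90 < 0.95: copy then perturb until inside (0.88, 0.92)
        x = g.dosage[:, 0].astype(float)
        y = g.dosage[:, 1].astype(float)
        for _ in range(100):
            y = np.where(rng.random(4000) < 0.97, x, rng.integers(0, 3, 4000))
            r2 = np.corrcoef(x, y)[0, 1] ** 2
            if 0.85 < r2 < 0.93:
                break
        g.dosage[:, 1] = y.astype(np.int8)
        tops = candidate_set(["v0", "v1"], [1e-6, 1e-5])
        pruned = ld_prune(tops, g, r2_max=0.95)
        assert pruned.variant_ids == ["v0", "v1"]

    def test_exhaustive_post_check_on_30_candidates(self):
        g = make_genotypes(100, 30, seed=5, chrom_count=2)
        # plant correlated clusters
        for j in (3, 7, 11):
            g.dosage[:, j] = g.dosage[:, 2]
        rng = np.random.default_rng(0)
        tops = candidate_set([f"v{j}" for j in range(30)],
                             rng.uniform(1e-8, 1e-4, 30))
        pruned = ld_prune(tops, g, r2_max=0.95)
        x = g.dosage_float()
        col = {v: i for i, v in enumerate(g.variants.ids)}
        vdf = g.variants.df.set_index("variant_id")
        kept = pruned.variant_ids
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                if vdf.loc[kept[a], "chrom"] != vdf.loc[kept[b], "chrom"]:
                    continue
                r2 = np.corrcoef(x[:, col[kept[a]]], x[:, col[kept[b]]])[0, 1] ** 2
                assert r2 <= 0.95

    def test_candidate_missing_from_genotypes(self):
        g = make_genotypes(10, 3)
        with pytest.raises(KeyError):
            ld_prune(candidate_set(["nope"], [1e-4]), g, 0.95)


class TestMafFilter:
    def test_boundary_below_removed_at_kept(self):
        # 1000 samples: dosage sum 9 -> freq 0.0045 (<0.005, removed);
        # dosage sum 10 -> freq 0.005 (kept, inclusive boundary)
        g = make_genotypes(1000, 2, seed=0)
        g.dosage[:, :] = 0
        g.dosage[:9, 0] = 1
        g.dosage[:10, 1] = 1
        tops = candidate_set(["v0", "v1"], [1e-5, 1e-5])
        out = maf_filter(tops, g, maf_min=0.005)
        assert out.variant_ids == ["v1"]
        assert ("v0", "LOW_MAF") in out.removed

    def test_matches_counting_oracle(self):
        g = make_genotypes(20, 5, seed=9, missing_rate=0.1)
        maf = g.maf()
        for j, vid in enumerate(g.variants.ids):
            dos = [d for d in g.dosage[:, j] if d >= 0]
            p = sum(dos) / (2 * len(dos))
            assert maf[j] == pytest.approx(min(p, 1 - p))


class TestHarmonize:
    def test_disjoint_unchanged(self):
        tops = candidate_set(["a", "b"], [1e-4, 1e-4])
        t2, panel = harmonize_with_array(tops, {"x", "y"})
        assert t2.variant_ids == ["a", "b"] and panel == {"x", "y"}

    def test_overlap_leaves_array(self):
        tops = candidate_set(["a", "b", "c", "d"], [1e-4] * 4)
        t2, panel = harmonize_with_array(tops, {"a", "b", "c", "x"})
        assert panel == {"x"} and t2.variant_ids == ["a", "b", "c", "d"]

    @settings(deadline=None, max_examples=50)
    @given(st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30)))
    def test_result_sets_always_disjoint(self, top_ids, arr_ids):
        tops = candidate_set([f"v{i}" for i in sorted(top_ids)],
                             [1e-4] * len(top_ids))
        t2, panel = harmonize_with_array(tops, {f"v{i}" for i in arr_ids})
        assert set(t2.variant_ids) & panel == set()


class TestAccounting:
    def test_every_removal_attributable(self):
        g = make_genotypes(80, 20, seed=6)
        g.dosage[:, 5] = g.dosage[:, 4]
        rng = np.random.default_rng(1)
        tops = candidate_set([f"v{j}" for j in range(20)],
                             rng.uniform(1e-8, 1e-4, 20))
        n0 = len(tops)
        pruned = ld_prune(tops, g, 0.95)
        final = maf_filter(pruned, g, 0.005)
        assert n0 == len(final) + len(final.removed)

    def test_pipeline_rerun_is_identical(self):
        g = make_genotypes(80, 20, seed=6)
        rng = np.random.default_rng(1)
        tops = candidate_set([f"v{j}" for j in range(20)],
                             rng.uniform(1e-8, 1e-4, 20))
        a = maf_filter(ld_prune(tops, g, 0.95), g, 0.005)
        b = maf_filter(ld_prune(tops, g, 0.95), g, 0.005)
        assert a.variant_ids == b.variant_ids and a.removed == b.removed
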