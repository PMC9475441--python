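"""Scoring-path checks: allele harmonization by hand enumeration, clumping
against a brute-force oracle, region exclusion at boundaries, the double-loop
scoring oracle, additivity across thresholds, and standardization contracts."""

import numpy as np
import pandas as pd
import pytest

from _oracles import double_loop_prs, greedy_clump
from polypen import prs_scoring as prs
from polypen import synthetic_cohort as sc


def _stats_row(vid, ea, oa, beta, p=0.5, chrom="1", pos=1000, freq=0.3):
    return {
        "variant_id": vid, "chromosome": chrom, "position": pos,
        "effect_allele": ea, "other_allele": oa, "beta": beta,
        "se": 0.01, "p": p, "frequency": freq,
    }


def _variant_row(vid, ref, alt, chrom="1", pos=1000, freq=0.3):
    return {
        "variant_id": vid, "chromosome": chrom, "position": pos,
        "ref_allele": ref, "alt_allele": alt, "alt_frequency": freq,
    }


class TestHarmonize:
    def test_hand_enumerated_mixed_toy(self):
        stats = pd.DataFrame([
            _stats_row("v1", "G", "A", 0.3),            # matches alt -> +0.3
            _stats_row("v2", "A", "G", 0.3),            # effect = ref -> -0.3
            _stats_row("v3", "A", "T", 0.2),            # strand-ambiguous
            _stats_row("v4", "C", "G", 0.2),            # strand-ambiguous
            _stats_row("v5", "A", "C", 0.1),            # allele mismatch
            _stats_row("v6", "T", "C", 0.4),            # matches alt -> +0.4
        ])
        variants = pd.DataFrame([
            _variant_row("v1", "A", "G"),
            _variant_row("v2", "A", "G"),
            _variant_row("v3", "A", "T"),
            _variant_row("v4", "C", "G"),
            _variant_row("v5", "A", "G"),
            _variant_row("v6", "C", "T"),
        ])
        weights, report = prs.harmonize_alleles(stats, variants)
        assert report == {"matched": 2, "flipped": 1, "ambiguous": 2,
                          "mismatch": 1, "absent": 0}
        w = weights.set_index("variant_id")["weight"]
        assert w["v1"] == pytest.approx(0.3)
        assert w["v2"] == pytest.approx(-0.3)
        assert w["v6"] == pytest.approx(0.4)
        assert set(weights["variant_id"]) == {"v1", "v2", "v6"}
        # flipped variant's effect-allele frequency is complemented
        assert weights.set_index("variant_id").loc["v2", "frequency"] == pytest.approx(0.7)

    def test_absent_variant_counted(self):
        stats = pd.DataFrame([_stats_row("vX", "G", "A", 0.3),
                              _stats_row("v1", "G", "A", 0.3)])
        variants = pd.DataFrame([_variant_row("v1", "A", "G")])
        _, report = prs.harmonize_alleles(stats, variants)
        assert report["absent"] == 1

    def test_nothing_survives_raises(self):
        stats = pd.DataFrame([_stats_row("v1", "A", "T", 0.3)])
        variants = pd.DataFrame([_variant_row("v1", "A", "T")])
        with pytest.raises(ValueError, match="no variants survived"):
            prs.harmonize_alleles(stats, variants)


class TestExcludeRegions:
    MHC = (("6", 25_000_000, 34_000_000),)

    @pytest.mark.parametrize(
        "chrom,pos,kept",
        [
            ("6", 30_000_000, False),   # inside
            ("6", 24_999_999, True),    # just below
            ("6", 25_000_000, False),   # closed lower boundary
            ("6", 34_000_000, False),   # closed upper boundary
            ("6", 34_000_001, True),    # just above
            ("1", 30_000_000, True),    # other chromosome
        ],
    )
    def test_boundaries(self, chrom, pos, kept):
        tab = pd.DataFrame([_variant_row("v1", "A", "G", chrom=chrom, pos=pos)])
        out = prs.exclude_regions(tab, self.MHC)
        assert (len(out) == 1) is kept

    def test_ten_variant_span(self):
        positions = [24_999_998 + i * 2_000_000 for i in range(10)]
        tab = pd.DataFrame(
            [_variant_row(f"v{i}", "A", "G", chrom="6", pos=p)
             for i, p in enumerate(positions)]
        )
        out = prs.exclude_regions(tab, self.MHC)
        survivors = [f"v{i}" for i, p in enumerate(positions)
                     if not (25_000_000 <= p <= 34_000_000)]
        assert list(out["variant_id"]) == survivors

    def test_malformed_region(self):
        tab = pd.DataFrame([_variant_row("v1", "A", "G")])
        with pytest.raises(ValueError, match="malformed"):
            prs.exclude_regions(tab, (("1", 100, 50),))


def _weights_frame(rows):
    return pd.DataFrame(rows)[
        ["variant_id", "chromosome", "position", "effect_allele",
         "weight", "p", "frequency"]
    ]


def _w_row(vid, chrom, pos, p, weight=0.1, freq=0.3):
    return {"variant_id": vid, "chromosome": chrom, "position": pos,
            "effect_allele": "G", "weight": weight, "p": p, "frequency": freq}


class TestClump:
    def test_outside_window_both_retained(self):
        w = _weights_frame([_w_row("a", "1", 100_000, 1e-8),
                            _w_row("b", "1", 700_000, 1e-4)])
        geno = pd.DataFrame(
            {"a": [0, 1, 2, 1, 0, 2], "b": [0, 1, 2, 1, 0, 2]},
            index=[f"s{i}" for i in range(6)],
        )
        kept = prs.ld_clump(w, geno, prs.ClumpConfig())
        assert kept == ["a", "b"]

    def test_within_window_best_p_wins(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 500)
        noise = rng.integers(0, 3, 500)
        b = np.where(rng.random(500) < 0.85, a, noise)  # r2 > 0.1
        assert np.corrcoef(a, b)[0, 1] ** 2 > 0.4
        geno = pd.DataFrame({"a": a, "b": b}, index=[f"s{i}" for i in range(500)])
        w = _weights_frame([_w_row("a", "1", 100_000, 1e-8),
                            _w_row("b", "1", 110_000, 1e-4)])
        assert prs.ld_clump(w, geno, prs.ClumpConfig()) == ["a"]

    def test_missing_reference_variant_listed(self):
        w = _weights_frame([_w_row("a", "1", 100_000, 1e-8)])
        geno = pd.DataFrame({"b": [0, 1, 2]}, index=["s0", "s1", "s2"])
        with pytest.raises(ValueError, match="a"):
            prs.ld_clump(w, geno, prs.ClumpConfig())

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        kept, oracle = _random_clump_instance(seed)
        assert kept == oracle

    def test_clump_invariants(self, cohort):
        w, _ = prs.harmonize_alleles(cohort["sumstats"], cohort["variants"])
        cfg = prs.ClumpConfig()
        kept = prs.ld_clump(w, cohort["genotypes"], cfg)
        assert set(kept) <= set(w["variant_id"])
        sub = w.set_index("variant_id").loc[kept]
        G = cohort["genotypes"]
        for i, vi in enumerate(kept):
            for vj in kept[i + 1:]:
                same_chrom = sub.loc[vi, "chromosome"] == sub.loc[vj, "chromosome"]
                close = abs(sub.loc[vi, "position"] - sub.loc[vj, "position"]) <= 500_000
                if same_chrom and close:
                    r2 = np.corrcoef(G[vi], G[vj])[0, 1] ** 2
                    assert r2 <= cfg.r2_threshold + 1e-12


def _random_clump_instance(seed, n_variants=200, n_blocks=5, n_ref=400):
    """Shared instance builder for the clumping oracle comparison."""
    rng = np.random.default_rng(seed)
    per = n_variants // n_blocks
    ld = sc.LDBlockSpec(
        sizes=(per,) * n_blocks,
        correlations=tuple(rng.uniform(0.0, 0.95, n_blocks)),
    )
    vt = sc.make_variant_table(n_variants, seed=seed + 1000, n_chromosomes=2,
                               spacing_bp=int(rng.integers(20_000, 200_000)))
    geno = sc.simulate_genotypes(n_ref, vt, ld, seed=seed + 2000)
    w = _weights_frame([
        _w_row(vid, chrom, pos, p)
        for vid, chrom, pos, p in zip(
            vt["variant_id"], vt["chromosome"], vt["position"],
            rng.uniform(1e-10, 1.0, n_variants),
        )
    ])
    cfg = prs.ClumpConfig()
    kept = prs.ld_clump(w, geno, cfg)
    oracle = greedy_clump(
        w["p"].to_numpy(), w["chromosome"].to_numpy(), w["position"].to_numpy(),
        w["variant_id"].to_numpy(), geno[w["variant_id"]].to_numpy(dtype=float),
        cfg.r2_threshold, cfg.window_kb * 1000,
    )
    return kept, oracle


class TestComputePrs:
    def test_zero_weights_zero_scores(self):
        geno = pd.DataFrame({"v1": [0, 1, 2]}, index=["a", "b", "c"])
        w = _weights_frame([_w_row("v1", "1", 100, 0.5, weight=0.0)])
        scores = prs.compute_prs(geno, w, (1.0,))
        assert (scores["p1"] == 0).all()

    def test_single_term(self):
        geno = pd.DataFrame({"v1": [2]}, index=["a"])
        w = _weights_frame([_w_row("v1", "1", 100, 0.5, weight=np.log(2))])
        scores = prs.compute_prs(geno, w, (1.0,))
        assert scores.loc["a", "p1"] == pytest.approx(2 * np.log(2))

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        geno = pd.DataFrame(
            rng.integers(0, 3, (5, 8)),
            index=[f"s{i}" for i in range(5)],
            columns=[f"v{j}" for j in range(8)],
        )
        pvals = rng.uniform(0, 1, 8)
        weights = rng.normal(0, 0.2, 8)
        w = _weights_frame([
            _w_row(f"v{j}", "1", 100 * j, pvals[j], weight=weights[j])
            for j in range(8)
        ])
        for t in (0.3, 0.8):
            got = prs.compute_prs(geno, w, (t,))[f"p{t:g}"].to_numpy()
            exp = double_loop_prs(geno.to_numpy(dtype=float), weights, pvals, t)
            assert np.allclose(got, exp)

    def test_additive_across_thresholds(self, cohort):
        w, _ = prs.harmonize_alleles(cohort["sumstats"], cohort["variants"])
        scores = prs.compute_prs(cohort["genotypes"], w, (1e-4, 1e-2, 1.0))
        extra_1 = prs.compute_prs(
            cohort["genotypes"], w[(w["p"] > 1e-4) & (w["p"] <= 1e-2)], (1.0,)
        )["p1"]
        assert np.allclose(scores["p0.01"], scores["p0.0001"] + extra_1)

    def test_missing_dosage_mean_imputed(self):
        geno = pd.DataFrame({"v1": [np.nan, 0.0]}, index=["a", "b"])
        w = _weights_frame([_w_row("v1", "1", 100, 0.5, weight=1.0, freq=0.3)])
        scores = prs.compute_prs(geno, w, (1.0,))
        assert scores.loc["a", "p1"] == pytest.approx(0.6)

    def test_empty_threshold_list_rejected(self, cohort):
        w, _ = prs.harmonize_alleles(cohort["sumstats"], cohort["variants"])
        with pytest.raises(ValueError, match="nonempty"):
            prs.compute_prs(cohort["genotypes"], w, ())

    def test_true_weight_scores_track_genetic_liability(self):
        # no-LD configuration, weights = generating joint effects, no noise
        vt = sc.make_variant_table(40, seed=70)
        ld = sc.LDBlockSpec(sizes=(10,) * 4, correlations=(0.0,) * 4)
        model, R = sc.make_liability_model(vt, ld, seed=71)
        geno = sc.simulate_genotypes(3000, vt, ld, seed=72)
        joint = model.loadings[0] * model.factor_effects + model.specific_effects[0]
        freqs = vt["alt_frequency"].to_numpy()
        w = _weights_frame([
            _w_row(vid, chrom, pos, 0.0, weight=float(b / np.sqrt(2 * f * (1 - f))), freq=f)
            for vid, chrom, pos, b, f in zip(
                vt["variant_id"], vt["chromosome"], vt["position"], joint, freqs
            )
        ])
        score = prs.compute_prs(geno, w, (1.0,))["p1"]
        x = sc.standardize_dosages(geno, vt)
        genetic_value = x @ joint
        assert np.corrcoef(score, genetic_value)[0, 1] > 0.99


class TestStandardize:
    def test_closed_form_three_scores(self):
        scores = pd.DataFrame({"s": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        out = prs.standardize_scores(scores)
        assert np.allclose(out["s"], [-1.224744871, 0.0, 1.224744871])

    def test_groups_standardized_independently(self):
        scores = pd.DataFrame({"s": [1.0, 2.0, 11.0, 12.0]},
                              index=["a", "b", "c", "d"])
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=scores.index)
        out = prs.standardize_scores(scores, groups)
        assert out.loc[["a", "b"], "s"].mean() == pytest.approx(0.0)
        assert out.loc[["c", "d"], "s"].mean() == pytest.approx(0.0)

    def test_postconditions_random_matrix(self):
        rng = np.random.default_rng(8)
        scores = pd.DataFrame(
            rng.normal(2, 5, (1000, 3)), columns=list("xyz"),
            index=[f"s{i}" for i in range(1000)],
        )
        groups = pd.Series(rng.choice(["a", "b"], 1000), index=scores.index)
        out = prs.standardize_scores(scores, groups)
        for g in ("a", "b"):
            block = out[groups == g]
            assert np.allclose(block.mean(), 0.0, atol=1e-8)
            assert np.allclose(block.std(ddof=0), 1.0, atol=1e-8)

    def test_zero_variance_names_group_and_column(self):
        scores = pd.DataFrame({"s": [1.0, 1.0, 5.0]}, index=["a", "b", "c"])
        groups = pd.Series(["g1", "g1", "g1"], index=scores.index)
        scores["t"] = [1.0, 2.0, 3.0]
        scores.loc[:, "s"] = 1.0
        with pytest.raises(ValueError, match="g1.*s"):
            prs.standardize_scores(scores, groups)
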