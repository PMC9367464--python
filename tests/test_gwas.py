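"""GWAS stage: PLINK text I/O, QC filters, exact association, Holm."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from sequestra import gwas
from sequestra.gwas import (
    GenotypeMatrix,
    GwasDataError,
    allelic_fisher,
    genomewide_threshold,
    holm_adjust,
    manhattan_qq_tables,
    mendelian_error_count,
    read_plink_text,
    run_association,
    sample_call_rate_filter,
    subset_rerun,
    variant_filters,
    write_plink_text,
)
from sequestra.simulate import (
    SimulationConfig,
    inject_mendelian_errors,
    simulate_cohort,
    simulate_genotypes,
)


def small_gm(calls, labels=None, sires=None, dams=None):
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    samples = pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(n)],
            "label": labels or ["case"] * (n // 2) + ["control"] * (n - n // 2),
            "sire": sires or [None] * n,
            "dam": dams or [None] * n,
        }
    )
    variants = pd.DataFrame(
        {
            "chrom": ["A1"] * m,
            "pos": np.arange(1, m + 1) * 100,
            "vid": [f"v{j}" for j in range(m)],
            "allele1": ["A"] * m,
            "allele2": ["G"] * m,
        }
    )
    return GenotypeMatrix(samples, variants, calls)


# ---------------------------------------------------------------------------
# PLINK text I/O
# ---------------------------------------------------------------------------


class TestPlinkText:
    def test_basic_parse_counts_second_allele(self, tmp_path):
        (tmp_path / "x.map").write_text("A1 v1 0 100\n")
        (tmp_path / "x.ped").write_text(
            "F 1 0 0 1 2 A A\nF 2 0 0 2 1 A G\n"
        )
        gm = read_plink_text(tmp_path / "x.ped", tmp_path / "x.map")
        np.testing.assert_array_equal(gm.calls, [[0.0], [1.0]])
        assert list(gm.samples["label"]) == ["case", "control"]

    def test_missing_call(self, tmp_path):
        (tmp_path / "x.map").write_text("A1 v1 0 100\n")
        (tmp_path / "x.ped").write_text("F 1 0 0 1 2 0 0\n")
        gm = read_plink_text(tmp_path / "x.ped", tmp_path / "x.map")
        assert np.isnan(gm.calls[0, 0])

    def test_three_alleles_rejected(self, tmp_path):
        (tmp_path / "x.map").write_text("A1 v1 0 100\n")
        (tmp_path / "x.ped").write_text(
            "F 1 0 0 1 2 A A\nF 2 0 0 1 1 A G\nF 3 0 0 1 1 T T\n"
        )
        with pytest.raises(GwasDataError, match="alleles"):
            read_plink_text(tmp_path / "x.ped", tmp_path / "x.map")

    def test_field_count_mismatch(self, tmp_path):
        (tmp_path / "x.map").write_text("A1 v1 0 100\nA1 v2 0 200\n")
        (tmp_path / "x.ped").write_text("F 1 0 0 1 2 A A\n")
        with pytest.raises(GwasDataError, match="expected"):
            read_plink_text(tmp_path / "x.ped", tmp_path / "x.map")

    def test_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_dams=4, litters_per_dam_mean=2,
                               n_variants=30, genotype_missing_rate=0.05)
        cohort = simulate_cohort(cfg, seed=4, genotypes=True)
        gm = cohort.genotypes
        write_plink_text(gm, tmp_path / "p.ped", tmp_path / "p.map")
        back = read_plink_text(tmp_path / "p.ped", tmp_path / "p.map")
        assert list(back.samples["id"]) == list(gm.samples["id"])
        assert list(back.variants["vid"]) == list(gm.variants["vid"])
        # codes may flip allele orientation when allele2 is seen first;
        # compare up to the deterministic recoding 2-g
        for j in range(gm.n_variants):
            a, b = gm.calls[:, j], back.calls[:, j]
            same = np.allclose(a, b, equal_nan=True)
            flipped = np.allclose(a, 2 - b, equal_nan=True)
            assert same or flipped

    def test_duplicate_variant_ids_rejected(self):
        with pytest.raises(GwasDataError, match="duplicate"):
            small_gm(np.zeros((2, 2))).variants  # construction ok
            v = pd.DataFrame(
                {"chrom": ["A1", "A1"], "pos": [1, 2], "vid": ["v", "v"],
                 "allele1": ["A", "A"], "allele2": ["G", "G"]}
            )
            GenotypeMatrix(small_gm(np.zeros((2, 2))).samples, v,
                           np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------


class TestQc:
    def test_sample_call_rate_strict_boundary(self):
        calls = np.zeros((3, 20))
        calls[0, :2] = np.nan   # rate 0.90 -> removed
        calls[1, :1] = np.nan   # rate 0.95 -> retained (strictly below)
        gm = small_gm(calls, labels=["case", "control", "control"])
        out, rep = sample_call_rate_filter(gm, 0.95)
        assert list(out.samples["id"]) == ["s1", "s2"]
        assert rep.steps[0]["removed"] == 1

    def test_variant_boundaries_retained(self):
        # 10 samples; v0: MAF exactly 0.05 -> kept; v1: MAF 0.0 -> dropped;
        # v2: call rate exactly 0.95 equivalent impossible with 10 samples,
        # use 20 below; v3 fine
        calls = np.zeros((10, 2))
        calls[8, 0] = 1.0  # alt count 1/20 = 0.05
        gm = small_gm(calls)
        out, rep = variant_filters(gm)
        assert list(out.variants["vid"]) == ["v0"]

    def test_variant_call_rate_boundary(self):
        calls = np.tile([0.0, 1.0], (20, 1))
        calls[0, 0] = np.nan          # v0 call rate 0.95 -> retained
        calls[:2, 1] = np.nan         # v1 call rate 0.90 -> dropped
        calls[5:9, 0] = 1.0           # keep MAF clear of the boundary
        gm = small_gm(calls)
        out, _ = variant_filters(gm)
        assert "v0" in list(out.variants["vid"])
        assert "v1" not in list(out.variants["vid"])

    def test_exactly_one_mendelian_error_retained(self):
        # parent s0 is AA (0), child s1 is BB (2) at v0 -> 1 error -> kept
        calls = np.array([[0.0, 1.0], [2.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        gm = small_gm(calls, labels=["control", "case", "case", "control"],
                      sires=[None, "s0", None, None])
        errors = mendelian_error_count(gm)
        np.testing.assert_array_equal(errors, [1, 0])
        out, rep = variant_filters(gm, maf_min=0.0)
        assert out.n_variants == 2  # "more than one" error required to drop

    def test_duo_heterozygote_always_compatible(self):
        for child in (0.0, 1.0, 2.0):
            calls = np.array([[1.0], [child]])
            gm = small_gm(calls, labels=["control", "case"],
                          sires=[None, "s0"])
            assert mendelian_error_count(gm)[0] == 0

    def test_trio_homozygous_parents_het_child_is_error(self):
        calls = np.array([[0.0], [0.0], [1.0]])
        gm = small_gm(calls, labels=["control", "control", "case"],
                      sires=[None, None, "s0"], dams=[None, None, "s1"])
        assert mendelian_error_count(gm)[0] == 1

    def test_trio_enumeration_against_gamete_logic(self):
        # oracle: child code possible iff one allele from each parent
        def possible(p1, p2):
            g1 = {0: {0}, 1: {0, 1}, 2: {1}}[p1]
            g2 = {0: {0}, 1: {0, 1}, 2: {1}}[p2]
            return {a + b for a in g1 for b in g2}

        for p1 in (0, 1, 2):
            for p2 in (0, 1, 2):
                for ch in (0, 1, 2):
                    calls = np.array([[float(p1)], [float(p2)], [float(ch)]])
                    gm = small_gm(
                        calls, labels=["control", "control", "case"],
                        sires=[None, None, "s0"], dams=[None, None, "s1"],
                    )
                    expected = 0 if ch in possible(p1, p2) else 1
                    assert mendelian_error_count(gm)[0] == expected, (p1, p2, ch)

    def test_missing_calls_contribute_nothing(self):
        calls = np.array([[np.nan], [2.0]])
        gm = small_gm(calls, labels=["control", "case"], sires=[None, "s0"])
        assert mendelian_error_count(gm)[0] == 0

    def test_qc_is_fixpoint(self):
        cfg = SimulationConfig(n_dams=6, n_variants=100,
                               genotype_missing_rate=0.08)
        cohort = simulate_cohort(cfg, seed=9, genotypes=True)
        gm1, _ = sample_call_rate_filter(cohort.genotypes)
        gm2, _ = variant_filters(gm1)
        gm3, rep2 = sample_call_rate_filter(gm2)
        gm4, rep2 = variant_filters(gm3, report=rep2)
        assert gm4.n_samples == gm2.n_samples
        assert gm4.n_variants == gm2.n_variants
        assert all(s["removed"] == 0 for s in rep2.steps if s["filter"] != "combined")

    def test_planted_failures_counted(self):
        cfg = SimulationConfig(n_dams=6, n_variants=50,
                               genotype_missing_rate=0.0)
        cohort = simulate_cohort(cfg, seed=10, genotypes=True)
        gm = cohort.genotypes
        assert mendelian_error_count(gm).sum() == 0  # consistent by construction
        bad = inject_mendelian_errors(gm, variant_index=7, n_errors=2, seed=1)
        assert mendelian_error_count(bad)[7] >= 2
        out, rep = variant_filters(bad, maf_min=0.0)
        assert gm.variants["vid"][7] not in set(out.variants["vid"])


# ---------------------------------------------------------------------------
# association, Holm, thresholds, plots
# ---------------------------------------------------------------------------


class TestAssociation:
    def test_monomorphic_variant_p_one(self):
        gm = small_gm(np.zeros((10, 1)))
        res = allelic_fisher(gm)
        assert res["p_raw"][0] == 1.0
        assert res["degenerate"][0]

    def test_perfect_separation_minimum_p(self):
        calls = np.vstack([np.full((10, 1), 2.0), np.zeros((10, 1))])
        gm = small_gm(calls)
        res = allelic_fisher(gm)
        # smallest achievable p for margins 20/20 split 20:20
        import math

        p_min = 2.0 / math.comb(40, 20) * math.comb(20, 20) * math.comb(20, 0)
        assert res["p_raw"][0] == pytest.approx(p_min, rel=1e-6)

    def test_missing_labels_excluded_from_test(self):
        calls = np.array([[2.0], [2.0], [0.0], [0.0]])
        gm = small_gm(calls, labels=["case", None, "control", "control"])
        res = allelic_fisher(gm)
        assert res["case_alt"][0] == 2  # only the labelled case counted

    def test_needs_both_groups(self):
        gm = small_gm(np.zeros((4, 1)), labels=["case"] * 4)
        with pytest.raises(GwasDataError, match="case and .*control"):
            allelic_fisher(gm)


class TestHolm:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.2]), [0.2])

    def test_two_p_stepwise(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_cap_at_one_genomewide(self):
        p = np.full(37_595, 0.5)
        p[123] = 1.8e-4
        adj = holm_adjust(p)
        assert adj[123] == 1.0  # 1.8e-4 * 37595 = 6.77 -> capped

    def test_definition_oracle_on_random_vectors(self):
        def holm_by_definition(p):
            m = len(p)
            order = np.argsort(p, kind="stable")
            adj = np.empty(m)
            running = 0.0
            for k, idx in enumerate(order):
                running = max(running, (m - k) * p[idx])
                adj[idx] = min(1.0, running)
            return adj

        rng = np.random.default_rng(11)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(holm_adjust(p), holm_by_definition(p),
                                       rtol=1e-12)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(12)
        p = rng.random(500) ** 2
        ref = multipletests(p, method="holm")[1]
        np.testing.assert_allclose(holm_adjust(p), ref, rtol=1e-10)

    def test_idempotent_on_adjusted(self):
        rng = np.random.default_rng(13)
        adj = holm_adjust(rng.random(50))
        srt = np.sort(adj)
        again = np.minimum(1.0, np.maximum.accumulate(
            srt * (len(srt) - np.arange(len(srt)))))
        # an already-monotone capped vector maps onto itself only at m=1;
        # the meaningful idempotence is stability of the order and cap
        assert (holm_adjust(adj) >= adj - 1e-12).all()
        assert (holm_adjust(adj) <= 1.0).all()
        assert np.all(np.diff(np.sort(again)) >= 0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestThresholdAndTables:
    def test_bonferroni_line(self):
        assert genomewide_threshold(37_595) == pytest.approx(1.33e-6, rel=0.01)
        assert genomewide_threshold(1) == 0.05
        assert genomewide_threshold(10) == 0.005
        with pytest.raises(ValueError):
            genomewide_threshold(0)

    def test_manhattan_ordering_and_qq_quantiles(self):
        df = pd.DataFrame(
            {
                "vid": ["a", "b", "c", "d"],
                "chrom": ["B1", "A1", "B1", "A1"],
                "pos": [50, 200, 10, 100],
                "p_raw": [0.5, 0.01, 0.9, 0.3],
            }
        )
        man, qq = manhattan_qq_tables(df)
        assert list(man["vid"]) == ["d", "b", "c", "a"]  # A1 first, by pos
        assert np.all(np.diff(man["genome_pos"]) > 0)
        np.testing.assert_allclose(
            qq["expected"], -np.log10((np.arange(1, 5) - 0.5) / 4)
        )

    def test_single_variant_qq(self):
        df = pd.DataFrame(
            {"vid": ["a"], "chrom": ["X"], "pos": [1], "p_raw": [0.2]}
        )
        _, qq = manhattan_qq_tables(df)
        assert qq["expected"][0] == pytest.approx(-np.log10(0.5))


class TestNullBehaviour:
    def test_permutation_null_calibration(self):
        """Null p-values are valid (never anti-conservative) and near uniform.

        Exact conditional tests have sub-uniform, discrete null p-values —
        P(p <= t) <= t by construction — so the check is one-sided
        calibration plus a bound on the conservativeness gap, not literal
        uniformity.
        """
        rng = np.random.default_rng(20)
        n, m = 600, 2000
        maf = rng.uniform(0.1, 0.5, size=m)
        calls = rng.binomial(2, maf, size=(n, m)).astype(float)
        labels = ["case"] * 300 + ["control"] * 300
        gm = small_gm(calls, labels=labels)
        p = np.sort(allelic_fisher(gm)["p_raw"].to_numpy())
        grid = np.linspace(0.005, 1.0, 200)
        ecdf = np.searchsorted(p, grid, side="right") / m
        se3 = 3 * np.sqrt(grid * (1 - grid) / m)
        # never anti-conservative anywhere on the grid
        assert np.all(ecdf <= grid + se3)
        # and not wildly conservative: close to the diagonal overall
        assert np.max(np.abs(ecdf - grid)) < 0.12
        rate = float((p < 0.05).mean())
        assert 0.02 <= rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / m)

    def test_planted_causal_variant_tops_ranking(self):
        """A fixed-vs-intermediate causal allele (frequency difference 0.5)
        at 14 cases / 10 controls leads the ranking among 5000 null variants.

        With 48 alleles the causal p-value bottoms out near 2e-6 while the
        minimum over 5000 null exact tests is occasionally of the same order,
        so the check is: strictly smallest raw p in a clear majority of
        seeded panels and never below rank 5.
        """
        hits, ranks = 0, []
        n_seeds = 10
        for s in range(n_seeds):
            rng = np.random.default_rng(100 + s)
            m = 5000
            maf = 0.05 + 0.45 * rng.beta(1.0, 3.0, size=m)
            cases = rng.binomial(2, maf, size=(14, m)).astype(float)
            controls = rng.binomial(2, maf, size=(10, m)).astype(float)
            cases[:, 0] = rng.binomial(2, 1.0, size=14)
            controls[:, 0] = rng.binomial(2, 0.5, size=10)
            gm = small_gm(
                np.vstack([cases, controls]),
                labels=["case"] * 14 + ["control"] * 10,
            )
            p = allelic_fisher(gm)["p_raw"].to_numpy()
            ranks.append(int((p < p[0]).sum()) + 1)
            hits += int(ranks[-1] == 1)
        assert hits >= 7
        assert max(ranks) <= 5


class TestPipeline:
    def test_full_run_and_subset_identity(self):
        cfg = SimulationConfig(n_dams=8, n_variants=200,
                               genotype_missing_rate=0.02)
        cohort = simulate_cohort(cfg, seed=30, genotypes=True)
        res = run_association(cohort.genotypes)
        assert (res.table["p_holm"] >= res.table["p_raw"] - 1e-12).all()
        assert res.bonferroni == pytest.approx(0.05 / res.n_tests)
        sub_res, diff = subset_rerun(cohort.genotypes, [])
        pd.testing.assert_frame_equal(sub_res.table, res.table)

    def test_subset_cannot_empty_a_group(self):
        cfg = SimulationConfig(n_dams=6, n_variants=50)
        cohort = simulate_cohort(cfg, seed=31, genotypes=True)
        controls = cohort.genotypes.samples.loc[
            cohort.genotypes.samples["label"] == "control", "id"
        ]
        with pytest.raises(GwasDataError, match="emptied"):
            subset_rerun(cohort.genotypes, list(controls))
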