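"""Population structure: curation rules, filters, admixture EM, FST, PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from reefcore import popgen, simulate
from reefcore.popgen import (
    MISSING,
    GenotypeMatrix,
    assign_lineage,
    concordance,
    curate_microsatellites,
    estimate_admixture,
    filter_loci_samples,
    genotype_pca,
    match_labels,
    nei_fst,
)
from reefcore.simulate import PopSimSpec


def raw_calls(rows):
    return pd.DataFrame(rows, columns=["sample", "locus", "run", "allele_size", "peak_height"])


def cell_of(g, sample, locus):
    i, l = g.samples.index(sample), g.loci.index(locus)
    pair = g.calls[i, l]
    if pair[0] == MISSING:
        return None
    return sorted(g.alleles[l][a] for a in pair)


def matrix_from_pairs(pairs, n_alleles=4):
    """Build a GenotypeMatrix from a dict {(sample, locus): (a, b) or None}."""
    samples = sorted({s for s, _ in pairs})
    loci = sorted({l for _, l in pairs})
    calls = np.full((len(samples), len(loci), 2), MISSING, dtype=np.int32)
    for (s, l), pair in pairs.items():
        if pair is not None:
            calls[samples.index(s), loci.index(l)] = pair
    alleles = [list(range(n_alleles)) for _ in loci]
    return GenotypeMatrix(samples=samples, loci=loci, alleles=alleles, calls=calls)


class TestCurateMicrosatellites:
    def test_two_allele_cell_unchanged(self):
        raw = raw_calls([("s1", "L1", "r1", 150, 900.0), ("s1", "L1", "r1", 154, 850.0)])
        g = curate_microsatellites(raw)
        assert cell_of(g, "s1", "L1") == [150, 154]

    def test_singleton_across_runs_dropped(self):
        # runs {A,B,C} and {A,B} -> {A,B}
        raw = raw_calls(
            [
                ("s1", "L1", "r1", 150, 800.0),
                ("s1", "L1", "r1", 154, 700.0),
                ("s1", "L1", "r1", 158, 650.0),
                ("s1", "L1", "r2", 150, 820.0),
                ("s1", "L1", "r2", 154, 720.0),
            ]
        )
        g = curate_microsatellites(raw)
        assert cell_of(g, "s1", "L1") == [150, 154]

    def test_half_height_rule_single_run(self):
        # A(1000), B(900), C(300): 300 < 450 -> {A,B}
        raw = raw_calls(
            [
                ("s1", "L1", "r1", 150, 1000.0),
                ("s1", "L1", "r1", 154, 900.0),
                ("s1", "L1", "r1", 158, 300.0),
            ]
        )
        g = curate_microsatellites(raw)
        assert cell_of(g, "s1", "L1") == [150, 154]

    def test_equal_peaks_fall_to_frequency_rule(self):
        rows = []
        # establish dataset-wide frequencies: 150 and 154 common, 158 rare
        for i in range(5):
            rows += [(f"u{i}", "L1", "r1", 150, 900.0), (f"u{i}", "L1", "r1", 154, 900.0)]
        rows += [
            ("amb", "L1", "r1", 150, 900.0),
            ("amb", "L1", "r1", 154, 880.0),
            ("amb", "L1", "r1", 158, 870.0),
        ]
        g = curate_microsatellites(raw_calls(rows))
        assert cell_of(g, "amb", "L1") == [150, 154]

    def test_single_allele_becomes_homozygote(self):
        raw = raw_calls([("s1", "L1", "r1", 150, 900.0)])
        g = curate_microsatellites(raw)
        assert cell_of(g, "s1", "L1") == [150, 150]

    def test_idempotent(self):
        rows = []
        rng = np.random.default_rng(4)
        for i in range(12):
            for locus in ("L1", "L2"):
                k = int(rng.integers(1, 4))
                sizes = rng.choice([150, 154, 158, 162], size=k, replace=False)
                for s in sizes:
                    rows.append((f"s{i}", locus, "r1", int(s), float(rng.integers(300, 1000))))
        g1 = curate_microsatellites(raw_calls(rows))
        # re-express g1 as raw calls (one run, equal heights) and re-curate
        rows2 = []
        for s in g1.samples:
            for l in g1.loci:
                pair = cell_of(g1, s, l)
                if pair is None:
                    continue
                for a in sorted(set(pair)):
                    rows2.append((s, l, "r1", a, 500.0))
        g2 = curate_microsatellites(raw_calls(rows2))
        for s in g1.samples:
            for l in g1.loci:
                assert cell_of(g1, s, l) == cell_of(g2, s, l)


class TestFilterLociSamples:
    def test_complete_matrix_unchanged(self):
        g = matrix_from_pairs({(f"s{i}", f"L{j}"): (0, 1) for i in range(4) for j in range(3)})
        out, report = filter_loci_samples(g, min_loci_per_sample=2)
        assert out.n_samples == 4 and out.n_loci == 3
        assert report.removed_loci == [] and report.removed_samples == []

    def test_locus_then_sample_removal(self):
        pairs = {}
        for i in range(5):
            for j in range(3):
                pairs[(f"s{i}", f"L{j}")] = (0, 1)
        # L2 is 60% missing -> dropped first
        for i in (0, 1, 2):
            pairs[(f"s{i}", "L2")] = None
        # s4 then has only 1 of the remaining 2 loci
        pairs[("s4", "L0")] = None
        g = matrix_from_pairs(pairs)
        out, report = filter_loci_samples(g, max_locus_missing=0.40, min_loci_per_sample=2)
        assert [name for name, _ in report.removed_loci] == ["L2"]
        assert [name for name, _ in report.removed_samples] == ["s4"]
        assert out.loci == ["L0", "L1"]
        assert "s4" not in out.samples

    def test_counts_reconcile(self, rng):
        pairs = {}
        for i in range(20):
            for j in range(8):
                pairs[(f"s{i:02d}", f"L{j}")] = None if rng.random() < 0.3 else (0, 1)
        g = matrix_from_pairs(pairs)
        out, report = filter_loci_samples(g, max_locus_missing=0.40, min_loci_per_sample=4)
        assert len(report.removed_loci) + out.n_loci == g.n_loci
        assert len(report.removed_samples) + out.n_samples == g.n_samples

    def test_all_loci_removed_errors(self):
        pairs = {(f"s{i}", "L0"): None if i < 3 else (0, 1) for i in range(4)}
        g = matrix_from_pairs(pairs)
        with pytest.raises(ValueError, match="all loci removed"):
            filter_loci_samples(g, max_locus_missing=0.5, min_loci_per_sample=1)


class TestEstimateAdmixture:
    def test_k1_closed_form(self):
        g, _ = simulate.simulate_genotypes(PopSimSpec(K=2, n_per_pop=15, n_loci=40, seed=1))
        fit = estimate_admixture(g, K=1, n_restarts=1, seed=1)
        np.testing.assert_allclose(fit.Q, 1.0)
        X, loc = g.allele_dosage()
        observed = X.sum(axis=0)
        # observed frequencies per locus
        for l in range(g.n_loci):
            cols = np.flatnonzero(loc == l)
            np.testing.assert_allclose(
                fit.P[0, cols], observed[cols] / observed[cols].sum(), atol=1e-6
            )

    def test_loglik_monotone_and_q_simplex(self):
        g, _ = simulate.simulate_genotypes(
            PopSimSpec(K=2, n_per_pop=20, n_loci=60, missing_rate=0.1, seed=2)
        )
        fit = estimate_admixture(g, K=2, n_restarts=2, max_iter=200, seed=3)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-6 * np.abs(fit.loglik))
        np.testing.assert_allclose(fit.Q.sum(axis=1), 1.0, atol=1e-9)

    def test_two_population_recovery(self):
        g, Q = simulate.simulate_genotypes(
            PopSimSpec(K=2, divergence_F=0.5, n_per_pop=30, n_loci=200, seed=4)
        )
        fit = estimate_admixture(g, K=2, n_restarts=3, max_iter=1000, tol=1e-4, seed=5)
        perm = match_labels(fit.Q, Q)
        rmse = float(np.sqrt(np.mean((fit.Q[:, perm] - Q) ** 2)))
        assert rmse < 0.05
        assert fit.Q.max(axis=1).mean() >= 0.95

    def test_four_lineage_structure_resolved(self):
        g, Q = simulate.simulate_genotypes(
            PopSimSpec(K=4, divergence_F=0.4, n_per_pop=20, n_loci=150, seed=6)
        )
        fit = estimate_admixture(g, K=4, n_restarts=3, max_iter=1000, tol=1e-4, seed=7)
        labels = assign_lineage(fit)
        truth = pd.Series(np.repeat(list("ABCD"), 20), index=g.samples)
        frac, _, _ = concordance(labels, truth)
        assert frac > 0.95

    def test_multiallelic_markers_supported(self):
        g, Q = simulate.simulate_genotypes(
            PopSimSpec(K=2, divergence_F=0.4, n_per_pop=25, n_loci=40, n_alleles=6, seed=8)
        )
        fit = estimate_admixture(g, K=2, n_restarts=2, max_iter=500, tol=1e-4, seed=9)
        perm = match_labels(fit.Q, Q)
        assert np.sqrt(np.mean((fit.Q[:, perm] - Q) ** 2)) < 0.1


class TestAssignLineage:
    @pytest.fixture
    def fit(self):
        Q = np.array([
            [1.0, 0.0, 0.0, 0.0],
            [0.6, 0.3, 0.05, 0.05],
            [0.4, 0.3, 0.2, 0.1],
        ])
        return popgen.AncestryMatrix(
            samples=["a", "b", "c"], Q=Q, P=np.ones((4, 2)) / 2, K=4,
            locus_of_col=np.zeros(2, dtype=int), loglik=0.0,
            loglik_trace=np.zeros(1), converged=True, n_restarts=1, seed=None,
        )

    def test_majority_rule(self, fit):
        labels = assign_lineage(fit, names=["DB", "LB", "PI", "RD"])
        assert labels.tolist() == ["DB", "DB", "admixed"]

    def test_threshold_strictness(self, fit):
        labels = assign_lineage(fit, threshold=0.6)
        assert labels.tolist() == ["L1", "admixed", "admixed"]


class TestConcordance:
    def test_identical_labelings(self):
        a = pd.Series(["x", "y", "x"], index=["1", "2", "3"])
        frac, _, n_adm = concordance(a, a.copy())
        assert frac == 1.0 and n_adm == 0

    def test_permuted_names_score_perfectly(self):
        idx = [f"s{i}" for i in range(40)]
        rng = np.random.default_rng(11)
        a = pd.Series(rng.choice(list("ABCD"), 40), index=idx)
        rename = {"A": "w", "B": "x", "C": "y", "D": "z"}
        b = a.map(rename)
        frac, mapping, _ = concordance(a, b)
        # exhaustive-permutation oracle over all 4! relabelings
        best = max(
            float(np.mean([perm[b_lab] == a_lab for a_lab, b_lab in zip(a, b)]))
            for perm in (
                dict(zip("wxyz", p)) for p in itertools.permutations("ABCD")
            )
        )
        assert best == 1.0
        assert frac == best
        assert mapping == {v: k for k, v in rename.items()}

    def test_admixed_excluded(self):
        a = pd.Series(["x", "x", "admixed", "y"], index=list("abcd"))
        b = pd.Series(["x", "y", "x", "y"], index=list("abcd"))
        frac, _, n_adm = concordance(a, b)
        assert n_adm == 1
        assert frac == pytest.approx(2 / 3)

    def test_disjoint_sets_rejected(self):
        a = pd.Series(["x"], index=["1"])
        b = pd.Series(["x"], index=["2"])
        with pytest.raises(ValueError, match="overlap"):
            concordance(a, b)


def hand_fst(g, idx_a, idx_b):
    """Independent small-instance Nei FST oracle: explicit per-locus loops
    with the sample-size corrections written out longhand."""
    hs_sum = ht_sum = 0.0
    for l in range(g.n_loci):
        freqs, sizes = {}, {}
        for label, idx in (("a", idx_a), ("b", idx_b)):
            alleles = []
            n_geno = 0
            for i in idx:
                pair = g.calls[i, l]
                if pair[0] != MISSING:
                    alleles += [pair[0], pair[1]]
                    n_geno += 1
            if not alleles:
                return None
            freq = np.zeros(len(g.alleles[l]))
            for a in alleles:
                freq[a] += 1
            freqs[label] = freq / freq.sum()
            sizes[label] = n_geno
        pbar = (freqs["a"] + freqs["b"]) / 2
        if pbar.max() >= 1 - 1e-12:
            continue
        h_a = (1 - (freqs["a"] ** 2).sum()) * 2 * sizes["a"] / (2 * sizes["a"] - 1)
        h_b = (1 - (freqs["b"] ** 2).sum()) * 2 * sizes["b"] / (2 * sizes["b"] - 1)
        hs = (h_a + h_b) / 2
        n_harm = 2 / (1 / sizes["a"] + 1 / sizes["b"])
        hs_sum += hs
        ht_sum += 1 - (pbar**2).sum() + hs / (4 * n_harm)
    return 0.0 if ht_sum == 0 else 1 - hs_sum / ht_sum


class TestNeiFst:
    def test_fixed_difference_gives_one(self):
        # group A fixed for allele 0, group B fixed for allele 1: Hs=0, Ht=0.5
        pairs = {}
        for i in range(3):
            pairs[(f"a{i}", "L0")] = (0, 0)
            pairs[(f"b{i}", "L0")] = (1, 1)
        g = matrix_from_pairs(pairs, n_alleles=2)
        groups = pd.Series(
            ["A"] * 3 + ["B"] * 3, index=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
        )
        fst = nei_fst(g, groups, n_boot=10, seed=1)
        assert fst.as_frame().loc["A", "B"] == pytest.approx(1.0)

    def test_null_groups_near_zero(self):
        g, _ = simulate.simulate_genotypes(
            PopSimSpec(K=1, divergence_F=0.3, n_per_pop=60, n_loci=200, seed=12)
        )
        half = pd.Series(["A"] * 30 + ["B"] * 30, index=g.samples)
        fst = nei_fst(g, half, n_boot=100, seed=13)
        i, j = fst.labels.index("A"), fst.labels.index("B")
        assert abs(fst.fst[i, j]) < 0.01
        assert fst.ci_low[i, j] <= 0.005

    def test_matches_hand_oracle_exactly_on_small_instances(self, rng):
        for trial in range(20):
            n_loci = int(rng.integers(1, 6))
            pairs = {}
            for i in range(8):
                for l in range(n_loci):
                    if rng.random() < 0.15:
                        pairs[(f"s{i}", f"L{l}")] = None
                    else:
                        pairs[(f"s{i}", f"L{l}")] = tuple(sorted(rng.integers(0, 3, 2)))
            g = matrix_from_pairs(pairs, n_alleles=3)
            groups = pd.Series(["A"] * 4 + ["B"] * 4, index=[f"s{i}" for i in range(8)])
            expected = hand_fst(g, range(4), range(4, 8))
            if expected is None:
                continue
            fst = nei_fst(g, groups, n_boot=5, seed=trial)
            i, j = fst.labels.index("A"), fst.labels.index("B")
            assert fst.fst[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetry_diagonal_and_range(self):
        g, _ = simulate.simulate_genotypes(
            PopSimSpec(K=3, divergence_F=0.3, n_per_pop=15, n_loci=80, seed=14)
        )
        groups = pd.Series(np.repeat(list("ABC"), 15), index=g.samples)
        fst = nei_fst(g, groups, n_boot=20, seed=15)
        np.testing.assert_array_equal(fst.fst, fst.fst.T)
        assert np.all(np.diag(fst.fst) == 0)
        assert np.all((fst.fst >= 0) & (fst.fst <= 1))

    def test_bootstrap_deterministic_under_seed(self):
        g, _ = simulate.simulate_genotypes(
            PopSimSpec(K=2, divergence_F=0.3, n_per_pop=10, n_loci=50, seed=16)
        )
        groups = pd.Series(["A"] * 10 + ["B"] * 10, index=g.samples)
        f1 = nei_fst(g, groups, n_boot=50, seed=17)
        f2 = nei_fst(g, groups, n_boot=50, seed=17)
        np.testing.assert_array_equal(f1.ci_low, f2.ci_low)


class TestGenotypePca:
    def test_diverged_populations_separate_on_pc1(self):
        g, _ = simulate.simulate_genotypes(
            PopSimSpec(K=2, divergence_F=0.5, n_per_pop=25, n_loci=150, seed=18)
        )
        res = genotype_pca(g)
        pc1 = res.coords[:, 0]
        a, b = pc1[:25], pc1[25:]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or max(b.min(), a.min()) > min(
            b.max(), a.max()
        )  # no overlap between the two clusters

    def test_duplicated_individuals_identical_coords(self):
        g, _ = simulate.simulate_genotypes(
            PopSimSpec(K=2, divergence_F=0.3, n_per_pop=6, n_loci=30, seed=19)
        )
        calls = np.concatenate([g.calls, g.calls[:1]], axis=0)
        g2 = GenotypeMatrix(
            samples=g.samples + ["dup"], loci=g.loci, alleles=g.alleles, calls=calls
        )
        res = genotype_pca(g2)
        np.testing.assert_allclose(res.coords[0], res.coords[-1], atol=1e-8)

    def test_explained_variance_fractions_valid(self):
        g, _ = simulate.simulate_genotypes(
            PopSimSpec(K=3, divergence_F=0.3, n_per_pop=10, n_loci=60, seed=20)
        )
        res = genotype_pca(g)
        evr = res.explained_variance_ratio
        assert evr.sum() <= 1.0 + 1e-9
        assert np.all(np.diff(evr) <= 1e-12)
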