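import math

import numpy as np
import pandas as pd
import pytest

from gchapkit.gchap_core import build_gchaps
from gchapkit.trait_assoc import (
    duncan_mrt,
    hap_trait_assoc,
    ld_half_decay,
    oneway_anova,
)
from gchapkit.io_genomics import PopulationLabels

import oracles
from conftest import make_matrix


class TestOnewayAnova:
    def test_hand_decomposition(self):
        res = oneway_anova([0, 1, 2, 3], ["a", "a", "b", "b"])
        assert res.f == pytest.approx(8.0)
        assert res.df_between == 1 and res.df_error == 2
        assert res.mse == pytest.approx(0.5)

    def test_exact_rational_value(self):
        from fractions import Fraction

        assert oracles.exact_f_ratio([[0, 1], [2, 3]]) == Fraction(8)

    def test_identical_groups_f_zero(self):
        res = oneway_anova([1.0, 2.0, 1.0, 2.0], ["a", "a", "b", "b"])
        assert res.f == pytest.approx(0.0, abs=1e-12)

    def test_zero_within_variance_guarded(self):
        res = oneway_anova([1, 1, 1, 5, 5, 5], ["a", "a", "a", "b", "b", "b"])
        assert math.isinf(res.f)
        assert res.p_value < 1e-300

    def test_small_group_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            res = oneway_anova(
                [0, 1, 2, 3, 9], ["a", "a", "b", "b", "c"]
            )
        assert res.df_error == 2

    def test_fewer_than_two_groups_errors(self):
        with pytest.raises(ValueError):
            oneway_anova([1, 2, 3], ["a", "a", "a"])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_scipy_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        labels, values = [], []
        for g in range(k):
            n = int(rng.integers(2, 11))
            labels += [f"g{g}"] * n
            values += rng.normal(g * 0.3, 1.0, size=n).tolist()
        res = oneway_anova(values, labels)
        f_o, p_o, mse_o, df_o = oracles.bf_anova(values, labels)
        assert res.f == pytest.approx(f_o, rel=1e-9)
        assert res.p_value == pytest.approx(p_o, rel=1e-9, abs=1e-12)
        assert res.mse == pytest.approx(mse_o, rel=1e-9)
        assert res.df_error == df_o


class TestDuncanMrt:
    def test_all_equal_means_share_a_letter(self):
        letters = duncan_mrt({"h1": 5.0, "h2": 5.0, "h3": 5.0},
                             {"h1": 10, "h2": 10, "h3": 10}, 1.0, 27)
        assert set(letters.values()) == {"a"}

    def test_extreme_separation_distinct_letters(self):
        letters = duncan_mrt({"h1": 0.0, "h2": 100.0},
                             {"h1": 10, "h2": 10}, 1.0, 18)
        assert letters["h1"] != letters["h2"]
        assert set("".join(letters.values())) == {"a", "b"}

    def test_single_group(self):
        assert duncan_mrt({"h1": 3.0}, {"h1": 5}, 1.0, 4) == {"h1": "a"}

    def test_df_error_validated(self):
        with pytest.raises(ValueError):
            duncan_mrt({"a": 1.0, "b": 2.0}, {"a": 3, "b": 3}, 1.0, 0)

    def test_relabeling_invariance(self):
        means = {"x": 1.0, "y": 3.5, "z": 3.6}
        ns = {"x": 8, "y": 8, "z": 8}
        l1 = duncan_mrt(means, ns, 1.2, 21)
        perm = {"z": "x", "x": "y", "y": "z"}
        l2 = duncan_mrt({perm[g]: m for g, m in means.items()},
                        {perm[g]: n for g, n in ns.items()}, 1.2, 21)
        for g in means:
            same1 = {h for h in means if set(l1[g]) & set(l1[h])}
            same2 = {perm[h] for h in means
                     if set(l2[perm[g]]) & set(l2[perm[h]])}
            assert {perm[x] for x in same1} == same2

    @pytest.mark.parametrize("seed", range(12))
    def test_letters_consistent_with_exhaustive_stretch_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 7))
        means = rng.normal(0, 1.5, size=k)
        ns = rng.integers(3, 20, size=k)
        mse = float(rng.uniform(0.3, 3.0))
        # a few fixed error-df values so the cached quantiles are reused
        df_e = int(rng.choice([20, 60]))
        letters = duncan_mrt(
            {f"g{i}": float(means[i]) for i in range(k)},
            {f"g{i}": int(ns[i]) for i in range(k)}, mse, df_e,
        )
        sig = oracles.bf_duncan_significant(means, ns, mse, df_e, 0.05)
        for i in range(k):
            for j in range(i + 1, k):
                share = bool(set(letters[f"g{i}"]) & set(letters[f"g{j}"]))
                is_sig = (i, j) in sig or (j, i) in sig
                assert share != is_sig, (
                    f"pair g{i},g{j}: share={share} sig={is_sig}"
                )


class TestHapTraitAssoc:
    def _census(self, sizes):
        rows = []
        for h, n in enumerate(sizes):
            vec = [0] * (len(sizes) - 1)
            if h > 0:
                vec[h - 1] = 1
            rows += [vec] * n
        sites, gm = make_matrix(np.array(rows, dtype=np.int16))
        return build_gchaps(sites, gm), gm.accessions

    def test_planted_effect_detected_and_lettered(self):
        rng = np.random.default_rng(0)
        census, accs = self._census([80, 80])
        hap_of = census.hap_of()
        y = {
            a: rng.normal(2.0 if hap_of[a] == "Hap2" else 0.0, 1.0)
            for a in accs
        }
        pheno = pd.DataFrame({"trait": pd.Series(y)})
        (res,) = hap_trait_assoc(census, pheno, min_carriers=50)
        assert res.p_value < 1e-4
        assert res.letters["Hap1"] != res.letters["Hap2"]

    def test_single_major_hap_skipped(self):
        census, accs = self._census([100, 10])
        pheno = pd.DataFrame(
            {"trait": pd.Series({a: 1.0 for a in accs})}
        )
        assert hap_trait_assoc(census, pheno, min_carriers=50) == []

    def test_two_way_subpopulation_factor(self):
        rng = np.random.default_rng(1)
        census, accs = self._census([100, 100])
        hap_of = census.hap_of()
        labels = PopulationLabels(
            {a: ("XI" if i % 2 else "GJ", "LAN")
             for i, a in enumerate(accs)}
        )
        y = {
            a: rng.normal(
                (1.5 if hap_of[a] == "Hap2" else 0.0)
                + (1.0 if labels.subpopulation(a) == "GJ" else 0.0),
                1.0,
            )
            for a in accs
        }
        pheno = pd.DataFrame({"t": pd.Series(y)})
        (res,) = hap_trait_assoc(
            census, pheno, labels, min_carriers=50, two_way=True
        )
        assert res.factor_p is not None
        assert res.factor_p["hap"] < 1e-4
        assert res.factor_p["subpop"] < 1e-3


class TestLdHalfDecay:
    def test_duplicated_site_perfect_r2(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 2, size=60).astype(np.int16)
        sites, gm = make_matrix(np.column_stack([col, col]))
        decay = ld_half_decay(gm, bin_bp=100)
        assert decay.r2[0] == pytest.approx(1.0)

    def test_independent_sites_mean_r2_near_reciprocal_n(self):
        rng = np.random.default_rng(3)
        n = 400
        calls = rng.integers(0, 2, size=(n, 30)).astype(np.int16)
        sites, gm = make_matrix(calls)
        decay = ld_half_decay(gm, bin_bp=10_000)
        # E[r^2] under independence is ~1/n
        assert decay.r2.mean() == pytest.approx(1.0 / n, rel=0.5)

    def test_exponential_decay_half_life_recovered(self):
        rng = np.random.default_rng(4)
        half_life = 5_000.0
        spacing, n_sites, n_acc = 500, 30, 400
        rho_step = math.exp(-spacing * math.log(2) / (2 * half_life))
        flip = (1 - rho_step) / 2

        def haplotype():
            h = np.empty(n_sites, dtype=np.int16)
            h[0] = rng.integers(0, 2)
            for j in range(1, n_sites):
                h[j] = h[j - 1] ^ (rng.random() < flip)
            return h

        geno = np.array(
            [haplotype() & haplotype() | (haplotype() * 0) for _ in range(n_acc)]
        )
        # inbred panel: one haplotype per accession, homozygous
        geno = np.array([haplotype() for _ in range(n_acc)], dtype=np.int16)
        sites, gm = make_matrix(geno)
        # positions from make_matrix are 10 bp apart; rebuild with spacing
        positions = np.arange(n_sites) * spacing
        bin_bp = 1000
        decay = ld_half_decay(gm, positions=positions, bin_bp=bin_bp)
        # expected profile: r2(d) = exp(-d ln2 / half_life)
        exp_bins = {}
        for i in range(n_sites):
            for j in range(i + 1, n_sites):
                d = abs(positions[j] - positions[i])
                exp_bins.setdefault(int(d // bin_bp), []).append(
                    math.exp(-d * math.log(2) / half_life)
                )
        mids = sorted(exp_bins)
        means = [np.mean(exp_bins[b]) for b in mids]
        half = max(means) / 2
        expected_mid = next(
            (b + 0.5) * bin_bp for b, m in zip(mids, means) if m <= half
        )
        assert abs(decay.half_decay_distance - expected_mid) <= bin_bp

    def test_needs_two_sites(self):
        sites, gm = make_matrix(np.zeros((10, 1), dtype=np.int16))
        with pytest.raises(ValueError):
            ld_half_decay(gm)
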