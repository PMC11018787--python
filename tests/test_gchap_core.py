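import numpy as np
import pytest

from gchapkit.gchap_core import (
    SaturationError,
    build_gchaps,
    kaks_ng86,
    major_haps,
    pav_summary,
    population_partition,
    shannon_equitability,
)
from gchapkit.io_genomics import HET, MISSING, PopulationLabels

import oracles
from conftest import make_matrix


class TestBuildGchaps:
    def test_identical_allele_strings_collapse(self):
        sites, gm = make_matrix([[0, 0], [0, 0], [0, 1]])
        c = build_gchaps(sites, gm)
        assert c.gchapn == 2
        assert c.haps[0].count == 2
        assert c.haps[0].hap_name == "Hap1"

    def test_het_policies(self):
        sites, gm = make_matrix([[0, 0], [0, 0], [HET, 1]])
        dropped = build_gchaps(sites, gm, "drop")
        assert dropped.n_excluded == 1
        assert dropped.gchapn == 1
        imputed = build_gchaps(sites, gm, "major")
        assert imputed.n_excluded == 0
        # HET at site 0 replaced by the majority allele 0
        assert imputed.gchapn == 2
        as_ref = build_gchaps(sites, gm, "as_ref")
        assert as_ref.haps[1].alleles == (0, 1)

    def test_zero_sites_gives_single_monomorphic_hap(self):
        sites, gm = make_matrix(np.empty((10, 0)))
        c = build_gchaps(sites, gm)
        assert c.gchapn == 1
        assert c.haps[0].count == 10
        assert c.e_h == 0.0

    def test_missing_always_excluded_under_drop(self):
        sites, gm = make_matrix([[0], [MISSING], [1]])
        c = build_gchaps(sites, gm)
        assert c.n_excluded == 1
        assert c.n_classified == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_grouping(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 51), rng.integers(1, 21)
        calls = rng.choice(
            [0, 1, 2, HET, MISSING], size=(n, m), p=[0.5, 0.25, 0.1, 0.1, 0.05]
        ).astype(np.int16)
        sites, gm = make_matrix(calls)
        c = build_gchaps(sites, gm)
        assert sorted(c.counts.tolist(), reverse=True) == oracles.bf_gchap_counts(
            calls
        )
        # conservation: carriers + excluded = accessions
        assert c.counts.sum() + c.n_excluded == n
        carriers = [a for h in c.haps for a in h.carriers]
        assert len(carriers) == len(set(carriers))


class TestShannonEquitability:
    def test_monomorphic_is_zero(self):
        assert shannon_equitability([100]) == 0.0

    def test_uniform_is_one(self):
        assert shannon_equitability([50, 50]) == pytest.approx(1.0)

    def test_60_40_value(self):
        assert shannon_equitability([60, 40]) == pytest.approx(
            0.97095, abs=1e-5
        )

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError):
            shannon_equitability([10, 0])

    @pytest.mark.parametrize("seed", range(5))
    def test_invariances(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 100, size=rng.integers(2, 8))
        e = shannon_equitability(counts)
        assert e == pytest.approx(
            shannon_equitability(rng.permutation(counts))
        )
        assert e == pytest.approx(shannon_equitability(counts * 7))
        assert 0.0 <= e <= 1.0
        # equal counts maximise E_H at 1
        e_uniform = shannon_equitability([5] * len(counts))
        assert e_uniform == pytest.approx(1.0)
        assert e <= e_uniform + 1e-12


class TestMajorHaps:
    def test_threshold_50(self):
        sites, gm = make_matrix(
            [[0]] * 60 + [[1]] * 50 + [[HET]] * 0 + [[2]] * 49
        )
        c = build_gchaps(sites, gm)
        names = [h.hap_name for h in major_haps(c, 50)]
        assert names == ["Hap1", "Hap2"]

    def test_threshold_one_keeps_all(self):
        sites, gm = make_matrix([[0], [1], [2]])
        c = build_gchaps(sites, gm)
        assert len(major_haps(c, 1)) == 3

    def test_empty_when_all_below(self):
        sites, gm = make_matrix([[0], [1]])
        c = build_gchaps(sites, gm)
        assert major_haps(c, 50) == []


class TestPopulationPartition:
    def make(self):
        sites, gm = make_matrix([[0]] * 5 + [[1]] * 3 + [[2]] * 2)
        census = build_gchaps(sites, gm)
        # acc000..004 -> XI, acc005..007 -> GJ, acc008..009 -> XI
        labels = PopulationLabels(
            {
                f"acc{i:03d}": ("XI" if i < 5 or i >= 8 else "GJ", "LAN")
                for i in range(10)
            }
        )
        return census, labels

    def test_unique_haps(self):
        census, labels = self.make()
        part = population_partition(census, labels)
        assert part.unique["XI"] == ["Hap1", "Hap3"]
        assert part.unique["GJ"] == ["Hap2"]

    def test_predominant_tie_breaks_to_lower_hap_index(self):
        sites, gm = make_matrix([[0]] * 3 + [[1]] * 3)
        census = build_gchaps(sites, gm)
        labels = PopulationLabels(
            {f"acc{i:03d}": ("XI", "LAN") for i in range(6)}
        )
        part = population_partition(census, labels)
        assert part.predominant == "Hap1"


class TestPavSummary:
    def test_core_flag_and_frequencies(self):
        import pandas as pd

        presence = pd.DataFrame(
            [[1, 1, 1, 1], [1, 0, 1, 1], [0, 0, 0, 0]],
            index=["gCore", "gPart", "gAbsent"],
            columns=["a1", "a2", "a3", "a4"],
        )
        labels = PopulationLabels(
            {"a1": ("XI", "LAN"), "a2": ("GJ", "LAN"),
             "a3": ("GJ", "MV"), "a4": ("XI", "MV")}
        )
        out = pav_summary(presence, labels)
        assert bool(out.loc["gCore", "core"])
        assert not bool(out.loc["gPart", "core"])
        assert out.loc["gPart", "freq_GJ"] == pytest.approx(0.5)
        assert out.loc["gAbsent", "presence_freq"] == 0.0

    def test_non_binary_entry_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            pav_summary(pd.DataFrame([[0, 2]]))


class TestKaKsNg86:
    def test_identical_sequences_ratio_undefined(self):
        res = kaks_ng86("ATGAAAGGG", "ATGAAAGGG")
        assert res.ka == 0.0 and res.ks == 0.0 and res.ratio is None

    def test_single_synonymous_codon_saturates(self):
        # TTT->TTC is synonymous; with S = 1/3 sites, ps = 3 >= 3/4
        with pytest.raises(SaturationError, match="synonymous"):
            kaks_ng86("TTT", "TTC")

    def test_length_validation(self):
        with pytest.raises(ValueError):
            kaks_ng86("ATGA", "ATGA")
        with pytest.raises(ValueError):
            kaks_ng86("ATG", "ATGATG")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_oracle_on_random_pairs(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b = _random_cds_pair(rng, n_codons=300, sub_rate=0.02)
        res = kaks_ng86(a, b)
        ka_o, ks_o = oracles.bf_ng86(a, b)
        assert res.ka == pytest.approx(ka_o, rel=1e-9, abs=1e-12)
        assert res.ks == pytest.approx(ks_o, rel=1e-9, abs=1e-12)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(7)
        a, b = _random_cds_pair(rng, n_codons=100, sub_rate=0.05)
        r1, r2 = kaks_ng86(a, b), kaks_ng86(b, a)
        assert r1.ka == pytest.approx(r2.ka)
        assert r1.ks == pytest.approx(r2.ks)


def _random_cds_pair(rng, n_codons=100, sub_rate=0.02):
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in stops:
            codons.append(c)
    a = "".join(codons)
    b = list(a)
    for i in rng.choice(len(b), size=max(1, int(sub_rate * len(b))),
                        replace=False):
        b[i] = rng.choice([x for x in "ACGT" if x != b[i]])
    b = "".join(b)
    # repair any stop codons introduced
    fixed = []
    for j in range(0, len(b), 3):
        c = b[j : j + 3]
        fixed.append(a[j : j + 3] if c in stops else c)
    return a, "".join(fixed)
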