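import hashlib

import pytest

from gchapkit.gchap_core import build_gchaps, major_haps
from gchapkit.hap_network import build_msn
from gchapkit.breeding_shift import emergent_haps
from gchapkit.cre_scan import load_motif_table, scan_promoter
from gchapkit.synthetic_data import (
    FIXTURES,
    MotifPlant,
    SimConfig,
    SimConfigError,
    simulate_matrices,
    simulate_panel,
    write_fixture,
)


def sha(path):
    return hashlib.sha256(path.read_bytes()).hexdigest()


class TestConfigValidation:
    def test_infeasible_haplotype_count_rejected(self):
        with pytest.raises(SimConfigError, match="segregating"):
            SimConfig(cds_codons=2, k_haps=6)

    def test_rate_bounds_checked(self):
        with pytest.raises(SimConfigError):
            SimConfig(shift_delta=1.5)

    def test_unknown_fixture_lists_registry(self, tmp_path):
        with pytest.raises(KeyError, match="tiny"):
            write_fixture("nope", tmp_path)

    def test_plant_gene_index_checked(self):
        with pytest.raises(SimConfigError):
            SimConfig(n_genes=1, motif_plants=(MotifPlant("MYB", (3,)),))


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = FIXTURES["tiny"]
        p1, _ = simulate_panel(cfg, tmp_path / "a")
        p2, _ = simulate_panel(cfg, tmp_path / "b")
        for key in p1:
            assert sha(p1[key]) == sha(p2[key]), key

    def test_different_seed_changes_genotypes(self, tmp_path):
        import dataclasses

        cfg = FIXTURES["tiny"]
        p1, _ = simulate_panel(cfg, tmp_path / "a")
        p2, _ = simulate_panel(
            dataclasses.replace(cfg, seed=cfg.seed + 1), tmp_path / "c"
        )
        assert sha(p1["vcf"]) != sha(p2["vcf"])


@pytest.fixture(scope="module")
def noiseless():
    return simulate_matrices(FIXTURES["shifted"])


class TestTruthRoundTrip:
    def test_census_recovers_truth_haplotype_strings(self, noiseless):
        per_gene, labels, pheno, truth = noiseless
        for gid, (sites, gm) in per_gene.items():
            census = build_gchaps(sites, gm)
            gt = truth.genes[gid]
            realized = {}
            for acc, lab in gt.assignments.items():
                realized[gt.hap_alleles[lab]] = (
                    realized.get(gt.hap_alleles[lab], 0) + 1
                )
            observed = {h.alleles: h.count for h in census.haps}
            assert observed == realized

    def test_emergent_report_matches_truth(self, noiseless):
        per_gene, labels, _pheno, truth = noiseless
        for gid, (sites, gm) in per_gene.items():
            census = build_gchaps(sites, gm)
            gt = truth.genes[gid]
            vec_of = {h.hap_name: h.alleles for h in census.haps}
            rep = emergent_haps(census, labels)
            emergent_vecs = {gt.hap_alleles[e] for e in gt.emergent}
            for sp in ("XI", "GJ"):
                listed = {vec_of[e.hap_name] for e in rep.by_subpop[sp]}
                # every truth-emergent hap realized in this subpop's MV
                # class must be listed; no LAN-carried hap may be
                realized_mv = {
                    gt.hap_alleles[lab]
                    for acc, lab in gt.assignments.items()
                    if labels.subpopulation(acc) == sp
                    and labels.breeding_class(acc) == "MV"
                }
                realized_lan = {
                    gt.hap_alleles[lab]
                    for acc, lab in gt.assignments.items()
                    if labels.subpopulation(acc) == sp
                    and labels.breeding_class(acc) == "LAN"
                }
                assert listed == realized_mv - realized_lan
                assert emergent_vecs & realized_lan == set()

    def test_msn_recovers_star_genealogy(self, noiseless):
        per_gene, _labels, _pheno, truth = noiseless
        for gid, (sites, gm) in per_gene.items():
            census = build_gchaps(sites, gm)
            gt = truth.genes[gid]
            majors = major_haps(census, 10)
            if len(majors) < 3:
                continue
            net = build_msn(majors)
            predominant_vec = gt.hap_alleles["H1"]
            center = next(
                h.hap_name for h in majors if h.alleles == predominant_vec
            )
            # star: every edge touches the predominant haplotype
            assert all(
                center in (e.hap_a, e.hap_b) for e in net.edges
            ), gid
            assert all(e.in_mst for e in net.edges)

    def test_frequencies_converge_to_design(self):
        cfg = SimConfig(
            n_genes=1, cds_codons=30, k_haps=4, freq_decay=0.5,
            n_lan_xi=10_000, n_mv_xi=0, n_lan_gj=0, n_mv_gj=0,
            shift_delta=0.0, emergent_prob=0.0, private_hap_fraction=0.0,
            het_rate=0.0, missing_rate=0.0, n_promoter_accessions=0,
            motif_plants=(), seed=13,
        )
        per_gene, _labels, _pheno, truth = simulate_matrices(cfg)
        (sites, gm) = per_gene["G001"]
        census = build_gchaps(sites, gm)
        gt = truth.genes["G001"]
        freq_design = gt.class_freqs["XI/LAN"]
        by_vec = {gt.hap_alleles[lab]: f for lab, f in freq_design.items()}
        for h in census.haps:
            assert h.count / census.n_classified == pytest.approx(
                by_vec[h.alleles], abs=0.01
            )

    def test_phenotype_effects_recorded_in_truth(self, noiseless):
        _per_gene, _labels, pheno, truth = noiseless
        for trait, (gid, beta) in truth.trait_effects.items():
            assert trait in pheno.columns
            assert gid in truth.genes
            assert beta["H1"] == 0.0


class TestPlantedMotifs:
    def test_planted_counts_recovered_exactly(self, tmp_path):
        paths, truth = write_fixture("cre-plant", tmp_path)
        motifs = {m.name: m for m in load_motif_table()}
        from pyfaidx import Fasta

        fa = Fasta(str(paths["promoters"]))
        labels_of = {}
        for line in paths["labels"].read_text().splitlines()[1:]:
            acc, sub, cls = line.split("\t")
            labels_of[acc] = sub
        for (gid, motif_name), expected in truth.plant_expected.items():
            target_pops = set(truth.plant_pops[(gid, motif_name)])
            m = motifs[motif_name]
            for name in fa.keys():
                g, acc = name.split("|", 1)
                if g != gid:
                    continue
                seq = str(fa[name][:])
                count = scan_promoter(seq, [m])[motif_name]
                want = expected if labels_of[acc] in target_pops else 0
                assert count == want, (gid, motif_name, acc)

    def test_planted_coordinates_are_the_only_matches(self, tmp_path):
        paths, truth = write_fixture("cre-plant", tmp_path)
        from pyfaidx import Fasta

        from gchapkit.cre_scan import scan_with_coords

        motifs = {m.name: m for m in load_motif_table()}
        fa = Fasta(str(paths["promoters"]))
        labels_of = {
            line.split("\t")[0]: line.split("\t")[1]
            for line in paths["labels"].read_text().splitlines()[1:]
        }
        for (gid, motif_name), coords in truth.plant_coords.items():
            m = motifs[motif_name]
            pops = set(truth.plant_pops[(gid, motif_name)])
            for name in fa.keys():
                g, acc = name.split("|", 1)
                if g != gid or labels_of[acc] not in pops:
                    continue
                hits = scan_with_coords(str(fa[name][:]), [m])[motif_name]
                starts = {h[0] for h in hits}
                assert starts == set(coords), (gid, motif_name)


class TestFixtures:
    def test_tiny_runs_end_to_end_quickly(self, tiny_matrices):
        per_gene, labels, pheno, truth = tiny_matrices
        assert len(per_gene) == 2
        assert len(pheno) == 12

    def test_null_fixture_has_no_shift_or_effects(self):
        cfg = FIXTURES["null"]
        assert cfg.shift_delta == 0.0
        assert cfg.hap_effect_sd == 0.0
        per_gene, _labels, _pheno, truth = simulate_matrices(cfg)
        for gt in truth.genes.values():
            assert gt.delta == {"XI": 0.0, "GJ": 0.0}
            assert gt.emergent == ()
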