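"""Truth-tagged synthetic multi-population rice-like panels.

Generates a complete input set — VCF of CDS SNPs, GFF3 gene models,
FASTA contigs with promoters, population labels, phenotypes and
per-accession promoter sequences with planted motifs — whose
statistical structure matches what the gcHap analyses assume: a skewed
haplotype frequency spectrum per gene, a configurable drop of the
predominant haplotype in modern varieties, haplotypes emerging only in
modern varieties, subspecies-private haplotypes, haplotype-linked
phenotype effects, and promoters whose only motif matches are the
planted ones.

Haplotypes sit on a star genealogy: the predominant haplotype H1 is
the all-reference vector and each derived haplotype Hj carries j - 1
private mutations, so every pairwise Hamming distance and the expected
minimum-spanning-network topology (a star centred on H1) are known
analytically.  Heterozygous/missing corruption is applied after
haplotype assignment, so the truth census stays well defined.

No coalescent realism (recombination, demography) is attempted; the
generator targets the structure the statistics assume.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cre_scan import MotifDef, load_motif_table, scan_promoter
from .io_genomics import (
    HET,
    MISSING,
    GeneModel,
    GenotypeMatrix,
    PopulationLabels,
    Site,
    SiteSet,
    revcomp,
)

__all__ = [
    "SimConfigError",
    "MotifPlant",
    "SimConfig",
    "GeneTruth",
    "SimTruth",
    "simulate_panel",
    "simulate_matrices",
    "write_fixture",
    "FIXTURES",
]

_CLASSES = (("XI", "LAN"), ("XI", "MV"), ("GJ", "LAN"), ("GJ", "MV"))
_BASES = np.array(list("ACGT"))


class SimConfigError(ValueError):
    """Raised for an infeasible or invalid simulation configuration."""


@dataclass(frozen=True)
class MotifPlant:
    """A motif planted into the promoters of selected gene x population."""

    motif: str
    gene_indices: tuple[int, ...] = (0,)
    populations: tuple[str, ...] = ("XI",)
    copies: int = 1


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic panel.

    Population-class sizes default to the landrace / modern-variety
    splits of the Xian and Geng subspecies in the 3,010-genome rice
    panel (732 / 328 / 358 / 139).  ``shift_delta`` is the frequency
    mass moved off the predominant haplotype in modern varieties;
    ``freq_decay`` the geometric ratio of the skewed haplotype
    frequency law (a Dirichlet concentration may be used instead).
    Phenotypes follow y = mu + beta_hap + gamma_pop + N(0, sigma^2).
    """

    n_genes: int = 6
    cds_codons: int = 300
    k_haps: int = 5
    freq_decay: float = 0.55
    dirichlet: float | None = None
    n_lan_xi: int = 732
    n_mv_xi: int = 328
    n_lan_gj: int = 358
    n_mv_gj: int = 139
    shift_delta: float = 0.15
    emergent_prob: float = 0.5
    emergent_freq: float = 0.05
    private_hap_fraction: float = 0.3
    mu: float = 100.0
    hap_effect_sd: float = 1.0
    fixed_hap_effect: float | None = None
    pop_effect: float = 1.0
    noise_sd: float = 2.0
    traits: tuple[str, ...] = ("CL", "TGW")
    het_rate: float = 0.01
    missing_rate: float = 0.02
    n_promoter_accessions: int = 50
    promoter_length: int = 2000
    motif_plants: tuple[MotifPlant, ...] = (
        MotifPlant("G-box", (0,), ("XI",), 2),
        MotifPlant("ABRE", (1,), ("GJ",), 1),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_haps < 2:
            raise SimConfigError("k_haps must be >= 2")
        n_sites = self.k_haps * (self.k_haps - 1) // 2 + 1
        if n_sites > 3 * self.cds_codons:
            raise SimConfigError(
                f"{self.k_haps} haplotypes need {n_sites} segregating "
                f"sites but the CDS has only {3 * self.cds_codons} bp"
            )
        for name in (
            "freq_decay", "shift_delta", "emergent_prob", "emergent_freq",
            "private_hap_fraction", "het_rate", "missing_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimConfigError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise SimConfigError("noise_sd must be >= 0")
        if min(self.n_lan_xi, self.n_mv_xi, self.n_lan_gj, self.n_mv_gj) < 0:
            raise SimConfigError("population sizes must be >= 0")
        for plant in self.motif_plants:
            if any(i >= self.n_genes for i in plant.gene_indices):
                raise SimConfigError(
                    f"motif plant {plant.motif!r} targets a gene index "
                    f">= n_genes"
                )


@dataclass(frozen=True)
class GeneTruth:
    """Everything needed to recompute the expected statistics of one gene."""

    gene_id: str
    chrom: str
    strand: str
    site_positions: tuple[int, ...]
    hap_alleles: dict[str, tuple[int, ...]]  # truth label -> allele vector
    class_freqs: dict[str, dict[str, float]]  # "XI/LAN" -> label -> freq
    assignments: dict[str, str]  # accession -> truth label
    predominant: str
    delta: dict[str, float]  # subpop -> designed MV - LAN freq of H1
    emergent: tuple[str, ...]
    private_to: dict[str, str]  # truth label -> subpop, for private haps


@dataclass
class SimTruth:
    config: SimConfig
    gene_ids: list[str]
    genes: dict[str, GeneTruth]
    trait_effects: dict[str, tuple[str, dict[str, float]]]
    # (gene, motif) -> 0-based promoter coordinates of planted copies
    plant_coords: dict[tuple[str, str], tuple[int, ...]]
    plant_pops: dict[tuple[str, str], tuple[str, ...]]
    # expected both-strand match count per (gene, motif) in the target
    # populations (a palindromic copy counts twice)
    plant_expected: dict[tuple[str, str], int]
    promoter_accessions: list[str]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "config": dataclasses.asdict(self.config),
            "gene_ids": self.gene_ids,
            "genes": {
                gid: {
                    "chrom": gt.chrom,
                    "strand": gt.strand,
                    "site_positions": list(gt.site_positions),
                    "hap_alleles": {
                        k: list(v) for k, v in gt.hap_alleles.items()
                    },
                    "class_freqs": gt.class_freqs,
                    "assignments": gt.assignments,
                    "predominant": gt.predominant,
                    "delta": gt.delta,
                    "emergent": list(gt.emergent),
                    "private_to": gt.private_to,
                }
                for gid, gt in self.genes.items()
            },
            "trait_effects": {
                t: {"gene": g, "beta": b}
                for t, (g, b) in self.trait_effects.items()
            },
            "plants": [
                {
                    "gene": gene,
                    "motif": motif,
                    "coords": list(coords),
                    "populations": list(self.plant_pops[(gene, motif)]),
                    "expected_count": self.plant_expected[(gene, motif)],
                }
                for (gene, motif), coords in self.plant_coords.items()
            ],
            "promoter_accessions": self.promoter_accessions,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# internal panel construction


def _accession_ids(cfg: SimConfig) -> dict[tuple[str, str], list[str]]:
    sizes = {
        ("XI", "LAN"): cfg.n_lan_xi,
        ("XI", "MV"): cfg.n_mv_xi,
        ("GJ", "LAN"): cfg.n_lan_gj,
        ("GJ", "MV"): cfg.n_mv_gj,
    }
    return {
        key: [f"{key[1]}_{key[0]}_{i:05d}" for i in range(sizes[key])]
        for key in _CLASSES
    }


def _base_freqs(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    k = cfg.k_haps
    if cfg.dirichlet is not None:
        f = rng.dirichlet([cfg.dirichlet] * k)
        return np.sort(f)[::-1]
    f = cfg.freq_decay ** np.arange(k)
    return f / f.sum()


def _class_frequencies(
    cfg: SimConfig,
    base: np.ndarray,
    private_to: dict[int, str],
    has_emergent: bool,
) -> dict[str, np.ndarray]:
    """Per class (subpop x breeding) frequency vector over k (+1) haps."""
    k = cfg.k_haps
    n_tot = k + (1 if has_emergent else 0)
    out: dict[str, np.ndarray] = {}
    for sub, cls in _CLASSES:
        f = np.zeros(n_tot)
        f[:k] = base
        for j, owner in private_to.items():
            if owner != sub:
                f[j] = 0.0
        f /= f.sum()
        if cls == "MV":
            delta_eff = min(cfg.shift_delta, max(f[0] - 0.01, 0.0))
            f[0] -= delta_eff
            rest = delta_eff
            if has_emergent:
                e = min(cfg.emergent_freq, delta_eff)
                f[k] = e
                rest = delta_eff - e
            # shifted mass goes preferentially to the *rare* haplotypes
            # (inverse-frequency weights), mirroring replacement of the
            # predominant allele by rare ones and keeping it predominant
            # in the pooled LAN+MV sample
            others = np.array([j for j in range(1, k) if f[j] > 0])
            if rest > 0:
                if others.size:
                    w = 1.0 / f[others]
                    f[others] += rest * w / w.sum()
                else:
                    f[0] += rest
            f /= f.sum()
        out[f"{sub}/{cls}"] = f
    return out


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _scrub_motifs(
    seq: np.ndarray, motifs: Sequence[MotifDef], rng: np.random.Generator
) -> np.ndarray:
    """Re-randomise windows until the sequence has zero motif matches
    (both strands)."""
    from .cre_scan import scan_with_coords

    seq = seq.copy()
    for _ in range(200):
        text = "".join(seq)
        hits = scan_with_coords(text, motifs, strands="both")
        dirty = [
            (pos, len(m.iupac))
            for m in motifs
            for pos, _strand in hits[m.name]
        ]
        if not dirty:
            return seq
        for pos, w in dirty:
            seq[pos : pos + w] = _random_seq(rng, w)
    raise SimConfigError("could not build a motif-free promoter background")


def _expand_iupac(motif: MotifDef, rng: np.random.Generator) -> str:
    from .cre_scan import IUPAC

    return "".join(rng.choice(list(IUPAC[ch])) for ch in motif.iupac.upper())


def _iupac_matches(literal: str, iupac: str) -> bool:
    from .cre_scan import IUPAC

    return len(literal) == len(iupac) and all(
        b in IUPAC[ch] for b, ch in zip(literal, iupac.upper())
    )


def _plant_slots(
    rng: np.random.Generator,
    length: int,
    widths: list[int],
) -> list[int]:
    """Non-overlapping 0-based start slots for motif insertions."""
    for _ in range(500):
        cand = [int(rng.integers(0, length - w + 1)) for w in widths]
        spans = sorted(zip(cand, widths))
        ok = all(
            spans[i][0] + spans[i][1] <= spans[i + 1][0]
            for i in range(len(spans) - 1)
        )
        if ok:
            return cand
    raise SimConfigError("could not place motif plants without overlap")


@dataclass
class _Panel:
    """Fully materialised in-memory panel, ready to serialise."""

    cfg: SimConfig
    gene_models: list[GeneModel]
    contigs: dict[str, str]
    site_sets: dict[str, SiteSet]
    matrices: dict[str, GenotypeMatrix]
    labels: PopulationLabels
    phenotypes: pd.DataFrame
    promoters: dict[tuple[str, str], str]
    truth: SimTruth


def _build_panel(cfg: SimConfig) -> _Panel:
    rng = np.random.default_rng(cfg.seed)
    acc_by_class = _accession_ids(cfg)
    accessions = [a for key in _CLASSES for a in acc_by_class[key]]
    label_map = {
        a: (key[0], key[1]) for key in _CLASSES for a in acc_by_class[key]
    }
    labels = PopulationLabels(label_map)

    motif_table = {m.name: m for m in load_motif_table()}
    for plant in cfg.motif_plants:
        if plant.motif not in motif_table:
            raise SimConfigError(f"unknown motif {plant.motif!r} in plants")

    gene_ids = [f"G{i + 1:03d}" for i in range(cfg.n_genes)]
    P, L = cfg.promoter_length, 3 * cfg.cds_codons
    flank = 200

    gene_models: list[GeneModel] = []
    contigs: dict[str, str] = {}
    site_sets: dict[str, SiteSet] = {}
    matrices: dict[str, GenotypeMatrix] = {}
    truths: dict[str, GeneTruth] = {}
    promoters: dict[tuple[str, str], str] = {}
    plant_coords: dict[tuple[str, str], tuple[int, ...]] = {}
    plant_pops: dict[tuple[str, str], tuple[str, ...]] = {}
    plant_expected: dict[tuple[str, str], int] = {}

    # promoter accession subset: half XI, half GJ, in panel order
    n_prom = min(cfg.n_promoter_accessions, len(accessions))
    xi_accs = [a for a in accessions if label_map[a][0] == "XI"]
    gj_accs = [a for a in accessions if label_map[a][0] == "GJ"]
    half = n_prom // 2
    prom_accs = xi_accs[:half] + gj_accs[: n_prom - half]

    k = cfg.k_haps
    for gi, gid in enumerate(gene_ids):
        chrom = f"chr{gi + 1}"
        strand = "+" if gi % 2 == 0 else "-"
        if strand == "+":
            cds_start = flank + P + 1
            cds_end = cds_start + L - 1
        else:
            cds_start = flank + 1
            cds_end = cds_start + L - 1
        contig_len = flank + P + L + flank
        contig = _random_seq(rng, contig_len)

        has_emergent = bool(rng.random() < cfg.emergent_prob)
        n_sites = k * (k - 1) // 2 + (1 if has_emergent else 0)
        positions = np.sort(
            rng.choice(
                np.arange(cds_start, cds_end + 1), size=n_sites, replace=False
            )
        )
        # partition site indices into private blocks per derived hap
        perm = rng.permutation(n_sites)
        hap_labels = [f"H{j + 1}" for j in range(k)]
        site_block: dict[str, np.ndarray] = {}
        cursor = 0
        for j in range(1, k):
            m = j  # Hj+1 carries j private mutations
            site_block[hap_labels[j]] = perm[cursor : cursor + m]
            cursor += m
        if has_emergent:
            hap_labels.append("E1")
            site_block["E1"] = perm[cursor : cursor + 1]
            cursor += 1

        hap_alleles: dict[str, tuple[int, ...]] = {}
        for lab in hap_labels:
            vec = np.zeros(n_sites, dtype=int)
            if lab in site_block:
                vec[site_block[lab]] = 1
            hap_alleles[lab] = tuple(int(x) for x in vec)

        base = _base_freqs(cfg, rng)
        private_to: dict[int, str] = {}
        for j in range(1, k):
            if rng.random() < cfg.private_hap_fraction:
                private_to[j] = "XI" if rng.random() < 0.5 else "GJ"
        freqs = _class_frequencies(cfg, base, private_to, has_emergent)

        assignments: dict[str, str] = {}
        for sub, cls in _CLASSES:
            f = freqs[f"{sub}/{cls}"]
            accs = acc_by_class[(sub, cls)]
            if accs:
                draws = rng.choice(len(hap_labels), size=len(accs), p=f)
                for a, d in zip(accs, draws):
                    assignments[a] = hap_labels[d]

        # genotype matrix with post-assignment corruption
        sites = []
        for p in positions:
            ref = str(contig[p - 1])
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            sites.append(Site(chrom, int(p), ref, (alt,)))
        site_set = SiteSet(gid, tuple(sites))
        calls = np.zeros((len(accessions), n_sites), dtype=np.int16)
        for i, a in enumerate(accessions):
            calls[i] = hap_alleles[assignments[a]]
        if cfg.het_rate or cfg.missing_rate:
            u = rng.random(calls.shape)
            calls[u < cfg.het_rate] = HET
            calls[
                (u >= cfg.het_rate) & (u < cfg.het_rate + cfg.missing_rate)
            ] = MISSING
        matrices[gid] = GenotypeMatrix(tuple(accessions), site_set, calls)
        site_sets[gid] = site_set

        gene_models.append(
            GeneModel(gid, chrom, strand, ((cds_start, cds_end),),
                      cds_start, cds_end)
        )

        # promoter background + plants
        plants_here = [
            p for p in cfg.motif_plants if gi in p.gene_indices
        ]
        bg = _random_seq(rng, P)
        if plants_here:
            defs = [motif_table[p.motif] for p in plants_here]
            bg = _scrub_motifs(bg, defs, rng)
            widths = [
                len(motif_table[p.motif].iupac)
                for p in plants_here
                for _ in range(p.copies)
            ]
            for _attempt in range(100):
                slots = _plant_slots(rng, P, widths)
                variants: dict[str, np.ndarray] = {
                    sub: bg.copy() for sub in ("XI", "GJ")
                }
                coords: dict[str, list[int]] = {p.motif: [] for p in plants_here}
                expected: dict[str, int] = {p.motif: 0 for p in plants_here}
                si = 0
                for p in plants_here:
                    mdef = motif_table[p.motif]
                    for _c in range(p.copies):
                        pos = slots[si]
                        si += 1
                        literal = _expand_iupac(mdef, rng)
                        for sub in p.populations:
                            variants[sub][pos : pos + len(literal)] = list(
                                literal
                            )
                        coords[p.motif].append(pos)
                        # a palindromic copy also matches on the reverse
                        # strand, so both-strand scans see it twice
                        expected[p.motif] += 1 + int(
                            _iupac_matches(revcomp(literal), mdef.iupac)
                        )
                # verify exact counts in each variant
                ok = True
                for sub in ("XI", "GJ"):
                    text = "".join(variants[sub])
                    counts = scan_promoter(text, defs, strands="both")
                    for p in plants_here:
                        want = expected[p.motif] if sub in p.populations else 0
                        if counts[p.motif] != want:
                            ok = False
                if ok:
                    break
            else:
                raise SimConfigError(
                    f"{gid}: could not plant motifs without spurious matches"
                )
            for p in plants_here:
                plant_coords[(gid, p.motif)] = tuple(sorted(coords[p.motif]))
                plant_pops[(gid, p.motif)] = tuple(p.populations)
                plant_expected[(gid, p.motif)] = expected[p.motif]
        else:
            variants = {"XI": bg, "GJ": bg}

        clean_text = "".join(bg)
        for a in prom_accs:
            sub = label_map[a][0]
            promoters[(gid, a)] = "".join(variants[sub])

        # embed the clean background as the reference promoter
        if strand == "+":
            w_start, w_end = cds_start - P, cds_start - 1
            window = np.array(list(clean_text))
        else:
            w_start, w_end = cds_end + 1, cds_end + P
            window = np.array(list(revcomp(clean_text)))
        contig[w_start - 1 : w_end] = window
        contigs[chrom] = "".join(contig)

        truths[gid] = GeneTruth(
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            site_positions=tuple(int(p) for p in positions),
            hap_alleles=hap_alleles,
            class_freqs={
                key: {
                    lab: float(f[idx])
                    for idx, lab in enumerate(hap_labels)
                }
                for key, f in freqs.items()
            },
            assignments=assignments,
            predominant="H1",
            delta={
                sub: float(
                    freqs[f"{sub}/MV"][0] - freqs[f"{sub}/LAN"][0]
                )
                for sub in ("XI", "GJ")
            },
            emergent=("E1",) if has_emergent else (),
            private_to={hap_labels[j]: s for j, s in private_to.items()},
        )

    # phenotypes
    trait_effects: dict[str, tuple[str, dict[str, float]]] = {}
    pheno = pd.DataFrame(index=accessions)
    pheno.index.name = "accession_id"
    for ti, trait in enumerate(cfg.traits):
        gid = gene_ids[ti % cfg.n_genes]
        gt = truths[gid]
        hap_labels = list(gt.hap_alleles)
        beta: dict[str, float] = {}
        for lab in hap_labels:
            if lab == "H1":
                beta[lab] = 0.0
            elif cfg.fixed_hap_effect is not None:
                beta[lab] = cfg.fixed_hap_effect if lab == "H2" else 0.0
            elif cfg.hap_effect_sd > 0:
                beta[lab] = float(rng.normal(0.0, cfg.hap_effect_sd))
            else:
                beta[lab] = 0.0
        vals = np.array(
            [
                cfg.mu
                + beta[gt.assignments[a]]
                + (cfg.pop_effect if label_map[a][0] == "GJ" else 0.0)
                for a in accessions
            ]
        )
        if cfg.noise_sd > 0:
            vals = vals + rng.normal(0.0, cfg.noise_sd, size=len(accessions))
        pheno[trait] = vals
        trait_effects[trait] = (gid, beta)

    truth = SimTruth(
        cfg, gene_ids, truths, trait_effects, plant_coords, plant_pops,
        plant_expected, prom_accs,
    )
    return _Panel(
        cfg, gene_models, contigs, site_sets, matrices, labels, pheno,
        promoters, truth,
    )


# ---------------------------------------------------------------------------
# public entry points


def simulate_matrices(
    cfg: SimConfig,
) -> tuple[
    dict[str, tuple[SiteSet, GenotypeMatrix]],
    PopulationLabels,
    pd.DataFrame,
    SimTruth,
]:
    """Simulate a panel in memory (no files).

    Returns per-gene (SiteSet, GenotypeMatrix), the labels, the
    phenotype table and the truth record.  Identical seeds give
    identical panels.
    """
    panel = _build_panel(cfg)
    per_gene = {
        gid: (panel.site_sets[gid], panel.matrices[gid])
        for gid in panel.truth.gene_ids
    }
    return per_gene, panel.labels, panel.phenotypes, panel.truth


def simulate_panel(
    cfg: SimConfig, out_dir: str | Path
) -> tuple[dict[str, Path], SimTruth]:
    """Simulate a panel and write its standard-format files.

    Emits ``variants.vcf``, ``genes.gff3``, ``genome.fasta``,
    ``labels.tsv``, ``phenotypes.tsv``, ``promoters.fasta`` (records
    named ``gene|accession``) and ``truth.json``.  The same seed yields
    byte-identical files.
    """
    panel = _build_panel(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "variants.vcf",
        "gff3": out / "genes.gff3",
        "fasta": out / "genome.fasta",
        "labels": out / "labels.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "promoters": out / "promoters.fasta",
        "truth": out / "truth.json",
    }

    accessions = list(panel.matrices[panel.truth.gene_ids[0]].accessions)
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        for gid in panel.truth.gene_ids:
            fh.write(f"##contig=<ID={panel.truth.genes[gid].chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(accessions)
            + "\n"
        )
        for gid in panel.truth.gene_ids:
            gm = panel.matrices[gid]
            for j, site in enumerate(gm.sites.sites):
                gts = []
                for c in gm.calls[:, j]:
                    if c == MISSING:
                        gts.append("./.")
                    elif c == HET:
                        gts.append("0/1")
                    else:
                        gts.append(f"{c}/{c}")
                fh.write(
                    f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t"
                    f"{site.alts[0]}\t.\tPASS\t.\tGT\t"
                    + "\t".join(gts)
                    + "\n"
                )

    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for gmod in panel.gene_models:
            s, e = gmod.cds_intervals[0]
            fh.write(
                f"{gmod.chrom}\tsim\tgene\t{gmod.start}\t{gmod.end}\t.\t"
                f"{gmod.strand}\t.\tID={gmod.gene_id}\n"
            )
            fh.write(
                f"{gmod.chrom}\tsim\tmRNA\t{gmod.start}\t{gmod.end}\t.\t"
                f"{gmod.strand}\t.\tID={gmod.gene_id}.1;"
                f"Parent={gmod.gene_id}\n"
            )
            fh.write(
                f"{gmod.chrom}\tsim\tCDS\t{s}\t{e}\t.\t{gmod.strand}\t0\t"
                f"ID={gmod.gene_id}.1.cds;Parent={gmod.gene_id}.1\n"
            )

    with open(paths["fasta"], "w") as fh:
        for gid in panel.truth.gene_ids:
            chrom = panel.truth.genes[gid].chrom
            seq = panel.contigs[chrom]
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    with open(paths["labels"], "w") as fh:
        fh.write("accession_id\tsubpopulation\tbreeding_class\n")
        for a in accessions:
            fh.write(
                f"{a}\t{panel.labels.subpopulation(a)}\t"
                f"{panel.labels.breeding_class(a)}\n"
            )

    panel.phenotypes.round(6).to_csv(paths["phenotypes"], sep="\t")

    with open(paths["promoters"], "w") as fh:
        for (gid, acc), seq in sorted(panel.promoters.items()):
            fh.write(f">{gid}|{acc}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    panel.truth.to_json(paths["truth"])
    return paths, panel.truth


FIXTURES: dict[str, SimConfig] = {
    "tiny": SimConfig(
        n_genes=2, cds_codons=60, k_haps=3, n_lan_xi=4, n_mv_xi=4,
        n_lan_gj=2, n_mv_gj=2, shift_delta=0.25, emergent_prob=1.0,
        private_hap_fraction=0.0, het_rate=0.0, missing_rate=0.0,
        noise_sd=1.0, n_promoter_accessions=8, seed=11,
    ),
    "shifted": SimConfig(
        n_genes=4, cds_codons=60, k_haps=4, n_lan_xi=500, n_mv_xi=500,
        n_lan_gj=500, n_mv_gj=500, shift_delta=0.3, emergent_prob=1.0,
        het_rate=0.0, missing_rate=0.0, seed=23,
    ),
    "null": SimConfig(
        n_genes=20, cds_codons=60, k_haps=4, n_lan_xi=200, n_mv_xi=200,
        n_lan_gj=200, n_mv_gj=200, shift_delta=0.0, emergent_prob=0.0,
        private_hap_fraction=0.0, hap_effect_sd=0.0, het_rate=0.0,
        missing_rate=0.0, seed=5,
    ),
    "cre-plant": SimConfig(
        n_genes=2, cds_codons=60, k_haps=3, n_lan_xi=10, n_mv_xi=10,
        n_lan_gj=10, n_mv_gj=10, het_rate=0.0, missing_rate=0.0,
        n_promoter_accessions=20,
        motif_plants=(
            MotifPlant("G-box", (0,), ("XI",), 2),
            MotifPlant("ABRE", (1,), ("GJ",), 3),
        ),
        seed=29,
    ),
}


def write_fixture(name: str, out_dir: str | Path) -> tuple[dict[str, Path], SimTruth]:
    """Write one of the canned miniature panels used by tests and docs."""
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; known: {sorted(FIXTURES)}"
        )
    return simulate_panel(FIXTURES[name], out_dir)
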