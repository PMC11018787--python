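"""End-to-end orchestration: extract -> census -> network -> shift ->
association -> CRE profile, from a single configuration.

Each gene is analysed independently; a failure in one gene is recorded
in the report and the run continues.  Every stochastic step derives its
seed from the run seed, so a rerun with the same configuration produces
an identical machine-readable summary.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from pyfaidx import Fasta

from . import breeding_shift, cre_scan, gchap_core, hap_network, io_genomics
from .io_genomics import PopulationLabels

__all__ = ["RunConfig", "run_pipeline", "census_table", "shift_table", "read_promoter_fasta"]


@dataclass
class RunConfig:
    """Inputs, thresholds and toggles for one pipeline run.

    Thresholds default to the analysis' standard values: 2000 bp
    promoters, >= 50 carriers for a major haplotype, MAF >= 0.05,
    missing rate < 20 %, alpha 0.05.
    """

    vcf: str
    gff3: str
    out_dir: str
    fasta: str | None = None
    labels: str | None = None
    phenotypes: str | None = None
    promoters: str | None = None  # per-accession FASTA, ids "gene|accession"
    motifs: str | None = None  # TSV; None = bundled table
    genes: Sequence[str] | None = None  # None = all genes in the GFF3
    min_carriers: int = 50
    maf_min: float = 0.05
    missing_max: float = 0.20
    alpha: float = 0.05
    promoter_length: int = 2000
    het_policy: str = "drop"
    n_boot: int = 1000
    seed: int = 17
    do_network: bool = True
    do_shift: bool = True
    do_assoc: bool = True
    do_cre: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("vcf", "gff3"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{name} input not found: {p}")
        for name in ("fasta", "labels", "phenotypes", "promoters", "motifs"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} input not found: {p}")
        if self.genes is not None and len(self.genes) == 0:
            raise ValueError("gene list is empty")
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min out of range")
        if not 0 <= self.missing_max <= 1:
            raise ValueError("missing_max out of range")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha out of range")


def census_table(census: gchap_core.GcHapCensus,
                 partition: gchap_core.PartitionResult | None) -> pd.DataFrame:
    rows = []
    for h in census.haps:
        row = {
            "gene": census.gene_id,
            "hap_name": h.hap_name,
            "allele_string": h.allele_string,
            "n_total": h.count,
            "gcHapN": census.gchapn,
            "E_H": census.e_h,
        }
        if partition is not None:
            for pop in partition.counts.columns:
                row[f"n_{pop}"] = int(partition.counts.loc[h.hap_name, pop])
        rows.append(row)
    return pd.DataFrame(rows)


def shift_table(results: list[breeding_shift.ShiftResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def read_promoter_fasta(path: str) -> dict[tuple[str, str], str]:
    out: dict[tuple[str, str], str] = {}
    fa = Fasta(path)
    for name in fa.keys():
        if "|" not in name:
            warnings.warn(f"promoter record {name!r} lacks 'gene|accession' id")
            continue
        gene, acc = name.split("|", 1)
        out[(gene, acc)] = str(fa[name][:]).upper()
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full per-gene analysis and write the report bundle.

    Writes per-gene census/network TSVs, shift/emergent/association
    tables, a machine-readable ``summary.json`` and a human-readable
    ``report.txt`` under ``cfg.out_dir``.  Returns the summary dict.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "network").mkdir(exist_ok=True)

    models = {g.gene_id: g for g in io_genomics.read_gene_models(cfg.gff3)}
    gene_ids = list(cfg.genes) if cfg.genes is not None else sorted(models)
    missing = [g for g in gene_ids if g not in models]
    if missing:
        raise ValueError(f"genes not in GFF3: {missing}")

    labels = (
        PopulationLabels.from_tsv(cfg.labels) if cfg.labels else None
    )
    phenotypes = (
        pd.read_csv(cfg.phenotypes, sep="\t", index_col=0)
        if cfg.phenotypes
        else None
    )

    summary: dict = {"seed": cfg.seed, "genes": {}, "errors": {}}
    census_frames, shift_frames, assoc_rows, emergent_rows = [], [], [], []

    for gid in gene_ids:
        try:
            gene = models[gid]
            sites, gm = io_genomics.extract_cds_snps(cfg.vcf, gene)
            gm = io_genomics.filter_sites(gm, cfg.maf_min, cfg.missing_max)
            census = gchap_core.build_gchaps(gm.sites, gm, cfg.het_policy)
            partition = (
                gchap_core.population_partition(census, labels)
                if labels
                else None
            )
            census_frames.append(census_table(census, partition))
            gene_summary = {
                "gcHapN": census.gchapn,
                "E_H": round(census.e_h, 6),
                "n_classified": census.n_classified,
                "n_excluded": census.n_excluded,
                "predominant": partition.predominant if partition else (
                    census.haps[0].hap_name if census.haps else ""
                ),
            }

            majors = gchap_core.major_haps(census, cfg.min_carriers)
            if cfg.do_network and majors:
                net = hap_network.build_msn(majors)
                net.write_edges_tsv(out / "network" / f"{gid}_edges.tsv")
                net.write_graphml(out / "network" / f"{gid}.graphml")
                gene_summary["network_nodes"] = len(net.nodes)
                gene_summary["network_edges"] = len(net.edges)

            if cfg.do_shift and labels is not None:
                res = breeding_shift.predominant_shift(
                    census, labels, n_boot=cfg.n_boot, seed=cfg.seed,
                )
                shift_frames.append(shift_table(res))
                gene_summary["shift"] = {
                    r.subpopulation: {
                        "hap": r.hap_name,
                        "delta": None if r.insufficient else round(r.delta, 6),
                        "p": None if r.insufficient else r.p_value,
                        "stars": r.stars,
                    }
                    for r in res
                }
                rep = breeding_shift.emergent_haps(census, labels)
                for sp, entries in rep.by_subpop.items():
                    for e in entries:
                        emergent_rows.append(
                            {
                                "gene": gid,
                                "subpopulation": sp,
                                "hap_name": e.hap_name,
                                "mv_count": e.mv_count,
                                "mv_freq": e.mv_freq,
                            }
                        )

            if cfg.do_assoc and phenotypes is not None:
                from .trait_assoc import hap_trait_assoc

                for r in hap_trait_assoc(
                    census, phenotypes, labels,
                    min_carriers=cfg.min_carriers, alpha=cfg.alpha,
                ):
                    for hap, (n, mean, sd) in r.groups.items():
                        assoc_rows.append(
                            {
                                "gene": gid,
                                "trait": r.trait,
                                "hap_name": hap,
                                "n": n,
                                "mean": mean,
                                "sd": sd,
                                "F": r.f,
                                "p_value": r.p_value,
                                "letters": r.letters[hap],
                            }
                        )

            summary["genes"][gid] = gene_summary
        except Exception as exc:  # isolate the failing gene, keep going
            summary["errors"][gid] = f"{type(exc).__name__}: {exc}"
            warnings.warn(f"gene {gid} failed: {exc}")

    if census_frames:
        pd.concat(census_frames, ignore_index=True).to_csv(
            out / "census.tsv", sep="\t", index=False
        )
    if shift_frames:
        pd.concat(shift_frames, ignore_index=True).to_csv(
            out / "shift.tsv", sep="\t", index=False
        )
    if emergent_rows:
        pd.DataFrame(emergent_rows).to_csv(
            out / "emergent.tsv", sep="\t", index=False
        )
    if assoc_rows:
        pd.DataFrame(assoc_rows).to_csv(
            out / "assoc.tsv", sep="\t", index=False
        )

    if cfg.do_cre and cfg.promoters and labels is not None:
        motifs = cre_scan.load_motif_table(cfg.motifs)
        promoters = read_promoter_fasta(cfg.promoters)
        promoters = {
            (g, a): s for (g, a), s in promoters.items() if g in gene_ids
        }
        if promoters:
            profile = cre_scan.population_cre_profile(
                promoters, motifs, labels
            )
            profile.population.to_csv(
                out / "cre_population.tsv", sep="\t", index=False
            )
            profile.counts.to_csv(
                out / "cre_counts.tsv", sep="\t", index=False
            )
            summary["cre"] = {
                "n_motifs": len(motifs),
                "n_discriminating": int(len(profile.discriminating)),
            }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    with open(out / "report.txt", "w") as fh:
        fh.write("gcHap pipeline report\n=====================\n")
        fh.write(f"seed: {cfg.seed}\n\n")
        for gid in gene_ids:
            if gid in summary["errors"]:
                fh.write(f"{gid}: FAILED ({summary['errors'][gid]})\n")
                continue
            gs = summary["genes"][gid]
            fh.write(
                f"{gid}: gcHapN={gs['gcHapN']} E_H={gs['E_H']:.4f} "
                f"classified={gs['n_classified']} "
                f"excluded={gs['n_excluded']} "
                f"predominant={gs['predominant']}\n"
            )
            for sp, sh in gs.get("shift", {}).items():
                if sh["delta"] is None:
                    fh.write(f"  shift {sp}: insufficient data\n")
                else:
                    fh.write(
                        f"  shift {sp}: {sh['hap']} delta={sh['delta']:+.3f} "
                        f"p={sh['p']:.3g} {sh['stars']}\n"
                    )
    return summary
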