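# gchapkit

Gene-CDS haplotype (gcHap) diversity analysis for crop population
panels: per-gene haplotype censuses from VCF + GFF3, diversity
statistics, minimum spanning haplotype networks, landrace-vs-modern-
variety frequency-shift tests, haplotype–trait association, and
promoter cis-regulatory-element profiling — with a truth-tagged
synthetic panel generator so every stage is testable without external
data.

## Who it is for

Population and breeding geneticists who work with resequencing panels
(rice-scale: thousands of accessions, e.g. landrace/modern-variety
splits of the *Xian* and *Geng* subspecies) and want gene-level allele
mining rather than genome-wide scans: which haplotypes exist at a
locus, how diverse the locus is, whether modern breeding moved its
allele frequencies, and which haplotypes track a trait.

## The model in brief

For a gene *g* with CDS SNPs *s₁ < s₂ < … < s_m*, an accession's
**gcHap** is its allele vector *(a₁, …, a_m)*; identical vectors are
one haplotype, named Hap1, Hap2, … by descending carrier count.
Per-gene diversity is **gcHapN** (number of distinct haplotypes) and
**Shannon's equitability**

    E_H = −Σ pᵢ ln pᵢ / ln(gcHapN)  ∈ [0, 1]

Selection during breeding is read from the predominant haplotype's
frequency drop Δ = f_MV − f_LAN, tested by a 2×2 chi-square (z² = χ²
without continuity correction). Haplotype–trait association uses
one-way ANOVA with Duncan's multiple range test
(R_p = q*(p, df)·√(MSE/n_h) at protection level 1 − (1−α)^(p−1)) and a
compact letter display. Networks connect major haplotypes (≥ 50
carriers) by Hamming distance, closest pairs first (minimum spanning
network). Promoters are the 2,000 bp upstream of the translation
start, scanned against an editable IUPAC motif table. See
`docs/methods.md` for the full treatment.

## Worked example

Every example in `examples/` builds a small synthetic panel and runs
one capability. `examples/01_census_and_diversity.py` prints:

```
gene   gcHapN     E_H classified
G001        3  0.9808         12
G002        4  0.7755         12
```

G001 has three haplotypes at near-equal frequencies (E_H close to 1 —
a diverse locus); G002's spectrum is more skewed.
`examples/03_breeding_shift.py` on a panel simulated with a designed
shift of δ = 0.3 prints, per gene and subpopulation:

```
G001 GJ: Hap1 LAN 0.478 -> MV 0.178 (delta -0.300, chi2 102.1, p 5.3e-24 ****)
G001 XI: Hap1 LAN 0.484 -> MV 0.196 (delta -0.288, chi2 92.4, p 7.1e-22 ****)
  emergent in GJ-MV: Hap5 (26 carriers, freq 0.052)
  emergent in XI-MV: Hap5 (22 carriers, freq 0.044)
```

The predominant haplotype dropped by ≈ 0.3 in modern varieties of both
subspecies (recovering the designed δ), with four stars marking
p < 0.0001, and a haplotype absent from all landraces appears in the
modern varieties — the newly-emergent pattern the shift analysis looks
for.

A thin CLI wraps the same calls
(`gchapkit simulate|extract|census|run`); `gchapkit run --config
run.yaml` executes the whole pipeline and writes per-gene TSVs, network
files, `summary.json` and a human-readable report.

## Layout

```
src/gchapkit/
  io_genomics.py     VCF/GFF3/FASTA/TSV input, filters, promoters
  gchap_core.py      haplotype census, E_H, PAV summary, NG86 Ka/Ks
  hap_network.py     minimum spanning haplotype networks
  breeding_shift.py  LAN vs MV shift tests, emergent haplotypes
  trait_assoc.py     ANOVA, Duncan MRT, letters, LD half-decay
  cre_scan.py        IUPAC motif scanning, population CRE profiles
  synthetic_data.py  truth-tagged panel generator and fixtures
  pipeline.py, cli.py
examples/            one narrative script per capability
tests/               pytest suite with independent brute-force oracles
```
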