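# Methods

## The gene-CDS haplotype (gcHap) model

For one gene, take every SNP that falls inside its coding sequence
(CDS) in a population panel. An accession's **gcHap** is the ordered
vector of its allele codes at those sites. Accessions with identical
vectors carry the same haplotype; haplotypes are named `Hap1, Hap2, …`
by descending carrier count (ties broken by lexicographic allele
vector), so `Hap1` is always the predominant haplotype. Diversity per
gene is summarised by

* **gcHapN** — the number of distinct haplotypes observed, and
* **Shannon's equitability** `E_H = H / ln(k)`, where
  `H = −Σ pᵢ ln pᵢ` is the Shannon entropy of the haplotype
  frequencies and `k = gcHapN`. `E_H` runs from 0 (monomorphic; defined
  as 0 when `k = 1`) to 1 (all haplotypes equally frequent). The
  denominator is `ln(gcHapN)` — the number of observed classes — which
  is the standard equitability definition and the only one bounded by 1.

Rice panels are almost entirely inbred, so heterozygous calls are rare
and carry little information. The census therefore resolves HET and
MISSING calls by a single `het_policy`:

* `drop` (default) — the accession is excluded from that gene's census
  if any CDS call is HET or MISSING; conservative, and the convention
  the package's reported numbers use;
* `major` — the call is imputed with the site's modal homozygous
  allele (ties to the lower allele code);
* `as_ref` — the call is replaced by the reference allele.

`major`/`as_ref` exist for sensitivity analysis. The policy applies to
both HET and MISSING calls so the three policies partition the same
accessions consistently.

## Coordinates and input handling

All public coordinates are 1-based closed, matching GFF3 and VCF;
conversion to Python's 0-based half-open slices happens only inside the
two helpers that index sequence strings, so there is a single
conversion point. The representative transcript per gene is the mRNA
with the longest total CDS (ties to the smallest start coordinate).
Promoters are the 2,000 bp upstream of the **translation** start (the
ATG), not the transcription start: on the + strand the window ends one
base before the first CDS base; on the − strand it is the reverse
complement of the window starting one base after the genomically
3′-most CDS base. Windows overrunning a contig are truncated and
flagged.

Site filters follow the standard criteria: minor allele frequency
≥ 0.05 (a heterozygote contributes one reference and one alternate
copy; MAF is one minus the major-allele frequency so multi-allelic
sites are handled) and missing rate strictly below 20 %. The filter is
idempotent.

## Haplotype networks

Major haplotypes (≥ 50 carriers by default) form the nodes; edge
weights are Hamming distances (mutation counts) between allele
vectors. Edges are added greedily in ascending distance (Kruskal), so
the most closely related haplotypes are connected first — ties resolved
by larger combined carrier count, then input order, making the output
byte-identical across runs. Besides the minimum spanning tree, every
non-tree edge whose length equals the largest tree edge on the path
between its endpoints is kept as an alternative connection (the
minimum-spanning-network convention). A `max_distance` option severs
edges above a limit, emulating a statistical-parsimony connection
cutoff; exact TCS-style parsimony is intentionally not implemented —
the greedy closest-first rule is the behaviour the analysis needs, and
is what standard haplotype-network software computes by default.

## Breeding frequency-shift tests

Within each subpopulation (Xian/indica and Geng/japonica in the rice
setting), accessions divide into landraces (LAN) and modern varieties
(MV). The predominant haplotype of the pooled LAN+MV carriers is
identified — pooling keeps the selection symmetric between the classes,
so the test remains valid under the null — and its LAN vs MV counts are
compared with a 2×2 chi-square (1 df, no Yates correction by default,
so the signed two-proportion z satisfies `z² = chi2` exactly; the
correction is available by flag). Significance stars follow the
convention `*` p < 0.05, `**` p < 0.01, `****` p < 0.0001 — the 0.001
level is deliberately absent from this convention.

`E_H` is compared between LAN and MV with a percentile-bootstrap z:
accessions are resampled with replacement within each class (B = 1000
by default, seeded), and the normal approximation on the bootstrap
standard errors gives the z and its two-sided p. `E_H` has no usable
closed-form standard error, which is why the bootstrap is used.

Haplotypes with zero LAN carriers and at least one MV carrier in a
subpopulation are reported as newly emergent.

## Trait association

Accessions are grouped by major haplotype and a one-way ANOVA is run
per trait; an optional additive subpopulation factor (Type II sums of
squares via statsmodels) guards against haplotype–subpopulation
confounding, the obvious reason a second factor would be wanted.
Group separation uses **Duncan's multiple range test**: for a stretch
of `p` ranked means the least significant range is
`R_p = q*(p, df_error) · sqrt(MSE / n_h)`, with `q*` the
studentized-range quantile at Duncan's protection level
`1 − (1−α)^(p−1)` and `n_h` the harmonic mean of the stretch's group
sizes (Kramer adjustment for unequal sizes). A stretch whose end gap
does not exceed its `R_p` is homogeneous, and so is every stretch it
encloses (containment rule). Letters come from the insert-and-absorb
compact-letter-display algorithm; groups sharing no letter differ at
the chosen α. Quantiles come from `scipy.stats.studentized_range`
(cached — the numerical inversion is expensive); accuracy is far inside
the 1e-6 target.

Degenerate inputs are guarded: groups with fewer than two observations
are dropped with a warning; zero within-group variance with differing
means reports `F = inf` and an underflowed p-value rather than raising.

## Ka/Ks (Nei–Gojobori 1986)

Synonymous site counts per codon use the fractional definition (the
fraction of the three possible changes at each position that are
synonymous), averaged over both sequences; observed synonymous and
nonsynonymous differences are averaged over all minimal mutational
pathways per codon. Mutations producing a stop codon count as
nonsynonymous, and pathways passing through a stop are excluded
(falling back to all pathways if none survive). Distances use the
Jukes–Cantor correction `d = −(3/4) ln(1 − 4p/3)`; a proportion
`p ≥ 3/4` raises a saturation error naming the saturated class, and
`Ks = 0` leaves the ratio undefined (`None`) rather than infinite.

## LD half-decay

Genotypes are coded as alternate-allele dosage (0, 1 for HET, 2),
missing calls pairwise-deleted, monomorphic pair members skipped.
`r²` is the squared Pearson correlation of dosages per site pair;
pairs are binned by distance and the half-decay distance is the first
bin midpoint at which the mean `r²` falls to half the maximum bin mean.

## Promoter cis-element scanning

Motifs are IUPAC consensus strings with one of five functional
categories (light, stress, hormone, development, MYB-related).
Matching is case-insensitive; ambiguity codes expand over A/C/G/T only,
so an `N` in the *sequence* never matches. All overlapping occurrences
are counted — copy-number comparisons need one deterministic, maximal
convention — and both-strand mode adds matches against the reverse
complement, so a palindromic site counts twice by design. The bundled
25-motif table approximates the consensus of commonly profiled plant
CREs and is explicitly illustrative: profiles are reproducible only
relative to a fixed, user-editable motif table, since the original
prediction service's matrix definitions are not public. Per-population
profiles report presence frequency (fraction of accessions with ≥ 1
copy) and mean copy number, with motifs whose presence differs between
two populations at p < 0.05 (two-proportion chi-square) flagged as
population-discriminating.

## The synthetic panel generator

The generator emits a complete input set — VCF, GFF3, FASTA, label and
phenotype TSVs, per-accession promoter FASTA and a `truth.json` — whose
statistical structure matches what the analyses assume:

* **Star genealogy.** `Hap1` is the all-reference vector; derived
  haplotype `Hj` carries `j − 1` private mutations. All pairwise
  Hamming distances and the expected network topology (a star centred
  on `Hap1`) are therefore known analytically.
* **Skewed frequency law.** Haplotype frequencies follow a geometric
  decay (ratio 0.55 by default; a Dirichlet law is available), giving
  one predominant haplotype plus progressively rarer ones.
* **Breeding shift.** In modern varieties a mass `δ` is moved off the
  predominant haplotype and redistributed to the *rare* haplotypes
  (inverse-frequency weights) and, optionally, to a haplotype that
  exists only in modern varieties — mirroring replacement of the
  ancestral predominant allele by rare or newly emerged ones, and
  keeping `Hap1` predominant in the pooled sample by construction.
* **Population structure.** Class sizes default to 732/328 landrace /
  modern-variety accessions for Xian and 358/139 for Geng — the
  3,010-genome rice panel's splits. A configurable fraction of derived
  haplotypes is private to one subspecies.
* **Phenotypes.** `y = μ + β_hap + γ_pop + N(0, σ²)`, with β per
  haplotype recorded in the truth (zero for `Hap1`); defaults
  μ = 100, β ~ N(0, 1), γ = 1 for Geng, σ = 2 — effect sizes of order
  half a phenotypic SD, typical of a moderate-effect locus.
* **Promoters.** Backgrounds are rejection-sampled to contain zero
  matches of the motifs being planted (both strands), then literal
  expansions are inserted at recorded coordinates; planted copies are
  verified to be the only matches, so recovery is exact. A palindromic
  copy legitimately counts twice under the both-strand convention; the
  truth records the expected count.
* **Corruption last.** HET/MISSING corruption (1 % / 2 % by default,
  roughly what filtered inbred-panel matrices look like) is applied
  after haplotype assignment, so the truth census stays well defined.

Values not fixed by the study design (δ = 0.15 default, emergent
haplotype probability 0.5 with frequency 0.05, private-haplotype
fraction 0.3) were chosen once as field-realistic magnitudes for loci
under moderate artificial selection.

What the generator does **not** emulate: recombination within genes,
coalescent demography, genotyping-error structure, linked selection, or
realistic promoter sequence composition. Passing tests therefore show
that the statistics recover the structure they assume — not that real
panels satisfy those assumptions.

## Verification sizes and determinism

The test suite checks each core statistic against an independent
brute-force implementation on 100 random small instances (exact for
integer outputs, 1e-9 relative for floats); type-I control of the
shift test on 200 null genes (300 LAN + 300 MV accessions each), with
the rejection rate required inside the binomial 99 % interval around
0.05; power ≥ 0.95 at α = 0.01 on 100 replicate genes with δ = 0.3 and
500 accessions per class; Duncan letter separation of a 2σ planted
effect in ≥ 95 of 100 replicates (3 groups × 60 observations); exact
truth round-trips on noiseless panels; and byte-identical outputs for
repeated runs at a fixed seed. These problem sizes are the package's
verification conditions; they were chosen to give the properties sharp
binomial bounds while keeping the default test run fast.

`scripts/acceptance.py` recomputes the same quantities from scratch at
an arbitrary seed (see the README's reproduction section).

## Known limitations

* The census treats the VCF as ground truth — no phasing, imputation or
  variant-calling QC.
* Multi-allelic heterozygotes lose allele identity in the genotype code
  (HET is one state); their MAF contribution assumes ref + first alt.
* The E_H bootstrap z is approximate for very small classes or
  near-monomorphic genes (bootstrap SE can be 0; such comparisons are
  reported as degenerate, p = 1).
* The bundled motif table is illustrative; biological conclusions about
  specific cis-elements require a curated table.
* `kaks_ng86` expects aligned, gap-free, in-frame sequences; it does
  not align.
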