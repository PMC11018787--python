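"""Gene-CDS haplotypes (gcHaps) and their diversity statistics.

An accession's gcHap is the ordered vector of its allele codes at every
SNP inside one gene's coding sequence.  Accessions with identical
vectors share one haplotype; haplotypes are named ``Hap1, Hap2, ...``
by descending carrier count so that Hap1 is the predominant one.
Diversity per gene is summarised by gcHapN (the number of distinct
haplotypes) and Shannon's equitability E_H, the Shannon entropy of the
haplotype frequencies normalised by ln(gcHapN), which runs from 0
(monomorphic) to 1 (all haplotypes equally frequent).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_genomics import (
    HET,
    MISSING,
    GenotypeMatrix,
    PopulationLabels,
    SiteSet,
)

__all__ = [
    "GcHap",
    "GcHapCensus",
    "PartitionResult",
    "build_gchaps",
    "shannon_equitability",
    "major_haps",
    "population_partition",
    "pav_summary",
    "kaks_ng86",
    "KaKsResult",
    "SaturationError",
]

HET_POLICIES = ("drop", "major", "as_ref")


@dataclass(frozen=True)
class GcHap:
    """One gene-CDS haplotype with its carrier accessions."""

    gene_id: str
    hap_name: str
    alleles: tuple[int, ...]
    carriers: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.carriers)

    @property
    def allele_string(self) -> str:
        return "".join(str(a) for a in self.alleles)


@dataclass(frozen=True)
class GcHapCensus:
    """Per-gene haplotype table with gcHapN and Shannon's equitability."""

    gene_id: str
    haps: tuple[GcHap, ...]
    n_classified: int
    n_excluded: int

    @property
    def gchapn(self) -> int:
        return len(self.haps)

    @property
    def counts(self) -> np.ndarray:
        return np.array([h.count for h in self.haps], dtype=int)

    @property
    def e_h(self) -> float:
        if not self.haps:
            return 0.0
        return shannon_equitability(self.counts)

    def hap_of(self) -> dict[str, str]:
        """Accession -> hap name for every classified accession."""
        return {
            acc: h.hap_name for h in self.haps for acc in h.carriers
        }


def build_gchaps(
    sites: SiteSet, gm: GenotypeMatrix, het_policy: str = "drop"
) -> GcHapCensus:
    """Collapse accessions into gene-CDS haplotypes.

    ``het_policy`` controls how HET and MISSING calls are resolved:

    * ``drop`` — the accession is excluded from this gene's census;
    * ``major`` — the call is replaced by the site's majority allele
      (modal homozygous code, ties to the lower code);
    * ``as_ref`` — the call is replaced by the reference allele.

    With zero sites every accession carries the single monomorphic
    haplotype.  Haplotypes are named by descending carrier count, ties
    broken by lexicographic allele vector.
    """
    if het_policy not in HET_POLICIES:
        raise ValueError(f"het_policy must be one of {HET_POLICIES}")
    if gm.sites is not sites and gm.sites != sites:
        raise ValueError("GenotypeMatrix does not match SiteSet")

    calls = gm.calls
    n_acc, n_sites = calls.shape

    if het_policy == "major" and n_sites:
        majority = np.zeros(n_sites, dtype=np.int16)
        for j in range(n_sites):
            col = calls[:, j]
            hom = col[col >= 0]
            if hom.size:
                counts = np.bincount(hom)
                majority[j] = np.flatnonzero(counts == counts.max())[0]

    groups: dict[tuple[int, ...], list[str]] = {}
    n_excluded = 0
    for i, acc in enumerate(gm.accessions):
        row = calls[i].copy()
        bad = row < 0
        if bad.any():
            if het_policy == "drop":
                n_excluded += 1
                continue
            if het_policy == "major":
                row[bad] = majority[bad]
            else:  # as_ref
                row[bad] = 0
        groups.setdefault(tuple(int(x) for x in row), []).append(acc)

    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    haps = tuple(
        GcHap(sites.gene_id, f"Hap{k + 1}", alleles, tuple(carriers))
        for k, (alleles, carriers) in enumerate(ordered)
    )
    return GcHapCensus(sites.gene_id, haps, n_acc - n_excluded, n_excluded)


def shannon_equitability(counts: Sequence[float] | np.ndarray) -> float:
    """Shannon's equitability E_H = H / ln(k) of a count vector.

    ``H`` is the Shannon entropy of the relative frequencies and ``k``
    the number of classes; a single class gives E_H = 0 by definition.
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0:
        raise ValueError("counts must be nonempty")
    if (c <= 0).any():
        raise ValueError("all counts must be > 0")
    if c.size == 1:
        return 0.0
    p = c / c.sum()
    h = -(p * np.log(p)).sum()
    return float(h / math.log(c.size))


def major_haps(census: GcHapCensus, min_carriers: int = 50) -> list[GcHap]:
    """Haplotypes carried by at least ``min_carriers`` accessions."""
    if min_carriers < 1:
        raise ValueError("min_carriers must be >= 1")
    return [h for h in census.haps if h.count >= min_carriers]


@dataclass(frozen=True)
class PartitionResult:
    """Per-subpopulation haplotype counts and derived summaries.

    ``counts`` is a haplotype x subpopulation table of carrier counts;
    ``unique`` maps each subpopulation to the haplotypes all of whose
    carriers belong to it; ``predominant`` is the globally most frequent
    haplotype (ties to the lower Hap index) and ``per_pop_predominant``
    the same within each subpopulation.
    """

    gene_id: str
    counts: pd.DataFrame
    frequencies: pd.DataFrame
    unique: dict[str, list[str]]
    predominant: str
    per_pop_predominant: dict[str, str]


def population_partition(
    census: GcHapCensus, labels: PopulationLabels
) -> PartitionResult:
    """Partition a gene's haplotype carriers by subpopulation."""
    pops = sorted(
        {labels.subpopulation(a) for h in census.haps for a in h.carriers}
    )
    hap_names = [h.hap_name for h in census.haps]
    counts = pd.DataFrame(0, index=hap_names, columns=pops, dtype=int)
    for h in census.haps:
        for acc in h.carriers:
            counts.loc[h.hap_name, labels.subpopulation(acc)] += 1
    totals = counts.sum(axis=0)
    freqs = counts / totals.replace(0, np.nan)
    unique: dict[str, list[str]] = {p: [] for p in pops}
    for h in census.haps:
        carried_in = [p for p in pops if counts.loc[h.hap_name, p] > 0]
        if len(carried_in) == 1:
            unique[carried_in[0]].append(h.hap_name)
    # census haps are already ordered by count desc then allele string, so
    # idxmax-by-order resolves ties to the lower Hap index
    predominant = hap_names[int(np.argmax(census.counts))] if hap_names else ""
    per_pop = {
        p: counts[p].idxmax() if counts[p].sum() else ""
        for p in pops
    }
    return PartitionResult(
        census.gene_id, counts, freqs, unique, predominant, per_pop
    )


def pav_summary(
    presence: pd.DataFrame, labels: PopulationLabels | None = None
) -> pd.DataFrame:
    """Summarise a gene x accession presence/absence (0/1) matrix.

    Returns one row per gene with the overall presence frequency, a
    ``core`` flag (present in every accession) and, when labels are
    given, per-subpopulation presence frequencies.
    """
    values = presence.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("presence matrix entries must be 0 or 1")
    out = pd.DataFrame(index=presence.index)
    out["presence_freq"] = presence.mean(axis=1)
    out["core"] = presence.all(axis=1)
    if labels is not None:
        pops = sorted({labels.subpopulation(a) for a in presence.columns})
        for p in pops:
            cols = [a for a in presence.columns if labels.subpopulation(a) == p]
            out[f"freq_{p}"] = presence[cols].mean(axis=1) if cols else np.nan
    return out


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) Ka/Ks


class SaturationError(ValueError):
    """Raised when a proportion of differences exceeds the Jukes-Cantor
    correctable range (p >= 3/4)."""


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    ratio: float | None  # None when Ks == 0 (undefined)
    s_sites: float
    n_sites: float
    sd: float
    nd: float


_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    # standard genetic code; '*' marks stops
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def _syn_sites(codon: str, table: dict[str, str]) -> float:
    """Synonymous site count of one codon (NG86 fractional definition).

    Mutations producing a stop codon count as nonsynonymous.
    """
    aa = table[codon]
    s = 0.0
    for i in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1 :]
            if table[mutant] != "*" and table[mutant] == aa:
                syn += 1
        s += syn / 3.0
    return s


def _pathway_counts(c1: str, c2: str, table: dict[str, str]) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts between two
    codons over all minimal mutational pathways.

    Pathways passing through a stop codon are excluded; when every
    pathway is excluded, all are used (degenerate fall-back).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results: list[tuple[int, int]] = []
    fallback: list[tuple[int, int]] = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        through_stop = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if table[cur] != "*" and table[nxt] == table[cur]:
                sd += 1
            else:
                nd += 1
            if table[nxt] == "*":
                through_stop = True
            cur = nxt
        fallback.append((sd, nd))
        if not through_stop:
            results.append((sd, nd))
    use = results or fallback
    sd = sum(r[0] for r in use) / len(use)
    nd = sum(r[1] for r in use) / len(use)
    return sd, nd


def _jc_correct(p: float, which: str) -> float:
    if p >= 0.75:
        raise SaturationError(
            f"{which} differences saturated (p = {p:.4f} >= 3/4); "
            "Jukes-Cantor correction undefined"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def kaks_ng86(cds_a: str, cds_b: str) -> KaKsResult:
    """Nei-Gojobori (1986) Ka, Ks and their ratio for two aligned CDS.

    Sequences must be equal length, gap free, length divisible by 3 and
    free of internal stop codons.  Site counts S and N are averaged over
    both sequences; observed differences Sd, Nd are averaged over all
    minimal mutational pathways per codon; distances use the
    Jukes-Cantor correction.  Ks = 0 leaves the ratio undefined
    (``None``).
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) % 3:
        raise ValueError("sequence length not divisible by 3")
    if not a:
        raise ValueError("empty sequences")
    for seq in (a, b):
        if set(seq) - set("ACGT"):
            raise ValueError("sequences must contain only A, C, G, T")
    table = _codon_table()
    codons_a = [a[i : i + 3] for i in range(0, len(a), 3)]
    codons_b = [b[i : i + 3] for i in range(0, len(b), 3)]
    for codons in (codons_a, codons_b):
        for c in codons[:-1]:
            if table[c] == "*":
                raise ValueError(f"internal stop codon {c}")

    s_a = sum(_syn_sites(c, table) for c in codons_a)
    s_b = sum(_syn_sites(c, table) for c in codons_b)
    s_sites = (s_a + s_b) / 2.0
    n_sites = len(a) - s_sites

    sd = nd = 0.0
    for c1, c2 in zip(codons_a, codons_b):
        d_s, d_n = _pathway_counts(c1, c2, table)
        sd += d_s
        nd += d_n

    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = _jc_correct(ps, "synonymous")
    ka = _jc_correct(pn, "nonsynonymous")
    ratio = (ka / ks) if ks > 0 else None
    return KaKsResult(ka, ks, ratio, s_sites, n_sites, sd, nd)
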