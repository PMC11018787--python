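"""Genomic file input/output and coordinate conventions.

Reads gene models from GFF3, SNP genotypes from VCF, and promoter
sequences from FASTA, and provides the site filters and genomic-context
classification the downstream haplotype analyses rely on.

Coordinate convention: every public coordinate in this package is
1-based and closed, matching GFF3 and VCF.  Conversion to Python's
0-based half-open slices happens only inside the helpers that touch
sequence strings, so there is a single conversion point.

Genotype codes in a :class:`GenotypeMatrix`:

* ``0 .. n_alt`` — homozygous for the allele with that index
  (0 = reference);
* :data:`HET` (``-1``) — heterozygous call;
* :data:`MISSING` (``-2``) — missing call (``./.``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from cyvcf2 import VCF
from pyfaidx import Fasta

__all__ = [
    "HET",
    "MISSING",
    "Gff3ParseError",
    "UnusableInputError",
    "GeneModel",
    "Site",
    "SiteSet",
    "GenotypeMatrix",
    "PopulationLabels",
    "Promoter",
    "read_gene_models",
    "extract_cds_snps",
    "filter_sites",
    "extract_promoter",
    "classify_feature_context",
    "write_vcf",
    "revcomp",
]

HET = -1
MISSING = -2

_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn", "TGCAYRSWMKVHDBNtgcayrswmkvhdbn"
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class Gff3ParseError(ValueError):
    """Raised for a structurally malformed GFF3 line."""


class UnusableInputError(ValueError):
    """Raised when an input file lacks required content (e.g. VCF GT)."""


@dataclass(frozen=True)
class GeneModel:
    """A gene's strand, transcription-unit span and representative CDS.

    ``cds_intervals`` are 1-based closed genomic intervals, sorted and
    non-overlapping.  ``translation_start`` is the genomic position of
    the first coding base: the 5'-most CDS base on the + strand, the
    3'-most genomic coordinate on the - strand.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    start: int  # transcription-unit start (gene feature), 1-based
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        ivals = tuple(sorted(tuple(iv) for iv in self.cds_intervals))
        for s, e in ivals:
            if s > e:
                raise ValueError(f"CDS interval start {s} > end {e}")
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise ValueError("CDS intervals overlap")
        object.__setattr__(self, "cds_intervals", ivals)
        if self.start > self.end:
            raise ValueError("gene start > end")

    @property
    def translation_start(self) -> int:
        if self.strand == "+":
            return self.cds_intervals[0][0]
        return self.cds_intervals[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    def contains_cds(self, pos: int) -> bool:
        """True if genomic position ``pos`` lies in a CDS interval."""
        return any(s <= pos <= e for s, e in self.cds_intervals)

    def promoter_window(self, length: int = 2000) -> tuple[int, int]:
        """Genomic window of the ``length``-bp promoter upstream of the ATG.

        The window is anchored at the translation start and is
        strand-aware; it may extend below position 1 (callers clip).
        """
        ts = self.translation_start
        if self.strand == "+":
            return (ts - length, ts - 1)
        return (ts + 1, ts + length)


@dataclass(frozen=True)
class Site:
    """One SNP: 1-based position, single-base REF and ALT alleles."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts


@dataclass(frozen=True)
class SiteSet:
    """Ordered CDS SNPs of one gene (ascending genomic position)."""

    gene_id: str
    sites: tuple[Site, ...]

    def __post_init__(self) -> None:
        pos = [s.pos for s in self.sites]
        if pos != sorted(pos):
            raise ValueError("sites must be in ascending position order")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=int)


@dataclass(frozen=True)
class GenotypeMatrix:
    """Accession x site genotype codes over one gene's :class:`SiteSet`."""

    accessions: tuple[str, ...]
    sites: SiteSet
    calls: np.ndarray  # (n_accessions, n_sites) int16

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls, dtype=np.int16)
        if calls.shape != (len(self.accessions), len(self.sites)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.sites)} sites"
            )
        object.__setattr__(self, "calls", calls)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def missing_rate(self) -> np.ndarray:
        """Per-site fraction of MISSING calls."""
        if self.n_accessions == 0:
            return np.zeros(self.n_sites)
        return (self.calls == MISSING).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-site minor allele frequency.

        A homozygote contributes two copies of its allele; a
        heterozygote contributes one reference and one first-alternate
        copy (allele identities of multi-allelic heterozygotes are not
        retained in the code).  MAF is 1 minus the major-allele
        frequency, so it generalises to multi-allelic sites.
        """
        out = np.zeros(self.n_sites)
        for j, site in enumerate(self.sites.sites):
            col = self.calls[:, j]
            n_alleles = len(site.alleles)
            counts = np.zeros(n_alleles, dtype=float)
            for a in range(n_alleles):
                counts[a] += 2 * np.count_nonzero(col == a)
            n_het = np.count_nonzero(col == HET)
            counts[0] += n_het
            if n_alleles > 1:
                counts[1] += n_het
            total = counts.sum()
            out[j] = 0.0 if total == 0 else 1.0 - counts.max() / total
        return out

    def subset_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        sites = SiteSet(
            self.sites.gene_id,
            tuple(s for s, k in zip(self.sites.sites, keep) if k),
        )
        return GenotypeMatrix(self.accessions, sites, self.calls[:, keep])


@dataclass(frozen=True)
class Promoter:
    """Promoter sequence with truncation flag and genomic window."""

    seq: str
    truncated: bool
    start: int
    end: int


class PopulationLabels:
    """Accession -> (subpopulation, breeding class) lookup.

    Subpopulations are free text (e.g. ``XI``/``GJ``); breeding classes
    are ``LAN`` (landrace), ``MV`` (modern variety) or ``other``.
    Accessions absent from the table are treated as unlabeled, never as
    errors.
    """

    UNLABELED = "unlabeled"

    def __init__(self, mapping: Mapping[str, tuple[str, str]]):
        self._map = dict(mapping)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PopulationLabels":
        """Read a TSV with header ``accession_id subpopulation breeding_class``."""
        mapping: dict[str, tuple[str, str]] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            try:
                i_acc = header.index("accession_id")
                i_sub = header.index("subpopulation")
                i_cls = header.index("breeding_class")
            except ValueError as exc:
                raise UnusableInputError(
                    "labels TSV needs columns accession_id, subpopulation, "
                    "breeding_class"
                ) from exc
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                acc = parts[i_acc]
                if acc in mapping:
                    raise UnusableInputError(f"accession {acc} labeled twice")
                mapping[acc] = (parts[i_sub], parts[i_cls])
        return cls(mapping)

    def subpopulation(self, accession: str) -> str:
        return self._map.get(accession, (self.UNLABELED, self.UNLABELED))[0]

    def breeding_class(self, accession: str) -> str:
        return self._map.get(accession, (self.UNLABELED, self.UNLABELED))[1]

    def subpopulations(self) -> list[str]:
        return sorted({v[0] for v in self._map.values()})

    def accessions(self) -> list[str]:
        return list(self._map)

    def __contains__(self, accession: str) -> bool:
        return accession in self._map

    def __len__(self) -> int:
        return len(self._map)


# ---------------------------------------------------------------------------
# GFF3


def _parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_models(gff3_path: str | Path) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/CDS features into :class:`GeneModel` objects.

    One representative transcript is chosen per gene: the mRNA with the
    longest total CDS, ties broken by smallest start coordinate.  CDS
    features attached directly to a gene (no mRNA level) are accepted.
    Genes with no CDS are skipped with a warning.
    """
    genes: dict[str, tuple[str, str, int, int]] = {}
    mrna_parent: dict[str, str] = {}
    cds_by_parent: dict[str, list[tuple[int, int]]] = {}

    with open(gff3_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise Gff3ParseError(
                    f"{gff3_path}: line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise Gff3ParseError(
                    f"{gff3_path}: line {lineno}: non-integer coordinates"
                ) from None
            a = _parse_attributes(attrs)
            if ftype == "gene":
                gid = a.get("ID", f"gene:{lineno}")
                genes[gid] = (chrom, strand, start, end)
            elif ftype in ("mRNA", "transcript"):
                tid = a.get("ID", f"mRNA:{lineno}")
                parent = a.get("Parent", tid)
                mrna_parent[tid] = parent
            elif ftype == "CDS":
                parent = a.get("Parent", "")
                for p in parent.split(","):
                    cds_by_parent.setdefault(p, []).append((start, end))

    models: list[GeneModel] = []
    for gid, (chrom, strand, gstart, gend) in genes.items():
        candidates: list[tuple[int, int, list[tuple[int, int]]]] = []
        for tid, parent in mrna_parent.items():
            if parent == gid and tid in cds_by_parent:
                ivals = sorted(cds_by_parent[tid])
                total = sum(e - s + 1 for s, e in ivals)
                candidates.append((total, ivals[0][0], ivals))
        if gid in cds_by_parent:  # CDS attached directly to the gene
            ivals = sorted(cds_by_parent[gid])
            total = sum(e - s + 1 for s, e in ivals)
            candidates.append((total, ivals[0][0], ivals))
        if not candidates:
            warnings.warn(f"gene {gid} has no CDS features; skipped")
            continue
        candidates.sort(key=lambda t: (-t[0], t[1]))
        ivals = candidates[0][2]
        models.append(
            GeneModel(gid, chrom, strand, tuple(ivals), gstart, gend)
        )
    return models


# ---------------------------------------------------------------------------
# VCF


def extract_cds_snps(
    vcf_path: str | Path, gene: GeneModel
) -> tuple[SiteSet, GenotypeMatrix]:
    """Pull single-base SNPs inside ``gene``'s CDS from a VCF.

    Indels and records with any multi-base allele are excluded.  An
    empty :class:`SiteSet` is a valid result (monomorphic gene).
    """
    vcf = VCF(str(vcf_path))
    accessions = tuple(vcf.samples)
    if not accessions:
        raise UnusableInputError(f"{vcf_path}: VCF has no samples")
    sites: list[Site] = []
    columns: list[np.ndarray] = []
    for v in vcf:
        if v.CHROM != gene.chrom or not gene.contains_cds(v.POS):
            continue
        alts = tuple(v.ALT)
        if len(v.REF) != 1 or v.REF not in _BASES or not alts:
            continue
        if any(len(a) != 1 or a not in _BASES for a in alts):
            continue
        if "GT" not in (v.FORMAT or []):
            raise UnusableInputError(f"{vcf_path}: record lacks GT field")
        col = np.empty(len(accessions), dtype=np.int16)
        for i, g in enumerate(v.genotypes):
            a, b = g[0], g[1] if len(g) > 2 else g[0]
            if a < 0 or b < 0:
                col[i] = MISSING
            elif a == b:
                col[i] = a
            else:
                col[i] = HET
        sites.append(Site(v.CHROM, v.POS, v.REF, alts))
        columns.append(col)
    site_set = SiteSet(gene.gene_id, tuple(sites))
    calls = (
        np.column_stack(columns)
        if columns
        else np.empty((len(accessions), 0), dtype=np.int16)
    )
    return site_set, GenotypeMatrix(accessions, site_set, calls)


def filter_sites(
    gm: GenotypeMatrix, maf_min: float = 0.05, missing_max: float = 0.20
) -> GenotypeMatrix:
    """Keep sites with MAF >= ``maf_min`` and missing rate < ``missing_max``.

    The missing-rate bound is a strict inequality.  Idempotent.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0 <= missing_max <= 1:
        raise ValueError("missing_max must be in [0, 1]")
    if gm.n_sites == 0:
        return gm
    keep = (gm.maf() >= maf_min) & (gm.missing_rate() < missing_max)
    if not keep.any():
        warnings.warn(
            f"{gm.sites.gene_id}: all {gm.n_sites} sites removed by filters"
        )
    return gm.subset_sites(keep)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix back to a minimal VCF (diploid GT only).

    Heterozygotes are emitted as ``0/1`` (the code does not retain
    multi-allelic het identities); re-reading reproduces the codes.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted({s.chrom for s in gm.sites.sites})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.accessions)
            + "\n"
        )
        for j, site in enumerate(gm.sites.sites):
            col = gm.calls[:, j]
            gts = []
            for c in col:
                if c == MISSING:
                    gts.append("./.")
                elif c == HET:
                    gts.append("0/1")
                else:
                    gts.append(f"{c}/{c}")
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t"
                f"{','.join(site.alts)}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def extract_promoter(
    fasta: str | Path | Fasta, gene: GeneModel, length: int = 2000
) -> Promoter:
    """Extract the promoter: ``length`` bp upstream of the translation start.

    On the + strand this is the window ending one base before the ATG in
    genomic orientation; on the - strand it is the reverse complement of
    the window starting one base after the (genomically 3'-most) ATG.
    The sequence is uppercased; windows overrunning the contig are
    truncated and flagged.
    """
    fa = fasta if isinstance(fasta, Fasta) else Fasta(str(fasta))
    if gene.chrom not in fa:
        raise KeyError(f"chromosome {gene.chrom!r} not in FASTA")
    contig_len = len(fa[gene.chrom])
    w_start, w_end = gene.promoter_window(length)
    start = max(1, w_start)
    end = min(contig_len, w_end)
    truncated = (start != w_start) or (end != w_end)
    if start > end:
        warnings.warn(f"{gene.gene_id}: promoter empty after truncation")
        return Promoter("", True, start, start - 1)
    seq = str(fa[gene.chrom][start - 1 : end]).upper()
    if gene.strand == "-":
        seq = revcomp(seq)
    return Promoter(seq, truncated, start, end)


# ---------------------------------------------------------------------------
# Feature-context classification


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def classify_feature_context(
    interval: tuple[str, int, int],
    genes: Iterable[GeneModel],
    promoter_len: int = 2000,
) -> str:
    """Classify an interval as ``genic``, ``promoter`` or ``intergenic``.

    Genic means overlapping any gene's transcription unit; promoter
    means overlapping any gene's strand-aware upstream window.
    Precedence: genic > promoter > intergenic.
    """
    chrom, start, end = interval
    if start > end:
        raise ValueError(f"invalid interval: start {start} > end {end}")
    genes = list(genes)
    for g in genes:
        if g.chrom == chrom and _overlaps(start, end, g.start, g.end):
            return "genic"
    for g in genes:
        if g.chrom != chrom:
            continue
        p_start, p_end = g.promoter_window(promoter_len)
        if _overlaps(start, end, max(1, p_start), p_end):
            return "promoter"
    return "intergenic"
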