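"""Promoter cis-regulatory element (CRE) scanning and profiling.

Motifs are defined by IUPAC consensus strings in an editable TSV table
(columns ``name``, ``iupac``, ``category``) and grouped into five
functional categories: light-, stress-, hormone- and
development-responsive plus MYB-related.  The scanner counts every
overlapping occurrence on the forward strand and, in both-strand mode,
on the reverse complement as well (a palindromic hit therefore counts
twice, by design, so copy-number comparisons use one deterministic
maximal convention).

The bundled table approximates the consensus of 25 commonly profiled
plant CREs; it is illustrative, and correctness of a profile is defined
relative to whatever motif table the caller supplies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .breeding_shift import two_prop_test
from .io_genomics import PopulationLabels, revcomp

__all__ = [
    "CATEGORIES",
    "MotifDef",
    "CREProfile",
    "compile_motif",
    "scan_promoter",
    "scan_with_coords",
    "load_motif_table",
    "population_cre_profile",
]

CATEGORIES = ("light", "stress", "hormone", "development", "MYB-related")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class MotifDef:
    """One CRE: name, IUPAC consensus and functional category."""

    name: str
    iupac: str
    category: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError(f"motif {self.name!r}: empty IUPAC string")
        for i, ch in enumerate(self.iupac.upper()):
            if ch not in IUPAC:
                raise ValueError(
                    f"motif {self.name!r}: invalid IUPAC character "
                    f"{ch!r} at position {i + 1}"
                )
        if self.category not in CATEGORIES:
            raise ValueError(
                f"motif {self.name!r}: category must be one of {CATEGORIES}"
            )


def compile_motif(m: MotifDef | str) -> re.Pattern[str]:
    """Compile an IUPAC consensus into an overlap-counting regex.

    The pattern is a zero-width lookahead, so ``finditer`` yields every
    (possibly overlapping) start position.  Ambiguity codes expand to
    character classes over A/C/G/T only — an ``N`` in the *sequence*
    never matches.  Matching is case-insensitive.
    """
    iupac = m.iupac if isinstance(m, MotifDef) else m
    if not isinstance(m, MotifDef):  # validate bare strings too
        MotifDef("_anon", iupac, "light")
    parts = []
    for ch in iupac.upper():
        bases = IUPAC[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile(f"(?=({''.join(parts)}))", re.IGNORECASE)


def scan_with_coords(
    seq: str, motifs: Sequence[MotifDef], strands: str = "both"
) -> dict[str, list[tuple[int, str]]]:
    """Per-motif match coordinates: (0-based start on given strand, strand).

    Reverse-strand matches are found by scanning the reverse complement
    and reported with their start mapped back to forward coordinates.
    """
    if strands not in ("both", "forward"):
        raise ValueError("strands must be 'both' or 'forward'")
    seq_u = seq.upper()
    rc = revcomp(seq_u) if strands == "both" else ""
    out: dict[str, list[tuple[int, str]]] = {}
    for m in motifs:
        pat = compile_motif(m)
        hits = [(mt.start(), "+") for mt in pat.finditer(seq_u)]
        if strands == "both":
            L, w = len(seq_u), len(m.iupac)
            hits += [
                (L - mt.start() - w, "-") for mt in pat.finditer(rc)
            ]
        out[m.name] = sorted(hits)
    return out


def scan_promoter(
    seq: str, motifs: Sequence[MotifDef], strands: str = "both"
) -> dict[str, int]:
    """Count overlapping occurrences of each motif in a promoter."""
    return {
        name: len(hits)
        for name, hits in scan_with_coords(seq, motifs, strands).items()
    }


def load_motif_table(path: str | Path | None = None) -> list[MotifDef]:
    """Load a motif TSV (columns name, iupac, category).

    With no path the bundled illustrative table of 25 plant CREs is
    used.
    """
    if path is None:
        ref = resources.files("gchapkit").joinpath("data/motifs.tsv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    lines = [l for l in text.splitlines() if l.strip()]
    header = lines[0].split("\t")
    idx = {c: header.index(c) for c in ("name", "iupac", "category")}
    return [
        MotifDef(
            parts[idx["name"]], parts[idx["iupac"]], parts[idx["category"]]
        )
        for parts in (l.split("\t") for l in lines[1:])
    ]


@dataclass(frozen=True)
class CREProfile:
    """Per-accession motif copy counts and per-population summaries.

    ``counts`` has one row per (gene, accession, motif) with the copy
    count; ``population`` one row per (gene, population, motif) with
    presence frequency (fraction of accessions carrying >= 1 copy) and
    mean copy number; ``category_summary`` the mean number of distinct
    CRE types per category; ``discriminating`` the motifs whose
    presence frequency differs between two populations at p < 0.05
    (two-proportion chi-square).
    """

    counts: pd.DataFrame
    population: pd.DataFrame
    category_summary: pd.DataFrame
    discriminating: pd.DataFrame


def population_cre_profile(
    promoters: Mapping[tuple[str, str], str],
    motifs: Sequence[MotifDef],
    labels: PopulationLabels,
    strands: str = "both",
) -> CREProfile:
    """Profile motif content of per-accession promoters across populations.

    ``promoters`` maps (gene, accession) to the promoter sequence; an
    accession without a promoter for a gene simply drops out of that
    gene's denominators.
    """
    cat_of = {m.name: m.category for m in motifs}
    rows = []
    for (gene, acc), seq in promoters.items():
        counts = scan_promoter(seq, motifs, strands)
        pop = labels.subpopulation(acc)
        for name, c in counts.items():
            rows.append((gene, acc, pop, name, c))
    counts_df = pd.DataFrame(
        rows, columns=["gene", "accession", "population", "motif", "count"]
    )

    pop_rows = []
    for (gene, pop, motif), sub in counts_df.groupby(
        ["gene", "population", "motif"], sort=True
    ):
        n = len(sub)
        pop_rows.append(
            (
                gene, pop, motif, cat_of[motif], n,
                float((sub["count"] >= 1).mean()),
                float(sub["count"].mean()),
            )
        )
    pop_df = pd.DataFrame(
        pop_rows,
        columns=[
            "gene", "population", "motif", "category", "n_accessions",
            "presence_freq", "mean_copies",
        ],
    )

    cat_rows = []
    per_acc = counts_df[counts_df["count"] >= 1]
    for (gene, pop), sub in counts_df.groupby(["gene", "population"]):
        accs = sub["accession"].unique()
        for cat in CATEGORIES:
            motifs_in_cat = [m.name for m in motifs if m.category == cat]
            present = per_acc[
                (per_acc["gene"] == gene)
                & (per_acc["population"] == pop)
                & (per_acc["motif"].isin(motifs_in_cat))
            ]
            types_per_acc = present.groupby("accession")["motif"].nunique()
            mean_types = (
                float(types_per_acc.reindex(accs, fill_value=0).mean())
                if len(accs)
                else 0.0
            )
            cat_rows.append((gene, pop, cat, mean_types))
    cat_df = pd.DataFrame(
        cat_rows, columns=["gene", "population", "category", "mean_types"]
    )

    disc_rows = []
    for (gene, motif), sub in counts_df.groupby(["gene", "motif"]):
        pops = sorted(sub["population"].unique())
        for pa, pb in ((x, y) for i, x in enumerate(pops) for y in pops[i + 1:]):
            va = sub[sub["population"] == pa]["count"]
            vb = sub[sub["population"] == pb]["count"]
            a, n1 = int((va >= 1).sum()), len(va)
            b, n2 = int((vb >= 1).sum()), len(vb)
            if n1 == 0 or n2 == 0:
                continue
            chi2, _z, p = two_prop_test(a, n1, b, n2)
            if p < 0.05:
                disc_rows.append(
                    (gene, motif, pa, pb, a / n1, b / n2, chi2, p)
                )
    disc_df = pd.DataFrame(
        disc_rows,
        columns=[
            "gene", "motif", "pop_a", "pop_b", "freq_a", "freq_b", "chi2", "p",
        ],
    )
    return CREProfile(counts_df, pop_df, cat_df, disc_df)
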