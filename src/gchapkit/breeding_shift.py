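"""Frequency shifts of predominant gcHaps under modern breeding.

Landraces (LAN) carry the ancestral haplotype spectrum of a
subpopulation; a drop of the predominant haplotype's frequency in
modern varieties (MV) signals artificial selection during breeding.
The module tests that drop with a two-proportion chi-square / Z test,
compares Shannon's equitability between the classes with a bootstrap Z,
and lists newly emergent haplotypes (present in MV, absent from LAN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .gchap_core import GcHapCensus, shannon_equitability
from .io_genomics import PopulationLabels

__all__ = [
    "ShiftResult",
    "EmergentHap",
    "EmergentReport",
    "two_prop_test",
    "predominant_shift",
    "emergent_haps",
    "significance_stars",
]

GLOBAL_SCOPE = "ALL"


def significance_stars(p: float) -> str:
    """Figure-legend star convention: ****, **, * at 1e-4, 0.01, 0.05."""
    if p < 1e-4:
        return "****"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def two_prop_test(
    a: int, n1: int, b: int, n2: int, correction: bool = False
) -> tuple[float, float, float]:
    """Two-proportion test on counts ``a/n1`` vs ``b/n2``.

    Returns ``(chi2, z, p)``: the 1-df chi-square on the 2x2 table, the
    pooled two-proportion z statistic signed by ``a/n1 - b/n2`` and the
    chi-square tail p-value.  Without the optional Yates correction,
    z**2 equals chi2 exactly.  Tables with both proportions 0 or both 1
    are degenerate: statistic 0, p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= a <= n1 and 0 <= b <= n2):
        raise ValueError("counts must satisfy 0 <= a <= n1, 0 <= b <= n2")
    c, d = n1 - a, n2 - b
    total = n1 + n2
    col1, col2 = a + b, c + d
    if col1 == 0 or col2 == 0:
        return 0.0, 0.0, 1.0
    diff = abs(a * d - b * c)
    if correction:
        diff = max(0.0, diff - total / 2.0)
    chi2 = total * diff**2 / (n1 * n2 * col1 * col2)
    sign = 1.0 if a / n1 >= b / n2 else -1.0
    z = sign * math.sqrt(chi2)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), float(z), p


@dataclass(frozen=True)
class ShiftResult:
    """Predominant-haplotype LAN vs MV comparison for one gene."""

    gene_id: str
    subpopulation: str
    hap_name: str
    n_lan: int
    n_mv: int
    count_lan: int
    count_mv: int
    freq_lan: float
    freq_mv: float
    delta: float  # freq_mv - freq_lan
    chi2: float
    z: float
    p_value: float
    stars: str
    eh_lan: float
    eh_mv: float
    eh_z: float
    eh_p: float
    insufficient: bool = False


def _class_assignments(
    census: GcHapCensus, labels: PopulationLabels, subpop: str
) -> dict[str, np.ndarray]:
    """Hap-index arrays for the LAN and MV accessions of one scope."""
    out: dict[str, list[int]] = {"LAN": [], "MV": []}
    for k, hap in enumerate(census.haps):
        for acc in hap.carriers:
            if subpop != GLOBAL_SCOPE and labels.subpopulation(acc) != subpop:
                continue
            cls = labels.breeding_class(acc)
            if cls in out:
                out[cls].append(k)
    return {c: np.array(v, dtype=int) for c, v in out.items()}


def _eh_of_assignment(assign: np.ndarray) -> float:
    if assign.size == 0:
        return 0.0
    counts = np.bincount(assign)
    counts = counts[counts > 0]
    return shannon_equitability(counts) if counts.size else 0.0


def _bootstrap_eh_z(
    lan: np.ndarray,
    mv: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Bootstrap z for the E_H difference between two accession sets.

    Accessions are resampled with replacement within each class; the
    normal approximation on the bootstrap standard errors gives the z
    and its two-sided p-value.
    """
    def se(assign: np.ndarray) -> float:
        idx = rng.integers(0, assign.size, size=(n_boot, assign.size))
        vals = np.empty(n_boot)
        for b in range(n_boot):
            vals[b] = _eh_of_assignment(assign[idx[b]])
        return float(vals.std(ddof=1))

    d = _eh_of_assignment(lan) - _eh_of_assignment(mv)
    s = math.hypot(se(lan), se(mv))
    if s == 0.0:
        return 0.0, 1.0
    z = d / s
    return z, float(2.0 * stats.norm.sf(abs(z)))


def predominant_shift(
    census: GcHapCensus,
    labels: PopulationLabels,
    scope: str = "per_subpop",
    n_boot: int = 1000,
    seed: int | None = None,
) -> list[ShiftResult]:
    """Test the predominant haplotype's LAN vs MV frequency shift.

    ``scope='per_subpop'`` runs one comparison per subpopulation using
    that subpopulation's own predominant haplotype; ``scope='global'``
    runs a single panel-wide comparison on the global predominant
    haplotype.  E_H is compared between the classes with a seeded
    percentile-bootstrap z (``n_boot`` resamples; 0 skips the E_H test).
    A class with zero classified accessions yields a result flagged
    ``insufficient`` and no test.
    """
    if scope not in ("per_subpop", "global"):
        raise ValueError("scope must be 'per_subpop' or 'global'")
    rng = np.random.default_rng(seed)
    if scope == "global":
        subpops = [GLOBAL_SCOPE]
    else:
        subpops = sorted(
            {
                labels.subpopulation(a)
                for h in census.haps
                for a in h.carriers
                if labels.breeding_class(a) in ("LAN", "MV")
            }
        )
    results: list[ShiftResult] = []
    for sp in subpops:
        assign = _class_assignments(census, labels, sp)
        lan, mv = assign["LAN"], assign["MV"]
        n1, n2 = lan.size, mv.size
        if n1 == 0 or n2 == 0:
            results.append(
                ShiftResult(
                    census.gene_id, sp, "", n1, n2, 0, 0,
                    math.nan, math.nan, math.nan, math.nan, math.nan,
                    math.nan, "ns", math.nan, math.nan, math.nan, math.nan,
                    insufficient=True,
                )
            )
            continue
        # predominant hap within this scope (ties resolve to the lower
        # Hap index because bincount/argmax scan in hap order)
        both = np.concatenate([lan, mv])
        k_pred = int(np.argmax(np.bincount(both)))
        hap_name = census.haps[k_pred].hap_name
        a = int((lan == k_pred).sum())
        b = int((mv == k_pred).sum())
        chi2, z, p = two_prop_test(a, n1, b, n2)
        if n_boot > 0:
            eh_z, eh_p = _bootstrap_eh_z(lan, mv, n_boot, rng)
        else:
            eh_z, eh_p = math.nan, math.nan
        results.append(
            ShiftResult(
                census.gene_id, sp, hap_name, n1, n2, a, b,
                a / n1, b / n2, b / n2 - a / n1,
                chi2, z, p, significance_stars(p),
                _eh_of_assignment(lan), _eh_of_assignment(mv), eh_z, eh_p,
            )
        )
    return results


@dataclass(frozen=True)
class EmergentHap:
    hap_name: str
    mv_count: int
    mv_freq: float


@dataclass(frozen=True)
class EmergentReport:
    """Haplotypes present in modern varieties but absent from landraces."""

    gene_id: str
    by_subpop: dict[str, tuple[EmergentHap, ...]] = field(default_factory=dict)


def emergent_haps(
    census: GcHapCensus, labels: PopulationLabels
) -> EmergentReport:
    """List per-subpopulation haplotypes with zero LAN and >= 1 MV carriers."""
    subpops = sorted(
        {
            labels.subpopulation(a)
            for h in census.haps
            for a in h.carriers
            if labels.breeding_class(a) in ("LAN", "MV")
        }
    )
    report: dict[str, tuple[EmergentHap, ...]] = {}
    for sp in subpops:
        n_mv_total = sum(
            1
            for h in census.haps
            for a in h.carriers
            if labels.subpopulation(a) == sp
            and labels.breeding_class(a) == "MV"
        )
        entries = []
        for h in census.haps:
            lan = mv = 0
            for acc in h.carriers:
                if labels.subpopulation(acc) != sp:
                    continue
                cls = labels.breeding_class(acc)
                if cls == "LAN":
                    lan += 1
                elif cls == "MV":
                    mv += 1
            if lan == 0 and mv >= 1:
                entries.append(
                    EmergentHap(h.hap_name, mv, mv / n_mv_total)
                )
        report[sp] = tuple(entries)
    return EmergentReport(census.gene_id, report)
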