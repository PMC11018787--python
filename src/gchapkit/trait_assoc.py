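"""Haplotype-trait association: ANOVA, Duncan's multiple range test,
compact letter display, and linkage-disequilibrium half-decay distance.

Accessions are grouped by major haplotype; group means of a
quantitative trait are compared by analysis of variance and, when the
omnibus test allows, separated by Duncan's multiple range test at the
chosen alpha.  Groups sharing no letter in the compact letter display
differ significantly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import studentized_range

from .gchap_core import GcHapCensus, major_haps
from .io_genomics import HET, MISSING, GenotypeMatrix, PopulationLabels

__all__ = [
    "AnovaResult",
    "AssocResult",
    "LDDecay",
    "oneway_anova",
    "duncan_mrt",
    "hap_trait_assoc",
    "ld_half_decay",
]


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p_value: float
    mse: float
    df_error: int
    df_between: int
    group_stats: dict[str, tuple[int, float, float]]  # name -> (n, mean, sd)


def oneway_anova(
    values: Sequence[float], group_labels: Sequence[str]
) -> AnovaResult:
    """Classical one-way between/within ANOVA decomposition.

    Groups with fewer than two observations are dropped with a warning;
    fewer than two usable groups is an error.  Zero within-group
    variance with differing means is guarded: F is infinite and the
    p-value underflows to 0 (< 1e-300).
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    ok = ~np.isnan(values)
    values, group_labels = values[ok], group_labels[ok]
    groups: dict[str, np.ndarray] = {}
    for g in pd.unique(group_labels):
        v = values[group_labels == g]
        if v.size < 2:
            warnings.warn(f"group {g!r} has < 2 observations; dropped")
            continue
        groups[str(g)] = v
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")
    n_total = sum(v.size for v in groups.values())
    grand = sum(v.sum() for v in groups.values()) / n_total
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b, df_e = k - 1, n_total - k
    msb, mse = ssb / df_b, ssw / df_e
    if mse == 0.0:
        f = math.inf if msb > 0 else 0.0
        p = 0.0 if msb > 0 else 1.0
    else:
        f = msb / mse
        p = float(stats.f.sf(f, df_b, df_e))
    gstats = {
        name: (int(v.size), float(v.mean()), float(v.std(ddof=1)))
        for name, v in groups.items()
    }
    return AnovaResult(float(f), p, float(mse), df_e, df_b, gstats)


from functools import lru_cache


@lru_cache(maxsize=4096)
def _duncan_critical(p_span: int, df_error: int, alpha: float) -> float:
    """Duncan's least-significant-range multiplier q*(p, df).

    Uses the studentized-range quantile at Duncan's protection level
    alpha_p = 1 - (1 - alpha)**(p - 1).  Cached: the quantile inversion
    is numerically expensive and the same (span, df) pairs recur.
    """
    alpha_p = 1.0 - (1.0 - alpha) ** (p_span - 1)
    return float(studentized_range.isf(alpha_p, p_span, df_error))


def _significant_pairs(
    means_sorted: np.ndarray,
    ns_sorted: np.ndarray,
    mse: float,
    df_error: int,
    alpha: float,
) -> set[tuple[int, int]]:
    """Pairs (i, j), i < j in descending-mean order, declared different.

    A stretch of p ranked means is non-significant when its end-gap does
    not exceed R_p = q*(p, df) * sqrt(MSE / n_h) with n_h the harmonic
    mean of the stretch's group sizes; a stretch enclosed by any
    non-significant stretch is itself declared non-significant
    (containment rule).
    """
    k = means_sorted.size
    raw_nonsig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            span = j - i + 1
            n_h = span / (1.0 / ns_sorted[i : j + 1]).sum()
            r_p = _duncan_critical(span, df_error, alpha) * math.sqrt(
                mse / n_h
            )
            if means_sorted[i] - means_sorted[j] <= r_p:
                raw_nonsig[i, j] = True
    sig: set[tuple[int, int]] = set()
    for i in range(k):
        for j in range(i + 1, k):
            covered = any(
                raw_nonsig[i2, j2]
                for i2 in range(i + 1)
                for j2 in range(j, k)
            )
            if not covered:
                sig.add((i, j))
    return sig


def _insert_absorb_letters(k: int, sig: set[tuple[int, int]]) -> list[str]:
    """Compact letter display by insert-and-absorb.

    Groups are indexed in descending-mean order; returns one letter
    string per group such that two groups share a letter iff they were
    not declared significantly different.
    """
    columns: list[set[int]] = [set(range(k))]
    for i, j in sorted(sig):
        new_cols: list[set[int]] = []
        for col in columns:
            if i in col and j in col:
                new_cols.append(col - {i})
                new_cols.append(col - {j})
            else:
                new_cols.append(col)
        # absorb columns that are subsets of others
        new_cols.sort(key=len, reverse=True)
        kept: list[set[int]] = []
        for col in new_cols:
            if not any(col <= other for other in kept):
                kept.append(col)
        columns = kept
    columns.sort(key=lambda c: (min(c), -len(c)))
    letters = [""] * k
    for li, col in enumerate(columns):
        ch = chr(ord("a") + li) if li < 26 else f"({li})"
        for g in sorted(col):
            letters[g] += ch
    return letters


def duncan_mrt(
    means: Mapping[str, float] | Sequence[float],
    ns: Mapping[str, int] | Sequence[int],
    mse: float,
    df_error: int,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Duncan's multiple range test with compact letter display.

    ``means`` and ``ns`` are parallel mappings (or sequences, keyed by
    position) of group means and sizes; ``mse`` and ``df_error`` come
    from the ANOVA.  Unequal sizes use the harmonic mean of the
    stretch's group sizes (Kramer adjustment).  Returns group -> letter
    string; groups sharing no letter differ at ``alpha``.
    """
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    if isinstance(means, Mapping):
        names = list(means)
        mean_arr = np.array([means[g] for g in names], dtype=float)
        n_arr = np.array([ns[g] for g in names], dtype=float)
    else:
        mean_arr = np.asarray(means, dtype=float)
        n_arr = np.asarray(ns, dtype=float)
        names = [str(i) for i in range(mean_arr.size)]
    if mean_arr.size == 1:
        return {names[0]: "a"}
    order = np.lexsort((np.arange(mean_arr.size), -mean_arr))
    sig = _significant_pairs(
        mean_arr[order], n_arr[order], mse, df_error, alpha
    )
    letters_sorted = _insert_absorb_letters(mean_arr.size, sig)
    out: dict[str, str] = {}
    for rank, idx in enumerate(order):
        out[names[idx]] = letters_sorted[rank]
    return out


@dataclass(frozen=True)
class AssocResult:
    """One gene x trait haplotype association."""

    gene_id: str
    trait: str
    groups: dict[str, tuple[int, float, float]]  # hap -> (n, mean, sd)
    f: float
    p_value: float
    mse: float
    df_error: int
    letters: dict[str, str]
    factor_p: dict[str, float] | None = None  # two-way per-factor p-values


def hap_trait_assoc(
    census: GcHapCensus,
    phenotypes: pd.DataFrame,
    labels: PopulationLabels | None = None,
    min_carriers: int = 50,
    alpha: float = 0.05,
    two_way: bool = False,
    traits: Sequence[str] | None = None,
) -> list[AssocResult]:
    """Associate a gene's major haplotypes with quantitative traits.

    ``phenotypes`` is indexed by accession with one numeric column per
    trait.  Genes with fewer than two major haplotypes are skipped.
    With ``two_way=True`` an additive subpopulation factor is fitted
    (Type II sums of squares via statsmodels); the haplotype F/p and the
    residual MSE then come from that model, and the per-factor p-values
    are reported alongside.
    """
    majors = major_haps(census, min_carriers)
    if len(majors) < 2:
        return []
    hap_of = {acc: h.hap_name for h in majors for acc in h.carriers}
    traits = list(traits) if traits is not None else list(phenotypes.columns)
    results: list[AssocResult] = []
    for trait in traits:
        series = phenotypes[trait]
        accs = [a for a in hap_of if a in series.index and pd.notna(series[a])]
        if not accs:
            warnings.warn(f"{census.gene_id}/{trait}: no phenotyped carriers")
            continue
        vals = np.array([float(series[a]) for a in accs])
        grps = np.array([hap_of[a] for a in accs])
        factor_p = None
        if two_way and labels is not None:
            import statsmodels.api as sm
            import statsmodels.formula.api as smf

            df = pd.DataFrame(
                {
                    "y": vals,
                    "hap": grps,
                    "subpop": [labels.subpopulation(a) for a in accs],
                }
            )
            if df["subpop"].nunique() < 2 or df["hap"].nunique() < 2:
                two_way_ok = False
            else:
                two_way_ok = True
            if two_way_ok:
                model = smf.ols("y ~ C(hap) + C(subpop)", data=df).fit()
                tbl = sm.stats.anova_lm(model, typ=2)
                f = float(tbl.loc["C(hap)", "F"])
                p = float(tbl.loc["C(hap)", "PR(>F)"])
                df_e = int(tbl.loc["Residual", "df"])
                mse = float(
                    tbl.loc["Residual", "sum_sq"] / tbl.loc["Residual", "df"]
                )
                factor_p = {
                    "hap": p,
                    "subpop": float(tbl.loc["C(subpop)", "PR(>F)"]),
                }
                gstats = {
                    g: (
                        int((grps == g).sum()),
                        float(vals[grps == g].mean()),
                        float(vals[grps == g].std(ddof=1)),
                    )
                    for g in pd.unique(grps)
                }
                aov = AnovaResult(f, p, mse, df_e, df["hap"].nunique() - 1, gstats)
            else:
                aov = oneway_anova(vals, grps)
        else:
            try:
                aov = oneway_anova(vals, grps)
            except ValueError:
                warnings.warn(
                    f"{census.gene_id}/{trait}: fewer than 2 usable groups"
                )
                continue
        means = {g: s[1] for g, s in aov.group_stats.items()}
        sizes = {g: s[0] for g, s in aov.group_stats.items()}
        letters = duncan_mrt(means, sizes, aov.mse, aov.df_error, alpha)
        results.append(
            AssocResult(
                census.gene_id, trait, aov.group_stats, aov.f, aov.p_value,
                aov.mse, aov.df_error, letters, factor_p,
            )
        )
    return results


# ---------------------------------------------------------------------------
# LD decay


@dataclass(frozen=True)
class LDDecay:
    distances: np.ndarray  # per retained pair, bp
    r2: np.ndarray
    bin_mids: np.ndarray
    bin_means: np.ndarray
    half_decay_distance: float


def ld_half_decay(
    gm: GenotypeMatrix,
    positions: Sequence[int] | None = None,
    bin_bp: int = 1000,
) -> LDDecay:
    """r-squared LD decay profile and half-decay distance.

    Genotypes are coded as alternate-allele dosage (0 / 1 for HET / 2);
    missing calls are pairwise deleted; monomorphic members of a pair
    are skipped.  r2 is the squared Pearson correlation of dosages.
    Pairs are binned by distance; the half-decay distance is the first
    bin midpoint at which the mean r2 drops to half the maximum bin
    mean.
    """
    if gm.n_sites < 2:
        raise ValueError("need at least 2 sites")
    pos = (
        np.asarray(positions, dtype=float)
        if positions is not None
        else gm.sites.positions.astype(float)
    )
    dosage = np.where(
        gm.calls == MISSING,
        np.nan,
        np.where(gm.calls == HET, 1.0, np.where(gm.calls >= 1, 2.0, 0.0)),
    )
    dists: list[float] = []
    r2s: list[float] = []
    n_sites = gm.n_sites
    for i in range(n_sites):
        xi = dosage[:, i]
        for j in range(i + 1, n_sites):
            xj = dosage[:, j]
            ok = ~np.isnan(xi) & ~np.isnan(xj)
            if ok.sum() < 2:
                continue
            a, b = xi[ok], xj[ok]
            if a.std() == 0 or b.std() == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            dists.append(abs(pos[j] - pos[i]))
            r2s.append(r * r)
    dist_arr = np.array(dists)
    r2_arr = np.array(r2s)
    if dist_arr.size == 0:
        return LDDecay(dist_arr, r2_arr, np.array([]), np.array([]), math.nan)
    n_bins = int(dist_arr.max() // bin_bp) + 1
    idx = (dist_arr // bin_bp).astype(int)
    mids, means = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            mids.append((b + 0.5) * bin_bp)
            means.append(r2_arr[sel].mean())
    mids_arr, means_arr = np.array(mids), np.array(means)
    half = means_arr.max() / 2.0
    below = np.flatnonzero(means_arr <= half)
    half_decay = float(mids_arr[below[0]]) if below.size else math.nan
    return LDDecay(dist_arr, r2_arr, mids_arr, means_arr, half_decay)
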