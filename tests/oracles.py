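"""Independent brute-force reference implementations used by the tests.

Each oracle recomputes a statistic from its definition by a different
route than the package (dictionary grouping, exhaustive enumeration,
library calls), so agreement is evidence of correctness rather than of
shared code.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
from scipy import stats


# -- haplotype grouping ------------------------------------------------------


def bf_gchap_counts(calls: np.ndarray) -> list[int]:
    """String-join + dict grouping of fully-called rows ('drop' policy)."""
    groups: dict[str, int] = {}
    n_excluded = 0
    for row in calls:
        if (row < 0).any():
            n_excluded += 1
            continue
        key = ",".join(str(int(x)) for x in row)
        groups[key] = groups.get(key, 0) + 1
    counts = sorted(groups.values(), reverse=True)
    return counts


# -- Shannon's equitability --------------------------------------------------


def bf_shannon(counts) -> float:
    total = sum(counts)
    k = len(counts)
    if k == 1:
        return 0.0
    h = 0.0
    for c in counts:
        p = c / total
        h -= p * math.log(p)
    return h / math.log(k)


# -- two-proportion chi-square ----------------------------------------------


def bf_two_prop(a: int, n1: int, b: int, n2: int) -> tuple[float, float]:
    """(chi2, p) via scipy's contingency-table machinery."""
    table = np.array([[a, n1 - a], [b, n2 - b]])
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


# -- one-way ANOVA -----------------------------------------------------------


def bf_anova(values, labels) -> tuple[float, float, float, int]:
    """(F, p, MSE, df_error) via scipy.f_oneway plus pooled variance."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in sorted(set(labels.tolist()))]
    res = stats.f_oneway(*groups)
    n = sum(len(g) for g in groups)
    df_e = n - len(groups)
    sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return float(res.statistic), float(res.pvalue), sse / df_e, df_e


def exact_f_ratio(groups: list[list[int]]) -> Fraction:
    """F statistic in exact rational arithmetic for integer data."""
    all_vals = [Fraction(v) for g in groups for v in g]
    n = len(all_vals)
    k = len(groups)
    grand = sum(all_vals, Fraction(0)) / n
    ssb = Fraction(0)
    ssw = Fraction(0)
    for g in groups:
        m = sum((Fraction(v) for v in g), Fraction(0)) / len(g)
        ssb += len(g) * (m - grand) ** 2
        ssw += sum(((Fraction(v) - m) ** 2 for v in g), Fraction(0))
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    return msb / msw


# -- Duncan's multiple range test -------------------------------------------


from functools import lru_cache


@lru_cache(maxsize=4096)
def _q_duncan(span: int, df: int, alpha: float) -> float:
    from scipy.stats import studentized_range

    alpha_p = 1 - (1 - alpha) ** (span - 1)
    return float(studentized_range.isf(alpha_p, span, df))


def bf_duncan_significant(
    means: np.ndarray, ns: np.ndarray, mse: float, df_error: int, alpha: float
) -> set[tuple[int, int]]:
    """Pairs (sorted-order indices) significantly different, derived by
    testing every stretch directly from the least-significant-range
    definition with the containment rule."""
    order = np.lexsort((np.arange(means.size), -means))
    m, n = means[order], ns[order]
    k = m.size

    def stretch_significant(i: int, j: int) -> bool:
        span = j - i + 1
        q = _q_duncan(span, df_error, alpha)
        n_h = span / sum(1.0 / n[t] for t in range(i, j + 1))
        return (m[i] - m[j]) > q * math.sqrt(mse / n_h)

    sig = set()
    for i in range(k):
        for j in range(i + 1, k):
            if all(
                stretch_significant(i2, j2)
                for i2 in range(i + 1)
                for j2 in range(j, k)
            ):
                sig.add((int(order[i]), int(order[j])))
    return sig


# -- minimum spanning tree ---------------------------------------------------


def bf_mst_weight(dist: np.ndarray) -> int:
    """Minimum spanning-tree weight by enumerating all spanning trees."""
    n = dist.shape[0]
    if n == 1:
        return 0
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = None
    for combo in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for i, j in combo:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[rj] = ri
        if not ok:
            continue
        w = sum(dist[i, j] for i, j in combo)
        if best is None or w < best:
            best = w
    return int(best)


# -- IUPAC motif scanning ----------------------------------------------------

_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _rc(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def bf_scan(seq: str, iupac: str, strands: str = "both") -> int:
    """Expand the IUPAC code to its literal set and compare every window."""
    literals = {
        "".join(combo)
        for combo in itertools.product(*(_IUPAC_SETS[c] for c in iupac.upper()))
    }
    w = len(iupac)

    def count(s: str) -> int:
        return sum(1 for i in range(len(s) - w + 1) if s[i : i + w] in literals)

    seq = seq.upper()
    total = count(seq)
    if strands == "both":
        total += count(_rc(seq))
    return total


# -- Nei-Gojobori 1986 -------------------------------------------------------


def _aa(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


def bf_ng86(seq1: str, seq2: str) -> tuple[float, float]:
    """(Ka, Ks) recomputed from the NG86 definitions via Biopython's
    translation, with stop-producing changes nonsynonymous and
    stop-traversing pathways excluded (falling back to all)."""
    codons1 = [seq1[i : i + 3] for i in range(0, len(seq1), 3)]
    codons2 = [seq2[i : i + 3] for i in range(0, len(seq2), 3)]

    def sites(codons):
        s = 0.0
        for codon in codons:
            ref_aa = _aa(codon)
            for pos in range(3):
                syn = sum(
                    1
                    for base in "ACGT"
                    if base != codon[pos]
                    and _aa(codon[:pos] + base + codon[pos + 1 :]) == ref_aa
                    and _aa(codon[:pos] + base + codon[pos + 1 :]) != "*"
                )
                s += syn / 3.0
        return s

    S = (sites(codons1) + sites(codons2)) / 2.0
    N = len(seq1) - S

    sd = nd = 0.0
    for c1, c2 in zip(codons1, codons2):
        positions = [p for p in range(3) if c1[p] != c2[p]]
        if not positions:
            continue
        paths = []
        all_paths = []
        for perm in itertools.permutations(positions):
            cur, s_cnt, n_cnt, hit_stop = c1, 0, 0, False
            for p in perm:
                nxt = cur[:p] + c2[p] + cur[p + 1 :]
                if _aa(nxt) == _aa(cur) and _aa(cur) != "*":
                    s_cnt += 1
                else:
                    n_cnt += 1
                if _aa(nxt) == "*":
                    hit_stop = True
                cur = nxt
            all_paths.append((s_cnt, n_cnt))
            if not hit_stop:
                paths.append((s_cnt, n_cnt))
        use = paths if paths else all_paths
        sd += sum(p[0] for p in use) / len(use)
        nd += sum(p[1] for p in use) / len(use)

    ps, pn = sd / S, nd / N
    ks = -0.75 * math.log(1 - 4 * ps / 3)
    ka = -0.75 * math.log(1 - 4 * pn / 3)
    return ka, ks
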