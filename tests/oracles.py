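"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by a route deliberately different from
the package implementation: exhaustive enumeration in exact rational
arithmetic for the exact tests, all-pairs scans for nearest-TSS search,
and textbook summation formulas for moments and correlation.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np

_TIE = Fraction(10_000_001, 10_000_000)  # 1 + 1e-7 relative tie tolerance


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by enumerating all tables with the same margins.

    Point probabilities from the factorial form of the hypergeometric pmf
    in exact rational arithmetic.
    """
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2
    f = math.factorial

    def prob(x: int) -> Fraction | None:
        bb, cc, dd = r1 - x, c1 - x, r2 - (c1 - x)
        if min(x, bb, cc, dd) < 0:
            return None
        return Fraction(
            f(r1) * f(r2) * f(c1) * f(c2),
            f(n) * f(x) * f(bb) * f(cc) * f(dd),
        )

    p_obs = prob(a)
    assert p_obs is not None
    cutoff = p_obs * _TIE
    return sum(p for x in range(c1 + 1) if (p := prob(x)) is not None and p <= cutoff)


def hypergeom_upper_enum(n_univ: int, n_cat: int, n_draw: int, k: int) -> Fraction:
    """P[overlap >= k] by enumerating every possible draw of the universe."""
    cat = set(range(n_cat))
    hits = sum(
        1
        for draw in itertools.combinations(range(n_univ), n_draw)
        if len(cat.intersection(draw)) >= k
    )
    return Fraction(hits, math.comb(n_univ, n_draw))


def nearest_tss_allpairs(centers, chroms_r, tss, chroms_g, gene_ids):
    """All-pairs nearest-TSS scan with lexicographic tie-break.

    Returns (gene_id, abs_distance) per region; ('no_gene', nan) when the
    region's chromosome has no genes.
    """
    tss = np.asarray(tss, dtype=np.int64)
    out = []
    for center, chrom in zip(centers, chroms_r):
        mask = np.asarray(chroms_g) == chrom
        if not mask.any():
            out.append(("no_gene", float("nan")))
            continue
        d = np.abs(tss[mask] - int(center))
        dmin = d.min()
        ties = np.asarray(gene_ids)[mask][d == dmin]
        out.append((min(ties), float(dmin)))
    return out


def pearson_textbook(x, y) -> float:
    """Sum-formula Pearson correlation, no numpy statistics calls."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


def mean_sd_population(values):
    """Looped mean and population SD (divide by n)."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    return mean, math.sqrt(var)


def fisher_z_interval(rho: float, n: int, z: float = 2.576):
    """Fisher-z confidence interval for a sample correlation at planted rho."""
    center = math.atanh(rho)
    half = z / math.sqrt(n - 3)
    return math.tanh(center - half), math.tanh(center + half)
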