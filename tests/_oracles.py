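"""Independent brute-force oracles used by the test suite.

Every function here recomputes a quantity by a route deliberately
different from the package implementation (exact rational arithmetic,
full enumeration, naive counting), so agreement is meaningful.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb


def categorize_oracle(i: int, N: int) -> tuple[str, bool, bool]:
    """Third-bin classification via explicit Fraction comparisons."""
    r = Fraction(i, N)
    if r <= Fraction(1, 3):
        bin_ = "first"
    elif r <= Fraction(2, 3):
        bin_ = "second"
    else:
        bin_ = "third"
    return bin_, r == Fraction(1, 2), r == 1


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration in Fractions."""
    r1, r2 = a + b, c + d
    c1 = a + c
    denom = comb(r1 + r2, c1)

    def prob(x: int) -> Fraction | None:
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return None
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(r1 + 1):
        p = prob(x)
        if p is not None and p <= p_obs:
            total += p
    return float(total)


def mann_whitney_permutation_p(x, y) -> float:
    """Two-sided Mann-Whitney p by exhaustive relabelling enumeration.

    p = fraction of group assignments whose U statistic is at least as
    far from its null mean as the observed one.  Exact for tie-free
    pooled samples.
    """
    pooled = list(x) + list(y)
    n1 = len(x)
    mean_u = n1 * len(y) / 2.0

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    obs_dev = abs(u_stat(x, y) - mean_u)
    hits = total = 0
    idx = range(len(pooled))
    for combo in combinations(idx, n1):
        sel = set(combo)
        xs = [pooled[k] for k in idx if k in sel]
        ys = [pooled[k] for k in idx if k not in sel]
        if abs(u_stat(xs, ys) - mean_u) >= obs_dev - 1e-12:
            hits += 1
        total += 1
    return hits / total


def count_positions_oracle(records, min_introns=3):
    """Naive per-category recount of a record collection."""
    kept = [r for r in records if r.N >= min_introns]
    out = {f"I{k}": 0 for k in range(1, 6)}
    out[">I5"] = 0
    out.update({"first": 0, "second": 0, "third": 0, "middle": 0, "last": 0})
    for r in kept:
        out[f"I{r.i}" if r.i <= 5 else ">I5"] += 1
        out[r.third_bin] += 1
        out["middle"] += r.is_middle
        out["last"] += r.is_last
    return len(kept), out


def derive_introns_oracle(exons, strand):
    """Per-pair subtraction, written independently of the implementation."""
    gaps = []
    for k in range(len(exons) - 1):
        gaps.append(exons[k + 1][0] - exons[k][1] - 1)
    return gaps[::-1] if strand == "-" else gaps
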