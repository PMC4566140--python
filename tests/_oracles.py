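"""Independent brute-force oracles used to verify the fast implementations.

Everything here favours transparency over speed: explicit enumeration,
direct summation, naive scans.  None of it imports the code paths it
checks beyond shared constants/definitions of the problem statement.
"""

from __future__ import annotations

import itertools

import mpmath

# --- folding ---------------------------------------------------------------

_PAIRABLE_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")}
_PAIRABLE_GU = {("G", "T"), ("T", "G"), ("G", "U"), ("U", "G")}


def _ptype(a: str, b: str) -> int:
    if (a, b) in _PAIRABLE_WC:
        return 1
    if (a, b) in _PAIRABLE_GU:
        return 2
    return 0


def enumerate_chains(seq, min_loop=3, max_interior=10):
    """Yield every single-stem structure (outer-to-inner chain of nested
    pairs) of the model class: pairable ends, hairpin loop >= min_loop,
    at most max_interior unpaired nt per side between consecutive pairs."""
    n = len(seq)
    pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + min_loop + 1, n)
        if _ptype(seq[i], seq[j])
    ]

    def extend(chain):
        yield chain
        i, j = chain[-1]
        for (k, l) in pairs:
            if i < k < l < j and k - i - 1 <= max_interior and j - l - 1 <= max_interior:
                yield from extend(chain + [(k, l)])

    for p in pairs:
        yield from extend([p])


def chain_energy(
    seq,
    chain,
    stack_ww=-2.0,
    stack_wg=-1.0,
    stack_gg=-0.5,
    hairpin=3.0,
    bulge=2.0,
    internal=1.5,
):
    """Score one chain under the published constants, written independently."""
    e = hairpin
    for (oi, oj), (ii, ij) in zip(chain, chain[1:]):
        left, right = ii - oi - 1, oj - ij - 1
        if left == 0 and right == 0:
            t1, t2 = _ptype(seq[oi], seq[oj]), _ptype(seq[ii], seq[ij])
            e += {(1, 1): stack_ww, (2, 2): stack_gg}.get((t1, t2), stack_wg)
        elif left == 0 or right == 0:
            e += bulge
        else:
            e += internal
    return e


def brute_force_mfe(seq, min_loop=3, max_interior=10):
    """Exhaustive minimum energy over the structure class (0 if nothing
    scores below the empty structure)."""
    best = 0.0
    for chain in enumerate_chains(seq, min_loop, max_interior):
        e = chain_energy(seq, chain)
        if e < best:
            best = e
    return best


# --- two-library exact test ------------------------------------------------


def _tail_sum(x: int, y: int, n1: int, n2: int, lower: bool):
    """Direct summation of the conditional tail at 60 decimal digits."""
    r = mpmath.mpf(n2) / n1
    term = (1 + r) ** mpmath.mpf(-(x + 1))  # p(0 | x)
    if lower:
        total = term
        for yp in range(y):
            term = term * r * (x + yp + 1) / ((yp + 1) * (1 + r))
            total += term
        return total
    # upper: sum from y upward until terms are negligible
    for yp in range(y):
        term = term * r * (x + yp + 1) / ((yp + 1) * (1 + r))
    total = term
    yp = y
    while True:
        term = term * r * (x + yp + 1) / ((yp + 1) * (1 + r))
        total += term
        yp += 1
        if term < total * mpmath.mpf("1e-40") or yp > x + y + 10_000:
            break
    return total


def brute_force_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided doubled-tail p-value, smaller conditioning orientation,
    by arbitrary-precision direct summation."""
    with mpmath.workdps(60):
        best = mpmath.mpf(1)
        for (a, b, na, nb) in ((x, y, n1, n2), (y, x, n2, n1)):
            lo = _tail_sum(a, b, na, nb, lower=True)
            up = _tail_sum(a, b, na, nb, lower=False)
            best = min(best, 2 * min(lo, up))
        return float(min(mpmath.mpf(1), best))


def pvalue_grid_oracle(n1: int, n2: int, xy_max: int = 200, y_extent: int = 1400):
    """{(x, y): p} for all 0 <= x, y <= xy_max by direct summation at 60
    decimal digits (prefix sums for lower tails, suffix sums for upper)."""
    with mpmath.workdps(60):

        def tails_for(x: int, na: int, nb: int):
            r = mpmath.mpf(nb) / na
            terms = [(1 + r) ** mpmath.mpf(-(x + 1))]
            for yp in range(y_extent):
                terms.append(terms[-1] * r * (x + yp + 1) / ((yp + 1) * (1 + r)))
            lower = [terms[0]]
            for t in terms[1:]:
                lower.append(lower[-1] + t)
            suffix = list(terms)
            for k in range(len(terms) - 2, -1, -1):
                suffix[k] = suffix[k] + suffix[k + 1]
            return lower, suffix

        half_a = {}  # conditioning on x
        for x in range(xy_max + 1):
            lower, upper = tails_for(x, n1, n2)
            for y in range(xy_max + 1):
                half_a[(x, y)] = 2 * min(lower[y], upper[y])
        out = {}
        for y in range(xy_max + 1):
            lower, upper = tails_for(y, n2, n1)
            for x in range(xy_max + 1):
                p = min(half_a[(x, y)], 2 * min(lower[x], upper[x]))
                out[(x, y)] = float(min(mpmath.mpf(1), p))
    return out


# --- target scanning --------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _pen(m: str, t: str, pos: int, core=(2, 13)) -> float:
    if _COMP[m] == t:
        p = 0.0
    elif (m == "G" and t == "T") or (m == "T" and t == "G"):
        p = 0.5
    else:
        p = 1.0
    return p * (2.0 if core[0] <= pos <= core[1] else 1.0)


def _gap_pen(pos: int, core=(2, 13)) -> float:
    return 2.0 * (2.0 if core[0] <= pos <= core[1] else 1.0)


def brute_force_sites(mirna: str, transcript: str, cutoff: float) -> dict:
    """{(start, end): best E} over all windows and single-gap placements."""
    m, n = len(mirna), len(transcript)
    found: dict[tuple[int, int], float] = {}

    def keep(start, end, e):
        if e <= cutoff and (e < found.get((start, end), float("inf"))):
            found[(start, end)] = e

    for i in range(n - m + 1):
        w = transcript[i : i + m]
        e = sum(_pen(mirna[k], w[m - 1 - k], k + 1) for k in range(m))
        keep(i, i + m, e)
    # one miRNA base unopposed (gap position g+1, not at/next to 10-11)
    for i in range(n - (m - 1) + 1):
        w = transcript[i : i + m - 1]
        for g in range(m):
            if g + 1 in (10, 11):
                continue
            e = _gap_pen(g + 1)
            for k in range(m):
                if k == g:
                    continue
                tr_idx = k if k < g else k - 1
                e += _pen(mirna[k], w[len(w) - 1 - tr_idx], k + 1)
            keep(i, i + m - 1, e)
    # one extra target base between miRNA positions g and g+1
    for i in range(n - (m + 1) + 1):
        w = transcript[i : i + m + 1]
        for g in range(1, m):
            if g in (9, 10, 11):
                continue
            e = _gap_pen(max(g, 1))
            for k in range(m):
                tr_idx = k if k < g else k + 1
                e += _pen(mirna[k], w[len(w) - 1 - tr_idx], k + 1)
            keep(i, i + m + 1, e)
    return found


# --- known-miRNA matching ---------------------------------------------------


def brute_force_best_hits(tags, db, max_mismatch=2, max_len_diff=2):
    """{tag: (best mismatches, ids at the optimum)} by all-pairs scan."""
    out = {}
    for tag in tags:
        best, ids = None, []
        for mid, mseq in db:
            short, long_ = (tag, mseq) if len(tag) <= len(mseq) else (mseq, tag)
            if len(long_) - len(short) > max_len_diff:
                continue
            d = min(
                sum(a != b for a, b in zip(short, long_[o : o + len(short)]))
                for o in range(len(long_) - len(short) + 1)
            )
            if d > max_mismatch:
                continue
            if best is None or d < best:
                best, ids = d, [mid]
            elif d == best:
                ids.append(mid)
        if best is not None:
            out[tag] = (best, ids)
    return out
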