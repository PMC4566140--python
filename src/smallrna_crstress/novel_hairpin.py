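"""Novel miRNA calling from unannotated mapped tags.

Candidate precursor windows are excised around each tag, folded with a
self-contained thermodynamic dynamic program, and screened against plant
stem-loop / miRNA:miRNA* duplex criteria.

Energy model
------------
Deliberately minimal ("nearest-neighbour-lite"): structures are single
stems — chains of nested base pairs (Watson-Crick or G:U) closing one
hairpin loop of >= 3 nt.  Adjacent pairs earn a stacking bonus that
depends on the pair types (WC/WC -2.0, WC/GU -1.0, GU/GU -0.5 kcal/mol);
non-adjacent consecutive pairs pay a bulge (+2.0) or internal-loop (+1.5)
penalty, with at most ``max_interior`` unpaired nucleotides per side;
closing the hairpin loop costs +3.0.  No dangles, no multiloop branching.
The minimum over this structure class is found exactly by dynamic
programming and verified against exhaustive enumeration in the test suite.
Energies are model units on the kcal/mol scale, not measured free
energies; the acceptance threshold (-18) is calibrated on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .annotate_known import Locus, reverse_complement
from .sequence_io import TagTable, normalize_seq

__all__ = [
    "EnergyModel",
    "FoldResult",
    "HairpinCriteria",
    "HairpinCandidate",
    "NovelMiRNA",
    "pair_type",
    "score_structure",
    "fold",
    "excise_candidates",
    "evaluate_hairpin",
    "call_novel",
]

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


@dataclass(frozen=True)
class EnergyModel:
    """All folding constants in one block (kcal/mol-scale model units)."""

    stack_wc_wc: float = -2.0
    stack_wc_gu: float = -1.0
    stack_gu_gu: float = -0.5
    hairpin_penalty: float = 3.0
    bulge_penalty: float = 2.0
    internal_penalty: float = 1.5
    min_loop: int = 3
    max_interior: int = 10  # max unpaired nt per side between stacked pairs


DEFAULT_MODEL = EnergyModel()


@dataclass
class FoldResult:
    sequence: str       # RNA alphabet
    structure: str      # dot-bracket
    mfe: float          # <= 0; empty structure scores 0

    def pair_table(self) -> list[int]:
        """partner index per position, -1 if unpaired."""
        table = [-1] * len(self.structure)
        stack: list[int] = []
        for i, c in enumerate(self.structure):
            if c == "(":
                stack.append(i)
            elif c == ")":
                j = stack.pop()
                table[i], table[j] = j, i
        return table

    def pairs(self) -> list[tuple[int, int]]:
        pt = self.pair_table()
        return [(i, j) for i, j in enumerate(pt) if 0 <= i < j]


def pair_type(a: str, b: str) -> int:
    """0 = unpairable, 1 = Watson-Crick, 2 = G:U wobble (DNA or RNA letters)."""
    x, y = _ENC.get(a, -1), _ENC.get(b, -1)
    if x < 0 or y < 0:
        return 0
    s = {(0, 3), (3, 0), (1, 2), (2, 1)}
    if (x, y) in s:
        return 1
    if (x, y) in {(2, 3), (3, 2)}:
        return 2
    return 0


def score_structure(
    seq: str, chain: Sequence[tuple[int, int]], model: EnergyModel = DEFAULT_MODEL
) -> float:
    """Energy of a single-stem structure given as an outer-to-inner chain
    of pairs.  Raises on structures outside the model class."""
    if not chain:
        return 0.0
    chain = sorted(chain)
    prev = None
    for (i, j) in chain:
        t = pair_type(seq[i], seq[j])
        if t == 0:
            raise ValueError(f"unpairable bases at ({i},{j})")
        if prev is not None:
            pi, pj = prev
            if not (pi < i < j < pj):
                raise ValueError("pairs do not form a nested chain")
        prev = (i, j)
    ii, jj = chain[-1]
    if jj - ii - 1 < model.min_loop:
        raise ValueError("hairpin loop shorter than minimum")
    energy = model.hairpin_penalty
    for (out, inn) in zip(chain, chain[1:]):
        left = inn[0] - out[0] - 1
        right = out[1] - inn[1] - 1
        if left > model.max_interior or right > model.max_interior:
            raise ValueError("interior loop exceeds model bound")
        if left == 0 and right == 0:
            t1 = pair_type(seq[out[0]], seq[out[1]])
            t2 = pair_type(seq[inn[0]], seq[inn[1]])
            if t1 == 1 and t2 == 1:
                energy += model.stack_wc_wc
            elif t1 == 2 and t2 == 2:
                energy += model.stack_gu_gu
            else:
                energy += model.stack_wc_gu
        elif left == 0 or right == 0:
            energy += model.bulge_penalty
        else:
            energy += model.internal_penalty
    return energy


@njit(cache=True)
def _dp_matrix(enc, min_loop, max_interior, s_ww, s_wg, s_gg, p_hp, p_bu, p_in):
    n = enc.shape[0]
    INF = 1e30
    pt = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = enc[i], enc[j]
            if (a == 0 and b == 3) or (a == 3 and b == 0) or (a == 1 and b == 2) or (a == 2 and b == 1):
                pt[i, j] = 1
            elif (a == 2 and b == 3) or (a == 3 and b == 2):
                pt[i, j] = 2
    V = np.full((n, n), INF)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            if pt[i, j] == 0:
                continue
            best = p_hp
            kmax = min(i + 1 + max_interior, j - 1)
            for k in range(i + 1, kmax + 1):
                lmin = max(k + min_loop + 1, j - 1 - max_interior)
                for l in range(lmin, j):
                    v = V[k, l]
                    if v >= INF:
                        continue
                    left = k - i - 1
                    right = j - l - 1
                    if left == 0 and right == 0:
                        t1, t2 = pt[i, j], pt[k, l]
                        if t1 == 1 and t2 == 1:
                            pen = s_ww
                        elif t1 == 2 and t2 == 2:
                            pen = s_gg
                        else:
                            pen = s_wg
                    elif left == 0 or right == 0:
                        pen = p_bu
                    else:
                        pen = p_in
                    cand = pen + v
                    if cand < best:
                        best = cand
            V[i, j] = best
    return V, pt


def _traceback(V, pt, i, j, model: EnergyModel) -> list[tuple[int, int]]:
    chain = [(i, j)]
    tol = 1e-9
    while True:
        target = V[i, j]
        found = False
        kmax = min(i + 1 + model.max_interior, j - 1)
        for k in range(i + 1, kmax + 1):
            lmin = max(k + model.min_loop + 1, j - 1 - model.max_interior)
            for l in range(lmin, j):
                v = V[k, l]
                if v >= 1e29:
                    continue
                left, right = k - i - 1, j - l - 1
                if left == 0 and right == 0:
                    t1, t2 = pt[i, j], pt[k, l]
                    if t1 == 1 and t2 == 1:
                        pen = model.stack_wc_wc
                    elif t1 == 2 and t2 == 2:
                        pen = model.stack_gu_gu
                    else:
                        pen = model.stack_wc_gu
                elif left == 0 or right == 0:
                    pen = model.bulge_penalty
                else:
                    pen = model.internal_penalty
                if abs(pen + v - target) < tol:
                    chain.append((k, l))
                    i, j = k, l
                    found = True
                    break
            if found:
                break
        if not found:
            break
    return chain


def fold(sequence: str, model: EnergyModel = DEFAULT_MODEL) -> FoldResult:
    """Minimum-energy single-stem structure of an RNA sequence.

    Deterministic; ties resolve to the outermost/leftmost optimal pair and
    then greedily inward in scan order.  Returns the empty structure with
    mfe 0 when no structure scores below zero.
    """
    seq = normalize_seq(sequence)
    if not (10 <= len(seq) <= 400):
        raise ValueError(f"sequence length {len(seq)} outside [10, 400]")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"invalid characters {sorted(bad)} (alphabet A/C/G/U)")
    rna = seq.replace("T", "U")
    enc = np.array([_ENC[c] for c in seq], dtype=np.int8)
    V, pt = _dp_matrix(
        enc, model.min_loop, model.max_interior,
        model.stack_wc_wc, model.stack_wc_gu, model.stack_gu_gu,
        model.hairpin_penalty, model.bulge_penalty, model.internal_penalty,
    )
    n = len(seq)
    flat = int(np.argmin(V))
    bi, bj = divmod(flat, n)
    best = float(V[bi, bj])
    if best >= 0.0:
        return FoldResult(rna, "." * n, 0.0)
    chain = _traceback(V, pt, bi, bj, model)
    dots = ["."] * n
    for (i, j) in chain:
        dots[i], dots[j] = "(", ")"
    mfe = score_structure(seq, chain, model)
    assert abs(mfe - best) < 1e-6, "traceback energy mismatch"
    return FoldResult(rna, "".join(dots), float(mfe))


# ---------------------------------------------------------------------------
# candidate excision and evaluation


@dataclass(frozen=True)
class Window:
    """A candidate precursor window on the reference."""

    ref_id: str
    start: int
    end: int
    strand: str
    mature_offset: int  # offset of the tag within the window sequence
    sequence: str

    def mature_interval(self, length: int) -> tuple[int, int]:
        """Reference coordinates (0-based half-open) of the mature tag."""
        if self.strand == "+":
            s = self.start + self.mature_offset
        else:
            s = self.end - self.mature_offset - length
        return s, s + length


@dataclass(frozen=True)
class HairpinCriteria:
    """Stem-loop / duplex acceptance thresholds for a novel miRNA call."""

    mature_min: int = 20
    mature_max: int = 24
    max_duplex_mismatch: int = 4
    max_asym_bulge: int = 2
    precursor_min: int = 40
    precursor_max: int = 350
    mfe_max: float = -18.0
    star_overhang: int = 2
    min_read_support: int = 1


DEFAULT_CRITERIA = HairpinCriteria()


@dataclass
class HairpinCandidate:
    window: Window
    fold: FoldResult | None
    mature: str
    arm: str | None = None           # 5p / 3p
    star: str | None = None
    star_offset: int | None = None
    star_observed: bool = False
    duplex_mismatches: int | None = None
    asymmetric_bulge: int | None = None
    accepted: bool = False
    reason: str = ""


@dataclass
class NovelMiRNA:
    name: str
    mature: str
    candidate: HairpinCandidate
    star_observed: bool
    supporting_tags: list[str] = field(default_factory=list)


def excise_candidates(
    tag_locus: Locus,
    reference: Mapping[str, str],
    max_precursor: int = 350,
    flank_step: int = 10,
    short_flank: int = 15,
) -> list[Window]:
    """Candidate precursor windows around a mapped tag.

    Windows place the tag alternately near the window 5' end (short
    upstream flank, long downstream flank — putative 5p arm) and mirrored
    (putative 3p arm), with total lengths from tag+30 up to
    ``max_precursor`` in ``flank_step`` steps, truncated at contig ends.
    """
    contig = normalize_seq(reference[tag_locus.ref_id])
    ts, te = tag_locus.start, tag_locus.end
    tag_len = te - ts
    n = len(contig)
    seen: set[tuple[int, int]] = set()
    out: list[Window] = []
    for total in range(tag_len + 30, max_precursor + 1, flank_step):
        for anchor in ("left", "right"):
            if anchor == "left":
                ws = max(0, ts - short_flank)
                we = min(n, ws + total)
            else:
                we = min(n, te + short_flank)
                ws = max(0, we - total)
            if ws > ts or we < te:
                continue  # must contain the full tag
            if (ws, we) in seen:
                continue
            seen.add((ws, we))
            sub = contig[ws:we]
            if tag_locus.strand == "+":
                seq, off = sub, ts - ws
            else:
                seq, off = reverse_complement(sub), we - te
            out.append(Window(tag_locus.ref_id, ws, we, tag_locus.strand, off, seq))
    return out


def evaluate_hairpin(
    window: Window,
    tag: str,
    tag_table: TagTable | None = None,
    criteria: HairpinCriteria = DEFAULT_CRITERIA,
    model: EnergyModel = DEFAULT_MODEL,
) -> HairpinCandidate:
    """Fold a window and apply the stem-loop / miRNA:miRNA* criteria.

    The star sequence is inferred from the fold with a 2-nt 3' overhang;
    duplex mismatches are unpaired mature positions (3'-overhang excluded)
    and the asymmetric bulge is the largest pairing-gap imbalance between
    the mature and star sides of the duplex.
    """
    cand = HairpinCandidate(window=window, fold=None, mature=tag)
    plen = len(window.sequence)
    if not (criteria.precursor_min <= plen <= criteria.precursor_max):
        cand.reason = "precursor-length"
        return cand
    if not (criteria.mature_min <= len(tag) <= criteria.mature_max):
        cand.reason = "mature-length"
        return cand
    fr = fold(window.sequence, model)
    cand.fold = fr
    if fr.mfe > criteria.mfe_max:
        cand.reason = "mfe"
        return cand
    pt = fr.pair_table()
    pairs = fr.pairs()
    if not pairs:
        cand.reason = "no-structure"
        return cand
    loop_k, loop_l = max(pairs)  # innermost pair of the single stem
    a = window.mature_offset
    b = a + len(tag)
    if b - 1 <= loop_k:
        cand.arm = "5p"
    elif a >= loop_l:
        cand.arm = "3p"
    else:
        cand.reason = "mature-in-loop"
        return cand
    core = range(a, b - 2)  # exclude the mature 2-nt 3' overhang
    anchors = [p for p in core if pt[p] >= 0]
    cand.duplex_mismatches = sum(1 for p in core if pt[p] < 0)
    if not anchors:
        cand.reason = "duplex-mismatches"
        return cand
    asym = 0
    for p, q in zip(anchors, anchors[1:]):
        g_m = q - p - 1
        g_s = abs(pt[p] - pt[q]) - 1
        asym = max(asym, abs(g_m - g_s))
    cand.asymmetric_bulge = asym
    q_lo = min(pt[p] for p in anchors)
    q_hi = max(pt[p] for p in anchors)
    s_start = q_lo
    s_end = min(plen, q_hi + criteria.star_overhang + 1)
    cand.star = window.sequence[s_start:s_end]
    cand.star_offset = s_start
    if tag_table is not None:
        lo = max(0, s_start - 2)
        hi = min(plen, s_end + 2)
        region = window.sequence[lo:hi]
        for ln in range(criteria.mature_min - 2, criteria.mature_max + 3):
            for st in range(0, len(region) - ln + 1):
                sub = region[st : st + ln]
                if sub != tag and sub in tag_table:
                    cand.star_observed = True
                    break
            if cand.star_observed:
                break
    if cand.duplex_mismatches > criteria.max_duplex_mismatch:
        cand.reason = "duplex-mismatches"
        return cand
    if asym > criteria.max_asym_bulge:
        cand.reason = "asymmetric-bulge"
        return cand
    cand.accepted = True
    cand.reason = "ok"
    return cand


def call_novel(
    unannotated_mapped: Mapping[str, Sequence[Locus]],
    reference: Mapping[str, str],
    tag_table: TagTable | None = None,
    criteria: HairpinCriteria = DEFAULT_CRITERIA,
    model: EnergyModel = DEFAULT_MODEL,
    max_precursor: int = 350,
    flank_step: int = 10,
    short_flank: int = 15,
) -> list[NovelMiRNA]:
    """Call novel miRNAs from unannotated mapped tags.

    Per tag the best-scoring accepted window is kept (lowest MFE, ties to
    the shortest precursor); overlapping candidates on the same locus are
    merged into one record (the most abundant tag becomes the mature, the
    partner marks the star as observed).  Records are numbered
    ``rsa-miRn-#`` by (reference id, precursor start) for reproducibility.
    """
    per_tag: list[tuple[str, HairpinCandidate]] = []
    for tag, loci in unannotated_mapped.items():
        if not (criteria.mature_min <= len(tag) <= criteria.mature_max):
            continue
        if tag_table is not None and tag_table.total_count(tag) < criteria.min_read_support:
            continue
        best: HairpinCandidate | None = None
        for locus in loci:
            for window in excise_candidates(
                locus, reference, max_precursor, flank_step, short_flank
            ):
                cand = evaluate_hairpin(window, tag, tag_table, criteria, model)
                if not cand.accepted:
                    continue
                key = (cand.fold.mfe, len(window.sequence))
                if best is None or key < (best.fold.mfe, len(best.window.sequence)):
                    best = cand
        if best is not None:
            per_tag.append((tag, best))

    per_tag.sort(key=lambda tc: (tc[1].window.ref_id, tc[1].window.start, tc[0]))
    merged: list[NovelMiRNA] = []
    for tag, cand in per_tag:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.candidate.window.ref_id == cand.window.ref_id
            and prev.candidate.window.strand == cand.window.strand
            and cand.window.start < prev.candidate.window.end
            and prev.candidate.window.start < cand.window.end
        ):
            prev.supporting_tags.append(tag)
            prev.star_observed = True
            if tag_table is not None and tag_table.total_count(tag) > tag_table.total_count(prev.mature):
                prev.mature = tag
                prev.candidate = cand
            continue
        merged.append(
            NovelMiRNA(
                name="",
                mature=tag,
                candidate=cand,
                star_observed=cand.star_observed,
                supporting_tags=[tag],
            )
        )
    for k, rec in enumerate(merged, start=1):
        rec.name = f"rsa-miRn-{k}"
    return merged
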