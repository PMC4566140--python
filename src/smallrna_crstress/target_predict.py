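"""Plant miRNA target prediction with the Allen-style expectation score.

A target site is an (almost) antisense match of the miRNA on a transcript.
Alignment columns are scored from the miRNA 5' end (position 1): mismatch
1, G:U wobble 0.5, gap 2, all doubled inside the core positions 2-13;
perfect matches cost 0.  Sites at or below the expectation cutoff
(default 3.0) are reported.  One gap at most, never opposite the central
cleavage positions 10-11.  A site whose central positions 9-11 pair
perfectly is called a cleavage target, otherwise translational inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .sequence_io import normalize_seq

__all__ = [
    "MATCH", "MISMATCH", "GU", "GAP",
    "TargetAlignment",
    "SchwabRules",
    "score_alignment",
    "find_sites",
    "classify_mode",
    "schwab_filter",
]

MATCH, MISMATCH, GU, GAP = "match", "mismatch", "gu", "gap"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _column_state(m: str, t: str) -> str:
    """Pairing state of miRNA base vs the opposing target base (both DNA)."""
    if _COMPLEMENT.get(m) == t:
        return MATCH
    if (m == "G" and t == "T") or (m == "T" and t == "G"):
        return GU
    return MISMATCH


@dataclass
class TargetAlignment:
    mirna_id: str
    transcript_id: str
    start: int  # transcript site, 0-based half-open
    end: int
    states: list[str]       # alignment columns, miRNA 5'->3'
    expectation: float
    mode: str = ""          # cleavage / translation
    gap_kind: str = ""      # '' / 'target' (miRNA base unopposed) / 'mirna'
    is_best: bool = False   # best site for this (miRNA, transcript) pair


@dataclass(frozen=True)
class SchwabRules:
    """Empirical plant-target constraints applied on top of the score."""

    max_cleavage_site_states: int = 0   # non-matches allowed at 10-11
    max_seed_mismatches: int = 1        # non-matches in positions 1-9
    max_consecutive_mismatches: int = 2


def _positions(states: Sequence[str], mirna_len: int) -> list[int]:
    """1-based miRNA position of each alignment column.

    A column list of miRNA length maps 1:1; one extra column means a
    target-side insertion, which takes the position of the preceding
    miRNA base (minimum 1) and does not advance the position counter.
    """
    n_gaps = sum(1 for s in states if s == GAP)
    if n_gaps > 1:
        raise ValueError("invalid alignment: more than one gap")
    if len(states) == mirna_len:
        return list(range(1, mirna_len + 1))
    if len(states) == mirna_len + 1 and n_gaps == 1:
        pos, out = 0, []
        for s in states:
            if s == GAP and len(out) == states.index(GAP):
                # insertion column: position of the previous miRNA base
                out.append(max(pos, 1))
            else:
                pos += 1
                out.append(pos)
        return out
    raise ValueError("states do not cover the miRNA length")


def score_alignment(
    states: Sequence[str],
    mirna_len: int | None = None,
    core: tuple[int, int] = (2, 13),
) -> float:
    """Allen expectation score of an alignment column list.

    ``mirna_len`` defaults to the column count (no target insertion).
    """
    mirna_len = len(states) if mirna_len is None else mirna_len
    penalties = {MATCH: 0.0, MISMATCH: 1.0, GU: 0.5, GAP: 2.0}
    total = 0.0
    for s, pos in zip(states, _positions(states, mirna_len)):
        pen = penalties[s]
        if core[0] <= pos <= core[1]:
            pen *= 2.0
        total += pen
    return total


def classify_mode(alignment: TargetAlignment) -> str:
    """cleavage if positions 9-11 all pair perfectly, else translation."""
    bad = any(
        s != MATCH
        for s, pos in zip(
            alignment.states, _positions(alignment.states, _mirna_len(alignment))
        )
        if 9 <= pos <= 11
    )
    return "translation" if bad else "cleavage"


def _mirna_len(alignment: TargetAlignment) -> int:
    n = len(alignment.states)
    return n - 1 if (alignment.gap_kind == "mirna") else n


def schwab_filter(
    alignment: TargetAlignment, rules: SchwabRules = SchwabRules()
) -> tuple[bool, list[str]]:
    """Apply the empirical constraints; returns (pass, failure reasons)."""
    pos = _positions(alignment.states, _mirna_len(alignment))
    reasons = []
    central = sum(
        1 for s, p in zip(alignment.states, pos) if 10 <= p <= 11 and s != MATCH
    )
    if central > rules.max_cleavage_site_states:
        reasons.append("cleavage-site mismatch")
    seed = sum(1 for s, p in zip(alignment.states, pos) if p <= 9 and s != MATCH)
    if seed > rules.max_seed_mismatches:
        reasons.append("seed mismatches > %d" % rules.max_seed_mismatches)
    run = best_run = 0
    for s in alignment.states:
        run = run + 1 if s != MATCH else 0
        best_run = max(best_run, run)
    if best_run > rules.max_consecutive_mismatches:
        reasons.append("consecutive mismatches > %d" % rules.max_consecutive_mismatches)
    return (not reasons, reasons)


def _states_ungapped(mirna: str, window: str) -> list[str]:
    # miRNA 5'->3' pairs the window 3'->5'
    return [_column_state(m, window[len(window) - 1 - k]) for k, m in enumerate(mirna)]


def find_sites(
    mirna: str,
    transcript: str,
    max_expectation: float = 3.0,
    mirna_id: str = "miRNA",
    transcript_id: str = "transcript",
    allow_gap: bool = True,
    core: tuple[int, int] = (2, 13),
) -> list[TargetAlignment]:
    """Scan a transcript for target sites of one miRNA.

    Every window is scored ungapped plus, optionally, all single-gap
    variants (a miRNA base unopposed, or one extra target base), the gap
    never at miRNA positions 10-11.  Sites with E <= ``max_expectation``
    are returned ordered by position, the best per window kept.
    """
    mirna = normalize_seq(mirna)
    transcript = normalize_seq(transcript)
    m, n = len(mirna), len(transcript)
    if not (18 <= m <= 26):
        raise ValueError("miRNA length outside 18-26 nt")
    if n < m:
        raise ValueError("transcript shorter than miRNA")
    found: dict[tuple[int, int], TargetAlignment] = {}

    def consider(start: int, end: int, states: list[str], gap_kind: str) -> None:
        e = score_alignment(states, m, core)
        if e > max_expectation:
            return
        key = (start, end)
        old = found.get(key)
        if old is None or e < old.expectation:
            aln = TargetAlignment(
                mirna_id, transcript_id, start, end, states, e, gap_kind=gap_kind
            )
            aln.mode = classify_mode(aln)
            found[key] = aln

    for i in range(n - m + 1):
        consider(i, i + m, _states_ungapped(mirna, transcript[i : i + m]), "")
    if allow_gap:
        # one miRNA base unopposed (target gap): window of m-1 target bases
        for i in range(n - (m - 1) + 1):
            window = transcript[i : i + m - 1]
            for g in range(m):
                pos = g + 1
                if pos in (10, 11):
                    continue
                reduced = mirna[:g] + mirna[g + 1 :]
                states = _states_ungapped(reduced, window)
                states.insert(g, GAP)
                consider(i, i + m - 1, states, "target")
        # one extra target base (miRNA gap): window of m+1 target bases
        for i in range(n - (m + 1) + 1):
            window = transcript[i : i + m + 1]
            for g in range(1, m):  # insertion between miRNA positions g and g+1
                if g + 1 in (10, 11) or g in (10, 11):
                    continue
                # drop the opposing target base at alignment column g
                # (window index from the 3' side)
                wi = len(window) - 1 - g
                reduced = window[:wi] + window[wi + 1 :]
                states = _states_ungapped(mirna, reduced)
                states.insert(g, GAP)
                consider(i, i + m + 1, states, "mirna")
    sites = sorted(found.values(), key=lambda a: (a.start, a.end))
    if sites:
        best = min(s.expectation for s in sites)
        for s in sites:
            s.is_best = s.expectation == best
    return sites
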