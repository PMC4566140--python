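"""Reference mapping, ncRNA exclusion and known-miRNA identification.

Tags are mapped to the reference by perfect (0-mismatch) substring match on
either strand; tags matching rRNA/tRNA/snRNA/snoRNA records are excluded;
the remainder is compared with a mature-miRNA database allowing up to two
mismatches.  Matching against the mature database is end-anchored and
ungapped: when tag and database sequence differ in length (at most 2 nt),
the shorter slides within the longer and the minimum Hamming distance over
the offsets is taken; the length difference itself is not penalized.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .sequence_io import LibraryStats, TagTable, normalize_seq

__all__ = [
    "Locus",
    "KnownMiRNAHit",
    "FamilySummary",
    "NCRNA_PRECEDENCE",
    "DEFAULT_FAMILY_MERGE",
    "DEFAULT_CONSERVED_FAMILIES",
    "reverse_complement",
    "map_reference",
    "filter_ncrna",
    "tag_mismatches",
    "match_mirbase",
    "assign_family",
    "family_summary",
]

_RC = str.maketrans("ACGTN", "TGCAN")

#: multi-class ncRNA hits resolve in this order
NCRNA_PRECEDENCE = ("rRNA", "tRNA", "snRNA", "snoRNA")

#: family numbers reported jointly (miR156/157 and miR165/166 behave as one
#: family each in Brassicaceae annotation)
DEFAULT_FAMILY_MERGE = {
    "156": "156/157",
    "157": "156/157",
    "165": "165/166",
    "166": "165/166",
}

#: conserved plant miRNA families; everything else is non-conserved
DEFAULT_CONSERVED_FAMILIES = frozenset(
    {
        "miR156/157", "miR158", "miR159", "miR160", "miR161", "miR162",
        "miR164", "miR165/166", "miR167", "miR168", "miR169", "miR171",
        "miR172", "miR319", "miR390", "miR391", "miR393", "miR394",
        "miR395", "miR396", "miR397", "miR398", "miR399", "miR408",
    }
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class Locus:
    """A perfect-match occurrence: (reference id, 0-based half-open, strand)."""

    ref_id: str
    start: int
    end: int
    strand: str  # '+' or '-'


@dataclass
class KnownMiRNAHit:
    tag: str
    mirna_id: str
    mismatches: int
    primary: bool = True
    family: str | None = None


@dataclass
class FamilySummary:
    family: str
    conserved: bool
    n_members: int
    reads_per_library: dict[str, int]
    normalized_per_library: dict[str, float]
    log2fc: float


# ---------------------------------------------------------------------------


def map_reference(
    tags: TagTable | Iterable[str],
    reference: Mapping[str, str],
) -> tuple[dict[str, list[Locus]], list[str]]:
    """Perfect-match mapping of tags to a reference sequence set.

    A tag maps iff it occurs exactly in a reference sequence or its reverse
    complement; every occurrence is recorded.  Returns (mapped tag ->
    loci, unmapped tags).
    """
    if not reference:
        raise ValueError("empty reference")
    seqs = tags.sequences() if isinstance(tags, TagTable) else list(tags)
    # one concatenated text ('#'-separated so matches cannot span contigs)
    ids: list[str] = []
    offsets: list[int] = []
    chunks: list[str] = []
    pos = 0
    for rid, s in reference.items():
        ids.append(rid)
        offsets.append(pos)
        s = normalize_seq(s)
        chunks.append(s)
        pos += len(s) + 1
    text = "#".join(chunks)

    import bisect

    def occurrences(query: str, strand: str) -> list[Locus]:
        out = []
        p = text.find(query)
        while p >= 0:
            k = bisect.bisect_right(offsets, p) - 1
            out.append(Locus(ids[k], p - offsets[k], p - offsets[k] + len(query), strand))
            p = text.find(query, p + 1)
        return out

    mapped: dict[str, list[Locus]] = {}
    unmapped: list[str] = []
    for tag in seqs:
        loci = occurrences(tag, "+") + occurrences(reverse_complement(tag), "-")
        if loci:
            mapped[tag] = loci
        else:
            unmapped.append(tag)
    return mapped, unmapped


def filter_ncrna(
    tags: Iterable[str],
    ncrna_db: Sequence[tuple[str, str, str]],
) -> tuple[dict[str, str], list[str]]:
    """Assign tags to ncRNA classes and remove them.

    ``ncrna_db`` holds (record id, class label, sequence) triples; a tag
    matching any record exactly (substring, either strand) takes that
    record's class, with precedence rRNA > tRNA > snRNA > snoRNA on
    multi-class hits.  Returns (tag -> class, remaining tags).
    """
    by_class: dict[str, list[str]] = {c: [] for c in NCRNA_PRECEDENCE}
    for rec_id, cls, seq in ncrna_db:
        if cls not in by_class:
            raise ValueError(f"ncRNA record {rec_id!r} has unknown class {cls!r}")
        by_class[cls].append(normalize_seq(seq))
    classified: dict[str, str] = {}
    remaining: list[str] = []
    for tag in tags:
        rc = reverse_complement(tag)
        hit = None
        for cls in NCRNA_PRECEDENCE:
            if any(tag in s or rc in s for s in by_class[cls]):
                hit = cls
                break
        if hit:
            classified[tag] = hit
        else:
            remaining.append(tag)
    return classified, remaining


def tag_mismatches(tag: str, mature: str, max_len_diff: int = 2) -> int | None:
    """End-anchored ungapped mismatch count between a tag and a mature
    sequence: the shorter slides within the longer; minimum Hamming distance
    over offsets.  Returns None when lengths differ by more than
    ``max_len_diff``.
    """
    a, b = (tag, mature) if len(tag) <= len(mature) else (mature, tag)
    diff = len(b) - len(a)
    if diff > max_len_diff:
        return None
    best = None
    for off in range(diff + 1):
        mism = sum(1 for x, y in zip(a, b[off : off + len(a)]) if x != y)
        if best is None or mism < best:
            best = mism
    return best


def _capped_mismatches(tag: str, mature: str, cap: int, max_len_diff: int = 2) -> int | None:
    """:func:`tag_mismatches` with an early abort once every offset exceeds
    ``cap`` — same result whenever the result is <= cap, else any value > cap."""
    a, b = (tag, mature) if len(tag) <= len(mature) else (mature, tag)
    diff = len(b) - len(a)
    if diff > max_len_diff:
        return None
    best: int | None = None
    for off in range(diff + 1):
        mism = 0
        for x, y in zip(a, b[off : off + len(a)]):
            if x != y:
                mism += 1
                if mism > cap:
                    break
        if best is None or mism < best:
            best = mism
            if best == 0:
                break
    return best


def match_mirbase(
    tags: Iterable[str],
    mature_db: Sequence[tuple[str, str]],
    max_mismatch: int = 2,
) -> list[KnownMiRNAHit]:
    """Identify known miRNAs among tags (<= ``max_mismatch`` mismatches).

    For each tag the hit(s) with the fewest mismatches are reported;
    database order breaks ties, the first co-optimal hit carrying
    ``primary=True``.
    """
    db = [(mid, normalize_seq(seq)) for mid, seq in mature_db]
    hits: list[KnownMiRNAHit] = []
    for tag in tags:
        best: int | None = None
        best_ids: list[str] = []
        for mid, mseq in db:
            mism = _capped_mismatches(tag, mseq, max_mismatch)
            if mism is None or mism > max_mismatch:
                continue
            if best is None or mism < best:
                best, best_ids = mism, [mid]
            elif mism == best:
                best_ids.append(mid)
        if best is not None:
            for k, mid in enumerate(best_ids):
                hits.append(
                    KnownMiRNAHit(tag=tag, mirna_id=mid, mismatches=best, primary=(k == 0))
                )
    return hits


_ID_RE = re.compile(
    r"^(?:[a-z]{3,4}-)?miR(?P<num>\d+)(?P<member>[a-z]*)(?:[-.](?P<arm>[35]p))?$",
    re.IGNORECASE,
)


def assign_family(
    mirna_id: str,
    merge_map: Mapping[str, str] | None = None,
) -> str:
    """Family label for a mature miRNA id.

    Strips the species prefix, lettered member suffix and -5p/-3p arm, then
    applies the merge map (default joins 156/157 and 165/166):
    ``"osa-miR156a-3p" -> "miR156/157"``.
    """
    merge = DEFAULT_FAMILY_MERGE if merge_map is None else merge_map
    m = _ID_RE.match(mirna_id.strip())
    if not m:
        raise ValueError(f"unparseable miRNA id {mirna_id!r}")
    num = m.group("num")
    return "miR" + merge.get(num, num)


def family_summary(
    hits: Sequence[KnownMiRNAHit],
    tag_table: TagTable,
    stats: Mapping[str, LibraryStats],
    conserved: frozenset[str] | set[str] = DEFAULT_CONSERVED_FAMILIES,
    merge_map: Mapping[str, str] | None = None,
    floor: float = 0.01,
) -> list[FamilySummary]:
    """Per-family member counts, reads, RPM and log2 fold change.

    Expects exactly two library labels in ``stats`` (control first,
    treatment second); the fold change is log2(treatment / control) on
    floor-substituted RPM values.
    """
    from .diff_expression import log2_fold_change, normalize_rpm, substitute_floor

    labels = list(stats)
    if len(labels) != 2:
        raise ValueError("family_summary needs exactly two libraries")
    # count each tag once per family even if several members tie
    members: dict[str, set[str]] = {}
    fam_tags: dict[str, set[str]] = {}
    for h in hits:
        if not h.primary:
            continue
        fam = assign_family(h.mirna_id, merge_map)
        members.setdefault(fam, set()).add(h.mirna_id)
        fam_tags.setdefault(fam, set()).add(h.tag)
    out = []
    for fam in sorted(members, key=_family_sort_key):
        reads = {
            lab: sum(tag_table.count(t, lab) for t in fam_tags[fam]) for lab in labels
        }
        norm = {
            lab: normalize_rpm(reads[lab], stats[lab].total_clean) for lab in labels
        }
        fc = log2_fold_change(
            substitute_floor(norm[labels[1]], floor),
            substitute_floor(norm[labels[0]], floor),
        )
        out.append(
            FamilySummary(
                family=fam,
                conserved=fam in conserved,
                n_members=len(members[fam]),
                reads_per_library=reads,
                normalized_per_library=norm,
                log2fc=fc,
            )
        )
    return out


def _family_sort_key(fam: str) -> tuple[int, str]:
    m = re.match(r"miR(\d+)", fam)
    return (int(m.group(1)) if m else 10**9, fam)
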