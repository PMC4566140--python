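"""Reading, cleaning and collapsing of small RNA sequencing libraries.

A raw library is an ordered collection of reads (optionally with Phred
qualities).  Cleaning removes adapter artefacts, poly-A tails and
out-of-range inserts; the survivors are collapsed into a table of unique
*tags*, each carrying a per-library read count.  Tags are the atomic unit
of every downstream stage (mapping, annotation, hairpin calling,
differential expression), and the cleaned per-library read total is the
denominator of RPM normalization.

All sequences are stored internally in the DNA alphabet (U -> T); they are
converted back to RNA only inside the folding engine.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from Bio import SeqIO

__all__ = [
    "RawRead",
    "RawLibrary",
    "CleaningReport",
    "TagTable",
    "LibraryStats",
    "CATEGORIES",
    "parse_reads",
    "clean_reads",
    "collapse",
    "merge_tables",
    "length_distribution",
    "category_accounting",
    "write_collapsed_fasta",
]

#: Table-1 annotation categories, in report order.
CATEGORIES = ("miRNA", "rRNA", "snRNA", "snoRNA", "tRNA", "unannotated")

_DNA_TRANS = str.maketrans("uU", "tT")


def normalize_seq(seq: str) -> str:
    """Uppercase a nucleotide string and map U to T."""
    return seq.translate(_DNA_TRANS).upper()


@dataclass(frozen=True)
class RawRead:
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty read sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError("quality string length differs from sequence length")


@dataclass
class RawLibrary:
    """One sequencing library: a label (e.g. ``CK``/``Cr200``) plus reads."""

    name: str
    reads: list[RawRead] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class CleaningReport:
    """Per-reason discard tallies from :func:`clean_reads`."""

    total_raw: int = 0
    kept: int = 0
    discarded: collections.Counter = field(default_factory=collections.Counter)

    def as_dict(self) -> dict[str, int]:
        out = {"total_raw": self.total_raw, "kept": self.kept}
        out.update(dict(self.discarded))
        return out


class TagTable:
    """Unique tag sequences with raw read counts per library label.

    ``tags`` maps sequence -> {library label -> count}.  The sum of counts
    for a label always equals that library's clean-read total (conservation
    is asserted by callers via :meth:`total`).
    """

    def __init__(self) -> None:
        self.tags: dict[str, dict[str, int]] = {}
        self.labels: list[str] = []

    def __len__(self) -> int:
        return len(self.tags)

    def __contains__(self, seq: str) -> bool:
        return seq in self.tags

    def add(self, seq: str, label: str, count: int = 1) -> None:
        if count < 0:
            raise ValueError("negative tag count")
        if label not in self.labels:
            self.labels.append(label)
        per = self.tags.setdefault(seq, {})
        per[label] = per.get(label, 0) + count

    def count(self, seq: str, label: str) -> int:
        return self.tags.get(seq, {}).get(label, 0)

    def total_count(self, seq: str) -> int:
        return sum(self.tags.get(seq, {}).values())

    def total(self, label: str) -> int:
        return sum(per.get(label, 0) for per in self.tags.values())

    def sequences(self) -> list[str]:
        return list(self.tags)


def merge_tables(a: TagTable, b: TagTable) -> TagTable:
    """Union two tag tables; the label sets must be disjoint."""
    dup = set(a.labels) & set(b.labels)
    if dup:
        raise ValueError(f"duplicate library label(s) on merge: {sorted(dup)}")
    out = TagTable()
    for table in (a, b):
        for seq, per in table.tags.items():
            for label, n in per.items():
                out.add(seq, label, n)
    return out


@dataclass
class LibraryStats:
    """Table-1-style accounting for one library.

    ``total_clean`` is the RPM normalization denominator N.  Categories
    partition the clean tags, so per-category totals sum to ``total_clean``
    and per-category unique counts sum to ``unique_clean``.
    """

    label: str
    total_raw: int
    total_clean: int
    unique_clean: int
    unique_by_category: dict[str, int]
    total_by_category: dict[str, int]

    def unique_pct(self, category: str) -> float:
        return round(100.0 * self.unique_by_category[category] / self.unique_clean, 2)

    def total_pct(self, category: str) -> float:
        return round(100.0 * self.total_by_category[category] / self.total_clean, 2)


# ---------------------------------------------------------------------------
# parsing


def parse_reads(path: str | Path, format: str = "fastq") -> RawLibrary:
    """Read a library from ``fastq``, ``fasta`` or ``collapsed-fasta``.

    ``collapsed-fasta`` headers end in ``_x<count>`` (e.g. ``>tag1_x257``);
    the count is honoured as a read multiplicity.
    """
    path = Path(path)
    name = path.stem
    lib = RawLibrary(name=name)
    if format == "fastq":
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            seq = normalize_seq(str(rec.seq))
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            _check_record(seq, i)
            lib.reads.append(RawRead(seq, qual))
    elif format == "fasta":
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
            seq = normalize_seq(str(rec.seq))
            _check_record(seq, i)
            lib.reads.append(RawRead(seq))
    elif format == "collapsed-fasta":
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
            seq = normalize_seq(str(rec.seq))
            _check_record(seq, i)
            head = rec.id
            if "_x" not in head:
                raise ValueError(
                    f"record {i}: collapsed-fasta header {head!r} lacks _x<count>"
                )
            try:
                mult = int(head.rsplit("_x", 1)[1])
            except ValueError as exc:
                raise ValueError(
                    f"record {i}: bad count suffix in header {head!r}"
                ) from exc
            lib.reads.extend([RawRead(seq)] * mult)
    else:
        raise ValueError(f"unknown format label {format!r}")
    return lib


def _check_record(seq: str, index: int) -> None:
    if not seq:
        raise ValueError(f"record {index}: empty sequence")
    if set(seq) - set("ACGTN"):
        raise ValueError(f"record {index}: non-nucleotide characters in {seq!r}")


# ---------------------------------------------------------------------------
# cleaning


def _find_adapter(seq: str, adapter: str, min_overlap: int, max_mismatch: int) -> int:
    """Leftmost start of the best 3' adapter prefix match, or -1.

    The adapter may run off the read end; overlaps shorter than
    ``min_overlap`` are not trusted.  Up to ``max_mismatch`` substitutions
    are tolerated within the overlap.
    """
    n, m = len(seq), len(adapter)
    # fast path: exact seed hit
    seed = adapter[: min(min_overlap, m)]
    exact = seq.find(seed)
    limit = exact if exact >= 0 else n
    for i in range(0, min(limit, n - min_overlap) + 1):
        if i > n - min_overlap:
            break
        overlap = min(m, n - i)
        mism = 0
        for a, b in zip(seq[i : i + overlap], adapter):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return i
    if exact >= 0 and exact <= n - min_overlap:
        return exact
    return -1


def clean_reads(
    lib: RawLibrary,
    adapter3: str | None,
    adapter5: str | None = None,
    min_len: int = 18,
    max_len: int = 30,
    polya_frac: float = 0.8,
    adapter_min_overlap: int = 8,
    adapter_max_mismatch: int = 1,
) -> tuple[RawLibrary, CleaningReport]:
    """Adapter/poly-A/length filtering of a raw library.

    Discard classes follow small RNA library conventions: reads with no
    locatable 3' adapter (``adapter3_null``), with an empty insert after
    trimming (``insert_null``), containing the 5' adapter
    (``adapter5_contaminant``), consisting mostly of A after trimming
    (``poly_a``), or with trimmed length outside the *exclusive* bounds
    (``too_short`` / ``too_long``; bounds 18/30 keep 19-29 nt inserts).

    Passing ``adapter3=None`` skips adapter location entirely (for
    re-cleaning already-trimmed reads); in that mode cleaning is idempotent.
    """
    if min_len >= max_len:
        raise ValueError("min_len must be < max_len")
    if adapter3 is not None:
        adapter3 = normalize_seq(adapter3)
    if adapter5 is not None:
        adapter5 = normalize_seq(adapter5)

    report = CleaningReport(total_raw=len(lib.reads))
    # Identical sequences clean identically, so process each unique
    # sequence once and weight the outcome by its multiplicity.
    mult = collections.Counter(r.sequence for r in lib.reads)
    verdicts: dict[str, str | None] = {}  # seq -> trimmed insert or None
    reasons: dict[str, str] = {}
    for seq, n in mult.items():
        insert: str | None = seq
        reason = None
        if adapter3 is not None:
            pos = _find_adapter(seq, adapter3, adapter_min_overlap, adapter_max_mismatch)
            if pos < 0:
                insert, reason = None, "adapter3_null"
            elif pos == 0:
                insert, reason = None, "insert_null"
            else:
                insert = seq[:pos]
        if insert is not None and adapter5 is not None and adapter5 in insert:
            insert, reason = None, "adapter5_contaminant"
        if insert is not None and insert.count("A") >= polya_frac * len(insert):
            insert, reason = None, "poly_a"
        if insert is not None and len(insert) <= min_len:
            insert, reason = None, "too_short"
        if insert is not None and len(insert) >= max_len:
            insert, reason = None, "too_long"
        verdicts[seq] = insert
        if reason is not None:
            reasons[seq] = reason
            report.discarded[reason] += n
        else:
            report.kept += n

    out = RawLibrary(name=lib.name)
    cache: dict[tuple[str, str | None], RawRead] = {}
    append = out.reads.append
    for read in lib.reads:
        insert = verdicts[read.sequence]
        if insert is not None:
            qual = read.quality[: len(insert)] if read.quality else None
            key = (insert, qual)
            obj = cache.get(key)
            if obj is None:
                obj = cache[key] = RawRead(insert, qual)
            append(obj)
    return out, report


# ---------------------------------------------------------------------------
# collapsing and accounting


def collapse(lib: RawLibrary, label: str | None = None) -> TagTable:
    """Collapse cleaned reads to unique tags with counts for ``label``."""
    label = label if label is not None else lib.name
    table = TagTable()
    if label not in table.labels:
        table.labels.append(label)
    counts = collections.Counter(r.sequence for r in lib.reads)
    for seq, n in counts.items():
        table.add(seq, label, n)
    assert table.total(label) == len(lib.reads), "collapse lost reads"
    return table


def length_distribution(tags: TagTable, label: str) -> tuple[dict[int, int], int | None]:
    """Total reads by tag length; returns (histogram, modal length)."""
    hist: dict[int, int] = collections.defaultdict(int)
    for seq, per in tags.tags.items():
        n = per.get(label, 0)
        if n:
            hist[len(seq)] += n
    hist = dict(sorted(hist.items()))
    mode = max(hist, key=lambda k: (hist[k], -k)) if hist else None
    return hist, mode


def category_accounting(
    tags: TagTable,
    annotations: Mapping[str, str],
    label: str,
    total_raw: int | None = None,
) -> LibraryStats:
    """Table-1-style unique/total accounting for one library.

    ``annotations`` must assign every tag present in ``label`` exactly one
    category from :data:`CATEGORIES`; a missing assignment is an annotation
    stage bug and raises.
    """
    uniq = dict.fromkeys(CATEGORIES, 0)
    tot = dict.fromkeys(CATEGORIES, 0)
    for seq, per in tags.tags.items():
        n = per.get(label, 0)
        if n == 0:
            continue
        cat = annotations.get(seq)
        if cat is None:
            raise RuntimeError(f"tag {seq!r} has no category assignment")
        if cat not in CATEGORIES:
            raise RuntimeError(f"tag {seq!r} assigned unknown category {cat!r}")
        uniq[cat] += 1
        tot[cat] += n
    total_clean = sum(tot.values())
    unique_clean = sum(uniq.values())
    assert total_clean == tags.total(label)
    return LibraryStats(
        label=label,
        total_raw=total_raw if total_raw is not None else total_clean,
        total_clean=total_clean,
        unique_clean=unique_clean,
        unique_by_category=uniq,
        total_by_category=tot,
    )


def write_collapsed_fasta(tags: TagTable, label: str, path: str | Path) -> None:
    """Write one library's tags as collapsed FASTA (``>t<i>_x<count>``)."""
    with open(path, "w") as fh:
        i = 0
        for seq in sorted(tags.tags):
            n = tags.tags[seq].get(label, 0)
            if n:
                i += 1
                fh.write(f">t{i}_x{n}\n{seq}\n")
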