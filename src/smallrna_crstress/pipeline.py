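"""End-to-end orchestration: clean -> map -> annotate -> novel -> DE -> targets.

The stages run in the canonical small RNA analysis order; every tag ends in
exactly one terminal category (ncRNA class, known miRNA, or unannotated),
which makes the category report sum to the clean totals by construction.
All outputs are plain TSV/FASTA so any stage can be re-fed fixtures.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate_known as ann
from . import diff_expression as de
from . import novel_hairpin as nh
from . import sequence_io as sio
from . import target_predict as tp
from Bio import SeqIO

log = logging.getLogger("smallrna_crstress")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "analyze_libraries"]


@dataclass
class PipelineConfig:
    libraries: dict[str, str] = field(default_factory=dict)  # label -> path
    library_format: str = "fastq"
    reference: str = ""
    mature_db: str = ""
    ncrna_db: str = ""
    transcripts: str | None = None
    adapter3: str | None = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str | None = None
    min_len: int = 18
    max_len: int = 30
    max_mismatch: int = 2
    hairpin: nh.HairpinCriteria = field(default_factory=nh.HairpinCriteria)
    thresholds: de.DEThresholds = field(default_factory=de.DEThresholds)
    target_cutoff: float = 3.0
    novel_min_support: int = 1
    seed: int = 0

    def validate(self) -> None:
        if len(self.libraries) != 2:
            raise ValueError("config must name exactly two libraries")
        if self.min_len >= self.max_len:
            raise ValueError("min_len must be < max_len")
        for name in ("reference", "mature_db", "ncrna_db"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{name} path missing: {p!r}")
        for label, p in self.libraries.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"library {label} path missing: {p!r}")
        if self.transcripts and not Path(self.transcripts).exists():
            raise FileNotFoundError(f"transcripts path missing: {self.transcripts!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "hairpin" in raw:
            raw["hairpin"] = nh.HairpinCriteria(**raw["hairpin"])
        if "thresholds" in raw:
            raw["thresholds"] = de.DEThresholds(**raw["thresholds"])
        return cls(**raw)


@dataclass
class PipelineResult:
    stats: dict[str, sio.LibraryStats]
    cleaning: dict[str, sio.CleaningReport]
    tag_table: sio.TagTable
    annotations: dict[str, str]
    known_hits: list[ann.KnownMiRNAHit]
    families: list[ann.FamilySummary]
    novel: list[nh.NovelMiRNA]
    records: list[de.ExpressionRecord]
    summary: dict[str, int]


def _read_fasta(path: str) -> dict[str, str]:
    return {rec.id: sio.normalize_seq(str(rec.seq)) for rec in SeqIO.parse(path, "fasta")}


def _read_ncrna(path: str) -> list[tuple[str, str, str]]:
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        cls = None
        for token in rec.description.split():
            if token.startswith("class="):
                cls = token.split("=", 1)[1]
        if cls is None:
            raise ValueError(f"ncRNA record {rec.id!r} lacks a class= label")
        out.append((rec.id, cls, sio.normalize_seq(str(rec.seq))))
    return out


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    run_novel: bool = True,
    run_targets: bool = True,
) -> PipelineResult:
    config.validate()
    libraries = {
        label: sio.parse_reads(path, config.library_format)
        for label, path in config.libraries.items()
    }
    reference = _read_fasta(config.reference)
    mature_db = list(_read_fasta(config.mature_db).items())
    ncrna_db = _read_ncrna(config.ncrna_db)
    result = analyze_libraries(
        libraries, reference, mature_db, ncrna_db, config, run_novel=run_novel
    )
    if out_dir is not None:
        _write_reports(result, Path(out_dir), config, reference, run_targets)
    return result


def analyze_libraries(
    libraries: dict[str, sio.RawLibrary],
    reference: dict[str, str],
    mature_db: list[tuple[str, str]],
    ncrna_db: list[tuple[str, str, str]],
    config: PipelineConfig | None = None,
    run_novel: bool = True,
) -> PipelineResult:
    """The analysis stages on already-loaded libraries (clean -> collapse ->
    map -> ncRNA exclusion -> known matching -> novel calling -> DE)."""
    config = config or PipelineConfig()
    labels = list(libraries)

    # clean + collapse
    table: sio.TagTable | None = None
    cleaning: dict[str, sio.CleaningReport] = {}
    raw_totals: dict[str, int] = {}
    for label in labels:
        lib = libraries[label]
        raw_totals[label] = len(lib)
        clean, report = sio.clean_reads(
            lib, config.adapter3, config.adapter5, config.min_len, config.max_len
        )
        clean.name = label
        cleaning[label] = report
        t = sio.collapse(clean, label)
        table = t if table is None else sio.merge_tables(table, t)
        log.info("%s: %d raw, %d clean, %d unique", label, len(lib), report.kept, len(t))
    assert table is not None

    # map, exclude ncRNA, identify known
    mapped, unmapped = ann.map_reference(table, reference)
    nc_classes, remaining = ann.filter_ncrna(list(mapped), ncrna_db)
    hits = ann.match_mirbase(remaining, mature_db, config.max_mismatch)
    hit_tags = {h.tag for h in hits}
    annotations: dict[str, str] = {}
    for tag in table.sequences():
        if tag in nc_classes:
            annotations[tag] = nc_classes[tag]
        elif tag in hit_tags:
            annotations[tag] = "miRNA"
        else:
            annotations[tag] = "unannotated"

    stats = {
        label: sio.category_accounting(table, annotations, label, raw_totals[label])
        for label in labels
    }
    families = ann.family_summary(hits, table, stats)

    # novel miRNAs from unannotated mapped tags
    novel: list[nh.NovelMiRNA] = []
    if run_novel:
        unann_mapped = {
            t: mapped[t]
            for t in mapped
            if annotations[t] == "unannotated"
            and table.total_count(t) >= config.novel_min_support
        }
        crit = dataclasses.replace(config.hairpin, min_read_support=config.novel_min_support)
        novel = nh.call_novel(unann_mapped, reference, table, crit)

    # differential expression: known (by primary mature id) + novel records
    n1, n2 = stats[labels[0]].total_clean, stats[labels[1]].total_clean
    counts: dict[str, tuple[int, int]] = {}
    kinds: dict[str, str] = {}
    fams: dict[str, str] = {}
    by_id: dict[str, set[str]] = {}
    for h in hits:
        if h.primary:
            by_id.setdefault(h.mirna_id, set()).add(h.tag)
    for mid, tags in by_id.items():
        counts[mid] = (
            sum(table.count(t, labels[0]) for t in tags),
            sum(table.count(t, labels[1]) for t in tags),
        )
        kinds[mid] = "known"
        fams[mid] = ann.assign_family(mid)
    for rec in novel:
        counts[rec.name] = (
            table.count(rec.mature, labels[0]),
            table.count(rec.mature, labels[1]),
        )
        kinds[rec.name] = "novel"
        fams[rec.name] = rec.name
    records = de.de_table(counts, n1, n2, config.thresholds, kinds, fams)
    summary = de.summarize(records)

    return PipelineResult(
        stats, cleaning, table, annotations, hits, families, novel, records, summary
    )


def _write_reports(
    res: PipelineResult,
    out_dir: Path,
    config: PipelineConfig,
    reference: dict[str, str],
    run_targets: bool,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = list(res.stats)

    rows = []
    for label in labels:
        st = res.stats[label]
        rows.append(
            {"library": label, "category": "total", "unique": st.unique_clean,
             "total": st.total_clean, "unique_pct": 100.0, "total_pct": 100.0}
        )
        for cat in sio.CATEGORIES:
            rows.append(
                {"library": label, "category": cat,
                 "unique": st.unique_by_category[cat], "total": st.total_by_category[cat],
                 "unique_pct": st.unique_pct(cat), "total_pct": st.total_pct(cat)}
            )
        assert sum(st.total_by_category.values()) == st.total_clean
    pd.DataFrame(rows).to_csv(out_dir / "table1_categories.tsv", sep="\t", index=False)

    rows = []
    for label in labels:
        hist, mode = sio.length_distribution(res.tag_table, label)
        for ln, n in hist.items():
            rows.append({"library": label, "length": ln, "reads": n, "modal": ln == mode})
    pd.DataFrame(rows).to_csv(out_dir / "length_histogram.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {"family": f.family, "conserved": f.conserved, "n_members": f.n_members,
             **{f"reads_{l}": f.reads_per_library[l] for l in labels},
             **{f"norm_{l}": round(f.normalized_per_library[l], 2) for l in labels},
             "log2fc": round(f.log2fc, 2)}
            for f in res.families
        ]
    ).to_csv(out_dir / "family_summary.tsv", sep="\t", index=False)

    frame = de.records_frame(res.records)
    frame[frame["mirna"].map(lambda m: not m.startswith("rsa-miRn"))].to_csv(
        out_dir / "de_known.tsv", sep="\t", index=False
    )
    frame[frame["mirna"].map(lambda m: m.startswith("rsa-miRn"))].to_csv(
        out_dir / "de_novel.tsv", sep="\t", index=False
    )

    with open(out_dir / "novel_mirnas.tsv", "w") as fh, open(
        out_dir / "precursors.fasta", "w"
    ) as fa, open(out_dir / "structures.dbn", "w") as db:
        fh.write("name\tmature\tref_id\tstart\tend\tstrand\tmfe\tstar_observed\n")
        for rec in res.novel:
            w = rec.candidate.window
            fh.write(
                f"{rec.name}\t{rec.mature}\t{w.ref_id}\t{w.start}\t{w.end}\t{w.strand}"
                f"\t{rec.candidate.fold.mfe:.1f}\t{rec.star_observed}\n"
            )
            fa.write(f">{rec.name}\n{rec.candidate.fold.sequence}\n")
            db.write(
                f">{rec.name}\n{rec.candidate.fold.sequence}\n"
                f"{rec.candidate.fold.structure} ({rec.candidate.fold.mfe:.1f})\n"
            )

    if run_targets and config.transcripts:
        transcripts = _read_fasta(config.transcripts)
        mature_by_id = dict(_mature_for_de(res))
        rows = []
        for mid in sorted(mature_by_id):
            for tid in sorted(transcripts):
                for site in tp.find_sites(
                    mature_by_id[mid], transcripts[tid], config.target_cutoff,
                    mirna_id=mid, transcript_id=tid,
                ):
                    ok, reasons = tp.schwab_filter(site)
                    rows.append(
                        {"mirna": mid, "transcript": tid, "start": site.start,
                         "end": site.end, "expectation": site.expectation,
                         "mode": site.mode, "passes": ok, "reasons": ";".join(reasons)}
                    )
        pd.DataFrame(rows).to_csv(out_dir / "targets.tsv", sep="\t", index=False)

    with open(out_dir / "run_log.txt", "w") as fh:
        for label in labels:
            fh.write(f"{label} cleaning: {res.cleaning[label].as_dict()}\n")
        fh.write(f"summary: {res.summary}\n")


def _mature_for_de(res: PipelineResult):
    sig = {r.mirna_id for r in res.records if r.significant}
    tag_by_id: dict[str, str] = {}
    for h in res.known_hits:
        if h.primary and h.mirna_id in sig and h.mirna_id not in tag_by_id:
            tag_by_id[h.mirna_id] = h.tag
    for rec in res.novel:
        if rec.name in sig:
            tag_by_id[rec.name] = rec.mature
    return tag_by_id.items()
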