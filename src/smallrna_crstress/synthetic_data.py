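"""Seeded synthetic study generator: reference, databases, libraries, truth.

Emulates the structure of a two-library (control vs treatment) small RNA
sequencing experiment at reduced scale: a contig reference with planted
known-miRNA loci, novel hairpin precursors and ncRNA decoys; a
mature-miRNA database; and two read libraries whose per-source counts are
drawn Poisson around specified expectations, with designated miRNAs given
true log2 fold changes.  Reads carry the 3' adapter and a 16-29 nt insert
length profile with a 21-nt mode, so the cleaning/collapsing stages see
realistic input.  Everything derives from one integer seed and is
bit-identical across runs.

What it does *not* emulate: sequencing error beyond adapter failure,
quality-score structure, genomic repeat families, or isomiR end
heterogeneity — so pipeline recovery on these data bounds algorithmic
correctness, not performance on real libraries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotate_known import reverse_complement
from .novel_hairpin import (
    DEFAULT_CRITERIA,
    DEFAULT_MODEL,
    EnergyModel,
    HairpinCriteria,
    Window,
    evaluate_hairpin,
)
from .sequence_io import RawLibrary, RawRead

__all__ = [
    "SimulationSpec",
    "PlantedLocus",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate",
    "table_fixtures",
]

# re-exported here because the printed-table fixtures are, like the
# generator, packaged stand-ins for data the pipeline cannot re-sequence
from .study_tables import table_fixtures  # noqa: E402

_BASES = np.array(list("ACGT"))

#: insert length profile over 16-29 nt, 21-nt modal (clean window keeps 19-29)
DEFAULT_LENGTH_PROFILE = {
    16: 0.01, 17: 0.01, 18: 0.02, 19: 0.05, 20: 0.12, 21: 0.35, 22: 0.15,
    23: 0.07, 24: 0.12, 25: 0.04, 26: 0.02, 27: 0.02, 28: 0.01, 29: 0.01,
}

#: true log2 fold changes planted by default (treatment over control)
DEFAULT_DE_LFC = (3.0, -3.0, 2.0, -2.0, 4.0, -4.0, 2.5, -2.5, 3.5, -3.5)


@dataclass
class SimulationSpec:
    """All generator knobs; the defaults are the simulated study design.

    Library depths keep the treated/control ratio of the sequenced study
    (~1.08) at one-twentieth scale per million.
    """

    seed: int = 0
    n_contigs: int = 20
    contig_length: int = 2000
    n_known_mirnas: int = 50
    n_novel_hairpins: int = 10
    n_ncrna_decoys: int = 8
    library_depths: dict[str, int] = field(
        default_factory=lambda: {"CK": 1_000_000, "Cr200": 1_080_000}
    )
    de_spec: dict[str, float] | None = None  # miRNA id -> true log2 FC
    contamination_fractions: dict[str, float] = field(
        default_factory=lambda: {"rRNA": 0.073, "tRNA": 0.009, "snRNA": 0.001, "snoRNA": 0.0005}
    )
    mirna_de_expected: tuple[int, int] = (150, 1500)   # expected CK counts, DE set
    mirna_null_expected: tuple[int, int] = (20, 2000)  # expected CK counts, null set
    novel_expected: tuple[int, int] = (50, 500)
    background_loci: int = 2000
    length_profile: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_PROFILE)
    )
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter_failure: float = 0.01
    star_fraction: float = 0.4   # hairpins that also emit star reads
    overdispersion: float = 0.0  # 0 = Poisson; >0 = gamma-Poisson dispersion
    hairpin_length_range: tuple[int, int] = (50, 330)
    n_decoy_mature: int = 10     # database entries with no planted locus

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.library_depths.values()):
            raise ValueError("library depths must be positive")
        if len(self.library_depths) != 2:
            raise ValueError("exactly two libraries expected")
        if abs(sum(self.length_profile.values()) - 1.0) > 1e-6:
            raise ValueError("length profile must sum to 1")

    @property
    def labels(self) -> tuple[str, str]:
        labs = tuple(self.library_depths)
        return labs  # (control, treatment) order

    def resolved_de_spec(self) -> dict[str, float]:
        if self.de_spec is not None:
            return dict(self.de_spec)
        names = [_mirna_name(i) for i in range(min(len(DEFAULT_DE_LFC), self.n_known_mirnas))]
        return dict(zip(names, DEFAULT_DE_LFC))


def _mirna_name(i: int) -> str:
    return f"miR{1001 + i}a"


@dataclass(frozen=True)
class PlantedLocus:
    kind: str  # known / novel / ncRNA / background
    name: str
    ref_id: str
    start: int
    end: int
    strand: str
    sequence: str  # the read-producing (mature/tag) sequence


@dataclass
class SyntheticTruth:
    planted: list[PlantedLocus]
    expected_counts: dict[str, dict[str, float]]  # name -> label -> expectation
    realized_counts: dict[str, dict[str, int]]
    true_log2fc: dict[str, float]

    def loci_by_kind(self, kind: str) -> list[PlantedLocus]:
        return [p for p in self.planted if p.kind == kind]


@dataclass
class SyntheticDataset:
    spec: SimulationSpec
    reference: dict[str, str]
    mature_db: list[tuple[str, str]]
    ncrna_db: list[tuple[str, str, str]]  # (id, class, sequence)
    libraries: dict[str, RawLibrary]
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write reference/mature/ncRNA FASTA, per-library FASTQ, truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        p = outdir / "reference.fasta"
        with open(p, "w") as fh:
            for rid, seq in self.reference.items():
                fh.write(f">{rid}\n{seq}\n")
        paths["reference"] = p
        p = outdir / "mature.fasta"
        with open(p, "w") as fh:
            for mid, seq in self.mature_db:
                fh.write(f">{mid}\n{seq.replace('T', 'U')}\n")
        paths["mature"] = p
        p = outdir / "ncrna.fasta"
        with open(p, "w") as fh:
            for rid, cls, seq in self.ncrna_db:
                fh.write(f">{rid} class={cls}\n{seq}\n")
        paths["ncrna"] = p
        for label, lib in self.libraries.items():
            p = outdir / f"{label}.fastq"
            with open(p, "w") as fh:
                for i, read in enumerate(lib.reads):
                    q = read.quality or "I" * len(read.sequence)
                    fh.write(f"@{label}_{i}\n{read.sequence}\n+\n{q}\n")
            paths[label] = p
        p = outdir / "truth.tsv"
        labels = list(self.libraries)
        with open(p, "w") as fh:
            fh.write(
                "name\tkind\tref_id\tstart\tend\tstrand\tsequence\t"
                + "\t".join(f"expected_{l}" for l in labels)
                + "\t" + "\t".join(f"count_{l}" for l in labels)
                + "\ttrue_log2fc\n"
            )
            for pl in self.truth.planted:
                exp = self.truth.expected_counts.get(pl.name, {})
                got = self.truth.realized_counts.get(pl.name, {})
                fh.write(
                    f"{pl.name}\t{pl.kind}\t{pl.ref_id}\t{pl.start}\t{pl.end}\t{pl.strand}\t{pl.sequence}\t"
                    + "\t".join(str(exp.get(l, "")) for l in labels)
                    + "\t" + "\t".join(str(got.get(l, "")) for l in labels)
                    + f"\t{self.truth.true_log2fc.get(pl.name, '')}\n"
                )
        paths["truth"] = p
        return paths


# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _plant(
    rng: np.random.Generator,
    contigs: dict[str, str],
    occupied: dict[str, list[tuple[int, int]]],
    seq: str,
    margin: int = 30,
) -> tuple[str, int]:
    """Overwrite a free stretch of a random contig with ``seq``."""
    rids = list(contigs)
    for _ in range(200):
        rid = rids[rng.integers(0, len(rids))]
        c = contigs[rid]
        if len(c) < len(seq) + 2 * margin:
            continue
        pos = int(rng.integers(margin, len(c) - len(seq) - margin))
        window = (pos - margin, pos + len(seq) + margin)
        if any(a < window[1] and window[0] < b for a, b in occupied[rid]):
            continue
        contigs[rid] = c[:pos] + seq + c[pos + len(seq):]
        occupied[rid].append((pos, pos + len(seq)))
        return rid, pos
    raise RuntimeError("could not place a planted locus; reference too crowded")


def _build_hairpin(
    rng: np.random.Generator,
    mature: str,
    target_len: int,
    criteria: HairpinCriteria = DEFAULT_CRITERIA,
    model: EnergyModel = DEFAULT_MODEL,
    max_tries: int = 100,
) -> tuple[str, int]:
    """Construct a precursor containing ``mature`` on its 5' arm that the
    hairpin caller accepts (rejection sampling against the model fold).

    Returns (precursor, mature offset).  The stem is an inverted repeat
    with 0-2 injected star mutations; flanking stem extensions reach the
    target length.
    """
    m = len(mature)
    if target_len < 2 * m + 8:
        raise ValueError(
            f"target length {target_len} cannot hold a {m}-nt mature:star duplex"
        )
    for _ in range(max_tries):
        loop = _random_seq(rng, int(rng.integers(8, 16)))
        star = list(reverse_complement(mature))
        for _ in range(int(rng.integers(0, 3))):  # mild duplex imperfection
            k = int(rng.integers(2, len(star) - 2))
            star[k] = str(rng.choice([b for b in "ACGT" if b != star[k]]))
        core5, core3 = mature, "".join(star)
        ext = max(0, (target_len - 2 * m - len(loop)) // 2)
        left = _random_seq(rng, ext)
        precursor = left + core5 + loop + core3 + reverse_complement(left)
        offset = ext
        window = Window("synthetic", 0, len(precursor), "+", offset, precursor)
        cand = evaluate_hairpin(window, mature, None, criteria, model)
        if cand.accepted:
            return precursor, offset
    raise RuntimeError(
        f"could not build an acceptable hairpin of ~{target_len} nt in {max_tries} tries"
    )


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, overdispersion: float) -> np.ndarray:
    if overdispersion > 0:
        shape = 1.0 / overdispersion
        lam = rng.gamma(shape, np.asarray(mean) / shape)
    else:
        lam = np.asarray(mean)
    return rng.poisson(lam)


def generate(spec: SimulationSpec) -> SyntheticDataset:
    """Generate the full synthetic dataset for one seed."""
    rng = np.random.default_rng(spec.seed)
    ctrl, treat = spec.labels
    depth_ratio = spec.library_depths[treat] / spec.library_depths[ctrl]
    de = spec.resolved_de_spec()

    contigs = {f"contig{i + 1}": _random_seq(rng, spec.contig_length) for i in range(spec.n_contigs)}
    occupied: dict[str, list[tuple[int, int]]] = {rid: [] for rid in contigs}
    planted: list[PlantedLocus] = []
    sources: list[tuple[str, str, str, float, float]] = []
    # (name, kind, insert sequence, expected ctrl count, expected treat count)

    # known miRNA loci + mature database
    mature_db: list[tuple[str, str]] = []
    seen_mature: set[str] = set()
    for i in range(spec.n_known_mirnas):
        name = _mirna_name(i)
        length = int(rng.choice([20, 21, 21, 21, 22]))
        mature = _random_seq(rng, length)
        while mature in seen_mature:
            mature = _random_seq(rng, length)
        seen_mature.add(mature)
        rid, pos = _plant(rng, contigs, occupied, mature)
        planted.append(PlantedLocus("known", name, rid, pos, pos + length, "+", mature))
        mature_db.append((name, mature))
        lfc = de.get(name, 0.0)
        if name in de:
            exp_ck = float(rng.integers(*spec.mirna_de_expected))
        else:
            lo, hi = spec.mirna_null_expected
            exp_ck = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        exp_tr = exp_ck * (2.0 ** lfc) * depth_ratio
        sources.append((name, "known", mature, exp_ck, exp_tr))
    for i in range(spec.n_decoy_mature):
        mature_db.append((f"miR{2001 + i}a", _random_seq(rng, 21)))

    # novel hairpin loci
    for i in range(spec.n_novel_hairpins):
        name = f"novel{i + 1}"
        mature = _random_seq(rng, 21)
        lo, hi = spec.hairpin_length_range
        precursor, offset = _build_hairpin(rng, mature, int(rng.integers(lo, hi + 1)))
        rid, pos = _plant(rng, contigs, occupied, precursor)
        planted.append(
            PlantedLocus("novel", name, rid, pos + offset, pos + offset + 21, "+", mature)
        )
        planted.append(
            PlantedLocus(
                "novel_precursor", f"{name}_pre", rid, pos, pos + len(precursor), "+", precursor
            )
        )
        exp_ck = float(rng.integers(*spec.novel_expected))
        sources.append((name, "novel", mature, exp_ck, exp_ck * depth_ratio))
        if rng.random() < spec.star_fraction and offset >= 2:
            # 3'-arm star with the canonical 2-nt 3' overhangs at both ends
            star = precursor[len(precursor) - offset - 21 + 2 : len(precursor) - offset + 2]
            if len(star) == 21:
                sources.append((f"{name}*", "novel_star", star, exp_ck * 0.1, exp_ck * 0.1 * depth_ratio))

    # ncRNA decoys, embedded in the reference and listed in the database
    classes = ("rRNA", "tRNA", "snRNA", "snoRNA")
    ncrna_db: list[tuple[str, str, str]] = []
    nc_loci: dict[str, list[tuple[str, str]]] = {c: [] for c in classes}
    for i in range(spec.n_ncrna_decoys):
        cls = classes[i % len(classes)]
        seq = _random_seq(rng, int(rng.integers(120, 220)))
        rid, pos = _plant(rng, contigs, occupied, seq)
        rec = f"{cls.lower()}_decoy{i + 1}"
        ncrna_db.append((rec, cls, seq))
        nc_loci[cls].append((rec, seq))
        planted.append(PlantedLocus("ncRNA", rec, rid, pos, pos + len(seq), "+", seq))

    # background (unannotated) loci
    lengths = np.array(sorted(spec.length_profile))
    length_p = np.array([spec.length_profile[l] for l in lengths])
    bg_seqs: list[str] = []
    rids = list(contigs)
    for i in range(spec.background_loci):
        ln = int(rng.choice(lengths, p=length_p))
        for _ in range(50):  # background lives in unannotated regions
            rid = rids[rng.integers(0, len(rids))]
            pos = int(rng.integers(0, spec.contig_length - ln))
            if not any(a < pos + ln and pos < b for a, b in occupied[rid]):
                break
        bg_seqs.append(contigs[rid][pos : pos + ln])

    # expected count budget per library
    depths = spec.library_depths
    exp: dict[str, dict[str, float]] = {lab: {} for lab in depths}
    scale = {ctrl: depths[ctrl] / 1e6, treat: depths[ctrl] / 1e6}
    for name, kind, seq, e_ck, e_tr in sources:
        exp[ctrl][name] = e_ck * scale[ctrl]
        exp[treat][name] = e_tr * scale[treat]
    nc_names: list[tuple[str, str]] = []  # (name, insert)
    nc_expected: dict[str, dict[str, float]] = {lab: {} for lab in depths}
    for cls, frac in spec.contamination_fractions.items():
        if not nc_loci[cls]:
            continue
        for lab in depths:
            per = frac * depths[lab]
            # reads are random sub-fragments of the class decoys
            for rec, seq in nc_loci[cls]:
                nc_expected[lab][rec] = per / len(nc_loci[cls])

    used = {lab: sum(exp[lab].values()) + sum(nc_expected[lab].values()) for lab in depths}
    bg_total = {lab: max(0.0, depths[lab] - used[lab]) for lab in depths}
    bg_w = np.exp(rng.uniform(0.0, math.log(50.0), size=len(bg_seqs)))
    bg_w /= bg_w.sum()

    libraries: dict[str, RawLibrary] = {}
    realized: dict[str, dict[str, int]] = {}
    for lab in depths:
        lib = RawLibrary(name=lab)
        # planted miRNA / novel sources
        names = [s[0] for s in sources]
        means = np.array([exp[lab][n] for n in names])
        counts = _draw_counts(rng, means, spec.overdispersion)
        for (name, kind, insert, _, _), n in zip(sources, counts):
            realized.setdefault(name, {})[lab] = int(n)
            _emit(rng, lib, insert, int(n), spec)
        # ncRNA fragments
        for rec, cls, seq in ncrna_db:
            mean = nc_expected[lab].get(rec, 0.0)
            n = int(_draw_counts(rng, np.array([mean]), spec.overdispersion)[0])
            realized.setdefault(rec, {})[lab] = n
            frag_lens = rng.choice(lengths, p=length_p, size=n)
            starts = rng.integers(0, np.maximum(1, len(seq) - frag_lens))
            frags: dict[str, int] = {}
            for st, ln in zip(starts, frag_lens):
                frag = seq[int(st) : int(st) + int(ln)]
                frags[frag] = frags.get(frag, 0) + 1
            for frag, k in frags.items():
                _emit(rng, lib, frag, k, spec)
        # background
        bcounts = _draw_counts(rng, bg_w * bg_total[lab], spec.overdispersion)
        for seq_, n in zip(bg_seqs, bcounts):
            if n:
                _emit(rng, lib, seq_, int(n), spec)
        libraries[lab] = lib

    true_lfc = {name: de.get(name, 0.0) for name, kind, *_ in sources if kind == "known"}
    for name, kind, *_ in sources:
        if kind == "novel":
            true_lfc[name] = 0.0
    truth = SyntheticTruth(
        planted=planted,
        expected_counts={
            name: {lab: exp[lab].get(name, nc_expected[lab].get(name, 0.0)) for lab in depths}
            for name in {*exp[ctrl], *nc_expected[ctrl]}
        },
        realized_counts=realized,
        true_log2fc=true_lfc,
    )
    return SyntheticDataset(
        spec=spec,
        reference=contigs,
        mature_db=mature_db,
        ncrna_db=ncrna_db,
        libraries=libraries,
        truth=truth,
    )


def _emit(rng: np.random.Generator, lib: RawLibrary, insert: str, n: int, spec: SimulationSpec) -> None:
    """Append n reads for one insert; a small fraction lack the adapter."""
    if n <= 0 or not insert:
        return
    n_fail = int(rng.binomial(n, spec.adapter_failure)) if spec.adapter_failure > 0 else 0
    if n - n_fail > 0:
        read = RawRead(insert + spec.adapter3)
        lib.reads.extend([read] * (n - n_fail))
    if n_fail > 0:
        bad = RawRead(insert + _random_seq(rng, len(spec.adapter3)))
        lib.reads.extend([bad] * n_fail)
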