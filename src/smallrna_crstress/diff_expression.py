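"""Two-library differential expression of miRNA counts.

The study design is two pooled libraries (control ``CK`` and treatment
``Cr200``) with no replicates, so significance comes from an exact
two-library count test in the Audic-Claverie family: conditional on a tag's
count x in library 1 (clean total n1), its count in library 2 (clean total
n2) follows, under the null of equal concentration,

    p(y | x) = r^y * (x+y)! / (x! * y! * (1+r)^(x+y+1)),    r = n2/n1,

a negative binomial with r+1 = x+1 successes and success probability
1/(1+r).  The two-sided p-value doubles the smaller tail; to make the
statistic exactly symmetric in the two libraries we evaluate both
conditioning orientations and report the smaller (they differ only in
which library is conditioned on, typically far below the reported
precision).

Expression values are normalized to reads per million (RPM) of the
library's clean total; zero RPM is replaced by a 0.01 floor before fold
changes, and miRNAs below 1 RPM in both libraries are excluded from
testing.  Significance uses the asymmetric thresholds log2FC >= 2 (up) or
< -0.5 (down) together with p <= 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import mpmath
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln, logsumexp

__all__ = [
    "DEThresholds",
    "ExpressionRecord",
    "normalize_rpm",
    "substitute_floor",
    "log2_fold_change",
    "two_library_pvalue",
    "classify",
    "de_table",
    "summarize",
]


@dataclass
class DEThresholds:
    """Decision thresholds for the up/down call.

    ``up_min``/``down_max`` are log2 units (up: >=, down: strict <);
    ``p_max`` the significance level; ``floor`` the RPM substituted for
    zero; ``min_norm`` the both-library RPM bound below which a miRNA is
    excluded as too low-abundance.
    """

    up_min: float = 2.0
    down_max: float = -0.5
    p_max: float = 0.05
    floor: float = 0.01
    min_norm: float = 1.0

    def __post_init__(self) -> None:
        if not (self.up_min > 0 > self.down_max):
            raise ValueError("need up_min > 0 > down_max")
        if not (0 < self.p_max < 1):
            raise ValueError("p_max must be in (0, 1)")
        if self.floor <= 0:
            raise ValueError("floor must be positive")


@dataclass
class ExpressionRecord:
    mirna_id: str
    count_ck: int
    count_tr: int
    norm_ck: float
    norm_tr: float
    log2fc: float = math.nan
    pvalue: float = math.nan
    excluded: bool = False
    significant: bool = False
    direction: str = "none"  # up / down / none
    kind: str = "known"      # known / novel
    family: str | None = None


def normalize_rpm(count: int, total_clean: int) -> float:
    """Reads-per-million: count / total clean reads * 1e6."""
    if total_clean <= 0:
        raise ValueError("total_clean must be positive")
    if count < 0:
        raise ValueError("negative count")
    return count / total_clean * 1e6


def substitute_floor(norm: float, floor: float = 0.01) -> float:
    """Replace a zero expression value by the floor (default 0.01 RPM)."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    return floor if norm == 0 else norm


def log2_fold_change(norm_tr: float, norm_ck: float) -> float:
    """log2(treatment / control); inputs must be floor-substituted."""
    if norm_tr <= 0 or norm_ck <= 0:
        raise ValueError("fold change needs positive inputs; apply the floor first")
    return math.log2(norm_tr / norm_ck)


def _tails(x: int, y: int, n1: int, n2: int) -> tuple[float, float]:
    """(lower, upper) tail of y conditional on x under equal concentration."""
    r = n2 / n1
    p = 1.0 / (1.0 + r)
    lo = float(sps.nbinom.cdf(y, x + 1, p))
    up = float(sps.nbinom.sf(y - 1, x + 1, p))
    return lo, up


def _tail_mpmath(x: int, y: int, n1: int, n2: int, lower: bool) -> float:
    """Arbitrary-precision direct tail summation (extreme-tail fallback
    for moderate counts)."""
    with mpmath.workdps(40):
        r = mpmath.mpf(n2) / n1
        term = (1 + r) ** mpmath.mpf(-(x + 1))  # p(0 | x)
        if lower:
            total = term
            for yp in range(y):
                term = term * r * (x + yp + 1) / ((yp + 1) * (1 + r))
                total += term
            return float(total)
        for yp in range(y):
            term = term * r * (x + yp + 1) / ((yp + 1) * (1 + r))
        total = term
        yp = y
        while True:
            term = term * r * (x + yp + 1) / ((yp + 1) * (1 + r))
            total += term
            yp += 1
            if term < total * mpmath.mpf("1e-25"):
                return float(total)


def _tail_logspace(x: int, y: int, n1: int, n2: int, lower: bool) -> float:
    """Float log-space tail summation for huge counts, where the absolute
    value is far below float range but only its magnitude matters."""
    logr = math.log(n2) - math.log(n1)
    log1pr = math.log1p(n2 / n1)

    def logterms(ys: np.ndarray) -> np.ndarray:
        return (
            gammaln(x + ys + 1)
            - gammaln(x + 1)
            - gammaln(ys + 1)
            + ys * logr
            - (x + ys + 1) * log1pr
        )

    if lower:
        total = float(logsumexp(logterms(np.arange(0, y + 1))))
    else:
        total = -math.inf
        start, chunk = y, 65_536
        while True:
            lt = logterms(np.arange(start, start + chunk))
            total = float(np.logaddexp(total, logsumexp(lt)))
            start += chunk
            if lt[-1] < total - 80.0:  # remaining terms are negligible
                break
    return max(math.exp(total), 5e-324)


def _onesided(x: int, y: int, n1: int, n2: int) -> float:
    lo, up = _tails(x, y, n1, n2)
    small = min(lo, up)
    if small == 0.0 or small < 1e-280:
        lower = lo <= up
        if x + y <= 20_000:
            small = _tail_mpmath(x, y, n1, n2, lower)
            if small == 0.0:
                # below the float range entirely; report the smallest
                # positive float rather than an exact zero
                small = 5e-324
        else:
            small = _tail_logspace(x, y, n1, n2, lower)
    return small


def two_library_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Exact two-sided p-value for counts (x of n1) vs (y of n2).

    Doubles the smaller conditional tail; evaluated in both conditioning
    orientations and the smaller taken, which makes the statistic exactly
    symmetric under (x, n1) <-> (y, n2).
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    p_a = 2.0 * _onesided(x, y, n1, n2)
    p_b = 2.0 * _onesided(y, x, n2, n1)
    return min(1.0, p_a, p_b)


def classify(record: ExpressionRecord, th: DEThresholds | None = None) -> ExpressionRecord:
    """Fill the excluded/significant/direction fields of a record.

    Exclusion uses *pre-floor* RPM values: a miRNA under ``min_norm`` RPM in
    both libraries is too low-abundance to test.  Significance requires
    p <= p_max and log2FC >= up_min (up) or < down_max (down).
    """
    th = th or DEThresholds()
    record.excluded = record.norm_ck < th.min_norm and record.norm_tr < th.min_norm
    if record.excluded:
        record.significant = False
        record.direction = "none"
        return record
    passes_fc = record.log2fc >= th.up_min or record.log2fc < th.down_max
    record.significant = bool(record.pvalue <= th.p_max and passes_fc)
    if record.significant:
        record.direction = "up" if record.log2fc > 0 else "down"
    else:
        record.direction = "none"
    return record


def de_table(
    counts: Mapping[str, tuple[int, int]],
    n1: int,
    n2: int,
    th: DEThresholds | None = None,
    kinds: Mapping[str, str] | None = None,
    families: Mapping[str, str] | None = None,
) -> list[ExpressionRecord]:
    """Build classified expression records from per-miRNA raw counts.

    ``counts`` maps miRNA id -> (count in library 1, count in library 2);
    ``n1``/``n2`` are the clean-read totals.  Records come back in
    deterministic (family, id) order.
    """
    th = th or DEThresholds()
    records = []
    for mid, (x, y) in counts.items():
        norm_ck = normalize_rpm(x, n1)
        norm_tr = normalize_rpm(y, n2)
        rec = ExpressionRecord(
            mirna_id=mid,
            count_ck=x,
            count_tr=y,
            norm_ck=norm_ck,
            norm_tr=norm_tr,
            kind=(kinds or {}).get(mid, "known"),
            family=(families or {}).get(mid),
        )
        rec.log2fc = log2_fold_change(
            substitute_floor(norm_tr, th.floor), substitute_floor(norm_ck, th.floor)
        )
        rec.pvalue = two_library_pvalue(x, y, n1, n2)
        classify(rec, th)
        records.append(rec)
    records.sort(key=lambda r: (r.family or "", r.mirna_id))
    return records


def summarize(records: Sequence[ExpressionRecord]) -> dict[str, int]:
    """Tallies of significant / up / down calls, split known vs novel."""
    sig = [r for r in records if r.significant]
    out = {
        "n_tested": sum(not r.excluded for r in records),
        "n_excluded": sum(r.excluded for r in records),
        "n_significant": len(sig),
        "n_up": sum(r.direction == "up" for r in sig),
        "n_down": sum(r.direction == "down" for r in sig),
        "n_known_significant": sum(r.kind == "known" for r in sig),
        "n_novel_significant": sum(r.kind == "novel" for r in sig),
    }
    assert out["n_up"] + out["n_down"] == out["n_significant"]
    return out


def records_frame(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    """Records as a DataFrame in report layout (RPM to 4 d.p., FC to 2)."""
    rows = []
    for r in records:
        rows.append(
            {
                "family": r.family or "",
                "mirna": r.mirna_id,
                "count_ck": r.count_ck,
                "count_tr": r.count_tr,
                "norm_ck": round(substitute_floor(r.norm_ck), 4),
                "norm_tr": round(substitute_floor(r.norm_tr), 4),
                "log2fc": round(r.log2fc, 2),
                "pvalue": r.pvalue,
                "sig": "**" if (r.significant and r.pvalue < 0.01) else "",
                "direction": {"up": "up-regulated", "down": "down-regulated"}.get(
                    r.direction, ""
                ),
                "excluded": r.excluded,
            }
        )
    return pd.DataFrame(rows)
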