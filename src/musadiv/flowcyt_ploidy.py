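"""Ploidy estimation from flow-cytometry nuclear DNA content.

2C DNA content is estimated from the ratio of the sample fluorescence peak
to an internal *Pisum sativum* standard (2C = 9.09 pg) and mapped to a
ploidy class through disjoint per-class windows. In *Musa* the three
cultivated ploidy classes sit near 1.26 pg (2x), 1.93 pg (3x) and 2.45 pg
(4x); the calling windows bracket the realized per-class ranges with
margin, so any 2C between windows is reported indeterminate rather than
force-classified. A sample whose histogram shows two sufficiently large
peaks in different windows is called mixoploid (nuclei of different ploidy
coexisting in one individual).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from musadiv.pipeline_io import MIXOPLOID, UNDETERMINED, AccessionRecord, PipelineConfig

log = logging.getLogger("musadiv")

#: 2C DNA content of the internal standard (Pisum sativum), pg.
STANDARD_2C_PG = 9.09

DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "2x": (1.10, 1.55),
    "3x": (1.75, 2.15),
    "4x": (2.20, 2.70),
}


@dataclass(frozen=True)
class FlowCytSample:
    """Peak statistics for one accession's histogram.

    ``sample_peaks`` holds (mean fluorescence, fraction of nuclei) pairs;
    ``standard_peak_mean`` is the internal-standard peak position.
    """

    sample_peaks: list[tuple[float, float]]
    standard_peak_mean: float
    replicate_cv: float | None = None

    def __post_init__(self) -> None:
        if not self.sample_peaks:
            raise ValueError("at least one sample peak required")
        fracs = [f for _, f in self.sample_peaks]
        if any(not 0 < f <= 1 for f in fracs) or sum(fracs) > 1 + 1e-9:
            raise ValueError("peak fractions must lie in (0, 1] and sum to <= 1")


@dataclass(frozen=True)
class PloidyCall:
    two_c: float
    klass: str  # 2x | 3x | 4x | mixoploid | indeterminate


def estimate_2c(sample_peak_mean: float, standard_peak_mean: float) -> float:
    """2C (pg) = (sample fluorescence / standard fluorescence) x 9.09 pg."""
    if sample_peak_mean <= 0 or standard_peak_mean <= 0:
        raise ValueError("peak means must be positive")
    return sample_peak_mean / standard_peak_mean * STANDARD_2C_PG


def _windows(windows: dict[str, tuple[float, float]] | None) -> dict[str, tuple[float, float]]:
    win = DEFAULT_WINDOWS if windows is None else windows
    spans = sorted(win.items(), key=lambda kv: kv[1][0])
    for (_, (_, hi)), (_, (lo, _)) in zip(spans, spans[1:]):
        if hi >= lo:
            raise ValueError("ploidy windows must be disjoint")
    return win


def call_ploidy(
    two_c: float, windows: dict[str, tuple[float, float]] | None = None
) -> PloidyCall:
    """Classify a numeric 2C value; values between windows are indeterminate."""
    if two_c <= 0:
        raise ValueError("2C must be positive")
    for klass, (lo, hi) in _windows(windows).items():
        if lo <= two_c <= hi:
            return PloidyCall(two_c=two_c, klass=klass)
    return PloidyCall(two_c=two_c, klass="indeterminate")


def detect_mixoploidy(
    sample: FlowCytSample,
    windows: dict[str, tuple[float, float]] | None = None,
    min_peak_fraction: float = 0.2,
) -> bool:
    """True iff >= 2 qualifying peaks fall in different ploidy windows.

    A peak qualifies when it carries at least ``min_peak_fraction`` of the
    nuclei, which keeps debris or replication shoulders from triggering a
    mixoploid call.
    """
    classes = set()
    for mean, frac in sample.sample_peaks:
        if frac < min_peak_fraction:
            continue
        call = call_ploidy(estimate_2c(mean, sample.standard_peak_mean), windows)
        if call.klass != "indeterminate":
            classes.add(call.klass)
    return len(classes) >= 2


def call_records(
    records: list[AccessionRecord],
    windows: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Apply :func:`call_ploidy` to every record with a numeric 2C.

    Mixoploid / undetermined rows keep their sentinel class. Returns a
    frame with columns ``index``, ``two_c``, ``klass``.
    """
    rows = []
    for rec in records:
        if rec.two_c == MIXOPLOID:
            rows.append((rec.index, np.nan, "mixoploid"))
        elif rec.two_c == UNDETERMINED:
            rows.append((rec.index, np.nan, "undetermined"))
        else:
            rows.append((rec.index, rec.two_c, call_ploidy(rec.two_c, windows).klass))
    log.info("ploidy calling: %d records, %d numeric", len(records),
             sum(np.isfinite(r[1]) for r in rows))
    return pd.DataFrame(rows, columns=["index", "two_c", "klass"])


def summarize_ploidy_classes(
    records: list[AccessionRecord],
    windows: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-class count / mean / min / max of 2C over numeric records.

    Mixoploid and undetermined records are tallied separately with NaN
    statistics.
    """
    calls = call_records(records, windows)
    out = []
    for klass, grp in calls.groupby("klass"):
        vals = grp["two_c"].dropna()
        out.append(
            {
                "klass": klass,
                "count": len(grp),
                "mean_2c": vals.mean() if len(vals) else np.nan,
                "min_2c": vals.min() if len(vals) else np.nan,
                "max_2c": vals.max() if len(vals) else np.nan,
            }
        )
    if not out:
        return pd.DataFrame(columns=["count", "mean_2c", "min_2c", "max_2c"],
                            index=pd.Index([], name="klass"))
    return pd.DataFrame(out).set_index("klass").sort_index()


def windows_from_config(config: PipelineConfig) -> dict[str, tuple[float, float]]:
    return config.ploidy_windows
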