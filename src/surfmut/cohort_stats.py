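"""Cohort-level statistics: per-patient burdens, prevalence, sharing spectrum.

Quartiles use linear interpolation between order statistics (numpy's
``method="linear"``), which yields fractional medians on even-sized
cohorts; the method name is echoed in the summary so reruns are
comparable. The sharing spectrum counts, for every unique protein-level
variant key, how many distinct patients carry it.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .msp_classifier import MSPCall
from .util import round_half_up

logger = logging.getLogger(__name__)

QUARTILE_METHOD = "linear"


@dataclass(frozen=True)
class PatientSummary:
    sample_id: str
    n_missense: int
    n_msp: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_msp <= self.n_missense):
            raise ValueError(
                f"{self.sample_id}: need 0 <= n_msp <= n_missense, "
                f"got msp={self.n_msp}, missense={self.n_missense}"
            )


@dataclass(frozen=True)
class DistributionStats:
    median: float
    q1: float
    q3: float
    iqr: float
    min: float
    max: float


@dataclass(frozen=True)
class CohortSummary:
    n_patients: int
    missense: DistributionStats
    msp: DistributionStats
    fraction_at_least: dict  # {"missense": {n: prop}, "msp": {n: prop}}
    quartile_method: str = QUARTILE_METHOD


@dataclass(frozen=True)
class SharingSpectrum:
    """How many distinct patients carry each unique variant key."""

    patient_counts: dict  # key -> number of distinct patients
    histogram: dict  # k -> number of unique keys carried by exactly k patients
    n_unique_keys: int
    n_occurrences: int

    def shared_by_at_least(self, k: int) -> int:
        return sum(v for kk, v in self.histogram.items() if kk >= k)

    def percent_shared_by_at_least(self, k: int) -> float:
        """Percentage of unique keys shared by >= k patients, 3 decimals."""
        if self.n_unique_keys == 0:
            return 0.0
        return round_half_up(100.0 * self.shared_by_at_least(k) / self.n_unique_keys, 3)


def summaries_from_calls(
    calls: Iterable[MSPCall], all_samples: Optional[Iterable[str]] = None
) -> list[PatientSummary]:
    """Aggregate classifier calls into per-patient counts.

    ``all_samples`` may name patients that must appear even with zero
    classified variants (they count toward cohort denominators).
    """
    missense: Counter = Counter()
    msp: Counter = Counter()
    samples = set(all_samples or ())
    for call in calls:
        sid = call.variant.sample_id
        samples.add(sid)
        missense[sid] += 1
        if call.is_msp:
            msp[sid] += 1
    return [
        PatientSummary(sid, missense.get(sid, 0), msp.get(sid, 0))
        for sid in sorted(samples)
    ]


def _distribution(values: Sequence[float]) -> DistributionStats:
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method=QUARTILE_METHOD)
    return DistributionStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(q3 - q1),
        min=float(arr.min()),
        max=float(arr.max()),
    )


def summarize_cohort(
    summaries: Sequence[PatientSummary], thresholds: Sequence[int] = (10,)
) -> CohortSummary:
    """Five-number-style summary of per-patient burdens plus prevalences."""
    if not summaries:
        raise ValueError("cannot summarize an empty cohort")
    return CohortSummary(
        n_patients=len(summaries),
        missense=_distribution([s.n_missense for s in summaries]),
        msp=_distribution([s.n_msp for s in summaries]),
        fraction_at_least={
            "missense": {
                int(n): fraction_at_least(summaries, n, "missense") for n in thresholds
            },
            "msp": {int(n): fraction_at_least(summaries, n, "msp") for n in thresholds},
        },
    )


def fraction_at_least(
    summaries: Sequence[PatientSummary],
    n: int,
    which: Literal["missense", "msp"] = "msp",
) -> float:
    """Exact proportion of patients with at least ``n`` counts of the given kind."""
    if not summaries:
        raise ValueError("empty cohort")
    attr = {"missense": "n_missense", "msp": "n_msp"}[which]
    hits = sum(1 for s in summaries if getattr(s, attr) >= n)
    return hits / len(summaries)


def sharing_spectrum(
    calls: Iterable[MSPCall], key_mode: str = "protein_level"
) -> SharingSpectrum:
    """Measure inter-patient sharing of unique variant keys.

    The key is protein-level — (gene, position, ref, alt) — and a patient
    contributes at most once per key. The conservation identities
    ``sum(histogram.values()) == n_unique_keys`` and
    ``sum(k * histogram[k]) == n_occurrences`` hold by construction and are
    asserted.
    """
    if key_mode != "protein_level":
        raise ValueError(f"unsupported key_mode {key_mode!r}")
    carriers: defaultdict = defaultdict(set)
    for call in calls:
        carriers[call.variant.key].add(call.variant.sample_id)
    patient_counts = {key: len(samples) for key, samples in carriers.items()}
    histogram: dict[int, int] = dict(Counter(patient_counts.values()))
    n_unique = len(patient_counts)
    n_occurrences = sum(patient_counts.values())
    assert sum(histogram.values()) == n_unique
    assert sum(k * v for k, v in histogram.items()) == n_occurrences
    return SharingSpectrum(
        patient_counts=patient_counts,
        histogram=histogram,
        n_unique_keys=n_unique,
        n_occurrences=n_occurrences,
    )


def tumor_volume(w: float, l: float) -> float:
    """Ellipsoid-style caliper volume (width squared times length, halved).

    Width is by convention the smaller dimension; inputs are swapped with a
    warning when violated. Negative inputs are a hard error.
    """
    if w < 0 or l < 0:
        raise ValueError("tumor dimensions must be non-negative")
    if w > l:
        logger.warning("width %g > length %g; swapping", w, l)
        w, l = l, w
    return (w**2 * l) / 2


def summaries_to_frame(summaries: Sequence[PatientSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in summaries],
            "n_missense": [s.n_missense for s in summaries],
            "n_msp": [s.n_msp for s in summaries],
        }
    )


def summary_to_dict(summary: CohortSummary) -> dict:
    """JSON-ready view of a cohort summary."""

    def stats(d: DistributionStats) -> dict:
        return {
            "median": d.median,
            "q1": d.q1,
            "q3": d.q3,
            "iqr": d.iqr,
            "min": d.min,
            "max": d.max,
        }

    return {
        "n_patients": summary.n_patients,
        "missense": stats(summary.missense),
        "msp": stats(summary.msp),
        "fraction_at_least": {
            kind: {str(k): v for k, v in mapping.items()}
            for kind, mapping in summary.fraction_at_least.items()
        },
        "quartile_method": summary.quartile_method,
    }


def spectrum_to_frame(spectrum: SharingSpectrum) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "n_patients": sorted(spectrum.histogram),
            "n_unique_keys": [
                spectrum.histogram[k] for k in sorted(spectrum.histogram)
            ],
        }
    )
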