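"""Synthetic proteome and cohort generator with recorded ground truth.

Stands in for real annotation databases and tumor variant tables so every
pipeline stage is testable offline. Sharing between patients and the
hypermutator tail are *constructed*, not sampled: the generator records the
injected sharing histogram, each variant's true residue location and
surface status, and the realized per-patient counts, so recovery tests can
demand exact equality.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation_store import (
    AnnotationStore,
    ProteinRecord,
    TopologyFeature,
)
from .variant_io import CANONICAL_AA, MissenseVariant, ProteinChange

logger = logging.getLogger(__name__)

_AA = np.array(sorted(CANONICAL_AA))

# protein classes generated, in deterministic assignment order
_CLASSES = ("membrane", "secreted", "intracellular")


@dataclass(frozen=True)
class ProteomeSpec:
    """Recipe for a toy annotated proteome."""

    n_proteins: int = 60
    length_range: tuple[int, int] = (90, 400)
    class_mix: tuple[float, float, float] = (0.5, 0.3, 0.2)  # membrane, secreted, intracellular
    ecto_len_range: tuple[int, int] = (20, 80)
    tm_len_range: tuple[int, int] = (18, 25)
    cyto_len_range: tuple[int, int] = (10, 60)
    signal_len_range: tuple[int, int] = (16, 22)
    p_cell_junction: float = 0.2
    p_ecm: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not math.isclose(sum(self.class_mix), 1.0, abs_tol=1e-9):
            raise ValueError("class_mix proportions must sum to 1")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError("bad length_range")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic somatic-variant cohort.

    Per-patient burdens follow a log-normal (median ``burden_median``) with
    a deterministic hypermutator multiplier applied to a fixed fraction of
    patients, echoing the heavy right tail of real tumor cohorts. When
    ``sharing_plan`` is given it is the complete target sharing histogram
    (number-of-patients -> number of unique variant keys) and fully
    determines the cohort's variant keys; otherwise every key is private.
    """

    n_patients: int = 100
    burden_median: float = 75.0
    burden_sigma: float = 1.0
    hypermutator_fraction: float = 0.05
    hypermutator_multiplier: float = 50.0
    fixed_count: Optional[int] = None
    sharing_plan: Optional[dict] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (0.0 <= self.hypermutator_fraction <= 1.0):
            raise ValueError("hypermutator_fraction must be in [0, 1]")
        if self.sharing_plan is not None:
            for k, m in self.sharing_plan.items():
                if k < 1 or m < 0:
                    raise ValueError("sharing_plan entries must have k >= 1, m >= 0")


@dataclass(frozen=True)
class VariantTruth:
    sample_id: str
    gene_symbol: str
    position: int
    ref_aa: str
    alt_aa: str
    residue_location: str
    is_msp: bool


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knew at creation time."""

    variants: tuple[VariantTruth, ...]
    injected_histogram: dict  # k -> number of unique keys shared by exactly k patients
    count_sample: dict  # sample_id -> realized variant count
    protein_classes: dict  # accession -> membrane | secreted | intracellular
    spec_echo: dict


# --- proteome -----------------------------------------------------------

_LOCATION_PRECEDENCE = (
    "transmembrane",
    "extracellular",
    "intracellular",
    "lumenal",
    "signal_peptide",
    "propeptide",
)


def _true_location(record: ProteinRecord, position: int) -> str:
    """Independent residue-location scan used only for ground truth.

    Deliberately a separate code path from the classifier: first match in
    precedence order over a plain feature list.
    """
    if not (1 <= position <= len(record.sequence)):
        return "position_out_of_bounds"
    for kind in _LOCATION_PRECEDENCE:
        for feat in record.features:
            if feat.kind == kind and feat.start <= position <= feat.end:
                return "signal_peptide" if kind == "propeptide" else kind
    return "unannotated"


def _true_is_msp(record: ProteinRecord, location: str) -> bool:
    if location == "extracellular":
        return True
    return record.is_secreted and location not in ("signal_peptide", "position_out_of_bounds")


def _class_counts(spec: ProteomeSpec) -> dict[str, int]:
    raw = [p * spec.n_proteins for p in spec.class_mix]
    counts = [int(math.floor(x)) for x in raw]
    # largest-remainder apportionment so counts always sum to n_proteins
    remainders = sorted(
        range(3), key=lambda i: (-(raw[i] - counts[i]), i)
    )
    for i in range(spec.n_proteins - sum(counts)):
        counts[remainders[i % 3]] += 1
    return dict(zip(_CLASSES, counts))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def _membrane_features(
    rng: np.random.Generator, length: int, spec: ProteomeSpec
) -> tuple[TopologyFeature, ...]:
    """Tile the whole sequence with ecto/TM/cyto segments, no gaps, no overlap."""
    kinds = ("extracellular", "transmembrane", "intracellular")
    ranges = (spec.ecto_len_range, spec.tm_len_range, spec.cyto_len_range)
    features: list[TopologyFeature] = []
    pos, i = 1, 0
    while pos <= length:
        lo, hi = ranges[i % 3]
        seg = int(rng.integers(lo, hi + 1))
        end = min(pos + seg - 1, length)
        features.append(TopologyFeature(kinds[i % 3], pos, end))
        pos = end + 1
        i += 1
    return tuple(features)


def make_proteome(spec: ProteomeSpec) -> tuple[AnnotationStore, GroundTruth]:
    """Generate a toy annotated proteome (deterministic under ``spec.seed``).

    Membrane proteins are tiled with alternating extracellular /
    transmembrane / intracellular features covering every residue; secreted
    proteins carry an N-terminal signal peptide plus the ``secreted``
    label; intracellular proteins carry neither. The returned ground-truth
    fragment records each protein's class.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _class_counts(spec)
    min_len = max(
        spec.length_range[0],
        spec.signal_len_range[1] + 1,
        spec.tm_len_range[0] + 2,
    )
    records: list[ProteinRecord] = []
    classes: dict[str, str] = {}
    idx = 0
    for cls in _CLASSES:
        for _ in range(counts[cls]):
            idx += 1
            accession = f"SYN{idx:05d}"
            gene = f"GENE{idx:04d}"
            length = 0
            for _attempt in range(100):
                length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
                if length >= min_len:
                    break
            else:
                raise ValueError(
                    f"cannot draw a feasible protein length in {spec.length_range} "
                    f"(need >= {min_len})"
                )
            sequence = _random_seq(rng, length)
            if cls == "membrane":
                features = _membrane_features(rng, length, spec)
                labels = {"plasma_membrane"}
                if rng.random() < spec.p_cell_junction:
                    labels.add("cell_junction")
                if rng.random() < spec.p_ecm:
                    labels.add("extracellular_matrix")
            elif cls == "secreted":
                sp_len = int(
                    rng.integers(spec.signal_len_range[0], spec.signal_len_range[1] + 1)
                )
                features = (TopologyFeature("signal_peptide", 1, min(sp_len, length - 1)),)
                labels = {"secreted"}
            else:
                features = ()
                labels = {"intracellular_other"}
            records.append(
                ProteinRecord(
                    accession=accession,
                    gene_symbol=gene,
                    sequence=sequence,
                    features=features,
                    location_labels=frozenset(labels),
                )
            )
            classes[accession] = cls
    store = AnnotationStore(records)
    truth = GroundTruth(
        variants=(),
        injected_histogram={},
        count_sample={},
        protein_classes=classes,
        spec_echo=asdict(spec),
    )
    return store, truth


# --- cohort -------------------------------------------------------------


def _draw_targets(spec: CohortSpec, rng: np.random.Generator) -> list[int]:
    n = spec.n_patients
    if spec.fixed_count is not None:
        targets = [int(spec.fixed_count)] * n
    else:
        draws = rng.lognormal(mean=math.log(spec.burden_median), sigma=spec.burden_sigma, size=n)
        targets = [max(2, int(round(x))) for x in draws]
    n_hyper = int(round(spec.hypermutator_fraction * n))
    if n_hyper and spec.fixed_count is None:
        hyper_idx = rng.choice(n, size=n_hyper, replace=False)
        for i in sorted(int(j) for j in hyper_idx):
            targets[i] = int(round(targets[i] * spec.hypermutator_multiplier))
    return targets


def _new_key(
    rng: np.random.Generator,
    records: Sequence[ProteinRecord],
    seen: set,
    max_attempts: int = 10000,
) -> tuple[ProteinRecord, ProteinChange]:
    for _ in range(max_attempts):
        rec = records[int(rng.integers(len(records)))]
        pos = int(rng.integers(1, len(rec.sequence) + 1))
        ref = rec.sequence[pos - 1]
        alt_choices = [a for a in _AA if a != ref]
        alt = str(alt_choices[int(rng.integers(len(alt_choices)))])
        key = (rec.gene_symbol.upper(), pos, ref, alt)
        if key not in seen:
            seen.add(key)
            return rec, ProteinChange(ref_aa=ref, position=pos, alt_aa=alt)
    raise ValueError("variant key space exhausted; enlarge the proteome")


def make_cohort(
    spec: CohortSpec, store: AnnotationStore
) -> tuple[list[MissenseVariant], GroundTruth]:
    """Generate a somatic cohort over a proteome, with complete ground truth.

    All variant keys are globally unique by construction. With a
    ``sharing_plan`` the plan *is* the sharing histogram: each key slated
    for k patients is copied into exactly k distinct patients (chosen to
    track the per-patient burden targets), so the measured spectrum matches
    the plan exactly. Realized per-patient counts are recorded in the
    ground truth.
    """
    if len(store) == 0:
        raise ValueError("annotation store is empty")
    records = store.records
    rng = np.random.default_rng(spec.seed)
    samples = [f"PT{i:04d}" for i in range(1, spec.n_patients + 1)]
    targets = _draw_targets(spec, rng)

    if spec.sharing_plan is not None:
        plan = {int(k): int(m) for k, m in spec.sharing_plan.items() if int(m) > 0}
        max_k = max(plan, default=1)
        if max_k > spec.n_patients:
            raise ValueError(
                f"sharing_plan wants keys in {max_k} patients but cohort has "
                f"{spec.n_patients}"
            )
    else:
        plan = None

    seen: set = set()
    assignments: list[tuple[ProteinRecord, ProteinChange, list[int]]] = []
    realized = [0] * spec.n_patients

    if plan is None:
        for i, t in enumerate(targets):
            for _ in range(t):
                rec, change = _new_key(rng, records, seen)
                assignments.append((rec, change, [i]))
                realized[i] += 1
        injected = {1: sum(targets)}
    else:
        remaining = [float(t) for t in targets]
        # shared keys first (largest k first), each into the k patients with
        # the most remaining burden — deterministic tie-break by index
        for k in sorted(plan, reverse=True):
            if k == 1:
                continue
            for _ in range(plan[k]):
                order = sorted(
                    range(spec.n_patients), key=lambda i: (-remaining[i], i)
                )[:k]
                rec, change = _new_key(rng, records, seen)
                assignments.append((rec, change, sorted(order)))
                for i in order:
                    remaining[i] -= 1
                    realized[i] += 1
        # private keys apportioned to remaining burden by largest remainder
        m1 = plan.get(1, 0)
        if m1:
            pos_remaining = [max(r, 0.0) for r in remaining]
            total_rem = sum(pos_remaining)
            if total_rem <= 0:
                quotas_f = [m1 / spec.n_patients] * spec.n_patients
            else:
                quotas_f = [m1 * r / total_rem for r in pos_remaining]
            quotas = [int(math.floor(q)) for q in quotas_f]
            order = sorted(
                range(spec.n_patients),
                key=lambda i: (-(quotas_f[i] - quotas[i]), i),
            )
            for j in range(m1 - sum(quotas)):
                quotas[order[j % spec.n_patients]] += 1
            for i, q in enumerate(quotas):
                for _ in range(q):
                    rec, change = _new_key(rng, records, seen)
                    assignments.append((rec, change, [i]))
                    realized[i] += 1
        injected = dict(sorted(plan.items()))

    variants: list[MissenseVariant] = []
    truths: list[VariantTruth] = []
    for rec, change, patient_idx in assignments:
        location = _true_location(rec, change.position)
        is_msp = _true_is_msp(rec, location)
        for i in patient_idx:
            variants.append(
                MissenseVariant(
                    sample_id=samples[i],
                    gene_symbol=rec.gene_symbol,
                    change=change,
                    classification_label="Missense_Mutation",
                )
            )
            truths.append(
                VariantTruth(
                    sample_id=samples[i],
                    gene_symbol=rec.gene_symbol,
                    position=change.position,
                    ref_aa=change.ref_aa,
                    alt_aa=change.alt_aa,
                    residue_location=location,
                    is_msp=is_msp,
                )
            )

    # canonical row order for byte-identical reruns
    order = sorted(
        range(len(variants)),
        key=lambda j: (
            variants[j].sample_id,
            variants[j].gene_symbol,
            variants[j].change.position,
            variants[j].change.alt_aa,
        ),
    )
    variants = [variants[j] for j in order]
    truths = [truths[j] for j in order]

    truth = GroundTruth(
        variants=tuple(truths),
        injected_histogram=injected,
        count_sample={samples[i]: realized[i] for i in range(spec.n_patients)},
        protein_classes={},
        spec_echo=asdict(spec),
    )
    return variants, truth


def truth_to_frame(truth: GroundTruth) -> pd.DataFrame:
    """Per-variant ground-truth table for TSV export."""
    return pd.DataFrame(
        {
            "sample_id": [t.sample_id for t in truth.variants],
            "gene_symbol": [t.gene_symbol for t in truth.variants],
            "position": [t.position for t in truth.variants],
            "ref_aa": [t.ref_aa for t in truth.variants],
            "alt_aa": [t.alt_aa for t in truth.variants],
            "residue_location": [t.residue_location for t in truth.variants],
            "is_msp": [t.is_msp for t in truth.variants],
        }
    )
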