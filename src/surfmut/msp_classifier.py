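"""Residue-level localization and mutated-surface-protein (MSP) calling.

A variant is an MSP when its mutated residue falls in an extracellular
topological domain, or when the protein is secreted and the residue lies in
the mature chain (signal-peptide residues are cleaved and therefore never
antibody-accessible). Protein-level compartment tallies report how many
classified variants fall on proteins carrying each surface-associated
location label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Literal, Optional, Sequence, Union

import pandas as pd

from .annotation_store import AnnotationStore, ProteinRecord
from .util import round_half_up
from .variant_io import MissenseVariant

logger = logging.getLogger(__name__)


class ResidueLocation(str, Enum):
    EXTRACELLULAR = "extracellular"
    TRANSMEMBRANE = "transmembrane"
    INTRACELLULAR = "intracellular"
    LUMENAL = "lumenal"
    SIGNAL_PEPTIDE = "signal_peptide"
    UNANNOTATED = "unannotated"
    POSITION_OUT_OF_BOUNDS = "position_out_of_bounds"


# Precedence when overlapping features cover one residue: the most
# structurally constrained annotation wins.
_KIND_PRECEDENCE = {
    "transmembrane": 0,
    "extracellular": 1,
    "intracellular": 2,
    "lumenal": 3,
    "signal_peptide": 4,
    "propeptide": 5,
}

# propeptide is, like the signal peptide, cleaved from the mature protein
_KIND_TO_LOCATION = {
    "transmembrane": ResidueLocation.TRANSMEMBRANE,
    "extracellular": ResidueLocation.EXTRACELLULAR,
    "intracellular": ResidueLocation.INTRACELLULAR,
    "lumenal": ResidueLocation.LUMENAL,
    "signal_peptide": ResidueLocation.SIGNAL_PEPTIDE,
    "propeptide": ResidueLocation.SIGNAL_PEPTIDE,
}

#: Compartment categories reported by :func:`compartment_tally`.
TALLY_CATEGORIES = ("plasma_membrane", "cell_junction", "extracellular_matrix")


@dataclass(frozen=True)
class MSPCall:
    """Verdict for one variant: residue location, surface status, MSP flag."""

    variant: MissenseVariant
    accession: str
    residue_location: ResidueLocation
    is_secreted_protein: bool
    is_msp: bool
    reason: str
    reference_mismatch: bool = False


@dataclass(frozen=True)
class Exclusion:
    """A variant dropped before classification (no annotation available)."""

    variant: MissenseVariant
    reason: str = "missing_annotation"


@dataclass(frozen=True)
class CompartmentTally:
    total: int
    counts: dict
    percentages: dict
    mode: str
    empty_input: bool = False


def locate_residue(record: ProteinRecord, position: int) -> ResidueLocation:
    """Classify one residue of a protein by its covering topology feature.

    Positions outside ``[1, len(sequence)]`` give ``POSITION_OUT_OF_BOUNDS``;
    positions covered by no feature give ``UNANNOTATED``. When several
    features overlap, transmembrane > extracellular > intracellular >
    lumenal > signal_peptide decides (and a warning is logged).
    """
    if not (1 <= position <= len(record.sequence)):
        return ResidueLocation.POSITION_OUT_OF_BOUNDS
    covering = [f for f in record.features if f.covers(position)]
    if not covering:
        return ResidueLocation.UNANNOTATED
    if len(covering) > 1:
        logger.warning(
            "%s: position %d covered by %d overlapping features",
            record.accession,
            position,
            len(covering),
        )
    best = min(covering, key=lambda f: _KIND_PRECEDENCE[f.kind])
    return _KIND_TO_LOCATION[best.kind]


def call_msp(record: ProteinRecord, variant: MissenseVariant) -> MSPCall:
    """Apply the MSP rule to one variant against its resolved record.

    If the record sequence at the variant position differs from the
    variant's reference residue, the call is flagged ``reference_mismatch``
    and is never an MSP (isoform/version skew is treated conservatively).
    """
    position = variant.change.position
    location = locate_residue(record, position)
    secreted = record.is_secreted

    mismatch = False
    if location is not ResidueLocation.POSITION_OUT_OF_BOUNDS:
        if record.sequence[position - 1] != variant.change.ref_aa:
            mismatch = True

    if mismatch:
        logger.info(
            "reference mismatch for %s %s (record %s has %s at %d)",
            variant.gene_symbol,
            variant.change,
            record.accession,
            record.sequence[position - 1],
            position,
        )
        return MSPCall(
            variant=variant,
            accession=record.accession,
            residue_location=location,
            is_secreted_protein=secreted,
            is_msp=False,
            reason="reference_mismatch",
            reference_mismatch=True,
        )

    if location is ResidueLocation.EXTRACELLULAR:
        is_msp, reason = True, "extracellular_domain"
    elif location is ResidueLocation.POSITION_OUT_OF_BOUNDS:
        is_msp, reason = False, "position_out_of_bounds"
    elif secreted and location is ResidueLocation.SIGNAL_PEPTIDE:
        is_msp, reason = False, "signal_peptide_excluded"
    elif secreted:
        is_msp, reason = True, "secreted_protein"
    else:
        is_msp, reason = False, "not_surface"
    return MSPCall(
        variant=variant,
        accession=record.accession,
        residue_location=location,
        is_secreted_protein=secreted,
        is_msp=is_msp,
        reason=reason,
    )


def classify_cohort(
    variants: Iterable[MissenseVariant], store: AnnotationStore
) -> tuple[list[MSPCall], list[Exclusion]]:
    """Classify every variant whose gene resolves; log and drop the rest.

    Output order matches the input order of retained variants.
    """
    calls: list[MSPCall] = []
    exclusions: list[Exclusion] = []
    for variant in variants:
        record = store.resolve(variant.gene_symbol)
        if record is None:
            logger.info("no annotation for gene %s; variant dropped", variant.gene_symbol)
            exclusions.append(Exclusion(variant))
            continue
        calls.append(call_msp(record, variant))
    return calls, exclusions


def compartment_tally(
    variants: Iterable[MissenseVariant],
    store: AnnotationStore,
    mode: Literal["exclusive", "overlapping"] = "overlapping",
) -> CompartmentTally:
    """Tally classified variants by their protein's compartment labels.

    A variant contributes to a category iff its protein carries that
    location label. ``overlapping`` counts a variant in every matching
    category; ``exclusive`` assigns one category by precedence
    plasma_membrane > cell_junction > extracellular_matrix. ``total`` is all
    classified (annotation-resolvable) variants, including those in no
    category. Percentages are 100*count/total rounded half-up to one
    decimal; an empty input reports 0.0 everywhere with ``empty_input`` set.
    """
    if mode not in ("exclusive", "overlapping"):
        raise ValueError(f"unknown tally mode {mode!r}")
    counts = {cat: 0 for cat in TALLY_CATEGORIES}
    total = 0
    for variant in variants:
        record = store.resolve(variant.gene_symbol)
        if record is None:
            continue
        total += 1
        if mode == "overlapping":
            for cat in TALLY_CATEGORIES:
                if cat in record.location_labels:
                    counts[cat] += 1
        else:
            for cat in TALLY_CATEGORIES:  # tuple order is the precedence
                if cat in record.location_labels:
                    counts[cat] += 1
                    break
    empty = total == 0
    percentages = {
        cat: (0.0 if empty else round_half_up(100.0 * counts[cat] / total, 1))
        for cat in TALLY_CATEGORIES
    }
    return CompartmentTally(
        total=total, counts=counts, percentages=percentages, mode=mode, empty_input=empty
    )


def calls_to_frame(calls: Sequence[MSPCall]) -> pd.DataFrame:
    """Flatten calls for TSV export."""
    return pd.DataFrame(
        {
            "sample_id": [c.variant.sample_id for c in calls],
            "gene_symbol": [c.variant.gene_symbol for c in calls],
            "protein_change": [str(c.variant.change) for c in calls],
            "accession": [c.accession for c in calls],
            "residue_location": [c.residue_location.value for c in calls],
            "is_secreted_protein": [c.is_secreted_protein for c in calls],
            "is_msp": [c.is_msp for c in calls],
            "reason": [c.reason for c in calls],
            "reference_mismatch": [c.reference_mismatch for c in calls],
        }
    )


def write_calls_tsv(calls: Sequence[MSPCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def write_exclusions_tsv(exclusions: Sequence[Exclusion], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [e.variant.sample_id for e in exclusions],
            "gene_symbol": [e.variant.gene_symbol for e in exclusions],
            "protein_change": [str(e.variant.change) for e in exclusions],
            "reason": [e.reason for e in exclusions],
        }
    ).to_csv(path, sep="\t", index=False)
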