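"""Mutant/wild-type peptide-window design, validation, and panel selection.

Each targeted mutation gets a fixed-length window of the protein sequence
(default 14 residues, mutated residue centered) plus the same window with
the substitution applied; the synthesis sequence appends a C-terminal
cysteine for carrier-protein conjugation. Panels pick one target per gene,
deterministically.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation_store import AnnotationStore, ProteinRecord
from .msp_classifier import MSPCall, ResidueLocation
from .variant_io import CANONICAL_AA, ProteinChange

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_LENGTH = 14
SYNTHESIS_TAG = "C"


class DesignError(ValueError):
    """Hard failure while designing a window (mismatch, impossible length)."""


@dataclass(frozen=True)
class PeptideWindow:
    """A mutant/wild-type peptide pair around one substitution."""

    accession: str
    window_start: int  # 1-based position of the window in the protein
    length: int
    wildtype_seq: str
    mutant_seq: str
    mutated_offset: int  # 1-based index of the substitution within the window
    synthesis_seq: str
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class PairValidation:
    """Outcome of checking that two peptides differ by exactly one residue."""

    passed: bool
    ref_aa: Optional[str] = None
    offset: Optional[int] = None  # 1-based
    alt_aa: Optional[str] = None
    reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class PanelSelection:
    targets: tuple  # of (MSPCall, PeptideWindow)
    excluded: tuple  # of (MSPCall, reason)
    requested: int
    shortfall: bool = False


def design_window(
    record: ProteinRecord,
    change: ProteinChange,
    length: int = DEFAULT_WINDOW_LENGTH,
    policy: str = "centered",
    window_start: Optional[int] = None,
    add_tag: bool = True,
) -> PeptideWindow:
    """Cut a peptide window around a substitution and apply it.

    The ``centered`` policy places the mutated residue at window offset
    ``ceil(length/2)``, clamped so the window stays within the protein; an
    explicit ``window_start`` overrides the policy. The record sequence must
    carry the reference residue at the mutated position.

    Informational flags: ``cysteine_in_window`` when the untagged mutant
    window already contains a cysteine (conjugation-chemistry risk) and
    ``crosses_feature_boundary`` when the window extends past the topology
    feature covering the mutated residue.
    """
    seq = record.sequence
    pos = change.position
    if length < 1:
        raise DesignError("window length must be >= 1")
    if length > len(seq):
        raise DesignError(
            f"window length {length} exceeds protein length {len(seq)} ({record.accession})"
        )
    if not (1 <= pos <= len(seq)):
        raise DesignError(f"position {pos} outside protein {record.accession}")
    if seq[pos - 1] != change.ref_aa:
        raise DesignError(
            f"reference mismatch at {record.accession}:{pos} "
            f"(sequence has {seq[pos - 1]}, change expects {change.ref_aa})"
        )

    if window_start is None:
        if policy != "centered":
            raise DesignError(f"unknown placement policy {policy!r}")
        center_offset = math.ceil(length / 2)
        window_start = pos - center_offset + 1
        window_start = max(1, min(window_start, len(seq) - length + 1))
    if not (1 <= window_start <= len(seq) - length + 1):
        raise DesignError(
            f"window [{window_start}, {window_start + length - 1}] outside protein"
        )
    if not (window_start <= pos <= window_start + length - 1):
        raise DesignError("window does not contain the mutated residue")

    offset = pos - window_start + 1
    wildtype = seq[window_start - 1 : window_start - 1 + length]
    mutant = wildtype[: offset - 1] + change.alt_aa + wildtype[offset:]

    flags: list[str] = []
    if SYNTHESIS_TAG in mutant:
        flags.append("cysteine_in_window")
        logger.warning(
            "%s window at %d already contains a cysteine", record.accession, window_start
        )
    covering = [f for f in record.features if f.covers(pos)]
    if covering and any(
        window_start < f.start or window_start + length - 1 > f.end for f in covering
    ):
        flags.append("crosses_feature_boundary")

    return PeptideWindow(
        accession=record.accession,
        window_start=window_start,
        length=length,
        wildtype_seq=wildtype,
        mutant_seq=mutant,
        mutated_offset=offset,
        synthesis_seq=mutant + SYNTHESIS_TAG if add_tag else mutant,
        flags=tuple(flags),
    )


def validate_pair(wildtype_seq: str, mutant_seq: str) -> PairValidation:
    """Check that two peptides are a single-substitution pair.

    Passes iff both sequences are equal-length, drawn from the canonical
    alphabet, and differ at exactly one position. On pass, reports the
    substitution triple (wild-type residue, 1-based offset, mutant residue).
    Failures are reported, never raised.
    """
    reasons: list[str] = []
    if len(wildtype_seq) != len(mutant_seq):
        reasons.append("length_mismatch")
    if set(wildtype_seq) - CANONICAL_AA or set(mutant_seq) - CANONICAL_AA:
        reasons.append("noncanonical_alphabet")
    if reasons:
        return PairValidation(passed=False, reasons=tuple(reasons))
    diffs = [i for i, (a, b) in enumerate(zip(wildtype_seq, mutant_seq)) if a != b]
    if len(diffs) == 0:
        return PairValidation(passed=False, reasons=("identical_sequences",))
    if len(diffs) > 1:
        return PairValidation(
            passed=False, reasons=(f"hamming_distance_{len(diffs)}",)
        )
    i = diffs[0]
    return PairValidation(
        passed=True, ref_aa=wildtype_seq[i], offset=i + 1, alt_aa=mutant_seq[i]
    )


def load_reference_pairs() -> list[dict]:
    """Load the bundled golden set of mutant/wild-type 14-mer pairs.

    Returns a list of ``{"id", "mutant", "wildtype"}`` dicts in file order.
    """
    text = (
        resources.files("surfmut").joinpath("data/reference_panel_pairs.tsv").read_text()
    )
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    return [dict(row) for row in reader]


def select_panel(
    calls: Sequence[MSPCall],
    store: AnnotationStore,
    n: int = 10,
    exclude_genes: Optional[Iterable[str]] = None,
    length: int = DEFAULT_WINDOW_LENGTH,
    policy: str = "centered",
) -> PanelSelection:
    """Pick up to ``n`` targets, one per gene, from MSP calls — deterministically.

    Excluded genes are dropped first; within a gene the call at the lowest
    position wins; genes are then ranked with extracellular-domain calls
    before secreted-protein calls and alphabetically within each group. If
    fewer than ``n`` genes are eligible, all are returned with a shortfall
    warning.
    """
    excluded: list[tuple[MSPCall, str]] = []
    banned = {g.upper() for g in (exclude_genes or ())}

    eligible: list[MSPCall] = []
    for call in calls:
        if not call.is_msp:
            excluded.append((call, "not_msp"))
        elif call.variant.gene_symbol.upper() in banned:
            excluded.append((call, "excluded_gene"))
        else:
            eligible.append(call)

    per_gene: dict[str, MSPCall] = {}
    for call in sorted(
        eligible,
        key=lambda c: (
            c.variant.gene_symbol.upper(),
            c.variant.change.position,
            c.variant.change.alt_aa,
            c.variant.sample_id,
        ),
    ):
        gene = call.variant.gene_symbol.upper()
        if gene in per_gene:
            excluded.append((call, "duplicate_gene"))
        else:
            per_gene[gene] = call

    ranked = sorted(
        per_gene.values(),
        key=lambda c: (
            0 if c.reason == "extracellular_domain" else 1,
            c.variant.gene_symbol.upper(),
        ),
    )
    chosen, overflow = ranked[:n], ranked[n:]
    excluded.extend((call, "rank_overflow") for call in overflow)

    targets = []
    for call in chosen:
        record = store.resolve(call.variant.gene_symbol)
        if record is None:  # calls came from this store; defensive only
            excluded.append((call, "missing_annotation"))
            continue
        window = design_window(record, call.variant.change, length=length, policy=policy)
        targets.append((call, window))

    shortfall = len(targets) < n
    if shortfall:
        logger.warning("panel shortfall: %d of %d requested targets", len(targets), n)
    return PanelSelection(
        targets=tuple(targets),
        excluded=tuple(excluded),
        requested=n,
        shortfall=shortfall,
    )


def pool_cocktail(concentrations: Iterable[float]) -> float:
    """Total concentration of a cocktail formed by pooling components.

    Components are mixed at their stated final concentrations (each already
    expressed in the pooled volume), so the total is the plain sum.
    """
    total = 0.0
    for c in concentrations:
        if c < 0:
            raise ValueError("component concentrations must be non-negative")
        total += c
    return total


def export_panel_fasta(panel: PanelSelection, path: Union[str, Path]) -> int:
    """Write a panel as FASTA: per target, the tagged mutant then the wild type."""
    records = []
    for call, window in panel.targets:
        gene = call.variant.gene_symbol
        change = str(call.variant.change)
        records.append(
            SeqRecord(
                Seq(window.synthesis_seq),
                id=f"{gene}|{change}|mutant",
                description=f"start={window.window_start} tagged",
            )
        )
        records.append(
            SeqRecord(
                Seq(window.wildtype_seq),
                id=f"{gene}|{change}|wildtype",
                description=f"start={window.window_start}",
            )
        )
    if not records:
        logger.warning("exporting an empty panel to %s", path)
        Path(path).write_text("")
        return 0
    return SeqIO.write(records, str(path), "fasta")


def panel_manifest_frame(panel: PanelSelection) -> pd.DataFrame:
    """Tabular manifest of a panel for TSV export."""
    rows = []
    for call, window in panel.targets:
        rows.append(
            {
                "gene_symbol": call.variant.gene_symbol,
                "accession": window.accession,
                "protein_change": str(call.variant.change),
                "reason": call.reason,
                "window_start": window.window_start,
                "length": window.length,
                "mutated_offset": window.mutated_offset,
                "wildtype_seq": window.wildtype_seq,
                "mutant_seq": window.mutant_seq,
                "synthesis_seq": window.synthesis_seq,
                "flags": ",".join(window.flags),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_symbol",
            "accession",
            "protein_change",
            "reason",
            "window_start",
            "length",
            "mutated_offset",
            "wildtype_seq",
            "mutant_seq",
            "synthesis_seq",
            "flags",
        ],
    )
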