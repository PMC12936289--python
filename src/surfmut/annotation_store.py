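"""Protein annotation store: sequences, topology features, location labels.

One canonical record per gene symbol (isoform choice happens when the store
is built, not at query time). The on-disk fixture format is a single JSON
document; coordinates are 1-based inclusive. A companion FASTA export is
provided for interoperability.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .variant_io import CANONICAL_AA

logger = logging.getLogger(__name__)

COORDINATE_CONVENTION = "1-based inclusive"

#: Allowed topology feature kinds.
FEATURE_KINDS = (
    "signal_peptide",
    "extracellular",
    "transmembrane",
    "intracellular",
    "lumenal",
    "propeptide",
)

#: Controlled vocabulary for protein-level subcellular-location labels.
LOCATION_VOCAB = (
    "plasma_membrane",
    "cell_junction",
    "extracellular_matrix",
    "secreted",
    "intracellular_other",
)


class StoreValidationError(ValueError):
    """A record violates the store invariants; message names the accession."""


@dataclass(frozen=True, order=True)
class TopologyFeature:
    """A residue interval assigned to one topological compartment."""

    kind: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise StoreValidationError(f"unknown feature kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise StoreValidationError(
                f"bad feature interval [{self.start}, {self.end}]"
            )

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ProteinRecord:
    """An annotated protein: sequence, topology features, location labels."""

    accession: str
    gene_symbol: str
    sequence: str
    features: tuple[TopologyFeature, ...] = ()
    location_labels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(self.features))
        object.__setattr__(self, "location_labels", frozenset(self.location_labels))
        if not self.accession:
            raise StoreValidationError("record with empty accession")
        if not self.sequence:
            raise StoreValidationError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - CANONICAL_AA
        if bad:
            raise StoreValidationError(
                f"{self.accession}: non-canonical residues {sorted(bad)}"
            )
        for feat in self.features:
            if feat.end > len(self.sequence):
                raise StoreValidationError(
                    f"{self.accession}: feature {feat.kind} [{feat.start},{feat.end}] "
                    f"exceeds sequence length {len(self.sequence)}"
                )
        unknown = self.location_labels - set(LOCATION_VOCAB)
        if unknown:
            raise StoreValidationError(
                f"{self.accession}: labels outside controlled vocabulary {sorted(unknown)}"
            )

    @property
    def is_secreted(self) -> bool:
        return "secreted" in self.location_labels


class AnnotationStore:
    """Mapping from gene symbol (case-insensitive) to one protein record."""

    def __init__(self, records: Iterable[ProteinRecord]):
        self._by_gene: dict[str, ProteinRecord] = {}
        accessions: set[str] = set()
        for rec in records:
            key = rec.gene_symbol.upper()
            if key in self._by_gene:
                raise StoreValidationError(
                    f"gene symbol {rec.gene_symbol!r} appears more than once "
                    f"({self._by_gene[key].accession}, {rec.accession})"
                )
            if rec.accession in accessions:
                raise StoreValidationError(
                    f"accession {rec.accession!r} appears more than once"
                )
            accessions.add(rec.accession)
            self._by_gene[key] = rec

    def __len__(self) -> int:
        return len(self._by_gene)

    def __contains__(self, gene_symbol: str) -> bool:
        return gene_symbol.upper() in self._by_gene

    @property
    def records(self) -> list[ProteinRecord]:
        """All records, ordered by upper-cased gene symbol."""
        return [self._by_gene[k] for k in sorted(self._by_gene)]

    @property
    def genes(self) -> list[str]:
        return sorted(self._by_gene)

    def resolve(self, gene_symbol: str) -> Optional[ProteinRecord]:
        """Return the record for a gene, or ``None`` for missing annotation.

        Missingness is a value, not an error: callers log and drop the
        variant (proteins without annotation cannot be localized).
        """
        return self._by_gene.get(gene_symbol.upper())


def _record_to_dict(rec: ProteinRecord) -> dict:
    return {
        "accession": rec.accession,
        "gene_symbol": rec.gene_symbol,
        "sequence": rec.sequence,
        "features": [
            {"kind": f.kind, "start": f.start, "end": f.end}
            for f in sorted(rec.features)
        ],
        "location_labels": sorted(rec.location_labels),
    }


def serialize_store(store: AnnotationStore) -> str:
    """Canonical JSON text for a store (stable ordering, 2-space indent)."""
    doc = {
        "coordinate_convention": COORDINATE_CONVENTION,
        "records": [_record_to_dict(r) for r in store.records],
    }
    return json.dumps(doc, indent=2) + "\n"


def save_store(store: AnnotationStore, path: Union[str, Path]) -> None:
    Path(path).write_text(serialize_store(store))


def load_store(path: Union[str, Path]) -> AnnotationStore:
    """Load and validate a store fixture; malformed records name the accession."""
    doc = json.loads(Path(path).read_text())
    if doc.get("coordinate_convention", COORDINATE_CONVENTION) != COORDINATE_CONVENTION:
        raise StoreValidationError(
            f"unsupported coordinate convention {doc.get('coordinate_convention')!r}"
        )
    records = []
    for raw in doc.get("records", []):
        accession = raw.get("accession", "<missing accession>")
        try:
            records.append(
                ProteinRecord(
                    accession=raw["accession"],
                    gene_symbol=raw["gene_symbol"],
                    sequence=raw["sequence"],
                    features=tuple(
                        TopologyFeature(f["kind"], int(f["start"]), int(f["end"]))
                        for f in raw.get("features", [])
                    ),
                    location_labels=frozenset(raw.get("location_labels", [])),
                )
            )
        except (KeyError, StoreValidationError) as exc:
            raise StoreValidationError(f"record {accession}: {exc}") from exc
    return AnnotationStore(records)


def export_fasta(store: AnnotationStore, path: Union[str, Path]) -> int:
    """Write all sequences as FASTA (accession as header); returns record count."""
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.accession, description=rec.gene_symbol)
        for rec in store.records
    ]
    return SeqIO.write(seq_records, str(path), "fasta")
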