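"""Reading and validation of somatic variant tables (MAF-dialect TSV).

Variants arrive already protein-annotated, one row per variant per sample.
Only four logical columns are required; everything else passes through
untouched. Rows that are not missense, carry an unparseable or nonstandard
protein change, or duplicate an earlier (sample, gene, change) triple are
rejected with a machine-readable reason rather than raised.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio.Data.IUPACData import protein_letters_3to1

logger = logging.getLogger(__name__)

#: The canonical 20-letter amino-acid alphabet.
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity/rare codes rejected for synthesis purposes.
NONSTANDARD_AA = frozenset("BZXUO")

#: Classification labels (case-insensitive) accepted as missense.
MISSENSE_LABELS = frozenset({"missense_mutation", "missense_variant", "missense"})

#: Default MAF column names for the four required logical columns.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "gene_symbol": "Hugo_Symbol",
    "classification": "Variant_Classification",
    "protein_change": "HGVSp_Short",
    "sample_id": "Tumor_Sample_Barcode",
}

_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}
# rare residues resolvable by 3-letter code but still nonstandard downstream
_THREE_TO_ONE.setdefault("SEC", "U")
_THREE_TO_ONE.setdefault("PYL", "O")

_HGVS_RE = re.compile(r"^([A-Za-z]{3}|[A-Za-z])(\d+)([A-Za-z]{3}|[A-Za-z])$")
_NON_MISSENSE_TOKENS = ("*", "FS", "DEL", "INS", "DUP", "EXT", "=", "?")


class MafFormatError(ValueError):
    """A structural problem with the input table (e.g. missing column)."""


class ProteinChangeError(ValueError):
    """Raised when a protein-change string cannot yield a missense change.

    ``reason`` is machine-readable: one of ``unparseable_hgvs``,
    ``nonstandard_aa``, ``synonymous``.
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass(frozen=True, order=True)
class ProteinChange:
    """One amino-acid substitution in protein coordinates (1-based)."""

    ref_aa: str
    position: int
    alt_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for aa in (self.ref_aa, self.alt_aa):
            if aa not in CANONICAL_AA:
                raise ValueError(f"non-canonical amino acid {aa!r}")
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref_aa and alt_aa must differ")

    def __str__(self) -> str:
        return f"p.{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass(frozen=True, order=True)
class MissenseVariant:
    """One somatic amino-acid substitution observed in one sample."""

    sample_id: str
    gene_symbol: str
    change: ProteinChange
    classification_label: str = "Missense_Mutation"

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")

    @property
    def key(self) -> tuple:
        """Protein-level identity used for dedup and sharing analysis."""
        return (
            self.gene_symbol.upper(),
            self.change.position,
            self.change.ref_aa,
            self.change.alt_aa,
        )


@dataclass(frozen=True)
class Rejection:
    """One input row that did not become a variant, and why."""

    row_index: int
    sample_id: str
    gene_symbol: str
    raw_change: str
    reason: str  # non_missense | unparseable_hgvs | nonstandard_aa | missing_field | duplicate
    detail: str = ""


def _to_one_letter(token: str) -> str:
    if len(token) == 1:
        return token.upper()
    one = _THREE_TO_ONE.get(token.upper())
    if one is None:
        raise ProteinChangeError("unparseable_hgvs", f"unknown residue code {token!r}")
    return one


def parse_protein_change(text: str) -> ProteinChange:
    """Parse an HGVS-style protein substitution such as ``p.N123T`` or ``p.Asn123Thr``.

    The leading ``p.`` is optional; 1- and 3-letter residue codes are accepted
    and normalized to 1-letter. Anything that is not a simple missense
    substitution (stop-gains, frameshifts, indels, synonymous changes) raises
    :class:`ProteinChangeError` with a machine-readable ``reason``.
    """
    if text is None:
        raise ProteinChangeError("unparseable_hgvs", "empty protein change")
    token = text.strip()
    if token.startswith("p."):
        token = token[2:]
    if not token:
        raise ProteinChangeError("unparseable_hgvs", "empty protein change")
    upper = token.upper()
    for bad in _NON_MISSENSE_TOKENS:
        if bad in upper:
            raise ProteinChangeError("unparseable_hgvs", f"non-missense token in {text!r}")
    m = _HGVS_RE.match(token)
    if not m:
        raise ProteinChangeError("unparseable_hgvs", f"cannot parse {text!r}")
    ref_tok, pos_str, alt_tok = m.groups()
    ref, alt = _to_one_letter(ref_tok), _to_one_letter(alt_tok)
    if ref in NONSTANDARD_AA or alt in NONSTANDARD_AA:
        raise ProteinChangeError("nonstandard_aa", f"nonstandard residue in {text!r}")
    if ref not in CANONICAL_AA or alt not in CANONICAL_AA:
        raise ProteinChangeError("unparseable_hgvs", f"non-amino-acid letter in {text!r}")
    if ref == alt:
        raise ProteinChangeError("synonymous", f"{text!r} is synonymous")
    position = int(pos_str)
    if position < 1:
        raise ProteinChangeError("unparseable_hgvs", f"position < 1 in {text!r}")
    return ProteinChange(ref_aa=ref, position=position, alt_aa=alt)


def format_protein_change(change: ProteinChange) -> str:
    """Inverse of :func:`parse_protein_change` for canonical 1-letter output."""
    return str(change)


def is_missense_label(label: str) -> bool:
    return label is not None and label.strip().lower() in MISSENSE_LABELS


def read_maf(
    path: Union[str, Path],
    column_map: Optional[Mapping[str, str]] = None,
) -> tuple[list[MissenseVariant], list[Rejection]]:
    """Read a MAF-dialect TSV, keeping parseable missense rows.

    Parameters
    ----------
    path
        TSV (optionally gzip-compressed) with a header line. Lines starting
        with ``#`` are treated as comments.
    column_map
        Optional overrides of the logical-to-physical column names in
        :data:`DEFAULT_COLUMNS` (keys: ``gene_symbol``, ``classification``,
        ``protein_change``, ``sample_id``).

    Returns
    -------
    (variants, rejections)
        Every input data row lands in exactly one of the two lists, so
        ``len(variants) + len(rejections)`` equals the row count. Duplicate
        (sample, gene, change) rows are rejected with reason ``duplicate``.

    Raises
    ------
    MafFormatError
        If a required column is absent.
    """
    columns = dict(DEFAULT_COLUMNS)
    if column_map:
        columns.update(column_map)

    try:
        frame = pd.read_csv(
            path, sep="\t", dtype=str, comment="#", keep_default_na=False
        )
    except pd.errors.EmptyDataError:
        logger.warning("empty variant table: %s", path)
        return [], []

    for logical, physical in columns.items():
        if physical not in frame.columns:
            raise MafFormatError(
                f"required column {physical!r} (logical {logical!r}) missing from {path}"
            )
    if frame.empty:
        logger.warning("variant table has a header but no rows: %s", path)
        return [], []

    variants: list[MissenseVariant] = []
    rejections: list[Rejection] = []
    seen: set[tuple] = set()
    for idx, row in enumerate(frame.itertuples(index=False)):
        record = dict(zip(frame.columns, row))
        sample = record[columns["sample_id"]].strip()
        gene = record[columns["gene_symbol"]].strip()
        label = record[columns["classification"]].strip()
        raw_change = record[columns["protein_change"]].strip()

        def reject(reason: str, detail: str = "") -> None:
            rejections.append(
                Rejection(idx, sample, gene, raw_change, reason, detail)
            )

        if not sample or not gene or not label or not raw_change:
            reject("missing_field", "one of the four required fields is empty")
            continue
        if not is_missense_label(label):
            reject("non_missense", f"classification {label!r}")
            continue
        try:
            change = parse_protein_change(raw_change)
        except ProteinChangeError as exc:
            reject(exc.reason, str(exc))
            continue
        dedup_key = (sample, gene.upper(), change)
        if dedup_key in seen:
            reject("duplicate", "identical (sample, gene, change) seen earlier")
            continue
        seen.add(dedup_key)
        variants.append(
            MissenseVariant(
                sample_id=sample,
                gene_symbol=gene,
                change=change,
                classification_label=label,
            )
        )
    n_dupes = sum(1 for r in rejections if r.reason == "duplicate")
    if n_dupes:
        logger.info("deduplicated %d repeated variant rows", n_dupes)
    return variants, rejections


def to_maf_frame(variants: Iterable[MissenseVariant]) -> pd.DataFrame:
    """Render variants back into the default MAF-dialect columns."""
    return pd.DataFrame(
        {
            "Hugo_Symbol": [v.gene_symbol for v in variants],
            "Variant_Classification": [v.classification_label for v in variants],
            "HGVSp_Short": [str(v.change) for v in variants],
            "Tumor_Sample_Barcode": [v.sample_id for v in variants],
        }
    )


def write_maf(variants: Sequence[MissenseVariant], path: Union[str, Path]) -> None:
    """Write variants as a MAF-dialect TSV readable by :func:`read_maf`."""
    to_maf_frame(variants).to_csv(path, sep="\t", index=False)


def write_variants_tsv(variants: Sequence[MissenseVariant], path: Union[str, Path]) -> None:
    """Write the normalized variant table (one row per accepted variant)."""
    pd.DataFrame(
        {
            "sample_id": [v.sample_id for v in variants],
            "gene_symbol": [v.gene_symbol for v in variants],
            "ref_aa": [v.change.ref_aa for v in variants],
            "position": [v.change.position for v in variants],
            "alt_aa": [v.change.alt_aa for v in variants],
        }
    ).to_csv(path, sep="\t", index=False)


def write_rejections_tsv(rejections: Sequence[Rejection], path: Union[str, Path]) -> None:
    """Write the rejection log as TSV."""
    pd.DataFrame(
        {
            "row_index": [r.row_index for r in rejections],
            "sample_id": [r.sample_id for r in rejections],
            "gene_symbol": [r.gene_symbol for r in rejections],
            "raw_change": [r.raw_change for r in rejections],
            "reason": [r.reason for r in rejections],
            "detail": [r.detail for r in rejections],
        }
    ).to_csv(path, sep="\t", index=False)
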