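"""Reading and writing the toolkit's external representations.

Covers FASTA peptide input, labeled peptide tables (IEDB-like exports),
feature matrices (CSV with a leading id column) and JSON metric reports.
Model-bundle persistence lives next to the models in
:mod:`epitopekit.model_selection`.

Validation is total: every input row is either accepted or produces a
located diagnostic (logged with its row/line number); rows containing
ambiguous residues (B, J, O, U, X, Z) or other non-canonical characters
are excluded at read time, since every downstream descriptor table is
defined only over the 20 canonical amino acids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("epitopekit")

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)
AMBIGUOUS_AA = frozenset("BJOUXZ")

LABELS = ("epitope", "non_epitope", "unknown")

#: The fixed 20-term organism lineage vocabulary, grouped by superkingdom:
#: 8 Virus classes, 5 Eukaryota classes, 7 Bacteria classes.  One-hot slots
#: are positional in exactly this order.
TAXONOMY_CLASSES = (
    # Virus (8)
    "Riboviria",
    "Duplodnaviria",
    "Monodnaviria",
    "Varidnaviria",
    "Ribozyviria",
    "Anelloviridae",
    "Naldaviricetes",
    "Adnaviria",
    # Eukaryota (5)
    "Metamonada",
    "Discoba",
    "Sar",
    "Viridiplantae",
    "Opisthokonta",
    # Bacteria (7)
    "Terrabacteria group",
    "Proteobacteria",
    "PVC group",
    "Spirochaetes",
    "FCB group",
    "Thermodesulfobacteria",
    "Fusobacteria",
)


class FormatError(ValueError):
    """Malformed external input (FASTA/table/matrix)."""


class SequenceError(ValueError):
    """A peptide sequence violates the canonical 20-letter alphabet."""


def validate_sequence(sequence: str, *, where: str = "") -> str:
    """Validate and return an uppercase canonical amino-acid sequence.

    Raises :class:`SequenceError` naming the first offending character.
    """
    if not sequence:
        raise SequenceError(f"empty sequence{' at ' + where if where else ''}")
    seq = sequence.upper()
    bad = [ch for ch in dict.fromkeys(seq) if ch not in _CANONICAL_SET]
    if bad:
        parts = [
            ("ambiguous residue " if ch in AMBIGUOUS_AA else "invalid character ")
            + repr(ch)
            for ch in bad
        ]
        raise SequenceError(
            f"{', '.join(parts)} in sequence {seq!r}"
            f"{' at ' + where if where else ''}"
        )
    return seq


@dataclass
class PeptideRecord:
    """One labeled peptide: a row of the curated dataset.

    Parameters
    ----------
    id : str
        Unique identifier.
    sequence : str
        Uppercase sequence over the 20 canonical amino-acid letters.
    label : str
        One of ``epitope``, ``non_epitope``, ``unknown``.
    organism_class : str
        One of the 20-term taxonomy vocabulary, or ``unknown``.
    evidence_count : int
        Number of distinct confirming assays (>= 0).
    """

    id: str
    sequence: str
    label: str = "unknown"
    organism_class: str = "unknown"
    evidence_count: int = 0

    def __post_init__(self) -> None:
        self.sequence = validate_sequence(self.sequence, where=f"record {self.id!r}")
        if self.label not in LABELS:
            raise ValueError(f"record {self.id!r}: unknown label {self.label!r}")
        if self.evidence_count < 0:
            raise ValueError(
                f"record {self.id!r}: negative evidence_count {self.evidence_count}"
            )


@dataclass(frozen=True)
class TaxonomyVocabulary:
    """Ordered vocabulary of the 20 organism lineage classes.

    Slot order is fixed (one-hot encoding is positional).
    """

    classes: tuple = TAXONOMY_CLASSES

    def __post_init__(self) -> None:
        if len(self.classes) != 20:
            raise ValueError(
                f"taxonomy vocabulary must have exactly 20 classes, got {len(self.classes)}"
            )
        if len(set(self.classes)) != 20:
            raise ValueError("taxonomy vocabulary classes must be unique")

    def __contains__(self, name: str) -> bool:
        return name in self.classes

    def index(self, name: str) -> int:
        return self.classes.index(name)


@dataclass
class FeatureMatrix:
    """Named numeric feature columns x peptides.

    The contract between featurization and modeling.  ``data`` is a pandas
    DataFrame indexed by peptide id with one named column per feature;
    ``provenance`` maps each feature name to the descriptor group that
    produced it.
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if len(cols) != len(set(cols)):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise FormatError(f"duplicate feature names: {dupes}")
        if self.data.shape[0] and self.data.isna().any().any():
            bad = [c for c in cols if self.data[c].isna().any()]
            raise FormatError(f"missing values in feature columns: {bad}")

    @property
    def feature_names(self) -> list:
        return list(self.data.columns)

    @property
    def ids(self) -> list:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return (
            self.feature_names == other.feature_names
            and self.ids == other.ids
            and np.allclose(self.values, other.values, rtol=0, atol=1e-12)
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list:
    """Read peptides from a FASTA file.

    The header convention ``>id|organism_class`` optionally carries the
    organism lineage class; labels are ``unknown`` (FASTA carries no label).
    Records with non-canonical residues are excluded with a logged
    diagnostic naming the offending line.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty FASTA input")

    entries = []  # (header, seq, line_no)
    header = None
    seq_parts: list = []
    header_line = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                entries.append((header, "".join(seq_parts), header_line))
            header = line[1:].strip()
            seq_parts = []
            header_line = lineno
            if not header:
                raise FormatError(f"{path}: line {lineno}: empty FASTA header")
        else:
            if header is None:
                raise FormatError(
                    f"{path}: line {lineno}: sequence data before any '>' header"
                )
            seq_parts.append(line)
    if header is not None:
        entries.append((header, "".join(seq_parts), header_line))
    if not entries:
        raise FormatError(f"{path}: no FASTA entries found")

    records = []
    for head, seq, lineno in entries:
        rec_id, _, org = head.partition("|")
        org = org.strip() or "unknown"
        if org != "unknown" and org not in TAXONOMY_CLASSES:
            logger.warning("%s: line %d: unknown organism %r mapped to 'unknown'",
                           path, lineno, org)
            org = "unknown"
        try:
            records.append(
                PeptideRecord(id=rec_id.strip(), sequence=seq, organism_class=org)
            )
        except SequenceError as exc:
            raise SequenceError(f"{path}: entry at line {lineno}: {exc}") from None
    return records


def write_fasta(records: Sequence[PeptideRecord], path) -> None:
    """Write peptides as FASTA, encoding organism class as ``>id|class``."""
    with open(path, "w") as fh:
        for rec in records:
            head = rec.id
            if rec.organism_class != "unknown":
                head = f"{rec.id}|{rec.organism_class}"
            fh.write(f">{head}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# Peptide tables
# ---------------------------------------------------------------------------

#: Default column-name map for labeled peptide tables.
DEFAULT_DIALECT = {
    "id": "id",
    "sequence": "sequence",
    "label": "label",
    "organism": "organism",
    "assays": "assays",
}

_LABEL_ALIASES = {
    "epitope": "epitope",
    "positive": "epitope",
    "1": "epitope",
    "non_epitope": "non_epitope",
    "non-epitope": "non_epitope",
    "negative": "non_epitope",
    "0": "non_epitope",
    "unknown": "unknown",
}


def read_peptide_table(path, dialect: Mapping[str, str] | None = None) -> list:
    """Read a labeled peptide table (TSV/CSV, delimiter sniffed by extension).

    ``dialect`` maps the logical column roles (``id``, ``sequence``,
    ``label``, ``organism``, ``assays``) to the file's column names.
    ``sequence`` and ``label`` are mandatory; rows failing validation are
    excluded with a logged diagnostic carrying the row number; unknown
    organism names map to ``"unknown"`` with a warning.
    """
    path = Path(path)
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    for role in ("sequence", "label"):
        if cols[role] not in df.columns:
            raise FormatError(
                f"{path}: missing mandatory column {cols[role]!r} "
                f"(have {list(df.columns)})"
            )

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        row_d = dict(zip(df.columns, row))
        rec_id = row_d.get(cols["id"], "") or f"row{i}"
        raw_label = row_d[cols["label"]].strip().lower()
        label = _LABEL_ALIASES.get(raw_label)
        if label is None:
            logger.warning("%s: row %d: unknown label %r, row excluded",
                           path, i, row_d[cols["label"]])
            continue
        org = row_d.get(cols["organism"], "unknown").strip() or "unknown"
        if org != "unknown" and org not in TAXONOMY_CLASSES:
            logger.warning("%s: row %d: unknown organism %r mapped to 'unknown'",
                           path, i, org)
            org = "unknown"
        raw_assays = row_d.get(cols["assays"], "0").strip() or "0"
        try:
            evidence = int(raw_assays)
        except ValueError:
            logger.warning("%s: row %d: non-integer assay count %r, row excluded",
                           path, i, raw_assays)
            continue
        try:
            records.append(
                PeptideRecord(
                    id=rec_id,
                    sequence=row_d[cols["sequence"]],
                    label=label,
                    organism_class=org,
                    evidence_count=evidence,
                )
            )
        except (SequenceError, ValueError) as exc:
            logger.warning("%s: row %d: %s, row excluded", path, i, exc)
    return records


def write_peptide_table(records: Sequence[PeptideRecord], path,
                        dialect: Mapping[str, str] | None = None) -> None:
    """Write records as a delimited peptide table (inverse of the reader)."""
    path = Path(path)
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.DataFrame(
        {
            cols["id"]: [r.id for r in records],
            cols["sequence"]: [r.sequence for r in records],
            cols["label"]: [r.label for r in records],
            cols["organism"]: [r.organism_class for r in records],
            cols["assays"]: [r.evidence_count for r in records],
        }
    )
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Feature matrices
# ---------------------------------------------------------------------------

def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    """Write a feature matrix as CSV with a leading ``id`` column.

    Floats use repr formatting, so the write/read round trip is lossless.
    """
    df = matrix.data.copy()
    df.index.name = "id"
    df.to_csv(path, float_format="%.17g")
    prov_path = Path(str(path) + ".provenance.json")
    if matrix.provenance:
        import json

        prov_path.write_text(json.dumps(matrix.provenance, indent=0, sort_keys=True))


def read_feature_matrix(path) -> FeatureMatrix:
    """Read a feature matrix written by :func:`write_feature_matrix`."""
    df = pd.read_csv(path, index_col="id")
    df.index = df.index.astype(str)
    cols = list(df.columns)
    if len(cols) != len(set(cols)) or any(c.endswith(".1") and c[:-2] in cols for c in cols):
        raise FormatError(f"{path}: duplicate feature names in header")
    provenance = {}
    prov_path = Path(str(path) + ".provenance.json")
    if prov_path.exists():
        import json

        provenance = json.loads(prov_path.read_text())
    return FeatureMatrix(data=df.astype(float), provenance=provenance)


def labels_to_binary(records: Iterable[PeptideRecord]) -> np.ndarray:
    """Encode labels as 1 (epitope) / 0 (non_epitope); rejects 'unknown'."""
    out = []
    for rec in records:
        if rec.label == "unknown":
            raise ValueError(f"record {rec.id!r} has no class label")
        out.append(1 if rec.label == "epitope" else 0)
    return np.asarray(out, dtype=int)
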