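"""Reading and validation of sequences, labels, and PSSM profiles.

The central containers are :class:`ProteinRecord` (one identified amino-acid
sequence, optionally labelled with a J-protein type and carrying a PSSM
profile) and :class:`LabeledDataset` (the fully assembled training/testing
collection every downstream stage consumes).

PSSM files follow the PSI-BLAST ASCII dialect: a couple of header lines,
then one row per residue whose first 20 numeric columns are the log-odds
scores.  PSI-BLAST prints columns in the order ``A R N D C Q E G H I L K M
F P S T W Y V``; internally every profile is remapped to alphabetical
``A C D E F ...`` order so that feature indices are stable regardless of
the file dialect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("jprotpred")

#: The 20 standard amino acids, alphabetical by one-letter code.  All
#: feature blocks and PSSM columns use this order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Residue-column order printed by PSI-BLAST in ASCII PSSM files.
PSIBLAST_COLUMN_ORDER: str = "ARNDCQEGHILKMFPSTWYV"

#: Recognised J-protein type labels.
CLASS_LABELS: tuple[str, ...] = ("I", "II", "III", "IV")

_AA_SET = frozenset(AMINO_ACIDS)
# column permutation: alphabetical index -> position in the PSI-BLAST row
_PSIBLAST_TO_ALPHA = np.array(
    [PSIBLAST_COLUMN_ORDER.index(aa) for aa in AMINO_ACIDS]
)


class ValidationError(ValueError):
    """Raised when an input fails a structural or alphabet check."""


@dataclass
class PSSMProfile:
    """An L x 20 position-specific scoring matrix in log-odds units.

    Columns follow :data:`AMINO_ACIDS` (alphabetical) order.  A profile
    with ``is_fallback=True`` is the all-zero matrix substituted when no
    homology profile is available for a sequence; sigmoid normalisation
    maps it to a constant 0.5 matrix, so its autocovariance features are
    exactly zero.
    """

    scores: np.ndarray
    is_fallback: bool = False
    column_order: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValidationError(
                f"PSSM must be L x 20, got shape {self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise ValidationError("PSSM must have at least one row")
        if self.is_fallback and np.any(self.scores != 0.0):
            raise ValidationError("fallback PSSM must be all zeros")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass
class ProteinRecord:
    """An identified protein sequence with optional label and PSSM."""

    id: str
    sequence: str
    label: str | None = None
    pssm: PSSMProfile | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = sorted(set(self.sequence) - _AA_SET)
        if bad:
            raise ValidationError(
                f"record {self.id!r}: nonstandard letter(s) {''.join(bad)!r}"
            )
        if self.label is not None and self.label not in CLASS_LABELS:
            raise ValidationError(
                f"record {self.id!r}: unknown class label {self.label!r}"
            )
        if self.pssm is not None and self.pssm.length != len(self.sequence):
            raise ValidationError(
                f"record {self.id!r}: PSSM has {self.pssm.length} rows for a "
                f"{len(self.sequence)}-residue sequence"
            )


@dataclass
class LabeledDataset:
    """A collection of labelled records plus a class tally."""

    records: list[ProteinRecord]
    class_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for rec in self.records:
            if rec.label is None:
                raise ValidationError(f"record {rec.id!r} has no label")
            counts[rec.label] = counts.get(rec.label, 0) + 1
        if not self.class_counts:
            self.class_counts = counts
        elif self.class_counts != counts:
            raise ValidationError("class_counts disagrees with records")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> list[str]:
        return [rec.label for rec in self.records]  # type: ignore[misc]


def read_fasta(path: str | Path, strict: bool = True) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Sequences are upper-cased.  Entries containing letters outside the
    20-letter standard alphabet (B, X, Z, U, O, gaps, ...) are rejected:
    in strict mode (the training default) the first offending entry raises
    :class:`ValidationError`; in lenient mode offending entries are skipped
    with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    n_seen = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        n_seen += 1
        seq = str(entry.seq).upper()
        try:
            records.append(ProteinRecord(id=entry.id, sequence=seq))
        except ValidationError as err:
            if strict:
                raise
            logger.warning("skipping record: %s", err)
    if n_seen == 0:
        raise ValidationError(f"no FASTA entries in {path}")
    return records


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column tab-separated ``id<TAB>class`` label table."""
    path = Path(path)
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected 'id<TAB>class', got {line!r}"
                )
            seq_id, cls = parts
            if cls not in CLASS_LABELS:
                raise ValidationError(
                    f"{path}:{lineno}: unknown class {cls!r}"
                )
            labels[seq_id] = cls
    return labels


def read_pssm(path: str | Path, expected_length: int) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM file.

    Takes the first 20 numeric columns of each residue row (the log-odds
    block) and remaps them from the file's PSI-BLAST residue order to
    alphabetical column order.  The row count must equal
    ``expected_length`` (the sequence length).
    """
    path = Path(path)
    rows: list[list[float]] = []
    file_order: str | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            # header line listing the 20 residue columns
            if file_order is None and len(parts) >= 20 and all(
                p in _AA_SET and len(p) == 1 for p in parts[:20]
            ):
                file_order = "".join(parts[:20])
                continue
            # residue row: index, residue letter, >= 20 numbers
            if parts[0].isdigit() and len(parts) >= 22 and parts[1] in _AA_SET:
                try:
                    rows.append([float(x) for x in parts[2:22]])
                except ValueError as err:
                    raise ValidationError(
                        f"{path}:{lineno}: malformed numeric field ({err})"
                    ) from None
    if not rows:
        raise ValidationError(f"{path}: no PSSM rows found")
    scores = np.asarray(rows, dtype=float)
    order = file_order if file_order is not None else PSIBLAST_COLUMN_ORDER
    perm = np.array([order.index(aa) for aa in AMINO_ACIDS])
    scores = scores[:, perm]
    if scores.shape[0] != expected_length:
        raise ValidationError(
            f"{path}: PSSM has {scores.shape[0]} rows, expected "
            f"{expected_length}"
        )
    return PSSMProfile(scores=scores, is_fallback=False)


def write_pssm(profile: PSSMProfile, path: str | Path, sequence: str) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect (log-odds block only)."""
    if profile.length != len(sequence):
        raise ValidationError("sequence length does not match profile")
    perm = _PSIBLAST_TO_ALPHA  # alphabetical -> file column positions
    inv = np.empty(20, dtype=int)
    inv[perm] = np.arange(20)  # file position -> alphabetical index
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted "
            "observed percentages rounded down, information per position, "
            "and relative weight of gapless real matches to pseudocounts\n"
        )
        fh.write("      " + "  ".join(PSIBLAST_COLUMN_ORDER) + "\n")
        for i, aa in enumerate(sequence):
            row = profile.scores[i][inv]
            nums = " ".join(f"{int(round(v)):3d}" for v in row)
            fh.write(f"{i + 1:5d} {aa} {nums}\n")


def zero_pssm(length: int) -> PSSMProfile:
    """The all-zero fallback profile used when no homology search hit exists."""
    if length < 1:
        raise ValidationError(f"PSSM length must be >= 1, got {length}")
    return PSSMProfile(scores=np.zeros((length, 20)), is_fallback=True)


def assemble_dataset(
    records: Sequence[ProteinRecord],
    labels: Mapping[str, str],
    pssm_dir: str | Path | None = None,
) -> LabeledDataset:
    """Attach labels and PSSM profiles to records, building the dataset.

    Every record id must appear in the label table.  PSSMs are looked up
    in ``pssm_dir`` as ``<id>.pssm``; a record without a profile receives
    the zero-matrix fallback, and the number of fallbacks is logged.
    """
    missing = [rec.id for rec in records if rec.id not in labels]
    if missing:
        raise ValidationError(
            f"records missing from label table: {', '.join(missing[:10])}"
            + ("..." if len(missing) > 10 else "")
        )
    out: list[ProteinRecord] = []
    n_fallback = 0
    for rec in records:
        pssm: PSSMProfile | None = None
        if pssm_dir is not None:
            candidate = Path(pssm_dir) / f"{rec.id}.pssm"
            if candidate.exists():
                pssm = read_pssm(candidate, expected_length=len(rec.sequence))
        if pssm is None:
            pssm = zero_pssm(len(rec.sequence))
            n_fallback += 1
        out.append(
            ProteinRecord(
                id=rec.id, sequence=rec.sequence,
                label=labels[rec.id], pssm=pssm,
            )
        )
    if n_fallback:
        logger.info(
            "assemble_dataset: %d/%d records use the zero-matrix PSSM "
            "fallback", n_fallback, len(out),
        )
    return LabeledDataset(records=out)
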