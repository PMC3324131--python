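"""Mutation-pattern parsing, mutation calling against a reference, and dataset I/O.

Mutation patterns use standard amino-acid nomenclature: a reference residue,
a 1-based position on the reference protein, and one or more accepted
alternate residues, e.g. ``"M41L"`` or ``"T215Y/F"``.  Alternates may be
written with or without slash separators (``"M184VI"`` == ``"M184V/I"``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Characters treated as "no evidence" at a pattern position (gap / ambiguous).
INDETERMINATE_CHARS = frozenset("-.X*?")

ID_COLUMN = "patient_id"
OUTCOME_COLUMN = "delta_vl_log10"


class MutationPatternError(ValueError):
    """Raised for malformed mutation-pattern labels."""


class AlignmentError(ValueError):
    """Raised when sequences are inconsistent with the reference alignment."""


class DatasetFormatError(ValueError):
    """Raised for invalid dataset CSV content."""


_LABEL_RE = re.compile(r"^([A-Z])(\d+)((?:[A-Z]/?)*[A-Z])$")


@dataclass(frozen=True)
class MutationPattern:
    """A reference position with its wild-type residue and alternate residues.

    ``position`` is 1-based on the reference amino-acid sequence.
    """

    position: int
    ref_residue: str
    alt_residues: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise MutationPatternError(f"position must be >= 1, got {self.position}")
        if self.ref_residue not in AMINO_ACIDS:
            raise MutationPatternError(f"invalid reference residue {self.ref_residue!r}")
        if not self.alt_residues:
            raise MutationPatternError("alternate residue set must be non-empty")
        for a in self.alt_residues:
            if a not in AMINO_ACIDS:
                raise MutationPatternError(f"invalid alternate residue {a!r}")
        if self.ref_residue in self.alt_residues:
            raise MutationPatternError(
                f"reference residue {self.ref_residue} listed among alternates"
            )
        if len(set(self.alt_residues)) != len(self.alt_residues):
            raise MutationPatternError("duplicate alternate residues")

    @property
    def label(self) -> str:
        """Canonical label, alternates slash-separated (``T215Y/F``)."""
        return f"{self.ref_residue}{self.position}" + "/".join(self.alt_residues)

    def matches(self, residues: Iterable[str]) -> bool:
        """True if any observed residue at the position is an alternate."""
        return any(r in self.alt_residues for r in residues)


def parse_mutation_pattern(label: str) -> MutationPattern:
    """Parse a mutation label such as ``"M41L"``, ``"T215Y/F"`` or ``"M184VI"``.

    Alternates with or without ``"/"`` separators are equivalent.
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise MutationPatternError(f"malformed mutation label: {label!r}")
    ref, pos, alts_raw = m.group(1), int(m.group(2)), m.group(3)
    alts = tuple(c for c in alts_raw if c != "/")
    try:
        return MutationPattern(position=pos, ref_residue=ref, alt_residues=alts)
    except MutationPatternError as exc:
        raise MutationPatternError(f"invalid mutation label {label!r}: {exc}") from exc


def format_mutation_pattern(pattern: MutationPattern) -> str:
    return pattern.label


@dataclass
class GenotypeMatrix:
    """Binary patients x mutations matrix with row and column labels."""

    values: np.ndarray
    patient_ids: list[str]
    mutation_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("genotype entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        n, p = self.values.shape
        if len(self.patient_ids) != n:
            raise ValueError("patient_ids length does not match row count")
        if len(self.mutation_labels) != p:
            raise ValueError("mutation_labels length does not match column count")
        if len(set(self.patient_ids)) != n:
            raise ValueError("patient ids must be unique")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_mutations(self) -> int:
        return self.values.shape[1]


@dataclass
class Dataset:
    """Genotype matrix plus a continuous outcome (change in log10 viral load)."""

    genotype: GenotypeMatrix
    outcome: np.ndarray

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=float)
        if self.outcome.ndim != 1:
            raise ValueError("outcome must be a vector")
        if len(self.outcome) != self.genotype.n_patients:
            raise ValueError("outcome length does not match patient count")
        if not np.isfinite(self.outcome).all():
            raise ValueError("outcome values must be finite")

    @property
    def X(self) -> np.ndarray:
        return self.genotype.values.astype(float)

    @property
    def y(self) -> np.ndarray:
        return self.outcome

    @property
    def n(self) -> int:
        return self.genotype.n_patients

    @property
    def p(self) -> int:
        return self.genotype.n_mutations

    @property
    def mutation_labels(self) -> list[str]:
        return self.genotype.mutation_labels


SequenceLike = Union[str, Sequence[str]]


def _cell(seq: SequenceLike, idx: int) -> str:
    """Residue(s) at 0-based ``idx``; a cell may hold a mixture like ``"VI"``."""
    cell = seq[idx]
    return str(cell)


def call_mutations(
    sequences: Mapping[str, SequenceLike],
    patterns: Sequence[MutationPattern],
    reference: str,
) -> GenotypeMatrix:
    """Call each mutation pattern on aligned amino-acid sequences.

    Entry (i, j) is 1 iff patient i carries any alternate residue of pattern j
    at the pattern position.  Mixtures (multiple residues in one cell) call the
    mutation if any residue is an alternate.  Gaps and ``X`` yield 0 with a
    logged warning.

    Raises
    ------
    AlignmentError
        If a sequence length differs from the reference, or the reference
        residue at a pattern position disagrees with the pattern.
    """
    ref_len = len(reference)
    for pat in patterns:
        if pat.position > ref_len:
            raise AlignmentError(
                f"pattern {pat.label} position {pat.position} beyond reference "
                f"length {ref_len}"
            )
        ref_res = str(reference[pat.position - 1]).upper()
        if ref_res != pat.ref_residue:
            raise AlignmentError(
                f"reference residue mismatch at position {pat.position}: "
                f"pattern {pat.label} expects {pat.ref_residue}, reference has {ref_res}"
            )

    patient_ids = list(sequences.keys())
    values = np.zeros((len(patient_ids), len(patterns)), dtype=np.int8)
    for i, pid in enumerate(patient_ids):
        seq = sequences[pid]
        if len(seq) != ref_len:
            raise AlignmentError(
                f"sequence {pid!r} length {len(seq)} differs from reference "
                f"length {ref_len}"
            )
        for j, pat in enumerate(patterns):
            residues = _cell(seq, pat.position - 1).upper()
            if all(r in INDETERMINATE_CHARS for r in residues):
                logger.warning(
                    "indeterminate residue %r for patient %s at position %d; "
                    "calling 0",
                    residues,
                    pid,
                    pat.position,
                )
                continue
            if pat.matches(residues):
                values[i, j] = 1
    return GenotypeMatrix(
        values=values,
        patient_ids=patient_ids,
        mutation_labels=[p.label for p in patterns],
    )


def prevalence(genotype: GenotypeMatrix) -> np.ndarray:
    """Per-mutation sample prevalence (column means)."""
    if genotype.n_patients == 0:
        raise ValueError("prevalence undefined for an empty genotype matrix")
    return genotype.values.mean(axis=0)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write the dataset as CSV: patient_id, one 0/1 column per mutation, outcome."""
    df = pd.DataFrame(
        dataset.genotype.values,
        columns=dataset.mutation_labels,
    )
    df.insert(0, ID_COLUMN, dataset.genotype.patient_ids)
    df[OUTCOME_COLUMN] = dataset.outcome
    df.to_csv(path, index=False)


def read_dataset(path: str | Path) -> Dataset:
    """Read a dataset CSV written by :func:`write_dataset`, with validation."""
    df = pd.read_csv(path, dtype={ID_COLUMN: str})
    for col in (ID_COLUMN, OUTCOME_COLUMN):
        if col not in df.columns:
            raise DatasetFormatError(f"missing required column {col!r}")
    mutation_labels = [c for c in df.columns if c not in (ID_COLUMN, OUTCOME_COLUMN)]
    if not mutation_labels:
        raise DatasetFormatError("no mutation columns found")
    ids = df[ID_COLUMN].tolist()
    if df[ID_COLUMN].isna().any():
        raise DatasetFormatError("missing patient id")
    dupes = df[ID_COLUMN][df[ID_COLUMN].duplicated()].tolist()
    if dupes:
        raise DatasetFormatError(f"duplicate patient ids: {dupes}")
    geno = df[mutation_labels]
    for col in mutation_labels:
        vals = geno[col]
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise DatasetFormatError(f"missing genotype value at row {row}, column {col!r}")
        bad = ~vals.isin((0, 1))
        if bad.any():
            row = int(vals.index[bad][0])
            raise DatasetFormatError(
                f"non-binary genotype value {vals[bad].iloc[0]!r} at row {row}, "
                f"column {col!r}"
            )
    outcome = df[OUTCOME_COLUMN]
    if outcome.isna().any():
        row = int(outcome.index[outcome.isna()][0])
        raise DatasetFormatError(f"missing outcome at row {row}")
    return Dataset(
        genotype=GenotypeMatrix(
            values=geno.to_numpy(),
            patient_ids=ids,
            mutation_labels=mutation_labels,
        ),
        outcome=outcome.to_numpy(dtype=float),
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read aligned amino-acid sequences; FASTA headers are patient ids."""
    from Bio import SeqIO

    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise DatasetFormatError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise DatasetFormatError(f"no FASTA records found in {path}")
    return records


def read_mutation_list(path: str | Path) -> list[MutationPattern]:
    """Read a plain-text mutation list: one label per line, '#' comments allowed."""
    patterns = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            patterns.append(parse_mutation_pattern(line))
    return patterns
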