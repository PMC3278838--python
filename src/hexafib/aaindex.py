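"""Amino-acid property tables: AAindex flat-file I/O and atomic composition.

An amino-acid index assigns one real number to each of the 20 standard
residues (hydrophobicity, volume, helix propensity, ...).  The AAindex
database distributes such indices as flat-file records; only the ``H``
(accession), ``D`` (description) and ``I`` (value block) lines are
interpreted here, all other record lines (R, A, T, J, C, ...) are passed
over.  Records whose value block contains a missing-value marker are
skipped and reported rather than imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

log = logging.getLogger(__name__)

#: The 20 standard residues in alphabetical one-letter order.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

# Column order of the AAindex "I" block: first row A..I, second row L..V.
_I_ROW1 = "ARNDCQEGHI"
_I_ROW2 = "LKMFPSTWYV"
_I_ORDER = _I_ROW1 + _I_ROW2

_MISSING_MARKERS = {"NA", "NULL", "-", "--"}


class AAindexParseError(ValueError):
    """Malformed AAindex record (wrong value count, missing H line, ...)."""


class DegenerateIndexError(ValueError):
    """An index with zero variance across residues cannot be standardized."""


@dataclass(frozen=True)
class AminoAcidIndex:
    """One amino-acid property: an accession, a description and 20 values."""

    accession: str
    description: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        keys = set(self.values)
        if keys != set(STANDARD_RESIDUES):
            missing = sorted(set(STANDARD_RESIDUES) - keys)
            extra = sorted(keys - set(STANDARD_RESIDUES))
            raise ValueError(
                f"index {self.accession!r}: values must cover exactly the 20 "
                f"standard residues (missing={missing}, extra={extra})"
            )
        for res, val in self.values.items():
            if not math.isfinite(val):
                raise ValueError(
                    f"index {self.accession!r}: non-finite value for {res}"
                )

    def as_vector(self, sequence: str) -> list[float]:
        """Per-position property values p_i for a residue string."""
        try:
            return [self.values[r] for r in sequence]
        except KeyError as exc:
            raise KeyError(
                f"residue {exc.args[0]!r} not covered by index {self.accession}"
            ) from exc


@dataclass(frozen=True)
class AtomTable:
    """Per-residue C/H/N/O/S atom counts (dehydrated, in-chain residues)."""

    counts: Mapping[str, tuple[int, int, int, int, int]]

    ELEMENTS = ("C", "H", "N", "O", "S")

    def __getitem__(self, residue: str) -> tuple[int, int, int, int, int]:
        return self.counts[residue]


# In-chain residue formulas: the free amino acid minus one water.  Sulphur
# appears only in Cys and Met; every residue keeps the backbone nitrogen.
_RESIDUE_ATOMS: dict[str, tuple[int, int, int, int, int]] = {
    #     C   H   N  O  S
    "A": (3, 5, 1, 1, 0),
    "R": (6, 12, 4, 1, 0),
    "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0),
    "C": (3, 5, 1, 1, 1),
    "Q": (5, 8, 2, 2, 0),
    "E": (5, 7, 1, 3, 0),
    "G": (2, 3, 1, 1, 0),
    "H": (6, 7, 3, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "L": (6, 11, 1, 1, 0),
    "K": (6, 12, 2, 1, 0),
    "M": (5, 9, 1, 1, 1),
    "F": (9, 9, 1, 1, 0),
    "P": (5, 7, 1, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "T": (4, 7, 1, 2, 0),
    "W": (11, 10, 2, 1, 0),
    "Y": (9, 9, 1, 2, 0),
    "V": (5, 9, 1, 1, 0),
}


def atomic_table() -> AtomTable:
    """The fixed residue-formula table used by the atomic-composition block."""
    return AtomTable(dict(_RESIDUE_ATOMS))


def parse_aaindex(
    source: str | IO[str], skipped: list[str] | None = None
) -> list[AminoAcidIndex]:
    """Parse AAindex flat-file records from a string or text handle.

    Records with a missing-value marker ("NA"/"-") in their I block are
    excluded from the result and reported through ``skipped`` (a caller
    supplied list of accessions) and the module logger.

    Raises
    ------
    AAindexParseError
        If a record is malformed (missing H line, wrong number of values).
    """
    text = source if isinstance(source, str) else source.read()
    records: list[AminoAcidIndex] = []
    accession: str | None = None
    description: list[str] = []
    tokens: list[str] | None = None
    start_line = 0

    def finish(line_no: int) -> None:
        nonlocal accession, description, tokens
        if accession is None and tokens is None and not description:
            return
        if accession is None:
            raise AAindexParseError(
                f"record ending at line {line_no}: missing H (accession) line"
            )
        if tokens is None:
            raise AAindexParseError(
                f"record {accession!r} ending at line {line_no}: missing I block"
            )
        if any(t.upper() in _MISSING_MARKERS for t in tokens):
            log.warning("skipping index %s: missing values in I block", accession)
            if skipped is not None:
                skipped.append(accession)
        else:
            if len(tokens) != 20:
                raise AAindexParseError(
                    f"record {accession!r} (line {start_line}): expected 20 "
                    f"values in I block, found {len(tokens)}"
                )
            try:
                vals = [float(t) for t in tokens]
            except ValueError as exc:
                raise AAindexParseError(
                    f"record {accession!r}: non-numeric value in I block"
                ) from exc
            records.append(
                AminoAcidIndex(
                    accession=accession,
                    description=" ".join(description),
                    values=dict(zip(_I_ORDER, vals)),
                )
            )
        accession, description, tokens = None, [], None

    in_i_block = False
    line_no = 0
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line.strip():
            continue
        if line.startswith("//"):
            finish(line_no)
            in_i_block = False
            continue
        key, _, rest = line[0], line[1:2], line[1:].strip()
        if line[0] != " ":
            in_i_block = False
        if key == "H" and line[0] == "H":
            if accession is not None:
                raise AAindexParseError(
                    f"line {line_no}: second H line inside record {accession!r}"
                )
            accession = rest
            start_line = line_no
        elif key == "D" and line[0] == "D":
            description.append(rest)
        elif key == "I" and line[0] == "I":
            tokens = []
            in_i_block = True
        elif line[0] == " ":
            if in_i_block and tokens is not None:
                tokens.extend(line.split())
            elif description and accession is not None and tokens is None:
                description.append(line.strip())
    finish(line_no if text.strip() else 0)
    return records


def write_aaindex(indices: Iterable[AminoAcidIndex]) -> str:
    """Serialize indices back to AAindex flat-file format (H/D/I records)."""
    chunks: list[str] = []
    for idx in indices:
        row1 = "  " + " ".join(f"{idx.values[r]:>16.12g}" for r in _I_ROW1)
        row2 = "  " + " ".join(f"{idx.values[r]:>16.12g}" for r in _I_ROW2)
        header = "    ".join(f"{a}/{b}" for a, b in zip(_I_ROW1, _I_ROW2))
        chunks.append(
            f"H {idx.accession}\n"
            f"D {idx.description}\n"
            f"I    {header}\n"
            f"{row1}\n{row2}\n//\n"
        )
    return "".join(chunks)


def standardize_index(index: AminoAcidIndex) -> AminoAcidIndex:
    """Center and scale an index to mean 0, population sd 1 over the residues.

    Standardization is the usual pre-conditioning for Moreau-Broto
    autocorrelation, so that products of property values are comparable
    across indices with different native scales.
    """
    vals = [index.values[r] for r in STANDARD_RESIDUES]
    mean = sum(vals) / len(vals)
    var = sum((v - mean) ** 2 for v in vals) / len(vals)
    if var == 0.0:
        raise DegenerateIndexError(
            f"index {index.accession!r} is constant; cannot standardize"
        )
    sd = math.sqrt(var)
    return AminoAcidIndex(
        accession=index.accession,
        description=index.description,
        values={r: (v - mean) / sd for r, v in index.values.items()},
    )
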