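"""Hexmer windowing and feature encoding.

A protein sequence is cut into overlapping six-residue windows (hexmers);
each window is encoded as a numeric vector built from up to three blocks:

* ``BPC``  — per-window arithmetic means of raw amino-acid index values,
  one feature per selected bio-physio-chemical property;
* ``AC``   — Moreau-Broto autocorrelation of standardized index values at
  lags 1..5, which restores the sequence-order effect that plain
  composition features discard;
* ``ATOM`` — total C, H, N, O, S atom counts of the window, which are
  permutation-invariant by construction.

Feature columns are min-max normalized with parameters fitted on the
training partition only and reused unchanged elsewhere.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .aaindex import STANDARD_RESIDUES, AminoAcidIndex, AtomTable, atomic_table, standardize_index

log = logging.getLogger(__name__)

WINDOW_SIZE = 6

BLOCK_BPC = "BPC"
BLOCK_AC = "AC"
BLOCK_ATOM = "ATOM"
ALL_BLOCKS = (BLOCK_BPC, BLOCK_AC, BLOCK_ATOM)

_STANDARD_SET = frozenset(STANDARD_RESIDUES)


class EncodingError(ValueError):
    """A window cannot be encoded under the given configuration."""


@dataclass(frozen=True)
class HexmerRecord:
    """A six-residue window, optionally labeled (1 = amyloidogenic)."""

    sequence: str
    label: int | None = None
    origin: tuple[str, int] | None = None  # (parent sequence id, 0-based start)

    def __post_init__(self) -> None:
        if len(self.sequence) != WINDOW_SIZE:
            raise ValueError(
                f"hexmer must have exactly {WINDOW_SIZE} residues, "
                f"got {self.sequence!r}"
            )
        bad = set(self.sequence) - _STANDARD_SET
        if bad:
            raise ValueError(f"non-standard residues {sorted(bad)} in {self.sequence!r}")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class EncodingConfig:
    """Which properties feed each feature block.

    ``ac_properties`` are the indices whose autocorrelation functions are
    computed (canonically the best 5 properties from pre-optimization);
    ``max_lag`` is the largest lag v (v = 1..max_lag, default 5, which must
    stay below the window size).  ``lag_normalized`` selects the
    1/(w-v)-scaled Moreau-Broto form; the raw-sum variant is kept as an
    alternative reading.  ``standardize_ac`` standardizes indices (mean 0,
    sd 1 over the 20 residues) before autocorrelation.
    """

    bpc_properties: tuple[str, ...] = ()
    ac_properties: tuple[str, ...] = ()
    max_lag: int = 5
    blocks: tuple[str, ...] = (BLOCK_BPC, BLOCK_AC, BLOCK_ATOM)
    lag_normalized: bool = True
    standardize_ac: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.max_lag < WINDOW_SIZE):
            raise ValueError(f"max_lag must be in [1, {WINDOW_SIZE - 1}]")
        unknown = set(self.blocks) - set(ALL_BLOCKS)
        if unknown:
            raise ValueError(f"unknown blocks {sorted(unknown)}")
        if not self.blocks:
            raise ValueError("at least one feature block required")

    @property
    def n_features(self) -> int:
        n = 0
        if BLOCK_BPC in self.blocks:
            n += len(self.bpc_properties)
        if BLOCK_AC in self.blocks:
            n += len(self.ac_properties) * self.max_lag
        if BLOCK_ATOM in self.blocks:
            n += 5
        return n

    def feature_names(self) -> list[str]:
        names: list[str] = []
        if BLOCK_BPC in self.blocks:
            names += [f"BPC:{a}" for a in self.bpc_properties]
        if BLOCK_AC in self.blocks:
            names += [
                f"AC:{a}:lag{v}"
                for a in self.ac_properties
                for v in range(1, self.max_lag + 1)
            ]
        if BLOCK_ATOM in self.blocks:
            names += [f"ATOM:{e}" for e in AtomTable.ELEMENTS]
        return names


def sliding_hexmers(
    sequence: str,
    regions: Sequence[tuple[int, int]] | None = None,
    seq_id: str = "",
    window: int = WINDOW_SIZE,
) -> list[HexmerRecord]:
    """Cut a sequence into all length-``window`` windows at step 1.

    A clean length-L sequence yields L - window + 1 records.  Windows
    containing any non-standard residue are skipped (and counted in the
    log).  When half-open positive ``regions`` [start, end) are given, a
    window is labeled 1 iff fully contained in some region, else 0;
    without regions labels are absent.
    """
    sequence = sequence.upper()
    out: list[HexmerRecord] = []
    skipped = 0
    for start in range(len(sequence) - window + 1):
        sub = sequence[start : start + window]
        if set(sub) - _STANDARD_SET:
            skipped += 1
            continue
        label: int | None = None
        if regions is not None:
            label = int(
                any(start >= s and start + window <= e for s, e in regions)
            )
        out.append(HexmerRecord(sub, label=label, origin=(seq_id, start)))
    if skipped:
        log.info(
            "sequence %s: skipped %d windows with non-standard residues",
            seq_id or "<anonymous>",
            skipped,
        )
    return out


def bpc_feature(hexmer: HexmerRecord | str, index: AminoAcidIndex) -> float:
    """Arithmetic mean of the raw index values over the six residues."""
    seq = hexmer.sequence if isinstance(hexmer, HexmerRecord) else hexmer
    try:
        vals = index.as_vector(seq)
    except KeyError as exc:
        raise EncodingError(str(exc)) from exc
    return float(sum(vals)) / len(vals)


def autocorrelation(
    hexmer: HexmerRecord | str,
    index: AminoAcidIndex,
    v: int,
    lag_normalized: bool = True,
) -> float:
    """Moreau-Broto autocorrelation F_v of an index within the window.

    F_v = (1/(w-v)) * sum_{i=1..w-v} p_i * p_{i+v}, with w the window size
    and p_i the per-position property values; pass ``lag_normalized=False``
    for the unnormalized sum.  The index is expected to be standardized
    upstream.
    """
    seq = hexmer.sequence if isinstance(hexmer, HexmerRecord) else hexmer
    w = len(seq)
    if not (1 <= v < w):
        raise ValueError(f"lag v must satisfy 1 <= v < {w}, got {v}")
    p = index.as_vector(seq)
    total = sum(p[i] * p[i + v] for i in range(w - v))
    return total / (w - v) if lag_normalized else total


def atomic_composition(
    hexmer: HexmerRecord | str, table: AtomTable | None = None
) -> tuple[int, int, int, int, int]:
    """Element-wise C/H/N/O/S totals over the window's residues."""
    seq = hexmer.sequence if isinstance(hexmer, HexmerRecord) else hexmer
    table = table if table is not None else atomic_table()
    sums = [0, 0, 0, 0, 0]
    for res in seq:
        for k, c in enumerate(table[res]):
            sums[k] += c
    return tuple(sums)  # type: ignore[return-value]


@dataclass
class NormalizationParams:
    """Per-feature min/max fitted on one matrix, mapped to a target range.

    The affine map v' = (v - min)/(max - min) * (new_max - new_min) + new_min
    is applied unchanged to any later matrix, so out-of-range values may
    leave [new_min, new_max].  Degenerate features (min == max) map to
    new_min.
    """

    feature_names: list[str]
    minima: dict[str, float]
    maxima: dict[str, float]
    new_min: float = 0.0
    new_max: float = 1.0

    def __post_init__(self) -> None:
        if self.new_min >= self.new_max:
            raise ValueError("new_min must be < new_max")

    @property
    def degenerate(self) -> list[str]:
        return [f for f in self.feature_names if self.minima[f] == self.maxima[f]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": self.feature_names,
                "minima": self.minima,
                "maxima": self.maxima,
                "new_min": self.new_min,
                "new_max": self.new_max,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "NormalizationParams":
        d = json.loads(text)
        return cls(
            feature_names=list(d["feature_names"]),
            minima=dict(d["minima"]),
            maxima=dict(d["maxima"]),
            new_min=float(d["new_min"]),
            new_max=float(d["new_max"]),
        )


def fit_minmax(
    matrix: pd.DataFrame, new_range: tuple[float, float] = (0.0, 1.0)
) -> NormalizationParams:
    """Record per-feature min/max from a (raw) feature matrix."""
    if matrix.empty:
        raise ValueError("cannot fit normalization on an empty matrix")
    params = NormalizationParams(
        feature_names=list(matrix.columns),
        minima={c: float(matrix[c].min()) for c in matrix.columns},
        maxima={c: float(matrix[c].max()) for c in matrix.columns},
        new_min=float(new_range[0]),
        new_max=float(new_range[1]),
    )
    for name in params.degenerate:
        log.warning("feature %s is constant on the fitting set", name)
    return params


def apply_minmax(matrix: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """Apply a fitted min-max map to a matrix (columns must be known)."""
    unknown = set(matrix.columns) - set(params.feature_names)
    if unknown:
        raise KeyError(f"features not covered by normalization params: {sorted(unknown)}")
    out = pd.DataFrame(index=matrix.index)
    span = params.new_max - params.new_min
    for c in matrix.columns:
        lo, hi = params.minima[c], params.maxima[c]
        if hi == lo:
            out[c] = params.new_min
        else:
            out[c] = (matrix[c] - lo) / (hi - lo) * span + params.new_min
    return out


def invert_minmax(matrix: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """Inverse of :func:`apply_minmax` for non-degenerate features."""
    out = pd.DataFrame(index=matrix.index)
    span = params.new_max - params.new_min
    for c in matrix.columns:
        lo, hi = params.minima[c], params.maxima[c]
        out[c] = (matrix[c] - params.new_min) / span * (hi - lo) + lo
    return out


def encode_dataset(
    hexmers: Iterable[HexmerRecord],
    indices: Mapping[str, AminoAcidIndex] | Sequence[AminoAcidIndex],
    config: EncodingConfig,
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Encode hexmers into a feature matrix with block order BPC, AC, ATOM.

    Returns the raw (unnormalized) matrix, indexed by hexmer sequence, and
    the label series (None when no record carries a label).
    """
    if not isinstance(indices, Mapping):
        indices = {ix.accession: ix for ix in indices}
    for acc in tuple(config.bpc_properties) + tuple(config.ac_properties):
        if acc not in indices:
            raise EncodingError(f"config references unknown index {acc!r}")

    ac_indices = {}
    if BLOCK_AC in config.blocks:
        for acc in config.ac_properties:
            ix = indices[acc]
            ac_indices[acc] = standardize_index(ix) if config.standardize_ac else ix
    table = atomic_table()

    records = list(hexmers)
    names = config.feature_names()
    data = np.empty((len(records), len(names)))
    labels: list[int | None] = []
    for r, hx in enumerate(records):
        col = 0
        if BLOCK_BPC in config.blocks:
            for acc in config.bpc_properties:
                data[r, col] = bpc_feature(hx, indices[acc])
                col += 1
        if BLOCK_AC in config.blocks:
            for acc in config.ac_properties:
                for v in range(1, config.max_lag + 1):
                    data[r, col] = autocorrelation(
                        hx, ac_indices[acc], v, config.lag_normalized
                    )
                    col += 1
        if BLOCK_ATOM in config.blocks:
            for count in atomic_composition(hx, table):
                data[r, col] = count
                col += 1
        labels.append(hx.label)

    matrix = pd.DataFrame(data, columns=names, index=[hx.sequence for hx in records])
    if all(l is None for l in labels):
        return matrix, None
    if any(l is None for l in labels):
        raise EncodingError("mixed labeled and unlabeled hexmers")
    return matrix, pd.Series(labels, index=matrix.index, name="label", dtype=int)


class HexmerEncoder(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: hexmer strings -> normalized feature rows.

    Parameters mirror :class:`EncodingConfig`; ``fit`` learns the min-max
    normalization on the training windows only, ``transform`` encodes and
    applies the stored map (so validation/test reuse training parameters).
    """

    def __init__(
        self,
        indices: Mapping[str, AminoAcidIndex] | Sequence[AminoAcidIndex] = (),
        bpc_properties: tuple[str, ...] = (),
        ac_properties: tuple[str, ...] = (),
        max_lag: int = 5,
        blocks: tuple[str, ...] = ALL_BLOCKS,
        lag_normalized: bool = True,
        standardize_ac: bool = True,
        feature_range: tuple[float, float] = (0.0, 1.0),
    ):
        self.indices = indices
        self.bpc_properties = bpc_properties
        self.ac_properties = ac_properties
        self.max_lag = max_lag
        self.blocks = blocks
        self.lag_normalized = lag_normalized
        self.standardize_ac = standardize_ac
        self.feature_range = feature_range

    def _config(self) -> EncodingConfig:
        return EncodingConfig(
            bpc_properties=tuple(self.bpc_properties),
            ac_properties=tuple(self.ac_properties),
            max_lag=self.max_lag,
            blocks=tuple(self.blocks),
            lag_normalized=self.lag_normalized,
            standardize_ac=self.standardize_ac,
        )

    @staticmethod
    def _as_records(X: Iterable[HexmerRecord | str]) -> list[HexmerRecord]:
        return [x if isinstance(x, HexmerRecord) else HexmerRecord(x) for x in X]

    def fit(self, X: Iterable[HexmerRecord | str], y=None) -> "HexmerEncoder":
        raw, _ = encode_dataset(self._as_records(X), self.indices, self._config())
        self.feature_names_ = list(raw.columns)
        self.normalization_ = fit_minmax(raw, self.feature_range)
        return self

    def transform(self, X: Iterable[HexmerRecord | str]) -> pd.DataFrame:
        raw, _ = encode_dataset(self._as_records(X), self.indices, self._config())
        return apply_minmax(raw, self.normalization_)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
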