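"""Synthetic datasets with the statistical structure the pipeline assumes.

Real curated hexmer datasets are built from experimentally assayed fibril
fragments; here labeled hexmers are drawn i.i.d. per position from
class-specific residue-frequency profiles.  The positive profile is
enriched in beta/aggregation-prone residues (V, I, F, Y, L, T) and the
negative in aggregation-breaking ones (P, G, D, E, K, R), a modeling
choice borrowed from the amyloid literature; an ``effect`` knob
interpolates both profiles toward uniform, so effect 0 makes the classes
statistically identical and effect 1 gives disjoint residue alphabets.

Also provided: synthetic amino-acid indices (standard-normal per-residue
values) standing in for property databases, and planted-signal Gaussian
feature matrices for exercising the feature-selection stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aaindex import STANDARD_RESIDUES, AminoAcidIndex
from .encoding import HexmerRecord, WINDOW_SIZE

_BETA_PRONE = "VIFYLT"
_BREAKERS = "PGDEKR"


def _profile(enriched: str) -> dict[str, float]:
    return {r: (1.0 / len(enriched) if r in enriched else 0.0) for r in STANDARD_RESIDUES}


#: Full-effect per-residue frequency profiles (disjoint supports).
POSITIVE_PROFILE = _profile(_BETA_PRONE)
NEGATIVE_PROFILE = _profile(_BREAKERS)


@dataclass(frozen=True)
class SimConfig:
    """Labeled-hexmer simulation: sizes mirror a curated hexmer corpus scale."""

    n_pos: int = 1232
    n_neg: int = 1280
    effect: float = 1.0
    positive_profile: dict[str, float] = field(
        default_factory=lambda: dict(POSITIVE_PROFILE)
    )
    negative_profile: dict[str, float] = field(
        default_factory=lambda: dict(NEGATIVE_PROFILE)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("need at least one sample per class")
        if not (0.0 <= self.effect <= 1.0):
            raise ValueError("effect must lie in [0, 1]")
        for prof in (self.positive_profile, self.negative_profile):
            if set(prof) != set(STANDARD_RESIDUES):
                raise ValueError("profiles must cover the 20 standard residues")
            if abs(sum(prof.values()) - 1.0) > 1e-9 or min(prof.values()) < 0:
                raise ValueError("profiles must be valid distributions")


@dataclass(frozen=True)
class PlantedDesign:
    """Gaussian feature matrix with class signal in a planted column subset."""

    pool_size: int = 60
    planted: tuple[str, ...] = ()
    shift: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shift < 0 or self.noise_sd <= 0:
            raise ValueError("shift must be >= 0 and noise_sd > 0")
        pool = set(self.pool_names())
        if not set(self.planted) <= pool:
            raise ValueError("planted columns must belong to the pool")

    def pool_names(self) -> list[str]:
        return [f"SYN{i + 1:04d}" for i in range(self.pool_size)]


def _interpolated(profile: dict[str, float], effect: float) -> np.ndarray:
    uniform = 1.0 / len(STANDARD_RESIDUES)
    probs = np.array(
        [uniform + effect * (profile[r] - uniform) for r in STANDARD_RESIDUES]
    )
    return probs / probs.sum()


def generate_hexmers(config: SimConfig) -> list[HexmerRecord]:
    """Draw labeled hexmers i.i.d. per position from class profiles."""
    rng = np.random.default_rng(config.seed)
    residues = np.array(list(STANDARD_RESIDUES))
    out: list[HexmerRecord] = []
    for label, n, prof in (
        (1, config.n_pos, config.positive_profile),
        (0, config.n_neg, config.negative_profile),
    ):
        probs = _interpolated(prof, config.effect)
        draws = rng.choice(len(residues), size=(n, WINDOW_SIZE), p=probs)
        for row in draws:
            out.append(HexmerRecord("".join(residues[row]), label=label))
    return out


def generate_indices(n: int, seed: int = 0) -> list[AminoAcidIndex]:
    """Synthetic amino-acid indices: standard-normal per-residue values.

    Accessions are SYN0001... and an index is redrawn if its spread over
    the 20 residues falls below 0.3, so no near-constant index is emitted.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        while True:
            vals = rng.normal(size=len(STANDARD_RESIDUES))
            if vals.std() >= 0.3:
                break
        out.append(
            AminoAcidIndex(
                accession=f"SYN{i + 1:04d}",
                description=f"synthetic property {i + 1}",
                values=dict(zip(STANDARD_RESIDUES, map(float, vals))),
            )
        )
    return out


def generate_planted_matrix(
    design: PlantedDesign, n_per_class: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature matrix whose planted columns shift by +-shift/2 with class.

    Non-planted columns are class-independent noise; labels come back as
    a 0/1 array (positives first).
    """
    rng = np.random.default_rng(design.seed)
    names = design.pool_names()
    planted = set(design.planted)
    n = 2 * n_per_class
    labels = np.array([1] * n_per_class + [0] * n_per_class)
    sign = np.where(labels == 1, 1.0, -1.0)
    data = rng.normal(scale=design.noise_sd, size=(n, len(names)))
    for j, name in enumerate(names):
        if name in planted:
            data[:, j] += sign * design.shift / 2.0
    return pd.DataFrame(data, columns=names), labels
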