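"""End-to-end experiment drivers: simulate -> encode -> select -> train -> evaluate.

These functions wire the stages together the way a user of the CLI would,
with one seed controlling every random choice, and are what the
reproducibility script runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ann_models import build_pm, split_data, train_ann
from .encoding import EncodingConfig, apply_minmax, encode_dataset, fit_minmax
from .evaluation import EvaluationReport, evaluate
from .feature_selection import MAConfig, embedded_preselect, run_memetic
from .synthetic_data import (
    PlantedDesign,
    SimConfig,
    generate_hexmers,
    generate_indices,
    generate_planted_matrix,
)


@dataclass
class EndToEndResult:
    report: EvaluationReport
    n_train: int
    n_test: int
    selected_bpc: list[str]
    ac_properties: list[str]


def run_end_to_end(
    effect: float = 1.0,
    n_pos: int = 1232,
    n_neg: int = 1280,
    n_indices: int = 60,
    n_bpc: int = 40,
    n_ac: int = 5,
    seed: int = 0,
) -> EndToEndResult:
    """Synthetic data through the PM3-style pipeline; held-out evaluation.

    Simulates labeled hexmers and a synthetic index collection, encodes
    all candidate per-property means, pre-selects ``n_bpc`` properties
    with the embedded linear SVM (top ``n_ac`` feed the autocorrelation
    block), re-encodes BPC + AC features, splits 60/20/20, trains the
    sigmoid network, and evaluates on the untouched test partition.
    """
    hexmers = generate_hexmers(SimConfig(n_pos=n_pos, n_neg=n_neg,
                                         effect=effect, seed=seed))
    indices = {ix.accession: ix for ix in generate_indices(n_indices, seed=seed)}
    accs = tuple(sorted(indices))

    # candidate matrix: one mean feature per property, for pre-selection.
    # Selection and normalization both see the training partition only,
    # so the held-out estimate carries no selection bias.
    cand_cfg = EncodingConfig(bpc_properties=accs, blocks=("BPC",))
    cand, labels = encode_dataset(hexmers, indices, cand_cfg)
    cand.columns = [c.removeprefix("BPC:") for c in cand.columns]
    (Ct, yt0), _, _ = split_data(cand, labels.to_numpy(), seed=seed)
    cand_norm = apply_minmax(Ct, fit_minmax(Ct))
    selected = embedded_preselect(cand_norm, yt0, k=n_bpc)
    ac_props = selected[:n_ac]

    config = EncodingConfig(
        bpc_properties=tuple(sorted(selected)),
        ac_properties=tuple(ac_props),
        blocks=("BPC", "AC"),
    )
    matrix, labels = encode_dataset(hexmers, indices, config)
    # same labels and seed -> identical partition as the selection split
    (Xt, yt), (Xv, yv), (Xs, ys) = split_data(matrix, labels.to_numpy(), seed=seed)
    params = fit_minmax(Xt)
    pm = build_pm("PM3", selected_bpc=config.bpc_properties,
                  ac_accessions=config.ac_properties, seed=seed)
    model = train_ann((apply_minmax(Xt, params), yt),
                      (apply_minmax(Xv, params), yv), pm)
    scores = model.predict_scores(apply_minmax(Xs, params))
    return EndToEndResult(
        report=evaluate(ys, scores),
        n_train=len(Xt),
        n_test=len(Xs),
        selected_bpc=selected,
        ac_properties=list(ac_props),
    )


@dataclass
class RecoveryResult:
    overlaps: list[int]
    n_planted: int
    subset_size: int
    fraction_recovered: float  # seeds with >= 8/10 planted
    permutation_p: float


def run_recovery_experiment(
    n_seeds: int = 5,
    pool_size: int = 60,
    n_planted: int = 10,
    subset_size: int = 10,
    shift: float = 1.0,
    n_per_class: int = 250,
    pop_size: int = 10,
    generations: int = 30,
    base_seed: int = 0,
    recovery_threshold: int = 8,
) -> RecoveryResult:
    """Planted-signal selection recovery over several seeds.

    The shift is deliberately moderate (per-feature d' = 1) so the SVM-CV
    fitness stays below its ceiling and subset improvements remain
    visible to selection.  The permutation p-value compares the mean
    planted-feature overlap of the selected subsets against the null of
    uniformly random subsets of the same size.
    """
    planted = tuple(f"SYN{i + 1:04d}" for i in range(n_planted))
    overlaps = []
    for i in range(n_seeds):
        design = PlantedDesign(pool_size=pool_size, planted=planted,
                               shift=shift, noise_sd=1.0,
                               seed=base_seed * 1009 + 100 + i)
        X, y = generate_planted_matrix(design, n_per_class)
        config = MAConfig(pool=tuple(X.columns), pop_size=pop_size,
                          subset_size=subset_size, generations=generations,
                          seed=base_seed * 131 + i, patience=generations)
        best, _ = run_memetic(X, y, config)
        overlaps.append(len(set(best.subset) & set(planted)))

    rng = np.random.default_rng(base_seed + 12345)
    observed = float(np.mean(overlaps))
    null = np.array([
        np.mean([
            len(set(rng.choice(pool_size, subset_size, replace=False))
                & set(range(n_planted)))
            for _ in range(n_seeds)
        ])
        for _ in range(10_000)
    ])
    p = float((np.sum(null >= observed) + 1) / (len(null) + 1))
    return RecoveryResult(
        overlaps=overlaps,
        n_planted=n_planted,
        subset_size=subset_size,
        fraction_recovered=float(np.mean([o >= recovery_threshold for o in overlaps])),
        permutation_p=p,
    )
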