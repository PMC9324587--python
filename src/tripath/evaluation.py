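"""Cross-validated evaluation: repeated five-fold CV, global LOOCV, sweeps.

The protocol masks known miRNA-disease positives, re-runs the full predictor
on the masked network, and asks whether the held-out positives outrank the
pairs that were never known to be associated. AUC is the rank statistic
(Mann-Whitney form; ties count one half).

Five-fold CV partitions the positives into five folds; each fold is zeroed
in turn and the predictor re-run. One AUC is computed per repeat by pooling
across folds: every held-out positive contributes its score from the fold
where it was hidden, and every never-positive pair contributes its score
from every fold run. Positives held out in *other* folds are thereby never
counted as negatives. Global LOOCV hides one positive at a time and reports
the mean of the per-leave-out AUCs (each a single positive ranked against
all never-positive pairs of that run).
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .matrices import AssociationMatrix, PathParams
from .path_scoring import predict

__all__ = ["CVResult", "auc_from_scores", "five_fold_cv", "global_loocv", "parameter_sweep"]


@dataclass(frozen=True)
class CVResult:
    """Per-repeat AUCs of a repeated cross-validation run."""

    auc_per_repeat: tuple[float, ...]
    params: PathParams
    n_folds: int
    n_repeats: int
    seed: int
    mean_auc: float = field(init=False)

    def __post_init__(self) -> None:
        if not all(0.0 <= a <= 1.0 for a in self.auc_per_repeat):
            raise ValueError("every AUC must lie in [0, 1]")
        object.__setattr__(self, "mean_auc", float(np.mean(self.auc_per_repeat)))


def auc_from_scores(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Rank-based AUC of positives vs negatives; ties contribute one half."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    return float(roc_auc_score(labels, np.concatenate([pos, neg])))


def _masked_copy(A1: AssociationMatrix, pairs: np.ndarray) -> AssociationMatrix:
    v = A1.values.copy()
    v[pairs[:, 0], pairs[:, 1]] = 0.0
    return AssociationMatrix(v, A1.row_index, A1.col_index, stage="raw")


def five_fold_cv(
    bundle,
    params: PathParams | None = None,
    *,
    n_repeats: int = 100,
    n_folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Repeated five-fold cross-validation over the known positives.

    *bundle* is anything exposing raw ``S1, S2, S3, A1, A2, A3`` attributes
    (a :class:`~tripath.synthetic.SyntheticBundle` qualifies). Caller-owned
    inputs are never mutated; each fold works on a masked copy of A1.
    """
    params = params or PathParams()
    positives = np.argwhere(bundle.A1.values > 0)
    if len(positives) < n_folds:
        raise ValueError(f"need at least {n_folds} positives, found {len(positives)}")
    never_pos = bundle.A1.values == 0

    aucs = []
    for rep in range(n_repeats):
        rng = np.random.default_rng([seed, rep])  # deterministic per-repeat sub-seed
        order = rng.permutation(len(positives))
        folds = np.array_split(order, n_folds)
        pos_scores: list[float] = []
        neg_scores: list[np.ndarray] = []
        for fold in folds:
            held = positives[fold]
            score = predict(
                bundle.S1, bundle.S2, bundle.S3,
                _masked_copy(bundle.A1, held), bundle.A2, bundle.A3,
                params,
            ).values
            pos_scores.extend(score[held[:, 0], held[:, 1]])
            neg_scores.append(score[never_pos])
        aucs.append(auc_from_scores(pos_scores, np.concatenate(neg_scores)))
    return CVResult(tuple(aucs), params, n_folds, n_repeats, seed)


def global_loocv(bundle, params: PathParams | None = None) -> float:
    """Global leave-one-out: each positive hidden in turn, ranked against all unknowns."""
    params = params or PathParams()
    positives = np.argwhere(bundle.A1.values > 0)
    if len(positives) < 2:
        raise ValueError("need at least 2 positives for leave-one-out")
    never_pos = bundle.A1.values == 0
    aucs = []
    for pair in positives:
        score = predict(
            bundle.S1, bundle.S2, bundle.S3,
            _masked_copy(bundle.A1, pair[None, :]), bundle.A2, bundle.A3,
            params,
        ).values
        aucs.append(auc_from_scores([score[pair[0], pair[1]]], score[never_pos]))
    return float(np.mean(aucs))


def parameter_sweep(
    bundle,
    T_values: Sequence[float],
    beta_values: Sequence[float],
    *,
    n_repeats: int = 5,
    seed: int = 0,
    n_folds: int = 5,
    base_params: PathParams | None = None,
) -> pd.DataFrame:
    """Grid-evaluate (T, beta) by five-fold CV; returns a (T, beta, mean_auc) table."""
    if len(T_values) == 0 or len(beta_values) == 0:
        raise ValueError("parameter grids must be non-empty")
    base = base_params or PathParams()
    rows = []
    for T in T_values:
        for beta in beta_values:
            params = PathParams(
                T=T, L=base.L, beta=beta, phi=base.phi,
                rescale_mediated=base.rescale_mediated,
            )
            result = five_fold_cv(
                bundle, params, n_repeats=n_repeats, n_folds=n_folds, seed=seed
            )
            rows.append((T, beta, result.mean_auc))
    return pd.DataFrame(rows, columns=["T", "beta", "mean_auc"])
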