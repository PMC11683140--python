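"""Repeated k-fold cross-validation of genomic predictive ability.

Predictive ability is the Pearson correlation between the genomic
predictions (GEBV or GETGV) and the stage-one BLUPs of the validation
clones, r = cor(yhat_val, y_val), estimated under 5-fold cross-validation
with five repetitions by default.  Relationship matrices are built once on
the full clone set (genotypes are available before phenotyping in a genomic
selection program); only validation *phenotypes* are masked from each
training fit, so there is no response leakage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["FoldPlan", "CVResult", "make_folds", "cross_validate"]


@dataclass
class FoldPlan:
    """Random fold assignments: one partition of the clones per repeat."""

    n_clones: int
    k: int
    repeats: int
    assignments: np.ndarray  # (repeats, n_clones) of fold indices
    seed: int

    def folds(self, repeat: int):
        """Yield (fold_index, boolean validation mask) for one repeat."""
        a = self.assignments[repeat]
        for f in range(self.k):
            yield f, a == f

    def to_frame(self, clone_ids=None) -> pd.DataFrame:
        ids = clone_ids if clone_ids is not None else np.arange(self.n_clones)
        rows = [(r, str(ids[i]), int(self.assignments[r, i]))
                for r in range(self.repeats) for i in range(self.n_clones)]
        return pd.DataFrame(rows, columns=["repeat", "clone", "fold"])


def make_folds(n: int, k: int = 5, repeats: int = 5, seed: int = 0) -> FoldPlan:
    """Random balanced partitions: fold sizes differ by at most one."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"cannot split {n} clones into {k} folds")
    rng = np.random.default_rng(seed)
    assignments = np.empty((repeats, n), dtype=int)
    base = np.repeat(np.arange(k), np.diff(np.linspace(0, n, k + 1).astype(int)))
    for r in range(repeats):
        assignments[r] = base[rng.permutation(n)]
    return FoldPlan(n, k, repeats, assignments, seed)


@dataclass
class CVResult:
    """Cross-validated predictive ability for one trait x method."""

    trait: str
    method: str
    per_fold: pd.DataFrame  # columns: repeat, fold, ability
    fold_plan_ref: str = ""

    @property
    def per_fold_ability(self) -> list[float]:
        return self.per_fold["ability"].tolist()

    @property
    def mean_ability(self) -> float:
        return float(self.per_fold["ability"].mean())

    @property
    def sd_ability(self) -> float:
        return float(self.per_fold["ability"].std(ddof=1))

    def summary(self) -> str:
        n_missing = int(self.per_fold["ability"].isna().sum())
        return (f"CV ability — trait '{self.trait}', method '{self.method}': "
                f"mean {self.mean_ability:.4f} (sd {self.sd_ability:.4f}) over "
                f"{len(self.per_fold)} folds ({n_missing} undefined)")


def cross_validate(y: pd.Series, fit_fn, plan: FoldPlan, value: str = "getgv",
                   trait: str = "", method: str = "") -> CVResult:
    """Run repeated k-fold CV of one predictor.

    Parameters
    ----------
    y : Series
        Response (stage-one BLUPs) indexed by clone; must cover the plan.
    fit_fn : callable
        Maps a training subset of ``y`` to a fitted ``PredictionResults``
        whose ``gebv``/``getgv`` cover all clones (see
        :func:`cassgs.predictors.make_predictor`).
    plan : FoldPlan
        Fold assignments over the clones of ``y`` (in index order).
    value : str
        Which prediction to correlate: ``'gebv'`` or ``'getgv'``.
    """
    if plan.n_clones != y.size:
        raise ValueError("fold plan does not cover the clones of y")
    if value not in ("gebv", "getgv"):
        raise ValueError("value must be 'gebv' or 'getgv'")
    clones = np.asarray(y.index)
    rows = []
    for r in range(plan.repeats):
        for f, val_mask in plan.folds(r):
            y_train = y.loc[clones[~val_mask]]
            res = fit_fn(y_train)
            preds = getattr(res, value)
            yhat_val = preds.loc[clones[val_mask]].to_numpy(dtype=float)
            y_val = y.loc[clones[val_mask]].to_numpy(dtype=float)
            if np.std(y_val) == 0.0 or np.std(yhat_val) == 0.0:
                warnings.warn(f"repeat {r} fold {f}: zero variance, "
                              "ability undefined", UserWarning)
                ability = np.nan
            else:
                ability = float(np.corrcoef(yhat_val, y_val)[0, 1])
            rows.append((r, f, ability))
    per_fold = pd.DataFrame(rows, columns=["repeat", "fold", "ability"])
    n_missing = int(per_fold["ability"].isna().sum())
    if n_missing:
        logger.info("%d of %d folds had undefined ability and are excluded "
                    "from the mean", n_missing, len(per_fold))
    return CVResult(trait=trait, method=method, per_fold=per_fold,
                    fold_plan_ref=f"seed={plan.seed},k={plan.k},repeats={plan.repeats}")
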