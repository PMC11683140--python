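"""Stage-one multi-environment analysis: REML variance components and BLUPs.

For each trait the model

    y = mu + block(env) [fixed] + env + row + col + clone + clone:env + e

is fitted by AI-REML, with environment, row, column, genotype and
genotype-by-environment as independent random terms.  Per-clone BLUPs from
this fit are the response passed to the genomic prediction models.  Two
heritabilities are reported for each trait:

* broad-sense  H^2 = s2_g / (s2_g + s2_r), from the phenotypic fit;
* SNP-based    h^2 = s2_A / (s2_A + s2_R), from regressing the BLUPs on the
  additive genomic relationship matrix G.

Row and column effects are nested within environment by default (field
coordinates only mean something inside one trial); ``nested_rowcol=False``
restores the fully crossed coding.

A structural caveat: with block-within-environment fixed, the environment
main effect is linearly confounded with the fixed part (each environment
indicator is the sum of its block dummies), so the restricted likelihood is
flat in the environment variance and its reported estimate is arbitrary.
All other components, the BLUPs, and both heritabilities are unaffected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cassgs.markers import RelationshipMatrix, PSD_RIDGE
from cassgs.reml import MixedModel, MixedModelResults, RandomEffect

logger = logging.getLogger(__name__)

__all__ = ["StageOneModel", "StageOneResults", "fit_stage_one",
           "variance_proportions", "broad_sense_h2", "snp_h2"]

REQUIRED_COLUMNS = ("clone", "env", "block", "row", "col", "trait", "value")
COMPONENTS = ("genotype", "environment", "gxe", "row", "column", "residual")


def _indicator(codes: pd.Series) -> tuple[np.ndarray, list]:
    """Dense 0/1 incidence matrix and level labels for one factor."""
    cats = pd.Categorical(codes)
    Z = np.zeros((len(codes), len(cats.categories)))
    Z[np.arange(len(codes)), cats.codes] = 1.0
    return Z, list(cats.categories)


@dataclass
class StageOneResults:
    """REML fit of the multi-environment model for one trait."""

    trait: str
    variance_components: dict[str, float]
    blups: pd.Series            # per-clone genotype effect predictions
    fitted_values: np.ndarray
    residuals: np.ndarray
    loglik: float
    converged: bool
    n_iterations: int
    n_obs: int
    single_environment: bool = False
    _reml: MixedModelResults | None = None

    def variance_proportions(self) -> dict[str, float]:
        return variance_proportions(self)

    def broad_sense_h2(self) -> float:
        return broad_sense_h2(self)

    def summary(self) -> str:
        lines = [f"Stage-one REML fit — trait '{self.trait}'", "-" * 48,
                 f"n obs: {self.n_obs}   n clones: {self.blups.size}   "
                 f"converged: {self.converged} ({self.n_iterations} iterations)"]
        props = self.variance_proportions()
        lines.append(f"{'component':<12s}{'variance':>12s}{'% of total':>12s}")
        for name in COMPONENTS:
            if name in self.variance_components:
                lines.append(f"{name:<12s}{self.variance_components[name]:>12.5g}"
                             f"{props.get(name, 0.0):>12.2f}")
        lines.append(f"Broad-sense H2: {self.broad_sense_h2():.4f}")
        return "\n".join(lines)

    def blup_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"clone": self.blups.index, "trait": self.trait,
                             "blup": self.blups.values})


class StageOneModel:
    """Multi-environment mixed model for one trait of a TrialTable.

    Parameters
    ----------
    data : DataFrame
        Long-format plot records with columns
        ``clone, env, block, row, col, trait, value``.
    trait : str
        Trait to analyse.
    nested_rowcol : bool
        Treat row/column effects as nested within environment (default).
    outlier_filter : bool
        If True, drop records with |standardized residual| > 4 after a first
        fit and refit once.
    """

    def __init__(self, data: pd.DataFrame, trait: str, nested_rowcol: bool = True,
                 outlier_filter: bool = False):
        missing = set(REQUIRED_COLUMNS) - set(data.columns)
        if missing:
            raise ValueError(f"TrialTable missing columns: {sorted(missing)}")
        sub = data.loc[data["trait"] == trait].copy()
        if sub.empty:
            raise ValueError(f"trait '{trait}' not present in the data")
        dup = sub.duplicated(subset=["clone", "env", "block", "trait"])
        if dup.any():
            raise ValueError("duplicate (clone, env, block, trait) records")
        if sub["clone"].nunique() < 2:
            raise ValueError("at least two clones are required")
        self.data = sub.reset_index(drop=True)
        self.trait = trait
        self.nested_rowcol = nested_rowcol
        self.outlier_filter = outlier_filter

    @classmethod
    def from_csv(cls, path, trait: str, **kw) -> "StageOneModel":
        return cls(pd.read_csv(path), trait, **kw)

    def _design(self, sub: pd.DataFrame):
        n = len(sub)
        single_env = sub["env"].nunique() == 1
        # fixed: intercept + block-within-environment (first level dropped)
        be = sub["env"].astype(str) + ":" + sub["block"].astype(str)
        Zbe, be_levels = _indicator(be)
        X = np.hstack([np.ones((n, 1)), Zbe[:, 1:]])

        effects = []
        if single_env:
            warnings.warn("single environment: dropping environment and GxE terms",
                          UserWarning)
        else:
            Ze, lev = _indicator(sub["env"])
            effects.append(RandomEffect("environment", Ze, levels=lev))
        if self.nested_rowcol:
            rows = sub["env"].astype(str) + ":" + sub["row"].astype(str)
            cols = sub["env"].astype(str) + ":" + sub["col"].astype(str)
        else:
            rows, cols = sub["row"], sub["col"]
        Zr, lev_r = _indicator(rows)
        effects.append(RandomEffect("row", Zr, levels=lev_r))
        Zc, lev_c = _indicator(cols)
        effects.append(RandomEffect("column", Zc, levels=lev_c))
        Zg, lev_g = _indicator(sub["clone"])
        effects.append(RandomEffect("genotype", Zg, levels=lev_g))
        if not single_env:
            ge = sub["clone"].astype(str) + ":" + sub["env"].astype(str)
            Zge, lev_ge = _indicator(ge)
            effects.append(RandomEffect("gxe", Zge, levels=lev_ge))
        return X, effects, single_env

    def _fit_once(self, sub: pd.DataFrame, **fit_kw):
        X, effects, single_env = self._design(sub)
        mm = MixedModel(sub["value"].to_numpy(), X, effects)
        return mm.fit(**fit_kw), single_env

    def fit(self, max_iter: int = 200, tol: float = 1e-8) -> StageOneResults:
        sub = self.data
        res, single_env = self._fit_once(sub, max_iter=max_iter, tol=tol)
        if self.outlier_filter:
            sr = res.residuals / (np.std(res.residuals) or 1.0)
            keep = np.abs(sr) <= 4.0
            if not keep.all():
                logger.info("outlier filter removed %d records", int((~keep).sum()))
                sub = sub.loc[keep].reset_index(drop=True)
                res, single_env = self._fit_once(sub, max_iter=max_iter, tol=tol)

        vc = {k: res.variance_components.get(k, 0.0)
              for k in COMPONENTS if single_env is False or k not in ("environment", "gxe")}
        vc["residual"] = res.variance_components["residual"]
        blups = pd.Series(res.random_effects["genotype"],
                          index=pd.Index(res.effect_levels["genotype"], name="clone"),
                          name=self.trait)
        return StageOneResults(
            trait=self.trait, variance_components=vc, blups=blups,
            fitted_values=res.fitted_values, residuals=res.residuals,
            loglik=res.loglik, converged=res.converged,
            n_iterations=res.n_iterations, n_obs=res.n_obs,
            single_environment=single_env, _reml=res)


def fit_stage_one(data: pd.DataFrame, trait: str, **kw) -> StageOneResults:
    """Fit the multi-environment mixed model for one trait by REML."""
    return StageOneModel(data, trait, **kw).fit()


def variance_proportions(fit: StageOneResults) -> dict[str, float]:
    """Each variance component as a percentage of their sum (sums to 100)."""
    total = sum(fit.variance_components.values())
    if total <= 0:
        raise ValueError("all variance components are zero")
    return {k: 100.0 * v / total for k, v in fit.variance_components.items()}


def broad_sense_h2(fit: StageOneResults) -> float:
    """H^2 = s2_g / (s2_g + s2_r) on the plot scale."""
    sg = fit.variance_components["genotype"]
    sr = fit.variance_components["residual"]
    if sg + sr == 0:
        raise ValueError("genotype and residual variances are both zero")
    return sg / (sg + sr)


def snp_h2(blups: pd.Series, g: RelationshipMatrix) -> float:
    """SNP-based heritability from regressing clone BLUPs on the additive GRM.

    Fits y = 1 mu + a + eps with a ~ N(0, G s2_A) by REML and returns
    s2_A / (s2_A + s2_R).
    """
    if g.kind != "additive":
        raise ValueError("snp_h2 requires an additive relationship matrix")
    common = [c for c in g.clone_ids if c in set(blups.index)]
    if len(common) < 3:
        raise ValueError("fewer than 3 clones shared between BLUPs and G")
    gsub = g.subset(common) if len(common) != g.n_clones else g
    y = blups.loc[common].to_numpy(dtype=float)
    n = len(common)
    eff = RandomEffect("additive", np.eye(n), K=gsub.stabilized(), levels=common)
    res = MixedModel(y, np.ones((n, 1)), [eff]).fit()
    sa = res.variance_components["additive"]
    sr = res.variance_components["residual"]
    if sa + sr == 0:
        raise ValueError("degenerate fit: zero total variance")
    return sa / (sa + sr)
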