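"""Genomic prediction engines.

Six methods produce per-clone predictions from stage-one BLUPs:

* RR-BLUP — ridge regression on centered marker dosages, variance components
  by REML; equivalent to additive G-BLUP when G uses the same centering.
* G-BLUP — clone effects with covariance G (additive) and optionally D
  (dominance); GEBV is the additive prediction, GETGV adds dominance.
* RKHS — the same single-kernel solver with a Gaussian kernel K in place
  of G.
* BayesA / BayesB — Gibbs-sampled marker effects with per-marker variances
  (scaled inverse chi-square priors); BayesB adds a point mass at zero with
  Beta-distributed inclusion probability.
* Random Forest — bagged regression trees on raw dosages (RSS splitting);
  training-clone predictions are out-of-bag to avoid trivial overfit.

Every engine accepts phenotypes for a subset of the clones in the marker /
relationship containers and returns predictions for *all* clones, so
cross-validation can mask validation phenotypes while matrices stay fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cassgs import _bayes
from cassgs.markers import MarkerMatrix, RelationshipMatrix, PSD_RIDGE
from cassgs.reml import MixedModel, RandomEffect

__all__ = ["PredictorSpec", "PredictionResults", "RRBLUP", "GBLUP", "RKHS",
           "BayesMarkerModel", "RandomForestGP", "fit_rrblup", "fit_gblup",
           "fit_rkhs", "fit_bayes", "fit_random_forest", "make_predictor",
           "SUPPORTED_METHODS"]

SUPPORTED_METHODS = ("rrblup", "gblup_a", "gblup_ad", "rkhs",
                     "bayes_a", "bayes_b", "random_forest")


@dataclass
class PredictorSpec:
    """Method name plus hyperparameters and seed."""

    method: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.method not in SUPPORTED_METHODS:
            raise ValueError(f"unknown method '{self.method}'")
        hp = self.hyperparams
        if "n_iter" in hp and "burn_in" in hp and hp["n_iter"] <= hp["burn_in"]:
            raise ValueError("n_iter must exceed burn_in")


@dataclass
class PredictionResults:
    """Fitted genomic prediction model: GEBVs, GETGVs and diagnostics."""

    method: str
    mu: float
    gebv: pd.Series
    getgv: pd.Series
    marker_effects: pd.Series | None = None
    dominance_effects: pd.Series | None = None
    variance_estimates: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"Genomic prediction — method '{self.method}'", "-" * 44,
                 f"n clones: {self.gebv.size}   mu: {self.mu:.5g}"]
        if self.variance_estimates:
            lines.append("Variance estimates:")
            for k, v in self.variance_estimates.items():
                lines.append(f"  {k:<12s} {v:.6g}")
        lines.append(f"GEBV sd: {self.gebv.std():.5g}   GETGV sd: {self.getgv.std():.5g}")
        for k, v in self.diagnostics.items():
            if np.isscalar(v):
                lines.append(f"  {k}: {v}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        pd.DataFrame({"clone": self.gebv.index, "gebv": self.gebv.values,
                      "getgv": self.getgv.values}).to_csv(path, index=False)


def _align(y: pd.Series, clone_ids: list) -> tuple[np.ndarray, np.ndarray]:
    """Observation indices into clone_ids (container order) and y values."""
    yset = set(y.index)
    unknown = yset - set(clone_ids)
    if unknown:
        raise ValueError(f"phenotyped clones absent from genotypes: {sorted(unknown)[:5]}")
    obs = np.array([i for i, c in enumerate(clone_ids) if c in yset])
    vals = y.loc[[clone_ids[i] for i in obs]].to_numpy(dtype=float)
    return obs, vals


def _as_series(y) -> pd.Series:
    if isinstance(y, pd.Series):
        return y
    return pd.Series(y)


class RRBLUP:
    """Ridge-regression BLUP of marker effects: y = 1 mu + M u + eps."""

    def __init__(self, y, markers: MarkerMatrix):
        if markers.n_markers < 1:
            raise ValueError("at least one marker is required")
        self.markers = markers
        self.y = _as_series(y)

    def fit(self) -> PredictionResults:
        m = self.markers
        Z_all = m.centered()
        obs, yv = _align(self.y, m.clone_ids)
        Z = Z_all[obs]
        n = obs.size
        # variance components on the equivalent n x n kernel Z Z' (same REML
        # problem as the marker-level parameterization, far better conditioned),
        # then marker effects from the ridge identity u = s2u Z' Vinv (y - mu)
        # the eigen-path solver stabilizes PSD kernels by eigenvalue clipping,
        # so Z Z' enters unridged and the VanRaden G-BLUP identity is exact
        Kzz = Z @ Z.T
        eff = RandomEffect("polygenic", np.eye(n), K=Kzz)
        res = MixedModel(yv, np.ones((n, 1)), [eff]).fit(tol=1e-10)
        s2u = res.variance_components["polygenic"]
        s2e = res.variance_components["residual"]
        if s2u + s2e > 0.0:
            V = s2u * Kzz + s2e * np.eye(n)
            r = yv - res.beta[0]
            u = s2u * (Z.T @ np.linalg.solve(V, r))
        else:  # constant response: degenerate fit, no signal
            u = np.zeros(m.n_markers)
        gebv = pd.Series(Z_all @ u, index=pd.Index(m.clone_ids, name="clone"))
        return PredictionResults(
            method="rrblup", mu=float(res.beta[0]), gebv=gebv, getgv=gebv.copy(),
            marker_effects=pd.Series(u, index=m.marker_ids),
            variance_estimates={"marker": s2u, "residual": s2e},
            diagnostics={"converged": res.converged, "n_iterations": res.n_iterations})


class GBLUP:
    """Clone-level BLUP with genomic covariance G (and optionally D)."""

    def __init__(self, y, g: RelationshipMatrix, d: RelationshipMatrix | None = None):
        if g.kind != "additive":
            raise ValueError("g must be an additive relationship matrix")
        if d is not None:
            if d.kind != "dominance":
                raise ValueError("d must be a dominance relationship matrix")
            if d.clone_ids != g.clone_ids:
                raise ValueError("G and D must cover the same clones in the same order")
        self.y = _as_series(y)
        self.g, self.d = g, d

    def fit(self) -> PredictionResults:
        g, d = self.g, self.d
        obs, yv = _align(self.y, g.clone_ids)
        n_all = g.n_clones
        Z = np.zeros((obs.size, n_all))
        Z[np.arange(obs.size), obs] = 1.0
        # additive-only fits go through the exact eigen solver (clipping
        # handles semidefiniteness); the two-kernel AI solve needs the ridge
        K_add = g.values if d is None else g.stabilized()
        effects = [RandomEffect("additive", Z, K=K_add, levels=list(g.clone_ids))]
        if d is not None:
            effects.append(RandomEffect("dominance", Z, K=d.stabilized(),
                                        levels=list(d.clone_ids)))
        res = MixedModel(yv, np.ones((obs.size, 1)), effects).fit()
        idx = pd.Index(g.clone_ids, name="clone")
        gebv = pd.Series(res.random_effects["additive"], index=idx)
        dom = None
        getgv = gebv.copy()
        if d is not None:
            dom = pd.Series(res.random_effects["dominance"], index=idx)
            getgv = gebv + dom
        vc = {"additive": res.variance_components["additive"],
              "residual": res.variance_components["residual"]}
        if d is not None:
            vc["dominance"] = res.variance_components["dominance"]
        return PredictionResults(
            method="gblup_ad" if d is not None else "gblup_a",
            mu=float(res.beta[0]), gebv=gebv, getgv=getgv,
            dominance_effects=dom, variance_estimates=vc,
            diagnostics={"converged": res.converged, "n_iterations": res.n_iterations})


class RKHS:
    """Gaussian-kernel regression: clone effects with covariance K."""

    def __init__(self, y, k: RelationshipMatrix):
        if k.kind != "gaussian":
            raise ValueError("k must be a gaussian kernel matrix")
        self.y = _as_series(y)
        self.k = k

    def fit(self) -> PredictionResults:
        k = self.k
        obs, yv = _align(self.y, k.clone_ids)
        Z = np.zeros((obs.size, k.n_clones))
        Z[np.arange(obs.size), obs] = 1.0
        Kst = k.values + 1e-8 * np.eye(k.n_clones)
        eff = RandomEffect("kernel", Z, K=Kst, levels=list(k.clone_ids))
        res = MixedModel(yv, np.ones((obs.size, 1)), [eff]).fit()
        ghat = pd.Series(res.random_effects["kernel"],
                         index=pd.Index(k.clone_ids, name="clone"))
        return PredictionResults(
            method="rkhs", mu=float(res.beta[0]), gebv=ghat, getgv=ghat.copy(),
            variance_estimates={"kernel": res.variance_components["kernel"],
                                "residual": res.variance_components["residual"]},
            diagnostics={"converged": res.converged, "bandwidth_h": k.bandwidth_h})


class BayesMarkerModel:
    """BayesA/BayesB marker-effect model fitted by Gibbs sampling."""

    def __init__(self, y, markers: MarkerMatrix, variant: str = "bayes_a",
                 n_iter: int = 20000, burn_in: int = 5000, thin: int = 10,
                 seed: int = 0, **hyper):
        if variant not in ("bayes_a", "bayes_b"):
            raise ValueError("variant must be 'bayes_a' or 'bayes_b'")
        if n_iter <= burn_in:
            raise ValueError("n_iter must exceed burn_in")
        self.y = _as_series(y)
        self.markers = markers
        self.variant = variant
        self.n_iter, self.burn_in, self.thin = n_iter, burn_in, thin
        self.seed = int(seed) % (2 ** 31)
        self.hyper = hyper

    def fit(self) -> PredictionResults:
        m = self.markers
        Z_all = m.centered()
        obs, yv = _align(self.y, m.clone_ids)
        out = _bayes.run_gibbs(Z_all[obs], yv, self.variant, self.n_iter,
                               self.burn_in, self.thin, self.seed, **self.hyper)
        u = out["u"]
        gebv = pd.Series(Z_all @ u, index=pd.Index(m.clone_ids, name="clone"))
        diag = {"ess_s2e": out["ess_s2e"], "pi": out["pi"],
                "n_samples": out["s2e_chain"].size}
        if self.variant == "bayes_b":
            diag["inclusion_prob"] = pd.Series(out["inclusion_prob"], index=m.marker_ids)
        return PredictionResults(
            method=self.variant, mu=float(out["mu"]), gebv=gebv, getgv=gebv.copy(),
            marker_effects=pd.Series(u, index=m.marker_ids),
            variance_estimates={"residual": out["s2e"]}, diagnostics=diag)


class RandomForestGP:
    """Bagged regression trees on raw dosages (mtry = floor(p/3), 500 trees).

    Predictions for phenotyped clones are out-of-bag; unphenotyped clones get
    ordinary ensemble predictions.
    """

    def __init__(self, y, markers: MarkerMatrix, n_trees: int = 500,
                 mtry: int | None = None, seed: int = 0):
        if markers.n_markers == 0:
            raise ValueError("no markers")
        self.y = _as_series(y)
        self.markers = markers
        self.n_trees = n_trees
        self.mtry = mtry if mtry is not None else max(1, markers.n_markers // 3)
        self.seed = int(seed) % (2 ** 31)

    def fit(self) -> PredictionResults:
        from sklearn.ensemble import RandomForestRegressor

        m = self.markers
        obs, yv = _align(self.y, m.clone_ids)
        X = m.dosages
        rf = RandomForestRegressor(n_estimators=self.n_trees, max_features=self.mtry,
                                   oob_score=True, bootstrap=True, n_jobs=1,
                                   random_state=self.seed)
        rf.fit(X[obs], yv)
        pred = rf.predict(X)
        oob = rf.oob_prediction_
        mode = np.full(m.n_clones, "refit", dtype=object)
        for j, i in enumerate(obs):
            if np.isfinite(oob[j]):
                pred[i] = oob[j]
                mode[i] = "oob"
        if float(np.std(yv)) == 0.0:  # constant response: every leaf is that constant
            pred[:] = yv[0]
        gebv = pd.Series(pred, index=pd.Index(m.clone_ids, name="clone"))
        return PredictionResults(
            method="random_forest", mu=float(np.mean(yv)), gebv=gebv,
            getgv=gebv.copy(),
            diagnostics={"oob_r2": float(rf.oob_score_) if np.std(yv) > 0 else float("nan"),
                         "prediction_mode": pd.Series(mode, index=m.clone_ids),
                         "n_trees": self.n_trees, "mtry": self.mtry})


# -- functional wrappers ------------------------------------------------------


def fit_rrblup(y, m: MarkerMatrix, spec: PredictorSpec | None = None) -> PredictionResults:
    return RRBLUP(y, m).fit()


def fit_gblup(y, g: RelationshipMatrix, d: RelationshipMatrix | None = None,
              spec: PredictorSpec | None = None) -> PredictionResults:
    return GBLUP(y, g, d).fit()


def fit_rkhs(y, k: RelationshipMatrix, spec: PredictorSpec | None = None) -> PredictionResults:
    return RKHS(y, k).fit()


def fit_bayes(y, m: MarkerMatrix, spec: PredictorSpec) -> PredictionResults:
    hp = dict(spec.hyperparams)
    return BayesMarkerModel(y, m, variant=spec.method,
                            n_iter=hp.pop("n_iter", 20000),
                            burn_in=hp.pop("burn_in", 5000),
                            thin=hp.pop("thin", 10), seed=spec.seed, **hp).fit()


def fit_random_forest(y, m: MarkerMatrix, spec: PredictorSpec | None = None) -> PredictionResults:
    hp = dict(spec.hyperparams) if spec else {}
    seed = spec.seed if spec else 0
    return RandomForestGP(y, m, n_trees=hp.get("n_trees", 500),
                          mtry=hp.get("mtry"), seed=seed).fit()


def make_predictor(method: str, markers: MarkerMatrix | None = None,
                   g: RelationshipMatrix | None = None,
                   d: RelationshipMatrix | None = None,
                   k: RelationshipMatrix | None = None,
                   hyperparams: dict | None = None, seed: int = 0):
    """Return a callable y -> PredictionResults for the named method.

    Relationship matrices / marker data are bound once, so repeated calls
    (as in cross-validation) reuse them.
    """
    spec = PredictorSpec(method, hyperparams or {}, seed)
    if method == "rrblup":
        return lambda y: fit_rrblup(y, markers, spec)
    if method == "gblup_a":
        return lambda y: fit_gblup(y, g, None, spec)
    if method == "gblup_ad":
        return lambda y: fit_gblup(y, g, d, spec)
    if method == "rkhs":
        return lambda y: fit_rkhs(y, k, spec)
    if method in ("bayes_a", "bayes_b"):
        return lambda y: fit_bayes(y, markers, spec)
    if method == "random_forest":
        return lambda y: fit_random_forest(y, markers, spec)
    raise ValueError(f"unknown method '{method}'")
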