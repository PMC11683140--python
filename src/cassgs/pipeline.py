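"""End-to-end orchestration: simulate/load -> QC -> BLUPs -> matrices ->
predict -> cross-validate -> select, with a reproducibility manifest.

Every stage writes plain-text artifacts (CSV/VCF/JSON) into the output
directory and records them, with SHA-256 checksums and the parameters and
seeds used, in ``manifest.json``.  The master seed deterministically spawns
one sub-seed per stage, so reruns with the same configuration reproduce every
artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from cassgs import evaluation, markers, predictors, selection, simulate, stage_one

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ("simulate", "qc", "blup", "matrices", "predict", "cv", "select")


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (see the CLI for YAML keys)."""

    outdir: str = "cassgs_run"
    seed: int = 0
    # either simulate…
    simulate: dict | None = None
    # …or load from files
    genotypes: str | None = None
    genotype_format: str = "dosage_csv"
    phenotypes: str | None = None
    # stage settings
    maf_threshold: float = 0.01
    traits: list[str] | None = None
    methods: list[str] = dc_field(default_factory=lambda: ["gblup_a", "gblup_ad"])
    rkhs_h: float = 1.0
    bayes: dict = dc_field(default_factory=lambda: {"n_iter": 20000, "burn_in": 5000,
                                                    "thin": 10})
    cv_k: int = 5
    cv_repeats: int = 5
    intensities: list[float] = dc_field(default_factory=lambda: list(selection.DEFAULT_INTENSITIES))
    index_weights: dict[str, float] | None = None
    standardize_index: bool = True
    dominance_denominator: str = "printed"

    def __post_init__(self):
        unknown = set(self.methods) - set(predictors.SUPPORTED_METHODS)
        if unknown:
            raise ValueError(f"unsupported methods: {sorted(unknown)}")
        if self.simulate is None and (self.genotypes is None or self.phenotypes is None):
            raise ValueError("either 'simulate' settings or genotype+phenotype "
                             "paths are required")
        if self.simulate is None:
            for p in (self.genotypes, self.phenotypes):
                if not Path(p).exists():
                    raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(_STAGES))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(_STAGES, children)}


class _Manifest:
    def __init__(self, outdir: Path, cfg: PipelineConfig, seeds):
        self.data = {"config": {k: v for k, v in vars(cfg).items()},
                     "stage_seeds": seeds, "stages": {}, "artifacts": {}}
        self.outdir = outdir

    def add(self, stage: str, name: str, path: Path):
        rel = str(path.relative_to(self.outdir))
        self.data["stages"].setdefault(stage, []).append(rel)
        self.data["artifacts"][rel] = _sha256(path)

    def note(self, stage: str, **info):
        self.data.setdefault("notes", {}).setdefault(stage, {}).update(info)

    def write(self):
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(self.data, fh, indent=2, default=str)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dictionary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    manifest = _Manifest(outdir, cfg, seeds)

    try:
        # -- stage 1: data -------------------------------------------------
        if cfg.simulate is not None:
            sim_cfg = simulate.SimulationConfig(**{**cfg.simulate,
                                                   "seed": cfg.simulate.get("seed", seeds["simulate"])})
            geno = simulate.simulate_genotypes(sim_cfg)
            table, truth = simulate.simulate_trials(geno, sim_cfg)
            geno.to_dosage_csv(outdir / "genotypes.csv")
            geno.to_vcf(outdir / "genotypes.vcf")
            table.to_csv(outdir / "phenotypes.csv", index=False)
            truth.to_csv(outdir / "ground_truth.csv")
            for f in ("genotypes.csv", "genotypes.vcf", "phenotypes.csv",
                      "ground_truth.csv"):
                manifest.add("simulate", f, outdir / f)
        else:
            geno = markers.load_genotypes(cfg.genotypes, cfg.genotype_format)
            table = pd.read_csv(cfg.phenotypes)

        traits = cfg.traits or sorted(table["trait"].unique())

        # -- stage 2: QC ----------------------------------------------------
        try:
            geno_qc = markers.qc_filter(geno, cfg.maf_threshold)
        except ValueError as exc:
            raise RuntimeError(f"stage 'qc' failed: {exc}") from exc
        geno_qc.to_dosage_csv(outdir / "genotypes_qc.csv")
        manifest.add("qc", "genotypes_qc.csv", outdir / "genotypes_qc.csv")
        manifest.note("qc", n_markers_in=geno.n_markers, n_markers_kept=geno_qc.n_markers)

        # -- stage 3: stage-one BLUPs ---------------------------------------
        blup_rows, vc_rows = [], []
        fits = {}
        for trait in traits:
            fit = stage_one.fit_stage_one(table, trait)
            fits[trait] = fit
            blup_rows.append(fit.blup_frame())
            props = fit.variance_proportions()
            for comp, var in fit.variance_components.items():
                vc_rows.append((trait, comp, var, props[comp]))
            vc_rows.append((trait, "H2", fit.broad_sense_h2(), np.nan))
        blups = pd.concat(blup_rows, ignore_index=True)
        blups.to_csv(outdir / "blups.csv", index=False)
        pd.DataFrame(vc_rows, columns=["trait", "component", "variance",
                                       "percent"]).to_csv(outdir / "variance_components.csv",
                                                          index=False)
        manifest.add("blup", "blups.csv", outdir / "blups.csv")
        manifest.add("blup", "variance_components.csv", outdir / "variance_components.csv")

        # -- stage 4: relationship matrices ----------------------------------
        G = markers.build_additive_grm(geno_qc)
        D = markers.build_dominance_grm(geno_qc, cfg.dominance_denominator)
        K = markers.build_gaussian_kernel(geno_qc, cfg.rkhs_h)
        for mat, name in ((G, "G"), (D, "D"), (K, "K")):
            mat.to_csv(outdir / f"matrix_{name}.csv")
            manifest.add("matrices", f"matrix_{name}.csv", outdir / f"matrix_{name}.csv")

        # SNP heritability from BLUPs + G
        h2_rows = []
        for trait in traits:
            y = blups.loc[blups["trait"] == trait].set_index("clone")["blup"]
            h2_rows.append((trait, stage_one.snp_h2(y, G),
                            fits[trait].broad_sense_h2()))
        pd.DataFrame(h2_rows, columns=["trait", "snp_h2", "broad_H2"]).to_csv(
            outdir / "heritabilities.csv", index=False)
        manifest.add("blup", "heritabilities.csv", outdir / "heritabilities.csv")

        # -- stage 5: genomic prediction on the full data --------------------
        def _predictor(method, seed):
            return predictors.make_predictor(
                method, markers=geno_qc, g=G, d=D, k=K, seed=seed,
                hyperparams=cfg.bayes if method.startswith("bayes") else {})

        pred_store: dict[tuple[str, str], predictors.PredictionResults] = {}
        for trait in traits:
            y = blups.loc[blups["trait"] == trait].set_index("clone")["blup"]
            y = y.loc[[c for c in G.clone_ids if c in y.index]]
            for method in cfg.methods:
                res = _predictor(method, seeds["predict"])(y)
                pred_store[(trait, method)] = res
                fname = f"predictions_{trait}_{method}.csv"
                res.to_csv(outdir / fname)
                manifest.add("predict", fname, outdir / fname)

        # -- stage 6: cross-validation ---------------------------------------
        cv_rows = []
        for trait in traits:
            y = blups.loc[blups["trait"] == trait].set_index("clone")["blup"]
            y = y.loc[[c for c in G.clone_ids if c in y.index]]
            plan = evaluation.make_folds(y.size, cfg.cv_k, cfg.cv_repeats, seeds["cv"])
            for method in cfg.methods:
                value = "getgv" if method == "gblup_ad" else "gebv"
                cv = evaluation.cross_validate(y, _predictor(method, seeds["cv"]),
                                               plan, value=value,
                                               trait=trait, method=method)
                for _, row in cv.per_fold.iterrows():
                    cv_rows.append((trait, method, int(row["repeat"]),
                                    int(row["fold"]), row["ability"]))
        cv_df = pd.DataFrame(cv_rows, columns=["trait", "method", "repeat",
                                               "fold", "ability"])
        cv_df.to_csv(outdir / "cv_folds.csv", index=False)
        (cv_df.groupby(["trait", "method"])["ability"].agg(["mean", "std"])
         .reset_index().to_csv(outdir / "cv_summary.csv", index=False))
        manifest.add("cv", "cv_folds.csv", outdir / "cv_folds.csv")
        manifest.add("cv", "cv_summary.csv", outdir / "cv_summary.csv")

        # -- stage 7: selection ------------------------------------------------
        weights = cfg.index_weights
        if weights is None:
            weights = ({t: selection.DEFAULT_INDEX_WEIGHTS[t] for t in traits}
                       if all(t in selection.DEFAULT_INDEX_WEIGHTS for t in traits)
                       else {t: 1.0 for t in traits})
        bases = {"blup": blups.pivot(index="clone", columns="trait", values="blup")}
        gebv_method = next((m for m in ("gblup_a", "rrblup", "rkhs", "bayes_a",
                                        "bayes_b", "random_forest")
                            if m in cfg.methods), None)
        getgv_method = "gblup_ad" if "gblup_ad" in cfg.methods else gebv_method
        if gebv_method:
            bases["gebv"] = pd.DataFrame({t: pred_store[(t, gebv_method)].gebv
                                          for t in traits})
        if getgv_method:
            bases["getgv"] = pd.DataFrame({t: pred_store[(t, getgv_method)].getgv
                                           for t in traits})

        sel_frames, sd_frames, sel_sets = [], [], {}
        n_universe = bases["blup"].shape[0]
        for basis, values in bases.items():
            report = selection.build_selection_report(
                values.dropna(), basis, weights, cfg.intensities,
                standardize=cfg.standardize_index)
            sel_frames.append(report.selected_frame())
            for inten, sd in report.differentials.items():
                sd = sd.reset_index()
                sd.insert(0, "intensity", inten)
                sd.insert(0, "basis", basis)
                sd_frames.append(sd)
            for inten, sel in report.selected.items():
                sel_sets[f"{basis}@{inten:g}"] = sel
        pd.concat(sel_frames, ignore_index=True).to_csv(outdir / "selected_clones.csv",
                                                        index=False)
        pd.concat(sd_frames, ignore_index=True).to_csv(outdir / "selection_differentials.csv",
                                                       index=False)
        selection.kappa_matrix(sel_sets, n_universe).to_csv(outdir / "kappa_matrix.csv")
        for f in ("selected_clones.csv", "selection_differentials.csv", "kappa_matrix.csv"):
            manifest.add("select", f, outdir / f)
    except RuntimeError:
        raise
    except Exception as exc:  # annotate which stage broke
        stage = manifest.data["stages"]
        last = list(stage)[-1] if stage else "setup"
        raise RuntimeError(f"pipeline aborted after stage '{last}': {exc}") from exc

    manifest.write()
    logger.info("pipeline complete: %s", outdir / "manifest.json")
    return manifest.data
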