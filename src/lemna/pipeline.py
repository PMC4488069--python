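"""Config-driven orchestration of the full occurrence analysis.

One run: load or simulate a survey, compute derived predictors, report
collinearity, then for every response fit all predictor subsets, average the
models within 2 AICc units of the best, choose the operating threshold, and
summarize classification performance and pseudo-R²; finally run the
species-pool permutation null and the environmental PCA.  Every table lands
in the output directory as CSV, with a machine-readable ``summary.json``
recording the seed, a config hash, library versions and per-stage results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import evaluation, glm, io, null_model, pca, predictors
from . import synthetic as synth
from .types import OccurrenceMatrix, ResponseSpec, SiteTable

log = logging.getLogger(__name__)

#: Default model predictors: Table-style covariate codes minus the two the
#: collinearity screen retires (alkalinity ~ conductivity/pH; maximum depth ~
#: Secchi depth/size).
DEFAULT_PREDICTORS = [
    "size", "shoreline", "totalP", "pH", "cond", "secchi", "nonFP",
    "latitude", "longitude", "lakes1km", "lakes10km", "boatlaunch",
]

DEFAULT_PCA_VARIABLES = [
    "size", "shoreline", "depth", "nonFP", "totalP", "pH", "cond", "alk",
    "secchi",
]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated settings for one pipeline run."""

    seed: int = 0
    synthetic: synth.SynthConfig | None = None
    input_paths: dict | None = None          # sites / occurrence / taxa
    responses: list[ResponseSpec] = field(default_factory=list)
    predictors: list[str] = field(default_factory=lambda: list(DEFAULT_PREDICTORS))
    exclude_predictors: list[str] = field(default_factory=list)
    exclude_sites: list[str] = field(default_factory=list)
    delta_max: float = 2.0
    threshold_step: float = 0.005
    averaging_variant: str = "full"
    prediction_mode: str = "mean_probability"
    pseudo_r2_variant: str = "cox_snell"
    cooks_threshold: float = 0.9
    collinearity_threshold: float = 0.7
    null_pool_sizes: list[int] = field(default_factory=lambda: [1, 6, 12, 24])
    null_iterations: int = 2000
    focal_group: str = synth.GROUP_LABEL
    pca_variables: list[str] = field(default_factory=lambda: list(DEFAULT_PCA_VARIABLES))
    distance_metric: str = "haversine"

    def __post_init__(self) -> None:
        if self.synthetic is None and self.input_paths is None:
            self.synthetic = synth.SynthConfig(seed=self.seed)
        if self.synthetic is not None and self.input_paths is not None:
            raise ValueError("give either synthetic settings or input paths, not both")
        if self.delta_max <= 0:
            raise ValueError("delta_max must be positive")
        if not 0 < self.threshold_step <= 0.5:
            raise ValueError("threshold_step must lie in (0, 0.5]")
        if self.averaging_variant not in ("full", "conditional"):
            raise ValueError(f"unknown averaging variant {self.averaging_variant!r}")
        if self.pseudo_r2_variant not in ("cox_snell", "nagelkerke"):
            raise ValueError(f"unknown pseudo-R2 variant {self.pseudo_r2_variant!r}")
        if not self.responses and self.synthetic is not None:
            members = synth.MEMBER_TAXA[:self.synthetic.group_size]
            self.responses = [
                ResponseSpec(name="floating_group", group=self.focal_group)]
            for code, taxon in zip(("distLM", "distSP", "distW"), members[:3]):
                self.responses.append(ResponseSpec(
                    name=taxon, taxon=taxon, distance_predictor=code))

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "synthetic" in raw and raw["synthetic"] is not None:
            sdict = dict(raw["synthetic"])
            if "member_offsets" in sdict:
                sdict["member_offsets"] = tuple(sdict["member_offsets"])
            for key in ("lat_range", "lon_range"):
                if key in sdict:
                    sdict[key] = tuple(sdict[key])
            sdict.setdefault("seed", raw.get("seed", 0))
            raw["synthetic"] = synth.SynthConfig(**sdict)
        if "responses" in raw:
            raw["responses"] = [ResponseSpec(**r) for r in raw["responses"]]
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_jsonable(self) -> dict:
        out = {k: v for k, v in self.__dict__.items()
               if k not in ("synthetic", "responses")}
        out["synthetic"] = self.synthetic.to_dict() if self.synthetic else None
        out["responses"] = [r.__dict__ for r in self.responses]
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _child_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def load_survey(config: RunConfig) -> tuple[SiteTable, OccurrenceMatrix, dict]:
    if config.input_paths is not None:
        sites, occ = io.read_survey(
            config.input_paths["sites"], config.input_paths["occurrence"],
            config.input_paths.get("taxa"))
        return sites, occ, {"source": "files", **config.input_paths}
    sites, occ, meta = synth.generate_survey(config.synthetic)
    meta["source"] = "synthetic"
    return sites, occ, meta


def build_design(sites: SiteTable, response: ResponseSpec,
                 config: RunConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Unit-rescaled predictor matrix and row mask for one response.

    Predictors are the configured list, minus exclusions, plus the
    response-specific distance covariate; sites with any missing predictor
    value (or listed in ``exclude_sites``) are dropped with a log line.
    """
    names = [p for p in config.predictors if p not in config.exclude_predictors]
    if response.distance_predictor and response.distance_predictor not in names:
        names = names + [response.distance_predictor]
    names = [n for n in names if n in sites.data.columns or n in ("latitude", "longitude")]
    raw = pd.DataFrame({n: sites.covariate(n) for n in names})
    keep = np.all(np.isfinite(raw.to_numpy(float)), axis=1)
    keep &= ~sites.site_ids.isin(config.exclude_sites).to_numpy()
    dropped = int((~keep).sum())
    if dropped:
        log.info("response %s: dropped %d sites (missing predictors or excluded)",
                 response.name, dropped)
    X = raw.loc[keep].reset_index(drop=True)
    scaled = {}
    for n in names:
        try:
            scaled[n] = predictors.rescale_unit_interval(X[n].to_numpy())
        except ValueError:
            log.warning("predictor %s is constant on the modelling rows; dropped", n)
    return pd.DataFrame(scaled), keep


def analyse_response(sites: SiteTable, occ: OccurrenceMatrix,
                     response: ResponseSpec, config: RunConfig) -> dict:
    """All-subsets fit, averaging, threshold evaluation for one response."""
    X, keep = build_design(sites, response, config)
    y = response.resolve(occ).to_numpy()[keep]
    models = glm.all_subsets(X, y)
    cand = glm.candidate_set(models, config.delta_max)
    avg = glm.model_average(cand)
    probs = glm.predict_average(avg, X, config.prediction_mode)
    t_star = evaluation.optimal_threshold(y, probs, config.threshold_step)
    ev = evaluation.confusion_matrix(y, probs, t_star)
    best = cand[0].fit
    null_fit = glm.fit_logistic(X[[]], y, ())
    r2 = {v: glm.pseudo_r2(best, null_fit, v)
          for v in ("cox_snell", "nagelkerke")}
    cooks = glm.cooks_distance(best)
    flagged = [str(s) for s, d in
               zip(sites.site_ids[keep], cooks) if d > config.cooks_threshold]
    model_rows = [{
        "terms": "+".join(c.fit.predictors) or "(intercept)",
        "k": c.fit.k, "loglik": c.fit.loglik, "AICc": c.aicc,
        "delta": c.delta, "weight": c.weight,
        "in_candidate_set": c.delta < config.delta_max and c.fit.ok,
    } for c in models]
    return {
        "name": response.name,
        "n": int(keep.sum()),
        "n_models": len(models),
        "n_candidates": len(cand),
        "averaged": avg,
        "model_table": pd.DataFrame(model_rows),
        "predictions": pd.DataFrame({
            "site_id": sites.site_ids[keep].to_numpy(),
            "observed": y.astype(int),
            "probability": probs,
        }),
        "threshold": t_star,
        "evaluation": ev,
        "pseudo_r2": r2,
        "high_cooks_sites": flagged,
    }


def run_pipeline(config: RunConfig, outdir: str | os.PathLike) -> dict:
    """Execute every stage and write the report bundle into ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    outdir = str(outdir)
    summary: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "versions": {m.__name__: m.__version__ for m in (np, pd)},
    }

    def stage(name, fn):
        try:
            log.info("stage %s", name)
            return fn()
        except Exception as exc:  # noqa: BLE001 - stage-named rethrow
            raise PipelineError(name, exc) from exc

    sites, occ, meta = stage("load", lambda: load_survey(config))
    summary["data"] = {"n_sites": sites.n_sites, "n_taxa": len(occ.taxa),
                       "source": meta.get("source")}
    if meta.get("source") == "synthetic":
        stage("write_survey", lambda: io.write_survey(sites, occ, outdir))

    screen = stage("collinearity", lambda: predictors.collinearity_screen(
        sites, config.collinearity_threshold))
    screen.to_csv(os.path.join(outdir, "collinearity.csv"), index=False)
    summary["collinearity_flagged"] = len(screen)

    summary["responses"] = {}
    for response in config.responses:
        res = stage(f"fit:{response.name}",
                    lambda r=response: analyse_response(sites, occ, r, config))
        tag = response.name
        res["model_table"].to_csv(
            os.path.join(outdir, f"models_{tag}.csv"), index=False)
        res["averaged"].to_frame().to_csv(
            os.path.join(outdir, f"averaged_{tag}.csv"), index=False)
        res["predictions"].to_csv(
            os.path.join(outdir, f"predictions_{tag}.csv"), index=False)
        pd.DataFrame([res["evaluation"].as_dict()]).to_csv(
            os.path.join(outdir, f"evaluation_{tag}.csv"), index=False)
        sig = res["averaged"].significant(config.averaging_variant)
        summary["responses"][tag] = {
            "n": res["n"], "n_models": res["n_models"],
            "n_candidates": res["n_candidates"],
            "threshold": res["threshold"],
            "PCC": evaluation.percent_correct(res["evaluation"]),
            "kappa": evaluation.cohen_kappa(res["evaluation"])[0],
            "pseudo_r2": res["pseudo_r2"],
            "significant_terms": [t for t, s in sig.items()
                                  if s and t != "intercept"],
            "high_cooks_sites": res["high_cooks_sites"],
        }

    def run_null():
        pool = occ.occupancy().to_numpy()
        observed = null_model.observed_empty_proportion(occ, config.focal_group)
        seed = _child_seed(config.seed, "null_model")
        results = null_model.null_model_curve(
            pool, config.null_pool_sizes, occ.n_sites,
            config.null_iterations, seed, observed=observed)
        return observed, seed, results

    observed, null_seed, null_results = stage("null_model", run_null)
    pd.DataFrame({f"S={r.pool_size}": r.samples for r in null_results}).to_csv(
        os.path.join(outdir, "nullmodel_samples.csv"), index=False)
    summary["null_model"] = {
        "observed_empty_proportion": observed,
        "seed": null_seed,
        "pool_sizes": [r.summary() for r in null_results],
    }

    pca_res = stage("pca", lambda: pca.pca_correlation(
        sites, [v for v in config.pca_variables if v in sites.data.columns]))
    pca_res.loadings_table().to_csv(os.path.join(outdir, "pca_loadings.csv"))
    pca_res.scores.to_csv(os.path.join(outdir, "pca_scores.csv"), index=False)
    summary["pca"] = {
        "variables": list(pca_res.variables),
        "proportion_of_variance": pca_res.proportions.tolist(),
    }

    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
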