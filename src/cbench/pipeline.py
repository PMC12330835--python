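"""Reproducible train -> GLM -> infer pipeline with config and provenance.

The run configuration is a JSON-serialisable dict; every stage's seed and
the configuration hash are embedded in the outputs so a run can be
reproduced and outputs audited.  Trained change models are cached keyed by
the (protocol, priors, roster, training) part of the configuration --
change models only need to be trained once per acquisition.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .changes import (
    ChangeSpec,
    default_roster,
    load_models,
    save_models,
    train_roster,
)
from .glm import SummaryGLM
from .inference import infer_table
from .protocol import AcquisitionProtocol, read_bvals_bvecs, two_shell_protocol
from .tissue import PRIOR_RANGES, PriorSet

log = logging.getLogger("cbench")


@dataclass
class RunConfig:
    """Pipeline configuration; every field JSON-serialisable."""

    protocol: dict = field(default_factory=dict)
    priors: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    glm: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    output_dir: str = "cbench_out"

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        return _hash_obj(self.to_dict())

    def training_hash(self) -> str:
        return _hash_obj(
            {"protocol": self.protocol, "priors": self.priors,
             "training": self.training}
        )


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True).encode()
    ).hexdigest()[:16]


def build_protocol(cfg: dict) -> AcquisitionProtocol:
    if "bval" in cfg:
        return read_bvals_bvecs(
            cfg["bval"], cfg["bvec"],
            delta_small=cfg.get("delta_small", 14.0),
            delta_big=cfg.get("delta_big", 24.0),
        )
    return two_shell_protocol(
        b_values=tuple(cfg.get("b_values", (7.0, 10.0))),
        n_directions=cfg.get("n_directions", 90),
        n_b0=cfg.get("n_b0", 18),
        delta_small=cfg.get("delta_small", 14.0),
        delta_big=cfg.get("delta_big", 24.0),
        seed=cfg.get("seed", 0),
    )


def build_priors(cfg: dict) -> PriorSet:
    ranges = dict(PRIOR_RANGES)
    for k, v in cfg.get("ranges", {}).items():
        ranges[k] = tuple(v)
    return PriorSet(ranges=ranges, with_ball=cfg.get("with_ball", True))


def build_roster(cfg: dict, priors: PriorSet) -> list[ChangeSpec]:
    names = cfg.get("roster")
    if not names:
        return default_roster(priors)
    roster = []
    for n in names:
        if "-" in n and not n.startswith("-"):
            up, down = n.split("-")
            roster.append(ChangeSpec.fraction_pair(up, down))
        else:
            roster.append(ChangeSpec.single(n.lstrip("-"),
                                            -1 if n.startswith("-") else +1))
    return roster


def train_stage(config: RunConfig, force: bool = False):
    """Train (or load cached) change models; returns (models, directory)."""
    out = Path(config.output_dir)
    cache = out / f"models-{config.training_hash()}"
    if cache.exists() and not force:
        log.info("reusing cached change models at %s", cache)
        return load_models(cache), cache
    protocol = build_protocol(config.protocol)
    priors = build_priors(config.priors)
    roster = build_roster(config.training, priors)
    models = train_roster(
        roster, priors, protocol,
        n_samples=config.training.get("n_pairs", 20_000),
        rng_seed=config.training.get("seed", 0),
    )
    save_models(models, cache)
    (cache / "provenance.json").write_text(
        json.dumps(
            {"config_hash": config.hash(),
             "training_hash": config.training_hash(),
             "seed": config.training.get("seed", 0),
             "n_pairs": config.training.get("n_pairs", 20_000),
             "roster": sorted(models)},
            indent=2, sort_keys=True,
        )
    )
    return models, cache


def _load_table(path) -> pd.DataFrame:
    path = str(path)
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def glm_stage(config: RunConfig, Y: pd.DataFrame, X: pd.DataFrame):
    """Run the GLM in 'all' (joint) or 'single' (one covariate at a time)
    mode; returns a list of fitted GLM results (one in 'all' mode)."""
    gcfg = config.glm
    mode = gcfg.get("mode", "all")
    est_kwargs = dict(
        effect_size_mode=gcfg.get("effect_size_mode", "percentile"),
        n_boot=gcfg.get("n_boot", 5000),
        subsample_size=gcfg.get("subsample", 1000),
        rng_seed=gcfg.get("seed", 0),
    )
    measure_cols = [c for c in Y.columns if c not in ("i", "j", "k")]
    Yv = Y[measure_cols].to_numpy(float)
    results = []
    if mode == "all":
        results.append(SummaryGLM(**est_kwargs).fit(X, Yv).result_)
    elif mode == "single":
        for c in X.columns:
            results.append(SummaryGLM(**est_kwargs).fit(X[[c]], Yv).result_)
    else:
        raise ValueError(f"unknown GLM mode {mode!r}")
    for r in results:
        r.measure_names = measure_cols
    return results


def run_pipeline(config: RunConfig) -> dict:
    """Execute train -> GLM -> infer; writes artefacts under output_dir.

    Outputs: models-<hash>/ (cached change models), glm.json, posterior.tsv,
    report.json.  Idempotent for a fixed config.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "config_hash": config.hash(),
                      "stages": {}}
    try:
        models, model_dir = train_stage(config)
        manifest["stages"]["train"] = {"dir": str(model_dir),
                                       "n_models": len(models)}

        for key in ("summaries", "covariates"):
            p = config.inputs.get(key)
            if not p or not Path(p).exists():
                raise FileNotFoundError(
                    f"pipeline input '{key}' missing or not found: {p!r}"
                )
        Y = _load_table(config.inputs["summaries"])
        X = _load_table(config.inputs["covariates"])
        results = glm_stage(config, Y, X)
        glm_out = []
        for r in results:
            glm_out.append(
                {
                    "covariates": r.covariate_names,
                    "beta_mean": r.beta_mean.tolist(),
                    "beta": r.beta.tolist(),
                    "delta": r.delta.tolist(),
                    "sigma": r.sigma.tolist(),
                    "n": r.n,
                    "meta": r.meta,
                }
            )
        (out / "glm.json").write_text(
            json.dumps({"config_hash": config.hash(), "results": glm_out},
                       indent=2, sort_keys=True)
        )
        manifest["stages"]["glm"] = {"n_fits": len(results)}

        tables = [infer_table(r, models) for r in results]
        posterior = pd.concat(tables, ignore_index=True)
        posterior = posterior.sort_values(
            ["covariate", "model"], kind="mergesort"
        ).reset_index(drop=True)
        with open(out / "posterior.tsv", "w") as fh:
            fh.write(f"# config_hash={config.hash()}\n")
            posterior.to_csv(fh, sep="\t", index=False, float_format="%.10g")
        manifest["stages"]["infer"] = {"rows": len(posterior)}
        manifest["status"] = "ok"
    except Exception:
        manifest["status"] = "failed"
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str)
        )
        raise
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    return {"posterior": posterior, "glm_results": results,
            "models": models, "manifest": manifest}
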