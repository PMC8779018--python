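"""Batch pipeline: a declarative chain of processing stages.

A :class:`RunConfig` lists stages (``simulate``, ``adjust-priors``,
``fuse-metadata``, ``pool``, ``evaluate``, ``split``) with per-stage
parameters. The chain is type-checked before any work: each stage
declares which artifacts it consumes (posteriors, labels, metadata, …)
and produces, and a stage whose inputs are neither produced upstream nor
supplied as explicit file paths is a configuration error. Runs are
deterministic given config + seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import io as fio
from .core import LabelSpace, PriorVector
from .errors import ConfigError
from .evaluation import evaluate, species_split
from .metadata_fusion import fit_frequency_model, fuse
from .prior_shift import PriorShiftSpec, adjust_posteriors, adjust_to_uniform, estimate_class_priors
from .simulator import build_model, sample_dataset
from .tta import PredictionStack, pool_mode, pool_sum

log = logging.getLogger("fungirec.pipeline")

# artifact kinds each stage consumes / produces (chain type checking)
_STAGE_TYPES: dict[str, tuple[set[str], set[str]]] = {
    "simulate": (set(), {"posteriors", "labels", "metadata", "train_prior"}),
    "adjust-priors": ({"posteriors", "train_prior"}, {"posteriors"}),
    "fuse-metadata": ({"posteriors", "labels", "metadata"}, {"posteriors"}),
    "pool": (set(), {"posteriors"}),  # reads its stacks from files
    "evaluate": ({"posteriors", "labels"}, {"report"}),
    "split": ({"labels"}, {"split"}),
}

# explicit file params that satisfy an artifact requirement
_PARAM_PROVIDES = {
    "posteriors": "posteriors",
    "train_prior": "train_prior",
    "train_labels": "labels",
    "truth": "labels",
    "metadata": "metadata",
}


@dataclass
class RunConfig:
    """Parsed pipeline configuration."""

    stages: list[dict[str, Any]]
    out_dir: Path
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_mapping(cls, payload: dict, base: Path | None = None) -> "RunConfig":
        if not isinstance(payload, dict):
            raise ConfigError("config root must be a mapping")
        stages = payload.get("stages", [])
        if not isinstance(stages, list):
            raise ConfigError("'stages' must be a list")
        norm = []
        for entry in stages:
            if isinstance(entry, str):
                entry = {"stage": entry}
            if "stage" not in entry:
                raise ConfigError(f"stage entry without a 'stage' name: {entry}")
            if entry["stage"] not in _STAGE_TYPES:
                raise ConfigError(
                    f"unknown stage {entry['stage']!r}; expected one of {sorted(_STAGE_TYPES)}"
                )
            norm.append({"stage": entry["stage"], "params": dict(entry.get("params", {}))})
        out_dir = Path(payload.get("out_dir", "."))
        if base is not None and not out_dir.is_absolute():
            out_dir = base / out_dir
        return cls(
            stages=norm,
            out_dir=out_dir,
            seed=int(payload.get("seed", 0)),
            verbosity=str(payload.get("verbosity", "INFO")),
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        payload = yaml.safe_load(path.read_text())
        return cls.from_mapping(payload or {}, base=path.parent)

    def check_chain(self) -> None:
        """Reject configs whose stage inputs are not available, before any work."""
        available: set[str] = set()
        for pos, entry in enumerate(self.stages):
            name, params = entry["stage"], entry["params"]
            consumes, produces = _STAGE_TYPES[name]
            provided = {
                kind for param, kind in _PARAM_PROVIDES.items() if params.get(param)
            }
            missing = consumes - available - provided
            if missing:
                raise ConfigError(
                    f"stage {pos} ({name}) needs {sorted(missing)} but no earlier "
                    "stage produces them and no input file is configured"
                )
            available |= produces | provided


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stage chain; returns a machine-readable report."""
    config.check_chain()
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    config.out_dir.mkdir(parents=True, exist_ok=True)

    ctx: dict[str, Any] = {"seed": config.seed}
    report: dict[str, Any] = {"seed": config.seed, "stages": []}
    for pos, entry in enumerate(config.stages):
        name, params = entry["stage"], entry["params"]
        t0 = time.perf_counter()
        info = _RUNNERS[name](ctx, params, config)
        elapsed = time.perf_counter() - t0
        info.update({"stage": name, "position": pos, "seconds": round(elapsed, 4)})
        log.info("stage %d (%s) finished in %.3fs: %s", pos, name, elapsed, info)
        report["stages"].append(info)
    fio.write_report(report, config.out_dir / "pipeline_report.json")
    return report


# -- stage runners ---------------------------------------------------------

def _load_posteriors(ctx, params):
    if params.get("posteriors"):
        return fio.read_posteriors(params["posteriors"])
    return ctx["posteriors"]


def _load_labels(ctx, params, *keys):
    for key in keys:
        if params.get(key):
            return fio.read_labels(params[key])[1]
    return list(ctx["labels"])


def _run_simulate(ctx, params, config):
    model = build_model(
        k=int(params.get("k", 50)),
        v=int(params.get("v", 200)),
        metadata_cardinalities=params.get("metadata_cardinalities"),
        concentrations=params.get("concentrations", 0.1),
        train_exponent=float(params.get("train_exponent", 1.0)),
        test_exponent=(
            None if params.get("test_exponent") is None else float(params["test_exponent"])
        ),
        seed=config.seed,
    )
    ds = sample_dataset(
        model,
        n=int(params.get("n", 1000)),
        which_prior=params.get("which_prior", "train"),
        seed=config.seed + 1,
        temperature=float(params.get("temperature", 1.0)),
        missing_rate=float(params.get("missing_rate", 0.0)),
    )
    out = config.out_dir
    fio.write_posteriors(ds.posteriors, out / "posteriors.csv")
    fio.write_labels(ds.observation_ids, ds.labels, out / "labels.csv")
    fio.write_metadata(ds.metadata, out / "metadata.csv")
    (out / "model.json").write_text(model.to_json())
    ctx.update(
        posteriors=ds.posteriors,
        labels=list(ds.labels),
        metadata=ds.metadata,
        train_prior=model.train_prior,
        space=model.space,
    )
    return {"rows": ds.n, "species": model.space.k}


def _run_adjust(ctx, params, config):
    post = _load_posteriors(ctx, params)
    if params.get("train_prior"):
        train = fio.read_prior(params["train_prior"], post.space)
    elif "train_prior" in ctx:
        train = ctx["train_prior"]
    else:
        train = estimate_class_priors(ctx["labels"], post.space)
    if params.get("target_prior"):
        target = fio.read_prior(params["target_prior"], post.space)
        adjusted = adjust_posteriors(post, PriorShiftSpec(train, target))
    else:  # default: uniform deployment prior
        adjusted = adjust_to_uniform(post, train)
    fio.write_posteriors(adjusted, config.out_dir / "posteriors_adjusted.csv")
    ctx["posteriors"] = adjusted
    return {"rows": adjusted.n}


def _run_fuse(ctx, params, config):
    post = _load_posteriors(ctx, params)
    metadata = (
        fio.read_metadata(params["metadata"]) if params.get("metadata") else ctx["metadata"]
    )
    labels = _load_labels(ctx, params, "train_labels")
    types = params.get("types", ["habitat", "substrate", "month"])
    if isinstance(types, str):
        types = [t for t in types.split(",") if t]
    model = fit_frequency_model(
        labels, metadata, post.space, alpha=float(params.get("alpha", 0.0))
    )
    fused = fuse(post, metadata, model, types)
    fio.write_posteriors(fused, config.out_dir / "posteriors_fused.csv")
    ctx["posteriors"] = fused
    return {"rows": fused.n, "types": list(types)}


def _run_pool(ctx, params, config):
    paths = params.get("inputs") or []
    members = [fio.read_posteriors(p) for p in paths]
    if "posteriors" in ctx:
        members.insert(0, ctx["posteriors"])
    stack = PredictionStack(members)
    method = params.get("method", "sum")
    if method == "sum":
        pooled = pool_sum(stack)
        fio.write_posteriors(pooled, config.out_dir / "posteriors_pooled.csv")
        ctx["posteriors"] = pooled
        return {"members": len(stack), "method": "sum"}
    if method == "mode":
        winners, _ = pool_mode(stack)
        fio.write_labels(stack.members[0].observation_ids, winners, config.out_dir / "mode_predictions.csv")
        return {"members": len(stack), "method": "mode"}
    raise ConfigError(f"unknown pool method {method!r}")


def _run_evaluate(ctx, params, config):
    post = _load_posteriors(ctx, params)
    truth = _load_labels(ctx, params, "truth")
    ks = params.get("ks", [1, 3, 5])
    if isinstance(ks, str):
        ks = [int(x) for x in ks.split(",")]
    rep = evaluate(post, truth, ks=ks)
    fio.write_report(rep.as_dict(), config.out_dir / "evaluation.json")
    ctx["report"] = rep
    return {"rows": post.n, "top1": round(rep.topk.get(1, float("nan")), 2)}


def _run_split(ctx, params, config):
    if params.get("truth"):
        obs, truth = fio.read_labels(params["truth"])
    else:
        truth = list(ctx["labels"])
        obs = [f"obs{i:06d}" for i in range(len(truth))]
    fraction = float(params.get("fraction", 0.9))
    seed = int(params.get("seed", config.seed))
    train_idx, test_idx = species_split(truth, fraction, seed)
    fio.write_labels([obs[i] for i in train_idx], [truth[i] for i in train_idx], config.out_dir / "train_labels.csv")
    fio.write_labels([obs[i] for i in test_idx], [truth[i] for i in test_idx], config.out_dir / "test_labels.csv")
    return {"train": int(train_idx.size), "test": int(test_idx.size)}


_RUNNERS = {
    "simulate": _run_simulate,
    "adjust-priors": _run_adjust,
    "fuse-metadata": _run_fuse,
    "pool": _run_pool,
    "evaluate": _run_evaluate,
    "split": _run_split,
}
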