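"""End-to-end orchestration: simulate/load -> split -> importance -> select -> train -> validate.

A single master seed makes the whole run deterministic: the train/test split,
the importance rounds and the ensemble members each draw from disjoint streams
derived from it, so re-running an identical config reproduces byte-identical
numeric outputs. Every artifact written to the output directory carries a
config echo for provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ensemble as ensemble_mod
from .classifiers import BaseClassifierSpec
from .datamodel import (
    ExpressionMatrix,
    read_expression_table,
    save_split,
    write_expression_table,
    write_importance_table,
)
from .ensemble import FeatureSelection, ensemble_predict, ensemble_score, train_ensemble
from .importance import ImportanceResult, ResamplingConfig, accumulate_importance, rank_variables, split_samples
from .simulate import SimulationConfig, generate_simulated_dataset
from .validate import ValidationReport, export_plots, validation_report

logger = logging.getLogger("ecfs_dea")

_SPLIT_STREAM = 2
_SIM_STREAM = 3


def derive_seed(master_seed: int, stream: int) -> int:
    """A 31-bit stage seed from the master seed (stable, documented streams)."""
    return int(np.random.SeedSequence(master_seed, spawn_key=(stream,)).generate_state(1)[0] % (2**31))


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """A fully deterministic run description (mirrors the YAML config file)."""

    seed: int
    out_dir: str
    classifier: BaseClassifierSpec
    data_path: str | None = None
    simulation: SimulationConfig | None = None
    orientation: str = "variables_as_rows"
    delimiter: str | None = None
    label_file: str | None = None
    rounds: int = 500
    test_fraction: float = 0.5
    in_bag_fraction: float = 0.7
    selection: list[int] | int | None = 2  # explicit indices, or m for "top-m"
    threads: int = 1
    plots: bool = False

    def __post_init__(self) -> None:
        if (self.data_path is None) == (self.simulation is None):
            raise ValueError("exactly one of data_path or simulation must be given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        clf = raw.get("classifier", {})
        spec = BaseClassifierSpec(clf.get("kind", "lda"), dict(clf.get("params", {})))
        data = raw.get("data", {})
        sim = None
        if "simulate" in data:
            sim_kw = dict(data["simulate"] or {})
            for key in ("null_mean_range", "alt_mean_pos", "alt_mean_neg"):
                if key in sim_kw:
                    sim_kw[key] = tuple(sim_kw[key])
            if "alt_cov" in sim_kw:
                sim_kw["alt_cov"] = tuple(tuple(r) for r in sim_kw["alt_cov"])
            sim_kw.setdefault("seed", derive_seed(int(raw["seed"]), _SIM_STREAM))
            sim = SimulationConfig(**sim_kw)
        selection = raw.get("selection", 2)
        if isinstance(selection, str):
            if not selection.startswith("top:"):
                raise ValueError("selection string must look like 'top:<m>'")
            selection = int(selection.split(":", 1)[1])
        return cls(
            seed=int(raw["seed"]),
            out_dir=str(raw["out_dir"]),
            classifier=spec,
            data_path=data.get("path"),
            simulation=sim,
            orientation=data.get("orientation", "variables_as_rows"),
            delimiter=data.get("delimiter"),
            label_file=data.get("label_file"),
            rounds=int(raw.get("rounds", 500)),
            test_fraction=float(raw.get("test_fraction", 0.5)),
            in_bag_fraction=float(raw.get("in_bag_fraction", 0.7)),
            selection=selection,
            threads=int(raw.get("threads", 1)),
            plots=bool(raw.get("plots", False)),
        )


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    return wrap


def _config_echo(config: RunConfig) -> str:
    sel = config.selection
    return (
        f"classifier={config.classifier.kind} params={config.classifier.params} "
        f"rounds={config.rounds} test_fraction={config.test_fraction} "
        f"in_bag_fraction={config.in_bag_fraction} seed={config.seed} selection={sel}"
    )


def run_pipeline(config: RunConfig) -> ValidationReport:
    """Execute all stages, writing artifacts under config.out_dir.

    Returns the test-set :class:`ValidationReport`. Artifacts: ``data.tsv``
    (when simulated), ``split.json``, ``importance.tsv``, ``model.pkl``, and
    ``validation.*`` tables (plus PNGs when ``plots`` is on).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    echo = _config_echo(config)

    if config.simulation is not None:
        matrix: ExpressionMatrix = _stage("simulate")(generate_simulated_dataset, config.simulation)
        _stage("simulate")(write_expression_table, matrix, out / "data.tsv")
        logger.info("simulated %d x %d dataset", matrix.n_samples, matrix.n_variables)
    else:
        matrix = _stage("read")(
            read_expression_table,
            config.data_path,
            orientation=config.orientation,
            delimiter=config.delimiter,
            label_file=config.label_file,
        )
        logger.info("loaded %d x %d dataset", matrix.n_samples, matrix.n_variables)

    split_seed = derive_seed(config.seed, _SPLIT_STREAM)
    split = _stage("split")(split_samples, matrix.labels, config.test_fraction, split_seed)
    save_split(split, out / "split.json", meta={"seed": split_seed, "config": echo})

    rcfg = ResamplingConfig(
        classifier=config.classifier,
        rounds=config.rounds,
        in_bag_fraction=config.in_bag_fraction,
        test_fraction=config.test_fraction,
        seed=config.seed,
    )
    train_X = matrix.values[split.train_indices]
    train_y = matrix.labels[split.train_indices]
    result: ImportanceResult = _stage("importance")(
        accumulate_importance,
        train_X,
        train_y,
        rcfg,
        n_jobs=config.threads,
        variable_names=matrix.variable_names,
    )
    write_importance_table(result, out / "importance.tsv", header_comment=echo)

    if isinstance(config.selection, int):
        ranked = rank_variables(result)
        indices = tuple(idx for idx, _ in ranked[: config.selection])
    else:
        indices = tuple(int(i) for i in config.selection)
        bad = [i for i in indices if not 0 <= i < matrix.n_variables]
        if bad:
            raise PipelineError(
                f"stage 'select' failed: indices {bad} out of range for "
                f"{matrix.n_variables} variables"
            )
    selection = _stage("select")(
        FeatureSelection,
        indices,
        tuple(matrix.variable_names[i] for i in indices),
        matrix.n_variables,
    )
    logger.info("selected variables %s", list(indices))

    model = _stage("train")(train_ensemble, train_X, train_y, selection, rcfg)
    ensemble_mod.save_model(model, out / "model.pkl")

    test_X = matrix.values[split.test_indices]
    test_y = matrix.labels[split.test_indices]
    y_pred = ensemble_predict(model, test_X)
    scores = ensemble_score(model, test_X)
    report = _stage("validate")(
        validation_report, test_y, y_pred, scores, matrix.class_names, seed=config.seed
    )
    _stage("validate")(
        export_plots,
        report,
        test_X[:, list(indices)],
        out / "validation",
        variable_names=list(selection.variable_names or ()),
        sample_ids=[matrix.sample_ids[i] for i in split.test_indices],
        y_true=test_y,
        y_pred=y_pred,
        render=config.plots,
    )
    with open(out / "run_config.json", "w") as fh:
        json.dump({"echo": echo, "selection": list(indices)}, fh, indent=1)
    logger.info(
        "weighted F1 = %.4f, AUC = %.4f", report.weighted.f1, report.auc
    )
    return report
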