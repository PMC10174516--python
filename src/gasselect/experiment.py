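"""Configuration-driven experiment grid: models x population sizes x with/without
wrapper selection, with summary statistics, paired model comparison, and report
export.

Per-cell seeds are ``seed_base XOR cell_index``; the dataset and its 80/20
split depend only on ``(seed_base, run_id)`` so that models within one run are
paired and comparable.  Wall-clock time is recorded in the run manifest only —
never in the results table — so a re-run under the same config digest
reproduces the results CSV byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aqo_core import AQOParams
from .classifiers import REGISTRY_NAMES, ClassifierSpec, make_classifier
from .data_model import Dataset, SplitPair, load_csv, train_test_split
from .evaluation import WilcoxonResult, confusion, macro_metrics, wilcoxon_signed_rank
from .exceptions import PairingError, ParameterError
from .feature_selection import FitnessSpec, apply_mask, select_features
from .hgso_core import HGSOParams, OptimizationTrace
from .synthetic_data import GeneratorSpec, generate_dataset

__all__ = [
    "ExperimentConfig",
    "ResultsTable",
    "run_experiment",
    "summarize",
    "compare_models",
    "export_report",
    "load_config",
    "preset_path",
]

METRIC_COLUMNS = ("accuracy", "recall", "precision", "f_measure", "sensitivity")


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment grid.

    ``lsa_epoch`` is an opaque passthrough kept for config fidelity; it is not
    interpreted anywhere.
    """

    runs: int = 1
    seed_base: int = 0
    domain_range: tuple[float, float] = (-1.0, 1.0)
    epochs: int = 50
    pop_sizes: tuple[int, ...] = (30,)
    models: tuple[str, ...] = REGISTRY_NAMES
    with_hgso: tuple[bool, ...] = (True, False)
    optimizer_strategy: str = "hgso"
    lambda_weight: float = 0.99
    fitness_classifier: str = "knn"
    split_fraction: float = 0.8
    n_clusters: int = 2
    lsa_epoch: int | None = None
    data_source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.runs < 1:
            raise ParameterError("runs must be >= 1")
        if not self.pop_sizes:
            raise ParameterError("pop_sizes must be non-empty")
        if not self.domain_range[0] < self.domain_range[1]:
            raise ParameterError("domain_range low must be < high")
        if self.optimizer_strategy not in ("hgso", "aqo", "hybrid"):
            raise ParameterError(f"unknown strategy {self.optimizer_strategy!r}")
        for m in self.models:
            if m not in REGISTRY_NAMES:
                raise ParameterError(f"unknown model {m!r}")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ResultsTable:
    """Per-cell results plus any recorded failures and optimizer traces."""

    df: pd.DataFrame
    failures: list[dict] = field(default_factory=list)
    traces: dict[str, OptimizationTrace] = field(default_factory=dict)
    config_digest: str = ""
    wall_times: dict[str, float] = field(default_factory=dict)


def load_config(path: str | Path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text())
    for key in ("pop_sizes", "models", "with_hgso", "domain_range"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return ExperimentConfig(**raw)


def preset_path(name: str) -> Path:
    """Path to a bundled preset config (``table3`` or ``section6``)."""
    p = Path(__file__).parent / "configs" / f"{name}.yaml"
    if not p.exists():
        raise ParameterError(f"no preset named {name!r}")
    return p


def _resolve_dataset(config: ExperimentConfig, run_id: int) -> Dataset:
    src = config.data_source
    if "csv" in src:
        return load_csv(src["csv"], src.get("label_column", "outcome"))
    gen = dict(src.get("generator", {}))
    for key in ("class_counts", "class_names", "domain_range"):
        if key in gen and isinstance(gen[key], list):
            gen[key] = tuple(gen[key])
    # the data seed depends only on (seed_base, run) so models pair per run
    data_seed = int(
        np.random.SeedSequence([config.seed_base, run_id]).generate_state(1)[0]
    )
    gen.setdefault("seed", 0)
    gen["seed"] = (gen["seed"] + data_seed) % (2**32)
    dataset, _ = generate_dataset(GeneratorSpec(**gen))
    return dataset


def run_experiment(config: ExperimentConfig, progress=None) -> ResultsTable:
    """Execute the full grid; failed cells are logged and skipped, not fatal."""
    cells = [
        (run, model, pop, flag)
        for run in range(config.runs)
        for model in config.models
        for pop in config.pop_sizes
        for flag in config.with_hgso
    ]
    rows, failures, traces, wall = [], [], {}, {}
    split_cache: dict[int, SplitPair] = {}
    for idx, (run, model, pop, flag) in enumerate(cells):
        cell_seed = config.seed_base ^ idx
        key = f"run{run}_{model}_p{pop}_{'hgso' if flag else 'plain'}"
        t0 = time.perf_counter()
        try:
            if run not in split_cache:
                dataset = _resolve_dataset(config, run)
                data_seed = int(
                    np.random.SeedSequence([config.seed_base, run]).generate_state(1)[0]
                ) % (2**32)
                split_cache[run] = train_test_split(
                    dataset, config.split_fraction, seed=data_seed, stratified=True
                )
            split = split_cache[run]
            n_selected = split.train.n_features
            best_fitness = float("nan")
            if flag:
                fitness_spec = FitnessSpec(
                    lambda_weight=config.lambda_weight,
                    classifier_name=config.fitness_classifier,
                    classifier_seed=cell_seed,
                    split_fraction=config.split_fraction,
                    split_seed=cell_seed,
                    domain_range=config.domain_range,
                )
                hgso = HGSOParams(
                    n_agents=pop,
                    n_clusters=config.n_clusters,
                    max_iter=config.epochs,
                    seed=cell_seed,
                )
                aqo = AQOParams(n_agents=pop, max_iter=config.epochs, seed=cell_seed)
                sel = select_features(
                    split.train,
                    optimizer=config.optimizer_strategy,
                    spec=fitness_spec,
                    params=aqo if config.optimizer_strategy == "aqo" else hgso,
                    aqo_params=aqo if config.optimizer_strategy == "hybrid" else None,
                )
                traces[key] = sel.trace
                n_selected = sel.best_mask.count
                best_fitness = sel.best_fitness
                model_split = SplitPair(
                    apply_mask(split.train, sel.best_mask),
                    apply_mask(split.test, sel.best_mask),
                    split.fraction,
                    split.seed,
                )
            else:
                model_split = split
            handle = make_classifier(ClassifierSpec(model, seed=cell_seed))
            handle.fit(model_split.train)
            predictions = handle.predict(model_split.test.features)
            cm = confusion(
                model_split.test.labels, predictions.labels, model_split.test.class_names
            )
            rec = macro_metrics(cm)
            rows.append(
                {
                    "run_id": run,
                    "model": model,
                    "pop_size": pop,
                    "with_hgso": flag,
                    "seed": cell_seed,
                    "accuracy": rec.accuracy,
                    "recall": rec.recall,
                    "precision": rec.precision,
                    "f_measure": rec.f_measure,
                    "sensitivity": rec.sensitivity,
                    "n_selected": n_selected,
                    "best_fitness": best_fitness,
                }
            )
        except Exception as exc:  # noqa: BLE001 - a cell failure must not kill the grid
            failures.append({"cell": key, "error": f"{type(exc).__name__}: {exc}"})
        wall[key] = time.perf_counter() - t0
        if progress is not None:
            progress(key)
    df = pd.DataFrame(rows)
    return ResultsTable(df, failures, traces, config.digest(), wall)


def summarize(results: ResultsTable, group_by=("model", "with_hgso")) -> pd.DataFrame:
    """Mean/min/max/SD per group (population SD, i.e. ddof=0)."""
    if results.df.empty:
        raise ParameterError("empty results table")
    agg_cols = list(METRIC_COLUMNS) + ["n_selected"]
    grouped = results.df.groupby(list(group_by), sort=True)
    out = grouped[agg_cols].agg(["mean", "min", "max", lambda s: s.std(ddof=0)])
    out.columns = [
        f"{col}_{'sd' if str(stat).startswith('<lambda') else stat}"
        for col, stat in out.columns
    ]
    return out.reset_index()


def compare_models(
    results: ResultsTable, model_a: str, model_b: str, metric: str = "accuracy"
) -> WilcoxonResult:
    """Wilcoxon signed-rank on per-run metric values paired by (run, pop, flag)."""
    keys = ["run_id", "pop_size", "with_hgso"]
    a = results.df[results.df.model == model_a].set_index(keys)[metric]
    b = results.df[results.df.model == model_b].set_index(keys)[metric]
    if len(a) == 0 or len(b) == 0:
        raise PairingError(f"no rows for {model_a!r} or {model_b!r}")
    if sorted(a.index) != sorted(b.index):
        raise PairingError("runs are not paired one-to-one between the two models")
    a = a.sort_index()
    b = b.sort_index()
    return wilcoxon_signed_rank(a.to_numpy(), b.to_numpy())


def export_report(
    results: ResultsTable, out_dir: str | Path, config: ExperimentConfig | None = None
) -> dict:
    """Write results/summary CSVs, per-run convergence CSVs and a manifest.

    Returns the manifest (also written as ``manifest.json``) listing every
    emitted file with its SHA-256 checksum.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    emitted: dict[str, str] = {}

    def write(name: str, text: str) -> None:
        path = out_dir / name
        path.write_text(text)
        emitted[name] = hashlib.sha256(text.encode()).hexdigest()

    write("results.csv", results.df.to_csv(index=False))
    if not results.df.empty:
        write("summary.csv", summarize(results).to_csv(index=False))
    for key, trace in results.traces.items():
        write(f"convergence_{key}.csv", pd.DataFrame(trace.to_rows()).to_csv(index=False))

    import sklearn

    manifest = {
        "files": emitted,
        "config_digest": results.config_digest,
        "sd_convention": "population (ddof=0)",
        "failures": results.failures,
        "wall_times_s": results.wall_times,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    if config is not None:
        manifest["config"] = dataclasses.asdict(config)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
    manifest["files"]["manifest.json"] = "self"
    return manifest
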