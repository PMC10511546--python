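"""End-to-end experiment driver.

One call runs the whole design: synthesise (or load) a cohort, QC-filter it,
harmonise sites, build the similarity networks, assemble the feature sets,
perform the age-stratified split, select algorithm + kernel per feature set
on the internal validation cohort, evaluate the selected model once on the
held-out test cohort, then run the resampling / permutation robustness
stage and the delta bias screens.  Every random stage draws its seed from
the run seed through a spawned seed sequence, and a JSON manifest records
configuration hash, seeds, stage timings and output checksums, including an
access count proving the test cohort was evaluated exactly once per
feature set in the main evaluation.
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

from . import __version__
from .delta import compute_delta, covariate_screen, delta_summary
from .evaluation import (
    MODEL_CELLS,
    EvalMetrics,
    evaluate_predictions,
    permutation_nhst,
    resample_performance,
    select_model,
)
from .features import FEATURE_SET_NAMES, assemble_feature_set, internal_split, stratified_undersample
from .models import fit_model
from .msn import build_msn_for_table
from .preprocessing import apply_qc_filter, harmonize_table, zscore_qa_within_site
from .synthetic import GeneratorConfig, MorphometryTable, QATable, generate_cohort

__all__ = ["RunConfig", "run_experiment", "paper_scale_config"]


@dataclass
class RunConfig:
    """Schema-checked configuration for one experiment run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    qc_z_cut: float = -1.5
    qc_max_fail: int = 1
    harmonisation_eb: bool = True
    msn_density: float | None = None      # None = unthresholded
    train_fraction: float = 0.75
    internal_fraction: float = 5 / 6
    bin_width: float = 0.5
    collapse_below: float = 9.0
    feature_sets: tuple[str, ...] = FEATURE_SET_NAMES
    combined_components: tuple[str, ...] = ()
    model_kwargs: dict = field(default_factory=dict)
    n_partitions: int = 20
    n_permutations: int = 99
    selection_alpha: float = 0.005
    bias_alpha: float = 0.05 / 60
    run_robustness: bool = True
    run_delta: bool = True
    seed: int = 0

    def validate(self) -> None:
        self.generator.validate()
        if not (0 < self.train_fraction < 1) or not (0 < self.internal_fraction < 1):
            raise ValueError("split fractions must lie in (0, 1)")
        if self.msn_density is not None and not (0 < self.msn_density <= 1):
            raise ValueError("msn_density must lie in (0, 1]")
        known = set(FEATURE_SET_NAMES) | {"combined"}
        unknown = set(self.feature_sets) - known
        if unknown:
            raise ValueError(f"unknown feature sets: {sorted(unknown)}")
        if "combined" in self.feature_sets and not self.combined_components:
            raise ValueError("combined feature set requires combined_components")
        if self.n_partitions < 1 or self.n_permutations < 1:
            raise ValueError("n_partitions and n_permutations must be >= 1")

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        gen = payload.pop("generator", {})
        if isinstance(gen, dict):
            gen_fields = {f.name for f in dataclasses.fields(GeneratorConfig)}
            unknown = set(gen) - gen_fields
            if unknown:
                raise ValueError(f"unknown generator config fields: {sorted(unknown)}")
            if "age_range" in gen:
                gen["age_range"] = tuple(gen["age_range"])
            gen = GeneratorConfig(**gen)
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - fields
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("feature_sets", "combined_components"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(generator=gen, **payload)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def paper_scale_config(seed: int = 0) -> RunConfig:
    """The full-scale preset: all ten feature sets, 100 resampling
    partitions and 1000 permutations."""
    return RunConfig(n_partitions=100, n_permutations=1000, seed=seed)


def _hash_config(config: RunConfig) -> str:
    text = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Manifest:
    def __init__(self, config: RunConfig):
        self.data = {
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": _hash_config(config),
            "seeds": {},
            "stages": {},
            "outputs": {},
            "test_cohort_evaluations": {},
            "status": "running",
        }
        self._t0 = None
        self._stage = None

    def start(self, stage: str):
        self._stage = stage
        self._t0 = time.perf_counter()

    def stop(self):
        self.data["stages"][self._stage] = round(time.perf_counter() - self._t0, 4)

    def record_output(self, path: Path):
        self.data["outputs"][path.name] = _checksum(path)

    def write(self, out_dir: Path):
        (out_dir / "manifest.json").write_text(json.dumps(self.data, indent=1, default=str))


def run_experiment(
    config: RunConfig,
    out_dir: str | Path,
    morpho: MorphometryTable | None = None,
    qa: QATable | None = None,
) -> dict:
    """Execute the full pipeline; returns the in-memory results bundle.

    Pass ``morpho``/``qa`` to run on an existing cohort instead of the
    synthetic generator.  All tables are also written under ``out_dir``.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ("generator", "split", "internal", "resample", "permutation"), ss.spawn(5))
    }
    manifest.data["seeds"] = stage_seeds
    results: dict = {}

    try:
        # ------------------------------------------------ generate / load
        manifest.start("generate")
        if morpho is None:
            gen_cfg = dataclasses.replace(config.generator, seed=stage_seeds["generator"])
            morpho, qa, truth = generate_cohort(gen_cfg)
            truth.to_json(out_dir / "ground_truth.json")
            manifest.record_output(out_dir / "ground_truth.json")
        elif qa is None:
            raise ValueError("a QA table is required when supplying a cohort")
        morpho.to_csv(out_dir / "cohort_raw.csv")
        qa.to_csv(out_dir / "qa.csv")
        manifest.stop()

        # ------------------------------------------------------------- QC
        manifest.start("qc")
        qc = zscore_qa_within_site(qa, z_cut=config.qc_z_cut, max_fail=config.qc_max_fail)
        included = apply_qc_filter(qc, z_cut=config.qc_z_cut, max_fail=config.qc_max_fail)
        qc.to_csv(out_dir / "qc_report.tsv", sep="\t", index=False)
        morpho = morpho.subset(included)
        manifest.stop()
        results["n_included"] = len(morpho)

        # ---------------------------------------------------- harmonise
        manifest.start("harmonise")
        morpho, _harm_models = harmonize_table(morpho, eb=config.harmonisation_eb)
        morpho.to_csv(out_dir / "cohort_harmonised.csv")
        manifest.stop()

        # ----------------------------------------------------------- MSN
        manifest.start("msn")
        graphs = build_msn_for_table(morpho, density=config.msn_density)
        manifest.stop()

        # -------------------------------------------------- feature sets
        manifest.start("feature_sets")
        fsets = {}
        for name in config.feature_sets:
            fs = assemble_feature_set(
                name, morpho, graphs,
                components=list(config.combined_components) if name == "combined" else None)
            fsets[fs.name] = fs
        manifest.stop()

        # ---------------------------------------------------------- split
        manifest.start("split")
        ages = morpho.frame["age"].to_numpy(dtype=float)
        sids = morpho.subject_ids
        split = stratified_undersample(
            ages, sids, train_fraction=config.train_fraction,
            bin_width=config.bin_width, collapse_below=config.collapse_below,
            seed=stage_seeds["split"])
        split = internal_split(split, train_fraction=config.internal_fraction,
                               seed=stage_seeds["internal"])
        split.to_csv(out_dir / "split.csv")
        part = split.frame.set_index("subject_id")["partition"]
        part = part.loc[sids].to_numpy()
        idx = {
            "internal_train": np.flatnonzero(part == "internal_train"),
            "internal_validation": np.flatnonzero(part == "internal_validation"),
            "train": np.flatnonzero(part != "test"),
            "test": np.flatnonzero(part == "test"),
        }
        manifest.stop()
        results["split_counts"] = {k: int(v.size) for k, v in idx.items()}

        # ------------------------------------- selection on validation set
        manifest.start("selection")
        selection_rows = []
        chosen: dict[str, tuple[str, str]] = {}
        for name, fs in fsets.items():
            grid: dict[tuple[str, str], EvalMetrics] = {}
            for algorithm, kernel in MODEL_CELLS:
                model = fit_model(algorithm, fs.matrix[idx["internal_train"]],
                                  ages[idx["internal_train"]], kernel=kernel,
                                  **config.model_kwargs)
                val_pred = model.predict(fs.matrix[idx["internal_validation"]])
                val = evaluate_predictions(val_pred, ages[idx["internal_validation"]])
                train_pred = model.predict(fs.matrix[idx["internal_train"]])
                trn = evaluate_predictions(train_pred, ages[idx["internal_train"]])
                grid[(algorithm, kernel)] = val
                selection_rows.append({
                    "feature_set": name, "algorithm": algorithm, "kernel": kernel,
                    "train_mae": trn.mae, "train_pred_r2": trn.pred_r2,
                    "validation_mae": val.mae, "validation_pred_r2": val.pred_r2,
                })
            chosen[name] = select_model(grid)
        selection_table = pd.DataFrame(selection_rows)
        selection_table["chosen"] = [
            chosen[r.feature_set] == (r.algorithm, r.kernel)
            for r in selection_table.itertuples()
        ]
        selection_table.to_csv(out_dir / "selection.tsv", sep="\t", index=False)
        manifest.record_output(out_dir / "selection.tsv")
        manifest.stop()
        results["selection"] = chosen

        # --------------------------------- single evaluation on test cohort
        manifest.start("test_evaluation")
        test_rows = []
        predictions: dict[str, np.ndarray] = {}
        for name, fs in fsets.items():
            algorithm, kernel = chosen[name]
            model = fit_model(algorithm, fs.matrix[idx["train"]], ages[idx["train"]],
                              kernel=kernel, **config.model_kwargs)
            train_m = evaluate_predictions(model.predict(fs.matrix[idx["train"]]),
                                           ages[idx["train"]])
            test_pred = model.predict(fs.matrix[idx["test"]])
            manifest.data["test_cohort_evaluations"][name] = (
                manifest.data["test_cohort_evaluations"].get(name, 0) + 1)
            test_m = evaluate_predictions(test_pred, ages[idx["test"]])
            predictions[name] = test_pred
            test_rows.append({
                "feature_set": name, "algorithm": algorithm, "kernel": kernel,
                "train_mae": train_m.mae, "train_pred_r2": train_m.pred_r2,
                "test_mae": test_m.mae, "test_pred_r2": test_m.pred_r2,
            })
        test_table = pd.DataFrame(test_rows)
        manifest.stop()

        # ------------------------------------- robustness and permutations
        if config.run_robustness:
            manifest.start("robustness")
            rob_rows = []
            for name, fs in fsets.items():
                algorithm, kernel = chosen[name]
                rob = resample_performance(
                    fs.matrix, ages, algorithm, kernel,
                    n_partitions=config.n_partitions, seed=stage_seeds["resample"],
                    train_fraction=config.train_fraction, bin_width=config.bin_width,
                    collapse_below=config.collapse_below, model_kwargs=config.model_kwargs)
                p, _ = permutation_nhst(
                    fs.matrix, ages, idx["train"], idx["test"], algorithm, kernel,
                    observed_stat=rob.mean_pred_r2, n_perm=config.n_permutations,
                    seed=stage_seeds["permutation"], model_kwargs=config.model_kwargs)
                rob.p_value = p
                rob.n_permutations = config.n_permutations
                rob.alpha = config.selection_alpha
                rob_rows.append({
                    "feature_set": name,
                    "mean_pred_r2": rob.mean_pred_r2,
                    "ci_low": rob.ci_low, "ci_high": rob.ci_high,
                    "n_partitions": rob.n_effective,
                    "p_value": p, "n_permutations": config.n_permutations,
                    "significant": rob.significant,
                })
                results.setdefault("robustness", {})[name] = rob
            rob_table = pd.DataFrame(rob_rows)
            test_table = test_table.merge(rob_table, on="feature_set")
            manifest.stop()
        test_table.to_csv(out_dir / "test_performance.tsv", sep="\t", index=False)
        manifest.record_output(out_dir / "test_performance.tsv")
        results["test_performance"] = test_table

        # -------------------------------------------------- delta screens
        if config.run_delta:
            manifest.start("delta")
            meta_test = morpho.frame.iloc[idx["test"]][["subject_id", "age", "sex", "iq"]]
            efc_map = qa.frame.set_index("subject_id")["efc"]
            cov = pd.DataFrame({
                "efc": efc_map.loc[meta_test["subject_id"]].to_numpy(),
                "iq": meta_test["iq"].to_numpy(),
                "sex": meta_test["sex"].to_numpy(),
            })
            delta_tables = {}
            for name in fsets:
                dt = compute_delta(predictions[name], ages[idx["test"]],
                                   meta_test["subject_id"].to_numpy(), covariates=cov)
                dt.to_csv(out_dir / f"delta_{name.replace(':', '_')}.csv", index=False)
                delta_tables[name] = dt
            screen, mean_r = covariate_screen(delta_tables, alpha=config.bias_alpha)
            screen.to_csv(out_dir / "bias_screen.tsv", sep="\t", index=False)
            manifest.record_output(out_dir / "bias_screen.tsv")
            results["delta_tables"] = delta_tables
            results["bias_screen"] = screen
            results["mean_pearson_r"] = mean_r
            results["delta_summaries"] = {n: delta_summary(t) for n, t in delta_tables.items()}
            manifest.stop()

        manifest.data["status"] = "completed"
    except Exception:
        manifest.data["status"] = "failed"
        manifest.write(out_dir)
        raise
    manifest.write(out_dir)
    results["manifest"] = manifest.data
    return results
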