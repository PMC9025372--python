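"""End-to-end orchestration with resumable stage artifacts.

Stages run in order — simulate (or load), filter_mi, boruta, mcfs, ifs
(both classifiers), rules — each writing its artifact into the output
directory.  A manifest records every stage's parameters and the content
hashes of its inputs and outputs; re-running with an identical
configuration skips completed stages, and any change to a stage's
parameters or inputs invalidates it and everything downstream.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io
from .boruta import BorutaConfig, run_boruta
from .ifs import ClassifierSpec, IFSConfig, run_ifs
from .mcfs import MCFSConfig, run_mcfs
from .relevance import DiscretizationScheme, max_relevance_filter
from .rules import extract_rules, fit_final_tree
from .simulate import SynthConfig, read_truth, simulate_profiles, write_truth

logger = logging.getLogger(__name__)

STAGES = ("simulate", "filter_mi", "boruta", "mcfs", "ifs", "rules")

# fixed per-stage offsets for deriving independent seeds from the global one
_STAGE_SEED = {name: 1000 + i for i, name in enumerate(STAGES)}


@dataclass
class PipelineConfig:
    """Nested stage configurations plus input paths and the global seed.

    With ``expression_path`` unset the synthetic generator provides the
    input; otherwise the matrix (+ ``labels_path``) is loaded from disk.
    """

    seed: int = 0
    expression_path: str | None = None
    labels_path: str | None = None
    synth: SynthConfig = field(default_factory=SynthConfig)
    mi_threshold: float = 0.001
    mi_alpha: float = 1.0
    boruta: BorutaConfig = field(default_factory=BorutaConfig)
    mcfs: MCFSConfig = field(default_factory=MCFSConfig)
    ifs_step: int = 5
    ifs_max_features: int = 1000
    ifs_folds: int = 10
    ifs_delta: float = 0.02
    rf_trees: int = 100
    smote_k: int = 5
    rules_balance: bool = True
    rules_top_n: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in doc.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, (SynthConfig, BorutaConfig, MCFSConfig)):
                setattr(cfg, key, type(current)(**val))
            else:
                setattr(cfg, key, val)
        return cfg

    def stage_seed(self, stage: str) -> int:
        return int(np.random.SeedSequence([self.seed, _STAGE_SEED[stage]]).generate_state(1)[0] % (2**31 - 1))

    def stage_params(self, stage: str) -> dict:
        if stage == "simulate":
            return asdict(self.synth) | {"seed": self.stage_seed(stage),
                                         "expression_path": self.expression_path,
                                         "labels_path": self.labels_path}
        if stage == "filter_mi":
            return {"threshold": self.mi_threshold, "alpha": self.mi_alpha}
        if stage == "boruta":
            return asdict(self.boruta) | {"seed": self.stage_seed(stage)}
        if stage == "mcfs":
            return asdict(self.mcfs) | {"seed": self.stage_seed(stage)}
        if stage == "ifs":
            return {"step": self.ifs_step, "max_features": self.ifs_max_features,
                    "n_folds": self.ifs_folds, "delta": self.ifs_delta,
                    "rf_trees": self.rf_trees, "smote_k": self.smote_k,
                    "seed": self.stage_seed(stage)}
        if stage == "rules":
            return {"balance": self.rules_balance, "top_n": self.rules_top_n,
                    "smote_k": self.smote_k, "seed": self.stage_seed(stage)}
        raise KeyError(stage)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_params(params: dict) -> str:
    return hashlib.sha256(json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


_STAGE_OUTPUTS = {
    "simulate": ["expression.tsv", "labels.tsv", "truth.json"],
    "filter_mi": ["mi_scores.tsv", "retained_mi.txt"],
    "boruta": ["boruta_result.json"],
    "mcfs": ["ranked_features.tsv"],
    "ifs": ["ifs_curve_rf.tsv", "ifs_curve_rf.meta.json",
            "ifs_curve_dt.tsv", "ifs_curve_dt.meta.json", "ifs_curve.tsv",
            "ifs_curve.meta.json"],
    "rules": ["rules.json", "rules.txt"],
}
_STAGE_INPUTS = {
    "simulate": [],
    "filter_mi": ["expression.tsv", "labels.tsv"],
    "boruta": ["expression.tsv", "labels.tsv", "retained_mi.txt"],
    "mcfs": ["expression.tsv", "labels.tsv", "boruta_result.json"],
    "ifs": ["expression.tsv", "labels.tsv", "ranked_features.tsv"],
    "rules": ["expression.tsv", "labels.tsv", "ranked_features.tsv",
              "ifs_curve_dt.meta.json"],
}


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Execute (or resume) every stage; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = {"stages": {}}
    if manifest_path.exists():
        with open(manifest_path) as fh:
            manifest = json.load(fh)

    executed = []
    for stage in STAGES:
        params = config.stage_params(stage)
        try:
            inputs = {}
            for rel in _STAGE_INPUTS[stage]:
                p = out / rel
                if not p.exists():
                    raise StageError(stage, f"missing input artifact {p}")
                inputs[rel] = _hash_file(p)
        except StageError:
            raise
        key = _hash_params({"params": params, "inputs": inputs})
        entry = manifest["stages"].get(stage)
        if entry and entry.get("key") == key:
            # completed with identical params+inputs: verify outputs, skip
            for rel, h in entry.get("outputs", {}).items():
                p = out / rel
                if not p.exists() or _hash_file(p) != h:
                    raise StageError(stage, f"artifact {p} is missing or corrupted")
            logger.info("stage %s: up to date, skipping", stage)
            continue
        logger.info("stage %s: running", stage)
        try:
            _run_stage(stage, config, out)
        except StageError:
            raise
        except Exception as e:  # halt with the stage name, earlier artifacts intact
            raise StageError(stage, str(e)) from e
        manifest["stages"][stage] = {
            "key": key,
            "params": params,
            "inputs": inputs,
            "outputs": {rel: _hash_file(out / rel) for rel in _STAGE_OUTPUTS[stage]},
        }
        executed.append(stage)
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
            fh.write("\n")
    manifest["executed_now"] = executed
    return manifest


def _run_stage(stage: str, config: PipelineConfig, out: Path) -> None:
    if stage == "simulate":
        if config.expression_path:
            matrix = io.read_expression(config.expression_path)
            labels = io.read_labels(config.labels_path, cell_ids=matrix.cell_ids)
            io.write_expression_tsv(matrix, out / "expression.tsv")
            io.write_labels(labels, matrix.cell_ids, out / "labels.tsv")
            (out / "truth.json").write_text("{}\n")
        else:
            synth = SynthConfig(**{**asdict(config.synth), "seed": config.stage_seed(stage)})
            matrix, labels, truth = simulate_profiles(synth)
            io.write_expression_tsv(matrix, out / "expression.tsv")
            io.write_labels(labels, matrix.cell_ids, out / "labels.tsv")
            write_truth(truth, out / "truth.json")
        return

    matrix = io.read_expression(out / "expression.tsv")
    labels = io.read_labels(out / "labels.tsv", cell_ids=matrix.cell_ids)

    if stage == "filter_mi":
        res = max_relevance_filter(
            matrix, labels, threshold=config.mi_threshold,
            scheme=DiscretizationScheme(alpha=config.mi_alpha),
        )
        with open(out / "mi_scores.tsv", "w") as fh:
            fh.write("gene\tmi_bits\n")
            for g in matrix.gene_ids:
                fh.write(f"{g}\t{res.mi_scores[g]!r}\n")
        (out / "retained_mi.txt").write_text("".join(g + "\n" for g in res.retained))
        return

    if stage == "boruta":
        retained = (out / "retained_mi.txt").read_text().split()
        cfg = BorutaConfig(**{**asdict(config.boruta), "seed": config.stage_seed(stage)})
        res = run_boruta(matrix.subset_genes(retained), labels, cfg)
        doc = {
            "confirmed": sorted(res.confirmed),
            "rejected": sorted(res.rejected),
            "tentative": sorted(res.tentative),
            "passed": [g for g in retained
                       if g in res.confirmed or (cfg.include_tentative and g in res.tentative)],
        }
        with open(out / "boruta_result.json", "w") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
        return

    if stage == "mcfs":
        with open(out / "boruta_result.json") as fh:
            passed = json.load(fh)["passed"]
        if not passed:
            raise ValueError("no features passed the shadow-feature stage")
        cfg = MCFSConfig(**{**asdict(config.mcfs), "seed": config.stage_seed(stage)})
        ranked = run_mcfs(matrix.subset_genes(passed), labels, cfg)
        io.write_ranked_features(ranked, out / "ranked_features.tsv")
        return

    if stage == "ifs":
        ranked = io.read_ranked_features(out / "ranked_features.tsv")
        seed = config.stage_seed(stage)
        curves = {}
        for kind, tag in (("random_forest", "rf"), ("decision_tree", "dt")):
            cfg = IFSConfig(
                step=config.ifs_step, max_features=config.ifs_max_features,
                n_folds=config.ifs_folds, delta=config.ifs_delta,
                classifier=ClassifierSpec(kind=kind, n_trees=config.rf_trees, seed=seed),
                k_neighbors=config.smote_k, seed=seed,
            )
            curve = run_ifs(matrix, labels, ranked, cfg)
            io.write_ifs_curve(curve, out / f"ifs_curve_{tag}.tsv")
            curves[tag] = curve
        # the headline curve (RF, the stronger classifier) under the generic name
        io.write_ifs_curve(curves["rf"], out / "ifs_curve.tsv")
        return

    if stage == "rules":
        ranked = io.read_ranked_features(out / "ranked_features.tsv")
        with open(out / "ifs_curve_dt.meta.json") as fh:
            k = json.load(fh)["optimal_k"]
        prefix = ranked.gene_ids[:k]
        seed = config.stage_seed(stage)
        tree = fit_final_tree(matrix, labels, prefix, balance=config.rules_balance,
                              seed=seed, k_neighbors=config.smote_k)
        rules = extract_rules(tree, matrix, labels, prefix, top_n=config.rules_top_n)
        io.write_rules(rules, out / "rules.json", out / "rules.txt")
        return

    raise KeyError(stage)
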