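"""End-to-end pipeline: normalise, cluster, build networks, detect
modules, select genes, classify, and write every intermediate artifact.

A run is fully described by a :class:`PipelineConfig` (loadable from
YAML) plus an output directory; identical config and seed produce
identical artifacts apart from the timing entries of the manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import cross_validate
from .fcm import fcm_fit
from .hsic import ibo_select
from .io import (
    ExpressionMatrix,
    TwoChannelTable,
    impute_missing,
    log_ratio_normalize,
    read_expression_table,
    write_matrix_tsv,
)
from .modules import dissimilarity, pam_dtc
from .network import differential_network, pearson_matrix, threshold_network
from .simulate import generate_dataset

__all__ = ["PipelineConfig", "run_pipeline"]


_DEFAULTS = {
    "normalize": {"summary": "median", "subtract_background": False},
    "fcm": {"c": 4, "m": 2.0, "tol": 1e-5, "max_iter": 300},
    "network": {"tau": 0.8, "mode": "absolute"},
    "modules": {"cut_height": None, "min_module_size": 5, "k_split": 2,
                "linkage": "average"},
    "selection": {"k": 10, "n_bats": 30, "n_iter": 100,
                  "candidates": "all", "label_kernel": "delta",
                  "gene_kernel": "linear"},
    "classifier": {"kernel": "rbf", "C": 1.0},
    "cv": {"folds": 5},
}


@dataclass
class PipelineConfig:
    """Validated pipeline parameters (see module docstring)."""

    seed: int
    input: dict | None = None       # {"path": ..., "format": ...}
    simulate: dict | None = None    # kwargs for generate_dataset
    normalize: dict = field(default_factory=dict)
    fcm: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    modules: dict = field(default_factory=dict)
    selection: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config missing required field 'seed'")
        if (self.input is None) == (self.simulate is None):
            raise ValueError(
                "config must set exactly one of 'input' or 'simulate'"
            )
        if self.input is not None:
            for key in ("path", "format"):
                if key not in self.input:
                    raise ValueError(f"config missing required field 'input.{key}'")
        for section, defaults in _DEFAULTS.items():
            merged = dict(defaults)
            merged.update(getattr(self, section))
            setattr(self, section, merged)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config missing required field 'seed'")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "input": self.input, "simulate": self.simulate,
            "normalize": self.normalize, "fcm": self.fcm,
            "network": self.network, "modules": self.modules,
            "selection": self.selection, "classifier": self.classifier,
            "cv": self.cv,
        }


def _load_expression(config: PipelineConfig) -> ExpressionMatrix:
    if config.simulate is not None:
        kwargs = dict(config.simulate)
        kwargs.setdefault("seed", config.seed)
        if "blocks" in kwargs:
            kwargs["blocks"] = tuple(kwargs["blocks"])
        x, _, _ = generate_dataset(**kwargs)
        return x
    data = read_expression_table(config.input["path"], config.input["format"])
    if isinstance(data, TwoChannelTable):
        return log_ratio_normalize(data, **config.normalize)
    return data


def _candidate_genes(kind: str, x, modules_result, diff_net) -> list[str]:
    if kind == "all":
        return list(x.gene_ids)
    if kind == "medoids":
        return sorted(modules_result.medoids.values())
    if kind == "differential":
        genes = sorted({g for e in diff_net.edge_set() for g in e})
        return genes if genes else list(x.gene_ids)
    raise ValueError(f"unknown candidate set {kind!r}")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage and write artifacts to ``outdir``.

    Returns the manifest dictionary (also written as manifest.json).
    Stage failures raise with the stage name prefixed; artifacts written
    before the failure are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "batsel",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "timings_s": {},
    }

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            _write_manifest(manifest, outdir)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["timings_s"][name] = round(time.perf_counter() - t0, 4)
        return result

    # --- data -------------------------------------------------------------
    def load():
        x = _load_expression(config)
        x = impute_missing(x)
        write_matrix_tsv(x, outdir / "expression.tsv")
        return x

    x = stage("normalize", load)
    manifest["stages"]["normalize"] = {
        "n_genes": x.n_genes, "n_samples": x.n_samples,
        "artifact": "expression.tsv",
    }

    # --- fuzzy C-means ----------------------------------------------------
    def run_fcm():
        part = fcm_fit(x, seed=config.seed, **config.fcm)
        part.to_tsv(outdir / "fcm_partition.tsv")
        return part

    part = stage("fcm", run_fcm)
    manifest["stages"]["fcm"] = {
        "c": part.c, "iterations": len(part.J_trace),
        "final_objective": part.J_trace[-1], "artifact": "fcm_partition.tsv",
    }

    # --- coexpression networks --------------------------------------------
    def run_networks():
        tau, mode = config.network["tau"], config.network["mode"]
        nets = {}
        if x.labels is not None:
            for state, lab in (("normal", 0), ("tumor", 1)):
                R = pearson_matrix(x, sample_subset=lab)
                nets[state] = threshold_network(R, x.gene_ids, tau, mode)
                nets[state].to_edgelist_tsv(outdir / f"network_{state}.tsv")
            diff = differential_network(nets["normal"], nets["tumor"])
            diff.to_edgelist_tsv(outdir / "network_differential.tsv")
        else:
            R = pearson_matrix(x)
            nets["all"] = threshold_network(R, x.gene_ids, tau, mode)
            nets["all"].to_edgelist_tsv(outdir / "network_all.tsv")
            diff = None
        return nets, diff

    nets, diff_net = stage("network", run_networks)
    manifest["stages"]["network"] = {
        "tau": config.network["tau"], "mode": config.network["mode"],
        "edges": {name: net.n_edges for name, net in nets.items()},
        "differential_edges": None if diff_net is None else diff_net.n_edges,
    }

    # --- module detection --------------------------------------------------
    def run_modules():
        R = pearson_matrix(x)
        D = dissimilarity(R, mode=config.network["mode"])
        mods = pam_dtc(
            D, x.gene_ids, seed=config.seed,
            cut_height=config.modules["cut_height"],
            min_module_size=config.modules["min_module_size"],
            k_split=config.modules["k_split"],
            linkage_method=config.modules["linkage"],
        )
        mods.to_tsv(outdir / "modules.tsv")
        return mods

    mods = stage("modules", run_modules)
    manifest["stages"]["modules"] = {
        "n_modules": mods.n_modules,
        "medoids": {str(k): v for k, v in sorted(mods.medoids.items())},
        "artifact": "modules.tsv",
    }

    # --- gene selection -----------------------------------------------------
    sel_cfg = dict(config.selection)
    candidates_kind = sel_cfg.pop("candidates")

    def run_selection():
        if x.labels is None:
            raise ValueError("gene selection requires sample labels")
        cand = _candidate_genes(candidates_kind, x, mods, diff_net)
        idx = [x.gene_index(g) for g in cand]
        k = min(sel_cfg["k"], len(cand))
        result = ibo_select(
            x.values[idx], x.labels, k=k, gene_ids=cand,
            n_bats=sel_cfg["n_bats"], n_iter=sel_cfg["n_iter"],
            seed=config.seed, label_kernel=sel_cfg["label_kernel"],
            gene_kernel=sel_cfg["gene_kernel"],
        )
        result.to_tsv(outdir / "selection.tsv")
        result.to_json(outdir / "selection.json")
        return cand, result

    candidates, selection = stage("select", run_selection)
    manifest["stages"]["select"] = {
        "candidates": candidates_kind, "n_candidates": len(candidates),
        "k": len(selection.selected_genes),
        "selected_genes": selection.selected_genes,
        "hsic_score": selection.hsic_score,
        "artifacts": ["selection.tsv", "selection.json"],
    }

    # --- nested-CV classification ------------------------------------------
    def run_classify():
        cand_idx = [x.gene_index(g) for g in candidates]
        cand_ids = list(candidates)
        k = min(sel_cfg["k"], len(cand_ids))

        def selector(G_train, y_train, fold_seed):
            sub = G_train[cand_idx]
            res = ibo_select(
                sub, y_train, k=k, gene_ids=cand_ids,
                n_bats=sel_cfg["n_bats"], n_iter=sel_cfg["n_iter"],
                seed=fold_seed, label_kernel=sel_cfg["label_kernel"],
                gene_kernel=sel_cfg["gene_kernel"],
            )
            mask = np.zeros(G_train.shape[0], dtype=bool)
            mask[[cand_idx[i] for i in np.flatnonzero(res.mask)]] = True
            return mask

        report = cross_validate(
            x, x.labels, selector=selector,
            kernel=config.classifier["kernel"], C=config.classifier["C"],
            folds=config.cv["folds"], seed=config.seed,
        )
        payload = {
            "metrics_percent": report.as_percent(),
            "counts": {
                "tpv": report.counts.tpv, "fpv": report.counts.fpv,
                "fnv": report.counts.fnv, "tnv": report.counts.tnv,
            },
            "mean_tpr": report.mean_tpr,
            "auc": report.auc,
            "roc_points": report.roc_points,
        }
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(outdir / "roc_points.tsv", "w", encoding="utf-8") as fh:
            fh.write("fpr\ttpr\n")
            for fpr, tpr in report.roc_points:
                fh.write(f"{fpr!r}\t{tpr!r}\n")
        return report

    report = stage("classify", run_classify)
    manifest["stages"]["classify"] = {
        "folds": config.cv["folds"],
        "metrics_percent": report.as_percent(),
        "artifacts": ["report.json", "roc_points.tsv"],
    }

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
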