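"""End-to-end pipeline: simulate -> cohort -> match -> featurize -> train ->
evaluate -> interpret, per (site, drug) cell, with a JSON run manifest.

Each (site, drug) cell is processed independently, mirroring a distributed
research network in which every hospital trains its own per-drug model.
Cells with fewer cases than ``min_cases`` are skipped with a logged reason.
A single global seed fans out deterministically to per-stage seeds through
``numpy.random.SeedSequence`` with a fixed (site, drug, stage) spawn key.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import interpret as interpret_mod
from .config import (AkiCriteria, ConfigurationError, ImvHyperparams,
                     RunConfig, SiteSimConfig, WindowSpec)
from .evaluate import compute_metrics
from .features import (WindowScaler, build_grid, build_window_tensor,
                       select_predictors, split_622, variable_catalog)
from .matching import PropensityMatcher
from .model import IMVLSTMClassifier
from .synthetic import CdmBundle, generate_site, read_bundle

log = logging.getLogger("akiwatch")

_STAGES = ("simulate", "match", "split", "train", "evaluate")


def stage_seed(global_seed: int, site: str, drug: str, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 (stable across processes)."""
    digest = hashlib.sha256(f"{site}|{drug}|{stage}".encode()).digest()
    key = int.from_bytes(digest[:4], "big") & 0x7FFFFFFF
    ss = np.random.SeedSequence([int(global_seed), key])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _run_cell(bundle: CdmBundle, drug: str, cfg: RunConfig) -> dict:
    """Cohort -> match -> features -> train -> evaluate for one cell."""
    site = bundle.site_id
    result: dict = {"site_id": site, "drug": drug, "status": "ok"}

    cohort = cohort_mod.apply_eligibility(bundle, drug, cfg.criteria)
    labeled = cohort[cohort["label"].notna()]
    n_cases = int((labeled["label"] == "case").sum())
    result["counts"] = {
        "exposed": int(len(cohort)),
        "excluded": {r: int((cohort["exclusion_reason"] == r).sum())
                     for r in cohort_mod.EXCLUSION_REASONS},
        "cases": n_cases,
        "controls": int((labeled["label"] == "control").sum()),
    }
    result["cohort"] = cohort
    if n_cases < cfg.min_cases:
        result["status"] = "skipped"
        result["reason"] = (f"cases={n_cases} < min_cases={cfg.min_cases}")
        log.info("cell %s/%s skipped: %s", site, drug, result["reason"])
        return result

    # propensity matching within site
    cov = cohort_mod.person_covariates(cohort, bundle)
    cov = cov.dropna(subset=["age", "baseline_scr"]).set_index("person_id")
    y = (cov["label"] == "case").astype(int)
    matcher = PropensityMatcher(k=cfg.match_ratio)
    matcher.fit(cov[["age", "male", "baseline_scr"]], y)
    matches = matcher.match()
    result["balance"] = matcher.balance()
    matched_ids = set(matches["case_id"]) | set(matches["control_id"])
    matched_cohort = labeled[labeled["person_id"].isin(matched_ids)]
    result["counts"]["matched_cases"] = int(matches["case_id"].nunique())
    result["counts"]["matched_controls"] = int(len(matches))
    result["matches"] = matches

    # featurization on the matched cohort
    catalog = variable_catalog(bundle, exclude_drugs=(drug,))
    grid = build_grid(bundle, matched_cohort, catalog,
                      n_days=cfg.criteria.followup_days + 1,
                      start_day=-cfg.window.lookback)
    selected = select_predictors(matched_cohort, grid, alpha=cfg.alpha)
    result["selected"] = selected
    keep = selected.loc[selected["selected"], "variable"].tolist()
    if len(keep) < 2:  # degenerate screen: keep all observed variables
        keep = list(grid.variables)
    keep_idx = [grid.variables.index(v) for v in keep]
    grid.variables = keep
    grid.kinds = [grid.kinds[i] for i in keep_idx]
    grid.data = {pid: mat[:, keep_idx] for pid, mat in grid.data.items()}

    windows = build_window_tensor(grid, matched_cohort, cfg.window)
    result["counts"]["windows"] = int(len(windows))
    result["counts"]["positive_windows"] = int(windows.labels.sum())
    if windows.labels.sum() == 0 or windows.labels.sum() == len(windows):
        result["status"] = "skipped"
        result["reason"] = "windows are single-class"
        return result

    tr, va, te = split_622(windows, seed=stage_seed(cfg.seed, site, drug, "split"))
    result["counts"]["split"] = {"train": len(tr), "val": len(va),
                                 "test": len(te)}
    if tr.labels.min() == tr.labels.max() or len(va) == 0 or len(te) == 0:
        result["status"] = "skipped"
        result["reason"] = "degenerate split"
        return result
    scaler = WindowScaler().fit(tr)
    tr_s, va_s, te_s = (scaler.transform(w) for w in (tr, va, te))

    hp = cfg.hyperparams
    clf = IMVLSTMClassifier(
        hidden_per_var=hp.hidden_per_var, epochs=hp.epochs, batch=hp.batch,
        lr=hp.lr, patience=hp.patience, class_weighting=hp.class_weighting,
        threshold=hp.threshold,
        seed=stage_seed(cfg.seed, site, drug, "train"))
    clf.fit(tr_s.data, tr_s.labels, X_val=va_s.data, y_val=va_s.labels)
    result["model"] = clf
    result["scaler"] = scaler
    result["variables"] = list(windows.variables)

    eval_seed = stage_seed(cfg.seed, site, drug, "evaluate")
    for split_name, ws in (("test", te_s), ("val", va_s)):
        if ws.labels.min() == ws.labels.max():
            continue
        p = clf.predict_proba(ws.data)[:, 1]
        result[f"metrics_{split_name}"] = compute_metrics(
            p, ws.labels, threshold=hp.threshold, n_boot=200, seed=eval_seed)

    # attention pooled over the test split's case windows
    case_mask = te_s.meta["is_case"].to_numpy(bool)
    pool = te_s.data[case_mask] if case_mask.any() else te_s.data
    _, alphas, betas = clf.attention(pool)
    result["attention"] = interpret_mod.aggregate_attention(
        alphas, betas, windows.variables)
    return result


def run_pipeline(config: RunConfig,
                 bundles: Optional[Sequence[CdmBundle]] = None,
                 write: bool = True) -> dict:
    """Run every (site, drug) cell and pooled analyses; return the manifest.

    ``bundles`` may be passed to reuse pre-generated data; otherwise each
    site's bundle is simulated from its :class:`SiteSimConfig` (with the
    site seed offset by the global seed).
    """
    out_dir = Path(config.output_dir)
    if write:
        out_dir.mkdir(parents=True, exist_ok=True)

    if bundles is None:
        bundles = []
        for sc in config.sites:
            sc2 = dataclasses.replace(
                sc, seed=stage_seed(config.seed, sc.site_id, "*", "simulate"))
            log.info("simulating site %s (n=%d)", sc2.site_id, sc2.n_patients)
            bundles.append(generate_site(sc2))

    manifest: dict = {"seed": config.seed, "cells": {}, "skipped": {}}
    cell_results = []
    for bundle in bundles:
        for drug in config.drugs:
            log.info("cell %s/%s ...", bundle.site_id, drug)
            res = _run_cell(bundle, drug, config)
            cell_results.append(res)
            key = f"{bundle.site_id}/{drug}"
            entry = {"status": res["status"], "counts": res["counts"]}
            if res["status"] == "skipped":
                entry["reason"] = res["reason"]
                manifest["skipped"][key] = res["reason"]
            else:
                for split in ("test", "val"):
                    mr = res.get(f"metrics_{split}")
                    if mr is not None:
                        entry[f"metrics_{split}"] = dataclasses.asdict(mr)
            manifest["cells"][key] = entry

    # pooled analyses over completed cohorts
    cohorts = [r["cohort"] for r in cell_results]
    pooled_cohort = (pd.concat(cohorts, ignore_index=True)
                     if cohorts else pd.DataFrame())
    onset = interpret_mod.onset_stats(pooled_cohort, min_cell=config.min_cases)
    manifest["onset"] = {
        "overall": onset["overall"],
        "per_drug": interpret_mod.per_drug_onset(pooled_cohort)
        .to_dict("records"),
    }

    trained = [r for r in cell_results if r["status"] == "ok"]
    manifest["n_models"] = len(trained)
    if trained:
        aurocs = [r["metrics_test"].auroc for r in trained
                  if "metrics_test" in r]
        manifest["mean_test_auroc"] = float(np.mean(aurocs)) if aurocs else None

        # pooled attention surface across models (shared variables only)
        weekly = [r["attention"].weekly for r in trained]
        pooled_attention = (pd.concat(weekly)
                            .groupby(level=0).mean())
        manifest["attention_top_variable"] = (
            pooled_attention.mean(axis=1).idxmax())
    else:
        pooled_attention = pd.DataFrame()

    if write:
        pooled_cohort.to_csv(out_dir / "cohort.csv", index=False)
        if len(pooled_attention):
            pooled_attention.to_csv(out_dir / "attention_weekly.csv")
        if len(onset["cells"]):
            onset["cells"].to_csv(out_dir / "onset_cells.csv", index=False)
        for r in trained:
            tag = f"{r['site_id']}_{r['drug']}"
            r["balance"].to_csv(out_dir / f"balance_{tag}.csv", index=False)
            if "metrics_test" in r:
                r["metrics_test"].to_json(out_dir / f"metrics_{tag}.json")
            r["model"].save(out_dir / f"model_{tag}.npz",
                            variables=r["variables"], scaler=r["scaler"])
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    manifest["_results"] = cell_results
    manifest["_attention_weekly"] = pooled_attention
    return manifest


# ---------------------------------------------------------------------------
# configuration files

_SECTION_TYPES = {"criteria": AkiCriteria, "window": WindowSpec,
                  "hyperparams": ImvHyperparams}


def _from_dict(cls, data: dict, where: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in {where}")
    return cls(**data)


def parse_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration; unknown keys rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    kwargs: dict = {}
    for key, val in raw.items():
        if key == "sites":
            sites = []
            for i, sd in enumerate(val):
                if "onset_lognormal" in sd:
                    sd["onset_lognormal"] = {
                        k: tuple(v) for k, v in sd["onset_lognormal"].items()}
                sites.append(_from_dict(SiteSimConfig, sd, f"sites[{i}]"))
            kwargs["sites"] = sites
        elif key in _SECTION_TYPES:
            kwargs[key] = _from_dict(_SECTION_TYPES[key], val, key)
        elif key in {f.name for f in dataclasses.fields(RunConfig)}:
            kwargs[key] = val
        else:
            raise ConfigurationError(f"unknown top-level key {key!r}")
    return RunConfig(**kwargs)


def write_config(config: RunConfig, path) -> None:
    """Serialize a RunConfig to YAML (inverse of :func:`parse_config`)."""
    raw = dataclasses.asdict(config)
    raw["sites"] = [dataclasses.asdict(s) for s in config.sites]
    for s in raw["sites"]:
        s["onset_lognormal"] = {k: list(v)
                                for k, v in s["onset_lognormal"].items()}
    raw["drugs"] = list(config.drugs)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def load_bundles(paths: Sequence[str]) -> list[CdmBundle]:
    return [read_bundle(p) for p in paths]
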