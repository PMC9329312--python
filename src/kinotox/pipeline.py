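"""End-to-end workflow: integrate -> fit -> screen -> evaluate, with a run
manifest sufficient to replay any run bit-identically.

A run is driven by a single config mapping (usually loaded from YAML) with a
``simulation`` block (synthetic inputs) or an ``inputs`` block (CSV layout on
disk), plus optional ``forest``, ``screen``, ``stratify`` and ``evaluate``
blocks.  Every random draw descends from the master seed through a
hierarchical SeedSequence scheme (master -> stage -> tree/iteration), so the
deterministic outputs of a rerun are byte-identical.  Wall-clock timings go
to the run log, not the manifest, to keep manifests reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import AnalysisDataset, load_dataset
from .evaluate import bootstrap_cv, loo_cv
from .forest import ForestConfig
from .screen import screen_all, stratify_km
from .simulate import SimulationConfig, config_from_dict, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "report_summary"]


def _forest_config(block: dict | None) -> ForestConfig:
    return ForestConfig(**(block or {}))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Execute the full workflow described by ``config`` into ``out_dir``.

    Writes VIMP tables, stratified curves, cross-validation summaries and a
    manifest; on stage failure, partial outputs are retained and the manifest
    marks the failure.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("kinotox")
    root.addHandler(handler)

    master_seed = int(config.get("seed", 0))
    manifest: dict = {
        "package_version": __version__,
        "master_seed": master_seed,
        "config": config,
        "stage_seeds": {},
        "stages": {},
        "input_checksums": {},
    }
    timings: dict[str, float] = {}

    def finish(status: str) -> Path:
        manifest["status"] = status
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
        )
        for stage, dt in timings.items():
            logger.info("stage %s took %.2fs", stage, dt)
        root.removeHandler(handler)
        handler.close()
        return out

    try:
        # ---- inputs -------------------------------------------------------
        t0 = time.perf_counter()
        if "simulation" in config:
            sim_seed = _stage_seed(master_seed, "simulate")
            manifest["stage_seeds"]["simulate"] = sim_seed
            sim_cfg = config_from_dict({**config["simulation"], "seed": sim_seed})
            data_dir = out / "data"
            dataset = generate_dataset(sim_cfg, data_dir)
            manifest["stages"]["simulate"] = "ok"
        elif "inputs" in config:
            data_dir = Path(config["inputs"]["directory"])
            if not data_dir.exists():
                raise FileNotFoundError(f"input directory not found: {data_dir}")
            dataset = load_dataset(data_dir)
            manifest["stages"]["load"] = "ok"
        else:
            raise ValueError(
                "config must contain either a 'simulation' or an 'inputs' block"
            )
        for f in sorted(data_dir.glob("*.csv")) + sorted(data_dir.glob("*.json")):
            manifest["input_checksums"][f.name] = _sha256(f)
        manifest["stages"]["integrate"] = "ok"
        timings["integrate"] = time.perf_counter() - t0

        fc = _forest_config(config.get("forest"))

        # ---- screening ----------------------------------------------------
        t0 = time.perf_counter()
        screen_block = config.get("screen", {})
        terms = screen_block.get("ae_terms")
        top_k = int(screen_block.get("top_k", 25))
        screen_seed = _stage_seed(master_seed, "screen")
        manifest["stage_seeds"]["screen"] = screen_seed
        tables, summary = screen_all(
            dataset, ae_terms=terms, forest_config=fc, top_k=top_k, seed=screen_seed
        )
        for term, vt in tables.items():
            safe = term.replace("/", "_").replace(" ", "_")
            vt.table.to_csv(out / f"vimp_{safe}.csv", index=False)
        (out / "screen_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        manifest["stages"]["screen"] = "ok"
        timings["screen"] = time.perf_counter() - t0

        # ---- stratification ----------------------------------------------
        t0 = time.perf_counter()
        for spec in config.get("stratify", []):
            kinase, term = spec["kinase"], spec["ae_term"]
            vt = tables.get(term)
            if vt is None or not vt.fitted:
                logger.warning("no fitted forest for term %r; skip stratify", term)
                continue
            curves = stratify_km(dataset, vt.forest, kinase, term)
            safe = f"{kinase}_{term}".replace("/", "_").replace(" ", "_")
            curves.curves.to_csv(out / f"stratified_{safe}.csv", index=False)
        manifest["stages"]["stratify"] = "ok"
        timings["stratify"] = time.perf_counter() - t0

        # ---- evaluation ---------------------------------------------------
        t0 = time.perf_counter()
        eval_block = config.get("evaluate")
        if eval_block:
            eval_seed = _stage_seed(master_seed, "evaluate")
            manifest["stage_seeds"]["evaluate"] = eval_seed
            scheme = eval_block.get("scheme", "bootstrap")
            eval_terms = eval_block.get("ae_terms") or [
                t for t, v in tables.items() if v.fitted
            ]
            summaries = []
            for term in eval_terms:
                outcome = dataset.outcome(term)
                if outcome["event"].sum() == 0:
                    logger.warning("term %r has no events; skipping evaluation", term)
                    continue
                if scheme == "bootstrap":
                    res = bootstrap_cv(
                        dataset.features,
                        outcome["time_days"].to_numpy(),
                        outcome["event"].to_numpy(),
                        ae_term=term,
                        config=fc,
                        B=int(eval_block.get("B", 500)),
                        train_frac=float(eval_block.get("train_frac", 0.8)),
                        seed=eval_seed,
                    )
                    summaries.append(res.summary())
                    pd.DataFrame(
                        {"iteration": np.arange(1, res.c_values.size + 1),
                         "c_index": res.c_values, "seed": res.seeds}
                    ).to_csv(
                        out / f"cv_{term.replace('/', '_').replace(' ', '_')}.csv",
                        index=False,
                    )
                elif scheme == "loo":
                    preds, c = loo_cv(
                        dataset.features,
                        outcome["time_days"].to_numpy(),
                        outcome["event"].to_numpy(),
                        config=fc,
                        seed=eval_seed,
                    )
                    summaries.append(
                        {"ae_term": term, "scheme": "loo", "c_pooled": c}
                    )
                    preds.to_csv(
                        out / f"loo_{term.replace('/', '_').replace(' ', '_')}.csv",
                        index=False,
                    )
                else:
                    raise ValueError(f"unknown evaluation scheme {scheme!r}")
            (out / "cv_summary.json").write_text(
                json.dumps(summaries, indent=2, sort_keys=True) + "\n"
            )
        manifest["stages"]["evaluate"] = "ok"
        timings["evaluate"] = time.perf_counter() - t0
    except Exception as exc:  # partial outputs retained; manifest records failure
        logger.exception("pipeline stage failed")
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        finish("failed")
        raise
    return finish("ok")


def report_summary(output_dir: str | Path) -> str:
    """Human-readable per-AE summary of a completed run."""
    out = Path(output_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        return "no runs found"
    manifest = json.loads(manifest_path.read_text())
    lines = [
        f"kinotox run (version {manifest.get('package_version')}, "
        f"seed {manifest.get('master_seed')}, status {manifest.get('status')})"
    ]
    missing = [
        s for s in ("integrate", "screen", "evaluate") if s not in manifest.get("stages", {})
    ]
    if missing:
        lines.append("incomplete run; missing stages: " + ", ".join(missing))
    screen_path = out / "screen_summary.json"
    if screen_path.exists():
        s = json.loads(screen_path.read_text())
        lines.append(
            f"screened {s['n_pairs_evaluated']} kinase-AE pairs "
            f"({s['n_kinases']} kinases x {s['n_ae_terms']} AE terms; "
            f"{s['n_terms_fitted']} fitted, {s['n_terms_skipped']} skipped)"
        )
    cv_path = out / "cv_summary.json"
    cv = {e["ae_term"]: e for e in json.loads(cv_path.read_text())} if cv_path.exists() else {}
    for vimp_file in sorted(out.glob("vimp_*.csv")):
        df = pd.read_csv(vimp_file)
        if df.empty:
            lines.append(f"- {vimp_file.stem[5:]}: not fitted (zero events)")
            continue
        term = df["ae_term"].iloc[0]
        top10 = ", ".join(df.head(10)["predictor"])
        entry = cv.get(term)
        cstr = ""
        if entry and "c_mean" in entry:
            cstr = (
                f"; C-index {entry['c_mean']:.3f} "
                f"(90% interval {entry['c_p05']:.3f}-{entry['c_p95']:.3f})"
            )
        elif entry and "c_pooled" in entry:
            cstr = f"; pooled LOO C-index {entry['c_pooled']:.3f}"
        lines.append(f"- {term}{cstr}; top-10 by VIMP: {top10}")
    return "\n".join(lines)
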