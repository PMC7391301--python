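"""Configuration-driven pipeline runner and the thin command-line entry.

A run is a YAML config with one section per requested stage (``simulate``,
``hubscan``, ``screen``, ``synergy``) plus a mandatory top-level ``seed`` and
an ``outdir``.  Unknown keys are rejected so typos cannot silently disable a
stage parameter.  Each run writes its stage tables plus a JSON manifest with
the config hash, input checksums and per-stage record counts; identical
config and inputs reproduce identical outputs.
"""

from __future__ import annotations

import argparse
import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import pandas as pd
import yaml

from . import hubscan as hs
from . import io as rio
from . import screen as sc
from . import simulate as sim
from . import synergy as syn

logger = logging.getLogger(__name__)

_TOP_KEYS = {"seed", "outdir", "simulate", "hubscan", "screen", "synergy"}
_STAGE_KEYS = {
    "simulate": {"expression", "screen", "doseresponse"},
    "hubscan": {"expression", "sample_metadata", "network", "alpha", "n_runs",
                "subsample_fraction", "n_perm", "min_partners",
                "retain_fraction"},
    "screen": {"counts", "sample_metadata", "mode", "z_cut", "ratio_cut",
               "min_shrnas", "target_total", "pseudocount",
               "robust_threshold", "max_excluded"},
    "synergy": {"doseresponse", "exclusive", "fa_min", "ci_max"},
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in cfg:
        raise ValueError("config must set an explicit seed")
    if "outdir" not in cfg:
        raise ValueError("config must set outdir")
    for stage, allowed in _STAGE_KEYS.items():
        if stage in cfg:
            bad = set(cfg[stage]) - allowed
            if bad:
                raise ValueError(f"unknown keys in [{stage}]: {sorted(bad)}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: dict) -> dict:
    """Execute the configured stages in order; returns the manifest dict."""
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {
        "tool": "rbscreen 0.1.0",
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "inputs": {},
        "stages": {},
    }

    def record_input(path):
        manifest["inputs"][str(path)] = _sha256(Path(path))

    if "simulate" in cfg:
        s = cfg["simulate"]
        stage: dict = {}
        if "expression" in s:
            spec = sim.SimExpressionSpec(**{**s["expression"], "seed": seed})
            expr, net, truth = sim.gen_expression(spec)
            rio.write_expression(expr, outdir / "sim_expression.tsv",
                                 outdir / "sim_expression_samples.tsv")
            rio.write_network(net, outdir / "sim_network.tsv")
            (outdir / "sim_expression_truth.tsv").write_text(
                "disrupted_hub\n" + "".join(f"{h}\n" for h in sorted(truth)))
            stage["expression_genes"] = len(expr.gene_ids)
        if "screen" in s:
            spec = sim.SimScreenSpec(**{**s["screen"], "seed": seed})
            counts, depleted, outliers = sim.gen_screen(spec)
            rio.write_counts(counts, outdir / "sim_counts.tsv",
                             outdir / "sim_counts_samples.tsv")
            (outdir / "sim_screen_truth.tsv").write_text(
                "depleted_gene\n" + "".join(f"{g}\n" for g in sorted(depleted)))
            stage["screen_shrnas"] = len(counts.shrna_ids)
        if "doseresponse" in s:
            d = dict(s["doseresponse"])
            n_drugs = int(d.pop("n_drugs", 2))
            spec = sim.SimDoseSpec(**{**d, "seed": seed})
            table, truth_ci = sim.gen_doseresponse(spec, n_drugs=n_drugs)
            rio.write_doseresponse(table, outdir / "sim_doseresponse.csv")
            stage["doseresponse_rows"] = len(table)
            stage["truth_ci"] = truth_ci
        manifest["stages"]["simulate"] = stage

    if "hubscan" in cfg:
        h = cfg["hubscan"]
        record_input(h["expression"])
        record_input(h["network"])
        expr = rio.read_expression(h["expression"], h["sample_metadata"])
        net = rio.read_network(h["network"])
        if "retain_fraction" in h:
            net = hs.extract_skeleton(net, retain_fraction=h["retain_fraction"])
        result = hs.consensus_scan(
            expr, net,
            n_runs=h.get("n_runs", 3),
            subsample_fraction=h.get("subsample_fraction", 2 / 3),
            alpha=h.get("alpha", 0.05),
            n_perm=h.get("n_perm", 1000),
            seed=seed,
            min_partners=h.get("min_partners", 5),
        )
        rows = []
        for hub in sorted(hs.identify_hubs(net, h.get("min_partners", 5))):
            per_run = [res[hub] for res in result.per_run_results]
            rows.append({
                "hub": hub,
                "n_partners_used": per_run[0].n_partners_used,
                "mean_score": float(pd.Series(
                    [r.score for r in per_run]).mean()),
                **{f"p_run{i + 1}": r.p_value for i, r in enumerate(per_run)},
                **{f"sig_run{i + 1}": hub in result.runs[i]
                   for i in range(result.n_runs)},
                "consensus": hub in result.disrupted_hubs,
            })
        pd.DataFrame(rows).to_csv(outdir / "hubscan_results.tsv", sep="\t",
                                  index=False)
        manifest["stages"]["hubscan"] = {
            "hubs_tested": len(rows),
            "disrupted": sorted(result.disrupted_hubs),
        }

    if "screen" in cfg:
        s = cfg["screen"]
        record_input(s["counts"])
        counts = rio.read_counts(s["counts"], s["sample_metadata"])
        mode = s.get("mode", "screen1")
        common = dict(
            target_total=s.get("target_total", 1e7),
            pseudocount=s.get("pseudocount", 0.1),
            robust_threshold=s.get("robust_threshold", 5.0),
            max_excluded=s.get("max_excluded", 2),
            min_shrnas=s.get("min_shrnas", 2),
        )
        if mode == "screen1":
            scores = sc.score_screen1(counts, z_cut=s.get("z_cut", -1.96),
                                      **common)
            per = pd.concat(scores.per_shrna, names=["cell_line", "shrna"])
            per.to_csv(outdir / "screen_shrna_scores.tsv", sep="\t")
            scores.gene_hits.to_csv(outdir / "screen_gene_hits.tsv", sep="\t")
            manifest["stages"]["screen"] = {
                "mode": mode,
                "dropout_shrnas": {line: int(df["dropout"].sum())
                                   for line, df in scores.per_shrna.items()},
                "hit_genes": int(scores.gene_hits["any_line"].sum()),
            }
        elif mode == "screen2":
            ratios, hits = sc.score_screen2(
                counts, cutoff=s.get("ratio_cut", -0.69), **common)
            ratios.to_csv(outdir / "screen_log_ratios.tsv", sep="\t")
            hits.to_csv(outdir / "screen_gene_hits.tsv", sep="\t")
            manifest["stages"]["screen"] = {
                "mode": mode,
                "tiers": hits["tier"].value_counts().to_dict(),
            }
        else:
            raise ValueError(f"unknown screen mode {mode!r}")

    if "synergy" in cfg:
        s = cfg["synergy"]
        record_input(s["doseresponse"])
        table = rio.read_doseresponse(s["doseresponse"])
        fits = syn.fit_table(table)
        points = syn.combo_points_from_table(
            table, fits, exclusive=s.get("exclusive", True))
        rows = [{**{f"{d}_dose": p.doses.get(d, 0.0) for d in sorted(fits)},
                 "fa": p.fa, "ci": p.ci,
                 **{f"dri_{d}": p.dri.get(d, float("nan")) for d in sorted(fits)}}
                for p in points]
        pd.DataFrame(rows).to_csv(outdir / "synergy_fa_ci.csv", index=False)
        fit_rows = [{"drug": f.drug, "m": f.m, "dm": f.dm, "r_fit": f.r_fit,
                     "n_points": f.n_points_used} for f in fits.values()]
        pd.DataFrame(fit_rows).to_csv(outdir / "synergy_fits.csv", index=False)
        assessment = syn.classify_potent(
            {"all": points}, fa_min=s.get("fa_min", 0.7),
            ci_max=s.get("ci_max", 0.7)) if points else None
        manifest["stages"]["synergy"] = {
            "n_combo_points": len(points),
            "potent": bool(assessment.potent) if assessment else None,
        }

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(
        prog="rbscreen",
        description="Hub co-expression scanning, shRNA dropout-screen scoring "
                    "and median-effect synergy analysis",
    )
    parser.add_argument("--config", required=True, help="YAML run config")
    args = parser.parse_args(argv)
    logging.basicConfig(level=logging.INFO, stream=sys.stderr,
                        format="%(levelname)s %(name)s: %(message)s")
    try:
        cfg = load_config(args.config)
    except (OSError, ValueError) as exc:
        logger.error("invalid config: %s", exc)
        return 1
    try:
        run_pipeline(cfg)
    except Exception as exc:  # noqa: BLE001 - CLI boundary
        logger.error("pipeline failed: %s", exc)
        return 2
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
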