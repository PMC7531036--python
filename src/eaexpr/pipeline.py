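"""End-to-end orchestration: simulate/load -> preprocess -> DE -> sets ->
enrichment -> scores/clusters -> paired tests, with a deterministic
machine-readable report.

The run is configured by a flat YAML file (see DEFAULT_CONFIG); every stage
derives its random stream from the single master seed, so two runs with the
same seed and config produce byte-identical summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de, enrich, paired, preprocess, scores, sets as set_algebra, simulate
from .io import (
    EAE_CONTRASTS,
    ExpressionExperiment,
    ValidationError,
    read_expression,
    read_gmt,
    write_expression,
    write_gmt,
)

logger = logging.getLogger("eaexpr")

DEFAULT_CONFIG: dict = {
    "experiment": "eae",            # "eae" or "th" or "files"
    "simulate": {},                 # SimulationConfig overrides
    "inputs": {},                   # matrix/sample_sheet/probe_annot/detection/gmt paths
    "preprocess": {"detect_alpha": 0.05, "detected_fraction": 0.9, "literal": False},
    "de": {"adjust": "BH", "alpha": 0.05},
    "contrasts": None,              # None -> design defaults
    "enrich": {
        "n_perm": 100_000,
        "adjust": "holm",
        # planted test collection emulating a prioritized risk-gene list
        "planted": {"set_size": 551, "omega": 4.0, "contrast": "OSE4-OSE0"},
    },
    "score": {"k": 4, "n_rep": 100, "n_pcs": 10,
              "control_groups": ["WT", "OSE0", "CFA"]},
    "paired": {"pairs": [["OSE4-OSE0", "OSE1-OSE0"], ["OSE4-OSE0", "MOG4-CFA"]],
               "consistency": ["OSE4-OSE0", "OSE1-OSE0"]},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict:
    cfg = {}
    if path is not None:
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, cfg)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _round(x, nd=10):
    if isinstance(x, float):
        return round(x, nd)
    return x


def run_pipeline(config_path=None, seed: int = 0, out_dir="run_out",
                 config: dict | None = None) -> dict:
    """Run the full analysis and write all stage outputs under ``out_dir``.

    Returns the summary dictionary (also written as summary.json).
    """
    cfg = config if config is not None else load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(seed)
    summary: dict = {"seed": seed}
    manifest: dict = {"seed": seed, "config": cfg, "stages": []}

    # ---- stage: obtain the experiment -------------------------------------
    truth = None
    if cfg["experiment"] in ("eae", "th"):
        sim_kwargs = dict(cfg.get("simulate") or {})
        sim_kwargs["seed"] = seed
        if cfg["experiment"] == "th":
            config_obj = simulate.th_config(**sim_kwargs)
        else:
            config_obj = simulate.SimulationConfig(**sim_kwargs)
        exp, truth = simulate.simulate_experiment(config_obj)
        write_expression(
            exp, out / "matrix.tsv", out / "samples.tsv", out / "probes.tsv",
            detection_path=out / "detection.tsv",
        )
        truth.true_lfc.to_csv(out / "truth_lfc.tsv", sep="\t")
        manifest["stages"].append({"stage": "simulate",
                                   "rho_true": truth.rho_true})
    elif cfg["experiment"] == "files":
        paths = cfg["inputs"]
        exp = read_expression(
            paths["matrix"], paths["sample_sheet"], paths["probe_annot"],
            detection_path=paths.get("detection"),
            dialect=paths.get("dialect", "separate"),
        )
        manifest["stages"].append(
            {"stage": "load",
             "inputs": {k: _sha256(Path(v)) for k, v in paths.items()
                        if k != "dialect" and v is not None}}
        )
    else:
        raise ValidationError(f"unknown experiment kind {cfg['experiment']!r}")
    summary["n_probes_raw"] = exp.n_probes
    summary["n_samples"] = exp.n_samples

    # ---- stage: preprocess -------------------------------------------------
    pp = cfg["preprocess"]
    filtered = preprocess.filter_probes(
        exp, detect_alpha=pp["detect_alpha"],
        detected_fraction=pp["detected_fraction"], literal=pp["literal"],
    )
    norm = preprocess.vst_transform(filtered)
    batch = preprocess.batch_association(norm, n_pcs=cfg["score"]["n_pcs"])
    batch.to_csv(out / "batch_association.tsv", sep="\t", index=False)
    summary["n_probes_filtered"] = norm.n_probes
    manifest["stages"].append({"stage": "preprocess",
                               "n_retained": norm.n_probes})

    # ---- stage: differential expression ------------------------------------
    contrasts = cfg["contrasts"]
    if contrasts is None:
        if set(exp.groups.unique()) >= set(simulate.TH_GROUPS):
            from .io import TH_CONTRASTS
            contrasts = TH_CONTRASTS
        else:
            contrasts = EAE_CONTRASTS
    else:
        from .io import parse_contrast
        contrasts = {name: parse_contrast(name) for name in contrasts}
    tables, rho_hat, params = de.run_de(
        norm, contrasts, adjust=cfg["de"]["adjust"], alpha=cfg["de"]["alpha"]
    )
    for name, tab in tables.items():
        tab.to_csv(out / f"contrast_{name.replace('-', '_')}.tsv", sep="\t")
    summary["consensus_correlation"] = _round(rho_hat)
    summary["d0"] = None if np.isinf(params.d0) else _round(params.d0)
    summary["s02"] = _round(params.s02)
    summary["n_significant"] = {n: int(t["significant"].sum())
                                for n, t in tables.items()}
    manifest["stages"].append({"stage": "de", "rho_hat": rho_hat})

    # ---- stage: set algebra -------------------------------------------------
    gene_map = norm.probe_annot["gene_id"]
    if set(("OSE4-OSE0", "MOG4-CFA", "OSE1-OSE0")) <= set(tables):
        analysis = set_algebra.define_analysis_sets(tables)
    else:
        analysis = set_algebra.define_exclusive_sets(tables)
    venn = set_algebra.directional_venn(tables)
    venn.to_csv(out / "venn_regions.tsv", sep="\t", index=False)
    gene_sets = analysis.gene_sets(gene_map)
    set_rows = []
    for name in analysis.names():
        ts = analysis[name]
        set_rows.append({"set": name, "n_probes": len(ts.probes),
                         "n_genes": len(gene_sets[name]), "rule": ts.rule})
        pd.Series(sorted(ts.probes)).to_csv(
            out / f"set_{name.replace('&', '_and_')}_probes.tsv",
            sep="\t", index=False, header=["probe_id"])
    pd.DataFrame(set_rows).to_csv(out / "analysis_sets.tsv", sep="\t", index=False)
    summary["analysis_sets"] = {r["set"]: {"probes": r["n_probes"],
                                           "genes": r["n_genes"]}
                                for r in set_rows}

    # ---- stage: enrichment --------------------------------------------------
    en = cfg["enrich"]
    universe = norm.gene_universe()
    if en.get("gmt"):
        collections = read_gmt(en["gmt"])
    elif truth is not None:
        pl = en["planted"]
        contrast_def = contrasts.get(pl["contrast"], next(iter(contrasts.values())))
        collections = simulate.plant_gene_set(
            truth, contrast_def, pl["set_size"], pl["omega"],
            seed=seed + 101, universe=universe, gene_map=gene_map,
            name="risk_genes",
        )
        null_set = simulate.plant_gene_set(
            truth, contrast_def, pl["set_size"], 1.0,
            seed=seed + 202, universe=universe, gene_map=gene_map,
            name="null_genes",
        )
        collections.sets.update(null_set.sets)
        collections.provenance.update(null_set.provenance)
        write_gmt(collections, out / "test_sets.gmt")
    else:
        collections = None
    if collections is not None:
        etable = enrich.run_enrichment_suite(
            gene_sets, collections, universe,
            n_perm=en["n_perm"], seed=seed, adjust=en["adjust"],
        )
        etable.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        summary["enrichment"] = [
            {k: _round(v) for k, v in row.items()}
            for row in etable.drop(columns=["seed"]).to_dict("records")
        ]
    manifest["stages"].append({"stage": "enrich", "n_universe": len(universe)})

    # ---- stage: scores and clusters ----------------------------------------
    sc = cfg["score"]
    full_scores, frac = scores.pca_scores(
        norm.intensities.to_numpy(dtype=float).T, n_components=2
    )
    records, modal = scores.kmeans_stability(
        full_scores, k=min(sc["k"], norm.n_samples), n_rep=sc["n_rep"], seed=seed
    )
    summary["clustering"] = {
        "modal_frequency": modal.frequency, "n_rep": sc["n_rep"],
        "variance_explained_pc1": _round(float(frac[0])),
    }
    ctrl = [g for g in sc["control_groups"] if g in set(exp.groups)]
    if ctrl and len(ctrl) < exp.groups.nunique():
        side_a = exp.groups.isin(ctrl).to_numpy()
        summary["clustering"]["bipartition_respect"] = _round(
            scores.bipartition_respect(records, side_a, ~side_a)
        )
    score_set = None
    if collections is not None and len(collections):
        score_set = collections[collections.names()[0]]
    if score_set:
        try:
            pc = scores.geneset_pc_scores(norm, score_set, n_components=2)
            comp = scores.compare_score_groups(
                pc.scores["PC1"], norm.groups, ctrl or [norm.groups.unique()[0]]
            )
            pc.scores.to_csv(out / "geneset_pc_scores.tsv", sep="\t")
            comp.to_csv(out / "score_comparisons.tsv", sep="\t", index=False)
            summary["geneset_score"] = {
                "variance_explained_pc1": _round(float(pc.variance_explained[0])),
                "comparisons": [
                    {k: _round(v) for k, v in row.items()}
                    for row in comp.to_dict("records")
                ],
            }
        except ValidationError as err:
            logger.warning("score stage skipped: %s", err)

    # ---- stage: paired tests ------------------------------------------------
    pr = cfg["paired"]
    paired_out = []
    for a, b in pr["pairs"]:
        if a in tables and b in tables:
            for restrict in ("all", "de_in_both"):
                try:
                    r = paired.magnitude_binomial(tables[a], tables[b], restrict)
                except ValidationError as err:
                    logger.warning("paired %s vs %s (%s) skipped: %s", a, b, restrict, err)
                    continue
                paired_out.append({"test": "magnitude", "a": a, "b": b,
                                   "restriction": restrict, "n": r.n, "k": r.k,
                                   "p": _round(r.p), "log10_p": _round(r.log10_p)})
    ca, cb = pr["consistency"]
    if ca in tables and cb in tables:
        try:
            r = paired.direction_consistency(tables[ca], tables[cb])
            paired_out.append({"test": "direction_consistency", "a": ca, "b": cb,
                               "restriction": "de_in_both", "n": r.n, "k": r.k,
                               "p": _round(r.p), "ci_low": _round(r.ci_low),
                               "ci_high": _round(r.ci_high)})
        except ValidationError as err:
            logger.warning("direction consistency skipped: %s", err)
    summary["paired_tests"] = paired_out

    # ---- report -------------------------------------------------------------
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return summary
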