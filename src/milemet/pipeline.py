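"""End-to-end pipeline orchestration and report rendering.

One configuration (file paths or a simulate block, plus stage settings and
a seed) drives: simulate? -> growth milestones -> metabolite preprocessing
-> consensus network -> MetS z-scores -> three-step screen -> report.
Every run writes a manifest with the seed and a configuration hash so a
run is reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import io
from .config import (MilestoneWindows, NetworkConfig, ScreenConfig,
                     SimulationConfig, SplineConfig, config_to_dict)
from .growth import GrowthCurveModel, eligibility_filter, standardize_exposures
from .mets import compute_mets_scores
from .network import ConsensusNetwork, membership_report
from .preprocess import MetabolitePreprocessor
from .screen import run_screen
from .simulate import simulate_cohort, write_dataset

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict, out_dir, seed: int | None = None,
                 overwrite: bool = False) -> dict:
    """Execute the full pipeline from a config dict; returns the manifest.

    ``config`` holds either an ``inputs`` block (paths to the CSV tables)
    or a ``simulate`` block (SimulationConfig fields), plus optional
    ``spline``, ``windows``, ``network`` and ``screen`` blocks.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if ("inputs" in config) == ("simulate" in config):
        raise ValueError("config must contain exactly one of "
                         "'inputs' or 'simulate'")
    seed = config.get("seed", 0) if seed is None else seed

    if "simulate" in config:
        logger.info("stage simulate: generating synthetic cohort")
        sim_cfg = SimulationConfig(**config["simulate"])
        dataset = simulate_cohort(sim_cfg, seed=seed)
        write_dataset(dataset, out_dir / "data", overwrite=overwrite)
        anthro = dataset.anthropometry
        matrix = dataset.metabolites
        meta = dataset.metabolite_meta
        comps = dataset.mets_components
        reference = dataset.reference_tables
        covariates = dataset.covariates
    else:
        paths = config["inputs"]
        anthro = io.read_anthropometry(paths["anthropometry"])
        matrix = io.read_metabolite_matrix(paths["metabolites"])
        meta = io.read_metabolite_meta(paths["metabolite_meta"])
        comps = io.read_table(paths["mets_components"])
        reference = io.read_reference_tables(paths["reference_tables"])
        covariates = io.read_table(paths["covariates"])

    # --- growth milestones -------------------------------------------------
    spline = SplineConfig(**config.get("spline", {}))
    windows = MilestoneWindows(**config.get("windows", {}))
    eligible = eligibility_filter(anthro)
    logger.info("stage milestones: %d eligible subjects",
                eligible["subject_id"].nunique())
    growth = GrowthCurveModel(spline=spline, windows=windows).fit(eligible)
    milestones = growth.extract_all_milestones()
    milestones.loc[~milestones["peak_identified"],
                   ["age_peak", "bmi_peak"]] = float("nan")
    milestones.loc[~milestones["rebound_identified"],
                   ["age_rebound", "bmi_rebound"]] = float("nan")
    scaled, sds = standardize_exposures(milestones)
    io.write_table(milestones, out_dir / "milestones.csv")
    io.write_table(sds, out_dir / "milestone_sds.csv")

    # --- metabolomics ------------------------------------------------------
    logger.info("stage preprocess: %d x %d metabolite matrix", *matrix.shape)
    prep = MetabolitePreprocessor()
    processed = prep.fit_transform(matrix, meta)
    io.write_table(processed.reset_index(),
                   out_dir / "metabolites_processed.csv")
    (out_dir / "preprocess_report.json").write_text(
        json.dumps(prep.report_, indent=1, sort_keys=True))

    strata = covariates.set_index("subject_id")["sex"]
    net_cfg = NetworkConfig(**config.get("network", {}))
    logger.info("stage network: consensus modules at power %.0f",
                net_cfg.soft_power)
    net = ConsensusNetwork(net_cfg).fit(processed, strata)
    io.write_table(net.module_labels_.reset_index(), out_dir / "modules.csv")
    for stratum, eig in net.eigengenes_.eigengenes.items():
        io.write_table(eig.reset_index(),
                       out_dir / f"eigengenes_{stratum}.csv")
        io.write_table(net.eigengenes_.kme[stratum].reset_index(),
                       out_dir / f"kme_{stratum}.csv")
    report = membership_report(net.eigengenes_, net.labels_, meta)
    io.write_table(report, out_dir / "membership_report.tsv", sep="\t")
    (out_dir / "network_qc.json").write_text(
        json.dumps(net.qc_, indent=1, sort_keys=True, default=str))

    # --- MetS score --------------------------------------------------------
    logger.info("stage mets: standardizing %d subjects", len(comps))
    mets_z = compute_mets_scores(comps, reference)
    io.write_table(mets_z, out_dir / "mets_z.csv")

    # --- screen ------------------------------------------------------------
    scr_cfg = ScreenConfig(**config.get("screen", {}))
    eig_nonoutlier = net.eigengenes_.eigengenes
    results = run_screen(scaled, eig_nonoutlier, mets_z, covariates, scr_cfg)
    for name in ("step1", "step2", "step3", "components", "sensitivity"):
        io.write_table(results[name], out_dir / f"{name}.tsv", sep="\t")
    render_tables(results, report, out_dir / "report.md")

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "config": config,
        "n_modules": int(net.labels_.max()),
        "outlier_samples": net.outliers_,
        "carried_milestones": results["carried_milestones"],
        "carried_pairs": {s: [list(p) for p in v]
                          for s, v in results["carried_pairs"].items()},
        "outputs": {p.name: _hash_file(p)
                    for p in sorted(out_dir.glob("*.csv"))
                    + sorted(out_dir.glob("*.tsv"))},
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return manifest


def _fmt_row(r) -> str:
    star = " *" if r.get("fdr_flag") else ""
    return (f"| {r['stratum']} | {r['exposure']} | {r['outcome']} | "
            f"{r['tier']} | {r['beta']:.3f} "
            f"({r['ci_lo']:.3f}, {r['ci_hi']:.3f}) | {r['p']:.4f}{star} | "
            f"{r['n']} |")


_HEADER = ("| stratum | exposure | outcome | tier | beta (95% CI) | p | n |\n"
           "|---|---|---|---|---|---|---|")


def render_tables(results: dict, membership: pd.DataFrame, path) -> str:
    """Markdown report mirroring the screen's published table shapes."""
    lines = ["# Meet-in-the-middle screen report", ""]
    lines += ["## Milestones vs MetS z-score (step 1)", "", _HEADER]
    lines += [_fmt_row(r) for _, r in results["step1"].iterrows()]
    lines += ["", "## Milestones vs module eigengenes (step 2; "
              "* = FDR-significant)", ""]
    if len(results["step2"]):
        lines += [_HEADER]
        lines += [_fmt_row(r) for _, r in results["step2"].iterrows()]
    else:
        lines += ["No milestones carried forward."]
    lines += ["", "## Carried eigengenes vs MetS z-score (step 3)", ""]
    if len(results["step3"]):
        lines += [_HEADER]
        lines += [_fmt_row(r) for _, r in results["step3"].iterrows()]
    else:
        lines += ["No networks carried forward."]
    lines += ["", "## Component follow-up", ""]
    if len(results["components"]):
        lines += [_HEADER]
        lines += [_fmt_row(r) for _, r in results["components"].iterrows()]
    else:
        lines += ["No Model-1-significant networks."]
    lines += ["", "## Top network members (|kME|)", ""]
    if len(membership):
        top = membership[membership["top10"]]
        for (stratum, module), grp in top.groupby(["stratum", "module"]):
            lines.append(f"### Module ME{module} ({stratum})")
            for _, r in grp.sort_values("rank").iterrows():
                lines.append(f"{int(r['rank'])}. {r['metabolite_id']} "
                             f"(kME = {r['kme']:.3f})")
            lines.append("")
    text = "\n".join(lines) + "\n"
    Path(path).write_text(text)
    return text
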