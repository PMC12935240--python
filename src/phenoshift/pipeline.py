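"""End-to-end pipeline: simulate/read -> filter -> fit -> summarize -> signal.

Configuration is a flat YAML file; every stage writes plain-text outputs
(CSV / JSON) into the output directory, together with a manifest echoing
the config, seeds and per-stage record counts.  The whole run is
deterministic under the master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path

import yaml

from . import __version__
from .circular_glm import CircularGLMConfig, fit
from .dataset_filters import STANDARD_DATASETS, DatasetCriteria, apply_criteria, eligibility_report
from .phylo_signal import grafen_branch_lengths, load_tree, permutation_test, prune_to, repair_near_zero
from .records_io import build_series, read_occurrences, records_from_frame
from .shift_metrics import estimates_to_frame, shift_from_fit, summarize_dataset, summary_to_frame
from .synthetic_data import load_sim_config, simulate_records

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "occurrences", "simulation", "tree", "dataset", "criteria", "mcmc",
    "permutations", "output_dir", "seed", "verbosity",
}
_MCMC_KEYS = {"n_chains", "burnin", "iterations", "seed"}
_CRITERIA_KEYS = {
    "max_months_flowering", "min_specimens", "min_year_span", "year_window",
    "max_per_day", "require_consecutive_months",
}


class ConfigError(ValueError):
    pass


def validate_config(raw: dict) -> dict:
    """Normalize a parsed config dict, injecting stage defaults.

    Defaults: dataset1 criteria (<=4 consecutive months, >=20 specimens,
    >=29-year span), 4 chains / burn-in 200 / 2500 iterations, 1000
    permutations.  Unknown keys and contradictory inputs are rejected.
    """
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    has_occ = raw.get("occurrences") is not None
    has_sim = raw.get("simulation") is not None
    if has_occ == has_sim:
        raise ConfigError("exactly one of 'occurrences' / 'simulation' must be set")

    cfg = dict(raw)
    cfg.setdefault("seed", 0)
    cfg.setdefault("output_dir", "phenoshift_out")
    cfg.setdefault("permutations", 1000)
    if int(cfg["permutations"]) < 1:
        raise ConfigError("permutations must be >= 1")

    mcmc = dict(cfg.get("mcmc") or {})
    unknown = set(mcmc) - _MCMC_KEYS
    if unknown:
        raise ConfigError(f"unknown mcmc keys: {sorted(unknown)}")
    mcmc.setdefault("n_chains", 4)
    mcmc.setdefault("burnin", 200)
    mcmc.setdefault("iterations", 2500)
    if min(mcmc["n_chains"], mcmc["iterations"]) < 1 or mcmc["burnin"] < 0:
        raise ConfigError("mcmc counts must be positive")
    cfg["mcmc"] = mcmc

    dataset = cfg.get("dataset")
    custom = cfg.get("criteria")
    if dataset is not None and custom is not None:
        raise ConfigError("give either a named 'dataset' or custom 'criteria', not both")
    if custom is not None:
        unknown = set(custom) - _CRITERIA_KEYS
        if unknown:
            raise ConfigError(f"unknown criteria keys: {sorted(unknown)}")
        window = custom.get("year_window")
        cfg["criteria"] = DatasetCriteria(
            max_months_flowering=int(custom.get("max_months_flowering", 4)),
            min_specimens=int(custom.get("min_specimens", 20)),
            min_year_span=custom.get("min_year_span", None),
            year_window=tuple(window) if window else None,
            max_per_day=custom.get("max_per_day"),
            require_consecutive_months=bool(custom.get("require_consecutive_months", True)),
        )
        cfg["dataset"] = "custom"
    else:
        name = dataset or "dataset1"
        if name not in STANDARD_DATASETS:
            raise ConfigError(f"unknown dataset {name!r}; options: {sorted(STANDARD_DATASETS)}")
        cfg["criteria"] = STANDARD_DATASETS[name]
        cfg["dataset"] = name
    return cfg


def load_run_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def run_pipeline(config: dict) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    if isinstance(config.get("criteria"), DatasetCriteria):
        cfg = config  # already validated (e.g. by load_run_config)
    else:
        cfg = validate_config(config)
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "dataset": cfg["dataset"],
        "stages": {},
    }

    # --- stage 1: acquire records
    if cfg.get("simulation"):
        sim_cfg = load_sim_config(cfg["simulation"])
        frame = simulate_records(sim_cfg)
        records = records_from_frame(frame)
        manifest["stages"]["simulate"] = {"n_records": len(records)}
    else:
        records = read_occurrences(cfg["occurrences"])
    manifest["stages"]["read"] = {"n_records": len(records)}
    if not records:
        raise RuntimeError("stage read: no usable records")

    # --- stage 2: filter
    criteria = cfg["criteria"]
    eligible, filtered = apply_criteria(records, criteria)
    eligibility_report(records, criteria).to_csv(out_dir / "eligibility.csv", index=False)
    manifest["stages"]["filter"] = {
        "n_species_in": len({r.species for r in records}),
        "n_species_eligible": len(eligible),
        "n_records": len(filtered),
    }

    # --- stage 3: per-species fits and shifts
    mcmc = cfg["mcmc"]
    estimates = []
    rhat_flags = {}
    for i, sp in enumerate(eligible):
        series = build_series(filtered, sp)
        glm_cfg = CircularGLMConfig(
            n_chains=int(mcmc["n_chains"]),
            burnin=int(mcmc["burnin"]),
            iterations=int(mcmc["iterations"]),
            seed=seed + 1000 * (i + 1),
        )
        try:
            fit_result = fit(series, glm_cfg)
        except ValueError as err:
            raise RuntimeError(f"stage fit failed for species {sp!r}: {err}") from err
        est = shift_from_fit(fit_result, species=sp)
        estimates.append(est)
        rhat_flags[sp] = {k: round(v, 4) for k, v in fit_result.rhat.items()}
        logger.info(
            "fit %s: n=%d dpd=%+.3f (sd %.3f) rhat=%s",
            sp, fit_result.n_obs, est.days_per_decade, est.days_per_decade_sd,
            rhat_flags[sp],
        )
    if not estimates:
        raise RuntimeError("stage fit: no eligible species to fit")
    est_frame = estimates_to_frame(estimates)
    est_frame.to_csv(out_dir / "estimates.csv", index=False)
    manifest["stages"]["fit"] = {"n_species_fit": len(estimates), "rhat": rhat_flags}

    # --- stage 4: dataset summary
    summary = summarize_dataset(estimates, cfg["dataset"])
    summary_to_frame([summary]).to_csv(out_dir / "summary.csv", index=False)
    manifest["stages"]["summarize"] = {
        "n_positive": summary.n_positive,
        "n_negative": summary.n_negative,
        "mean_abs_days_per_decade": summary.mean_abs_days_per_decade,
    }

    # --- stage 5: phylogenetic signal (optional: needs a tree)
    if cfg.get("tree"):
        tree = load_tree(cfg["tree"])
        trait = {e.species: e.abs_days_per_decade for e in estimates}
        tip_labels = {t.label for t in tree.taxon_namespace}
        shared = sorted(set(trait) & tip_labels)
        if len(shared) < 3:
            raise RuntimeError("stage signal: fewer than 3 species shared with tree")
        pruned = prune_to(tree, shared)
        has_lengths = all(
            e.length is not None and e.length > 0
            for e in pruned.preorder_edge_iter() if e.tail_node is not None
        )
        if not has_lengths:
            pruned = grafen_branch_lengths(pruned)
        pruned = repair_near_zero(pruned)
        result = permutation_test(
            pruned, {k: trait[k] for k in shared},
            n_permutations=int(cfg["permutations"]), seed=seed + 99,
        )
        signal = {
            "K": result.K,
            "p": result.p_value,
            "n_permutations": result.n_permutations,
            "seed": result.seed,
            "n_tips": result.n_tips,
        }
        (out_dir / "signal.json").write_text(json.dumps(signal, indent=2))
        manifest["stages"]["signal"] = signal

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _criteria_to_dict(criteria: DatasetCriteria) -> dict:
    d = dataclasses.asdict(criteria)
    if d.get("year_window") is not None:
        d["year_window"] = list(d["year_window"])
    return d
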