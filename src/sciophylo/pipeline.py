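"""Configuration-driven orchestration of the full analysis chain.

Stages mirror the study: (1) ML ancestral-state reconstruction of the
12-state feeding character (Mk1) and the binary habitat character (Mk1 +
AsymmMk) with the T=2 rule and the unknown-removal robustness check;
(2) the DEC habitat analysis with the profiled transition-rate ratio;
(3) constrained minimum-transition counting.  Every run writes TSV/JSON
reports plus a manifest (config, seed, package version) sufficient to
reproduce the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .characters import read_character_table
from .counting import clade_origin_count, constraints_from_asr, min_transitions
from .dec import dec_node_estimates, default_ratio_grid, fit_dec, sweep_ratio
from .fixtures import (
    FEEDING_STATES,
    binary_habitat,
    dec_habitat_ranges,
    load_study_characters,
    load_study_tree,
)
from .mk import drop_unknowns_rerun, fit_asymm, fit_mk1, marginal_asr
from .trees import read_newick_file, validate_congruence

log = logging.getLogger("sciophylo")

HABITAT_STATES = ("aquatic", "terrestrial")


@dataclass
class RunConfig:
    """Inputs and knobs of one pipeline run (YAML-loadable)."""

    output_dir: str = "results"
    tree: str | None = None          # Newick path; None -> packaged study tree
    characters: str | None = None    # TSV path; None -> packaged codings
    threshold: float = 2.0
    ratio_grid: list[float] = field(
        default_factory=lambda: list(default_ratio_grid())
    )
    clades: dict[str, list[str]] = field(
        default_factory=lambda: {
            "Tetanocerini": ["Anticheta_melanosoma", "Tetanocera_vicina"],
            "Tetanocera": ["Tetanocera_robusta", "Tetanocera_vicina"],
        }
    )
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if 1.0 not in cfg.ratio_grid:
            raise ValueError("ratio_grid must include the 1:1 null")
        return cfg


def _load_inputs(config: RunConfig):
    tree = (
        read_newick_file(config.tree) if config.tree else load_study_tree()
    )
    matrix = (
        read_character_table(config.characters)
        if config.characters
        else load_study_characters()
    )
    report = validate_congruence(tree, matrix)
    if not report["ok"]:
        raise ValueError(
            f"tree tips missing from character table: {report['tree_only']}"
        )
    return tree, matrix


def _write_manifest(config: RunConfig, outdir: Path, stage: str) -> None:
    payload = {
        "stage": stage,
        "config": asdict(config),
        "seed": config.seed,
        "version": __version__,
    }
    payload["config_hash"] = hashlib.sha256(
        json.dumps(payload["config"], sort_keys=True).encode()
    ).hexdigest()[:16]
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def run_asr(config: RunConfig) -> dict:
    """Mk1 feeding + Mk1/AsymmMk habitat reconstructions with T-rule."""
    tree, matrix = _load_inputs(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    T = config.threshold

    log.info("fitting Mk1 to the feeding-group character")
    feed = matrix.states("feeding_group")
    feed_alpha = matrix.alphabets["feeding_group"]
    mk_feed, lnl_feed = fit_mk1(
        tree, feed, k=len(feed_alpha), alphabet=feed_alpha
    )
    asr_feed = marginal_asr(tree, feed, mk_feed, feed_alpha, T=T)
    asr_feed.to_frame(tree).to_csv(outdir / "asr_feeding.tsv", sep="\t",
                                   index=False)

    log.info("fitting Mk1 and AsymmMk to the habitat character")
    hab = binary_habitat(matrix)
    mk_hab, lnl_mk = fit_mk1(
        tree, hab, k=2, alphabet=HABITAT_STATES
    )
    asym, lnl_asym = fit_asymm(
        tree, hab, HABITAT_STATES, seed=config.seed
    )
    asr_hab = marginal_asr(tree, hab, asym, HABITAT_STATES, T=T)
    asr_hab.to_frame(tree).to_csv(outdir / "asr_habitat.tsv", sep="\t",
                                  index=False)

    log.info("unknown-removal robustness check")
    robust = drop_unknowns_rerun(
        tree, hab, HABITAT_STATES, model="asymm", T=T
    )
    with open(outdir / "robustness_habitat.json", "w") as fh:
        json.dump(
            {
                "agreement_fraction": robust["agreement_fraction"],
                "n_shared_nodes": len(robust["agreement"]),
            },
            fh, indent=2,
        )
    summary = {
        "feeding": {"rate": mk_feed.rate, "lnL": lnl_feed},
        "habitat_mk1": {"rate": mk_hab.rate, "lnL": lnl_mk},
        "habitat_asymm": {
            "q_aquatic_to_terrestrial": asym.q01,
            "q_terrestrial_to_aquatic": asym.q10,
            "ratio": asym.q01 / asym.q10,
            "lnL": lnl_asym,
            "lr_vs_mk1": 2 * (lnl_asym - lnl_mk),
        },
        "robustness_agreement": robust["agreement_fraction"],
    }
    with open(outdir / "asr_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    _write_manifest(config, outdir, "asr")
    return {
        "tree": tree, "matrix": matrix,
        "feeding": asr_feed, "habitat": asr_hab, "summary": summary,
    }


def run_habitat_dec(config: RunConfig) -> dict:
    """DEC ratio sweep, significance call and node estimates."""
    tree, matrix = _load_inputs(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ranges = dec_habitat_ranges(matrix)
    coded = [l for l in tree.tip_labels if l in ranges]
    dtree = tree.retain_tips(coded)
    log.info("DEC ratio sweep over %d ratios on %d coded tips",
             len(config.ratio_grid), len(coded))
    profile = sweep_ratio(
        dtree, ranges, grid=config.ratio_grid,
        threshold=config.threshold,
    )
    profile.to_frame().to_csv(outdir / "dec_ratio_profile.tsv", sep="\t",
                              index=False)
    best = profile.params[profile.best_index]
    est = dec_node_estimates(
        dtree, ranges, best, threshold=config.threshold
    )
    rows = []
    for i, v in sorted(est.node_logliks.items()):
        rows.append(
            {
                "node": i,
                "tips": ";".join(sorted(dtree.tip_set(i))[:3]),
                "lnL[A]": v[0], "lnL[T]": v[1], "lnL[AT]": v[2],
                "reported": ";".join(est.reported_sets[i]),
                "unambiguous": est.is_unambiguous(i),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "dec_node_estimates.tsv", sep="\t",
                              index=False)

    # node-by-node congruence with the Mesquite-style binary reconstruction
    hab = binary_habitat(matrix)
    asym, _ = fit_asymm(tree, hab, HABITAT_STATES, seed=config.seed)
    asr = marginal_asr(tree, hab, asym, HABITAT_STATES,
                       T=config.threshold)
    congr = []
    short = {"aquatic": "A", "terrestrial": "T"}
    for j in dtree.internal_indices:
        tipset = dtree.tip_set(j)
        i = tree.mrca(tipset)
        if tree.tip_set(i) & set(coded) != tipset:
            continue
        mes = {short[s] for s in asr.significant_sets[i]}
        dec_set = {
            s for r in est.reported_sets[j] for s in (r if r != "AT" else "AT",)
        }
        congruent = bool(mes & {x for r in est.reported_sets[j]
                                for x in (("A", "T") if r == "AT" else (r,))})
        congr.append(
            {
                "node": i,
                "mesquite": ";".join(sorted(mes)),
                "dec": ";".join(est.reported_sets[j]),
                "congruent": congruent,
            }
        )
    pd.DataFrame(congr).to_csv(outdir / "dec_mesquite_congruence.tsv",
                               sep="\t", index=False)
    with open(outdir / "dec_summary.json", "w") as fh:
        json.dump(
            {
                "best_ratio": profile.best_ratio,
                "max_lnL": profile.max_loglik,
                "null_lnL": profile.null_loglik,
                "delta_vs_null": profile.max_loglik - profile.null_loglik,
                "significant_vs_null": profile.significant_vs_null,
                "ratios_within_threshold": list(profile.within_threshold),
                "d": best.d, "e": best.e,
            },
            fh, indent=2,
        )
    _write_manifest(config, outdir, "dec")
    return {"profile": profile, "node_estimates": est, "tree": dtree}


def run_counts(config: RunConfig) -> dict:
    """Constrained minimum-transition counts for both characters."""
    tree, matrix = _load_inputs(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    asr = run_asr(
        RunConfig(**{**asdict(config), "output_dir": str(outdir)})
    )
    clade_nodes = {}
    for name, pair in config.clades.items():
        try:
            clade_nodes[name] = tree.mrca(pair)
        except Exception:
            raise ValueError(
                f"unknown clade {name!r}; available tips are the tree's"
            ) from None

    report: dict = {}
    hab = binary_habitat(matrix)
    cons_h = constraints_from_asr(tree, asr["habitat"], hab)
    scope = clade_nodes.get("Tetanocerini")
    tc_h = min_transitions(tree, cons_h, HABITAT_STATES, scope=scope)
    report["habitat"] = {
        "total": tc_h.total_changes,
        "counts": {f"{a}->{b}": c for (a, b), c in tc_h.pair_counts.items()},
        "min": {f"{a}->{b}": c for (a, b), c in tc_h.pair_min.items()},
        "max": {f"{a}->{b}": c for (a, b), c in tc_h.pair_max.items()},
        "tied": tc_h.tied,
    }
    feed = matrix.states("feeding_group")
    feed_alpha = matrix.alphabets["feeding_group"]
    cons_f = constraints_from_asr(tree, asr["feeding"], feed)
    tc_f = min_transitions(tree, cons_f, feed_alpha, scope=scope)
    report["feeding"] = {
        "total": tc_f.total_changes,
        "counts": {f"{a}->{b}": c for (a, b), c in tc_f.pair_counts.items()},
        "tied": tc_f.tied,
    }
    origins = {}
    for name, node in clade_nodes.items():
        origins[name] = {
            "terrestrial_habitat": clade_origin_count(
                tree, cons_h, HABITAT_STATES, "terrestrial", node
            ),
            "feeding_transitions": min_transitions(
                tree, cons_f, feed_alpha, scope=node
            ).total_changes,
            "shoreline_predation": clade_origin_count(
                tree, cons_f, feed_alpha, "shoreline_snail_predator", node
            ),
            "terrestrial_snail_predation": clade_origin_count(
                tree, cons_f, feed_alpha, "terrestrial_snail_predator", node
            ),
            "slug_parasitoidism": clade_origin_count(
                tree, cons_f, feed_alpha, "slug_parasitoid", node
            ),
        }
    report["clades"] = origins
    with open(outdir / "transition_counts.json", "w") as fh:
        json.dump(report, fh, indent=2)
    _write_manifest(config, outdir, "counts")
    return report


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )
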