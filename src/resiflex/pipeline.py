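"""End-to-end pipelines and report bundles.

``run_stability_pipeline`` drives strip -> align-to-original -> average
reference -> per-residue profile -> focal ordering -> cumulative curves ->
variant comparison for one or more labelled trajectories, writing
``<label>_profile.csv``, ``<label>_curve.csv``, ``comparison.json`` and
``run_metadata.json`` into the output directory.

``run_cohort_pipeline`` validates a cohort table and writes contingency
tables, proportions (exact fraction + rounded percent), two-sided Fisher
p-values for 2x2 tables, the mutation x TKI exposure table when the drug
columns are present, and the attribute rankings of all evaluators.

Identical inputs and config produce byte-identical outputs; every bundle
embeds provenance (config echo, config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .errors import ResiflexError
from .model import Trajectory
from .stability import (DEFAULT_FOCAL_RESIDUE, DEFAULT_K_WINDOW, DEFAULT_TRIM,
                        analyze_trajectory, compare_mutants)
from .cohort import (ATTRIBUTES, EVALUATORS, build_contingency,
                     fisher_exact_two_sided, load_cohort, proportion,
                     rank_attributes)

log = logging.getLogger("resiflex")


@dataclass
class RunConfig:
    """Configuration shared by the pipelines; JSON round-trippable."""

    trajectories: Dict[str, str] = field(default_factory=dict)  # label -> path
    original: Optional[str] = None          # fit target (default: first frame)
    cohort: Optional[str] = None            # cohort CSV path
    focal_residue: int = DEFAULT_FOCAL_RESIDUE
    trim: Tuple[int, int] = DEFAULT_TRIM
    fit_mask: str = "heavy"                 # all heavy atoms (sole mask so far)
    curve_statistic: str = "mean"
    k_window: int = DEFAULT_K_WINDOW
    table_attributes: Tuple[str, ...] = ("bone_met", "initial_egfr_mutation")
    evaluators: Tuple[str, ...] = EVALUATORS
    out_dir: str = "resiflex_out"
    seed: int = 0
    log_level: str = "INFO"

    def to_json(self) -> str:
        d = asdict(self)
        d["trim"] = list(d["trim"])
        d["table_attributes"] = list(d["table_attributes"])
        d["evaluators"] = list(d["evaluators"])
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        for k in ("trim",):
            if k in d:
                d[k] = tuple(d[k])
        for k in ("table_attributes", "evaluators"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    return {"package": "resiflex", "version": __version__,
            "config": json.loads(config.to_json()),
            "config_hash": config.config_hash, "seed": config.seed}


def _load_traj(path: str) -> Trajectory:
    if os.path.isdir(path):
        from .fixture_io import read_fixture
        return read_fixture(path)
    from .pdbio import read_multimodel_pdb
    return read_multimodel_pdb(path)


def _write_json(path, obj):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_stability_pipeline(config: RunConfig) -> dict:
    """Full residue-stability analysis for each configured trajectory."""
    logging.basicConfig(level=config.log_level)
    if not config.trajectories:
        raise ResiflexError("no trajectories configured")
    os.makedirs(config.out_dir, exist_ok=True)
    original = None
    if config.original:
        original = _load_traj(config.original).frame(0)
    curves = {}
    report = {"provenance": _provenance(config), "labels": {}}
    for label, path in config.trajectories.items():
        t0 = time.perf_counter()
        try:
            traj = _load_traj(path)
            profile, ordering, curve_set = analyze_trajectory(
                traj, original=original,
                focal_residue_number=config.focal_residue, trim=config.trim)
        except ResiflexError as exc:
            raise type(exc)(f"stage stability[{label}] ({path}): {exc}") from None
        prof_df = profile.to_frame()
        prof_df["dist_to_focal_A"] = [ordering.dist_for(r)
                                      for r in profile.residue_numbers]
        prof_df["rank"] = [ordering.rank_of(r)
                           for r in profile.residue_numbers]
        prof_path = os.path.join(config.out_dir, f"{label}_profile.csv")
        prof_df.to_csv(prof_path, index=False, float_format="%.10g")
        curve_df = pd.DataFrame({
            "k": np.arange(curve_set["mean"].n_residues),
            "residue_number": curve_set["mean"].residue_numbers,
            "cumulative_mean_A": curve_set["mean"].values,
        })
        if "std" in curve_set:
            curve_df["cumulative_std_A"] = curve_set["std"].values
        curve_path = os.path.join(config.out_dir, f"{label}_curve.csv")
        curve_df.to_csv(curve_path, index=False, float_format="%.10g")
        curves[label] = curve_set[config.curve_statistic]
        report["labels"][label] = {
            "profile_csv": prof_path, "curve_csv": curve_path,
            "n_frames": profile.n_frames, "n_residues": profile.n_residues,
        }
        log.info("stability[%s]: %d residues x %d frames in %.2fs", label,
                 profile.n_residues, profile.n_frames,
                 time.perf_counter() - t0)
    if curves:
        cmp_res = compare_mutants(curves, k_window=config.k_window)
        report["comparison"] = {
            "k_window": cmp_res.k_window,
            "statistic": cmp_res.statistic,
            "least_stable_first": cmp_res.labels,
            "scores_A": cmp_res.scores,
            "ties": [list(t) for t in cmp_res.ties],
        }
        _write_json(os.path.join(config.out_dir, "comparison.json"),
                    report["comparison"] | {"provenance": report["provenance"]})
    _write_json(os.path.join(config.out_dir, "run_metadata.json"),
                report["provenance"])
    return report


def run_cohort_pipeline(config: RunConfig) -> dict:
    """Cohort tables, proportions, Fisher tests and attribute rankings."""
    logging.basicConfig(level=config.log_level)
    if not config.cohort:
        raise ResiflexError("no cohort CSV configured")
    os.makedirs(config.out_dir, exist_ok=True)
    cohort = load_cohort(config.cohort)
    report = {"provenance": _provenance(config), "n_patients": len(cohort),
              "tables": {}, "rankings": {}}
    for attr in config.table_attributes:
        table = build_contingency(cohort, attr)
        entry = {"rows": [str(r) for r in table.row_labels],
                 "cols": [str(c) for c in table.col_labels],
                 "counts": table.counts.tolist(),
                 "proportions": {}}
        for r in table.row_labels:
            p = proportion(table, r, True if True in table.col_labels else
                           table.col_labels[0])
            entry["proportions"][str(r)] = (
                None if p is None else
                {"k": p.numerator, "n": p.denominator,
                 "percent": p.percent, "percent_rounded": p.percent_rounded})
        if table.counts.shape == (2, 2):
            entry["fisher_p_two_sided"] = fisher_exact_two_sided(table)
        report["tables"][attr] = entry
    if {"second_tki", "third_tki"} <= set(cohort.columns):
        from .datasets import mutation_tki_table
        tab = mutation_tki_table(cohort)
        report["mutation_tki_table"] = {
            tki: {mut: {"k": p.numerator, "n": p.denominator,
                        "percent_rounded": p.percent_rounded}
                  for mut, p in row.items()}
            for tki, row in tab.items()}
    for ev in config.evaluators:
        ranking = rank_attributes(cohort, ev, seed=config.seed)
        report["rankings"][ev] = [
            {"attribute": a, "score": s} for a, s in ranking.ranking]
    _write_json(os.path.join(config.out_dir, "cohort_report.json"), report)
    return report
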