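"""Pipeline configuration: YAML with one section per stage.

A written config re-read yields an identical run; ``default_config``
carries every tunable with its default so thresholds are visible and
citable in the file.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .filtering import FilterConfig

CONFIG_COMMENT = """\
# cloneroute pipeline configuration
# simulator: clonal-evolution simulator (route, depth, purity, noise)
# filter:    multi-sample somatic site filters and presence rescue
# clonality: exact-binomial clonal/subclonal calls vs purity x 0.5
# routes:    seeding-route classification thresholds
"""


def default_config() -> dict:
    return {
        "seed": 0,
        "simulator": {
            "route": "linear",
            "steps": None,  # null -> route-appropriate default
            "branch_size_min": 10,
            "branch_size_max": 60,
            "n_primary_subclones": 2,
            "purity": None,  # null -> drawn per sample from purity range
            "purity_min": 0.3,
            "purity_max": 0.9,
            "mean_depth": 300,
            "terminal_fraction": 0.45,
            "met_private_fraction": 0.7,
            "error_rate": 0.001,
            "germline_rate": 0.0,
            "artifact_rate": 0.0,
            "n_cluster_artifacts": 0,
        },
        "filter": {
            "normal_baf_max": 0.02,
            "min_depth_all": 50,
            "tumor_baf_min": 0.05,
            "rescue_baf_min": 0.025,
            "rescue_depth_min": 200,
            "popaf_max": 0.01,
            "cluster_window": 100,
            "cluster_max": 2,
        },
        "clonality": {
            "ci_level": 0.95,
            "tolerance": 0.2,
        },
        "routes": {
            "min_evidence": 2,
            "containment_tolerance": 0,
            "uncertain_policy": "absent",
        },
    }


def filter_config_from(cfg: dict, exclusion_intervals=None) -> FilterConfig:
    f = cfg.get("filter", {})
    return FilterConfig(
        normal_baf_max=f.get("normal_baf_max", 0.02),
        min_depth_all=f.get("min_depth_all", 50),
        tumor_baf_min=f.get("tumor_baf_min", 0.05),
        rescue_baf_min=f.get("rescue_baf_min", 0.025),
        rescue_depth_min=f.get("rescue_depth_min", 200),
        popaf_max=f.get("popaf_max", 0.01),
        cluster_window=f.get("cluster_window", 100),
        cluster_max=f.get("cluster_max", 2),
        exclusion_intervals=exclusion_intervals,
    )


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for section, values in user.items():
        if isinstance(values, dict) and isinstance(cfg.get(section), dict):
            cfg[section].update(values)
        else:
            cfg[section] = values
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write(CONFIG_COMMENT)
        yaml.safe_dump(cfg, fh, sort_keys=True, default_flow_style=False)


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
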