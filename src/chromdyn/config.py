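"""Declarative pipeline configuration (YAML) with strict key validation."""
from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .errors import ConfigError

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "chromdyn_out",
    "simulation": {
        "n_chroms": 4,
        "chrom_size": 5_000_000,
        "n_genes": 600,
        "gene_min_spacing": 5000,
        "n_static": 100,
        "n_activated": 100,
        "n_esc_only": 30,
        "frac_brg1_bound": 0.8,
        "frac_brg1_bound_static": 0.2,
        "delta_bound": 0.5,
        "base_enrichment": 30.0,
        "n_polycomb": 50,
        "k27me3_enrichment": 10.0,
        "ko_decay": 0.5,
        "bin_size": 25,
        "chip_depth": 1_000_000,
        "rna_depth": 2_000_000,
        "peak_halfwidth": 500,
        "rna_dispersion": 0.05,
        "n_replicates": 2,
    },
    "peak_calling": {
        "window_size": 500,
        "step": 25,
        "q_threshold": 0.01,
        "merge_gap": 100,
        "duplicate_cap": 50,
    },
    "expression": {
        "fdr": 0.01,
        "min_fold": 2.0,
        "rpkm_floor": 0.5,
        "method": "nb",
    },
    "enhancers": {
        "distal_cutoff": 2500,
        "pseudocount": 1.0,
        "stitch_distance": 12500,
        "tss_exclusion": 2500,
    },
    "stats": {
        "n_perm": 10000,
        "perm_seed_offset": 1,
    },
    "density": {
        "flank": 5000,
        "n_bins": 100,
    },
}


def _check_keys(cfg: dict, template: dict, path: str = "") -> None:
    for key, val in cfg.items():
        if key not in template:
            raise ConfigError(f"unknown configuration key: {path}{key}")
        if isinstance(template[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{path}{key} must be a mapping")
            _check_keys(val, template[key], f"{path}{key}.")


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML config over the defaults; unknown keys are rejected."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config file must contain a YAML mapping")
        _check_keys(user, DEFAULT_CONFIG)
        cfg = _deep_merge(cfg, user)
    if overrides:
        _check_keys(overrides, DEFAULT_CONFIG)
        cfg = _deep_merge(cfg, overrides)
    return cfg


def dump_default() -> str:
    return yaml.safe_dump(DEFAULT_CONFIG, sort_keys=False)
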