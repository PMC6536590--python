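"""Pipeline configuration: defaults, YAML loading and validation.

One declarative document drives every stage, so a run of the analysis is
reproducible from (config, seed) alone. CLI flags override file values.
"""

from __future__ import annotations

import copy
from typing import Any, Mapping

import yaml

__all__ = ["DEFAULTS", "load_config", "merge_config"]

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "circular": False,
    "smoothing": {"window_bp": 50, "step_bp": 10},
    "peaks": {"fold_threshold": 3.0, "merge_gap_bp": 50, "min_windows": 2},
    "window": {"flank_bp": 50},
    "promoter": {"upstream_bp": 500, "downstream_bp": 100},
    "motif": {
        "width": 18,
        "symmetric": True,
        "max_iter": 200,
        "tol": 1.0e-6,
        "n_seeds": 10,
    },
    "de": {"fold_cutoff": 5.0, "p_cutoff": 0.05, "bh_correct": False},
    "gating": {"quantile": 0.995},
    "simulation": {
        "length_bp": 500_000,
        "gc_fraction": 0.54,
        "n_genes": 300,
        "mean_gene_bp": 1000,
        "intergenic_bp": 400,
        "n_sites": 30,
        "promoter_fraction": 0.8,
        "mutation_rate": 0.1,
        "background_lambda": 20.0,
        "enrichment_fold": 10.0,
        "site_sd_bp": 60.0,
        "n_replicates": 4,
        "noise_sd": 0.3,
        "effect_log2": -2.8,
        "off_target_fraction": 0.05,
    },
}


def merge_config(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict:
    """Recursively merge ``override`` into ``base`` (returns a new dict)."""
    out = copy.deepcopy(dict(base))
    for key, value in override.items():
        if (
            key in out
            and isinstance(out[key], dict)
            and isinstance(value, Mapping)
        ):
            out[key] = merge_config(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, Mapping):
            raise ValueError(f"{path}: config must be a YAML mapping")
        cfg = merge_config(cfg, user)
    return cfg
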