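"""Run configuration: defaults, YAML loading, presets, validation.

Configuration is a flat namespace of dotted keys (``qc.sp_frac``,
``coex.theta``, ...).  YAML files may spell them dotted or nested; both are
accepted.  Unknown keys are rejected so typos fail loudly, and the fully
resolved configuration is echoed alongside every result bundle.
"""

from __future__ import annotations

import copy

import yaml

from .io_screening import CBMC_CONTAMINATED_ADTS


class ConfigError(ValueError):
    pass


#: key -> (default, allowed types or callable validator)
DEFAULTS: dict = {
    "io.rna_path": None,
    "io.rna_format": "mtx_dir",
    "io.adt_path": None,
    "io.adt_format": "mtx_dir",
    "io.orientation": "features_by_cells",
    "qc.t_frac": 0.01,
    "qc.sp_frac": 0.05,
    "qc.drop_adts": [],
    "qc.species_prefix": None,
    "qc.top_cv_n": 100,
    "qc.strict_adt_names": False,
    "norm.clr_pseudocount": 1.0,
    "norm.literal_eq5": False,
    "reduce.rna_k": "auto",
    "reduce.adt_k": "auto",
    "reduce.multimodal_k": "auto",
    "reduce.passthrough": False,
    "reduce.seed": None,
    "cluster.k_neighbors": 30,
    "cluster.resolution": 1.0,
    "cluster.seed": None,
    "cluster.merge": [],
    "umap.seed": None,
    "umap.n_neighbors": 15,
    "umap.min_dist": 0.5,
    "de.test": "ranksum",
    "de.min_cells": 3,
    "coex.theta": 0.5,
    "coex.epsilon": 1e-6,
    "coex.product_form": False,
    "output.dir": "citemo_out",
    "seed": 0,
    "preset": "none",
}

#: the two published analysis styles, encoded as configuration
PRESETS: dict[str, dict] = {
    "none": {},
    # cord-blood style: drop the three contaminated conjugates, genes must be
    # expressed in >5% of cells, few ADTs so they pass through un-reduced,
    # 10 RNA PCs + all ADTs stacked, 15 multimodal PCs
    "cbmc_like": {
        "qc.drop_adts": list(CBMC_CONTAMINATED_ADTS),
        "qc.sp_frac": 0.05,
        "reduce.passthrough": True,
        "reduce.rna_k": 10,
        "reduce.multimodal_k": 15,
    },
    # bone-marrow style: keep all ADTs, milder sparsity screen, both
    # modalities PCA-reduced (30 RNA + 18 ADT components)
    "hbmc_like": {
        "qc.sp_frac": 0.01,
        "reduce.passthrough": False,
        "reduce.rna_k": 30,
        "reduce.adt_k": 18,
    },
}


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for key, val in d.items():
        dotted = f"{prefix}{key}"
        if isinstance(val, dict) and any(f"{dotted}.{k2}" in DEFAULTS for k2 in val):
            out.update(_flatten(val, f"{dotted}."))
        else:
            out[dotted] = val
    return out


def _check_types(cfg: dict) -> None:
    def expect(key, *types):
        if cfg[key] is not None and not isinstance(cfg[key], types):
            raise ConfigError(f"{key}: expected {'/'.join(t.__name__ for t in types)}, "
                              f"got {type(cfg[key]).__name__}")

    for key in ("qc.t_frac", "qc.sp_frac", "norm.clr_pseudocount", "cluster.resolution",
                "umap.min_dist", "coex.theta", "coex.epsilon"):
        expect(key, int, float)
        if isinstance(cfg[key], bool):
            raise ConfigError(f"{key}: expected a number, got a boolean")
    for key in ("qc.top_cv_n", "cluster.k_neighbors", "umap.n_neighbors",
                "de.min_cells", "seed", "reduce.seed", "cluster.seed", "umap.seed"):
        expect(key, int)
    for key in ("qc.strict_adt_names", "norm.literal_eq5", "reduce.passthrough",
                "coex.product_form"):
        expect(key, bool)
    for key in ("qc.drop_adts", "cluster.merge"):
        expect(key, list)
    for key in ("reduce.rna_k", "reduce.adt_k", "reduce.multimodal_k"):
        val = cfg[key]
        if not (val == "auto" or (isinstance(val, int) and not isinstance(val, bool) and val >= 1)):
            raise ConfigError(f"{key}: must be 'auto' or a positive integer, got {val!r}")

    if not 0 <= cfg["coex.theta"] <= 1:
        raise ConfigError(f"coex.theta must lie in [0, 1], got {cfg['coex.theta']}")
    if not (0 <= cfg["qc.t_frac"] <= 1 and 0 <= cfg["qc.sp_frac"] <= 1):
        raise ConfigError("qc.t_frac and qc.sp_frac must lie in [0, 1]")
    if cfg["coex.epsilon"] <= 0:
        raise ConfigError("coex.epsilon must be positive")
    if cfg["de.test"] not in ("ranksum", "signedrank"):
        raise ConfigError(f"de.test must be ranksum or signedrank, got {cfg['de.test']!r}")
    if cfg["preset"] not in PRESETS:
        raise ConfigError(f"preset must be one of {sorted(PRESETS)}")
    if cfg["reduce.passthrough"] and isinstance(cfg["reduce.adt_k"], int):
        raise ConfigError(
            "reduce.passthrough=true contradicts an explicit reduce.adt_k: "
            "passthrough uses every ADT as-is"
        )
    for pair in cfg["cluster.merge"]:
        if not (isinstance(pair, (list, tuple)) and len(pair) == 2
                and all(isinstance(v, int) for v in pair)):
            raise ConfigError(f"cluster.merge entries must be [label, label] pairs, got {pair!r}")


def resolve_config(overrides: dict | None = None, path: str | None = None) -> dict:
    """Defaults <- preset <- file <- explicit overrides, then validated.

    Per-stage seeds left unset inherit the global ``seed``.
    """
    cfg = copy.deepcopy(DEFAULTS)
    layers = []
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        layers.append(_flatten(loaded))
    if overrides:
        layers.append(_flatten(dict(overrides)))

    preset_name = "none"
    for layer in layers:
        if "preset" in layer:
            preset_name = layer["preset"]
    if preset_name not in PRESETS:
        raise ConfigError(f"preset must be one of {sorted(PRESETS)}")
    cfg.update(PRESETS[preset_name])
    cfg["preset"] = preset_name

    for layer in layers:
        for key, val in layer.items():
            if key not in DEFAULTS:
                raise ConfigError(f"unknown config key {key!r}")
            cfg[key] = val

    _check_types(cfg)
    for stage_seed in ("reduce.seed", "cluster.seed", "umap.seed"):
        if cfg[stage_seed] is None:
            cfg[stage_seed] = cfg["seed"]
    return cfg


def validate_config(path: str) -> dict:
    """Load, validate and resolve a YAML config file."""
    return resolve_config(path=path)
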