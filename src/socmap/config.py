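"""YAML run configuration: layer paths, roles/kinds, model and CV settings.

Example
-------
::

    crs: EPSG:32644
    layers:
      elevation: {path: dem.asc, role: c, kind: continuous}
      soil:      {path: soil.asc, role: s, kind: categorical}
    forest_mask: forest.asc
    road_mask: roads.asc
    plots: plots.csv
    qrf: {n_trees: 500, min_node_size: 5, seed: 1}
    cv: {k: 10, seed: 1}
    variogram: {max_dist_m: 25000, n_bins: 50, n_perm: 99, seed: 1}
    aoa: {quantile: 0.95}
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .qrf import QRFParams
from .raster import CovariateStack, Raster, align_stack, read_raster


def load_config(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    cfg["_base_dir"] = path.parent
    return cfg


def _resolve(cfg: dict, p: str | Path) -> Path:
    p = Path(p)
    return p if p.is_absolute() else cfg["_base_dir"] / p


def load_stack(cfg: dict) -> CovariateStack:
    layers, roles, kinds = {}, {}, {}
    for name, spec in (cfg.get("layers") or {}).items():
        layers[name] = read_raster(_resolve(cfg, spec["path"]))
        roles[name] = spec.get("role", "n")
        kinds[name] = spec.get("kind", "continuous")
    return align_stack(layers, roles=roles, kinds=kinds)


def load_mask(cfg: dict, key: str) -> Raster:
    if key not in cfg:
        raise KeyError(f"config has no '{key}' entry")
    return read_raster(_resolve(cfg, cfg[key]))


def qrf_params(cfg: dict) -> QRFParams:
    q = cfg.get("qrf") or {}
    return QRFParams(
        n_trees=int(q.get("n_trees", 500)),
        mtry=q.get("mtry"),
        min_node_size=int(q.get("min_node_size", 5)),
        seed=int(q.get("seed", 0)),
    )
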