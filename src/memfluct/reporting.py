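"""Small quantification utilities and result export.

Nuclear-to-cytoplasmic intensity ratio (cytoplasmic ROI = cell ROI minus
nuclear ROI), qPCR relative expression (2^-dCT scaled by 1e5, averaged after
transform), and deterministic table export with embedded run metadata.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "NCRatio",
    "ExpressionRecord",
    "nuclear_cytoplasmic_ratio",
    "qpcr_relative_expression",
    "export_results",
    "config_hash",
    "load_config",
]


def load_config(path) -> Dict:
    """Load a YAML run configuration (thresholds, presets, seeds)."""
    with open(path) as handle:
        config = yaml.safe_load(handle) or {}
    if not isinstance(config, dict):
        raise ValueError("configuration must be a mapping")
    return config

QPCR_SCALE = 100_000.0


@dataclass
class NCRatio:
    nuclear_density: float
    cytoplasmic_density: float
    ratio: Optional[float]
    mode: str


def nuclear_cytoplasmic_ratio(image, nuclear_mask, cell_mask,
                              mode: str = "mean-density") -> NCRatio:
    """Nuclear / cytoplasmic intensity density ratio.

    The cytoplasmic region is the cell mask minus the nuclear mask.  In
    ``mean-density`` mode densities are mean intensities; in
    ``integrated-density`` mode they are summed intensities.  An empty
    cytoplasm yields ratio=None (undefined) rather than an exception; a
    nuclear mask not nested in the cell mask is an error.
    """
    if mode not in ("mean-density", "integrated-density"):
        raise ValueError("mode must be mean-density or integrated-density")
    image = np.asarray(image, dtype=float)
    nuclear_mask = np.asarray(nuclear_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if np.any(nuclear_mask & ~cell_mask):
        raise ValueError("nuclear_mask must be nested inside cell_mask")
    cyto_mask = cell_mask & ~nuclear_mask
    if not cyto_mask.any():
        raise ValueError("nuclear_mask must be a strict subset of cell_mask "
                         "(no cytoplasmic region left)")
    if not nuclear_mask.any():
        raise ValueError("nuclear mask is empty")
    if mode == "mean-density":
        nuc = float(image[nuclear_mask].mean())
        cyto = float(image[cyto_mask].mean())
    else:
        nuc = float(image[nuclear_mask].sum())
        cyto = float(image[cyto_mask].sum())
    ratio = nuc / cyto if cyto > 0 else None   # undefined-ratio flag
    return NCRatio(nuclear_density=nuc, cytoplasmic_density=cyto,
                   ratio=ratio, mode=mode)


@dataclass
class ExpressionRecord:
    ct_target: np.ndarray
    ct_housekeeping: np.ndarray
    delta_ct: np.ndarray       # per target replicate vs mean housekeeping CT
    rel_expr: float            # mean of per-replicate 2^-dCT * 1e5


def qpcr_relative_expression(ct_target, ct_housekeeping) -> ExpressionRecord:
    """Relative expression (2^-dCT) * 100,000, averaged after transform.

    dCT is computed per target replicate against the mean housekeeping CT;
    the per-replicate expression values are transformed first and then
    averaged.
    """
    ct_target = np.atleast_1d(np.asarray(ct_target, dtype=float))
    ct_housekeeping = np.atleast_1d(np.asarray(ct_housekeeping, dtype=float))
    if ct_target.size == 0 or ct_housekeeping.size == 0:
        raise ValueError("replicate lists must be non-empty")
    delta_ct = ct_target - ct_housekeeping.mean()
    rel = (2.0 ** -delta_ct) * QPCR_SCALE
    return ExpressionRecord(ct_target=ct_target,
                            ct_housekeeping=ct_housekeeping,
                            delta_ct=delta_ct, rel_expr=float(rel.mean()))


def config_hash(config: Dict) -> str:
    """Stable hash over a canonicalized configuration mapping."""
    canonical = json.dumps(config, sort_keys=True, separators=(",", ":"),
                           default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def export_results(tables: Dict[str, pd.DataFrame], out_dir,
                   config: Optional[Dict] = None, seed: Optional[int] = None,
                   fmt: str = "csv") -> Dict[str, Path]:
    """Write result tables plus a metadata sidecar; byte-stable re-export."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}
    for name, table in tables.items():
        if fmt == "csv":
            path = out_dir / f"{name}.csv"
            table.to_csv(path, index=False, lineterminator="\n")
        elif fmt == "json":
            path = out_dir / f"{name}.json"
            path.write_text(table.to_json(orient="records", indent=2))
        else:
            raise ValueError(f"unknown format {fmt!r}")
        written[name] = path
    meta = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config or {}),
        "tables": sorted(tables),
    }
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    written["run_metadata"] = meta_path
    return written
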