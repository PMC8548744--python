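"""Parameter checkpointing: one archive of named arrays + JSON metadata.

Round-trips are bit-exact: arrays are stored uncompressed at full float64
precision and reloaded verbatim.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["save_checkpoint", "load_checkpoint", "restore_network"]


def save_checkpoint(named_params: dict, path, metadata: dict | None = None) -> None:
    """Write ``name -> Tensor/array`` to ``<path>`` (npz) with a
    ``<path>.meta.json`` sidecar describing variant, skip, dims, seed."""
    path = Path(path)
    if not path.name.endswith(".npz"):
        path = path.with_name(path.name + ".npz")
    arrays = {
        name: (p.value if hasattr(p, "value") else np.asarray(p))
        for name, p in named_params.items()
    }
    np.savez(path, **arrays)
    meta = dict(metadata or {})
    meta["parameters"] = sorted(arrays)
    _meta_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def load_checkpoint(path) -> tuple[dict, dict]:
    """Returns (name -> ndarray, metadata)."""
    path = Path(path)
    if not path.name.endswith(".npz"):
        path = path.with_name(path.name + ".npz")
    with np.load(path) as z:
        arrays = {k: z[k].copy() for k in z.files}
    meta_path = _meta_path(path)
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return arrays, meta


def restore_network(net, arrays: dict) -> None:
    """Load arrays into a network's parameters in place, by name."""
    params = net.named_parameters()
    missing = set(params) - set(arrays)
    if missing:
        raise ValueError(f"checkpoint missing parameters: {sorted(missing)}")
    for name, p in params.items():
        a = np.asarray(arrays[name])
        if a.shape != p.value.shape:
            raise ValueError(f"{name}: shape {a.shape} != {p.value.shape}")
        p.value = a.astype(np.float64, copy=True)


def _meta_path(path: Path) -> Path:
    name = path.name
    if name.endswith(".npz"):
        name = name[: -len(".npz")]
    return path.with_name(name + ".meta.json")
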