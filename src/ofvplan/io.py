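"""Phantom container serialization.

Format (version 1): a single NumPy ``.npz`` archive holding one uint8 array
``mask_<name>`` per structure plus a JSON metadata string under ``meta``
with keys ``format`` ("ofvplan-phantom"), ``version`` (1), ``grid_shape``,
``spacing_mm``, ``slice_thickness_mm``, ``laterality``, and ``seed``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .phantom import Phantom, REQUIRED_ROLES

FORMAT_NAME = "ofvplan-phantom"
FORMAT_VERSION = 1


def save_phantom(phantom: Phantom, path: str | Path) -> None:
    meta = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "grid_shape": list(phantom.grid_shape),
        "spacing_mm": phantom.spacing_mm,
        "slice_thickness_mm": phantom.slice_thickness_mm,
        "laterality": phantom.laterality,
        "seed": phantom.seed,
    }
    arrays = {f"mask_{name}": mask.astype(np.uint8)
              for name, mask in phantom.masks.items()}
    np.savez(path, meta=json.dumps(meta, sort_keys=True), **arrays)


def load_phantom(path: str | Path) -> Phantom:
    with np.load(path) as archive:
        meta = json.loads(str(archive["meta"]))
        if meta.get("format") != FORMAT_NAME:
            raise ValueError(f"{path} is not an {FORMAT_NAME} container")
        if meta.get("version") != FORMAT_VERSION:
            raise ValueError(f"unsupported container version {meta.get('version')}")
        masks = {key[len("mask_"):]: archive[key].astype(bool)
                 for key in archive.files if key.startswith("mask_")}
    missing = set(REQUIRED_ROLES) - set(masks)
    if missing:
        raise ValueError(f"container is missing masks: {sorted(missing)}")
    return Phantom(tuple(meta["grid_shape"]), meta["spacing_mm"],
                   meta["slice_thickness_mm"], masks, meta["laterality"],
                   meta["seed"])
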