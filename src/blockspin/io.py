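"""File formats: model configs (JSON/YAML), sample matrices (TSV/CSV),
partition tables with JSON diagnostics sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import BlockSpinModel, BlockSpinError, build_model
from .sampler import SampleMatrix
from .detect import GroupingResult

__all__ = [
    "read_model_config",
    "write_model_config",
    "read_sample",
    "write_sample",
    "write_partition",
    "read_partition",
]

_CONFIG_KEYS = {"sizes", "J", "labels", "seed"}


def read_model_config(path) -> tuple[BlockSpinModel, int | None]:
    """Load a model config (JSON or YAML by extension).

    Recognised keys: ``sizes`` (list of int), ``J`` (row-major nested list),
    optional ``labels`` (list of int) and ``seed`` (int).  Unknown keys are
    rejected.  Returns ``(model, seed)``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise BlockSpinError("config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise BlockSpinError(f"unknown config keys: {sorted(unknown)}")
    if "sizes" not in raw or "J" not in raw:
        raise BlockSpinError("config requires 'sizes' and 'J'")
    model = build_model(raw["sizes"], raw["J"], labels=raw.get("labels"))
    seed = raw.get("seed")
    return model, (int(seed) if seed is not None else None)


def write_model_config(model: BlockSpinModel, path, seed: int | None = None) -> None:
    """Write a config that round-trips bit-exactly through the reader."""
    path = Path(path)
    payload: dict = {
        "sizes": [int(s) for s in model.sizes],
        "J": [[float(v) for v in row] for row in model.J],
    }
    default_labels = np.repeat(np.arange(model.M), model.sizes)
    if not np.array_equal(model.labels, default_labels):
        payload["labels"] = [int(l) for l in model.labels]
    if seed is not None:
        payload["seed"] = int(seed)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=1))


def read_sample(path, encoding: str = "pm1") -> SampleMatrix:
    """Read a sample matrix from TSV/CSV.

    ``encoding='pm1'`` expects entries in {-1, +1}; ``encoding='01'`` maps
    {0, 1} -> {-1, +1}.  An optional header row ``ind_1..ind_N`` is
    detected and skipped.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    first = path.open().readline()
    header = 0 if "ind_" in first else None
    df = pd.read_csv(path, sep=sep, header=header)
    data = df.to_numpy()
    if encoding == "01":
        if not np.isin(data, (0, 1)).all():
            raise BlockSpinError("entries must be 0 or 1 under encoding '01'")
        data = data * 2 - 1
    elif encoding == "pm1":
        if not np.isin(data, (-1, 1)).all():
            raise BlockSpinError("entries must be -1 or +1 under encoding 'pm1'")
    else:
        raise BlockSpinError(f"unknown encoding {encoding!r}")
    return SampleMatrix(data=data, seed=None, method="file", model_digest=path.name)


def write_sample(sample: SampleMatrix, path, header: bool = True) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(
        sample.data, columns=[f"ind_{k + 1}" for k in range(sample.N)]
    )
    df.to_csv(path, sep=sep, index=False, header=header)


def write_partition(result: GroupingResult, path) -> None:
    """Write the partition TSV (individual, class, label_hat) and a JSON
    diagnostics sidecar at ``<path>.json``."""
    path = Path(path)
    rows = []
    for i, cls in enumerate(result.labels):
        hat = ""
        if cls >= 0 and result.labels_hat is not None:
            hat = result.labels_hat[cls]
            hat = "" if hat is None else int(hat)
        rows.append({"individual": i + 1, "class": int(cls), "label_hat": hat})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    sidecar = {
        "status": result.status,
        "n_classes": result.n_classes,
        "class_sizes": [int(c.size) for c in result.classes],
        "class_level": [int(u) for u in result.class_level],
        "ambiguous": bool(result.ambiguous),
        "diagnostics": result.diagnostics,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_partition(path):
    """Read back a partition TSV and its JSON sidecar."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    return table, sidecar
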