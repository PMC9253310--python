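"""Readers/writers for the tabular and volumetric interchange formats.

Everything tabular is tab-separated with a header row. Lattice-embedded
phantoms can additionally be written as NIfTI label/scalar volumes.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .fingerprints import ENDPOINT_COLUMNS, Fingerprint, SeedRegion

__all__ = [
    "write_coordinates", "read_coordinates",
    "write_fingerprint", "read_fingerprint",
    "write_endpoint_table", "read_endpoint_table",
    "write_timeseries", "read_timeseries",
    "write_morphometry",
    "write_labels", "read_labels",
    "write_config_sidecar",
    "write_label_nifti", "read_label_nifti",
    "write_json",
]


def write_coordinates(path, phantom):
    df = pd.DataFrame(
        {
            "unit_id": np.arange(phantom.n_units),
            "x": phantom.coordinates[:, 0],
            "y": phantom.coordinates[:, 1],
            "z": phantom.coordinates[:, 2],
            "axis": phantom.axis_coordinate,
            "true_label": phantom.true_labels,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_coordinates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fingerprint(path, fp: Fingerprint):
    pd.DataFrame(fp.matrix, columns=list(fp.target_names)).to_csv(
        path, sep="\t", index=False
    )


def read_fingerprint(path, normalization: str = "raw") -> Fingerprint:
    df = pd.read_csv(path, sep="\t")
    return Fingerprint(df.to_numpy(float), tuple(df.columns), normalization)


def write_endpoint_table(path, table: pd.DataFrame):
    table.loc[:, list(ENDPOINT_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_endpoint_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_timeseries(path, matrix):
    pd.DataFrame(np.asarray(matrix)).to_csv(path, sep="\t", index=False, header=False)


def read_timeseries(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", header=None).to_numpy(float)


def write_morphometry(path, maps):
    pd.DataFrame({"myelin": maps.myelin, "thickness": maps.thickness}).to_csv(
        path, sep="\t", index=False
    )


def write_labels(path, labels, unit_ids=None):
    n = len(labels)
    ids = np.arange(n) if unit_ids is None else np.asarray(unit_ids)
    pd.DataFrame({"unit_id": ids, "label": np.asarray(labels)}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_config_sidecar(path, config, extra=None):
    """YAML sidecar capturing every generation parameter plus seeds."""
    payload = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(config).items()
    }
    payload["fingerprint_concentration"] = (
        None
        if not np.isfinite(payload["fingerprint_concentration"])
        else float(payload["fingerprint_concentration"])
    )
    if extra:
        payload.update(extra)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def _lattice_volume(coordinates, values, fill=0.0):
    coords = np.asarray(coordinates)
    idx = np.round(coords - coords.min(axis=0)).astype(int)
    shape = idx.max(axis=0) + 1
    vol = np.full(tuple(shape), fill, dtype=float)
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = values
    return vol, coords.min(axis=0)


def write_label_nifti(path, phantom, labels=None, label_order=("HG1", "HG2", "HG3")):
    """Integer label volume on the phantom's 1 mm lattice (0 = background,
    1.. = label_order)."""
    labels = phantom.true_labels if labels is None else np.asarray(labels)
    code = {name: i + 1 for i, name in enumerate(label_order)}
    values = np.array([code.get(l, 0) for l in labels], dtype=float)
    vol, origin = _lattice_volume(phantom.coordinates, values)
    affine = np.eye(4)
    affine[:3, 3] = origin
    nib.save(nib.Nifti1Image(vol.astype(np.int16), affine), str(path))


def read_label_nifti(path, label_order=("HG1", "HG2", "HG3")):
    """Load a label volume back into (SeedRegion, labels) in mm coordinates."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    idx = np.argwhere(data > 0)
    codes = data[idx[:, 0], idx[:, 1], idx[:, 2]].astype(int)
    mm = nib.affines.apply_affine(img.affine, idx)
    labels = np.array([label_order[c - 1] for c in codes], dtype=object)
    return SeedRegion(mm, np.arange(len(mm))), labels


def write_json(path, payload):
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default))
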