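"""Readers, writers, and configuration for the command-line front end.

File conventions
----------------
* Vector fields: an HDF5 group with datasets ``vectors`` (float,
  (t, *grid, D)) and ``validity`` (uint8), and attributes ``grid_step``,
  ``grid_origin``, ``units`` plus provenance metadata.
* Label maps: HDF5 dataset ``labels`` (uint8, 0 = none / 1 = V / 2 = D).
* Images: multi-page TIFF (time as pages, z folded per frame for 3D) or
  an HDF5 dataset with an ``axes`` attribute of ``"tyx"`` / ``"tzyx"``.
* Configs and presets: TOML; angles in degrees, speeds in px (or vx) per
  frame.

Anatomical-to-array axis mapping (documented once, used everywhere):
image row index increases ventrally (downward), so a reference vector
given anatomically as (rx, ry[, rz]) with y pointing dorsally becomes
``(-ry, rx)`` in 2D (row, col) components and ``(rz, -ry, rx)`` in 3D
(z, row, col) components; the dorsal axis "up" is ``(-1, 0)`` / ``(0,
-1, 0)``.  Cylinder-map references are given per side directly in
(longitudinal, latitudinal) map components.
"""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .piv import ImageSequence, PivConfig, VectorFieldSequence
from .segmentation import ReferenceField, WaveParams, WaveRecord

__all__ = [
    "RunConfig",
    "load_config",
    "load_preset",
    "preset_wave_params",
    "read_field_h5",
    "write_field_h5",
    "read_labels_h5",
    "write_labels_h5",
    "read_image_sequence",
    "read_mask",
    "wave_records_to_frame",
    "write_wave_records_csv",
]

PRESET_NAMES = ("lateral", "volume", "cylinder")

_PARAM_KEYS_REQUIRED = (
    "theta_r",
    "theta_V",
    "theta_D",
    "theta_VD",
    "M_min",
    "M_avg",
    "M_total",
)
_PARAM_KEYS_OPTIONAL = ("window_N", "max_gap", "enforce_dorsal_halfplane")


# -- HDF5 fields and labels -------------------------------------------------


def write_field_h5(path, fields: VectorFieldSequence, config_hash: str = "") -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("field")
        g.create_dataset("vectors", data=fields.vectors)
        g.create_dataset("validity", data=fields.validity.astype(np.uint8))
        g.attrs["grid_step"] = fields.grid_step
        g.attrs["grid_origin"] = fields.grid_origin
        g.attrs["units"] = fields.units
        g.attrs["axis_order"] = "yx" if fields.ndim == 2 else "zyx"
        g.attrs["coordinate_base"] = 0
        g.attrs["tool_version"] = __version__
        g.attrs["config_hash"] = config_hash


def read_field_h5(path) -> VectorFieldSequence:
    with h5py.File(path, "r") as f:
        g = f["field"]
        return VectorFieldSequence(
            vectors=g["vectors"][...],
            validity=g["validity"][...].astype(bool),
            grid_step=tuple(int(s) for s in g.attrs["grid_step"]),
            grid_origin=tuple(int(o) for o in g.attrs["grid_origin"]),
            units=str(g.attrs.get("units", "px/frame")),
        )


def write_labels_h5(path, labels: np.ndarray, config_hash: str = "") -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("labels", data=np.asarray(labels, dtype=np.uint8))
        d.attrs["legend"] = "0=none 1=V 2=D"
        d.attrs["tool_version"] = __version__
        d.attrs["config_hash"] = config_hash


def read_labels_h5(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["labels"][...]


# -- images and masks -------------------------------------------------------


def read_image_sequence(path, n_z: int | None = None) -> ImageSequence:
    """Read a TIFF or HDF5 recording.

    TIFF pages are time frames; for a 3D recording stored as a flat page
    stack pass ``n_z`` to fold z into each frame.  HDF5 files must hold a
    dataset named ``data`` with an ``axes`` attribute (``tyx``/``tzyx``).
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            ds = f["data"]
            axes = str(ds.attrs.get("axes", "tyx"))
            data = ds[...]
        if axes not in ("tyx", "tzyx"):
            raise ValueError(f"unsupported axes attribute {axes!r}")
        return ImageSequence(data=data)
    data = tifffile.imread(path)
    if n_z is not None:
        if data.shape[0] % n_z:
            raise ValueError("page count is not a multiple of n_z")
        data = data.reshape(data.shape[0] // n_z, n_z, *data.shape[1:])
    return ImageSequence(data=np.asarray(data))


def read_mask(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return f["data"][...].astype(bool)
    return np.asarray(tifffile.imread(path)).astype(bool)


# -- wave tables ------------------------------------------------------------


def wave_records_to_frame(records: list[WaveRecord]) -> pd.DataFrame:
    """Tabulate per-position wave records."""
    rows = []
    for r in records:
        rows.append(
            {
                "position": "-".join(str(c) for c in (r.position or ())),
                "t_max": r.t_max,
                "t_min": r.t_min,
                "v_start": r.v_frames[0],
                "v_stop": r.v_frames[1],
                "d_start": r.d_frames[0],
                "d_stop": r.d_frames[1],
                "v_duration": r.v_duration,
                "d_duration": r.d_duration,
                "mean_speed_v": r.mean_speed_v,
                "total_displacement": r.total_displacement,
            }
        )
    columns = [
        "position",
        "t_max",
        "t_min",
        "v_start",
        "v_stop",
        "d_start",
        "d_stop",
        "v_duration",
        "d_duration",
        "mean_speed_v",
        "total_displacement",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_wave_records_csv(path, records: list[WaveRecord]) -> None:
    wave_records_to_frame(records).to_csv(path, index=False, float_format="%.6f")


# -- configuration ----------------------------------------------------------


@dataclass
class RunConfig:
    """Validated configuration of the end-to-end pipeline."""

    representation: str
    params: WaveParams
    reference: dict[str, Any]
    piv: PivConfig = field(default_factory=PivConfig)
    images_path: str | None = None
    fields_path: str | None = None
    mask_path: str | None = None
    distortion_path: str | None = None
    synthetic_preset: str | None = None
    seed: int = 0
    noise_sigma: float = 0.2
    rupture_frame: int | None = None
    polar_crop_rows: int = 0
    split_col: int | None = None
    open_radius: int = 1
    min_size: int = 50
    region_path: str | None = None
    config_hash: str = ""

    def reference_field(self, grid_shape: tuple[int, ...]) -> ReferenceField:
        return build_reference_field(
            self.representation, self.reference, grid_shape, split_col=self.split_col
        )


def _parse_wave_params(raw: dict[str, Any], representation: str) -> WaveParams:
    unknown = set(raw) - set(_PARAM_KEYS_REQUIRED) - set(_PARAM_KEYS_OPTIONAL)
    if unknown:
        raise ValueError(f"unknown parameter key(s): {sorted(unknown)}")
    for key in _PARAM_KEYS_REQUIRED:
        if key not in raw:
            raise ValueError(f"missing required parameter key: {key}")
    kwargs = dict(raw)
    if kwargs.get("enforce_dorsal_halfplane", True):
        kwargs["dorsal_axis"] = _dorsal_axis(representation)
    return WaveParams(**kwargs)


def _dorsal_axis(representation: str) -> np.ndarray | None:
    if representation == "lateral":
        return np.array([-1.0, 0.0])
    if representation == "volume":
        return np.array([0.0, -1.0, 0.0])
    return None  # cylinder: the half-plane gate is not used


def anatomical_to_axis_order(rx: float, ry: float, rz: float | None = None) -> np.ndarray:
    """Map anatomical (rx, ry[, rz]) with y = dorsal-up to array axis order."""
    if rz is None:
        return np.array([-ry, rx])
    return np.array([rz, -ry, rx])


def build_reference_field(
    representation: str,
    ref: dict[str, Any],
    grid_shape: tuple[int, ...],
    split_col: int | None = None,
) -> ReferenceField:
    if representation in ("lateral", "volume"):
        r = anatomical_to_axis_order(ref["rx"], ref["ry"], ref.get("rz"))
        return ReferenceField.constant(r, grid_shape)
    if representation == "cylinder":
        if split_col is None:
            split_col = grid_shape[-1] // 2
        left = np.array([ref["rx_left"], ref["ry"]])
        right = np.array([ref["rx_right"], ref["ry"]])
        return ReferenceField.split_columns(left, right, split_col, grid_shape)
    raise ValueError(f"unknown representation {representation!r}")


def load_preset(name: str) -> dict[str, Any]:
    """Parsed packaged preset (raw values plus a constructed WaveParams)."""
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    text = resources.files("waveseg.presets").joinpath(f"{name}.toml").read_text()
    raw = tomllib.loads(text)
    raw["params_obj"] = _parse_wave_params(raw["params"], raw["representation"])
    return raw


def preset_wave_params(name: str) -> WaveParams:
    return load_preset(name)["params_obj"]


_TOP_KEYS = {
    "representation",
    "params",
    "params_preset",
    "reference",
    "piv",
    "input",
    "postprocess",
    "rupture_frame",
    "polar_crop_rows",
    "split_col",
    "seed",
}


def load_config(path) -> RunConfig:
    """Load and validate a TOML run configuration.

    Either a ``params_preset`` name or a full ``[params]`` table (all
    seven threshold keys) must be present; unknown keys raise descriptive
    errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = tomllib.loads(path.read_text())
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")

    preset_name = raw.get("params_preset")
    if preset_name is not None:
        preset = load_preset(preset_name)
        representation = raw.get("representation", preset["representation"])
        params = preset["params_obj"]
        reference = dict(preset["reference"])
    else:
        if "representation" not in raw:
            raise ValueError("missing required config key: representation")
        representation = raw["representation"]
        if "params" not in raw:
            raise ValueError("missing required config key: params (or params_preset)")
        params = _parse_wave_params(raw["params"], representation)
        if "reference" not in raw:
            raise ValueError("missing required config key: reference")
        reference = dict(raw["reference"])
    reference.update(raw.get("reference", {}))
    _validate_reference(representation, reference)

    piv_raw = raw.get("piv", {})
    piv_keys = {"interrogation_size", "search_margin", "grid_step", "min_mask_fraction", "subpixel"}
    unknown = set(piv_raw) - piv_keys
    if unknown:
        raise ValueError(f"unknown piv key(s): {sorted(unknown)}")
    piv = PivConfig(**piv_raw)

    inp = raw.get("input", {})
    input_keys = {"images", "fields", "mask", "distortion", "synthetic", "noise_sigma"}
    unknown = set(inp) - input_keys
    if unknown:
        raise ValueError(f"unknown input key(s): {sorted(unknown)}")

    post = raw.get("postprocess", {})
    post_keys = {"open_radius", "min_size", "region"}
    unknown = set(post) - post_keys
    if unknown:
        raise ValueError(f"unknown postprocess key(s): {sorted(unknown)}")

    cfg = RunConfig(
        representation=representation,
        params=params,
        reference=reference,
        piv=piv,
        images_path=inp.get("images"),
        fields_path=inp.get("fields"),
        mask_path=inp.get("mask"),
        distortion_path=inp.get("distortion"),
        synthetic_preset=inp.get("synthetic"),
        seed=int(raw.get("seed", 0)),
        noise_sigma=float(inp.get("noise_sigma", 0.2)),
        rupture_frame=raw.get("rupture_frame"),
        polar_crop_rows=int(raw.get("polar_crop_rows", 0)),
        split_col=raw.get("split_col"),
        open_radius=int(post.get("open_radius", 1)),
        min_size=int(post.get("min_size", 50)),
        region_path=post.get("region"),
        config_hash=hashlib.sha256(path.read_bytes()).hexdigest()[:16],
    )
    if (
        cfg.images_path is None
        and cfg.fields_path is None
        and cfg.synthetic_preset is None
    ):
        raise ValueError("config must name input images, fields, or a synthetic preset")
    return cfg


def _validate_reference(representation: str, reference: dict[str, Any]) -> None:
    if representation == "cylinder":
        required = {"rx_left", "rx_right", "ry"}
    elif representation == "volume":
        required = {"rx", "ry", "rz"}
    elif representation == "lateral":
        required = {"rx", "ry"}
    else:
        raise ValueError(f"unknown representation {representation!r}")
    missing = required - set(reference)
    if missing:
        raise ValueError(f"missing reference key(s): {sorted(missing)}")
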