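"""End-to-end run: PIV -> wave segmentation -> post-processing -> descriptors.

``run_pipeline`` executes the stages named in a :class:`~waveseg.io.RunConfig`
and writes a reproducible artifact bundle: vector fields, raw and cleaned
label maps, a per-wave CSV table, per-phase kymographs, divergence maps
(2D only), and a JSON summary report.  Every output embeds the config
hash and tool version; reruns on identical inputs are byte-identical.

The summary counts *wave events*: maximal runs of consecutive time steps
in which the cleaned label map is non-empty.  Events are split into
pre-/post-rupture epochs at a user-supplied rupture frame (the rupture
itself is identified visually, not by this tool).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__, io, synthetic
from .cartography import DistortionGrid, correct_distortion
from .descriptors import divergence_map, label_kymographs
from .piv import VectorFieldSequence, average_velocity, compute_piv_sequence
from .postprocess import morphological_open_labels, region_filter, size_filter
from .segmentation import WaveRecord, segment_field

__all__ = ["run_pipeline", "summary_report", "wave_events"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def wave_events(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive frames with any non-zero label."""
    active = np.array([bool(np.any(frame)) for frame in labels])
    events: list[tuple[int, int]] = []
    start: int | None = None
    for t, a in enumerate(active):
        if a and start is None:
            start = t
        elif not a and start is not None:
            events.append((start, t - 1))
            start = None
    if start is not None:
        events.append((start, len(active) - 1))
    return events


def summary_report(
    records: list[WaveRecord],
    labels: np.ndarray,
    rupture_frame: int | None,
    split_col: int | None = None,
) -> dict[str, Any]:
    """Operational wave statistics from records and a cleaned label map."""
    events = wave_events(labels)
    if rupture_frame is None:
        pre = len(events)
        post = None
    else:
        pre = sum(1 for s, _ in events if s < rupture_frame)
        post = len(events) - pre
    v_durations = [r.v_duration for r in records]
    d_durations = [r.d_duration for r in records]
    area = (labels > 0).sum(axis=tuple(range(1, labels.ndim)))
    report: dict[str, Any] = {
        "n_wave_events": len(events),
        "wave_events": [list(e) for e in events],
        "pre_rupture_wave_count": pre,
        "post_rupture_wave_count": post,
        "n_position_records": len(records),
        "median_v_duration": float(np.median(v_durations)) if v_durations else None,
        "median_d_duration": float(np.median(d_durations)) if d_durations else None,
        "segmented_area_per_frame": area.astype(int).tolist(),
    }
    if split_col is not None and labels.ndim == 3:
        left = (labels[:, :, :split_col] > 0).sum(axis=(1, 2))
        right = (labels[:, :, split_col:] > 0).sum(axis=(1, 2))
        report["segmented_area_per_frame_left"] = left.astype(int).tolist()
        report["segmented_area_per_frame_right"] = right.astype(int).tolist()
    return report


def _obtain_fields(cfg: io.RunConfig) -> VectorFieldSequence:
    if cfg.synthetic_preset is not None:
        if cfg.synthetic_preset != "mini":
            raise ValueError(f"unknown synthetic preset {cfg.synthetic_preset!r}")
        return synthetic.mini_scene(seed=cfg.seed, noise_sigma=cfg.noise_sigma).fields
    if cfg.fields_path is not None:
        return io.read_field_h5(cfg.fields_path)
    images = io.read_image_sequence(cfg.images_path)
    mask = io.read_mask(cfg.mask_path) if cfg.mask_path else None
    return compute_piv_sequence(images, mask, cfg.piv)


def run_pipeline(cfg: io.RunConfig, outdir) -> dict[str, Any]:
    """Run all stages and write the artifact bundle into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        fields = _obtain_fields(cfg)
    except Exception as exc:  # noqa: BLE001 - stage-named rewrap
        raise StageError(f"input/PIV stage failed: {exc}") from exc

    try:
        if cfg.distortion_path is not None:
            grid = DistortionGrid.from_csv(cfg.distortion_path)
            fields = correct_distortion(fields, grid)
        if cfg.polar_crop_rows > 0:
            c = cfg.polar_crop_rows
            fields = VectorFieldSequence(
                vectors=fields.vectors[:, c:-c],
                validity=fields.validity[:, c:-c],
                grid_step=fields.grid_step,
                grid_origin=(
                    fields.grid_origin[0] + c * fields.grid_step[0],
                    *fields.grid_origin[1:],
                ),
                units=fields.units,
            )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"distortion stage failed: {exc}") from exc

    io.write_field_h5(outdir / "fields.h5", fields, cfg.config_hash)

    try:
        refs = cfg.reference_field(fields.grid_shape)
        records, labels_raw = segment_field(fields, refs, cfg.params)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"segmentation stage failed: {exc}") from exc

    try:
        labels = morphological_open_labels(labels_raw, cfg.open_radius)
        labels = size_filter(labels, cfg.min_size)
        if cfg.region_path:
            labels = region_filter(labels, io.read_mask(cfg.region_path))
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"postprocess stage failed: {exc}") from exc

    io.write_labels_h5(outdir / "labels_raw.h5", labels_raw, cfg.config_hash)
    io.write_labels_h5(outdir / "labels.h5", labels, cfg.config_hash)
    io.write_wave_records_csv(outdir / "waves.csv", records)

    try:
        kymos = label_kymographs(labels, axis="x") if labels.ndim == 3 else {}
        for phase, kymo in kymos.items():
            np.savetxt(
                outdir / f"kymograph_{phase}.csv",
                kymo,
                delimiter=",",
                fmt="%.1f",
                header=f"config_hash={cfg.config_hash} version={__version__}",
            )
        div = None
        if fields.ndim == 2 and all(
            n >= 17 for n in fields.grid_shape
        ):
            div = divergence_map(fields)
            with_h5 = outdir / "divergence.h5"
            import h5py

            with h5py.File(with_h5, "w") as f:
                d = f.create_dataset("divergence", data=div)
                d.attrs["config_hash"] = cfg.config_hash
                d.attrs["tool_version"] = __version__
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"descriptor stage failed: {exc}") from exc

    report = summary_report(records, labels, cfg.rupture_frame, cfg.split_col)
    report["avg_velocity_per_frame"] = [
        None if np.isnan(v) else round(float(v), 6) for v in average_velocity(fields)
    ]
    report["config_hash"] = cfg.config_hash
    report["tool_version"] = __version__
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    return {
        "fields": fields,
        "records": records,
        "labels_raw": labels_raw,
        "labels": labels,
        "kymographs": kymos,
        "divergence": div,
        "report": report,
    }
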