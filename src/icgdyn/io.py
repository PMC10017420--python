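"""File I/O: videos as multi-page TIFF (or MP4/AVI through imageio when a
backend is available), ROI annotations as JSON, traces as CSV + JSON
metadata, maps as TIFF/PNG."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError
from .trace_extraction import FrameSequencePair, ROISpec, ROITrace

__all__ = [
    "save_pair",
    "load_pair",
    "load_video",
    "load_rois",
    "save_rois",
    "save_trace",
    "load_trace",
    "save_label_map",
    "save_rgb",
    "save_float_map",
]


def save_pair(pair: FrameSequencePair, out_dir: str | Path, stem: str = "scene") -> dict:
    """Write the NIR (and white-light / overlay) stacks as multi-page TIFFs
    plus a metadata JSON; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    nir_path = out / f"{stem}_nir.tif"
    tifffile.imwrite(nir_path, pair.nir)
    paths["nir"] = str(nir_path)
    if pair.white is not None:
        p = out / f"{stem}_white.tif"
        tifffile.imwrite(p, pair.white)
        paths["white"] = str(p)
    if pair.overlay is not None:
        p = out / f"{stem}_overlay.tif"
        tifffile.imwrite(p, pair.overlay)
        paths["overlay"] = str(p)
    meta = {"fps": pair.fps, "timestamps": pair.timestamps.tolist()}
    meta_path = out / f"{stem}_meta.json"
    meta_path.write_text(json.dumps(meta))
    paths["meta"] = str(meta_path)
    return paths


def load_video(path: str | Path) -> np.ndarray:
    """Load a video file as a frame stack; TIFF natively, otherwise via
    imageio (requires an ffmpeg backend for MP4/AVI)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    import imageio.v3 as iio

    try:
        return iio.imread(path)
    except Exception as e:  # pragma: no cover - backend-dependent
        raise FormatError(
            f"cannot read {path}: no suitable imageio backend ({e}); "
            "convert to multi-page TIFF"
        ) from e


def load_pair(
    white_path: str | Path | None,
    nir_path: str | Path,
    fps: float = 30.0,
    overlay_mode: bool = False,
) -> FrameSequencePair:
    """Assemble a FrameSequencePair from video files.

    In overlay mode ``nir_path`` may point at an RGB overlay video; the
    NIR channel is recovered by green-channel extraction.
    """
    nir = load_video(nir_path)
    if nir.ndim == 4:
        if not overlay_mode:
            raise FormatError("NIR stack is RGB; pass overlay_mode=True for overlay video")
        from .trace_extraction import overlay_to_grayscale

        nir = np.stack([overlay_to_grayscale(f) for f in nir])
    white = None
    if white_path is not None and not overlay_mode:
        white = load_video(white_path)
    timestamps = np.arange(nir.shape[0]) / fps
    return FrameSequencePair(nir=nir, timestamps=timestamps, fps=fps, white=white)


def load_rois(path: str | Path) -> list[ROISpec]:
    """ROI annotations from JSON: a list of objects with keys
    roi_id, patient_id, label, frame, polygon ([[row, col], ...])."""
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = data.get("rois", [data])
    return [
        ROISpec(
            polygon=np.asarray(item["polygon"], dtype=float),
            label=item["label"],
            roi_id=str(item["roi_id"]),
            patient_id=str(item.get("patient_id", "")),
            frame=int(item.get("frame", 0)),
        )
        for item in data
    ]


def save_rois(rois: list[ROISpec], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            [
                {
                    "roi_id": r.roi_id,
                    "patient_id": r.patient_id,
                    "label": r.label,
                    "frame": r.frame,
                    "polygon": r.polygon.tolist(),
                }
                for r in rois
            ],
            indent=2,
        )
    )


def save_trace(trace: ROITrace, out_dir: str | Path) -> tuple[Path, Path]:
    """Trace as CSV (time_s, intensity_gu) plus a JSON metadata sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / f"{trace.roi_id}.csv"
    pd.DataFrame({"time_s": trace.times, "intensity_gu": trace.intensities}).to_csv(
        csv_path, index=False
    )
    meta_path = out / f"{trace.roi_id}.json"
    meta_path.write_text(
        json.dumps(
            {
                "roi_id": trace.roi_id,
                "patient_id": trace.patient_id,
                "label": trace.label,
                "fps": trace.fps,
                "n_samples": trace.n_samples,
            }
        )
    )
    return csv_path, meta_path


def load_trace(csv_path: str | Path) -> ROITrace:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta_path = csv_path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    times = df["time_s"].to_numpy()
    dt = np.median(np.diff(times)) if len(times) > 1 else 1.0
    return ROITrace(
        times=times,
        intensities=df["intensity_gu"].to_numpy(),
        fps=float(meta.get("fps", 1.0 / dt)),
        label=meta.get("label", "unknown"),
        roi_id=meta.get("roi_id", csv_path.stem),
        patient_id=meta.get("patient_id", ""),
    )


def save_label_map(labels: np.ndarray, path: str | Path) -> None:
    """Integer label image as PNG (labels offset by +1 so -1 = 0 = black)."""
    import imageio.v3 as iio

    arr = (np.asarray(labels) + 1).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def save_rgb(image: np.ndarray, path: str | Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def save_float_map(map_: np.ndarray, path: str | Path) -> None:
    """Quantitative map as 32-bit single-channel TIFF."""
    tifffile.imwrite(Path(path), np.asarray(map_, dtype=np.float32))
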