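"""Readers and writers for every on-disk artifact the pipelines touch.

Two open stack dialects are supported:

* multi-page TIFF / OME-TIFF (float32 or uint16), read with :mod:`tifffile`;
* raw little-endian float32 binary with a mandatory JSON sidecar giving the
  array shape and acquisition metadata.

All arrays are time-major ``(T, rows, cols)``; pixel indexing is 0-based and
row-major; times are seconds from frame 0.  Proprietary vendor containers
(acquisition-software ``.dat``, Zeiss LSM) are deliberately not parsed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "StackMetadata",
    "EventMarkers",
    "read_stack",
    "write_stack",
    "write_table",
    "read_table",
    "write_heatmap",
    "read_heatmap_matrix",
    "DEFAULT_SAMPLING_RATE_HZ",
    "DEFAULT_PIXEL_SIZE_UM",
]

#: Default acquisition rates per modality: LSCI perfusion imaging at 4.4 Hz,
#: two-photon vessel time series at one frame per 2 s.
DEFAULT_SAMPLING_RATE_HZ = {"lsci": 4.4, "tpm": 0.5}
DEFAULT_PIXEL_SIZE_UM = 1.0

_TIFF_SUFFIXES = {".tif", ".tiff"}


@dataclass
class StackMetadata:
    """Acquisition metadata for one time-ordered image stack.

    Parameters
    ----------
    sampling_rate_hz
        Acquisitions per second (> 0).
    pixel_size_um
        Physical edge length of one pixel/voxel in micrometres (> 0).
    time_origin_s
        Timestamp of frame 0 in seconds.
    modality
        ``"lsci"`` (wide-field perfusion) or ``"tpm"`` (two-photon).
    """

    sampling_rate_hz: float
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    time_origin_s: float = 0.0
    modality: str = "lsci"

    def __post_init__(self) -> None:
        if self.modality not in ("lsci", "tpm"):
            raise ValueError(f"modality must be 'lsci' or 'tpm', got {self.modality!r}")
        if not self.sampling_rate_hz > 0:
            raise ValueError(f"sampling_rate_hz must be > 0, got {self.sampling_rate_hz}")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")

    def frame_times(self, n_frames: int) -> np.ndarray:
        """Timestamps in seconds for ``n_frames`` frames starting at the origin."""
        return self.time_origin_s + np.arange(n_frames) / self.sampling_rate_hz

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EventMarkers:
    """Externally supplied stimulus events, e.g. a capnograph-defined CO2 window.

    ``events`` is a list of ``(label, start_s, end_s)`` with ``start_s < end_s``
    and no overlap between events sharing a label.
    """

    events: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_label: dict[str, list[tuple[float, float]]] = {}
        for label, start, end in self.events:
            if not start < end:
                raise ValueError(f"event {label!r}: start_s {start} must be < end_s {end}")
            by_label.setdefault(label, []).append((start, end))
        for label, spans in by_label.items():
            spans = sorted(spans)
            for (s0, e0), (s1, _e1) in zip(spans, spans[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping events for label {label!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "EventMarkers":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(events=[(str(e["label"]), float(e["start_s"]), float(e["end_s"])) for e in raw])

    def to_json(self, path: str | Path) -> None:
        payload = [{"label": l, "start_s": s, "end_s": e} for l, s, e in self.events]
        Path(path).write_text(json.dumps(payload, indent=2))

    def for_label(self, label: str) -> list[tuple[float, float]]:
        return sorted((s, e) for l, s, e in self.events if l == label)


def _metadata_from_mapping(raw: Mapping, context: str) -> StackMetadata:
    """Build metadata from a sidecar mapping, warning on every assumed default."""
    modality = raw.get("modality")
    if modality is None:
        modality = "lsci"
        warnings.warn(f"{context}: no modality in sidecar, assuming 'lsci'")
    rate = raw.get("sampling_rate_hz")
    if rate is None:
        rate = DEFAULT_SAMPLING_RATE_HZ[modality]
        warnings.warn(
            f"{context}: no sampling_rate_hz in sidecar, assuming {rate} Hz ({modality} default)"
        )
    pixel = raw.get("pixel_size_um")
    if pixel is None:
        pixel = DEFAULT_PIXEL_SIZE_UM
        warnings.warn(f"{context}: no pixel_size_um in sidecar, assuming {pixel} um")
    origin = float(raw.get("time_origin_s", 0.0))
    return StackMetadata(
        sampling_rate_hz=float(rate),
        pixel_size_um=float(pixel),
        time_origin_s=origin,
        modality=str(modality),
    )


def read_stack(
    path: str | Path, metadata_path: str | Path | None = None
) -> tuple[np.ndarray, StackMetadata]:
    """Read a time-ordered image stack plus its acquisition metadata.

    ``path`` is either a multi-page TIFF/OME-TIFF or a raw little-endian
    float32 binary.  Raw binaries require a JSON sidecar (``metadata_path`` or
    ``<path>.json``) providing at least ``shape``; TIFFs may carry an optional
    sidecar for the metadata fields.  Absent fields fall back to documented
    defaults with a warning.

    Returns
    -------
    (frames, metadata)
        ``frames`` has shape ``(T, rows, cols)`` in acquisition order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar: dict = {}
    sidecar_path = Path(metadata_path) if metadata_path is not None else path.with_name(path.name + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
    elif metadata_path is not None:
        raise FileNotFoundError(metadata_path)

    if path.suffix.lower() in _TIFF_SUFFIXES:
        frames = np.asarray(tifffile.imread(path))
        if frames.ndim == 2:
            frames = frames[None]
        if frames.ndim != 3:
            raise ValueError(f"{path}: expected a 2-D page series, got ndim={frames.ndim}")
    else:
        if "shape" not in sidecar:
            raise ValueError(f"{path}: raw binary stacks need a JSON sidecar with 'shape'")
        shape = tuple(int(s) for s in sidecar["shape"])
        if len(shape) != 3:
            raise ValueError(f"{path}: sidecar shape must be (T, rows, cols), got {shape}")
        data = np.fromfile(path, dtype="<f4")
        if data.size != int(np.prod(shape)):
            raise ValueError(
                f"{path}: byte count implies {data.size} float32 values, "
                f"sidecar shape {shape} needs {int(np.prod(shape))}"
            )
        frames = data.reshape(shape)
    meta = _metadata_from_mapping(sidecar, context=str(path))
    return frames, meta


def write_stack(
    frames: np.ndarray,
    metadata: StackMetadata,
    path: str | Path,
    dialect: str = "tiff",
) -> Path:
    """Write a stack in one of the two open dialects (``"tiff"`` or ``"raw"``).

    The JSON sidecar is always written next to the stack so that
    :func:`read_stack` round-trips without extra arguments.
    """
    path = Path(path)
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError(f"frames must be (T, rows, cols), got shape {frames.shape}")
    sidecar = dict(metadata.to_dict(), shape=list(frames.shape))
    if dialect == "tiff":
        tifffile.imwrite(path, frames.astype(np.float32))
    elif dialect == "raw":
        frames.astype("<f4").tofile(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.with_name(path.name + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def _records_to_frame(records: Sequence[Mapping]) -> pd.DataFrame:
    if not records:
        return pd.DataFrame()
    schema = list(records[0].keys())
    for i, rec in enumerate(records):
        if list(rec.keys()) != schema:
            raise ValueError(
                f"record {i} schema {list(rec.keys())} differs from first record {schema}"
            )
    return pd.DataFrame.from_records(records, columns=schema)


def write_table(
    records: Sequence[Mapping],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> Path:
    """Write per-peak / per-response records to a CSV with a deterministic header.

    All records must share one schema (identical keys in identical order);
    heterogeneous schemas are rejected.  An empty record list produces a
    header-only CSV when ``columns`` is given, else an empty file with header
    of zero columns.
    """
    path = Path(path)
    frame = _records_to_frame(list(records))
    if columns is not None:
        if len(frame) == 0:
            frame = pd.DataFrame(columns=list(columns))
        else:
            frame = frame[list(columns)]
    # %.17g guarantees float64 values survive the text round trip exactly
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_table` (round-trip exact)."""
    return pd.read_csv(path, float_precision="round_trip")


def write_heatmap(
    values: np.ndarray,
    path: str | Path,
    scale: tuple[float, float] = (0.0, 15.0),
    cmap: str = "viridis",
) -> tuple[Path, Path]:
    """Render a percent-change response map as a PNG with a fixed colour scale.

    The default 0-15 % scale spans the dynamic range of cortical perfusion
    responses to whisker stimulation.  A lossless numeric export (CSV of the
    full-precision matrix) is written alongside the PNG; missing pixels (NaN)
    are rendered in the colormap's bad colour and stay NaN in the CSV.
    Non-finite values other than NaN are rejected with the offending index.

    Returns ``(png_path, csv_path)``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = np.asarray(values, dtype=float)
    bad = np.isinf(values)
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(f"non-finite value at pixel {idx}")
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    np.savetxt(csv_path, values, delimiter=",")

    cm = plt.get_cmap(cmap).copy()
    cm.set_bad("black")
    fig, ax = plt.subplots(figsize=(4, 4), dpi=150)
    im = ax.imshow(values, cmap=cm, vmin=scale[0], vmax=scale[1], interpolation="nearest")
    fig.colorbar(im, ax=ax, label="% change vs. baseline")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path, csv_path


def read_heatmap_matrix(csv_path: str | Path) -> np.ndarray:
    """Read the numeric export written next to a heat-map PNG."""
    return np.loadtxt(csv_path, delimiter=",", ndmin=2)
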