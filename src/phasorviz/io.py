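"""File formats: TIFF decay stacks with YAML sidecars, columnar phasor
tables, decay curves, colormap/calibration/run configs, and RGB exports.

TIFF tags are unreliable across acquisition software, so acquisition
metadata (repetition rate, bin count) travels in a YAML sidecar next to
the stack (``<stack>.yaml``).
"""

from __future__ import annotations

import dataclasses
import pathlib

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .core import CalibrationTransform, DecayStack, PhasorField
from .colormap import ColorMapConfig
from .preprocess import SmoothConfig, ThresholdConfig

__all__ = [
    "write_decay_stack",
    "read_decay_stack",
    "export_phasor_table",
    "import_phasor_table",
    "read_decay_curve",
    "write_decay_curve",
    "load_colormap_config",
    "save_colormap_config",
    "load_calibration",
    "save_calibration",
    "write_rgb_png",
    "write_rgb_tiff",
    "RunConfig",
]


def _sidecar_path(stack_path) -> pathlib.Path:
    return pathlib.Path(str(stack_path) + ".yaml")


def write_decay_stack(stack: DecayStack, path, sidecar_path=None) -> None:
    """Write counts as a multi-page TIFF (pages = time bins) plus sidecar."""
    counts = stack.counts
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("stack counts must be integer-valued for TIFF export")
    counts = np.round(counts).astype(np.int64)
    dtype = np.uint16 if counts.max() <= np.iinfo(np.uint16).max else np.uint32
    pages = np.transpose(counts.astype(dtype), (2, 0, 1))
    tifffile.imwrite(path, pages)
    meta = {
        "rep_rate_MHz": float(stack.rep_rate_MHz),
        "n_bins": int(stack.n_bins),
    }
    with open(sidecar_path or _sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_decay_stack(path, metadata: dict | None = None,
                     sidecar_path=None) -> DecayStack:
    """Read a multi-page TIFF stack; metadata from the sidecar unless given."""
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        raise ValueError(f"{path}: single-page TIFF; a decay stack needs "
                         "at least 2 time-bin pages")
    if pages.ndim != 3:
        raise ValueError(f"{path}: expected a (pages, rows, cols) TIFF")
    if pages.dtype.kind != "u":
        raise ValueError(
            f"{path}: dtype {pages.dtype} not allowed; decay stacks must "
            "hold unsigned-integer photon counts"
        )
    if metadata is None:
        sp = pathlib.Path(sidecar_path) if sidecar_path else _sidecar_path(path)
        if not sp.exists():
            raise ValueError(f"missing metadata sidecar {sp} (rep_rate_MHz "
                             "is required)")
        with open(sp) as fh:
            metadata = yaml.safe_load(fh)
    if "rep_rate_MHz" not in metadata:
        raise ValueError("metadata must provide rep_rate_MHz")
    if "n_bins" in metadata and int(metadata["n_bins"]) != pages.shape[0]:
        raise ValueError(
            f"sidecar says {metadata['n_bins']} bins but TIFF has "
            f"{pages.shape[0]} pages"
        )
    counts = np.transpose(pages, (1, 2, 0))
    return DecayStack.from_counts(counts,
                                  rep_rate_MHz=float(metadata["rep_rate_MHz"]))


_TABLE_HEADER = "row col G S intensity valid"


def export_phasor_table(field: PhasorField, path) -> None:
    """Columnar text dump of a phasor field, lossless at full precision."""
    rows, cols = field.shape
    with open(path, "w") as fh:
        fh.write(f"# shape {rows} {cols} harmonic {field.harmonic}\n")
        fh.write("# " + _TABLE_HEADER + "\n")
        for r in range(rows):
            for c in range(cols):
                v = int(field.valid[r, c])
                g = float(field.G[r, c])
                s = float(field.S[r, c])
                inten = float(field.intensity[r, c])
                fh.write(f"{r} {c} {g!r} {s!r} {inten!r} {v}\n")


def import_phasor_table(path) -> PhasorField:
    """Read a phasor table written by :func:`export_phasor_table`."""
    with open(path) as fh:
        first = fh.readline().split()
        if len(first) < 5 or first[1] != "shape":
            raise ValueError(f"{path}: malformed phasor table header")
        rows, cols = int(first[2]), int(first[3])
        harmonic = int(first[5]) if len(first) > 5 else 1
        second = fh.readline()
        if _TABLE_HEADER not in second:
            raise ValueError(f"{path}: malformed phasor table column header")
        body = fh.read()
    data = (np.loadtxt(body.splitlines(), ndmin=2) if body.strip()
            else np.empty((0, 6)))
    g = np.full((rows, cols), np.nan)
    s = np.full((rows, cols), np.nan)
    inten = np.zeros((rows, cols))
    valid = np.zeros((rows, cols), dtype=bool)
    if data.size:
        r = data[:, 0].astype(int)
        c = data[:, 1].astype(int)
        g[r, c] = data[:, 2]
        s[r, c] = data[:, 3]
        inten[r, c] = data[:, 4]
        valid[r, c] = data[:, 5] > 0
    return PhasorField(g, s, inten, valid, harmonic=harmonic)


def read_decay_curve(path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column text decay curve: time_ns, counts."""
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (time_ns, counts)")
    return data[:, 0], data[:, 1]


def write_decay_curve(time_ns, counts, path) -> None:
    np.savetxt(path, np.column_stack([time_ns, counts]),
               header="time_ns counts")


def load_colormap_config(path) -> ColorMapConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return ColorMapConfig.from_dict(d)


def save_colormap_config(cfg: ColorMapConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh)


def load_calibration(path) -> CalibrationTransform:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    known = {"modulation_factor", "phase_shift_rad", "harmonic",
             "reference_lifetime_ns"}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown calibration keys: {sorted(unknown)}")
    return CalibrationTransform(**d)


def save_calibration(t: CalibrationTransform, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(t), fh)


def write_rgb_png(rgb: np.ndarray, path) -> None:
    """8-bit RGB PNG from a float [0, 1] image."""
    iio.imwrite(path, (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8))


def write_rgb_tiff(rgb: np.ndarray, path) -> None:
    """16-bit RGB TIFF from a float [0, 1] image."""
    tifffile.imwrite(path, (np.clip(rgb, 0, 1) * 65535).round().astype(np.uint16))


@dataclasses.dataclass
class RunConfig:
    """One structured config driving a batch of stacks with a frozen
    colormap (the same color coding applied to many files)."""

    inputs: list[str]
    colormap: ColorMapConfig
    rep_rate_MHz: float = 80.0
    harmonic: int = 1
    calibration: str | None = None  # path to a calibration YAML
    smoothing: SmoothConfig = dataclasses.field(default_factory=SmoothConfig)
    thresholds: ThresholdConfig = dataclasses.field(
        default_factory=ThresholdConfig)
    log_crossover_percent: float = 1.0
    out_dir: str = "."
    seed: int = 0

    _KEYS = {"inputs", "colormap", "rep_rate_MHz", "harmonic", "calibration",
             "smoothing", "thresholds", "log_crossover_percent", "out_dir",
             "seed"}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        base = pathlib.Path(path).parent
        with open(path) as fh:
            d = yaml.safe_load(fh)
        unknown = set(d) - cls._KEYS
        if unknown:
            raise ValueError(f"unknown run config keys: {sorted(unknown)}")
        if "inputs" not in d or "colormap" not in d:
            raise ValueError("run config requires 'inputs' and 'colormap'")
        inputs = [str(base / p) for p in d["inputs"]]
        for p in inputs:
            if not pathlib.Path(p).exists():
                raise ValueError(f"input stack not found: {p}")
        smoothing = SmoothConfig(**d.get("smoothing", {}))
        thr = d.get("thresholds", {})
        thresholds = ThresholdConfig(
            low_fraction=thr.get("low"), high_fraction=thr.get("high")
        )
        calib = d.get("calibration")
        if calib is not None:
            calib = str(base / calib)
            if not pathlib.Path(calib).exists():
                raise ValueError(f"calibration file not found: {calib}")
        return cls(
            inputs=inputs,
            colormap=ColorMapConfig.from_dict(d["colormap"]),
            rep_rate_MHz=float(d.get("rep_rate_MHz", 80.0)),
            harmonic=int(d.get("harmonic", 1)),
            calibration=calib,
            smoothing=smoothing,
            thresholds=thresholds,
            log_crossover_percent=float(d.get("log_crossover_percent", 1.0)),
            out_dir=str(base / d.get("out_dir", ".")),
            seed=int(d.get("seed", 0)),
        )
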