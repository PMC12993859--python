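"""Vegetation-index extraction from masked 10-channel multispectral cubes.

The imager records nine narrowband channels (blue 475 nm through NIR-940)
plus a broad-spectrum white channel.  A vegetation index (VI) is an
arithmetic expression over named channels — most usefully a normalized
difference such as NDVI = (nir850 - red) / (nir850 + red) — evaluated per
pixel over a plant's mask (its foliar surface) and summarized as mean,
median and standard deviation.  The index registry is data-driven: the
default approximates the study's ~106-feature set with all 36 normalized
differences over the narrowband channels (the five indices identified in
the field — NDVI, GNDVI, NDRE, NDWI, GRVI — keep their canonical names;
NIR-940 stands in for shortwave infrared in NDWI).
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CHANNEL_NAMES",
    "CHANNEL_WAVELENGTHS_NM",
    "ChannelMap",
    "MSICube",
    "IndexDefinition",
    "default_registry",
    "load_registry",
    "save_registry",
    "compute_index",
    "summarize",
    "build_feature_table",
    "write_cube_tiff",
    "read_cube_tiff",
    "write_mask_png",
    "read_mask_png",
]

# Acquisition channel order; peak wavelengths in nm (white is broad-spectrum).
_CHANNEL_TABLE = (
    ("blue", 475.0), ("cyan", 497.0), ("green", 526.0), ("amber", 603.0),
    ("red", 640.0), ("deep_red", 665.0), ("far_red", 740.0),
    ("nir850", 855.0), ("nir940", 949.0), ("white", None),
)
CHANNEL_NAMES = tuple(name for name, _ in _CHANNEL_TABLE)
CHANNEL_WAVELENGTHS_NM = {name: wl for name, wl in _CHANNEL_TABLE}


@dataclass(frozen=True)
class ChannelMap:
    """Ordered channel names with peak wavelengths (nm; None = broad)."""

    names: tuple[str, ...] = CHANNEL_NAMES
    wavelengths_nm: tuple[float | None, ...] = tuple(wl for _, wl in _CHANNEL_TABLE)

    def __post_init__(self):
        if len(self.names) != 10 or len(set(self.names)) != 10:
            raise ValueError("channel map must have 10 unique channels")
        narrow = [w for w in self.wavelengths_nm if w is not None]
        if any(b <= a for a, b in zip(narrow, narrow[1:])):
            raise ValueError("narrowband wavelengths must be strictly increasing")

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None


DEFAULT_CHANNEL_MAP = ChannelMap()


@dataclass
class MSICube:
    """One overhead multispectral capture: (10, H, W) array + metadata."""

    data: np.ndarray
    channel_map: ChannelMap = field(default_factory=lambda: DEFAULT_CHANNEL_MAP)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.channel_map.names):
            raise ValueError(
                f"cube must be (n_channels, H, W) with {len(self.channel_map.names)} channels"
            )

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_map.index(name)]


@dataclass(frozen=True)
class IndexDefinition:
    """A named VI formula over channel names, e.g. ``(nir850-red)/(nir850+red)``.

    ``role`` is an informational growth-stage tag (early/mid/late).
    """

    name: str
    formula: str
    role: str = ""

    def channels_used(self) -> set[str]:
        tree = ast.parse(self.formula, mode="eval")
        return {n.id for n in ast.walk(tree) if isinstance(n, ast.Name)}


_NAMED_INDICES = {
    "NDVI": ("(nir850 - red) / (nir850 + red)", "mid"),
    "GNDVI": ("(nir850 - green) / (nir850 + green)", "late"),
    "NDRE": ("(nir850 - far_red) / (nir850 + far_red)", "mid"),
    "NDWI": ("(nir850 - nir940) / (nir850 + nir940)", "early"),
    "GRVI": ("(green - red) / (green + red)", "early"),
}
_NAMED_PAIRS = {
    "NDVI": frozenset({"nir850", "red"}),
    "GNDVI": frozenset({"nir850", "green"}),
    "NDRE": frozenset({"nir850", "far_red"}),
    "NDWI": frozenset({"nir850", "nir940"}),
    "GRVI": frozenset({"green", "red"}),
}


def default_registry(named_only: bool = False) -> list[IndexDefinition]:
    """The default VI registry.

    ``named_only`` gives just the five canonical indices; the full default
    is every normalized difference over the nine narrowband channels
    (36 indices, hence 108 features after the x3 statistics).
    """
    defs = [IndexDefinition(n, f, role) for n, (f, role) in _NAMED_INDICES.items()]
    if named_only:
        return defs
    pair_to_name = {pair: name for name, pair in _NAMED_PAIRS.items()}
    narrow = [n for n in CHANNEL_NAMES if n != "white"]
    for i, a in enumerate(narrow):
        for b in narrow[i + 1:]:
            if frozenset({a, b}) in pair_to_name:
                continue
            defs.append(IndexDefinition(f"nd_{b}_{a}", f"({b} - {a}) / ({b} + {a})"))
    return defs


def load_registry(path: str | Path) -> list[IndexDefinition]:
    """Read a YAML registry: ``{name: formula}`` or ``{name: {formula, role}}``."""
    raw = yaml.safe_load(Path(path).read_text())
    defs = []
    for name, val in raw.items():
        if isinstance(val, str):
            defs.append(IndexDefinition(name, val))
        else:
            defs.append(IndexDefinition(name, val["formula"], val.get("role", "")))
    return defs


def save_registry(defs: list[IndexDefinition], path: str | Path) -> None:
    payload = {
        d.name: ({"formula": d.formula, "role": d.role} if d.role else d.formula)
        for d in defs
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


class _FormulaEvaluator(ast.NodeVisitor):
    """Evaluate a VI formula over channel arrays with safe division.

    Division returns 0 wherever |denominator| < eps, so summaries never see
    NaN or inf from zero-reflectance pixels.
    """

    def __init__(self, channels: dict[str, np.ndarray], eps: float):
        self.channels = channels
        self.eps = eps

    def visit(self, node):
        if isinstance(node, ast.Expression):
            return self.visit(node.body)
        if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
            return float(node.value)
        if isinstance(node, ast.Name):
            if node.id not in self.channels:
                raise KeyError(f"unknown channel {node.id!r} in formula")
            return self.channels[node.id]
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
            return -self.visit(node.operand)
        if isinstance(node, ast.BinOp):
            left, right = self.visit(node.left), self.visit(node.right)
            if isinstance(node.op, ast.Add):
                return left + right
            if isinstance(node.op, ast.Sub):
                return left - right
            if isinstance(node.op, ast.Mult):
                return left * right
            if isinstance(node.op, ast.Div):
                num = np.asarray(left, dtype=np.float64)
                den = np.asarray(right, dtype=np.float64)
                num, den = np.broadcast_arrays(num, den)
                out = np.zeros_like(num)
                np.divide(num, den, out=out, where=np.abs(den) >= self.eps)
                return out if out.ndim else float(out)
            raise ValueError(f"unsupported operator {type(node.op).__name__}")
        raise ValueError(f"unsupported syntax {type(node).__name__} in formula")


def compute_index(
    cube: MSICube,
    index: IndexDefinition,
    mask: np.ndarray | None = None,
    eps: float = 1e-9,
) -> np.ndarray:
    """Evaluate one VI per pixel over the mask (or the whole frame).

    Returns a 1-D array of the masked pixels' index values (row-major mask
    order), or the full (H, W) image when ``mask`` is None.  All returned
    values are finite (safe division maps near-zero denominators to 0).
    """
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("mask is empty")
        channels = {name: cube.channel(name)[mask] for name in cube.channel_map.names}
    else:
        channels = {name: cube.channel(name) for name in cube.channel_map.names}
    tree = ast.parse(index.formula, mode="eval")
    return _FormulaEvaluator(channels, eps).visit(tree)


def summarize(values: np.ndarray) -> tuple[float, float, float]:
    """(mean, median, population SD) of an index image over one foliar surface."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("no pixels to summarize")
    return float(values.mean()), float(np.median(values)), float(values.std(ddof=0))


_STATS = ("mean", "median", "std")


def build_feature_table(
    captures,
    registry: list[IndexDefinition] | None = None,
    mode: str = "single-image",
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Aggregate per-capture VI summaries into a per-(plant, DAT) feature table.

    ``mode='single-image'`` keeps one designated capture per night — index 1
    when eight captures exist (the 11 pm frame of an hourly series starting
    at 10 pm), otherwise index 0.  ``mode='daily-average'`` averages the
    per-capture summaries over all of that night's captures.  Columns are
    ``{index}_{mean|median|std}`` plus plant/tank/treatment/DAT metadata.
    """
    if mode not in ("single-image", "daily-average"):
        raise ValueError(f"unknown mode {mode!r}")
    registry = registry if registry is not None else default_registry()

    rows = []
    for cap in captures:
        for _, meta in cap.plant_meta.iterrows():
            pid = str(meta["plant_id"])
            mask = cap.masks[pid]
            row = {
                "plant_id": pid, "tank_id": meta["tank_id"],
                "treatment": meta["treatment"], "DAT": cap.dat,
                "capture_index": cap.capture_index,
            }
            for idx in registry:
                vals = compute_index(cap.cube, idx, mask, eps=eps)
                for stat, v in zip(_STATS, summarize(vals)):
                    row[f"{idx.name}_{stat}"] = v
            rows.append(row)
    per_capture = pd.DataFrame(rows)
    if per_capture.empty:
        raise ValueError("no captures supplied")

    feature_cols = [c for c in per_capture.columns
                    if c.endswith(("_mean", "_median", "_std"))]
    meta_cols = ["plant_id", "tank_id", "treatment", "DAT"]
    if mode == "single-image":
        designated = per_capture.groupby(["plant_id", "DAT"])["capture_index"].transform(
            lambda s: 1 if s.max() >= 7 else 0
        )
        table = per_capture[per_capture["capture_index"] == designated]
        table = table[meta_cols + feature_cols].reset_index(drop=True)
    else:
        table = (
            per_capture.groupby(meta_cols, as_index=False, sort=True)[feature_cols].mean()
        )
    source = "single-11pm-image" if mode == "single-image" else "daily-average"
    table = table.sort_values(["plant_id", "DAT"]).reset_index(drop=True)
    table.attrs["source"] = source
    return table


# -- standard-format I/O ----------------------------------------------------


def write_cube_tiff(cube: MSICube, path: str | Path) -> None:
    """Write a cube as a 10-page TIFF (page order = acquisition channel order)."""
    import tifffile

    tifffile.imwrite(str(path), cube.data.astype(np.float32), metadata=None)


def read_cube_tiff(path: str | Path, channel_map: ChannelMap | None = None) -> MSICube:
    import tifffile

    data = tifffile.imread(str(path))
    return MSICube(data=np.asarray(data, dtype=np.float64),
                   channel_map=channel_map or DEFAULT_CHANNEL_MAP)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit 0/255 PNG."""
    import imageio.v3 as iio

    iio.imwrite(str(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_mask_png(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(str(path))) > 127
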