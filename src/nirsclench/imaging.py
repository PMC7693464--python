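"""Hb-to-grayscale image encoding.

Each 10 Hz sample becomes one 5x10-pixel grayscale frame: every channel
owns a 1x2 pixel block on the grid, coded into 256 gradations (0 = black =
scope minimum, 255 = white = scope maximum). Three modalities:

* ``oxy``   - both block pixels carry the oxy-Hb code;
* ``deoxy`` - both block pixels carry the deoxy-Hb code;
* ``od``    - mixed frame: left pixel oxy-Hb, right pixel deoxy-Hb.

Frames touching a masked (missing) channel value are invalid and excluded.
The default normalisation scope is per subject and per Hb species over all
unmasked rest+clench deltas, so rest and clench frames of one subject share
a gray scale. For the CNN the 5x10 frame is squash-resized (aspect ratio
ignored) to a square, nearest-neighbour by default so channel blocks stay
piecewise constant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import EpochDeltas, SPECIES, WINDOWS
from .synth import N_CHANNELS

MODALITIES = ("oxy", "deoxy", "od")
GRID_ROWS, GRID_COLS = 5, 10

REGION_CHANNELS = {
    "SFG": (2, 3, 7, 12, 16, 21),
    "MFG": (1, 4, 5, 6, 8, 9, 10, 11, 13, 15, 17, 20, 22),
    "IFG": (14, 18, 19),
}


class LayoutError(ValueError):
    pass


@dataclass(frozen=True)
class GrayscaleScheme:
    """256-gradation coding with configurable normalisation scope."""

    n_levels: int = 256
    scope: str = "per_subject"  # per_subject | per_frame | global

    @property
    def max_code(self) -> int:
        return self.n_levels - 1

    def __post_init__(self) -> None:
        if self.scope not in ("per_subject", "per_frame", "global"):
            raise ValueError(f"unknown normalisation scope {self.scope!r}")


@dataclass(frozen=True)
class ChannelLayout:
    """Pixel-block coordinates of the 22 channels on the 5x10 grid.

    ``blocks[ch]`` is (row, col_start); each block spans columns
    ``col_start`` and ``col_start + 1``. Region labels follow the probe's
    anatomical assignment (SFG/MFG/IFG).
    """

    blocks: dict[int, tuple[int, int]]
    regions: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sorted(self.blocks) != list(range(1, N_CHANNELS + 1)):
            raise LayoutError("layout must place channels 1..22")
        seen: set[tuple[int, int]] = set()
        for ch, (row, col) in self.blocks.items():
            if not (0 <= row < GRID_ROWS and 0 <= col and col + 1 < GRID_COLS):
                raise LayoutError(f"channel {ch} block outside the 5x10 grid")
            cells = {(row, col), (row, col + 1)}
            if cells & seen:
                raise LayoutError(f"channel {ch} block overlaps another block")
            seen |= cells
        if not self.regions:
            object.__setattr__(self, "regions", {
                ch: region
                for region, chans in REGION_CHANNELS.items()
                for ch in chans
            })

    @classmethod
    def default(cls) -> "ChannelLayout":
        # rows of 4/5/4/5/4 channels matching the 3x5 optode grid;
        # 4-channel rows are left-aligned at column 1 (blank column each side)
        rows = [(1, 4), (5, 9), (10, 13), (14, 18), (19, 22)]
        blocks: dict[int, tuple[int, int]] = {}
        for row, (first, last) in enumerate(rows):
            n = last - first + 1
            col0 = 1 if n == 4 else 0
            for k, ch in enumerate(range(first, last + 1)):
                blocks[ch] = (row, col0 + 2 * k)
        return cls(blocks=blocks)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "channels": {str(ch): {"row": r, "col_start": c}
                         for ch, (r, c) in sorted(self.blocks.items())},
            "regions": {str(ch): reg for ch, reg in sorted(self.regions.items())},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ChannelLayout":
        payload = json.loads(Path(path).read_text())
        blocks = {int(ch): (v["row"], v["col_start"])
                  for ch, v in payload["channels"].items()}
        regions = {int(ch): reg for ch, reg in payload.get("regions", {}).items()}
        return cls(blocks=blocks, regions=regions)


@dataclass
class HbImage:
    """One grayscale frame with its provenance."""

    modality: str
    pixels: np.ndarray  # (5, 10) uint8-valued ints
    label: str  # rest | clench
    subject_id: str
    sample_index: int
    valid: bool = True
    invalid_reason: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (GRID_ROWS, GRID_COLS):
            raise ValueError("frame must be 5x10")
        if self.valid and ((self.pixels < 0).any() or (self.pixels > 255).any()):
            raise ValueError("pixel codes must lie in [0, 255]")


def scale_to_gray(values: np.ndarray, vmin: float, vmax: float,
                  max_code: int = 255) -> np.ndarray:
    """Map values linearly onto integer codes 0..max_code.

    Round-half-up (so the exact midpoint maps to 128), clipped as a safety
    net; a degenerate scope (vmax == vmin) maps everything to the mid-gray
    code 127.
    """
    values = np.asarray(values, dtype=float)
    if not (np.isfinite(vmin) and np.isfinite(vmax)) or vmax < vmin:
        raise ValueError(f"invalid bounds [{vmin}, {vmax}]")
    if not np.isfinite(values[~np.isnan(values)]).all():
        raise ValueError("non-finite values must be masked upstream")
    if vmax == vmin:
        return np.full(values.shape, (max_code + 1) // 2 - 1, dtype=int)
    scaled = max_code * (values - vmin) / (vmax - vmin)
    codes = np.floor(scaled + 0.5)  # round half up
    return np.clip(codes, 0, max_code).astype(int)


def render_frame(oxy_codes: np.ndarray | None, deoxy_codes: np.ndarray | None,
                 oxy_missing: np.ndarray | None, deoxy_missing: np.ndarray | None,
                 layout: ChannelLayout, modality: str, *,
                 label: str = "", subject_id: str = "",
                 sample_index: int = 0) -> HbImage:
    """Place per-channel codes into their 1x2 blocks for one timepoint.

    Background (unassigned) cells are 0. A frame needing a channel whose
    value is missing at this timepoint is returned with ``valid=False``.
    """
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    need_oxy = modality in ("oxy", "od")
    need_deoxy = modality in ("deoxy", "od")
    for need, codes, name in ((need_oxy, oxy_codes, "oxy"),
                              (need_deoxy, deoxy_codes, "deoxy")):
        if need:
            if codes is None or np.asarray(codes).shape != (N_CHANNELS,):
                raise LayoutError(f"{name} codes must cover {N_CHANNELS} channels")

    pixels = np.zeros((GRID_ROWS, GRID_COLS), dtype=int)
    missing: list[int] = []
    for ch, (row, col) in layout.blocks.items():
        i = ch - 1
        if need_oxy and oxy_missing is not None and oxy_missing[i]:
            missing.append(ch)
            continue
        if need_deoxy and deoxy_missing is not None and deoxy_missing[i]:
            missing.append(ch)
            continue
        if modality == "oxy":
            pixels[row, col:col + 2] = oxy_codes[i]
        elif modality == "deoxy":
            pixels[row, col:col + 2] = deoxy_codes[i]
        else:  # od: oxy left, deoxy right
            pixels[row, col] = oxy_codes[i]
            pixels[row, col + 1] = deoxy_codes[i]

    img = HbImage(modality=modality, pixels=pixels, label=label,
                  subject_id=subject_id, sample_index=sample_index)
    if missing:
        img.valid = False
        img.invalid_reason = "missing channel(s): " + ",".join(map(str, missing))
    return img


def decode_frame(img: HbImage, layout: ChannelLayout,
                 species: str = "oxy") -> np.ndarray:
    """Read per-channel codes back out of a frame (layout round-trip)."""
    codes = np.empty(N_CHANNELS, dtype=int)
    for ch, (row, col) in layout.blocks.items():
        if img.modality == "od":
            codes[ch - 1] = img.pixels[row, col] if species == "oxy" else img.pixels[row, col + 1]
        else:
            codes[ch - 1] = img.pixels[row, col]
    return codes


def _scope_bounds(epoch: EpochDeltas, species: str) -> tuple[float, float]:
    vals = [epoch.deltas[species][w][~epoch.mask[species][w]] for w in WINDOWS]
    pool = np.concatenate([v.ravel() for v in vals])
    if pool.size == 0:
        return 0.0, 0.0
    return float(pool.min()), float(pool.max())


def build_image_set(epoch: EpochDeltas, layout: ChannelLayout,
                    scheme: GrayscaleScheme = GrayscaleScheme(),
                    modalities: tuple[str, ...] = MODALITIES,
                    global_bounds: dict[str, tuple[float, float]] | None = None,
                    keep_invalid: bool = False,
                    sample_stride: int = 1) -> dict[str, list[HbImage]]:
    """Render one candidate frame per sample per modality; drop invalid ones.

    OD validity is the intersection of oxy and deoxy validity at that
    sample. ``sample_stride`` keeps every k-th frame (1 = all, the native
    10 Hz cadence).
    """
    bounds: dict[str, tuple[float, float]] = {}
    for sp in SPECIES:
        if scheme.scope == "global" and global_bounds is not None:
            bounds[sp] = global_bounds[sp]
        else:
            bounds[sp] = _scope_bounds(epoch, sp)

    out: dict[str, list[HbImage]] = {m: [] for m in modalities}
    for window in WINDOWS:
        n = epoch.deltas["oxy"][window].shape[0]
        for t in range(0, n, sample_stride):
            codes: dict[str, np.ndarray] = {}
            miss: dict[str, np.ndarray] = {}
            for sp in SPECIES:
                vals = epoch.deltas[sp][window][t]
                miss[sp] = epoch.mask[sp][window][t]
                if scheme.scope == "per_frame":
                    ok = vals[~miss[sp]]
                    vmin, vmax = (float(ok.min()), float(ok.max())) if ok.size else (0.0, 0.0)
                else:
                    vmin, vmax = bounds[sp]
                safe = np.where(miss[sp], vmin, vals)
                codes[sp] = scale_to_gray(safe, vmin, vmax, scheme.max_code)
            for m in modalities:
                img = render_frame(codes["oxy"], codes["deoxy"],
                                   miss["oxy"], miss["deoxy"], layout, m,
                                   label=window, subject_id=epoch.subject_id,
                                   sample_index=t)
                if img.valid or keep_invalid:
                    out[m].append(img)
    return out


def resize_squash(img: HbImage | np.ndarray, side: int = 256,
                  mode: str = "nearest") -> np.ndarray:
    """Squash-resize the 5x10 frame to ``side`` x ``side`` pixels.

    Nearest-neighbour (default) maps output pixel (i, j) to input cell
    (floor(i*5/side), floor(j*10/side)), so every output value exists in
    the input and blocks stay rectangular. ``mode='bilinear'`` delegates to
    Pillow for a smoothed alternative.
    """
    pixels = img.pixels if isinstance(img, HbImage) else np.asarray(img)
    rows, cols = pixels.shape
    if mode == "nearest":
        ri = (np.arange(side) * rows) // side
        ci = (np.arange(side) * cols) // side
        return pixels[np.ix_(ri, ci)]
    if mode == "bilinear":
        from PIL import Image

        im = Image.fromarray(pixels.astype(np.uint8), mode="L")
        return np.asarray(im.resize((side, side), Image.BILINEAR), dtype=int)
    raise ValueError(f"unknown resize mode {mode!r}")


def export_png(img: HbImage, path: str | Path, side: int | None = None) -> None:
    """Write a frame as an 8-bit grayscale PNG (optionally squash-resized)."""
    from PIL import Image

    pixels = img.pixels if side is None else resize_squash(img, side)
    Image.fromarray(pixels.astype(np.uint8), mode="L").save(Path(path))
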