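"""Topographic-map image generation.

Preprocessed recordings are cut into non-overlapping 0.5 s segments; each
segment is reduced to one scalar per channel (window mean by default),
interpolated over the unit head disk, and rendered as an RGB image with the
jet colormap.  Colour is min-max scaled *per image*, so every map shows only
the relative spatial pattern of that half second.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps
from PIL import Image
from scipy.interpolate import RBFInterpolator

from .montage import Montage, default_montage
from .recording import Recording

DEFAULT_WINDOW_S = 0.5
DEFAULT_GRID_N = 360
#: Background RGB for pixels outside the head disk.
BACKGROUND = (255, 255, 255)


@dataclass
class Segment:
    """One analysis window of a recording."""

    data: np.ndarray  # channels x window samples
    start_s: float
    index: int
    pair_id: int
    role: str
    system: str
    category: str
    montage: Montage = field(default_factory=default_montage, repr=False)


def segment(rec: Recording, window_s: float = DEFAULT_WINDOW_S) -> list[Segment]:
    """Cut a recording into consecutive non-overlapping windows.

    Yields ``floor(duration / window)`` segments; a trailing remainder
    shorter than the window is dropped.
    """
    n_win = window_s * rec.rate
    if abs(n_win - round(n_win)) > 1e-9:
        raise ValueError(
            f"window of {window_s} s is not an integer number of samples "
            f"at {rec.rate} Hz"
        )
    n_win = int(round(n_win))
    if n_win > rec.n_samples:
        raise ValueError("window is longer than the recording")
    n_seg = rec.n_samples // n_win
    return [
        Segment(rec.data[:, k * n_win:(k + 1) * n_win], k * window_s, k,
                rec.pair_id, rec.role, rec.system, rec.category, rec.montage)
        for k in range(n_seg)
    ]


def channel_summary(seg: Segment, method: str = "mean") -> np.ndarray:
    """Reduce a segment to one scalar per channel, in montage order."""
    if method == "mean":
        return seg.data.mean(axis=1)
    if method == "rms":
        return np.sqrt((seg.data ** 2).mean(axis=1))
    raise ValueError(f"unknown summary method {method!r}")


def interpolate_scalp_field(values: np.ndarray, montage: Montage | None = None,
                            grid_n: int = DEFAULT_GRID_N,
                            kernel: str = "thin_plate_spline") -> np.ma.MaskedArray:
    """Interpolate 16 electrode values onto a grid over the head disk.

    Radial-basis interpolation (thin-plate kernel by default) through the 2D
    electrode positions: exact at every electrode, continuous inside the
    disk, and extrapolating smoothly from the electrode hull to the disk
    border.  Pixels outside the unit disk are masked.
    """
    montage = montage or default_montage()
    values = np.asarray(values, dtype=float)
    if values.shape != (len(montage),):
        raise ValueError(f"need {len(montage)} values, got {values.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError("electrode values must be finite")
    pts = montage.coords
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() < 1e-9:
        i, j = np.unravel_index(int(np.argmin(d)), d.shape)
        raise ValueError(
            f"coincident electrode positions: {montage.names[i]} and {montage.names[j]}"
        )
    interp = RBFInterpolator(pts, values, kernel=kernel)

    ax = np.linspace(-1.0, 1.0, grid_n)
    gx, gy = np.meshgrid(ax, ax)
    # image row 0 is the top of the head (nose up): flip the y axis
    gy = gy[::-1]
    inside = gx**2 + gy**2 <= 1.0
    field = np.full((grid_n, grid_n), np.nan)
    pts_in = np.column_stack([gx[inside], gy[inside]])
    field[inside] = interp(pts_in)
    return np.ma.masked_invalid(field)


@dataclass
class TopomapImage:
    """A rendered scalp map plus the labels and scaling it was built from."""

    pixels: np.ndarray  # grid_n x grid_n x 3, uint8
    vmin: float
    vmax: float
    pair_id: int
    role: str
    system: str
    category: str
    segment_index: int

    @property
    def filename(self) -> str:
        return f"{self.pair_id}_{self.system}_{self.role}_{self.segment_index}.png"

    def save(self, path) -> None:
        Image.fromarray(self.pixels).save(path)


def render_field(field: np.ma.MaskedArray, cmap: str = "jet") -> tuple[np.ndarray, float, float]:
    """Map a masked scalar field to 8-bit RGB with per-image min-max scaling.

    The field minimum maps to the colormap's low end (dark blue for jet) and
    the maximum to its high end (dark red); a constant field maps to the
    colormap midpoint.  Masked pixels get the uniform background colour.
    Deterministic: the same field always yields byte-identical pixels.
    """
    vmin = float(field.min())
    vmax = float(field.max())
    # a range at numerical-noise level counts as constant (midpoint colour);
    # interpolating a flat map leaves ~1e-13 ripple that must not be
    # stretched to the full colour scale
    if vmax - vmin > 1e-9 * max(1.0, abs(vmax), abs(vmin)):
        norm = (field.filled(vmin) - vmin) / (vmax - vmin)
    else:
        norm = np.full(field.shape, 0.5)
    rgba = colormaps[cmap](norm, bytes=True)
    rgb = np.array(rgba[..., :3], dtype=np.uint8)
    rgb[np.ma.getmaskarray(field)] = BACKGROUND
    return rgb, vmin, vmax


def render_image(field: np.ma.MaskedArray, seg: Segment | None = None,
                 cmap: str = "jet") -> TopomapImage:
    """Render an interpolated field as a labelled topographic-map image."""
    rgb, vmin, vmax = render_field(field, cmap)
    if seg is None:
        return TopomapImage(rgb, vmin, vmax, -1, "", "", "", -1)
    return TopomapImage(rgb, vmin, vmax, seg.pair_id, seg.role, seg.system,
                        seg.category, seg.index)


def render_segment(seg: Segment, grid_n: int = DEFAULT_GRID_N,
                   method: str = "mean", kernel: str = "thin_plate_spline",
                   cmap: str = "jet") -> TopomapImage:
    """Segment -> channel summary -> interpolated field -> rendered image."""
    values = channel_summary(seg, method)
    field = interpolate_scalp_field(values, seg.montage, grid_n, kernel)
    return render_image(field, seg, cmap)


def render_recording(rec: Recording, window_s: float = DEFAULT_WINDOW_S,
                     grid_n: int = DEFAULT_GRID_N, method: str = "mean",
                     kernel: str = "thin_plate_spline") -> list[TopomapImage]:
    """All topographic maps of one recording (120 per 60 s at 0.5 s windows)."""
    return [render_segment(s, grid_n, method, kernel) for s in segment(rec, window_s)]
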