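"""Categorical palette generation and multi-feature color blending.

Palettes: maximally distinct discrete colors are found by seeded k-means
over a dense sample of a perceptual constraint box (lightness, chroma,
hue ranges in CIELAB/LCh), the strategy behind distinct-color generators
of the I-Want-Hue family. Seven preset families are registered: two
full-hue schemes (``default``, ``light``) and five hue-confined ones
(``red``, ``yellow``, ``green``, ``blue``, ``purple``). Centroids are
snapped to the nearest in-box gamut sample so every emitted color
provably satisfies its family's constraints.

Blending: up to three per-cell features are scaled to [0, 1] (quantile
clip then min-max) and mixed either additively in RGB (black = no
signal, brighter = more) or subtractive-style in RYB (white = no signal,
deeper = more). RYB mixing is trilinear interpolation over 8 tuned
corner colors; the defaults darken yellow toward gold and lighten blue
toward azure, because the pure primaries render poorly on screen. A
corner table is rejected at load unless increasing any RYB coordinate
never raises CIELAB lightness on a validation grid (the "deeper color
for more signal" contract).
"""
from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import DataError, UsageError

__all__ = [
    "FAMILIES",
    "PaletteConstraints",
    "BlendSpec",
    "generate_palette",
    "preset_palette",
    "palette_families",
    "blend_rgb",
    "blend_ryb",
    "scale_feature",
    "load_ryb_corners",
    "hex_color",
]

_CORNER_KEYS = [
    "white", "red", "yellow", "blue", "orange", "green", "purple", "black",
]
# RYB unit-cube coordinate of each corner
_CORNER_COORDS = {
    "white": (0, 0, 0), "red": (1, 0, 0), "yellow": (0, 1, 0), "blue": (0, 0, 1),
    "orange": (1, 1, 0), "green": (0, 1, 1), "purple": (1, 0, 1), "black": (1, 1, 1),
}


def _data_text(name: str) -> str:
    return resources.files("pathcell").joinpath("data", name).read_text()


def _rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    from skimage import color

    return color.rgb2lab(rgb.reshape(-1, 1, 3)).reshape(-1, 3)


def _lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    import warnings as _w

    from skimage import color

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        return color.lab2rgb(lab.reshape(-1, 1, 3)).reshape(-1, 3)


def hex_color(rgb) -> str:
    r, g, b = (int(round(float(c) * 255)) for c in rgb)
    return f"#{r:02X}{g:02X}{b:02X}"


def _hue_of(lab: np.ndarray) -> np.ndarray:
    return np.degrees(np.arctan2(lab[:, 2], lab[:, 1])) % 360


def _chroma_of(lab: np.ndarray) -> np.ndarray:
    return np.hypot(lab[:, 1], lab[:, 2])


@dataclass(frozen=True)
class PaletteConstraints:
    """Constraint box in LCh: hue (degrees, may wrap), lightness, chroma."""

    hue_range: tuple[float, float] = (0.0, 360.0)
    lightness_range: tuple[float, float] = (35.0, 70.0)
    chroma_range: tuple[float, float] = (25.0, 70.0)

    def hue_ok(self, hue: np.ndarray, tol: float = 0.0) -> np.ndarray:
        lo, hi = self.hue_range
        if (hi - lo) % 360 == 0 and hi != lo:
            return np.ones_like(hue, dtype=bool)  # full hue circle
        lo, hi = lo - tol, hi + tol
        if lo <= hi:
            return (hue >= lo) & (hue <= hi)
        return (hue >= lo % 360) | (hue <= hi % 360)  # wrapped interval

    def contains(self, lab: np.ndarray, tol: float = 1e-6) -> np.ndarray:
        L, C, h = lab[:, 0], _chroma_of(lab), _hue_of(lab)
        ok = (L >= self.lightness_range[0] - tol) & (L <= self.lightness_range[1] + tol)
        ok &= (C >= self.chroma_range[0] - tol) & (C <= self.chroma_range[1] + tol)
        return ok & self.hue_ok(h, tol=tol)


@functools.lru_cache(maxsize=1)
def _family_config() -> dict:
    cfg = yaml.safe_load(_data_text("palette_families.yaml"))
    fams = cfg["families"]
    if len(fams) != 7:
        raise DataError(f"expected 7 palette families, found {len(fams)}")
    return cfg


def palette_families() -> list[str]:
    """The registered preset family names (exactly 7)."""
    return list(_family_config()["families"])


FAMILIES = ("default", "light", "red", "yellow", "green", "blue", "purple")


def family_constraints(family: str) -> PaletteConstraints:
    fams = _family_config()["families"]
    if family not in fams:
        raise UsageError(
            f"unknown palette family {family!r}; valid families: {', '.join(fams)}"
        )
    f = fams[family]
    return PaletteConstraints(
        hue_range=tuple(f["hue_range"]),
        lightness_range=tuple(f["lightness_range"]),
        chroma_range=tuple(f["chroma_range"]),
    )


def _sample_box(constraints: PaletteConstraints, seed: int,
                n_samples: int = 4000) -> np.ndarray:
    """Seeded LAB sample of the in-gamut part of the constraint box."""
    rng = np.random.default_rng(seed)
    lo_h, hi_h = constraints.hue_range
    span = (hi_h - lo_h) % 360 or 360.0
    h = (lo_h + rng.uniform(0, span, n_samples)) % 360
    L = rng.uniform(*constraints.lightness_range, n_samples)
    C = rng.uniform(*constraints.chroma_range, n_samples)
    lab = np.column_stack([
        L, C * np.cos(np.radians(h)), C * np.sin(np.radians(h))
    ])
    rgb = _lab_to_rgb(lab)
    lab_back = _rgb_to_lab(rgb)
    in_gamut = np.linalg.norm(lab - lab_back, axis=1) < 1.0
    lab = lab[in_gamut]
    if len(lab) == 0:
        raise DataError("palette constraints leave no displayable colors")
    return lab


def generate_palette(n: int, constraints: PaletteConstraints | None = None,
                     seed: int = 0) -> list[str]:
    """n maximally distinct hex colors inside a perceptual constraint box.

    Seeded k-means in CIELAB over a dense in-gamut sample of the box;
    each centroid is snapped to its nearest sample so the constraints
    hold exactly. Output sorted by hue.
    """
    if n < 1:
        raise UsageError("n must be >= 1")
    constraints = constraints or PaletteConstraints()
    lab = _sample_box(constraints, seed)
    if n == 1:
        centers = lab.mean(axis=0, keepdims=True)
    else:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=min(n, len(lab)), random_state=seed, n_init=4)
        km.fit(lab)
        centers = km.cluster_centers_
    # snap to nearest in-box sample
    d = np.linalg.norm(lab[None, :, :] - centers[:, None, :], axis=2)
    snapped = lab[np.argmin(d, axis=1)]
    order = np.argsort(_hue_of(snapped), kind="stable")
    rgb = np.clip(_lab_to_rgb(snapped[order]), 0, 1)
    return [hex_color(c) for c in rgb]


@functools.lru_cache(maxsize=128)
def preset_palette(family: str, n: int) -> tuple[str, ...]:
    """Deterministic palette for one of the 7 preset families."""
    fams = _family_config()["families"]
    if family not in fams:
        raise UsageError(
            f"unknown palette family {family!r}; valid families: {', '.join(fams)}"
        )
    seed = int(fams[family]["seed"])
    return tuple(generate_palette(n, family_constraints(family), seed=seed))


# ---------------------------------------------------------------- blending

@dataclass(frozen=True)
class BlendSpec:
    """Multi-feature blending parameters."""

    mode: str = "ryb"
    q_hi: float = 0.99
    corners: tuple[tuple[float, float, float], ...] | None = None  # RYB corner RGBs

    def __post_init__(self) -> None:
        if self.mode not in ("rgb", "ryb"):
            raise UsageError(f"unknown blend mode {self.mode!r}")


@functools.lru_cache(maxsize=4)
def load_ryb_corners(path: str | None = None) -> dict[str, tuple[float, float, float]]:
    """Load and validate the 8 RYB corner colors.

    Validation: exactly the 8 expected corner names; RGB in [0, 1]; and
    monotone deepening — on a 6x6x6 grid, increasing any single RYB
    coordinate never increases CIELAB L*.
    """
    text = Path(path).read_text() if path else _data_text("ryb_corners.yaml")
    raw = yaml.safe_load(text)["corners"]
    if sorted(raw) != sorted(_CORNER_KEYS):
        raise DataError(f"RYB corner table must define exactly {_CORNER_KEYS}")
    corners = {k: tuple(float(v) for v in raw[k]) for k in _CORNER_KEYS}
    for k, rgb in corners.items():
        if len(rgb) != 3 or min(rgb) < 0 or max(rgb) > 1:
            raise DataError(f"corner {k!r} is not a valid RGB triplet: {rgb}")
    _validate_monotone(corners)
    return corners


def _corner_array(corners: dict[str, tuple[float, float, float]]) -> np.ndarray:
    arr = np.zeros((2, 2, 2, 3))
    for name, (i, j, k) in _CORNER_COORDS.items():
        arr[i, j, k] = corners[name]
    return arr


def _trilinear(coords: np.ndarray, table: np.ndarray) -> np.ndarray:
    x, y, z = coords[:, 0:1], coords[:, 1:2], coords[:, 2:3]
    out = np.zeros((len(coords), 3))
    for i in (0, 1):
        wi = x if i else 1 - x
        for j in (0, 1):
            wj = y if j else 1 - y
            for k in (0, 1):
                wk = z if k else 1 - z
                out += wi * wj * wk * table[i, j, k]
    return out


def _validate_monotone(corners: dict, grid: int = 6) -> None:
    table = _corner_array(corners)
    t = np.linspace(0, 1, grid)
    pts = np.array(np.meshgrid(t, t, t, indexing="ij")).reshape(3, -1).T
    rgb = np.clip(_trilinear(pts, table), 0, 1)
    L = _rgb_to_lab(rgb)[:, 0].reshape(grid, grid, grid)
    for axis in range(3):
        dL = np.diff(L, axis=axis)
        if dL.max() > 1e-6:
            raise DataError(
                "RYB corner table rejected: lightness increases along axis "
                f"{axis} (max +{dL.max():.3f} L*); deeper color must mean more signal"
            )


def scale_feature(values, q_hi: float = 0.99) -> np.ndarray:
    """Clip at the q_hi quantile then min-max scale to [0, 1].

    A constant vector maps to all zeros.
    """
    if not (0 < q_hi <= 1):
        raise UsageError(f"q_hi must be in (0, 1], got {q_hi}")
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise DataError("scale_feature needs at least one value")
    hi = np.quantile(values, q_hi)
    lo = values.min()
    clipped = np.minimum(values, hi)
    if hi == lo:
        return np.zeros_like(values)
    return (clipped - lo) / (hi - lo)


def _scaled_channels(features, q_hi: float, n_channels: int = 3) -> np.ndarray:
    if not 1 <= len(features) <= 3:
        raise UsageError("blending takes 1-3 feature vectors")
    arrays = [np.asarray(f, dtype=float) for f in features]
    lengths = {len(a) for a in arrays}
    if len(lengths) != 1:
        raise DataError(f"feature vectors differ in length: {sorted(lengths)}")
    n = lengths.pop()
    channels = np.zeros((n, n_channels))
    for i, a in enumerate(arrays):
        channels[:, i] = scale_feature(a, q_hi)
    return channels


def blend_rgb(features, spec: BlendSpec | None = None) -> np.ndarray:
    """Additive RGB blending: scaled features drive R, G, B directly.

    Zero signal is black; saturated signal on all channels is white.
    Returns per-cell RGB triplets in [0, 1].
    """
    spec = spec or BlendSpec(mode="rgb")
    return _scaled_channels(features, spec.q_hi)


def blend_ryb(features, spec: BlendSpec | None = None) -> np.ndarray:
    """Subtractive-style RYB blending via trilinear corner interpolation.

    Scaled features form an RYB coordinate in [0,1]^3; output is the
    trilinear mix of the 8 configured corner colors. Zero signal maps to
    the white corner exactly; each unit corner reproduces its color.
    """
    spec = spec or BlendSpec(mode="ryb")
    if spec.corners is not None:
        corners = dict(zip(_CORNER_KEYS, spec.corners))
        _validate_monotone(corners)
    else:
        corners = load_ryb_corners()
    coords = _scaled_channels(features, spec.q_hi)
    return np.clip(_trilinear(coords, _corner_array(corners)), 0, 1)
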