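"""Dense SIFT feature extraction on a regular overlapping grid lattice.

Each descriptor summarises local gradient structure inside one fixed-size
square grid: the grid is split into a ``subgrid_layout`` x ``subgrid_layout``
array of subgrids, an 8-bin orientation histogram of gradient magnitudes is
built per subgrid, and the histograms are concatenated (row-major) into a
128-dimensional vector which is then L2-normalized.  Unlike keypoint SIFT,
grids are placed densely at every ``grid_step`` pixels over the whole image
and no dominant-orientation alignment is performed, so descriptors are
translation-covariant but not rotation invariant.

Conventions fixed here and used everywhere downstream:

* coordinates are 0-based ``(row, col)`` integer pairs;
* gradients are central differences in the interior, one-sided at image
  borders; a zero-magnitude gradient reports orientation 0;
* orientation bin centers sit at 0, 45, ..., 315 degrees and every gradient
  is linearly split between its two nearest centers;
* the recorded feature location is the grid center
  ``origin + (grid_size - 1) // 2`` per axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSpec",
    "SiftFeatures",
    "InvalidInputError",
    "compute_gradients",
    "extract_descriptor",
    "extract_dense",
]


class InvalidInputError(ValueError):
    """Raised when an operation receives input violating its preconditions."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the dense SIFT lattice.

    Parameters
    ----------
    grid_size : int
        Side length in pixels of one descriptor grid (default 16).
    grid_step : int
        Spacing in pixels between neighboring grid origins (default 2).
    subgrid_layout : int
        Number of subgrids per side (fixed at 4 in practice).
    n_orientations : int
        Number of orientation histogram bins (fixed at 8 in practice).
    """

    grid_size: int = 16
    grid_step: int = 2
    subgrid_layout: int = 4
    n_orientations: int = 8

    def __post_init__(self) -> None:
        if self.grid_step < 1:
            raise InvalidInputError("grid_step must be >= 1")
        if self.grid_size % self.subgrid_layout != 0:
            raise InvalidInputError(
                "grid_size must be divisible by subgrid_layout "
                f"(got {self.grid_size} / {self.subgrid_layout})"
            )

    @property
    def subgrid_size(self) -> int:
        return self.grid_size // self.subgrid_layout

    @property
    def descriptor_length(self) -> int:
        return self.subgrid_layout**2 * self.n_orientations

    @property
    def center_offset(self) -> int:
        # center = origin + grid_size/2 - 0.5, floored to an integer pixel
        return (self.grid_size - 1) // 2


@dataclass
class SiftFeatures:
    """A batch of dense SIFT features.

    Attributes
    ----------
    descriptors : (n, 128) float array, L2-normalized rows (zero rows stay zero).
    locations : (n, 2) int array of (row, col) grid-center pixel positions.
    """

    descriptors: np.ndarray
    locations: np.ndarray

    def __len__(self) -> int:
        return self.descriptors.shape[0]

    def __getitem__(self, idx):
        return self.descriptors[idx], self.locations[idx]


def _as_image(image) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise InvalidInputError("empty image")
    if img.ndim != 2:
        raise InvalidInputError(f"expected a 2-D grayscale image, got ndim={img.ndim}")
    if not np.all(np.isfinite(img)):
        raise InvalidInputError("image contains non-finite intensities")
    return img


def compute_gradients(image) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel gradient magnitude and orientation.

    Central differences in the interior, one-sided differences at borders.
    Orientation is the angle of (d/dcol, d/drow) in degrees in [0, 360);
    pixels with zero magnitude report orientation 0 by convention.

    Returns
    -------
    magnitude, orientation : float arrays of the image's shape.
    """
    img = _as_image(image)
    if img.shape[0] > 1:
        gy = np.gradient(img, axis=0)
    else:
        gy = np.zeros_like(img)
    if img.shape[1] > 1:
        gx = np.gradient(img, axis=1)
    else:
        gx = np.zeros_like(img)
    magnitude = np.hypot(gx, gy)
    orientation = np.degrees(np.arctan2(gy, gx)) % 360.0
    orientation[magnitude == 0] = 0.0
    return magnitude, orientation


def _orientation_channels(image, spec: GridSpec) -> np.ndarray:
    """(H, W, n_orientations) stack: each gradient's magnitude linearly split
    between its two nearest bin centers (bin width 360/n_orientations deg)."""
    magnitude, orientation = compute_gradients(image)
    n_ori = spec.n_orientations
    bin_width = 360.0 / n_ori
    t = orientation / bin_width
    i0 = np.floor(t).astype(np.intp) % n_ori
    frac = t - np.floor(t)
    i1 = (i0 + 1) % n_ori
    h, w = magnitude.shape
    channels = np.zeros((h, w, n_ori), dtype=np.float64)
    rows, cols = np.indices((h, w))
    channels[rows, cols, i0] = magnitude * (1.0 - frac)
    channels[rows, cols, i1] += magnitude * frac
    return channels


def _normalize_rows(desc: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(desc, axis=-1, keepdims=True)
    safe = np.where(norms > 0, norms, 1.0)
    return desc / safe


def extract_descriptor(
    image, grid_origin, spec: GridSpec | None = None, *, normalize: bool = True
) -> SiftFeatures:
    """Compute the 128-dim descriptor for a single grid placed at ``grid_origin``.

    The grid must lie fully inside the image.  Returns a one-feature batch so
    the result composes with the rest of the pipeline.  ``normalize=False``
    returns raw histogram mass (its sum equals the total gradient magnitude
    over the grid's pixels).
    """
    spec = spec or GridSpec()
    img = _as_image(image)
    r0, c0 = int(grid_origin[0]), int(grid_origin[1])
    g = spec.grid_size
    if r0 < 0 or c0 < 0 or r0 + g > img.shape[0] or c0 + g > img.shape[1]:
        raise InvalidInputError(
            f"grid at origin ({r0}, {c0}) with size {g} extends past the "
            f"image bounds {img.shape}"
        )
    channels = _orientation_channels(img, spec)
    sub = spec.subgrid_size
    parts = []
    for i in range(spec.subgrid_layout):
        for j in range(spec.subgrid_layout):
            block = channels[r0 + i * sub : r0 + (i + 1) * sub,
                             c0 + j * sub : c0 + (j + 1) * sub]
            parts.append(block.sum(axis=(0, 1)))
    desc = np.concatenate(parts)[None, :]
    loc = np.array([[r0 + spec.center_offset, c0 + spec.center_offset]], dtype=np.intp)
    if normalize:
        desc = _normalize_rows(desc)
    return SiftFeatures(desc, loc)


def grid_origins(shape, spec: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Row and column origins of every fully-contained grid (step-spaced)."""
    h, w = shape
    rows = np.arange(0, h - spec.grid_size + 1, spec.grid_step, dtype=np.intp)
    cols = np.arange(0, w - spec.grid_size + 1, spec.grid_step, dtype=np.intp)
    return rows, cols


def extract_dense(
    image, spec: GridSpec | None = None, *, normalize: bool = True
) -> SiftFeatures:
    """Extract one descriptor per grid origin in row-major order.

    Grid origins run over {0, step, 2*step, ...} per axis, keeping only grids
    fully contained in the image.  An image smaller than one grid yields an
    empty batch with a warning rather than an error.

    Uses per-orientation integral images so the dense case costs O(H*W) per
    channel regardless of the number of grids.
    """
    spec = spec or GridSpec()
    img = _as_image(image)
    rows, cols = grid_origins(img.shape, spec)
    n_ori = spec.n_orientations
    if rows.size == 0 or cols.size == 0:
        warnings.warn(
            f"image of shape {img.shape} is smaller than one "
            f"{spec.grid_size}x{spec.grid_size} grid; no features extracted",
            stacklevel=2,
        )
        return SiftFeatures(
            np.empty((0, spec.descriptor_length)), np.empty((0, 2), dtype=np.intp)
        )

    channels = _orientation_channels(img, spec)
    # integral image with a zero first row/col: window sums by 4 lookups
    ii = np.zeros((img.shape[0] + 1, img.shape[1] + 1, n_ori), dtype=np.float64)
    np.cumsum(channels, axis=0, out=ii[1:, 1:])
    np.cumsum(ii[1:, 1:], axis=1, out=ii[1:, 1:])

    sub = spec.subgrid_size
    layout = spec.subgrid_layout
    n_r, n_c = rows.size, cols.size
    desc = np.empty((n_r, n_c, layout * layout, n_ori), dtype=np.float64)
    for i in range(layout):
        for j in range(layout):
            r = rows + i * sub
            c = cols + j * sub
            block = (
                ii[np.ix_(r + sub, c + sub)]
                - ii[np.ix_(r, c + sub)]
                - ii[np.ix_(r + sub, c)]
                + ii[np.ix_(r, c)]
            )
            desc[:, :, i * layout + j, :] = block
    desc = desc.reshape(n_r * n_c, spec.descriptor_length)
    # integral-image subtraction can leave tiny negative residues on flat areas
    np.clip(desc, 0.0, None, out=desc)

    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    locations = np.stack(
        [rr.ravel() + spec.center_offset, cc.ravel() + spec.center_offset], axis=1
    ).astype(np.intp)
    if normalize:
        desc = _normalize_rows(desc)
    return SiftFeatures(desc, locations)
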