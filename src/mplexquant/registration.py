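"""Cross-round image registration on nuclei channels.

Two-stage alignment: a global rigid transform estimated on down-sampled
images (normalized cross-correlation over a bounded angle search, then
subpixel translation by phase correlation at full resolution), followed by
local deformable registration on a coarse grid (default 500 px spacing)
estimated at full resolution by windowed cross-correlation per grid node.
The dense displacement field is the bilinear interpolation of the node
vectors; grid nodes whose correlation peak falls below a confidence floor
inherit their neighbours' interpolated displacement.

Conventions: an estimated transform maps the *moving* image onto the
*fixed* frame, i.e. ``aligned(x) = moving(A(x + d(x)))`` where ``A`` is the
rigid map about the image center and ``d`` the dense displacement field.
Coordinates are (row, col), 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage as ndi
from scipy.interpolate import griddata
from skimage.registration import phase_cross_correlation

from .cellquant import _bilinear_resize
from .errors import EstimationError, StageError, ValidationError
from .io import MultiplexImage

logger = logging.getLogger(__name__)

__all__ = [
    "RigidTransform",
    "DeformationGrid",
    "rescale_to_common_pixel_size",
    "estimate_rigid",
    "estimate_deformation",
    "apply_transform",
    "normalize_decomposition",
    "register_rounds",
    "save_transform",
    "load_transform",
]


@dataclass
class RigidTransform:
    """Rotation about the image center, translation, optional scale.

    Maps a point ``x`` (row, col) in the fixed frame to
    ``scale · R(theta) · (x − c) + c + t`` in the moving frame, where ``c``
    is the image center.
    """

    theta_rad: float = 0.0
    ty_px: float = 0.0  # row translation
    tx_px: float = 0.0  # col translation
    scale: float = 1.0

    def __post_init__(self):
        if not self.scale > 0:
            raise ValidationError("scale must be positive")

    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.theta_rad), np.sin(self.theta_rad)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply_to_points(self, pts: np.ndarray, center: np.ndarray) -> np.ndarray:
        """Apply to an (..., 2) array of (row, col) points."""
        t = np.array([self.ty_px, self.tx_px])
        return (pts - center) @ self.matrix().T + center + t

    def inverse(self) -> "RigidTransform":
        rinv = np.array(
            [[np.cos(self.theta_rad), np.sin(self.theta_rad)],
             [-np.sin(self.theta_rad), np.cos(self.theta_rad)]]
        ) / self.scale
        t = np.array([self.ty_px, self.tx_px])
        tinv = -rinv @ t
        return RigidTransform(
            theta_rad=-self.theta_rad,
            ty_px=float(tinv[0]),
            tx_px=float(tinv[1]),
            scale=1.0 / self.scale,
        )

    @property
    def is_identity(self) -> bool:
        return (
            abs(self.theta_rad) < 1e-12
            and abs(self.ty_px) < 1e-12
            and abs(self.tx_px) < 1e-12
            and abs(self.scale - 1) < 1e-12
        )


@dataclass
class DeformationGrid:
    """Coarse grid of (dy, dx) displacements defining a smooth warp.

    ``node_rows``/``node_cols`` are the node coordinates (pixels, covering
    the full image extent); ``displacements`` has shape
    (n_rows, n_cols, 2).  The dense field is the bilinear interpolation of
    the node vectors; an all-zero grid is the identity warp.
    """

    step_px: int
    node_rows: np.ndarray
    node_cols: np.ndarray
    displacements: np.ndarray

    def __post_init__(self):
        self.node_rows = np.asarray(self.node_rows, dtype=float)
        self.node_cols = np.asarray(self.node_cols, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.step_px <= 0:
            raise ValidationError("step_px must be positive")
        expected = (len(self.node_rows), len(self.node_cols), 2)
        if self.displacements.shape != expected:
            raise ValidationError(
                f"displacements shape {self.displacements.shape} != {expected}"
            )

    @classmethod
    def zero(cls, shape: tuple[int, int], step_px: int) -> "DeformationGrid":
        rows = _node_coords(shape[0], step_px)
        cols = _node_coords(shape[1], step_px)
        return cls(step_px, rows, cols, np.zeros((len(rows), len(cols), 2)))

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Displacement at arbitrary (..., 2) points, bilinear, clamped."""
        pts = np.asarray(points, dtype=float)
        rows, cols = self.node_rows, self.node_cols
        r = np.clip(pts[..., 0], rows[0], rows[-1])
        c = np.clip(pts[..., 1], cols[0], cols[-1])
        i = np.clip(np.searchsorted(rows, r, side="right") - 1, 0, len(rows) - 2)
        j = np.clip(np.searchsorted(cols, c, side="right") - 1, 0, len(cols) - 2)
        tr = ((r - rows[i]) / (rows[i + 1] - rows[i]))[..., None]
        tc = ((c - cols[j]) / (cols[j + 1] - cols[j]))[..., None]
        d = self.displacements
        v00, v01 = d[i, j], d[i, j + 1]
        v10, v11 = d[i + 1, j], d[i + 1, j + 1]
        top = v00 + tc * (v01 - v00)
        bot = v10 + tc * (v11 - v10)
        return top + tr * (bot - top)

    @property
    def max_displacement(self) -> float:
        return float(np.abs(self.displacements).max()) if self.displacements.size else 0.0


def _node_coords(n: int, step: int) -> np.ndarray:
    coords = list(range(0, n, step))
    if coords[-1] != n - 1:
        coords.append(n - 1)
    return np.array(coords, dtype=float)


# ---------------------------------------------------------------------------
# Rescaling


def rescale_to_common_pixel_size(
    image: MultiplexImage, target_um: float
) -> MultiplexImage:
    """Resample all channels to ``target_um`` per pixel (bilinear)."""
    if not target_um > 0:
        raise ValidationError("target_um must be positive")
    if abs(target_um - image.pixel_size_um) < 1e-12:
        return image
    ratio = image.pixel_size_um / target_um
    h, w = image.shape
    out_shape = (max(1, round(h * ratio)), max(1, round(w * ratio)))
    channels = {
        name: _bilinear_resize(np.asarray(c, dtype=np.float64), out_shape)
        for name, c in image.channels.items()
    }
    return MultiplexImage(
        round_id=image.round_id,
        channels=channels,
        pixel_size_um=target_um,
        nuclei_channel=image.nuclei_channel,
    )


# ---------------------------------------------------------------------------
# Rigid estimation


def _block_mean(img: np.ndarray, f: int) -> np.ndarray:
    h, w = img.shape
    ph, pw = (-h) % f, (-w) % f
    padded = np.pad(img, ((0, ph), (0, pw)), mode="edge")
    return padded.reshape(padded.shape[0] // f, f, padded.shape[1] // f, f).mean(
        axis=(1, 3)
    )


def _rotate_about_center(img: np.ndarray, theta_rad: float) -> np.ndarray:
    """out(x) = img(R(x−c)+c), bilinear, zero fill."""
    h, w = img.shape
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.stack([rr, cc], axis=-1) - c
    rot = np.array(
        [[np.cos(theta_rad), -np.sin(theta_rad)],
         [np.sin(theta_rad), np.cos(theta_rad)]]
    )
    src = pts @ rot.T + c
    return ndi.map_coordinates(
        img, [src[..., 0], src[..., 1]], order=1, mode="constant", cval=0.0
    )


def _ncc_at_shift(fixed: np.ndarray, moving: np.ndarray, shift: np.ndarray) -> float:
    """Pearson correlation on the overlap after an integer shift of moving."""
    dy, dx = int(round(shift[0])), int(round(shift[1]))
    h, w = fixed.shape
    fy0, fy1 = max(0, dy), min(h, h + dy)
    fx0, fx1 = max(0, dx), min(w, w + dx)
    my0, my1 = max(0, -dy), min(h, h - dy)
    mx0, mx1 = max(0, -dx), min(w, w - dx)
    a = fixed[fy0:fy1, fx0:fx1].ravel()
    b = moving[my0:my1, mx0:mx1].ravel()
    if a.size < 16 or a.std() == 0 or b.std() == 0:
        return -1.0
    return float(np.corrcoef(a, b)[0, 1])


def _best_shift(fixed: np.ndarray, moving: np.ndarray, upsample: int = 1):
    shift, _, _ = phase_cross_correlation(
        fixed, moving, upsample_factor=upsample, normalization=None
    )
    return shift, _ncc_at_shift(fixed, moving, shift)


def estimate_rigid(
    fixed_nuclei: np.ndarray,
    moving_nuclei: np.ndarray,
    downsample: int = 10,
    angle_range_deg: float = 10.0,
    coarse_step_deg: float = 0.25,
    fine_downsample: int = 2,
    fine_step_deg: float = 0.1,
) -> RigidTransform:
    """Estimate the rigid transform mapping ``moving`` onto ``fixed``.

    A coarse search over rotations in ±``angle_range_deg`` (NCC score after
    phase-correlation translation) runs on ``downsample``-fold block-mean
    reduced images; the angle is refined locally at ``fine_downsample``;
    the translation is finally refined at full resolution with subpixel
    phase correlation.
    """
    fixed = np.asarray(fixed_nuclei, dtype=np.float64)
    moving = np.asarray(moving_nuclei, dtype=np.float64)
    if fixed.shape != moving.shape:
        raise ValidationError("fixed and moving rasters must share a shape")
    if np.ptp(fixed) == 0 or np.ptp(moving) == 0:
        raise EstimationError("constant image: rigid registration is undefined")

    f_ds = _block_mean(fixed, downsample)
    m_ds = _block_mean(moving, downsample)

    def search(fx, mv, angles):
        best = (-np.inf, 0.0)
        for ang in angles:
            rot = _rotate_about_center(mv, np.deg2rad(ang)) if ang else mv
            _, score = _best_shift(fx, rot)
            if score > best[0]:
                best = (score, ang)
        return best[1]

    coarse_angles = np.arange(
        -angle_range_deg, angle_range_deg + 1e-9, coarse_step_deg
    )
    theta_deg = search(f_ds, m_ds, coarse_angles)

    if fine_downsample < downsample:
        f_f = _block_mean(fixed, fine_downsample)
        m_f = _block_mean(moving, fine_downsample)
        fine_angles = np.arange(
            theta_deg - 2 * coarse_step_deg,
            theta_deg + 2 * coarse_step_deg + 1e-9,
            fine_step_deg,
        )
        theta_deg = search(f_f, m_f, fine_angles)

    theta = np.deg2rad(theta_deg)
    rotated = _rotate_about_center(moving, theta) if theta else moving
    shift, _, _ = phase_cross_correlation(
        fixed, rotated, upsample_factor=20, normalization=None
    )
    # rotated(x − s) ≈ fixed(x)  ⇒  moving(R(x−c)+c − R·s) = fixed(x)
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    t = -rot @ np.asarray(shift, dtype=float)
    return RigidTransform(theta_rad=float(theta), ty_px=float(t[0]), tx_px=float(t[1]))


# ---------------------------------------------------------------------------
# Deformable estimation


def estimate_deformation(
    fixed_nuclei: np.ndarray,
    moving_rigid_aligned: np.ndarray,
    step_px: int = 500,
    confidence_floor: float = 0.3,
    upsample: int = 10,
    n_iter: int = 6,
    tol_px: float = 0.15,
    window_px: int | None = None,
) -> DeformationGrid:
    """Per-node translation field on a coarse grid.

    A matching window (default half the grid step) centered on each grid
    node is matched by phase cross-correlation; the node keeps the estimate
    only if the NCC at the recovered shift reaches ``confidence_floor``,
    otherwise it inherits the interpolation of its confident neighbours
    (zero if none).

    Because a window average of a bilinear field mixes a node with its
    neighbours, the per-node measurement is biased when the field varies;
    the estimate is therefore refined iteratively: the moving image is
    warped with the current grid and the residual per-node shifts are
    accumulated until the largest update falls below ``tol_px`` (at most
    ``n_iter`` rounds).  The half-step window keeps the node's own
    displacement dominant in each measurement, which makes this iteration
    contract quickly.
    """
    fixed = np.asarray(fixed_nuclei, dtype=np.float64)
    moving = np.asarray(moving_rigid_aligned, dtype=np.float64)
    if fixed.shape != moving.shape:
        raise ValidationError("fixed and moving rasters must share a shape")
    if step_px < 64:
        raise ValidationError("step_px must be ≥ 64")
    h, w = fixed.shape
    if h < step_px or w < step_px:
        raise ValidationError(
            f"image {fixed.shape} smaller than one {step_px} px tile"
        )
    if window_px is None:
        window_px = step_px // 2
    rows = _node_coords(h, step_px)
    cols = _node_coords(w, step_px)
    grid = DeformationGrid(
        step_px, rows, cols, np.zeros((len(rows), len(cols), 2))
    )
    warped = moving
    for it in range(n_iter):
        resid, valid = _node_shifts(
            fixed, warped, rows, cols, window_px, confidence_floor, upsample
        )
        if valid.any() and not valid.all():
            resid = _fill_invalid_nodes(rows, cols, resid, valid)
        elif not valid.any():
            if it == 0:
                logger.warning(
                    "no confident deformation nodes; returning zero field"
                )
            break
        grid.displacements = grid.displacements + resid
        if np.abs(resid).max() < tol_px or it == n_iter - 1:
            break
        warped = _warp_raster(moving, grid)
    return grid


def _node_shifts(fixed, moving, rows, cols, window_px, floor, upsample):
    half = window_px // 2
    h, w = fixed.shape
    disp = np.zeros((len(rows), len(cols), 2))
    valid = np.zeros((len(rows), len(cols)), dtype=bool)
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            r0, r1 = int(max(r - half, 0)), int(min(r + half, h))
            c0, c1 = int(max(c - half, 0)), int(min(c + half, w))
            wf = fixed[r0:r1, c0:c1]
            wm = moving[r0:r1, c0:c1]
            if np.ptp(wf) == 0 or np.ptp(wm) == 0:
                continue
            shift, _, _ = phase_cross_correlation(
                wf, wm, upsample_factor=upsample, normalization=None
            )
            score = _ncc_at_shift(wf, wm, shift)
            if score >= floor:
                # aligned(x) = moving(x + d): moving(x − s) ≈ fixed ⇒ d = −s
                disp[i, j] = -np.asarray(shift, dtype=float)
                valid[i, j] = True
    return disp, valid


def _warp_raster(raster: np.ndarray, grid: DeformationGrid) -> np.ndarray:
    h, w = raster.shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                         indexing="ij")
    pts = np.stack([rr, cc], axis=-1)
    src = pts + grid.sample(pts)
    return ndi.map_coordinates(raster, [src[..., 0], src[..., 1]], order=1,
                               mode="constant", cval=0.0)


def normalize_decomposition(
    rigid: RigidTransform, grid: DeformationGrid
) -> tuple[RigidTransform, DeformationGrid]:
    """Gauge-fix the rigid/deformable split without changing the warp.

    A constant displacement μ in the grid is indistinguishable from extra
    rigid translation (``A(x + μ + d') = A(x + d') + s·R·μ``); this moves
    the node-mean of the grid into the translation so the grid is
    mean-zero.  Comparisons between two decompositions of the same warp are
    only meaningful after both are normalized this way.
    """
    mu = grid.displacements.reshape(-1, 2).mean(axis=0)
    t = np.array([rigid.ty_px, rigid.tx_px]) + rigid.matrix() @ mu
    fixed_rigid = RigidTransform(
        theta_rad=rigid.theta_rad, ty_px=float(t[0]), tx_px=float(t[1]),
        scale=rigid.scale,
    )
    new_grid = DeformationGrid(
        grid.step_px, grid.node_rows.copy(), grid.node_cols.copy(),
        grid.displacements - mu,
    )
    return fixed_rigid, new_grid


def _fill_invalid_nodes(rows, cols, disp, valid):
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    pts_ok = np.stack([rr[valid], cc[valid]], axis=-1)
    pts_bad = np.stack([rr[~valid], cc[~valid]], axis=-1)
    out = disp.copy()
    for k in range(2):
        vals = disp[..., k][valid]
        filled = griddata(pts_ok, vals, pts_bad, method="linear")
        nn = griddata(pts_ok, vals, pts_bad, method="nearest")
        filled = np.where(np.isnan(filled), nn, filled)
        ch = out[..., k]
        ch[~valid] = filled
        out[..., k] = ch
    return out


# ---------------------------------------------------------------------------
# Warping


def transform_coordinates(
    shape: tuple[int, int],
    rigid: RigidTransform | None,
    deformation: DeformationGrid | None,
) -> np.ndarray:
    """Source coordinates ``A(x + d(x))`` for each output pixel x; (H, W, 2)."""
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                         indexing="ij")
    pts = np.stack([rr, cc], axis=-1)
    if deformation is not None and deformation.max_displacement > 0:
        pts = pts + deformation.sample(pts)
    if rigid is not None and not rigid.is_identity:
        center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        pts = rigid.apply_to_points(pts, center)
    return pts


def apply_transform(
    image: MultiplexImage,
    rigid: RigidTransform | None = None,
    deformation: DeformationGrid | None = None,
) -> MultiplexImage:
    """Warp all channels identically (rigid then deformable composition).

    Bilinear intensity interpolation; out-of-domain pixels are 0.  With an
    identity transform the image is returned pixel-identical.
    """
    src = transform_coordinates(image.shape, rigid, deformation)
    identity = (rigid is None or rigid.is_identity) and (
        deformation is None or deformation.max_displacement == 0
    )
    if identity:
        return image.with_channels({n: np.asarray(c).copy()
                                    for n, c in image.channels.items()})
    coords = [src[..., 0], src[..., 1]]
    channels = {
        name: ndi.map_coordinates(
            np.asarray(c, dtype=np.float64), coords, order=1,
            mode="constant", cval=0.0,
        )
        for name, c in image.channels.items()
    }
    return image.with_channels(channels)


# ---------------------------------------------------------------------------
# Round orchestration


def register_rounds(
    reference: MultiplexImage,
    others: list[MultiplexImage],
    downsample: int = 10,
    step_px: int = 500,
) -> tuple[list[MultiplexImage], list[tuple[RigidTransform, DeformationGrid]]]:
    """Align every round to ``reference`` on the nuclei channels.

    Per round: rescale to the reference pixel size, estimate the global
    rigid transform, estimate the residual deformation grid, then warp all
    channels with the composed transform.
    """
    aligned: list[MultiplexImage] = []
    transforms: list[tuple[RigidTransform, DeformationGrid]] = []
    for rnd in others:
        try:
            img = rescale_to_common_pixel_size(rnd, reference.pixel_size_um)
            img = _pad_or_crop_to(img, reference.shape)
            rigid = estimate_rigid(reference.nuclei, img.nuclei,
                                   downsample=downsample)
            rigid_aligned = apply_transform(img, rigid=rigid)
            if min(reference.shape) >= step_px:
                grid = estimate_deformation(
                    reference.nuclei, rigid_aligned.nuclei, step_px=step_px
                )
            else:
                grid = DeformationGrid.zero(reference.shape, step_px)
            rigid, grid = normalize_decomposition(rigid, grid)
            out = apply_transform(img, rigid=rigid, deformation=grid)
            aligned.append(out)
            transforms.append((rigid, grid))
        except Exception as exc:  # noqa: BLE001 - re-raise with round id
            raise StageError("registration", f"round {rnd.round_id}: {exc}") from exc
    return aligned, transforms


def _pad_or_crop_to(image: MultiplexImage, shape: tuple[int, int]) -> MultiplexImage:
    h, w = image.shape
    th, tw = shape
    if (h, w) == (th, tw):
        return image

    def fix(a):
        a = a[:th, :tw]
        return np.pad(a, ((0, th - a.shape[0]), (0, tw - a.shape[1])))

    return image.with_channels({n: fix(np.asarray(c, dtype=np.float64))
                                for n, c in image.channels.items()})


# ---------------------------------------------------------------------------
# Serialization


def save_transform(path, rigid: RigidTransform, grid: DeformationGrid) -> None:
    data = {
        "rigid": {
            "theta_rad": float(rigid.theta_rad),
            "ty_px": float(rigid.ty_px),
            "tx_px": float(rigid.tx_px),
            "scale": float(rigid.scale),
        },
        "deformation": {
            "step_px": int(grid.step_px),
            "node_rows": [float(v) for v in grid.node_rows],
            "node_cols": [float(v) for v in grid.node_cols],
            "displacements": grid.displacements.tolist(),
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


def load_transform(path) -> tuple[RigidTransform, DeformationGrid]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    rigid = RigidTransform(**data["rigid"])
    d = data["deformation"]
    grid = DeformationGrid(
        step_px=d["step_px"],
        node_rows=np.array(d["node_rows"]),
        node_cols=np.array(d["node_cols"]),
        displacements=np.array(d["displacements"]),
    )
    return rigid, grid
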