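"""Synthetic tissue phantoms with complete ground truth.

The generator emulates the statistical structure of a multiplexed
immunofluorescence slide of pancreas-like tissue: elliptical non-overlapping
nuclei of varying size, cells with nuclear or cytosolic marker
localization, islet versus acinar compartments, mutually exclusive
marker-defined expression clusters, a smooth low-frequency autofluorescence
background, shot-like noise, and (for registration benchmarks) known rigid
plus smooth deformable misalignment between imaging rounds.

Every phantom carries exact ground truth — label maps, per-cell drawn
intensities, cluster and subtype assignments, and true transforms — so each
downstream stage can be scored against a known answer.  With a fixed seed
all outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import disk as draw_disk

from .cellquant import _bilinear_resize, expand_cells
from .errors import CapacityError, ValidationError
from .io import MultiplexImage
from .registration import (
    DeformationGrid,
    RigidTransform,
    _node_coords,
    transform_coordinates,
)

__all__ = [
    "ClusterProfile",
    "TissuePhantomConfig",
    "GroundTruth",
    "generate_tissue",
    "generate_round_pair",
    "planted_islet_population",
    "sample_cluster_expression",
    "default_cluster_profiles",
    "default_islet_profiles",
]

SENESCENCE_MARKERS = ["P53", "P21", "P16", "53BP1", "HMGB1", "LaminB1"]
ENDOCRINE_MARKERS = ["Insulin", "Glucagon", "SST28"]

#: Expression levels of the exclusive-cluster design: a cluster is "high"
#: in exactly one marker and "low" in the rest, with roughly a 10-SD
#: separation between the levels.  The diffuse negative mass sits at the
#: detection floor with a small spread; enriched clusters carry the larger
#: biological and staining variability.
HIGH_MEAN, HIGH_SD = 10.0, 1.0
LOW_MEAN, LOW_SD = 1.0, 0.3


@dataclass
class ClusterProfile:
    """One mixture component of per-marker expression."""

    name: str
    weight: float
    means: dict[str, float]
    sds: dict[str, float]
    subtype: str = "negative"


def default_cluster_profiles(
    markers: list[str] | None = None, diffuse_weight: float = 0.4
) -> list[ClusterProfile]:
    """Exclusive-marker clusters plus a diffuse low-expression mass.

    Each of the given markers defines one cluster with high expression of
    that marker only; the remaining weight goes to a diffuse component with
    low expression of everything.
    """
    markers = list(markers or SENESCENCE_MARKERS)
    w = (1.0 - diffuse_weight) / len(markers)
    profiles = []
    for m in markers:
        means = {x: LOW_MEAN for x in markers}
        sds = {x: LOW_SD for x in markers}
        means[m], sds[m] = HIGH_MEAN, HIGH_SD
        profiles.append(ClusterProfile(f"{m}-high", w, means, sds))
    low = ClusterProfile(
        "diffuse-low",
        diffuse_weight,
        {x: LOW_MEAN for x in markers},
        {x: LOW_SD for x in markers},
    )
    return profiles + [low]


def default_islet_profiles() -> list[ClusterProfile]:
    """Endocrine subtype mixture inside islets (β, α, δ cells)."""
    out = []
    for marker, subtype, weight in [
        ("Insulin", "Insulin+", 0.55),
        ("Glucagon", "Glucagon+", 0.30),
        ("SST28", "SST28+", 0.15),
    ]:
        means = {m: LOW_MEAN for m in ENDOCRINE_MARKERS}
        sds = {m: LOW_SD for m in ENDOCRINE_MARKERS}
        means[marker], sds[marker] = HIGH_MEAN, HIGH_SD
        out.append(ClusterProfile(f"{subtype}-cell", weight, means, sds, subtype))
    return out


@dataclass
class TissuePhantomConfig:
    """Study conditions of the synthetic slide.

    Defaults: a 1024² image at 0.65 µm/px (~666 µm field), ~600 cells with
    nucleus radii 2.6–5.2 µm, two islets, the exclusive-marker cluster
    design with a 40 % diffuse low-expression mass, a smooth
    autofluorescence field and mild shot-like noise.
    """

    image_size_px: tuple[int, int] = (1024, 1024)
    n_cells: int = 600
    nucleus_radius_range_um: tuple[float, float] = (2.6, 5.2)
    pixel_size_um: float = 0.65
    islet_specs: list[tuple[tuple[float, float], float]] = field(
        default_factory=lambda: [((300.0, 300.0), 50.0), ((700.0, 650.0), 65.0)]
    )
    cluster_profiles: list[ClusterProfile] = field(
        default_factory=default_cluster_profiles
    )
    islet_profiles: list[ClusterProfile] = field(default_factory=default_islet_profiles)
    marker_localization: dict[str, str] = field(
        default_factory=lambda: {
            **{m: "nuclear" for m in SENESCENCE_MARKERS},
            "P16": "cell",
            **{m: "cell" for m in ENDOCRINE_MARKERS},
        }
    )
    dapi_mean: float = 50.0
    dapi_sd: float = 5.0
    islet_base_intensity: dict[str, float] = field(
        default_factory=lambda: {"Insulin": 8.0, "Glucagon": 6.0}
    )
    background_base: float = 5.0
    background_amplitude: float = 2.0
    noise_sd: float = 1.0
    expansion_px: int = 7
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValidationError("n_cells must be ≥ 0")
        lo, hi = self.nucleus_radius_range_um
        if not 0 < lo <= hi:
            raise ValidationError("nucleus radii must be positive and ordered")
        for _, radius in self.islet_specs:
            if radius <= 0:
                raise ValidationError("islet radii must be positive")
        for profs in (self.cluster_profiles, self.islet_profiles):
            total = sum(p.weight for p in profs)
            if profs and abs(total - 1.0) > 1e-9:
                raise ValidationError(f"mixture weights sum to {total}, not 1")

    @property
    def markers(self) -> list[str]:
        names: list[str] = []
        for p in self.cluster_profiles + self.islet_profiles:
            for m in p.means:
                if m not in names:
                    names.append(m)
        return names

    def noiseless(self) -> "TissuePhantomConfig":
        """Copy with noise, background and intensity spreads switched off."""
        zero_sd = [
            replace(p, sds={m: 0.0 for m in p.sds}) for p in self.cluster_profiles
        ]
        zero_islet = [
            replace(p, sds={m: 0.0 for m in p.sds}) for p in self.islet_profiles
        ]
        return replace(
            self,
            cluster_profiles=zero_sd,
            islet_profiles=zero_islet,
            dapi_sd=0.0,
            background_base=0.0,
            background_amplitude=0.0,
            noise_sd=0.0,
        )


@dataclass
class GroundTruth:
    """Exact answers for a generated phantom."""

    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    islet_labels: np.ndarray
    cells: pd.DataFrame  # one row per cell: assignments + drawn intensities
    config: TissuePhantomConfig
    rigid: RigidTransform | None = None
    deformation: DeformationGrid | None = None


# ---------------------------------------------------------------------------
# Tissue generation


def _place_nuclei(cfg: TissuePhantomConfig, rng: np.random.Generator):
    h, w = cfg.image_size_px
    r_lo = cfg.nucleus_radius_range_um[0] / cfg.pixel_size_um
    r_hi = cfg.nucleus_radius_range_um[1] / cfg.pixel_size_um
    placed: list[tuple[float, float, float, float, float]] = []
    centers = np.empty((0, 2))
    radii = np.empty(0)
    tries = 0
    max_tries = max(cfg.n_cells * 200, 1000)
    while len(placed) < cfg.n_cells:
        if tries >= max_tries:
            raise CapacityError(
                f"placed only {len(placed)}/{cfg.n_cells} nuclei after "
                f"{max_tries} tries"
            )
        tries += 1
        major = rng.uniform(r_lo, r_hi)
        minor = major * rng.uniform(0.7, 1.0)
        margin = major + 1
        r = rng.uniform(margin, h - 1 - margin)
        c = rng.uniform(margin, w - 1 - margin)
        if centers.size:
            d = np.hypot(centers[:, 0] - r, centers[:, 1] - c)
            if np.any(d < radii + major + 2):
                continue
        theta = rng.uniform(0, np.pi)
        placed.append((r, c, major, minor, theta))
        centers = np.vstack([centers, [r, c]])
        radii = np.append(radii, major)
    return placed


def _render_labels(cfg, placed):
    h, w = cfg.image_size_px
    labels = np.zeros((h, w), dtype=np.int32)
    for i, (r, c, major, minor, theta) in enumerate(placed, start=1):
        rr, cc = draw_ellipse(r, c, minor, major, rotation=theta, shape=(h, w))
        labels[rr, cc] = i
    return labels


def _islet_label_map(cfg) -> np.ndarray:
    h, w = cfg.image_size_px
    labels = np.zeros((h, w), dtype=np.int32)
    for k, ((r, c), radius_um) in enumerate(cfg.islet_specs, start=1):
        rr, cc = draw_disk((r, c), radius_um / cfg.pixel_size_um, shape=(h, w))
        labels[rr, cc] = k
    return labels


def _smooth_field(shape, rng, n_knots: int = 9) -> np.ndarray:
    coarse = rng.normal(size=(n_knots, n_knots))
    fieldv = _bilinear_resize(coarse, shape)
    ptp = np.ptp(fieldv)
    if ptp == 0:
        return np.zeros(shape)
    return (fieldv - fieldv.min()) / ptp


def generate_tissue(
    config: TissuePhantomConfig,
) -> tuple[MultiplexImage, GroundTruth]:
    """Render one imaging round of the phantom plus its ground truth.

    Order of construction: nuclei placement → label maps → per-cell cluster
    assignment and marker draws → channel rendering (nuclear markers over
    the nucleus, cytosolic markers over the annulus between nucleus and
    cell boundary) → smooth background → shot-like noise last.  The ground
    truth records the pre-noise answers.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size_px
    placed = _place_nuclei(config, rng)
    nucleus_labels = _render_labels(config, placed)
    cell_labels = expand_cells(nucleus_labels, config.expansion_px)
    islet_labels = _islet_label_map(config)

    n = len(placed)
    markers = config.markers
    centroids = np.array([(p[0], p[1]) for p in placed]).reshape(n, 2)
    if n:
        islet_of_cell = islet_labels[
            np.clip(np.round(centroids[:, 0]).astype(int), 0, h - 1),
            np.clip(np.round(centroids[:, 1]).astype(int), 0, w - 1),
        ]
    else:
        islet_of_cell = np.zeros(0, dtype=int)

    profiles = list(config.cluster_profiles) + list(config.islet_profiles)
    n_acinar = len(config.cluster_profiles)
    cluster_id = np.zeros(n, dtype=int)
    for i in range(n):
        if islet_of_cell[i] > 0 and config.islet_profiles:
            wts = np.array([p.weight for p in config.islet_profiles])
            cluster_id[i] = n_acinar + rng.choice(len(wts), p=wts / wts.sum())
        else:
            wts = np.array([p.weight for p in config.cluster_profiles])
            cluster_id[i] = rng.choice(len(wts), p=wts / wts.sum())

    values = np.zeros((n, len(markers)))
    for i in range(n):
        prof = profiles[cluster_id[i]]
        for j, m in enumerate(markers):
            mu = prof.means.get(m, LOW_MEAN)
            sd = prof.sds.get(m, 0.0)
            values[i, j] = max(0.0, mu + (rng.normal(0.0, sd) if sd > 0 else 0.0))

    dapi_values = np.maximum(
        config.dapi_mean
        + (rng.normal(0.0, config.dapi_sd, n) if config.dapi_sd > 0 else np.zeros(n)),
        0.0,
    )

    channels: dict[str, np.ndarray] = {"DAPI": np.zeros((h, w))}
    for m in markers:
        channels[m] = np.zeros((h, w))

    nuc_mask = nucleus_labels > 0
    lut_dapi = np.zeros(n + 1)
    lut_dapi[1:] = dapi_values
    channels["DAPI"][nuc_mask] = lut_dapi[nucleus_labels[nuc_mask]]

    annulus = (cell_labels > 0) & ~nuc_mask
    for j, m in enumerate(markers):
        lut = np.zeros(n + 1)
        lut[1:] = values[:, j]
        if config.marker_localization.get(m, "nuclear") == "nuclear":
            channels[m][nuc_mask] = lut[nucleus_labels[nuc_mask]]
        else:
            channels[m][annulus] = lut[cell_labels[annulus]]

    # interstitial islet staining: positive islet matrix outside any cell,
    # so per-cell intensities stay exactly the drawn values
    interstitial = (islet_labels > 0) & (cell_labels == 0)
    for m, level in config.islet_base_intensity.items():
        if m in channels:
            channels[m][interstitial] += level

    if config.background_base > 0 or config.background_amplitude > 0:
        fieldv = _smooth_field((h, w), rng)
        bg = config.background_base + config.background_amplitude * fieldv
        for m in channels:
            channels[m] = channels[m] + bg

    if config.noise_sd > 0:
        for m in channels:
            noise = rng.normal(0.0, 1.0, (h, w)) * config.noise_sd * np.sqrt(
                1.0 + np.maximum(channels[m], 0.0)
            )
            channels[m] = np.maximum(channels[m] + noise, 0.0)

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "centroid_row": centroids[:, 0] if n else np.zeros(0),
            "centroid_col": centroids[:, 1] if n else np.zeros(0),
            "islet_id": islet_of_cell,
            "cluster_id": cluster_id,
            "cluster_name": [profiles[k].name for k in cluster_id],
            "subtype": [profiles[k].subtype for k in cluster_id],
        }
    )
    for j, m in enumerate(markers):
        cells[f"{m}_true"] = values[:, j] if n else np.zeros(0)
    cells["DAPI_true"] = dapi_values if n else np.zeros(0)

    image = MultiplexImage(
        round_id="r1",
        channels=channels,
        pixel_size_um=config.pixel_size_um,
        nuclei_channel="DAPI",
    )
    truth = GroundTruth(
        nucleus_labels=nucleus_labels,
        cell_labels=cell_labels,
        islet_labels=islet_labels,
        cells=cells,
        config=config,
    )
    return image, truth


# ---------------------------------------------------------------------------
# Misaligned round pairs


def generate_round_pair(
    config: TissuePhantomConfig,
    rigid: RigidTransform,
    deform_amplitude_px: float,
    deform_step_px: int = 500,
) -> tuple[MultiplexImage, MultiplexImage, GroundTruth]:
    """A fixed round and a misaligned copy with known true transforms.

    The stored ground truth is exactly the transform that maps the moving
    round back onto the fixed one (the transform a registration stage must
    estimate): ``moving`` is built by numerically inverting the aligning
    warp ``M(x) = A(x + d(x))`` so that ``moving(M(x)) = fixed(x)``.  Node
    displacements are drawn uniformly in ±amplitude and interpolated
    bilinearly, the same smooth representation the registration module
    estimates.
    """
    if abs(deform_amplitude_px) >= deform_step_px / 4:
        raise ValidationError(
            "deformation amplitude must stay below a quarter of the grid step"
        )
    fixed, truth = generate_tissue(config)
    h, w = fixed.shape
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    rows = _node_coords(h, deform_step_px)
    cols = _node_coords(w, deform_step_px)
    if deform_amplitude_px > 0:
        disp = rng.uniform(
            -deform_amplitude_px, deform_amplitude_px, (len(rows), len(cols), 2)
        )
        # mean-zero field: a constant displacement is indistinguishable from
        # rigid translation, so the planted split must be gauge-fixed
        disp -= disp.reshape(-1, 2).mean(axis=0)
    else:
        disp = np.zeros((len(rows), len(cols), 2))
    grid = DeformationGrid(deform_step_px, rows, cols, disp)

    src = _invert_warp(fixed.shape, rigid, grid)
    if rigid.is_identity and grid.max_displacement == 0:
        moving = fixed.with_channels(
            {n: np.asarray(c).copy() for n, c in fixed.channels.items()}
        )
    else:
        coords = [src[..., 0], src[..., 1]]
        moving = fixed.with_channels(
            {
                n: ndi.map_coordinates(
                    np.asarray(c, dtype=np.float64), coords, order=1,
                    mode="constant", cval=0.0,
                )
                for n, c in fixed.channels.items()
            }
        )
    moving.round_id = "r2"
    truth.rigid = rigid
    truth.deformation = grid
    return fixed, moving, truth


def _invert_warp(shape, rigid: RigidTransform, grid: DeformationGrid,
                 n_iter: int = 8, tol_px: float = 1e-3) -> np.ndarray:
    """Fixed-point inversion of M(x) = A(x + d(x)); returns M⁻¹ per pixel."""
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                         indexing="ij")
    y = np.stack([rr, cc], axis=-1)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    inv = rigid.inverse()
    x = inv.apply_to_points(y, center)
    if grid.max_displacement == 0:
        return x
    rinv = inv.matrix()
    for _ in range(n_iter):
        mx = rigid.apply_to_points(x + grid.sample(x), center)
        step = (mx - y) @ rinv.T
        x = x - step
        if np.abs(step).max() < tol_px:
            break
    return x


# ---------------------------------------------------------------------------
# Planted islet-level correlation


def planted_islet_population(
    n_islets: int,
    r_target: float,
    seed: int = 0,
    area_mean_um2: float = 5000.0,
    area_sd_um2: float = 1200.0,
    marker_mean: float = 2.0,
    marker_sd: float = 0.5,
    marker_name: str = "P16",
) -> pd.DataFrame:
    """Islet-level table with Pearson(area, marker) = ``r_target`` in the
    population (bivariate-normal construction); the sample correlation
    converges to the target as ``n_islets`` grows."""
    if not abs(r_target) < 1:
        raise ValidationError("r_target must satisfy |r| < 1")
    if n_islets < 3:
        raise ValidationError("need at least 3 islets")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n_islets)
    z2 = rng.standard_normal(n_islets)
    area = area_mean_um2 + area_sd_um2 * z1
    marker = marker_mean + marker_sd * (
        r_target * z1 + np.sqrt(1 - r_target**2) * z2
    )
    return pd.DataFrame(
        {
            "islet_id": np.arange(1, n_islets + 1),
            "area_um2": area,
            f"{marker_name}_mean": marker,
        }
    )


# ---------------------------------------------------------------------------
# Expression-only sampling (no rendering)


def sample_cluster_expression(
    profiles: list[ClusterProfile],
    n_cells: int,
    seed: int = 0,
    markers: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw per-cell marker vectors straight from a mixture of profiles.

    Returns the expression matrix (cells × markers) and the true component
    index per cell; used for clustering benchmarks where image rendering
    adds nothing.
    """
    if markers is None:
        markers = []
        for p in profiles:
            for m in p.means:
                if m not in markers:
                    markers.append(m)
    weights = np.array([p.weight for p in profiles], dtype=float)
    if abs(weights.sum() - 1) > 1e-9:
        raise ValidationError("profile weights must sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(profiles), size=n_cells, p=weights)
    x = np.zeros((n_cells, len(markers)))
    for j, m in enumerate(markers):
        mu = np.array([p.means.get(m, LOW_MEAN) for p in profiles])
        sd = np.array([p.sds.get(m, LOW_SD) for p in profiles])
        x[:, j] = np.maximum(mu[comp] + rng.standard_normal(n_cells) * sd[comp], 0.0)
    frame = pd.DataFrame(x, columns=markers)
    frame.insert(0, "cell_id", np.arange(1, n_cells + 1))
    return frame, comp
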