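"""Pipeline configuration.

All scalar parameters of the workflow live here with the defaults used
throughout: 0.65 µm pixels, a 4.5 µm (7 px) cell expansion, a 7×7 median
background window on 10×-downsized images, a 400 µm² islet size cutoff, a
500 px deformation grid, 2000 px ROIs, and a z-score → PCA(0.95) → K-means
(k=20) clustering stage.  An empty override therefore reproduces the
standard analysis parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .errors import ConfigurationError
from .io import DEFAULT_PIXEL_SIZE_UM


@dataclass
class PipelineConfig:
    """Scalar parameters of the whole quantification workflow.

    Attributes
    ----------
    pixel_size_um
        Physical pixel pitch in µm.
    expansion_um
        Cell boundary expansion from the nucleus boundary, in µm.  The
        pixel radius used for tessellation is ``round(expansion_um /
        pixel_size_um)`` with half-up rounding (4.5/0.65 → 7 px).
    background_window_px
        Side of the square median-filter window (odd).
    background_downsize
        Integer factor by which images are down-sized (block average)
        before median filtering.
    islet_min_area_um2
        Islet regions smaller than this are excluded.
    deform_grid_step_px
        Grid spacing of the local deformable registration.
    roi_size_px
        Side of the square ROIs sampled for single-cell analysis.
    n_rois
        Number of non-overlapping ROIs to select.
    kmeans_k
        Number of expression subtypes for K-means.
    pca_var_frac
        Fraction of variance the retained principal axes must explain.
    marker_localization
        Per-marker ``"nuclear"`` or ``"cell"`` flag choosing which mean
        intensity represents the marker (cytosolic markers such as P16 use
        the cell-region mean).
    thresholds
        Per-marker positivity threshold spec: a number (manual), the string
        ``"otsu"`` (automatic bimodal on log intensities), or
        ``{"quantile": q}``.
    """

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    expansion_um: float = 4.5
    background_window_px: int = 7
    background_downsize: int = 10
    islet_min_area_um2: float = 400.0
    deform_grid_step_px: int = 500
    roi_size_px: int = 2000
    n_rois: int = 11
    kmeans_k: int = 20
    kmeans_n_init: int = 10
    pca_var_frac: float = 0.95
    rigid_downsample: int = 10
    struct_radius_px: int = 3
    marker_localization: dict[str, str] = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    random_seed: int = 0

    def __post_init__(self):
        positive = [
            "pixel_size_um",
            "background_window_px",
            "background_downsize",
            "islet_min_area_um2",
            "deform_grid_step_px",
            "roi_size_px",
            "n_rois",
            "kmeans_k",
            "kmeans_n_init",
            "rigid_downsample",
            "struct_radius_px",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.expansion_um < 0:
            raise ConfigurationError("expansion_um must be non-negative")
        if not 0 < self.pca_var_frac <= 1:
            raise ConfigurationError("pca_var_frac must be in (0, 1]")
        if self.background_window_px % 2 != 1:
            raise ConfigurationError("background_window_px must be odd")
        for marker, loc in self.marker_localization.items():
            if loc not in ("nuclear", "cell"):
                raise ConfigurationError(
                    f"marker {marker!r}: localization must be 'nuclear' or 'cell'"
                )

    @property
    def expansion_px(self) -> int:
        """Expansion radius in pixels, rounded half-up (4.5/0.65 → 7)."""
        from math import floor

        return int(floor(self.expansion_um / self.pixel_size_um + 0.5))

    @property
    def islet_min_area_px(self) -> int:
        """Pixel-area cutoff: ceil(min_area_um2 / pixel_size_um²)."""
        from math import ceil

        return int(ceil(self.islet_min_area_um2 / self.pixel_size_um**2))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a config; missing keys fall back to the standard defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
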