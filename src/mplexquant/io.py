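"""Image and table I/O.

Images are multichannel 2D rasters stored as (OME-)TIFF, one page per
channel; tables are plain CSV with a header row.  Coordinates are 0-based
(row, col) with the origin at the top-left pixel; label maps are integer
TIFFs with label 0 reserved for background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ValidationError

#: Default physical pixel pitch of the acquisition setup (µm per pixel).
DEFAULT_PIXEL_SIZE_UM = 0.65


@dataclass
class MultiplexImage:
    """Named 2D intensity channels of one imaging round.

    Parameters
    ----------
    round_id
        Identifier of the imaging round (e.g. ``"r1"``).
    channels
        Ordered mapping of channel name to a 2D array of non-negative
        intensities.  All channels must share the same height × width.
    pixel_size_um
        Physical size of one pixel in µm (> 0).
    nuclei_channel
        Name of the nuclei counterstain channel (DAPI or equivalent);
        must be a key of ``channels``.
    """

    round_id: str
    channels: dict[str, np.ndarray]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    nuclei_channel: str = "DAPI"

    def __post_init__(self):
        if not self.channels:
            raise ValidationError("MultiplexImage requires at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValidationError(f"channels have inconsistent shapes: {shapes}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValidationError(f"channels must be 2D, got shape {shape}")
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be positive")
        if self.nuclei_channel not in self.channels:
            raise ValidationError(
                f"nuclei_channel {self.nuclei_channel!r} not among channels "
                f"{list(self.channels)}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def nuclei(self) -> np.ndarray:
        return self.channels[self.nuclei_channel]

    def stack(self) -> np.ndarray:
        """Channels stacked into a (C, H, W) array in channel order."""
        return np.stack(list(self.channels.values()))

    def with_channels(self, channels: dict[str, np.ndarray]) -> "MultiplexImage":
        return MultiplexImage(
            round_id=self.round_id,
            channels=channels,
            pixel_size_um=self.pixel_size_um,
            nuclei_channel=self.nuclei_channel,
        )


def read_multiplex_image(
    path,
    channel_names: list[str],
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    nuclei_channel: str | None = None,
    round_id: str = "r1",
) -> MultiplexImage:
    """Read a single- or multi-page TIFF into a :class:`MultiplexImage`.

    The page count must equal ``len(channel_names)``; channels are keyed in
    the given order and intensities are preserved bit-exactly.
    """
    try:
        data = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 2D pages, got array of shape {data.shape}")
    if data.shape[0] != len(channel_names):
        raise FormatError(
            f"{path}: {data.shape[0]} pages but {len(channel_names)} channel names"
        )
    channels = {name: data[i] for i, name in enumerate(channel_names)}
    if nuclei_channel is None:
        nuclei_channel = channel_names[0]
    return MultiplexImage(
        round_id=round_id,
        channels=channels,
        pixel_size_um=pixel_size_um,
        nuclei_channel=nuclei_channel,
    )


def write_multiplex_image(image: MultiplexImage, path) -> None:
    """Write all channels as an OME-TIFF with minimal metadata.

    Channel names and the physical pixel size are recorded; intensities are
    written bit-exactly in channel order, one page per channel.
    """
    stack = image.stack()
    tifffile.imwrite(
        path,
        stack,
        ome=True,
        metadata={
            "axes": "CYX",
            "Channel": {"Name": image.channel_names},
            "PhysicalSizeX": image.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": image.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
        },
    )


def write_label_map(labels: np.ndarray, path) -> None:
    """Store an integer label raster (0 = background) as TIFF."""
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValidationError("label map must have an integer dtype")
    tifffile.imwrite(path, labels.astype(np.int32))


def read_label_map(path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim != 2 or not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path}: not a 2D integer label map")
    return arr


# ---------------------------------------------------------------------------
# Tables

#: Columns every cell feature table must carry (per-channel intensity columns
#: come on top of these and are named ``<channel>_nuc_mean`` etc.).
CELL_TABLE_REQUIRED = [
    "cell_id",
    "centroid_row",
    "centroid_col",
    "nucleus_area_px",
    "nucleus_area_um2",
    "aspect_ratio",
    "circularity",
    "equivalent_radius_px",
    "cell_area_px",
    "cell_area_um2",
]

ISLET_TABLE_REQUIRED = [
    "islet_id",
    "area_px",
    "area_um2",
    "aspect_ratio",
    "circularity",
    "solidity",
]


def write_cell_table(table: pd.DataFrame, path) -> None:
    """Write a cell feature table as CSV (header + full-precision floats)."""
    _check_columns(table, CELL_TABLE_REQUIRED, "cell table")
    table.to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    _check_columns(table, CELL_TABLE_REQUIRED, f"cell table {path}")
    return table


def write_islet_table(table: pd.DataFrame, path) -> None:
    _check_columns(table, ISLET_TABLE_REQUIRED, "islet table")
    table.to_csv(path, index=False)


def read_islet_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    _check_columns(table, ISLET_TABLE_REQUIRED, f"islet table {path}")
    return table


def _check_columns(table: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"{what}: missing required columns {missing}")
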