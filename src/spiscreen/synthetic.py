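"""Synthetic data generators for every stage of the SPI pipeline.

Forward models with known ground truth: colony-array screens with planted
growth-defect strains, rendered plate scans, two-channel 3D fluorescence
stacks with spherical nuclei, and binomially sampled cell-count tables.
Everything is driven by an explicit integer seed so downstream estimates can
be compared against the quantities that generated them.

The colony model mirrors how an SPI screen produces data: each strain is
pinned as a square block of replicates on a 1536-position grid (32 x 48),
plates carry a multiplicative scale factor (growth/medium batch effects), and
individual colonies carry multiplicative lognormal noise.  A strain with a
true log growth ratio (LGR) of L grows experimental colonies attenuated by
exp(-L) relative to its control colonies, which is exactly the quantity the
screen statistics attempt to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk

__all__ = [
    "ScreenSimConfig",
    "GroundTruth",
    "StackSimConfig",
    "Nucleus",
    "GridGeometry",
    "CapacityError",
    "PlacementError",
    "generate_screen",
    "render_plate_image",
    "generate_stack",
    "generate_counts",
    "lognormal_factors",
]

#: grid pitch of a 1536-density colony array, in millimetres (industry standard
#: 32 x 48 layout on a 128 x 86 mm plate).
PITCH_MM = 2.25


class CapacityError(ValueError):
    """Strain replicates do not fit on the requested plate geometry."""


class PlacementError(ValueError):
    """A synthetic nucleus does not fit inside the stack."""


def lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal factors with mean 1 and coefficient of variation *cv*.

    cv = 0 returns exact ones so that noiseless configurations are bit-exact.
    """
    if cv < 0:
        raise ValueError(f"coefficient of variation must be >= 0, got {cv}")
    if cv == 0:
        return np.ones(size, dtype=float)
    sigma2 = math.log1p(cv * cv)
    sigma = math.sqrt(sigma2)
    return np.exp(rng.normal(-sigma2 / 2.0, sigma, size=size))


@dataclass
class ScreenSimConfig:
    """Parameters of a simulated colony-array screen.

    Replicates of each strain are pinned as contiguous square blocks (2x2 for
    4 replicates, 4x4 for 16), reproducing the robot upscaling geometry that
    puts 384 or 96 strains on one 1536-colony plate.
    """

    n_strains: int = 384
    replicates_per_strain: int = 4          # 4 or 16
    plate_rows: int = 32
    plate_cols: int = 48
    plasmids: tuple[str, ...] = ("experimental", "control-1", "control-2")
    experimental: str = "experimental"
    plate_effect_cv: float = 0.1            # CV of per-plate multiplicative scale
    colony_noise_cv: float = 0.2            # CV of per-colony multiplicative noise
    hit_lgr: Mapping[str, float] = field(default_factory=dict)  # strain -> true LGR
    baseline_size: float = 100.0            # arbitrary colony-size units
    edge_effect: float = 1.0                # multiplicative factor on border cells
    max_plates: int | None = None           # cap on plates per plasmid (None: as many as needed)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_strain not in (4, 16):
            raise ValueError("replicates_per_strain must be 4 or 16")
        if self.plate_effect_cv < 0 or self.colony_noise_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.experimental not in self.plasmids:
            raise ValueError("experimental plasmid must appear in plasmids")
        if len(self.plasmids) < 2:
            raise ValueError("need at least one control plasmid")
        b = self.block_side
        if self.plate_rows % b or self.plate_cols % b:
            raise ValueError("plate dimensions must be multiples of the replicate block")
        for s, lgr in self.hit_lgr.items():
            if lgr < 0:
                raise ValueError(f"true LGR of planted hit {s!r} must be >= 0")

    @property
    def block_side(self) -> int:
        return int(round(math.sqrt(self.replicates_per_strain)))

    @property
    def strains_per_plate(self) -> int:
        b = self.block_side
        return (self.plate_rows // b) * (self.plate_cols // b)

    @property
    def controls(self) -> tuple[str, ...]:
        return tuple(p for p in self.plasmids if p != self.experimental)

    @property
    def n_plates(self) -> int:
        needed = -(-self.n_strains // self.strains_per_plate)
        return needed if self.max_plates is None else min(needed, self.max_plates)


@dataclass
class GroundTruth:
    """What the generator actually did: planted effects and realised sizes."""

    true_lgr: dict[str, float]
    plate_factors: pd.DataFrame   # columns: plasmid, plate, factor
    sizes: pd.DataFrame           # columns: plate, row, col, strain, plasmid, size

    def lgr_of(self, strain: str) -> float:
        return self.true_lgr.get(strain, 0.0)


def _layout(config: ScreenSimConfig, strains: Sequence[str]) -> pd.DataFrame:
    """Place each strain's replicates as a square block; strains row-major by block."""
    b = config.block_side
    blocks_per_row = config.plate_cols // b
    blocks_per_plate = config.strains_per_plate
    rows, cols, plates, names = [], [], [], []
    for i, strain in enumerate(strains):
        plate = i // blocks_per_plate
        k = i % blocks_per_plate
        br, bc = divmod(k, blocks_per_row)
        for dr in range(b):
            for dc in range(b):
                plates.append(plate)
                rows.append(br * b + dr)
                cols.append(bc * b + dc)
                names.append(strain)
    return pd.DataFrame({"plate": plates, "row": rows, "col": cols, "strain": names})


def generate_screen(
    config: ScreenSimConfig, strains: Sequence[str] | None = None
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], GroundTruth]:
    """Simulate one screen: a layout, one colony table per plasmid, and ground truth.

    Returns
    -------
    layout : DataFrame with columns plate, row, col, strain (identical across plasmids).
    tables : dict mapping plasmid label to a colony table with columns
        plate, row, col, strain, plasmid, size.
    truth : :class:`GroundTruth`.

    Control-plasmid colonies are drawn without any LGR attenuation; the
    experimental plasmid attenuates each planted hit by exp(-true LGR).
    """
    if strains is None:
        strains = [f"strain-{i + 1:04d}" for i in range(config.n_strains)]
    if len(strains) != config.n_strains:
        raise ValueError("strain list length must equal n_strains")
    unknown = set(config.hit_lgr) - set(strains)
    if unknown:
        raise ValueError(f"hit strains not in strain list: {sorted(unknown)}")
    if config.n_strains > config.strains_per_plate * config.n_plates:
        raise CapacityError("layout capacity exceeded")

    rng = np.random.default_rng(config.seed)
    layout = _layout(config, strains)
    true_lgr = {s: float(config.hit_lgr.get(s, 0.0)) for s in strains}
    lgr_per_pos = layout["strain"].map(true_lgr).to_numpy()

    edge = np.ones(len(layout))
    if config.edge_effect != 1.0:
        r = layout["row"].to_numpy()
        c = layout["col"].to_numpy()
        border = (r == 0) | (c == 0) | (r == config.plate_rows - 1) | (c == config.plate_cols - 1)
        edge[border] = config.edge_effect

    tables: dict[str, pd.DataFrame] = {}
    factor_rows = []
    for plasmid in config.plasmids:
        factors = lognormal_factors(rng, config.plate_effect_cv, config.n_plates)
        for p, f in enumerate(factors):
            factor_rows.append((plasmid, p, float(f)))
        noise = lognormal_factors(rng, config.colony_noise_cv, len(layout))
        attenuation = (
            np.exp(-lgr_per_pos) if plasmid == config.experimental else np.ones(len(layout))
        )
        size = (
            config.baseline_size
            * factors[layout["plate"].to_numpy()]
            * attenuation
            * noise
            * edge
        )
        tbl = layout.copy()
        tbl["plasmid"] = plasmid
        tbl["size"] = size
        tables[plasmid] = tbl
    truth = GroundTruth(
        true_lgr=true_lgr,
        plate_factors=pd.DataFrame(factor_rows, columns=["plasmid", "plate", "factor"]),
        sizes=pd.concat(tables.values(), ignore_index=True),
    )
    return layout, tables, truth


@dataclass
class GridGeometry:
    """Uniform colony grid in pixel coordinates (row-major, y before x)."""

    n_rows: int
    n_cols: int
    origin: tuple[float, float]   # (y, x) of cell (0, 0) centre
    pitch: tuple[float, float]    # (dy, dx) between adjacent centres

    def __post_init__(self) -> None:
        if self.pitch[0] <= 0 or self.pitch[1] <= 0:
            raise ValueError("pitch must be positive")

    def center(self, row: int, col: int) -> tuple[float, float]:
        return (self.origin[0] + row * self.pitch[0], self.origin[1] + col * self.pitch[1])

    def centers(self) -> np.ndarray:
        """(n_rows*n_cols, 2) array of (y, x) centres, row-major."""
        rr, cc = np.meshgrid(np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij")
        ys = self.origin[0] + rr.ravel() * self.pitch[0]
        xs = self.origin[1] + cc.ravel() * self.pitch[1]
        return np.column_stack([ys, xs])


def render_plate_image(
    table: pd.DataFrame,
    dpi: float = 300.0,
    background: float = 30.0,
    foreground: float = 220.0,
    noise_sd: float = 0.0,
    area_per_unit: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, GridGeometry]:
    """Render one plate's colony table as a grayscale scan.

    Each colony becomes a filled disc at its grid position with pixel area
    proportional to its size; a size of zero renders nothing.  The pixel
    pitch follows the physical 1536-array geometry (2.25 mm) at *dpi*.

    Parameters
    ----------
    table : colony table restricted to a single plate (columns row, col, size).
    area_per_unit : pixels of disc area per colony-size unit.  ``None``
        auto-scales so the largest colony occupies 42 % of the pitch radius,
        which keeps neighbouring discs disjoint.

    Returns
    -------
    (image, geometry) : float image (background/foreground gray levels, plus
        optional additive Gaussian noise) and the exact grid used.
    """
    if dpi < 300:
        raise ValueError("dpi must be >= 300 (scanner minimum)")
    if (table["size"] < 0).any():
        raise ValueError("colony sizes must be >= 0")
    if "plate" in table.columns and table["plate"].nunique() > 1:
        raise ValueError("render one plate at a time")

    n_rows = int(table["row"].max()) + 1
    n_cols = int(table["col"].max()) + 1
    pitch = PITCH_MM / 25.4 * dpi
    origin = (pitch, pitch)  # one-pitch margin on every side
    geom = GridGeometry(n_rows, n_cols, origin, (pitch, pitch))
    shape = (
        int(round(pitch * (n_rows + 1))),
        int(round(pitch * (n_cols + 1))),
    )
    max_size = float(table["size"].max())
    if area_per_unit is None:
        if max_size > 0:
            r_max = 0.42 * pitch
            area_per_unit = math.pi * r_max * r_max / max_size
        else:
            area_per_unit = 1.0

    img = np.full(shape, background, dtype=float)
    for row, col, size in zip(table["row"], table["col"], table["size"]):
        if size <= 0:
            continue
        radius = math.sqrt(area_per_unit * float(size) / math.pi)
        # integer pixel centres: equal sizes rasterize to identical discs
        cy, cx = geom.center(int(row), int(col))
        rr, cc = disk((round(cy), round(cx)), radius, shape=shape)
        img[rr, cc] = foreground
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=shape)
        np.clip(img, 0.0, None, out=img)
    return img, geom


@dataclass
class Nucleus:
    """Spherical nucleus phantom: centre in physical µm (z, y, x), radius in µm."""

    center_um: tuple[float, float, float]
    radius_um: float
    marker_intensity: float = 1000.0
    measure_intensity: float = 200.0


@dataclass
class StackSimConfig:
    """Two-channel 3D stack phantom with anisotropic voxels.

    Defaults follow a widefield system imaging yeast: 205 nm pixels in x/y,
    300 nm z steps, 16-bit sensor with ~30,000 gray-level dynamic range.
    """

    shape: tuple[int, int, int] = (20, 128, 128)    # (z, y, x) voxels
    voxel_xy_nm: float = 205.0
    voxel_z_nm: float = 300.0
    nuclei: Sequence[Nucleus] = ()
    background: float = 50.0          # measurement-channel background level
    marker_background: float = 10.0
    noise_sd: float = 0.0             # additive Gaussian, both channels
    dynamic_range: float = 30000.0    # 12-bit ~3000, 16-bit ~30000
    shell_margin_vox: int = 6         # offset+thickness of the background shell
    seed: int = 0

    def __post_init__(self) -> None:
        for nuc in self.nuclei:
            if nuc.marker_intensity > self.dynamic_range or nuc.measure_intensity > self.dynamic_range:
                raise ValueError("nucleus intensity exceeds sensor dynamic range")


def sphere_mask(
    shape: tuple[int, int, int],
    center_um: tuple[float, float, float],
    radius_um: float,
    voxel_z_nm: float,
    voxel_xy_nm: float,
) -> np.ndarray:
    """Voxels whose centres lie within *radius_um* of the sphere centre.

    Voxel (k, j, i) has its centre at physical position
    (k*voxel_z, j*voxel_xy, i*voxel_xy); membership uses <= radius.
    """
    vz, vxy = voxel_z_nm / 1000.0, voxel_xy_nm / 1000.0
    zz = np.arange(shape[0])[:, None, None] * vz - center_um[0]
    yy = np.arange(shape[1])[None, :, None] * vxy - center_um[1]
    xx = np.arange(shape[2])[None, None, :] * vxy - center_um[2]
    return zz * zz + yy * yy + xx * xx <= radius_um * radius_um


def generate_stack(config: StackSimConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Build a two-channel stack and its per-nucleus truth table.

    Channel 0 is the nuclear marker (spheres of marker intensity on a dim
    background); channel 1 is the measurement channel (nucleus intensity
    inside spheres, background outside).  The truth table records, per
    nucleus, the voxel count and the true background-corrected mean
    (measure_intensity - background).

    Raises :class:`PlacementError` if a sphere, dilated in-plane by the
    background-shell margin, would leave the stack.
    """
    vz, vxy = config.voxel_z_nm / 1000.0, config.voxel_xy_nm / 1000.0
    nz, ny, nx = config.shape
    marker = np.full(config.shape, config.marker_background, dtype=float)
    measure = np.full(config.shape, config.background, dtype=float)
    margin_um = config.shell_margin_vox * vxy
    records = []
    for i, nuc in enumerate(config.nuclei):
        cz, cy, cx = nuc.center_um
        if not (nuc.radius_um <= cz <= (nz - 1) * vz - nuc.radius_um):
            raise PlacementError(f"nucleus {i} overlaps the stack edge in z")
        r_ext = nuc.radius_um + margin_um
        if not (r_ext <= cy <= (ny - 1) * vxy - r_ext and r_ext <= cx <= (nx - 1) * vxy - r_ext):
            raise PlacementError(f"nucleus {i} (plus shell margin) overlaps the stack edge")
        mask = sphere_mask(config.shape, nuc.center_um, nuc.radius_um, config.voxel_z_nm, config.voxel_xy_nm)
        marker[mask] = nuc.marker_intensity
        measure[mask] = nuc.measure_intensity
        records.append(
            {
                "nucleus": i,
                "center_z_um": cz,
                "center_y_um": cy,
                "center_x_um": cx,
                "radius_um": nuc.radius_um,
                "voxel_count": int(mask.sum()),
                "true_corrected": nuc.measure_intensity - config.background,
            }
        )
    stack = np.stack([marker, measure])
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        stack = stack + rng.normal(0.0, config.noise_sd, size=stack.shape)
    np.clip(stack, 0.0, config.dynamic_range, out=stack)
    truth = pd.DataFrame(
        records,
        columns=[
            "nucleus", "center_z_um", "center_y_um", "center_x_um",
            "radius_um", "voxel_count", "true_corrected",
        ],
    )
    return stack, truth


def generate_counts(
    n_per_condition: Sequence[int],
    true_proportions: Sequence[float],
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Binomially sampled cell-count tables, one row per condition.

    Emulates scoring a few hundred cells per condition for a binary phenotype
    (e.g. large-budded cells with paired kinetochore foci).
    """
    if len(n_per_condition) != len(true_proportions):
        raise ValueError("n_per_condition and true_proportions must match in length")
    for p in true_proportions:
        if not 0.0 <= p <= 1.0:
            raise ValueError("proportions must lie in [0, 1]")
    if labels is None:
        labels = [f"condition-{i + 1}" for i in range(len(n_per_condition))]
    rng = np.random.default_rng(seed)
    pos = rng.binomial(np.asarray(n_per_condition), np.asarray(true_proportions))
    n = np.asarray(n_per_condition, dtype=int)
    return pd.DataFrame(
        {
            "condition": list(labels),
            "positive": pos.astype(int),
            "negative": (n - pos).astype(int),
            "total": n,
            "true_p": np.asarray(true_proportions, dtype=float),
        }
    )
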