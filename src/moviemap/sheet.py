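"""Synthetic two-hemisphere retinotopic cortical sheets and ground-truth maps.

The sheet is a rectangular grid per hemisphere rather than a triangulated
surface: every analysis in this package consumes sets of cortical units
(areas, traced lines), not geodesic geometry. One grid axis carries
eccentricity (0 = foveal to 1 = peripheral); the other carries area identity,
with dorsal areas stacked above V1 and ventral areas below, mirroring the
conventional flattened-occipital layout. Both hemispheres use the same layout
so homotopic units correspond index-for-index, and ground-truth maps are
exactly mirror symmetric (biological asymmetry is out of scope).

Two label schemes are available: the 8 retinotopically traced areas
(V1v/V1d ... hV4/V3A-B) used for the homotopy contrasts and map analyses,
and a broader 12-area "anatomical atlas" scheme (adding VO1/PHC1 ventrally
and LO1/hMT dorsally) for the stream-clustering analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .stats import ContractError

__all__ = [
    "AreaSpec",
    "CorticalSheet",
    "GroundTruthMaps",
    "GradientLine",
    "build_cortical_sheet",
    "generate_ground_truth_maps",
    "trace_gradient_lines",
    "jitter_maps",
]

HEMIS = ("left", "right")


@dataclass(frozen=True)
class AreaSpec:
    name: str
    stream: str  # "ventral" | "dorsal"
    level: int  # hierarchy level: V1=1, V2=2, V3=3, hV4/V3A-B=4, ...


# Row layout top-to-bottom on the flattened grid: dorsal periphery down to
# V1, then V1v down through the ventral hierarchy.
RETINOTOPIC_SCHEME = (
    AreaSpec("V3A-B", "dorsal", 4),
    AreaSpec("V3d", "dorsal", 3),
    AreaSpec("V2d", "dorsal", 2),
    AreaSpec("V1d", "dorsal", 1),
    AreaSpec("V1v", "ventral", 1),
    AreaSpec("V2v", "ventral", 2),
    AreaSpec("V3v", "ventral", 3),
    AreaSpec("hV4", "ventral", 4),
)

ANATOMICAL_SCHEME = (
    AreaSpec("hMT", "dorsal", 6),
    AreaSpec("LO1", "dorsal", 5),
    AreaSpec("V3A-B", "dorsal", 4),
    AreaSpec("V3d", "dorsal", 3),
    AreaSpec("V2d", "dorsal", 2),
    AreaSpec("V1d", "dorsal", 1),
    AreaSpec("V1v", "ventral", 1),
    AreaSpec("V2v", "ventral", 2),
    AreaSpec("V3v", "ventral", 3),
    AreaSpec("hV4", "ventral", 4),
    AreaSpec("VO1", "ventral", 5),
    AreaSpec("PHC1", "ventral", 6),
)

SCHEMES = {"retinotopic": RETINOTOPIC_SCHEME, "anatomical": ANATOMICAL_SCHEME}


@dataclass(frozen=True)
class CorticalSheet:
    """Labeled two-hemisphere grid of cortical units.

    Units are stored flattened, left hemisphere first then right, each
    hemisphere in C order over a (height, width) grid. ``area``/``stream``/
    ``level`` label each unit; ``eccentricity`` runs 0 (foveal) to 1
    (peripheral) along the width axis and ``polar_angle`` (radians) advances
    along the area axis so that meridian representations alternate at area
    boundaries.
    """

    height: int
    width: int
    scheme: str
    areas: tuple[AreaSpec, ...]
    area: np.ndarray  # (n_units,) str
    stream: np.ndarray  # (n_units,) str
    level: np.ndarray  # (n_units,) int
    hemi: np.ndarray  # (n_units,) str, "left"/"right"
    row: np.ndarray  # (n_units,) int
    col: np.ndarray  # (n_units,) int
    eccentricity: np.ndarray  # (n_units,) float in [0, 1]
    polar_angle: np.ndarray  # (n_units,) float, radians

    @property
    def n_units(self) -> int:
        return 2 * self.height * self.width

    @property
    def units_per_hemi(self) -> int:
        return self.height * self.width

    @property
    def rows_per_area(self) -> int:
        return self.height // len(self.areas)

    def hemi_slice(self, hemi: str) -> slice:
        n = self.units_per_hemi
        return slice(0, n) if hemi == "left" else slice(n, 2 * n)

    def to_grid(self, values: np.ndarray, hemi: str) -> np.ndarray:
        """Reshape a per-unit vector to the (height, width) grid of one hemisphere."""
        return np.asarray(values)[self.hemi_slice(hemi)].reshape(self.height, self.width)

    def from_grids(self, left: np.ndarray, right: np.ndarray) -> np.ndarray:
        return np.concatenate([np.ravel(left), np.ravel(right)])

    def homotopic_partner(self, index: int) -> int:
        """Index of the mirror unit in the opposite hemisphere."""
        n = self.units_per_hemi
        return index + n if index < n else index - n

    def area_indices(self, area: str, hemi: str) -> np.ndarray:
        return np.nonzero((self.area == area) & (self.hemi == hemi))[0]

    def area_names(self) -> list[str]:
        return [a.name for a in self.areas]

    def area_meta(self) -> dict[str, AreaSpec]:
        return {a.name: a for a in self.areas}

    def boundary_rows(self) -> np.ndarray:
        """Row indices r such that rows r-1 and r belong to different areas."""
        rpa = self.rows_per_area
        return np.arange(rpa, self.height, rpa)


def build_cortical_sheet(
    height: int = 24,
    width: int = 32,
    scheme: Literal["retinotopic", "anatomical"] = "retinotopic",
) -> CorticalSheet:
    """Deterministically lay out a mirrored two-hemisphere sheet.

    Eccentricity increases along the width axis; area identity changes along
    the height axis, dorsal areas above V1 and ventral below. The grid must
    be at least 16 x 16 and the height divisible by the number of areas.
    """
    if scheme not in SCHEMES:
        raise ContractError(f"unknown label scheme: {scheme!r}")
    areas = SCHEMES[scheme]
    if height < 16 or width < 16:
        raise ContractError("grid too small: need at least 16 x 16 per hemisphere")
    if height % len(areas) != 0:
        raise ContractError(
            f"height {height} not divisible by the {len(areas)} areas of scheme {scheme!r}"
        )
    rpa = height // len(areas)
    rows = np.repeat(np.arange(height), width)
    cols = np.tile(np.arange(width), height)
    area_of_row = np.repeat([a.name for a in areas], rpa)
    stream_of_row = np.repeat([a.stream for a in areas], rpa)
    level_of_row = np.repeat([a.level for a in areas], rpa)
    area = area_of_row[rows]
    stream = stream_of_row[rows]
    level = level_of_row[rows]
    ecc = cols / (width - 1)
    # continuous area coordinate: integer values at boundaries, so the
    # meridian representation cos(2 * polar_angle) flips sign at each boundary
    u = (rows + 0.5) / rpa
    polar = np.pi * u / 2.0
    n = height * width
    return CorticalSheet(
        height=height,
        width=width,
        scheme=scheme,
        areas=areas,
        area=np.concatenate([area, area]),
        stream=np.concatenate([stream, stream]),
        level=np.concatenate([level, level]).astype(int),
        hemi=np.array(["left"] * n + ["right"] * n),
        row=np.concatenate([rows, rows]).astype(int),
        col=np.concatenate([cols, cols]).astype(int),
        eccentricity=np.concatenate([ecc, ecc]),
        polar_angle=np.concatenate([polar, polar]),
    )


@dataclass(frozen=True)
class GroundTruthMaps:
    """Per-unit retinotopic contrast maps (signed, arbitrary contrast units).

    ``spatial_frequency``: positive = high spatial-frequency (foveal)
    preference, strictly decreasing from fovea to periphery within any area.
    ``meridian``: positive = horizontal-meridian preference, alternating sign
    across successive area boundaries.
    """

    spatial_frequency: np.ndarray
    meridian: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "spatial_frequency": self.spatial_frequency,
            "meridian": self.meridian,
        }


def generate_ground_truth_maps(
    sheet: CorticalSheet, smoothing_sigma: float = 0.5
) -> GroundTruthMaps:
    """Analytic ground-truth maps on a sheet, lightly smoothed.

    The spatial-frequency map is a strictly decreasing function of
    eccentricity; the meridian map is ``cos(2 * polar_angle)`` (zero exactly
    at area boundaries) with an amplitude envelope that decays toward the
    periphery. A small Gaussian kernel is applied per hemisphere; it
    preserves strict monotonicity along eccentricity and the boundary sign
    alternation because the kernel is symmetric and the construction is
    (locally) odd around each boundary.
    """
    sf = 1.0 - 2.0 * sheet.eccentricity
    # sin(2*polar) is zero exactly at area boundaries (integer area
    # coordinate), so its sign is constant within an area and flips at
    # every boundary a perpendicular line crosses
    merid = np.sin(2.0 * sheet.polar_angle) * (1.0 - 0.4 * sheet.eccentricity)
    if smoothing_sigma > 0:
        sf_s, merid_s = [], []
        for hemi in HEMIS:
            for src, dst in ((sf, sf_s), (merid, merid_s)):
                g = sheet.to_grid(src, hemi)
                dst.append(ndimage.gaussian_filter(g, smoothing_sigma, mode="nearest"))
        sf = np.concatenate([sf_s[0].ravel(), sf_s[1].ravel()])
        merid = np.concatenate([merid_s[0].ravel(), merid_s[1].ravel()])
    return GroundTruthMaps(spatial_frequency=sf, meridian=merid)


@dataclass(frozen=True)
class GradientLine:
    """Ordered path of unit indices traced relative to area boundaries.

    Parallel lines run foveal-to-peripheral within a single area; a
    perpendicular line crosses the area hierarchy of one stream starting
    from V1.
    """

    indices: np.ndarray
    orientation: str  # "parallel" | "perpendicular"
    hemi: str
    areas: tuple[str, ...]

    @property
    def length(self) -> int:
        return int(self.indices.size)

    def boundary_positions(self, sheet: CorticalSheet) -> np.ndarray:
        """Gap indices g where units g and g+1 belong to different areas."""
        labels = sheet.area[self.indices]
        return np.nonzero(labels[:-1] != labels[1:])[0]


def trace_gradient_lines(
    sheet: CorticalSheet, orientation: Literal["parallel", "perpendicular"]
) -> list[GradientLine]:
    """Deterministically trace gradient lines on a sheet.

    Parallel: one line per grid row (``rows_per_area`` per area per
    hemisphere), ordered fovea to periphery. Perpendicular: lines at fixed
    eccentricities spanning the full dorsal hierarchy (V1d outward) and the
    full ventral hierarchy (V1v outward), ordered from V1.
    """
    lines: list[GradientLine] = []
    h, w = sheet.height, sheet.width
    if orientation == "parallel":
        for hemi in HEMIS:
            offset = sheet.hemi_slice(hemi).start
            for r in range(h):
                idx = offset + r * w + np.arange(w)
                lines.append(
                    GradientLine(
                        indices=idx,
                        orientation="parallel",
                        hemi=hemi,
                        areas=(str(sheet.area[idx[0]]),),
                    )
                )
    elif orientation == "perpendicular":
        # rows of each stream, ordered from the V1 side outward
        row_stream = sheet.stream[: h * w : w]  # stream label of each row (left hemi)
        dorsal = np.nonzero(row_stream == "dorsal")[0][::-1]  # V1d upward
        ventral = np.nonzero(row_stream == "ventral")[0]  # V1v downward
        for hemi in HEMIS:
            offset = sheet.hemi_slice(hemi).start
            for rows in (dorsal, ventral):
                for c in (w // 3, (2 * w) // 3):
                    idx = offset + rows * w + c
                    seen: list[str] = []
                    for a in sheet.area[idx]:
                        if not seen or seen[-1] != a:
                            seen.append(str(a))
                    lines.append(
                        GradientLine(
                            indices=idx,
                            orientation="perpendicular",
                            hemi=hemi,
                            areas=tuple(seen),
                        )
                    )
    else:
        raise ContractError(f"unknown orientation: {orientation!r}")
    return lines


def jitter_maps(
    maps: GroundTruthMaps,
    sheet: CorticalSheet,
    jitter_scale: float,
    seed: int = 0,
) -> GroundTruthMaps:
    """Displace maps by a seeded smooth spatial warp of the given scale.

    Emulates between-participant anatomical misalignment: a smooth random
    displacement field with RMS amplitude ``jitter_scale`` (grid units) is
    drawn per hemisphere and the map values are resampled along it with
    linear interpolation. ``jitter_scale = 0`` is the identity.
    """
    if jitter_scale < 0:
        raise ContractError("jitter_scale must be >= 0")
    if jitter_scale == 0:
        return maps
    rng = np.random.default_rng(seed)
    h, w = sheet.height, sheet.width
    out = {}
    fields = maps.as_dict()
    warped = {k: [] for k in fields}
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    for hemi in HEMIS:
        # one warp per hemisphere, shared by both maps (they ride on the
        # same anatomy)
        disp = []
        for _ in range(2):
            d = ndimage.gaussian_filter(rng.standard_normal((h, w)), 3.0, mode="nearest")
            rms = float(np.sqrt(np.mean(d**2)))
            disp.append(d / rms * jitter_scale if rms > 0 else d)
        coords = np.stack([rr + disp[0], cc + disp[1]])
        for name, vals in fields.items():
            g = sheet.to_grid(vals, hemi)
            warped[name].append(
                ndimage.map_coordinates(g, coords, order=1, mode="nearest")
            )
    for name in fields:
        out[name] = np.concatenate([warped[name][0].ravel(), warped[name][1].ravel()])
    return GroundTruthMaps(
        spatial_frequency=out["spatial_frequency"], meridian=out["meridian"]
    )
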