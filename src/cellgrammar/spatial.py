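"""Initialize agents from annotated spatial-transcriptomics spot tables.

Visium-style capture arrays place spots on a triangular lattice with
~71 um pitch; each annotated spot carries (x, y, cell-type label). To
seed a simulation at cell scale, the spot cloud is recentered on the
mean of a selected subset H (by default the spots annotated
``other_cells`` in the main tissue mass) and rescaled by

    bias * cell_diameter / lattice_spacing

so the lattice pitch shrinks from the capture spacing d to roughly one
cell diameter df. The transform is a pure similarity (translation +
isotropic scale): pairwise distance ratios are preserved exactly.

A synthetic triangular-lattice fixture generator stands in for
restricted-access Visium data in tests and examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "TransformParams",
    "compute_center",
    "transform_spots",
    "spots_to_agents",
    "synth_visium_fixture",
    "read_spot_table",
    "DEFAULT_BIAS",
    "DEFAULT_CELL_DIAMETER",
    "DEFAULT_LATTICE_SPACING",
]

DEFAULT_BIAS = 0.97             # global spacing bias (dimensionless)
DEFAULT_CELL_DIAMETER = 16.825  # hypothesized average cell diameter df, um
DEFAULT_LATTICE_SPACING = 71.0  # Visium capture spacing d, um
OTHER_CELLS = "other_cells"


def _default_selector(annotations: pd.Series) -> pd.Series:
    return annotations == OTHER_CELLS


@dataclass
class TransformParams:
    """Constants of the center/scale spot transform."""

    bias: float = DEFAULT_BIAS
    cell_diameter: float = DEFAULT_CELL_DIAMETER
    lattice_spacing: float = DEFAULT_LATTICE_SPACING
    center_selector: Callable[[pd.Series], pd.Series] = field(
        default=_default_selector)

    def __post_init__(self) -> None:
        if self.bias <= 0 or self.cell_diameter <= 0 or self.lattice_spacing <= 0:
            raise ValueError("bias, cell_diameter and lattice_spacing must be positive")

    @property
    def scale(self) -> float:
        """The isotropic scale factor bias * df / d."""
        return self.bias * self.cell_diameter / self.lattice_spacing


def read_spot_table(path_or_buffer) -> pd.DataFrame:
    """Read a spot table CSV with columns x, y, annotation (um, um, token)."""
    df = pd.read_csv(path_or_buffer)
    missing = {"x", "y", "annotation"} - set(df.columns)
    if missing:
        raise ValueError(f"spot table missing columns {sorted(missing)}")
    if not np.isfinite(df[["x", "y"]].to_numpy()).all():
        raise ValueError("spot coordinates must be finite")
    return df


def compute_center(spots: pd.DataFrame,
                   selector: Optional[Callable] = None) -> np.ndarray:
    """Arithmetic mean (x, y) over the selected spot subset H."""
    selector = selector or _default_selector
    mask = np.asarray(selector(spots["annotation"]), dtype=bool)
    if mask.sum() == 0:
        raise ValueError("center selector matches no spots")
    sub = spots.loc[mask, ["x", "y"]].to_numpy(dtype=float)
    return sub.mean(axis=0)


def transform_spots(spots: pd.DataFrame,
                    params: TransformParams = TransformParams()) -> pd.DataFrame:
    """Recenter on the H-subset mean and rescale by bias * df / d.

    Returns a copy with transformed x, y; the center maps to (0, 0).
    """
    center = compute_center(spots, params.center_selector)
    out = spots.copy()
    xy = spots[["x", "y"]].to_numpy(dtype=float)
    out[["x", "y"]] = (xy - center) * params.scale
    return out


def spots_to_agents(transformed: pd.DataFrame, population,
                    type_map: Optional[dict] = None) -> list:
    """Create one agent per spot, typed by its annotation.

    ``type_map`` optionally renames annotations to cell-definition names
    (e.g. mapping ``other_cells`` to an inert bounding type). Unknown
    annotations raise.
    """
    type_map = type_map or {}
    agents = []
    for row in transformed.itertuples(index=False):
        name = type_map.get(row.annotation, row.annotation)
        if name not in population.type_index:
            raise KeyError(
                f"spot annotation {row.annotation!r} has no matching cell definition"
            )
        agents.append(population.add(name, (row.x, row.y)))
    return agents


def write_placement_csv(transformed: pd.DataFrame, path,
                        type_map: Optional[dict] = None) -> None:
    """Write the x,y,z,type placement CSV consumed by the engine (z = 0)."""
    type_map = type_map or {}
    out = pd.DataFrame({
        "x": transformed["x"],
        "y": transformed["y"],
        "z": 0.0,
        "type": [type_map.get(a, a) for a in transformed["annotation"]],
    })
    out.to_csv(path, index=False)


def synth_visium_fixture(rows: int = 20, cols: int = 20,
                         spacing: float = DEFAULT_LATTICE_SPACING,
                         annotation_scheme: str = "disk",
                         seed: int = 0,
                         tumor_fraction: float = 0.45,
                         fibroblast_fraction: float = 0.75) -> pd.DataFrame:
    """Generate a synthetic triangular-lattice spot table.

    Alternate rows are offset by spacing/2 with row pitch
    spacing*sqrt(3)/2, so every nearest-neighbor distance equals the
    spacing and interior spots have six equidistant neighbors — the
    Visium capture geometry.

    Annotation schemes (all centered on the lattice centroid):

    - ``disk``: central disk of epithelial_tumor spots inside
      ``tumor_fraction`` of the half-extent, a fibroblast annulus out to
      ``fibroblast_fraction``, ``other_cells`` beyond — a dense, uniform
      fibroblast rim around a single lesion.
    - ``patchy``: seeded random tumor foci with thin fibroblast collars
      in an ``other_cells`` field — scattered lesions with uneven
      fibroblast coverage.
    - ``uniform``: every spot ``other_cells``.
    """
    if rows < 1 or cols < 1 or spacing <= 0:
        raise ValueError("rows, cols and spacing must be positive")
    rng = np.random.default_rng(seed)
    ii, jj = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x = jj * spacing + (ii % 2) * (spacing / 2.0)
    y = ii * spacing * np.sqrt(3.0) / 2.0
    x, y = x.ravel(), y.ravel()
    center = np.array([x.mean(), y.mean()])
    r = np.hypot(x - center[0], y - center[1])
    half_extent = min(x.max() - x.min(), y.max() - y.min()) / 2.0

    annotation = np.full(x.shape, OTHER_CELLS, dtype=object)
    if annotation_scheme == "disk":
        annotation[r <= fibroblast_fraction * half_extent] = "fibroblast"
        annotation[r <= tumor_fraction * half_extent] = "epithelial_tumor"
    elif annotation_scheme == "patchy":
        n_foci = max(2, (rows * cols) // 100)
        foci = np.column_stack([
            rng.uniform(x.min(), x.max(), n_foci),
            rng.uniform(y.min(), y.max(), n_foci),
        ])
        for f in foci:
            d = np.hypot(x - f[0], y - f[1])
            annotation[d <= 2.5 * spacing] = "fibroblast"
        for f in foci:
            d = np.hypot(x - f[0], y - f[1])
            annotation[d <= 1.5 * spacing] = "epithelial_tumor"
    elif annotation_scheme != "uniform":
        raise ValueError(f"unknown annotation scheme {annotation_scheme!r}")

    return pd.DataFrame({"x": x, "y": y, "annotation": annotation})


def nearest_neighbor_distances(spots: pd.DataFrame) -> np.ndarray:
    """Each spot's Euclidean distance to its nearest neighbor."""
    from scipy.spatial import cKDTree

    xy = spots[["x", "y"]].to_numpy(dtype=float)
    if len(xy) < 2:
        raise ValueError("need at least two spots")
    d, _ = cKDTree(xy).query(xy, k=2)
    return d[:, 1]
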