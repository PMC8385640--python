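"""2D atrial tissue construction: fibrosis layouts, ACh patches, diffusion map.

A tissue is a square lattice of nodes (default 251 x 251 at dx = 0.02 cm,
i.e. 5 x 5 cm) where each node is a myocyte or a fibroblast.  Diffuse
fibrosis replaces nodes with fibroblasts either uniformly (Fu: i.i.d.
Bernoulli over the whole sheet) or non-uniformly (Fnu: Bernoulli confined to
circular patches).  Parasympathetic innervation sites are circular patches in
which the ACh concentration is raised to 0.1 uM, activating IKACh.

Node (i, j) sits at physical coordinates (i * dx, j * dx), origin at the
tissue corner; a node is inside a circle iff its Euclidean distance to the
center is <= r.  Diffusion coefficients live on lattice edges, so the stated
coupling reductions (transverse-to-longitudinal ratio, 4-fold reduction at
fibroblast coupling) are exact per edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MYOCYTE", "FIBROBLAST", "ACH_DOSE_UM",
    "Patch", "TissueModel",
    "uniform_fibrosis", "patchy_fibrosis", "place_ach_patches",
    "build_diffusion", "fnu_preset", "ach_geometry_spec",
]

MYOCYTE = 0
FIBROBLAST = 1
ACH_DOSE_UM = 0.1


@dataclass(frozen=True)
class Patch:
    """Circular patch: center (x, y) in cm, radius in cm, kind 'ACh'|'fibrosis'."""
    cx: float
    cy: float
    r: float
    kind: str = "ACh"


@dataclass
class TissueModel:
    nx: int = 251
    ny: int = 251
    dx: float = 0.02                    # cm
    cell_label: np.ndarray = None       # (ny, nx) uint8
    ach_map: np.ndarray = None          # (ny, nx) uM
    d_long: float = 0.003               # cm^2/ms
    anisotropy_ratio: float = 0.5
    fibro_coupling_factor: float = 0.25
    fiber_axis: str = "y"
    patch_registry: list = field(default_factory=list)

    def __post_init__(self):
        if self.dx <= 0 or self.d_long <= 0:
            raise ValueError("dx and d_long must be > 0")
        if self.fiber_axis not in ("x", "y"):
            raise ValueError("fiber_axis must be 'x' or 'y'")
        if self.cell_label is None:
            self.cell_label = np.zeros((self.ny, self.nx), dtype=np.uint8)
        if self.ach_map is None:
            self.ach_map = np.zeros((self.ny, self.nx), dtype=float)
        if self.cell_label.shape != (self.ny, self.nx):
            raise ValueError("cell_label shape mismatch")
        if self.ach_map.shape != (self.ny, self.nx):
            raise ValueError("ach_map shape mismatch")
        if np.any(self.ach_map < 0):
            raise ValueError("ach_map must be >= 0")

    @property
    def size_x(self) -> float:
        """Physical extent along x (cm)."""
        return (self.nx - 1) * self.dx

    @property
    def size_y(self) -> float:
        return (self.ny - 1) * self.dx

    def node_coords(self):
        """(x, y) meshgrid of node coordinates in cm, each (ny, nx)."""
        x = np.arange(self.nx) * self.dx
        y = np.arange(self.ny) * self.dx
        return np.meshgrid(x, y)

    def rasterize_registry(self, kind: str = "ACh", value: float = ACH_DOSE_UM):
        """Map rebuilt from the patch registry (ground truth check)."""
        out = np.zeros((self.ny, self.nx), dtype=float)
        xg, yg = self.node_coords()
        for p in self.patch_registry:
            if p.kind != kind:
                continue
            mask = (xg - p.cx) ** 2 + (yg - p.cy) ** 2 <= p.r ** 2
            out[mask] = value
        return out


def _circle_mask(nx, ny, dx, cx, cy, r):
    x = np.arange(nx) * dx
    y = np.arange(ny) * dx
    xg, yg = np.meshgrid(x, y)
    return (xg - cx) ** 2 + (yg - cy) ** 2 <= r ** 2


def uniform_fibrosis(nx: int, ny: int, density: float, seed: int) -> np.ndarray:
    """I.i.d. Bernoulli(density) fibroblast labels over the whole sheet."""
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lab = (rng.random((ny, nx)) < density).astype(np.uint8)
    return lab


def patchy_fibrosis(nx: int, ny: int, patches, density: float, seed: int,
                    dx: float = 0.02) -> np.ndarray:
    """Bernoulli(density) fibroblast labels inside a union of circles only."""
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0, 1]")
    patches = list(patches)
    if not patches:
        raise ValueError("at least one fibrotic patch is required")
    rng = np.random.default_rng(seed)
    inside = np.zeros((ny, nx), dtype=bool)
    for p in patches:
        inside |= _circle_mask(nx, ny, dx, p.cx, p.cy, p.r)
    lab = np.zeros((ny, nx), dtype=np.uint8)
    lab[inside] = (rng.random(int(inside.sum())) < density).astype(np.uint8)
    return lab


def place_ach_patches(nx: int, ny: int, radii, n_per_radius, seed: int,
                      min_separation: float = 0.1, dx: float = 0.02,
                      dose_uM: float = ACH_DOSE_UM, region=None,
                      max_tries: int = 2000):
    """Place non-overlapping ACh circles at uniform random centers.

    ``radii`` lists circle radii in cm and ``n_per_radius`` how many circles
    of each radius to draw.  Circles must lie fully inside ``region``
    (x0, x1, y0, y1) in cm — by default the whole sheet — and keep at least
    ``min_separation`` cm between circle rims.  Raises if a circle cannot be
    placed after ``max_tries`` rejections.

    Returns ``(ach_map, registry)``; the registry holds the exact geometry
    used as detection ground truth.
    """
    radii = list(radii)
    if np.isscalar(n_per_radius):
        n_per_radius = [int(n_per_radius)] * len(radii)
    if any(r <= 0 for r in radii):
        raise ValueError("radii must be > 0")
    if region is None:
        region = (0.0, (nx - 1) * dx, 0.0, (ny - 1) * dx)
    x0, x1, y0, y1 = region
    rng = np.random.default_rng(seed)
    # place the largest circles first: tight regions stay feasible; if an
    # early circle blocks the rest, restart the whole layout
    order = sorted([(r, k) for k, r in enumerate(radii)], reverse=True)
    placed: list[Patch] = []
    for restart in range(50):
        placed = []
        failed = False
        for r, k in order:
            for _ in range(n_per_radius[k]):
                for attempt in range(max_tries):
                    cx = rng.uniform(x0 + r, x1 - r)
                    cy = rng.uniform(y0 + r, y1 - r)
                    ok = all((cx - p.cx) ** 2 + (cy - p.cy) ** 2
                             >= (r + p.r + min_separation) ** 2 for p in placed)
                    if ok:
                        placed.append(Patch(cx, cy, r, "ACh"))
                        break
                else:
                    failed = True
                    break
            if failed:
                break
        if not failed:
            break
    else:
        raise RuntimeError(
            f"could not place ACh circles {radii} x {n_per_radius} in region "
            f"{region} after 50 layout restarts")
    ach = np.zeros((ny, nx), dtype=float)
    for p in placed:
        ach[_circle_mask(nx, ny, dx, p.cx, p.cy, p.r)] = dose_uM
    return ach, placed


def build_diffusion(cell_label: np.ndarray, d_long: float,
                    anisotropy_ratio: float = 0.5,
                    fibro_coupling_factor: float = 0.25,
                    fiber_axis: str = "y"):
    """Edge-wise diffusion map ``(Dx, Dy)``.

    ``Dx[j, i]`` couples nodes (i, j)-(i+1, j); ``Dy[j, i]`` couples
    (i, j)-(i, j+1).  Edges parallel to the fiber axis carry ``d_long``,
    perpendicular edges ``anisotropy_ratio * d_long``; any edge touching a
    fibroblast is further multiplied by ``fibro_coupling_factor``.
    """
    lab = np.asarray(cell_label)
    ny, nx = lab.shape
    d_trans = anisotropy_ratio * d_long
    dx_base = d_long if fiber_axis == "x" else d_trans
    dy_base = d_long if fiber_axis == "y" else d_trans
    Dx = np.full((ny, nx - 1), dx_base, dtype=float)
    Dy = np.full((ny - 1, nx), dy_base, dtype=float)
    fib = lab == FIBROBLAST
    Dx[fib[:, :-1] | fib[:, 1:]] *= fibro_coupling_factor
    Dy[fib[:-1, :] | fib[1:, :]] *= fibro_coupling_factor
    return Dx, Dy


# ---------------------------------------------------------------------------
# Named presets
# ---------------------------------------------------------------------------
# Non-uniform fibrosis layouts.  The published layouts exist only as
# drawings; these presets are qualitative equivalents (Fnu1: several
# mid-sized patches scattered over the sheet, Fnu2: fewer, larger patches).
# Centers and radii are fractions of the tissue side length so the layouts
# scale with the domain.
_FNU_PRESETS = {
    "Fnu1": [(0.24, 0.26, 0.17), (0.72, 0.30, 0.16),
             (0.30, 0.72, 0.16), (0.76, 0.74, 0.17)],
    "Fnu2": [(0.34, 0.38, 0.27), (0.72, 0.70, 0.23)],
}


def fnu_preset(name: str, size_cm: float = 5.0):
    """Fibrotic-patch layout 'Fnu1' or 'Fnu2' scaled to a tissue side length."""
    if name not in _FNU_PRESETS:
        raise ValueError(f"unknown fibrosis preset {name!r}")
    return [Patch(cx * size_cm, cy * size_cm, r * size_cm, "fibrosis")
            for cx, cy, r in _FNU_PRESETS[name]]


# ACh geometries: circle radii in cm and counts, chosen to occupy a roughly
# comparable fraction of the centrally mapped region for every geometry.
_ACH_GEOMETRIES = {
    "r032": ([0.32], [6]),
    "r050": ([0.5], [3]),
    "r076": ([0.76], [1]),
    "mixed_050_024": ([0.5, 0.24], [2, 3]),
}


def ach_geometry_spec(name: str):
    """(radii, counts) of the named ACh-circle geometry."""
    if name not in _ACH_GEOMETRIES:
        raise ValueError(f"unknown ACh geometry {name!r}")
    return _ACH_GEOMETRIES[name]
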