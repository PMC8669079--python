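"""Synthetic infarct tissue geometry.

Builds 2-D node-centred lattices standing in for MRI-derived infarcted left
ventricular wall: a myocardial sheet containing a non-conducting scar band
pierced by a conducting critical-isthmus channel ("CI"), a border-zone rim,
rule-based fibre orientation, and two extracellular bath bands (a "cavity"
side and an "exterior" side).  Electrode regions (five-square bipolar array,
transmural pair, pacing block) are placed into the bath / tissue on top of
the lattice.

Coordinates are node-centred, 0-based, lengths in cm.  The lattice is indexed
``[ix, iy]``; x spans the sheet laterally, y runs transmurally:
cavity bath | tissue (with the scar band across x) | exterior bath.
Fibre angle is measured from the +x axis in radians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "Label",
    "ScarSpec",
    "FiberRule",
    "TissueGrid",
    "ElectrodeSet",
    "build_slab_geometry",
    "place_bipolar_array",
    "place_transmural_pair",
    "place_atp_site",
    "place_edge_pacing_site",
    "sensitivity_variants",
]

_EPS = 1e-9


class Label(IntEnum):
    """Per-node tissue class."""

    BATH = 0
    HEALTHY = 1
    BZ = 2
    SCAR = 3
    ELECTRODE_CORE = 4


APPLIED = "APPLIED"
GROUND = "GROUND"

TISSUE_LABELS = (Label.HEALTHY, Label.BZ, Label.SCAR)
ACTIVE_LABELS = (Label.HEALTHY, Label.BZ)


@dataclass(frozen=True)
class ScarSpec:
    """Scar-with-isthmus description.

    The scar is a band across the full lateral (x) extent of the tissue,
    ``band_thickness`` cm in the transmural (y) direction, pierced by a single
    conducting channel of width ``isthmus_width``.  A border-zone rim of
    thickness ``bz_rim`` surrounds the scar and lines the channel walls.
    ``ci_bz_fraction`` converts the given fraction of the channel interior
    (taken from the +x wall) to border zone, producing the heterogeneous
    channel composition (healthy lane / border-zone lane) that real isthmuses
    exhibit.  ``islet_width`` > 0 inserts a thin non-conducting fibrotic
    strand along the lane boundary (ending ``islet_margin`` cm short of the
    band edges, so the channel remains a single connected region); the two
    lanes then rejoin at both mouths, forming the anatomical circuit around
    which isthmus-dependent reentry circulates.
    """

    band_thickness: float = 2.0
    band_center: float | None = None  # y centre within tissue; default mid-wall
    isthmus_width: float = 0.4
    ci_center: float | None = None  # x centre; default mid-sheet
    bz_rim: float = 0.05
    ci_bz_fraction: float = 0.375
    islet_width: float = 0.075  # thin fibrotic strand inside the channel (0 = none)
    islet_margin: float = 0.12  # gap between strand ends and the band edges


@dataclass(frozen=True)
class FiberRule:
    """Rule-based fibre orientation.

    ``angle`` is the base helix angle (radians from +x); ``transmural_rotation``
    linearly rotates fibres across the wall (cavity face gets ``-rotation/2``,
    exterior face ``+rotation/2``).
    """

    angle: float = 0.0
    transmural_rotation: float = 0.0


@dataclass
class TissueGrid:
    """Labelled lattice with fibre angles and named node-sets.

    ``labels``/``fiber_angle`` have shape ``(nx, ny)``; named regions are flat
    node indices (``np.ravel_multi_index`` order).  ``fiber_angle`` is NaN on
    non-tissue nodes.
    """

    labels: np.ndarray
    spacing: float
    fiber_angle: np.ndarray
    regions: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def nx(self) -> int:
        return self.labels.shape[0]

    @property
    def ny(self) -> int:
        return self.labels.shape[1]

    def coords(self, flat_idx: np.ndarray) -> np.ndarray:
        """(n, 2) array of node coordinates in cm for flat indices."""
        ix, iy = np.unravel_index(np.asarray(flat_idx), self.shape)
        return np.stack([ix, iy], axis=-1) * self.spacing

    def flat(self, mask: np.ndarray) -> np.ndarray:
        return np.flatnonzero(mask.ravel())

    def mask_of(self, *labels: Label) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        for lb in labels:
            m |= self.labels == lb
        return m

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.mask_of(*TISSUE_LABELS)

    @property
    def active_mask(self) -> np.ndarray:
        return self.mask_of(*ACTIVE_LABELS)

    @property
    def bath_mask(self) -> np.ndarray:
        return self.labels == Label.BATH

    def region_mask(self, name: str) -> np.ndarray:
        m = np.zeros(self.nx * self.ny, dtype=bool)
        m[self.regions[name]] = True
        return m.reshape(self.shape)

    def clone(self) -> "TissueGrid":
        """Deep copy (labels, fibre angles, regions).  Electrode placement
        relabels bath nodes, so each electrode configuration gets its own
        clone; tissue node indices are identical across clones, which lets a
        checkpointed state be reused under any electrode layout."""
        return TissueGrid(
            self.labels.copy(),
            self.spacing,
            self.fiber_angle.copy(),
            {k: v.copy() for k, v in self.regions.items()},
            dict(self.meta),
        )

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        """Raise ValueError if any lattice invariant is violated."""
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.fiber_angle.shape != self.labels.shape:
            raise ValueError("fiber_angle/labels shape mismatch")
        tis = self.tissue_mask
        if np.isnan(self.fiber_angle[tis]).any():
            raise ValueError("fiber_angle undefined on some tissue nodes")
        if not np.isnan(self.fiber_angle[~tis]).all():
            raise ValueError("fiber_angle defined off tissue")
        n_comp = ndimage.label(tis, structure=np.ones((3, 3)))[1]
        if n_comp > 1 and not self.meta.get("allow_islands", False):
            raise ValueError(f"tissue has {n_comp} disconnected components")
        n = self.nx * self.ny
        for name, idx in self.regions.items():
            if len(idx) and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(f"region {name!r} has out-of-range node indices")
        if "CI" in self.regions and len(self.regions["CI"]):
            ci = self.region_mask("CI")
            if not np.isin(self.labels[ci], ACTIVE_LABELS).all():
                raise ValueError("CI nodes must be HEALTHY or BZ")
            if not ci_disconnects(self):
                raise ValueError("removing CI does not disconnect the scar flanks")


def ci_disconnects(grid: TissueGrid) -> bool:
    """Flood-fill check: removing the CI node-set must disconnect the two
    excitable regions flanking the scar band (flood fill runs over
    HEALTHY/BZ nodes; scar does not conduct activation)."""
    tis = grid.active_mask & ~grid.region_mask("CI")
    lab, _ = ndimage.label(tis, structure=np.ones((3, 3)))
    lo = grid.regions.get("flank_cavity")
    hi = grid.regions.get("flank_exterior")
    if lo is None or hi is None or not len(lo) or not len(hi):
        return False
    lab_flat = lab.ravel()
    lo_ids = set(np.unique(lab_flat[lo])) - {0}
    hi_ids = set(np.unique(lab_flat[hi])) - {0}
    return not (lo_ids & hi_ids)


@dataclass
class ElectrodeSet:
    """Node-sets with polarity, standing in for physical electrode surfaces.

    ``members`` maps flat node indices to a polarity (APPLIED or GROUND).
    For shock configurations all member nodes lie in the bath (on electrode
    faces); electrode interiors are labelled ELECTRODE_CORE in the grid and
    excluded from bath conduction.  For the ``atp_block`` tag the node-set is
    the stimulated tissue block instead.
    """

    members: list[tuple[np.ndarray, str]]
    geometry_tag: str
    clearance: float | None = None
    meta: dict = field(default_factory=dict)

    def nodes(self, polarity: str) -> np.ndarray:
        sets = [idx for idx, pol in self.members if pol == polarity]
        return np.unique(np.concatenate(sets)) if sets else np.empty(0, dtype=np.intp)

    @property
    def applied_nodes(self) -> np.ndarray:
        return self.nodes(APPLIED)

    @property
    def ground_nodes(self) -> np.ndarray:
        return self.nodes(GROUND)

    @property
    def all_nodes(self) -> np.ndarray:
        return np.unique(np.concatenate([idx for idx, _ in self.members]))

    def validate(self, grid: TissueGrid) -> None:
        if self.geometry_tag != "atp_block":
            pols = {pol for _, pol in self.members}
            if APPLIED not in pols or GROUND not in pols:
                raise ValueError("need at least one APPLIED and one GROUND node-set")
            on_tissue = grid.tissue_mask.ravel()[self.all_nodes]
            if on_tissue.any():
                raise ValueError("electrode nodes must lie in bath, not tissue")
        n_cubes = self.meta.get("n_cubes")
        if self.geometry_tag == "bipolar_array" and n_cubes != 5:
            raise ValueError("bipolar_array must have exactly 5 cubes")
        if self.geometry_tag == "transmural_pair" and n_cubes != 2:
            raise ValueError("transmural_pair must have exactly 2 cubes")


# ---------------------------------------------------------------------------
# construction helpers


def _n_nodes(length: float, dx: float) -> int:
    return int(round(length / dx)) + 1


def _index_range(lo: float, hi: float, dx: float, n: int) -> tuple[int, int]:
    """Inclusive node-index range covering [lo, hi] (clipped to the lattice)."""
    i0 = max(0, int(np.ceil(lo / dx - _EPS)))
    i1 = min(n - 1, int(np.floor(hi / dx + _EPS)))
    return i0, i1


def build_slab_geometry(
    tissue_size: tuple[float, float] = (4.0, 3.2),
    spacing: float = 0.025,
    scar: ScarSpec | None = ScarSpec(),
    bath: tuple[float, float] = (1.2, 1.2),
    fiber: FiberRule = FiberRule(),
) -> TissueGrid:
    """Build the synthetic scar-with-isthmus slab.

    Parameters
    ----------
    tissue_size
        Lateral x transmural tissue extent in cm.
    spacing
        Node pitch in cm (must be <= 0.05).
    scar
        Scar band description, or None for an all-healthy sheet.
    bath
        Thickness of the cavity-side and exterior-side bath bands in cm.
    fiber
        Rule-based fibre orientation.

    Returns a validated :class:`TissueGrid` whose ``"CI"`` node-set is the
    single conducting channel through the scar; flood-fill from one flank
    reaches the other only through it.
    """
    W, H = tissue_size
    if spacing > 0.05 + _EPS:
        raise ValueError("spacing must be <= 0.05 cm to resolve the channel")
    if scar is not None and W < 10 * scar.isthmus_width - _EPS:
        raise ValueError("tissue extent must be >= 10x the isthmus width")
    b_cav, b_ext = bath
    dx = spacing
    nx = _n_nodes(W, dx)
    ny = _n_nodes(b_cav + H + b_ext, dx)
    labels = np.zeros((nx, ny), dtype=np.uint8)

    y = np.arange(ny) * dx
    x = np.arange(nx) * dx
    y0_t, y1_t = b_cav, b_cav + H
    tis_cols = (y >= y0_t - _EPS) & (y <= y1_t + _EPS)
    labels[:, tis_cols] = Label.HEALTHY

    regions: dict[str, np.ndarray] = {}
    shape = (nx, ny)

    def flat_of(maskx, masky):
        m = np.zeros(shape, dtype=bool)
        m[np.ix_(maskx, masky)] = True
        return np.flatnonzero(m.ravel())

    if scar is not None:
        if scar.isthmus_width / dx < 3 - _EPS:
            raise ValueError(
                f"isthmus width {scar.isthmus_width} cm is under 3 nodes at "
                f"{dx} cm pitch; channel unresolvable"
            )
        yc = y0_t + (scar.band_center if scar.band_center is not None else H / 2)
        xc = scar.ci_center if scar.ci_center is not None else W / 2
        yb0, yb1 = yc - scar.band_thickness / 2, yc + scar.band_thickness / 2
        xi0, xi1 = xc - scar.isthmus_width / 2, xc + scar.isthmus_width / 2
        band_y = (y >= yb0 - _EPS) & (y <= yb1 + _EPS) & tis_cols
        chan_x = (x >= xi0 - _EPS) & (x <= xi1 + _EPS)
        scar_m = np.zeros(shape, dtype=bool)
        scar_m[np.ix_(~chan_x, band_y)] = True
        labels[scar_m] = Label.SCAR

        # border-zone rim: tissue within bz_rim of scar (surrounds the band and
        # lines the channel walls), plus the +x-side fraction of the channel.
        if scar.bz_rim > 0:
            dist = ndimage.distance_transform_edt(~scar_m, sampling=dx)
            rim = (dist <= scar.bz_rim + _EPS) & (labels == Label.HEALTHY)
            labels[rim] = Label.BZ
        xbz = xi1 - scar.ci_bz_fraction * scar.isthmus_width
        if scar.ci_bz_fraction > 0:
            bz_lane = np.zeros(shape, dtype=bool)
            bz_lane[np.ix_((x >= xbz - _EPS) & chan_x, band_y)] = True
            labels[bz_lane & (labels == Label.HEALTHY)] = Label.BZ
        if scar.islet_width > 0:
            # fibrotic strand along the lane boundary; ends short of the band
            # edges so the channel stays singly connected through both mouths
            is_x = (x >= xbz - scar.islet_width / 2 - _EPS) & (
                x <= xbz + scar.islet_width / 2 + _EPS
            )
            is_y = (y >= yb0 + scar.islet_margin - _EPS) & (
                y <= yb1 - scar.islet_margin + _EPS
            )
            islet = np.zeros(shape, dtype=bool)
            islet[np.ix_(is_x & chan_x, is_y & band_y)] = True
            labels[islet] = Label.SCAR
            scar_m |= islet

        ci = np.zeros(shape, dtype=bool)
        ci[np.ix_(chan_x, band_y)] = True
        ci &= np.isin(labels, ACTIVE_LABELS)
        regions["CI"] = np.flatnonzero(ci.ravel())
        regions["scar"] = np.flatnonzero(scar_m.ravel())
        if scar.islet_width > 0:
            fast = ci.copy()
            fast[x >= xbz - scar.islet_width / 2 - _EPS, :] = False
            slow = ci.copy()
            slow[x <= xbz + scar.islet_width / 2 + _EPS, :] = False
            regions["ci_fast_lane"] = np.flatnonzero(fast.ravel())
            regions["ci_slow_lane"] = np.flatnonzero(slow.ravel())
        regions["flank_cavity"] = flat_of(
            np.ones(nx, dtype=bool), tis_cols & (y < yb0 - _EPS)
        )
        regions["flank_exterior"] = flat_of(
            np.ones(nx, dtype=bool), tis_cols & (y > yb1 + _EPS)
        )
        # channel mouths: first active row just outside the band, over the channel
        for name, ymask in (
            ("ci_mouth_cavity", (y < yb0 - _EPS) & (y >= yb0 - 3 * dx) & tis_cols),
            ("ci_mouth_exterior", (y > yb1 + _EPS) & (y <= yb1 + 3 * dx) & tis_cols),
        ):
            regions[name] = flat_of(chan_x, ymask)
        grid_meta = {
            "scar": scar,
            "ci_bbox": (xi0, yb0, xi1, yb1),
            "ci_centroid": (xc, (yb0 + yb1) / 2),
        }
    else:
        grid_meta = {"scar": None}

    regions["cavity_bath"] = flat_of(np.ones(nx, dtype=bool), y < y0_t - _EPS)
    regions["exterior_bath"] = flat_of(np.ones(nx, dtype=bool), y > y1_t + _EPS)

    fiber_angle = np.full(shape, np.nan)
    tis = np.isin(labels, TISSUE_LABELS)
    if fiber.transmural_rotation:
        frac = np.clip((y - y0_t) / max(H, _EPS), 0.0, 1.0)
        ang = fiber.angle + fiber.transmural_rotation * (frac - 0.5)
        fiber_angle[tis] = np.broadcast_to(ang, shape)[tis]
    else:
        fiber_angle[tis] = fiber.angle

    grid_meta.update(
        {
            "tissue_size": (W, H),
            "bath": (b_cav, b_ext),
            "tissue_y": (y0_t, y1_t),
            "fiber": fiber,
        }
    )
    grid = TissueGrid(labels, dx, fiber_angle, regions, grid_meta)
    grid.validate()
    return grid


def _square_nodes(grid: TissueGrid, x0, x1, y0, y1):
    """Index ranges and masks for an axis-aligned square [x0,x1]x[y0,y1]."""
    i0, i1 = _index_range(x0, x1, grid.spacing, grid.nx)
    j0, j1 = _index_range(y0, y1, grid.spacing, grid.ny)
    if i1 < i0 or j1 < j0:
        raise ValueError("electrode square does not contain any lattice node")
    return i0, i1, j0, j1


def _flat_box(grid, i0, i1, j0, j1):
    ii, jj = np.meshgrid(np.arange(i0, i1 + 1), np.arange(j0, j1 + 1), indexing="ij")
    return np.ravel_multi_index((ii.ravel(), jj.ravel()), grid.shape)


def place_bipolar_array(
    grid: TissueGrid,
    centre: tuple[float, float] | None = None,
    cube_edge: float = 0.4,
    spacing: float = 0.4,
) -> ElectrodeSet:
    """Place the five-square bipolar array in the cavity-side bath.

    Squares (2-D sections of the cubes) are aligned along x with the given
    edge length and gap.  For each square the face nearest the CI becomes a
    GROUND node-set and the opposite face an APPLIED node-set; interiors are
    labelled ELECTRODE_CORE and excluded from bath conduction.
    """
    ci_cx, ci_cy = grid.meta.get("ci_centroid", (None, None))
    if centre is None:
        if ci_cx is None:
            raise ValueError("no CI in grid; give an explicit centre")
        b_cav = grid.meta["bath"][0]
        centre = (ci_cx, b_cav / 2)  # mid-cavity, aligned with the channel
    cx, cy = centre
    pitch = cube_edge + spacing
    members: list[tuple[np.ndarray, str]] = []
    core_flat: list[np.ndarray] = []
    tis = grid.tissue_mask.ravel()
    for k in range(-2, 3):
        x0 = cx + k * pitch - cube_edge / 2
        x1 = x0 + cube_edge
        y0, y1 = cy - cube_edge / 2, cy + cube_edge / 2
        i0, i1, j0, j1 = _square_nodes(grid, x0, x1, y0, y1)
        box = _flat_box(grid, i0, i1, j0, j1)
        if tis[box].any():
            raise ValueError(f"bipolar cube {k + 2} overlaps tissue")
        if (grid.labels.ravel()[box] != Label.BATH).any():
            raise ValueError(f"bipolar cube {k + 2} not fully inside bath")
        # orientation: face nearest the CI centroid is GROUND
        if ci_cx is None:
            raise ValueError("grid has no CI; cannot orient array faces")
        ccx, ccy = (i0 + i1) / 2 * grid.spacing, (j0 + j1) / 2 * grid.spacing
        d = (ci_cx - ccx, ci_cy - ccy)
        if abs(d[0]) >= abs(d[1]):  # faces perpendicular to x
            near, far = (i0, i1) if d[0] < 0 else (i1, i0)
            ground = _flat_box(grid, near, near, j0, j1)
            applied = _flat_box(grid, far, far, j0, j1)
            core = _flat_box(grid, min(near, far) + 1, max(near, far) - 1, j0, j1)
        else:  # faces perpendicular to y
            near, far = (j0, j1) if d[1] < 0 else (j1, j0)
            ground = _flat_box(grid, i0, i1, near, near)
            applied = _flat_box(grid, i0, i1, far, far)
            core = _flat_box(grid, i0, i1, min(near, far) + 1, max(near, far) - 1)
        members.append((ground, GROUND))
        members.append((applied, APPLIED))
        core_flat.append(core)
    core_all = np.concatenate(core_flat)
    lab = grid.labels.ravel()
    lab[core_all] = Label.ELECTRODE_CORE
    grid.labels = lab.reshape(grid.shape)
    es = ElectrodeSet(
        members, "bipolar_array", meta={"n_cubes": 5, "cube_edge": cube_edge}
    )
    es.validate(grid)
    return es


def place_transmural_pair(
    grid: TissueGrid,
    ci_centre: tuple[float, float] | None = None,
    cube_edge: float = 0.5,
    clearance: float = 1.0,
) -> ElectrodeSet:
    """Place the transmural pair: APPLIED square in the cavity-side bath,
    GROUND square in the exterior-side bath, both centred on the CI normal,
    each at (approximately) the requested minimum distance from tissue."""
    ci_cx, _ = grid.meta.get("ci_centroid", (None, None))
    if ci_centre is not None:
        ci_cx = ci_centre[0]
    if ci_cx is None:
        raise ValueError("no CI in grid; give an explicit ci_centre")
    b_cav, b_ext = grid.meta["bath"]
    y0_t, y1_t = grid.meta["tissue_y"]
    for side, depth in (("cavity", b_cav), ("exterior", b_ext)):
        need = clearance + cube_edge
        if depth + _EPS < need:
            raise ValueError(
                f"{side}-side bath too thin for clearance {clearance} cm: "
                f"need {need:.3f} cm, have {depth:.3f} cm "
                f"(deficit {need - depth:.3f} cm)"
            )
    dx = grid.spacing
    members = []
    cores = []
    for pol, (ylo, yhi) in (
        (APPLIED, (y0_t - clearance - cube_edge, y0_t - clearance)),
        (GROUND, (y1_t + clearance, y1_t + clearance + cube_edge)),
    ):
        i0, i1, j0, j1 = _square_nodes(
            grid, ci_cx - cube_edge / 2, ci_cx + cube_edge / 2, ylo, yhi
        )
        box = _flat_box(grid, i0, i1, j0, j1)
        if (grid.labels.ravel()[box] != Label.BATH).any():
            raise ValueError("transmural electrode overlaps non-bath nodes")
        boundary = np.setdiff1d(box, _flat_box(grid, i0 + 1, i1 - 1, j0 + 1, j1 - 1))
        members.append((boundary, pol))
        if i1 - i0 > 1 and j1 - j0 > 1:
            cores.append(_flat_box(grid, i0 + 1, i1 - 1, j0 + 1, j1 - 1))
    if cores:
        lab = grid.labels.ravel()
        lab[np.concatenate(cores)] = Label.ELECTRODE_CORE
        grid.labels = lab.reshape(grid.shape)
    es = ElectrodeSet(
        members,
        "transmural_pair",
        clearance=clearance,
        meta={"n_cubes": 2, "cube_edge": cube_edge, "ci_x": ci_cx},
    )
    es.validate(grid)
    measured = electrode_tissue_distance(grid, es)
    if abs(measured - clearance) > 0.1 * clearance + dx:
        raise ValueError(
            f"measured tissue clearance {measured:.3f} cm outside 10% of "
            f"requested {clearance:.3f} cm"
        )
    es.meta["measured_clearance"] = measured
    return es


def electrode_tissue_distance(grid: TissueGrid, es: ElectrodeSet) -> float:
    """Minimum node distance (cm) between any electrode node and tissue."""
    dist = ndimage.distance_transform_edt(~grid.tissue_mask, sampling=grid.spacing)
    return float(dist.ravel()[es.all_nodes].min())


def place_atp_site(
    grid: TissueGrid,
    location: tuple[float, float] | None = None,
    edge: float = 0.5,
) -> ElectrodeSet:
    """Define the pacing block: excitable tissue nodes inside a square of the
    given edge, mimicking a lead tip remote from the CI.  Only HEALTHY/BZ
    nodes are retained; the intersected area is stored for current scaling."""
    if location is None:
        # remote site on the cavity-side flank, off the channel axis
        W, H = grid.meta["tissue_size"]
        y0_t, _ = grid.meta["tissue_y"]
        location = (W / 4, y0_t + 0.3)
    cx, cy = location
    i0, i1, j0, j1 = _square_nodes(
        grid, cx - edge / 2, cx + edge / 2, cy - edge / 2, cy + edge / 2
    )
    box = _flat_box(grid, i0, i1, j0, j1)
    active = box[np.isin(grid.labels.ravel()[box], ACTIVE_LABELS)]
    if not len(active):
        raise ValueError(
            "pacing block contains no excitable tissue (entirely bath or scar)"
        )
    area = len(active) * grid.spacing**2
    grid.regions["atp_site"] = active
    return ElectrodeSet(
        [(active, APPLIED)],
        "atp_block",
        meta={"edge": edge, "area_cm2": area, "n_nodes": len(active)},
    )


def place_edge_pacing_site(
    grid: TissueGrid, side: str = "cavity", depth: float = 0.1
) -> ElectrodeSet:
    """Stimulus strip along one tissue face (drive-train pacing electrode)."""
    y0_t, y1_t = grid.meta["tissue_y"]
    y = np.arange(grid.ny) * grid.spacing
    if side == "cavity":
        ymask = (y >= y0_t - _EPS) & (y <= y0_t + depth + _EPS)
    else:
        ymask = (y >= y1_t - depth - _EPS) & (y <= y1_t + _EPS)
    m = np.zeros(grid.shape, dtype=bool)
    m[:, ymask] = True
    m &= grid.active_mask
    idx = np.flatnonzero(m.ravel())
    if not len(idx):
        raise ValueError("no excitable tissue on the requested face")
    grid.regions[f"pace_{side}"] = idx
    return ElectrodeSet(
        [(idx, APPLIED)], "atp_block", meta={"edge": depth, "n_nodes": len(idx)}
    )


def sensitivity_variants(grid: TissueGrid, base: ElectrodeSet) -> list[ElectrodeSet]:
    """Placement/geometry variants of the transmural pair.

    Returns up to 7 variants: five ground-electrode translations spanning the
    CI length (the middle one identical to ``base``), one with both electrodes
    prolonged by 2.0 cm along the lateral axis (centroids still aligned with
    the CI centre), and one with the APPLIED electrode moved to the
    exterior-side bath (polarity-swapped mirror) so the centroid-centroid
    segment still crosses the CI.  Variants that would leave the bath are
    dropped with a logged warning.
    """
    if base.geometry_tag != "transmural_pair":
        raise ValueError("base must be a transmural pair")
    edge = base.meta["cube_edge"]
    clearance = base.clearance
    ci_x = base.meta["ci_x"]
    xi0, yb0, xi1, yb1 = grid.meta["ci_bbox"]
    ci_len = yb1 - yb0
    W = grid.meta["tissue_size"][0]
    y0_t, y1_t = grid.meta["tissue_y"]
    out: list[ElectrodeSet] = []

    applied_members = [(idx, pol) for idx, pol in base.members if pol == APPLIED]

    offsets = np.linspace(-ci_len / 2, ci_len / 2, 5)
    for k, off in enumerate(offsets):
        if abs(off) < _EPS:
            v = replace(base, meta={**base.meta, "variant": "ground_shift_0"})
            out.append(v)
            continue
        gx = ci_x + off
        if gx - edge / 2 < -_EPS or gx + edge / 2 > W + _EPS:
            log.warning(
                "dropping ground-shift variant %+0.3f cm: electrode leaves the bath",
                off,
            )
            continue
        try:
            i0, i1, j0, j1 = _square_nodes(
                grid,
                gx - edge / 2,
                gx + edge / 2,
                y1_t + clearance,
                y1_t + clearance + edge,
            )
            box = _flat_box(grid, i0, i1, j0, j1)
            bad = ~np.isin(
                grid.labels.ravel()[box], [Label.BATH, Label.ELECTRODE_CORE]
            )
            if bad.any():
                raise ValueError("ground variant overlaps tissue")
        except ValueError as e:
            log.warning("dropping ground-shift variant %+0.3f cm: %s", off, e)
            continue
        out.append(
            ElectrodeSet(
                applied_members + [(box, GROUND)],
                "variant",
                clearance=clearance,
                meta={**base.meta, "variant": f"ground_shift_{off:+.2f}"},
            )
        )

    # prolonged electrodes: +2.0 cm along the lateral axis, centred on the CI
    long_edge = edge + 2.0
    if ci_x - long_edge / 2 < -_EPS or ci_x + long_edge / 2 > W + _EPS:
        log.warning("dropping prolonged variant: extended electrodes leave the bath")
    else:
        members = []
        ok = True
        for pol, (ylo, yhi) in (
            (APPLIED, (y0_t - clearance - edge, y0_t - clearance)),
            (GROUND, (y1_t + clearance, y1_t + clearance + edge)),
        ):
            i0, i1, j0, j1 = _square_nodes(
                grid, ci_x - long_edge / 2, ci_x + long_edge / 2, ylo, yhi
            )
            box = _flat_box(grid, i0, i1, j0, j1)
            if not np.isin(
                grid.labels.ravel()[box], [Label.BATH, Label.ELECTRODE_CORE]
            ).all():
                log.warning("dropping prolonged variant: overlaps tissue")
                ok = False
                break
            members.append((box, pol))
        if ok:
            out.append(
                ElectrodeSet(
                    members,
                    "variant",
                    clearance=clearance,
                    meta={**base.meta, "variant": "prolonged", "length": long_edge},
                )
            )

    # APPLIED moved to the exterior-side bath (polarity-swapped mirror):
    # the centroid-centroid segment still passes straight through the CI.
    members = []
    for pol, (ylo, yhi) in (
        (APPLIED, (y1_t + clearance, y1_t + clearance + edge)),
        (GROUND, (y0_t - clearance - edge, y0_t - clearance)),
    ):
        i0, i1, j0, j1 = _square_nodes(
            grid, ci_x - edge / 2, ci_x + edge / 2, ylo, yhi
        )
        members.append((_flat_box(grid, i0, i1, j0, j1), pol))
    out.append(
        ElectrodeSet(
            members,
            "variant",
            clearance=clearance,
            meta={**base.meta, "variant": "applied_exterior"},
        )
    )
    return out


def segment_hits_ci(grid: TissueGrid, es: ElectrodeSet, n_samples: int = 400) -> bool:
    """Whether the APPLIED->GROUND centroid segment intersects the CI node-set."""
    ci = grid.region_mask("CI")
    a = grid.coords(es.applied_nodes).mean(axis=0)
    g = grid.coords(es.ground_nodes).mean(axis=0)
    for t in np.linspace(0.0, 1.0, n_samples):
        p = a + t * (g - a)
        ix = int(round(p[0] / grid.spacing))
        iy = int(round(p[1] / grid.spacing))
        if 0 <= ix < grid.nx and 0 <= iy < grid.ny and ci[ix, iy]:
            return True
    return False
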