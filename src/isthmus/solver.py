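"""Discrete monodomain / bidomain operators and time stepping.

The tissue is the classical two-phase continuum: intracellular and
extracellular potentials phi_i, phi_e coupled through the membrane,
V_m = phi_i - phi_e, with the surrounding bath governed by a Laplace
equation and flux continuity at the tissue-bath interface.  Between
therapies the harmonic-mean monodomain reduction is stepped; during shock
delivery the full bidomain system is solved with Dirichlet electrode faces.

Discretisation: structured-grid finite differences.  The anisotropic tensor
(rotated per-node by the fibre angle) enters through face-averaged
conductances for the axis terms and a symmetric central scheme for the
cross-derivative terms; with axis-aligned fibres this reduces exactly to the
5-point anisotropic stencil.  Harmonic face averaging makes sigma = 0
outside a domain act as a no-flux boundary, so each operator is assembled
over its own node-set with natural sealed boundaries.  All matrices are
symmetric with zero row sums on interior nodes.

Time integration is first-order operator splitting: reaction (Rush-Larsen /
forward Euler, in `ionic`) then Crank-Nicolson diffusion; the bidomain adds
an elliptic extracellular solve per step (sparse LU, factorisations cached).

Units: cm / ms / mV / uA/cm^2 / uF/cm^2; conductivities are stored in S/m
(as usually quoted) and converted to mS/cm (factor 10) at assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import ACTIVE_LABELS, Label, TissueGrid, ElectrodeSet
from .ionic import IonicState

__all__ = [
    "ConductivitySet",
    "DiscreteOperators",
    "ShockSpec",
    "TissueState",
    "ModelMap",
    "harmonic_mean_tensor",
    "assemble",
    "step_monodomain",
    "step_bidomain",
    "apply_shock",
    "solve_extracellular",
    "TissueSim",
    "S_PER_M_TO_MS_PER_CM",
]

S_PER_M_TO_MS_PER_CM = 10.0  # 1 S/m = 10 mS/cm


@dataclass(frozen=True)
class ConductivitySet:
    """Tissue/bath conductivities (S/m) and surface-to-volume ratio (1/cm).

    Longitudinal/transverse intra- and extracellular values are the standard
    ventricular set; border zone carries ``bz_factor`` on all tissue
    conductivities; scar and bath are isotropic.
    """

    sigma_il: float = 0.174
    sigma_el: float = 0.625
    sigma_it: float = 0.019
    sigma_et: float = 0.236
    bz_factor: float = 0.5
    sigma_scar: float = 0.05
    sigma_bath: float = 1.0
    beta: float = 1400.0  # 1/cm (= 0.14 1/um)

    def __post_init__(self):
        for f in (
            "sigma_il",
            "sigma_el",
            "sigma_it",
            "sigma_et",
            "bz_factor",
            "sigma_scar",
            "sigma_bath",
            "beta",
        ):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


def harmonic_mean_tensor(c: ConductivitySet) -> tuple[float, float]:
    """Per-eigendirection harmonic mean sigma_i sigma_e / (sigma_i + sigma_e),
    returned in S/m (longitudinal, transverse)."""
    sl = c.sigma_il * c.sigma_el / (c.sigma_il + c.sigma_el)
    st = c.sigma_it * c.sigma_et / (c.sigma_it + c.sigma_et)
    return sl, st


def _tensor_fields(angle, sl, st):
    """Per-node 2x2 tensor components from fibre angle and eigenvalues."""
    ca, sa = np.cos(angle), np.sin(angle)
    sxx = sl * ca**2 + st * sa**2
    syy = sl * sa**2 + st * ca**2
    sxy = (sl - st) * ca * sa
    return sxx, syy, sxy


def _face_hmean(a, b):
    """Face conductance between adjacent nodes: harmonic average 2ab/(a+b)
    (zero when either side is zero, i.e. a sealed boundary)."""
    s = a + b
    out = np.zeros_like(a)
    nz = s > 0
    out[nz] = 2.0 * a[nz] * b[nz] / s[nz]
    return out


def _series(a, b):
    """Series (harmonic) combination ab/(a+b) of the two phase
    conductivities -- the monodomain reduction tensor."""
    s = a + b
    out = np.zeros_like(a)
    nz = s > 0
    out[nz] = a[nz] * b[nz] / s[nz]
    return out


def assemble_laplacian(mask, sxx, syy, sxy, dx):
    """Symmetric anisotropic Laplacian over the True nodes of ``mask``.

    Returns (L csr over local indices, flat global indices of the nodes).
    Off-mask conductivity is treated as zero (harmonic face average -> sealed
    no-flux boundary).  Diagonal entries are set to minus the row sum.
    """
    nx, ny = mask.shape
    idx = np.full(mask.shape, -1, dtype=np.intp)
    nodes = np.flatnonzero(mask.ravel())
    idx.ravel()[nodes] = np.arange(len(nodes))

    sxx = np.where(mask, sxx, 0.0)
    syy = np.where(mask, syy, 0.0)
    sxy = np.where(mask, sxy, 0.0)

    rows, cols, vals = [], [], []

    def add(r, c, v):
        keep = (r >= 0) & (c >= 0) & (v != 0.0)
        rows.append(r[keep])
        cols.append(c[keep])
        vals.append(v[keep])

    inv2 = 1.0 / dx**2
    # x faces
    g = _face_hmean(sxx[:-1, :], sxx[1:, :]) * inv2
    r = idx[:-1, :].ravel()
    c = idx[1:, :].ravel()
    gv = g.ravel()
    add(r, c, gv)
    add(c, r, gv)
    # y faces
    g = _face_hmean(syy[:, :-1], syy[:, 1:]) * inv2
    r = idx[:, :-1].ravel()
    c = idx[:, 1:].ravel()
    gv = g.ravel()
    add(r, c, gv)
    add(c, r, gv)

    if np.any(sxy):
        inv4 = 1.0 / (4.0 * dx**2)
        # coefficient between (i,j) and (i+1,j+1): (sxy[i+1,j]+sxy[i,j+1])/4dx^2
        cpp = (sxy[1:, :-1] + sxy[:-1, 1:]) * inv4
        r = idx[:-1, :-1].ravel()
        c = idx[1:, 1:].ravel()
        # drop contributions whose sample nodes fall off-mask (sxy is already
        # zeroed there, harmonic-style sealing)
        gv = cpp.ravel()
        add(r, c, gv)
        add(c, r, gv)
        # coefficient between (i,j) and (i+1,j-1): -(sxy[i+1,j]+sxy[i,j-1])/4dx^2
        cpm = -(sxy[1:, 1:] + sxy[:-1, :-1]) * inv4
        r = idx[:-1, 1:].ravel()
        c = idx[1:, :-1].ravel()
        gv = cpm.ravel()
        add(r, c, gv)
        add(c, r, gv)

    n = len(nodes)
    rows = np.concatenate(rows) if rows else np.empty(0, dtype=np.intp)
    cols = np.concatenate(cols) if cols else np.empty(0, dtype=np.intp)
    vals = np.concatenate(vals) if vals else np.empty(0)
    L = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    L = L - sp.diags(np.asarray(L.sum(axis=1)).ravel())
    return L.tocsr(), nodes


@dataclass(frozen=True)
class ShockSpec:
    """Monophasic rectangular extracellular shock.

    ``voltage`` (V) is applied to the APPLIED face node-sets, GROUND faces
    are fixed at 0 V, for ``duration`` ms.  ``onset_fraction`` is the timing
    rule: the shock fires that fraction of the VTCL after the last sensed
    activation at the reference site.
    """

    electrodes: ElectrodeSet
    voltage: float
    duration: float = 5.0
    onset_fraction: float = 0.88
    waveform: str = "monophasic"

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not (0.0 < self.onset_fraction <= 1.0):
            raise ValueError("onset_fraction must be in (0, 1]")
        if self.waveform != "monophasic":
            raise ValueError("only monophasic rectangular shocks are supported")


@dataclass
class ModelMap:
    """Membrane model per active node: built model objects plus a per-node
    group id (index into ``models``)."""

    models: list
    node_group: np.ndarray  # (n_active,), int

    @classmethod
    def uniform(cls, model, n_active):
        return cls([model], np.zeros(n_active, dtype=np.int8))

    @classmethod
    def by_label(cls, grid: TissueGrid, healthy, bz):
        """Healthy model on HEALTHY nodes, border-zone model on BZ nodes."""
        lab = grid.labels.ravel()[grid.flat(grid.active_mask)]
        group = np.where(lab == Label.BZ, 1, 0).astype(np.int8)
        return cls([healthy, bz], group)

    def with_models(self, models):
        return ModelMap(models, self.node_group)

    def initial_state(self, n_active):
        vm = np.empty(n_active)
        eta = np.zeros((max(m.n_eta for m in self.models), n_active))
        for gi, m in enumerate(self.models):
            sel = self.node_group == gi
            st = m.initial_state(int(sel.sum()))
            vm[sel] = st.vm
            eta[: m.n_eta, sel] = st.eta
        return vm, eta

    def react(self, vm, eta, dt, istim):
        for gi, m in enumerate(self.models):
            sel = self.node_group == gi
            stim = istim[sel] if isinstance(istim, np.ndarray) else istim
            v, e = m.step(vm[sel], eta[: m.n_eta, sel], dt, stim)
            vm[sel] = v
            eta[: m.n_eta, sel] = e
        return vm, eta

    @property
    def v_rest(self):
        return self.models[0].v_rest

    @property
    def cm(self):
        return getattr(self.models[0], "cm", 1.0)


@dataclass
class TissueState:
    """Field state: V_m over tissue nodes (healthy/BZ/scar, operator order),
    membrane variables over active nodes, extracellular potential over the
    tissue+bath nodes when a bidomain step produced one."""

    vm: np.ndarray
    eta: np.ndarray
    t: float = 0.0
    phi_e: np.ndarray | None = None

    def copy(self):
        return TissueState(
            self.vm.copy(),
            self.eta.copy(),
            self.t,
            None if self.phi_e is None else self.phi_e.copy(),
        )


class DiscreteOperators:
    """Assembled spatial operators for one grid + conductivity setting.

    Attributes of note: ``active_nodes`` / ``tissue_nodes`` / ``extra_nodes``
    (flat grid indices, in operator order); ``L_mono`` (harmonic-mean tensor,
    active nodes); ``L_i`` (intracellular, tissue nodes); ``L_ie``
    (intra+extra over tissue plus bath -- the elliptic operator);
    ``L_i_ext`` (intracellular operator zero-padded onto the extracellular
    index set, used for the elliptic right-hand side and the coupling term).
    """

    def __init__(self, grid: TissueGrid, cset: ConductivitySet,
                 region_factors: dict[str, float] | None = None):
        self.grid = grid
        self.cset = cset
        self.region_factors = dict(region_factors or {})
        dx = grid.spacing
        k = S_PER_M_TO_MS_PER_CM
        lab = grid.labels

        active = grid.active_mask
        tissue = grid.tissue_mask
        extra = tissue | (lab == Label.BATH)

        # eigenvalue fields (mS/cm) on the full lattice
        ang = np.where(np.isnan(grid.fiber_angle), 0.0, grid.fiber_angle)
        sil = np.zeros(grid.shape)
        sit = np.zeros(grid.shape)
        sel_ = np.zeros(grid.shape)
        set_ = np.zeros(grid.shape)
        healthy = lab == Label.HEALTHY
        bz = lab == Label.BZ
        sil[healthy] = cset.sigma_il * k
        sit[healthy] = cset.sigma_it * k
        sel_[healthy] = cset.sigma_el * k
        set_[healthy] = cset.sigma_et * k
        sil[bz] = cset.sigma_il * cset.bz_factor * k
        sit[bz] = cset.sigma_it * cset.bz_factor * k
        sel_[bz] = cset.sigma_el * cset.bz_factor * k
        set_[bz] = cset.sigma_et * cset.bz_factor * k
        for name, f in self.region_factors.items():
            m = grid.region_mask(name) & active
            for arr in (sil, sit, sel_, set_):
                arr[m] *= f
        scar = lab == Label.SCAR
        for arr in (sil, sit):
            arr[scar] = cset.sigma_scar * k
        for arr in (sel_, set_):
            arr[scar] = cset.sigma_scar * k

        # intracellular tensor (tissue only)
        sxx_i, syy_i, sxy_i = _tensor_fields(ang, sil, sit)
        # extracellular tensor (tissue anisotropic + isotropic bath)
        sxx_e, syy_e, sxy_e = _tensor_fields(ang, sel_, set_)
        bath = lab == Label.BATH
        sxx_e = np.where(bath, cset.sigma_bath * k, sxx_e)
        syy_e = np.where(bath, cset.sigma_bath * k, syy_e)
        sxy_e = np.where(bath, 0.0, sxy_e)

        # harmonic-mean monodomain tensor on active nodes
        sml = _series(sil, sel_)
        smt = _series(sit, set_)
        sxx_m, syy_m, sxy_m = _tensor_fields(ang, sml, smt)

        self.L_mono, self.active_nodes = assemble_laplacian(
            active, sxx_m, syy_m, sxy_m, dx
        )
        self.L_i, self.tissue_nodes = assemble_laplacian(
            tissue, sxx_i, syy_i, sxy_i, dx
        )
        self.L_e_ext, self.extra_nodes = assemble_laplacian(
            extra, sxx_e, syy_e, sxy_e, dx
        )
        self.L_i_ext, extra_nodes2 = assemble_laplacian(
            extra, sxx_i, syy_i, sxy_i, dx
        )
        assert np.array_equal(self.extra_nodes, extra_nodes2)
        # elliptic operator: sum of the two phase operators (keeps the
        # discrete system exactly symmetric and the energy split exact)
        self.L_ie = (self.L_i_ext + self.L_e_ext).tocsr()
        # extracellular tensor restricted to tissue (for the in-heart energy
        # fraction); assembled lazily
        self._e_tissue_fields = (
            np.where(tissue, sxx_e, 0.0),
            np.where(tissue, syy_e, 0.0),
            np.where(tissue, sxy_e, 0.0),
        )
        self._L_e_tissue = None

        n_grid = grid.nx * grid.ny
        self._local = {}
        for name, nodes in (
            ("active", self.active_nodes),
            ("tissue", self.tissue_nodes),
            ("extra", self.extra_nodes),
        ):
            m = np.full(n_grid, -1, dtype=np.intp)
            m[nodes] = np.arange(len(nodes))
            self._local[name] = m
        # active nodes inside the tissue operator and vice versa
        self.active_in_tissue = self._local["tissue"][self.active_nodes]
        self.tissue_in_extra = self._local["extra"][self.tissue_nodes]

        self._mono_fac: dict[float, object] = {}
        self._para_fac: dict[float, object] = {}
        self._ell_fac: dict[tuple, object] = {}

    # -- helpers ------------------------------------------------------------

    def L_e_tissue(self):
        """Extracellular operator with conductivity zeroed outside tissue
        (used to split deposited field energy into tissue vs bath)."""
        if self._L_e_tissue is None:
            extra = self.grid.tissue_mask | (self.grid.labels == Label.BATH)
            sxx, syy, sxy = self._e_tissue_fields
            self._L_e_tissue, _ = assemble_laplacian(
                extra, sxx, syy, sxy, self.grid.spacing
            )
        return self._L_e_tissue

    def to_local(self, space: str, flat_nodes: np.ndarray) -> np.ndarray:
        loc = self._local[space][np.asarray(flat_nodes, dtype=np.intp)]
        if (loc < 0).any():
            raise ValueError(f"nodes outside the {space} operator domain")
        return loc

    def initial_state(self, models: ModelMap) -> TissueState:
        vm_a, eta = models.initial_state(len(self.active_nodes))
        vm = np.full(len(self.tissue_nodes), models.v_rest, dtype=float)
        vm[self.active_in_tissue] = vm_a
        return TissueState(vm, eta, 0.0)

    # -- factorisation caches ------------------------------------------------

    def _mono_solver(self, dt, beta, cm):
        key = (dt, beta, cm)
        if key not in self._mono_fac:
            a = dt / (2.0 * beta * cm)
            n = self.L_mono.shape[0]
            I = sp.identity(n, format="csc")
            self._mono_fac[key] = (
                splu((I - a * self.L_mono).tocsc()),
                (I + a * self.L_mono).tocsr(),
            )
        return self._mono_fac[key]

    def _para_solver(self, dt, beta, cm):
        key = (dt, beta, cm)
        if key not in self._para_fac:
            a = dt / (2.0 * beta * cm)
            n = self.L_i.shape[0]
            I = sp.identity(n, format="csc")
            self._para_fac[key] = (
                splu((I - a * self.L_i).tocsc()),
                (I + a * self.L_i).tocsr(),
            )
        return self._para_fac[key]

    def _elliptic_solver(self, dirichlet_local: np.ndarray | None):
        """LU of the elliptic operator with the given Dirichlet node-set
        (local extra indices); None = gauge-fixed free system (pin + demean)."""
        n = self.L_ie.shape[0]
        if dirichlet_local is None or not len(dirichlet_local):
            key = ("gauge",)
            if key not in self._ell_fac:
                A = (-self.L_ie).tolil()
                A[0, :] = 0.0
                A[:, 0] = 0.0
                A[0, 0] = 1.0
                self._ell_fac[key] = (splu(A.tocsc()), None)
            return self._ell_fac[key]
        d = np.unique(dirichlet_local)
        key = ("dir", d.tobytes())
        if key not in self._ell_fac:
            free = np.setdiff1d(np.arange(n), d, assume_unique=False)
            A = -self.L_ie
            A_ff = A[free][:, free].tocsc()
            A_fd = A[free][:, d].tocsr()
            self._ell_fac[key] = (splu(A_ff), (free, d, A_fd))
        return self._ell_fac[key]


def assemble(
    grid: TissueGrid,
    c: ConductivitySet = ConductivitySet(),
    region_factors: dict[str, float] | None = None,
) -> DiscreteOperators:
    """Assemble all discrete operators for a grid.

    ``region_factors`` multiplies the tissue conductivities (both spaces)
    inside named node-sets, e.g. ``{"CI": 0.3}`` to slow isthmus conduction.
    """
    return DiscreteOperators(grid, c, region_factors)


# ---------------------------------------------------------------------------
# time stepping


def solve_extracellular(
    ops: DiscreteOperators,
    state: TissueState,
    dirichlet: list[tuple[np.ndarray, float]] | None = None,
    i_e: np.ndarray | None = None,
) -> np.ndarray:
    """Elliptic solve for phi_e over tissue+bath (mV).

    -div((sigma_i+sigma_e) grad phi_e) = div(sigma_i grad V_m) + I_e, with
    Dirichlet values (mV) on the given flat node-sets, or the zero-mean gauge
    when no electrode is active.
    """
    n = ops.L_ie.shape[0]
    vm_ext = np.zeros(n)
    vm_ext[ops.tissue_in_extra] = state.vm
    rhs = ops.L_i_ext @ vm_ext
    if i_e is not None:
        rhs = rhs + i_e
    if dirichlet:
        loc = [(ops.to_local("extra", nodes), v) for nodes, v in dirichlet]
        d_all = np.concatenate([d for d, _ in loc])
        lu, aux = ops._elliptic_solver(d_all)
        free, d, A_fd = aux
        phi = np.zeros(n)
        vals = np.zeros(n)
        for dloc, v in loc:
            vals[dloc] = v
        phi[d] = vals[d]
        phi[free] = lu.solve(rhs[free] - A_fd @ vals[d])
        return phi
    lu, _ = ops._elliptic_solver(None)
    rhs = rhs - rhs.mean()
    rhs[0] = 0.0
    phi = lu.solve(rhs)
    return phi - phi.mean()


def step_monodomain(
    state: TissueState,
    ops: DiscreteOperators,
    models: ModelMap,
    dt: float,
    stimuli: np.ndarray | float = 0.0,
) -> TissueState:
    """One operator-split monodomain step (reaction then Crank-Nicolson
    diffusion) on the active tissue; V_m is untouched on scar and bath.
    ``stimuli`` is the transmembrane current density I_s per active node
    (uA/cm^2)."""
    if dt > 0.1 + 1e-12:
        raise ValueError("dt must be <= 0.1 ms for the diffusion substep")
    beta, cm = ops.cset.beta, models.cm
    vm_a = state.vm[ops.active_in_tissue]
    vm_a, eta = models.react(vm_a, state.eta, dt, stimuli)
    lu, B = ops._mono_solver(dt, beta, cm)
    vm_a = lu.solve(B @ vm_a)
    if not np.isfinite(vm_a).all():
        raise FloatingPointError("monodomain linear solve produced non-finite V_m")
    vm = state.vm
    vm[ops.active_in_tissue] = vm_a
    return TissueState(vm, eta, state.t + dt, None)


def step_bidomain(
    state: TissueState,
    ops: DiscreteOperators,
    models: ModelMap,
    dt: float,
    dirichlet: list[tuple[np.ndarray, float]] | None = None,
    i_e: np.ndarray | None = None,
    stimuli: np.ndarray | float = 0.0,
    corrector: bool = True,
) -> TissueState:
    """One operator-split bidomain step.

    Elliptic phi_e solve (with optional Dirichlet electrode faces or
    extracellular current density), reaction on active nodes, then the
    parabolic V_m update C_m dV/dt = [L_i V_m + L_i phi_e]/beta - I_ion with
    Crank-Nicolson on the V_m term.  Scar nodes are passive (no I_ion).

    The phi_e coupling term is explicit; with ``corrector`` (default) a
    second elliptic solve at the predicted V_m centres it in time, restoring
    second-order accuracy of the coupling (one extra sparse solve per
    step)."""
    if dt > 0.1 + 1e-12:
        raise ValueError("dt must be <= 0.1 ms for the diffusion substep")
    beta, cm = ops.cset.beta, models.cm
    phi = solve_extracellular(ops, state, dirichlet, i_e)
    vm0 = state.vm.copy()
    vm_a = vm0[ops.active_in_tissue]
    vm_a, eta = models.react(vm_a, state.eta, dt, stimuli)
    vm0[ops.active_in_tissue] = vm_a
    lu, B = ops._para_solver(dt, beta, cm)
    a = dt / (beta * cm)
    rhs0 = B @ vm0
    vm = lu.solve(rhs0 + a * (ops.L_i_ext @ phi)[ops.tissue_in_extra])
    if corrector:
        pred = TissueState(vm, eta, state.t + dt, None)
        phi1 = solve_extracellular(ops, pred, dirichlet, i_e)
        src = (a / 2.0) * (ops.L_i_ext @ (phi + phi1))[ops.tissue_in_extra]
        vm = lu.solve(rhs0 + src)
        phi = phi1
    if not np.isfinite(vm).all():
        raise FloatingPointError("bidomain linear solve produced non-finite V_m")
    return TissueState(vm, eta, state.t + dt, phi)


def _shock_dirichlet(shock: ShockSpec):
    es = shock.electrodes
    a, g = es.applied_nodes, es.ground_nodes
    if np.intersect1d(a, g).size:
        raise ValueError("applied and ground Dirichlet sets must be disjoint")
    return [(a, shock.voltage * 1e3), (g, 0.0)]


def apply_shock(
    state: TissueState,
    ops: DiscreteOperators,
    shock: ShockSpec,
    models: ModelMap,
    dt: float = 0.025,
    record_phi: bool = False,
):
    """Deliver one monophasic shock: for ``duration`` ms the APPLIED faces are
    held at +voltage and the GROUND faces at 0 V in the extracellular system,
    with full bidomain stepping; afterwards the faces are released.

    Returns ``(state, snapshots)`` where snapshots is a list of (t, phi_e)
    if requested (phi at shock onset is always included)."""
    dirichlet = _shock_dirichlet(shock)
    n_steps = max(1, int(round(shock.duration / dt)))
    snaps = []
    st = state
    for k in range(n_steps):
        st = step_bidomain(st, ops, models, dt, dirichlet=dirichlet)
        if record_phi and (k == 0 or k == n_steps - 1):
            snaps.append((st.t, st.phi_e.copy()))
    return st, snaps


# ---------------------------------------------------------------------------
# simulation driver


@dataclass
class StimulusEvent:
    """Rectangular transmembrane stimulus: flat grid node-set, onset (ms),
    duration (ms), amplitude (uA/cm^2)."""

    nodes: np.ndarray
    t0: float
    duration: float
    amplitude: float


class TissueSim:
    """Monodomain/bidomain time-stepping driver with site recording.

    Records the mean V_m of named node-sets every ``sample_dt`` ms into
    ``traces`` (and times into ``trace_t``); stimuli are applied as
    transmembrane current on active nodes.
    """

    def __init__(
        self,
        grid: TissueGrid,
        ops: DiscreteOperators,
        models: ModelMap,
        dt: float = 0.1,
        dt_shock: float = 0.025,
        record: dict[str, np.ndarray] | None = None,
        sample_dt: float = 0.5,
        state: TissueState | None = None,
    ):
        self.grid = grid
        self.ops = ops
        self.models = models
        self.dt = dt
        self.dt_shock = dt_shock
        self.state = state.copy() if state is not None else ops.initial_state(models)
        self.sample_dt = sample_dt
        self._rec_local = {}
        for name, nodes in (record or {}).items():
            self._rec_local[name] = ops.to_local("tissue", nodes)
        self.trace_t: list[float] = []
        self.traces: dict[str, list[float]] = {k: [] for k in self._rec_local}
        self._next_sample = self.state.t
        self._sample()

    def _sample(self):
        if self.state.t + 1e-9 >= self._next_sample:
            self.trace_t.append(self.state.t)
            for name, loc in self._rec_local.items():
                self.traces[name].append(float(self.state.vm[loc].mean()))
            self._next_sample = self.state.t + self.sample_dt

    def trace(self, name: str):
        return np.asarray(self.trace_t), np.asarray(self.traces[name])

    def _stim_vector(self, t, events):
        out = None
        for ev in events:
            if ev.t0 - 1e-9 <= t < ev.t0 + ev.duration - 1e-9:
                if out is None:
                    out = np.zeros(len(self.ops.active_nodes))
                out[self.ops.to_local("active", ev.nodes)] += ev.amplitude
        return 0.0 if out is None else out

    def run(self, until: float, stimuli: list[StimulusEvent] | None = None):
        """Monodomain stepping until time ``until`` (ms)."""
        events = stimuli or []
        while self.state.t < until - 1e-9:
            dt = min(self.dt, until - self.state.t)
            istim = self._stim_vector(self.state.t, events)
            self.state = step_monodomain(self.state, self.ops, self.models, dt, istim)
            self._sample()
        return self.state

    def run_bidomain(self, until: float, dirichlet=None, i_e=None):
        while self.state.t < until - 1e-9:
            dt = min(self.dt_shock, until - self.state.t)
            self.state = step_bidomain(
                self.state, self.ops, self.models, dt, dirichlet=dirichlet, i_e=i_e
            )
            self._sample()
        return self.state

    def deliver_shock(self, shock: ShockSpec, record_phi: bool = False):
        """Full-bidomain shock delivery from the current state, sampling
        traces during the pulse."""
        dirichlet = _shock_dirichlet(shock)
        t_end = self.state.t + shock.duration
        snaps = []
        first = True
        while self.state.t < t_end - 1e-9:
            dt = min(self.dt_shock, t_end - self.state.t)
            self.state = step_bidomain(
                self.state, self.ops, self.models, dt, dirichlet=dirichlet
            )
            if record_phi and (first or self.state.t >= t_end - 1e-9):
                snaps.append((self.state.t, self.state.phi_e.copy()))
            first = False
            self._sample()
        return snaps
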