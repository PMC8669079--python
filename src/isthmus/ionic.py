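"""Membrane kinetics.

Three interchangeable membrane models drive the reaction step of the tissue
solver:

* :class:`TT06` - the 2006 human ventricular (epicardial) ionic model, with
  dimensionless multipliers on G_Kr, G_Ks and G_Na.  The healthy "porcine"
  variant raises both delayed-rectifier potassium conductances by 50% to
  shorten the action potential toward porcine values; border-zone variants
  reduce the potassium and sodium conductances from that basis.
* :class:`ReducedModel` - a two-variable threshold-recovery surrogate
  (Mitchell-Schaeffer type) used where many seconds of tissue activity must
  be simulated quickly.  The same conductance multipliers map onto its time
  constants so border-zone remodelling (slower upstroke, longer action
  potential, post-repolarisation refractoriness) is preserved qualitatively.
* :class:`PassiveModel` - a linear leak membrane for cable-theory validation.

All models share one interface: ``n_eta`` state variables besides V_m,
``initial_state``, ``iion`` (uA/cm^2), and ``step`` which advances gates by
Rush-Larsen and concentrations by forward Euler.  Units: mV, ms, uA/cm^2,
uF/cm^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellModel",
    "IonicState",
    "TT06",
    "ReducedModel",
    "PassiveModel",
    "healthy_porcine",
    "make_bz_model",
    "ionic_rhs",
    "pace_single_cell",
    "apd90",
]

HEALTHY_PORCINE = "HEALTHY_PORCINE"
BZ = "BZ"
CUSTOM = "CUSTOM"
REDUCED = "REDUCED"

# multipliers defining the healthy porcine basis: +50% I_Kr and I_Ks
PORCINE_KR = 1.5
PORCINE_KS = 1.5


@dataclass(frozen=True)
class CellModel:
    """Membrane parameter scalings on top of a base model.

    ``scale_*`` are dimensionless multipliers on the maximal conductances
    G_Kr, G_Ks and G_Na of the base model; ``cm`` is membrane capacitance per
    unit area in uF/cm^2.
    """

    base: str = "tt06-epi"
    scale_gkr: float = 1.0
    scale_gks: float = 1.0
    scale_gna: float = 1.0
    cm: float = 1.0
    tag: str = CUSTOM

    def __post_init__(self):
        if self.cm <= 0:
            raise ValueError("cm must be positive")

    def build(self):
        """Instantiate the runnable membrane model."""
        if self.base == "tt06-epi":
            return TT06(self)
        if self.base == "reduced":
            return ReducedModel.from_cell_model(self)
        raise ValueError(f"unknown base model {self.base!r}")


def healthy_porcine(base: str = "tt06-epi") -> CellModel:
    """Healthy-tissue model: +50% G_Kr and G_Ks on the human base."""
    return CellModel(
        base=base,
        scale_gkr=PORCINE_KR,
        scale_gks=PORCINE_KS,
        scale_gna=1.0,
        tag=HEALTHY_PORCINE,
    )


def make_bz_model(
    kr_reduction: float,
    ks_reduction: float,
    na_reduction: float,
    base: str = "tt06-epi",
) -> CellModel:
    """Border-zone model: fractional conductance reductions applied to the
    healthy porcine basis (i.e. after the 1.5x potassium scaling).

    Remodelled ranges are 30-65% for the potassium currents and 10-90% for
    the sodium current; values outside warn but proceed (exploratory sweeps).
    """
    for name, r in (
        ("kr_reduction", kr_reduction),
        ("ks_reduction", ks_reduction),
        ("na_reduction", na_reduction),
    ):
        if r >= 1.0:
            raise ValueError(f"{name} must be < 1 (got {r})")
        if r < 0.0:
            raise ValueError(f"{name} must be >= 0 (got {r})")
    if not (0.30 <= kr_reduction <= 0.65) or not (0.30 <= ks_reduction <= 0.65):
        if (kr_reduction, ks_reduction) != (0.0, 0.0):
            warnings.warn("potassium reduction outside the 30-65% remodelled range")
    if not (0.10 <= na_reduction <= 0.90) and na_reduction != 0.0:
        warnings.warn("sodium reduction outside the 10-90% remodelled range")
    tag = HEALTHY_PORCINE if (kr_reduction, ks_reduction, na_reduction) == (0, 0, 0) else BZ
    return CellModel(
        base=base,
        scale_gkr=PORCINE_KR * (1.0 - kr_reduction),
        scale_gks=PORCINE_KS * (1.0 - ks_reduction),
        scale_gna=1.0 - na_reduction,
        tag=tag,
    )


@dataclass
class IonicState:
    """Per-node membrane state: V_m (mV), gating/concentration vector eta
    (shape ``(n_eta, n_nodes)``), and time in ms."""

    vm: np.ndarray
    eta: np.ndarray
    t: float = 0.0

    def copy(self) -> "IonicState":
        return IonicState(self.vm.copy(), self.eta.copy(), self.t)

    def check_finite(self):
        bad = ~np.isfinite(np.atleast_1d(self.vm))
        if bad.any():
            raise FloatingPointError(
                f"non-finite V_m at node index {int(np.flatnonzero(bad)[0])}"
            )
        if not np.isfinite(self.eta).all():
            j = int(np.flatnonzero(~np.isfinite(self.eta))[0] % self.eta.shape[-1])
            raise FloatingPointError(f"non-finite state variable at node index {j}")


# ---------------------------------------------------------------------------
# 2006 human ventricular model, epicardial parameter set


class TT06:
    """Epicardial human ventricular membrane kinetics (2006 parameter set).

    State layout (eta rows): m, h, j, xr1, xr2, xs, r, s, d, f, f2, fcass,
    Rbar, Cai, CaSS, CaSR, Nai, Ki.  Gates (first 12 rows) are advanced by
    Rush-Larsen; Rbar and the concentrations by forward Euler.
    """

    n_eta = 18
    GATES = slice(0, 12)
    v_rest = -85.23

    # physical constants
    R = 8314.472
    T = 310.0
    F = 96485.3415
    # cell geometry / capacitance (model-standard values)
    CM = 0.185
    Vc = 0.016404
    Vsr = 0.001094
    Vss = 0.00005468
    # external concentrations (mM)
    Ko = 5.4
    Nao = 140.0
    Cao = 2.0
    # maximal conductances / fluxes
    GNa = 14.838
    GK1 = 5.405
    Gto = 0.294  # epicardial
    GKr = 0.153
    GKs = 0.392  # epicardial
    GCaL = 3.98e-5
    GbNa = 0.00029
    GbCa = 0.000592
    GpCa = 0.1238
    KpCa = 0.0005
    GpK = 0.0146
    PNaK = 2.724
    KmK = 1.0
    KmNa = 40.0
    kNaCa = 1000.0
    KmNai = 87.5
    KmCa = 1.38
    ksat = 0.1
    gamma = 0.35
    alpha_naca = 2.5
    pKNa = 0.03
    # SR calcium handling
    Vmaxup = 0.006375
    Kup = 0.00025
    Vrel = 0.102
    Vleak = 0.00036
    Vxfer = 0.0038
    k1p = 0.15
    k2p = 0.045
    k3 = 0.060
    k4 = 0.005
    EC = 1.5
    maxsr = 2.5
    minsr = 1.0
    Bufc = 0.2
    Kbufc = 0.001
    Bufsr = 10.0
    Kbufsr = 0.3
    Bufss = 0.4
    Kbufss = 0.00025

    # 1 Hz steady-state initial conditions (model-standard)
    _Y0 = {
        "vm": -85.23,
        "m": 0.00172,
        "h": 0.7444,
        "j": 0.7045,
        "xr1": 0.00621,
        "xr2": 0.4712,
        "xs": 0.0095,
        "r": 2.42e-8,
        "s": 0.999998,
        "d": 3.373e-5,
        "f": 0.7888,
        "f2": 0.9755,
        "fcass": 0.9953,
        "Rbar": 0.9073,
        "Cai": 0.000126,
        "CaSS": 0.00036,
        "CaSR": 3.64,
        "Nai": 8.604,
        "Ki": 136.89,
    }

    def __init__(self, params: CellModel | None = None):
        p = params or CellModel(tag=CUSTOM)
        self.params = p
        self.gna = self.GNa * p.scale_gna
        self.gkr = self.GKr * p.scale_gkr
        self.gks = self.GKs * p.scale_gks
        self.cm = p.cm

    def initial_state(self, n: int) -> IonicState:
        vals = list(self._Y0.values())
        vm = np.full(n, vals[0])
        eta = np.tile(np.array(vals[1:])[:, None], (1, n))
        return IonicState(vm, eta, 0.0)

    # -- kinetics -----------------------------------------------------------

    def _rates(self, v, eta):
        """Gate steady states / time constants and the ionic currents."""
        (m, h, jg, xr1, xr2, xs, r, s, d, f, f2, fcass,
         Rbar, Cai, CaSS, CaSR, Nai, Ki) = eta
        RTF = self.R * self.T / self.F
        vf_rt = v * self.F / (self.R * self.T)

        ena = RTF * np.log(self.Nao / Nai)
        ek = RTF * np.log(self.Ko / Ki)
        eks = RTF * np.log((self.Ko + self.pKNa * self.Nao) / (Ki + self.pKNa * Nai))
        eca = 0.5 * RTF * np.log(self.Cao / Cai)

        # fast sodium
        ina = self.gna * m**3 * h * jg * (v - ena)
        m_inf = 1.0 / (1.0 + np.exp((-56.86 - v) / 9.03)) ** 2
        am = 1.0 / (1.0 + np.exp((-60.0 - v) / 5.0))
        bm = 0.1 / (1.0 + np.exp((v + 35.0) / 5.0)) + 0.1 / (
            1.0 + np.exp((v - 50.0) / 200.0)
        )
        tau_m = am * bm
        h_inf = 1.0 / (1.0 + np.exp((v + 71.55) / 7.43)) ** 2
        lo = v < -40.0
        ah = np.where(lo, 0.057 * np.exp(-(v + 80.0) / 6.8), 0.0)
        bh = np.where(
            lo,
            2.7 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.3485 * v),
            0.77 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1))),
        )
        tau_h = 1.0 / (ah + bh)
        j_inf = h_inf
        aj = np.where(
            lo,
            (-2.5428e4 * np.exp(0.2444 * v) - 6.948e-6 * np.exp(-0.04391 * v))
            * (v + 37.78)
            / (1.0 + np.exp(0.311 * (v + 79.23))),
            0.0,
        )
        bj = np.where(
            lo,
            0.02424 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14))),
            0.6 * np.exp(0.057 * v) / (1.0 + np.exp(-0.1 * (v + 32.0))),
        )
        tau_j = 1.0 / (aj + bj)

        # L-type calcium
        expv15 = np.exp(2.0 * (v - 15.0) * self.F / (self.R * self.T))
        ical = (
            self.GCaL
            * d
            * f
            * f2
            * fcass
            * 4.0
            * (v - 15.0)
            * self.F**2
            / (self.R * self.T)
            * (0.25 * CaSS * expv15 - self.Cao)
            / (expv15 - 1.0)
        )
        d_inf = 1.0 / (1.0 + np.exp((-8.0 - v) / 7.5))
        ad = 1.4 / (1.0 + np.exp((-35.0 - v) / 13.0)) + 0.25
        bd = 1.4 / (1.0 + np.exp((v + 5.0) / 5.0))
        gd = 1.0 / (1.0 + np.exp((50.0 - v) / 20.0))
        tau_d = ad * bd + gd
        f_inf = 1.0 / (1.0 + np.exp((v + 20.0) / 7.0))
        tau_f = (
            1102.5 * np.exp(-((v + 27.0) ** 2) / 225.0)
            + 200.0 / (1.0 + np.exp((13.0 - v) / 10.0))
            + 180.0 / (1.0 + np.exp((v + 30.0) / 10.0))
            + 20.0
        )
        f2_inf = 0.67 / (1.0 + np.exp((v + 35.0) / 7.0)) + 0.33
        tau_f2 = (
            562.0 * np.exp(-((v + 27.0) ** 2) / 240.0)
            + 31.0 / (1.0 + np.exp((25.0 - v) / 10.0))
            + 80.0 / (1.0 + np.exp((v + 30.0) / 10.0))
        )
        fcass_inf = 0.6 / (1.0 + (CaSS / 0.05) ** 2) + 0.4
        tau_fcass = 80.0 / (1.0 + (CaSS / 0.05) ** 2) + 2.0

        # transient outward (epicardial)
        ito = self.Gto * r * s * (v - ek)
        r_inf = 1.0 / (1.0 + np.exp((20.0 - v) / 6.0))
        tau_r = 9.5 * np.exp(-((v + 40.0) ** 2) / 1800.0) + 0.8
        s_inf = 1.0 / (1.0 + np.exp((v + 20.0) / 5.0))
        tau_s = (
            85.0 * np.exp(-((v + 45.0) ** 2) / 320.0)
            + 5.0 / (1.0 + np.exp((v - 20.0) / 5.0))
            + 3.0
        )

        # delayed rectifiers
        ikr = self.gkr * np.sqrt(self.Ko / 5.4) * xr1 * xr2 * (v - ek)
        xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - v) / 7.0))
        axr1 = 450.0 / (1.0 + np.exp((-45.0 - v) / 10.0))
        bxr1 = 6.0 / (1.0 + np.exp((v + 30.0) / 11.5))
        tau_xr1 = axr1 * bxr1
        xr2_inf = 1.0 / (1.0 + np.exp((v + 88.0) / 24.0))
        axr2 = 3.0 / (1.0 + np.exp((-60.0 - v) / 20.0))
        bxr2 = 1.12 / (1.0 + np.exp((v - 60.0) / 20.0))
        tau_xr2 = axr2 * bxr2
        iks = self.gks * xs**2 * (v - eks)
        xs_inf = 1.0 / (1.0 + np.exp((-5.0 - v) / 14.0))
        axs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - v) / 6.0))
        bxs = 1.0 / (1.0 + np.exp((v - 35.0) / 15.0))
        tau_xs = axs * bxs + 80.0

        # inward rectifier
        ak1 = 0.1 / (1.0 + np.exp(0.06 * (v - ek - 200.0)))
        bk1 = (
            3.0 * np.exp(0.0002 * (v - ek + 100.0)) + np.exp(0.1 * (v - ek - 10.0))
        ) / (1.0 + np.exp(-0.5 * (v - ek)))
        ik1 = self.GK1 * np.sqrt(self.Ko / 5.4) * ak1 / (ak1 + bk1) * (v - ek)

        # pumps and exchangers
        inak = (
            self.PNaK
            * self.Ko
            * Nai
            / ((self.Ko + self.KmK) * (Nai + self.KmNa))
            / (1.0 + 0.1245 * np.exp(-0.1 * vf_rt) + 0.0353 * np.exp(-vf_rt))
        )
        inaca = (
            self.kNaCa
            * (
                np.exp(self.gamma * vf_rt) * Nai**3 * self.Cao
                - np.exp((self.gamma - 1.0) * vf_rt)
                * self.Nao**3
                * Cai
                * self.alpha_naca
            )
            / (
                (self.KmNai**3 + self.Nao**3)
                * (self.KmCa + self.Cao)
                * (1.0 + self.ksat * np.exp((self.gamma - 1.0) * vf_rt))
            )
        )
        ipca = self.GpCa * Cai / (Cai + self.KpCa)
        ipk = self.GpK * (v - ek) / (1.0 + np.exp((25.0 - v) / 5.98))
        ibna = self.GbNa * (v - ena)
        ibca = self.GbCa * (v - eca)

        iion = (
            ina + ik1 + ito + ikr + iks + ical + inaca + inak + ipca + ipk + ibna + ibca
        )

        # SR calcium fluxes
        ileak = self.Vleak * (CaSR - Cai)
        iup = self.Vmaxup / (1.0 + self.Kup**2 / Cai**2)
        kcasr = self.maxsr - (self.maxsr - self.minsr) / (1.0 + (self.EC / CaSR) ** 2)
        k1 = self.k1p / kcasr
        k2 = self.k2p * kcasr
        dRbar = -k2 * CaSS * Rbar + self.k4 * (1.0 - Rbar)
        O = k1 * CaSS**2 * Rbar / (self.k3 + k1 * CaSS**2)
        irel = self.Vrel * O * (CaSR - CaSS)
        ixfer = self.Vxfer * (CaSS - Cai)

        bufc = 1.0 / (1.0 + self.Bufc * self.Kbufc / (Cai + self.Kbufc) ** 2)
        bufsr = 1.0 / (1.0 + self.Bufsr * self.Kbufsr / (CaSR + self.Kbufsr) ** 2)
        bufss = 1.0 / (1.0 + self.Bufss * self.Kbufss / (CaSS + self.Kbufss) ** 2)
        cmvf = self.CM / (2.0 * self.Vc * self.F)
        dCai = bufc * (
            (ileak - iup) * self.Vsr / self.Vc + ixfer - (ibca + ipca - 2.0 * inaca) * cmvf
        )
        dCaSR = bufsr * (iup - irel - ileak)
        dCaSS = bufss * (
            -ical * self.CM / (2.0 * self.Vss * self.F)
            + irel * self.Vsr / self.Vss
            - ixfer * self.Vc / self.Vss
        )
        dNai = -(ina + ibna + 3.0 * inak + 3.0 * inaca) * self.CM / (self.Vc * self.F)
        dKi = -(ik1 + ito + ikr + iks - 2.0 * inak + ipk) * self.CM / (self.Vc * self.F)

        inf = np.stack(
            [m_inf, h_inf, j_inf, xr1_inf, xr2_inf, xs_inf, r_inf, s_inf,
             d_inf, f_inf, f2_inf, fcass_inf]
        )
        tau = np.stack(
            [tau_m, tau_h, tau_j, tau_xr1, tau_xr2, tau_xs, tau_r, tau_s,
             tau_d, tau_f, tau_f2, tau_fcass]
        )
        dconc = np.stack([dRbar, dCai, dCaSS, dCaSR, dNai, dKi])
        return iion, inf, tau, dconc

    def iion(self, vm, eta):
        return self._rates(vm, eta)[0]

    def rhs(self, vm, eta):
        """(I_ion, d eta/dt) at the given state."""
        iion, inf, tau, dconc = self._rates(vm, eta)
        dgates = (inf - eta[self.GATES]) / tau
        return iion, np.concatenate([dgates, dconc])

    def step(self, vm, eta, dt, istim=0.0):
        """One reaction step: Rush-Larsen gates, forward-Euler concentrations,
        forward-Euler V_m with the stimulus current density (uA/cm^2)."""
        iion, inf, tau, dconc = self._rates(vm, eta)
        eta[self.GATES] = inf + (eta[self.GATES] - inf) * np.exp(-dt / tau)
        eta[12:] += dt * dconc
        vm = vm + dt * (-(iion) + istim) / self.cm
        return vm, eta

    def state_names(self):
        return list(self._Y0.keys())[1:]


# ---------------------------------------------------------------------------
# reduced threshold-recovery surrogate


@dataclass
class ReducedModel:
    """Two-variable threshold-recovery membrane (Mitchell-Schaeffer type).

    The normalised excitation variable u = (V_m - v_rest)/v_amp obeys
    du/dt = h u^2 (1-u)/tau_in - u/tau_out; the recovery gate h opens with
    tau_open below the gate voltage and closes with tau_close above it.
    Conductance multipliers from :class:`CellModel` map onto the time
    constants: reduced sodium slows the upstroke (tau_in) and delays recovery
    of excitability (tau_open); reduced potassium (relative to the healthy
    porcine basis) prolongs the action potential (tau_close).
    """

    tau_in: float = 0.3
    tau_out: float = 6.0
    tau_open: float = 120.0
    tau_close: float = 70.0
    v_gate: float = 0.13
    v_rest: float = -80.0
    v_amp: float = 100.0
    cm: float = 1.0
    params: CellModel | None = None

    n_eta = 1
    GATES = slice(0, 0)

    @classmethod
    def from_cell_model(cls, p: CellModel, **base) -> "ReducedModel":
        m = cls(**base) if base else cls()
        k_rel = ((p.scale_gkr + p.scale_gks) / 2.0) / PORCINE_KR
        gna = max(p.scale_gna, 1e-3)
        return cls(
            tau_in=m.tau_in / gna,
            tau_out=m.tau_out,
            tau_open=m.tau_open / gna,
            tau_close=m.tau_close / max(k_rel, 1e-3),
            v_gate=m.v_gate,
            v_rest=m.v_rest,
            v_amp=m.v_amp,
            cm=p.cm,
            params=p,
        )

    def initial_state(self, n: int) -> IonicState:
        return IonicState(np.full(n, self.v_rest), np.ones((1, n)), 0.0)

    def _dudh(self, vm, h):
        u = (vm - self.v_rest) / self.v_amp
        uc = np.clip(u, 0.0, 1.0)
        # cubic excitation on the clipped variable; the linear outward term
        # acts on the raw one so shock-hyperpolarised (u < 0) and strongly
        # depolarised (u > 1) tissue both relax back with tau_out
        du = h * uc * uc * (1.0 - uc) / self.tau_in - u / self.tau_out
        dh = np.where(
            u < self.v_gate, (1.0 - h) / self.tau_open, -h / self.tau_close
        )
        return du, dh

    def iion(self, vm, eta):
        du, _ = self._dudh(vm, eta[0])
        return -du * self.v_amp * self.cm  # uA/cm^2 (inward negative convention)

    def rhs(self, vm, eta):
        du, dh = self._dudh(vm, eta[0])
        return -du * self.v_amp * self.cm, dh[None, :]

    def step(self, vm, eta, dt, istim=0.0):
        du, dh = self._dudh(vm, eta[0])
        eta[0] = np.clip(eta[0] + dt * dh, 0.0, 1.0)
        vm = vm + dt * (du * self.v_amp + istim / self.cm)
        return vm, eta


@dataclass
class PassiveModel:
    """Linear leak membrane: I_ion = g_m (V_m - v_rest), g_m in mS/cm^2."""

    g_m: float = 1.0
    v_rest: float = -80.0
    cm: float = 1.0
    n_eta = 0

    def initial_state(self, n: int) -> IonicState:
        return IonicState(np.full(n, self.v_rest), np.zeros((0, n)), 0.0)

    def iion(self, vm, eta):
        return self.g_m * (vm - self.v_rest)

    def rhs(self, vm, eta):
        return self.iion(vm, eta), np.zeros((0, len(np.atleast_1d(vm))))

    def step(self, vm, eta, dt, istim=0.0):
        vm = vm + dt * (-(self.iion(vm, eta)) + istim) / self.cm
        return vm, eta


# ---------------------------------------------------------------------------
# single-cell protocols


def ionic_rhs(state: IonicState, model: CellModel | object):
    """I_ion (uA/cm^2) and d eta/dt for a state, validating finiteness.

    ``model`` may be a :class:`CellModel` (built on the fly) or an already
    built membrane model.
    """
    state.check_finite()
    m = model.build() if isinstance(model, CellModel) else model
    return m.rhs(np.atleast_1d(np.asarray(state.vm, dtype=float)), state.eta)


def apd90(t: np.ndarray, vm: np.ndarray) -> float:
    """Action potential duration at 90% repolarisation of the last AP in a
    trace (ms); NaN when no AP is present."""
    v_rest = vm.min()
    v_peak = vm.max()
    if v_peak - v_rest < 30.0:
        return float("nan")
    v90 = v_peak - 0.9 * (v_peak - v_rest)
    up = np.flatnonzero((vm[:-1] < v90) & (vm[1:] >= v90))
    if not len(up):
        return float("nan")
    t_up = t[up[-1]]
    down = np.flatnonzero((vm[:-1] >= v90) & (vm[1:] < v90) & (t[:-1] > t_up))
    if not len(down):
        return float("nan")
    return float(t[down[0]] - t_up)


class CaptureError(RuntimeError):
    pass


def pace_single_cell(
    model: CellModel,
    n_beats: int = 100,
    rate: float = 2.0,
    amp: float = 52.0,
    dur: float = 1.0,
    dt: float = 0.025,
    state: IonicState | None = None,
):
    """Pace an isolated cell to its limit cycle.

    Stimulates ``n_beats`` times at ``rate`` Hz with a rectangular current of
    ``amp`` uA/cm^2 for ``dur`` ms, returns ``(state, apd90_ms)`` of the final
    beat.  Raises :class:`CaptureError` if a stimulus in the final 10 beats
    fails to elicit an action potential, or if APD90 still alternates by more
    than 1 ms per beat over the last 5 beats.
    """
    m = model.build()
    st = state.copy() if state is not None else m.initial_state(1)
    if n_beats == 0:
        return st, float("nan")
    cl = 1000.0 / rate
    n_per = int(round(cl / dt))
    n_dur = max(1, int(round(dur / dt)))
    check_from = max(0, n_beats - 10)
    apds = []
    for b in range(n_beats):
        rec_t = np.empty(n_per)
        rec_v = np.empty(n_per)
        for k in range(n_per):
            istim = amp if k < n_dur else 0.0
            st.vm, st.eta = m.step(st.vm, st.eta, dt, istim)
            st.t += dt
            rec_t[k] = st.t
            rec_v[k] = st.vm[0]
        a = apd90(rec_t, rec_v)
        apds.append(a)
        if b >= check_from and not np.isfinite(a):
            raise CaptureError(f"loss of capture at beat {b + 1}")
    last5 = np.array(apds[-5:])
    if len(last5) == 5 and np.isfinite(last5).all():
        if np.abs(np.diff(last5)).max() > 1.0:
            raise CaptureError(
                f"APD90 alternans beyond 1 ms over the final beats "
                f"(max beat-to-beat change {np.abs(np.diff(last5)).max():.2f} ms)"
            )
    st.check_finite()
    return st, float(apds[-1])
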