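"""Signal analysis and endpoint computation.

Activation sensing on site traces, cycle-length and conduction-velocity
measurement, termination verdicts, efficacy tables stratified by VT class,
and shock-energy accounting (capacitive discharge and deposited field
energy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ActivationSeries",
    "EfficacyTable",
    "detect_activations",
    "measure_vtcl",
    "classify_vt",
    "SLOW",
    "FAST",
    "measure_cv",
    "is_terminated",
    "efficacy",
    "shock_energy",
    "fit_capacitance",
    "field_energy",
    "DEFAULT_CAPACITANCE",
    "ACTIVATION_THRESHOLD",
    "REFRACTORY_GATE",
    "FAST_VT_BOUNDARY_MS",
]

SLOW = "SLOW"
FAST = "FAST"
FAST_VT_BOUNDARY_MS = 320.0

ACTIVATION_THRESHOLD = -20.0  # mV, upward crossing with positive slope
REFRACTORY_GATE = 50.0  # ms between accepted activations

# Effective discharge capacitance (F).  The four quoted (voltage, energy)
# operating points -- 37 J @ 860 V, 145 J @ 1700 V, 0.32 J @ 80 V,
# 0.72 J @ 120 V -- are all consistent with E = C V^2 / 2 at C = 1.0e-4 F to
# better than 1.5%; `fit_capacitance` recovers this value and is unit-tested.
DEFAULT_CAPACITANCE = 1.0e-4


@dataclass
class ActivationSeries:
    """Strictly increasing activation times (ms) sensed at one site."""

    site: str
    times: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) > 1:
            gaps = np.diff(self.times)
            if (gaps <= 0).any():
                raise ValueError("activation times must be strictly increasing")
            if (gaps < REFRACTORY_GATE - 1e-9).any():
                raise ValueError(
                    f"activations closer than the {REFRACTORY_GATE} ms refractory gate"
                )

    def __len__(self):
        return len(self.times)

    def last_before(self, t: float) -> float | None:
        prev = self.times[self.times <= t + 1e-9]
        return float(prev[-1]) if len(prev) else None


def detect_activations(
    t: np.ndarray,
    vm: np.ndarray,
    threshold: float = ACTIVATION_THRESHOLD,
    refractory: float = REFRACTORY_GATE,
    hysteresis: float = 10.0,
    site: str = "site",
) -> ActivationSeries:
    """Sense activations on a uniformly sampled V_m trace.

    An activation is an upward crossing of ``threshold`` with positive
    slope.  Crossings within ``refractory`` ms of the previous accepted
    activation are discarded, and the detector re-arms only once the trace
    has fallen ``hysteresis`` mV below threshold (so noise riding on the
    repolarisation tail cannot double-count a beat).
    """
    t = np.asarray(t, dtype=float)
    vm = np.asarray(vm, dtype=float)
    if t.size == 0 or vm.size == 0:
        raise ValueError("empty trace")
    if t.shape != vm.shape:
        raise ValueError("time and voltage arrays differ in length")
    cross = np.flatnonzero((vm[:-1] < threshold) & (vm[1:] >= threshold))
    below = vm < threshold - hysteresis
    times = []
    last_i = None
    last = -np.inf
    for i in cross:
        ti = t[i + 1]
        if ti - last < refractory - 1e-9:
            continue
        if last_i is not None and not below[last_i + 1 : i + 1].any():
            continue  # not re-armed since the previous activation
        times.append(ti)
        last = ti
        last_i = i
    return ActivationSeries(site, np.asarray(times))


def measure_vtcl(series: ActivationSeries, n_cycles: int = 5):
    """Mean inter-activation interval over the last ``n_cycles`` cycles and
    its coefficient of variation.  Requires at least 3 activations."""
    if len(series) < 3:
        raise ValueError("need at least 3 activations to measure a cycle length")
    gaps = np.diff(series.times)[-n_cycles:]
    vtcl = float(gaps.mean())
    cv = float(gaps.std(ddof=0) / vtcl) if vtcl > 0 else float("nan")
    return vtcl, cv


def classify_vt(vtcl: float) -> str:
    """FAST iff the cycle length is at most 320 ms, SLOW otherwise."""
    if vtcl <= 0:
        raise ValueError("vtcl must be positive")
    return FAST if vtcl <= FAST_VT_BOUNDARY_MS else SLOW


def measure_cv(
    grid,
    ops,
    models,
    direction: str = "x",
    amp: float = 80.0,
    stim_dur: float = 2.0,
    t_max: float = 200.0,
    run_in: float = 0.5,
    probe_gap: float = 1.0,
    dt: float = 0.1,
) -> float:
    """Planar conduction velocity (m/s) on a strip geometry.

    A plane stimulus is applied along the first lattice line perpendicular to
    ``direction``; CV is the probe distance over the activation-time
    difference between two full-width probe lines ``probe_gap`` cm apart,
    placed after a ``run_in`` cm run-in.  Raises if the wave never reaches
    the distal probe.
    """
    from .solver import TissueSim, StimulusEvent  # local import, avoids cycle

    dx = grid.spacing
    act = grid.active_mask
    if direction == "x":
        coord = np.arange(grid.nx)[:, None] * dx * np.ones((1, grid.ny))
    else:
        coord = np.ones((grid.nx, 1)) * np.arange(grid.ny)[None, :] * dx
    cmin = coord[act].min()
    stim = act & (coord <= cmin + 2 * dx + 1e-9)
    p1 = act & (np.abs(coord - (cmin + run_in)) <= dx / 2 + 1e-9)
    p2 = act & (np.abs(coord - (cmin + run_in + probe_gap)) <= dx / 2 + 1e-9)
    if not p1.any() or not p2.any():
        raise ValueError("strip too short for the requested probe layout")
    sim = TissueSim(
        grid,
        ops,
        models,
        dt=dt,
        record={"p1": grid.flat(p1), "p2": grid.flat(p2)},
        sample_dt=min(0.5, dt * 5),
    )
    sim.run(t_max, [StimulusEvent(grid.flat(stim), 1.0, stim_dur, amp)])
    t1s = detect_activations(*sim.trace("p1"))
    t2s = detect_activations(*sim.trace("p2"))
    if not len(t1s) or not len(t2s):
        raise RuntimeError("planar wave failed to reach the probes")
    dt_act = t2s.times[0] - t1s.times[0]
    if dt_act <= 0:
        raise RuntimeError("distal probe activated before proximal probe")
    return float(probe_gap / dt_act * 10.0)  # cm/ms -> m/s


def is_terminated(
    post_series: ActivationSeries,
    vtcl: float,
    therapy_end: float,
    sim_end: float,
    final_vm_max: float,
    window_factor: float = 3.0,
    vm_quiescent: float = -60.0,
) -> bool:
    """Termination verdict.

    True iff no activation is sensed at the reference site during the final
    window of ``window_factor * vtcl`` ms before ``sim_end`` AND the maximum
    tissue V_m at the end of the run is below ``vm_quiescent`` (globally
    repolarised).  Raises if the post-therapy simulation is shorter than the
    required window -- a verdict is never given silently on short data.
    """
    window = window_factor * vtcl
    if sim_end - therapy_end < window - 1e-9:
        raise ValueError(
            f"post-therapy simulation ({sim_end - therapy_end:.0f} ms) shorter "
            f"than the termination window ({window:.0f} ms)"
        )
    in_window = post_series.times[post_series.times > sim_end - window + 1e-9]
    return len(in_window) == 0 and final_vm_max < vm_quiescent


@dataclass
class EfficacyTable:
    """Per-therapy success fractions, stratified ALL / SLOW / FAST."""

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["therapy", "strength", "class", "n_success", "n_total", "efficacy"]
        )
    )

    def to_csv(self, path):
        self.frame.to_csv(path, index=False)

    def to_json(self, path):
        self.frame.to_json(path, orient="records", indent=2)


def efficacy(outcomes, strata: bool = True) -> EfficacyTable:
    """Build the efficacy table from therapy outcomes.

    ``outcomes`` is an iterable of objects (or dicts) with attributes
    ``therapy``, ``strength``, ``terminated`` and ``vt_class``.  Efficacy is
    rounded to integer percent; ALL rows always appear, SLOW/FAST rows when
    ``strata``.  Empty strata report n_total 0 with efficacy NaN.
    """
    rows = []
    recs = []
    for o in outcomes:
        get = o.get if isinstance(o, dict) else lambda k, _o=o: getattr(_o, k)
        recs.append(
            {
                "therapy": get("therapy"),
                "strength": get("strength"),
                "terminated": bool(get("terminated")),
                "vt_class": get("vt_class"),
            }
        )
    if not recs:
        raise ValueError("no outcomes to tabulate")
    df = pd.DataFrame(recs)
    classes = ["ALL"] + ([SLOW, FAST] if strata else [])
    for (therapy, strength), grp in df.groupby(["therapy", "strength"], sort=False):
        for cls in classes:
            sub = grp if cls == "ALL" else grp[grp["vt_class"] == cls]
            n_tot = len(sub)
            n_suc = int(sub["terminated"].sum())
            eff = round(100.0 * n_suc / n_tot) if n_tot else float("nan")
            rows.append(
                {
                    "therapy": therapy,
                    "strength": strength,
                    "class": cls,
                    "n_success": n_suc,
                    "n_total": n_tot,
                    "efficacy": eff,
                }
            )
    return EfficacyTable(pd.DataFrame(rows))


def shock_energy(voltage: float, capacitance: float = DEFAULT_CAPACITANCE) -> float:
    """Capacitive-discharge energy estimate E = C V^2 / 2 in joules."""
    if voltage < 0:
        raise ValueError("voltage must be non-negative")
    return 0.5 * capacitance * voltage**2


def fit_capacitance(pairs) -> float:
    """Effective capacitance (F) from (voltage V, energy J) operating points,
    by least squares on E = C V^2 / 2."""
    v = np.array([p[0] for p in pairs], dtype=float)
    e = np.array([p[1] for p in pairs], dtype=float)
    if (v <= 0).any():
        raise ValueError("voltages must be positive")
    return float(2.0 * (e * v**2).sum() / (v**4).sum())


def field_energy(phi_e: np.ndarray, ops, duration: float, depth: float = 1.0):
    """Energy deposited by an extracellular field over ``duration`` ms.

    Evaluates the quadratic form int sigma |grad phi|^2 dV x duration from
    the assembled extracellular operator (phi in mV over the tissue+bath
    node-set), assuming ``depth`` cm of tissue in the out-of-plane direction.
    Returns a dict with total joules and the tissue/bath split.
    """
    dx = ops.grid.spacing
    # L entries are conductance densities (mS/cm / cm^2); the quadratic form
    # -phi^T L phi has units mS/cm * mV^2 / cm^2 per node; multiply by the
    # node volume dx^2*depth and convert mS*mV^2 = 1e-9 W, ms = 1e-3 s.
    scale = dx * dx * depth * 1e-12 * duration

    def quad(L):
        return float(-phi_e @ (L @ phi_e)) * scale

    total = quad(ops.L_e_ext)  # extracellular-phase quadratic form
    tissue = quad(ops.L_e_tissue())
    return {
        "total_J": total,
        "tissue_J": tissue,
        "bath_J": total - tissue,
        "tissue_fraction": tissue / total if total > 0 else float("nan"),
    }
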