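"""Experiment drivers: VT induction and stabilisation, library generation,
burst anti-tachycardia pacing, single-shock therapy with strength/timing
search, and the calibration-strength selection rule.

The drivers operate on a :class:`VTSetup` (grid + assembled operators +
membrane model map) and exchange :class:`VTEpisode` objects: checkpointed
tissue states sustaining monomorphic reentry, with measured cycle length and
full provenance.

Protocol economy follows standard practice for defibrillation studies: the
computationally cheap monodomain model is stepped between therapies, the
full bidomain system only during shock delivery; the switch copies V_m and
the membrane state and resets the extracellular potential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import analysis as an
from .geometry import ElectrodeSet, TissueGrid, place_edge_pacing_site
from .ionic import CellModel, healthy_porcine
from .solver import (
    ConductivitySet,
    DiscreteOperators,
    ModelMap,
    ShockSpec,
    StimulusEvent,
    TissueSim,
    TissueState,
    assemble,
)

log = logging.getLogger(__name__)

__all__ = [
    "VTSetup",
    "VTEpisode",
    "PacingProtocol",
    "TherapyOutcome",
    "NonInducible",
    "NotFound",
    "StabilizationFailed",
    "induce_vt",
    "stabilize_vt",
    "generate_vt_library",
    "atp_schedule",
    "run_atp",
    "run_shock",
    "find_min_strength",
    "timing_sweep",
    "select_protocol_strengths",
    "with_electrodes",
]

QUIESCENT_MV = -60.0
REFERENCE_SITE = "ci_mouth_cavity"


class NonInducible(Exception):
    """The S1-S2(-S3) search exhausted its coupling-interval grid without
    producing sustained reentry."""


class StabilizationFailed(Exception):
    """Reentry died while the border-zone ionic properties were being
    normalised or conductivities adjusted."""


class _NotFoundType:
    """Sentinel: no strength on the voltage grid terminated the episode."""

    def __repr__(self):
        return "NotFound"

    def __bool__(self):
        return False


NotFound = _NotFoundType()


@dataclass
class VTSetup:
    """Simulation context: geometry, conductivities (with optional per-region
    factors), and the membrane model map."""

    grid: TissueGrid
    cset: ConductivitySet = field(default_factory=ConductivitySet)
    region_factors: dict[str, float] = field(default_factory=dict)
    healthy: CellModel = field(default_factory=lambda: healthy_porcine("reduced"))
    bz: CellModel | None = None
    dt: float = 0.1
    dt_shock: float = 0.025
    _ops: DiscreteOperators | None = None
    _models: ModelMap | None = None

    @property
    def ops(self) -> DiscreteOperators:
        if self._ops is None:
            self._ops = assemble(self.grid, self.cset, self.region_factors)
        return self._ops

    @property
    def models(self) -> ModelMap:
        if self._models is None:
            h = self.healthy.build()
            b = (self.bz or self.healthy).build()
            self._models = ModelMap.by_label(self.grid, h, b)
        return self._models

    def variant(self, bz=None, region_factors=None, healthy=None) -> "VTSetup":
        """Same grid, different ionic/conductivity setting (operators and
        models rebuilt lazily)."""
        return VTSetup(
            grid=self.grid,
            cset=self.cset,
            region_factors=dict(
                region_factors if region_factors is not None else self.region_factors
            ),
            healthy=healthy or self.healthy,
            bz=bz if bz is not None else self.bz,
            dt=self.dt,
            dt_shock=self.dt_shock,
        )

    def sim(self, state=None, record=None, sample_dt=0.5) -> TissueSim:
        rec = {REFERENCE_SITE: self.grid.regions[REFERENCE_SITE]}
        if record:
            rec.update(record)
        return TissueSim(
            self.grid,
            self.ops,
            self.models,
            dt=self.dt,
            dt_shock=self.dt_shock,
            record=rec,
            sample_dt=sample_dt,
            state=state,
        )


@dataclass
class VTEpisode:
    """Checkpointed tissue state sustaining monomorphic reentry."""

    setup: VTSetup
    checkpoint: TissueState
    vtcl: float
    provenance: dict = field(default_factory=dict)
    reference_site: str = REFERENCE_SITE

    def __post_init__(self):
        if self.vtcl <= 0:
            raise ValueError("vtcl must be positive")
        self._onset_cache: dict = {}

    @property
    def vt_class(self) -> str:
        return an.classify_vt(self.vtcl)

    def verify(self, n_cycles: int = 2, tol: float = 0.02) -> float:
        """Re-simulate the checkpoint for ``n_cycles`` cycles and check the
        measured cycle length against the stored one (2% by default)."""
        sim = self.setup.sim(state=self.checkpoint)
        sim.run(self.checkpoint.t + (n_cycles + 1.5) * self.vtcl)
        series = an.detect_activations(*sim.trace(self.reference_site))
        if len(series) < 3:
            raise StabilizationFailed("reentry not reproduced from checkpoint")
        vtcl, _ = an.measure_vtcl(series, n_cycles=min(n_cycles, len(series) - 1))
        if abs(vtcl - self.vtcl) > tol * self.vtcl:
            raise StabilizationFailed(
                f"checkpoint reproduces VTCL {vtcl:.0f} ms vs stored "
                f"{self.vtcl:.0f} ms (> {tol:.0%})"
            )
        return vtcl


@dataclass(frozen=True)
class PacingProtocol:
    """Burst pacing: ``n_sequences`` trains of ``pulses_per_seq`` stimuli at
    ``interval_fraction`` of the VTCL, the second train 10 ms faster, started
    ``interval_fraction`` x VTCL after the last sensed activation at the
    pacing site."""

    site: ElectrodeSet
    n_sequences: int = 2
    pulses_per_seq: int = 8
    interval_fraction: float = 0.88
    second_seq_shortening: float = 10.0
    amplitude: float = 50.0  # uA/cm^2
    pulse_duration: float = 2.0
    gap_rule: str = "resense"  # or "fixed": one interval after the last pulse


@dataclass
class TherapyOutcome:
    """Per-episode verdict of one therapy application."""

    therapy: str
    strength: float
    terminated: bool
    vt_class: str
    vtcl: float
    time_of_last_activation: float
    post_window_used: float
    detail: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# induction


def _active_vm_max(sim) -> float:
    """Maximum V_m over excitable nodes (scar holds a frozen, possibly
    shock-polarised value in monodomain and must not enter activity
    checks)."""
    return float(sim.state.vm[sim.ops.active_in_tissue].max())


def _run_until_quiescent_or(sim, t_end, stimuli=None, chunk=100.0):
    """Advance in chunks, stopping early once the excitable tissue is
    globally repolarised and no stimulus is pending."""
    events = stimuli or []
    while sim.state.t < t_end - 1e-9:
        sim.run(min(sim.state.t + chunk, t_end), events)
        pending = any(ev.t0 + ev.duration > sim.state.t for ev in events)
        if not pending and _active_vm_max(sim) < QUIESCENT_MV:
            break
    return sim


def _extend_for_cycles(sim, s2_time, min_cycles, t_cap):
    """Keep simulating while activity persists until ``min_cycles + 1``
    post-stimulus activations are visible (slow circuits need longer
    follow-up than the nominal window)."""
    while sim.state.t < t_cap and _active_vm_max(sim) >= QUIESCENT_MV:
        series = an.detect_activations(*sim.trace(REFERENCE_SITE))
        post = series.times[series.times > s2_time - 1.0]
        if len(post) >= min_cycles + 1 or len(post) < 2:
            break
        gap = float(np.diff(post)[-3:].mean())
        need = (min_cycles + 1 - len(post)) * gap + 0.5 * gap
        _run_until_quiescent_or(sim, min(sim.state.t + need, t_cap))
    return sim


def _reentry_check(sim, s2_time, min_cycles=3, cv_tol=0.10):
    """Sustained-reentry test on the reference-site trace after a premature
    stimulus; returns (times, vtcl, cv) or None."""
    t, v = sim.trace(REFERENCE_SITE)
    series = an.detect_activations(t, v)
    post = series.times[series.times > s2_time - 1.0]
    if len(post) < min_cycles + 1:
        return None
    gaps = np.diff(post)
    # the first post-block cycle is the establishment transient; judge
    # monomorphism on the settled rhythm
    tail = (gaps[1:] if len(gaps) >= 2 else gaps)[-5:]
    vtcl = float(tail.mean())
    cv = float(tail.std() / vtcl)
    if cv > cv_tol:
        return None
    if _active_vm_max(sim) < QUIESCENT_MV:
        return None  # died after a few beats
    return post, vtcl, cv


def induce_vt(
    setup: VTSetup,
    pace_site: ElectrodeSet | None = None,
    s1_bcl: float = 500.0,
    n_s1: int = 3,
    s2_start: float = 500.0,
    decrement: float = 10.0,
    floor: float = 200.0,
    amp: float = 60.0,
    dur: float = 2.0,
    follow: float = 1700.0,
    min_cycles: int = 3,
    max_attempts: int = 31,
) -> VTEpisode:
    """Programmed-stimulation VT induction.

    Three S1 at the basic cycle length are delivered at the pacing site; an
    S2 follows at a coupling interval decremented from ``s2_start`` until
    unidirectional block at the isthmus produces sustained reentry.  If
    capture fails before block occurs, an S3 is added and decremented the
    same way.  Raises :class:`NonInducible` when the coupling floor (or the
    attempt budget) is reached.

    Success requires ``min_cycles`` reentrant cycles at the reference site
    with <=10% cycle-length variation, with activity still present at the
    end of the follow-up window.  The returned episode's checkpoint is the
    end-of-follow-up state; provenance records the S2/S3 intervals and the
    block evidence (one-ended channel entry).
    """
    grid = setup.grid
    if "CI" not in grid.regions or not len(grid.regions["CI"]):
        raise NonInducible("no isthmus in this grid: nothing to induce")
    if pace_site is None:
        name = "pace_cavity"
        if name not in grid.regions:
            pace_site = place_edge_pacing_site(grid, "cavity", depth=0.075)
        else:
            pace_site = ElectrodeSet(
                [(grid.regions[name], "APPLIED")], "atp_block"
            )
    nodes = pace_site.all_nodes

    drive = setup.sim(sample_dt=1.0)
    s1_events = [
        StimulusEvent(nodes, 10.0 + k * s1_bcl, dur, amp) for k in range(n_s1)
    ]
    t_last_s1 = 10.0 + (n_s1 - 1) * s1_bcl
    drive.run(t_last_s1 + 240.0, s1_events)
    base = drive.state.copy()
    base_traces = (list(drive.trace_t), {k: list(v) for k, v in drive.traces.items()})

    # slow-lane end probes: antegrade beats activate the entrance (cavity)
    # end first; a blocked premature beat activates the lane retrogradely,
    # exit end first -- the unidirectional-block signature
    lane_probes = {}
    if "ci_slow_lane" in grid.regions and len(grid.regions["ci_slow_lane"]):
        lane = grid.regions["ci_slow_lane"]
        ys = grid.coords(lane)[:, 1]
        span = ys.max() - ys.min()
        lane_probes["_sl_entry"] = lane[ys <= ys.min() + span / 4]
        lane_probes["_sl_exit"] = lane[ys >= ys.max() - span / 4]
    attempts = []

    def try_premature(intervals):
        """Run S2(,S3) at the given coupling intervals from the last S1."""
        sim = setup.sim(state=base, sample_dt=1.0)
        sim.trace_t, sim.traces = list(base_traces[0]), {
            k: list(v) for k, v in base_traces[1].items()
        }
        for pname, pnodes in lane_probes.items():
            sim._rec_local.setdefault(pname, sim.ops.to_local("tissue", pnodes))
            sim.traces.setdefault(pname, [np.nan] * len(sim.trace_t))
        times = []
        t0 = t_last_s1
        for ci in intervals:
            t0 = t0 + ci
            times.append(t0)
        events = [StimulusEvent(nodes, t, dur, amp) for t in times]
        _run_until_quiescent_or(sim, times[-1] + follow, events)
        _extend_for_cycles(sim, times[-1], min_cycles, times[-1] + 2.5 * follow)
        return sim, times[-1]

    # S2 scan
    ci2 = s2_start
    n_att = 0
    captured_any = False
    while ci2 >= floor and n_att < max_attempts:
        sim, s2_t = try_premature([ci2])
        n_att += 1
        t, v = sim.trace(REFERENCE_SITE)
        series = an.detect_activations(t, v)
        captured = bool((series.times > s2_t - 1.0).sum())
        captured_any |= captured
        res = _reentry_check(sim, s2_t, min_cycles)
        attempts.append(("S2", ci2, captured, res is not None))
        if res is not None:
            return _episode_from(setup, sim, s2_t, res, {"s1_bcl": s1_bcl,
                                 "s2": ci2, "s3": None, "attempts": attempts})
        if not captured:
            break  # capture failure: move to S3
        ci2 -= decrement

    if not captured_any:
        raise NonInducible("S2 never captured at the pacing site")
    # S3: fix S2 at the shortest capturing interval, decrement S3
    s2_fixed = ci2 + decrement if ci2 < s2_start else s2_start
    ci3 = s2_fixed
    while ci3 >= floor and n_att < max_attempts:
        sim, s3_t = try_premature([s2_fixed, ci3])
        n_att += 1
        res = _reentry_check(sim, s3_t, min_cycles)
        t, v = sim.trace(REFERENCE_SITE)
        captured = bool(
            (an.detect_activations(t, v).times > s3_t - 1.0).sum()
        )
        attempts.append(("S3", ci3, captured, res is not None))
        if res is not None:
            return _episode_from(setup, sim, s3_t, res, {"s1_bcl": s1_bcl,
                                 "s2": s2_fixed, "s3": ci3, "attempts": attempts})
        if not captured:
            break
        ci3 -= decrement
    raise NonInducible(
        f"no sustained reentry down to the {floor:.0f} ms coupling floor "
        f"({n_att} attempts)"
    )


def _episode_from(setup, sim, s_t, res, prov):
    post, vtcl, cv = res
    # unidirectional block evidence: after the premature beat the slow lane
    # activates exit-end first (retrograde), the reverse of antegrade beats
    if "_sl_entry" in sim.traces:
        tt = np.asarray(sim.trace_t)

        def first_act(name):
            v = np.asarray(sim.traces[name])
            ok = np.isfinite(v)
            try:
                acts = an.detect_activations(tt[ok], v[ok]).times
            except ValueError:
                return None
            acts = acts[acts > s_t]
            return float(acts[0]) if len(acts) else None

        t_entry, t_exit = first_act("_sl_entry"), first_act("_sl_exit")
        prov["block_one_ended"] = (
            None if t_entry is None or t_exit is None else bool(t_entry > t_exit)
        )
    prov.update({"vtcl_cv": cv, "premature_time": s_t,
                 "bz": getattr(setup.bz, "__dict__", None),
                 "region_factors": dict(setup.region_factors)})
    ep = VTEpisode(setup, sim.state.copy(), vtcl, prov)
    return ep


# ---------------------------------------------------------------------------
# stabilisation and library


def _strip_cv(setup: VTSetup, multiplier: float = 1.0) -> float:
    """Planar longitudinal CV (m/s) for this conductivity setting, measured
    on a healthy strip at the setup's pitch."""
    from .geometry import build_slab_geometry

    strip = build_slab_geometry(
        tissue_size=(2.0, 0.15),
        spacing=setup.grid.spacing,
        scar=None,
        bath=(0.0, 0.0),
    )
    cset = setup.cset
    if multiplier != 1.0:
        cset = replace(
            cset,
            sigma_il=cset.sigma_il * multiplier,
            sigma_el=cset.sigma_el * multiplier,
            sigma_it=cset.sigma_it * multiplier,
            sigma_et=cset.sigma_et * multiplier,
        )
    ops = assemble(strip, cset)
    models = ModelMap.uniform(setup.healthy.build(), len(ops.active_nodes))
    return an.measure_cv(strip, ops, models, direction="x", dt=setup.dt)


def stabilize_vt(
    episode: VTEpisode,
    conductivity_multiplier: float = 1.0,
    cv_bound: float = 0.60,
    n_cycles: int = 3,
    cv_cycle_tol: float = 0.05,
) -> VTEpisode:
    """Normalise the border-zone ionic properties to healthy tissue (longer
    border-zone action potentials are anti-arrhythmic and attenuate
    sustenance) and optionally scale the tissue conductivities, subject to a
    measured conduction-velocity change of at most ``cv_bound`` (60%).

    Re-simulates >= ``n_cycles`` cycles and requires a monomorphic rhythm
    (cycle-length coefficient of variation below ``cv_cycle_tol``).
    """
    setup = episode.setup
    if conductivity_multiplier != 1.0:
        cv0 = _strip_cv(setup, 1.0)
        cv1 = _strip_cv(setup, conductivity_multiplier)
        change = abs(cv1 - cv0) / cv0
        if change > cv_bound:
            raise ValueError(
                f"conductivity multiplier {conductivity_multiplier} changes CV "
                f"by {change:.0%} (measured {cv0:.3f} -> {cv1:.3f} m/s), "
                f"exceeding the {cv_bound:.0%} bound"
            )
        cset = setup.cset
        cset = replace(
            cset,
            sigma_il=cset.sigma_il * conductivity_multiplier,
            sigma_el=cset.sigma_el * conductivity_multiplier,
            sigma_it=cset.sigma_it * conductivity_multiplier,
            sigma_et=cset.sigma_et * conductivity_multiplier,
        )
        new_setup = VTSetup(
            grid=setup.grid, cset=cset, region_factors=dict(setup.region_factors),
            healthy=setup.healthy, bz=None, dt=setup.dt, dt_shock=setup.dt_shock,
        )
    else:
        new_setup = setup.variant(bz=setup.healthy)
    sim = new_setup.sim(state=episode.checkpoint, sample_dt=1.0)
    sim.run(episode.checkpoint.t + (n_cycles + 2.5) * episode.vtcl)
    series = an.detect_activations(*sim.trace(episode.reference_site))
    post = series.times[series.times > episode.checkpoint.t]
    if len(post) < n_cycles + 1 or _active_vm_max(sim) < QUIESCENT_MV:
        raise StabilizationFailed(
            "reentry died during border-zone normalisation"
        )
    gaps = np.diff(post)
    vtcl = float(gaps[-min(5, len(gaps)):].mean())
    cv = float(gaps[-min(5, len(gaps)):].std() / vtcl)
    if cv > cv_cycle_tol:
        raise StabilizationFailed(
            f"rhythm not monomorphic after stabilisation (cycle CV {cv:.1%})"
        )
    prov = dict(episode.provenance)
    prov.update(
        {"stabilized": True, "conductivity_multiplier": conductivity_multiplier}
    )
    return VTEpisode(new_setup, sim.state.copy(), vtcl, prov,
                     episode.reference_site)


def generate_vt_library(
    base: VTEpisode,
    sweep: list[dict] | None = None,
    n_cycles: int = 5,
    cv_cycle_tol: float = 0.05,
    cv_bound: float = 0.10,
) -> list[VTEpisode]:
    """Generate a library of VT episodes by re-conditioning the base episode.

    Each sweep entry may set ``bz`` (a border-zone CellModel re-applied to
    the BZ label), ``ci_factor`` (conductivity multiplier on the isthmus
    node-set), and ``conductivity_multiplier`` (global tissue scaling,
    subject to a measured-CV change of at most ``cv_bound`` = 10%).  Each
    variant is re-simulated for more than ``n_cycles`` cycles from the base
    checkpoint and kept only when stable and monomorphic; the measured VTCL
    and full provenance are recorded.
    """
    episodes = [base]
    if not sweep:
        return episodes
    cv0 = None
    for entry in sweep:
        rf = dict(base.setup.region_factors)
        if entry.get("ci_factor") is not None:
            rf["CI"] = entry["ci_factor"]
        mult = entry.get("conductivity_multiplier", 1.0)
        if mult != 1.0:
            if cv0 is None:
                cv0 = _strip_cv(base.setup, 1.0)
            cv1 = _strip_cv(base.setup, mult)
            if abs(cv1 - cv0) / cv0 > cv_bound:
                log.warning(
                    "library variant %s dropped: CV change %.0f%% exceeds %.0f%%",
                    entry, 100 * abs(cv1 - cv0) / cv0, 100 * cv_bound,
                )
                continue
        cset = base.setup.cset
        if mult != 1.0:
            cset = replace(
                cset,
                sigma_il=cset.sigma_il * mult, sigma_el=cset.sigma_el * mult,
                sigma_it=cset.sigma_it * mult, sigma_et=cset.sigma_et * mult,
            )
        setup = VTSetup(
            grid=base.setup.grid, cset=cset, region_factors=rf,
            healthy=base.setup.healthy, bz=entry.get("bz"),
            dt=base.setup.dt, dt_shock=base.setup.dt_shock,
        )
        sim = setup.sim(state=base.checkpoint, sample_dt=1.0)
        _run_until_quiescent_or(sim, base.checkpoint.t + (n_cycles + 2.5) * base.vtcl)
        series = an.detect_activations(*sim.trace(base.reference_site))
        post = series.times[series.times > base.checkpoint.t]
        # a variant may rotate slower than the base: extend until enough
        # cycles are observed (up to 2x the nominal follow-up)
        t_cap = base.checkpoint.t + 2.0 * (n_cycles + 2.5) * base.vtcl
        while (
            len(post) >= 3
            and len(post) < n_cycles + 1
            and _active_vm_max(sim) >= QUIESCENT_MV
            and sim.state.t < t_cap
        ):
            gap = float(np.diff(post)[-3:].mean())
            need = (n_cycles + 1 - len(post)) * gap + 0.5 * gap
            _run_until_quiescent_or(sim, min(sim.state.t + need, t_cap))
            series = an.detect_activations(*sim.trace(base.reference_site))
            post = series.times[series.times > base.checkpoint.t]
        if len(post) < n_cycles + 1 or _active_vm_max(sim) < QUIESCENT_MV:
            log.warning("library variant %s not sustained; dropped", entry)
            continue
        gaps = np.diff(post)
        vtcl = float(gaps[-5:].mean())
        cv = float(gaps[-5:].std() / vtcl)
        if cv > cv_cycle_tol:
            log.warning("library variant %s not monomorphic (CV %.1f%%)", entry,
                        100 * cv)
            continue
        prov = dict(base.provenance)
        prov.update({"library_variant": entry, "vtcl_cv": cv})
        episodes.append(
            VTEpisode(setup, sim.state.copy(), vtcl, prov, base.reference_site)
        )
    if not episodes:
        raise RuntimeError("empty VT library: widen the sweep")
    return episodes


# ---------------------------------------------------------------------------
# anti-tachycardia pacing


def atp_schedule(
    vtcl: float,
    t_last: float,
    proto: PacingProtocol,
    sequence: int = 1,
    refractory_floor: float = 50.0,
) -> list[float]:
    """Pulse times for one burst sequence.

    Sequence 1 paces at ``interval_fraction`` x VTCL starting that same
    interval after ``t_last`` (the last sensed activation at the site);
    sequence 2 uses an interval 10 ms shorter.  An interval at or below the
    absolute refractory floor is rejected.
    """
    if vtcl <= 0:
        raise ValueError("vtcl must be positive")
    if sequence < 1 or sequence > proto.n_sequences:
        return []
    interval = proto.interval_fraction * vtcl
    if sequence == 2:
        interval -= proto.second_seq_shortening
    if interval <= refractory_floor:
        raise ValueError(
            f"pacing interval {interval:.0f} ms at or below the "
            f"{refractory_floor:.0f} ms refractory floor"
        )
    start = t_last + proto.interval_fraction * vtcl
    if sequence == 2:
        start = t_last + interval
    return [start + k * interval for k in range(proto.pulses_per_seq)]


def _last_activation(sim, site_name, after=-np.inf):
    t, v = sim.trace(site_name)
    series = an.detect_activations(t, v)
    sel = series.times[series.times > after]
    return float(sel[-1]) if len(sel) else None


def run_atp(
    episode: VTEpisode,
    proto: PacingProtocol,
    window_factor: float = 3.0,
) -> TherapyOutcome:
    """Deliver burst pacing from the protocol's site block and judge the
    outcome.

    The site trace is sensed from the checkpoint; each sequence starts at the
    rule time after the last sensed site activation (re-sensed between
    sequences under the default gap rule), stimuli are transmembrane current
    over the site block, and termination requires a silent reference site
    over ``window_factor`` x VTCL plus global repolarisation.
    """
    setup = episode.setup
    site_nodes = proto.site.all_nodes
    site_active = site_nodes[
        np.isin(site_nodes, setup.ops.active_nodes, assume_unique=False)
    ]
    rec = {"_atp_site": site_active}
    sim = setup.sim(state=episode.checkpoint, record=rec, sample_dt=0.5)
    t0 = episode.checkpoint.t
    # sense the site for up to 1.5 cycles
    sim.run(t0 + 1.5 * episode.vtcl)
    t_last = _last_activation(sim, "_atp_site", after=t0)
    if t_last is None:
        raise RuntimeError("no activation sensed at the pacing site")
    events = []
    vtcl = episode.vtcl
    seq1 = atp_schedule(vtcl, t_last, proto, sequence=1)
    if seq1:
        events = [StimulusEvent(site_active, t, proto.pulse_duration,
                                proto.amplitude) for t in seq1]
        sim.run(seq1[-1] + proto.pulse_duration + 50.0, events)
    if proto.n_sequences >= 2 and seq1:
        if proto.gap_rule == "resense":
            t_last2 = _last_activation(sim, "_atp_site", after=seq1[-1])
            t_last2 = t_last2 if t_last2 is not None else seq1[-1]
        else:
            t_last2 = seq1[-1]
        seq2 = atp_schedule(vtcl, t_last2, proto, sequence=2)
        ev2 = [StimulusEvent(site_active, t, proto.pulse_duration,
                             proto.amplitude) for t in seq2]
        sim.run(seq2[-1] + proto.pulse_duration, ev2)
    therapy_end = sim.state.t
    terminated, series = _judge(sim, episode, therapy_end, window_factor)
    last = series.times[-1] if len(series) else np.nan
    return TherapyOutcome(
        therapy="atp",
        strength=proto.amplitude,
        terminated=terminated,
        vt_class=episode.vt_class,
        vtcl=vtcl,
        time_of_last_activation=float(last),
        post_window_used=window_factor * episode.vtcl,
        detail={"n_sequences": proto.n_sequences},
    )


# ---------------------------------------------------------------------------
# shocks


def with_electrodes(episode: VTEpisode, place_fn):
    """Re-host an episode on a grid clone carrying one electrode layout.

    Electrode placement relabels bath nodes (insulating cores), so the
    extracellular operator must be assembled after placement; cloning keeps
    layouts independent.  Tissue node ordering is identical across clones,
    so the checkpoint (and any cached pre-roll states) transfer unchanged.

    Returns ``(episode_on_clone, electrode_set)`` where ``place_fn(grid)``
    performs the placement.
    """
    setup = episode.setup
    grid2 = setup.grid.clone()
    electrodes = place_fn(grid2)
    if not np.array_equal(
        grid2.flat(grid2.tissue_mask), setup.grid.flat(setup.grid.tissue_mask)
    ):
        raise ValueError("electrode placement altered tissue nodes")
    setup2 = VTSetup(
        grid=grid2,
        cset=setup.cset,
        region_factors=dict(setup.region_factors),
        healthy=setup.healthy,
        bz=setup.bz,
        dt=setup.dt,
        dt_shock=setup.dt_shock,
    )
    ep2 = VTEpisode(
        setup2,
        episode.checkpoint.copy(),
        episode.vtcl,
        dict(episode.provenance),
        episode.reference_site,
    )
    # monodomain dynamics are electrode-independent: pre-rolls transfer
    ep2._onset_cache = dict(episode._onset_cache)
    return ep2, electrodes


def _judge(sim, episode, therapy_end, window_factor, cap_factor=3.0):
    """Run the post-therapy follow-up and return the termination verdict.

    The follow-up extends until the final ``window_factor x VTCL`` window is
    free of reference-site activations (a shock can leave activity that
    degenerates and dies a few hundred ms later) or until
    ``cap_factor`` x window of post-therapy time has elapsed with activity
    still present -- then the arrhythmia is judged sustained.
    """
    window = window_factor * episode.vtcl
    cap = therapy_end + cap_factor * window
    _run_until_quiescent_or(sim, therapy_end + window + 2.0)
    while True:
        series = an.detect_activations(*sim.trace(episode.reference_site))
        last = series.times[-1] if len(series) else -np.inf
        needed = max(therapy_end, last) + window + 2.0
        if sim.state.t >= needed - 1e-9:
            break
        if needed > cap:
            sim.run(min(needed, cap))
            series = an.detect_activations(*sim.trace(episode.reference_site))
            break
        _run_until_quiescent_or(sim, needed)
        sim.run(needed)
    sim.run(max(sim.state.t, therapy_end + window + 2.0))
    series = an.detect_activations(*sim.trace(episode.reference_site))
    terminated = an.is_terminated(
        series, episode.vtcl, therapy_end, sim.state.t, _active_vm_max(sim),
        window_factor,
    )
    return terminated, series


def _state_at_onset(episode: VTEpisode, fraction: float) -> TissueState:
    """Monodomain pre-roll to the shock onset time (fraction of the VTCL
    after the last sensed activation at the reference site); cached per
    episode so a strength search shares one pre-roll."""
    key = round(fraction, 6)
    if key in episode._onset_cache:
        return episode._onset_cache[key]
    setup = episode.setup
    sim = setup.sim(state=episode.checkpoint, sample_dt=0.5)
    t0 = episode.checkpoint.t
    sim.run(t0 + 1.3 * episode.vtcl)
    t_last = _last_activation(sim, episode.reference_site, after=t0)
    if t_last is None:
        raise RuntimeError("no activation sensed at the reference site")
    onset = t_last + fraction * episode.vtcl
    if onset < sim.state.t:
        onset += episode.vtcl  # next cycle, same phase
    sim.run(onset)
    episode._onset_cache[key] = (sim.state.copy(), t_last)
    return episode._onset_cache[key]


def run_shock(
    episode: VTEpisode,
    shock: ShockSpec,
    window_factor: float = 3.0,
) -> TherapyOutcome:
    """Deliver one monophasic shock at the protocol's timing rule and judge the
    outcome.

    Monodomain pre-roll resolves the onset (fraction of VTCL after the last
    sensed reference-site activation), the 5 ms pulse runs under the full
    bidomain system with Dirichlet electrode faces, and the follow-up is
    monodomain over at least ``window_factor`` x VTCL.
    """
    onset_state, t_last = _state_at_onset(episode, shock.onset_fraction)
    setup = episode.setup
    sim = setup.sim(state=onset_state, sample_dt=0.5)
    sim.deliver_shock(shock)
    therapy_end = sim.state.t
    terminated, series = _judge(sim, episode, therapy_end, window_factor)
    last = series.times[-1] if len(series) else np.nan
    return TherapyOutcome(
        therapy=shock.electrodes.geometry_tag,
        strength=shock.voltage,
        terminated=terminated,
        vt_class=episode.vt_class,
        vtcl=episode.vtcl,
        time_of_last_activation=float(last),
        post_window_used=window_factor * episode.vtcl,
        detail={
            "onset_fraction": shock.onset_fraction,
            "energy_J": an.shock_energy(abs(shock.voltage)),
        },
    )


def find_min_strength(
    episode: VTEpisode,
    electrodes: ElectrodeSet,
    step: float,
    vmax: float,
    fraction: float = 0.88,
    duration: float = 5.0,
    _cache: dict | None = None,
):
    """Smallest voltage on the grid {step, 2*step, ...} <= vmax that
    terminates the episode.

    The linear bottom-up scan guarantees by construction that the returned
    strength terminates while (returned - step) does not (both outcomes are
    simulated).  Returns :data:`NotFound` when the cap is reached without
    success.  Outcomes are memoised in ``_cache`` (voltage -> TherapyOutcome)
    so sweeps and verification reuse runs.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    cache = _cache if _cache is not None else {}
    v = step
    while v <= vmax + 1e-9:
        if v not in cache:
            cache[v] = run_shock(
                episode,
                ShockSpec(electrodes, v, duration=duration,
                          onset_fraction=fraction),
            )
        if cache[v].terminated:
            return v
        v += step
    return NotFound


def timing_sweep(
    episodes: list[VTEpisode],
    electrodes: ElectrodeSet,
    fractions=(0.50, 0.60, 0.70, 0.80, 0.88),
    step: float = 10.0,
    vmax: float = 300.0,
) -> pd.DataFrame:
    """Minimum termination strength versus delivery timing.

    For each timing fraction: the per-episode minimum strengths, their mean
    over successful episodes only (failed episodes are excluded from the
    mean, as in the reference averaging rule), and the failure count.
    """
    if not episodes:
        raise ValueError("need at least one episode")
    rows = []
    for frac in fractions:
        mins = []
        failures = 0
        for ep in episodes:
            v = find_min_strength(ep, electrodes, step, vmax, fraction=frac)
            if v is NotFound:
                failures += 1
                mins.append(np.nan)
            else:
                mins.append(v)
        ok = [m for m in mins if np.isfinite(m)]
        rows.append(
            {
                "fraction": frac,
                "mean_min_strength": float(np.mean(ok)) if ok else np.nan,
                "n_failures": failures,
                "per_episode": mins,
            }
        )
    return pd.DataFrame(rows)


def select_protocol_strengths(min_strengths: list, quota_partial: int = 5,
                              quota_full: int = 6):
    """Calibration strengths from per-episode minimum termination strengths
    (``NotFound`` allowed): the smallest grid strength terminating at least
    ``quota_partial`` of the episodes, and the smallest terminating all
    ``quota_full``.

    With the default quotas the input is the 6-episode calibration set;
    returns ``(S_pEff, S_fEff)``, either of which may be :data:`NotFound`.
    """
    vals = sorted(v for v in min_strengths if v is not NotFound)
    n = len(min_strengths)

    def quota(k):
        if k > n or len(vals) < k:
            return NotFound
        return vals[k - 1]

    return quota(quota_partial), quota(quota_full)
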