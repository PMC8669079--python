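"""Seed-deterministic fixture generators.

Stand-ins for the undeposited animal data at every analysis stage: synthetic
action-potential trains with known activation times, a passive-cable harness
with its closed-form space constant, and parameterised families of reentrant
episodes generated on the default synthetic infarct.

The default infarct (geometry + border-zone remodelling + induction
protocol) defines the study conditions used throughout the package: a
4.0 x 3.2 cm sheet at 0.025 cm pitch whose 2.0 cm scar band is pierced by a
single 0.4 cm channel containing a thin fibrotic strand; the channel's fast
(healthy) and slow (border-zone) lanes rejoin at both mouths, and programmed
stimulation induces a figure-of-eight reentry circulating through them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import analysis as an
from .geometry import ScarSpec, TissueGrid, build_slab_geometry
from .ionic import CellModel, healthy_porcine, make_bz_model
from .protocols import (
    NonInducible,
    VTEpisode,
    VTSetup,
    generate_vt_library,
    induce_vt,
    stabilize_vt,
)
from .solver import ConductivitySet, S_PER_M_TO_MS_PER_CM, harmonic_mean_tensor

__all__ = [
    "FixtureSpec",
    "make_ap_train",
    "make_passive_cable",
    "default_infarct_grid",
    "default_infarct_setup",
    "DEFAULT_BZ_REDUCTIONS",
    "make_episode_family",
    "cable_lambda",
]

# Calibrated border-zone remodelling for the inducible default episode:
# strong potassium-current reduction (top of the 30-65% remodelled range)
# gives the slow lane the long refractoriness that blocks the premature
# beat; the mild sodium reduction slows its upstroke without making the
# lane inexcitable at this pitch.
DEFAULT_BZ_REDUCTIONS = (0.65, 0.65, 0.30)


@dataclass(frozen=True)
class FixtureSpec:
    """Seeded fixture request; identical seed+params give bit-identical
    fixtures."""

    seed: int = 0
    family: str = "ap_train"
    params: dict = field(default_factory=dict)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


def _ap_pulse(t, onset, apd, upstroke=1.0, v_rest=-80.0, v_peak=20.0):
    """Smooth action-potential-shaped pulse: fast upstroke, plateau, and a
    repolarisation steep enough that the trace does not dwell near typical
    sensing thresholds."""
    x = t - onset
    rise = _sigmoid(x / (upstroke / 4.0))
    fall = _sigmoid(-(x - apd) / (apd / 30.0))
    return (v_peak - v_rest) * rise * fall


def make_ap_train(spec: FixtureSpec):
    """Synthetic V_m(t) trace of evenly spaced action potentials plus the
    ground-truth activation times.

    params: ``n_pulses`` (default 5), ``period`` ms (300), ``apd`` ms (180),
    ``dt`` ms (0.5), ``noise_sd`` mV (0), ``t_start`` ms (20).
    Returns ``(t, vm, true_times)``.
    """
    p = {"n_pulses": 5, "period": 300.0, "apd": 180.0, "dt": 0.5,
         "noise_sd": 0.0, "t_start": 20.0, "v_rest": -80.0}
    p.update(spec.params)
    if p["n_pulses"] > 0 and p["period"] <= an.REFRACTORY_GATE:
        raise ValueError("period must exceed the refractory gate")
    t_end = p["t_start"] + max(p["n_pulses"], 1) * p["period"]
    t = np.arange(0.0, t_end, p["dt"])
    vm = np.full_like(t, p["v_rest"])
    true_times = np.array(
        [p["t_start"] + k * p["period"] for k in range(p["n_pulses"])]
    )
    for onset in true_times:
        vm = vm + _ap_pulse(t, onset, p["apd"], v_rest=p["v_rest"])
    if p["noise_sd"] > 0:
        vm = vm + spec.rng().normal(0.0, p["noise_sd"], size=t.shape)
    return t, vm, true_times


def cable_lambda(c: ConductivitySet | None = None, g_m: float = 1.0) -> float:
    """Closed-form steady-state space constant lambda = sqrt(sigma_ml /
    (beta g_m)) in cm, with the longitudinal harmonic-mean conductivity in
    mS/cm, beta in 1/cm and the passive membrane conductance g_m in
    mS/cm^2."""
    c = c or ConductivitySet()
    sml = harmonic_mean_tensor(c)[0] * S_PER_M_TO_MS_PER_CM
    return float(np.sqrt(sml / (c.beta * g_m)))


def make_passive_cable(spec: FixtureSpec):
    """1-D passive-cable fixture plus its analytic steady-state profile.

    params: ``g_m`` mS/cm^2 (1.0), ``length_lambdas`` (12), ``dx_lambdas``
    (1/20 of lambda, capped at 0.025 cm).  Returns ``(grid, cset, g_m,
    lam, profile)`` where ``profile(x, v0)`` is the sealed-end analytic
    solution for a clamp of amplitude v0 above rest at x = 0.
    """
    p = {"g_m": 1.0, "length_lambdas": 12.0, "dx_over_lambda": 1.0 / 20.0}
    p.update(spec.params)
    if p["length_lambdas"] < 10.0:
        raise ValueError("cable must be at least 10 space constants long")
    cset = ConductivitySet()
    lam = cable_lambda(cset, p["g_m"])
    dx = min(0.025, p["dx_over_lambda"] * lam)
    length = p["length_lambdas"] * lam
    grid = build_slab_geometry(
        tissue_size=(length, 2 * dx), spacing=dx, scar=None, bath=(0.0, 0.0)
    )

    def profile(x, v0):
        L = length
        return v0 * np.cosh((L - np.asarray(x)) / lam) / np.cosh(L / lam)

    return grid, cset, p["g_m"], lam, profile


def default_infarct_grid(
    spacing: float = 0.025,
    bath: tuple[float, float] = (1.2, 1.2),
) -> TissueGrid:
    """The study's synthetic infarct lattice (see module docstring)."""
    return build_slab_geometry(
        tissue_size=(4.0, 3.2),
        spacing=spacing,
        scar=ScarSpec(),
        bath=bath,
    )


def default_infarct_setup(
    grid: TissueGrid | None = None,
    bz_reductions: tuple[float, float, float] = DEFAULT_BZ_REDUCTIONS,
    base: str = "reduced",
    ci_factor: float | None = None,
) -> VTSetup:
    """Simulation context for the default infarct with the calibrated
    border-zone remodelling."""
    grid = grid if grid is not None else default_infarct_grid()
    rf = {} if ci_factor is None else {"CI": ci_factor}
    return VTSetup(
        grid=grid,
        healthy=healthy_porcine(base=base),
        bz=make_bz_model(*bz_reductions, base=base),
        region_factors=rf,
    )


# Conductivity factors applied to the isthmus node-set for the episode
# family: slower channel conduction lengthens the cycle (the long-channel
# regime), faster conduction shortens it into the fast-VT class.
DEFAULT_CI_FACTORS = (0.6, 1.0, 1.5, 2.5)


def make_episode_family(
    spec: FixtureSpec,
    grid: TissueGrid | None = None,
    setup: VTSetup | None = None,
    base_episode: VTEpisode | None = None,
):
    """Family of stabilised reentrant episodes spanning slow and fast
    classes.

    Induces the base episode on the default infarct (S1 x 3 at 500 ms, S2
    decremented by 10 ms), normalises the border zone, then sweeps the
    isthmus conductivity factor (params: ``ci_factors``, default
    ``DEFAULT_CI_FACTORS``; ``s2_start`` to shorten the induction scan).
    Returns ``(episodes, noninducible)`` where ``noninducible`` lists sweep
    points that produced no stable episode.  ``n_episodes`` caps the family
    size; 0 returns an empty family.
    """
    p = {"ci_factors": DEFAULT_CI_FACTORS, "s2_start": 500.0,
         "n_episodes": None}
    p.update(spec.params)
    if p["n_episodes"] == 0:
        return [], []
    if setup is None:
        setup = default_infarct_setup(grid)
    failed: list = []
    if base_episode is None:
        try:
            raw = induce_vt(setup, s2_start=p["s2_start"])
        except NonInducible as e:
            return [], [{"stage": "induction", "reason": str(e)}]
        base_episode = stabilize_vt(raw)
    sweep = [
        {"ci_factor": f} for f in p["ci_factors"] if f != 1.0
    ]
    episodes = generate_vt_library(base_episode, sweep)
    if p["n_episodes"] is not None:
        episodes = episodes[: p["n_episodes"]]
    produced = {e.provenance.get("library_variant", {}).get("ci_factor", 1.0)
                for e in episodes}
    failed.extend(
        {"stage": "library", "ci_factor": f}
        for f in p["ci_factors"]
        if f not in produced
    )
    return episodes, failed
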