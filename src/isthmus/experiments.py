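"""End-to-end experiment orchestration.

``run_experiment`` executes a validated config: build the synthetic infarct,
induce and stabilise the base reentry, generate the episode library, apply
the enabled therapies, and write the efficacy table, energy report and
minimum-strength table (with full provenance) to the output directory.
``report`` renders a bundle as a human-readable markdown summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis as an
from .config import ExperimentConfig, load_config
from .geometry import (
    FiberRule,
    ScarSpec,
    build_slab_geometry,
    place_atp_site,
    place_bipolar_array,
    place_transmural_pair,
)
from .ionic import healthy_porcine, make_bz_model
from .protocols import (
    NonInducible,
    NotFound,
    PacingProtocol,
    ShockSpec,
    VTSetup,
    find_min_strength,
    generate_vt_library,
    induce_vt,
    run_atp,
    run_shock,
    stabilize_vt,
    with_electrodes,
)
from .solver import ConductivitySet

log = logging.getLogger(__name__)

__all__ = ["ResultBundle", "run_experiment", "report"]


class StageError(RuntimeError):
    """A pipeline stage failed; partial artifacts are preserved on disk."""

    def __init__(self, stage, cause):
        super().__init__(f"experiment failed at stage {stage!r}: {cause}")
        self.stage = stage


@dataclass
class ResultBundle:
    config: ExperimentConfig
    outdir: Path
    vtcls: list[float] = field(default_factory=list)
    efficacy: an.EfficacyTable | None = None
    min_strengths: dict = field(default_factory=dict)
    energy: dict = field(default_factory=dict)
    outcomes: list = field(default_factory=list)
    noninducible: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def run_experiment(config: ExperimentConfig | str | Path) -> ResultBundle:
    """Run the full pipeline for a config (path or object); artifacts land
    under ``config.outdir``.  Any stage failure raises :class:`StageError`
    naming the stage, with artifacts from completed stages preserved."""
    cfg = config if isinstance(config, ExperimentConfig) else load_config(config)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ResultBundle(cfg, outdir)
    bundle.provenance = {
        "seed": cfg.seed,
        "stage_seeds": {s: cfg.stage_seed(s) for s in
                        ["geometry", "induction", "library", "therapy", "analysis"]},
        "config": cfg.model_dump(),
    }

    stage = "geometry"
    try:
        g = cfg.geometry
        scar = (
            ScarSpec(
                band_thickness=g.band_thickness,
                isthmus_width=g.isthmus_width,
                bz_rim=g.bz_rim,
                ci_bz_fraction=g.ci_bz_fraction,
                islet_width=g.islet_width,
                islet_margin=g.islet_margin,
            )
            if g.scar
            else None
        )
        grid = build_slab_geometry(
            tissue_size=g.tissue_size,
            spacing=g.spacing,
            scar=scar,
            bath=g.bath,
            fiber=FiberRule(angle=g.fiber_angle),
        )
        cset = ConductivitySet(
            bz_factor=cfg.solver.bz_factor,
            sigma_scar=cfg.solver.sigma_scar,
            sigma_bath=cfg.solver.sigma_bath,
        )
        setup = VTSetup(
            grid=grid,
            cset=cset,
            healthy=healthy_porcine(base=cfg.models.base),
            bz=make_bz_model(*cfg.models.bz_reductions, base=cfg.models.base),
            dt=cfg.solver.dt,
            dt_shock=cfg.solver.dt_shock,
        )

        stage = "induction"
        ind = cfg.induction
        try:
            raw = induce_vt(
                setup,
                s1_bcl=ind.s1_bcl,
                n_s1=ind.n_s1,
                s2_start=ind.s2_start,
                decrement=ind.decrement,
                floor=ind.floor,
            )
        except NonInducible as e:
            bundle.noninducible.append({"stage": "induction", "reason": str(e)})
            _write(bundle)
            return bundle
        base = stabilize_vt(raw)

        stage = "library"
        sweep = [{"ci_factor": f} for f in cfg.library.ci_factors if f != 1.0]
        episodes = generate_vt_library(base, sweep, n_cycles=cfg.library.n_cycles)
        bundle.vtcls = [e.vtcl for e in episodes]

        stage = "therapy"
        rng = np.random.default_rng(cfg.stage_seed("therapy"))
        outcomes = []
        if cfg.therapies.atp.enabled:
            site = place_atp_site(grid)
            proto = PacingProtocol(
                site=site,
                amplitude=cfg.therapies.atp.amplitude,
                pulse_duration=cfg.therapies.atp.pulse_duration,
                n_sequences=cfg.therapies.atp.n_sequences,
                pulses_per_seq=cfg.therapies.atp.pulses_per_seq,
            )
            for ep in episodes:
                outcomes.append(run_atp(ep, proto,
                                        window_factor=cfg.analysis.window_factor))
        for name, tc in (
            ("transmural", cfg.therapies.transmural),
            ("bipolar", cfg.therapies.bipolar),
        ):
            if not tc.enabled:
                continue
            if name == "transmural":
                place = lambda g: place_transmural_pair(
                    g, cube_edge=tc.cube_edge, clearance=tc.clearance
                )
            else:
                place = lambda g: place_bipolar_array(
                    g, cube_edge=tc.cube_edge, spacing=tc.spacing
                )
            mins = []
            for i, ep in enumerate(episodes):
                ep2, electrodes = with_electrodes(ep, place)
                cache: dict = {}
                v = find_min_strength(
                    ep2, electrodes, step=tc.step, vmax=tc.vmax,
                    fraction=tc.fraction, _cache=cache,
                )
                mins.append(v)
                outcomes.extend(cache.values())
            bundle.min_strengths[name] = [
                None if m is NotFound else m for m in mins
            ]
            ok = [m for m in mins if m is not NotFound]
            if ok:
                bundle.energy[name] = {
                    "mean_min_strength_V": float(np.mean(ok)),
                    "energy_at_mean_J": an.shock_energy(
                        float(np.mean(ok)), cfg.analysis.capacitance
                    ),
                }
        bundle.outcomes = outcomes

        stage = "analysis"
        if outcomes:
            bundle.efficacy = an.efficacy(outcomes)
        _write(bundle)
    except StageError:
        raise
    except Exception as e:  # preserve partial artifacts, name the stage
        _write(bundle)
        raise StageError(stage, e) from e
    return bundle


def _write(bundle: ResultBundle) -> None:
    out = bundle.outdir
    if bundle.outcomes:
        pd.DataFrame(
            [
                {
                    "therapy": o.therapy,
                    "strength": o.strength,
                    "terminated": o.terminated,
                    "vt_class": o.vt_class,
                    "vtcl_ms": o.vtcl,
                }
                for o in bundle.outcomes
            ]
        ).to_csv(out / "outcomes.csv", index=False)
    if bundle.efficacy is not None:
        bundle.efficacy.to_csv(out / "efficacy.csv")
    summary = {
        "vtcls_ms": bundle.vtcls,
        "min_strengths_V": bundle.min_strengths,
        "energy": bundle.energy,
        "noninducible": bundle.noninducible,
        "provenance": bundle.provenance,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))


def report(bundle: ResultBundle) -> str:
    """Markdown summary of a result bundle (efficacy, minimum strengths,
    energies, library statistics); incomplete bundles are flagged."""
    lines = ["# Experiment report", ""]
    complete = True
    if bundle.vtcls:
        arr = np.asarray(bundle.vtcls)
        lines += [
            "## VT library",
            f"- {len(arr)} episodes, VTCL {arr.min():.0f}-{arr.max():.0f} ms "
            f"(median {np.median(arr):.0f} ms)",
            f"- classes: {sum(v <= an.FAST_VT_BOUNDARY_MS for v in arr)} fast, "
            f"{sum(v > an.FAST_VT_BOUNDARY_MS for v in arr)} slow",
            "",
        ]
    else:
        complete = False
        lines += ["## VT library", "- (no episodes)", ""]
    if bundle.efficacy is not None:
        lines += ["## Efficacy", bundle.efficacy.frame.to_string(index=False), ""]
    else:
        complete = False
    if bundle.min_strengths:
        lines.append("## Minimum termination strengths")
        for name, mins in bundle.min_strengths.items():
            shown = ["-" if m is None else f"{m:.0f} V" for m in mins]
            lines.append(f"- {name}: {', '.join(shown)}")
        lines.append("")
    if bundle.energy:
        lines.append("## Shock energy (capacitive discharge)")
        for name, e in bundle.energy.items():
            lines.append(
                f"- {name}: mean min strength {e['mean_min_strength_V']:.0f} V "
                f"-> {e['energy_at_mean_J']:.2g} J"
            )
        lines.append("")
    if bundle.noninducible:
        lines.append(f"- non-inducible points: {bundle.noninducible}")
    if not complete:
        lines.append("**partial report: some stages produced no results**")
    return "\n".join(lines)
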