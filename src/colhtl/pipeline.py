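"""End-to-end pipeline: simulate -> dose -> measure -> analyse.

Stage order mirrors the study design: generate the crossover cohort, plan
the CO dosing schedule and its carboxyhaemoglobin time course, account the
accumulated hypoxic dose, simulate and then re-estimate every outcome
(rebreathing haematology in duplicate, NIRS recovery constant, lactate
threshold speeds), and finally run the crossover statistics.  A manifest
records the seed, the full configuration and its hash, so identical configs
produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    Cohort,
    CrossoverDesign,
    OcclusionProtocol,
    ParticipantState,
    ResponseModel,
    generate_cohort,
    simulate_lactate_trials,
    simulate_rebreathing_record,
    simulate_tsi_trace,
)
from .dosing import DosingPlanParams, simulate_schedule
from .hypoxic import EquivalenceParams, accumulate_dose
from .markers import speed_at_lactate
from .nirs import fit_recovery_k, normalize_pn, occlusion_slopes
from .rebreathe import HaemConstants, derive_volumes, hbmass_from_rebreathing
from .stats import EffectEstimate, ancova_treatment, change_anova
from .tableio import CROSSOVER_SCHEMA, write_table

log = logging.getLogger("colhtl")

__all__ = ["PipelineConfig", "StatsOptions", "run_pipeline", "measure_cohort"]

OUTCOMES = (
    "hbmass_g", "hbmass_rel", "rbcv_ml", "pv_ml", "bv_ml",
    "k_min", "speed4_ms", "speed2_ms", "la_max_mm",
)


@dataclass(frozen=True)
class StatsOptions:
    period_term: bool = False
    subject_diff: bool = False


def _from_dict(cls, data: dict[str, Any]):
    """Strict dataclass construction: unknown keys are rejected."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{cls.__name__}: unknown config keys {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
    return cls(**kwargs)


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    dose_kmh: float = 847.9
    design: CrossoverDesign = field(default_factory=CrossoverDesign)
    response: ResponseModel = field(default_factory=ResponseModel)
    dosing: DosingPlanParams = field(default_factory=DosingPlanParams)
    equivalence: EquivalenceParams = field(default_factory=EquivalenceParams)
    haem: HaemConstants = field(default_factory=HaemConstants)
    nirs_protocol: OcclusionProtocol = field(default_factory=OcclusionProtocol)
    stats: StatsOptions = field(default_factory=StatsOptions)

    _SECTIONS = {
        "design": CrossoverDesign,
        "response": ResponseModel,
        "dosing": DosingPlanParams,
        "equivalence": EquivalenceParams,
        "haem": HaemConstants,
        "nirs_protocol": OcclusionProtocol,
        "stats": StatsOptions,
    }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        scalars = {"seed", "dose_kmh"}
        unknown = set(data) - scalars - set(cls._SECTIONS)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        kwargs: dict[str, Any] = {k: data[k] for k in scalars if k in data}
        for key, sub_cls in cls._SECTIONS.items():
            if key in data:
                kwargs[key] = _from_dict(sub_cls, data[key] or {})
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d))  # tuples -> lists, plain types

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _measure_state(
    state: ParticipantState,
    cfg: PipelineConfig,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Re-estimate every outcome from simulated raw measurements."""
    te = cfg.response.measurement_te_pct
    rec1 = simulate_rebreathing_record(state, te_pct=te, constants=cfg.haem, rng=rng)
    rec2 = simulate_rebreathing_record(state, te_pct=te, constants=cfg.haem, rng=rng)
    hb1 = hbmass_from_rebreathing(rec1, cfg.haem)
    hb2 = hbmass_from_rebreathing(rec2, cfg.haem)
    hbmass = 0.5 * (hb1 + hb2)
    vols = derive_volumes(hbmass, rec1.hb_conc, rec1.hct, cfg.haem, state.body_mass)

    trace = simulate_tsi_trace(
        state, cfg.nirs_protocol, k_cv_pct=cfg.response.nirs_cv_pct, rng=rng
    )
    pn, _ = normalize_pn(trace)
    slopes = occlusion_slopes(trace, pn)
    kfit = fit_recovery_k(slopes)

    trials = simulate_lactate_trials(
        state, noise_sd=cfg.response.lactate_noise_mm, rng=rng
    )
    v4 = speed_at_lactate(trials, 4.0)
    v2 = speed_at_lactate(trials, 2.0)
    la_max = max(t.la_peak for t in trials)

    return {
        "hbmass_g": hbmass,
        "hbmass_rel": hbmass / state.body_mass,
        "rbcv_ml": vols.rbcv,
        "pv_ml": vols.pv,
        "bv_ml": vols.bv,
        "k_min": kfit.k,
        "speed4_ms": v4,
        "speed2_ms": v2,
        "la_max_mm": la_max,
    }


def measure_hbmass_table(
    cohort: Cohort,
    te_pct: float = 2.0,
    constants: HaemConstants = HaemConstants(),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Duplicate-rebreathing Hb_mass measurements only, as a tidy table.

    The cheap path for replicate experiments that need the haematology
    outcome without the NIRS and lactate batteries.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for pt in cohort.periods:
        vals = {}
        for label, state in (("pre", pt.pre), ("post", pt.post)):
            estimates = [
                hbmass_from_rebreathing(
                    simulate_rebreathing_record(
                        state, te_pct=te_pct, constants=constants, rng=rng),
                    constants,
                )
                for _ in range(2)
            ]
            vals[label] = 0.5 * sum(estimates)
        rows.append(
            dict(participant=pt.participant_id, treatment=pt.treatment,
                 period=pt.period, outcome="hbmass_g", **vals)
        )
    return pd.DataFrame(rows)


def measure_cohort(cohort: Cohort, cfg: PipelineConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Simulate the full measurement battery pre and post each period and
    return the tidy crossover table."""
    rows = []
    for pt in cohort.periods:
        pre = _measure_state(pt.pre, cfg, rng)
        post = _measure_state(pt.post, cfg, rng)
        for outcome in OUTCOMES:
            rows.append(
                dict(
                    participant=pt.participant_id,
                    treatment=pt.treatment,
                    period=pt.period,
                    outcome=outcome,
                    pre=pre[outcome],
                    post=post[outcome],
                )
            )
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Run every stage and write the result bundle under ``outdir``.

    Returns a dict with the cohort, the crossover table, per-outcome effect
    estimates, the COHb series summary and the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    log.info("stage simulate: seed=%d n=%d", cfg.seed, cfg.design.n_participants)
    cohort = generate_cohort(
        cfg.design, cfg.response, dose_kmh=cfg.dose_kmh,
        constants=cfg.haem, rng=rng,
    )

    # dosing / kinetics for a representative subject (median Hb_mass)
    hbm = float(np.median([p.true_hbmass for p in cohort.participants]))
    series, events = simulate_schedule(
        hbm, cfg.dosing, days=cfg.design.block_length_days
    )
    kmh_est = accumulate_dose(series.times, series.cohb, series.baseline,
                              cfg.equivalence)
    log.info("stage dosing: %d boluses, mean COHb %.1f%%, dose %.1f km·h",
             len(events), series.time_weighted_mean(), kmh_est)

    table = measure_cohort(cohort, cfg, rng)
    write_table(table, outdir / "crossover_table.csv", CROSSOVER_SCHEMA)

    effects: dict[str, EffectEstimate] = {}
    anova_p: dict[str, float] = {}
    for outcome in OUTCOMES:
        try:
            effects[outcome] = ancova_treatment(
                table, outcome,
                period_term=cfg.stats.period_term,
                subject_diff=cfg.stats.subject_diff,
            )
            anova_p[outcome] = change_anova(table, outcome)[1]
        except ValueError as exc:  # complete-case n too small for this outcome
            log.warning("stage stats: %s skipped (%s)", outcome, exc)

    eff_df = pd.DataFrame(
        [dataclasses.asdict(e) | {"p_change_anova": anova_p.get(e.outcome, np.nan)}
         for e in effects.values()]
    )
    eff_df.to_csv(outdir / "effects.csv", index=False)

    dose_df = pd.DataFrame(
        {"time_h": [e.time_h for e in events],
         "volume_co_ml": [e.volume_co for e in events]}
    )
    dose_df.to_csv(outdir / "dose_events.csv", index=False)

    manifest = {
        "package": "colhtl",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "mean_cohb_pct": round(series.time_weighted_mean(), 3),
        "kmh_estimate": round(kmh_est, 1),
        "n_dose_events": len(events),
    }
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "cohort": cohort,
        "table": table,
        "effects": effects,
        "anova_p": anova_p,
        "cohb_series": series,
        "dose_events": events,
        "kmh_estimate": kmh_est,
        "manifest": manifest,
    }
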