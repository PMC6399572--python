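"""End-to-end analysis: service-cost table, cost-effectiveness synthesis,
break-even solve and sensitivity scenarios, assembled into a deterministic,
machine-readable report bundle.

Every table keeps unrounded values alongside the whole-euro display values
(round-half-up at the final aggregation step only).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

from . import cea as _cea
from .cea import (
    SOCIETAL,
    TrialUnitCosts,
    breakeven_curves,
    build_arm_summary,
    per_consultation_cost,
    run_scenario,
    standard_scenarios,
)
from .costing import (
    AnnuityParams,
    CostComponent,
    _selected,
    aggregate_annual_cost,
    annualize,
    round_half_up,
)
from .errors import TeleceaError
from .io import (
    RunConfig,
    load_cost_config,
    load_distances,
    load_fares,
    load_tariff,
    load_trial_unit_costs,
    sha256_of,
    write_json,
)

log = logging.getLogger("telecea")

__all__ = ["run_full_analysis", "service_cost_report", "synthesis_report"]


def service_cost_report(
    components: Sequence[CostComponent], annuity: AnnuityParams, volume: int = 300
) -> dict:
    """Annual service costs per equipment alternative (the published cost
    table): investment totals, annualized equivalents, subtotals, shared
    additional costs and total annual costs, in whole euros."""
    out: dict = {"volume": volume}
    shared_recurring = sum(
        c.amount for c in components
        if c.alternative == "shared" and c.category == "recurring_annual"
    )
    shared_variable = sum(
        c.amount for c in components
        if c.alternative == "shared" and c.category == "per_consultation"
    )
    additional = shared_recurring + shared_variable * volume
    for label, alternative in (("A", "telemedicine_A"), ("B", "telemedicine_B")):
        selected = _selected(list(components), alternative)
        investment = sum(c.amount for c in selected if c.category == "investment")
        annualized = annualize(investment, annuity)
        own_recurring = sum(
            c.amount for c in selected
            if c.category == "recurring_annual" and c.alternative != "shared"
        )
        summary = aggregate_annual_cost(components, alternative, volume, annuity)
        out[f"alternative_{label}"] = {
            "total_investment": round_half_up(investment),
            "annualized_investment": round_half_up(annualized),
            "subtotal": round_half_up(annualized + own_recurring),
            "total_additional_costs": round_half_up(additional),
            "total_annual_cost": round_half_up(summary.total_annual(volume)),
            "total_annual_cost_unrounded": summary.total_annual(volume),
        }
    std = aggregate_annual_cost(components, "standard", volume, annuity)
    out["standard"] = {
        "total_annual_cost": round_half_up(std.total_annual(volume)),
        "total_annual_cost_unrounded": std.total_annual(volume),
    }
    return out


def synthesis_report(
    components: Sequence[CostComponent],
    unit_costs: TrialUnitCosts,
    annuity: AnnuityParams,
    volume: int = 300,
    equipment_alternative: str = "A",
) -> dict:
    """Cost-and-effectiveness synthesis at the assumed annual workload
    under the societal perspective: service, travel and time costs per
    consultation, incremental cost and QALY gains for both arms."""
    arms = {}
    for arm in ("standard", "telemedicine"):
        service = aggregate_annual_cost(
            components,
            arm if arm == "standard" else f"telemedicine_{equipment_alternative}",
            volume, annuity,
        )
        uc = unit_costs.for_arm(arm)
        total_pc = per_consultation_cost(
            build_arm_summary(components, arm, unit_costs, annuity, volume,
                              equipment_alternative), volume, SOCIETAL
        )
        arms[arm] = {
            "service_annual_cost": round_half_up(service.total_annual(volume)),
            "service_cost_per_consultation": round_half_up(
                service.total_annual(volume) / volume),
            "travel_cost_per_consultation": round_half_up(uc.travel_per_consultation),
            "time_cost_per_consultation": round_half_up(
                uc.production_loss_per_consultation),
            "time_and_travel_per_consultation": round_half_up(
                uc.travel_per_consultation + uc.production_loss_per_consultation),
            "total_cost_per_consultation": round_half_up(total_pc),
            "total_cost_per_consultation_unrounded": total_pc,
            "qaly_gain": (unit_costs.qaly_gain_standard if arm == "standard"
                          else unit_costs.qaly_gain_telemedicine),
        }
    delta = (arms["standard"]["total_cost_per_consultation_unrounded"]
             - arms["telemedicine"]["total_cost_per_consultation_unrounded"])
    out = {
        "volume": volume,
        "perspective": "societal",
        **arms,
        "incremental_cost_per_consultation": round_half_up(delta),
        "incremental_cost_per_consultation_unrounded": delta,
        "incremental_qaly": round(unit_costs.qaly_gain_telemedicine
                                  - unit_costs.qaly_gain_standard, 10),
        "annual_saving_at_volume": float(round_half_up(delta) * volume),
        # Rounding the per-consultation saving before scaling changes the
        # annual figure; both are reported so the sensitivity is auditable.
        "annual_saving_unrounded": delta * volume,
    }
    return out


def _scenario_result_dict(result) -> dict:
    return {
        "scenario": result.scenario,
        "perspective": result.perspective,
        "volume": result.volume,
        "cost_per_consultation_standard": result.cost_per_consultation_standard,
        "cost_per_consultation_telemedicine": result.cost_per_consultation_telemedicine,
        "incremental_cost_per_consultation": result.incremental_cost_per_consultation,
        "incremental_cost_rounded": round_half_up(
            result.incremental_cost_per_consultation),
        "incremental_qaly": result.incremental_qaly,
        "classification": result.classification,
        "icer": result.icer,
        "break_even_volume": (None if result.break_even_volume == float("inf")
                              else int(result.break_even_volume)),
        "annual_saving_at_volume": result.annual_saving_at_volume,
        "annual_saving_unrounded": result.annual_saving_unrounded,
    }


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.output_dir``.

    Emits service-cost, synthesis, break-even, scenario and QALY reports plus
    break-even curve data; the run log records the seed and config checksums
    so identical configs yield byte-identical reports. Any stage failure
    aborts with the stage named.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load-config"
    try:
        cost_cfg = load_cost_config(config.cost_config)
        fares = load_fares(config.fares)
        tariff = load_tariff(config.tariff)
        unit_costs = load_trial_unit_costs(config.unit_costs)
        distances = load_distances(config.unit_costs)

        stage = "trial-data"
        qaly_report: dict = {
            "source": "unit-cost config",
            "standard": {"mean_gain": unit_costs.qaly_gain_standard},
            "telemedicine": {"mean_gain": unit_costs.qaly_gain_telemedicine},
            "p_value": unit_costs.qaly_p_value,
        }
        if config.patients_csv is not None:
            from .io import read_patients
            from .trial import trial_qaly_summary

            patients = read_patients(config.patients_csv)
            qaly_report = trial_qaly_summary(patients, tariff)
            unit_costs = TrialUnitCosts(
                user_fee=unit_costs.user_fee,
                standard=unit_costs.standard,
                telemedicine=unit_costs.telemedicine,
                qaly_gain_standard=qaly_report["standard"]["mean_gain"],
                qaly_gain_telemedicine=qaly_report["telemedicine"]["mean_gain"],
                qaly_p_value=qaly_report["p_value"],
            )
        if config.consultations_csv is not None:
            from .costing import arm_unit_costs
            from .io import read_consultations

            consultations = read_consultations(config.consultations_csv)
            priced = arm_unit_costs(consultations, fares)
            unit_costs = TrialUnitCosts(
                user_fee=fares.user_fee,
                standard=_cea.ArmUnitCosts(
                    travel_per_consultation=priced["standard"]["travel_per_consultation"],
                    production_loss_per_consultation=priced["standard"][
                        "production_loss_per_consultation"],
                ),
                telemedicine=_cea.ArmUnitCosts(
                    travel_per_consultation=priced["telemedicine"][
                        "travel_per_consultation"],
                    production_loss_per_consultation=priced["telemedicine"][
                        "production_loss_per_consultation"],
                ),
                qaly_gain_standard=unit_costs.qaly_gain_standard,
                qaly_gain_telemedicine=unit_costs.qaly_gain_telemedicine,
                qaly_p_value=unit_costs.qaly_p_value,
            )

        stage = "service-costs"
        costs = service_cost_report(cost_cfg.components, cost_cfg.annuity, config.volume)
        write_json(costs, outdir / "service_costs.json")

        stage = "synthesis"
        synthesis = synthesis_report(
            cost_cfg.components, unit_costs, cost_cfg.annuity, config.volume)
        write_json(synthesis, outdir / "synthesis.json")
        write_json(qaly_report, outdir / "qaly.json")

        stage = "scenarios"
        specs = standard_scenarios(
            clinic_mean_km=distances.get("telemedicine_mean_km", 47.0),
            standard_mean_km=distances.get("standard_mean_km", 248.0),
        )
        if config.scenario_names:
            wanted = set(config.scenario_names)
            specs = [s for s in specs if s.name in wanted]
        results = [
            run_scenario(spec, cost_cfg.components, unit_costs, cost_cfg.annuity,
                         config.volume)
            for spec in specs
        ]
        scenarios = [_scenario_result_dict(r) for r in results]
        write_json(scenarios, outdir / "scenarios.json")
        breakeven = {r.scenario: (None if r.break_even_volume == float("inf")
                                  else int(r.break_even_volume)) for r in results}
        write_json(breakeven, outdir / "breakeven.json")

        stage = "curves"
        base = next((r for r in results if r.scenario == "base_case"), results[0])
        variants = {r.scenario: r.summaries["telemedicine"] for r in results
                    if r.perspective == "societal" and r.summaries}
        curves = breakeven_curves(
            base.summaries["standard"], variants, range(1, 601), SOCIETAL)
        curves.to_csv(outdir / "breakeven_curves.csv", index=False)

        stage = "run-log"
        run_log = {
            "seed": config.seed,
            "volume": config.volume,
            "config_checksums": {
                "cost_config": sha256_of(config.cost_config),
                "fares": sha256_of(config.fares),
                "tariff": sha256_of(config.tariff),
                "unit_costs": sha256_of(config.unit_costs),
            },
            "stages": ["load-config", "trial-data", "service-costs", "synthesis",
                       "scenarios", "curves"],
        }
        write_json(run_log, outdir / "run_log.json")
    except TeleceaError as exc:
        raise TeleceaError(f"stage {stage!r} failed: {exc}") from exc
    return {
        "service_costs": costs,
        "synthesis": synthesis,
        "qaly": qaly_report,
        "scenarios": scenarios,
        "breakeven": breakeven,
        "curves": curves,
        "run_log": run_log,
    }
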