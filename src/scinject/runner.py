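"""Scenario orchestration: wire physiology, rheology, depot, pressure and
enzyme models into a single deterministic run."""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .depot import VoxelGrid, build_fields, depot_geometry, geometry_series
from .physiology import AdiposeFlows, adipose_flows
from .pressure import BackflowResult, PressureTrace, simulate_pressure
from .scenario import Scenario

__all__ = ["RunResult", "run", "leakage_table", "average_fold_error"]

log = logging.getLogger("scinject")


@dataclass
class RunResult:
    scenario: Scenario
    flows: AdiposeFlows
    eta_if: float  # mPa·s actually used
    geometry: pd.DataFrame
    trace: PressureTrace
    backflow: Optional[BackflowResult]
    fields: Optional[VoxelGrid]
    provenance: dict


def _config_hash(scenario: Scenario) -> str:
    blob = json.dumps(scenario.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run(scenario: Scenario) -> RunResult:
    """Execute one scenario end to end. Deterministic: the model contains no
    randomness, so identical configs give bit-identical outputs."""
    flows = adipose_flows(scenario.subject)
    eta_if = scenario.tissue.resolve_if_viscosity()
    log.info("scenario %s: eta_IF=%.3f mPa·s, k=%.3g m²",
             scenario.name, eta_if, scenario.tissue.k)

    trace = simulate_pressure(
        scenario.protocol,
        eta_if,
        epsilon=scenario.tissue.epsilon,
        k=scenario.tissue.k,
        skin=scenario.tissue.skin,
        enzyme=scenario.enzyme,
        f_calibration=scenario.f_calibration,
        numerics=scenario.numerics,
    )
    for ph in range(2, 6):
        idx = np.nonzero(trace.phase == ph)[0]
        if idx.size:
            log.info("scenario %s: phase %d enters at t=%.3f s",
                     scenario.name, ph, trace.t[idx[0]])

    geom = geometry_series(
        scenario.protocol.v_inj / 1000.0,
        scenario.protocol.q_inj,
        scenario.tissue.epsilon,
    )

    fields = None
    if scenario.depot.grid_n > 0:
        end_geom = depot_geometry(
            scenario.protocol.t_end,
            scenario.protocol.v_inj / 1000.0,
            scenario.protocol.q_inj,
            scenario.tissue.epsilon,
        )
        fields = build_fields(
            end_geom,
            scenario.depot.profile_params(),
            dose=scenario.depot.dose,
            n=scenario.depot.grid_n,
        )

    return RunResult(
        scenario=scenario,
        flows=flows,
        eta_if=eta_if,
        geometry=geom,
        trace=trace,
        backflow=trace.backflow,
        fields=fields,
        provenance={"config_hash": _config_hash(scenario), "version": __version__},
    )


def average_fold_error(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """AFE = exp(mean |ln(pred/obs)|): geometric-mean fold discrepancy, ≥ 1."""
    pairs = [(p, o) for p, o in zip(predicted, observed) if p > 0 and o > 0]
    if not pairs:
        return math.nan
    return math.exp(
        sum(abs(math.log(p / o)) for p, o in pairs) / len(pairs)
    )


def leakage_table(scenarios: Iterable[Scenario]) -> tuple[pd.DataFrame, Optional[float]]:
    """Predicted needle-removal losses per scenario, plus the AFE against
    attached observations when any are present."""
    rows = []
    for sc in scenarios:
        res = run(sc)
        bf = res.backflow
        if bf is None:
            raise ValueError(f"scenario {sc.name}: no needle removal configured")
        rows.append(
            {
                "name": sc.name,
                "v_inj_uL": sc.protocol.v_inj,
                "q_inj_uL_min": sc.protocol.q_inj,
                "v_dead_uL": bf.v_dead,
                "v_loss_uL": bf.v_loss,
                "percent_dose_loss": bf.percent_dose_loss,
                "observed_uL": sc.observed_leakage_ul,
            }
        )
    table = pd.DataFrame(rows)
    obs = table.dropna(subset=["observed_uL"])
    afe = None
    if len(obs):
        afe = average_fold_error(obs["v_loss_uL"].to_numpy(), obs["observed_uL"].to_numpy())
        table.attrs["mean_abs_percent_error"] = float(
            (100 * (obs["v_loss_uL"] - obs["observed_uL"]).abs() / obs["observed_uL"]).mean()
        )
    table.attrs["afe"] = afe
    return table, afe
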