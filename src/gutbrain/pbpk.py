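"""Whole-body permeability-limited PBPK transport of toxin species.

Six tissues (brain, heart, adipose, liver, gut, kidney by default) are each
modelled as a two-compartment, permeability-limited, well-stirred tank: a
vascular compartment with concentration ``C_T`` and an extravascular
compartment with concentration ``C_EV,T``, exchanging across the capillary
wall with permeability-surface-area product ``P_T * S_T`` and partition
coefficient ``K_T``.  The circulatory system connects the tissues through a
single well-mixed blood pool ``C_ART`` with flow-weighted venous return and
renal clearance ``CL_R`` acting on the arterial concentration.

With ``f = V_T / V_EV,T`` the governing mass balances are::

    (f*V_T/(1+f)) dC_T/dt   = Q_T (C_ART - C_T) + P_T S_T (C_EV,T/K_T - C_T)
    (V_T/(1+f))   dC_EV,T/dt = P_T S_T (C_T - C_EV,T/K_T)
                               + generation_T - consumption_T - E_T C_EV,T
    V_B dC_ART/dt            = sum_T Q_T C_T - (sum_T Q_T) C_ART - CL_R C_ART

Generation/consumption terms (mol/hr) are supplied per tissue by the coupled
constraint-based organ models (zero by default).  ``E_T`` is an optional
per-tissue intrinsic elimination rate (L/hr).  The left-hand-side effective
volume factors are implemented exactly as written above; the conservation
helper :func:`total_amount` uses the same factors, so total mass is
conserved whenever ``CL_R``, ``E_T`` and all terms are zero.

Units: volumes L, flows and clearances L/hr, concentrations M (mol/L),
time hr.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "DEFAULT_TISSUES",
    "TissueParameters",
    "PBPKParameters",
    "PBPKTrajectory",
    "compute_f",
    "tissue_derivatives",
    "simulate_pbpk",
    "total_amount",
    "uniform_state",
]

logger = logging.getLogger(__name__)

DEFAULT_TISSUES = ("brain", "heart", "adipose", "liver", "gut", "kidney")


def compute_f(V_T: float, V_EV_T: float) -> float:
    """Ratio f = V_T / V_EV,T of total tissue to extravascular volume."""
    if V_T <= 0 or V_EV_T <= 0:
        raise ValueError("tissue volumes must be strictly positive")
    return V_T / V_EV_T


@dataclass(frozen=True)
class TissueParameters:
    """Physiological constants of one tissue compartment pair."""

    blood_flow: float           # Q_T, L/hr
    volume: float               # V_T, L
    extravascular_volume: float  # V_EV,T, L
    permeability: float         # P_T, L/hr per unit area
    surface_area: float         # S_T, area units (P_T*S_T in L/hr)
    partition: float = 1.0      # K_T, dimensionless
    gram_weight: float = 1.0    # organ weight, g (rat-scale)
    elimination: float = 0.0    # intrinsic elimination E_T, L/hr

    def __post_init__(self) -> None:
        if min(self.blood_flow, self.volume, self.extravascular_volume,
               self.partition, self.gram_weight) <= 0:
            raise ValueError("flows, volumes, K_T and gram weight must be > 0")
        if self.extravascular_volume >= self.volume:
            raise ValueError("V_EV,T must be smaller than V_T")

    @property
    def f(self) -> float:
        return compute_f(self.volume, self.extravascular_volume)

    @property
    def PS(self) -> float:
        return self.permeability * self.surface_area

    @property
    def vascular_volume_factor(self) -> float:
        """Effective vascular volume f*V_T/(1+f) (L)."""
        return self.f * self.volume / (1.0 + self.f)

    @property
    def extravascular_volume_factor(self) -> float:
        """Effective extravascular volume V_T/(1+f) (L)."""
        return self.volume / (1.0 + self.f)


@dataclass(frozen=True)
class PBPKParameters:
    """Whole-body parameter set: per-tissue constants + blood pool."""

    tissues: dict[str, TissueParameters]
    blood_volume: float = 1.0   # V_B, L
    renal_clearance: float = 0.0  # CL_R, L/hr, applied to C_ART

    def __post_init__(self) -> None:
        if self.blood_volume <= 0:
            raise ValueError("blood volume must be > 0")
        if self.renal_clearance < 0:
            raise ValueError("renal clearance must be >= 0")

    @property
    def tissue_names(self) -> list[str]:
        return list(self.tissues)

    def with_renal_clearance(self, CL_R: float) -> "PBPKParameters":
        return replace(self, renal_clearance=CL_R)

    # --- YAML round trip -------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "blood_volume": self.blood_volume,
            "renal_clearance": self.renal_clearance,
            "tissues": {
                name: {
                    "blood_flow": t.blood_flow,
                    "volume": t.volume,
                    "extravascular_volume": t.extravascular_volume,
                    "permeability": t.permeability,
                    "surface_area": t.surface_area,
                    "partition": t.partition,
                    "gram_weight": t.gram_weight,
                    "elimination": t.elimination,
                }
                for name, t in self.tissues.items()
            },
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PBPKParameters":
        payload = yaml.safe_load(Path(path).read_text())
        tissues = {
            name: TissueParameters(**spec) for name, spec in payload["tissues"].items()
        }
        return cls(
            tissues=tissues,
            blood_volume=float(payload.get("blood_volume", 1.0)),
            renal_clearance=float(payload.get("renal_clearance", 0.0)),
        )


# state vector layout for one species: [C_ART, C_T (n tissues), C_EV,T (n)]

def uniform_state(params: PBPKParameters, concentration: float) -> np.ndarray:
    n = len(params.tissues)
    return np.full(1 + 2 * n, float(concentration))


def tissue_derivatives(
    state: np.ndarray,
    params: PBPKParameters,
    generation: Mapping[str, float] | None = None,
    consumption: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Right-hand side of the PBPK mass balances for one species.

    ``generation``/``consumption`` map tissue name to a mol/hr term applied
    to that tissue's extravascular compartment.
    """
    names = params.tissue_names
    n = len(names)
    state = np.asarray(state, dtype=float)
    if state.shape != (1 + 2 * n,):
        raise ValueError(
            f"state has shape {state.shape}, expected ({1 + 2 * n},) for {n} tissues"
        )
    generation = generation or {}
    consumption = consumption or {}
    C_ART = state[0]
    C_T = state[1 : 1 + n]
    C_EV = state[1 + n :]
    dC_T = np.empty(n)
    dC_EV = np.empty(n)
    venous_return = 0.0
    total_flow = 0.0
    for i, name in enumerate(names):
        t = params.tissues[name]
        flux_in = t.blood_flow * (C_ART - C_T[i])
        permeation = t.PS * (C_EV[i] / t.partition - C_T[i])
        dC_T[i] = (flux_in + permeation) / t.vascular_volume_factor
        net_terms = (
            generation.get(name, 0.0)
            - consumption.get(name, 0.0)
            - t.elimination * C_EV[i]
        )
        dC_EV[i] = (-permeation + net_terms) / t.extravascular_volume_factor
        venous_return += t.blood_flow * C_T[i]
        total_flow += t.blood_flow
    dC_ART = (
        venous_return - total_flow * C_ART - params.renal_clearance * C_ART
    ) / params.blood_volume
    return np.concatenate(([dC_ART], dC_T, dC_EV))


def total_amount(state: np.ndarray, params: PBPKParameters) -> float:
    """Total amount (mol) using the same effective volumes as the ODEs."""
    names = params.tissue_names
    n = len(names)
    C_ART = state[0]
    amount = params.blood_volume * C_ART
    for i, name in enumerate(names):
        t = params.tissues[name]
        amount += t.vascular_volume_factor * state[1 + i]
        amount += t.extravascular_volume_factor * state[1 + n + i]
    return float(amount)


@dataclass
class PBPKTrajectory:
    """Sampled concentration trajectories, one array per toxin species."""

    times: np.ndarray
    states: dict[str, np.ndarray]  # species -> (n_times, 1 + 2n)
    params: PBPKParameters

    def concentration(self, species: str, tissue: str, compartment: str = "extravascular") -> np.ndarray:
        names = self.params.tissue_names
        n = len(names)
        if tissue == "blood":
            return self.states[species][:, 0]
        i = names.index(tissue)
        offset = 1 + (n if compartment == "extravascular" else 0)
        return self.states[species][:, offset + i]

    def to_frame(self) -> pd.DataFrame:
        names = self.params.tissue_names
        n = len(names)
        rows = []
        for species, arr in self.states.items():
            for j, t in enumerate(self.times):
                rows.append((t, "blood", "arterial", species, arr[j, 0]))
                for i, name in enumerate(names):
                    rows.append((t, name, "vascular", species, arr[j, 1 + i]))
                    rows.append((t, name, "extravascular", species, arr[j, 1 + n + i]))
        return pd.DataFrame(
            rows, columns=["time", "tissue", "compartment", "species", "concentration"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def simulate_pbpk(
    params: PBPKParameters,
    initial_state: Mapping[str, np.ndarray] | np.ndarray,
    duration: float,
    output_step: float | None = None,
    generation: Mapping[str, Mapping[str, float]] | None = None,
    consumption: Mapping[str, Mapping[str, float]] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> PBPKTrajectory:
    """Integrate the PBPK ODEs over ``duration`` hours.

    ``initial_state`` is either a single state vector (species ``"toxin"``)
    or a mapping species -> state vector; species are independent and are
    integrated separately.  ``generation``/``consumption`` map species ->
    tissue -> constant mol/hr term.  Output states are sampled every
    ``output_step`` hours (defaults to the full duration, i.e. endpoints
    only).  A stiff-capable adaptive integrator (LSODA) is used;
    concentrations that undershoot zero are clipped with a warning.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if isinstance(initial_state, np.ndarray):
        initial_state = {"toxin": initial_state}
    step = output_step or duration
    n_out = int(round(duration / step))
    if abs(n_out * step - duration) > 1e-9 * max(1.0, duration):
        raise ValueError("output_step must divide duration evenly")
    t_eval = np.linspace(0.0, duration, n_out + 1)
    states: dict[str, np.ndarray] = {}
    for species, y0 in initial_state.items():
        gen = (generation or {}).get(species, {})
        cons = (consumption or {}).get(species, {})
        result = solve_ivp(
            lambda _t, y: tissue_derivatives(y, params, gen, cons),
            (0.0, duration),
            np.asarray(y0, dtype=float),
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not result.success:
            raise RuntimeError(
                f"PBPK integration failed for {species!r} at t={result.t[-1]:.4f} hr: "
                f"{result.message}"
            )
        arr = result.y.T.copy()
        if (arr < 0).any():
            worst = arr.min()
            if worst < -10 * atol:
                logger.warning(
                    "negative concentrations (min %.3e) clipped to 0 for %s",
                    worst, species,
                )
            np.clip(arr, 0.0, None, out=arr)
        states[species] = arr
    return PBPKTrajectory(times=t_eval, states=states, params=params)
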