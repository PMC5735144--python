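"""MM/PBSA-style free-energy bookkeeping under single- and triple-trajectory schemes.

The binding free energy is assembled from five components:

    dG_bind = dG_gas + dG_sol
    dG_gas  = (dE_ele + dE_vdw + dE_int) + (-T*dS)
    dG_sol  = dG_pb + dG_np

In the single-trajectory scheme only the complex is simulated, the
protein-ligand structure is treated as a rigid body and the internal
(strain) term dE_int is identically zero.  The triple scheme differences
per-species component tables (complex - protein - ligand) and accepts
dE_int as an external number.  The entropy term is either an interaction
entropy result or an externally computed normal-mode value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import CompletenessError, EmptyInputError, SchemeError, ValidationError
from .interaction_entropy import IEResult, ThermoParams, interaction_entropy
from .io_formats import EnergySeries

_IDENTITY_TOL = 1e-9

COMPONENT_FIELDS = [
    "e_ele",
    "e_vdw",
    "e_internal",
    "g_pb",
    "g_np",
    "g_sol",
    "minus_t_delta_s",
    "g_gas",
    "g_bind",
]


@dataclass(frozen=True)
class FreeEnergyBreakdown:
    """Five-component free-energy ledger, all values in kcal/mol."""

    scheme: str  # "single" | "triple"
    entropy_method: str  # "IE" | "external_nmode"
    e_ele: float
    e_vdw: float
    e_internal: float
    g_pb: float
    g_np: float
    g_sol: float
    minus_t_delta_s: float
    g_gas: float
    g_bind: float

    def __post_init__(self):
        if self.scheme not in ("single", "triple"):
            raise SchemeError(f"unknown scheme: {self.scheme}")
        if self.entropy_method not in ("IE", "external_nmode"):
            raise ValidationError(f"unknown entropy method: {self.entropy_method}")
        if self.scheme == "single" and self.e_internal != 0.0:
            raise SchemeError("single scheme requires e_internal == 0 (rigid-body assumption)")
        if abs(self.g_sol - (self.g_pb + self.g_np)) > _IDENTITY_TOL:
            raise ValidationError("g_sol != g_pb + g_np")
        gas = self.e_ele + self.e_vdw + self.e_internal + self.minus_t_delta_s
        if abs(self.g_gas - gas) > _IDENTITY_TOL:
            raise ValidationError("g_gas != e_ele + e_vdw + e_internal + (-T dS)")
        if abs(self.g_bind - (self.g_gas + self.g_sol)) > _IDENTITY_TOL:
            raise ValidationError("g_bind != g_gas + g_sol")

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in COMPONENT_FIELDS}
        d["scheme"] = self.scheme
        d["entropy_method"] = self.entropy_method
        return d


@dataclass(frozen=True)
class GroupStats:
    """Per-component mean and sample SD (n-1 denominator) over snapshot groups."""

    table: pd.DataFrame  # index: component; columns: mean, sd
    n_groups: int
    n_snapshots_per_group: Optional[int] = None


def combine(
    components: Mapping[str, float],
    scheme: str = "single",
    entropy_method: str = "external_nmode",
) -> FreeEnergyBreakdown:
    """Assemble a breakdown from a partial component mapping.

    Accepted keys: ``e_ele``, ``e_vdw`` (or ``e_int_total`` for an unsplit
    gas-phase interaction energy), ``e_internal``, ``g_pb``/``g_np`` or a
    combined ``g_sol``, and ``minus_t_delta_s``.  The derived quantities
    g_sol, g_gas, g_bind are filled from the identities above.
    """
    comp = dict(components)
    if "e_int_total" in comp:
        if "e_ele" in comp or "e_vdw" in comp:
            raise ValidationError("give either e_int_total or the e_ele/e_vdw split")
        comp["e_ele"] = comp.pop("e_int_total")
        comp["e_vdw"] = 0.0
    for key in ("e_ele", "e_vdw", "minus_t_delta_s"):
        if key not in comp:
            raise CompletenessError(f"missing component '{key}'")
    e_internal = float(comp.get("e_internal", 0.0))
    if "g_sol" in comp:
        if "g_pb" in comp or "g_np" in comp:
            raise ValidationError("give either g_sol or the g_pb/g_np split")
        g_pb, g_np = float(comp["g_sol"]), 0.0
    else:
        if "g_pb" not in comp and "g_np" not in comp:
            raise CompletenessError("missing solvation component (g_sol or g_pb/g_np)")
        g_pb = float(comp.get("g_pb", 0.0))
        g_np = float(comp.get("g_np", 0.0))
    e_ele = float(comp["e_ele"])
    e_vdw = float(comp["e_vdw"])
    tds = float(comp["minus_t_delta_s"])
    g_sol = g_pb + g_np
    g_gas = e_ele + e_vdw + e_internal + tds
    return FreeEnergyBreakdown(
        scheme=scheme,
        entropy_method=entropy_method,
        e_ele=e_ele,
        e_vdw=e_vdw,
        e_internal=e_internal,
        g_pb=g_pb,
        g_np=g_np,
        g_sol=g_sol,
        minus_t_delta_s=tds,
        g_gas=g_gas,
        g_bind=g_gas + g_sol,
    )


def _entropy_value(
    entropy: Union[IEResult, float], series: Optional[EnergySeries], thermo: ThermoParams
) -> tuple[float, str]:
    if isinstance(entropy, IEResult):
        return entropy.minus_t_delta_s, "IE"
    if entropy == "ie":
        if series is None:
            raise CompletenessError("entropy='ie' needs an energy series")
        return interaction_entropy(series, thermo).minus_t_delta_s, "IE"
    return float(entropy), "external_nmode"


def single_scheme(
    series: EnergySeries,
    g_pb_series: Sequence[float],
    g_np: float,
    entropy: Union[IEResult, float, str],
    thermo: ThermoParams = ThermoParams(),
) -> FreeEnergyBreakdown:
    """Single-trajectory breakdown from complex-only frame data.

    ``entropy`` may be an :class:`IEResult`, the string ``"ie"`` (compute IE
    from ``series``), or an external scalar -T*dS (e.g. a normal-mode value).
    """
    if series.n_frames == 0:
        raise EmptyInputError("empty energy series")
    g_pb_series = np.asarray(g_pb_series, dtype=float)
    if len(g_pb_series) != series.n_frames:
        raise ValidationError(
            f"g_pb series length {len(g_pb_series)} != energy series length {series.n_frames}"
        )
    tds, method = _entropy_value(entropy, series, thermo)
    return combine(
        {
            "e_ele": float(np.mean(series.e_ele)),
            "e_vdw": float(np.mean(series.e_vdw)),
            "g_pb": float(np.mean(g_pb_series)),
            "g_np": float(g_np),
            "minus_t_delta_s": tds,
        },
        scheme="single",
        entropy_method=method,
    )


_SPECIES_KEYS = ("e_ele", "e_vdw", "g_pb", "g_np")


def triple_scheme(
    complex_components: Mapping[str, float],
    protein_components: Mapping[str, float],
    ligand_components: Mapping[str, float],
    e_internal: float,
    minus_t_delta_s: float,
    entropy_method: str = "external_nmode",
) -> FreeEnergyBreakdown:
    """Triple-trajectory breakdown: dX = X_complex - X_protein - X_ligand.

    Each species mapping must carry the gas and solvation components
    ``e_ele, e_vdw, g_pb, g_np``.  The internal/strain change dE_int and the
    entropy term are external inputs (their per-species decomposition is not
    available from inter-group energies).
    """
    tables = {
        "complex": complex_components,
        "protein": protein_components,
        "ligand": ligand_components,
    }
    for name, tab in tables.items():
        missing = [k for k in _SPECIES_KEYS if k not in tab]
        if missing:
            raise CompletenessError(f"{name} table is missing component(s): {missing}")
    delta = {
        k: float(tables["complex"][k]) - float(tables["protein"][k]) - float(tables["ligand"][k])
        for k in _SPECIES_KEYS
    }
    delta["e_internal"] = float(e_internal)
    delta["minus_t_delta_s"] = float(minus_t_delta_s)
    return combine(delta, scheme="triple", entropy_method=entropy_method)


def group_std(breakdowns: Sequence[FreeEnergyBreakdown],
              n_snapshots_per_group: Optional[int] = None) -> GroupStats:
    """Mean and sample SD of each component over snapshot-group breakdowns.

    Mirrors the procedure of cutting a long production run into groups of
    snapshots, computing a full breakdown per group, and reporting the
    spread over groups.
    """
    if len(breakdowns) < 2:
        raise ValidationError("need at least 2 breakdowns for group statistics")
    schemes = {b.scheme for b in breakdowns}
    if len(schemes) > 1:
        raise SchemeError(f"mixed schemes in group statistics: {sorted(schemes)}")
    data = {f: np.array([getattr(b, f) for b in breakdowns]) for f in COMPONENT_FIELDS}
    table = pd.DataFrame(
        {
            "mean": {f: float(np.mean(v)) for f, v in data.items()},
            "sd": {f: float(np.std(v, ddof=1)) for f, v in data.items()},
        }
    )
    return GroupStats(table=table, n_groups=len(breakdowns),
                      n_snapshots_per_group=n_snapshots_per_group)
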