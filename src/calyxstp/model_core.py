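"""Kinetic core of the two-step vesicle priming/fusion model.

The model describes a population of ``N_total`` identical presynaptic release
sites at which synaptic vesicles (SVs) dock and mature through two sequential,
reversible priming steps::

    ES  <-- k1/b1 -->  LS  <-- k2/b2 -->  TS
    ERS --- b4 ---> ES                TS --(AP, p_fusion)--> ERS
    LS --(AP, kappa)--> TSL --- b3 ---> LS

ES are empty sites available for docking, LS loosely docked SVs, TS tightly
docked (fusion-competent) SVs, TSL a short-lived labile tight state populated
from LS immediately after each action potential (AP), and ERS refractory sites
left behind by fusion that recover to ES with rate ``b4``.

The forward priming rates ``k1`` and ``k2`` increase linearly with the
"effective" intracellular calcium concentration; calcium itself follows a
phenomenological AP-evoked transient (a fast local plus a slower global
component) on top of the resting level.

This module holds the parameter containers, the closed-form equilibrium
analysis of the scheme, the effective-calcium waveform, and small scalar
relations (Michaelis–Menten influx saturation).  The hybrid ODE/event train
simulation lives in :mod:`calyxstp.train_simulator`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

__all__ = [
    "PrimingParameters",
    "CaTransientParameters",
    "InfluxDynamicsParameters",
    "StateOccupancy",
    "TransientMode",
    "priming_rates",
    "effective_ca",
    "transient_integral",
    "equilibrium_occupancy",
    "half_max_ca",
    "frp_fraction",
    "influx_ratio_mm",
    "builtin_condition",
    "BUILTIN_CONDITIONS",
    "load_condition",
    "dump_condition",
]

# ---------------------------------------------------------------------------
# units
# ---------------------------------------------------------------------------

_CONC_UNITS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}


def _to_molar(value) -> float:
    """Parse a concentration given either as a plain float (molar) or a
    string/tuple with an explicit unit tag, e.g. ``"50 nM"`` or ``[50, "nM"]``."""
    if isinstance(value, str):
        parts = value.split()
        if len(parts) != 2 or parts[1] not in _CONC_UNITS:
            raise ValueError(f"cannot parse concentration {value!r}")
        return float(parts[0]) * _CONC_UNITS[parts[1]]
    if isinstance(value, (list, tuple)) and len(value) == 2:
        return float(value[0]) * _CONC_UNITS[str(value[1])]
    return float(value)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrimingParameters:
    """Kinetic constants of one model condition.

    Rates are s^-1, sensitivities M^-1 s^-1, concentrations molar.
    ``tau_TSL`` is the mean lifetime of the labile tight state (1/b3) and
    ``kappa_TSL`` the per-AP fraction of LS vesicles transferred into it.
    """

    p_fusion: float
    N_total: float
    k1_rest: float
    b1: float
    sigma1: float
    k2_rest: float
    b2: float
    sigma2: float
    tau_TSL: float
    kappa_TSL: float
    b4: float
    ca_rest: float

    def __post_init__(self) -> None:
        for name in ("k1_rest", "b1", "sigma1", "k2_rest", "b2", "sigma2", "b4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.p_fusion <= 1.0:
            raise ValueError("p_fusion must be in [0, 1]")
        if not 0.0 <= self.kappa_TSL <= 1.0:
            raise ValueError("kappa_TSL must be in [0, 1]")
        if self.N_total <= 0:
            raise ValueError("N_total must be > 0")
        if self.ca_rest <= 0:
            raise ValueError("ca_rest must be > 0")
        if self.tau_TSL <= 0:
            raise ValueError("tau_TSL must be > 0")

    @property
    def b3(self) -> float:
        return 1.0 / self.tau_TSL


class TransientMode(str, Enum):
    """Shape of the effective calcium transient.

    ``control_biexp``: single amplitude with a bi-exponential decay.
    ``local_plus_global``: large fast-decaying local component plus a smaller
    bi-exponential global component (the revised, low-Ca-sensitivity model).
    """

    CONTROL_BIEXP = "control_biexp"
    LOCAL_PLUS_GLOBAL = "local_plus_global"


@dataclass(frozen=True)
class CaTransientParameters:
    """Amplitude/shape of the AP-evoked effective Ca2+ transient (molar, s)."""

    mode: TransientMode
    amp_global: float
    tau_fast: float
    tau_slow: float
    f_slow: float
    amp_local: float = 0.0
    tau_local: float = 0.25e-3

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_slow <= 1.0:
            raise ValueError("f_slow must be in [0, 1]")
        if min(self.tau_fast, self.tau_slow, self.tau_local) <= 0:
            raise ValueError("all time constants must be > 0")
        if self.amp_global < 0 or self.amp_local < 0:
            raise ValueError("amplitudes must be >= 0")

    def component_amplitudes(self) -> np.ndarray:
        """Per-AP amplitude of each exponential component (local, global-fast,
        global-slow), before any influx scaling."""
        local = self.amp_local if self.mode is TransientMode.LOCAL_PLUS_GLOBAL else 0.0
        return np.array(
            [local, self.amp_global * (1.0 - self.f_slow), self.amp_global * self.f_slow]
        )

    def component_taus(self) -> np.ndarray:
        return np.array([self.tau_local, self.tau_fast, self.tau_slow])


@dataclass(frozen=True)
class InfluxDynamicsParameters:
    """Per-AP facilitation (y) and depression (z) of the Ca2+ influx amplitude.

    Each AP moves y a fraction ``y_inc`` toward the ceiling ``y_max`` and z a
    fraction ``z_dec`` toward the floor ``z_min``; between APs both relax
    exponentially back to 1 with time constants ``tau_y`` and ``tau_z``.
    The transient amplitude of AP *j* is scaled by y_j * z_j.
    """

    y_inc: float
    z_dec: float
    y_max: float
    z_min: float
    tau_y: float
    tau_z: float

    def __post_init__(self) -> None:
        if self.y_max < 1.0:
            raise ValueError("y_max must be >= 1")
        if not 0.0 < self.z_min <= 1.0:
            raise ValueError("z_min must be in (0, 1]")
        if not (0.0 <= self.y_inc <= 1.0 and 0.0 <= self.z_dec <= 1.0):
            raise ValueError("y_inc and z_dec must be in [0, 1]")
        if self.tau_y <= 0 or self.tau_z <= 0:
            raise ValueError("tau_y and tau_z must be > 0")


@dataclass
class StateOccupancy:
    """Instantaneous occupancy (site counts) of the five model states."""

    ES: float
    LS: float
    TS: float
    TSL: float
    ERS: float

    def total(self) -> float:
        return self.ES + self.LS + self.TS + self.TSL + self.ERS

    def as_array(self) -> np.ndarray:
        return np.array([self.ES, self.LS, self.TS, self.TSL, self.ERS])

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "StateOccupancy":
        return cls(*(float(v) for v in x))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def priming_rates(params: PrimingParameters, ca: float):
    """Ca2+-dependent forward priming rates (k1, k2) in s^-1.

    Both rates increase linearly with the effective [Ca2+]_i above rest and are
    clamped at zero below rest (rates are physical quantities).
    """
    ca = np.asarray(ca, dtype=float)
    if np.any(ca < 0):
        raise ValueError("ca must be >= 0")
    dca = ca - params.ca_rest
    k1 = np.maximum(params.k1_rest + params.sigma1 * dca, 0.0)
    k2 = np.maximum(params.k2_rest + params.sigma2 * dca, 0.0)
    if k1.ndim == 0:
        return float(k1), float(k2)
    return k1, k2


def effective_ca(
    tp: CaTransientParameters,
    ca_rest: float,
    ap_times: Sequence[float],
    ap_scales: Sequence[float],
    t,
    summation: str = "additive",
):
    """Effective [Ca2+]_i (molar) at time(s) ``t`` given past AP times.

    ``ap_scales`` carries the y*z influx factor of each AP.  In ``additive``
    mode the transients of all past APs superpose linearly; in ``reset`` mode
    only the most recent past AP contributes.  Before the first AP the resting
    concentration is returned exactly.
    """
    ap_times = np.asarray(ap_times, dtype=float)
    ap_scales = np.asarray(ap_scales, dtype=float)
    if ap_times.shape != ap_scales.shape:
        raise ValueError("ap_times and ap_scales must have the same length")
    if ap_times.size > 1 and np.any(np.diff(ap_times) < 0):
        raise ValueError("ap_times must be sorted ascending")
    if summation not in ("additive", "reset"):
        raise ValueError("summation must be 'additive' or 'reset'")

    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    amps = tp.component_amplitudes()
    taus = tp.component_taus()
    out = np.full(t_arr.shape, ca_rest, dtype=float)
    if ap_times.size:
        if summation == "additive":
            for tj, sj in zip(ap_times, ap_scales):
                dt = t_arr - tj
                mask = dt >= 0
                if not mask.any():
                    continue
                out[mask] += sj * np.sum(
                    amps[:, None] * np.exp(-dt[mask][None, :] / taus[:, None]), axis=0
                )
        else:
            idx = np.searchsorted(ap_times, t_arr, side="right") - 1
            mask = idx >= 0
            if mask.any():
                dt = t_arr[mask] - ap_times[idx[mask]]
                out[mask] += ap_scales[idx[mask]] * np.sum(
                    amps[:, None] * np.exp(-dt[None, :] / taus[:, None]), axis=0
                )
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return float(out[0])
    return out


def transient_integral(tp: CaTransientParameters):
    """Analytic time integral above rest of a unit-scaled single-AP transient,
    returned as (per-component integrals, total).  Units: M*s."""
    comp = tp.component_amplitudes() * tp.component_taus()
    return comp, float(comp.sum())


def equilibrium_occupancy(params: PrimingParameters, ca: float) -> StateOccupancy:
    """Closed-form resting equilibrium of the scheme at a fixed [Ca2+]_i.

    At rest TSL and ERS are empty and detailed balance along the chain gives
    LS/ES = k1/b1 and TS/LS = k2/b2; the three fractions are scaled to sum to
    ``N_total``.  Vanishing backward rates are handled as limits (all mass
    pushed downstream) rather than as errors.
    """
    k1, k2 = priming_rates(params, ca)
    # weights proportional to (ES, LS, TS); inf-handling for b1 or b2 == 0
    if params.b2 == 0:
        if k2 == 0:  # fully degenerate: no TS flux, treat chain up to LS
            w = _chain_weights(k1, params.b1, 0.0, 1.0)
        else:
            w = np.array([0.0, 0.0, 1.0])
    elif params.b1 == 0:
        if k1 == 0:
            w = np.array([1.0, 0.0, 0.0])
        else:
            r2 = k2 / params.b2
            w = np.array([0.0, 1.0, r2])
    else:
        w = _chain_weights(k1, params.b1, k2, params.b2)
    w = w / w.sum() * params.N_total
    return StateOccupancy(ES=w[0], LS=w[1], TS=w[2], TSL=0.0, ERS=0.0)


def _chain_weights(k1: float, b1: float, k2: float, b2: float) -> np.ndarray:
    r1 = k1 / b1
    r2 = k2 / b2 if b2 > 0 else 0.0
    return np.array([1.0, r1, r1 * r2])


def _ts_fraction(params: PrimingParameters, ca: float) -> float:
    occ = equilibrium_occupancy(params, ca)
    return occ.TS / params.N_total


def half_max_ca(
    params: PrimingParameters,
    ca_ref: float = 50e-9,
    ca_max: float = 10e-6,
    xtol: float = 0.01e-9,
) -> float:
    """[Ca2+]_i at which the equilibrium TS occupancy reaches half of its
    maximum possible increase above the reference condition, i.e. solves
    TS(ca) = TS(ca_ref) + 0.5 * (N_total - TS(ca_ref)).

    Root-found by bisection on the closed form over [ca_ref, ca_max]; raises
    if the target is not bracketed there.
    """
    ts_ref = _ts_fraction(params, ca_ref)
    target = ts_ref + 0.5 * (1.0 - ts_ref)
    if ts_ref >= 1.0:
        return ca_ref

    def f(ca: float) -> float:
        return _ts_fraction(params, ca) - target

    lo, hi = f(ca_ref), f(ca_max)
    if lo > 0 or hi < 0:
        raise ValueError(
            "half-maximum TS occupancy not bracketed in "
            f"[{ca_ref:.3g}, {ca_max:.3g}] M"
        )
    return float(brentq(f, ca_ref, ca_max, xtol=xtol))


def frp_fraction(params: PrimingParameters, ca: float) -> float:
    """Equilibrium fast-releasing pool fraction (LS + TS) / N_total."""
    occ = equilibrium_occupancy(params, ca)
    return (occ.LS + occ.TS) / params.N_total


def influx_ratio_mm(ca_ext_a: float, ca_ext_b: float, ec50: float = 2.6) -> float:
    """Fold change of presynaptic Ca2+ influx when external [Ca2+] changes
    from ``ca_ext_a`` to ``ca_ext_b`` (mM), from Michaelis–Menten saturation
    of influx with half-maximum at ``ec50``."""
    if ca_ext_a <= 0 or ca_ext_b <= 0 or ec50 < 0:
        raise ValueError("concentrations must be > 0 and ec50 >= 0")
    fa = ca_ext_a / (ca_ext_a + ec50)
    fb = ca_ext_b / (ca_ext_b + ec50)
    return fb / fa


# ---------------------------------------------------------------------------
# reference parameter sets
# ---------------------------------------------------------------------------
# One block per published model condition for the calyx of Held: paired
# control/ionomycin, external Ca2+ 1.5 vs 2.0 mM, and paired control/PDBu.
# Concentrations in molar, rates in s^-1, sensitivities in M^-1 s^-1.

_SHARED_TRANSIENT = dict(
    mode="local_plus_global",
    tau_fast=0.06,
    tau_slow=0.23,
    f_slow=0.15,
    amp_global=4.54e-7,
    tau_local=0.25e-3,
    amp_local=3.0e-5,
)
_SHARED_INFLUX = dict(y_inc=0.39, z_dec=0.4, tau_y=0.017, tau_z=3.0)

_RAW_CONDITIONS: dict[str, dict] = {
    "control": dict(
        priming=dict(
            p_fusion=0.22, N_total=2622, k1_rest=0.370, b1=0.221, sigma1=2.245e6,
            k2_rest=0.199, b2=0.253, sigma2=1.014e6, tau_TSL=0.09, kappa_TSL=0.10,
            b4=2.6, ca_rest=5e-8,
        ),
        transient=dict(_SHARED_TRANSIENT),
        influx=dict(_SHARED_INFLUX, y_max=1.31, z_min=0.87),
    ),
    "ionomycin": dict(
        priming=dict(
            p_fusion=0.30, N_total=2622, k1_rest=0.370, b1=0.221, sigma1=2.245e6,
            k2_rest=0.199, b2=0.253, sigma2=1.014e6, tau_TSL=0.09, kappa_TSL=0.15,
            b4=4.2, ca_rest=1.3e-7,
        ),
        transient=dict(_SHARED_TRANSIENT),
        influx=dict(_SHARED_INFLUX, y_max=1.16, z_min=1.0),
    ),
    "ca15": dict(
        priming=dict(
            p_fusion=0.22, N_total=2910, k1_rest=0.374015, b1=0.215, sigma1=2.181e6,
            k2_rest=0.191, b2=0.264, sigma2=1.042e6, tau_TSL=0.09, kappa_TSL=0.10,
            b4=2.5, ca_rest=5e-8,
        ),
        transient=dict(_SHARED_TRANSIENT),
        influx=dict(_SHARED_INFLUX, y_max=1.28, z_min=0.84),
    ),
    "ca20": dict(
        priming=dict(
            p_fusion=0.42, N_total=2910, k1_rest=0.374015, b1=0.215, sigma1=2.181e6,
            k2_rest=0.191, b2=0.264, sigma2=1.042e6, tau_TSL=0.09, kappa_TSL=0.10,
            b4=2.9, ca_rest=9e-8,
        ),
        transient=dict(_SHARED_TRANSIENT, amp_global=5.45e-7, amp_local=3.6e-5),
        influx=dict(_SHARED_INFLUX, y_max=1.28, z_min=0.84),
    ),
    "pdbu_control": dict(
        priming=dict(
            p_fusion=0.22, N_total=2590, k1_rest=0.373, b1=0.210, sigma1=2.051e6,
            k2_rest=0.187, b2=0.271, sigma2=1.019e6, tau_TSL=0.09, kappa_TSL=0.11,
            b4=2.8, ca_rest=5e-8,
        ),
        transient=dict(_SHARED_TRANSIENT),
        influx=dict(_SHARED_INFLUX, y_max=1.27, z_min=0.87),
    ),
    "pdbu": dict(
        priming=dict(
            p_fusion=0.29, N_total=3297, k1_rest=0.373, b1=0.210, sigma1=2.051e6,
            k2_rest=0.378, b2=0.271, sigma2=2.436e6, tau_TSL=0.09, kappa_TSL=0.11,
            b4=2.8, ca_rest=5e-8,
        ),
        transient=dict(_SHARED_TRANSIENT),
        influx=dict(_SHARED_INFLUX, y_max=1.27, z_min=0.87),
    ),
}

BUILTIN_CONDITIONS = tuple(_RAW_CONDITIONS)


def _build_condition(block: Mapping) -> tuple[
    PrimingParameters, CaTransientParameters, InfluxDynamicsParameters
]:
    pr = dict(block["priming"])
    pr["ca_rest"] = _to_molar(pr["ca_rest"])
    tr = dict(block["transient"])
    tr["mode"] = TransientMode(tr["mode"])
    for key in ("amp_global", "amp_local"):
        if key in tr:
            tr[key] = _to_molar(tr[key])
    return (
        PrimingParameters(**pr),
        CaTransientParameters(**tr),
        InfluxDynamicsParameters(**block["influx"]),
    )


def builtin_condition(name: str):
    """Return (PrimingParameters, CaTransientParameters, InfluxDynamicsParameters)
    for one of the published reference conditions: control, ionomycin, ca15,
    ca20, pdbu_control, pdbu."""
    try:
        return _build_condition(_RAW_CONDITIONS[name])
    except KeyError:
        raise KeyError(f"unknown condition {name!r}; choose from {BUILTIN_CONDITIONS}")


def load_condition(path):
    """Load one condition block (priming/transient/influx) from a YAML or JSON
    file; concentrations may carry explicit unit tags ("50 nM")."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _build_condition(data)


def dump_condition(name_or_blocks, path) -> None:
    """Write a condition block to YAML (round-trips through load_condition)."""
    if isinstance(name_or_blocks, str):
        data = _RAW_CONDITIONS[name_or_blocks]
    else:
        pr, tr, idp = name_or_blocks
        data = dict(
            priming=asdict(pr),
            transient={**asdict(tr), "mode": tr.mode.value},
            influx=asdict(idp),
        )
    with open(path, "w") as fh:
        yaml.safe_dump(_make_plain(data), fh, sort_keys=False)


def _make_plain(obj):
    if isinstance(obj, Mapping):
        return {k: _make_plain(v) for k, v in obj.items()}
    if isinstance(obj, float) and obj == int(obj) and abs(obj) < 1e6:
        return obj
    return obj
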