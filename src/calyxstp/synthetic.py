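"""Synthetic cohort generator: the full experimental design in silico.

Generates a heterogeneous population of model synapses and simulates every
stimulus layer of the experimental design (40-stimulus trains at 5, 10, 20,
50, 100 and 200 Hz, plus 100 and 200 Hz trains preconditioned with two or
four stimuli at 10 Hz), adds trial-level measurement noise, averages
repetitions, and assembles the release tensor together with its ground truth
so that every downstream stage (NTF, pool estimators) is testable without any
recorded data.

Population heterogeneity enters through the total number of release sites
(``N_total``, log-normal, CV 0.35) and the resting LS->TS priming rate
(``k2_rest``, log-normal, CV 0.4), while the fusion probability is uniform
across synapses — a cohort in which synaptic strength and short-term
plasticity vary because the priming equilibrium varies, not the fusion step.
With the default dispersions the cohort spans roughly 0.28-0.59 in f_TS and
several-fold in initial quantal content, matching the heterogeneity reported
for calyx of Held synapses.

Noise is multiplicative log-normal per response (amplitude measurement
noise); binomial sampling of fusion counts can be switched on in addition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    CaTransientParameters,
    InfluxDynamicsParameters,
    PrimingParameters,
    builtin_condition,
    equilibrium_occupancy,
)
from .ntf import ReleaseTensor
from .train_simulator import Precondition, StimulusProtocol, simulate_train

__all__ = [
    "STANDARD_LAYERS",
    "standard_protocols",
    "PopulationSpec",
    "GroundTruth",
    "generate_population",
    "binomial_fusion_noise",
]

#: the ten tensor layers of the experimental design: (label, f_stim, n_pre)
STANDARD_LAYERS: tuple[tuple[str, float, int], ...] = (
    ("5Hz", 5.0, 0),
    ("10Hz", 10.0, 0),
    ("20Hz", 20.0, 0),
    ("50Hz", 50.0, 0),
    ("100Hz", 100.0, 0),
    ("200Hz", 200.0, 0),
    ("100Hz_pre2", 100.0, 2),
    ("100Hz_pre4", 100.0, 4),
    ("200Hz_pre2", 200.0, 2),
    ("200Hz_pre4", 200.0, 4),
)


def standard_protocols(n_stim: int = 40) -> dict[str, StimulusProtocol]:
    """The layer label -> protocol mapping of the standard design."""
    out = {}
    for label, f_stim, n_pre in STANDARD_LAYERS:
        pre = Precondition(n_pre=n_pre) if n_pre else None
        out[label] = StimulusProtocol(f_stim=f_stim, n_stim=n_stim, precondition=pre)
    return out


@dataclass(frozen=True)
class PopulationSpec:
    """Design of one synthetic cohort."""

    n_synapses: int = 50
    condition: str = "control"
    n_total_cv: float = 0.35
    k2_rest_cv: float = 0.4
    noise_cv: float = 0.1
    n_repetitions: int = 3
    binomial_sampling: bool = False
    n_stim: int = 40
    seed: int = 0
    base_params: Optional[PrimingParameters] = None
    transient: Optional[CaTransientParameters] = None
    influx: Optional[InfluxDynamicsParameters] = None

    def __post_init__(self) -> None:
        if self.n_synapses < 2:
            raise ValueError("n_synapses must be >= 2")
        if min(self.n_total_cv, self.k2_rest_cv, self.noise_cv) < 0:
            raise ValueError("all CVs must be >= 0")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")

    def resolve(self):
        base, tp, idp = builtin_condition(self.condition)
        return (
            self.base_params or base,
            self.transient or tp,
            self.influx or idp,
        )


@dataclass
class GroundTruth:
    """Per-synapse generative truth and the noiseless traces."""

    params: list[PrimingParameters]
    n_total: np.ndarray
    ls_rest: np.ndarray
    ts_rest: np.ndarray
    f_ts: np.ndarray
    p_fusion: float
    noiseless: np.ndarray  # (n_stim, n_synapses, n_layers)
    layers: Sequence[str]
    seed: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "synapse_id": [f"syn{i:03d}" for i in range(len(self.n_total))],
                "N_total": self.n_total,
                "LS_rest": self.ls_rest,
                "TS_rest": self.ts_rest,
                "f_TS": self.f_ts,
                "p_fusion": self.p_fusion,
            }
        )


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean log-normal multipliers with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def binomial_fusion_noise(
    expected_m: float, n_available: float, rng: np.random.Generator
) -> int:
    """Sample an integer quantal count from a binomial with ``n_available``
    trials and success probability ``expected_m / n_available``."""
    n = int(round(n_available))
    if expected_m < 0 or expected_m > n_available:
        raise ValueError("expected_m must lie in [0, n_available]")
    if n == 0:
        return 0
    p = min(expected_m / n_available, 1.0)
    return int(rng.binomial(n, p))


def generate_population(
    spec: PopulationSpec,
    rtol: float = 1e-8,
) -> tuple[ReleaseTensor, GroundTruth]:
    """Simulate a synthetic cohort and return (tensor, ground truth).

    For each synapse all layers are simulated deterministically; each of the
    ``n_repetitions`` trials then receives multiplicative log-normal noise per
    response (and optionally binomial resampling of the fusion count), and
    trials are averaged — mirroring the trial-averaging performed on recorded
    trains before decomposition.
    """
    rng = np.random.default_rng(spec.seed)
    base, tp, idp = spec.resolve()
    protocols = standard_protocols(spec.n_stim)
    layers = [label for label, _, _ in STANDARD_LAYERS]

    nt_factors = _lognormal_factors(rng, spec.n_total_cv, spec.n_synapses)
    k2_factors = _lognormal_factors(rng, spec.k2_rest_cv, spec.n_synapses)

    params_list: list[PrimingParameters] = []
    noiseless = np.empty((spec.n_stim, spec.n_synapses, len(layers)))
    ls_rest = np.empty(spec.n_synapses)
    ts_rest = np.empty(spec.n_synapses)

    for s in range(spec.n_synapses):
        p_s = replace(
            base,
            N_total=base.N_total * nt_factors[s],
            k2_rest=base.k2_rest * k2_factors[s],
        )
        params_list.append(p_s)
        occ = equilibrium_occupancy(p_s, p_s.ca_rest)
        ls_rest[s] = occ.LS
        ts_rest[s] = occ.TS
        for li, label in enumerate(layers):
            res = simulate_train(p_s, tp, idp, protocols[label], rtol=rtol)
            noiseless[:, s, li] = res.m

    values = np.zeros_like(noiseless)
    for _ in range(spec.n_repetitions):
        trial = noiseless.copy()
        if spec.binomial_sampling:
            p_fu = base.p_fusion
            avail = noiseless / p_fu if p_fu > 0 else np.zeros_like(noiseless)
            flat = trial.ravel()
            av = avail.ravel()
            for i in range(flat.size):
                flat[i] = binomial_fusion_noise(flat[i], max(av[i], flat[i]), rng)
            trial = flat.reshape(trial.shape)
        if spec.noise_cv > 0:
            sigma = np.sqrt(np.log1p(spec.noise_cv**2))
            trial = trial * rng.lognormal(
                mean=-0.5 * sigma**2, sigma=sigma, size=trial.shape
            )
        values += trial
    values /= spec.n_repetitions

    tensor = ReleaseTensor(
        values=values,
        layers=layers,
        synapses=[f"syn{i:03d}" for i in range(spec.n_synapses)],
    )
    truth = GroundTruth(
        params=params_list,
        n_total=np.array([p.N_total for p in params_list]),
        ls_rest=ls_rest,
        ts_rest=ts_rest,
        f_ts=ts_rest / (ls_rest + ts_rest),
        p_fusion=base.p_fusion,
        noiseless=noiseless,
        layers=layers,
        seed=spec.seed,
    )
    return tensor, truth
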