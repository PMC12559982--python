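"""Run configuration, pipeline orchestration and tabular I/O.

Ties the stages together: synthetic cohort generation -> (simulation /
ingestion of train tables) -> NTF decomposition -> pool/STP analysis.  Every
run writes a manifest recording the configuration hash, seeds, package
version and per-stage outputs, so results are reproducible byte-for-byte
given the same configuration.

Tabular dialect: comma-separated, header row, UTF-8, '.' decimal; quantal
contents as floating point; ``stimulus_index`` 1-based (m1 ... m40).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (
    PoolEstimates,
    frp_apparent,
    frp_extrapolate,
    fts_from_amplitudes,
    pfusion_regression,
    compound_probabilities,
    stp_metrics,
)
from .model_core import builtin_condition, equilibrium_occupancy, load_condition
from .ntf import ReleaseTensor, mls_target_value, ntf_three_component, ntf_two_component
from .synthetic import PopulationSpec, generate_population

__all__ = ["RunConfig", "run_pipeline", "analyze_cohort", "setup_logging"]

logger = logging.getLogger("calyxstp")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: Path
    stages: Sequence[str] = ("synth", "ntf", "analyze")
    condition: str = "control"
    params_file: Optional[Path] = None
    input_table: Optional[Path] = None
    seed: int = 0
    n_synapses: int = 50
    noise_cv: float = 0.1
    n_repetitions: int = 3
    rtol: float = 1e-8
    ntf_iters_two: int = 200
    ntf_iters_three: int = 100
    shift_fraction: float = 0.3
    frp_window: int = 10
    occupancy: float = 0.75
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data["out_dir"] = Path(data.get("out_dir", "results"))
        for key in ("params_file", "input_table"):
            if data.get(key):
                data[key] = Path(data[key])
        return cls(**data)

    def content_hash(self) -> str:
        payload = {k: str(v) for k, v in self.__dict__.items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]

    def condition_blocks(self):
        if self.params_file is not None:
            return load_condition(self.params_file)
        return builtin_condition(self.condition)


def _file_hash(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def analyze_cohort(
    tensor: ReleaseTensor,
    iters_two: int = 200,
    iters_three: int = 100,
    shift_fraction: float = 0.3,
    frp_window: int = 10,
    occupancy: float = 0.75,
) -> dict:
    """Full cohort analysis of a release tensor: NTF stages, pool estimates,
    fusion probability and train metrics.

    Returns a dictionary mirroring the headline per-condition parameters
    (m1, FRP, M_TS, M_LS, p_fusion, f_TS, F, p_r) plus per-synapse tables.
    """
    layers = list(tensor.layers)
    # initial quantal content per synapse: first response averaged over the
    # unconditioned layers
    plain = [l for l in layers if "pre" not in l] or layers
    plain_idx = [layers.index(l) for l in plain]
    m1_by_synapse = tensor.values[0][:, plain_idx].mean(axis=1)

    two = ntf_two_component(tensor, n_iter=iters_two)
    p_fusion_hat = pfusion_regression(m1_by_synapse, two.M_TS)

    # per-synapse apparent pools at the high frequencies, corrected by the
    # 1/FRP' vs ISI extrapolation
    frp_by_synapse = np.empty(tensor.n_synapses)
    frp_apparent_mean: dict[float, float] = {}
    high = [(l, f) for l, f in (("50Hz", 50.0), ("100Hz", 100.0), ("200Hz", 200.0)) if l in layers]
    per_freq: dict[float, np.ndarray] = {}
    for label, f in high:
        li = layers.index(label)
        per_freq[f] = np.array(
            [
                frp_apparent(tensor.values[:, s, li], f, fit_window=frp_window)
                for s in range(tensor.n_synapses)
            ]
        )
        frp_apparent_mean[f] = float(per_freq[f].mean())
    for s in range(tensor.n_synapses):
        frp_by_synapse[s] = frp_extrapolate({1.0 / f: per_freq[f][s] for f in per_freq})
    # cohort FRP from one regression through the pooled 1/FRP' scatter
    frp_mean = frp_extrapolate({1.0 / f: per_freq[f] for f in per_freq})

    target = mls_target_value(frp_mean, float(two.M_TS.mean()))
    three = ntf_three_component(
        tensor,
        frozen_bf_ts=two.base_functions[0],
        mls_target=target,
        n_iter=iters_three,
        shift_fraction=shift_fraction,
        initial_mts=two.M_TS,
        initial_bf_lsrs=two.base_functions[1],
    )
    f_ts = fts_from_amplitudes(three.amplitude("TS"), three.amplitude("LS"))
    F, p_r = compound_probabilities(f_ts, min(p_fusion_hat, 1.0), occupancy)

    metrics = {}
    for label, f in (("10Hz", 10.0), ("100Hz", 100.0), ("200Hz", 200.0)):
        if label in layers:
            li = layers.index(label)
            mean_trace = tensor.values[:, :, li].mean(axis=1)
            metrics[label] = stp_metrics(mean_trace, f).__dict__

    return {
        "m1_mean": float(m1_by_synapse.mean()),
        "FRP": frp_mean,
        "FRP_apparent": frp_apparent_mean,
        "M_TS_mean": float(two.M_TS.mean()),
        "M_LS_mean": float(three.amplitude("LS").mean()),
        "p_fusion": float(p_fusion_hat),
        "f_TS": float(f_ts),
        "F": float(F),
        "p_r": float(p_r),
        "initial_bf_ts": two.initial_bf_ts(),
        "metrics": metrics,
        "_pool_estimates": PoolEstimates(
            frp_apparent=frp_apparent_mean,
            frp=frp_mean,
            f_ts=float(f_ts),
            p_fusion_hat=float(p_fusion_hat),
            F=float(F),
            p_r=float(p_r),
        ),
        "_two": two,
        "_three": three,
        "_m1_by_synapse": m1_by_synapse,
        "_frp_by_synapse": frp_by_synapse,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write a manifest.

    Stages: ``synth`` (generate a synthetic cohort), ``equilibrium``
    (closed-form occupancy table), ``ntf`` + ``analyze`` (decomposition and
    pool estimates on the train table).  Any stage failure aborts with a
    diagnostic naming the stage.
    """
    setup_logging(config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }
    if config.input_table is not None:
        manifest["input_hashes"] = {str(config.input_table): _file_hash(config.input_table)}

    table_path = config.input_table
    try:
        if "synth" in config.stages:
            spec = PopulationSpec(
                n_synapses=config.n_synapses,
                condition=config.condition,
                noise_cv=config.noise_cv,
                n_repetitions=config.n_repetitions,
                seed=config.seed,
            )
            tensor, truth = generate_population(spec, rtol=config.rtol)
            table_path = out / "trains.csv"
            tensor.to_frame().to_csv(table_path, index=False)
            truth.frame().to_csv(out / "ground_truth.csv", index=False)
            manifest["stages"]["synth"] = {
                "trains": str(table_path),
                "ground_truth": str(out / "ground_truth.csv"),
            }
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'synth' failed: {exc}") from exc

    try:
        if "equilibrium" in config.stages:
            params, _, _ = config.condition_blocks()
            ca = np.linspace(50e-9, 500e-9, 46)
            rows = []
            for c in ca:
                occ = equilibrium_occupancy(params, c)
                rows.append((c, occ.ES, occ.LS, occ.TS))
            eq = pd.DataFrame(rows, columns=["ca_M", "ES", "LS", "TS"])
            eq.to_csv(out / "equilibrium.csv", index=False)
            manifest["stages"]["equilibrium"] = {"table": str(out / "equilibrium.csv")}
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'equilibrium' failed: {exc}") from exc

    results = None
    try:
        if "ntf" in config.stages or "analyze" in config.stages:
            if table_path is None:
                raise ValueError("no input table: run the synth stage or set input_table")
            tensor = ReleaseTensor.from_frame(pd.read_csv(table_path))
            results = analyze_cohort(
                tensor,
                iters_two=config.ntf_iters_two,
                iters_three=config.ntf_iters_three,
                shift_fraction=config.shift_fraction,
                frp_window=config.frp_window,
                occupancy=config.occupancy,
            )
            two, three = results.pop("_two"), results.pop("_three")
            results.pop("_pool_estimates")
            two.amplitude_frame().merge(
                three.amplitude_frame(), on="synapse_id", suffixes=("_2c", "_3c")
            ).to_csv(out / "amplitudes.csv", index=False)
            three.base_function_frame().to_csv(out / "base_functions.csv", index=False)
            with open(out / "fit_history.json", "w") as fh:
                json.dump(
                    {
                        "two_component": two.fit_history.tolist(),
                        "three_component": three.fit_history.tolist(),
                    },
                    fh,
                )
            per_syn = pd.DataFrame(
                {
                    "synapse_id": list(tensor.synapses),
                    "m1": results.pop("_m1_by_synapse"),
                    "FRP": results.pop("_frp_by_synapse"),
                }
            )
            per_syn.to_csv(out / "per_synapse.csv", index=False)
            with open(out / "results.json", "w") as fh:
                json.dump(results, fh, indent=2)
            manifest["stages"]["analyze"] = {
                "results": str(out / "results.json"),
                "amplitudes": str(out / "amplitudes.csv"),
                "base_functions": str(out / "base_functions.csv"),
                "fit_history": str(out / "fit_history.json"),
                "per_synapse": str(out / "per_synapse.csv"),
            }
    except RuntimeError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'ntf/analyze' failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("pipeline finished; manifest at %s", out / "manifest.json")
    return {"manifest": manifest, "results": results}
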