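"""Pool-size, fusion-probability and short-term-plasticity estimators.

This is the estimator layer that turns measured (or simulated) quantal-content
trains and NTF amplitudes into the quantities of interest:

* conversion of EPSC peak amplitudes to quantal contents via the effective
  quantal size q* (−6.6 pA in the presence of 1 mM kynurenate);
* the fast-releasing pool (FRP = LS + TS at rest), estimated per train
  frequency by back-extrapolating cumulative release (FRP', an
  incomplete-depletion estimate) and corrected by extrapolating 1/FRP'
  against the inter-stimulus interval to ISI = 0;
* the initial fusion probability as the slope of a regression through the
  origin of m1 against M_TS across synapses;
* compound release probabilities F = f_TS * p_fusion and
  p_r = f_TS * p_fusion * occupancy;
* train metrics: paired-pulse ratio, m5/m1, m_max/m1, steady-state depression;
* membrane-capacitance to vesicle-count conversion (80 aF per vesicle).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TrainMetrics",
    "PoolEstimates",
    "quantal_content",
    "frp_apparent",
    "frp_extrapolate",
    "pfusion_regression",
    "compound_probabilities",
    "stp_metrics",
    "dcm_to_sv",
    "fts_from_amplitudes",
]

#: effective quantal size (pA) in 1 mM kynurenate; inward currents negative
Q_STAR_PA = -6.6
#: single-vesicle membrane capacitance (aF)
SV_CAPACITANCE_AF = 80.0
#: high train frequencies usable for apparent-pool estimation (Hz)
FRP_FREQUENCIES = (50.0, 100.0, 200.0)
#: cumulative-release points used for the back-extrapolation line
FRP_FIT_WINDOW = 10


@dataclass(frozen=True)
class TrainMetrics:
    """Scalar short-term-plasticity descriptors of one quantal-content train."""

    m1: float
    m5_over_m1: float
    mmax_over_m1: float
    ppr: float
    ssd: float
    f_stim: float


@dataclass(frozen=True)
class PoolEstimates:
    """Cohort-level pool and probability estimates."""

    frp_apparent: Mapping[float, float]  # per f_stim (Hz) -> FRP' (SVs)
    frp: float  # ISI->0 extrapolated FRP (SVs)
    f_ts: float
    p_fusion_hat: float
    F: float
    p_r: float


def quantal_content(peak_amplitudes, q_star: float = Q_STAR_PA, allow_sign_mismatch: bool = False):
    """Convert eEPSC peak amplitudes (pA) to quantal contents m = peak / q*.

    Peaks are expected on the same sign convention as ``q_star`` (inward
    currents negative).  Sign mismatches warn, and raise unless
    ``allow_sign_mismatch`` is set, in which case magnitudes are used.
    """
    if q_star == 0:
        raise ValueError("q_star must be non-zero")
    peaks = np.asarray(peak_amplitudes, dtype=float)
    m = peaks / q_star
    if np.any(m < 0):
        warnings.warn("peak amplitudes and q_star differ in sign", stacklevel=2)
        if not allow_sign_mismatch:
            raise ValueError(
                "sign mismatch between peaks and q_star; pass allow_sign_mismatch=True "
                "to use magnitudes"
            )
        m = np.abs(m)
    if m.ndim == 0:
        return float(m)
    return m


def frp_apparent(
    m,
    f_stim: float,
    fit_window: int = FRP_FIT_WINDOW,
    frequencies: Sequence[float] = FRP_FREQUENCIES,
) -> float:
    """Apparent fast-releasing pool FRP' from one high-frequency train.

    Fits a straight line to the late, replenishment-dominated segment of
    cumulative release versus stimulus index (the last ``fit_window`` of the
    40 points by default) and returns its intercept at index 0; the slope
    absorbs the steady-state replenishment rate.
    """
    if f_stim not in frequencies:
        raise ValueError(f"f_stim must be one of {frequencies} Hz for FRP' estimation")
    m = np.asarray(m, dtype=float)
    if m.ndim != 1 or m.size < fit_window + 1:
        raise ValueError("train too short for the requested fit window")
    if np.mean(m[-5:]) >= m[0]:
        raise ValueError("train does not depress to a steady state; FRP' undefined")
    cum = np.cumsum(m)
    idx = np.arange(1, m.size + 1, dtype=float)
    slope, intercept = np.polyfit(idx[-fit_window:], cum[-fit_window:], 1)
    return float(intercept)


def frp_extrapolate(frp_apparent_by_isi: Mapping[float, "float | np.ndarray"]) -> float:
    """Correct FRP' for incomplete depletion: regress 1/FRP' on the
    inter-stimulus interval (s) and return the inverse of the intercept at
    ISI = 0 (i.e. the pool at infinite stimulation frequency).

    Each ISI may map to a single FRP' or to an array of per-synapse FRP'
    values; in the latter case a single regression line is fitted through the
    pooled scatter of all synapses' points, the way cohort-level pool
    estimates are drawn in 1/FRP'-vs-ISI plots.
    """
    if len(frp_apparent_by_isi) < 2:
        raise ValueError("need FRP' estimates at >= 2 distinct ISIs")
    isi_all, inv_all = [], []
    for isi in sorted(frp_apparent_by_isi):
        vals = np.atleast_1d(np.asarray(frp_apparent_by_isi[isi], dtype=float))
        isi_all.append(np.full(vals.size, isi))
        inv_all.append(1.0 / vals)
    fit = stats.linregress(np.concatenate(isi_all), np.concatenate(inv_all))
    if fit.intercept <= 0:
        raise ValueError("non-positive 1/FRP' intercept; inconsistent inputs")
    return float(1.0 / fit.intercept)


def pfusion_regression(m1_by_synapse, mts_by_synapse) -> float:
    """Initial fusion probability as the slope of the regression through the
    origin of m1 on M_TS across synapses: sum(m1*M_TS) / sum(M_TS^2)."""
    m1 = np.asarray(m1_by_synapse, dtype=float)
    mts = np.asarray(mts_by_synapse, dtype=float)
    if m1.shape != mts.shape or m1.size < 1:
        raise ValueError("m1 and M_TS vectors must be non-empty and equal length")
    if np.any(m1 < 0) or np.any(mts < 0):
        raise ValueError("inputs must be non-negative")
    denom = np.sum(mts**2)
    if denom == 0:
        raise ValueError("all M_TS are zero; slope undefined")
    return float(np.sum(m1 * mts) / denom)


def compound_probabilities(f_ts: float, p_fusion: float, occupancy: float):
    """Release fraction F = f_TS * p_fusion and per-site release probability
    p_r = F * occupancy (occupancy = fraction of non-empty sites at rest)."""
    for name, v in (("f_ts", f_ts), ("p_fusion", p_fusion), ("occupancy", occupancy)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    F = f_ts * p_fusion
    return F, F * occupancy


def stp_metrics(m, f_stim: float, ssd_mode: str = "mean_last5") -> TrainMetrics:
    """Short-term-plasticity metrics of one train.

    ``ssd_mode`` selects the steady-state numerator: mean of responses 36-40
    (measured/synthetic trains) or the last response (deterministic
    simulations).
    """
    m = np.asarray(m, dtype=float)
    if m.size < 5:
        raise ValueError("train must have >= 5 stimuli")
    m1 = float(m[0])
    if m1 == 0:
        return TrainMetrics(0.0, np.nan, np.nan, np.nan, np.nan, f_stim)
    if ssd_mode == "mean_last5":
        if m.size < 40:
            raise ValueError("mean_last5 steady state requires >= 40 stimuli")
        m_ss = float(np.mean(m[35:40]))
    elif ssd_mode == "last":
        m_ss = float(m[-1])
    else:
        raise ValueError("ssd_mode must be 'mean_last5' or 'last'")
    return TrainMetrics(
        m1=m1,
        m5_over_m1=float(m[4] / m1),
        mmax_over_m1=float(np.max(m[1:]) / m1),
        ppr=float(m[1] / m1),
        ssd=m_ss / m1,
        f_stim=f_stim,
    )


def dcm_to_sv(delta_cm_fF: float, sv_capacitance_aF: float = SV_CAPACITANCE_AF) -> float:
    """Convert a presynaptic membrane-capacitance jump (fF) into a vesicle
    count using the single-vesicle capacitance (aF); 1 fF = 1000 aF."""
    if delta_cm_fF <= 0 or sv_capacitance_aF <= 0:
        raise ValueError("inputs must be > 0")
    return delta_cm_fF * 1000.0 / sv_capacitance_aF


def fts_from_amplitudes(mts, mls) -> float:
    """Cohort f_TS estimate TS/(LS+TS) from NTF amplitudes (cohort means)."""
    mts_mean = float(np.mean(np.asarray(mts, dtype=float)))
    mls_mean = float(np.mean(np.asarray(mls, dtype=float)))
    if mts_mean + mls_mean <= 0:
        raise ValueError("mean amplitudes must be positive")
    return mts_mean / (mts_mean + mls_mean)
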