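"""Constrained non-negative tensor factorization (NTF) of release trains.

A cohort of synapses is stimulated with the same set of train protocols
("layers": six regular frequencies plus preconditioned variants of the two
highest).  The trial-averaged quantal contents form a tensor
``X[stimulus, synapse, layer]`` which is decomposed as::

    X[j, s, l]  ~  sum_c  A[s, c] * B[c, l, j]

where the per-synapse component amplitudes ``A`` (M_TS, M_LS, M_RS — the
numbers of vesicles that were tightly docked, loosely docked, or not yet
docked before stimulation) are shared across layers, and the base functions
``B`` (normalized release time courses) are shared across synapses within a
layer and normalized to unit cumulative sum over the 40 stimuli.

Constraints beyond plain non-negative least squares:

* BF_TS is constrained to the one-parameter release schedule of a
  pre-existing, non-replenished pool fusing with probability ``p`` per
  stimulus — a geometric decay whose first entry is ``p`` and whose decay
  ratio is ``1 - p`` — shared by all layers (which ties its first entry
  across layers exactly).  This coupling of scale and shape is what makes
  the TS/non-TS split identifiable: with a free-form BF_TS the problem has
  a flat direction (shrink the TS amplitudes, raise the first entry) along
  which iterates drift without changing the fit;
* BF_LS and BF_RS start from very small first-entry guesses, and their first
  entries are kept there, so that release on the first stimulus is
  attributed to pre-existing TS vesicles;
* in the three-component stage BF_TS is frozen to the two-component result
  and the mean M_LS is pulled a fixed fraction per iteration toward an
  externally supplied target (FRP − mean M_TS), because the LS/RS split is
  otherwise not unique.

Updates are multiplicative least-squares (Lee–Seung style) adapted to the
shared-base-function structure, which preserves non-negativity and decreases
the squared reconstruction error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar, nnls

__all__ = [
    "ReleaseTensor",
    "DecompositionResult",
    "ntf_two_component",
    "ntf_three_component",
    "mls_target_value",
]

_EPS = 1e-12


@dataclass
class ReleaseTensor:
    """Quantal contents indexed (stimulus, synapse, layer).

    ``values`` has shape (n_stim, n_synapses, n_layers); all entries must be
    non-negative and complete.  ``layers`` and ``synapses`` carry labels.
    """

    values: np.ndarray
    layers: Sequence[str]
    synapses: Sequence[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-d array (stimulus, synapse, layer)")
        if self.values.shape[1] != len(self.synapses):
            raise ValueError("synapse labels do not match tensor shape")
        if self.values.shape[2] != len(self.layers):
            raise ValueError("layer labels do not match tensor shape")
        if not np.isfinite(self.values).all():
            raise ValueError("tensor contains missing or non-finite entries")
        if (self.values < 0).any():
            raise ValueError("quantal contents must be non-negative")

    @property
    def n_stim(self) -> int:
        return self.values.shape[0]

    @property
    def n_synapses(self) -> int:
        return self.values.shape[1]

    @property
    def n_layers(self) -> int:
        return self.values.shape[2]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table (synapse_id, layer, stimulus_index, m); 1-based stimuli."""
        j, s, l = np.meshgrid(
            np.arange(1, self.n_stim + 1),
            np.arange(self.n_synapses),
            np.arange(self.n_layers),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "synapse_id": np.asarray(self.synapses)[s.ravel()],
                "layer": np.asarray(self.layers)[l.ravel()],
                "stimulus_index": j.ravel(),
                "m": self.values.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ReleaseTensor":
        """Assemble from a tidy table with columns synapse_id, layer,
        stimulus_index (1-based) and m.  Every (synapse, layer) trace must be
        complete."""
        synapses = list(pd.unique(frame["synapse_id"]))
        layers = list(pd.unique(frame["layer"]))
        n_stim = int(frame["stimulus_index"].max())
        values = np.full((n_stim, len(synapses), len(layers)), np.nan)
        s_idx = {s: i for i, s in enumerate(synapses)}
        l_idx = {l: i for i, l in enumerate(layers)}
        values[
            frame["stimulus_index"].to_numpy() - 1,
            frame["synapse_id"].map(s_idx).to_numpy(),
            frame["layer"].map(l_idx).to_numpy(),
        ] = frame["m"].to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError("incomplete traces: every (synapse, layer) needs all stimuli")
        return cls(values=values, layers=layers, synapses=synapses)


@dataclass
class DecompositionResult:
    """Amplitudes, base functions and fit history of one NTF stage."""

    amplitudes: np.ndarray  # (n_synapses, n_components)
    base_functions: np.ndarray  # (n_components, n_layers, n_stim)
    component_names: Sequence[str]
    fit_history: np.ndarray  # relative SSE per iteration
    layers: Sequence[str]
    synapses: Sequence[str]

    def amplitude(self, component: str) -> np.ndarray:
        return self.amplitudes[:, list(self.component_names).index(component)]

    @property
    def M_TS(self) -> np.ndarray:
        return self.amplitude("TS")

    def reconstruction(self) -> np.ndarray:
        return np.einsum("sc,clj->jsl", self.amplitudes, self.base_functions)

    def initial_bf_ts(self) -> float:
        """First entry of BF_TS (identical across layers by construction);
        this is the NTF estimate of the initial fusion probability."""
        return float(self.base_functions[list(self.component_names).index("TS"), 0, 0])

    def amplitude_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.amplitudes,
            columns=[f"M_{c}" for c in self.component_names],
        ).assign(synapse_id=list(self.synapses))[
            ["synapse_id"] + [f"M_{c}" for c in self.component_names]
        ]

    def base_function_frame(self) -> pd.DataFrame:
        rows = []
        for ci, cname in enumerate(self.component_names):
            for li, lname in enumerate(self.layers):
                for j in range(self.base_functions.shape[2]):
                    rows.append((cname, lname, j + 1, self.base_functions[ci, li, j]))
        return pd.DataFrame(rows, columns=["component", "layer", "stimulus_index", "bf"])


# ---------------------------------------------------------------------------
# update machinery
# ---------------------------------------------------------------------------


def _reconstruct(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return np.einsum("sc,clj->jsl", A, B)


def _relative_sse(X: np.ndarray, A: np.ndarray, B: np.ndarray) -> float:
    resid = X - _reconstruct(A, B)
    return float(np.sum(resid**2) / np.sum(X**2))


def _update_amplitudes(X: np.ndarray, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    num = np.einsum("jsl,clj->sc", X, B)
    den = np.einsum("jsl,clj->sc", _reconstruct(A, B), B)
    return A * num / np.maximum(den, _EPS)

def _update_base_functions(
    X: np.ndarray, A: np.ndarray, B: np.ndarray, frozen: Sequence[int] = ()
) -> np.ndarray:
    num = np.einsum("jsl,sc->clj", X, A)
    den = np.einsum("jsl,sc->clj", _reconstruct(A, B), A)
    Bn = B * num / np.maximum(den, _EPS)
    for c in frozen:
        Bn[c] = B[c]
    return Bn


#: cap on the first entry of the delayed (LS/RS) base functions: release on
#: the first stimulus is attributed to pre-existing tightly docked vesicles
_FIRST_ENTRY_GUESS = 1e-3


def _project_constraints(
    A: np.ndarray,
    B: np.ndarray,
    tie_first_entry: Optional[int],
    frozen: Sequence[int] = (),
    delayed: Sequence[int] = (),
    tie_layers: Optional[Sequence[int]] = None,
):
    """Tie the first BF entry of one component across layers (by averaging),
    keep the first entries of the delayed components near their very small
    initial guesses, and renormalize every base function to unit cumulative
    sum, rescaling the amplitudes compensatorily (by the layer-mean norm,
    since amplitudes are shared across layers)."""
    if tie_first_entry is not None and tie_first_entry not in frozen:
        idx = list(tie_layers) if tie_layers is not None else slice(None)
        B[tie_first_entry, idx, 0] = B[tie_first_entry, idx, 0].mean()
    n_stim = B.shape[2]
    for c in delayed:
        np.minimum(B[c, :, 0], _FIRST_ENTRY_GUESS / n_stim, out=B[c, :, 0])
    for c in range(B.shape[0]):
        if c in frozen:
            continue
        norms = B[c].sum(axis=1)  # per layer
        B[c] = B[c] / np.maximum(norms[:, None], _EPS)
        A[:, c] = A[:, c] * norms.mean()
    return A, B


def _nnls_amplitudes(X: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Initialize amplitudes by per-synapse non-negative least squares against
    the current base functions (layers stacked)."""
    n_stim, n_syn, n_layers = X.shape
    n_comp = B.shape[0]
    G = B.transpose(1, 2, 0).reshape(n_layers * n_stim, n_comp)
    A = np.empty((n_syn, n_comp))
    for s in range(n_syn):
        x = X[:, s, :].T.reshape(-1)
        A[s], _ = nnls(G, x)
    return A


def _init_bf_ts(X: np.ndarray) -> np.ndarray:
    """Geometric-decay initial guess for BF_TS, fitted per layer to the decay
    of the mean trace over the first stimuli (TS-dominated release)."""
    n_stim, _, n_layers = X.shape
    mean_traces = X.mean(axis=1)  # (n_stim, n_layers)
    B = np.empty((n_layers, n_stim))
    j = np.arange(n_stim)
    for l in range(n_layers):
        trace = mean_traces[:, l]
        m1 = max(trace[0], _EPS)
        m5 = max(trace[min(4, n_stim - 1)], _EPS)
        rho = float(np.clip((m5 / m1) ** (1.0 / max(min(4, n_stim - 1), 1)), 0.05, 0.95))
        bf = rho**j
        B[l] = bf / bf.sum()
    return B


def _geometric_bf(p: float, n_stim: int) -> np.ndarray:
    """Normalized release schedule of a pre-existing pool fusing with
    probability ``p`` per stimulus: entries proportional to p*(1-p)**(j-1)."""
    bf = p * (1.0 - p) ** np.arange(n_stim)
    return bf / bf.sum()


def _fit_geometric_p(rows: np.ndarray) -> float:
    """Least-squares projection of (row-normalized) base-function rows onto
    the geometric family; returns the shared shape parameter p."""
    n_stim = rows.shape[-1]
    rows = rows / np.maximum(rows.sum(axis=-1, keepdims=True), _EPS)

    def cost(p: float) -> float:
        return float(((rows - _geometric_bf(p, n_stim)) ** 2).sum())

    res = minimize_scalar(cost, bounds=(0.01, 0.95), method="bounded")
    return float(res.x)


def _init_bf_small_start(n_layers: int, n_stim: int, power: float = 1.0) -> np.ndarray:
    """Delayed-onset initial guess with a very small first entry, used for the
    components that should not contribute to the first response."""
    j = np.arange(n_stim, dtype=float)
    ramp = (j / max(n_stim - 1, 1)) ** power
    ramp[0] = 1e-3 / n_stim
    bf = ramp / ramp.sum()
    return np.tile(bf, (n_layers, 1))


def _check_tensor(tensor: ReleaseTensor) -> np.ndarray:
    X = tensor.values
    if np.all(X == 0):
        raise ValueError("all-zero tensor cannot be decomposed")
    return X


# ---------------------------------------------------------------------------
# public stages
# ---------------------------------------------------------------------------


def ntf_two_component(tensor: ReleaseTensor, n_iter: int = 200) -> DecompositionResult:
    """Stage 1: two-component decomposition into release from pre-existing
    tightly docked vesicles (TS) and everything else (LSRS).

    BF_TS is constrained to the shared geometric release schedule (see the
    module docstring); its first entry — identical across all layers by
    construction — is the cohort-level estimate of the initial fusion
    probability, and the per-synapse M_TS amplitudes estimate the number of
    tightly docked vesicles at rest.
    """
    X = _check_tensor(tensor)
    n_stim, n_syn, n_layers = X.shape
    B = np.empty((2, n_layers, n_stim))
    B[0] = _geometric_bf(_fit_geometric_p(_init_bf_ts(X)), n_stim)[None, :]
    B[1] = _init_bf_small_start(n_layers, n_stim, power=1.0)
    A = _nnls_amplitudes(X, B)

    history = np.empty(n_iter)
    for it in range(n_iter):
        A = _update_amplitudes(X, A, B)
        B = _update_base_functions(X, A, B)
        # mass-compensated projection of the TS row onto the geometric family
        A[:, 0] *= B[0].sum(axis=1).mean()
        B[0] = _geometric_bf(_fit_geometric_p(B[0]), n_stim)[None, :]
        A, B = _project_constraints(A, B, tie_first_entry=None, frozen=(0,), delayed=(1,))
        history[it] = _relative_sse(X, A, B)

    return DecompositionResult(
        amplitudes=A,
        base_functions=B,
        component_names=("TS", "LSRS"),
        fit_history=history,
        layers=tensor.layers,
        synapses=tensor.synapses,
    )


def mls_target_value(frp: float, mean_mts: float) -> float:
    """Target for the cohort-mean number of pre-existing loosely docked
    vesicles: the fast-releasing pool minus the mean M_TS."""
    if frp <= mean_mts:
        raise ValueError(
            f"FRP estimate ({frp:.6g}) must exceed mean M_TS ({mean_mts:.6g})"
        )
    return frp - mean_mts


def ntf_three_component(
    tensor: ReleaseTensor,
    frozen_bf_ts: np.ndarray,
    mls_target: float,
    n_iter: int = 100,
    shift_fraction: float = 0.3,
    initial_mts: Optional[np.ndarray] = None,
    initial_bf_lsrs: Optional[np.ndarray] = None,
) -> DecompositionResult:
    """Stage 2: three-component decomposition (TS / LS / RS) with BF_TS frozen
    to the two-component result and the cohort-mean M_LS pulled toward
    ``mls_target`` by ``shift_fraction`` per iteration.

    The M_LS adjustment rescales every synapse's M_LS proportionally and
    compensates M_RS by the opposite amount (clipped at zero), which preserves
    each synapse's total reconstructed quanta exactly because all base
    functions have unit cumulative sum.  The shift is applied between the
    amplitude and base-function updates, so the LS/RS shapes re-adapt to the
    shifted split each cycle and the cohort mean settles at the target (the
    split is otherwise not identifiable).  ``initial_bf_lsrs`` (ideally the
    combined LS+RS base function of the two-component stage) seeds both
    delayed components; without it a delayed-onset ramp is used.
    """
    if mls_target <= 0:
        raise ValueError("mls_target must be > 0")
    if not 0.0 <= shift_fraction <= 1.0:
        raise ValueError("shift_fraction must be in [0, 1]")
    X = _check_tensor(tensor)
    n_stim, n_syn, n_layers = X.shape
    frozen_bf_ts = np.asarray(frozen_bf_ts, dtype=float)
    if frozen_bf_ts.shape != (n_layers, n_stim):
        raise ValueError("frozen_bf_ts must have shape (n_layers, n_stim)")

    B = np.empty((3, n_layers, n_stim))
    B[0] = frozen_bf_ts
    if initial_bf_lsrs is not None:
        initial_bf_lsrs = np.asarray(initial_bf_lsrs, dtype=float)
        if initial_bf_lsrs.shape != (n_layers, n_stim):
            raise ValueError("initial_bf_lsrs must have shape (n_layers, n_stim)")
        B[1] = initial_bf_lsrs
        B[2] = initial_bf_lsrs
    else:
        B[1] = _init_bf_small_start(n_layers, n_stim, power=1.0)
        B[2] = _init_bf_small_start(n_layers, n_stim, power=2.0)
    A = _nnls_amplitudes(X, B)
    if initial_mts is not None:
        A[:, 0] = np.asarray(initial_mts, dtype=float)

    def _shift(A: np.ndarray) -> np.ndarray:
        mean_mls = A[:, 1].mean()
        if shift_fraction > 0 and mean_mls > 0:
            new_mean = mean_mls + shift_fraction * (mls_target - mean_mls)
            delta = A[:, 1] * (new_mean / mean_mls - 1.0)
            A[:, 1] += delta
            A[:, 2] = np.maximum(A[:, 2] - delta, 0.0)
        return A

    history = np.empty(n_iter)
    for it in range(n_iter):
        A = _update_amplitudes(X, A, B)
        A = _shift(A)
        B = _update_base_functions(X, A, B, frozen=(0,))
        A, B = _project_constraints(
            A, B, tie_first_entry=None, frozen=(0,), delayed=(1, 2)
        )
        history[it] = _relative_sse(X, A, B)

    return DecompositionResult(
        amplitudes=A,
        base_functions=B,
        component_names=("TS", "LS", "RS"),
        fit_history=history,
        layers=tensor.layers,
        synapses=tensor.synapses,
    )
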