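"""The eleven turning-intensity models.

Each model maps the configuration of neighbours (and, for the non-Markovian
variants, its recent history) to a latent *turning intensity* ``lambda`` — the
log-odds that the focal individual reverses its travel direction in the next
time step — which a logistic link converts to a probability.

Model families:

* ``Null`` — no interaction; a baseline intensity ``lambda0`` estimated from
  single-individual data.
* ``MF`` (mean field) — every opposite-moving individual ("negative"
  neighbour), anywhere on the ring, adds ``w_neg`` to the intensity.
* ``T`` (topological) — as MF but restricted to the ``K`` nearest neighbours.
* ``S1``-``S4`` (spatial, Markovian) — neighbours only count inside a spatial
  zone: symmetric of total width ``R`` centred on the focal (S1, S3) or
  extending ``R`` ahead of it (S2, S4).  S3/S4 additionally let same-direction
  ("positive") neighbours contribute ``w_pos`` (free sign).
* ``D1``-``D4`` (spatial, non-Markovian) — the spatial variants with memory: a
  neighbour's influence persists after it leaves the zone, decaying
  geometrically with factor ``alpha`` per step, and the intensity resets to
  baseline on the step after the focal's own turn.

The per-neighbour-trace semantics of the memory models is the default
*dialect*: an in-zone neighbour contributes its full weight (re-evaluated each
step from its current relative direction), a departed neighbour's trace decays
by ``alpha`` per step, and a focal turn clears all traces.  An *aggregate*
dialect (``lambda_t = lambda0 + alpha*(lambda_{t-1} - lambda0) + w*n_new``) is
provided as a configuration switch for sensitivity analysis; with ``alpha=0``
both dialects reduce exactly to the matching Markovian spatial model on any
configuration without a pending reset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import expit

from ._angles import angular_separation, signed_ahead

MODEL_IDS = ("Null", "MF", "T", "S1", "S2", "S3", "S4", "D1", "D2", "D3", "D4")

ZONE_KINDS = ("global", "nearest_k", "symmetric", "forward")


@dataclass(frozen=True)
class ZoneSpec:
    """Interaction-zone structure.

    ``extent`` is the zone radius ``R`` in radians (symmetric/forward kinds)
    or the neighbour count ``K`` (nearest_k); it is ``None`` for the global
    zone and when the extent is a free parameter supplied at evaluation time.
    """

    kind: str
    extent: float | int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ZONE_KINDS:
            raise ValueError(f"unknown zone kind {self.kind!r}")
        if self.extent is not None and self.extent <= 0:
            raise ValueError("zone extent must be positive")


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one model: zone kind, positive-neighbour flag, memory flag."""

    id: str
    zone: str | None          # None for the non-interacting Null model
    uses_positive: bool
    memory: bool


MODELS: dict[str, ModelSpec] = {
    "Null": ModelSpec("Null", None, False, False),
    "MF": ModelSpec("MF", "global", False, False),
    "T": ModelSpec("T", "nearest_k", False, False),
    "S1": ModelSpec("S1", "symmetric", False, False),
    "S2": ModelSpec("S2", "forward", False, False),
    "S3": ModelSpec("S3", "symmetric", True, False),
    "S4": ModelSpec("S4", "forward", True, False),
    "D1": ModelSpec("D1", "symmetric", False, True),
    "D2": ModelSpec("D2", "forward", False, True),
    "D3": ModelSpec("D3", "symmetric", True, True),
    "D4": ModelSpec("D4", "forward", True, True),
}


def get_model(model_id: str) -> ModelSpec:
    try:
        return MODELS[model_id]
    except KeyError:
        raise ValueError(f"unknown model id {model_id!r}") from None


@dataclass(frozen=True)
class ParamSet:
    """Parameter vector; fields are present iff the model uses them.

    ``lambda0`` baseline intensity (log-odds per step); ``w_neg`` >= 0
    increment per negative neighbour; ``w_pos`` increment per positive
    neighbour (unconstrained sign); ``R`` zone extent in radians; ``K``
    neighbour count; ``alpha`` in [0, 1) geometric memory decay per step.
    """

    lambda0: float
    w_neg: float | None = None
    w_pos: float | None = None
    R: float | None = None
    K: int | None = None
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.w_neg is not None and self.w_neg < 0:
            raise ValueError("w_neg must be >= 0")
        if self.alpha is not None and not (0.0 <= self.alpha < 1.0):
            raise ValueError("alpha must lie in [0, 1)")
        if self.R is not None and self.R <= 0:
            raise ValueError("R must be positive")
        if self.K is not None and self.K < 1:
            raise ValueError("K must be >= 1")


def free_param_names(model: ModelSpec) -> tuple[str, ...]:
    """Names of the model's free parameters (lambda0 is always pinned)."""
    if model.id == "Null":
        return ()
    if model.id == "MF":
        return ("w_neg",)
    if model.id == "T":
        return ("K", "w_neg")
    names: list[str] = ["R", "w_neg"]
    if model.uses_positive:
        names.append("w_pos")
    if model.memory:
        names.append("alpha")
    return tuple(names)


def require_params(model: ModelSpec, params: ParamSet) -> None:
    for name in free_param_names(model):
        if getattr(params, name) is None:
            raise ValueError(f"model {model.id} requires parameter {name!r}")


# ---------------------------------------------------------------------------
# geometry

def in_zone(focal_theta, focal_orientation, other_theta, zone: ZoneSpec):
    """Whether ``other_theta`` lies inside a spatial zone of the focal.

    Symmetric zones have total width ``extent`` (half-width R/2 on each side,
    boundary inclusive); forward zones cover the interval (0, R] ahead of the
    focal along its heading.  An individual exactly at the focal's position
    counts for a symmetric zone but not a forward one.
    """
    if zone.kind == "symmetric":
        return angular_separation(focal_theta, other_theta) <= zone.extent / 2.0
    if zone.kind == "forward":
        d = signed_ahead(focal_theta, focal_orientation, other_theta)
        return (d > 0) & (d <= zone.extent)
    raise ValueError("in_zone applies to symmetric/forward zones only")


def neighbour_counts(thetas, orientations, focal: int, zone: ZoneSpec):
    """(n_neg, n_pos) for one focal individual at one snapshot.

    ``n_neg`` counts opposite-orientation individuals inside the zone,
    ``n_pos`` same-orientation ones.  The global zone counts all others;
    ``nearest_k`` selects the K smallest angular separations with ties broken
    by ascending individual index.  The focal is never its own neighbour.
    """
    thetas = np.asarray(thetas, dtype=float)
    orientations = np.asarray(orientations)
    n = len(thetas)
    others = np.delete(np.arange(n), focal)
    if zone.kind == "global":
        sel = others
    elif zone.kind == "nearest_k":
        k = int(zone.extent)
        if k >= n:
            raise ValueError("K must be < N")
        sep = angular_separation(thetas[focal], thetas[others])
        order = np.argsort(sep, kind="stable")  # stable: ties by ascending index
        sel = others[order[:k]]
    else:
        inside = in_zone(thetas[focal], orientations[focal], thetas[others], zone)
        sel = others[inside]
    opp = orientations[sel] != orientations[focal]
    return int(np.sum(opp)), int(np.sum(~opp))


# ---------------------------------------------------------------------------
# intensities

def turn_probability(lam):
    """Logistic link: p = 1 / (1 + exp(-lambda)).  Strictly increasing."""
    return expit(lam)


def intensity_markov(model: ModelSpec, params: ParamSet, counts):
    """Turning intensity of a memoryless model from zone counts (n_neg, n_pos)."""
    if model.memory:
        raise ValueError("intensity_markov applies to memoryless models")
    n_neg, n_pos = counts
    if model.id == "Null":
        return params.lambda0
    require_params(model, params)
    lam = params.lambda0 + params.w_neg * n_neg
    if model.uses_positive:
        lam = lam + params.w_pos * n_pos
    return lam


@dataclass
class MemoryState:
    """Per-focal memory for the non-Markovian models.

    ``traces`` maps neighbour id to its current contribution (units of w);
    ``prev_lambda`` and ``prev_in_zone`` support the aggregate dialect.
    """

    traces: dict = field(default_factory=dict)
    prev_lambda: float | None = None
    prev_in_zone: frozenset = frozenset()


def intensity_memory_step(model: ModelSpec, params: ParamSet, mem: MemoryState,
                          in_zone_neighbours: Mapping[int, bool],
                          focal_turned_last_step: bool,
                          dialect: str = "trace"):
    """One step of the non-Markovian intensity for a single focal individual.

    ``in_zone_neighbours`` maps each neighbour id currently inside the zone to
    a flag: True if it travels opposite to the focal (negative neighbour).

    Trace dialect (default): an in-zone neighbour contributes its full weight,
    re-evaluated from its current relative direction; a departed neighbour's
    trace decays by ``alpha`` per step; after the focal's own turn all traces
    are cleared and the intensity is exactly ``lambda0``.

    Aggregate dialect: ``lambda_t = lambda0 + alpha*(lambda_{t-1} - lambda0)
    + sum of weights of new arrivals``, with the same reset rule.

    Returns ``(lambda, new MemoryState)``.
    """
    if not model.memory:
        raise ValueError("intensity_memory_step applies to memory models")
    require_params(model, params)
    lam0, alpha = params.lambda0, params.alpha

    def weight(is_neg: bool) -> float:
        if is_neg:
            return params.w_neg
        return params.w_pos if model.uses_positive else 0.0

    current = frozenset(in_zone_neighbours)
    if dialect == "trace":
        if focal_turned_last_step:
            return lam0, MemoryState({}, lam0, current)
        traces = {}
        for j, tr in mem.traces.items():
            if j not in current:
                decayed = alpha * tr
                if decayed != 0.0:
                    traces[j] = decayed
        for j, is_neg in in_zone_neighbours.items():
            traces[j] = weight(is_neg)
        lam = lam0 + sum(traces.values())
        return lam, MemoryState(traces, lam, current)
    if dialect == "aggregate":
        if focal_turned_last_step:
            return lam0, MemoryState({}, lam0, current)
        prev_lam = mem.prev_lambda if mem.prev_lambda is not None else lam0
        new_ids = current - mem.prev_in_zone
        contrib = sum(weight(in_zone_neighbours[j]) for j in new_ids)
        lam = lam0 + alpha * (prev_lam - lam0) + contrib
        return lam, MemoryState({}, lam, current)
    raise ValueError("dialect must be 'trace' or 'aggregate'")


# ---------------------------------------------------------------------------
# vectorised memory recursions shared by the likelihood and the simulator

def memory_trace_update(tau, inz, W, turned_prev, lam0: float, alpha: float):
    """One vectorised step of the trace dialect.

    ``tau``/``inz``/``W`` have shape (..., N, N) indexed [focal, neighbour];
    ``turned_prev`` has shape (..., N).  Returns ``(lam, tau_new)`` with
    ``lam`` of shape (..., N).  Diagonal entries must be excluded upstream
    (``inz`` False on the diagonal keeps the self-trace at zero).
    """
    tau = np.where(inz, W, alpha * tau)
    tau = np.where(turned_prev[..., None], 0.0, tau)
    lam = lam0 + tau.sum(axis=-1)
    lam = np.where(turned_prev, lam0, lam)
    return lam, tau


def memory_aggregate_update(lam_prev, new_contrib, turned_prev, lam0: float, alpha: float):
    """One vectorised step of the aggregate dialect (shapes (..., N))."""
    lam = lam0 + alpha * (lam_prev - lam0) + new_contrib
    return np.where(turned_prev, lam0, lam)


def table_param_columns(model: ModelSpec, params: ParamSet) -> dict:
    """Report row with the standard column names (NA for unused parameters)."""
    used = set(free_param_names(model))
    return {
        "lambda0": params.lambda0,
        "R_rad": params.R if "R" in used else None,
        "K": params.K if "K" in used else None,
        "w_neg": params.w_neg if "w_neg" in used else None,
        "w_pos": params.w_pos if "w_pos" in used else None,
        "alpha": params.alpha if "alpha" in used else None,
    }
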