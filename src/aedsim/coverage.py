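"""Response-time models and coverage structures.

Two response models are compared on the same demand points:

* **ambulance** — one-way vehicular travel from the station to the scene
  (dispatch and on-scene intervals are deliberately excluded; the model
  is station→scene travel only);
* **bystander round-trip** — a bystander walks from the victim to the
  nearest AED and back while CPR continues, so the response time is the
  walking round-trip. At the default 300 s budget this allows 150 s
  (2.5 min) per stretch.

A demand point is *covered* when its response time is within the budget
(inclusive: "within 300 s" reads as ≤ 300 s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from aedsim.network import (
    PointSet,
    RoadNetwork,
    TravelMode,
    TravelTimeMatrix,
    get_mode,
    snap_points,
    travel_time_matrix,
)

__all__ = [
    "CoverageParams",
    "ResponseTimes",
    "CoverageMatrix",
    "ambulance_response_times",
    "bystander_roundtrip_times",
    "roundtrip_time_matrix",
    "coverage_count",
    "build_coverage_matrix",
]


@dataclass
class CoverageParams:
    """Service-standard parameters.

    ``threshold_s`` is the coverage budget (default 300 s); the budget is
    applied to the *total* round trip, which under symmetric walking
    equals the per-stretch reading (``stretch_limit_s`` each way, kept as
    informational metadata).
    """

    threshold_s: float = 300.0
    stretch_limit_s: float = 150.0
    bystander_mode: TravelMode = field(default_factory=lambda: get_mode("walk"))
    ambulance_mode: TravelMode = field(default_factory=lambda: get_mode("ambulance"))

    def __post_init__(self) -> None:
        if self.threshold_s <= 0:
            raise ValueError("threshold_s must be positive")


@dataclass
class ResponseTimes:
    """Per-demand-point response times (seconds), aligned with demand order."""

    demand: PointSet
    times: np.ndarray
    model: str  # ambulance | bystander_roundtrip
    params: CoverageParams

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (len(self.demand),):
            raise ValueError("times length must match demand set")
        if np.any(self.times < 0):
            raise ValueError("response times must be nonnegative")


@dataclass
class CoverageMatrix:
    """Binary coverage relation: a[i, j] = 1 iff candidate j covers demand i."""

    demand: PointSet
    candidates: PointSet
    a: np.ndarray
    params: CoverageParams

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.int8)
        if self.a.shape != (len(self.demand), len(self.candidates)):
            raise ValueError("coverage matrix shape mismatch")
        if not np.isin(self.a, (0, 1)).all():
            raise ValueError("coverage entries must be 0/1")


def ambulance_response_times(
    network: RoadNetwork,
    station: PointSet,
    demand: PointSet,
    params: CoverageParams | None = None,
) -> ResponseTimes:
    """One-way vehicular travel time from the (nearest) station to each scene."""
    params = params or CoverageParams()
    if len(station) == 0:
        raise ValueError("empty station set")
    m = travel_time_matrix(network, station, demand, params.ambulance_mode)
    times = m.t.min(axis=0)
    return ResponseTimes(demand=m.destinations, times=times, model="ambulance", params=params)


def roundtrip_time_matrix(
    network: RoadNetwork,
    demand: PointSet,
    aed_sites: PointSet,
    params: CoverageParams | None = None,
) -> TravelTimeMatrix:
    """Walking round-trip time demand i ↔ AED site j (both legs summed).

    Pedestrian traversal is undirected, so this equals twice the one-way
    time; both legs are computed explicitly so the model stays valid if an
    asymmetric bystander mode is ever configured.
    """
    params = params or CoverageParams()
    fwd = travel_time_matrix(network, demand, aed_sites, params.bystander_mode)
    if params.bystander_mode.directed:
        back = travel_time_matrix(
            network, fwd.destinations, fwd.origins, params.bystander_mode
        )
        rt = fwd.t + back.t.T
    else:
        # undirected traversal: the return leg equals the outbound leg
        rt = 2.0 * fwd.t
    return TravelTimeMatrix(fwd.origins, fwd.destinations, params.bystander_mode, rt)


def bystander_roundtrip_times(
    network: RoadNetwork,
    demand: PointSet,
    aed_sites: PointSet,
    params: CoverageParams | None = None,
) -> ResponseTimes:
    """Round-trip walking time to the nearest AED, per demand point.

    With no AED sites every time is ``+inf`` (no device to fetch).
    """
    params = params or CoverageParams()
    if len(demand) == 0:
        raise ValueError("demand set is empty")
    if len(aed_sites) == 0:
        snapped = snap_points(network, demand)
        times = np.full(len(demand), math.inf)
        return ResponseTimes(snapped, times, "bystander_roundtrip", params)
    m = roundtrip_time_matrix(network, demand, aed_sites, params)
    return ResponseTimes(m.origins, m.t.min(axis=1), "bystander_roundtrip", params)


def coverage_count(times: ResponseTimes, params: CoverageParams | None = None) -> tuple[int, float]:
    """Count (and fraction) of demand points attended within the budget."""
    params = params or times.params
    n = len(times.times)
    count = int(np.sum(times.times <= params.threshold_s))
    return count, count / n if n else 0.0


def build_coverage_matrix(
    network: RoadNetwork,
    demand: PointSet,
    candidates: PointSet,
    params: CoverageParams | None = None,
) -> CoverageMatrix:
    """Binary coverage: candidate j covers demand i iff the walking
    round trip fits the budget."""
    params = params or CoverageParams()
    rt = roundtrip_time_matrix(network, demand, candidates, params)
    a = (rt.t <= params.threshold_s).astype(np.int8)
    return CoverageMatrix(demand=rt.origins, candidates=rt.destinations, a=a, params=params)
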