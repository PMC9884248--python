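"""Huff choice probabilities, accessibility, criticality, isolation, compounding
and scenario comparison.

The measures, per origin ``S_i`` with population weight ``w_s`` and facilities
``j`` with footprint areas ``A_j``:

* choice probability (Huff gravity model over the reachable choice set)

      P[i, j] = (A_j / t[i, j]) / sum_k reachable (A_k / t[i, k])

* accessibility — the expected travel time to the whole service system

      Accessibility_i = sum_j t[i, j] * P[i, j]

* criticality — preference- and population-weighted edge betweenness: each
  trip i -> j contributes ``alpha * w_s * P[i, j]`` to every edge of its
  tie-broken shortest path, and an edge's score is the sum over all trips;

* isolation — the total population at origins from which no facility at all
  is reachable.

Facilities that become unreachable under a hazard are renormalized out of the
choice set: the remaining probabilities still sum to one, capturing the shift
of preference toward the facilities that stay reachable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import jensenshannon

from .errors import ValidationError
from .network_model import Amenity, RoadNetwork, edge_key
from .hazards import Scenario
from .routing import ODMatrix

__all__ = [
    "ChoiceMatrix",
    "ServiceImportance",
    "AccessibilityResult",
    "CriticalityResult",
    "IsolationResult",
    "ScenarioComparison",
    "huff_probabilities",
    "choice_matrix",
    "accessibility",
    "criticality",
    "isolation",
    "compound_aggregate",
    "compare_scenarios",
    "TIME_FLOOR_MIN",
]

#: Co-located origin/facility pairs (t = 0) would put a zero in the Huff
#: denominator; travel times are floored at this value (minutes) instead,
#: preserving near-certain choice of a co-located facility without infinities.
TIME_FLOOR_MIN = 0.1

#: Weighted access-share bins, in hours (upper-open), plus overflow and
#: unreachable categories.
ACCESS_BINS_H = ((0, 1), (1, 2), (2, 3), (3, 4))


@dataclass
class ServiceImportance:
    """Importance factor alpha per service type (policy-provided; default 1)."""

    alpha: Mapping[str, float] = field(default_factory=dict)
    default: float = 1.0

    def __post_init__(self) -> None:
        for k, a in self.alpha.items():
            if a < 0 or not math.isfinite(a):
                raise ValidationError(f"alpha for {k!r} must be finite and >= 0")

    def lookup(self, service_type: str) -> float:
        return float(self.alpha.get(service_type, self.default))


@dataclass
class ChoiceMatrix:
    """Huff probabilities P[i, j] of origin i choosing facility j.

    Rows over reachable facilities sum to 1; unreachable facilities carry 0.
    An all-zero row marks an isolated origin.
    """

    origin_ids: list[str]
    dest_ids: list[str]
    probabilities: np.ndarray
    areas: np.ndarray

    def top_choice(self) -> list[str | None]:
        """argmax facility per origin (None for isolated origins)."""
        out: list[str | None] = []
        for row in self.probabilities:
            if row.sum() == 0:
                out.append(None)
            else:
                out.append(self.dest_ids[int(np.argmax(row))])
        return out


def huff_probabilities(
    od: ODMatrix,
    areas: Sequence[float] | Mapping[str, float],
    origin_index: int,
    time_floor_min: float = TIME_FLOOR_MIN,
) -> np.ndarray:
    """Huff choice-probability vector for one origin.

    Attractivity of facility j is ``A_j / t[i, j]`` (area over travel time);
    probabilities are these attractivities normalized over the reachable
    choice set.  Unreachable facilities are excluded from numerator and
    denominator and get probability 0; if nothing is reachable the vector is
    all zeros (isolated origin).
    """
    a = _areas_array(areas, od.dest_ids)
    t = od.times[origin_index].astype(float).copy()
    reachable = np.isfinite(t)
    p = np.zeros_like(t)
    if not reachable.any():
        return p
    t_eff = np.maximum(t[reachable], time_floor_min)
    attract = a[reachable] / t_eff
    p[reachable] = attract / attract.sum()
    return p


def choice_matrix(
    od: ODMatrix,
    areas: Sequence[float] | Mapping[str, float],
    time_floor_min: float = TIME_FLOOR_MIN,
) -> ChoiceMatrix:
    """Huff probabilities for every origin (row-wise :func:`huff_probabilities`)."""
    a = _areas_array(areas, od.dest_ids)
    probs = np.vstack(
        [huff_probabilities(od, a, i, time_floor_min) for i in range(len(od.origin_ids))]
    ) if od.origin_ids else np.zeros((0, len(od.dest_ids)))
    return ChoiceMatrix(
        origin_ids=list(od.origin_ids),
        dest_ids=list(od.dest_ids),
        probabilities=probs,
        areas=a,
    )


def _areas_array(areas, dest_ids: list[str]) -> np.ndarray:
    if isinstance(areas, Mapping):
        a = np.array([float(areas[d]) for d in dest_ids])
    else:
        a = np.asarray(areas, dtype=float)
    if (a < 0).any():
        raise ValidationError("facility areas must be non-negative")
    return a


@dataclass
class AccessibilityResult:
    """Expected travel time (minutes) per origin, with isolated origins set apart.

    Isolated origins have no finite expectation; they are excluded from the
    summary statistics and reported through ``isolated``.
    """

    origin_ids: list[str]
    expected_min: np.ndarray  # NaN for isolated origins
    isolated: np.ndarray  # bool mask

    @property
    def mean(self) -> float:
        vals = self.expected_min[~self.isolated]
        return float(np.mean(vals)) if len(vals) else math.nan

    @property
    def median(self) -> float:
        vals = self.expected_min[~self.isolated]
        return float(np.median(vals)) if len(vals) else math.nan


def accessibility(od: ODMatrix, choice: ChoiceMatrix) -> AccessibilityResult:
    """Probability-weighted expected travel time to the service system."""
    n = len(od.origin_ids)
    expected = np.full(n, np.nan)
    iso = od.isolated_mask()
    for i in range(n):
        if iso[i]:
            continue
        reach = np.isfinite(od.times[i])
        expected[i] = float(np.dot(od.times[i][reach], choice.probabilities[i][reach]))
    return AccessibilityResult(list(od.origin_ids), expected, iso)


@dataclass
class CriticalityResult:
    """Per-edge criticality scores with ranks and a display-oriented scaling."""

    scores: dict[tuple[str, str], float]

    def ranked(self) -> list[tuple[tuple[str, str], float]]:
        """Edges by descending score, ties broken by edge id."""
        return sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))

    def scaled(self) -> dict[tuple[str, str], float]:
        """Min-max scaling to [0, 1] over edges with nonzero score (display only)."""
        nz = [s for s in self.scores.values() if s > 0]
        if not nz:
            return {k: 0.0 for k in self.scores}
        lo, hi = min(nz), max(nz)
        span = hi - lo
        return {
            k: (1.0 if span == 0 and s > 0 else (s - lo) / span if s > 0 else 0.0)
            for k, s in self.scores.items()
        }

    def total(self) -> float:
        return float(sum(self.scores.values()))


def criticality(
    network: RoadNetwork | Scenario,
    od: ODMatrix,
    choice: ChoiceMatrix,
    weights: Sequence[float] | np.ndarray | None = None,
    alpha: float | ServiceImportance = 1.0,
    amenities: Sequence[Amenity] | None = None,
) -> CriticalityResult:
    """Population- and preference-weighted edge criticality.

    For every finite trip i -> j the contribution ``alpha_j * w_i * P[i, j]``
    is imputed to each edge of the tie-broken shortest path from i to j
    (``od`` must have been computed with ``return_paths=True``).  Edges used
    by no trip score 0.

    ``alpha`` may be a scalar or a :class:`ServiceImportance`; the latter
    requires ``amenities`` to resolve each destination's service type.
    """
    if od.paths is None:
        raise ValidationError("criticality needs an ODMatrix computed with return_paths=True")
    graph = network.network.graph if isinstance(network, Scenario) else network.graph
    directed = network.baseline.directed if isinstance(network, Scenario) else network.directed
    if weights is None:
        weights = od.origin_weights
    if weights is None:
        raise ValidationError("origin weights are required for criticality")
    w = np.asarray(weights, dtype=float)

    if isinstance(alpha, ServiceImportance):
        if amenities is None:
            raise ValidationError("ServiceImportance alpha requires the amenity list")
        by_id = {am.id: am for am in amenities}
        alpha_j = np.array([alpha.lookup(by_id[d].service_type) for d in od.dest_ids])
    else:
        alpha_j = np.full(len(od.dest_ids), float(alpha))

    scores = {edge_key(u, v, directed): 0.0 for u, v in graph.edges}
    for i, o in enumerate(od.origin_ids):
        for j, d in enumerate(od.dest_ids):
            if not math.isfinite(od.times[i, j]):
                continue
            c = alpha_j[j] * w[i] * choice.probabilities[i, j]
            if c == 0:
                continue
            seq = od.paths[(o, d)]
            for a, b in zip(seq, seq[1:]):
                scores[edge_key(a, b, directed)] += c
    return CriticalityResult(scores)


@dataclass
class IsolationResult:
    """Isolated population total and the origins contributing to it."""

    total_population: float
    isolated_origins: list[str]


def isolation(od: ODMatrix, weights: Sequence[float] | np.ndarray | None = None) -> IsolationResult:
    """Population that cannot reach any facility (every t[i, j] infinite)."""
    if weights is None:
        weights = od.origin_weights
    if weights is None:
        raise ValidationError("origin weights are required for isolation")
    w = np.asarray(weights, dtype=float)
    mask = od.isolated_mask()
    return IsolationResult(
        total_population=float(w[mask].sum()),
        isolated_origins=[o for o, m in zip(od.origin_ids, mask) if m],
    )


def compound_aggregate(results: Sequence, mode: str):
    """Combine per-hazard results into a compound result.

    Criticality results combine edge-wise by ``sum`` or ``max``; accessibility
    results only ever combine by per-origin ``max`` (requesting ``sum`` is an
    error).  Isolated origins stay isolated in the compound.
    """
    if not results:
        raise ValidationError("no results to aggregate")
    first = results[0]
    if isinstance(first, CriticalityResult):
        if mode not in ("sum", "max"):
            raise ValidationError(f"criticality compound mode must be sum or max, got {mode!r}")
        keys = set()
        for r in results:
            keys |= set(r.scores)
        op = sum if mode == "sum" else max
        return CriticalityResult(
            {k: float(op(r.scores.get(k, 0.0) for r in results)) for k in keys}
        )
    if isinstance(first, AccessibilityResult):
        if mode != "max":
            raise ValidationError("accessibility compound supports only the max mode")
        ids = first.origin_ids
        for r in results[1:]:
            if r.origin_ids != ids:
                raise ValidationError("accessibility results cover different origin sets")
        iso = np.logical_or.reduce([r.isolated for r in results])
        stacked = np.vstack([r.expected_min for r in results])
        expected = np.nanmax(stacked, axis=0)
        expected[iso] = np.nan
        return AccessibilityResult(list(ids), expected, iso)
    raise ValidationError(f"cannot aggregate results of type {type(first).__name__}")


@dataclass
class ScenarioComparison:
    """How a disrupted scenario differs from the baseline."""

    js_divergence: float
    pref_change_fraction: float
    n_pref_changed: int
    n_comparable: int
    n_isolated_any: int
    shift_graph: dict[tuple[str, str], int]
    mean_time_delta_min: float
    access_share_baseline: dict[str, float]
    access_share_disrupted: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "js_divergence": self.js_divergence,
            "pref_change_fraction": self.pref_change_fraction,
            "n_pref_changed": self.n_pref_changed,
            "n_comparable": self.n_comparable,
            "n_isolated_any": self.n_isolated_any,
            "shift_graph": [
                {"from": a, "to": b, "count": c} for (a, b), c in sorted(self.shift_graph.items())
            ],
            "mean_time_delta_min": self.mean_time_delta_min,
            "access_share_baseline": self.access_share_baseline,
            "access_share_disrupted": self.access_share_disrupted,
        }


def _js_divergence(base: np.ndarray, dis: np.ndarray, n_bins: int) -> float:
    """Jensen-Shannon divergence (natural log) between histogrammed samples.

    Both samples are binned on shared equal-width bins spanning their pooled
    finite range.  Identical samples give exactly 0.
    """
    base = base[np.isfinite(base)]
    dis = dis[np.isfinite(dis)]
    if len(base) == 0 or len(dis) == 0:
        return math.nan
    pooled = np.concatenate([base, dis])
    lo, hi = float(pooled.min()), float(pooled.max())
    if lo == hi:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    p, _ = np.histogram(base, bins=edges)
    q, _ = np.histogram(dis, bins=edges)
    # scipy returns the JS *distance* (sqrt of the divergence)
    return float(jensenshannon(p, q, base=math.e) ** 2)


def access_share_table(
    access: AccessibilityResult, weights: Sequence[float] | np.ndarray
) -> dict[str, float]:
    """Population shares (%) by expected-access-time bin, in hours.

    Bins: [0-1), [1-2), [2-3), [3-4), 4+ and Unreachable; shares sum to 100.
    """
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    table: dict[str, float] = {}
    hours = access.expected_min / 60.0
    for lo, hi in ACCESS_BINS_H:
        m = ~access.isolated & (hours >= lo) & (hours < hi)
        table[f"{lo} - {hi}"] = 100.0 * w[m].sum() / total if total else 0.0
    m4 = ~access.isolated & (hours >= ACCESS_BINS_H[-1][1])
    table["4+"] = 100.0 * w[m4].sum() / total if total else 0.0
    table["Unreachable"] = 100.0 * w[access.isolated].sum() / total if total else 0.0
    return table


def compare_scenarios(
    base_access: AccessibilityResult,
    base_choice: ChoiceMatrix,
    dis_access: AccessibilityResult,
    dis_choice: ChoiceMatrix,
    weights: Sequence[float] | np.ndarray,
    n_bins: int = 256,
    base_od: ODMatrix | None = None,
    dis_od: ODMatrix | None = None,
) -> ScenarioComparison:
    """Compare a disrupted scenario against the baseline.

    Reports the Jensen-Shannon divergence of the accessibility distributions
    (histogrammed on shared bins), the fraction of origins whose top-choice
    facility changed (origins isolated in either scenario are counted
    separately, not in the fraction), the facility-to-facility preference
    shift graph, the mean accessibility delta over origins finite in both
    scenarios, and the binned population access-share tables.
    """
    if base_access.origin_ids != dis_access.origin_ids:
        raise ValidationError("scenario comparison requires identical origin sets")
    w = np.asarray(weights, dtype=float)

    js = _js_divergence(base_access.expected_min, dis_access.expected_min, n_bins)

    base_top = base_choice.top_choice()
    dis_top = dis_choice.top_choice()
    shift: dict[tuple[str, str], int] = {}
    changed = comparable = iso_any = 0
    for bt, dt in zip(base_top, dis_top):
        if bt is None or dt is None:
            iso_any += 1
            continue
        comparable += 1
        if bt != dt:
            changed += 1
            shift[(bt, dt)] = shift.get((bt, dt), 0) + 1

    both = ~base_access.isolated & ~dis_access.isolated
    delta = (
        float(np.mean(dis_access.expected_min[both] - base_access.expected_min[both]))
        if both.any()
        else math.nan
    )

    return ScenarioComparison(
        js_divergence=js,
        pref_change_fraction=changed / comparable if comparable else 0.0,
        n_pref_changed=changed,
        n_comparable=comparable,
        n_isolated_any=iso_any,
        shift_graph=shift,
        mean_time_delta_min=delta,
        access_share_baseline=access_share_table(base_access, w),
        access_share_disrupted=access_share_table(dis_access, w),
    )
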