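"""Streamline seeding, integration and pulmonary flow distribution (PFD).

PFD from an inlet A to an outlet B is the percentage of classified traces
seeded at A that reach B:

    PFD_{A,B} = N_{A,B} / (N_{A,LPA} + N_{A,RPA}) * 100

Traces that reach neither outlet (mask exit, stagnation, or step limit) are
"missing" and excluded from the PFD denominator; their fraction is reported
as a data-quality diagnostic.

Integration is steady streamline tracing of the time-averaged field:
4th-order Runge-Kutta in arc length with trilinear velocity interpolation.
A trace is classified at its first crossing of an outlet cutting plane where
the crossing point lies inside that outlet's lumen.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .core import INLETS, OUTLETS, SegmentationMask, VelocityField, \
    check_geometry
from .errors import DomainError, GeometryError, InputError
from .quantify import CrossSection, plane_flow_rate

STAGNATION_SPEED = 1e-4  # m/s; below this a trace is considered stagnant


@dataclass
class Trace:
    """One integrated streamline."""

    points_mm: np.ndarray        # (n, 3), n >= 1
    seed_region: str
    status: str                  # "reached-LPA" | "reached-RPA" | "missing"
    steps: int
    reason: str                  # "outlet" | "left-mask" | "max-steps" | "stagnation"
    destination: str | None = None   # outlet name when status is reached-*


@dataclass
class PFDResult:
    """Trace counts and the derived pulmonary-flow-distribution percentages."""

    counts: dict[str, dict[str, int]]        # counts[source][outlet]
    seeded: dict[str, int]
    missing: dict[str, int]
    source_weights: dict[str, float]         # pooling weights (e.g. inlet |Q|)
    pfd_pct: dict[str, dict[str, float | None]] = dc_field(default_factory=dict)
    total_pct: dict[str, float | None] = dc_field(default_factory=dict)
    missing_fraction_per_source: dict[str, float] = dc_field(default_factory=dict)
    missing_fraction_overall: float = 0.0
    seeded_total: int = 0
    undefined_sources: list[str] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        outlets = sorted({o for c in self.counts.values() for o in c})
        self.pfd_pct = {}
        self.undefined_sources = []
        for src, c in self.counts.items():
            classified = sum(c.values())
            if classified == 0:
                self.pfd_pct[src] = {o: None for o in outlets}
                self.undefined_sources.append(src)
            else:
                self.pfd_pct[src] = {o: 100.0 * c[o] / classified
                                     for o in outlets}
        defined = [s for s in self.counts if s not in self.undefined_sources]
        self.total_pct = {}
        wsum = sum(self.source_weights.get(s, 0.0) for s in defined)
        for o in outlets:
            if not defined or wsum <= 0:
                self.total_pct[o] = None
            else:
                self.total_pct[o] = sum(
                    self.source_weights[s] * self.pfd_pct[s][o]
                    for s in defined) / wsum
        self.missing_fraction_per_source = {
            s: (self.missing[s] / self.seeded[s]) if self.seeded[s] else 1.0
            for s in self.seeded}
        self.seeded_total = sum(self.seeded.values())
        tot_missing = sum(self.missing.values())
        self.missing_fraction_overall = (
            tot_missing / self.seeded_total if self.seeded_total else 1.0)


def missing_fraction(result: PFDResult) -> dict[str, float]:
    """Missing-trace fraction per source and pooled over all sources."""
    out = dict(result.missing_fraction_per_source)
    out["overall"] = result.missing_fraction_overall
    return out


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def seed_points(section: CrossSection, n: int, strategy: str = "flux-weighted",
                rng_seed: int | None = None) -> np.ndarray:
    """Seed positions (mm) on the lumen of an inlet cross-section.

    ``uniform`` subsamples the lumen lattice evenly (area-uniform);
    ``flux-weighted`` draws lumen lattice points with probability
    proportional to the local through-plane speed |u . n|, which makes the
    seed ensemble flow-representative.  Reproducible for a fixed seed.
    """
    if n < 1:
        raise InputError("need at least one seed")
    pts = section.points_mm[section.lumen]
    if len(pts) == 0:
        raise GeometryError("inlet section has no lumen samples")
    rng = np.random.default_rng(rng_seed)
    jitter = rng.uniform(-0.5, 0.5, size=(n, 3)) * section.pitch_mm
    jitter -= (jitter @ section.normal)[:, None] * section.normal  # in-plane
    if strategy == "uniform":
        take = np.linspace(0, len(pts) - 1, num=n).round().astype(int)
        return pts[take] + jitter * 0.0
    if strategy == "flux-weighted":
        w = np.abs(section.velocity[section.lumen] @ section.normal)
        if w.sum() <= 0:
            raise GeometryError("no through-plane flow to weight seeds by")
        idx = rng.choice(len(pts), size=n, replace=True, p=w / w.sum())
        return pts[idx] + jitter
    raise InputError(f"unknown seeding strategy {strategy!r}")


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

class _FieldSampler:
    """Trilinear samplers for velocity, lumen and per-outlet indicators."""

    def __init__(self, field: VelocityField, mask: SegmentationMask,
                 outlet_sections: Mapping[str, CrossSection]):
        check_geometry(field, mask)
        self.u = field.u3
        self.origin = mask.origin[:, None]
        self.spacing = mask.spacing[:, None]
        self.lumen = mask.lumen.astype(float)
        self.outlets = []
        for name, sec in outlet_sections.items():
            ind = mask.region(name if name in ("lpa", "rpa", "svc", "conduit")
                              else sec.region).astype(float)
            self.outlets.append((name, sec.origin_mm, sec.normal, ind))

    def _idx(self, p: np.ndarray) -> np.ndarray:
        return (p - self.origin) / self.spacing

    def velocity(self, p: np.ndarray) -> np.ndarray:
        idx = self._idx(p)
        return np.stack([map_coordinates(self.u[c], idx, order=1,
                                         mode="constant", cval=0.0)
                         for c in range(3)])

    def inside(self, p: np.ndarray) -> np.ndarray:
        return map_coordinates(self.lumen, self._idx(p), order=1,
                               mode="constant", cval=0.0) >= 0.5

    def outlet_hit(self, name_ind: np.ndarray, p: np.ndarray) -> np.ndarray:
        return map_coordinates(name_ind, self._idx(p), order=1,
                               mode="constant", cval=0.0) >= 0.5


def _advect(sampler: _FieldSampler, seeds_mm: np.ndarray, step_mm: float,
            max_steps: int, stagnation: float, record: bool):
    """Batched arc-length RK4 advection.

    Returns (status, reason, steps, paths) where status holds the outlet name
    or None, reason one of outlet/left-mask/max-steps/stagnation, and paths
    the per-trace polylines when ``record`` is true (else final points only).
    """
    p = np.asarray(seeds_mm, float).T.copy()      # (3, n)
    n = p.shape[1]
    status: list[str | None] = [None] * n
    reason = ["max-steps"] * n
    steps = np.zeros(n, int)
    active = np.ones(n, bool)
    paths = [[p[:, i].copy()] for i in range(n)] if record else None

    if not sampler.inside(p).all():
        raise InputError("seed outside the segmented lumen")

    def unit(v):
        s = np.linalg.norm(v, axis=0)
        return v / np.maximum(s, 1e-30), s

    for _ in range(max_steps):
        if not active.any():
            break
        ai = np.where(active)[0]
        pa = p[:, ai]
        v1 = sampler.velocity(pa)
        d1, s1 = unit(v1)
        stag = s1 < stagnation
        d2, _ = unit(sampler.velocity(pa + 0.5 * step_mm * d1))
        d3, _ = unit(sampler.velocity(pa + 0.5 * step_mm * d2))
        d4, _ = unit(sampler.velocity(pa + step_mm * d3))
        pn = pa + step_mm * (d1 + 2 * d2 + 2 * d3 + d4) / 6.0

        done = stag.copy()
        for k in np.where(stag)[0]:
            status[ai[k]] = None
            reason[ai[k]] = "stagnation"

        # first outlet-plane crossing wins (outlets checked in fixed order)
        for name, o, nrm, ind in sampler.outlets:
            d_old = (pa - o[:, None]).T @ nrm
            d_new = (pn - o[:, None]).T @ nrm
            crossed = (d_old * d_new <= 0) & (np.abs(d_old) + np.abs(d_new) > 0) \
                & ~done
            if crossed.any():
                t = d_old[crossed] / (d_old[crossed] - d_new[crossed])
                pc = pa[:, crossed] + t * (pn[:, crossed] - pa[:, crossed])
                hit = sampler.outlet_hit(ind, pc)
                rows = np.where(crossed)[0][hit]
                for k in rows:
                    status[ai[k]] = name
                    reason[ai[k]] = "outlet"
                done[rows] = True

        exited = ~sampler.inside(pn) & ~done
        for k in np.where(exited)[0]:
            status[ai[k]] = None
            reason[ai[k]] = "left-mask"
        done |= exited

        p[:, ai] = pn
        steps[ai] += 1
        if record:
            for k, i in enumerate(ai):
                paths[i].append(pn[:, k].copy())
        active[ai[done]] = False

    return status, reason, steps, paths if record else [[p[:, i]] for i in range(n)]


def integrate_streamline(field: VelocityField, mask: SegmentationMask,
                         seed_mm, outlet_sections: Mapping[str, CrossSection],
                         seed_region: str = "conduit",
                         step_mm: float | None = None, max_steps: int = 10000,
                         stagnation: float = STAGNATION_SPEED) -> Trace:
    """Integrate a single streamline and classify its termination.

    Default step is a quarter of the smallest voxel spacing.
    """
    sampler = _FieldSampler(field, mask, outlet_sections)
    if step_mm is None:
        step_mm = 0.25 * float(mask.spacing.min())
    seeds = np.asarray(seed_mm, float).reshape(1, 3)
    status, reason, steps, paths = _advect(sampler, seeds, step_mm, max_steps,
                                           stagnation, record=True)
    dest = status[0]
    return Trace(points_mm=np.array(paths[0]),
                 seed_region=seed_region,
                 status=f"reached-{dest.upper()}" if dest else "missing",
                 steps=int(steps[0]), reason=reason[0], destination=dest)


def classify_traces(traces: Iterable[Trace],
                    outlets: Sequence[str] = OUTLETS,
                    sources: Sequence[str] = INLETS,
                    source_weights: Mapping[str, float] | None = None
                    ) -> PFDResult:
    """Count traces per (source, outlet) and derive PFD percentages.

    ``source_weights`` set how per-source percentages pool into the
    "total to LPA/RPA" columns (e.g. inlet flow magnitudes for
    flux-weighted pooling); default is the per-source seed counts.
    """
    counts = {s: {o: 0 for o in outlets} for s in sources}
    seeded = {s: 0 for s in sources}
    missing = {s: 0 for s in sources}
    for tr in traces:
        s = tr.seed_region
        if s not in counts:
            counts[s] = {o: 0 for o in outlets}
            seeded[s] = 0
            missing[s] = 0
        seeded[s] += 1
        if tr.destination in outlets:
            counts[s][tr.destination] += 1
        else:
            missing[s] += 1
    weights = dict(source_weights) if source_weights is not None \
        else {s: float(seeded[s]) for s in seeded}
    return PFDResult(counts=counts, seeded=seeded, missing=missing,
                     source_weights=weights)


def trace_pulmonary_distribution(
        field: VelocityField, mask: SegmentationMask,
        inlet_sections: Mapping[str, CrossSection],
        outlet_sections: Mapping[str, CrossSection],
        n_seeds: int = 10000, strategy: str = "flux-weighted",
        rng_seed: int | None = None, step_mm: float | None = None,
        max_steps: int = 10000, stagnation: float = STAGNATION_SPEED,
        pooling: str = "flux") -> PFDResult:
    """Seed both inlets, trace all streamlines, and compute the PFD.

    Seeds are split across inlets proportionally to inlet flow magnitude
    (``pooling="flux"``, the default, which makes pooled totals
    flow-representative) or equally (``pooling="count"``).
    """
    if pooling not in ("flux", "count"):
        raise InputError(f"unknown pooling rule {pooling!r}")
    sampler = _FieldSampler(field, mask, outlet_sections)
    if step_mm is None:
        step_mm = 0.25 * float(mask.spacing.min())
    flows = {name: abs(plane_flow_rate(sec).m3_per_s)
             for name, sec in inlet_sections.items()}
    total_flow = sum(flows.values())
    if pooling == "flux" and total_flow > 0:
        alloc = {s: flows[s] / total_flow for s in flows}
    else:
        alloc = {s: 1.0 / len(inlet_sections) for s in inlet_sections}

    traces: list[Trace] = []
    rng = np.random.default_rng(rng_seed)
    for i, (name, sec) in enumerate(sorted(inlet_sections.items())):
        ns = max(1, int(round(n_seeds * alloc[name])))
        seeds = seed_points(sec, ns, strategy=strategy,
                            rng_seed=int(rng.integers(0, 2**31 - 1)))
        inside = sampler.inside(seeds.T)
        seeds = seeds[inside]
        status, reason, steps, _ = _advect(sampler, seeds, step_mm, max_steps,
                                           stagnation, record=False)
        for k in range(len(seeds)):
            dest = status[k]
            traces.append(Trace(
                points_mm=seeds[k][None, :], seed_region=name,
                status=f"reached-{dest.upper()}" if dest else "missing",
                steps=int(steps[k]), reason=reason[k], destination=dest))

    weights = flows if pooling == "flux" else None
    return classify_traces(traces, outlets=tuple(sorted(outlet_sections)),
                           sources=tuple(sorted(inlet_sections)),
                           source_weights=weights)
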