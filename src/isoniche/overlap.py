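"""Pairwise and aggregate overlap between SEAc ellipses.

Each corrected standard ellipse is discretized as a convex polygon whose
shoelace area equals SEAc exactly; intersections are computed by convex
polygon clipping (shapely).  Overlap is reported as intersection area and as
a percentage of each member's area.  The aggregate-niche analysis refits a
single SEAc ellipse to the pooled points of every species except a focal one
and reports how much of the focal ellipse lies inside it — the test used to
show an omnivore's niche nested within the rest of the community.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .ellipse import StandardEllipse, fit_standard_ellipse
from .io import SpeciesDataset, as_dataset

#: intersection areas below this (‰²) count as "no overlap"
OVERLAP_EPS = 1e-9


@dataclass
class OverlapResult:
    species_a: str
    species_b: str
    intersection_area: float  # ‰²
    pct_of_a: float  # 100·intersection/area_a
    pct_of_b: float


@dataclass
class AggregateNiche:
    excluded_species: str
    ellipse: StandardEllipse  # fitted to the pooled points of all other species
    containment_pct: float  # % of the excluded species' SEAc ellipse inside it


def _polygon(e: StandardEllipse, vertices: int) -> Polygon:
    return Polygon(e.boundary(vertices=vertices, scale="seac"))


def ellipse_overlap(a: StandardEllipse, b: StandardEllipse, vertices: int = 1024,
                    label_a: str = "a", label_b: str = "b") -> OverlapResult:
    """Intersection of two SEAc ellipses by convex polygon clipping."""
    if vertices < 64:
        raise ValueError("vertices must be >= 64 for the stated discretization accuracy")
    pa, pb = _polygon(a, vertices), _polygon(b, vertices)
    inter = pa.intersection(pb).area
    return OverlapResult(
        species_a=label_a,
        species_b=label_b,
        intersection_area=inter,
        pct_of_a=100.0 * inter / pa.area,
        pct_of_b=100.0 * inter / pb.area,
    )


def pairwise_overlaps(ellipses: dict[str, StandardEllipse], vertices: int = 1024) -> list[OverlapResult]:
    """All unordered species pairs, in lexicographic order."""
    labels = sorted(ellipses)
    out = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            out.append(ellipse_overlap(ellipses[la], ellipses[lb], vertices, la, lb))
    return out


def median_overlap(results: list[OverlapResult], focal: str,
                   include_zeros: bool = True) -> tuple[float, int]:
    """Median percent of the focal ellipse shared with each other species.

    Returns ``(median_pct, n_partners_with_overlap)`` where a partner counts
    as overlapping when the intersection exceeds a numeric-noise guard.
    Zero-overlap pairs enter the median by default ("between any one species
    and another" = every pairing); set ``include_zeros=False`` for the
    overlapping-pairs-only convention.
    """
    pcts = []
    for r in results:
        if r.species_a == focal:
            pcts.append(r.pct_of_a)
        elif r.species_b == focal:
            pcts.append(r.pct_of_b)
    if not pcts:
        raise KeyError(f"focal species {focal!r} appears in no pair")
    n_partners = sum(1 for r in results
                     if focal in (r.species_a, r.species_b) and r.intersection_area > OVERLAP_EPS)
    if not include_zeros:
        pcts = [p for p in pcts if p > 0] or [0.0]
    return float(np.median(pcts)), n_partners


def aggregate_containment(community: list[SpeciesDataset], excluded: str,
                          vertices: int = 1024) -> AggregateNiche:
    """Containment of one species' SEAc ellipse within the pooled-rest ellipse."""
    community = [as_dataset(d) for d in community]
    labels = [d.species for d in community]
    if excluded not in labels:
        raise KeyError(f"species {excluded!r} not in community")
    rest = [d for d in community if d.species != excluded]
    if len(rest) < 2:
        raise ValueError("need at least 2 non-excluded species for an aggregate niche")
    pooled = np.vstack([d.xy for d in rest])
    agg = fit_standard_ellipse(pooled)
    focal = fit_standard_ellipse(next(d for d in community if d.species == excluded))
    pf, pagg = _polygon(focal, vertices), _polygon(agg, vertices)
    pct = 100.0 * pf.intersection(pagg).area / pf.area
    return AggregateNiche(excluded_species=excluded, ellipse=agg, containment_pct=pct)


def monte_carlo_overlap(a: StandardEllipse, b: StandardEllipse, n_points: int = 1_000_000,
                        seed=None) -> float:
    """Grid Monte-Carlo oracle for the intersection area of two SEAc ellipses.

    Uniform points over the joint bounding box; independent of the polygon
    clipping path, for cross-validation.
    """
    rng = np.random.default_rng(seed)
    va = a.boundary(64, scale="seac")
    vb = b.boundary(64, scale="seac")
    allv = np.vstack([va, vb])
    lo, hi = allv.min(axis=0) - 0.01, allv.max(axis=0) + 0.01
    pts = rng.uniform(lo, hi, size=(n_points, 2))
    scale_a = np.sqrt(a.seac_ / a.sea_)
    scale_b = np.sqrt(b.seac_ / b.sea_)
    in_a = a.mahalanobis_sq(pts) <= scale_a ** 2
    in_b = b.mahalanobis_sq(pts) <= scale_b ** 2
    box_area = np.prod(hi - lo)
    return float(np.mean(in_a & in_b) * box_area)
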