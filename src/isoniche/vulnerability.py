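"""Breeding Vulnerability Index (BVI) and the combined vulnerability ranking.

The BVI is a 0–4 rubric summing two factors:

* flood-pulse dependence — critical (breeds exclusively during spate) = 2,
  moderate (marked spate breeding peak) = 1, low (year-round / weak peak) = 0;
* breeding habitat — most threatened (steep eastern-shore shallows or the
  Omo River) = 2, threatened (gently sloped western shallows or all inflowing
  rivers) = 1, least threatened (pelagic) = 0; species with several breeding
  sub-populations take the weight-averaged habitat score.

High BVI plus a small isotopic niche (low intraspecific trophic diversity)
marks the species most exposed to reduced river inflow.  The two axes are
combined here as composite = BVI/4 + (1 − minmax(SEAc)), an explicit
operationalization of the "direction of increasing vulnerability"; species
above a threshold (default 1.0) are classed as likely "losers".
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

FLOOD_SCORES = {"critical": 2.0, "moderate": 1.0, "low": 0.0}
HABITAT_SCORES = {"most_threatened": 2.0, "threatened": 1.0, "least_threatened": 0.0}


@dataclass
class BreedingTraits:
    species: str
    flood_category: str                         # critical | moderate | low
    habitat_components: list[tuple[str, float]]  # (category, weight), weights sum to 1

    def __post_init__(self):
        if self.flood_category not in FLOOD_SCORES:
            raise ValueError(f"unknown flood category {self.flood_category!r}")
        if not self.habitat_components:
            raise ValueError("need at least one habitat component")
        for cat, w in self.habitat_components:
            if cat not in HABITAT_SCORES:
                raise ValueError(f"unknown habitat category {cat!r}")
            if not 0 < w <= 1:
                raise ValueError("habitat weights must lie in (0, 1]")
        total = sum(w for _, w in self.habitat_components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"habitat weights must sum to 1, got {total}")


@dataclass
class BVIScore:
    species: str
    flood_score: float    # 0, 1 or 2
    habitat_score: float  # in [0, 2], weight-averaged
    total: float          # in [0, 4]


@dataclass
class VulnerabilityRecord:
    species: str
    bvi: BVIScore
    seac: float
    composite: float
    klass: str  # "winner" | "loser"


def flood_score(category: str) -> float:
    if category not in FLOOD_SCORES:
        raise ValueError(f"unknown flood category {category!r}")
    return FLOOD_SCORES[category]


def habitat_score(components: list[tuple[str, float]]) -> float:
    """Weighted mean of habitat-category scores (weights must sum to 1)."""
    total = sum(w for _, w in components)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"habitat weights must sum to 1, got {total}")
    for cat, _ in components:
        if cat not in HABITAT_SCORES:
            raise ValueError(f"unknown habitat category {cat!r}")
    return sum(HABITAT_SCORES[cat] * w for cat, w in components)


def bvi(traits: BreedingTraits) -> BVIScore:
    """Sum the flood-pulse and habitat factor scores."""
    f = flood_score(traits.flood_category)
    h = habitat_score(traits.habitat_components)
    return BVIScore(species=traits.species, flood_score=f, habitat_score=h, total=f + h)


def rank_species(scores: list[BVIScore], seac: dict[str, float],
                 threshold: float = 1.0) -> list[VulnerabilityRecord]:
    """Combine BVI and niche size into a single vulnerability ranking.

    composite = total/4 + (1 − minmax(SEAc)) over the species present in both
    inputs; class = "loser" iff composite > threshold.  When every SEAc is
    equal the min-max rescale degenerates and all species take 0.5 on the
    niche axis (ranking then reduces to BVI).  Ties in the descending
    composite order break lexicographically.
    """
    both = [s for s in scores if s.species in seac]
    if len(both) < 2:
        raise ValueError("need >= 2 species with both a BVI and a SEAc value")
    vals = np.array([seac[s.species] for s in both], dtype=float)
    lo, hi = vals.min(), vals.max()
    scaled = np.full_like(vals, 0.5) if hi == lo else (vals - lo) / (hi - lo)
    recs = []
    for s, z in zip(both, scaled):
        comp = s.total / 4.0 + (1.0 - z)
        recs.append(VulnerabilityRecord(
            species=s.species, bvi=s, seac=float(seac[s.species]),
            composite=float(comp), klass="loser" if comp > threshold else "winner"))
    recs.sort(key=lambda r: (-r.composite, r.species))
    return recs


def read_traits(path=None) -> list[BreedingTraits]:
    """Read a species-trait CSV (species, flood_category, habitat components
    encoded as ``category:weight`` pairs separated by ``;``).

    With no path, loads the packaged Lake Turkana trait table for the seven
    study species.
    """
    if path is None:
        path = resources.files("isoniche").joinpath("data/turkana_traits.csv")
        with resources.as_file(path) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    out = []
    for r in df.itertuples():
        comps = []
        for part in str(r.habitat_components).split(";"):
            cat, _, w = part.strip().partition(":")
            comps.append((cat.strip(), float(w) if w else 1.0))
        out.append(BreedingTraits(species=str(r.species),
                                  flood_category=str(r.flood_category).strip(),
                                  habitat_components=comps))
    return out
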