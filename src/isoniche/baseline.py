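"""Baseline-signature variance attribution and the unique-sites analysis.

Spatial/temporal variation in the isotopic baseline propagates into consumer
signatures and could inflate apparent niche size.  Two checks separate that
from genuine diet variation:

1. per species and isotope, regress the signature on body length, then ask
   what share of the residual variance a site + year + site:year categorical
   model explains (large, consistent shares across species would implicate
   baseline variability);
2. count each species' "unique sites" (site×year cells with strictly more
   than a minimum number of individuals, default 5) and test whether that
   count predicts niche size across species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import SpeciesDataset, as_dataset


@dataclass
class VariancePartition:
    species: str
    isotope: str            # "d13C" or "d15N"
    r2_site_year: float     # share of size-corrected variance from site+year+site:year
    n_used: int             # individuals with length present


@dataclass
class UniqueSiteCount:
    species: str
    count: int


def size_correct(dataset: SpeciesDataset, isotope: str) -> pd.Series:
    """OLS residuals of an isotope signature on body length.

    Individuals with missing length are excluded (their count is the
    difference between the dataset size and ``len(result)``); residuals are
    returned indexed by the original rows, mean zero.
    """
    ds = as_dataset(dataset)
    if isotope not in ("d13C", "d15N"):
        raise ValueError("isotope must be 'd13C' or 'd15N'")
    df = ds.data
    ok = df["length"].notna() & df[isotope].notna()
    sub = df.loc[ok]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 individuals with length for {ds.species}")
    x = sub["length"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("length is constant; size regression undefined")
    model = sm.OLS(sub[isotope].to_numpy(dtype=float), sm.add_constant(x)).fit()
    return pd.Series(model.resid, index=sub.index, name=f"resid_{isotope}")


def variance_partition(residuals: pd.Series, site: pd.Series, year: pd.Series,
                       species: str = "sample", isotope: str = "") -> VariancePartition:
    """R² of the full categorical model site + year + site:year on the residuals.

    Factor levels are dummy-coded; inestimable interaction cells are handled
    by the least-squares fit's rank deficiency rather than failing, but a
    fully saturated design (zero residual degrees of freedom) is an error.
    """
    df = pd.DataFrame({
        "r": np.asarray(residuals, dtype=float),
        "site": np.asarray(site).astype(str),
        "year": np.asarray(year).astype(str),
    })
    if df["site"].nunique() < 2 and df["year"].nunique() < 2:
        raise ValueError("need >= 2 levels in site or year")
    cell = df["site"] + "\x00" + df["year"]
    X = pd.get_dummies(pd.DataFrame({"site": df["site"], "year": df["year"], "cell": cell}),
                       drop_first=True, dtype=float)
    X = sm.add_constant(X, has_constant="add")
    model = sm.OLS(df["r"], X).fit()
    if model.df_resid <= 0:
        raise ValueError("saturated model: one observation per site×year cell everywhere")
    return VariancePartition(species=species, isotope=isotope,
                             r2_site_year=float(model.rsquared), n_used=len(df))


def partition_species(dataset: SpeciesDataset, isotope: str) -> VariancePartition:
    """Convenience: size-correct then partition one species/isotope."""
    ds = as_dataset(dataset)
    resid = size_correct(ds, isotope)
    sub = ds.data.loc[resid.index]
    return variance_partition(resid, sub["site"], sub["year"],
                              species=ds.species, isotope=isotope)


def unique_sites(dataset: SpeciesDataset, min_n: int = 5) -> UniqueSiteCount:
    """Count site×year combinations with strictly more than ``min_n`` individuals."""
    ds = as_dataset(dataset)
    if len(ds.data) == 0:
        return UniqueSiteCount(species=ds.species, count=0)
    counts = ds.data.groupby([ds.data["site"].astype(str), ds.data["year"].astype(str)]).size()
    return UniqueSiteCount(species=ds.species, count=int((counts > min_n).sum()))


def relate(x, y) -> tuple[float, float]:
    """OLS r² and two-sided p of y on x across species (e.g. niche size vs
    unique-site count)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 species")
    if np.ptp(x) == 0:
        raise ValueError("correlation undefined for constant x")
    res = stats.linregress(x, y)
    return float(res.rvalue ** 2), float(res.pvalue)
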