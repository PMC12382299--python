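"""Stage 1: plot aggregation, adjusted genotype means and heritability.

The field trial is a two-year p-rep layout: every hybrid once per year, a
random subset twice, with complete randomization on a row x column grid.
Adjusted means come from a mixed model with genotype fixed and year,
genotype x year, row-within-year and column-within-year random; the
per-year variant drops the year terms and un-nests row/column.

Broad-sense heritability on an entry-mean basis uses the pairwise-contrast
form suited to unbalanced designs:

    H^2 = sigma2_G / (sigma2_G + v_bar_Delta / 2)

where sigma2_G is the genotypic variance from the dual model with genotype
random, and v_bar_Delta is the mean variance of all pairwise contrasts of
the fixed-genotype adjusted means.  On a balanced one-way layout with r
replicates this collapses to the textbook sigma2_G / (sigma2_G + sigma2_e/r).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reml import (ModelSpec, RandomTerm, blues_and_contrast_variance,
                   dummy_design, fit_reml, incidence)

log = logging.getLogger(__name__)

DESIGN_COLS = ("genotype", "mother", "year", "row", "column")


@dataclass
class TraitSummary:
    trait: str
    H2: float
    sigma2_G: float
    v_bar_delta: float
    adjusted_means: pd.Series
    population_mean: float
    cv: float
    per_year_means: dict | None = None
    mother_means: dict | None = None
    t_test_p: float | None = None


def apply_range_rules(pheno: pd.DataFrame, rules: dict) -> pd.DataFrame:
    """Blank out implausible trait values per caller-supplied (min, max) rules."""
    out = pheno.copy()
    for trait, (lo, hi) in rules.items():
        if trait not in out.columns:
            continue
        bad = (out[trait] < lo) | (out[trait] > hi)
        if bad.any():
            log.info("range rule %s in [%s, %s]: %d values excluded", trait, lo, hi, int(bad.sum()))
            out.loc[bad, trait] = np.nan
    return out


def aggregate_plants_to_plot(raw: pd.DataFrame, traits: list[str],
                             plot_keys=("genotype", "mother", "year", "row", "column")) -> pd.DataFrame:
    """Arithmetic mean of plant-level records per plot and trait.

    A plot with no non-missing plant record for a trait gets a missing
    value there; other traits on the plot are unaffected.
    """
    keys = [k for k in plot_keys if k in raw.columns]
    return raw.groupby(keys, as_index=False)[list(traits)].mean()


def _random_terms(df: pd.DataFrame, scope: str) -> list[RandomTerm]:
    """Year, GxE, row-in-year and column-in-year terms, keeping only those
    identifiable in the data at hand (>= 2 levels, columns present)."""
    terms = []
    multi_year = "year" in df.columns and df["year"].nunique() > 1
    if scope == "across_years" and multi_year:
        Zy, _ = incidence(df, "year")
        terms.append(RandomTerm("year", Zy))
        gxe = df["genotype"].astype(str) + ":" + df["year"].astype(str)
        Zg, _ = incidence(df.assign(_gxe=gxe), "_gxe")
        terms.append(RandomTerm("genotype:year", Zg))
    for coord, name in (("row", "row"), ("column", "col")):
        if coord not in df.columns:
            continue
        if multi_year and scope == "across_years":
            fac = df["year"].astype(str) + ":" + df[coord].astype(str)
        else:
            fac = df[coord].astype(str)
        if fac.nunique() > 1:
            Zc, _ = incidence(df.assign(_f=fac), "_f")
            terms.append(RandomTerm(f"{name}(year)" if multi_year else name, Zc))
    return terms


def adjusted_means(pheno: pd.DataFrame, trait: str, scope: str = "across_years",
                   year: int | None = None):
    """Adjusted per-genotype means (BLUEs) and the mean contrast variance.

    ``scope='across_years'`` fits the full model on all years;
    ``scope='single_year'`` restricts to ``year`` and drops the year terms.
    Returns ``(estimates, v_bar_delta, fit)``.
    """
    df = pheno.dropna(subset=[trait]).copy()
    if scope == "single_year":
        if year is None:
            raise ValueError("single_year scope requires a year")
        df = df[df["year"] == year]
    if df["genotype"].nunique() < 2:
        raise ValueError(f"trait {trait!r}: need >= 2 genotypes with data")
    dropped = set(pheno["genotype"].unique()) - set(df["genotype"].unique())
    if dropped:
        log.info("trait %s: %d genotypes without data omitted", trait, len(dropped))

    X, names, term_levels = dummy_design(df, ["genotype"])
    spec = ModelSpec(y=df[trait].to_numpy(float), X=X, fixed_names=names,
                     random_terms=_random_terms(df, scope), term_levels=term_levels)
    fit = fit_reml(spec)
    est, v_bar = blues_and_contrast_variance(fit, "genotype")
    est.index.name = "genotype"
    return est, v_bar, fit


def genetic_variance(pheno: pd.DataFrame, trait: str, scope: str = "across_years",
                     year: int | None = None) -> tuple[float, object]:
    """sigma2_G from the all-random dual model (genotype random)."""
    df = pheno.dropna(subset=[trait]).copy()
    if scope == "single_year":
        df = df[df["year"] == year]
    Zg, _ = incidence(df, "genotype")
    terms = [RandomTerm("genotype", Zg)] + _random_terms(df, scope)
    spec = ModelSpec(y=df[trait].to_numpy(float), X=np.ones((len(df), 1)),
                     fixed_names=["Intercept"], random_terms=terms)
    fit = fit_reml(spec)
    return fit.vc["genotype"], fit


def heritability(pheno: pd.DataFrame, trait: str, with_mother_test: bool = True) -> TraitSummary:
    """Entry-mean heritability plus the Table-1-style summary statistics."""
    est, v_bar, _ = adjusted_means(pheno, trait, scope="across_years")
    s2g, _ = genetic_variance(pheno, trait, scope="across_years")
    denom = s2g + v_bar / 2.0
    h2 = 0.0 if denom <= 0 or s2g <= 0 else s2g / denom
    if not 0.0 <= h2 <= 1.0:
        log.warning("trait %s: H^2=%.4f outside [0,1], clamping", trait, h2)
        h2 = min(max(h2, 0.0), 1.0)

    mu = float(est.mean())
    cv = float(est.std(ddof=1) / mu) if mu != 0 else float("nan")

    mother_means = None
    t_p = None
    if with_mother_test and "mother" in pheno.columns and pheno["mother"].nunique() == 2:
        geno_mother = pheno.drop_duplicates("genotype").set_index("genotype")["mother"]
        groups = est.groupby(est.index.map(geno_mother))
        mother_means = {str(k): float(v) for k, v in groups.mean().items()}
        sets = [g.to_numpy() for _, g in groups]
        if len(sets) == 2 and min(map(len, sets)) > 1:
            # Welch's unequal-variance t-test on the adjusted means
            t_p = float(stats.ttest_ind(sets[0], sets[1], equal_var=False).pvalue)

    return TraitSummary(trait=trait, H2=float(h2), sigma2_G=float(s2g),
                        v_bar_delta=float(v_bar), adjusted_means=est,
                        population_mean=mu, cv=cv,
                        mother_means=mother_means, t_test_p=t_p)


def trait_summary_table(pheno: pd.DataFrame, traits: list[str]) -> tuple[pd.DataFrame, dict]:
    """Per-trait summary rows and the TraitSummary objects keyed by trait."""
    rows, summaries = [], {}
    for trait in traits:
        s = heritability(pheno, trait)
        summaries[trait] = s
        row = {"trait": trait, "H2": s.H2, "sigma2_G": s.sigma2_G,
               "v_bar_delta": s.v_bar_delta, "population_mean": s.population_mean,
               "cv": s.cv}
        if s.mother_means:
            for k, v in s.mother_means.items():
                row[f"mean_mother_{k}"] = v
            row["p_t_test_mothers"] = s.t_test_p
        rows.append(row)
    return pd.DataFrame(rows), summaries


def means_matrix(pheno: pd.DataFrame, traits: list[str], scope: str = "across_years",
                 year: int | None = None) -> pd.DataFrame:
    """Adjusted means for several traits as one genotype x trait DataFrame."""
    cols = {}
    for trait in traits:
        est, _, _ = adjusted_means(pheno, trait, scope=scope, year=year)
        cols[trait] = est
    return pd.DataFrame(cols)
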