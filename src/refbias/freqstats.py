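"""Reference-allele frequency error statistics and associated tests.

FE at site i is the REF-allele frequency in the NGS call set minus its
frequency in the (ambiguity-corrected) gold standard:

    FE_i = f_i,NGS - f_i,gold

MAE per gene is the mean of |FE_i| over its SNPs.  Sites are classified as
overestimated (FE > 0.1), underestimated (FE < -0.1), well estimated
(|FE| < 0.01) or intermediate; a site is *unreliable* when |FE| > 0.1 in two
or more populations.  A two-sided exact binomial test asks whether deviations
are equally often in the REF and ALT direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

FE_LARGE = 0.1
FE_WELL = 0.01

OVERESTIMATED = "overestimated"
UNDERESTIMATED = "underestimated"
WELL_ESTIMATED = "well_estimated"
INTERMEDIATE = "intermediate"


@dataclass(frozen=True)
class FrequencyRecord:
    locus: str
    site: int
    population: str
    ref_base: str
    f_ngs: float
    f_gold: float

    @property
    def fe(self) -> float:
        return self.f_ngs - self.f_gold


def _copy_sets(genotype):
    # accepts SiteGenotype, a pair of base sets, or a 2-char string
    alleles = getattr(genotype, "alleles", genotype)
    return [set(a) for a in alleles]


def ref_allele_frequency(genotypes, ref_base: str) -> float:
    """REF-allele frequency from diploid genotypes.

    Residual ambiguous base sets that contain REF contribute fractionally
    (1/|set| per copy, i.e. 0.5 for a two-base set), which avoids biasing the
    estimate in either direction.
    """
    genotypes = list(genotypes)
    if not genotypes:
        raise ValueError("no non-missing genotypes at site")
    count = 0.0
    for g in genotypes:
        for copy in _copy_sets(g):
            if ref_base in copy:
                count += 1.0 / len(copy)
    return count / (2 * len(genotypes))


def frequency_error(f_ngs: float, f_gold: float) -> float:
    for f in (f_ngs, f_gold):
        if not 0 <= f <= 1:
            raise ValueError(f"frequency {f} outside [0, 1]")
    return f_ngs - f_gold


def mae(fe_list) -> float:
    fe = np.asarray(list(fe_list), dtype=float)
    if fe.size == 0:
        raise ValueError("mae of an empty FE list")
    return float(np.mean(np.abs(fe)))


def classify_site(fe: float, fe_large: float = FE_LARGE, fe_well: float = FE_WELL) -> str:
    """Partition of FE values: every FE maps to exactly one class."""
    if fe > fe_large:
        return OVERESTIMATED
    if fe < -fe_large:
        return UNDERESTIMATED
    if abs(fe) < fe_well:
        return WELL_ESTIMATED
    return INTERMEDIATE


def unreliable_sites(
    fe_table: pd.DataFrame,
    threshold: float = FE_LARGE,
    min_pops: int = 2,
    site_cols=("locus", "site"),
) -> list:
    """Sites with |FE| > threshold in at least ``min_pops`` populations.

    ``fe_table`` needs columns ``site`` (plus optionally ``locus``),
    ``population`` and ``fe``; the "global" pseudo-population is ignored.
    """
    df = fe_table[fe_table["population"] != "global"]
    cols = [c for c in site_cols if c in df.columns]
    exceed = df[df["fe"].abs() > threshold]
    counts = exceed.groupby(cols)["population"].nunique()
    flagged = counts[counts >= min_pops].index.tolist()
    return sorted(flagged)


def direction_test(n_ref_skewed: int, n_alt_skewed: int) -> float:
    """Exact two-sided binomial p for equal REF-ward and ALT-ward deviations.

    Two-sided in the minimum-likelihood sense: the sum of probabilities of all
    outcomes no more likely than the observed count under p = 1/2.
    """
    if n_ref_skewed < 0 or n_alt_skewed < 0:
        raise ValueError("counts must be non-negative")
    n = n_ref_skewed + n_alt_skewed
    if n < 1:
        raise ValueError("need at least one deviating site")
    return float(stats.binomtest(n_ref_skewed, n, p=0.5).pvalue)


def heterozygosity(p):
    """H = 2p(1-p) for a biallelic site."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("allele frequency outside [0, 1]")
    h = 2 * p * (1 - p)
    return float(h) if h.ndim == 0 else h


def pearson_with_p(x, y):
    """Sample Pearson r with a two-sided p via the t distribution (n-2 df)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class HeterozygosityFilterReport:
    """Gold-standard heterozygosities of flagged (excluded) vs retained sites."""

    excluded: np.ndarray
    retained: np.ndarray

    @property
    def mean_excluded(self) -> float:
        return float(np.mean(self.excluded)) if self.excluded.size else float("nan")

    @property
    def mean_retained(self) -> float:
        return float(np.mean(self.retained)) if self.retained.size else float("nan")


def heterozygosity_filter_report(
    gold_frequencies: dict, flagged_sites
) -> HeterozygosityFilterReport:
    """Split site heterozygosities (computed from GOLD frequencies only) by
    whether the site is on the unreliable list."""
    flagged = set(flagged_sites)
    excluded, retained = [], []
    for site, p in gold_frequencies.items():
        (excluded if site in flagged else retained).append(heterozygosity(p))
    return HeterozygosityFilterReport(
        excluded=np.asarray(excluded, dtype=float),
        retained=np.asarray(retained, dtype=float),
    )
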