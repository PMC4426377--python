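"""Per-site diploid genotype comparison between a gold standard and an NGS call set.

The gold standard is derived from sequence-based typing and may carry
*ambiguous* base sets at a site (e.g. ``{A, T}`` on one chromosome copy when
the typing cannot distinguish two candidate alleles).  NGS calls are single
bases.  Before comparison, each ambiguous gold base set whose intersection
with the NGS allele pair is non-empty is resolved to the NGS base ("ambiguity
correction"); a genotype then counts as a match only if both NGS alleles can
be paired one-to-one with the gold chromosome copies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")


def _as_base_set(x) -> frozenset:
    if isinstance(x, str):
        s = frozenset(x)
    else:
        s = frozenset(x)
    if not s or not s <= VALID_BASES:
        raise ValueError(f"invalid base set {x!r}: bases must be non-empty subset of ACGT")
    return s


@dataclass(frozen=True)
class SiteGenotype:
    """Unordered pair of per-copy alleles at one CDS site for one sample.

    Each element of ``alleles`` is a base set: a singleton for an NGS call or
    an unambiguous gold copy, larger for an ambiguous gold copy.
    """

    alleles: tuple[frozenset, frozenset]
    site: int = 0
    sample_id: str = ""

    def __post_init__(self):
        if len(self.alleles) != 2:
            raise ValueError("a diploid genotype has exactly two alleles")
        object.__setattr__(
            self, "alleles", tuple(_as_base_set(a) for a in self.alleles)
        )

    @classmethod
    def of(cls, a, b, site: int = 0, sample_id: str = "") -> "SiteGenotype":
        return cls((_as_base_set(a), _as_base_set(b)), site=site, sample_id=sample_id)

    @property
    def is_ambiguous(self) -> bool:
        return any(len(a) > 1 for a in self.alleles)

    def single_bases(self) -> tuple[str, str]:
        if self.is_ambiguous:
            raise ValueError("genotype has non-singleton base sets")
        (a,), (b,) = (tuple(s) for s in self.alleles)
        return a, b


@dataclass
class ComparisonResult:
    sample_id: str
    site: int
    match: bool
    corrected: bool
    gold_after_correction: SiteGenotype
    ngs: SiteGenotype


def genotypes_match(gold: SiteGenotype, ngs: SiteGenotype) -> bool:
    """True iff the NGS allele pair can be paired one-to-one with the gold copies.

    Each NGS base must be a member of the gold base set it is paired with, so a
    homozygous NGS call (A, A) requires A in *both* gold sets.  Symmetric in
    the order of gold copies and of NGS alleles.
    """
    n1, n2 = ngs.single_bases()
    g1, g2 = gold.alleles
    return (n1 in g1 and n2 in g2) or (n1 in g2 and n2 in g1)


def correct_ambiguity(gold: SiteGenotype, ngs: SiteGenotype) -> SiteGenotype:
    """Resolve ambiguous gold base sets against the NGS allele pair.

    Every non-singleton gold set that intersects the NGS pair is replaced by
    one base from the intersection; when several resolutions are possible the
    one that maximizes the subsequent match is chosen (ties broken on sorted
    base order, deterministically).  Singleton sets and non-intersecting
    ambiguous sets are left unchanged.
    """
    ngs_bases = set(ngs.single_bases())
    options = []
    for s in gold.alleles:
        inter = s & ngs_bases
        if len(s) > 1 and inter:
            options.append([frozenset({b}) for b in sorted(inter)])
        else:
            options.append([s])
    best = None
    best_key = None
    for resolved in itertools.product(*options):
        cand = SiteGenotype(tuple(resolved), site=gold.site, sample_id=gold.sample_id)
        key = (genotypes_match(cand, ngs), )
        if best is None or key > best_key:
            best, best_key = cand, key
    return best


def compare_genotypes(gold: SiteGenotype, ngs: SiteGenotype) -> ComparisonResult:
    corrected_gold = correct_ambiguity(gold, ngs)
    return ComparisonResult(
        sample_id=gold.sample_id or ngs.sample_id,
        site=gold.site or ngs.site,
        match=genotypes_match(corrected_gold, ngs),
        corrected=corrected_gold.alleles != gold.alleles,
        gold_after_correction=corrected_gold,
        ngs=ngs,
    )


@dataclass
class MismatchSummary:
    overall: float
    n_comparisons: int
    n_mismatches: int
    per_site: pd.DataFrame        # site, n, n_mismatch, proportion
    per_individual: pd.DataFrame  # sample_id, n, n_mismatch


def mismatch_summary(results: list[ComparisonResult]) -> MismatchSummary:
    """Overall, per-site and per-individual mismatch rates."""
    if not results:
        raise ValueError("mismatch_summary requires at least one comparison")
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "site": [r.site for r in results],
            "mismatch": [not r.match for r in results],
        }
    )
    per_site = (
        df.groupby("site")["mismatch"]
        .agg(n="count", n_mismatch="sum")
        .reset_index()
    )
    per_site["proportion"] = per_site["n_mismatch"] / per_site["n"]
    per_ind = (
        df.groupby("sample_id")["mismatch"]
        .agg(n="count", n_mismatch="sum")
        .reset_index()
    )
    n_mm = int(df["mismatch"].sum())
    return MismatchSummary(
        overall=n_mm / len(df),
        n_comparisons=len(df),
        n_mismatches=n_mm,
        per_site=per_site,
        per_individual=per_ind,
    )


def mismatch_concentration(per_site_counts, mass_fraction: float) -> float:
    """Fraction of sites needed (largest first) to accumulate ``mass_fraction``
    of all mismatches.

    E.g. a return of 0.187 at mass_fraction=0.5 means 18.7% of sites hold half
    the mismatches.
    """
    if not 0 < mass_fraction <= 1:
        raise ValueError("mass_fraction must be in (0, 1]")
    counts = np.asarray(list(per_site_counts))
    if counts.size == 0 or (counts < 0).any():
        raise ValueError("counts must be non-negative and non-empty")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero mismatch counts")
    ordered = np.sort(counts)[::-1]
    cum = np.cumsum(ordered)
    k = int(np.searchsorted(cum, mass_fraction * total, side="left")) + 1
    return k / counts.size
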