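"""Synthetic gold-standard + NGS benchmark data under a mapping-loss read model.

The generator emulates the statistical structure the benchmarking pipeline
assumes, so every stage is testable end to end without external data:

* an allele *pool* (catalog) over a synthetic ARS coding sequence — a random
  reference sequence plus polymorphic background sites, designated *focal*
  SNPs whose ALT allele is linked to ``delta`` extra flanking differences
  (the haplotype structure that drives mapping bias), and "twin" alleles
  differing at a single site (the near-identical alleles behind typing
  ambiguity);
* diploid population samples with symmetric-Dirichlet allele frequencies,
  reported as gold typings with configurable ambiguity and missingness;
* an NGS caller whose reads are fixed windows around each SNP: a read with m
  mismatches to the reference (central site included — a mapper does not know
  which site is focal) survives alignment with probability (1-lambda)^m,
  surviving reads are miscalled with probability epsilon, and the diploid
  genotype is the maximum-likelihood call under a symmetric-error read model.
  Individuals with zero surviving reads at a site are emitted as homozygous
  reference by default, mimicking reference-biased integrated call sets.

All randomness flows from ``SimConfig.seed``; runs are bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .alleles import AlleleCatalog, AlleleName, Exon, LocusSpec

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FocalSite:
    """A SNP at which the ALT allele carries linked flanking differences."""

    site: int                       # 1-based CDS position
    alt_fraction: float = 0.4       # fraction of pool alleles carrying ALT
    linked_flank_variants: int = 3  # delta: extra ALT-haplotype flanking diffs
    alt_base: str | None = None     # drawn at pool build time when None


def _default_focal_sites():
    return (
        FocalSite(site=100, alt_fraction=0.35),
        FocalSite(site=220, alt_fraction=0.40),
        FocalSite(site=340, alt_fraction=0.45),
        FocalSite(site=460, alt_fraction=0.50),
    )


@dataclass
class SimConfig:
    """All generator parameters; defaults are the study conditions emulated.

    The locus is a class-I-like 546-bp ARS coding sequence in two exons; the
    sample is 12 populations of 78 diploids (930-sample scale); SNP density,
    mapping-loss strength, linked-flank counts and base-call error follow the
    benchmarking scenario the pipeline targets.
    """

    seed: int = 0
    locus_id: str = "SYN"
    hla_class: str = "I"
    length: int = 546
    n_alleles: int = 4096
    twin_fraction: float = 0.1
    n_populations: int = 12
    n_individuals: int = 78          # per population
    snp_density: float = 0.12
    focal_sites: tuple = field(default_factory=_default_focal_sites)
    concentration: float = 2.0       # symmetric Dirichlet over pool alleles
    mean_depth: float = 8.0          # c: expected reads per individual per site
    read_half_width: int = 25        # w: reads span 2w+1 bases
    mapping_loss: float = 0.3        # lambda: per-mismatch read-loss rate
    base_error: float = 0.005        # epsilon: per-read base-call error
    ambiguity_rate: float = 0.1      # a: per-copy ambiguous-call probability
    missing_rate: float = 0.02       # m: per-individual missing-locus probability
    zero_read_policy: str = "hom_ref"  # or "missing"
    strand: str = "+"
    chrom: str = "chr6"

    def __post_init__(self):
        rates = {
            "twin_fraction": self.twin_fraction,
            "snp_density": self.snp_density,
            "mapping_loss": self.mapping_loss,
            "base_error": self.base_error,
            "ambiguity_rate": self.ambiguity_rate,
            "missing_rate": self.missing_rate,
        }
        for k, v in rates.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{k} must be in [0, 1], got {v}")
        if self.length < 2 * self.read_half_width + 1:
            raise ValueError("locus length must be at least 2w+1")
        if self.zero_read_policy not in ("hom_ref", "missing"):
            raise ValueError("zero_read_policy must be 'hom_ref' or 'missing'")
        self.focal_sites = tuple(
            f if isinstance(f, FocalSite) else FocalSite(**f)
            for f in self.focal_sites
        )
        for f in self.focal_sites:
            if not 1 <= f.site <= self.length:
                raise ValueError(f"focal site {f.site} outside [1, {self.length}]")
            if f.linked_flank_variants > 2 * self.read_half_width:
                raise ValueError(
                    f"focal site {f.site}: delta={f.linked_flank_variants} "
                    f"exceeds window span 2w={2 * self.read_half_width}"
                )

    def to_json(self) -> str:
        d = asdict(self)
        d["focal_sites"] = [asdict(f) for f in self.focal_sites]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        d["focal_sites"] = tuple(FocalSite(**f) for f in d.get("focal_sites", ()))
        return cls(**d)


@dataclass
class AllelePool:
    """The simulated catalog plus the internals downstream stages need."""

    config: SimConfig
    locus: LocusSpec
    catalog: AlleleCatalog
    names: list                     # AlleleName per pool index
    haplotypes: np.ndarray          # (K, L) uint8 base codes 0..3
    ref_codes: np.ndarray           # (L,) uint8
    variable_sites: np.ndarray      # sorted 1-based CDS positions
    alt_code: dict                  # site -> alt base code
    focal: tuple                    # resolved FocalSite objects
    flank_positions: dict           # focal site -> tuple of linked positions
    twin_of: dict                   # pool index -> partner pool index

    @property
    def n_alleles(self) -> int:
        return self.haplotypes.shape[0]

    def sequence(self, idx: int) -> str:
        return _codes_to_str(self.haplotypes[idx])

    def ref_base(self, site: int) -> str:
        return _BASES[self.ref_codes[site - 1]]

    def alt_base(self, site: int) -> str:
        return _BASES[self.alt_code[site]]


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASE_ARR[codes].tobytes().decode("ascii")


def _make_locus(config: SimConfig, ref_seq: str) -> LocusSpec:
    L = len(ref_seq)
    if config.hla_class == "I":
        len2 = (L + 1) // 2
        len3 = L - len2
        if config.strand == "+":
            exons = (Exon("exon2", 1001, 1000 + len2), Exon("exon3", 2001, 2000 + len3))
        else:  # coding order is genomically descending on the minus strand
            exons = (Exon("exon2", 2001, 2000 + len2), Exon("exon3", 1001, 1000 + len3))
    else:
        exons = (Exon("exon2", 1001, 1000 + L),)
    return LocusSpec(
        locus_id=config.locus_id,
        ars_exons=exons,
        strand=config.strand,
        reference_ars_seq=ref_seq,
        hla_class=config.hla_class,
        chrom=config.chrom,
    )


def simulate_allele_pool(config: SimConfig, rng: np.random.Generator | None = None) -> AllelePool:
    """Build the synthetic allele catalog and locus description.

    Focal-site ALT carriers receive ``delta`` perfectly linked flanking
    variants within the read window; background sites segregate independently
    with a skewed carrier-fraction distribution.  Twin pairs (near-identical
    alleles differing at one background site) supply ambiguity partners and
    share a 2-field name prefix.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L, K, w = config.length, config.n_alleles, config.read_half_width
    ref_codes = rng.integers(0, 4, size=L, dtype=np.uint8)

    used = set()
    focal = []
    flank_positions = {}
    for f in config.focal_sites:
        if f.site in used:
            raise ValueError(f"duplicate focal site {f.site}")
        used.add(f.site)
        alt_base = f.alt_base
        if alt_base is None:
            choices = [b for b in _BASES if b != _BASES[ref_codes[f.site - 1]]]
            alt_base = choices[rng.integers(0, 3)]
        elif alt_base == _BASES[ref_codes[f.site - 1]]:
            raise ValueError(f"focal site {f.site}: alt_base equals the reference base")
        focal.append(
            FocalSite(f.site, f.alt_fraction, f.linked_flank_variants, alt_base)
        )
    for f in focal:
        lo, hi = max(1, f.site - w), min(L, f.site + w)
        avail = [p for p in range(lo, hi + 1) if p not in used]
        if len(avail) < f.linked_flank_variants:
            raise ValueError(
                f"focal site {f.site}: not enough free positions for "
                f"{f.linked_flank_variants} linked flanking variants"
            )
        picked = sorted(
            rng.choice(len(avail), size=f.linked_flank_variants, replace=False)
        )
        flank_positions[f.site] = tuple(avail[i] for i in picked)
        used.update(flank_positions[f.site])

    n_background = int(round(config.snp_density * L))
    free = np.array([p for p in range(1, L + 1) if p not in used])
    n_background = min(n_background, len(free))
    background = np.sort(rng.choice(free, size=n_background, replace=False))

    n_pairs = int(round(K * config.twin_fraction / 2))
    if n_pairs > 0 and n_background == 0:
        raise ValueError("twin alleles need at least one background site")
    n_base = K - n_pairs

    # alt base codes per variable site
    alt_code = {}
    for f in focal:
        alt_code[f.site] = _BASES.index(f.alt_base)
    linked_parent = {}
    for f in focal:
        for p in flank_positions[f.site]:
            linked_parent[p] = f.site
    for p in list(linked_parent) + list(background):
        if p not in alt_code:
            alt_code[int(p)] = int((ref_codes[p - 1] + 1 + rng.integers(0, 3)) % 4)

    # carrier matrix over the base alleles
    carriers = {}
    for f in focal:
        carriers[f.site] = rng.random(n_base) < f.alt_fraction
    for p, parent in linked_parent.items():
        carriers[p] = carriers[parent].copy()
    bg_fraction = np.clip(rng.beta(0.8, 4.0, size=n_background), 0.02, 0.5)
    for j, p in enumerate(background):
        carriers[int(p)] = rng.random(n_base) < bg_fraction[j]

    hap = np.tile(ref_codes, (K, 1))
    for p, mask in carriers.items():
        hap[:n_base, p - 1][mask] = alt_code[p]

    twin_of = {}
    if n_pairs > 0:
        flip_sites = rng.choice(background, size=n_pairs, replace=True)
        for t in range(n_pairs):
            twin = n_base + t
            hap[twin] = hap[t]
            p = int(flip_sites[t])
            if hap[twin, p - 1] == ref_codes[p - 1]:
                hap[twin, p - 1] = alt_code[p]
            else:
                hap[twin, p - 1] = ref_codes[p - 1]
            twin_of[t] = twin
            twin_of[twin] = t

    names = []
    for i in range(n_base):
        g, p = i // 99 + 1, i % 99 + 1
        if i < n_pairs:
            names.append(AlleleName(config.locus_id, (g, p, 1)))
        else:
            names.append(AlleleName(config.locus_id, (g, p)))
    for t in range(n_pairs):
        g, p = t // 99 + 1, t % 99 + 1
        names.append(AlleleName(config.locus_id, (g, p, 2)))

    variable = np.array(
        sorted(p for p in alt_code if (hap[:, p - 1] != ref_codes[p - 1]).any()),
        dtype=int,
    )
    catalog = AlleleCatalog(
        {names[i]: _codes_to_str(hap[i]) for i in range(K)}
    )
    locus = _make_locus(config, _codes_to_str(ref_codes))
    return AllelePool(
        config=config,
        locus=locus,
        catalog=catalog,
        names=names,
        haplotypes=hap,
        ref_codes=ref_codes,
        variable_sites=variable,
        alt_code=alt_code,
        focal=tuple(focal),
        flank_positions=flank_positions,
        twin_of=twin_of,
    )


@dataclass
class SimTruth:
    """Ground truth for one simulated sample."""

    sample_ids: list
    populations: np.ndarray        # (N,) str labels
    allele_idx: np.ndarray         # (N, 2) pool indices
    missing: np.ndarray            # (N,) bool: locus missing from the gold typing
    ambiguous: np.ndarray          # (N, 2) bool: copy reported as an ambiguity set
    population_frequencies: np.ndarray | None = None  # (n_pops, K) Dirichlet draws

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def genotype_codes(self, pool: AllelePool, sites) -> np.ndarray:
        """(N, S) count of ALT alleles in the true genotypes."""
        sites = np.asarray(sites)
        cols = sites - 1
        alt = np.array([pool.alt_code[int(s)] for s in sites], dtype=np.uint8)
        is_alt = pool.haplotypes[self.allele_idx][:, :, cols] == alt[None, None, :]
        return is_alt.sum(axis=1).astype(np.int8)

    def true_ref_frequency(self, pool: AllelePool, site: int, mask=None) -> float:
        codes = self.genotype_codes(pool, [site])[:, 0]
        if mask is not None:
            codes = codes[mask]
        if codes.size == 0:
            raise ValueError("no individuals selected")
        return 1.0 - codes.mean() / 2.0


def simulate_population(
    pool: AllelePool, config: SimConfig, rng: np.random.Generator | None = None
):
    """Draw diploid individuals and report their gold typings.

    Returns ``(gold_table, truth)``.  Per population, allele frequencies are a
    symmetric Dirichlet draw over the pool; each copy independently becomes an
    ambiguity set (true allele + its twin) with probability ``a`` where a twin
    exists, and each individual's locus is missing with probability ``m``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    K = pool.n_alleles
    N = config.n_populations * config.n_individuals
    allele_idx = np.empty((N, 2), dtype=np.int64)
    populations = np.empty(N, dtype=object)
    pop_freqs = np.empty((config.n_populations, K))
    row = 0
    for p in range(config.n_populations):
        freqs = rng.dirichlet(np.full(K, config.concentration))
        pop_freqs[p] = freqs
        n = config.n_individuals
        allele_idx[row : row + n] = rng.choice(K, size=(n, 2), p=freqs)
        populations[row : row + n] = f"POP{p + 1:02d}"
        row += n
    sample_ids = [f"S{i + 1:04d}" for i in range(N)]

    amb_request = rng.random((N, 2)) < config.ambiguity_rate
    has_twin = np.isin(allele_idx, list(pool.twin_of.keys()))
    ambiguous = amb_request & has_twin
    n_skipped = int((amb_request & ~has_twin).sum())
    if n_skipped:
        logger.warning(
            "%d ambiguity request(s) skipped: no catalog allele within 2 "
            "differences of the true allele",
            n_skipped,
        )
    missing = rng.random(N) < config.missing_rate

    rows = []
    for i in range(N):
        if missing[i]:
            continue
        calls = []
        for c in range(2):
            idx = int(allele_idx[i, c])
            name = str(pool.names[idx])
            if ambiguous[i, c]:
                partner = str(pool.names[pool.twin_of[idx]])
                name = "/".join(sorted([name, partner]))
            calls.append(name)
        rows.append(
            {
                "sample_id": sample_ids[i],
                "population": populations[i],
                "locus": config.locus_id,
                "allele1": calls[0],
                "allele2": calls[1],
            }
        )
    gold = pd.DataFrame(rows, columns=["sample_id", "population", "locus", "allele1", "allele2"])
    truth = SimTruth(
        sample_ids=sample_ids,
        populations=populations.astype(str),
        allele_idx=allele_idx,
        missing=missing,
        ambiguous=ambiguous,
        population_frequencies=pop_freqs,
    )
    return gold, truth


@dataclass
class NgsCallSet:
    """Simulated NGS genotypes and per-site retained-read depth."""

    sites: np.ndarray          # (S,) 1-based CDS positions
    ref_bases: list            # CDS-space REF base per site
    alt_bases: list
    genotypes: np.ndarray      # (N, S) ALT-allele count; -1 = missing
    depth: np.ndarray          # (N, S) retained reads
    sample_ids: list

    def site_index(self, site: int) -> int:
        idx = int(np.searchsorted(self.sites, site))
        if idx >= len(self.sites) or self.sites[idx] != site:
            raise KeyError(f"site {site} not among simulated call sites")
        return idx

    def ref_frequency(self, site: int, mask=None) -> float:
        g = self.genotypes[:, self.site_index(site)]
        if mask is not None:
            g = g[mask]
        g = g[g >= 0]
        if g.size == 0:
            raise ValueError("no non-missing NGS genotypes at site")
        return 1.0 - g.mean() / 2.0


def window_mismatch_matrix(
    pool: AllelePool, sites, half_width: int | None = None, include_central: bool = True
) -> np.ndarray:
    """(K, S) mismatch counts of each pool allele's read window vs the index.

    ``include_central=True`` is the read-retention convention (a mapper sees
    every mismatch); analysis-side window statistics exclude the central site.
    """
    w = pool.config.read_half_width if half_width is None else half_width
    mism = (pool.haplotypes != pool.ref_codes[None, :]).astype(np.int32)
    cum = np.concatenate(
        [np.zeros((pool.n_alleles, 1), dtype=np.int32), np.cumsum(mism, axis=1)], axis=1
    )
    L = pool.config.length
    sites = np.asarray(sites)
    lo = np.maximum(sites - w, 1)
    hi = np.minimum(sites + w, L)
    counts = cum[:, hi] - cum[:, lo - 1]
    if not include_central:
        counts = counts - mism[:, sites - 1]
    return counts


def simulate_ngs_calls(
    pool: AllelePool,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> NgsCallSet:
    """Generate NGS genotype calls under the per-read mapping-loss model.

    Reads at a site are fixed (2w+1)-windows of the underlying haplotype; a
    read with m mismatches to the index (central site included) survives with
    probability (1-lambda)^m; surviving reads report the copy's base, flipped
    to a uniformly chosen other base with probability epsilon; the genotype is
    the ML diploid call among {hom REF, het, hom ALT} under a symmetric-error
    read model.  Sites fixed for REF among the sampled haplotypes are not
    reported (nothing to discover).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    lam, eps, c = config.mapping_loss, config.base_error, config.mean_depth

    # discovered sites: ALT present among the sampled chromosomes
    alt_all = np.array(
        [pool.alt_code[int(s)] for s in pool.variable_sites], dtype=np.uint8
    )
    sampled = pool.haplotypes[truth.allele_idx]  # (N, 2, L)
    is_alt_all = sampled[:, :, pool.variable_sites - 1] == alt_all[None, None, :]
    keep = is_alt_all.any(axis=(0, 1))
    sites = pool.variable_sites[keep]
    is_alt = is_alt_all[:, :, keep]              # (N, 2, S)

    m_win = window_mismatch_matrix(pool, sites, include_central=True)
    with np.errstate(invalid="ignore"):
        p_ret = np.power(1.0 - lam, m_win)       # 0**0 == 1 covers lambda=1
    # retention probability per (individual, copy, site)
    p_copy = p_ret[truth.allele_idx]             # (N, 2, S)

    reads = rng.poisson(c / 2.0 * p_copy)        # surviving reads per copy
    errors = rng.binomial(reads, eps)
    to_partner = rng.binomial(errors, 1.0 / 3.0)  # errors landing on the other allele

    correct = reads - errors
    n_ref = np.where(~is_alt, correct, to_partner).sum(axis=1)
    n_alt = np.where(is_alt, correct, to_partner).sum(axis=1)
    n_other = (errors - to_partner).sum(axis=1)

    ll_rr = xlogy(n_ref, 1 - eps) + xlogy(n_alt + n_other, eps / 3.0)
    ll_aa = xlogy(n_alt, 1 - eps) + xlogy(n_ref + n_other, eps / 3.0)
    het = (1 - eps) / 2.0 + eps / 6.0
    ll_ra = xlogy(n_ref + n_alt, het) + xlogy(n_other, eps / 3.0)
    geno = np.argmax(np.stack([ll_rr, ll_ra, ll_aa]), axis=0).astype(np.int8)

    depth = reads.sum(axis=1)
    zero = depth == 0
    geno[zero] = 0 if config.zero_read_policy == "hom_ref" else -1

    return NgsCallSet(
        sites=sites,
        ref_bases=[pool.ref_base(int(s)) for s in sites],
        alt_bases=[pool.alt_base(int(s)) for s in sites],
        genotypes=geno,
        depth=depth.astype(np.int32),
        sample_ids=list(truth.sample_ids),
    )


@dataclass
class SimBundle:
    config: SimConfig
    pool: AllelePool
    gold: pd.DataFrame
    truth: SimTruth
    ngs: NgsCallSet

    def focal_fe(self, population: str | None = None) -> pd.DataFrame:
        """FE at the focal sites (gold side from the generator truth, exact
        because twin ambiguity never touches focal sites)."""
        from .freqstats import frequency_error

        if population is None:
            mask = ~self.truth.missing
        else:
            mask = (~self.truth.missing) & (self.truth.populations == population)
        rows = []
        for f in self.pool.focal:
            f_gold = self.truth.true_ref_frequency(self.pool, f.site, mask=mask)
            f_ngs = self.ngs.ref_frequency(f.site)
            rows.append(
                {
                    "site": f.site,
                    "population": population or "global",
                    "f_ngs": f_ngs,
                    "f_gold": f_gold,
                    "fe": frequency_error(f_ngs, f_gold),
                }
            )
        return pd.DataFrame(rows)


def simulate_bundle(config: SimConfig) -> SimBundle:
    """Run the three generator stages with a single root seed."""
    root = np.random.default_rng(config.seed)
    seeds = root.spawn(3)
    pool = simulate_allele_pool(config, seeds[0])
    gold, truth = simulate_population(pool, config, seeds[1])
    ngs = simulate_ngs_calls(pool, truth, config, seeds[2])
    return SimBundle(config=config, pool=pool, gold=gold, truth=truth, ngs=ngs)


def write_fixture_bundle(bundle: SimBundle, out_dir) -> dict:
    """Write the bundle in the pipeline's standard input formats.

    Emits a VCF, gold typing TSV, allele-catalog FASTA, exon-map JSON,
    depth table and truth TSV; re-ingesting them through the pipeline
    reproduces the in-memory objects.
    """
    from pathlib import Path

    from . import io as rio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "exon_map": out / "exon_map.json",
        "catalog": out / "catalog.fasta",
        "gold": out / "gold.tsv",
        "vcf": out / "calls.vcf",
        "depth": out / "depth.tsv",
        "truth": out / "truth.tsv",
        "config": out / "sim_config.json",
    }
    rio.write_exon_map(paths["exon_map"], [bundle.pool.locus])
    rio.write_catalog_fasta(paths["catalog"], bundle.pool.catalog)
    rio.write_gold_table(paths["gold"], bundle.gold)
    rio.write_vcf(
        paths["vcf"],
        bundle.pool.locus,
        sites=bundle.ngs.sites,
        ref_bases=bundle.ngs.ref_bases,
        alt_bases=bundle.ngs.alt_bases,
        genotypes=bundle.ngs.genotypes,
        sample_ids=bundle.ngs.sample_ids,
    )
    rio.write_depth_table(
        paths["depth"],
        bundle.pool.locus,
        sites=bundle.ngs.sites,
        depth=bundle.ngs.depth,
        sample_ids=bundle.ngs.sample_ids,
    )
    truth_df = pd.DataFrame(
        {
            "sample_id": bundle.truth.sample_ids,
            "population": bundle.truth.populations,
            "locus": bundle.config.locus_id,
            "allele1": [str(bundle.pool.names[i]) for i in bundle.truth.allele_idx[:, 0]],
            "allele2": [str(bundle.pool.names[i]) for i in bundle.truth.allele_idx[:, 1]],
            "missing": bundle.truth.missing.astype(int),
        }
    )
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    paths["config"].write_text(bundle.config.to_json() + "\n")
    return {k: str(v) for k, v in paths.items()}
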