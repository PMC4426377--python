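"""End-to-end benchmarking pipeline: comparison -> frequency statistics ->
site classification -> direction test -> mapping-bias windows -> coverage.

The pipeline consumes the standard inputs (VCF, gold typing table, allele
catalog, exon map, optional depth table), restricts to the samples present in
both datasets, and produces tidy per-comparison / per-site tables plus a
summary.  All sites are analysed in 1-based CDS coordinates of the
concatenated ARS exons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import coverage as cov
from . import freqstats, io, windows
from .alleles import ConsensusSequence, expand_call_to_consensus, parse_allele_call
from .compare import SiteGenotype, compare_genotypes, mismatch_concentration

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    vcf: str
    gold: str
    catalog: str
    exon_map: str
    depth: str | None = None
    out_dir: str | None = None
    fe_large: float = 0.1
    fe_well: float = 0.01
    min_pops: int = 2
    half_width: int = 25
    concentration_mass: float = 0.5

    def __post_init__(self):
        if self.fe_large <= 0 or self.fe_well <= 0:
            raise ValueError("thresholds must be positive")
        if self.fe_well >= self.fe_large:
            raise ValueError("fe_well must be below fe_large")


@dataclass
class PipelineResult:
    config: RunConfig
    comparisons: pd.DataFrame       # locus, sample_id, population, site, match, corrected
    per_site_mismatch: pd.DataFrame
    per_individual_mismatch: pd.DataFrame
    fe_table: pd.DataFrame          # locus, site, population, f_ngs, f_gold, fe
    site_table: pd.DataFrame        # pooled per-site statistics + class + flag
    gene_table: pd.DataFrame        # per-locus MAE, direction counts, binomial p
    window_table: pd.DataFrame      # per-window mismatch counts
    window_report: pd.DataFrame     # GroupSummary rows
    unreliable: list
    coverage_comparison: object | None
    h_filter: freqstats.HeterozygosityFilterReport
    summary: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "comparisons.tsv": self.comparisons,
            "per_site_mismatch.tsv": self.per_site_mismatch,
            "per_individual_mismatch.tsv": self.per_individual_mismatch,
            "fe_table.tsv": self.fe_table,
            "site_table.tsv": self.site_table,
            "gene_table.tsv": self.gene_table,
            "window_table.tsv": self.window_table,
            "window_report.tsv": self.window_report,
        }
        for name, df in tables.items():
            df.to_csv(out / name, sep="\t", index=False)
        pd.DataFrame(self.unreliable, columns=["locus", "site"]).to_csv(
            out / "unreliable_sites.tsv", sep="\t", index=False
        )
        (out / "summary.json").write_text(
            json.dumps(self.summary, indent=2, default=float) + "\n"
        )


def _code_to_genotype(code: int, ref: str, alt: str, site: int, sample: str):
    if code == 0:
        pair = (ref, ref)
    elif code == 1:
        pair = (ref, alt)
    elif code == 2:
        pair = (alt, alt)
    else:
        return None
    return SiteGenotype.of(pair[0], pair[1], site=site, sample_id=sample)


def run_full_pipeline(config: RunConfig) -> PipelineResult:
    loci = io.read_exon_map(config.exon_map)
    catalog = io.read_catalog_fasta(config.catalog)
    gold = io.read_gold_table(config.gold)
    vcf = io.read_vcf_ars_sites(config.vcf, loci)
    if vcf.sites.empty:
        raise ValueError("no usable biallelic ARS-exon SNPs in the VCF")
    logger.info("VCF ingest: %d sites kept, skipped %s", len(vcf.sites), vcf.skipped)

    depth_df = None
    if config.depth is not None:
        depth_df = io.read_depth_table(config.depth, loci)

    vcf_sample_idx = {s: i for i, s in enumerate(vcf.samples)}

    comp_rows: list[dict] = []
    fe_rows: list[dict] = []
    all_windows: list = []

    for locus_id, locus in loci.items():
        lsites = vcf.sites[vcf.sites["locus"] == locus_id]
        if lsites.empty:
            continue
        lgold = gold[gold["locus"] == locus_id]
        lgold = lgold[lgold["sample_id"].isin(vcf_sample_idx)]
        if lgold.empty:
            logger.warning("locus %s: no overlapping samples; skipped", locus_id)
            continue

        consensus: list[tuple[ConsensusSequence, ConsensusSequence]] = []
        samples, pops = [], []
        for row in lgold.itertuples(index=False):
            c1 = expand_call_to_consensus(parse_allele_call(row.allele1), catalog)
            c2 = expand_call_to_consensus(parse_allele_call(row.allele2), catalog)
            consensus.append((c1, c2))
            samples.append(row.sample_id)
            pops.append(row.population)
        pops = np.asarray(pops, dtype=object)
        vcols = np.array([vcf_sample_idx[s] for s in samples])

        index_bits = ConsensusSequence.from_string(locus.reference_ars_seq)

        for srow in lsites.itertuples(index=True):
            site_idx = int(srow.Index)  # column position in vcf.genotypes
            site, ref, alt = int(srow.site), srow.ref, srow.alt
            ngs_codes = vcf.genotypes[vcols, site_idx]

            corrected_sets: list[tuple[frozenset, frozenset]] = []
            for i, sample in enumerate(samples):
                c1, c2 = consensus[i]
                gold_gt = SiteGenotype(
                    (c1.base_set(site), c2.base_set(site)), site=site, sample_id=sample
                )
                ngs_gt = _code_to_genotype(int(ngs_codes[i]), ref, alt, site, sample)
                if ngs_gt is None:  # missing NGS genotype: no comparison
                    corrected_sets.append(gold_gt.alleles)
                    continue
                res = compare_genotypes(gold_gt, ngs_gt)
                corrected_sets.append(res.gold_after_correction.alleles)
                comp_rows.append(
                    {
                        "locus": locus_id,
                        "sample_id": sample,
                        "population": pops[i],
                        "site": site,
                        "match": res.match,
                        "corrected": res.corrected,
                    }
                )

            groups = {"global": np.ones(len(samples), dtype=bool)}
            for p in sorted(set(pops) - {"NA"}):
                groups[p] = pops == p
            for pop_label, mask in groups.items():
                gold_gts = [corrected_sets[i] for i in np.nonzero(mask)[0]]
                codes = ngs_codes[mask]
                codes = codes[codes >= 0]
                if not gold_gts or codes.size == 0:
                    continue
                f_gold = freqstats.ref_allele_frequency(gold_gts, ref)
                f_ngs = float(1.0 - codes.mean() / 2.0)
                fe_rows.append(
                    {
                        "locus": locus_id,
                        "site": site,
                        "population": pop_label,
                        "ref": ref,
                        "alt": alt,
                        "f_ngs": f_ngs,
                        "f_gold": f_gold,
                        "fe": freqstats.frequency_error(f_ngs, f_gold),
                    }
                )

            copies = [c for pair in consensus for c in pair]
            sources = [(s, k) for s in samples for k in (0, 1)]
            ws = windows.windows_with_mismatches(
                copies,
                site,
                ref,
                index_seq=index_bits,
                half_width=config.half_width,
                sources=sources,
                locus=locus_id,
            )
            all_windows.extend(ws)

    if not comp_rows:
        raise ValueError("no comparable genotypes between the VCF and gold table")

    comparisons = pd.DataFrame(comp_rows)
    n_comparisons = len(comparisons)
    overall_mismatch = float((~comparisons["match"]).mean())
    per_site_mm = (
        comparisons.groupby(["locus", "site"])["match"]
        .agg(n="count", n_mismatch=lambda m: int((~m).sum()))
        .reset_index()
    )
    per_site_mm["proportion"] = per_site_mm["n_mismatch"] / per_site_mm["n"]
    per_ind_mm = (
        comparisons.groupby("sample_id")["match"]
        .agg(n="count", n_mismatch=lambda m: int((~m).sum()))
        .reset_index()
    )

    fe_table = pd.DataFrame(fe_rows)
    pooled = fe_table[fe_table["population"] == "global"].copy()
    pooled["class"] = [
        freqstats.classify_site(fe, config.fe_large, config.fe_well)
        for fe in pooled["fe"]
    ]
    flagged = freqstats.unreliable_sites(
        fe_table, threshold=config.fe_large, min_pops=config.min_pops
    )
    flagged_set = set(flagged)
    pooled["flagged"] = [
        (l, s) in flagged_set for l, s in zip(pooled["locus"], pooled["site"])
    ]
    pooled["h_gold"] = freqstats.heterozygosity(pooled["f_gold"].to_numpy())
    site_table = pooled.merge(
        per_site_mm[["locus", "site", "proportion"]].rename(
            columns={"proportion": "mismatch_proportion"}
        ),
        on=["locus", "site"],
        how="left",
    )
    if depth_df is not None and not depth_df.empty:
        mean_depth = (
            depth_df.groupby(["locus", "site"])["depth"].mean().rename("mean_depth")
        )
        site_table = site_table.merge(
            mean_depth.reset_index(), on=["locus", "site"], how="left"
        )

    gene_rows = []
    for locus_id, sub in site_table.groupby("locus"):
        flagged_sub = sub[sub["flagged"]]
        n_ref = int((flagged_sub["fe"] > 0).sum())
        n_alt = int((flagged_sub["fe"] < 0).sum())
        gene_rows.append(
            {
                "locus": locus_id,
                "n_sites": len(sub),
                "mae": freqstats.mae(sub["fe"]),
                "n_flagged": len(flagged_sub),
                "n_ref_skewed": n_ref,
                "n_alt_skewed": n_alt,
                "p_direction": (
                    freqstats.direction_test(n_ref, n_alt) if n_ref + n_alt else np.nan
                ),
            }
        )
    gene_table = pd.DataFrame(gene_rows)

    site_classes = {
        (l, s): c
        for l, s, c in zip(site_table["locus"], site_table["site"], site_table["class"])
    }
    window_report = windows.bias_mechanism_report(all_windows, site_classes)
    window_table = pd.DataFrame(
        {
            "locus": [w.locus for w in all_windows],
            "site": [w.central_site for w in all_windows],
            "central_class": [w.central_class for w in all_windows],
            "mismatch_count": [w.mismatch_count for w in all_windows],
        }
    )

    h_filter = freqstats.heterozygosity_filter_report(
        {
            (l, s): f
            for l, s, f in zip(site_table["locus"], site_table["site"], site_table["f_gold"])
        },
        flagged,
    )

    def _safe_pearson(x, y):
        try:
            return freqstats.pearson_with_p(x, y)
        except ValueError as e:
            logger.warning("correlation skipped: %s", e)
            return (np.nan, np.nan)

    r_h_fe, p_h_fe = _safe_pearson(site_table["h_gold"], site_table["fe"])
    r_h_absfe, p_h_absfe = _safe_pearson(site_table["h_gold"], site_table["fe"].abs())
    r_mm_absfe, p_mm_absfe = _safe_pearson(
        site_table["mismatch_proportion"], site_table["fe"].abs()
    )

    coverage_comparison = None
    r_cov = p_cov = np.nan
    if depth_df is not None and not depth_df.empty:
        try:
            coverage_comparison = cov.coverage_by_match_status(depth_df, comparisons)
        except ValueError as e:
            logger.warning("coverage comparison skipped: %s", e)
        if "mean_depth" in site_table.columns:
            ok = site_table["mean_depth"].notna()
            r_cov, p_cov = _safe_pearson(
                site_table.loc[ok, "mean_depth"], site_table.loc[ok, "fe"].abs()
            )

    conc = mismatch_concentration(
        per_site_mm["n_mismatch"].to_numpy(), config.concentration_mass
    ) if per_site_mm["n_mismatch"].sum() else np.nan

    summary = {
        "n_samples": int(comparisons["sample_id"].nunique()),
        "n_sites": int(len(site_table)),
        "n_comparisons": n_comparisons,
        "overall_mismatch_proportion": overall_mismatch,
        "mismatch_concentration_at_half": conc,
        "mae_by_locus": {r["locus"]: r["mae"] for r in gene_rows},
        "n_flagged_sites": len(flagged),
        "direction_counts": {
            r["locus"]: [r["n_ref_skewed"], r["n_alt_skewed"]] for r in gene_rows
        },
        "direction_p": {r["locus"]: r["p_direction"] for r in gene_rows},
        "h_vs_fe": {"r": r_h_fe, "p": p_h_fe},
        "h_vs_abs_fe": {"r": r_h_absfe, "p": p_h_absfe},
        "mismatch_vs_abs_fe": {"r": r_mm_absfe, "p": p_mm_absfe},
        "coverage_vs_abs_fe": {"r": r_cov, "p": p_cov},
        "mean_h_excluded": h_filter.mean_excluded,
        "mean_h_retained": h_filter.mean_retained,
        "vcf_skipped": vcf.skipped,
    }
    if coverage_comparison is not None:
        summary["coverage_by_match"] = {
            "mean_matched": coverage_comparison.mean_matched,
            "mean_mismatched": coverage_comparison.mean_mismatched,
            "p_matched_greater": coverage_comparison.p_matched_greater,
        }
    if not window_report.empty:
        summary["window_report"] = window_report.to_dict(orient="records")

    result = PipelineResult(
        config=config,
        comparisons=comparisons,
        per_site_mismatch=per_site_mm,
        per_individual_mismatch=per_ind_mm,
        fe_table=fe_table,
        site_table=site_table,
        gene_table=gene_table,
        window_table=window_table,
        window_report=window_report,
        unreliable=flagged,
        coverage_comparison=coverage_comparison,
        h_filter=h_filter,
        summary=summary,
    )
    if config.out_dir is not None:
        result.write(config.out_dir)
    return result
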