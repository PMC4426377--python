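"""Per-site sequencing depth and its relationship to genotype errors.

Depth extraction from alignments is delegated to standard tooling (e.g.
``genomeCoverageBed``); this module ingests per-base depth tables and relates
depth to genotype match status and to the magnitude of the allele-frequency
error |FE|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import freqstats, windows


@dataclass
class CoverageComparison:
    matched: np.ndarray
    mismatched: np.ndarray
    mean_matched: float
    mean_mismatched: float
    p_matched_greater: float


def coverage_by_match_status(
    depth: pd.DataFrame, results
) -> CoverageComparison:
    """Depth distributions of matched vs mismatched genotype observations.

    ``depth`` needs columns ``sample_id``, ``site`` (CDS position, optionally
    ``locus``) and ``depth``; ``results`` is a list of comparison results or a
    DataFrame with ``sample_id``, ``site``, ``match`` (and optionally
    ``locus``).  The one-tailed rank-sum p is for matched observations having
    higher depth than mismatched ones.
    """
    if isinstance(results, pd.DataFrame):
        res_df = results
    else:
        res_df = pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in results],
                "site": [r.site for r in results],
                "match": [r.match for r in results],
            }
        )
    keys = ["sample_id", "site"]
    if "locus" in depth.columns and "locus" in res_df.columns:
        keys = ["sample_id", "locus", "site"]
    merged = res_df.merge(depth[keys + ["depth"]], on=keys, how="inner")
    if merged.empty:
        raise ValueError("no overlap between coverage and comparison records")
    matched = merged.loc[merged["match"], "depth"].to_numpy(dtype=float)
    mismatched = merged.loc[~merged["match"], "depth"].to_numpy(dtype=float)
    if matched.size == 0 or mismatched.size == 0:
        raise ValueError("need both matched and mismatched observations")
    return CoverageComparison(
        matched=matched,
        mismatched=mismatched,
        mean_matched=float(matched.mean()),
        mean_mismatched=float(mismatched.mean()),
        p_matched_greater=windows.mannwhitney_one_tailed(matched, mismatched),
    )


def coverage_vs_fe(mean_site_coverage, abs_fe):
    """Pearson correlation between per-site mean depth and |FE|."""
    return freqstats.pearson_with_p(mean_site_coverage, abs_fe)


def mean_depth_per_site(depth: pd.DataFrame) -> pd.Series:
    """Mean depth per site over individuals (indexed by site, or by
    (locus, site) when a locus column is present)."""
    keys = ["locus", "site"] if "locus" in depth.columns else ["site"]
    return depth.groupby(keys)["depth"].mean()
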