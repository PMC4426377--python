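"""Flanking-window test for reference-allele mapping bias.

For every chromosome copy in the sample, a window of up to 51 bp (25 bases
either side of a SNP) is cut from the copy's ARS allele sequence.  Windows are
split by whether the central base is the REF or the ALT allele, and each
window's mismatch count against the index (reference) sequence is computed,
*excluding* the central site.  If mapping bias drives the frequency error at a
site, ALT-centered windows carry more flanking mismatches than REF-centered
ones; the excess is tested with a one-tailed rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .alleles import BASE_BIT, ConsensusSequence, seq_to_bits

logger = logging.getLogger(__name__)

REF = "REF"
ALT = "ALT"

# total group size up to which the exact rank-sum enumeration (midrank DP)
# is used; beyond, the normal approximation with tie correction takes over
EXACT_MAX_TOTAL = 100


@dataclass
class WindowObservation:
    central_site: int            # 1-based CDS position
    central_class: str           # REF or ALT
    start: int                   # 1-based CDS position of first window base
    masks: np.ndarray            # uint8 base-set bits, one per window position
    mismatch_count: int | None = None
    source: tuple = ()
    locus: str = ""

    def __len__(self) -> int:
        return len(self.masks)

    @property
    def window_seq(self) -> str:
        return ConsensusSequence(self.masks).to_string()


def _as_masks(seq) -> np.ndarray:
    if isinstance(seq, ConsensusSequence):
        return seq.masks
    return seq_to_bits(seq)


def build_windows(
    sequences,
    site: int,
    ref_base: str,
    half_width: int = 25,
    sources=None,
    locus: str = "",
) -> list:
    """One window per chromosome copy, centered on ``site`` and truncated at
    the CDS boundaries.

    ``sequences`` holds one allele sequence (string or
    :class:`~refbias.alleles.ConsensusSequence`) per chromosome copy.  A copy
    whose central base equals ``ref_base`` yields a REF window, any other
    single base an ALT window; copies whose central base is residually
    ambiguous are excluded from both groups.
    """
    sequences = list(sequences)
    if not sequences:
        raise ValueError("no sequences supplied")
    L = len(sequences[0])
    if not 1 <= site <= L:
        raise ValueError(f"site {site} outside [1, {L}]")
    ref_bit = BASE_BIT[ref_base]
    lo = max(1, site - half_width)
    hi = min(L, site + half_width)
    out = []
    for idx, seq in enumerate(sequences):
        masks = _as_masks(seq)
        if len(masks) != L:
            raise ValueError("sequences have unequal lengths")
        central = int(masks[site - 1])
        if central not in BASE_BIT.values():  # residual ambiguity at the SNP
            continue
        out.append(
            WindowObservation(
                central_site=site,
                central_class=REF if central == ref_bit else ALT,
                start=lo,
                masks=masks[lo - 1 : hi],
                source=sources[idx] if sources is not None else (idx,),
                locus=locus,
            )
        )
    return out


def count_window_mismatches(window: WindowObservation, index_seq) -> int:
    """Mismatches of the window against the aligned index slice, excluding the
    central SNP.

    A residually ambiguous flanking position counts as a match when the index
    base is among its possible bases, else as one mismatch.
    """
    index_bits = _as_masks(index_seq)
    lo = window.start
    hi = lo + len(window.masks) - 1
    if hi > len(index_bits):
        raise ValueError(
            f"window [{lo}, {hi}] extends past index sequence of length "
            f"{len(index_bits)}"
        )
    idx_slice = index_bits[lo - 1 : hi]
    mismatch = (window.masks & idx_slice) == 0
    mismatch[window.central_site - lo] = False
    n = int(mismatch.sum())
    window.mismatch_count = n
    return n


def windows_with_mismatches(sequences, site, ref_base, index_seq, **kw) -> list:
    """Convenience: build windows and fill in their mismatch counts."""
    ws = build_windows(sequences, site, ref_base, **kw)
    for w in ws:
        count_window_mismatches(w, index_seq)
    return ws


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """P(rank sum of group a >= observed) by enumeration over all C(N, n_a)
    assignments, with midranks for ties (dynamic program over doubled ranks)."""
    pooled = np.concatenate([a, b])
    ranks2 = np.rint(2 * stats.rankdata(pooled)).astype(np.int64)
    n_a = len(a)
    observed = int(ranks2[:n_a].sum())
    total = int(ranks2.sum())
    # dp[k, s] = number of size-k subsets of the values seen so far with sum s
    dp = np.zeros((n_a + 1, total + 1))
    dp[0, 0] = 1.0
    for v in ranks2:
        dp[1:, v:] += dp[:-1, : total + 1 - v]
    n_subsets = comb(len(pooled), n_a)
    count_ge = dp[n_a, observed:].sum()
    return float(count_ge / n_subsets)


def mannwhitney_one_tailed(group_a, group_b) -> float:
    """One-tailed rank-sum p for the alternative that ``group_a``
    stochastically dominates ``group_b``.

    Exact enumeration (midranks, tie-aware) for small groups; normal
    approximation with tie-corrected variance otherwise.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size + b.size <= EXACT_MAX_TOTAL and max(a.size, b.size) <= 50:
        return _exact_rank_sum_p(a, b)
    res = stats.mannwhitneyu(a, b, alternative="greater", method="asymptotic")
    return float(res.pvalue)


@dataclass
class GroupSummary:
    site_class: str
    n_ref: int
    n_alt: int
    mean_ref: float
    mean_alt: float
    p_alt_greater: float


def bias_mechanism_report(windows, site_classes: dict) -> pd.DataFrame:
    """Mean flanking mismatch counts of REF vs ALT windows per site class.

    ``windows`` must already carry mismatch counts; ``site_classes`` maps a
    site (or ``(locus, site)``) to its frequency-error class.  For each class
    the one-tailed rank-sum p tests for an excess of mismatches on ALT
    windows.  Classes missing either group are omitted with a warning.
    """
    rows = []
    by_class: dict = {}
    for w in windows:
        if w.mismatch_count is None:
            raise ValueError("windows must carry mismatch counts; "
                             "run count_window_mismatches first")
        key = (w.locus, w.central_site) if w.locus else w.central_site
        cls = site_classes.get(key)
        if cls is None:
            continue
        by_class.setdefault(cls, {REF: [], ALT: []})[w.central_class].append(
            w.mismatch_count
        )
    for cls in sorted(by_class):
        groups = by_class[cls]
        if not groups[REF] or not groups[ALT]:
            logger.warning(
                "class %r lacks %s windows; omitted from report",
                cls,
                REF if not groups[REF] else ALT,
            )
            continue
        rows.append(
            GroupSummary(
                site_class=cls,
                n_ref=len(groups[REF]),
                n_alt=len(groups[ALT]),
                mean_ref=float(np.mean(groups[REF])),
                mean_alt=float(np.mean(groups[ALT])),
                p_alt_greater=mannwhitney_one_tailed(groups[ALT], groups[REF]),
            )
        )
    return pd.DataFrame([vars(r) for r in rows])
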