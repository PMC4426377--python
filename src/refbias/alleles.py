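"""HLA-style allele nomenclature, ARS exon sequences and coordinate mapping.

Allele names follow the colon-delimited convention used for classical HLA
loci: a locus designator, a ``*``, and 1-4 numeric fields (serotype group,
nonsynonymous, synonymous, noncoding).  A typing result may be ambiguous —
either an explicit ``/``-separated list of candidate names, or a name given at
lower than full resolution, which stands for every catalog allele sharing the
prefix.  Candidates are expanded to their ARS (antigen recognition site) exon
coding sequences and collapsed into a per-position *consensus* in which
ambiguous positions carry the set of possible bases.

All analysis coordinates are 1-based positions in the concatenated ARS coding
sequence (CDS space); :func:`cds_to_genomic` / :func:`genomic_to_cds` translate
to genomic coordinates through an ordered exon map, reverse-complementing on
minus-strand loci.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .compare import SiteGenotype

# 4-bit base encoding so a set of bases is a bitwise OR
BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
BIT_BASES = {
    mask: frozenset(b for b, bit in BASE_BIT.items() if mask & bit)
    for mask in range(1, 16)
}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_SEQ_TO_BITS = np.zeros(256, dtype=np.uint8)
for _b, _bit in BASE_BIT.items():
    _SEQ_TO_BITS[ord(_b)] = _bit


class AlleleNameError(ValueError):
    pass


class CatalogLookupError(KeyError):
    pass


def seq_to_bits(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as a uint8 bit array."""
    arr = _SEQ_TO_BITS[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 0).any():
        bad = seq[int(np.argmax(arr == 0))]
        raise ValueError(f"invalid base {bad!r} in sequence")
    return arr


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


_NAME_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]*)\*(\d+(?::\d+)*)([A-Za-z]*)$")


@dataclass(frozen=True)
class AlleleName:
    """A possibly partial-resolution allele name, e.g. ``B*35:03``."""

    locus: str
    fields: tuple
    raw: str = field(default="", compare=False)

    def __post_init__(self):
        if not 1 <= len(self.fields) <= 4:
            raise AlleleNameError(
                f"allele name needs 1-4 numeric fields, got {len(self.fields)}"
            )
        object.__setattr__(self, "fields", tuple(int(f) for f in self.fields))

    def __str__(self) -> str:
        return f"{self.locus}*" + ":".join(f"{f:02d}" for f in self.fields)

    @property
    def resolution(self) -> int:
        return len(self.fields)

    def is_prefix_of(self, other: "AlleleName") -> bool:
        return (
            self.locus == other.locus
            and len(self.fields) <= len(other.fields)
            and other.fields[: len(self.fields)] == self.fields
        )


def parse_allele_name(raw: str) -> AlleleName:
    """Parse ``LOCUS*F1[:F2[:F3[:F4]]]``.

    Expression-suffix letters (N, L, S, C, A, Q) are outside this data model
    and rejected explicitly.
    """
    raw = raw.strip()
    m = _NAME_RE.match(raw)
    if m is None:
        raise AlleleNameError(f"malformed allele name {raw!r}")
    locus, fields_str, suffix = m.groups()
    if suffix:
        raise AlleleNameError(
            f"allele name {raw!r} carries expression suffix {suffix!r}, "
            "which is not supported"
        )
    fields = tuple(int(f) for f in fields_str.split(":"))
    if len(fields) > 4:
        raise AlleleNameError(f"allele name {raw!r} has more than 4 fields")
    return AlleleName(locus=locus, fields=fields, raw=raw)


@dataclass(frozen=True)
class AlleleCall:
    """A possibly ambiguous typing result: a set of candidate allele names."""

    candidates: frozenset

    def __post_init__(self):
        if not self.candidates:
            raise AlleleNameError("an allele call needs at least one candidate")
        loci = {c.locus for c in self.candidates}
        if len(loci) > 1:
            raise AlleleNameError(f"mixed loci in one allele call: {sorted(loci)}")

    @property
    def locus(self) -> str:
        return next(iter(self.candidates)).locus

    @property
    def is_ambiguous(self) -> bool:
        return len(self.candidates) > 1

    def __str__(self) -> str:
        return "/".join(sorted(str(c) for c in self.candidates))


def parse_allele_call(raw: str) -> AlleleCall:
    """Parse a ``/``-separated candidate list, e.g. ``B*35:02/B*35:03/B*35:04``."""
    parts = [p for p in raw.strip().split("/") if p]
    if not parts:
        raise AlleleNameError(f"empty allele call {raw!r}")
    return AlleleCall(candidates=frozenset(parse_allele_name(p) for p in parts))


@dataclass(frozen=True)
class Exon:
    label: str
    start: int  # 1-based inclusive genomic
    end: int    # 1-based inclusive genomic

    def __post_init__(self):
        if self.start > self.end or self.start < 1:
            raise ValueError(f"bad exon interval {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class LocusSpec:
    """One locus: its ARS exons (in coding order), strand and index sequence.

    ``reference_ars_seq`` is the concatenation of the ARS exons in coding
    orientation — the sequence against which reads were aligned (the index).
    Class I loci span exons 2+3 (546 coding bases); class II, exon 2 (270).
    """

    locus_id: str
    ars_exons: tuple
    strand: str
    reference_ars_seq: str
    hla_class: str = "I"
    chrom: str = "chr6"

    def __post_init__(self):
        object.__setattr__(self, "ars_exons", tuple(self.ars_exons))
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        total = sum(e.length for e in self.ars_exons)
        if total != len(self.reference_ars_seq):
            raise ValueError(
                f"exon lengths sum to {total} but reference sequence has "
                f"{len(self.reference_ars_seq)} bases"
            )
        seq_to_bits(self.reference_ars_seq)  # validates alphabet

    @property
    def cds_length(self) -> int:
        return len(self.reference_ars_seq)

    def reference_bits(self) -> np.ndarray:
        return seq_to_bits(self.reference_ars_seq)


def cds_to_genomic(locus: LocusSpec, cds_pos: int) -> int:
    """Map a 1-based CDS position to its 1-based genomic coordinate.

    On minus-strand loci CDS position 1 maps to the *highest* coordinate of
    the first coding exon.
    """
    if not 1 <= cds_pos <= locus.cds_length:
        raise ValueError(
            f"CDS position {cds_pos} outside [1, {locus.cds_length}] for "
            f"{locus.locus_id}"
        )
    offset = cds_pos - 1
    for exon in locus.ars_exons:
        if offset < exon.length:
            if locus.strand == "+":
                return exon.start + offset
            return exon.end - offset
        offset -= exon.length
    raise AssertionError("unreachable")


def genomic_to_cds(locus: LocusSpec, genomic_pos: int):
    """Inverse of :func:`cds_to_genomic`; returns None for positions outside
    the ARS exons."""
    offset = 0
    for exon in locus.ars_exons:
        if exon.start <= genomic_pos <= exon.end:
            if locus.strand == "+":
                return offset + (genomic_pos - exon.start) + 1
            return offset + (exon.end - genomic_pos) + 1
        offset += exon.length
    return None


class ConsensusSequence:
    """Per-position base sets for one chromosome copy, stored as a bit array."""

    def __init__(self, masks: np.ndarray):
        masks = np.asarray(masks, dtype=np.uint8)
        if (masks == 0).any():
            raise ValueError("consensus positions must hold non-empty base sets")
        self.masks = masks

    @classmethod
    def from_string(cls, seq: str) -> "ConsensusSequence":
        return cls(seq_to_bits(seq))

    @classmethod
    def from_sequences(cls, seqs) -> "ConsensusSequence":
        seqs = list(seqs)
        if not seqs:
            raise ValueError("need at least one sequence")
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths {sorted(lengths)}")
        masks = seq_to_bits(seqs[0])
        for s in seqs[1:]:
            masks = masks | seq_to_bits(s)
        return cls(masks)

    def __len__(self) -> int:
        return len(self.masks)

    def base_set(self, pos: int) -> frozenset:
        if not 1 <= pos <= len(self):
            raise ValueError(f"position {pos} outside [1, {len(self)}]")
        return BIT_BASES[int(self.masks[pos - 1])]

    def ambiguous_positions(self) -> np.ndarray:
        """1-based positions holding more than one possible base."""
        popcount = np.unpackbits(self.masks[:, None], axis=1).sum(axis=1)
        return np.nonzero(popcount > 1)[0] + 1

    def to_string(self, ambiguity_char: str = "N") -> str:
        out = []
        for m in self.masks:
            bases = BIT_BASES[int(m)]
            out.append(next(iter(bases)) if len(bases) == 1 else ambiguity_char)
        return "".join(out)

    def __eq__(self, other):
        return isinstance(other, ConsensusSequence) and np.array_equal(
            self.masks, other.masks
        )


class AlleleCatalog:
    """Mapping from allele names to ARS coding sequences for one or more loci.

    Lookups at lower resolution than the stored entries return every matching
    higher-resolution sequence.
    """

    def __init__(self, entries: dict):
        self._entries: dict[AlleleName, str] = {}
        self._by_prefix: dict[tuple, list] = {}
        self._locus_length: dict[str, int] = {}
        for name, seq in entries.items():
            if isinstance(name, str):
                name = parse_allele_name(name)
            self.add(name, seq)

    def add(self, name: AlleleName, seq: str) -> None:
        seq = seq.upper()
        seq_to_bits(seq)
        want = self._locus_length.setdefault(name.locus, len(seq))
        if len(seq) != want:
            raise ValueError(
                f"sequence for {name} has length {len(seq)}, expected {want} "
                f"at locus {name.locus}"
            )
        self._entries[name] = seq
        for k in range(1, len(name.fields) + 1):
            self._by_prefix.setdefault((name.locus, name.fields[:k]), []).append(name)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, name: AlleleName) -> bool:
        return bool(self.matching_names(name))

    def items(self):
        return self._entries.items()

    def cds_length(self, locus: str) -> int:
        return self._locus_length[locus]

    def loci(self):
        return sorted(self._locus_length)

    def matching_names(self, name: AlleleName) -> list:
        """Catalog entries equal to ``name`` or refining it with extra fields."""
        return list(self._by_prefix.get((name.locus, name.fields), ()))

    def sequences(self, name: AlleleName) -> list:
        matches = self.matching_names(name)
        if not matches:
            raise CatalogLookupError(f"allele {name} not in catalog")
        return [self._entries[m] for m in matches]


def expand_call_to_consensus(call: AlleleCall, catalog: AlleleCatalog) -> ConsensusSequence:
    """Position-wise union of the sequences of every candidate allele.

    Both explicit ``/`` ambiguities and lower-than-full-resolution names
    contribute all matching catalog sequences; a position is ambiguous exactly
    where at least two contributing sequences disagree.
    """
    seqs, missing = [], []
    for cand in sorted(call.candidates, key=str):
        try:
            seqs.extend(catalog.sequences(cand))
        except CatalogLookupError:
            missing.append(str(cand))
    if missing:
        raise CatalogLookupError(
            f"allele(s) absent from catalog: {', '.join(missing)}"
        )
    return ConsensusSequence.from_sequences(seqs)


def deconstruct_genotypes(
    copy1: ConsensusSequence,
    copy2: ConsensusSequence,
    sites,
    sample_id: str = "",
) -> list:
    """Deconstruct a diploid pair of (consensus) allele sequences into per-site
    gold genotypes at the given 1-based CDS positions."""
    if len(copy1) != len(copy2):
        raise ValueError("chromosome copies have different CDS lengths")
    out = []
    for site in sites:
        if not 1 <= site <= len(copy1):
            raise ValueError(f"site {site} outside [1, {len(copy1)}]")
        out.append(
            SiteGenotype(
                (copy1.base_set(site), copy2.base_set(site)),
                site=site,
                sample_id=sample_id,
            )
        )
    return out
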