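"""Readers and writers for the pipeline's standard input/output formats.

* VCF (v4.x) for NGS genotypes, restricted on ingest to biallelic SNPs whose
  genomic positions fall inside configured ARS exons, with positions
  translated to CDS space (reverse-complementing alleles on minus-strand
  loci);
* gold typing TSV: ``sample_id  population  locus  allele1  allele2`` where an
  allele entry may be a ``/``-separated ambiguity list or a lower-resolution
  name;
* allele-catalog FASTA whose headers are allele names;
* exon-map JSON describing each locus (exons in coding order, strand, class,
  reference ARS sequence);
* per-base depth tables (``sample_id  chrom  pos  depth``, 1-based).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alleles import (
    AlleleCatalog,
    Exon,
    LocusSpec,
    cds_to_genomic,
    genomic_to_cds,
    parse_allele_name,
    reverse_complement,
)

GOLD_COLUMNS = ["sample_id", "population", "locus", "allele1", "allele2"]


# ---------------------------------------------------------------- exon map

def write_exon_map(path, loci) -> None:
    payload = {
        "loci": [
            {
                "locus_id": l.locus_id,
                "chrom": l.chrom,
                "strand": l.strand,
                "hla_class": l.hla_class,
                "exons": [
                    {"label": e.label, "start": e.start, "end": e.end}
                    for e in l.ars_exons
                ],
                "reference_ars_seq": l.reference_ars_seq,
            }
            for l in loci
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_exon_map(path) -> dict:
    """Returns ``{locus_id: LocusSpec}``; exons are listed in coding order."""
    payload = json.loads(Path(path).read_text())
    out = {}
    for entry in payload["loci"]:
        out[entry["locus_id"]] = LocusSpec(
            locus_id=entry["locus_id"],
            ars_exons=tuple(
                Exon(e["label"], int(e["start"]), int(e["end"]))
                for e in entry["exons"]
            ),
            strand=entry["strand"],
            reference_ars_seq=entry["reference_ars_seq"],
            hla_class=entry.get("hla_class", "I"),
            chrom=entry.get("chrom", "chr6"),
        )
    return out


# ----------------------------------------------------------------- catalog

def write_catalog_fasta(path, catalog: AlleleCatalog) -> None:
    records = [
        SeqRecord(Seq(seq), id=str(name), description="")
        for name, seq in sorted(catalog.items(), key=lambda kv: str(kv[0]))
    ]
    SeqIO.write(records, str(path), "fasta")


def read_catalog_fasta(path) -> AlleleCatalog:
    entries = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        entries[parse_allele_name(rec.id)] = str(rec.seq).upper()
    if not entries:
        raise ValueError(f"no sequences in catalog FASTA {path}")
    return AlleleCatalog(entries)


# -------------------------------------------------------------- gold table

def write_gold_table(path, gold: pd.DataFrame) -> None:
    gold[GOLD_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gold_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GOLD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gold table lacks column(s) {missing}")
    # samples without a population fall into "NA" and are excluded from
    # per-population (but not global) statistics downstream
    df["population"] = df["population"].fillna("NA")
    return df


# --------------------------------------------------------------------- VCF

@dataclass
class VcfData:
    """Biallelic ARS-exon SNPs in CDS space plus per-sample genotypes."""

    sites: pd.DataFrame        # locus, site, genomic_pos, ref, alt (CDS-space bases)
    genotypes: np.ndarray      # (n_samples, n_sites) ALT count, -1 missing
    samples: list
    skipped: dict              # reason -> count


def write_vcf(path, locus: LocusSpec, sites, ref_bases, alt_bases, genotypes, sample_ids):
    """Write CDS-space genotypes as a VCF v4.2 with genomic coordinates.

    ``genotypes`` is (n_samples, n_sites) with ALT-allele counts (-1 for
    missing).  On minus-strand loci REF/ALT are reverse-complemented into
    genomic space.
    """
    sites = np.asarray(sites)
    order = np.argsort([cds_to_genomic(locus, int(s)) for s in sites])
    gt_str = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    lines = [
        "##fileformat=VCFv4.2",
        "##source=refbias",
        f"##contig=<ID={locus.chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids),
    ]
    for j in order:
        site = int(sites[j])
        pos = cds_to_genomic(locus, site)
        ref, alt = ref_bases[j], alt_bases[j]
        if locus.strand == "-":
            ref, alt = reverse_complement(ref), reverse_complement(alt)
        gts = "\t".join(gt_str[int(g)] for g in genotypes[:, j])
        lines.append(
            f"{locus.chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_ars_sites(path, loci) -> VcfData:
    """Read a VCF, keeping biallelic SNPs inside the configured ARS exons.

    Positions are translated to 1-based CDS coordinates; on minus-strand loci
    REF/ALT bases are reverse-complemented into CDS space.  Indels,
    multiallelic records and out-of-exon records are skipped with counts.
    """
    if isinstance(loci, LocusSpec):
        loci = {loci.locus_id: loci}
    skipped = {"not_snp": 0, "multiallelic": 0, "outside_ars": 0, "malformed": 0}
    rows, geno_cols = [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if "GT" not in vcf.header.formats:
            raise ValueError(f"VCF {path} has no GT format field")
        for rec in vcf:
            try:
                alts = rec.alts or ()
                if len(alts) != 1:
                    skipped["multiallelic" if len(alts) > 1 else "malformed"] += 1
                    continue
                ref, alt = rec.ref.upper(), alts[0].upper()
                if len(ref) != 1 or len(alt) != 1 or {ref, alt} - set("ACGT"):
                    skipped["not_snp"] += 1
                    continue
                hit = None
                for locus in loci.values():
                    if locus.chrom != rec.chrom:
                        continue
                    cds = genomic_to_cds(locus, rec.pos)
                    if cds is not None:
                        hit = (locus, cds)
                        break
                if hit is None:
                    skipped["outside_ars"] += 1
                    continue
                locus, cds = hit
                if locus.strand == "-":
                    ref, alt = reverse_complement(ref), reverse_complement(alt)
                gts = np.full(len(samples), -1, dtype=np.int8)
                for i, s in enumerate(samples):
                    gt = rec.samples[s].get("GT")
                    if gt is None or any(a is None for a in gt):
                        continue
                    gts[i] = sum(1 for a in gt if a == 1)
                rows.append(
                    {
                        "locus": locus.locus_id,
                        "site": cds,
                        "genomic_pos": rec.pos,
                        "ref": ref,
                        "alt": alt,
                    }
                )
                geno_cols.append(gts)
            except (ValueError, KeyError):
                skipped["malformed"] += 1
    sites = pd.DataFrame(rows, columns=["locus", "site", "genomic_pos", "ref", "alt"])
    genotypes = (
        np.stack(geno_cols, axis=1) if geno_cols else np.zeros((len(samples), 0), np.int8)
    )
    if len(sites):
        order = sites.sort_values(["locus", "site"]).index.to_numpy()
        sites = sites.loc[order].reset_index(drop=True)
        genotypes = genotypes[:, order]
    return VcfData(sites=sites, genotypes=genotypes, samples=samples, skipped=skipped)


# ------------------------------------------------------------- depth table

def write_depth_table(path, locus: LocusSpec, sites, depth, sample_ids) -> None:
    """Per-site retained-read depth as a BED-like 1-based TSV."""
    sites = np.asarray(sites)
    gpos = np.array([cds_to_genomic(locus, int(s)) for s in sites])
    n, s = depth.shape
    df = pd.DataFrame(
        {
            "sample_id": np.repeat(sample_ids, s),
            "chrom": locus.chrom,
            "pos": np.tile(gpos, n),
            "depth": depth.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_depth_table(path, loci, one_based: bool = True) -> pd.DataFrame:
    """Read per-base depth; returns rows inside ARS exons with CDS sites.

    Columns out: ``sample_id, locus, site, depth``.  Positions are declared
    1-based by default; pass ``one_based=False`` for BED-style 0-based starts.
    """
    if isinstance(loci, LocusSpec):
        loci = {loci.locus_id: loci}
    df = pd.read_csv(path, sep="\t")
    need = {"sample_id", "chrom", "pos", "depth"}
    if not need <= set(df.columns):
        raise ValueError(f"depth table lacks column(s) {sorted(need - set(df.columns))}")
    pos = df["pos"].to_numpy(dtype=int) + (0 if one_based else 1)
    out = []
    for locus in loci.values():
        in_chrom = df["chrom"] == locus.chrom
        cds = np.array(
            [genomic_to_cds(locus, int(p)) if ok else None for p, ok in zip(pos, in_chrom)]
        )
        mask = cds != None  # noqa: E711  (None-aware elementwise comparison)
        sub = df.loc[mask, ["sample_id", "depth"]].copy()
        sub["locus"] = locus.locus_id
        sub["site"] = cds[mask].astype(int)
        out.append(sub[["sample_id", "locus", "site", "depth"]])
    if not out:
        return pd.DataFrame(columns=["sample_id", "locus", "site", "depth"])
    return pd.concat(out, ignore_index=True)
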