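import logging

import numpy as np
import pytest

from refbias.alleles import AlleleCatalog, Exon, LocusSpec
from refbias.simulate import FocalSite, SimConfig, simulate_bundle

logging.getLogger("refbias").setLevel(logging.ERROR)


@pytest.fixture
def toy_locus():
    """Plus-strand locus with two exons of 20 bp each (CDS length 40)."""
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
    return LocusSpec(
        locus_id="TOY",
        ars_exons=(Exon("exon2", 1001, 1020), Exon("exon3", 2001, 2020)),
        strand="+",
        reference_ars_seq=seq,
        hla_class="I",
        chrom="chrT",
    )


@pytest.fixture
def toy_catalog():
    """Four alleles over a 10-bp ARS; includes a 3-field pair sharing a
    2-field prefix (near-identical twins) for ambiguity handling."""
    base = "ACGTACGTAC"
    return AlleleCatalog(
        {
            "TOY*01:01": base,
            "TOY*01:02": base[:4] + "T" + base[5:],        # differs at pos 5 (A->T)
            "TOY*02:01:01": base[:2] + "T" + base[3:],     # differs at pos 3 (G->T)
            "TOY*02:01:02": base[:2] + "T" + base[3:8] + "G" + base[9:],  # +pos 9 (A->G)
        }
    )


@pytest.fixture(scope="session")
def small_bundle():
    """Small default-mechanism simulation reused across tests (biased)."""
    cfg = SimConfig(seed=11, n_alleles=512, n_populations=4, n_individuals=40)
    return simulate_bundle(cfg)


@pytest.fixture(scope="session")
def null_bundle():
    """Unbiased simulation: no mapping loss, no linked flanking variants."""
    base = SimConfig()
    focal = tuple(
        FocalSite(f.site, f.alt_fraction, 0) for f in base.focal_sites
    )
    cfg = SimConfig(
        seed=12,
        n_alleles=512,
        n_populations=4,
        n_individuals=40,
        mapping_loss=0.0,
        focal_sites=focal,
    )
    return simulate_bundle(cfg)
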