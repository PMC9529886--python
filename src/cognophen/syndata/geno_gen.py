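"""Gene-dropped pedigree genotypes and the case/control variant fixture."""

from __future__ import annotations

import numpy as np
import pandas as pd

from cognophen.errors import ConfigError
from cognophen.geno import GenotypeMatrix, Sample, VariantRecord
from cognophen.syndata.config import SimConfig


def _founder(rng: np.random.Generator, p: np.ndarray) -> np.ndarray:
    """Two allele rows (2, n_sites) drawn from per-site founder frequencies."""
    return (rng.random((2, p.size)) < p).astype(np.int8)


def _child(rng: np.random.Generator, mother: np.ndarray,
           father: np.ndarray) -> np.ndarray:
    """Mendelian gene dropping at unlinked sites."""
    n = mother.shape[1]
    mi = rng.integers(0, 2, n)
    fi = rng.integers(0, 2, n)
    return np.stack([mother[mi, np.arange(n)], father[fi, np.arange(n)]])


def gen_pedigree_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Gene-drop unlinked autosomal SNPs through a two-member pedigree.

    Founder allele frequencies are drawn per site from
    ``Uniform(*cfg.maf_law)``; alleles are dropped through the pedigree
    realizing ``cfg.relationship`` and the two focal individuals are
    returned as diploid 0/1/2 genotypes (samples ``P1`` and ``P2``).
    """
    if cfg.n_snps < 1:
        raise ConfigError("n_snps must be >= 1")
    rng = cfg.rng("pedigree")
    p = rng.uniform(cfg.maf_law[0], cfg.maf_law[1], cfg.n_snps)

    def F() -> np.ndarray:
        return _founder(rng, p)

    rel = cfg.relationship
    if rel == "duplicate":
        a = F()
        b = a
    elif rel == "unrelated":
        a, b = F(), F()
    elif rel == "parent_offspring":
        a = F()
        b = _child(rng, a, F())
    elif rel == "full_sib":
        m, f = F(), F()
        a, b = _child(rng, m, f), _child(rng, m, f)
    elif rel == "half_sib":
        shared = F()
        a, b = _child(rng, shared, F()), _child(rng, shared, F())
    elif rel == "first_cousin":
        gm, gf = F(), F()
        sib1, sib2 = _child(rng, gm, gf), _child(rng, gm, gf)
        a, b = _child(rng, sib1, F()), _child(rng, sib2, F())
    else:  # pragma: no cover - guarded by SimConfig
        raise ConfigError(f"unknown relationship {rel!r}")

    sites = pd.DataFrame({
        "chrom": np.repeat("1", cfg.n_snps),
        "pos": np.arange(1, cfg.n_snps + 1),
        "ref": "A",
        "alt": "G",
    })
    genotypes = np.stack([a.sum(axis=0), b.sum(axis=0)]).astype(np.int8)
    return GenotypeMatrix(
        samples=[Sample("P1"), Sample("P2")],
        sites=sites,
        genotypes=genotypes,
    )


# ---------------------------------------------------------------------------
# Case/control screening fixture
# ---------------------------------------------------------------------------

CASES = ("M593", "M639", "M344")
CONTROLS = ("M1486", "M1488", "M1140", "M1969")

# Published screening hits: genotypes of the three case animals and the
# population genotype counts (n = 1235 animals; 411 males for the X site).
# ref/alt bases for APOC1 and HTR2C are synthetic stand-ins consistent with
# the reported amino-acid changes; the MAP2 site is the reported A>G.
_HITS = [
    dict(gene="MAP2", chrom="12", pos=97_032_118, ref="A", alt="G",
         consequence={"NCBI-103": "missense", "Ensembl-104": "missense"},
         counts=dict(n_hom_alt=23, n_het=73, n_total=1235),
         genotypes={"M593": 2, "M639": 2, "M344": 1}),
    dict(gene="APOC1", chrom="19", pos=44_953_713, ref="C", alt="T",
         consequence={"NCBI-103": "missense", "Ensembl-104": "missense"},
         counts=dict(n_hom_alt=27, n_het=182, n_total=1235),
         genotypes={"M593": 1, "M639": 2, "M344": 1}),
    dict(gene="HTR2C", chrom="X", pos=111_431_585, ref="C", alt="T",
         consequence={"NCBI-103": "nonsense", "Ensembl-104": "synonymous"},
         counts=dict(n_hemi_alt=8, n_total=411),
         genotypes={"M593": 1, "M639": 1, "M344": 1}),
]

# Decoy variants, each constructed to fail exactly one screening filter.
_DECOYS = [
    dict(gene="DECOY_CTRL", chrom="2", pos=1_000_001, ref="G", alt="A",
         consequence={"NCBI-103": "missense", "Ensembl-104": "missense"},
         counts=dict(n_hom_alt=2, n_het=20, n_total=1235),
         genotypes={"M593": 1, "M639": 1, "M344": 1, "M1486": 1}),
    dict(gene="DECOY_CASES", chrom="3", pos=2_000_002, ref="T", alt="C",
         consequence={"NCBI-103": "missense", "Ensembl-104": "missense"},
         counts=dict(n_hom_alt=1, n_het=15, n_total=1235),
         genotypes={"M593": 1, "M639": 1}),  # M344 does not carry
    dict(gene="DECOY_PANEL", chrom="4", pos=3_000_003, ref="A", alt="T",
         consequence={"NCBI-103": "missense", "Ensembl-104": "missense"},
         panel_member=False,
         counts=dict(n_hom_alt=3, n_het=30, n_total=1235),
         genotypes={"M593": 1, "M639": 1, "M344": 1}),
    dict(gene="DECOY_SYN", chrom="5", pos=4_000_004, ref="C", alt="G",
         consequence={"NCBI-103": "synonymous", "Ensembl-104": "synonymous"},
         counts=dict(n_hom_alt=2, n_het=25, n_total=1235),
         genotypes={"M593": 2, "M639": 1, "M344": 1}),
    dict(gene="DECOY_COMMON", chrom="6", pos=5_000_005, ref="G", alt="C",
         consequence={"NCBI-103": "missense", "Ensembl-104": "missense"},
         counts=dict(n_hom_alt=100, n_het=300, n_total=1235),  # AF = 0.202
         genotypes={"M593": 1, "M639": 2, "M344": 1}),
]


def case_control_fixture(include_decoys: bool = True
                         ) -> tuple[GenotypeMatrix, list[VariantRecord]]:
    """Deterministic screening fixture: 7 male samples (3 cases, 4 controls),
    the three published case-shared variants with their printed genotypes
    and population counts, and decoy variants each failing exactly one
    screening filter. Controls carry reference alleles at every hit site;
    the HTR2C X-site is hemizygous (haploid) in all males.
    """
    specs = list(_HITS) + (list(_DECOYS) if include_decoys else [])
    samples = [Sample(n, sex="male", group="case") for n in CASES] + \
              [Sample(n, sex="male", group="control") for n in CONTROLS]
    names = [s.name for s in samples]

    sites = pd.DataFrame({
        "chrom": [s["chrom"] for s in specs],
        "pos": [s["pos"] for s in specs],
        "ref": [s["ref"] for s in specs],
        "alt": [s["alt"] for s in specs],
    })
    genotypes = np.zeros((len(samples), len(specs)), dtype=np.int8)
    variants: list[VariantRecord] = []
    for k, s in enumerate(specs):
        for name, g in s["genotypes"].items():
            genotypes[names.index(name), k] = g
        variants.append(VariantRecord(
            chrom=s["chrom"], pos=s["pos"], ref=s["ref"], alt=s["alt"],
            gene=s["gene"], consequence=s["consequence"],
            panel_member=s.get("panel_member", True),
            **s["counts"],
        ))
    gm = GenotypeMatrix(samples=samples, sites=sites, genotypes=genotypes)
    return gm, variants
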