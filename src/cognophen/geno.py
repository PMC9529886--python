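"""Kinship estimation and case/control rare-variant screening.

The kinship coefficient between two individuals is estimated with the
KING-robust between-family estimator from autosomal biallelic SNP genotypes:

    phi = (N_het,het - 2 * N_opp_hom) / (N_het(i) + N_het(j))

where N_het,het counts sites at which both individuals are heterozygous,
N_opp_hom counts opposite-homozygote sites, and N_het(.) counts each
individual's heterozygous sites over the shared (pairwise non-missing) site
set. Relationship degree follows the standard power-of-two bins
(phi ~ 0.25 full siblings, 0.125 second degree, 0.0625 first cousins).

Variant screening searches an annotated variant table for sites at which
every case carries at least one alternate allele, no control carries any,
the gene belongs to the neuropsychiatric panel, the consequence under the
chosen annotation model is loss-of-function or missense, and the population
alternate-allele frequency is below a threshold (default 10%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from cognophen.errors import DataError

MISSING = -1
X_CHROMS = {"X", "chrX", "x"}

LOSS_OF_FUNCTION = {"nonsense", "splice", "start_loss", "stop_loss"}

DEGREE_BINS = (
    (0.354, "duplicate"),
    (0.177, "1st-degree"),
    (0.0884, "2nd-degree"),
    (0.0442, "3rd-degree"),
)


@dataclass
class Sample:
    name: str
    sex: str = "male"          # male | female
    group: str = "population"  # case | control | population


@dataclass
class GenotypeMatrix:
    """Individuals x sites genotype codes with sample metadata.

    Genotypes are alternate-allele counts: 0/1/2 for diploid sites, 0/1 for
    hemizygous male-X sites, and −1 for missing. A diploid-coded hom-alt male
    X genotype (2) is normalized to haploid 1 on construction.
    """

    samples: list[Sample]
    sites: pd.DataFrame  # columns chrom, pos, ref, alt
    genotypes: np.ndarray  # (n_samples, n_sites) int8

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.sites)):
            raise DataError("genotype matrix shape mismatch")
        on_x = self.sites["chrom"].isin(X_CHROMS).to_numpy()
        for k, s in enumerate(self.samples):
            if s.sex == "male" and on_x.any():
                row = self.genotypes[k, on_x]
                if np.any(row == 2):
                    import warnings
                    warnings.warn(
                        f"sample {s.name}: diploid hom-alt code on male X "
                        "normalized to haploid"
                    )
                    row[row == 2] = 1
                    self.genotypes[k, on_x] = row

    def sample_index(self, name: str) -> int:
        for k, s in enumerate(self.samples):
            if s.name == name:
                return k
        raise DataError(f"sample {name!r} not present")

    def autosomal_mask(self) -> np.ndarray:
        return ~self.sites["chrom"].isin(X_CHROMS).to_numpy()


@dataclass
class VariantRecord:
    """One annotated variant with panel membership and population counts."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: dict[str, str]  # annotation-model name -> effect
    panel_member: bool = True
    n_hom_alt: int = 0
    n_het: int = 0
    n_hemi_alt: int = 0
    n_total: int = 0

    def __post_init__(self) -> None:
        if not self.consequence:
            raise DataError(f"{self.gene}:{self.pos}: no annotation model present")
        for c in (self.n_hom_alt, self.n_het, self.n_hemi_alt):
            if c > self.n_total:
                raise DataError(f"{self.gene}:{self.pos}: counts exceed n_total")

    @property
    def on_x(self) -> bool:
        return self.chrom in X_CHROMS


@dataclass
class KinshipEstimate:
    sample_i: str
    sample_j: str
    phi: float
    n_informative_sites: int
    degree: str


def _classify_degree(phi: float) -> str:
    for lo, name in DEGREE_BINS:
        if phi > lo:
            return name
    return "unrelated"


def king_kinship(g_i: np.ndarray, g_j: np.ndarray,
                 names: tuple[str, str] = ("i", "j")) -> KinshipEstimate:
    """KING-robust between-family kinship estimate from two genotype vectors.

    Vectors are autosomal diploid alternate-allele counts (0/1/2, −1
    missing); missing sites are dropped pairwise. Raises when neither
    individual has a heterozygous site (estimator undefined).
    """
    gi = np.asarray(g_i, dtype=int)
    gj = np.asarray(g_j, dtype=int)
    if gi.shape != gj.shape:
        raise DataError("genotype vectors differ in length")
    ok = (gi != MISSING) & (gj != MISSING)
    gi, gj = gi[ok], gj[ok]
    n_het_i = int(np.sum(gi == 1))
    n_het_j = int(np.sum(gj == 1))
    if n_het_i + n_het_j == 0:
        raise DataError("kinship undefined: no heterozygous sites in either sample")
    n_hh = int(np.sum((gi == 1) & (gj == 1)))
    n_opp = int(np.sum(((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))))
    phi = (n_hh - 2.0 * n_opp) / (n_het_i + n_het_j)
    return KinshipEstimate(names[0], names[1], float(phi), int(gi.size),
                           _classify_degree(phi))


def kinship_matrix(gm: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise KING-robust kinship over all samples, autosomal sites only."""
    mask = gm.autosomal_mask()
    rows = []
    for a in range(len(gm.samples)):
        for b in range(a + 1, len(gm.samples)):
            names = (gm.samples[a].name, gm.samples[b].name)
            try:
                est = king_kinship(gm.genotypes[a, mask], gm.genotypes[b, mask],
                                   names)
                rows.append({"sample_i": est.sample_i, "sample_j": est.sample_j,
                             "phi": est.phi, "n_sites": est.n_informative_sites,
                             "degree": est.degree})
            except DataError:  # no heterozygous sites in the pair
                rows.append({"sample_i": names[0], "sample_j": names[1],
                             "phi": float("nan"), "n_sites": int(mask.sum()),
                             "degree": "undefined"})
    return pd.DataFrame(rows)


def _round_half_up(x: float, ndigits: int = 1) -> float:
    factor = 10.0 ** ndigits
    return float(np.floor(x * factor + 0.5) / factor)


@dataclass
class VariantFrequencies:
    pct_hom: float
    pct_het: float
    pct_hemi: float
    allele_frequency: float


def variant_frequencies(v: VariantRecord) -> VariantFrequencies:
    """Carrier percentages (one decimal, round half-up) and allele frequency.

    Autosomes: AF = (2*n_hom_alt + n_het) / (2*n_total). X sites use the
    male hemizygote counts, each male contributing one allele, so
    AF = n_hemi_alt / n_total over the male population.
    """
    if v.n_total <= 0:
        raise DataError(f"{v.gene}:{v.pos}: zero population size")
    pct_hom = _round_half_up(100.0 * v.n_hom_alt / v.n_total)
    pct_het = _round_half_up(100.0 * v.n_het / v.n_total)
    pct_hemi = _round_half_up(100.0 * v.n_hemi_alt / v.n_total)
    if v.on_x:
        af = v.n_hemi_alt / v.n_total
    else:
        af = (2.0 * v.n_hom_alt + v.n_het) / (2.0 * v.n_total)
    return VariantFrequencies(pct_hom, pct_het, pct_hemi, float(af))


@dataclass
class ScreenResult:
    hits: list[VariantRecord]
    table: pd.DataFrame  # one row per variant with pass/fail detail


def _effect_class(effect: str) -> str:
    return "loss_of_function" if effect in LOSS_OF_FUNCTION else effect


def screen_variants(gm: GenotypeMatrix, variants: Sequence[VariantRecord],
                    cases: Sequence[str], controls: Sequence[str],
                    annotation_model: str,
                    af_max: float = 0.10,
                    effects: frozenset[str] = frozenset({"loss_of_function", "missense"}),
                    frequency_mode: str = "allele") -> ScreenResult:
    """Case-shared, control-absent rare-variant screen.

    A variant is a hit iff (1) every case carries at least one alternate
    allele (het, hom, or hemizygous), (2) no control carries any alternate
    allele, (3) the gene is on the neuropsychiatric panel, (4) its
    consequence under ``annotation_model`` falls in ``effects``
    (nonsense/splice/start-loss/stop-loss collapse to loss_of_function), and
    (5) its population alternate-allele frequency is below ``af_max``
    (``frequency_mode="carrier"`` filters on the total carrier rate
    instead). Hits whose effect class differs between stored annotation
    models are flagged ``model_dependent``.
    """
    models = set()
    for v in variants:
        models |= set(v.consequence)
    if annotation_model not in models:
        raise DataError(
            f"unknown annotation model {annotation_model!r}; available: {sorted(models)}"
        )
    case_idx = [gm.sample_index(s) for s in cases]
    control_idx = [gm.sample_index(s) for s in controls]

    site_key = {(c, p): k for k, (c, p) in
                enumerate(zip(gm.sites["chrom"], gm.sites["pos"]))}
    rows = []
    hits: list[VariantRecord] = []
    for v in variants:
        k = site_key.get((v.chrom, v.pos))
        if k is None:
            raise DataError(f"variant {v.gene}:{v.chrom}:{v.pos} absent from genotypes")
        g = gm.genotypes[:, k]
        all_cases_carry = all(g[i] >= 1 for i in case_idx)
        controls_clear = all(g[i] == 0 for i in control_idx)
        freqs = variant_frequencies(v)
        if frequency_mode == "allele":
            freq_value = freqs.allele_frequency
        elif frequency_mode == "carrier":
            freq_value = (v.n_hom_alt + v.n_het + v.n_hemi_alt) / v.n_total
        else:
            raise DataError(f"unknown frequency_mode {frequency_mode!r}")
        rare = freq_value < af_max
        effect = v.consequence.get(annotation_model, "other")
        effect_ok = _effect_class(effect) in effects
        classes = {m: _effect_class(e) in effects for m, e in v.consequence.items()}
        model_dependent = len(set(classes.values())) > 1

        failed = []
        if not all_cases_carry:
            failed.append("cases_not_shared")
        if not controls_clear:
            failed.append("control_carrier")
        if not v.panel_member:
            failed.append("off_panel")
        if not effect_ok:
            failed.append("consequence")
        if not rare:
            failed.append("common")
        is_hit = not failed
        if is_hit:
            hits.append(v)
        rows.append({
            "gene": v.gene, "chrom": v.chrom, "pos": v.pos,
            "effect": effect, "allele_frequency": freqs.allele_frequency,
            "hit": is_hit, "failed_filters": ",".join(failed),
            "model_dependent": model_dependent,
        })
    return ScreenResult(hits, pd.DataFrame(rows))


def private_variant_listing(gm: GenotypeMatrix, variants: Sequence[VariantRecord],
                            annotation_model: str,
                            samples: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-sample listing of carried loss-of-function variants (report shape)."""
    names = samples or [s.name for s in gm.samples]
    site_key = {(c, p): k for k, (c, p) in
                enumerate(zip(gm.sites["chrom"], gm.sites["pos"]))}
    rows = []
    for v in variants:
        if _effect_class(v.consequence.get(annotation_model, "other")) != "loss_of_function":
            continue
        k = site_key.get((v.chrom, v.pos))
        if k is None:
            continue
        for name in names:
            g = gm.genotypes[gm.sample_index(name), k]
            if g >= 1:
                rows.append({"sample": name, "gene": v.gene, "chrom": v.chrom,
                             "pos": v.pos, "genotype": int(g)})
    return pd.DataFrame(rows, columns=["sample", "gene", "chrom", "pos", "genotype"])
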