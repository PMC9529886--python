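"""Readers and writers for the pipeline's on-disk formats.

Trial tables travel as TSV, LFP arrays as HDF5 (``/lfp`` float array of
trials x contacts x samples with ``fs_hz`` and ``event_sample`` attributes),
genotypes as VCF v4.2 with a sample-metadata TSV, and configurations as
YAML.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from cognophen.geno import MISSING, X_CHROMS, GenotypeMatrix, Sample
from cognophen.lfp import LfpArray


def write_trials_tsv(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, sep="\t", index=False)


def read_trials_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_lfp_h5(lfp: LfpArray, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("lfp", data=lfp.data)
        d.attrs["fs_hz"] = lfp.fs_hz
        d.attrs["event_sample"] = lfp.event_sample
        d.attrs["alignment_event"] = lfp.alignment_event
        d.attrs["contact_spacing_um"] = lfp.contact_spacing_um


def read_lfp_h5(path: str | Path) -> LfpArray:
    with h5py.File(path, "r") as f:
        d = f["lfp"]
        return LfpArray(
            d[...],
            fs_hz=float(d.attrs["fs_hz"]),
            event_sample=int(d.attrs["event_sample"]),
            alignment_event=str(d.attrs.get("alignment_event", "event")),
            contact_spacing_um=float(d.attrs.get("contact_spacing_um", 200.0)),
        )


def write_config_yaml(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_config_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, path: str | Path,
              metadata_path: str | Path | None = None) -> None:
    """Write genotypes as VCF v4.2 with haploid GT on male-X sites, plus an
    optional sample-metadata TSV (sample, group, sex)."""
    names = [s.name for s in gm.samples]
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names),
    ]
    gt_diploid = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    gt_haploid = {0: "0", 1: "1", MISSING: "."}
    for k, site in gm.sites.reset_index(drop=True).iterrows():
        on_x = site["chrom"] in X_CHROMS
        gts = []
        for s_idx, s in enumerate(gm.samples):
            g = int(gm.genotypes[s_idx, k])
            if on_x and s.sex == "male":
                gts.append(gt_haploid.get(g, "."))
            else:
                gts.append(gt_diploid.get(g, "./."))
        lines.append(
            f"{site['chrom']}\t{site['pos']}\t.\t{site['ref']}\t{site['alt']}"
            f"\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")
    if metadata_path is not None:
        meta = pd.DataFrame(
            {"sample": names,
             "group": [s.group for s in gm.samples],
             "sex": [s.sex for s in gm.samples]}
        )
        meta.to_csv(metadata_path, sep="\t", index=False)


def read_vcf(path: str | Path,
             metadata_path: str | Path | None = None) -> GenotypeMatrix:
    """Read a VCF v4.2 with GT fields back into a :class:`GenotypeMatrix`
    (parsing via cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    names = list(vcf.samples)
    rows: list[dict] = []
    geno_rows: list[list[int]] = []
    for v in vcf:
        codes = []
        for gt in v.genotypes:  # [allele0, allele1, phased] or [allele, phased]
            alleles = [a for a in gt[:-1] if a is not None]
            alleles = [a for a in alleles if a >= -1]
            if any(a == -1 for a in alleles) or not alleles:
                codes.append(MISSING)
            else:
                codes.append(sum(int(a > 0) for a in alleles))
        rows.append({"chrom": v.CHROM, "pos": v.POS, "ref": v.REF,
                     "alt": v.ALT[0] if v.ALT else "."})
        geno_rows.append(codes)
    vcf.close()
    meta = {}
    if metadata_path is not None:
        mdf = pd.read_csv(metadata_path, sep="\t")
        meta = {r["sample"]: r for _, r in mdf.iterrows()}
    samples = [
        Sample(n,
               sex=meta.get(n, {}).get("sex", "male") if meta else "male",
               group=meta.get(n, {}).get("group", "population") if meta else "population")
        for n in names
    ]
    sites = pd.DataFrame(rows)
    genotypes = np.array(geno_rows, dtype=np.int8).T
    return GenotypeMatrix(samples=samples, sites=sites, genotypes=genotypes)
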