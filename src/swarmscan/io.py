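"""Plain-text interchange: VCF for genotypes, TSV for mosaics and tables.

The mosaic segment format is BED-like (chrom, start, end, haplotype index,
founder label) but deliberately uses 1-based inclusive coordinates to match
the VCF position convention; the header line says so.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synth import UNKNOWN, GenotypeMatrix, MosaicGenome

_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as a VCF v4.2 with diploid GT calls ('./.' for missing)."""
    path = Path(path)
    samples = list(genotypes.samples["individual_id"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for arm in genotypes.genome.arms:
            fh.write(f"##contig=<ID={arm.name},length={arm.length_bp}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        sites = genotypes.sites
        for j in range(len(sites)):
            row = sites.iloc[j]
            calls = "\t".join(_GT[int(d)] for d in genotypes.dosage[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['chrom']}:{row['pos']}\t"
                f"{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_vcf_dosage(path: str | Path) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    """Read a VCF into (sites, sample ids, dosage matrix) using cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    dosages = []
    for var in vcf:
        rows.append({"chrom": var.CHROM, "pos": var.POS, "ref": var.REF, "alt": var.ALT[0]})
        gts = var.genotypes  # [allele1, allele2, phased]
        dosages.append([a + b if a >= 0 and b >= 0 else -1 for a, b, *_ in gts])
    sites = pd.DataFrame(rows)
    return sites, samples, np.array(dosages, dtype=np.int8).T


MOSAIC_HEADER = "# coordinates are 1-based inclusive (start and end), not BED half-open"


def write_mosaics_tsv(mosaics: list[MosaicGenome], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(MOSAIC_HEADER + "\n")
        fh.write("individual_id\tgeneration\tpopulation\tsex\tchrom\thaplotype\tstart\tend\tfounder\n")
        for m in mosaics:
            for arm, haps in m.haplotypes.items():
                for h, hap in enumerate(haps):
                    for s, e, f in hap:
                        label = "UNKNOWN" if f == UNKNOWN else str(f)
                        fh.write(
                            f"{m.individual_id}\t{m.generation}\t{m.population}\t{m.sex}\t"
                            f"{arm}\t{h}\t{s}\t{e}\t{label}\n"
                        )


def read_mosaics_tsv(path: str | Path) -> list[MosaicGenome]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for ind, grp in df.groupby("individual_id", sort=False):
        haps: dict[str, list[list]] = {}
        for (arm, h), seg_grp in grp.groupby(["chrom", "haplotype"], sort=False):
            hap = [
                (int(s), int(e), UNKNOWN if f == "UNKNOWN" else int(f))
                for s, e, f in zip(seg_grp["start"], seg_grp["end"], seg_grp["founder"].astype(str))
            ]
            haps.setdefault(arm, [None, None])
            haps[arm][int(h)] = sorted(hap)
        haps = {arm: [h for h in v if h is not None] for arm, v in haps.items()}
        first = grp.iloc[0]
        out.append(
            MosaicGenome(
                individual_id=str(ind),
                generation=int(first["generation"]),
                population=str(first["population"]),
                sex=str(first["sex"]),
                haplotypes=haps,
            )
        )
    return out
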