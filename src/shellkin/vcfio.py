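"""Reading and writing genotype panels as VCF v4.2.

Writing is deliberately minimal and deterministic: biallelic SNPs, GT
mandatory, per-genotype DP optional, no timestamps in the header, so the
same matrix always produces byte-identical output.  Reading goes through
cyvcf2 and accepts any VCF with GT (DP picked up when present).
"""

from __future__ import annotations

import numpy as np

from .matrix import GenotypeMatrix

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path, depth: np.ndarray | None = None) -> None:
    """Write a genotype matrix as an uncompressed VCF v4.2 text file.

    ``depth`` is an optional int array of per-genotype read depths with the
    same shape as ``g.dosage``.
    """
    if depth is not None:
        depth = np.asarray(depth)
        if depth.shape != g.dosage.shape:
            raise ValueError("depth shape does not match genotype matrix")
    lines = [
        "##fileformat=VCFv4.2",
        "##source=shellkin",
        "##contig=<ID=1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if depth is not None:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if g.sample_ids:
        header += "\tFORMAT\t" + "\t".join(g.sample_ids)
    lines.append(header)
    fmt = "GT:DP" if depth is not None else "GT"
    for j, locus in enumerate(g.locus_ids):
        fields = ["1", str(1000 * (j + 1)), str(locus), "A", "C", ".", "PASS", "."]
        if g.sample_ids:
            fields.append(fmt)
        for i in range(g.n_samples):
            d = g.dosage[i, j]
            gt = "./." if np.isnan(d) else _GT[d]
            if depth is not None:
                gt = f"{gt}:{int(depth[i, j])}"
            fields.append(gt)
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path) -> tuple[GenotypeMatrix, np.ndarray | None]:
    """Load a biallelic-SNP VCF into a GenotypeMatrix (+ DP matrix if present)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    locus_ids: list[str] = []
    dosages: list[np.ndarray] = []
    depths: list[np.ndarray] = []
    has_dp = "DP" in {f for f in _format_ids(vcf)}
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"{v.CHROM}:{v.POS}: only biallelic records supported")
        row = np.full(len(samples), np.nan)
        for i, gt in enumerate(v.genotypes):
            a0, a1 = gt[0], gt[1]
            if a0 >= 0 and a1 >= 0:
                row[i] = a0 + a1
        dosages.append(row)
        locus_ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        if has_dp:
            dp = v.format("DP")
            if dp is None:
                depths.append(np.full(len(samples), np.nan))
            else:
                dp = dp.astype(float).reshape(-1)
                dp[dp < 0] = np.nan
                depths.append(dp)
    vcf.close()
    dosage = (
        np.array(dosages).T if dosages else np.empty((len(samples), 0))
    )
    g = GenotypeMatrix(samples, locus_ids, dosage)
    depth = np.array(depths).T if (has_dp and depths) else None
    return g, depth


def _format_ids(vcf) -> list[str]:
    ids = []
    for line in vcf.raw_header.splitlines():
        if line.startswith("##FORMAT=<ID="):
            ids.append(line.split("ID=")[1].split(",")[0])
    return ids
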