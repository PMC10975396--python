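"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as a minimal VCF (GT field, one sample per line) or as a
line x marker CSV of -1/0/1 codes; phenotypes, pedigrees, kernels and truth
tables are plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_vcf",
    "read_vcf_calls",
    "write_codes_csv",
    "read_codes_csv",
]


def write_vcf(calls: pd.DataFrame, meta: pd.DataFrame, path) -> None:
    """Write two-character allele calls as a minimal VCF (GT only).

    ``meta`` must carry ``chrom`` and ``pos`` per marker; ref is the major
    allele when recorded, otherwise the first allele observed.
    """
    path = Path(path)
    samples = list(calls.index)
    contigs = list(dict.fromkeys(meta["chrom"]))
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for j, marker in enumerate(calls.columns):
            col = calls[marker]
            alleles: list[str] = []
            for val in col:
                if isinstance(val, str) and len(val) == 2:
                    for a in val:
                        if a not in alleles:
                            alleles.append(a)
            if not alleles:
                continue
            ref = meta["major_allele"].get(marker, "") if "major_allele" in meta else ""
            if not ref:
                ref = alleles[0]
            alts = [a for a in alleles if a != ref] or ["."]
            pos = int(meta["pos"].get(marker, j + 1)) if "pos" in meta else j + 1
            allele_idx = {ref: 0, **{a: i + 1 for i, a in enumerate(alts)}}
            gts = []
            for val in col:
                if not isinstance(val, str) or len(val) != 2:
                    gts.append("./.")
                else:
                    gts.append(f"{allele_idx[val[0]]}/{allele_idx[val[1]]}")
            fh.write(
                f"{meta['chrom'].get(marker, '.')}\t{max(pos, 1)}\t{marker}\t"
                f"{ref}\t{','.join(alts)}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf_calls(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read GT calls from a VCF into a line x marker call table plus metadata.

    Uses cyvcf2 when importable, otherwise a plain-text fallback for
    uncompressed VCF.  Returns ``(calls, meta)`` with calls as two-character
    allele strings (NaN where missing).
    """
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover - cyvcf2 is normally available
        return _read_vcf_text(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, list] = {}
    meta_rows = []
    for var in vcf:
        alleles = [var.REF, *var.ALT]
        calls = []
        for g in var.genotypes:
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                calls.append(np.nan)
            else:
                pair = sorted((alleles[a], alleles[b]))
                calls.append(pair[0] + pair[1])
        marker = var.ID or f"{var.CHROM}_{var.POS}"
        cols[marker] = calls
        meta_rows.append(
            (marker, var.CHROM, var.POS,
             any(len(a) != 1 for a in alleles if a != "."))
        )
    calls = pd.DataFrame(cols, index=samples)
    meta = pd.DataFrame(
        meta_rows, columns=["marker", "chrom", "pos", "is_indel"]
    ).set_index("marker")
    return calls, meta


def _read_vcf_text(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    samples: list[str] = []
    cols: dict[str, list] = {}
    meta_rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            chrom, pos, marker, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            alleles = [ref, *alt.split(",")]
            calls = []
            for gt in parts[9:]:
                gt = gt.split(":")[0]
                sep = "/" if "/" in gt else "|"
                a, b = gt.split(sep)
                if a == "." or b == ".":
                    calls.append(np.nan)
                else:
                    pair = sorted((alleles[int(a)], alleles[int(b)]))
                    calls.append(pair[0] + pair[1])
            cols[marker] = calls
            meta_rows.append(
                (marker, chrom, pos, any(len(a) != 1 for a in alleles if a != "."))
            )
    calls = pd.DataFrame(cols, index=samples)
    meta = pd.DataFrame(
        meta_rows, columns=["marker", "chrom", "pos", "is_indel"]
    ).set_index("marker")
    return calls, meta


def write_codes_csv(codes: pd.DataFrame, path) -> None:
    codes.rename_axis("line").to_csv(path)


def read_codes_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
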