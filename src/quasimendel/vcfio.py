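"""Reading and writing the package's minimal VCF 4.2 dialect.

The dialect carries genotypes as ``GT:DP:GQ``, the site QC metrics as INFO
keys (QD, FS, MQ, MQRankSum, ReadPosRankSum, SOR, ExcessHet), and the VQSR
outcome in FILTER (``PASS`` or ``VQSRTrancheSNP90.00to99.00``).  Variants
are laid out on a synthetic contig in input order.  Writing is plain text
generation; reading goes through cyvcf2.  Every file opens with ``##source``
comment lines recording the tool version, seed and configuration hash, so a
run can be reproduced from its artifacts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import __version__
from .cohort_sim import MISSING, CallAnnotations, GenotypeMatrix

__all__ = ["write_vcf", "read_vcf", "validate_vcf", "VcfDiagnostic"]

_INFO_KEYS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR", "ExcessHet")
_FAIL_FILTER = "VQSRTrancheSNP90.00to99.00"
_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _header(sample_ids: list[str], seed: int | None, config_hash: str | None) -> list[str]:
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=quasimendel v{__version__}",
    ]
    if seed is not None:
        lines.append(f"##quasimendel_seed={seed}")
    if config_hash is not None:
        lines.append(f"##quasimendel_config_hash={config_hash}")
    lines += [
        '##contig=<ID=chrS,length=200000000>',
        '##FILTER=<ID=PASS,Description="Passed VQSR">',
        f'##FILTER=<ID={_FAIL_FILTER},Description="Failed VQSR tranche">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias (phred)">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank-sum">',
        '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank-sum">',
        '##INFO=<ID=SOR,Number=1,Type=Float,Description="Strand odds ratio">',
        '##INFO=<ID=ExcessHet,Number=1,Type=Float,Description="Phred-scaled heterozygote excess">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids),
    ]
    return lines


def write_vcf(path, g: GenotypeMatrix, ann: CallAnnotations | None = None,
              genes: dict[str, str] | None = None, seed: int | None = None,
              config_hash: str | None = None) -> None:
    """Write the matrix (and annotations, if given) as minimal VCF 4.2."""
    genes = genes or {v: v.split(":")[0] for v in g.variant_ids}
    lines = _header(list(g.sample_ids), seed, config_hash)
    for j, vid in enumerate(g.variant_ids):
        info = [f"GENE={genes.get(vid, '.')}"]
        filt = "PASS"
        if ann is not None:
            row = ann.site.iloc[j]
            for key in _INFO_KEYS:
                val = row[key]
                if pd.notna(val):
                    info.append(f"{key}={float(val):.4f}")
            filt = "PASS" if bool(row["vqsr_pass"]) else _FAIL_FILTER
        cells = []
        for i in range(g.n_samples):
            gt = _GT[int(g.dosages[i, j])]
            if ann is not None:
                cells.append(f"{gt}:{int(ann.dp[i, j])}:{int(ann.gq[i, j])}")
            else:
                cells.append(f"{gt}:.:.")
        lines.append(
            f"chrS\t{1000 * (j + 1)}\t{vid}\tA\tT\t.\t{filt}\t"
            + ";".join(info) + "\tGT:DP:GQ\t" + "\t".join(cells)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path) -> tuple[GenotypeMatrix, CallAnnotations, dict[str, str]]:
    """Read a dialect VCF back into matrix + annotations + gene map."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosages, dps, gqs, site_rows, vids = [], [], [], [], []
    genes: dict[str, str] = {}
    for var in vcf:
        vids.append(var.ID)
        genes[var.ID] = var.INFO.get("GENE", ".")
        # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.array(var.gt_types)
        dosages.append(np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], MISSING))
        dp = var.format("DP")
        gq = var.format("GQ")
        dps.append(np.zeros(len(samples), dtype=int) if dp is None else dp[:, 0].astype(int))
        gqs.append(np.zeros(len(samples), dtype=int) if gq is None else gq[:, 0].astype(int))
        row = {k: var.INFO.get(k, np.nan) for k in _INFO_KEYS}
        row["vqsr_pass"] = var.FILTER is None  # cyvcf2 reports PASS as None
        site_rows.append(row)
    vcf.close()
    g = GenotypeMatrix(np.array(dosages, dtype=np.int8).T, samples, vids)
    ann = CallAnnotations(
        dp=np.array(dps).T, gq=np.array(gqs).T,
        site=pd.DataFrame(site_rows, index=vids),
    )
    return g, ann, genes


class VcfDiagnostic(tuple):
    """(line number, message) pair; truthy like a tuple."""

    def __new__(cls, lineno: int, message: str):
        return super().__new__(cls, (lineno, message))

    @property
    def lineno(self) -> int:
        return self[0]

    @property
    def message(self) -> str:
        return self[1]


def validate_vcf(path) -> list[VcfDiagnostic]:
    """Line-level checks of the minimal dialect; returns violations.

    Checks: the fileformat line, column count against the sample header, the
    ``GT:DP:GQ`` FORMAT, presence of the required INFO keys, and the FILTER
    vocabulary.  Parse problems are reported with their line number.
    """
    problems: list[VcfDiagnostic] = []
    n_samples = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        return [VcfDiagnostic(1, "empty file")]
    if not lines[0].startswith("##fileformat=VCFv4.2"):
        problems.append(VcfDiagnostic(1, "missing ##fileformat=VCFv4.2 line"))
    for idx, line in enumerate(lines, start=1):
        if line.startswith("##"):
            continue
        if line.startswith("#CHROM"):
            cols = line.split("\t")
            if cols[:9] != ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL",
                           "FILTER", "INFO", "FORMAT"]:
                problems.append(VcfDiagnostic(idx, "malformed column header"))
            n_samples = len(cols) - 9
            continue
        if not line.strip():
            continue
        cols = line.split("\t")
        if n_samples is None:
            problems.append(VcfDiagnostic(idx, "data line before #CHROM header"))
            continue
        if len(cols) != 9 + n_samples:
            problems.append(
                VcfDiagnostic(idx, f"expected {9 + n_samples} columns, found {len(cols)}")
            )
            continue
        if cols[8] != "GT:DP:GQ":
            problems.append(VcfDiagnostic(idx, f"FORMAT must be GT:DP:GQ, found {cols[8]!r}"))
        if cols[6] not in ("PASS", _FAIL_FILTER):
            problems.append(VcfDiagnostic(idx, f"unknown FILTER value {cols[6]!r}"))
        info_keys = {kv.split("=", 1)[0] for kv in cols[7].split(";")}
        missing = [k for k in _INFO_KEYS if k not in info_keys]
        if missing and info_keys != {"GENE"}:  # bare matrices carry GENE only
            problems.append(VcfDiagnostic(idx, f"missing INFO key(s): {','.join(missing)}"))
        for s, cell in enumerate(cols[9:]):
            parts = cell.split(":")
            if len(parts) != 3:
                problems.append(
                    VcfDiagnostic(idx, f"sample {s + 1}: expected GT:DP:GQ cell, found {cell!r}")
                )
                break
    return problems


def write_truth_tsv(path, truth: pd.DataFrame, seed: int | None = None,
                    config_hash: str | None = None) -> None:
    """Phenotype/truth table as TSV with a reproducibility header comment."""
    with open(path, "w") as fh:
        fh.write(f"# quasimendel v{__version__} seed={seed} config={config_hash}\n")
        truth.to_csv(fh, sep="\t", index=False)
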