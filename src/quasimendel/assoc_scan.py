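"""Carrier-conditioned rare/low-frequency variant association scan.

Given an ascertained case cohort (index-variant heterozygotes) and a control
cohort, the scan selects nonsynonymous panel-gene variants whose control
allele frequency lies in a window (0.1-5% by default, the index variant
itself excluded), tests each with the exact allelic 2x2 test, applies a
Bonferroni family-wise threshold of alpha / n_tested, and renders a ranked
report plus quantile-quantile diagnostics.

Tests are allele-based: the 2x2 table counts alt and ref alleles (2n per
group, missing calls excluded from denominators).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_sim import GenotypeMatrix
from .exact_stats import Table2x2, bonferroni_threshold, fisher_test

__all__ = ["ScanConfig", "AssocRow", "select_variants", "scan", "qq_data", "report"]


@dataclass(frozen=True)
class ScanConfig:
    """Frequency window, panel, index-variant exclusion and alpha."""

    maf_low: float = 0.001
    maf_high: float = 0.05
    index_variant_id: str | None = None
    alpha: float = 0.05
    panel: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_low < self.maf_high < 0.5):
            raise ValueError(
                f"need 0 < maf_low < maf_high < 0.5, got ({self.maf_low}, {self.maf_high})"
            )
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        object.__setattr__(self, "panel", tuple(self.panel))


@dataclass(frozen=True)
class AssocRow:
    """One tested variant, shaped like a row of the published results table."""

    gene: str
    variant: str
    freq_cases: float
    freq_controls: float
    or_cmle: float
    ci_low: float
    ci_high: float
    p: float
    significant: bool


def select_variants(control_freqs: pd.DataFrame, cfg: ScanConfig) -> list[str]:
    """Variants passing the control-frequency window and panel filters.

    ``control_freqs`` needs columns ``variant``, ``gene`` and ``freq``; an
    optional boolean ``nonsynonymous`` column restricts to coding-changing
    variants (all retained when absent).  Window bounds are inclusive.
    """
    if not cfg.panel:
        raise ValueError("gene panel must be non-empty")
    df = control_freqs
    required = {"variant", "gene", "freq"}
    if not required.issubset(df.columns):
        raise ValueError(f"control frequency table needs columns {sorted(required)}")
    keep = (
        df["freq"].between(cfg.maf_low, cfg.maf_high, inclusive="both")
        & df["gene"].isin(cfg.panel)
    )
    if "nonsynonymous" in df.columns:
        keep &= df["nonsynonymous"].astype(bool)
    if cfg.index_variant_id is not None:
        keep &= df["variant"] != cfg.index_variant_id
    return df.loc[keep, "variant"].tolist()


def _allele_table(case_col: np.ndarray, ctrl_col: np.ndarray) -> Table2x2:
    case_obs = case_col >= 0
    ctrl_obs = ctrl_col >= 0
    a = int(case_col[case_obs].sum())
    b = int(2 * case_obs.sum() - a)
    c = int(ctrl_col[ctrl_obs].sum())
    d = int(2 * ctrl_obs.sum() - c)
    return Table2x2(a, b, c, d)


def scan(cases: GenotypeMatrix, controls: GenotypeMatrix, cfg: ScanConfig,
         control_freqs: pd.DataFrame | None = None,
         gene_of: dict[str, str] | None = None) -> list[AssocRow]:
    """Exact allelic test of every selected variant, ranked by p-value.

    Control frequencies default to those computed from the control matrix;
    ``gene_of`` maps variant id to gene symbol (defaults to the prefix before
    ``:`` in the variant id, the package's id convention).
    """
    if control_freqs is None:
        ac = controls.allele_counts()
        control_freqs = pd.DataFrame(
            {
                "variant": ac["variant"],
                "gene": [v.split(":")[0] for v in ac["variant"]],
                "freq": ac["freq"],
            }
        )
    selected = select_variants(control_freqs, cfg)
    if not selected:
        return []
    n_tested = len(selected)
    threshold = bonferroni_threshold(cfg.alpha, n_tested)
    lookup = gene_of or {v: v.split(":")[0] for v in selected}
    rows = []
    for vid in selected:
        t = _allele_table(cases.column(vid), controls.column(vid))
        res = fisher_test(t)
        rows.append(
            AssocRow(
                gene=lookup.get(vid, ""),
                variant=vid,
                freq_cases=t.a / (t.a + t.b),
                freq_controls=t.c / (t.c + t.d),
                or_cmle=res.or_cmle,
                ci_low=res.ci_low,
                ci_high=res.ci_high,
                p=res.p_two_sided,
                significant=res.p_two_sided < threshold,
            )
        )
    rows.sort(key=lambda r: (r.p, r.variant))
    return rows


def qq_data(pvals) -> tuple[np.ndarray, np.ndarray]:
    """Expected vs observed -log10 p pairs for a quantile-quantile plot.

    Expected quantiles use the (i - 0.5)/n plotting positions; both arrays
    are sorted ascending so matching indices pair expected with observed.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("p-value list must be non-empty")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    obs = np.sort(-np.log10(p))
    n = p.size
    exp = np.sort(-np.log10((np.arange(1, n + 1) - 0.5) / n))
    return exp, obs


def scan_frame(rows: list[AssocRow]) -> pd.DataFrame:
    """The scan result as a full-precision DataFrame."""
    return pd.DataFrame([r.__dict__ for r in rows])


def report(rows: list[AssocRow], top_k: int = 10) -> str:
    """Ranked top-``top_k`` table at the published precision.

    Frequencies with 3 decimals, OR and CI with 2, p in scientific notation,
    a trailing ``*`` marking rows below the Bonferroni threshold.
    """
    header = "Gene\tVariant\tFrequency in cases\tFrequency in controls\tOR\t95% CI (OR)\tp-value"
    lines = [header]
    for r in rows[:top_k]:
        orr = "inf" if np.isinf(r.or_cmle) else f"{r.or_cmle:.2f}"
        hi = "inf" if np.isinf(r.ci_high) else f"{r.ci_high:.2f}"
        star = "*" if r.significant else ""
        lines.append(
            f"{r.gene}\t{r.variant}\t{r.freq_cases:.3f}\t{r.freq_controls:.3f}"
            f"\t{orr}\t{r.ci_low:.2f}-{hi}\t{r.p:.1E}{star}"
        )
    return "\n".join(lines) + "\n"
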