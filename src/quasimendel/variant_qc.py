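"""Six-step genotype/site quality-control cascade with a per-rule audit trail.

The cascade mirrors a standard exome hard-filtering protocol, applied in a
fixed order:

1. mask individual calls with DP < 8 or GQ < 20;
2. exclude sites whose mean GQ (over surviving calls) is <= 35;
3. exclude sites with call rate <= 0.9 (computed after step 1);
4. exclude sites deviating from Hardy-Weinberg equilibrium at the
   Bonferroni-corrected exact-test level (divisor = polymorphic sites
   entering this step);
5. exclude sites failing the VQSR pass flag;
6. exclude sites failing any hard-filter threshold
   (QD >= 2, FS <= 60, MQ >= 40, MQRankSum >= -12.5, ReadPosRankSum >= -8,
   SOR <= 3, ExcessHet <= 20).

Inequality directions are applied literally: boundaries are inclusive for
keeping in steps 1 and 6, exclusionary in steps 2 and 3.  A site is charged
to the first rule it fails; missing (NaN) annotation values pass but are
flagged in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .cohort_sim import MISSING, CallAnnotations, GenotypeMatrix
from .exact_stats import HweCounts, hwe_exact

__all__ = ["QcThresholds", "QcReport", "mask_calls", "filter_sites", "run_qc"]

SITE_RULE_ORDER = ("mean_gq", "callrate", "hwe", "vqsr", "hard_filter")


@dataclass(frozen=True)
class QcThresholds:
    """Hard-filter thresholds; defaults follow the published protocol."""

    min_dp: int = 8
    min_gq: int = 20
    max_mean_gq_excl: float = 35.0
    max_callrate_excl: float = 0.9
    hwe_alpha: float = 0.05
    vqsr_required: bool = True
    min_qd: float = 2.0
    max_fs: float = 60.0
    min_mq: float = 40.0
    min_mqranksum: float = -12.5
    min_readposranksum: float = -8.0
    max_sor: float = 3.0
    max_excesshet: float = 20.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not np.isfinite(v):
                raise ValueError(f"threshold {f.name} must be finite")

    @classmethod
    def from_mapping(cls, overrides: dict | None) -> "QcThresholds":
        known = {f.name for f in fields(cls)}
        overrides = overrides or {}
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(f"unknown QC threshold(s): {sorted(unknown)}")
        return cls(**overrides)


@dataclass
class QcReport:
    """Per-rule removal log of one cascade run."""

    n_calls_masked: int = 0
    removed_sites: dict[str, list[str]] = field(default_factory=dict)
    surviving_sites: list[str] = field(default_factory=list)
    hwe_divisor: int = 0
    missing_annotation_sites: list[str] = field(default_factory=list)

    @property
    def n_removed_per_rule(self) -> dict[str, int]:
        return {rule: len(v) for rule, v in self.removed_sites.items()}

    @property
    def n_removed_total(self) -> int:
        return sum(len(v) for v in self.removed_sites.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"rule": rule, "site": site, "order": i + 2}
            for i, rule in enumerate(SITE_RULE_ORDER)
            for site in self.removed_sites.get(rule, [])
        ]
        return pd.DataFrame(rows, columns=["rule", "site", "order"])


def mask_calls(g: GenotypeMatrix, ann: CallAnnotations,
               thr: QcThresholds = QcThresholds()) -> tuple[GenotypeMatrix, int]:
    """Set calls with DP < min_dp or GQ < min_gq to missing.

    Returns the masked matrix and the number of newly masked calls.
    """
    if ann.dp.shape != g.dosages.shape:
        raise ValueError("annotation shape does not match genotype matrix")
    bad = (ann.dp < thr.min_dp) | (ann.gq < thr.min_gq)
    newly = bad & (g.dosages != MISSING)
    dosages = np.where(bad, MISSING, g.dosages).astype(np.int8)
    return (
        GenotypeMatrix(dosages, list(g.sample_ids), list(g.variant_ids)),
        int(newly.sum()),
    )


def filter_sites(g: GenotypeMatrix, ann: CallAnnotations,
                 thr: QcThresholds = QcThresholds()) -> tuple[GenotypeMatrix, QcReport]:
    """Apply site rules (2)-(6) in order to an already call-masked matrix.

    Each removed site is charged to the first rule it fails; the report also
    carries the Bonferroni divisor used for the Hardy-Weinberg rule and the
    sites whose rank-sum annotations were missing (treated as passing).
    """
    if len(ann.site) != g.n_variants:
        raise ValueError("site annotation length does not match genotype matrix")
    report = QcReport(removed_sites={r: [] for r in SITE_RULE_ORDER})
    d = g.dosages
    obs = d != MISSING
    vids = np.array(g.variant_ids)

    # (2) mean GQ over surviving calls; a site with no calls has mean 0
    gq_sum = np.where(obs, ann.gq, 0).sum(axis=0)
    n_obs = obs.sum(axis=0)
    mean_gq = np.divide(gq_sum, np.maximum(n_obs, 1), dtype=float)
    mean_gq[n_obs == 0] = 0.0
    alive = np.ones(g.n_variants, dtype=bool)
    fail = mean_gq <= thr.max_mean_gq_excl
    report.removed_sites["mean_gq"] = list(vids[fail])
    alive &= ~fail

    # (3) call rate on post-mask missingness
    callrate = n_obs / g.n_samples
    fail = alive & (callrate <= thr.max_callrate_excl)
    report.removed_sites["callrate"] = list(vids[fail])
    alive &= ~fail

    # (4) exact HWE on post-mask genotype counts; Bonferroni divisor =
    # polymorphic sites entering this step
    n_hom_ref = (np.where(obs, d, 9) == 0).sum(axis=0)
    n_het = (d == 1).sum(axis=0)
    n_hom_alt = (d == 2).sum(axis=0)
    entering = np.flatnonzero(alive)
    poly = [
        j for j in entering
        if n_obs[j] > 0 and 0 < (2 * n_hom_alt[j] + n_het[j]) < 2 * n_obs[j]
    ]
    report.hwe_divisor = len(poly)
    if poly:
        hwe_thr = thr.hwe_alpha / len(poly)
        for j in poly:
            p = hwe_exact(HweCounts(int(n_hom_ref[j]), int(n_het[j]), int(n_hom_alt[j])))
            if not (p > hwe_thr):
                report.removed_sites["hwe"].append(str(vids[j]))
                alive[j] = False

    # (5) VQSR pass flag
    if thr.vqsr_required:
        vq = ann.site["vqsr_pass"].to_numpy(dtype=bool)
        fail = alive & ~vq
        report.removed_sites["vqsr"] = list(vids[fail])
        alive &= ~fail

    # (6) hard filters; NaN annotations pass but are flagged
    s = ann.site
    checks = [
        (s["QD"].to_numpy(float) >= thr.min_qd),
        (s["FS"].to_numpy(float) <= thr.max_fs),
        (s["MQ"].to_numpy(float) >= thr.min_mq),
        (s["MQRankSum"].to_numpy(float) >= thr.min_mqranksum),
        (s["ReadPosRankSum"].to_numpy(float) >= thr.min_readposranksum),
        (s["SOR"].to_numpy(float) <= thr.max_sor),
        (s["ExcessHet"].to_numpy(float) <= thr.max_excesshet),
    ]
    nan_any = np.zeros(g.n_variants, dtype=bool)
    ok = np.ones(g.n_variants, dtype=bool)
    for arr, col in zip(checks, ("QD", "FS", "MQ", "MQRankSum",
                                 "ReadPosRankSum", "SOR", "ExcessHet")):
        vals = s[col].to_numpy(float)
        nan = np.isnan(vals)
        nan_any |= nan
        ok &= np.where(nan, True, arr)
    report.missing_annotation_sites = list(vids[alive & nan_any])
    fail = alive & ~ok
    report.removed_sites["hard_filter"] = list(vids[fail])
    alive &= ~fail

    report.n_calls_masked = 0
    report.surviving_sites = list(vids[alive])
    filtered = g.subset_variants(report.surviving_sites)
    return filtered, report


def run_qc(g: GenotypeMatrix, ann: CallAnnotations,
           thr: QcThresholds = QcThresholds()) -> tuple[GenotypeMatrix, QcReport]:
    """Full cascade: call masking (1) followed by site rules (2)-(6)."""
    masked, n_masked = mask_calls(g, ann, thr)
    filtered, report = filter_sites(masked, ann, thr)
    report.n_calls_masked = n_masked
    return filtered, report
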