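"""Synthetic cohort generator under a quasi-Mendelian load-threshold model.

The generator forward-simulates diploid genotypes at independent biallelic
loci under Hardy-Weinberg equilibrium, assigns affection status from a
mutational-load threshold rule, and builds ascertained case/control cohorts
by rejection sampling, so every downstream stage (QC, relatedness, carrier
screen, association scan) runs on data whose ground truth is known.

The load model: each allele has a severity weight ``w`` in [0, 1]; an
individual's load is the weighted sum of alt dosages over all loci, and the
individual is affected iff load >= threshold ``T``.  With the defaults
(severe nulls ``w = 1``, the frequent hypomorphic nonsense ``w = 0.5``,
``T = 1.5``) this reproduces every genotype-phenotype combination reported
for the RP1 alleles: biallelic severe genotypes (m1/m1, m1/m2, m1/m3) are
affected; the hypomorph alone — heterozygous or homozygous — is benign; a
hypomorph heterozygote plus one severe modifier allele elsewhere crosses the
threshold (non-Mendelian route).

Affection is deterministic given the genotype (full penetrance, no
phenocopies) unless a phenocopy rate is configured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exact_stats import HweCounts, excess_het_phred

__all__ = [
    "AlleleSpec",
    "PenetranceModel",
    "CohortConfig",
    "GenotypeMatrix",
    "CallAnnotations",
    "AscertainmentInfeasibleError",
    "MISSING",
    "sample_genotypes",
    "assign_phenotype",
    "simulate_cohort",
    "simulate_annotations",
    "default_loci",
    "PLANTED_DRIVER",
    "INDEX_VARIANT",
    "default_panel_genes",
]

#: Sentinel dosage for a missing genotype call.
MISSING = -1

ALLELE_CLASSES = ("severe_null", "hypomorph", "modifier", "neutral")

#: Index variant of the study: the frequent RP1 nonsense rs118031911/T.
INDEX_VARIANT = "RP1:c.5797C>T"


class AscertainmentInfeasibleError(RuntimeError):
    """No individual can satisfy the ascertainment predicate."""


@dataclass(frozen=True)
class AlleleSpec:
    """One biallelic variant: population frequency and severity weight."""

    id: str
    gene: str
    q: float
    w: float
    klass: str = "modifier"

    def __post_init__(self) -> None:
        if not (0.0 < self.q < 1.0):
            raise ValueError(f"{self.id}: allele frequency must lie in (0,1), got {self.q}")
        if not (0.0 <= self.w <= 1.0):
            raise ValueError(f"{self.id}: weight must lie in [0,1], got {self.w}")
        if self.klass not in ALLELE_CLASSES:
            raise ValueError(f"{self.id}: unknown allele class {self.klass!r}")
        if self.klass == "severe_null" and self.w != 1.0:
            raise ValueError(f"{self.id}: severe_null alleles must have weight 1.0")


@dataclass(frozen=True)
class PenetranceModel:
    """Threshold rule mapping diploid genotypes to affection status.

    Load is the dosage-weighted sum over all loci; dosage within one gene adds
    (compound heterozygosity for two severe alleles is equivalent to
    homozygosity for one).  ``phenocopy_rate`` adds genotype-independent
    affected individuals, off by default.
    """

    threshold: float = 1.5
    weights: dict[str, float] = field(default_factory=dict)
    phenocopy_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if not (0.0 <= self.phenocopy_rate < 1.0):
            raise ValueError("phenocopy rate must lie in [0, 1)")

    @classmethod
    def from_loci(cls, loci: list[AlleleSpec], threshold: float = 1.5,
                  phenocopy_rate: float = 0.0) -> "PenetranceModel":
        return cls(threshold, {s.id: s.w for s in loci}, phenocopy_rate)


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix (0/1/2, ``MISSING`` = -1)."""

    dosages: np.ndarray
    sample_ids: list[str]
    variant_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosage array must be 2-dimensional")
        if self.dosages.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError("dosage shape does not match id lists")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("variant ids must be unique")
        valid = np.isin(self.dosages, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing (-1)")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.col_index(variant_id)]

    def col_index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"unknown variant id {variant_id!r}") from None

    def allele_counts(self) -> pd.DataFrame:
        """Per-variant alt/ref allele counts and frequency, missing excluded."""
        d = self.dosages
        obs = d != MISSING
        alt = np.where(obs, d, 0).sum(axis=0)
        total = 2 * obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
        return pd.DataFrame(
            {"variant": self.variant_ids, "n_alt": alt, "n_alleles": total, "freq": freq}
        )

    def genotype_counts(self, variant_id: str) -> HweCounts:
        col = self.column(variant_id)
        return HweCounts(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )

    def subset_variants(self, variant_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.col_index(v) for v in variant_ids]
        return GenotypeMatrix(self.dosages[:, idx], list(self.sample_ids), list(variant_ids))


@dataclass
class CallAnnotations:
    """Per-call DP/GQ and per-site QC metrics for a GenotypeMatrix.

    ``site`` is indexed like the matrix columns, with columns QD, FS, MQ,
    MQRankSum, ReadPosRankSum, SOR, ExcessHet and vqsr_pass.  ``truth`` maps
    each QC rule to the call coordinates or site indices planted to fail it.
    """

    dp: np.ndarray
    gq: np.ndarray
    site: pd.DataFrame
    truth: dict[str, np.ndarray] = field(default_factory=dict)

    SITE_KEYS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR", "ExcessHet")

    def __post_init__(self) -> None:
        self.dp = np.asarray(self.dp)
        self.gq = np.asarray(self.gq)
        if self.dp.shape != self.gq.shape:
            raise ValueError("DP and GQ arrays must have the same shape")
        missing = [k for k in (*self.SITE_KEYS, "vqsr_pass") if k not in self.site.columns]
        if missing:
            raise ValueError(f"site annotation table lacks columns: {missing}")
        if len(self.site) != self.dp.shape[1]:
            raise ValueError("site table length does not match call matrix width")


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

_REAL_GENES = [
    "EYS", "USH2A", "RP1", "CRB1", "ABCA4", "RPGR", "CEP290", "PDZD7",
    "CC2D2A", "RPGRIP1L", "BBIP1", "RHO", "PRPH2", "RDH12", "CNGA1",
    "CNGB1", "PDE6A", "PDE6B", "RP2", "RPE65", "MERTK", "TULP1", "CRX",
    "NR2E3", "NRL", "SAG", "GUCY2D", "AIPL1", "CEP78", "ARL6", "BBS1",
    "BBS2", "BBS4", "BBS5", "BBS7", "BBS9", "BBS10", "BBS12", "MKKS", "TTC8",
]


def default_panel_genes(n: int = 228) -> list[str]:
    """A curated retinal-disease gene panel of ``n`` symbols.

    Real HRD gene symbols first, padded with synthetic RETG### placeholders —
    the panel is an input list in production use, this is its stand-in.
    """
    genes = list(_REAL_GENES)
    i = 1
    while len(genes) < n:
        sym = f"RETG{i:03d}"
        if sym not in genes:
            genes.append(sym)
        i += 1
    return genes[:n]


#: Id of the planted strong modifier (the EYS p.Gly843Glu analogue).
PLANTED_DRIVER = "EYS:c.2528G>A"


def default_loci(n_modifiers: int = 178, n_out_of_window: int = 12,
                 rng_seed: int = 20190628) -> list[AlleleSpec]:
    """The default locus panel emulating the study's variant landscape.

    * the three RP1 alleles: two severe nulls (m1-like Alu frameshift at
      q = 1e-3, m2-like frameshift at q = 5e-5) and the frequent hypomorphic
      nonsense (q = 6e-3, weight 0.5);
    * ``n_modifiers`` panel-gene modifier variants with control frequencies
      in the scan window [0.001, 0.05], spread over 84 genes.  The planted
      EYS-like driver (q = 0.017, weight 1.0) is the dominant single-variant
      route to affection in index-variant heterozygotes; two minor severe
      co-drivers (q = 0.002 and 0.004) mimic the other printed EYS hits; the
      remaining panel modifiers are near-neutral passengers (w = 0.02) that
      can only be enriched by chance;
    * ``n_background`` weight-0.34 hypomorphs in genes *outside* the curated
      panel (cumulative frequency ~0.53, so three alt alleles plus the index
      hypomorph cross the threshold).  They supply the residual oligogenic
      route that leaves most ascertained cases unexplained by any panel
      variant — the association scan never tests them, as in the study,
      where most index-carrier patients had no panel-gene explanation.  The
      route probabilities are calibrated so the planted driver explains ~1/4
      of ascertained cases, i.e. a case allele frequency near 0.125 against
      0.017 in controls;
    * a few out-of-window variants exercising the frequency filter.

    Frequencies of the non-driver modifiers are drawn log-uniformly inside
    the window from a fixed internal seed: the panel is a reproducible
    constant, not a per-run random object.
    """
    loci = [
        AlleleSpec("RP1:c.4052_4053ins328", "RP1", 1.0e-3, 1.0, "severe_null"),
        AlleleSpec("RP1:c.4196del", "RP1", 5.0e-5, 1.0, "severe_null"),
        AlleleSpec(INDEX_VARIANT, "RP1", 6.0e-3, 0.5, "hypomorph"),
    ]
    drivers = [
        (PLANTED_DRIVER, "EYS", 0.017),
        ("EYS:c.8805C>A", "EYS", 0.002),
        ("EYS:c.4957del", "EYS", 0.004),
    ]
    for vid, gene, q in drivers:
        loci.append(AlleleSpec(vid, gene, q, 1.0, "modifier"))
    rng = np.random.default_rng(rng_seed)
    genes = default_panel_genes()[:84]
    n_rest = n_modifiers - len(drivers)
    qs = np.exp(rng.uniform(np.log(1.1e-3), np.log(4.9e-2), size=n_rest))
    for i in range(n_rest):
        gene = genes[i % len(genes)]
        loci.append(AlleleSpec(f"{gene}:mod{i:03d}", gene, float(qs[i]), 0.02, "modifier"))
    # background hypomorphs outside the panel: three-hit alternative route
    # with P(>= 3 alleles) ~ 0.09 under Poisson(2 * 0.53)
    bq = np.exp(rng.uniform(np.log(2e-3), np.log(2e-2), size=68))
    bq *= 0.53 / bq.sum()
    for i, q in enumerate(bq):
        loci.append(AlleleSpec(f"EXG{i:03d}:hyp", f"EXG{i:03d}", float(q), 0.34, "modifier"))
    for i in range(n_out_of_window):
        q = 5e-4 if i % 2 == 0 else float(rng.uniform(0.055, 0.10))
        gene = genes[(i * 7) % len(genes)]
        loci.append(AlleleSpec(f"{gene}:oow{i:02d}", gene, q, 0.0, "neutral"))
    return loci


@dataclass(frozen=True)
class CohortConfig:
    """Cohort sizes, locus panel, penetrance model and ascertainment mode."""

    n_cases: int = 28
    n_controls: int = 3554
    loci: tuple[AlleleSpec, ...] = ()
    penetrance: PenetranceModel | None = None
    ascertainment: str = "affected_m3_het_no_other_rp1"
    seed: int = 0
    max_draws_per_case: int = 10_000_000

    ASCERTAINMENT_MODES = ("population", "affected", "affected_m3_het_no_other_rp1")

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("cohort sizes must be >= 1")
        if self.ascertainment not in self.ASCERTAINMENT_MODES:
            raise ValueError(f"unknown ascertainment mode {self.ascertainment!r}")
        loci = tuple(self.loci) if self.loci else tuple(default_loci())
        object.__setattr__(self, "loci", loci)
        if self.penetrance is None:
            object.__setattr__(self, "penetrance", PenetranceModel.from_loci(list(loci)))


# ---------------------------------------------------------------------------
# simulation operations
# ---------------------------------------------------------------------------

def sample_genotypes(loci: list[AlleleSpec], n: int,
                     seed: int | np.random.Generator = 0,
                     id_prefix: str = "S") -> GenotypeMatrix:
    """Draw ``n`` individuals with dosage ~ Binomial(2, q) per locus (HWE)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not loci:
        raise ValueError("locus list must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    qs = np.array([s.q for s in loci])
    dosages = rng.binomial(2, qs, size=(n, len(loci))).astype(np.int8)
    ids = [f"{id_prefix}{i:06d}" for i in range(n)]
    return GenotypeMatrix(dosages, ids, [s.id for s in loci])


def compute_load(g: GenotypeMatrix, m: PenetranceModel) -> np.ndarray:
    """Per-individual mutational load; missing calls contribute nothing."""
    try:
        w = np.array([m.weights[v] for v in g.variant_ids])
    except KeyError as e:
        raise KeyError(f"penetrance model lacks a weight for variant {e.args[0]!r}") from None
    d = np.where(g.dosages == MISSING, 0, g.dosages)
    return d @ w


def assign_phenotype(g: GenotypeMatrix, m: PenetranceModel,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Deterministic affection calls: affected iff load >= threshold.

    A small tolerance absorbs float round-off so a load summing exactly to
    the threshold counts as affected.  Phenocopies (if configured) are drawn
    independently of genotype and require ``rng``.
    """
    load = compute_load(g, m)
    affected = load >= m.threshold - 1e-9
    if m.phenocopy_rate > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        affected |= rng.random(g.n_samples) < m.phenocopy_rate
    return affected


def _predicate(cfg: CohortConfig, g: GenotypeMatrix, affected: np.ndarray) -> np.ndarray:
    if cfg.ascertainment == "population":
        return np.ones(g.n_samples, dtype=bool)
    if cfg.ascertainment == "affected":
        return affected
    # affected, heterozygous for the index hypomorph, no severe RP1 allele
    keep = affected & (g.column(INDEX_VARIANT) == 1)
    for spec in cfg.loci:
        if spec.klass == "severe_null" and spec.gene == "RP1":
            keep &= g.column(spec.id) == 0
    return keep


def _max_attainable_load(cfg: CohortConfig) -> float:
    """Largest load an individual satisfying the ascertainment predicate can carry."""
    total = 0.0
    for spec in cfg.loci:
        w = cfg.penetrance.weights.get(spec.id, spec.w)
        if cfg.ascertainment == "affected_m3_het_no_other_rp1":
            if spec.id == INDEX_VARIANT:
                total += w  # dosage fixed at 1
                continue
            if spec.klass == "severe_null" and spec.gene == "RP1":
                continue  # dosage fixed at 0
        total += 2 * w
    return total


def simulate_cohort(cfg: CohortConfig, batch_size: int = 20_000):
    """Rejection-sample an ascertained case cohort plus an unselected control cohort.

    Returns ``(cases, controls, truth)``: two GenotypeMatrix objects and a
    per-individual truth table (cohort, affected, load, contributing
    variants).  Reproducible given ``cfg.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    loci = list(cfg.loci)
    model = cfg.penetrance

    if cfg.ascertainment != "population" and cfg.penetrance.phenocopy_rate == 0:
        if _max_attainable_load(cfg) < model.threshold:
            raise AscertainmentInfeasibleError(
                "no genotype compatible with the ascertainment predicate can reach "
                f"the affection threshold {model.threshold}"
            )

    collected: list[np.ndarray] = []
    n_found = 0
    draws = 0
    cap = cfg.max_draws_per_case * cfg.n_cases
    while n_found < cfg.n_cases:
        if draws >= cap:
            raise AscertainmentInfeasibleError(
                f"ascertainment predicate not satisfied within {cap} draws"
            )
        batch = sample_genotypes(loci, batch_size, rng, id_prefix="tmp")
        draws += batch_size
        affected = assign_phenotype(batch, model, rng)
        keep = _predicate(cfg, batch, affected)
        if keep.any():
            collected.append(batch.dosages[keep])
            n_found += int(keep.sum())
    case_dosages = np.concatenate(collected)[: cfg.n_cases]
    cases = GenotypeMatrix(
        case_dosages, [f"CASE{i:04d}" for i in range(cfg.n_cases)], [s.id for s in loci]
    )
    controls = sample_genotypes(loci, cfg.n_controls, rng, id_prefix="CTRL")

    truth = _truth_table(cases, controls, model)
    return cases, controls, truth


def _truth_table(cases: GenotypeMatrix, controls: GenotypeMatrix,
                 model: PenetranceModel) -> pd.DataFrame:
    rows = []
    for cohort, g in (("case", cases), ("control", controls)):
        load = compute_load(g, model)
        affected = load >= model.threshold - 1e-9
        w = np.array([model.weights[v] for v in g.variant_ids])
        contrib = (np.where(g.dosages == MISSING, 0, g.dosages) * w) > 0
        vids = np.array(g.variant_ids)
        for i, sid in enumerate(g.sample_ids):
            rows.append(
                {
                    "sample": sid,
                    "cohort": cohort,
                    "affected": bool(affected[i]),
                    "load": float(load[i]),
                    "causal_variants": ",".join(vids[contrib[i]]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# QC annotation simulation
# ---------------------------------------------------------------------------

#: fail_rates keys understood by :func:`simulate_annotations`; call-level
#: rules act per call, site-level rules per variant.
CALL_RULES = ("dp", "gq")
SITE_RULES = ("mean_gq", "callrate", "vqsr", "qd", "fs", "mq",
              "mqranksum", "readposranksum", "sor")


def simulate_annotations(g: GenotypeMatrix, fail_rates: dict[str, float] | None = None,
                         seed: int | np.random.Generator = 0) -> CallAnnotations:
    """Draw DP/GQ and site metrics with planted, recorded QC failures.

    With all fail rates zero every call has DP >= 8 and GQ >= 20 and every
    site metric passes the hard-filter thresholds.  For each rule named in
    ``fail_rates`` a Binomial(rate) subset of calls (DP, GQ) or sites (the
    rest) is planted out of range and recorded in ``truth``.  ExcessHet is
    computed from the actual genotypes, not drawn, so heterozygote-excess
    sites fail honestly.
    """
    fail_rates = dict(fail_rates or {})
    unknown = set(fail_rates) - set(CALL_RULES) - set(SITE_RULES)
    if unknown:
        raise ValueError(f"unknown QC rule(s) in fail_rates: {sorted(unknown)}")
    for k, v in fail_rates.items():
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"fail rate for {k!r} must lie in [0,1], got {v}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, m = g.dosages.shape

    dp = 8 + rng.poisson(32.0, size=(n, m))
    gq = rng.integers(40, 100, size=(n, m))
    truth: dict[str, np.ndarray] = {}

    def site_mask(rule: str) -> np.ndarray:
        rate = fail_rates.get(rule, 0.0)
        mask = rng.random(m) < rate
        truth[rule] = np.flatnonzero(mask)
        return mask

    # site-level planting first, call-level after, so call-level truth is
    # never overwritten by whole-column draws.
    # mean-GQ failures: depress every call's GQ into [20, 35) so the site
    # fails rule (2) without tripping the per-call GQ < 20 mask
    mgq = site_mask("mean_gq")
    if mgq.any():
        gq[:, mgq] = rng.integers(20, 33, size=(n, int(mgq.sum())))
    # call-rate failures: push > 10% of the site's calls under the DP floor;
    # the affected calls are recorded separately (they are masked at rule 1)
    cr = site_mask("callrate")
    cr_calls = []
    for j in np.flatnonzero(cr):
        k = max(int(np.ceil(0.12 * n)), min(n, 2))
        rows = rng.choice(n, size=k, replace=False)
        dp[rows, j] = rng.integers(0, 8, size=k)
        cr_calls.extend((int(i), int(j)) for i in rows)
    truth["callrate_calls"] = np.array(cr_calls, dtype=int).reshape(-1, 2)

    def plant_calls(rule: str) -> np.ndarray:
        rate = fail_rates.get(rule, 0.0)
        mask = rng.random((n, m)) < rate
        truth[rule] = np.argwhere(mask)
        return mask

    mask = plant_calls("dp")
    dp[mask] = rng.integers(0, 8, size=int(mask.sum()))
    mask = plant_calls("gq")
    gq[mask] = rng.integers(0, 20, size=int(mask.sum()))

    site = pd.DataFrame(
        {
            "QD": rng.uniform(10.0, 35.0, m),
            "FS": rng.uniform(0.0, 10.0, m),
            "MQ": rng.uniform(55.0, 60.0, m),
            "MQRankSum": rng.uniform(-2.0, 2.0, m),
            "ReadPosRankSum": rng.uniform(-2.0, 2.0, m),
            "SOR": rng.uniform(0.2, 2.5, m),
            "vqsr_pass": np.ones(m, dtype=bool),
        },
        index=list(g.variant_ids),
    )
    fail_draws = {
        "qd": ("QD", lambda k: rng.uniform(0.0, 1.9, k)),
        "fs": ("FS", lambda k: rng.uniform(61.0, 200.0, k)),
        "mq": ("MQ", lambda k: rng.uniform(10.0, 39.0, k)),
        "mqranksum": ("MQRankSum", lambda k: rng.uniform(-20.0, -12.6, k)),
        "readposranksum": ("ReadPosRankSum", lambda k: rng.uniform(-20.0, -8.1, k)),
        "sor": ("SOR", lambda k: rng.uniform(3.1, 9.0, k)),
    }
    for rule, (colname, draw) in fail_draws.items():
        mask = site_mask(rule)
        if mask.any():
            site.loc[mask, colname] = draw(int(mask.sum()))
    vq = site_mask("vqsr")
    site.loc[vq, "vqsr_pass"] = False

    site["ExcessHet"] = [
        excess_het_phred(g.genotype_counts(v)) for v in g.variant_ids
    ]
    return CallAnnotations(dp=dp, gq=gq, site=site, truth=truth)
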