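"""Method-of-moments IBD estimation and PI_HAT relatedness screening.

Re-implements the classical IBS-based moment estimator popularised by PLINK's
``--genome``: for each pair, tally the sites sharing 0, 1 or 2 alleles
identical by state; compare the IBS-0 and IBS-1 counts with their
expectations under IBD state 0/1 (computed from sample allele frequencies
with the standard finite-sample correction terms); solve for the IBD-state
probabilities z0, z1, z2 in that order; clip to [0, 1], renormalise, and
report PI_HAT = z2 + z1/2.

Allele frequencies are estimated from the analysed sample itself, so a
small-sample bias is expected and accepted (documented in the methods note);
near-monomorphic sites (in-sample MAF below 1%) are dropped before
estimation because they carry no IBS information.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .cohort_sim import MISSING, GenotypeMatrix

__all__ = [
    "IbsCounts",
    "IbdEstimate",
    "ibs_counts",
    "expected_ibs_fractions",
    "moment_ibd",
    "relatedness_screen",
]


@dataclass(frozen=True)
class IbsCounts:
    """Counts of jointly genotyped sites sharing 0/1/2 alleles by state."""

    n_ibs0: int
    n_ibs1: int
    n_ibs2: int

    @property
    def total(self) -> int:
        return self.n_ibs0 + self.n_ibs1 + self.n_ibs2


@dataclass(frozen=True)
class IbdEstimate:
    """Estimated IBD-state probabilities and PI_HAT = z2 + z1/2."""

    z0: float
    z1: float
    z2: float

    @property
    def pi_hat(self) -> float:
        return self.z2 + 0.5 * self.z1


def ibs_counts(gi: np.ndarray, gj: np.ndarray) -> IbsCounts:
    """Tally IBS sharing between two dosage vectors, skipping missing calls.

    Per site IBS = 2 - |di - dj|, except opposite homozygotes (0 vs 2) which
    share no allele (IBS 0).
    """
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    if gi.shape != gj.shape:
        raise ValueError("genotype vectors must have equal length")
    obs = (gi != MISSING) & (gj != MISSING)
    di, dj = gi[obs].astype(int), gj[obs].astype(int)
    diff = np.abs(di - dj)
    ibs = 2 - diff  # diff 2 (opposite homozygotes) already maps to IBS 0
    return IbsCounts(
        int((ibs == 0).sum()), int((ibs == 1).sum()), int((ibs == 2).sum())
    )


def expected_ibs_fractions(freqs: np.ndarray, n_alleles: int) -> dict[str, float]:
    """Mean expected P(IBS = i | IBD = j) over sites, with finite-sample correction.

    ``n_alleles`` is the number of chromosomes the frequencies were estimated
    from (2 x sample size); the correction replaces powers of the frequency
    with without-replacement products, the convention of the standard tool.
    Returns means of e00, e10, e20, e11, e21 over sites (e22 = 1).
    """
    p = np.asarray(freqs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("site frequencies must lie strictly in (0, 1)")
    Na = float(n_alleles)
    if Na < 4:
        raise ValueError("need at least 4 sampled alleles for the correction terms")
    q = 1.0 - p
    x = 1.0 / Na
    c3 = Na**3 / ((Na - 1) * (Na - 2) * (Na - 3))
    c2 = Na**2 / ((Na - 1) * (Na - 2))
    e00 = 2 * p * p * q * q * ((p - x) * (q - x)) / (p * q) * c3
    e10 = (
        4 * p**3 * q * ((p - x) * (p - 2 * x)) / (p * p)
        + 4 * p * q**3 * ((q - x) * (q - 2 * x)) / (q * q)
    ) * c3
    e20 = (
        p**4 * ((p - x) * (p - 2 * x) * (p - 3 * x)) / (p**3)
        + q**4 * ((q - x) * (q - 2 * x) * (q - 3 * x)) / (q**3)
        + 4 * p * p * q * q * ((p - x) * (q - x)) / (p * q)
    ) * c3
    e11 = (2 * p * p * q * ((p - x) / p) + 2 * p * q * q * ((q - x) / q)) * c2
    e21 = (
        p**3 * ((p - x) * (p - 2 * x)) / (p * p)
        + q**3 * ((q - x) * (q - 2 * x)) / (q * q)
        + p * p * q * ((p - x) / p)
        + p * q * q * ((q - x) / q)
    ) * c2
    return {
        "e00": float(e00.mean()),
        "e10": float(e10.mean()),
        "e20": float(e20.mean()),
        "e11": float(e11.mean()),
        "e21": float(e21.mean()),
    }


def moment_ibd(c: IbsCounts, site_freqs: np.ndarray,
               n_alleles: int | None = None) -> IbdEstimate:
    """Moment estimator of IBD-state probabilities from IBS counts.

    ``site_freqs`` are the frequencies of the sites the counts were taken
    over; ``n_alleles`` is 2 x the number of individuals those frequencies
    were estimated from (a large-sample default is used when omitted, which
    disables most of the finite-sample correction).
    """
    if c.total == 0:
        raise ValueError("no jointly genotyped informative sites")
    freqs = np.asarray(site_freqs, dtype=float)
    if n_alleles is None:
        n_alleles = 2 * max(c.total, 4)
    e = expected_ibs_fractions(freqs, n_alleles)
    s = float(c.total)
    obs0, obs1 = c.n_ibs0 / s, c.n_ibs1 / s
    z0 = obs0 / e["e00"]
    z1 = (obs1 - z0 * e["e10"]) / e["e11"]
    z2 = 1.0 - z0 - z1
    # bound handling in the order of the classical implementation: a state
    # estimate above 1 takes everything; negatives are zeroed and the other
    # two states renormalised
    if z0 > 1:
        z0, z1, z2 = 1.0, 0.0, 0.0
    elif z1 > 1:
        z0, z1, z2 = 0.0, 1.0, 0.0
    elif z2 > 1:
        z0, z1, z2 = 0.0, 0.0, 1.0
    for neg in range(3):
        z = [z0, z1, z2]
        if z[neg] < 0:
            others = [z[i] for i in range(3) if i != neg]
            s = sum(others)
            scale = 1.0 / s if s > 0 else 0.0
            z = [v * scale for v in z]
            z[neg] = 0.0
            if s == 0:  # degenerate: fall back to the nearest pure state
                z[(neg + 1) % 3] = 1.0
            z0, z1, z2 = z
    return IbdEstimate(float(z0), float(z1), float(z2))


def relatedness_screen(g: GenotypeMatrix, threshold: float = 0.2,
                       min_maf: float = 0.01) -> pd.DataFrame:
    """PI_HAT for all pairs, sorted descending, pairs >= threshold flagged.

    Site frequencies come from the analysed matrix itself; sites with
    in-sample MAF below ``min_maf`` are dropped as uninformative.
    """
    if g.n_samples < 2:
        raise ValueError("need at least two individuals")
    ac = g.allele_counts()
    maf = np.minimum(ac["freq"], 1 - ac["freq"]).to_numpy()
    keep = np.flatnonzero((maf >= min_maf) & (ac["n_alleles"].to_numpy() > 0))
    if keep.size == 0:
        raise ValueError("no informative sites after the MAF filter")
    freqs = ac["freq"].to_numpy()[keep]
    sub = g.dosages[:, keep]
    n_alleles = 2 * g.n_samples
    rows = []
    for i, j in combinations(range(g.n_samples), 2):
        cnt = ibs_counts(sub[i], sub[j])
        est = moment_ibd(cnt, freqs, n_alleles)
        rows.append(
            {
                "id1": g.sample_ids[i],
                "id2": g.sample_ids[j],
                "z0": est.z0,
                "z1": est.z1,
                "z2": est.z2,
                "pi_hat": est.pi_hat,
                "flagged": est.pi_hat >= threshold,
            }
        )
    df = pd.DataFrame(rows).sort_values("pi_hat", ascending=False, kind="stable")
    return df.reset_index(drop=True)
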