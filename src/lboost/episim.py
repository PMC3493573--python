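"""Two-locus epistasis simulator under the liability threshold model.

Disease arises when a latent liability — the sum of a binary genetic factor
effect and a standard-normal residual — exceeds a threshold.  A two-locus
risk pattern ("prime implicant", PI) is carried with population probability
``p_pi`` determined by Hardy–Weinberg genotype frequencies and the
interaction model:

* dominant–dominant (DD): at least one minor allele at *both* loci,
  ``p_pi = (1 - (1 - maf)^2)^2``;
* recessive–recessive (RR): two minor-allele copies at both loci,
  ``p_pi = (maf^2)^2``.

Liability is standardized to unit total variance: the binary factor
contributes variance ``h2``, so its displacement is
``d = sqrt(h2 / (p(1-p)))`` with centered means (non-carriers at ``-p*d``,
carriers at ``(1-p)*d``), and the residual is normal with variance
``1 - h2``.  The threshold is the normal quantile ``Phi^{-1}(1 -
prevalence)`` of the (approximately standard normal) marginal liability;
penetrances ``f1 = P(D+|PI+)`` and ``f0 = P(D+|PI-)`` are the upper-tail
probabilities of each carrier group.  Because the marginal liability is a
normal mixture, not exactly normal, the implied marginal prevalence
``p*f1 + (1-p)*f0`` matches the nominal prevalence only to a few parts per
thousand — the approximation the threshold convention accepts.

Defaults follow a common-disease design: prevalence 0.1, h2 = 0.02 per
interaction, 100 biallelic SNPs with non-causal minor-allele frequencies
drawn uniformly from (0.05, 0.5), subjects sampled prospectively from the
population (so cases appear at roughly the prevalence rate).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .data import BinaryDataset

__all__ = [
    "DD",
    "RR",
    "Interaction",
    "EpistasisScenario",
    "LiabilitySolution",
    "pi_probability",
    "solve_liability",
    "prob_pi_given_disease",
    "simulate_dataset",
    "simulate_case_control",
]

DD = "DD"  # jointly dominant-dominant (Type 1)
RR = "RR"  # jointly recessive-recessive (Type 2)


def pi_probability(maf: float, model_type: str) -> float:
    """Population probability of carrying the two-locus risk pattern (HWE).

    DD requires at least one minor allele at both loci; RR requires two
    copies at both loci.  Both causal loci share the given MAF.
    """
    if not 0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    if model_type == DD:
        return (1.0 - (1.0 - maf) ** 2) ** 2
    if model_type == RR:
        return (maf**2) ** 2
    raise ValueError(f"unknown model type {model_type!r}")


@dataclass(frozen=True)
class LiabilitySolution:
    """Solved liability-threshold model for one binary risk factor."""

    p_pi: float
    prevalence: float
    h2: float
    displacement: float
    threshold: float
    f1: float  # P(D+ | PI+)
    f0: float  # P(D+ | PI-)
    odds_ratio: float  # inf when f1 = 1 at working precision

    def implied_h2(self) -> float:
        """Variance ratio recomputed from the penetrances, not the stored d.

        Inverts f1 and f0 back to the group displacement on the liability
        scale and returns its binary-factor variance — a consistency check
        that should reproduce the h2 the model was solved for.
        """
        if self.h2 == 0:
            return 0.0
        sigma = np.sqrt(1.0 - self.h2)
        d = sigma * (stats.norm.isf(self.f0) - stats.norm.isf(self.f1))
        return float(self.p_pi * (1.0 - self.p_pi) * d**2)

    def implied_prevalence(self) -> float:
        """Marginal disease probability implied by the penetrances."""
        return self.p_pi * self.f1 + (1.0 - self.p_pi) * self.f0


def _displacement(p_pi: float, h2: float) -> float:
    """Carrier/non-carrier liability shift giving the factor variance h2."""
    return np.sqrt(h2 / (p_pi * (1.0 - p_pi)))


def solve_liability(p_pi: float, prevalence: float, h2: float) -> LiabilitySolution:
    """Solve the liability threshold model for a single binary risk factor.

    Liability = centered binary factor (variance ``h2``) + normal residual
    (variance ``1 - h2``); the threshold is the standard-normal upper
    quantile of the prevalence, treating the marginal liability as N(0, 1).
    Penetrances are the upper-tail probabilities of the carrier and
    non-carrier groups.
    """
    if not 0 < p_pi < 1:
        raise ValueError("p_pi must be in (0, 1)")
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    if not 0 <= h2 < 1:
        raise ValueError("h2 must be in [0, 1)")
    if h2 > 0 and p_pi * (1.0 - p_pi) == 0.0:  # pragma: no cover - guarded above
        raise RuntimeError("h2 > 0 incompatible with a degenerate factor")

    d = _displacement(p_pi, h2) if h2 > 0 else 0.0
    mu1 = (1.0 - p_pi) * d
    mu0 = -p_pi * d
    sigma = np.sqrt(1.0 - h2)
    threshold = float(stats.norm.isf(prevalence))

    f1 = float(stats.norm.sf((threshold - mu1) / sigma))
    f0 = float(stats.norm.sf((threshold - mu0) / sigma))
    if f1 >= 1.0 - 1e-12 or f0 <= 0.0:
        odds_ratio = float("inf")
    else:
        odds_ratio = (f1 / (1.0 - f1)) / (f0 / (1.0 - f0))
    return LiabilitySolution(
        p_pi=p_pi,
        prevalence=prevalence,
        h2=h2,
        displacement=d,
        threshold=float(threshold),
        f1=f1,
        f0=f0,
        odds_ratio=odds_ratio,
    )


def prob_pi_given_disease(sol: LiabilitySolution) -> float:
    """P(PI+ | D+) by Bayes' rule: p_pi * f1 / prevalence."""
    return sol.p_pi * sol.f1 / sol.prevalence


# ---------------------------------------------------------------------------
# Scenarios and dataset simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Interaction:
    """One causal two-locus interaction: model type, shared MAF, locus columns."""

    model_type: str
    maf: float
    loci: tuple[int, int]

    def p_pi(self) -> float:
        return pi_probability(self.maf, self.model_type)


@dataclass(frozen=True)
class EpistasisScenario:
    """Simulation design: causal interactions plus background SNPs.

    ``coding`` selects the binary recoding applied to *every* SNP column:
    "dominant" (indicator of at least one minor allele) for DD studies,
    "recessive" (indicator of two copies) for RR studies.
    """

    interactions: tuple[Interaction, ...]
    prevalence: float = 0.1
    h2_per_interaction: float = 0.02
    p_total_snps: int = 100
    noise_maf_range: tuple[float, float] = (0.05, 0.5)
    coding: str = "dominant"

    def __post_init__(self) -> None:
        if self.coding not in ("dominant", "recessive"):
            raise ValueError("coding must be 'dominant' or 'recessive'")
        for inter in self.interactions:
            for locus in inter.loci:
                if not 0 <= locus < self.p_total_snps:
                    raise ValueError("causal locus index outside SNP panel")

    # -- presets for the three study designs --------------------------------

    @classmethod
    def one_dd(cls, maf: float) -> "EpistasisScenario":
        """A single dominant-dominant interaction on columns (0, 1)."""
        return cls(interactions=(Interaction(DD, maf, (0, 1)),), coding="dominant")

    @classmethod
    def two_dd(cls, maf_first: float, maf_second: float = 0.1) -> "EpistasisScenario":
        """Two independent DD interactions on columns (0, 1) and (2, 3)."""
        return cls(
            interactions=(
                Interaction(DD, maf_first, (0, 1)),
                Interaction(DD, maf_second, (2, 3)),
            ),
            coding="dominant",
        )

    @classmethod
    def one_rr(cls, maf: float) -> "EpistasisScenario":
        """A single recessive-recessive interaction on columns (0, 1)."""
        return cls(interactions=(Interaction(RR, maf, (0, 1)),), coding="recessive")

    def null(self) -> "EpistasisScenario":
        """Same design with the genetic effect removed (h2 = 0)."""
        return replace(self, h2_per_interaction=0.0)

    def true_pi_keys(self) -> list[str]:
        """Canonical keys of the causal PIs in the coded predictor matrix."""
        return [
            f"X{inter.loci[0] + 1}&X{inter.loci[1] + 1}" for inter in self.interactions
        ]


def simulate_dataset(
    scenario: EpistasisScenario, n: int, rng: np.random.Generator
) -> tuple[BinaryDataset, dict]:
    """Draw a prospective case-control SNP dataset under the scenario.

    Genotypes at every locus are independent HWE draws (minor-allele count
    ~ Binomial(2, maf)); each causal interaction contributes its centered
    liability displacement (variance ``h2`` per interaction, additively);
    the residual is normal with the complementary variance so total
    liability variance is 1, and disease is liability above
    ``Phi^{-1}(1 - prevalence)``.  All SNPs are then recoded by the
    scenario's binary coding.  Returns the dataset and a truth record with
    the causal PI keys and the per-interaction liability parameters.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p_total = scenario.p_total_snps

    mafs = rng.uniform(*scenario.noise_maf_range, size=p_total)
    for inter in scenario.interactions:
        mafs[list(inter.loci)] = inter.maf

    genotypes = rng.binomial(2, mafs, size=(n, p_total))

    p_list = [inter.p_pi() for inter in scenario.interactions]
    h2 = scenario.h2_per_interaction
    d_list = [_displacement(p, h2) if h2 > 0 else 0.0 for p in p_list]
    h2_total = h2 * len(p_list)
    if h2_total >= 1:
        raise ValueError("total heritability across interactions must be < 1")
    threshold = float(stats.norm.isf(scenario.prevalence))

    liability = np.sqrt(1.0 - h2_total) * rng.standard_normal(n)
    for inter, p_pi, d in zip(scenario.interactions, p_list, d_list):
        a, b = inter.loci
        if inter.model_type == DD:
            carrier = (genotypes[:, a] >= 1) & (genotypes[:, b] >= 1)
        else:
            carrier = (genotypes[:, a] == 2) & (genotypes[:, b] == 2)
        liability += (carrier - p_pi) * d
    y = (liability > threshold).astype(np.uint8)

    if scenario.coding == "dominant":
        X = (genotypes >= 1).astype(np.uint8)
    else:
        X = (genotypes == 2).astype(np.uint8)

    columns = [f"X{j + 1}" for j in range(p_total)]
    truth = {
        "pi_keys": scenario.true_pi_keys(),
        "threshold": threshold,
        "interactions": [
            {
                "model_type": inter.model_type,
                "maf": inter.maf,
                "loci": list(inter.loci),
                "p_pi": p_pi,
                "displacement": d,
            }
            for inter, p_pi, d in zip(scenario.interactions, p_list, d_list)
        ],
    }
    return BinaryDataset(X, y, columns=columns), truth


def simulate_case_control(
    scenario: EpistasisScenario, n: int, rng: np.random.Generator
) -> tuple[BinaryDataset, dict]:
    """Draw a balanced case-control sample of n subjects under the scenario.

    Subjects are drawn from the same population model as
    :func:`simulate_dataset` and retained until ``n//2`` cases and the
    remaining controls are collected (rejection sampling, so genotype
    frequencies are correctly disease-enriched among cases).  This is the
    sampling design of a matched case-control association study: at a
    disease prevalence well below one half, a prospective draw leaves the
    minority class too small for misclassification-scored trees to model,
    so recovery studies use this sampler.
    """
    if n < 2:
        raise ValueError("n must be >= 2 for a case-control sample")
    need = {1: n // 2, 0: n - n // 2}
    got = {1: 0, 0: 0}
    Xs, ys = [], []
    truth = None
    # expected draws per case = 1/prevalence; chunk accordingly
    chunk = max(int(np.ceil(n / scenario.prevalence / 2)), 1000)
    while got[1] < need[1] or got[0] < need[0]:
        data, truth = simulate_dataset(scenario, chunk, rng)
        for cls in (1, 0):
            idx = np.nonzero(data.y == cls)[0][: need[cls] - got[cls]]
            Xs.append(data.X[idx])
            ys.append(data.y[idx])
            got[cls] += len(idx)
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    perm = rng.permutation(n)
    dataset = BinaryDataset(X[perm], y[perm], columns=[f"X{j + 1}" for j in range(X.shape[1])])
    truth = dict(truth)
    truth["sampling"] = "case_control"
    return dataset, truth
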