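"""Recovery experiments: simulate, fit LBoost and Logic Forest, score top-20 recovery.

A causal interaction counts as *recovered* in one replicate when its
canonical PI key ranks among the 20 PIs with largest absolute importance
for the method.  Recovery proportions over replicates get Wilson 95%
confidence intervals (well behaved near 0 and 1, where Logic Forest's
rare-PI recovery lives).  Replicates use seeds derived from (seed,
replicate index) so results do not depend on execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .annealing import AnnealSchedule
from .boosting import fit_lboost
from .episim import EpistasisScenario, simulate_case_control, simulate_dataset
from .forest import fit_logic_forest, v_lf
from .importance import recovered, top_k_pis, v_lb

__all__ = ["ExperimentConfig", "RecoveryResult", "run_experiment", "wilson_ci"]


def wilson_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must be in [0, trials]")
    lo, hi = proportion_confint(successes, trials, alpha=1 - level, method="wilson")
    # the closed form hits 0 and 1 exactly at the boundary counts
    lo = 0.0 if lo < 1e-12 else float(lo)
    hi = 1.0 if hi > 1 - 1e-12 else float(hi)
    return lo, hi


@dataclass
class ExperimentConfig:
    """One recovery study: scenario, sample sizes, replicate count, methods."""

    scenario: EpistasisScenario
    n_values: tuple[int, ...] = (400, 800, 1200, 1600, 2000, 2400)
    n_sim: int = 500
    methods: tuple[str, ...] = ("lboost", "lf")
    K: int = 5
    A: int = 20
    max_size_cap: int = 8
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    top_k: int = 20
    sampling: str = "case_control"  # balanced draw; "population" for prospective
    seed: int = 0

    def __post_init__(self) -> None:
        for m in self.methods:
            if m not in ("lboost", "lf"):
                raise ValueError(f"unknown method {m!r}")
        if self.sampling not in ("case_control", "population"):
            raise ValueError(f"unknown sampling design {self.sampling!r}")
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")

    @property
    def n_trees(self) -> int:
        """Total trees per model; LF uses the same number for comparability."""
        return self.K * self.A


@dataclass
class RecoveryResult:
    """Aggregated recovery proportions plus the per-replicate log."""

    table: pd.DataFrame  # method, n, pi, recovered_count, n_sim, prop, ci_lo, ci_hi
    log: pd.DataFrame  # method, n, replicate, pi, recovered
    config: ExperimentConfig

    def proportion(self, method: str, n: int, pi: str) -> float:
        row = self.table[
            (self.table.method == method) & (self.table.n == n) & (self.table.pi == pi)
        ]
        if row.empty:
            raise KeyError((method, n, pi))
        return float(row["prop"].iloc[0])

    def plot(self, pi: str | None = None, ax=None):
        """Recovery-vs-n curves with CI error bars, one line per method."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tab = self.table if pi is None else self.table[self.table.pi == pi]
        for method, sub in tab.groupby("method"):
            sub = sub.sort_values("n")
            ax.errorbar(
                sub["n"],
                sub["prop"],
                yerr=[sub["prop"] - sub["ci_lo"], sub["ci_hi"] - sub["prop"]],
                marker="o",
                capsize=3,
                label=method,
            )
        ax.set_xlabel("sample size n")
        ax.set_ylabel("top-20 recovery proportion")
        ax.set_ylim(-0.02, 1.02)
        ax.legend()
        return ax


def _one_replicate(
    config: ExperimentConfig, n: int, rep: int
) -> list[tuple[str, int, int, str, bool]]:
    seed_seq = np.random.SeedSequence((config.seed, n, rep))
    rngs = {
        name: np.random.default_rng(s)
        for name, s in zip(("sim", "lboost", "lf", "imp"), seed_seq.spawn(4))
    }
    simulate = (
        simulate_case_control if config.sampling == "case_control" else simulate_dataset
    )
    data, truth = simulate(config.scenario, n, rngs["sim"])
    rows = []
    for method in config.methods:
        if method == "lboost":
            forest = fit_lboost(
                data.X,
                data.y,
                K=config.K,
                A=config.A,
                max_size_cap=config.max_size_cap,
                schedule=config.schedule,
                rng=rngs["lboost"],
            )
            table = v_lb(forest, data.X, data.y, rng=rngs["imp"])
        else:
            bagged = fit_logic_forest(
                data.X,
                data.y,
                B=config.n_trees,
                max_size_cap=config.max_size_cap,
                schedule=config.schedule,
                rng=rngs["lf"],
            )
            table = v_lf(bagged, data.X, data.y)
        top = top_k_pis(table, k=config.top_k) if len(table) else []
        for pi in truth["pi_keys"]:
            rows.append((method, n, rep, pi, recovered(pi, top)))
    return rows


def run_experiment(config: ExperimentConfig, n_jobs: int = 1) -> RecoveryResult:
    """Run the full replicate grid and aggregate recovery proportions.

    A failing replicate is recorded with a warning and excluded from the
    denominators, never silently dropped.
    """
    from joblib import Parallel, delayed

    jobs = [(n, rep) for n in config.n_values for rep in range(config.n_sim)]

    def safe(n: int, rep: int):
        try:
            return _one_replicate(config, n, rep)
        except Exception as exc:  # noqa: BLE001 - replicate isolation
            warnings.warn(f"replicate (n={n}, rep={rep}) failed: {exc}")
            return None

    if n_jobs == 1:
        results = [safe(n, rep) for n, rep in jobs]
    else:
        results = Parallel(n_jobs=n_jobs)(delayed(safe)(n, rep) for n, rep in jobs)

    log_rows = [row for res in results if res is not None for row in res]
    log = pd.DataFrame(
        log_rows, columns=["method", "n", "replicate", "pi", "recovered"]
    )

    agg_rows = []
    for (method, n, pi), sub in log.groupby(["method", "n", "pi"]):
        count = int(sub["recovered"].sum())
        trials = len(sub)
        prop = count / trials
        lo, hi = wilson_ci(count, trials)
        agg_rows.append((method, n, pi, count, trials, prop, lo, hi))
    table = pd.DataFrame(
        agg_rows,
        columns=["method", "n", "pi", "recovered_count", "n_sim", "prop", "ci_lo", "ci_hi"],
    )
    return RecoveryResult(table=table, log=log, config=config)
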