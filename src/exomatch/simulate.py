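"""Validation study for the case-only framework.

Each scenario generates synthetic per-gene LOF/MIS/SYN counts from
correlated negative-binomial marginals (NORTA / Gaussian copula), draws
gene-of-interest (GOI) labels from a logistic model on those counts with a
Gaussian disturbance on the linear predictor, assigns clusters of interest
on a fixed pre-computed gene partition, refits the case-only logistic
model on the COI universe, and summarizes the estimates across iterations.

Defaults encode the study conditions the framework was validated under:
class means from the observed exome totals (2,328 LOF / 31,015 MIS /
46,046 SYN over 19,108 genes), the 3x3 count correlation matrix with
off-diagonals 0.166 / 0.257 / 0.688 (LOF-MIS / LOF-SYN / MIS-SYN), three
effect vectors (intercept, LOF, MIS, SYN) = (-3, 0.75, 0.05, 0.1),
(-5, 1.25, 0.1, 0.2), (-7, 1.75, 0.2, 0.3), and disturbance SDs spanning
0.55-1.45.  The null model regenerates the counts after the response is
drawn, breaking the response-predictor dependence so any detected signal
is a false positive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .association import TERMS, fit_logistic
from .cluster import ClusterPartition
from .norta import NegativeBinomialMarginal, NortaGenerator
from .variants import CLASSES, GeneVariantCounts

logger = logging.getLogger(__name__)

__all__ = [
    "NBMarginal",
    "SimulationScenario",
    "SimulationSummary",
    "EXOME_GENE_COUNT",
    "EXOME_CLASS_TOTALS",
    "DEFAULT_CLASS_MEANS",
    "DEFAULT_DISPERSION",
    "COUNT_CORRELATIONS",
    "BETA_GRID",
    "ERROR_SD_GRID",
    "fit_nb_marginals",
    "simulate_correlated_counts",
    "simulate_response",
    "run_scenario",
    "default_scenarios",
]

#: An NB marginal is fully specified by mean and dispersion (size):
#: variance = mean + mean**2 / dispersion.
NBMarginal = NegativeBinomialMarginal

#: Observed exome reference frame: qualifying-variant totals per class over
#: the canonical gene universe.
EXOME_GENE_COUNT = 19_108
EXOME_CLASS_TOTALS = {"lof": 2_328, "mis": 31_015, "syn": 46_046}
#: Per-gene class means implied by the totals.
DEFAULT_CLASS_MEANS = {c: t / EXOME_GENE_COUNT for c, t in EXOME_CLASS_TOTALS.items()}
#: Default NB size: moderate overdispersion, shared by all three classes.
DEFAULT_DISPERSION = 1.5

#: Target Pearson correlations among the three count classes
#: (order lof, mis, syn).
COUNT_CORRELATIONS = np.array(
    [
        [1.000, 0.166, 0.257],
        [0.166, 1.000, 0.688],
        [0.257, 0.688, 1.000],
    ]
)

#: Effect grids for the true-effect scenarios: (b0, bLOF, bMIS, bSYN) on the
#: log-odds scale, crossed with the disturbance SD levels.
BETA_GRID = (
    (-3.0, 0.75, 0.05, 0.10),
    (-5.0, 1.25, 0.10, 0.20),
    (-7.0, 1.75, 0.20, 0.30),
)
ERROR_SD_GRID = (0.55, 1.00, 1.45)


def default_marginals() -> dict[str, NBMarginal]:
    return {
        c: NBMarginal(DEFAULT_CLASS_MEANS[c], DEFAULT_DISPERSION) for c in CLASSES
    }


def fit_nb_marginals(counts: GeneVariantCounts) -> dict[str, NBMarginal]:
    """Fit a negative-binomial marginal per consequence class.

    Method-of-moments start, refined by maximum likelihood (the NB mean MLE
    is the sample mean; the size is profiled out by 1-D optimization).
    Equidispersed or underdispersed classes fall back to the Poisson limit
    (dispersion = inf) with a warning; an all-zero class is an error.
    """
    if len(counts.frame) < 2:
        raise ValueError("need counts for at least 2 genes")
    out: dict[str, NBMarginal] = {}
    for c in CLASSES:
        x = counts.frame[c].to_numpy(dtype=np.float64)
        m, v = x.mean(), x.var(ddof=1)
        if m == 0.0:
            raise ValueError(f"class {c!r} has all-zero counts; cannot fit a marginal")
        if v <= m:
            logger.warning(
                "fit_nb_marginals: class %r is not overdispersed "
                "(var %.4g <= mean %.4g); using the Poisson limit", c, v, m,
            )
            out[c] = NBMarginal(m, math.inf)
            continue
        size0 = m * m / (v - m)

        def nll(log_size):
            k = math.exp(log_size)
            return -stats.nbinom.logpmf(x, k, k / (k + m)).sum()

        res = optimize.minimize_scalar(
            nll, bracket=(math.log(size0) - 1.0, math.log(size0) + 1.0)
        )
        out[c] = NBMarginal(m, float(math.exp(res.x)))
    return out


def _count_generator(
    marginals: dict[str, NBMarginal] | None = None,
    target: np.ndarray | None = None,
) -> NortaGenerator:
    marginals = marginals or default_marginals()
    target = COUNT_CORRELATIONS if target is None else np.asarray(target, float)
    return NortaGenerator([marginals[c] for c in CLASSES], target)


def simulate_correlated_counts(
    p: int,
    marginals: dict[str, NBMarginal] | None = None,
    target: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    genes=None,
) -> GeneVariantCounts:
    """Draw ``p`` genes' worth of correlated LOF/MIS/SYN counts.

    NORTA generation: trivariate normal with calibrated intermediate
    correlations, mapped through the normal CDF and the class NB quantile
    functions.  Deterministic given ``seed``.
    """
    gen = _count_generator(marginals, target)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = gen.sample(p, rng).astype(np.int64)
    if genes is None:
        width = max(5, len(str(p)))
        genes = [f"G{i:0{width}d}" for i in range(1, p + 1)]
    return GeneVariantCounts.from_matrix(genes, values)


def simulate_response(
    counts: GeneVariantCounts | np.ndarray,
    betas,
    error_sd: float,
    seed: int | np.random.Generator = 0,
):
    """GOI probabilities and labels from a logit model with Gaussian error.

    eta = b0 + bLOF*LOF + bMIS*MIS + bSYN*SYN + eps, eps ~ N(0, error_sd^2);
    probability = expit(eta); status ~ Bernoulli(probability).
    Returns ``(probability, status)`` arrays.
    """
    betas = np.asarray(betas, dtype=np.float64)
    if betas.shape != (4,):
        raise ValueError("betas must be (intercept, lof, mis, syn)")
    if error_sd < 0:
        raise ValueError("error_sd must be >= 0")
    if isinstance(counts, GeneVariantCounts):
        x = counts.frame[list(CLASSES)].to_numpy(dtype=np.float64)
    else:
        x = np.asarray(counts, dtype=np.float64)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eta = betas[0] + x @ betas[1:]
    if error_sd > 0:
        eta = eta + rng.normal(0.0, error_sd, size=len(x))
    prob = expit(eta)
    status = (rng.random(len(x)) < prob).astype(np.int64)
    return prob, status


@dataclass(frozen=True)
class SimulationScenario:
    """One parameterization of the validation study."""

    betas: tuple[float, float, float, float]
    error_sd: float
    n_iter: int = 1000
    seed: int = 0
    null_model: bool = False
    count_corr: tuple[tuple[float, ...], ...] = tuple(map(tuple, COUNT_CORRELATIONS))
    marginal_means: tuple[float, float, float] = tuple(
        DEFAULT_CLASS_MEANS[c] for c in CLASSES
    )
    dispersion: float = DEFAULT_DISPERSION
    name: str = ""

    def __post_init__(self):
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.error_sd < 0:
            raise ValueError("error_sd must be >= 0")

    def marginals(self) -> dict[str, NBMarginal]:
        return {
            c: NBMarginal(m, self.dispersion)
            for c, m in zip(CLASSES, self.marginal_means)
        }

    @property
    def label(self) -> str:
        tag = "null" if self.null_model else "effect"
        return self.name or (
            f"{tag}_b0={self.betas[0]:g}_sd={self.error_sd:g}"
        )


@dataclass
class SimulationSummary:
    """Across-iteration summaries of one scenario (converged fits only)."""

    scenario: SimulationScenario
    estimates: pd.DataFrame  # one row per converged iteration
    n_converged: int
    n_skipped: int
    n_not_converged: int
    goi_counts: np.ndarray = field(default_factory=lambda: np.array([]))
    coi_sizes: np.ndarray = field(default_factory=lambda: np.array([]))

    def term_summary(self) -> pd.DataFrame:
        """Mean estimate, SE of that mean, SD of estimates, mean z and
        |z|>1.96 rejection rate per model term."""
        rows = []
        true = {
            "intercept": self.scenario.betas[0],
            "lof": self.scenario.betas[1],
            "mis": self.scenario.betas[2],
            "syn": self.scenario.betas[3],
        }
        for t in TERMS:
            est = self.estimates[f"est_{t}"].to_numpy()
            z = self.estimates[f"z_{t}"].to_numpy()
            sd = est.std(ddof=1) if len(est) > 1 else float("nan")
            rows.append(
                {
                    "term": t,
                    "true_beta": 0.0 if self.scenario.null_model and t != "intercept" else true[t],
                    "mean_estimate": est.mean() if len(est) else float("nan"),
                    "sd_estimate": sd,
                    "se_mean": sd / math.sqrt(len(est)) if len(est) > 1 else float("nan"),
                    "mean_z": z.mean() if len(z) else float("nan"),
                    "rejection_rate": float(np.mean(np.abs(z) > 1.959964)) if len(z) else float("nan"),
                }
            )
        return pd.DataFrame(rows)

    def as_frame(self) -> pd.DataFrame:
        """Flat one-row-per-term summary including GOI/COI size ranges."""
        frame = self.term_summary()
        frame.insert(0, "scenario", self.scenario.label)
        for name, arr in (("goi", self.goi_counts), ("coi", self.coi_sizes)):
            frame[f"min_{name}"] = arr.min() if len(arr) else float("nan")
            frame[f"max_{name}"] = arr.max() if len(arr) else float("nan")
            frame[f"med_{name}"] = float(np.median(arr)) if len(arr) else float("nan")
        frame["n_converged"] = self.n_converged
        frame["n_skipped"] = self.n_skipped
        frame["n_not_converged"] = self.n_not_converged
        return frame


def run_scenario(
    scenario: SimulationScenario, partition: ClusterPartition
) -> SimulationSummary:
    """Run all iterations of one scenario on a fixed gene partition.

    Simulated genes are mapped 1:1 onto the clustered universe in order.
    Per iteration: draw counts, draw the response (for the null model the
    counts are then re-drawn from a fresh stream, decoupling predictors
    from the response), flag clusters containing >= 1 simulated GOI as
    COIs, and fit the case-only logistic model over the COI membership.
    Iterations with zero GOIs or zero controls are skipped and counted;
    summaries cover converged fits only.
    """
    p = len(partition.genes)
    labels = np.asarray(partition.labels)
    gen = _count_generator(scenario.marginals(), np.asarray(scenario.count_corr))
    gen._cholesky()  # calibrate once up front
    betas = np.asarray(scenario.betas)

    records = []
    goi_counts, coi_sizes = [], []
    n_skipped = n_not_converged = 0
    children = np.random.SeedSequence(scenario.seed).spawn(scenario.n_iter)
    for it, child in enumerate(children):
        rng = np.random.default_rng(child)
        counts = gen.sample(p, rng)
        _, status = simulate_response(counts, betas, scenario.error_sd, rng)
        if scenario.null_model:
            # re-generate the predictors after the response: null by design
            counts = gen.sample(p, rng)
        n_goi = int(status.sum())
        if n_goi == 0 or n_goi == p:
            n_skipped += 1
            continue
        coi_labels = np.unique(labels[status == 1])
        in_coi = np.isin(labels, coi_labels)
        y = status[in_coi].astype(np.float64)
        if y.sum() == len(y):  # no control genes in any COI
            n_skipped += 1
            continue
        X = np.column_stack([np.ones(int(in_coi.sum())), counts[in_coi]])
        beta_hat, se, converged, _, _ = fit_logistic(X, y)
        goi_counts.append(n_goi)
        coi_sizes.append(int(in_coi.sum()))
        if not converged:
            n_not_converged += 1
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta_hat / se
        rec = {"iteration": it}
        for j, t in enumerate(TERMS):
            rec[f"est_{t}"] = beta_hat[j]
            rec[f"z_{t}"] = z[j]
        records.append(rec)
    estimates = pd.DataFrame(
        records,
        columns=["iteration"] + [f"{k}_{t}" for t in TERMS for k in ("est", "z")],
    )
    return SimulationSummary(
        scenario=scenario,
        estimates=estimates,
        n_converged=len(records),
        n_skipped=n_skipped,
        n_not_converged=n_not_converged,
        goi_counts=np.asarray(goi_counts),
        coi_sizes=np.asarray(coi_sizes),
    )


def default_scenarios(
    seed: int,
    n_iter: int = 1000,
    include_null: bool = True,
) -> list[SimulationScenario]:
    """The 3x3 true-effect grid (betas x disturbance SDs) plus one null.

    The null scenario reuses the first grid cell's parameters so its count
    and response distributions match a true-effect scenario while the
    dependence between them is severed.  Per-scenario seeds are spawned
    from the master seed.
    """
    n = len(BETA_GRID) * len(ERROR_SD_GRID) + (1 if include_null else 0)
    children = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    scenarios = []
    i = 0
    for betas in BETA_GRID:
        for sd in ERROR_SD_GRID:
            scenarios.append(
                SimulationScenario(
                    betas=betas, error_sd=sd, n_iter=n_iter, seed=int(children[i])
                )
            )
            i += 1
    if include_null:
        scenarios.append(
            SimulationScenario(
                betas=BETA_GRID[0],
                error_sd=ERROR_SD_GRID[0],
                n_iter=n_iter,
                seed=int(children[i]),
                null_model=True,
            )
        )
    return scenarios
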