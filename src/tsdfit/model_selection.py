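"""Goodness of fit by deviance and model / dataset comparison by AICc and BIC.

Deviance is twice the log-likelihood gap between the saturated model (one
observed proportion per listed group) and the fitted model. Its chi-squared
reference distribution is asymptotic and unreliable at the small counts
typical of sex-ratio studies, so a parametric-bootstrap alternative is
provided: null datasets are simulated from the fitted reaction norm with the
observed design (same temperatures, same eggs per temperature), refit, and
their deviances compared with the observed one.

Sample-size conventions (empirically the ones that make the two criteria
consistent with each other on pooled incubation data):

* AICc uses n = number of incubation groups as listed;
* the grouped-vs-separated BIC comparison uses n = number of *distinct*
  temperatures (pooled-distinct for the grouped hypothesis, sum of
  per-dataset distinct counts for the separated one).

Both are exposed through explicit arguments rather than hidden defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import TSDDataset, merge_duplicate_temperatures
from .mle_fit import FitError, FitResult, binomial_neg_ln_L, fit_mle, neg_log_likelihood
from .reaction_norms import sex_ratio
from .synthetic_data import SimulationDesign, simulate_dataset

__all__ = [
    "GOFResult",
    "SelectionTable",
    "BICComparison",
    "saturated_ln_L",
    "deviance_gof",
    "null_deviance_test",
    "information_criteria",
    "grouped_vs_separated",
]


@dataclass
class GOFResult:
    """Deviance-based goodness of fit for one fitted model."""

    deviance: float
    df: int
    p_chi2: float
    p_random: float | None = None
    null_deviances: np.ndarray | None = None
    n_rep: int | None = None
    n_failed: int = 0
    seed: int | None = None


@dataclass
class SelectionTable:
    """Per-model AICc comparison on one dataset."""

    table: pd.DataFrame
    n_for_aicc: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


@dataclass
class BICComparison:
    """Grouped-vs-separated dataset comparison under BIC."""

    grouped: dict
    separated: dict
    per_dataset: list[dict] = field(default_factory=list)

    @property
    def delta(self) -> float:
        return self.separated["BIC"] - self.grouped["BIC"]

    @property
    def w_values(self) -> dict:
        """BIC weights of the two hypotheses (they sum to 1)."""
        b = np.array([self.grouped["BIC"], self.separated["BIC"]])
        w = np.exp(-(b - b.min()) / 2.0)
        w /= w.sum()
        return {"grouped": float(w[0]), "separated": float(w[1])}

    def to_frame(self) -> pd.DataFrame:
        w = self.w_values
        return pd.DataFrame(
            [
                {"hypothesis": "grouped", **self.grouped, "w-value": w["grouped"]},
                {"hypothesis": "separated", **self.separated, "w-value": w["separated"]},
            ]
        ).set_index("hypothesis")


def saturated_ln_L(ds: TSDDataset) -> float:
    """ln L of the saturated model: observed proportion per listed group.

    Groups with no sexed embryos are skipped; an all-male or all-female group
    contributes only its (zero) binomial-coefficient term.
    """
    M = np.array([g.males for g in ds.groups if g.n_sexed > 0], float)
    F = np.array([g.females for g in ds.groups if g.n_sexed > 0], float)
    with np.errstate(invalid="ignore"):
        p = M / (M + F)
    return -binomial_neg_ln_L(p, M, F)


def deviance_gof(fit: FitResult, ds: TSDDataset) -> GOFResult:
    """Deviance, degrees of freedom and the chi-squared tail probability.

    df = (number of listed groups) - (number of model parameters); raises
    when the model is over-parameterized for the dataset.
    """
    ln_L_S = saturated_ln_L(ds)
    ln_L_M = -neg_log_likelihood(ds, fit.params)
    D = 2.0 * (ln_L_S - ln_L_M)
    df = len(ds) - fit.params.n_params
    if df < 0:
        raise ValueError(f"over-parameterized: {len(ds)} groups for {fit.params.n_params} parameters")
    p = float(stats.chi2.sf(D, df)) if df > 0 else (1.0 if D <= 1e-12 else 0.0)
    return GOFResult(deviance=float(D), df=df, p_chi2=p)


def null_deviance_test(
    fit: FitResult,
    ds: TSDDataset,
    n_rep: int = 1000,
    seed: int | None = None,
) -> GOFResult:
    """Parametric-bootstrap deviance test.

    Each replicate redraws the male count of every group from a binomial with
    the observed group size and the fitted sex ratio, refits the same model
    family (seeded at the fitted parameters), and records the replicate
    deviance. ``p_random`` is the fraction of null deviances greater than or
    equal to the observed deviance. Replicates whose refit fails are logged
    and excluded; more than 10% failures triggers a warning.
    """
    base = deviance_gof(fit, ds)
    t = np.array([g.temperature for g in ds.groups], float)
    n_eggs = [g.n_sexed for g in ds.groups]
    root = np.random.default_rng(seed)
    child_seeds = root.integers(0, 2**31 - 1, size=n_rep)
    null_devs = []
    n_failed = 0
    for s in child_seeds:
        design = SimulationDesign(
            temperatures=list(t),
            eggs_per_temperature=n_eggs,
            truth=fit.params,
            seed=int(s),
        )
        sim = simulate_dataset(design)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # replicate-level diagnostics unused
                refit = fit_mle(
                    sim,
                    fit.params.family,
                    init=fit.params,
                    compute_covariance=False,
                    multi_start=False,
                )
            null_devs.append(deviance_gof(refit, sim).deviance)
        except (FitError, ValueError):
            n_failed += 1
    if n_failed > 0.1 * n_rep:
        warnings.warn(
            f"{n_failed}/{n_rep} null-deviance replicates failed to refit", stacklevel=2
        )
    null_devs = np.asarray(null_devs)
    p_random = float((null_devs >= base.deviance).mean()) if null_devs.size else np.nan
    return GOFResult(
        deviance=base.deviance,
        df=base.df,
        p_chi2=base.p_chi2,
        p_random=p_random,
        null_deviances=null_devs,
        n_rep=n_rep,
        n_failed=n_failed,
        seed=seed,
    )


def information_criteria(
    fits: list[FitResult],
    labels: list[str] | None = None,
    n: int | None = None,
) -> SelectionTable:
    """AIC / AICc / Akaike-weight table for models fitted to the same dataset.

    ``n`` is the AICc sample size; it defaults to the number of incubation
    groups as listed in the (shared) dataset. Weights are
    ``exp(-ΔAICc/2)`` normalized over the candidate set; two models with
    equal AICc therefore share the weight equally.
    """
    if not fits:
        raise ValueError("no fits to compare")
    group_counts = {f.n_groups for f in fits}
    if len(group_counts) > 1:
        raise ValueError("fits being compared must come from the same dataset")
    n = fits[0].n_groups if n is None else n
    labels = labels if labels is not None else [f.params.family for f in fits]
    rows = []
    for lab, f in zip(labels, fits):
        p = f.params.n_params
        aicc = f.aicc(n)
        if not np.isfinite(aicc):
            warnings.warn(
                f"AICc undefined for model {lab!r} (n - p - 1 <= 0); using AIC value",
                stacklevel=2,
            )
        rows.append({"model": lab, "p": p, "-lnL": f.neg_ln_L, "AIC": f.aic, "AICc": aicc})
    table = pd.DataFrame(rows).set_index("model")
    table["dAICc"] = table["AICc"] - table["AICc"].min()
    w = np.exp(-table["dAICc"].to_numpy() / 2.0)
    table["Akaike weight"] = w / w.sum()
    return SelectionTable(table=table, n_for_aicc=n)


def _distinct_n(ds: TSDDataset, tolerance: float) -> int:
    return len(merge_duplicate_temperatures(ds, tolerance).groups)


def grouped_vs_separated(
    datasets: list[TSDDataset],
    family: str = "logistic",
    n_convention: str = "distinct_temperatures",
    merge_tolerance: float = 0.0,
) -> BICComparison:
    """BIC test of a single shared reaction norm versus one per dataset.

    The grouped hypothesis pools all datasets and fits p parameters; the
    separated hypothesis fits each dataset on its own (k·p parameters, -ln L
    summed). Under the default ``distinct_temperatures`` convention the BIC
    sample size is the number of distinct temperatures of the pooled data for
    the grouped hypothesis and the sum of per-dataset distinct counts for the
    separated one; ``n_convention="groups"`` uses listed group counts
    instead. Any failing separate fit aborts the comparison with a report of
    which dataset failed.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets to compare")
    if n_convention not in ("distinct_temperatures", "groups"):
        raise ValueError(f"unknown n_convention {n_convention!r}")

    pooled = TSDDataset(
        [g for ds in datasets for g in ds.groups],
        label=" + ".join(ds.label for ds in datasets),
    )
    fit_grouped = fit_mle(pooled, family, compute_covariance=False)

    per_dataset = []
    failures = []
    for ds in datasets:
        try:
            f = fit_mle(ds, family, compute_covariance=False)
        except FitError as exc:
            failures.append((ds.label, str(exc)))
            continue
        if n_convention == "distinct_temperatures":
            n_i = _distinct_n(ds, merge_tolerance)
        else:
            n_i = len(ds)
        per_dataset.append({"dataset": ds.label, "-lnL": f.neg_ln_L, "n": n_i, "fit": f})
    if failures:
        detail = "; ".join(f"{lab}: {msg}" for lab, msg in failures)
        raise FitError(f"separate fit failed, comparison aborted — {detail}")

    p = fit_grouped.params.n_params
    if n_convention == "distinct_temperatures":
        n_grouped = _distinct_n(pooled, merge_tolerance)
    else:
        n_grouped = len(pooled)
    n_separated = sum(d["n"] for d in per_dataset)
    nll_sep = sum(d["-lnL"] for d in per_dataset)
    grouped = {
        "-lnL": fit_grouped.neg_ln_L,
        "p": p,
        "n": n_grouped,
        "BIC": 2.0 * fit_grouped.neg_ln_L + p * np.log(n_grouped),
    }
    separated = {
        "-lnL": nll_sep,
        "p": p * len(per_dataset),
        "n": n_separated,
        "BIC": 2.0 * nll_sep + p * len(per_dataset) * np.log(n_separated),
    }
    return BICComparison(
        grouped=grouped,
        separated=separated,
        per_dataset=[{k: v for k, v in d.items() if k != "fit"} for d in per_dataset],
    )
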