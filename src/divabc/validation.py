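"""Model checking: cross-validation and posterior-predictive fit.

The cross-validation protocol classifies pseudo-observed datasets (PODs)
of known generating model and reports, per model:

- the **accuracy rate** — among PODs inferred to correspond to model M
  with strong support (best posterior at or above the threshold below),
  the proportion actually generated under M. When no POD reaches strong
  support for M the rate is 1 by convention: no incorrect confident
  inference was made. This threshold-gated reading is the one under which
  an accuracy of 1 can coexist with an ambiguity of 1 for model pairs
  that genuinely overlap (the heterogeneous-migration model contains the
  homogeneous one as the limit p -> 1). The plain per-assignment
  precision and recall over best-model calls are reported alongside;
- the **ambiguity rate** — the proportion of PODs generated under M whose
  best model is not strongly supported, i.e. its posterior probability
  falls below ``P_min = 1/k + 1/3`` for ``k`` compared models.

Goodness-of-fit is a posterior predictive check: parameter draws are
resampled (Epanechnikov-weighted, no regression adjustment) from the
retained simulations, datasets are re-simulated under them, and each
observed statistic is flagged when it falls outside the simulated central
95% interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_choice import ABCModelChoice, ModelChoiceResults, ReferenceTable
from .scenarios import ScenarioParams
from .simulate import SimLayout, simulate_summary


def pmin_threshold(k: int) -> float:
    """Strong-support threshold: one third above the uniform expectation.

    ``1/k + 1/3``: 0.8333… for two models, 0.5 for six, 0.4242… for
    eleven.
    """
    if k < 2:
        raise ValueError("need at least two compared models")
    return 1.0 / k + 1.0 / 3.0


@dataclass
class CVReport:
    """Cross-validation outcome.

    ``confusion`` has true models as rows and inferred models as columns;
    each row sums to the number of PODs for that true model.
    """

    accuracy: pd.Series          # threshold-gated, per inferred model
    precision: pd.Series         # plain, per inferred model (best-model calls)
    recall: pd.Series            # per true model
    ambiguity: pd.Series         # per true model
    confusion: pd.DataFrame
    p_min: float
    n_pods: int
    best_probabilities: pd.DataFrame  # per POD: true label + best model + its prob
    manifest: dict = field(default_factory=dict)


def _classify_pods(rt: ReferenceTable, pod_stats: pd.DataFrame,
                   pod_labels: np.ndarray, method: str, tolerance: float,
                   n_retain: int | None, seed: int | None,
                   exclude_self: np.ndarray | None = None,
                   classify_method: str | None = None) -> CVReport:
    models = rt.models
    k = len(models)
    p_min = pmin_threshold(k)
    rows = []
    for i in range(len(pod_stats)):
        if exclude_self is not None:
            mask = np.ones(rt.n_rows, dtype=bool)
            mask[exclude_self[i]] = False
            table = rt.subset(mask)
        else:
            table = rt
        fit = ABCModelChoice(table, pod_stats.iloc[i]).fit(
            method=method, tolerance=tolerance, n_retain=n_retain, seed=seed)
        if classify_method is not None and classify_method != method:
            cls_fit = ABCModelChoice(table, pod_stats.iloc[i]).fit(
                method=classify_method, tolerance=tolerance,
                n_retain=n_retain, seed=seed)
            inferred = cls_fit.best_model
        else:
            inferred = fit.best_model
        rows.append({"true": pod_labels[i], "inferred": inferred,
                     "best": fit.best_model,
                     "best_prob": float(fit.probabilities.max())})
    per_pod = pd.DataFrame(rows)
    confusion = pd.crosstab(per_pod["true"], per_pod["inferred"]) \
        .reindex(index=models, columns=models, fill_value=0)
    inferred_totals = confusion.sum(axis=0)
    precision = pd.Series(
        {m: (confusion.loc[m, m] / inferred_totals[m]) if inferred_totals[m] else np.nan
         for m in models})
    true_totals = confusion.sum(axis=1)
    recall = pd.Series(
        {m: (confusion.loc[m, m] / true_totals[m]) if true_totals[m] else np.nan
         for m in models})
    ambiguous = per_pod["best_prob"] < p_min
    ambiguity = pd.Series(
        {m: ambiguous[per_pod["true"] == m].mean() if (per_pod["true"] == m).any()
         else np.nan for m in models})
    # threshold-gated accuracy: correctness among strongly supported calls;
    # with no strongly supported call for M there is no confident error -> 1
    confident = ~ambiguous
    accuracy = {}
    for m in models:
        calls = confident & (per_pod["best"] == m)
        accuracy[m] = float((per_pod.loc[calls, "true"] == m).mean()) if calls.any() else 1.0
    n_per_model = int(true_totals.max()) if len(true_totals) else 0
    return CVReport(accuracy=pd.Series(accuracy), precision=precision,
                    recall=recall, ambiguity=ambiguity,
                    confusion=confusion, p_min=p_min, n_pods=n_per_model,
                    best_probabilities=per_pod)


def cross_validate(rt: ReferenceTable, n_pods: int = 100,
                   method: str = "mnlogistic", tolerance: float = 0.001,
                   n_retain: int | None = None, seed: int | None = None,
                   pods: tuple[pd.DataFrame, np.ndarray] | None = None,
                   classify_method: str | None = None) -> CVReport:
    """Leave-one-out cross-validation of the model-choice machinery.

    By default ``n_pods`` rows per model are extracted from the reference
    table itself as pseudo-observed datasets; each is classified against
    the table with that row excluded. Alternatively ``pods`` supplies an
    external labelled batch ``(stats, labels)`` — e.g. strong-contrast
    draws — classified against the full table.

    ``classify_method`` optionally uses a different estimator for the
    assignment step than for the strong-support (ambiguity) step, e.g.
    retained-frequency assignment alongside regression posteriors.
    """
    rng = np.random.default_rng(seed)
    if pods is None:
        chosen: list[int] = []
        for m in rt.models:
            rows = np.flatnonzero(rt.labels == m)
            if len(rows) <= n_pods:
                raise ValueError(
                    f"model {m} has only {len(rows)} rows; need more than {n_pods}")
            chosen.extend(rng.choice(rows, size=n_pods, replace=False))
        chosen_arr = np.array(chosen)
        pod_stats = rt.stats.iloc[chosen_arr].reset_index(drop=True)
        pod_labels = rt.labels[chosen_arr]
        report = _classify_pods(rt, pod_stats, pod_labels, method, tolerance,
                                n_retain, seed, exclude_self=chosen_arr,
                                classify_method=classify_method)
    else:
        pod_stats, pod_labels = pods
        report = _classify_pods(rt, pod_stats.reset_index(drop=True),
                                np.asarray(pod_labels), method, tolerance,
                                n_retain, seed, classify_method=classify_method)
    report.manifest = {"method": method, "classify_method": classify_method,
                       "tolerance": tolerance, "n_retain": n_retain,
                       "seed": seed, "external_pods": pods is not None}
    return report


@dataclass
class GofReport:
    """Posterior predictive check: per-statistic 95% envelope and flags."""

    table: pd.DataFrame  # observed, q2.5, q97.5, outside
    n_ppc: int

    @property
    def n_outside(self) -> int:
        return int(self.table["outside"].sum())


def goodness_of_fit(results: ModelChoiceResults, layout: SimLayout,
                    n_ppc: int = 500,
                    rng: np.random.Generator | int | None = None,
                    model: str | None = None) -> GofReport:
    """Re-simulate summaries under retained parameter draws.

    Draws ``n_ppc`` parameter vectors (with the rejection weights) from
    the retained simulations of ``model`` (default: the best model),
    re-simulates each, and flags observed statistics outside the central
    95% simulated interval. Fewer than 100 replicates makes the quantiles
    unstable and triggers a warning.
    """
    import warnings

    if n_ppc < 100:
        warnings.warn("n_ppc < 100 gives unstable quantiles")
    rng = np.random.default_rng(rng)
    target = model or results.best_model
    labels = results.retained_labels
    params = results.retained_params.reset_index(drop=True)
    weights = results.rejection.weights
    mask = labels == target
    if not mask.any():
        raise ValueError(f"no retained simulations under model {target}")
    params = params[mask].reset_index(drop=True)
    w = weights[mask]
    w = w / w.sum()
    rt = results.model.reference_table
    scheme = rt.scheme
    picks = rng.choice(len(params), size=n_ppc, replace=True, p=w)
    sims = []
    for row_i in picks:
        row = params.iloc[row_i]
        sp = ScenarioParams(**{k: row[k] for k in row.index})
        sims.append(simulate_summary(sp, layout, scheme, rng).values)
    sim_frame = pd.DataFrame(sims)
    lo = sim_frame.quantile(0.025)
    hi = sim_frame.quantile(0.975)
    obs = results.model.observed
    out = pd.DataFrame({"observed": obs, "q2.5": lo, "q97.5": hi})
    out["outside"] = (out["observed"] < out["q2.5"]) | (out["observed"] > out["q97.5"])
    return GofReport(table=out, n_ppc=n_ppc)
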