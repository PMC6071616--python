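"""ABC model choice: reference tables, rejection sampling, posteriors.

The central objects follow the model/results pattern:
:class:`ABCModelChoice` is built from a simulated :class:`ReferenceTable`
and an observed summary-statistic vector; its :meth:`~ABCModelChoice.fit`
performs the rejection step (statistics standardized by their median
absolute deviation, Euclidean distance, nearest fraction retained with
Epanechnikov weights) followed by one of three posterior estimators, and
returns a :class:`ModelChoiceResults` carrying per-model posterior
probabilities, Bayes factors, the retained simulations and a summary
table.

Posterior estimators:

``rejection``
    weighted model frequencies among the retained simulations (exact and
    oracle-friendly);
``mnlogistic``
    multinomial logistic regression of the model label on the statistics
    over the retained set, evaluated at the observed vector
    (deterministic default);
``neuralnet``
    a single-hidden-layer neural network in place of the multinomial
    logistic fit, seed-controlled (size and restarts configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from .scenarios import PriorConfig, ScenarioParams, sample_prior
from .simulate import SimLayout, simulate_summary

METHODS = ("rejection", "mnlogistic", "neuralnet")


@dataclass
class ReferenceTable:
    """Simulated statistic matrix with model labels and parameter draws.

    ``stats`` rows are simulations, columns the scheme-ordered statistics;
    ``labels`` holds the scenario label of each row; ``params`` the
    corresponding parameter draws. The layout fingerprint and seed
    manifest make the table reproducible.
    """

    stats: pd.DataFrame
    labels: np.ndarray
    params: pd.DataFrame
    scheme: str
    layout: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.stats) != len(self.labels) or len(self.stats) != len(self.params):
            raise ValueError("stats, labels and params must have equal length")
        if self.stats.isna().any().any():
            raise ValueError("reference table contains missing statistics")

    @property
    def n_rows(self) -> int:
        return len(self.stats)

    @property
    def models(self) -> list[str]:
        return sorted(set(self.labels))

    def subset(self, mask: np.ndarray) -> "ReferenceTable":
        return ReferenceTable(stats=self.stats[mask].reset_index(drop=True),
                              labels=self.labels[mask],
                              params=self.params[mask].reset_index(drop=True),
                              scheme=self.scheme, layout=self.layout,
                              manifest=self.manifest)

    def append(self, other: "ReferenceTable") -> "ReferenceTable":
        if other.scheme != self.scheme or other.layout != self.layout:
            raise ValueError("cannot append tables with different scheme/layout")
        return ReferenceTable(
            stats=pd.concat([self.stats, other.stats], ignore_index=True),
            labels=np.concatenate([self.labels, other.labels]),
            params=pd.concat([self.params, other.params], ignore_index=True),
            scheme=self.scheme, layout=self.layout,
            manifest={**self.manifest, **other.manifest})


def build_reference_table(models: list[tuple[str, str]], n_per_model: int,
                          layout: SimLayout, scheme: str, seed: int,
                          prior: PriorConfig | None = None,
                          progress: bool = False) -> ReferenceTable:
    """Simulate ``n_per_model`` prior draws per scenario into a table.

    Fully reproducible from the seed: a seed sequence spawns one child
    stream per (model, replicate) so tables for the same seed are
    identical regardless of generation order.
    """
    if n_per_model < 1:
        raise ValueError("n_per_model must be >= 1")
    prior = prior or (layout.prior if layout.prior is not None else PriorConfig())
    stats_rows, label_rows, param_rows = [], [], []
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(models))
    for (model_id, mode), stream in zip(models, streams):
        children = stream.spawn(n_per_model)
        for k, child in enumerate(children):
            rng = np.random.default_rng(child)
            sp = sample_prior(model_id, mode, prior, rng)
            summ = simulate_summary(sp, layout, scheme, rng)
            stats_rows.append(summ.values)
            label_rows.append(sp.label)
            param_rows.append(pd.Series(sp.to_dict()))
            if progress and (k + 1) % 500 == 0:
                print(f"  {sp.label}: {k + 1}/{n_per_model}", flush=True)
    return ReferenceTable(stats=pd.DataFrame(stats_rows).reset_index(drop=True),
                          labels=np.array(label_rows),
                          params=pd.DataFrame(param_rows).reset_index(drop=True),
                          scheme=scheme, layout=layout.to_dict(),
                          manifest={"seed": seed, "n_per_model": n_per_model,
                                    "models": ["+".join(m) for m in models],
                                    "prior": prior.to_dict()})


# --- rejection step --------------------------------------------------------


@dataclass
class RejectionResult:
    indices: np.ndarray          # positions of retained rows in the table
    distances: np.ndarray        # their distances, ascending
    weights: np.ndarray          # Epanechnikov kernel weights
    scale: pd.Series             # per-statistic scale used
    dropped_columns: list[str]   # zero-variance statistics excluded


def _robust_scale(stats: pd.DataFrame) -> pd.Series:
    """MAD per column, falling back to the SD where the MAD is zero."""
    med = stats.median()
    mad = (stats - med).abs().median()
    sd = stats.std(ddof=0)
    scale = mad.where(mad > 0, sd)
    return scale


def rejection_select(rt: ReferenceTable, observed: pd.Series,
                     tolerance: float = 0.001,
                     n_retain: int | None = None) -> RejectionResult:
    """Retain the simulations nearest to the observed statistics.

    Statistics are standardized by a robust scale (MAD, SD fallback)
    estimated on the reference table; zero-variance statistics are
    excluded from the Euclidean distance with a warning. The nearest
    ``ceil(tolerance * N)`` rows (or ``n_retain``, if given) are kept with
    Epanechnikov weights ``1 - (d / d_max)^2`` (rows at the bandwidth edge
    keep a small positive floor so a retained set at a single distance
    still has mass).
    """
    cols = list(rt.stats.columns)
    if list(observed.index) != cols:
        observed = observed.reindex(cols)
        if observed.isna().any():
            raise ValueError("observed summary does not match the table's scheme")
    scale = _robust_scale(rt.stats)
    dropped = [c for c in cols if not scale[c] > 0]
    if dropped:
        warnings.warn(f"zero-variance statistics excluded from distance: {dropped}")
    use = [c for c in cols if c not in dropped]
    if not use:
        raise ValueError("no informative statistics left for the distance")
    X = rt.stats[use].to_numpy(float) / scale[use].to_numpy(float)
    y = observed[use].to_numpy(float) / scale[use].to_numpy(float)
    d = np.sqrt(((X - y) ** 2).sum(axis=1))
    if n_retain is None:
        n_retain = int(np.ceil(tolerance * len(d)))
    n_retain = max(1, min(n_retain, len(d)))
    idx = np.argsort(d, kind="stable")[:n_retain]
    dist = d[idx]
    dmax = dist[-1]
    if dmax == 0:
        w = np.ones_like(dist)
    else:
        w = np.maximum(1.0 - (dist / dmax) ** 2, 1e-8)
    return RejectionResult(indices=idx, distances=dist, weights=w,
                           scale=scale[use], dropped_columns=dropped)


def bayes_factors(probabilities: pd.Series) -> dict:
    """Bayes factors of the best model against the runners-up.

    ``BF_1/2`` divides the best model's posterior probability by the
    second best's, ``BF_1/3`` by the third best's (when at least three
    models are compared). Ties are broken by model-name order and flagged;
    a zero denominator is reported as infinity with a flag.
    """
    if len(probabilities) < 2:
        raise ValueError("Bayes factors need at least two models")
    ordered = probabilities.sort_values(ascending=False, kind="stable")
    tie = len(set(np.round(ordered.to_numpy(), 12))) < len(ordered)
    out = {"best": ordered.index[0], "tied": bool(tie)}
    p1, p2 = ordered.iloc[0], ordered.iloc[1]
    out["BF_1/2"] = np.inf if p2 == 0 else p1 / p2
    out["infinite"] = p2 == 0
    if len(ordered) >= 3:
        p3 = ordered.iloc[2]
        out["BF_1/3"] = np.inf if p3 == 0 else p1 / p3
        out["infinite"] = out["infinite"] or p3 == 0
    return out


# --- model / results -------------------------------------------------------


class ABCModelChoice:
    """Model-choice problem: a reference table plus an observed summary."""

    def __init__(self, reference_table: ReferenceTable,
                 observed: pd.Series | "BinnedSummary"):
        if isinstance(observed, pd.Series):
            values = observed
        elif isinstance(getattr(observed, "values", None), pd.Series):
            values = observed.values
        else:
            raise TypeError("observed must be a pandas Series or BinnedSummary")
        obs_scheme = getattr(observed, "scheme", None)
        if obs_scheme is not None and obs_scheme != reference_table.scheme:
            raise ValueError(
                f"observed scheme {obs_scheme!r} != table scheme {reference_table.scheme!r}")
        if len(reference_table.models) < 2:
            raise ValueError("model choice needs at least two models in the table")
        self.reference_table = reference_table
        self.observed = values

    def fit(self, method: str = "mnlogistic", tolerance: float = 0.001,
            n_retain: int | None = None, seed: int | None = None,
            hidden_units: int = 8, restarts: int = 1) -> "ModelChoiceResults":
        """Rejection step followed by the chosen posterior estimator."""
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
        rt = self.reference_table
        rej = rejection_select(rt, self.observed, tolerance=tolerance,
                               n_retain=n_retain)
        labels = rt.labels[rej.indices]
        models = rt.models
        present = sorted(set(labels))
        missing = [m for m in models if m not in present]
        if missing:
            warnings.warn(f"models absent from the retained set: {missing} "
                          "(posterior probability 0)")
        probs = pd.Series(0.0, index=models)
        if method == "rejection" or len(present) == 1:
            w = rej.weights
            for m in present:
                probs[m] = w[labels == m].sum()
            probs /= probs.sum()
        else:
            use = list(rej.scale.index)
            X = rt.stats[use].to_numpy(float)[rej.indices] / rej.scale.to_numpy(float)
            yobs = (self.observed[use].to_numpy(float) /
                    rej.scale.to_numpy(float)).reshape(1, -1)
            mu, sdev = X.mean(axis=0), X.std(axis=0)
            sdev[sdev == 0] = 1.0
            Xs = (X - mu) / sdev
            yo = (yobs - mu) / sdev
            if method == "mnlogistic":
                clf = LogisticRegression(max_iter=2000)
                clf.fit(Xs, labels, sample_weight=rej.weights)
            else:
                best, best_loss = None, np.inf
                base = np.random.SeedSequence(seed if seed is not None else 0)
                for child in base.spawn(max(1, restarts)):
                    net = MLPClassifier(hidden_layer_sizes=(hidden_units,),
                                        max_iter=2000, alpha=1e-3,
                                        random_state=np.random.default_rng(child)
                                        .integers(0, 2**31 - 1))
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", ConvergenceWarning)
                        net.fit(Xs, labels)
                    if net.loss_ < best_loss:
                        best, best_loss = net, net.loss_
                clf = best
            p = clf.predict_proba(yo)[0]
            for m, pi in zip(clf.classes_, p):
                probs[m] = pi
            probs = probs.clip(lower=0.0, upper=1.0)
            probs /= probs.sum()
        return ModelChoiceResults(model=self, method=method, tolerance=tolerance,
                                  probabilities=probs, rejection=rej)


@dataclass
class ModelChoiceResults:
    """Fitted posterior probabilities over the candidate scenarios."""

    model: ABCModelChoice
    method: str
    tolerance: float
    probabilities: pd.Series
    rejection: RejectionResult

    def __post_init__(self) -> None:
        total = float(self.probabilities.sum())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"posterior probabilities sum to {total}, not 1")

    @property
    def best_model(self) -> str:
        return self.probabilities.idxmax()

    @property
    def retained_params(self) -> pd.DataFrame:
        rt = self.model.reference_table
        return rt.params.iloc[self.rejection.indices]

    @property
    def retained_labels(self) -> np.ndarray:
        return self.model.reference_table.labels[self.rejection.indices]

    def bayes_factors(self) -> dict:
        return bayes_factors(self.probabilities)

    def parameter_posterior(self, model: str | None = None,
                            adjust: bool = False) -> pd.DataFrame:
        """Weighted posterior summary of the retained parameter draws.

        Restricted to retained rows of ``model`` (default: the best
        model). With ``adjust`` a local-linear regression correction of
        each numeric parameter on the standardized statistics is applied
        (the retained draws are shifted to the observed point before
        summarizing). Returns mean and 2.5/50/97.5% weighted quantiles.
        """
        target = model or self.best_model
        mask = self.retained_labels == target
        if not mask.any():
            raise ValueError(f"no retained rows under model {target}")
        params = self.retained_params.reset_index(drop=True)[mask].reset_index(drop=True)
        w = self.rejection.weights[mask]
        w = w / w.sum()
        numeric = params.select_dtypes("number")
        if adjust:
            rt = self.model.reference_table
            use = list(self.rejection.scale.index)
            X = (rt.stats[use].to_numpy(float)[self.rejection.indices][mask] /
                 self.rejection.scale.to_numpy(float))
            y = (self.model.observed[use].to_numpy(float) /
                 self.rejection.scale.to_numpy(float))
            Xc = np.column_stack([np.ones(len(X)), X - y])
            sw = np.sqrt(w)
            adjusted = {}
            for col in numeric.columns:
                beta, *_ = np.linalg.lstsq(Xc * sw[:, None],
                                           numeric[col].to_numpy(float) * sw,
                                           rcond=None)
                resid = numeric[col].to_numpy(float) - Xc @ beta
                adjusted[col] = beta[0] + resid
            numeric = pd.DataFrame(adjusted)
        out = {}
        order = {c: np.argsort(numeric[c].to_numpy()) for c in numeric.columns}
        for col in numeric.columns:
            v = numeric[col].to_numpy(float)
            idx = order[col]
            cw = np.cumsum(w[idx])
            qs = np.interp([0.025, 0.5, 0.975], cw / cw[-1], v[idx])
            out[col] = {"mean": float(np.sum(w * v)), "q2.5": qs[0],
                        "median": qs[1], "q97.5": qs[2]}
        return pd.DataFrame(out).T

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        bf = self.bayes_factors()
        lines = ["ABC model choice",
                 "=" * 44,
                 f"method:      {self.method}",
                 f"scheme:      {self.model.reference_table.scheme}",
                 f"table rows:  {self.model.reference_table.n_rows}",
                 f"retained:    {len(self.rejection.indices)}",
                 "-" * 44,
                 f"{'model':<16}{'posterior':>12}",
                 "-" * 44]
        for m, p in self.probabilities.sort_values(ascending=False).items():
            lines.append(f"{m:<16}{p:>12.4f}")
        lines.append("-" * 44)
        lines.append(f"best model:  {bf['best']}")
        lines.append(f"BF_1/2:      {bf['BF_1/2']:.3g}")
        if "BF_1/3" in bf:
            lines.append(f"BF_1/3:      {bf['BF_1/3']:.3g}")
        return "\n".join(lines)


# late import for the type check in ABCModelChoice.__init__
from .summaries import BinnedSummary  # noqa: E402,F401
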