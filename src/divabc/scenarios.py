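"""Speciation scenarios, their priors, and epoch schedules.

Six temporal patterns of migration between two daughter populations are
modelled, each deriving from an ancestral population of size ``N_A`` that
split ``T_split`` generations ago into populations of constant sizes
``N_1`` and ``N_2``:

``SI``
    strict isolation — no gene flow after the split.
``IM``
    isolation with migration — continuous gene flow since the split.
``AM``
    ancient migration — gene flow early in divergence, then a single
    isolation period of duration ``T_iso`` lasting until the present.
``PAM``
    periodic ancient migration — like AM but migration was interrupted
    twice, with an intermediate isolation period; the two isolation
    windows have duration ``T_iso / 2`` each.
``SC``
    secondary contact — isolation after the split, then a single recent
    contact episode of duration ``T_sc`` lasting until the present.
``PSC``
    periodic secondary contact — two contact episodes of ``T_sc / 2``
    each, separated by isolation.

Every migration model comes in a ``homo`` variant (one effective migration
rate per direction shared by all loci) and a ``hetero`` variant in which a
proportion ``1 - p`` of loci are linked to barrier genes and have their
migration rate multiplied by a per-locus gene-flow factor (gff) drawn from
a Beta(alpha, beta) distribution — the semi-permeable-barrier model.

Times are expressed in units of ``4 N_ref`` generations, effective sizes
as ratios ``theta_i / theta_ref`` (equivalently ``N_i / N_ref``), and
migration as ``M = 4 N m`` per direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

MODELS = ("SI", "IM", "AM", "PAM", "SC", "PSC")
MIGRATION_MODES = ("none", "homo", "hetero")

#: The eleven model/mode combinations compared in the full analysis.
ALL_SCENARIOS = (
    ("SI", "none"),
    ("IM", "homo"), ("IM", "hetero"),
    ("AM", "homo"), ("AM", "hetero"),
    ("PAM", "homo"), ("PAM", "hetero"),
    ("SC", "homo"), ("SC", "hetero"),
    ("PSC", "homo"), ("PSC", "hetero"),
)


@dataclass
class PriorConfig:
    """Bounds of the uniform priors and the fixed reference constants.

    Defaults follow the study design: theta ratios uniform on 0-20 with
    ``theta_ref = 4 N_ref mu``, ``T_split / 4 N_ref`` uniform on 0-25,
    per-direction migration rates ``M = 4 N m`` uniform on 0-40, barrier
    proportion complement ``p`` uniform on 0-1, gff Beta shapes alpha in
    0.001-10 and beta in 0.001-5. The misorientation proportion ``e`` has
    no stated prior; the default is uniform on 0-0.2 and is recorded in
    every run manifest.
    """

    theta_bounds: tuple[float, float] = (0.0, 20.0)
    tsplit_bounds: tuple[float, float] = (0.0, 25.0)
    mig_bounds: tuple[float, float] = (0.0, 40.0)
    p_bounds: tuple[float, float] = (0.0, 1.0)
    alpha_bounds: tuple[float, float] = (0.001, 10.0)
    beta_bounds: tuple[float, float] = (0.001, 5.0)
    e_bounds: tuple[float, float] = (0.0, 0.2)
    n_ref: float = 100_000.0
    mu: float = 2.763e-8  # per bp per generation

    def __post_init__(self) -> None:
        for name in ("theta_bounds", "tsplit_bounds", "mig_bounds",
                     "p_bounds", "alpha_bounds", "beta_bounds", "e_bounds"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound {lo} > upper bound {hi}")
        if self.n_ref <= 0 or self.mu <= 0:
            raise ValueError("n_ref and mu must be positive")

    @property
    def theta_ref(self) -> float:
        """Per-bp reference scaled mutation rate ``4 N_ref mu``."""
        return 4.0 * self.n_ref * self.mu

    def to_dict(self) -> dict:
        return asdict(self)


#: Prior used for "strong-contrast" pseudo-observed datasets: informative
#: data in the regime where heterogeneous gene flow leaves its signature
#: (high migration, deep split, recent contact, strong barrier). Used by
#: the scaled-down cross-validation experiments.
STRONG_CONTRAST = PriorConfig(
    theta_bounds=(5.0, 20.0),
    tsplit_bounds=(10.0, 25.0),
    mig_bounds=(20.0, 40.0),
    p_bounds=(0.0, 0.2),
    alpha_bounds=(0.001, 1.0),
    beta_bounds=(2.0, 5.0),
)


@dataclass
class ScenarioParams:
    """One draw of all demographic and nuisance parameters for one model.

    Times (``t_split``, ``t_iso``, ``t_sc``) are in units of ``4 N_ref``
    generations; ``theta_*`` are ratios to ``theta_ref``; ``m12``/``m21``
    are ``4 N m`` rates (forward direction: 1 -> 2 and 2 -> 1); ``p`` is
    the proportion of freely-introgressing loci; ``alpha``/``beta`` shape
    the gff distribution of barrier loci; ``e`` is the proportion of SNPs
    whose ancestral state is misassigned.
    """

    model_id: str
    migration_mode: str
    theta_anc: float
    theta_1: float
    theta_2: float
    t_split: float
    t_iso: float = 0.0
    t_sc: float = 0.0
    m12: float = 0.0
    m21: float = 0.0
    p: float = 1.0
    alpha: float = 1.0
    beta: float = 1.0
    e: float = 0.0

    def __post_init__(self) -> None:
        if self.model_id not in MODELS:
            raise ValueError(f"unknown model {self.model_id!r}")
        if self.migration_mode not in MIGRATION_MODES:
            raise ValueError(f"unknown migration mode {self.migration_mode!r}")
        if (self.model_id == "SI") != (self.migration_mode == "none"):
            raise ValueError("SI requires mode 'none'; migration models require homo/hetero")
        if not (0.0 <= self.t_iso <= self.t_split if self.t_split > 0 else self.t_iso == 0):
            raise ValueError("need 0 <= t_iso <= t_split")
        if not (0.0 <= self.t_sc <= self.t_split if self.t_split > 0 else self.t_sc == 0):
            raise ValueError("need 0 <= t_sc <= t_split")
        for name in ("theta_anc", "theta_1", "theta_2", "m12", "m21"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.e <= 1.0:
            raise ValueError("e must lie in [0, 1]")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")

    @property
    def label(self) -> str:
        """Scenario label, e.g. ``"SC.hetero"`` or ``"SI"``."""
        if self.migration_mode == "none":
            return self.model_id
        return f"{self.model_id}.{self.migration_mode}"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EpochSchedule:
    """Migration on/off epochs backward in time, tiling ``[0, t_split]``.

    ``epochs`` is an ordered list of ``(start, end, migration_on)`` with
    ``start`` < ``end``, the first epoch starting at 0 (the present) and
    the last ending at ``t_split`` (the population split, at which the two
    populations merge into the ancestral one, looking backward).
    """

    t_split: float
    epochs: list[tuple[float, float, bool]] = field(default_factory=list)

    def validate(self) -> None:
        if self.t_split == 0:
            if self.epochs:
                raise ValueError("t_split = 0 admits no epochs")
            return
        if not self.epochs:
            raise ValueError("empty schedule")
        if self.epochs[0][0] != 0.0:
            raise ValueError("first epoch must start at 0")
        for (s, e, _), (s2, _e2, _) in zip(self.epochs, self.epochs[1:]):
            if e != s2:
                raise ValueError("epochs must tile [0, t_split] without gaps/overlaps")
        for s, e, _ in self.epochs:
            if not s < e:
                raise ValueError("epoch start must precede its end")
        if self.epochs[-1][1] != self.t_split:
            raise ValueError("last epoch must end at t_split")


def sample_prior(model_id: str, mode: str, cfg: PriorConfig | None = None,
                 rng: np.random.Generator | int | None = None) -> ScenarioParams:
    """Draw one :class:`ScenarioParams` from the uniform priors.

    ``t_iso`` and ``t_sc`` are drawn uniformly on ``(0, t_split)``
    conditional on the drawn split time. Fields unused by the model/mode
    are set to inert defaults. Deterministic under a fixed ``rng`` seed.
    """
    cfg = cfg or PriorConfig()
    rng = np.random.default_rng(rng)
    t_split = rng.uniform(*cfg.tsplit_bounds)
    kwargs: dict = dict(
        model_id=model_id,
        migration_mode=mode,
        theta_anc=rng.uniform(*cfg.theta_bounds),
        theta_1=rng.uniform(*cfg.theta_bounds),
        theta_2=rng.uniform(*cfg.theta_bounds),
        t_split=t_split,
        e=rng.uniform(*cfg.e_bounds),
    )
    if model_id in ("AM", "PAM"):
        kwargs["t_iso"] = rng.uniform(0.0, t_split)
    elif model_id in ("SC", "PSC"):
        kwargs["t_sc"] = rng.uniform(0.0, t_split)
    if mode in ("homo", "hetero"):
        # one rate per direction of introgression, drawn independently
        kwargs["m12"] = rng.uniform(*cfg.mig_bounds)
        kwargs["m21"] = rng.uniform(*cfg.mig_bounds)
    if mode == "hetero":
        kwargs["p"] = rng.uniform(*cfg.p_bounds)
        kwargs["alpha"] = rng.uniform(*cfg.alpha_bounds)
        kwargs["beta"] = rng.uniform(*cfg.beta_bounds)
    return ScenarioParams(**kwargs)


def epoch_schedule(sp: ScenarioParams) -> EpochSchedule:
    """Translate a parameter draw into an explicit migration schedule.

    Backward in time from the present:

    - ``SI``: off for the whole divergence.
    - ``IM``: on for the whole divergence.
    - ``AM``: off on ``[0, t_iso)``, on until the split.
    - ``SC``: on on ``[0, t_sc)``, off until the split.
    - ``PAM``: two isolation windows of ``t_iso / 2`` (one ending at the
      present) alternating with two equal migration windows of
      ``(t_split - t_iso) / 2``.
    - ``PSC``: two contact windows of ``t_sc / 2`` (one ending at the
      present) alternating with two equal isolation windows of
      ``(t_split - t_sc) / 2``.
    """
    T = sp.t_split
    if sp.t_iso > T or sp.t_sc > T:
        raise ValueError("t_iso and t_sc cannot exceed t_split")
    sched = EpochSchedule(t_split=T)
    if T == 0:
        sched.validate()
        return sched

    def tile(durations: list[float], states: list[bool]) -> None:
        t = 0.0
        for d, on in zip(durations, states):
            if d > 0:
                sched.epochs.append((t, t + d, on))
                t += d
        # snap the final boundary to T against float drift
        if sched.epochs:
            s, _, on = sched.epochs[-1]
            sched.epochs[-1] = (s, T, on)

    if sp.model_id == "SI":
        tile([T], [False])
    elif sp.model_id == "IM":
        tile([T], [True])
    elif sp.model_id == "AM":
        tile([sp.t_iso, T - sp.t_iso], [False, True])
    elif sp.model_id == "SC":
        tile([sp.t_sc, T - sp.t_sc], [True, False])
    elif sp.model_id == "PAM":
        w = (T - sp.t_iso) / 2.0
        h = sp.t_iso / 2.0
        tile([h, w, h, w], [False, True, False, True])
    elif sp.model_id == "PSC":
        w = (T - sp.t_sc) / 2.0
        h = sp.t_sc / 2.0
        tile([h, w, h, w], [True, False, True, False])
    if not sched.epochs:  # all durations zero except possibly one
        tile([T], [sp.model_id in ("IM", "SC", "PSC")])
    sched.validate()
    return sched


def draw_locus_migration_factors(sp: ScenarioParams, n_loci: int,
                                 rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Per-locus gene-flow factors under the heterogeneous model.

    Each locus independently is neutral (gff = 1) with probability ``p``,
    otherwise barrier-linked with gff ~ Beta(alpha, beta). The factor
    multiplies both directional migration rates of that locus.
    """
    if sp.migration_mode != "hetero":
        raise ValueError("gene-flow factors are defined only for hetero mode")
    rng = np.random.default_rng(rng)
    gff = rng.beta(sp.alpha, sp.beta, size=n_loci)
    gff[rng.random(n_loci) < sp.p] = 1.0
    return gff
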