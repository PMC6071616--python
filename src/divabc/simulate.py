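"""Multilocus coalescent simulation of the speciation scenarios.

Each locus is an independent two-population coalescent (free recombination
between loci) with the epoch schedule's migration switches, constant sizes
``N1``/``N2``, ancestral size ``NA`` and a merge at ``T_split``; the
per-locus scaled mutation rate is ``theta_locus = ratio * theta_ref * L``
and the intra-locus recombination rate equals the mutation rate by default
(``rho = theta``). In the heterogeneous mode each locus's migration rates
are multiplied by its gene-flow factor.

msprime backs the module; the contract is the demography plus per-locus
rates, not the engine. Two output paths exist:

- a counts path used for reference tables: the branch-mode joint
  allele-frequency spectrum of each tree sequence gives the expected
  number of mutations per jSFS cell, from which Poisson site counts are
  drawn (exact under the infinite-sites model, and much faster than
  placing mutations);
- a haplotype path used for dataset generation: explicit infinite-sites
  mutations with discretized positions, from which sequences and
  per-locus statistics can be built.

SNP misorientation is applied post hoc at the SNP level: each SNP flips
its derived counts ``(i, j) -> (2 n1 - i, 2 n2 - j)`` independently with
probability ``e``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .io import SiteTable
from .scenarios import (EpochSchedule, PriorConfig, ScenarioParams,
                        draw_locus_migration_factors, epoch_schedule)
from .summaries import BinnedSummary, aggregate_mscalc, bin_jsfs, build_jsfs, locus_stats


@dataclass
class SimLayout:
    """Shape of a simulated dataset.

    ``locus_length`` may be a constant or a per-locus list (default 500 bp;
    the study's loci are at least 300 bp). ``rho_over_theta`` scales the
    intra-locus recombination rate relative to the mutation rate (1.0 for
    the ``rho = theta`` rule, 0.0 to disable recombination).
    """

    n_loci: int
    n1: int = 2
    n2: int = 2
    locus_length: int | list[int] = 500
    rho_over_theta: float = 1.0
    prior: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.n1 < 1 or self.n2 < 1:
            raise ValueError("n_loci, n1, n2 must be >= 1")
        if min(self.lengths()) < 1:
            raise ValueError("locus lengths must be >= 1 bp")

    def lengths(self) -> list[int]:
        if isinstance(self.locus_length, int):
            return [self.locus_length] * self.n_loci
        if len(self.locus_length) != self.n_loci:
            raise ValueError("per-locus length list must have n_loci entries")
        return list(self.locus_length)

    def to_dict(self) -> dict:
        return {"n_loci": self.n_loci, "n1": self.n1, "n2": self.n2,
                "locus_length": self.locus_length,
                "rho_over_theta": self.rho_over_theta}


@dataclass
class LocusSim:
    """Haplotype-level output for one simulated locus.

    ``genotypes`` is a (sites x haplotypes) 0/1 derived-allele matrix with
    columns ordered species-1 haplotypes then species-2 haplotypes;
    ``positions`` are distinct 0-based integer sites within the locus.
    """

    locus_id: str
    length_bp: int
    genotypes: np.ndarray
    positions: np.ndarray
    gff: float = 1.0


def _demography(sp: ScenarioParams, cfg: PriorConfig, gff: float) -> tuple[msprime.Demography, dict]:
    """msprime demography for one parameter draw and one gene-flow factor.

    Sizes are ``ratio * N_ref`` diploids, times ``t * 4 N_ref``
    generations, per-generation backward migration ``M * gff / (4 N_ref)``
    (a lineage sampled in the recipient population traces back to the
    donor). With ``t_split = 0`` the model collapses to a single
    panmictic population of the ancestral size.
    """
    nref = cfg.n_ref
    if sp.t_split <= 0:
        d = msprime.Demography()
        d.add_population(name="anc", initial_size=max(sp.theta_anc, 1e-12) * nref)
        return d, {"anc": None}
    sched = epoch_schedule(sp)
    d = msprime.Demography()
    d.add_population(name="sp1", initial_size=max(sp.theta_1, 1e-12) * nref)
    d.add_population(name="sp2", initial_size=max(sp.theta_2, 1e-12) * nref)
    d.add_population(name="anc", initial_size=max(sp.theta_anc, 1e-12) * nref)
    m12 = gff * sp.m12 / (4.0 * nref)  # forward 1 -> 2: lineages in sp2 move to sp1
    m21 = gff * sp.m21 / (4.0 * nref)
    first = sched.epochs[0]
    if first[2]:
        d.set_migration_rate(source="sp2", dest="sp1", rate=m12)
        d.set_migration_rate(source="sp1", dest="sp2", rate=m21)
    for start, _end, on in sched.epochs[1:]:
        t = start * 4.0 * nref
        d.add_migration_rate_change(time=t, source="sp2", dest="sp1",
                                    rate=m12 if on else 0.0)
        d.add_migration_rate_change(time=t, source="sp1", dest="sp2",
                                    rate=m21 if on else 0.0)
    d.add_population_split(time=sp.t_split * 4.0 * nref,
                           derived=["sp1", "sp2"], ancestral="anc")
    d.sort_events()
    return d, {"split": sp.t_split}


def _locus_groups(sp: ScenarioParams, layout: SimLayout,
                  rng: np.random.Generator) -> list[tuple[float, list[int]]]:
    """Group locus indices by gene-flow factor (all loci share one group
    outside the heterogeneous mode); batching identical demographies lets
    msprime amortize its per-simulation setup cost."""
    if sp.migration_mode == "hetero" and sp.model_id != "SI":
        gff = draw_locus_migration_factors(sp, layout.n_loci, rng)
    else:
        gff = np.ones(layout.n_loci)
    groups: dict[float, list[int]] = {}
    for i, g in enumerate(gff):
        groups.setdefault(float(g), []).append(i)
    return sorted(groups.items())


def _sample_sets(ts, single_pop: bool, n1: int) -> tuple[list[int], list[int]]:
    if single_pop:
        samples = list(ts.samples())
        return samples[: 2 * n1], samples[2 * n1:]
    return list(ts.samples(population=0)), list(ts.samples(population=1))


def _iter_tree_sequences(sp: ScenarioParams, layout: SimLayout,
                         rng: np.random.Generator):
    """Yield ``(locus_index, gff, tree_sequence)`` for every locus."""
    cfg = layout.prior
    lengths = layout.lengths()
    single_pop = sp.t_split <= 0
    for g, idxs in _locus_groups(sp, layout, rng):
        demog, _ = _demography(sp, cfg, g)
        samples = ({"anc": layout.n1 + layout.n2} if single_pop
                   else {"sp1": layout.n1, "sp2": layout.n2})
        by_len: dict[int, list[int]] = {}
        for i in idxs:
            by_len.setdefault(lengths[i], []).append(i)
        for L, sub in sorted(by_len.items()):
            seed = int(rng.integers(1, 2**31 - 1))
            reps = msprime.sim_ancestry(
                samples=samples, demography=demog, sequence_length=L,
                recombination_rate=layout.rho_over_theta * cfg.mu,
                num_replicates=len(sub), random_seed=seed, ploidy=2)
            for i, ts in zip(sub, reps):
                yield i, g, ts


def simulate_counts(sp: ScenarioParams, layout: SimLayout,
                    rng: np.random.Generator | int | None = None) -> SiteTable:
    """Fast counts-only simulation of a SiteTable (no misorientation).

    Site counts per jSFS cell are Poisson draws with mean ``mu`` times the
    branch-mode joint allele-frequency spectrum, which is exact under
    infinite sites. Positions are sequential placeholders.
    """
    rng = np.random.default_rng(rng)
    cfg = layout.prior
    single_pop = sp.t_split <= 0
    rows_d1, rows_d2, rows_locus = [], [], []
    for i, _g, ts in _iter_tree_sequences(sp, layout, rng):
        s1, s2 = _sample_sets(ts, single_pop, layout.n1)
        afs = ts.allele_frequency_spectrum(sample_sets=[s1, s2], mode="branch",
                                           polarised=True, span_normalise=False)
        lam = cfg.mu * afs
        lam[0, 0] = 0.0
        lam[-1, -1] = 0.0
        counts = rng.poisson(lam)
        if counts.sum() == 0:
            continue
        ii, jj = np.nonzero(counts)
        reps = counts[ii, jj]
        rows_d1.append(np.repeat(ii, reps))
        rows_d2.append(np.repeat(jj, reps))
        rows_locus.append(np.full(int(reps.sum()), i))
    if rows_d1:
        d1 = np.concatenate(rows_d1)
        d2 = np.concatenate(rows_d2)
        loci = np.concatenate(rows_locus)
        order = np.argsort(loci, kind="stable")
        loci, d1, d2 = loci[order], d1[order], d2[order]
        per_locus = np.bincount(loci)
        pos = np.concatenate([np.arange(c) for c in per_locus if c > 0])
        data = pd.DataFrame({"locus_id": [f"locus_{k:05d}" for k in loci],
                             "pos": pos.astype(np.int64),
                             "dac1": d1.astype(np.int64),
                             "dac2": d2.astype(np.int64)})
    else:
        data = pd.DataFrame({"locus_id": pd.Series(dtype=str),
                             "pos": pd.Series(dtype=np.int64),
                             "dac1": pd.Series(dtype=np.int64),
                             "dac2": pd.Series(dtype=np.int64)})
    return SiteTable(data=data, n1=layout.n1, n2=layout.n2,
                     n_locus=layout.n_loci, provenance=sp.label)


def _discretize_positions(pos: np.ndarray, length: int) -> np.ndarray:
    """Map continuous infinite-sites positions to distinct integer sites."""
    out = np.floor(pos).astype(np.int64)
    for k in range(1, len(out)):
        if out[k] <= out[k - 1]:
            out[k] = out[k - 1] + 1
    if len(out) and out[-1] >= length:
        # shift left to fit; collisions only matter for sequence writing
        out = np.minimum(out, length - 1)
        for k in range(len(out) - 2, -1, -1):
            if out[k] >= out[k + 1]:
                out[k] = out[k + 1] - 1
        if len(out) and out[0] < 0:
            raise ValueError("more segregating sites than base pairs in locus")
    return out


def simulate_dataset(sp: ScenarioParams, layout: SimLayout,
                     rng: np.random.Generator | int | None = None,
                     ) -> tuple[SiteTable, list[LocusSim]]:
    """Simulate a dataset with explicit haplotypes (no misorientation).

    Returns the polarized SiteTable (ancestral state known by
    construction, masked corners excluded — they cannot arise under
    infinite sites) and the per-locus haplotype matrices, row-aligned with
    the table.
    """
    rng = np.random.default_rng(rng)
    cfg = layout.prior
    single_pop = sp.t_split <= 0
    lengths = layout.lengths()
    sims: dict[int, LocusSim] = {}
    for i, g, ts in _iter_tree_sequences(sp, layout, rng):
        mut_seed = int(rng.integers(1, 2**31 - 1))
        mts = msprime.sim_mutations(ts, rate=cfg.mu, discrete_genome=False,
                                    random_seed=mut_seed)
        s1, s2 = _sample_sets(mts, single_pop, layout.n1)
        G = mts.genotype_matrix()
        if G.size:
            G = (G[:, s1 + s2] > 0).astype(np.int8)
            pos = _discretize_positions(mts.tables.sites.position, lengths[i])
        else:
            G = np.zeros((0, 2 * (layout.n1 + layout.n2)), dtype=np.int8)
            pos = np.array([], dtype=np.int64)
        sims[i] = LocusSim(locus_id=f"locus_{i:05d}", length_bp=lengths[i],
                           genotypes=G, positions=pos, gff=g)
    loci = [sims[i] for i in sorted(sims)]
    rows = []
    for loc in loci:
        n1h = 2 * layout.n1
        d1 = loc.genotypes[:, :n1h].sum(axis=1)
        d2 = loc.genotypes[:, n1h:].sum(axis=1)
        keep = ~((d1 == 0) & (d2 == 0))
        loc.genotypes = loc.genotypes[keep]
        loc.positions = loc.positions[keep]
        for p, a, b in zip(loc.positions, d1[keep], d2[keep]):
            rows.append((loc.locus_id, int(p), int(a), int(b)))
    data = pd.DataFrame(rows, columns=list(SiteTable.COLUMNS))
    if data.empty:
        data = data.astype({"locus_id": str, "pos": np.int64,
                            "dac1": np.int64, "dac2": np.int64})
    st = SiteTable(data=data, n1=layout.n1, n2=layout.n2,
                   n_locus=layout.n_loci, provenance=sp.label)
    return st, loci


def apply_misorientation(st: SiteTable, e: float,
                         rng: np.random.Generator | int | None = None,
                         return_flips: bool = False):
    """Flip each SNP's ancestral/derived assignment with probability ``e``.

    A flipped row ``(i, j)`` becomes ``(2 n1 - i, 2 n2 - j)``; rows that
    would land on a masked corner are removed (none can, since the corners
    are masked on input).
    """
    if not 0.0 <= e <= 1.0:
        raise ValueError("misorientation proportion e must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    d1, d2 = st.counts()
    flips = rng.random(len(d1)) < e
    nd1 = np.where(flips, 2 * st.n1 - d1, d1)
    nd2 = np.where(flips, 2 * st.n2 - d2, d2)
    keep = ~(((nd1 == 0) & (nd2 == 0)) |
             ((nd1 == 2 * st.n1) & (nd2 == 2 * st.n2)))
    data = pd.DataFrame({"locus_id": st.data["locus_id"].to_numpy()[keep],
                         "pos": st.data["pos"].to_numpy()[keep],
                         "dac1": nd1[keep], "dac2": nd2[keep]})
    out = SiteTable(data=data, n1=st.n1, n2=st.n2,
                    n_locus=st.n_locus, provenance=st.provenance)
    if return_flips:
        return out, flips
    return out


def simulate_summary(sp: ScenarioParams, layout: SimLayout, scheme: str,
                     rng: np.random.Generator | int | None = None) -> BinnedSummary:
    """One reference-table row: simulate, misorient, summarize.

    Deterministic under a fixed seed. The jSFS schemes use the fast counts
    path; the mscalc scheme needs haplotypes and is correspondingly
    slower.
    """
    rng = np.random.default_rng(rng)
    if scheme in ("jsfs4", "jsfs7", "jsfs23"):
        st = simulate_counts(sp, layout, rng)
        st = apply_misorientation(st, sp.e, rng)
        return bin_jsfs(build_jsfs(st), scheme)
    if scheme == "mscalc":
        _st, loci = simulate_dataset(sp, layout, rng)
        stats = []
        n1h = 2 * layout.n1
        for loc in loci:
            full1 = np.zeros((n1h, loc.length_bp), dtype=np.int8)
            full2 = np.zeros((2 * layout.n2, loc.length_bp), dtype=np.int8)
            if len(loc.positions):
                full1[:, loc.positions] = loc.genotypes[:, :n1h].T
                full2[:, loc.positions] = loc.genotypes[:, n1h:].T
            stats.append(locus_stats(full1, full2, loc.length_bp))
        vec = aggregate_mscalc(stats).as_vector()
        return BinnedSummary("mscalc", vec)
    raise ValueError(f"unknown scheme {scheme!r}")
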