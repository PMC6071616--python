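"""The unfolded joint SFS, its 4/7/23-class binnings, and mscalc statistics.

The joint site frequency spectrum (jSFS) tabulates SNPs by the number of
copies of the derived allele in each species. Because only sites with two
distinct alleles in the inter-specific alignment are observable, the cells
{0;0} and {2n1;2n2} are masked.

Three decompositions serve as ABC summary-statistic vectors:

``jsfs4``
    the Wakeley–Hey classes — fixed differences (Sf), private
    polymorphisms of each species (Sx1, Sx2), shared polymorphisms (Ss);
``jsfs7``
    Sf split by which species carries the derived fixation (sfA, sfB) and
    each Sx split by the other species' state (derived absent: sxA, sxB;
    derived fixed: sxfA, sxfB), plus ss;
``jsfs23``
    the cross-tabulation of per-species frequency categories
    {absent, singleton, doubleton, intermediate, fixed} (5 x 5 minus the
    two masked corners = 23 cells). For n = 2 diploids per species this is
    the full spectrum.

The alternative "mscalc" summary is the across-locus mean and standard
deviation of classical per-locus statistics (S and its classes, pi,
Watterson's theta, Tajima's D, FST, divergence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SiteTable

SCHEMES = ("jsfs4", "jsfs7", "jsfs23", "mscalc")

CATEGORIES = ("absent", "singleton", "doubleton", "mid", "fixed")
_POLY = ("singleton", "doubleton", "mid")
_POLY_SUFFIX = {"singleton": "1", "doubleton": "2", "mid": "m"}

JSFS4_NAMES = ("Sf", "Sx1", "Sx2", "Ss")
JSFS7_NAMES = ("sfA", "sfB", "sxA", "sxB", "sxfA", "sxfB", "ss")


def _cell_name(ca: str, cb: str) -> str | None:
    """Name of a 23-class cell from the two frequency categories.

    Letter convention follows the printed class names: ``sf``/``sx`` cells
    carry the letter of the species holding the derived allele
    (fixed/polymorphic respectively); ``ssf`` cells — polymorphic in one
    species, derived fixed in the other — carry the letter of the species
    where it is fixed, with ``_1``/``_2`` refining singletons/doubletons
    of the polymorphic species (e.g. ``ssfB_2``); ``ss`` cells are suffixed
    by both species' categories.
    """
    if ca == "absent" and cb == "absent":
        return None
    if ca == "fixed" and cb == "fixed":
        return None
    if ca == "fixed" and cb == "absent":
        return "sfA"
    if ca == "absent" and cb == "fixed":
        return "sfB"
    if cb == "absent":  # polymorphic in A only
        return "sxA" if ca == "mid" else f"sxA_{_POLY_SUFFIX[ca]}"
    if ca == "absent":
        return "sxB" if cb == "mid" else f"sxB_{_POLY_SUFFIX[cb]}"
    if cb == "fixed":  # polymorphic in A, derived fixed in B
        return "ssfB" if ca == "mid" else f"ssfB_{_POLY_SUFFIX[ca]}"
    if ca == "fixed":
        return "ssfA" if cb == "mid" else f"ssfA_{_POLY_SUFFIX[cb]}"
    return f"ss_{_POLY_SUFFIX[ca]}{_POLY_SUFFIX[cb]}"


JSFS23_NAMES = tuple(
    n for n in (
        "sfA", "sfB",
        "sxA_1", "sxA_2", "sxA", "sxB_1", "sxB_2", "sxB",
        "ssfA_1", "ssfA_2", "ssfA", "ssfB_1", "ssfB_2", "ssfB",
        "ss_11", "ss_12", "ss_1m", "ss_21", "ss_22", "ss_2m",
        "ss_m1", "ss_m2", "ss_mm",
    )
)

#: Exact regrouping of the 23 classes into the 7, and of the 7 into the 4.
JSFS23_TO_7 = {
    "sfA": ("sfA",), "sfB": ("sfB",),
    "sxA": ("sxA_1", "sxA_2", "sxA"), "sxB": ("sxB_1", "sxB_2", "sxB"),
    "sxfA": ("ssfB_1", "ssfB_2", "ssfB"),  # polymorphic in A, fixed in B
    "sxfB": ("ssfA_1", "ssfA_2", "ssfA"),
    "ss": ("ss_11", "ss_12", "ss_1m", "ss_21", "ss_22", "ss_2m",
           "ss_m1", "ss_m2", "ss_mm"),
}
JSFS7_TO_4 = {
    "Sf": ("sfA", "sfB"),
    "Sx1": ("sxA", "sxfA"),
    "Sx2": ("sxB", "sxfB"),
    "Ss": ("ss",),
}


@dataclass
class JSFS:
    """Unfolded joint SFS: ``matrix[i, j]`` counts SNPs with ``i`` derived
    copies in species 1 (of ``2 n1``) and ``j`` in species 2 (of ``2 n2``).
    """

    matrix: np.ndarray
    n1: int
    n2: int

    def __post_init__(self) -> None:
        expected = (2 * self.n1 + 1, 2 * self.n2 + 1)
        if self.matrix.shape != expected:
            raise ValueError(f"jSFS shape {self.matrix.shape} != {expected}")
        if (self.matrix < 0).any():
            raise ValueError("negative cell counts")
        if self.matrix[0, 0] != 0 or self.matrix[-1, -1] != 0:
            raise ValueError("masked corner cells must be zero")

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


@dataclass
class BinnedSummary:
    """A named statistic vector under one binning scheme (fixed order)."""

    scheme: str
    values: pd.Series

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        expected = {"jsfs4": JSFS4_NAMES, "jsfs7": JSFS7_NAMES,
                    "jsfs23": JSFS23_NAMES}.get(self.scheme)
        if expected is not None and tuple(self.values.index) != expected:
            raise ValueError(f"{self.scheme} entries must be {expected}")

    @property
    def total(self) -> float:
        return float(self.values.sum())


def build_jsfs(st: SiteTable) -> JSFS:
    """Tally a SiteTable into the joint SFS matrix."""
    matrix = np.zeros((2 * st.n1 + 1, 2 * st.n2 + 1), dtype=np.int64)
    d1, d2 = st.counts()
    np.add.at(matrix, (d1, d2), 1)
    return JSFS(matrix=matrix, n1=st.n1, n2=st.n2)


def categorize_count(k: int, two_n: int) -> str:
    """Frequency category of a derived count among ``two_n`` haplotypes.

    ``absent`` (0), ``singleton`` (1), ``doubleton`` (2), ``fixed``
    (``two_n``), ``mid`` otherwise. A count equal to both 2 and
    ``two_n - 2`` is a doubleton (the doubleton class takes precedence);
    a count equal to ``two_n`` is fixed even when ``two_n`` is 2.
    """
    if not 0 <= k <= two_n:
        raise ValueError(f"count {k} out of range 0..{two_n}")
    if k == 0:
        return "absent"
    if k == two_n:
        return "fixed"
    if k == 1:
        return "singleton"
    if k == 2:
        return "doubleton"
    return "mid"


def bin_jsfs(j: JSFS, scheme: str) -> BinnedSummary:
    """Bin the joint SFS into one of the summary schemes."""
    if scheme not in ("jsfs4", "jsfs7", "jsfs23"):
        raise ValueError(f"unknown binning scheme {scheme!r}")
    counts = dict.fromkeys(JSFS23_NAMES, 0)
    for i in range(2 * j.n1 + 1):
        ca = categorize_count(i, 2 * j.n1)
        for jj in range(2 * j.n2 + 1):
            cb = categorize_count(jj, 2 * j.n2)
            name = _cell_name(ca, cb)
            if name is not None:
                counts[name] += int(j.matrix[i, jj])
    s23 = pd.Series(counts, index=list(JSFS23_NAMES))
    if scheme == "jsfs23":
        return BinnedSummary("jsfs23", s23)
    s7 = pd.Series({k: s23[list(v)].sum() for k, v in JSFS23_TO_7.items()},
                   index=list(JSFS7_NAMES))
    if scheme == "jsfs7":
        return BinnedSummary("jsfs7", s7)
    s4 = pd.Series({k: s7[list(v)].sum() for k, v in JSFS7_TO_4.items()},
                   index=list(JSFS4_NAMES))
    return BinnedSummary("jsfs4", s4)


def rebin(summary: BinnedSummary, scheme: str) -> BinnedSummary:
    """Regroup a finer binned summary into a coarser one (23 -> 7 -> 4)."""
    if summary.scheme == scheme:
        return summary
    if summary.scheme == "jsfs23":
        s7 = pd.Series({k: summary.values[list(v)].sum()
                        for k, v in JSFS23_TO_7.items()}, index=list(JSFS7_NAMES))
        if scheme == "jsfs7":
            return BinnedSummary("jsfs7", s7)
        summary = BinnedSummary("jsfs7", s7)
    if summary.scheme == "jsfs7" and scheme == "jsfs4":
        s4 = pd.Series({k: summary.values[list(v)].sum()
                        for k, v in JSFS7_TO_4.items()}, index=list(JSFS4_NAMES))
        return BinnedSummary("jsfs4", s4)
    raise ValueError(f"cannot regroup {summary.scheme} into {scheme}")


# --- per-locus statistics (the "mscalc" scheme) ----------------------------

LOCUS_STAT_NAMES = ("S", "Sf", "Sx1", "Sx2", "Ss", "pi1", "pi2",
                    "thetaW1", "thetaW2", "D1", "D2", "FST", "div", "netdiv")


@dataclass
class LocusStats:
    """Classical polymorphism/divergence statistics for one locus.

    Counts (S and its Wakeley–Hey decomposition) are per locus;
    diversities (pi, Watterson's theta, div, netdiv) are per bp. ``D1``,
    ``D2`` and ``FST`` may be undefined (NaN) on degenerate loci.
    """

    S: int
    Sf: int
    Sx1: int
    Sx2: int
    Ss: int
    pi1: float
    pi2: float
    thetaW1: float
    thetaW2: float
    D1: float
    D2: float
    FST: float
    div: float
    netdiv: float

    def as_series(self) -> pd.Series:
        return pd.Series({k: getattr(self, k) for k in LOCUS_STAT_NAMES})


def _harmonic(k: int) -> float:
    return sum(1.0 / i for i in range(1, k + 1))


def _pairwise_diff_total(h: np.ndarray) -> float:
    """Sum of pairwise differences over all haplotype pairs (count units)."""
    m = h.shape[0]
    total = 0
    for a in range(m):
        for b in range(a + 1, m):
            total += int((h[a] != h[b]).sum())
    return float(total)


def _tajimas_d(S: int, pi_count: float, m: int) -> float:
    if S == 0 or m < 2:
        return math.nan
    a1 = _harmonic(m - 1)
    a2 = sum(1.0 / i**2 for i in range(1, m))
    b1 = (m + 1) / (3.0 * (m - 1))
    b2 = 2.0 * (m**2 + m + 3) / (9.0 * m * (m - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (m + 2) / (a1 * m) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    return (pi_count - S / a1) / math.sqrt(var)


def locus_stats(hap1: np.ndarray | list[str], hap2: np.ndarray | list[str],
                length_bp: int | None = None) -> LocusStats:
    """Compute :class:`LocusStats` from the two species' haplotypes.

    ``hap1``/``hap2`` are lists of equal-length sequences or 2-D character
    (or integer) arrays of shape (haplotypes, sites). Pairwise statistics
    need no outgroup: the Wakeley–Hey classes are defined by within- and
    between-species segregation alone.
    """
    h1 = np.array([list(s) for s in hap1]) if isinstance(hap1[0], str) else np.asarray(hap1)
    h2 = np.array([list(s) for s in hap2]) if isinstance(hap2[0], str) else np.asarray(hap2)
    if h1.shape[1] != h2.shape[1]:
        raise ValueError("species haplotypes differ in length")
    L = length_bp if length_bp is not None else h1.shape[1]
    if L <= 0:
        raise ValueError("zero-length locus")
    m1, m2 = h1.shape[0], h2.shape[0]
    if m1 < 2 or m2 < 2:
        raise ValueError("need >= 2 haplotypes per species")

    poly1 = np.array([len(set(h1[:, c])) > 1 for c in range(h1.shape[1])])
    poly2 = np.array([len(set(h2[:, c])) > 1 for c in range(h2.shape[1])])
    pooled = np.vstack([h1, h2])
    poly_t = np.array([len(set(pooled[:, c])) > 1 for c in range(pooled.shape[1])])

    S = int(poly_t.sum())
    Ss = int((poly1 & poly2).sum())
    Sx1 = int((poly1 & ~poly2).sum())
    Sx2 = int((poly2 & ~poly1).sum())
    Sf = S - Ss - Sx1 - Sx2  # fixed differences: segregating pooled, mono within each

    S1 = int(poly1.sum())
    S2 = int(poly2.sum())
    pi1_count = _pairwise_diff_total(h1) / (m1 * (m1 - 1) / 2)
    pi2_count = _pairwise_diff_total(h2) / (m2 * (m2 - 1) / 2)
    pi1 = pi1_count / L
    pi2 = pi2_count / L
    thetaW1 = S1 / (_harmonic(m1 - 1) * L)
    thetaW2 = S2 / (_harmonic(m2 - 1) * L)

    between = 0
    for a in range(m1):
        for b in range(m2):
            between += int((h1[a] != h2[b]).sum())
    div = between / (m1 * m2) / L
    netdiv = div - (pi1 + pi2) / 2.0

    mt = m1 + m2
    piT = _pairwise_diff_total(pooled) / (mt * (mt - 1) / 2) / L
    piS = (pi1 + pi2) / 2.0
    FST = math.nan if piT == 0 else 1.0 - piS / piT

    return LocusStats(S=S, Sf=Sf, Sx1=Sx1, Sx2=Sx2, Ss=Ss, pi1=pi1, pi2=pi2,
                      thetaW1=thetaW1, thetaW2=thetaW2,
                      D1=_tajimas_d(S1, pi1_count, m1),
                      D2=_tajimas_d(S2, pi2_count, m2),
                      FST=FST, div=div, netdiv=netdiv)


@dataclass
class MscalcSummary:
    """Across-locus mean and SD of every per-locus statistic.

    Undefined per-locus entries (e.g. Tajima's D on a monomorphic locus)
    are excluded; ``n_defined`` reports how many loci contributed to each
    statistic. The SD is the population SD (divide by the number of loci),
    switchable via ``ddof``.
    """

    mean: pd.Series
    sd: pd.Series
    n_defined: pd.Series
    ddof: int = 0

    def as_vector(self) -> pd.Series:
        out = {}
        for name in LOCUS_STAT_NAMES:
            out[f"{name}_avg"] = self.mean[name]
            out[f"{name}_std"] = self.sd[name]
        return pd.Series(out)


def aggregate_mscalc(stats: list[LocusStats], ddof: int = 0) -> MscalcSummary:
    """Mean and SD of each statistic across loci where it is defined."""
    if not stats:
        raise ValueError("need at least one locus")
    frame = pd.DataFrame([s.as_series() for s in stats])
    n_def = frame.notna().sum()
    mean = frame.mean(skipna=True)
    sd = frame.std(skipna=True, ddof=ddof).fillna(0.0)
    return MscalcSummary(mean=mean, sd=sd, n_defined=n_def, ddof=ddof)
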