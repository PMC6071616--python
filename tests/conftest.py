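import numpy as np
import pandas as pd
import pytest

from divabc.io import LocusAlignment, LocusSet, SiteTable


def make_locus(locus_id: str, seqs_sp1: list[str], seqs_sp2: list[str],
               outgroup: str, annotations=None) -> LocusAlignment:
    """Build a LocusAlignment from per-species haplotype strings.

    Consecutive pairs of strings form one diploid individual.
    """
    sequences = {}
    for k, s in enumerate(seqs_sp1):
        sequences[("sp1", f"ind{k // 2}", k % 2)] = s
    for k, s in enumerate(seqs_sp2):
        sequences[("sp2", f"ind{k // 2}", k % 2)] = s
    sequences[("outgroup", "ind0", 0)] = outgroup
    return LocusAlignment(locus_id=locus_id, length_bp=len(outgroup),
                          sequences=sequences, site_annotations=annotations)


def make_site_table(rows, n1=2, n2=2) -> SiteTable:
    data = pd.DataFrame(rows, columns=["locus_id", "pos", "dac1", "dac2"])
    return SiteTable(data=data, n1=n1, n2=n2, n_locus=data["locus_id"].nunique())


def random_site_table(rng: np.random.Generator, n_rows: int, n1=2, n2=2) -> SiteTable:
    d1 = rng.integers(0, 2 * n1 + 1, size=n_rows)
    d2 = rng.integers(0, 2 * n2 + 1, size=n_rows)
    bad = ((d1 == 0) & (d2 == 0)) | ((d1 == 2 * n1) & (d2 == 2 * n2))
    d1[bad] = 1  # move masked-corner draws to a legal cell
    rows = [("locus_0", i, int(a), int(b)) for i, (a, b) in enumerate(zip(d1, d2))]
    return make_site_table(rows, n1=n1, n2=n2)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
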