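"""Reading per-locus alignments, applying site/locus filters, polarizing SNPs.

The observed unit of data is a set of per-locus multiple alignments of two
focal species plus an outgroup. Sites are filtered (no missing data, at
most two alleles across the three-species alignment, optionally synonymous
positions only), loci shorter than 300 bp after filtering are dropped, and
each remaining segregating site is polarized by treating the outgroup
allele as the fixed ancestral state. The result is a :class:`SiteTable` of
per-SNP derived-allele counts in each species — the input to every
downstream summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGT")
SPECIES = ("sp1", "sp2", "outgroup")


@dataclass
class LocusAlignment:
    """Aligned haplotypes for one locus.

    ``sequences`` maps ``(species, individual, haplotype_index)`` to an
    upper-case nucleotide string; every diploid focal individual
    contributes exactly two haplotypes, the outgroup at least one.
    ``site_annotations`` optionally flags each column as ``"synonymous"``,
    ``"other"`` or ``"unknown"``.
    """

    locus_id: str
    length_bp: int
    sequences: dict[tuple[str, str, int], str]
    site_annotations: list[str] | None = None

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.locus_id}: non-positive length")
        lengths = {len(s) for s in self.sequences.values()}
        if lengths != {self.length_bp}:
            raise ValueError(
                f"{self.locus_id}: sequences have unequal lengths {sorted(lengths)}"
            )
        if self.site_annotations is not None and len(self.site_annotations) != self.length_bp:
            raise ValueError(f"{self.locus_id}: annotation length mismatch")
        for sp in ("sp1", "sp2"):
            for ind in self.individuals(sp):
                k = sum(1 for (s, i, _h) in self.sequences if s == sp and i == ind)
                if k != 2:
                    raise ValueError(
                        f"{self.locus_id}: {sp}/{ind} has {k} haplotypes, expected 2"
                    )
        if not self.individuals("outgroup"):
            raise ValueError(f"{self.locus_id}: no outgroup haplotype")

    def individuals(self, species: str) -> list[str]:
        return sorted({i for (s, i, _h) in self.sequences if s == species})

    def haplotypes(self, species: str) -> list[str]:
        """Haplotype strings of one species in canonical (individual, index) order."""
        keys = sorted(k for k in self.sequences if k[0] == species)
        return [self.sequences[k] for k in keys]

    def column(self, pos: int) -> dict[str, list[str]]:
        return {sp: [h[pos] for h in self.haplotypes(sp)] for sp in SPECIES}


@dataclass
class LocusSet:
    """An ordered collection of loci with constant sample sizes."""

    loci: list[LocusAlignment]
    n1: int
    n2: int
    provenance: str = ""

    def __post_init__(self) -> None:
        for loc in self.loci:
            if len(loc.individuals("sp1")) != self.n1 or len(loc.individuals("sp2")) != self.n2:
                raise ValueError(
                    f"{loc.locus_id}: sample sizes differ from the set's (n1={self.n1}, n2={self.n2})"
                )

    @property
    def n_locus(self) -> int:
        return len(self.loci)


@dataclass
class SiteTable:
    """Polarized derived-allele counts per SNP.

    One row per SNP: ``locus_id``, 0-based ``pos`` within the locus, and
    the derived-allele counts ``dac1`` (0..2*n1) and ``dac2`` (0..2*n2).
    The masked joint-spectrum corners — derived absent in both species
    ({0;0}) or fixed in both ({2n;2n}) — never appear.
    """

    data: pd.DataFrame
    n1: int
    n2: int
    n_locus: int = 0
    provenance: str = ""

    COLUMNS = ("locus_id", "pos", "dac1", "dac2")

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        if list(self.data.columns) != list(self.COLUMNS):
            raise ValueError(f"SiteTable columns must be {self.COLUMNS}")
        d1 = self.data["dac1"].to_numpy()
        d2 = self.data["dac2"].to_numpy()
        if ((d1 < 0) | (d1 > 2 * self.n1) | (d2 < 0) | (d2 > 2 * self.n2)).any():
            raise ValueError("derived counts out of range")
        both_zero = (d1 == 0) & (d2 == 0)
        both_max = (d1 == 2 * self.n1) & (d2 == 2 * self.n2)
        if both_zero.any() or both_max.any():
            raise ValueError("masked corner rows {0;0} / {2n;2n} are not allowed")

    @property
    def n_snp(self) -> int:
        return len(self.data)

    def counts(self) -> tuple[np.ndarray, np.ndarray]:
        return (self.data["dac1"].to_numpy(np.int64),
                self.data["dac2"].to_numpy(np.int64))

    # --- tabular round-trip -------------------------------------------------

    def write(self, tsv_path: str | Path) -> None:
        """Write TSV plus a JSON sidecar carrying n1, n2, n_locus, provenance."""
        tsv_path = Path(tsv_path)
        self.data.to_csv(tsv_path, sep="\t", index=False)
        sidecar = tsv_path.with_suffix(tsv_path.suffix + ".json")
        sidecar.write_text(json.dumps(
            {"n1": self.n1, "n2": self.n2, "n_locus": self.n_locus,
             "provenance": self.provenance}, indent=1))

    @classmethod
    def read(cls, tsv_path: str | Path) -> "SiteTable":
        tsv_path = Path(tsv_path)
        data = pd.read_csv(tsv_path, sep="\t",
                           dtype={"locus_id": str, "pos": np.int64,
                                  "dac1": np.int64, "dac2": np.int64})
        meta = json.loads(tsv_path.with_suffix(tsv_path.suffix + ".json").read_text())
        return cls(data=data, n1=int(meta["n1"]), n2=int(meta["n2"]),
                   n_locus=int(meta.get("n_locus", 0)),
                   provenance=meta.get("provenance", ""))


@dataclass
class FilterAudit:
    """Per-locus record of what the site/locus filters removed and why."""

    records: list[dict] = field(default_factory=list)
    n_dropped_outgroup_polymorphic: int = 0
    n_dropped_third_allele_outgroup: int = 0

    def log(self, locus_id: str, action: str, **detail) -> None:
        self.records.append({"locus_id": locus_id, "action": action, **detail})

    def dropped_loci(self) -> list[str]:
        return [r["locus_id"] for r in self.records if r["action"] == "drop_locus"]


# --- reading ---------------------------------------------------------------


def read_locus_alignments(paths: Iterable[str | Path],
                          sample_map: Mapping[str, tuple[str, str]],
                          provenance: str = "") -> LocusSet:
    """Read one multi-FASTA per locus into a :class:`LocusSet`.

    ``sample_map`` maps each FASTA record name to ``(species, individual)``
    with species one of ``sp1``/``sp2``/``outgroup``; the two haplotypes of
    a diploid individual are numbered in file order. Unmapped names and
    unequal sequence lengths are hard errors.
    """
    loci: list[LocusAlignment] = []
    n1 = n2 = None
    for path in sorted(Path(p) for p in paths):
        counters: dict[tuple[str, str], int] = {}
        sequences: dict[tuple[str, str, int], str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id not in sample_map:
                raise KeyError(
                    f"{path.name}: sequence {rec.id!r} is absent from the sample map")
            species, individual = sample_map[rec.id]
            if species not in SPECIES:
                raise ValueError(f"{rec.id}: unknown species {species!r}")
            h = counters.get((species, individual), 0)
            counters[(species, individual)] = h + 1
            sequences[(species, individual, h)] = str(rec.seq).upper()
        if not sequences:
            raise ValueError(f"{path}: empty FASTA")
        length = len(next(iter(sequences.values())))
        loc = LocusAlignment(locus_id=path.stem, length_bp=length, sequences=sequences)
        if n1 is None:
            n1, n2 = len(loc.individuals("sp1")), len(loc.individuals("sp2"))
        loci.append(loc)
    if n1 is None:
        raise ValueError("no loci read")
    return LocusSet(loci=loci, n1=n1, n2=n2, provenance=provenance)


# --- filtering -------------------------------------------------------------


def _column_alleles(loc: LocusAlignment, pos: int) -> list[str]:
    return [h[pos] for sp in SPECIES for h in loc.haplotypes(sp)]


def filter_loci(ls: LocusSet, min_len: int = 300,
                synonymous_only: bool = False) -> tuple[LocusSet, FilterAudit]:
    """Apply the site and locus filters.

    Per locus, columns containing missing/ambiguous bases or more than two
    distinct alleles across the three-species alignment are removed; with
    ``synonymous_only`` columns not flagged synonymous are removed too.
    Loci whose remaining length falls below ``min_len`` are dropped. The
    returned audit log lists every removal with its reason. Idempotent.
    """
    audit = FilterAudit()
    kept: list[LocusAlignment] = []
    for loc in ls.loci:
        keep_cols: list[int] = []
        n_missing = n_multi = n_nonsyn = 0
        for pos in range(loc.length_bp):
            alleles = _column_alleles(loc, pos)
            if any(a not in VALID_BASES for a in alleles):
                n_missing += 1
                continue
            if len(set(alleles)) > 2:
                n_multi += 1
                continue
            if synonymous_only:
                ann = (loc.site_annotations[pos]
                       if loc.site_annotations is not None else "unknown")
                if ann != "synonymous":
                    n_nonsyn += 1
                    continue
            keep_cols.append(pos)
        if n_missing or n_multi or n_nonsyn:
            audit.log(loc.locus_id, "remove_columns", missing=n_missing,
                      multiallelic=n_multi, non_synonymous=n_nonsyn)
        if len(keep_cols) < min_len:
            audit.log(loc.locus_id, "drop_locus",
                      remaining_bp=len(keep_cols), min_len=min_len)
            continue
        if len(keep_cols) == loc.length_bp:
            kept.append(loc)
            continue
        new_sequences = {k: "".join(s[p] for p in keep_cols)
                         for k, s in loc.sequences.items()}
        new_ann = ([loc.site_annotations[p] for p in keep_cols]
                   if loc.site_annotations is not None else None)
        kept.append(LocusAlignment(locus_id=loc.locus_id, length_bp=len(keep_cols),
                                   sequences=new_sequences, site_annotations=new_ann))
    return LocusSet(loci=kept, n1=ls.n1, n2=ls.n2, provenance=ls.provenance), audit


# degeneracy of the third codon position per leading dinucleotide: codons
# whose first two bases fix the amino acid regardless of the third base
_FOURFOLD_PREFIXES = {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"}


def annotate_synonymous(loc: LocusAlignment, frame: int = 0) -> LocusAlignment:
    """Flag four-fold degenerate third codon positions as synonymous.

    A conservative built-in alternative to external annotations: a column
    is flagged "synonymous" when it is the third position of a codon
    (relative to ``frame``) whose first two bases are identical across
    all haplotypes and four-fold degenerate; every other column is
    "other". Returns a new alignment with annotations attached.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    seqs = list(loc.sequences.values())
    ann = ["other"] * loc.length_bp
    for pos in range(frame + 2, loc.length_bp, 3):
        prefixes = {s[pos - 2:pos].upper() for s in seqs}
        if len(prefixes) == 1 and prefixes.pop() in _FOURFOLD_PREFIXES:
            ann[pos] = "synonymous"
    return LocusAlignment(locus_id=loc.locus_id, length_bp=loc.length_bp,
                          sequences=dict(loc.sequences), site_annotations=ann)


def read_vcf_sites(path: str | Path, sp1_samples: list[str],
                   sp2_samples: list[str], outgroup_sample: str,
                   n_locus: int = 0, provenance: str = "") -> SiteTable:
    """Convenience VCF ingestion: biallelic complete-call diploid sites.

    The CHROM field is the locus id, POS is converted to 0-based. Sites
    with missing calls, more than two alleles, or a heterozygous/missing
    outgroup genotype are skipped; the outgroup's (homozygous) allele is
    ancestral. Phasing, half-calls and other VCF subtleties are out of
    scope.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    i1 = [samples.index(s) for s in sp1_samples]
    i2 = [samples.index(s) for s in sp2_samples]
    io_ = samples.index(outgroup_sample)
    rows = []
    n1, n2 = len(i1), len(i2)
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        gt = np.asarray(v.genotype.array())[:, :2]
        if (gt < 0).any():
            continue  # missing call somewhere
        out = gt[io_]
        if out[0] != out[1]:
            continue  # polymorphic outgroup treated as unresolvable
        anc = out[0]
        d1 = int((gt[i1] != anc).sum())
        d2 = int((gt[i2] != anc).sum())
        if (d1 == 0 and d2 == 0) or (d1 == 2 * n1 and d2 == 2 * n2):
            continue
        rows.append((v.CHROM, v.POS - 1, d1, d2))
    data = pd.DataFrame(rows, columns=list(SiteTable.COLUMNS))
    if data.empty:
        data = data.astype({"locus_id": str, "pos": np.int64,
                            "dac1": np.int64, "dac2": np.int64})
    return SiteTable(data=data, n1=n1, n2=n2, n_locus=n_locus,
                     provenance=provenance)


# --- polarization ----------------------------------------------------------


def polarize(ls: LocusSet, audit: FilterAudit | None = None) -> SiteTable:
    """Polarize every segregating filtered column into a SiteTable row.

    The outgroup allele is declared ancestral. Columns where the outgroup
    sample is itself polymorphic, or carries neither focal allele, are
    dropped and counted. Rows in the masked jSFS corners are excluded (a
    {0;0} row cannot arise; a {2n;2n} row arises when both species are
    fixed for a non-outgroup allele).
    """
    audit = audit if audit is not None else FilterAudit()
    rows = []
    for loc in ls.loci:
        h1 = loc.haplotypes("sp1")
        h2 = loc.haplotypes("sp2")
        ho = loc.haplotypes("outgroup")
        if not ho:
            raise ValueError(f"{loc.locus_id}: locus with zero outgroup haplotypes")
        a1 = np.array([list(h) for h in h1])
        a2 = np.array([list(h) for h in h2])
        ao = np.array([list(h) for h in ho])
        for pos in range(loc.length_bp):
            col_focal = np.concatenate([a1[:, pos], a2[:, pos]])
            alleles = set(col_focal) | set(ao[:, pos])
            if len(alleles) < 2:
                continue  # monomorphic across the three species
            out_alleles = set(ao[:, pos])
            if len(out_alleles) > 1:
                audit.n_dropped_outgroup_polymorphic += 1
                continue
            anc = next(iter(out_alleles))
            focal_alleles = set(col_focal)
            if anc not in focal_alleles:
                # outgroup carries a third (private) allele; under the
                # two-allele filter this means both focal species share one
                # allele and the site is uninformative for polarization
                audit.n_dropped_third_allele_outgroup += 1
                continue
            derived = focal_alleles - {anc}
            if not derived:
                continue  # focal species monomorphic for the ancestral allele
            d = next(iter(derived))
            dac1 = int((a1[:, pos] == d).sum())
            dac2 = int((a2[:, pos] == d).sum())
            if (dac1 == 0 and dac2 == 0) or (dac1 == 2 * ls.n1 and dac2 == 2 * ls.n2):
                continue  # masked corners
            rows.append((loc.locus_id, pos, dac1, dac2))
    data = pd.DataFrame(rows, columns=list(SiteTable.COLUMNS))
    if data.empty:
        data = data.astype({"locus_id": str, "pos": np.int64,
                            "dac1": np.int64, "dac2": np.int64})
    return SiteTable(data=data, n1=ls.n1, n2=ls.n2,
                     n_locus=ls.n_locus, provenance=ls.provenance)
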