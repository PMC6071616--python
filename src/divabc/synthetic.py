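"""Study-like synthetic datasets with known ground truth.

Generates concrete per-locus FASTA files (two focal species plus one
outgroup haplotype) by threading simulated mutations onto random
background sequence, together with the true SiteTable and a truth
manifest, so the whole read/filter/polarize/summarize pipeline is
testable without external downloads. Presets mirror the two study
layouts: "exome capture" (512-557 loci, ~4,000-5,100 SNPs) and "rna-seq"
(1,842-2,147 loci, ~17,300-17,900 SNPs) at n = 2, 4 or 8 diploid
individuals per species.

Background sequences are uniform random nucleotides; codon structure is
not emulated (the downstream statistics depend only on site counts, and
simulated sites are neutral by construction, so every site is treated as
eligible). The outgroup carries the true ancestral allele everywhere
except at misoriented sites, where it carries the derived allele —
exactly reproducing the polarization error the misorientation parameter
models. Optional corruption knobs inject missing bases and third alleles
at known rates to exercise the documented filters, and private outgroup
mutations to exercise the third-allele drop rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import SiteTable
from .scenarios import PriorConfig, ScenarioParams, sample_prior
from .simulate import (LocusSim, SimLayout, apply_misorientation,
                       simulate_counts, simulate_dataset, simulate_summary)
from .summaries import bin_jsfs, build_jsfs

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class DatasetPreset:
    """One study layout: locus count, sample size and target SNP scale."""

    name: str
    n_loci: int
    n: int                      # diploid individuals per species (n1 = n2)
    snp_target: tuple[int, int]
    locus_length: int = 500


PRESETS = {p.name: p for p in (
    DatasetPreset("exome_n2", 516, 2, (3900, 5100)),
    DatasetPreset("exome_n4", 557, 4, (3900, 5100)),
    DatasetPreset("exome_n8", 512, 8, (3900, 5100)),
    DatasetPreset("rnaseq_n2", 2147, 2, (17200, 17950)),
    DatasetPreset("rnaseq_n4", 1842, 4, (17200, 17950)),
)}


def preset_layout(preset: DatasetPreset | str, **kwargs) -> SimLayout:
    p = PRESETS[preset] if isinstance(preset, str) else preset
    return SimLayout(n_loci=p.n_loci, n1=p.n, n2=p.n,
                     locus_length=p.locus_length, **kwargs)


def calibrate_theta(preset: DatasetPreset | str, sp: ScenarioParams,
                    seed: int = 0, pilot_loci: int = 40) -> ScenarioParams:
    """Scale the theta ratios so the simulated SNP total hits the preset's.

    The expected number of segregating sites is linear in theta
    (Watterson), so a small pilot simulation at the drawn parameters
    yields the scaling factor directly.
    """
    p = PRESETS[preset] if isinstance(preset, str) else preset
    pilot = SimLayout(n_loci=pilot_loci, n1=p.n, n2=p.n,
                      locus_length=p.locus_length)
    st = simulate_counts(sp, pilot, np.random.default_rng(seed))
    per_locus = st.n_snp / pilot_loci
    target_per_locus = (p.snp_target[0] + p.snp_target[1]) / 2.0 / p.n_loci
    if per_locus == 0:
        raise ValueError("pilot simulation produced no SNPs; theta too small")
    f = target_per_locus / per_locus
    d = sp.to_dict()
    for k in ("theta_anc", "theta_1", "theta_2"):
        d[k] *= f
    return ScenarioParams(**d)


def _write_locus_fasta(path: Path, loc: LocusSim, n1: int, n2: int,
                       background: np.ndarray, derived: np.ndarray,
                       outgroup_has_derived: np.ndarray) -> None:
    """Write one locus: focal haplotypes then a single outgroup haplotype."""
    seqs = []
    n1h, n2h = 2 * n1, 2 * n2
    for h in range(n1h + n2h):
        s = background.copy()
        if len(loc.positions):
            carry = loc.genotypes[:, h] == 1
            s[loc.positions[carry]] = derived[carry]
        seqs.append(s)
    out = background.copy()
    if len(loc.positions):
        out[loc.positions[outgroup_has_derived]] = derived[outgroup_has_derived]
    with open(path, "w") as fh:
        for h in range(n1h):
            fh.write(f">sp1_ind{h // 2}_h{h % 2}\n{''.join(seqs[h])}\n")
        for h in range(n2h):
            fh.write(f">sp2_ind{h // 2}_h{h % 2}\n{''.join(seqs[n1h + h])}\n")
        fh.write(f">outgroup_ind0_h0\n{''.join(out)}\n")


def default_sample_map(n1: int, n2: int) -> dict[str, tuple[str, str]]:
    """Sample map matching the FASTA record names this module writes."""
    sm: dict[str, tuple[str, str]] = {}
    for i in range(n1):
        for h in range(2):
            sm[f"sp1_ind{i}_h{h}"] = ("sp1", f"ind{i}")
    for i in range(n2):
        for h in range(2):
            sm[f"sp2_ind{i}_h{h}"] = ("sp2", f"ind{i}")
    sm["outgroup_ind0_h0"] = ("outgroup", "ind0")
    return sm


def generate_study_like_dataset(preset: DatasetPreset | str, sp: ScenarioParams,
                                seed: int, out_dir: str | Path,
                                n_loci: int | None = None,
                                missing_rate: float = 0.0,
                                third_allele_rate: float = 0.0,
                                ) -> tuple[SiteTable, dict]:
    """Write per-locus FASTA files, the true SiteTable, and a truth manifest.

    The returned SiteTable is the truth *after* misorientation — i.e. what
    error-free polarization by the written outgroup recovers. With
    ``missing_rate``/``third_allele_rate`` > 0, extra background positions
    are corrupted (an 'N' in one haplotype / a third allele) to trigger
    the site filters at a known rate.
    """
    p = PRESETS[preset] if isinstance(preset, str) else preset
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout = SimLayout(n_loci=n_loci or p.n_loci, n1=p.n, n2=p.n,
                       locus_length=p.locus_length)
    rng = np.random.default_rng(seed)
    st, loci = simulate_dataset(sp, layout, rng)
    st_obs, flips = apply_misorientation(st, sp.e, rng, return_flips=True)

    row = 0
    for loc in loci:
        L = loc.length_bp
        background = BASES[rng.integers(0, 4, size=L)]
        derived = np.empty(len(loc.positions), dtype="<U1")
        for k, pos in enumerate(loc.positions):
            anc = background[pos]
            derived[k] = rng.choice([b for b in "ACGT" if b != anc])
        n_sites = len(loc.positions)
        site_flips = flips[row:row + n_sites]
        row += n_sites
        _write_locus_fasta(out_dir / f"{loc.locus_id}.fasta", loc,
                           layout.n1, layout.n2, background, derived,
                           outgroup_has_derived=site_flips)
        if missing_rate > 0 or third_allele_rate > 0:
            _corrupt_locus(out_dir / f"{loc.locus_id}.fasta", loc, rng,
                           missing_rate, third_allele_rate)

    st_obs.write(out_dir / "sites_truth.tsv")
    manifest = {"preset": p.name, "seed": seed, "params": sp.to_dict(),
                "gff": [loc.gff for loc in loci],
                "n_snp_truth": st_obs.n_snp,
                "n_misoriented": int(flips.sum()),
                "missing_rate": missing_rate,
                "third_allele_rate": third_allele_rate}
    (out_dir / "truth.json").write_text(json.dumps(manifest, indent=1))
    return st_obs, manifest


def _corrupt_locus(path: Path, loc: LocusSim, rng: np.random.Generator,
                   missing_rate: float, third_allele_rate: float) -> None:
    """Inject 'N's and third alleles at monomorphic background positions."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    L = loc.length_bp
    snp = set(loc.positions.tolist())
    eligible = [i for i in range(L) if i not in snp]
    seqs = [list(str(r.seq)) for r in records]
    for pos in eligible:
        r = rng.random()
        if r < missing_rate:
            seqs[rng.integers(0, len(seqs))][pos] = "N"
        elif r < missing_rate + third_allele_rate:
            present = {s[pos] for s in seqs}
            alt = [b for b in "ACGT" if b not in present]
            if len(alt) >= 2:
                i, j = rng.choice(len(seqs), size=2, replace=False)
                seqs[i][pos] = alt[0]
                seqs[j][pos] = alt[1]
    with open(path, "w") as fh:
        for r, s in zip(records, seqs):
            fh.write(f">{r.id}\n{''.join(s)}\n")


def make_pod_batch(models: list[tuple[str, str]], n_per_model: int,
                   layout: SimLayout, scheme: str, seed: int,
                   prior: PriorConfig | None = None,
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """Labelled batch of pseudo-observed summaries for CV experiments.

    Each POD derives its own stream from the master seed, so batches are
    reproducible and per-POD independent. ``prior`` defaults to the full
    study prior; pass :data:`divabc.scenarios.STRONG_CONTRAST` for
    informative-regime draws.
    """
    prior = prior or PriorConfig()
    stats_rows, labels = [], []
    root = np.random.SeedSequence(seed)
    for (model_id, mode), stream in zip(models, root.spawn(len(models))):
        for child in stream.spawn(n_per_model):
            rng = np.random.default_rng(child)
            sp = sample_prior(model_id, mode, prior, rng)
            stats_rows.append(simulate_summary(sp, layout, scheme, rng).values)
            labels.append(sp.label)
    return pd.DataFrame(stats_rows).reset_index(drop=True), np.array(labels)
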