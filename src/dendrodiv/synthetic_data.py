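"""Synthetic inputs with the statistical structure the analysis assumes.

Every pipeline stage can be exercised without downloads:

* two-species replicate log-expression matrices with a planted fraction of
  divergently expressed orthologs (the replicate design mirrors the study:
  9 arrays for species A, 14 for species B);
* many-to-many orthology instances — BLAST-style transcript hit tables,
  probe hit tables and probe-set memberships — together with the
  ground-truth metagene partition they encode;
* pairwise codon alignments evolved from a common ancestor under a Kimura
  two-parameter mutation process with selection (non-synonymous changes
  accepted with probability ω), with a complete substitution event log;
* soma→dendrite intensity transects at a planted D/S ratio with
  multiplicative pixel noise.

A single root seed derives per-component generators, so outputs are
bit-for-bit reproducible.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from dendrodiv.imaging_quant import TransectProfile
from dendrodiv.molevol import (
    STOP_CODONS,
    CodonAlignment,
    classify_codon_degeneracy,
    translate_codon,
)
from dendrodiv.ortholog_map import (
    BlastHit,
    MetageneMap,
    ProbeSet,
    metagene_map_from_components,
)

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def rng_children(seed: int, n: int) -> list[np.random.Generator]:
    """Independent generators derived from one root seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# -- expression -------------------------------------------------------------

@dataclasses.dataclass
class ExpressionSimSpec:
    """Two-species replicate design with a planted divergent fraction.

    Defaults mirror the dendrite study design: 9 replicate arrays in species
    A and 14 in species B, Gaussian replicate noise on the log scale with
    sd ``noise_sd``, and a fraction ``divergent_fraction`` of genes shifted
    in species B by ±``effect_size`` (2σ by default).
    """

    n_genes: int = 10833
    n_reps_a: int = 9
    n_reps_b: int = 14
    divergent_fraction: float = 0.2
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline_mean: float = 0.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.divergent_fraction <= 1:
            raise ValueError("divergent_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_genes < 1 or self.n_reps_a < 1 or self.n_reps_b < 1:
            raise ValueError("counts must be positive")


def simulate_two_species_expression(
    spec: ExpressionSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, set]:
    """Simulate (expr_A, expr_B, planted divergent gene ids)."""
    rng = np.random.default_rng(spec.seed)
    ids = [f"MG{i + 1:05d}" for i in range(spec.n_genes)]
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_genes)
    n_div = int(round(spec.divergent_fraction * spec.n_genes))
    divergent_idx = rng.choice(spec.n_genes, size=n_div, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_div)
    shift = np.zeros(spec.n_genes)
    shift[divergent_idx] = signs * spec.effect_size
    a = baseline[:, None] + rng.normal(0, spec.noise_sd, (spec.n_genes, spec.n_reps_a))
    b = (baseline + shift)[:, None] + rng.normal(
        0, spec.noise_sd, (spec.n_genes, spec.n_reps_b)
    )
    expr_a = pd.DataFrame(a, index=ids, columns=[f"A{j + 1}" for j in range(spec.n_reps_a)])
    expr_b = pd.DataFrame(b, index=ids, columns=[f"B{j + 1}" for j in range(spec.n_reps_b)])
    return expr_a, expr_b, {ids[i] for i in divergent_idx}


# -- orthology --------------------------------------------------------------

@dataclasses.dataclass
class OrthologySim:
    hits_ab: list[BlastHit]
    hits_ba: list[BlastHit]
    probe_hits_a: list[BlastHit]
    probe_hits_b: list[BlastHit]
    probesets_a: list[ProbeSet]
    probesets_b: list[ProbeSet]
    truth: MetageneMap


def _probe_hit(probe_id: str, transcript: str, mismatches: int = 0) -> BlastHit:
    return BlastHit(
        query_id=probe_id,
        subject_id=transcript,
        pct_identity=100.0 * (25 - mismatches) / 25,
        alignment_length=25,
        mismatches=mismatches,
        gapopen=0,
        qstart=1,
        qend=25,
        sstart=1,
        send=25,
        evalue=1e-9,
        bitscore=50.0 - mismatches,
    )


def _transcript_hit(q: str, s: str, evalue: float, bitscore: float) -> BlastHit:
    return BlastHit(
        query_id=q,
        subject_id=s,
        pct_identity=95.0,
        alignment_length=500,
        mismatches=25,
        gapopen=0,
        qstart=1,
        qend=500,
        sstart=1,
        send=500,
        evalue=evalue,
        bitscore=bitscore,
    )


def simulate_orthology_tables(
    n_transcripts: int,
    many_to_many_fraction: float = 0.3,
    seed: int = 0,
    n_probes: int = 11,
    subthreshold_fraction: float = 0.0,
    decoy_fraction: float = 0.3,
    nonreciprocal_fraction: float = 0.1,
) -> OrthologySim:
    """Generate BLAST-style orthology inputs plus the planted metagene truth.

    ``n_transcripts`` cross-species transcript pairs are created as mutual
    best hits; a ``many_to_many_fraction`` of them get extra probe sets on
    one or both sides (producing multi-member metagenes), ``decoy_fraction``
    get an additional worse-scoring off-target hit, and a
    ``nonreciprocal_fraction`` of extra transcripts have one-directional
    best hits only (these must not enter the map). A
    ``subthreshold_fraction`` of probe sets get probes aligning with only
    23/25 matched bases, so they fail the 24/25 probe-match rule and drop
    out of the truth partition.
    """
    if not 0 <= many_to_many_fraction <= 1:
        raise ValueError("many_to_many_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    hits_ab: list[BlastHit] = []
    hits_ba: list[BlastHit] = []
    probe_hits = {"A": [], "B": []}
    probesets = {"A": [], "B": []}
    components: list[tuple[frozenset, frozenset]] = []

    def add_probeset(species: str, ps_id: str, transcript: str, subthreshold: bool) -> bool:
        """Create a probe set whose probes hit `transcript`; returns True if it maps."""
        probe_ids = tuple(f"{ps_id}_p{k + 1}" for k in range(n_probes))
        probesets[species].append(ProbeSet(ps_id, species, probe_ids))
        mism = 2 if subthreshold else 0
        for pid in probe_ids:
            probe_hits[species].append(_probe_hit(pid, transcript, mismatches=mism))
        return not subthreshold

    for i in range(n_transcripts):
        ta, tb = f"tA{i:04d}", f"tB{i:04d}"
        hits_ab.append(_transcript_hit(ta, tb, 1e-50, 500.0))
        hits_ba.append(_transcript_hit(tb, ta, 1e-50, 500.0))
        if rng.random() < decoy_fraction:
            j = int(rng.integers(n_transcripts))
            if j != i:
                hits_ab.append(_transcript_hit(ta, f"tB{j:04d}", 1e-8, 100.0))
        n_extra_a = n_extra_b = 0
        if rng.random() < many_to_many_fraction:
            pattern = rng.integers(3)
            n_extra_a = 1 if pattern in (0, 2) else 0
            n_extra_b = 1 if pattern in (1, 2) else 0
        mem_a, mem_b = set(), set()
        for k in range(1 + n_extra_a):
            ps_id = f"psA{i:04d}_{k}"
            if add_probeset("A", ps_id, ta, rng.random() < subthreshold_fraction):
                mem_a.add(ps_id)
        for k in range(1 + n_extra_b):
            ps_id = f"psB{i:04d}_{k}"
            if add_probeset("B", ps_id, tb, rng.random() < subthreshold_fraction):
                mem_b.add(ps_id)
        if mem_a and mem_b:
            components.append((frozenset(mem_a), frozenset(mem_b)))

    n_nonrec = int(round(nonreciprocal_fraction * n_transcripts))
    for i in range(n_nonrec):
        ta = f"tAx{i:04d}"
        target = f"tB{int(rng.integers(n_transcripts)):04d}"
        # one-directional: ta's best hit is a paired transcript whose own
        # best hit is its reciprocal partner, so ta never enters the map
        hits_ab.append(_transcript_hit(ta, target, 1e-20, 300.0))
        add_probeset("A", f"psAx{i:04d}", ta, False)

    truth = metagene_map_from_components(components)
    return OrthologySim(
        hits_ab=hits_ab,
        hits_ba=hits_ba,
        probe_hits_a=probe_hits["A"],
        probe_hits_b=probe_hits["B"],
        probesets_a=probesets["A"],
        probesets_b=probesets["B"],
        truth=truth,
    )


# -- codon evolution --------------------------------------------------------

@dataclasses.dataclass
class CodonSimSpec:
    """Pairwise codon-evolution parameters.

    ``branch_length`` is the expected number of *proposed* substitutions per
    site separating the two sequences (split evenly between the lineages);
    ``kappa`` the transition/transversion rate ratio; ``omega`` the
    probability that a proposed non-synonymous change is accepted (1 =
    neutral, <1 purifying selection). ``utr_length`` optionally evolves
    flanking neutral non-coding sequence under the same K2P process.
    """

    n_codons: int = 300
    branch_length: float = 0.2
    kappa: float = 2.0
    omega: float = 1.0
    utr_length: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.branch_length < 0:
            raise ValueError("branch_length must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.n_codons < 1:
            raise ValueError("n_codons must be positive")


@dataclasses.dataclass(frozen=True)
class SubstitutionEvent:
    lineage: str           # "A" or "B"
    codon_index: int
    position: int          # 1..3
    site_class: int        # degeneracy class (0/2/4) of the site when hit
    transition: bool
    synonymous: bool


def _random_sense_codons(n: int, rng: np.random.Generator) -> list[str]:
    sense = sorted(
        c
        for c in ("".join(t) for t in itertools.product(_BASES, repeat=3))
        if c not in STOP_CODONS
    )
    return [sense[i] for i in rng.integers(len(sense), size=n)]


def _propose_base(base: str, kappa: float, rng: np.random.Generator) -> tuple[str, bool]:
    """K2P proposal: transition with probability kappa/(kappa+2), else a transversion."""
    if rng.random() < kappa / (kappa + 2.0):
        return _TRANSITION[base], True
    tv = _TRANSVERSIONS[base]
    return tv[int(rng.integers(2))], False


def _evolve_lineage(
    codons: list[str],
    spec: CodonSimSpec,
    lineage: str,
    rng: np.random.Generator,
) -> tuple[list[str], list[SubstitutionEvent]]:
    codons = list(codons)
    n_sites = 3 * len(codons)
    n_events = rng.poisson(spec.branch_length / 2.0 * n_sites)
    events = []
    for _ in range(n_events):
        site = int(rng.integers(n_sites))
        ci, pos = divmod(site, 3)
        codon = codons[ci]
        new_base, is_ts = _propose_base(codon[pos], spec.kappa, rng)
        mutant = codon[:pos] + new_base + codon[pos + 1 :]
        if mutant in STOP_CODONS:
            continue
        synonymous = translate_codon(mutant) == translate_codon(codon)
        if not synonymous and rng.random() >= spec.omega:
            continue
        events.append(
            SubstitutionEvent(
                lineage=lineage,
                codon_index=ci,
                position=pos + 1,
                site_class=classify_codon_degeneracy(codon, pos + 1),
                transition=is_ts,
                synonymous=synonymous,
            )
        )
        codons[ci] = mutant
    return codons, events


def _evolve_neutral(seq: str, t: float, kappa: float, rng: np.random.Generator) -> str:
    seq = list(seq)
    n_events = rng.poisson(t / 2.0 * len(seq))
    for _ in range(n_events):
        i = int(rng.integers(len(seq)))
        seq[i], _ = _propose_base(seq[i], kappa, rng)
    return "".join(seq)


def simulate_codon_pair(
    spec: CodonSimSpec, gene_id: str = "gene"
) -> tuple[CodonAlignment, list[SubstitutionEvent]]:
    """Evolve two descendants of a random ancestor; return alignment + event log."""
    rng_anc, rng_a, rng_b, rng_utr = rng_children(spec.seed, 4)
    ancestor = _random_sense_codons(spec.n_codons, rng_anc)
    codons_a, events_a = _evolve_lineage(ancestor, spec, "A", rng_a)
    codons_b, events_b = _evolve_lineage(ancestor, spec, "B", rng_b)
    utr5_a = utr5_b = utr3_a = utr3_b = None
    if spec.utr_length:
        anc5 = "".join(_BASES[i] for i in rng_utr.integers(4, size=spec.utr_length))
        anc3 = "".join(_BASES[i] for i in rng_utr.integers(4, size=spec.utr_length))
        utr5_a = _evolve_neutral(anc5, spec.branch_length, spec.kappa, rng_utr)
        utr5_b = _evolve_neutral(anc5, spec.branch_length, spec.kappa, rng_utr)
        utr3_a = _evolve_neutral(anc3, spec.branch_length, spec.kappa, rng_utr)
        utr3_b = _evolve_neutral(anc3, spec.branch_length, spec.kappa, rng_utr)
    aln = CodonAlignment(
        gene_id=gene_id,
        seq_a="".join(codons_a),
        seq_b="".join(codons_b),
        utr5_a=utr5_a,
        utr5_b=utr5_b,
        utr3_a=utr3_a,
        utr3_b=utr3_b,
    )
    return aln, events_a + events_b


# -- transects --------------------------------------------------------------

def simulate_transects(
    n_cells: int,
    n_dendrites_per_cell: int,
    planted_ratio: float,
    decay: str = "flat",
    pixel_sigma_log: float = 0.0,
    seed: int = 0,
    soma_level: float = 1000.0,
    n_soma_samples: int = 40,
    sample_spacing_um: float = 0.5,
    max_distance_um: float = 40.0,
    species: str = "",
    probe: str = "",
) -> list[TransectProfile]:
    """Simulate soma→dendrite transects at a planted D/S ratio.

    Soma pixels scatter multiplicatively around ``soma_level``; dendrite
    pixels around ``planted_ratio * soma_level`` shaped by ``decay`` ("flat"
    or "linear", the latter falling to zero at ``max_distance_um``).
    Multiplicative log-normal pixel noise leaves the median — and hence the
    recovered D/S ratio — unbiased.
    """
    if planted_ratio <= 0:
        raise ValueError("planted_ratio must be positive")
    if decay not in ("flat", "linear"):
        raise ValueError("decay must be 'flat' or 'linear'")
    rng = np.random.default_rng(seed)
    distances = np.arange(0.0, max_distance_um + sample_spacing_um, sample_spacing_um)
    shape = np.ones_like(distances)
    if decay == "linear":
        shape = 1.0 - distances / max_distance_um
    out = []
    for c in range(n_cells):
        cell_id = f"cell{c + 1:03d}"
        soma = soma_level * np.exp(
            rng.normal(0, pixel_sigma_log, n_soma_samples)
        )
        for d in range(n_dendrites_per_cell):
            dend = (
                planted_ratio
                * soma_level
                * shape
                * np.exp(rng.normal(0, pixel_sigma_log, distances.size))
            )
            out.append(
                TransectProfile(
                    cell_id=cell_id,
                    dendrite_id=f"d{d + 1:02d}",
                    distance_um=distances.copy(),
                    intensity=dend,
                    soma_intensity_samples=soma,
                    species=species,
                    probe=probe,
                )
            )
    return out


def simulate_ds_ratios(
    n: int, planted_ratio: float, sigma_log: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-dendrite D/S ratios with log-normal scatter around a planted median."""
    if planted_ratio <= 0:
        raise ValueError("planted_ratio must be positive")
    return planted_ratio * np.exp(rng.normal(0.0, sigma_log, n))
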