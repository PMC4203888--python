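"""Molecular-evolution rate estimation from pairwise alignments.

Synonymous (Ks) and non-synonymous (Ka) substitution rates are estimated
from pairwise coding alignments with the Li (1993) / Pamilo–Bianchi
estimator: codon sites are classified as nondegenerate (L0), two-fold (L2)
or four-fold (L4) degenerate by how many nucleotide changes at the site
preserve the amino acid, transition (P) and transversion (Q) proportions are
accumulated per class, each class is corrected for multiple hits with the
Kimura two-parameter (K2P) model,

    A = 1/2 ln(1/(1-2P-Q)) - 1/4 ln(1/(1-2Q))   (transition component)
    B = 1/2 ln(1/(1-2Q))                        (transversion component)

and the rates combine the class components as

    Ks = (L2*A2 + L4*A4) / (L2 + L4) + B4
    Ka = A0 + (L0*B0 + L2*B2) / (L0 + L2).

Untranslated regions get the plain K2P distance K = A + B. Saturated
estimates (a K2P logarithm argument <= 0) are flagged degenerate and
excluded, as are genes at or below the minimum length of 100 amino acids.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

logger = logging.getLogger(__name__)

NONDEGENERATE, TWOFOLD, FOURFOLD = 0, 2, 4
_BASES = "ACGT"
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)


def translate_codon(codon: str) -> str | None:
    """Amino acid for a sense codon, None for stops/ambiguity."""
    return _TABLE.forward_table.get(codon.upper())


_codon_aa = translate_codon


def _build_degeneracy() -> dict[tuple[str, int], int]:
    table: dict[tuple[str, int], int] = {}
    for b1 in _BASES:
        for b2 in _BASES:
            for b3 in _BASES:
                codon = b1 + b2 + b3
                aa = _codon_aa(codon)
                if aa is None:
                    continue
                for pos in (1, 2, 3):
                    n_syn = 0
                    for alt in _BASES:
                        if alt == codon[pos - 1]:
                            continue
                        mutant = codon[: pos - 1] + alt + codon[pos:]
                        if _codon_aa(mutant) == aa:
                            n_syn += 1
                    if n_syn == 0:
                        cls = NONDEGENERATE
                    elif n_syn == 3:
                        cls = FOURFOLD
                    else:
                        # 1 or 2 synonymous alternatives: two-fold class
                        # (three-fold degenerate Ile sites fold in here)
                        cls = TWOFOLD
                    table[(codon, pos)] = cls
    return table


_DEGENERACY = _build_degeneracy()


def classify_codon_degeneracy(codon: str, position: int) -> int:
    """Degeneracy class (0, 2 or 4) of one codon position under the standard code."""
    codon = codon.upper()
    if position not in (1, 2, 3):
        raise ValueError("position must be 1, 2 or 3")
    if (codon, position) not in _DEGENERACY:
        raise ValueError(f"codon {codon!r} is not a sense codon over ACGT")
    return _DEGENERACY[(codon, position)]


def is_transition(b1: str, b2: str) -> bool:
    return (b1 in _PURINES and b2 in _PURINES) or (
        b1 in _PYRIMIDINES and b2 in _PYRIMIDINES
    )


@dataclasses.dataclass
class CodonAlignment:
    """A pairwise alignment: coding region plus optional aligned UTRs."""

    gene_id: str
    seq_a: str
    seq_b: str
    utr5_a: str | None = None
    utr5_b: str | None = None
    utr3_a: str | None = None
    utr3_b: str | None = None

    def __post_init__(self) -> None:
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(f"{self.gene_id}: unequal aligned coding lengths")
        if len(self.seq_a) % 3 != 0:
            raise ValueError(f"{self.gene_id}: aligned coding length not divisible by 3")
        for name in ("utr5", "utr3"):
            ua, ub = getattr(self, f"{name}_a"), getattr(self, f"{name}_b")
            if (ua is None) != (ub is None):
                raise ValueError(f"{self.gene_id}: {name} present for only one species")
            if ua is not None and len(ua) != len(ub):
                raise ValueError(f"{self.gene_id}: unequal aligned {name} lengths")


@dataclasses.dataclass
class SubstitutionCounts:
    """Per-degeneracy-class site counts and difference proportions."""

    L: dict[int, float]   # mean site count per class
    P: dict[int, float]   # transition proportion per class
    Q: dict[int, float]   # transversion proportion per class
    n_codons_compared: int
    n_codons_skipped: int


def count_pairwise_substitutions(aln: CodonAlignment) -> SubstitutionCounts:
    """Classify every compared coding site and tally differences.

    Codon columns containing a gap, an ambiguous base or a stop codon in
    either sequence are skipped (counted). Site counts L_i average the two
    sequences' per-class counts; a differing site contributes half a count
    to each sequence's class for that position (the classes can disagree
    when the codons differ elsewhere). P_i and Q_i are reported as
    proportions of L_i.
    """
    l_counts = {c: 0.0 for c in (NONDEGENERATE, TWOFOLD, FOURFOLD)}
    ts_counts = {c: 0.0 for c in (NONDEGENERATE, TWOFOLD, FOURFOLD)}
    tv_counts = {c: 0.0 for c in (NONDEGENERATE, TWOFOLD, FOURFOLD)}
    n_compared = n_skipped = 0
    for i in range(0, len(aln.seq_a), 3):
        ca, cb = aln.seq_a[i : i + 3], aln.seq_b[i : i + 3]
        if (
            any(b not in _BASES for b in ca + cb)
            or ca in STOP_CODONS
            or cb in STOP_CODONS
        ):
            n_skipped += 1
            continue
        n_compared += 1
        for pos in (1, 2, 3):
            cls_a = _DEGENERACY[(ca, pos)]
            cls_b = _DEGENERACY[(cb, pos)]
            l_counts[cls_a] += 0.5
            l_counts[cls_b] += 0.5
            ba, bb = ca[pos - 1], cb[pos - 1]
            if ba != bb:
                bucket = ts_counts if is_transition(ba, bb) else tv_counts
                bucket[cls_a] += 0.5
                bucket[cls_b] += 0.5
    if n_skipped:
        logger.debug("%s: skipped %d codon columns", aln.gene_id, n_skipped)
    P, Q = {}, {}
    for cls in (NONDEGENERATE, TWOFOLD, FOURFOLD):
        if l_counts[cls] == 0 and (ts_counts[cls] or tv_counts[cls]):
            raise ValueError(
                f"{aln.gene_id}: class {cls} has differences but zero sites"
            )
        P[cls] = ts_counts[cls] / l_counts[cls] if l_counts[cls] else 0.0
        Q[cls] = tv_counts[cls] / l_counts[cls] if l_counts[cls] else 0.0
    return SubstitutionCounts(l_counts, P, Q, n_compared, n_skipped)


class SaturatedDistanceError(ValueError):
    """K2P correction undefined: observed divergence at or past saturation."""


def k2p_components(P: float, Q: float) -> tuple[float, float, float]:
    """Kimura two-parameter components (A, B) and distance K = A + B."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedDistanceError(f"saturated: P={P}, Q={Q}")
    A = 0.5 * math.log(1.0 / w1) - 0.25 * math.log(1.0 / w2)
    B = 0.5 * math.log(1.0 / w2)
    return A, B, A + B


def li_ka_ks(counts: SubstitutionCounts) -> tuple[float, float, float]:
    """Li (1993) / Pamilo–Bianchi Ka, Ks and their ratio from class counts.

    Raises :class:`SaturatedDistanceError` if any needed class is saturated.
    Ka/Ks is NaN when Ks = 0 (undefined ratio; flagged upstream).
    """
    A, B = {}, {}
    for cls in (NONDEGENERATE, TWOFOLD, FOURFOLD):
        if counts.L[cls] > 0:
            A[cls], B[cls], _ = k2p_components(counts.P[cls], counts.Q[cls])
        else:
            A[cls], B[cls] = 0.0, 0.0
    L0, L2, L4 = (counts.L[c] for c in (NONDEGENERATE, TWOFOLD, FOURFOLD))
    if L2 + L4 == 0 or L0 + L2 == 0:
        raise SaturatedDistanceError("no sites in a required degeneracy class")
    Ks = (L2 * A[TWOFOLD] + L4 * A[FOURFOLD]) / (L2 + L4) + B[FOURFOLD]
    Ka = A[NONDEGENERATE] + (L0 * B[NONDEGENERATE] + L2 * B[TWOFOLD]) / (L0 + L2)
    if Ks == 0:
        ratio = 0.0 if Ka == 0 else float("nan")
    else:
        ratio = Ka / Ks
    return Ka, Ks, ratio


def utr_k2p(utr_a: str, utr_b: str) -> float:
    """K2P distance over the non-gap aligned columns of a UTR alignment."""
    pairs = [
        (a, b)
        for a, b in zip(utr_a.upper(), utr_b.upper())
        if a in _BASES and b in _BASES
    ]
    if not pairs:
        raise ValueError("no comparable UTR columns")
    n = len(pairs)
    ts = sum(1 for a, b in pairs if a != b and is_transition(a, b))
    tv = sum(1 for a, b in pairs if a != b and not is_transition(a, b))
    _, _, K = k2p_components(ts / n, tv / n)
    return K


def compute_rate_table(
    alignments: Iterable[CodonAlignment], min_aa: int = 100
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene rate estimates plus across-gene summary (mean, standard error).

    Genes are kept only when longer than ``min_aa`` amino acids (compared
    sense codons) and when every K2P component is non-degenerate; exclusion
    counts are logged. The summary covers Ks, Ka and Ka/Ks.
    """
    rows = []
    n_short = n_saturated = 0
    for aln in alignments:
        counts = count_pairwise_substitutions(aln)
        if counts.n_codons_compared <= min_aa:
            n_short += 1
            continue
        try:
            ka, ks, ratio = li_ka_ks(counts)
            k5 = utr_k2p(aln.utr5_a, aln.utr5_b) if aln.utr5_a else np.nan
            k3 = utr_k2p(aln.utr3_a, aln.utr3_b) if aln.utr3_a else np.nan
        except SaturatedDistanceError:
            n_saturated += 1
            continue
        rows.append(
            {
                "gene_id": aln.gene_id,
                "aa_length": counts.n_codons_compared,
                "L0": counts.L[NONDEGENERATE],
                "L2": counts.L[TWOFOLD],
                "L4": counts.L[FOURFOLD],
                "P0": counts.P[NONDEGENERATE],
                "P2": counts.P[TWOFOLD],
                "P4": counts.P[FOURFOLD],
                "Q0": counts.Q[NONDEGENERATE],
                "Q2": counts.Q[TWOFOLD],
                "Q4": counts.Q[FOURFOLD],
                "Ka": ka,
                "Ks": ks,
                "KaKs": ratio,
                "K_utr5": k5,
                "K_utr3": k3,
            }
        )
    if n_short or n_saturated:
        logger.info(
            "excluded %d genes <= %d aa and %d with saturated estimates",
            n_short,
            min_aa,
            n_saturated,
        )
    table = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame()
    summary_rows = {}
    for col in ("Ks", "Ka", "KaKs"):
        vals = table[col].dropna().to_numpy() if len(table) else np.array([])
        summary_rows[col] = {
            "mean": float(np.mean(vals)) if vals.size else np.nan,
            "stderr": float(stats.sem(vals)) if vals.size > 1 else np.nan,
            "n": int(vals.size),
        }
    summary = pd.DataFrame(summary_rows).T
    return table, summary


def kruskal_wallis_rates(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and chi-square p across rate groups.

    Used to ask whether, e.g., expression-divergent and non-divergent genes
    differ in Ks, Ka or Ka/Ks. Identical samples across groups give p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs >= 2 values")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)
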