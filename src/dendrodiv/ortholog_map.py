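"""Cross-species ortholog / metagene map construction.

Orthologs between the two array platforms are called by reciprocal best
BLAST hits (each transcript is the other's top-ranked hit below an e-value
cutoff).  Array probe sets are tied to transcripts by a per-probe match rule
(a 25-mer probe must align with at least 24 matched bases) and a quorum rule
(at least 9 of a probe set's 11 probes must call the same transcript).
Combining probe-set→transcript links with the transcript-level ortholog
pairs yields a match graph whose connected components are *metagenes* — the
cross-species expression units.  A metagene's expression in each species is
the per-array median over its member probe sets.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_MIN_MATCH = 24  # matched bases out of a 25-mer probe
DEFAULT_QUORUM_FRACTION = 9 / 11


@dataclasses.dataclass(frozen=True)
class BlastHit:
    """One row of a BLAST tabular (outfmt 6) hit table."""

    query_id: str
    subject_id: str
    pct_identity: float
    alignment_length: int
    mismatches: int
    gapopen: int = 0
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0
    evalue: float = 0.0
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if self.alignment_length < 1:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: alignment_length must be >= 1"
            )
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: negative e-value")
        if not 0 <= self.pct_identity <= 100:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: pct_identity outside [0, 100]"
            )

    @property
    def matched_bases(self) -> int:
        return self.alignment_length - self.mismatches


@dataclasses.dataclass(frozen=True)
class ProbeSet:
    """An array probe set: a group of (nominally 11) 25-mer probes."""

    probeset_id: str
    species: str
    probe_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.probe_ids:
            raise ValueError(f"probe set {self.probeset_id} has no probes")


@dataclasses.dataclass
class Metagene:
    metagene_id: str
    members_a: frozenset[str]
    members_b: frozenset[str]


@dataclasses.dataclass
class MetageneMap:
    """Partition of probe sets into cross-species metagene units."""

    metagenes: list[Metagene]
    n_dropped_single_species: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mg in self.metagenes:
            for ps in sorted(mg.members_a):
                rows.append((mg.metagene_id, "A", ps))
            for ps in sorted(mg.members_b):
                rows.append((mg.metagene_id, "B", ps))
        return pd.DataFrame(rows, columns=["metagene_id", "species", "probeset_id"])

    def members(self, species: str) -> dict[str, frozenset[str]]:
        attr = "members_a" if species == "A" else "members_b"
        return {mg.metagene_id: getattr(mg, attr) for mg in self.metagenes}


def _best_subject(hits: Sequence[BlastHit]) -> str | None:
    """Best subject for one query: lowest e-value, then highest bitscore.

    Duplicate hits to the same subject are collapsed to that subject's best.
    A residual tie between *distinct* subjects is ambiguous: no best hit.
    """
    per_subject: dict[str, tuple[float, float]] = {}
    for h in hits:
        key = (h.evalue, -h.bitscore)
        if h.subject_id not in per_subject or key < per_subject[h.subject_id]:
            per_subject[h.subject_id] = key
    ranked = sorted(per_subject.items(), key=lambda kv: (kv[1], kv[0]))
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None
    return ranked[0][0]


def best_hits(hits: Iterable[BlastHit], evalue_max: float) -> dict[str, str]:
    """Unique best subject per query after the e-value filter."""
    by_query: dict[str, list[BlastHit]] = defaultdict(list)
    for h in hits:
        if h.evalue <= evalue_max:
            by_query[h.query_id].append(h)
    out = {}
    for q, qhits in by_query.items():
        best = _best_subject(qhits)
        if best is not None:
            out[q] = best
    return out


def reciprocal_best_hits(
    hits_ab: Iterable[BlastHit],
    hits_ba: Iterable[BlastHit],
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> list[tuple[str, str]]:
    """Reciprocal-best-hit ortholog pairs between species A and B.

    Returns the (a, b) pairs where b is a's unique best hit and a is b's
    unique best hit, after removing hits with e-value above ``evalue_max``.
    Output is sorted by the species-A query id.
    """
    if evalue_max <= 0:
        raise ValueError("evalue_max must be positive")
    fwd = best_hits(hits_ab, evalue_max)
    rev = best_hits(hits_ba, evalue_max)
    pairs = [(a, b) for a, b in fwd.items() if rev.get(b) == a]
    return sorted(pairs)


def quorum_size(n_probes: int, fraction: float = DEFAULT_QUORUM_FRACTION) -> int:
    """Probes that must agree for a probe-set call: 9 when n=11, ceil(0.818 n) otherwise."""
    if n_probes == 11:
        return 9
    return max(1, math.ceil(fraction * n_probes))


def map_probeset_to_transcript(
    probe_hits: Iterable[BlastHit],
    probesets: Sequence[ProbeSet],
    min_probe_match: int = DEFAULT_MIN_MATCH,
    quorum_fraction: float = DEFAULT_QUORUM_FRACTION,
) -> dict[str, str]:
    """Map probe sets to transcripts via per-probe top hits and a quorum.

    A probe's call is its top hit provided that hit has at least
    ``min_probe_match`` matched bases (alignment length minus mismatches).
    A probe set maps to transcript T when at least the quorum of its probes
    (9 of 11 for standard probe sets) call T; probe sets failing the quorum
    are absent from the returned mapping.
    """
    probe_owner: dict[str, str] = {}
    for ps in probesets:
        for pid in ps.probe_ids:
            if pid in probe_owner:
                raise ValueError(f"probe {pid} belongs to more than one probe set")
            probe_owner[pid] = ps.probeset_id

    by_probe: dict[str, list[BlastHit]] = defaultdict(list)
    n_orphans = 0
    for h in probe_hits:
        if h.query_id not in probe_owner:
            n_orphans += 1
            continue
        by_probe[h.query_id].append(h)
    if n_orphans:
        logger.warning("ignored %d probe hits from probes absent from any probe set", n_orphans)

    calls: dict[str, str] = {}
    for pid, hits in by_probe.items():
        top = _best_subject(hits)
        if top is None:
            continue
        best = min(
            (h for h in hits if h.subject_id == top),
            key=lambda h: (h.evalue, -h.bitscore),
        )
        if best.matched_bases >= min_probe_match:
            calls[pid] = top

    mapping: dict[str, str] = {}
    for ps in probesets:
        votes: dict[str, int] = defaultdict(int)
        for pid in ps.probe_ids:
            if pid in calls:
                votes[calls[pid]] += 1
        if not votes:
            continue
        transcript, n = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
        if n >= quorum_size(len(ps.probe_ids), quorum_fraction):
            mapping[ps.probeset_id] = transcript
    return mapping


def build_metagene_map(
    rbh_pairs: Sequence[tuple[str, str]],
    links_a: Mapping[str, str],
    links_b: Mapping[str, str],
) -> MetageneMap:
    """Collapse ortholog pairs plus probe-set links into metagenes.

    Nodes are species-tagged probe sets and transcripts; edges are the
    probe-set→transcript links in each species and the cross-species
    ortholog (RBH) pairs.  Each connected component containing probe sets
    of both species becomes one metagene; unique 1:1 matches come first in
    the id ordering.  Single-species components carry no cross-species
    signal and are dropped (counted).
    """
    g = nx.Graph()
    for ps, t in links_a.items():
        g.add_edge(("psA", ps), ("tA", t))
    for ps, t in links_b.items():
        g.add_edge(("psB", ps), ("tB", t))
    for a, b in rbh_pairs:
        g.add_edge(("tA", a), ("tB", b))

    components = []
    n_dropped = 0
    for comp in nx.connected_components(g):
        mem_a = frozenset(n[1] for n in comp if n[0] == "psA")
        mem_b = frozenset(n[1] for n in comp if n[0] == "psB")
        if not mem_a or not mem_b:
            n_dropped += 1
            continue
        components.append((mem_a, mem_b))
    if n_dropped:
        logger.info("dropped %d single-species components", n_dropped)
    return metagene_map_from_components(components, n_dropped=n_dropped)


def metagene_map_from_components(
    components: Sequence[tuple[frozenset[str], frozenset[str]]],
    n_dropped: int = 0,
) -> MetageneMap:
    """Assign deterministic metagene ids: unique 1:1 matches first, then by member id."""

    def sort_key(c):
        mem_a, mem_b = c
        unique = len(mem_a) == 1 and len(mem_b) == 1
        return (not unique, min(mem_a), min(mem_b))

    ordered = sorted(components, key=sort_key)
    width = max(5, len(str(len(ordered))))
    metagenes = [
        Metagene(f"MG{i + 1:0{width}d}", frozenset(mem_a), frozenset(mem_b))
        for i, (mem_a, mem_b) in enumerate(ordered)
    ]
    return MetageneMap(metagenes, n_dropped_single_species=n_dropped)


def aggregate_metagene_expression(
    expr: pd.DataFrame, metagene_map: MetageneMap, species: str
) -> pd.DataFrame:
    """Per-array median over member probe-set rows, one row per metagene.

    ``expr`` is indexed by probe-set id with one column per array; a
    single-member metagene's row equals its member's row exactly.
    """
    rows = {}
    for mg_id, members in metagene_map.members(species).items():
        missing = sorted(m for m in members if m not in expr.index)
        if missing:
            raise KeyError(
                f"metagene {mg_id}: probe set(s) {missing} missing from expression matrix"
            )
        rows[mg_id] = expr.loc[sorted(members)].median(axis=0)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out = out.reindex(sorted(rows))
    out.columns = expr.columns
    return out
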