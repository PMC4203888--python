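"""Readers and writers for every format the pipeline touches.

Formats are deliberately plain: tab-separated expression matrices (row ids
in the first column, array labels in the header), BLAST tabular hit tables
(outfmt 6, twelve columns), two-record aligned FASTA files with ``key=value``
metadata in the headers, and TSV transect/soma tables. Validation is strict:
duplicate row ids, blank cells and ragged rows are errors, never silently
imputed — the analysis has no imputation step.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from dendrodiv.imaging_quant import TransectProfile
from dendrodiv.molevol import CodonAlignment
from dendrodiv.ortholog_map import BlastHit

BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


# -- expression matrices ----------------------------------------------------

def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV expression matrix (rows = features, columns = arrays)."""
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False, na_values=[]
    )
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row ids {dups[:5]}")
    if df.isna().any().any() or (df == "").any().any():
        raise ValueError(f"{path}: blank cells are not allowed")
    try:
        out = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from None
    if not np.isfinite(out.to_numpy()).all():
        raise ValueError(f"{path}: non-finite values")
    return out


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="id", float_format="%.10g")


# -- BLAST tabular ----------------------------------------------------------

def read_blast_tab(path: str | Path) -> list[BlastHit]:
    """Parse a 12-column BLAST tabular (outfmt 6) file; '#' lines are comments."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                hits.append(
                    BlastHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        alignment_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gapopen=int(fields[5]),
                        qstart=int(fields[6]),
                        qend=int(fields[7]),
                        sstart=int(fields[8]),
                        send=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed hit record ({exc})") from None
    return hits


def write_blast_tab(hits: Iterable[BlastHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        h.alignment_length,
                        h.mismatches,
                        h.gapopen,
                        h.qstart,
                        h.qend,
                        h.sstart,
                        h.send,
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )


# -- probe-set membership ---------------------------------------------------

def read_probesets_tsv(path: str | Path):
    """Read a probe-set membership table (probeset_id, species, probe_id rows)."""
    from dendrodiv.ortholog_map import ProbeSet

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probeset_id", "species", "probe_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    out = []
    for (ps_id, species), grp in df.groupby(["probeset_id", "species"], sort=True):
        out.append(ProbeSet(ps_id, species, tuple(grp["probe_id"])))
    return out


def write_probesets_tsv(probesets, path: str | Path) -> None:
    rows = [
        (ps.probeset_id, ps.species, pid)
        for ps in probesets
        for pid in ps.probe_ids
    ]
    pd.DataFrame(rows, columns=["probeset_id", "species", "probe_id"]).to_csv(
        path, sep="\t", index=False
    )


# -- aligned FASTA ----------------------------------------------------------

def _parse_header(description: str) -> dict[str, str]:
    meta = {}
    for token in description.split()[1:]:
        if "=" in token:
            key, val = token.split("=", 1)
            meta[key] = val
    return meta


def read_fasta_alignment(path: str | Path) -> CodonAlignment:
    """Read one gene's pairwise alignment from a FASTA file.

    The file holds exactly two equal-length records. Headers follow
    ``>seqid species=A region=cds gene=G1``; records optionally carry
    ``utr5``/``utr3`` regions in companion files (see
    :func:`read_alignment_dir`). Sequences are uppercased.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 records, found {len(records)}")
    seqs = [str(r.seq).upper() for r in records]
    if len(seqs[0]) != len(seqs[1]):
        raise ValueError(f"{path}: records have unequal aligned lengths")
    bad = set(seqs[0] + seqs[1]) - set("ACGT-")
    if bad:
        raise ValueError(f"{path}: invalid alignment characters {sorted(bad)}")
    meta = _parse_header(records[0].description)
    gene_id = meta.get("gene", records[0].id)
    return CodonAlignment(gene_id=gene_id, seq_a=seqs[0], seq_b=seqs[1])


def write_fasta_alignment(aln: CodonAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(aln.seq_a), id=f"{aln.gene_id}_A", description=f"species=A region=cds gene={aln.gene_id}"),
        SeqRecord(Seq(aln.seq_b), id=f"{aln.gene_id}_B", description=f"species=B region=cds gene={aln.gene_id}"),
    ]
    SeqIO.write(records, str(path), "fasta")


def read_alignment_dir(directory: str | Path) -> list[CodonAlignment]:
    """Read every ``*.fasta`` pairwise alignment under a directory, sorted by name."""
    directory = Path(directory)
    return [read_fasta_alignment(p) for p in sorted(directory.glob("*.fasta"))]


# -- transects --------------------------------------------------------------

def read_transects_tsv(
    transect_path: str | Path, soma_path: str | Path
) -> list[TransectProfile]:
    """Read dendrite transects plus per-cell soma reference pixels.

    The transect table has columns (cell_id, dendrite_id, distance_um,
    intensity) with optional species/probe columns; the soma table has
    (cell_id, intensity). Every transect's cell must appear in the soma
    table.
    """
    tr = pd.read_csv(transect_path, sep="\t")
    soma = pd.read_csv(soma_path, sep="\t")
    for col in ("cell_id", "dendrite_id", "distance_um", "intensity"):
        if col not in tr.columns:
            raise ValueError(f"{transect_path}: missing column {col!r}")
    if not {"cell_id", "intensity"}.issubset(soma.columns):
        raise ValueError(f"{soma_path}: need columns cell_id, intensity")
    soma_by_cell = {
        str(cid): grp["intensity"].to_numpy(float)
        for cid, grp in soma.groupby("cell_id")
    }
    out = []
    for (cid, did), grp in tr.groupby(["cell_id", "dendrite_id"], sort=True):
        cid = str(cid)
        if cid not in soma_by_cell:
            raise ValueError(f"{transect_path}: cell {cid} has no soma samples")
        grp = grp.sort_values("distance_um")
        out.append(
            TransectProfile(
                cell_id=cid,
                dendrite_id=str(did),
                distance_um=grp["distance_um"].to_numpy(float),
                intensity=grp["intensity"].to_numpy(float),
                soma_intensity_samples=soma_by_cell[cid],
                species=str(grp["species"].iloc[0]) if "species" in grp else "",
                probe=str(grp["probe"].iloc[0]) if "probe" in grp else "",
            )
        )
    return out


def write_transects_tsv(
    transects: Sequence[TransectProfile],
    transect_path: str | Path,
    soma_path: str | Path,
) -> None:
    rows = []
    soma_rows = []
    seen_cells = set()
    for t in transects:
        for d, v in zip(t.distance_um, t.intensity):
            rows.append((t.cell_id, t.dendrite_id, d, v, t.species, t.probe))
        if t.cell_id not in seen_cells:
            seen_cells.add(t.cell_id)
            for v in t.soma_intensity_samples:
                soma_rows.append((t.cell_id, v))
    pd.DataFrame(
        rows,
        columns=["cell_id", "dendrite_id", "distance_um", "intensity", "species", "probe"],
    ).to_csv(transect_path, sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(soma_rows, columns=["cell_id", "intensity"]).to_csv(
        soma_path, sep="\t", index=False, float_format="%.10g"
    )
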