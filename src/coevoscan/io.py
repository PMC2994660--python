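"""Readers and writers for the pipeline's file formats.

FASTA goes through Biopython; Newick through the tree module
(dendropy-backed).  Coverage tracks are exchanged as bedGraph
(contig, start, end, count runs; 0-based half-open), regions as
BED-like TSV, and fit results both as a human-readable key/value table
and as a machine-readable JSON record.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
from Bio import SeqIO

from .chip_enrichment import CoverageTrack, GenomeRegion
from .codon_core import FitResult

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bedgraph",
    "write_bedgraph",
    "read_regions_bed",
    "fit_report_lines",
    "fit_report_json",
    "write_window_table",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_bedgraph(path, contig_lengths: dict | None = None
                  ) -> dict[str, CoverageTrack]:
    """Run-length coverage to per-base integer tracks.

    Contig lengths default to the largest end coordinate seen per contig.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["contig", "start", "end", "count"])
    if contig_lengths is None:
        contig_lengths = df.groupby("contig")["end"].max().to_dict()
    tracks = {c: np.zeros(int(L), dtype=np.int64)
              for c, L in contig_lengths.items()}
    for row in df.itertuples():
        arr = tracks[row.contig]
        if not (0 <= row.start < row.end <= len(arr)):
            raise ValueError(f"bedGraph interval out of bounds: {row}")
        arr[row.start:row.end] = row.count
    return {c: CoverageTrack(c, a) for c, a in tracks.items()}


def write_bedgraph(tracks: dict[str, CoverageTrack], path) -> None:
    with open(path, "w") as fh:
        for contig in tracks:
            counts = tracks[contig].counts
            if len(counts) == 0:
                continue
            # emit maximal runs of equal count
            change = np.flatnonzero(np.diff(counts)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(counts)]])
            for s, e in zip(starts, ends):
                fh.write(f"{contig}\t{s}\t{e}\t{counts[s]}\n")


def read_regions_bed(path) -> list[GenomeRegion]:
    """BED-like region file: contig, start, end, label[, role]."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else f"{contig}:{start}-{end}"
            role = parts[4] if len(parts) > 4 else "query"
            regions.append(GenomeRegion(contig, start, end, label, role))
    return regions


def _fit_record(fit: FitResult) -> dict:
    rec = {
        "model": fit.model,
        "lnL": fit.lnL,
        "kappa": fit.params.kappa,
        "converged": fit.converged,
        "n_evaluations": fit.n_evaluations,
        "tree": fit.tree.to_newick(),
    }
    if fit.params.omega is not None:
        rec["omega"] = fit.params.omega
    if fit.mixture is not None:
        rec["mixture"] = {k: v for k, v in
                          dataclasses.asdict(fit.mixture).items()}
    if fit.branch_omegas is not None:
        rec["branch_omegas"] = fit.branch_omegas
    if fit.message:
        rec["message"] = fit.message
    return rec


def fit_report_lines(fit: FitResult) -> str:
    """Tab-separated key/value report for one fit."""
    rec = _fit_record(fit)
    lines = []
    for key, val in rec.items():
        if isinstance(val, dict):
            for k2, v2 in val.items():
                lines.append(f"{key}.{k2}\t{v2}")
        else:
            lines.append(f"{key}\t{val}")
    return "\n".join(lines) + "\n"


def fit_report_json(fit: FitResult) -> str:
    return json.dumps(_fit_record(fit), indent=2, default=float)


def write_window_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
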