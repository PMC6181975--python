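"""Readers and writers for the pipeline's plain-text formats.

FASTA via Biopython; BED/bedGraph/TSV via pandas.  All genomic intervals
are 0-based half-open (native BED).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import InsulatorSiteSpec
from .domains import Domain, SignalTrack, bin_intervals
from .fragments import RestrictionFragment

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_fragments_bed",
    "read_fragments_bed",
    "write_bedgraph",
    "read_bedgraph_track",
    "write_domains_bed",
    "write_boundaries_bed",
    "write_insulator_bed",
    "read_insulator_bed",
    "read_captures",
    "read_embryos",
]


def read_fasta(path) -> dict[str, str]:
    """All records of a FASTA as {name: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, name: str, sequence: str) -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


def write_fragments_bed(path, fragments: list[RestrictionFragment]) -> None:
    """BED6 with name = fragment id and score = fragment length."""
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\t{f.length}\t+\n")


def read_fragments_bed(path) -> list[RestrictionFragment]:
    frags = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            frags.append(RestrictionFragment(chrom, int(start), int(end)))
    return frags


def write_bedgraph(path, track: SignalTrack) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(track.values):
            fh.write(f"{track.chrom}\t{i * track.bin_size}\t{(i + 1) * track.bin_size}\t{v:.6g}\n")


def read_bedgraph_track(path, bin_size: int, mark: str = "", span: int | None = None) -> SignalTrack:
    """Read a bedGraph and regrid it to uniform bins by coverage-weighted mean."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(f"expected a single-sequence bedGraph, got {list(chroms)}")
    span = int(df["end"].max()) if span is None else span
    values = bin_intervals(
        df["start"].to_numpy(), df["end"].to_numpy(),
        df["value"].to_numpy(dtype=float), bin_size, span,
    )
    return SignalTrack(chrom=str(chroms[0]), bin_size=bin_size, values=np.clip(values, 0, None),
                       mark=mark or Path(str(path)).stem)


def write_domains_bed(path, domains: list[Domain], chrom: str) -> None:
    with open(path, "w") as fh:
        for d in domains:
            fh.write(f"{chrom}\t{d.start}\t{d.end}\t{d.state}\n")


def write_boundaries_bed(path, boundaries: list[int], chrom: str) -> None:
    """Boundaries as 1 bp BED intervals."""
    with open(path, "w") as fh:
        for b in boundaries:
            fh.write(f"{chrom}\t{b}\t{b + 1}\tboundary\n")


def read_boundaries_bed(path) -> list[int]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                out.append(int(line.split("\t")[1]))
    return sorted(out)


def write_insulator_bed(path, sites: list[InsulatorSiteSpec], chrom: str) -> None:
    """BED with the name field a semicolon-joined bound-protein list."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{chrom}\t{s.start}\t{s.end}\t{';'.join(s.proteins)}\n")


def read_insulator_bed(path) -> list[InsulatorSiteSpec]:
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            sites.append(InsulatorSiteSpec(int(fields[1]), int(fields[2]),
                                           tuple(fields[3].split(";"))))
    return sites


def read_captures(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "censored" in df.columns:
        df["censored"] = df["censored"].astype(bool)
    return df


def read_embryos(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
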