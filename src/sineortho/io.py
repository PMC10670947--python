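"""Readers/writers: FASTA (plain or gzip), BED6(+), verdict TSV, YAML config.

Coordinates are 0-based half-open everywhere, matching BED.  BED scores
for SINE copies encode int(percent identity x 10).
"""

from __future__ import annotations

import gzip
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from sineortho.types import CandidateLocus, InvalidInputError, SineConsensus, SineHit

_REPORT_REGIONS = ("LF", "SINE", "RF")


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """FASTA file (optionally .gz) -> {record id: uppercase sequence}."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path, contigs: dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in contigs.items()]
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def read_consensus(path) -> SineConsensus:
    contigs = read_fasta(path)
    if len(contigs) != 1:
        raise InvalidInputError(f"expected exactly one consensus record in {path}")
    name, seq = next(iter(contigs.items()))
    return SineConsensus(name, seq)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def hits_to_bed(hits: list[SineHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.contig}\t{h.start}\t{h.end}\t{h.hit_id}"
                     f"\t{int(round(h.pct_identity * 10))}\t{h.strand}\n")


def loci_to_bed(loci: list[CandidateLocus], path) -> None:
    with open(path, "w") as fh:
        for l in loci:
            members = ",".join(l.source_ids) if l.source_ids else "."
            fh.write(f"{l.contig}\t{l.start}\t{l.end}\t{l.locus_id}\t0\t{l.strand}"
                     f"\t{members}\n")


def read_bed(path) -> list[dict]:
    """Parse BED6(+); raises with the line number on malformed lines."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InvalidInputError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise InvalidInputError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end < start:
                raise InvalidInputError(f"{path}:{lineno}: bad interval {start}-{end}")
            row = {"contig": fields[0], "start": start, "end": end,
                   "name": fields[3] if len(fields) > 3 else ".",
                   "score": fields[4] if len(fields) > 4 else "0",
                   "strand": fields[5] if len(fields) > 5 else "+"}
            if len(fields) > 6:
                row["extra"] = fields[6:]
            rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# Verdict report
# ---------------------------------------------------------------------------

def verdicts_to_frame(verdicts, genome_a: str, genome_b: str) -> pd.DataFrame:
    """Final per-pair report: coordinates, status and segment statistics."""
    rows = []
    for v in verdicts:
        row = {
            "genome_a": genome_a, "genome_b": genome_b,
            "status": v.status, "discard_reason": v.discard_reason,
            "foreign_b": v.foreign_b,
        }
        for tag, locus in (("a", v.locus_a), ("b", v.locus_b)):
            if locus is not None:
                row[f"locus_{tag}"] = locus.locus_id
                row[f"contig_{tag}"] = locus.contig
                row[f"start_{tag}"] = locus.start
                row[f"end_{tag}"] = locus.end
                row[f"strand_{tag}"] = locus.strand
        for region in _REPORT_REGIONS:
            st = v.stats.get(region)
            if st is None:
                continue
            p = region.lower()
            row[f"{p}_len_a"] = st.len_a
            row[f"{p}_len_b"] = st.len_b
            row[f"{p}_identical_ab"] = st.identical_ab
            row[f"{p}_pct_ab"] = round(st.pct_ab, 2)
            if region == "SINE":
                row["sine_identical_a_cons"] = st.identical_a_cons
                row["sine_pct_a_cons"] = round(st.pct_a_cons, 2)
                row["sine_identical_b_cons"] = st.identical_b_cons
                row["sine_pct_b_cons"] = round(st.pct_b_cons, 2)
        rows.append(row)
    return pd.DataFrame(rows)


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise InvalidInputError(f"config {path} is not a mapping")
    return data


def dump_config(obj, path) -> None:
    data = asdict(obj) if hasattr(obj, "__dataclass_fields__") else dict(obj)
    data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
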