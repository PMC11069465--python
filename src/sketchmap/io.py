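"""FASTA/FASTQ ingestion and TSV serialization of sketches, threshold
models, and mapping results."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
from Bio import SeqIO

from .calibrate import ThresholdModel
from .mapping import FinalMapping
from .sketch import Sketch

__all__ = [
    "read_sequences",
    "write_fasta",
    "sketch_to_tsv",
    "sketch_from_tsv",
    "threshold_models_to_tsv",
    "threshold_models_from_tsv",
    "MAPPING_COLUMNS",
    "write_mappings_tsv",
    "write_mappings_paf",
]

MAPPING_COLUMNS = (
    "read_id",
    "ref_id",
    "strand",
    "ref_start",
    "ref_end",
    "sketch_i",
    "sketch_j",
    "window_len",
    "shared_count",
    "score",
    "threshold",
)


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_sequences(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA or FASTQ file (gzip accepted)."""
    path = Path(path)
    stem = path.name[:-3] if path.name.endswith(".gz") else path.name
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with _open_text(path) as fh:
        # full header line (description) so simulated-read truth metadata
        # survives the round trip; consumers split on whitespace for the id
        return [
            (rec.description or rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(fh, fmt)
        ]


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def sketch_to_tsv(sketch: Sketch, path_or_fh) -> None:
    """Dump a sketch as TSV: a metadata header line plus one
    (record_id, offset, kmer) row per retained k-mer."""
    own = not hasattr(path_or_fh, "write")
    fh: TextIO = _open_text(path_or_fh, "wt") if own else path_or_fh
    try:
        params = ";".join(f"{k}={v}" for k, v in sorted(sketch.params.items()))
        fh.write(
            f"#k={sketch.k}\tmethod={sketch.method}\tparams={params}"
            f"\tseed={sketch.seed}\n"
        )
        fh.write("record_id\toffset\tkmer\n")
        rid = sketch.record_id or "."
        for off, kmer in zip(sketch.offsets, sketch.kmers):
            fh.write(f"{rid}\t{int(off)}\t{kmer}\n")
    finally:
        if own:
            fh.close()


def sketch_from_tsv(path_or_fh) -> Sketch:
    own = not hasattr(path_or_fh, "read")
    fh: TextIO = _open_text(path_or_fh) if own else path_or_fh
    try:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError("sketch TSV must start with a '#' metadata line")
        meta = dict(item.split("=", 1) for item in header[1:].split("\t"))
        params: dict = {}
        for item in meta.get("params", "").split(";"):
            if not item:
                continue
            key, val = item.split("=", 1)
            try:
                params[key] = int(val)
            except ValueError:
                try:
                    params[key] = float(val)
                except ValueError:
                    params[key] = {"True": True, "False": False}.get(val, val)
        fh.readline()  # column header
        kmers, offsets, rid = [], [], None
        for line in fh:
            r, off, kmer = line.rstrip("\n").split("\t")
            rid = None if r == "." else r
            offsets.append(int(off))
            kmers.append(kmer)
        return Sketch(
            kmers,
            np.asarray(offsets, dtype=np.int64),
            int(meta["k"]),
            method=meta.get("method", "identity"),
            params=params,
            seed=int(meta.get("seed", 0)),
            record_id=rid,
        )
    finally:
        if own:
            fh.close()


def threshold_models_to_tsv(
    models: dict[float, ThresholdModel], path_or_fh, metadata: dict | None = None
) -> None:
    """One row per calibration length; one threshold column per confidence."""
    own = not hasattr(path_or_fh, "write")
    fh: TextIO = _open_text(path_or_fh, "wt") if own else path_or_fh
    try:
        confs = sorted(models)
        for key, val in (metadata or {}).items():
            fh.write(f"#{key}={val}\n")
        cols = ["length", "mean_sketch_len"] + [f"thr_conf_{c:g}" for c in confs]
        fh.write("\t".join(cols) + "\n")
        first = models[confs[0]]
        for row, length in enumerate(first.lengths):
            vals = [f"{length:g}", f"{first.mean_pattern_len[row]:g}"]
            vals += [f"{models[c].thresholds[row]:.6g}" for c in confs]
            fh.write("\t".join(vals) + "\n")
    finally:
        if own:
            fh.close()


def threshold_models_from_tsv(path_or_fh) -> tuple[dict[float, ThresholdModel], dict]:
    own = not hasattr(path_or_fh, "read")
    fh: TextIO = _open_text(path_or_fh) if own else path_or_fh
    try:
        metadata: dict = {}
        header = None
        rows = []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                metadata[key] = val
            elif header is None:
                header = line.split("\t")
            elif line:
                rows.append(line.split("\t"))
        if header is None or not rows:
            raise ValueError("threshold model TSV has no data rows")
        lengths = np.array([float(r[0]) for r in rows])
        mean_p = np.array([float(r[1]) for r in rows])
        models: dict[float, ThresholdModel] = {}
        for col, name in enumerate(header):
            if not name.startswith("thr_conf_"):
                continue
            conf = float(name[len("thr_conf_") :])
            models[conf] = ThresholdModel(
                mode="table",
                lengths=lengths,
                thresholds=np.array([float(r[col]) for r in rows]),
                mean_pattern_len=mean_p,
                confidence=conf,
                scheme_kind=metadata.get("score", "linear"),
            )
        return models, metadata
    finally:
        if own:
            fh.close()


def write_mappings_tsv(
    rows: Iterable[tuple[str, FinalMapping]], path_or_fh
) -> None:
    """One row per final mapping; ``rows`` yields (read_id, mapping)."""
    own = not hasattr(path_or_fh, "write")
    fh: TextIO = _open_text(path_or_fh, "wt") if own else path_or_fh
    try:
        fh.write("\t".join(MAPPING_COLUMNS) + "\n")
        for read_id, m in rows:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        read_id,
                        m.ref_id if m.ref_id is not None else ".",
                        m.strand,
                        m.start if m.start is not None else m.a,
                        m.end if m.end is not None else m.b,
                        m.i,
                        m.j,
                        m.b - m.a + 1,
                        m.count,
                        f"{m.score:.6g}",
                        f"{m.threshold:.6g}",
                    )
                )
                + "\n"
            )
    finally:
        if own:
            fh.close()


def write_mappings_paf(
    rows: Sequence[tuple[str, int, FinalMapping, int]], path_or_fh
) -> None:
    """Minimal PAF-like emission: (read_id, read_len, mapping, ref_len)
    per row; the residue-match column carries the shared k-mer count."""
    own = not hasattr(path_or_fh, "write")
    fh: TextIO = _open_text(path_or_fh, "wt") if own else path_or_fh
    try:
        for read_id, read_len, m, ref_len in rows:
            start = m.start if m.start is not None else m.a
            end = m.end if m.end is not None else m.b + 1
            block = end - start
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        read_id, read_len, 0, read_len, m.strand,
                        m.ref_id or ".", ref_len, start, end,
                        m.count, block, 255, f"sc:f:{m.score:.6g}",
                    )
                )
                + "\n"
            )
    finally:
        if own:
            fh.close()
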