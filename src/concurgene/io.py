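"""Tab-delimited file dialects used by the pipeline.

All files are plain TSV with a mandatory header line.  Chromosome labels
are taken verbatim (no "chr" normalization); coordinates are 1-based
inclusive.  Writers and readers round-trip values at full precision
(`repr` float formatting) so a rerun under the same seed is byte-identical.

Dialects
--------
matrix        first column = row id (marker_id / probe / gene), one column
              per sample.
marker map    marker_id, chromosome, position.
SEG           sample_id, chromosome, start_pos, end_pos, n_markers,
              seg_mean [, state] — the optional 7th column carries CNV calls.
gene map      gene, chromosome, start, end (BED-like, 1-based inclusive;
              a zero-length gene covers markers at exactly its position).
outcomes      sample_id, time, event — or sample_id, label for dichotomous
              outcomes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_marker_map",
    "write_marker_map",
    "read_seg",
    "write_seg",
    "read_bed_genes",
    "write_bed_genes",
    "read_outcomes",
    "write_outcomes",
]


class ParseError(ValueError):
    """Malformed pipeline input file; the message names the offending line."""


def _fmt(value) -> str:
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    return str(value)


def _write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, frame.columns)) + "\n")
        for row in frame.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.reset_index()
    out.columns = [matrix.index.name or "id", *matrix.columns]
    _write_tsv(out, path)


def read_matrix(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    id_col = frame.columns[0]
    dup = frame[id_col].duplicated()
    if dup.any():
        line = int(dup.idxmax()) + 2  # header is line 1
        raise ParseError(f"{path}: duplicated row id at line {line}")
    out = frame.set_index(id_col)
    out.index.name = id_col
    return out.astype(float)


def write_marker_map(marker_map: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(marker_map[["marker_id", "chromosome", "position"]], path)


def read_marker_map(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep="\t", dtype={"marker_id": str, "chromosome": str, "position": int}
    )
    missing = {"marker_id", "chromosome", "position"} - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: marker map lacks columns {sorted(missing)}")
    dup = frame["marker_id"].duplicated()
    if dup.any():
        raise ParseError(f"{path}: duplicated marker_id at line {int(dup.idxmax()) + 2}")
    return frame


def write_seg(segments: pd.DataFrame, path: str | Path) -> None:
    cols = ["sample_id", "chromosome", "start_pos", "end_pos", "n_markers", "seg_mean"]
    if "state" in segments.columns:
        cols.append("state")
    _write_tsv(segments[cols], path)


def read_seg(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chromosome": str}, float_precision="round_trip")
    required = {"sample_id", "chromosome", "start_pos", "end_pos", "n_markers", "seg_mean"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: SEG file lacks columns {sorted(missing)}")
    bad = frame["end_pos"] < frame["start_pos"]
    if bad.any():
        raise ParseError(f"{path}: end < start at line {int(bad.idxmax()) + 2}")
    if (frame["n_markers"] < 1).any():
        bad_line = int((frame["n_markers"] < 1).idxmax()) + 2
        raise ParseError(f"{path}: n_markers < 1 at line {bad_line}")
    return frame


def write_bed_genes(genes: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(genes[["gene", "chromosome", "start", "end"]], path)


def read_bed_genes(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str, "chromosome": str})
    missing = {"gene", "chromosome", "start", "end"} - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: gene map lacks columns {sorted(missing)}")
    dup = frame["gene"].duplicated()
    if dup.any():
        raise ParseError(f"{path}: duplicated gene at line {int(dup.idxmax()) + 2}")
    bad = frame["end"] < frame["start"]
    if bad.any():
        raise ParseError(f"{path}: end < start at line {int(bad.idxmax()) + 2}")
    return frame


def write_outcomes(outcome: pd.DataFrame, path: str | Path) -> None:
    cols = (
        ["sample_id", "time", "event"]
        if "time" in outcome.columns
        else ["sample_id", "label"]
    )
    _write_tsv(outcome[cols], path)


def read_outcomes(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, float_precision="round_trip")
    if "time" in frame.columns:
        required = {"sample_id", "time", "event"}
        missing = required - set(frame.columns)
        if missing:
            raise ParseError(f"{path}: outcome table lacks columns {sorted(missing)}")
        if (frame["time"] <= 0).any():
            bad_line = int((frame["time"] <= 0).idxmax()) + 2
            raise ParseError(f"{path}: nonpositive time at line {bad_line}")
        if not frame["event"].isin([0, 1]).all():
            bad_line = int((~frame["event"].isin([0, 1])).idxmax()) + 2
            raise ParseError(f"{path}: event not in {{0,1}} at line {bad_line}")
    elif "label" in frame.columns:
        if not frame["label"].isin([0, 1]).all():
            bad_line = int((~frame["label"].isin([0, 1])).idxmax()) + 2
            raise ParseError(f"{path}: label not in {{0,1}} at line {bad_line}")
    else:
        raise ParseError(f"{path}: outcome table needs time/event or label columns")
    dup = frame["sample_id"].duplicated()
    if dup.any():
        raise ParseError(f"{path}: duplicated sample_id at line {int(dup.idxmax()) + 2}")
    return frame
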