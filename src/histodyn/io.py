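"""Plain-text I/O: 6-column BED, fixed-step bedGraph, annotation/truth TSV.

All coordinates are 0-based half-open. The BED score column carries occurrence
counts (collapsed duplicate reads); an absent score means 1. Comment lines
starting with ``#`` are metadata headers (seed, config hash) and are skipped on
read but exposed via ``read_header``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

__all__ = [
    "read_bed",
    "write_bed",
    "write_bedgraph",
    "read_bedgraph",
    "read_header",
    "write_tsv",
    "read_tsv",
]


class BedFormatError(ValueError):
    """A malformed BED record, reported with its 1-based line number."""


def _open_text(path_or_buf, mode="r"):
    if isinstance(path_or_buf, (str, Path)):
        return open(path_or_buf, mode), True
    return path_or_buf, False


def read_bed(path) -> pd.DataFrame:
    """Read a 6-column BED file into a DataFrame.

    Fewer columns are tolerated: missing name -> ".", missing score -> 1,
    missing strand -> "+". Malformed lines raise :class:`BedFormatError`
    naming the line number.
    """
    handle, close = _open_text(path)
    chroms, starts, ends, names, scores, strands = [], [], [], [], [], []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(
                    f"line {lineno}: expected at least 3 tab-separated fields, got {len(fields)}"
                )
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise BedFormatError(f"line {lineno}: non-integer coordinate: {exc}") from None
            if start < 0 or end <= start:
                raise BedFormatError(
                    f"line {lineno}: invalid interval [{start}, {end})"
                )
            score = 1
            if len(fields) >= 5 and fields[4] not in (".", ""):
                try:
                    score = int(fields[4])
                except ValueError:
                    raise BedFormatError(
                        f"line {lineno}: non-integer score {fields[4]!r}"
                    ) from None
                if score < 1:
                    raise BedFormatError(f"line {lineno}: score must be >= 1, got {score}")
            strand = fields[5] if len(fields) >= 6 else "+"
            if strand not in ("+", "-"):
                raise BedFormatError(f"line {lineno}: invalid strand {strand!r}")
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            names.append(fields[3] if len(fields) >= 4 else ".")
            scores.append(score)
            strands.append(strand)
    finally:
        if close:
            handle.close()
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.asarray(starts, dtype=np.int64),
            "end": np.asarray(ends, dtype=np.int64),
            "name": names,
            "score": np.asarray(scores, dtype=np.int64),
            "strand": strands,
        }
    )


def write_bed(df: pd.DataFrame, path, header: Mapping[str, object] | None = None) -> None:
    """Write a 6-column BED file, with optional ``# key=value`` header lines."""
    handle, close = _open_text(path, "w")
    try:
        _write_header(handle, header)
        df.to_csv(handle, sep="\t", header=False, index=False, columns=BED_COLUMNS)
    finally:
        if close:
            handle.close()


def _write_header(handle, header: Mapping[str, object] | None) -> None:
    if header:
        for key, value in header.items():
            handle.write(f"# {key}={value}\n")


def read_header(path) -> dict[str, str]:
    """Parse leading ``# key=value`` comment lines of a text file."""
    out: dict[str, str] = {}
    handle, close = _open_text(path)
    try:
        for line in handle:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                out[key.strip()] = value.strip()
    finally:
        if close:
            handle.close()
    return out


def write_bedgraph(
    chrom_values: Mapping[str, np.ndarray],
    bin_size: int,
    path,
    header: Mapping[str, object] | None = None,
) -> None:
    """Write fixed-step binned values as bedGraph (one line per bin)."""
    handle, close = _open_text(path, "w")
    try:
        _write_header(handle, header)
        for chrom, values in chrom_values.items():
            n = len(values)
            starts = np.arange(n, dtype=np.int64) * bin_size
            block = pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + bin_size,
                    "value": np.asarray(values, dtype=float),
                }
            )
            block.to_csv(handle, sep="\t", header=False, index=False, float_format="%.10g")
    finally:
        if close:
            handle.close()


def read_bedgraph(path) -> tuple[dict[str, np.ndarray], int, dict[str, str]]:
    """Read a fixed-step bedGraph written by :func:`write_bedgraph`.

    Returns (per-chromosome value arrays, bin size, header metadata).
    """
    meta = read_header(path)
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    if df.empty:
        raise ValueError(f"empty bedGraph: {path}")
    steps = (df["end"] - df["start"]).unique()
    if len(steps) != 1:
        raise ValueError(f"bedGraph {path} is not fixed-step: steps {sorted(steps)}")
    bin_size = int(steps[0])
    out: dict[str, np.ndarray] = {}
    for chrom, block in df.groupby("chrom", sort=False):
        expected = np.arange(len(block), dtype=np.int64) * bin_size
        if not np.array_equal(block["start"].to_numpy(), expected):
            raise ValueError(f"bedGraph {path}: non-contiguous bins on {chrom}")
        out[str(chrom)] = block["value"].to_numpy()
    return out, bin_size, meta


def write_tsv(df: pd.DataFrame, path, header: Mapping[str, object] | None = None, index=False) -> None:
    """Write a TSV table with optional ``# key=value`` header lines."""
    handle, close = _open_text(path, "w")
    try:
        _write_header(handle, header)
        df.to_csv(handle, sep="\t", index=index)
    finally:
        if close:
            handle.close()


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
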