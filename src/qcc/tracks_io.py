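"""Reading, aligning, and writing probe-level signal tracks.

Two plain-text formats are supported: 4-column bedGraph (chrom, start,
end, value; no header or track line required) and tab-delimited with a
header, either ``chrom/start/end/value`` or ``id/value``.  Coordinates
are 0-based half-open throughout.  An ``id/value`` file carries no
genomic coordinates, so a synthetic single-chromosome frame (chrom
``"probe"``, start = input row index) is attached and alignment then uses
the probe-id key.

Values are used as-is: correlation statistics are computed on the given
log-ratios with no normalization step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corestats import PairedReplicates
from .exceptions import DataError, ParseError

__all__ = [
    "ProbeTrack",
    "read_track",
    "write_track",
    "write_intervals",
    "align_replicates",
    "probe_intervals_to_genomic",
]

logger = logging.getLogger(__name__)

_COORD_COLS = ["chrom", "start", "end", "value"]


@dataclass
class ProbeTrack:
    """Sorted probe records: chrom, start, end, value (+ optional probe_id).

    Sorted by (chrom, start, end) with duplicate coordinate keys removed
    (first occurrence kept) and non-finite values dropped; both events
    are logged with counts at load time.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COORD_COLS if c not in self.data.columns]
        if missing:
            raise DataError(f"probe track is missing columns: {missing}")
        if len(self.data) == 0:
            raise DataError("probe track is empty")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_ids(self) -> bool:
        return "probe_id" in self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data["value"].to_numpy()

    def split_by_chrom(self) -> dict[str, "ProbeTrack"]:
        """One contiguous track per chromosome, preserving genomic order."""
        return {
            str(chrom): ProbeTrack(sub.reset_index(drop=True))
            for chrom, sub in self.data.groupby("chrom", sort=True)
        }


def _finalize(df: pd.DataFrame, origin: str) -> ProbeTrack:
    bad = ~np.isfinite(df["value"].to_numpy())
    if bad.any():
        logger.info("%s: dropped %d non-finite value(s)", origin, int(bad.sum()))
        df = df.loc[~bad]
    if len(df) == 0:
        raise DataError(f"{origin}: no valid probe records")
    df = df.sort_values(["chrom", "start", "end"], kind="stable")
    dup = df.duplicated(subset=["chrom", "start", "end"], keep="first")
    if dup.any():
        logger.info(
            "%s: dropped %d duplicate probe key(s), kept first", origin, int(dup.sum())
        )
        df = df.loc[~dup]
    return ProbeTrack(df.reset_index(drop=True))


def _numeric(df: pd.DataFrame, col: str, lines: np.ndarray, path, kind: str):
    converted = pd.to_numeric(df[col], errors="coerce")
    unparsed = converted.isna().to_numpy()
    if unparsed.any():
        # pandas rejects literal "nan"/"inf" tokens that Python accepts;
        # those are legitimate (non-finite rows are dropped downstream)
        converted = converted.copy()
        for idx in np.flatnonzero(unparsed):
            raw = df[col].iloc[idx]
            try:
                converted.iloc[idx] = float(raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: line {int(lines[idx])}: cannot parse "
                    f"{col!r} field {raw!r} as {kind}"
                ) from None
    if kind == "integer":
        vals = converted.to_numpy(dtype=np.float64)
        bad = ~np.isfinite(vals) | (vals != np.floor(vals))
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{path}: line {int(lines[idx])}: {col!r} field "
                f"{df[col].iloc[idx]!r} is not an integer"
            )
    return converted


def read_track(path, format: str = "bedgraph") -> ProbeTrack:
    """Load a probe track from ``path``.

    ``format`` is ``"bedgraph"`` (4 columns, no header; ``track``,
    ``browser`` and ``#`` lines skipped) or ``"tsv"`` (tab-delimited with
    a header of either chrom/start/end/value or id/value).  Malformed
    lines raise :class:`ParseError` with the 1-based line number.
    """
    path = Path(path)
    if format not in ("bedgraph", "tsv"):
        raise ParseError(f"unknown track format: {format!r}")
    raw_lines = path.read_text().splitlines()
    records: list[list[str]] = []
    linenos: list[int] = []
    header: list[str] | None = None
    for i, line in enumerate(raw_lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith(("#", "track", "browser")):
            continue
        fields = stripped.split("\t") if "\t" in stripped else stripped.split()
        if format == "tsv" and header is None:
            header = [f.strip().lower() for f in fields]
            continue
        records.append(fields)
        linenos.append(i)
    if format == "tsv" and header is None:
        raise DataError(f"{path}: empty file")
    if not records:
        raise DataError(f"{path}: no probe records")
    lines = np.asarray(linenos)

    if format == "bedgraph":
        widths = {len(r) for r in records}
        if widths != {4}:
            bad = next(j for j, r in enumerate(records) if len(r) != 4)
            raise ParseError(
                f"{path}: line {lines[bad]}: expected 4 bedGraph fields, "
                f"got {len(records[bad])}"
            )
        df = pd.DataFrame(records, columns=_COORD_COLS)
    else:
        if header == _COORD_COLS:
            columns = _COORD_COLS
        elif header == ["id", "value"]:
            columns = ["probe_id", "value"]
        else:
            raise ParseError(
                f"{path}: line 1: header must be chrom/start/end/value or "
                f"id/value, got {header}"
            )
        widths = {len(r) for r in records}
        if widths != {len(columns)}:
            bad = next(j for j, r in enumerate(records) if len(r) != len(columns))
            raise ParseError(
                f"{path}: line {lines[bad]}: expected {len(columns)} fields, "
                f"got {len(records[bad])}"
            )
        df = pd.DataFrame(records, columns=columns)
        if columns == ["probe_id", "value"]:
            # no coordinates in this format: attach a synthetic frame so the
            # track is positional; alignment will key on probe_id
            dup = df.duplicated(subset=["probe_id"], keep="first")
            if dup.any():
                logger.info(
                    "%s: dropped %d duplicate probe id(s), kept first",
                    path,
                    int(dup.sum()),
                )
                df = df.loc[~dup].reset_index(drop=True)
            df = pd.DataFrame(
                {
                    "chrom": "probe",
                    "start": np.arange(len(df), dtype=np.int64),
                    "end": np.arange(1, len(df) + 1, dtype=np.int64),
                    "value": df["value"],
                    "probe_id": df["probe_id"],
                }
            )
            lines = lines[: len(df)]

    df = df.assign(
        start=_numeric(df, "start", lines, path, "integer").astype(np.int64),
        end=_numeric(df, "end", lines, path, "integer").astype(np.int64),
        value=_numeric(df, "value", lines, path, "number").astype(np.float64),
    )
    if (df["end"] <= df["start"]).any():
        bad = int(lines[np.flatnonzero((df["end"] <= df["start"]).to_numpy())[0]])
        raise ParseError(f"{path}: line {bad}: interval end must exceed start")
    logger.info("%s: loaded %d probe records", path, len(df))
    return _finalize(df, str(path))


def write_track(track: ProbeTrack, path, format: str = "bedgraph") -> None:
    """Write a track as bedGraph (no header) or headered TSV; lossless round-trip."""
    path = Path(path)
    cols = _COORD_COLS
    if format == "bedgraph":
        track.data[cols].to_csv(path, sep="\t", header=False, index=False)
    elif format == "tsv":
        track.data[cols].to_csv(path, sep="\t", header=True, index=False)
    else:
        raise ParseError(f"unknown track format: {format!r}")


def write_intervals(
    intervals: Iterable[tuple[str, int, int]], path
) -> None:
    """Write genomic intervals as 3-column BED (0-based, half-open)."""
    path = Path(path)
    with path.open("w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{int(start)}\t{int(end)}\n")


def probe_intervals_to_genomic(
    track: ProbeTrack, probe_intervals: Sequence[tuple[int, int]]
) -> list[tuple[str, int, int]]:
    """Map 0-based half-open probe-index intervals to genomic BED intervals.

    Each probe interval must lie within one chromosome of the (sorted)
    track; the genomic interval spans the first probe's start to the last
    probe's end.
    """
    chroms = track.data["chrom"].to_numpy()
    starts = track.data["start"].to_numpy()
    ends = track.data["end"].to_numpy()
    out = []
    for s, e in probe_intervals:
        if not (0 <= s < e <= len(track)):
            raise DataError(f"probe interval ({s}, {e}) outside track of {len(track)}")
        block = set(chroms[s:e])
        if len(block) != 1:
            raise DataError(f"probe interval ({s}, {e}) spans chromosomes {block}")
        out.append((str(chroms[s]), int(starts[s]), int(ends[e - 1])))
    return out


def align_replicates(
    track_a: ProbeTrack, track_b: ProbeTrack, join: str = "intersection"
) -> PairedReplicates:
    """Pair two tracks probe-by-probe on shared keys.

    Probes are matched on the probe-id column when both tracks carry one,
    otherwise exactly on (chrom, start, end).  Only the intersection is
    retained (the only supported join); unmatched counts on each side are
    logged.  Output order is genomic order, so cluster calling can run on
    the paired vectors.  Alignment is symmetric: ``align(a, b)`` pairs
    the same probes as ``align(b, a)`` with the value columns swapped.
    """
    if join != "intersection":
        raise DataError(f"only the intersection join is supported, got {join!r}")
    key = ["probe_id"] if (track_a.has_ids and track_b.has_ids) else [
        "chrom",
        "start",
        "end",
    ]
    left = track_a.data[key + ["chrom", "start", "end", "value"]].copy() \
        if key == ["probe_id"] else track_a.data[key + ["value"]].copy()
    left = left.loc[:, ~left.columns.duplicated()]
    right = track_b.data[key + ["value"]].copy()
    merged = left.merge(right, on=key, how="inner", suffixes=("_x", "_y"))
    n_a, n_b, n = len(track_a), len(track_b), len(merged)
    if n == 0:
        raise DataError("replicate tracks share no probes")
    if n < n_a or n < n_b:
        logger.info(
            "alignment: %d unmatched probe(s) in first track, %d in second",
            n_a - n,
            n_b - n,
        )
    merged = merged.sort_values(["chrom", "start", "end"], kind="stable")
    if key == ["probe_id"]:
        keys = merged["probe_id"].tolist()
    else:
        keys = list(
            zip(merged["chrom"], merged["start"].tolist(), merged["end"].tolist())
        )
    return PairedReplicates(
        merged["value_x"].to_numpy(), merged["value_y"].to_numpy(), probe_keys=keys
    )
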