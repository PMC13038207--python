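"""Readers and writers for every external format the pipeline touches.

All internal times are Zeitgeber (ZT) minutes, with ZT0 = lights-on;
conversion from wall-clock happens only inside readers.  Monitor rows whose
status field is not 1 become *missing* bins — downstream sleep detection
treats a missing bin as breaking any inactivity run, so a recording gap can
never fabricate sleep.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("somno")

#: Number of trailing channel columns in a beam-crossing monitor file.
DAM_N_CHANNELS = 32

#: Decimal places used when serialising floats in output tables.
FLOAT_PRECISION = 6


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level.upper())


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ActivityTrace:
    """Per-fly beam-crossing time series with its light schedule.

    Parameters
    ----------
    fly_id, genotype, sex
        Identifiers; ``sex`` may be ``None``.
    bin_minutes
        Acquisition cadence in minutes per bin (default 1).
    zt0_offset_min
        Minutes from the start of the record to the first ZT0 (lights-on).
        Bin ``i`` covers ZT minute ``i * bin_minutes - zt0_offset_min``.
    schedule
        ``"LD"`` (12:12 light/dark) or ``"DD"`` (constant darkness).
    counts
        Non-negative beam crossings per bin.
    missing
        Boolean mask, True where a bin could not be recorded.
    """

    fly_id: str
    genotype: str
    counts: np.ndarray
    sex: str | None = None
    bin_minutes: int = 1
    zt0_offset_min: int = 0
    schedule: str = "LD"
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if (self.counts < 0).any():
            raise ValueError(f"negative counts in trace {self.fly_id!r}")
        if self.bin_minutes < 1:
            raise ValueError("bin_minutes must be a positive integer")
        if self.schedule not in ("LD", "DD"):
            raise ValueError(f"schedule must be 'LD' or 'DD', got {self.schedule!r}")
        if self.missing is None:
            self.missing = np.zeros(self.counts.size, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.counts.shape:
                raise ValueError("missing mask must match counts length")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def bins_per_day(self) -> int:
        return 1440 // self.bin_minutes

    def zt_min(self, i: int) -> int:
        """ZT minute at the start of bin ``i``."""
        return i * self.bin_minutes - self.zt0_offset_min


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional universe of testable genes."""

    sets: dict[str, list[str]]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) != len(set(members)):
                raise ValueError(f"duplicate members in gene set {name!r}")


# ---------------------------------------------------------------------------
# Activity readers
# ---------------------------------------------------------------------------

def read_dam_monitor(
    path: str | Path,
    bin_minutes: int = 1,
    channel_map: Mapping[int, tuple[str, str]] | None = None,
) -> list[ActivityTrace]:
    """Parse a TriKinetics-DAM-style monitor text file.

    Each tab-delimited row carries a reading index, date, time, a status
    field, and 32 trailing integer channel columns.  Rows with status != 1
    are recorded as missing bins for every channel and reported via the
    parse log; timestamps must be strictly increasing at the stated cadence.

    Parameters
    ----------
    channel_map
        Optional ``{channel (1-based): (fly_id, genotype)}``; channels not
        listed are skipped.  By default all 32 channels are returned with
        ids ``ch01`` .. ``ch32`` and genotype ``"unknown"``.
    """
    path = Path(path)
    statuses: list[int] = []
    times: list[datetime] = []
    rows: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 4 + DAM_N_CHANNELS:
                raise FormatError(
                    f"{path.name}:{lineno}: expected at least {4 + DAM_N_CHANNELS} "
                    f"columns, got {len(fields)}"
                )
            try:
                stamp = datetime.strptime(
                    f"{fields[1]} {fields[2]}", "%d %b %y %H:%M:%S"
                )
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: bad timestamp") from exc
            if times and stamp <= times[-1]:
                raise FormatError(
                    f"{path.name}:{lineno}: non-monotone timestamp {stamp}"
                )
            try:
                status = int(fields[3])
                channels = [int(v) for v in fields[-DAM_N_CHANNELS:]]
            except ValueError as exc:
                raise FormatError(
                    f"{path.name}:{lineno}: non-integer channel or status field"
                ) from exc
            times.append(stamp)
            statuses.append(status)
            rows.append(channels)

    if not rows:
        raise FormatError(f"{path.name}: empty monitor file")

    data = np.asarray(rows, dtype=np.int64)
    missing = np.asarray(statuses) != 1
    if missing.any():
        logger.warning(
            "%s: %d of %d rows have status != 1; flagged as missing bins",
            path.name, int(missing.sum()), len(rows),
        )
    data[missing, :] = 0

    if channel_map is None:
        channel_map = {
            ch: (f"ch{ch:02d}", "unknown") for ch in range(1, DAM_N_CHANNELS + 1)
        }

    traces = []
    for ch, (fly_id, genotype) in sorted(channel_map.items()):
        if not 1 <= ch <= DAM_N_CHANNELS:
            raise ValueError(f"channel {ch} out of range 1..{DAM_N_CHANNELS}")
        traces.append(
            ActivityTrace(
                fly_id=fly_id,
                genotype=genotype,
                counts=data[:, ch - 1],
                bin_minutes=bin_minutes,
                missing=missing.copy(),
            )
        )
    return traces


def read_activity_csv(path: str | Path, schedule: str = "LD") -> list[ActivityTrace]:
    """Read long-format activity: columns fly_id, genotype, zt_min, counts.

    Bins must be contiguous at a fixed cadence per fly; a gap or duplicate
    (fly_id, zt_min) pair is rejected.
    """
    df = pd.read_csv(path)
    required = {"fly_id", "genotype", "zt_min", "counts"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise FormatError(f"activity CSV missing columns: {sorted(missing_cols)}")
    if (df["counts"] < 0).any():
        raise FormatError("negative counts in activity CSV")

    traces = []
    for fly_id, sub in df.groupby("fly_id", sort=True):
        sub = sub.sort_values("zt_min")
        zt = sub["zt_min"].to_numpy()
        if np.unique(zt).size != zt.size:
            raise FormatError(f"duplicate (fly_id, zt_min) for fly {fly_id!r}")
        steps = np.diff(zt)
        if zt.size > 1:
            cadence = int(steps[0])
            if cadence <= 0 or not (steps == cadence).all():
                gap_at = int(zt[np.argmax(steps != cadence)])
                raise FormatError(
                    f"non-contiguous bins for fly {fly_id!r} (gap after ZT {gap_at})"
                )
        else:
            cadence = 1
        traces.append(
            ActivityTrace(
                fly_id=str(fly_id),
                genotype=str(sub["genotype"].iloc[0]),
                counts=sub["counts"].to_numpy(),
                bin_minutes=cadence,
                zt0_offset_min=-int(zt[0]),
                schedule=schedule,
            )
        )
    return traces


def write_activity_csv(traces: Sequence[ActivityTrace], path: str | Path) -> None:
    """Write traces in the long format consumed by :func:`read_activity_csv`."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "fly_id": tr.fly_id,
                    "genotype": tr.genotype,
                    "zt_min": [tr.zt_min(i) for i in range(tr.n_bins)],
                    "counts": tr.counts,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_image(path: str | Path) -> np.ndarray:
    """Read a 2-D grayscale fluorescence image (TIFF or PNG) as float.

    Multi-channel images are reduced to their first channel.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(path)
    else:
        from skimage.io import imread

        img = imread(path)
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:
        img = img[..., 0] if img.shape[-1] <= 4 else img[0]
    if img.ndim != 2:
        raise FormatError(f"{path.name}: expected a 2-D grayscale image")
    return img


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def read_counts(
    path: str | Path,
    format: str = "tsv",
    metadata: str | Path | None = None,
):
    """Read a gene x sample raw count table into a :class:`~somno.robust_de.CountMatrix`.

    ``format="tsv"`` expects gene rows with a leading identifier column and
    one column per sample.  ``format="mtx"`` expects a MatrixMarket triplet
    file with sidecars ``<stem>.genes.txt`` and ``<stem>.samples.txt``.
    ``metadata`` points to a TSV with columns ``sample`` and ``genotype``
    (control = 0, mutant = 1 after factor coding).
    """
    from .robust_de import CountMatrix  # deferred: avoids import cycle

    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        bad = df.map(lambda v: not np.isreal(v) or pd.isna(v))
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise FormatError(
                f"non-numeric cell at gene {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        genes = [str(g) for g in df.index]
        samples = [str(s) for s in df.columns]
        counts = df.to_numpy()
    elif format == "mtx":
        from scipy.io import mmread

        counts = np.asarray(mmread(path).todense())
        genes = Path(path).with_suffix(".genes.txt").read_text().split()
        samples = Path(path).with_suffix(".samples.txt").read_text().split()
    else:
        raise ValueError(f"unknown counts format {format!r}")

    if len(genes) != len(set(genes)):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise FormatError(f"duplicate gene identifiers: {dupes}")
    counts = np.asarray(counts)
    if not np.allclose(counts, np.round(counts)):
        raise FormatError("counts matrix contains non-integer values")
    counts = counts.astype(np.int64)

    genotype = None
    if metadata is not None:
        meta = pd.read_csv(metadata, sep="\t")
        meta = meta.set_index(meta.columns[0])
        absent = [s for s in meta.index.astype(str) if s not in samples]
        if absent:
            raise FormatError(f"metadata samples absent from matrix: {absent}")
        genotype = np.array(
            [int(meta.loc[s, "genotype"]) for s in samples], dtype=np.int64
        )
    return CountMatrix(genes=genes, samples=samples, counts=counts, genotype=genotype)


def write_counts_tsv(matrix, path: str | Path) -> None:
    """Write a CountMatrix as the TSV layout read_counts consumes."""
    pd.DataFrame(matrix.counts, index=matrix.genes, columns=matrix.samples).to_csv(
        path, sep="\t"
    )


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets_gmt(path: str | Path) -> GeneSetCollection:
    """Read standard GMT: name, description, then member genes, tab-delimited.

    Duplicate members within a set are dropped with a logged warning count.
    """
    sets: dict[str, list[str]] = {}
    n_dupes = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            members = list(dict.fromkeys(fields[2:]))  # order-preserving dedup
            n_dupes += len(fields[2:]) - len(members)
            sets[name] = members
    if n_dupes:
        logger.warning("GMT %s: dropped %d duplicate members", path, n_dupes)
    return GeneSetCollection(sets=sets)


def write_gene_sets_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------

def write_table(
    records: Sequence[Mapping],
    path: str | Path,
    format: str = "tsv",
    precision: int = FLOAT_PRECISION,
) -> None:
    """Write records sharing one field schema, with deterministic column order.

    Column order follows the first record's key order; floats are rounded to
    ``precision`` decimal places.  ``format="json"`` writes an array of
    objects.
    """
    records = list(records)
    if records:
        schema = list(records[0].keys())
        for i, rec in enumerate(records):
            if list(rec.keys()) != schema:
                raise ValueError(f"record {i} does not match schema {schema}")
    else:
        schema = []

    def _fmt(v):
        if isinstance(v, (float, np.floating)):
            return round(float(v), precision)
        if isinstance(v, np.integer):
            return int(v)
        return v

    rows = [{k: _fmt(v) for k, v in rec.items()} for rec in records]
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(schema) + "\n")
            for row in rows:
                fh.write("\t".join("" if row[k] is None else str(row[k]) for k in schema) + "\n")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown table format {format!r}")


def read_table(path: str | Path, format: str = "tsv") -> list[dict]:
    """Read back a table written by :func:`write_table`."""
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        return df.to_dict(orient="records")
    if format == "json":
        with open(path) as fh:
            return json.load(fh)
    raise ValueError(f"unknown table format {format!r}")
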