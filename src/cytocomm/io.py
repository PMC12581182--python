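"""Event-level cytometry I/O and study metadata.

Event data travel as :class:`EventMatrix` (cells x channels, raw intensities,
one acquisition-time channel).  Two on-disk dialects are supported: FCS 3.0
(float32 list mode) and a bit-exact CSV fallback (UTF-8, comma separated,
header row of channel names, ``.`` decimal point).  Sample sheets and
ligand-receptor catalogues are plain CSV.
"""

from __future__ import annotations

import re
import struct
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventMatrix",
    "normalize_marker",
    "read_events",
    "write_events",
    "read_sample_sheet",
    "read_lr_catalogue",
    "default_lr_catalogue",
    "MARKER_ALIASES",
]

TOOL_VERSION = "cytocomm-0.1.0"

# Canonical spellings for markers whose names vary across panels and vendors.
# Keys are names stripped of non-alphanumerics and upper-cased.
MARKER_ALIASES = {
    "PD1": "PD1",
    "PDL1": "PDL1",
    "PDL2": "PDL2",
    "CTLA4": "CTLA4",
    "HLADR": "HLA-DR",
    "TIM3": "TIM3",
    "LAG3": "LAG3",
    "41BB": "CD137",
    "41BBL": "CD137L",
    "CD137": "CD137",
    "CD137L": "CD137L",
    "ICOS": "ICOS",
    "ICOSL": "ICOSL",
    "OX40": "OX40",
    "OX40L": "OX40L",
    "BTLA": "BTLA",
    "HVEM": "HVEM",
    "TIGIT": "TIGIT",
    "PVR": "PVR",
    "CD155": "PVR",
    "FAS": "FAS",
    "CD95": "FAS",
    "FASL": "FASL",
    "CD40": "CD40",
    "CD40L": "CD40L",
    "CD80": "CD80",
    "CD86": "CD86",
    "GALECTIN9": "GAL9",
    "GAL9": "GAL9",
}


def normalize_marker(name: str) -> str:
    """Map a marker name to its canonical spelling (e.g. ``PD-1`` -> ``PD1``).

    Unknown names pass through unchanged.
    """
    key = re.sub(r"[^0-9A-Za-z]", "", name).upper()
    return MARKER_ALIASES.get(key, name)


@dataclass
class EventMatrix:
    """One sample's cells x channels raw intensities.

    Parameters
    ----------
    sample_id : str
        Identifier of the sample the events belong to.
    channels : list of str
        Ordered channel names; marker channels are canonicalised via
        :func:`normalize_marker` on construction.
    values : ndarray of shape (n_events, n_channels)
        Raw-scale intensities (non-negative except for baseline noise).
    time_channel : str
        Name of the acquisition-time channel, if present.
    labels : DataFrame, optional
        Per-cell annotations (ground-truth metacluster, QC flags, ...).
    """

    sample_id: str
    channels: list[str]
    values: np.ndarray
    time_channel: str = "Time"
    labels: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x channels)")
        if self.values.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.values.shape[1]} value columns for "
                f"{len(self.channels)} channel names"
            )
        if np.isnan(self.values).any():
            raise ValueError("event matrix contains NaN")
        self.channels = [
            c if c == self.time_channel else normalize_marker(c)
            for c in self.channels
        ]
        if self.labels is not None and len(self.labels) != len(self.values):
            raise ValueError("labels length does not match event count")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def marker_channels(self) -> list[str]:
        return [c for c in self.channels if c != self.time_channel]

    def channel_index(self, name: str) -> int:
        name = normalize_marker(name)
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.sample_id}") from None

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.channel_index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.channels)

    def with_values(self, values: np.ndarray, labels: pd.DataFrame | None = None,
                    row_mask: np.ndarray | None = None) -> "EventMatrix":
        """Copy with new values; ``row_mask`` subsets labels consistently."""
        lab = self.labels if labels is None else labels
        if lab is not None and row_mask is not None:
            lab = lab.loc[row_mask].reset_index(drop=True)
        return EventMatrix(
            sample_id=self.sample_id,
            channels=list(self.channels),
            values=values,
            time_channel=self.time_channel,
            labels=lab,
            metadata=dict(self.metadata),
        )

    def sorted_by_time(self) -> "EventMatrix":
        if self.time_channel not in self.channels:
            return self
        order = np.argsort(self.channel(self.time_channel), kind="stable")
        out = self.with_values(self.values[order])
        if self.labels is not None:
            out.labels = self.labels.iloc[order].reset_index(drop=True)
        return out


# ---------------------------------------------------------------------------
# FCS 3.0
# ---------------------------------------------------------------------------

_HEADER_LEN = 58  # "FCS3.0" + 4 spaces + 6 eight-byte ASCII offsets


def _fcs_text_segment(pairs: dict[str, str], delim: str = "/") -> bytes:
    parts = [delim]
    for k, v in pairs.items():
        v = str(v)
        if delim in k or delim in v:
            raise ValueError("delimiter may not appear in FCS keywords")
        parts.append(f"{k}{delim}{v}{delim}")
    return "".join(parts).encode("utf-8")


def write_fcs(events: EventMatrix, path) -> None:
    """Write a minimal FCS 3.0 file: float32, list mode, little-endian."""
    path = Path(path)
    values = np.asarray(events.values, dtype="<f4")
    n, p = values.shape
    data = values.tobytes()

    pairs: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$NEXTDATA": "0",
        "$BEGINDATA": "0" * 12,  # placeholder, fixed width
        "$ENDDATA": "0" * 12,
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$TOT": str(n),
        "$PAR": str(p),
        "$FIL": path.name,
        "$SRC": events.sample_id,
        "CYTOCOMM_VERSION": TOOL_VERSION,
    }
    for key, val in events.metadata.items():
        k = str(key).upper()
        if not k.startswith("$"):
            pairs.setdefault(k, str(val))
    rng_top = float(np.max(values)) if n else 0.0
    for i, ch in enumerate(events.channels, start=1):
        pairs[f"$P{i}N"] = ch
        pairs[f"$P{i}S"] = ch
        pairs[f"$P{i}B"] = "32"
        pairs[f"$P{i}E"] = "0,0"
        pairs[f"$P{i}R"] = str(int(max(rng_top, 1.0)) + 1)

    text = _fcs_text_segment(pairs)
    text_start = _HEADER_LEN
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + len(data) - 1 if data else 0
    # patch fixed-width offsets into the TEXT segment
    text = text.replace(
        b"$BEGINDATA/" + b"0" * 12, b"$BEGINDATA/" + b"%012d" % data_start
    ).replace(b"$ENDDATA/" + b"0" * 12, b"$ENDDATA/" + b"%012d" % max(data_end, 0))

    def _off(x: int) -> bytes:
        return b"%8d" % x if x < 10**8 else b"       0"

    header = b"FCS3.0    " + _off(text_start) + _off(text_end)
    header += _off(data_start if data else 0) + _off(data_end)
    header += _off(0) + _off(0)
    assert len(header) == _HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data)


def _parse_fcs_text(raw: bytes) -> dict[str, str]:
    delim = raw[:1].decode("latin-1")
    body = raw.decode("latin-1")[1:]
    # split on single delimiters; doubled delimiters escape a literal one
    tokens = re.split(re.escape(delim), body)
    merged: list[str] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        while i + 1 < len(tokens) and tokens[i + 1] == "" and i + 2 < len(tokens):
            tok += delim + tokens[i + 2]
            i += 2
        merged.append(tok)
        i += 1
    if merged and merged[-1] == "":
        merged.pop()
    if len(merged) % 2:
        merged.pop()
    return {merged[j].strip(): merged[j + 1] for j in range(0, len(merged), 2)}


def read_fcs(path) -> EventMatrix:
    """Read an FCS 3.0 file (float32/double list mode)."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_LEN:
        raise ValueError(f"{path}: truncated FCS header")
    if not raw[:6] == b"FCS3.0":
        raise ValueError(f"{path}: not an FCS 3.0 file")

    def _int(b: bytes) -> int:
        s = b.decode("latin-1").strip()
        return int(s) if s else 0

    text_start, text_end = _int(raw[10:18]), _int(raw[18:26])
    data_start, data_end = _int(raw[26:34]), _int(raw[34:42])
    if text_end >= len(raw) or text_start >= text_end:
        raise ValueError(f"{path}: truncated TEXT segment")
    kw = _parse_fcs_text(raw[text_start : text_end + 1])

    if data_start == 0:
        data_start = int(kw.get("$BEGINDATA", 0))
        data_end = int(kw.get("$ENDDATA", 0))
    n = int(kw["$TOT"])
    p = int(kw["$PAR"])
    dtype_code = kw.get("$DATATYPE", "F").upper()
    if dtype_code not in ("F", "D"):
        raise ValueError(f"{path}: unsupported $DATATYPE {dtype_code}")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    itemsize = 4 if dtype_code == "F" else 8
    expected = n * p * itemsize
    if n and (data_end - data_start + 1) != expected:
        raise ValueError(
            f"{path}: data segment holds {data_end - data_start + 1} bytes, "
            f"expected {expected} for $TOT={n} x $PAR={p}"
        )
    if data_start + expected > len(raw):
        raise ValueError(f"{path}: truncated DATA segment")
    dt = np.dtype(f"{endian}f{itemsize}")
    values = (
        np.frombuffer(raw, dtype=dt, count=n * p, offset=data_start)
        .reshape(n, p)
        .astype(float)
        if n
        else np.empty((0, p))
    )
    channels = []
    for i in range(1, p + 1):
        name = kw.get(f"$P{i}S") or kw.get(f"$P{i}N") or f"P{i}"
        channels.append(name)
    time_channel = next(
        (c for c in channels if c.strip().lower() == "time"), "Time"
    )
    meta = {k: v for k, v in kw.items() if k.startswith("CYTOCOMM_")}
    sample_id = kw.get("$SRC") or path.stem
    return EventMatrix(
        sample_id=sample_id,
        channels=channels,
        values=values,
        time_channel=time_channel,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# CSV dialect (UTF-8, comma, header row = channel names, '.' decimal)
# ---------------------------------------------------------------------------

def write_csv_events(events: EventMatrix, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# sample_id: {events.sample_id}\n")
        fh.write(f"# tool: {TOOL_VERSION}\n")
        for key, val in events.metadata.items():
            fh.write(f"# {key}: {val}\n")
        fh.write(",".join(events.channels) + "\n")
        np.savetxt(fh, events.values, delimiter=",", fmt="%.9g")


def read_csv_events(path) -> EventMatrix:
    path = Path(path)
    meta: dict[str, str] = {}
    sample_id = path.stem
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                k, v = k.strip(), v.strip()
                if k == "sample_id":
                    sample_id = v
                elif k != "tool":
                    meta[k] = v
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in event CSV")
    channels = [str(c) for c in df.columns]
    time_channel = next(
        (c for c in channels if c.strip().lower() == "time"), "Time"
    )
    return EventMatrix(
        sample_id=sample_id,
        channels=channels,
        values=df.to_numpy(dtype=float),
        time_channel=time_channel,
        metadata=meta,
    )


def read_events(path, dialect: str = "auto") -> EventMatrix:
    """Read an :class:`EventMatrix` from ``path``.

    ``dialect`` is ``"fcs3"``, ``"csv"`` or ``"auto"`` (sniffed from the
    file's leading bytes).
    """
    path = Path(path)
    if dialect == "auto":
        with open(path, "rb") as fh:
            dialect = "fcs3" if fh.read(6) == b"FCS3.0" else "csv"
    if dialect == "fcs3":
        return read_fcs(path)
    if dialect == "csv":
        return read_csv_events(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_events(events: EventMatrix, path, dialect: str = "fcs3") -> None:
    if dialect == "fcs3":
        write_fcs(events, path)
    elif dialect == "csv":
        write_csv_events(events, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Sample sheet and ligand-receptor catalogue
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = ("sample_id", "group", "path")


def read_sample_sheet(path, groups: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a sample sheet CSV with columns sample_id, group, path[, panel_id].

    Unknown columns are preserved.  Duplicate sample ids and (optionally)
    undeclared group labels raise.
    """
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing required columns: {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    if groups is not None:
        bad = sorted(set(df["group"]) - set(groups))
        if bad:
            raise ValueError(f"undeclared group labels: {bad}")
    return df


def read_lr_catalogue(path=None) -> pd.DataFrame:
    """Read a ligand-receptor catalogue CSV (columns ligand, receptor).

    With ``path=None`` the shipped default catalogue is returned.  Marker
    names are canonicalised; duplicate ordered pairs raise.
    """
    if path is None:
        with resources.files("cytocomm.data").joinpath(
            "lr_catalogue.csv"
        ).open("r") as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    for col in ("ligand", "receptor"):
        if col not in df.columns:
            raise ValueError(f"LR catalogue missing column {col!r}")
        df[col] = df[col].map(normalize_marker)
    if df.duplicated(subset=["ligand", "receptor"]).any():
        raise ValueError("duplicate ordered ligand-receptor pairs in catalogue")
    return df


def default_lr_catalogue() -> pd.DataFrame:
    return read_lr_catalogue(None)
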