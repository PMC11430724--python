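"""Containers and file formats for TMS-EEG sessions.

Covers the artifact plumbing around the analysis: 64-channel EEG records
(raw float32 + JSON sidecar, or 16-bit EDF), per-session event tables
(CSV, one row per trial with TMS-pulse / stimulus / phoneme timestamps
and true vs. identified labels), montages (CSV with positions and
reference/decodable flags), and stimulus-locked epoch extraction.

Timestamps are seconds from recording start; CSV stores them at
microsecond precision.  Epochs are half-open ``[t0, t1)`` windows so a
window of ``(t1 - t0) * fs`` samples never double-counts a boundary
sample.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = "MISSING"

#: consonants x vowels of the discrimination task; 4 x 5 x 2 orders = 40 pairs
CONSONANTS = ("b", "p", "d", "t")
VOWELS = ("i", "E", "A", "u", "oU")
ORDERS = ("CV", "VC")

#: place-of-articulation categories
CATEGORY_OF_CONSONANT = {"b": "bilabial", "p": "bilabial", "d": "alveolar", "t": "alveolar"}

EVENT_COLUMNS = [
    "trial_index",
    "t_tms_pulse2",
    "t_stim_onset",
    "t_phoneme_onsets",
    "site",
    "tms",
    "order",
    "true_label",
    "response_label",
    "rt",
]


def phoneme_pair_inventory(
    consonants: Sequence[str] = CONSONANTS,
    vowels: Sequence[str] = VOWELS,
    orders: Sequence[str] = ORDERS,
) -> list[str]:
    """All phoneme-pair labels, e.g. ``b+A`` (CV) and ``A+b`` (VC)."""
    pairs = []
    for order in orders:
        for c in consonants:
            for v in vowels:
                pairs.append(f"{c}+{v}" if order == "CV" else f"{v}+{c}")
    return pairs


def pair_consonant(label: str) -> str:
    """Consonant member of a pair label (works for CV and VC order)."""
    a, b = label.split("+")
    return a if a in CONSONANTS else b


class EventValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# montage


@dataclass
class Montage:
    """Electrode montage: labels, positions (mm) and role flags.

    Exactly one channel is the reference; the decodable subset (reference
    and configured peripheral channels excluded) must have a size
    divisible by three so it can be partitioned into channel triples.
    """

    table: pd.DataFrame

    REQUIRED = ("label", "x", "y", "z", "is_reference", "is_decodable")

    def __post_init__(self) -> None:
        for c in self.REQUIRED:
            if c not in self.table.columns:
                raise ValueError(f"montage missing column {c!r}")
        t = self.table
        if t["label"].duplicated().any():
            raise ValueError("montage labels must be unique")
        if int(t["is_reference"].sum()) != 1:
            raise ValueError("montage must have exactly one reference channel")
        n_dec = int(t["is_decodable"].sum())
        if n_dec % 3 != 0:
            raise ValueError(
                f"decodable channel count {n_dec} not divisible by 3; "
                "adjust is_decodable flags"
            )
        if bool(t.loc[t["is_reference"], "is_decodable"].any()):
            raise ValueError("the reference channel cannot be decodable")

    @property
    def labels(self) -> list[str]:
        return list(self.table["label"])

    @property
    def reference(self) -> str:
        return str(self.table.loc[self.table["is_reference"], "label"].iloc[0])

    @property
    def decodable_labels(self) -> list[str]:
        return list(self.table.loc[self.table["is_decodable"], "label"])

    def positions(self, labels: Iterable[str] | None = None) -> np.ndarray:
        t = self.table.set_index("label")
        labels = list(labels) if labels is not None else self.labels
        return t.loc[labels, ["x", "y", "z"]].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["is_reference"] = out["is_reference"].astype(int)
        out["is_decodable"] = out["is_decodable"].astype(int)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Montage":
        t = pd.read_csv(path)
        t["is_reference"] = t["is_reference"].astype(bool)
        t["is_decodable"] = t["is_decodable"].astype(bool)
        return cls(t)


#: labels of the 64-channel cap used by the default montage
DEFAULT_CAP_LABELS = [
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2",
    "FC6", "T7", "C3", "Cz", "C4", "T8", "CP5", "CP1", "CP2", "CP6", "P7",
    "P3", "Pz", "P4", "P8", "POz", "O1", "Oz", "O2", "AF7", "AF3", "AF4",
    "AF8", "F5", "F1", "F2", "F6", "FC3", "FCz", "FC4", "C5", "C1", "C2",
    "C6", "CP3", "CP4", "P5", "P1", "P2", "P6", "PO5", "PO3", "PO4", "PO6",
    "FT7", "FT8", "TP7", "TP8", "PO7", "PO8", "M1", "M2", "CPz",
]

DEFAULT_REFERENCE = "CPz"
#: peripheral channels excluded from decoding: the two mastoids plus the
#: frontal-pole midline electrode, leaving 60 decodable channels (20 triples)
DEFAULT_EXCLUDED = ("M1", "M2", "Fpz")


def default_montage(
    reference: str = DEFAULT_REFERENCE,
    excluded: Sequence[str] = DEFAULT_EXCLUDED,
) -> Montage:
    """64-channel cap montage with standard 10-05 positions (mm)."""
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        try:
            std = mne.channels.make_standard_montage("standard_1005")
        except ValueError:  # pragma: no cover - montage renamed in newer mne
            std = mne.channels.make_standard_montage("colin27_1005")
    pos = std.get_positions()["ch_pos"]
    rows = []
    for lab in DEFAULT_CAP_LABELS:
        p = np.asarray(pos[lab], dtype=float) * 1000.0  # m -> mm
        rows.append(
            {
                "label": lab,
                "x": p[0],
                "y": p[1],
                "z": p[2],
                "is_reference": lab == reference,
                "is_decodable": lab != reference and lab not in excluded,
            }
        )
    return Montage(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# EEG records


@dataclass
class EEGRecord:
    """Multichannel sampled signal in microvolts."""

    sample_rate: float
    channels: list[str]
    data: np.ndarray  # (n_channels, n_samples)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but {len(self.channels)} labels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data contain non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


def write_eeg_record(record: EEGRecord, path: str | Path, dialect: str = "raw") -> None:
    """Write an EEG record as raw float32 + JSON sidecar or 16-bit EDF."""
    path = Path(path)
    if dialect == "raw":
        path.write_bytes(record.data.astype("<f4").tobytes(order="C"))
        sidecar = {
            "fs": record.sample_rate,
            "channels": list(record.channels),
            "units": "uV",
            "start_time": record.start_time,
            "dtype": "float32",
            "order": "channels_major",
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    elif dialect == "edf":
        _write_edf(record, path)
    else:
        raise ValueError(f"unsupported dialect {dialect!r}; use 'raw' or 'edf'")


def read_eeg_record(path: str | Path, dialect: str | None = None) -> EEGRecord:
    """Read an EEG record; dialect inferred from the extension when omitted."""
    path = Path(path)
    if dialect is None:
        dialect = "edf" if path.suffix.lower() == ".edf" else "raw"
    if dialect == "raw":
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(f"missing sidecar {sidecar_path}")
        meta = json.loads(sidecar_path.read_text())
        payload = path.read_bytes()
        if len(payload) % 4 != 0:
            raise ValueError(
                f"raw payload of {len(payload)} bytes does not divide into "
                "float32 samples"
            )
        data = np.frombuffer(payload, dtype="<f4").astype(float)
        n_ch = len(meta["channels"])
        if data.size % n_ch != 0:
            raise ValueError(
                f"raw payload of {data.size} samples does not divide into "
                f"{n_ch} channels"
            )
        return EEGRecord(
            sample_rate=float(meta["fs"]),
            channels=list(meta["channels"]),
            data=data.reshape(n_ch, -1),
            start_time=float(meta.get("start_time", 0.0)),
        )
    if dialect == "edf":
        return _read_edf(path)
    raise ValueError(f"unsupported dialect {dialect!r}; use 'raw' or 'edf'")


def _write_edf(record: EEGRecord, path: Path) -> None:
    """Minimal continuous 16-bit EDF writer (one data record per second)."""
    fs = record.sample_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate")
    spr = int(round(fs))
    n_ch = len(record.channels)
    n_rec = int(np.ceil(record.n_samples / spr))
    data = np.zeros((n_ch, n_rec * spr), dtype=float)
    data[:, : record.n_samples] = record.data
    pmin = float(np.floor(min(data.min(), -1.0)))
    pmax = float(np.ceil(max(data.max(), 1.0)))
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    dig = np.round((data - pmin) * scale + dmin).clip(dmin, dmax).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")
        if len(b) > n:
            raise ValueError(f"EDF field too long: {s!r}")
        return b.ljust(n)

    hdr = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate X X X X", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + n_ch)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),
            pad(str(n_ch), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(pad(c, 16) for c in record.channels),
            b"".join(pad("AgAgCl electrode", 80) for _ in range(n_ch)),
            b"".join(pad("uV", 8) for _ in range(n_ch)),
            b"".join(pad(f"{pmin:g}", 8) for _ in range(n_ch)),
            b"".join(pad(f"{pmax:g}", 8) for _ in range(n_ch)),
            b"".join(pad(str(dmin), 8) for _ in range(n_ch)),
            b"".join(pad(str(dmax), 8) for _ in range(n_ch)),
            b"".join(pad("", 80) for _ in range(n_ch)),
            b"".join(pad(str(spr), 8) for _ in range(n_ch)),
            b"".join(pad("", 32) for _ in range(n_ch)),
        ]
    )
    payload = b"".join(
        dig[:, r * spr : (r + 1) * spr].tobytes(order="C") for r in range(n_rec)
    )
    path.write_bytes(hdr + sig + payload)


def _read_edf(path: Path) -> EEGRecord:
    """Read an EDF file through mne, returning data in microvolts."""
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # structured error for malformed headers
        raise ValueError(f"could not parse EDF file {path}: {exc}") from exc
    data = raw.get_data() * 1e6  # Volts -> microvolts
    return EEGRecord(
        sample_rate=float(raw.info["sfreq"]),
        channels=list(raw.ch_names),
        data=data,
    )


# ---------------------------------------------------------------------------
# event tables


@dataclass
class EventTable:
    """Per-trial timestamps, condition fields and true/response labels.

    One row per trial.  ``t_tms_pulse2`` is NaN on sham rows; a missing
    button press is kept as the ``MISSING`` response label so behavioral
    filters downstream decide what to exclude.
    """

    table: pd.DataFrame
    inventory: tuple[str, ...] = tuple(phoneme_pair_inventory())

    def __post_init__(self) -> None:
        t = self.table
        for c in EVENT_COLUMNS:
            if c not in t.columns:
                raise EventValidationError(f"event table missing column {c!r}")
        if len(t) == 0:
            return
        stim = t["t_stim_onset"].to_numpy(dtype=float)
        if np.any(~np.isfinite(stim)):
            raise EventValidationError("t_stim_onset must be finite on every row")
        if np.any(np.diff(stim) <= 0):
            raise EventValidationError("t_stim_onset must be strictly increasing")
        tms = t["tms"].astype(bool).to_numpy()
        p2 = t["t_tms_pulse2"].to_numpy(dtype=float)
        bad = tms & ~(p2 < stim)
        if bad.any():
            i = int(np.nonzero(bad)[0][0])
            raise EventValidationError(
                f"row {i}: TMS trial needs t_tms_pulse2 < t_stim_onset "
                f"(got {p2[i]} >= {stim[i]})"
            )
        inv = set(self.inventory)
        unknown = set(t["true_label"]) - inv
        if unknown:
            raise EventValidationError(f"unknown phoneme labels: {sorted(unknown)}")
        bad_resp = set(t["response_label"].dropna()) - inv - {MISSING}
        if bad_resp:
            raise EventValidationError(f"unknown response labels: {sorted(bad_resp)}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_tms(self) -> int:
        return int(self.table["tms"].astype(bool).sum())


def write_event_table(events: EventTable, path: str | Path) -> None:
    """Write the documented event CSV (lossless round trip)."""
    t = events.table
    out = pd.DataFrame(
        {
            "trial_index": t["trial_index"].astype(int),
            "t_tms_pulse2": [
                "" if not np.isfinite(v) else f"{v:.6f}"
                for v in t["t_tms_pulse2"].astype(float)
            ],
            "t_stim_onset": [f"{v:.6f}" for v in t["t_stim_onset"].astype(float)],
            "t_phoneme_onsets": [
                ";".join(f"{p:.6f}" for p in ons) for ons in t["t_phoneme_onsets"]
            ],
            "site": t["site"],
            "tms": t["tms"].astype(bool).astype(int),
            "order": t["order"],
            "true_label": t["true_label"],
            "response_label": t["response_label"].fillna(MISSING),
            "rt": [
                "" if (v is None or not np.isfinite(v)) else f"{v:.6f}"
                for v in t["rt"].astype(float)
            ],
        }
    )
    out.to_csv(path, index=False)


def read_event_table(
    path: str | Path, inventory: Sequence[str] | None = None
) -> EventTable:
    """Read an event CSV, validating timestamps and phoneme labels."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for c in EVENT_COLUMNS:
        if c not in raw.columns:
            raise EventValidationError(f"event CSV missing column {c!r}")

    def parse_time(v: str, row: int, col: str) -> float:
        if v == "":
            return np.nan
        try:
            return float(v)
        except ValueError as exc:
            raise EventValidationError(
                f"row {row}: malformed timestamp {v!r} in column {col!r}"
            ) from exc

    rows = []
    for i, r in raw.iterrows():
        onsets = [
            parse_time(p, i, "t_phoneme_onsets")
            for p in r["t_phoneme_onsets"].split(";")
            if p != ""
        ]
        rows.append(
            {
                "trial_index": int(r["trial_index"]),
                "t_tms_pulse2": parse_time(r["t_tms_pulse2"], i, "t_tms_pulse2"),
                "t_stim_onset": parse_time(r["t_stim_onset"], i, "t_stim_onset"),
                "t_phoneme_onsets": onsets,
                "site": r["site"],
                "tms": bool(int(r["tms"])),
                "order": r["order"],
                "true_label": r["true_label"],
                "response_label": r["response_label"] if r["response_label"] else MISSING,
                "rt": parse_time(r["rt"], i, "rt"),
            }
        )
    table = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    if inventory is not None:
        return EventTable(table, tuple(inventory))
    return EventTable(table)


# ---------------------------------------------------------------------------
# epochs


@dataclass
class Epoch:
    """One trial's data cut relative to an anchor event, window [t0, t1)."""

    trial_index: int
    condition: dict
    data: np.ndarray  # (n_channels, n_samples)
    window: tuple[float, float]
    sample_rate: float
    channels: list[str]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def extract_epochs(
    record: EEGRecord,
    events: EventTable,
    anchor: str = "stim_onset",
    window: tuple[float, float] = (0.0, 0.5),
) -> tuple[list[Epoch], int]:
    """Cut one epoch per event row around the requested anchor.

    ``anchor`` is ``"stim_onset"`` or ``"tms_pulse2"``; sham rows have no
    TMS pulse and are skipped (counted) under the latter.  Trials whose
    window would run outside the recording are skipped and counted too.
    Returns ``(epochs, n_skipped)``.
    """
    t0, t1 = window
    if not t0 < t1:
        raise ValueError("window must satisfy t0 < t1")
    col = {"stim_onset": "t_stim_onset", "tms_pulse2": "t_tms_pulse2"}.get(anchor)
    if col is None:
        raise ValueError("anchor must be 'stim_onset' or 'tms_pulse2'")
    n = int(round((t1 - t0) * record.sample_rate))
    epochs: list[Epoch] = []
    skipped = 0
    cond_cols = ["site", "tms", "order", "true_label", "response_label", "rt"]
    for _, row in events.table.iterrows():
        t_anchor = float(row[col])
        if not np.isfinite(t_anchor):
            skipped += 1
            continue
        i0 = int(round((t_anchor + t0 - record.start_time) * record.sample_rate))
        if i0 < 0 or i0 + n > record.n_samples:
            skipped += 1
            continue
        epochs.append(
            Epoch(
                trial_index=int(row["trial_index"]),
                condition={c: row[c] for c in cond_cols}
                | {"t_stim_onset": float(row["t_stim_onset"])},
                data=np.asarray(record.data[:, i0 : i0 + n], dtype=float),
                window=(t0, t1),
                sample_rate=record.sample_rate,
                channels=list(record.channels),
            )
        )
    if skipped:
        logger.info("extract_epochs: skipped %d trials", skipped)
    return epochs, skipped
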