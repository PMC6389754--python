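"""File I/O: EDF and delimited EEG matrices, covariate tables, maps.

EDF reading goes through :func:`mne.io.read_raw_edf`; writing uses a
minimal EDF implementation (16-bit samples, per-channel physical
min/max, 1-second data records) sufficient for the 19-channel resting
segments this package produces.  All other artifacts are plain
tab-separated text with headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import normalize_label, standard_1020_layout
from .scalpmap import ScalpMap
from .segment import EEGSegment
from .synthcohort import COHORT_COLUMNS

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _pad(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r}")
    return s.ljust(width).encode("ascii")


def write_edf(seg: EEGSegment, path: str | Path) -> None:
    """Write a segment as 16-bit EDF with 1-second data records.

    Requires an integer sampling rate and an integer number of seconds.
    Quantization error is bounded by the per-channel physical range over
    2^16 levels.
    """
    fs = int(round(seg.fs))
    if abs(fs - seg.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records, rem = divmod(seg.n_samples, fs)
    if rem:
        raise ValueError("EDF writer requires a whole number of seconds")
    n_sig = seg.n_channels
    phys_min = seg.data.min(axis=1)
    phys_max = seg.data.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)

    hdr = b"".join([
        _pad("0", 8), _pad("X X X X", 80), _pad("Startdate 01-JAN-2000", 80),
        _pad("01.01.00", 8), _pad("00.00.00", 8),
        _pad(str(256 * (1 + n_sig)), 8), _pad("", 44),
        _pad(str(n_records), 8), _pad("1", 8), _pad(str(n_sig), 4),
    ])
    fields = [
        [f"EEG {lbl}" for lbl in seg.channel_labels],            # label
        [""] * n_sig,                                             # transducer
        ["uV"] * n_sig,                                           # dimension
        [f"{v:.8g}"[:8] for v in phys_min],
        [f"{v:.8g}"[:8] for v in phys_max],
        [str(_EDF_DIG_MIN)] * n_sig,
        [str(_EDF_DIG_MAX)] * n_sig,
        [""] * n_sig,                                             # prefilter
        [str(fs)] * n_sig,                                        # smp/record
        [""] * n_sig,                                             # reserved
    ]
    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    sig_hdr = b"".join(
        b"".join(_pad(v, w) for v in col) for col, w in zip(fields, widths))

    pmin = np.array([float(f"{v:.8g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.8g}"[:8]) for v in phys_max])
    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (pmax - pmin)
    dig = np.round((seg.data - pmin[:, None]) * scale[:, None]
                   + _EDF_DIG_MIN)
    dig = np.clip(dig, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(hdr + sig_hdr)
        for r in range(n_records):
            fh.write(dig[:, r * fs:(r + 1) * fs].tobytes())


def read_edf(path: str | Path, normalize_labels: bool = True) -> EEGSegment:
    """Read an EDF/EDF+ file into an :class:`EEGSegment` (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6
    labels = [normalize_label(ch) if normalize_labels else ch
              for ch in raw.ch_names]
    return EEGSegment(data=data_uv, fs=float(raw.info["sfreq"]),
                      channel_labels=labels, layout=standard_1020_layout()
                      if normalize_labels else None)


def write_matrix(seg: EEGSegment, path: str | Path) -> None:
    """Tab-delimited samples x channels matrix with a channel header.

    The sampling rate is recorded on a leading ``# fs=...`` comment line.
    """
    with open(path, "w") as fh:
        fh.write(f"# fs={seg.fs:g}\n")
        fh.write("\t".join(seg.channel_labels) + "\n")
        np.savetxt(fh, seg.data.T, fmt="%.10g", delimiter="\t")


def read_matrix(path: str | Path, fs: float | None = None) -> EEGSegment:
    """Read a delimited channels-in-columns matrix written by write_matrix."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("# fs="):
            fs = float(first.split("=", 1)[1])
            header = fh.readline()
        else:
            header = first
        labels = [normalize_label(lbl) for lbl in header.strip().split("\t")]
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if fs is None:
        raise ValueError(f"{path.name}: no sampling rate in file; pass fs=")
    return EEGSegment(data=data.T, fs=fs, channel_labels=labels,
                      layout=standard_1020_layout())


def read_eeg(path: str | Path) -> EEGSegment:
    """Dispatch on extension: .edf via mne, anything else as delimited."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        try:
            return read_edf(path)
        except Exception as err:
            raise ValueError(f"malformed EDF file {path.name}: {err}") from err
    return read_matrix(path)


def write_covariates(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read and schema-validate a per-subject covariate table."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"covariate table is missing required column(s): "
                         f"{missing}")
    if table["subject_id"].duplicated().any():
        dup = table.loc[table["subject_id"].duplicated(), "subject_id"]
        raise ValueError(f"duplicate subject ids: {sorted(dup)}")
    for col, allowed in [("group", {"HS", "patient"}),
                         ("syndrome", {"FE", "IGE", "none"}),
                         ("seizure_control", {"GSC", "PSC", "none"}),
                         ("gender", {"F", "M"})]:
        bad = set(table[col].astype(str)) - allowed
        if bad:
            raise ValueError(f"invalid values in column {col!r}: {sorted(bad)}")
    return table


def write_spectra(spectra, subject_ids, path: str | Path) -> None:
    """Long-format spectra: one row per subject x channel, columns = Hz."""
    rows = []
    for sid, ps in zip(subject_ids, spectra):
        for i, lbl in enumerate(ps.channel_labels):
            rows.append({"subject_id": sid, "channel": lbl,
                         **{f"{f}Hz": ps.power[i, j]
                            for j, f in enumerate(ps.freqs)}})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.10g")


def write_shifts(profiles, subject_ids, path: str | Path) -> None:
    """Per-subject shift table: per-channel and global log2 shifts."""
    rows = []
    for sid, pr in zip(subject_ids, profiles):
        row = {"subject_id": sid}
        row.update({lbl: v for lbl, v in
                    zip(pr.channel_labels, pr.per_channel_log2_shift)})
        row["global"] = pr.global_log2_shift
        row["mean_channel"] = pr.mean_channel_log2_shift
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.10g")


def read_shifts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_map(m: ScalpMap, stem: str | Path) -> None:
    """Serialize a map as <stem>.grid.tsv, <stem>.mask.tsv, <stem>.json."""
    stem = Path(stem)
    np.savetxt(f"{stem}.grid.tsv", m.grid, fmt="%.10g", delimiter="\t")
    np.savetxt(f"{stem}.mask.tsv", m.mask.astype(int), fmt="%d",
               delimiter="\t")
    meta = {"x0": float(m.x[0]), "y0": float(m.y[0]),
            "spacing": m.spacing, "n": len(m.x),
            "smoothing_sigma_mm": m.smoothing_sigma}
    Path(f"{stem}.json").write_text(json.dumps(meta, indent=1))


def read_map(stem: str | Path) -> ScalpMap:
    stem = Path(stem)
    meta = json.loads(Path(f"{stem}.json").read_text())
    grid = np.loadtxt(f"{stem}.grid.tsv", delimiter="\t")
    mask = np.loadtxt(f"{stem}.mask.tsv", delimiter="\t").astype(bool)
    ax = meta["x0"] + meta["spacing"] * np.arange(meta["n"])
    ay = meta["y0"] + meta["spacing"] * np.arange(meta["n"])
    return ScalpMap(grid=grid, x=ax, y=ay, mask=mask,
                    smoothing_sigma=meta["smoothing_sigma_mm"])
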