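"""Readers and writers for the pipeline's plain-text formats.

Bulk precursor-ion scans travel either as long-form CSV peak tables
(columns mz, intensity, channel) or as MGF, with one "spectrum" per
diagnostic product channel per sample (pyteomics handles the MGF format
itself). MRM results, copepod metadata, transition lists and presence tables
are CSV; ground truth and summaries are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "read_peak_table",
    "write_peak_table",
    "read_mgf_scan",
    "write_mgf_scan",
    "write_json",
    "read_json",
]

PEAK_COLUMNS = ["mz", "intensity", "channel"]


def read_peak_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak table {path} missing columns: {sorted(missing)}")
    return df[PEAK_COLUMNS]


def write_peak_table(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks[PEAK_COLUMNS].to_csv(path, index=False)


def write_mgf_scan(peaks: pd.DataFrame, path: str | Path, sample_id: str) -> None:
    """Write one bulk scan as MGF, one pseudo-spectrum per product channel.

    The precursor-ion scan has no single precursor; each channel's peaks are
    stored as an MS2-style peak list whose PEPMASS field carries the
    diagnostic product channel m/z.
    """
    from pyteomics import mgf

    spectra = []
    for channel, sub in peaks.groupby("channel"):
        spectra.append(
            {
                "m/z array": sub["mz"].to_numpy(),
                "intensity array": sub["intensity"].to_numpy(),
                "params": {
                    "title": f"{sample_id} channel {channel:.1f}",
                    "pepmass": float(channel),
                },
            }
        )
    mgf.write(spectra, str(path), file_mode="w")


def read_mgf_scan(path: str | Path) -> pd.DataFrame:
    """Read an MGF written by :func:`write_mgf_scan` back to a peak table."""
    from pyteomics import mgf

    rows = []
    with mgf.MGF(str(path)) as reader:
        for spectrum in reader:
            channel = float(spectrum["params"]["pepmass"][0])
            for mz, intensity in zip(
                spectrum["m/z array"], spectrum["intensity array"]
            ):
                rows.append(
                    {"mz": float(mz), "intensity": float(intensity), "channel": channel}
                )
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def write_json(obj: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
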