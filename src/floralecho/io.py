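"""File I/O: flower CSV tables, HDF5 scan containers, float WAV audio.

The HDF5 layout is one group per flower, one subgroup per scan plane:

    /<flower_id>/                attrs: species_id, syndrome, family, surface_area
        azimuth/irs              (n_angles, n_samples) float64
        azimuth/angles           (n_angles,) degrees
        azimuth/...              attrs: sample_rate
        elevation/...

WAV files are written as 32-bit float at the acoustic sample rate (500 kHz by
default). Recordings at other sample rates are refused, not silently
resampled.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .sonar import ImpulseResponseScan
from .synthdata import FlowerSpecimen

FlowerScans = Dict[str, Dict[str, ImpulseResponseScan]]


def write_flowers_csv(flowers_frame: pd.DataFrame, path) -> None:
    flowers_frame.to_csv(path, index=False)


def read_flowers_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_scans_h5(
    path,
    scans_by_flower: FlowerScans,
    flowers: Optional[Sequence[FlowerSpecimen]] = None,
) -> None:
    meta = {f.flower_id: f for f in flowers} if flowers else {}
    with h5py.File(path, "w") as h5:
        for flower_id, planes in scans_by_flower.items():
            grp = h5.create_group(flower_id)
            if flower_id in meta:
                f = meta[flower_id]
                grp.attrs["species_id"] = f.species_id
                grp.attrs["syndrome"] = f.syndrome
                grp.attrs["family"] = f.family
                grp.attrs["surface_area"] = f.surface_area
            for plane, scan in planes.items():
                sub = grp.create_group(plane)
                sub.create_dataset("irs", data=scan.irs)
                sub.create_dataset("angles", data=scan.angles)
                sub.attrs["sample_rate"] = scan.sample_rate


def read_scans_h5(path) -> Tuple[FlowerScans, pd.DataFrame]:
    """Load the scan container; returns (scans, per-flower metadata table)."""
    scans: FlowerScans = {}
    rows = []
    with h5py.File(path, "r") as h5:
        for flower_id in h5:
            grp = h5[flower_id]
            row = {"flower_id": flower_id}
            for key in ("species_id", "syndrome", "family", "surface_area"):
                if key in grp.attrs:
                    row[key] = grp.attrs[key]
            rows.append(row)
            scans[flower_id] = {}
            for plane in grp:
                sub = grp[plane]
                scans[flower_id][plane] = ImpulseResponseScan(
                    flower_id=flower_id,
                    plane=plane,
                    angles=sub["angles"][()],
                    irs=sub["irs"][()],
                    sample_rate=float(sub.attrs["sample_rate"]),
                )
    return scans, pd.DataFrame(rows)


def write_wav(path, waveform: np.ndarray, sample_rate: float) -> None:
    wavfile.write(path, int(round(sample_rate)), np.asarray(waveform, dtype=np.float32))


def read_wav(path, expected_rate: Optional[float] = None) -> Tuple[np.ndarray, float]:
    rate, data = wavfile.read(path)
    if expected_rate is not None and int(round(expected_rate)) != rate:
        raise ValueError(
            f"{path}: sample rate {rate} Hz differs from expected "
            f"{expected_rate} Hz; resample explicitly before processing"
        )
    return np.asarray(data, dtype=float), float(rate)
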