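"""File formats: FSL 3-column event files, NIfTI-1 volumes, provenance TSVs."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from fceq.core import EventSchedule, VolumeSeries


def write_events(schedule: EventSchedule, path: str | Path) -> None:
    """Write an FSL 3-column event file (onset, duration, amplitude; seconds)."""
    with open(path, "w") as fh:
        for onset, dur, amp in zip(schedule.onsets, schedule.durations, schedule.amplitudes):
            fh.write(f"{onset:.6f}\t{dur:.6f}\t{amp:.6f}\n")


def read_events(
    path: str | Path, scan_duration: float, condition_name: str | None = None
) -> EventSchedule:
    """Parse an FSL 3-column event file; errors name the offending line."""
    path = Path(path)
    onsets, durations, amplitudes = [], [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 whitespace-separated fields")
        try:
            onset, dur, amp = (float(f) for f in fields)
        except ValueError as err:
            raise ValueError(f"{path}:{lineno}: non-numeric field") from err
        if dur <= 0:
            raise ValueError(f"{path}:{lineno}: duration must be positive (got {dur})")
        if onset < 0:
            raise ValueError(f"{path}:{lineno}: onset must be non-negative (got {onset})")
        onsets.append(onset)
        durations.append(dur)
        amplitudes.append(amp)
    return EventSchedule(
        condition_name=condition_name or path.stem,
        onsets=np.asarray(onsets),
        durations=np.asarray(durations),
        amplitudes=np.asarray(amplitudes),
        scan_duration=scan_duration,
    )


def save_series(series: VolumeSeries, path: str | Path) -> None:
    """Write a VolumeSeries as 4D NIfTI-1 (affine from the voxel size, TR in the header)."""
    affine = np.diag(list(series.voxel_size) + [1.0])
    img = nib.Nifti1Image(series.data.astype(np.float32), affine)
    img.header.set_zooms(series.voxel_size + (series.tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_series(path: str | Path, tr: float | None = None) -> VolumeSeries:
    """Load a 4D NIfTI-1 file; TR comes from the header unless overridden."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got {data.ndim}D")
    zooms = img.header.get_zooms()
    voxel_size = tuple(float(z) for z in zooms[:3])
    if tr is None:
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return VolumeSeries(data=data, voxel_size=voxel_size, tr=tr)


def save_map(volume: np.ndarray, voxel_size, path: str | Path) -> None:
    """Write a 3D map (or k x-stacked 4D maps) as NIfTI-1."""
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def write_table(df: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    """TSV with '#'-prefixed provenance header lines (config hash, seeds, version)."""
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
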