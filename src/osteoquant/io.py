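"""Delimited-text and raster readers/writers for all signal types.

Every tabular file is plain CSV with an optional header metadata block of
``# key: value`` lines (animal, group, site, pixel size, ...).  Topography
rasters are accepted either as grayscale TIFF (via :mod:`tifffile`) or as
a plain-text matrix written by :func:`write_topography`.  Ground-truth
sidecars for synthetic data are YAML.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .afm import ForceCurve
from .exceptions import ParameterError
from .fibril import TopographyImage
from .hplc import Chromatogram
from .raman import RamanSpectrum
from .rpi import IndentationTrace


def _read_meta_and_table(path: str | Path) -> tuple[dict, pd.DataFrame]:
    path = Path(path)
    meta: dict[str, str] = {}
    lines = path.read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body_start = i + 1
            if ":" in line:
                key, _, value = line.lstrip("#").partition(":")
                meta[key.strip()] = value.strip()
        else:
            break
    df = pd.read_csv(_io.StringIO("\n".join(lines[body_start:])))
    return meta, df


def _write_meta_and_table(path: str | Path, meta: dict, df: pd.DataFrame):
    path = Path(path)
    with path.open("w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


# -- RPI traces -------------------------------------------------------------


def write_indentation_trace(trace: IndentationTrace, path: str | Path):
    _write_meta_and_table(
        path,
        {"animal": trace.animal_id, "group": trace.group_label,
         "site": trace.site_id},
        pd.DataFrame({
            "time_s": trace.time,
            "force_N": trace.force,
            "displacement_um": trace.displacement,
        }),
    )


def read_indentation_trace(path: str | Path) -> IndentationTrace:
    meta, df = _read_meta_and_table(path)
    for col in ("time_s", "force_N", "displacement_um"):
        if col not in df.columns:
            raise ParameterError(f"{path}: missing column {col!r}")
    return IndentationTrace(
        time=df["time_s"].to_numpy(),
        force=df["force_N"].to_numpy(),
        displacement=df["displacement_um"].to_numpy(),
        site_id=meta.get("site", ""),
        animal_id=meta.get("animal", ""),
        group_label=meta.get("group", ""),
    )


# -- AFM force curves -------------------------------------------------------


def write_force_curve(curve: ForceCurve, path: str | Path):
    _write_meta_and_table(
        path,
        {"animal": curve.animal_id, "group": curve.group_label,
         "grid_row": curve.grid_position[0],
         "grid_col": curve.grid_position[1]},
        pd.DataFrame({
            "separation_m": curve.separation,
            "force_N": curve.force,
            "segment": curve.segment,
        }),
    )


def read_force_curve(path: str | Path) -> ForceCurve:
    meta, df = _read_meta_and_table(path)
    return ForceCurve(
        separation=df["separation_m"].to_numpy(),
        force=df["force_N"].to_numpy(),
        segment=df["segment"].to_numpy(),
        grid_position=(int(meta.get("grid_row", 0)),
                       int(meta.get("grid_col", 0))),
        animal_id=meta.get("animal", ""),
        group_label=meta.get("group", ""),
    )


# -- Raman spectra ----------------------------------------------------------


def write_spectrum(spectrum: RamanSpectrum, path: str | Path):
    _write_meta_and_table(
        path,
        {"animal": spectrum.animal_id, "group": spectrum.group_label,
         "site": spectrum.site_id},
        pd.DataFrame({
            "wavenumber_cm1": spectrum.wavenumber,
            "intensity": spectrum.intensity,
        }),
    )


def read_spectrum(path: str | Path) -> RamanSpectrum:
    meta, df = _read_meta_and_table(path)
    return RamanSpectrum(
        wavenumber=df["wavenumber_cm1"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        site_id=meta.get("site", ""),
        animal_id=meta.get("animal", ""),
        group_label=meta.get("group", ""),
    )


# -- Topography images ------------------------------------------------------


def write_topography(image: TopographyImage, path: str | Path):
    """Write a raster: ``.tif``/``.tiff`` via tifffile, else text matrix."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.height.astype(np.float32))
        meta_path = path.with_suffix(path.suffix + ".meta.yaml")
        meta_path.write_text(yaml.safe_dump({
            "pixel_size_nm": float(image.pixel_size),
            "field": image.field_id,
            "animal": image.animal_id,
            "group": image.group_label,
        }))
    else:
        header = (
            f"pixel_size_nm: {image.pixel_size}\n"
            f"field: {image.field_id}\n"
            f"animal: {image.animal_id}\n"
            f"group: {image.group_label}"
        )
        np.savetxt(path, image.height, header=header)


def read_topography(
    path: str | Path, pixel_size_nm: float | None = None
) -> TopographyImage:
    path = Path(path)
    meta: dict = {}
    if path.suffix.lower() in (".tif", ".tiff"):
        height = np.asarray(tifffile.imread(path), dtype=float)
        meta_path = path.with_suffix(path.suffix + ".meta.yaml")
        if meta_path.exists():
            meta = yaml.safe_load(meta_path.read_text()) or {}
    else:
        height = np.loadtxt(path)
        for line in path.read_text().splitlines():
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, value = line.lstrip("#").partition(":")
                meta[key.strip()] = value.strip()
    px = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
    if px is None:
        raise ParameterError(
            f"{path}: pixel size neither in metadata nor given explicitly"
        )
    return TopographyImage(
        height=height,
        pixel_size=float(px),
        field_id=str(meta.get("field", "")),
        animal_id=str(meta.get("animal", "")),
        group_label=str(meta.get("group", "")),
    )


# -- Chromatograms ----------------------------------------------------------


def write_chromatogram(chrom: Chromatogram, path: str | Path):
    _write_meta_and_table(
        path,
        {"animal": chrom.animal_id, "group": chrom.group_label,
         "channel": chrom.channel},
        pd.DataFrame({
            "rt_min": chrom.retention_time,
            "signal": chrom.signal,
        }),
    )


def read_chromatogram(path: str | Path) -> Chromatogram:
    meta, df = _read_meta_and_table(path)
    return Chromatogram(
        retention_time=df["rt_min"].to_numpy(),
        signal=df["signal"].to_numpy(),
        channel=meta.get("channel", "fluorescence"),
        animal_id=meta.get("animal", ""),
        group_label=meta.get("group", ""),
    )


# -- Ground-truth sidecars --------------------------------------------------


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialisation."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_truth_sidecar(truth, path: str | Path):
    """Write a ground-truth sidecar (key-value YAML) next to a signal file."""
    if hasattr(truth, "__dataclass_fields__"):
        import dataclasses

        truth = dataclasses.asdict(truth)
    Path(path).write_text(yaml.safe_dump(_plain(truth), sort_keys=True))


def read_truth_sidecar(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
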