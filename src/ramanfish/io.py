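"""Plain-text readers/writers for spectra and maps.

Spectrum files are two-column tab-separated text with a
``# wavenumber_cm1\tintensity_counts`` header and metadata as leading
``# key=value`` comments. Map files are long-format TSV with columns
``x_um  y_um  wavenumber_cm1  intensity_counts`` (one block per pixel)
and the raster pixel area in a ``# pixel_area_um2=`` header.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import RamanMap, Spectrum

__all__ = ["read_spectrum", "write_spectrum", "read_map", "write_map"]

_HEADER = "# wavenumber_cm1\tintensity_counts"


def _parse_meta_value(raw: str):
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    return raw


def read_spectrum(path: str | Path) -> Spectrum:
    meta: dict = {}
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = _parse_meta_value(val.strip())
                continue
            w, s = line.split("\t")
            rows.append((float(w), float(s)))
    arr = np.array(rows)
    return Spectrum(arr[:, 0], arr[:, 1], meta)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, val in spectrum.meta.items():
            fh.write(f"# {key}={val}\n")
        fh.write(_HEADER + "\n")
        for w, s in zip(spectrum.wavenumbers, spectrum.intensities):
            fh.write(f"{w:.6g}\t{s:.10g}\n")


def read_map(path: str | Path) -> RamanMap:
    meta: dict = {}
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith("#") and "=" in line:
            key, _, val = line.lstrip("#").strip().partition("=")
            meta[key.strip()] = _parse_meta_value(val.strip())
    df = pd.read_csv(
        _io.StringIO(text), sep="\t", comment="#",
        names=["x_um", "y_um", "wavenumber_cm1", "intensity_counts"],
    )
    pixel_area = float(meta.pop("pixel_area_um2"))
    map_id = str(meta.pop("map_id", ""))
    grouped = df.groupby(["x_um", "y_um"], sort=True)
    coords, rows = [], []
    wavenumbers = None
    for (x, y), block in grouped:
        block = block.sort_values("wavenumber_cm1")
        w = block["wavenumber_cm1"].to_numpy()
        if wavenumbers is None:
            wavenumbers = w
        elif not np.array_equal(w, wavenumbers):
            raise ValueError("all pixels must share one wavenumber grid")
        coords.append((x, y))
        rows.append(block["intensity_counts"].to_numpy())
    return RamanMap(
        wavenumbers, np.vstack(rows), np.array(coords), pixel_area, map_id, meta
    )


def write_map(rmap: RamanMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pixel_area_um2={rmap.pixel_area:.10g}\n")
        if rmap.map_id:
            fh.write(f"# map_id={rmap.map_id}\n")
        fh.write("# x_um\ty_um\twavenumber_cm1\tintensity_counts\n")
        for i in range(rmap.n_pixels):
            x, y = rmap.coords[i]
            for w, s in zip(rmap.wavenumbers, rmap.intensities[i]):
                fh.write(f"{x:.6g}\t{y:.6g}\t{w:.6g}\t{s:.10g}\n")
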