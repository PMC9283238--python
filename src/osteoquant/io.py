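"""File formats shared by all pipeline stages.

* Spectra: two-column delimited text (wavenumber cm^-1, intensity),
  ``#`` comment lines; repeated accumulations of one measurement are
  stored as blocks separated by blank lines.
* Indent curves: delimited text with a header naming ``time_s``,
  ``load_uN``, ``disp_nm``.
* BSE images: 8-bit grayscale BMP/TIFF/PNG with a same-shape mask image
  (nonzero = in ROI).
* Manifest: one CSV row per measurement (path, kind, sample, group,
  region, lacunar distance, calibration reference).

All CSV output is UTF-8 with a header row and period decimal separators.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .indentation import IndentCurve
from .qbei import BSEImage
from .spectra import RamanSpectrum, SpectrumState

__all__ = [
    "read_spectrum_file",
    "write_spectrum_file",
    "read_indent_file",
    "write_indent_file",
    "read_bse_image",
    "write_bse_image",
    "Manifest",
    "read_manifest",
]

KINDS = ("spectrum", "indent", "image")
GROUPS = ("CTRL", "CKD", "CKD_KP")


def read_spectrum_file(path: str | Path, meta: dict | None = None,
                       ) -> list[RamanSpectrum]:
    """Read one or more accumulation blocks from a two-column text file."""
    blocks: list[list[tuple[float, float]]] = [[]]
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                continue
            if not line:
                if blocks[-1]:
                    blocks.append([])
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed spectrum line {line!r}")
            blocks[-1].append((float(parts[0]), float(parts[1])))
    if not blocks[-1]:
        blocks.pop()
    if not blocks:
        raise ValueError(f"{path}: no spectral data found")
    out = []
    for b in blocks:
        arr = np.asarray(b, dtype=float)
        out.append(RamanSpectrum(wavenumber=arr[:, 0], intensity=arr[:, 1],
                                 state=SpectrumState.RAW,
                                 meta=dict(meta or {})))
    return out


def write_spectrum_file(path: str | Path,
                        spectra: list[RamanSpectrum] | RamanSpectrum) -> None:
    if isinstance(spectra, RamanSpectrum):
        spectra = [spectra]
    with open(path, "w") as fh:
        fh.write("# wavenumber_cm-1\tintensity\n")
        for i, s in enumerate(spectra):
            if i:
                fh.write("\n")
            for w, y in zip(s.wavenumber, s.intensity):
                fh.write(f"{w:.2f}\t{y:.6f}\n")


def read_indent_file(path: str | Path, meta: dict | None = None) -> IndentCurve:
    """Read a time/load/displacement record with named columns."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"time_s", "load_uN", "disp_nm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return IndentCurve(time_s=df["time_s"].to_numpy(float),
                       load_uN=df["load_uN"].to_numpy(float),
                       disp_nm=df["disp_nm"].to_numpy(float),
                       meta=dict(meta or {}))


def write_indent_file(path: str | Path, c: IndentCurve) -> None:
    with open(path, "w") as fh:
        fh.write("time_s\tload_uN\tdisp_nm\n")
        for t, p, h in zip(c.time_s, c.load_uN, c.disp_nm):
            fh.write(f"{t:.4f}\t{p:.6f}\t{h:.6f}\n")


def _mask_path(image_path: Path) -> Path:
    return image_path.with_name(image_path.stem + "_mask" + image_path.suffix)


def read_bse_image(path: str | Path, mask_path: str | Path | None = None,
                   meta: dict | None = None) -> BSEImage:
    """Read an 8-bit grayscale image plus its ROI mask.

    The mask defaults to ``<stem>_mask<suffix>`` next to the image; if no
    mask file exists the whole frame is taken as ROI.
    """
    path = Path(path)
    img = Image.open(path)
    if img.mode != "L":
        img = img.convert("L")
    pixels = np.asarray(img, dtype=np.uint8)
    mp = Path(mask_path) if mask_path is not None else _mask_path(path)
    if mp.exists():
        mask = np.asarray(Image.open(mp).convert("L")) > 0
    else:
        mask = np.ones_like(pixels, dtype=bool)
    return BSEImage(pixels=pixels, roi_mask=mask, meta=dict(meta or {}))


def write_bse_image(path: str | Path, img: BSEImage) -> None:
    path = Path(path)
    Image.fromarray(img.pixels, mode="L").save(path)
    Image.fromarray((img.roi_mask * np.uint8(255)), mode="L").save(
        _mask_path(path))


@dataclass(frozen=True)
class Manifest:
    """Validated study manifest; paths resolved relative to its location."""

    records: pd.DataFrame
    root: Path

    def __len__(self) -> int:
        return len(self.records)


def read_manifest(path: str | Path) -> Manifest:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"path", "kind", "sample", "group", "region"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    if "distance_um" not in df.columns:
        df["distance_um"] = np.nan
    bad_kind = set(df["kind"]) - set(KINDS)
    if bad_kind:
        raise ValueError(f"manifest has unknown kinds {sorted(bad_kind)}")
    bad_group = set(df["group"]) - set(GROUPS)
    if bad_group:
        raise ValueError(f"manifest has unknown groups {sorted(bad_group)}")
    peri = df["region"] == "perilacunar"
    if df.loc[peri, "distance_um"].isna().any():
        raise ValueError("perilacunar manifest rows must carry distance_um")
    if (~peri & df["distance_um"].notna() & (df["kind"] != "image")).any():
        raise ValueError("distance_um is only valid for perilacunar rows")
    return Manifest(records=df, root=path.parent)
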