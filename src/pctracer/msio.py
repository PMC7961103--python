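"""imzML (+ibd) reading/writing and the in-memory MSI dataset model.

Backed by pyimzml; this layer adds the dataset container, strict invariant
checking (sorted centroid m/z arrays, unique in-grid pixel coordinates),
0-based image-convention coordinates, and explicit format validation
(imzML/ibd UUID agreement, centroid-mode requirement).

Pixel coordinates are 0-based with x = column increasing rightward and
y = row increasing downward; the 1-based imzML source coordinates are
shifted on read and restored on write.  Files are written in processed
mode with 64-bit m/z and 32-bit intensities.
"""

from __future__ import annotations

import uuid as _uuid
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "MSIDataset",
    "ImzMLFormatError",
    "read_imzml",
    "write_imzml",
    "read_peaklist",
    "write_peaklist",
]


class ImzMLFormatError(ValueError):
    """Malformed or unsupported imzML/ibd input."""


@dataclass
class Spectrum:
    """One pixel's centroid spectrum: sorted m/z, intensities, coordinates."""

    mz: np.ndarray
    intensities: np.ndarray
    pixel_xy: tuple[int, int]

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.mz.shape != self.intensities.shape or self.mz.ndim != 1:
            raise ValueError("m/z and intensity arrays must be equal-length 1-D")
        if len(self.mz) > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError(
                f"m/z array not strictly increasing at pixel {self.pixel_xy}"
            )
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        self.pixel_xy = (int(self.pixel_xy[0]), int(self.pixel_xy[1]))

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def tic(self) -> float:
        """Total ion current: sum of all centroid intensities."""
        return float(self.intensities.sum())


@dataclass
class MSIDataset:
    """Pixel-indexed collection of centroid spectra on a rectangular grid.

    ``grid_shape`` is (n_columns, n_rows).  Spectrum order is acquisition
    order and is preserved through write/read round trips.
    """

    spectra: list[Spectrum]
    grid_shape: tuple[int, int]
    pixel_size_um: float = 40.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ncols, nrows = self.grid_shape
        seen: set[tuple[int, int]] = set()
        for s in self.spectra:
            x, y = s.pixel_xy
            if not (0 <= x < ncols and 0 <= y < nrows):
                raise ValueError(f"pixel {s.pixel_xy} outside grid {self.grid_shape}")
            if s.pixel_xy in seen:
                raise ValueError(f"duplicate pixel coordinate {s.pixel_xy}")
            seen.add(s.pixel_xy)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    @property
    def base_peak_intensity(self) -> float:
        """Largest single centroid intensity anywhere in the dataset."""
        return max((float(s.intensities.max()) for s in self.spectra if len(s)), default=0.0)

    def pixel_index(self) -> dict[tuple[int, int], int]:
        return {s.pixel_xy: i for i, s in enumerate(self.spectra)}


# ---------------------------------------------------------------------------
# imzML reading
# ---------------------------------------------------------------------------

_CV = "{http://psi.hupo.org/ms/mzml}cvParam"
_ACC_UUID = "IMS:1000080"
_ACC_PROFILE = "MS:1000128"
_ACC_CONTINUOUS = "IMS:1000030"


def _scan_header(imzml_path: Path) -> tuple[str | None, bool, bool]:
    """Return (uuid string, is_profile, is_continuous) from the imzML XML."""
    file_uuid: str | None = None
    profile = False
    continuous = False
    try:
        for _event, elem in ET.iterparse(str(imzml_path), events=("end",)):
            tag = elem.tag.rsplit("}", 1)[-1]
            if tag == "cvParam":
                acc = elem.get("accession", "")
                if acc == _ACC_UUID:
                    file_uuid = elem.get("value", "")
                elif acc == _ACC_PROFILE:
                    profile = True
                elif acc == _ACC_CONTINUOUS:
                    continuous = True
            elif tag == "fileDescription":
                # all needed flags live in the header; stop before spectra
                break
    except ET.ParseError as exc:
        raise ImzMLFormatError(f"malformed imzML XML in {imzml_path}: {exc}") from exc
    return file_uuid, profile, continuous


def _normalize_uuid(text: str) -> str:
    return text.strip().strip("{}").replace("-", "").lower()


def read_imzml(path: str | Path) -> MSIDataset:
    """Read an imzML(+ibd) file into an :class:`MSIDataset`.

    Both continuous and processed binary modes are accepted; spectra must be
    centroided.  Raises :class:`ImzMLFormatError` on a missing ibd companion,
    an imzML/ibd UUID mismatch, profile-mode data, or malformed XML.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ibd_path = path.with_suffix(".ibd")
    if not ibd_path.exists():
        raise ImzMLFormatError(f"missing ibd companion for {path}")

    file_uuid, profile, continuous = _scan_header(path)
    if profile:
        raise ImzMLFormatError(
            "profile-mode spectra are not supported; centroid the data first"
        )
    if file_uuid:
        with open(ibd_path, "rb") as fh:
            ibd_uuid = _uuid.UUID(bytes=fh.read(16))
        if _normalize_uuid(file_uuid) != _normalize_uuid(str(ibd_uuid)):
            raise ImzMLFormatError(
                f"UUID mismatch: imzML declares {file_uuid} but ibd holds {ibd_uuid}"
            )

    if b"<spectrum " not in path.read_bytes():  # header-only (pixel-less) file
        return MSIDataset([], (0, 0), metadata={"source": str(path), "mode": "processed"})

    parser = ImzMLParser(str(path))
    spectra: list[Spectrum] = []
    max_x = max_y = 0
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        mz = np.asarray(mz, dtype=np.float64)
        inten = np.asarray(inten, dtype=np.float64)
        order = np.argsort(mz, kind="stable")
        if not np.array_equal(order, np.arange(len(mz))):
            mz, inten = mz[order], inten[order]
        spectra.append(Spectrum(mz, inten, (x - 1, y - 1)))
        max_x, max_y = max(max_x, x), max(max_y, y)

    meta = {
        "source": str(path),
        "mode": "continuous" if continuous else "processed",
        "traversal": [s.pixel_xy for s in spectra],
    }
    imzmldict = getattr(parser, "imzmldict", None) or {}
    ncols = int(imzmldict.get("max count of pixels x", max_x) or max_x)
    nrows = int(imzmldict.get("max count of pixels y", max_y) or max_y)
    px = imzmldict.get("pixel size x", None)
    return MSIDataset(
        spectra=spectra,
        grid_shape=(max(ncols, max_x), max(nrows, max_y)) if spectra else (0, 0),
        pixel_size_um=float(px) if px else 40.0,
        metadata=meta,
    )


def write_imzml(dataset: MSIDataset, path: str | Path) -> None:
    """Write a dataset as standard processed-mode imzML + ibd.

    Round trip through :func:`read_imzml` reproduces every m/z bit-exactly
    (stored as float64) and every intensity at float32 precision, in the
    same acquisition order.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = Path(path)
    for s in dataset.spectra:  # validate before touching the filesystem
        if len(s.mz) > 1 and not np.all(np.diff(s.mz) > 0):
            raise ValueError(f"unsorted m/z at pixel {s.pixel_xy}")
    if not dataset.spectra:
        _write_empty_imzml(path)
        return
    with ImzMLWriter(
        str(path),
        mz_dtype=np.float64,
        intensity_dtype=np.float32,
        mode="processed",
        spec_type="centroid",
    ) as writer:
        for s in dataset.spectra:
            x, y = s.pixel_xy
            writer.addSpectrum(s.mz, s.intensities, (x + 1, y + 1, 1))


_EMPTY_IMZML = """<?xml version="1.0" encoding="ISO-8859-1"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="http://psidev.info/ms/mzML/psi-ms.obo"/>
    <cv id="IMS" fullName="Imaging MS Ontology" URI="http://www.maldi-msi.org/download/imzml/imagingMS.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
      <cvParam cvRef="IMS" accession="IMS:1000031" name="processed" value=""/>
      <cvParam cvRef="IMS" accession="IMS:1000080" name="universally unique identifier" value="{uuid}"/>
    </fileContent>
  </fileDescription>
  <referenceableParamGroupList count="0"/>
  <softwareList count="1">
    <software id="pctracer" version="0"/>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1"/>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="export">
      <processingMethod order="1" softwareRef="pctracer"/>
    </dataProcessing>
  </dataProcessingList>
  <run defaultInstrumentConfigurationRef="IC1" id="run0">
    <spectrumList count="0" defaultDataProcessingRef="export"/>
  </run>
</mzML>
"""


def _write_empty_imzml(path: Path) -> None:
    """A pixel-less dataset is a header-only document plus a UUID-only ibd."""
    new_uuid = _uuid.uuid4()
    path.write_text(_EMPTY_IMZML.format(uuid="{" + str(new_uuid).upper() + "}"))
    path.with_suffix(".ibd").write_bytes(new_uuid.bytes)


# ---------------------------------------------------------------------------
# Centroid peak lists (MS/MS spectra) as TSV
# ---------------------------------------------------------------------------


def read_peaklist(path: str | Path) -> Spectrum:
    """Read a centroid peak list TSV with required header columns mz, intensity."""
    df = pd.read_csv(path, sep="\t")
    if not {"mz", "intensity"}.issubset(df.columns):
        raise ImzMLFormatError(f"{path}: peak list needs 'mz' and 'intensity' columns")
    order = np.argsort(df["mz"].to_numpy())
    return Spectrum(
        df["mz"].to_numpy()[order], df["intensity"].to_numpy()[order], (0, 0)
    )


def write_peaklist(spectrum: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"mz": spectrum.mz, "intensity": spectrum.intensities}).to_csv(
        path, sep="\t", index=False
    )
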