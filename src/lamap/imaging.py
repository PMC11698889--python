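"""Core data types and I/O for multi-element ablation images.

A laser-ablation run produces one 2-D intensity map per monitored isotope,
all sharing a single pixel grid (row = laser line, column = position along
the line, origin top-left).  This module holds those maps together with
acquisition metadata, boolean masks, histology-derived region annotations
and per-patient sample records, and reads/writes them as plain-text CSV
matrices plus YAML sidecar files (multi-page TIFF stacks are accepted on
read).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Region vocabulary used by annotations.  ``tumor_niche`` and ``stroma`` are
#: sub-compartments of the epithelial (lesion) area.
REGION_NAMES = ("background", "adipose", "epithelial", "tumor_niche", "stroma")

#: Default integer coding for region label maps.
DEFAULT_LEGEND = {
    0: "background",
    1: "adipose",
    2: "epithelial",
    3: "tumor_niche",
    4: "stroma",
}

_SPOT_SHAPES = ("square", "circle")
_INTENSITY_UNITS = ("counts", "cps")


@dataclass
class AcquisitionMeta:
    """Acquisition settings shared by every image of a run.

    ``dwell_ms`` is the effective integration time represented by one stored
    pixel (spectra are binned on acquisition; the image starts at pixel
    granularity).
    """

    pixel_size_um: float = 35.0
    spot_shape: str = "square"
    dwell_ms: float = 23.0
    isotopes: list[str] = field(default_factory=list)
    intensity_unit: str = "cps"

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.dwell_ms > 0:
            raise ValueError("dwell_ms must be positive")
        if self.spot_shape not in _SPOT_SHAPES:
            raise ValueError(f"spot_shape must be one of {_SPOT_SHAPES}")
        if self.intensity_unit not in _INTENSITY_UNITS:
            raise ValueError(f"intensity_unit must be one of {_INTENSITY_UNITS}")
        if len(set(self.isotopes)) != len(self.isotopes):
            raise ValueError("isotope labels must be unique")


@dataclass
class ElementImage:
    """A single isotope's 2-D intensity map."""

    isotope: str
    data: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"{self.isotope}: image data must be 2-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"{self.isotope}: image contains non-finite values")
        if np.any(self.data < 0):
            raise ValueError(f"{self.isotope}: intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class ImageStack:
    """All element images of one sample, congruent in shape and metadata."""

    images: dict[str, ElementImage]
    sample_id: str = ""
    nan_filled: int = 0  # cells zero-filled on read

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError("stack must contain at least one element image")
        shapes = {img.shape for img in self.images.values()}
        if len(shapes) != 1:
            raise ValueError(f"incongruent image shapes in stack: {sorted(shapes)}")
        metas = list(img.meta for img in self.images.values())
        if any(m != metas[0] for m in metas[1:]):
            raise ValueError("images in a stack must share acquisition metadata")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.images.values())).shape

    @property
    def isotopes(self) -> list[str]:
        return list(self.images)

    @property
    def meta(self) -> AcquisitionMeta:
        return next(iter(self.images.values())).meta

    def __getitem__(self, isotope: str) -> ElementImage:
        return self.images[isotope]


@dataclass
class Mask:
    """Boolean pixel mask; True means the pixel is retained."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def n_retained(self) -> int:
        return int(self.data.sum())


@dataclass
class RegionAnnotation:
    """Integer label map with a legend into the region vocabulary.

    Histology (H&E) annotations label each pixel with exactly one region;
    the epithelial lesion may be subdivided into tumor niche and stroma, so
    ``region_mask("epithelial")`` unions those sub-compartments by default.
    """

    labels: np.ndarray
    legend: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        unknown_names = set(self.legend.values()) - set(REGION_NAMES)
        if unknown_names:
            raise ValueError(f"legend contains unknown region names: {sorted(unknown_names)}")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels present without legend entry: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def codes_for(self, region: str) -> list[int]:
        return [c for c, name in self.legend.items() if name == region]

    def region_mask(self, region: str, include_subregions: bool = True) -> Mask:
        """Boolean mask of one region.

        For ``"epithelial"`` with ``include_subregions`` (default), pixels
        labelled ``tumor_niche`` or ``stroma`` are included as well.
        """
        if region not in REGION_NAMES:
            raise ValueError(f"unknown region {region!r}; expected one of {REGION_NAMES}")
        names = {region}
        if region == "epithelial" and include_subregions:
            names |= {"tumor_niche", "stroma"}
        codes = [c for c, name in self.legend.items() if name in names]
        return Mask(np.isin(self.labels, codes))

    def regions_present(self) -> list[str]:
        """Region names with at least one pixel (epithelial uses the
        tumor_niche/stroma union, so it is present whenever the lesion is)."""
        return [name for name in REGION_NAMES
                if self.region_mask(name).data.any()]


_GROUPS = ("H", "NM", "M")


@dataclass
class SampleRecord:
    """Per-patient metadata: group and receptor status.

    ``group`` is H (healthy), NM (non-metastatic) or M (metastatic);
    ER/PR/HER2 receptor status is 0/1 or None when not determined.
    """

    sample_id: str
    group: str
    er: Optional[int] = None
    pr: Optional[int] = None
    her2: Optional[int] = None

    def __post_init__(self) -> None:
        if self.group not in _GROUPS:
            raise ValueError(f"group must be one of {_GROUPS}, got {self.group!r}")
        for name in ("er", "pr", "her2"):
            v = getattr(self, name)
            if v is not None and v not in (0, 1):
                raise ValueError(f"{name} must be 0, 1 or None")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_matrix_csv(path: Path) -> tuple[np.ndarray, int]:
    """Read a rectangular numeric CSV. Returns (array, n_nan_filled)."""
    rows: list[list[float]] = []
    n_nan = 0
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh)):
            if not row:
                continue
            if rows and len(row) != len(rows[0]):
                raise ValueError(f"{path.name}: non-rectangular CSV at row {i}")
            vals = []
            for cell in row:
                cell = cell.strip()
                if cell == "" or cell.lower() == "nan":
                    vals.append(0.0)
                    n_nan += 1
                    continue
                x = float(cell)
                if np.isnan(x):
                    x = 0.0
                    n_nan += 1
                vals.append(x)
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path.name}: empty CSV")
    return np.asarray(rows, dtype=float), n_nan


def _meta_from_dict(d: dict) -> AcquisitionMeta:
    return AcquisitionMeta(
        pixel_size_um=float(d.get("pixel_size_um", 35.0)),
        spot_shape=str(d.get("spot_shape", "square")),
        dwell_ms=float(d.get("dwell_ms", 23.0)),
        isotopes=[str(s) for s in d["isotopes"]],
        intensity_unit=str(d.get("intensity_unit", "cps")),
    )


def read_stack(path: str | Path, meta_path: str | Path | None = None) -> ImageStack:
    """Read an image stack from a directory of per-isotope CSVs or a TIFF.

    ``path`` is either a directory containing ``<isotope>.csv`` for every
    isotope in the metadata file (default ``<path>/metadata.yaml``), or a
    multi-page TIFF whose pages follow the metadata isotope order.  NaN or
    empty cells are zero-filled and counted in ``stack.nan_filled`` with a
    logged warning.
    """
    path = Path(path)
    if meta_path is None:
        if path.is_dir():
            meta_path = path / "metadata.yaml"
        else:
            raise ValueError("meta_path is required when reading a TIFF stack")
    with open(meta_path) as fh:
        meta_dict = yaml.safe_load(fh)
    meta = _meta_from_dict(meta_dict)
    sample_id = str(meta_dict.get("sample_id", path.stem))

    images: dict[str, ElementImage] = {}
    n_nan = 0
    if path.is_dir():
        for iso in meta.isotopes:
            f = path / f"{iso}.csv"
            if not f.exists():
                raise FileNotFoundError(f"missing image file for isotope {iso}: {f}")
            arr, n = _read_matrix_csv(f)
            n_nan += n
            images[iso] = ElementImage(iso, arr, meta)
    else:
        import tifffile

        pages = np.asarray(tifffile.imread(path), dtype=float)
        if pages.ndim == 2:
            pages = pages[None]
        if pages.shape[0] != len(meta.isotopes):
            raise ValueError(
                f"TIFF has {pages.shape[0]} pages but metadata lists "
                f"{len(meta.isotopes)} isotopes")
        for iso, page in zip(meta.isotopes, pages):
            bad = ~np.isfinite(page)
            n_nan += int(bad.sum())
            page = np.where(bad, 0.0, page)
            images[iso] = ElementImage(iso, page, meta)

    if n_nan:
        logger.warning("read_stack(%s): zero-filled %d NaN/empty cells", path, n_nan)
    return ImageStack(images=images, sample_id=sample_id, nan_filled=n_nan)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write one CSV matrix per isotope plus ``metadata.yaml``.

    Values are written with 17 significant digits, which round-trips IEEE
    doubles exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = stack.meta
    for iso, img in stack.images.items():
        np.savetxt(path / f"{iso}.csv", img.data, fmt="%.17g", delimiter=",")
    meta_dict = {
        "sample_id": stack.sample_id,
        "pixel_size_um": meta.pixel_size_um,
        "spot_shape": meta.spot_shape,
        "dwell_ms": meta.dwell_ms,
        "intensity_unit": meta.intensity_unit,
        "isotopes": list(stack.isotopes),
    }
    with open(path / "metadata.yaml", "w") as fh:
        yaml.safe_dump(meta_dict, fh, sort_keys=False)


def read_annotation(path: str | Path, legend_path: str | Path | None = None) -> RegionAnnotation:
    """Read an integer label CSV plus a YAML legend mapping code -> region."""
    path = Path(path)
    if legend_path is None:
        legend_path = path.with_name(path.stem + "_legend.yaml")
    with open(legend_path) as fh:
        raw = yaml.safe_load(fh)
    legend = {int(k): str(v) for k, v in raw.items()}
    arr, _ = _read_matrix_csv(path)
    labels = arr.astype(int)
    if not np.array_equal(labels, arr):
        raise ValueError(f"{path.name}: annotation labels must be integers")
    return RegionAnnotation(labels=labels, legend=legend)


def write_annotation(annotation: RegionAnnotation, path: str | Path,
                     legend_path: str | Path | None = None) -> None:
    path = Path(path)
    if legend_path is None:
        legend_path = path.with_name(path.stem + "_legend.yaml")
    np.savetxt(path, annotation.labels, fmt="%d", delimiter=",")
    with open(legend_path, "w") as fh:
        yaml.safe_dump({int(k): v for k, v in annotation.legend.items()}, fh,
                       sort_keys=True)


def write_mask(mask: Mask, path: str | Path) -> None:
    np.savetxt(path, mask.data.astype(int), fmt="%d", delimiter=",")


def read_mask(path: str | Path) -> Mask:
    arr, _ = _read_matrix_csv(Path(path))
    return Mask(arr != 0)


def write_sample_records(records: list[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"sample_id": r.sample_id, "group": r.group,
          "er": r.er, "pr": r.pr, "her2": r.her2} for r in records])
    df.to_csv(path, index=False)


def read_sample_records(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        def _opt(v):
            return None if pd.isna(v) else int(v)
        out.append(SampleRecord(sample_id=str(row.sample_id), group=str(row.group),
                                er=_opt(row.er), pr=_opt(row.pr), her2=_opt(row.her2)))
    return out
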