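"""Readers, writers and report serialization.

Contours travel in a small JSON exchange format (schema shipped in
``contour_schema.json`` next to this module and validated on load);
images are accepted as NIfTI alongside DICOM. Analysis should start from
uncompressed or losslessly compressed source images, so the loader
records the compression state and warns on lossy transfer syntaxes.
Report serialization is deterministic (stable field order), and reports
carry the method tags a standardized report must mention: papillary mode,
area-length method, T2 cutoff provenance, peak-velocity mode, truncation
count, reader identity.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .geometry import ContourPolygon, ContourStack, SliceGeometry, StudyMeta

SCHEMA_PATH = Path(__file__).with_name("contour_schema.json")

# DICOM transfer syntaxes with lossy compression
_LOSSY_SYNTAXES = {
    "1.2.840.10008.1.2.4.50",  # JPEG baseline
    "1.2.840.10008.1.2.4.51",
    "1.2.840.10008.1.2.4.81",  # JPEG-LS near-lossless
    "1.2.840.10008.1.2.4.91",  # JPEG 2000 lossy
    "1.2.840.10008.1.2.4.93",
}


def _require(obj: dict, key: str, where: str):
    if key not in obj:
        raise ValidationError(f"missing field {key!r} in {where}")
    return obj[key]


def load_contours(path: str | Path) -> ContourStack:
    """Load and validate a contour-exchange JSON file into a ContourStack."""
    with open(path) as fh:
        doc = json.load(fh)
    slices = []
    for i, s in enumerate(_require(doc, "slices", "document")):
        where = f"slices[{i}]"
        slices.append(
            SliceGeometry(
                slice_index=int(_require(s, "index", where)),
                z_location=float(_require(s, "z_mm", where)),
                thickness=float(_require(s, "thickness_mm", where)),
                gap=float(s.get("gap_mm", 0.0)),
                pixel_spacing=tuple(s.get("pixel_spacing_mm", (1.0, 1.0))),
            )
        )
    contours: dict = {}
    n_phases = 1
    for i, c in enumerate(_require(doc, "contours", "document")):
        where = f"contours[{i}]"
        key = (
            int(_require(c, "slice", where)),
            int(_require(c, "phase", where)),
            str(_require(c, "role", where)),
        )
        pts = np.asarray(_require(c, "points_mm", where), dtype=float)
        contours.setdefault(key, []).append(ContourPolygon(pts, role=key[2]))
        n_phases = max(n_phases, key[1] + 1)
    meta_doc = doc.get("meta", {})
    meta = StudyMeta(
        heart_rate=meta_doc.get("heart_rate_bpm"),
        body_surface_area=meta_doc.get("bsa_m2"),
        acquisition_plane=meta_doc.get("acquisition_plane", "short_axis"),
    )
    return ContourStack(slices=slices, contours=contours, n_phases=n_phases, meta=meta)


def save_contours(stack: ContourStack, path: str | Path) -> None:
    """Write a ContourStack to the contour-exchange JSON format (lossless round trip)."""
    doc = {
        "slices": [
            {
                "index": s.slice_index,
                "z_mm": s.z_location,
                "thickness_mm": s.thickness,
                "gap_mm": s.gap,
                "pixel_spacing_mm": list(s.pixel_spacing),
            }
            for s in stack.slices
        ],
        "contours": [
            {
                "slice": key[0],
                "phase": key[1],
                "role": key[2],
                "points_mm": poly.vertices.tolist(),
            }
            for key, polys in sorted(stack.contours.items())
            for poly in polys
        ],
        "meta": {
            "heart_rate_bpm": stack.meta.heart_rate,
            "bsa_m2": stack.meta.body_surface_area,
            "acquisition_plane": stack.meta.acquisition_plane,
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


@dataclass
class StudyBundle:
    """Loaded image series plus contours and provenance."""

    images: dict[str, np.ndarray]
    spacing: dict[str, tuple]
    contours: ContourStack | None
    meta: StudyMeta
    provenance: dict = field(default_factory=dict)


def load_study(
    image_paths: dict[str, str | Path] | None = None,
    format: str = "nifti",
    contours_path: str | Path | None = None,
    reader_identity: str = "",
) -> StudyBundle:
    """Load image series (NIfTI or DICOM) and contours into a validated bundle."""
    images: dict[str, np.ndarray] = {}
    spacing: dict[str, tuple] = {}
    provenance: dict = {"reader_identity": reader_identity, "format": format}
    warnings_list: list[str] = []
    for name, p in (image_paths or {}).items():
        if format == "nifti":
            import nibabel as nib

            img = nib.load(str(p))
            images[name] = np.asarray(img.get_fdata())
            spacing[name] = tuple(float(z) for z in img.header.get_zooms())
            provenance[f"{name}_compression"] = (
                "gzip (lossless)" if str(p).endswith(".gz") else "uncompressed"
            )
        elif format == "dicom":
            import pydicom

            ds = pydicom.dcmread(str(p))
            images[name] = ds.pixel_array
            ps = getattr(ds, "PixelSpacing", [1.0, 1.0])
            spacing[name] = (float(ps[0]), float(ps[1]))
            syntax = str(ds.file_meta.TransferSyntaxUID)
            lossy = syntax in _LOSSY_SYNTAXES or getattr(ds, "LossyImageCompression", "00") == "01"
            provenance[f"{name}_compression"] = "LOSSY" if lossy else "lossless"
            if lossy:
                msg = f"series {name!r} uses lossy compression; analysis requires lossless sources"
                warnings_list.append(msg)
                warnings.warn(msg, stacklevel=2)
        else:
            raise ValidationError(f"unknown image format {format!r}")
    stack = load_contours(contours_path) if contours_path else None
    provenance["warnings"] = warnings_list
    meta = stack.meta if stack is not None else StudyMeta()
    return StudyBundle(images, spacing, stack, meta, provenance)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_report(results: dict, path: str | Path, format: str = "json") -> None:
    """Serialize a results mapping deterministically (byte-stable across runs)."""
    payload = _to_jsonable(results)
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, allow_nan=True)
            fh.write("\n")
    elif format == "csv":
        flat = _flatten(payload)
        with open(path, "w") as fh:
            fh.write("field,value\n")
            for k in sorted(flat):
                fh.write(f"{k},{flat[k]}\n")
    else:
        raise ValidationError(f"unknown report format {format!r}")


def _flatten(obj, prefix: str = "") -> dict:
    out: dict = {}
    if isinstance(obj, dict):
        for k, v in obj.items():
            out.update(_flatten(v, f"{prefix}{k}." if not prefix else f"{prefix}{k}."))
    elif isinstance(obj, list):
        out[prefix.rstrip(".")] = ";".join(str(v) for v in obj)
    else:
        out[prefix.rstrip(".")] = obj
    return out
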