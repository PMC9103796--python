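"""Container I/O: array archives, ENVI interchange, measurement archives.

The primary storage is a numpy ``.npz`` archive holding the cube values,
its wavelength grid (nm, always ascending) and free-form metadata.  For
interoperability an ENVI-style pair (text header + raw binary, BSQ
interleave, float32) can be read and written.  Whole measurements (six
radiance cubes, references, masks) round-trip through a single archive
with named datasets.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .scenes import GroundTruth, Measurement
from .stereo import LightGeometry

__all__ = [
    "write_cube",
    "read_cube",
    "write_cube_envi",
    "read_cube_envi",
    "write_measurement",
    "read_measurement",
    "write_manifest",
]


def write_cube(path, values: np.ndarray, wavelengths=None, **metadata) -> None:
    """Lossless cube archive: values + wavelengths + scalar metadata."""
    arrays = {"values": np.asarray(values)}
    if wavelengths is not None:
        arrays["wavelengths"] = np.asarray(wavelengths, dtype=float)
    if metadata:
        arrays["metadata_json"] = np.frombuffer(
            json.dumps(metadata, sort_keys=True).encode(), dtype=np.uint8
        )
    np.savez(path, **arrays)


def read_cube(path):
    """Read a cube archive -> (values, wavelengths or None, metadata dict)."""
    with np.load(path) as data:
        values = data["values"]
        wavelengths = data["wavelengths"] if "wavelengths" in data else None
        meta = {}
        if "metadata_json" in data:
            meta = json.loads(bytes(data["metadata_json"]).decode())
    return values, wavelengths, meta


def write_cube_envi(path, values: np.ndarray, wavelengths=None) -> None:
    """Write an ENVI-style header (.hdr) + raw float32 binary, BSQ interleave."""
    path = Path(path)
    v = np.asarray(values, dtype=np.float32)
    if v.ndim == 2:
        v = v[:, :, None]
    lines, samples, bands = v.shape
    hdr = [
        "ENVI",
        "description = {hsskin cube}",
        f"samples = {samples}",
        f"lines = {lines}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 4",
        "interleave = bsq",
        "byte order = 0",
    ]
    if wavelengths is not None:
        wl = np.asarray(wavelengths, dtype=float)
        if wl.size != bands:
            raise ValueError(f"{wl.size} wavelengths for {bands} bands")
        hdr.append("wavelength units = nm")
        hdr.append("wavelength = {" + ", ".join(f"{w:g}" for w in wl) + "}")
    path.with_suffix(".hdr").write_text("\n".join(hdr) + "\n")
    # BSQ: band-sequential layout
    np.ascontiguousarray(np.moveaxis(v, 2, 0)).tofile(path.with_suffix(".raw"))


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key, buf, in_braces = None, [], False
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.upper() == "ENVI":
            continue
        if not in_braces:
            if "=" not in line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip().lower(), val.strip()
            if val.startswith("{") and not val.endswith("}"):
                in_braces, buf = True, [val.lstrip("{")]
            else:
                fields[key] = val.strip("{}").strip()
        else:
            if line.endswith("}"):
                buf.append(line.rstrip("}"))
                fields[key] = " ".join(buf).strip()
                in_braces = False
            else:
                buf.append(line)
    return fields


def read_cube_envi(path):
    """Read an ENVI header + binary pair -> (values (H, W, bands), wavelengths)."""
    path = Path(path)
    fields = _parse_envi_header(path.with_suffix(".hdr").read_text())
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    if int(fields.get("data type", 4)) != 4:
        raise ValueError("only float32 (ENVI data type 4) is supported")
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise ValueError("only BSQ interleave is supported")
    raw = np.fromfile(path.with_suffix(".raw"), dtype=np.float32)
    expected = samples * lines * bands
    if raw.size != expected:
        raise ValueError(
            f"binary holds {raw.size} values, header promises {expected} "
            f"({lines}x{samples}x{bands}); refusing truncated/padded data"
        )
    values = np.moveaxis(raw.reshape(bands, lines, samples), 0, 2)
    wavelengths = None
    if "wavelength" in fields:
        wavelengths = np.array([float(w) for w in fields["wavelength"].split(",")])
        if wavelengths.size != bands:
            raise ValueError(
                f"header lists {wavelengths.size} wavelengths for {bands} bands"
            )
    return values, wavelengths


def write_measurement(path, meas: Measurement, gt: GroundTruth | None = None) -> None:
    """One archive per measurement, datasets named by role/direction/range."""
    arrays = {}
    for i in range(3):
        arrays[f"radiance_{i}_vis"] = meas.radiance_vis[i]
        arrays[f"radiance_{i}_vnir"] = meas.radiance_vnir[i]
    arrays["white_vis"] = meas.white_vis
    arrays["white_vnir"] = meas.white_vnir
    arrays["dark_vis"] = meas.dark_vis
    arrays["dark_vnir"] = meas.dark_vnir
    arrays["wavelengths"] = meas.wavelengths
    g = meas.light_geometry
    arrays["light_geometry"] = np.array(
        [g.elevation_deg, *g.azimuths_deg, g.distance_mm, g.ring_dimension_mm]
    )
    if gt is not None:
        arrays["height_map"] = gt.height_map
        arrays["class_mask"] = gt.class_mask
        arrays["healthy_mask"] = gt.healthy_mask
        arrays["albedo_true"] = gt.albedo_true
        arrays["lesion_class"] = np.frombuffer(gt.lesion_class.encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def read_measurement(path):
    """Inverse of :func:`write_measurement` -> (Measurement, GroundTruth | None)."""
    with np.load(path) as data:
        geom_arr = data["light_geometry"]
        geom = LightGeometry(
            elevation_deg=float(geom_arr[0]),
            azimuths_deg=tuple(float(a) for a in geom_arr[1:4]),
            distance_mm=float(geom_arr[4]),
            ring_dimension_mm=float(geom_arr[5]),
        )
        meas = Measurement(
            radiance_vis=[data[f"radiance_{i}_vis"] for i in range(3)],
            radiance_vnir=[data[f"radiance_{i}_vnir"] for i in range(3)],
            white_vis=data["white_vis"],
            white_vnir=data["white_vnir"],
            dark_vis=data["dark_vis"],
            dark_vnir=data["dark_vnir"],
            light_geometry=geom,
            wavelengths=data["wavelengths"],
        )
        gt = None
        if "height_map" in data:
            gt = GroundTruth(
                height_map=data["height_map"],
                class_mask=data["class_mask"],
                healthy_mask=data["healthy_mask"],
                albedo_true=data["albedo_true"],
                lesion_class=bytes(data["lesion_class"]).decode(),
            )
    return meas, gt


def write_manifest(path, config_text: str, seed: int, stage_counts) -> dict:
    """Run manifest: config hash, seed and stage counts, as JSON."""
    manifest = {
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": int(seed),
        "stage_counts": [[name, int(n)] for name, n in stage_counts],
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
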