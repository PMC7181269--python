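"""Hyperspectral cube and manifest I/O.

Single source of truth for axis conventions: in memory every cube is a
``lines x samples x bands`` array (axis 0 = scan lines, axis 1 = sensor
samples, axis 2 = spectral bands, 0-based).  On disk a cube is an
ENVI-style pair: a plain-text ``.hdr`` and a raw binary raster, BIL
interleave by default.  No other module parses files.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "Stage",
    "Label",
    "ExclusionReason",
    "HSCube",
    "Manifest",
    "read_cube",
    "write_cube",
    "load_manifest",
    "save_manifest",
]

#: Nominal acquisition geometry of the push-broom microscope.
NOMINAL_LINES = 800
NOMINAL_SAMPLES = 1004
NOMINAL_BANDS = 826
#: Spectral range of the camera, nm.
WAVELENGTH_MIN = 400.0
WAVELENGTH_MAX = 1000.0


def nominal_wavelengths(bands: int = NOMINAL_BANDS) -> np.ndarray:
    """Evenly spaced wavelength grid over the camera's 400-1000 nm range."""
    return np.linspace(WAVELENGTH_MIN, WAVELENGTH_MAX, bands)


class Stage(str, enum.Enum):
    """Processing stage of a cube."""

    RADIANCE = "radiance"
    TRANSMITTANCE = "transmittance"
    REDUCED = "reduced"


class Label(str, enum.Enum):
    """Per-ROI (weak) class label shared by every patch of a cube."""

    TUMOR = "tumor"
    NON_TUMOR = "non_tumor"
    UNKNOWN = "unknown"


class ExclusionReason(str, enum.Enum):
    """Why a cube is excluded from evaluation (never from disk)."""

    NONE = "none"
    INK = "ink"
    UNFOCUSED = "unfocused"
    ARTIFACT = "artifact"
    BLOOD = "blood"
    NECROSIS = "necrosis"


@dataclass
class HSCube:
    """A hyperspectral raster with its wavelength axis and provenance.

    Parameters
    ----------
    data : ndarray, shape (lines, samples, bands)
        Radiance counts (stage ``radiance``) or dimensionless
        transmittance in [0, 1] (stages ``transmittance`` / ``reduced``).
    wavelengths_nm : ndarray, shape (bands,)
        Strictly ascending band centres within [400, 1000] nm.
    """

    data: np.ndarray
    wavelengths_nm: np.ndarray
    stage: Stage = Stage.RADIANCE
    patient_id: str = ""
    roi_id: str = ""
    label: Label = Label.UNKNOWN

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.stage = Stage(self.stage)
        self.label = Label(self.label)
        self.validate()

    # -- geometry ----------------------------------------------------
    @property
    def lines(self) -> int:
        return self.data.shape[0]

    @property
    def samples(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]

    def validate(self) -> None:
        """Check the cube's invariants; raise ValidationError otherwise."""
        if self.data.ndim != 3:
            raise ValidationError(
                f"cube data must be 3-D lines x samples x bands, got ndim={self.data.ndim}"
            )
        wl = self.wavelengths_nm
        if wl.ndim != 1 or wl.size != self.data.shape[2]:
            raise ValidationError(
                f"wavelength count {wl.size} does not match band count {self.data.shape[2]}"
            )
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelengths must be strictly ascending")
        if wl.size and (wl[0] < WAVELENGTH_MIN - 1e-9 or wl[-1] > WAVELENGTH_MAX + 1e-9):
            raise ValidationError(
                f"wavelengths must lie within [{WAVELENGTH_MIN:g}, {WAVELENGTH_MAX:g}] nm, "
                f"got [{wl[0]:g}, {wl[-1]:g}]"
            )
        if self.stage is Stage.RADIANCE:
            if self.data.size and float(self.data.min()) < 0:
                raise ValidationError("radiance cube contains negative values")
        else:
            if self.data.size and (
                float(self.data.min()) < 0 or float(self.data.max()) > 1 + 1e-9
            ):
                raise ValidationError(
                    f"{self.stage.value} cube values must lie in [0, 1]; "
                    f"got range [{self.data.min():g}, {self.data.max():g}]"
                )

    def with_data(self, data: np.ndarray, *, stage: Stage | None = None,
                  wavelengths_nm: np.ndarray | None = None) -> "HSCube":
        """Copy of this cube with new data (and optionally stage/wavelengths)."""
        return replace(
            self,
            data=data,
            stage=self.stage if stage is None else stage,
            wavelengths_nm=self.wavelengths_nm if wavelengths_nm is None else wavelengths_nm,
        )


# ---------------------------------------------------------------------------
# ENVI-style header + raw raster
# ---------------------------------------------------------------------------

_DTYPE_CODES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_CODE_FOR_DTYPE = {np.dtype(v): k for k, v in _DTYPE_CODES.items()}

#: Raster axis order for each interleave, as (memory axis -> file axis) permutation
#: relative to the in-memory (lines, samples, bands) convention.
_INTERLEAVE_PERM = {
    "bil": (0, 2, 1),  # line, band, sample
    "bsq": (2, 0, 1),  # band, line, sample
    "bip": (0, 1, 2),  # line, sample, band
}


def _header_path(path: str) -> str:
    if path.endswith(".hdr"):
        return path
    return os.path.splitext(path)[0] + ".hdr" if path.endswith(".img") else path + ".hdr"


def _raster_path_for(header_path: str) -> str:
    base = header_path[: -len(".hdr")]
    for cand in (base + ".img", base, base + ".raw", base + ".dat"):
        if os.path.isfile(cand):
            return cand
    raise FormatError(f"no raster file found next to header {header_path!r}")


def _parse_header(text: str, path: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError(f"{path!r}: missing ENVI magic on first line")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    i = 0
    lines = body.splitlines()
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{"):
            while "}" not in value and i < len(lines):
                value += " " + lines[i].strip()
                i += 1
            if "}" not in value:
                raise FormatError(f"{path!r}: unterminated {{...}} value for field {key!r}")
            value = value[1 : value.index("}")].strip()
        fields[key] = value
    return fields


def _require(fields: dict, key: str, path: str) -> str:
    if key not in fields:
        raise FormatError(f"{path!r}: required header field {key!r} is missing")
    return fields[key]


def read_cube(path: str) -> HSCube:
    """Read an ENVI-style header/raster pair into an :class:`HSCube`.

    ``path`` may point to the header, the raster, or their common stem.
    Any interleave (bil/bsq/bip) is normalized to lines x samples x bands.
    """
    hdr = _header_path(path)
    if not os.path.isfile(hdr):
        raise FormatError(f"header file not found: {hdr!r}")
    with open(hdr, "r", encoding="utf-8") as fh:
        fields = _parse_header(fh.read(), hdr)

    try:
        lines = int(_require(fields, "lines", hdr))
        samples = int(_require(fields, "samples", hdr))
        bands = int(_require(fields, "bands", hdr))
        dtype_code = int(_require(fields, "data type", hdr))
    except ValueError as exc:
        raise FormatError(f"{hdr!r}: non-integer dimension field ({exc})") from exc
    if dtype_code not in _DTYPE_CODES:
        raise FormatError(f"{hdr!r}: unsupported 'data type' code {dtype_code}")
    interleave = fields.get("interleave", "bil").lower()
    if interleave not in _INTERLEAVE_PERM:
        raise FormatError(f"{hdr!r}: unknown interleave {interleave!r}")

    wl_text = _require(fields, "wavelength", hdr)
    try:
        wavelengths = np.array(
            [float(tok) for tok in wl_text.replace(",", " ").split()], dtype=float
        )
    except ValueError as exc:
        raise FormatError(f"{hdr!r}: malformed 'wavelength' list ({exc})") from exc
    if wavelengths.size != bands:
        raise FormatError(
            f"{hdr!r}: 'wavelength' lists {wavelengths.size} values but 'bands' = {bands}"
        )

    raster = _raster_path_for(hdr)
    offset = int(fields.get("header offset", 0))
    raw = np.fromfile(raster, dtype=_DTYPE_CODES[dtype_code], offset=offset)
    expected = lines * samples * bands
    if raw.size != expected:
        raise FormatError(
            f"{raster!r}: raster holds {raw.size} values but header "
            f"declares {lines}x{samples}x{bands} = {expected}"
        )
    perm = _INTERLEAVE_PERM[interleave]
    file_shape = tuple((lines, samples, bands)[ax] for ax in perm)
    data = raw.reshape(file_shape).transpose(np.argsort(perm))

    stage = Stage(fields.get("stage", Stage.RADIANCE.value))
    label = Label(fields.get("label", Label.UNKNOWN.value))
    return HSCube(
        data=data,
        wavelengths_nm=wavelengths,
        stage=stage,
        patient_id=fields.get("patient id", ""),
        roi_id=fields.get("roi id", ""),
        label=label,
    )


def write_cube(cube: HSCube, path: str, interleave: str = "bil") -> str:
    """Persist a cube as ``<stem>.hdr`` + ``<stem>.img``; returns the header path.

    The cube is validated first; ``read_cube`` inverts this exactly
    (bit-for-bit on data, wavelengths and metadata).
    """
    cube.validate()
    if interleave not in _INTERLEAVE_PERM:
        raise ValueError(f"unknown interleave {interleave!r}")
    hdr = _header_path(path)
    stem = hdr[: -len(".hdr")]
    dtype = np.dtype(cube.data.dtype)
    if dtype not in _CODE_FOR_DTYPE:
        dtype = np.dtype(np.float32)
    data = np.ascontiguousarray(cube.data.astype(dtype, copy=False))

    wl = " , ".join(repr(float(w)) for w in cube.wavelengths_nm)
    header = (
        "ENVI\n"
        "description = {hsipath hyperspectral cube}\n"
        f"samples = {cube.samples}\n"
        f"lines = {cube.lines}\n"
        f"bands = {cube.bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_CODE_FOR_DTYPE[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
        f"stage = {cube.stage.value}\n"
        f"patient id = {cube.patient_id}\n"
        f"roi id = {cube.roi_id}\n"
        f"label = {cube.label.value}\n"
    )
    with open(hdr, "w", encoding="utf-8") as fh:
        fh.write(header)
    data.transpose(_INTERLEAVE_PERM[interleave]).tofile(stem + ".img")
    return hdr


# ---------------------------------------------------------------------------
# Dataset manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "patient_id",
    "roi_id",
    "cube_path",
    "reference_path",
    "label",
    "excluded",
    "exclusion_reason",
]


@dataclass
class Manifest:
    """Validated table of cubes: one row per acquired HS image.

    Exclusion flags are metadata applied at evaluation time only;
    nothing is ever dropped at read time.
    """

    frame: pd.DataFrame
    root: str = "."

    def __post_init__(self) -> None:
        self.frame = self.frame.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.frame
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"manifest missing required columns: {missing}")
        bad_rows: list[str] = []
        valid_labels = {Label.TUMOR.value, Label.NON_TUMOR.value}
        valid_reasons = {r.value for r in ExclusionReason}
        for idx, row in df.iterrows():
            if row["label"] not in valid_labels:
                bad_rows.append(f"row {idx}: unknown label {row['label']!r}")
            if row["exclusion_reason"] not in valid_reasons:
                bad_rows.append(
                    f"row {idx}: unknown exclusion_reason {row['exclusion_reason']!r}"
                )
            elif bool(row["excluded"]) != (row["exclusion_reason"] != "none"):
                bad_rows.append(
                    f"row {idx}: excluded={row['excluded']} inconsistent with "
                    f"exclusion_reason={row['exclusion_reason']!r}"
                )
            if not str(row["cube_path"]) or not str(row["reference_path"]):
                bad_rows.append(f"row {idx}: empty cube_path or reference_path")
        if bad_rows:
            raise ValidationError("invalid manifest:\n" + "\n".join(bad_rows))

    def __len__(self) -> int:
        return len(self.frame)

    def resolve(self, rel_path: str) -> str:
        return rel_path if os.path.isabs(rel_path) else os.path.join(self.root, rel_path)

    def check_paths(self) -> None:
        """Raise if any cube or reference file is dangling."""
        bad = []
        for idx, row in self.frame.iterrows():
            for col in ("cube_path", "reference_path"):
                p = self.resolve(str(row[col]))
                if not (os.path.isfile(p) or os.path.isfile(_header_path(p))):
                    bad.append(f"row {idx}: dangling {col} {row[col]!r}")
        if bad:
            raise ValidationError("manifest references missing files:\n" + "\n".join(bad))

    # -- bookkeeping -------------------------------------------------
    def patients(self) -> list[str]:
        return sorted(self.frame["patient_id"].unique())

    def class_table(self) -> pd.DataFrame:
        """Per-patient cube counts per class (columns tumor / non_tumor)."""
        if not len(self.frame):
            return pd.DataFrame(columns=["tumor", "non_tumor"])
        tab = (
            self.frame.groupby(["patient_id", "label"]).size().unstack(fill_value=0)
        )
        for col in ("tumor", "non_tumor"):
            if col not in tab.columns:
                tab[col] = 0
        return tab[["tumor", "non_tumor"]]

    def patients_with_both(self) -> list[str]:
        tab = self.class_table()
        return sorted(tab.index[(tab["tumor"] > 0) & (tab["non_tumor"] > 0)])

    def tumor_only_patients(self) -> list[str]:
        tab = self.class_table()
        return sorted(tab.index[(tab["tumor"] > 0) & (tab["non_tumor"] == 0)])

    def rows_for(self, patients) -> pd.DataFrame:
        return self.frame[self.frame["patient_id"].isin(set(patients))]


def load_manifest(path: str, check_paths: bool = True) -> Manifest:
    """Load and validate a manifest CSV; paths resolve relative to its directory."""
    try:
        df = pd.read_csv(
            path,
            dtype={"patient_id": str, "roi_id": str, "cube_path": str,
                   "reference_path": str, "label": str, "exclusion_reason": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=MANIFEST_COLUMNS)
    if "excluded" in df.columns:
        df["excluded"] = df["excluded"].astype(bool) if len(df) else df["excluded"]
    man = Manifest(frame=df, root=os.path.dirname(os.path.abspath(path)))
    if check_paths:
        man.check_paths()
    return man


def save_manifest(manifest: Manifest, path: str) -> None:
    manifest.frame[MANIFEST_COLUMNS].to_csv(path, index=False)
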