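"""Reading and writing spectral datasets.

Two plain-text formats are supported:

* a wide CSV dialect — header row of wavenumbers, first column a spectrum id,
  one intensity row per spectrum — paired with a metadata CSV keyed by
  spectrum id (columns ``spectrum_id,set_id,level_id,added_water,
  deposit_index,scan_index,modality``);
* a minimal, read-only JCAMP-DX 4.24 subset (uncompressed AFFN
  ``##XYDATA=(X++(Y..Y))`` or ``##XYPOINTS=(XY..XY)``) for ingesting single
  reference spectra.

Wavenumbers are stored and processed in ascending order throughout; files in
descending (display) order are re-sorted on read with intensity columns
permuted consistently.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MODALITIES = ("ATR-IR", "NIR-B", "NIR-H", "Raman-B")

META_COLUMNS = (
    "spectrum_id",
    "set_id",
    "level_id",
    "added_water",
    "deposit_index",
    "scan_index",
    "modality",
)


class SpectraIOError(ValueError):
    """Raised for malformed spectra/metadata files."""


@dataclass(frozen=True)
class SpectrumMeta:
    """Sample-unit annotation for one recorded spectrum.

    ``added_water`` is the nominal standard-addition label in %w/w — the
    regression target y. ``deposit_index``/``scan_index`` identify the
    replicate within a sample (e.g. 3 deposits x 3 scans).
    """

    spectrum_id: str
    set_id: str
    level_id: str
    added_water: float
    deposit_index: int
    scan_index: int

    def __post_init__(self) -> None:
        if self.added_water < 0:
            raise SpectraIOError(
                f"added_water must be >= 0, got {self.added_water} for {self.spectrum_id}"
            )


@dataclass
class SpectralDataset:
    """Wavenumber axis + intensity matrix + per-spectrum metadata.

    Invariants (enforced on construction):

    * ``intensities`` is (n_spectra, n_channels) with
      ``n_channels == len(wavenumbers)``;
    * wavenumbers are finite and strictly increasing;
    * each (set_id, level_id, deposit_index, scan_index) triple occurs once,
      spectrum ids are unique, and all spectra of one (set, level) sample
      carry the same added-water label.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: list[SpectrumMeta]
    modality: str

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise SpectraIOError("intensities must be a 2-D matrix")
        if self.wavenumbers.ndim != 1:
            raise SpectraIOError("wavenumbers must be a 1-D vector")
        if self.intensities.shape[1] != self.wavenumbers.size:
            raise SpectraIOError(
                f"intensity rows have {self.intensities.shape[1]} channels, "
                f"axis has {self.wavenumbers.size}"
            )
        if self.intensities.shape[0] != len(self.meta):
            raise SpectraIOError(
                f"{self.intensities.shape[0]} spectra but {len(self.meta)} metadata entries"
            )
        if not np.all(np.isfinite(self.wavenumbers)):
            raise SpectraIOError("wavenumbers contain NaN/inf")
        if self.wavenumbers.size > 1 and not np.all(np.diff(self.wavenumbers) > 0):
            raise SpectraIOError("wavenumbers must be strictly increasing")
        if self.modality not in MODALITIES:
            raise SpectraIOError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        ids = [m.spectrum_id for m in self.meta]
        if len(set(ids)) != len(ids):
            raise SpectraIOError("duplicate spectrum ids")
        triples = [(m.set_id, m.level_id, m.deposit_index, m.scan_index) for m in self.meta]
        if len(set(triples)) != len(triples):
            raise SpectraIOError("duplicate (set, level, deposit, scan) replicate triples")
        labels: dict[tuple[str, str], float] = {}
        for m in self.meta:
            key = (m.set_id, m.level_id)
            if key in labels and labels[key] != m.added_water:
                raise SpectraIOError(
                    f"inconsistent added_water within sample {key}: "
                    f"{labels[key]} vs {m.added_water}"
                )
            labels.setdefault(key, m.added_water)

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.wavenumbers.size

    def meta_frame(self) -> pd.DataFrame:
        """Metadata as a DataFrame aligned with the intensity rows."""
        return pd.DataFrame(
            {
                "spectrum_id": [m.spectrum_id for m in self.meta],
                "set_id": [m.set_id for m in self.meta],
                "level_id": [m.level_id for m in self.meta],
                "added_water": [m.added_water for m in self.meta],
                "deposit_index": [m.deposit_index for m in self.meta],
                "scan_index": [m.scan_index for m in self.meta],
            }
        )

    def sample_keys(self) -> list[tuple[str, str]]:
        """Unique (set_id, level_id) sample units, sorted."""
        return sorted({(m.set_id, m.level_id) for m in self.meta})


def read_dataset(spectra_path: str | Path, meta_path: str | Path) -> SpectralDataset:
    """Read a wide-CSV spectral matrix and its metadata file.

    The spectra file header row holds the wavenumbers; the first column holds
    spectrum ids. Every spectrum id must be keyed in the metadata file. Files
    stored with a descending wavenumber axis are re-sorted ascending with the
    intensity columns permuted consistently.
    """
    spectra_path, meta_path = Path(spectra_path), Path(meta_path)
    with open(spectra_path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise SpectraIOError(f"{spectra_path}: empty file")
    header = rows[0]
    if len(header) < 2:
        raise SpectraIOError(f"{spectra_path}: header must contain at least one wavenumber")
    try:
        wavenumbers = np.array([float(w) for w in header[1:]], dtype=float)
    except ValueError as exc:
        raise SpectraIOError(f"{spectra_path}: non-numeric wavenumber in header: {exc}") from exc
    n_channels = wavenumbers.size

    ids: list[str] = []
    matrix = np.empty((len(rows) - 1, n_channels), dtype=float)
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != n_channels + 1:
            raise SpectraIOError(
                f"{spectra_path}: ragged row {r}: expected {n_channels + 1} fields, got {len(row)}"
            )
        ids.append(row[0])
        for c, cell in enumerate(row[1:]):
            try:
                matrix[r - 2, c] = float(cell)
            except ValueError as exc:
                raise SpectraIOError(
                    f"{spectra_path}: non-numeric cell at row {r}, column {c + 2}: {cell!r}"
                ) from exc

    order = np.argsort(wavenumbers, kind="stable")
    wavenumbers = wavenumbers[order]
    matrix = matrix[:, order]

    meta_df = pd.read_csv(meta_path, dtype={"spectrum_id": str})
    missing_cols = set(META_COLUMNS) - set(meta_df.columns)
    if missing_cols:
        raise SpectraIOError(f"{meta_path}: missing metadata columns {sorted(missing_cols)}")
    meta_df = meta_df.set_index("spectrum_id")
    meta: list[SpectrumMeta] = []
    modalities = set()
    for sid in ids:
        if sid not in meta_df.index:
            raise SpectraIOError(f"{meta_path}: no metadata for spectrum id {sid!r}")
        row = meta_df.loc[sid]
        modalities.add(str(row["modality"]))
        meta.append(
            SpectrumMeta(
                spectrum_id=sid,
                set_id=str(row["set_id"]),
                level_id=str(row["level_id"]),
                added_water=float(row["added_water"]),
                deposit_index=int(row["deposit_index"]),
                scan_index=int(row["scan_index"]),
            )
        )
    if len(modalities) > 1:
        raise SpectraIOError(f"{meta_path}: mixed modalities {sorted(modalities)}")
    modality = modalities.pop() if modalities else "ATR-IR"
    return SpectralDataset(wavenumbers=wavenumbers, intensities=matrix, meta=meta, modality=modality)


def write_dataset(ds: SpectralDataset, spectra_path: str | Path, meta_path: str | Path) -> None:
    """Write a dataset in the wide-CSV dialect accepted by :func:`read_dataset`.

    Values are written with ``repr`` precision, so a read/write round trip
    preserves them to float precision.
    """
    spectra_path, meta_path = Path(spectra_path), Path(meta_path)
    with open(spectra_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["spectrum_id"] + [repr(float(w)) for w in ds.wavenumbers])
        for m, row in zip(ds.meta, ds.intensities):
            writer.writerow([m.spectrum_id] + [repr(float(v)) for v in row])
    frame = ds.meta_frame()
    frame["modality"] = ds.modality
    frame.to_csv(meta_path, index=False)


# --- JCAMP-DX (minimal, read-only) -----------------------------------------

_AFFN_TOKEN = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")


def _jcamp_records(text: str) -> tuple[dict[str, str], list[str]]:
    """Split labelled-data records; return header fields and data-table lines."""
    fields: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for raw in text.splitlines():
        line = raw.split("$$")[0].rstrip()
        if not line.strip():
            continue
        if line.startswith("##"):
            label, _, value = line[2:].partition("=")
            label = label.replace(" ", "").replace("-", "").replace("_", "").upper()
            if label in ("XYDATA", "XYPOINTS"):
                in_data = True
                fields["DATAFORM"] = label
                fields[label] = value.strip()
            elif label == "END":
                in_data = False
            else:
                in_data = False
                fields[label] = value.strip()
        elif in_data:
            data_lines.append(line)
    return fields, data_lines


def read_jcamp_xy(path: str | Path, modality: str = "ATR-IR") -> SpectralDataset:
    """Read a single-spectrum JCAMP-DX file (uncompressed AFFN only).

    Supports ``##XYDATA=(X++(Y..Y))`` with FIRSTX/LASTX/NPOINTS/XFACTOR/YFACTOR
    and ``##XYPOINTS=(XY..XY)``. SQZ/DIF/DUP compressed tables raise an
    explicit "unsupported dialect" error rather than misparsing silently.
    """
    path = Path(path)
    fields, data_lines = _jcamp_records(path.read_text())
    if "DATAFORM" not in fields:
        raise SpectraIOError(f"{path}: no ##XYDATA or ##XYPOINTS record")
    for line in data_lines:
        if any(ch.isalpha() and ch not in "eE" for ch in line):
            raise SpectraIOError(
                f"{path}: unsupported dialect (SQZ/DIF/DUP-compressed data); only AFFN is supported"
            )

    xfactor = float(fields.get("XFACTOR", "1"))
    yfactor = float(fields.get("YFACTOR", "1"))
    title = fields.get("TITLE", path.stem) or path.stem

    if fields["DATAFORM"] == "XYDATA":
        try:
            firstx = float(fields["FIRSTX"])
            lastx = float(fields["LASTX"])
            npoints = int(float(fields["NPOINTS"]))
        except KeyError as exc:
            raise SpectraIOError(f"{path}: XYDATA requires FIRSTX/LASTX/NPOINTS ({exc})") from exc
        ys: list[float] = []
        for line in data_lines:
            tokens = _AFFN_TOKEN.findall(line)
            if not tokens:
                continue
            # first token on each line is the (redundant) X start value
            ys.extend(float(t) for t in tokens[1:])
        if len(ys) != npoints:
            raise SpectraIOError(f"{path}: expected {npoints} Y values, parsed {len(ys)}")
        # FIRSTX/LASTX are actual axis values; XFACTOR scales only table X tokens
        x = np.linspace(firstx, lastx, npoints)
        y = np.array(ys, dtype=float) * yfactor
    else:  # XYPOINTS
        pairs: list[float] = []
        for line in data_lines:
            pairs.extend(float(t) for t in _AFFN_TOKEN.findall(line))
        if len(pairs) % 2:
            raise SpectraIOError(f"{path}: odd number of values in XYPOINTS table")
        arr = np.array(pairs, dtype=float).reshape(-1, 2)
        x = arr[:, 0] * xfactor
        y = arr[:, 1] * yfactor

    order = np.argsort(x, kind="stable")
    meta = [
        SpectrumMeta(
            spectrum_id=title,
            set_id="JCAMP",
            level_id="NA",
            added_water=0.0,
            deposit_index=1,
            scan_index=1,
        )
    ]
    return SpectralDataset(
        wavenumbers=x[order], intensities=y[order][None, :], meta=meta, modality=modality
    )
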