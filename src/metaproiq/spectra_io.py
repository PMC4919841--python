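"""MS/MS spectrum I/O and peak-list preprocessing.

MGF is the reference dialect (mzML is accepted through the same ``Run``
contract when pyteomics can read it).  Retention times are normalised to
minutes on read.  Preprocessing mimics common search-engine peak
filtering: low-m/z removal, top-N selection, square-root intensity
compression and max-normalisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from pyteomics import mgf as _mgf


@dataclass
class Spectrum:
    """One centroided MS/MS scan.

    ``charge`` is ``None`` when the precursor charge is unknown (the
    search then tries a configured charge list).  ``rt`` is in minutes.
    ``precursor_intensity`` is the second PEPMASS field when present and
    is what quantification uses as the precursor signal.
    """

    scan_id: str
    precursor_mz: float
    charge: int | None
    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    precursor_intensity: float | None = None
    searchable: bool = True
    preprocessed: bool = False

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz/intensity length mismatch")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass
class Run:
    """All spectra of one sample, ordered by retention time."""

    sample_id: str
    spectra: list[Spectrum] = field(default_factory=list)
    source_path: str = ""
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.spectra = sorted(self.spectra, key=lambda s: (s.rt, s.scan_id))
        ids = [s.scan_id for s in self.spectra]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate scan ids in run {self.sample_id!r}")

    def __len__(self) -> int:
        return len(self.spectra)


def read_mgf(path: str | Path, sample_id: str | None = None) -> Run:
    """Read an MGF file into a :class:`Run`.

    Blocks without PEPMASS are skipped with a warning; malformed blocks
    are a hard error.  RTINSECONDS is converted to minutes; a missing
    CHARGE leaves the charge unknown.
    """
    path = Path(path)
    sample_id = sample_id or path.stem
    spectra: list[Spectrum] = []
    n_skipped = 0
    try:
        with _mgf.MGF(str(path)) as reader:
            for i, entry in enumerate(reader):
                params = entry["params"]
                if "pepmass" not in params or params["pepmass"] is None:
                    warnings.warn(f"{path.name}: block {i} has no PEPMASS, skipped", stacklevel=2)
                    n_skipped += 1
                    continue
                pepmass = params["pepmass"]
                prec_mz = float(pepmass[0])
                prec_int = None
                if len(pepmass) > 1 and pepmass[1] is not None:
                    prec_int = float(pepmass[1])
                charge = None
                if params.get("charge"):
                    charge = int(params["charge"][0])
                rt = float(params.get("rtinseconds", 0.0)) / 60.0
                scan_id = str(params.get("title", f"{sample_id}.{i}"))
                spectra.append(
                    Spectrum(
                        scan_id=scan_id,
                        precursor_mz=prec_mz,
                        charge=charge,
                        rt=rt,
                        mz=entry["m/z array"],
                        intensity=entry["intensity array"],
                        precursor_intensity=prec_int,
                    )
                )
    except Exception as exc:  # noqa: BLE001 - annotate parse failures with the path
        if isinstance(exc, (ValueError, KeyError)) and not isinstance(exc, FileNotFoundError):
            raise ValueError(f"malformed MGF {path}: {exc}") from exc
        raise
    return Run(sample_id=sample_id, spectra=spectra, source_path=str(path), n_skipped=n_skipped)


def write_mgf(run: Run, path: str | Path) -> None:
    """Write a :class:`Run` back to MGF (round-trips :func:`read_mgf`)."""
    entries = []
    for s in run.spectra:
        params: dict = {
            "title": s.scan_id,
            "rtinseconds": round(s.rt * 60.0, 6),
        }
        if s.precursor_intensity is not None:
            params["pepmass"] = (s.precursor_mz, s.precursor_intensity)
        else:
            params["pepmass"] = (s.precursor_mz,)
        if s.charge is not None:
            params["charge"] = s.charge
        entries.append({"params": params, "m/z array": s.mz, "intensity array": s.intensity})
    _mgf.write(entries, str(path), file_mode="w")


def read_mzml(path: str | Path, sample_id: str | None = None) -> Run:
    """Optional mzML reader behind the same Run contract."""
    from pyteomics import mzml as _mzml

    path = Path(path)
    sample_id = sample_id or path.stem
    spectra: list[Spectrum] = []
    n_skipped = 0
    with _mzml.MzML(str(path)) as reader:
        for i, entry in enumerate(reader):
            if entry.get("ms level") != 2:
                continue
            try:
                precursor = entry["precursorList"]["precursor"][0]
                ion = precursor["selectedIonList"]["selectedIon"][0]
                prec_mz = float(ion["selected ion m/z"])
            except (KeyError, IndexError):
                n_skipped += 1
                continue
            charge = ion.get("charge state")
            charge = int(charge) if charge is not None else None
            rt = 0.0
            scan = entry.get("scanList", {}).get("scan", [{}])[0]
            if "scan start time" in scan:
                rt = float(scan["scan start time"])  # pyteomics yields minutes
            spectra.append(
                Spectrum(
                    scan_id=str(entry.get("id", f"{sample_id}.{i}")),
                    precursor_mz=prec_mz,
                    charge=charge,
                    rt=rt,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    precursor_intensity=ion.get("peak intensity"),
                )
            )
    return Run(sample_id=sample_id, spectra=spectra, source_path=str(path), n_skipped=n_skipped)


def preprocess(spectrum: Spectrum, top_n: int = 50, min_mz: float = 150.0) -> Spectrum:
    """Filter and normalise a peak list for scoring.

    Peaks below ``min_mz`` are removed, at most ``top_n`` most intense
    peaks are retained, intensities are square-root transformed and
    scaled so the maximum is 1.  Duplicate m/z values are summed so the
    output grid is strictly increasing.  Re-running on an already
    preprocessed spectrum is a no-op (fixed point by flag).
    """
    if spectrum.preprocessed:
        return spectrum
    keep = spectrum.mz >= min_mz
    mz, intensity = spectrum.mz[keep], spectrum.intensity[keep]
    if mz.size:
        # merge exact duplicates so the grid is strictly increasing
        uniq, inverse = np.unique(mz, return_inverse=True)
        if uniq.size != mz.size:
            intensity = np.bincount(inverse, weights=intensity)
            mz = uniq
    if mz.size > top_n:
        order = np.argsort(intensity, kind="stable")[::-1][:top_n]
        order = np.sort(order)
        mz, intensity = mz[order], intensity[order]
    searchable = mz.size > 0
    if searchable:
        intensity = np.sqrt(intensity)
        peak_max = intensity.max()
        if peak_max > 0:
            intensity = intensity / peak_max
    out = replace(
        spectrum,
        mz=mz,
        intensity=intensity,
        searchable=searchable,
        preprocessed=True,
    )
    return out
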