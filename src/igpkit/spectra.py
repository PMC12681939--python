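"""Fragment-spectrum I/O and preprocessing.

Preprocessing follows the glycopeptide-search convention: remove
isobaric reporter ions, denoise (retain the most intense peaks per
100 Th window), deisotope (collapse isotope envelopes onto their
monoisotopic peak, summing intensity).  Preprocessed spectra are then
screened for the HexNAc oxonium ion before any database search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np
from pyteomics import mgf as _mgf
from pyteomics import mzml as _mzml

from .constants import (
    ISOTOPE_SPACING,
    OXONIUM_HEX,
    OXONIUM_HEX2,
    OXONIUM_HEXNAC,
    OXONIUM_HEXNAC_HEX_FUC,
    OXONIUM_NEUAC,
    OXONIUM_NEUAC_H2O,
    PROTON,
    TMT11_REPORTERS,
)

logger = logging.getLogger(__name__)


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass
class FragmentSpectrum:
    """A centroided MS/MS spectrum with its precursor.

    Peaks are stored as parallel numpy arrays sorted by ascending m/z.
    ``ms1_envelope`` optionally carries the experimental MS1 isotope
    profile of the precursor for isotope scoring.
    """

    scan_id: str
    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray
    ms1_envelope: np.ndarray | None = None  # shape (n, 2): mz, intensity

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    @property
    def precursor_neutral_mass(self) -> float:
        return (self.precursor_mz - PROTON) * self.precursor_charge

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class ReporterDesign:
    """Isobaric labeling design: named reporter channels and a tolerance."""

    channels: dict[str, float] = field(default_factory=lambda: dict(TMT11_REPORTERS))
    tolerance_da: float = 0.003

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)


@dataclass(frozen=True)
class PreprocessParams:
    denoise_window: float = 100.0      # Th
    denoise_top_n: int = 100           # peaks kept per window
    fragment_tol_ppm: float = 20.0
    oxonium_mz: float = OXONIUM_HEXNAC
    oxonium_top_n: int = 10


def read_spectra(path: str | Path) -> Iterator[FragmentSpectrum]:
    """Stream MS/MS spectra from an MGF or mzML file (by extension).

    Scans lacking a precursor are skipped; a missing precursor charge
    defaults to 2 with a warning.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".mgf":
        yield from _read_mgf(path)
    elif suffix == ".mzml":
        yield from _read_mzml(path)
    else:
        raise ValueError(f"unrecognized spectrum file extension {suffix!r} for {path}")


def _read_mgf(path: Path) -> Iterator[FragmentSpectrum]:
    with _mgf.MGF(str(path)) as reader:
        for i, scan in enumerate(reader):
            params = scan["params"]
            pepmass = params.get("pepmass")
            if pepmass is None:
                logger.warning("scan %d in %s lacks PEPMASS; skipped", i, path)
                continue
            charge_field = params.get("charge")
            if charge_field:
                charge = int(charge_field[0])
            else:
                logger.warning("scan %d in %s lacks CHARGE; defaulting to 2", i, path)
                charge = 2
            yield FragmentSpectrum(
                scan_id=str(params.get("title", f"scan={i}")),
                precursor_mz=float(pepmass[0]),
                precursor_charge=charge,
                mz=scan["m/z array"],
                intensity=scan["intensity array"],
            )


def _read_mzml(path: Path) -> Iterator[FragmentSpectrum]:
    with _mzml.MzML(str(path)) as reader:
        for scan in reader:
            if scan.get("ms level") != 2:
                continue
            try:
                precursor = scan["precursorList"]["precursor"][0]
                ion = precursor["selectedIonList"]["selectedIon"][0]
                pre_mz = float(ion["selected ion m/z"])
            except (KeyError, IndexError):
                logger.warning("MS2 scan %s lacks precursor; skipped", scan.get("id"))
                continue
            charge = ion.get("charge state")
            if charge is None:
                logger.warning("scan %s lacks precursor charge; defaulting to 2", scan.get("id"))
                charge = 2
            yield FragmentSpectrum(
                scan_id=str(scan.get("id", "")),
                precursor_mz=pre_mz,
                precursor_charge=int(charge),
                mz=scan["m/z array"],
                intensity=scan["intensity array"],
            )


def write_mgf(spectra: Iterable[FragmentSpectrum], path: str | Path) -> None:
    """Write spectra to an MGF file (round-trips through read_spectra)."""
    records = []
    for s in spectra:
        records.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": {
                    "title": s.scan_id,
                    "pepmass": s.precursor_mz,
                    "charge": s.precursor_charge,
                },
            }
        )
    _mgf.write(records, str(path), file_mode="w")


def remove_reporter_ions(
    s: FragmentSpectrum, design: ReporterDesign | None = None
) -> FragmentSpectrum:
    """Drop peaks within tolerance of any reporter channel."""
    design = design or ReporterDesign()
    keep = np.ones(len(s), dtype=bool)
    for mz in design.channels.values():
        keep &= np.abs(s.mz - mz) > design.tolerance_da
    return replace(s, mz=s.mz[keep], intensity=s.intensity[keep])


def _denoise(s: FragmentSpectrum, window: float, top_n: int) -> FragmentSpectrum:
    if len(s) == 0:
        return s
    bins = np.floor(s.mz / window).astype(int)
    keep = np.zeros(len(s), dtype=bool)
    for b in np.unique(bins):
        idx = np.nonzero(bins == b)[0]
        if len(idx) <= top_n:
            keep[idx] = True
        else:
            best = idx[np.argsort(s.intensity[idx])[-top_n:]]
            keep[best] = True
    return replace(s, mz=s.mz[keep], intensity=s.intensity[keep])


def _deisotope(s: FragmentSpectrum, tol_ppm: float) -> FragmentSpectrum:
    """Collapse isotope envelopes onto the monoisotopic peak.

    Envelopes are chains with spacing 1.00335/z (z up to the precursor
    charge) whose intensities decrease after the first or second
    isotope.  Intensities are summed onto the monoisotopic member.
    """
    n = len(s)
    if n == 0:
        return s
    mz, inten = s.mz, s.intensity
    consumed = np.zeros(n, dtype=bool)
    out_mz: list[float] = []
    out_int: list[float] = []
    max_z = max(1, s.precursor_charge)
    for i in range(n):
        if consumed[i]:
            continue
        best_chain: list[int] = [i]
        for z in range(1, max_z + 1):
            chain = [i]
            spacing = ISOTOPE_SPACING / z
            cur = i
            while True:
                target = mz[cur] + spacing
                tol = target * tol_ppm * 1e-6
                j = np.searchsorted(mz, target)
                cand = None
                for k in (j - 1, j):
                    if 0 <= k < n and not consumed[k] and abs(mz[k] - target) <= tol:
                        if cand is None or abs(mz[k] - target) < abs(mz[cand] - target):
                            cand = k
                if cand is None:
                    break
                # envelope must decrease after the first or second isotope
                pos = len(chain)
                if pos >= 2 and inten[cand] > inten[chain[-1]]:
                    break
                chain.append(cand)
                cur = cand
            if len(chain) > len(best_chain):
                best_chain = chain
        consumed[best_chain] = True
        out_mz.append(mz[i])
        out_int.append(float(inten[best_chain].sum()))
    return replace(s, mz=np.array(out_mz), intensity=np.array(out_int))


def preprocess(
    s: FragmentSpectrum,
    params: PreprocessParams | None = None,
    design: ReporterDesign | None = None,
) -> FragmentSpectrum:
    """Reporter removal, then denoising, then deisotoping."""
    params = params or PreprocessParams()
    s = remove_reporter_ions(s, design)
    s = _denoise(s, params.denoise_window, params.denoise_top_n)
    s = _deisotope(s, params.fragment_tol_ppm)
    return s


def _has_peak(s: FragmentSpectrum, mz: float, tol_ppm: float) -> bool:
    if len(s) == 0:
        return False
    tol = mz * tol_ppm * 1e-6
    j = np.searchsorted(s.mz, mz)
    for k in (j - 1, j):
        if 0 <= k < len(s) and abs(s.mz[k] - mz) <= tol:
            return True
    return False


def oxonium_screen(s: FragmentSpectrum, params: PreprocessParams | None = None) -> bool:
    """True iff a HexNAc-oxonium peak ranks among the top-10 most intense.

    Expects reporter ions to have been removed already.
    """
    params = params or PreprocessParams()
    if len(s) == 0:
        return False
    top = np.argsort(s.intensity)[-params.oxonium_top_n:]
    tol = params.oxonium_mz * params.fragment_tol_ppm * 1e-6
    return bool(np.any(np.abs(s.mz[top] - params.oxonium_mz) <= tol))


def diagnostic_ion_flags(
    s: FragmentSpectrum, tol_ppm: float = 20.0
) -> dict[str, bool]:
    """Glycan-type diagnostic flags from characteristic oxonium ions.

    sialylated: NeuAc oxonium at 274.092/292.103; fucosylated:
    HexNAc+Hex+Fuc at 512.197; high_mannose: Hex-series ions
    (163.060/325.113) without either terminal signature.
    """
    sialylated = _has_peak(s, OXONIUM_NEUAC, tol_ppm) or _has_peak(
        s, OXONIUM_NEUAC_H2O, tol_ppm
    )
    fucosylated = _has_peak(s, OXONIUM_HEXNAC_HEX_FUC, tol_ppm)
    hex_series = _has_peak(s, OXONIUM_HEX, tol_ppm) and _has_peak(s, OXONIUM_HEX2, tol_ppm)
    return {
        "sialylated": sialylated,
        "fucosylated": fucosylated,
        "high_mannose": hex_series and not sialylated and not fucosylated,
    }
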