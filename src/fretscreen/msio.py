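"""Peak-list I/O: MGF (one spectrum per BEGIN IONS block) and two-column TSV."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
from pyteomics import mgf as _mgf

from .fragments import Spectrum

__all__ = ["read_mgf", "write_mgf", "read_tsv", "write_tsv", "read_peaklist"]


def read_mgf(path) -> list[Spectrum]:
    """Read every spectrum block from an MGF file."""
    spectra = []
    with _mgf.read(str(path)) as reader:
        for entry in reader:
            params = entry.get("params", {})
            pepmass = params.get("pepmass", (None,))
            charge = params.get("charge")
            charge = int(charge[0]) if charge else 1
            spectra.append(
                Spectrum(
                    peaks_mz=np.asarray(entry["m/z array"], dtype=float),
                    peaks_intensity=np.asarray(entry["intensity array"], dtype=float),
                    precursor_mz=float(pepmass[0]) if pepmass[0] is not None else None,
                    precursor_charge=charge,
                    title=str(params.get("title", "")),
                )
            )
    if not spectra:
        raise ValueError(f"{path}: no spectrum blocks found (not a valid MGF?)")
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    entries = []
    for i, s in enumerate(spectra):
        params = {"title": s.title or f"spectrum_{i}"}
        if s.precursor_mz is not None:
            params["pepmass"] = s.precursor_mz
            params["charge"] = f"{s.precursor_charge}+"
        entries.append(
            {"params": params, "m/z array": s.peaks_mz, "intensity array": s.peaks_intensity}
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_tsv(path, precursor_mz: float | None = None, precursor_charge: int = 1) -> Spectrum:
    """Read a two-column ``mz<TAB>intensity`` peak list (precursor supplied by caller)."""
    data = np.loadtxt(str(path), delimiter="\t", ndmin=2, comments="#")
    if data.shape[1] != 2:
        raise ValueError(f"{path}: expected two tab-separated columns, got {data.shape[1]}")
    return Spectrum(
        peaks_mz=data[:, 0],
        peaks_intensity=data[:, 1],
        precursor_mz=precursor_mz,
        precursor_charge=precursor_charge,
        title=Path(str(path)).stem,
    )


def write_tsv(spectrum: Spectrum, path) -> None:
    np.savetxt(
        str(path),
        np.column_stack([spectrum.peaks_mz, spectrum.peaks_intensity]),
        delimiter="\t",
        fmt="%.6f\t%.4f".split("\t"),
    )


def read_peaklist(path, precursor_mz: float | None = None, precursor_charge: int = 1) -> list[Spectrum]:
    """Dispatch on extension: ``.mgf`` → all blocks, anything else → TSV."""
    if str(path).lower().endswith(".mgf"):
        return read_mgf(path)
    return [read_tsv(path, precursor_mz=precursor_mz, precursor_charge=precursor_charge)]
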