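"""Standard-format I/O: FASTA sequences, titration CSVs, spectra CSVs.

Titration CSV layout::

    # labeled_total_uM=1.0
    # mode=mst
    titrant_conc_uM,signal
    2800.0,0.998
    ...

Spectra CSV layout: first column ``wavelength_nm``, remaining columns one
titration point each.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binding import SignalMode, SpectraMatrix, TitrationSeries

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_titration_csv",
    "write_titration_csv",
    "read_spectra_csv",
    "write_spectra_csv",
]


def read_fasta(path: "str | Path") -> Dict[str, str]:
    """FASTA file -> ordered {id: sequence} mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def write_fasta(path: "str | Path", sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_titration_csv(path: "str | Path", series: TitrationSeries) -> None:
    with open(path, "w") as fh:
        fh.write(f"# labeled_total_uM={series.labeled_total!r}\n")
        fh.write(f"# mode={series.mode.value}\n")
        fh.write("titrant_conc_uM,signal\n")
        for t, y in zip(series.titrant_totals, series.signal):
            fh.write(f"{float(t)!r},{float(y)!r}\n")


def read_titration_csv(path: "str | Path") -> TitrationSeries:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    if "labeled_total_uM" not in meta:
        raise ValueError(f"{path}: missing '# labeled_total_uM=' header line")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    if not {"titrant_conc_uM", "signal"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns titrant_conc_uM,signal")
    return TitrationSeries(
        labeled_total=float(meta["labeled_total_uM"]),
        titrant_totals=df["titrant_conc_uM"].to_numpy(float),
        signal=df["signal"].to_numpy(float),
        mode=SignalMode.parse(meta.get("mode", "fluorescence")),
    )


def write_spectra_csv(path: "str | Path", spectra: SpectraMatrix) -> None:
    cols = {"wavelength_nm": spectra.wavelengths}
    for j, p in enumerate(spectra.titration_points):
        cols[f"point_{j}"] = spectra.intensities[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_spectra_csv(path: "str | Path") -> SpectraMatrix:
    df = pd.read_csv(path)
    if df.columns[0] != "wavelength_nm":
        raise ValueError(f"{path}: first column must be wavelength_nm")
    wl = df["wavelength_nm"].to_numpy(float)
    m = df.iloc[:, 1:].to_numpy(float)
    return SpectraMatrix(wavelengths=wl, titration_points=np.arange(m.shape[1]),
                         intensities=m)
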