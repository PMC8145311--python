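"""Reading and writing the workflow's tabular and spectral formats.

Spectra come in three dialects: wide TSV (one row per replicate, one
intensity column per unit m/z), long TSV (one row per point), or mzML
(profile or centroid; read with pyteomics and collapsed to the nominal
grid). All tabular outputs are plain TSV.
"""

from __future__ import annotations

import re
from typing import Sequence

import pandas as pd

from .loocv import PCVSet, SampleClassification, SignificantPeak
from .preprocess import (
    DEFAULT_MZ_HI,
    DEFAULT_MZ_LO,
    PeakAreaVector,
    ReplicateSpectrum,
    ValidationError,
    nominal_bin,
)


def read_spectra_tsv(
    path, mz_lo: int = DEFAULT_MZ_LO, mz_hi: int = DEFAULT_MZ_HI
) -> list[ReplicateSpectrum]:
    """Read replicate spectra from a wide or long TSV (dialect auto-detected).

    Wide: ``sample_id  replicate  I400 ... I2000``. Long: ``sample_id
    replicate  mz  intensity``. The wide dialect's intensity columns
    define the grid; the declared ``mz_lo``/``mz_hi`` apply to the long
    dialect.
    """
    df = pd.read_csv(path, sep="\t")
    cols = set(df.columns)
    if {"mz", "intensity"} <= cols:
        return _from_long(df, mz_lo, mz_hi)
    icols = [c for c in df.columns if re.fullmatch(r"I\d+", str(c))]
    if not icols:
        raise ValidationError(
            "unrecognized spectra TSV: need either mz/intensity columns (long) "
            "or I<mz> columns (wide)"
        )
    return _from_wide(df, icols)


def _from_wide(df: pd.DataFrame, icols: list[str]) -> list[ReplicateSpectrum]:
    mzs = sorted(int(c[1:]) for c in icols)
    lo, hi = mzs[0], mzs[-1]
    if mzs != list(range(lo, hi + 1)):
        raise ValidationError("wide TSV intensity columns must form a contiguous unit grid")
    ordered = [f"I{m}" for m in mzs]
    out = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        intens = [rec[c] for c in ordered]
        out.append(
            ReplicateSpectrum(str(rec["sample_id"]), int(rec["replicate"]), intens, lo, hi)
        )
    return out


def _from_long(df: pd.DataFrame, mz_lo: int, mz_hi: int) -> list[ReplicateSpectrum]:
    out = []
    for (sid, rep), grp in df.groupby(["sample_id", "replicate"], sort=True):
        pts = list(zip(grp["mz"].astype(float), grp["intensity"].astype(float)))
        out.append(nominal_bin(pts, mz_lo, mz_hi, sample_id=str(sid), replicate_index=int(rep)))
    return out


def read_spectra_mzml(
    path,
    sample_id: str,
    mz_lo: int = DEFAULT_MZ_LO,
    mz_hi: int = DEFAULT_MZ_HI,
) -> list[ReplicateSpectrum]:
    """Read an mzML file; each MS1 spectrum becomes one replicate.

    Profile or centroid peak lists are both simply accumulated onto the
    nominal unit-mass grid.
    """
    from pyteomics import mzml as _mzml

    out = []
    with _mzml.MzML(str(path)) as reader:
        rep = 0
        for spec in reader:
            if spec.get("ms level", 1) != 1:
                continue
            rep += 1
            pts = list(zip(spec["m/z array"], spec["intensity array"]))
            out.append(nominal_bin(pts, mz_lo, mz_hi, sample_id=sample_id, replicate_index=rep))
    return out


def write_peak_matrix(vectors: dict[str, PeakAreaVector], path) -> None:
    """Samples x unit-m/z TSV of averaged areas (0 for absent peaks)."""
    all_mz = sorted({mz for v in vectors.values() for mz in v.areas})
    rows = {sid: [v.area_at(mz) for mz in all_mz] for sid, v in vectors.items()}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=all_mz)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def write_spectra_wide(replicates: Sequence[ReplicateSpectrum], path) -> None:
    """Emit replicate spectra in the wide TSV dialect."""
    if not replicates:
        raise ValidationError("no replicates to write")
    lo, hi = replicates[0].mz_lo, replicates[0].mz_hi
    cols = [f"I{m}" for m in range(lo, hi + 1)]
    rows = []
    for r in replicates:
        row = {"sample_id": r.sample_id, "replicate": r.replicate_index}
        row.update(zip(cols, r.intensities))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_pcv_set(pcvs: PCVSet, path) -> None:
    rows = [
        {
            "mz": p.mz,
            "p_value": p.p_value,
            "mean_A": p.mean_A,
            "mean_B": p.mean_B,
            "direction": p.direction,
            "pcv": p.pcv,
        }
        for p in pcvs.peaks
    ]
    pd.DataFrame(rows, columns=["mz", "p_value", "mean_A", "mean_B", "direction", "pcv"]).to_csv(
        path, sep="\t", index=False
    )


def read_pcv_set(path, alpha: float, floor_fraction: float) -> PCVSet:
    df = pd.read_csv(path, sep="\t")
    peaks = [
        SignificantPeak(
            mz=int(r.mz), p_value=float(r.p_value), mean_A=float(r.mean_A),
            mean_B=float(r.mean_B), direction=str(r.direction), pcv=float(r.pcv),
        )
        for r in df.itertuples(index=False)
    ]
    return PCVSet(peaks, left_in_ids=[], alpha=alpha, floor_fraction=floor_fraction)


def write_classifications(cls: Sequence[SampleClassification], path) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "true_group": c.true_group,
            "n_peaks": c.n_peaks_scored,
            "pct_A": c.pct_A,
            "pct_B": c.pct_B,
        }
        for c in cls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_log2_ratios(ratios: dict[str, float], path) -> None:
    """Two-column pathway-tool export: symbol, log2 hit ratio."""
    pd.DataFrame(
        {"symbol": list(ratios), "log2_ratio": list(ratios.values())}
    ).to_csv(path, sep="\t", index=False)


def write_randomization_plan(plan, path, original_labels: dict[str, str] | None = None) -> None:
    original_labels = original_labels or {}
    rows = [
        {
            "sample_id": sid,
            "original_group": original_labels.get(sid, ""),
            "randomized_group": grp,
        }
        for sid, grp in sorted(plan.permuted_labels.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
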