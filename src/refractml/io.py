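"""Delimited-text I/O for coefficient tables, cohorts and predictions.

All on-disk formats are plain CSV so every pipeline stage can be inspected
and re-run independently:

* coefficient file — long format, one row per mode:
  ``eye_id, basis, n, m, value_um, pupil_radius_mm``
* cohort file — one row per eye:
  ``patient_id, eye_id, side, age, sex, pupil_mm, sphere_D, cylinder_D,
  axis_deg, M, J0, J45``
* prediction file — ``eye_id, M, J0, J45``
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .basis import LDHD, ZERNIKE, ModeIndex, WavefrontCoefficients

__all__ = [
    "write_coefficients",
    "read_coefficients",
    "write_cohort",
    "read_cohort_frame",
    "write_transform",
]

COEFF_COLUMNS = ["eye_id", "basis", "n", "m", "value_um", "pupil_radius_mm"]


def write_coefficients(
    path: str | Path, coeffs: dict[str, WavefrontCoefficients]
) -> None:
    rows = []
    for eye_id, w in coeffs.items():
        for mode, v in zip(w.modes, w.values):
            rows.append(
                {
                    "eye_id": eye_id,
                    "basis": w.basis,
                    "n": mode.n,
                    "m": mode.m,
                    "value_um": v,
                    "pupil_radius_mm": w.pupil_radius_mm,
                }
            )
    pd.DataFrame(rows, columns=COEFF_COLUMNS).to_csv(path, index=False)


def read_coefficients(
    path: str | Path, max_order: int = 6
) -> dict[str, WavefrontCoefficients]:
    """Read and validate a long-format coefficient table."""
    df = pd.read_csv(path)
    missing = [c for c in COEFF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"coefficient file missing columns {missing}")
    out: dict[str, WavefrontCoefficients] = {}
    for eye_id, grp in df.groupby("eye_id", sort=False):
        bases = grp["basis"].unique()
        if len(bases) != 1 or bases[0] not in (ZERNIKE, LDHD):
            raise ValueError(f"eye {eye_id}: invalid or mixed basis {bases}")
        radii = grp["pupil_radius_mm"].unique()
        if len(radii) != 1 or radii[0] <= 0:
            raise ValueError(f"eye {eye_id}: invalid pupil radius {radii}")
        coeffs = {}
        for _, row in grp.iterrows():
            mode = ModeIndex(int(row["n"]), int(row["m"]))  # validates (n, m)
            coeffs[(mode.n, mode.m)] = float(row["value_um"])
        out[str(eye_id)] = WavefrontCoefficients.from_dict(
            basis=str(bases[0]),
            coeffs=coeffs,
            pupil_radius_mm=float(radii[0]),
            max_order=max_order,
        )
    return out


def write_cohort(path: str | Path, cohort) -> None:
    cohort.to_frame().to_csv(path, index=False)


def read_cohort_frame(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "eye_id", "M", "J0", "J45"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing columns {sorted(missing)}")
    return df


def write_transform(path: str | Path, transform) -> None:
    """Dump the Zernike -> LD/HD change-of-basis matrix with mode labels."""
    transform.to_frame().to_csv(path)
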