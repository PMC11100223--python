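"""Derivation of hydraulic, pit-sealing and wall-mechanics traits from raw
tracheid and pit measurements.

All inputs are in the units the measurements are recorded in: lengths in
micrometres, tracheid density in tracheids per mm^2.  The theoretical
hydraulic conductivity K_s is returned in kg m^-1 MPa^-1 s^-1; unit
conversions to SI happen internally.

Traits
------
D_h    conductivity-weighted (hydraulic) mean tracheid diameter, sum(d^5)/sum(d^4)
K_s    Hagen-Poiseuille theoretical conductivity per sapwood area
TO     torus overlap, (DT - DPA)/DT
MF     margo flexibility, (DPM - DT)/DPM
VE     valve effect, TO * MF
TSR    thickness-to-span ratio, 2*DWT / mean lumen diameter (implosion-resistance proxy)
CWR    cell wall ratio, percent wall area in the tracheid cross-section
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

#: scalar raw-measurement columns an anatomy table must provide
RAW_COLUMNS = [
    "species", "individual",
    "D_r", "LD_r", "D_c", "LD_c",
    "TD", "DWT", "FL", "RH", "NR",
    "DPM", "DT", "DPA",
]

#: column holding the per-individual list of measured tracheid diameters
DIAM_LIST_COLUMN = "tracheid_diams"

#: derived traits added by :func:`derive_all`
DERIVED_COLUMNS = ["D_h", "K_s", "TO", "MF", "VE", "TSR", "CWR"]

#: Table-style grouping of the 19 analysed traits, used for labelling output
TRAIT_GROUPS = {
    "pit": ["DPM", "DPA", "DT", "TO", "MF", "VE"],
    "tracheid": ["D_r", "LD_r", "D_c", "LD_c", "TD"],
    "hydraulic": ["D_h", "K_s"],
    "mechanics": ["DWT", "FL", "RH", "NR", "TSR", "CWR"],
}

ALL_TRAITS = [t for group in TRAIT_GROUPS.values() for t in group]


class PitMetrics(NamedTuple):
    TO: float
    MF: float
    VE: float
    in_range: bool


class WallMetrics(NamedTuple):
    TSR: float
    CWR: float


def hydraulic_diameter(diams: Iterable[float]) -> float:
    """Conductivity-weighted mean diameter sum(d^5)/sum(d^4) of a set of
    tracheid diameters (micrometres).

    Weights each conduit by its fourth-power contribution to laminar flow,
    so wide tracheids dominate.  Always >= the arithmetic mean (power-mean
    inequality), with equality only when all diameters are equal.
    """
    d = np.asarray(list(diams) if not isinstance(diams, np.ndarray) else diams,
                   dtype=float)
    if d.size == 0:
        raise ValueError("hydraulic_diameter: empty diameter list")
    if not np.all(np.isfinite(d)) or np.any(d <= 0):
        raise ValueError("hydraulic_diameter: all diameters must be finite and > 0")
    return float(np.sum(d ** 5) / np.sum(d ** 4))


def conductivity(
    dh_um: float,
    density_per_mm2: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Theoretical hydraulic conductivity K_s from the Hagen-Poiseuille law.

    K_s = (pi * rho_w / (128 * eta)) * CD * D^4

    Parameters
    ----------
    dh_um : hydraulic diameter in micrometres.
    density_per_mm2 : tracheid (conduit) density CD in mm^-2.
    constants : water density/viscosity; defaults are at 20 C.

    Returns
    -------
    K_s in kg m^-1 MPa^-1 s^-1.  Strictly increasing in both arguments:
    quartic in diameter, linear in density.
    """
    if not (dh_um > 0 and density_per_mm2 > 0):
        raise ValueError("conductivity: diameter and density must be > 0")
    dh_m = dh_um * 1e-6
    cd_m2 = density_per_mm2 * 1e6
    ks_per_pa = (
        math.pi * constants.water_density / (128.0 * constants.water_viscosity)
    ) * cd_m2 * dh_m ** 4
    return ks_per_pa * 1e6  # per-Pa -> per-MPa


def pit_metrics(dpm: float, dt: float, dpa: float) -> PitMetrics:
    """Torus overlap, margo flexibility and valve effect of a bordered pit.

    TO = (DT - DPA)/DT, MF = (DPM - DT)/DPM, VE = TO*MF.  All three lie in
    (0, 1) exactly when DPA < DT < DPM (aperture narrower than torus, torus
    narrower than membrane).  Geometrically inconsistent pits are still
    computed but flagged via ``in_range`` and a warning, since the source
    measurements state no exclusion rule.
    """
    if not (dpm > 0 and dt > 0 and dpa > 0):
        raise ValueError("pit_metrics: all pit diameters must be > 0")
    to = (dt - dpa) / dt
    mf = (dpm - dt) / dpm
    ve = to * mf
    in_range = dpa < dt < dpm
    if not in_range:
        warnings.warn(
            f"pit geometry out of range (DPA={dpa}, DT={dt}, DPM={dpm}); "
            "TO/MF fall outside (0,1)",
            stacklevel=2,
        )
    return PitMetrics(to, mf, ve, in_range)


def wall_metrics(
    dwt: float,
    d_r: float,
    ld_r: float,
    d_c: float,
    ld_c: float,
    tsr_formula: str = "double_wall_over_span",
    cwr_formula: str = "area_fraction",
) -> WallMetrics:
    """Thickness-to-span ratio and cell wall ratio from wall and lumen sizes.

    TSR (default) = 2*DWT / mean(LD_r, LD_c): double wall thickness relative
    to the mean lumen span, the standard implosion-resistance proxy.
    Alternative ``"squared"``: (DWT / mean lumen)^2.

    CWR (default) = 100 * (1 - (LD_r*LD_c)/(D_r*D_c)): percent of the
    cross-section that is wall, treating the cell outline and lumen as
    rectangles.  Alternative ``"linear"``: 100 * (1 - mean lumen / mean
    diameter).
    """
    for name, v in [("DWT", dwt), ("D_r", d_r), ("LD_r", ld_r),
                    ("D_c", d_c), ("LD_c", ld_c)]:
        if not v > 0:
            raise ValueError(f"wall_metrics: {name} must be > 0 (got {v})")
    if ld_r > d_r or ld_c > d_c:
        raise ValueError("wall_metrics: lumen diameter exceeds tracheid diameter")

    span = 0.5 * (ld_r + ld_c)
    if tsr_formula == "double_wall_over_span":
        tsr = 2.0 * dwt / span
    elif tsr_formula == "squared":
        tsr = (dwt / span) ** 2
    else:
        raise ValueError(f"unknown tsr_formula: {tsr_formula!r}")

    if cwr_formula == "area_fraction":
        cwr = 100.0 * (1.0 - (ld_r * ld_c) / (d_r * d_c))
    elif cwr_formula == "linear":
        cwr = 100.0 * (1.0 - span / (0.5 * (d_r + d_c)))
    else:
        raise ValueError(f"unknown cwr_formula: {cwr_formula!r}")
    return WallMetrics(tsr, cwr)


def _parse_diam_list(value) -> list[float] | None:
    if value is None:
        return None
    if isinstance(value, str):
        value = value.strip()
        if not value:
            return None
        return [float(tok) for tok in value.replace(",", ";").split(";") if tok]
    if isinstance(value, (list, tuple, np.ndarray)):
        return [float(v) for v in value]
    if isinstance(value, float) and math.isnan(value):
        return None
    return [float(value)]


def validate_anatomy(df: pd.DataFrame) -> None:
    """Check schema and per-row measurement invariants of an anatomy table."""
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"anatomy table is missing required columns: {missing}; "
            f"expected {RAW_COLUMNS}"
        )
    if df.empty:
        return
    for col in ["D_r", "LD_r", "D_c", "LD_c", "TD", "DWT", "FL", "RH",
                "NR", "DPM", "DT", "DPA"]:
        bad = df.index[~(df[col].astype(float) > 0)]
        if len(bad):
            raise ValueError(f"anatomy column {col!r} must be > 0 "
                             f"(first offending row index: {bad[0]})")
    for lum, full in [("LD_r", "D_r"), ("LD_c", "D_c")]:
        bad = df.index[df[lum].astype(float) > df[full].astype(float)]
        if len(bad):
            raise ValueError(
                f"lumen diameter {lum} exceeds tracheid diameter {full} "
                f"(first offending row index: {bad[0]})"
            )


def derive_all(
    df: pd.DataFrame,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    tsr_formula: str = "double_wall_over_span",
    cwr_formula: str = "area_fraction",
) -> pd.DataFrame:
    """Derive all computed traits, one output row per (species, individual).

    D_h is computed from the individual's own measured-diameter list
    (``tracheid_diams``) when present, falling back to the scalar D_r.
    K_s uses that individual's D_h and TD, so species-level K_s should be
    averaged over individuals rather than recomputed from species-mean D_h
    (Jensen's inequality makes the two differ).
    """
    validate_anatomy(df)
    out = df.copy().reset_index(drop=True)
    if out.empty:
        for col in DERIVED_COLUMNS + ["pit_in_range"]:
            out[col] = pd.Series(dtype=float)
        return out

    dh, ks, to, mf, ve, tsr, cwr, ok = [], [], [], [], [], [], [], []
    for _, row in out.iterrows():
        diams = None
        if DIAM_LIST_COLUMN in out.columns:
            diams = _parse_diam_list(row[DIAM_LIST_COLUMN])
        if diams is None:
            diams = [float(row["D_r"])]
        d_h = hydraulic_diameter(diams)
        dh.append(d_h)
        ks.append(conductivity(d_h, float(row["TD"]), constants))
        pm = pit_metrics(float(row["DPM"]), float(row["DT"]), float(row["DPA"]))
        to.append(pm.TO)
        mf.append(pm.MF)
        ve.append(pm.VE)
        ok.append(pm.in_range)
        wm = wall_metrics(float(row["DWT"]), float(row["D_r"]), float(row["LD_r"]),
                          float(row["D_c"]), float(row["LD_c"]),
                          tsr_formula=tsr_formula, cwr_formula=cwr_formula)
        tsr.append(wm.TSR)
        cwr.append(wm.CWR)

    out["D_h"] = dh
    out["K_s"] = ks
    out["TO"] = to
    out["MF"] = mf
    out["VE"] = ve
    out["TSR"] = tsr
    out["CWR"] = cwr
    out["pit_in_range"] = ok
    return out


def species_summary(derived: pd.DataFrame, traits: Sequence[str] | None = None):
    """Species x trait tables of means, standard deviations and counts."""
    traits = list(traits) if traits is not None else [
        t for t in ALL_TRAITS if t in derived.columns
    ]
    grouped = derived.groupby("species")[traits]
    return grouped.mean(), grouped.std(ddof=1), grouped.size()


# ---------------------------------------------------------------------------
# CSV I/O.  Diameter lists are stored semicolon-joined in one column; header
# comment lines (starting with '#') carry the units.

_UNITS_COMMENT = (
    "# units: lengths um; TD, NR mm^-2; K_s kg m^-1 MPa^-1 s^-1; "
    "CWR percent; TO, MF, VE, TSR dimensionless"
)


def read_anatomy_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if DIAM_LIST_COLUMN in df.columns:
        df[DIAM_LIST_COLUMN] = df[DIAM_LIST_COLUMN].map(_parse_diam_list)
    validate_anatomy(df)
    return df


def write_anatomy_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if DIAM_LIST_COLUMN in out.columns:
        out[DIAM_LIST_COLUMN] = out[DIAM_LIST_COLUMN].map(
            lambda v: ";".join(f"{x:.3f}" for x in v) if v is not None else ""
        )
    with open(path, "w") as fh:
        fh.write(_UNITS_COMMENT + "\n")
        out.to_csv(fh, index=False)


def write_derived_csv(df: pd.DataFrame, path) -> None:
    out = df.drop(columns=[DIAM_LIST_COLUMN], errors="ignore")
    with open(path, "w") as fh:
        fh.write(_UNITS_COMMENT + "\n")
        out.to_csv(fh, index=False)
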