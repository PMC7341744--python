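"""Weight-for-height z-scores by the LMS method and severe-acute-malnutrition flags.

The LMS method summarises a growth reference by three smooth functions of
height (and sex): a Box-Cox power ``L``, a median ``M`` (kg) and a
coefficient of variation ``S``.  A child's weight ``y`` maps to a z-score

    z = ((y / M)**L - 1) / (L * S)        for L != 0
    z = ln(y / M) / S                     in the L -> 0 limit

Severe acute malnutrition (SAM) is a weight-for-height z-score (WHZ)
strictly below -3, or the presence of nutritional oedema.  Records with
|WHZ| > 5 are flagged as biologically implausible and excluded from
analysis upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LMSTable",
    "WHZResult",
    "lms_zscore",
    "lms_weight_from_z",
    "lookup_lms",
    "compute_whz",
    "compute_whz_table",
    "flag_sam",
    "SAM_WHZ_THRESHOLD",
    "IMPLAUSIBLE_ABS_WHZ",
]

#: WHZ below this value (strict) defines SAM.
SAM_WHZ_THRESHOLD = -3.0

#: |WHZ| beyond this is treated as a measurement artefact and excluded.
IMPLAUSIBLE_ABS_WHZ = 5.0

_L_LOG_FORM_EPS = 1e-8

_LMS_COLUMNS = ["sex", "height_cm", "L", "M", "S"]


class LMSTable:
    """Sex- and height-indexed (L, M, S) reference rows.

    Wraps a DataFrame with columns ``sex, height_cm, L, M, S``.  Within each
    sex, heights must be strictly increasing, ``M > 0`` and ``S > 0``.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _LMS_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"LMS table missing columns: {missing}")
        frame = frame.loc[:, _LMS_COLUMNS].copy()
        frame["sex"] = frame["sex"].astype(str)
        for sex, sub in frame.groupby("sex"):
            h = sub["height_cm"].to_numpy(float)
            if not np.all(np.diff(h) > 0):
                raise ValueError(f"heights not strictly increasing for sex={sex!r}")
            if not np.all(sub["M"].to_numpy(float) > 0):
                raise ValueError(f"non-positive M for sex={sex!r}")
            if not np.all(sub["S"].to_numpy(float) > 0):
                raise ValueError(f"non-positive S for sex={sex!r}")
        self.frame = frame.reset_index(drop=True)
        # per-sex arrays for interpolation
        self._by_sex = {
            sex: (
                sub["height_cm"].to_numpy(float),
                sub[["L", "M", "S"]].to_numpy(float),
            )
            for sex, sub in frame.groupby("sex")
        }

    @property
    def sexes(self) -> list[str]:
        return sorted(self._by_sex)

    def height_range(self, sex: str) -> tuple[float, float]:
        h, _ = self._sex_arrays(sex)
        return float(h[0]), float(h[-1])

    def _sex_arrays(self, sex: str):
        try:
            return self._by_sex[str(sex)]
        except KeyError:
            raise KeyError(f"sex {sex!r} not in LMS table (have {self.sexes})") from None

    @classmethod
    def read_csv(cls, path) -> "LMSTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class WHZResult:
    """Weight-for-height z-score with plausibility and SAM flags."""

    whz: float
    implausible: bool
    sam: bool


def lms_zscore(weight, L, M, S):
    """Box-Cox (LMS) z-score of ``weight`` against reference (L, M, S).

    Uses the logarithmic limit form when ``|L| < 1e-8`` so the map is
    continuous in L at 0.  Vectorised over all arguments.
    """
    weight = np.asarray(weight, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(weight <= 0) or np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("weight, M and S must all be positive")
    ratio = weight / M
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(
            np.abs(L) < _L_LOG_FORM_EPS,
            np.log(ratio) / S,
            (np.power(ratio, L) - 1.0) / (L * S),
        )
    if z.ndim == 0:
        return float(z)
    return z


def lms_weight_from_z(z, L, M, S):
    """Inverse LMS map: the weight whose z-score is ``z`` under (L, M, S)."""
    z = np.asarray(z, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    small = np.abs(L) < _L_LOG_FORM_EPS
    L_safe = np.where(small, 1.0, L)
    with np.errstate(invalid="ignore"):
        w = np.where(
            small,
            M * np.exp(S * z),
            M * np.power(1.0 + L * S * z, 1.0 / L_safe),
        )
    if w.ndim == 0:
        return float(w)
    return w


def lookup_lms(table: LMSTable, sex, height):
    """Linearly interpolated (L, M, S) at ``height`` cm for ``sex``.

    Heights on a grid point return that row exactly; heights outside the
    table's range raise ``ValueError`` (such records are excluded upstream).
    """
    h_grid, lms = table._sex_arrays(sex)
    h = float(height)
    if h < h_grid[0] or h > h_grid[-1]:
        raise ValueError(
            f"height {h} cm outside reference range "
            f"[{h_grid[0]}, {h_grid[-1]}] for sex={sex!r}"
        )
    L = float(np.interp(h, h_grid, lms[:, 0]))
    M = float(np.interp(h, h_grid, lms[:, 1]))
    S = float(np.interp(h, h_grid, lms[:, 2]))
    return L, M, S


def flag_sam(whz, oedema: bool = False) -> bool:
    """SAM iff WHZ strictly below -3 or nutritional oedema is present.

    The threshold is strict: WHZ = -3.0 exactly is not SAM.
    """
    whz = float(whz)
    if not np.isfinite(whz):
        raise ValueError("whz must be finite")
    return bool(whz < SAM_WHZ_THRESHOLD or oedema)


def compute_whz(weight, height, sex, table: LMSTable, oedema: bool = False) -> WHZResult:
    """WHZ, implausibility flag and SAM flag for one child."""
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    L, M, S = lookup_lms(table, sex, height)
    z = lms_zscore(weight, L, M, S)
    implausible = abs(z) > IMPLAUSIBLE_ABS_WHZ
    return WHZResult(whz=float(z), implausible=bool(implausible), sam=flag_sam(z, oedema))


def compute_whz_table(
    records: pd.DataFrame,
    table: LMSTable,
    weight_col: str = "weight_kg",
    height_col: str = "height_cm",
    sex_col: str = "sex",
    oedema_col: str | None = None,
) -> pd.DataFrame:
    """Vectorised WHZ over a child table.

    Returns a copy of ``records`` with ``whz``, ``implausible`` and ``sam``
    columns appended.  Heights outside the reference range get NaN WHZ and
    ``implausible=True`` instead of raising, so batch runs can count and
    drop them.
    """
    out = records.copy()
    whz = np.full(len(out), np.nan)
    for sex, idx in out.groupby(sex_col, sort=False).groups.items():
        h_grid, lms = table._sex_arrays(sex)
        h = out.loc[idx, height_col].to_numpy(float)
        w = out.loc[idx, weight_col].to_numpy(float)
        in_range = (h >= h_grid[0]) & (h <= h_grid[-1]) & (w > 0)
        L = np.interp(h[in_range], h_grid, lms[:, 0])
        M = np.interp(h[in_range], h_grid, lms[:, 1])
        S = np.interp(h[in_range], h_grid, lms[:, 2])
        vals = np.full(len(h), np.nan)
        vals[in_range] = lms_zscore(w[in_range], L, M, S)
        whz[out.index.get_indexer(idx)] = vals
    out["whz"] = whz
    out["implausible"] = ~np.isfinite(whz) | (np.abs(whz) > IMPLAUSIBLE_ABS_WHZ)
    oedema = (
        out[oedema_col].astype(bool).to_numpy()
        if oedema_col is not None
        else np.zeros(len(out), dtype=bool)
    )
    out["sam"] = ((whz < SAM_WHZ_THRESHOLD) & np.isfinite(whz)) | oedema
    return out
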