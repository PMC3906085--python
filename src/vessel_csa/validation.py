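"""Comparison statistics against a reference lumen-area series.

The reference is either an IVUS pullback table (per-frame lumen diameters and
area along the catheter arc length) or, on phantoms, the analytic ground
truth.  The statistics are the field's standard trio:

* signed per-point percent error ``(A_ref - A_test) / A_ref * 100``,
* root-mean-square error normalized to the reference mean, in percent,
* ordinary least-squares fit of test on reference, read against the
  identity line.

Alignment between series is by arc length: the reference frame positions
(shifted by a user-supplied landmark offset) are mapped onto the test
profile, whose area is linearly interpolated at those stations — the test
profile is the coarser series, so it is the one interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .csa import CSAProfile

__all__ = [
    "IVUSFrame",
    "ComparisonResult",
    "read_pullback",
    "align_series",
    "percent_error",
    "rmse_normalized",
    "identity_fit",
    "compare",
]

PULLBACK_COLUMNS = ["frame", "position", "max_d", "min_d", "avg_d", "area"]


@dataclass
class IVUSFrame:
    """One traced IVUS frame: position along the pullback plus lumen measures."""

    frame: int
    position: float  # mm along the pullback
    max_d: float  # maximal lumen diameter, mm
    min_d: float  # minimal lumen diameter, mm
    avg_d: float  # average lumen diameter, mm
    area: float  # lumen area, mm^2

    def validate(self) -> str | None:
        if not (self.min_d <= self.avg_d <= self.max_d):
            return (
                f"frame {self.frame}: diameters violate min <= avg <= max "
                f"({self.min_d}, {self.avg_d}, {self.max_d})"
            )
        if self.area <= 0:
            return f"frame {self.frame}: non-positive lumen area {self.area}"
        return None


@dataclass
class ComparisonResult:
    positions: np.ndarray  # matched stations, mm
    ref: np.ndarray  # reference areas (IVUS or truth), mm^2
    test: np.ndarray  # CT-derived areas interpolated at the stations, mm^2
    percent_errors: np.ndarray = field(init=False)
    mean_percent_error: float = field(init=False)  # signed
    mean_abs_percent_error: float = field(init=False)
    rmse_normalized: float = field(init=False)  # %
    slope: float = field(init=False)
    intercept: float = field(init=False)

    def __post_init__(self) -> None:
        self.percent_errors = percent_error(self.ref, self.test)
        self.mean_percent_error = float(self.percent_errors.mean())
        self.mean_abs_percent_error = float(np.abs(self.percent_errors).mean())
        self.rmse_normalized = rmse_normalized(self.ref, self.test)
        self.slope, self.intercept, _ = identity_fit(self.ref, self.test)

    def summary(self) -> dict:
        return {
            "n_pairs": int(len(self.ref)),
            "mean_percent_error": self.mean_percent_error,
            "mean_abs_percent_error": self.mean_abs_percent_error,
            "rmse_normalized_pct": self.rmse_normalized,
            "fit_slope": self.slope,
            "fit_intercept": self.intercept,
        }

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position_mm": self.positions,
                "area_ref_mm2": self.ref,
                "area_test_mm2": self.test,
                "percent_error": self.percent_errors,
            }
        )


def read_pullback(path: str) -> list[IVUSFrame]:
    """Read a pullback CSV (columns frame, position, max_d, min_d, avg_d, area).

    Rows violating the per-frame invariants are rejected with a warning;
    non-monotone positions among the surviving rows are a hard error.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"pullback file {path} has no rows")
    missing = [c for c in PULLBACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pullback file {path} missing columns {missing}")
    frames = []
    for _, row in df.iterrows():
        f = IVUSFrame(
            frame=int(row["frame"]),
            position=float(row["position"]),
            max_d=float(row["max_d"]),
            min_d=float(row["min_d"]),
            avg_d=float(row["avg_d"]),
            area=float(row["area"]),
        )
        problem = f.validate()
        if problem:
            warnings.warn(f"rejecting row: {problem}")
            continue
        frames.append(f)
    if not frames:
        raise ValueError(f"no valid frames in {path}")
    positions = np.array([f.position for f in frames])
    if np.any(np.diff(positions) < 0):
        raise ValueError("pullback positions are not nondecreasing")
    return frames


def align_series(
    profile: CSAProfile,
    frames: list[IVUSFrame],
    start_offset: float = 0.0,
    end_trim: float = 0.0,
) -> ComparisonResult:
    """Pair reference frames with the CT profile by arc length.

    Frame positions are shifted by ``start_offset`` (the landmark offset, mm)
    into the profile's arc-length coordinate; the profile area is linearly
    interpolated there.  Pairs outside the overlap, or within ``end_trim`` mm
    of the profile's far end, are dropped.
    """
    s_prof = profile.s
    a_prof = profile.areas
    if len(s_prof) < 2:
        raise ValueError("profile has fewer than 2 valid sections")
    pos = np.array([f.position for f in frames]) + start_offset
    ref = np.array([f.area for f in frames])
    lo, hi = s_prof[0], s_prof[-1] - end_trim
    keep = (pos >= lo) & (pos <= hi)
    if not keep.any():
        raise ValueError("no overlap between pullback and profile arc ranges")
    pos, ref = pos[keep], ref[keep]
    test = np.interp(pos, s_prof, a_prof)
    return ComparisonResult(positions=pos, ref=ref, test=test)


def percent_error(a_ref, a_test) -> np.ndarray | float:
    """Signed percent error (a_ref - a_test) / a_ref * 100."""
    a_ref = np.asarray(a_ref, dtype=float)
    a_test = np.asarray(a_test, dtype=float)
    if np.any(a_ref <= 0):
        raise ValueError("reference values must be positive")
    out = (a_ref - a_test) / a_ref * 100.0
    return float(out) if out.ndim == 0 else out


def rmse_normalized(ref, test) -> float:
    """RMSE between the series divided by the reference mean, in percent."""
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape or ref.size < 2:
        raise ValueError("series must have equal length >= 2")
    rmse = float(np.sqrt(np.mean((ref - test) ** 2)))
    return rmse / float(ref.mean()) * 100.0


def identity_fit(ref, test) -> tuple[float, float, float]:
    """OLS fit of test on ref: returns (slope, intercept, normalized RMSE %).

    Read against the identity line y = x: slope 1 / intercept 0 means the CT
    series reproduces the reference without proportional or constant bias.
    """
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.size < 3:
        raise ValueError("need at least 3 points for a meaningful fit")
    with warnings.catch_warnings():
        # a (near-)constant reference makes slope/intercept ill-conditioned;
        # the numbers are still reported, the normalized RMSE carries the news
        warnings.simplefilter("ignore", np.exceptions.RankWarning)
        slope, intercept = np.polyfit(ref, test, 1)
    return float(slope), float(intercept), rmse_normalized(ref, test)


def compare(
    profile: CSAProfile,
    frames: list[IVUSFrame],
    start_offset: float = 0.0,
    end_trim: float = 0.0,
) -> ComparisonResult:
    """Convenience wrapper: align then summarize."""
    return align_series(profile, frames, start_offset, end_trim)


def plot_identity(result: ComparisonResult, path: str | None = None):
    """Scatter of test vs reference with the OLS fit and the identity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(result.ref, result.test, "ko", ms=3, label="data")
    lim = [0, max(result.ref.max(), result.test.max()) * 1.1]
    ax.plot(lim, lim, "k:", label="y = x")
    xs = np.linspace(*lim, 10)
    ax.plot(
        xs,
        result.slope * xs + result.intercept,
        "k-",
        label=f"y = {result.slope:.2f}x + {result.intercept:.2f}",
    )
    ax.set_xlabel("reference area (mm$^2$)")
    ax.set_ylabel("CT area (mm$^2$)")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
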