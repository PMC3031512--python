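"""Nuclear-to-cytoplasm intensity-ratio quantification and region statistics.

The measured quantity per cell and time point is the ratio R of the mean
fluorescence intensity inside the nuclear mask to the mean intensity inside
the cytoplasmic mask of the same cell. Traces are normalized to the
pre-stimulus ratio, ``R_norm(t) = R(t)/R(0)``, so every cell starts at 1 and
the model state variable is ``y = R_norm - 1``.

Masks are inputs, not computed here: segmentation is out of scope, and the
synthetic renderer emits ground-truth masks so the pipeline is testable
end to end. Stack projection defaults to maximum intensity (preserves
nuclear puncta against out-of-focus planes); a mean mode is available.

Region comparisons use the two-sided Mann-Whitney U rank-sum test, exact
enumeration for small tie-free samples and the tie-corrected normal
approximation otherwise, with significance flagged at alpha = 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InvalidArgumentError,
    MissingDataError,
    ParseError,
    UndefinedStatisticError,
)

__all__ = [
    "CellTrace",
    "RegionComparison",
    "project_stack",
    "intensity_ratio",
    "normalize_trace",
    "compare_regions",
    "region_summary",
    "read_traces_csv",
    "write_traces_csv",
]

TRACE_COLUMNS = ("cell_id", "explant_id", "region", "time_min", "i_nuc", "i_cyt")


@dataclass(frozen=True)
class CellTrace:
    """One cell's time series of compartment intensities.

    ``i_nuc`` and ``i_cyt`` are mean intensities (arbitrary units) over the
    nuclear and cytoplasmic masks; ``i_cyt`` must be positive wherever used.
    Derived quantities: ``ratio`` R = I_nuc/I_cyt, ``ratio_norm``
    R_norm = R/R(0) and ``y`` = R_norm - 1.
    """

    cell_id: str
    explant_id: str
    region: str
    times: np.ndarray
    i_nuc: np.ndarray
    i_cyt: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        nuc = np.asarray(self.i_nuc, dtype=float)
        cyt = np.asarray(self.i_cyt, dtype=float)
        if not (t.shape == nuc.shape == cyt.shape) or t.size == 0:
            raise InvalidArgumentError("times, i_nuc, i_cyt must share a nonzero length")
        if np.any(np.diff(t) <= 0):
            raise InvalidArgumentError("times must be strictly increasing")
        if np.any(cyt <= 0):
            raise InvalidArgumentError("cytoplasmic intensity must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "i_nuc", nuc)
        object.__setattr__(self, "i_cyt", cyt)

    @property
    def ratio(self) -> np.ndarray:
        return self.i_nuc / self.i_cyt

    @property
    def ratio_norm(self) -> np.ndarray:
        r = self.ratio
        return r / r[0]

    @property
    def y(self) -> np.ndarray:
        return self.ratio_norm - 1.0

    def value_at(self, t: float, what: str = "ratio_norm") -> float:
        idx = np.flatnonzero(np.isclose(self.times, t))
        if idx.size == 0:
            raise MissingDataError(
                f"cell {self.cell_id} has no sample at t={t}", offenders=[self.cell_id]
            )
        return float(getattr(self, what)[idx[0]])


def project_stack(
    stack: np.ndarray, method: Literal["max", "mean"] = "max"
) -> np.ndarray:
    """Project a z-stack (axial axis first) to a single 2D image."""
    arr = np.asarray(stack)
    if arr.size == 0 or arr.ndim != 3:
        raise InvalidArgumentError("stack must be a nonempty 3D array (z, y, x)")
    if method == "max":
        return arr.max(axis=0)
    if method == "mean":
        return arr.mean(axis=0)
    raise InvalidArgumentError(f"unknown projection method {method!r}")


def intensity_ratio(
    image: np.ndarray, nuc_mask: np.ndarray, cyt_mask: np.ndarray
) -> float:
    """Ratio of mean intensity over the nuclear mask to the cytoplasmic mask.

    Masks are boolean (or nonzero = member), disjoint, nonempty and
    image-shaped. Invariant to rescaling the whole image by a positive
    scalar.
    """
    img = np.asarray(image, dtype=float)
    nuc = np.asarray(nuc_mask).astype(bool)
    cyt = np.asarray(cyt_mask).astype(bool)
    if nuc.shape != img.shape or cyt.shape != img.shape:
        raise InvalidArgumentError("masks must match the image shape")
    if not nuc.any() or not cyt.any():
        raise InvalidArgumentError("masks must be nonempty")
    if (nuc & cyt).any():
        raise InvalidArgumentError("nuclear and cytoplasmic masks overlap")
    cyt_mean = float(img[cyt].mean())
    if cyt_mean == 0.0:
        raise UndefinedStatisticError("zero mean cytoplasmic intensity")
    return float(img[nuc].mean()) / cyt_mean


def normalize_trace(trace: CellTrace) -> CellTrace:
    """Validate that the pre-stimulus ratio is positive and return the trace.

    Normalization itself is definitional (``ratio_norm`` divides by R(0), so
    R_norm(0) = 1 and y(0) = 0 exactly); this entry point exists to signal
    unusable baselines explicitly.
    """
    r0 = float(trace.ratio[0])
    if r0 <= 0:
        raise InvalidArgumentError(
            f"cell {trace.cell_id}: pre-stimulus ratio {r0} is not positive"
        )
    return trace


@dataclass(frozen=True)
class RegionComparison:
    """Two-sided Mann-Whitney U comparison of two regions' ratio samples."""

    region_a: str
    region_b: str
    u_statistic: float
    p_value: float
    n_a: int
    n_b: int
    alpha: float = 0.01

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_json_dict(self) -> dict:
        return {
            "region_a": self.region_a,
            "region_b": self.region_b,
            "U": self.u_statistic,
            "p_value": self.p_value,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "significant_at_0.01": self.significant,
        }


def compare_regions(
    a: Sequence[float],
    b: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
    alpha: float = 0.01,
) -> RegionComparison:
    """Two-sided Mann-Whitney U test between two samples of ratios.

    Exact null distribution when both samples have at most 8 observations
    and no ties cross the samples; otherwise the normal approximation with
    tie correction and continuity correction.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size == 0 or xb.size == 0:
        raise InvalidArgumentError("both samples must be nonempty")
    ties = np.intersect1d(xa, xb).size > 0 or (
        np.unique(np.concatenate([xa, xb])).size < xa.size + xb.size
    )
    exact_ok = xa.size <= 8 and xb.size <= 8 and not ties
    method = "exact" if exact_ok else "asymptotic"
    res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
    return RegionComparison(
        region_a=label_a,
        region_b=label_b,
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_a=int(xa.size),
        n_b=int(xb.size),
        alpha=alpha,
    )


def region_summary(
    traces: Iterable[CellTrace], t: float, what: str = "ratio_norm"
) -> pd.DataFrame:
    """Per-region mean, sample SD (n-1 denominator) and n at time ``t``.

    A single-cell region reports SD = 0.0 with n = 1 so the caller can flag
    it. Cells missing the time point abort with a
    :class:`MissingDataError` naming them.
    """
    traces = list(traces)
    if not traces:
        raise InvalidArgumentError("no traces supplied")
    missing = [
        tr.cell_id for tr in traces if not np.any(np.isclose(tr.times, t))
    ]
    if missing:
        raise MissingDataError(
            f"{len(missing)} cell(s) lack a sample at t={t}: {missing}",
            offenders=missing,
        )
    rows = [
        {"region": tr.region, "cell_id": tr.cell_id, "value": tr.value_at(t, what)}
        for tr in traces
    ]
    df = pd.DataFrame(rows)
    out = (
        df.groupby("region")["value"]
        .agg(mean="mean", sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
             n="size")
        .reset_index()
    )
    return out


def traces_to_frame(traces: Iterable[CellTrace]) -> pd.DataFrame:
    """Long-format table of traces with derived ratio columns appended."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "explant_id": tr.explant_id,
                    "region": tr.region,
                    "time_min": tr.times,
                    "i_nuc": tr.i_nuc,
                    "i_cyt": tr.i_cyt,
                    "ratio": tr.ratio,
                    "ratio_norm": tr.ratio_norm,
                    "y": tr.y,
                }
            )
        )
    if not frames:
        raise InvalidArgumentError("no traces supplied")
    return pd.concat(frames, ignore_index=True)


def write_traces_csv(traces: Iterable[CellTrace], path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces_csv(path) -> list[CellTrace]:
    """Read a trace table, validating the required schema.

    Required columns: cell_id, explant_id, region, time_min, i_nuc, i_cyt.
    Derived columns present in the file are ignored and recomputed.
    """
    df = pd.read_csv(path)
    for col in TRACE_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"trace CSV is missing required column {col!r}")
    bad = df[["time_min", "i_nuc", "i_cyt"]].isna()
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        col = bad.columns[bad.iloc[row].to_numpy().argmax()]
        raise ParseError(f"unparseable value at row {row}, column {col!r}")
    traces = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("time_min")
        traces.append(
            CellTrace(
                cell_id=str(cell_id),
                explant_id=str(grp["explant_id"].iloc[0]),
                region=str(grp["region"].iloc[0]),
                times=grp["time_min"].to_numpy(dtype=float),
                i_nuc=grp["i_nuc"].to_numpy(dtype=float),
                i_cyt=grp["i_cyt"].to_numpy(dtype=float),
            )
        )
    return traces
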