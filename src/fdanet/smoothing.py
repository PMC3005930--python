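"""Spline smoothing of expression time series.

Discrete expression measurements are turned into continuous, differentiable
trajectories by interpolating each gene's series with a cubic spline
(not-a-knot end conditions by default).  The spline's analytic derivative is
what the gradient-matching fit regresses against, so interpolation fidelity
and derivative quality are the load-bearing properties here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "ExpressionSeries",
    "SplineTrajectory",
    "fit_spline",
    "eval_spline",
    "eval_derivative",
    "presmooth",
    "read_expression_tsv",
    "write_expression_tsv",
    "dump_spline_coefficients",
]


@dataclass(frozen=True)
class ExpressionSeries:
    """One observed expression time series: N genes sampled on a common grid.

    Parameters
    ----------
    series_id : str
        Label of the trajectory (e.g. a space point or a replicate).
    gene_names : tuple of str
        Ordered gene labels; one row of ``values`` per gene.
    times : ndarray, shape (T,)
        Strictly increasing sample times (arbitrary units).
    values : ndarray, shape (N, T)
        Nonnegative expression levels, aligned to ``gene_names``.
    """

    series_id: str
    gene_names: tuple[str, ...]
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if times.ndim != 1 or times.size < 2:
            raise ValueError(
                f"series {self.series_id!r}: need at least 2 time points"
            )
        if np.any(np.diff(times) <= 0):
            raise ValueError(
                f"series {self.series_id!r}: times must be strictly increasing"
            )
        if values.shape != (len(self.gene_names), times.size):
            raise ValueError(
                f"series {self.series_id!r}: values shape {values.shape} does "
                f"not match {len(self.gene_names)} genes x {times.size} times"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError(f"series {self.series_id!r}: non-finite values")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_names", tuple(self.gene_names))

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_names.index(gene)
        except ValueError:
            raise KeyError(
                f"gene {gene!r} not in series {self.series_id!r}"
            ) from None


@dataclass(frozen=True)
class SplineTrajectory:
    """Continuous trajectory: one interpolating cubic spline per gene.

    ``spline`` is vectorised over genes (scipy ``CubicSpline`` with
    ``axis=1``); ``derivative`` is its analytic first derivative, obtained by
    coefficient differentiation, never by finite differences.
    """

    series_id: str
    gene_names: tuple[str, ...]
    knots: np.ndarray
    spline: CubicSpline = field(repr=False)
    derivative: CubicSpline = field(repr=False)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.knots[0]), float(self.knots[-1])

    @property
    def coefficients(self) -> np.ndarray:
        """Piecewise polynomial coefficients, shape (4, n_intervals, N)."""
        return self.spline.c

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_names.index(gene)
        except ValueError:
            raise KeyError(
                f"gene {gene!r} not in trajectory {self.series_id!r}"
            ) from None


def fit_spline(series: ExpressionSeries, bc_type: str = "not-a-knot") -> SplineTrajectory:
    """Interpolate each gene's series with a cubic spline.

    Parameters
    ----------
    series : ExpressionSeries
    bc_type : str
        End condition: ``"not-a-knot"`` (default; third derivative continuous
        across the second and penultimate knots), ``"natural"`` or
        ``"clamped"``.

    Returns
    -------
    SplineTrajectory
        Interpolating spline (reproduces the data at the knots) together with
        its analytic derivative.
    """
    if series.times.size < 4:
        raise ValueError(
            f"series {series.series_id!r}: cubic spline interpolation needs "
            f"at least 4 time points, got {series.times.size}"
        )
    if bc_type not in ("not-a-knot", "natural", "clamped"):
        raise ValueError(f"unsupported end condition {bc_type!r}")
    cs = CubicSpline(series.times, series.values, axis=1, bc_type=bc_type)
    return SplineTrajectory(
        series_id=series.series_id,
        gene_names=series.gene_names,
        knots=series.times.copy(),
        spline=cs,
        derivative=cs.derivative(),
    )


def _check_domain(traj: SplineTrajectory, t: np.ndarray) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t, dtype=float))
    lo, hi = traj.domain
    eps = 1e-12 * max(1.0, abs(hi - lo))
    if np.any(t < lo - eps) or np.any(t > hi + eps):
        raise ValueError(
            f"evaluation points outside spline domain [{lo}, {hi}] for "
            f"trajectory {traj.series_id!r}; extrapolation is not allowed"
        )
    return np.clip(t, lo, hi)


def eval_spline(traj: SplineTrajectory, t) -> np.ndarray:
    """Evaluate the spline at times ``t`` (within the domain); shape (N, |t|)."""
    return traj.spline(_check_domain(traj, t))


def eval_derivative(traj: SplineTrajectory, t) -> np.ndarray:
    """Evaluate the spline's analytic first derivative at ``t``; shape (N, |t|)."""
    return traj.derivative(_check_domain(traj, t))


def presmooth(series: ExpressionSeries, window: int) -> ExpressionSeries:
    """Centered moving-average smoothing with edge replication.

    ``window`` must be odd; ``window=1`` is the identity.  Optional
    pre-processing before spline interpolation; times are unchanged.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if window == 1:
        return series
    half = window // 2
    padded = np.pad(series.values, ((0, 0), (half, half)), mode="edge")
    kernel = np.full(window, 1.0 / window)
    smoothed = np.apply_along_axis(
        lambda row: np.convolve(row, kernel, mode="valid"), 1, padded
    )
    return ExpressionSeries(
        series_id=series.series_id,
        gene_names=series.gene_names,
        times=series.times,
        values=smoothed,
    )


# ---------------------------------------------------------------------------
# I/O: long-format expression tables


def read_expression_tsv(path) -> list[ExpressionSeries]:
    """Read a long-format expression table (columns gene/series/time/value).

    Rows are grouped into one :class:`ExpressionSeries` per ``series`` label;
    gene order follows first appearance in the file.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "series", "time", "value"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    genes = tuple(dict.fromkeys(df["gene"].astype(str)))
    out: list[ExpressionSeries] = []
    for sid, grp in df.groupby("series", sort=False):
        pivot = grp.pivot_table(
            index="gene", columns="time", values="value", sort=False
        )
        pivot = pivot.reindex(index=list(genes)).sort_index(axis=1)
        if pivot.isna().any().any():
            raise ValueError(
                f"{path}: series {sid!r} is not a complete gene x time grid"
            )
        out.append(
            ExpressionSeries(
                series_id=str(sid),
                gene_names=genes,
                times=pivot.columns.to_numpy(dtype=float),
                values=pivot.to_numpy(dtype=float),
            )
        )
    return out


def write_expression_tsv(series_list: list[ExpressionSeries], path) -> None:
    """Write series in the long format read by :func:`read_expression_tsv`."""
    rows = []
    for s in series_list:
        for gi, gene in enumerate(s.gene_names):
            for ti, t in enumerate(s.times):
                rows.append((gene, s.series_id, t, s.values[gi, ti]))
    pd.DataFrame(rows, columns=["gene", "series", "time", "value"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def dump_spline_coefficients(traj: SplineTrajectory, path) -> None:
    """Debug dump: per-gene, per-interval cubic coefficients as TSV.

    Coefficients are in scipy's local convention:
    ``sum_k c[k] * (t - knot_left)**(3-k)``.
    """
    c = traj.coefficients  # (4, n_intervals, N)
    rows = []
    for gi, gene in enumerate(traj.gene_names):
        for j in range(c.shape[1]):
            rows.append(
                (gene, traj.knots[j], traj.knots[j + 1], *c[:, j, gi])
            )
    pd.DataFrame(
        rows, columns=["gene", "t_left", "t_right", "c3", "c2", "c1", "c0"]
    ).to_csv(path, sep="\t", index=False)
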