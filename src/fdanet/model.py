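"""Model/Results interface over the gradient-matching pipeline.

:class:`GeneNetworkModel` is constructed from expression series (or a long
DataFrame / TSV), holds the smoothing and fitting configuration, and its
:meth:`~GeneNetworkModel.fit` returns a :class:`GeneNetworkResults` carrying
the estimated sigmoid network, per-gene errors and diagnostics, with
``summary()``, signed-adjacency extraction, comparison against a gold
standard, simulation and plotting attached.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import enumeration, fitting, smoothing
from .dynamics import NetworkModel
from .evaluation import ComparisonMetrics, SignedAdjacency, compare_networks
from .fitting import FitConfig, FitResult, config_from_preset
from .smoothing import ExpressionSeries, SplineTrajectory

__all__ = ["GeneNetworkModel", "GeneNetworkResults"]


class GeneNetworkModel:
    """Sigmoid gene-network model to be estimated from expression series.

    Parameters
    ----------
    series : list of ExpressionSeries
        Observed trajectories (all sharing one gene list).
    targets : sequence of str, optional
        Genes to model; defaults to all genes.  Genes not modeled act as
        exogenous inputs.
    candidates : dict, optional
        Per-target candidate regulator lists; defaults to every gene
        (minus the target itself unless ``allow_autoregulation``).
    preset : str
        Bounds preset, ``"irma_gnw"`` (default) or ``"drosophila"``.
    allow_autoregulation : bool, optional
        Defaults to the preset's convention.
    presmooth_window : int, optional
        Odd moving-average window applied before spline interpolation.

    Examples
    --------
    >>> mod = GeneNetworkModel(series, preset="irma_gnw")
    >>> res = mod.fit(n_starts=50, seed=1)
    >>> print(res.summary())
    """

    def __init__(
        self,
        series: list[ExpressionSeries],
        targets=None,
        candidates: dict | None = None,
        *,
        preset: str = "irma_gnw",
        allow_autoregulation: bool | None = None,
        sigmoid_kind: str = "logistic",
        presmooth_window: int | None = None,
        bc_type: str = "not-a-knot",
        quadrature_points_per_interval: int = 5,
    ):
        if not series:
            raise ValueError("need at least one expression series")
        if presmooth_window is not None:
            series = [smoothing.presmooth(s, presmooth_window) for s in series]
        self.series = list(series)
        self.gene_names = series[0].gene_names
        self.preset = preset
        base = config_from_preset(
            preset,
            sigmoid_kind=sigmoid_kind,
            quadrature_points_per_interval=quadrature_points_per_interval,
        )
        self._base_config = base
        if allow_autoregulation is None:
            allow_autoregulation = fitting.BOUNDS_PRESETS[preset][
                "allow_autoregulation"
            ]
        self.allow_autoregulation = bool(allow_autoregulation)
        self.targets = tuple(targets) if targets is not None else self.gene_names
        unknown = set(self.targets) - set(self.gene_names)
        if unknown:
            raise ValueError(f"unknown target genes {sorted(unknown)}")
        if candidates is None:
            candidates = {
                t: tuple(
                    g
                    for g in self.gene_names
                    if self.allow_autoregulation or g != t
                )
                for t in self.targets
            }
        self.candidates = {t: tuple(candidates[t]) for t in self.targets}
        for t, cands in self.candidates.items():
            if not self.allow_autoregulation and t in cands:
                raise ValueError(
                    f"candidate list of {t!r} contains the gene itself but "
                    "autoregulation is disallowed"
                )
        self.splines: list[SplineTrajectory] = [
            smoothing.fit_spline(s, bc_type=bc_type) for s in self.series
        ]

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "GeneNetworkModel":
        """Build from a long-format frame with gene/series/time/value columns."""
        import io

        buf = io.StringIO()
        df.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        return cls(smoothing.read_expression_tsv(buf), **kwargs)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "GeneNetworkModel":
        """Build from a long-format expression TSV file."""
        return cls(smoothing.read_expression_tsv(path), **kwargs)

    # -- configuration -----------------------------------------------------

    def _config(self, n_starts: int, seed: int, penalty_c: float) -> FitConfig:
        return replace(
            self._base_config,
            n_starts=n_starts,
            seed=seed,
            penalty_c=penalty_c,
        )

    # -- estimation --------------------------------------------------------

    def fit(
        self,
        n_starts: int = 1000,
        seed: int = 0,
        penalty_c: float = 0.0,
    ) -> "GeneNetworkResults":
        """Multi-start gradient-matching fit of every target gene."""
        config = self._config(n_starts, seed, penalty_c)
        network, results = fitting.fit_network(
            self.targets, self.candidates, self.splines, config
        )
        return GeneNetworkResults(self, network, results, config)

    def fit_regularization_path(
        self,
        c_grid=None,
        n_starts: int = 1000,
        seed: int = 0,
    ) -> fitting.RegularizationPath:
        """Refit along an L1-penalty grid (default 0 to 10 in steps of 0.1)."""
        if c_grid is None:
            c_grid = np.round(np.arange(0.0, 10.0 + 1e-9, 0.1), 10)
        config = self._config(n_starts, seed, 0.0)
        return fitting.regularization_path(
            self.targets,
            self.candidates,
            self.splines,
            config,
            c_grid,
            autoregulation_allowed=self.allow_autoregulation,
        )

    def enumerate_regulators(
        self, n_starts: int = 50, seed: int = 0
    ) -> tuple[dict[str, enumeration.EnumerationResult], int]:
        """Exhaustively fit every regulator subset of every target."""
        config = self._config(n_starts, seed, 0.0)
        return enumeration.enumerate_network(
            self.targets, self.candidates, self.splines, config
        )


class GeneNetworkResults:
    """Estimates, errors and diagnostics from a gradient-matching fit."""

    def __init__(
        self,
        model: GeneNetworkModel,
        network: NetworkModel,
        fit_results: dict[str, FitResult],
        config: FitConfig,
    ):
        self.model = model
        self.network = network
        self.fit_results = fit_results
        self.config = config

    @property
    def params(self) -> NetworkModel:
        return self.network

    @property
    def total_error_E0(self) -> float:
        return float(sum(r.error_E0 for r in self.fit_results.values()))

    @property
    def total_error_E1(self) -> float:
        return float(sum(r.error_E1 for r in self.fit_results.values()))

    def signed_adjacency(self, threshold: float | None = None) -> SignedAdjacency:
        """Threshold fitted weights into -1/0/+1 calls (default 0.006)."""
        thr = (
            self.config.weight_zero_threshold if threshold is None else threshold
        )
        return fitting.threshold_weights(
            self.network, thr, autoregulation_allowed=self.model.allow_autoregulation
        )

    def compare(
        self, gold: SignedAdjacency, threshold: float | None = None
    ) -> ComparisonMetrics:
        """Score the thresholded architecture against a gold standard."""
        return compare_networks(gold, self.signed_adjacency(threshold))

    def simulate(self, x0, times, exogenous=None) -> ExpressionSeries:
        """Integrate the fitted network forward from ``x0``."""
        from .dynamics import simulate as _simulate

        return _simulate(self.network, x0, times, exogenous=exogenous)

    def params_frame(self) -> pd.DataFrame:
        """Per-gene parameter table (one row per target)."""
        rows = []
        for t in self.model.targets:
            r = self.fit_results[t]
            p = r.params
            row = {
                "gene": t,
                "R": p.production_rate,
                "lambda": p.decay_rate,
                "h": p.bias,
                "E0": r.error_E0,
                "E1": r.error_E1,
                "converged_fraction": r.converged_fraction,
            }
            for reg in self.model.gene_names:
                row[f"T[{reg}]"] = p.weights.get(reg, 0.0)
            rows.append(row)
        return pd.DataFrame(rows).set_index("gene")

    def summary(self) -> str:
        """Human-readable fit summary."""
        df = self.params_frame()
        lines = [
            "Gradient-matching network fit",
            "=" * 64,
            f"genes: {len(self.model.gene_names)}  "
            f"targets: {len(self.model.targets)}  "
            f"series: {len(self.model.series)}",
            f"preset: {self.model.preset}  sigmoid: {self.config.sigmoid_kind}  "
            f"autoregulation: {self.model.allow_autoregulation}",
            f"starts per gene: {self.config.n_starts}  seed: {self.config.seed}  "
            f"L1 penalty c: {self.config.penalty_c}",
            f"total E0: {self.total_error_E0:.6g}  "
            f"total E1: {self.total_error_E1:.6g}",
            "-" * 64,
            df.to_string(float_format=lambda v: f"{v:.4g}"),
            "-" * 64,
            f"signed links (|T| >= {self.config.weight_zero_threshold}): "
            f"{self.signed_adjacency().n_edges}",
        ]
        return "\n".join(lines)

    def plot_fit(self, series_index: int = 0, ax=None):
        """Plot one observed series against the fitted model's simulation."""
        import matplotlib.pyplot as plt

        series = self.model.series[series_index]
        sim = self.simulate(
            np.array(
                [series.values[series.gene_index(g), 0] for g in self.network.gene_names]
            ),
            series.times,
        )
        if ax is None:
            _, ax = plt.subplots()
        for g in self.network.modeled_genes:
            ax.plot(
                series.times,
                series.values[series.gene_index(g)],
                "o",
                label=f"{g} observed",
            )
            ax.plot(sim.times, sim.values[sim.gene_index(g)], "-", label=f"{g} fit")
        ax.set_xlabel("time")
        ax.set_ylabel("expression")
        ax.legend(fontsize="small")
        return ax
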