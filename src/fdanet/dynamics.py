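"""Sigmoid production/decay gene-network dynamics.

Each modeled gene g evolves as

    dx_g/dt = R_g * sigma( sum_{g'} T_{gg'} x_{g'} + h_g ) - lambda_g x_g

where sigma is a sigmoid ranging in (0, 1), R_g the maximum production rate,
T_{gg'} the regulatory weight of gene g' on g, h_g a bias and lambda_g the
linear decay rate.  Genes without a parameter entry are exogenous inputs:
observed (or supplied as trajectories) but never integrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.integrate import solve_ivp
from scipy.special import expit

from .smoothing import ExpressionSeries

__all__ = [
    "GeneModelParams",
    "NetworkModel",
    "ParameterBounds",
    "BOUNDS_PRESETS",
    "sigmoid",
    "sigmoid_derivative",
    "dxdt",
    "simulate",
    "simulate_rk4",
    "steady_state_residual",
]


def sigmoid(u, kind: str = "logistic"):
    """Sigmoid regulation function, strictly increasing from 0 to 1.

    ``logistic``: 1/(1+exp(-u)); ``algebraic``: (u/sqrt(u^2+1) + 1)/2.
    """
    u = np.asarray(u, dtype=float)
    if kind == "logistic":
        out = expit(u)
    elif kind == "algebraic":
        out = 0.5 * (u / np.sqrt(u * u + 1.0) + 1.0)
    else:
        raise ValueError(f"unknown sigmoid kind {kind!r}")
    # saturate numerically *inside* the open interval (0, 1)
    out = np.clip(out, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
    return out if out.ndim else float(out)


def sigmoid_derivative(u, kind: str = "logistic"):
    """d sigma / du for the chosen sigmoid."""
    u = np.asarray(u, dtype=float)
    if kind == "logistic":
        s = expit(u)
        out = s * (1.0 - s)
    elif kind == "algebraic":
        out = 0.5 * (u * u + 1.0) ** -1.5
    else:
        raise ValueError(f"unknown sigmoid kind {kind!r}")
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GeneModelParams:
    """Dynamics parameters for one target gene.

    ``weights`` maps regulator label -> regulatory weight; a missing key is a
    structural zero (the regulator does not enter the input sum at all).
    """

    target_gene: str
    production_rate: float  # R_g >= 0, expression units / time
    weights: dict[str, float]
    bias: float  # h_g, dimensionless
    decay_rate: float  # lambda_g >= 0, 1 / time

    def __post_init__(self) -> None:
        if self.production_rate < 0:
            raise ValueError(f"{self.target_gene}: production_rate must be >= 0")
        if self.decay_rate < 0:
            raise ValueError(f"{self.target_gene}: decay_rate must be >= 0")
        object.__setattr__(self, "weights", dict(self.weights))


@dataclass(frozen=True)
class NetworkModel:
    """A sigmoid gene-network model over an ordered gene list.

    ``genes`` holds one :class:`GeneModelParams` per *modeled* target; genes
    absent from it are exogenous inputs.
    """

    gene_names: tuple[str, ...]
    genes: dict[str, GeneModelParams]
    sigmoid_kind: str = "logistic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        names = set(self.gene_names)
        for target, p in self.genes.items():
            if target not in names:
                raise ValueError(f"modeled gene {target!r} not in gene_names")
            unknown = set(p.weights) - names
            if unknown:
                raise ValueError(
                    f"{target!r}: weights reference unknown genes {sorted(unknown)}"
                )

    @property
    def modeled_genes(self) -> tuple[str, ...]:
        return tuple(g for g in self.gene_names if g in self.genes)

    @property
    def exogenous_genes(self) -> tuple[str, ...]:
        return tuple(g for g in self.gene_names if g not in self.genes)

    def weight_matrix(self) -> np.ndarray:
        """Dense (regulator x target) weight matrix; structural zeros as 0."""
        n = len(self.gene_names)
        W = np.zeros((n, n))
        idx = {g: i for i, g in enumerate(self.gene_names)}
        for target, p in self.genes.items():
            for reg, w in p.weights.items():
                W[idx[reg], idx[target]] = w
        return W

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "genes": list(self.gene_names),
            "sigmoid_kind": self.sigmoid_kind,
            "models": {
                t: {
                    "R": float(p.production_rate),
                    "lambda": float(p.decay_rate),
                    "h": float(p.bias),
                    "weights": {k: float(v) for k, v in sorted(p.weights.items())},
                }
                for t, p in sorted(self.genes.items())
            },
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkModel":
        genes = {
            t: GeneModelParams(
                target_gene=t,
                production_rate=m["R"],
                weights=dict(m.get("weights", {})),
                bias=m["h"],
                decay_rate=m["lambda"],
            )
            for t, m in d.get("models", {}).items()
        }
        return cls(
            gene_names=tuple(d["genes"]),
            genes=genes,
            sigmoid_kind=d.get("sigmoid_kind", "logistic"),
        )

    @classmethod
    def from_yaml(cls, path) -> "NetworkModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def dxdt(model: NetworkModel, state) -> np.ndarray:
    """Time derivatives of the modeled genes at the given full state vector.

    ``state`` holds one value per gene in ``model.gene_names``; the returned
    vector is ordered like ``model.modeled_genes``.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (len(model.gene_names),):
        raise ValueError(
            f"state length {state.shape} does not match "
            f"{len(model.gene_names)} genes"
        )
    idx = {g: i for i, g in enumerate(model.gene_names)}
    out = np.empty(len(model.modeled_genes))
    for k, target in enumerate(model.modeled_genes):
        p = model.genes[target]
        u = p.bias + sum(w * state[idx[reg]] for reg, w in p.weights.items())
        out[k] = (
            p.production_rate * sigmoid(u, model.sigmoid_kind)
            - p.decay_rate * state[idx[target]]
        )
    return out


def steady_state_residual(model: NetworkModel, state) -> float:
    """Infinity norm of dx/dt at ``state`` (0 at a steady state)."""
    return float(np.max(np.abs(dxdt(model, state)))) if model.genes else 0.0


def _full_state(model, modeled_state, t, exogenous, x0, idx_mod, idx_exo):
    x = np.empty(len(model.gene_names))
    x[idx_mod] = modeled_state
    for j, g in zip(idx_exo, model.exogenous_genes):
        if exogenous is not None and g in exogenous:
            x[j] = exogenous[g](t)
        else:
            x[j] = x0[j]
    return x


def simulate(
    model: NetworkModel,
    x0,
    times,
    exogenous: dict | None = None,
    series_id: str = "sim",
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> ExpressionSeries:
    """Integrate the network ODE and sample it on ``times``.

    Uses an adaptive explicit Runge-Kutta pair (RK45).  ``x0`` holds the
    initial value of every gene; exogenous genes follow the callables in
    ``exogenous`` exactly (held constant at their ``x0`` value if absent).

    Returns an :class:`ExpressionSeries` over all genes.
    """
    x0 = np.asarray(x0, dtype=float)
    times = np.asarray(times, dtype=float)
    if x0.shape != (len(model.gene_names),):
        raise ValueError("x0 must have one value per gene")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    idx_mod = np.array(
        [model.gene_names.index(g) for g in model.modeled_genes], dtype=int
    )
    idx_exo = np.array(
        [model.gene_names.index(g) for g in model.exogenous_genes], dtype=int
    )

    def rhs(t, y):
        x = _full_state(model, y, t, exogenous, x0, idx_mod, idx_exo)
        return dxdt(model, x)

    if len(idx_mod) == 0:
        modeled = np.zeros((0, times.size))
    else:
        sol = solve_ivp(
            rhs,
            (times[0], times[-1]),
            x0[idx_mod],
            t_eval=times,
            method="RK45",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise RuntimeError(f"ODE solver failed near t={sol.t[-1]:g}: {sol.message}")
        modeled = sol.y

    values = np.empty((len(model.gene_names), times.size))
    values[idx_mod] = modeled
    for j, g in zip(idx_exo, model.exogenous_genes):
        if exogenous is not None and g in exogenous:
            values[j] = [exogenous[g](t) for t in times]
        else:
            values[j] = x0[j]
    return ExpressionSeries(
        series_id=series_id,
        gene_names=model.gene_names,
        times=times,
        values=values,
    )


def simulate_rk4(
    model: NetworkModel,
    x0,
    times,
    step: float,
    exogenous: dict | None = None,
    series_id: str = "sim-rk4",
) -> ExpressionSeries:
    """Fixed-step classic RK4 integration sampled at ``times``.

    Provided for order-of-convergence checks; `simulate` is the default
    integrator.
    """
    x0 = np.asarray(x0, dtype=float)
    times = np.asarray(times, dtype=float)
    idx_mod = np.array(
        [model.gene_names.index(g) for g in model.modeled_genes], dtype=int
    )
    idx_exo = np.array(
        [model.gene_names.index(g) for g in model.exogenous_genes], dtype=int
    )

    def rhs(t, y):
        x = _full_state(model, y, t, exogenous, x0, idx_mod, idx_exo)
        return dxdt(model, x)

    out = np.empty((len(idx_mod), times.size))
    y = x0[idx_mod].copy()
    t = times[0]
    out[:, 0] = y
    for j in range(1, times.size):
        t_target = times[j]
        while t < t_target - 1e-12:
            h = min(step, t_target - t)
            k1 = rhs(t, y)
            k2 = rhs(t + h / 2, y + h / 2 * k1)
            k3 = rhs(t + h / 2, y + h / 2 * k2)
            k4 = rhs(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        if not np.all(np.isfinite(y)):
            raise RuntimeError(f"RK4 state non-finite at t={t:g}")
        out[:, j] = y
        t = t_target

    values = np.empty((len(model.gene_names), times.size))
    values[idx_mod] = out
    for j, g in zip(idx_exo, model.exogenous_genes):
        if exogenous is not None and g in exogenous:
            values[j] = [exogenous[g](t) for t in times]
        else:
            values[j] = x0[j]
    return ExpressionSeries(
        series_id=series_id,
        gene_names=model.gene_names,
        times=times,
        values=values,
    )


@dataclass(frozen=True)
class ParameterBounds:
    """Box constraints for one gene's parameters during fitting."""

    weight_range: tuple[float, float] = (-0.2, 0.2)
    production_range: tuple[float, float] = (0.0, 25.0)
    decay_range: tuple[float, float] = (0.0, 10.0)
    bias_range: tuple[float, float] = (-25.0, 25.0)

    def __post_init__(self) -> None:
        for name in ("weight_range", "production_range", "decay_range", "bias_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lo {lo} > hi {hi}")


# Presets follow the two fitting regimes: the gap-gene-style regime works on
# the native 0-255 scale with the bias fixed at -3.5; the IRMA/GeneNetWeaver
# regime works on data rescaled to [0, 100] with a free bias.
BOUNDS_PRESETS: dict[str, dict] = {
    "drosophila": {
        "bounds": ParameterBounds(
            weight_range=(-0.1, 0.1),
            production_range=(0.0, 25.0),
            decay_range=(0.0, 10.0),
            bias_range=(-3.5, -3.5),
        ),
        "bias_fixed": -3.5,
        "allow_autoregulation": True,
    },
    "irma_gnw": {
        "bounds": ParameterBounds(
            weight_range=(-0.2, 0.2),
            production_range=(0.0, 25.0),
            decay_range=(0.0, 10.0),
            bias_range=(-25.0, 25.0),
        ),
        "bias_fixed": None,
        "allow_autoregulation": False,
    },
}
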