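"""Exhaustive regulator-subset enumeration.

Because the gradient-matching fit decomposes per gene and each evaluation is
cheap, every one of the 2^K regulator subsets of a gene's K candidates can
be fitted and ranked outright (e.g. 7 candidates -> 128 fits per gene, four
modeled genes -> 512 fits).  The best-per-size ranking shows which
regulators, and which combinations, matter for explaining a gene's observed
derivatives — and whether near-equivalent alternative explanations exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import GeneModelParams, NetworkModel
from .evaluation import SignedAdjacency
from .fitting import FitConfig, FitResult, _Design, fit_gene, threshold_weights
from .smoothing import SplineTrajectory

__all__ = [
    "EnumerationEntry",
    "EnumerationResult",
    "all_subsets",
    "total_fit_count",
    "enumerate_gene",
    "enumerate_network",
    "best_k_architecture",
    "export_lattice",
]


def all_subsets(candidates) -> list[tuple[str, ...]]:
    """All 2^K subsets of the candidate list, in bitmask order.

    Bit i of the mask selects ``candidates[i]``; the empty set is mask 0.
    """
    candidates = tuple(candidates)
    k = len(candidates)
    return [
        tuple(candidates[i] for i in range(k) if mask >> i & 1)
        for mask in range(2**k)
    ]


def total_fit_count(targets, candidates: dict) -> int:
    """Number of fits an exhaustive enumeration performs: sum of 2^K_target."""
    return sum(2 ** len(candidates[t]) for t in targets)


@dataclass(frozen=True)
class EnumerationEntry:
    subset: tuple[str, ...]
    bitmask: int
    error_E0: float
    params: GeneModelParams
    fit: FitResult

    @property
    def size(self) -> int:
        return len(self.subset)


@dataclass(frozen=True)
class BestPerSize:
    size: int
    subset: tuple[str, ...]
    error_E0: float
    added_regulator: str | None
    """Regulator whose addition turns the best (k-1)-subset into this one;
    None when the best size-k subset does not nest the best size-(k-1)."""


@dataclass(frozen=True)
class EnumerationResult:
    target_gene: str
    candidate_regulators: tuple[str, ...]
    entries: list[EnumerationEntry]
    best_per_size: list[BestPerSize]

    @property
    def n_fits(self) -> int:
        return len(self.entries)

    def best(self) -> EnumerationEntry:
        """Global minimum-error entry (ties broken by smaller bitmask)."""
        return min(self.entries, key=lambda e: (e.error_E0, e.bitmask))


def enumerate_gene(
    target: str,
    candidates,
    splines: list[SplineTrajectory],
    config: FitConfig,
    _design: _Design | None = None,
) -> EnumerationResult:
    """Fit every subset of ``candidates`` as the regulator set of ``target``.

    Entries are sorted by (size, error, bitmask); ``best_per_size`` records
    the minimum-error subset of each size k = 0..K and, when that subset
    extends the best (k-1)-subset, the regulator whose addition achieved it.
    """
    candidates = tuple(candidates)
    design = _design if _design is not None else _Design(splines, config)
    entries = []
    for mask, subset in enumerate(all_subsets(candidates)):
        fit = fit_gene(target, subset, splines, config, _design=design)
        entries.append(
            EnumerationEntry(
                subset=subset,
                bitmask=mask,
                error_E0=fit.error_E0,
                params=fit.params,
                fit=fit,
            )
        )
    entries.sort(key=lambda e: (e.size, e.error_E0, e.bitmask))

    best_per_size = []
    prev_subset: tuple[str, ...] = ()
    for k in range(len(candidates) + 1):
        of_size = [e for e in entries if e.size == k]
        best = min(of_size, key=lambda e: (e.error_E0, e.bitmask))
        added = None
        if k > 0 and set(prev_subset) <= set(best.subset):
            extra = set(best.subset) - set(prev_subset)
            if len(extra) == 1:
                added = extra.pop()
        best_per_size.append(
            BestPerSize(
                size=k,
                subset=best.subset,
                error_E0=best.error_E0,
                added_regulator=added,
            )
        )
        prev_subset = best.subset
    return EnumerationResult(
        target_gene=target,
        candidate_regulators=candidates,
        entries=entries,
        best_per_size=best_per_size,
    )


def enumerate_network(
    targets,
    candidates: dict,
    splines: list[SplineTrajectory],
    config: FitConfig,
) -> tuple[dict[str, EnumerationResult], int]:
    """Independent exhaustive enumeration per target.

    Returns the per-target results and the total number of fits performed
    (= sum over targets of 2^K_target).
    """
    design = _Design(splines, config)
    results = {
        t: enumerate_gene(t, candidates[t], splines, config, _design=design)
        for t in targets
    }
    n_fits = sum(r.n_fits for r in results.values())
    assert n_fits == total_fit_count(targets, candidates)
    return results, n_fits


def best_k_architecture(
    results: dict[str, EnumerationResult],
    k: int,
    config: FitConfig,
    gene_names=None,
    autoregulation_allowed: bool = True,
) -> tuple[NetworkModel, SignedAdjacency]:
    """Assemble the network from each gene's best size-k regulator subset.

    ``k`` must not exceed any gene's candidate count.  The fitted weights of
    the winning subsets are thresholded into signed calls.
    """
    max_k = min(len(r.candidate_regulators) for r in results.values())
    if not 0 <= k <= max_k:
        raise ValueError(f"k={k} out of range [0, {max_k}]")
    genes = {}
    for target, res in results.items():
        best = res.best_per_size[k]
        entry = next(
            e
            for e in res.entries
            if e.subset == best.subset and e.size == k
        )
        genes[target] = entry.params
    if gene_names is None:
        seen = dict.fromkeys(results)
        for res in results.values():
            seen.update(dict.fromkeys(res.candidate_regulators))
        gene_names = tuple(seen)
    model = NetworkModel(
        gene_names=tuple(gene_names),
        genes=genes,
        sigmoid_kind=config.sigmoid_kind,
    )
    adjacency = threshold_weights(
        model, config.weight_zero_threshold, autoregulation_allowed
    )
    return model, adjacency


def export_lattice(result: EnumerationResult) -> pd.DataFrame:
    """Ranking table of all subsets for one gene (2^K rows).

    Columns: subset members, size, E0, rank within size, overall rank, and an
    inverse-error score for plotting subset lattices (larger = better fit).
    """
    entries = sorted(result.entries, key=lambda e: (e.error_E0, e.bitmask))
    overall_rank = {e.bitmask: i + 1 for i, e in enumerate(entries)}
    rank_in_size: dict[int, int] = {}
    for k in range(len(result.candidate_regulators) + 1):
        of_size = sorted(
            (e for e in result.entries if e.size == k),
            key=lambda e: (e.error_E0, e.bitmask),
        )
        for i, e in enumerate(of_size):
            rank_in_size[e.bitmask] = i + 1
    tiny = 1e-300
    rows = [
        {
            "subset": "+".join(e.subset) if e.subset else "(none)",
            "size": e.size,
            "error_E0": e.error_E0,
            "rank_in_size": rank_in_size[e.bitmask],
            "overall_rank": overall_rank[e.bitmask],
            "inverse_error_score": 1.0 / (e.error_E0 + tiny),
        }
        for e in result.entries
    ]
    return pd.DataFrame(rows)
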