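"""Signed-network comparison metrics.

An estimated regulatory architecture is a matrix of -1/0/+1 calls over
directed (regulator, target) pairs.  Against a gold standard we report:

* CF  — fraction of pairs whose -/0/+ call matches;
* TP/TN/FP/FN — sign-blind presence/absence counts (TP = nonzero in both);
* PPV = TP/(TP+FP), Sens = TP/(TP+FN);
* CSF — among pairs nonzero in both networks, the fraction with equal sign.

Fractions with an empty denominator are ``None`` (undefined), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SignedAdjacency",
    "ComparisonMetrics",
    "compare_networks",
    "random_baseline_cf",
    "read_edge_list_tsv",
    "write_edge_list_tsv",
]


@dataclass(frozen=True)
class SignedAdjacency:
    """Signed regulator -> target call matrix with entries in {-1, 0, +1}.

    When ``autoregulation_allowed`` is False, diagonal pairs (regulator ==
    target) must be zero and are excluded from every metric denominator.
    """

    regulators: tuple[str, ...]
    targets: tuple[str, ...]
    signs: np.ndarray  # shape (|regulators|, |targets|)
    autoregulation_allowed: bool = True

    def __post_init__(self) -> None:
        signs = np.asarray(self.signs, dtype=int)
        if signs.shape != (len(self.regulators), len(self.targets)):
            raise ValueError(
                f"signs shape {signs.shape} does not match "
                f"{len(self.regulators)} regulators x {len(self.targets)} targets"
            )
        if not np.isin(signs, (-1, 0, 1)).all():
            raise ValueError("signs must be -1, 0 or +1")
        if not self.autoregulation_allowed:
            for i, r in enumerate(self.regulators):
                for j, t in enumerate(self.targets):
                    if r == t and signs[i, j] != 0:
                        raise ValueError(
                            f"autoregulation disallowed but {r!r}->{t!r} is nonzero"
                        )
        object.__setattr__(self, "signs", signs)
        object.__setattr__(self, "regulators", tuple(self.regulators))
        object.__setattr__(self, "targets", tuple(self.targets))

    def considered_mask(self) -> np.ndarray:
        """Boolean mask of (regulator, target) pairs entering the metrics."""
        mask = np.ones(self.signs.shape, dtype=bool)
        if not self.autoregulation_allowed:
            for i, r in enumerate(self.regulators):
                for j, t in enumerate(self.targets):
                    if r == t:
                        mask[i, j] = False
        return mask

    @property
    def n_edges(self) -> int:
        """Number of nonzero calls."""
        return int(np.count_nonzero(self.signs))

    def sign_of(self, regulator: str, target: str) -> int:
        return int(
            self.signs[self.regulators.index(regulator), self.targets.index(target)]
        )

    def relabeled(self, mapping: dict[str, str]) -> "SignedAdjacency":
        return SignedAdjacency(
            regulators=tuple(mapping.get(r, r) for r in self.regulators),
            targets=tuple(mapping.get(t, t) for t in self.targets),
            signs=self.signs.copy(),
            autoregulation_allowed=self.autoregulation_allowed,
        )


@dataclass(frozen=True)
class ComparisonMetrics:
    n_links_considered: int
    correct: int
    correct_fraction: float
    true_positives: int
    true_negatives: int
    false_positives: int
    false_negatives: int
    ppv: float | None
    sensitivity: float | None
    csf: float | None

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "n": self.n_links_considered,
                "Corr": self.correct,
                "CF": self.correct_fraction,
                "TP": self.true_positives,
                "TN": self.true_negatives,
                "FP": self.false_positives,
                "FN": self.false_negatives,
                "PPV": self.ppv,
                "Sens": self.sensitivity,
                "CSF": self.csf,
            }
        )

    def __str__(self) -> str:
        def fmt(x):
            return "undefined" if x is None else f"{x:.4f}"

        return (
            f"links considered: {self.n_links_considered}\n"
            f"Corr: {self.correct}  CF: {self.correct_fraction:.4f}\n"
            f"TP: {self.true_positives}  TN: {self.true_negatives}  "
            f"FP: {self.false_positives}  FN: {self.false_negatives}\n"
            f"PPV: {fmt(self.ppv)}  Sens: {fmt(self.sensitivity)}  "
            f"CSF: {fmt(self.csf)}"
        )


def compare_networks(
    gold: SignedAdjacency, estimate: SignedAdjacency
) -> ComparisonMetrics:
    """Score an estimated signed adjacency against a gold standard.

    Both adjacencies must share regulator/target label order and the
    autoregulation flag; only considered pairs (off-diagonal when
    autoregulation is disallowed) enter the counts.
    """
    if gold.regulators != estimate.regulators or gold.targets != estimate.targets:
        raise ValueError(
            "label mismatch between gold and estimate: "
            f"regulators {set(gold.regulators) ^ set(estimate.regulators) or '(order)'}"
            f", targets {set(gold.targets) ^ set(estimate.targets) or '(order)'}"
        )
    if gold.autoregulation_allowed != estimate.autoregulation_allowed:
        raise ValueError("autoregulation flags differ between gold and estimate")

    mask = gold.considered_mask()
    g = gold.signs[mask]
    e = estimate.signs[mask]
    n = int(mask.sum())

    correct = int(np.count_nonzero(g == e))
    tp = int(np.count_nonzero((g != 0) & (e != 0)))
    tn = int(np.count_nonzero((g == 0) & (e == 0)))
    fp = int(np.count_nonzero((g == 0) & (e != 0)))
    fn = int(np.count_nonzero((g != 0) & (e == 0)))
    same_sign_tp = int(np.count_nonzero((g != 0) & (e != 0) & (g == e)))

    return ComparisonMetrics(
        n_links_considered=n,
        correct=correct,
        correct_fraction=correct / n if n else float("nan"),
        true_positives=tp,
        true_negatives=tn,
        false_positives=fp,
        false_negatives=fn,
        ppv=tp / (tp + fp) if (tp + fp) else None,
        sensitivity=tp / (tp + fn) if (tp + fn) else None,
        csf=same_sign_tp / tp if tp else None,
    )


def random_baseline_cf(n_links: int) -> float:
    """Expected CF of a uniformly random -/0/+ estimate: 1/3 for any size."""
    if n_links < 1:
        raise ValueError("n_links must be >= 1")
    return 1.0 / 3.0


# ---------------------------------------------------------------------------
# Edge-list I/O


def read_edge_list_tsv(
    path,
    regulators: tuple[str, ...] | None = None,
    targets: tuple[str, ...] | None = None,
    autoregulation_allowed: bool = True,
) -> SignedAdjacency:
    """Read a signed edge list (columns regulator/target/sign).

    Pairs absent from the file default to 0.  Label order defaults to first
    appearance in the file (regulators and targets each over all mentioned
    genes) unless given explicitly.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"regulator", "target", "sign"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    df["regulator"] = df["regulator"].astype(str)
    df["target"] = df["target"].astype(str)
    if regulators is None:
        regulators = tuple(
            dict.fromkeys([*df["regulator"], *df["target"]])
        )
    if targets is None:
        targets = regulators
    signs = np.zeros((len(regulators), len(targets)), dtype=int)
    for _, row in df.iterrows():
        if row["regulator"] in regulators and row["target"] in targets:
            signs[regulators.index(row["regulator"]), targets.index(row["target"])] = int(
                np.sign(row["sign"])
            )
    return SignedAdjacency(
        regulators=regulators,
        targets=targets,
        signs=signs,
        autoregulation_allowed=autoregulation_allowed,
    )


def write_edge_list_tsv(
    adj: SignedAdjacency, path, weights: np.ndarray | None = None
) -> None:
    """Write nonzero calls as a TSV edge list (optionally with weights)."""
    rows = []
    for i, r in enumerate(adj.regulators):
        for j, t in enumerate(adj.targets):
            if adj.signs[i, j] != 0:
                row = [r, t, int(adj.signs[i, j])]
                if weights is not None:
                    row.append(weights[i, j])
                rows.append(row)
    cols = ["regulator", "target", "sign"] + (
        ["weight"] if weights is not None else []
    )
    pd.DataFrame(rows, columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def metrics_to_tsv(metrics: ComparisonMetrics, path) -> None:
    """Serialize metrics as a one-row TSV; undefined fractions become empty."""
    metrics.to_series().to_frame().T.to_csv(
        path, sep="\t", index=False, float_format="%.6g", na_rep=""
    )
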