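"""Cohort-level statistics: hierarchical group comparison and pairwise
measure-redundancy analysis.

Recordings are hierarchical — several neurons per animal — so neurons are
not exchangeable units.  Group differences are therefore tested with
permutation tests that move whole animals between groups, respecting the
random-effect structure without fitting a multilevel model.  Redundancy
between measures is probed by fitting each pair both on the raw (linear)
scale and on a log-log scale (power law); a significantly better log-log
fit marks the relation as nonlinear.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import InvalidParameterError

__all__ = [
    "PairwiseFit",
    "GroupComparison",
    "pairwise_fit",
    "group_compare",
    "redundancy_matrix",
    "redundancy_table",
    "LOG_TRANSFORMS",
    "MEASURE_COLUMNS",
]

MEASURE_COLUMNS = ("fr_hz", "cv", "apd_ms", "op_entropy", "bins_entropy", "plzc")

#: Per-measure transform applied before the log-log fit.  Entropies of
#: near-random trains crowd against 1, so OP Entropy enters power laws as
#: its distance from the random ceiling, 1 - H; everything else is log(x).
LOG_TRANSFORMS = {
    "op_entropy": lambda x: 1.0 - x,
}


@dataclass(frozen=True)
class FitResult:
    """One least-squares fit on one scale."""

    scale: str
    coefficient: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class PairwiseFit:
    """Linear-vs-power-law comparison for one measure pair.

    ``best`` is whichever scale gives the larger |Pearson r|; on the
    ``loglog`` scale the coefficient is the power-law exponent.
    """

    x_name: str
    y_name: str
    linear: FitResult
    loglog: FitResult | None
    n_dropped: int = 0

    @property
    def best(self) -> FitResult:
        if self.loglog is not None and abs(self.loglog.pearson_r) > abs(self.linear.pearson_r):
            return self.loglog
        return self.linear

    @property
    def scale(self) -> str:
        return self.best.scale

    @property
    def coefficient(self) -> float:
        return self.best.coefficient

    @property
    def pearson_r(self) -> float:
        return self.best.pearson_r

    @property
    def p_value(self) -> float:
        return self.best.p_value


@dataclass(frozen=True)
class GroupComparison:
    """Permutation test for a group difference of one measure."""

    measure_name: str
    group_names: tuple[str, str]
    group_means: tuple[float, float]
    statistic: float
    p_value: float
    n_permutations: int
    permute_unit: str = "animal"
    null_statistics: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def _transform(name: str, x: np.ndarray) -> np.ndarray:
    fn = LOG_TRANSFORMS.get(name)
    return fn(x) if fn is not None else x


def pairwise_fit(
    x, y, x_name: str = "x", y_name: str = "y", min_pairs: int = 10
) -> PairwiseFit:
    """Fit y against x on linear and log-log scales; keep both, flag the best.

    The log-log fit regresses log(ty) on log(tx) after the per-measure
    transform map (so its slope is the power-law exponent); pairs whose
    transformed values are non-positive cannot enter the log fit and are
    dropped with a logged count.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < min_pairs:
        raise InvalidParameterError(f"need >= {min_pairs} paired finite values")
    lin = sps.linregress(x, y)
    linear = FitResult(
        scale="linear",
        coefficient=float(lin.slope),
        intercept=float(lin.intercept),
        pearson_r=float(lin.rvalue),
        p_value=float(lin.pvalue),
        n=int(x.size),
    )
    tx, ty = _transform(x_name, x), _transform(y_name, y)
    pos = (tx > 0) & (ty > 0)
    n_dropped = int(np.sum(~pos))
    loglog: FitResult | None = None
    if int(pos.sum()) >= min_pairs and np.unique(tx[pos]).size > 1:
        if n_dropped:
            warnings.warn(
                f"{x_name} vs {y_name}: dropped {n_dropped} non-positive pairs "
                "from the log-log fit",
                stacklevel=2,
            )
        ll = sps.linregress(np.log(tx[pos]), np.log(ty[pos]))
        loglog = FitResult(
            scale="loglog",
            coefficient=float(ll.slope),
            intercept=float(ll.intercept),
            pearson_r=float(ll.rvalue),
            p_value=float(ll.pvalue),
            n=int(pos.sum()),
        )
    return PairwiseFit(x_name=x_name, y_name=y_name, linear=linear, loglog=loglog, n_dropped=n_dropped)


def group_compare(
    values,
    group_labels,
    animal_ids,
    n_perm: int = 10_000,
    seed: int | None = None,
    permute_unit: str = "animal",
    measure_name: str = "",
) -> GroupComparison:
    """Two-group permutation test on per-neuron values.

    The statistic is the difference of group means (group order = sorted
    label order; its sign equals sign(mean1 - mean2)).  Under
    ``permute_unit="animal"`` the null is built by permuting group labels
    across whole animals — all neurons of an animal move together — which
    requires every animal to lie in a single group and every group to span
    at least 2 animals.  For contrasts defined within animals (e.g.
    rhythmic vs non-rhythmic neurons of the same rat) the hierarchical
    permutation is undefined; ``permute_unit="neuron"`` falls back to
    exchanging neuron labels.  p is the two-sided rank p-value
    ``(1 + #{|T*| >= |T|}) / (n_perm + 1)`` and can never be 0.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    animal_ids = np.asarray(animal_ids)
    if not (values.size == group_labels.size == animal_ids.size):
        raise InvalidParameterError("values, group_labels and animal_ids must align")
    ok = np.isfinite(values)
    values, group_labels, animal_ids = values[ok], group_labels[ok], animal_ids[ok]
    names = sorted(set(group_labels.tolist()))
    if len(names) != 2:
        raise InvalidParameterError(f"need exactly 2 groups, got {names}")
    g1 = group_labels == names[0]
    mean1, mean2 = float(values[g1].mean()), float(values[~g1].mean())
    observed = mean1 - mean2
    rng = np.random.default_rng(seed)

    if permute_unit == "animal":
        animals = pd.unique(animal_ids)
        animal_group = {}
        for a in animals:
            labs = set(group_labels[animal_ids == a].tolist())
            if len(labs) > 1:
                raise InvalidParameterError(
                    f"animal {a!r} has neurons in both groups; animal-level "
                    "permutation is undefined — use permute_unit='neuron'"
                )
            animal_group[a] = labs.pop()
        per_group_animals = {
            name: [a for a in animals if animal_group[a] == name] for name in names
        }
        for name, members in per_group_animals.items():
            if len(members) < 2:
                raise InvalidParameterError(
                    f"group {name!r} has {len(members)} animal(s); need >= 2 for "
                    "a hierarchical permutation test"
                )
        animal_list = list(animals)
        labels_vec = np.array([animal_group[a] for a in animal_list])
        blocks = [values[animal_ids == a] for a in animal_list]
        sizes = np.array([b.size for b in blocks])
        sums = np.array([b.sum() for b in blocks])
        null = np.empty(n_perm)
        for k in range(n_perm):
            perm = rng.permutation(labels_vec)
            in1 = perm == names[0]
            null[k] = sums[in1].sum() / sizes[in1].sum() - sums[~in1].sum() / sizes[~in1].sum()
    elif permute_unit == "neuron":
        null = np.empty(n_perm)
        n1 = int(g1.sum())
        for k in range(n_perm):
            perm = rng.permutation(values)
            null[k] = perm[:n1].mean() - perm[n1:].mean()
    else:
        raise InvalidParameterError("permute_unit must be 'animal' or 'neuron'")

    # relative tie tolerance keeps the rank p invariant under rescaling
    threshold = abs(observed) * (1.0 - 1e-12)
    p = (1 + int(np.sum(np.abs(null) >= threshold))) / (n_perm + 1)
    return GroupComparison(
        measure_name=measure_name,
        group_names=(names[0], names[1]),
        group_means=(mean1, mean2),
        statistic=float(observed),
        p_value=float(p),
        n_permutations=n_perm,
        permute_unit=permute_unit,
        null_statistics=null,
    )


def redundancy_matrix(measures: pd.DataFrame, columns=MEASURE_COLUMNS) -> list[PairwiseFit]:
    """All C(6,2) = 15 pairwise fits over the per-neuron measure table."""
    missing = [c for c in columns if c not in measures.columns]
    if missing:
        raise InvalidParameterError(f"measure table missing columns: {missing}")
    fits = []
    for a, b in itertools.combinations(columns, 2):
        fits.append(pairwise_fit(measures[a], measures[b], x_name=a, y_name=b))
    return fits


def redundancy_table(fits: list[PairwiseFit]) -> pd.DataFrame:
    """Tidy table of the pairwise fits, with a Holm-corrected p column.

    The Holm column is an extension beyond the raw per-pair p-values and is
    labeled as such.
    """
    rows = []
    for f in fits:
        rows.append(
            dict(
                x=f.x_name,
                y=f.y_name,
                best_scale=f.scale,
                coefficient=f.coefficient,
                pearson_r=f.pearson_r,
                p_value=f.p_value,
                linear_r=f.linear.pearson_r,
                linear_p=f.linear.p_value,
                loglog_r=f.loglog.pearson_r if f.loglog else np.nan,
                loglog_p=f.loglog.p_value if f.loglog else np.nan,
                n_dropped_log=f.n_dropped,
            )
        )
    df = pd.DataFrame(rows)
    # Holm step-down correction (extension; raw p_value is the primary column).
    p = df["p_value"].to_numpy()
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    df["p_holm_extension"] = adj
    return df
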