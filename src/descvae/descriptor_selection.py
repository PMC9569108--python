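"""Filter-based descriptor selection and correlation-matched noisy descriptors.

The selection pipeline is the classical filter method: remove
low-variance descriptors (sample variance <= 0.5 by default), rank the
rest by absolute Pearson correlation with the task label, greedily
prune descriptors whose pairwise |r| with an already-kept, more
task-correlated descriptor exceeds 0.9, and keep the top three
survivors.

``make_noisy_descriptor`` builds synthetic descriptors whose
correlation with the label is attenuated to a chosen value by adding
Gaussian noise: for noise sd s, corr(d + eps, y) = r_d * sd(d) /
sqrt(sd(d)^2 + s^2), which inverts to s = sd(d) * sqrt((r_d/r_t)^2 - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .chem_data import DescriptorTable

__all__ = [
    "CorrelationRanking",
    "SelectionResult",
    "variance_filter",
    "rank_by_target_correlation",
    "prune_intercorrelated",
    "select_top_k",
    "select_descriptors",
    "make_noisy_descriptor",
]


@dataclass
class CorrelationRanking:
    """Descriptors ordered by decreasing |Pearson r| with the target."""

    entries: list[tuple[str, float]]
    target_name: str = "y"
    excluded_constant: list[str] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    def r_of(self, name: str) -> float:
        for n, r in self.entries:
            if n == name:
                return r
        raise KeyError(name)


@dataclass
class SelectionResult:
    selected: list[str]
    ranking: CorrelationRanking
    removed_low_variance: list[str] = field(default_factory=list)
    removed_intercorrelated: list[tuple[str, str, float]] = field(default_factory=list)


def variance_filter(table: DescriptorTable, threshold: float = 0.5
                    ) -> tuple[DescriptorTable, list[str]]:
    """Retain columns whose sample variance exceeds ``threshold``.

    The comparison is strict: a column at exactly the threshold is
    removed.  Returns (filtered table, removed names).
    """
    if table.n_molecules == 0 or not table.names:
        raise ValueError("descriptor table is empty")
    variances = table.data.var(ddof=1)
    kept = [n for n in table.names if variances[n] > threshold]
    removed = [n for n in table.names if n not in kept]
    return table.subset(kept) if kept else DescriptorTable(
        data=table.data[[]].copy(), source={}, dropped_rows=list(table.dropped_rows)
    ), removed


def rank_by_target_correlation(table: DescriptorTable, y: np.ndarray,
                               mask: np.ndarray | None = None,
                               target_name: str = "y") -> CorrelationRanking:
    """Pearson r of every column against ``y``, sorted by |r| descending.

    ``mask`` restricts the correlation to a subset of rows (used for
    tasks where only some compounds carry numeric labels).  Constant
    columns have undefined correlation and are excluded with a record.
    Ties in |r| break alphabetically.
    """
    y = np.asarray(y, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        y = y[mask]
    if y.size != (table.n_molecules if mask is None else int(mask.sum())):
        raise ValueError("label vector length does not match table rows")
    if np.ptp(y) == 0:
        raise ValueError("target is constant; correlation undefined")

    entries: list[tuple[str, float]] = []
    excluded: list[str] = []
    for name in table.names:
        col = table.column(name)
        if mask is not None:
            col = col[mask]
        if np.ptp(col) == 0:
            excluded.append(name)
            continue
        r, _ = stats.pearsonr(col, y)
        entries.append((name, float(r)))
    entries.sort(key=lambda e: (-abs(e[1]), e[0]))
    return CorrelationRanking(entries=entries, target_name=target_name,
                              excluded_constant=excluded)


def prune_intercorrelated(ranking: CorrelationRanking, table: DescriptorTable,
                          r_max: float = 0.9) -> SelectionResult:
    """Greedy pruning in ranking order.

    A descriptor is kept iff its pairwise |r| with every already-kept
    descriptor is <= ``r_max``; the more task-correlated member of each
    offending pair therefore survives.  Each drop records (dropped,
    kept partner, offending r).
    """
    kept: list[str] = []
    removed: list[tuple[str, str, float]] = []
    cols = {n: table.column(n) for n in ranking.names}
    for name in ranking.names:
        offender = None
        for other in kept:
            r, _ = stats.pearsonr(cols[name], cols[other])
            if abs(r) > r_max:
                offender = (name, other, float(r))
                break
        if offender is None:
            kept.append(name)
        else:
            removed.append(offender)
    return SelectionResult(selected=kept, ranking=ranking,
                           removed_intercorrelated=removed)


def select_top_k(result: SelectionResult, k: int = 3) -> list[str]:
    """First min(k, available) surviving descriptors in ranking order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return result.selected[:k]


def select_descriptors(table: DescriptorTable, y: np.ndarray, k: int = 3,
                       variance_threshold: float = 0.5, r_max: float = 0.9,
                       mask: np.ndarray | None = None,
                       target_name: str = "y") -> SelectionResult:
    """Full filter pipeline: variance filter -> rank -> prune -> top k.

    The returned result's ``selected`` holds only the top-k names;
    the pruning audit trail is preserved.
    """
    filtered, removed_low_var = variance_filter(table, variance_threshold)
    ranking = rank_by_target_correlation(filtered, y, mask=mask,
                                         target_name=target_name)
    result = prune_intercorrelated(ranking, filtered, r_max=r_max)
    result.removed_low_variance = removed_low_var
    result.selected = select_top_k(result, k)
    return result


def make_noisy_descriptor(d: np.ndarray, y: np.ndarray, r_target: float,
                          seed: int) -> np.ndarray:
    """Attenuate corr(d, y) to ``r_target`` by adding Gaussian noise.

    The analytic scale for noise sd s follows the attenuation formula
    s = sd(d) * sqrt((r_d/r_target)^2 - 1); the scale applied to the
    drawn noise vector is then calibrated (closed-form quadratic in
    the sample moments) so the realized sample correlation matches
    ``r_target`` rather than only its expectation.  Infeasible when
    |r_target| exceeds the existing |corr(d, y)| or the signs differ;
    r_target exactly equal to the current correlation returns ``d``
    verbatim.
    """
    d = np.asarray(d, dtype=float)
    y = np.asarray(y, dtype=float)
    if r_target == 0:
        raise ValueError("r_target must be nonzero")
    r_d, _ = stats.pearsonr(d, y)
    if np.sign(r_target) != np.sign(r_d) or abs(r_target) > abs(r_d):
        raise ValueError(
            f"cannot reach r_target={r_target:.3f} from r_d={r_d:.3f} by adding noise")
    if r_target == r_d:
        return d.copy()
    s_analytic = d.std(ddof=1) * np.sqrt((r_d / r_target) ** 2 - 1.0)
    rng = np.random.default_rng(seed)
    e = rng.standard_normal(d.shape)
    # calibrate the scale c of the drawn vector: corr(d + c*e, y) = r_target
    # => (a + c*b)^2 = t^2 (v_d + 2c*v_de + c^2 v_e) with sample moments
    dc, ec, yc = d - d.mean(), e - e.mean(), y - y.mean()
    a = float(dc @ yc)
    b = float(ec @ yc)
    v_d, v_e, v_de = float(dc @ dc), float(ec @ ec), float(dc @ ec)
    v_y = float(yc @ yc)
    t2 = r_target ** 2 * v_y
    qa = b ** 2 - t2 * v_e
    qb = 2 * (a * b - t2 * v_de)
    qc = a ** 2 - t2 * v_d
    disc = qb ** 2 - 4 * qa * qc
    c = s_analytic
    if disc >= 0 and qa != 0:
        roots = [(-qb + np.sqrt(disc)) / (2 * qa), (-qb - np.sqrt(disc)) / (2 * qa)]
        valid = [r for r in roots if r > 0
                 and np.sign(a + r * b) == np.sign(r_target)]
        if valid:
            c = min(valid, key=lambda r: abs(r - s_analytic))
    return d + c * e
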