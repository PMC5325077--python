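"""Per-gene slice profiles: imputation, normalisation, and Earth Mover's Distance.

A slice profile is the ordered vector of FPKM values for one gene in one
embryo, anterior first.  Profiles are converted to unit-mass point
distributions over slice centres ``(i + 0.5) / N`` on ``[0, 1]`` and compared
with the exact 1-D Wasserstein-1 distance, so that distances are in ``[0, 1]``
and comparable between embryos with different slice counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SliceProfile",
    "SpatialDistribution",
    "EmdValue",
    "impute_bad_slices",
    "max_normalize",
    "slice_centers",
    "to_distribution",
    "emd",
    "emd_matrix",
    "emd_partial",
    "emd_lp_oracle",
    "emd_to_uniform",
    "adjacent_slice_similarity",
]

HEATMAP_FLOOR_FPKM = 10.0


@dataclass(frozen=True)
class SliceProfile:
    """One gene's per-slice FPKM values in one embryo (anterior first).

    ``qc_mask`` is True where the slice passed QC and the value is usable.
    """

    gene_id: str
    embryo_id: str
    values: np.ndarray
    qc_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        mask = self.qc_mask
        if mask is None:
            mask = np.ones(values.shape, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        object.__setattr__(self, "qc_mask", mask)
        if values.ndim != 1 or mask.shape != values.shape:
            raise ValueError("values and qc_mask must be 1-D and equal length")
        if np.any(~np.isfinite(values)) or np.any(values < 0):
            raise ValueError(f"profile {self.gene_id}/{self.embryo_id}: "
                             "values must be finite and non-negative")

    @property
    def n_slices(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SpatialDistribution:
    """Unit-mass point distribution over slice-centre positions in [0, 1].

    ``all_zero`` marks profiles with no expression; such distributions carry
    no mass and must be excluded from distance computations.
    """

    positions: np.ndarray
    masses: np.ndarray
    all_zero: bool = False

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        mas = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "masses", mas)
        if pos.shape != mas.shape or pos.ndim != 1:
            raise ValueError("positions and masses must be 1-D and equal length")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(mas < 0):
            raise ValueError("masses must be non-negative")
        if not self.all_zero and abs(mas.sum() - 1.0) >= 1e-9:
            raise ValueError("masses must sum to 1 unless all_zero is set")


@dataclass(frozen=True)
class EmdValue:
    """An EMD between two embryos' profiles of the same gene."""

    value: float
    gene_id: str
    embryo_pair: tuple[str, str]


def impute_bad_slices(profile: SliceProfile) -> SliceProfile:
    """Replace QC-failed slices from their usable neighbours.

    Interior failed slices take the mean of the nearest usable slice on each
    side; a failed run at either end copies the nearest usable value.  The
    returned profile has a fully usable mask.
    """
    mask = profile.qc_mask
    if not mask.any():
        raise ValueError(
            f"profile {profile.gene_id}/{profile.embryo_id}: all slices failed QC")
    if mask.all():
        return profile
    values = profile.values.copy()
    n = values.size
    good = np.flatnonzero(mask)
    for i in np.flatnonzero(~mask):
        left = good[good < i]
        right = good[good > i]
        if left.size and right.size:
            values[i] = 0.5 * (values[left[-1]] + values[right[0]])
        elif left.size:
            values[i] = values[left[-1]]
        else:
            values[i] = values[right[0]]
    return replace(profile, values=values, qc_mask=np.ones(n, dtype=bool))


def max_normalize(values, floor: float = HEATMAP_FLOOR_FPKM) -> np.ndarray:
    """Scale a profile by max(max(values), floor), mapping it into [0, 1].

    The floor keeps weakly expressed genes from being stretched to full
    intensity.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("negative expression values")
    denom = max(float(values.max(initial=0.0)), float(floor))
    return values / denom


def slice_centers(n_slices: int) -> np.ndarray:
    """Fractional AP positions of slice centres, (i + 0.5)/N for i = 0..N-1."""
    return (np.arange(n_slices) + 0.5) / n_slices


def to_distribution(values) -> SpatialDistribution:
    """Turn a slice profile into a unit-mass distribution at slice centres."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("negative expression values")
    positions = slice_centers(values.size)
    total = values.sum()
    if total == 0:
        return SpatialDistribution(positions, np.zeros_like(values), all_zero=True)
    return SpatialDistribution(positions, values / total)


def _check_not_all_zero(d: SpatialDistribution, name: str) -> None:
    if d.all_zero:
        raise ValueError(
            f"distribution {name} carries no mass; classify the gene as "
            "low_expression instead of computing an EMD")


def emd(a: SpatialDistribution, b: SpatialDistribution) -> float:
    """Exact 1-D Wasserstein-1 distance between two unit-mass distributions.

    Computed as the integral of |CDF_a - CDF_b| over the merged support,
    which is exact for point masses.  Symmetric, non-negative, satisfies the
    triangle inequality, and equals 0 iff the distributions are identical.
    """
    _check_not_all_zero(a, "a")
    _check_not_all_zero(b, "b")
    grid = np.union1d(a.positions, b.positions)
    cdf_a = np.concatenate(([0.0], np.cumsum(a.masses)))[
        np.searchsorted(a.positions, grid, side="right")]
    cdf_b = np.concatenate(([0.0], np.cumsum(b.masses)))[
        np.searchsorted(b.positions, grid, side="right")]
    return float(np.sum(np.abs(cdf_a[:-1] - cdf_b[:-1]) * np.diff(grid)))


def emd_matrix(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """Row-wise EMD between two gene x slice FPKM matrices.

    Rows are matched by index (same genes in two embryos); the embryos may
    have different slice counts.  Rows that are all zero in either matrix
    yield NaN.
    """
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    if np.any(values_a < 0) or np.any(values_b < 0):
        raise ValueError("negative expression values")
    pos_a = slice_centers(values_a.shape[1])
    pos_b = slice_centers(values_b.shape[1])
    grid = np.union1d(pos_a, pos_b)
    sum_a = values_a.sum(axis=1, keepdims=True)
    sum_b = values_b.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        mass_a = values_a / sum_a
        mass_b = values_b / sum_b
    ia = np.searchsorted(pos_a, grid, side="right")
    ib = np.searchsorted(pos_b, grid, side="right")
    zeros = np.zeros((values_a.shape[0], 1))
    cdf_a = np.hstack([zeros, np.cumsum(mass_a, axis=1)])[:, ia]
    cdf_b = np.hstack([zeros, np.cumsum(mass_b, axis=1)])[:, ib]
    out = np.sum(np.abs(cdf_a[:, :-1] - cdf_b[:, :-1]) * np.diff(grid), axis=1)
    out[(sum_a[:, 0] == 0) | (sum_b[:, 0] == 0)] = np.nan
    return out


def emd_partial(values_a, values_b, floor: float = HEATMAP_FLOOR_FPKM) -> float:
    """Partial-matching (Rubner) EMD on max-normalised, unequal-mass profiles.

    Ships min(total_a, total_b) mass at minimal cost and divides by the
    shipped mass.  Exposed as an alternative to the unit-mass default; not
    used by the pipeline.
    """
    a = max_normalize(values_a, floor)
    b = max_normalize(values_b, floor)
    pos_a = slice_centers(a.size)
    pos_b = slice_centers(b.size)
    ta, tb = a.sum(), b.sum()
    if ta == 0 or tb == 0:
        raise ValueError("cannot match an all-zero profile")
    shipped = min(ta, tb)
    n, m = a.size, b.size
    cost = np.abs(pos_a[:, None] - pos_b[None, :]).ravel()
    # inequality constraints: row sums <= a, column sums <= b, total == shipped
    a_ub = np.zeros((n + m, n * m))
    for i in range(n):
        a_ub[i, i * m:(i + 1) * m] = 1.0
    for j in range(m):
        a_ub[n + j, j::m] = 1.0
    res = optimize.linprog(
        cost, A_ub=a_ub, b_ub=np.concatenate([a, b]),
        A_eq=np.ones((1, n * m)), b_eq=[shipped], method="highs")
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"partial EMD LP failed: {res.message}")
    return float(res.fun / shipped)


def emd_lp_oracle(a: SpatialDistribution, b: SpatialDistribution) -> float:
    """Reference EMD via an explicit transportation linear program.

    Independent of :func:`emd`; intended for testing.  Limited to small
    instances (<= 200 atoms total).
    """
    _check_not_all_zero(a, "a")
    _check_not_all_zero(b, "b")
    if a.positions.size + b.positions.size > 200:
        raise ValueError("oracle limited to 200 atoms total")
    if abs(a.masses.sum() - b.masses.sum()) > 1e-9:
        raise ValueError("transportation problem infeasible: unequal total mass")
    n, m = a.positions.size, b.positions.size
    cost = np.abs(a.positions[:, None] - b.positions[None, :]).ravel()
    a_eq = np.zeros((n + m, n * m))
    for i in range(n):
        a_eq[i, i * m:(i + 1) * m] = 1.0
    for j in range(m):
        a_eq[n + j, j::m] = 1.0
    b_eq = np.concatenate([a.masses, b.masses])
    # dual simplex at tightened tolerances; the default interior-point
    # branch of "highs" only reaches ~1e-8 of the optimum
    res = optimize.linprog(
        cost, A_eq=a_eq, b_eq=b_eq, method="highs-ds",
        options={"primal_feasibility_tolerance": 1e-10,
                 "dual_feasibility_tolerance": 1e-10})
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"transportation LP failed: {res.message}")
    return float(res.fun)


def emd_to_uniform(profile: SliceProfile | np.ndarray) -> float:
    """EMD between a profile and the uniform distribution on its slice centres."""
    values = profile.values if isinstance(profile, SliceProfile) else np.asarray(profile, float)
    d = to_distribution(values)
    _check_not_all_zero(d, "profile")
    uniform = SpatialDistribution(d.positions, np.full(values.size, 1.0 / values.size))
    return emd(d, uniform)


def adjacent_slice_similarity(values: np.ndarray, qc_mask=None) -> dict[int, float]:
    """Mean Spearman correlation of genome-wide slice vectors vs slice offset.

    ``values`` is a genes x slices FPKM matrix for one embryo.  For each
    offset d the mean correlation over all usable slice pairs (i, i + d) is
    returned; offsets with fewer than two valid pairs are omitted, as are
    pairs where either vector is constant.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    mask = np.ones(n, dtype=bool) if qc_mask is None else np.asarray(qc_mask, bool)
    if mask.sum() < 3:
        raise ValueError("need at least 3 usable slices")
    curve: dict[int, float] = {}
    for d in range(1, n):
        rhos = []
        for i in range(n - d):
            if not (mask[i] and mask[i + d]):
                continue
            x, y = values[:, i], values[:, i + d]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho = stats.spearmanr(x, y).statistic
            if np.isfinite(rho):
                rhos.append(rho)
        if len(rhos) >= 2:
            curve[d] = float(np.mean(rhos))
    return curve
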