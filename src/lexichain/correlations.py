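"""Correlation inference: Pearson, first-order partials, and tests for
comparing dependent overlapping correlations.

All statistics are computed from their defining formulas (with p-values
from scipy's t and normal distributions):

* Pearson r with ``t = r * sqrt(n-2) / sqrt(1-r^2)`` on n-2 df;
* first-order partial correlation
  ``r_xy.z = (r_xy - r_xz*r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))`` with
  ``t = r * sqrt(n-3) / sqrt(1-r^2)`` on n-3 df;
* Steiger's Z for two dependent correlations sharing one variable
  (Fisher transforms, covariance estimated from the non-shared
  correlation and the back-transformed average), with Williams' t as the
  selectable alternative;
* a permutation oracle that builds the null by swapping the roles of the
  two non-shared variables within sampling units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .latent_model import TASKS

__all__ = [
    "CorrelationResult",
    "PartialCorrelationResult",
    "DependentComparisonResult",
    "PermutationComparisonResult",
    "CrossTaskCorrelations",
    "pearson",
    "partial_correlation_from_r",
    "partial_correlation",
    "partial_p",
    "fisher_z",
    "fisher_z_inv",
    "compare_dependent_overlapping",
    "permutation_compare",
    "correlation_matrix",
]

READING_TASKS = ("ADT", "LDT", "GDT")

#: the three comparisons of overlapping correlations among the reading
#: tasks: (pair 1, pair 2, shared variable)
COMPARISON_TRIADS = (
    (("ADT", "LDT"), ("LDT", "GDT"), "LDT"),
    (("ADT", "GDT"), ("ADT", "LDT"), "ADT"),
    (("ADT", "GDT"), ("LDT", "GDT"), "GDT"),
)


@dataclass
class CorrelationResult:
    r: float
    n: int
    t: float
    df: int
    p: float

    def to_dict(self) -> dict:
        return {"r": self.r, "n": self.n, "t": self.t, "df": self.df, "p": self.p}


@dataclass
class PartialCorrelationResult:
    r_partial: float
    controlled: str
    n: int
    df: int
    t: float
    p: float

    def to_dict(self) -> dict:
        return {
            "r_partial": self.r_partial,
            "controlled": self.controlled,
            "n": self.n,
            "df": self.df,
            "t": self.t,
            "p": self.p,
        }


@dataclass
class DependentComparisonResult:
    r_jk: float
    r_jh: float
    r_kh: float
    n: int
    statistic: float
    p: float
    method: str
    shared: str | None = None

    def to_dict(self) -> dict:
        return {
            "r_jk": self.r_jk,
            "r_jh": self.r_jh,
            "r_kh": self.r_kh,
            "n": self.n,
            "statistic": self.statistic,
            "p": self.p,
            "method": self.method,
            "shared": self.shared,
        }


@dataclass
class PermutationComparisonResult:
    p: float
    delta_r: float
    n_perm: int


def _as_vector(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if not np.isfinite(v).all():
        raise ValueError(f"{name} contains non-finite values")
    return v


def _t_pvalue(t: float, df: int) -> float:
    return float(2.0 * stats.t.sf(abs(t), df))


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with its two-sided t test on n-2 df."""
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    n = xv.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    ssx = float(xc @ xc)
    ssy = float(yc @ yc)
    if ssx == 0.0 or ssy == 0.0:
        raise ValueError("zero variance input")
    r = float(xc @ yc) / np.sqrt(ssx * ssy)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2
    denom = 1.0 - r * r
    if denom <= 0.0:
        t = float("inf") if r > 0 else float("-inf")
        p = 0.0
    else:
        t = r * np.sqrt(df) / np.sqrt(denom)
        p = _t_pvalue(t, df)
    return CorrelationResult(r=r, n=n, t=float(t), df=df, p=p)


def _check_triad_psd(r_xy: float, r_xz: float, r_yz: float) -> None:
    for name, r in (("r_xy", r_xy), ("r_xz", r_xz), ("r_yz", r_yz)):
        if abs(r) >= 1.0:
            raise ValueError(f"{name} = {r} must satisfy |r| < 1")
    det = 1.0 - r_xy**2 - r_xz**2 - r_yz**2 + 2.0 * r_xy * r_xz * r_yz
    if det < -1e-12:
        raise ValueError(
            f"correlation triad (r_xy={r_xy}, r_xz={r_xz}, r_yz={r_yz}) is not "
            f"positive semi-definite (det = {det:.3g})"
        )


def partial_correlation_from_r(
    r_xy: float, r_xz: float, r_yz: float, n: int, controlled: str = "z"
) -> PartialCorrelationResult:
    """First-order partial correlation of x and y controlling z, from the
    three pairwise correlations."""
    _check_triad_psd(r_xy, r_xz, r_yz)
    r_p = (r_xy - r_xz * r_yz) / np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    r_p = float(np.clip(r_p, -1.0, 1.0))
    df = n - 3
    if df < 1:
        raise ValueError(f"need n > 3 for a first-order partial, got n = {n}")
    denom = 1.0 - r_p * r_p
    if denom <= 0.0:
        t = float("inf") if r_p > 0 else float("-inf")
        p = 0.0
    else:
        t = r_p * np.sqrt(df) / np.sqrt(denom)
        p = _t_pvalue(t, df)
    return PartialCorrelationResult(
        r_partial=r_p, controlled=controlled, n=n, df=df, t=float(t), p=p
    )


def partial_correlation(x, y, z, controlled: str = "z") -> PartialCorrelationResult:
    """Data-vector overload: computes the three Pearson r's first.

    Algebraically identical to correlating the residuals of x and y after
    linear regression on z.
    """
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    zv = _as_vector(z, "z")
    if not (xv.size == yv.size == zv.size):
        raise ValueError("x, y, z must have equal length")
    r_xy = pearson(xv, yv).r
    r_xz = pearson(xv, zv).r
    r_yz = pearson(yv, zv).r
    return partial_correlation_from_r(r_xy, r_xz, r_yz, xv.size, controlled=controlled)


def partial_p(r_partial: float, n: int, n_controls: int = 1) -> float:
    """Two-sided p for a partial correlation on n - 2 - n_controls df."""
    if abs(r_partial) >= 1.0:
        raise ValueError("|r_partial| must be < 1")
    df = n - 2 - n_controls
    if df < 1:
        raise ValueError(f"non-positive degrees of freedom (n={n}, controls={n_controls})")
    t = r_partial * np.sqrt(df) / np.sqrt(1.0 - r_partial**2)
    return _t_pvalue(float(t), df)


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher's variance-stabilising transform, atanh(r)."""
    return np.arctanh(r)


def fisher_z_inv(z: float | np.ndarray) -> float | np.ndarray:
    return np.tanh(z)


def _steiger_z(r_jk: float, r_jh: float, r_kh: float, n: int) -> tuple[float, float]:
    z1 = float(np.arctanh(r_jk))
    z2 = float(np.arctanh(r_jh))
    # back-transformed average of the two correlations
    r_bar = float(np.tanh(0.5 * (z1 + z2)))
    rb2 = r_bar * r_bar
    cov = (r_kh * (1.0 - 2.0 * rb2) - 0.5 * rb2 * (1.0 - 2.0 * rb2 - r_kh**2)) / (
        (1.0 - rb2) ** 2
    )
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 - 2.0 * cov))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), p


def _williams_t(r_jk: float, r_jh: float, r_kh: float, n: int) -> tuple[float, float]:
    r_bar = 0.5 * (r_jk + r_jh)
    det = 1.0 - r_jk**2 - r_jh**2 - r_kh**2 + 2.0 * r_jk * r_jh * r_kh
    t = (r_jk - r_jh) * np.sqrt(
        (n - 1) * (1.0 + r_kh)
        / (2.0 * det * (n - 1) / (n - 3) + r_bar**2 * (1.0 - r_kh) ** 3)
    )
    p = _t_pvalue(float(t), n - 3)
    return float(t), p


def compare_dependent_overlapping(
    r_jk: float,
    r_jh: float,
    r_kh: float,
    n: int,
    method: str = "steiger_z",
    shared: str | None = None,
) -> DependentComparisonResult:
    """Test r_jk = r_jh for two correlations sharing variable j.

    ``r_kh`` is the correlation between the two non-shared variables.
    ``steiger_z`` (default) Fisher-transforms both correlations and uses
    their estimated covariance; ``williams_t`` is the t-form alternative
    on n-3 df.  The statistic is antisymmetric in (r_jk, r_jh).
    """
    if n < 10:
        raise ValueError(f"n = {n} too small for a dependent-correlation test")
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if abs(r) >= 1.0:
            raise ValueError(f"{name} = {r}: |r| must be < 1 (Fisher transform diverges)")
    _check_triad_psd(r_jk, r_jh, r_kh)
    if method == "steiger_z":
        statistic, p = _steiger_z(r_jk, r_jh, r_kh, n)
    elif method == "williams_t":
        statistic, p = _williams_t(r_jk, r_jh, r_kh, n)
    else:
        raise ValueError(f"unknown method {method!r}")
    return DependentComparisonResult(
        r_jk=r_jk,
        r_jh=r_jh,
        r_kh=r_kh,
        n=n,
        statistic=statistic,
        p=p,
        method=method,
        shared=shared,
    )


def permutation_compare(
    x, y, z, n_perm: int = 2000, seed: int | np.random.Generator = 0
) -> PermutationComparisonResult:
    """Permutation test of r(x,y) = r(x,z), sharing variable x.

    The null is built by randomly swapping the roles of y and z within
    each sampling unit; the p-value is the proportion of permuted |delta
    r| at least as large as observed (add-one estimator).
    """
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    zv = _as_vector(z, "z")
    if not (xv.size == yv.size == zv.size):
        raise ValueError("x, y, z must have equal length")
    if n_perm < 1000:
        raise ValueError("n_perm must be at least 1000")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = xv.size

    def _corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        ac = a - a.mean(axis=1, keepdims=True)
        bc = b - b.mean(axis=1, keepdims=True)
        num = (ac * bc).sum(axis=1)
        den = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
        return num / den

    obs = pearson(xv, yv).r - pearson(xv, zv).r
    swap = rng.random((n_perm, n)) < 0.5
    y_perm = np.where(swap, zv, yv)
    z_perm = np.where(swap, yv, zv)
    x_rows = np.broadcast_to(xv, (n_perm, n))
    delta = _corr_rows(x_rows, y_perm) - _corr_rows(x_rows, z_perm)
    count = int((np.abs(delta) >= abs(obs) - 1e-12).sum())
    p = (count + 1) / (n_perm + 1)
    return PermutationComparisonResult(p=float(p), delta_r=float(obs), n_perm=n_perm)


@dataclass
class CrossTaskCorrelations:
    """Full correlation section: pairwise grid, partials, comparisons."""

    r_matrix: pd.DataFrame
    pairwise: dict[tuple[str, str], CorrelationResult]
    partials: dict[tuple[str, str], PartialCorrelationResult]
    comparisons: list[DependentComparisonResult]
    n: int
    control: str
    method: str
    degenerate: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "control": self.control,
            "method": self.method,
            "degenerate": list(self.degenerate),
            "r_matrix": {
                t1: {t2: float(self.r_matrix.loc[t1, t2]) for t2 in self.r_matrix.columns}
                for t1 in self.r_matrix.index
            },
            "pairwise": {
                f"{a}~{b}": res.to_dict() for (a, b), res in self.pairwise.items()
            },
            "partials": {
                f"{a}~{b}|{self.control}": res.to_dict()
                for (a, b), res in self.partials.items()
            },
            "comparisons": [c.to_dict() for c in self.comparisons],
        }


def correlation_matrix(
    std_matrix: pd.DataFrame, control: str = "NRT", method: str = "steiger_z"
) -> CrossTaskCorrelations:
    """Pairwise correlations, partials controlling ``control``, and the
    three dependent-correlation comparisons among the reading tasks.

    ``std_matrix`` is the participants x tasks matrix (standardisation is
    not required for the r's, which are affine-invariant, but is the
    conventional input).
    """
    missing = [t for t in TASKS if t not in std_matrix.columns]
    if missing:
        raise ValueError(f"missing task column(s): {missing}")
    data = std_matrix[list(TASKS)].dropna()
    n = len(data)
    if n < 4:
        raise ValueError(f"need at least 4 complete participants, got {n}")

    pairwise: dict[tuple[str, str], CorrelationResult] = {}
    r_mat = pd.DataFrame(np.eye(len(TASKS)), index=list(TASKS), columns=list(TASKS))
    for i, t1 in enumerate(TASKS):
        for t2 in TASKS[i + 1 :]:
            res = pearson(data[t1], data[t2])
            pairwise[(t1, t2)] = res
            r_mat.loc[t1, t2] = res.r
            r_mat.loc[t2, t1] = res.r

    def _r(a: str, b: str) -> float:
        return float(r_mat.loc[a, b])

    partials: dict[tuple[str, str], PartialCorrelationResult] = {}
    reading = [t for t in READING_TASKS if t != control]
    degenerate: list[str] = []
    for i, t1 in enumerate(reading):
        for t2 in reading[i + 1 :]:
            try:
                partials[(t1, t2)] = partial_correlation_from_r(
                    _r(t1, t2), _r(t1, control), _r(t2, control), n, controlled=control
                )
            except ValueError as exc:
                degenerate.append(f"partial {t1}~{t2}|{control}: {exc}")

    comparisons = []
    for (j1, k1), (j2, k2), shared in COMPARISON_TRIADS:
        other1 = k1 if j1 == shared else j1
        other2 = k2 if j2 == shared else j2
        try:
            comparisons.append(
                compare_dependent_overlapping(
                    _r(*sorted((shared, other1), key=TASKS.index)),
                    _r(*sorted((shared, other2), key=TASKS.index)),
                    _r(*sorted((other1, other2), key=TASKS.index)),
                    n,
                    method=method,
                    shared=shared,
                )
            )
        except ValueError as exc:
            degenerate.append(f"comparison shared {shared}: {exc}")
    return CrossTaskCorrelations(
        r_matrix=r_mat,
        pairwise=pairwise,
        partials=partials,
        comparisons=comparisons,
        n=n,
        control=control,
        method=method,
        degenerate=degenerate,
    )
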