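"""Degradation kinetics, Duncan's multiple-range test and response surfaces.

Residue dissipation is summarized the standard way: ordinary least squares on
``ln C(t) = ln C0 - k t`` gives the first-order rate constant ``k`` and the
half-life ``t_1/2 = ln 2 / k``.  Condition effects on residue levels are
compared with Duncan's multiple-range test (ranked means, studentized-range
critical values at Duncan's protection levels, compact letter display).  The
joint temperature/humidity effect on half-life is fit as a quadratic response
surface on coded factors A (temperature) and B (humidity).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import studentized_range


@lru_cache(maxsize=4096)
def _q_crit(quantile: float, p: int, df: int) -> float:
    return float(studentized_range.ppf(quantile, p, df))

from .synthetic import ResidueSeries

__all__ = [
    "KineticFit",
    "DuncanResult",
    "SurfaceFit",
    "fit_first_order",
    "duncan_mrt",
    "coded_levels",
    "response_surface_fit",
]


@dataclass(frozen=True)
class KineticFit:
    C0_hat: float
    k_hat: float
    t_half: float
    r_squared: float


@dataclass(frozen=True)
class DuncanResult:
    means: np.ndarray
    sds: np.ndarray
    ns: np.ndarray
    ms_error: float
    df_error: int
    alpha: float
    letters: list[str]          # one letter-set per group, input order
    different: np.ndarray       # boolean (g, g) matrix of declared differences

    def format_rows(self, names=None) -> list[str]:
        names = names or [f"group{i + 1}" for i in range(len(self.means))]
        return [f"{n}: {m:.2f} ± {s:.2f}^{lt}"
                for n, m, s, lt in zip(names, self.means, self.sds, self.letters)]


@dataclass(frozen=True)
class SurfaceFit:
    """Quadratic surface y = b0 + b1 A + b2 B + b3 AB + b4 A^2 + b5 B^2."""

    beta: np.ndarray
    residual_sd: float

    TERMS = ("intercept", "A", "B", "AB", "A^2", "B^2")

    def predict(self, A, B) -> np.ndarray:
        A = np.asarray(A, dtype=float)
        B = np.asarray(B, dtype=float)
        b = self.beta
        return b[0] + b[1] * A + b[2] * B + b[3] * A * B + b[4] * A**2 + b[5] * B**2

    def stationary_point(self) -> tuple[float, float]:
        """Coded (A, B) where both partial derivatives vanish."""
        b = self.beta
        H = np.array([[2 * b[4], b[3]], [b[3], 2 * b[5]]])
        rhs = -np.array([b[1], b[2]])
        sol = np.linalg.solve(H, rhs)
        return float(sol[0]), float(sol[1])


def fit_first_order(series: ResidueSeries | None = None, *,
                    days=None, conc=None) -> KineticFit:
    """Log-linear first-order fit; half-life ``ln 2 / k``.

    Only strictly positive concentrations enter the fit (log scale).  A
    non-positive slope yields an infinite half-life with a warning.
    """
    if series is not None:
        t = np.asarray(series.days, dtype=float)
        c = np.asarray(series.conc, dtype=float)
    else:
        t = np.asarray(days, dtype=float)
        c = np.asarray(conc, dtype=float)
    mask = c > 0
    if mask.sum() < 3:
        raise ValueError("need at least 3 positive concentrations")
    t, c = t[mask], c[mask]
    X = np.stack([np.ones(len(t)), t], axis=1)
    y = np.log(c)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ coef
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    k_hat = -float(coef[1])
    if k_hat <= 0:
        warnings.warn("non-positive decay rate: half-life reported as +inf",
                      stacklevel=2)
        t_half = np.inf
    else:
        t_half = float(np.log(2) / k_hat)
    return KineticFit(C0_hat=float(np.exp(coef[0])), k_hat=k_hat,
                      t_half=t_half, r_squared=max(0.0, min(1.0, r2)))


def _letter_display(order: np.ndarray, distinct: np.ndarray) -> list[str]:
    """Compact letter display by the insert-and-absorb procedure.

    *order* ranks groups by descending mean; ``distinct[i, j]`` says groups i
    and j (original indices) are significantly different.  Returns one letter
    string per group in original index order.
    """
    g = len(order)
    # columns: sets of ranked positions sharing a letter
    columns: list[set[int]] = [set(range(g))]
    for i in range(g):
        for j in range(i + 1, g):
            gi, gj = order[i], order[j]
            if not distinct[gi, gj]:
                continue
            new_columns: list[set[int]] = []
            for col in columns:
                if i in col and j in col:
                    a, b = col - {j}, col - {i}
                    for piece in (a, b):
                        if not any(piece <= other for other in
                                   new_columns + [c for c in columns if c is not col]):
                            new_columns.append(piece)
                else:
                    new_columns.append(col)
            columns = new_columns
    # absorb columns contained in others
    columns = [c for c in columns
               if not any(c < other for other in columns)]
    columns.sort(key=lambda c: min(c))
    letters = [""] * g
    for li, col in enumerate(columns):
        ch = chr(ord("a") + li)
        for pos in col:
            letters[order[pos]] += ch
    return letters


def duncan_mrt(groups, alpha: float = 0.05) -> DuncanResult:
    """Duncan's multiple-range test after one-way ANOVA.

    For a stretch of ``p`` ranked means the critical range is
    ``R_p = q(1 - alpha_p, p, df_err) * sqrt(MS_err / n)`` with Duncan's
    protection level ``alpha_p = 1 - (1 - alpha)^(p - 1)``; two means differ
    when their gap exceeds the critical range of the stretch they span and no
    enclosing stretch is non-significant.  Unequal group sizes use the
    harmonic mean n.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    g = len(groups)
    ns = np.array([len(x) for x in groups])
    means = np.array([x.mean() for x in groups])
    sds = np.array([x.std(ddof=1) for x in groups])
    df_error = int(ns.sum() - g)
    ms_error = float(sum(((x - x.mean()) ** 2).sum() for x in groups) / df_error)
    n_h = g / np.sum(1.0 / ns)  # harmonic mean group size

    distinct = np.zeros((g, g), dtype=bool)
    if ms_error == 0:
        for i, j in itertools.combinations(range(g), 2):
            distinct[i, j] = distinct[j, i] = means[i] != means[j]
    else:
        order = np.argsort(-means, kind="stable")  # descending
        ranked = means[order]
        se = np.sqrt(ms_error / n_h)
        crit = {p: _q_crit((1 - alpha) ** (p - 1), p, df_error) * se
                for p in range(2, g + 1)}
        # protected sequential testing: a stretch is only significant if no
        # enclosing stretch was retained as non-significant
        nonsig = np.zeros((g, g), dtype=bool)  # ranked-position spans
        for span in range(g, 1, -1):
            for i in range(0, g - span + 1):
                j = i + span - 1
                if any(nonsig[a, b] for a in range(i + 1)
                       for b in range(j, g) if (a, b) != (i, j)):
                    nonsig[i, j] = True
                    continue
                if ranked[i] - ranked[j] <= crit[span]:
                    nonsig[i, j] = True
        for i in range(g):
            for j in range(i + 1, g):
                if not nonsig[i, j]:
                    gi, gj = order[i], order[j]
                    distinct[gi, gj] = distinct[gj, gi] = True
    order = np.argsort(-means, kind="stable")
    letters = _letter_display(order, distinct)
    return DuncanResult(means=means, sds=sds, ns=ns, ms_error=ms_error,
                        df_error=df_error, alpha=alpha, letters=letters,
                        different=distinct)


def coded_levels(temperature_C, rh_pct) -> tuple:
    """Map raw factors to coded units: A = (T - 35)/5, B = (H - 75)/5.

    The coded levels -1/0/+1 correspond to 30/35/40 degC and 70/75/80 % RH.
    """
    T = np.asarray(temperature_C, dtype=float)
    H = np.asarray(rh_pct, dtype=float)
    A = (T - 35.0) / 5.0
    B = (H - 75.0) / 5.0
    if A.ndim == 0:
        return float(A), float(B)
    return A, B


def full_factorial_design() -> list[tuple[float, float]]:
    """The default 3x3 factorial on coded levels {-1, 0, +1}."""
    return [(a, b) for a in (-1.0, 0.0, 1.0) for b in (-1.0, 0.0, 1.0)]


def response_surface_fit(design, responses) -> SurfaceFit:
    """Least-squares quadratic surface over coded (A, B) design points."""
    design = np.asarray(design, dtype=float)
    y = np.asarray(responses, dtype=float)
    if design.ndim != 2 or design.shape[1] != 2 or len(design) != len(y):
        raise ValueError("design must be (n, 2) matching responses")
    if len(design) < 6:
        raise ValueError("need at least 6 design points for 6 coefficients")
    for col, name in ((design[:, 0], "A"), (design[:, 1], "B")):
        if len(np.unique(col)) < 3:
            raise ValueError(
                f"factor {name} needs >= 3 distinct levels to identify "
                f"its quadratic term")
    A, B = design[:, 0], design[:, 1]
    X = np.stack([np.ones(len(y)), A, B, A * B, A**2, B**2], axis=1)
    rank = np.linalg.matrix_rank(X)
    if rank < 6:
        # name the terms whose columns are linearly dependent
        bad = []
        for i in range(6):
            others = np.delete(X, i, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(SurfaceFit.TERMS[i])
        raise ValueError(f"rank-deficient design; unidentifiable terms: {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(y) - 6, 1)
    return SurfaceFit(beta=beta, residual_sd=float(np.sqrt(resid @ resid / dof)))
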