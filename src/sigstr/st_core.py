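"""Signal transduction quantity (ST), signal transduction rate (STR) and
the constrained-extremum theory that predicts constant STR along an
activated cascade.

The ST of a cascade is the amount-weighted Kullback-Leibler divergence
between the molecule-amount distribution during the signal event and the
pre-stimulation baseline:

    delta_I = sum_j X_j * ln(X_j / X_j^st)          [nats * a.u.]

The STR of one molecule is the information gain per unit signal duration,

    beta_j = ln(integral_ratio_j) / tau_j           [1/min]

where integral_ratio_j is the time-averaged phosphorylation fold change over
one signal duration. All logarithms are natural (the calculus of the
Lagrangian below requires it), so ST is measured in nats.

Constrained-extremum theory
---------------------------
Introducing multipliers for the total amount and the total signal duration
and setting the derivatives of L = delta_I + alpha*sum p_j + beta*X*sum
p_j tau_j to zero yields the exponentially tilted allocation

    p_j = p_j^st * exp(-beta * tau_j),

whose per-molecule STR (1/tau_j) ln(p_j/p_j^st) equals -beta for *every* j:
at the constrained extremum the STR is independent of the molecule index.
Because the generalized KLD is strictly convex in the allocation, the tilt
is the constrained *minimum* of ST among allocations with the same total
amount and total duration — equivalently, it *maximizes the total signal
duration* attainable at a given ST and amount budget. Either way it is the
unique allocation at which signaling is extremal, and it is the one with
uniform STR. ``check_extremality`` verifies both facets numerically.

Sign convention: an activated cascade has measured STR beta_j > 0
(phosphorylation rises above baseline); the Lagrange multiplier equals
-beta_j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq


@dataclass(frozen=True)
class CascadeState:
    """Amounts of the molecules of one cascade at baseline and during an
    event, with their signal durations."""

    molecule_ids: tuple[str, ...]
    X_st: np.ndarray
    X: np.ndarray
    tau_vec: np.ndarray

    def __post_init__(self):
        for name in ("X_st", "X", "tau_vec"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.molecule_ids)
        if not (len(self.X_st) == len(self.X) == len(self.tau_vec) == n):
            raise ValueError("molecule_ids, X_st, X and tau_vec must have equal length")
        if np.any(self.X_st <= 0):
            raise ValueError("baseline amounts X_st must be positive")
        if np.any(self.X < 0):
            raise ValueError("amounts X must be nonnegative")
        if np.any(self.tau_vec <= 0):
            raise ValueError("durations must be positive")


@dataclass(frozen=True)
class StrEstimate:
    """STR of one molecule in one replicate: beta = delta_I / tau."""

    molecule_id: str
    replicate: int
    tau: float
    integral_ratio: float
    beta: float

    @property
    def delta_I(self) -> float:
        return self.beta * self.tau


@dataclass(frozen=True)
class TiltSolution:
    """Exponential tilt solving one constraint; the multiplier convention
    (alpha = -total amount) fixes the tilt coefficient to 1."""

    beta: float
    p_tilted: np.ndarray
    constraint_kind: str
    target: float
    constraint_residual: float


def compute_st(state: CascadeState) -> float:
    """Amount-weighted ST (generalized KLD) of a cascade state, in nats*a.u.

    Terms with X_j = 0 contribute 0 (the 0*ln 0 convention). Nonnegative
    whenever total amounts are conserved (Gibbs' inequality), with equality
    iff X == X_st.
    """
    x, xst = state.X, state.X_st
    terms = np.where(x > 0, x * np.log(np.where(x > 0, x, 1.0) / xst), 0.0)
    return float(terms.sum())


def st_of_allocation(p: np.ndarray, p_st: np.ndarray) -> float:
    """ST of a bare allocation vector against its baseline (same generalized
    KLD as :func:`compute_st`, without the CascadeState wrapper)."""
    p = np.asarray(p, dtype=float)
    p_st = np.asarray(p_st, dtype=float)
    terms = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0) / p_st), 0.0)
    return float(terms.sum())


def total_duration(state: CascadeState) -> float:
    """Total signal event duration: sum_j X_j * tau_j  [a.u. * min]."""
    return float(np.sum(state.X * state.tau_vec))


def compute_str(integral_ratio: float, tau: float) -> float:
    """STR from the time-averaged fold change and the signal duration:
    beta = ln(integral_ratio) / tau  [1/min]."""
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if integral_ratio <= 0:
        raise ValueError(f"integral_ratio must be positive, got {integral_ratio}")
    return float(np.log(integral_ratio) / tau)


def tilt_distribution(p_st: np.ndarray, tau_vec: np.ndarray, beta: float) -> np.ndarray:
    """Exponentially tilted allocation p_j = p_j^st * exp(-beta * tau_j).

    By construction every molecule's STR (1/tau_j) ln(p_j/p_j^st) equals
    -beta exactly.
    """
    p_st = np.asarray(p_st, dtype=float)
    tau_vec = np.asarray(tau_vec, dtype=float)
    if np.any(p_st <= 0) or np.any(tau_vec <= 0):
        raise ValueError("p_st and tau_vec must be positive")
    return p_st * np.exp(-beta * tau_vec)


def solve_beta(
    p_st: np.ndarray,
    tau_vec: np.ndarray,
    target: float,
    constraint_kind: str = "duration",
    tol: float = 1e-12,
) -> TiltSolution:
    """Find the tilt multiplier beta matching one constraint.

    ``constraint_kind="normalization"``: sum_j p_st_j exp(-beta tau_j) = target.
    ``constraint_kind="duration"``:     sum_j p_st_j tau_j exp(-beta tau_j) = target.

    Both objectives are strictly decreasing in beta with range (0, inf), so a
    unique root exists for any positive target; nonpositive targets are
    unattainable and raise with the attainable interval reported.
    """
    p_st = np.asarray(p_st, dtype=float)
    tau_vec = np.asarray(tau_vec, dtype=float)
    if constraint_kind == "normalization":
        weights = p_st
    elif constraint_kind == "duration":
        weights = p_st * tau_vec
    else:
        raise ValueError(f"unknown constraint_kind {constraint_kind!r}")
    if target <= 0:
        raise ValueError(
            f"target {target} outside attainable range (0, inf) for "
            f"{constraint_kind} constraint"
        )

    def objective(beta: float) -> float:
        return float(np.sum(weights * np.exp(-beta * tau_vec))) - target

    lo, hi = -1.0, 1.0
    while objective(lo) < 0:  # objective decreasing: widen until f(lo) > 0
        lo *= 2
        if lo < -1e6:
            raise ValueError("target unattainably large")
    while objective(hi) > 0:
        hi *= 2
        if hi > 1e6:
            raise ValueError("target unattainably small")
    beta = brentq(objective, lo, hi, xtol=tol, rtol=8.9e-16)
    residual = objective(beta)
    return TiltSolution(
        beta=float(beta),
        p_tilted=tilt_distribution(p_st, tau_vec, beta),
        constraint_kind=constraint_kind,
        target=target,
        constraint_residual=float(residual),
    )


def verify_uniform_str(
    p: np.ndarray,
    p_st: np.ndarray,
    tau_vec: np.ndarray,
    tol: float = 1e-10,
) -> tuple[bool, np.ndarray]:
    """Check whether an allocation has molecule-independent STR.

    Returns (is_uniform, per_step_beta) with
    per_step_beta_j = (1/tau_j) ln(p_j / p_st_j); uniform iff the spread
    (max - min) of the per-step rates is <= tol.
    """
    p = np.asarray(p, dtype=float)
    p_st = np.asarray(p_st, dtype=float)
    tau_vec = np.asarray(tau_vec, dtype=float)
    per_step = np.log(p / p_st) / tau_vec
    return bool(per_step.max() - per_step.min() <= tol), per_step


# ---------------------------------------------------------------------------
# Numerical extremality check
# ---------------------------------------------------------------------------

def random_matched_allocations(
    p: np.ndarray,
    tau_vec: np.ndarray,
    n: int,
    rng: np.random.Generator,
    scale: float = 0.2,
) -> np.ndarray:
    """Random positive allocations sharing p's total amount and total
    duration: perturbations drawn in the null space of [1; tau]."""
    p = np.asarray(p, dtype=float)
    tau_vec = np.asarray(tau_vec, dtype=float)
    if len(p) < 3:
        raise ValueError("need at least 3 molecules to perturb under 2 constraints")
    A = np.vstack([np.ones_like(tau_vec), tau_vec])
    _, _, vt = np.linalg.svd(A)
    null = vt[2:]
    out = np.empty((n, len(p)))
    for i in range(n):
        v = null.T @ rng.normal(size=null.shape[0])
        vmax = np.abs(v).max()
        if vmax == 0:
            out[i] = p
            continue
        eps = scale * p.min() / vmax * rng.uniform(0.05, 1.0)
        out[i] = p + eps * v
    return out


def check_extremality(
    p_st: np.ndarray,
    tau_vec: np.ndarray,
    beta_j: float,
    n_perturb: int = 100,
    rng: np.random.Generator | None = None,
) -> dict:
    """Verify numerically that the tilted allocation is the ST extremum.

    Builds the tilt p = p_st * exp(beta_j * tau) (beta_j > 0: activation) and
    draws ``n_perturb`` random allocations matched on total amount and total
    duration. Reports the tilt's ST, the perturbed STs, and whether the tilt
    attains the minimum ST of the matched family — the constrained-extremum
    property, equivalent to the tilt maximizing total duration at fixed ST.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    p_st = np.asarray(p_st, dtype=float)
    tau_vec = np.asarray(tau_vec, dtype=float)
    p_tilt = tilt_distribution(p_st, tau_vec, -beta_j)
    st0 = st_of_allocation(p_tilt, p_st)
    perturbed = random_matched_allocations(p_tilt, tau_vec, n_perturb, rng)
    sts = np.array([st_of_allocation(q, p_st) for q in perturbed])
    return {
        "st_tilt": st0,
        "st_perturbed": sts,
        "tilt_is_minimum": bool(np.all(sts >= st0 - 1e-12)),
        "total_amount": float(p_tilt.sum()),
        "total_duration": float((p_tilt * tau_vec).sum()),
    }


def check_duration_maximality(
    p_st: np.ndarray,
    tau_vec: np.ndarray,
    beta_j: float,
    n_perturb: int = 100,
    rng: np.random.Generator | None = None,
) -> dict:
    """Dual facet of the extremum: among allocations with the *same ST and
    total amount* as the tilt, none achieves a longer total signal duration.

    Alternative allocations are constructed by moving away from the tilt
    along random amount-preserving directions until the ST returns to the
    tilt's value (the second root of the convex ST profile along the line).

    Requires ``beta_j > 0`` (activation): the constrained-minimum ST as a
    function of the duration budget has slope ``beta_j`` at the tilt, so the
    activation tilt sits at the *long*-duration end of its ST level set; a
    suppression tilt (``beta_j < 0``) would instead be the duration minimum.
    """
    if beta_j <= 0:
        raise ValueError(
            "duration maximality holds for activation tilts only (beta_j > 0)"
        )
    rng = np.random.default_rng(0) if rng is None else rng
    p_st = np.asarray(p_st, dtype=float)
    tau_vec = np.asarray(tau_vec, dtype=float)
    p_tilt = tilt_distribution(p_st, tau_vec, -beta_j)
    st0 = st_of_allocation(p_tilt, p_st)
    dur0 = float((p_tilt * tau_vec).sum())

    durations = []
    while len(durations) < n_perturb:
        w = rng.normal(size=len(p_st))
        w -= w.mean()  # preserve total amount
        if np.all(w == 0):
            continue
        # largest step keeping the allocation strictly positive
        neg = w < 0
        a_max = 0.9 * np.min(np.where(neg, -p_tilt / np.where(neg, w, -1.0), np.inf))
        if not np.isfinite(a_max) or a_max <= 0:
            continue
        f = lambda a: st_of_allocation(p_tilt + a * w, p_st) - st0
        grid = np.linspace(1e-9, a_max, 200)
        vals = np.array([f(a) for a in grid])
        cross = np.flatnonzero((vals[:-1] < 0) & (vals[1:] >= 0))
        if len(cross) == 0:
            continue  # ST never recovers within the positivity region
        i = int(cross[0])
        a_star = brentq(f, grid[i], grid[i + 1])
        q = p_tilt + a_star * w
        durations.append(float((q * tau_vec).sum()))
    durations = np.asarray(durations)
    return {
        "duration_tilt": dur0,
        "duration_matched_st": durations,
        "tilt_is_maximum": bool(np.all(durations <= dur0 + 1e-9 * max(dur0, 1.0))),
    }
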