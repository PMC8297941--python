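"""Partial information decomposition (PID) of multivariate transfer entropy.

Given two sender neurons J, K and a receiver I, the multivariate TE

    mvTE = I(I_t ; (J_{t-d}, K_{t-d}) | I_{t-d})

is decomposed into four nonnegative, non-overlapping parts: redundancy
(information both senders carry), two unique terms, and synergy (information
available only from the joint sender state).  Synergy is the quantity of
interest downstream - it proxies nontrivial two-input computation by the
receiver - and is obtained from the identity

    synergy = mvTE - TE(J->I) - TE(K->I) + redundancy.

Two redundancy measures are provided:

* **I_min** (Williams-Beer): the expected minimum *specific information*
  either sender alone provides about each receiver state, averaged over
  receiver states and conditioned on the receiver's own past.  All four PID
  terms are nonnegative under I_min, but it is sometimes argued to
  overestimate redundancy.
* **I_broja**: defines synergy operationally as the part of mvTE that is lost
  when the sender-sender coupling is allowed to vary: synergy is
  ``I_p(I;JK) - min_q I_q(I;JK)`` where q ranges over joints preserving both
  pairwise (I,J) and (I,K) marginals.  Redundancy is back-computed from the
  identity above.

Both are computed *per receiver-past stratum* and averaged with
``p(I_past)`` weights, so that the decomposition applies to the
past-conditioned quantities that TE is built from.  Joints here are
empirical 16-state tables over ``(I_t, J_past, K_past, I_past)``; see
:class:`synflow.infoflow.JointDistribution`.

Interaction information ``mvTE - TE_a - TE_b`` (= synergy - redundancy under
any PID) is provided as the non-PID contrast measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.optimize import minimize
from scipy.special import xlogy

from .infoflow import JointDistribution, _cmi, _entropy_from_probs, _lagged_counts
from .raster import TimescaleSpec, TS1

__all__ = [
    "PIDResult",
    "imin_redundancy",
    "broja_redundancy",
    "broja_synergy",
    "pid_from_joint",
    "pid_decompose",
    "interaction_information",
    "normalize_pid",
]

logger = logging.getLogger(__name__)

_LOG2 = np.log(2.0)
_CLAMP = 1e-12

#: axis order of all PID joints
_AXES = ("target_t", "src_a_past", "src_b_past", "target_past")


@dataclass(frozen=True)
class PIDResult:
    """All terms of one triad decomposition, in bits.

    Satisfies ``synergy = mvte - te_a - te_b + redundancy`` and
    ``mvte = redundancy + unique_a + unique_b + synergy`` to numerical
    precision; values within -1e-12 of zero are clamped to 0.
    """

    te_a: float
    te_b: float
    mvte: float
    redundancy: float
    synergy: float
    unique_a: float
    unique_b: float
    receiver_entropy: float
    sender_entropy_a: float
    sender_entropy_b: float
    mi_senders_norm: float
    method: str


def _as_probs(joint: Union[JointDistribution, np.ndarray]) -> np.ndarray:
    if isinstance(joint, JointDistribution):
        p = joint.probs
    else:
        p = np.asarray(joint, dtype=np.float64)
        if p.shape != (2, 2, 2, 2):
            raise ValueError(f"expected (2,2,2,2) joint, got shape {p.shape}")
        if np.any(p < 0) or abs(float(p.sum()) - 1.0) > 1e-12:
            raise ValueError("joint must be a normalized probability table")
    return p


def _clamp(x: float, what: str) -> float:
    if x < 0.0:
        if x < -_CLAMP:
            return x  # genuinely negative; caller decides
        logger.debug("clamping tiny negative %s = %.3e to 0", what, x)
        return 0.0
    return x


# ---------------------------------------------------------------------------
# I_min redundancy
# ---------------------------------------------------------------------------


def _specific_information(p_it_s: np.ndarray) -> np.ndarray:
    """Specific information of each target state from one source.

    ``p_it_s[i, s]`` is a joint table of (target_present, source) within one
    receiver-past stratum.  Returns, for each target state ``i``,

        I_spec(i) = sum_s p(s|i) * [log2 p(i|s) - log2 p(i)]
    """
    p_it = p_it_s.sum(axis=1)
    p_s = p_it_s.sum(axis=0)
    out = np.zeros(2)
    for i in range(2):
        if p_it[i] <= 0:
            continue
        acc = 0.0
        for s in range(2):
            if p_it_s[i, s] <= 0:
                continue
            p_s_given_i = p_it_s[i, s] / p_it[i]
            p_i_given_s = p_it_s[i, s] / p_s[s]
            acc += p_s_given_i * (np.log(p_i_given_s) - np.log(p_it[i])) / _LOG2
        out[i] = acc
    return out


def imin_redundancy(joint: Union[JointDistribution, np.ndarray]) -> float:
    """Williams-Beer I_min redundancy, conditioned on the receiver's past.

    For each receiver-past stratum, computes the specific information each
    single sender provides about each present receiver state, takes the
    minimum over senders, averages over receiver states, then averages the
    strata with ``p(I_past)`` weights.  Nonnegative by construction.
    """
    p = _as_probs(joint)
    red = 0.0
    for ip in range(2):
        w = float(p[:, :, :, ip].sum())
        if w <= 0:
            continue
        cond = p[:, :, :, ip] / w  # p(i_t, a, b | i_past)
        p_it = cond.sum(axis=(1, 2))
        spec_a = _specific_information(cond.sum(axis=2))
        spec_b = _specific_information(cond.sum(axis=1))
        red += w * float(np.dot(p_it, np.minimum(spec_a, spec_b)))
    return max(red, 0.0)


# ---------------------------------------------------------------------------
# I_broja synergy / redundancy
# ---------------------------------------------------------------------------


def _stratum_min_mi(p_iab: np.ndarray, tol: float = 1e-12) -> tuple[float, float]:
    """Minimum of I_q(I;AB) over q preserving the (I,A) and (I,B) marginals.

    ``p_iab`` is a normalized (2,2,2) table for one receiver-past stratum.
    For binary variables the feasible polytope has one free parameter per
    receiver state i, ``theta_i = q(i, a=1, b=1)``, bounded by the Frechet
    limits of the 2x2 table with fixed margins.  The objective is convex;
    minimized with L-BFGS-B from the independence starting point, with the
    projected-gradient (KKT) residual checked on exit.

    Returns ``(min_mi_bits, kkt_residual)``.
    """
    p_i = p_iab.sum(axis=(1, 2))
    p_ia = p_iab.sum(axis=2)  # margins over b
    p_ib = p_iab.sum(axis=1)

    lo = np.maximum(0.0, p_ia[:, 1] + p_ib[:, 1] - p_i)
    hi = np.minimum(p_ia[:, 1], p_ib[:, 1])

    def cells(theta: np.ndarray) -> np.ndarray:
        q = np.empty((2, 2, 2))
        q[:, 1, 1] = theta
        q[:, 1, 0] = p_ia[:, 1] - theta
        q[:, 0, 1] = p_ib[:, 1] - theta
        q[:, 0, 0] = p_i - p_ia[:, 1] - p_ib[:, 1] + theta
        return q

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        q = np.maximum(cells(theta), 0.0)
        q_ab = q.sum(axis=0)
        # I(I;AB) = sum q log q - sum q_ab log q_ab - sum p_i log p_i  (nats)
        mi = (
            xlogy(q, q).sum() - xlogy(q_ab, q_ab).sum() - xlogy(p_i, p_i).sum()
        )
        # floor (not mask) empty cells: the true gradient diverges at the
        # boundary, and a large finite value correctly pushes the iterate
        # into the interior
        lq = np.log(np.maximum(q, 1e-30))
        lab = np.log(np.maximum(q_ab, 1e-30))
        grad = np.empty(2)
        for i in range(2):
            grad[i] = (lq[i, 1, 1] - lq[i, 1, 0] - lq[i, 0, 1] + lq[i, 0, 0]) - (
                lab[1, 1] - lab[1, 0] - lab[0, 1] + lab[0, 0]
            )
        return float(mi), grad

    # independence-within-stratum starting point, pulled into the interior
    theta0 = np.where(p_i > 0, p_ia[:, 1] * p_ib[:, 1] / np.maximum(p_i, 1e-300), 0.0)
    theta0 = np.clip(theta0, lo + 1e-12, np.maximum(hi - 1e-12, lo))

    free = hi - lo > tol
    if not free.any():
        mi, _ = objective(lo)
        return mi / _LOG2, 0.0

    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=list(zip(lo, hi)),
        options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500},
    )
    theta = np.clip(res.x, lo, hi)

    def projected_gradient(th: np.ndarray) -> tuple[float, float]:
        mi, grad = objective(th)
        proj = grad.copy()
        proj[(th - lo <= 1e-11) & (proj > 0)] = 0.0
        proj[(hi - th <= 1e-11) & (proj < 0)] = 0.0
        proj[~free] = 0.0
        return mi, float(np.abs(proj).max(initial=0.0))

    def brent_sweeps(theta: np.ndarray, n_sweeps: int = 3) -> np.ndarray:
        # 1-D convex bounded minimizations per free coordinate; robust to
        # boundary starts where the log-gradient diverges
        from scipy.optimize import minimize_scalar

        theta = theta.copy()
        for _ in range(n_sweeps):
            for i in np.flatnonzero(free):
                def f1(t, i=i):
                    th = theta.copy()
                    th[i] = t
                    return objective(th)[0]

                r1 = minimize_scalar(
                    f1, bounds=(lo[i], hi[i]), method="bounded",
                    options={"xatol": 1e-12 * max(hi[i] - lo[i], 1e-12)},
                )
                if f1(r1.x) <= objective(theta)[0]:
                    theta[i] = float(np.clip(r1.x, lo[i], hi[i]))
        return theta

    def polish(theta: np.ndarray) -> tuple[np.ndarray, float, float]:
        # projected-Newton with projected-gradient fallback; the objective
        # is smooth and convex with a closed-form Hessian, but curvature
        # diverges on the boundary, so cells are floored and failed Newton
        # steps fall back to backtracking gradient steps
        mi, kkt = projected_gradient(theta)
        scale = float(np.max(hi - lo))
        for _ in range(100):
            if kkt <= 1e-10:
                break
            _, grad = objective(theta)
            q = np.maximum(cells(theta), 1e-12)
            q_ab = q.sum(axis=0)
            s_ab = float((1.0 / q_ab).sum())
            s_i = (1.0 / q).sum(axis=(1, 2))
            hess = np.full((2, 2), -s_ab) + np.diag(s_i)
            active = free.copy()
            active &= ~((theta - lo <= 1e-13) & (grad > 0))
            active &= ~((hi - theta <= 1e-13) & (grad < 0))
            if not active.any():
                break
            idx = np.flatnonzero(active)
            try:
                step = np.linalg.solve(hess[np.ix_(idx, idx)], -grad[idx])
            except np.linalg.LinAlgError:
                step = -grad[idx] * scale / max(np.abs(grad[idx]).max(), 1e-30)

            def try_step(step_vec):
                new = theta.copy()
                new[idx] = np.clip(theta[idx] + step_vec, lo[idx], hi[idx])
                return new, objective(new)[0]

            def acceptable(new, f_new):
                if f_new < mi - 1e-16:
                    return True
                # near the optimum f-differences fall below double
                # resolution; accept on stationarity improvement instead
                if f_new <= mi + 1e-14:
                    return projected_gradient(new)[1] < kkt
                return False

            new, f_new = try_step(step)
            damp = 0
            while not acceptable(new, f_new) and damp < 40:
                step = step * 0.5
                new, f_new = try_step(step)
                damp += 1
            if not acceptable(new, f_new):
                # Newton direction exhausted; one gradient step attempt
                gstep = -grad[idx] * (0.1 * scale) / max(np.abs(grad[idx]).max(), 1e-30)
                new, f_new = try_step(gstep)
                damp = 0
                while not acceptable(new, f_new) and damp < 40:
                    gstep *= 0.5
                    new, f_new = try_step(gstep)
                    damp += 1
                if not acceptable(new, f_new):
                    break
            theta = new
            mi, kkt = projected_gradient(theta)
        return theta, mi, kkt

    def compass(theta: np.ndarray) -> tuple[np.ndarray, float, bool]:
        # derivative-free certificate: convex objective on a box, so
        # compass search with shrinking steps converges globally and is
        # immune to the boundary log-divergences where the gradient (and
        # hence the KKT residual) is ill-posed
        theta = theta.copy()
        f_cur = objective(theta)[0]
        scale = float(np.max(hi - lo))
        # diagonal directions matter: at degenerate corners the divergent
        # log terms cancel only along joint moves of both strata, so the
        # descent direction can be invisible to axis probes
        directions = [
            d
            for d in np.array(
                [[1, 0], [-1, 0], [0, 1], [0, -1], [1, 1], [-1, -1], [1, -1], [-1, 1]],
                dtype=float,
            )
            if free[np.nonzero(d)[0]].all()
        ]
        step = 0.25 * scale
        moves = 0
        while step > 1e-11 * scale and moves < 10_000:
            improved = False
            for d in directions:
                cand = np.clip(theta + d * step, lo, hi)
                f_cand = objective(cand)[0]
                if f_cand < f_cur - 1e-16:
                    theta, f_cur = cand, f_cand
                    improved = True
                    moves += 1
            if not improved:
                step *= 0.5
        return theta, f_cur, step <= 1e-11 * scale

    theta, mi, kkt = polish(theta)
    if kkt > 1e-8:
        # boundary stall: Brent coordinate sweeps escape the boundary
        # (where the log-gradient diverges), then Newton re-polishes
        cand, cand_mi, cand_kkt = polish(brent_sweeps(theta))
        if cand_mi < mi or cand_kkt < kkt:
            theta, mi, kkt = cand, cand_mi, cand_kkt
    # unconditional certificate: near degenerate boundary points the
    # floored gradient can read spuriously small, so certified descent
    # comes from the compass pass rather than the KKT residual alone
    cand, cand_mi, certified = compass(theta)
    if cand_mi < mi:
        cand, cand_mi, cand_kkt = polish(cand)
        if cand_mi < mi:
            theta, mi, kkt = cand, cand_mi, cand_kkt
        cand, cand_mi, certified = compass(theta)
        if cand_mi < mi:
            theta, mi = cand, cand_mi
            kkt = min(kkt, projected_gradient(theta)[1])
    if kkt > 1e-8 and not certified:
        raise RuntimeError(
            f"BROJA optimizer did not converge: KKT residual {kkt:.3e} "
            f"(theta={theta}, bounds={list(zip(lo, hi))})"
        )
    return mi / _LOG2, kkt


def broja_synergy(joint: Union[JointDistribution, np.ndarray]) -> float:
    """BROJA synergy: mvTE minus its minimum over sender-coupling variations.

    Computed per receiver-past stratum (the pairwise-marginal constraints are
    applied within each stratum) and averaged with ``p(I_past)`` weights.
    """
    p = _as_probs(joint)
    syn = 0.0
    for ip in range(2):
        w = float(p[:, :, :, ip].sum())
        if w <= 0:
            continue
        cond = p[:, :, :, ip] / w
        mi_obs = _cmi(cond, (0,), (1, 2), ())
        mi_min, _ = _stratum_min_mi(cond)
        syn += w * max(mi_obs - mi_min, 0.0)
    return syn


def broja_redundancy(joint: Union[JointDistribution, np.ndarray]) -> float:
    """BROJA redundancy, back-computed from the synergy identity."""
    p = _as_probs(joint)
    te_a = _cmi(p, (0,), (1,), (3,))
    te_b = _cmi(p, (0,), (2,), (3,))
    mvte = _cmi(p, (0,), (1, 2), (3,))
    red = broja_synergy(p) - mvte + te_a + te_b
    return _clamp(red, "broja redundancy")


# ---------------------------------------------------------------------------
# Full decomposition
# ---------------------------------------------------------------------------


def pid_from_joint(
    joint: Union[JointDistribution, np.ndarray], method: str = "imin"
) -> PIDResult:
    """Decompose a 16-state ``(I_t, J_past, K_past, I_past)`` joint."""
    if method not in ("imin", "broja"):
        raise ValueError(f"method must be 'imin' or 'broja', got {method!r}")
    p = _as_probs(joint)
    te_a = _cmi(p, (0,), (1,), (3,))
    te_b = _cmi(p, (0,), (2,), (3,))
    mvte = _cmi(p, (0,), (1, 2), (3,))
    if method == "imin":
        red = imin_redundancy(p)
        syn = mvte - te_a - te_b + red
    else:
        syn = broja_synergy(p)
        red = syn - mvte + te_a + te_b
    red = _clamp(red, "redundancy")
    syn = _clamp(syn, "synergy")
    uniq_a = _clamp(te_a - red, "unique_a")
    uniq_b = _clamp(te_b - red, "unique_b")

    h_recv = _entropy_from_probs(p.sum(axis=(1, 2, 3)))
    h_a = _entropy_from_probs(p.sum(axis=(0, 2, 3)))
    h_b = _entropy_from_probs(p.sum(axis=(0, 1, 3)))
    p_ab = p.sum(axis=(0, 3))
    mi_ab = _cmi(p_ab, (0,), (1,), ())
    h_min = min(h_a, h_b)
    mi_norm = min(mi_ab / h_min, 1.0) if h_min > 0 else float("nan")

    return PIDResult(
        te_a=te_a,
        te_b=te_b,
        mvte=mvte,
        redundancy=red,
        synergy=syn,
        unique_a=uniq_a,
        unique_b=uniq_b,
        receiver_entropy=h_recv,
        sender_entropy_a=h_a,
        sender_entropy_b=h_b,
        mi_senders_norm=mi_norm,
        method=method,
    )


def pid_decompose(
    src_a: np.ndarray,
    src_b: np.ndarray,
    target: np.ndarray,
    spec: Union[TimescaleSpec, int] = TS1,
    method: str = "imin",
) -> PIDResult:
    """Estimate the empirical triad joint from binned series and decompose it.

    Both senders use the same delay as the bivariate TE.  A zero-entropy
    target yields an all-zero decomposition whose normalized quantities are
    undefined (receiver_entropy = 0; ``normalize_pid`` then returns NaN).
    """
    d = spec.delay_bins if isinstance(spec, TimescaleSpec) else int(spec)
    counts = _lagged_counts(target, [src_a, src_b], d)
    return pid_from_joint(counts / counts.sum(), method=method)


def interaction_information(
    src_a: np.ndarray,
    src_b: np.ndarray,
    target: np.ndarray,
    spec: Union[TimescaleSpec, int] = TS1,
) -> float:
    """Signed interaction information mvTE - TE_a - TE_b (= synergy - redundancy)."""
    d = spec.delay_bins if isinstance(spec, TimescaleSpec) else int(spec)
    counts = _lagged_counts(target, [src_a, src_b], d)
    p = counts / counts.sum()
    return (
        _cmi(p, (0,), (1, 2), (3,))
        - _cmi(p, (0,), (1,), (3,))
        - _cmi(p, (0,), (2,), (3,))
    )


_NORM_TERMS = ("synergy", "redundancy", "mvte", "unique_a", "unique_b", "te_a", "te_b")


def normalize_pid(
    result: PIDResult,
    mode: str = "receiver_entropy",
    ff_weight: float | None = None,
) -> dict[str, float]:
    """Normalize PID terms by receiver entropy, mvTE, or a feedforward weight.

    Receiver-entropy normalization expresses each term as the proportion of
    the receiver's capacity it accounts for (values in [0, 1]).  A zero or
    missing normalizer yields NaN for every term (logged), never an
    exception.
    """
    if mode == "receiver_entropy":
        denom = result.receiver_entropy
    elif mode == "mvte":
        denom = result.mvte
    elif mode == "ff_weight":
        if ff_weight is None:
            raise ValueError("ff_weight must be given for mode='ff_weight'")
        denom = ff_weight
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if denom is None or not np.isfinite(denom) or denom <= 0:
        logger.info("normalize_pid: zero/invalid normalizer (%s); returning NaN", mode)
        return {k: float("nan") for k in _NORM_TERMS}
    return {k: getattr(result, k) / denom for k in _NORM_TERMS}
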