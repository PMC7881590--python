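"""Compressive k-means: centroid estimation from a data sketch.

Given the sketch SK of an embedded dataset and the frequency set that
produced it, CKM searches for k feature-space centroids c_1..c_k and
non-negative weights alpha_1..alpha_k minimizing

    || SK - sum_i alpha_i SK(c_i) ||_2^2          (the sketch-matching objective)

where SK(c) is the random Fourier feature of a single point.  The solver is a
greedy matching-pursuit heuristic: it alternates expanding the centroid set
with the point whose (unit-normalized) sketch is most correlated with the
current residual and re-solving the weights by non-negative least squares;
a final joint minimization polishes all centroids and weights together.
Complexity depends on (m, s, k) only, never on the dataset size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .compression import FrequencySet, Sketch, sketch_point

__all__ = ["CentroidSet", "ckm_fit", "residual", "nnls_weights"]


@dataclass
class CentroidSet:
    """k feature-space centroids with non-negative mixture weights.

    Ordered by decreasing weight; ``weights`` are renormalized to sum to 1
    for reporting while ``raw_weights`` keeps the NNLS solution.
    """

    centroids: np.ndarray    # k x s
    weights: np.ndarray      # k, normalized
    raw_weights: np.ndarray  # k, as returned by NNLS
    k: int
    objective: float


def residual(
    data_sketch: Sketch, centroids: np.ndarray, weights: np.ndarray,
    freqs: FrequencySet,
) -> np.ndarray:
    """data_sketch - sum_i alpha_i SK(c_i), as a complex m-vector."""
    res = data_sketch.values.copy()
    for c, a in zip(np.atleast_2d(centroids), np.atleast_1d(weights)):
        res -= a * sketch_point(c, freqs)
    return res


def nnls_weights(centroid_sketches: np.ndarray, data_sketch: Sketch) -> np.ndarray:
    """Non-negative least-squares weights for given centroid sketches.

    The complex system is stacked into a real one of twice the rows.
    """
    S = np.atleast_2d(centroid_sketches)  # k x m complex
    A = np.vstack([S.real.T, S.imag.T])   # 2m x k
    b = np.concatenate([data_sketch.values.real, data_sketch.values.imag])
    alpha, _ = _scipy_nnls(A, b)
    return alpha


def _objective(sk_values, centroids, weights, freqs):
    model = np.zeros_like(sk_values)
    for c, a in zip(centroids, weights):
        model += a * sketch_point(c, freqs)
    return float(np.abs(sk_values - model).__pow__(2).sum())


def _corr_and_grad(c, res, freqs):
    """Correlation Re<SK(c), res> (SK(c) has unit norm) and its gradient in c."""
    s = sketch_point(c, freqs)
    corr = float(np.real(np.vdot(s, res)))
    # d conj(s_j)/dc = i w_j conj(s_j)
    grad = freqs.frequencies.T @ np.real(1j * np.conj(s) * res)
    return corr, grad


def _ascend_correlation(c0, res, freqs, max_iter=100, tol=1e-8):
    """Gradient ascent with backtracking on the residual correlation."""
    c = c0.copy()
    f, g = _corr_and_grad(c, res, freqs)
    step = 1.0
    for _ in range(max_iter):
        gnorm2 = float(g @ g)
        if gnorm2 < tol**2:
            break
        # backtracking (Armijo) on -f
        accepted = False
        for _bt in range(30):
            cand = c + step * g
            f_new, g_new = _corr_and_grad(cand, res, freqs)
            if f_new >= f + 1e-4 * step * gnorm2:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        if abs(f_new - f) <= tol * max(abs(f), 1.0):
            c, f, g = cand, f_new, g_new
            break
        c, f, g = cand, f_new, g_new
        step = min(step * 2.0, 1e6)
    return c, f


def _joint_grad_centroids(sk_values, centroids, weights, freqs):
    """Gradient of the sketch-matching objective w.r.t. each centroid."""
    sketches = np.array([sketch_point(c, freqs) for c in centroids])
    res = sk_values - weights @ sketches
    grads = np.empty_like(centroids)
    for i, (c, a) in enumerate(zip(centroids, weights)):
        # d res_j / dc_i = alpha_i * i * w_j * s_j(c_i)
        grads[i] = 2.0 * a * (
            freqs.frequencies.T @ np.real(1j * np.conj(res) * sketches[i])
        )
    return grads, float(np.abs(res).__pow__(2).sum())


def _joint_minimize(sk_values, centroids, weights, freqs,
                    max_iter=300, rel_tol=1e-6):
    """Alternating polish: projected descent on centroids, NNLS on weights.

    Each iteration takes a backtracking gradient step on all centroids (which
    cannot increase the objective) followed by an exact NNLS re-weighting
    (which cannot increase it either), so the objective is non-increasing.
    """
    C = centroids.copy()
    alpha = weights.copy()
    sketch_obj = Sketch(values=sk_values, n_points=1)
    f_prev = _objective(sk_values, C, alpha, freqs)
    step = 1.0
    history = [f_prev]
    for _ in range(max_iter):
        grads, f_cur = _joint_grad_centroids(sk_values, C, alpha, freqs)
        gnorm2 = float((grads**2).sum())
        if gnorm2 > 0:
            accepted = False
            for _bt in range(30):
                C_new = C - step * grads
                f_new = _objective(sk_values, C_new, alpha, freqs)
                if f_new <= f_cur - 1e-4 * step * gnorm2:
                    accepted = True
                    break
                step *= 0.5
            if accepted:
                C = C_new
                step = min(step * 2.0, 1e6)
        sketches = np.array([sketch_point(c, freqs) for c in C])
        alpha = nnls_weights(sketches, sketch_obj)
        f_now = _objective(sk_values, C, alpha, freqs)
        history.append(f_now)
        if abs(f_prev - f_now) <= rel_tol * max(f_prev, 1e-30):
            break
        f_prev = f_now
    return C, alpha, history


def ckm_fit(
    data_sketch: Sketch,
    freqs: FrequencySet,
    k: int,
    init_points: np.ndarray,
    seed: int = 0,
    n_starts: int = 3,
    n_polish_starts: int = 4,
    verbose: bool = False,
) -> CentroidSet:
    """Estimate k centroids from a data sketch by compressive k-means.

    ``init_points`` is a cloud of feature-space points (typically the embedded
    Nyström landmarks) from which multi-start candidates are drawn.  Runs k
    greedy expansions, each followed by NNLS re-weighting, then a joint
    gradient polish of all centroids and weights.  Deterministic given
    (seed, sketch, freqs, init_points).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    m, s = freqs.frequencies.shape
    if m < k * s:
        import warnings

        warnings.warn(
            f"sketch size m={m} below the k*s={k * s} sizing guidance; "
            "centroid recovery may be unreliable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    init_points = np.atleast_2d(np.asarray(init_points, dtype=float))

    def _propose(res):
        """Best centroid for the current residual: score every init point's
        sketch correlation (cheap), gradient-ascend from the top starts."""
        phases = init_points @ freqs.frequencies.T  # n_init x m
        init_sk = np.exp(-1j * phases) / np.sqrt(freqs.m)
        scores = np.real(np.conj(init_sk) @ res)
        ranked = np.argsort(-scores, kind="stable")
        # top starts plus one random for diversity
        start_ids = list(ranked[: max(n_starts - 1, 1)])
        start_ids.append(int(rng.integers(init_points.shape[0])))
        best_c, best_f = None, -np.inf
        for i in start_ids:
            c_opt, f_opt = _ascend_correlation(init_points[i], res, freqs)
            if f_opt > best_f:
                best_c, best_f = c_opt, f_opt
        return best_c, best_f

    centroids: list[np.ndarray] = []
    alpha = np.zeros(0)
    for _t in range(k):
        res = residual(data_sketch, np.array(centroids).reshape(-1, s), alpha, freqs)
        best_c, _best_f = _propose(res)
        centroids.append(best_c)
        sketches = np.array([sketch_point(c, freqs) for c in centroids])
        alpha = nnls_weights(sketches, data_sketch)

    # replacement pass: one fresh proposal per centroid (2k proposals total),
    # kept only when it lowers the objective
    for i in range(k):
        others = [c for t, c in enumerate(centroids) if t != i]
        res_i = residual(
            data_sketch, np.array(others).reshape(-1, s),
            np.delete(alpha, i), freqs,
        ) if k > 1 else data_sketch.values.copy()
        best_c, _best_f = _propose(res_i)
        trial = list(centroids)
        trial[i] = best_c
        trial_sketches = np.array([sketch_point(c, freqs) for c in trial])
        trial_alpha = nnls_weights(trial_sketches, data_sketch)
        cur_obj = _objective(data_sketch.values, np.array(centroids), alpha, freqs)
        if _objective(data_sketch.values, np.array(trial), trial_alpha, freqs) < cur_obj:
            centroids, alpha = trial, trial_alpha

    C_greedy, alpha_greedy = np.array(centroids), alpha.copy()
    greedy_obj = _objective(data_sketch.values, C_greedy, alpha_greedy, freqs)

    # joint polish from the greedy solution plus a few random k-subsets of the
    # init cloud; the sketch objective is multimodal and restarts of the
    # smooth descent are the cheapest effective global search
    inits = [(C_greedy, alpha_greedy)]
    for _ in range(n_polish_starts):
        ids = rng.choice(init_points.shape[0], size=k, replace=init_points.shape[0] < k)
        C0 = init_points[ids]
        a0 = nnls_weights(np.array([sketch_point(c, freqs) for c in C0]), data_sketch)
        inits.append((C0, a0))
    C, alpha, final_obj, history = C_greedy, alpha_greedy, greedy_obj, [greedy_obj]
    for C0, a0 in inits:
        C_try, a_try, hist = _joint_minimize(data_sketch.values, C0, a0, freqs)
        if hist[-1] < final_obj:  # keeps the contract: never worse than greedy
            C, alpha, final_obj, history = C_try, a_try, hist[-1], hist
    if verbose:
        for i, f in enumerate(history):
            print(f"  ckm polish iter {i}: objective {f:.6e}")

    order = np.argsort(-alpha, kind="stable")
    C, alpha = C[order], alpha[order]
    total = alpha.sum()
    weights = alpha / total if total > 0 else alpha
    return CentroidSet(
        centroids=C, weights=weights, raw_weights=alpha, k=k, objective=final_obj
    )
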