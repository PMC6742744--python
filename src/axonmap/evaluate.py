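"""Quantitative validation of the segmentation methods.

Two complementary views:

* **Hausdorff distance** between the selected electrode coordinates and a
  ground-truth arbor point set, H(A, E) = max of the two directed sup-inf
  Euclidean distances — a shape-disagreement measure.

* **Mixture-model ROC.**  Each method's per-electrode score distribution is
  fitted with a two-component mixture separating axonal signals (positive
  class P) from background (negative class N):

  - method I scores x = log(V_n / s_n): two normal components, the one with
    the smaller mean labeled background;
  - method II scores x = s_tau / (T/2) in [0, 1]: a beta component for the
    background (broad mode near 2/sqrt(12)) plus a truncated exponential
    lam * exp(-lam x) / (1 - exp(-lam)) for the near-zero axonal mode.

  TPR and FPR follow from the fitted component CDFs for every threshold;
  the area under the ROC curve summarizes separability per neuron.

Both fits are expectation-maximization with exact M-steps, so the observed
log-likelihood is non-decreasing across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial.distance import directed_hausdorff
from scipy.special import betaln, digamma, logsumexp
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .geometry import ElectrodeLayout
from .segment import (
    Segmentation,
    delay_sd_map,
    segment_method_I,
    segment_method_II,
    threshold_from_valley,
)
from .sort_sta import Footprint

__all__ = [
    "hausdorff",
    "MixtureFit",
    "fit_score_mixture_I",
    "fit_score_mixture_II",
    "truncexp_pdf",
    "truncexp_cdf",
    "mixture_pdf",
    "ROCResult",
    "roc_from_mixture",
    "operating_point",
    "compare_methods",
]


def clip_to_layout(
    points: np.ndarray, layout: ElectrodeLayout, margin_um: float | None = None
) -> np.ndarray:
    """Drop ground-truth points outside the recorded area.

    Electrodes cannot witness arbor stretches beyond the array, so a fair
    Hausdorff comparison restricts the reference set to the layout's
    bounding box (default margin: one pitch).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    margin = layout.pitch if margin_um is None else margin_um
    lo = layout.positions.min(axis=0) - margin
    hi = layout.positions.max(axis=0) + margin
    return points[np.all((points >= lo) & (points <= hi), axis=1)]


def hausdorff(a: np.ndarray, e: np.ndarray) -> float:
    """Hausdorff distance between two planar point sets (μm)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    e = np.atleast_2d(np.asarray(e, dtype=float))
    if a.size == 0 or e.size == 0:
        raise ValueError("point sets must be non-empty")
    return float(max(directed_hausdorff(a, e)[0], directed_hausdorff(e, a)[0]))


# --- truncated exponential on [0, 1] --------------------------------------

def truncexp_pdf(x, lam: float) -> np.ndarray:
    """Density lam * exp(-lam x) / (1 - exp(-lam)) on [0, 1]."""
    x = np.asarray(x, dtype=float)
    if abs(lam) < 1e-12:
        return np.ones_like(x)
    return lam * np.exp(-lam * x) / -np.expm1(-lam)


def truncexp_cdf(x, lam: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if abs(lam) < 1e-12:
        return x.copy()
    return np.expm1(-lam * x) / np.expm1(-lam)


def _truncexp_mean(lam: float) -> float:
    if lam < 1e-8:
        return 0.5
    return 1.0 / lam - np.exp(-lam) / -np.expm1(-lam)


def _truncexp_mle(mean: float) -> float:
    """Maximum-likelihood rate for a truncated exponential with the given
    sample mean; mean-matching is the exact MLE."""
    if mean >= 0.5 - 1e-9:
        return 1e-8
    lo, hi = 1e-6, 1e6
    return float(optimize.brentq(lambda l: _truncexp_mean(l) - mean, lo, hi))


# --- weighted beta MLE -----------------------------------------------------

def _beta_weighted_mle(
    x: np.ndarray, w: np.ndarray, x0: tuple[float, float] | None = None
) -> tuple[float, float]:
    wsum = w.sum()
    if wsum <= 0:
        return (1.0, 1.0)
    sa = float(w @ np.log(x))
    sb = float(w @ np.log1p(-x))
    if x0 is None:
        m = float(w @ x) / wsum
        v = float(w @ (x - m) ** 2) / wsum
        v = max(v, 1e-6)
        common = max(m * (1 - m) / v - 1.0, 0.1)
        x0 = (max(m * common, 0.05), max((1 - m) * common, 0.05))

    def nll_grad(p):
        a, b = p
        nll = -(sa * (a - 1) + sb * (b - 1) - wsum * betaln(a, b))
        dab = digamma(a + b)
        ga = -(sa - wsum * (digamma(a) - dab))
        gb = -(sb - wsum * (digamma(b) - dab))
        return nll, np.array([ga, gb])

    res = optimize.minimize(
        nll_grad, x0=np.asarray(x0), jac=True, method="L-BFGS-B",
        bounds=[(1e-2, 1e4), (1e-2, 1e4)],
    )
    return float(res.x[0]), float(res.x[1])


@dataclass(frozen=True)
class MixtureFit:
    """Two-component score mixture: weights, parameters and fit diagnostics."""

    kind: str                     # "two-normal" | "beta-truncexp"
    weight_neg: float
    weight_pos: float
    params: dict
    loglik: float
    n: int
    converged: bool
    loglik_trace: tuple = field(default=(), repr=False)


def _nm_component_logpdf(x, mu, sigma):
    return norm.logpdf(x, loc=mu, scale=sigma)


def _run_em_normal(x, w, mu, sg, max_iter, tol):
    trace = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        log_r = np.stack(
            [
                np.log(w[0]) + _nm_component_logpdf(x, mu[0], sg[0]),
                np.log(w[1]) + _nm_component_logpdf(x, mu[1], sg[1]),
            ]
        )
        norm_c = logsumexp(log_r, axis=0)
        ll = float(norm_c.sum())
        trace.append(ll)
        r = np.exp(log_r - norm_c)
        w = r.mean(axis=1)
        w = np.clip(w, 1e-10, None)
        w = w / w.sum()
        for c in (0, 1):
            rc = r[c]
            tot = rc.sum()
            mu[c] = rc @ x / tot
            sg[c] = np.sqrt(max(rc @ (x - mu[c]) ** 2 / tot, 1e-12))
        if ll - prev < tol * max(1.0, abs(ll)):
            converged = True
            break
        prev = ll
    return w, mu, sg, trace, converged


def fit_score_mixture_I(
    scores: np.ndarray,
    rng: np.random.Generator | None = None,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-10,
    min_scores: int = 50,
) -> MixtureFit:
    """EM fit of a two-normal mixture to method-I scores x = log(V_n/s_n).

    Initialized by method-of-moments on a quantile split; restarted with
    seeded random split points and the best likelihood kept.  The component
    with the smaller mean is labeled N (background).
    """
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_scores:
        raise ValueError(f"need >= {min_scores} scores, got {x.size}")
    rng = rng if rng is not None else np.random.default_rng(0)

    splits = [0.5] + list(rng.uniform(0.2, 0.8, size=max(n_restarts - 1, 0)))
    best = None
    for q in splits:
        cut = np.quantile(x, q)
        lo, hi = x[x <= cut], x[x > cut]
        if lo.size < 2 or hi.size < 2:
            continue
        mu = np.array([lo.mean(), hi.mean()])
        sg = np.array([max(lo.std(), 1e-3), max(hi.std(), 1e-3)])
        w = np.array([lo.size, hi.size], dtype=float) / x.size
        w, mu, sg, trace, conv = _run_em_normal(x, w, mu.copy(), sg.copy(), max_iter, tol)
        if best is None or trace[-1] > best[4][-1]:
            best = (w, mu, sg, conv, trace)
    w, mu, sg, conv, trace = best
    order = np.argsort(mu)       # N = smaller mean
    i_n, i_p = int(order[0]), int(order[1])
    return MixtureFit(
        kind="two-normal",
        weight_neg=float(w[i_n]),
        weight_pos=float(w[i_p]),
        params={
            "mu_n": float(mu[i_n]),
            "sigma_n": float(sg[i_n]),
            "mu_p": float(mu[i_p]),
            "sigma_p": float(sg[i_p]),
        },
        loglik=float(trace[-1]),
        n=int(x.size),
        converged=bool(conv),
        loglik_trace=tuple(trace),
    )


def fit_score_mixture_II(
    scores: np.ndarray,
    rng: np.random.Generator | None = None,
    n_restarts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-10,
    min_scores: int = 50,
) -> MixtureFit:
    """EM fit of p_N * Beta(alpha, beta) + p_P * TruncExp(lambda) on [0, 1]
    to method-II scores x = s_tau / (T/2).

    The truncated-exponential component (concentrated near zero) is the
    axonal, positive class.  Both M-steps are exact maximum likelihood
    (mean-matching for the rate; weighted numerical MLE for the beta), so
    the log-likelihood is monotone.
    """
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_scores:
        raise ValueError(f"need >= {min_scores} scores, got {x.size}")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("method-II scores must lie in [0, 1]")
    x = np.clip(x, 1e-9, 1 - 1e-9)
    rng = rng if rng is not None else np.random.default_rng(0)

    splits = [0.15] + list(rng.uniform(0.03, 0.4, size=max(n_restarts - 1, 0)))
    best = None
    for cut in splits:
        low = x < cut
        p_pos = np.clip(low.mean(), 0.02, 0.8)
        m_pos = x[low].mean() if low.any() else cut / 2
        lam = _truncexp_mle(min(m_pos, 0.49))
        a, b = _beta_weighted_mle(x, (~low).astype(float))
        w = np.array([1 - p_pos, p_pos])
        trace = []
        prev = -np.inf
        conv = False
        ab_prev = (a, b)
        for _ in range(max_iter):
            log_neg = np.log(w[0]) + beta_dist.logpdf(x, a, b)
            with np.errstate(divide="ignore"):
                log_pos = np.log(w[1]) + np.log(truncexp_pdf(x, lam))
            norm_c = logsumexp(np.stack([log_neg, log_pos]), axis=0)
            ll = float(norm_c.sum())
            trace.append(ll)
            r_pos = np.exp(log_pos - norm_c)
            r_neg = 1.0 - r_pos
            w = np.clip(
                np.array([r_neg.mean(), r_pos.mean()]), 1e-10, None
            )
            w = w / w.sum()
            tot_pos = r_pos.sum()
            if tot_pos > 0:
                lam = _truncexp_mle(float(r_pos @ x / tot_pos))
            a, b = _beta_weighted_mle(x, r_neg, x0=ab_prev)
            ab_prev = (a, b)
            if ll - prev < tol * max(1.0, abs(ll)):
                conv = True
                break
            prev = ll
        if best is None or trace[-1] > best[5][-1]:
            best = (w, lam, a, b, conv, trace)
    w, lam, a, b, conv, trace = best
    return MixtureFit(
        kind="beta-truncexp",
        weight_neg=float(w[0]),
        weight_pos=float(w[1]),
        params={"alpha_n": float(a), "beta_n": float(b), "lambda_p": float(lam)},
        loglik=float(trace[-1]),
        n=int(x.size),
        converged=bool(conv),
        loglik_trace=tuple(trace),
    )


def mixture_pdf(fit: MixtureFit, x) -> np.ndarray:
    """Density of the fitted two-component mixture at x."""
    x = np.asarray(x, dtype=float)
    if fit.kind == "two-normal":
        p = fit.params
        return fit.weight_neg * norm.pdf(x, p["mu_n"], p["sigma_n"]) + \
            fit.weight_pos * norm.pdf(x, p["mu_p"], p["sigma_p"])
    if fit.kind == "beta-truncexp":
        p = fit.params
        return fit.weight_neg * beta_dist.pdf(x, p["alpha_n"], p["beta_n"]) + \
            fit.weight_pos * truncexp_pdf(x, p["lambda_p"])
    raise ValueError(f"unknown mixture kind {fit.kind!r}")


def _class_cdfs(fit: MixtureFit, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(CDF_neg, CDF_pos) of the fitted components at x."""
    p = fit.params
    if fit.kind == "two-normal":
        return (
            norm.cdf(x, p["mu_n"], p["sigma_n"]),
            norm.cdf(x, p["mu_p"], p["sigma_p"]),
        )
    if fit.kind == "beta-truncexp":
        return (
            beta_dist.cdf(x, p["alpha_n"], p["beta_n"]),
            truncexp_cdf(x, p["lambda_p"]),
        )
    raise ValueError(f"unknown mixture kind {fit.kind!r}")


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_from_mixture(fit: MixtureFit, n_thresholds: int = 2000) -> ROCResult:
    """ROC curve from the fitted component CDFs.

    The "axon side" of a threshold is high scores for method I (large
    amplitudes) and low scores for method II (small delay SDs); TPR is the
    positive-component mass on that side, FPR the negative-component mass.
    AUC by trapezoidal integration over the FPR-sorted curve.
    """
    if fit.kind == "two-normal":
        p = fit.params
        lo = min(p["mu_n"] - 8 * p["sigma_n"], p["mu_p"] - 8 * p["sigma_p"])
        hi = max(p["mu_n"] + 8 * p["sigma_n"], p["mu_p"] + 8 * p["sigma_p"])
        thr = np.linspace(lo, hi, n_thresholds)
        cdf_n, cdf_p = _class_cdfs(fit, thr)
        fpr, tpr = 1.0 - cdf_n, 1.0 - cdf_p   # axon side: x > threshold
        order = np.argsort(fpr, kind="stable")
        thr, fpr, tpr = thr[order], fpr[order], tpr[order]
    else:
        thr = np.linspace(0.0, 1.0, n_thresholds)
        cdf_n, cdf_p = _class_cdfs(fit, thr)
        fpr, tpr = cdf_n, cdf_p               # axon side: x < threshold
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    thr = np.concatenate([[np.nan], thr, [np.nan]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def operating_point(fit: MixtureFit, threshold: float) -> tuple[float, float]:
    """(FPR, TPR) of a concrete decision threshold under the fitted mixture."""
    cdf_n, cdf_p = _class_cdfs(fit, np.asarray([threshold], dtype=float))
    if fit.kind == "two-normal":
        return float(1.0 - cdf_n[0]), float(1.0 - cdf_p[0])
    return float(cdf_n[0]), float(cdf_p[0])


def compare_methods(
    footprints: list[Footprint],
    layout: ElectrodeLayout,
    rng: np.random.Generator | None = None,
    ground_truths: dict | None = None,
    scale: int = 1,
    min_members: int = 5,
    k: float = 5.0,
) -> pd.DataFrame:
    """Per-neuron AUC (both methods), operating points, and — when ground
    truth is given — Hausdorff distances of both segmentations.

    ``ground_truths`` maps neuron label to an (n, 2) point set in the same
    μm frame as the layout.  Neurons whose segmentation comes out empty get
    NaN Hausdorff (undefined rather than infinite).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    rows = []
    for fp in footprints:
        row: dict = {"neuron": fp.neuron}

        ok = (fp.v_n > 0) & (fp.s_n > 0)
        fit_i = fit_score_mixture_I(np.log(fp.v_n[ok] / fp.s_n[ok]), rng=rng)
        row["auc_I"] = roc_from_mixture(fit_i).auc
        row["fpr_I"], row["tpr_I"] = operating_point(fit_i, np.log(k))

        dmap = delay_sd_map(fp, layout, scale=scale, min_members=min_members)
        gate = dmap.tau_ms > fp.tau_ais_ms
        pool = dmap.valid & gate & np.isfinite(dmap.s_tau_ms)
        s_vals = dmap.s_tau_ms[pool]
        x = np.clip(s_vals / (fp.T / 2.0), 1e-9, 1 - 1e-9)
        fit_ii = fit_score_mixture_II(x, rng=rng)
        row["auc_II"] = roc_from_mixture(fit_ii).auc
        s_min = threshold_from_valley(s_vals, fp.T, rng=rng)
        row["s_min_ms"] = s_min
        row["fpr_II"], row["tpr_II"] = operating_point(fit_ii, s_min / (fp.T / 2.0))

        if ground_truths is not None and fp.neuron in ground_truths:
            gt = np.asarray(ground_truths[fp.neuron], dtype=float)
            for name, seg in (
                ("hausdorff_I_um", segment_method_I(fp, k=k)),
                ("hausdorff_II_um", segment_method_II(
                    fp, layout, scale=scale, min_members=min_members,
                    s_min=s_min, rng=rng)),
            ):
                if seg.n_electrodes == 0:
                    row[name] = np.nan
                else:
                    coords = np.stack(
                        [layout.position_of(e) for e in seg.electrode_ids]
                    )
                    row[name] = hausdorff(gt, coords)
        rows.append(row)
    return pd.DataFrame(rows)
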