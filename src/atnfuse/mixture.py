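"""Mixture-model thresholding of component spatial maps.

Each map's feature values are modeled as a mixture of a Gaussian noise class
and up to two offset-Gamma signal classes (one positive, one mirrored
negative, reflecting that maps carry signed weights).  Parameters are fit by
expectation-maximization on internally standardized values; a feature is
retained when its posterior probability of belonging to any signal class
exceeds a cutoff (``mmthresh``, conventionally 0.5).

Model/Results convention: ``GammaGaussianMixture(values).fit()`` returns a
:class:`MixtureResults`; :meth:`MixtureResults.threshold` produces the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, polygamma

_MIN_SHAPE = 1.0  # keeps Gamma densities bounded at the offset


def _gamma_mle_shape(mean: float, mean_log: float, log_mean: float) -> float:
    """Weighted Gamma shape MLE: solve log(a) - digamma(a) = log(mean) - mean(log x)."""
    s = log_mean - mean_log
    if s <= 1e-12:
        return 1e6  # nearly degenerate; huge shape
    a = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(50):
        f = np.log(a) - digamma(a) - s
        fp = 1.0 / a - polygamma(1, a)
        step = f / fp
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2
        if abs(a_new - a) < 1e-10 * max(1.0, a):
            a = a_new
            break
        a = a_new
    return float(max(a, _MIN_SHAPE))


def _gamma_logpdf(x: np.ndarray, shape: float, rate: float) -> np.ndarray:
    """log density of Gamma(shape, rate) at x (x > 0 assumed where used)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = shape * np.log(rate) - gammaln(shape) + (shape - 1) * np.log(x) - rate * x
    return out


@dataclass
class MixtureResults:
    """Fitted noise + signal mixture of one spatial map.

    All parameters refer to the internally standardized values
    ``(x - mean) / sd``; posteriors and masks are reported per input feature.
    """

    noise_mean: float
    noise_sd: float
    pos_signal: tuple[float, float, float] | None   # (shape, rate, offset)
    neg_signal: tuple[float, float, float] | None   # mirrored Gamma below offset
    class_proportions: np.ndarray                   # (noise, pos, neg) simplex
    posteriors: np.ndarray                          # P(signal) per feature
    converged: bool
    loglik_trace: np.ndarray
    standardization: tuple[float, float]            # (mean, sd) of the raw map
    n_iter: int = 0
    values_std: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def threshold(self, mmthresh: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
        """Mask of features whose signal posterior exceeds ``mmthresh``.

        Returns (mask, posteriors); mmthresh = 0 keeps every feature with a
        nonzero posterior, mmthresh = 1 keeps none.
        """
        if not (0.0 <= mmthresh <= 1.0):
            raise ValueError("mmthresh must lie in [0, 1]")
        return self.posteriors > mmthresh, self.posteriors

    @property
    def signal_proportion(self) -> float:
        return float(self.class_proportions[1:].sum())

    def summary(self) -> str:
        p = self.class_proportions
        lines = ["Gaussian-Gamma mixture fit", "=" * 36,
                 f"noise: mean={self.noise_mean:.4f} sd={self.noise_sd:.4f} pi={p[0]:.3f}",
                 f"converged: {self.converged} after {self.n_iter} iterations"]
        for name, sig, pi in (("pos", self.pos_signal, p[1]), ("neg", self.neg_signal, p[2])):
            if sig is not None:
                lines.append(f"{name} signal: shape={sig[0]:.3f} rate={sig[1]:.3f} "
                             f"offset={sig[2]:.3f} pi={pi:.3f}")
        return "\n".join(lines)


class GammaGaussianMixture:
    """EM fit of a Gaussian noise class plus offset-Gamma signal class(es).

    Parameters
    ----------
    values : per-feature map statistics (>= 100 finite values).
    two_sided : model a mirrored negative-signal Gamma as well (default);
        a side whose support collapses is dropped automatically.
    seed : tie-breaking only; the fit is otherwise deterministic.
    """

    def __init__(self, values: np.ndarray, two_sided: bool = True, seed: int = 0):
        v = np.asarray(values, dtype=float).ravel()
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite map values")
        if v.size < 100:
            raise ValueError(f"need >= 100 values, got {v.size}")
        if np.ptp(v) == 0:
            raise ValueError("all-constant map")
        self.raw = v
        self.two_sided = two_sided
        self.seed = seed

    def fit(self, max_iter: int = 500, tol: float = 1e-7) -> MixtureResults:
        """Fit candidate structures (noise only, +pos, +neg, +both) by EM and
        select by BIC, so spurious signal classes are never retained on
        pure-noise maps.  A selected side is additionally dropped when its
        Gamma sits within 2 noise SDs of the noise mean (it then models the
        noise flank, not signal) or its support collapses."""
        mu_raw, sd_raw = float(self.raw.mean()), float(self.raw.std())
        x = (self.raw - mu_raw) / sd_raw
        n = x.size

        candidates = [(False, False), (True, False)]
        if self.two_sided:
            candidates += [(False, True), (True, True)]
        best = None
        for use_pos, use_neg in candidates:
            fit = _run_em(x, use_pos, use_neg, max_iter, tol)
            if fit is None:
                continue
            k_par = 2 + (3 if fit["pi"][1] > 0 else 0) + (3 if fit["pi"][2] > 0 else 0)
            bic = -2.0 * fit["loglik"][-1] + k_par * np.log(n)
            if best is None or bic < best[0] - 1e-9:
                best = (bic, fit)
        fit = best[1]
        pi, pos, neg = fit["pi"], fit["pos"], fit["neg"]
        mu0, sd0, offset = fit["mu0"], fit["sd0"], fit["offset"]

        # drop collapsed or flank-fitting signal classes (proportion -> 0)
        for j, params in ((1, pos), (2, neg)):
            if pi[j] <= 0:
                continue
            collapsed = pi[j] < 1e-3 or pi[j] * n < 5
            if params is not None:
                separation = (params[0] / params[1]) / max(sd0, 1e-12)
                collapsed = collapsed or separation < 2.0
            if collapsed:
                pi[j] = 0.0
                if j == 1:
                    pos = None
                else:
                    neg = None
        pi = pi / pi.sum()

        r = _responsibilities(x, pi, mu0, sd0, pos, neg, offset)[0]
        posteriors = r[1] + r[2]
        return MixtureResults(
            noise_mean=mu0, noise_sd=sd0,
            pos_signal=None if pos is None or pi[1] == 0 else (pos[0], pos[1], offset),
            neg_signal=None if neg is None or pi[2] == 0 else (neg[0], neg[1], offset),
            class_proportions=pi, posteriors=posteriors, converged=fit["converged"],
            loglik_trace=np.asarray(fit["loglik"]), standardization=(mu_raw, sd_raw),
            n_iter=fit["n_iter"], values_std=x)


def _responsibilities(x, pi, mu0, sd0, pos, neg, offset):
    """Class responsibilities and per-point log mixture density."""
    n = x.size
    logp = np.full((3, n), -np.inf)
    logp[0] = -0.5 * ((x - mu0) / sd0) ** 2 - np.log(sd0) - 0.5 * np.log(2 * np.pi)
    if pi[1] > 0 and pos is not None:
        mask = x > offset
        logp[1, mask] = _gamma_logpdf(x[mask] - offset, *pos)
    if pi[2] > 0 and neg is not None:
        mask = x < offset
        logp[2, mask] = _gamma_logpdf(offset - x[mask], *neg)
    with np.errstate(divide="ignore"):
        logw = logp + np.log(np.maximum(pi, 1e-300))[:, None]
    mx = logw.max(axis=0)
    lse = mx + np.log(np.exp(logw - mx).sum(axis=0))
    return np.exp(logw - lse), lse


def _run_em(x: np.ndarray, use_pos: bool, use_neg: bool, max_iter: int,
            tol: float) -> dict | None:
    """One EM run for a fixed class structure; returns None when a requested
    signal side cannot be initialized (no tail support)."""
    n = x.size
    # initialization by quantile split: central 80% -> noise moments
    lo, hi = np.quantile(x, [0.10, 0.90])
    core = x[(x >= lo) & (x <= hi)]
    mu0, sd0 = float(core.mean()), float(max(core.std(), 1e-3))
    offset = mu0  # fixed across EM so every update is a true M-step

    def init_gamma(vals: np.ndarray, side: int):
        d = side * (vals - offset)
        d = d[d > 1e-12]
        if d.size < 5:
            return None
        m, v = float(d.mean()), float(max(d.var(), 1e-6))
        return (max(m * m / v, _MIN_SHAPE), max(m * m / v, _MIN_SHAPE) / m)

    pos = init_gamma(x[x > hi], +1) if use_pos else None
    neg = init_gamma(x[x < lo], -1) if use_neg else None
    if (use_pos and pos is None) or (use_neg and neg is None):
        return None
    pi = np.array([0.8, 0.1 if pos else 0.0, 0.1 if neg else 0.0])
    pi /= pi.sum()

    dp = x - offset
    dn = offset - x
    loglik = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        r, lse = _responsibilities(x, pi, mu0, sd0, pos, neg, offset)
        ll = float(lse.sum())
        loglik.append(ll)
        # M-step; classes are never hard-dropped mid-run so the trace is
        # monotone (a collapsing side's proportion decays toward 0)
        nk = r.sum(axis=1)
        pi_new = nk / n
        mu0 = float((r[0] * x).sum() / max(nk[0], 1e-12))
        var0 = float((r[0] * (x - mu0) ** 2).sum() / max(nk[0], 1e-12))
        sd0 = float(max(np.sqrt(var0), 1e-4))

        def mstep_gamma(rj: np.ndarray, d: np.ndarray):
            w = rj * (d > 0)
            tot = w.sum()
            if tot < 1e-9:
                return None
            dm = np.maximum(d, 1e-300)
            m = float((w * d).sum() / tot)
            mlog = float((w * np.log(dm)).sum() / tot)
            shape = _gamma_mle_shape(m, mlog, float(np.log(m)))
            return (shape, shape / m)

        if pi_new[1] > 0 and pos is not None:
            upd = mstep_gamma(r[1], dp)
            pos = upd if upd is not None else pos
        if pi_new[2] > 0 and neg is not None:
            upd = mstep_gamma(r[2], dn)
            neg = upd if upd is not None else neg
        if len(loglik) >= 2 and abs(ll - loglik[-2]) < tol * (abs(loglik[-2]) + 1.0):
            pi = pi_new
            converged = True
            break
        pi = pi_new
    return {"pi": pi, "pos": pos, "neg": neg, "mu0": mu0, "sd0": sd0,
            "offset": offset, "loglik": loglik, "converged": converged, "n_iter": it}


def fit_mixture(map_values: np.ndarray, max_iter: int = 500, tol: float = 1e-7,
                seed: int = 0, two_sided: bool = True) -> MixtureResults:
    """Fit the noise + signal mixture to one component map (shorthand)."""
    return GammaGaussianMixture(map_values, two_sided=two_sided, seed=seed).fit(
        max_iter=max_iter, tol=tol)


def threshold_map(fit: MixtureResults, mmthresh: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Retain features whose signal posterior exceeds ``mmthresh``."""
    return fit.threshold(mmthresh)
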