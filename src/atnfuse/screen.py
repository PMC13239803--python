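"""Component-phenotype correlation screen and CSF-sample eligibility rules.

Per-component Pearson correlations between loadings and a clinical variable,
with Benjamini-Hochberg control of the false discovery rate across
components; eligibility selection of CSF biomarker draws relative to the
imaging visit (within one year, nearest draw, ties toward the earlier one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from statsmodels.stats.multitest import multipletests

CSF_WINDOW_DAYS = 365  # inclusive


@dataclass
class CorrelationScreen:
    """Per-component correlation results with FDR adjustment."""

    r: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray  # q < alpha
    n: np.ndarray
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": np.arange(len(self.r)),
            "r": self.r, "p": self.p, "q": self.q,
            "significant": self.significant, "n": self.n,
        })

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def summary(self) -> str:
        k = len(self.r)
        top = int(np.argmax(np.abs(self.r)))
        return (f"Correlation screen over {k} components: "
                f"{self.n_significant}/{k} significant at q < {self.alpha:g}; "
                f"strongest component {top} (r = {self.r[top]:.3f}, q = {self.q[top]:.2g})")


def correlation_screen(loadings: np.ndarray, variable: np.ndarray,
                       alpha: float = 0.05) -> CorrelationScreen:
    """Pearson r of every loading column with a variable, BH-adjusted.

    Missing values in the variable are dropped pairwise; each correlation
    needs at least 3 complete pairs; zero-variance columns raise.
    """
    Z = np.atleast_2d(np.asarray(loadings, dtype=float))
    v = np.asarray(variable, dtype=float)
    ok = np.isfinite(v)
    K = Z.shape[1]
    r = np.empty(K)
    p = np.empty(K)
    n = np.empty(K, dtype=int)
    for k in range(K):
        use = ok & np.isfinite(Z[:, k])
        if use.sum() < 3:
            raise ValueError(f"component {k}: fewer than 3 complete pairs")
        zk = Z[use, k]
        if zk.std() < 1e-12 or v[use].std() < 1e-12:
            raise ValueError(f"component {k}: zero-variance input")
        r[k], p[k] = pearsonr(zk, v[use])
        n[k] = use.sum()
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return CorrelationScreen(r=r, p=p, q=q, significant=q < alpha, n=n, alpha=alpha)


def select_csf_samples(draw_offsets_days, window_days: int = CSF_WINDOW_DAYS) -> int | None:
    """Index of the eligible CSF draw: nearest to the visit within the window.

    ``draw_offsets_days`` are signed day offsets of each draw from the
    imaging visit.  Draws farther than ``window_days`` (inclusive) are
    ineligible; among equally near draws the earlier one is chosen.  Returns
    None when no draw qualifies.
    """
    offs = np.asarray(draw_offsets_days, dtype=float)
    if offs.ndim != 1:
        raise ValueError("expected a 1-D sequence of day offsets")
    if offs.size and not np.all(np.isfinite(offs)):
        raise ValueError("malformed draw offsets")
    eligible = np.abs(offs) <= window_days
    if not eligible.any():
        return None
    idx = np.flatnonzero(eligible)
    dist = np.abs(offs[idx])
    best = dist.min()
    cands = idx[dist == best]
    return int(cands[np.argmin(offs[cands])])  # tie -> earlier draw


def select_csf_by_date(draw_dates, visit_date, window_days: int = CSF_WINDOW_DAYS) -> int | None:
    """Date-based wrapper around :func:`select_csf_samples`."""
    try:
        visit = pd.Timestamp(visit_date)
        offs = np.array([(pd.Timestamp(d) - visit).days for d in draw_dates], dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed dates: {exc}") from None
    return select_csf_samples(offs, window_days=window_days)


def csf_association(loadings: np.ndarray, component_index: int,
                    csf_values: np.ndarray) -> tuple[float, float, int]:
    """Pearson (r, p, n) between one component's loadings and a CSF biomarker.

    Only complete pairs enter; fewer than 3 raise.
    """
    z = np.asarray(loadings, dtype=float)
    if z.ndim == 2:
        z = z[:, component_index]
    v = np.asarray(csf_values, dtype=float)
    ok = np.isfinite(z) & np.isfinite(v)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 complete loading-biomarker pairs")
    r, p = pearsonr(z[ok], v[ok])
    return float(r), float(p), int(ok.sum())


def eligible_csf_mask(pheno: pd.DataFrame, window_days: int = CSF_WINDOW_DAYS) -> np.ndarray:
    """Subjects with a usable CSF draw within the eligibility window."""
    offs = pheno["csf_offset_days"].to_numpy(dtype=float)
    vals = pheno["csf_abeta42"].to_numpy(dtype=float)
    return np.isfinite(offs) & np.isfinite(vals) & (np.abs(offs) <= window_days)
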