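"""Synthetic multimodal cohort generator with known latent ground truth.

Emulates the structure of a multimodal Alzheimer's imaging study: several
subject-by-feature modality matrices sharing a low-rank latent decomposition
(shared subject loadings, per-modality sparse spatial maps, nonnegative
per-component modality weights), scanner-level additive/multiplicative batch
effects, a clinical severity target (CDR-SOB, 0-18 in half points) that is
linear in a sparse subset of the loadings, diagnosis bands derived from the
target, a binary genetic-risk carrier label driven by one designated
component, and optional CSF biomarker values with draw dates.

Every stochastic quantity is drawn from a single seeded generator so a config
plus seed fully determines the dataset, bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .datasets import DEFAULT_MODALITIES, GroundTruth, MultimodalDataset

# CDR-SOB band translation: half-point score -> clinical stage
BAND_LABELS = ("CN", "MCI_SCD", "mild", "moderate", "severe")


def band_cdr_sob(score: float) -> str:
    """Map a CDR-SOB score (half-point grid, 0-18) to its clinical stage band.

    0 -> CN; 0.5-4 -> MCI/subjective cognitive decline; 4.5-9 -> mild
    dementia; 9.5-15.5 -> moderate dementia; 16-18 -> severe dementia.
    """
    s = float(score)
    if not (0.0 <= s <= 18.0):
        raise ValueError(f"CDR-SOB score {s} outside [0, 18]")
    if abs(s * 2 - round(s * 2)) > 1e-9:
        raise ValueError(f"CDR-SOB score {s} not on the half-point grid")
    if s == 0.0:
        return "CN"
    if s <= 4.0:
        return "MCI_SCD"
    if s <= 9.0:
        return "mild"
    if s <= 15.5:
        return "moderate"
    return "severe"


def inject_batch_effects(X: np.ndarray, scanner: np.ndarray,
                         gamma: dict[str, np.ndarray],
                         delta: dict[str, np.ndarray]) -> np.ndarray:
    """Apply per-scanner location/scale batch effects to a feature matrix.

    X'[i, j] = (X[i, j] + gamma[scanner_i][j]) * delta[scanner_i][j].
    """
    X = np.asarray(X, dtype=float)
    out = np.empty_like(X)
    levels = np.unique(scanner)
    for lev in levels:
        if lev not in gamma or lev not in delta:
            raise KeyError(f"unknown scanner level {lev!r}")
        d = np.asarray(delta[lev], dtype=float)
        if np.any(d <= 0):
            raise ValueError("multiplicative batch factors must be positive")
        rows = scanner == lev
        out[rows] = (X[rows] + np.asarray(gamma[lev], dtype=float)) * d
    return out


@dataclass
class SplitAssignment:
    """Site-grouped train/validation/test assignment."""

    split: np.ndarray  # per-subject label in {"train","val","test"}
    site_to_split: dict[str, str]
    fractions: tuple[float, float, float]
    seed: int

    @property
    def train(self) -> np.ndarray:
        return np.flatnonzero(self.split == "train")

    @property
    def val(self) -> np.ndarray:
        return np.flatnonzero(self.split == "val")

    @property
    def test(self) -> np.ndarray:
        return np.flatnonzero(self.split == "test")

    def indices(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.split == name)


def grouped_split(site: np.ndarray, fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                  seed: int = 0) -> SplitAssignment:
    """Assign whole sites to train/validation/test splits.

    All subjects from one imaging site land in the same split, preventing
    site-related leakage.  Sites are shuffled (seeded) and each is assigned
    greedily to the split whose subject count is furthest below its target.
    """
    site = np.asarray(site)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    levels, counts = np.unique(site, return_counts=True)
    names = ("train", "val", "test")
    if len(levels) < len(names):
        raise ValueError(f"need at least {len(names)} sites, got {len(levels)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(levels))
    n_total = site.size
    targets = np.array(fractions) * n_total
    assigned = np.zeros(3)
    site_to_split: dict[str, str] = {}
    for idx in order:
        deficit = targets - assigned
        j = int(np.argmax(deficit))  # ties -> train, then val, then test
        site_to_split[levels[idx]] = names[j]
        assigned[j] += counts[idx]
    split = np.array([site_to_split[s] for s in site])
    return SplitAssignment(split=split, site_to_split=site_to_split,
                           fractions=tuple(fractions), seed=seed)


@dataclass
class SimulationConfig:
    """Generator configuration; defaults emulate a realistic multimodal aging cohort.

    n_subjects : cohort size.
    features_per_modality : feature count per modality (list or scalar).
    k_true : latent rank of the shared decomposition.
    sparsity : fraction of nonzero features per spatial-map column.
    snr : per-modality variance ratio var(signal)/var(noise).
    n_sites / n_scanners : site count (Dirichlet-multinomial sizes) and
        scanner-manufacturer count; every subject at one site shares a scanner.
    beta_support : number of components with nonzero target coefficient.
    target_r2 : fraction of pre-clipping target variance explained by the
        loadings (the known prediction ceiling of the simulation).
    cn_fraction : fraction of the cohort clipped to CDR-SOB 0 (cognitively
        normal mass of the cohort).
    carrier_slope : logistic slope of the carrier label on its driving
        component; carrier_prevalence sets the marginal carrier rate.
    batch_gamma_sd / batch_delta_log_sd : scale of additive and (log)
        multiplicative scanner effects; set both to 0 for a batch-free cohort.
    csf_rho_abeta / csf_rho_ptau : planted correlation between the carrier
        component's loading and CSF A-beta-42 / p-tau-181.
    csf_missing_rate : fraction of subjects without a usable CSF draw.
    """

    n_subjects: int = 300
    n_modalities: int = 5
    features_per_modality: int | list[int] = 2000
    k_true: int = 6
    sparsity: float = 0.2
    snr: float = 5.0
    n_sites: int = 12
    n_scanners: int = 3
    beta_support: int = 3
    target_r2: float = 0.85
    cn_fraction: float = 0.50
    carrier_slope: float = 4.0
    carrier_prevalence: float = 0.405
    batch_gamma_sd: float = 0.3
    batch_delta_log_sd: float = 0.1
    csf_rho_abeta: float = -0.40
    csf_rho_ptau: float = 0.50
    csf_missing_rate: float = 0.23
    modalities: tuple[str, ...] = field(default_factory=lambda: DEFAULT_MODALITIES)
    seed: int = 0

    def feature_counts(self) -> list[int]:
        p = self.features_per_modality
        if isinstance(p, int):
            return [p] * self.n_modalities
        if len(p) != self.n_modalities:
            raise ValueError("features_per_modality length must equal n_modalities")
        return list(p)

    def as_dict(self) -> dict:
        return asdict(self)


def _sparse_map(rng: np.random.Generator, p: int, sparsity: float) -> np.ndarray:
    """One spatial-map column: hard-zeroed uniform support, two-sided Gamma values."""
    col = np.zeros(p)
    k = max(1, int(round(sparsity * p)))
    idx = rng.choice(p, size=k, replace=False)
    mag = rng.gamma(shape=3.0, scale=1.0, size=k)
    sgn = rng.choice([-1.0, 1.0], size=k)
    col[idx] = mag * sgn
    return col


def _solve_carrier_intercept(slope: float, z: np.ndarray, prevalence: float) -> float:
    """Intercept b with mean(sigmoid(slope*z + b)) = prevalence (bisection)."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expit(slope * z + mid).mean() < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_dataset(config: SimulationConfig, seed: int | None = None) -> MultimodalDataset:
    """Generate a multimodal dataset with known ground truth.

    X_m = inject_batch_effects(Z diag(W_m) S_m' + E_m) with per-modality noise
    scaled to the requested signal-to-noise ratio; the target is linear in a
    sparse subset of loadings, rescaled/clipped to [0, 18] and rounded to half
    points; diagnosis bands follow :func:`band_cdr_sob`; the carrier label is
    Bernoulli with logistic probability in one designated component.
    """
    cfg = config
    if seed is not None:
        cfg = SimulationConfig(**{**config.as_dict(), "seed": seed})
    P = cfg.feature_counts()
    N, K, M = cfg.n_subjects, cfg.k_true, cfg.n_modalities
    if N < 2 * K:
        raise ValueError(f"need n_subjects >= 2*k_true ({N} < {2 * K})")
    if cfg.snr <= 0:
        raise ValueError("snr must be positive")
    if cfg.n_sites < 3:
        raise ValueError("need at least 3 sites")
    if any(K > p for p in P):
        raise ValueError("k_true exceeds a modality's feature count")
    rng = np.random.default_rng(cfg.seed)

    # latent structure
    Z = rng.standard_normal((N, K))
    maps = [np.column_stack([_sparse_map(rng, p, cfg.sparsity) for _ in range(K)]) for p in P]
    # per-component active-modality pattern: uniform subset size 1..M.
    # Weight columns are normalized to equal total energy so the nominal
    # snr applies to every component (a component is uni- vs multi-modal
    # in how its energy is distributed, not in how strong it is overall).
    W = np.zeros((M, K))
    for k in range(K):
        n_active = int(rng.integers(1, M + 1))
        active = rng.choice(M, size=n_active, replace=False)
        W[active, k] = rng.uniform(0.5, 1.5, size=n_active)
        W[:, k] *= np.sqrt(2.0) / np.linalg.norm(W[:, k])

    # sites and scanners: Dirichlet-multinomial sizes; scanner constant per site
    site_probs = rng.dirichlet(np.full(cfg.n_sites, 5.0))
    site_idx = rng.choice(cfg.n_sites, size=N, p=site_probs)
    # guarantee every site has at least one subject (relabel if needed)
    present = np.unique(site_idx)
    if present.size < cfg.n_sites:
        missing = np.setdiff1d(np.arange(cfg.n_sites), present)
        take = rng.choice(N, size=missing.size, replace=False)
        site_idx[take] = missing
    site = np.array([f"site{j:02d}" for j in site_idx])
    # balanced round-robin site-to-manufacturer assignment (every subject at
    # one site shares a scanner; each manufacturer covers several sites)
    site_scanner = np.arange(cfg.n_sites) % cfg.n_scanners
    scanner = np.array([f"scanner{site_scanner[j]}" for j in site_idx])
    scanner_levels = [f"scanner{j}" for j in range(cfg.n_scanners)]

    # signal, noise (scaled to exact empirical snr), batch effects
    X = []
    noise_sd = np.zeros(M)
    gamma = {lev: [] for lev in scanner_levels}
    delta = {lev: [] for lev in scanner_levels}
    for m in range(M):
        signal = Z @ np.diag(W[m]) @ maps[m].T
        sd_target = float(np.std(signal)) / np.sqrt(cfg.snr)
        noise = rng.standard_normal((N, P[m]))
        if sd_target > 0:
            noise -= noise.mean()
            noise *= sd_target / noise.std()
        else:
            noise[:] = 0.0
        noise_sd[m] = sd_target
        xm = signal + noise
        for lev in scanner_levels:
            g = rng.standard_normal(P[m]) * cfg.batch_gamma_sd * max(sd_target, 1e-12)
            d = np.exp(rng.standard_normal(P[m]) * cfg.batch_delta_log_sd)
            if cfg.batch_gamma_sd == 0:
                g = np.zeros(P[m])
            if cfg.batch_delta_log_sd == 0:
                d = np.ones(P[m])
            gamma[lev].append(g)
            delta[lev].append(d)
        xm = inject_batch_effects(xm, scanner, {lev: gamma[lev][m] for lev in scanner_levels},
                                  {lev: delta[lev][m] for lev in scanner_levels})
        X.append(xm)

    # target: linear in a sparse loading subset, rescaled/clipped to [0, 18]
    beta = np.zeros(K)
    support = rng.choice(K, size=min(cfg.beta_support, K), replace=False)
    beta[support] = rng.uniform(0.5, 1.5, size=support.size) * rng.choice([-1, 1], size=support.size)
    y_signal = Z @ beta
    sig_sd = float(np.std(y_signal))
    eps_sd = sig_sd * np.sqrt(1.0 / cfg.target_r2 - 1.0)
    y_lin = y_signal + rng.standard_normal(N) * eps_sd
    c = np.quantile(y_lin, cfg.cn_fraction)
    hi = np.quantile(y_lin, 0.995)
    if hi <= c:
        hi = c + 1.0
    target = np.clip((y_lin - c) / (hi - c) * 18.0, 0.0, 18.0)
    target = np.round(target * 2.0) / 2.0
    diagnosis = np.array([band_cdr_sob(t) for t in target])

    # carrier label: logistic in the designated component's loading
    carrier_k = int(support[0])
    zc = Z[:, carrier_k]
    b0 = _solve_carrier_intercept(cfg.carrier_slope, zc, cfg.carrier_prevalence)
    p_carrier = expit(cfg.carrier_slope * zc + b0)
    carrier = (rng.random(N) < p_carrier).astype(int)

    # demographics: age mildly tracks the latent severity axis; sex independent
    u = (y_lin - y_lin.mean()) / max(y_lin.std(), 1e-12)
    age = 70.8 + 6.9 * (0.25 * u + np.sqrt(1 - 0.25 ** 2) * rng.standard_normal(N))
    sex = rng.choice(["F", "M"], size=N, p=[0.56, 0.44])

    # CSF biomarkers correlated with the carrier component's loading
    zs = (zc - zc.mean()) / max(zc.std(), 1e-12)
    ab_lat = cfg.csf_rho_abeta * zs + np.sqrt(1 - cfg.csf_rho_abeta ** 2) * rng.standard_normal(N)
    pt_lat = cfg.csf_rho_ptau * zs + np.sqrt(1 - cfg.csf_rho_ptau ** 2) * rng.standard_normal(N)
    csf_abeta = 1050.0 + 420.0 * ab_lat
    csf_ptau = 22.0 + 9.0 * pt_lat
    offsets = rng.integers(-540, 541, size=N).astype(float)
    missing = rng.random(N) < cfg.csf_missing_rate
    csf_abeta[missing] = np.nan
    csf_ptau[missing] = np.nan
    offsets[missing] = np.nan

    ids = [f"sub{i:04d}" for i in range(N)]
    pheno = pd.DataFrame(
        {
            "target": target, "site": site, "scanner": scanner,
            "diagnosis": diagnosis, "carrier": carrier, "age": age, "sex": sex,
            "csf_abeta42": csf_abeta, "csf_ptau181": csf_ptau,
            "csf_offset_days": offsets,
        },
        index=pd.Index(ids, name="subject_id"),
    )
    truth = GroundTruth(
        loadings_true=Z, maps_true=maps, modality_weights_true=W, beta_true=beta,
        noise_sd_per_modality=noise_sd, batch_gamma=gamma, batch_delta=delta,
        carrier_component_index=carrier_k, target_linear=y_signal,
    )
    return MultimodalDataset(X=X, pheno=pheno,
                             modalities=list(cfg.modalities[:M]) if len(cfg.modalities) >= M
                             else [f"MOD{m}" for m in range(M)],
                             truth=truth)
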