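"""Semi-supervised linked matrix factorization of multimodal feature matrices.

The model jointly decomposes M subject-by-feature modality matrices into a
shared subject-loading matrix Z (N x K), per-modality sparse spatial maps S_m
(P_m x K), nonnegative per-component modality weights W_m (length K), and a
linear prediction head (beta, b0) for a continuous clinical target, by
minimizing

    L = sum_m a_m ||X_m - Z diag(W_m) S_m'||_F^2 / (N P_m)
        + gamma ||y - Z beta - b0||^2 / N
        + l1 * sum_m ||S_m||_1,

with a_m = 1/M.  Optimization is mini-batch Adam from a randomized-SVD
initialization of the concatenated standardized modalities, with early
stopping on validation prediction loss and nonnegativity projection of W
after every step.  Features are z-scored per column on the training split
only; held-out subjects receive loadings by ridge least squares against the
weighted maps (the decomposition is fully linear, so projection is closed
form).

Follows the Model/Results convention: build :class:`SupervisedFusion` from a
dataset and split, call :meth:`~SupervisedFusion.fit`, and work with the
returned :class:`FusionResults`.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr
from sklearn.decomposition import FastICA
from sklearn.utils.extmath import randomized_svd


@dataclass
class FusionHyperparams:
    """Optimizer and penalty settings for :class:`SupervisedFusion`.

    gamma : reconstruction/prediction trade-off (weight of the squared
        prediction error; 0 gives the unsupervised limit).
    l1 : spatial-map sparsity penalty.
    learning_rate, batch_size, max_epochs, patience : Adam schedule; early
        stopping monitors validation prediction loss (training total loss
        when gamma = 0 or no validation split) and returns the best snapshot.
    ridge : Tikhonov weight of the closed-form loading projection.
    seed : controls initialization and batch shuffling.
    """

    gamma: float = 1.0
    l1: float = 0.0
    learning_rate: float = 0.01
    batch_size: int = 64
    max_epochs: int = 2000
    patience: int = 50
    ridge: float = 1e-6
    seed: int = 0


@dataclass
class _State:
    Z: np.ndarray
    S: list[np.ndarray]
    W: np.ndarray  # (M, K), >= 0
    beta: np.ndarray
    b0: float

    def copy(self) -> "_State":
        return _State(self.Z.copy(), [s.copy() for s in self.S], self.W.copy(),
                      self.beta.copy(), float(self.b0))


class SupervisedFusion:
    """Supervised multimodal factorization model.

    Parameters
    ----------
    dataset : MultimodalDataset
        Modality matrices plus phenotype table with the continuous target.
    split : SplitAssignment
        Site-grouped train/validation/test assignment.
    k : int
        Number of latent components.
    hyperparams : FusionHyperparams, optional
    """

    def __init__(self, dataset, split, k: int, hyperparams: FusionHyperparams | None = None):
        self.dataset = dataset
        self.split = split
        self.k = int(k)
        self.hyperparams = hyperparams or FusionHyperparams()
        n_tr = split.train.size
        p_min = min(x.shape[1] for x in dataset.X)
        if not (1 <= self.k <= min(p_min, n_tr)):
            raise ValueError(f"k={self.k} outside [1, min(features, train subjects)="
                             f"{min(p_min, n_tr)}]")
        if n_tr == 0:
            raise ValueError("empty training split")

    # ------------------------------------------------------------------
    def _standardize(self):
        tr = self.split.train
        mus, sds, X_std = [], [], []
        for x in self.dataset.X:
            mu = x[tr].mean(axis=0)
            sd = x[tr].std(axis=0)
            sd = np.where(sd < 1e-8, 1.0, sd)
            mus.append(mu)
            sds.append(sd)
            X_std.append((x - mu) / sd)
        return mus, sds, X_std

    def fit(self) -> "FusionResults":
        hp = self.hyperparams
        rng = np.random.default_rng(hp.seed)
        tr, va = self.split.train, self.split.val
        # the target is z-scored (training split) inside the optimizer so the
        # gamma trade-off is scale-free: reconstruction terms are O(1) in
        # standardized feature space and the prediction term must be too,
        # otherwise a target with large variance lets the free training
        # loadings overfit target noise.  The returned head is in target units.
        y_raw = self.dataset.target
        y_mu = float(y_raw[tr].mean())
        y_sd = float(y_raw[tr].std()) or 1.0
        y = (y_raw - y_mu) / y_sd
        mus, sds, X_std = self._standardize()
        Xtr = [x[tr] for x in X_std]
        M = len(Xtr)
        N = tr.size
        P = [x.shape[1] for x in Xtr]
        a = np.full(M, 1.0 / M)

        # init: randomized SVD of the weighted concatenated training matrices,
        # then an ICA unmixing of the concatenated maps.  Reconstruction is
        # rotation-invariant (maps are modality-specific), so component
        # identifiability comes from map non-Gaussianity/sparsity; the ICA
        # step is an exact invertible reparameterization (S -> S T', Z ->
        # Z T^-1) that leaves the initial reconstruction untouched.
        wts = np.sqrt(a / np.asarray(P, dtype=float))
        concat = np.hstack([w * x for w, x in zip(wts, Xtr)])
        U, sv, Vt = randomized_svd(concat, n_components=self.k,
                                   random_state=int(rng.integers(2**31)))
        Z = U * np.sqrt(N)
        V = Vt.T * sv / np.sqrt(N)
        if self.k > 1:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ica = FastICA(n_components=self.k, whiten="unit-variance",
                              random_state=int(rng.integers(2**31)),
                              max_iter=1000, tol=1e-5)
                try:
                    ica.fit(V)
                    V = V @ ica.components_.T
                    Z = Z @ ica.mixing_
                except Exception:
                    pass  # keep the plain SVD basis
        S, off = [], 0
        for m in range(M):
            S.append(V[off:off + P[m]] / wts[m])
            off += P[m]
        W = np.ones((M, self.k))
        # prediction head: OLS of the training target on the initial loadings
        beta, b0 = _ols_head(Z, y[tr])
        state = _State(Z, S, W, beta, b0)
        _standardize_loadings(state)

        init_state = state.copy()
        init_terms = _loss_terms(state, Xtr, y[tr], a, hp)
        history = [init_terms]

        def stop_metric(st: _State) -> float:
            if hp.gamma > 0 and va.size > 0:
                Zv = project_loadings([x[va] for x in X_std], st.S, st.W, a, hp.ridge)
                return float(np.mean((y[va] - Zv @ st.beta - st.b0) ** 2))
            return _loss_terms(st, Xtr, y[tr], a, hp)["total"]

        best_metric = stop_metric(state)
        best_state = state.copy()
        best_epoch = 0
        opt = _Adam(state, hp.learning_rate)
        batch = max(1, min(hp.batch_size, N))
        since_best = 0
        for epoch in range(1, hp.max_epochs + 1):
            order = rng.permutation(N)
            for start in range(0, N, batch):
                rows = order[start:start + batch]
                grads = _batch_gradients(state, Xtr, y[tr], rows, a, hp, N)
                opt.step(state, grads, rows)
                np.maximum(state.W, 0.0, out=state.W)
            _standardize_loadings(state)
            terms = _loss_terms(state, Xtr, y[tr], a, hp)
            if not np.isfinite(terms["total"]):
                bad = {k: v for k, v in terms.items() if not np.isfinite(v)}
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}: {bad}")
            history.append(terms)
            metric = stop_metric(state)
            if metric < best_metric - 1e-12:
                best_metric = metric
                best_state = state.copy()
                best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= hp.patience:
                    break
        # guarantee: returned snapshot never worse than initialization
        if _loss_terms(best_state, Xtr, y[tr], a, hp)["total"] > init_terms["total"]:
            best_state, best_epoch = init_state, 0
        # restore the prediction head to original target units
        best_state.beta = best_state.beta * y_sd
        best_state.b0 = y_mu + y_sd * best_state.b0
        return FusionResults(model=self, state=best_state, feature_means=mus,
                             feature_sds=sds, modality_scales=a,
                             train_history=history, best_epoch=best_epoch)


# ----------------------------------------------------------------------
# internals

def _ols_head(Z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    A = np.column_stack([Z, np.ones(len(y))])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef[:-1], float(coef[-1])


def _standardize_loadings(state: _State) -> None:
    """Project onto the constraint: training-loading columns have mean 0, var 1.

    The column scale is absorbed into the maps and the prediction head, the
    mean into the intercept, so predictions are unchanged.
    """
    mu = state.Z.mean(axis=0)
    sd = state.Z.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    state.b0 = float(state.b0 + mu @ state.beta)
    state.beta = state.beta * sd
    for s in state.S:
        s *= sd
    state.Z = (state.Z - mu) / sd


def _loss_terms(state: _State, X: list[np.ndarray], y: np.ndarray, a: np.ndarray,
                hp: FusionHyperparams) -> dict[str, float]:
    terms = loss_terms_for(state.Z, state.S, state.W, state.beta, state.b0,
                           X, y, a, hp.gamma, hp.l1)
    return terms


def loss_terms_for(Z, S, W, beta, b0, X, y, a, gamma, l1) -> dict[str, float]:
    """Evaluate every loss term of the fusion objective at the given parameters."""
    N = Z.shape[0]
    terms: dict[str, float] = {}
    total = 0.0
    for m, (x, s) in enumerate(zip(X, S)):
        R = x - Z @ (s * W[m]).T
        val = a[m] * float(np.sum(R * R)) / (N * x.shape[1])
        terms[f"recon_{m}"] = val
        total += val
    e = y - Z @ beta - b0
    terms["pred"] = gamma * float(e @ e) / N
    terms["l1"] = l1 * float(sum(np.abs(s).sum() for s in S))
    total += terms["pred"] + terms["l1"]
    terms["total"] = total
    return terms


def _batch_gradients(state: _State, X: list[np.ndarray], y: np.ndarray, rows: np.ndarray,
                     a: np.ndarray, hp: FusionHyperparams, n_train: int) -> dict:
    Zb = state.Z[rows]
    b = rows.size
    scale = n_train / b  # unbiased scaling of shared-parameter gradients
    gZ = np.zeros_like(Zb)
    gS = [np.zeros_like(s) for s in state.S]
    gW = np.zeros_like(state.W)
    for m, (x, s) in enumerate(zip(X, state.S)):
        A = s * state.W[m]  # (P, K)
        R = x[rows] - Zb @ A.T
        c = 2.0 * a[m] / (n_train * x.shape[1])
        gZ -= c * (R @ A)
        gS[m] -= (c * scale) * ((R.T @ Zb) * state.W[m])
        T = R @ s  # (b, K)
        gW[m] -= (c * scale) * np.einsum("ik,ik->k", Zb, T)
        if hp.l1 > 0:
            gS[m] += hp.l1 * np.sign(s)
    e = y[rows] - Zb @ state.beta - state.b0
    cp = 2.0 * hp.gamma / n_train
    gZ -= cp * e[:, None] * state.beta[None, :]
    gbeta = -(cp * scale) * (Zb.T @ e)
    gb0 = -(cp * scale) * float(e.sum())
    return {"Z": gZ, "S": gS, "W": gW, "beta": gbeta, "b0": gb0}


class _Adam:
    """Adam with per-row moments for the loading matrix."""

    def __init__(self, state: _State, lr: float, b1: float = 0.9, b2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.t = 0
        self.m = {"Z": np.zeros_like(state.Z),
                  "S": [np.zeros_like(s) for s in state.S],
                  "W": np.zeros_like(state.W),
                  "beta": np.zeros_like(state.beta), "b0": 0.0}
        self.v = copy.deepcopy(self.m)

    def _upd(self, m, v, g):
        m *= self.b1
        m += (1 - self.b1) * g
        v *= self.b2
        v += (1 - self.b2) * g * g
        mhat = m / (1 - self.b1 ** self.t)
        vhat = v / (1 - self.b2 ** self.t)
        return self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def step(self, state: _State, grads: dict, rows: np.ndarray) -> None:
        self.t += 1
        mz, vz = self.m["Z"][rows], self.v["Z"][rows]
        dz = self._upd(mz, vz, grads["Z"])
        self.m["Z"][rows], self.v["Z"][rows] = mz, vz
        state.Z[rows] -= dz
        for s, ms, vs, g in zip(state.S, self.m["S"], self.v["S"], grads["S"]):
            s -= self._upd(ms, vs, g)
        state.W -= self._upd(self.m["W"], self.v["W"], grads["W"])
        state.beta -= self._upd(self.m["beta"], self.v["beta"], grads["beta"])
        mb = self.b1 * self.m["b0"] + (1 - self.b1) * grads["b0"]
        vb = self.b2 * self.v["b0"] + (1 - self.b2) * grads["b0"] ** 2
        self.m["b0"], self.v["b0"] = mb, vb
        state.b0 -= self.lr * (mb / (1 - self.b1 ** self.t)) / (
            np.sqrt(vb / (1 - self.b2 ** self.t)) + self.eps)


def project_loadings(X_std: list[np.ndarray], S: list[np.ndarray], W: np.ndarray,
                     a: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    """Closed-form ridge projection of standardized matrices onto the maps.

    Solves argmin_Z sum_m (a_m/P_m) ||X_m - Z diag(W_m) S_m'||_F^2 + ridge ||Z||_F^2.
    """
    K = S[0].shape[1]
    G = np.zeros((K, K))
    B = np.zeros((X_std[0].shape[0], K))
    for m, (x, s) in enumerate(zip(X_std, S)):
        A = s * W[m]
        w = a[m] / x.shape[1]
        G += w * (A.T @ A)
        B += w * (x @ A)
    return np.linalg.solve(G + ridge * np.eye(K), B.T).T


# ----------------------------------------------------------------------
class FusionResults:
    """Fitted supervised fusion decomposition.

    Attributes
    ----------
    Z : (N_train, K) training-subject loadings, column-standardized.
    S : list of (P_m, K) spatial maps.
    W : (M, K) nonnegative modality weights.
    beta, intercept : linear prediction head in target units.
    train_history : per-epoch loss-term dictionaries.
    """

    def __init__(self, model: SupervisedFusion, state: _State, feature_means, feature_sds,
                 modality_scales, train_history, best_epoch):
        self.model = model
        self._state = state
        self.feature_means = feature_means
        self.feature_sds = feature_sds
        self.modality_scales = np.asarray(modality_scales, dtype=float)
        self.train_history = train_history
        self.best_epoch = best_epoch

    # -- parameter access ------------------------------------------------
    @property
    def Z(self) -> np.ndarray:
        return self._state.Z

    @property
    def S(self) -> list[np.ndarray]:
        return self._state.S

    @property
    def W(self) -> np.ndarray:
        return self._state.W

    @property
    def beta(self) -> np.ndarray:
        return self._state.beta

    @property
    def intercept(self) -> float:
        return self._state.b0

    @property
    def k(self) -> int:
        return self.model.k

    # -- operations ------------------------------------------------------
    def standardize(self, X_new: list[np.ndarray]) -> list[np.ndarray]:
        """Apply the stored training-split feature standardization."""
        return [(x - mu) / sd for x, mu, sd in zip(X_new, self.feature_means, self.feature_sds)]

    def project(self, X_new: list[np.ndarray], standardized: bool = False,
                ridge: float | None = None) -> np.ndarray:
        """Loadings for new subjects by closed-form ridge projection."""
        if len(X_new) != len(self.S):
            raise ValueError("modality count differs from the fitted model")
        for x, s in zip(X_new, self.S):
            if x.shape[1] != s.shape[0]:
                raise ValueError("feature count differs from the stored maps")
        Xs = X_new if standardized else self.standardize(X_new)
        rho = self.model.hyperparams.ridge if ridge is None else ridge
        return project_loadings(Xs, self.S, self.W, self.modality_scales, rho)

    def predict(self, Z: np.ndarray | None = None,
                X_new: list[np.ndarray] | None = None) -> np.ndarray:
        """Predicted target: Z beta + intercept."""
        if Z is None:
            Z = self.Z if X_new is None else self.project(X_new)
        Z = np.asarray(Z, dtype=float)
        if Z.shape[1] != self.k:
            raise ValueError(f"expected {self.k} loading columns, got {Z.shape[1]}")
        return Z @ self.beta + self.intercept

    def loadings_for(self, which: str = "train") -> np.ndarray:
        """Loadings for a split: stored Z for 'train', projection otherwise."""
        if which == "train":
            return self.Z
        idx = self.model.split.indices(which)
        X = [x[idx] for x in self.model.dataset.X]
        return self.project(X)

    def loadings_all(self) -> np.ndarray:
        """Loadings for every subject in dataset order (train rows from the fit)."""
        ds, sp = self.model.dataset, self.model.split
        out = np.empty((ds.n_subjects, self.k))
        out[sp.train] = self.Z
        for name in ("val", "test"):
            idx = sp.indices(name)
            if idx.size:
                out[idx] = self.project([x[idx] for x in ds.X])
        return out

    def loss_terms(self, which: str = "train", Z: np.ndarray | None = None) -> dict[str, float]:
        """Every loss term of the objective evaluated on one split."""
        ds, sp = self.model.dataset, self.model.split
        idx = sp.indices(which)
        Xs = self.standardize([x[idx] for x in ds.X])
        if Z is None:
            Z = self.Z if which == "train" else self.project(
                [x[idx] for x in ds.X])
        hp = self.model.hyperparams
        return loss_terms_for(Z, self.S, self.W, self.beta, self.intercept, Xs,
                              ds.target[idx], self.modality_scales, hp.gamma, hp.l1)

    def reconstruction_error(self, which: str = "train") -> np.ndarray:
        """Per-modality relative Frobenius reconstruction error (standardized space)."""
        ds, sp = self.model.dataset, self.model.split
        idx = sp.indices(which)
        Xs = self.standardize([x[idx] for x in ds.X])
        Z = self.Z if which == "train" else self.project([x[idx] for x in ds.X])
        errs = []
        for m, (x, s) in enumerate(zip(Xs, self.S)):
            R = x - Z @ (s * self.W[m]).T
            errs.append(np.linalg.norm(R) / max(np.linalg.norm(x), 1e-300))
        return np.asarray(errs)

    def modality_weight_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-component modality shares W_m[k] * ||S_m[:,k]||_2, normalized to sum 1.

        Returns (shares (K, M), degenerate flags).  A component whose total
        map energy is zero is flagged degenerate and its shares set to NaN.
        """
        energy = np.stack([self.W[m] * np.linalg.norm(s, axis=0)
                           for m, s in enumerate(self.S)], axis=1)  # (K, M)
        tot = energy.sum(axis=1)
        degenerate = tot <= 0
        shares = np.full_like(energy, np.nan)
        ok = ~degenerate
        shares[ok] = energy[ok] / tot[ok, None]
        return shares, degenerate

    def summary(self) -> str:
        """Human-readable fit summary table."""
        ds, sp = self.model.dataset, self.model.split
        hp = self.model.hyperparams
        last = self.train_history[-1]
        shares, degen = self.modality_weight_distribution()
        lines = [
            "Supervised multimodal fusion results",
            "=" * 52,
            f"components (K):        {self.k}",
            f"modalities:            {', '.join(ds.modalities)}",
            f"subjects (train/val/test): {sp.train.size}/{sp.val.size}/{sp.test.size}",
            f"epochs run / best:     {len(self.train_history) - 1}/{self.best_epoch}",
            f"gamma / l1:            {hp.gamma:g} / {hp.l1:g}",
            f"final training loss:   {last['total']:.6g}",
            f"degenerate components: {int(degen.sum())}",
            "",
            "per-modality relative reconstruction error (train):",
        ]
        for code, err in zip(ds.modalities, self.reconstruction_error("train")):
            lines.append(f"  {code:4s} {err:.4f}")
        for name in ("val", "test"):
            idx = sp.indices(name)
            if idx.size >= 3:
                pred = self.predict(Z=self.loadings_for(name))
                r = pearsonr(pred, ds.target[idx])[0]
                lines.append(f"predicted-vs-observed target r ({name}): {r:.3f}")
        return "\n".join(lines)

    # -- plotting (thin wrappers; see atnfuse.plotting) -------------------
    def plot_modality_weights(self, ax=None):
        from .plotting import plot_modality_weights
        return plot_modality_weights(self, ax=ax)

    def plot_prediction(self, which: str = "test", ax=None):
        from .plotting import plot_prediction
        return plot_prediction(self, which=which, ax=ax)


# ----------------------------------------------------------------------
# spec-level convenience operations

def fit_fusion(dataset, split, k: int, hyperparams: FusionHyperparams | None = None) -> FusionResults:
    """Fit the supervised fusion decomposition (model-object shorthand)."""
    return SupervisedFusion(dataset, split, k, hyperparams).fit()


def project_subjects(results: FusionResults, X_new: list[np.ndarray],
                     standardized: bool = False) -> np.ndarray:
    return results.project(X_new, standardized=standardized)


def predict_target(results: FusionResults, Z: np.ndarray) -> np.ndarray:
    return results.predict(Z=Z)


def modality_weight_distribution(results: FusionResults) -> tuple[np.ndarray, np.ndarray]:
    return results.modality_weight_distribution()


def regress_target_on_loadings(Z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """OLS of the target on all loading columns plus intercept.

    Returns (coefficients, intercept, rank_deficient flag); a rank-deficient
    design yields the minimum-norm solution with the flag set.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    if Z.shape[0] <= Z.shape[1]:
        raise ValueError("need more training subjects than components")
    A = np.column_stack([Z, np.ones(Z.shape[0])])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    return coef[:-1], float(coef[-1]), bool(rank < A.shape[1])


def match_components(estimated: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best one-to-one matching of estimated to true components by |correlation|.

    Hungarian assignment on the |Pearson correlation| matrix between loading
    columns; returns (permutation est->true, matched |r| per true component).
    """
    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(truth, dtype=float)
    ez = (est - est.mean(0)) / np.where(est.std(0) < 1e-12, 1.0, est.std(0))
    tz = (tru - tru.mean(0)) / np.where(tru.std(0) < 1e-12, 1.0, tru.std(0))
    C = np.abs(ez.T @ tz) / est.shape[0]  # (K_est, K_true)
    rows, cols = linear_sum_assignment(-C)
    perm = np.empty(len(cols), dtype=int)
    vals = np.empty(len(cols))
    for r, c in zip(rows, cols):
        perm[c] = r
        vals[c] = C[r, c]
    return perm, vals


@dataclass
class StabilityReport:
    """Grid of refits across dimensionalities and initialization seeds."""

    grid: list[tuple[int, int]]
    heldout_r: list[float]
    predictions: list[np.ndarray]
    pairwise_prediction_correlations: np.ndarray
    component_reproducibility: list[np.ndarray] = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return len(self.grid)


def stability_analysis(dataset, split, k_grid, seeds,
                       hyperparams: FusionHyperparams | None = None) -> StabilityReport:
    """Refit across a (K, seed) grid and quantify run-to-run agreement.

    Records the held-out (test-split) predicted target per run, the Pearson
    correlation of predictions between every pair of runs, and per-run
    best-match loading correlations against the first run.
    """
    base = hyperparams or FusionHyperparams()
    grid = [(int(k), int(s)) for k in k_grid for s in seeds]
    if len(grid) < 2:
        raise ValueError("stability analysis needs at least 2 runs")
    preds, rs, loads = [], [], []
    y_test = dataset.target[split.test]
    for k, s in grid:
        try:
            res = SupervisedFusion(dataset, split, k, replace(base, seed=s)).fit()
        except Exception as exc:  # annotate with the grid cell
            raise RuntimeError(f"stability run (K={k}, seed={s}) failed: {exc}") from exc
        pred = res.predict(Z=res.loadings_for("test"))
        preds.append(pred)
        rs.append(float(pearsonr(pred, y_test)[0]) if y_test.size >= 3 else np.nan)
        loads.append(res.Z)
    n = len(grid)
    C = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            C[i, j] = C[j, i] = float(pearsonr(preds[i], preds[j])[0])
    repro = [match_components(L, loads[0])[1] for L in loads]
    return StabilityReport(grid=grid, heldout_r=rs, predictions=preds,
                           pairwise_prediction_correlations=C,
                           component_reproducibility=repro)
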