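"""Predicting MoCA from gait velocities: multivariable linear regression vs a
descending-width sigmoid neural network, compared by MAE under repeated
80/20 holdout validation.

The linear model is

    MoCA = b1*V1 + ... + bn*Vn + b_{n+1}

fit by least squares with 95% confidence intervals for every parameter.  The
network has fully connected layers of widths n, n-1, ..., 2, 1 with sigmoid
activations at every node (output included), MSE loss and the Adam optimizer;
training runs up to 10,000 epochs with early stopping (patience 50 on the
validation MSE, best weights restored).  Because a sigmoid output cannot span
the MoCA range, the target is min-max scaled into (0.05, 0.95) on the
training split and predictions are inverse-scaled before computing MAE.
Inputs are z-standardized; by default the standardizer is fit on the training
split only (leakage-free), with a flag to fit on all rows for fidelity runs.

"Validation" here means 20 repeated random 80/20 holdouts; the per-repeat
holdout MAEs give the mean MAE and its 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GaitcogError, InvalidParameterError

VELOCITY_INPUTS = (
    "velocity_normal_left",
    "velocity_normal_right",
    "velocity_fast_left",
    "velocity_fast_right",
    "velocity_dual_left",
    "velocity_dual_right",
)

#: Reference coefficient set for the six-velocity MoCA predictor, as reported
#: for the ENBIND midlife T2DM cohort (slopes for normal/fast/dual-task walk
#: velocity, left then right foot, plus intercept, in MoCA points per m/s).
REFERENCE_MOCA_COEFFS = np.array([5.74, -4.39, 1.03, 0.61, 1.01, 1.21])
REFERENCE_MOCA_INTERCEPT = 21.2


@dataclass
class Standardizer:
    """Per-variable z-scoring: Z = (x - mu) / sigma, with inverse transform."""

    mu: np.ndarray
    sigma: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        mu = X.mean(axis=0)
        sigma = X.std(axis=0, ddof=1)
        if np.any(sigma <= 0):
            raise InvalidParameterError("zero-variance variable cannot be standardized")
        return cls(mu=mu, sigma=sigma)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mu) / self.sigma

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.sigma + self.mu


def zstandardize(X: np.ndarray, fitted: Standardizer) -> np.ndarray:
    return fitted.transform(X)


@dataclass
class FitResult:
    kind: str  # "mlr" | "nn"
    input_names: tuple[str, ...]
    coef: np.ndarray  # one slope per input
    intercept: float
    conf_int: np.ndarray | None = None  # (n_inputs+1, 2), intercept last (MLR)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if len(self.coef) != len(self.input_names):
            raise InvalidParameterError("one coefficient per input is required")


@dataclass
class ValidationReport:
    model: str
    maes: np.ndarray
    split: float
    seed: int

    @property
    def mean_mae(self) -> float:
        return float(np.mean(self.maes))

    @property
    def ci95(self) -> tuple[float, float]:
        return _t_ci(self.maes)

    def to_dict(self) -> dict:
        lo, hi = self.ci95
        return {
            "model": self.model,
            "mean_mae": self.mean_mae,
            "ci95": [lo, hi],
            "maes": self.maes.tolist(),
            "split": self.split,
            "seed": self.seed,
        }


@dataclass
class ModelComparison:
    diff_mean: float  # mean(A - B) over paired repeats
    ci_low: float
    ci_high: float
    verdict: str  # "ns" | "significant"


def _t_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    n = len(x)
    m = x.mean()
    se = x.std(ddof=1) / np.sqrt(n)
    if se == 0.0:
        return (float(m), float(m))
    tcrit = stats.t.ppf(0.5 + level / 2, n - 1)
    return (float(m - tcrit * se), float(m + tcrit * se))


# --------------------------------------------------------------------------
# multivariable linear regression
# --------------------------------------------------------------------------

def fit_mlr(X: np.ndarray, y: np.ndarray, input_names: tuple[str, ...] | None = None) -> FitResult:
    """Least-squares fit of the cognitive score on the selected gait variables."""
    import statsmodels.api as sm

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise InvalidParameterError("X must be 2-D (rows x inputs)")
    n, p = X.shape
    if n <= p + 1:
        raise InvalidParameterError(f"need more than {p + 1} rows, got {n}")
    design = np.column_stack([X, np.ones(n)])
    if np.linalg.matrix_rank(design) < p + 1:
        raise GaitcogError("rank-deficient design matrix")
    fit = sm.OLS(y, design).fit()
    names = input_names or tuple(f"v{i + 1}" for i in range(p))
    return FitResult(
        kind="mlr",
        input_names=tuple(names),
        coef=fit.params[:p],
        intercept=float(fit.params[p]),
        conf_int=np.asarray(fit.conf_int()),
        meta={"n": n},
    )


def predict_mlr(fit: FitResult, V: np.ndarray) -> np.ndarray | float:
    """Evaluate sum(beta_i * V_i) + intercept for one vector or a row block."""
    V = np.asarray(V, dtype=float)
    if V.shape[-1] != len(fit.coef):
        raise InvalidParameterError(
            f"expected {len(fit.coef)} inputs, got {V.shape[-1]}"
        )
    out = V @ fit.coef + fit.intercept
    return float(out) if out.ndim == 0 else out


def reference_predictor() -> FitResult:
    """The published six-velocity MoCA predictor as a FitResult."""
    return FitResult(
        kind="mlr",
        input_names=VELOCITY_INPUTS,
        coef=REFERENCE_MOCA_COEFFS.copy(),
        intercept=REFERENCE_MOCA_INTERCEPT,
    )


# --------------------------------------------------------------------------
# descending-width sigmoid network
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkSpec:
    """Layer widths n, n-1, ..., 2, 1 (input width first, output last)."""

    widths: tuple[int, ...]

    @property
    def n_parameters(self) -> int:
        return sum(
            w_in * w_out + w_out for w_in, w_out in zip(self.widths[:-1], self.widths[1:])
        )


def build_nn(n_inputs: int) -> NetworkSpec:
    """Fully connected widths descending by one from n_inputs down to 1."""
    if n_inputs < 2:
        raise InvalidParameterError("network needs >= 2 inputs")
    return NetworkSpec(widths=tuple(range(n_inputs, 0, -1)))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SigmoidNet:
    """Tiny fully connected network, sigmoid at every node, trained with
    full-batch Adam on MSE loss."""

    def __init__(self, spec: NetworkSpec, seed: int | None = None) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for w_in, w_out in zip(spec.widths[:-1], spec.widths[1:]):
            limit = np.sqrt(6.0 / (w_in + w_out))
            self.W.append(rng.uniform(-limit, limit, size=(w_in, w_out)))
            self.b.append(np.zeros(w_out))

    def forward(self, X: np.ndarray) -> np.ndarray:
        a = X
        for W, b in zip(self.W, self.b):
            a = _sigmoid(a @ W + b)
        return a[:, 0]

    def _forward_cache(self, X: np.ndarray):
        acts = [X]
        for W, b in zip(self.W, self.b):
            acts.append(_sigmoid(acts[-1] @ W + b))
        return acts

    def _step(self, X, y, state, lr, beta1, beta2, eps):
        acts = self._forward_cache(X)
        n = X.shape[0]
        pred = acts[-1][:, 0]
        # d(MSE)/d(pred) then chain through sigmoid layers
        delta = (2.0 * (pred - y) / n)[:, None] * (acts[-1] * (1 - acts[-1]))
        grads_W, grads_b = [], []
        for li in range(len(self.W) - 1, -1, -1):
            grads_W.append(acts[li].T @ delta)
            grads_b.append(delta.sum(axis=0))
            if li > 0:
                delta = (delta @ self.W[li].T) * (acts[li] * (1 - acts[li]))
        grads_W.reverse()
        grads_b.reverse()
        state["t"] += 1
        t = state["t"]
        for params, grads, mkey, vkey in (
            (self.W, grads_W, "mW", "vW"),
            (self.b, grads_b, "mb", "vb"),
        ):
            for i, g in enumerate(grads):
                state[mkey][i] = beta1 * state[mkey][i] + (1 - beta1) * g
                state[vkey][i] = beta2 * state[vkey][i] + (1 - beta2) * g * g
                mhat = state[mkey][i] / (1 - beta1**t)
                vhat = state[vkey][i] / (1 - beta2**t)
                params[i] -= lr * mhat / (np.sqrt(vhat) + eps)
        return float(np.mean((pred - y) ** 2))

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
        max_epochs: int = 10_000,
        patience: int = 50,
        lr: float = 1e-3,
    ) -> dict:
        """Train with early stopping on the validation MSE; restore best weights."""
        state = {
            "t": 0,
            "mW": [np.zeros_like(w) for w in self.W],
            "vW": [np.zeros_like(w) for w in self.W],
            "mb": [np.zeros_like(b) for b in self.b],
            "vb": [np.zeros_like(b) for b in self.b],
        }
        best_val = np.inf
        best = None
        best_epoch = 0
        wait = 0
        epoch = 0
        for epoch in range(1, max_epochs + 1):
            train_loss = self._step(X, y, state, lr, 0.9, 0.999, 1e-8)
            if not np.isfinite(train_loss):
                raise GaitcogError(f"divergent training loss at epoch {epoch}")
            val_loss = float(np.mean((self.forward(X_val) - y_val) ** 2))
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best = ([w.copy() for w in self.W], [b.copy() for b in self.b])
                best_epoch = epoch
                wait = 0
            else:
                wait += 1
                if wait >= patience:
                    break
        if best is not None:
            self.W, self.b = best
        return {"epochs_run": epoch, "best_epoch": best_epoch, "best_val_mse": best_val}


@dataclass
class NNRegressor:
    """End-to-end wrapper: standardize inputs, scale the target into
    (0.05, 0.95), train the sigmoid network, inverse-scale predictions."""

    seed: int = 0
    max_epochs: int = 10_000
    patience: int = 50
    lr: float = 1e-3
    target_margin: float = 0.05
    net: SigmoidNet | None = None
    standardizer: Standardizer | None = None
    _y_lo: float = 0.0
    _y_hi: float = 1.0
    history: dict = field(default_factory=dict)

    def _scale_y(self, y: np.ndarray) -> np.ndarray:
        span = self._y_hi - self._y_lo
        lo, m = self._y_lo, self.target_margin
        return m + (1 - 2 * m) * (y - lo) / span

    def _unscale_y(self, s: np.ndarray) -> np.ndarray:
        span = self._y_hi - self._y_lo
        lo, m = self._y_lo, self.target_margin
        return lo + (s - m) / (1 - 2 * m) * span

    def fit(self, X: np.ndarray, y: np.ndarray, X_val: np.ndarray, y_val: np.ndarray) -> "NNRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.standardizer = Standardizer.fit(X)
        self._y_lo = float(np.min(y))
        self._y_hi = float(np.max(y))
        if self._y_hi <= self._y_lo:
            raise InvalidParameterError("constant target cannot be scaled")
        spec = build_nn(X.shape[1])
        self.net = SigmoidNet(spec, seed=self.seed)
        self.history = self.net.fit(
            self.standardizer.transform(X),
            self._scale_y(y),
            self.standardizer.transform(np.asarray(X_val, dtype=float)),
            self._scale_y(np.asarray(y_val, dtype=float)),
            max_epochs=self.max_epochs,
            patience=self.patience,
            lr=self.lr,
        )
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._unscale_y(self.net.forward(self.standardizer.transform(X)))


def train_nn(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    max_epochs: int = 10_000,
    patience: int = 50,
    seed: int = 0,
) -> tuple[NNRegressor, FitResult]:
    """Train the descending-width sigmoid network; returns the regressor and a
    FitResult carrying training metadata (no linear coefficients)."""
    reg = NNRegressor(seed=seed, max_epochs=max_epochs, patience=patience)
    reg.fit(X_train, y_train, X_val, y_val)
    n = np.asarray(X_train).shape[1]
    fr = FitResult(
        kind="nn",
        input_names=tuple(f"v{i + 1}" for i in range(n)),
        coef=np.full(n, np.nan),
        intercept=float("nan"),
        meta={"seed": seed, **reg.history},
    )
    return reg, fr


# --------------------------------------------------------------------------
# repeated-holdout validation and model comparison
# --------------------------------------------------------------------------

def validate(
    model: str,
    X: np.ndarray,
    y: np.ndarray,
    repeats: int = 20,
    split: float = 0.8,
    seed: int = 0,
    max_epochs: int = 10_000,
    patience: int = 50,
) -> ValidationReport:
    """Repeated random 80/20 holdout MAE for ``model`` in {"mlr", "nn"}.

    Rows with missing values are dropped (complete-case).  Each repeat draws
    an independent split; the holdout also serves as the network's
    early-stopping validation set, as in the original protocol.
    """
    from sklearn.model_selection import train_test_split

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(X).all(axis=1) & np.isfinite(y)
    X, y = X[ok], y[ok]
    # canonical row order so the reported MAE does not depend on how the
    # cohort table happened to be sorted
    order = np.lexsort(np.vstack([X.T, y]))
    X, y = X[order], y[order]
    n_val = int(round((1 - split) * len(y)))
    if n_val < 1 or len(y) - n_val < X.shape[1] + 2:
        raise InvalidParameterError("too few rows for the requested split")
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(repeats)]
    maes = np.empty(repeats)
    for i, rs in enumerate(rep_seeds):
        Xtr, Xva, ytr, yva = train_test_split(
            X, y, train_size=split, random_state=rs, shuffle=True
        )
        if model == "mlr":
            fit = fit_mlr(Xtr, ytr)
            pred = predict_mlr(fit, Xva)
        elif model == "nn":
            reg, _ = train_nn(
                Xtr, ytr, Xva, yva, max_epochs=max_epochs, patience=patience, seed=rs
            )
            pred = reg.predict(Xva)
        else:
            raise InvalidParameterError(f"unknown model kind {model!r}")
        maes[i] = float(np.mean(np.abs(pred - yva)))
    return ValidationReport(model=model, maes=maes, split=split, seed=seed)


def compare_models(rep_a: ValidationReport, rep_b: ValidationReport) -> ModelComparison:
    """Paired per-repeat MAE differences (A - B) with a 95% t CI.

    Verdict is "ns" when the CI covers zero.
    """
    if len(rep_a.maes) != len(rep_b.maes):
        raise InvalidParameterError("reports must have equal repeat counts")
    diffs = rep_a.maes - rep_b.maes
    lo, hi = _t_ci(diffs)
    verdict = "ns" if lo <= 0.0 <= hi else "significant"
    return ModelComparison(
        diff_mean=float(diffs.mean()), ci_low=lo, ci_high=hi, verdict=verdict
    )


def velocity_feature_frame(summaries: pd.DataFrame) -> pd.DataFrame:
    """Pivot per-walk summaries to one row per subject with the six velocity
    columns named per VELOCITY_INPUTS."""
    wide = summaries.pivot_table(
        index="subject_id", columns=["task", "foot"], values="velocity_mps"
    )
    wide.columns = [f"velocity_{task}_{foot}" for task, foot in wide.columns]
    return wide.reset_index()
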