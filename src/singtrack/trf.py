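"""Ridge temporal-response-function (TRF) encoding of EEG from the envelope.

The encoder regresses each EEG channel onto time-lagged copies of the sound
envelope (lags −100…+500 ms at the 500 Hz sample step), i.e. it solves

    w = (XᵀX + λ·m·I)⁻¹ Xᵀy        per channel,

where X is the lag (design) matrix with columns centered and variance-
normalized on training data, and m is the mean diagonal of the normalized
XᵀX so that grid exponents are comparable across subjects. λ is chosen per
subject on a log grid 10⁻⁷…10⁷ by 5-fold cross-validation within the
training split (first contiguous 80% of retained epochs); predictive
accuracy is the Pearson correlation between predicted and observed EEG on
the held-out final 20%, reported per channel together with its Fisher z.

`TRFEncoder` is the model object; `fit()` returns a `TRFResults` carrying
the coefficients, the selected λ, the cross-validation curve, and scoring /
permutation-null methods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import AlignedDataset

__all__ = [
    "LagConfig",
    "LambdaGrid",
    "AccuracyRecord",
    "TRFEncoder",
    "TRFResults",
    "build_lag_matrix",
    "fit_ridge",
    "select_lambda",
    "score_accuracy",
    "accuracy_table",
    "SingularityError",
]


class SingularityError(np.linalg.LinAlgError):
    """Raised when λ = 0 meets a rank-deficient design."""


@dataclass(frozen=True)
class LagConfig:
    """Stimulus–response lag window in milliseconds.

    Positive lags mean the EEG follows the stimulus. The default window is
    −100…+500 ms at a 2 ms step (one sample at 500 Hz).
    """

    t_min: float = -100.0
    t_max: float = 500.0
    step: float = 2.0

    def __post_init__(self) -> None:
        if self.t_min > self.t_max:
            raise ValueError("t_min must not exceed t_max")
        span = self.t_max - self.t_min
        if abs(round(span / self.step) * self.step - span) > 1e-9:
            raise ValueError("step must divide the lag span")

    @property
    def n_lags(self) -> int:
        return int(round((self.t_max - self.t_min) / self.step)) + 1

    @property
    def lags_ms(self) -> np.ndarray:
        return self.t_min + self.step * np.arange(self.n_lags)

    def lags_samples(self, sfreq: float) -> np.ndarray:
        lags = self.lags_ms * sfreq / 1000.0
        rounded = np.round(lags).astype(int)
        if np.max(np.abs(lags - rounded)) > 1e-6:
            raise ValueError("lag step must be an integer number of samples")
        return rounded


@dataclass(frozen=True)
class LambdaGrid:
    """Log-spaced ridge penalties 10^exponent for integer exponents."""

    min_exponent: int = -7
    max_exponent: int = 7

    def __post_init__(self) -> None:
        if self.min_exponent > self.max_exponent:
            raise ValueError("empty lambda grid")

    @property
    def exponents(self) -> np.ndarray:
        return np.arange(self.min_exponent, self.max_exponent + 1)

    @property
    def values(self) -> np.ndarray:
        return 10.0 ** self.exponents

    def __len__(self) -> int:
        return self.exponents.size


@dataclass
class AccuracyRecord:
    """Predictive accuracy of one channel for one dyad × condition pairing."""

    dyad_id: str
    condition: str
    data_type: str  # 'true' or 'shifted'
    channel: str
    r: float
    z: float
    flagged: bool = False


def accuracy_table(records: Sequence[AccuracyRecord]) -> pd.DataFrame:
    """Tidy long table of accuracy records (flagged records excluded)."""
    rows = [
        {
            "dyad_id": rec.dyad_id,
            "condition": rec.condition,
            "data_type": rec.data_type,
            "channel": rec.channel,
            "r": rec.r,
            "z": rec.z,
        }
        for rec in records
        if not rec.flagged
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# design matrix


def _lag_tensor(
    envelope_segments: np.ndarray, lags: LagConfig, sfreq: float
) -> np.ndarray:
    """Per-epoch lag design tensor (n_epochs, samples_per_epoch, n_lags)."""
    env = np.atleast_2d(np.asarray(envelope_segments, dtype=float))
    n_ep, per = env.shape
    lag_samp = lags.lags_samples(sfreq)
    span = int(np.max(np.abs(lag_samp)))
    if span >= per:
        raise ValueError(
            f"lag span ({span} samples) must be below the epoch length ({per})"
        )
    pad = span
    padded = np.pad(env, [(0, 0), (pad, pad)])
    # idx[t, j] = t + pad - lag_j
    idx = np.arange(per)[:, None] + pad - lag_samp[None, :]
    return padded[:, idx]


def build_lag_matrix(
    envelope_segments: np.ndarray,
    lags: LagConfig = LagConfig(),
    sfreq: float = 500.0,
) -> np.ndarray:
    """Stack per-epoch lag matrices: row t holds envelope values at t − τ.

    Lag windows never cross an epoch boundary; out-of-range entries are
    zero-padded. Returns shape (n_epochs × samples_per_epoch, n_lags).
    """
    X = _lag_tensor(envelope_segments, lags, sfreq)
    return X.reshape(-1, X.shape[2])


def _valid_rows(per: int, lags: LagConfig, sfreq: float) -> slice:
    """Rows of one epoch whose lag window lies fully inside the epoch."""
    lag_samp = lags.lags_samples(sfreq)
    lo = max(int(lag_samp.max()), 0)
    hi = per + min(int(lag_samp.min()), 0)
    if hi <= lo:
        raise ValueError("lag span leaves no boundary-free rows in an epoch")
    return slice(lo, hi)


def _epoch_cross_products(
    env_segments: np.ndarray,
    eeg_epochs: np.ndarray,
    lags: LagConfig,
    sfreq: float,
    fit_rows: str = "valid",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Per-epoch XᵀX, XᵀY, column sums and Y sums (for fold arithmetic).

    With ``fit_rows='valid'`` only rows whose lag window is fully inside the
    epoch enter the moments: zero-padded boundary rows present the model
    with regressors the recorded EEG never saw, which biases the weights.
    """
    per = env_segments.shape[1]
    X = _lag_tensor(env_segments, lags, sfreq)  # (n_ep, per, p)
    Y = np.ascontiguousarray(eeg_epochs.transpose(0, 2, 1))  # (n_ep, per, C)
    if fit_rows == "valid":
        rows = _valid_rows(per, lags, sfreq)
        X = X[:, rows]
        Y = Y[:, rows]
    n_rows = X.shape[1]
    Xt = X.transpose(0, 2, 1)
    xtx = Xt @ X  # batched GEMM
    xty = Xt @ Y
    return xtx, xty, X.sum(axis=1), Y.sum(axis=1), n_rows


def _solve_ridge_from_moments(
    xtx: np.ndarray,
    xty: np.ndarray,
    xsum: np.ndarray,
    ysum: np.ndarray,
    n_rows: int,
    lambdas: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Raw-scale weights/intercepts for every λ from accumulated moments.

    Columns are centered and variance-normalized with the training
    statistics implied by the moments; weights are mapped back to the raw
    envelope scale. Returns (weights (L, p, C), intercepts (L, C), mu, sd).
    """
    mu = xsum / n_rows
    ybar = ysum / n_rows
    xtx_c = xtx - n_rows * np.outer(mu, mu)
    var = np.clip(np.diag(xtx_c) / n_rows, 0.0, None)
    sd = np.sqrt(var)
    sd_safe = np.where(sd > 0, sd, 1.0)
    xtx_n = xtx_c / np.outer(sd_safe, sd_safe)
    xty_c = xty - np.outer(mu, ybar) * n_rows
    xty_n = xty_c / sd_safe[:, None]
    m = float(np.mean(np.diag(xtx_n)))
    p = xtx.shape[0]
    weights = np.empty((lambdas.size, p, xty.shape[1]))
    intercepts = np.empty((lambdas.size, xty.shape[1]))
    eye = np.eye(p)
    for i, lam in enumerate(lambdas):
        if lam == 0:
            cond = np.linalg.cond(xtx_n)
            if not np.isfinite(cond) or cond > 1e12:
                raise SingularityError(
                    "XtX is rank deficient at lambda = 0; use a positive ridge penalty"
                )
            w_n = np.linalg.solve(xtx_n, xty_n)
        else:
            w_n = np.linalg.solve(xtx_n + lam * m * eye, xty_n)
        w_raw = w_n / sd_safe[:, None]
        weights[i] = w_raw
        intercepts[i] = ybar - mu @ w_raw
    return weights, intercepts, mu, sd


def fit_ridge(
    X: np.ndarray, Y: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Ridge solution on a prebuilt design matrix.

    Columns of X are centered and variance-normalized internally (training
    statistics only); returned weights (p × n_channels) and intercepts are
    on the raw scale of X. λ = 0 with a rank-deficient XᵀX raises
    :class:`SingularityError`.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    if Y.shape[0] != X.shape[0]:
        raise ValueError("X and Y must be row-aligned")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    xtx = X.T @ X
    xty = X.T @ Y
    weights, intercepts, _, _ = _solve_ridge_from_moments(
        xtx, xty, X.sum(axis=0), Y.sum(axis=0), X.shape[0], np.array([lam])
    )
    return weights[0], intercepts[0]


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r between two (n, k) arrays; 0-variance → nan."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    na = np.sqrt((a**2).sum(axis=0))
    nb = np.sqrt((b**2).sum(axis=0))
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=0) / denom
    r[denom == 0] = np.nan
    return r


# ---------------------------------------------------------------------------
# model / results


class TRFEncoder:
    """Per-subject ridge TRF encoding model.

    Parameters
    ----------
    dataset : AlignedDataset
        Epoch-screened EEG paired with its envelope.
    lags : LagConfig
        Lag window; defaults to −100…+500 ms at one-sample steps.
    grid : LambdaGrid
        Ridge penalty grid for cross-validation.
    folds : int
        Number of contiguous cross-validation folds within the training
        split (one fold comprises 1/folds of the training data).
    train_fraction : float
        Leading fraction of epochs used for training; the trailing remainder
        is the held-out test set (contiguity limits autocorrelation leakage).
    fit_rows : str
        'valid' (default) fits on rows whose lag window lies fully inside
        the epoch; 'all' also uses the zero-padded boundary rows.
    """

    def __init__(
        self,
        dataset: AlignedDataset,
        lags: LagConfig = LagConfig(),
        grid: LambdaGrid = LambdaGrid(),
        folds: int = 5,
        train_fraction: float = 0.8,
        dyad_id: str = "S00",
        fit_rows: str = "valid",
    ) -> None:
        if dataset.n_epochs < folds:
            raise ValueError("fewer epochs than folds")
        if fit_rows not in ("valid", "all"):
            raise ValueError("fit_rows must be 'valid' or 'all'")
        self.dataset = dataset
        self.lags = lags
        self.grid = grid
        self.folds = folds
        self.train_fraction = train_fraction
        self.dyad_id = dyad_id
        self.fit_rows = fit_rows
        n_train = int(round(train_fraction * dataset.n_epochs))
        n_train = min(max(n_train, folds), dataset.n_epochs - 1)
        self.train_idx = np.arange(n_train)
        self.test_idx = np.arange(n_train, dataset.n_epochs)

    @classmethod
    def from_arrays(
        cls,
        envelope_segments: np.ndarray,
        eeg_epochs: np.ndarray,
        condition: str = "playsong",
        sfreq: float = 500.0,
        ch_names: Sequence[str] = (),
        **kwargs,
    ) -> "TRFEncoder":
        ds = AlignedDataset(
            epochs=np.asarray(eeg_epochs, dtype=float),
            envelope_segments=np.asarray(envelope_segments, dtype=float),
            condition=condition,
            sfreq=sfreq,
            ch_names=list(ch_names) or [f"CH{i:02d}" for i in range(eeg_epochs.shape[1])],
        )
        return cls(ds, **kwargs)

    # -- fitting ------------------------------------------------------------

    def _moments(self) -> None:
        if not hasattr(self, "_xp"):
            ds = self.dataset
            self._xp = _epoch_cross_products(
                ds.envelope_segments, ds.epochs, self.lags, ds.sfreq, self.fit_rows
            )

    def _fold_slices(self) -> list[np.ndarray]:
        return [f for f in np.array_split(self.train_idx, self.folds) if f.size]

    def cross_validate(self) -> pd.DataFrame:
        """Mean held-out correlation (across folds and channels) per grid λ."""
        self._moments()
        xtx_e, xty_e, xsum_e, ysum_e, per = self._xp
        ds = self.dataset
        lambdas = self.grid.values
        folds = self._fold_slices()
        if min(len(f) for f in folds) < 1:
            raise ValueError("not enough training epochs for the fold count")
        tr = self.train_idx
        tot_xtx = xtx_e[tr].sum(axis=0)
        tot_xty = xty_e[tr].sum(axis=0)
        tot_xsum = xsum_e[tr].sum(axis=0)
        tot_ysum = ysum_e[tr].sum(axis=0)
        r_by_lambda = np.zeros((lambdas.size, len(folds)))
        for fi, fold in enumerate(folds):
            n_rows = (tr.size - fold.size) * per
            weights, intercepts, _, _ = _solve_ridge_from_moments(
                tot_xtx - xtx_e[fold].sum(axis=0),
                tot_xty - xty_e[fold].sum(axis=0),
                tot_xsum - xsum_e[fold].sum(axis=0),
                tot_ysum - ysum_e[fold].sum(axis=0),
                n_rows,
                lambdas,
            )
            Xf_t = _lag_tensor(ds.envelope_segments[fold], self.lags, ds.sfreq)
            Yf_t = ds.epochs[fold].transpose(0, 2, 1)
            if self.fit_rows == "valid":
                rows = _valid_rows(ds.envelope_segments.shape[1], self.lags, ds.sfreq)
                Xf_t = Xf_t[:, rows]
                Yf_t = Yf_t[:, rows]
            Xf = Xf_t.reshape(-1, Xf_t.shape[2])
            Yf = np.ascontiguousarray(Yf_t).reshape(-1, ds.epochs.shape[1])
            # one BLAS call for all lambdas
            stacked = np.concatenate(list(weights), axis=1)  # (p, L*C)
            preds = Xf @ stacked + np.concatenate(list(intercepts))
            n_ch = Yf.shape[1]
            for i in range(lambdas.size):
                r = _pearson_columns(preds[:, i * n_ch : (i + 1) * n_ch], Yf)
                r_by_lambda[i, fi] = np.nanmean(r)
        return pd.DataFrame(
            {
                "exponent": self.grid.exponents,
                "lambda": lambdas,
                "mean_r": r_by_lambda.mean(axis=1),
            }
        )

    def fit(self, lambda_: float | None = None, seed: int | None = None) -> "TRFResults":
        """Fit the TRF; when λ is not given, select it by cross-validation.

        Ties on the CV criterion resolve to the smaller λ. The final model
        is refit on the full training split at the selected λ.
        """
        self._moments()
        xtx_e, xty_e, xsum_e, ysum_e, per = self._xp
        cv = None
        if lambda_ is None:
            cv = self.cross_validate()
            scores = cv["mean_r"].to_numpy()
            best = int(np.argmax(scores))  # first max => smaller lambda on ties
            lambda_ = float(cv["lambda"].iloc[best])
        tr = self.train_idx
        weights, intercepts, _, _ = _solve_ridge_from_moments(
            xtx_e[tr].sum(axis=0),
            xty_e[tr].sum(axis=0),
            xsum_e[tr].sum(axis=0),
            ysum_e[tr].sum(axis=0),
            tr.size * per,
            np.array([lambda_]),
        )
        return TRFResults(
            encoder=self,
            weights=weights[0].T.copy(),  # (n_channels, n_lags)
            intercept=intercepts[0].copy(),
            lambda_selected=lambda_,
            cv_accuracy_by_lambda=cv,
        )


@dataclass
class TRFResults:
    """Fitted TRF: channel × lag coefficients plus CV metadata."""

    encoder: TRFEncoder
    weights: np.ndarray  # (n_channels, n_lags), raw envelope scale
    intercept: np.ndarray  # (n_channels,)
    lambda_selected: float
    cv_accuracy_by_lambda: pd.DataFrame | None = None

    @property
    def lags_ms(self) -> np.ndarray:
        return self.encoder.lags.lags_ms

    @property
    def ch_names(self) -> list[str]:
        return list(self.encoder.dataset.ch_names)

    @property
    def train_fraction(self) -> float:
        return self.encoder.train_fraction

    def predict(self, envelope_segments: np.ndarray) -> np.ndarray:
        """Predicted EEG epochs (n, channels, samples) from envelope epochs."""
        env = np.atleast_2d(np.asarray(envelope_segments, dtype=float))
        n_ep, per = env.shape
        X = build_lag_matrix(env, self.encoder.lags, self.encoder.dataset.sfreq)
        pred = X @ self.weights.T + self.intercept
        return pred.reshape(n_ep, per, -1).transpose(0, 2, 1)

    def test_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(prediction, observed) concatenated over held-out test epochs,
        both shaped (channels, samples)."""
        ds = self.encoder.dataset
        idx = self.encoder.test_idx
        pred = self.predict(ds.envelope_segments[idx])
        n_ch = ds.epochs.shape[1]
        return (
            pred.transpose(1, 0, 2).reshape(n_ch, -1),
            ds.epochs[idx].transpose(1, 0, 2).reshape(n_ch, -1),
        )

    def score(self, dyad_id: str | None = None) -> list[AccuracyRecord]:
        """Per-channel Pearson r (and Fisher z) on the held-out test split."""
        pred, obs = self.test_arrays()
        r = _pearson_columns(pred.T, obs.T)
        ds = self.encoder.dataset
        out = []
        for ch, name in enumerate(self.ch_names):
            r_ch = float(r[ch])
            degenerate = not np.isfinite(r_ch) or abs(r_ch) >= 1.0 - 1e-12
            out.append(
                AccuracyRecord(
                    dyad_id=dyad_id or self.encoder.dyad_id,
                    condition=ds.condition,
                    data_type="true",
                    channel=name,
                    r=r_ch,
                    z=float(np.arctanh(np.clip(r_ch, -1.0, 1.0)))
                    if np.isfinite(r_ch)
                    else float("nan"),
                    flagged=degenerate,
                )
            )
        return out

    def shifted_null(self, n_permutations: int = 400, seed: int = 0, **kwargs):
        """Reversed circular-shift null distribution; see
        :func:`singtrack.inference.shifted_null`."""
        from .inference import shifted_null as _shifted_null

        return _shifted_null(self, n_permutations=n_permutations, seed=seed, **kwargs)

    def summary(self) -> str:
        ds = self.encoder.dataset
        recs = self.score()
        r_vals = [rec.r for rec in recs if not rec.flagged]
        lines = [
            "TRF encoding results",
            "====================",
            f"condition:        {ds.condition}",
            f"channels:         {len(self.ch_names)}",
            f"lags:             {self.encoder.lags.t_min:.0f}..{self.encoder.lags.t_max:.0f} ms "
            f"({self.encoder.lags.n_lags} lags)",
            f"epochs:           {ds.n_epochs} "
            f"(train {self.encoder.train_idx.size}, test {self.encoder.test_idx.size})",
            f"selected lambda:  {self.lambda_selected:.3g}",
            f"mean test r:      {np.mean(r_vals):.4f}" if r_vals else "mean test r:      n/a",
        ]
        if self.cv_accuracy_by_lambda is not None:
            lines.append("\nCV accuracy by lambda:")
            lines.append(
                self.cv_accuracy_by_lambda.to_string(
                    index=False, float_format=lambda v: f"{v: .5f}"
                )
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional convenience operations


def select_lambda(
    ds: AlignedDataset,
    grid: LambdaGrid = LambdaGrid(),
    folds: int = 5,
    seed: int | None = None,
    lags: LagConfig = LagConfig(),
    train_fraction: float = 0.8,
    dyad_id: str = "S00",
) -> TRFResults:
    """Cross-validate λ over the grid and refit on the training split."""
    if ds.n_epochs < folds * 10:
        raise ValueError("need at least folds x 10 epochs for stable CV")
    enc = TRFEncoder(
        ds, lags=lags, grid=grid, folds=folds, train_fraction=train_fraction, dyad_id=dyad_id
    )
    return enc.fit(seed=seed)


def score_accuracy(results: TRFResults, dyad_id: str | None = None) -> list[AccuracyRecord]:
    """Per-channel predictive accuracy on the held-out test split."""
    return results.score(dyad_id=dyad_id)
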