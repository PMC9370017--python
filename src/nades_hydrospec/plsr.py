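"""Single-response partial least squares regression via NIPALS.

PLS1 with mean-centering only (no variance scaling, the chemometrics default
for spectra). For a univariate response the NIPALS loop needs no inner
iteration: per component

    w = X_c' y_c / ||X_c' y_c||      (unit weight)
    t = X_c w                        (score)
    p = X_c' t / (t't)               (x-loading)
    q = y_c' t / (t't)               (y-loading)
    X_c <- X_c - t p',   y_c <- y_c - q t

and the regression vector is b = W (P'W)^-1 q with intercept
y_mean - x_mean' b, so prediction is the affine map y_hat = X b + intercept.

Extraction is deterministic. If the covariance ||X_c' y_c|| collapses below
1e-12 before the requested number of components, :func:`fit_plsr` raises an
error naming the achievable rank; the tolerant path fitter used by
cross-validation stops there instead, since further components cannot change
predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

_COV_TOL = 1e-12


@dataclass
class PLSRModel:
    """A fitted PLS1 model with its factor decomposition.

    ``W`` (n_channels x n_lv) unit-norm weights, ``P`` x-loadings, ``q``
    y-loadings, ``b``/``intercept`` the assembled regression vector for the
    full model. ``wavenumbers`` is the training axis (None when fitted on a
    bare matrix).
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    b: np.ndarray
    intercept: float
    wavenumbers: np.ndarray | None = None

    def coefficients(self, n_lv: int | None = None) -> tuple[np.ndarray, float]:
        """Regression vector and intercept using the first ``n_lv`` components."""
        k = self.n_lv if n_lv is None else int(n_lv)
        if not 1 <= k <= self.n_lv:
            raise ValueError(f"n_lv must be in 1..{self.n_lv}, got {k}")
        b = _assemble_b(self.W[:, :k], self.P[:, :k], self.q[:k])
        return b, self.y_mean - float(self.x_mean @ b)

    def coefficient_path(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_channels x n_lv) matrix of b vectors and per-LV intercepts."""
        B = np.empty((self.W.shape[0], self.n_lv))
        intercepts = np.empty(self.n_lv)
        for k in range(1, self.n_lv + 1):
            B[:, k - 1], intercepts[k - 1] = self.coefficients(k)
        return B, intercepts

    def to_json(self, path: str | Path) -> None:
        """Serialize the model (including factors) to a flat JSON file."""
        payload = {
            "n_lv": self.n_lv,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "W": self.W.tolist(),
            "P": self.P.tolist(),
            "q": self.q.tolist(),
            "b": self.b.tolist(),
            "intercept": self.intercept,
            "wavenumbers": None if self.wavenumbers is None else self.wavenumbers.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSRModel":
        d = json.loads(Path(path).read_text())
        return cls(
            n_lv=int(d["n_lv"]),
            x_mean=np.array(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            W=np.array(d["W"], dtype=float),
            P=np.array(d["P"], dtype=float),
            q=np.array(d["q"], dtype=float),
            b=np.array(d["b"], dtype=float),
            intercept=float(d["intercept"]),
            wavenumbers=None if d["wavenumbers"] is None else np.array(d["wavenumbers"]),
        )


def _assemble_b(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    # P'W is triangular with unit diagonal in exact arithmetic; a dense solve on the
    # small (n_lv x n_lv) system is robust either way
    return W @ np.linalg.solve(P.T @ W, q)


def _nipals(
    Xc: np.ndarray, yc: np.ndarray, n_lv: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Extract up to n_lv components; returns (W, P, q, n_achieved)."""
    n, p = Xc.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    Xc = Xc.copy()
    yc = yc.copy()
    achieved = 0
    for a in range(n_lv):
        w = Xc.T @ yc
        wnorm = float(np.linalg.norm(w))
        if wnorm < _COV_TOL:
            break
        w /= wnorm
        t = Xc @ w
        tt = float(t @ t)
        if tt < _COV_TOL:
            break
        p_a = (Xc.T @ t) / tt
        q_a = float(yc @ t) / tt
        Xc -= np.outer(t, p_a)
        yc = yc - q_a * t
        W[:, a], P[:, a], q[a] = w, p_a, q_a
        achieved = a + 1
    return W[:, :achieved], P[:, :achieved], q[:achieved], achieved


def _fit(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    wavenumbers: np.ndarray | None,
    strict: bool,
) -> PLSRModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if X.shape[0] != y.size:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.size} entries")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training spectra")
    if n_lv < 1:
        raise ValueError(f"n_lv must be >= 1, got {n_lv}")
    if float(np.ptp(y)) == 0.0:
        raise ValueError("y has zero variance; cannot fit a regression")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, achieved = _nipals(X - x_mean, y - y_mean, n_lv)
    if achieved < n_lv and strict:
        raise ValueError(
            f"requested {n_lv} latent variables but the centered data support "
            f"only {achieved} (covariance exhausted)"
        )
    b = _assemble_b(W, P, q)
    return PLSRModel(
        n_lv=achieved,
        x_mean=x_mean,
        y_mean=y_mean,
        W=W,
        P=P,
        q=q,
        b=b,
        intercept=y_mean - float(x_mean @ b),
        wavenumbers=None if wavenumbers is None else np.asarray(wavenumbers, dtype=float),
    )


def fit_plsr(
    X: np.ndarray, y: np.ndarray, n_lv: int, wavenumbers: np.ndarray | None = None
) -> PLSRModel:
    """Fit a PLS1 model with exactly ``n_lv`` latent variables.

    Raises if the centered data cannot support ``n_lv`` components, naming
    the achievable rank.
    """
    return _fit(X, y, n_lv, wavenumbers, strict=True)


def fit_plsr_path(
    X: np.ndarray, y: np.ndarray, max_lv: int, wavenumbers: np.ndarray | None = None
) -> PLSRModel:
    """Fit up to ``max_lv`` components, stopping at the achievable rank.

    Used by cross-validation so that LV curves on (near-)noiseless data do
    not abort once the response is fully explained; the model's ``n_lv`` is
    the number actually extracted.
    """
    return _fit(X, y, max_lv, wavenumbers, strict=False)


def predict(model: PLSRModel, X: np.ndarray, wavenumbers: np.ndarray | None = None) -> np.ndarray:
    """Predict the response (%w/w added water) for spectra rows of X."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.b.size:
        raise ValueError(f"X has {X.shape[1]} channels, model expects {model.b.size}")
    if wavenumbers is not None and model.wavenumbers is not None:
        wn = np.asarray(wavenumbers, dtype=float)
        if wn.size != model.wavenumbers.size:
            raise ValueError(
                f"axis length mismatch: {wn.size} vs model {model.wavenumbers.size}"
            )
        bad = np.nonzero(wn != model.wavenumbers)[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"wavenumber axis mismatch at channel {i}: {wn[i]} vs model {model.wavenumbers[i]}"
            )
    return X @ model.b + model.intercept


def regression_vector(model: PLSRModel) -> tuple[np.ndarray, np.ndarray]:
    """(wavenumbers, b) of the fitted model, for plotting/export.

    Positive coefficients mark channels whose intensity rises with water
    (e.g. the OH-stretch region), negative ones the anticorrelated
    constituent bands.
    """
    wn = model.wavenumbers if model.wavenumbers is not None else np.arange(model.b.size, dtype=float)
    return wn, model.b.copy()
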