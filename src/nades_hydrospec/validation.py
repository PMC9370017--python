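"""Monte-Carlo three-way validation protocol for the water calibration.

The data are partitioned at the SAMPLE level (a sample is one set x
concentration level unit carrying 9 replicate spectra): two replicate sets
form the training pool (18 samples), the other three are held out as an
independent test set (27 samples). Each Monte-Carlo iteration randomly
splits the training pool 2/3 calibration (12 samples) / 1/3 validation
(6 samples), fits PLS models for 1..max_lv latent variables on the
calibration spectra and evaluates per-sample mean predictions on the
validation samples. RMSECV per LV is aggregated over (by default) 100
iterations; the chosen LV is the argmin of the mean curve (smallest LV on
ties). Test performance (RMSEP, R^2) refits at the chosen LV per iteration
and predicts the untouched test samples, yielding a distribution whose mean
and SD are reported. Relative errors per test sample use the iteration-mean
prediction, excluding samples whose true added water is 0 (relative error is
undefined there).

All replicate spectra of a sample always travel together across splits, so
replicate leakage between calibration and validation is impossible by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plsr import fit_plsr_path, predict
from .preprocess import PreprocessPlan, apply_plan
from .spectra_io import SpectralDataset

RE_BIN_EDGES = (0.0, 1.0, 2.5, 5.0, 7.5, 10.0, np.inf)
RE_BIN_LABELS = ("<1", "<2.5", "<5", "<7.5", "<10", ">10")

SampleKey = tuple[str, str]


@dataclass(frozen=True)
class SplitProtocol:
    """The three-way split: fixed training/test sets, random cal/val inside."""

    training_sets: tuple[str, ...] = ("SET_02", "SET_04")
    test_sets: tuple[str, ...] = ("SET_01", "SET_03", "SET_05")
    calibration_fraction: float = 2.0 / 3.0
    n_iterations: int = 100
    max_lv: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.training_sets) & set(self.test_sets):
            raise ValueError("training and test set ids must be disjoint")
        if not 0 < self.calibration_fraction < 1:
            raise ValueError("calibration_fraction must be in (0, 1)")
        if self.n_iterations < 1 or self.max_lv < 1:
            raise ValueError("n_iterations and max_lv must be >= 1")


@dataclass
class CrossValidationResult:
    """RMSECV/R^2 per LV (mean +/- SD over iterations) and the stored splits."""

    lv: np.ndarray
    rmsecv_mean: np.ndarray
    rmsecv_sd: np.ndarray
    r2_mean: np.ndarray
    r2_sd: np.ndarray
    chosen_lv: int
    splits: list[tuple[list[SampleKey], list[SampleKey]]]
    protocol: SplitProtocol

    @property
    def rmsecv(self) -> tuple[float, float]:
        """(mean, sd) RMSECV at the chosen LV."""
        i = self.chosen_lv - 1
        return float(self.rmsecv_mean[i]), float(self.rmsecv_sd[i])

    @property
    def r2_cv(self) -> tuple[float, float]:
        i = self.chosen_lv - 1
        return float(self.r2_mean[i]), float(self.r2_sd[i])

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lv": self.lv,
                "rmsecv_mean": self.rmsecv_mean,
                "rmsecv_sd": self.rmsecv_sd,
                "r2_mean": self.r2_mean,
                "r2_sd": self.r2_sd,
            }
        )


@dataclass
class TestResult:
    """Independent-test performance at the chosen LV."""

    rmsep_mean: float
    rmsep_sd: float
    r2_mean: float
    r2_sd: float
    per_sample: pd.DataFrame  # set_id, level_id, true, predicted, rel_error_pct


@dataclass
class ValidationReport:
    """Full outcome of the protocol for one dataset/plan."""

    modality: str
    plan_name: str
    cross_validation: CrossValidationResult
    test: TestResult
    relative_errors: pd.DataFrame

    @property
    def chosen_lv(self) -> int:
        return self.cross_validation.chosen_lv


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root-mean-square error, in the units of y (%w/w added water)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError(f"length mismatch or empty input: {y_true.shape} vs {y_pred.shape}")
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Squared Pearson correlation between measured and predicted values."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need >= 2 paired points")
    if float(np.std(y_true)) == 0.0 or float(np.std(y_pred)) == 0.0:
        raise ValueError("zero variance input to r_squared")
    r = float(np.corrcoef(y_true, y_pred)[0, 1])
    return r * r


def split_samples(
    training_samples: list[SampleKey], fraction: float, rng: np.random.Generator
) -> tuple[list[SampleKey], list[SampleKey]]:
    """Random sample-level partition into (calibration, validation).

    Calibration size is round(fraction * n); all replicate spectra of a
    sample follow it into its side of the split.
    """
    n = len(training_samples)
    if n < 3:
        raise ValueError(f"need at least 3 training samples, got {n}")
    n_cal = int(round(fraction * n))
    if n_cal >= n or n_cal < 1:
        raise ValueError(f"degenerate split: {n_cal} calibration of {n} samples")
    order = rng.permutation(n)
    cal = [training_samples[i] for i in sorted(order[:n_cal])]
    val = [training_samples[i] for i in sorted(order[n_cal:])]
    return cal, val


def _design_arrays(ds: SpectralDataset):
    """Per-spectrum sample keys and labels plus the per-sample label map."""
    keys = [(m.set_id, m.level_id) for m in ds.meta]
    y = np.array([m.added_water for m in ds.meta], dtype=float)
    label_of = {}
    for k, v in zip(keys, y):
        label_of[k] = v
    return keys, y, label_of


def _rows_of_samples(keys: list[SampleKey], samples: list[SampleKey]) -> np.ndarray:
    wanted = set(samples)
    return np.array([i for i, k in enumerate(keys) if k in wanted], dtype=int)


def _per_sample_means(
    keys: list[SampleKey], rows: np.ndarray, preds: np.ndarray, samples: list[SampleKey]
) -> np.ndarray:
    """Mean prediction per sample; preds has one row per spectrum in rows.

    preds may be (n_rows,) or (n_rows, n_lv); returns (n_samples,) or
    (n_samples, n_lv) in the order of ``samples``.
    """
    index = {s: j for j, s in enumerate(samples)}
    groups = np.array([index[keys[i]] for i in rows], dtype=int)
    counts = np.bincount(groups, minlength=len(samples)).astype(float)
    if preds.ndim == 1:
        sums = np.bincount(groups, weights=preds, minlength=len(samples))
        return sums / counts
    out = np.empty((len(samples), preds.shape[1]))
    for k in range(preds.shape[1]):
        out[:, k] = np.bincount(groups, weights=preds[:, k], minlength=len(samples)) / counts
    return out


def run_cross_validation(
    ds: SpectralDataset, plan: PreprocessPlan, protocol: SplitProtocol
) -> CrossValidationResult:
    """Monte-Carlo cross-validation over the training sets.

    Iteration k draws its split from substream k of the protocol seed, so
    extending ``n_iterations`` never changes earlier splits.
    """
    pp = apply_plan(ds, plan)
    keys, y, label_of = _design_arrays(pp)
    training_samples = sorted(k for k in set(keys) if k[0] in protocol.training_sets)
    if not training_samples:
        raise ValueError(f"no training samples for sets {protocol.training_sets}")
    max_lv = protocol.max_lv

    children = np.random.SeedSequence(protocol.seed).spawn(protocol.n_iterations)
    rmsecv_iter = np.empty((protocol.n_iterations, max_lv))
    r2_iter = np.empty((protocol.n_iterations, max_lv))
    splits: list[tuple[list[SampleKey], list[SampleKey]]] = []

    for it in range(protocol.n_iterations):
        rng = np.random.default_rng(children[it])
        cal, val = split_samples(training_samples, protocol.calibration_fraction, rng)
        splits.append((cal, val))
        cal_rows = _rows_of_samples(keys, cal)
        val_rows = _rows_of_samples(keys, val)
        y_cal = y[cal_rows]
        if np.unique(y_cal).size < 2:
            raise ValueError(f"iteration {it}: fewer than 2 distinct y values in calibration")
        model = fit_plsr_path(pp.intensities[cal_rows], y_cal, max_lv, pp.wavenumbers)
        B, intercepts = model.coefficient_path()
        preds = pp.intensities[val_rows] @ B + intercepts  # (n_val_spectra, n_achieved)
        sample_preds = _per_sample_means(keys, val_rows, preds, val)
        y_val = np.array([label_of[s] for s in val])
        for k in range(max_lv):
            kk = min(k, model.n_lv - 1)  # beyond the achieved rank the fit is frozen
            rmsecv_iter[it, k] = rmse(y_val, sample_preds[:, kk])
            r2_iter[it, k] = r_squared(y_val, sample_preds[:, kk])

    rmsecv_mean = rmsecv_iter.mean(axis=0)
    chosen_lv = int(np.argmin(rmsecv_mean)) + 1  # first minimum = smallest LV on ties
    return CrossValidationResult(
        lv=np.arange(1, max_lv + 1),
        rmsecv_mean=rmsecv_mean,
        rmsecv_sd=rmsecv_iter.std(axis=0, ddof=1) if protocol.n_iterations > 1 else np.zeros(max_lv),
        r2_mean=r2_iter.mean(axis=0),
        r2_sd=r2_iter.std(axis=0, ddof=1) if protocol.n_iterations > 1 else np.zeros(max_lv),
        chosen_lv=chosen_lv,
        splits=splits,
        protocol=protocol,
    )


def evaluate_test(
    ds: SpectralDataset,
    plan: PreprocessPlan,
    protocol: SplitProtocol,
    chosen_lv: int,
    splits: list[tuple[list[SampleKey], list[SampleKey]]],
) -> TestResult:
    """Refit at the chosen LV per stored split and predict the test sets."""
    pp = apply_plan(ds, plan)
    keys, y, label_of = _design_arrays(pp)
    test_samples = sorted(k for k in set(keys) if k[0] in protocol.test_sets)
    if not test_samples:
        raise ValueError(f"no test samples for sets {protocol.test_sets}")
    test_rows = _rows_of_samples(keys, test_samples)
    y_test = np.array([label_of[s] for s in test_samples])

    rmsep = np.empty(len(splits))
    r2 = np.empty(len(splits))
    pred_accum = np.zeros(len(test_samples))
    for it, (cal, _val) in enumerate(splits):
        cal_rows = _rows_of_samples(keys, cal)
        model = fit_plsr_path(pp.intensities[cal_rows], y[cal_rows], chosen_lv, pp.wavenumbers)
        preds = predict(model, pp.intensities[test_rows])
        sample_preds = _per_sample_means(keys, test_rows, preds, test_samples)
        rmsep[it] = rmse(y_test, sample_preds)
        r2[it] = r_squared(y_test, sample_preds)
        pred_accum += sample_preds
    pred_mean = pred_accum / len(splits)

    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(y_test > 0, 100.0 * np.abs(pred_mean - y_test) / y_test, np.nan)
    per_sample = pd.DataFrame(
        {
            "set_id": [s[0] for s in test_samples],
            "level_id": [s[1] for s in test_samples],
            "true_added_water": y_test,
            "predicted_added_water": pred_mean,
            "rel_error_pct": rel,
        }
    )
    return TestResult(
        rmsep_mean=float(rmsep.mean()),
        rmsep_sd=float(rmsep.std(ddof=1)) if len(splits) > 1 else 0.0,
        r2_mean=float(r2.mean()),
        r2_sd=float(r2.std(ddof=1)) if len(splits) > 1 else 0.0,
        per_sample=per_sample,
    )


def relative_error_table(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Binned relative-error summary over test samples with true > 0.

    Bins are half-open [a, b): [0,1), [1,2.5), [2.5,5), [5,7.5), [7.5,10),
    [10, inf). Samples at 0 added water are excluded (relative error is
    undefined), so the default design contributes 24 of 27 test samples.
    """
    mask = per_sample["true_added_water"].to_numpy() > 0
    re = per_sample.loc[mask, "rel_error_pct"].to_numpy(dtype=float)
    counts = [
        int(((re >= lo) & (re < hi)).sum())
        for lo, hi in zip(RE_BIN_EDGES[:-1], RE_BIN_EDGES[1:])
    ]
    row = {label: n for label, n in zip(RE_BIN_LABELS, counts)}
    row["n_samples"] = int(mask.sum())
    row["mean_re_pct"] = float(re.mean()) if re.size else float("nan")
    row["min_re_pct"] = float(re.min()) if re.size else float("nan")
    row["max_re_pct"] = float(re.max()) if re.size else float("nan")
    return pd.DataFrame([row])


def validate_dataset(
    ds: SpectralDataset, plan: PreprocessPlan, protocol: SplitProtocol
) -> ValidationReport:
    """Run the full protocol: CV + LV choice, test evaluation, error table."""
    cv = run_cross_validation(ds, plan, protocol)
    test = evaluate_test(ds, plan, protocol, cv.chosen_lv, cv.splits)
    return ValidationReport(
        modality=ds.modality,
        plan_name=plan.name,
        cross_validation=cv,
        test=test,
        relative_errors=relative_error_table(test.per_sample),
    )
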