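"""Validation designs for spectra-to-trait models, in increasing order of
statistical rigour: leave-one-out cross-validation, repeated random
train/test splits, and a stress holdout that trains on calm dates and tests
on the consecutive date pair with the largest within-population spread in
predawn water potential.

Every fold runs the full leak-free pipeline on its training rows only:
column autoscaling/centring statistics and the RMSEP-selected component
count are estimated inside the fold (the row-wise SNV and derivative
stages are sample-local and fold-independent).  The headline R-squared is
the squared Pearson correlation between observed and predicted held-out
values — the convention of observed-vs-predicted scatter panels — with the
1 - SSE/SST "prediction R-squared" reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fvcb import KineticConstants, fit_aci, qc_aci
from .pls import PLSRegressionNIPALS, select_ncomp
from .spectra import SpectralPreprocessor, average_replicates, qc_spectrum
from .simulate import StudyTable

__all__ = [
    "Metrics",
    "RunResult",
    "ValidationResult",
    "Dataset",
    "build_dataset",
    "metrics",
    "loo_cv",
    "repeated_split",
    "stress_holdout",
]


@dataclass
class Metrics:
    """Observed-vs-predicted performance: Pearson-squared R2 and RMSE.

    ``r2_sse`` is the alternative 1 - SSE/SST convention; ``r_squared`` is
    the headline squared-correlation convention."""

    r_squared: float
    rmse: float
    r2_sse: float = float("nan")
    undefined: bool = False


def metrics(observed, predicted) -> Metrics:
    """Compute R2 (squared Pearson correlation) and RMSE for paired vectors."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length 1-d, n>=2")
    if np.any(~np.isfinite(obs)) or np.any(~np.isfinite(pred)):
        raise ValueError("non-finite values in observed/predicted")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        return Metrics(r_squared=float("nan"), rmse=rmse,
                       r2_sse=float("nan"), undefined=True)
    r = float(np.corrcoef(obs, pred)[0, 1])
    return Metrics(r_squared=r * r, rmse=rmse,
                   r2_sse=1.0 - float(np.sum((pred - obs) ** 2)) / sst)


@dataclass
class RunResult:
    r_squared: float
    rmse: float
    r2_sse: float
    n_train: int
    n_test: int
    n_components: int
    rmsep_curve: np.ndarray | None = None
    held_out: list = field(default_factory=list)


@dataclass
class ValidationResult:
    scheme: str
    runs: list[RunResult]
    observed: np.ndarray
    predicted: np.ndarray
    pooled: Metrics
    summary: dict
    held_out_dates: tuple | None = None


@dataclass
class Dataset:
    """Assembled modelling table: mean raw spectra plus trait vectors."""

    X: np.ndarray                 # samples x wavelengths, raw reflectance
    wavelengths: np.ndarray
    y: dict                       # trait name -> vector
    psi_pd: np.ndarray
    date_index: np.ndarray
    tree_id: np.ndarray


def build_dataset(table: StudyTable, trait_source: str = "fitted",
                  k: KineticConstants | None = None) -> Dataset:
    """Average replicate spectra per leaf and attach trait vectors.

    ``trait_source='fitted'`` estimates Vcmax/Jmax by fitting the FvCB model
    to each leaf's A/Ci curve (the gas-exchange route); ``'true'`` uses the
    generator's latent traits (noise-free oracle).
    """
    X_rows, vc, jm, psi, dates, trees = [], [], [], [], [], []
    for rec in table.records:
        if not rec.spectra:
            raise ValueError("record has no spectra; run the full simulation")
        mean_spec = average_replicates([qc_spectrum(s) for s in rec.spectra])
        X_rows.append(mean_spec.reflectance)
        if trait_source == "fitted":
            if rec.aci_curve is None:
                raise ValueError("record has no A/Ci curve")
            qc = qc_aci(rec.aci_curve)
            if not qc.passed:
                warnings.warn(
                    f"leaf tree{rec.tree_id}/date{rec.date_index} excluded: "
                    + "; ".join(qc.reasons), stacklevel=2)
                vc.append(np.nan)
                jm.append(np.nan)
            else:
                f = fit_aci(rec.aci_curve, k=k)
                vc.append(f.vcmax if f.success else np.nan)
                jm.append(f.jmax if f.success else np.nan)
        elif trait_source == "true":
            vc.append(rec.true_vcmax)
            jm.append(rec.true_jmax)
        else:
            raise ValueError("trait_source must be 'fitted' or 'true'")
        psi.append(rec.psi_pd)
        dates.append(rec.date_index)
        trees.append(rec.tree_id)
    return Dataset(X=np.vstack(X_rows),
                   wavelengths=table.records[0].spectra[0].wavelengths,
                   y={"vcmax": np.array(vc), "jmax": np.array(jm)},
                   psi_pd=np.array(psi), date_index=np.array(dates),
                   tree_id=np.array(trees))


def _as_dataset(table, trait: str, trait_source: str) -> tuple:
    ds = table if isinstance(table, Dataset) else build_dataset(
        table, trait_source=trait_source)
    if trait not in ds.y:
        raise KeyError(f"unknown trait {trait!r}")
    y = ds.y[trait]
    ok = np.isfinite(y)
    if not ok.all():
        ds = Dataset(X=ds.X[ok], wavelengths=ds.wavelengths,
                     y={k: v[ok] for k, v in ds.y.items()},
                     psi_pd=ds.psi_pd[ok], date_index=ds.date_index[ok],
                     tree_id=ds.tree_id[ok])
        y = ds.y[trait]
    return ds, y


def _fold_fit_predict(R_train, y_train, R_test, max_components, cv_folds,
                      seed, fixed_ncomp=None):
    """Fit the column stage + PLSR on one training fold; predict the test
    rows.  `R_*` are matrices after the row-wise SNV/derivative stages."""
    if fixed_ncomp is None:
        kmax = min(max_components, len(y_train) - 1 - len(y_train) // cv_folds)
        ncomp, curve = select_ncomp(R_train, y_train, max_components=max(kmax, 1),
                                    cv_folds=cv_folds, seed=seed,
                                    rescale_within_folds=True,
                                    return_curve=True)
    else:
        ncomp, curve = fixed_ncomp, None
    sd = R_train.std(axis=0, ddof=1)
    sd = np.where(sd > 1e-15, sd, 1.0)
    model = PLSRegressionNIPALS(n_components=ncomp).fit(R_train / sd, y_train)
    return model.predict(R_test / sd), ncomp, curve


def _row_stage(ds: Dataset, sg_window: int, sg_polyorder: int):
    prep = SpectralPreprocessor(wavelengths=ds.wavelengths,
                                sg_window=sg_window, sg_polyorder=sg_polyorder)
    return prep.row_stage(ds.X)


def _summary(r2s: list) -> dict:
    arr = np.asarray(r2s, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return {"mean_r2": float("nan"), "sd_r2": float("nan"),
                "median_r2": float("nan"), "n_runs": 0}
    return {"mean_r2": float(arr.mean()),
            "sd_r2": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "median_r2": float(np.median(arr)), "n_runs": int(arr.size)}


def loo_cv(table, trait: str, trait_source: str = "fitted",
           max_components: int = 10, cv_folds: int = 10, seed: int = 0,
           fixed_ncomp: int | None = None, sg_window: int = 15,
           sg_polyorder: int = 2) -> ValidationResult:
    """Leave-one-out validation: n leak-free model fits, n held-out
    predictions, pooled observed-vs-predicted metrics.  Deterministic."""
    ds, y = _as_dataset(table, trait, trait_source)
    n = len(y)
    if n < 5:
        raise ValueError("need at least 5 observations for LOO")
    R = _row_stage(ds, sg_window, sg_polyorder)
    preds = np.empty(n)
    runs = []
    for i in range(n):
        tr = np.arange(n) != i
        pred, ncomp, curve = _fold_fit_predict(
            R[tr], y[tr], R[~tr], max_components, cv_folds, seed,
            fixed_ncomp=fixed_ncomp)
        preds[i] = pred[0]
        runs.append(RunResult(r_squared=float("nan"), rmse=float("nan"),
                              r2_sse=float("nan"), n_train=n - 1, n_test=1,
                              n_components=ncomp, rmsep_curve=curve,
                              held_out=[i]))
    pooled = metrics(y, preds)
    return ValidationResult(scheme="loo", runs=runs, observed=y,
                            predicted=preds, pooled=pooled,
                            summary=_summary([pooled.r_squared]))


def repeated_split(table, trait: str, train_fraction: float = 0.8,
                   n_reps: int = 100, seed: int = 0,
                   trait_source: str = "fitted", max_components: int = 10,
                   cv_folds: int = 10, fixed_ncomp: int | None = None,
                   sg_window: int = 15, sg_polyorder: int = 2) -> ValidationResult:
    """Repeated random train/test splits; per-rep metrics, summarised as the
    mean, sd and median of R2 across repetitions."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ds, y = _as_dataset(table, trait, trait_source)
    n = len(y)
    R = _row_stage(ds, sg_window, sg_polyorder)
    rng = np.random.default_rng(seed)
    runs, obs_all, pred_all = [], [], []
    for _ in range(n_reps):
        perm = rng.permutation(n)
        n_train = int(round(train_fraction * n))
        tr, te = perm[:n_train], perm[n_train:]
        if len(te) < 2:
            continue  # cannot score a split this small
        pred, ncomp, curve = _fold_fit_predict(
            R[tr], y[tr], R[te], max_components, cv_folds,
            int(rng.integers(2 ** 31)), fixed_ncomp=fixed_ncomp)
        m = metrics(y[te], pred)
        runs.append(RunResult(r_squared=m.r_squared, rmse=m.rmse,
                              r2_sse=m.r2_sse, n_train=len(tr),
                              n_test=len(te), n_components=ncomp,
                              rmsep_curve=curve, held_out=te.tolist()))
        obs_all.append(y[te])
        pred_all.append(pred)
    if not runs:
        raise ValueError("every repetition produced a test set of size < 2")
    observed = np.concatenate(obs_all)
    predicted = np.concatenate(pred_all)
    return ValidationResult(scheme="repeated_split", runs=runs,
                            observed=observed, predicted=predicted,
                            pooled=metrics(observed, predicted),
                            summary=_summary([r.r_squared for r in runs]))


def select_stress_dates(psi_pd, date_index) -> tuple:
    """The consecutive date pair with the largest individual variation in
    psi_pd.

    'Individual variation' is the within-date variance of psi_pd across
    trees, averaged over the two dates of the pair — pooling across dates
    would conflate the seasonal psi trend with between-tree spread.
    'Consecutive' means adjacent in the sorted list of sampling dates; ties
    resolve to the earlier pair."""
    psi_pd = np.asarray(psi_pd, dtype=float)
    date_index = np.asarray(date_index)
    dates = np.unique(date_index)
    if len(dates) < 3:
        raise ValueError("need at least 3 distinct dates for a stress holdout")
    per_date = {d: float(np.var(psi_pd[date_index == d], ddof=1))
                for d in dates if (date_index == d).sum() >= 2}
    best_pair, best_var = None, -np.inf
    for d1, d2 in zip(dates[:-1], dates[1:]):
        if d1 not in per_date or d2 not in per_date:
            continue
        v = 0.5 * (per_date[d1] + per_date[d2])
        if v > best_var:  # strict: ties keep the earlier pair
            best_pair, best_var = (d1, d2), v
    return best_pair


def stress_holdout(table, trait: str, trait_source: str = "fitted",
                   max_components: int = 10, cv_folds: int = 10, seed: int = 0,
                   fixed_ncomp: int | None = None, sg_window: int = 15,
                   sg_polyorder: int = 2) -> ValidationResult:
    """Train on the calm dates, test on the consecutive date pair with the
    largest within-population psi_pd variance."""
    ds, y = _as_dataset(table, trait, trait_source)
    pair = select_stress_dates(ds.psi_pd, ds.date_index)
    te = np.isin(ds.date_index, pair)
    tr = ~te
    if te.sum() < 2 or tr.sum() < 5:
        raise ValueError("stress holdout leaves too few samples")
    R = _row_stage(ds, sg_window, sg_polyorder)
    pred, ncomp, curve = _fold_fit_predict(R[tr], y[tr], R[te],
                                           max_components, cv_folds, seed,
                                           fixed_ncomp=fixed_ncomp)
    m = metrics(y[te], pred)
    run = RunResult(r_squared=m.r_squared, rmse=m.rmse, r2_sse=m.r2_sse,
                    n_train=int(tr.sum()), n_test=int(te.sum()),
                    n_components=ncomp, rmsep_curve=curve,
                    held_out=np.flatnonzero(te).tolist())
    return ValidationResult(scheme="stress_holdout", runs=[run],
                            observed=y[te], predicted=pred, pooled=m,
                            summary=_summary([m.r_squared]),
                            held_out_dates=tuple(int(d) for d in pair))
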