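"""Calibration-model evaluation: seeded 70/30 splitting, the RMSECV / R2CV /
RMSEP / R2P / RPD metric battery, and the pre-processing x analyte
comparison grid.

Metric conventions (they matter, and they interlock):

* R2 is 1 - SS_res / SS_tot with SS_tot about the observed mean of the same
  set -- the coefficient of determination, not a squared Pearson correlation.
* RPD is the sample SD of the *test-set* observed values divided by RMSEP.
* Under these two conventions RPD = (1 - R2P)^{-1/2} holds exactly, and
  RPD x RMSEP equals the test-set SD, so it is constant across
  pre-processing variants within one analyte and split.  Both identities
  are enforced as invariants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ANALYTES, average_replicates
from .pls import PLSModel, cross_validate
from .preprocess import DEFAULT_SPECS, PreprocessorSpec, apply
from .synthetic import SyntheticDataset


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitPlan:
    """Seeded random train/test partition of sample IDs."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    train_fraction: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test IDs overlap")


def split(sample_ids, train_fraction: float = 0.70, seed: int = 0) -> SplitPlan:
    """Unstratified random split: a seeded permutation, the first
    round(train_fraction * n) IDs to the training set."""
    ids = [str(s) for s in sample_ids]
    n = len(ids)
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    train = tuple(ids[i] for i in perm[:n_train])
    test = tuple(ids[i] for i in perm[n_train:])
    return SplitPlan(train, test, train_fraction, seed)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def rmse(observed, predicted) -> float:
    """Root mean square error."""
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.size == 0 or obs.size != pred.size:
        raise ValueError("observed and predicted must be equal non-zero length")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.size == 0 or obs.size != pred.size:
        raise ValueError("observed and predicted must be equal non-zero length")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero-variance observed vector: R2 undefined")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def rpd(observed_test, rmsep: float) -> float:
    """Ratio of performance to deviation: test-set sample SD / RMSEP."""
    obs = np.asarray(observed_test, dtype=float).ravel()
    if obs.size < 2:
        raise ValueError("need >= 2 test observations for RPD")
    sd = float(np.std(obs, ddof=1))
    if sd == 0:
        raise ValueError("zero-variance observed vector: RPD undefined")
    if rmsep <= 0:
        raise ValueError("RMSEP must be positive for RPD")
    return sd / rmsep


def rpd_from_r2(r2p: float) -> float:
    """The RPD implied by R2P under the population identity (1-R2)^{-1/2}.

    With R2 = 1 - SS_res/SS_tot and RPD = SD/RMSE on the same set, the two
    differ only through the n-1 vs n variance denominators; at test-set
    sizes of a few hundred the identity holds to the third decimal.
    """
    if not (0.0 <= r2p < 1.0):
        raise ValueError("identity defined for R2 in [0, 1)")
    return float((1.0 - r2p) ** -0.5)


# ---------------------------------------------------------------------------
# Expolinear curve (visual aid; fitted to spectra in the source analysis)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpolinearParams:
    """Smooth zero-to-linear transition: asymptotic slope c_m, rate r_m and
    break location t_b."""

    c_m: float
    r_m: float
    t_b: float

    def __post_init__(self) -> None:
        if self.r_m == 0:
            raise ValueError("r_m must be non-zero")


def expolinear(t, params: ExpolinearParams):
    """y = (c_m / r_m) * ln(1 + exp(r_m (t - t_b))), via a stable softplus."""
    t = np.asarray(t, dtype=float)
    z = params.r_m * (t - params.t_b)
    out = (params.c_m / params.r_m) * np.logaddexp(0.0, z)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# The comparison grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricRow:
    """One (analyte x pre-processing) row of the evaluation grid."""

    analyte: str
    preprocessing: str
    rmsecv: float
    r2cv: float
    rmsep: float
    r2p: float
    rpd: float

    def __post_init__(self) -> None:
        if self.rmsecv < 0 or self.rmsep < 0 or self.rpd <= 0:
            raise ValueError("invalid metric magnitudes")


def evaluate_combination(
    dataset: SyntheticDataset,
    analyte: str,
    spec: PreprocessorSpec,
    plan: SplitPlan,
    *,
    n_components: int = 20,
    cv_seed: int = 0,
    n_folds: int = 10,
) -> MetricRow:
    """Run the full pipeline for one analyte and pre-processing choice.

    average replicates -> pre-process -> fit PLS1 on the training partition
    (fixed component count) -> RMSECV/R2CV by k-fold CV on the training
    partition -> predict the test partition -> RMSEP/R2P/RPD.
    """
    averaged = average_replicates(dataset.spectra)
    processed = apply(averaged, spec)
    index = {sid: i for i, sid in enumerate(processed.samples)}
    tr = [index[s] for s in plan.train_ids]
    te = [index[s] for s in plan.test_ids]
    y = dataset.reference.column(analyte)
    X = processed.values

    cv = cross_validate(
        X[tr], y[tr], a_grid=range(1, n_components + 1),
        n_folds=n_folds, seed=cv_seed,
    )
    rmsecv, r2cv = cv.score_at(n_components)

    res = PLSModel(y[tr], X[tr]).fit(n_components)
    pred = res.predict(X[te])
    rmsep = rmse(y[te], pred)
    r2p = r_squared(y[te], pred)
    return MetricRow(
        analyte=analyte,
        preprocessing=spec.name,
        rmsecv=rmsecv,
        r2cv=r2cv,
        rmsep=rmsep,
        r2p=r2p,
        rpd=rpd(y[te], rmsep),
    )


@dataclass
class EvaluationReport:
    """The analyte x pre-processing metric grid plus best-per-metric flags."""

    rows: list[MetricRow]
    split_seed: int
    cv_seed: int
    n_components: int

    _HIGHER_BETTER = {"rmsecv": False, "r2cv": True, "rmsep": False,
                      "r2p": True, "rpd": True}

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "analyte": r.analyte,
                    "preprocessing": r.preprocessing,
                    "RMSECV": r.rmsecv,
                    "R2CV": r.r2cv,
                    "RMSEP": r.rmsep,
                    "R2P": r.r2p,
                    "RPD": r.rpd,
                }
                for r in self.rows
            ]
        )
        return df

    def best_flags(self) -> pd.DataFrame:
        """Boolean grid marking, per analyte and metric, the best row(s).

        Ties flag every tied row."""
        df = self.to_dataframe()
        flags = df[["analyte", "preprocessing"]].copy()
        metric_cols = {"rmsecv": "RMSECV", "r2cv": "R2CV", "rmsep": "RMSEP",
                       "r2p": "R2P", "rpd": "RPD"}
        for key, col in metric_cols.items():
            best = []
            for analyte, grp in df.groupby("analyte"):
                target = grp[col].max() if self._HIGHER_BETTER[key] else grp[col].min()
                best.extend(grp.index[grp[col] == target].tolist())
            flags[col + "_best"] = flags.index.isin(best)
        return flags

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.12g")

    def render(self, decimals: int = 3) -> str:
        """Aligned text table, one analyte block per column group."""
        df = self.to_dataframe().round(decimals)
        return df.to_string(index=False)


def build_report(
    dataset: SyntheticDataset,
    *,
    analytes=ANALYTES,
    specs=DEFAULT_SPECS,
    split_seed: int = 0,
    cv_seed: int = 0,
    n_components: int = 20,
    train_fraction: float = 0.70,
    n_folds: int = 10,
) -> EvaluationReport:
    """Evaluate every analyte x pre-processing combination on one split."""
    for a in analytes:
        if a not in dataset.reference.data.columns:
            raise ValueError(f"reference table lacks analyte {a!r}")
    plan = split(dataset.spectra.samples, train_fraction, split_seed)
    rows = [
        evaluate_combination(
            dataset, analyte, spec, plan,
            n_components=n_components, cv_seed=cv_seed, n_folds=n_folds,
        )
        for analyte in analytes
        for spec in specs
    ]
    return EvaluationReport(
        rows=rows, split_seed=split_seed, cv_seed=cv_seed,
        n_components=n_components,
    )
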