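"""Locus-restricted carrier prediction with an L1-penalised logistic model.

Carrier status is predicted from the CpG probes at the target locus (gene
body plus 1 kb flanks). Features are standardised by training mean/SD, the
L1 penalty is chosen to minimise mean 10-fold cross-validated binomial
deviance over a glmnet-style path, and the final model is refit on the full
training set at the chosen penalty. A frozen :class:`PredictorModel` is a
plain-text-serialisable object that can be applied to any cohort sharing the
probe universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .annotation import PLATFORMS
from .datasets import CARRIER, NON_CARRIER, MethylationDataset

__all__ = [
    "PredictorModel",
    "CarrierClassifier",
    "select_locus_probes",
    "split_train_test",
    "train_lasso",
    "predict_carriers",
    "locus_pca",
    "save_model",
    "load_model",
]


def select_locus_probes(
    annotation: pd.DataFrame,
    platform: str = "epicv2",
    region: tuple[str, int, int] | None = None,
) -> list[str]:
    """Locus probes present on the requested array platform, by position.

    A probe qualifies when its ``in_region`` flag is set (or, if a
    ``region=(chrom, start, end)`` is given, when its position falls in
    that 1-based inclusive interval) and its platform presence flag is
    true. Raises when nothing qualifies.
    """
    platform = platform.lower()
    if platform not in PLATFORMS:
        raise ValueError(f"unknown platform {platform!r}; choose from {PLATFORMS}")
    ann = annotation
    if region is not None:
        chrom, start, end = region
        in_region = (
            (ann["chrom"].astype(str) == str(chrom))
            & (ann["pos"] >= start)
            & (ann["pos"] <= end)
        )
    else:
        in_region = ann["in_region"].astype(bool)
    keep = ann[in_region & ann[platform].astype(bool)].sort_values("pos")
    if keep.empty:
        raise ValueError(
            f"no locus probes selected for platform {platform!r}; "
            "check the region coordinates and platform flags"
        )
    return keep["probe_id"].tolist()


def split_train_test(
    ds: MethylationDataset,
    train_fraction: float = 0.7,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[MethylationDataset, MethylationDataset]:
    """Random disjoint, exhaustive train/test split of the cohort.

    When stratified (default), the per-class training count is
    ``round(train_fraction * n_class)``, so the carrier proportion is
    preserved to within one sample in each part. Deterministic given seed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    y = ds.carrier_mask()
    if y.all() or not y.any():
        raise ValueError("both carrier classes must be present to split")
    rng = np.random.default_rng(seed)
    n = ds.n_samples
    train_idx: list[int] = []
    if stratified:
        for cls in (False, True):
            members = np.flatnonzero(y == cls)
            k = int(round(train_fraction * len(members)))
            if k == 0 or k == len(members):
                raise ValueError(
                    "stratified split leaves a class absent from train or "
                    f"test (class size {len(members)})"
                )
            train_idx.extend(rng.permutation(members)[:k])
    else:
        k = int(round(train_fraction * n))
        train_idx.extend(rng.permutation(n)[:k])
    train_mask = np.zeros(n, dtype=bool)
    train_mask[np.asarray(train_idx)] = True
    ids = np.asarray(ds.sample_ids)
    return ds.subset_samples(ids[train_mask]), ds.subset_samples(ids[~train_mask])


@dataclass
class PredictorModel:
    """Frozen locus classifier: probes, scaling, coefficients, penalty.

    Coefficients are on the standardised feature scale; ``means`` and
    ``sds`` store the training-set standardisation so the model is portable
    across cohorts. ``penalty`` is the chosen regularisation strength
    lambda (glmnet parameterisation, = 1 / (C * n_train)).
    """

    probe_ids: list[str]
    intercept: float
    coefficients: np.ndarray
    penalty: float
    means: np.ndarray
    sds: np.ndarray
    cv_folds: int = 10
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        k = len(self.probe_ids)
        if not (len(self.coefficients) == len(self.means) == len(self.sds) == k):
            raise ValueError("coefficient/scaling lengths must match probe_ids")
        if self.penalty <= 0:
            raise ValueError("penalty must be positive")
        if (self.sds <= 0).any():
            raise ValueError("standardisation SDs must be positive")

    @property
    def selected_probes(self) -> list[str]:
        """Probes with non-zero coefficients."""
        return [p for p, c in zip(self.probe_ids, self.coefficients) if c != 0.0]

    def predict_proba(self, ds: MethylationDataset) -> pd.Series:
        missing = [p for p in self.probe_ids if p not in ds.m_values.columns]
        if missing:
            raise ValueError(f"dataset lacks model probes: {missing[:10]}")
        X = ds.m_values[self.probe_ids].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("missing M-values among model probes")
        z = (X - self.means) / self.sds
        return pd.Series(
            expit(self.intercept + z @ self.coefficients),
            index=ds.m_values.index,
            name="probability",
        )

    def summary(self) -> str:
        lines = [
            "Locus carrier classifier (L1 logistic regression)",
            "=" * 50,
            f"features:        {len(self.probe_ids)} probes "
            f"({len(self.selected_probes)} with non-zero coefficients)",
            f"penalty lambda:  {self.penalty:.4g} "
            f"(chosen by {self.cv_folds}-fold CV deviance)",
            f"intercept:       {self.intercept:+.4f}",
            "",
            "probe            coef (standardised)",
        ]
        for pid, c in zip(self.probe_ids, self.coefficients):
            if c != 0.0:
                lines.append(f"{pid:<16s} {c:+.4f}")
        return "\n".join(lines)


class CarrierClassifier:
    """Model object: locus probes + labelled training data -> PredictorModel.

    Thin statsmodels-style wrapper around :func:`train_lasso`::

        clf = CarrierClassifier(train_ds, probes)
        model = clf.fit(cv_folds=10, seed=1)
        calls = predict_carriers(model, test_ds)
    """

    def __init__(self, train: MethylationDataset, probes: list[str]):
        self.train = train
        self.probes = list(probes)

    def fit(self, cv_folds: int = 10, seed: int = 0, n_lambdas: int = 30) -> PredictorModel:
        return train_lasso(
            self.train, self.probes, cv_folds=cv_folds, seed=seed,
            n_lambdas=n_lambdas,
        )


def _lambda_path(Xz: np.ndarray, y: np.ndarray, n_lambdas: int) -> np.ndarray:
    """glmnet-style geometric penalty path from lambda_max down 4 decades."""
    n = len(y)
    resid = y - y.mean()
    lam_max = np.abs(Xz.T @ resid).max() / n
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * 1e-4, n_lambdas)


def train_lasso(
    train: MethylationDataset,
    probes: list[str],
    cv_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 30,
) -> PredictorModel:
    """Fit the L1-penalised logistic carrier model with CV penalty choice.

    Features are standardised by training mean/SD (constant probes are
    dropped with a warning). The penalty is chosen to minimise mean
    cross-validated binomial deviance over a geometric path, with folds
    stratified by carrier status so every fold contains carriers; the final
    model is refit on the whole training set at that penalty.
    """
    missing = [p for p in probes if p not in train.m_values.columns]
    if missing:
        raise ValueError(f"training data lacks probes: {missing[:10]}")
    y = train.carrier_mask().astype(int)
    if y.sum() < 2:
        raise ValueError("need >= 2 carriers in the training set")
    X = train.m_values[list(probes)].to_numpy(dtype=float)
    sds = X.std(axis=0, ddof=0)
    keep = sds > 0
    if not keep.all():
        dropped = [p for p, k in zip(probes, keep) if not k]
        warnings.warn(f"dropping constant probes before fitting: {dropped}")
        probes = [p for p, k in zip(probes, keep) if k]
        X = X[:, keep]
        sds = sds[keep]
    if X.shape[1] == 0:
        raise ValueError("no non-constant probes left to fit")
    means = X.mean(axis=0)
    Xz = (X - means) / sds

    n = len(y)
    lambdas = _lambda_path(Xz, y, n_lambdas)
    Cs = 1.0 / (n * lambdas)
    folds = min(cv_folds, int(y.sum()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    clf = LogisticRegressionCV(
        Cs=Cs,
        cv=skf,
        l1_ratios=(1.0,),  # pure L1 penalty
        solver="liblinear",
        scoring="neg_log_loss",  # mean CV binomial deviance (up to sign/2)
        refit=True,
        tol=1e-8,  # tight convergence: predictions reproducible to ~1e-6
        max_iter=5000,
        random_state=seed,
        use_legacy_attributes=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        clf.fit(Xz, y)
    best_C = float(np.atleast_1d(clf.C_)[0])
    penalty = 1.0 / (n * best_C)
    return PredictorModel(
        probe_ids=list(probes),
        intercept=float(np.ravel(clf.intercept_)[0]),
        coefficients=np.asarray(clf.coef_).reshape(-1).copy(),
        penalty=penalty,
        means=means,
        sds=sds,
        cv_folds=folds,
        training_meta={
            "seed": seed,
            "n_train": n,
            "n_carriers_train": int(y.sum()),
            "n_lambdas": n_lambdas,
        },
    )


def predict_carriers(
    model: PredictorModel, ds: MethylationDataset, threshold: float = 0.5
) -> pd.DataFrame:
    """Per-sample carrier probability and label at the given threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    prob = model.predict_proba(ds)
    label = np.where(prob > threshold, CARRIER, NON_CARRIER)
    return pd.DataFrame({"probability": prob, "label": label}, index=prob.index)


def locus_pca(ds: MethylationDataset, probes: list[str]) -> pd.DataFrame:
    """First two principal-component scores over the locus probes.

    Columns are mean-centred; the sign of each component is fixed by making
    the loading of the first (left-most) probe non-negative, so scores are
    reproducible across probe orderings.
    """
    if ds.n_samples < 3:
        raise ValueError("need >= 3 samples for PCA")
    probes = list(probes)
    if len(probes) < 2:
        raise ValueError("need >= 2 probes for PCA")
    X = ds.m_values[probes].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    if not (Xc.var(axis=0) > 0).any():
        raise ValueError("all probes have zero variance")
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    order = np.argsort(probes)  # sign anchor independent of column order
    anchor = order[0]
    scores = u[:, :2] * s[:2]
    for k in range(2):
        j = next((i for i in order if vt[k, i] != 0), anchor)
        if vt[k, j] < 0:
            scores[:, k] = -scores[:, k]
    return pd.DataFrame(scores, index=ds.m_values.index, columns=["PC1", "PC2"])


# -- plain-text model serialisation --------------------------------------
def save_model(model: PredictorModel, path) -> None:
    """Write a frozen model as portable plain text."""
    with open(path, "w") as fh:
        fh.write("#repeatmeth-predictor-v1\n")
        fh.write(f"intercept\t{float(model.intercept)!r}\n")
        fh.write(f"penalty\t{float(model.penalty)!r}\n")
        fh.write(f"cv_folds\t{model.cv_folds}\n")
        for key, val in model.training_meta.items():
            fh.write(f"meta:{key}\t{val}\n")
        fh.write("#coefficients\nprobe_id\tmean\tsd\tcoef\n")
        for pid, mu, sd, c in zip(
            model.probe_ids, model.means, model.sds, model.coefficients
        ):
            fh.write(f"{pid}\t{float(mu)!r}\t{float(sd)!r}\t{float(c)!r}\n")


def load_model(path) -> PredictorModel:
    """Read a model written by :func:`save_model`."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != "#repeatmeth-predictor-v1":
        raise ValueError(f"not a repeatmeth predictor file: {path}")
    header: dict[str, str] = {}
    meta: dict[str, str] = {}
    rows: list[tuple[str, float, float, float]] = []
    in_coef = False
    for line in lines[1:]:
        if line == "#coefficients":
            in_coef = True
            continue
        if not line or line.startswith("probe_id\t"):
            continue
        parts = line.split("\t")
        if in_coef:
            rows.append(
                (parts[0], float(parts[1]), float(parts[2]), float(parts[3]))
            )
        elif parts[0].startswith("meta:"):
            meta[parts[0][5:]] = parts[1]
        else:
            header[parts[0]] = parts[1]
    return PredictorModel(
        probe_ids=[r[0] for r in rows],
        intercept=float(header["intercept"]),
        coefficients=np.array([r[3] for r in rows]),
        penalty=float(header["penalty"]),
        means=np.array([r[1] for r in rows]),
        sds=np.array([r[2] for r in rows]),
        cv_folds=int(header.get("cv_folds", 10)),
        training_meta=meta,
    )
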