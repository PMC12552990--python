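"""Core data containers and file I/O for methylation array matrices.

The central object is :class:`MethylationDataset`: a samples x probes matrix
of M-values together with per-sample covariates (age, sex, six leukocyte
fractions, smoking score, batch) and an optional tri-state carrier label.
All analysis modules operate on this container; plain delimited text is the
only on-disk format (TSV by default, comma accepted), with ``NA`` as the
missing token.

M-values are log2 methylated/unmethylated odds; beta-values are methylated
signal fractions in [0, 1]. :func:`beta_to_m` / :func:`m_to_beta` convert
between the two scales.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MethylationDataset",
    "SampleFilterReport",
    "ProbeFilterReport",
    "beta_to_m",
    "m_to_beta",
    "read_methylation_matrix",
    "write_methylation_matrix",
    "read_covariates",
    "load_dataset",
    "filter_samples",
    "filter_probes",
    "drop_incomplete_probes",
    "drop_unlabelled_samples",
    "CELL_TYPES",
    "CARRIER",
    "NON_CARRIER",
    "UNKNOWN",
    "MISSING_TOKEN",
]

#: Reference-based leukocyte fractions carried as covariates.
CELL_TYPES = ("CD8T", "CD4T", "NK", "B", "monocyte", "neutrophil")

CARRIER = "carrier"
NON_CARRIER = "non_carrier"
UNKNOWN = "unknown"
CARRIER_STATES = (CARRIER, NON_CARRIER, UNKNOWN)

MISSING_TOKEN = "NA"

#: Clipping bound applied to beta-values before the log-odds transform.
BETA_EPS = 1e-6

#: Tolerance on the sum of the six cell fractions per sample.
CELL_SUM_TOL = 0.02


def beta_to_m(beta):
    """Convert beta-values (methylated fraction) to M-values (log2 odds).

    ``M = log2(beta / (1 - beta))`` after clipping beta to
    ``[1e-6, 1 - 1e-6]`` so boundary values map to large finite M rather
    than +/- infinity.

    Parameters
    ----------
    beta : float or array-like
        Methylation proportions, each in [0, 1].

    Returns
    -------
    float or ndarray
        M-values, same shape as the input.
    """
    arr = np.asarray(beta, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (arr < 0) | (arr > 1)
    if np.any(bad) or np.any(np.isnan(arr)):
        raise ValueError("beta values must lie in [0, 1] and be non-missing")
    clipped = np.clip(arr, BETA_EPS, 1.0 - BETA_EPS)
    m = np.log2(clipped / (1.0 - clipped))
    return float(m) if np.isscalar(beta) else m


def m_to_beta(m):
    """Convert M-values back to beta-values: ``beta = 2^M / (1 + 2^M)``."""
    arr = np.asarray(m, dtype=float)
    # expit formulation is overflow-safe for large |M|
    from scipy.special import expit

    beta = expit(arr * np.log(2.0))
    return float(beta) if np.isscalar(m) else beta


@dataclass
class MethylationDataset:
    """Samples x probes M-value matrix with covariates and carrier labels.

    Parameters
    ----------
    m_values : DataFrame
        Samples in rows (index = sample ids), probes in columns. May contain
        NaN for missing measurements.
    covariates : DataFrame, optional
        Indexed by sample id. Recognised columns: ``age`` (years), ``sex``
        (0/1 code), the six cell fractions in :data:`CELL_TYPES`
        (proportions summing to 1), ``smoking_score`` and ``batch``
        (categorical label). Extra columns are carried through untouched.
    carrier : Series, optional
        Per-sample label, values in ``{"carrier", "non_carrier", "unknown"}``.
    metadata : dict
        Free-form provenance (sex code mapping, generator config, ...).
    """

    m_values: pd.DataFrame
    covariates: pd.DataFrame | None = None
    carrier: pd.Series | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.m_values = self.m_values.astype(float)
        self._check_unique(self.m_values.index, "sample")
        self._check_unique(self.m_values.columns, "probe")
        if self.covariates is not None:
            missing = self.m_values.index.difference(self.covariates.index)
            if len(missing):
                raise ValueError(
                    f"covariates missing for samples: {list(missing[:10])}"
                )
            self.covariates = self.covariates.loc[self.m_values.index]
            self._check_cell_fractions(self.covariates)
        if self.carrier is not None:
            self.carrier = pd.Series(self.carrier).reindex(self.m_values.index)
            bad = set(self.carrier.dropna().unique()) - set(CARRIER_STATES)
            if bad:
                raise ValueError(f"invalid carrier labels: {sorted(bad)}")
            self.carrier = self.carrier.fillna(UNKNOWN)

    @staticmethod
    def _check_unique(index, what):
        if index.has_duplicates:
            dups = index[index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate {what} ids: {dups[:10]}")

    @staticmethod
    def _check_cell_fractions(cov):
        present = [c for c in CELL_TYPES if c in cov.columns]
        if not present:
            return
        if len(present) != len(CELL_TYPES):
            raise ValueError(
                f"incomplete cell fraction columns: have {present}"
            )
        frac = cov[list(CELL_TYPES)].to_numpy(dtype=float)
        if (frac < 0).any() or (frac > 1).any():
            raise ValueError("cell fractions must lie in [0, 1]")
        sums = frac.sum(axis=1)
        off = np.abs(sums - 1.0) > CELL_SUM_TOL
        if off.any():
            bad = cov.index[off][:10].tolist()
            raise ValueError(
                f"cell fractions must sum to 1 +/- {CELL_SUM_TOL}: {bad}"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return self.m_values.index.tolist()

    @property
    def probe_ids(self) -> list[str]:
        return self.m_values.columns.tolist()

    @property
    def n_samples(self) -> int:
        return self.m_values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.m_values.shape[1]

    def __repr__(self):  # pragma: no cover - cosmetic
        lab = ""
        if self.carrier is not None:
            n_car = int((self.carrier == CARRIER).sum())
            lab = f", {n_car} carriers"
        return (
            f"<MethylationDataset {self.n_samples} samples x "
            f"{self.n_probes} probes{lab}>"
        )

    # -- subsetting (order preserving) -----------------------------------
    def subset_samples(self, sample_ids) -> "MethylationDataset":
        """Restrict to the given samples, preserving their order."""
        idx = pd.Index(sample_ids)
        missing = idx.difference(self.m_values.index)
        if len(missing):
            raise KeyError(f"unknown sample ids: {list(missing[:10])}")
        return MethylationDataset(
            m_values=self.m_values.loc[idx],
            covariates=None if self.covariates is None else self.covariates.loc[idx],
            carrier=None if self.carrier is None else self.carrier.loc[idx],
            metadata=dict(self.metadata),
        )

    def subset_probes(self, probe_ids) -> "MethylationDataset":
        """Restrict to the given probes, preserving their order."""
        idx = pd.Index(probe_ids)
        missing = idx.difference(self.m_values.columns)
        if len(missing):
            raise KeyError(f"unknown probe ids: {list(missing[:10])}")
        return MethylationDataset(
            m_values=self.m_values.loc[:, idx],
            covariates=self.covariates,
            carrier=self.carrier,
            metadata=dict(self.metadata),
        )

    def carrier_mask(self) -> np.ndarray:
        """Boolean vector: True for carriers. Requires no unknown labels."""
        if self.carrier is None:
            raise ValueError("dataset has no carrier labels")
        if (self.carrier == UNKNOWN).any():
            raise ValueError(
                "dataset contains samples with unknown carrier status; "
                "drop them first (drop_unlabelled_samples)"
            )
        return (self.carrier == CARRIER).to_numpy()


# -- reports -------------------------------------------------------------
@dataclass
class SampleFilterReport:
    """Samples removed by the call-rate filter and their missing fractions."""

    removed: pd.Series  # sample id -> missing fraction
    threshold: float

    @property
    def n_removed(self) -> int:
        return len(self.removed)


@dataclass
class ProbeFilterReport:
    """Probes removed by QC-flag filtering, tallied by flag and chromosome."""

    removed_ids: list[str]
    counts_by_flag: dict[str, int]
    counts_by_chrom: dict[str, int]

    @property
    def n_removed(self) -> int:
        return len(self.removed_ids)


# -- delimited text I/O --------------------------------------------------
def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_methylation_matrix(
    path, orientation: str = "samples_in_rows", sep: str | None = None
) -> pd.DataFrame:
    """Read a delimited M-value matrix, returning samples x probes.

    Parameters
    ----------
    path : path-like
        Delimited text with a header row of ids and ids in the first
        column; ``NA`` marks missing values.
    orientation : {"samples_in_rows", "probes_in_rows"}
        How the *file* is laid out. It is never guessed; the returned
        frame is always samples x probes.
    sep : str, optional
        Field separator; defaults to tab (comma for ``.csv``).

    Raises
    ------
    ValueError
        On duplicate row/column ids (the duplicates are named) or a
        non-numeric cell (its row and column are named).
    """
    if orientation not in ("samples_in_rows", "probes_in_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    path = Path(path)
    sep = sep or _sep_for(path)
    with open(path) as fh:  # pandas mangles duplicate header ids; check raw
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    dups = sorted({h for h in header if h in seen or seen.add(h)})
    if dups:
        raise ValueError(f"duplicate column ids in {path.name}: {dups[:10]}")
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=[MISSING_TOKEN], keep_default_na=False
    )
    for axis, what in ((df.index, "row"), (df.columns, "column")):
        if axis.has_duplicates:
            dups = axis[axis.duplicated()].unique().tolist()
            raise ValueError(f"duplicate {what} ids in {path.name}: {dups[:10]}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise ValueError(
                    f"non-numeric value at row {row!r}, column {col!r} "
                    f"in {path.name}: {df.loc[row, col]!r}"
                ) from None
        raise
    if orientation == "probes_in_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_methylation_matrix(
    ds_or_frame, path, orientation: str = "samples_in_rows", sep: str | None = None
) -> None:
    """Write an M-value matrix as delimited text (inverse of the reader)."""
    df = ds_or_frame.m_values if isinstance(ds_or_frame, MethylationDataset) else ds_or_frame
    if orientation == "probes_in_rows":
        df = df.T
    elif orientation != "samples_in_rows":
        raise ValueError(f"unknown orientation: {orientation!r}")
    path = Path(path)
    df.to_csv(path, sep=sep or _sep_for(path), na_rep=MISSING_TOKEN)


def read_covariates(path, sep: str | None = None) -> pd.DataFrame:
    """Read the per-sample covariate table keyed by sample id.

    A ``carrier`` column, when present, is validated against the
    tri-state vocabulary and returned with the rest of the table.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep=sep or _sep_for(path), index_col=0,
        na_values=[MISSING_TOKEN], keep_default_na=False,
    )
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {path.name}: {dups[:10]}")
    return df


def load_dataset(
    matrix_path,
    covariates_path=None,
    orientation: str = "samples_in_rows",
) -> MethylationDataset:
    """Assemble a :class:`MethylationDataset` from matrix + covariate files."""
    m = read_methylation_matrix(matrix_path, orientation=orientation)
    cov = carrier = None
    if covariates_path is not None:
        cov = read_covariates(covariates_path)
        if "carrier" in cov.columns:
            carrier = cov["carrier"]
            cov = cov.drop(columns=["carrier"])
    return MethylationDataset(m_values=m, covariates=cov, carrier=carrier)


def write_dataset(ds: MethylationDataset, out_dir, prefix: str = "cohort") -> dict:
    """Write matrix and covariates under ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"matrix": out_dir / f"{prefix}_mvalues.tsv"}
    write_methylation_matrix(ds, paths["matrix"])
    if ds.covariates is not None or ds.carrier is not None:
        cov = ds.covariates.copy() if ds.covariates is not None else pd.DataFrame(
            index=ds.m_values.index
        )
        if ds.carrier is not None:
            cov["carrier"] = ds.carrier
        paths["covariates"] = out_dir / f"{prefix}_covariates.tsv"
        cov.to_csv(paths["covariates"], sep="\t", na_rep=MISSING_TOKEN)
    return paths


# -- QC filters ----------------------------------------------------------
def filter_samples(
    ds: MethylationDataset, max_missing_fraction: float
) -> tuple[MethylationDataset, SampleFilterReport]:
    """Drop samples whose fraction of missing probe values exceeds the cut.

    Mirrors array call-rate filtering: a sample failing hybridisation shows
    missing values across many probes. Sample order is preserved.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    frac = ds.m_values.isna().mean(axis=1)
    removed = frac[frac > max_missing_fraction]
    keep = frac.index[frac <= max_missing_fraction]
    if len(keep) == 0:
        raise ValueError("sample filter would remove every sample")
    report = SampleFilterReport(removed=removed, threshold=max_missing_fraction)
    return ds.subset_samples(keep), report


def filter_probes(
    ds: MethylationDataset, annotation: pd.DataFrame, flags_to_drop: set[str]
) -> tuple[MethylationDataset, ProbeFilterReport]:
    """Drop probes whose QC flags intersect ``flags_to_drop``.

    ``annotation`` must cover every probe in the dataset and provide
    ``chrom`` and ``qc_flags`` columns (``qc_flags`` as a semicolon-joined
    string or a set). A probe carrying several offending flags is counted
    once in the total but under each flag in the per-flag tally.
    """
    from .annotation import parse_qc_flags

    ann = annotation.set_index("probe_id") if "probe_id" in annotation.columns else annotation
    missing = pd.Index(ds.probe_ids).difference(ann.index)
    if len(missing):
        raise ValueError(
            f"probes missing from annotation (first 10): {list(missing[:10])}"
        )
    flags_to_drop = set(flags_to_drop)
    removed_ids: list[str] = []
    by_flag: dict[str, int] = {}
    by_chrom: dict[str, int] = {}
    if flags_to_drop:
        for pid in ds.probe_ids:
            flags = parse_qc_flags(ann.at[pid, "qc_flags"])
            hit = flags & flags_to_drop
            if hit:
                removed_ids.append(pid)
                for f in hit:
                    by_flag[f] = by_flag.get(f, 0) + 1
                chrom = str(ann.at[pid, "chrom"])
                by_chrom[chrom] = by_chrom.get(chrom, 0) + 1
    keep = [p for p in ds.probe_ids if p not in set(removed_ids)]
    report = ProbeFilterReport(
        removed_ids=removed_ids, counts_by_flag=by_flag, counts_by_chrom=by_chrom
    )
    return ds.subset_probes(keep), report


def drop_incomplete_probes(
    ds: MethylationDataset,
) -> tuple[MethylationDataset, list[str]]:
    """Drop probes with any missing value across the retained samples.

    Per-probe least squares needs complete columns; imputation is out of
    scope, so incomplete probes are removed before modelling.
    """
    has_na = ds.m_values.isna().any(axis=0)
    dropped = ds.m_values.columns[has_na].tolist()
    if not dropped:
        return ds, []
    return ds.subset_probes(ds.m_values.columns[~has_na]), dropped


def drop_unlabelled_samples(
    ds: MethylationDataset,
) -> tuple[MethylationDataset, list[str]]:
    """Drop samples whose carrier status is unknown (e.g. no repeat assay)."""
    if ds.carrier is None:
        raise ValueError("dataset has no carrier labels")
    unknown = ds.carrier.index[ds.carrier == UNKNOWN].tolist()
    if not unknown:
        return ds, []
    keep = ds.carrier.index[ds.carrier != UNKNOWN]
    return ds.subset_samples(keep), unknown
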