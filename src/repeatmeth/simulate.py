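"""Synthetic EPIC-style methylation cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a blood-DNA cohort of a few hundred samples in which a small
minority carry a pathogenic repeat expansion, measured on tens of thousands
of null background CpG probes plus a handful of locus probes that are
hypermethylated (positive M-value shift) in carriers. Covariate structure
(age, sex, leukocyte composition, smoking, batch) is implanted on a random
subset of probes so that covariate adjustment actually matters, and probe
noise levels are drawn from a right-skewed distribution so that
empirical-Bayes variance moderation has heterogeneity to shrink.

Everything is deterministic given the config seed: a single root
``SeedSequence`` is split into named child streams (covariates, baselines,
effects, noise, missingness), so adding samples or probes perturbs only the
streams involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import PLATFORMS, load_locus_manifest
from .datasets import (
    CARRIER,
    CELL_TYPES,
    NON_CARRIER,
    UNKNOWN,
    MethylationDataset,
    beta_to_m,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_cohort",
    "implant_carrier_profile",
    "generate_independent_cohort",
    "TOP_LOCUS_PROBES",
]

#: The eight locus probes used by the default implanted-effect profile,
#: ordered from strongest to weakest carrier hypermethylation.
TOP_LOCUS_PROBES = (
    "cg13533410",
    "cg01589701",
    "cg01589155",
    "cg14363787",
    "cg23074747",
    "cg03854581",
    "cg13533404",
    "cg05151778",
)

#: Mean beta per island context: islands are canonically hypomethylated,
#: open sea hypermethylated.
DEFAULT_BASELINE_BETA = {
    "island": 0.15,
    "shore": 0.35,
    "shelf": 0.55,
    "open_sea": 0.75,
}

#: SD of the random per-probe slope for each covariate (M units per unit of
#: the centred covariate), applied to a random subset of probes.
DEFAULT_COVARIATE_EFFECTS = {
    "age": 0.01,
    "sex": 0.3,
    "smoking_score": 0.2,
    "neutrophil": 1.0,
}

#: Dirichlet means for the six leukocyte fractions (neutrophil-dominant,
#: typical of whole blood).
CELL_MEANS = np.array([0.08, 0.15, 0.06, 0.06, 0.08, 0.57])
CELL_CONCENTRATION = 60.0


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the discovery-cohort conditions: 277 samples with 27
    expansion carriers, 20,000 null background probes plus the packaged
    locus manifest, four experimental batches, no missing values.
    """

    n_samples: int = 277
    n_carriers: int = 27
    n_background_probes: int = 20_000
    locus_manifest: pd.DataFrame | None = None
    affected_probes: list[tuple[str, float]] = field(default_factory=list)
    baseline_beta_by_context: dict = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_BETA)
    )
    baseline_m_jitter_sd: float = 0.5
    noise_sd_m: float = 0.4  #: median per-probe residual SD (M units)
    noise_sd_log_spread: float = 0.4  #: sigma of the lognormal SD spread
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    covariate_affected_fraction: float = 0.10
    batch_effect_sd: float = 0.2  #: SD of per-(probe, batch) offsets (M units)
    batch_affected_fraction: float = 0.20
    n_batches: int = 4
    missing_rate: float = 0.0
    n_failing_samples: int = 0
    failing_missing_fraction: float = 0.10
    n_unlabelled: int = 0  #: samples generated without a carrier assay
    seed: int = 0

    def __post_init__(self):
        if self.locus_manifest is None:
            self.locus_manifest = load_locus_manifest()
        if self.n_carriers > self.n_samples:
            raise ValueError("n_carriers cannot exceed n_samples")
        if any(v < 0 for v in (
            self.n_samples, self.n_carriers, self.n_background_probes,
            self.n_failing_samples, self.n_unlabelled, self.n_batches,
        )):
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        for pid, delta in self.affected_probes:
            if not np.isfinite(delta):
                raise ValueError(f"non-finite delta_m for {pid}")
        known = set(self.locus_manifest["probe_id"])
        missing = [p for p, _ in self.affected_probes if p not in known]
        if missing:
            raise ValueError(
                f"affected probes absent from locus manifest: {missing}"
            )


@dataclass
class GroundTruth:
    """What the generator implanted: labels, affected probes, null flags."""

    carrier: pd.Series  #: true tri-state-free label per sample
    affected: dict[str, float]  #: probe id -> implanted delta_m
    is_null: pd.Series  #: True for probes with no carrier effect

    @property
    def carrier_ids(self) -> list[str]:
        return self.carrier.index[self.carrier == CARRIER].tolist()


def implant_carrier_profile(cfg: SimulationConfig) -> SimulationConfig:
    """Mark the eight top locus probes as carrier-hypermethylated.

    Effect sizes decrease linearly from +4.0 to +1.5 M units across
    :data:`TOP_LOCUS_PROBES` (strongest first). Idempotent; raises if the
    manifest lacks any of the eight ids.
    """
    known = set(cfg.locus_manifest["probe_id"])
    missing = [p for p in TOP_LOCUS_PROBES if p not in known]
    if missing:
        raise ValueError(f"locus manifest missing implant probes: {missing}")
    deltas = np.linspace(4.0, 1.5, len(TOP_LOCUS_PROBES))
    affected = [(p, float(d)) for p, d in zip(TOP_LOCUS_PROBES, deltas)]
    return replace(cfg, affected_probes=affected)


def _streams(seed: int, cohort: str) -> dict[str, np.random.Generator]:
    """Named child generators split from one root seed sequence."""
    names = (
        "labels", "covariates", "baseline", "noise_sd", "cov_effects",
        "batch_effects", "noise", "missing", "background_ann",
    )
    root = np.random.SeedSequence(seed, spawn_key=(hash(cohort) % (2**31),))
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _background_annotation(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Null background probes spread over the autosomes."""
    chroms = rng.integers(1, 23, size=n)
    pos = rng.integers(1, 240_000_000, size=n)
    rel = rng.choice(
        ["island", "shore", "shelf", "open_sea"],
        size=n,
        p=[0.30, 0.25, 0.10, 0.35],
    )
    ann = pd.DataFrame(
        {
            "probe_id": [f"bg{i:07d}" for i in range(n)],
            "chrom": [f"chr{c}" for c in chroms],
            "pos": pos,
            "island_relation": rel,
            "gene": "",
            "in_region": False,
            "epicv2": True,
            "epicv1": False,
            "m450k": False,
            "m27k": False,
            "qc_flags": "",
        }
    )
    return ann


def _sample_covariates(
    n: int, n_batches: int, rng: np.random.Generator, sample_ids
) -> pd.DataFrame:
    age = rng.normal(63.0, 8.0, size=n)
    while True:  # truncate to a plausible clinic age range
        out = (age < 30) | (age > 95)
        if not out.any():
            break
        age[out] = rng.normal(63.0, 8.0, size=int(out.sum()))
    sex = rng.binomial(1, 0.4, size=n)
    cells = rng.dirichlet(CELL_MEANS * CELL_CONCENTRATION, size=n)
    smoking = rng.normal(0.0, 1.0, size=n)
    batch = rng.integers(0, max(n_batches, 1), size=n)
    cov = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            **{ct: cells[:, i] for i, ct in enumerate(CELL_TYPES)},
            "smoking_score": smoking,
            "batch": [f"batch{b + 1}" for b in batch],
        },
        index=sample_ids,
    )
    return cov


def _synthesise(
    cfg: SimulationConfig,
    n_carriers: int,
    cohort: str,
    sample_prefix: str,
) -> tuple[MethylationDataset, pd.DataFrame, GroundTruth]:
    """Shared machinery behind the discovery and validation cohorts."""
    rngs = _streams(cfg.seed, cohort)
    n = cfg.n_samples
    sample_ids = pd.Index([f"{sample_prefix}{i + 1:05d}" for i in range(n)])

    ann = pd.concat(
        [
            cfg.locus_manifest.copy(),
            _background_annotation(cfg.n_background_probes, rngs["background_ann"]),
        ],
        ignore_index=True,
    )
    probe_ids = ann["probe_id"].to_numpy()
    p = len(probe_ids)

    # -- sample roles: failing call-rate / no repeat assay / clean ------
    lab_rng = rngs["labels"]
    order = lab_rng.permutation(n)
    failing = order[: cfg.n_failing_samples]
    unlabelled = order[cfg.n_failing_samples : cfg.n_failing_samples + cfg.n_unlabelled]
    clean = order[cfg.n_failing_samples + cfg.n_unlabelled :]
    if n_carriers > len(clean):
        raise ValueError("not enough clean samples to place all carriers")
    carrier_idx = lab_rng.choice(clean, size=n_carriers, replace=False)

    true_label = np.full(n, NON_CARRIER, dtype=object)
    true_label[carrier_idx] = CARRIER
    observed = true_label.copy()
    observed[unlabelled] = UNKNOWN

    cov = _sample_covariates(n, cfg.n_batches, rngs["covariates"], sample_ids)

    # -- per-probe baselines and noise scales ---------------------------
    base_rng = rngs["baseline"]
    beta0 = np.array(
        [cfg.baseline_beta_by_context[r] for r in ann["island_relation"]]
    )
    base_m = beta_to_m(beta0) + base_rng.normal(0.0, cfg.baseline_m_jitter_sd, size=p)
    sd = cfg.noise_sd_m * np.exp(
        rngs["noise_sd"].normal(0.0, cfg.noise_sd_log_spread, size=p)
    )

    M = np.tile(base_m, (n, 1))

    # -- covariate structure on a random subset of probes ---------------
    eff_rng = rngs["cov_effects"]
    n_affected = int(round(cfg.covariate_affected_fraction * p))
    for name, tau in cfg.covariate_effects.items():
        if name not in cov.columns or n_affected == 0:
            continue
        idx = eff_rng.choice(p, size=n_affected, replace=False)
        slopes = eff_rng.normal(0.0, tau, size=n_affected)
        x = cov[name].to_numpy(dtype=float)
        M[:, idx] += np.outer(x - x.mean(), slopes)

    # -- batch offsets ---------------------------------------------------
    bat_rng = rngs["batch_effects"]
    n_batch_probes = int(round(cfg.batch_affected_fraction * p))
    if cfg.n_batches > 1 and n_batch_probes:
        idx = bat_rng.choice(p, size=n_batch_probes, replace=False)
        offsets = bat_rng.normal(
            0.0, cfg.batch_effect_sd, size=(cfg.n_batches, n_batch_probes)
        )
        batch_code = cov["batch"].str.removeprefix("batch").astype(int) - 1
        M[:, idx] += offsets[batch_code.to_numpy()]

    # -- implanted carrier effect ----------------------------------------
    pid_to_col = {pid: i for i, pid in enumerate(probe_ids)}
    affected = {pid: float(d) for pid, d in cfg.affected_probes}
    carrier_rows = np.flatnonzero(true_label == CARRIER)
    for pid, delta in affected.items():
        M[carrier_rows, pid_to_col[pid]] += delta

    M += rngs["noise"].normal(0.0, sd, size=(n, p))

    # -- missingness ------------------------------------------------------
    miss_rng = rngs["missing"]
    if cfg.missing_rate > 0:
        mask = miss_rng.random((n, p)) < cfg.missing_rate
        M[mask] = np.nan
    for s in failing:
        k = int(np.ceil(cfg.failing_missing_fraction * p))
        cols = miss_rng.choice(p, size=k, replace=False)
        M[s, cols] = np.nan

    m_values = pd.DataFrame(M, index=sample_ids, columns=probe_ids)
    ds = MethylationDataset(
        m_values=m_values,
        covariates=cov,
        carrier=pd.Series(observed, index=sample_ids),
        metadata={
            "generator": "repeatmeth.simulate",
            "cohort": cohort,
            "seed": cfg.seed,
            "sex_codes": {"0": "male", "1": "female"},
        },
    )
    truth = GroundTruth(
        carrier=pd.Series(true_label, index=sample_ids),
        affected=affected,
        is_null=pd.Series(
            [pid not in affected for pid in probe_ids], index=probe_ids
        ),
    )
    return ds, ann, truth


def generate_cohort(
    cfg: SimulationConfig,
) -> tuple[MethylationDataset, pd.DataFrame, GroundTruth]:
    """Generate the labelled discovery cohort.

    Returns the dataset (carrier labels observed except for any
    ``n_unlabelled`` samples), the probe annotation covering locus and
    background probes, and the ground truth. Bit-identical for identical
    configs.
    """
    return _synthesise(cfg, cfg.n_carriers, cohort="discovery", sample_prefix="S")


def generate_independent_cohort(
    cfg: SimulationConfig, n_hidden_carriers: int
) -> tuple[MethylationDataset, GroundTruth]:
    """Generate a validation cohort whose carrier status is hidden.

    The dataset's carrier field is ``unknown`` for every sample; the true
    labels (``n_hidden_carriers`` carriers) live only in the returned
    :class:`GroundTruth`. The probe universe matches the training manifest.
    """
    if n_hidden_carriers > cfg.n_samples:
        raise ValueError("n_hidden_carriers cannot exceed n_samples")
    ds, _, truth = _synthesise(
        cfg, n_hidden_carriers, cohort="validation", sample_prefix="V"
    )
    ds.carrier = pd.Series(UNKNOWN, index=ds.m_values.index)
    return ds, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Persist ground truth as TSV (samples block, then affected probes)."""
    with open(path, "w") as fh:
        fh.write("#samples\nsample_id\tcarrier\n")
        for sid, lab in truth.carrier.items():
            fh.write(f"{sid}\t{lab}\n")
        fh.write("#affected_probes\nprobe_id\tdelta_m\n")
        for pid, d in truth.affected.items():
            fh.write(f"{pid}\t{d}\n")
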