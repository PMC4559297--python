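"""Synthetic expression benchmarks with known modulator ground truth.

The generator emulates the situation the ranking method is built for: a
transcription factor whose ``d`` target genes are co-regulated only in the
subset of expression profiles where an *effective* modulator (a kinase
activating the TF) is expressed.

Each dataset consists of ``n_geps`` profiles over a gene universe made of
known TF targets plus candidate modulators (some effective, some decoys,
optionally some "hidden" unknown targets):

- In the co-regulated profile subset, target (and hidden-target) genes are
  drawn from a zero-mean multivariate Gaussian whose off-diagonal covariance
  entries are ``rho * sigma_ij^2`` with ``rho = 0.6`` and ``sigma_ij^2``
  uniform on (0, 0.5); in the remaining profiles the covariance is diagonal.
- Effective modulators are Normal(1, 0.1) in the co-regulated subset and
  Normal(0, 0.1) in the independent subset (second parameter read as a
  variance by default), so their expression level separates the two subsets.
- Decoy modulators are i.i.d. zero-mean Gaussians with per-gene variance
  uniform on (0, 0.5) in every profile.

Presets reproduce the standard benchmark configurations: ``d1`` (60 genes,
50 candidates, 20 effective, 10 hidden targets), ``d2`` (760 genes, 750
candidates, 50 effective) and four "noisy-bin" variants of ``d2`` where the
co-regulated subset covers 30/40/60/70 of the 100 profiles instead of half.

The module also provides the sampling routines used to study estimator
convergence (multivariate Gaussians and Beta-marginal Gaussian-copula
samples, each returned together with the closed-form true multi-information).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats

from .rmi import gaussian_copula_rmi

__all__ = [
    "SyntheticDatasetSpec",
    "GroundTruth",
    "generate_dataset",
    "preset_spec",
    "PRESETS",
    "generate_gaussian_convergence_sample",
    "generate_beta_copula_sample",
]

_EIG_FLOOR = 1e-3


@dataclass
class SyntheticDatasetSpec:
    """Parameters of one synthetic benchmark dataset."""

    n_geps: int = 100
    n_dependent_geps: int = 50
    n_targets: int = 10
    n_hidden_targets: int = 10
    n_potential_modulators: int = 50
    n_effective_modulators: int = 20
    rho: float = 0.6
    sigma2_low: float = 0.0
    sigma2_high: float = 0.5
    modulator_on_mean: float = 1.0
    modulator_off_mean: float = 0.0
    modulator_spread: float = 0.1
    # the modulator distribution is printed as N(1, 0.1); by default the
    # second parameter is read as a variance (sd ~= 0.316), flip to read sd
    spread_is_sd: bool = False
    seed: int = 0

    def validate(self) -> "SyntheticDatasetSpec":
        if not 0 <= self.n_dependent_geps <= self.n_geps:
            raise ValueError("n_dependent_geps must lie in [0, n_geps]")
        if self.n_targets < 2:
            raise ValueError("need at least 2 target genes")
        n_decoys = (
            self.n_potential_modulators
            - self.n_effective_modulators
            - self.n_hidden_targets
        )
        if min(self.n_hidden_targets, self.n_effective_modulators, n_decoys) < 0:
            raise ValueError(
                "modulator counts inconsistent: effective + hidden targets "
                "must not exceed n_potential_modulators"
            )
        if not 0 <= self.sigma2_low < self.sigma2_high:
            raise ValueError("variance range must satisfy 0 <= low < high")
        return self

    @property
    def n_genes(self) -> int:
        return self.n_targets + self.n_potential_modulators

    @property
    def n_decoy_modulators(self) -> int:
        return (
            self.n_potential_modulators
            - self.n_effective_modulators
            - self.n_hidden_targets
        )


@dataclass
class GroundTruth:
    """Role labels for every gene in a synthetic dataset."""

    target_ids: list[str]
    hidden_target_ids: list[str]
    effective_modulator_ids: list[str]
    decoy_modulator_ids: list[str]
    coregulated_sample_ids: list[str] = field(default_factory=list)

    @property
    def modulator_ids(self) -> list[str]:
        """All candidate modulators, in gene order (hidden targets included)."""
        return (
            self.effective_modulator_ids
            + self.hidden_target_ids
            + self.decoy_modulator_ids
        )

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [(g, "target") for g in self.target_ids]
            + [(g, "effective_modulator") for g in self.effective_modulator_ids]
            + [(g, "hidden_target") for g in self.hidden_target_ids]
            + [(g, "decoy_modulator") for g in self.decoy_modulator_ids]
        )
        return pd.DataFrame(rows, columns=["gene_id", "role"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GroundTruth":
        by_role = {
            role: frame.loc[frame["role"] == role, "gene_id"].tolist()
            for role in frame["role"].unique()
        }
        return cls(
            target_ids=by_role.get("target", []),
            hidden_target_ids=by_role.get("hidden_target", []),
            effective_modulator_ids=by_role.get("effective_modulator", []),
            decoy_modulator_ids=by_role.get("decoy_modulator", []),
        )


def _nearest_pd(sigma: np.ndarray, floor: float = _EIG_FLOOR) -> np.ndarray:
    """Clip eigenvalues at a small positive floor so sampling is possible.

    The literal recipe (off-diagonal entries ``rho * sigma_ij^2`` with the
    ``sigma_ij^2`` drawn independently) does not guarantee positive
    definiteness; clipping preserves the intended dependence strength.
    """
    w, v = np.linalg.eigh(sigma)
    if w.min() >= floor:
        return sigma
    w = np.clip(w, floor, None)
    return (v * w) @ v.T


def _coregulated_covariance(dc: int, spec: SyntheticDatasetSpec, rng: np.random.Generator) -> np.ndarray:
    s2 = rng.uniform(spec.sigma2_low, spec.sigma2_high, size=(dc, dc))
    s2 = np.triu(s2, 1) + np.triu(s2, 1).T  # symmetric sigma_ij^2
    sigma = spec.rho * s2
    np.fill_diagonal(sigma, rng.uniform(spec.sigma2_low, spec.sigma2_high, size=dc))
    return _nearest_pd(sigma)


def generate_dataset(spec: SyntheticDatasetSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one benchmark dataset.

    Returns the expression matrix (genes x samples, gene ids in the index,
    sample ids in the columns) and the ground-truth role labels.  Profiles
    from the co-regulated and independent subsets are interleaved by a seeded
    random permutation of the columns, so only the modulator expression
    level — not the sample order — can separate them.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_co = spec.n_dependent_geps
    n_ind = spec.n_geps - n_co
    sd_mod = spec.modulator_spread if spec.spread_is_sd else float(np.sqrt(spec.modulator_spread))

    target_ids = [f"TARGET_{i+1:03d}" for i in range(spec.n_targets)]
    hidden_ids = [f"MOD_HID_{i+1:03d}" for i in range(spec.n_hidden_targets)]
    eff_ids = [f"MOD_EFF_{i+1:03d}" for i in range(spec.n_effective_modulators)]
    decoy_ids = [f"MOD_DEC_{i+1:03d}" for i in range(spec.n_decoy_modulators)]

    # targets + hidden targets: jointly Gaussian, co-regulated only in the
    # dependent subset
    dc = spec.n_targets + spec.n_hidden_targets
    sigma_co = _coregulated_covariance(dc, spec, rng)
    co_block = rng.multivariate_normal(np.zeros(dc), sigma_co, size=n_co).T
    ind_var = rng.uniform(spec.sigma2_low, spec.sigma2_high, size=dc)
    ind_block = rng.normal(size=(dc, n_ind)) * np.sqrt(ind_var)[:, None]

    # effective modulators: "on" (mean 1) in the co-regulated subset,
    # "off" (mean 0) elsewhere
    ne = spec.n_effective_modulators
    eff_co = rng.normal(spec.modulator_on_mean, sd_mod, size=(ne, n_co))
    eff_ind = rng.normal(spec.modulator_off_mean, sd_mod, size=(ne, n_ind))

    nd = spec.n_decoy_modulators
    decoy_var = rng.uniform(spec.sigma2_low, spec.sigma2_high, size=nd)
    decoys = rng.normal(size=(nd, spec.n_geps)) * np.sqrt(decoy_var)[:, None]

    values = np.zeros((spec.n_genes, spec.n_geps))
    gene_ids = target_ids + hidden_ids + eff_ids + decoy_ids
    values[:dc, :n_co] = co_block
    values[:dc, n_co:] = ind_block
    values[dc : dc + ne, :n_co] = eff_co
    values[dc : dc + ne, n_co:] = eff_ind
    values[dc + ne :, :] = decoys

    order = rng.permutation(spec.n_geps)
    values = values[:, order]
    co_flags = np.zeros(spec.n_geps, dtype=bool)
    co_flags[:n_co] = True
    co_flags = co_flags[order]
    sample_ids = [f"GEP_{i+1:03d}" for i in range(spec.n_geps)]

    expr = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    truth = GroundTruth(
        target_ids=target_ids,
        hidden_target_ids=hidden_ids,
        effective_modulator_ids=eff_ids,
        decoy_modulator_ids=decoy_ids,
        coregulated_sample_ids=[s for s, f in zip(sample_ids, co_flags) if f],
    )
    return expr, truth


def _d1_spec(seed: int) -> SyntheticDatasetSpec:
    return SyntheticDatasetSpec(seed=seed)


def _d2_spec(seed: int) -> SyntheticDatasetSpec:
    return SyntheticDatasetSpec(
        n_hidden_targets=0,
        n_potential_modulators=750,
        n_effective_modulators=50,
        seed=seed,
    )


def _noisy_spec(n_dependent: int, seed: int) -> SyntheticDatasetSpec:
    spec = _d2_spec(seed)
    spec.n_dependent_geps = n_dependent
    return spec


PRESETS = {
    "d1": _d1_spec,
    "d2": _d2_spec,
    "noisy30": lambda seed: _noisy_spec(30, seed),
    "noisy40": lambda seed: _noisy_spec(40, seed),
    "noisy60": lambda seed: _noisy_spec(60, seed),
    "noisy70": lambda seed: _noisy_spec(70, seed),
}


def preset_spec(name: str, seed: int = 0) -> SyntheticDatasetSpec:
    """Benchmark preset by name: ``d1``, ``d2``, ``noisy30/40/60/70``."""
    try:
        return PRESETS[name](seed)
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None


def _random_covariance(d: int, rng: np.random.Generator) -> np.ndarray:
    """Well-conditioned random symmetric positive-definite covariance."""
    A = rng.normal(size=(d, 2 * d))
    return (A @ A.T) / (2 * d)


def generate_gaussian_convergence_sample(
    d: int, n: int, dependent: bool, seed: int = 0, alpha: float = 0.99
):
    """Multivariate Gaussian sample plus the exact multi-information.

    Independent case: identity covariance, true value 0.  Dependent case: a
    randomly drawn (seeded, recorded) symmetric positive-definite covariance;
    the true order-``alpha`` multi-information follows in closed form from
    its correlation matrix.

    Returns ``(sample, true_rmi, covariance)`` with ``sample`` of shape
    ``(n, d)``.
    """
    rng = np.random.default_rng(seed)
    if dependent:
        cov = _random_covariance(d, rng)
        true_rmi = gaussian_copula_rmi(cov, alpha)
    else:
        cov = np.eye(d)
        true_rmi = 0.0
    X = rng.multivariate_normal(np.zeros(d), cov, size=n)
    return X, true_rmi, cov


def generate_beta_copula_sample(
    d: int, n: int, dependent: bool, seed: int = 0, alpha: float = 0.99
):
    """Beta-marginal sample built on a Gaussian copula, plus the exact RMI.

    Each coordinate has Beta(a_j, b_j) marginals with ``a_j, b_j`` drawn from
    the standard uniform distribution; dependence is injected through a
    Gaussian copula with a recorded random correlation matrix.  Because
    multi-information is invariant under monotone marginal transforms, the
    true value equals that of the underlying Gaussian copula.

    Returns ``(sample, true_rmi, correlation, (a, b))``.
    """
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.0, 1.0, size=d)
    b = rng.uniform(0.0, 1.0, size=d)
    if dependent:
        cov = _random_covariance(d, rng)
        sd = np.sqrt(np.diag(cov))
        corr = cov / np.outer(sd, sd)
        true_rmi = gaussian_copula_rmi(corr, alpha)
    else:
        corr = np.eye(d)
        true_rmi = 0.0
    Z = rng.multivariate_normal(np.zeros(d), corr, size=n)
    U = stats.norm.cdf(Z)
    X = np.column_stack([stats.beta.ppf(U[:, j], a[j], b[j]) for j in range(d)])
    return X, true_rmi, corr, (a, b)
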