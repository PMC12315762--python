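"""Synthetic cohort generator with planted, analytically checkable effects.

The generator emulates the statistical structure the decoding analysis
assumes: per subject and parcel, a linear coupling between a latent
standardized behavioral variable and the parcel's trial-wise activation,
with couplings allowed to take opposite signs in different subjects.

Construction (per subject ``s``, trial ``t``, parcel ``r``)::

    z_rt[t]   ~ N(0, 1)                    latent behavioral state for RT
    z_conf[t] = rho * z_rt + sqrt(1-rho^2) * N(0,1)   (rho = latent_correlation)
    rt[t]     = exp(loc + scale * z_rt[t])            log-normal seconds
    conf[t]   = equal-probability ordinal bin of z_conf, levels 1..K
    beta[t,r] = c_rt[s,r]*z_rt + c_conf[s,r]*z_conf + lam[s,r]*eta[t,r]

where ``eta`` is unit-variance nuisance noise (a per-trial factor shared by
all parcels plus idiosyncratic per-cell noise, mixed according to
``shared_noise_sd``/``idiosyncratic_noise_sd``) and ``lam`` is chosen so
that beta has unit variance.  Consequently, with independent latents, the
population correlation between a parcel and its latent equals the planted
coupling *exactly*, and the correlation with the observable behavior has
the closed form::

    corr(beta, rt)   = c_rt   * scale / sqrt(exp(scale^2) - 1)
    corr(beta, conf) = c_conf * sum_k phi(Phi^-1(k/K)) / sqrt((K^2-1)/12)

exposed via :func:`expected_attenuation` / :func:`expected_correlation` so
tests can assert recovery against an analytic value.

``mean_fd`` is drawn independently of every coupling, so the motion QC
regression is null by construction.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import TARGETS, ValidationError, derive_seed
from .io import NETWORKS, Atlas, SubjectData


@dataclasses.dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the regime the pipeline is designed for: a cohort of
    50 subjects, 700 trials each, 200 parcels, sparse moderate couplings
    with an even mixture of signs across subjects.
    """

    n_subjects: int = 50
    n_trials: int = 700
    n_rois: int = 200
    #: probability that a subject × ROI cell (within an eligible ROI) is coupled
    coupling_sparsity: float = 0.3
    #: standardized coupling magnitude (= population corr with the latent)
    coupling_magnitude: float = 0.3
    #: probability a coupled cell's slope is positive
    sign_mixture: float = 0.5
    #: probability an ROI is eligible for coupling at all (ROI-level sparsity;
    #: 1.0 means every ROI may couple, 0.5 leaves ~half the parcels inert)
    coupled_roi_fraction: float = 1.0
    shared_noise_sd: float = 0.2
    idiosyncratic_noise_sd: float = 1.0
    #: log-normal RT: median exp(rt_log_loc) seconds, shape rt_log_scale
    rt_log_loc: float = math.log(0.8)
    rt_log_scale: float = 0.35
    confidence_levels: int = 4
    #: fraction of initial trials lacking confidence (whole-run blocks)
    confidence_missing_fraction: float = 0.0
    #: correlation between the RT and confidence latents
    latent_correlation: float = 0.0
    #: per-target overrides; None -> use the shared coupling fields
    confidence_sparsity: float | None = None
    confidence_magnitude: float | None = None
    confidence_sign_mixture: float | None = None
    #: optional per-subject trial counts (len n_subjects) for unequal cohorts
    n_trials_per_subject: list | None = None
    n_runs: int = 6
    mean_fd_log_loc: float = math.log(0.15)
    mean_fd_log_scale: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "coupling_sparsity": self.coupling_sparsity,
            "sign_mixture": self.sign_mixture,
            "coupled_roi_fraction": self.coupled_roi_fraction,
            "confidence_missing_fraction": self.confidence_missing_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}={p} outside [0, 1]")
        if not 0.0 <= self.coupling_magnitude < 1.0:
            raise ValidationError("coupling_magnitude must be in [0, 1)")
        m_conf = self._conf("magnitude")
        if self.coupling_magnitude**2 + m_conf**2 > 1.0:
            raise ValidationError(
                "coupling magnitudes too large: squared RT and confidence "
                "magnitudes must sum to at most 1 (unit-variance betas)")
        if self.shared_noise_sd < 0 or self.idiosyncratic_noise_sd < 0:
            raise ValidationError("noise sds must be >= 0")
        if self.n_trials < 4:
            raise ValidationError("n_trials must be >= 4")
        if self.confidence_levels < 2:
            raise ValidationError("confidence_levels must be >= 2")
        if not -1.0 < self.latent_correlation < 1.0:
            raise ValidationError("latent_correlation must be in (-1, 1)")
        if self.rt_log_scale <= 0:
            raise ValidationError("rt_log_scale must be > 0")
        if self.n_trials_per_subject is not None:
            if len(self.n_trials_per_subject) != self.n_subjects:
                raise ValidationError("n_trials_per_subject length mismatch")
            if min(self.n_trials_per_subject) < 4:
                raise ValidationError("per-subject n_trials must be >= 4")

    def _conf(self, field: str) -> float:
        override = getattr(self, f"confidence_{field}")
        if override is not None:
            return override
        return getattr(self, f"coupling_{field}"
                       if field != "sign_mixture" else "sign_mixture")

    def trials_for(self, subject_index: int) -> int:
        if self.n_trials_per_subject is not None:
            return int(self.n_trials_per_subject[subject_index])
        return self.n_trials


@dataclasses.dataclass
class SyntheticTruth:
    """Planted standardized couplings, zero exactly where uncoupled."""

    subject_ids: list
    #: mapping target -> (n_subjects, n_rois) array of signed couplings
    coupling: dict

    def sign(self, target: str) -> np.ndarray:
        return np.sign(self.coupling[target]).astype(int)


# ---------------------------------------------------------------------------
# closed-form expected correlations
# ---------------------------------------------------------------------------

def expected_attenuation(config: SyntheticConfig, target: str) -> float:
    """Analytic factor mapping latent-scale coupling to behavior-scale r.

    For the log-normal RT, ``corr(z, exp(scale*z)) = scale/sqrt(e^scale^2-1)``;
    for K equal-probability ordinal confidence bins, Stein's identity gives
    ``corr(z, bin(z)) = sum_{k<K} phi(Phi^-1(k/K)) / sqrt((K^2-1)/12)``.
    """
    if target == "rt":
        s = config.rt_log_scale
        return s / math.sqrt(math.expm1(s * s))
    if target == "confidence":
        K = config.confidence_levels
        cuts = stats.norm.ppf(np.arange(1, K) / K)
        return float(stats.norm.pdf(cuts).sum() / math.sqrt((K * K - 1) / 12.0))
    raise ValidationError(f"unknown target {target!r}")


def expected_correlation(config: SyntheticConfig, target: str,
                         coupling: float | None = None) -> float:
    """Expected Pearson r between a coupled parcel and the observed behavior."""
    if config.latent_correlation != 0.0:
        raise ValidationError(
            "closed form requires independent latents (latent_correlation=0)")
    c = config.coupling_magnitude if coupling is None else coupling
    return c * expected_attenuation(config, target)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _sample_coupling(rng, n_subjects, n_rois, sparsity, magnitude,
                     sign_mixture, roi_eligible) -> np.ndarray:
    coupled = rng.random((n_subjects, n_rois)) < sparsity
    coupled &= roi_eligible[None, :]
    signs = np.where(rng.random((n_subjects, n_rois)) < sign_mixture, 1.0, -1.0)
    return np.where(coupled, signs * magnitude, 0.0)


def simulate_cohort(config: SyntheticConfig,
                    seed: int | None = None) -> tuple[list, SyntheticTruth]:
    """Generate a full cohort with planted ground truth.

    Returns ``(cohort, truth)`` where *cohort* is a list of
    :class:`~roidecode.io.SubjectData` and *truth* records the signed
    standardized couplings per target.  Bitwise reproducible from
    ``(config, seed)``; *seed* defaults to ``config.seed``.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    S, R = config.n_subjects, config.n_rois

    rng_truth = np.random.default_rng(derive_seed(seed, "truth"))
    eligible = {t: rng_truth.random(R) < config.coupled_roi_fraction
                for t in TARGETS}
    c_rt = _sample_coupling(rng_truth, S, R, config.coupling_sparsity,
                            config.coupling_magnitude, config.sign_mixture,
                            eligible["rt"])
    c_conf = _sample_coupling(rng_truth, S, R, config._conf("sparsity"),
                              config._conf("magnitude"),
                              config._conf("sign_mixture"),
                              eligible["confidence"])

    sd_noise = math.hypot(config.shared_noise_sd, config.idiosyncratic_noise_sd)
    rho = config.latent_correlation
    K = config.confidence_levels
    cuts = stats.norm.ppf(np.arange(1, K) / K)

    subject_ids = [f"sub-{i + 1:03d}" for i in range(S)]
    cohort = []
    for s in range(S):
        n = config.trials_for(s)
        rng = np.random.default_rng(derive_seed(seed, "subject", subject_ids[s]))
        z_rt = rng.standard_normal(n)
        z_conf = rho * z_rt + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
        rt = np.exp(config.rt_log_loc + config.rt_log_scale * z_rt)
        conf = (np.digitize(z_conf, cuts) + 1).astype(float)
        n_missing = int(round(config.confidence_missing_fraction * n))
        conf[:n_missing] = np.nan

        shared = rng.standard_normal(n)
        eps = rng.standard_normal((n, R))
        if sd_noise > 0:
            eta = (config.shared_noise_sd * shared[:, None]
                   + config.idiosyncratic_noise_sd * eps) / sd_noise
        else:
            eta = np.zeros((n, R))
        lam = np.sqrt(np.clip(1.0 - c_rt[s] ** 2 - c_conf[s] ** 2, 0.0, None))
        betas = (z_rt[:, None] * c_rt[s] + z_conf[:, None] * c_conf[s]
                 + lam[None, :] * eta)

        run_id = 1 + (np.arange(n) * config.n_runs) // n
        mean_fd = float(np.exp(config.mean_fd_log_loc
                               + config.mean_fd_log_scale * rng.standard_normal()))
        cohort.append(SubjectData(subject_id=subject_ids[s], betas=betas,
                                  rt=rt, confidence=conf, run_id=run_id,
                                  mean_fd=mean_fd))
    truth = SyntheticTruth(subject_ids=subject_ids,
                           coupling={"rt": c_rt, "confidence": c_conf})
    return cohort, truth


def truth_sign_table(truth: SyntheticTruth, target: str = "rt") -> pd.DataFrame:
    """Per-ROI counts of subjects with positive / negative / zero coupling."""
    c = truth.coupling[target]
    return pd.DataFrame({
        "roi_id": np.arange(1, c.shape[1] + 1),
        "n_pos": (c > 0).sum(axis=0),
        "n_neg": (c < 0).sum(axis=0),
        "n_zero": (c == 0).sum(axis=0),
    })


def synthetic_atlas(n_rois: int) -> Atlas:
    """Round-robin assignment of the seven networks to n_rois parcels."""
    networks = [NETWORKS[i % len(NETWORKS)] for i in range(n_rois)]
    names = [f"{net}_parcel_{i + 1}" for i, net in enumerate(networks)]
    return Atlas(np.arange(1, n_rois + 1), names, networks)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def dataset1_preset(**overrides) -> SyntheticConfig:
    """Cohort shaped like the primary study: 50 subjects × 700 trials × 200
    parcels, six subjects with fewer trials (incomplete sessions)."""
    per_subject = [700] * 50
    per_subject[:6] = [672, 672, 672, 608, 608, 608]
    cfg = SyntheticConfig(n_subjects=50, n_trials=700, n_rois=200,
                          n_trials_per_subject=per_subject)
    return dataclasses.replace(cfg, **overrides)


def dataset2_preset(**overrides) -> SyntheticConfig:
    """Replication-style cohort: 36 subjects × 804 trials, confidence rated
    on only the second half of trials."""
    cfg = SyntheticConfig(n_subjects=36, n_trials=804, n_rois=200,
                          confidence_missing_fraction=0.5)
    return dataclasses.replace(cfg, **overrides)


def tiny_preset(**overrides) -> SyntheticConfig:
    """Smoke-test cohort: 4 subjects × 60 trials × 10 parcels."""
    cfg = SyntheticConfig(n_subjects=4, n_trials=60, n_rois=10,
                          coupling_sparsity=0.5, coupling_magnitude=0.5)
    return dataclasses.replace(cfg, **overrides)
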