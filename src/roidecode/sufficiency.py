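"""Trial-number sufficiency test.

How many trials does a subject-level decoder need?  A whole-brain
multilinear model (all parcels jointly → behavior) is trained on a sweep of
training fractions from 5% to 95% of trials and tested on the held-out
trials, 25 random re-splits per fraction.  Per subject the mean and the
across-repeat standard deviation of the test-bin Pearson r are computed,
then averaged across subjects.  Two optimality criteria are reported: the
fraction minimizing the across-repeat SD, and the fraction maximizing
(mean performance − SD).

Rank-deficient fits (training count below the number of parcels, e.g. 35
trials on 200 predictors) use the minimum-norm least-squares solution.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import linalg

from ._utils import ValidationError, derive_seed, pearson


@dataclasses.dataclass
class SufficiencySpec:
    """Sweep configuration.

    test_policy "complement" scores all held-out trials; "fixed" scores a
    fixed random subset of ``fixed_test_count`` held-out trials (default 5%
    of trials) so performance is compared on equal test sizes.
    """

    grid_step: float = 0.05
    fractions: tuple | None = None
    n_repeats: int = 25
    test_policy: str = "complement"
    fixed_test_count: int | None = None
    standardize: bool = False
    rng_seed: int = 0

    def grid(self) -> np.ndarray:
        if self.fractions is not None:
            f = np.asarray(self.fractions, dtype=float)
        else:
            n = int(round((0.95 - 0.05) / self.grid_step)) + 1
            f = np.round(0.05 + self.grid_step * np.arange(n), 10)
        if not (np.all(np.diff(f) > 0) and f[0] >= 0.05 - 1e-9
                and f[-1] <= 0.95 + 1e-9):
            raise ValidationError("fractions must increase within [0.05, 0.95]")
        return f

    def validate(self, n_trials: int) -> None:
        f = self.grid()
        if int(round(f[0] * n_trials)) < 3:
            raise ValidationError(
                f"fraction {f[0]} yields < 3 training trials of {n_trials}")
        if self.test_policy not in ("complement", "fixed"):
            raise ValidationError(f"unknown test policy {self.test_policy!r}")
        if self.test_policy == "fixed":
            k = self.fixed_test_count or int(round(0.05 * n_trials))
            if int(round(f[-1] * n_trials)) + k > n_trials:
                raise ValidationError("fixed test count does not fit at the "
                                      "largest training fraction")


@dataclasses.dataclass
class SufficiencyCurve:
    fractions: np.ndarray
    #: across-subject mean of the per-subject repeat-mean performance
    mean_perf: np.ndarray
    #: across-subject mean of the per-subject across-repeat SD
    sd_perf: np.ndarray
    n_repeats: int
    #: (n_subjects, n_fractions) per-subject repeat means / SDs
    per_subject_mean: np.ndarray
    per_subject_sd: np.ndarray
    argmin_variance_fraction: float = float("nan")
    argmax_gap_fraction: float = float("nan")


def _fit_predict(X_train, y_train, X_test, standardize: bool) -> np.ndarray:
    """Minimum-norm multilinear fit with intercept; predictions on X_test."""
    if standardize:
        mu = X_train.mean(axis=0)
        sd = X_train.std(axis=0)
        sd[sd == 0] = 1.0
        X_train = (X_train - mu) / sd
        X_test = (X_test - mu) / sd
    A = np.column_stack([np.ones(X_train.shape[0]), X_train])
    # gelsy = complete orthogonal factorization -> minimum-norm solution,
    # well defined for rank-deficient designs (n_train < n_rois)
    coef = linalg.lstsq(A, y_train, lapack_driver="gelsy")[0]
    return np.column_stack([np.ones(X_test.shape[0]), X_test]) @ coef


def sufficiency_curve(cohort, target: str,
                      spec: SufficiencySpec | None = None,
                      seed: int = 0) -> SufficiencyCurve:
    """Compute the sufficiency curve for a cohort and target."""
    if spec is None:
        spec = SufficiencySpec()
    fractions = spec.grid()
    S = len(cohort)
    means = np.full((S, fractions.size), np.nan)
    sds = np.full((S, fractions.size), np.nan)
    for si, subject in enumerate(cohort):
        y_all = subject.target_vector(target)
        mask = np.isfinite(y_all)
        X = subject.betas[mask]
        y = y_all[mask]
        n = y.size
        spec.validate(n)
        rng = np.random.default_rng(
            derive_seed(seed, subject.subject_id, target, "sufficiency",
                        spec.rng_seed))
        for fi, f in enumerate(fractions):
            n_train = int(round(f * n))
            if spec.test_policy == "fixed":
                n_test = spec.fixed_test_count or int(round(0.05 * n))
            else:
                n_test = n - n_train
            r = np.full(spec.n_repeats, np.nan)
            for rep in range(spec.n_repeats):
                order = rng.permutation(n)
                tr = order[:n_train]
                te = order[n_train:n_train + n_test]
                pred = _fit_predict(X[tr], y[tr], X[te], spec.standardize)
                r[rep] = pearson(y[te], pred)
            ok = np.isfinite(r)
            if ok.sum() >= 2:
                means[si, fi] = r[ok].mean()
                sds[si, fi] = r[ok].std(ddof=1)
    curve = SufficiencyCurve(
        fractions=fractions,
        mean_perf=np.nanmean(means, axis=0),
        sd_perf=np.nanmean(sds, axis=0),
        n_repeats=spec.n_repeats,
        per_subject_mean=means,
        per_subject_sd=sds,
    )
    fmin, fgap = optimal_fractions(curve)
    curve.argmin_variance_fraction = fmin
    curve.argmax_gap_fraction = fgap
    return curve


def optimal_fractions(curve: SufficiencyCurve) -> tuple[float, float]:
    """The two optimality criteria; ties break toward the smaller fraction.

    Returns (fraction minimizing across-repeat SD, fraction maximizing
    mean performance minus SD).  np.argmin/argmax return the first hit on
    ties, which with an increasing grid is the smaller fraction.
    """
    sd = curve.sd_perf
    gap = curve.mean_perf - sd
    if not (np.isfinite(sd).any() and np.isfinite(gap).any()):
        raise ValidationError("sufficiency curve has no finite entries")
    fmin = float(curve.fractions[np.nanargmin(sd)])
    fgap = float(curve.fractions[np.nanargmax(gap)])
    return fmin, fgap
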