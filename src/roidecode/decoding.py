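"""Per-ROI repeated random-split decoding with a permutation null.

For one subject, one parcel and one behavioral target, trials are split at
random into disjoint training and testing bins (default 25 repeats).  A
regressor (ordinary least squares by default) is fit on the training bin
and its predictions on the testing bin are scored by the Pearson
correlation between empirical and predicted behavior.  The 25 correlations
are aggregated on the Fisher z scale and converted back to r.  Subject-level
significance comes from a permutation null: the target vector is globally
shuffled, the repeated-split analysis is re-run (with a reduced number of
splits by default, see :func:`permutation_null`), and the observed
aggregated r is ranked one-tailed against the null aggregates.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
from scipy import stats

from ._utils import (RoidecodeError, TARGETS, ValidationError, derive_seed,
                     pearson, pearson_rows)
from .io import SubjectData

#: |r| is clipped here before atanh so noiseless r = ±1 stays finite.
FISHER_CLIP = 1.0 - 1e-12


@dataclasses.dataclass
class SplitSpec:
    """Train/test sizing for the repeated random splits.

    ``n_train + n_test`` may be smaller than the number of usable trials;
    leftover trials are simply unused in that repeat (e.g. 301/101 splits of
    402 rated trials).
    """

    n_train: int
    n_test: int
    n_repeats: int = 25
    rng_seed: int = 0

    def validate(self, n_trials: int) -> None:
        if self.n_train < 3:
            raise ValidationError("n_train must be >= 3")
        if self.n_test < 2:
            raise ValidationError("n_test must be >= 2")
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")
        if self.n_train + self.n_test > n_trials:
            raise ValidationError(
                f"split {self.n_train}+{self.n_test} exceeds {n_trials} trials")


@dataclasses.dataclass
class RepeatSet:
    """Per-repeat decoding outcomes for one (subject, ROI, target) cell."""

    r_per_repeat: np.ndarray
    slope_per_repeat: np.ndarray
    r_aggregated: float
    z_aggregated: float

    @property
    def mean_slope(self) -> float:
        ok = np.isfinite(self.slope_per_repeat)
        if not ok.any():
            return float("nan")
        return float(self.slope_per_repeat[ok].mean())


@dataclasses.dataclass
class CellResult:
    subject_id: str
    roi_id: int
    target: str
    repeat_set: RepeatSet | None
    p_perm: float = float("nan")
    n_perm_used: int = 0
    missing: bool = False
    reason: str = ""

    @property
    def r_aggregated(self) -> float:
        if self.repeat_set is None:
            return float("nan")
        return self.repeat_set.r_aggregated

    @property
    def z_aggregated(self) -> float:
        if self.repeat_set is None:
            return float("nan")
        return self.repeat_set.z_aggregated

    @property
    def mean_slope(self) -> float:
        if self.repeat_set is None:
            return float("nan")
        return self.repeat_set.mean_slope

    @property
    def direction(self) -> int:
        """Sign of the mean fitted slope across repeats (0 if exactly zero
        or undefined); the per-cell brain–behavior direction."""
        m = self.mean_slope
        if not np.isfinite(m):
            return 0
        return int(np.sign(m))


class DecodingResult:
    """Collection of :class:`CellResult` over subjects × ROIs × targets."""

    def __init__(self, cells: Iterable[CellResult], spec_by_target: dict,
                 subject_ids: list, roi_ids: np.ndarray):
        self.cells = list(cells)
        self.spec_by_target = dict(spec_by_target)
        self.subject_ids = list(subject_ids)
        self.roi_ids = np.asarray(roi_ids, dtype=int)
        self._index = {}
        for c in self.cells:
            key = (c.subject_id, c.roi_id, c.target)
            if key in self._index:
                raise ValidationError(f"duplicate cell {key}")
            self._index[key] = c

    def __len__(self):
        return len(self.cells)

    def cell(self, subject_id, roi_id, target) -> CellResult:
        return self._index[(subject_id, roi_id, target)]

    @property
    def targets(self):
        return sorted({c.target for c in self.cells},
                      key=lambda t: TARGETS.index(t))

    def _matrix(self, target, getter) -> np.ndarray:
        out = np.full((len(self.subject_ids), self.roi_ids.size), np.nan)
        for i, sid in enumerate(self.subject_ids):
            for j, rid in enumerate(self.roi_ids):
                c = self._index.get((sid, int(rid), target))
                if c is not None and not c.missing:
                    out[i, j] = getter(c)
        return out

    def performance_matrix(self, target) -> np.ndarray:
        return self._matrix(target, lambda c: c.r_aggregated)

    def z_matrix(self, target) -> np.ndarray:
        return self._matrix(target, lambda c: c.z_aggregated)

    def p_matrix(self, target) -> np.ndarray:
        return self._matrix(target, lambda c: c.p_perm)

    def direction_matrix(self, target) -> np.ndarray:
        return self._matrix(target, lambda c: float(c.direction))


# ---------------------------------------------------------------------------
# regressors
# ---------------------------------------------------------------------------

class OLSRegressor:
    """Simple least-squares line: slope = cov(x, y) / var(x)."""

    def fit(self, x_train: np.ndarray, y_train: np.ndarray) -> "OLSRegressor":
        self.intercept_, self.slope_ = fit_linear_decoder(x_train, y_train)
        return self

    def predict(self, x_test: np.ndarray) -> np.ndarray:
        return self.intercept_ + self.slope_ * np.asarray(x_test, dtype=float)


class SVRRegressor:
    """Epsilon-insensitive support-vector regressor (linear kernel).

    Defaults: C=1.0, epsilon=0.1, x standardized with training-fold
    statistics.  Deterministic for a fixed configuration.
    """

    def __init__(self, C: float = 1.0, epsilon: float = 0.1):
        self.C = C
        self.epsilon = epsilon

    def fit(self, x_train, y_train):
        from sklearn.svm import SVR

        x = np.asarray(x_train, dtype=float)
        self._mu = x.mean()
        sd = x.std()
        self._sd = sd if sd > 0 else 1.0
        self._svr = SVR(kernel="linear", C=self.C, epsilon=self.epsilon)
        self._svr.fit(((x - self._mu) / self._sd)[:, None],
                      np.asarray(y_train, dtype=float))
        self.slope_ = float(self._svr.coef_[0, 0] / self._sd)
        return self

    def predict(self, x_test):
        x = np.asarray(x_test, dtype=float)
        return self._svr.predict(((x - self._mu) / self._sd)[:, None])


def make_regressor(name: str):
    if name == "ols":
        return OLSRegressor()
    if name == "svr":
        return SVRRegressor()
    raise ValidationError(f"unknown regressor {name!r}")


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def split_trials(n_trials: int, spec: SplitSpec,
                 repeat_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint train/test index sets, deterministic in (seed, repeat)."""
    spec.validate(n_trials)
    rng = np.random.default_rng(
        np.random.SeedSequence((spec.rng_seed, int(repeat_index))))
    order = rng.permutation(n_trials)
    return order[:spec.n_train], order[spec.n_train:spec.n_train + spec.n_test]


def fit_linear_decoder(x_train: np.ndarray,
                       y_train: np.ndarray) -> tuple[float, float]:
    """Closed-form simple regression of y on x: (intercept, slope).

    Zero-variance x is a degenerate fit and raises; callers turn that into
    a missing repeat.
    """
    x = np.asarray(x_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    if x.size < 3:
        raise ValidationError("need >= 3 training trials")
    xc = x - x.mean()
    sxx = xc @ xc
    if sxx <= 0.0:
        raise ValidationError("zero-variance predictor: degenerate fit")
    slope = (xc @ (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    return float(intercept), float(slope)


def fisher_aggregate(r_values) -> tuple[float, float]:
    """Fisher-mean of correlations: z = mean(atanh(clipped r)), r = tanh(z).

    Missing (NaN) entries are ignored; an all-missing input aggregates to
    (nan, nan).
    """
    r = np.asarray(r_values, dtype=float)
    ok = np.isfinite(r)
    if not ok.any():
        return float("nan"), float("nan")
    z = np.arctanh(np.clip(r[ok], -FISHER_CLIP, FISHER_CLIP)).mean()
    return float(np.tanh(z)), float(z)


def parametric_pvalue(r: float, n_test: int) -> float:
    """One-tailed p for r > 0 via the r→t conversion, df = n_test − 2.

    Alternative subject-level criterion to the permutation test; unlike a
    permutation p it is not floored at 1/(n_perm + 1), so it can in
    principle pass arbitrarily strict Bonferroni thresholds.
    """
    if not np.isfinite(r) or n_test < 3:
        return float("nan")
    r = float(np.clip(r, -FISHER_CLIP, FISHER_CLIP))
    t = r * np.sqrt((n_test - 2) / (1.0 - r * r))
    return float(stats.t.sf(t, df=n_test - 2))


# ---------------------------------------------------------------------------
# cell-level decoding
# ---------------------------------------------------------------------------

def _usable(subject: SubjectData, roi_id: int, target: str):
    x = subject.betas[:, roi_id - 1]
    y = subject.target_vector(target)
    mask = np.isfinite(y) & np.isfinite(x)
    return x[mask], y[mask]


def decode_cell(subject: SubjectData, roi_id: int, target: str,
                spec: SplitSpec, regressor=None) -> RepeatSet:
    """Repeated-split decoding of one (subject, ROI, target) cell.

    Trials with a missing target are dropped before splitting.  Repeats with
    a degenerate fit or undefined test correlation are recorded as missing
    and ignored by the Fisher aggregate.
    """
    if regressor is None:
        regressor = OLSRegressor()
    x, y = _usable(subject, roi_id, target)
    spec.validate(x.size)
    r_vals = np.full(spec.n_repeats, np.nan)
    slopes = np.full(spec.n_repeats, np.nan)
    for i in range(spec.n_repeats):
        tr, te = split_trials(x.size, spec, i)
        try:
            model = regressor.fit(x[tr], y[tr])
        except (ValidationError, ValueError):
            continue
        pred = np.asarray(model.predict(x[te]), dtype=float)
        if pred.shape != (te.size,):
            raise RoidecodeError(
                f"regressor contract violation: predict returned shape "
                f"{pred.shape}, expected ({te.size},)")
        slopes[i] = getattr(model, "slope_", np.nan)
        r_vals[i] = pearson(y[te], pred)
    r_agg, z_agg = fisher_aggregate(r_vals)
    return RepeatSet(r_per_repeat=r_vals, slope_per_repeat=slopes,
                     r_aggregated=r_agg, z_aggregated=z_agg)


def _null_aggregates_ols(x: np.ndarray, y: np.ndarray, n_train: int,
                         n_test: int, n_perm: int, null_repeats: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Vectorized null distribution of aggregated r for the OLS decoder.

    Exploits the identity r(y, a + b*x) = sign(b) * r(y, x), exact for any
    affine prediction, so each null repeat needs one train-bin slope sign
    and one test-bin correlation.
    """
    n = x.size
    out = np.empty(n_perm)
    for p in range(n_perm):
        y_p = rng.permutation(y)
        order = np.argsort(rng.random((null_repeats, n)), axis=1)
        tr = order[:, :n_train]
        te = order[:, n_train:n_train + n_test]
        Xtr, Ytr = x[tr], y_p[tr]
        Xtr_c = Xtr - Xtr.mean(axis=1, keepdims=True)
        sxx = np.einsum("ij,ij->i", Xtr_c, Xtr_c)
        sxy = np.einsum("ij,ij->i", Xtr_c, Ytr - Ytr.mean(axis=1, keepdims=True))
        with np.errstate(invalid="ignore", divide="ignore"):
            slope = np.where(sxx > 0.0, sxy / sxx, np.nan)
        r_te = pearson_rows(x[te], y_p[te])
        r_i = r_te * np.sign(slope)
        r_i[slope == 0.0] = np.nan
        ok = np.isfinite(r_i)
        if ok.any():
            z = np.arctanh(np.clip(r_i[ok], -FISHER_CLIP, FISHER_CLIP)).mean()
            out[p] = np.tanh(z)
        else:
            out[p] = np.nan
    return out


def permutation_null(subject: SubjectData, roi_id: int, target: str,
                     spec: SplitSpec, n_perm: int = 1000,
                     null_repeats: int = 5, regressor=None,
                     observed: RepeatSet | None = None,
                     seed: int | None = None) -> tuple[float, int]:
    """One-tailed permutation p-value for positive decoding.

    Each permutation shuffles the target vector once across trials and
    re-runs the repeated-split decoding with ``null_repeats`` fresh splits
    (default 5 rather than the full observed repeat count — a documented
    cost/variance trade-off; set ``null_repeats=spec.n_repeats`` for the
    full policy).  The add-one estimator ``p = (1 + #{null >= obs}) /
    (1 + n_perm)`` guarantees p in (0, 1]; ties count against significance.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if observed is None:
        observed = decode_cell(subject, roi_id, target, spec, regressor)
    obs = observed.r_aggregated
    if not np.isfinite(obs):
        return float("nan"), 0
    x, y = _usable(subject, roi_id, target)
    if seed is None:
        seed = derive_seed(spec.rng_seed, subject.subject_id, roi_id,
                           target, "null")
    rng = np.random.default_rng(seed)
    if regressor is None or isinstance(regressor, OLSRegressor):
        null_r = _null_aggregates_ols(x, y, spec.n_train, spec.n_test,
                                      n_perm, null_repeats, rng)
    else:
        null_spec = dataclasses.replace(spec, n_repeats=null_repeats)
        null_r = np.empty(n_perm)
        for p in range(n_perm):
            y_p = rng.permutation(y)
            shuffled = dataclasses.replace(
                subject, betas=x[:, None], rt=y_p, confidence=y_p,
                run_id=np.zeros(x.size, dtype=int))
            null_spec = dataclasses.replace(
                null_spec, rng_seed=int(rng.integers(2**31)))
            null_r[p] = decode_cell(shuffled, 1, target, null_spec,
                                    regressor).r_aggregated
    count = int(np.sum(null_r[np.isfinite(null_r)] >= obs))
    return (1.0 + count) / (1.0 + n_perm), n_perm


# ---------------------------------------------------------------------------
# cohort-level driver
# ---------------------------------------------------------------------------

def decode_all(cohort, atlas, spec, regressor_name: str = "ols",
               n_perm: int = 1000, null_repeats: int = 5,
               master_seed: int = 0, targets=TARGETS,
               spec_by_target: dict | None = None,
               progress=None) -> DecodingResult:
    """Decode every (subject, ROI, target) cell of a cohort.

    ``spec`` applies to every target unless ``spec_by_target`` overrides a
    target's sizing (e.g. 301/101 splits for half-rated confidence).  Each
    cell draws its own seed from ``(master_seed, subject, roi, target)`` so
    results are independent of scheduling order.  Sizing problems (too few
    usable trials, zero-variance parcels) flag the cell missing rather than
    aborting the cohort.
    """
    if not cohort:
        raise ValidationError("empty cohort")
    spec_by_target = dict(spec_by_target or {})
    for t in targets:
        spec_by_target.setdefault(t, spec)
    subject_ids = [s.subject_id for s in cohort]
    cells = []
    for subject in cohort:
        for target in targets:
            base = spec_by_target[target]
            for roi_id in atlas.roi_id:
                roi_id = int(roi_id)
                cell_seed = derive_seed(master_seed, subject.subject_id,
                                        roi_id, target, "decode")
                cell_spec = dataclasses.replace(base, rng_seed=cell_seed)
                try:
                    rep = decode_cell(subject, roi_id, target, cell_spec,
                                      make_regressor(regressor_name))
                    if not np.isfinite(rep.r_aggregated):
                        raise ValidationError("undefined aggregate (zero variance)")
                    null_seed = derive_seed(master_seed, subject.subject_id,
                                            roi_id, target, "null")
                    p, used = permutation_null(
                        subject, roi_id, target, cell_spec, n_perm=n_perm,
                        null_repeats=null_repeats,
                        regressor=make_regressor(regressor_name),
                        observed=rep, seed=null_seed)
                    cells.append(CellResult(subject.subject_id, roi_id, target,
                                            rep, p, used))
                except ValidationError as exc:
                    cells.append(CellResult(subject.subject_id, roi_id, target,
                                            None, missing=True,
                                            reason=str(exc)))
            if progress is not None:
                progress(subject.subject_id, target)
    return DecodingResult(cells, spec_by_target, subject_ids, atlas.roi_id)
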