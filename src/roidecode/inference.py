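"""Significance ledger, group-level tests, coverage summaries, motion QC.

Subject-level p-values are evaluated at a base alpha (0.05) and at three
Bonferroni corrections: for the number of subjects, the number of ROIs, and
their product.  The four boolean maps are nested by factor magnitude (a
larger correction factor is a stricter threshold; in the usual regime with
fewer subjects than ROIs this coincides with list order) and are
summarized three ways: per level the percentage of ROIs with at least one
significant subject, per ROI the percentage of significant subjects, and
per subject the percentage of significant ROIs.

Group-level decoding aggregates subject performance per ROI on the Fisher-z
scale and applies a one-tailed one-sample t-test against zero, Bonferroni
corrected for the number of ROIs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import ValidationError, pearson
from .decoding import DecodingResult

#: Human-readable names of the four correction levels, loosest first.
LEVEL_NAMES = ("uncorrected", "n_subjects", "n_rois", "n_subjects_x_n_rois")


@dataclasses.dataclass
class SignificanceLedger:
    """Boolean significance maps at the four Bonferroni levels.

    ``significant[i, j, k]`` is True when subject i decodes ROI j at level
    k (p < alpha / correction_factors[k]).  ``most_conservative_level`` is
    0 for NS, 1 for uncorrected only, up to 4 for the strictest level.
    """

    target: str
    alpha: float
    correction_factors: tuple
    subject_ids: list
    roi_ids: np.ndarray
    significant: np.ndarray
    most_conservative_level: np.ndarray

    @property
    def n_levels(self) -> int:
        return len(self.correction_factors)


def build_ledger(results: DecodingResult, target: str,
                 alpha: float = 0.05) -> SignificanceLedger:
    """Threshold the permutation p-values at all four correction levels.

    Missing cells (no p-value) are NS everywhere.  Note a permutation p is
    floored at 1/(n_perm + 1): with 1000 permutations the strictest levels
    of a large cohort (alpha/10000 = 5e-6) are unreachable by construction;
    :func:`roidecode.decoding.parametric_pvalue` is the alternative route
    for that regime.
    """
    p = results.p_matrix(target)
    S, R = p.shape
    factors = (1, S, R, S * R)
    thresholds = np.array([alpha / f for f in factors])
    with np.errstate(invalid="ignore"):
        sig = p[:, :, None] < thresholds[None, None, :]
    sig[~np.isfinite(p)] = False
    level = sig.sum(axis=2)
    return SignificanceLedger(
        target=target, alpha=alpha, correction_factors=factors,
        subject_ids=results.subject_ids, roi_ids=results.roi_ids,
        significant=sig, most_conservative_level=level)


@dataclasses.dataclass
class CoverageSummary:
    """The three percentage families, per correction level."""

    target: str
    level_names: tuple
    #: per level: % of ROIs with >= 1 significant subject
    pct_rois_any_subject: np.ndarray
    #: (n_rois, n_levels): % of subjects significant per ROI
    pct_subjects_per_roi: np.ndarray
    #: (n_subjects, n_levels): % of ROIs significant per subject
    pct_rois_per_subject: np.ndarray

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "levels": list(self.level_names),
            "pct_rois_any_subject": self.pct_rois_any_subject.tolist(),
            "mean_pct_subjects_per_roi":
                self.pct_subjects_per_roi.mean(axis=0).tolist(),
            "mean_pct_rois_per_subject":
                self.pct_rois_per_subject.mean(axis=0).tolist(),
            "pct_subjects_per_roi": self.pct_subjects_per_roi.tolist(),
            "pct_rois_per_subject": self.pct_rois_per_subject.tolist(),
        }


def summarize_coverage(ledger: SignificanceLedger) -> CoverageSummary:
    sig = ledger.significant
    S, R, L = sig.shape
    return CoverageSummary(
        target=ledger.target,
        level_names=LEVEL_NAMES,
        pct_rois_any_subject=100.0 * sig.any(axis=0).sum(axis=0) / R,
        pct_subjects_per_roi=100.0 * sig.sum(axis=0) / S,
        pct_rois_per_subject=100.0 * sig.sum(axis=1) / R,
    )


def group_decode(results: DecodingResult, target: str,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Group-level decoding per ROI, Bonferroni corrected across ROIs.

    Subject aggregated performances are averaged on the Fisher-z scale and
    tested against zero with a one-tailed one-sample t-test (alternative:
    mean z > 0).  ROIs with fewer than 3 contributing subjects are flagged
    untestable; zero-variance ROIs (all subjects identical) are flagged
    degenerate rather than silently dropped.
    """
    z = results.z_matrix(target)
    R = results.roi_ids.size
    rows = []
    for j, rid in enumerate(results.roi_ids):
        zj = z[:, j]
        zj = zj[np.isfinite(zj)]
        n = zj.size
        row = {"roi_id": int(rid), "n_subjects": n,
               "r_group": float(np.tanh(zj.mean())) if n else np.nan,
               "t": np.nan, "p_one_tailed": np.nan,
               "untestable": n < 3, "degenerate": False,
               "significant_corrected": False}
        if n >= 3:
            if np.ptp(zj) == 0.0:
                row["degenerate"] = True
            else:
                res = stats.ttest_1samp(zj, 0.0, alternative="greater")
                row["t"] = float(res.statistic)
                row["p_one_tailed"] = float(res.pvalue)
                row["significant_corrected"] = bool(res.pvalue < alpha / R)
        rows.append(row)
    return pd.DataFrame(rows)


def fd_qc(cohort, results: DecodingResult, target: str) -> tuple[float, float]:
    """Motion check: regress per-subject mean performance on mean FD.

    Per subject, aggregated performance is averaged over ROIs on the z
    scale; a simple linear regression on the subject's mean frame
    displacement yields (R², two-tailed p).  Identical FD across subjects
    is a degenerate design and raises.
    """
    z = results.z_matrix(target)
    perf = np.nanmean(z, axis=1)
    fd = np.array([s.mean_fd for s in cohort], dtype=float)
    ok = np.isfinite(perf) & np.isfinite(fd)
    if ok.sum() < 3:
        raise ValidationError("fd_qc needs >= 3 subjects with FD and performance")
    fd, perf = fd[ok], perf[ok]
    if np.ptp(fd) == 0.0:
        raise ValidationError("fd_qc degenerate: identical FD across subjects")
    res = stats.linregress(fd, perf)
    return float(res.rvalue**2), float(res.pvalue)
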