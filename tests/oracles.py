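"""Independent naive-loop reference implementations used as test oracles.

These deliberately avoid the package's computational paths: fits go through
numpy's polyfit / pinv, correlations through np.corrcoef, aggregations and
counts through explicit Python loops.  They share only the split-index
*policy* functions (which indices go where is a convention, not math).
"""

import math

import numpy as np

from roidecode import split_trials
from roidecode.decoding import FISHER_CLIP
from roidecode._utils import derive_seed


def naive_pearson(a, b):
    return float(np.corrcoef(a, b)[0, 1])


def naive_fisher_mean(r_list):
    zs = [math.atanh(max(-FISHER_CLIP, min(FISHER_CLIP, r)))
          for r in r_list if np.isfinite(r)]
    if not zs:
        return float("nan")
    return math.tanh(sum(zs) / len(zs))


def naive_decode_cell(subject, roi_id, target, spec):
    """Loop-and-polyfit re-implementation of repeated-split decoding."""
    x_all = subject.betas[:, roi_id - 1]
    y_all = subject.target_vector(target)
    mask = np.isfinite(y_all) & np.isfinite(x_all)
    x, y = x_all[mask], y_all[mask]
    rs = []
    for i in range(spec.n_repeats):
        tr, te = split_trials(x.size, spec, i)
        if np.std(x[tr]) == 0:
            rs.append(float("nan"))
            continue
        slope, intercept = np.polyfit(x[tr], y[tr], 1)
        pred = intercept + slope * x[te]
        if np.std(pred) == 0 or np.std(y[te]) == 0:
            rs.append(float("nan"))
        else:
            rs.append(naive_pearson(y[te], pred))
    return naive_fisher_mean(rs)


def naive_group_decode(z_matrix, roi_ids, alpha=0.05):
    """Per-ROI loop of one-sample one-tailed t-tests on Fisher-z values."""
    from scipy import stats

    out = []
    R = len(roi_ids)
    for j in range(R):
        zj = z_matrix[:, j]
        zj = zj[np.isfinite(zj)]
        if zj.size < 3 or np.ptp(zj) == 0:
            out.append((float("nan"), float("nan"), False))
            continue
        m = zj.mean()
        se = zj.std(ddof=1) / math.sqrt(zj.size)
        t = m / se
        p = float(stats.t.sf(t, df=zj.size - 1))
        out.append((t, p, p < alpha / R))
    return out


def naive_coverage(significant):
    """Brute-force recount of the three coverage percentage families."""
    S, R, L = significant.shape
    any_subj = np.zeros(L)
    per_roi = np.zeros((R, L))
    per_subj = np.zeros((S, L))
    for lev in range(L):
        n_any = 0
        for j in range(R):
            col = [significant[i, j, lev] for i in range(S)]
            if any(col):
                n_any += 1
            per_roi[j, lev] = 100.0 * sum(col) / S
        any_subj[lev] = 100.0 * n_any / R
        for i in range(S):
            row = [significant[i, j, lev] for j in range(R)]
            per_subj[i, lev] = 100.0 * sum(row) / R
    return any_subj, per_roi, per_subj


def naive_sign_counts(significant_level, direction):
    """Loop recount of positive/negative significant subjects per ROI."""
    S, R = significant_level.shape
    pos = np.zeros(R, dtype=int)
    neg = np.zeros(R, dtype=int)
    for j in range(R):
        for i in range(S):
            if significant_level[i, j]:
                if direction[i, j] > 0:
                    pos[j] += 1
                elif direction[i, j] < 0:
                    neg[j] += 1
    return pos, neg


def naive_sufficiency_curve(cohort, target, fractions, n_repeats, seed,
                            rng_seed=0):
    """pinv-based re-implementation of the whole-brain sufficiency sweep.

    Reproduces the package's split policy (same RNG stream definition),
    but fits via explicit pseudoinverse and scores via np.corrcoef.
    """
    S = len(cohort)
    means = np.full((S, len(fractions)), np.nan)
    sds = np.full((S, len(fractions)), np.nan)
    for si, subject in enumerate(cohort):
        y_all = subject.target_vector(target)
        mask = np.isfinite(y_all)
        X, y = subject.betas[mask], y_all[mask]
        n = y.size
        rng = np.random.default_rng(
            derive_seed(seed, subject.subject_id, target, "sufficiency",
                        rng_seed))
        for fi, f in enumerate(fractions):
            n_train = int(round(f * n))
            rs = []
            for rep in range(n_repeats):
                order = rng.permutation(n)
                tr, te = order[:n_train], order[n_train:]
                A = np.column_stack([np.ones(tr.size), X[tr]])
                coef = np.linalg.pinv(A) @ y[tr]
                pred = np.column_stack([np.ones(te.size), X[te]]) @ coef
                if np.std(pred) == 0 or np.std(y[te]) == 0:
                    rs.append(float("nan"))
                else:
                    rs.append(naive_pearson(y[te], pred))
            rs = np.asarray(rs)
            ok = np.isfinite(rs)
            if ok.sum() >= 2:
                means[si, fi] = rs[ok].mean()
                sds[si, fi] = rs[ok].std(ddof=1)
    return np.nanmean(means, axis=0), np.nanmean(sds, axis=0)
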