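"""Tabular I/O for the decoding pipeline.

All files are tab-separated UTF-8 text with a mandatory header row; missing
values are written as empty fields.  A subject table has one row per trial
with columns ``trial``, ``run``, ``rt`` (seconds), ``confidence`` (ordinal,
may be empty), one ``roi_<id>`` column per atlas parcel, and optionally a
constant ``mean_fd`` column (mm).  ROI columns are matched by *name* against
the atlas, never by position.  ``roi_id`` is 1-based everywhere at the
interface.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import FormatError, ValidationError

#: The seven large-scale cortical networks of the 200-parcel scheme.
NETWORKS = ("FPN", "DMN", "DAN", "LIM", "VAN", "SOM", "VIS")

#: Text float format preserving full double precision on round-trip.
_FLOAT_FMT = "%.17g"


@dataclasses.dataclass
class SubjectData:
    """One subject's trials-by-ROIs activations plus behavior.

    Attributes
    ----------
    subject_id : str
    betas : ndarray, shape (n_trials, n_rois)
        Trial-wise activation estimates (mean single-trial beta per parcel).
    rt : ndarray, shape (n_trials,)
        Reaction times in seconds; NaN where missing.  Strictly positive
        where present.
    confidence : ndarray, shape (n_trials,)
        Ordinal confidence ratings as floats; NaN where missing (e.g. when
        only half the trials carry ratings).
    run_id : ndarray of int, shape (n_trials,)
    mean_fd : float
        Subject-average frame displacement in mm (head-motion nuisance);
        NaN if unknown.
    """

    subject_id: str
    betas: np.ndarray
    rt: np.ndarray
    confidence: np.ndarray
    run_id: np.ndarray
    mean_fd: float = float("nan")

    def __post_init__(self):
        self.betas = np.atleast_2d(np.asarray(self.betas, dtype=float))
        self.rt = np.asarray(self.rt, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        self.run_id = np.asarray(self.run_id, dtype=int)
        n = self.betas.shape[0]
        for name, vec in (("rt", self.rt), ("confidence", self.confidence),
                          ("run", self.run_id)):
            if vec.shape != (n,):
                raise ValidationError(
                    f"subject {self.subject_id}: column '{name}' has "
                    f"{vec.shape[0] if vec.ndim == 1 else '?'} rows, betas have {n}")
        bad = np.flatnonzero(~np.isnan(self.rt) & (self.rt <= 0))
        if bad.size:
            raise ValidationError(
                f"subject {self.subject_id}: non-positive rt at row {bad[0]}")

    @property
    def n_trials(self) -> int:
        return self.betas.shape[0]

    @property
    def n_rois(self) -> int:
        return self.betas.shape[1]

    def target_vector(self, target: str) -> np.ndarray:
        if target == "rt":
            return self.rt
        if target == "confidence":
            return self.confidence
        raise ValidationError(f"unknown target {target!r}")


@dataclasses.dataclass
class Atlas:
    """Parcellation lookup: 1-based contiguous ROI ids, names and networks."""

    roi_id: np.ndarray
    roi_name: list
    network: list

    def __post_init__(self):
        self.roi_id = np.asarray(self.roi_id, dtype=int)
        ids = self.roi_id
        if ids.size == 0:
            raise ValidationError("atlas is empty")
        if len(set(ids.tolist())) != ids.size:
            raise FormatError("atlas contains duplicate roi_id")
        if not np.array_equal(np.sort(ids), np.arange(1, ids.size + 1)):
            raise FormatError("atlas roi_id range is non-contiguous or not 1-based")
        bad = sorted(set(self.network) - set(NETWORKS))
        if bad:
            raise FormatError(f"unknown network label(s): {bad}")

    @property
    def n_rois(self) -> int:
        return self.roi_id.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"roi_id": self.roi_id, "roi_name": self.roi_name,
             "network": self.network})


@dataclasses.dataclass
class CohortManifest:
    """Pointer file tying a dataset together: subject tables + split policy."""

    dataset_name: str
    subject_paths: list
    has_rt: bool = True
    has_confidence: bool = True
    #: mapping target -> (n_train, n_test)
    split_policy: dict = dataclasses.field(default_factory=dict)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["subject_paths"] = [str(p) for p in self.subject_paths]
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortManifest":
        d = json.loads(text)
        d["split_policy"] = {k: tuple(v) for k, v in d.get("split_policy", {}).items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_atlas(path) -> Atlas:
    """Read an atlas TSV with columns roi_id, roi_name, network."""
    df = pd.read_csv(path, sep="\t")
    for col in ("roi_id", "roi_name", "network"):
        if col not in df.columns:
            raise FormatError(f"atlas file {path}: missing column '{col}'")
    return Atlas(df["roi_id"].to_numpy(), df["roi_name"].tolist(),
                 df["network"].tolist())


def read_subject_table(path, atlas: Atlas, subject_id: str | None = None,
                       mean_fd: float | None = None) -> SubjectData:
    """Read one subject's trial table, matching ROI columns against *atlas*.

    Trial order in the returned :class:`SubjectData` equals file row order.
    Missing confidence entries stay missing (NaN), never zero.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("trial", "run", "rt"):
        if col not in df.columns:
            raise FormatError(f"subject file {path}: missing column '{col}'")
    roi_cols = [f"roi_{i}" for i in atlas.roi_id]
    missing = [c for c in roi_cols if c not in df.columns]
    if missing:
        raise FormatError(
            f"subject file {path}: missing ROI column '{missing[0]}'")
    if "confidence" in df.columns:
        conf = pd.to_numeric(df["confidence"], errors="coerce").to_numpy(float)
    else:
        conf = np.full(len(df), np.nan)
    if mean_fd is None:
        if "mean_fd" in df.columns:
            fd_col = df["mean_fd"].to_numpy(float)
            uniq = np.unique(fd_col[~np.isnan(fd_col)])
            if uniq.size > 1:
                raise FormatError(
                    f"subject file {path}: mean_fd column is not constant")
            mean_fd = float(uniq[0]) if uniq.size else float("nan")
        else:
            mean_fd = float("nan")
    if subject_id is None:
        subject_id = Path(path).stem
    rt = df["rt"].to_numpy(float)
    bad = np.flatnonzero(~np.isnan(rt) & (rt <= 0))
    if bad.size:
        raise ValidationError(
            f"subject file {path}: non-positive rt at row {bad[0]}")
    return SubjectData(
        subject_id=subject_id,
        betas=df[roi_cols].to_numpy(float),
        rt=rt,
        confidence=conf,
        run_id=df["run"].to_numpy(int),
        mean_fd=mean_fd,
    )


def read_cohort(manifest_path) -> tuple[list, CohortManifest, Atlas]:
    """Read a cohort manifest plus atlas and all subject tables it lists."""
    manifest_path = Path(manifest_path)
    manifest = CohortManifest.from_json(manifest_path.read_text())
    base = manifest_path.parent
    atlas = read_atlas(base / "atlas.tsv")
    cohort = [read_subject_table(base / p, atlas) for p in manifest.subject_paths]
    n_rois = {s.n_rois for s in cohort}
    if len(n_rois) > 1:
        raise ValidationError(f"cohort mixes ROI counts: {sorted(n_rois)}")
    return cohort, manifest, atlas


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_atlas(atlas: Atlas, path) -> None:
    atlas.to_frame().to_csv(path, sep="\t", index=False)


def write_subject_table(subject: SubjectData, path, roi_ids=None) -> None:
    """Write a SubjectData back to the subject-table TSV dialect."""
    if roi_ids is None:
        roi_ids = np.arange(1, subject.n_rois + 1)
    df = pd.DataFrame({"trial": np.arange(1, subject.n_trials + 1),
                       "run": subject.run_id,
                       "rt": subject.rt,
                       "confidence": subject.confidence})
    if np.isfinite(subject.mean_fd):
        df["mean_fd"] = subject.mean_fd
    for j, rid in enumerate(roi_ids):
        df[f"roi_{rid}"] = subject.betas[:, j]
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _matrix_frame(values: np.ndarray, subject_ids: Sequence[str],
                  roi_ids: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(values, columns=[f"roi_{i}" for i in roi_ids])
    df.insert(0, "subject_id", list(subject_ids))
    return df


def write_result_tables(results, ledger, out_dir, atlas: Atlas | None = None):
    """Write the decoding result bundle for one target.

    Produces four files under *out_dir* (deterministic roi_id-ascending
    column order):

    - ``performance_<target>.tsv`` — subject × ROI aggregated r
    - ``p_perm_<target>.tsv`` — subject × ROI permutation p-values
    - ``levels_<target>.tsv`` — most conservative correction level passed
      (0 = NS, 1 = uncorrected, 2..4 = the three Bonferroni factors);
      missing cells are empty
    - ``direction_<target>.tsv`` — sign of the mean fitted slope per cell
    - ``coverage_<target>.json`` — the coverage percentage summary

    Cells with undefined performance (e.g. a zero-variance ROI) are written
    as empty fields in every matrix.  Returns the list of written paths.
    """
    from .inference import summarize_coverage  # local import avoids a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    target = ledger.target
    subject_ids, roi_ids = ledger.subject_ids, ledger.roi_ids

    perf = results.performance_matrix(target)
    pmat = results.p_matrix(target)
    direction = results.direction_matrix(target)
    levels = ledger.most_conservative_level.astype(float)
    levels[np.isnan(perf)] = np.nan
    direction[np.isnan(perf)] = np.nan

    written = []
    for stem, mat in (("performance", perf), ("p_perm", pmat),
                      ("levels", levels), ("direction", direction)):
        path = out_dir / f"{stem}_{target}.tsv"
        _matrix_frame(mat, subject_ids, roi_ids).to_csv(
            path, sep="\t", index=False, float_format=_FLOAT_FMT)
        written.append(path)

    cov = summarize_coverage(ledger)
    path = out_dir / f"coverage_{target}.json"
    path.write_text(json.dumps(cov.to_dict(), indent=2, sort_keys=True))
    written.append(path)
    return written


def read_matrix_table(path) -> tuple[list, np.ndarray, np.ndarray]:
    """Re-parse a subject × ROI matrix TSV; returns (subject_ids, roi_ids, values)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    roi_cols = [c for c in df.columns if c.startswith("roi_")]
    roi_ids = np.array([int(c.split("_", 1)[1]) for c in roi_cols])
    return df["subject_id"].tolist(), roi_ids, df[roi_cols].to_numpy(float)
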