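"""Opposite-sign brain–behavior relationships across subjects.

An ROI is *divergent* at a given correction level when at least one subject
decodes it significantly with a positive fitted slope and at least one
other subject with a negative slope — the same parcel predicting, say,
slower RT with higher activation in one person and faster RT in another.
Counts, flags and percentages are computed at every ledger level and
broken down by cortical network.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ._utils import ValidationError
from .decoding import DecodingResult
from .inference import LEVEL_NAMES, SignificanceLedger
from .io import Atlas


@dataclasses.dataclass
class DivergenceResult:
    target: str
    level_names: tuple
    #: (n_rois, n_levels) bool: both signs present among significant subjects
    roi_flags: np.ndarray
    #: per level, % of all ROIs flagged
    pct_rois_divergent: np.ndarray
    #: (n_rois, n_levels, 2): n_pos_significant, n_neg_significant
    sign_counts: np.ndarray
    roi_ids: np.ndarray
    #: network -> per-level % of that network's ROIs flagged
    network_pct: dict

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "levels": list(self.level_names),
            "pct_rois_divergent": self.pct_rois_divergent.tolist(),
            "network_pct": {k: v.tolist() for k, v in self.network_pct.items()},
        }


def sign_counts(results: DecodingResult, ledger: SignificanceLedger,
                level: int) -> pd.DataFrame:
    """Per-ROI counts of significantly positive / negative subjects.

    ``level`` indexes the ledger's correction factors (0 = uncorrected).
    Direction 0 cells (exactly zero mean slope) count in neither column.
    """
    if not 0 <= level < ledger.n_levels:
        raise ValidationError(f"level {level} out of range")
    sig = ledger.significant[:, :, level]
    direction = results.direction_matrix(ledger.target)
    pos = (sig & (direction > 0)).sum(axis=0)
    neg = (sig & (direction < 0)).sum(axis=0)
    return pd.DataFrame({"roi_id": ledger.roi_ids,
                         "n_pos": pos.astype(int),
                         "n_neg": neg.astype(int)})


def divergent_rois(results: DecodingResult, ledger: SignificanceLedger,
                   atlas: Atlas) -> DivergenceResult:
    """Flag divergent ROIs at every correction level and summarize."""
    R = ledger.roi_ids.size
    L = ledger.n_levels
    counts = np.zeros((R, L, 2), dtype=int)
    flags = np.zeros((R, L), dtype=bool)
    for lev in range(L):
        c = sign_counts(results, ledger, lev)
        counts[:, lev, 0] = c["n_pos"]
        counts[:, lev, 1] = c["n_neg"]
        flags[:, lev] = (counts[:, lev, 0] >= 1) & (counts[:, lev, 1] >= 1)
    pct = 100.0 * flags.sum(axis=0) / R

    networks = np.asarray(atlas.network)
    net_pct = {}
    for net in sorted(set(networks.tolist())):
        members = networks == net
        net_pct[net] = 100.0 * flags[members].sum(axis=0) / members.sum()

    return DivergenceResult(target=ledger.target, level_names=LEVEL_NAMES,
                            roi_flags=flags, pct_rois_divergent=pct,
                            sign_counts=counts, roi_ids=ledger.roi_ids,
                            network_pct=net_pct)
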