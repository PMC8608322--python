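"""Regulation sets: which reactions the flux difference should agree with.

From per-reaction fold changes the method needs the set of upregulated
reactions ``R_up`` (expression went up, so the flux difference is encouraged
to be positive) and downregulated reactions ``R_down``, each with a
non-negative weight (default 1), plus per-reaction thresholds mu/eta beyond
which a flux difference counts as a genuine increase/decrease.  Reactions can
also be forced to zero flux change.  Sets are expressed as *split-network*
indices; a regulated reversible reaction contributes its forward half, the
backward half being governed by the pair-coupling constraints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gpr import ReactionDelta
from .model_io import SplitNetwork

__all__ = [
    "RegulationInput",
    "select_regulated",
    "apply_knockout",
    "default_thresholds",
    "read_regulation_table",
]


@dataclass
class RegulationInput:
    """Up/down regulation sets with weights, thresholds and forced zeros.

    ``r_up``/``r_down`` map split-reaction indices to weights; ``mu``/``eta``
    are per-split-reaction thresholds (flux units) for calling a difference
    positive/negative; ``forced_zero`` indices must have zero flux change.
    """

    r_up: dict[int, float] = field(default_factory=dict)
    r_down: dict[int, float] = field(default_factory=dict)
    forced_zero: set[int] = field(default_factory=set)
    mu: np.ndarray | None = None
    eta: np.ndarray | None = None

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.r_up.values()) or any(w < 0 for w in self.r_down.values()):
            raise ValueError("regulation weights must be non-negative")
        if self.mu is not None and np.any(np.asarray(self.mu) < 0):
            raise ValueError("mu thresholds must be non-negative")
        if self.eta is not None and np.any(np.asarray(self.eta) < 0):
            raise ValueError("eta thresholds must be non-negative")

    def validate_disjoint(self, split: SplitNetwork) -> None:
        """R_up and R_down must not share an original reaction."""
        up = {int(split.origin_index[k]) for k in self.r_up}
        down = {int(split.origin_index[k]) for k in self.r_down}
        both = up & down
        if both:
            ids = [split.net.reaction_ids[i] for i in sorted(both)]
            raise ValueError(f"reactions in both R_up and R_down: {ids}")


def default_thresholds(
    split: SplitNetwork, epsilon_frac: float = 0.001
) -> tuple[np.ndarray, np.ndarray]:
    """Constant thresholds mu = eta = epsilon_frac x largest bound magnitude.

    The magnitude is taken over all split reactions and both conditions
    (infinite bounds ignored).  The default fraction 0.001 makes epsilon
    0.1% of the largest flux bound.
    """
    mags = np.abs(
        np.concatenate([split.lb_C, split.ub_C, split.lb_P, split.ub_P])
    )
    mags = mags[np.isfinite(mags)]
    eps = epsilon_frac * (mags.max() if mags.size else 0.0)
    if eps == 0.0:
        warnings.warn("all flux bounds are zero; thresholds set to 0")
    mu = np.full(split.n_split, eps)
    return mu, mu.copy()


def select_regulated(
    rdelta: ReactionDelta,
    split: SplitNetwork,
    mode: str = "fc_cutoff",
    param: float = 1.0,
    epsilon_frac: float = 0.001,
) -> RegulationInput:
    """Build R_up / R_down from reaction fold changes.

    mode="fc_cutoff": R_up = {fc > param}, R_down = {fc < 1/param}; param >= 1
    is a symmetric cutoff on the log scale (param=1 selects every reaction
    whose expression moved at all).

    mode="percentile": reactions are ranked by log2 fold change and the top
    and bottom ``param`` percent (0 < param < 50) selected, ties at the
    boundary included; a reaction only enters R_up with fc > 1 and R_down
    with fc < 1.

    Uncovered reactions are never selected.  All weights default to 1.
    """
    if not rdelta.covered.any():
        raise ValueError("no reaction has expression coverage")
    fc = rdelta.rxn_fc
    cov = rdelta.covered
    if mode == "fc_cutoff":
        if param < 1:
            raise ValueError("fc_cutoff param must be >= 1")
        up_mask = cov & (fc > param)
        down_mask = cov & (fc < 1.0 / param)
    elif mode == "percentile":
        if not 0 < param < 50:
            raise ValueError("percentile param must be in (0, 50)")
        lfc = np.log2(fc[cov])
        k = int(np.floor(len(lfc) * param / 100.0))
        up_mask = np.zeros_like(cov)
        down_mask = np.zeros_like(cov)
        if k > 0:
            order = np.sort(lfc)
            hi, lo = order[-k], order[k - 1]
            up_mask = cov & (np.log2(fc, where=fc > 0, out=np.full_like(fc, -np.inf)) >= hi)
            down_mask = cov & (np.log2(fc, where=fc > 0, out=np.full_like(fc, np.inf)) <= lo)
        up_mask &= fc > 1.0
        down_mask &= fc < 1.0
    else:
        raise ValueError(f"unknown selection mode {mode!r}")

    reg = RegulationInput(
        r_up={int(split.forward_of[j]): 1.0 for j in np.where(up_mask)[0]},
        r_down={int(split.forward_of[j]): 1.0 for j in np.where(down_mask)[0]},
    )
    reg.mu, reg.eta = default_thresholds(split, epsilon_frac)
    if not reg.r_up and not reg.r_down:
        warnings.warn("regulation selection produced empty R_up and R_down")
    return reg


def apply_knockout(
    reg: RegulationInput,
    split: SplitNetwork,
    reaction_ids: list[str],
    weight: float = 10.0,
) -> RegulationInput:
    """Add knocked-out reactions to R_down with a high weight (default 10).

    A knockout's flux falls to zero in the perturbed condition, so its flux
    difference should be negative; the elevated weight prioritizes this over
    ordinary expression evidence.  A reaction already in R_down keeps the
    larger of the two weights; one in R_up is removed from it.
    """
    for rid in reaction_ids:
        k = int(split.forward_of[split.net.reaction_index(rid)])
        reg.r_up.pop(k, None)
        reg.r_down[k] = max(weight, reg.r_down.get(k, 0.0))
    return reg


def read_regulation_table(path, split: SplitNetwork) -> RegulationInput:
    """Read explicit regulation sets: TSV with reaction_id, direction, weight."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    reg = RegulationInput()
    for row in df.itertuples():
        k = int(split.forward_of[split.net.reaction_index(str(row.reaction_id))])
        w = float(getattr(row, "weight", 1.0))
        d = str(row.direction).lower()
        if d == "up":
            reg.r_up[k] = w
        elif d == "down":
            reg.r_down[k] = w
        else:
            raise ValueError(f"direction must be up/down, got {row.direction!r}")
    reg.validate_disjoint(split)
    reg.mu, reg.eta = default_thresholds(split)
    return reg
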