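"""Downstream interpretation of a flux-difference solution.

Two analyses: (1) metabolic-subsystem enrichment — are upregulated (or
downregulated) flux changes over-represented in a pathway? Fisher's exact
test per (subsystem, direction) with Benjamini-Hochberg correction within a
direction; (2) metabolite flux-throughput differences — the change in total
directional production flux of each metabolite, compartments collapsed,
which flags candidate biomarker metabolites.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .core import DeltaSolution
from .model_io import SplitNetwork

__all__ = [
    "classify_changed",
    "subsystem_enrichment",
    "metabolite_throughput_delta",
    "EnrichmentResult",
    "strip_compartment",
]

# trailing "_c" / "_m" style tags and "[c]" style tags
_COMPARTMENT_PATTERNS = (re.compile(r"_[a-z0-9]+$"), re.compile(r"\[[a-z0-9]+\]$"))


@dataclass
class EnrichmentResult:
    subsystem: str
    direction: str
    in_changed: int
    in_unchanged: int
    out_changed: int
    out_unchanged: int
    odds_ratio: float
    p_value: float
    adjusted_p: float


def classify_changed(sol: DeltaSolution, eps: float) -> np.ndarray:
    """Label each original reaction 'up' (dv_net > eps), 'down' (< -eps) or
    'unchanged' (strict inequalities; |dv| = eps is unchanged)."""
    dv = np.asarray(sol.dv_net, dtype=float)
    return np.where(dv > eps, "up", np.where(dv < -eps, "down", "unchanged"))


def subsystem_enrichment(
    labels: np.ndarray,
    subsystems: list[str],
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """One Fisher exact test per (subsystem, direction).

    The 2x2 table for direction d and subsystem s counts reactions by
    (in s?) x (labelled d?).  One-sided 'greater' tests over-representation;
    p-values are BH-adjusted across subsystems within each direction and
    results are sorted by adjusted p.  Empty subsystem labels are skipped.
    """
    labels = np.asarray(labels)
    subsystems = np.asarray(subsystems)
    if labels.size != subsystems.size:
        raise ValueError("labels and subsystems must align per reaction")
    if not np.any(labels != "unchanged"):
        raise ValueError("no changed reaction; enrichment is undefined")
    results: list[EnrichmentResult] = []
    for direction in ("up", "down"):
        changed = labels == direction
        rows = []
        for s in sorted({s for s in subsystems if s}):
            in_s = subsystems == s
            a = int(np.sum(in_s & changed))
            b = int(np.sum(in_s & ~changed))
            c = int(np.sum(~in_s & changed))
            d = int(np.sum(~in_s & ~changed))
            odds, p = fisher_exact([[a, b], [c, d]], alternative=alternative)
            rows.append((s, a, b, c, d, float(odds), float(p)))
        if not rows:
            continue
        pvals = [r[6] for r in rows]
        adj = multipletests(pvals, method="fdr_bh")[1]
        for (s, a, b, c, d, odds, p), q in zip(rows, adj):
            results.append(EnrichmentResult(s, direction, a, b, c, d, odds, p, float(q)))
    results.sort(key=lambda r: (r.adjusted_p, r.p_value, r.subsystem))
    return results


def strip_compartment(met_id: str) -> str:
    for pat in _COMPARTMENT_PATTERNS:
        if pat.search(met_id):
            return pat.sub("", met_id)
    return met_id


def metabolite_throughput_delta(
    sol: DeltaSolution,
    split: SplitNetwork,
    threshold_frac: float = 0.01,
) -> pd.DataFrame:
    """Change in total production flux per metabolite, compartments collapsed.

    In split space all fluxes are direction-resolved, so production is
    well-defined: for each metabolite, sum ``S_entry * dv_split`` over split
    reactions that produce it (positive stoichiometric entry), then sum over
    compartment instances of the same base id.  Rows with
    ``|delta| <= threshold_frac x largest flux bound`` are dropped
    (threshold_frac=0 keeps everything).  Metabolites with exactly one
    producing and one consuming reaction in the original network are flagged
    as linear-chain intermediates rather than removed.
    """
    S = split.S_split.tocsr()
    dv = np.asarray(sol.dv_split, dtype=float)
    prod = S.maximum(0).dot(dv)  # per-metabolite production change

    S0 = split.net.S.tocsr()
    n_prod = np.asarray((S0 > 0).sum(axis=1)).ravel()
    n_cons = np.asarray((S0 < 0).sum(axis=1)).ravel()

    df = pd.DataFrame({
        "metabolite": [strip_compartment(m) for m in split.net.metabolite_ids],
        "delta_throughput": prod,
        "n_producers": n_prod,
        "n_consumers": n_cons,
    })
    agg = df.groupby("metabolite", sort=True).agg(
        delta_throughput=("delta_throughput", "sum"),
        n_producers=("n_producers", "sum"),
        n_consumers=("n_consumers", "sum"),
    ).reset_index()
    agg["linear_chain_flag"] = (agg["n_producers"] == 1) & (agg["n_consumers"] == 1)

    mags = np.concatenate([split.lb_C, split.ub_C, split.lb_P, split.ub_P])
    mags = np.abs(mags[np.isfinite(mags)])
    cut = threshold_frac * (mags.max() if mags.size else 0.0)
    if cut > 0:
        agg = agg[np.abs(agg["delta_throughput"]) > cut]
    return agg.sort_values("delta_throughput", ascending=False).reset_index(drop=True)
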