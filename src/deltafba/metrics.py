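"""Agreement between predicted and measured flux differences.

Three metrics: the uncentered Pearson correlation (cosine similarity of the
two difference vectors — no mean subtraction, since the natural origin of a
flux difference is zero), the root-mean-square error normalized by the range
of the measured differences (NRMSE), and the fraction of reactions whose
discretized change direction (+1 / 0 / -1) matches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "uncentered_pearson",
    "nrmse",
    "sign_accuracy",
    "EvaluationReport",
    "evaluate",
    "read_measured_fluxes",
    "align_measured",
]


def _pair(a, b):
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("empty vectors")
    return a, b


def uncentered_pearson(dv_measured, dv_predicted) -> float:
    """rho = (m . p) / (||m|| ||p||); NaN with a warning if either is zero."""
    m, p = _pair(dv_measured, dv_predicted)
    nm, np_ = np.linalg.norm(m), np.linalg.norm(p)
    if nm == 0.0 or np_ == 0.0:
        warnings.warn("uncentered Pearson undefined for a zero vector")
        return float("nan")
    return float(m @ p / (nm * np_))


def nrmse(dv_measured, dv_predicted) -> float:
    """RMS error divided by the measured range max(m) - min(m)."""
    m, p = _pair(dv_measured, dv_predicted)
    rng = m.max() - m.min()
    if rng == 0.0:
        warnings.warn("NRMSE undefined for a constant measured vector")
        return float("nan")
    return float(np.sqrt(np.mean((m - p) ** 2)) / rng)


def discretize(x, threshold) -> np.ndarray:
    """+1 above threshold, -1 below -threshold, else 0 (strict inequalities)."""
    x = np.asarray(x, dtype=float)
    t = np.broadcast_to(np.asarray(threshold, dtype=float), x.shape)
    return np.where(x > t, 1, np.where(x < -t, -1, 0))


def sign_accuracy(dv_measured, dv_predicted, eps_pred=0.0, eps_meas=0.0) -> float:
    """Fraction of entries with matching discretized change direction.

    Predictions are conventionally discretized at the method's threshold
    epsilon while measured values use exact zero (measured differences are
    often exactly 0); both thresholds are explicit arguments.
    """
    m, p = _pair(dv_measured, dv_predicted)
    return float(np.mean(discretize(m, eps_meas) == discretize(p, eps_pred)))


@dataclass
class EvaluationReport:
    rho: float
    nrmse: float
    sign_acc: float
    n_m: int

    def as_dict(self) -> dict:
        return {"rho": self.rho, "nrmse": self.nrmse,
                "sign_acc": self.sign_acc, "n_m": self.n_m}


def evaluate(dv_measured, dv_predicted, eps_pred=0.0, eps_meas=0.0) -> EvaluationReport:
    m, p = _pair(dv_measured, dv_predicted)
    return EvaluationReport(
        rho=uncentered_pearson(m, p),
        nrmse=nrmse(m, p),
        sign_acc=sign_accuracy(m, p, eps_pred, eps_meas),
        n_m=int(m.size),
    )


def read_measured_fluxes(path: str | Path) -> pd.Series:
    """TSV with columns flux_id, dv_measured."""
    df = pd.read_csv(path, sep="\t")
    if not {"flux_id", "dv_measured"}.issubset(df.columns):
        raise ValueError("measured-flux file needs columns flux_id, dv_measured")
    return pd.Series(df["dv_measured"].astype(float).values,
                     index=df["flux_id"].astype(str))


def align_measured(
    measured: pd.Series,
    dv_net: pd.Series,
    mapping: pd.DataFrame | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Align measured fluxes with predictions.

    Without a mapping, measured flux ids must be model reaction ids.  A
    mapping (columns flux_id, reaction_id, coefficient) expresses each
    measured flux as a signed sum of model reactions — the usual situation
    when isotope-tracing fluxes lump several model reactions.
    """
    if mapping is None:
        common = [r for r in measured.index if r in dv_net.index]
        if not common:
            raise ValueError("no measured flux id matches a model reaction id")
        return measured[common].to_numpy(), dv_net[common].to_numpy()
    need = {"flux_id", "reaction_id", "coefficient"}
    if not need.issubset(mapping.columns):
        raise ValueError(f"mapping file needs columns {sorted(need)}")
    meas, pred = [], []
    for fid, grp in mapping.groupby("flux_id"):
        if fid not in measured.index:
            continue
        meas.append(measured[fid])
        pred.append(sum(float(c) * dv_net.get(str(r), 0.0)
                        for r, c in zip(grp["reaction_id"], grp["coefficient"])))
    if not meas:
        raise ValueError("mapping matched no measured flux")
    return np.asarray(meas), np.asarray(pred)
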