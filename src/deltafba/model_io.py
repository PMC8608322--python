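"""Genome-scale metabolic model I/O and the irreversible (split) representation.

A genome-scale metabolic model (GEM) is held as a :class:`MetabolicNetwork`:
the stoichiometric matrix ``S`` (m metabolites x n reactions), per-reaction
flux bounds for *two* conditions — a control ``C`` and a perturbed ``P`` —
gene-protein-reaction (GPR) rule strings and pathway (subsystem) labels.
Flux-difference prediction operates on an all-irreversible representation
(:class:`SplitNetwork`) in which every reaction that admits negative flux in
either condition is written as a forward/backward pair of irreversible
reactions, and on interval bounds for the flux difference
``dv = v_P - v_C`` (:class:`DeltaBounds`).

SBML (Level 3 + FBC) and COBRA-style JSON models are read through cobrapy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "MetabolicNetwork",
    "SplitNetwork",
    "DeltaBounds",
    "load_model",
    "split_reversible",
    "delta_bounds",
    "read_bound_overrides",
]


@dataclass
class MetabolicNetwork:
    """A GEM with per-condition flux bounds.

    Bounds are in flux units (conventionally mmol gDW^-1 h^-1). ``lb_C/ub_C``
    apply to the control condition and ``lb_P/ub_P`` to the perturbed one;
    by default both are the model's bounds, and condition differences enter
    only through explicit overrides (e.g. measured uptake-rate differences).
    """

    metabolite_ids: list[str]
    metabolite_compartments: list[str]
    reaction_ids: list[str]
    S: sp.csc_matrix
    lb_C: np.ndarray
    ub_C: np.ndarray
    lb_P: np.ndarray
    ub_P: np.ndarray
    gpr_rules: list[str]
    subsystems: list[str]
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.S = sp.csc_matrix(self.S, dtype=float)
        m, n = self.S.shape
        if n == 0:
            raise ValueError("empty network: model declares zero reactions")
        if len(self.metabolite_ids) != m or len(self.reaction_ids) != n:
            raise ValueError(
                f"S is {m}x{n} but {len(self.metabolite_ids)} metabolites / "
                f"{len(self.reaction_ids)} reactions were declared"
            )
        for name in ("lb_C", "ub_C", "lb_P", "ub_P"):
            arr = np.asarray(getattr(self, name), dtype=float).ravel()
            if arr.size != n:
                raise ValueError(f"{name} has length {arr.size}, expected {n}")
            setattr(self, name, arr)
        if np.any(self.lb_C > self.ub_C) or np.any(self.lb_P > self.ub_P):
            bad = np.where((self.lb_C > self.ub_C) | (self.lb_P > self.ub_P))[0]
            raise ValueError(
                f"lower bound exceeds upper bound for reactions {bad.tolist()}"
            )
        if not np.all(np.isfinite(self.S.data)):
            raise ValueError("non-finite stoichiometric coefficient")
        if len(self.gpr_rules) != n or len(self.subsystems) != n:
            raise ValueError("gpr_rules and subsystems must have one entry per reaction")
        self._register_rule_genes()

    def _register_rule_genes(self) -> None:
        # genes referenced by a rule but absent from gene_ids are registered
        # with a warning rather than rejected (common in hand-edited models)
        from .gpr import parse_gpr, rule_genes

        declared = set(self.gene_ids)
        missing: set[str] = set()
        for rule in self.gpr_rules:
            expr = parse_gpr(rule)
            missing.update(g for g in rule_genes(expr) if g not in declared)
        if missing:
            warnings.warn(
                f"GPR rules reference {len(missing)} gene(s) not declared in the "
                f"model; auto-registering: {sorted(missing)[:5]}...",
                stacklevel=2,
            )
            self.gene_ids = list(self.gene_ids) + sorted(missing)

    @property
    def n_metabolites(self) -> int:
        return self.S.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction id {rid!r}") from None


@dataclass
class SplitNetwork:
    """All-irreversible representation of a :class:`MetabolicNetwork`.

    ``origin_index[k]`` is the original reaction index of split column k and
    ``origin_dir[k]`` is +1 (forward) or -1 (backward).  ``pair_map`` lists
    (k, k') index pairs, k the forward and k' the backward half of one
    reversible reaction.  All split lower bounds are >= 0.
    """

    net: MetabolicNetwork
    S_split: sp.csc_matrix
    split_ids: list[str]
    origin_index: np.ndarray
    origin_dir: np.ndarray
    pair_map: list[tuple[int, int]]
    lb_C: np.ndarray
    ub_C: np.ndarray
    lb_P: np.ndarray
    ub_P: np.ndarray
    forward_of: np.ndarray = field(init=False)   # original -> forward split col
    backward_of: np.ndarray = field(init=False)  # original -> backward col or -1

    def __post_init__(self) -> None:
        n = self.net.n_reactions
        self.forward_of = np.full(n, -1, dtype=int)
        self.backward_of = np.full(n, -1, dtype=int)
        for k, (oi, d) in enumerate(zip(self.origin_index, self.origin_dir)):
            if d > 0:
                self.forward_of[oi] = k
            else:
                self.backward_of[oi] = k

    @property
    def n_split(self) -> int:
        return self.S_split.shape[1]

    def net_vector(self, x_split: np.ndarray) -> np.ndarray:
        """Map a split-space vector to original reactions (forward - backward)."""
        x_split = np.asarray(x_split, dtype=float)
        out = x_split[self.forward_of]
        has_b = self.backward_of >= 0
        out[has_b] -= x_split[self.backward_of[has_b]]
        return out

    def split_index(self, rid: str, direction: int = +1) -> int:
        oi = self.net.reaction_index(rid)
        k = self.forward_of[oi] if direction > 0 else self.backward_of[oi]
        if k < 0:
            raise KeyError(f"reaction {rid!r} has no split column for direction {direction}")
        return int(k)


@dataclass
class DeltaBounds:
    """Interval bounds for the flux difference in split space.

    ``dv_min[i] = v_min_P[i] - v_max_C[i]`` and
    ``dv_max[i] = v_max_P[i] - v_min_C[i]`` unless overridden.
    ``net_overrides`` holds overrides that apply to the *net* difference of a
    reversible reaction (forward minus backward half), which cannot be
    expressed as split box bounds; they become extra constraint rows.
    """

    dv_min: np.ndarray
    dv_max: np.ndarray
    net_overrides: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dv_min = np.asarray(self.dv_min, dtype=float).ravel()
        self.dv_max = np.asarray(self.dv_max, dtype=float).ravel()
        if np.any(self.dv_min > self.dv_max):
            bad = np.where(self.dv_min > self.dv_max)[0]
            raise ValueError(f"dv_min > dv_max for split reactions {bad.tolist()}")


def _network_from_cobra(model) -> MetabolicNetwork:
    from cobra.util.array import create_stoichiometric_matrix

    if len(model.reactions) == 0:
        raise ValueError("empty network: model declares zero reactions")
    S = sp.csc_matrix(create_stoichiometric_matrix(model, array_type="lil"))
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    return MetabolicNetwork(
        metabolite_ids=[m.id for m in model.metabolites],
        metabolite_compartments=[m.compartment or "" for m in model.metabolites],
        reaction_ids=[r.id for r in model.reactions],
        S=S,
        lb_C=lb.copy(),
        ub_C=ub.copy(),
        lb_P=lb.copy(),
        ub_P=ub.copy(),
        gpr_rules=[r.gene_reaction_rule or "" for r in model.reactions],
        subsystems=[r.subsystem or "" for r in model.reactions],
        gene_ids=[g.id for g in model.genes],
    )


def load_model(path: str | Path, format: str | None = None) -> MetabolicNetwork:
    """Read a GEM from SBML (L3 + FBC) or COBRA-style JSON.

    Both conditions' bounds are initialized to the model's bounds; condition
    differences are introduced afterwards via bound overrides.

    Parameters
    ----------
    path : file path
    format : "sbml", "json" or None to infer from the file extension.
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    if format == "json":
        model = cobra.io.load_json_model(str(path))
    elif format == "sbml":
        model = cobra.io.read_sbml_model(str(path))
    else:
        raise ValueError(f"unknown model format {format!r} (expected 'sbml' or 'json')")
    return _network_from_cobra(model)


def split_reversible(net: MetabolicNetwork) -> SplitNetwork:
    """Split every reaction that admits negative flux in either condition.

    The forward half keeps the reaction's stoichiometric column with bounds
    ``[max(lb,0), max(ub,0)]`` per condition; the backward half gets the
    negated column with bounds ``[max(-ub,0), max(-lb,0)]``.  Reactions that
    are non-negative in both conditions map to a single unchanged column.
    """
    cols = []
    ids: list[str] = []
    origin_index: list[int] = []
    origin_dir: list[int] = []
    pair_map: list[tuple[int, int]] = []
    bounds = {k: [] for k in ("lb_C", "ub_C", "lb_P", "ub_P")}

    S = net.S.tocsc()
    for j, rid in enumerate(net.reaction_ids):
        col = S[:, j]
        reversible = net.lb_C[j] < 0 or net.lb_P[j] < 0
        cols.append(col)
        ids.append(rid)
        origin_index.append(j)
        origin_dir.append(+1)
        for cond in ("C", "P"):
            lb, ub = getattr(net, f"lb_{cond}")[j], getattr(net, f"ub_{cond}")[j]
            bounds[f"lb_{cond}"].append(max(lb, 0.0))
            bounds[f"ub_{cond}"].append(max(ub, 0.0))
        if reversible:
            k_fwd = len(cols) - 1
            cols.append(-col)
            ids.append(rid + "_rev")
            origin_index.append(j)
            origin_dir.append(-1)
            for cond in ("C", "P"):
                lb, ub = getattr(net, f"lb_{cond}")[j], getattr(net, f"ub_{cond}")[j]
                bounds[f"lb_{cond}"].append(max(-ub, 0.0))
                bounds[f"ub_{cond}"].append(max(-lb, 0.0))
            pair_map.append((k_fwd, k_fwd + 1))

    S_split = sp.hstack(cols, format="csc")
    return SplitNetwork(
        net=net,
        S_split=S_split,
        split_ids=ids,
        origin_index=np.array(origin_index, dtype=int),
        origin_dir=np.array(origin_dir, dtype=int),
        pair_map=pair_map,
        **{k: np.array(v, dtype=float) for k, v in bounds.items()},
    )


def delta_bounds(
    split: SplitNetwork,
    overrides: dict[str, tuple[float, float]] | None = None,
) -> DeltaBounds:
    """Flux-difference bounds ``dv_min = lb_P - ub_C``, ``dv_max = ub_P - lb_C``.

    ``overrides`` maps original reaction ids to a (dv_min, dv_max) interval
    that replaces the computed one — e.g. a measured uptake-rate or
    growth-rate difference (an equality is the degenerate interval lo == hi).
    For reversible reactions the override constrains the net difference and is
    recorded in ``net_overrides``.
    """
    dv_min = split.lb_P - split.ub_C
    dv_max = split.ub_P - split.lb_C
    net_ov: dict[int, tuple[float, float]] = {}
    for rid, (lo, hi) in (overrides or {}).items():
        if lo > hi:
            raise ValueError(f"override for {rid!r} has dv_min={lo} > dv_max={hi}")
        oi = split.net.reaction_index(rid)
        k_fwd, k_bwd = split.forward_of[oi], split.backward_of[oi]
        if k_bwd < 0:
            dv_min[k_fwd], dv_max[k_fwd] = lo, hi
        else:
            net_ov[oi] = (float(lo), float(hi))
    return DeltaBounds(dv_min=dv_min, dv_max=dv_max, net_overrides=net_ov)


def read_bound_overrides(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read a TSV with columns reaction_id, dv_min, dv_max."""
    df = pd.read_csv(path, sep="\t")
    required = {"reaction_id", "dv_min", "dv_max"}
    if not required.issubset(df.columns):
        raise ValueError(f"override file must have columns {sorted(required)}")
    return {
        str(row.reaction_id): (float(row.dv_min), float(row.dv_max))
        for row in df.itertuples()
    }
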