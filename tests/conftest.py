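import numpy as np
import pytest
import scipy.sparse as sp

from deltafba.model_io import MetabolicNetwork


def make_network(reactions, metabolites, bounds, rules=None, subsystems=None):
    """Small helper: build a MetabolicNetwork from a reaction dict list.

    ``reactions`` is a list of (id, {metabolite: coef}); ``bounds`` a list of
    (lb, ub) applied to both conditions.
    """
    m_index = {m: i for i, m in enumerate(metabolites)}
    S = sp.lil_matrix((len(metabolites), len(reactions)))
    for j, (_, coefs) in enumerate(reactions):
        for met, c in coefs.items():
            S[m_index[met], j] = c
    lb = np.array([b[0] for b in bounds], dtype=float)
    ub = np.array([b[1] for b in bounds], dtype=float)
    n = len(reactions)
    return MetabolicNetwork(
        metabolite_ids=list(metabolites),
        metabolite_compartments=["c"] * len(metabolites),
        reaction_ids=[r[0] for r in reactions],
        S=sp.csc_matrix(S),
        lb_C=lb.copy(), ub_C=ub.copy(), lb_P=lb.copy(), ub_P=ub.copy(),
        gpr_rules=list(rules) if rules else [""] * n,
        subsystems=list(subsystems) if subsystems else ["Pathway"] * n,
    )


@pytest.fixture
def chain_network():
    """EX_A -> A, A -> B, B -> EX_B; all irreversible, bounds [0, 10]."""
    return make_network(
        reactions=[("EX_A", {"A": 1.0}),
                   ("R_AB", {"A": -1.0, "B": 1.0}),
                   ("EX_B", {"B": -1.0})],
        metabolites=["A", "B"],
        bounds=[(0, 10), (0, 10), (0, 10)],
        rules=["", "g1", ""],
        subsystems=["Exchange", "Conversion", "Exchange"],
    )
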