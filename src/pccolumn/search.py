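"""Exhaustive combinatorial search for prediction-error microcircuits.

The search enumerates every within-motif connectivity (nine free binary
inhibitory-source connections on top of the six mandatory edges, 2^9 = 512)
and every afferent input pattern (six free binary bottom-up/top-down target
assignments on top of the two mandatory ones, 2^6 = 64), then simulates each
of the 512 x 64 = 32,768 candidates to steady state under three scenarios:
balanced drives (BU = TD), bottom-up surplus (BU > TD) and top-down surplus
(BU < TD).  An input pattern qualifies for the PE+ role if the motif's E
cell is silent under balance and top-down surplus but responds to bottom-up
surplus; the PE- role is the mirror image.  A valid combination is a
connectivity together with one qualifying pattern for each role.

The search is deterministic and treats divergent or non-convergent
candidates as failures of the scenario in which they occur.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import DynamicsParams
from .microcircuit import (
    CELL_ORDER,
    MANDATORY_EDGES,
    CellType,
    InputPattern,
    MotifConnectivity,
    MotifSpec,
    build_motif_weights,
    motif_response,
)

__all__ = [
    "FREE_CONNECTIONS",
    "FREE_INPUTS",
    "SearchSpace",
    "ScenarioDrives",
    "SelectionThresholds",
    "CandidateResult",
    "SearchResult",
    "enumerate_connectivities",
    "enumerate_input_patterns",
    "evaluate_candidate",
    "run_search",
]

#: The nine free connections: all inhibitory-source pairs (including
#: self-connections) that are not mandatory.  E outgoing edges are fixed by
#: the constraint that E projects to all cell types, and E->E is excluded.
FREE_CONNECTIONS = (
    (CellType.PV, CellType.PV),
    (CellType.PV, CellType.SST),
    (CellType.PV, CellType.VIP),
    (CellType.SST, CellType.PV),
    (CellType.SST, CellType.SST),
    (CellType.SST, CellType.VIP),
    (CellType.VIP, CellType.E),
    (CellType.VIP, CellType.PV),
    (CellType.VIP, CellType.VIP),
)

#: The six free input assignments: bottom-up to the interneurons and
#: top-down to E, PV, SST (bottom-up to E and top-down to VIP are fixed).
FREE_INPUTS = (
    ("BU", CellType.PV),
    ("BU", CellType.SST),
    ("BU", CellType.VIP),
    ("TD", CellType.E),
    ("TD", CellType.PV),
    ("TD", CellType.SST),
)


@dataclass(frozen=True)
class SearchSpace:
    free_connections: tuple = FREE_CONNECTIONS
    free_inputs: tuple = FREE_INPUTS

    def __post_init__(self) -> None:
        if len(self.free_connections) != 9:
            raise ValueError("expected 9 free connections (2^9 = 512 connectivities)")
        if len(self.free_inputs) != 6:
            raise ValueError("expected 6 free inputs (2^6 = 64 patterns)")
        if MANDATORY_EDGES & set(self.free_connections):
            raise ValueError("free connections must be disjoint from mandatory edges")


@dataclass(frozen=True)
class ScenarioDrives:
    """(bu, td) drive pairs for the three selection scenarios.

    Pixel inputs live in [0, 1], hence the unit-magnitude defaults.
    """

    equal: tuple = (1.0, 1.0)
    bu_gt_td: tuple = (1.0, 0.5)
    bu_lt_td: tuple = (0.5, 1.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.equal, self.bu_gt_td, self.bu_lt_td], dtype=float)


@dataclass(frozen=True)
class SelectionThresholds:
    """eps separates numerically-zero E rates ("no error") from graded
    responses; theta is the minimum rate counted as an error response."""

    eps: float = 1e-3
    theta: float = 0.05


@dataclass
class CandidateResult:
    passed: bool
    e_rates_pos: np.ndarray  # E steady rates of the PE+ role, scenarios 1-3
    e_rates_neg: np.ndarray
    statuses_pos: tuple
    statuses_neg: tuple


def enumerate_connectivities(space: SearchSpace = SearchSpace()) -> list[MotifConnectivity]:
    """All 512 connectivities, in binary counting order of the free bits
    (first listed connection toggles slowest)."""
    out = []
    for bits in itertools.product((0, 1), repeat=len(space.free_connections)):
        edges = set(MANDATORY_EDGES)
        for b, edge in zip(bits, space.free_connections):
            if b:
                edges.add(edge)
        out.append(MotifConnectivity(frozenset(edges)))
    return out


def enumerate_input_patterns(space: SearchSpace = SearchSpace()) -> list[InputPattern]:
    """All 64 input patterns, in binary counting order of the free bits."""
    out = []
    for bits in itertools.product((0, 1), repeat=len(space.free_inputs)):
        bu = {CellType.E}
        td = {CellType.VIP}
        for b, (signal, target) in zip(bits, space.free_inputs):
            if b:
                (bu if signal == "BU" else td).add(target)
        out.append(InputPattern(frozenset(bu), frozenset(td)))
    return out


def _role_ok(rates: np.ndarray, statuses, respond_idx: int, thr: SelectionThresholds) -> bool:
    if any(s != "converged" for s in statuses):
        return False
    for k in range(3):
        if k == respond_idx:
            if not rates[k] > thr.theta:
                return False
        else:
            if not rates[k] < thr.eps:
                return False
    return True


def evaluate_candidate(
    conn: MotifConnectivity,
    p_pos: InputPattern,
    p_neg: InputPattern,
    drives: ScenarioDrives = ScenarioDrives(),
    thresholds: SelectionThresholds = SelectionThresholds(),
    params: DynamicsParams = DynamicsParams(),
    *,
    t_max: float = 2.0,
) -> CandidateResult:
    """Evaluate one (connectivity, PE+ pattern, PE- pattern) triple.

    The triple passes iff, across the three scenarios, the PE+ role's E cell
    responds only to bottom-up surplus and the PE- role's E cell only to
    top-down surplus; failures (including divergence or non-convergence in
    any scenario) are results, not errors.
    """
    scen = drives.as_array()
    e_idx = CellType.E.index

    def run(pattern):
        rates = np.zeros(3)
        statuses = []
        for k, (bu, td) in enumerate(scen):
            res = motif_response(conn, pattern, bu, td, params, t_max=t_max)
            rates[k] = res.state.rates[e_idx]
            statuses.append(res.status)
        return rates, tuple(statuses)

    rates_pos, st_pos = run(p_pos)
    rates_neg, st_neg = run(p_neg)
    passed = (
        p_pos != p_neg
        and _role_ok(rates_pos, st_pos, 1, thresholds)
        and _role_ok(rates_neg, st_neg, 2, thresholds)
    )
    return CandidateResult(passed, rates_pos, rates_neg, st_pos, st_neg)


def _batched_steady_states(
    conns: list[MotifConnectivity],
    patterns: list[InputPattern],
    drives: ScenarioDrives,
    params: DynamicsParams,
    t_max: float,
    tol: float,
):
    """Vectorised steady-state evaluation of every (connectivity, pattern,
    scenario) combination; agrees with :func:`evaluate_candidate` (tested).

    Returns E-rate array of shape (n_conn, n_pat, 3) plus boolean converged
    and diverged arrays of the same shape.
    """
    n_c, n_p = len(conns), len(patterns)
    scen = drives.as_array()  # (3, 2)
    # weight tensors, oriented so that drive = r @ W  (W[source, target])
    W = np.stack([build_motif_weights(c) for c in conns])  # (n_c, 4, 4)
    bu_vecs = np.stack([p.bu_vector for p in patterns])  # (n_p, 4)
    td_vecs = np.stack([p.td_vector for p in patterns])
    ext = scen[None, :, 0, None] * bu_vecs[:, None, :] + scen[None, :, 1, None] * td_vecs[:, None, :]
    ext = np.broadcast_to(ext.reshape(1, n_p * 3, 4), (n_c, n_p * 3, 4))

    tau = np.array(
        [params.tau_exc if c is CellType.E else params.tau_inh for c in CELL_ORDER]
    )
    coef = params.dt / tau
    r = np.zeros((n_c, n_p * 3, 4))
    cap = params.rate_cap
    for _ in range(int(round(t_max / params.dt))):
        target = np.matmul(r, W) + ext
        np.maximum(target, 0.0, out=target)
        r += coef * (target - r)
        # keep runaway candidates finite; they stay above cap and are
        # classified as diverged below
        np.clip(r, 0.0, 10.0 * cap, out=r)
    target = np.maximum(np.matmul(r, W) + ext, 0.0)
    resid = np.abs(target - r).max(axis=2)
    diverged = (r.max(axis=2) > cap).reshape(n_c, n_p, 3)
    converged = (resid < tol).reshape(n_c, n_p, 3) & ~diverged
    e_rates = r[:, :, CellType.E.index].reshape(n_c, n_p, 3)
    return e_rates, converged, diverged


@dataclass
class SearchResult:
    """Full outcome of the exhaustive search.

    ``valid_combinations`` lists every passing (connectivity, PE+ pattern,
    PE- pattern) triple as index pairs into the enumerations;
    ``materialize`` turns one into a :class:`MotifSpec`.
    """

    connectivities: list
    patterns: list
    e_rates: np.ndarray  # (512, 64, 3)
    converged: np.ndarray
    diverged: np.ndarray
    thresholds: SelectionThresholds
    drives: ScenarioDrives
    valid_combinations: list = field(default_factory=list)  # (conn_i, pos_i, neg_i)

    @property
    def n_evaluated(self) -> int:
        return len(self.connectivities) * len(self.patterns)

    @property
    def n_valid(self) -> int:
        return len(self.valid_combinations)

    @property
    def n_valid_connectivities(self) -> int:
        return len({c for c, _, _ in self.valid_combinations})

    def role_masks(self, thresholds: SelectionThresholds | None = None):
        """Boolean (n_conn, n_pat) masks of PE+ and PE- qualifying pairs."""
        thr = thresholds or self.thresholds
        ok = (self.converged & ~self.diverged).all(axis=2)
        r = self.e_rates
        is_pos = ok & (r[:, :, 0] < thr.eps) & (r[:, :, 1] > thr.theta) & (r[:, :, 2] < thr.eps)
        is_neg = ok & (r[:, :, 0] < thr.eps) & (r[:, :, 1] < thr.eps) & (r[:, :, 2] > thr.theta)
        return is_pos, is_neg

    def count_valid(self, thresholds: SelectionThresholds | None = None) -> int:
        """Number of valid triples under (possibly alternative) thresholds,
        used to report robustness of the count across an (eps, theta) grid."""
        is_pos, is_neg = self.role_masks(thresholds)
        return int((is_pos.sum(axis=1) * is_neg.sum(axis=1)).sum())

    def materialize(self, combo) -> MotifSpec:
        c, p, q = combo
        return MotifSpec(self.connectivities[c], self.patterns[p], self.patterns[q])

    def contains(self, spec: MotifSpec) -> bool:
        try:
            c = self.connectivities.index(spec.conn)
            p = self.patterns.index(spec.input_pos)
            q = self.patterns.index(spec.input_neg)
        except ValueError:
            return False
        return (c, p, q) in set(self.valid_combinations)

    def to_dataframe(self) -> pd.DataFrame:
        """One row per valid triple: free-bit booleans and per-scenario
        steady E rates for both roles."""
        rows = []
        conn_names = [f"{s.value}->{t.value}" for s, t in FREE_CONNECTIONS]
        inp_names = [f"{sig}->{t.value}" for sig, t in FREE_INPUTS]
        for c, p, q in self.valid_combinations:
            conn = self.connectivities[c]
            row = {"conn_index": c, "pos_index": p, "neg_index": q}
            for name, edge in zip(conn_names, FREE_CONNECTIONS):
                row[f"conn[{name}]"] = edge in conn.edges
            for role, idx in (("pos", p), ("neg", q)):
                pat = self.patterns[idx]
                for name, (sig, t) in zip(inp_names, FREE_INPUTS):
                    members = pat.bu_targets if sig == "BU" else pat.td_targets
                    row[f"{role}[{name}]"] = t in members
                for k, scen in enumerate(("equal", "bu_gt_td", "bu_lt_td")):
                    row[f"{role}_E_{scen}"] = self.e_rates[c, idx, k]
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "n_evaluated": self.n_evaluated,
            "n_connectivities": len(self.connectivities),
            "n_input_patterns": len(self.patterns),
            "n_valid": self.n_valid,
            "n_valid_connectivities": self.n_valid_connectivities,
            "thresholds": {"eps": self.thresholds.eps, "theta": self.thresholds.theta},
            "drives": {
                "equal": list(self.drives.equal),
                "bu_gt_td": list(self.drives.bu_gt_td),
                "bu_lt_td": list(self.drives.bu_lt_td),
            },
        }


def run_search(
    space: SearchSpace = SearchSpace(),
    drives: ScenarioDrives = ScenarioDrives(),
    thresholds: SelectionThresholds = SelectionThresholds(),
    params: DynamicsParams = DynamicsParams(),
    *,
    t_max: float = 2.0,
    tol: float = 1e-6,
) -> SearchResult:
    """Run the exhaustive, deterministic search over 512 x 64 candidates.

    Every candidate motif is simulated to steady state (2 s horizon) in each
    of the three scenarios; a valid combination is a connectivity with one
    PE+-qualifying and one PE--qualifying input pattern.
    """
    conns = enumerate_connectivities(space)
    patterns = enumerate_input_patterns(space)
    e_rates, converged, diverged = _batched_steady_states(
        conns, patterns, drives, params, t_max, tol
    )
    result = SearchResult(conns, patterns, e_rates, converged, diverged, thresholds, drives)
    is_pos, is_neg = result.role_masks()
    for c in range(len(conns)):
        pos_idx = np.flatnonzero(is_pos[c])
        neg_idx = np.flatnonzero(is_neg[c])
        for p in pos_idx:
            for q in neg_idx:
                result.valid_combinations.append((c, int(p), int(q)))
    return result
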