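"""The four-cell-type prediction-error motif and the representation circuit.

A prediction-error (PE) microcircuit contains one rate unit per cell type —
excitatory (E), PV, SST and VIP — wired by a binary connectivity pattern in
which every existing synapse has magnitude one and carries the sign of its
source (Dale's principle).  Six connections are mandatory on neurobiological
grounds: E projects to all three interneurons, PV and SST inhibit E, and
VIP inhibits SST (the disinhibitory route).  The same connectivity computes
a positive prediction error (active when bottom-up exceeds top-down input)
or a negative one (active when top-down exceeds bottom-up), depending only
on which cell types receive the bottom-up and top-down afferents.

The representation circuit of the higher area is a hard-wired one-to-one
L4 E <-> L4 PV recurrent pair plus an L5 E population that faithfully
relays L4 E activity as the top-down prediction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .dynamics import ConvergenceResult, DynamicsParams, run_to_convergence

__all__ = [
    "CellType",
    "CELL_ORDER",
    "MANDATORY_EDGES",
    "MotifConnectivity",
    "InputPattern",
    "MotifSpec",
    "RepCircuitSpec",
    "build_motif_weights",
    "motif_response",
    "default_motif_spec",
]


class CellType(enum.Enum):
    """E, PV, SST or VIP; the synaptic sign follows from the label."""

    E = "E"
    PV = "PV"
    SST = "SST"
    VIP = "VIP"

    @property
    def sign(self) -> int:
        return 1 if self is CellType.E else -1

    @property
    def index(self) -> int:
        return CELL_ORDER.index(self)

    @property
    def is_inhibitory(self) -> bool:
        return self is not CellType.E


CELL_ORDER = (CellType.E, CellType.PV, CellType.SST, CellType.VIP)

#: Connections required in every motif: E drives all interneurons, PV and
#: SST inhibit E, VIP disinhibits E through SST.
MANDATORY_EDGES = frozenset(
    {
        (CellType.E, CellType.PV),
        (CellType.E, CellType.SST),
        (CellType.E, CellType.VIP),
        (CellType.PV, CellType.E),
        (CellType.SST, CellType.E),
        (CellType.VIP, CellType.SST),
    }
)


def _as_celltype(x) -> CellType:
    return x if isinstance(x, CellType) else CellType(str(x))


@dataclass(frozen=True)
class MotifConnectivity:
    """Binary (source, target) edge set among the four cell types.

    Must contain all mandatory edges; the E->E self-connection is excluded.
    Edge weight magnitude is fixed at one and is not plastic.
    """

    edges: frozenset = field(default=MANDATORY_EDGES)

    def __post_init__(self) -> None:
        edges = frozenset((_as_celltype(s), _as_celltype(t)) for s, t in self.edges)
        object.__setattr__(self, "edges", edges)
        missing = MANDATORY_EDGES - edges
        if missing:
            names = sorted(f"{s.value}->{t.value}" for s, t in missing)
            raise ValueError(f"missing mandatory connection(s): {', '.join(names)}")
        if (CellType.E, CellType.E) in edges:
            raise ValueError("E->E self-connection is not allowed")

    @property
    def adj(self) -> np.ndarray:
        """4x4 binary presence matrix, entry (source, target)."""
        a = np.zeros((4, 4))
        for s, t in self.edges:
            a[s.index, t.index] = 1.0
        return a

    def extra_edges(self) -> frozenset:
        return self.edges - MANDATORY_EDGES

    def without(self, source: CellType, target: CellType) -> "MotifConnectivity":
        """Copy with one non-mandatory edge removed (for ablation tests)."""
        edge = (_as_celltype(source), _as_celltype(target))
        if edge in MANDATORY_EDGES:
            raise ValueError("cannot remove a mandatory connection")
        return MotifConnectivity(self.edges - {edge})


@dataclass(frozen=True)
class InputPattern:
    """Which cell types receive the bottom-up and top-down afferents.

    E always receives bottom-up input and VIP always receives top-down
    input; the remaining memberships are free.
    """

    bu_targets: frozenset = field(default=frozenset({CellType.E}))
    td_targets: frozenset = field(default=frozenset({CellType.VIP}))

    def __post_init__(self) -> None:
        bu = frozenset(_as_celltype(c) for c in self.bu_targets)
        td = frozenset(_as_celltype(c) for c in self.td_targets)
        object.__setattr__(self, "bu_targets", bu)
        object.__setattr__(self, "td_targets", td)
        if CellType.E not in bu:
            raise ValueError("E must receive bottom-up input")
        if CellType.VIP not in td:
            raise ValueError("VIP must receive top-down input")

    @property
    def bu_vector(self) -> np.ndarray:
        return np.array([1.0 if c in self.bu_targets else 0.0 for c in CELL_ORDER])

    @property
    def td_vector(self) -> np.ndarray:
        return np.array([1.0 if c in self.td_targets else 0.0 for c in CELL_ORDER])


@dataclass(frozen=True)
class MotifSpec:
    """One connectivity shared by two input patterns: the PE+ role (responds
    to bottom-up surplus) and the PE- role (responds to top-down surplus)."""

    conn: MotifConnectivity
    input_pos: InputPattern
    input_neg: InputPattern

    # -- serialization: a motif is a versioned config artifact ------------

    def to_dict(self) -> dict:
        def pat(p: InputPattern) -> dict:
            return {
                "bu_targets": sorted(c.value for c in p.bu_targets),
                "td_targets": sorted(c.value for c in p.td_targets),
            }

        conn = {
            f"{s.value}->{t.value}": True
            for s, t in sorted(self.conn.edges, key=lambda e: (e[0].index, e[1].index))
        }
        return {"connectivity": conn, "input_pos": pat(self.input_pos), "input_neg": pat(self.input_neg)}

    @classmethod
    def from_dict(cls, d: dict) -> "MotifSpec":
        edges = frozenset(
            tuple(CellType(x) for x in key.split("->"))
            for key, present in d["connectivity"].items()
            if present
        )

        def pat(p: dict) -> InputPattern:
            return InputPattern(
                bu_targets=frozenset(CellType(c) for c in p["bu_targets"]),
                td_targets=frozenset(CellType(c) for c in p["td_targets"]),
            )

        return cls(MotifConnectivity(edges), pat(d["input_pos"]), pat(d["input_neg"]))

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "MotifSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class RepCircuitSpec:
    """Representation circuit of the higher area: n one-to-one columns of
    L4 E <-> L4 PV (E excites PV, PV inhibits E, both with unit weight) and
    an L5 E relay of L4 E."""

    n_units: int = 784

    def __post_init__(self) -> None:
        if self.n_units <= 0:
            raise ValueError("n_units must be positive")


def build_motif_weights(conn: MotifConnectivity) -> np.ndarray:
    """Signed 4x4 weight matrix, entry (source, target) = sign(source)*adj.

    Rows of inhibitory cells are <= 0 and the E row is >= 0 by construction.
    """
    signs = np.array([c.sign for c in CELL_ORDER], dtype=float)
    return conn.adj * signs[:, None]


def motif_response(
    conn: MotifConnectivity,
    pattern: InputPattern,
    bu: float,
    td: float,
    params: DynamicsParams,
    *,
    tol: float = 1e-6,
    t_max: float = 2.0,
) -> ConvergenceResult:
    """Steady response of a single 4-unit motif to constant drives.

    ``bu`` is added to every cell in ``pattern.bu_targets`` and ``td`` to
    every cell in ``pattern.td_targets``.  Divergence and non-convergence
    are reported in the result status, not raised: both are legitimate
    outcomes of the circuit search.
    """
    if bu < 0 or td < 0:
        raise ValueError("drives must be non-negative")
    weights = build_motif_weights(conn).T  # row = target for the integrator
    drive = bu * pattern.bu_vector + td * pattern.td_vector
    tau = np.array(
        [params.tau_exc if c is CellType.E else params.tau_inh for c in CELL_ORDER]
    )
    return run_to_convergence(weights, drive, params, tau=tau, tol=tol, t_max=t_max)


def default_motif_spec() -> MotifSpec:
    """The frozen motif used by default network configurations.

    One of the valid configurations found by :func:`pccolumn.search.run_search`,
    selected because it also reproduces the qualitative network-level
    behaviours (damped inference rhythm, silencing taxonomy, oddball
    response) and shipped as a versioned YAML artifact.
    """
    path = Path(__file__).parent / "data" / "default_motif.yaml"
    return MotifSpec.load(path)
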