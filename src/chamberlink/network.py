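"""Distance-contrast interaction networks for paired-strain consortia.

A strain's growth statistic measured at the closest (25 um) and farthest
(250 um) separation from its partner defines a directed interaction: the
partner's effect strength on the strain is

    D_d = 1 - D_25 / D_250,

and the node size for display scales as (10 ln(1/D_25))^2.

By default the statistic D is the strain's doubling time: if a strain doubles
faster near its partner (D_25 < D_250), D_d > 0 and the incoming edge is
positive (the strain benefits from proximity).  A rate-based mode is exposed
for statistics where larger means better; the caption-level ambiguity between
the two readings is documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
import json
import math

__all__ = [
    "InteractionEdge",
    "InteractionNetwork",
    "interaction_strength",
    "node_size",
    "classify_edge",
    "network_from_doubling_times",
]

DEFAULT_NEUTRAL_BAND = 0.1


def interaction_strength(D25: float, D250: float) -> float:
    """Edge strength 1 - D_25 / D_250 (0 when distance has no effect)."""
    if D250 <= 0:
        raise ZeroDivisionError("D250 must be positive")
    if D25 < 0:
        raise ValueError("D25 must be non-negative")
    return 1.0 - D25 / D250

def node_size(D25: float) -> float:
    """Display size (10 ln(1/D_25))^2 from the near-separation statistic."""
    if D25 <= 0:
        raise ValueError("D25 must be positive")
    return (10.0 * math.log(1.0 / D25)) ** 2


def classify_edge(D_d: float, neutral_band: float = DEFAULT_NEUTRAL_BAND) -> str:
    """'neutral' inside +/- neutral_band, else the sign of the strength."""
    if neutral_band < 0:
        raise ValueError("neutral_band must be non-negative")
    if abs(D_d) <= neutral_band:
        return "neutral"
    return "positive" if D_d > 0 else "negative"


@dataclass
class InteractionEdge:
    source: str                 # the strain whose proximity acts
    target: str                 # the strain whose statistic responds
    strength: float
    sign: str


@dataclass
class InteractionNetwork:
    """Two-strain signed network with per-node display sizes."""

    nodes: dict[str, dict]      # name -> {"D25":, "D250":, "node_size":}
    edges: list[InteractionEdge]

    def edge(self, source: str, target: str) -> InteractionEdge:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e
        raise KeyError(f"no edge {source}->{target}")

    def to_json(self) -> str:
        return json.dumps({
            "nodes": self.nodes,
            "edges": [vars(e) for e in self.edges],
        }, indent=2)


def network_from_doubling_times(stats: dict[str, dict[float, float]],
                                neutral_band: float = DEFAULT_NEUTRAL_BAND,
                                near_um: float = 25.0,
                                far_um: float = 250.0) -> InteractionNetwork:
    """Build the two-strain network from per-strain distance-resolved
    doubling times ``{strain: {distance_um: doubling_time}}``.

    The directed edge partner->strain uses the strain's own doubling times at
    the near and far separations; with the doubling-time convention a
    positive strength means the strain grows faster when its partner is
    close.
    """
    strains = sorted(stats)
    if len(strains) != 2:
        raise ValueError("expected exactly two strains")
    nodes, edges = {}, []
    for strain in strains:
        d25 = stats[strain][near_um]
        d250 = stats[strain][far_um]
        nodes[strain] = {"D25": d25, "D250": d250,
                         "node_size": node_size(d25) if d25 > 0 else float("nan")}
        strength = interaction_strength(d25, d250)
        partner = strains[1] if strain == strains[0] else strains[0]
        edges.append(InteractionEdge(source=partner, target=strain,
                                     strength=strength,
                                     sign=classify_edge(strength, neutral_band)))
    return InteractionNetwork(nodes=nodes, edges=edges)
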